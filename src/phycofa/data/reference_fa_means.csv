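fa_label,Chlorella vulgaris,Chlorococcum amblystomatis,Scenedesmus obliquus,Tetraselmis chui,Phaeodactylum tricornutum,Spirulina sp.,Nannochloropsis oceanica
C12:0,,,,,,,0.2
C14:0,0.3,1.4,0.5,0.5,4.2,0.1,3.5
C15:0,0.3,0.2,0.2,0.2,0.3,,0.2
C16:0,,21.5,14.9,24.2,14.7,38.6,22.6
C16:1,,,2.9,,,,
C16:1 ∆11 (ω-5),,0.5,2.7,0.4,1.3,,0.7
C16:1 ∆9 (ω-7),2.4,8.9,1.3,1.1,16.4,5.1,21.6
C16:1 ∆7 (ω-9),0.9,,1.2,0.7,0.2,1.6,0.1
C16:2,,,,,0.8,,
"C16:2 ∆9,12 (ω-4)",,,,,5.1,0.2,
"C16:2 ∆7,10 (ω-6)",6.7,0.3,0.3,0.5,,,0.1
"C16:3 ∆7,10,13 (ω-3)",14.2,0.8,0.7,1.3,0.2,,
"C16:3 ∆6,9,12 (ω-4)",,,,,4.7,,
"C16:3 ∆4,7,10 (ω-6)",,0.7,0.2,0.4,,,
"C16:4 ∆6,9,12,15 (ω-1)",,,,,7.6,,
"C16:4 ∆4,7,10,13 (ω-3)",,12.7,15.5,14.5,0.6,,
C17:0,0.7,0.2,0.3,0.1,0.1,0.2,0.1
C17:1,0.5,0.2,0.1,,,0.2,0.4
C18:0,6.5,4.0,9.7,8.8,3.7,5.4,6.3
C18:1 ∆11 (ω-7),2.3,4.4,1.8,4.8,2.6,1.4,0.5
C18:1 ∆9 (ω-9),4.1,2.2,4.3,7.0,1.3,2.6,4.1
"C18:2 ∆9,12 (ω-6)",17.6,2.9,3.5,3.6,3.1,21.4,3.2
"C18:3 ∆9,12,15 (ω-3)",26.3,21.9,35.0,18.3,1.8,,
"C18:3 ∆6,9,12 (ω-6)",,1.3,0.4,2.3,0.2,23.3,0.2
"C18:4 ∆6,9,12,15 (ω-3)",,4.0,4.7,6.3,0.5,,
C20:1 ∆11,,,,0.6,,,
"C20:3 ∆5,11,14 (ω-6)",,,,,0.3,,
"C20:4 ∆5,11,14,17 (ω-3)",,,,,0.3,,
"C20:4 ∆5,8,11,14 (ω-6)",,1.5,,0.3,1.1,,5.3
"C20:5 ∆5,8,11,14,17 (ω-3)",,10.7,,4.2,27.3,,30.8
"C22:6 ∆4,7,10,13,16,19 (ω-3)",,,,,0.6,,
C24:0,,,,,0.9,,
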