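# Methods

This note records the models, conventions and numerical choices behind
`phycofa`, and what the synthetic-data tests do and do not demonstrate.

## FA nomenclature

Labels follow the `C<carbons>:<double bonds>` shorthand with optional
carboxyl-numbered double-bond positions (Δ list) and an ω class counted from
the methyl terminus (terminal methyl carbon = 1), so that
`ω = carbons − max(Δ)`. Parsing strips typographic decoration (superscript
markers, bold markers, unicode delta/omega/minus variants) before applying
the grammar; decoration is transport noise, not chemistry. Three validation
rules are enforced: the Δ-list length must equal the double-bond count, Δ
positions must be strictly increasing within `[2, carbons−1]`, and an ω tag
that contradicts the Δ list is an error — it is never silently corrected,
because either the positions or the tag is wrong and the package cannot know
which. Labels with unsaturation but no positional information (e.g. a bare
`C16:1`) are retained with absent optional fields; they count toward
MUFA/PUFA class sums but never toward ω-class sums, since their ω class is
unknowable from the label. The canonical form is `C<c>:<d> [d<p1,...>]
[n-<ω>]`; parsing a canonical string is the identity on the descriptor
(with ω completed from Δ when only Δ is given).

## Profiles and closure

A profile maps canonical labels to relative abundance in % of total FA.
Blank table cells mean "not detected" and are 0. Closure to exactly 100% is
available (`normalize_profile`) and accepts raw totals in [95, 105];
anything outside signals an incomplete or corrupted column and is rejected
with the offending sum. Index computation does not require closure: AI and
h/H are ratios of linear forms and are scale-invariant as written. TI is
not — its Σω-3/Σω-6 ratio term is dimensionless while the other denominator
terms carry abundance units — so TI interprets its inputs on the percent
scale by closing all sums internally; this makes all three indices invariant
under uniform rescaling of a profile, which property tests assert.

The packaged reference table carries the seven-species mean compositions
(32 FA labels). One column (Chlorella vulgaris) omits its C16:0 value in
the source and totals only ≈82.8%; every quantity involving C16:0 for that
species (AI, TI, h/H, ΣSFA) is therefore flagged non-reproducible — the
report manifest carries a warning naming the absent index inputs — rather
than imputed.

## Nutritional indices

The canonical Ulbricht–Southgate forms are used:

* `AI = (C12:0 + 4·C14:0 + C16:0) / (ΣMUFA + Σn-6 + Σn-3)`
* `TI = (C14:0 + C16:0 + C18:0) / (0.5·ΣMUFA + 0.5·Σn-6 + 3·Σn-3 + Σn-3/Σn-6)`
* `h/H = (C18:1 n-9 + C18:2 n-6 + C18:3 n-3 + C20:4 n-6 + C20:5 n-3) / (C14:0 + C16:0)`

Index denominators use ΣMUFA + Σω-6 + Σω-3, not ΣPUFA: PUFA of other ω
classes (ω-1, ω-4, ω-5, and PUFA without ω annotation) are excluded,
consistent with the Σ(n−6)/Σ(n−3) symbols of the published equations. Edge
cases: Σω-3 = 0 makes the TI ratio term 0 and the ω-6/ω-3 ratio absent
(never 0 or ∞); Σω-3 > 0 with Σω-6 = 0 leaves TI undefined (absent with a
diagnostic); a zero denominator makes the respective index absent. Numerator
FAs are matched by (chain length, unsaturation, ω class) rather than exact
label string, so positional spelling variants of e.g. oleic acid all count.

Per-species summaries compute indices per replicate and then average
(sample SD, n−1). Whether a published summary table averaged per-replicate
indices or took indices of mean profiles is generally unstated; the two
differ in the second decimal at typical replicate noise (e.g. an h/H of
2.8 from mean profiles vs a printed 2.9), which is why the recomputation
tests assert only the arithmetically self-consistent cells. All arithmetic
is at full precision; rounding is half-up to one decimal, at presentation
only.

## Scavenging assays

Inhibition uses the colour-corrected grouping
`100·(A_radical − (A_sample − A_control))/A_radical`: the control well
(sample plus solvent, no radical) measures the extract's own absorbance, so
adding the same colour offset to sample and control cancels exactly (an
invariant under test). ICs are computed at the reading nearest 120 min, the
protocol endpoint; earlier readings are retained for QC only. The
dose–response model is deliberately a straight line fitted by OLS — matching
the source protocol — not a 4-parameter logistic; `ICx = (x − intercept)/
slope`. A non-positive slope is a no-convergence signal (exception), not a
number. ICs outside the tested concentration range are returned but flagged
extrapolated. Replicates are averaged before regression (matching
triplicate mean ± SD reporting); per-replicate regression is available as
an option to propagate an IC SD, since how published SDs were propagated is
unstated. Inhibition may be negative (pro-oxidant/noise) and is clipped only
at presentation. The reported level is a per-assay parameter defaulting to
IC50 for ABTS and IC20 for DPPH. `TE = 1000·IC_Trolox/IC_sample`; by
construction TE·IC_sample recovers a single assay-wide Trolox IC, a
consistency property the tests check against the two published ABTS pairs
(agreement within 0.1%).

## Statistics

* **glog**: `log2((x + √(x² + λ²))/2)`, λ > 0 defaulting to the smallest
  positive value of the matrix — the common metabolomics default when only
  the software is named. λ is recorded in outputs and configurable.
* **PCA**: SVD of the column-centered glog matrix (centering optional, no
  unit-variance scaling: glog output is already variance-stabilised).
  Components with numerically zero variance are dropped; fractions are
  eigenvalues over their sum. Sign is fixed by making each loading vector's
  largest-magnitude entry positive. Validation is by property (fractions
  sum to 1, match a covariance-eigenvalue oracle, row-permutation
  invariance); the exact published variance percentages are not targets
  because the replicate-level matrix behind them is unpublished.
* **Clustering**: Ward linkage on Euclidean distances of the glog matrix,
  rows sorted lexicographically first so ties break deterministically;
  export to Newick with branch lengths from merge heights.
* **Kruskal–Wallis/Dunn**: scipy's tie-corrected H; Dunn z from mean joint
  ranks with the tie term Σ(t³−t)/(12(N−1)), implemented in-package.
  Pairwise p are adjusted per variable by Benjamini–Hochberg step-up
  (Benjamini–Yekutieli by flag). Letters follow the
  shared-letter-marks-a-significant-pair convention (q < 0.05), one letter
  per significant pair, and the letter assignment round-trips to the
  significant-pair set.
* **Correlation**: Pearson and Spearman both reported (the appropriate
  choice for a 7-point species summary is debatable). The Spearman p is an
  exact permutation enumeration for n ≤ 8, a t approximation above.

## Synthetic data

The profile generator perturbs each species' mean composition
multiplicatively with log-normal factors of unit mean and configured CV
(default 0.05, i.e. SDs proportional to means, the pattern seen in
published FA tables), then re-closes each replicate to 100%. Defaults are
5 replicates per species, matching the reference protocol. Closure has a
compositional consequence worth knowing: the realised CV of dominant FAs
(share ≫ 10%) is damped below the nominal CV because part of their noise is
absorbed by the total, while minor FAs realise the nominal CV; the
calibration test therefore checks CV recovery on FAs with share ≤ 5%.
Zeros stay exactly zero — the generator never invents an FA.

The plate generator anchors a linear truth through `(true_ic, level)` with a
default slope reaching 100% inhibition at the top tested concentration
(full quench at the highest dose), which keeps every absorbance
non-negative; a user-set slope that pushes truth past 100% triggers a
warning and absorbance flooring. Absorbance relaxes exponentially from the
radical working value (0.9 AU, the protocol's working-solution absorbance)
to its endpoint truth, reaching it exactly at 120 min so that noise-free
recovery is exact to machine precision; the kinetic shape is a modelling
convenience and not part of any contract. Control wells carry a 0.01 AU
constant colour offset to exercise the correction path; Gaussian noise
(default experiments: 0.005 AU) is added per reading. Everything is
deterministic per seed.

Parameter-recovery experiments use the protocol's 1:5:10:20 dilution
pattern scaled to bracket the truth IC (0.25/1.25/2.5/5 × true_ic), the way
a plate ladder is chosen to bracket an expected IC; with the published IC50
values as truth, noisy recovery lands within 5% in ≥ 9 of 10 seeds, and the
simulated-replicate index means land within 1% of the generating truth at
n = 1000.

What passing these tests shows — and does not. They demonstrate that the
reduction pipeline is unbiased and correctly calibrated under its own
generative assumptions (independent multiplicative noise, linear
dose–response, additive read noise). Real plates have saturating
dose–response curves, drift, and edge effects; real FA tables have
correlated noise between FAs sharing biosynthetic pathways. None of these
are simulated, so the tests validate the arithmetic and statistics, not the
assay chemistry.

## Problem sizes

The default test suite and the acceptance script run on the packaged
seven-species table, 10-seed × 2-truth plate recoveries, 1000-replicate
profile simulations and a 500-iteration null-calibration of the
multiplicity control; the whole suite completes in well under a minute on
one core.

## Known limitations

* Absolute quantification (µg FA per mg biomass) and internal-standard
  correction are out of scope; the pipeline starts from identified
  relative-abundance tables.
* cis/trans isomers, branched chains and oxygenated FAs are not modelled.
* The linear ICx model extrapolates poorly outside the tested range
  (flagged, not forbidden).
* Significance letters assign one letter per significant pair, which is
  compact only when few pairs differ (true for per-index species
  comparisons, not for all-FA comparisons).
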