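"""CSV readers/writers and the packaged seven-species reference table.

Two FA-table dialects are supported (UTF-8, RFC-4180, decimal point):

* long — ``species,replicate,fa_label,abundance_pct``, one row per value;
* wide — first column ``fa_label``, one column per species (used by the
  packaged mean-composition table; blank cells mean "not detected" = 0).

Plate kinetics use the long dialect
``assay,well,role,analyte,concentration,conc_units,time_min,absorbance``.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path

import pandas as pd

from .antioxidant_assay import PlateKineticsRecord
from .fa_nomenclature import parse_fa_label
from .lipid_metrics import FAProfile

__all__ = [
    "SPECIES_PHYLUM",
    "CHLOROPHYTA",
    "load_reference_means",
    "reference_profiles",
    "read_fa_table",
    "write_fa_table",
    "profiles_to_matrix",
    "read_plate_table",
    "write_plate_table",
    "write_json",
]

#: Phylum membership of the seven reference species.
SPECIES_PHYLUM = {
    "Chlorella vulgaris": "Chlorophyta",
    "Chlorococcum amblystomatis": "Chlorophyta",
    "Scenedesmus obliquus": "Chlorophyta",
    "Tetraselmis chui": "Chlorophyta",
    "Phaeodactylum tricornutum": "Bacillariophyta",
    "Spirulina sp.": "Cyanobacteria",
    "Nannochloropsis oceanica": "Ochrophyta",
}

CHLOROPHYTA = tuple(s for s, p in SPECIES_PHYLUM.items() if p == "Chlorophyta")


def load_reference_means() -> pd.DataFrame:
    """Packaged species × FA mean composition matrix (%), canonical labels.

    Blank source cells are 0 ("not detected").  Note the Chlorella vulgaris
    column omits its C16:0 value in the source and therefore closes well
    below 100%; quantities involving C16:0 for that species are not
    reproducible from this table (see :func:`phycofa.lipid_metrics.missing_index_inputs`).
    """
    ref = importlib.resources.files("phycofa") / "data" / "reference_fa_means.csv"
    with importlib.resources.as_file(ref) as path:
        wide = pd.read_csv(path)
    wide["fa_label"] = [parse_fa_label(l).label for l in wide["fa_label"]]
    wide = wide.set_index("fa_label").fillna(0.0)
    return wide.T  # species x FA


def reference_profiles() -> list[FAProfile]:
    """The packaged mean table as one single-replicate profile per species."""
    means = load_reference_means()
    return [
        FAProfile(
            species_id=str(sp),
            replicate_id="mean",
            abundances={l: float(v) for l, v in row.items()},
        )
        for sp, row in means.iterrows()
    ]


def read_fa_table(path: str | Path, dialect: str = "long") -> list[FAProfile]:
    """Read an FA table into profiles, canonicalizing every label.

    Raises on empty files, duplicate (species, replicate, fa) triples and
    unparseable labels (naming the offending line).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if dialect == "wide":
        if df.columns[0] != "fa_label":
            raise ValueError(f"{path}: wide dialect requires a leading fa_label column")
        long_rows = df.melt(
            id_vars="fa_label", var_name="species", value_name="abundance_pct"
        )
        long_rows["replicate"] = "mean"
        df = long_rows.dropna(subset=["abundance_pct"])
    elif dialect != "long":
        raise ValueError(f"unknown dialect {dialect!r}")
    required = {"species", "replicate", "fa_label", "abundance_pct"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")

    profiles: dict[tuple[str, str], dict[str, float]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            label = parse_fa_label(str(row.fa_label)).label
        except ValueError as exc:
            raise ValueError(f"{path} line {i + 2}: {exc}") from exc
        key = (str(row.species), str(row.replicate))
        bucket = profiles.setdefault(key, {})
        if label in bucket:
            raise ValueError(
                f"{path} line {i + 2}: duplicate entry for "
                f"({key[0]}, {key[1]}, {label})"
            )
        value = float(row.abundance_pct) if pd.notna(row.abundance_pct) else 0.0
        bucket[label] = value
    return [
        FAProfile(species_id=sp, replicate_id=rep, abundances=ab)
        for (sp, rep), ab in profiles.items()
    ]


def write_fa_table(profiles: list[FAProfile], path: str | Path) -> None:
    """Write profiles in the long dialect."""
    rows = [
        {
            "species": p.species_id,
            "replicate": p.replicate_id,
            "fa_label": label,
            "abundance_pct": value,
        }
        for p in profiles
        for label, value in p.abundances.items()
    ]
    frame = pd.DataFrame(rows)
    # repr is the shortest lossless float form; pandas' default truncates
    frame["abundance_pct"] = frame["abundance_pct"].map(repr)
    frame.to_csv(path, index=False)


def profiles_to_matrix(profiles: list[FAProfile]) -> pd.DataFrame:
    """Replicate × FA abundance matrix (rows ``species|replicate``), zeros filled."""
    rows = {
        f"{p.species_id}|{p.replicate_id}": p.abundances for p in profiles
    }
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)


PLATE_COLUMNS = [
    "assay",
    "well",
    "role",
    "analyte",
    "concentration",
    "conc_units",
    "time_min",
    "absorbance",
]


def read_plate_table(path: str | Path) -> list[PlateKineticsRecord]:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    group_keys = ["assay", "well", "role"]
    for (assay, well, role), grp in df.groupby(group_keys, sort=False):
        grp = grp.sort_values("time_min")
        analyte = grp["analyte"].iloc[0]
        conc = grp["concentration"].iloc[0]
        units = grp["conc_units"].iloc[0]
        records.append(
            PlateKineticsRecord(
                assay=str(assay),
                well_id=str(well),
                role=str(role),
                analyte_id=None if pd.isna(analyte) else str(analyte),
                concentration=None if pd.isna(conc) else float(conc),
                conc_units=None if pd.isna(units) else str(units),
                series=list(
                    zip(grp["time_min"].astype(float), grp["absorbance"].astype(float))
                ),
            )
        )
    return records


def write_plate_table(records: list[PlateKineticsRecord], path: str | Path) -> None:
    rows = [
        {
            "assay": r.assay,
            "well": r.well_id,
            "role": r.role,
            "analyte": r.analyte_id,
            "concentration": r.concentration,
            "conc_units": r.conc_units,
            "time_min": t,
            "absorbance": a,
        }
        for r in records
        for t, a in r.series
    ]
    frame = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    for col in ("time_min", "absorbance"):
        frame[col] = frame[col].map(repr)
    frame.to_csv(path, index=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
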