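"""Orchestration of the full analysis into a report bundle.

``run_full_analysis`` executes, in order: profile aggregation (class sums and
nutritional indices with per-species significance letters), multivariate
statistics (glog → PCA, Ward clustering) and — when plate data are present —
the scavenging-assay reduction; it writes CSV outputs, a Newick tree and a
machine-readable JSON manifest (versions, seed, parameters, warnings).
"""

from __future__ import annotations

import datetime
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import sklearn

from . import __version__
from . import antioxidant_assay as ax
from . import io as pio
from . import lipid_metrics as lm
from . import stats_multivariate as sm

log = logging.getLogger("phycofa")

__all__ = ["RunConfig", "run_full_analysis"]


@dataclass
class RunConfig:
    """Inputs and options for one analysis run."""

    profiles_csv: str | None = None
    profiles_dialect: str = "long"
    plate_csv: str | None = None
    outdir: str = "phycofa_out"
    assay_levels: dict[str, float] = field(
        default_factory=lambda: dict(ax.DEFAULT_LEVELS)
    )
    glog_lambda: float | None = None
    linkage: str = "ward"
    adjust: str = "fdr_bh"
    alpha: float = 0.05
    rounding: int = 1
    seed: int = 0


def _letters_for(rep: pd.DataFrame, quantity: str, alpha: float, adjust: str):
    groups = {
        sp: grp[quantity].dropna().to_numpy()
        for sp, grp in rep.groupby("species", sort=False)
    }
    groups = {sp: v for sp, v in groups.items() if len(v) > 0}
    if len(groups) < 2 or all(len(v) < 2 for v in groups.values()):
        return None
    try:
        return sm.kruskal_dunn(groups, alpha=alpha, adjust=adjust, variable=quantity)
    except ValueError:
        return None


def run_full_analysis(config: RunConfig) -> dict:
    """Run every applicable stage; returns the manifest dictionary.

    Any stage failure propagates as an exception tagged with the stage name.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": {"name": "phycofa", "version": __version__},
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
        },
        "seed": config.seed,
        "parameters": {
            "assay_levels": config.assay_levels,
            "glog_lambda": config.glog_lambda,
            "linkage": config.linkage,
            "adjust": config.adjust,
            "alpha": config.alpha,
            "rounding": config.rounding,
        },
        "warnings": [],
        "outputs": [],
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }

    def record_warnings(caught) -> None:
        manifest["warnings"].extend(str(w.message) for w in caught)

    # ---------------------------------------------------------------- indices
    if config.profiles_csv is not None:
        profiles = pio.read_fa_table(config.profiles_csv, config.profiles_dialect)
    else:
        profiles = pio.reference_profiles()
    log.info("indices: %d profiles, %d species", len(profiles),
             len({p.species_id for p in profiles}))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        rep = lm.replicate_table(profiles)
        table = lm.index_table(profiles, rounded=True)
        for p in profiles:
            # A total far below closure marks an incomplete column (e.g. an
            # unreported major FA); its index inputs are then suspect.
            if p.total < 95.0:
                missing = lm.missing_index_inputs(p)
                manifest["warnings"].append(
                    f"{p.species_id}/{p.replicate_id}: abundance total "
                    f"{p.total:.1f}% < 95%; index inputs absent "
                    f"({', '.join(missing) or 'none'}) — dependent quantities "
                    "not reproducible from this table"
                )
    record_warnings(caught)
    for quantity in ("ai", "ti", "h_over_h"):
        comp = _letters_for(rep, quantity, config.alpha, config.adjust)
        table[f"{quantity}_letters"] = (
            pd.Series(comp.letters) if comp is not None else ""
        )
    table.to_csv(outdir / "index_table.csv")
    manifest["outputs"].append("index_table.csv")

    # ------------------------------------------------------------------ stats
    matrix = pio.profiles_to_matrix(profiles)
    if matrix.shape[0] >= 2:
        transformed = sm.glog_transform(matrix, lam=config.glog_lambda)
        manifest["parameters"]["glog_lambda_used"] = transformed.lam
        pca = sm.run_pca(transformed)
        pca.scores.to_csv(outdir / "pca_scores.csv")
        pca.loadings.to_csv(outdir / "pca_loadings.csv")
        pd.Series(
            pca.variance_fraction,
            index=pca.scores.columns,
            name="variance_fraction",
        ).to_csv(outdir / "pca_variance.csv")
        tree = sm.hierarchical_clustering(transformed, method=config.linkage)
        (outdir / "clustering.nwk").write_text(sm.to_newick(tree) + "\n")
        manifest["outputs"] += [
            "pca_scores.csv",
            "pca_loadings.csv",
            "pca_variance.csv",
            "clustering.nwk",
        ]

    # ------------------------------------------------------------------ assay
    if config.plate_csv is not None:
        records = pio.read_plate_table(config.plate_csv)
        by_assay: dict[str, list] = {}
        for r in records:
            by_assay.setdefault(r.assay, []).append(r)
        rows = []
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            for assay, recs in sorted(by_assay.items()):
                level = config.assay_levels.get(assay)
                for res in ax.reduce_assay(recs, level=level):
                    rows.append(
                        {
                            "assay": res.assay,
                            "analyte": res.analyte_id,
                            "inhibition_level": res.inhibition_level,
                            "ic_value": res.ic_value,
                            "conc_units": res.conc_units,
                            "te_umol_per_g": res.te,
                            "slope": res.slope,
                            "intercept": res.intercept,
                            "r_squared": res.r_squared,
                            "extrapolated": res.extrapolated,
                        }
                    )
        record_warnings(caught)
        pd.DataFrame(rows).to_csv(outdir / "scavenging_results.csv", index=False)
        manifest["outputs"].append("scavenging_results.csv")
        log.info("assay: %d wells, %d results", len(records), len(rows))

    pio.write_json(manifest, outdir / "manifest.json")
    return manifest
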