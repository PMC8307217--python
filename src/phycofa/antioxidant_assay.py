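"""Reduction of DPPH/ABTS microplate kinetics to ICx and Trolox equivalents.

A scavenging run reads absorbance (517 nm for DPPH, 734 nm for ABTS) every
5 min for 120 min in wells of four roles:

* ``radical_blank`` — radical working solution plus solvent (defines the
  uninhibited absorbance);
* ``sample`` — extract dilution plus radical;
* ``sample_control`` — extract dilution plus solvent instead of radical
  (corrects for the sample's own colour);
* ``standard`` — the Trolox reference plus radical (its colour controls are
  ``sample_control`` wells with the standard's analyte id).

Inhibition at a concentration is
``100 · (A_radical − (A_sample − A_control)) / A_radical`` evaluated at the
reading nearest the chosen time point (default 120 min, the endpoint of the
protocol).  The dose–response is reduced by ordinary least squares of
inhibition on concentration — a deliberately linear model — and
``ICx = (x − intercept) / slope``.  Trolox equivalents are
``TE = 1000 · IC_trolox / IC_sample`` (µmol Trolox per g extract when the
standard IC is in µmol/L and the sample IC in µg/mL).

Inhibition may be negative (pro-oxidant behaviour or noise); values are
clipped only at presentation, never before regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "PlateKineticsRecord",
    "DoseResponseCurve",
    "ScavengingResult",
    "PlateLayoutError",
    "DoseResponseError",
    "LinearDoseResponse",
    "inhibition_percent",
    "build_curve",
    "estimate_icx",
    "trolox_equivalents",
    "implied_trolox_ic",
    "reduce_assay",
    "DEFAULT_LEVELS",
]

ROLES = ("radical_blank", "sample", "sample_control", "standard")

#: The reported inhibition level is a per-assay convention: extracts reach
#: 50% inhibition of the ABTS radical cation within the tested range but only
#: 20% of the more recalcitrant DPPH radical.
DEFAULT_LEVELS = {"ABTS": 50.0, "DPPH": 20.0}


class PlateLayoutError(ValueError):
    """Plate is missing wells the reduction requires."""


class DoseResponseError(RuntimeError):
    """Dose–response regression cannot produce a meaningful IC."""


@dataclass
class PlateKineticsRecord:
    """Raw time-series of one well."""

    assay: str
    well_id: str
    role: str
    analyte_id: str | None
    concentration: float | None
    conc_units: str | None
    series: list[tuple[float, float]]  # (time in min, absorbance in AU)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown well role {self.role!r}")
        times = [t for t, _ in self.series]
        if any(t < 0 for t in times):
            raise ValueError(f"well {self.well_id}: negative time")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"well {self.well_id}: times not strictly increasing")
        if self.role == "radical_blank" and self.concentration is not None:
            raise ValueError("radical_blank wells carry no concentration")

    def absorbance_at(self, time_point: float) -> float:
        """Absorbance of the reading nearest ``time_point`` (min)."""
        times = np.array([t for t, _ in self.series])
        values = [a for _, a in self.series]
        return float(values[int(np.argmin(np.abs(times - time_point)))])


@dataclass
class DoseResponseCurve:
    """Per-concentration inhibition summary at one time point."""

    assay: str
    analyte_id: str
    time_point: float
    points: pd.DataFrame  # concentration, inhibition_mean, inhibition_sd, n
    replicate_points: pd.DataFrame = field(repr=False, default=None)  # type: ignore[assignment]
    conc_units: str | None = None


@dataclass
class ScavengingResult:
    """Reduced output for one analyte: ICx, regression fit and (optionally) TE."""

    assay: str
    analyte_id: str
    inhibition_level: float
    ic_value: float
    slope: float
    intercept: float
    r_squared: float
    extrapolated: bool
    conc_units: str | None = None
    te: float | None = None
    ic_sd: float | None = None


class LinearDoseResponse(RegressorMixin, BaseEstimator):
    """Ordinary least-squares line of inhibition (%) on concentration.

    A scikit-learn compatible estimator; ``fit`` expects ``X`` of shape
    ``(n, 1)`` (concentrations) and ``y`` (inhibition %).  After fitting,
    :meth:`ic` inverts the line at a requested inhibition level.
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != 1:
            raise ValueError("LinearDoseResponse expects a single feature")
        y = np.asarray(y, dtype=float)
        if len(np.unique(X[:, 0])) < 2:
            raise ValueError("need >= 2 distinct concentrations")
        res = stats.linregress(X[:, 0], y)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue**2)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "slope_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + self.slope_ * X[:, 0]

    def ic(self, level: float) -> float:
        """Concentration at which the fitted line reaches ``level`` %."""
        check_is_fitted(self, "slope_")
        if self.slope_ <= 0:
            raise DoseResponseError(
                f"non-positive dose-response slope ({self.slope_:.4g}); "
                "no IC can be estimated"
            )
        return (level - self.intercept_) / self.slope_


def inhibition_percent(
    abs_radical: float, abs_sample: float, abs_sample_control: float
) -> float:
    """Radical inhibition in %, colour-corrected by the sample control."""
    if abs_radical <= 0:
        raise ValueError(f"radical absorbance must be > 0, got {abs_radical}")
    return 100.0 * (abs_radical - (abs_sample - abs_sample_control)) / abs_radical


def build_curve(
    records: list[PlateKineticsRecord],
    analyte_id: str,
    *,
    time_point: float = 120.0,
) -> DoseResponseCurve:
    """Reduce matched sample/control wells to a dose–response curve.

    Per concentration, sample (or standard) wells are paired with the
    analyte's ``sample_control`` wells replicate-wise (sorted well order; a
    single control is broadcast), inhibition is computed per replicate
    against the mean radical blank, then summarised as mean ± sample SD.
    """
    assays = {r.assay for r in records}
    if len(assays) != 1:
        raise PlateLayoutError(f"records span assays {sorted(assays)}; expected one")
    assay = assays.pop()

    blanks = [r for r in records if r.role == "radical_blank"]
    if not blanks:
        raise PlateLayoutError("no radical_blank wells present")
    abs_rad = float(np.mean([r.absorbance_at(time_point) for r in blanks]))

    samples = [
        r
        for r in records
        if r.role in ("sample", "standard") and r.analyte_id == analyte_id
    ]
    controls = [
        r
        for r in records
        if r.role == "sample_control" and r.analyte_id == analyte_id
    ]
    if not samples:
        raise PlateLayoutError(f"no measurement wells for analyte {analyte_id!r}")

    units = {r.conc_units for r in samples if r.conc_units is not None}
    rep_rows = []
    for conc in sorted({r.concentration for r in samples}):
        s_wells = sorted(
            (r for r in samples if r.concentration == conc), key=lambda r: r.well_id
        )
        c_wells = sorted(
            (r for r in controls if r.concentration == conc), key=lambda r: r.well_id
        )
        if not c_wells:
            raise PlateLayoutError(
                f"analyte {analyte_id!r}: no sample_control wells at "
                f"concentration {conc}"
            )
        if len(c_wells) == 1 and len(s_wells) > 1:
            c_wells = c_wells * len(s_wells)
        if len(c_wells) != len(s_wells):
            raise PlateLayoutError(
                f"analyte {analyte_id!r} at {conc}: {len(s_wells)} sample vs "
                f"{len(c_wells)} control wells cannot be paired"
            )
        for i, (s, c) in enumerate(zip(s_wells, c_wells)):
            rep_rows.append(
                {
                    "concentration": conc,
                    "replicate": i,
                    "inhibition": inhibition_percent(
                        abs_rad,
                        s.absorbance_at(time_point),
                        c.absorbance_at(time_point),
                    ),
                }
            )
    reps = pd.DataFrame(rep_rows)
    points = (
        reps.groupby("concentration")["inhibition"]
        .agg(
            inhibition_mean="mean",
            inhibition_sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0,
            n="count",
        )
        .reset_index()
    )
    return DoseResponseCurve(
        assay=assay,
        analyte_id=analyte_id,
        time_point=time_point,
        points=points,
        replicate_points=reps,
        conc_units=units.pop() if len(units) == 1 else None,
    )


def estimate_icx(
    curve: DoseResponseCurve,
    level: float,
    *,
    per_replicate: bool = False,
) -> ScavengingResult:
    """ICx by linear regression of inhibition on concentration.

    Replicates are averaged before regression (matching mean ± SD reporting
    of triplicate plates); with ``per_replicate=True`` the regression is
    repeated per replicate and the IC spread across replicates is reported
    as ``ic_sd``.  ICs outside the tested concentration range are flagged
    ``extrapolated``.  A non-positive slope raises :class:`DoseResponseError`.
    """
    pts = curve.points
    if len(pts) < 2:
        raise DoseResponseError("need >= 2 distinct concentrations")
    model = LinearDoseResponse().fit(
        pts["concentration"].to_numpy(), pts["inhibition_mean"].to_numpy()
    )
    ic = model.ic(level)
    ic_sd = None
    if per_replicate and curve.replicate_points is not None:
        ics = []
        for _, grp in curve.replicate_points.groupby("replicate"):
            m = LinearDoseResponse().fit(
                grp["concentration"].to_numpy(), grp["inhibition"].to_numpy()
            )
            try:
                ics.append(m.ic(level))
            except DoseResponseError:
                continue
        if len(ics) > 1:
            ic_sd = float(np.std(ics, ddof=1))
    lo, hi = pts["concentration"].min(), pts["concentration"].max()
    extrapolated = not lo <= ic <= hi
    if extrapolated:
        warnings.warn(
            f"{curve.assay}/{curve.analyte_id}: IC{level:g} = {ic:.3g} lies "
            f"outside the tested range [{lo:g}, {hi:g}]",
            stacklevel=2,
        )
    return ScavengingResult(
        assay=curve.assay,
        analyte_id=curve.analyte_id,
        inhibition_level=level,
        ic_value=float(ic),
        slope=model.slope_,
        intercept=model.intercept_,
        r_squared=model.r_squared_,
        extrapolated=extrapolated,
        conc_units=curve.conc_units,
        ic_sd=ic_sd,
    )


def trolox_equivalents(
    ic_sample: float,
    ic_trolox: float,
    *,
    sample_level: float | None = None,
    trolox_level: float | None = None,
) -> float:
    """TE = 1000 · IC_trolox / IC_sample (µmol Trolox per g extract).

    The two ICs must refer to the same inhibition level; pass the levels to
    have the pairing checked.
    """
    if ic_sample <= 0 or ic_trolox <= 0:
        raise ValueError("IC values must be positive")
    if (
        sample_level is not None
        and trolox_level is not None
        and sample_level != trolox_level
    ):
        raise ValueError(
            f"inhibition level mismatch: sample IC{sample_level:g} vs "
            f"Trolox IC{trolox_level:g}"
        )
    return 1000.0 * ic_trolox / ic_sample


def implied_trolox_ic(te: float, ic_sample: float) -> float:
    """Back-solve the standard's IC from a reported (TE, IC_sample) pair."""
    return te * ic_sample / 1000.0


def reduce_assay(
    records: list[PlateKineticsRecord],
    *,
    level: float | None = None,
    trolox_analyte: str = "Trolox",
    time_point: float = 120.0,
    per_replicate: bool = False,
) -> list[ScavengingResult]:
    """Full reduction of one assay run: ICx per extract plus TE vs Trolox.

    ``level`` defaults per assay (IC50 for ABTS, IC20 for DPPH).  The Trolox
    standard is reduced first; each extract's TE is then attached.
    """
    assays = {r.assay for r in records}
    if len(assays) != 1:
        raise PlateLayoutError(f"records span assays {sorted(assays)}; expected one")
    assay = assays.pop()
    if level is None:
        level = DEFAULT_LEVELS.get(assay, 50.0)

    analytes = sorted(
        {
            r.analyte_id
            for r in records
            if r.role in ("sample", "standard") and r.analyte_id is not None
        }
    )
    trolox_result = None
    if trolox_analyte in analytes:
        trolox_result = estimate_icx(
            build_curve(records, trolox_analyte, time_point=time_point),
            level,
            per_replicate=per_replicate,
        )
    results = []
    for analyte in analytes:
        if analyte == trolox_analyte:
            continue
        res = estimate_icx(
            build_curve(records, analyte, time_point=time_point),
            level,
            per_replicate=per_replicate,
        )
        if trolox_result is not None:
            res.te = trolox_equivalents(
                res.ic_value,
                trolox_result.ic_value,
                sample_level=res.inhibition_level,
                trolox_level=trolox_result.inhibition_level,
            )
        results.append(res)
    if trolox_result is not None:
        results.append(trolox_result)
    return results
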