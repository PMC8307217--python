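"""Aggregation of FA profiles into class sums and lipid nutritional indices.

A profile is the relative-abundance composition (% of total FA) of one
replicate of one species.  From it this module derives:

* class sums: ΣSFA, ΣMUFA, ΣPUFA and the ω-3 / ω-6 PUFA sums with their
  ω-6/ω-3 ratio;
* the atherogenicity index AI = (C12:0 + 4·C14:0 + C16:0) /
  (ΣMUFA + Σω-6 + Σω-3);
* the thrombogenicity index TI = (C14:0 + C16:0 + C18:0) /
  (0.5·ΣMUFA + 0.5·Σω-6 + 3·Σω-3 + Σω-3/Σω-6), the ratio term taken as 0
  when Σω-3 = 0 and undefined (TI absent) when Σω-6 = 0 with Σω-3 > 0;
* the hypocholesterolemic/hypercholesterolemic ratio h/H =
  (C18:1 ω-9 + C18:2 ω-6 + C18:3 ω-3 + C20:4 ω-6 + C20:5 ω-3) /
  (C14:0 + C16:0).

All three indices are pure ratios of abundances and therefore invariant
under uniform rescaling of a profile; absent FAs contribute 0 and a zero
denominator yields an absent (None) value, never an exception.  Omega sums
are restricted to PUFA of the ω-3 / ω-6 classes; PUFA of other ω classes
(ω-1, ω-4, ω-5) count toward ΣPUFA but never toward the index denominators.
Internal arithmetic is done at full precision; rounding (half-up, one
decimal) is applied only at presentation.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fa_nomenclature import FALabelError, FattyAcidDescriptor, parse_fa_label

__all__ = [
    "FAProfile",
    "ClassSummary",
    "NutritionalIndices",
    "ProfileSumError",
    "normalize_profile",
    "class_summary",
    "atherogenicity_index",
    "thrombogenicity_index",
    "hypo_hyper_ratio",
    "nutritional_indices",
    "index_table",
    "missing_index_inputs",
    "round_half_up",
]

#: FAs entering the index numerators/denominator, as (carbons, double_bonds,
#: omega) keys; omega None means "any".
INDEX_INPUT_FAS: tuple[tuple[int, int, int | None], ...] = (
    (12, 0, None),
    (14, 0, None),
    (16, 0, None),
    (18, 0, None),
    (18, 1, 9),
    (18, 2, 6),
    (18, 3, 3),
    (20, 4, 6),
    (20, 5, 3),
)


class ProfileSumError(ValueError):
    """Raw abundance total outside the accepted closure tolerance."""


@dataclass
class FAProfile:
    """One replicate's FA composition for one species.

    ``abundances`` maps canonical FA labels to relative abundance in % of
    total FA.  Values must be non-negative; totals are only constrained when
    :func:`normalize_profile` is applied (profiles with known missing cells,
    e.g. an unreported major FA, are representable as-is).
    """

    species_id: str
    replicate_id: str
    abundances: dict[str, float]

    def __post_init__(self) -> None:
        for label, value in self.abundances.items():
            if value < 0:
                raise ValueError(
                    f"negative abundance {value} for {label!r} in "
                    f"{self.species_id}/{self.replicate_id}"
                )

    @property
    def total(self) -> float:
        return float(sum(self.abundances.values()))

    def descriptors(self) -> dict[str, FattyAcidDescriptor]:
        """Parse every label; raises naming the first offending label."""
        out = {}
        for label in self.abundances:
            try:
                out[label] = parse_fa_label(label)
            except FALabelError as exc:
                raise FALabelError(
                    f"{self.species_id}/{self.replicate_id}: "
                    f"unparseable FA label {label!r}: {exc}"
                ) from exc
        return out


@dataclass(frozen=True)
class ClassSummary:
    sfa_pct: float
    mufa_pct: float
    pufa_pct: float
    pufa_n3_pct: float
    pufa_n6_pct: float
    n6_over_n3: float | None


@dataclass(frozen=True)
class NutritionalIndices:
    ai: float | None
    ti: float | None
    h_over_h: float | None


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (presentation only)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(
        decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


def normalize_profile(
    profile: FAProfile, *, tolerance: tuple[float, float] = (95.0, 105.0)
) -> FAProfile:
    """Close a profile to exactly 100%.

    The raw total must lie within ``tolerance`` (default [95, 105]); a total
    outside it signals a corrupted or incomplete table and is rejected with
    the offending sum.  Zero entries are preserved.
    """
    total = profile.total
    lo, hi = tolerance
    if not lo <= total <= hi:
        raise ProfileSumError(
            f"{profile.species_id}/{profile.replicate_id}: abundance total "
            f"{total:.4f}% outside [{lo}, {hi}]"
        )
    scale = 100.0 / total
    return FAProfile(
        species_id=profile.species_id,
        replicate_id=profile.replicate_id,
        abundances={k: v * scale for k, v in profile.abundances.items()},
    )


def _sum_matching(
    profile: FAProfile,
    catalog: dict[str, FattyAcidDescriptor],
    carbons: int,
    double_bonds: int,
    omega: int | None = None,
) -> float:
    """Total abundance of FAs matching chain length, unsaturation and omega."""
    total = 0.0
    for label, value in profile.abundances.items():
        d = catalog[label]
        if d.carbons == carbons and d.double_bonds == double_bonds:
            if omega is None or d.omega_class == omega:
                total += value
    return total


def class_summary(
    profile: FAProfile,
    catalog: dict[str, FattyAcidDescriptor] | None = None,
) -> ClassSummary:
    """Saturation-class and omega-class sums for one profile.

    Omega sums cover PUFA with omega class 3 or 6 only; PUFA lacking an omega
    annotation (no delta list, no tag) count toward ΣPUFA but not toward the
    omega sums.  The ω-6/ω-3 ratio is absent (None) when Σω-3 = 0.
    """
    catalog = catalog if catalog is not None else profile.descriptors()
    sfa = mufa = pufa = n3 = n6 = 0.0
    for label, value in profile.abundances.items():
        d = catalog[label]
        if d.saturation_class == "SFA":
            sfa += value
        elif d.saturation_class == "MUFA":
            mufa += value
        else:
            pufa += value
            if d.omega_class == 3:
                n3 += value
            elif d.omega_class == 6:
                n6 += value
    ratio = n6 / n3 if n3 > 0 else None
    return ClassSummary(
        sfa_pct=sfa,
        mufa_pct=mufa,
        pufa_pct=pufa,
        pufa_n3_pct=n3,
        pufa_n6_pct=n6,
        n6_over_n3=ratio,
    )


def atherogenicity_index(
    profile: FAProfile, summary: ClassSummary | None = None
) -> float | None:
    """AI = (C12:0 + 4·C14:0 + C16:0) / (ΣMUFA + Σω-6 + Σω-3).

    Lower values indicate lower atherogenic potential.  Returns None when the
    denominator is zero.
    """
    catalog = profile.descriptors()
    summary = summary if summary is not None else class_summary(profile, catalog)
    num = (
        _sum_matching(profile, catalog, 12, 0)
        + 4.0 * _sum_matching(profile, catalog, 14, 0)
        + _sum_matching(profile, catalog, 16, 0)
    )
    den = summary.mufa_pct + summary.pufa_n6_pct + summary.pufa_n3_pct
    if den <= 0:
        warnings.warn(
            f"{profile.species_id}/{profile.replicate_id}: AI undefined "
            "(ΣMUFA + Σω-6 + Σω-3 = 0)",
            stacklevel=2,
        )
        return None
    return num / den


def thrombogenicity_index(
    profile: FAProfile, summary: ClassSummary | None = None
) -> float | None:
    """TI = (C14:0 + C16:0 + C18:0) / (0.5·ΣMUFA + 0.5·Σω-6 + 3·Σω-3 + Σω-3/Σω-6).

    The ratio term is 0 when Σω-3 = 0; when Σω-3 > 0 but Σω-6 = 0 the term is
    undefined and TI is absent.  Returns None when the denominator is zero or
    the ratio term is undefined.

    The dimensionless Σω-3/Σω-6 term makes TI inhomogeneous in the raw
    abundances, so the profile is interpreted on the percent scale: all sums
    are closed to a 100% total internally, which keeps the index invariant
    under uniform rescaling of the input.
    """
    catalog = profile.descriptors()
    summary = summary if summary is not None else class_summary(profile, catalog)
    total = profile.total
    if total <= 0:
        warnings.warn(
            f"{profile.species_id}/{profile.replicate_id}: TI undefined "
            "(empty profile)",
            stacklevel=2,
        )
        return None
    scale = 100.0 / total
    num = scale * (
        _sum_matching(profile, catalog, 14, 0)
        + _sum_matching(profile, catalog, 16, 0)
        + _sum_matching(profile, catalog, 18, 0)
    )
    n3, n6 = scale * summary.pufa_n3_pct, scale * summary.pufa_n6_pct
    if n3 > 0 and n6 == 0:
        warnings.warn(
            f"{profile.species_id}/{profile.replicate_id}: TI undefined "
            "(Σω-3 > 0 with Σω-6 = 0, ratio term diverges)",
            stacklevel=2,
        )
        return None
    ratio_term = n3 / n6 if n3 > 0 else 0.0
    den = 0.5 * scale * summary.mufa_pct + 0.5 * n6 + 3.0 * n3 + ratio_term
    if den <= 0:
        warnings.warn(
            f"{profile.species_id}/{profile.replicate_id}: TI undefined "
            "(zero denominator)",
            stacklevel=2,
        )
        return None
    return num / den


def hypo_hyper_ratio(profile: FAProfile) -> float | None:
    """h/H = (C18:1 ω-9 + C18:2 ω-6 + C18:3 ω-3 + C20:4 ω-6 + C20:5 ω-3) / (C14:0 + C16:0).

    Higher values indicate a more hypocholesterolemic FA pool.  Returns None
    when C14:0 + C16:0 = 0.
    """
    catalog = profile.descriptors()
    num = (
        _sum_matching(profile, catalog, 18, 1, omega=9)
        + _sum_matching(profile, catalog, 18, 2, omega=6)
        + _sum_matching(profile, catalog, 18, 3, omega=3)
        + _sum_matching(profile, catalog, 20, 4, omega=6)
        + _sum_matching(profile, catalog, 20, 5, omega=3)
    )
    den = _sum_matching(profile, catalog, 14, 0) + _sum_matching(
        profile, catalog, 16, 0
    )
    if den <= 0:
        warnings.warn(
            f"{profile.species_id}/{profile.replicate_id}: h/H undefined "
            "(C14:0 + C16:0 = 0)",
            stacklevel=2,
        )
        return None
    return num / den


def nutritional_indices(profile: FAProfile) -> NutritionalIndices:
    summary = class_summary(profile)
    return NutritionalIndices(
        ai=atherogenicity_index(profile, summary),
        ti=thrombogenicity_index(profile, summary),
        h_over_h=hypo_hyper_ratio(profile),
    )


def missing_index_inputs(profile: FAProfile) -> list[str]:
    """Index-input FAs absent (or zero) in a profile.

    Used to flag species whose indices are not reproducible from the given
    table, e.g. a major FA left blank in a published column.  Only FAs that
    enter the AI/TI/h/H formulas are reported.
    """
    catalog = profile.descriptors()
    missing = []
    for carbons, db, omega in INDEX_INPUT_FAS:
        if _sum_matching(profile, catalog, carbons, db, omega) == 0.0:
            key = f"C{carbons}:{db}" + (f" n-{omega}" if omega is not None else "")
            missing.append(key)
    return missing

_QUANTITIES = (
    "sfa_pct",
    "mufa_pct",
    "pufa_pct",
    "pufa_n6_pct",
    "pufa_n3_pct",
    "n6_over_n3",
    "ai",
    "ti",
    "h_over_h",
)


def replicate_table(profiles: list[FAProfile]) -> pd.DataFrame:
    """Per-replicate class sums and indices, one row per (species, replicate)."""
    rows = []
    for p in profiles:
        s = class_summary(p)
        idx = NutritionalIndices(
            ai=atherogenicity_index(p, s),
            ti=thrombogenicity_index(p, s),
            h_over_h=hypo_hyper_ratio(p),
        )
        rows.append(
            {
                "species": p.species_id,
                "replicate": p.replicate_id,
                "sfa_pct": s.sfa_pct,
                "mufa_pct": s.mufa_pct,
                "pufa_pct": s.pufa_pct,
                "pufa_n6_pct": s.pufa_n6_pct,
                "pufa_n3_pct": s.pufa_n3_pct,
                "n6_over_n3": np.nan if s.n6_over_n3 is None else s.n6_over_n3,
                "ai": np.nan if idx.ai is None else idx.ai,
                "ti": np.nan if idx.ti is None else idx.ti,
                "h_over_h": np.nan if idx.h_over_h is None else idx.h_over_h,
            }
        )
    return pd.DataFrame(rows)


def index_table(
    profiles: list[FAProfile], *, rounded: bool = False
) -> pd.DataFrame:
    """Per-species mean ± sample SD of class sums and indices.

    Indices are computed per replicate, then averaged (sample SD, n−1); an
    absent per-replicate value (undefined index) is excluded from that
    species' aggregate.  With ``rounded=True`` the means and SDs are rounded
    half-up to one decimal for presentation; internal consumers should keep
    the default full precision.
    """
    if not profiles:
        raise ValueError("no profiles given")
    rep = replicate_table(profiles)
    out = {}
    for species, grp in rep.groupby("species", sort=False):
        row: dict[str, float] = {"n_replicates": len(grp)}
        for q in _QUANTITIES:
            vals = grp[q].dropna()
            if vals.empty:
                row[f"{q}_mean"] = np.nan
                row[f"{q}_sd"] = np.nan
                continue
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            if rounded:
                mean, sd = round_half_up(mean), round_half_up(sd)
            row[f"{q}_mean"] = mean
            row[f"{q}_sd"] = sd
        out[species] = row
    table = pd.DataFrame.from_dict(out, orient="index")
    table.index.name = "species"
    return table
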