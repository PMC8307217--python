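"""Synthetic replicate FA tables and microplate kinetics with known truth.

The generator emulates the statistical structure the analysis assumes, so
every downstream stage can be exercised and its parameter recovery measured
without any instrument data.

Profiles
--------
Replicates are drawn around species mean compositions by perturbing each FA
multiplicatively with a log-normal factor of unit mean and the requested
coefficient of variation, then re-closing the vector to 100%.  The
multiplicative model (rather than, say, a Dirichlet) makes the per-FA CV
directly controllable, matching tables whose SDs scale roughly with their
means; zeros stay exactly zero.

Plates
------
The truth inhibition at the endpoint (120 min) is linear in concentration,
anchored so that ``inhibition(true_ic) = level``; the default slope makes
the truth reach 100% at the top tested concentration (full quench at the
highest dose), which keeps every absorbance physical.  Well absorbance
relaxes exponentially from the radical working-solution value to its
endpoint truth — reaching it *exactly* at 120 min, so noise-free recovery is
exact; the kinetic shape itself is a modelling convenience and not part of
any contract.  Sample-control wells carry a small constant colour offset to
exercise the colour-correction path, and additive Gaussian noise is applied
to every reading.  All outputs are deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .antioxidant_assay import PlateKineticsRecord
from .lipid_metrics import FAProfile

__all__ = [
    "ProfileSimConfig",
    "AssaySimConfig",
    "simulate_profiles",
    "simulate_plate",
    "simulate_assay_run",
]

EXTRACT_CONCENTRATIONS = (25.0, 125.0, 250.0, 500.0)  # µg/mL
TROLOX_CONCENTRATIONS = (5.0, 12.5, 25.0, 37.5)  # µmol/L


@dataclass
class ProfileSimConfig:
    """Replicate-generation settings.

    ``means`` is a species × FA matrix in % (rows nominally closing to
    ~100); ``cv`` is the per-FA coefficient of variation of the multiplicative
    noise; ``n_replicates`` defaults to the five analytical replicates of the
    reference protocol.
    """

    means: pd.DataFrame
    cv: float = 0.05
    n_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError(f"cv must be >= 0, got {self.cv}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if (self.means.to_numpy(dtype=float) < 0).any():
            raise ValueError("means must be non-negative")


def simulate_profiles(config: ProfileSimConfig) -> list[FAProfile]:
    """Draw closed replicate compositions around the configured means."""
    rng = np.random.default_rng(config.seed)
    sigma = float(np.sqrt(np.log1p(config.cv**2)))
    profiles = []
    for species, row in config.means.iterrows():
        means = row.to_numpy(dtype=float)
        labels = list(row.index)
        for r in range(config.n_replicates):
            factors = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=len(means))
            values = means * factors
            total = values.sum()
            if total <= 0:
                raise ValueError(f"species {species!r}: all-zero mean row")
            values = values * (100.0 / total)
            profiles.append(
                FAProfile(
                    species_id=str(species),
                    replicate_id=f"r{r + 1}",
                    abundances={l: float(v) for l, v in zip(labels, values)},
                )
            )
    return profiles


@dataclass
class AssaySimConfig:
    """Plate-generation settings for one analyte of one assay.

    ``true_ic`` is the concentration at which the truth line crosses
    ``level`` % inhibition.  ``inhibition_slope`` (% per concentration unit)
    defaults to ``(100 - level) / (max(concentrations) - true_ic)`` so the
    truth reaches complete quench at the top tested dose.  ``radical_abs0``
    is the radical working-solution absorbance (~0.9 AU per protocol);
    readings run 0–120 min at 5-min spacing in triplicate.
    """

    assay: str = "ABTS"
    analyte_id: str = "extract"
    role: str = "sample"
    true_ic: float = 100.0
    level: float = 50.0
    inhibition_slope: float | None = None
    radical_abs0: float = 0.9
    noise_sd: float = 0.0
    concentrations: tuple[float, ...] = EXTRACT_CONCENTRATIONS
    conc_units: str = "ug/mL"
    time_grid: tuple[float, ...] = tuple(float(t) for t in range(0, 121, 5))
    n_replicates: int = 3
    control_offset: float = 0.01
    decay_rate: float = 0.05  # 1/min
    seed: int = 0
    emit_radical_blank: bool = True

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(set(self.concentrations)) != len(self.concentrations) or any(
            c <= 0 for c in self.concentrations
        ):
            raise ValueError("concentrations must be positive and distinct")
        if self.true_ic <= 0:
            raise ValueError("true_ic must be positive")

    @property
    def slope(self) -> float:
        if self.inhibition_slope is not None:
            return self.inhibition_slope
        c_max = max(self.concentrations)
        if c_max > self.true_ic:
            return (100.0 - self.level) / (c_max - self.true_ic)
        return self.level / self.true_ic

    def truth_inhibition(self, concentration: float) -> float:
        return self.level + self.slope * (concentration - self.true_ic)


@dataclass
class PlateSimResult:
    records: list[PlateKineticsRecord]
    config: AssaySimConfig
    warnings: list[str] = field(default_factory=list)


def _kinetic_series(
    times: np.ndarray, a0: float, a_end: float, k: float
) -> np.ndarray:
    """Exponential relaxation from a0 hitting a_end exactly at the last time."""
    t_end = times[-1]
    w = (np.exp(-k * times) - np.exp(-k * t_end)) / (1.0 - np.exp(-k * t_end))
    return a_end + (a0 - a_end) * w


def simulate_plate(config: AssaySimConfig) -> PlateSimResult:
    """Emit radical blanks, measurement wells and colour controls."""
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.time_grid, dtype=float)
    notes: list[str] = []
    records: list[PlateKineticsRecord] = []

    def noisy(values: np.ndarray) -> np.ndarray:
        if config.noise_sd == 0:
            return values
        return values + rng.normal(0.0, config.noise_sd, size=values.shape)

    if config.emit_radical_blank:
        for r in range(config.n_replicates):
            series = noisy(np.full_like(times, config.radical_abs0))
            records.append(
                PlateKineticsRecord(
                    assay=config.assay,
                    well_id=f"BLK{r + 1}",
                    role="radical_blank",
                    analyte_id=None,
                    concentration=None,
                    conc_units=None,
                    series=list(zip(times.tolist(), np.maximum(series, 0.0).tolist())),
                )
            )

    max_truth = config.truth_inhibition(max(config.concentrations))
    if max_truth > 100.0 + 1e-9:
        notes.append(
            f"truth inhibition reaches {max_truth:.1f}% at the top tested "
            "concentration; absorbances are floored at 0"
        )
        warnings.warn(notes[-1], stacklevel=2)

    for ci, conc in enumerate(config.concentrations):
        inh = config.truth_inhibition(conc)
        a_end = config.radical_abs0 * (1.0 - inh / 100.0) + config.control_offset
        a_end = max(a_end, 0.0)
        a_start = config.radical_abs0 + config.control_offset
        clean = _kinetic_series(times, a_start, a_end, config.decay_rate)
        for r in range(config.n_replicates):
            sample_series = np.maximum(noisy(clean.copy()), 0.0)
            control_series = np.maximum(
                noisy(np.full_like(times, config.control_offset)), 0.0
            )
            records.append(
                PlateKineticsRecord(
                    assay=config.assay,
                    well_id=f"S{ci + 1}_{r + 1}",
                    role=config.role,
                    analyte_id=config.analyte_id,
                    concentration=float(conc),
                    conc_units=config.conc_units,
                    series=list(zip(times.tolist(), sample_series.tolist())),
                )
            )
            records.append(
                PlateKineticsRecord(
                    assay=config.assay,
                    well_id=f"C{ci + 1}_{r + 1}",
                    role="sample_control",
                    analyte_id=config.analyte_id,
                    concentration=float(conc),
                    conc_units=config.conc_units,
                    series=list(zip(times.tolist(), control_series.tolist())),
                )
            )
    return PlateSimResult(records=records, config=config, warnings=notes)


def simulate_assay_run(
    extract_configs: list[AssaySimConfig],
    trolox_config: AssaySimConfig | None = None,
    *,
    seed: int | None = None,
) -> list[PlateKineticsRecord]:
    """One assay run: extract wells plus the Trolox standard ladder.

    When ``seed`` is given, each sub-simulation gets a distinct seed derived
    from it; the radical blank is emitted once (by the first simulation).
    """
    records: list[PlateKineticsRecord] = []
    configs = list(extract_configs)
    if trolox_config is not None:
        trolox_config.role = "standard"
        configs.append(trolox_config)
    for i, cfg in enumerate(configs):
        if seed is not None:
            cfg.seed = (seed * 1009 + i) % (2**31)
        cfg.emit_radical_blank = i == 0
        result = simulate_plate(cfg)
        for rec in result.records:
            if rec.role != "radical_blank":
                rec.well_id = f"{cfg.analyte_id}:{rec.well_id}"
        records.extend(result.records)
    return records
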