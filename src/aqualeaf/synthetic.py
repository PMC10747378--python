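"""Synthetic drought-experiment spectra.

The generator emulates the statistical structure a leaf NIR drought study
produces: two genotypes (one drought-tolerant with a late stress onset,
one sensitive with an early onset), 10 stressed + 10 control plants per
genotype, leaves 2–4 measured at three positions, on drought days
3/7/10/12/14/17 and rewatering days 3/4.

Forward model per spectrum::

    A(λ) = b · ( baseline(λ) + (1 + δ)·Σ_bands amp·G(λ; center, width) )
           + a + ε(λ)

with Gaussian bands, per-spectrum multiplicative/additive scatter (b, a)
and iid band noise ε.  δ is a per-(plant, leaf) random effect scaling all
water-band amplitudes jointly — leaves differ in the magnitude of their
water absorption, not in a flat offset — so it survives derivative
pretreatment and acts as the day-independent nuisance latent direction a
calibration model must separate from the drought signal.

Stressed plants additionally dry at individual rates: a per-plant
multiplier γ ~ N(1, plant_rate_sd) scales the stress progress, so the
spectral state at nominal day d reflects γ·(d − onset) effective days.
This is the irreducible noise of any days-of-drought calibration — two
plants at the same calendar day are at different physiological stages —
and :func:`irreducible_day_rmse` gives its closed form.  Under stress,
free/weakly bound water bands (≤1422 nm, strongest at the 1409.843 nm
free-water band) decline linearly after the genotype's onset day while
strongly bound/structural water bands (≥1441 nm) rise; recovery spectra
stay at the day-17 state with an extra bound-water contribution above
1500 nm.  Amplitudes are in absorbance units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .aquagram import default_wamacs
from .spectra import SpectraSet, nearest_band_index


def build_default_grid(n_bands: int = 125, lo: float = 908.0, hi: float = 1670.0) -> np.ndarray:
    """Instrument-like grid: uniform 908–1670 nm, snapped to the printed
    WAMAC wavelengths at the nearest pixels so the aquagram bands map
    exactly."""
    grid = np.linspace(lo, hi, n_bands)
    for w in default_wamacs().wavelengths:
        grid[nearest_band_index(grid, w)] = w
    if np.any(np.diff(grid) <= 0):  # pragma: no cover - guards grid edits
        raise ValueError("WAMAC snapping broke grid monotonicity")
    return grid


@dataclass(frozen=True)
class SpectralBand:
    """One Gaussian component: amplitude declines (negative slope) or
    rises (positive slope) per day of stress past onset."""

    center: float
    width: float
    base_amplitude: float
    day_slope: float


def default_bands() -> tuple[SpectralBand, ...]:
    """Water bands: two short-wavelength water features plus the 19 WAMACs,
    split into a declining free/weakly-bound group (≤1422 nm) and a rising
    strongly-bound group (≥1441 nm)."""
    bands = [
        SpectralBand(930.0, 20.0, 0.30, -0.004),
        SpectralBand(1155.0, 25.0, 0.50, -0.005),
    ]
    for w in default_wamacs().wavelengths:
        if w <= 1425.0:  # free / weakly hydrogen-bonded water
            amp, slope = (0.55, -0.010) if abs(w - 1409.843) < 0.5 else (0.45, -0.006)
            bands.append(SpectralBand(float(w), 12.0, amp, slope))
        else:  # strongly bound / structural water
            bands.append(SpectralBand(float(w), 14.0, 0.40, +0.006))
    return tuple(bands)


@dataclass(frozen=True)
class GeneratorConfig:
    wavelengths: np.ndarray = field(default_factory=build_default_grid)
    line_labels: tuple[str, str] = ("tolerant", "sensitive")
    onset_days: dict = field(
        default_factory=lambda: {"tolerant": 7, "sensitive": 3}
    )
    n_plants_per_arm: int = 10
    leaves: tuple[int, ...] = (2, 3, 4)
    replicates: int = 3
    stress_days: tuple[int, ...] = (3, 7, 10, 12, 14, 17)
    recovery_days: tuple[int, ...] = (3, 4)
    bands: tuple[SpectralBand, ...] = field(default_factory=default_bands)
    baseline_intercept: float = 0.35
    baseline_slope: float = 0.15  # total rise over the grid span
    scatter_slope_sd: float = 0.03
    scatter_offset_sd: float = 0.02
    noise_sd: float = 0.005
    leaf_effect_sd: float = 0.05  # relative SD of the per-leaf band scaling δ
    plant_rate_sd: float = 0.10   # relative SD of the per-plant drying rate γ
    recovery_bound_boost: float = 0.04
    trajectory: str = "linear"  # or "sigmoid"
    seed: int = 0

    def validate(self) -> list[str]:
        """Human-readable configuration issues; empty list iff runnable."""
        issues = []
        for name in ("scatter_slope_sd", "scatter_offset_sd", "noise_sd",
                     "leaf_effect_sd", "plant_rate_sd"):
            if getattr(self, name) < 0:
                issues.append(f"{name} must be >= 0")
        for line in self.line_labels:
            if line not in self.onset_days:
                issues.append(f"no onset day for line {line!r}")
            elif self.onset_days[line] not in self.stress_days:
                issues.append(
                    f"onset day {self.onset_days[line]} for {line!r} is not "
                    "a scheduled stress day"
                )
        if any(b.base_amplitude < 0 for b in self.bands):
            issues.append("band base amplitudes must be >= 0")
        if self.n_plants_per_arm < 1:
            issues.append("n_plants_per_arm must be >= 1")
        if self.replicates < 1:
            issues.append("replicates must be >= 1")
        if self.trajectory not in ("linear", "sigmoid"):
            issues.append(f"unknown trajectory {self.trajectory!r}")
        wl = np.asarray(self.wavelengths)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            issues.append("wavelength grid must be ascending, length >= 2")
        else:
            for b in self.bands:
                if not wl[0] <= b.center <= wl[-1]:
                    issues.append(f"band centre {b.center} nm outside the grid")
        return issues


def _stress_progress(day: float, onset: float, cfg: GeneratorConfig) -> float:
    """Effective days of physiological stress at a measurement day."""
    if cfg.trajectory == "linear":
        return max(0.0, day - onset)
    # sigmoid alternative: same day-17 endpoint, smooth onset
    span = max(cfg.stress_days) - onset
    if span <= 0:
        return 0.0
    x = (day - onset - span / 2) / (span / 6)
    scale = 1.0 / (1.0 + np.exp(-3.0))
    return span * (1.0 / (1.0 + np.exp(-x))) / scale


def _amps_with_rate(
    day: float, treatment: str, line: str, cfg: GeneratorConfig, rate: float
) -> np.ndarray:
    base = np.array([b.base_amplitude for b in cfg.bands])
    slope = np.array([b.day_slope for b in cfg.bands])
    centers = np.array([b.center for b in cfg.bands])
    onset = cfg.onset_days[line]
    if treatment == "control":
        return base
    if treatment == "stress":
        amps = base + slope * rate * _stress_progress(day, onset, cfg)
        return np.clip(amps, 0.0, None)
    if treatment == "recovery":
        # leaves do not rebound: hold the day-17 state, with extra bound
        # (crystalline/structural) water absorbance above 1500 nm
        amps = base + slope * rate * _stress_progress(
            max(cfg.stress_days), onset, cfg
        )
        amps = amps + np.where(
            (centers >= 1500.0) & (slope > 0), cfg.recovery_bound_boost, 0.0
        )
        return np.clip(amps, 0.0, None)
    raise ValueError(f"unknown treatment {treatment!r}")


def band_amplitudes(
    day: float, treatment: str, line: str, cfg: GeneratorConfig
) -> np.ndarray:
    """Noiseless band amplitudes for one (day, treatment, line) cell at the
    population-average drying rate (γ = 1)."""
    return _amps_with_rate(day, treatment, line, cfg, 1.0)


def irreducible_day_rmse(cfg: GeneratorConfig, line: str) -> float:
    """Closed-form floor on the RMS error of predicting nominal day.

    The spectral state of a stressed plant at nominal day d is
    γ·max(0, d − onset) effective days with γ ~ N(1, plant_rate_sd).  An
    estimator that inverts the mean trajectory (d̂ = onset + state) is
    left with variance plant_rate_sd²·(d − onset)² per post-onset day; for
    pre-onset days the state is identically zero, so no estimator can do
    better than the mean of those days.  The RMS over the measurement
    schedule is the irreducible error of the calibration problem.
    """
    onset = cfg.onset_days[line]
    days = np.asarray(cfg.stress_days, dtype=float)
    pre = days[days <= onset]
    post = days[days > onset]
    mse = 0.0
    if pre.size:
        mse += float(np.sum((pre - pre.mean()) ** 2))
    mse += float(cfg.plant_rate_sd**2 * np.sum((post - onset) ** 2))
    return float(np.sqrt(mse / days.size))


def _band_matrix(cfg: GeneratorConfig) -> np.ndarray:
    wl = np.asarray(cfg.wavelengths, dtype=float)
    centers = np.array([b.center for b in cfg.bands])[:, None]
    widths = np.array([b.width for b in cfg.bands])[:, None]
    return np.exp(-((wl[None, :] - centers) ** 2) / (2.0 * widths**2))


def _baseline(cfg: GeneratorConfig) -> np.ndarray:
    wl = np.asarray(cfg.wavelengths, dtype=float)
    span = wl[-1] - wl[0]
    return cfg.baseline_intercept + cfg.baseline_slope * (wl - wl[0]) / span


def render_spectrum(amplitudes: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    """Deterministic forward model: baseline plus the Gaussian band mixture."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.size != len(cfg.bands):
        raise ValueError("one amplitude per configured band required")
    return _baseline(cfg) + amplitudes @ _band_matrix(cfg)


@dataclass
class GroundTruth:
    """Noiseless generator state: per-spectrum scatter parameters, leaf
    effects, band amplitudes and clean renders, aligned with the
    SpectraSet rows."""

    records: pd.DataFrame          # spectrum_id, a, b, leaf_effect
    amplitudes: np.ndarray         # n_spectra × n_bands(model)
    renders: np.ndarray            # n_spectra × n_grid, before scatter/noise
    config: GeneratorConfig


def generate_experiment(cfg: GeneratorConfig | None = None) -> tuple[SpectraSet, GroundTruth]:
    """Simulate the full crossed design.

    Defaults: 2 lines × (10 stress + 10 control) plants × 3 leaves ×
    (6 drought + 2 rewatering occasions) × 3 replicates = 2880 spectra.
    Fully reproducible from ``cfg.seed``.
    """
    if cfg is None:
        cfg = GeneratorConfig()
    issues = cfg.validate()
    if issues:
        raise ValueError("invalid generator config: " + "; ".join(issues))

    rng = np.random.default_rng(cfg.seed)
    G = _band_matrix(cfg)
    baseline = _baseline(cfg)
    n_grid = len(cfg.wavelengths)

    occasions = [("drought", d) for d in cfg.stress_days] + [
        ("rewatering", d) for d in cfg.recovery_days
    ]

    meta_rows, spectra, amps_rows, renders = [], [], [], []
    gt_rows = []
    for line in cfg.line_labels:
        for arm, prefix in (("stress", "S"), ("control", "C")):
            for plant in range(1, cfg.n_plants_per_arm + 1):
                plant_id = f"{line}-{prefix}{plant:02d}"
                rate = (
                    rng.normal(1.0, cfg.plant_rate_sd) if arm == "stress" else 1.0
                )
                for leaf in cfg.leaves:
                    delta = rng.normal(0.0, cfg.leaf_effect_sd)
                    for stage, day in occasions:
                        if arm == "control":
                            treatment = "control"
                        else:
                            treatment = "stress" if stage == "drought" else "recovery"
                        amps = _amps_with_rate(
                            day, treatment, line, cfg, rate
                        ) * (1.0 + delta)
                        clean = baseline + amps @ G
                        for rep in range(1, cfg.replicates + 1):
                            a = rng.normal(0.0, cfg.scatter_offset_sd)
                            b = rng.normal(1.0, cfg.scatter_slope_sd)
                            noise = rng.normal(0.0, cfg.noise_sd, n_grid)
                            spec = b * clean + a + noise
                            sid = f"{plant_id}-L{leaf}-{stage[:3]}{day:02d}-R{rep}"
                            meta_rows.append(
                                {
                                    "spectrum_id": sid,
                                    "line_label": line,
                                    "plant_id": plant_id,
                                    "leaf_index": leaf,
                                    "replicate": rep,
                                    "treatment": treatment,
                                    "day": day,
                                    "stage_tag": stage,
                                }
                            )
                            spectra.append(spec)
                            amps_rows.append(amps)
                            renders.append(clean)
                            gt_rows.append(
                                {
                                    "spectrum_id": sid,
                                    "a": a,
                                    "b": b,
                                    "leaf_effect": delta,
                                    "drying_rate": rate,
                                    "stress_progress": rate
                                    * _stress_progress(
                                        day, cfg.onset_days[line], cfg
                                    )
                                    if treatment != "control"
                                    else 0.0,
                                }
                            )

    sset = SpectraSet(
        np.asarray(cfg.wavelengths, dtype=float).copy(),
        np.vstack(spectra),
        pd.DataFrame(meta_rows),
    )
    truth = GroundTruth(
        records=pd.DataFrame(gt_rows),
        amplitudes=np.vstack(amps_rows),
        renders=np.vstack(renders),
        config=cfg,
    )
    return sset, truth


def zero_signal_config(cfg: GeneratorConfig | None = None) -> GeneratorConfig:
    """Negative-control variant: all day slopes zero (no drought signal)."""
    if cfg is None:
        cfg = GeneratorConfig()
    flat = tuple(replace(b, day_slope=0.0) for b in cfg.bands)
    return replace(cfg, bands=flat, recovery_bound_boost=0.0)
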