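"""Spectral pretreatments: Savitzky–Golay derivatives, multiplicative
scatter correction (MSC) and day-difference spectra.

Two pretreatment paths are used downstream and never mix:

* aquagram path — raw absorbance → MSC → per-band z-scores;
* calibration path — raw absorbance → SG 2nd derivative → 1300–1600 nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .spectra import SpectraSet, average_spectra, grid_step


@dataclass(frozen=True)
class SgConfig:
    """Savitzky–Golay derivative settings.

    ``scale='per_index'`` returns derivatives with respect to the band
    index; ``'per_nm'`` divides by ``step**deriv_order`` so units are per
    nm^deriv.  Window is in points and must be odd.
    """

    window: int = 11
    polyorder: int = 2
    deriv_order: int = 2
    scale: str = "per_index"

    def __post_init__(self) -> None:
        if self.window < 5 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 5, got {self.window}")
        if self.polyorder < 2 or self.polyorder >= self.window:
            raise ValueError("require 2 <= polyorder < window")
        if not 0 <= self.deriv_order <= self.polyorder:
            raise ValueError("require 0 <= deriv_order <= polyorder")
        if self.scale not in ("per_index", "per_nm"):
            raise ValueError(f"unknown scale {self.scale!r}")


def sg_derivative(s: SpectraSet, cfg: SgConfig = SgConfig()) -> SpectraSet:
    """Savitzky–Golay derivative of every spectrum.

    The half-window at each edge is dropped: only interior bands, where
    the local polynomial fit is centred, are returned.
    """
    if s.n_bands < cfg.window:
        raise ValueError(
            f"window {cfg.window} exceeds number of bands {s.n_bands}"
        )
    deriv = savgol_filter(
        s.absorbance, cfg.window, cfg.polyorder, deriv=cfg.deriv_order,
        delta=1.0, axis=1,
    )
    if cfg.scale == "per_nm":
        deriv = deriv / grid_step(s.wavelengths) ** cfg.deriv_order
    half = cfg.window // 2
    return SpectraSet(
        s.wavelengths[half:-half], deriv[:, half:-half], s.meta.copy()
    )


@dataclass
class MscModel:
    """Fitted multiplicative scatter correction.

    ``reference`` is the mean training spectrum; ``offsets``/``slopes``
    are the per-spectrum affine fits from the training pass.
    """

    reference: np.ndarray
    wavelengths: np.ndarray
    offsets: np.ndarray
    slopes: np.ndarray


def _msc_correct(
    absorbance: np.ndarray, reference: np.ndarray, ids: Iterable
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ref_c = reference - reference.mean()
    denom = float(ref_c @ ref_c)
    if denom < 1e-24:
        raise ValueError("reference spectrum has no variance; MSC undefined")
    slopes = (absorbance - absorbance.mean(axis=1, keepdims=True)) @ ref_c / denom
    offsets = absorbance.mean(axis=1) - slopes * reference.mean()
    bad = np.abs(slopes) < 1e-12
    if bad.any():
        which = [str(i) for i, b in zip(ids, bad) if b]
        raise ValueError(
            f"degenerate spectrum (slope ~ 0) in MSC: {', '.join(which)}"
        )
    corrected = (absorbance - offsets[:, None]) / slopes[:, None]
    return corrected, offsets, slopes


def msc_fit_transform(s: SpectraSet) -> tuple[SpectraSet, MscModel]:
    """Fit MSC on a set (reference = set mean) and correct it.

    Each spectrum ``x`` is regressed on the reference, ``x ≈ a + b·ref``,
    and replaced by ``(x − a)/b``.
    """
    if s.n_spectra < 2:
        raise ValueError("MSC needs at least two spectra")
    reference = s.absorbance.mean(axis=0)
    ids = (
        s.meta["spectrum_id"].tolist()
        if "spectrum_id" in s.meta.columns
        else list(range(s.n_spectra))
    )
    corrected, offsets, slopes = _msc_correct(s.absorbance, reference, ids)
    model = MscModel(reference, s.wavelengths.copy(), offsets, slopes)
    return SpectraSet(s.wavelengths.copy(), corrected, s.meta.copy()), model


def msc_apply(model: MscModel, s: SpectraSet) -> SpectraSet:
    """Correct new spectra against a stored MSC reference."""
    if s.n_bands != model.wavelengths.size or not np.allclose(
        s.wavelengths, model.wavelengths, rtol=0, atol=1e-9
    ):
        raise ValueError("wavelength grid does not match the MSC model")
    ids = (
        s.meta["spectrum_id"].tolist()
        if "spectrum_id" in s.meta.columns
        else list(range(s.n_spectra))
    )
    corrected, _, _ = _msc_correct(s.absorbance, model.reference, ids)
    return SpectraSet(s.wavelengths.copy(), corrected, s.meta.copy())


def difference_spectra(
    s: SpectraSet,
    baseline: object,
    field: str = "day",
    within: Iterable[str] = (),
) -> SpectraSet:
    """Differences of group-mean spectra against a baseline group.

    The input is averaged over ``within + [field]``; for every non-baseline
    value of ``field`` the output row is ``mean(field=v) − mean(field=baseline)``
    (computed separately for each combination of the ``within`` fields).
    The baseline rows themselves are excluded.
    """
    within = list(within)
    means = average_spectra(s, within + [field])
    if not (means.meta[field] == baseline).any():
        raise ValueError(f"baseline {field}={baseline!r} not present")
    rows, recs = [], []
    if within:
        groups = means.meta.groupby(within, sort=False).indices.items()
    else:
        groups = [((), np.arange(means.n_spectra))]
    for wname, idx in groups:
        wname = wname if isinstance(wname, tuple) else (wname,)
        block = means.meta.iloc[idx]
        base_pos = idx[block[field] == baseline]
        if len(base_pos) == 0:
            raise ValueError(
                f"baseline {field}={baseline!r} missing for group {wname}"
            )
        base_row = means.absorbance[base_pos[0]]
        for i in idx:
            if means.meta.iloc[i][field] == baseline:
                continue
            rows.append(means.absorbance[i] - base_row)
            rec = {k: v for k, v in zip(within, wname)}
            rec[field] = means.meta.iloc[i][field]
            rec["baseline"] = baseline
            rec["spectrum_id"] = (
                "diff:" + "|".join(map(str, wname))
                + f"|{field}={means.meta.iloc[i][field]}-vs-{baseline}"
            )
            recs.append(rec)
    if not rows:
        warnings.warn("difference set is empty (only the baseline was present)")
        return SpectraSet(
            s.wavelengths.copy(),
            np.empty((0, s.n_bands)),
            pd.DataFrame(columns=list(within) + [field, "baseline", "spectrum_id"]),
        )
    return SpectraSet(s.wavelengths.copy(), np.vstack(rows), pd.DataFrame(recs))
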