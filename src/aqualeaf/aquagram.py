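"""Aquagrams: normalized water-band absorbance over the 19 WAMACs.

A WAMAC (water matrix coordinate) is a characteristic water absorption
band in the first overtone region.  The aquagram value at WAMAC λ is the
z-score of the (scatter-corrected) absorbance across all spectra,

    Aq_λ = (A_λ − μ_λ) / σ_λ,

with μ_λ and σ_λ taken over the whole normalization population, so that
group means are directly comparable on one radar chart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .spectra import SpectraSet, grid_step, nearest_band_index


class Wamac(NamedTuple):
    code: str
    wavelength_nm: float
    annotation: str


@dataclass(frozen=True)
class WamacTable:
    """Ordered list of water matrix coordinates (C1…C19)."""

    entries: tuple[Wamac, ...]

    def __post_init__(self) -> None:
        wl = [e.wavelength_nm for e in self.entries]
        if any(b <= a for a, b in zip(wl, wl[1:])):
            raise ValueError("WAMAC wavelengths must be strictly increasing")

    @property
    def codes(self) -> list[str]:
        return [e.code for e in self.entries]

    @property
    def wavelengths(self) -> np.ndarray:
        return np.array([e.wavelength_nm for e in self.entries])

    def __len__(self) -> int:
        return len(self.entries)


_DEFAULT_WAMACS = (
    ("C1", 1347.899, "water shell / proton hydration"),
    ("C2", 1360.288, "proton hydration"),
    ("C3", 1372.677, "ion hydration"),
    ("C4", 1385.065, "trapped water"),
    ("C5", 1391.260, "trapped water / water vapour"),
    ("C6", 1409.843, "free water"),
    ("C7", 1416.037, "free water / weakly hydrogen-bonded water"),
    ("C8", 1422.231, "water dimer, weakly hydrogen-bonded"),
    ("C9", 1440.814, "water with one hydrogen bond"),
    ("C10", 1447.009, "water hydration band"),
    ("C11", 1453.203, "hydrated / solvated water"),
    ("C12", 1465.592, "water with two hydrogen bonds; protein–water"),
    ("C13", 1471.786, "water with three hydrogen bonds"),
    ("C14", 1490.369, "water with four hydrogen bonds"),
    ("C15", 1502.758, "strongly bound water; water–cellulose"),
    ("C16", 1515.147, "strongly bound water"),
    ("C17", 1521.341, "water–cellulose interaction"),
    ("C18", 1533.730, "water–cellulose / structural water"),
    ("C19", 1570.896, "strongly bound, structural water"),
)


def default_wamacs() -> WamacTable:
    """The 19-coordinate WAMAC set used for leaf water spectral patterns."""
    return WamacTable(tuple(Wamac(*row) for row in _DEFAULT_WAMACS))


@dataclass
class AquagramResult:
    """Per-spectrum and group-mean aquagram values.

    ``per_spectrum_aq`` is ``n_spectra × n_wamacs``; ``group_aq`` is a
    DataFrame with the grouping fields plus one column per WAMAC code.
    ``mu``/``sigma`` are the normalization statistics per WAMAC.
    """

    codes: list[str]
    wavelengths: np.ndarray
    band_indices: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    per_spectrum_aq: np.ndarray
    meta: pd.DataFrame
    group_keys: list[str]
    group_aq: pd.DataFrame
    group_sizes: pd.Series


def compute_aquagram(
    s: SpectraSet,
    wamacs: WamacTable | None = None,
    by: str | Iterable[str] = "treatment",
    ddof: int = 1,
) -> AquagramResult:
    """Aquagram z-scores per spectrum plus group means.

    The caller is expected to pass MSC-corrected absorbance.  The
    normalization population is *all* spectra in ``s`` — control, stress
    and recovery together — so group aquagrams share one scale.
    ``ddof=1`` (sample SD) by default.
    """
    if wamacs is None:
        wamacs = default_wamacs()
    if s.n_spectra < 2:
        raise ValueError("aquagram needs at least two spectra")
    keys = [by] if isinstance(by, str) else list(by)
    unknown = [k for k in keys if k not in s.meta.columns]
    if unknown:
        raise KeyError(f"unknown grouping field(s): {unknown}")

    step = grid_step(s.wavelengths)
    idx = np.array(
        [nearest_band_index(s.wavelengths, w) for w in wamacs.wavelengths]
    )
    off = np.abs(s.wavelengths[idx] - wamacs.wavelengths)
    if np.any(off > step / 2 + 1e-9):
        worst = wamacs.codes[int(np.argmax(off))]
        warnings.warn(
            f"WAMAC {worst} is {off.max():.2f} nm from the nearest band; "
            "using the nearest band"
        )

    A = s.absorbance[:, idx]
    mu = A.mean(axis=0)
    sigma = A.std(axis=0, ddof=ddof)
    if np.any(sigma < 1e-12):
        bad = wamacs.codes[int(np.argmin(sigma))]
        raise ValueError(f"degenerate variance at WAMAC {bad}")
    aq = (A - mu) / sigma

    aq_df = pd.DataFrame(aq, columns=wamacs.codes)
    aq_df[keys] = s.meta[keys].to_numpy()
    grouped = aq_df.groupby(keys, sort=False)
    group_aq = grouped[wamacs.codes].mean().reset_index()
    sizes = grouped.size()

    return AquagramResult(
        codes=wamacs.codes,
        wavelengths=wamacs.wavelengths,
        band_indices=idx,
        mu=mu,
        sigma=sigma,
        per_spectrum_aq=aq,
        meta=s.meta.copy(),
        group_keys=keys,
        group_aq=group_aq,
        group_sizes=sizes,
    )


def export_aquagram(
    r: AquagramResult, path_csv: str | Path, path_chart: str | Path | None = None
) -> list[Path]:
    """Write the group aquagram as CSV and (optionally) a radar chart.

    CSV columns are the grouping fields then ``<code>_<wavelength>`` per
    WAMAC.  The radar chart draws one closed polygon per group with axes
    C1→C19 clockwise.
    """
    path_csv = Path(path_csv)
    out = r.group_aq.copy()
    colmap = {
        c: f"{c}_{w:.3f}" for c, w in zip(r.codes, r.wavelengths)
    }
    out = out.rename(columns=colmap)
    out.to_csv(path_csv, index=False, float_format="%.17g")
    written = [path_csv]

    if path_chart is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n = len(r.codes)
        # clockwise from the top
        angles = -np.linspace(0, 2 * np.pi, n, endpoint=False) + np.pi / 2
        fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(7, 7))
        for _, row in r.group_aq.iterrows():
            vals = row[r.codes].to_numpy(dtype=float)
            theta = np.concatenate([angles, angles[:1]])
            vv = np.concatenate([vals, vals[:1]])
            label = " / ".join(str(row[k]) for k in r.group_keys)
            ax.plot(theta, vv, label=label)
        ax.set_xticks(angles)
        ax.set_xticklabels(
            [f"{c}\n{w:.0f}" for c, w in zip(r.codes, r.wavelengths)], fontsize=7
        )
        ax.set_title("Aquagram (normalized absorbance at the WAMACs)")
        ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=8)
        fig.savefig(path_chart, bbox_inches="tight", dpi=120)
        plt.close(fig)
        written.append(Path(path_chart))
    return written
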