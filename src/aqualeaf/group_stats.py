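"""Group-comparison statistics for aquagram values, plus the RWC utility.

The procedure mirrors common practice in spectral phenotyping: per WAMAC,
a Levene test (group-mean centred) decides between Tukey's HSD
(homoscedastic) and Dunnett's T3 (heteroscedastic) pairwise comparisons,
and each pair's p-value is binned into strength bands at 0.001, 0.01 and
0.05.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aquagram import AquagramResult

STRENGTH_BANDS = ("lt_0.001", "0.001_0.01", "0.01_0.05", "ns")


def strength_band(p: float) -> str:
    """Bin a p-value; boundary values fall in the more significant band."""
    if p <= 0.001:
        return "lt_0.001"
    if p <= 0.01:
        return "0.001_0.01"
    if p <= 0.05:
        return "0.01_0.05"
    return "ns"


def _split(values, groups) -> tuple[list[str], list[np.ndarray]]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    labels = list(pd.unique(groups))
    samples = [values[groups == g] for g in labels]
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    for lab, sample in zip(labels, samples):
        if sample.size < 2:
            raise ValueError(f"group {lab!r} has fewer than two observations")
    return [str(lab) for lab in labels], samples


def levene(values: Sequence[float], groups: Sequence) -> tuple[float, float]:
    """Levene's test for equality of variances (group-mean centred)."""
    _, samples = _split(values, groups)
    stat, p = stats.levene(*samples, center="mean")
    return float(stat), float(p)


def dunnett_t3(samples: list[np.ndarray]) -> list[tuple[int, int, float]]:
    """Dunnett's T3 all-pairs comparisons for unequal variances.

    Per pair: Welch t statistic and df; the p-value uses the independence
    approximation to the studentized-maximum-modulus distribution,
    ``p = 1 − (2·F_t(|t|; df) − 1)^m`` with m = number of pairs.
    """
    k = len(samples)
    m = k * (k - 1) // 2
    out = []
    for i, j in combinations(range(k), 2):
        a, b = samples[i], samples[j]
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        se2 = va + vb
        if se2 <= 0:
            t, df = np.inf, 1.0
        else:
            t = abs(a.mean() - b.mean()) / np.sqrt(se2)
            df = se2**2 / (
                va**2 / (a.size - 1) + vb**2 / (b.size - 1)
            )
        central = 2.0 * stats.t.cdf(t, df) - 1.0
        p = 1.0 - np.clip(central, 0.0, 1.0) ** m
        out.append((i, j, float(np.clip(p, 0.0, 1.0))))
    return out


def posthoc(
    values: Sequence[float],
    groups: Sequence,
    alpha_levene: float = 0.05,
) -> pd.DataFrame:
    """Levene-gated all-pairs post hoc comparisons.

    Homoscedastic (Levene p ≥ ``alpha_levene``) → Tukey HSD; otherwise
    Dunnett T3.  Returns one row per pair with p-value, strength band,
    the test used and the Levene p.
    """
    labels, samples = _split(values, groups)
    lev_stat, lev_p = levene(values, groups)
    rows = []
    if lev_p >= alpha_levene:
        test = "tukey"
        res = stats.tukey_hsd(*samples)
        pairs = [
            (i, j, float(res.pvalue[i, j]))
            for i, j in combinations(range(len(samples)), 2)
        ]
    else:
        test = "dunnett_t3"
        pairs = dunnett_t3(samples)
    for i, j, p in pairs:
        rows.append(
            {
                "pair": f"{labels[i]}-{labels[j]}",
                "p_value": p,
                "strength_band": strength_band(p),
                "test": test,
                "levene_p": lev_p,
            }
        )
    return pd.DataFrame(rows)


def wamac_significance(
    r: AquagramResult,
    group_field: str = "treatment",
    alpha_levene: float = 0.05,
) -> pd.DataFrame:
    """Per-WAMAC pairwise significance of aquagram values between groups.

    Runs :func:`posthoc` over ``group_field`` on the per-spectrum aquagram
    values at every WAMAC; output has one row per (WAMAC, pair).
    """
    if group_field not in r.meta.columns:
        raise KeyError(f"metadata field {group_field!r} not present")
    groups = r.meta[group_field].to_numpy()
    tables = []
    for col, (code, wl) in enumerate(zip(r.codes, r.wavelengths)):
        tab = posthoc(r.per_spectrum_aq[:, col], groups, alpha_levene)
        tab.insert(0, "wamac_code", code)
        tab.insert(0, "wavelength_nm", wl)
        tables.append(tab)
    return pd.concat(tables, ignore_index=True)


def rwc(fw: float, dw: float, ftw: float) -> float:
    """Relative water content in percent: ``100·(FW − DW)/(FTW − DW)``.

    FW fresh weight, DW dry weight, FTW fresh turgor weight (g).  FW below
    DW is physically impossible; it is clamped to 0% with a warning.
    """
    if ftw <= dw:
        raise ValueError("fresh turgor weight must exceed dry weight")
    if fw < dw:
        warnings.warn("fresh weight below dry weight; RWC clamped to 0%")
        return 0.0
    return 100.0 * (fw - dw) / (ftw - dw)
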