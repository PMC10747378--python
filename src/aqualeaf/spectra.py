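"""Spectral data model and I/O.

A :class:`SpectraSet` bundles a common wavelength grid (nm), an absorbance
matrix (log(1/R) convention, one spectrum per row) and a per-spectrum
metadata table.  It is the exchange currency of the whole pipeline:
pretreatments, aquagrams, significance tables and calibration models all
consume and produce it.

The canonical on-disk representation is a wide CSV: the metadata columns
first, then one numeric column per band named by its wavelength in nm.
A long (tidy) dialect with one row per (spectrum, band) is also supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

#: Metadata columns of the wide CSV dialect, in canonical order.
META_COLUMNS = [
    "spectrum_id",
    "line_label",
    "plant_id",
    "leaf_index",
    "replicate",
    "treatment",
    "day",
    "stage_tag",
]

_TREATMENTS = {"control", "stress", "recovery"}


class SpectraFormatError(ValueError):
    """Raised when an input file violates the spectral table format."""


@dataclass
class SpectraSet:
    """A set of spectra sharing one wavelength grid.

    Parameters
    ----------
    wavelengths
        Band centres in nm, strictly ascending.
    absorbance
        Matrix of shape ``(n_spectra, n_bands)``; no NaN/inf allowed.
    meta
        One row per spectrum.  Arbitrary extra columns are preserved;
        the canonical columns are listed in :data:`META_COLUMNS`.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be one-dimensional")
        if self.absorbance.shape[0] == 0:
            self.absorbance = self.absorbance.reshape(0, self.wavelengths.size)
        if self.absorbance.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} bands but the grid "
                f"has {self.wavelengths.size}"
            )
        if self.wavelengths.size and np.any(np.diff(self.wavelengths) <= 0):
            # normalise: accept any input order but store ascending
            order = np.argsort(self.wavelengths, kind="stable")
            if np.any(np.diff(self.wavelengths[order]) <= 0):
                raise ValueError("duplicate wavelengths in grid")
            self.wavelengths = self.wavelengths[order]
            self.absorbance = self.absorbance[:, order]
        if self.meta is None or (len(self.meta) == 0 and self.meta.shape[1] == 0):
            self.meta = pd.DataFrame(index=range(self.absorbance.shape[0]))
        self.meta = self.meta.reset_index(drop=True)
        if len(self.meta) != self.absorbance.shape[0]:
            raise ValueError(
                f"meta has {len(self.meta)} rows but absorbance has "
                f"{self.absorbance.shape[0]} spectra"
            )
        if self.absorbance.size and not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")

    # ------------------------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size

    def copy(self) -> "SpectraSet":
        return SpectraSet(
            self.wavelengths.copy(), self.absorbance.copy(), self.meta.copy()
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lo = self.wavelengths[0] if self.n_bands else float("nan")
        hi = self.wavelengths[-1] if self.n_bands else float("nan")
        return (
            f"SpectraSet(n_spectra={self.n_spectra}, n_bands={self.n_bands}, "
            f"range=[{lo:.1f}, {hi:.1f}] nm)"
        )


# ----------------------------------------------------------------------
# I/O


def _format_wavelength(w: float) -> str:
    """Column label for a band: at least three decimals, lossless."""
    s = f"{w:.3f}"
    return s if float(s) == w else repr(float(w))


def load_spectra(path: str | Path, dialect: str = "wide_csv") -> SpectraSet:
    """Read a :class:`SpectraSet` from CSV.

    ``wide_csv``: metadata columns (:data:`META_COLUMNS`) followed by one
    column per band, named by wavelength in nm.  ``long_csv``: columns
    ``META_COLUMNS + [wavelength_nm, absorbance]``, one row per band.
    Wavelengths are normalised to ascending order on load.
    """
    path = Path(path)
    if dialect == "wide_csv":
        df = pd.read_csv(path)
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise SpectraFormatError(
                f"missing metadata column(s) {missing} in {path}"
            )
        band_cols = [c for c in df.columns if c not in META_COLUMNS]
        try:
            wavelengths = np.array([float(c) for c in band_cols])
        except ValueError as exc:
            raise SpectraFormatError(
                f"non-numeric band column in {path}: {exc}"
            ) from exc
        absorbance = df[band_cols].to_numpy(dtype=float)
        if absorbance.size and np.any(~np.isfinite(absorbance)):
            bad = int(np.where(~np.isfinite(absorbance).all(axis=1))[0][0])
            raise SpectraFormatError(f"missing absorbance value(s) at row {bad}")
        meta = df[META_COLUMNS].copy()
        return SpectraSet(wavelengths, absorbance, meta)
    if dialect == "long_csv":
        df = pd.read_csv(path)
        required = META_COLUMNS + ["wavelength_nm", "absorbance"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SpectraFormatError(f"missing column(s) {missing} in {path}")
        wide = df.pivot_table(
            index="spectrum_id",
            columns="wavelength_nm",
            values="absorbance",
            sort=False,
        )
        if wide.isna().to_numpy().any():
            sid = wide.index[wide.isna().any(axis=1)][0]
            raise SpectraFormatError(
                f"spectrum {sid!r} is missing one or more bands"
            )
        meta = (
            df[META_COLUMNS]
            .drop_duplicates(subset="spectrum_id")
            .set_index("spectrum_id")
            .loc[wide.index]
            .reset_index()
        )
        wavelengths = wide.columns.to_numpy(dtype=float)
        return SpectraSet(wavelengths, wide.to_numpy(dtype=float), meta)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_spectra(s: SpectraSet, path: str | Path, dialect: str = "wide_csv") -> Path:
    """Write a :class:`SpectraSet` to CSV; inverse of :func:`load_spectra`.

    Round-trips metadata exactly and absorbance to full double precision.
    """
    path = Path(path)
    meta = s.meta.copy()
    for col in META_COLUMNS:
        if col not in meta.columns:
            meta[col] = "" if col not in ("leaf_index", "replicate", "day") else 0
    meta = meta[META_COLUMNS + [c for c in meta.columns if c not in META_COLUMNS]]
    if dialect == "wide_csv":
        band_cols = [_format_wavelength(w) for w in s.wavelengths]
        out = pd.concat(
            [meta.reset_index(drop=True),
             pd.DataFrame(s.absorbance, columns=band_cols)],
            axis=1,
        )
        out.to_csv(path, index=False, float_format="%.17g")
        return path
    if dialect == "long_csv":
        rows = meta.reset_index(drop=True)
        long = rows.loc[rows.index.repeat(s.n_bands)].reset_index(drop=True)
        long["wavelength_nm"] = np.tile(s.wavelengths, s.n_spectra)
        long["absorbance"] = s.absorbance.ravel()
        long.to_csv(path, index=False, float_format="%.17g")
        return path
    raise ValueError(f"unknown dialect {dialect!r}")


# ----------------------------------------------------------------------
# Selection / grouping primitives


def select_wavelength_range(s: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Keep bands with ``lo <= wavelength <= hi`` (inclusive)."""
    if not lo < hi:
        raise ValueError(f"require lo < hi, got [{lo}, {hi}]")
    mask = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not mask.any():
        raise ValueError(f"no band in range [{lo}, {hi}] nm")
    return SpectraSet(s.wavelengths[mask], s.absorbance[:, mask], s.meta.copy())


def subset(
    s: SpectraSet, predicate: str | Callable[[pd.DataFrame], Sequence[bool]]
) -> SpectraSet:
    """Row-filter by a metadata predicate.

    ``predicate`` is either a pandas query string (e.g.
    ``"treatment == 'stress' and leaf_index == 3"``) or a callable mapping
    the metadata frame to a boolean mask.  Row order is preserved.
    """
    if isinstance(predicate, str):
        try:
            kept = s.meta.query(predicate)
        except pd.errors.UndefinedVariableError as exc:
            raise KeyError(f"unknown metadata field in predicate: {exc}") from exc
        mask = s.meta.index.isin(kept.index)
    else:
        mask = np.asarray(predicate(s.meta), dtype=bool)
        if mask.shape != (s.n_spectra,):
            raise ValueError("predicate mask has wrong length")
    return SpectraSet(s.wavelengths.copy(), s.absorbance[mask], s.meta[mask].copy())


def average_spectra(s: SpectraSet, by: str | Iterable[str]) -> SpectraSet:
    """Arithmetic group-mean spectra.

    One output spectrum per distinct combination of the ``by`` metadata
    fields; output metadata carries the group labels plus ``n_members``.
    Groups appear in order of first occurrence.
    """
    keys = [by] if isinstance(by, str) else list(by)
    unknown = [k for k in keys if k not in s.meta.columns]
    if unknown:
        raise KeyError(f"unknown metadata field(s): {unknown}")
    if s.n_spectra == 0:
        raise ValueError("cannot average an empty SpectraSet")
    grouped = s.meta.groupby(keys, sort=False, dropna=False)
    labels, rows, counts = [], [], []
    for name, idx in grouped.indices.items():
        labels.append(name if isinstance(name, tuple) else (name,))
        rows.append(s.absorbance[idx].mean(axis=0))
        counts.append(len(idx))
    meta = pd.DataFrame(labels, columns=keys)
    meta["n_members"] = counts
    meta["spectrum_id"] = [
        "mean:" + "|".join(str(v) for v in lab) for lab in labels
    ]
    return SpectraSet(s.wavelengths.copy(), np.vstack(rows), meta)


def nearest_band_index(wavelengths: np.ndarray, target: float) -> int:
    """Index of the band closest to ``target`` nm; ties go to the lower band."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size == 0:
        raise ValueError("empty wavelength grid")
    # argmin returns the first minimiser; with an ascending grid that is
    # the lower-wavelength band, which is the documented tie rule.
    return int(np.argmin(np.abs(wavelengths - target)))


def grid_step(wavelengths: np.ndarray) -> float:
    """Median spacing of the grid in nm."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size < 2:
        raise ValueError("need at least two bands")
    return float(np.median(np.diff(wavelengths)))
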