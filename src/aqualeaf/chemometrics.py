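"""PLS1 calibration with grouped cross-validation and SECV factor choice.

The calibration relates second-derivative spectra to days of drought.
Replicate spectra of one leaf at one measurement occasion are never split
between training and validation: cross-validation leaves out whole
replicate groups, and the number of latent factors is the one minimising
the standard error of cross-validation (SECV), ties going to fewer
factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class PlsModel:
    n_factors: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray       # p × a
    x_loadings: np.ndarray    # p × a
    y_loadings: np.ndarray    # a
    regression_vector: np.ndarray  # p
    wavelengths: np.ndarray | None = None


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_factors: int):
    """Mean-centred PLS1; returns weights W, loadings P and y-loadings q.

    For a single response NIPALS needs no inner iteration: per factor,
    w ∝ X'y, t = Xw, then X is deflated by t p' and y by q t.
    """
    n, p = Xc.shape
    W = np.zeros((p, n_factors))
    P = np.zeros((p, n_factors))
    q = np.zeros(n_factors)
    X = Xc.copy()
    y = yc.copy()
    a = 0
    for _ in range(n_factors):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-13:
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-13:
            break
        P[:, a] = X.T @ t / tt
        q[a] = float(y @ t) / tt
        W[:, a] = w
        X -= np.outer(t, P[:, a])
        y = y - q[a] * t
        a += 1
    return W[:, :a], P[:, :a], q[:a]


def _beta(W: np.ndarray, P: np.ndarray, q: np.ndarray, k: int) -> np.ndarray:
    """Regression vector from the first k factors: B = W (P'W)^{-1} q."""
    Wk, Pk, qk = W[:, :k], P[:, :k], q[:k]
    return Wk @ np.linalg.solve(Pk.T @ Wk, qk)


def fit_pls(
    X: np.ndarray,
    y: np.ndarray,
    n_factors: int,
    wavelengths: np.ndarray | None = None,
) -> PlsModel:
    """Fit a mean-centred PLS1 model with ``n_factors`` latent factors."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y have incompatible shapes")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    if n < 2:
        raise ValueError("need at least two samples")
    if y.std() < 1e-13:
        raise ValueError("y has zero variance; nothing to calibrate")
    if not 1 <= n_factors <= min(n - 1, p):
        raise ValueError(
            f"n_factors must be in [1, {min(n - 1, p)}], got {n_factors}"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q = _nipals_pls1(X - x_mean, y - y_mean, n_factors)
    if W.shape[1] < n_factors:
        warnings.warn(
            f"X rank exhausted after {W.shape[1]} factors "
            f"(requested {n_factors})"
        )
    beta = _beta(W, P, q, W.shape[1])
    return PlsModel(
        n_factors=W.shape[1],
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        regression_vector=beta,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths),
    )


def predict(m: PlsModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != m.x_mean.size:
        raise ValueError(
            f"model was trained on {m.x_mean.size} bands, got {X.shape[1]}"
        )
    return m.y_mean + (X - m.x_mean) @ m.regression_vector


def leave_one_group_out(group_ids) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic leave-one-group-out partition.

    Folds are ordered by sorted unique group id; each fold's test set is
    exactly the rows of one group, its training set all other rows.
    """
    group_ids = np.asarray(group_ids)
    uniq = sorted(pd.unique(group_ids).tolist())
    if len(uniq) < 2:
        raise ValueError("need at least two groups for grouped CV")
    folds = []
    for g in uniq:
        test = np.flatnonzero(group_ids == g)
        train = np.flatnonzero(group_ids != g)
        folds.append((train, test))
    return folds


@dataclass
class CvReport:
    secv_curve: np.ndarray          # SECV per factor count 1..max
    n_factors: int
    secv: float
    sec: float
    r2cv: float
    r2cal: float
    r2cv_press: float               # 1 − PRESS/SStot alternative
    r2cal_press: float
    cv_predictions: np.ndarray      # at the chosen factor count
    fold_group_ids: list = field(default_factory=list)
    model: PlsModel | None = None


def _r2_corr(y: np.ndarray, yhat: np.ndarray) -> float:
    if np.std(yhat) < 1e-13:
        return 0.0
    return float(np.corrcoef(y, yhat)[0, 1] ** 2)


def grouped_cv(
    X: np.ndarray,
    y: np.ndarray,
    group_ids,
    max_factors: int = 10,
    wavelengths: np.ndarray | None = None,
) -> CvReport:
    """Leave-one-group-out cross-validation over 1..max_factors factors.

    SECV_k = sqrt(Σ(ŷ_cv − y)²/n) per factor count k; the chosen model has
    the argmin SECV (first minimum on ties).  SEC/R²cal come from a full
    refit at the chosen count; R²cv is the squared Pearson correlation of
    the CV predictions with y (the 1 − PRESS/SStot variant is also
    reported).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    folds = leave_one_group_out(group_ids)
    biggest = max(len(test) for _, test in folds)
    if biggest >= X.shape[0]:
        raise ValueError("one group contains every row")
    a_max = min(max_factors, X.shape[0] - biggest - 1, X.shape[1])
    if a_max < 1:
        raise ValueError("no admissible factor count for these folds")

    preds = np.full((X.shape[0], a_max), np.nan)
    for train, test in folds:
        xm = X[train].mean(axis=0)
        ym = float(y[train].mean())
        W, P, q = _nipals_pls1(X[train] - xm, y[train] - ym, a_max)
        avail = W.shape[1]
        for k in range(1, avail + 1):
            beta = _beta(W, P, q, k)
            preds[test, k - 1] = ym + (X[test] - xm) @ beta
        # rank-deficient training fold: carry the last model forward
        for k in range(avail + 1, a_max + 1):
            preds[test, k - 1] = preds[test, avail - 1]

    resid = preds - y[:, None]
    secv_curve = np.sqrt(np.mean(resid**2, axis=0))
    chosen = int(np.argmin(secv_curve)) + 1

    model = fit_pls(X, y, chosen, wavelengths=wavelengths)
    y_cal = predict(model, X)
    sec = float(np.sqrt(np.mean((y_cal - y) ** 2)))
    sstot = float(np.sum((y - y.mean()) ** 2))
    cvp = preds[:, chosen - 1]
    return CvReport(
        secv_curve=secv_curve,
        n_factors=chosen,
        secv=float(secv_curve[chosen - 1]),
        sec=sec,
        r2cv=_r2_corr(y, cvp),
        r2cal=_r2_corr(y, y_cal),
        r2cv_press=float(1.0 - np.sum((cvp - y) ** 2) / sstot),
        r2cal_press=float(1.0 - np.sum((y_cal - y) ** 2) / sstot),
        cv_predictions=cvp,
        fold_group_ids=sorted(pd.unique(np.asarray(group_ids)).tolist()),
        model=model,
    )


def correlation_spectrum(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation between y and each band; length p, in [−1, 1].

    Zero-variance bands get r = 0 with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if y.std() < 1e-13:
        raise ValueError("y has zero variance")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = float(np.sqrt((yc**2).sum()))
    zero = sx < 1e-13
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance band(s); r set to 0")
    r = np.zeros(X.shape[1])
    ok = ~zero
    r[ok] = (Xc[:, ok].T @ yc) / (sx[ok] * sy)
    return np.clip(r, -1.0, 1.0)


def important_bands(
    m: PlsModel, top_k: int, wavelengths: np.ndarray | None = None
) -> list[tuple[float, float]]:
    """Bands ranked by |regression coefficient|, largest first.

    Returns (wavelength, signed coefficient) pairs; falls back to band
    indices if no grid is attached to the model.
    """
    beta = m.regression_vector
    wl = wavelengths if wavelengths is not None else m.wavelengths
    if wl is None:
        wl = np.arange(beta.size, dtype=float)
    if np.allclose(beta, 0.0):
        warnings.warn("all regression coefficients are zero")
        return []
    if top_k > beta.size:
        warnings.warn(f"top_k={top_k} exceeds {beta.size} bands; clipping")
        top_k = beta.size
    order = np.argsort(-np.abs(beta), kind="stable")[:top_k]
    return [(float(wl[i]), float(beta[i])) for i in order]
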