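"""Multi-trial VAR modeling and time-domain pairwise-conditional Granger
causality over ROI timecourses.

Input series are lists of segments (one per trial, time x ROI); lagged
predictors never cross a segment boundary, so short trial-wise timecourses
can be pooled without spurious transitions.  The conditional Granger
causality from source i to target j given the remaining ROIs is the
log-ratio of the target's residual variance in the reduced model (omitting
i's lags, keeping everyone else's) over the full model,

    F[i -> j] = ln( var(e_j | all lags except i) / var(e_j | all lags) ),

computed by explicit full-vs-reduced least-squares fits.  For a pure VAR
process this equals the population Granger causality; e.g. in the two-channel
system y_t = a y_{t-1} + c x_{t-1} + e with white unit-variance x,
F[x -> y] = ln(1 + c^2 sigma_x^2 / sigma_e^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats

__all__ = ["VARModel", "GCResult", "select_var_order", "fit_var",
           "pairwise_conditional_gc", "compare_gc_conditions"]


@dataclass
class VARModel:
    order: int
    coefs: np.ndarray           # (p, n_rois, n_rois); coefs[k][i, j] = effect of j's lag-(k+1) on i
    intercept: np.ndarray
    sigma: np.ndarray           # residual covariance
    n_rois: int
    n_obs: int                  # pooled usable rows
    stable: bool = True


@dataclass
class GCResult:
    rois: list
    F: np.ndarray               # F[i, j] = GC from roi i to roi j; diagonal NaN
    order: int
    condition: str = ""


def _as_segments(segments) -> list[np.ndarray]:
    segs = [np.asarray(s, float) for s in segments]
    if not segs:
        raise ValueError("no segments provided")
    width = {s.shape[1] for s in segs}
    if len(width) != 1:
        raise ValueError("segments have inconsistent channel counts")
    return segs


def _lagged_rows(segs: list[np.ndarray], p: int, demean: bool = True):
    """Stacked (target, lagged-predictor) rows, lags confined within segments."""
    Ys, Xs = [], []
    for s in segs:
        if demean:
            s = s - s.mean(axis=0)
        if s.shape[0] <= p:
            continue
        Ys.append(s[p:])
        Xs.append(np.hstack([s[p - k - 1:s.shape[0] - k - 1] for k in range(p)]))
    if not Ys:
        raise ValueError(f"no segment longer than the model order {p}")
    return np.vstack(Ys), np.vstack(Xs)


def select_var_order(segments, p_max: int = 10, demean: bool = True) -> int:
    """AIC-minimizing VAR order over 1..p_max on pooled segments.

    Each candidate order is evaluated on the same rows (those usable at
    p_max) so the criteria are comparable.
    """
    segs = _as_segments(segments)
    if min(s.shape[0] for s in segs) <= p_max:
        raise ValueError("segment length must exceed p_max")
    n_ch = segs[0].shape[1]
    best_p, best_aic = None, np.inf
    for p in range(1, p_max + 1):
        # evaluate on rows usable at p_max for comparability
        trimmed = [s[p_max - p:] for s in segs]
        Y, X = _lagged_rows(trimmed, p, demean)
        T = Y.shape[0]
        X1 = np.hstack([X, np.ones((T, 1))])
        B, *_ = np.linalg.lstsq(X1, Y, rcond=None)
        E = Y - X1 @ B
        sigma = (E.T @ E) / T
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            continue
        aic = logdet + 2.0 * p * n_ch * n_ch / T
        if aic < best_aic:
            best_aic, best_p = aic, p
    if best_p is None:
        raise RuntimeError("AIC evaluation failed for all candidate orders")
    return best_p


def fit_var(segments, p: int, demean: bool = True) -> VARModel:
    """Least-squares multi-segment VAR(p) fit with pooled residual covariance."""
    if p < 1:
        raise ValueError("order must be >= 1")
    segs = _as_segments(segments)
    n_ch = segs[0].shape[1]
    Y, X = _lagged_rows(segs, p, demean)
    T = Y.shape[0]
    X1 = np.hstack([X, np.ones((T, 1))])
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient VAR design")
    B, *_ = np.linalg.lstsq(X1, Y, rcond=None)
    E = Y - X1 @ B
    dof = max(T - X1.shape[1], 1)
    sigma = (E.T @ E) / dof
    coefs = np.stack([B[k * n_ch:(k + 1) * n_ch].T for k in range(p)])
    companion = np.zeros((n_ch * p, n_ch * p))
    for k in range(p):
        companion[:n_ch, k * n_ch:(k + 1) * n_ch] = coefs[k]
    if p > 1:
        companion[n_ch:, :-n_ch] = np.eye(n_ch * (p - 1))
    stable = bool(np.max(np.abs(np.linalg.eigvals(companion))) < 1)
    if not stable:
        warnings.warn("fitted VAR is unstable (companion spectral radius >= 1)")
    return VARModel(order=p, coefs=coefs, intercept=B[-1], sigma=sigma,
                    n_rois=n_ch, n_obs=T, stable=stable)


def _resid_var(Y, X1, j: int) -> float:
    # ML (1/T) variance: nesting then guarantees reduced >= full, so F >= 0
    b, *_ = np.linalg.lstsq(X1, Y[:, j], rcond=None)
    e = Y[:, j] - X1 @ b
    return float(e @ e) / Y.shape[0]


def pairwise_conditional_gc(segments, p: int, rois: list | None = None,
                            demean: bool = True, condition: str = "") -> GCResult:
    """Time-domain pairwise-conditional Granger causality matrix."""
    segs = _as_segments(segments)
    n_ch = segs[0].shape[1]
    if n_ch < 2:
        raise ValueError("need at least 2 ROIs")
    rois = list(rois) if rois is not None else [f"roi{i}" for i in range(n_ch)]
    Y, X = _lagged_rows(segs, p, demean)
    T = Y.shape[0]
    X1 = np.hstack([X, np.ones((T, 1))])
    F = np.full((n_ch, n_ch), np.nan)
    full_var = [_resid_var(Y, X1, j) for j in range(n_ch)]
    for i in range(n_ch):
        # reduced design: drop source i's lags at every lag order
        keep = np.ones(X.shape[1], bool)
        for k in range(p):
            keep[k * n_ch + i] = False
        Xr = np.hstack([X[:, keep], np.ones((T, 1))])
        for j in range(n_ch):
            if i == j:
                continue
            rv = _resid_var(Y, Xr, j)
            F[i, j] = max(np.log(rv / full_var[j]), 0.0)
    return GCResult(rois=rois, F=F, order=p, condition=condition)


def compare_gc_conditions(gc_a: list[GCResult], gc_b: list[GCResult],
                          fdr_q: float | None = 0.05) -> pd.DataFrame:
    """Paired tests per directed connection between two conditions.

    ``gc_a`` and ``gc_b`` are per-subject GC results (matched order).
    Returns a tidy frame with t, p, Cohen's d and (optionally) BH-FDR
    adjusted p per connection.
    """
    if len(gc_a) != len(gc_b) or len(gc_a) < 3:
        raise ValueError("need matched per-subject results with n >= 3")
    rois = gc_a[0].rois
    A = np.stack([g.F for g in gc_a])
    B = np.stack([g.F for g in gc_b])
    rows = []
    for i in range(len(rois)):
        for j in range(len(rois)):
            if i == j:
                continue
            res = stats.paired_t(A[:, i, j], B[:, i, j])
            rows.append({"source": rois[i], "target": rois[j],
                         "mean_a": A[:, i, j].mean(), "mean_b": B[:, i, j].mean(),
                         "t": res.statistic, "p": res.p, "cohen_d": res.effect_size})
    df = pd.DataFrame(rows)
    if fdr_q is not None:
        df["p_fdr"], df["significant"] = stats.bh_fdr(df["p"].to_numpy(), q=fdr_q)
    return df
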