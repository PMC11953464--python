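"""GLM estimation surfaces for ultrafast-fMRI runs.

Implements the estimation ladder used throughout the package:

* percent-signal scaling of each voxel (temporal mean -> 100),
* whole-event regressors (onset trains convolved with the double-gamma HRF),
* shape-free FIR deconvolution (one regressor per post-onset TR lag,
  default 69 lags ~ 13.5 s at TR = 199 ms),
* censoring plus AR(1) prewhitened generalized least squares,
* condition-level FIR timecourses (with arbitrary trial groupings, e.g.
  RT quartiles),
* simultaneous single-trial whole-event betas (pattern estimation), and
* single-trial FIR timecourses by the least-squares-sum (LSS) scheme: the
  target trial gets its own FIR set while the remaining same-condition
  trials share one set and every other condition shares one set each.

Serial correlation is handled by feasible GLS: AR(1) coefficients are
estimated per voxel from OLS residuals and the median across voxels is used
to whiten data and design (per-voxel whitening available via
``ar_pooling='voxel'`` for small problems).  Incorrect trials are always
modeled separately as nuisance, and slow drift as per-run Legendre
polynomials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import legendre
from scipy import linalg

from .bold import BOLDRun
from .hrf import HRFParams, eval_hrf

__all__ = [
    "DesignMatrix",
    "BetaEstimates",
    "ConditionTimecourse",
    "scale_percent",
    "build_fir_basis",
    "build_event_regressor",
    "fit_glm_prewhitened",
    "estimate_condition_timecourses",
    "estimate_trial_betas",
    "estimate_trialwise_timecourses_lss",
    "condition_tmaps",
    "DEFAULT_WINDOW_POINTS",
]

#: FIR window length in TR lags.  13.53 s at TR = 199 ms; chosen to match the
#: conventional 69-point trial window for this design.
DEFAULT_WINDOW_POINTS = 69


# ---------------------------------------------------------------------------
# containers

@dataclass
class DesignMatrix:
    matrix: np.ndarray                 # time x regressors (censoring not yet applied)
    names: list[str]
    groups: dict = field(default_factory=dict)  # label -> column index array

    def cols(self, label: str) -> np.ndarray:
        return self.groups[label]


@dataclass
class BetaEstimates:
    betas: np.ndarray                  # regressors x voxels
    names: list[str]
    sigma2: np.ndarray                 # per voxel
    ar_coeff: np.ndarray               # per voxel (lag-1, from OLS residuals)
    dof: int
    tstats: dict = field(default_factory=dict)

    def block(self, design: DesignMatrix, label: str) -> np.ndarray:
        return self.betas[design.cols(label)]


@dataclass
class ConditionTimecourse:
    """ROI-mean percent-signal-change per post-onset lag for one condition."""

    condition: str
    time: np.ndarray                   # s from trial onset, spacing = TR
    values: np.ndarray
    n_trials: int
    roi: str | None = None


# ---------------------------------------------------------------------------
# elementary builders

def scale_percent(run: BOLDRun) -> BOLDRun:
    """Divide each voxel by its temporal mean and multiply by 100.

    Voxels with non-positive mean are flagged and excluded (dropped from the
    returned run).  Idempotent up to gain: scaling twice equals scaling once.
    """
    mean = run.data.mean(axis=0)
    bad = mean <= 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} voxel(s) with non-positive mean")
    keep = ~bad
    data = run.data[:, keep] / mean[keep] * 100.0
    return BOLDRun(data=data, tr=run.tr, run=run.run,
                   roi_labels=run.roi_labels[keep], nuisance=run.nuisance,
                   censor=run.censor)


def build_fir_basis(onsets: np.ndarray, window_points: int, tr: float,
                    n_volumes: int) -> np.ndarray:
    """FIR (per-lag indicator) columns for a set of onsets within one run.

    Column ``k`` has a 1 at ``volume(onset) + k`` for every onset; overlapping
    trials sum.  Onsets are rounded to the nearest TR.  Windows extending past
    the run end are truncated with a warning.
    """
    X = np.zeros((n_volumes, window_points))
    truncated = False
    for onset in np.atleast_1d(onsets):
        v0 = int(round(onset / tr))
        hi = min(window_points, n_volumes - v0)
        if hi < window_points:
            truncated = True
        if hi <= 0:
            continue
        X[v0 + np.arange(hi), np.arange(hi)] += 1.0
    if truncated:
        warnings.warn("FIR window truncated at run end")
    return X


def build_event_regressor(
    onsets: np.ndarray,
    hrf: HRFParams,
    tr: float,
    n_volumes: int,
    durations: np.ndarray | float | None = None,
    oversample: int = 10,
) -> np.ndarray:
    """Delta (or boxcar) train convolved with the HRF, sampled at the TR."""
    onsets = np.atleast_1d(np.asarray(onsets, float))
    dt = tr / oversample
    n_fine = n_volumes * oversample
    train = np.zeros(n_fine)
    if durations is None:
        for onset in onsets:
            i = int(round(onset / dt))
            if 0 <= i < n_fine:
                train[i] += 1.0
    else:
        durs = np.broadcast_to(np.atleast_1d(np.asarray(durations, float)), onsets.shape)
        for onset, d in zip(onsets, durs):
            i0 = int(round(onset / dt))
            i1 = int(round((onset + d) / dt))
            train[max(i0, 0):max(min(i1, n_fine), 0)] += dt
    kernel = eval_hrf(hrf, np.arange(0, 40.0, dt))
    conv = np.convolve(train, kernel)[:n_fine]
    return conv[::oversample]


def _drift_matrix(n_volumes: int, order: int) -> np.ndarray:
    x = np.linspace(-1, 1, n_volumes)
    return np.stack([legendre.legval(x, [0] * d + [1]) for d in range(order + 1)], axis=1)


# ---------------------------------------------------------------------------
# prewhitened GLS

def _segment_bounds(segments: np.ndarray) -> list[tuple[int, int]]:
    """Maximal contiguous blocks of identical segment id."""
    bounds = []
    start = 0
    for i in range(1, len(segments) + 1):
        if i == len(segments) or segments[i] != segments[start]:
            bounds.append((start, i))
            start = i
    return bounds


def _whiten(A: np.ndarray, rho: float, segments: np.ndarray) -> np.ndarray:
    """AR(1) whitening transform applied within contiguous segments."""
    out = np.empty_like(A, dtype=float)
    for s, e in _segment_bounds(segments):
        out[s] = A[s] * np.sqrt(1.0 - rho ** 2)
        out[s + 1:e] = A[s + 1:e] - rho * A[s:e - 1]
    return out


def _lag1_autocorr(R: np.ndarray, segments: np.ndarray) -> np.ndarray:
    num = np.zeros(R.shape[1])
    den = np.zeros(R.shape[1])
    for s, e in _segment_bounds(segments):
        seg = R[s:e]
        num += (seg[1:] * seg[:-1]).sum(axis=0)
        den += (seg ** 2).sum(axis=0)
    den[den == 0] = 1.0
    return np.clip(num / den, -0.95, 0.95)


def fit_glm_prewhitened(
    Y: np.ndarray,
    X: DesignMatrix | np.ndarray,
    censor: np.ndarray | None = None,
    segments: np.ndarray | None = None,
    contrasts: dict | None = None,
    ar_pooling: str = "pooled",
) -> BetaEstimates:
    """Censored, AR(1)-prewhitened GLS fit.

    ``segments`` marks rows that are temporally contiguous (run ids);
    censoring splits segments further so whitening never differences across
    a gap.  ``ar_pooling='pooled'`` whitens all voxels with the median AR
    coefficient (one solve); ``'voxel'`` whitens per voxel; ``'none'`` is OLS.
    """
    names = X.names if isinstance(X, DesignMatrix) else [f"x{i}" for i in range(X.shape[1])]
    Xm = X.matrix if isinstance(X, DesignMatrix) else np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    censor = np.ones(n, bool) if censor is None else np.asarray(censor, bool)
    segments = np.zeros(n, int) if segments is None else np.asarray(segments)
    # censoring deletes rows; gaps break whitening segments
    gap_id = np.cumsum(~censor)
    seg_after = (segments.astype(np.int64) * (n + 1) + gap_id)[censor]
    Yc, Xc = Y[censor], Xm[censor]

    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        _, R, piv = linalg.qr(Xc, mode="economic", pivoting=True)
        bad = sorted(names[j] for j in piv[rank:])
        raise np.linalg.LinAlgError(
            f"design is rank deficient after censoring; collinear columns: {bad}")

    beta_ols, *_ = linalg.lstsq(Xc, Yc, lapack_driver="gelsy")
    resid = Yc - Xc @ beta_ols
    rho_vox = _lag1_autocorr(resid, seg_after)
    dof = Xc.shape[0] - Xc.shape[1]

    def _gls(rho, Ysub):
        Xw = _whiten(Xc, rho, seg_after)
        Yw = _whiten(Ysub, rho, seg_after)
        b, *_ = linalg.lstsq(Xw, Yw, lapack_driver="gelsy")
        r = Yw - Xw @ b
        s2 = (r ** 2).sum(axis=0) / dof
        return b, s2, Xw

    if ar_pooling == "none":
        betas, sigma2, Xw = beta_ols, (resid ** 2).sum(axis=0) / dof, Xc
    elif ar_pooling == "voxel":
        betas = np.empty_like(beta_ols)
        sigma2 = np.empty(Y.shape[1])
        Xw = Xc
        for v in range(Y.shape[1]):
            b, s2, Xw = _gls(float(rho_vox[v]), Yc[:, [v]])
            betas[:, v], sigma2[v] = b[:, 0], s2[0]
    else:
        rho = float(np.median(rho_vox))
        betas, sigma2, Xw = _gls(rho, Yc)

    tstats = {}
    if contrasts:
        XtXi = linalg.pinv(Xw.T @ Xw)
        for name, c in contrasts.items():
            c = np.asarray(c, float)
            se = np.sqrt(sigma2 * float(c @ XtXi @ c))
            se[se == 0] = np.inf
            tstats[name] = (c @ betas) / se
    return BetaEstimates(betas=betas, names=names, sigma2=sigma2,
                         ar_coeff=rho_vox, dof=dof, tstats=tstats)


# ---------------------------------------------------------------------------
# session-level assembly

def _stack_runs(runs: list[BOLDRun], percent: bool = True):
    runs = [scale_percent(r) if percent else r for r in runs]
    Y = np.vstack([r.data for r in runs])
    censor = np.concatenate([r.censor for r in runs])
    seg = np.concatenate([np.full(r.n_volumes, r.run) for r in runs])
    return runs, Y, censor, seg


def _session_nuisance_drift(runs: list[BOLDRun], drift_order: int):
    """Block-diagonal per-run drift (Legendre 0..order) and nuisance columns."""
    cols, names = [], []
    n_total = sum(r.n_volumes for r in runs)
    offset = 0
    for r in runs:
        blocks = [_drift_matrix(r.n_volumes, drift_order)]
        blk_names = [f"drift{d}_run{r.run}" for d in range(drift_order + 1)]
        if r.nuisance.size:
            blocks.append(r.nuisance)
            blk_names += [f"nuis{j}_run{r.run}" for j in range(r.nuisance.shape[1])]
        B = np.hstack(blocks)
        full = np.zeros((n_total, B.shape[1]))
        full[offset:offset + r.n_volumes] = B
        cols.append(full)
        names += blk_names
        offset += r.n_volumes
    return np.hstack(cols), names


def _session_fir(runs: list[BOLDRun], trials: pd.DataFrame, idx, window_points: int):
    """Session-stacked FIR columns for the trials at positions ``idx``."""
    n_total = sum(r.n_volumes for r in runs)
    X = np.zeros((n_total, window_points))
    offset = {r.run: off for r, off in
              zip(runs, np.cumsum([0] + [r.n_volumes for r in runs[:-1]]))}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _, row in trials.loc[idx].iterrows():
            run = int(row["run"])
            r = next(r for r in runs if r.run == run)
            X[offset[run]:offset[run] + r.n_volumes] += build_fir_basis(
                np.array([row["onset_t1"]]), window_points, r.tr, r.n_volumes)
    return X


def _session_events(runs: list[BOLDRun], trials: pd.DataFrame, idx, hrf: HRFParams):
    n_total = sum(r.n_volumes for r in runs)
    x = np.zeros(n_total)
    offset = 0
    for r in runs:
        sub = trials.loc[idx]
        onsets = sub.loc[sub["run"] == r.run, "onset_t1"].to_numpy(float)
        if len(onsets):
            x[offset:offset + r.n_volumes] = build_event_regressor(
                onsets, hrf, r.tr, r.n_volumes)
        offset += r.n_volumes
    return x


def _base_groups(trials: pd.DataFrame, groupby=None):
    """Correct-trial groups (label -> positional index) plus the incorrect set."""
    correct = trials["correct"] if "correct" in trials else pd.Series(True, index=trials.index)
    if groupby is None:
        labels = trials["condition"]
    elif callable(groupby):
        labels = trials.apply(groupby, axis=1)
    else:
        labels = trials[groupby].astype(str)
    groups = {}
    for lab in labels[correct].unique():
        groups[str(lab)] = trials.index[(labels == lab) & correct]
    incorrect_idx = trials.index[~correct]
    return groups, incorrect_idx


# ---------------------------------------------------------------------------
# estimation surfaces

def estimate_condition_timecourses(
    runs: list[BOLDRun],
    trials: pd.DataFrame,
    window_points: int = DEFAULT_WINDOW_POINTS,
    groupby=None,
    rois: list[str] | None = None,
    drift_order: int = 3,
    ar_pooling: str = "pooled",
    percent: bool = True,
) -> dict:
    """Condition-level FIR timecourses, ROI-averaged after estimation.

    ``groupby`` generalizes the grouping beyond the condition column (e.g. a
    callable returning ``f"{condition}-Q{quartile}"`` implements the quartile
    variant with four regressor sets per condition).  Incorrect trials share a
    separate nuisance FIR set.  Returns ``{roi: {group: ConditionTimecourse}}``.
    """
    runs_s, Y, censor, seg = _stack_runs(runs, percent)
    groups, incorrect_idx = _base_groups(trials, groupby)
    if not groups:
        raise ValueError("no correct trials to model")
    cols, names, col_groups = [], [], {}
    at = 0
    for lab, idx in groups.items():
        if len(idx) == 0:
            warnings.warn(f"group {lab!r} has no correct trials; skipped")
            continue
        X = _session_fir(runs_s, trials, idx, window_points)
        cols.append(X)
        names += [f"{lab}_lag{k}" for k in range(window_points)]
        col_groups[lab] = np.arange(at, at + window_points)
        at += window_points
    if len(incorrect_idx):
        cols.append(_session_fir(runs_s, trials, incorrect_idx, window_points))
        names += [f"incorrect_lag{k}" for k in range(window_points)]
        at += window_points
    nd, nd_names = _session_nuisance_drift(runs_s, drift_order)
    cols.append(nd)
    names += nd_names
    design = DesignMatrix(np.hstack(cols), names, col_groups)
    est = fit_glm_prewhitened(Y, design, censor=censor, segments=seg, ar_pooling=ar_pooling)

    labels = runs_s[0].roi_labels
    rois = rois if rois is not None else list(dict.fromkeys(labels))
    tr = runs_s[0].tr
    time = np.arange(window_points) * tr
    out: dict = {}
    for roi in rois:
        vox = np.nonzero(labels == roi)[0]
        out[roi] = {}
        for lab, ci in col_groups.items():
            vals = est.betas[np.ix_(ci, vox)].mean(axis=1)
            out[roi][lab] = ConditionTimecourse(condition=lab, time=time,
                                                values=vals, n_trials=len(groups[lab]),
                                                roi=roi)
    return out


def estimate_trial_betas(
    runs: list[BOLDRun],
    trials: pd.DataFrame,
    hrf: HRFParams | None = None,
    conditions: tuple[str, ...] = ("AO", "VM"),
    drift_order: int = 3,
    ar_pooling: str = "pooled",
    condition_number_warn: float = 1e4,
) -> pd.DataFrame:
    """Simultaneous single-trial whole-event betas (trial x voxel patterns).

    Each correct trial of the target conditions gets its own HRF-convolved
    regressor in one model; other conditions and incorrect trials are modeled
    as aggregate nuisance regressors.  Rows are indexed by the trial-table
    index.
    """
    hrf = hrf or HRFParams()
    runs_s, Y, censor, seg = _stack_runs(runs)
    correct = trials["correct"] if "correct" in trials else pd.Series(True, index=trials.index)
    target = trials.index[trials["condition"].isin(conditions) & correct]
    if len(target) == 0:
        raise ValueError("no correct trials in the target conditions")
    cols = [np.stack([_session_events(runs_s, trials, [i], hrf) for i in target], axis=1)]
    names = [f"trial{i}" for i in target]
    for cond in trials["condition"].unique():
        if cond in conditions:
            continue
        idx = trials.index[(trials["condition"] == cond) & correct]
        if len(idx):
            cols.append(_session_events(runs_s, trials, idx, hrf)[:, None])
            names.append(f"cond_{cond}")
    if (~correct).any():
        cols.append(_session_events(runs_s, trials, trials.index[~correct], hrf)[:, None])
        names.append("incorrect")
    nd, nd_names = _session_nuisance_drift(runs_s, drift_order)
    cols.append(nd)
    names += nd_names
    X = np.hstack(cols)
    trial_block = X[:, :len(target)]
    cn = np.linalg.cond(trial_block[censor])
    if cn > condition_number_warn:
        warnings.warn(f"trial regressors nearly collinear (condition number {cn:.2g})")
    est = fit_glm_prewhitened(Y, DesignMatrix(X, names), censor=censor,
                              segments=seg, ar_pooling=ar_pooling)
    return pd.DataFrame(est.betas[:len(target)], index=target)


def estimate_trialwise_timecourses_lss(
    runs: list[BOLDRun],
    trials: pd.DataFrame,
    window_points: int = DEFAULT_WINDOW_POINTS,
    conditions: tuple[str, ...] | None = None,
    drift_order: int = 3,
    prewhiten: bool = True,
) -> tuple[np.ndarray, pd.Index]:
    """Single-trial FIR timecourses by least-squares-sum (LSS).

    For each target trial the model contains the trial's own FIR set, one
    shared FIR set for the remaining same-condition trials, one shared FIR
    set per other condition, the incorrect-trial set, drift and nuisance.
    Implemented with a shared-design QR factorization: for target trial t of
    condition c, span([F_t, F_c - F_t, ...]) = span([F_c, ..., F_t]), so the
    target beta equals the coefficient on the appended F_t plus the updated
    coefficient on the shared F_c set.  Exact, but one matrix factorization
    instead of one per trial.

    Returns ``(tc, index)`` where ``tc[k]`` is the (window_points, n_voxels)
    timecourse of trial ``index[k]``.
    """
    runs_s, Y, censor, seg = _stack_runs(runs)
    groups, incorrect_idx = _base_groups(trials)
    if conditions is not None:
        targets = [c for c in conditions if c in groups]
    else:
        targets = list(groups)
    cols, names, col_groups = [], [], {}
    at = 0
    for lab, idx in groups.items():
        cols.append(_session_fir(runs_s, trials, idx, window_points))
        names += [f"{lab}_lag{k}" for k in range(window_points)]
        col_groups[lab] = np.arange(at, at + window_points)
        at += window_points
    if len(incorrect_idx):
        cols.append(_session_fir(runs_s, trials, incorrect_idx, window_points))
        names += [f"incorrect_lag{k}" for k in range(window_points)]
        at += window_points
    nd, _ = _session_nuisance_drift(runs_s, drift_order)
    cols.append(nd)
    X0 = np.hstack(cols)

    # whiten once from the base model's OLS residuals (pooled AR coefficient)
    gap_id = np.cumsum(~censor)
    seg_c = (seg.astype(np.int64) * (len(censor) + 1) + gap_id)[censor]
    Yc, X0c = Y[censor], X0[censor]
    if prewhiten:
        b0, *_ = linalg.lstsq(X0c, Yc, lapack_driver="gelsy")
        rho = float(np.median(_lag1_autocorr(Yc - X0c @ b0, seg_c)))
        Yc = _whiten(Yc, rho, seg_c)
        X0c = _whiten(X0c, rho, seg_c)
    else:
        rho = 0.0

    Q0, R0 = np.linalg.qr(X0c)
    base_coef = linalg.solve_triangular(R0, Q0.T @ Yc)

    results: dict = {}
    todo: list[tuple] = []          # (trial index, condition block)
    for cond in targets:
        idx = groups[cond]
        block = col_groups[cond]
        if len(idx) < 2:
            warnings.warn(f"condition {cond!r} has a single correct trial; "
                          "falling back to the shared FIR estimate")
            for i in idx:
                results[i] = base_coef[block]
            continue
        todo += [(i, block) for i in idx]

    # chunked: one large orthogonalization GEMM for many trials at once
    chunk = 32
    w = window_points
    for at in range(0, len(todo), chunk):
        part = todo[at:at + chunk]
        F = np.concatenate(
            [_session_fir(runs_s, trials, [i], w)[censor] for i, _ in part], axis=1)
        if rho:
            F = _whiten(F, rho, seg_c)
        G = Q0.T @ F
        Fo = F - Q0 @ G
        for j, (i, block) in enumerate(part):
            sl = slice(j * w, (j + 1) * w)
            Fj, Gj = Fo[:, sl], G[:, sl]
            a_hat = linalg.lstsq(Fj.T @ Fj, Fj.T @ Yc, lapack_driver="gelsy")[0]
            beta_shared = base_coef[block] - linalg.solve_triangular(
                R0, Gj @ a_hat)[block]
            results[i] = a_hat + beta_shared

    index = pd.Index([i for grp in targets for i in groups[grp]])
    return np.stack([results[i] for i in index]), index


def condition_tmaps(
    runs: list[BOLDRun],
    trials: pd.DataFrame,
    hrf: HRFParams | None = None,
    conditions: tuple[str, ...] = ("AO", "VM"),
    drift_order: int = 3,
) -> dict:
    """Per-voxel t statistics of each condition's whole-event response vs.
    baseline (the activation maps feature selection ranks)."""
    hrf = hrf or HRFParams()
    runs_s, Y, censor, seg = _stack_runs(runs)
    correct = trials["correct"] if "correct" in trials else pd.Series(True, index=trials.index)
    cols, names = [], []
    for cond in trials["condition"].unique():
        idx = trials.index[(trials["condition"] == cond) & correct]
        if len(idx):
            cols.append(_session_events(runs_s, trials, idx, hrf)[:, None])
            names.append(str(cond))
    if (~correct).any():
        cols.append(_session_events(runs_s, trials, trials.index[~correct], hrf)[:, None])
        names.append("incorrect")
    nd, nd_names = _session_nuisance_drift(runs_s, drift_order)
    cols.append(nd)
    names += nd_names
    X = np.hstack(cols)
    contrasts = {}
    for cond in conditions:
        if cond in names:
            c = np.zeros(X.shape[1])
            c[names.index(cond)] = 1.0
            contrasts[cond] = c
    est = fit_glm_prewhitened(Y, DesignMatrix(X, names), censor=censor,
                              segments=seg, contrasts=contrasts)
    return {cond: est.tstats[cond] for cond in contrasts}
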