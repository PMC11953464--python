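"""Group-level inferential helpers.

Thin, uniformly-shaped wrappers: paired t with Cohen's d, one-way
repeated-measures ANOVA with partial eta squared, Pearson correlation,
Benjamini-Hochberg FDR, and a Jeffreys-Zellner-Siow Bayes factor quantifying
support for the null in one-sample/paired t designs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["TestResult", "paired_t", "rm_anova", "bh_fdr", "pearson_corr", "jzs_bf01"]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    dof: tuple
    p: float
    effect_size: float
    effect_name: str
    n: int
    tails: int = 2


def paired_t(x, y, tails: int = 2) -> TestResult:
    """Paired-sample t test; effect size Cohen's d = mean(diff)/sd(diff)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length with n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0:
        t = np.inf if d.mean() > 0 else (-np.inf if d.mean() < 0 else 0.0)
        p = 0.0 if t else 1.0
        return TestResult(t, (n - 1,), p, np.inf if t else 0.0, "cohen_d", n, tails)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    if tails == 1:
        p = sps.t.sf(t, n - 1)
    return TestResult(float(t), (n - 1,), float(p), float(d.mean() / sd),
                      "cohen_d", n, tails)


def rm_anova(matrix) -> TestResult:
    """One-way repeated-measures ANOVA on a subject x condition matrix.

    F = MS_condition / MS_(condition x subject); partial eta squared =
    SS_condition / (SS_condition + SS_error).  With two conditions,
    F equals the square of the paired t statistic.
    """
    M = np.asarray(matrix, float)
    if M.ndim != 2 or M.shape[0] < 3 or M.shape[1] < 2:
        raise ValueError("need a subject x condition matrix with >= 3 subjects, >= 2 conditions")
    if not np.all(np.isfinite(M)):
        raise ValueError("missing cells are not supported")
    n, k = M.shape
    grand = M.mean()
    ss_cond = n * ((M.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((M.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((M - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err == 0:
        F = np.inf if ms_cond > 0 else 0.0
        p = 0.0 if ms_cond > 0 else 1.0
    else:
        F = ms_cond / ms_err
        p = sps.f.sf(F, df1, df2)
    eta = ss_cond / (ss_cond + ss_err) if (ss_cond + ss_err) > 0 else 0.0
    return TestResult(float(F), (df1, df2), float(p), float(eta),
                      "partial_eta_sq", n, 2)


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, rejections at q)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy(), np.zeros(0, bool)
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson r with a two-tailed t-based p value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def jzs_bf01(t: float, n: int, r_scale: float = np.sqrt(2) / 2) -> float:
    """JZS Bayes factor BF01 (null over alternative) for a one-sample /
    paired t statistic, Cauchy prior scale ``r_scale``, by quadrature."""
    if n < 2:
        raise ValueError("need n >= 2")
    nu = n - 1
    t = float(t)

    def integrand(g):
        m = 1.0 + n * g * r_scale ** 2
        like = m ** -0.5 * (1.0 + t * t / (m * nu)) ** (-(nu + 1) / 2.0)
        prior = (2 * np.pi) ** -0.5 * g ** -1.5 * np.exp(-1.0 / (2 * g))
        return like * prior

    num, err = integrate.quad(integrand, 0, np.inf, limit=200)
    if not np.isfinite(num) or num <= 0:
        raise RuntimeError(f"BF integration failed (value {num}, err {err})")
    denom = (1.0 + t * t / nu) ** (-(nu + 1) / 2.0)
    return float(denom / num)
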