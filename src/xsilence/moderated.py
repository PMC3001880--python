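"""Two-group moderated-t differential expression on log2 intensities.

A deliberately small, fully specified stand-in for empirical-Bayes linear
modelling of microarrays: per gene, intensities are log2-transformed with a
pseudo-count of 1 and compared by a pooled-variance t-test whose per-gene
variance is shrunk toward a prior.  The prior ``(d0, s0^2)`` is fitted by
method of moments to the distribution of ``log s_g^2`` across genes, using
the scaled-F marginal of gene variances:

    E[log s_g^2] = log s0^2 + psi(d/2) - log(d/2) - psi(d0/2) + log(d0/2)
    Var[log s_g^2] = psi'(d/2) + psi'(d0/2)

where ``d`` is the per-gene residual degrees of freedom and ``psi`` the
digamma function.  The shrunk variance is the convex combination
``(d0*s0^2 + d*s_g^2) / (d0 + d)`` and the moderated t has ``d0 + d``
degrees of freedom.  Multiple testing is controlled by Benjamini-Hochberg.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import norm
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError


@dataclass
class DEParams:
    """Thresholds and options for differential-expression calling.

    A gene is called iff its BH-adjusted p-value is <= ``fdr_threshold``
    and its |log2 fold change| >= ``min_abs_log2_fold_change``.  With
    ``variance_shrinkage`` off an ordinary Welch t-test is used instead of
    the moderated t.
    """

    fdr_threshold: float = 0.05
    min_abs_log2_fold_change: float = 1.0
    variance_shrinkage: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_threshold < 1.0:
            raise AnalysisError("fdr_threshold must lie in (0, 1)")
        if self.min_abs_log2_fold_change < 0.0:
            raise AnalysisError("min_abs_log2_fold_change must be >= 0")


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve ``psi'(x) = y`` for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma is positive; y must be > 0")
    # psi'(x) ~ 1/x + 1/(2x^2) gives a good starting point
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        f = float(polygamma(1, x)) - y
        fprime = float(polygamma(2, x))
        step = f / fprime
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < tol * max(1.0, x):
            return x_new
        x = x_new
    return x


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior (d0, s0^2) to gene variances.

    Returns ``d0 = inf`` when the observed spread of ``log s2`` is no larger
    than expected from the chi-square sampling noise alone (all genes share
    one variance).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise AnalysisError("need at least two positive variances to fit the prior")
    z = np.log(s2)
    e = z - float(digamma(df / 2.0)) + math.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1))
    rhs = e_var - float(polygamma(1, df / 2.0))
    if rhs <= 0:
        return math.inf, float(math.exp(e_mean))
    half_d0 = trigamma_inverse(rhs)
    d0 = 2.0 * half_d0
    s0_2 = float(math.exp(e_mean + digamma(half_d0) - math.log(half_d0)))
    return d0, s0_2


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def moderated_ttest(
    group_a: pd.DataFrame, group_b: pd.DataFrame, params: DEParams | None = None
) -> pd.DataFrame:
    """Per-gene two-group test on log2(x + 1) intensities.

    Parameters
    ----------
    group_a, group_b
        Genes x replicates of linear intensities, identical row index.
        ``log2fc`` is mean(b) - mean(a), i.e. positive means higher in b.

    Returns
    -------
    DataFrame indexed like the input with columns ``log2fc``, ``t_stat``,
    ``p_value``, ``q_value``, ``s2``, ``s2_shrunk``, ``df_total``.
    """
    params = params or DEParams()
    if not group_a.index.equals(group_b.index):
        raise AnalysisError("the two groups must share the same gene index")
    n1, n2 = group_a.shape[1], group_b.shape[1]
    if n1 < 2 or n2 < 2:
        raise AnalysisError("need at least 2 replicates per group")
    la = np.log2(group_a.to_numpy(dtype=float) + 1.0)
    lb = np.log2(group_b.to_numpy(dtype=float) + 1.0)
    diff = lb.mean(axis=1) - la.mean(axis=1)
    va = la.var(axis=1, ddof=1)
    vb = lb.var(axis=1, ddof=1)
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * va + (n2 - 1) * vb) / d

    if params.variance_shrinkage and (s2 > 0).sum() >= 2:
        d0, s0_2 = fit_variance_prior(s2, d)
        if math.isinf(d0):
            s2_shrunk = np.full_like(s2, s0_2)
            df_total = math.inf
        else:
            s2_shrunk = (d0 * s0_2 + d * s2) / (d0 + d)
            df_total = d0 + d
        se = np.sqrt(s2_shrunk * (1.0 / n1 + 1.0 / n2))
        with np.errstate(invalid="ignore"):
            t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.sign(diff) * np.inf)
        t = np.where(np.isnan(t), 0.0, t)
        if math.isinf(df_total):
            p = 2.0 * norm.sf(np.abs(t))
        else:
            p = 2.0 * t_dist.sf(np.abs(t), df_total)
        p = np.where(se > 0, p, np.where(np.abs(diff) > 1e-12, 0.0, 1.0))
    else:
        if params.variance_shrinkage:
            warnings.warn(
                "all replicate variances are zero; variance shrinkage disabled, "
                "ordinary t used",
                stacklevel=2,
            )
        # Welch t-test; degenerate zero-variance genes decided by the mean diff
        se2 = va / n1 + vb / n2
        se = np.sqrt(se2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, diff / np.where(se > 0, se, 1.0), np.sign(diff) * np.inf)
            t = np.where(np.isnan(t), 0.0, t)
            num = se2**2
            den = (va / n1) ** 2 / (n1 - 1) + (vb / n2) ** 2 / (n2 - 1)
            df_w = np.where(den > 0, num / np.where(den > 0, den, 1.0), d)
        p = np.where(
            se > 0,
            2.0 * t_dist.sf(np.abs(t), np.maximum(df_w, 1.0)),
            np.where(np.abs(diff) > 1e-12, 0.0, 1.0),
        )
        s2_shrunk = s2
        df_total = float(d)

    p = np.clip(p, 0.0, 1.0)
    q = _bh_adjust(p)
    return pd.DataFrame(
        {
            "log2fc": diff,
            "t_stat": t,
            "p_value": p,
            "q_value": q,
            "s2": s2,
            "s2_shrunk": s2_shrunk,
            "df_total": df_total,
        },
        index=group_a.index,
    )


def call_genes(result: pd.DataFrame, params: DEParams | None = None) -> pd.Series:
    """Three-way call per gene: ``up`` / ``down`` (in group b relative to
    group a) / ``unchanged`` for genes failing either threshold."""
    params = params or DEParams()
    called = (result["q_value"] <= params.fdr_threshold) & (
        result["log2fc"].abs() >= params.min_abs_log2_fold_change
    )
    calls = np.where(
        called & (result["log2fc"] > 0),
        "up",
        np.where(called & (result["log2fc"] < 0), "down", "unchanged"),
    )
    return pd.Series(calls, index=result.index, name="call")
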