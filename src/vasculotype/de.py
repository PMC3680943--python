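"""Two-group moderated differential expression with empirical-Bayes
variance shrinkage, BH-FDR adjustment, and the rank/parametric tests used
elsewhere in the pipeline.

The hierarchical model: gene-wise residual variances s2_g (d residual df)
are shrunk toward a prior scale s0^2 with prior df d0, both estimated by
method of moments on log s2_g.  The moderated statistic
``t = beta / sqrt(s2_post * v)`` is referred to a t distribution on
``d0 + d`` degrees of freedom (normal when d0 is infinite).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .exceptions import ValidationError
from .expression import ExpressionMatrix

__all__ = [
    "ModerationPrior",
    "TwoGroupFit",
    "bh_adjust",
    "estimate_prior",
    "fit_two_group",
    "moderated_de",
    "moderated_test",
    "trigamma_inverse",
    "two_sample_t",
    "wilcoxon_rank_sum",
]

#: exact Wilcoxon enumeration is used when min group size <= this and no ties
WILCOXON_EXACT_MAX_N = 12


@dataclass(frozen=True)
class TwoGroupFit:
    """Per-gene two-group least-squares summaries (shared df and leverage)."""

    gene_ids: tuple[str, ...]
    beta: np.ndarray  # mean(group2) - mean(group1), log2 units
    s2: np.ndarray  # pooled within-group variance
    df: int  # n1 + n2 - 2
    v: float  # 1/n1 + 1/n2

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "s2", np.asarray(self.s2, dtype=float))
        if self.df < 1:
            raise ValidationError("residual df must be >= 1")
        if self.v <= 0:
            raise ValidationError("effect variance multiplier must be > 0")
        if np.any(self.s2 < 0):
            raise ValidationError("residual variances must be >= 0")


@dataclass(frozen=True)
class ModerationPrior:
    """Empirical-Bayes hyperparameters (d0 may be ``math.inf``; 0 disables)."""

    d0: float
    s02: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValidationError("prior df must be >= 0")
        if self.d0 > 0 and self.s02 <= 0:
            raise ValidationError("prior variance must be > 0")


def fit_two_group(
    matrix: ExpressionMatrix, group_labels: Sequence[int] | np.ndarray
) -> TwoGroupFit:
    """Per-gene difference of group means with pooled within-group variance.

    ``group_labels`` is a binary vector over samples; the effect is
    mean(group 1) - mean(group 0).
    """
    labels = np.asarray(group_labels)
    if labels.shape != (matrix.n_samples,):
        raise ValidationError("group_labels must have one entry per sample")
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValidationError(f"need exactly 2 groups, got {uniq.size}")
    g0 = matrix.values[:, labels == uniq[0]]
    g1 = matrix.values[:, labels == uniq[1]]
    n0, n1 = g0.shape[1], g1.shape[1]
    if min(n0, n1) < 2:
        raise ValidationError("each group needs >= 2 samples")
    beta = g1.mean(axis=1) - g0.mean(axis=1)
    ss = ((g0 - g0.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (g1 - g1.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    df = n0 + n1 - 2
    return TwoGroupFit(matrix.gene_ids, beta, ss / df, df, 1.0 / n0 + 1.0 / n1)


def trigamma_inverse(target: float, tol: float = 1e-12, max_iter: int = 80) -> float:
    """Solve psi'(x) = target for x > 0 (Newton on the inverse-scale)."""
    if target <= 0:
        raise ValidationError("trigamma target must be > 0")
    if target > 1e7:
        return 1.0 / math.sqrt(target)
    if target < 1e-6:
        return 1.0 / target
    x = 0.5 + 1.0 / target
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / target) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: int) -> ModerationPrior:
    """Method-of-moments hyperparameter estimation on log variances.

    With e_g = log s2_g - psi(d/2) + log(d/2): the excess dispersion of e
    over psi'(d/2) determines d0 via trigamma inversion; zero or negative
    excess yields an infinite-d0 (fully shrunk) prior.
    """
    s2 = np.asarray(s2, dtype=float)
    if np.all(s2 <= 0):
        raise ValidationError("all residual variances are zero")
    positive = s2[s2 > 0]
    if positive.size < s2.size:
        warnings.warn(
            f"dropping {s2.size - positive.size} non-positive variance(s) "
            "from prior estimation",
            stacklevel=2,
        )
    if positive.size < 10:
        raise ValidationError("need >= 10 genes with positive variance")
    half_d = df / 2.0
    e = np.log(positive) - special.digamma(half_d) + math.log(half_d)
    mean_e = float(e.mean())
    excess = float(e.var(ddof=1)) - float(special.polygamma(1, half_d))
    if excess <= 0:
        return ModerationPrior(math.inf, math.exp(mean_e))
    half_d0 = trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s02 = math.exp(mean_e + float(special.digamma(half_d0)) - math.log(half_d0))
    return ModerationPrior(d0, s02)


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def moderated_test(fit: TwoGroupFit, prior: ModerationPrior) -> pd.DataFrame:
    """Moderated t table: logFC, s2, s2_post, t_mod, df_total, p, q.

    ``prior.d0 == 0`` forces the ordinary (unmoderated) t statistic;
    ``prior.d0 == inf`` uses the prior variance alone with normal tails.
    """
    d0, s02, d, v = prior.d0, prior.s02, fit.df, fit.v
    if d0 == 0:
        s2_post = fit.s2.copy()
        df_total = float(d)
    elif math.isinf(d0):
        s2_post = np.full_like(fit.s2, s02)
        df_total = math.inf
    else:
        s2_post = (d0 * s02 + d * fit.s2) / (d0 + d)
        df_total = d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = fit.beta / np.sqrt(s2_post * v)
    t_mod = np.where(np.isnan(t_mod), 0.0, t_mod)  # 0/0 -> no evidence
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, 0.0, 1.0)
    return pd.DataFrame(
        {
            "gene_id": list(fit.gene_ids),
            "logFC": fit.beta,
            "s2": fit.s2,
            "s2_post": s2_post,
            "t_mod": t_mod,
            "df_total": df_total,
            "p": p,
            "q": bh_adjust(p),
        }
    )


def moderated_de(
    matrix: ExpressionMatrix, group_labels: Sequence[int] | np.ndarray
) -> pd.DataFrame:
    """Convenience composition: fit, estimate prior, moderated test."""
    fit = fit_two_group(matrix, group_labels)
    prior = estimate_prior(fit.s2, fit.df)
    return moderated_test(fit, prior)


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Rank-sum statistic of ``x`` and its p-value.

    Exact null enumeration when the smaller group has <= 12 observations and
    there are no ties; otherwise a normal approximation with tie correction
    and 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    exact = (min(x.size, y.size) <= WILCOXON_EXACT_MAX_N) and not has_ties
    res = stats.mannwhitneyu(
        x,
        y,
        alternative=alternative,
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0
    return w, float(res.pvalue)


def _rank_sum_rows(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised rank-sum over matrix rows: (W, p) arrays.

    Uses exact enumeration per row when possible (same policy as
    :func:`wilcoxon_rank_sum`); rows with ties fall back to the corrected
    normal approximation.
    """
    n1 = x.shape[1]
    combined = np.hstack([x, y])
    tied = np.array(
        [np.unique(row).size < row.size for row in combined]
    )
    w = np.empty(combined.shape[0])
    p = np.empty(combined.shape[0])
    clean = ~tied
    if clean.any():
        method = "exact" if min(x.shape[1], y.shape[1]) <= WILCOXON_EXACT_MAX_N else "asymptotic"
        res = stats.mannwhitneyu(
            x[clean], y[clean], alternative=alternative, method=method,
            use_continuity=True, axis=1,
        )
        w[clean] = res.statistic + n1 * (n1 + 1) / 2.0
        p[clean] = res.pvalue
    if tied.any():
        res = stats.mannwhitneyu(
            x[tied], y[tied], alternative=alternative, method="asymptotic",
            use_continuity=True, axis=1,
        )
        w[tied] = res.statistic + n1 * (n1 + 1) / 2.0
        p[tied] = res.pvalue
    return w, p


def two_sample_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Welch two-sample t with Welch-Satterthwaite df, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs >= 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        raise ValidationError("both groups constant with different means (infinite t)")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)
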