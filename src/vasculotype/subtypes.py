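"""Cluster characterisation: marker scoring/ordering, rank correlation,
Fisher exact tests, gene-signature overlap, signature-induced segregation,
and clinical-covariate association.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

from . import cluster as _cluster
from .exceptions import ValidationError
from .expression import ExpressionMatrix, GeneSet, row_zscore

__all__ = [
    "MarkerScore",
    "SegregationResult",
    "clinical_association",
    "fisher_exact_2x2",
    "induced_segregation",
    "marker_score",
    "signature_overlap",
    "spearman_correlation",
]


@dataclass(frozen=True)
class MarkerScore:
    """Per-sample mean of row-Z-scored marker expression."""

    scores: pd.Series  # indexed by sample id
    used: tuple[str, ...]
    missing: tuple[str, ...]

    def ordering(self) -> list[str]:
        """Sample ids by descending score; ties broken by sample id."""
        frame = self.scores.rename("score").rename_axis("sample_id").reset_index()
        frame = frame.sort_values(["score", "sample_id"], ascending=[False, True])
        return frame["sample_id"].tolist()


def marker_score(matrix: ExpressionMatrix, markers: GeneSet) -> MarkerScore:
    """Mean row-Z-score over the marker genes present in the matrix."""
    present = [g for g in matrix.gene_ids if g in markers.members]
    missing = tuple(sorted(markers.members - set(present)))
    if not present:
        raise ValidationError(
            f"no marker gene present in matrix; requested: {sorted(markers.members)}"
        )
    z = row_zscore(matrix.subset_genes(present))
    scores = pd.Series(z.values.mean(axis=0), index=list(matrix.sample_ids), name="score")
    return MarkerScore(scores, tuple(present), missing)


def spearman_correlation(
    x, y, method: str = "spearman"
) -> tuple[float, float]:
    """Rank (or, with ``method='pearson'``, linear) correlation with p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValidationError("need >= 3 paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValidationError("correlation undefined for a constant vector")
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
    elif method == "pearson":
        rho, p = stats.pearsonr(x, y)
    else:
        raise ValidationError(f"unknown method: {method!r}")
    return float(rho), float(p)


def fisher_exact_2x2(table, alternative: str = "two-sided") -> float:
    """Fisher exact p for a 2x2 count table.

    Two-sided p follows the probability-mass rule: the sum over all tables
    (margins fixed) whose point probability does not exceed the observed one.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if np.any(arr < 0) or not np.all(arr == arr.astype(int)):
        raise ValidationError("table entries must be non-negative integers")
    if arr.sum() == 0:
        raise ValidationError("table total must be > 0")
    _odds, p = stats.fisher_exact(arr.astype(int), alternative=alternative)
    return float(p)


def signature_overlap(
    set_a: GeneSet, set_b: GeneSet, universe: GeneSet
) -> tuple[np.ndarray, float]:
    """Membership 2x2 table and one-sided (over-representation) Fisher p."""
    for name, s in (("set_a", set_a), ("set_b", set_b)):
        stray = s.members - universe.members
        if stray:
            raise ValidationError(f"{name} not contained in universe: {sorted(stray)}")
    a = len(set_a.members & set_b.members)
    b = len(set_a.members - set_b.members)
    c = len(set_b.members - set_a.members)
    d = len(universe.members - set_a.members - set_b.members)
    table = np.array([[a, b], [c, d]])
    return table, fisher_exact_2x2(table, alternative="greater")


@dataclass(frozen=True)
class SegregationResult:
    predicted: pd.Series  # sample id -> cluster label (int)
    misassigned: int
    ari: float


def induced_segregation(
    matrix: ExpressionMatrix, signature: GeneSet, labels: pd.Series
) -> SegregationResult:
    """Cluster on a gene signature and score agreement with known groups.

    Subsets to signature genes, clusters samples (correlation distance +
    Ward), cuts at k = number of label groups, and reports the adjusted Rand
    index plus the minimal misassignment count over label matchings.
    """
    labels = labels.reindex(list(matrix.sample_ids))
    if labels.isna().any():
        raise ValidationError("labels must cover every sample in the matrix")
    groups = labels.unique()
    if groups.size < 2:
        raise ValidationError("need >= 2 label groups")
    present = [g for g in matrix.gene_ids if g in signature.members]
    if len(present) < 2:
        raise ValidationError(
            f"need >= 2 signature genes present in matrix, found {len(present)}"
        )
    sub = matrix.subset_genes(present)
    tree = _cluster.ward_linkage(_cluster.correlation_distance(sub), sub.sample_ids)
    cut = _cluster.cut_k(tree, int(groups.size))
    predicted = pd.Series({s: cut[s] for s in matrix.sample_ids}, name="cluster")
    ari = float(adjusted_rand_score(labels.to_numpy(), predicted.to_numpy()))
    confusion = pd.crosstab(predicted, labels).to_numpy()
    # pad to square for the assignment problem
    k = max(confusion.shape)
    padded = np.zeros((k, k), dtype=int)
    padded[: confusion.shape[0], : confusion.shape[1]] = confusion
    rows, cols = linear_sum_assignment(-padded)
    misassigned = int(labels.size - padded[rows, cols].sum())
    return SegregationResult(predicted, misassigned, ari)


def clinical_association(labels: pd.Series, table: pd.DataFrame) -> pd.DataFrame:
    """Per-covariate association between cluster labels and clinical fields.

    Categorical covariates use a Fisher exact test (2x2) or a chi-squared
    test (larger tables); continuous covariates use Welch's t between two
    clusters.  Samples with NA in a covariate are dropped for that covariate
    and counted in ``n_dropped``.  Entirely-NA covariates are reported as
    untestable with ``p = NaN``.
    """
    from .de import two_sample_t  # local import to avoid cycle at module load

    if labels.nunique() < 2:
        raise ValidationError("need >= 2 clusters")
    annot = table.set_index("sample_id").loc[labels.index]
    covariates = [
        ("mvd_class", "categorical"),
        ("er_status", "categorical"),
        ("her2_status", "categorical"),
        ("node_status", "categorical"),
        ("grade", "categorical"),
        ("recurrence", "categorical"),
        ("tumor_size", "continuous"),
    ]
    rows = []
    for name, kind in covariates:
        if name not in annot.columns:
            continue
        values = annot[name]
        mask = values.notna()
        n_used, n_dropped = int(mask.sum()), int((~mask).sum())
        sub_labels = labels[mask]
        sub_values = values[mask]
        p: float = np.nan
        test = "untestable"
        if n_used > 0 and sub_values.nunique() > 0 and sub_labels.nunique() >= 2:
            if kind == "continuous":
                if sub_labels.nunique() == 2:
                    groups = [
                        sub_values[sub_labels == g].to_numpy(dtype=float)
                        for g in sub_labels.unique()
                    ]
                    if min(len(g) for g in groups) >= 2:
                        try:
                            _t, p = two_sample_t(groups[0], groups[1])
                            test = "welch_t"
                        except ValidationError:
                            pass
                else:
                    groups = [
                        sub_values[sub_labels == g].to_numpy(dtype=float)
                        for g in sub_labels.unique()
                    ]
                    _f, p = stats.f_oneway(*groups)
                    test = "anova"
            else:
                if sub_values.nunique() == 1:
                    p, test = 1.0, "fisher_exact"
                else:
                    ct = pd.crosstab(sub_labels, sub_values).to_numpy()
                    if ct.shape == (2, 2):
                        p = fisher_exact_2x2(ct)
                        test = "fisher_exact"
                    else:
                        _c, p, _df, _e = stats.chi2_contingency(ct)
                        test = "chi2"
        rows.append(
            {"covariate": name, "test": test, "n_used": n_used,
             "n_dropped": n_dropped, "p": p}
        )
    return pd.DataFrame(rows)
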