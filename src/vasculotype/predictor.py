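"""Subtype-adjusted recurrence prediction under nested leave-one-out CV.

Each fold: (1) remove the per-gene mean difference between the two subtypes,
estimated on training samples only; (2) rank genes by a two-sided Wilcoxon
rank-sum test of recurrent vs nonrecurrent training samples and keep the top
k; (3) train a pooled-covariance linear discriminant on those genes;
(4) predict the held-out sample.  The prediction score is the posterior
probability of recurrence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .de import _rank_sum_rows
from .exceptions import ValidationError
from .expression import ExpressionMatrix
from .subtypes import fisher_exact_2x2

__all__ = [
    "CVReport",
    "LDAModel",
    "lda_predict",
    "lda_train",
    "loocv_run",
    "size_scan",
    "subtype_adjust",
    "wilcoxon_select",
]


def subtype_adjust(
    matrix: ExpressionMatrix,
    subtype_labels: pd.Series,
    training_ids: list[str],
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Remove the per-gene B-minus-A training mean difference from B samples.

    The adjustment vector is estimated on training samples only but applied
    to every subtype-B column of the supplied matrix (so a held-out B sample
    is shifted too).  After adjustment the per-gene training means of the two
    subtypes coincide.
    """
    labels = subtype_labels.reindex(list(matrix.sample_ids))
    if labels.isna().any():
        missing = labels[labels.isna()].index.tolist()
        raise ValidationError(f"samples without subtype label: {missing}")
    train = [s for s in training_ids if s in matrix.sample_ids]
    if set(train) != set(training_ids):
        raise ValidationError("training_ids must all be matrix samples")
    train_labels = labels.loc[train]
    for subtype in ("A", "B"):
        if (train_labels == subtype).sum() < 1:
            raise ValidationError(f"subtype {subtype} absent from training set")
    cols = {s: i for i, s in enumerate(matrix.sample_ids)}
    a_idx = [cols[s] for s in train if labels[s] == "A"]
    b_idx = [cols[s] for s in train if labels[s] == "B"]
    delta = matrix.values[:, b_idx].mean(axis=1) - matrix.values[:, a_idx].mean(axis=1)
    adjusted = matrix.values.copy()
    all_b = [cols[s] for s in matrix.sample_ids if labels[s] == "B"]
    adjusted[:, all_b] -= delta[:, None]
    return (
        ExpressionMatrix(adjusted, matrix.gene_ids, matrix.sample_ids),
        delta,
    )


def wilcoxon_select(
    matrix: ExpressionMatrix, outcome_labels: pd.Series, k: int
) -> list[str]:
    """Top-k genes by ascending two-sided Wilcoxon rank-sum p.

    Ties in p are broken by descending distance of the rank-sum statistic
    from its null expectation, then lexicographic gene id.
    """
    labels = outcome_labels.reindex(list(matrix.sample_ids))
    if labels.isna().any():
        raise ValidationError("outcome label required for every sample")
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValidationError(f"need exactly 2 outcome classes, got {classes}")
    if not 1 <= k <= matrix.n_genes:
        raise ValidationError(f"k={k} out of range [1, {matrix.n_genes}]")
    pos_mask = (labels == classes[1]).to_numpy()
    x = matrix.values[:, pos_mask]
    y = matrix.values[:, ~pos_mask]
    w, p = _rank_sum_rows(x, y)
    n1, n = x.shape[1], matrix.n_samples
    e0 = n1 * (n + 1) / 2.0
    frame = pd.DataFrame(
        {"gene_id": list(matrix.gene_ids), "p": p, "dev": -np.abs(w - e0)}
    )
    frame = frame.sort_values(["p", "dev", "gene_id"], kind="stable")
    return frame["gene_id"].head(k).tolist()


@dataclass(frozen=True)
class LDAModel:
    """Gaussian LDA with pooled within-class covariance."""

    gene_ids: tuple[str, ...]
    classes: tuple[str, ...]
    means: np.ndarray  # (n_classes, k)
    cov: np.ndarray  # (k, k), after any ridge
    priors: np.ndarray
    ridge_eps: float
    positive_class: str
    _cov_inv: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_cov_inv", np.linalg.inv(self.cov))


def lda_train(
    features: np.ndarray,
    labels: pd.Series | np.ndarray,
    gene_ids: list[str] | None = None,
    positive_class: str | None = None,
) -> LDAModel:
    """Fit pooled-covariance LDA with empirical class priors.

    A ridge of ``1e-6 * trace(cov) / k`` is added when the pooled covariance
    is singular or has condition number above 1e8.
    """
    x = np.asarray(features, dtype=float)
    labels = pd.Series(np.asarray(labels)).astype(str)
    if x.ndim != 2 or x.shape[0] != labels.size:
        raise ValidationError("features must be samples x k matching labels")
    k = x.shape[1]
    if k == 0:
        raise ValidationError("need >= 1 feature")
    classes = tuple(sorted(labels.unique()))
    if len(classes) < 2:
        raise ValidationError("need >= 2 classes")
    counts = labels.value_counts()
    small = [c for c in classes if counts[c] < 2]
    if small:
        raise ValidationError(f"class(es) with < 2 training samples: {small}")
    n = labels.size
    means = np.vstack([x[(labels == c).to_numpy()].mean(axis=0) for c in classes])
    pooled = np.zeros((k, k))
    for ci, c in enumerate(classes):
        xc = x[(labels == c).to_numpy()] - means[ci]
        pooled += xc.T @ xc
    pooled /= n - len(classes)
    eps = 0.0
    cond = np.linalg.cond(pooled)
    if not np.isfinite(cond) or cond > 1e8:
        eps = 1e-6 * np.trace(pooled) / k
        if eps <= 0:
            eps = 1e-6
        pooled = pooled + eps * np.eye(k)
    priors = np.array([counts[c] / n for c in classes])
    if positive_class is None:
        positive_class = classes[-1]
    if positive_class not in classes:
        raise ValidationError(f"positive_class {positive_class!r} not in {classes}")
    return LDAModel(
        tuple(gene_ids) if gene_ids else tuple(f"f{i}" for i in range(k)),
        classes,
        means,
        pooled,
        priors,
        eps,
        positive_class,
    )


def lda_predict(model: LDAModel, x: np.ndarray) -> tuple[str, float]:
    """Argmax-posterior label and posterior probability of the positive class."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != model.means.shape[1]:
        raise ValidationError(
            f"feature vector length {x.size} != model dimension {model.means.shape[1]}"
        )
    disc = np.array(
        [
            x @ model._cov_inv @ mu
            - 0.5 * mu @ model._cov_inv @ mu
            + math.log(pi)
            for mu, pi in zip(model.means, model.priors)
        ]
    )
    disc -= disc.max()  # stabilise softmax
    post = np.exp(disc)
    post /= post.sum()
    label = model.classes[int(np.argmax(disc))]
    p_positive = float(post[model.classes.index(model.positive_class)])
    return label, p_positive


@dataclass(frozen=True)
class CVReport:
    """Nested-LOOCV outcome: per-fold records plus overall summaries."""

    folds: pd.DataFrame  # sample_id, subtype, actual, predicted, score, genes
    accuracy: float
    confusion: pd.DataFrame  # predicted x actual counts
    fisher_p: float

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "fisher_p": self.fisher_p,
            "confusion": self.confusion.to_dict(),
            "folds": self.folds.assign(
                genes=self.folds["genes"].map(list)
            ).to_dict(orient="records"),
        }


def _derive_subtype(
    matrix: ExpressionMatrix, subtype_labels: pd.Series, train: list[str], held: str
) -> str:
    """Nearest-centroid (correlation) subtype for a held-out sample."""
    cols = {s: i for i, s in enumerate(matrix.sample_ids)}
    x = matrix.values[:, cols[held]]
    best, best_r = None, -np.inf
    for subtype in ("A", "B"):
        members = [cols[s] for s in train if subtype_labels[s] == subtype]
        centroid = matrix.values[:, members].mean(axis=1)
        r = np.corrcoef(x, centroid)[0, 1]
        if r > best_r:
            best, best_r = subtype, r
    return best


def loocv_run(
    matrix: ExpressionMatrix,
    subtype_labels: pd.Series,
    outcome_labels: pd.Series,
    k: int = 6,
    adjust: bool = True,
    strict_subtype: bool = False,
    select_outside_cv: bool = False,
    positive_class: str = "yes",
) -> CVReport:
    """Nested leave-one-out cross-validation of the recurrence predictor.

    Every data-dependent step (subtype adjustment, gene selection, LDA
    training) is re-run inside each fold.  ``select_outside_cv=True`` is a
    deliberately leaky diagnostic variant that selects genes once on the full
    data set; it exists only to demonstrate that the nesting matters and must
    not be used for reported accuracies.
    """
    samples = list(matrix.sample_ids)
    outcome = outcome_labels.reindex(samples)
    if outcome.isna().any():
        raise ValidationError("outcome label required for every sample")
    counts = outcome.value_counts()
    if len(counts) != 2 or counts.min() < 2:
        raise ValidationError("need >= 2 samples in each outcome class")
    if not 1 <= k <= matrix.n_genes:
        raise ValidationError(f"k={k} out of range [1, {matrix.n_genes}]")

    preselected: list[str] | None = None
    if select_outside_cv:
        full = matrix
        if adjust:
            full, _ = subtype_adjust(matrix, subtype_labels, samples)
        preselected = wilcoxon_select(full, outcome, k)

    records = []
    for held in samples:
        train = [s for s in samples if s != held]
        train_outcome = outcome.loc[train]
        if train_outcome.nunique() < 2:
            raise ValidationError(f"fold {held}: single outcome class in training")
        working = matrix
        fold_subtypes = subtype_labels.copy()
        if adjust:
            if strict_subtype:
                fold_subtypes.loc[held] = _derive_subtype(
                    matrix, subtype_labels, train, held
                )
            try:
                working, _delta = subtype_adjust(matrix, fold_subtypes, train)
            except ValidationError as err:
                raise ValidationError(f"fold {held}: {err}") from None
        genes = (
            preselected
            if preselected is not None
            else wilcoxon_select(working.subset_samples(train), train_outcome, k)
        )
        sub = working.subset_genes(genes)
        cols = {s: i for i, s in enumerate(sub.sample_ids)}
        x_train = sub.values[:, [cols[s] for s in train]].T
        model = lda_train(
            x_train, train_outcome.to_numpy(), genes, positive_class=positive_class
        )
        label, score = lda_predict(model, sub.values[:, cols[held]])
        records.append(
            {
                "sample_id": held,
                "subtype": subtype_labels.get(held),
                "actual": outcome.loc[held],
                "predicted": label,
                "score": score,
                "genes": tuple(genes),
            }
        )
    folds = pd.DataFrame(records)
    accuracy = float((folds["predicted"] == folds["actual"]).mean())
    classes = sorted(outcome.unique())
    confusion = pd.crosstab(folds["predicted"], folds["actual"]).reindex(
        index=classes, columns=classes, fill_value=0
    )
    fisher_p = fisher_exact_2x2(confusion.to_numpy())
    return CVReport(folds, accuracy, confusion, fisher_p)


def size_scan(
    matrix: ExpressionMatrix,
    subtype_labels: pd.Series,
    outcome_labels: pd.Series,
    k_range=range(2, 101),
    adjust: bool = True,
    strict_subtype: bool = False,
) -> tuple[pd.DataFrame, int]:
    """LOOCV accuracy per gene-set size; argmax ties go to the smallest k."""
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValidationError("k_range is empty")
    if ks[0] < 1 or ks[-1] > matrix.n_genes:
        raise ValidationError(
            f"k_range must lie in [1, {matrix.n_genes}], got [{ks[0]}, {ks[-1]}]"
        )
    rows = []
    for k in ks:
        report = loocv_run(
            matrix, subtype_labels, outcome_labels, k=k,
            adjust=adjust, strict_subtype=strict_subtype,
        )
        rows.append({"k": k, "accuracy": report.accuracy})
    frame = pd.DataFrame(rows)
    best_k = int(frame.loc[frame["accuracy"].idxmax(), "k"])  # idxmax -> first max
    return frame, best_k
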