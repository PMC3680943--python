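"""Unsupervised class discovery: correlation-distance Ward clustering,
tree cutting, bootstrap clade support, and PCA sample summaries.

The Ward implementation applies the Lance-Williams minimum-variance update
directly to the supplied dissimilarities (the classical behaviour, default);
``squared=True`` squares the input first and reports square-root heights.
Bootstrap support is the ordinary bootstrap probability: the fraction of
gene-resampled trees in which an internal node's exact leaf set reappears.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import ValidationError
from .expression import ExpressionMatrix

__all__ = [
    "Dendrogram",
    "bootstrap_support",
    "correlation_distance",
    "cut_k",
    "pca_first_components",
    "ward_linkage",
]


def correlation_distance(matrix: ExpressionMatrix) -> np.ndarray:
    """Between-sample distance 1 - Pearson r, computed across genes."""
    if matrix.n_genes < 2:
        raise ValidationError("correlation distance needs >= 2 genes")
    sds = matrix.values.std(axis=0)
    if np.any(sds == 0):
        bad = [s for s, sd in zip(matrix.sample_ids, sds) if sd == 0]
        raise ValidationError(f"constant sample column(s), correlation undefined: {bad}")
    corr = np.corrcoef(matrix.values, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


def _check_distance(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValidationError("distance matrix diagonal must be zero")
    if np.any(d < 0):
        raise ValidationError("distances must be non-negative")
    return d


@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration history over ``leaf_ids``.

    Node ids: leaves are ``0..n-1``; the merge created at step ``t`` is node
    ``n + t``.  ``merges`` has one row per step: (child_a, child_b, height).
    ``support`` (optional) holds one bootstrap proportion per merge.
    """

    leaf_ids: tuple[str, ...]
    merges: np.ndarray  # (n-1, 3) float; children are integral node ids
    support: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "leaf_ids", tuple(self.leaf_ids))
        merges = np.asarray(self.merges, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "merges", merges)
        n = len(self.leaf_ids)
        if merges.shape[0] != max(n - 1, 0):
            raise ValidationError(f"{n} leaves require {n - 1} merges, got {merges.shape[0]}")
        if merges.size and np.any(merges[:, 2] < -1e-12):
            raise ValidationError("merge heights must be non-negative")
        if self.support is not None:
            support = np.asarray(self.support, dtype=float)
            if support.shape != (merges.shape[0],):
                raise ValidationError("support must have one value per merge")
            object.__setattr__(self, "support", support)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def clades(self) -> list[frozenset[int]]:
        """Leaf-index set of each internal node, in merge order."""
        n = self.n_leaves
        sets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
        out = []
        for t, (a, b, _h) in enumerate(self.merges):
            clade = sets[int(a)] | sets[int(b)]
            sets[n + t] = clade
            out.append(clade)
        return out

    def to_newick(self, digits: int = 3) -> str:
        """Newick string; internal nodes labeled with support when present."""
        n = self.n_leaves
        if n == 1:
            return f"{self.leaf_ids[0]};"

        def render(node: int) -> str:
            if node < n:
                return self.leaf_ids[node]
            t = node - n
            a, b, _h = self.merges[t]
            label = ""
            if self.support is not None:
                label = f"{self.support[t]:.{digits}f}"
            return f"({render(int(a))},{render(int(b))}){label}"

        return render(2 * n - 2) + ";"


def ward_linkage(
    dist: np.ndarray,
    leaf_ids: Sequence[str] | None = None,
    squared: bool = False,
) -> Dendrogram:
    """Agglomerate with Ward's minimum-variance Lance-Williams update.

    With ``squared=False`` (default) the update is applied to the supplied
    dissimilarities as given; with ``squared=True`` to their squares, and the
    reported heights are square roots.
    """
    d = _check_distance(dist).copy()
    n = d.shape[0]
    if n < 2:
        raise ValidationError("need >= 2 observations to cluster")
    if leaf_ids is None:
        leaf_ids = [str(i) for i in range(n)]
    if len(leaf_ids) != n:
        raise ValidationError("leaf_ids length must match distance matrix")
    if squared:
        d = d ** 2

    size = {i: 1 for i in range(n)}
    node = {i: i for i in range(n)}  # row index -> current node id
    active = list(range(n))
    work = d
    merges = np.zeros((n - 1, 3))
    next_id = n
    for step in range(n - 1):
        # find the closest active pair; ties -> smallest (i, j) row indices
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                dij = work[i, j]
                if best is None or dij < best[0]:
                    best = (dij, i, j)
        dij, i, j = best
        ni, nj = size[i], size[j]
        for k in active:
            if k in (i, j):
                continue
            nk = size[k]
            new = ((ni + nk) * work[i, k] + (nj + nk) * work[j, k] - nk * dij) / (
                ni + nj + nk
            )
            work[i, k] = work[k, i] = new
        height = np.sqrt(dij) if squared else dij
        merges[step] = (node[i], node[j], height)
        node[i] = next_id
        size[i] = ni + nj
        next_id += 1
        active.remove(j)
    return Dendrogram(tuple(leaf_ids), merges)


def cut_k(tree: Dendrogram, k: int) -> dict[str, int]:
    """Cluster labels from removing the k-1 highest merges.

    Merges are removed top-down: a merge is only removable once its parent is
    (the root has none), so exactly ``k`` components remain even if heights
    are non-monotone.  Labels are numbered by order of first leaf appearance.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} out of range [1, {n}]")
    m = tree.merges.shape[0]
    parent = {}
    for t, (a, b, _h) in enumerate(tree.merges):
        parent[int(a)] = n + t
        parent[int(b)] = n + t
    removed: set[int] = set()
    for _ in range(k - 1):
        candidates = [
            t
            for t in range(m)
            if (n + t) not in removed
            and ((n + t) not in parent or parent[n + t] in removed)
        ]
        # highest merge first; ties broken by later merge index
        t_star = max(candidates, key=lambda t: (tree.merges[t, 2], t))
        removed.add(n + t_star)

    comp = list(range(2 * n - 1))

    def find(x: int) -> int:
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    for t in range(m):
        if (n + t) in removed:
            continue
        a, b, _h = tree.merges[t]
        for child in (int(a), int(b)):
            ra, rb = find(child), find(n + t)
            comp[ra] = rb
    label_of_root: dict[int, int] = {}
    labels: dict[str, int] = {}
    for leaf in range(n):
        root = find(leaf)
        if root not in label_of_root:
            label_of_root[root] = len(label_of_root)
        labels[tree.leaf_ids[leaf]] = label_of_root[root]
    return labels


def bootstrap_support(
    matrix: ExpressionMatrix,
    n_boot: int,
    seed: int,
    squared: bool = False,
) -> Dendrogram:
    """Full-data tree annotated with ordinary bootstrap clade probabilities.

    Genes (rows) are resampled with replacement at full size; each internal
    node's support is the fraction of resampled trees containing its exact
    leaf set as a clade.  Iteration ``b`` uses the independent substream
    ``default_rng([seed, b])``.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    if seed < 0:
        raise ValidationError("seed must be a non-negative integer")
    full = ward_linkage(correlation_distance(matrix), matrix.sample_ids, squared=squared)
    targets = full.clades()
    counts = np.zeros(len(targets))
    n_genes = matrix.n_genes
    for b in range(n_boot):
        rng = np.random.default_rng([seed, b])
        idx = rng.integers(0, n_genes, size=n_genes)
        resampled = ExpressionMatrix(
            matrix.values[idx],
            tuple(f"g{i}" for i in range(n_genes)),
            matrix.sample_ids,
        )
        tree_b = ward_linkage(
            correlation_distance(resampled), matrix.sample_ids, squared=squared
        )
        clades_b = set(tree_b.clades())
        for t, clade in enumerate(targets):
            if clade in clades_b:
                counts[t] += 1
    return Dendrogram(full.leaf_ids, full.merges, counts / n_boot)


def pca_first_components(
    matrix: ExpressionMatrix, n_components: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample scores and variance fractions of the top principal components.

    Samples are the observations and genes the variables; each gene is mean
    centered before the decomposition.  Returns ``(scores, fractions)`` with
    ``scores`` of shape (n_samples, n_components).  Component signs are fixed
    so the largest-magnitude loading of each component is positive.
    """
    if matrix.n_samples < 2:
        raise ValidationError("PCA needs >= 2 samples")
    max_rank = min(matrix.n_samples, matrix.n_genes)
    if not 1 <= n_components <= max_rank:
        raise ValidationError(f"n_components={n_components} out of range [1, {max_rank}]")
    x = matrix.values.T  # samples x genes
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # deterministic sign: largest |loading| positive per component
    signs = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    signs[signs == 0] = 1.0
    u = u * signs
    scores = (u * s)[:, :n_components]
    var = s ** 2 / max(matrix.n_samples - 1, 1)
    total = xc.var(axis=0, ddof=1).sum()
    fractions = var[:n_components] / total if total > 0 else np.zeros(n_components)
    return scores, fractions
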