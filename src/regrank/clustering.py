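"""Expression clustering: Pearson-distance complete linkage and SOTA.

Hierarchical clustering uses the distance d = 1 - r (Pearson correlation r
across samples) with complete linkage, the classic configuration for
expression heatmaps. The number of clusters can instead be *discovered* by
the Self-Organizing Tree Algorithm (SOTA): a binary tree of cells grows by
repeatedly splitting the most variable cell until every cell's internal
variability (mean Pearson distance of its members to the cell vector) falls
below a threshold; the leaves are the clusters.

Clustering input is conventionally log2(FPKM + 1); see ``log_transform``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


def log_transform(fpkm_matrix: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    return np.log2(np.asarray(fpkm_matrix, dtype=float) + pseudocount)


def pearson_distance_matrix(expr_matrix: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Symmetric distance matrix d = 1 - Pearson r between rows.

    Returns (D, zero_variance_flags). A zero-variance row has no defined
    correlation; its distance to every other row is set to 1 (uncorrelated)
    and it is flagged rather than raising.
    """
    X = np.asarray(expr_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples per gene")
    flags = X.std(axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    d = 1.0 - r
    d[np.isnan(d)] = 1.0
    d[flags, :] = 1.0
    d[:, flags] = 1.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return d, flags


def _relabel_first_appearance(labels: np.ndarray) -> np.ndarray:
    mapping = {}
    out = np.empty_like(labels)
    for i, v in enumerate(labels):
        if v not in mapping:
            mapping[v] = len(mapping) + 1
        out[i] = mapping[v]
    return out


def hclust_complete(distance_matrix: np.ndarray, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Complete-linkage agglomeration cut at exactly k clusters.

    Returns (scipy linkage matrix, labels 1..k renumbered in order of first
    appearance). Ties in merge distance are resolved by the linkage backend;
    on continuous distances the merge sequence is unique.
    """
    D = np.asarray(distance_matrix, dtype=float)
    n = D.shape[0]
    if k > n or k < 1:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    Z = hierarchy.linkage(squareform(D, checks=False), method="complete")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return Z, _relabel_first_appearance(labels)


# ---------------------------------------------------------------------------
# SOTA


def _row_distance(x: np.ndarray, v: np.ndarray) -> float:
    """Pearson distance between a data row and a cell vector (1 if degenerate)."""
    sx, sv = x.std(), v.std()
    if sx == 0 or sv == 0:
        return 1.0
    r = float(np.dot(x - x.mean(), v - v.mean()) / (len(x) * sx * sv))
    return 1.0 - r


@dataclass
class _Cell:
    vector: np.ndarray
    parent: Optional["_Cell"] = None
    children: List["_Cell"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def sibling(self) -> Optional["_Cell"]:
        if self.parent is None:
            return None
        for c in self.parent.children:
            if c is not self:
                return c
        return None


def sota_cluster(
    expr_matrix: np.ndarray,
    variability_threshold: float = 0.1,
    max_epochs: int = 500,
    seed: int = 0,
    alpha_winner: float = 0.1,
    alpha_mother: float = 0.05,
    alpha_sister: float = 0.01,
    conv_tol: float = 1e-3,
    max_adapt_epochs: int = 30,
    max_clusters: Optional[int] = None,
) -> dict:
    """Self-Organizing Tree Algorithm clustering under Pearson distance.

    Starts from a single cell at the data mean. Each growth cycle splits the
    leaf with the highest variability into two daughters and then trains only
    those daughters on only the mother's member rows (the winning daughter
    moves toward the presented row at ``alpha_winner``, the mother at
    ``alpha_mother`` and the losing sister at ``alpha_sister``). Restricting
    competition to the split cell's members is what keeps already-settled
    clusters intact while a mixed cell is being resolved. Growth stops when
    every leaf's variability is at or below ``variability_threshold`` (so an
    infinite threshold always yields one cluster), or when the epoch or
    cluster budget runs out. Deterministic for a fixed seed: rows are
    presented in order and the only randomness is the tiny symmetry-breaking
    jitter at each split.

    Returns {"labels": 1..k per row, "k", "variability": per-leaf, "epochs"}.
    """
    X = np.asarray(expr_matrix, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("expression matrix must be finite")
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty matrix")
    max_clusters = n if max_clusters is None else min(max_clusters, n)
    rng = np.random.default_rng(seed)

    root = _Cell(X.mean(axis=0).copy())
    leaves: List[_Cell] = [root]
    members: dict = {id(root): list(range(n))}
    epochs = 0

    def leaf_variability(leaf: "_Cell") -> float:
        rows = members[id(leaf)]
        if not rows:
            return 0.0
        return float(np.mean([_row_distance(X[i], leaf.vector) for i in rows]))

    while True:
        variability = np.array([leaf_variability(c) for c in leaves])
        if (
            variability.max(initial=0.0) <= variability_threshold
            or len(leaves) >= max_clusters
            or epochs >= max_epochs
        ):
            break
        li = int(np.argmax(variability))
        mother = leaves[li]
        rows = members[id(mother)]
        # one daughter inherits the mother's vector, the other starts at the
        # mother's most distant member: an informed split that peels one
        # coherent subgroup off instead of bisecting along presentation order
        far = max(rows, key=lambda i: (_row_distance(X[i], mother.vector), i))
        mother.children.append(_Cell(mother.vector.copy(), parent=mother))
        mother.children.append(_Cell(X[far].astype(float).copy(), parent=mother))
        d1, d2 = mother.children

        # adaptation: daughters compete over the mother's rows only; capped
        # per cycle because online updates keep the error jittering at the
        # learning-rate scale and must not starve later growth cycles
        prev_err = None
        cycle_epochs = 0
        while epochs < max_epochs and cycle_epochs < max_adapt_epochs:
            total = 0.0
            order = rng.permutation(len(rows))
            for i in (rows[j] for j in order):
                x = X[i]
                dd1 = _row_distance(x, d1.vector)
                dd2 = _row_distance(x, d2.vector)
                w, s = (d1, d2) if dd1 <= dd2 else (d2, d1)
                total += min(dd1, dd2)
                w.vector += alpha_winner * (x - w.vector)
                mother.vector += alpha_mother * (x - mother.vector)
                s.vector += alpha_sister * (x - s.vector)
            epochs += 1
            cycle_epochs += 1
            err = total / max(len(rows), 1)
            if prev_err is not None and abs(prev_err - err) <= conv_tol * max(err, 1e-12):
                break
            prev_err = err

        members[id(d1)] = [
            i for i in rows
            if _row_distance(X[i], d1.vector) <= _row_distance(X[i], d2.vector)
        ]
        members[id(d2)] = [i for i in rows if i not in set(members[id(d1)])]
        del members[id(mother)]
        leaves = [c for c in leaves if c is not mother] + [d1, d2]

    assignment = np.zeros(n, dtype=int)
    for li, leaf in enumerate(leaves):
        for i in members[id(leaf)]:
            assignment[i] = li
    labels = _relabel_first_appearance(assignment + 1)
    return {
        "labels": labels,
        "k": len(leaves),
        "variability": np.array([leaf_variability(c) for c in leaves]),
        "epochs": epochs,
    }
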