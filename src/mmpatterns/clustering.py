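"""Pairwise Yule's Q association and Ward agglomerative clustering.

The pattern-discovery core: for every pair of conditions a 2x2 contingency
table is summarized by Yule's Q = (ad - bc)/(ad + bc); 1 - Q is used as the
dissimilarity, and agglomerative clustering with Ward's method (via the
Lance-Williams distance-update recurrence) builds the dendrogram whose k-cut
gives the multimorbidity patterns.

Because 1 - Q is not a Euclidean distance, the Ward "dialect" matters: by
default the recurrence is applied to the dissimilarities as supplied
(the behaviour of R's ``hclust(method="ward.D")``); pass
``square_dissimilarity=True`` to apply it to squared dissimilarities and
report square-rooted heights (``ward.D2`` / SciPy behaviour).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import ValidationError, logger
from .diagnosis import DiseaseMatrix
from .registry import DEFAULT_REGISTRY, DiseaseRegistry


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Joint counts for two binary variables.

    a: both present; b: first only; c: second only; d: both absent.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def contingency(matrix: DiseaseMatrix, i: str, j: str) -> ContingencyTable2x2:
    """Exact 2x2 joint counts of two disease columns."""
    if i == j:
        raise ValidationError("contingency requires two distinct diseases")
    x = matrix.column(i).astype(bool)
    y = matrix.column(j).astype(bool)
    return ContingencyTable2x2(
        a=int((x & y).sum()),
        b=int((x & ~y).sum()),
        c=int((~x & y).sum()),
        d=int((~x & ~y).sum()),
    )


def yule_q(table: ContingencyTable2x2, *,
           continuity_correction: float = 0.5) -> float:
    """Yule's Q for a 2x2 table, with a Haldane-Anscombe fallback.

    Q = (ad - bc)/(ad + bc), in [-1, 1]; 0 at independence.  When the table
    is degenerate (ad + bc = 0, i.e. a zero cell in both products, or a zero
    marginal), ``continuity_correction`` is added to all four cells for this
    pair only, keeping Q defined and strictly inside (-1, 1); the event is
    logged.
    """
    if table.n == 0:
        raise ValidationError("Yule's Q undefined for an all-zero table")
    a, b, c, d = (float(table.a), float(table.b),
                  float(table.c), float(table.d))
    if a * d + b * c == 0:
        logger.info("yule_q: continuity correction applied to "
                    "degenerate table a=%d b=%d c=%d d=%d",
                    table.a, table.b, table.c, table.d)
        a, b, c, d = (a + continuity_correction, b + continuity_correction,
                      c + continuity_correction, d + continuity_correction)
    return (a * d - b * c) / (a * d + b * c)


@dataclass
class AssociationMatrix:
    """Symmetric matrix of pairwise Yule's Q in registry order (diagonal 1)."""

    q: np.ndarray
    registry: DiseaseRegistry = DEFAULT_REGISTRY
    codes: tuple[str, ...] | None = None  # subset in use; defaults to registry

    def __post_init__(self) -> None:
        if self.codes is None:
            self.codes = self.registry.codes
        self.q = np.asarray(self.q, dtype=float)
        m = len(self.codes)
        if self.q.shape != (m, m):
            raise ValidationError(f"association matrix must be {m}x{m}")
        if not np.allclose(self.q, self.q.T):
            raise ValidationError("association matrix must be symmetric")
        if np.nanmax(np.abs(self.q)) > 1 + 1e-12:
            raise ValidationError("Yule's Q entries must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.q, index=list(self.codes),
                            columns=list(self.codes))


@dataclass
class DissimilarityMatrix:
    """1 - Q off-diagonal, 0 diagonal; entries in [0, 2]."""

    d: np.ndarray
    codes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        m = len(self.codes)
        if self.d.shape != (m, m):
            raise ValidationError(f"dissimilarity matrix must be {m}x{m}")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("dissimilarity matrix must be symmetric")
        if (self.d < -1e-12).any() or (self.d > 2 + 1e-12).any():
            raise ValidationError("dissimilarities must lie in [0, 2]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.codes),
                            columns=list(self.codes))


def association_matrix(matrix: DiseaseMatrix) -> AssociationMatrix:
    """All pairwise Yule's Q coefficients for a disease matrix.

    Raises a named-disease error for any constant column: Q is undefined
    (and uninformative even with correction) for a disease nobody — or
    everybody — has; exclude the disease or regenerate the cohort.
    """
    values = matrix.values
    sums = values.sum(axis=0)
    constant = [code for code, s in zip(matrix.registry.codes, sums)
                if s == 0 or s == matrix.n]
    if constant:
        raise ValidationError(
            f"constant disease columns {constant}: Yule's Q is undefined; "
            "exclude these diseases or regenerate the cohort"
        )
    m = len(matrix.registry)
    # vectorized joint counts: A[i,j] = #(both), from which b, c, d follow
    v = values.astype(np.int64)
    both = v.T @ v
    ones = sums.astype(np.int64)
    q = np.ones((m, m))
    for i, j in itertools.combinations(range(m), 2):
        a = int(both[i, j])
        b = int(ones[i] - a)
        c = int(ones[j] - a)
        d = int(matrix.n - a - b - c)
        q[i, j] = q[j, i] = yule_q(ContingencyTable2x2(a, b, c, d))
    return AssociationMatrix(q=q, registry=matrix.registry)


def to_dissimilarity(assoc: AssociationMatrix) -> DissimilarityMatrix:
    """1 - Q element-wise off the diagonal; exact zeros on the diagonal."""
    d = 1.0 - assoc.q
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    d = (d + d.T) / 2.0
    return DissimilarityMatrix(d=d, codes=tuple(assoc.codes))


@dataclass
class Merge:
    """One agglomeration step; node ids follow the SciPy convention

    (leaves 0..n-1, the i-th merge creates node n+i)."""

    left: int
    right: int
    height: float
    size: int


@dataclass
class Dendrogram:
    """Full merge history of an agglomerative clustering of n leaves."""

    merges: list[Merge]
    leaves: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValidationError(f"expected {n - 1} merges, "
                                  f"got {len(self.merges)}")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def heights(self) -> np.ndarray:
        return np.array([m.height for m in self.merges])

    def to_linkage(self) -> np.ndarray:
        """SciPy-compatible (n-1) x 4 linkage matrix."""
        return np.array([[m.left, m.right, m.height, m.size]
                         for m in self.merges], dtype=float)

    def to_merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.left, m.right, m.height, m.size) for m in self.merges],
            columns=["left", "right", "height", "size"],
        )


@dataclass
class ClusterAssignment:
    """Flat clustering: disease code -> cluster id (1..k)."""

    mapping: dict[str, int]
    k: int
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = set(self.mapping.values())
        if len(ids) != self.k:
            raise ValidationError(
                f"expected {self.k} distinct cluster ids, got {len(ids)}"
            )

    def members(self, cluster_id: int) -> list[str]:
        return [c for c, g in self.mapping.items() if g == cluster_id]

    def labels(self, codes: tuple[str, ...] | None = None) -> np.ndarray:
        codes = codes or tuple(self.mapping)
        return np.array([self.mapping[c] for c in codes])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c, g, self.names.get(g, f"cluster_{g}"))
             for c, g in self.mapping.items()],
            columns=["code", "cluster", "name"],
        )


def agglomerate_ward(dissim: DissimilarityMatrix, *,
                     square_dissimilarity: bool = False) -> Dendrogram:
    """Agglomerative clustering with Ward's method.

    Implements the Lance-Williams recurrence with Ward coefficients

        d(k, i+j) = [(n_i + n_k) d(k,i) + (n_j + n_k) d(k,j)
                     - n_k d(i,j)] / (n_i + n_j + n_k)

    applied to the supplied dissimilarities as-is (``ward.D`` dialect) or,
    with ``square_dissimilarity=True``, to their squares with square-rooted
    heights (``ward.D2`` dialect, what SciPy's ward computes).  Among equal
    minimal distances the pair with the lexicographically smallest
    (cluster-index, cluster-index) ids is merged, so the result is
    deterministic.
    """
    n = len(dissim.codes)
    if n < 2:
        raise ValidationError("need at least two leaves to cluster")
    work = dissim.d.astype(float).copy()
    if square_dissimilarity:
        work = work ** 2

    # distances keyed by scipy-style node id
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = work[i, j]
    size = {i: 1 for i in range(n)}
    active = sorted(size)
    merges: list[Merge] = []

    for step in range(n - 1):
        best = min(
            ((dist[(a, b)], a, b)
             for a, b in itertools.combinations(active, 2)),
            key=lambda t: (t[0], t[1], t[2]),
        )
        h, i, j = best
        new = n + step
        size[new] = size[i] + size[j]
        for k in active:
            if k in (i, j):
                continue
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            ni, nj, nk = size[i], size[j], size[k]
            dist[(k, new)] = (
                (ni + nk) * dik + (nj + nk) * djk - nk * h
            ) / (ni + nj + nk)
        active = [k for k in active if k not in (i, j)] + [new]
        merges.append(Merge(i, j, float(np.sqrt(h)) if square_dissimilarity
                            else float(h), size[new]))
    return Dendrogram(merges=merges, leaves=tuple(dissim.codes))


def cut(dend: Dendrogram, k: int) -> ClusterAssignment:
    """Cut the dendrogram into k flat clusters (undo the last k-1 merges).

    Cluster ids are 1..k in order of each cluster's first leaf.
    """
    n = dend.n_leaves
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step, m in enumerate(dend.merges[: n - k]):
        members[n + step] = members.pop(m.left) + members.pop(m.right)
    clusters = sorted(members.values(), key=min)
    mapping: dict[str, int] = {}
    for cid, leaf_idx in enumerate(clusters, start=1):
        for i in leaf_idx:
            mapping[dend.leaves[i]] = cid
    return ClusterAssignment(mapping=mapping, k=k)


#: Seed diseases used to attach human pattern names to clusters: a cluster
#: takes the name of the seed list it overlaps most (ties stay unnamed).
DEFAULT_PATTERN_SEEDS: dict[str, tuple[str, ...]] = {
    "cardiometabolic": ("hypertension", "diabetes", "acute_mi",
                        "angina", "stroke_tia"),
    "respiratory": ("emphysema", "chronic_bronchitis", "copd", "asthma",
                    "pulmonary_tb"),
    "digestive-bone-kidney": ("chronic_hepatitis_cirrhosis", "peptic_ulcer",
                              "gallstones_cholecystitis",
                              "chronic_kidney_disease", "osteoporosis",
                              "fracture"),
    "mental-cancer": ("depression", "anxiety", "neurasthenia",
                      "other_mental", "cancer"),
}


def name_clusters(assignment: ClusterAssignment,
                  seeds: dict[str, tuple[str, ...]] | None = None,
                  ) -> ClusterAssignment:
    """Attach pattern names by overlap with configurable seed-disease lists."""
    seeds = seeds or DEFAULT_PATTERN_SEEDS
    names: dict[int, str] = {}
    for cid in sorted(set(assignment.mapping.values())):
        mem = set(assignment.members(cid))
        scores = {nm: len(mem & set(lst)) for nm, lst in seeds.items()}
        top = max(scores.values())
        winners = [nm for nm, s in scores.items() if s == top]
        if top > 0 and len(winners) == 1:
            names[cid] = winners[0]
    return ClusterAssignment(mapping=dict(assignment.mapping),
                             k=assignment.k, names=names)


def export_newick(dend: Dendrogram) -> str:
    """Serialize the dendrogram as a Newick string with branch lengths.

    Each branch length is the parent merge height minus the child's height
    (leaves sit at height 0), so leaf-to-root path length equals the root
    merge height.
    """
    n = dend.n_leaves
    height = {i: 0.0 for i in range(n)}
    node: dict[int, str] = {i: dend.leaves[i] for i in range(n)}
    for step, m in enumerate(dend.merges):
        nid = n + step
        height[nid] = m.height
        parts = []
        for child in (m.left, m.right):
            bl = max(m.height - height[child], 0.0)
            parts.append(f"{node.pop(child)}:{bl:.10g}")
        node[nid] = f"({parts[0]},{parts[1]})"
    (root,) = node.values()
    return root + ";"


def adjusted_rand_index(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Adjusted Rand index between two flat partitions of the same items.

    Chance-corrected pair-counting agreement: 1 for identical partitions,
    ~0 for independent ones.  Computed from the contingency table via the
    standard pair-count formula.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValidationError("partitions must label the same items")
    n = a.size
    if n < 2:
        return 1.0
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ct = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(ct, (ai, bi), 1)

    def comb2(x: np.ndarray) -> float:
        return float((x * (x - 1) // 2).sum())

    sum_ij = comb2(ct)
    sum_a = comb2(ct.sum(axis=1))
    sum_b = comb2(ct.sum(axis=0))
    total = n * (n - 1) / 2
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:  # both partitions trivial
        return 1.0
    return (sum_ij - expected) / (max_index - expected)
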