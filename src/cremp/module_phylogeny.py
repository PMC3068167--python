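"""Module segregation analysis: p-distances, UPGMA, cluster purity, identity.

The a/b-segregation observation is quantified here without a multiple
aligner: same-length module rows (b-type rows trimmed to a-module length)
give a p-distance matrix, UPGMA builds an ultrametric tree, and the two
root-level clusters are scored for type purity — 1.0 meaning the two
module types separate completely.

UPGMA and Needleman–Wunsch are implemented in-package because their
deterministic tie-break / traceback orders are part of the contract;
tests cross-check them against scipy average linkage and Bio.Align
alignment scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .conservation_profile import ModuleStack


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape must match the label count")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must be symmetric with a zero diagonal")
        self.values = v


@dataclass
class TreeNode:
    """Node of a rooted UPGMA tree; ``height`` is the merge height."""

    height: float
    name: str | None = None
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [leaf for child in self.children for leaf in child.leaves()]

    def to_newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf:
            return self.name
        parts = []
        for child in self.children:
            branch = self.height - child.height
            parts.append(f"{child._newick_inner()}:{branch:.6g}")
        return "(" + ",".join(parts) + ")"


def pdistance_matrix(stack: ModuleStack, labels: Sequence[str] | None = None) -> DistanceMatrix:
    """Pairwise p-distance (mismatch fraction) over a stack's rows.

    X mismatches everything, including another X: unknowns never count as
    agreement.  Row labels default to ``<type><index>_<seq_id>_<start>``.
    """
    rows = stack.rows
    if labels is None:
        labels = []
        for i, row in enumerate(rows):
            t = stack.row_types[i] if stack.row_types else "m"
            sid, start = stack.source[i] if stack.source else ("row", i)
            labels.append(f"{t}{i:03d}_{sid}_{start}")
    labels = list(labels)
    n = len(rows)
    width = len(rows[0])
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mism = sum(
                1
                for x, y in zip(rows[i], rows[j])
                if x != y or x == "X"  # x == y == "X" still mismatches
            )
            values[i, j] = values[j, i] = mism / width
    return DistanceMatrix(labels=labels, values=values)


def upgma(matrix: DistanceMatrix) -> TreeNode:
    """Average-linkage (UPGMA) clustering of a distance matrix.

    Repeatedly merges the closest cluster pair at height d/2, updating
    distances as size-weighted averages.  Ties are broken toward the
    lexicographically smallest (representative-label) pair, making the
    tree deterministic.
    """
    n = len(matrix.labels)
    if n < 2:
        raise ValueError("UPGMA requires at least 2 leaves")
    clusters: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, name=matrix.labels[i]) for i in range(n)
    }
    sizes = {i: 1 for i in range(n)}
    reprs = {i: matrix.labels[i] for i in range(n)}  # min leaf label, for tie-breaks
    dist: dict[tuple[int, int], float] = {
        (i, j): float(matrix.values[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while len(clusters) > 1:
        best = None
        for (i, j), d in dist.items():
            pair = tuple(sorted((reprs[i], reprs[j])))
            key = (d, pair)
            if best is None or key < best[0]:
                best = (key, i, j)
        (_, _pair), i, j = best[0], best[1], best[2]
        d_ij = dist[(i, j) if (i, j) in dist else (j, i)]
        node = TreeNode(height=d_ij / 2.0, children=(clusters[i], clusters[j]))
        si, sj = sizes[i], sizes[j]
        new_dists = {}
        for k in clusters:
            if k in (i, j):
                continue
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            new_dists[k] = (si * dik + sj * djk) / (si + sj)
        for key in list(dist):
            if i in key or j in key:
                del dist[key]
        del clusters[i], clusters[j], sizes[i], sizes[j], reprs[i], reprs[j]
        clusters[next_id] = node
        sizes[next_id] = si + sj
        reprs[next_id] = min(node.leaves())
        for k, d in new_dists.items():
            dist[tuple(sorted((k, next_id)))] = d
        next_id += 1
    return next(iter(clusters.values()))


def segregation_purity(tree: TreeNode, type_tags: Mapping[str, str]) -> float:
    """Type purity of the two root-level clusters, in [0, 1].

    Each of the final merge's two subtrees is assigned its majority type;
    purity is the fraction of leaves matching their subtree's majority.
    1.0 reproduces complete a/b segregation.
    """
    if tree.is_leaf:
        raise ValueError("purity requires a tree with at least one merge")
    tags = [type_tags[leaf] for leaf in tree.leaves()]
    if len(set(tags)) < 2:
        warnings.warn("single-type input: segregation purity is trivially 1.0")
        return 1.0
    total = 0
    majority_sum = 0
    for child in tree.children:
        leaf_tags = [type_tags[leaf] for leaf in child.leaves()]
        total += len(leaf_tags)
        counts = {}
        for t in leaf_tags:
            counts[t] = counts.get(t, 0) + 1
        majority_sum += max(counts.values())
    return majority_sum / total


def nw_align(
    s1: str, s2: str, match: float = 1.0, mismatch: float = 0.0, gap: float = -1.0
) -> tuple[float, int, int]:
    """Needleman–Wunsch global alignment with linear gap scores.

    Returns ``(optimal score, identical aligned pairs, alignment columns)``
    with a deterministic traceback preferring diagonal, then up (gap in
    *s2*), then left.
    """
    if not s1 or not s2:
        raise ValueError("global alignment requires two non-empty sequences")
    n, m = len(s1), len(s2)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = gap * np.arange(n + 1)
    score[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1, j - 1] + (match if s1[i - 1] == s2[j - 1] else mismatch)
            up = score[i - 1, j] + gap
            left = score[i, j - 1] + gap
            score[i, j] = max(diag, up, left)
    i, j = n, m
    columns = 0
    identical = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and np.isclose(
            score[i, j],
            score[i - 1, j - 1] + (match if s1[i - 1] == s2[j - 1] else mismatch),
        ):
            identical += s1[i - 1] == s2[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and np.isclose(score[i, j], score[i - 1, j] + gap):
            i -= 1
        else:
            j -= 1
        columns += 1
    return float(score[n, m]), identical, columns


def nw_identity(
    s1: str, s2: str, match: float = 1.0, mismatch: float = 0.0, gap: float = -1.0
) -> float:
    """Global-alignment percent identity: identical pairs / columns × 100."""
    _, identical, columns = nw_align(s1, s2, match, mismatch, gap)
    return 100.0 * identical / columns


def segregate(stack: ModuleStack) -> tuple[DistanceMatrix, TreeNode, float]:
    """p-distance → UPGMA → purity, on a cross-type module stack."""
    matrix = pdistance_matrix(stack)
    tree = upgma(matrix)
    tags = {
        label: (stack.row_types[i] if stack.row_types else "m")
        for i, label in enumerate(matrix.labels)
    }
    return matrix, tree, segregation_purity(tree, tags)
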