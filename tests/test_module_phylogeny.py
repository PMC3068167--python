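"""p-distances, UPGMA trees, segregation purity, global-alignment identity.

UPGMA heights are cross-checked against scipy's average linkage and
against a brute-force ultrametric oracle on 4-leaf instances; alignment
scores are cross-checked against Bio.Align.PairwiseAligner.
"""

import itertools

import numpy as np
import pytest
from Bio import Align
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from cremp import (
    DistanceMatrix,
    nw_identity,
    pdistance_matrix,
    segregate,
    segregation_purity,
    upgma,
)
from cremp.conservation_profile import ModuleStack
from cremp.module_phylogeny import TreeNode

from conftest import CANONICAL_A, CANONICAL_B


def _stack(rows, types=None):
    return ModuleStack(
        context="t", rows=rows,
        source=[("s", i) for i in range(len(rows))],
        row_types=types or ["m"] * len(rows),
    )


# ------------------------------------------------------------ p-distance

def test_identical_rows_have_zero_distance():
    m = pdistance_matrix(_stack(["CAD", "CAD", "CAD"]))
    assert np.allclose(m.values, 0.0)


def test_single_mismatch_over_three_columns():
    m = pdistance_matrix(_stack(["CAD", "CED"]))
    assert m.values[0, 1] == pytest.approx(1 / 3)


def test_canonical_a_vs_trimmed_b_differ_at_three_positions():
    m = pdistance_matrix(_stack([CANONICAL_A, CANONICAL_B[:27]]))
    assert m.values[0, 1] == pytest.approx(3 / 27)


def test_unknown_residues_never_match_even_each_other():
    m = pdistance_matrix(_stack(["XA", "XA"]))
    assert m.values[0, 1] == pytest.approx(1 / 2)


def test_unequal_row_lengths_rejected():
    with pytest.raises(ValueError):
        pdistance_matrix(_stack(["CAD", "CADA"]))


# ----------------------------------------------------------------- UPGMA

def test_two_leaves_merge_at_half_distance():
    m = DistanceMatrix(labels=["A", "B"], values=np.array([[0, 0.4], [0.4, 0]]))
    tree = upgma(m)
    assert tree.height == pytest.approx(0.2)
    assert sorted(tree.leaves()) == ["A", "B"]


def test_three_leaf_hand_computed_heights():
    values = np.array(
        [[0.0, 0.2, 0.6],
         [0.2, 0.0, 0.6],
         [0.6, 0.6, 0.0]]
    )
    tree = upgma(DistanceMatrix(labels=["A", "B", "C"], values=values))
    assert tree.height == pytest.approx(0.3)
    inner = next(c for c in tree.children if not c.is_leaf)
    assert inner.height == pytest.approx(0.1)
    assert sorted(inner.leaves()) == ["A", "B"]


def test_tied_pairs_resolve_lexicographically_and_deterministically():
    # d(A,B) == d(C,D): the (A,B) merge must happen first, every run
    values = np.array(
        [[0.0, 0.2, 0.9, 0.9],
         [0.2, 0.0, 0.9, 0.9],
         [0.9, 0.9, 0.0, 0.2],
         [0.9, 0.9, 0.2, 0.0]]
    )
    newicks = set()
    for _ in range(5):
        tree = upgma(DistanceMatrix(labels=["A", "B", "C", "D"], values=values))
        newicks.add(tree.to_newick())
    assert len(newicks) == 1
    first_merge = min(
        (c for c in _iter_nodes(tree) if not c.is_leaf), key=lambda n: n.height
    )
    assert sorted(first_merge.leaves()) == ["A", "B"]


def _iter_nodes(node):
    yield node
    for c in node.children:
        yield from _iter_nodes(c)


def _cophenetic(tree):
    """Leaf-pair merge heights implied by the tree (×2 = cophenetic distance)."""
    out = {}
    for node in _iter_nodes(tree):
        if node.is_leaf:
            continue
        for left, right in itertools.combinations(node.children, 2):
            for a in left.leaves():
                for b in right.leaves():
                    out[frozenset((a, b))] = node.height * 2
    return out


def test_merge_heights_match_scipy_average_linkage():
    rng = np.random.default_rng(17)
    for _ in range(20):
        n = int(rng.integers(4, 9))
        d = rng.uniform(0.05, 1.0, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        labels = [f"L{i}" for i in range(n)]
        tree = upgma(DistanceMatrix(labels=labels, values=d))
        heights = sorted(
            node.height for node in _iter_nodes(tree) if not node.is_leaf
        )
        Z = linkage(squareform(d), method="average")
        assert np.allclose(heights, sorted(Z[:, 2] / 2), atol=1e-12)


def test_upgma_recovers_ultrametric_4_leaf_trees_exactly():
    # brute-force oracle: for an ultrametric input, the true tree is the
    # unique ultrametric fit, so cophenetic(upgma(M)) must equal M
    rng = np.random.default_rng(23)
    labels = ["A", "B", "C", "D"]
    for _ in range(50):
        h1 = rng.uniform(0.05, 0.3)   # first cherry
        h2 = rng.uniform(h1 + 0.05, 0.6)
        h3 = rng.uniform(h2 + 0.05, 1.0)  # root
        perm = rng.permutation(4)
        # topology ((A,B),(C,D)) with heights h1, h2, root h3 — permuted leaves
        base = {
            frozenset(("A", "B")): 2 * h1,
            frozenset(("C", "D")): 2 * h2,
        }
        values = np.zeros((4, 4))
        for i, j in itertools.combinations(range(4), 2):
            a, b = labels[perm[i]], labels[perm[j]]
            values[i, j] = values[j, i] = base.get(frozenset((a, b)), 2 * h3)
        perm_labels = [labels[k] for k in perm]
        tree = upgma(DistanceMatrix(labels=perm_labels, values=values))
        coph = _cophenetic(tree)
        for i, j in itertools.combinations(range(4), 2):
            key = frozenset((perm_labels[i], perm_labels[j]))
            assert coph[key] == pytest.approx(values[i, j], abs=1e-12)


def test_upgma_requires_two_leaves():
    with pytest.raises(ValueError):
        upgma(DistanceMatrix(labels=["A"], values=np.zeros((1, 1))))


# ----------------------------------------------------------------- purity

def _perfect_tree():
    a1, a2 = TreeNode(0, "a1"), TreeNode(0, "a2")
    b1, b2 = TreeNode(0, "b1"), TreeNode(0, "b2")
    return TreeNode(
        0.5,
        children=(TreeNode(0.1, children=(a1, a2)), TreeNode(0.1, children=(b1, b2))),
    )


def test_perfect_segregation_scores_one():
    tags = {"a1": "a", "a2": "a", "b1": "b", "b2": "b"}
    assert segregation_purity(_perfect_tree(), tags) == 1.0


def test_one_mislabeled_leaf_among_ten_scores_09():
    left = [TreeNode(0, f"l{i}") for i in range(5)]
    right = [TreeNode(0, f"r{i}") for i in range(5)]

    def chain(leaves):
        node = leaves[0]
        for k, leaf in enumerate(leaves[1:], start=1):
            node = TreeNode(0.01 * k, children=(node, leaf))
        return node

    tree = TreeNode(0.5, children=(chain(left), chain(right)))
    tags = {f"l{i}": "a" for i in range(5)}
    tags.update({f"r{i}": "b" for i in range(5)})
    tags["r4"] = "a"  # one a leaf stranded in the b subtree
    assert segregation_purity(tree, tags) == pytest.approx(0.9)


def test_fully_mixed_subtrees_score_half():
    left = [TreeNode(0, f"x{i}") for i in range(10)]
    right = [TreeNode(0, f"y{i}") for i in range(10)]

    def chain(leaves):
        node = leaves[0]
        for k, leaf in enumerate(leaves[1:], start=1):
            node = TreeNode(0.01 * k, children=(node, leaf))
        return node

    tree = TreeNode(0.5, children=(chain(left), chain(right)))
    tags = {f"x{i}": ("a" if i < 5 else "b") for i in range(10)}
    tags.update({f"y{i}": ("a" if i < 5 else "b") for i in range(10)})
    assert segregation_purity(tree, tags) == pytest.approx(0.5)


def test_single_type_input_warns_and_returns_one():
    tags = {"a1": "a", "a2": "a", "b1": "a", "b2": "a"}
    with pytest.warns(UserWarning, match="single-type"):
        assert segregation_purity(_perfect_tree(), tags) == 1.0


def test_noiseless_canonical_modules_segregate_perfectly():
    rows = [CANONICAL_A] * 4 + [CANONICAL_B[:27]] * 4
    stack = _stack(rows, types=["a"] * 4 + ["b"] * 4)
    _, tree, purity = segregate(stack)
    assert purity == 1.0


# ----------------------------------------------------- alignment identity

def test_identical_sequences_align_at_100_percent():
    repeat = CANONICAL_A + CANONICAL_B
    assert nw_identity(repeat, repeat) == pytest.approx(100.0)


def test_single_mismatch_over_three_columns_identity():
    assert nw_identity("ACD", "AED") == pytest.approx(66.67, abs=0.005)


def test_single_gap_column_halves_identity():
    assert nw_identity("AC", "A") == pytest.approx(50.0)


def test_identity_is_symmetric_and_positional_when_gap_free():
    rng = np.random.default_rng(31)
    aa = list("ACDEFG")
    for _ in range(25):
        n = int(rng.integers(3, 30))
        s1 = "".join(rng.choice(aa, size=n))
        s2 = "".join(rng.choice(aa, size=n))
        ident = nw_identity(s1, s2)
        assert ident == pytest.approx(nw_identity(s2, s1), abs=1e-9)
        positional = 100.0 * sum(a == b for a, b in zip(s1, s2)) / n
        # equality holds whenever the optimal alignment is gap-free
        matches = sum(a == b for a, b in zip(s1, s2))
        if matches >= n - 2:  # gap-free alignment clearly optimal
            assert ident == pytest.approx(positional, abs=1e-9)


def test_alignment_score_matches_biopython_aligner():
    from cremp.module_phylogeny import nw_align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    rng = np.random.default_rng(41)
    aa = list("ACDEFGHIK")
    for _ in range(15):
        s1 = "".join(rng.choice(aa, size=int(rng.integers(2, 25))))
        s2 = "".join(rng.choice(aa, size=int(rng.integers(2, 25))))
        score, identical, columns = nw_align(s1, s2)
        assert score == pytest.approx(aligner.score(s1, s2))
        assert 0 <= identical <= columns


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        nw_identity("", "ACD")
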