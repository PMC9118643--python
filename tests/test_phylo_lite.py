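import math

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import TreeNode

from sodfam.io_formats import ProteinRecord, SodfamError
from sodfam.phylo_lite import (
    alignment_distance_matrix,
    bootstrap_support,
    cut_clades,
    distance_matrix,
    family_bipartition_support,
    nj_tree,
    progressive_align,
    protein_distance,
)
from sodfam.synthetic_data import make_protein_family


def test_distance_is_zero_on_self_and_symmetric():
    a = ProteinRecord("a", "MKVLASGHWQ")
    b = ProteinRecord("b", "MKVLASGHWR")
    assert protein_distance(a, a) == 0.0
    assert protein_distance(a, b) == protein_distance(b, a)


def test_distance_closed_form_on_toy_pair():
    # 10 aligned columns, 2 mismatches: p = 0.2, d = -ln(0.8)
    a = "MKVLASGHWQ"
    b = "MKVLASGHYR"
    assert protein_distance(a, b) == pytest.approx(-math.log(0.8), abs=1e-6)


def _random_additive_tree(rng, n_leaves):
    """Random binary tree with positive branch lengths; returns (taxa,
    leaf-to-leaf distance matrix) computed by path summation."""
    nodes = [({f"t{i}"}, {f"t{i}": 0.0}) for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (set_j, d_j) = nodes.pop(j)
        (set_i, d_i) = nodes.pop(i)
        bl_i = float(rng.uniform(0.1, 1.0))
        bl_j = float(rng.uniform(0.1, 1.0))
        merged = set_i | set_j
        dist = {t: d + bl_i for t, d in d_i.items()}
        dist.update({t: d + bl_j for t, d in d_j.items()})
        nodes.append((merged, dist))
        # record cross distances on a shared matrix
        for ta in set_i:
            for tb in set_j:
                _CROSS[(ta, tb)] = d_i[ta] + bl_i + d_j[tb] + bl_j
                _CROSS[(tb, ta)] = _CROSS[(ta, tb)]
    taxa = sorted(nodes[0][0])
    mat = np.zeros((len(taxa), len(taxa)))
    for x, ta in enumerate(taxa):
        for y, tb in enumerate(taxa):
            if x != y:
                mat[x, y] = _CROSS[(ta, tb)]
    return taxa, mat


_CROSS: dict = {}


def test_three_taxa_closed_form():
    # d_ab = x+y, d_ac = x+z, d_bc = y+z -> x = (ab+ac-bc)/2 etc.
    d = DistanceMatrix(np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float), list("ABC"))
    tree = nj_tree(d)
    tt = tree.tip_tip_distances(list("ABC"))
    assert np.allclose(tt.data, d.data, atol=1e-9)


def test_nj_exact_on_four_taxon_additive_matrix():
    d = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
    )
    dm = DistanceMatrix(d, list("ABCD"))
    tree = nj_tree(dm)
    tt = tree.tip_tip_distances(list("ABCD"))
    assert np.allclose(tt.data, d, atol=1e-9)
    # cherry (A,B) exists
    ab = tree.lca(["A", "B"])
    assert {t.name for t in ab.tips()} == {"A", "B"}


def test_nj_exact_on_random_additive_matrices():
    """50 random 6-10 leaf trees: NJ reproduces all leaf-to-leaf distances
    exactly (additive consistency)."""
    rng = np.random.default_rng(37)
    for _ in range(50):
        _CROSS.clear()
        taxa, mat = _random_additive_tree(rng, int(rng.integers(6, 11)))
        tree = nj_tree(DistanceMatrix(mat, taxa))
        tt = tree.tip_tip_distances(taxa)
        assert np.allclose(tt.data, mat, atol=1e-6)


def test_nj_invariant_to_taxon_order():
    rng = np.random.default_rng(4)
    _CROSS.clear()
    taxa, mat = _random_additive_tree(rng, 7)
    tree1 = nj_tree(DistanceMatrix(mat, taxa))
    perm = list(rng.permutation(len(taxa)))
    tree2 = nj_tree(DistanceMatrix(mat[np.ix_(perm, perm)], [taxa[i] for i in perm]))
    assert np.allclose(
        tree1.tip_tip_distances(taxa).data, tree2.tip_tip_distances(taxa).data, atol=1e-6
    )


def test_nj_requires_three_taxa():
    with pytest.raises(SodfamError):
        nj_tree(DistanceMatrix(np.array([[0, 1], [1, 0]], float), ["a", "b"]))


def test_distance_matrix_from_records(family_fixture):
    records, _ = family_fixture
    dm = distance_matrix(records[:4])
    assert dm.shape == (4, 4)
    assert np.allclose(dm.data, dm.data.T)
    assert np.allclose(np.diag(dm.data), 0)


@pytest.fixture(scope="module")
def two_family_alignment():
    records, _ = make_protein_family(n_per_group=5, background_mut_rate=0.08, seed=31)
    fam = [r for r in records if r.id.startswith(("cuzn_active", "mnsod"))]
    return progressive_align(fam)


def test_family_split_gets_full_bootstrap_support(two_family_alignment):
    """Two clearly separated synthetic families (Cu/Zn-like vs Mn-like
    templates, 5 each): the family bipartition is supported in 100% of
    replicates."""
    tree = bootstrap_support(two_family_alignment, n_reps=100, seed=31)
    cuzn = {t for t in two_family_alignment if t.startswith("cuzn")}
    assert family_bipartition_support(tree, cuzn) == pytest.approx(100.0)


def test_single_replicate_supports_are_binary(two_family_alignment):
    tree = bootstrap_support(two_family_alignment, n_reps=1, seed=9)
    supports = [
        n.support for n in tree.non_tips(include_self=False) if n.support is not None
    ]
    assert supports and all(s in (0.0, 100.0) for s in supports)


def test_bootstrap_deterministic_under_seed(two_family_alignment):
    t1 = bootstrap_support(two_family_alignment, n_reps=25, seed=3)
    t2 = bootstrap_support(two_family_alignment, n_reps=25, seed=3)
    s1 = sorted(n.support for n in t1.non_tips(include_self=False) if n.support is not None)
    s2 = sorted(n.support for n in t2.non_tips(include_self=False) if n.support is not None)
    assert s1 == s2


def test_bootstrap_rejects_zero_replicates(two_family_alignment):
    with pytest.raises(SodfamError):
        bootstrap_support(two_family_alignment, n_reps=0, seed=1)


def _with_support(newick, supports):
    tree = TreeNode.read([newick])
    for node in tree.non_tips(include_self=False):
        node.support = supports.get(node.name)
    return tree


def test_cut_clades_star_tree_all_singletons():
    tree = TreeNode.read(["(A,B,C,D,E);"])
    clades = cut_clades(tree, 50)
    assert len(set(clades.values())) == 5


def test_cut_clades_caterpillar_cuts_at_maximal_supported_edges():
    tree = _with_support("((((A,B)n1,C)n2,D)n3,E);", {"n1": 100.0, "n2": 100.0, "n3": 100.0})
    clades = cut_clades(tree, 50)
    # the deepest qualifying edge below the root claims {A,B,C,D}; E remains
    groups = {}
    for taxon, cid in clades.items():
        groups.setdefault(cid, set()).add(taxon)
    assert {frozenset(g) for g in groups.values()} == {
        frozenset({"A", "B", "C", "D"}), frozenset({"E"}),
    }


def test_cut_clades_threshold_above_100_gives_singletons():
    tree = _with_support("((A,B)n1,(C,D)n2);", {"n1": 100.0, "n2": 100.0})
    clades = cut_clades(tree, 101)
    assert len(set(clades.values())) == 4


def test_alignment_distance_ignores_gap_columns():
    aligned = {"a": "MKV-AS", "b": "MKVLAS", "c": "MKWLAS"}
    dm = alignment_distance_matrix(aligned)
    assert dm["a", "b"] == 0.0  # identical over shared columns
    assert dm["b", "c"] == pytest.approx(-math.log(5 / 6))
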