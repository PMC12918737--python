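import random
import warnings

import numpy as np
import pytest

from tadscan.cluster_calling import PresenceMatrix
from tadscan.genome_io import Genome, Replicon
from tadscan.phylo import (DistanceMatrix, TreeNode, ani,
                           ani_distance_matrix, concat_distance,
                           ladderized_leaf_order, neighbor_joining,
                           order_matrix_by_tree, p_distance, read_newick,
                           tree_path_lengths, upgma, write_newick)
from tadscan.synthetic_data import (GenomeSpec, build_genome, mutate_dna,
                                    random_dna, random_protein)


def random_additive_tree(names, rng):
    nodes = [TreeNode(name=n, length=rng.uniform(0.05, 1.0)) for n in names]
    while len(nodes) > 3:
        rng.shuffle(nodes)
        a, b = nodes.pop(), nodes.pop()
        nodes.append(TreeNode(children=[a, b],
                              length=rng.uniform(0.05, 1.0)))
    return TreeNode(children=nodes)


def matrix_from_tree(tree, names):
    pl = tree_path_lengths(tree)
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pl[tuple(sorted((names[i], names[j])))]
    return DistanceMatrix(taxa=list(names), d=d)


def test_three_taxon_closed_form():
    """d(A,B)=2, d(A,C)=4, d(B,C)=4 -> branches 1, 1, 3."""
    dm = DistanceMatrix(taxa=["A", "B", "C"],
                        d=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
    tree = neighbor_joining(dm)
    lengths = {l.name: l.length for l in tree.leaves()}
    assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})


def test_nj_recovers_additive_matrices_exactly():
    rng = random.Random(71)
    for _ in range(30):
        names = [f"t{i}" for i in range(rng.randint(4, 8))]
        true_tree = random_additive_tree(names, rng)
        dm = matrix_from_tree(true_tree, names)
        recovered = neighbor_joining(dm)
        got = tree_path_lengths(recovered)
        expected = tree_path_lengths(true_tree)
        for key in expected:
            assert got[key] == pytest.approx(expected[key], abs=1e-9)


def test_nj_agrees_with_scikit_bio_on_noisy_matrix():
    """Independent-oracle cross-check on a generic (tie-free) matrix."""
    import skbio

    rng = np.random.default_rng(72)
    n = 6
    names = [f"t{i}" for i in range(n)]
    d = rng.uniform(0.2, 1.0, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    ours = neighbor_joining(DistanceMatrix(taxa=names, d=d))
    theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids=names))
    got = tree_path_lengths(ours)
    for a, b in got:
        assert got[(a, b)] == pytest.approx(theirs.find(a).distance(
            theirs.find(b)), abs=1e-6)


def test_equal_distances_resolve_deterministically():
    n = 5
    names = [f"t{i}" for i in range(n)]
    d = np.full((n, n), 0.5)
    np.fill_diagonal(d, 0.0)
    t1 = neighbor_joining(DistanceMatrix(taxa=names, d=d))
    t2 = neighbor_joining(DistanceMatrix(taxa=names, d=d))
    assert write_newick(t1) == write_newick(t2)
    assert all(l.length >= 0 for l in t1.leaves())


def test_nj_rejects_bad_matrices():
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(taxa=["a", "b"],
                                        d=np.zeros((2, 2))))
    with pytest.raises(ValueError):
        DistanceMatrix(taxa=["a", "b", "c"],
                       d=np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]]))


def test_upgma_is_ultrametric():
    rng = random.Random(73)
    names = [f"t{i}" for i in range(5)]
    d = np.zeros((5, 5))
    for i in range(5):
        for j in range(i + 1, 5):
            d[i, j] = d[j, i] = rng.uniform(0.2, 1.0)
    tree = upgma(DistanceMatrix(taxa=names, d=d))

    def depth(node, acc=0.0):
        if node.is_leaf:
            return {acc + node.length}
        out = set()
        for c in node.children:
            out |= depth(c, acc + node.length)
        return out

    depths = depth(tree)
    assert max(depths) - min(depths) < 1e-9


def test_newick_round_trip_preserves_everything():
    rng = random.Random(74)
    tree = random_additive_tree([f"t{i}" for i in range(7)], rng)
    text = write_newick(tree)
    reread = read_newick(text)
    assert write_newick(reread) == text
    assert sorted(reread.leaf_names()) == sorted(tree.leaf_names())
    with pytest.raises(ValueError):
        read_newick("(a,b")
    with pytest.raises(ValueError):
        read_newick("((a,b),(a,c));")


def test_p_distance_definition():
    assert p_distance("A" * 100, "A" * 100) == 0.0
    a = "A" * 100
    b = "C" * 5 + "A" * 95
    assert p_distance(a, b) == pytest.approx(0.05)
    # gap columns are excluded
    assert p_distance("AC-G", "AC-G"[::1].replace("G", "T")) == \
        pytest.approx(1 / 3)


def test_concat_distance_counts_columns(refs):
    rng = np.random.default_rng(75)
    base = {r: random_protein(120, rng) for r in ("tadA", "tadB", "tadC")}

    def diverged(markers, n_subs, rng):
        out = {}
        for role, seq in markers.items():
            s = list(seq)
            for p in rng.choice(np.arange(1, len(s)), size=n_subs,
                                replace=False):
                s[p] = "W" if s[p] != "W" else "Y"
            out[role] = "".join(s)
        return out

    markers = {
        "t0": base,
        "t1": diverged(base, 6, np.random.default_rng(76)),
        "t2": diverged(base, 30, np.random.default_rng(77)),
    }
    dm = concat_distance(markers)
    # 3 markers x 120 aa = 360 columns; t1 differs at <= 18 of them
    i0, i1, i2 = (dm.taxa.index(t) for t in ("t0", "t1", "t2"))
    assert dm.d[i0, i1] == pytest.approx(18 / 360, abs=0.01)
    assert dm.d[i0, i2] > dm.d[i0, i1]


def test_concat_distance_drops_taxa_missing_markers(refs):
    rng = np.random.default_rng(78)
    base = {r: random_protein(100, rng) for r in ("tadA", "tadB", "tadC")}
    markers = {f"t{i}": dict(base) for i in range(4)}
    del markers["t3"]["tadC"]
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        dm = concat_distance(markers)
    assert dm.taxa == ["t0", "t1", "t2"]
    assert any("t3" in str(w.message) for w in caught)
    with pytest.raises(ValueError):
        concat_distance({"t0": base, "t1": base})


def test_ani_identity_and_null(refs):
    genome, _ = build_genome(GenomeSpec(genome_id="gA", implants=[],
                                        genome_len=40_000, n_decoy_genes=0),
                             refs, seed=80)
    assert ani(genome, genome) == pytest.approx(100.0)
    rng = np.random.default_rng(81)
    unrelated = Genome(id="gB", replicons=[
        Replicon(id="u", sequence=random_dna(40_000, 0.5, rng))])
    assert ani(genome, unrelated) is None


def test_ani_tracks_mutation_rate(refs):
    genome, _ = build_genome(GenomeSpec(genome_id="gA", implants=[],
                                        genome_len=40_000, n_decoy_genes=0),
                             refs, seed=82)
    rng = np.random.default_rng(83)
    mutated = Genome(id="gM", replicons=[
        Replicon(id="m", sequence=mutate_dna(genome.replicons[0].sequence,
                                             0.05, rng))])
    value = ani(genome, mutated)
    assert value == pytest.approx(95.0, abs=1.0)


def test_ani_distance_matrix_symmetrises(refs):
    g0, _ = build_genome(GenomeSpec(genome_id="g0", implants=[],
                                    genome_len=30_000, n_decoy_genes=0),
                         refs, seed=84)
    rng = np.random.default_rng(85)
    seq = g0.replicons[0].sequence
    g1 = Genome(id="g1", replicons=[
        Replicon(id="g1r", sequence=mutate_dna(seq, 0.02, rng))])
    g2 = Genome(id="g2", replicons=[
        Replicon(id="g2r", sequence=mutate_dna(seq, 0.10, rng))])
    dm = ani_distance_matrix([g0, g1, g2])
    assert dm.d[0, 1] < dm.d[0, 2]
    assert np.allclose(dm.d, dm.d.T)


def _matrix(rows):
    import pandas as pd

    table = pd.DataFrame.from_dict(
        {r: {"cluster_1": "complete"} for r in rows}, orient="index")
    return PresenceMatrix(table)


def test_order_matrix_by_tree_uses_ladderized_order():
    tree = read_newick("((d:1,(a:1,c:1):1):1,b:1);")
    order = ladderized_leaf_order(tree)
    matrix = _matrix(["a", "b", "c", "d"])
    ordered = order_matrix_by_tree(matrix, tree)
    assert list(ordered.table.index) == order
    assert order[0] == "b"  # smallest subtree first


def test_order_matrix_appends_missing_rows_alphabetically():
    tree = read_newick("(x:1,(b:1,a:1):1);")
    matrix = _matrix(["a", "b", "x", "zz", "mm"])
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        ordered = order_matrix_by_tree(matrix, tree)
    rows = list(ordered.table.index)
    assert rows[-2:] == ["mm", "zz"]
    assert set(rows[:3]) == {"a", "b", "x"}
    assert any("not in tree" in str(w.message) for w in caught)


def test_single_leaf_tree_puts_that_row_first():
    tree = read_newick("bb;")
    matrix = _matrix(["aa", "bb", "cc"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ordered = order_matrix_by_tree(matrix, tree)
    assert list(ordered.table.index) == ["bb", "aa", "cc"]


def test_row_multiset_preserved():
    tree = read_newick("((a:1,b:1):1,(c:1,d:1):1);")
    matrix = _matrix(["d", "b", "a", "c"])
    ordered = order_matrix_by_tree(matrix, tree)
    assert sorted(ordered.table.index) == ["a", "b", "c", "d"]
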