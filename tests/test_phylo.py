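"""Dice distances, neighbor joining, bootstrap support and Newick IO."""

import itertools

import dendropy
import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from bandpop.matrix import BandMatrix, BandMatrixError
from bandpop.phylo import (
    PhyloTree,
    bootstrap_support,
    dice_similarity,
    dissimilarity_matrix,
    group_mean_similarity,
    nj_tree,
    write_newick,
)
from bandpop.simulate import SimulationConfig, simulate_band_matrix

from conftest import make_matrix


class TestDice:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 0, 1], [1, 0, 1], 1.0),
            ([1, 1, 0], [1, 0, 1], 0.5),
            ([1, 0], [0, 1], 0.0),
        ],
    )
    def test_closed_forms(self, x, y, expected):
        assert dice_similarity(x, y) == expected

    def test_undefined_for_two_empty_profiles(self):
        with pytest.raises(ValueError, match="all-zero"):
            dice_similarity([0, 0], [0, 0])

    def test_invariant_to_shared_absences(self, rng):
        x = rng.integers(0, 2, 15)
        x[0] = 1
        y = rng.integers(0, 2, 15)
        y[0] = 1
        base = dice_similarity(x, y)
        assert dice_similarity(np.append(x, [0, 0]), np.append(y, [0, 0])) == base


class TestDistanceMatrix:
    def test_identical_samples_have_zero_distance(self):
        m = make_matrix([[1, 0, 1]] * 3)
        assert not dissimilarity_matrix(m).data.any()

    def test_matches_scipy_and_double_loop(self, rng):
        v = (rng.random((10, 20)) < 0.5).astype(int)
        v[:, 0] = 1  # no all-zero profile
        m = make_matrix(v)
        d = dissimilarity_matrix(m).data
        assert np.allclose(d, squareform(pdist(v.astype(bool), "dice")))
        for i, j in itertools.combinations(range(10), 2):
            assert d[i, j] == pytest.approx(1 - dice_similarity(v[i], v[j]))

    def test_band_order_invariance(self, random_matrix, rng):
        d = dissimilarity_matrix(random_matrix).data
        perm = rng.permutation(random_matrix.n_bands)
        m2 = BandMatrix(
            random_matrix.sample_ids,
            [random_matrix.band_ids[j] for j in perm],
            random_matrix.values[:, perm],
            random_matrix.band_to_primer,
            random_matrix.primer_system,
        )
        assert np.allclose(dissimilarity_matrix(m2).data, d)


class TestGroupSimilarity:
    def test_two_clone_groups(self):
        x, y = [1, 1, 0, 0], [1, 0, 1, 0]
        m = make_matrix([x, x, y, y])
        g = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
        out = group_mean_similarity(m, g)
        assert out.loc["A", "A"] == 1.0 and out.loc["B", "B"] == 1.0
        assert out.loc["A", "B"] == pytest.approx(dice_similarity(x, y))

    def test_singleton_group_diagonal_missing(self):
        m = make_matrix([[1, 1, 0], [1, 0, 1]])
        out = group_mean_similarity(m, {"s1": "A", "s2": "B"})
        assert np.isnan(out.loc["A", "A"]) and np.isnan(out.loc["B", "B"])
        assert out.loc["A", "B"] == 0.5

    def test_invariant_to_within_group_relabeling(self, random_matrix, rng):
        labels = ["G1"] * 10 + ["G2"] * 10
        g = dict(zip(random_matrix.sample_ids, labels))
        base = group_mean_similarity(random_matrix, g)
        perm = np.concatenate([rng.permutation(10), 10 + rng.permutation(10)])
        m2 = random_matrix.subset_samples([random_matrix.sample_ids[i] for i in perm])
        again = group_mean_similarity(m2, g)
        assert np.allclose(base.to_numpy(), again.to_numpy())


# ---------------------------------------------------------------------------
# additive-tree oracle: enumerate all unrooted binary topologies


def _all_topologies(leaves):
    """Edge lists of every unrooted binary tree over ``leaves`` (leaf insertion)."""
    a, b, c, *rest = leaves
    base = [("X0", a), ("X0", b), ("X0", c)]
    trees = [(base, 1)]
    for leaf in rest:
        nxt = []
        for edges, n_int in trees:
            for k in range(len(edges)):
                u, v = edges[k]
                new_int = f"X{n_int}"
                e2 = edges[:k] + edges[k + 1 :]
                e2 += [(u, new_int), (new_int, v), (new_int, leaf)]
                nxt.append((e2, n_int + 1))
        trees = nxt
    return [edges for edges, _ in trees]


def _path_distances(edges, lengths, leaves):
    import networkx as nx

    g = nx.Graph()
    for (u, v), w in zip(edges, lengths):
        g.add_edge(u, v, weight=w)
    n = len(leaves)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = nx.shortest_path_length(
            g, leaves[i], leaves[j], weight="weight"
        )
    return d


def _tip_distances(tree, leaves):
    n = len(leaves)
    tips = {t.name: t for t in tree.tips()}
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = tips[leaves[i]].distance(tips[leaves[j]])
    return d


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # from ((A:1,B:2):0.5,(C:3,D:4):0.5)
        ids = list("ABCD")
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        t = nj_tree(DistanceMatrix(d, ids))
        assert np.allclose(_tip_distances(t.tree, ids), d)
        # the AB|CD split is an internal bipartition
        sides = {
            frozenset(x.name for x in n.tips())
            for n in t.tree.traverse(include_self=False)
            if not n.is_tip()
        }
        assert frozenset("AB") in sides or frozenset("CD") in sides

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        t = nj_tree(DistanceMatrix(d, list("ABC")))
        lengths = {tip.name: tip.length for tip in t.tree.tips()}
        assert lengths == pytest.approx({"A": 0.0, "B": 2.0, "C": 3.0})

    @pytest.mark.parametrize("n_leaves", [4, 5])
    def test_recovers_every_additive_topology(self, n_leaves, rng):
        """NJ is exact on additive distances for all 4- and 5-leaf topologies."""
        leaves = [f"L{i}" for i in range(n_leaves)]
        for edges in _all_topologies(leaves):
            lengths = rng.uniform(0.1, 2.0, size=len(edges))
            d = _path_distances(edges, lengths, leaves)
            t = nj_tree(DistanceMatrix(d, leaves))
            assert np.allclose(_tip_distances(t.tree, leaves), d, atol=1e-9)

    def test_matches_skbio_on_additive_input(self, rng):
        leaves = [f"L{i}" for i in range(5)]
        edges = _all_topologies(leaves)[3]
        d = _path_distances(edges, rng.uniform(0.2, 1.5, size=len(edges)), leaves)
        ours = _tip_distances(nj_tree(DistanceMatrix(d, leaves)).tree, leaves)
        theirs = _tip_distances(skbio_nj(DistanceMatrix(d, leaves)), leaves)
        assert np.allclose(ours, theirs, atol=1e-9)

    def test_tie_break_is_deterministic(self):
        # equidistant taxa: every join has equal Q; lowest index pair first
        d = np.ones((4, 4)) - np.eye(4)
        t1 = nj_tree(DistanceMatrix(d, list("ABCD")))
        t2 = nj_tree(DistanceMatrix(d, list("ABCD")))
        assert str(t1.tree) == str(t2.tree)

    def test_asymmetric_matrix_rejected(self):
        bad = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError):
            nj_tree(bad, ids=list("ABC"))

    def test_branch_lengths_nonnegative_on_noisy_data(self):
        m, _, _ = simulate_band_matrix(
            SimulationConfig(n_pops=4, samples_per_pop=5, divergence=0.05, seed=44)
        )
        t = nj_tree(dissimilarity_matrix(m))
        assert all(
            (n.length or 0) >= 0 for n in t.tree.traverse(include_self=False)
        )


class TestBootstrap:
    def test_single_replicate_supports_are_zero_or_hundred(self):
        m, _, _ = simulate_band_matrix(
            SimulationConfig(n_pops=3, samples_per_pop=4, divergence=0.3, seed=5)
        )
        t = bootstrap_support(m, n_reps=1, seed=9)
        assert set(t.supports.values()) <= {0.0, 100.0}

    def test_duplicating_every_band_preserves_topology(self):
        m, _, _ = simulate_band_matrix(
            SimulationConfig(n_pops=3, samples_per_pop=4, divergence=0.3, seed=6)
        )
        doubled = BandMatrix(
            m.sample_ids,
            list(m.band_ids) + [b + "_dup" for b in m.band_ids],
            np.hstack([m.values, m.values]),
            {**m.band_to_primer, **{b + "_dup": m.band_to_primer[b] for b in m.band_ids}},
            m.primer_system,
        )
        d1 = dissimilarity_matrix(m).data
        d2 = dissimilarity_matrix(doubled).data
        assert np.allclose(d1, d2)  # Dice is scale invariant
        assert str(nj_tree(dissimilarity_matrix(m)).tree) == str(
            nj_tree(dissimilarity_matrix(doubled)).tree
        )

    def test_seed_reproducibility_and_band_order_invariance(self, rng):
        m, _, _ = simulate_band_matrix(
            SimulationConfig(n_pops=3, samples_per_pop=5, divergence=0.3, seed=77)
        )
        s1 = bootstrap_support(m, n_reps=25, seed=4).supports
        s2 = bootstrap_support(m, n_reps=25, seed=4).supports
        assert s1 == s2


class TestNewick:
    def test_three_leaf_round_trip(self, tmp_path):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        t = nj_tree(DistanceMatrix(d, list("ABC")))
        p = tmp_path / "t.nwk"
        write_newick(t, p)
        parsed = dendropy.Tree.get(path=str(p), schema="newick")
        assert {x.taxon.label for x in parsed.leaf_node_iter()} == set("ABC")

    def test_supports_written_as_internal_labels(self, tmp_path):
        m, _, _ = simulate_band_matrix(
            SimulationConfig(n_pops=3, samples_per_pop=4, divergence=0.4, seed=12)
        )
        t = bootstrap_support(m, n_reps=10, seed=2)
        p = tmp_path / "t.nwk"
        write_newick(t, p)
        text = p.read_text()
        labels = [str(int(round(v))) for v in t.supports.values()]
        assert any(f"){lab}:" in text for lab in labels)

    def test_round_trip_is_isomorphic_via_independent_parser(self, tmp_path):
        m, _, _ = simulate_band_matrix(
            SimulationConfig(n_pops=4, samples_per_pop=4, divergence=0.3, seed=18)
        )
        t = nj_tree(dissimilarity_matrix(m))
        p = tmp_path / "t.nwk"
        write_newick(t, p)
        parsed = dendropy.Tree.get(path=str(p), schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in parsed.taxon_namespace}
        ids = list(m.sample_ids)
        ours = _tip_distances(t.tree, ids)
        for i, j in itertools.combinations(range(len(ids)), 2):
            got = pdm.distance(taxa[ids[i]], taxa[ids[j]])
            assert got == pytest.approx(ours[i, j], abs=1e-6)
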