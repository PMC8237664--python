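"""Kinship, IBS distances, neighbor joining, and bootstrap supports."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hircus import simdata
from hircus.genotypes import MISSING, PseudohaploidMatrix
from hircus.relatedness import (
    DistanceMatrix,
    TreeNode,
    bootstrap_tree,
    ibs_distance,
    kinship_pihat,
    neighbor_joining,
    pairwise_mismatch,
    tree_bipartitions,
)

from conftest import haploidize, make_panel, matrix_from_genotypes


def small_matrix(calls, samples=None):
    calls = np.asarray(calls, dtype=np.int8)
    samples = samples or tuple(f"s{i}" for i in range(calls.shape[0]))
    return PseudohaploidMatrix(calls, tuple(samples), make_panel(calls.shape[1], 1))


class TestPairwiseMismatch:
    def test_identical_and_complementary(self):
        m = small_matrix([[0, 1, 0, 1], [0, 1, 0, 1], [1, 0, 1, 0]])
        table = pairwise_mismatch(m)
        by_pair = {(r["a"], r["b"]): r["mismatch"] for _, r in table.iterrows()}
        assert by_pair[("s0", "s1")] == 0.0
        assert by_pair[("s0", "s2")] == 1.0

    def test_missing_excluded_from_overlap(self):
        m = small_matrix([[0, 1, 0, MISSING], [0, 0, 0, 1]])
        row = pairwise_mismatch(m).iloc[0]
        assert row["overlap"] == 3
        assert row["mismatch"] == pytest.approx(1 / 3)

    def test_zero_overlap_flagged(self):
        m = small_matrix([[0, MISSING], [MISSING, 1]])
        row = pairwise_mismatch(m).iloc[0]
        assert not row["usable"] and np.isnan(row["mismatch"])


class TestKinshipPihat:
    def _table(self, mismatches):
        rows = [
            {"a": f"a{i}", "b": f"b{i}", "mismatch": m, "overlap": 1000, "usable": True}
            for i, m in enumerate(mismatches)
        ]
        return pd.DataFrame(rows)

    def test_baseline_pair_is_unrelated(self):
        table = self._table([0.2, 0.2, 0.2, 0.2])
        for est in kinship_pihat(table):
            assert est.pi_hat == 0.0

    def test_half_baseline_is_self(self):
        table = self._table([0.2, 0.2, 0.2, 0.1])
        est = {e.pair: e for e in kinship_pihat(table)}
        assert est[("a3", "b3")].pi_hat == pytest.approx(1.0)

    def test_designated_pairs_baseline(self):
        table = self._table([0.2, 0.3, 0.1])
        ests = kinship_pihat(
            table,
            baseline_strategy="designated_pairs",
            designated_pairs=[("a0", "b0")],
        )
        assert all(e.baseline == 0.2 for e in ests)

    def test_degenerate_baseline_rejected(self):
        with pytest.raises(ValueError):
            kinship_pihat(self._table([0.0, 0.0, 0.0]))

    def test_pedigree_recovery(self, rng):
        # 6 unrelated + parent-offspring + self pairs at 5e4 sites
        n_sites = 50_000
        freqs = rng.uniform(0.05, 0.95, n_sites)
        genos, names = [], []
        for i in range(6):
            a, b, _ = simdata.simulate_pedigree_pair(freqs, "unrelated", rng)
            genos.append(a)
            names.append(f"u{i}")
        po_a, po_b, _ = simdata.simulate_pedigree_pair(freqs, "parent_offspring", rng)
        sf_a, sf_b, _ = simdata.simulate_pedigree_pair(freqs, "self", rng)
        genos += [po_a, po_b, sf_a, sf_b]
        names += ["par", "off", "self1", "self2"]
        matrix = matrix_from_genotypes(genos, names, rng)
        ests = {
            frozenset(e.pair): e.pi_hat
            for e in kinship_pihat(pairwise_mismatch(matrix))
        }
        assert ests[frozenset(("par", "off"))] == pytest.approx(0.5, abs=0.05)
        assert ests[frozenset(("self1", "self2"))] >= 0.95
        for i, j in itertools.combinations(range(6), 2):
            assert ests[frozenset((f"u{i}", f"u{j}"))] <= 0.1


class TestIbsDistance:
    def test_symmetry_zero_diagonal(self, rng):
        calls = rng.integers(0, 2, (5, 400)).astype(np.int8)
        d = ibs_distance(small_matrix(calls))
        assert np.allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)

    def test_population_structure_ordering(self, rng):
        # within-population distances below between-population distances
        n_sites = 20_000
        root = rng.uniform(0.05, 0.95, n_sites)
        pa = simdata.drift_frequencies(root, 0.15, rng)
        pb = simdata.drift_frequencies(root, 0.15, rng)
        genos, names = [], []
        for pop, freqs in (("a", pa), ("b", pb)):
            g = simdata.simulate_individuals(freqs, 3, rng)
            for i in range(3):
                genos.append(g[i])
                names.append(f"{pop}{i}")
        matrix = matrix_from_genotypes(genos, names, rng)
        d = ibs_distance(matrix)
        idx = {n: i for i, n in enumerate(d.labels)}
        within = [
            d.values[idx[f"{p}{i}"], idx[f"{p}{j}"]]
            for p in "ab"
            for i, j in itertools.combinations(range(3), 2)
        ]
        between = [
            d.values[idx[f"a{i}"], idx[f"b{j}"]] for i in range(3) for j in range(3)
        ]
        assert max(within) < min(between)


def tree_distance_matrix(root, labels):
    """Leaf-to-leaf path lengths of a TreeNode tree."""

    def leaf_depths(node, depth=0.0):
        if node.is_leaf:
            return {node.name: depth}
        out = {}
        for child, ln in node.children:
            out.update(leaf_depths(child, depth + ln))
        return out

    def all_dists(node):
        dists = {}
        if node.is_leaf:
            return dists
        child_maps = []
        for child, ln in node.children:
            dists.update(all_dists(child))
            child_maps.append(leaf_depths(child, ln))
        for m1, m2 in itertools.combinations(child_maps, 2):
            for a, da in m1.items():
                for b, db in m2.items():
                    dists[frozenset((a, b))] = da + db
        return dists

    dmap = all_dists(root)
    n = len(labels)
    D = np.zeros((n, n))
    for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
        D[i, j] = D[j, i] = dmap[frozenset((a, b))]
    return D


def random_additive_tree(labels, rng):
    """Random binary topology with branch lengths; returns (splits, D)."""
    nodes = [TreeNode(lab) for lab in labels]
    lengths = {id(n): rng.uniform(0.05, 1.0) for n in nodes}
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = TreeNode()
        parent.children = [
            (nodes[i], lengths[id(nodes[i])]),
            (nodes[j], lengths[id(nodes[j])]),
        ]
        lengths[id(parent)] = rng.uniform(0.05, 1.0)
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    root.children = [(n, lengths[id(n)]) for n in nodes]
    return tree_bipartitions(root), tree_distance_matrix(root, labels)


class TestNeighborJoining:
    def test_additive_four_taxon_recovery(self):
        # distances from tree ((a:1,b:2):1,(c:3,d:4)) -> exact recovery
        labels = ("a", "b", "c", "d")
        D = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 0, 0],
            ],
            dtype=float,
        )
        D[2, 3] = D[3, 2] = 7
        tree = neighbor_joining(DistanceMatrix(labels, D, np.ones((4, 4))))
        assert tree.bipartitions() == {frozenset(("c", "d"))}
        # recovered path lengths are exact on additive input
        recovered = tree_distance_matrix(tree.root, labels)
        assert np.allclose(recovered, D)

    def test_consistency_on_random_additive_matrices(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 13))
            labels = tuple(f"t{i}" for i in range(n))
            true_splits, D = random_additive_tree(labels, rng)
            tree = neighbor_joining(
                DistanceMatrix(labels, D, np.ones_like(D))
            )
            assert tree.bipartitions() == true_splits

    def test_matches_reference_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj

        for _ in range(5):
            labels = tuple(f"t{i}" for i in range(8))
            _, D = random_additive_tree(labels, rng)
            ours = neighbor_joining(DistanceMatrix(labels, D, np.ones_like(D)))
            ref = nj(skbio.DistanceMatrix(D, ids=list(labels)))
            all_set = frozenset(labels)
            anchor = min(labels)
            ref_splits = set()
            for node in ref.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                canon = all_set - side if anchor in side else side
                if 2 <= len(canon) <= len(labels) - 2:
                    ref_splits.add(canon)
            assert ours.bipartitions() == ref_splits

    def test_taxon_order_invariance(self, rng):
        labels = tuple(f"t{i}" for i in range(7))
        _, D = random_additive_tree(labels, rng)
        perm = rng.permutation(len(labels))
        Dp = D[np.ix_(perm, perm)]
        t1 = neighbor_joining(DistanceMatrix(labels, D, np.ones_like(D)))
        t2 = neighbor_joining(
            DistanceMatrix(
                tuple(labels[i] for i in perm), Dp, np.ones_like(Dp)
            )
        )
        assert t1.bipartitions() == t2.bipartitions()

    def test_negative_branches_clamped(self):
        # a non-additive matrix that would yield a negative NJ branch
        labels = ("a", "b", "c", "d")
        D = np.array(
            [
                [0.0, 0.1, 0.4, 0.4],
                [0.1, 0.0, 0.4, 0.4],
                [0.4, 0.4, 0.0, 0.05],
                [0.4, 0.4, 0.05, 0.0],
            ]
        )
        tree = neighbor_joining(DistanceMatrix(labels, D, np.ones_like(D)))

        def min_branch(node):
            out = [0.0]
            for child, ln in node.children:
                out.append(ln)
                out.append(min_branch(child))
            return min(out)

        assert min_branch(tree.root) >= 0.0

    def test_nan_rejected(self):
        D = np.zeros((4, 4))
        D[0, 1] = D[1, 0] = np.nan
        with pytest.raises(ValueError):
            neighbor_joining(
                DistanceMatrix(("a", "b", "c", "d"), D, np.ones_like(D))
            )


class TestBootstrapTree:
    def _structured_matrix(self, rng, drift=0.3, n_sites=8000):
        root = rng.uniform(0.05, 0.95, n_sites)
        pa = simdata.drift_frequencies(root, drift, rng)
        pb = simdata.drift_frequencies(root, drift, rng)
        genos, names = [], []
        for pop, freqs in (("a", pa), ("b", pb)):
            g = simdata.simulate_individuals(freqs, 3, rng)
            for i in range(3):
                genos.append(g[i])
                names.append(f"{pop}{i}")
        return matrix_from_genotypes(genos, names, rng, n_chroms=4)

    def test_supports_bounded_and_deterministic(self, rng):
        matrix = self._structured_matrix(rng)
        t1 = bootstrap_tree(matrix, np.random.default_rng(11), n_reps=25)
        t2 = bootstrap_tree(matrix, np.random.default_rng(11), n_reps=25)
        assert t1.supports == t2.supports
        assert all(0.0 <= s <= 1.0 for s in t1.supports.values())

    def test_deep_clades_highly_supported(self, rng):
        matrix = self._structured_matrix(rng, drift=0.3)
        tree = bootstrap_tree(matrix, rng, n_reps=50)
        clade_a = frozenset(("a0", "a1", "a2"))
        clade_b = frozenset(("b0", "b1", "b2"))
        splits = tree.supports
        assert clade_a in splits or clade_b in splits
        for clade in (clade_a, clade_b):
            if clade in splits:
                assert splits[clade] >= 0.9

    def test_support_monotone_in_drift(self, rng):
        supports = []
        for drift in (0.02, 0.1, 0.3):
            matrix = self._structured_matrix(
                np.random.default_rng(5), drift=drift, n_sites=3000
            )
            tree = bootstrap_tree(matrix, np.random.default_rng(7), n_reps=30)
            clade = frozenset(("a0", "a1", "a2"))
            alt = frozenset(("b0", "b1", "b2"))
            s = max(tree.supports.get(clade, 0.0), tree.supports.get(alt, 0.0))
            supports.append(s)
        assert supports == sorted(supports)

    def test_newick_contains_supports(self, rng):
        matrix = self._structured_matrix(rng)
        tree = bootstrap_tree(matrix, rng, n_reps=10)
        nwk = tree.newick()
        assert nwk.endswith(";") and "(" in nwk
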