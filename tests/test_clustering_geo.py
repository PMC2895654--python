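"""K2P distances, neighbor joining vs additive oracles, bootstrap support,
haversine geography, and Mantel calibration."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from ddpop.clustering_geo import (
    EARTH_RADIUS_KM,
    SkbioDistanceMatrix,
    bipartitions,
    bootstrap_support,
    geographic_distances,
    haversine_km,
    k2p_distance,
    mantel_test,
    neighbor_joining,
)
from ddpop.seqio import Concatenation, StrainTable


def _concat(seqs):
    length = len(next(iter(seqs.values())))
    return Concatenation(seqs, [("f1", 0, length)], {"f1": ("chr1", 1)})


class TestK2P:
    def test_identical_sequences_zero(self):
        out = k2p_distance(_concat({"a": "ACGT" * 5, "b": "ACGT" * 5}))
        assert out.matrix["a", "b"] == 0.0

    def test_pure_transition_closed_form(self):
        # 10 columns, one A<->G difference: P=0.1, Q=0 -> -0.5*ln(0.8)
        a = "A" + "C" * 9
        b = "G" + "C" * 9
        out = k2p_distance(_concat({"a": a, "b": b}))
        assert out.matrix["a", "b"] == pytest.approx(-0.5 * np.log(0.8), abs=1e-9)
        assert out.matrix["a", "b"] == pytest.approx(0.11157, abs=1e-5)

    def test_symmetric(self, mini_study):
        from ddpop.seqio import concatenate_alignments

        out = k2p_distance(concatenate_alignments(mini_study.fragments[:6]))
        assert np.allclose(out.matrix.data, out.matrix.data.T)

    def test_saturation_reported_undefined(self):
        # 75% transversions: 1 - 2Q = -0.5 -> log undefined
        a = "AAAA"
        b = "CCCA"
        out = k2p_distance(_concat({"a": a, "b": b}))
        assert ("a", "b") in out.undefined_pairs


def _random_tree_distances(n_taxa: int, rng) -> tuple[dict, SkbioDistanceMatrix]:
    """Random binary unrooted tree with positive branch lengths -> additive
    distance matrix plus the generating tree's bipartitions."""
    import itertools

    nodes = [frozenset([i]) for i in range(n_taxa)]
    children: dict = {f: [] for f in nodes}
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = nodes[i] | nodes[j]
        children[merged] = [nodes[i], nodes[j]]
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [merged]
    lengths = {}
    all_edges = [k for k in children if 0 < len(k) < n_taxa] + list(
        frozenset([i]) for i in range(n_taxa)
    )
    for e in set(all_edges):
        lengths[e] = float(rng.uniform(0.05, 1.0))

    def leaf_path(a: int) -> set:
        # edges on the path from leaf a up to the (virtual) root
        path = set()
        for e in lengths:
            if a in e:
                path.add(e)
        return path

    ids = [f"t{i}" for i in range(n_taxa)]
    d = np.zeros((n_taxa, n_taxa))
    for a, b in combinations(range(n_taxa), 2):
        sym = leaf_path(a) ^ leaf_path(b)
        d[a, b] = d[b, a] = sum(lengths[e] for e in sym)
    parts = {
        frozenset(f"t{i}" for i in e)
        for e in lengths
        if 2 <= len(e) <= n_taxa - 2
    }
    # canonicalize: smaller side of each split
    canon = set()
    full = frozenset(ids)
    for p in parts:
        q = full - p
        canon.add(p if (len(p), sorted(p)) <= (len(q), sorted(q)) else q)
    return {"ids": ids, "splits": canon}, SkbioDistanceMatrix(d, ids=ids)


def _quartet_split(dm: SkbioDistanceMatrix, quartet) -> frozenset:
    """The additive-matrix quartet topology: the pairing with minimal sum
    (exhaustive over the three pairings)."""
    a, b, c, d = quartet
    sums = {
        frozenset([frozenset([a, b]), frozenset([c, d])]): dm[a, b] + dm[c, d],
        frozenset([frozenset([a, c]), frozenset([b, d])]): dm[a, c] + dm[b, d],
        frozenset([frozenset([a, d]), frozenset([b, c])]): dm[a, d] + dm[b, c],
    }
    return min(sums, key=sums.get)


class TestNeighborJoining:
    def test_three_taxa_star(self):
        dm = SkbioDistanceMatrix(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], ids=["a", "b", "c"]
        )
        tree = neighbor_joining(dm).tree
        assert {t.name for t in tree.tips()} == {"a", "b", "c"}
        assert bipartitions(tree) == set()

    def test_additive_four_taxon_recovery(self):
        # tree ((a:1,b:2):1,(c:3,d:1)): d(a,b)=3, d(a,c)=5, d(a,d)=3, ...
        d = np.array(
            [
                [0, 3, 5, 3],
                [3, 0, 6, 4],
                [5, 6, 0, 4],
                [3, 4, 4, 0],
            ],
            dtype=float,
        )
        dm = SkbioDistanceMatrix(d, ids=["a", "b", "c", "d"])
        tree = neighbor_joining(dm).tree
        assert bipartitions(tree) == {frozenset(["a", "b"])}
        # additive matrix: patristic distances reproduce the input exactly
        for x, y in combinations("abcd", 2):
            tx = tree.find(x)
            assert tx.distance(tree.find(y)) == pytest.approx(dm[x, y], abs=1e-9)

    def test_random_additive_matrices_vs_exhaustive_quartets(self):
        """NJ on additive matrices recovers the generating topology, and the
        recovered splits agree with the exhaustive three-pairing quartet
        minimum on every sampled quartet."""
        rng = np.random.default_rng(23)
        for _ in range(15):
            n_taxa = int(rng.integers(4, 9))
            truth, dm = _random_tree_distances(n_taxa, rng)
            tree = neighbor_joining(dm).tree
            parts = bipartitions(tree)
            assert parts == truth["splits"]
            full = frozenset(truth["ids"])
            two_sided = [(p, full - p) for p in parts]
            quartets = list(combinations(truth["ids"], 4))
            rng.shuffle(quartets)
            for quartet in quartets[:10]:
                matrix_split = _quartet_split(dm, quartet)
                qset = set(quartet)
                tree_pairings = set()
                for side, other in two_sided:
                    left = qset & side
                    if len(left) == 2:
                        tree_pairings.add(
                            frozenset([frozenset(left), frozenset(qset - left)])
                        )
                if tree_pairings:  # unresolved quartets cannot occur on binary trees
                    assert matrix_split in tree_pairings

    def test_leaf_order_permutation_same_topology(self):
        rng = np.random.default_rng(4)
        _, dm = _random_tree_distances(6, rng)
        t1 = neighbor_joining(dm).tree
        order = list(dm.ids)[::-1]
        t2 = neighbor_joining(dm.filter(order)).tree
        assert bipartitions(t1) == bipartitions(t2)


class TestBootstrap:
    def test_identical_pair_cherry_full_support(self):
        """Two identical strains distinct from the rest: their cherry at 100%."""
        rng = np.random.default_rng(9)
        base = rng.choice(list("ACGT"), size=200)
        seqs = {}
        twin = base.copy()
        twin[:30] = np.where(twin[:30] == "A", "G", "A")
        seqs["a"] = "".join(twin)
        seqs["b"] = "".join(twin)  # identical to a
        for k, name in enumerate(["c", "d", "e"]):
            mutant = base.copy()
            pos = rng.choice(200, size=15, replace=False)
            mutant[pos] = np.where(mutant[pos] == "C", "T", "C")
            seqs[name] = "".join(mutant)
        out = bootstrap_support(_concat(seqs), replicates=100, seed=0)
        assert out.supports[frozenset(["a", "b"])] == 100.0

    def test_supports_in_range_and_reproducible(self, mini_study):
        from ddpop.seqio import concatenate_alignments

        concat = concatenate_alignments(mini_study.fragments[:10])
        r1 = bootstrap_support(concat, replicates=30, seed=5)
        r2 = bootstrap_support(concat, replicates=30, seed=5)
        assert all(0 <= v <= 100 for v in r1.supports.values())
        assert r1.supports == r2.supports  # seed-fixed: bit-reproducible


class TestGeography:
    def _table(self, rows):
        return StrainTable(
            pd.DataFrame(
                rows,
                columns=["strain_id", "site_name", "latitude", "longitude", "mating_type"],
            )
        )

    def test_shared_site_gets_within_site_constant(self):
        t = self._table(
            [("a", "s1", 37.3, -80.5, "matA1"), ("b", "s1", 37.4, -80.6, "matA2")]
        )
        out = geographic_distances(t)
        assert out.matrix["a", "b"] == 1.0

    def test_identical_coordinates_different_sites_zero(self):
        t = self._table(
            [("a", "s1", 37.3, -80.5, "matA1"), ("b", "s2", 37.3, -80.5, "matA2")]
        )
        assert geographic_distances(t).matrix["a", "b"] == 0.0

    def test_antipodal_half_circumference(self):
        assert haversine_km(0.0, 0.0, 0.0, 180.0) == pytest.approx(
            np.pi * EARTH_RADIUS_KM, rel=1e-9
        )

    def test_missing_coordinates_named(self):
        t = self._table(
            [("a", "s1", 37.3, -80.5, "matA1"), ("b", "s2", np.nan, -80.5, "matA2")]
        )
        with pytest.raises(ValueError, match="b"):
            geographic_distances(t)


class TestMantel:
    def _random_dm(self, n, rng, ids=None):
        x = rng.uniform(1, 10, size=(n, n))
        d = np.triu(x, 1)
        d = d + d.T
        return SkbioDistanceMatrix(d, ids=ids or [f"s{i}" for i in range(n)])

    def test_self_correlation_attains_floor(self):
        rng = np.random.default_rng(0)
        dm = self._random_dm(10, rng)
        r, p = mantel_test(dm, dm, n_perm=200, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 201)

    def test_matches_skbio_statistic(self):
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(7)
        a = self._random_dm(12, rng)
        b = self._random_dm(12, rng)
        r, _ = mantel_test(a, b, n_perm=10, seed=0)
        expected = skbio_mantel(a, b, method="pearson", permutations=0)[0]
        assert r == pytest.approx(float(expected), abs=1e-9)

    def test_type_i_error_calibrated(self):
        """Unrelated matrices: rejection rate at alpha=0.05 in (0.01, 0.10)."""
        rng = np.random.default_rng(31)
        rejections, runs = 0, 100
        for k in range(runs):
            a = self._random_dm(12, rng)
            b = self._random_dm(12, rng)
            _, p = mantel_test(a, b, n_perm=199, seed=k)
            if p <= 0.05:
                rejections += 1
        assert 0.01 <= rejections / runs <= 0.10

    def test_constant_matrix_undefined(self):
        ids = [f"s{i}" for i in range(5)]
        const = SkbioDistanceMatrix(np.ones((5, 5)) - np.eye(5), ids=ids)
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="constant"):
            mantel_test(const, self._random_dm(5, rng, ids), n_perm=10, seed=0)
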