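"""Nei-Li similarity, UPGMA, bootstrap supports and Newick output."""

import io as stdio

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from ugms.config import DiversityConfig
from ugms.diversity import (
    AlleleIncidence,
    bootstrap_consensus,
    clades,
    cophenetic_matrix,
    distance_matrix,
    incidence_from_matrix,
    nei_li_similarity,
    similarity_matrix,
    to_newick,
    upgma,
)
from ugms.genotyping import GenotypeMatrix


class TestNeiLi:
    def test_identical_profiles(self):
        a = np.array([1, 0, 1, 1])
        assert nei_li_similarity(a, a) == 1.0

    def test_disjoint_profiles(self):
        assert nei_li_similarity([1, 1, 0, 0], [0, 0, 1, 1]) == 0.0

    def test_partial_sharing(self):
        # 3 presences each, 2 shared: 2*2 / (2*2 + 1 + 1)
        a = [1, 1, 1, 0]
        b = [1, 1, 0, 1]
        assert nei_li_similarity(a, b) == pytest.approx(2 * 2 / (2 * 2 + 1 + 1))

    def test_empty_profiles_rejected(self):
        with pytest.raises(ValueError):
            nei_li_similarity([0, 0], [0, 0])

    def test_symmetric_and_bounded_on_random_profiles(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            a = rng.integers(0, 2, size=20)
            b = rng.integers(0, 2, size=20)
            if not (a.any() or b.any()):
                continue
            s = nei_li_similarity(a, b)
            assert s == nei_li_similarity(b, a)
            assert 0.0 <= s <= 1.0
            assert (s == 1.0) == bool((a == b).all())


def _random_incidence(rng, n_samples=6, n_loci=5, alleles_per_locus=3):
    rows, data = [], []
    for li in range(n_loci):
        for ai in range(alleles_per_locus):
            rows.append(((f"p{li}", "a"), 100 + ai))
            data.append(rng.integers(0, 2, size=n_samples))
    arr = np.array(data, dtype=np.int8)
    arr[0] = 1  # ensure nobody has an all-zero profile
    return AlleleIncidence(
        rows=tuple(rows),
        samples=tuple(f"s{i}" for i in range(n_samples)),
        data=arr,
    )


class TestDistanceMatrix:
    def test_symmetric_zero_diagonal_on_random_panels(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            inc = _random_incidence(rng)
            D = distance_matrix(inc)
            assert np.allclose(D.values, D.values.T)
            assert np.allclose(np.diag(D.values), 0.0)
            assert ((D.values >= 0) & (D.values <= 1)).all()


class TestUPGMA:
    def test_two_taxa_cherry(self):
        D = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]], index=["A", "B"], columns=["A", "B"])
        tree = upgma(D)
        assert sorted(tree.leaves()) == ["A", "B"]
        assert tree.height == pytest.approx(0.2)

    def test_three_taxa_topology_and_height(self):
        D = pd.DataFrame(
            [[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]],
            index=list("ABC"), columns=list("ABC"),
        )
        tree = upgma(D)
        assert clades(tree) == {frozenset({"A", "B"})}
        assert tree.height == pytest.approx(0.3)

    def test_ultrametric_input_cophenetic_recovery(self):
        """On an ultrametric matrix UPGMA reproduces the input exactly."""
        tree_heights = {("A", "B"): 0.1, ("A", "C"): 0.25, ("B", "C"): 0.25,
                        ("A", "D"): 0.4, ("B", "D"): 0.4, ("C", "D"): 0.4}
        names = list("ABCD")
        D = pd.DataFrame(0.0, index=names, columns=names)
        for (a, b), d in tree_heights.items():
            D.loc[a, b] = D.loc[b, a] = 2 * d / 2 * 2  # cophenetic = 2*height
        D /= 2
        tree = upgma(D)
        C = cophenetic_matrix(tree)
        pd.testing.assert_frame_equal(C.loc[names, names], D, atol=1e-12)

    def test_matches_scipy_average_linkage(self):
        """Cophenetic distances agree with SciPy's average-linkage
        clustering on random distance matrices (independent oracle)."""
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            X = rng.random((n, 4))
            D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
            names = [f"t{i}" for i in range(n)]
            tree = upgma(pd.DataFrame(D, index=names, columns=names))
            C = cophenetic_matrix(tree).loc[names, names].to_numpy()
            Z = average(squareform(D, checks=False))
            C_scipy = squareform(cophenet(Z))
            assert np.allclose(C, C_scipy, atol=1e-10)

    def test_ultrametric_output(self):
        rng = np.random.default_rng(3)
        inc = _random_incidence(rng, n_samples=7)
        tree = upgma(distance_matrix(inc))
        # all leaves equidistant from the root
        def depth(node, acc):
            if node.is_leaf:
                return [acc]
            out = []
            for c in node.children:
                out += depth(c, acc + node.height - c.height)
            return out
        depths = depth(tree, 0.0)
        assert np.allclose(depths, depths[0], atol=1e-9)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(9)
        inc = _random_incidence(rng, n_samples=6)
        D = distance_matrix(inc)
        perm = list(np.random.default_rng(1).permutation(D.index))
        t1 = upgma(D)
        t2 = upgma(D.loc[perm, perm])
        assert clades(t1) == clades(t2)

    def test_nan_rejected(self):
        D = pd.DataFrame([[0.0, np.nan], [np.nan, 0.0]], index=["A", "B"], columns=["A", "B"])
        with pytest.raises(ValueError):
            upgma(D)


def _two_group_incidence():
    """Two groups of 3 that differ at every locus."""
    rows, data = [], []
    for li in range(6):
        rows.append(((f"p{li}", "a"), 100))
        data.append([1, 1, 1, 0, 0, 0])
        rows.append(((f"p{li}", "a"), 110))
        data.append([0, 0, 0, 1, 1, 1])
    return AlleleIncidence(
        rows=tuple(rows),
        samples=("a1", "a2", "a3", "b1", "b2", "b3"),
        data=np.array(data, dtype=np.int8),
    )


class TestBootstrap:
    def test_group_split_supported_by_every_locus_has_support_100(self):
        inc = _two_group_incidence()
        cfg = DiversityConfig(n_bootstrap=100, seed=1)
        tree, consensus, supports = bootstrap_consensus(inc, cfg)
        assert supports.get(frozenset({"a1", "a2", "a3"})) == 100
        assert supports.get(frozenset({"b1", "b2", "b3"})) == 100
        assert frozenset({"a1", "a2", "a3"}) in clades(consensus)

    def test_single_replicate_supports_binary(self):
        inc = _two_group_incidence()
        cfg = DiversityConfig(n_bootstrap=1, seed=5)
        _, _, supports = bootstrap_consensus(inc, cfg)
        assert set(supports.values()) <= {0, 100}

    def test_seed_reproducibility(self):
        inc = _two_group_incidence()
        cfg = DiversityConfig(n_bootstrap=50, seed=9)
        r1 = bootstrap_consensus(inc, cfg)
        r2 = bootstrap_consensus(inc, cfg)
        assert r1[2] == r2[2]
        assert to_newick(r1[0]) == to_newick(r2[0])

    def test_locus_order_invariance(self):
        inc = _two_group_incidence()
        cfg = DiversityConfig(n_bootstrap=80, seed=3)
        _, _, s1 = bootstrap_consensus(inc, cfg)
        perm_rows = tuple(reversed(inc.rows))
        inc2 = AlleleIncidence(rows=perm_rows, samples=inc.samples, data=inc.data[::-1])
        _, _, s2 = bootstrap_consensus(inc2, cfg)
        # supports for the group clades must not depend on locus order
        key = frozenset({"a1", "a2", "a3"})
        assert s1[key] == s2[key] == 100

    def test_consensus_bipartition_count_bound(self):
        inc = _two_group_incidence()
        _, consensus, _ = bootstrap_consensus(inc, DiversityConfig(n_bootstrap=50, seed=2))
        n = len(inc.samples)
        assert len(clades(consensus)) <= n - 2

    def test_too_few_genotypes_or_loci_rejected(self):
        inc = _two_group_incidence()
        small = AlleleIncidence(rows=inc.rows[:2], samples=inc.samples, data=inc.data[:2])
        with pytest.raises(ValueError):
            bootstrap_consensus(small, DiversityConfig(n_bootstrap=5, seed=0))


class TestNewick:
    def test_parseable_with_supports_and_ultrametric_lengths(self):
        inc = _two_group_incidence()
        tree, consensus, _ = bootstrap_consensus(inc, DiversityConfig(n_bootstrap=20, seed=4))
        nwk = to_newick(tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert {l.taxon.label for l in parsed.leaf_node_iter()} == set(inc.samples)
        # root-to-leaf distances equal (ultrametric rendering)
        dists = [l.distance_from_root() for l in parsed.leaf_node_iter()]
        assert np.allclose(dists, dists[0], atol=1e-6)
        # consensus parses without branch lengths
        parsed2 = dendropy.Tree.get(
            data=to_newick(consensus, branch_lengths=False), schema="newick"
        )
        assert len(parsed2.leaf_nodes()) == 6


class TestIncidence:
    def test_rows_from_genotype_matrix(self):
        gm = GenotypeMatrix(
            entries={
                ("p1", "a"): {"s1": frozenset({150, 156}), "s2": frozenset({150})},
            }
        )
        inc = incidence_from_matrix(gm)
        assert inc.rows == ((("p1", "a"), 150), (("p1", "a"), 156))
        assert inc.data.tolist() == [[1, 1], [1, 0]]
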