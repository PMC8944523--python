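"""Alignment, Poisson distances, neighbor joining and bootstrap."""

import itertools
import math

import numpy as np
import pytest
import skbio

from genefamkit.phylo import (
    Msa,
    bipartitions,
    bootstrap_support,
    filter_by_identity,
    global_align,
    neighbor_joining,
    percent_identity,
    poisson_distance,
    progressive_align,
)


class TestGlobalAlign:
    def test_identical_sequences_100pct(self):
        a, b, ident = global_align("MKVLAG", "MKVLAG")
        assert ident == 100.0 and a == b == "MKVLAG"

    def test_half_identity_with_simple_scores(self):
        # exhaustive DP on 4-mers: best alignment is gapless, 2/4 matches
        _, _, ident = global_align("AAAA", "AATT", match=1, mismatch=-1,
                                   gap_open=5, gap_extend=5)
        assert ident == 50.0

    def test_symmetry(self):
        for a, b in [("MKVLAG", "MKVAG"), ("WCNQF", "WCQF")]:
            assert percent_identity(a, b) == pytest.approx(percent_identity(b, a))

    def test_empty_fails(self):
        with pytest.raises(ValueError):
            global_align("", "MKV")


class TestIdentityFilter:
    def test_identical_pair_kept(self):
        seqs = {"a": "MKVLAGWCNQF", "b": "MKVLAGWCNQF"}
        assert set(filter_by_identity(seqs)) == {"a", "b"}

    def test_singleton_retained(self):
        assert filter_by_identity({"only": "MKV"}) == {"only": "MKV"}

    def test_threshold_zero_keeps_all(self):
        seqs = {"a": "MKVLAG", "b": "WWWWWW", "c": "CCCCCC"}
        assert set(filter_by_identity(seqs, threshold=0.0)) == {"a", "b", "c"}

    def test_decoy_dropped_from_conserved_family(self, members):
        """A random decoy protein falls below 50% identity to every family
        member and is filtered out; the family survives."""
        rng = np.random.default_rng(4)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        decoy = "M" + "".join(aas[rng.integers(0, 20, 180)])
        seqs = {m.name: m.protein for m in members}
        seqs["decoy"] = decoy
        retained = filter_by_identity(seqs)
        assert "decoy" not in retained
        assert set(retained) == {m.name for m in members}


class TestProgressiveAlign:
    def test_identical_sequences_gap_free(self):
        seqs = {f"s{i}": "MKVLAGWCNQF" for i in range(3)}
        msa = progressive_align(seqs)
        assert all("-" not in row for row in msa.rows)

    def test_single_indel_recovered_as_one_gap_block(self):
        seqs = {"x": "MKLLVVAGHEW", "y": "MKLLVAGHEW"}
        msa = progressive_align(seqs)
        row_y = msa.rows[msa.names.index("y")]
        assert row_y.count("-") == 1
        assert msa.ungapped("x") == seqs["x"] and msa.ungapped("y") == seqs["y"]

    def test_ungapping_reproduces_inputs(self, members):
        seqs = {m.name: m.protein for m in members[:5]}
        msa = progressive_align(seqs)
        for name, seq in seqs.items():
            assert msa.ungapped(name) == seq

    def test_input_order_invariant_for_identical_triple(self):
        seqs = {"a": "MKVLA", "b": "MKVLA", "c": "MKVLA"}
        m1 = progressive_align(seqs)
        m2 = progressive_align(dict(reversed(list(seqs.items()))))
        assert sorted(m1.rows) == sorted(m2.rows)


class TestPoissonDistance:
    @pytest.mark.parametrize("p,expected", [(0.0, 0.0), (0.1, 0.10536), (0.5, 0.69315)])
    def test_closed_form(self, p, expected):
        n = 100
        n_diff = int(p * n)
        msa = Msa(["a", "b"], ["A" * n, "C" * n_diff + "A" * (n - n_diff)])
        dm = poisson_distance(msa)
        assert dm["a", "b"] == pytest.approx(expected, abs=1e-5)

    def test_gap_columns_excluded(self):
        msa = Msa(["a", "b"], ["AC-A", "ACG-"])
        assert poisson_distance(msa)["a", "b"] == 0.0

    def test_saturation_fails(self):
        msa = Msa(["a", "b"], ["AAAA", "CCCC"])
        with pytest.raises(ValueError):
            poisson_distance(msa)

    def test_poisson_at_least_p_distance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = 50
            row_a = "".join(rng.choice(list("ACDE"), n))
            row_b = "".join(rng.choice(list("ACDE"), n))
            p = sum(x != y for x, y in zip(row_a, row_b)) / n
            if p >= 1.0:
                continue
            d = poisson_distance(Msa(["a", "b"], [row_a, row_b]))["a", "b"]
            assert d >= p - 1e-12
            if p == 0:
                assert d == 0


def _random_additive_distances(n, rng):
    """Path-length distances of a random binary tree with positive branch
    lengths: the independent oracle for NJ recovery."""
    leaf_sets = {i: {i: 0.0} for i in range(n)}
    active = list(range(n))
    D = np.zeros((n, n))
    nxt = n
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[i], active[j]
        la, lb = rng.uniform(0.1, 1.0, 2)
        for l1, d1 in leaf_sets[a].items():
            for l2, d2 in leaf_sets[b].items():
                D[l1, l2] = D[l2, l1] = d1 + la + d2 + lb
        leaf_sets[nxt] = {l: d + la for l, d in leaf_sets[a].items()}
        leaf_sets[nxt].update({l: d + lb for l, d in leaf_sets[b].items()})
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return D


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d12, d13, d23 = 0.4, 0.6, 0.8
        dm = skbio.DistanceMatrix(
            [[0, d12, d13], [d12, 0, d23], [d13, 0.8, 0]], ids=["a", "b", "c"]
        )
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx((d12 + d13 - d23) / 2)
        assert lengths["b"] == pytest.approx((d12 + d23 - d13) / 2)
        assert lengths["c"] == pytest.approx((d13 + d23 - d12) / 2)

    def test_fewer_than_three_taxa_fails(self):
        dm = skbio.DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"])
        with pytest.raises(ValueError):
            neighbor_joining(dm)

    def test_additive_distances_recovered_exactly(self):
        """On additive distances NJ reproduces the generating tree's path
        lengths (random trees, n <= 8)."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(4, 9))
            D = _random_additive_distances(n, rng)
            names = [f"t{k}" for k in range(n)]
            tree = neighbor_joining(skbio.DistanceMatrix(D, ids=names))
            tips = {t.name: t for t in tree.tips()}
            for i, j in itertools.combinations(range(n), 2):
                assert tips[names[i]].distance(tips[names[j]]) == pytest.approx(
                    D[i, j], abs=1e-9
                )

    def test_taxon_order_invariant_topology(self):
        rng = np.random.default_rng(3)
        D = _random_additive_distances(6, rng)
        names = [f"t{k}" for k in range(6)]
        dm1 = skbio.DistanceMatrix(D, ids=names)
        perm = [3, 1, 5, 0, 4, 2]
        dm2 = skbio.DistanceMatrix(D[np.ix_(perm, perm)],
                                   ids=[names[k] for k in perm])
        assert bipartitions(neighbor_joining(dm1)) == bipartitions(
            neighbor_joining(dm2)
        )

    def test_matches_reference_nj_on_generic_matrix(self):
        """Cross-check against scikit-bio's NJ on a tie-free matrix."""
        rng = np.random.default_rng(11)
        M = rng.uniform(0.2, 1.0, (7, 7))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        dm = skbio.DistanceMatrix(M, ids=[f"s{k}" for k in range(7)])
        assert bipartitions(neighbor_joining(dm)) == bipartitions(skbio.tree.nj(dm))


@pytest.fixture()
def msa():
    return Msa(
        ["a", "b", "c", "d"],
        ["AAAAAAAAAA", "AAAAAAAAGG", "TTAAAAATTT", "TTAAAATTTT"],
    )


class TestBootstrap:

    def test_supports_within_range_and_deterministic(self, msa):
        _, sup1 = bootstrap_support(msa, replicates=100, seed=5)
        _, sup2 = bootstrap_support(msa, replicates=100, seed=5)
        assert sup1 == sup2
        assert all(0.0 <= v <= 100.0 for v in sup1.values())

    def test_clean_split_gets_full_support(self, msa):
        _, sup = bootstrap_support(msa, replicates=100, seed=1)
        assert sup[frozenset({"a", "b"})] == 100.0

    def test_zero_replicates_means_no_supports(self, msa):
        tree, sup = bootstrap_support(msa, replicates=0, seed=1)
        assert sup == {} and len(list(tree.tips())) == 4

    def test_needs_four_rows(self):
        msa = Msa(["a", "b", "c"], ["AAA", "AAC", "ACC"])
        with pytest.raises(ValueError):
            bootstrap_support(msa, replicates=10, seed=0)


def test_poisson_distance_symmetry_invariant():
    msa = Msa(["a", "b", "c"], ["AAAC", "AAAA", "AACA"])
    dm = poisson_distance(msa)
    arr = dm.data
    assert np.allclose(arr, arr.T) and np.allclose(np.diag(arr), 0)


def test_family_filter_keeps_members_above_threshold(members):
    """Synthetic family members share a template and stay above the 50%
    identity bar used before tree building."""
    seqs = {m.name: m.protein for m in members}
    assert set(filter_by_identity(seqs)) == set(seqs)
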