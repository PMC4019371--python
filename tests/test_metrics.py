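import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import mutual_info_score

from multitad import (
    Domain,
    DomainSet,
    entropy,
    hierarchy_score,
    hierarchy_significance,
    mutual_information,
    random_domain_set,
    shuffle_domain_set,
    to_partition,
    variation_of_information,
)
from multitad.exceptions import UndefinedScoreError
from multitad.metrics import IntervalPartition


def bin_labels(ds: DomainSet, L: int) -> np.ndarray:
    """Each block (domain or gap) of the induced partition gets its own label."""
    part = to_partition(ds, L)
    lab = np.empty(L, dtype=int)
    for idx, (a, b, _) in enumerate(part.blocks):
        lab[a : b + 1] = idx
    return lab


def vi_binlevel(ds1, ds2, L):
    """Independent oracle: per-bin labels + standard clustering comparison."""
    l1, l2 = bin_labels(ds1, L), bin_labels(ds2, L)

    def H(lab):
        _, counts = np.unique(lab, return_counts=True)
        p = counts / L
        return -np.sum(p * np.log(p))

    return H(l1) + H(l2) - 2.0 * mutual_info_score(l1, l2)


def random_set(L, rng, max_domains=6):
    k = int(rng.integers(0, max_domains + 1))
    if k == 0:
        return DomainSet(())
    try:
        return random_domain_set(L, k, 2, max(3, L // (2 * k)), rng)
    except Exception:
        return DomainSet(())


class TestPartition:
    def test_no_domains_single_gap(self):
        part = to_partition(DomainSet(()), 10)
        assert part.blocks == ((0, 9, False),)
        assert part.probabilities.tolist() == [1.0]

    def test_full_chromosome_domain(self):
        part = to_partition(DomainSet((Domain(0, 9),)), 10)
        assert part.blocks == ((0, 9, True),)

    def test_gaps_inserted(self):
        part = to_partition(DomainSet((Domain(2, 4), Domain(7, 9))), 12)
        assert part.blocks == (
            (0, 1, False),
            (2, 4, True),
            (5, 6, False),
            (7, 9, True),
            (10, 11, False),
        )

    def test_domain_beyond_length_rejected(self):
        with pytest.raises(ValueError):
            to_partition(DomainSet((Domain(2, 12),)), 10)

    def test_blocks_must_tile(self):
        with pytest.raises(ValueError):
            IntervalPartition(L=5, blocks=((0, 1, True), (3, 4, False)))


class TestEntropyAndMI:
    def test_single_block_zero_entropy(self):
        assert entropy(to_partition(DomainSet(()), 7)) == 0.0

    def test_two_equal_blocks(self):
        part = to_partition(DomainSet((Domain(0, 4),)), 10)
        assert entropy(part) == pytest.approx(np.log(2))

    def test_entropy_matches_direct_sum(self):
        rng = np.random.default_rng(3)
        ds = random_set(50, rng)
        part = to_partition(ds, 50)
        p = part.probabilities
        assert entropy(part) == pytest.approx(float(-(p * np.log(p)).sum()))

    def test_self_mi_is_entropy(self):
        rng = np.random.default_rng(4)
        ds = random_set(60, rng)
        part = to_partition(ds, 60)
        assert mutual_information(part, part) == pytest.approx(entropy(part))

    def test_single_block_zero_mi(self):
        rng = np.random.default_rng(5)
        p1 = to_partition(DomainSet(()), 40)
        p2 = to_partition(random_set(40, rng), 40)
        assert mutual_information(p1, p2) == pytest.approx(0.0, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mutual_information(
                to_partition(DomainSet(()), 4), to_partition(DomainSet(()), 5)
            )

    def test_mi_matches_bin_contingency_oracle(self):
        rng = np.random.default_rng(6)
        L = 80
        for _ in range(20):
            d1, d2 = random_set(L, rng), random_set(L, rng)
            got = mutual_information(to_partition(d1, L), to_partition(d2, L))
            expect = mutual_info_score(bin_labels(d1, L), bin_labels(d2, L))
            assert got == pytest.approx(expect, abs=1e-9)


class TestVariationOfInformation:
    def test_identity(self):
        rng = np.random.default_rng(7)
        ds = random_set(100, rng)
        assert variation_of_information(ds, ds, 100) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            d1, d2 = random_set(70, rng), random_set(70, rng)
            v12 = variation_of_information(d1, d2, 70)
            v21 = variation_of_information(d2, d1, 70)
            assert v12 == pytest.approx(v21)
            assert v12 >= 0.0

    def test_triangle_inequality(self):
        rng = np.random.default_rng(9)
        for _ in range(15):
            a, b, c = (random_set(60, rng) for _ in range(3))
            vab = variation_of_information(a, b, 60)
            vbc = variation_of_information(b, c, 60)
            vac = variation_of_information(a, c, 60)
            assert vac <= vab + vbc + 1e-9

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000), L=st.integers(20, 200))
    def test_matches_binlevel_oracle(self, seed, L):
        rng = np.random.default_rng(seed)
        d1, d2 = random_set(L, rng), random_set(L, rng)
        assert variation_of_information(d1, d2, L) == pytest.approx(
            vi_binlevel(d1, d2, L), abs=1e-9
        )


class TestHierarchyScore:
    def test_disjoint_pool_scores_zero(self):
        pool = [Domain(10 * i, 10 * i + 5) for i in range(6)]
        res = hierarchy_score(pool, alpha=0.1)
        assert res.h == 0.0

    def test_nested_chain_scores_one(self):
        pool = [Domain(10 * i, 159 - 20 * i) for i in range(5)]
        res = hierarchy_score(pool, alpha=0.1)
        assert res.h == 1.0
        assert res.pair_count == 10

    def test_alpha_filters_near_identical_pairs(self):
        # [0,99] vs [0,98]: difference fraction 1/100 <= 0.1 -> not counted;
        # adding a clearly different nested domain restores a qualifying pair
        pool = [Domain(0, 99), Domain(0, 98), Domain(10, 49)]
        res = hierarchy_score(pool, alpha=0.1)
        assert res.pair_count == 2  # (0,99)-(10,49) and (0,98)-(10,49)
        assert res.h == 1.0

    def test_bounded_and_order_invariant(self):
        rng = np.random.default_rng(10)
        pool = [tuple(d) for d in random_domain_set(200, 8, 2, 30, rng)]
        pool += [(5, 120), (30, 90)]
        r1 = hierarchy_score(pool, alpha=0.1)
        r2 = hierarchy_score(list(reversed(pool)), alpha=0.1)
        assert 0.0 <= r1.h <= 1.0
        assert r1.h == r2.h and r1.pair_count == r2.pair_count

    def test_too_few_domains_undefined(self):
        with pytest.raises(UndefinedScoreError):
            hierarchy_score([Domain(0, 5)], alpha=0.1)

    def test_only_similar_nested_pairs_undefined(self):
        with pytest.raises(UndefinedScoreError):
            hierarchy_score([Domain(0, 99), Domain(0, 98)], alpha=0.1)

    def test_subsampling_is_seeded_and_reproducible(self):
        rng = np.random.default_rng(11)
        pool = [tuple(d) for d in random_domain_set(2000, 40, 2, 30, rng)]
        pool += [(i, i + 100) for i in range(0, 300, 17)]
        full = hierarchy_score(pool, alpha=0.1)
        s1 = hierarchy_score(pool, alpha=0.1, max_pairs=200, seed=3)
        s2 = hierarchy_score(pool, alpha=0.1, max_pairs=200, seed=3)
        assert s1.h == s2.h
        assert s1.pair_count <= full.pair_count
        assert abs(s1.h - full.h) < 0.35  # subsample estimates the same quantity


class TestShuffle:
    def test_length_multisets_preserved(self):
        rng = np.random.default_rng(12)
        for seed in range(10):
            ds = random_domain_set(80, 5, 2, 10, rng)
            sh = shuffle_domain_set(ds, 80, seed=seed)
            assert sorted(d.n_bins for d in sh) == sorted(d.n_bins for d in ds)

            def gap_lengths(s):
                gaps, pos = [], 0
                for d in s:
                    gaps.append(d.a - pos)
                    pos = d.b + 1
                gaps.append(80 - pos)
                return sorted(gaps)

            assert gap_lengths(sh) == gap_lengths(ds)

    def test_deterministic_given_seed(self):
        ds = DomainSet((Domain(0, 5), Domain(10, 30), Domain(40, 49)))
        a = shuffle_domain_set(ds, 60, seed=5)
        b = shuffle_domain_set(ds, 60, seed=5)
        assert a.domains == b.domains

    def test_single_domain_keeps_length(self):
        ds = DomainSet((Domain(3, 9),))
        sh = shuffle_domain_set(ds, 50, seed=1)
        assert len(sh) == 1
        assert sh[0].n_bins == 7

    def test_empty_set(self):
        assert shuffle_domain_set(DomainSet(()), 30, seed=0).domains == ()


class TestSignificance:
    def _nested_solutions(self):
        # three solutions whose pool is strongly nested (observed h = 1)
        return [
            DomainSet((Domain(0, 159),)),
            DomainSet((Domain(10, 139),)),
            DomainSet((Domain(20, 119),)),
        ]

    def test_pvalue_bounds_and_addone_formula(self):
        res = hierarchy_significance(
            {"chr1": self._nested_solutions()}, L=200, replicates=19, seed=0
        )["chr1"]
        assert res.h == 1.0
        assert len(res.null_scores) == 19
        expect = (1 + np.sum(res.null_scores >= res.h)) / 20
        assert res.p_value == pytest.approx(expect)
        assert 0 < res.p_value <= 1

    def test_bh_adjustment_matches_hand_computation(self):
        pools = {f"chr{i}": self._nested_solutions() for i in (1, 2, 3)}
        out = hierarchy_significance(pools, L=200, replicates=9, seed=1)
        pvals = np.array([out[c].p_value for c in out])
        m = len(pvals)
        order = np.argsort(pvals)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, pvals[i] * m / (rank_idx + 1))
            adj[i] = running
        got = np.array([out[c].p_adjusted for c in out])
        np.testing.assert_allclose(got, adj)

    def test_replicates_must_be_positive(self):
        with pytest.raises(ValueError):
            hierarchy_significance(
                {"chr1": self._nested_solutions()}, L=200, replicates=0
            )
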