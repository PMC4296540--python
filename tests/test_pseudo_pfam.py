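"""Pseudo-Pfam permutation test: sampling, null building, P-values."""

import itertools

import numpy as np
import pytest

from pfamdiff import (
    PfamTargetList,
    SamplingPool,
    aggregate_communities,
    build_sampling_pool,
    observed_difference,
    permutation_null,
    pseudo_pfam_pvalue,
    run_pseudo_pfam_test,
    sample_pseudo_pfam,
)
from pfamdiff.catalog_io import PfamTarget


def pool(values, cid="c"):
    return SamplingPool(community_id=cid, values=np.array(values, dtype=float))


def enumerate_null(values_a, values_b, n_a, n_b):
    """Exhaustive pseudo-difference distribution for tiny pools: every
    unordered subset pair, equally likely (the independent oracle)."""
    sums_a = [sum(c) for c in itertools.combinations(values_a, n_a)] or [0.0]
    sums_b = [sum(c) for c in itertools.combinations(values_b, n_b)] or [0.0]
    return np.array([a - b for a in sums_a for b in sums_b])


class TestObservedDifference:
    @pytest.mark.parametrize("pa,pb,d", [(4, 4, 0), (5, 2, 3), (0, 2, -2)])
    def test_signed_difference(self, pa, pb, d):
        assert observed_difference(pa, pb) == d


class TestSamplePseudoPfam:
    def test_forced_and_exhaustive_draws(self, rng):
        assert sample_pseudo_pfam(pool([0.2]), 1, rng) == pytest.approx(0.2)
        assert sample_pseudo_pfam(pool([1, 2, 3]), 3, rng) == pytest.approx(6.0)
        assert sample_pseudo_pfam(pool([1, 2, 3]), 0, rng) == 0.0

    def test_oversized_group_rejected_with_capping_hint(self, rng):
        with pytest.raises(ValueError, match="cap"):
            sample_pseudo_pfam(pool([1, 2]), 3, rng)

    def test_pairs_drawn_uniformly(self, rng):
        # pool {1,2,3}, n=2: sums 3/4/5 each with probability 1/3
        draws = np.array(
            [sample_pseudo_pfam(pool([1, 2, 3]), 2, rng) for _ in range(3000)]
        )
        freqs = np.array([(draws == s).mean() for s in (3, 4, 5)])
        assert freqs.sum() == 1.0
        se = np.sqrt((1 / 3) * (2 / 3) / 3000)
        assert np.all(np.abs(freqs - 1 / 3) < 4 * se)


class TestPermutationNull:
    def test_identical_singleton_pools_give_zero(self, rng):
        null = permutation_null(pool([5.0]), pool([5.0]), 1, 1, 50, rng)
        assert np.all(null == 0.0)

    def test_requested_length(self, rng):
        null = permutation_null(pool([1, 2, 3]), pool([1, 2]), 1, 1, 10_000, rng)
        assert null.shape == (10_000,)

    def test_matches_exhaustive_enumeration(self, rng):
        # pools {1,2,3} vs {1,2,3}, n=1 each: 9 ordered pairs,
        # D in {0,+-1,+-2} with probabilities {3,2,2,1,1}/9
        null = permutation_null(pool([1, 2, 3]), pool([1, 2, 3]), 1, 1, 9000, rng)
        expected = {0: 3 / 9, 1: 2 / 9, -1: 2 / 9, 2: 1 / 9, -2: 1 / 9}
        for d, prob in expected.items():
            freq = (null == d).mean()
            se = np.sqrt(prob * (1 - prob) / 9000)
            assert abs(freq - prob) < 4 * se


class TestPseudoPfamPvalue:
    def test_add_one_smoothing(self):
        null = enumerate_null([1, 2, 3], [1, 2, 3], 1, 1)  # 9 outcomes
        assert pseudo_pfam_pvalue(2.0, null) == pytest.approx(2 / 10)

    def test_symmetric_null_at_zero_at_least_half(self):
        null = np.array([-2, -1, -1, 0, 0, 0, 1, 1, 2], dtype=float)
        assert pseudo_pfam_pvalue(0.0, null) >= 0.5

    def test_never_exactly_zero_or_above_one(self):
        null = np.zeros(10_000)
        assert pseudo_pfam_pvalue(1e9, null) == pytest.approx(1 / 10_001)
        assert pseudo_pfam_pvalue(-1e9, null) == 1.0

    def test_monotone_nonincreasing_in_signed_difference(self, rng):
        null = rng.normal(size=5000)
        ps = [pseudo_pfam_pvalue(d, null) for d in np.linspace(-3, 3, 25)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


def _two_community_setup(small_catalog):
    catalogs, counts = small_catalog
    aggregates, sf, norm = aggregate_communities(catalogs, counts)
    pools = {
        cid: build_sampling_pool(catalogs[cid], norm[cid], sf[cid], cid)
        for cid in catalogs
    }
    return aggregates, pools


class TestRunPseudoPfamTest:
    targets = PfamTargetList(
        [
            PfamTarget("PF00001", "F1", "GH"),
            PfamTarget("PF00002", "F2", "GH"),
            PfamTarget("PF00003", "F3", "GH"),
            PfamTarget("PF00099", "F99", "GH"),
        ]
    )

    def test_undetected_family_flagged(self, small_catalog):
        aggregates, pools = _two_community_setup(small_catalog)
        results = {
            r.pfam: r
            for r in run_pseudo_pfam_test(
                aggregates, pools, self.targets, reps=200, n_runs=2, seed=3
            )
        }
        assert not results["PF00099"].detected  # absent from both catalogs
        assert results["PF00099"].p_values == []
        # PF00003 is annotated (community B) but has zero expression in
        # both communities -> equally "not detected"
        assert not results["PF00003"].detected
        assert results["PF00001"].detected
        assert len(results["PF00001"].p_values) == 2
        assert results["PF00001"].p_mean == pytest.approx(
            np.mean(results["PF00001"].p_values)
        )

    def test_same_seed_reproduces_bit_exactly(self, small_catalog):
        aggregates, pools = _two_community_setup(small_catalog)
        r1 = run_pseudo_pfam_test(aggregates, pools, self.targets,
                                  reps=500, n_runs=3, seed=42)
        r2 = run_pseudo_pfam_test(aggregates, pools, self.targets,
                                  reps=500, n_runs=3, seed=42)
        assert [(r.pfam, r.p_values) for r in r1] == [
            (r.pfam, r.p_values) for r in r2
        ]

    def test_direction_flip_reverses_tail(self, small_catalog):
        aggregates, pools = _two_community_setup(small_catalog)
        kw = dict(reps=4000, n_runs=1, seed=7)
        toward_b = {
            r.pfam: r for r in run_pseudo_pfam_test(
                aggregates, pools, self.targets, overexpressed_in="B", **kw)
        }
        toward_a = {
            r.pfam: r for r in run_pseudo_pfam_test(
                aggregates, pools, self.targets, overexpressed_in="A", **kw)
        }
        for pf in ("PF00001", "PF00002"):
            assert toward_b[pf].D_obs == pytest.approx(-toward_a[pf].D_obs)
            # tails complement up to the Monte-Carlo tie mass at D_obs
            assert toward_b[pf].p_mean + toward_a[pf].p_mean >= 1.0

    def test_production_path_matches_enumeration_oracle(self, small_catalog):
        """Shared-permutation prefix sums agree with the exhaustively
        enumerated null probability for every family."""
        aggregates, pools = _two_community_setup(small_catalog)
        reps = 10_000
        results = {
            r.pfam: r
            for r in run_pseudo_pfam_test(
                aggregates, pools, self.targets, reps=reps, n_runs=1, seed=11,
                overexpressed_in="B",
            )
        }
        agg = {(a.community_id, a.pfam): a for a in aggregates}
        for pf in ("PF00001", "PF00002"):
            n_a = agg[("A", pf)].n_expressed
            n_b = agg[("B", pf)].n_expressed if ("B", pf) in agg else 0
            null = enumerate_null(
                pools["B"].values, pools["A"].values, n_b, n_a
            )
            d = results[pf].D_obs
            exact = (null >= d).mean()
            se = np.sqrt(max(exact * (1 - exact), 1e-9) / reps)
            assert abs(results[pf].p_mean - exact) < 3 * se + 2 / reps
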