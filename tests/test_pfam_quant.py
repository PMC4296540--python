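"""Length normalization, collation, size factors (median of ratios)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pfamdiff import (
    EstimationError,
    aggregate_communities,
    collate_by_pfam,
    collate_raw_counts,
    compute_size_factors,
    length_normalize,
    normalize_pfam_expression,
)

from conftest import make_counts, make_gene


class TestLengthNormalize:
    @pytest.mark.parametrize(
        "count,length,expected", [(300, 1500, 0.2), (0, 777, 0.0), (120, 600, 0.2)]
    )
    def test_reads_per_nucleotide(self, count, length, expected):
        catalog = [make_gene("g", length)]
        norm = length_normalize(catalog, make_counts("c", {"g": count}))
        assert norm["g"] == pytest.approx(expected)

    def test_gene_missing_from_count_table_is_zero(self):
        catalog = [make_gene("g1"), make_gene("g2")]
        norm = length_normalize(catalog, make_counts("c", {"g1": 10}))
        assert norm["g2"] == 0.0


class TestCollate:
    def test_multi_annotated_gene_counts_fully_in_each_family(self):
        catalog = [
            make_gene("g1", 1000, {"X"}),
            make_gene("g2", 1000, {"X", "Y"}),
            make_gene("g3", 1000, set()),
        ]
        norm = {"g1": 0.2, "g2": 0.3, "g3": 0.5}
        collated = collate_by_pfam(norm, catalog)
        assert collated["X"][0] == pytest.approx(0.5)
        assert collated["Y"][0] == pytest.approx(0.3)
        assert set(collated) == {"X", "Y"}  # unannotated g3 nowhere

    def test_n_expressed_counts_only_nonzero_genes(self):
        catalog = [make_gene("g1", 1000, {"X"}), make_gene("g2", 1000, {"X"})]
        collated = collate_by_pfam({"g1": 0.1, "g2": 0.0}, catalog)
        assert collated["X"] == (pytest.approx(0.1), 1)

    def test_all_unannotated_gives_empty_map(self):
        catalog = [make_gene("g1"), make_gene("g2")]
        assert collate_by_pfam({"g1": 1.0, "g2": 2.0}, catalog) == {}

    def test_additive_over_disjoint_gene_sets(self, rng):
        genes = [
            make_gene(f"g{i}", 500 + i, {f"PF{i % 3}"}) for i in range(12)
        ]
        norm = {g.gene_id: float(v) for g, v in zip(genes, rng.random(12))}
        whole = collate_by_pfam(norm, genes)
        part1 = collate_by_pfam(norm, genes[:5])
        part2 = collate_by_pfam(norm, genes[5:])
        for pf in whole:
            assert whole[pf][0] == pytest.approx(
                part1.get(pf, (0, 0))[0] + part2.get(pf, (0, 0))[0]
            )
            assert whole[pf][1] == part1.get(pf, (0, 0))[1] + part2.get(pf, (0, 0))[1]

    def test_raw_count_collation_matches_rules(self):
        catalog = [
            make_gene("g1", 1000, {"X"}),
            make_gene("g2", 1000, {"X", "Y"}),
            make_gene("g3", 1000, set()),
        ]
        counts = make_counts("c", {"g1": 5, "g2": 7, "g3": 100})
        raw = collate_raw_counts(counts, catalog)
        assert raw == {"X": 12, "Y": 7}


class TestSizeFactors:
    def test_constant_fourfold_depth_difference(self):
        sf = compute_size_factors(
            {"A": {"p1": 2, "p2": 2, "p3": 2}, "B": {"p1": 8, "p2": 8, "p3": 8}}
        )
        assert sf["A"] == 0.5 and sf["B"] == 2.0
        assert sf["A"] * sf["B"] == 1.0

    def test_identical_communities_give_unit_factors(self):
        t = {"p1": 3.0, "p2": 7.0, "p3": 11.0}
        sf = compute_size_factors({"A": dict(t), "B": dict(t)})
        assert sf["A"] == 1.0 and sf["B"] == 1.0

    def test_median_ratio_one_for_antisymmetric_profile(self):
        sf = compute_size_factors(
            {"A": {"p1": 2, "p2": 8, "p3": 4}, "B": {"p1": 8, "p2": 2, "p3": 4}}
        )
        assert sf["A"] == 1.0 and sf["B"] == 1.0

    def test_zero_in_one_community_excluded_from_median(self):
        base = {"A": {"p1": 2, "p2": 2, "p3": 2}, "B": {"p1": 8, "p2": 8, "p3": 8}}
        with_zero = {
            "A": {**base["A"], "p4": 5.0},
            "B": {**base["B"], "p4": 0.0},
        }
        assert compute_size_factors(with_zero).factors == compute_size_factors(
            base
        ).factors

    def test_no_common_family_raises(self):
        with pytest.raises(EstimationError):
            compute_size_factors({"A": {"p1": 1.0, "p2": 0.0},
                                  "B": {"p1": 0.0, "p2": 1.0}})

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        p=st.lists(
            st.tuples(
                st.floats(0.01, 1e6, allow_nan=False),
                st.floats(0.01, 1e6, allow_nan=False),
            ),
            min_size=3,
            max_size=15,
        ).filter(lambda v: len(v) % 2 == 1)
    )
    def test_two_community_reciprocal_identity_within_ulps(self, p):
        """Odd family count: medians select one reciprocal ratio pair, so
        S_A*S_B sits within a few ulp of 1 (exactly 1 on dyadic inputs)."""
        sf = compute_size_factors(
            {"A": {f"p{i}": a for i, (a, _) in enumerate(p)},
             "B": {f"p{i}": b for i, (_, b) in enumerate(p)}}
        )
        prod = sf["A"] * sf["B"]
        assert abs(prod - 1.0) <= 4 * math.ulp(1.0)


class TestNormalizedExpression:
    def test_division_by_size_factor(self):
        tables = {"A": {"p1": (2.0, 1)}, "B": {"p1": (8.0, 2)}}
        sf = compute_size_factors({"A": {"p1": 2.0}, "B": {"p1": 8.0}})
        aggs = normalize_pfam_expression(tables, sf)
        by = {(a.community_id, a.pfam): a for a in aggs}
        assert by[("A", "p1")].P_norm == pytest.approx(2.0 / sf["A"])
        assert by[("B", "p1")].P_norm == pytest.approx(8.0 / sf["B"])

    def test_depth_difference_removed(self):
        # constant 4x depth: after size normalization both communities match
        tables = {
            "A": {f"p{i}": (2.0, 1) for i in range(3)},
            "B": {f"p{i}": (8.0, 1) for i in range(3)},
        }
        sf = compute_size_factors(
            {c: {pf: v[0] for pf, v in t.items()} for c, t in tables.items()}
        )
        aggs = normalize_pfam_expression(tables, sf)
        values = {(a.community_id, a.pfam): a.P_norm for a in aggs}
        for i in range(3):
            assert values[("A", f"p{i}")] == pytest.approx(values[("B", f"p{i}")])

    def test_uniform_scaling_leaves_fold_changes_unchanged(self, small_catalog):
        catalogs, counts = small_catalog
        aggs, sf, _ = aggregate_communities(catalogs, counts)
        scaled = {
            "A": counts["A"],
            "B": type(counts["B"])(
                community_id="B",
                counts={g: 7 * c for g, c in counts["B"].counts.items()},
            ),
        }
        aggs2, sf2, _ = aggregate_communities(catalogs, scaled)
        P1 = {(a.community_id, a.pfam): a.P_norm for a in aggs}
        P2 = {(a.community_id, a.pfam): a.P_norm for a in aggs2}
        # both communities' P vectors rescale together: ratios and D-signs hold
        for pf in {pf for _, pf in P1}:
            a1, b1 = P1.get(("A", pf), 0.0), P1.get(("B", pf), 0.0)
            a2, b2 = P2.get(("A", pf), 0.0), P2.get(("B", pf), 0.0)
            if a1 > 0 and b1 > 0:
                assert (a2 / b2) == pytest.approx(a1 / b1, rel=1e-12)
            assert np.sign(a2 - b2) == np.sign(a1 - b1)
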