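"""Distance binning, pair labelling, stratified tests and enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cld.enrichment import (
    DISCARDED,
    IN_INTERACTION,
    LONGEST_HUMAN_CHROM,
    NOT_IN_INTERACTION,
    StratifiedCounts,
    assign_distance_bin,
    cutoff_ratio_curve,
    distance_bins,
    fisher_exact,
    hypergeom_enrichment,
    label_pairs,
    mantel_haenszel,
    matched_ld_sample,
    stratified_counts,
)
from cld.haplotype_io import Region, RegionSet


class TestDistanceBins:
    def test_geometric_progression_closed_form(self):
        edges = distance_bins()
        assert len(edges) == 13
        assert edges[0] == 35_000
        assert edges[-1] == 35_000 * 2**12 == 143_360_000
        np.testing.assert_allclose(edges[1:] / edges[:-1], 2.0)

    def test_top_edge_below_longest_chromosome(self):
        assert distance_bins()[-1] <= LONGEST_HUMAN_CHROM

    def test_membership(self):
        edges = distance_bins()
        assert assign_distance_bin(100_000, edges) == 2  # (70k, 140k]
        assert assign_distance_bin(35_000, edges) == 0
        assert assign_distance_bin(1e9, edges) == -1

    def test_validation(self):
        with pytest.raises(ValueError):
            distance_bins(first_edge=0)
        with pytest.raises(ValueError):
            distance_bins(ratio=1.0)


def demo_regions():
    return RegionSet(
        [
            Region("chr1", 0, 10_000, "G0"),
            Region("chr1", 50_000, 60_000, "G1"),
            Region("chr1", 200_000, 210_000, "G2"),
            Region("chr1", 500_000, 510_000, "G3"),
        ]
    )


def demo_pairs():
    rows = []
    for a, b in itertools.combinations(["G0", "G1", "G2", "G3"], 2):
        rows.append(
            {"region_a": a, "region_b": b, "r2": 0.1, "defined": True}
        )
    return pd.DataFrame(rows)


class TestLabelPairs:
    def test_labelling_rules(self):
        regions = demo_regions()
        anchors = [("chr1", 0, 11_000), ("chr1", 49_000, 61_000)]  # G0, G1 in
        out = label_pairs(demo_pairs(), regions, anchors)
        lab = dict(zip(zip(out["region_a"], out["region_b"]), out["label"]))
        assert lab[("G0", "G1")] == IN_INTERACTION
        assert lab[("G2", "G3")] == NOT_IN_INTERACTION
        assert lab[("G0", "G2")] == DISCARDED  # exactly one gene in

    def test_empty_anchor_list(self):
        out = label_pairs(demo_pairs(), demo_regions(), [])
        assert (out["label"] == NOT_IN_INTERACTION).all()

    def test_midpoint_distance(self):
        out = label_pairs(demo_pairs(), demo_regions(), [])
        row = out[(out["region_a"] == "G0") & (out["region_b"] == "G1")].iloc[0]
        assert row["distance"] == pytest.approx(55_000 - 5_000)

    def test_one_bp_overlap_counts(self):
        regions = demo_regions()
        anchors = [("chr1", 9_999, 10_000)]  # overlaps G0 by exactly 1 bp
        out = label_pairs(demo_pairs(), regions, anchors)
        row = out[(out["region_a"] == "G0") & (out["region_b"] == "G1")].iloc[0]
        assert row["label"] == DISCARDED


class TestStratifiedCounts:
    def test_hand_counted_table(self):
        p = pd.DataFrame(
            {
                "region_a": list("aabb"),
                "region_b": list("cdcd"),
                "distance": [50_000] * 4,
                "label": [IN_INTERACTION, IN_INTERACTION,
                          NOT_IN_INTERACTION, NOT_IN_INTERACTION],
                "statistic": [3.0, 4.0, 1.0, 2.0],
            }
        )
        t = stratified_counts(p, distance_bins())
        assert len(t.tables) == 1
        # median cutoff 2.5: in-pairs {3,4} above, not-in {1,2} below
        np.testing.assert_array_equal(t.tables[0], [[2, 0], [0, 2]])
        assert t.cutoffs[0] == pytest.approx(2.5)

    def test_marginals_match_rows(self, rng):
        n = 200
        p = pd.DataFrame(
            {
                "region_a": [f"a{i}" for i in range(n)],
                "region_b": [f"b{i}" for i in range(n)],
                "distance": rng.uniform(10_000, 1e8, n),
                "label": rng.choice([IN_INTERACTION, NOT_IN_INTERACTION], n),
                "statistic": rng.random(n),
            }
        )
        t = stratified_counts(p, distance_bins())
        total = sum(tab.sum() for tab in t.tables)
        edges = distance_bins()
        in_range = p[p["distance"] <= edges[-1]]
        binned = np.searchsorted(edges, in_range["distance"].to_numpy(), side="left")
        dropped_bins = {lab for lab in t.dropped}
        # counts conserve all non-dropped rows
        kept = 0
        for k in range(len(edges)):
            lab = f"({0 if k == 0 else edges[k - 1]:.0f}, {edges[k]:.0f}]"
            if lab not in dropped_bins:
                kept += int((binned == k).sum())
        assert total == kept

    def test_all_strata_dropped_raises(self):
        p = pd.DataFrame(
            {
                "region_a": ["a"],
                "region_b": ["b"],
                "distance": [50_000.0],
                "label": [IN_INTERACTION],
                "statistic": [0.5],
            }
        )
        with pytest.raises(ValueError):
            stratified_counts(p, distance_bins())


class TestMantelHaenszel:
    def test_single_stratum_closed_form(self):
        t = StratifiedCounts([np.array([[10, 2], [2, 10]])], ["s"], [0.0])
        res = mantel_haenszel(t)
        assert res.odds_ratio == pytest.approx(25.0)
        assert res.p_value < 0.05

    def test_null_strata(self):
        tables = [np.array([[20, 20], [20, 20]]), np.array([[5, 5], [5, 5]])]
        res = mantel_haenszel(
            StratifiedCounts(tables, ["a", "b"], [0, 0]), correction=False
        )
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_permutation_null_uniform_pvalues(self, rng):
        """Under label permutation the MH p-value is ~Uniform(0,1)."""
        n = 400
        stat = rng.random(n)
        dist = rng.uniform(10_000, 5e6, n)
        pvals = []
        for _ in range(300):
            labels = rng.permutation(
                [IN_INTERACTION] * (n // 2) + [NOT_IN_INTERACTION] * (n // 2)
            )
            p = pd.DataFrame(
                {
                    "region_a": [f"a{i}" for i in range(n)],
                    "region_b": [f"b{i}" for i in range(n)],
                    "distance": dist,
                    "label": labels,
                    "statistic": stat,
                }
            )
            t = stratified_counts(p, distance_bins())
            pvals.append(mantel_haenszel(t, correction=False).p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestFisherExact:
    def test_empty_table(self):
        assert fisher_exact(np.zeros((2, 2), dtype=int)) == 1.0

    def test_diagonal_table_exact_value(self):
        # [[5,0],[0,5]]: 2/C(10,5) = 2/252
        assert fisher_exact(np.array([[5, 0], [0, 5]])) == pytest.approx(2 / 252)

    def test_matches_enumeration_small_tables(self, rng):
        """Exhaustive hypergeometric enumeration oracle, totals <= 20."""

        def enumerate_p(table):
            a, b = table[0]
            c, d = table[1]
            r1, r2 = a + b, c + d
            c1 = a + c
            n = r1 + r2
            obs = math.comb(r1, a) * math.comb(r2, c) / math.comb(n, c1)
            total = 0.0
            for x in range(max(0, c1 - r2), min(r1, c1) + 1):
                p = math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
                if p <= obs * (1 + 1e-9):
                    total += p
            return total

        for _ in range(150):
            table = rng.integers(0, 6, size=(2, 2))
            if table.sum() == 0 or table.sum() > 20:
                continue
            assert fisher_exact(table) == pytest.approx(
                enumerate_p(table), abs=1e-10
            )


class TestCutoffRatioCurve:
    def test_null_normalized_ratio_near_one(self, rng):
        n = 4000
        p = pd.DataFrame(
            {
                "label": rng.choice([IN_INTERACTION, NOT_IN_INTERACTION], n),
                "statistic": rng.random(n),
                "distance": np.ones(n),
                "region_a": "a",
                "region_b": "b",
            }
        )
        out = cutoff_ratio_curve(p, [0.1, 0.5, 0.9])
        assert np.allclose(out["ratio_normalized"], 1.0, atol=0.25)

    def test_separated_classes_give_inf(self):
        p = pd.DataFrame(
            {
                "label": [IN_INTERACTION] * 3 + [NOT_IN_INTERACTION] * 3,
                "statistic": [0.9, 0.8, 0.85, 0.1, 0.2, 0.15],
                "distance": 1.0,
                "region_a": "a",
                "region_b": "b",
            }
        )
        out = cutoff_ratio_curve(p, [0.5])
        assert np.isinf(out["ratio_raw"].iloc[0])

    def test_stochastically_larger_class_monotone_trend(self, rng):
        n = 3000
        labels = np.array([IN_INTERACTION] * n + [NOT_IN_INTERACTION] * n)
        stat = np.concatenate([rng.beta(3, 2, n), rng.beta(2, 3, n)])
        p = pd.DataFrame(
            {"label": labels, "statistic": stat, "distance": 1.0,
             "region_a": "a", "region_b": "b"}
        )
        cutoffs = [0.2, 0.4, 0.6, 0.8]
        out = cutoff_ratio_curve(p, cutoffs)
        ratios = out["ratio_normalized"].to_numpy()
        assert (ratios > 1).all()
        assert (np.diff(ratios) > -0.05).all()  # non-decreasing trend

    def test_unsorted_cutoffs_rejected(self):
        p = pd.DataFrame(
            {"label": [IN_INTERACTION], "statistic": [0.5], "distance": [1.0],
             "region_a": ["a"], "region_b": ["b"]}
        )
        with pytest.raises(ValueError):
            cutoff_ratio_curve(p, [0.5, 0.1])


class TestMatchedLDSample:
    def test_brute_force_matching(self, rng):
        from cld.simulation import make_fixture
        from cld.core_stats import pairwise_cld

        H, R, _ = make_fixture(
            n_hap=100, n_regions=4, variants_per_region=6,
            maf_low=0.02, maf_high=0.1, seed=21,
        )
        pairs = pairwise_cld(H, R)
        regions = list(R)
        anchors = [(regions[0].chrom, regions[0].start, regions[1].end)]
        labelled = label_pairs(pairs, R, anchors)
        out = matched_ld_sample(labelled, H, R, n_pairs=50, seed=3)
        assert len(out) > 0
        # every matched distance is the nearest-achievable distance
        pool = labelled[labelled["label"] == NOT_IN_INTERACTION]
        pool_d = []
        coords = {r.name: r for r in R}
        for _, row in pool.iterrows():
            ca = H.columns_in(coords[row["region_a"]])
            cb = H.columns_in(coords[row["region_b"]])
            for i in ca:
                for j in cb:
                    pool_d.append(abs(H.variants[i].pos0 - H.variants[j].pos0))
        pool_d = np.array(sorted(pool_d))
        for _, row in out.iterrows():
            best = np.min(np.abs(pool_d - row["distance_in"]))
            assert abs(row["distance_matched"] - row["distance_in"]) == pytest.approx(
                best
            )

    def test_pool_of_one_candidate(self):
        from cld.simulation import make_fixture
        from cld.core_stats import pairwise_cld

        H, R, _ = make_fixture(
            n_hap=60, n_regions=3, variants_per_region=1,
            maf_low=0.05, maf_high=0.2, seed=4,
        )
        pairs = pairwise_cld(H, R)
        regions = list(R)
        # G0,G1 in interaction; only pair (G1,G2)? no: one-in pairs discarded,
        # leaving (G2, x) none. Use anchors covering G0 and G1 -> pool = none.
        # Instead anchor covers nothing -> no labelled pairs -> error.
        labelled = label_pairs(pairs, R, [])
        with pytest.raises(ValueError):
            matched_ld_sample(labelled, H, R)


class TestHypergeomEnrichment:
    def test_exact_small_case(self):
        universe = {f"g{i}" for i in range(10)}
        database = {f"g{i}" for i in range(5)}
        selected = set(database)
        res = hypergeom_enrichment(selected, database, universe)
        assert (res.q, res.m, res.n, res.k) == (5, 5, 5, 5)
        assert res.p_value == pytest.approx(1 / 252)

    def test_full_overlap_minimal_p(self):
        universe = {f"g{i}" for i in range(20)}
        database = {f"g{i}" for i in range(10)}
        res = hypergeom_enrichment(database, database, universe)
        assert res.q == res.m
        assert res.p_value == pytest.approx(
            1 / math.comb(20, 10), rel=1e-9
        )

    def test_expected_overlap_moderate_p(self, rng):
        universe = {f"g{i}" for i in range(100)}
        database = {f"g{i}" for i in range(50)}
        selected = {f"g{i}" for i in range(30, 70)}  # overlap 20 = k*m/(m+n)
        res = hypergeom_enrichment(selected, database, universe)
        assert 0.2 < res.p_value < 0.8

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(set(), set(), set())


def test_permutation_rejection_rate_both_tests(rng):
    """Under label permutation, MH and Fisher reject at ~alpha."""
    n = 600
    stat = rng.random(n)
    mh_rej = 0
    fi_rej = 0
    reps = 500
    for _ in range(reps):
        dist = rng.uniform(1e5, 1e6, n)
        labels = rng.permutation(
            [IN_INTERACTION] * (n // 2) + [NOT_IN_INTERACTION] * (n // 2)
        )
        p = pd.DataFrame(
            {
                "region_a": [f"a{i}" for i in range(n)],
                "region_b": [f"b{i}" for i in range(n)],
                "distance": dist,
                "label": labels,
                "statistic": stat,
            }
        )
        t = stratified_counts(p, distance_bins())
        if mantel_haenszel(t, correction=False).p_value < 0.05:
            mh_rej += 1
        pooled = np.sum(t.tables, axis=0)
        if fisher_exact(pooled) < 0.05:
            fi_rej += 1
    assert abs(mh_rej / reps - 0.05) <= 0.02
    assert abs(fi_rej / reps - 0.05) <= 0.02
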