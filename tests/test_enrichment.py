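"""Hypergeometric/interval enrichment, superenhancers, coverage rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiretina.enrichment import (
    call_superenhancers,
    coverage_overlap_fraction,
    covered_at_least_half,
    define_direct_targets,
    hypergeometric_enrichment,
    interval_feature_enrichment,
    motif_occurrence_summary,
    rose_cutoff_index,
    two_factor_partition,
)
from epiretina.genome import (
    GeneModel,
    GenomeAnnotation,
    Interval,
    ReadIndex,
    ReadLibrary,
)
from epiretina.peaks import Peak, PeakSet


class TestHypergeometric:
    def test_exact_enumeration_example(self):
        # universe 10, category 5, cluster 4, observed 4:
        # expected 2.0, ratio 2.0, p = C(5,4)C(5,0)/C(10,4) = 5/210
        universe = [f"g{i}" for i in range(10)]
        category = universe[:5]
        cluster = universe[:4]
        r = hypergeometric_enrichment(category, cluster, universe)
        assert r.n_observed == 4
        assert r.n_expected == pytest.approx(2.0)
        assert r.ratio == pytest.approx(2.0)
        assert r.p == pytest.approx(5 / 210)

    def test_category_equals_universe(self):
        universe = [f"g{i}" for i in range(8)]
        r = hypergeometric_enrichment(universe, universe[:3], universe)
        assert r.ratio == pytest.approx(1.0)
        assert r.p == pytest.approx(1.0)

    def test_disjoint_depletion_tail(self):
        universe = [f"g{i}" for i in range(10)]
        r = hypergeometric_enrichment(universe[:5], universe[5:9], universe)
        assert r.ratio == 0.0
        assert r.direction == "depletion"
        # P[X <= 0] for Hypergeom(10, 5, 4) = C(5,4)/C(10,4)
        assert r.p == pytest.approx(5 / 210)

    def test_matches_exhaustive_enumeration_small_universes(self):
        """Upper-tail p equals direct combinatorial enumeration, M <= 20."""
        rng = np.random.default_rng(12)
        for _ in range(20):
            m = int(rng.integers(5, 21))
            universe = [f"g{i}" for i in range(m)]
            k = int(rng.integers(1, m + 1))
            n = int(rng.integers(1, m + 1))
            category = list(rng.choice(universe, size=k, replace=False))
            cluster = list(rng.choice(universe, size=n, replace=False))
            r = hypergeometric_enrichment(category, cluster, universe)
            obs = len(set(category) & set(cluster))
            if r.direction == "enrichment":
                expect = sum(
                    math.comb(k, x) * math.comb(m - k, n - x) / math.comb(m, n)
                    for x in range(obs, min(k, n) + 1)
                )
            else:
                expect = sum(
                    math.comb(k, x) * math.comb(m - k, n - x) / math.comb(m, n)
                    for x in range(0, obs + 1)
                )
            assert r.p == pytest.approx(expect, rel=1e-9)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(["a"], ["a"], [])


class TestIntervalFeatureEnrichment:
    def _windows(self):
        return {
            1: [Interval("chr1", i * 20_000, i * 20_000 + 10_000) for i in range(10)],
            2: [Interval("chr2", i * 20_000, i * 20_000 + 10_000) for i in range(10)],
        }

    def test_uniform_features_ratio_one(self):
        windows = self._windows()
        features = [
            Interval(w.chrom, w.start + 100, w.start + 200)
            for ws in windows.values()
            for w in ws
        ]
        t = interval_feature_enrichment(features, windows).set_index("cluster")
        assert t["ratio"].to_numpy() == pytest.approx([1.0, 1.0])

    def test_planted_enrichment(self):
        windows = self._windows()
        rng = np.random.default_rng(3)
        features = [
            Interval("chr1", int(s), int(s) + 50)
            for s in rng.integers(0, 9_000, size=200)
        ]  # all in cluster-1 windows
        t = interval_feature_enrichment(features, windows).set_index("cluster")
        assert t.loc[1, "ratio"] > 1.5
        assert t.loc[1, "p"] < 1e-6

    def test_observed_sums_and_expected_weighted_ratio(self):
        windows = self._windows()
        rng = np.random.default_rng(8)
        chroms = np.where(rng.random(120) < 0.7, "chr1", "chr2")
        features = [
            Interval(str(c), int(s), int(s) + 10)
            for c, s in zip(chroms, rng.integers(0, 190_000, size=120))
        ]
        t = interval_feature_enrichment(features, windows)
        n_assigned = sum(
            1
            for f in features
            if any(
                w.chrom == f.chrom and w.start <= f.midpoint < w.end
                for ws in windows.values()
                for w in ws
            )
        )
        assert t["n_observed"].sum() == n_assigned
        assert t["n_expected"].sum() == pytest.approx(n_assigned)
        weighted = (t["ratio"] * t["n_expected"]).sum() / t["n_expected"].sum()
        assert weighted == pytest.approx(1.0)


class TestCoverageFraction:
    def test_half_covered_boundary(self):
        a = Interval("chr1", 0, 100)
        assert coverage_overlap_fraction(a, [Interval("chr1", 50, 150)]) == 0.5
        assert covered_at_least_half(a, [Interval("chr1", 50, 150)])  # >= rule

    def test_fully_covered(self):
        a = Interval("chr1", 10, 110)
        assert coverage_overlap_fraction(a, [Interval("chr1", 0, 500)]) == 1.0

    def test_union_of_overlapping_pieces(self):
        a = Interval("chr1", 0, 100)
        b = [Interval("chr1", 0, 30), Interval("chr1", 20, 60)]
        assert coverage_overlap_fraction(a, b) == pytest.approx(0.6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 900), st.integers(1, 300)), max_size=8
        ),
        st.tuples(st.integers(0, 500), st.integers(50, 400)),
    )
    def test_monotone_and_order_invariant(self, pieces, region):
        a = Interval("chr1", region[0], region[0] + region[1])
        b = [Interval("chr1", s, s + l) for s, l in pieces]
        f_all = coverage_overlap_fraction(a, b)
        assert 0.0 <= f_all <= 1.0
        # permutation invariance
        assert coverage_overlap_fraction(a, b[::-1]) == pytest.approx(f_all)
        # adding an interval never decreases coverage
        for i in range(len(b)):
            assert coverage_overlap_fraction(a, b[:i]) <= f_all + 1e-12


class TestSuperEnhancers:
    def _ann(self):
        return GenomeAnnotation(
            [GeneModel("g", "chr1", "+", 490_000, 495_000)], {"chr1": 1_000_000}
        )

    def _chip_index(self, counts_by_region):
        parts = []
        for (s, e), n in counts_by_region.items():
            starts = np.linspace(s, e - 50, n).astype(np.int64)
            parts.append(
                ReadLibrary(
                    np.full(n, "chr1", dtype=object), starts, starts + 50,
                    np.full(n, "+", dtype="U1"),
                )
            )
        return ReadIndex(ReadLibrary.concat(parts))

    def test_stitching_within_distance(self):
        peaks = PeakSet(
            [
                Peak(Interval("chr1", 100_000, 101_000), 1.0),
                Peak(Interval("chr1", 106_000, 107_000), 1.0),
                Peak(Interval("chr1", 112_000, 113_000), 1.0),
                Peak(Interval("chr1", 300_000, 301_000), 1.0),
                Peak(Interval("chr1", 700_000, 701_000), 1.0),
            ]
        )
        chip = self._chip_index({(100_000, 113_000): 30, (300_000, 301_000): 10,
                                 (700_000, 701_000): 10})
        ses = call_superenhancers(peaks, chip, None, self._ann())
        spans = sorted((s.interval.start, s.interval.end) for s in ses)
        assert spans[0] == (100_000, 113_000)  # 5 kb gaps stitched
        assert len(ses) == 3

    def test_tangent_cutoff_selects_outlier(self):
        """Signals {1,1,1,1,100}: exactly the 100-signal region is super."""
        centers = [100_000, 200_000, 300_000, 400_000, 700_000]
        peaks = PeakSet(
            [Peak(Interval("chr1", c, c + 1000), 1.0) for c in centers]
        )
        counts = {(c, c + 1000): (100 if c == 700_000 else 1) for c in centers}
        ses = call_superenhancers(peaks, self._chip_index(counts), None, self._ann())
        supers = [s for s in ses if s.is_super]
        assert len(supers) == 1
        assert supers[0].interval.start == 700_000
        assert supers[0].rank == 1

    def test_tss_proximal_peak_removed(self):
        ann = self._ann()  # TSS at 490_000
        peaks = PeakSet(
            [Peak(Interval("chr1", 489_500, 490_500), 1.0)]  # inside TSS +/- 2 kb
            + [
                Peak(Interval("chr1", c, c + 1000), 1.0)
                for c in (100_000, 200_000, 300_000)
            ]
        )
        chip = self._chip_index({(c, c + 1000): 5 for c in (100_000, 200_000, 300_000)})
        ses = call_superenhancers(peaks, chip, None, ann)
        assert all(s.interval.start != 489_500 for s in ses)
        assert len(ses) == 3

    def test_fewer_than_three_regions_all_non_super(self):
        peaks = PeakSet([Peak(Interval("chr1", 100_000, 101_000), 1.0)])
        chip = self._chip_index({(100_000, 101_000): 50})
        with pytest.warns(UserWarning):
            ses = call_superenhancers(peaks, chip, None, self._ann())
        assert all(not s.is_super for s in ses)

    def test_cutoff_matches_brute_force_slope_scan(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            y = np.sort(rng.lognormal(0, 1.0, size=int(rng.integers(3, 40))))
            cut = rose_cutoff_index(y)
            ys = y / y.max()
            xs = np.arange(len(y)) / (len(y) - 1)
            brute = min(range(len(y)), key=lambda i: ys[i] - xs[i])
            assert cut == brute


class TestMotifsAndTargets:
    def test_motif_occurrence_percentage(self):
        # 455 of 495 regions carry >= 1 hit -> 92%; 6 hits each among positives
        regions = [Interval("chr1", i * 1000, i * 1000 + 500) for i in range(495)]
        hits = [
            Interval("chr1", i * 1000 + 10 + j, i * 1000 + 20 + j)
            for i in range(455)
            for j in range(6)
        ]
        t = motif_occurrence_summary({10: regions}, {"motifA": hits})
        assert t.loc[0, "percent_with_hit"] == 92
        assert t.loc[0, "mean_cooccurrence"] == pytest.approx(6.0)

    def test_no_hits_anywhere(self):
        regions = [Interval("chr1", 0, 100)]
        t = motif_occurrence_summary({1: regions}, {"m": []})
        assert t.loc[0, "percent_with_hit"] == 0
        assert np.isnan(t.loc[0, "mean_cooccurrence"])

    def test_direct_target_intersection(self):
        ann = GenomeAnnotation(
            [
                GeneModel("g1", "chr1", "+", 1000, 2000),
                GeneModel("g2", "chr1", "+", 50_000, 60_000),
                GeneModel("g3", "chr1", "+", 100_000, 110_000),
            ],
            {"chr1": 200_000},
        )
        sites = [
            Interval("chr1", 900, 950),
            Interval("chr1", 49_000, 49_100),
            Interval("chr1", 99_000, 99_100),
        ]
        targets = define_direct_targets(sites, {"g2", "g3", "g4"}, ann)
        assert targets == {"g2", "g3"}

    def test_two_factor_partition_counts(self):
        a = {f"a{i}" for i in range(805)} | {f"c{i}" for i in range(305)}
        b = {f"b{i}" for i in range(376)} | {f"c{i}" for i in range(305)}
        part = two_factor_partition(a, b)
        assert part == {"a_only": 805, "b_only": 376, "common": 305, "union": 1486}
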