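"""Binomial cluster test, p-distance regression, Wilcoxon, enrichment."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hopscan.genome_model import (
    AnnotatedReplicon,
    GeneFeature,
    GenomicInterval,
    RepeatElement,
)
from hopscan.spatial_stats import (
    PDistancePair,
    cluster_probability,
    enrichment_heatmap_table,
    hopping_regression,
    p_distance,
    pooled_hopping_regression,
    pseudogene_enrichment,
    scan_clusters,
    wilcoxon_rank_sum,
)


def _binom_tail_oracle(k_min: int, n: int, p: float) -> float:
    """Independent exhaustive binomial sum P(X >= k_min)."""
    return sum(
        math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(k_min, n + 1)
    )


class TestClusterProbability:
    def test_single_element_always_certain(self):
        assert cluster_probability(1, 1, 12345, 1_000_000) == 1.0

    def test_window_equal_to_replicon_certain(self):
        assert cluster_probability(4, 4, 5_000, 5_000) == 1.0

    def test_three_in_tenth_window(self):
        p = cluster_probability(3, 3, 100_000, 1_000_000)
        assert p == pytest.approx(0.01, abs=1e-12)

    def test_matches_exhaustive_binomial_sums(self):
        for n in range(1, 7):
            for x in range(1, n + 1):
                for w in (0.02, 0.1, 0.5, 0.9):
                    expected = _binom_tail_oracle(x - 1, n - 1, w)
                    got = cluster_probability(x, n, w * 1e6, 1e6)
                    assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_monte_carlo_placement(self):
        """Binomial model equals uniform-placement frequency of n-1 points."""
        rng = np.random.default_rng(99)
        n, x, w = 5, 3, 0.12
        draws = rng.random((100_000, n - 1))
        freq = np.mean((draws < w).sum(axis=1) >= x - 1)
        model = cluster_probability(x, n, w * 1e6, 1e6)
        se = math.sqrt(model * (1 - model) / 100_000)
        assert abs(freq - model) <= 3 * se

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cluster_probability(1, 0, 10, 100)
        with pytest.raises(ValueError):
            cluster_probability(5, 3, 10, 100)
        with pytest.raises(ValueError):
            cluster_probability(2, 3, 200, 100)

    def test_zero_window_multiple_elements_impossible(self):
        assert cluster_probability(3, 5, 0, 1000) == 0.0


def _els(mids, frac=1.0, rid="r", repeat="ISx"):
    return [
        RepeatElement(repeat, GenomicInterval(rid, int(m) - 5, int(m) + 5),
                      fraction_full=frac)
        for m in mids
    ]


class TestScanClusters:
    def _rep(self, L=1_000_000):
        return AnnotatedReplicon(id="r", length_bp=L)

    def test_tight_cluster_detected_with_tiny_probability(self):
        rep = self._rep()
        rng = np.random.default_rng(5)
        mids = rng.uniform(0, 0.01 * rep.length_bp, 5)
        tests = scan_clusters(_els(mids), rep)
        assert tests[0].headline_p < 1e-6
        full = next(t for t in tests if t.x_in_window == 5)
        assert full.probability <= 1e-8  # ~ P(Bin(4, 0.01) >= 4)

    def test_single_qualifying_element_empty(self):
        rep = self._rep()
        assert scan_clusters(_els([1000]), rep) == []

    def test_fraction_filter_excludes_short_elements(self):
        rep = self._rep()
        els = _els([1000, 2000], frac=0.6) + _els([500_000], frac=0.9)
        assert scan_clusters(els, rep) == []

    def test_mixed_repeats_rejected(self):
        rep = self._rep()
        els = _els([1000]) + _els([2000], repeat="ISy")
        with pytest.raises(ValueError, match="one repeat"):
            scan_clusters(els, rep)

    def test_uniform_placement_rarely_flagged(self):
        """Headline p-value keeps its nominal level under uniformity."""
        rep = self._rep()
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(100):
            mids = rng.uniform(0, rep.length_bp, 5)
            tests = scan_clusters(_els(mids), rep)
            if tests[0].headline_p < 0.05:
                rejections += 1
        assert rejections <= 10


class TestPDistance:
    def test_identical_sequences(self):
        assert p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_single_substitution(self):
        assert p_distance("ACGT", "ACGA") == pytest.approx(0.25)

    def test_single_deletion_counts_as_gap_column(self):
        assert p_distance("ACGTACGT", "ACGACGT") == pytest.approx(1 / 8)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            p_distance("", "ACGT")

    @given(
        st.text(alphabet="ACGT", min_size=1, max_size=60),
        st.text(alphabet="ACGT", min_size=1, max_size=60),
    )
    @settings(max_examples=80, deadline=None)
    def test_symmetric_bounded_zero_iff_equal(self, a, b):
        d = p_distance(a, b)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(p_distance(b, a))
        if a == b:
            assert d == 0.0
        if d == 0.0:
            assert a == b


class TestHoppingRegression:
    def _pairs(self, x_mbp, y_pct):
        return [
            PDistancePair("a", "b", p_distance=y / 100.0, separation_bp=x * 1e6)
            for x, y in zip(x_mbp, y_pct)
        ]

    def test_flat_response_gives_zero_slope_p_one(self):
        fit = hopping_regression(self._pairs([0.1, 0.5, 1.0, 2.0], [3, 3, 3, 3]))
        assert fit.slope_per_mbp == 0.0
        assert fit.p_value == pytest.approx(1.0)

    def test_noiseless_line_recovered_exactly(self):
        x = [0.2, 0.5, 0.8, 1.4, 2.2, 3.0]
        y = [0.5 * xi + 1.0 for xi in x]
        fit = hopping_regression(self._pairs(x, y))
        assert fit.slope_per_mbp == pytest.approx(0.5, rel=1e-9)
        assert fit.intercept == pytest.approx(1.0, rel=1e-9)
        assert fit.identity_slope_per_mbp == pytest.approx(-0.5, rel=1e-9)

    def test_too_few_pairs_refused(self):
        with pytest.raises(ValueError, match=">= 3"):
            hopping_regression(self._pairs([1, 2], [1, 2]))

    def test_zero_separation_variance_refused(self):
        with pytest.raises(ValueError, match="zero variance"):
            hopping_regression(self._pairs([1, 1, 1], [1, 2, 3]))

    def test_pooled_equals_single_for_one_repeat(self):
        pairs = self._pairs([0.2, 0.7, 1.1, 1.9], [1.2, 1.9, 2.4, 3.1])
        single = hopping_regression(pairs)
        pooled = pooled_hopping_regression({"ISx": pairs})
        assert pooled.slope_per_mbp == pytest.approx(single.slope_per_mbp)
        assert pooled.p_value == pytest.approx(single.p_value)

    def test_pooled_common_trend_recovered(self):
        p1 = self._pairs([0.2, 0.8, 1.6], [0.5 * 0.2 + 1, 0.5 * 0.8 + 1, 0.5 * 1.6 + 1])
        p2 = self._pairs([0.4, 1.0, 2.0], [0.5 * 0.4 + 1, 0.5 * 1.0 + 1, 0.5 * 2.0 + 1])
        fit = pooled_hopping_regression({"a": p1, "b": p2})
        assert fit.slope_per_mbp == pytest.approx(0.5, rel=1e-9)


class TestWilcoxonRankSum:
    def test_identical_samples_no_evidence(self):
        _, p = wilcoxon_rank_sum([1, 2, 3, 3], [1, 2, 3, 3])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_fully_separated_triples_exact(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_large_shift_detected(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 200)
        b = rng.normal(1, 1, 200)
        _, p = wilcoxon_rank_sum(a, b)
        assert p < 1e-6

    def test_exact_path_agrees_with_enumeration(self):
        """Exact small-sample p-values equal full permutation enumeration."""
        values = list(range(1, 7))
        for na in range(1, 6):
            for a_idx in itertools.combinations(range(6), na):
                a = [values[i] for i in a_idx]
                b = [values[i] for i in range(6) if i not in a_idx]
                _, p = wilcoxon_rank_sum(a, b)
                # enumeration oracle over all labellings
                obs = sum(a)
                stats = []
                for comb in itertools.combinations(values, na):
                    stats.append(sum(comb))
                mean = np.mean(stats)
                p_oracle = np.mean(
                    [abs(s - mean) >= abs(obs - mean) - 1e-12 for s in stats]
                )
                assert p == pytest.approx(p_oracle, abs=1e-12)


def _toy_genome():
    """3 ISs each with 2 pseudogenes within 5 kbp; 3 genes each with 1."""
    L = 400_000
    feats = []
    els = []
    for k in range(3):
        base = 20_000 + k * 100_000
        els.append(
            RepeatElement("ISx", GenomicInterval("r", base, base + 1000),
                          fraction_full=1.0)
        )
        feats.append(GeneFeature(f"p{k}a", base + 2000, base + 2500, is_pseudo=True))
        feats.append(GeneFeature(f"p{k}b", base + 3000, base + 3500, is_pseudo=True))
        gbase = base + 50_000
        feats.append(GeneFeature(f"g{k}", gbase, gbase + 1000))
        feats.append(GeneFeature(f"p{k}c", gbase + 2000, gbase + 2500, is_pseudo=True))
    return AnnotatedReplicon(id="r", length_bp=L, features=feats, elements=els)


class TestPseudogeneEnrichment:
    def test_hand_countable_ratio(self):
        rep = _toy_genome()
        prof = pseudogene_enrichment([rep], distances=(5_000,))
        # near each IS: its own 2 planted pseudogenes; near each focal gene:
        # pseudogenes within 5 kb of it (planted pairs sit near each other)
        assert prof.computable
        assert prof.mean_pseudo_near_is[0] == pytest.approx(2.0)
        ratio = prof.enrichment_ratio[0]
        assert ratio == pytest.approx(
            prof.mean_pseudo_near_is[0] / prof.mean_pseudo_near_gene[0]
        )

    def test_no_pseudogenes_ratio_undefined(self):
        rep = _toy_genome()
        for f in rep.features:
            f.is_pseudo = False
        prof = pseudogene_enrichment([rep], distances=(5_000,))
        assert prof.computable
        assert math.isnan(prof.enrichment_ratio[0])
        assert prof.wilcoxon_p[0] == pytest.approx(1.0)

    def test_no_is_elements_flagged_not_computable(self):
        rep = _toy_genome()
        rep.elements = []
        prof = pseudogene_enrichment([rep], distances=(5_000,))
        assert not prof.computable
        assert prof.reason == "no IS elements"

    def test_native_only_variant_drops_is_like_pseudogenes(self):
        rep = _toy_genome()
        for f in rep.features:
            if f.is_pseudo and f.locus_id.endswith(("a", "b")):
                f.is_is_like = True  # planted near-IS pseudogenes are IS debris
        full = pseudogene_enrichment([rep], distances=(5_000,), variant="all")
        native = pseudogene_enrichment([rep], distances=(5_000,), variant="native_only")
        assert native.mean_pseudo_near_is[0] < full.mean_pseudo_near_is[0]

    def test_omit_within_1kb_variant(self):
        rep = _toy_genome()
        # move one pseudogene to 500 bp from its IS: dropped by the variant
        rep.features[0].start = 20_000 + 1_500
        rep.features[0].end = 20_000 + 1_900
        full = pseudogene_enrichment([rep], distances=(5_000,), variant="all")
        omit = pseudogene_enrichment(
            [rep], distances=(5_000,), variant="omit_within_1kb"
        )
        assert omit.mean_pseudo_near_is[0] < full.mean_pseudo_near_is[0]

    def test_focal_feature_never_counts_itself(self):
        L = 100_000
        feats = [GeneFeature("p1", 50_000, 51_000, is_pseudo=True)]
        els = [RepeatElement("ISx", GenomicInterval("r", 10_000, 11_000),
                             fraction_full=1.0)]
        rep = AnnotatedReplicon(id="r", length_bp=L, features=feats, elements=els)
        prof = pseudogene_enrichment([rep], distances=(5_000,))
        # the lone pseudogene is its own only neighbour: gene-side count is 0
        assert prof.mean_pseudo_near_gene[0] == 0.0


class TestHeatmapTable:
    def _profile(self, ratios, pvals, n_pseudo=10):
        from hopscan.spatial_stats import EnrichmentProfile

        d = tuple(5_000 * (i + 1) for i in range(len(ratios)))
        return EnrichmentProfile(
            distances=d,
            mean_pseudo_near_is=list(ratios),
            mean_pseudo_near_gene=[1.0] * len(ratios),
            enrichment_ratio=list(ratios),
            wilcoxon_p=list(pvals),
            n_pseudogenes=n_pseudo,
        )

    def test_zero_pseudogene_genome_omitted(self):
        table = enrichment_heatmap_table(
            {"g0": self._profile([2, 2, 2], [0.01, 0.01, 0.01], n_pseudo=0)}
        )
        assert table.empty

    def test_single_significant_point_omitted(self):
        table = enrichment_heatmap_table(
            {"g1": self._profile([2, 1, 1], [0.01, 0.5, 0.5])}
        )
        assert table.empty

    def test_fully_significant_genome_retained(self):
        table = enrichment_heatmap_table(
            {"g2": self._profile([2, 1.8, 1.5], [0.001, 0.01, 0.04])}
        )
        assert list(table.index) == ["g2"]
        assert bool(table.loc["g2", "sig_5000"]) is True
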