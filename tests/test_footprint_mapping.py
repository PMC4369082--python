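"""Hit search, footprint merging, iterative decomposition, occupancy."""

import itertools

import numpy as np
import pytest

from hopscan import _align
from hopscan.genome_model import (
    AnnotatedReplicon,
    GenomicInterval,
    RepeatElement,
    revcomp,
)
from hopscan.footprint_mapping import (
    AlignmentHit,
    Footprint,
    classify_fraction,
    decompose_footprint,
    fraction_of_full,
    fragment_histogram,
    merge_footprints,
    occupancy_summary,
    scan_replicon,
    search_hits,
)
from hopscan.repeat_discovery import RepeatLibrary, RepeatSequence

from .conftest import random_seq, replicon_with


def _hit(start, end, repeat="A", strand="+", rid="chr"):
    return AlignmentHit(
        repeat_id=repeat,
        interval=GenomicInterval(rid, start, end),
        strand=strand,
        score=float(end - start),
        evalue=1e-20,
        repeat_span=(0, end - start),
    )


class TestSearchHits:
    def test_exact_planted_copy_found_once(self, rng, toy_library):
        A = toy_library.get("A")
        bg = random_seq(rng, 50_000)
        rep = replicon_with([(20_000, A.sequence)], bg)
        hits = search_hits(A, rep)
        assert len(hits) == 1
        h = hits[0]
        assert h.strand == "+"
        assert h.evalue < 1e-6
        assert h.interval.length >= 0.99 * A.length_bp
        assert abs(h.interval.start - 20_000) <= 5

    def test_reverse_complement_copy_on_minus_strand(self, rng, toy_library):
        A = toy_library.get("A")
        bg = random_seq(rng, 50_000)
        rep = replicon_with([(20_000, revcomp(A.sequence))], bg)
        hits = search_hits(A, rep)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert hits[0].interval.length >= 0.99 * A.length_bp

    @pytest.mark.parametrize("trial", range(10))
    def test_absent_repeat_yields_no_hits(self, trial):
        rng = np.random.default_rng(4000 + trial)
        repeat = RepeatSequence(
            id="Q", name="Q", source="de_novo", sequence=random_seq(rng, 800)
        )
        rep = AnnotatedReplicon(
            id="bg", length_bp=50_000, sequence=random_seq(rng, 50_000)
        )
        assert search_hits(repeat, rep) == []

    def test_repeat_shorter_than_seed_rejected(self, rng):
        tiny = RepeatSequence(id="t", name="t", source="de_novo", sequence="ACGTAC")
        rep = AnnotatedReplicon(id="r", length_bp=1000, sequence=random_seq(rng, 1000))
        with pytest.raises(ValueError, match="seed length"):
            search_hits(tiny, rep)

    def test_evalue_calibration_not_anticonservative(self):
        """Chance hits with E < e occur at no more than ~e per search."""
        n_loose = 0
        n_searches = 0
        for trial in range(3):
            rng = np.random.default_rng(7000 + trial)
            rep = AnnotatedReplicon(
                id=f"bg{trial}", length_bp=200_000, sequence=random_seq(rng, 200_000)
            )
            for q in range(10):
                repeat = RepeatSequence(
                    id=f"q{q}", name=f"q{q}", source="de_novo",
                    sequence=random_seq(rng, 1000),
                )
                hits = search_hits(repeat, rep, evalue_max=0.1)
                n_loose += len(hits)
                n_searches += 1
        # expectation at E<0.1 is <=0.1 per search; allow a 3x margin
        assert n_loose <= max(3, int(3 * 0.1 * n_searches))


class TestMergeFootprints:
    def test_disjoint_hits_stay_separate(self):
        fps = merge_footprints([_hit(100, 900), _hit(11_000, 11_800)])
        assert len(fps) == 2

    def test_overlapping_hits_union(self):
        fps = merge_footprints([_hit(100, 900), _hit(800, 1600)])
        assert len(fps) == 1
        assert (fps[0].interval.start, fps[0].interval.end) == (100, 1600)

    def test_three_repeat_overlap_chain(self):
        fps = merge_footprints(
            [_hit(0, 500, "A"), _hit(400, 900, "B"), _hit(850, 1300, "C")]
        )
        assert len(fps) == 1
        assert len(fps[0].hits) == 3

    def test_empty_in_empty_out(self):
        assert merge_footprints([]) == []

    def test_adjacent_hits_merge_within_gap(self):
        assert len(merge_footprints([_hit(0, 500), _hit(520, 900)], merge_gap=50)) == 1
        assert len(merge_footprints([_hit(0, 500), _hit(520, 900)], merge_gap=0)) == 2


def _footprint_over(rep, start, end):
    return Footprint(interval=GenomicInterval(rep.id, start, end), hits=[])


class TestDecomposeFootprint:
    def test_nested_insertion_recovers_three_elements(self, rng, toy_library):
        A, B = toy_library.get("A"), toy_library.get("B")
        fp_seq = B.sequence[:500] + A.sequence + B.sequence[500:]
        bg = random_seq(rng, 30_000)
        rep = replicon_with([(10_000, fp_seq)], bg)
        dec = decompose_footprint(
            _footprint_over(rep, 10_000, 10_000 + len(fp_seq)),
            toy_library,
            rep.sequence,
        )
        assert [e.repeat_id for e in dec.elements] == ["B", "A", "B"]
        assert dec.unassigned == []
        a = dec.elements[1]
        assert a.fraction_full >= 0.95
        assert abs(a.interval.start - 10_500) <= 20
        assert abs(a.interval.end - 11_300) <= 20
        fb1, fb2 = dec.elements[0], dec.elements[2]
        assert fb1.fraction_full == pytest.approx(500 / 1100, abs=0.02)
        assert fb2.fraction_full == pytest.approx(600 / 1100, abs=0.02)

    def test_footprint_equal_to_one_repeat(self, rng, toy_library):
        A = toy_library.get("A")
        bg = random_seq(rng, 20_000)
        rep = replicon_with([(5_000, A.sequence)], bg)
        dec = decompose_footprint(
            _footprint_over(rep, 5_000, 5_800), toy_library, rep.sequence
        )
        assert len(dec.elements) == 1
        assert dec.elements[0].repeat_id == "A"
        assert dec.elements[0].fraction_full >= 0.95

    def test_tandem_pair_gives_two_full_elements(self, rng, toy_library):
        A = toy_library.get("A")
        bg = random_seq(rng, 20_000)
        rep = replicon_with([(5_000, A.sequence + A.sequence)], bg)
        dec = decompose_footprint(
            _footprint_over(rep, 5_000, 6_600), toy_library, rep.sequence
        )
        assert [e.repeat_id for e in dec.elements] == ["A", "A"]
        assert all(e.fraction_full >= 0.95 for e in dec.elements)

    def test_unmatchable_segment_reported_not_dropped(self, rng, toy_library):
        rep = AnnotatedReplicon(
            id="chr", length_bp=5_000, sequence=random_seq(rng, 5_000)
        )
        dec = decompose_footprint(
            _footprint_over(rep, 1_000, 1_400), toy_library, rep.sequence
        )
        assert dec.elements == []
        assert len(dec.unassigned) == 1
        assert (dec.unassigned[0].start, dec.unassigned[0].end) == (1_000, 1_400)

    def test_partition_conserves_every_base(self, rng, toy_library):
        """Assigned spans plus unassigned leftovers tile the footprint."""
        A, B, C = (toy_library.get(n) for n in "ABC")
        junk = random_seq(rng, 300)
        fp_seq = C.sequence[:350] + A.sequence + junk + B.sequence[200:900]
        bg = random_seq(rng, 20_000)
        rep = replicon_with([(7_000, fp_seq)], bg)
        dec = decompose_footprint(
            _footprint_over(rep, 7_000, 7_000 + len(fp_seq)),
            toy_library,
            rep.sequence,
        )
        pieces = [(e.interval.start, e.interval.end) for e in dec.elements]
        pieces += [(iv.start, iv.end) for iv in dec.unassigned]
        pieces.sort()
        # disjoint
        for (s1, e1), (s2, e2) in itertools.pairwise(pieces):
            assert e1 <= s2
        covered = sum(e - s for s, e in pieces)
        assert covered >= len(fp_seq) - 2 * 49  # flanks below min_leftover may remain

    def test_greedy_matches_exhaustive_attribution(self, rng, toy_library):
        """On small planted footprints greedy equals the best total-score
        attribution found by exhaustive search over claim orders."""
        A, B = toy_library.get("A"), toy_library.get("B")
        fp_seq = B.sequence[:500] + A.sequence + B.sequence[500:]
        bg = random_seq(rng, 10_000)
        rep = replicon_with([(3_000, fp_seq)], bg)
        fp = _footprint_over(rep, 3_000, 3_000 + len(fp_seq))
        dec = decompose_footprint(fp, toy_library, rep.sequence)

        def best_total(seg_start, seg_end, depth=0):
            if seg_end - seg_start < 50 or depth > 4:
                return 0.0
            seg = rep.sequence[seg_start:seg_end]
            best = 0.0
            for repeat in toy_library.repeats:
                for q in (repeat.sequence, revcomp(repeat.sequence)):
                    aln = _align.local_align(q, seg)
                    if aln is None or aln.score < 40:
                        continue
                    total = (
                        aln.score
                        + best_total(seg_start, seg_start + aln.target_start, depth + 1)
                        + best_total(seg_start + aln.target_end, seg_end, depth + 1)
                    )
                    best = max(best, total)
            return best

        greedy_total = sum(e.score for e in dec.elements)
        assert greedy_total == pytest.approx(
            best_total(3_000, 3_000 + len(fp_seq)), rel=1e-9
        )


class TestFractionAndHistogram:
    @pytest.mark.parametrize(
        "elen,reflen,frac,band",
        [
            (800, 800, 1.0, "full_length"),
            (100, 800, 0.125, "severe_fragment"),
            (790, 800, 0.9875, "full_length"),
            (300, 800, 0.375, "fragment"),
        ],
    )
    def test_fraction_bands(self, elen, reflen, frac, band):
        f = fraction_of_full(elen, reflen)
        assert f == pytest.approx(frac)
        assert classify_fraction(f) == band

    def test_zero_reference_length_rejected(self):
        with pytest.raises(ValueError):
            fraction_of_full(100, 0)

    def _els(self, fracs):
        return [
            RepeatElement("A", GenomicInterval("r", i * 1000, i * 1000 + 10),
                          fraction_full=f)
            for i, f in enumerate(fracs)
        ]

    def test_all_full_length_mass_in_last_bin(self):
        edges, freqs = fragment_histogram(self._els([1.0, 1.0, 0.99, 1.02]))
        assert freqs[-1] == pytest.approx(1.0)
        assert freqs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_bin_counting(self):
        edges, freqs = fragment_histogram(self._els([0.10, 0.10, 0.90, 1.0]))
        bin_010 = int(0.10 / 0.05)
        assert freqs[bin_010] == pytest.approx(0.5)

    def test_empty_input_flagged(self):
        with pytest.raises(ValueError, match="no elements"):
            fragment_histogram([])


class TestOccupancySummary:
    def _rep(self, length, spans, rid="r"):
        els = [
            RepeatElement("ISx", GenomicInterval(rid, s, e), fraction_full=1.0)
            for s, e in spans
        ]
        return AnnotatedReplicon(id=rid, length_bp=length, elements=els)

    def test_simple_percentage(self):
        rep = self._rep(1_000_000, [(i * 10_000, i * 10_000 + 1430) for i in range(100)])
        occ = occupancy_summary([rep])
        assert occ.percent_occupied == pytest.approx(0.143)
        assert occ.repeats_per_mbp == pytest.approx(100.0)

    def test_no_elements(self):
        occ = occupancy_summary([self._rep(1000, [])])
        assert occ.total_repeat_hits == 0
        assert occ.percent_occupied == 0.0

    def test_overlap_counted_once(self):
        occ = occupancy_summary([self._rep(10_000, [(0, 1000), (500, 1500)])])
        assert occ.repeat_bp == 1500
        assert occ.genome_minus_is_bp == 8_500

    def test_order_invariance(self):
        spans = [(0, 1000), (500, 1500), (4000, 4800)]
        a = occupancy_summary([self._rep(10_000, spans)])
        b = occupancy_summary([self._rep(10_000, spans[::-1])])
        assert a == b

    def test_is_class_filter_and_pseudo_accounting(self):
        from hopscan.genome_model import GeneFeature

        rep = self._rep(10_000, [(0, 1000)])
        rep.elements.append(
            RepeatElement("oddball", GenomicInterval("r", 3000, 3400), fraction_full=0.4)
        )
        rep.features.append(
            GeneFeature(locus_id="p1", start=500, end=2000, is_pseudo=True)
        )
        occ = occupancy_summary([rep], {"ISx": "isfinder_is", "oddball": "unclassified"})
        assert occ.total_repeat_hits == 2
        assert occ.total_is_hits == 1
        assert occ.genome_minus_is_bp == 9_000
        # pseudogene bp outside the IS span: 2000-1000 = 1000
        assert occ.genome_minus_is_and_pseudo_bp == 8_000


def test_scan_replicon_refuses_empty_library(rng):
    rep = AnnotatedReplicon(id="r", length_bp=1000, sequence=random_seq(rng, 1000))
    with pytest.raises(ValueError, match="no repeats"):
        scan_replicon(rep, RepeatLibrary())
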