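"""Footprint scanning and iterative decomposition into repeat elements.

Each library repeat is searched against a replicon with a seeded local
aligner; hits below the E-value cutoff are merged into footprints (regions
covered by one or more hits), and every footprint is then decomposed
greedily: the best-scoring repeat claims its aligned span, and the search
recurses on the remaining segments until nothing of at least
``min_leftover`` bp is left unexplained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from . import _align
from ._align import Scoring
from .genome_model import AnnotatedReplicon, GenomicInterval, RepeatElement, revcomp
from .repeat_discovery import RepeatLibrary, RepeatSequence

__all__ = [
    "AlignmentHit",
    "Footprint",
    "OccupancySummary",
    "Decomposition",
    "search_hits",
    "merge_footprints",
    "decompose_footprint",
    "scan_replicon",
    "fraction_of_full",
    "classify_fraction",
    "fragment_histogram",
    "occupancy_summary",
]

IS_CLASSES = frozenset({"isfinder_is", "putative_is"})


@dataclass
class AlignmentHit:
    """A thresholded local alignment of a repeat against a replicon."""

    repeat_id: str
    interval: GenomicInterval
    strand: str
    score: float
    evalue: float
    repeat_span: tuple[int, int]  # [qstart, qend) on the repeat, + orientation


@dataclass
class Footprint:
    """A maximal run of mutually overlapping hits; interval = union span."""

    interval: GenomicInterval
    hits: list[AlignmentHit] = field(default_factory=list)


class Decomposition(NamedTuple):
    elements: list[RepeatElement]
    unassigned: list[GenomicInterval]


# cache of per-replicon k-mer seed indexes, keyed on the sequence object
_scan_cache: dict[int, tuple[str, dict[int, _align.SeedIndex]]] = {}


def _seed_index(replicon: AnnotatedReplicon, k: int) -> _align.SeedIndex:
    seq = replicon.require_sequence()
    key = id(replicon)
    entry = _scan_cache.get(key)
    if entry is None or entry[0] is not seq:
        if len(_scan_cache) > 4:
            _scan_cache.clear()
        entry = (seq, {})
        _scan_cache[key] = entry
    per_k = entry[1]
    if k not in per_k:
        per_k[k] = _align.SeedIndex(_align.kmer_hashes(_align.encode(seq), k))
    return per_k[k]


def search_hits(
    repeat: RepeatSequence,
    replicon: AnnotatedReplicon,
    evalue_max: float = 1e-6,
    scoring: Scoring = Scoring(),
    word_size: int = 11,
    min_seeds: int = 2,
) -> list[AlignmentHit]:
    """Local-alignment hits of one repeat on both strands with E < evalue_max.

    Candidate windows come from clustered exact ``word_size``-mer seeds
    (at least ``min_seeds`` per cluster); each window is aligned with the
    affine-gap local aligner and scored with the Karlin-Altschul
    expectation over the two-strand search space.
    """
    if repeat.length_bp < word_size:
        raise ValueError(
            f"repeat {repeat.name} shorter than the seed length {word_size}"
        )
    seq = replicon.require_sequence()
    index = _seed_index(replicon, word_size)
    m, n = repeat.length_bp, replicon.length_bp
    hits: list[AlignmentHit] = []
    for strand in "+-":
        query = repeat.sequence if strand == "+" else revcomp(repeat.sequence)
        qhash = _align.kmer_hashes(_align.encode(query), word_size)
        tpos, qoff = index.matches(qhash)
        for wstart, wend in _align.cluster_seeds(
            tpos, qoff, repeat.length_bp, min_seeds=min_seeds
        ):
            wend = min(wend, n)
            aln = _align.local_align(query, seq[wstart:wend], scoring)
            if aln is None:
                continue
            ev = scoring.evalue(aln.score, m, 2 * n)
            if ev >= evalue_max:
                continue
            qs, qe = aln.query_start, aln.query_end
            if strand == "-":
                qs, qe = m - aln.query_end, m - aln.query_start
            hits.append(
                AlignmentHit(
                    repeat_id=repeat.name,
                    interval=GenomicInterval(
                        replicon.id, wstart + aln.target_start, wstart + aln.target_end
                    ),
                    strand=strand,
                    score=aln.score,
                    evalue=ev,
                    repeat_span=(qs, qe),
                )
            )
    # windows from different seed clusters may rediscover the same locus
    hits.sort(key=lambda h: (-h.score, h.interval.start))
    kept: list[AlignmentHit] = []
    for h in hits:
        if any(
            h.strand == k.strand
            and h.interval.overlap(k.interval) > 0.5 * min(h.interval.length, k.interval.length)
            for k in kept
        ):
            continue
        kept.append(h)
    kept.sort(key=lambda h: h.interval.start)
    return kept


def merge_footprints(hits: Iterable[AlignmentHit], merge_gap: int = 0) -> list[Footprint]:
    """Group hits whose genomic intervals overlap (or are within merge_gap)."""
    hits = sorted(hits, key=lambda h: (h.interval.start, h.interval.end))
    if not hits:
        return []
    rid = {h.interval.replicon_id for h in hits}
    if len(rid) > 1:
        raise ValueError(f"hits span multiple replicons: {sorted(rid)}")
    out: list[Footprint] = []
    cur = [hits[0]]
    cur_end = hits[0].interval.end
    for h in hits[1:]:
        if h.interval.start <= cur_end + merge_gap:
            cur.append(h)
            cur_end = max(cur_end, h.interval.end)
        else:
            out.append(_make_footprint(cur))
            cur = [h]
            cur_end = h.interval.end
    out.append(_make_footprint(cur))
    return out


def _make_footprint(hits: list[AlignmentHit]) -> Footprint:
    start = min(h.interval.start for h in hits)
    end = max(h.interval.end for h in hits)
    return Footprint(
        interval=GenomicInterval(hits[0].interval.replicon_id, start, end), hits=hits
    )


def decompose_footprint(
    footprint: Footprint,
    library: RepeatLibrary,
    sequence: str,
    min_leftover: int = 50,
    evalue_max: float = 1e-6,
    scoring: Scoring = Scoring(),
    candidate_names: Iterable[str] | None = None,
) -> Decomposition:
    """Iteratively attribute a footprint to repeat elements.

    At each step every candidate repeat is aligned (both orientations)
    against the unassigned segment; the best scorer claims its aligned
    genomic span as one element and the remaining flanks of at least
    ``min_leftover`` bp are re-queued.  Ties break on (higher score, longer
    span, lexicographic repeat name), which makes the decomposition
    deterministic.  Segments no repeat can claim at E < evalue_max are
    returned as ``unassigned`` rather than silently dropped.

    ``sequence`` is the full replicon sequence; ``candidate_names`` defaults
    to the repeats present in the footprint's hits (the full library when
    the footprint carries no hits).
    """
    if candidate_names is None:
        candidate_names = sorted({h.repeat_id for h in footprint.hits}) or library.names
    candidates = [library.get(name) for name in sorted(candidate_names)]
    rid = footprint.interval.replicon_id
    elements: list[RepeatElement] = []
    unassigned: list[GenomicInterval] = []
    queue = [(footprint.interval.start, footprint.interval.end)]
    while queue:
        seg_start, seg_end = queue.pop()
        seg = sequence[seg_start:seg_end]
        best = None  # (-score, -span, name, repeat, aln, strand)
        for repeat in candidates:
            for strand in "+-":
                q = repeat.sequence if strand == "+" else revcomp(repeat.sequence)
                aln = _align.local_align(q, seg, scoring)
                if aln is None:
                    continue
                ev = scoring.evalue(aln.score, repeat.length_bp, 2 * len(seg))
                if ev >= evalue_max:
                    continue
                span = aln.target_end - aln.target_start
                key = (-aln.score, -span, repeat.name, strand)
                if best is None or key < best[0]:
                    best = (key, repeat, aln, strand)
        if best is None:
            unassigned.append(GenomicInterval(rid, seg_start, seg_end))
            continue
        _, repeat, aln, strand = best
        g_start = seg_start + aln.target_start
        g_end = seg_start + aln.target_end
        elements.append(
            RepeatElement(
                repeat_id=repeat.name,
                interval=GenomicInterval(rid, g_start, g_end),
                strand=strand,
                fraction_full=fraction_of_full(g_end - g_start, repeat.length_bp),
                score=aln.score,
            )
        )
        if g_start - seg_start >= min_leftover:
            queue.append((seg_start, g_start))
        if seg_end - g_end >= min_leftover:
            queue.append((g_end, seg_end))
    elements.sort(key=lambda e: e.interval.start)
    unassigned.sort(key=lambda iv: iv.start)
    return Decomposition(elements, unassigned)


def scan_replicon(
    replicon: AnnotatedReplicon,
    library: RepeatLibrary,
    evalue_max: float = 1e-6,
    merge_gap: int = 0,
    min_leftover: int = 50,
    scoring: Scoring = Scoring(),
) -> tuple[list[RepeatElement], list[Footprint], list[GenomicInterval]]:
    """Search all library repeats, merge hits into footprints, decompose.

    Returns (elements sorted by start, footprints, unassigned leftovers).
    The replicon's ``elements`` list is not modified; callers attach the
    result where appropriate.
    """
    if len(library) == 0:
        raise ValueError("library has no repeats")
    all_hits: list[AlignmentHit] = []
    for repeat in sorted(library.repeats, key=lambda r: r.name):
        all_hits.extend(search_hits(repeat, replicon, evalue_max, scoring))
    footprints = merge_footprints(all_hits, merge_gap)
    seq = replicon.require_sequence()
    elements: list[RepeatElement] = []
    unassigned: list[GenomicInterval] = []
    for fp in footprints:
        dec = decompose_footprint(
            fp, library, seq, min_leftover, evalue_max, scoring
        )
        elements.extend(dec.elements)
        unassigned.extend(dec.unassigned)
    elements.sort(key=lambda e: e.interval.start)
    return elements, footprints, unassigned


# ---------------------------------------------------------------------------
# fragment statistics and occupancy
# ---------------------------------------------------------------------------

def fraction_of_full(element_len: int, reference_len: int) -> float:
    """Element span length as a fraction of its reference repeat length."""
    if reference_len < 1:
        raise ValueError("reference_len must be >= 1")
    return element_len / reference_len


def classify_fraction(fraction: float) -> str:
    """Band a fraction-of-full value: full-length / half / fragment / severe."""
    if fraction >= 0.95:
        return "full_length"
    if fraction < 0.15:
        return "severe_fragment"
    if fraction < 0.50:
        return "fragment"
    return "near_full"


def fragment_histogram(
    elements: list[RepeatElement], bin_width: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of fraction-of-full values over fixed-width bins.

    Returns (bin left edges, frequencies summing to 1).  Fractions above 1
    are absorbed into the final bin.  Raises on empty input so an empty
    element list is never confused with an all-zero distribution.
    """
    if not elements:
        raise ValueError("fragment_histogram: no elements")
    nbins = int(round(1.0 / bin_width))
    edges = np.arange(nbins + 1) * bin_width
    fracs = np.clip([e.fraction_full for e in elements], 0, 1 - 1e-12)
    counts, _ = np.histogram(fracs, bins=edges)
    return edges[:-1], counts / counts.sum()


def _union_bp(intervals: Iterable[tuple[int, int]]) -> int:
    ivs = sorted(intervals)
    total = 0
    cur_s = cur_e = None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


@dataclass
class OccupancySummary:
    """Genome-level repeat occupancy accounting."""

    total_repeat_hits: int
    total_is_hits: int
    repeat_bp: int
    percent_occupied: float
    repeats_per_mbp: float
    genome_bp: int
    genome_minus_is_bp: int
    genome_minus_is_and_pseudo_bp: int


def occupancy_summary(
    replicons: list[AnnotatedReplicon],
    repeat_classes: dict[str, str] | None = None,
) -> OccupancySummary:
    """Summarise repeat content across a genome's replicons.

    ``repeat_classes`` maps repeat name to class; elements whose class is an
    IS class count as IS hits (all elements when no mapping is given).
    Overlapping element spans are counted once.
    """
    genome_bp = sum(r.length_bp for r in replicons)
    n_hits = 0
    n_is = 0
    repeat_bp = 0
    is_bp = 0
    pseudo_extra_bp = 0
    for rep in replicons:
        spans = [(e.interval.start, e.interval.end) for e in rep.elements]
        n_hits += len(spans)
        repeat_bp += _union_bp(spans)
        if repeat_classes is None:
            is_spans = spans
            n_is += len(spans)
        else:
            is_spans = [
                (e.interval.start, e.interval.end)
                for e in rep.elements
                if repeat_classes.get(e.repeat_id, "unclassified") in IS_CLASSES
            ]
            n_is += len(is_spans)
        is_bp += _union_bp(is_spans)
        # pseudogene bp not already inside called elements
        pseudo_spans = [(f.start, f.end) for f in rep.features if f.is_pseudo]
        both = _union_bp(pseudo_spans + is_spans)
        pseudo_extra_bp += both - _union_bp(is_spans)
    return OccupancySummary(
        total_repeat_hits=n_hits,
        total_is_hits=n_is,
        repeat_bp=repeat_bp,
        percent_occupied=repeat_bp / genome_bp if genome_bp else 0.0,
        repeats_per_mbp=n_hits / (genome_bp / 1e6) if genome_bp else 0.0,
        genome_bp=genome_bp,
        genome_minus_is_bp=genome_bp - is_bp,
        genome_minus_is_and_pseudo_bp=genome_bp - is_bp - pseudo_extra_bp,
    )
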