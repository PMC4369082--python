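"""Internal alignment engine shared by repeat discovery, footprint scanning
and pairwise distance computation.

Local alignment is done with Biopython's :class:`PairwiseAligner` on short
candidate windows located by exact k-mer seeding; seeding uses numpy rolling
hashes so a multi-megabase replicon is indexed once per scan.  Significance
of a local alignment score S against a search space of m x n residues is the
Karlin-Altschul expectation E = K * m * n * exp(-lambda * S); lambda is
solved from the scoring scheme under uniform base composition, K is a
calibration constant for the default scheme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from scipy.optimize import brentq

_BASE_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to int codes (A,C,G,T -> 0..3, other -> 4)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_hashes(codes: np.ndarray, k: int) -> np.ndarray:
    """Rolling base-4 hashes of every k-mer; windows containing N get -1."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    h = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        window = codes[j : j + n]
        h = h * 4 + np.where(window == 4, 0, window)
        bad |= window == 4
    h[bad] = -1
    return h


@dataclass(frozen=True)
class Scoring:
    """Match/mismatch/affine-gap scores, BLASTN-like defaults."""

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0

    @property
    def karlin_lambda(self) -> float:
        return _ungapped_lambda(self.match, self.mismatch)

    # K for the default (1,-2,5,2) scheme; approximate for other schemes.
    karlin_k: float = 0.46

    def evalue(self, score: float, m: int, n: int) -> float:
        """Expected number of chance alignments scoring >= score."""
        x = self.karlin_k * m * n * math.exp(-self.karlin_lambda * score)
        return x


@lru_cache(maxsize=8)
def _ungapped_lambda(match: float, mismatch: float) -> float:
    """Solve (1/4)e^{lambda*match} + (3/4)e^{lambda*mismatch} = 1, lambda>0."""

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return brentq(f, 1e-6, 10.0 / match)


@lru_cache(maxsize=8)
def _aligner(scoring: Scoring, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.match_score = scoring.match
    al.mismatch_score = scoring.mismatch
    # PairwiseAligner's open score applies to the first gap position
    al.open_gap_score = scoring.gap_open
    al.extend_gap_score = scoring.gap_extend
    return al


@dataclass
class LocalAlignment:
    """Best local alignment of a query against a target window."""

    score: float
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    identity: float  # identical columns / aligned columns
    n_columns: int


def local_align(query: str, target: str, scoring: Scoring = Scoring()) -> LocalAlignment | None:
    """Best-scoring local alignment, or None when nothing scores > 0."""
    if not query or not target:
        return None
    al = _aligner(scoring, "local")
    alignments = al.align(query, target)
    if alignments.score <= 0:
        return None
    aln = alignments[0]
    score = alignments.score
    qblocks, tblocks = aln.aligned
    if len(qblocks) == 0:
        return None
    counts = aln.counts()
    ncol = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / ncol if ncol else 0.0
    return LocalAlignment(
        score=float(score),
        query_start=int(qblocks[0][0]),
        query_end=int(qblocks[-1][1]),
        target_start=int(tblocks[0][0]),
        target_end=int(tblocks[-1][1]),
        identity=identity,
        n_columns=int(ncol),
    )


class SeedIndex:
    """Sorted k-mer hash index of a target sequence.

    Built once per (replicon, k); lookups for a query are two vectorised
    binary searches, so scanning many repeats against one genome never
    rescans the genome.
    """

    def __init__(self, target_hashes: np.ndarray) -> None:
        self.order = np.argsort(target_hashes, kind="stable")
        self.sorted_hashes = target_hashes[self.order]

    def matches(self, query_hashes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Parallel arrays (target_pos, query_offset) of exact k-mer matches.

        N-containing k-mers (hash -1) never match.
        """
        valid = np.nonzero(query_hashes >= 0)[0]
        if valid.size == 0 or self.sorted_hashes.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qh = query_hashes[valid]
        lo = np.searchsorted(self.sorted_hashes, qh, side="left")
        hi = np.searchsorted(self.sorted_hashes, qh, side="right")
        out_t = []
        out_q = []
        for off, a, b in zip(valid, lo, hi):
            if b > a:
                out_t.append(self.order[a:b])
                out_q.append(np.full(b - a, off, dtype=np.int64))
        if not out_t:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        return np.concatenate(out_t), np.concatenate(out_q)


def cluster_seeds(
    tpos: np.ndarray,
    qoff: np.ndarray,
    query_len: int,
    band: int = 64,
    min_seeds: int = 2,
    min_span: int = 12,
) -> list[tuple[int, int]]:
    """Group seed matches into candidate target windows.

    Seeds are grouped when they lie on nearby diagonals (within ``band``)
    and within one query length along the target.  A cluster must contain
    at least ``min_seeds`` seeds spanning at least ``min_span`` bp of the
    target (the two-hit rule: a run of mutually overlapping chance seeds
    never qualifies).  Returns (start, end) windows on the target.
    """
    if tpos.size == 0:
        return []
    diag = tpos - qoff
    order = np.lexsort((tpos, diag))
    diag = diag[order]
    tp = tpos[order]
    qo = qoff[order]
    windows: list[tuple[int, int]] = []

    def _emit(idx: np.ndarray) -> None:
        # split a diagonal-band group on target-position gaps > query_len
        sub = idx[np.argsort(tp[idx], kind="stable")]
        run_start = 0
        for j in range(1, sub.size + 1):
            if j == sub.size or tp[sub[j]] - tp[sub[j - 1]] > query_len:
                run = sub[run_start:j]
                if (
                    run.size >= min_seeds
                    and int(tp[run].max() - tp[run].min()) >= min_span
                ):
                    lo = int((tp[run] - qo[run]).min())
                    hi = int((tp[run] + (query_len - qo[run])).max())
                    windows.append((max(0, lo - 32), hi + 32))
                run_start = j
    start_i = 0
    for i in range(1, tp.size + 1):
        if i == tp.size or diag[i] - diag[i - 1] > band:
            _emit(np.arange(start_i, i))
            start_i = i
    # windows are kept per diagonal cluster (not merged): two copies of the
    # query in one region must each get their own alignment window
    return sorted(set(windows))
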