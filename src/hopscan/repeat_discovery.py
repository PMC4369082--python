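"""Repeat-library construction.

De novo discovery of long repeat families by exact-seed counting and greedy
bidirectional consensus extension, merger with a reference IS catalogue
(catalogue names take precedence over de novo duplicates), deduplication and
ordinal naming.  Discovery operates on the forward strand; a family present
in both orientations is reported once from its forward occurrences.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from . import _align
from .genome_model import AnnotatedReplicon, read_fasta_replicons, write_fasta

__all__ = [
    "RepeatSequence",
    "RepeatLibrary",
    "find_denovo_repeats",
    "filter_known_gene_repeats",
    "assemble_library",
    "name_repeats",
    "read_catalogue_fasta",
    "write_library_fasta",
]

DEFAULT_NONMOBILE_KEYWORDS = ("rRNA", "tRNA", "photosystem", "phycobilisome")

_CODE_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)


@dataclass
class RepeatSequence:
    """A named reference repeat: catalogue IS or de novo consensus."""

    id: str
    name: str
    source: str  # "reference_catalogue" or "de_novo"
    sequence: str
    repeat_class: str = "unclassified"
    origin_genome: str = ""

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass
class RepeatLibrary:
    """A deduplicated collection of repeats with a provenance log."""

    repeats: list[RepeatSequence] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.repeats)

    def __len__(self) -> int:
        return len(self.repeats)

    def get(self, name: str) -> RepeatSequence:
        for r in self.repeats:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.repeats]


def _consensus_extend(
    codes: np.ndarray,
    positions: np.ndarray,
    seed_len: int,
    max_divergence: float,
    agree_window: int = 15,
) -> tuple[int, int, str]:
    """Extend a set of seed occurrences bidirectionally into a consensus.

    Columns are taken across all occurrences at a common offset; extension
    stops when the mean column agreement with the majority base over the
    trailing ``agree_window`` columns drops below ``1 - max_divergence``.
    Returns (left_extension, right_extension, consensus string).
    """
    n = codes.size
    thresh = 1.0 - max_divergence

    def extend(direction: int) -> tuple[int, list[int]]:
        # direction +1 extends right of the seed, -1 extends left
        ext = 0
        cons: list[int] = []
        window: list[float] = []
        while True:
            if direction > 0:
                cols = positions + seed_len + ext
            else:
                cols = positions - 1 - ext
            if cols.min() < 0 or cols.max() >= n:
                break
            col = codes[cols]
            col = col[col < 4]
            if col.size == 0:
                break
            counts = np.bincount(col, minlength=4)
            maj = int(counts.argmax())
            agree = counts[maj] / col.size
            window.append(agree)
            if len(window) > agree_window:
                window.pop(0)
            if sum(window) / len(window) < thresh:
                # trim the failing tail
                while cons and window and window[-1] < thresh:
                    cons.pop()
                    window.pop()
                break
            cons.append(maj)
            ext += 1
        return len(cons), cons

    right_n, right_cons = extend(+1)
    left_n, left_cons = extend(-1)
    seed_cons = []
    for off in range(seed_len):
        col = codes[positions + off]
        col = col[col < 4]
        counts = np.bincount(col, minlength=4)
        seed_cons.append(int(counts.argmax()))
    full = list(reversed(left_cons)) + seed_cons + right_cons
    consensus = _CODE_TO_BASE[np.asarray(full, dtype=np.int64)].tobytes().decode()
    return left_n, right_n, consensus


def find_denovo_repeats(
    replicons: list[AnnotatedReplicon],
    min_repeat_len: int = 500,
    min_copies: int = 2,
    seed_len: int = 16,
    max_divergence: float = 0.1,
    max_families_per_genome: int = 200,
) -> list[RepeatSequence]:
    """Discover repeat families occurring >= min_copies times per replicon set.

    High-frequency exact ``seed_len``-mers are extended greedily in both
    directions, tolerating ``max_divergence`` column disagreement; the
    column-majority consensus is reported for families whose consensus is at
    least ``min_repeat_len`` long.  Families whose occurrences fall inside an
    already-claimed region are skipped, so nested sub-repeats of a longer
    family are not re-reported.
    """
    if min_repeat_len < seed_len:
        raise ValueError("min_repeat_len must be >= seed_len")
    found: list[RepeatSequence] = []
    counter = 0
    for rep in replicons:
        seq = rep.sequence
        if not seq:
            continue
        codes = _align.encode(seq)
        hashes = _align.kmer_hashes(codes, seed_len)
        valid = hashes >= 0
        if not valid.any():
            continue
        uniq, inverse, counts = np.unique(
            hashes[valid], return_inverse=True, return_counts=True
        )
        repeated = counts >= min_copies
        if not repeated.any():
            continue
        pos_of = defaultdict(list)
        vpos = np.nonzero(valid)[0]
        for p, inv in zip(vpos, inverse):
            if repeated[inv]:
                pos_of[int(inv)].append(int(p))
        claimed = np.zeros(len(seq), dtype=bool)
        # visit seeds from most to least frequent; ties by hash for determinism
        order = sorted(pos_of, key=lambda i: (-counts[i], uniq[i]))
        for inv in order:
            positions = np.asarray(pos_of[inv], dtype=np.int64)
            positions = positions[~claimed[positions]]
            if positions.size < min_copies:
                continue
            left, right, consensus = _consensus_extend(
                codes, positions, seed_len, max_divergence
            )
            if len(consensus) < min_repeat_len:
                continue
            counter += 1
            found.append(
                RepeatSequence(
                    id=f"denovo_{counter}",
                    name=f"denovo_{counter}",
                    source="de_novo",
                    sequence=consensus,
                    origin_genome=rep.id,
                )
            )
            for p in positions:
                lo = max(0, p - left)
                hi = min(len(seq), p + seed_len + right)
                claimed[lo:hi] = True
            if counter >= max_families_per_genome:
                break
    # drop families subsumed by a longer family's consensus
    found.sort(key=lambda r: -r.length_bp)
    kept: list[RepeatSequence] = []
    for fam in found:
        if any(_redundant(fam, longer, 0.95, 0.8) for longer in kept):
            continue
        kept.append(fam)
    return kept


def _redundant(
    shorter: RepeatSequence,
    longer: RepeatSequence,
    identity: float,
    coverage: float,
) -> bool:
    """True when the shorter repeat aligns to the longer at >= identity over
    >= coverage of its length (either orientation)."""
    from .genome_model import revcomp

    a, b = (shorter, longer) if shorter.length_bp <= longer.length_bp else (longer, shorter)
    for seq in (a.sequence, revcomp(a.sequence)):
        aln = _align.local_align(seq, b.sequence)
        if aln is None:
            continue
        cov = (aln.query_end - aln.query_start) / a.length_bp
        if aln.identity >= identity and cov >= coverage:
            return True
    return False


def filter_known_gene_repeats(
    repeats: list[RepeatSequence],
    exclusion_annotations: dict[str, str],
    keywords: tuple[str, ...] = DEFAULT_NONMOBILE_KEYWORDS,
) -> tuple[list[RepeatSequence], list[str]]:
    """Drop repeats annotated as non-mobile repeated genes (rRNA, tRNA, ...).

    ``exclusion_annotations`` maps repeat id or name to a product
    description; repeats whose description contains a keyword
    (case-insensitive) are removed.  Returns (kept, log lines).
    """
    lowered = tuple(k.lower() for k in keywords)
    known = {r.id for r in repeats} | {r.name for r in repeats}
    log = []
    for rid in exclusion_annotations:
        if rid not in known:
            log.append(f"warning: annotation for unknown repeat {rid!r} ignored")
    kept = []
    for r in repeats:
        product = exclusion_annotations.get(r.id) or exclusion_annotations.get(r.name) or ""
        if any(k in product.lower() for k in lowered):
            log.append(f"removed {r.name}: non-mobile repeated gene ({product})")
        else:
            kept.append(r)
    return kept, log


def assemble_library(
    denovo: list[RepeatSequence],
    catalogue: list[RepeatSequence],
    dedup_identity: float = 0.95,
    dedup_coverage: float = 0.8,
) -> RepeatLibrary:
    """Merge de novo repeats with the reference catalogue, dropping duplicates.

    A de novo repeat aligning to a catalogue entry at >= dedup_identity
    identity over >= dedup_coverage of the shorter sequence is dropped and
    the catalogue entry (and name) survives.  De novo repeats redundant with
    an already-kept de novo repeat are likewise merged (longer entry wins).
    """
    names = [c.name for c in catalogue]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate names in catalogue: {dupes}")
    log: list[str] = []
    repeats: list[RepeatSequence] = list(catalogue)
    kept_denovo: list[RepeatSequence] = []
    for cand in sorted(denovo, key=lambda r: (-r.length_bp, r.name)):
        dup = None
        for ref in catalogue:
            if _redundant(cand, ref, dedup_identity, dedup_coverage):
                dup = ref
                break
        if dup is None:
            for ref in kept_denovo:
                if _redundant(cand, ref, dedup_identity, dedup_coverage):
                    dup = ref
                    break
        if dup is not None:
            log.append(f"merged {cand.name} into {dup.name} (dedup)")
        else:
            kept_denovo.append(cand)
            repeats.append(cand)
    return RepeatLibrary(repeats=repeats, provenance=log)


def name_repeats(
    library: RepeatLibrary, organism_abbrevs: dict[str, str]
) -> RepeatLibrary:
    """Name de novo repeats ``<Abbrev>_R_<k>`` in discovery order per genome.

    Catalogue names are never touched.  Raises when a de novo repeat's
    genome of origin has no abbreviation.
    """
    missing = sorted(
        {
            r.origin_genome
            for r in library.repeats
            if r.source == "de_novo" and r.origin_genome not in organism_abbrevs
        }
    )
    if missing:
        raise ValueError(f"no organism abbreviation for genome(s): {missing}")
    counters: dict[str, int] = defaultdict(int)
    out = []
    log = list(library.provenance)
    for r in library.repeats:
        if r.source == "de_novo":
            abbrev = organism_abbrevs[r.origin_genome]
            counters[abbrev] += 1
            new_name = f"{abbrev}_R_{counters[abbrev]}"
            log.append(f"named {r.name} -> {new_name}")
            r = RepeatSequence(
                id=r.id,
                name=new_name,
                source=r.source,
                sequence=r.sequence,
                repeat_class=r.repeat_class,
                origin_genome=r.origin_genome,
            )
        out.append(r)
    return RepeatLibrary(repeats=out, provenance=log)


def read_catalogue_fasta(path, repeat_class: str = "isfinder_is") -> list[RepeatSequence]:
    """Read a reference IS catalogue (one record per named IS)."""
    out = []
    for rep in read_fasta_replicons(path):
        out.append(
            RepeatSequence(
                id=rep.id,
                name=rep.id,
                source="reference_catalogue",
                sequence=rep.sequence,
                repeat_class=repeat_class,
            )
        )
    return out


def write_library_fasta(library: RepeatLibrary, path) -> None:
    write_fasta([(r.name, r.sequence) for r in library.repeats], path)
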