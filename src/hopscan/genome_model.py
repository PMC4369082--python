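"""Core data model: replicons, gene features, repeat elements, GenBank/FASTA I/O.

Coordinates are 0-based half-open everywhere inside the package; the 1-based
inclusive convention of GenBank flat files exists only at the I/O boundary.
A feature that spans the origin of a circular replicon is stored with
``end > start`` where ``end`` may exceed ``length_bp`` (the feature wraps);
its length is always ``end - start``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "GeneFeature",
    "RepeatElement",
    "AnnotatedReplicon",
    "GenBankParseError",
    "read_genbank",
    "write_genbank",
    "read_fasta_replicons",
    "write_fasta",
    "separation",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# products that mark a gene as itself being mobile-element derived
_IS_LIKE_RE = re.compile(
    r"transposase|insertion sequence|integrase|\bIS\d+|mobile element",
    re.IGNORECASE,
)


class GenBankParseError(ValueError):
    """Raised when a GenBank record cannot be mapped onto the data model."""


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase and collapse every ambiguity character other than ACGT to N."""
    seq = seq.upper()
    if re.search(r"[^ACGTN]", seq):
        seq = re.sub(r"[^ACGTN]", "N", seq)
    return seq


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named replicon."""

    replicon_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.replicon_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared bp (0 when disjoint or on different replicons)."""
        if self.replicon_id != other.replicon_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int:
        """Closest-edge gap in bp; 0 when the intervals touch or overlap."""
        if self.replicon_id != other.replicon_id:
            raise ValueError("gap between intervals on different replicons")
        return max(0, self.start - other.end, other.start - self.end)


@dataclass
class GeneFeature:
    """An annotated gene (or pseudogene) on a replicon.

    ``is_pseudo`` mirrors the GenBank ``/pseudo`` qualifier.  ``is_is_like``
    marks genes that are themselves mobile-element derived (e.g. annotated
    transposases); such pseudogenes can be excluded from proximity counts.
    """

    locus_id: str
    start: int
    end: int
    strand: str = "+"
    is_pseudo: bool = False
    is_is_like: bool = False
    product: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"feature {self.locus_id}: start must precede end")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.locus_id}: bad strand {self.strand!r}")

    def interval(self, replicon_id: str) -> GenomicInterval:
        return GenomicInterval(replicon_id, self.start, self.end)


@dataclass
class RepeatElement:
    """One genomic occurrence of a repeat, attributed to a library entry."""

    repeat_id: str
    interval: GenomicInterval
    strand: str = "+"
    fraction_full: float = 1.0
    score: float = 0.0

    @property
    def is_full_length(self) -> bool:
        return self.fraction_full >= 0.95


@dataclass
class AnnotatedReplicon:
    """A replicon with sequence, gene features and attributed repeat elements."""

    id: str
    length_bp: int
    topology: str = "linear"  # "circular" or "linear"
    sequence: str | None = None
    features: list[GeneFeature] = field(default_factory=list)
    elements: list[RepeatElement] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"bad topology {self.topology!r}")
        if self.sequence is not None and len(self.sequence) != self.length_bp:
            raise ValueError(
                f"{self.id}: sequence length {len(self.sequence)} != "
                f"length_bp {self.length_bp}"
            )

    def require_sequence(self) -> str:
        if self.sequence is None:
            raise ValueError(f"replicon {self.id} was loaded without sequence")
        return self.sequence

    def element_sequence(self, element: RepeatElement) -> str:
        """Genomic sequence of an element, reverse-complemented for − strand."""
        seq = self.require_sequence()
        iv = element.interval
        if iv.end <= self.length_bp:
            s = seq[iv.start : iv.end]
        else:  # wraps the origin of a circular replicon
            s = seq[iv.start :] + seq[: iv.end - self.length_bp]
        return s if element.strand == "+" else revcomp(s)

    def pseudogenes(self, native_only: bool = False) -> list[GeneFeature]:
        out = [f for f in self.features if f.is_pseudo]
        if native_only:
            out = [f for f in out if not f.is_is_like]
        return out


def separation(
    a: GenomicInterval, b: GenomicInterval, replicon: AnnotatedReplicon
) -> float:
    """Midpoint-to-midpoint distance in bp; min-arc on circular replicons."""
    if a.replicon_id != b.replicon_id:
        raise ValueError(
            f"cannot compute separation across replicons "
            f"({a.replicon_id} vs {b.replicon_id})"
        )
    d = abs(a.midpoint - b.midpoint)
    if replicon.topology == "circular":
        d = min(d, replicon.length_bp - d)
    return d


# ---------------------------------------------------------------------------
# GenBank I/O
# ---------------------------------------------------------------------------

_GENE_TYPES = frozenset({"gene", "pseudogene"})
_ELEMENT_TYPES = frozenset({"repeat_region", "mobile_element"})


def _location_bounds(feature: SeqFeature, replicon_len: int) -> tuple[int, int]:
    """Map a (possibly origin-spanning compound) location to [start, end).

    An origin-spanning join such as ``join(4900..5000,1..100)`` becomes a
    single interval whose end exceeds the replicon length; the total span
    length is preserved.
    """
    loc = feature.location
    if isinstance(loc, CompoundLocation):
        parts = loc.parts
        if (
            len(parts) == 2
            and int(parts[0].end) == replicon_len
            and int(parts[1].start) == 0
        ):
            start = int(parts[0].start)
            total = sum(int(p.end) - int(p.start) for p in parts)
            return start, start + total
        return int(loc.start), int(loc.end)
    return int(loc.start), int(loc.end)


def _parse_gene(feature: SeqFeature, replicon_len: int, index: int) -> GeneFeature:
    q = feature.qualifiers
    locus = (q.get("locus_tag") or q.get("gene") or q.get("label") or [f"feat{index}"])[0]
    product = (q.get("product") or [""])[0]
    start, end = _location_bounds(feature, replicon_len)
    if start >= end:
        raise GenBankParseError(f"feature {locus}: degenerate location {feature.location}")
    is_like = "true" in (q.get("is_like") or [""])[0].lower() or bool(
        _IS_LIKE_RE.search(product)
    )
    return GeneFeature(
        locus_id=locus,
        start=start,
        end=end,
        strand="-" if feature.location.strand == -1 else "+",
        is_pseudo="pseudo" in q or "pseudogene" in q,
        is_is_like=is_like,
        product=product,
    )


def _parse_element(feature: SeqFeature, replicon_id: str, replicon_len: int) -> RepeatElement:
    q = feature.qualifiers
    name = (q.get("rpt_family") or q.get("mobile_element_type") or ["repeat"])[0]
    start, end = _location_bounds(feature, replicon_len)
    note = ";".join(q.get("note", []))
    frac = 1.0
    score = 0.0
    m = re.search(r"fraction_full=([0-9.]+)", note)
    if m:
        frac = float(m.group(1))
    m = re.search(r"score=([0-9.eE+-]+)", note)
    if m:
        score = float(m.group(1))
    return RepeatElement(
        repeat_id=name,
        interval=GenomicInterval(replicon_id, start, end),
        strand="-" if feature.location.strand == -1 else "+",
        fraction_full=frac,
        score=score,
    )


def read_genbank(path) -> list[AnnotatedReplicon]:
    """Read a GenBank flat file into :class:`AnnotatedReplicon` objects.

    Gene/pseudogene features become :class:`GeneFeature`; ``repeat_region``
    and ``mobile_element`` features become :class:`RepeatElement`.  GenBank
    1-based inclusive coordinates are converted to 0-based half-open.
    Records without sequence content load with ``sequence=None``.
    """
    replicons: list[AnnotatedReplicon] = []
    for record in SeqIO.parse(str(path), "genbank"):
        length = len(record.seq) if record.seq is not None else 0
        if length == 0:
            raise GenBankParseError(f"record {record.id}: zero-length sequence")
        try:
            sequence: str | None = normalize_sequence(str(record.seq))
        except Exception:  # undefined sequence (e.g. CONTIG-only record)
            sequence = None
        topology = record.annotations.get("topology", "linear")
        features: list[GeneFeature] = []
        elements: list[RepeatElement] = []
        for i, feat in enumerate(record.features):
            try:
                if feat.type in _GENE_TYPES:
                    features.append(_parse_gene(feat, length, i))
                elif feat.type in _ELEMENT_TYPES:
                    elements.append(_parse_element(feat, record.id, length))
            except GenBankParseError:
                raise
            except Exception as exc:
                locus = (feat.qualifiers.get("locus_tag") or ["?"])[0]
                raise GenBankParseError(
                    f"record {record.id}, locus {locus}: {exc}"
                ) from exc
        replicons.append(
            AnnotatedReplicon(
                id=record.id,
                length_bp=length,
                topology=topology if topology in ("circular", "linear") else "linear",
                sequence=sequence,
                features=features,
                elements=elements,
            )
        )
    if not replicons:
        raise GenBankParseError(f"no GenBank records found in {path}")
    return replicons


def _location_for(start: int, end: int, strand: str, length: int) -> SimpleLocation | CompoundLocation:
    s = 1 if strand == "+" else -1
    if end <= length:
        return SimpleLocation(start, end, strand=s)
    # wraps the origin: emit the canonical two-segment join
    return CompoundLocation(
        [SimpleLocation(start, length, strand=s), SimpleLocation(0, end - length, strand=s)]
    )


def write_genbank(replicon: AnnotatedReplicon, path) -> None:
    """Write a replicon, its genes and its repeat elements to GenBank."""
    seq = replicon.sequence if replicon.sequence is not None else "N" * replicon.length_bp
    record = SeqRecord(Seq(seq), id=replicon.id, name=replicon.id[:16], description="")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = replicon.topology
    L = replicon.length_bp
    for f in replicon.features:
        q: dict = {"locus_tag": [f.locus_id]}
        if f.product:
            q["product"] = [f.product]
        if f.is_pseudo:
            q["pseudo"] = [""]
        if f.is_is_like:
            q["is_like"] = ["true"]
        record.features.append(
            SeqFeature(_location_for(f.start, f.end, f.strand, L), type="gene", qualifiers=q)
        )
    for el in replicon.elements:
        q = {
            "rpt_family": [el.repeat_id],
            "note": [f"fraction_full={el.fraction_full:.4f};score={el.score:.1f}"],
        }
        record.features.append(
            SeqFeature(
                _location_for(el.interval.start, el.interval.end, el.strand, L),
                type="repeat_region",
                qualifiers=q,
            )
        )
    with open(path, "w") as fh:
        SeqIO.write([record], fh, "genbank")


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta_replicons(path, topology: str = "linear") -> list[AnnotatedReplicon]:
    """Read raw sequences from FASTA as feature-less replicons."""
    out = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(record.seq))
        out.append(
            AnnotatedReplicon(
                id=record.id, length_bp=len(seq), topology=topology, sequence=seq
            )
        )
    return out


def write_fasta(entries: list[tuple[str, str]], path) -> None:
    """Write (name, sequence) pairs to FASTA, 70 columns per line."""
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
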