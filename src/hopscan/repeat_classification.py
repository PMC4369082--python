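"""Repeat classification from protein-similarity evidence and copy numbers.

Live protein database searches are deliberately out of scope: classification
consumes a precomputed evidence table (repeat_id, hit_description, evalue,
category_hint) such as the one the synthetic-genome simulator emits, and
applies a fixed precedence:

1. reference-catalogue repeats are ``isfinder_is``;
2. transposase evidence below the E-value cutoff -> ``putative_is``;
3. phage evidence -> ``phage``;
4. replication-related evidence -> ``putative_mge``;
   DNA-interacting evidence (endonucleases, helicases, reverse
   transcriptases) -> ``dna_interacting``;
5. no informative evidence but >= ``high_copy_min`` copies in one genome ->
   ``highly_repeated``; otherwise ``unclassified``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .genome_model import RepeatElement
from .repeat_discovery import RepeatLibrary, RepeatSequence

__all__ = [
    "REPEAT_CLASSES",
    "ProteinEvidence",
    "classify_repeat",
    "classify_library",
    "class_census",
    "read_evidence_table",
]

REPEAT_CLASSES = (
    "isfinder_is",
    "putative_is",
    "phage",
    "putative_mge",
    "highly_repeated",
    "dna_interacting",
    "unclassified",
)

_HINTS = ("transposase", "phage", "replication_related", "dna_interacting", "none")


@dataclass(frozen=True)
class ProteinEvidence:
    """One protein-similarity hit for a repeat, with a category hint."""

    repeat_id: str
    hit_description: str
    evalue: float
    category_hint: str = "none"

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.category_hint not in _HINTS:
            raise ValueError(f"unknown category_hint {self.category_hint!r}")


def classify_repeat(
    repeat: RepeatSequence,
    evidence: list[ProteinEvidence],
    max_copies_in_any_genome: int,
    evalue_is: float = 1e-5,
    high_copy_min: int = 6,
) -> str:
    """Assign a single class to a repeat; see module docstring for precedence.

    Conflicting evidence rows resolve to the highest-precedence class.
    """
    if repeat.source == "reference_catalogue":
        return "isfinder_is"
    ev = [e for e in evidence if e.repeat_id in (repeat.id, repeat.name)]
    if any(e.category_hint == "transposase" and e.evalue < evalue_is for e in ev):
        return "putative_is"
    if any(e.category_hint == "phage" for e in ev):
        return "phage"
    if any(e.category_hint == "replication_related" for e in ev):
        return "putative_mge"
    if any(e.category_hint == "dna_interacting" for e in ev):
        return "dna_interacting"
    if max_copies_in_any_genome >= high_copy_min:
        return "highly_repeated"
    return "unclassified"


def classify_library(
    library: RepeatLibrary,
    evidence: list[ProteinEvidence],
    copies_per_genome: dict[str, dict[str, int]],
    evalue_is: float = 1e-5,
    high_copy_min: int = 6,
) -> RepeatLibrary:
    """Classify every repeat in place; ``copies_per_genome`` maps
    repeat name -> genome -> attributed copy count."""
    for r in library.repeats:
        per_genome = copies_per_genome.get(r.name, {})
        max_copies = max(per_genome.values(), default=0)
        r.repeat_class = classify_repeat(r, evidence, max_copies, evalue_is, high_copy_min)
    return library


def class_census(
    library: RepeatLibrary, elements: list[RepeatElement]
) -> pd.DataFrame:
    """Per-class counts of distinct repeat sequences and genomic copies.

    Column sums equal the library size and the element count, so nothing is
    double-counted or lost.
    """
    class_of = {r.name: r.repeat_class for r in library.repeats}
    seq_counts = Counter(r.repeat_class for r in library.repeats)
    copy_counts = Counter(
        class_of.get(e.repeat_id, "unclassified") for e in elements
    )
    rows = [
        {
            "repeat_class": c,
            "n_sequences": seq_counts.get(c, 0),
            "n_copies": copy_counts.get(c, 0),
        }
        for c in REPEAT_CLASSES
    ]
    return pd.DataFrame(rows).set_index("repeat_class")


def read_evidence_table(path) -> list[ProteinEvidence]:
    """Read a TSV with columns repeat_id, hit_description, evalue, category_hint."""
    df = pd.read_csv(path, sep="\t", dtype={"repeat_id": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ProteinEvidence(
                repeat_id=str(row.repeat_id),
                hit_description=str(row.hit_description),
                evalue=float(row.evalue),
                category_hint=str(row.category_hint),
            )
        )
    return out
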