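"""Shared fixtures: seeded random sequences and planted-repeat genomes."""

from __future__ import annotations

import numpy as np
import pytest

from hopscan.genome_model import AnnotatedReplicon
from hopscan.repeat_discovery import RepeatLibrary, RepeatSequence

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    out = bytearray(seq.encode())
    for pos in rng.choice(len(out), size=n_subs, replace=False):
        choices = [b for b in b"ACGT" if b != out[pos]]
        out[pos] = choices[int(rng.integers(0, 3))]
    return out.decode()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260930)


@pytest.fixture
def toy_library(rng) -> RepeatLibrary:
    """Three unrelated random repeats of distinct lengths."""
    return RepeatLibrary(
        repeats=[
            RepeatSequence(id="A", name="A", source="de_novo", sequence=random_seq(rng, 800)),
            RepeatSequence(id="B", name="B", source="de_novo", sequence=random_seq(rng, 1100)),
            RepeatSequence(id="C", name="C", source="de_novo", sequence=random_seq(rng, 600)),
        ]
    )


def replicon_with(inserts: list[tuple[int, str]], background: str, rid: str = "chr") -> AnnotatedReplicon:
    """Background sequence with pieces inserted at the given positions
    (positions refer to the background, applied right to left)."""
    seq = background
    for pos, piece in sorted(inserts, reverse=True):
        seq = seq[:pos] + piece + seq[pos:]
    return AnnotatedReplicon(id=rid, length_bp=len(seq), topology="linear", sequence=seq)
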