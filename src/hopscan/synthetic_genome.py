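"""Forward simulator of IS-bearing replicons with a replayable event log.

The simulator builds a random background genome with uniformly spaced
genes, seeds a configurable number of IS species (random consensus
sequences), and then applies transposition events one at a time.  Each
event picks a random extant copy; its destination is drawn from a signed
exponential displacement kernel around the source (a "local hop") with
probability ``p_local``, otherwise uniformly.  With probability
``p_copy_paste`` the source copy stays (replicative transposition),
otherwise it is excised (cut-and-paste).  The moved or newly created copy
receives Binomial(len, sub_rate) substitutions — mutation load accrues per
transposition event, so copies separated by more events have diverged
more.  An insertion landing inside a gene pseudogenizes it with
probability ``p_pseudogenize``.  Optional truncation events clip a uniform
fraction from one end of a copy, deleting the clipped bases from the
genome.

Every random draw is recorded in a :class:`TruthLog`; replaying the log
from the initial genome reproduces the final genome byte for byte, and the
final element/pseudogene truth supports recall/precision scoring of the
annotation pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .genome_model import AnnotatedReplicon, GeneFeature, GenomicInterval, RepeatElement
from .repeat_discovery import RepeatLibrary, RepeatSequence

__all__ = [
    "SimulationConfig",
    "TruthLog",
    "TruthComparison",
    "simulate",
    "replay",
    "truth_compare",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the forward simulation; defaults give a mid-size replicon
    with a moderately active, locally hopping IS population."""

    seed: int
    replicon_bp: int = 1_000_000
    topology: str = "circular"
    n_genes: int = 800
    gene_len_bp: int = 900
    n_is_species: int = 5
    is_len_bp: int = 1000
    initial_copies: int = 2
    n_transpositions: int = 100
    p_copy_paste: float = 0.5
    p_local: float = 1.0
    local_scale_bp: float = 50_000.0
    sub_rate: float = 0.005
    p_pseudogenize: float = 0.5
    p_truncate: float = 0.0
    truncate_frac_range: tuple[float, float] = (0.1, 0.85)
    background_pseudo_rate: float = 0.05

    def validate(self) -> None:
        for name in (
            "p_copy_paste",
            "p_local",
            "sub_rate",
            "p_pseudogenize",
            "p_truncate",
            "background_pseudo_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0 < self.local_scale_bp < self.replicon_bp:
            raise ValueError("local_scale_bp must be in (0, replicon_bp)")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"bad topology {self.topology!r}")
        if self.n_genes * self.gene_len_bp >= self.replicon_bp:
            raise ValueError("genes do not fit on the replicon")
        lo, hi = self.truncate_frac_range
        if not 0.0 <= lo <= hi < 1.0:
            raise ValueError("truncate_frac_range must satisfy 0 <= lo <= hi < 1")


@dataclass
class TruthLog:
    """Replayable event history plus planted final truth."""

    config: SimulationConfig
    initial_sequence: str
    initial_genes: list[GeneFeature]
    species: dict[str, str]  # species name -> consensus sequence
    events: list[dict] = field(default_factory=list)
    final_elements: list[RepeatElement] = field(default_factory=list)
    final_pseudo_loci: list[str] = field(default_factory=list)

    def events_json(self) -> str:
        return json.dumps(self.events, indent=None, separators=(",", ":"))


class _SimState:
    """Mutable genome state shared by the simulator and the replayer."""

    def __init__(self, sequence: bytes, genes: list[GeneFeature]) -> None:
        self.seq = bytearray(sequence)
        self.genes = [replace(g) for g in genes]
        self.elements: list[dict] = []  # id, species, start, end

    # -- coordinate maintenance -------------------------------------------

    def _shift_insert(self, pos: int, length: int) -> None:
        for g in self.genes:
            if g.start >= pos:
                g.start += length
                g.end += length
            elif g.start < pos < g.end:
                g.end += length  # interrupted feature keeps its total extent
        for e in self.elements:
            if e["start"] >= pos:
                e["start"] += length
                e["end"] += length
            # elements are never interrupted: collisions are re-drawn

    def _shift_delete(self, ds: int, de: int) -> None:
        length = de - ds

        def newpos(x: int) -> int:
            return x - (min(x, de) - min(x, ds))

        for g in self.genes:
            g.start, g.end = newpos(g.start), newpos(g.end)
        for e in self.elements:
            e["start"], e["end"] = newpos(e["start"]), newpos(e["end"])

    # -- primitive operations ---------------------------------------------

    def insert(self, pos: int, piece: bytes) -> None:
        self.seq[pos:pos] = piece
        self._shift_insert(pos, len(piece))

    def delete(self, ds: int, de: int) -> bytes:
        removed = bytes(self.seq[ds:de])
        del self.seq[ds:de]
        self._shift_delete(ds, de)
        return removed

    def substitute(self, start: int, offsets: list[int], bases: list[int]) -> None:
        for off, b in zip(offsets, bases):
            self.seq[start + off] = b

    def gene_at(self, pos: int) -> GeneFeature | None:
        for g in self.genes:
            if g.start < pos < g.end:
                return g
        return None

    def element_by_id(self, eid: str) -> dict:
        for e in self.elements:
            if e["id"] == eid:
                return e
        raise KeyError(eid)

    def collides(self, pos: int) -> bool:
        return any(e["start"] < pos < e["end"] for e in self.elements)

    # -- event application (used identically by simulate and replay) ------

    def apply_event(self, ev: dict) -> None:
        etype = ev["type"]
        if etype == "insertion":
            piece = ev["piece"].encode()
            self.insert(ev["pos"], piece)
            new = {
                "id": ev["element_id"],
                "species": ev["species"],
                "start": ev["pos"],
                "end": ev["pos"] + len(piece),
            }
            self.elements.append(new)
            self.substitute(new["start"], ev["sub_offsets"], [ord(c) for c in ev["sub_bases"]])
            for locus in ev["pseudogenized"]:
                for g in self.genes:
                    if g.locus_id == locus:
                        g.is_pseudo = True
        elif etype == "excision":
            e = self.element_by_id(ev["element_id"])
            self.delete(e["start"], e["end"])
            self.elements.remove(e)
        elif etype == "truncation":
            e = self.element_by_id(ev["element_id"])
            cut = ev["cut_bp"]
            if ev["side"] == "left":
                self.delete(e["start"], e["start"] + cut)
            else:
                self.delete(e["end"] - cut, e["end"])
        else:
            raise ValueError(f"unknown event type {etype!r}")


def _random_sequence(rng: np.random.Generator, n: int) -> bytes:
    return _BASES[rng.integers(0, 4, n)].tobytes()


def _draw_substitutions(
    rng: np.random.Generator, seq: bytes, sub_rate: float
) -> tuple[list[int], str]:
    k = int(rng.binomial(len(seq), sub_rate))
    if k == 0:
        return [], ""
    offsets = sorted(int(o) for o in rng.choice(len(seq), size=k, replace=False))
    bases = []
    for off in offsets:
        cur = seq[off]
        choices = [b for b in b"ACGT" if b != cur]
        bases.append(chr(choices[int(rng.integers(0, 3))]))
    return offsets, "".join(bases)


def simulate(
    config: SimulationConfig,
) -> tuple[AnnotatedReplicon, RepeatLibrary, TruthLog]:
    """Run the forward simulation; deterministic under ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # background genome with uniformly spaced genes
    background = _random_sequence(rng, config.replicon_bp)
    spacing = config.replicon_bp / config.n_genes
    genes: list[GeneFeature] = []
    offset = (spacing - config.gene_len_bp) / 2
    for i in range(config.n_genes):
        start = int(i * spacing + offset)
        genes.append(
            GeneFeature(
                locus_id=f"g{i + 1:05d}",
                start=start,
                end=start + config.gene_len_bp,
                strand="+" if rng.random() < 0.5 else "-",
                is_pseudo=bool(rng.random() < config.background_pseudo_rate),
            )
        )

    species = {
        f"ISsim{k + 1}": _random_sequence(rng, config.is_len_bp).decode()
        for k in range(config.n_is_species)
    }

    log = TruthLog(
        config=config,
        initial_sequence=background.decode(),
        initial_genes=[replace(g) for g in genes],
        species=species,
    )
    state = _SimState(background, genes)
    eid_counter = 0

    def draw_insertion_pos(center: float | None) -> int | None:
        """Destination draw with collision re-draws (<= 100 attempts)."""
        L = len(state.seq)
        for _ in range(100):
            if center is None or rng.random() >= config.p_local:
                pos = int(rng.integers(0, L + 1))
            else:
                disp = rng.exponential(config.local_scale_bp)
                disp = disp if rng.random() < 0.5 else -disp
                pos = int(round(center + disp))
                if config.topology == "circular":
                    pos %= L + 1
                elif not 0 <= pos <= L:
                    continue
            if not state.collides(pos):
                return pos
        return None

    def record_insertion(
        pos: int, species_name: str, piece: bytes, src_mid: float | None = None
    ) -> None:
        nonlocal eid_counter
        eid_counter += 1
        offsets, bases = _draw_substitutions(rng, piece, config.sub_rate)
        host = state.gene_at(pos)
        pseudogenized = []
        if host is not None and not host.is_pseudo:
            if rng.random() < config.p_pseudogenize:
                pseudogenized.append(host.locus_id)
        ev = {
            "type": "insertion",
            "element_id": f"e{eid_counter}",
            "species": species_name,
            "pos": pos,
            "src_mid": src_mid,  # hop origin, for displacement diagnostics
            "piece": piece.decode(),
            "sub_offsets": offsets,
            "sub_bases": bases,
            "pseudogenized": pseudogenized,
        }
        state.apply_event(ev)
        log.events.append(ev)

    # initial placement, recorded as ordinary insertion events
    for name in species:
        for _ in range(config.initial_copies):
            pos = draw_insertion_pos(None)
            if pos is None:
                log.events.append({"type": "skip", "reason": "no insertion site"})
                continue
            record_insertion(pos, name, species[name].encode())

    # transpositions
    for _ in range(config.n_transpositions):
        if not state.elements:
            break
        src = state.elements[int(rng.integers(0, len(state.elements)))]
        src_piece = bytes(state.seq[src["start"] : src["end"]])
        copy = bool(rng.random() < config.p_copy_paste)
        center = (src["start"] + src["end"]) / 2
        if not copy:
            ev = {"type": "excision", "element_id": src["id"]}
            # destination center keeps the pre-excision coordinate sense:
            # positions left of the source are unaffected by the deletion,
            # and the kernel is symmetric, so re-centre after deleting.
            state.apply_event(ev)
            log.events.append(ev)
            center = min(center, len(state.seq))
        pos = draw_insertion_pos(center)
        if pos is None:
            log.events.append({"type": "skip", "reason": "destination collision"})
            continue
        record_insertion(pos, src["species"], src_piece, src_mid=center)

    # truncation pass
    if config.p_truncate > 0:
        lo, hi = config.truncate_frac_range
        for e in list(state.elements):
            if rng.random() >= config.p_truncate:
                continue
            frac = float(rng.uniform(lo, hi))
            cut = int(round(frac * (e["end"] - e["start"])))
            if cut <= 0 or cut >= e["end"] - e["start"]:
                continue
            ev = {
                "type": "truncation",
                "element_id": e["id"],
                "side": "left" if rng.random() < 0.5 else "right",
                "cut_bp": cut,
            }
            state.apply_event(ev)
            log.events.append(ev)

    # assemble outputs
    replicon_id = f"sim_seed{config.seed}"
    elements = [
        RepeatElement(
            repeat_id=e["species"],
            interval=GenomicInterval(replicon_id, e["start"], e["end"]),
            strand="+",
            fraction_full=(e["end"] - e["start"]) / config.is_len_bp,
        )
        for e in sorted(state.elements, key=lambda e: e["start"])
    ]
    replicon = AnnotatedReplicon(
        id=replicon_id,
        length_bp=len(state.seq),
        topology=config.topology,
        sequence=state.seq.decode(),
        features=state.genes,
        elements=elements,
    )
    library = RepeatLibrary(
        repeats=[
            RepeatSequence(
                id=name,
                name=name,
                source="reference_catalogue",
                sequence=seq,
                repeat_class="isfinder_is",
            )
            for name, seq in species.items()
        ],
        provenance=[f"simulated IS species, seed={config.seed}"],
    )
    log.final_elements = elements
    log.final_pseudo_loci = [g.locus_id for g in state.genes if g.is_pseudo]
    return replicon, library, log


def replay(log: TruthLog) -> str:
    """Re-apply the recorded events to the initial genome; returns the
    final sequence (must equal the simulated one byte for byte)."""
    state = _SimState(log.initial_sequence.encode(), log.initial_genes)
    for ev in log.events:
        if ev["type"] == "skip":
            continue
        state.apply_event(ev)
    return state.seq.decode()


# ---------------------------------------------------------------------------
# truth comparison
# ---------------------------------------------------------------------------

@dataclass
class TruthComparison:
    """Recall/precision of called elements against the planted truth."""

    recall: float
    precision: float
    n_truth: int
    n_called: int
    n_matched: int
    mean_boundary_error_bp: float
    frac_within_slack: float


def truth_compare(
    called: list[RepeatElement],
    truth: TruthLog | list[RepeatElement],
    slack_bp: int = 20,
    min_truth_fraction: float = 0.0,
    min_overlap: float = 0.8,
) -> TruthComparison:
    """Match called elements to planted truth and score the calling.

    A call matches a truth element when both carry the same repeat id and
    their intervals overlap reciprocally by at least ``min_overlap``.
    Truth elements below ``min_truth_fraction`` of full length are ignored
    on the recall side (and their matching calls are excluded from the
    precision denominator, so heavily eroded copies are neither required
    nor penalised).
    """
    truth_elements = truth.final_elements if isinstance(truth, TruthLog) else truth
    scored_truth = [t for t in truth_elements if t.fraction_full >= min_truth_fraction]
    small_truth = [t for t in truth_elements if t.fraction_full < min_truth_fraction]
    matched_truth: set[int] = set()
    matched_calls: set[int] = set()
    boundary_errors: list[float] = []
    for ci, c in enumerate(called):
        best = None
        for ti, t in enumerate(scored_truth):
            if ti in matched_truth or t.repeat_id != c.repeat_id:
                continue
            ov = c.interval.overlap(t.interval)
            if ov >= min_overlap * max(c.interval.length, t.interval.length):
                if best is None or ov > best[1]:
                    best = (ti, ov)
        if best is not None:
            ti = best[0]
            matched_truth.add(ti)
            matched_calls.add(ci)
            t = scored_truth[ti]
            boundary_errors.append(
                (
                    abs(c.interval.start - t.interval.start)
                    + abs(c.interval.end - t.interval.end)
                )
                / 2.0
            )
    # calls explained by sub-threshold truth are excluded from precision
    excused: set[int] = set()
    for ci, c in enumerate(called):
        if ci in matched_calls:
            continue
        for t in small_truth:
            if t.repeat_id == c.repeat_id and c.interval.overlap(t.interval) > 0:
                excused.add(ci)
                break
    n_eval_calls = len(called) - len(excused)
    recall = len(matched_truth) / len(scored_truth) if scored_truth else 1.0
    precision = len(matched_calls) / n_eval_calls if n_eval_calls else 1.0
    within = (
        sum(1 for b in boundary_errors if b <= slack_bp) / len(boundary_errors)
        if boundary_errors
        else 1.0
    )
    return TruthComparison(
        recall=recall,
        precision=precision,
        n_truth=len(scored_truth),
        n_called=len(called),
        n_matched=len(matched_truth),
        mean_boundary_error_bp=float(np.mean(boundary_errors)) if boundary_errors else 0.0,
        frac_within_slack=within,
    )
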