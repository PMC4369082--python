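"""Reproducible validation experiments on synthetic data.

Each benchmark regenerates its inputs from a seed, runs the relevant part
of the pipeline, and returns summary numbers.  They back the acceptance
test suite and the ``scripts/acceptance.py`` report; problem sizes are the
package's standard validation conditions (see docs/methods.md).
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .footprint_mapping import Footprint, decompose_footprint, scan_replicon
from .genome_model import AnnotatedReplicon, GenomicInterval, RepeatElement
from .repeat_discovery import RepeatLibrary, RepeatSequence
from .spatial_stats import (
    cluster_probability,
    hopping_regression,
    pdistance_pairs,
    pseudogene_enrichment,
    scan_clusters,
    wilcoxon_rank_sum,
)
from .synthetic_genome import SimulationConfig, simulate, truth_compare

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


# ---------------------------------------------------------------------------
# 1. footprint decomposition oracle
# ---------------------------------------------------------------------------

def footprint_decomposition_benchmark(seed: int, n_footprints: int = 100) -> dict:
    """Decompose constructed footprints with planted truth.

    Motifs: nested (A inside B), tandem (A+A), truncated single copy, and
    triple-nested (C inside A inside B).  Returns the fraction of footprints
    whose tile attribution exactly matches the construction and the worst
    boundary error in bp.
    """
    rng = np.random.default_rng(seed)
    A = RepeatSequence(id="A", name="A", source="de_novo", sequence=_rand_seq(rng, 800))
    B = RepeatSequence(id="B", name="B", source="de_novo", sequence=_rand_seq(rng, 1100))
    C = RepeatSequence(id="C", name="C", source="de_novo", sequence=_rand_seq(rng, 600))
    library = RepeatLibrary(repeats=[A, B, C])
    motifs = ("nested", "tandem", "truncated", "triple_nested")
    n_correct = 0
    max_boundary = 0.0
    for i in range(n_footprints):
        motif = motifs[i % len(motifs)]
        if motif == "nested":
            cut = int(rng.integers(200, 900))
            seq = B.sequence[:cut] + A.sequence + B.sequence[cut:]
            truth = [("B", 0, cut), ("A", cut, cut + 800), ("B", cut + 800, 1100 + 800)]
        elif motif == "tandem":
            seq = A.sequence + A.sequence
            truth = [("A", 0, 800), ("A", 800, 1600)]
        elif motif == "truncated":
            keep = int(rng.integers(200, 700))
            seq = A.sequence[:keep]
            truth = [("A", 0, keep)]
        else:  # triple_nested
            cut_b = int(rng.integers(200, 900))
            cut_a = int(rng.integers(100, 700))
            inner = A.sequence[:cut_a] + C.sequence + A.sequence[cut_a:]
            seq = B.sequence[:cut_b] + inner + B.sequence[cut_b:]
            truth = [
                ("B", 0, cut_b),
                ("A", cut_b, cut_b + cut_a),
                ("C", cut_b + cut_a, cut_b + cut_a + 600),
                ("A", cut_b + cut_a + 600, cut_b + 1400),
                ("B", cut_b + 1400, cut_b + 1400 + (1100 - cut_b)),
            ]
        bg = _rand_seq(rng, 4000)
        genome = bg[:2000] + seq + bg[2000:]
        rep = AnnotatedReplicon(id=f"fp{i}", length_bp=len(genome), sequence=genome)
        fp = Footprint(interval=GenomicInterval(rep.id, 2000, 2000 + len(seq)))
        dec = decompose_footprint(fp, library, rep.sequence)
        called = [
            (e.repeat_id, e.interval.start - 2000, e.interval.end - 2000)
            for e in dec.elements
        ]
        ok = len(called) == len(truth) and all(
            c[0] == t[0] and abs(c[1] - t[1]) <= 20 and abs(c[2] - t[2]) <= 20
            for c, t in zip(called, truth)
        )
        if ok:
            n_correct += 1
            max_boundary = max(
                max_boundary,
                max(
                    max(abs(c[1] - t[1]), abs(c[2] - t[2]))
                    for c, t in zip(called, truth)
                ),
            )
    return {
        "attribution_accuracy": n_correct / n_footprints,
        "max_boundary_error_bp": max_boundary,
        "n": n_footprints,
    }


# ---------------------------------------------------------------------------
# 2. binomial cluster probability exactness
# ---------------------------------------------------------------------------

def binomial_exactness_benchmark(seed: int, mc_draws: int = 100_000) -> dict:
    """Exhaustive-sum agreement (n <= 6) and Monte-Carlo placement check."""
    max_diff = 0.0
    for n in range(1, 7):
        for x in range(1, n + 1):
            for w in (0.01, 0.1, 0.3, 0.5, 0.9):
                exact = sum(
                    math.comb(n - 1, k) * w**k * (1 - w) ** (n - 1 - k)
                    for k in range(x - 1, n)
                )
                got = cluster_probability(x, n, w * 1e6, 1e6)
                max_diff = max(max_diff, abs(got - exact))
    rng = np.random.default_rng(seed)
    max_z = 0.0
    for n, x, w in ((4, 3, 0.1), (5, 3, 0.12), (6, 4, 0.25)):
        draws = rng.random((mc_draws, n - 1))
        freq = float(np.mean((draws < w).sum(axis=1) >= x - 1))
        model = cluster_probability(x, n, w * 1e6, 1e6)
        se = math.sqrt(model * (1 - model) / mc_draws)
        max_z = max(max_z, abs(freq - model) / se)
    return {"max_abs_error": max_diff, "mc_max_z": max_z, "n": mc_draws}


# ---------------------------------------------------------------------------
# 3. cluster-scan calibration
# ---------------------------------------------------------------------------

def cluster_calibration_benchmark(
    seed: int, n_reps: int = 500, n_elements: int = 5
) -> dict:
    """Type-I error of the scan headline under uniform element placement."""
    rng = np.random.default_rng(seed)
    rep = AnnotatedReplicon(id="cal", length_bp=5_000_000, topology="linear")
    rejections = 0
    for _ in range(n_reps):
        mids = rng.uniform(1000, rep.length_bp - 1000, n_elements)
        els = [
            RepeatElement(
                "ISx", GenomicInterval("cal", int(m) - 500, int(m) + 500),
                fraction_full=1.0,
            )
            for m in mids
        ]
        tests = scan_clusters(els, rep)
        if tests and tests[0].headline_p < 0.05:
            rejections += 1
    return {"false_positive_rate": rejections / n_reps, "n": n_reps}


# ---------------------------------------------------------------------------
# 4. local-hopping recovery
# ---------------------------------------------------------------------------

def _hopping_config(seed: int, p_local: float) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        replicon_bp=5_000_000,
        n_genes=50,
        n_is_species=1,
        is_len_bp=1000,
        initial_copies=1,
        n_transpositions=39,  # grows 1 copy into 40
        p_copy_paste=1.0,
        p_local=p_local,
        local_scale_bp=50_000,
        sub_rate=0.005,
        p_pseudogenize=0.0,
        background_pseudo_rate=0.0,
    )


def hopping_recovery_benchmark(seed: int, n_reps: int = 50) -> dict:
    """Slope detection rate with the local kernel on vs off.

    Each replicate simulates one IS expanding to 40 copies, computes
    pairwise p-distances of near-full-length copies against their genomic
    separation, and fits the regression.  Detection = positive slope with
    p < 0.05.
    """
    out = {}
    for label, p_local in (("local", 1.0), ("uniform", 0.0)):
        detected = 0
        used = 0
        for r in range(n_reps):
            rep, _, _ = simulate(_hopping_config(seed + 1000 * (p_local == 0) + r, p_local))
            pairs = pdistance_pairs(rep, rep.elements, min_fraction=0.90)
            if len(pairs) < 3:
                continue
            used += 1
            try:
                fit = hopping_regression(pairs, "ISsim1")
            except ValueError:
                continue
            if fit.slope_per_mbp > 0 and fit.p_value < 0.05:
                detected += 1
        out[f"{label}_detection_rate"] = detected / used if used else float("nan")
        out[f"{label}_n"] = used
    return out


# ---------------------------------------------------------------------------
# 5. pseudogene-enrichment recovery
# ---------------------------------------------------------------------------

def _enrichment_signal_config(seed: int) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        replicon_bp=1_000_000,
        n_genes=700,
        gene_len_bp=900,
        n_is_species=1,
        initial_copies=2,
        n_transpositions=60,
        p_copy_paste=0.8,
        p_local=1.0,
        local_scale_bp=50_000,
        sub_rate=0.005,
        p_pseudogenize=0.9,
        background_pseudo_rate=0.02,
    )


def _enrichment_null_config(seed: int) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        replicon_bp=1_000_000,
        n_genes=700,
        gene_len_bp=900,
        n_is_species=1,
        initial_copies=40,
        n_transpositions=0,
        p_local=0.0,
        sub_rate=0.0,
        p_pseudogenize=0.0,
        background_pseudo_rate=0.05,
    )


def enrichment_recovery_benchmark(
    seed: int, n_signal: int = 50, n_null: int = 200
) -> dict:
    """Enrichment detection with insertional pseudogenization on vs off.

    Signal: transposing IS pseudogenizes 90% of hit genes; detection =
    5 kbp enrichment ratio >= 1.3 with Wilcoxon p < 0.05.  Null: uniform IS
    placement, background pseudogenes only.
    """
    detected = 0
    ratios = []
    for r in range(n_signal):
        rep, _, _ = simulate(_enrichment_signal_config(seed + r))
        prof = pseudogene_enrichment([rep], distances=(5_000,))
        ratios.append(prof.enrichment_ratio[0])
        if prof.enrichment_ratio[0] >= 1.3 and prof.wilcoxon_p[0] < 0.05:
            detected += 1
    null_ratios = []
    null_rejections = 0
    for r in range(n_null):
        rep, _, _ = simulate(_enrichment_null_config(seed + 10_000 + r))
        prof = pseudogene_enrichment([rep], distances=(5_000,))
        if np.isfinite(prof.enrichment_ratio[0]):
            null_ratios.append(prof.enrichment_ratio[0])
        if prof.wilcoxon_p[0] < 0.05:
            null_rejections += 1
    return {
        "signal_detection_rate": detected / n_signal,
        "signal_mean_ratio_5kbp": float(np.mean(ratios)),
        "null_mean_ratio_5kbp": float(np.mean(null_ratios)),
        "null_rejection_rate": null_rejections / n_null,
        "n_signal": n_signal,
        "n_null": n_null,
    }


# ---------------------------------------------------------------------------
# 6. Wilcoxon exactness
# ---------------------------------------------------------------------------

def wilcoxon_exactness_benchmark(max_total: int = 8) -> dict:
    """Exact path versus full enumeration for every tie-free split."""
    max_diff = 0.0
    n_checked = 0
    for n in range(2, max_total + 1):
        values = list(range(1, n + 1))
        for na in range(1, n):
            for a_idx in itertools.combinations(range(n), na):
                a = [values[i] for i in a_idx]
                b = [values[i] for i in range(n) if i not in a_idx]
                _, p = wilcoxon_rank_sum(a, b)
                sums = [sum(c) for c in itertools.combinations(values, na)]
                mean = float(np.mean(sums))
                obs = sum(a)
                p_oracle = float(
                    np.mean([abs(s - mean) >= abs(obs - mean) - 1e-12 for s in sums])
                )
                max_diff = max(max_diff, abs(p - p_oracle))
                n_checked += 1
    return {"max_abs_error": max_diff, "n": n_checked}


# ---------------------------------------------------------------------------
# 7. end-to-end pipeline on a simulated genome
# ---------------------------------------------------------------------------

def _end_to_end_config(seed: int) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        replicon_bp=5_000_000,
        n_genes=500,
        n_is_species=20,
        initial_copies=2,
        n_transpositions=160,
        p_copy_paste=0.8,
        p_local=0.5,
        local_scale_bp=50_000,
        sub_rate=0.02,
        p_pseudogenize=0.5,
        p_truncate=0.15,
    )


def end_to_end_benchmark(seed: int) -> dict:
    """Simulate, scan with the truth library, score against planted truth.

    Recall/precision are evaluated for planted copies of at least half
    their reference length; the scan is run twice on independently rebuilt
    inputs to confirm byte-identical determinism.
    """
    results = []
    for _ in range(2):
        rep, library, log = simulate(_end_to_end_config(seed))
        elements, _, _ = scan_replicon(rep, library)
        rows = "\n".join(
            f"{e.repeat_id}\t{e.interval.start}\t{e.interval.end}\t{e.strand}"
            f"\t{e.fraction_full:.4f}"
            for e in elements
        )
        results.append((elements, rows, log))
    elements, rows, log = results[0]
    tc = truth_compare(elements, log, min_truth_fraction=0.5)
    return {
        "recall": tc.recall,
        "precision": tc.precision,
        "mean_boundary_error_bp": tc.mean_boundary_error_bp,
        "deterministic": float(results[0][1] == results[1][1]),
        "n": tc.n_truth,
    }
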