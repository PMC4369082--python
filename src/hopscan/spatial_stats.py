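"""Spatial statistics for insertion-sequence elements.

Three analyses:

* **Cluster probability** — for x of n elements of one repeat found inside a
  window of w bp on a replicon of L bp, the chance under uniform placement is
  P(Binomial(n-1, w/L) >= x-1): one element anchors the window with
  certainty, the remaining n-1 are independent Bernoulli trials.  Because a
  scanned window's ends are themselves data-chosen order statistics, the
  scan's *headline* p-value is computed from the exact null law of the span
  of x consecutive order statistics (Beta(x-1, n-x+2)), Bonferroni-corrected
  over all windows tested, which keeps the scan's type-I error at or below
  the nominal level.

* **Local-hopping regression** — uncorrected p-distance (percentage units)
  of element pairs regressed on their genomic separation (Mbp) by OLS; a
  positive slope (equivalently, identity decreasing with separation) is the
  local-hopping signature.

* **Pseudogene-proximity enrichment** — mean pseudogene count within a set
  of distances of IS elements versus annotated genes, ratio plus two-sided
  Wilcoxon rank-sum test, with variants excluding IS-like pseudogenes or
  pseudogenes within 1 kb of the focal feature.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import AnnotatedReplicon, RepeatElement, separation

__all__ = [
    "ClusterTest",
    "PDistancePair",
    "HoppingFit",
    "EnrichmentProfile",
    "DEFAULT_ENRICHMENT_DISTANCES",
    "cluster_probability",
    "scan_clusters",
    "p_distance",
    "pdistance_pairs",
    "hopping_regression",
    "pooled_hopping_regression",
    "pseudogene_enrichment",
    "wilcoxon_rank_sum",
    "enrichment_heatmap_table",
]

DEFAULT_ENRICHMENT_DISTANCES = (5_000, 10_000, 50_000, 100_000, 200_000, 500_000)


# ---------------------------------------------------------------------------
# binomial clustering test
# ---------------------------------------------------------------------------

def cluster_probability(
    x_in_window: int, n_total: int, window_bp: float, replicon_bp: float
) -> float:
    """P(Binomial(n_total-1, window_bp/replicon_bp) >= x_in_window-1).

    The probability that at least x of the replicon's n elements fall in a
    window of the given size by chance, with one element anchoring the
    window ("there is a 100% chance of one element being somewhere").
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 1 <= x_in_window <= n_total:
        raise ValueError("need 1 <= x_in_window <= n_total")
    if window_bp > replicon_bp:
        raise ValueError("window larger than replicon")
    p = window_bp / replicon_bp
    # P(X >= x-1) for X ~ Bin(n-1, p); sf(k) = P(X > k)
    return float(stats.binom.sf(x_in_window - 2, n_total - 1, p))


@dataclass
class ClusterTest:
    """One scanned window of consecutive qualifying elements."""

    repeat_id: str
    window_bp: float
    x_in_window: int
    n_total: int
    success_p: float
    probability: float  # the binomial probability above (the per-window statistic)
    headline_p: float  # calibrated scan p-value (Beta span law, Bonferroni)
    window_start_mid: float
    window_end_mid: float


def scan_clusters(
    elements: list[RepeatElement],
    replicon: AnnotatedReplicon,
    min_fraction: float = 0.70,
) -> list[ClusterTest]:
    """Scan every window of consecutive qualifying elements of one repeat.

    Elements qualify when ``fraction_full > min_fraction``.  For each window
    (i..j) over the position-sorted qualifying elements the paper-style
    binomial probability is reported, together with a calibrated headline
    p-value: the exact probability that the span of x consecutive uniform
    order statistics (out of n) is as small as observed —
    Beta(x-1, n-x+2) — Bonferroni-corrected for the number of windows
    scanned.  Results are sorted by headline p-value; fewer than two
    qualifying elements yield an empty list.
    """
    qual = [e for e in elements if e.fraction_full > min_fraction]
    rids = {e.repeat_id for e in qual}
    if len(rids) > 1:
        raise ValueError(f"scan_clusters expects one repeat, got {sorted(rids)}")
    if len(qual) < 2:
        return []
    repeat_id = qual[0].repeat_id
    L = float(replicon.length_bp)
    mids = np.sort([e.interval.midpoint for e in qual])
    n = len(mids)
    n_windows = n * (n - 1) // 2
    out: list[ClusterTest] = []
    for i, j in itertools.combinations(range(n), 2):
        x = j - i + 1
        w = mids[j] - mids[i]
        raw = cluster_probability(x, n, w, L)
        span_p = float(stats.beta.cdf(w / L, x - 1, n - x + 2))
        out.append(
            ClusterTest(
                repeat_id=repeat_id,
                window_bp=w,
                x_in_window=x,
                n_total=n,
                success_p=w / L if L else 0.0,
                probability=raw,
                headline_p=min(1.0, span_p * n_windows),
                window_start_mid=float(mids[i]),
                window_end_mid=float(mids[j]),
            )
        )
    out.sort(key=lambda t: (t.headline_p, t.probability, t.window_bp))
    return out


# ---------------------------------------------------------------------------
# p-distance and local-hopping regression
# ---------------------------------------------------------------------------

def p_distance(seq_a: str, seq_b: str) -> float:
    """Uncorrected p-distance from a global pairwise alignment.

    Differing columns (mismatches plus gapped columns) divided by aligned
    columns; gap-gap columns cannot occur in a pairwise alignment.  The
    alignment is the minimum-edit-cost global (Needleman-Wunsch) path.
    """
    if not seq_a or not seq_b:
        raise ValueError("p_distance of an empty sequence")
    if seq_a == seq_b:
        return 0.0
    # co-optimal edit paths can differ in column count; align in canonical
    # argument order so the statistic is exactly symmetric
    if (len(seq_b), seq_b) < (len(seq_a), seq_a):
        seq_a, seq_b = seq_b, seq_a
    res = edlib.align(seq_a, seq_b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, seq_a, seq_b)
    qa = np.frombuffer(nice["query_aligned"].encode(), dtype=np.uint8)
    ta = np.frombuffer(nice["target_aligned"].encode(), dtype=np.uint8)
    ncols = qa.size
    diffs = int((qa != ta).sum())
    return diffs / ncols


@dataclass(frozen=True)
class PDistancePair:
    """A pair of same-repeat elements with divergence and separation."""

    element_a: str
    element_b: str
    p_distance: float
    separation_bp: float

    @property
    def identity(self) -> float:
        return 1.0 - self.p_distance


def pdistance_pairs(
    replicon: AnnotatedReplicon,
    elements: list[RepeatElement],
    min_fraction: float = 0.90,
) -> list[PDistancePair]:
    """All within-replicon pairs of qualifying elements of one repeat.

    Only elements longer than ``min_fraction`` of their reference qualify;
    pairs never cross replicons.
    """
    qual = [e for e in elements if e.fraction_full > min_fraction]
    seqs = [replicon.element_sequence(e) for e in qual]
    labels = [
        f"{e.repeat_id}@{e.interval.start}-{e.interval.end}" for e in qual
    ]
    out = []
    for i, j in itertools.combinations(range(len(qual)), 2):
        out.append(
            PDistancePair(
                element_a=labels[i],
                element_b=labels[j],
                p_distance=p_distance(seqs[i], seqs[j]),
                separation_bp=separation(
                    qual[i].interval, qual[j].interval, replicon
                ),
            )
        )
    return out


@dataclass
class HoppingFit:
    """OLS fit of p-distance (percentage units) on separation (Mbp)."""

    repeat_id: str
    n_pairs: int
    slope_per_mbp: float
    intercept: float
    p_value: float
    r_value: float = float("nan")

    @property
    def identity_slope_per_mbp(self) -> float:
        """Slope in percent-identity units (the complementary convention)."""
        return -self.slope_per_mbp


def hopping_regression(
    pairs: list[PDistancePair], repeat_id: str = ""
) -> HoppingFit:
    """Fit p-distance (in %) against separation (in Mbp) by least squares.

    A positive slope with a small two-sided p-value is the local-hopping
    signature: nearby copies are more alike than distant ones.  Refuses
    fewer than 3 pairs or a separation column with zero variance.
    """
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 pairs for a fit, got {len(pairs)}")
    x = np.array([p.separation_bp for p in pairs]) / 1e6
    y = np.array([p.p_distance for p in pairs]) * 100.0
    if np.ptp(x) == 0:
        raise ValueError(
            "zero variance in separations: all pairs equally separated; "
            "slope is unidentifiable"
        )
    if np.ptp(y) == 0:
        # flat response: slope exactly 0, no evidence of trend
        return HoppingFit(repeat_id, len(pairs), 0.0, float(y[0]), 1.0, 0.0)
    res = stats.linregress(x, y)
    return HoppingFit(
        repeat_id=repeat_id,
        n_pairs=len(pairs),
        slope_per_mbp=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        r_value=float(res.rvalue),
    )


def pooled_hopping_regression(
    pairs_by_repeat: dict[str, list[PDistancePair]]
) -> HoppingFit:
    """One OLS over the pooled pair set of many repeats (and genomes)."""
    pooled = [p for pairs in pairs_by_repeat.values() for p in pairs]
    return hopping_regression(pooled, repeat_id="pooled")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null enumeration when the samples are small (n_a + n_b <= 12) and
    tie-free; otherwise the normal approximation with continuity and
    midrank tie correction.  Returns (U statistic of the first sample,
    p-value).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("wilcoxon_rank_sum: empty sample")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if a.size + b.size <= 12 and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(1.0, res.pvalue))


# ---------------------------------------------------------------------------
# pseudogene-proximity enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentProfile:
    """Per-distance pseudogene enrichment near IS elements vs genes."""

    distances: tuple[int, ...]
    mean_pseudo_near_is: list[float]
    mean_pseudo_near_gene: list[float]
    enrichment_ratio: list[float]  # nan when the gene-side mean is 0
    wilcoxon_p: list[float]
    variant: str = "all"
    computable: bool = True
    n_is: int = 0
    n_genes: int = 0
    n_pseudogenes: int = 0
    reason: str = ""

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance_bp": self.distances,
                "mean_pseudo_near_is": self.mean_pseudo_near_is,
                "mean_pseudo_near_gene": self.mean_pseudo_near_gene,
                "enrichment_ratio": self.enrichment_ratio,
                "wilcoxon_p": self.wilcoxon_p,
            }
        )


def _proximity_counts(
    focals: list[tuple[int, int]],
    pseudos: list[tuple[int, int]],
    d: int,
    self_index: dict[int, int],
    omit_gap: int | None,
) -> np.ndarray:
    """Count pseudogenes with closest-edge gap <= d of each focal interval.

    ``self_index`` maps positions in ``focals`` to positions in ``pseudos``
    for focal features that are themselves in the pseudogene set (excluded
    from their own count).  ``omit_gap`` drops pseudogenes closer than that
    gap (the "unidentified IS fragment" guard).
    """
    if not pseudos:
        return np.zeros(len(focals), dtype=float)
    ps = np.array([p[0] for p in pseudos])
    pe = np.array([p[1] for p in pseudos])
    order = np.argsort(ps, kind="stable")
    ps, pe = ps[order], pe[order]
    inv = np.empty_like(order)
    inv[order] = np.arange(order.size)
    max_len = int((pe - ps).max())
    counts = np.zeros(len(focals), dtype=float)
    lo_gap = omit_gap if omit_gap is not None else -1
    for i, (s, e) in enumerate(focals):
        lo = np.searchsorted(ps, s - d - max_len, side="left")
        hi = np.searchsorted(ps, e + d, side="right")
        if hi <= lo:
            continue
        gaps = np.maximum(0, np.maximum(ps[lo:hi] - e, s - pe[lo:hi]))
        mask = (gaps <= d) & (gaps >= lo_gap) if omit_gap is not None else gaps <= d
        j = self_index.get(i)
        if j is not None:
            k = inv[j] - lo
            if 0 <= k < mask.size:
                mask[k] = False
        counts[i] = mask.sum()
    return counts


def pseudogene_enrichment(
    replicons: list[AnnotatedReplicon],
    distances: tuple[int, ...] = DEFAULT_ENRICHMENT_DISTANCES,
    variant: str = "all",
    omit_gap: int = 1000,
) -> EnrichmentProfile:
    """Pseudogene counts near IS elements versus near annotated genes.

    For every IS element and every non-IS-like gene (pooled across all
    replicons), pseudogenes whose closest-edge gap is at most each distance
    are counted (the focal feature never counts itself).  Variants:
    ``all`` counts every pseudogene, ``native_only`` drops IS-like
    pseudogenes, ``omit_within_1kb`` drops pseudogenes closer than
    ``omit_gap`` to the focal feature.  The ratio of the two mean counts
    and a two-sided Wilcoxon rank-sum p-value are reported per distance.
    """
    if variant not in ("all", "native_only", "omit_within_1kb"):
        raise ValueError(f"unknown variant {variant!r}")
    is_counts: dict[int, list[np.ndarray]] = {d: [] for d in distances}
    gene_counts: dict[int, list[np.ndarray]] = {d: [] for d in distances}
    n_is = n_genes = n_pseudo = 0
    gap = omit_gap if variant == "omit_within_1kb" else None
    for rep in replicons:
        pseudo_feats = rep.pseudogenes(native_only=(variant == "native_only"))
        pseudos = [(f.start, f.end) for f in pseudo_feats]
        n_pseudo += len(pseudos)
        is_focals = [(e.interval.start, e.interval.end) for e in rep.elements]
        genes = [f for f in rep.features if not f.is_is_like]
        gene_focals = [(f.start, f.end) for f in genes]
        pseudo_pos = {id(f): k for k, f in enumerate(pseudo_feats)}
        gene_self = {
            i: pseudo_pos[id(f)]
            for i, f in enumerate(genes)
            if id(f) in pseudo_pos
        }
        n_is += len(is_focals)
        n_genes += len(gene_focals)
        for d in distances:
            is_counts[d].append(
                _proximity_counts(is_focals, pseudos, d, {}, gap)
            )
            gene_counts[d].append(
                _proximity_counts(gene_focals, pseudos, d, gene_self, gap)
            )
    if n_is == 0 or n_genes == 0:
        return EnrichmentProfile(
            distances=tuple(distances),
            mean_pseudo_near_is=[float("nan")] * len(distances),
            mean_pseudo_near_gene=[float("nan")] * len(distances),
            enrichment_ratio=[float("nan")] * len(distances),
            wilcoxon_p=[float("nan")] * len(distances),
            variant=variant,
            computable=False,
            n_is=n_is,
            n_genes=n_genes,
            n_pseudogenes=n_pseudo,
            reason="no IS elements" if n_is == 0 else "no genes",
        )
    mean_is, mean_gene, ratios, pvals = [], [], [], []
    for d in distances:
        ci = np.concatenate(is_counts[d])
        cg = np.concatenate(gene_counts[d])
        mi, mg = float(ci.mean()), float(cg.mean())
        mean_is.append(mi)
        mean_gene.append(mg)
        ratios.append(mi / mg if mg > 0 else float("nan"))
        if np.ptp(np.concatenate([ci, cg])) == 0:
            pvals.append(1.0)  # all counts identical; no evidence either way
        else:
            pvals.append(wilcoxon_rank_sum(ci, cg)[1])
    return EnrichmentProfile(
        distances=tuple(distances),
        mean_pseudo_near_is=mean_is,
        mean_pseudo_near_gene=mean_gene,
        enrichment_ratio=ratios,
        wilcoxon_p=pvals,
        variant=variant,
        computable=True,
        n_is=n_is,
        n_genes=n_genes,
        n_pseudogenes=n_pseudo,
    )


def enrichment_heatmap_table(
    profiles: dict[str, EnrichmentProfile], alpha: float = 0.05
) -> pd.DataFrame:
    """Genome x distance table of enrichment ratios with significance flags.

    Genomes with no annotated pseudogenes, non-computable profiles, or
    fewer than two significant distances are omitted.  Columns are
    ``ratio_<d>`` and ``sig_<d>`` per distance.
    """
    rows = {}
    for genome, prof in profiles.items():
        if not prof.computable or prof.n_pseudogenes == 0:
            continue
        sig = [
            (p < alpha) and np.isfinite(r)
            for p, r in zip(prof.wilcoxon_p, prof.enrichment_ratio)
        ]
        if sum(sig) < 2:
            continue
        row = {}
        for d, r, s in zip(prof.distances, prof.enrichment_ratio, sig):
            row[f"ratio_{d}"] = r
            row[f"sig_{d}"] = bool(s)
        rows[genome] = row
    return pd.DataFrame.from_dict(rows, orient="index")
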