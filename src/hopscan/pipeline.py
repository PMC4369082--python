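"""Pipeline configuration and the table-producing steps behind the CLI.

All thresholds live in one :class:`PipelineConfig` whose defaults are the
analysis' canonical values (hit E-value 1e-6, transposase-evidence E-value
1e-5, cluster qualification fraction 0.70, p-distance qualification 0.90,
full-length fraction 0.95, proximity distances 5..500 kbp, 1 kb omission
gap), so sensitivity analyses are config-only edits.  Outputs are plain
TSV with deterministic float formatting: identical config and seed give
byte-identical files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .footprint_mapping import occupancy_summary, scan_replicon
from .genome_model import AnnotatedReplicon
from .repeat_discovery import RepeatLibrary
from .spatial_stats import (
    DEFAULT_ENRICHMENT_DISTANCES,
    EnrichmentProfile,
    hopping_regression,
    pdistance_pairs,
    pooled_hopping_regression,
    pseudogene_enrichment,
    scan_clusters,
)

__all__ = ["PipelineConfig", "scan_tables", "stats_tables", "report_tables", "DATA_DICTIONARY"]


@dataclass
class PipelineConfig:
    """Every threshold of the pipeline in one place."""

    min_repeat_len: int = 500
    dedup_identity: float = 0.95
    dedup_coverage: float = 0.8
    evalue_hit: float = 1e-6
    evalue_is: float = 1e-5
    cluster_min_fraction: float = 0.70
    pdist_min_fraction: float = 0.90
    full_length: float = 0.95
    high_copy_min: int = 6
    min_leftover: int = 50
    merge_gap: int = 0
    omit_gap: int = 1000
    enrichment_distances: tuple[int, ...] = DEFAULT_ENRICHMENT_DISTANCES
    seed: int = 0

    def validate(self) -> None:
        for name in ("dedup_identity", "dedup_coverage", "cluster_min_fraction",
                     "pdist_min_fraction", "full_length"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")
        if self.evalue_hit <= 0 or self.evalue_is <= 0:
            raise ValueError("E-value thresholds must be positive")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# hopscan {__version__} configuration\n")
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if isinstance(v, tuple):
                    v = ",".join(str(x) for x in v)
                fh.write(f"{f.name}={v}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            f = types[key]
            if f.name == "enrichment_distances":
                kwargs[key] = tuple(int(x) for x in val.split(","))
            elif f.type in ("int",):
                kwargs[key] = int(val)
            else:
                kwargs[key] = float(val) if "." in val or "e" in val.lower() else int(val)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def _fmt(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def scan_tables(
    replicon: AnnotatedReplicon,
    library: RepeatLibrary,
    config: PipelineConfig,
    outdir: Path,
    prefix: str = "",
) -> AnnotatedReplicon:
    """Scan one replicon against a library; write hits/elements/occupancy
    TSVs and return the replicon with elements attached."""
    elements, footprints, unassigned = scan_replicon(
        replicon,
        library,
        evalue_max=config.evalue_hit,
        merge_gap=config.merge_gap,
        min_leftover=config.min_leftover,
    )
    replicon.elements = elements
    hit_rows = [
        {
            "replicon": h.interval.replicon_id,
            "repeat": h.repeat_id,
            "start": h.interval.start,
            "end": h.interval.end,
            "strand": h.strand,
            "score": h.score,
            "evalue": h.evalue,
            "qstart": h.repeat_span[0],
            "qend": h.repeat_span[1],
        }
        for fp in footprints
        for h in fp.hits
    ]
    _fmt(pd.DataFrame(hit_rows), outdir / f"{prefix}hits.tsv")
    classes = {r.name: r.repeat_class for r in library.repeats}
    el_rows = [
        {
            "replicon": e.interval.replicon_id,
            "repeat": e.repeat_id,
            "start": e.interval.start,
            "end": e.interval.end,
            "strand": e.strand,
            "fraction_full": round(e.fraction_full, 4),
            "full_length": e.fraction_full >= config.full_length,
            "score": e.score,
            "repeat_class": classes.get(e.repeat_id, "unclassified"),
        }
        for e in elements
    ]
    _fmt(pd.DataFrame(el_rows), outdir / f"{prefix}elements.tsv")
    un_rows = [
        {"replicon": iv.replicon_id, "start": iv.start, "end": iv.end}
        for iv in unassigned
    ]
    _fmt(pd.DataFrame(un_rows), outdir / f"{prefix}unassigned.tsv")
    occ = occupancy_summary([replicon], classes)
    _fmt(pd.DataFrame([dataclasses.asdict(occ)]), outdir / f"{prefix}occupancy.tsv")
    return replicon


def stats_tables(
    replicons: list[AnnotatedReplicon],
    config: PipelineConfig,
    outdir: Path,
    prefix: str = "",
) -> dict[str, EnrichmentProfile]:
    """Cluster scans, p-distance pairs, hopping fits and enrichment TSVs."""
    cluster_rows = []
    pair_rows = []
    fit_rows = []
    pairs_by_repeat: dict[str, list] = {}
    for rep in replicons:
        by_repeat: dict[str, list] = {}
        for e in rep.elements:
            by_repeat.setdefault(e.repeat_id, []).append(e)
        for rid in sorted(by_repeat):
            els = by_repeat[rid]
            for t in scan_clusters(els, rep, config.cluster_min_fraction)[:5]:
                cluster_rows.append(
                    {
                        "replicon": rep.id,
                        "repeat": rid,
                        "x_in_window": t.x_in_window,
                        "n_total": t.n_total,
                        "window_bp": round(t.window_bp, 1),
                        "binomial_probability": t.probability,
                        "headline_p": t.headline_p,
                    }
                )
            pairs = pdistance_pairs(rep, els, config.pdist_min_fraction)
            pairs_by_repeat.setdefault(rid, []).extend(pairs)
            for p in pairs:
                pair_rows.append(
                    {
                        "replicon": rep.id,
                        "repeat": rid,
                        "element_a": p.element_a,
                        "element_b": p.element_b,
                        "separation_bp": round(p.separation_bp, 1),
                        "p_distance": round(p.p_distance, 6),
                        "identity": round(p.identity, 6),
                    }
                )
            if len(pairs) >= 3:
                try:
                    fit = hopping_regression(pairs, rid)
                except ValueError:
                    continue
                fit_rows.append(
                    {
                        "repeat": rid,
                        "n_pairs": fit.n_pairs,
                        "slope_pdist_pct_per_mbp": fit.slope_per_mbp,
                        "slope_identity_pct_per_mbp": fit.identity_slope_per_mbp,
                        "intercept_pct": fit.intercept,
                        "p_value": fit.p_value,
                    }
                )
    all_pairs = [p for ps in pairs_by_repeat.values() for p in ps]
    if len(all_pairs) >= 3:
        try:
            fit = pooled_hopping_regression(pairs_by_repeat)
            fit_rows.append(
                {
                    "repeat": "POOLED",
                    "n_pairs": fit.n_pairs,
                    "slope_pdist_pct_per_mbp": fit.slope_per_mbp,
                    "slope_identity_pct_per_mbp": fit.identity_slope_per_mbp,
                    "intercept_pct": fit.intercept,
                    "p_value": fit.p_value,
                }
            )
        except ValueError:
            pass
    _fmt(pd.DataFrame(cluster_rows), outdir / f"{prefix}clusters.tsv")
    _fmt(pd.DataFrame(pair_rows), outdir / f"{prefix}pairs.tsv")
    _fmt(pd.DataFrame(fit_rows), outdir / f"{prefix}fits.tsv")
    profiles = {}
    enr_rows = []
    for variant in ("all", "native_only", "omit_within_1kb"):
        prof = pseudogene_enrichment(
            replicons, config.enrichment_distances, variant, config.omit_gap
        )
        profiles[variant] = prof
        df = prof.as_frame()
        df.insert(0, "variant", variant)
        enr_rows.append(df)
    _fmt(pd.concat(enr_rows, ignore_index=True), outdir / f"{prefix}enrichment.tsv")
    return profiles


DATA_DICTIONARY = """\
column	description
replicon	replicon identifier
repeat	repeat (library entry) name
start	0-based inclusive start of the interval
end	0-based exclusive end of the interval
strand	genomic strand of the hit/element
score	local alignment score (match/mismatch units)
evalue	Karlin-Altschul expectation of the hit
qstart	0-based start of the matched span on the repeat
qend	0-based exclusive end of the matched span on the repeat
fraction_full	element span length / reference repeat length
full_length	fraction_full at or above the full-length threshold
repeat_class	assigned repeat class
x_in_window	elements inside the scanned window
n_total	qualifying elements of the repeat on the replicon
window_bp	window span between first and last element midpoint
binomial_probability	P(Binomial(n_total-1, window/replicon) >= x-1)
headline_p	calibrated scan p-value (Beta span law, Bonferroni)
element_a/element_b	pair member labels (repeat@start-end)
separation_bp	midpoint separation (min arc on circular replicons)
p_distance	differing columns / aligned columns of the global alignment
identity	1 - p_distance
slope_pdist_pct_per_mbp	OLS slope of p-distance (%) per Mbp separation
slope_identity_pct_per_mbp	same slope in identity units (sign flipped)
intercept_pct	OLS intercept in percentage units
p_value	two-sided test of zero slope / Wilcoxon rank-sum p
variant	enrichment variant (all / native_only / omit_within_1kb)
distance_bp	proximity distance threshold
mean_pseudo_near_is	mean pseudogene count within distance of an IS element
mean_pseudo_near_gene	mean pseudogene count within distance of a gene
enrichment_ratio	mean_pseudo_near_is / mean_pseudo_near_gene
wilcoxon_p	two-sided Wilcoxon rank-sum p-value
total_repeat_hits	attributed repeat elements on the genome
total_is_hits	elements attributed to IS-class repeats
repeat_bp	bp covered by elements (overlaps counted once)
percent_occupied	repeat_bp / genome length
repeats_per_mbp	elements per Mbp of genome
genome_minus_is_bp	genome length minus IS-covered bp
genome_minus_is_and_pseudo_bp	additionally minus pseudogene bp outside elements
"""


def report_tables(
    replicons: list[AnnotatedReplicon],
    repeat_classes: dict[str, str],
    config: PipelineConfig,
    outdir: Path,
) -> pd.DataFrame:
    """Per-genome summary: hits, IS hits, densities, occupancy, sizes."""
    rows = []
    for rep in replicons:
        occ = occupancy_summary([rep], repeat_classes)
        n_pseudo = len(rep.pseudogenes())
        rows.append(
            {
                "replicon": rep.id,
                "length_bp": rep.length_bp,
                "total_repeat_hits": occ.total_repeat_hits,
                "total_is_hits": occ.total_is_hits,
                "repeats_per_mbp": round(occ.repeats_per_mbp, 2),
                "pseudogenes_per_mbp": round(n_pseudo / (rep.length_bp / 1e6), 2),
                "percent_occupied": round(100 * occ.percent_occupied, 2),
                "genome_minus_is_bp": occ.genome_minus_is_bp,
                "genome_minus_is_and_pseudo_bp": occ.genome_minus_is_and_pseudo_bp,
            }
        )
    df = pd.DataFrame(rows)
    _fmt(df, outdir / "report.tsv")
    (outdir / "data_dictionary.tsv").write_text(DATA_DICTIONARY)
    return df
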