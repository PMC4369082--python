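# Methods

This note documents the models, algorithms, numerical choices and
validation conditions behind `hopscan`. Coordinates are 0-based half-open
throughout; GenBank's 1-based inclusive convention exists only at the I/O
boundary. A feature spanning the origin of a circular replicon is stored
with `end > length_bp` (the two GenBank join segments are fused; total
length preserved).

## Repeat library construction

De novo discovery counts exact `seed_len`-mers (default 16) per replicon
and extends each high-frequency seed bidirectionally across its
occurrence set, one column at a time. A column's agreement is the
fraction of occurrences carrying the majority base; extension stops when
the mean agreement over a trailing 15-column window falls below
`1 − max_divergence` (default 0.9), and the failing tail is trimmed. The
column-majority consensus is reported for families with at least
`min_copies` (default 2) occurrences and `min_repeat_len` (default 500 bp)
consensus length. Discovery is forward-strand; a family present in both
orientations is reported once from its forward occurrences. Families
whose consensus is contained in a longer family's consensus at the
deduplication thresholds are dropped.

Library assembly merges de novo repeats into a reference IS catalogue.
Redundancy is decided by local alignment of the shorter sequence against
the longer (both orientations): identity ≥ `dedup_identity` (0.95) over
≥ `dedup_coverage` (0.8) of the shorter sequence. The coverage threshold
is deliberately below 1 so that repeats sharing only a short domain are
not collapsed, while catalogue entries rediscovered de novo are. The
catalogue name always survives a merge. De novo repeats are named
`<Abbrev>_R_<k>` in discovery order per genome.

An exclusion filter removes repeats whose user-supplied annotation
matches a non-mobile keyword list (default: rRNA, tRNA, photosystem,
phycobilisome) — repeated housekeeping genes are repeats but not mobile
elements. The filter consumes a table; no live database is queried.

## Footprint scanning and decomposition

Hit search is seed-and-extend: exact 11-mer matches between repeat and
genome (both strands) are located through a sorted-hash index built once
per replicon, grouped into candidate windows by diagonal (band 64 bp) and
target position (gap ≤ one query length). A window must contain at least
2 seeds spanning ≥ 12 bp of the target — a two-hit rule; without it,
chance ~12–14 bp matches (which produce runs of mutually overlapping
seeds) generate hundreds of spurious alignment windows per repeat.
Windows from distinct diagonal clusters are aligned separately on
purpose: two copies of a repeat in one region (tandems, fragments
flanking an insertion) must each get their own alignment.

Each window is aligned with an affine-gap local aligner (match +1,
mismatch −2, gap open −5, gap extend −2). Significance uses the
Karlin–Altschul expectation E = K·m·n·exp(−λS) over the two-strand search
space, with λ solved from the scoring scheme under uniform base
composition and K = 0.46 calibrated for the default scheme. Hits with
E < 10⁻⁶ are kept; overlapping same-strand hits of one repeat keep the
best score. A calibration property test checks that chance hits at looser
E are not systematically more frequent than E predicts.

Overlapping hits (any repeats) merge into footprints. Decomposition is
greedy: every candidate repeat (those with hits on the footprint; the
whole library when a footprint carries none) is aligned to the unassigned
segment in both orientations; the best scorer claims its aligned genomic
span as one element, and remaining flanks ≥ `min_leftover` (50 bp)
recurse. Ties break on higher score, then longer span, then repeat name —
the decomposition is deterministic. Segments nothing claims at the
E-value cutoff are returned as explicit unassigned intervals, never
dropped. Within a footprint, assigned spans are disjoint by construction,
so assigned elements plus unassigned leftovers tile the footprint.

`fraction_full` is the genomic span length divided by the reference
repeat length (not aligned columns — a deliberate choice, since eroded
copies with internal deletions should count as shorter). Bands:
full-length ≥ 0.95, fragment < 0.50, severe fragment < 0.15. Occupancy
summaries count overlapping element spans once (interval union); IS-only
accounting uses the repeat-class map (classes `isfinder_is` and
`putative_is` count as IS).

## Repeat classification

Classification consumes a precomputed protein-evidence table
(repeat_id, hit_description, evalue, category_hint) instead of running
live protein searches. Precedence: reference-catalogue source →
`isfinder_is`; transposase evidence with E < 10⁻⁵ → `putative_is`; phage
evidence → `phage`; replication-related → `putative_mge`;
DNA-interacting → `dna_interacting`; no informative evidence but ≥ 6
copies in a single genome → `highly_repeated`; else `unclassified`.
"More than five copies" is read strictly as ≥ 6. Conflicting evidence
rows resolve to the highest-precedence class; classification is
order-independent in the evidence list.

## Cluster statistic

For x of n qualifying copies (fraction_full > 0.70) of one repeat inside
a window of w bp on a replicon of L bp, the reported per-window
probability is P(Bin(n−1, w/L) ≥ x−1): one copy anchors the window with
certainty, the remaining n−1 are independent Bernoulli(w/L) trials.

A scanned window's ends are themselves order statistics of the data, so
this probability is not a valid scan p-value (measured type I ≈ 15% at
nominal 5% for n = 5). The scan therefore also reports a calibrated
*headline* p-value: the span of x consecutive order statistics out of n
uniform points has the exact law Beta(x−1, n−x+2); each window's span
probability is Bonferroni-corrected by the number of windows scanned
(n(n−1)/2). Measured type I over 5000 uniform placements is ≈ 4.2% at
the 0.05 level, and a tight cluster (5 copies within 1% of the replicon)
yields headline p < 10⁻⁶. Windows are all contiguous runs of
position-sorted qualifying copies; the minimum-headline window leads the
output. Separations use element midpoints, min-arc on circular replicons
— the anchor convention is a package choice.

## p-distance and local-hopping regression

The uncorrected p-distance of a pair is (mismatched + gapped columns) /
aligned columns of a global pairwise alignment; gap–gap columns cannot
occur pairwise. The alignment is the minimum-edit-cost Needleman–Wunsch
path (edlib), computed in canonical argument order so the statistic is
exactly symmetric (co-optimal paths can differ in column count). For the
near-identical, near-full-length copies this statistic is restricted to
(fraction_full > 0.90), the minimum-edit path coincides with any
reasonable scoring alignment, and the edit-path implementation is ~200×
faster than an affine-gap DP — which is what makes the replicated
recovery benchmarks tractable. Pairwise alignment replaces a multiple
alignment deliberately: it is deterministic and per-pair independent.

The regression is OLS of p-distance (percentage units) on separation
(Mbp), with a two-sided t-test on the slope; fits require ≥ 3 pairs and
non-degenerate separations (zero variance is refused with a diagnostic;
an exactly flat response returns slope 0, p 1). A positive slope —
equivalently, identity falling with separation — is the local-hopping
signature; both sign conventions are emitted
(`slope_pdist_pct_per_mbp`, `slope_identity_pct_per_mbp`) so either
reading is available. Pairs never cross replicons. The pooled fit is a
single OLS over the union of pair sets.

## Pseudogene-proximity enrichment

For each IS element and each non-IS-like annotated gene (pooled across
replicons), pseudogenes with closest-edge gap ≤ d are counted for
d ∈ {5, 10, 50, 100, 200, 500} kbp; a focal feature never counts itself.
Gaps are computed on linear coordinates (a package choice; near-origin
neighbours of circular replicons affect both focal sets symmetrically).
The enrichment ratio is mean(count near IS) / mean(count near gene);
significance is a two-sided Wilcoxon rank-sum on the two count vectors —
exact enumeration when the pooled sample is ≤ 12 and tie-free, otherwise
the normal approximation with continuity and midrank-tie correction.
Variants: `native_only` excludes IS-like pseudogenes (transposase
fragments are not evidence that ISs damage *native* genes);
`omit_within_1kb` drops pseudogenes closer than 1 kb to the focal feature
(such pseudogenes may be unrecognized fragments of the element itself).
An all-identical count configuration (e.g. zero pseudogenes) returns
p = 1 and an undefined (NaN) ratio rather than failing. No
multiple-testing correction is applied across distances or genomes; the
heat-table view omits genomes with no annotated pseudogenes or fewer
than two significant distances.

## Forward simulator

The simulator builds a uniform-random background genome (GC skew is not
modelled) with `n_genes` uniformly spaced genes of fixed length, seeds
`n_is_species` random consensus sequences, and applies events:

* **Transposition** — a uniformly chosen extant copy moves
  (cut-and-paste) or replicates (copy-and-paste, probability
  `p_copy_paste`). The destination is source midpoint + a signed
  Exponential(`local_scale_bp`) displacement with probability `p_local`,
  else uniform; the kernel shape is a package choice — the local-hopping
  phenomenon constrains only that hops be short. Destinations inside an
  existing element are re-drawn (≤ 100 attempts, then the event is
  skipped and logged), so elements never nest.
* **Mutation** — the moved/created copy receives Binomial(len,
  `sub_rate`) substitutions at uniform positions. Mutation load accrues
  per transposition event, not per unit time: copies separated by more
  events have diverged more, which is precisely the mechanism the
  hopping regression detects.
* **Pseudogenization** — an insertion landing inside a gene marks it
  pseudo with probability `p_pseudogenize`; the gene's span grows by the
  insert (an interrupted gene keeps its extent). Background
  pseudogenes are drawn independently at rate `background_pseudo_rate`.
* **Truncation** — after the transposition phase each copy is, with
  probability `p_truncate`, clipped by a Uniform(`truncate_frac_range`)
  fraction from one end; the clipped bases are deleted from the genome.

Defaults (1 Mb circular replicon, 800 × 900 bp genes ≈ 72% coding, 5
species × 1 kb, 2 initial copies each, 100 transpositions,
p_copy_paste 0.5, p_local 1.0, scale 50 kb, sub_rate 0.005,
p_pseudogenize 0.5, background 0.05) give a mid-size bacterial replicon
with a moderately active IS population; hop scale and per-event mutation
count are calibration choices, not empirical claims. Target-site
duplications, selection, recombination between repeat-flanked regions
and horizontal transfer are not simulated — so passing recovery tests
show the statistics detect the modelled mechanisms, not that real
genomes contain no confounders (e.g. deletion sweeps that remove
IS-dense regions wholesale).

Every random draw is recorded in the event log; the same state-update
code applies events during simulation and replay, and a test asserts
byte-for-byte replay of the final genome. `truth_compare` matches calls
to planted elements by repeat identity and ≥ 80% reciprocal overlap;
calls explained only by sub-threshold truth fragments are excluded from
the precision denominator.

## Validation conditions

The acceptance benchmarks (`hopscan.benchmarks`, driven by
`tests/test_acceptance.py` and `scripts/acceptance.py`) use these
problem sizes, chosen to make each check statistically meaningful at
desk scale:

* Decomposition oracle: 100 footprints over motifs nested / tandem /
  truncated / triple-nested, random breakpoints, exact segment copies;
  required: 100% attribution, ≤ 20 bp boundary error.
* Binomial exactness: all (x, n ≤ 6) against independent `math.comb`
  tail sums (tolerance 10⁻¹²) and 10⁵-draw uniform-placement Monte Carlo
  (within 3 SE).
* Scan calibration: 500 placements of 5 uniform elements on 5 Mb;
  headline p < 0.05 in ≤ 7%.
* Hopping recovery: 50 simulations each of 5 Mb, one species grown from
  1 to 40 copies by copy-paste, scale 50 kb, sub_rate 0.005, with
  p_local 1 (expected detection ≥ 80%) and p_local 0 (≤ 10%).
* Enrichment recovery: 50 signal simulations (1 Mb, 700 genes,
  p_pseudogenize 0.9, local kernel) — 5 kbp ratio ≥ 1.3 with p < 0.05 in
  ≥ 90%; 200 null simulations (40 uniform copies, background pseudogenes
  only) — mean ratio within [0.9, 1.1], rejection ≤ 7%. The 1 Mb size is
  the package's choice for replicate throughput.
* Wilcoxon exactness: every tie-free two-sample split of up to 8
  observations against full permutation enumeration.
* End-to-end: one 5 Mb genome, 20 species, 160 transpositions,
  sub_rate 0.02, 15% truncation; recall and precision ≥ 0.95 for planted
  copies of ≥ 50% reference length, plus byte-identical rerun.

## Known limitations

* Discovery is forward-strand and consensus boundaries carry ±1–2
  column fuzz at family edges (majority columns at the boundary
  occasionally pass the agreement window).
* The E-value constant K is calibrated for the default scoring scheme
  only; other schemes fall back to the ungapped λ with the same K.
* Footprint decomposition is greedy; on adversarial footprints whose
  best local alignment crosses a true segment boundary the tiling can
  differ from the generative history (not observed across the benchmark
  motifs).
* Enrichment gaps ignore circular wrap-around, and pairwise p-distance
  will differ from a multiple-alignment column count when elements carry
  many indels.
* Plot generation is not included; all outputs are TSV tables intended
  for downstream plotting.
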