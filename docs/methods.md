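# Methods

This note records the models, parameter choices and numerical conventions
behind `outronscan`, and what the synthetic benchmarks do and do not show.

## Coordinates and formats

All internal coordinates are 0-based half-open on the forward genomic
strand; only GFF3 I/O converts (GFF3 is 1-based inclusive), BED passes
through unchanged. "Upstream"/"5′" always refers to a feature's own
strand; sequence extraction reverse-complements on `-`. A site position is
the genomic coordinate of the RNA's 5′-most base (so on `-` a read
covering genomic `[a, b)` has its site at `b − 1`). This single-convention
rule is deliberate: coordinate conversion happens in exactly one module
(`ioformats`), which eliminates the usual class of off-by-one errors
between BED/GFF3/FASTQ-derived positions.

## Synthetic genome model

The generator emulates the statistical structure of a tunicate-like
genome as seen by 5′-end tag sequencing. Its defaults are the study
conditions the package is validated under.

* **Background**: i.i.d. uniform A/C/G/T, so enrichment nulls are exact
  and every planted signal has a known expectation.
* **Gene architecture**: 2–4 exons; exon 2+ lengths U(80, 200) bp,
  internal introns U(100, 300) bp. The first exon + first intron span (the
  5′ transcribed region upstream of the first cis acceptor; the outron of
  a trans-spliced gene) is log-normal with median 458 bp (σ_log = 0.4,
  clamped to [220, 2500]); 458 bp is a realistic scale
  for *Ciona* 5′ transcribed regions. The true shape of outron length
  distributions is not known; the log-normal is a stand-in, not an
  inference.
* **Trans-splicing**: each non-operonic gene is trans-spliced with
  probability 0.5. Trans-spliced genes split 45/55 between the TS-1stAS
  group (major TAS exactly at the first cis acceptor site) and the TS-5UTR
  group (major TAS inside the first exon). Every TAS has `AG` immediately
  5′ (strand-aware) — at first acceptor sites this comes from the planted
  acceptor window, elsewhere it is written explicitly. Minor TAS
  (Poisson(1.5), ≤ 3) sit within ±50 bp of the major site at geometric
  offsets (scale 15 bp) with shares decaying by 0.3 per rank, so the major
  site always carries the largest expected share.
* **Ratios and reads**: the per-gene trans-splicing ratio is
  Beta(2, 2) — a broad, symmetric spread with no mass exactly at 0 or 1,
  which is what a mixed SL/capped tag library looks like. Per gene, read
  count ~ Poisson(depth); the SL count is Binomial(n, ratio); SL reads are
  `SL16 + 34 nt` of genomic sequence from a TAS drawn by site share,
  capped reads are 50 nt from the TSS with small symmetric jitter (70% at
  the exact TSS, ±1–2 bp otherwise). Reads are genomically contiguous and
  error-free by default (`error_rate` is configurable), which is what
  makes the exact-match mapper a valid stand-in for a spliced aligner at
  this scale.
* **Operons**: runs of 2–3 consecutive same-strand genes with exactly zero
  intergenic distance; every transcriptionally non-first member starts at
  a TAS (ratio 1.0, no TSS of its own, `AG` planted in the upstream
  neighbour's terminal bases). All run members are flagged operonic in the
  truth, matching how operonic genes are counted in annotation practice.
* **Donor weakening**: TS-1stAS genes' first-intron donor is sampled from
  the consensus donor PWM mixed 50% toward uniform (GT at +1/+2 kept).
  This plants the "weak first donor" signal the strength comparison is
  meant to detect. Acceptor windows are identical across groups — the
  pipeline should (and does, across seeds) find no systematic acceptor
  difference. The per-gene ratio is drawn independently of the donor
  weakening, so the TS-High vs TS-Low strength contrast is null in the
  demo; only the group-level donor effect is planted.
* **Composition bias**: the whole TSS..first-AS region of each
  trans-spliced gene is resampled with G and T upweighted by the bias
  factor (default 1.5 ⇒ G+U content 0.6 vs 0.5), emulating GU/AU-rich
  outrons.
* **Planted motifs**: occurrences are sampled from the motif PWM and
  written into a fixed band (default offsets 60–120 from the TSS) of
  trans-spliced genes at a per-gene rate (default 0.5), never into
  controls or intergenic space. The default planted motif is an
  information-rich 10-mer (0.94 consensus probability per column) so that
  PWM-sampled occurrences almost always clear a FIMO-style 1e-4 score
  threshold; a broader/shorter motif would confound scanner sensitivity
  with enrichment-test power.
* **Decoys**: intergenic ATAC peaks (default 5) and intergenic capped-tag
  sites outside any peak (default 8) exercise the open-chromatin filter.
* Everything is deterministic given the config seed; read simulation and
  background sampling use fixed offsets from it.

What the simulation does **not** model: sequencing errors under default
settings, spliced reads, soft-clipping, PCR duplication structure,
non-uniform genomic composition (isochores, repeats), overlapping genes,
and any coupling between expression level and trans-splicing. Passing the
benchmarks therefore demonstrates correctness of the algorithms under
their stated assumptions, not performance on real libraries.

## Tag calling

Classification: a read is SL iff its first `min_prefix_match` (default 16,
the full SL) bases equal the SL 3′ suffix of that length; the matched
prefix is trimmed. Shorter suffix matching is supported because real reads
may truncate the SL. Mapping: exact search seeded on a 16-mer index with
full-length verification, both strands; with uniqueness required (the
default) a read counts only if it occurs exactly once genome-wide.
Clustering: single-linkage chaining of per-position counts with gap ≤ 50
bp (from the observed ±50 bp scatter of minor acceptor sites); cluster
mode ties break 5′-most for determinism. TAS calling keeps every cluster
position with upstream `AG` — canonical for acceptor sites, recorded here
as an assumption since tag evidence alone cannot distinguish acceptor
classes. TSS calling keeps capped clusters overlapping an open-chromatin
peak by ≥ 1 bp; the representative TSS per gene region is the mode of the
highest-count overlapping cluster.

## Gene classification

Bodies are the union span of known plus assigned novel transcripts; novel
transcripts attach to the same-strand overlapping gene with the largest
overlap (ties to the 5′-most gene), so the gene count never changes.
"Zero intergenic distance" for operons is implemented as gap ≤ 0
(abutting or overlapping) — the strict reading, as opposed to the older
<100 bp proximity rules used by earlier operon annotations. TAS-at-acceptor coincidence is an
exact position match (both are single-base acceptor coordinates). The
trans-splicing ratio uses the gene's summed TAS tag counts against the
representative TSS cluster's tag count, oriented so that higher means
more trans-splicing; it is defined only when both a TSS and a TAS were
identified, and genes without it are excluded (and counted) from the
High/Low analysis. The High/Low threshold (default 0.5) is boundary-
inclusive on the High side and sweepable.

The first-acceptor binomial test takes k = genes whose major TAS is at
AS_1, n = genes whose major TAS is at any determined cis acceptor, and a
background p₀ that is, by default, the fraction of all cis acceptor sites
that are first sites ("per_site"); whether the background should instead
be averaged per gene is genuinely ambiguous, so a "per_gene" mode
(mean of 1/#acceptors) is exposed as a flag.

## Splice-site models

Donor windows span −3..+6 (9 nt), acceptor windows −20..+3 (23 nt), the
canonical MaxEnt geometries. Models are trained from user-supplied site
sets rather than shipped as fixed score tables: the published
maximum-entropy splice models are trained on large curated human site
collections, and a trainable model keeps the package self-contained and
organism-agnostic (a documented divergence — scores here are not
comparable to published MaxEnt numbers). The MEM is fitted by iterative
proportional fitting on the full 4⁹ donor joint until every constrained
marginal matches within `tol` (default 1e-8; non-convergence raises with
the worst residual); with only single-position constraints it reduces
exactly to the PWM, which the tests assert. The 4²³ acceptor space cannot
be enumerated, so acceptor MEMs are factorized over disjoint adjacent
pairs, each block carrying its own joint — the exact maximum-entropy
solution for that constraint set. Scores are log₂(P_signal/P_background);
the default background is uniform. Pseudocounts (default 0.5 per
single-position cell, scaled for blocks) keep probabilities strictly
positive.

One numerical trap worth recording: the signal model must be trained on
sites disjoint from those being scored. Training on "all sites of the
control group" leaves the control group's first sites in-sample and
inflates their scores (by ~1 bit for the pair-factorized acceptor model at
n ≈ 400), manufacturing a spurious group difference. The pipeline
therefore trains on internal (non-first) splice sites of all genes, which
are never scored.

Group comparisons are two-sided Mann–Whitney U; the donor and acceptor
first-site comparisons form one BH batch.

## Enrichment analyses

Window geometry is 30 bp — the conventional width for this kind of local
profile — with a 10-bp step; the step has no canonical value, so 10 bp is
this package's default and it is configurable. Genes whose 5′ region is shorter than a window offset drop
out of that window's sample, so per-window n varies; windows with < 2
genes in either group are reported untested and excluded from the BH
batch. Whole-region comparisons (first exon + intron) are two-sided with
BH over the 4 N or 6 N+N content specs; windowed tests are one-sided
(greater in trans-spliced genes). Fold enrichment is a ratio of means by
default, with medians available via `center="median"`.

Motif scanning discretizes per-column log₂-odds into 1/1000-bit integer
bins and computes the null score distribution exactly by dynamic
programming under the 0-order background; "hit" means score p-value ≤
1e-4 (the FIMO default). Scanning is sense-strand only, as appropriate for
RNA-binding motifs on transcribed regions. "Sequence has the motif in a
window" counts ≥ 1 hit whose start lies in the window — presence/absence,
because the two enrichment formulas count sequences, not sites. Both stage
tests use upper-tail summation, the standard test interpretation of the
binomial and hypergeometric enrichment formulas. Background sequences
(default n = 3000) are drawn uniformly from
intergenic intervals at the profiled region length, seeded. Stage-2
tables with degenerate margins (C = 0 or C = N) get p = 1. Motif
redundancy merging uses best-ungapped-offset mean per-column Pearson
correlation with single-linkage clustering at 0.8 and position-wise
averaging against the widest member; merging procedures vary across
tools, and this correlation-based one is the package's own choice. The fold-enrichment matrix
uses FE = (x/R)/((C−x)/(N−R)); motifs are ordered by complete-linkage
clustering of Euclidean distances between log₂ FE vectors, computed
pairwise over windows where both motifs are defined.

## Statistical primitives

Binomial and hypergeometric upper tails go through scipy's survival
functions (log-space internally; finite to n = 10⁶ and beyond). The
Mann–Whitney test enumerates all C(n+m, n) assignments when n + m ≤ 16 —
exact under ties, where the common exact formulas are not — and otherwise
uses the tie-corrected normal approximation with continuity correction;
the crossover at 16 keeps enumeration under ~13k arrangements. Identical
pooled samples return p = 1. BH is the step-up rule with NaN passthrough
for untested hypotheses (they do not count toward m).

## Validation design and problem sizes

The benchmarks run at desk scale, chosen to finish in minutes on one CPU
while keeping every rate estimate well-conditioned: site recovery on 200
genes at tag depth 10³ (perfect classification required; ≥ 95% exact
major-TAS recovery; 100% decoy rejection), ratio recovery on 100 genes at
depth 10⁴ (≥ 95% of genes within 3 binomial SE of truth), operon flags vs
a brute-force region scanner on 1000 random layouts, donor-weakening
power over 100 seeds at 200 sites/group, null window calibration over
1000 replicates (6 windows, n = 100/group; the observed type-I rate is
required to lie in 0.025–0.075 around α = 0.05, a band covering
Monte-Carlo error plus the slight conservatism of the continuity-corrected
approximation), GU-bias power on a 450-gene genome (≥ 80% of planted
windows at FDR < 0.05), and motif power/false-positive rates over 20
seeds (planted motif called in ≥ 95%, never-planted in ≤ 5%). Quantities that
depend on real sequencing libraries (absolute gene counts and the like)
are beyond what synthetic data can certify, so validation is
property-based throughout.

## Known limitations

* The exact-match mapper ignores mismatches and splicing; it is valid only
  for the error-free, contiguous reads the simulator emits.
* The trainable splice models do not reproduce published MaxEnt score
  tables; only relative comparisons within a run are meaningful.
* The acceptor MEM's pair factorization cannot represent long-range
  dependencies between tract positions.
* Minor-TAS shares follow a fixed geometric decay; real minor-site usage
  is more dispersed.
* The demo's TS-High/TS-Low strength contrast is uninformative by design
  (ratio and donor strength are drawn independently).
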