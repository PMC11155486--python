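# outronscan

Analysis toolkit for spliced-leader (SL) *trans*-splicing, exercised
end-to-end on synthetic genomes with planted ground truth.

In tunicates such as *Ciona*, and in nematodes, roughly half of all genes
undergo SL *trans*-splicing: the 16-nt 5′ exon of a small SL RNA is joined
to a *trans*-splice acceptor site (TAS) on a pre-mRNA, and the 5′ region
upstream of the TAS — the **outron** — is discarded. 5′-end tag sequencing
(TSS-seq/oligo-capping) sees both RNA populations at once: reads that
begin with the SL sequence mark acceptor sites, reads that begin with the
cap mark transcription start sites (TSSs). This package implements the
full chain of analyses that characterizes *trans*-spliced genes from such
data, for computational biologists who want a tested, reproducible desk-
scale implementation of each step:

* **Tag calling** (`tagcall`): classify reads by the SL prefix, map 5′
  ends (exact k-mer-indexed search with uniqueness filtering), cluster
  tags by single-linkage chaining (gap ≤ 50 bp), call TAS at positions
  with the obligatory upstream `AG`, and keep TSS clusters only where they
  overlap open-chromatin (ATAC-like) peaks.
* **Gene classification** (`geneclass`): redefine gene bodies from known +
  novel transcripts, detect operons (runs of ≥ 2 same-strand genes with
  zero intergenic distance whose downstream members start at a TAS),
  classify genes as *trans*-spliced / non-*trans*-spliced / ambiguous,
  select the major (most tag-supported) TAS, locate it relative to the
  cis-exon structure (5′ UTR of exon 1, *k*-th acceptor site, …), test
  for preferential *trans*-splicing at the first acceptor site (upper-tail
  binomial test against the background fraction of first acceptor sites),
  and estimate the per-gene *trans*-splicing ratio
  r = n_TAS / (n_TAS + n_TSS) with a TS-High/TS-Low split.
* **Splice-site strength** (`splicestrength`): trainable position-weight
  and maximum-entropy models over the canonical 9-bp donor (−3..+6) and
  23-bp acceptor (−20..+3) windows; strength is the log₂-odds of a window
  under signal vs background; groups are compared by Mann–Whitney U with
  Benjamini–Hochberg adjustment over the comparison batch.
* **Content enrichment** (`contentenrich`): N and N+N nucleotide content
  (U ≡ T on the coding strand) of 5′ transcribed regions, whole-region and
  in 30-bp sliding windows anchored at the TSS or the first acceptor site,
  tested one-sided (greater) per window with BH FDR.
* **Motif enrichment** (`motifenrich`): FIMO-style PWM scanning with exact
  score p-values (dynamic programming over integer-discretized column
  scores), then the two-stage local enrichment test — per window, a
  binomial test P = Σ_{j≥k} C(n,j) p^j (1−p)^{n−j} of target sequences
  against intergenic background (n = 3000 by default), FDR < 0.05 windows
  passing to a one-sided Fisher exact test against control genes — plus
  motif redundancy merging and a log₂ fold-enrichment matrix with
  complete-linkage clustering.
* **Statistics** (`statcore`): exact binomial/Fisher upper tails,
  Mann–Whitney U (exact permutation for n+m ≤ 16, tie-corrected normal
  approximation otherwise), BH step-up — each verified against
  enumeration oracles in the test suite.
* **Synthetic data** (`synthdata`): the generator that makes all of this
  testable — a toy genome with operons, planted TAS (AG contexts, minor
  sites within ±50 bp at geometrically decaying shares), log-normal outron
  lengths, per-gene Beta-distributed *trans*-splicing ratios, weakened
  first donor sites for TS-1stAS genes, GU/AU-biased outrons, planted
  motif occurrences, SL/capped reads and ATAC peaks, all with full ground
  truth and byte-identical outputs for a fixed seed.

## Worked example

The numbered drivers under `analysis/` run a 300-gene study (three 600-kb
chromosomes, ~50% *trans*-spliced genes, 10% operonic, GU/AU-biased
outrons, one planted motif) and write their tables under `results/run/`:

```bash
python analysis/01_simulate_genome.py
python analysis/02_call_sites.py
python analysis/03_classify_genes.py
python analysis/04_splice_strength.py
python analysis/05_content_enrichment.py
python analysis/06_motif_enrichment.py
```

Representative output (seed 1):

```
genes: 300 (143 trans-spliced, 30 operonic)
reads: 60174 (16579 SL, 43595 capped); peaks: 287
TAS called: 322 (non-AG positions discarded: 0)
TSS clusters kept in open chromatin: 282/290 (artifact clusters rejected: 8)
major TAS locations (top): [('5UTR_first_exon', 71), ('AS_1', 54)]
first-acceptor preference: k=54/54 at AS_1, background p0=0.495, binomial p=3.06e-17
first_donor: TS-1stAS weaker (5.04 vs 7.79 bits), FDR=1.8e-06
region GU content higher in trans-spliced genes (0.602 vs 0.502, FDR=2e-44)
planted_GU10: 7 candidate windows (stage 1), locally enriched: True
null_CA10: 0 candidate windows (stage 1), locally enriched: False
```

Reading: every simulated read is classified and uniquely mapped; the 8
capped tag clusters planted outside open chromatin are rejected as
artifacts; all 54 genes whose major TAS sits at a cis acceptor site sit at
the *first* one, far above the 49.5% background rate; the planted weak
first donors of TS-1stAS genes score ~2.8 bits below those of
non-*trans*-spliced genes; outrons show the planted GU excess (0.60 vs
0.50); and the planted motif — but not a never-planted control motif —
passes both enrichment stages.

The same pipeline is available as a CLI
(`outronscan simulate|classify|map|call-tas|call-tss|classify-genes|run-all
--config cfg.yaml [--seed N]`).

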