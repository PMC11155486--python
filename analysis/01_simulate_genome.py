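"""Simulate the toy genome: 300 genes with planted trans-splicing truth.

Writes genome FASTA, annotation GFF3, 5'-tag FASTQ, ATAC-like peak BED and
the ground-truth tables under results/run/, and prints a summary of what
was planted.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RUN_DIR, demo_config

from outronscan import synthdata
from outronscan.ioformats import write_bed, write_fasta, write_fastq, write_gff3, write_tsv


def main() -> None:
    cfg = demo_config()
    RUN_DIR.mkdir(parents=True, exist_ok=True)
    genome, annotation, truth = synthdata.generate_genome(cfg.simulation)
    reads, read_truth = synthdata.simulate_tags(genome, truth)
    peaks = synthdata.simulate_atac(truth)

    write_fasta(RUN_DIR / "genome.fa", genome)
    write_gff3(RUN_DIR / "annotation.gff3", annotation)
    write_fastq(RUN_DIR / "tags.fastq", reads)
    write_bed(RUN_DIR / "atac_peaks.bed", peaks)
    write_tsv(RUN_DIR / "read_truth.tsv", read_truth)
    write_tsv(RUN_DIR / "gene_truth.tsv", synthdata.truth_gene_table(truth))

    n_ts = sum(g.is_ts for g in truth.genes)
    n_op = sum(g.operonic for g in truth.genes)
    n_sl = int((read_truth.category == "SL").sum())
    print(f"genome: {cfg.simulation.n_chromosomes} x {cfg.simulation.chrom_length} bp")
    print(f"genes: {len(truth.genes)} ({n_ts} trans-spliced, {n_op} operonic)")
    print(f"planted TAS: {sum(len(g.tas_positions) for g in truth.genes)}; "
          f"motif occurrences: {len(truth.motif_occurrences)}")
    print(f"reads: {len(reads)} ({n_sl} SL, {len(reads) - n_sl} capped); "
          f"peaks: {len(peaks)}")
    print(f"outputs in {RUN_DIR}")


if __name__ == "__main__":
    main()
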