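"""Call trans-splice acceptor sites and TSSs from the simulated tags.

Reads the files written by 01, classifies reads by the SL prefix, maps
their 5' ends, clusters them, AG-filters SL clusters into TAS and keeps
capped clusters inside open chromatin as TSS evidence. Writes
tas_sites.tsv and tss_clusters.tsv and prints the filter counts.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RUN_DIR, demo_config

from outronscan import tagcall
from outronscan.ioformats import read_bed, read_fasta, read_fastq, write_tsv


def main() -> None:
    cfg = demo_config()
    genome = read_fasta(RUN_DIR / "genome.fa")
    reads = read_fastq(RUN_DIR / "tags.fastq")
    peaks = read_bed(RUN_DIR / "atac_peaks.bed")

    sl, capped, cstats = tagcall.classify_reads(reads, cfg.simulation.sl_sequence,
                                                cfg.min_prefix_match)
    index = tagcall.KmerIndex(genome)
    sl_aln, sl_ms = tagcall.map_five_prime(sl, genome, "SL", True, index)
    cap_aln, cap_ms = tagcall.map_five_prime(capped, genome, "capped", True, index)
    sl_clusters = tagcall.cluster_tags(sl_aln, cfg.max_gap)
    tas_sites, tas_stats = tagcall.call_tas(sl_clusters, genome)
    cap_clusters = tagcall.cluster_tags(cap_aln, cfg.max_gap)
    tss_clusters = tagcall.call_tss(cap_clusters, peaks)

    write_tsv(RUN_DIR / "tas_sites.tsv", pd.DataFrame(
        [{"chrom": s.chrom, "pos": s.pos, "strand": s.strand,
          "tag_count": s.tag_count} for s in tas_sites]))
    write_tsv(RUN_DIR / "tss_clusters.tsv", pd.DataFrame(
        [{"chrom": c.interval.chrom, "start": c.interval.start,
          "end": c.interval.end, "strand": c.strand, "mode_pos": c.mode_pos,
          "total_tags": c.total_tags} for c in tss_clusters]))

    print(f"classified: {cstats.n_sl} SL / {cstats.n_capped} capped")
    print(f"mapped SL {sl_ms.n_mapped} (multi {sl_ms.n_multimapped}), "
          f"capped {cap_ms.n_mapped} (multi {cap_ms.n_multimapped})")
    print(f"TAS called: {tas_stats.n_positions_kept} "
          f"(non-AG positions discarded: {tas_stats.n_positions_discarded})")
    print(f"TSS clusters kept in open chromatin: {len(tss_clusters)}/{len(cap_clusters)} "
          f"(artifact clusters rejected: {len(cap_clusters) - len(tss_clusters)})")


if __name__ == "__main__":
    main()
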