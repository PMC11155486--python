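"""Nucleotide-content enrichment of 5' transcribed regions.

Whole-region comparison (first exon + intron) of single-nucleotide and
dinucleotide content between trans-spliced and non-trans-spliced genes,
then the 30-bp sliding-window local enrichment anchored at the TSS and at
the first acceptor site. Writes region_content_*.tsv and
content_enrichment.tsv and prints the significantly enriched contents.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RUN_DIR, demo_config

from outronscan import contentenrich as ce, geneclass
from outronscan.ioformats import read_fasta, read_gff3, read_tsv, write_tsv
from outronscan.pipeline import N_CONTENT_SPECS, NN_CONTENT_SPECS, five_prime_region_seq


def main() -> None:
    cfg = demo_config()
    genome = read_fasta(RUN_DIR / "genome.fa")
    models = {m.gene_id: m for m in
              geneclass.gene_models_from_gff(read_gff3(RUN_DIR / "annotation.gff3"))}
    cls = read_tsv(RUN_DIR / "gene_classification.tsv")
    non_op = cls[~cls.operonic]
    ts = [models[g] for g in non_op[non_op.status == "trans_spliced"].gene_id]
    nt = [models[g] for g in non_op[non_op.status == "non_trans_spliced"].gene_id]

    t_seqs = [s for m in ts if (s := five_prime_region_seq(m, genome, 10**9))]
    c_seqs = [s for m in nt if (s := five_prime_region_seq(m, genome, 10**9))]
    for label, specs in (("N", N_CONTENT_SPECS), ("NN", NN_CONTENT_SPECS)):
        df = ce.compare_region_content(t_seqs, c_seqs, specs)
        write_tsv(RUN_DIR / f"region_content_{label}.tsv", df)
        sig = df[df.fdr < 0.05]
        for r in sig.itertuples():
            direction = "higher" if r.target_mean > r.control_mean else "lower"
            print(f"region {r.content} content {direction} in trans-spliced genes "
                  f"({r.target_mean:.3f} vs {r.control_mean:.3f}, FDR={r.fdr:.2g})")

    tables = []
    for anchor in ("tss", "first_as"):
        for spec in N_CONTENT_SPECS + NN_CONTENT_SPECS:
            tprof = [p for m in ts if (p := ce.profile_gene(
                m, genome, anchor, spec, cfg.window, cfg.step,
                max_offset=cfg.region_cap)) is not None]
            cprof = [p for m in nt if (p := ce.profile_gene(
                m, genome, anchor, spec, cfg.window, cfg.step,
                max_offset=cfg.region_cap)) is not None]
            res = ce.test_windows(tprof, cprof)
            tables.append(ce.enrichment_table(res, spec, anchor))
    long_df = pd.concat(tables, ignore_index=True)
    write_tsv(RUN_DIR / "content_enrichment.tsv", long_df)
    sig = long_df[(long_df.tested) & (long_df.fdr < 0.05)]
    summary = sig.groupby(["anchor", "content"]).size()
    print("\nwindows with FDR < 0.05 by anchor/content:")
    for (anchor, content), n in summary.items():
        total = len(long_df[(long_df.anchor == anchor) & (long_df.content == content)
                            & long_df.tested])
        print(f"  {anchor:9s} {content:2s}: {n}/{total}")


if __name__ == "__main__":
    main()
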