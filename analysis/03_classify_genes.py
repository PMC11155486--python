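"""Classify genes, locate major TAS, and test first-acceptor preference.

Reads the annotation and the called sites from 01/02, detects operons,
splits genes into trans-spliced / non-trans-spliced, locates each major
TAS relative to the cis-exon structure (5' UTR of exon 1, k-th acceptor
site, ...), computes per-gene trans-splicing ratios with the TS-High/Low
split, and runs the binomial test for preferential trans-splicing at the
first cis acceptor site. Writes gene_classification.tsv.
"""

import sys
from collections import Counter
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RUN_DIR, demo_config

from outronscan import geneclass, tagcall
from outronscan.ioformats import Interval, read_gff3, read_tsv, write_tsv
from outronscan.pipeline import classification_table


def main() -> None:
    cfg = demo_config()
    models = geneclass.gene_models_from_gff(read_gff3(RUN_DIR / "annotation.gff3"))
    tas = [tagcall.TransSpliceSite(r.chrom, int(r.pos), r.strand, int(r.tag_count))
           for r in read_tsv(RUN_DIR / "tas_sites.tsv").itertuples()]
    tss = [tagcall.TagCluster(Interval(r.chrom, int(r.start), int(r.end), r.strand),
                              "capped", int(r.mode_pos), int(r.total_tags),
                              {int(r.mode_pos): int(r.total_tags)})
           for r in read_tsv(RUN_DIR / "tss_clusters.tsv").itertuples()]

    cls = geneclass.classify_genes(models, tas, tss,
                                   ratio_threshold=cfg.ratio_threshold)
    write_tsv(RUN_DIR / "gene_classification.tsv", classification_table(cls))

    status = Counter(c.status for c in cls)
    print(f"status: {dict(status)}")
    non_op = [c for c in cls if not c.operonic]
    print(f"operonic: {sum(c.operonic for c in cls)}; non-operonic analysed: {len(non_op)}")
    locations = Counter(c.tas_location for c in non_op
                        if c.status == geneclass.STATUS_TS)
    print(f"major TAS locations (top): {locations.most_common(6)}")
    ratios = [c.ts_ratio for c in non_op if c.ts_ratio is not None]
    classes = Counter(c.ts_class for c in non_op if c.ts_class)
    print(f"ratios defined for {len(ratios)} genes; TS-High/Low: {dict(classes)}")

    model_by_id = {m.gene_id: m for m in models}
    locs = [c.tas_location for c in non_op if c.status == geneclass.STATUS_TS]
    k, n, p0, p = geneclass.first_as_enrichment_test(
        locs, [model_by_id[c.gene_id] for c in non_op], cfg.first_as_mode)
    print(f"first-acceptor preference: k={k}/{n} at AS_1, background p0={p0:.3f}, "
          f"binomial p={p:.3g}")


if __name__ == "__main__":
    main()
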