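"""Compare first donor/acceptor splice-site strength between gene groups.

Trains a maximum-entropy donor model (full 9-mer joint, single-position
constraints) and a factorized acceptor model on the non-trans-spliced
genes' sites, scores the first donor and first acceptor of TS-1stAS
versus non-trans-spliced genes, and BH-adjusts the two Mann-Whitney
comparisons. Also contrasts TS-High and TS-Low donor scores. Writes
splice_strength.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RUN_DIR, demo_config

from outronscan import geneclass, splicestrength as ss
from outronscan.ioformats import read_fasta, read_gff3, read_tsv, write_tsv


def main() -> None:
    genome = read_fasta(RUN_DIR / "genome.fa")
    models = {m.gene_id: m for m in
              geneclass.gene_models_from_gff(read_gff3(RUN_DIR / "annotation.gff3"))}
    cls = read_tsv(RUN_DIR / "gene_classification.tsv")
    non_op = cls[~cls.operonic]
    ts1 = [models[g] for g in non_op[non_op.group == "TS-1stAS"].gene_id]
    non_ts = [models[g] for g in non_op[non_op.status == "non_trans_spliced"].gene_id]

    comparisons = []
    trained = {}
    for site_type in ("donor", "acceptor"):
        a = ss.extract_sites(ts1, genome, site_type, scope="first")
        b = ss.extract_sites(non_ts, genome, site_type, scope="first")
        # internal (non-first) sites: out-of-sample training pool
        train = ss.extract_sites(ts1 + non_ts, genome, site_type, scope="internal")
        if site_type == "donor":
            model = ss.train_mem(train, ss.single_position_constraints(9))
        else:
            model = ss.train_factorized_mem(train)
        trained[site_type] = model
        comparisons.append(ss.compare_strength(a, b, model, alternative="two-sided",
                                               label=f"first_{site_type}"))
    ss.adjust_comparisons(comparisons)

    rows = []
    for c in comparisons:
        rows.append({"comparison": c.label, "n_ts1": len(c.scores_a),
                     "n_non_ts": len(c.scores_b),
                     "mean_ts1": float(np.mean(c.scores_a)),
                     "mean_non_ts": float(np.mean(c.scores_b)),
                     "U": c.u, "pvalue": c.pvalue, "fdr": c.fdr})
        direction = "weaker" if np.mean(c.scores_a) < np.mean(c.scores_b) else "stronger"
        print(f"{c.label}: TS-1stAS {direction} "
              f"({np.mean(c.scores_a):.2f} vs {np.mean(c.scores_b):.2f} bits), "
              f"FDR={c.fdr:.2g}")
    write_tsv(RUN_DIR / "splice_strength.tsv", pd.DataFrame(rows))

    # TS-High vs TS-Low first donor scores
    hi = [models[g] for g in non_op[(non_op.group == "TS-1stAS")
                                    & (non_op.ts_class == "TS_High")].gene_id]
    lo = [models[g] for g in non_op[(non_op.group == "TS-1stAS")
                                    & (non_op.ts_class == "TS_Low")].gene_id]
    a = ss.extract_sites(hi, genome, "donor", scope="first")
    b = ss.extract_sites(lo, genome, "donor", scope="first")
    if len(a) >= 2 and len(b) >= 2:
        c = ss.compare_strength(a, b, trained["donor"], alternative="two-sided",
                                label="donor_high_vs_low")
        print(f"TS-High vs TS-Low first donor: {np.mean(c.scores_a):.2f} vs "
              f"{np.mean(c.scores_b):.2f} bits (p={c.pvalue:.2g}, "
              f"n={len(a)}/{len(b)})")


if __name__ == "__main__":
    main()
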