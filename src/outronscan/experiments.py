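"""Benchmark experiments on synthetic genomes with planted truth.

Each function runs one self-contained experiment — simulate, analyze,
score against the planted ground truth — and returns a dict of summary
metrics. The defaults are the study conditions the package is validated
under (gene counts, tag depths, bias factors, numbers of replicate seeds);
the analysis drivers and the acceptance script call these functions
directly.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import contentenrich, geneclass, motifenrich, splicestrength, statcore, synthdata, tagcall
from .geneclass import STATUS_TS
from .ioformats import MotifPWM
from .pipeline import five_prime_region_seq
from .synthdata import (
    DEFAULT_PLANTED_MOTIF,
    DONOR_FIXED_POSITIONS,
    DONOR_PWM,
    NULL_MOTIF,
    PlantedMotif,
    SimulationConfig,
    _weaken,
)


def sample_sites_from_pwm(matrix: np.ndarray, n: int, rng: np.random.Generator) -> list[str]:
    """Vectorized sampling of n sites from a PWM."""
    cols = []
    for row in matrix:
        cols.append(rng.choice(4, size=n, p=row / row.sum()))
    idx = np.stack(cols, axis=1)
    lut = np.array(list("ACGT"))
    return ["".join(lut[r]) for r in idx]


def _call_sites(genome, truth, cfg):
    """Shared tag-calling front end: simulate reads, classify, map, cluster,
    call TAS and TSS. Returns everything downstream scoring needs."""
    reads, read_truth = synthdata.simulate_tags(genome, truth, cfg)
    peaks = synthdata.simulate_atac(truth)
    sl_reads, capped_reads, cstats = tagcall.classify_reads(reads, cfg.sl_sequence)
    truth_cat = dict(zip(read_truth.read_id, read_truth.category))
    n_correct = sum(1 for r in sl_reads if truth_cat[r.read_id] == "SL") + sum(
        1 for r in capped_reads if truth_cat[r.read_id] == "capped"
    )
    index = tagcall.KmerIndex(genome)
    sl_aln, _ = tagcall.map_five_prime(sl_reads, genome, "SL", True, index)
    cap_aln, _ = tagcall.map_five_prime(capped_reads, genome, "capped", True, index)
    sl_clusters = tagcall.cluster_tags(sl_aln)
    tas_sites, _ = tagcall.call_tas(sl_clusters, genome)
    cap_clusters = tagcall.cluster_tags(cap_aln)
    tss_clusters = tagcall.call_tss(cap_clusters, peaks)
    return dict(
        reads=reads, read_truth=read_truth, peaks=peaks,
        classification_accuracy=n_correct / max(1, len(reads)),
        tas_sites=tas_sites, tss_clusters=tss_clusters,
        cap_clusters=cap_clusters,
    )


def run_site_recovery(seed: int, n_genes: int = 200, depth: float = 1000.0) -> dict:
    """Site-calling recovery on a synthetic genome at the stated tag depth
    with zero read error: SL/capped classification accuracy, exact-position
    recovery of true major TAS, rejection of decoy TSS clusters outside
    open chromatin, and TSS recovery within 5 bp."""
    cfg = SimulationConfig(seed=seed, n_genes=n_genes, n_chromosomes=4,
                           chrom_length=250_000, tag_depth_per_gene=depth)
    genome, annotation, truth = synthdata.generate_genome(cfg)
    called = _call_sites(genome, truth, cfg)
    models = geneclass.gene_models_from_gff(annotation)
    classifications = geneclass.classify_genes(models, called["tas_sites"],
                                               called["tss_clusters"])
    by_id = {c.gene_id: c for c in classifications}

    ts_genes = [g for g in truth.genes if g.is_ts]
    n_major = sum(
        1 for g in ts_genes
        if by_id[g.gene_id].major_tas is not None
        and by_id[g.gene_id].major_tas.pos == g.major_tas
    )
    tss_genes = [g for g in truth.genes if g.tss is not None]
    n_tss = sum(
        1 for g in tss_genes
        if by_id[g.gene_id].tss is not None and abs(by_id[g.gene_id].tss - g.tss) <= 5
    )
    # decoy capped clusters: those whose mode sits at a decoy tag site
    decoy_pos = {(c, p, s) for c, p, s in truth.decoy_tag_sites}
    decoy_clusters = [
        cl for cl in called["cap_clusters"]
        if (cl.interval.chrom, cl.mode_pos, cl.strand) in decoy_pos
    ]
    kept = set(id(cl) for cl in called["tss_clusters"])
    n_decoy_rejected = sum(1 for cl in decoy_clusters if id(cl) not in kept)
    locations = [c.tas_location for c in classifications
                 if not c.operonic and c.status == STATUS_TS]
    model_by_id = {m.gene_id: m for m in models}
    non_op = [model_by_id[c.gene_id] for c in classifications if not c.operonic]
    _, _, _, first_as_p = geneclass.first_as_enrichment_test(locations, non_op)
    return {
        "first_as_binomial_p": first_as_p,
        "classification_accuracy": called["classification_accuracy"],
        "major_tas_recovery": n_major / len(ts_genes),
        "n_ts_genes": len(ts_genes),
        "tss_recovery": n_tss / len(tss_genes),
        "n_decoy_clusters": len(decoy_clusters),
        "decoy_rejection": n_decoy_rejected / max(1, len(decoy_clusters)),
    }


def run_ratio_recovery(seed: int, n_genes: int = 100, depth: float = 10_000.0) -> dict:
    """Trans-splicing ratio recovery at high depth: fraction of genes whose
    estimated ratio lies within 3 binomial standard errors of the
    Beta-drawn truth."""
    cfg = SimulationConfig(seed=seed, n_genes=n_genes, n_chromosomes=4,
                           chrom_length=250_000, tag_depth_per_gene=depth)
    genome, annotation, truth = synthdata.generate_genome(cfg)
    called = _call_sites(genome, truth, cfg)
    models = geneclass.gene_models_from_gff(annotation)
    classifications = geneclass.classify_genes(models, called["tas_sites"],
                                               called["tss_clusters"])
    by_id = {c.gene_id: c for c in classifications}
    n_ok = n_def = 0
    eligible = [g for g in truth.genes if g.is_ts and g.tss is not None]
    for g in eligible:
        c = by_id[g.gene_id]
        if c.ts_ratio is None:
            continue
        n_def += 1
        n_tags = c.tss_tags + c.tas_tags
        se = np.sqrt(max(g.ts_ratio * (1 - g.ts_ratio), 1e-12) / n_tags)
        if abs(c.ts_ratio - g.ts_ratio) <= 3 * se:
            n_ok += 1
    return {
        "n_eligible": len(eligible),
        "n_defined": n_def,
        "frac_defined": n_def / max(1, len(eligible)),
        "frac_within_3se": n_ok / max(1, n_def),
    }


def run_strength_power(
    n_seeds: int = 100,
    n_per_group: int = 200,
    n_train: int = 300,
    weakening: float = 0.5,
    seed0: int = 0,
) -> dict:
    """Power of the splice-strength comparison: per seed, a weak-donor
    group (donor PWM mixed toward uniform, GT dinucleotide kept) is
    compared against a strong-donor group under a MEM signal model trained
    on an independent strong sample; the batch (donor + null acceptor
    comparison) is BH-adjusted as in the strength stage. Also verifies the
    MEM/PWM equivalence under single-position constraints and the fitted
    marginals."""
    weak_matrix = _weaken(DONOR_PWM.matrix, weakening, DONOR_FIXED_POSITIONS)
    n_sig = 0
    max_diff = 0.0
    max_resid = 0.0
    for s in range(n_seeds):
        rng = np.random.default_rng(seed0 + 1000 + s)
        train = sample_sites_from_pwm(DONOR_PWM.matrix, n_train, rng)
        weak = sample_sites_from_pwm(weak_matrix, n_per_group, rng)
        strong = sample_sites_from_pwm(DONOR_PWM.matrix, n_per_group, rng)
        mem = splicestrength.train_mem(
            train, splicestrength.single_position_constraints(9))
        donor_cmp = splicestrength.compare_strength(weak, strong, mem,
                                                    alternative="two-sided",
                                                    label="first_donor")
        # matched-acceptor control comparison completes the BH batch
        acc_a = sample_sites_from_pwm(synthdata.ACCEPTOR_PWM.matrix, n_per_group, rng)
        acc_b = sample_sites_from_pwm(synthdata.ACCEPTOR_PWM.matrix, n_per_group, rng)
        acc_model = splicestrength.train_factorized_mem(
            sample_sites_from_pwm(synthdata.ACCEPTOR_PWM.matrix, n_train, rng))
        acc_cmp = splicestrength.compare_strength(acc_a, acc_b, acc_model,
                                                  alternative="two-sided",
                                                  label="first_acceptor")
        splicestrength.adjust_comparisons([donor_cmp, acc_cmp])
        direction_ok = donor_cmp.scores_a.mean() < donor_cmp.scores_b.mean()
        if donor_cmp.fdr < 0.05 and direction_ok:
            n_sig += 1
        if s == 0:
            pwm = splicestrength.train_pwm(train)
            probe = sample_sites_from_pwm(DONOR_PWM.matrix, 50, rng)
            diffs = [abs(mem.log2_prob(k) - pwm.log2_prob(k)) for k in probe]
            max_diff = max(diffs)
            for c in mem.constraints:
                emp = splicestrength._empirical_marginal(train, c, 0.5)
                max_resid = max(max_resid, float(np.max(np.abs(mem.marginal(c) - emp))))
    return {
        "n_seeds": n_seeds,
        "power": n_sig / n_seeds,
        "mem_pwm_max_abs_diff": max_diff,
        "mem_marginal_max_resid": max_resid,
    }


def run_null_calibration(
    n_reps: int = 1000,
    n_windows: int = 6,
    n_per_group: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I rate of the per-window one-sided Mann-Whitney content test
    when target and control windows are drawn from the same distribution."""
    rng = np.random.default_rng(seed)
    n_tests = n_rej = 0
    for _ in range(n_reps):
        for _ in range(n_windows):
            t = rng.normal(0.5, 0.1, size=n_per_group)
            c = rng.normal(0.5, 0.1, size=n_per_group)
            _, p = statcore.mann_whitney(t, c, alternative="greater")
            n_tests += 1
            if p < alpha:
                n_rej += 1
    return {"n_tests": n_tests, "type1_rate": n_rej / n_tests, "alpha": alpha}


def _big_genome_config(seed: int, n_genes: int, planted_motifs=()) -> SimulationConfig:
    return SimulationConfig(seed=seed, n_genes=n_genes, n_chromosomes=3,
                            chrom_length=1_000_000, planted_motifs=planted_motifs)


def run_content_power(seed: int, n_genes: int = 450, bias: float = 1.5) -> dict:
    """Detection of the planted GU-rich 5' regions: fraction of tested
    TSS-anchored GU-content windows reaching FDR < 0.05 (the bias spans the
    whole profiled region of every trans-spliced gene, so every tested
    window is a planted window)."""
    cfg = dataclasses.replace(_big_genome_config(seed, n_genes), planted_gu_au_bias=bias)
    genome, annotation, truth = synthdata.generate_genome(cfg)
    models = geneclass.gene_models_from_gff(annotation)
    by_id = {m.gene_id: m for m in models}
    ts = [by_id[g.gene_id] for g in truth.genes if g.is_ts and not g.operonic]
    nt = [by_id[g.gene_id] for g in truth.genes if not g.is_ts and not g.operonic]
    tprof = [p for m in ts if (p := contentenrich.profile_gene(
        m, genome, "tss", "GU", max_offset=600)) is not None]
    cprof = [p for m in nt if (p := contentenrich.profile_gene(
        m, genome, "tss", "GU", max_offset=600)) is not None]
    res = contentenrich.test_windows(tprof, cprof)
    tested = [r for r in res if r.tested]
    n_sig = sum(1 for r in tested if r.fdr < 0.05)
    return {
        "n_target_genes": len(tprof),
        "n_control_genes": len(cprof),
        "n_windows": len(tested),
        "frac_windows_significant": n_sig / max(1, len(tested)),
    }


def run_motif_power(
    n_seeds: int = 20,
    n_genes: int = 450,
    rate: float = 0.5,
    background_n: int = 3000,
    seed0: int = 0,
) -> dict:
    """Two-stage local motif enrichment power and false-positive rate: per
    seed, the planted motif (rate occurrences/gene in a fixed band of
    trans-spliced genes, absent from controls and background) and a
    never-planted motif are both put through stage 1 (binomial vs
    intergenic background) and stage 2 (Fisher vs non-trans-spliced
    controls)."""
    n_planted_called = n_null_called = 0
    for s in range(n_seeds):
        cfg = _big_genome_config(
            seed0 + 2000 + s, n_genes,
            planted_motifs=(PlantedMotif(DEFAULT_PLANTED_MOTIF, rate=rate, band=(60, 120)),))
        genome, annotation, truth = synthdata.generate_genome(cfg)
        models = geneclass.gene_models_from_gff(annotation)
        by_id = {m.gene_id: m for m in models}
        ts = [g.gene_id for g in truth.genes if g.is_ts and not g.operonic]
        nt = [g.gene_id for g in truth.genes if not g.is_ts and not g.operonic]
        t_seqs = [q for g in ts if (q := five_prime_region_seq(by_id[g], genome, 600))]
        c_seqs = [q for g in nt if (q := five_prime_region_seq(by_id[g], genome, 600))]
        bg = motifenrich.sample_background(genome, models, background_n, 600,
                                           seed=cfg.seed + 7)
        results = motifenrich.run_motif_enrichment(
            t_seqs, c_seqs, bg, [DEFAULT_PLANTED_MOTIF, NULL_MOTIF])
        called = {r.motif_id: r.locally_enriched for r in results}
        n_planted_called += int(called[DEFAULT_PLANTED_MOTIF.motif_id])
        n_null_called += int(called[NULL_MOTIF.motif_id])
    return {
        "n_seeds": n_seeds,
        "planted_called_rate": n_planted_called / n_seeds,
        "null_called_rate": n_null_called / n_seeds,
    }
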