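"""End-to-end orchestration: simulate -> classify tags -> map -> cluster ->
call TAS/TSS -> classify genes -> splice-strength / content / motif
analyses, with reproducible, provenance-stamped outputs.

Every stage is also usable directly from the library; `run_all` wires the
stages together, writes each result table as TSV with a header recording
the tool version, config hash and seed, and logs the counts at each
filtering step.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import contentenrich, geneclass, motifenrich, splicestrength, synthdata, tagcall
from .geneclass import GeneClassification, GeneModel
from .ioformats import (
    BedRecord,
    Interval,
    MotifPWM,
    read_meme,
    write_bed,
    write_fasta,
    write_fastq,
    write_gff3,
    write_tsv,
)
from .synthdata import GroundTruth, SimulationConfig, transcribed_seq

logger = logging.getLogger(__name__)

N_CONTENT_SPECS = ("A", "C", "G", "U")
NN_CONTENT_SPECS = ("AC", "AG", "AU", "CG", "CU", "GU")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # tag calling
    min_prefix_match: int = 16
    max_gap: int = tagcall.DEFAULT_MAX_GAP
    required_unique: bool = True
    # gene classification
    ratio_threshold: float = 0.5
    first_as_mode: str = "per_site"
    # enrichment geometry
    window: int = 30
    step: int = 10
    region_cap: int = 600  # profiled span downstream of the TSS
    # motif enrichment
    background_n: int = 3000
    motif_p_threshold: float = 1e-4
    fdr_threshold: float = 0.05
    motif_file: Optional[str] = None
    # stage toggles
    run_strength: bool = True
    run_content: bool = True
    run_motif: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("simulation", {})
        motifs = [synthdata.PlantedMotif(MotifPWM(m["id"], np.array(m["matrix"])),
                                         rate=m.get("rate", 0.5),
                                         band=tuple(m.get("band", (60, 120))))
                  for m in sim_raw.pop("planted_motifs", [])]
        sim = SimulationConfig(**sim_raw, planted_motifs=tuple(motifs))
        return cls(simulation=sim, **raw)

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)
        # stage toggles are excluded: they select which outputs are written
        # but never change the content of the stages that do run
        skip = {"simulation", "run_strength", "run_content", "run_motif"}
        blob = yaml.safe_dump(
            {"simulation": {k: (v.tolist() if isinstance(v, np.ndarray) else str(v))
                            for k, v in asdict(self.simulation).items()},
             **{k: str(v) for k, v in asdict(self).items() if k not in skip}},
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: RunConfig
    genome: dict[str, str]
    truth: GroundTruth
    annotation: list
    peaks: list[BedRecord]
    models: list[GeneModel]
    tas_sites: list[tagcall.TransSpliceSite]
    tss_clusters: list[tagcall.TagCluster]
    classifications: list[GeneClassification]
    classify_stats: tagcall.ClassifyStats
    map_stats: dict[str, tagcall.MapStats]
    tas_stats: tagcall.TasStats
    first_as: Optional[tuple[int, int, float, float]] = None
    strength: list[splicestrength.StrengthComparison] = field(default_factory=list)
    content_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    motif_results: list[motifenrich.MotifEnrichmentResult] = field(default_factory=list)


def _header(cfg: RunConfig, extra: str = "") -> list[str]:
    lines = [f"outronscan {__version__}", f"config_hash {cfg.config_hash()}",
             f"seed {cfg.simulation.seed}"]
    if extra:
        lines.append(extra)
    return lines


def five_prime_region_seq(model: GeneModel, genome: dict[str, str], cap: int) -> Optional[str]:
    """Transcribed-strand sequence from the TSS to the first cis acceptor
    site (capped), the region content/motif analyses profile."""
    tx = model.reference_transcript()
    if tx is None:
        return None
    accs = tx.acceptor_positions()
    if not accs:
        return None
    length = min(abs(accs[0] - tx.five_prime), cap)
    if length < 1:
        return None
    return transcribed_seq(genome, model.chrom, tx.five_prime, model.strand, length)


def classification_table(classifications: Sequence[GeneClassification]) -> pd.DataFrame:
    rows = []
    for c in classifications:
        rows.append({
            "gene_id": c.gene_id,
            "status": c.status,
            "operonic": c.operonic,
            "n_tas": len(c.tas_sites),
            "major_tas": -1 if c.major_tas is None else c.major_tas.pos,
            "location": c.tas_location,
            "group": c.group,
            "tss": -1 if c.tss is None else c.tss,
            "tss_tags": c.tss_tags,
            "tas_tags": c.tas_tags,
            "ts_ratio": np.nan if c.ts_ratio is None else c.ts_ratio,
            "ts_class": c.ts_class or "",
        })
    return pd.DataFrame(rows)


def run_all(cfg: RunConfig, outdir: str | Path) -> PipelineResult:
    """Execute all stages in dependency order; a stage failure raises
    PipelineStageError naming the stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        genome, annotation, truth = synthdata.generate_genome(cfg.simulation)
        reads, read_truth = synthdata.simulate_tags(genome, truth)
        peaks = synthdata.simulate_atac(truth)
        write_fasta(outdir / "genome.fa", genome)
        write_gff3(outdir / "annotation.gff3", annotation)
        write_fastq(outdir / "tags.fastq", reads)
        write_bed(outdir / "atac_peaks.bed", peaks)
        write_tsv(outdir / "read_truth.tsv", read_truth, _header(cfg))
        write_tsv(outdir / "gene_truth.tsv", synthdata.truth_gene_table(truth), _header(cfg))
        logger.info("simulate: %d genes, %d reads, %d peaks",
                    len(truth.genes), len(reads), len(peaks))

        stage = "classify"
        sl_reads, capped_reads, cstats = tagcall.classify_reads(
            reads, cfg.simulation.sl_sequence, cfg.min_prefix_match)
        logger.info("classify: %d SL, %d capped, %d empty skipped",
                    cstats.n_sl, cstats.n_capped, cstats.n_empty_skipped)

        stage = "map"
        index = tagcall.KmerIndex(genome)
        sl_aln, sl_ms = tagcall.map_five_prime(sl_reads, genome, "SL",
                                               cfg.required_unique, index)
        cap_aln, cap_ms = tagcall.map_five_prime(capped_reads, genome, "capped",
                                                 cfg.required_unique, index)
        map_stats = {"SL": sl_ms, "capped": cap_ms}
        for cat, ms in map_stats.items():
            logger.info("map %s: %d mapped, %d multimapped dropped, %d unmapped",
                        cat, ms.n_mapped, ms.n_multimapped, ms.n_unmapped)

        stage = "call-tas"
        sl_clusters = tagcall.cluster_tags(sl_aln, cfg.max_gap)
        tas_sites, tas_stats = tagcall.call_tas(sl_clusters, genome)
        logger.info("call-tas: %d sites kept, %d positions discarded, %d clusters dropped",
                    tas_stats.n_positions_kept, tas_stats.n_positions_discarded,
                    tas_stats.n_clusters_dropped)
        tas_df = pd.DataFrame([{"chrom": s.chrom, "pos": s.pos, "strand": s.strand,
                                "tag_count": s.tag_count} for s in tas_sites])
        write_tsv(outdir / "tas_sites.tsv", tas_df, _header(cfg))

        stage = "call-tss"
        cap_clusters = tagcall.cluster_tags(cap_aln, cfg.max_gap)
        tss_clusters = tagcall.call_tss(cap_clusters, peaks)
        tss_df = pd.DataFrame([
            {"chrom": cl.interval.chrom, "mode_pos": cl.mode_pos, "strand": cl.strand,
             "total_tags": cl.total_tags, "start": cl.interval.start, "end": cl.interval.end}
            for cl in tss_clusters
        ])
        write_tsv(outdir / "tss_clusters.tsv", tss_df, _header(cfg))

        stage = "classify-genes"
        models = geneclass.gene_models_from_gff(annotation)
        classifications = geneclass.classify_genes(
            models, tas_sites, tss_clusters, ratio_threshold=cfg.ratio_threshold)
        cls_df = classification_table(classifications)
        write_tsv(outdir / "gene_classification.tsv", cls_df, _header(cfg))
        by_status = cls_df["status"].value_counts().to_dict()
        logger.info("classify-genes: %s", by_status)
        locations = [c.tas_location for c in classifications
                     if not c.operonic and c.status == geneclass.STATUS_TS]
        model_by_id = {m.gene_id: m for m in models}
        non_operonic_models = [model_by_id[c.gene_id] for c in classifications
                               if not c.operonic]
        first_as = None
        try:
            first_as = geneclass.first_as_enrichment_test(
                locations, non_operonic_models, cfg.first_as_mode)
            logger.info("first-AS binomial: k=%d n=%d p0=%.4f p=%.3g", *first_as)
        except ValueError as exc:
            logger.warning("first-AS test skipped: %s", exc)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    result = PipelineResult(
        config=cfg, genome=genome, truth=truth, annotation=annotation, peaks=peaks,
        models=models, tas_sites=tas_sites, tss_clusters=tss_clusters,
        classifications=classifications, classify_stats=cstats, map_stats=map_stats,
        tas_stats=tas_stats, first_as=first_as,
    )

    ts1 = [c.gene_id for c in classifications if not c.operonic and c.group == "TS-1stAS"]
    ts_all = [c.gene_id for c in classifications
              if not c.operonic and c.status == geneclass.STATUS_TS]
    non_ts = [c.gene_id for c in classifications
              if not c.operonic and c.status == geneclass.STATUS_NON_TS]
    model_by_id = {m.gene_id: m for m in models}

    if cfg.run_strength:
        stage = "splice-strength"
        try:
            result.strength = _strength_stage(cfg, outdir, genome, model_by_id, ts1, non_ts)
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc
    if cfg.run_content:
        stage = "content-enrich"
        try:
            result.content_tables = _content_stage(cfg, outdir, genome, model_by_id,
                                                   ts_all, non_ts)
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc
    if cfg.run_motif:
        stage = "motif-enrich"
        try:
            result.motif_results = _motif_stage(cfg, outdir, genome, models,
                                                model_by_id, ts_all, non_ts)
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc
    return result


def _strength_stage(cfg, outdir, genome, model_by_id, ts1, non_ts):
    ts_models = [model_by_id[g] for g in ts1]
    nt_models = [model_by_id[g] for g in non_ts]
    comparisons = []
    for site_type in ("donor", "acceptor"):
        a = splicestrength.extract_sites(ts_models, genome, site_type, scope="first")
        b = splicestrength.extract_sites(nt_models, genome, site_type, scope="first")
        if len(a) < 2 or len(b) < 2:
            logger.warning("strength %s: too few sites (%d vs %d)", site_type, len(a), len(b))
            continue
        # train on internal (non-first) sites so the scored first sites are
        # out-of-sample; in-sample scoring inflates the training group
        train = splicestrength.extract_sites(ts_models + nt_models, genome,
                                             site_type, scope="internal")
        if len(train) < 10:
            logger.warning("strength %s: training pool too small (%d)",
                           site_type, len(train))
            continue
        if site_type == "donor":
            signal = splicestrength.train_mem(
                train, splicestrength.single_position_constraints(len(train[0])))
        else:
            signal = splicestrength.train_factorized_mem(train)
        comparisons.append(splicestrength.compare_strength(
            a, b, signal, alternative="two-sided", label=f"first_{site_type}"))
    splicestrength.adjust_comparisons(comparisons)
    rows = [{"comparison": c.label, "n_ts": len(c.scores_a), "n_non_ts": len(c.scores_b),
             "mean_ts": float(np.mean(c.scores_a)), "mean_non_ts": float(np.mean(c.scores_b)),
             "U": c.u, "pvalue": c.pvalue, "fdr": c.fdr} for c in comparisons]
    write_tsv(outdir / "splice_strength.tsv", pd.DataFrame(rows), _header(cfg))
    return comparisons


def _content_stage(cfg, outdir, genome, model_by_id, ts_all, non_ts):
    tables = {}
    ts_models = [model_by_id[g] for g in ts_all]
    nt_models = [model_by_id[g] for g in non_ts]
    long_rows = []
    for anchor in ("tss", "first_as"):
        for spec in N_CONTENT_SPECS + NN_CONTENT_SPECS:
            tprof = [p for m in ts_models
                     if (p := contentenrich.profile_gene(
                         m, genome, anchor, spec, cfg.window, cfg.step,
                         max_offset=cfg.region_cap)) is not None]
            cprof = [p for m in nt_models
                     if (p := contentenrich.profile_gene(
                         m, genome, anchor, spec, cfg.window, cfg.step,
                         max_offset=cfg.region_cap)) is not None]
            if not tprof or not cprof:
                continue
            res = contentenrich.test_windows(tprof, cprof)
            long_rows.append(contentenrich.enrichment_table(res, spec, anchor))
    long_df = pd.concat(long_rows, ignore_index=True) if long_rows else pd.DataFrame()
    write_tsv(outdir / "content_enrichment.tsv", long_df, _header(cfg))
    tables["windows"] = long_df

    # whole-region comparison of the first exon + intron
    t_seqs = [s for g in ts_all
              if (s := five_prime_region_seq(model_by_id[g], genome, 10 ** 9))]
    c_seqs = [s for g in non_ts
              if (s := five_prime_region_seq(model_by_id[g], genome, 10 ** 9))]
    if t_seqs and c_seqs:
        for label, specs in (("N", N_CONTENT_SPECS), ("NN", NN_CONTENT_SPECS)):
            df = contentenrich.compare_region_content(t_seqs, c_seqs, specs)
            write_tsv(outdir / f"region_content_{label}.tsv", df, _header(cfg))
            tables[f"region_{label}"] = df
    return tables


def _motif_stage(cfg, outdir, genome, models, model_by_id, ts_all, non_ts):
    if cfg.motif_file:
        pwms = read_meme(cfg.motif_file)
    elif cfg.simulation.planted_motifs:
        pwms = [pm.pwm for pm in cfg.simulation.planted_motifs]
    else:
        logger.info("motif stage: no motifs supplied; skipping")
        return []
    pwms = motifenrich.merge_redundant_motifs(pwms)
    t_seqs = [s for g in ts_all
              if (s := five_prime_region_seq(model_by_id[g], genome, cfg.region_cap))]
    c_seqs = [s for g in non_ts
              if (s := five_prime_region_seq(model_by_id[g], genome, cfg.region_cap))]
    bg = motifenrich.sample_background(genome, models, cfg.background_n,
                                       cfg.region_cap, seed=cfg.simulation.seed + 7)
    results = motifenrich.run_motif_enrichment(
        t_seqs, c_seqs, bg, pwms, cfg.window, cfg.step,
        cfg.motif_p_threshold, cfg.fdr_threshold)
    rows = []
    for r in results:
        for t in r.stage1:
            rows.append({"motif": r.motif_id, "stage": 1, "offset": t.offset,
                         "n": t.n, "k": t.k, "p": t.p, "x": np.nan, "C": np.nan,
                         "pvalue": t.pvalue, "fdr": t.fdr, "log2_fe": np.nan})
        for t in r.stage2:
            rows.append({"motif": r.motif_id, "stage": 2, "offset": t.offset,
                         "n": t.N, "k": t.R, "p": np.nan, "x": t.x, "C": t.C,
                         "pvalue": t.pvalue, "fdr": t.fdr,
                         "log2_fe": np.nan if t.log2_fold_enrichment is None
                         else t.log2_fold_enrichment})
    write_tsv(outdir / "motif_enrichment.tsv", pd.DataFrame(rows), _header(cfg))
    summary = pd.DataFrame([{"motif": r.motif_id,
                             "n_candidate_windows": len(r.candidate_offsets),
                             "locally_enriched": r.locally_enriched} for r in results])
    write_tsv(outdir / "motif_summary.tsv", summary, _header(cfg))
    return results
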