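import logging

import pytest

from outronscan import synthdata, tagcall
from outronscan.synthdata import SimulationConfig

logging.getLogger("outronscan").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def small_sim():
    """A 60-gene toy genome with reads, peaks and ground truth, shared by
    read-level and gene-level tests."""
    cfg = SimulationConfig(seed=11, n_genes=60)
    genome, annotation, truth = synthdata.generate_genome(cfg)
    reads, read_truth = synthdata.simulate_tags(genome, truth)
    peaks = synthdata.simulate_atac(truth)
    return dict(cfg=cfg, genome=genome, annotation=annotation, truth=truth,
                reads=reads, read_truth=read_truth, peaks=peaks)


@pytest.fixture(scope="session")
def called_sites(small_sim):
    """Tag calling run end-to-end on the small simulation."""
    cfg, genome = small_sim["cfg"], small_sim["genome"]
    sl, capped, cstats = tagcall.classify_reads(small_sim["reads"], cfg.sl_sequence)
    index = tagcall.KmerIndex(genome)
    sl_aln, sl_stats = tagcall.map_five_prime(sl, genome, "SL", True, index)
    cap_aln, cap_stats = tagcall.map_five_prime(capped, genome, "capped", True, index)
    sl_clusters = tagcall.cluster_tags(sl_aln)
    tas_sites, tas_stats = tagcall.call_tas(sl_clusters, genome)
    cap_clusters = tagcall.cluster_tags(cap_aln)
    tss_clusters = tagcall.call_tss(cap_clusters, small_sim["peaks"])
    return dict(sl=sl, capped=capped, cstats=cstats, sl_aln=sl_aln, cap_aln=cap_aln,
                sl_stats=sl_stats, cap_stats=cap_stats, sl_clusters=sl_clusters,
                cap_clusters=cap_clusters, tas_sites=tas_sites, tas_stats=tas_stats,
                tss_clusters=tss_clusters)
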