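"""Shared configuration for the analysis drivers.

One 300-gene toy genome (three 600-kb chromosomes, ~50% trans-spliced
genes, 10% operonic, GU/AU-biased outrons, one planted motif) analysed by
scripts 01-06. All drivers read/write under results/run/.
"""

from pathlib import Path

from outronscan.pipeline import RunConfig
from outronscan.synthdata import (
    DEFAULT_PLANTED_MOTIF,
    PlantedMotif,
    SimulationConfig,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
RUN_DIR = RESULTS / "run"


def demo_config(seed: int = 1) -> RunConfig:
    sim = SimulationConfig(
        seed=seed,
        n_genes=300,
        n_chromosomes=3,
        chrom_length=600_000,
        planted_motifs=(PlantedMotif(DEFAULT_PLANTED_MOTIF, rate=0.5, band=(60, 120)),),
    )
    return RunConfig(simulation=sim, background_n=2000)
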