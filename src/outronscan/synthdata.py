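"""Synthetic toy genome with planted spliced-leader trans-splicing truth.

The generator emulates the statistical structure the downstream analysis
assumes for a tunicate-like genome in which roughly half of the genes are
SL trans-spliced:

* multi-exon genes placed on both strands of uniform-background
  chromosomes, a configurable fraction grouped into operons (consecutive
  same-strand genes with zero intergenic gap whose downstream members start
  at a trans-splice acceptor site);
* per trans-spliced gene, a major trans-splice acceptor site (TAS) either
  at the first cis-splice acceptor site (the "TS-1stAS" group) or inside
  the first exon's 5' UTR (the "TS-5UTR" group), plus geometrically decaying
  minor sites within +/-50 bp, every site with the obligatory AG
  immediately 5';
* an outron (TSS to first acceptor site) with log-normal length,
  GU/AU-biased composition for trans-spliced genes, and optionally planted
  motif occurrences in a fixed band downstream of the TSS;
* 5'-end tag reads: SL-prefixed reads starting at TAS positions and capped
  reads starting at the TSS, mixed at a per-gene Beta-drawn trans-splicing
  ratio; plus decoy capped tags at intergenic positions outside any open
  chromatin peak;
* open-chromatin (ATAC-like) peaks covering every true TSS, plus decoys.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ioformats import (
    ALPHABET,
    BedRecord,
    FastqRead,
    GffRecord,
    Interval,
    MotifPWM,
    revcomp,
)

# Default 16-nt spliced-leader 5' exon (the SL RNA fragment joined to the TAS).
DEFAULT_SL_SEQUENCE = "ATTCTATTTGAATAAG"

# Strong donor site model over the 9-bp window (-3..+6); GT at +1/+2 is
# invariant. Values are consensus-like, not fitted to any organism.
DONOR_PWM = MotifPWM(
    "donor_strong",
    np.array(
        [
            [0.33, 0.36, 0.18, 0.13],  # -3
            [0.60, 0.13, 0.14, 0.13],  # -2
            [0.09, 0.05, 0.78, 0.08],  # -1
            [0.00, 0.00, 1.00, 0.00],  # +1 G
            [0.00, 0.00, 0.00, 1.00],  # +2 T
            [0.60, 0.03, 0.34, 0.03],  # +3
            [0.70, 0.08, 0.10, 0.12],  # +4
            [0.06, 0.06, 0.82, 0.06],  # +5
            [0.18, 0.18, 0.19, 0.45],  # +6
        ]
    ),
)

# Acceptor model over the 23-bp window (-20..+3): pyrimidine-rich tract,
# then the invariant AG at -2/-1.
_PYRIMIDINE_ROW = [0.12, 0.30, 0.13, 0.45]
ACCEPTOR_PWM = MotifPWM(
    "acceptor_strong",
    np.array(
        [_PYRIMIDINE_ROW] * 16
        + [
            [0.22, 0.30, 0.08, 0.40],  # -4
            [0.05, 0.65, 0.05, 0.25],  # -3
            [1.00, 0.00, 0.00, 0.00],  # -2 A
            [0.00, 0.00, 1.00, 0.00],  # -1 G
            [0.25, 0.10, 0.50, 0.15],  # +1
            [0.25, 0.20, 0.20, 0.35],  # +2
            [0.25, 0.25, 0.25, 0.25],  # +3
        ]
    ),
)

DONOR_FIXED_POSITIONS = (3, 4)  # GT, kept even when the donor is weakened


def _sharp_pwm(motif_id: str, consensus: str, major: float = 0.94) -> MotifPWM:
    minor = (1.0 - major) / 3.0
    rows = []
    for b in consensus:
        row = [minor] * 4
        row["ACGT".index(b)] = major
        rows.append(row)
    return MotifPWM(motif_id, np.array(rows))


# Default planted motif: an information-rich 10-mer (GU-flavoured, matching
# the biased 5' regions it is planted into) whose PWM-sampled sites almost
# always pass a FIMO-style 1e-4 score threshold.
DEFAULT_PLANTED_MOTIF = _sharp_pwm("planted_GU10", "TGTAGTGCTT")
# A motif that is never planted anywhere; its enrichment calls estimate the
# pipeline's false-positive rate.
NULL_MOTIF = _sharp_pwm("null_CA10", "CACGATACCA")


class SizingError(ValueError):
    """Gene complement cannot fit into the configured chromosomes."""


@dataclass(frozen=True)
class PlantedMotif:
    """A PWM planted at `rate` occurrences/gene in a fixed band of the 5'
    transcribed region (offsets from the TSS, transcript coordinates) of
    trans-spliced genes."""

    pwm: MotifPWM
    rate: float = 0.5
    band: tuple[int, int] = (60, 120)
    region: str = "outron"


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 150_000
    n_genes: int = 60
    operon_fraction: float = 0.10
    ts_gene_fraction: float = 0.50
    per_gene_ts_ratio_distribution: tuple[float, float] = (2.0, 2.0)
    sl_sequence: str = DEFAULT_SL_SEQUENCE
    tag_depth_per_gene: float = 200.0
    tas_positional_jitter: float = 15.0
    planted_gu_au_bias: float = 1.5
    planted_motifs: tuple[PlantedMotif, ...] = ()
    # gene architecture
    ts_first_as_fraction: float = 0.45
    outron_length_median: float = 458.0
    outron_length_sigma: float = 0.40
    minor_tas_mean: float = 1.5
    minor_tas_decay: float = 0.30
    ts_first_donor_weakening: float = 0.5
    # reads
    read_length: int = 50
    error_rate: float = 0.0
    # decoys
    n_decoy_peaks: int = 5
    n_decoy_tss: int = 8
    decoy_tag_depth: float = 30.0
    # layout
    min_intergenic_gap: int = 200
    max_intergenic_gap: int = 800

    def __post_init__(self) -> None:
        if len(self.sl_sequence) != 16:
            raise ValueError("sl_sequence must be exactly 16 nt")
        for name in ("operon_fraction", "ts_gene_fraction", "ts_first_as_fraction",
                     "ts_first_donor_weakening", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_chromosomes", "chrom_length", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.planted_gu_au_bias < 1.0:
            raise ValueError("planted_gu_au_bias must be >= 1")
        a, b = self.per_gene_ts_ratio_distribution
        if a <= 0 or b <= 0:
            raise ValueError("Beta parameters must be positive")
        if self.read_length <= len(self.sl_sequence):
            raise ValueError("read_length must exceed the SL length")


@dataclass
class GeneTruth:
    gene_id: str
    chrom: str
    strand: str
    body: Interval
    tss: Optional[int]  # genomic coordinate of the 5'-most transcribed base
    tas_positions: list[int] = field(default_factory=list)
    tas_shares: list[float] = field(default_factory=list)
    ts_ratio: float = 0.0
    is_ts: bool = False
    operonic: bool = False
    operon_id: str = ""
    group: str = "none"  # TS-1stAS | TS-5UTR | none
    exons: list[Interval] = field(default_factory=list)  # genomic, sorted
    outron: Optional[Interval] = None
    first_donor_weak: bool = False

    @property
    def major_tas(self) -> Optional[int]:
        if not self.tas_positions:
            return None
        return self.tas_positions[int(np.argmax(self.tas_shares))]


@dataclass
class GroundTruth:
    config: SimulationConfig
    genes: list[GeneTruth]
    motif_occurrences: list[tuple[str, str, Interval]] = field(default_factory=list)
    enriched_regions: list[Interval] = field(default_factory=list)
    decoy_peaks: list[Interval] = field(default_factory=list)
    decoy_tag_sites: list[tuple[str, int, str]] = field(default_factory=list)

    def gene(self, gene_id: str) -> GeneTruth:
        return next(g for g in self.genes if g.gene_id == gene_id)


# ---------------------------------------------------------------------------
# coordinate helpers

def transcribed_seq(genome: dict[str, str], chrom: str, pos: int, strand: str, length: int) -> str:
    """Genomic sequence of `length` bases starting at `pos` and running
    downstream on `strand` (pos is the 5'-most transcribed base)."""
    if strand == "+":
        return genome[chrom][pos: pos + length]
    return revcomp(genome[chrom][pos - length + 1: pos + 1])


def ag_upstream(genome: dict[str, str], chrom: str, pos: int, strand: str) -> bool:
    """True if the two genomic bases immediately 5' of `pos` read AG on
    `strand`."""
    seq = genome[chrom]
    if strand == "+":
        return pos >= 2 and seq[pos - 2: pos] == "AG"
    return pos + 3 <= len(seq) and seq[pos + 1: pos + 3] == "CT"


def _sample_from_pwm(rng: np.random.Generator, pwm_matrix: np.ndarray) -> str:
    idx = [rng.choice(4, p=row / row.sum()) for row in pwm_matrix]
    return "".join(ALPHABET[i] for i in idx)


def _weaken(matrix: np.ndarray, weight: float, fixed: Sequence[int]) -> np.ndarray:
    """Mix PWM columns toward uniform by `weight`, keeping `fixed` rows."""
    out = (1.0 - weight) * matrix + weight * 0.25
    for i in fixed:
        out[i] = matrix[i]
    return out


# ---------------------------------------------------------------------------
# per-gene architecture (local transcript coordinates, 0 = 5' end)

@dataclass
class _GenePlan:
    length: int
    seq: list[str]  # local transcript-strand sequence
    exon_bounds: list[tuple[int, int]]  # local, for the full (non-SL) transcript
    tss_local: Optional[int]
    tas_local: list[int]
    tas_shares: list[float]
    outron_end: Optional[int]  # local end of the TSS..first-AS region
    group: str
    first_donor_weak: bool
    motif_occurrences: list[tuple[str, int, int]]  # (pwm_id, local_start, local_end)


def _reserve(reserved: list[tuple[int, int]], start: int, end: int) -> bool:
    for s, e in reserved:
        if start < e and s < end:
            return False
    reserved.append((start, end))
    return True


def _plan_gene(rng: np.random.Generator, cfg: SimulationConfig, *,
               is_ts: bool, group: str, operon_member: bool) -> _GenePlan:
    """Lay out one gene in local transcript coordinates and build its
    sequence with all signals planted."""
    # outron = exon1 + intron1 (TSS to first cis acceptor site)
    outron = int(round(float(rng.lognormal(math.log(cfg.outron_length_median),
                                           cfg.outron_length_sigma))))
    outron = int(np.clip(outron, 220, 2500))
    e1 = int(np.clip(int(outron * rng.uniform(0.3, 0.6)), 140, outron - 60))
    n_exons = int(rng.integers(2, 5))
    exon_lens = [e1] + [int(rng.integers(80, 201)) for _ in range(n_exons - 1)]
    intron_lens = [outron - e1] + [int(rng.integers(100, 301)) for _ in range(n_exons - 2)]

    exon_bounds, pos = [], 0
    for i, el in enumerate(exon_lens):
        exon_bounds.append((pos, pos + el))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    length = pos

    seq = list(rng.choice(list(ALPHABET), size=length))
    reserved: list[tuple[int, int]] = []

    # GU/AU composition bias over the 5' region of trans-spliced genes
    if is_ts and not operon_member and cfg.planted_gu_au_bias > 1.0:
        f = cfg.planted_gu_au_bias
        w = np.array([1.0, 1.0, f, f])
        w /= w.sum()
        biased = rng.choice(list(ALPHABET), size=outron, p=w)
        seq[:outron] = list(biased)

    # splice sites for every intron
    weak_first = is_ts and group == "TS-1stAS" and cfg.ts_first_donor_weakening > 0
    for k in range(n_exons - 1):
        d_end = exon_bounds[k][1]  # local coord of intron start
        a_start = exon_bounds[k + 1][0]  # local coord of exon k+2 start
        donor_matrix = DONOR_PWM.matrix
        if k == 0 and weak_first:
            donor_matrix = _weaken(donor_matrix, cfg.ts_first_donor_weakening,
                                   DONOR_FIXED_POSITIONS)
        donor = _sample_from_pwm(rng, donor_matrix)
        seq[d_end - 3: d_end + 6] = list(donor)
        _reserve(reserved, d_end - 3, d_end + 6)
        acceptor = _sample_from_pwm(rng, ACCEPTOR_PWM.matrix)
        seq[a_start - 20: a_start + 3] = list(acceptor)
        _reserve(reserved, a_start - 20, a_start + 3)

    # TAS placement
    tas_local: list[int] = []
    tas_shares: list[float] = []
    if is_ts:
        if operon_member:
            major = 0  # gene starts at its TAS; upstream AG is planted later
        elif group == "TS-1stAS":
            major = outron  # first cis acceptor site (AG from the acceptor window)
        else:  # TS-5UTR: inside exon 1, downstream of the TSS
            major = int(rng.integers(80, e1 - 30))
            seq[major - 2: major] = ["A", "G"]
            _reserve(reserved, major - 2, major)
        tas_local.append(major)
        tas_shares.append(1.0)
        if not operon_member:
            n_minor = min(int(rng.poisson(cfg.minor_tas_mean)), 3)
            lo = 30 if group == "TS-5UTR" else max(30, major - 50)
            hi = min(length - 40, major + 50)
            for j in range(n_minor):
                placed = False
                for _ in range(20):
                    off = int(rng.geometric(1.0 / cfg.tas_positional_jitter))
                    cand = major + off * (1 if rng.random() < 0.5 else -1)
                    if cand == major or not lo <= cand <= hi or cand in tas_local:
                        continue
                    if _reserve(reserved, cand - 2, cand):
                        seq[cand - 2: cand] = ["A", "G"]
                        tas_local.append(cand)
                        tas_shares.append(cfg.minor_tas_decay ** (j + 1))
                        placed = True
                        break
                if not placed:
                    break
            total = sum(tas_shares)
            tas_shares = [s / total for s in tas_shares]

    # planted motif occurrences in the 5' band
    occurrences: list[tuple[str, int, int]] = []
    if is_ts and not operon_member:
        for pm in cfg.planted_motifs:
            n_occ = int(rng.random() < pm.rate) if pm.rate <= 1.0 else int(rng.poisson(pm.rate))
            band_lo, band_hi = pm.band
            band_hi = min(band_hi, outron) - pm.pwm.width
            for _ in range(n_occ):
                for _ in range(20):
                    start = int(rng.integers(band_lo, max(band_lo + 1, band_hi)))
                    if _reserve(reserved, start, start + pm.pwm.width):
                        site = _sample_from_pwm(rng, pm.pwm.matrix)
                        seq[start: start + pm.pwm.width] = list(site)
                        occurrences.append((pm.pwm.motif_id, start, start + pm.pwm.width))
                        break

    tss_local = None if operon_member else 0
    return _GenePlan(
        length=length,
        seq=seq,
        exon_bounds=exon_bounds,
        tss_local=tss_local,
        tas_local=tas_local,
        tas_shares=tas_shares,
        outron_end=None if operon_member else outron,
        group="none" if operon_member else group,
        first_donor_weak=weak_first and not operon_member,
        motif_occurrences=occurrences,
    )


# ---------------------------------------------------------------------------
# genome assembly

def _local_to_genomic(t: int, start: int, end: int, strand: str) -> int:
    return start + t if strand == "+" else end - 1 - t


def _plan_layout(rng: np.random.Generator, cfg: SimulationConfig) -> list[list[dict]]:
    """Group genes into placement units (operon runs and singletons) with
    strands assigned; returns a list of units, each a list of gene slots."""
    n_operonic = int(round(cfg.operon_fraction * cfg.n_genes))
    units: list[list[dict]] = []
    remaining = cfg.n_genes
    op_idx = 0
    while n_operonic >= 2 and remaining >= 2:
        size = int(min(rng.integers(2, 4), n_operonic, remaining))
        # avoid stranding a single leftover operonic gene (runs need >= 2)
        if n_operonic - size == 1:
            size = size + 1 if size + 1 <= min(n_operonic, remaining) else size - 1
        if size < 2:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        op_id = f"operon_{op_idx}"
        unit = []
        for j in range(size):
            unit.append({"operonic": True, "operon_id": op_id, "strand": strand,
                         "member_index": j})
        units.append(unit)
        n_operonic -= size
        remaining -= size
        op_idx += 1
    for _ in range(remaining):
        strand = "+" if rng.random() < 0.5 else "-"
        units.append([{"operonic": False, "operon_id": "", "strand": strand,
                       "member_index": 0}])
    perm = rng.permutation(len(units))
    return [units[i] for i in perm]


def generate_genome(cfg: SimulationConfig) -> tuple[dict[str, str], list[GffRecord], GroundTruth]:
    """Build the toy genome, its annotation, and the full ground truth.

    Raises SizingError when the gene complement cannot fit.
    """
    rng = np.random.default_rng(cfg.seed)
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    chroms = {name: list(rng.choice(list(ALPHABET), size=cfg.chrom_length))
              for name in chrom_names}

    margin = max(cfg.min_intergenic_gap, cfg.read_length + 10)
    units = _plan_layout(rng, cfg)

    truth = GroundTruth(config=cfg, genes=[])
    chrom_i, cursor = 0, margin
    gene_idx = 0
    operon_ag_fixups: list[tuple[str, int, str]] = []  # (chrom, gene5', strand)

    for unit in units:
        # plan all members first so the unit length is known before placement
        plans = []
        for slot in unit:
            member = slot["member_index"]
            if slot["operonic"]:
                is_ts = member > 0  # downstream operon members start at a TAS
                group = "none"
            else:
                is_ts = bool(rng.random() < cfg.ts_gene_fraction)
                group = ("TS-1stAS" if rng.random() < cfg.ts_first_as_fraction
                         else "TS-5UTR") if is_ts else "none"
            plans.append(_plan_gene(rng, cfg, is_ts=is_ts, group=group,
                                    operon_member=slot["operonic"] and member > 0))
        unit_len = sum(p.length for p in plans)
        gap = int(rng.integers(cfg.min_intergenic_gap, cfg.max_intergenic_gap + 1))
        while cursor + unit_len + margin > cfg.chrom_length:
            chrom_i += 1
            cursor = margin
            if chrom_i >= cfg.n_chromosomes:
                raise SizingError(
                    f"{cfg.n_genes} genes do not fit in {cfg.n_chromosomes} x "
                    f"{cfg.chrom_length} bp chromosomes"
                )
        chrom = chrom_names[chrom_i]
        strand = unit[0]["strand"]
        # transcriptional order within an operon: left-to-right on '+',
        # right-to-left on '-'; plans[0] is the transcriptionally first gene.
        placement = plans if strand == "+" else plans[::-1]
        starts = []
        for plan in placement:
            starts.append(cursor)
            chroms[chrom][cursor: cursor + plan.length] = (
                plan.seq if strand == "+" else list(revcomp("".join(plan.seq)))
            )
            cursor += plan.length
        cursor += gap
        if strand == "-":
            starts = starts[::-1]

        for slot, plan, gstart in zip(unit, plans, starts):
            gend = gstart + plan.length
            gid = f"gene_{gene_idx:04d}"
            gene_idx += 1
            g = lambda t: _local_to_genomic(t, gstart, gend, strand)
            exons = []
            for (s, e) in plan.exon_bounds:
                a, b = g(s), g(e - 1)
                lo, hi = (a, b) if a <= b else (b, a)
                exons.append(Interval(chrom, lo, hi + 1, strand))
            exons.sort(key=lambda iv: iv.start)
            tas_pos = [g(t) for t in plan.tas_local]
            is_ts = bool(tas_pos)
            ratio = 0.0
            if is_ts:
                if slot["operonic"] and slot["member_index"] > 0:
                    ratio = 1.0
                else:
                    a, b = cfg.per_gene_ts_ratio_distribution
                    ratio = float(rng.beta(a, b))
            outron_iv = None
            if plan.outron_end is not None and is_ts:
                a, b = g(0), g(plan.outron_end - 1)
                lo, hi = (a, b) if a <= b else (b, a)
                outron_iv = Interval(chrom, lo, hi + 1, strand)
                truth.enriched_regions.append(outron_iv)
            gt = GeneTruth(
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                body=Interval(chrom, gstart, gend, strand),
                tss=g(plan.tss_local) if plan.tss_local is not None else None,
                tas_positions=tas_pos,
                tas_shares=list(plan.tas_shares),
                ts_ratio=ratio,
                is_ts=is_ts,
                operonic=slot["operonic"],
                operon_id=slot["operon_id"],
                group=plan.group,
                exons=exons,
                outron=outron_iv,
                first_donor_weak=plan.first_donor_weak,
            )
            truth.genes.append(gt)
            for motif_id, s, e in plan.motif_occurrences:
                a, b = g(s), g(e - 1)
                lo, hi = (a, b) if a <= b else (b, a)
                truth.motif_occurrences.append((motif_id, gid, Interval(chrom, lo, hi + 1, strand)))
            if slot["operonic"] and slot["member_index"] > 0:
                operon_ag_fixups.append((chrom, g(0), strand))

    # plant AG immediately 5' of operonic downstream gene starts (these two
    # bases fall inside the upstream neighbour because the gap is zero)
    for chrom, g5, strand in operon_ag_fixups:
        if strand == "+":
            chroms[chrom][g5 - 2: g5] = ["A", "G"]
        else:
            chroms[chrom][g5 + 1: g5 + 3] = ["C", "T"]

    genome = {name: "".join(seq) for name, seq in chroms.items()}

    # decoy ATAC peaks and decoy capped-tag sites in intergenic space
    peak_half = 150
    tss_list = [(g.chrom, g.tss) for g in truth.genes if g.tss is not None]
    occupied = [(g.chrom, g.body.start - margin, g.body.end + margin) for g in truth.genes]

    def _intergenic(chrom: str, pos: int, pad: int) -> bool:
        return all(not (c == chrom and s - pad < pos < e + pad) for c, s, e in occupied)

    attempts = 0
    while len(truth.decoy_peaks) < cfg.n_decoy_peaks and attempts < 2000:
        attempts += 1
        chrom = chrom_names[int(rng.integers(cfg.n_chromosomes))]
        pos = int(rng.integers(peak_half + 1, cfg.chrom_length - peak_half - 1))
        if _intergenic(chrom, pos, peak_half) and all(
            not (p.chrom == chrom and abs(pos - (p.start + p.end) // 2) < 2 * peak_half)
            for p in truth.decoy_peaks
        ):
            truth.decoy_peaks.append(Interval(chrom, pos - peak_half, pos + peak_half))
    attempts = 0
    while len(truth.decoy_tag_sites) < cfg.n_decoy_tss and attempts < 2000:
        attempts += 1
        chrom = chrom_names[int(rng.integers(cfg.n_chromosomes))]
        pos = int(rng.integers(cfg.read_length + 2, cfg.chrom_length - cfg.read_length - 2))
        near_peak = any(
            p.chrom == chrom and p.start - 60 <= pos < p.end + 60 for p in truth.decoy_peaks
        ) or any(c == chrom and abs(pos - t) < peak_half + 60 for c, t in tss_list)
        if _intergenic(chrom, pos, 60) and not near_peak and all(
            not (c == chrom and abs(pos - q) < 120) for c, q, _ in truth.decoy_tag_sites
        ):
            strand = "+" if rng.random() < 0.5 else "-"
            truth.decoy_tag_sites.append((chrom, pos, strand))

    annotation = truth_annotation(truth)
    return genome, annotation, truth


# ---------------------------------------------------------------------------
# annotation emission

def _transcript_records(gt: GeneTruth, tx_id: str, five_start: int, status: str) -> list[GffRecord]:
    """Exon chain of a transcript whose 5' end (genomic coordinate of the
    5'-most base) is `five_start`; exons are clipped accordingly."""
    if gt.strand == "+":
        exons = [Interval(gt.chrom, max(e.start, five_start), e.end, "+")
                 for e in gt.exons if e.end > five_start]
        span = Interval(gt.chrom, exons[0].start, exons[-1].end, "+")
    else:
        exons = [Interval(gt.chrom, e.start, min(e.end, five_start + 1), "-")
                 for e in gt.exons if e.start <= five_start]
        span = Interval(gt.chrom, exons[0].start, exons[-1].end, "-")
    records = [GffRecord("mRNA", span, tx_id, gt.gene_id,
                         attributes={"five_prime_status": status})]
    for i, e in enumerate(exons):
        records.append(GffRecord("exon", e, f"{tx_id}.e{i + 1}", tx_id))
    return records


def truth_annotation(truth: GroundTruth) -> list[GffRecord]:
    """Full annotation: per gene, the non-SL transcript from the true TSS
    when the gene has one, and an SL transcript from the major TAS for
    trans-spliced genes."""
    records = []
    for gt in truth.genes:
        records.append(GffRecord("gene", gt.body, gt.gene_id))
        if gt.tss is not None:
            records.extend(_transcript_records(gt, f"{gt.gene_id}.t1", gt.tss, "non-SL"))
        if gt.is_ts and gt.major_tas is not None:
            records.extend(_transcript_records(gt, f"{gt.gene_id}.tSL", gt.major_tas, "SL"))
    return records


def truncated_annotation(truth: GroundTruth) -> tuple[list[GffRecord], list[GffRecord]]:
    """Emulate an incomplete reference annotation plus novel transcripts.

    The "known" set truncates trans-spliced genes at their major TAS (as an
    EST-based model would, since efficient trans-splicing hides the outron);
    the "novel" set holds the outron-containing transcripts recovered by
    re-assembly. Redefining gene bodies from known+novel restores the truth.
    """
    known, novel = [], []
    for gt in truth.genes:
        if gt.is_ts and gt.major_tas is not None:
            if gt.strand == "+":
                body = Interval(gt.chrom, gt.major_tas, gt.body.end, "+")
            else:
                body = Interval(gt.chrom, gt.body.start, gt.major_tas + 1, "-")
            known.append(GffRecord("gene", body, gt.gene_id))
            known.extend(_transcript_records(gt, f"{gt.gene_id}.t1", gt.major_tas, "SL"))
            if gt.tss is not None:
                novel.extend(_transcript_records(gt, f"{gt.gene_id}.nov1", gt.tss, "non-SL"))
        else:
            known.append(GffRecord("gene", gt.body, gt.gene_id))
            if gt.tss is not None:
                known.extend(_transcript_records(gt, f"{gt.gene_id}.t1", gt.tss, "non-SL"))
    return known, novel


# ---------------------------------------------------------------------------
# reads and peaks

_TSS_JITTER_OFFSETS = np.array([-2, -1, 0, 1, 2])
_TSS_JITTER_PROBS = np.array([0.05, 0.10, 0.70, 0.10, 0.05])


def _maybe_error(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = ALPHABET[int(rng.integers(4))]
    return "".join(chars)


def simulate_tags(
    genome: dict[str, str],
    truth: GroundTruth,
    cfg: Optional[SimulationConfig] = None,
) -> tuple[list[FastqRead], pd.DataFrame]:
    """5'-end tag reads plus a per-read truth table.

    SL reads carry the full SL prefix followed by genomic sequence from a
    TAS (site chosen by the per-site expected shares); capped reads start at
    the TSS with small positional jitter. Per-gene read counts are Poisson
    around tag_depth_per_gene; the SL count is Binomial(n, true ratio).
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng(cfg.seed + 1)
    sl = cfg.sl_sequence
    reads: list[FastqRead] = []
    rows = []
    genomic_len_sl = cfg.read_length - len(sl)

    for gt in truth.genes:
        n = int(rng.poisson(cfg.tag_depth_per_gene))
        if n == 0:
            continue
        n_sl = int(rng.binomial(n, gt.ts_ratio)) if gt.is_ts else 0
        if not gt.tas_positions:
            n_sl = 0
        if gt.tss is None:
            n_sl = n  # operonic downstream genes emit SL tags only
        n_cap = n - n_sl
        if gt.tas_positions and n_sl:
            sites = rng.choice(len(gt.tas_positions), size=n_sl, p=np.asarray(gt.tas_shares))
        else:
            sites = []
        for i, si in enumerate(sites):
            pos = gt.tas_positions[int(si)]
            body = transcribed_seq(genome, gt.chrom, pos, gt.strand, genomic_len_sl)
            seq = _maybe_error(rng, sl + body, cfg.error_rate)
            rid = f"{gt.gene_id}:SL:{i}"
            reads.append(FastqRead(rid, seq))
            rows.append((rid, gt.gene_id, "SL", gt.chrom, pos, gt.strand))
        if gt.tss is not None:
            offs = rng.choice(_TSS_JITTER_OFFSETS, size=n_cap, p=_TSS_JITTER_PROBS)
            sign = 1 if gt.strand == "+" else -1
            for i, off in enumerate(offs):
                pos = gt.tss + sign * int(off)
                seq = _maybe_error(
                    rng, transcribed_seq(genome, gt.chrom, pos, gt.strand, cfg.read_length),
                    cfg.error_rate,
                )
                rid = f"{gt.gene_id}:cap:{i}"
                reads.append(FastqRead(rid, seq))
                rows.append((rid, gt.gene_id, "capped", gt.chrom, pos, gt.strand))

    for d_idx, (chrom, pos, strand) in enumerate(truth.decoy_tag_sites):
        n = int(rng.poisson(cfg.decoy_tag_depth))
        for i in range(n):
            seq = _maybe_error(
                rng, transcribed_seq(genome, chrom, pos, strand, cfg.read_length),
                cfg.error_rate,
            )
            rid = f"decoy_{d_idx}:cap:{i}"
            reads.append(FastqRead(rid, seq))
            rows.append((rid, f"decoy_{d_idx}", "capped", chrom, pos, strand))

    table = pd.DataFrame(rows, columns=["read_id", "gene_id", "category", "chrom", "pos", "strand"])
    return reads, table


def simulate_atac(truth: GroundTruth, peak_half_width: int = 150) -> list[BedRecord]:
    """One open-chromatin peak spanning each true TSS, plus the decoy peaks
    chosen at genome-generation time."""
    records = []
    for gt in truth.genes:
        if gt.tss is None:
            continue
        chrom_len = truth.config.chrom_length
        start = max(0, gt.tss - peak_half_width)
        end = min(chrom_len, gt.tss + peak_half_width)
        records.append(BedRecord(Interval(gt.chrom, start, end), f"peak_{gt.gene_id}"))
    for i, iv in enumerate(truth.decoy_peaks):
        records.append(BedRecord(iv, f"decoy_peak_{i}"))
    return records


def truth_gene_table(truth: GroundTruth) -> pd.DataFrame:
    rows = []
    for g in truth.genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": g.body.start,
                "end": g.body.end,
                "strand": g.strand,
                "tss": -1 if g.tss is None else g.tss,
                "major_tas": -1 if g.major_tas is None else g.major_tas,
                "tas_positions": ",".join(map(str, g.tas_positions)),
                "tas_shares": ",".join(f"{s:.6f}" for s in g.tas_shares),
                "ts_ratio": g.ts_ratio,
                "is_ts": g.is_ts,
                "operonic": g.operonic,
                "operon_id": g.operon_id,
                "group": g.group,
            }
        )
    return pd.DataFrame(rows)
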