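"""Gene-level classification of spliced-leader trans-splicing.

Gene bodies are redefined from known plus newly assembled transcripts,
operons detected (runs of same-strand genes with zero intergenic distance
whose downstream members start at a trans-splice acceptor site), each gene
classified as trans-spliced / non-trans-spliced / ambiguous from two TAS
sources, the major (most tag-supported) TAS located relative to the gene's
cis-exon structure, and the per-gene trans-splicing ratio computed from
TAS and TSS tag counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import statcore
from .ioformats import GffRecord, Interval
from .tagcall import TagCluster, TransSpliceSite, representative_tss

logger = logging.getLogger(__name__)

STATUS_TS = "trans_spliced"
STATUS_NON_TS = "non_trans_spliced"
STATUS_AMBIGUOUS = "ambiguous"


@dataclass
class Transcript:
    tx_id: str
    chrom: str
    strand: str
    exons: list[Interval]  # sorted by genomic start
    five_prime_status: str = "ND"  # non-SL | SL | ND

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping exons in transcript {self.tx_id}")

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    @property
    def exons_5to3(self) -> list[Interval]:
        return self.exons if self.strand == "+" else self.exons[::-1]

    @property
    def five_prime(self) -> int:
        return self.span.five_prime

    def acceptor_positions(self) -> list[int]:
        """Genomic coordinate of the first base of each internal exon, in
        transcript order; element k-1 is the k-th cis-splice acceptor site."""
        out = []
        for exon in self.exons_5to3[1:]:
            out.append(exon.start if self.strand == "+" else exon.end - 1)
        return out

    def donor_positions(self) -> list[int]:
        """Genomic coordinate of the first intronic base after each
        non-terminal exon, in transcript order."""
        out = []
        for exon in self.exons_5to3[:-1]:
            out.append(exon.end if self.strand == "+" else exon.start - 1)
        return out


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)
    declared_body: Optional[Interval] = None

    @property
    def body(self) -> Interval:
        """Union span of all transcripts (or the declared gene interval if
        the gene has no transcript records)."""
        if not self.transcripts:
            if self.declared_body is None:
                raise ValueError(f"gene {self.gene_id} has no extent")
            return self.declared_body
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        if self.declared_body is not None:
            start = min(start, self.declared_body.start)
            end = max(end, self.declared_body.end)
        return Interval(self.chrom, start, end, self.strand)

    @property
    def five_prime(self) -> int:
        return self.body.five_prime

    def reference_transcript(self) -> Optional[Transcript]:
        """The transcript against which TAS locations are judged: the
        non-SL (TSS-anchored) transcript when available, else the 5'-most
        transcript of undetermined status."""
        non_sl = [t for t in self.transcripts if t.five_prime_status == "non-SL"]
        pool = non_sl or self.transcripts
        if not pool:
            return None
        sign = 1 if self.strand == "+" else -1
        return min(pool, key=lambda t: sign * t.five_prime)


def gene_models_from_gff(records: Sequence[GffRecord]) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    tx_parent: dict[str, str] = {}
    tx_meta: dict[str, GffRecord] = {}
    tx_exons: dict[str, list[Interval]] = {}
    for r in records:
        if r.feature_type == "gene":
            genes[r.feature_id] = GeneModel(r.feature_id, r.interval.chrom,
                                            r.interval.strand, [], r.interval)
        elif r.feature_type in ("mRNA", "transcript"):
            tx_parent[r.feature_id] = r.parent
            tx_meta[r.feature_id] = r
            tx_exons.setdefault(r.feature_id, [])
        elif r.feature_type == "exon":
            tx_exons.setdefault(r.parent, []).append(r.interval)
    for tx_id, exons in tx_exons.items():
        meta = tx_meta.get(tx_id)
        if meta is None or not exons:
            continue
        status = meta.attributes.get("five_prime_status", "ND")
        tx = Transcript(tx_id, meta.interval.chrom, meta.interval.strand, exons, status)
        parent = tx_parent.get(tx_id, "")
        if parent in genes:
            genes[parent].transcripts.append(tx)
    return list(genes.values())


# ---------------------------------------------------------------------------
# gene-body redefinition

def redefine_gene_bodies(
    known: Sequence[GeneModel],
    novel_transcripts: Sequence[Transcript],
) -> list[GeneModel]:
    """Attach each novel transcript to the same-strand known gene it
    overlaps most (ties go to the 5'-most gene on the transcript's strand);
    transcripts overlapping no gene are dropped and logged. Gene count is
    unchanged; bodies become the union span of known + assigned transcripts.
    """
    out = [GeneModel(g.gene_id, g.chrom, g.strand, list(g.transcripts), g.declared_body)
           for g in known]
    n_dropped = 0
    for tx in novel_transcripts:
        overlaps = []
        for g in out:
            if g.chrom == tx.chrom and g.strand == tx.strand and g.body.overlaps(tx.span):
                ov = min(g.body.end, tx.span.end) - max(g.body.start, tx.span.start)
                overlaps.append((ov, g))
        if not overlaps:
            n_dropped += 1
            logger.info("novel transcript %s overlaps no known gene; dropped", tx.tx_id)
            continue
        best = max(ov for ov, _ in overlaps)
        tied = [g for ov, g in overlaps if ov == best]
        if len(tied) > 1:
            sign = 1 if tx.strand == "+" else -1
            tied.sort(key=lambda g: sign * g.five_prime)
            logger.info("novel transcript %s ties between genes; assigned to 5'-most %s",
                        tx.tx_id, tied[0].gene_id)
        tied[0].transcripts.append(tx)
    if n_dropped:
        logger.info("redefine_gene_bodies: %d novel transcripts dropped", n_dropped)
    return out


# ---------------------------------------------------------------------------
# operons

def detect_operons(
    models: Sequence[GeneModel],
    tas_sites: Sequence[TransSpliceSite],
) -> dict[str, bool]:
    """Flag maximal same-strand runs of >= 2 genes with pairwise intergenic
    distance <= 0 in which every transcriptionally non-first gene's 5' end
    coincides with a trans-splice acceptor site."""
    tas_set = {(s.chrom, s.strand, s.pos) for s in tas_sites}
    flags = {g.gene_id: False for g in models}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in models:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, genes in by_chrom.items():
        genes.sort(key=lambda g: (g.body.start, g.body.end))
        run = [genes[0]] if genes else []
        for g in genes[1:]:
            prev = run[-1]
            gap = g.body.start - prev.body.end
            downstream = g if g.strand == "+" else prev
            chained = (
                g.strand == prev.strand
                and gap <= 0
                and (chrom, downstream.strand, downstream.five_prime) in tas_set
            )
            if chained:
                run.append(g)
            else:
                if len(run) >= 2:
                    for m in run:
                        flags[m.gene_id] = True
                run = [g]
        if len(run) >= 2:
            for m in run:
                flags[m.gene_id] = True
    return flags


# ---------------------------------------------------------------------------
# classification

def _sites_on_body(model: GeneModel, sites: Sequence[TransSpliceSite]) -> list[TransSpliceSite]:
    body = model.body
    return [s for s in sites
            if s.chrom == model.chrom and s.strand == model.strand and body.contains(s.pos)]


def classify_gene(
    model: GeneModel,
    primary_tas: Sequence[TransSpliceSite],
    secondary_tas: Sequence[TransSpliceSite] = (),
) -> str:
    """trans_spliced if >= 1 primary (tag-based) TAS lies on the gene body;
    ambiguous if only secondary (annotation-based) TAS do; otherwise
    non_trans_spliced."""
    if _sites_on_body(model, primary_tas):
        return STATUS_TS
    if _sites_on_body(model, secondary_tas):
        return STATUS_AMBIGUOUS
    return STATUS_NON_TS


def select_major_tas(sites: Sequence[TransSpliceSite]) -> TransSpliceSite:
    """The most tag-supported site; ties break 5'-most on the site strand."""
    if not sites:
        raise ValueError("select_major_tas requires >= 1 site")
    best = max(s.tag_count for s in sites)
    tied = [s for s in sites if s.tag_count == best]
    if len(tied) > 1:
        logger.info("major TAS tie (%d sites at count %d); taking 5'-most", len(tied), best)
    sign = 1 if tied[0].strand == "+" else -1
    return min(tied, key=lambda s: sign * s.pos)


LOCATION_AS_PREFIX = "AS_"


def locate_tas(model: GeneModel, major: TransSpliceSite) -> str:
    """Locate the major TAS relative to the reference transcript.

    Categories: AS_k (coincides with the k-th cis-splice acceptor site),
    5UTR_first_exon (inside the first exon), internal_exon, other; the
    suffix _nd replaces the determined forms when the reference transcript
    is not TSS-anchored (non-SL)."""
    tx = model.reference_transcript()
    if tx is None or not tx.exons:
        return "other"
    determined = tx.five_prime_status == "non-SL"
    for k, acc in enumerate(tx.acceptor_positions(), start=1):
        if major.pos == acc:
            return f"AS_{k}" if determined else "AS_nd"
    exons = tx.exons_5to3
    if exons[0].contains(major.pos):
        return "5UTR_first_exon" if determined else "5UTR_nd"
    for exon in exons[1:]:
        if exon.contains(major.pos):
            return "internal_exon"
    return "other"


def group_label(status: str, location: str) -> str:
    if status != STATUS_TS:
        return "none"
    if location == "AS_1":
        return "TS-1stAS"
    if location == "5UTR_first_exon":
        return "TS-5UTR"
    return "other"


def compute_ts_ratio(tss_tags: int, tas_tags: int) -> float:
    """Fraction of a gene's 5'-end tags that are SL-derived:
    tas / (tas + tss). Higher means more trans-splicing."""
    if tss_tags < 0 or tas_tags < 0:
        raise ValueError("tag counts must be non-negative")
    if tss_tags + tas_tags == 0:
        raise ValueError("trans-splicing ratio undefined when both counts are zero")
    return tas_tags / (tas_tags + tss_tags)


def split_high_low(ratios: Sequence[float], threshold: float = 0.5) -> list[str]:
    """ratio >= threshold -> TS_High else TS_Low (boundary inclusive)."""
    return ["TS_High" if r >= threshold else "TS_Low" for r in ratios]


def first_as_enrichment_test(
    locations: Sequence[str],
    models: Sequence[GeneModel],
    mode: str = "per_site",
) -> tuple[int, int, float, float]:
    """Upper-tail binomial test that major TAS fall at the first cis-splice
    acceptor site more often than background.

    k = genes whose major TAS is at AS_1; n = genes whose major TAS is at
    any determined cis acceptor site. Background p0 is, in "per_site" mode,
    the fraction of all cis acceptor sites (over reference transcripts with
    introns) that are first sites; in "per_gene" mode the mean over genes
    of 1 / (number of acceptor sites). Returns (k, n, p0, p).
    """
    k = sum(1 for loc in locations if loc == "AS_1")
    n = sum(1 for loc in locations
            if loc.startswith(LOCATION_AS_PREFIX) and loc != "AS_nd")
    if n == 0:
        raise ValueError("no genes with a major TAS at a determined acceptor site")
    counts = []
    for m in models:
        tx = m.reference_transcript()
        if tx is not None:
            n_acc = len(tx.acceptor_positions())
            if n_acc > 0:
                counts.append(n_acc)
    if not counts:
        raise ValueError("no spliced reference transcripts for the background")
    if mode == "per_site":
        p0 = len(counts) / sum(counts)
    elif mode == "per_gene":
        p0 = sum(1.0 / c for c in counts) / len(counts)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    p = statcore.binom_upper_tail(statcore.BinomialInput(n=n, k=k, p=p0))
    return k, n, p0, p


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class GeneClassification:
    gene_id: str
    status: str
    operonic: bool
    tas_sites: list[TransSpliceSite] = field(default_factory=list)
    major_tas: Optional[TransSpliceSite] = None
    tas_location: str = ""
    group: str = "none"
    tss: Optional[int] = None
    tss_tags: int = 0
    tas_tags: int = 0
    ts_ratio: Optional[float] = None
    ts_class: Optional[str] = None


def _tss_search_region(model: GeneModel, major: Optional[TransSpliceSite],
                       margin: int = 10) -> Interval:
    """Region in which a gene's TSS clusters are sought: from slightly
    upstream of the gene body down to (but excluding) the major TAS."""
    body = model.body
    if model.strand == "+":
        end = major.pos if major is not None else body.end
        return Interval(model.chrom, max(0, body.start - margin), max(body.start + 1, end), "+")
    start = major.pos + 1 if major is not None else body.start
    return Interval(model.chrom, min(start, body.end - 1), body.end + margin, "-")


def classify_genes(
    models: Sequence[GeneModel],
    primary_tas: Sequence[TransSpliceSite],
    tss_clusters: Sequence[TagCluster] = (),
    secondary_tas: Sequence[TransSpliceSite] = (),
    ratio_threshold: float = 0.5,
) -> list[GeneClassification]:
    """Full per-gene classification from called sites and TSS clusters."""
    operon_flags = detect_operons(models, primary_tas)
    out = []
    for model in models:
        status = classify_gene(model, primary_tas, secondary_tas)
        rec = GeneClassification(model.gene_id, status, operon_flags[model.gene_id])
        if status == STATUS_TS:
            rec.tas_sites = _sites_on_body(model, primary_tas)
            rec.major_tas = select_major_tas(rec.tas_sites)
            rec.tas_location = locate_tas(model, rec.major_tas)
            rec.group = group_label(status, rec.tas_location)
            rec.tas_tags = sum(s.tag_count for s in rec.tas_sites)
        region = _tss_search_region(model, rec.major_tas)
        rep = representative_tss(tss_clusters, region)
        if rep is not None:
            rec.tss = rep.mode_pos
            rec.tss_tags = rep.total_tags
        if rec.major_tas is not None and rec.tss is not None:
            rec.ts_ratio = compute_ts_ratio(rec.tss_tags, rec.tas_tags)
            rec.ts_class = split_high_low([rec.ts_ratio], ratio_threshold)[0]
        out.append(rec)
    n_undef = sum(1 for r in out if r.status == STATUS_TS and r.ts_ratio is None)
    if n_undef:
        logger.info("classify_genes: %d trans-spliced genes lack a defined ratio "
                    "(no TSS identified); excluded from High/Low analysis", n_undef)
    return out
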