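"""Classify 5'-end tag reads, map their 5' ends, cluster them, and call
trans-splice acceptor sites (TAS) and transcription start sites (TSS).

Reads carrying the spliced-leader (SL) prefix mark trans-splice acceptor
sites; reads without it mark capped 5' ends (TSS candidates). Mapping is
exact-match via a 2-bit k-mer index (the simulator emits error-free,
genome-contiguous tags, so ungapped exact search is sufficient at this
scale); reads mapping to more than one locus are dropped when uniqueness is
required. Capped clusters count as TSS evidence only when they overlap an
open-chromatin peak.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .ioformats import BedRecord, FastqRead, Interval, revcomp

logger = logging.getLogger(__name__)

DEFAULT_MAX_GAP = 50  # bp; minor acceptor sites scatter within 50 bp of major ones


@dataclass(frozen=True)
class TagAlignment:
    """5'-most base of one or more identical tags on the genome."""

    chrom: str
    pos: int
    strand: str
    category: str  # "SL" | "capped"
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.category not in ("SL", "capped"):
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class TagCluster:
    interval: Interval
    category: str
    mode_pos: int
    total_tags: int
    positions: dict[int, int]  # per-position tag counts

    def __post_init__(self) -> None:
        assert self.interval.contains(self.mode_pos)
        assert self.total_tags == sum(self.positions.values())

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class TransSpliceSite:
    chrom: str
    pos: int
    strand: str
    tag_count: int
    gene_id: str = ""
    is_major: bool = False


@dataclass
class ClassifyStats:
    n_sl: int = 0
    n_capped: int = 0
    n_empty_skipped: int = 0


@dataclass
class MapStats:
    n_mapped: int = 0
    n_unmapped: int = 0
    n_multimapped: int = 0


@dataclass
class TasStats:
    n_positions_kept: int = 0
    n_positions_discarded: int = 0
    n_clusters_dropped: int = 0


# ---------------------------------------------------------------------------
# read classification

def classify_reads(
    reads: Iterable[FastqRead],
    sl_sequence: str,
    min_prefix_match: int = 16,
) -> tuple[list[FastqRead], list[FastqRead], ClassifyStats]:
    """Partition reads into SL (prefix-trimmed) and capped sets.

    A read is SL iff its first `min_prefix_match` bases exactly equal the
    3'-terminal `min_prefix_match` bases of the SL sequence (shorter
    matches accommodate 5'-truncated SL tails). Empty reads are skipped
    with a logged warning.
    """
    if not 1 <= min_prefix_match <= len(sl_sequence):
        raise ValueError("min_prefix_match must be in [1, len(sl_sequence)]")
    suffix = sl_sequence[-min_prefix_match:]
    sl_reads, capped_reads = [], []
    stats = ClassifyStats()
    for r in reads:
        if not r.seq:
            logger.warning("skipping empty read %s", r.read_id)
            stats.n_empty_skipped += 1
            continue
        if r.seq[:min_prefix_match] == suffix:
            trimmed = FastqRead(r.read_id, r.seq[min_prefix_match:],
                                r.qual[min_prefix_match:] if r.qual else "")
            sl_reads.append(trimmed)
            stats.n_sl += 1
        else:
            capped_reads.append(r)
            stats.n_capped += 1
    return sl_reads, capped_reads, stats


# ---------------------------------------------------------------------------
# exact mapping via a 2-bit k-mer index

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


class KmerIndex:
    """Exact-occurrence index: seed on the first k bases, verify in full."""

    def __init__(self, genome: dict[str, str], k: int = 16):
        self.k = k
        self.genome = genome
        self._chroms: list[str] = []
        self._kmers: list[np.ndarray] = []  # sorted kmer codes per chrom
        self._positions: list[np.ndarray] = []
        for chrom, seq in genome.items():
            codes = _encode(seq).astype(np.uint64)
            if len(codes) < k:
                km = np.empty(0, dtype=np.uint64)
            else:
                n = len(codes) - k + 1
                km = np.zeros(n, dtype=np.uint64)
                for j in range(k):
                    km |= codes[j: n + j] << np.uint64(2 * (k - 1 - j))
            order = np.argsort(km, kind="stable")
            self._chroms.append(chrom)
            self._kmers.append(km[order])
            self._positions.append(order.astype(np.int64))

    def _encode_kmer(self, seq: str) -> int:
        codes = _encode(seq[: self.k])
        if (codes > 3).any():
            return -1
        val = 0
        for c in codes:
            val = (val << 2) | int(c)
        return val

    def find_all(self, pattern: str) -> list[tuple[str, int]]:
        """All exact forward-strand occurrence start positions genome-wide."""
        if len(pattern) < self.k:
            raise ValueError(f"pattern shorter than index k={self.k}")
        key = self._encode_kmer(pattern)
        if key < 0:
            return []
        hits = []
        for chrom, kms, pos in zip(self._chroms, self._kmers, self._positions):
            lo = np.searchsorted(kms, key, side="left")
            hi = np.searchsorted(kms, key, side="right")
            seq = self.genome[chrom]
            for p in pos[lo:hi]:
                p = int(p)
                if seq[p: p + len(pattern)] == pattern:
                    hits.append((chrom, p))
        return hits


def map_five_prime(
    reads: Sequence[FastqRead],
    genome: dict[str, str],
    category: str,
    required_unique: bool = True,
    index: Optional[KmerIndex] = None,
) -> tuple[list[TagAlignment], MapStats]:
    """Map read 5' ends by exact search on both strands.

    `pos` is the genomic coordinate of the RNA's 5'-most base: the match
    start on '+', the match end minus one on '-'. With `required_unique`, a
    read is kept only when it occurs exactly once genome-wide (both strands
    combined); multi-mapping and unmapped reads are counted and dropped.
    Identical sequences are mapped once and their counts aggregated.
    """
    index = index or KmerIndex(genome)
    stats = MapStats()
    seq_counts = Counter(r.seq for r in reads)
    agg: Counter[tuple[str, int, str]] = Counter()
    for seq, n in seq_counts.items():
        fwd = index.find_all(seq)
        rev = index.find_all(revcomp(seq))
        total = len(fwd) + len(rev)
        if total == 0:
            stats.n_unmapped += n
            continue
        if required_unique and total > 1:
            stats.n_multimapped += n
            continue
        if fwd:
            chrom, p = fwd[0]
            agg[(chrom, p, "+")] += n
        else:
            chrom, p = rev[0]
            agg[(chrom, p + len(seq) - 1, "-")] += n
        stats.n_mapped += n
    alignments = [
        TagAlignment(chrom, pos, strand, category, count)
        for (chrom, pos, strand), count in sorted(agg.items())
    ]
    return alignments, stats


# ---------------------------------------------------------------------------
# clustering

def cluster_tags(alignments: Sequence[TagAlignment], max_gap: int = DEFAULT_MAX_GAP) -> list[TagCluster]:
    """Single-linkage chaining of tag positions per chrom/strand/category:
    consecutive positions <= max_gap apart join one cluster. The mode is the
    highest-count position; ties break 5'-most on the cluster's strand."""
    groups: dict[tuple[str, str, str], Counter] = {}
    for a in alignments:
        groups.setdefault((a.chrom, a.strand, a.category), Counter())[a.pos] += a.count
    clusters = []
    for (chrom, strand, category), counts in sorted(groups.items()):
        positions = sorted(counts)
        run: list[int] = []
        for p in positions + [None]:  # type: ignore[list-item]
            if run and (p is None or p - run[-1] > max_gap):
                sub = {q: counts[q] for q in run}
                best = max(sub.values())
                modes = [q for q, c in sub.items() if c == best]
                mode = min(modes) if strand == "+" else max(modes)
                clusters.append(
                    TagCluster(
                        interval=Interval(chrom, run[0], run[-1] + 1, strand),
                        category=category,
                        mode_pos=mode,
                        total_tags=sum(sub.values()),
                        positions=sub,
                    )
                )
                run = []
            if p is not None:
                run.append(p)
    return clusters


# ---------------------------------------------------------------------------
# site calling

def ag_upstream(genome: dict[str, str], chrom: str, pos: int, strand: str) -> bool:
    """True if the dinucleotide immediately 5' of pos reads AG on strand."""
    seq = genome[chrom]
    if strand == "+":
        return pos >= 2 and seq[pos - 2: pos] == "AG"
    return pos + 3 <= len(seq) and seq[pos + 1: pos + 3] == "CT"


def call_tas(
    sl_clusters: Sequence[TagCluster],
    genome: dict[str, str],
) -> tuple[list[TransSpliceSite], TasStats]:
    """Within each SL cluster, every tag position with an upstream AG
    becomes a trans-splice acceptor site carrying its tag count; positions
    failing the AG check are discarded, clusters with no AG-compatible
    position dropped (both counted)."""
    stats = TasStats()
    sites = []
    for cl in sl_clusters:
        if cl.category != "SL":
            raise ValueError("call_tas expects SL-category clusters")
        kept_any = False
        for pos, count in sorted(cl.positions.items()):
            if ag_upstream(genome, cl.interval.chrom, pos, cl.strand):
                sites.append(TransSpliceSite(cl.interval.chrom, pos, cl.strand, count))
                stats.n_positions_kept += 1
                kept_any = True
            else:
                stats.n_positions_discarded += 1
        if not kept_any:
            stats.n_clusters_dropped += 1
    for s in sites:
        assert ag_upstream(genome, s.chrom, s.pos, s.strand)
    return sites, stats


def peak_tree(peaks: Sequence[BedRecord]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.interval.chrom, IntervalTree()).addi(p.interval.start, p.interval.end)
    return trees


def call_tss(
    capped_clusters: Sequence[TagCluster],
    peaks: Sequence[BedRecord],
) -> list[TagCluster]:
    """Keep capped clusters whose interval overlaps at least one
    open-chromatin peak by >= 1 bp; the rest are artifacts. The cluster
    mode is the putative TSS."""
    trees = peak_tree(peaks)
    kept = []
    for cl in capped_clusters:
        if cl.category != "capped":
            raise ValueError("call_tss expects capped-category clusters")
        tree = trees.get(cl.interval.chrom)
        if tree is not None and tree.overlaps(cl.interval.start, cl.interval.end):
            kept.append(cl)
    logger.info("call_tss: %d/%d capped clusters overlap open chromatin",
                len(kept), len(capped_clusters))
    return kept


def representative_tss(clusters: Sequence[TagCluster], region: Interval) -> Optional[TagCluster]:
    """Highest-count TSS cluster whose mode lies in `region` (same strand);
    ties break on the 5'-most mode."""
    candidates = [
        cl for cl in clusters
        if cl.interval.chrom == region.chrom and cl.strand == region.strand
        and region.contains(cl.mode_pos)
    ]
    if not candidates:
        return None
    sign = 1 if region.strand == "+" else -1
    return max(candidates, key=lambda cl: (cl.total_tags, -sign * cl.mode_pos))
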