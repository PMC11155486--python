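"""PWM motif scanning and two-stage local motif enrichment.

Scanning is FIMO-style: at each offset the window is scored by the summed
log-likelihood ratio of the PWM against a 0-order background, and the score
p-value is computed from the exact null score distribution obtained by
dynamic programming over integer-discretized per-column scores under the
background model. A hit is an offset whose score p-value is at or below
the threshold (default 1e-4).

Local enrichment proceeds in two stages over 30-bp windows of the 5'
transcribed regions: (1) a binomial test of the fraction of target
sequences with a hit in the window against the hit rate of intergenic
background sequences, BH-adjusted over windows, keeping windows with
FDR < 0.05 as candidates; (2) a one-sided Fisher exact test of targets
against control (non-trans-spliced) sequences in the candidate windows,
again BH-adjusted. A motif is locally enriched when at least one window
survives both stages. Each test counts sequences with >= 1 hit starting in
the window (presence/absence, not hit counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from . import statcore
from .geneclass import GeneModel
from .ioformats import ALPHABET, Interval, MotifPWM
from .tagcall import _encode  # 2-bit base encoding shared with the mapper

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLD = 1e-4
DEFAULT_WINDOW = 30
DEFAULT_STEP = 10
SCORE_PRECISION = 1000  # integer bins per log2 unit in the score DP


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    offset: int
    strand: str
    score: float  # log2 likelihood ratio
    pvalue: float


class MotifScanner:
    """Exact-p-value PWM scanner over the forward (sense) strand.

    Per-column log2-odds scores are discretized to 1/SCORE_PRECISION bins;
    the null distribution of the integer window score under the background
    model is computed exactly by DP, giving a monotone score -> p-value map
    and hence a minimal integer hit score for the chosen threshold.
    """

    def __init__(self, pwm: MotifPWM, p_threshold: float = DEFAULT_P_THRESHOLD):
        if (pwm.matrix == 0).any():
            raise ValueError(
                f"PWM {pwm.motif_id} has zero entries; apply a pseudocount before scanning"
            )
        if (pwm.background == 0).any():
            raise ValueError("background must be strictly positive")
        self.pwm = pwm
        self.p_threshold = p_threshold
        lods = np.log2(pwm.matrix / pwm.background)
        self.int_scores = np.rint(lods * SCORE_PRECISION).astype(np.int64)  # w x 4
        # exact null over integer scores by DP across columns
        dist: dict[int, float] = {0: 1.0}
        for col in range(pwm.width):
            nxt: dict[int, float] = {}
            for s, pr in dist.items():
                for b in range(4):
                    key = s + int(self.int_scores[col, b])
                    nxt[key] = nxt.get(key, 0.0) + pr * float(pwm.background[b])
            dist = nxt
        scores = np.array(sorted(dist))
        probs = np.array([dist[int(s)] for s in scores])
        self._null_scores = scores
        # P(S >= s) for each distinct s
        self._null_upper = np.cumsum(probs[::-1])[::-1]
        ge = self._null_upper <= p_threshold
        self.min_hit_score = int(scores[ge.argmax()]) if ge.any() else None

    def score_pvalue(self, int_score: int) -> float:
        i = np.searchsorted(self._null_scores, int_score, side="left")
        if i >= len(self._null_scores):
            return 0.0
        return float(self._null_upper[i])

    def _window_scores(self, seq: str) -> np.ndarray:
        w = self.pwm.width
        codes = _encode(seq)
        if len(codes) < w:
            raise ValueError("sequence shorter than motif width")
        valid = codes <= 3
        codes = np.where(valid, codes, 0)
        per_pos = self.int_scores[np.arange(w)[:, None],
                                  np.lib.stride_tricks.sliding_window_view(codes, w).T]
        scores = per_pos.sum(axis=0)
        bad = ~np.all(np.lib.stride_tricks.sliding_window_view(valid, w), axis=1)
        scores[bad] = np.iinfo(np.int64).min
        return scores

    def hit_offsets(self, seq: str) -> np.ndarray:
        """Offsets of hits (score p-value <= threshold)."""
        if self.min_hit_score is None:
            return np.empty(0, dtype=int)
        scores = self._window_scores(seq)
        return np.flatnonzero(scores >= self.min_hit_score)

    def scan(self, seq: str, seq_id: str = "") -> list[MotifHit]:
        scores = self._window_scores(seq)
        hits = []
        for off in np.flatnonzero(scores > np.iinfo(np.int64).min):
            p = self.score_pvalue(int(scores[off]))
            if p <= self.p_threshold:
                hits.append(MotifHit(seq_id, int(off), "+",
                                     scores[off] / SCORE_PRECISION, p))
        return hits


def scan_motif(pwm: MotifPWM, seq: str, p_threshold: float = DEFAULT_P_THRESHOLD,
               seq_id: str = "") -> list[MotifHit]:
    return MotifScanner(pwm, p_threshold).scan(seq, seq_id)


# ---------------------------------------------------------------------------
# background sampling

def intergenic_intervals(genome: dict[str, str], models: Sequence[GeneModel]) -> list[Interval]:
    out = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    for chrom, seq in genome.items():
        bodies = sorted((m.body.start, m.body.end) for m in by_chrom.get(chrom, []))
        cursor = 0
        for s, e in bodies:
            if s > cursor:
                out.append(Interval(chrom, cursor, s))
            cursor = max(cursor, e)
        if cursor < len(seq):
            out.append(Interval(chrom, cursor, len(seq)))
    return out


def sample_background(
    genome: dict[str, str],
    models: Sequence[GeneModel],
    n: int = 3000,
    length: int = 600,
    seed: int = 0,
) -> list[str]:
    """`n` sequences of `length` bp drawn uniformly from intergenic
    intervals (forward strand), seeded. Raises when the intergenic space is
    smaller than n * length."""
    rng = np.random.default_rng(seed)
    if n == 0:
        return []
    intervals = [iv for iv in intergenic_intervals(genome, models) if len(iv) >= length]
    total = sum(len(iv) for iv in intergenic_intervals(genome, models))
    if not intervals or total < n * length:
        raise ValueError(
            f"insufficient intergenic space ({total} bp) for {n} x {length} bp samples"
        )
    starts_per_iv = np.array([len(iv) - length + 1 for iv in intervals], dtype=float)
    probs = starts_per_iv / starts_per_iv.sum()
    out = []
    for _ in range(n):
        iv = intervals[int(rng.choice(len(intervals), p=probs))]
        s = int(rng.integers(iv.start, iv.end - length + 1))
        out.append(genome[iv.chrom][s: s + length])
    return out


# ---------------------------------------------------------------------------
# two-stage window enrichment

@dataclass
class BinomialWindowTest:
    offset: int
    n: int  # target sequences covering the window
    k: int  # target sequences with >= 1 hit in the window
    p: float  # fraction of background sequences with a hit in the window
    pvalue: float
    fdr: float = float("nan")


@dataclass
class FisherWindowTest:
    offset: int
    N: int
    C: int
    R: int
    x: int
    pvalue: float
    fdr: float = float("nan")

    @property
    def log2_fold_enrichment(self) -> Optional[float]:
        if self.R == 0 or self.N == self.R:
            return None
        target_rate = self.x / self.R
        control_rate = (self.C - self.x) / (self.N - self.R)
        if target_rate <= 0 or control_rate <= 0:
            return None
        return float(np.log2(target_rate / control_rate))


def _window_presence(hit_offsets: Sequence[np.ndarray], lengths: Sequence[int],
                     offset: int, window: int) -> tuple[int, int]:
    """(#sequences covering the window, #with >= 1 hit starting in it)."""
    covering = with_hit = 0
    for offs, L in zip(hit_offsets, lengths):
        if L < offset + window:
            continue
        covering += 1
        if len(offs) and np.any((offs >= offset) & (offs < offset + window)):
            with_hit += 1
    return covering, with_hit


def _scan_all(scanner: MotifScanner, seqs: Sequence[str]) -> tuple[list[np.ndarray], list[int]]:
    offs, lens = [], []
    for s in seqs:
        lens.append(len(s))
        offs.append(scanner.hit_offsets(s) if len(s) >= scanner.pwm.width
                    else np.empty(0, dtype=int))
    return offs, lens


def stage1_binomial(
    target_seqs: Sequence[str],
    background_seqs: Sequence[str],
    scanner: MotifScanner,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    fdr_threshold: float = 0.05,
) -> tuple[list[BinomialWindowTest], list[int]]:
    """Stage 1: per window, upper-tail binomial test of the number of
    target sequences with the motif against the background hit rate;
    windows with BH FDR < fdr_threshold are enrichment candidates."""
    if not target_seqs or not background_seqs:
        raise ValueError("target and background sets must be non-empty")
    t_offs, t_lens = _scan_all(scanner, target_seqs)
    b_offs, b_lens = _scan_all(scanner, background_seqs)
    max_len = max(t_lens)
    tests = []
    for off in range(0, max_len - window + 1, step):
        n, k = _window_presence(t_offs, t_lens, off, window)
        nb, kb = _window_presence(b_offs, b_lens, off, window)
        if n == 0 or nb == 0:
            continue
        p = kb / nb
        if p == 0.0 and k > 0:
            logger.info("window %d: zero background hit rate with k=%d; exact "
                        "upper tail is 0", off, k)
        pv = statcore.binom_upper_tail(statcore.BinomialInput(n=n, k=k, p=p))
        tests.append(BinomialWindowTest(off, n, k, p, pv))
    fdrs = statcore.bh_fdr([t.pvalue for t in tests])
    for t, q in zip(tests, fdrs):
        t.fdr = float(q)
    candidates = [t.offset for t in tests if t.fdr < fdr_threshold]
    return tests, candidates


def stage2_fisher(
    target_seqs: Sequence[str],
    control_seqs: Sequence[str],
    scanner: MotifScanner,
    candidate_offsets: Sequence[int],
    window: int = DEFAULT_WINDOW,
    fdr_threshold: float = 0.05,
) -> tuple[list[FisherWindowTest], bool]:
    """Stage 2: one-sided Fisher exact test of target vs control presence
    in each candidate window, BH over candidate windows. Returns the tests
    and whether the motif is locally enriched (>= 1 window FDR below the
    threshold)."""
    t_offs, t_lens = _scan_all(scanner, target_seqs)
    c_offs, c_lens = _scan_all(scanner, control_seqs)
    tests = []
    for off in candidate_offsets:
        r, x = _window_presence(t_offs, t_lens, off, window)
        m, y = _window_presence(c_offs, c_lens, off, window)
        if r == 0 or m == 0:
            continue
        N, C = r + m, x + y
        if C == 0 or C == N:
            pv = 1.0
        else:
            pv = statcore.fisher_one_sided(statcore.FisherInput(N=N, C=C, R=r, x=x))
        tests.append(FisherWindowTest(off, N, C, r, x, pv))
    fdrs = statcore.bh_fdr([t.pvalue for t in tests])
    for t, q in zip(tests, fdrs):
        t.fdr = float(q)
    enriched = any(t.fdr < fdr_threshold for t in tests)
    return tests, enriched


@dataclass
class MotifEnrichmentResult:
    motif_id: str
    stage1: list[BinomialWindowTest] = field(default_factory=list)
    candidate_offsets: list[int] = field(default_factory=list)
    stage2: list[FisherWindowTest] = field(default_factory=list)
    locally_enriched: bool = False


def run_motif_enrichment(
    target_seqs: Sequence[str],
    control_seqs: Sequence[str],
    background_seqs: Sequence[str],
    pwms: Sequence[MotifPWM],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    fdr_threshold: float = 0.05,
) -> list[MotifEnrichmentResult]:
    results = []
    for pwm in pwms:
        scanner = MotifScanner(pwm, p_threshold)
        stage1, candidates = stage1_binomial(target_seqs, background_seqs, scanner,
                                             window, step, fdr_threshold)
        stage2, enriched = stage2_fisher(target_seqs, control_seqs, scanner,
                                         candidates, window, fdr_threshold)
        results.append(MotifEnrichmentResult(pwm.motif_id, stage1, candidates,
                                             stage2, enriched))
    return results


# ---------------------------------------------------------------------------
# motif redundancy merging

def _column_pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a - a.mean(), b - b.mean()
    denom = np.sqrt((sa ** 2).sum() * (sb ** 2).sum())
    if denom == 0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float((sa * sb).sum() / denom)


def _best_alignment(a: MotifPWM, b: MotifPWM, min_overlap: int = 4) -> tuple[float, int]:
    """Best (similarity, offset of b relative to a) over ungapped shifts;
    similarity is the mean per-column Pearson correlation of the overlap."""
    wa, wb = a.width, b.width
    min_overlap = min(min_overlap, wa, wb)
    best, best_off = -np.inf, 0
    for off in range(-(wb - min_overlap), wa - min_overlap + 1):
        lo_a, hi_a = max(0, off), min(wa, off + wb)
        if hi_a - lo_a < min_overlap:
            continue
        cols = [
            _column_pearson(a.matrix[i], b.matrix[i - off]) for i in range(lo_a, hi_a)
        ]
        sim = float(np.mean(cols))
        if sim > best or (sim == best and abs(off) < abs(best_off)):
            best, best_off = sim, off
    return best, best_off


def merge_redundant_motifs(
    pwms: Sequence[MotifPWM],
    similarity_threshold: float = 0.8,
) -> list[MotifPWM]:
    """Single-linkage clustering of PWMs by best-offset mean column Pearson
    correlation; clusters above the threshold are merged by position-wise
    averaging after aligning every member to the cluster representative
    (the widest member, ties by id). Deterministic and order-invariant."""
    if not pwms:
        raise ValueError("need >= 1 PWM")
    pwms = sorted(pwms, key=lambda p: p.motif_id)
    n = len(pwms)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            sim, _ = _best_alignment(pwms[i], pwms[j])
            if sim >= similarity_threshold:
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    merged = []
    for members in clusters.values():
        group = [pwms[i] for i in members]
        rep = max(group, key=lambda p: (p.width, p.motif_id))
        if len(group) == 1:
            merged.append(rep)
            continue
        sums = np.zeros_like(rep.matrix)
        counts = np.zeros(rep.width)
        for m in group:
            _, off = _best_alignment(rep, m)
            lo, hi = max(0, off), min(rep.width, off + m.width)
            sums[lo:hi] += m.matrix[lo - off: hi - off]
            counts[lo:hi] += 1
        counts = np.maximum(counts, 1)
        mat = sums / counts[:, None]
        # columns never covered by any member fall back to the representative
        uncovered = sums.sum(axis=1) == 0
        mat[uncovered] = rep.matrix[uncovered]
        mat = mat / mat.sum(axis=1, keepdims=True)
        merged.append(MotifPWM(rep.motif_id, mat, rep.background))
    return sorted(merged, key=lambda p: p.motif_id)


# ---------------------------------------------------------------------------
# fold-enrichment matrix and clustering

def fold_enrichment_matrix(
    per_motif_tests: dict[str, Sequence[FisherWindowTest]],
) -> tuple[pd.DataFrame, list[str]]:
    """Motif x window matrix of log2 fold enrichment
    FE = (x/R) / ((C-x)/(N-R)), with degenerate windows missing, plus the
    leaf order of complete-linkage clustering on Euclidean distances
    between motif FE vectors (missing values excluded pairwise)."""
    offsets = sorted({t.offset for tests in per_motif_tests.values() for t in tests})
    motif_ids = sorted(per_motif_tests)
    mat = np.full((len(motif_ids), len(offsets)), np.nan)
    col = {off: j for j, off in enumerate(offsets)}
    for i, mid in enumerate(motif_ids):
        for t in per_motif_tests[mid]:
            fe = t.log2_fold_enrichment
            mat[i, col[t.offset]] = np.nan if fe is None else fe
    df = pd.DataFrame(mat, index=motif_ids, columns=offsets)
    if len(motif_ids) < 2:
        return df, motif_ids
    dist = np.zeros((len(motif_ids), len(motif_ids)))
    for i in range(len(motif_ids)):
        for j in range(i + 1, len(motif_ids)):
            both = np.isfinite(mat[i]) & np.isfinite(mat[j])
            if both.any():
                d = float(np.sqrt(((mat[i, both] - mat[j, both]) ** 2).sum()))
            else:
                d = float(np.nanmax(np.abs(mat)) * mat.shape[1] + 1.0)
            dist[i, j] = dist[j, i] = d
    order = leaves_list(linkage(squareform(dist), method="complete"))
    return df, [motif_ids[i] for i in order]
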