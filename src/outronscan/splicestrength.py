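"""Splice-site strength models over fixed donor/acceptor windows.

A donor site is scored on the 9-bp window spanning -3..+6 around the
exon|intron boundary (3 exonic + 6 intronic bases); an acceptor site on the
23-bp window spanning -20..+3 (20 intronic + 3 exonic bases). Strength is
the log2 odds of a window under a signal model versus a background model:
higher means a stronger (more confident) splice site.

Two trainable model families are provided: a position weight matrix (PWM,
independent positions) and a maximum-entropy model (MEM) fitted by
iterative proportional scaling to match a chosen set of marginal
constraints. With only single-position constraints the MEM reduces exactly
to the PWM. The donor 9-mer space (4^9) is fitted over the full joint; the
acceptor 23-mer space is intractable to enumerate, so acceptor MEMs are
factorized over disjoint adjacent-position blocks, each block carrying its
own joint distribution (the exact maximum-entropy solution for that
constraint set).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np

from . import statcore
from .geneclass import GeneModel
from .ioformats import ALPHABET, revcomp

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

DONOR_EXONIC, DONOR_INTRONIC = 3, 6
ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC = 20, 3
DONOR_WIDTH = DONOR_EXONIC + DONOR_INTRONIC  # 9
ACCEPTOR_WIDTH = ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC  # 23

MAX_JOINT_WIDTH = 12  # 4^12 = 16.7M states is the largest joint we enumerate


class ConvergenceError(RuntimeError):
    pass


def _kmer_indices(kmer: str) -> tuple[int, ...]:
    try:
        return tuple(_BASE_INDEX[b] for b in kmer)
    except KeyError as exc:
        raise ValueError(f"non-ACGT base in k-mer {kmer!r}") from exc


class SiteModel(Protocol):
    width: int

    def log2_prob(self, kmer: str) -> float: ...


@dataclass
class PwmModel:
    """Independent-position model; matrix is width x 4 probabilities."""

    matrix: np.ndarray
    site_type: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log2_prob(self, kmer: str) -> float:
        idx = _kmer_indices(kmer)
        if len(idx) != self.width:
            raise ValueError(f"k-mer length {len(idx)} != model width {self.width}")
        probs = self.matrix[np.arange(self.width), idx]
        if (probs == 0).any():
            raise ValueError("zero probability under PWM; train with a pseudocount")
        return float(np.log2(probs).sum())


@dataclass
class MemModel:
    """Full-joint maximum-entropy model over the 4^width k-mer space."""

    joint: np.ndarray  # shape (4,) * width
    constraints: tuple[tuple[int, ...], ...]
    site_type: str = ""

    @property
    def width(self) -> int:
        return self.joint.ndim

    def log2_prob(self, kmer: str) -> float:
        idx = _kmer_indices(kmer)
        p = float(self.joint[idx])
        if p == 0:
            raise ValueError("zero probability under MEM; train with a pseudocount")
        return math.log2(p)

    def marginal(self, positions: tuple[int, ...]) -> np.ndarray:
        """Marginal over ascending `positions` (constraint tuples are kept
        ascending throughout, so axis order is preserved by summation)."""
        axes = tuple(i for i in range(self.width) if i not in positions)
        return self.joint.sum(axis=axes)


@dataclass
class FactorizedMemModel:
    """Product of per-block joint distributions over disjoint position
    blocks; the exact maximum-entropy model for block-marginal constraints."""

    blocks: tuple[tuple[int, ...], ...]
    dists: list[np.ndarray]
    site_type: str = ""

    @property
    def width(self) -> int:
        return max(p for blk in self.blocks for p in blk) + 1

    def log2_prob(self, kmer: str) -> float:
        idx = _kmer_indices(kmer)
        if len(idx) != self.width:
            raise ValueError(f"k-mer length {len(idx)} != model width {self.width}")
        total = 0.0
        for blk, dist in zip(self.blocks, self.dists):
            p = float(dist[tuple(idx[i] for i in blk)])
            if p == 0:
                raise ValueError("zero probability under factorized MEM")
            total += math.log2(p)
        return total


def uniform_background(width: int) -> PwmModel:
    return PwmModel(np.full((width, 4), 0.25))


# ---------------------------------------------------------------------------
# training

def _validate_sites(sites: Sequence[str], width: Optional[int] = None) -> int:
    if not sites:
        raise ValueError("need >= 1 training site")
    w = width if width is not None else len(sites[0])
    for s in sites:
        if len(s) != w:
            raise ValueError(f"site {s!r} has length {len(s)}, expected {w}")
    return w


def train_pwm(sites: Sequence[str], pseudocount: float = 0.5, site_type: str = "") -> PwmModel:
    """Column probabilities (count + pseudocount) / (n + 4 * pseudocount)."""
    w = _validate_sites(sites)
    counts = np.zeros((w, 4))
    for s in sites:
        for i, b in enumerate(s):
            counts[i, _BASE_INDEX[b]] += 1
    matrix = (counts + pseudocount) / (len(sites) + 4 * pseudocount)
    return PwmModel(matrix, site_type)


def _empirical_marginal(sites: Sequence[str], positions: tuple[int, ...],
                        pseudocount: float) -> np.ndarray:
    shape = (4,) * len(positions)
    counts = np.zeros(shape)
    for s in sites:
        counts[tuple(_BASE_INDEX[s[p]] for p in positions)] += 1
    counts += pseudocount / counts.size * 4  # total pseudocount mass 4/site-dim
    return counts / counts.sum()


def single_position_constraints(width: int) -> list[tuple[int, ...]]:
    return [(i,) for i in range(width)]


def adjacent_pair_constraints(width: int) -> list[tuple[int, ...]]:
    return [(i,) for i in range(width)] + [(i, i + 1) for i in range(width - 1)]


def train_mem(
    sites: Sequence[str],
    constraints: Optional[Sequence[tuple[int, ...]]] = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    pseudocount: float = 0.5,
    site_type: str = "",
) -> MemModel:
    """Fit the maximum-entropy distribution matching the empirical marginals
    of `constraints` by iterative proportional fitting on the full 4^width
    joint. The constraint set must cover every position (single-position
    marginals at minimum). Raises ConvergenceError with the worst marginal
    residual if max_iter passes do not reach `tol`."""
    w = _validate_sites(sites)
    if w > MAX_JOINT_WIDTH:
        raise ValueError(
            f"width {w} joint is not enumerable; use train_factorized_mem for acceptors"
        )
    if constraints is None:
        constraints = single_position_constraints(w)
    constraints = [tuple(c) for c in constraints]
    covered = {p for c in constraints for p in c}
    if covered != set(range(w)):
        raise ValueError("constraint set must cover all positions")
    emp = {c: _empirical_marginal(sites, c, pseudocount) for c in constraints}
    joint = np.full((4,) * w, 4.0 ** -w)
    for _ in range(max_iter):
        for c, target in emp.items():
            if list(c) != sorted(c):
                raise ValueError("constraint positions must be ascending tuples")
            axes = tuple(i for i in range(w) if i not in c)
            cur = joint.sum(axis=axes)
            factor = np.where(cur > 0, target / np.where(cur > 0, cur, 1.0), 0.0)
            shape = [1] * w
            for p in c:
                shape[p] = 4
            joint = joint * factor.reshape(shape)
        joint /= joint.sum()
        resid = max(
            float(np.max(np.abs(joint.sum(axis=tuple(i for i in range(w) if i not in c)) - t)))
            for c, t in emp.items()
        )
        if resid < tol:
            return MemModel(joint, tuple(constraints), site_type)
    raise ConvergenceError(f"IPF did not converge: max marginal residual {resid:.3g}")


def train_factorized_mem(
    sites: Sequence[str],
    block_size: int = 2,
    pseudocount: float = 0.5,
    site_type: str = "",
) -> FactorizedMemModel:
    """Maximum-entropy model constrained on disjoint adjacent-position
    blocks (default pairs); exact solution is the product of block joints."""
    w = _validate_sites(sites)
    blocks = tuple(tuple(range(i, min(i + block_size, w))) for i in range(0, w, block_size))
    dists = [_empirical_marginal(sites, blk, pseudocount) for blk in blocks]
    return FactorizedMemModel(blocks, dists, site_type)


# ---------------------------------------------------------------------------
# scoring and comparison

def score_site(signal: SiteModel, background: SiteModel, kmer: str) -> float:
    """log2(P_signal(kmer) / P_background(kmer))."""
    return signal.log2_prob(kmer) - background.log2_prob(kmer)


def score_sites(signal: SiteModel, background: SiteModel, kmers: Sequence[str]) -> np.ndarray:
    return np.array([score_site(signal, background, k) for k in kmers])


@dataclass
class StrengthComparison:
    label: str
    scores_a: np.ndarray
    scores_b: np.ndarray
    u: float
    pvalue: float
    alternative: str
    fdr: Optional[float] = None


def compare_strength(
    sites_a: Sequence[str],
    sites_b: Sequence[str],
    signal: SiteModel,
    background: Optional[SiteModel] = None,
    alternative: str = "two-sided",
    label: str = "",
) -> StrengthComparison:
    """Mann-Whitney U comparison of splice-site strength between two site
    groups scored under the same signal/background pair."""
    if len(sites_a) < 2 or len(sites_b) < 2:
        raise ValueError("each group needs >= 2 sites")
    background = background or uniform_background(len(sites_a[0]))
    sa = score_sites(signal, background, sites_a)
    sb = score_sites(signal, background, sites_b)
    u, p = statcore.mann_whitney(sa, sb, alternative=alternative)
    return StrengthComparison(label, sa, sb, u, p, alternative)


def adjust_comparisons(comparisons: Sequence[StrengthComparison]) -> list[StrengthComparison]:
    """BH-adjust the p-values of one batch of comparisons (e.g. the first
    donor and first acceptor tests) in place."""
    fdrs = statcore.bh_fdr([c.pvalue for c in comparisons])
    for c, q in zip(comparisons, fdrs):
        c.fdr = float(q)
    return list(comparisons)


# ---------------------------------------------------------------------------
# window extraction from gene models

def _donor_window(genome: dict[str, str], chrom: str, strand: str, donor_pos: int) -> Optional[str]:
    seq = genome[chrom]
    if strand == "+":
        s, e = donor_pos - DONOR_EXONIC, donor_pos + DONOR_INTRONIC
        if s < 0 or e > len(seq):
            return None
        return seq[s:e]
    s, e = donor_pos - DONOR_INTRONIC + 1, donor_pos + DONOR_EXONIC + 1
    if s < 0 or e > len(seq):
        return None
    return revcomp(seq[s:e])


def _acceptor_window(genome: dict[str, str], chrom: str, strand: str, acc_pos: int) -> Optional[str]:
    seq = genome[chrom]
    if strand == "+":
        s, e = acc_pos - ACCEPTOR_INTRONIC, acc_pos + ACCEPTOR_EXONIC
        if s < 0 or e > len(seq):
            return None
        return seq[s:e]
    s, e = acc_pos - ACCEPTOR_EXONIC + 1, acc_pos + ACCEPTOR_INTRONIC + 1
    if s < 0 or e > len(seq):
        return None
    return revcomp(seq[s:e])


def extract_sites(
    models: Sequence[GeneModel],
    genome: dict[str, str],
    site_type: str,
    scope: str = "first",
) -> list[str]:
    """Donor or acceptor windows from each gene's reference transcript.

    scope="first" takes only the first intron's site (the one flanking the
    trans-splice acceptor position in the TS-1stAS group); scope="all"
    takes every intron; scope="internal" takes every intron except the
    first (an out-of-sample training pool for scoring first sites).
    Intronless genes contribute nothing; windows crossing contig edges are
    dropped.
    """
    if site_type not in ("donor", "acceptor"):
        raise ValueError("site_type must be 'donor' or 'acceptor'")
    if scope not in ("first", "all", "internal"):
        raise ValueError("scope must be 'first', 'all' or 'internal'")
    out = []
    for m in models:
        tx = m.reference_transcript()
        if tx is None:
            continue
        positions = tx.donor_positions() if site_type == "donor" else tx.acceptor_positions()
        if not positions:
            continue
        if scope == "first":
            positions = positions[:1]
        elif scope == "internal":
            positions = positions[1:]
        for pos in positions:
            window = (_donor_window if site_type == "donor" else _acceptor_window)(
                genome, m.chrom, m.strand, pos
            )
            if window is not None:
                out.append(window)
    return out
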