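"""Windowed nucleotide-content profiles of 5' transcribed regions and
local enrichment testing of trans-spliced against non-trans-spliced genes.

Content is measured on the transcribed strand with T reported as U (so
"GU" content is the G+T fraction of the coding-strand sequence). Profiles
use a 30-bp sliding window anchored either at the TSS (windows tiled
downstream) or at the first cis-splice acceptor site (a centred walk
across the site). Genes whose 5' region is shorter than a window offset
simply drop out of that window's sample, so per-window group sizes vary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import statcore
from .geneclass import GeneModel
from .synthdata import transcribed_seq

DEFAULT_WINDOW = 30
DEFAULT_STEP = 10


def _base_set(content_spec: str) -> frozenset[str]:
    bases = frozenset(content_spec.upper().replace("U", "T"))
    if not bases or not bases <= frozenset("ACGT"):
        raise ValueError(f"invalid content spec {content_spec!r}")
    return bases


def region_content(seq: str, content_spec: str) -> float:
    """Fraction of bases in `seq` that belong to the content spec (e.g.
    "U", "GU", "AU"); U is equivalent to T on the coding strand."""
    if not seq:
        raise ValueError("empty sequence")
    bases = _base_set(content_spec)
    return sum(1 for b in seq if b in bases) / len(seq)


@dataclass
class ContentProfile:
    gene_id: str
    anchor: str  # "tss" | "first_as"
    content_spec: str
    window: int
    step: int
    offsets: np.ndarray  # window start offsets from the anchor
    values: np.ndarray  # per-window content fractions in [0, 1]


def profile_sequence(
    seq: str,
    content_spec: str,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    first_offset: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window content over `seq`; windows extending past the end
    are excluded. Offsets are reported relative to the sequence start plus
    `first_offset`."""
    bases = _base_set(content_spec)
    indicator = np.fromiter((b in bases for b in seq), dtype=float, count=len(seq))
    starts = np.arange(0, max(0, len(seq) - window) + 1, step)
    if len(seq) < window:
        starts = np.empty(0, dtype=int)
    cums = np.concatenate([[0.0], np.cumsum(indicator)])
    values = (cums[starts + window] - cums[starts]) / window if len(starts) else np.empty(0)
    return starts + first_offset, values


def five_prime_region_length(model: GeneModel) -> Optional[int]:
    """Length of the TSS..first-acceptor region (first exon + first intron;
    the outron for trans-spliced genes); None for intronless genes."""
    tx = model.reference_transcript()
    if tx is None:
        return None
    accs = tx.acceptor_positions()
    if not accs:
        return None
    return abs(accs[0] - tx.five_prime)


def profile_gene(
    model: GeneModel,
    genome: dict[str, str],
    anchor: str,
    content_spec: str,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    max_offset: int = 600,
    upstream: int = 300,
    downstream: int = 120,
) -> Optional[ContentProfile]:
    """Per-gene content profile anchored at the TSS or at the first
    cis-splice acceptor site of the reference transcript.

    TSS anchor: windows tile downstream from the TSS over the 5' region
    (capped at max_offset). First-AS anchor: windows walk from `upstream`
    bases before to `downstream` bases after the acceptor, truncated at the
    TSS. Returns None when the available region is shorter than one window.
    """
    tx = model.reference_transcript()
    if tx is None:
        return None
    accs = tx.acceptor_positions()
    if not accs:
        return None
    t5 = tx.five_prime
    region_len = abs(accs[0] - t5)
    if anchor == "tss":
        length = min(region_len, max_offset)
        if length < window:
            return None
        seq = transcribed_seq(genome, model.chrom, t5, model.strand, length)
        offsets, values = profile_sequence(seq, content_spec, window, step)
    elif anchor == "first_as":
        lo = -min(upstream, region_len)
        seq = transcribed_seq(
            genome, model.chrom, t5, model.strand, region_len + downstream
        )[region_len + lo:]
        if len(seq) < window:
            return None
        offsets, values = profile_sequence(seq, content_spec, window, step, first_offset=lo)
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    if len(offsets) == 0:
        return None
    return ContentProfile(model.gene_id, anchor, content_spec, window, step,
                          offsets, values)


@dataclass
class WindowEnrichment:
    offset: int
    n_target: int
    n_control: int
    fold_enrichment: float
    pvalue: float
    fdr: float = float("nan")
    tested: bool = True


def test_windows(
    target_profiles: Sequence[ContentProfile],
    control_profiles: Sequence[ContentProfile],
    center: str = "mean",
    min_group: int = 2,
) -> list[WindowEnrichment]:
    """Per-window one-sided (greater) Mann-Whitney test of target content
    against control content, BH-adjusted across all tested windows of the
    batch; fold enrichment is the ratio of group means (or medians)."""
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    centre = np.mean if center == "mean" else np.median

    def collect(profiles: Sequence[ContentProfile]) -> dict[int, list[float]]:
        by_offset: dict[int, list[float]] = {}
        for p in profiles:
            for off, v in zip(p.offsets, p.values):
                by_offset.setdefault(int(off), []).append(float(v))
        return by_offset

    tgt, ctl = collect(target_profiles), collect(control_profiles)
    results = []
    for off in sorted(set(tgt) | set(ctl)):
        tv, cv = tgt.get(off, []), ctl.get(off, [])
        if len(tv) < min_group or len(cv) < min_group:
            results.append(WindowEnrichment(off, len(tv), len(cv), float("nan"),
                                            float("nan"), tested=False))
            continue
        _, p = statcore.mann_whitney(tv, cv, alternative="greater")
        denom = centre(cv)
        fe = centre(tv) / denom if denom > 0 else float("nan")
        results.append(WindowEnrichment(off, len(tv), len(cv), fe, p))
    fdrs = statcore.bh_fdr([r.pvalue if r.tested else float("nan") for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
    return results


def compare_region_content(
    target_seqs: Sequence[str],
    control_seqs: Sequence[str],
    content_specs: Sequence[str],
) -> pd.DataFrame:
    """Whole-region content comparison (two-sided Mann-Whitney per content
    spec, BH over the batch of specs) of the first exon + intron regions."""
    rows = []
    for spec in content_specs:
        tv = [region_content(s, spec) for s in target_seqs]
        cv = [region_content(s, spec) for s in control_seqs]
        u, p = statcore.mann_whitney(tv, cv, alternative="two-sided")
        rows.append({"content": spec, "n_target": len(tv), "n_control": len(cv),
                     "target_mean": float(np.mean(tv)), "control_mean": float(np.mean(cv)),
                     "U": u, "pvalue": p})
    df = pd.DataFrame(rows)
    df["fdr"] = statcore.bh_fdr(df["pvalue"].to_numpy())
    return df


def enrichment_table(results: Sequence[WindowEnrichment], content_spec: str,
                     anchor: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "anchor": anchor,
                "content": content_spec,
                "offset": r.offset,
                "n_target": r.n_target,
                "n_control": r.n_control,
                "fold_enrichment": r.fold_enrichment,
                "pvalue": r.pvalue,
                "fdr": r.fdr,
                "tested": r.tested,
            }
            for r in results
        ]
    )
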