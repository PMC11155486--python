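"""Readers and writers for every external format the pipeline touches.

Internal coordinates are everywhere 0-based half-open; only GFF3 I/O
converts (GFF3 files are 1-based inclusive). BED is already 0-based
half-open and passes through. "Upstream" always means 5' of a feature on
its own strand; sequence extraction reverse-complements on the minus
strand.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import gffutils
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """Raised when an input file violates its format."""


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """Stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5'-most base on the interval's strand."""
        return self.start if self.strand == "+" else self.end - 1


def extract(genome: Mapping[str, str], iv: Interval) -> str:
    """Strand-aware sequence of an interval (reverse-complemented on '-')."""
    seq = genome[iv.chrom][iv.start:iv.end]
    return revcomp(seq) if iv.strand == "-" else seq


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class FastqRead:
    read_id: str
    seq: str
    qual: str = ""

    def __post_init__(self) -> None:
        if self.qual and len(self.qual) != len(self.seq):
            raise ValueError(f"quality length mismatch for read {self.read_id}")


def read_fastq(path: str | Path) -> list[FastqRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        qual = "".join(chr(q + 33) for q in quals)
        out.append(FastqRead(rec.id, str(rec.seq).upper(), qual))
    return out


def write_fastq(path: str | Path, reads: Iterable[FastqRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qual or "I" * len(r.seq)
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# GFF3

@dataclass
class GffRecord:
    """One GFF3 feature with coordinates already converted to 0-based
    half-open. `attributes` holds all key=value pairs except ID/Parent."""

    feature_type: str
    interval: Interval
    feature_id: str = ""
    parent: str = ""
    source: str = "outronscan"
    attributes: dict[str, str] = field(default_factory=dict)


def read_gff3(path: str | Path) -> list[GffRecord]:
    """Parse GFF3 (1-based inclusive) into internal 0-based half-open records.

    A cheap line-level pre-pass reports the offending line number for
    malformed rows before handing the file to gffutils.
    """
    path = Path(path)
    text = path.read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}")
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        if not 1 <= start <= end:
            raise ParseError(f"{path}:{lineno}: invalid 1-based range {start}..{end}")
        if fields[6] not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: unsupported strand {fields[6]!r}")
    try:
        db = gffutils.create_db(text, ":memory:", from_string=True, keep_order=True,
                                merge_strategy="create_unique")
    except Exception as exc:  # gffutils raises assorted exception types
        raise ParseError(f"{path}: {exc}") from exc
    records = []
    for f in db.all_features(order_by=("seqid", "start")):
        attrs = {k: v[0] for k, v in f.attributes.items()}
        feature_id = attrs.pop("ID", f.id)
        parent = attrs.pop("Parent", "")
        records.append(
            GffRecord(
                feature_type=f.featuretype,
                interval=Interval(f.seqid, f.start - 1, f.end, f.strand),
                feature_id=feature_id,
                parent=parent,
                source=f.source,
                attributes=attrs,
            )
        )
    return records


def write_gff3(path: str | Path, records: Iterable[GffRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            attrs = []
            if r.feature_id:
                attrs.append(f"ID={r.feature_id}")
            if r.parent:
                attrs.append(f"Parent={r.parent}")
            attrs.extend(f"{k}={v}" for k, v in r.attributes.items())
            iv = r.interval
            fh.write(
                "\t".join(
                    [iv.chrom, r.source, r.feature_type, str(iv.start + 1), str(iv.end),
                     ".", iv.strand, ".", ";".join(attrs) or "."]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED

@dataclass(frozen=True)
class BedRecord:
    interval: Interval
    name: str = "."
    score: float = 0.0


def read_bed(path: str | Path) -> list[BedRecord]:
    path = Path(path)
    out = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: BED needs >= 3 fields")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        if not start < end:
            raise ParseError(f"{path}:{lineno}: start must be < end")
        name = fields[3] if len(fields) > 3 else "."
        score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
        strand = fields[5] if len(fields) > 5 else "+"
        out.append(BedRecord(Interval(fields[0], start, end, strand), name, score))
    return out


def write_bed(path: str | Path, records: Iterable[BedRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            iv = r.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.name}\t{r.score:g}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# MEME minimal motif format

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


@dataclass
class MotifPWM:
    """Position weight matrix: `matrix` is width x 4 (A, C, G, T)
    probabilities; `background` the 0-order background distribution."""

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be width x 4")
        if (self.matrix < 0).any() or (self.background < 0).any():
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM row must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))


def read_meme(path: str | Path) -> list[MotifPWM]:
    """Read MEME minimal format; per-position probabilities are renormalized
    to sum exactly to 1 (files often carry 3-decimal rounding)."""
    try:
        with open(path) as fh:
            parsed = bio_motifs.parse(fh, "minimal")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    out = []
    for m in parsed:
        mat = np.array([[m.pwm[b][i] for b in ALPHABET] for i in range(m.length)])
        mat = mat / mat.sum(axis=1, keepdims=True)
        bg = np.array([m.background[b] for b in ALPHABET])
        bg = bg / bg.sum()
        out.append(MotifPWM(m.name, mat, bg))
    return out


def write_meme(path: str | Path, pwms: Sequence[MotifPWM]) -> None:
    buf = io.StringIO()
    buf.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
    bg = pwms[0].background if pwms else np.full(4, 0.25)
    buf.write("Background letter frequencies\n")
    buf.write(" ".join(f"{b} {v:.6f}" for b, v in zip(ALPHABET, bg)) + "\n\n")
    for pwm in pwms:
        buf.write(f"MOTIF {pwm.motif_id}\n")
        buf.write(f"letter-probability matrix: alength= 4 w= {pwm.width} nsites= 20 E= 0\n")
        for row in pwm.matrix:
            buf.write(" ".join(f"{v:.6f}" for v in row) + "\n")
        buf.write("\n")
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# TSV with provenance header

def write_tsv(path: str | Path, df: pd.DataFrame, header_comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
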