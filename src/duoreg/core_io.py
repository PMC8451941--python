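"""Shared coordinate/annotation types and readers/writers for the standard
text formats the pipeline touches (FASTA, BED, JASPAR PFM, tab-delimited
tables).

Coordinate convention: all intervals are 0-based half-open (BED style);
gene TSS coordinates are 0-based. Strand is optional everywhere except
:class:`GeneAnnotation` and defaults to ``+``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A chrom/start/end region, 0-based half-open."""

    chrom: str
    start: int
    end: int
    id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"interval {self.id!r}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def centre(self) -> int:
        return self.start + self.length // 2


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene reduced to its transcription start site."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValidationError(f"gene {self.gene_id!r}: tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id!r}: strand must be + or -")


@dataclass
class MotifMatrix:
    """A position frequency matrix over A,C,G,T with a pseudocount.

    ``counts`` has shape (L, 4) with columns ordered A, C, G, T.
    """

    name: str
    counts: np.ndarray
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4 or self.counts.shape[0] < 1:
            raise ValidationError(f"motif {self.name!r}: counts must be L x 4 with L >= 1")
        if np.any(self.counts < 0):
            raise ValidationError(f"motif {self.name!r}: counts must be non-negative")
        if np.any(self.counts.sum(axis=1) <= 0):
            raise ValidationError(f"motif {self.name!r}: every position needs a positive column sum")
        if self.pseudocount <= 0:
            raise ValidationError(f"motif {self.name!r}: pseudocount must be positive")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def probabilities(self) -> np.ndarray:
        adj = self.counts + self.pseudocount
        return adj / adj.sum(axis=1, keepdims=True)

    def log_odds(self, background: Sequence[float] | None = None) -> np.ndarray:
        """Per-position log2 odds against a background base distribution."""
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        if bg.shape != (4,) or np.any(bg <= 0):
            raise ValidationError("background must be four positive frequencies")
        return np.log2(self.probabilities() / bg)

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.counts.argmax(axis=1))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a name -> uppercase sequence mapping.

    Sequence names are the token before the first whitespace; order is
    preserved. Only A, C, G, T, N are allowed after case folding.
    """
    path = Path(path)
    records = {}
    with open(path) as fh:
        first = fh.read(1)
        if first == "":
            raise FormatError(f"{path}: empty FASTA file")
        if first != ">":
            raise FormatError(f"{path}: line 1: expected '>' header")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            bad = set(seq) - set("ACGTN")
            if bad:
                raise FormatError(
                    f"{path}: record {rec.id!r} contains non-DNA characters {sorted(bad)}"
                )
            records[rec.id] = seq
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED4 intervals, preserving input order.

    Column 4 is used as the interval id when present, otherwise
    ``chrom:start-end`` is synthesised.
    """
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) >= 4 and fields[3] != "" else f"{chrom}:{start}-{end}"
            try:
                out.append(GenomicInterval(chrom, start, end, name))
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\n")


# ---------------------------------------------------------------------------
# JASPAR PFM text

_JASPAR_ROWS = ("A", "C", "G", "T")


def read_jaspar(path: str | Path) -> MotifMatrix:
    """Read a single JASPAR 2016+ text record into a :class:`MotifMatrix`.

    Rows are mapped by their A/C/G/T labels, not their order in the file.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith(">"):
        raise FormatError(f"{path}: expected JASPAR '>' header on line 1")
    header = lines[0][1:].split()
    name = header[-1] if header else "motif"
    rows: dict[str, list[float]] = {}
    for ln in lines[1:5]:
        parts = ln.replace("[", " ").replace("]", " ").split()
        if not parts or parts[0].upper() not in _JASPAR_ROWS:
            raise FormatError(f"{path}: malformed JASPAR count row: {ln!r}")
        base = parts[0].upper()
        try:
            rows[base] = [float(v) for v in parts[1:]]
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric count in row {base}") from exc
    missing = [b for b in _JASPAR_ROWS if b not in rows]
    if missing:
        raise FormatError(f"{path}: missing count rows for {missing}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise FormatError(f"{path}: count rows have unequal lengths {sorted(lengths)}")
    counts = np.column_stack([rows[b] for b in _JASPAR_ROWS])
    return MotifMatrix(name=name, counts=counts)


def write_jaspar(motif: MotifMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{motif.name} {motif.name}\n")
        for i, base in enumerate(_JASPAR_ROWS):
            vals = " ".join(f"{v:.0f}" for v in motif.counts[:, i])
            fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# Tab-delimited tables


def read_table(path: str | Path, required: Sequence[str] = (),
               dtypes: Mapping[str, type] | None = None) -> pd.DataFrame:
    """Read a tab-delimited table with header, checking required columns.

    Unknown extra columns are preserved as-is. Lines starting with ``#``
    are treated as comments.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if dtypes:
        for col, typ in dtypes.items():
            if col in df.columns:
                try:
                    df[col] = df[col].astype(typ)
                except (ValueError, TypeError) as exc:
                    raise FormatError(f"{path}: column {col!r} not coercible to {typ}") from exc
    return df


def write_table(df: pd.DataFrame, path: str | Path, comment: str | None = None,
                float_format: str = "%.6g") -> None:
    """Write a TSV with an optional commented provenance header.

    Floats are written with fixed precision so repeated runs produce
    byte-identical files.
    """
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)


def genes_from_table(df: pd.DataFrame) -> list[GeneAnnotation]:
    need = [c for c in ("gene_id", "chrom", "tss") if c not in df.columns]
    if need:
        raise FormatError(f"gene table missing column(s) {need}")
    strands = df["strand"] if "strand" in df.columns else ["+"] * len(df)
    return [
        GeneAnnotation(str(g), str(c), int(t), str(s))
        for g, c, t, s in zip(df["gene_id"], df["chrom"], df["tss"], strands)
    ]
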