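"""Core domain types, format I/O and conventions shared by the pipeline.

Coordinate convention
---------------------
All internal arithmetic is 0-based half-open ``[start, end)``.  Everything
printed or written to GFF/TSV is 1-based inclusive, the convention genome
browsers and the retrovirology literature use ("nt 328 to 332").  The pair
:func:`to_one_based` / :func:`from_one_based` is the single crossing point
between the two conventions; no other code performs the +/-1 arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomicInterval",
    "SequenceRecord",
    "FeatureRecord",
    "FEATURE_KINDS",
    "FormatError",
    "to_one_based",
    "from_one_based",
    "read_fasta",
    "write_fasta",
    "read_depth_tsv",
    "write_depth_tsv",
    "read_junction_tsv",
    "write_junction_tsv",
    "read_gff",
    "write_gff",
    "read_newick",
    "write_newick",
    "revcomp",
    "get_logger",
    "configure_logging",
]

STRANDS = {"+", "-", "."}

#: Controlled vocabulary for structural annotations of an LTR element locus.
FEATURE_KINDS = {
    "exon", "LTR5", "LTR3", "U3", "R", "U5", "PBS", "PPT", "TSD",
    "ORF", "element", "flank",
}

_NT = set("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def get_logger(name: str) -> logging.Logger:
    return logging.getLogger(f"retronest.{name}")


log = get_logger("core_io")


# --------------------------------------------------------------------------
# coordinate conversion — the only crossing point between conventions
# --------------------------------------------------------------------------

def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open ``[start, end)`` -> 1-based inclusive ``(first, last)``."""
    return start + 1, end


def from_one_based(first: int, last: int) -> tuple[int, int]:
    """1-based inclusive ``(first, last)`` -> 0-based half-open ``(start, end)``."""
    return first - 1, last


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval on a named sequence (internal 0-based convention)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {sorted(STRANDS)}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def one_based(self) -> tuple[int, int]:
        return to_one_based(self.start, self.end)

    @classmethod
    def from_one_based(cls, chrom: str, first: int, last: int, strand: str = ".") -> "GenomicInterval":
        start, end = from_one_based(first, last)
        return cls(chrom, start, end, strand)

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def __str__(self) -> str:
        first, last = self.one_based()
        return f"{self.chrom}:{first:,}-{last:,}({self.strand})"


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence (stored upper-case)."""

    id: str
    seq: str
    alphabet: str = "nt"  # "nt" or "aa"

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "seq", self.seq.upper())
        if self.alphabet == "nt":
            bad = set(self.seq) - _NT
            if bad:
                raise ValueError(f"sequence {self.id!r} has non-ACGTN symbols {sorted(bad)}")
        elif self.alphabet != "aa":
            raise ValueError(f"alphabet must be 'nt' or 'aa', got {self.alphabet!r}")

    def __len__(self) -> int:
        return len(self.seq)

    def slice(self, start: int, end: int, sub_id: str | None = None) -> "SequenceRecord":
        return SequenceRecord(sub_id or f"{self.id}:{start}-{end}", self.seq[start:end], self.alphabet)

    def reverse_complement(self, sub_id: str | None = None) -> "SequenceRecord":
        if self.alphabet != "nt":
            raise ValueError("reverse complement requires a nucleotide sequence")
        return SequenceRecord(sub_id or f"{self.id}_rc", revcomp(self.seq), "nt")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class FeatureRecord:
    """A structural annotation: an interval plus a controlled-vocabulary kind."""

    interval: GenomicInterval
    kind: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}; allowed: {sorted(FEATURE_KINDS)}")


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: str = "nt") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects (order preserved).

    Sequences are upper-cased on read.  An empty file or a duplicated header id
    raises :class:`FormatError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq), alphabet))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# --------------------------------------------------------------------------
# depth TSV (chrom, 1-based position, depth)
# --------------------------------------------------------------------------

def read_depth_tsv(path: str | Path):
    """Read a 3-column depth track (chrom, 1-based position, integer depth).

    Returns a :class:`retronest.depth_cn.DepthTrack`.  Positions absent from the
    file are treated as depth 0.  Unsorted positions are accepted with a
    warning; a negative depth or malformed row raises :class:`FormatError`
    naming the offending line.
    """
    from .depth_cn import DepthTrack  # deferred: depth_cn imports core_io

    chrom = None
    positions: list[int] = []
    depths: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            try:
                pos, depth = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer position/depth") from exc
            if depth < 0:
                raise FormatError(f"{path}:{lineno}: negative depth {depth}")
            if pos < 1:
                raise FormatError(f"{path}:{lineno}: position must be >= 1, got {pos}")
            if chrom is None:
                chrom = parts[0]
            elif parts[0] != chrom:
                raise FormatError(f"{path}:{lineno}: multiple chromosomes in one track "
                                  f"({chrom!r} and {parts[0]!r}); split per chrom")
            positions.append(pos)
            depths.append(depth)
    if chrom is None:
        raise FormatError(f"empty depth track {path}")
    if positions != sorted(positions):
        log.warning("depth track %s has unsorted positions; sorting", path)
        order = sorted(range(len(positions)), key=positions.__getitem__)
        positions = [positions[i] for i in order]
        depths = [depths[i] for i in order]
    import numpy as np

    arr = np.zeros(max(positions), dtype=np.int64)  # missing positions -> depth 0
    arr[[from_one_based(p, p)[0] for p in positions]] = depths
    return DepthTrack(chrom=chrom, depth=arr)


def write_depth_tsv(track, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, d in enumerate(track.depth):
            first, _ = to_one_based(i, i + 1)
            fh.write(f"{track.chrom}\t{first}\t{int(d)}\n")


# --------------------------------------------------------------------------
# junction TSV (chrom, intron start, intron end, strand, unique read count)
# --------------------------------------------------------------------------

def read_junction_tsv(path: str | Path):
    """Read a splice-junction table; intron coordinates are 1-based inclusive
    first/last intronic base.  Returns a list of
    :class:`retronest.splice_class.JunctionRecord`."""
    from .splice_class import JunctionRecord

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            chrom, first, last, strand, count = parts
            try:
                interval = GenomicInterval.from_one_based(chrom, int(first), int(last), strand)
                n = int(count)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed junction row") from exc
            if n < 0:
                raise FormatError(f"{path}:{lineno}: negative read count {n}")
            out.append(JunctionRecord(intron=interval, strand=strand, read_count=n))
    return out


def write_junction_tsv(junctions, path: str | Path) -> None:
    with open(path, "w") as fh:
        for j in junctions:
            first, last = j.intron.one_based()
            fh.write(f"{j.intron.chrom}\t{first}\t{last}\t{j.strand}\t{j.read_count}\n")


# --------------------------------------------------------------------------
# GFF-lite (9-column GFF3, 1-based inclusive on disk)
# --------------------------------------------------------------------------

_GFF_SOURCE = "retronest"


def write_gff(features: Sequence[FeatureRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            first, last = feat.interval.one_based()
            attrs = f"label={feat.label}" if feat.label else "."
            fh.write("\t".join([
                feat.interval.chrom, _GFF_SOURCE, feat.kind,
                str(first), str(last), ".", feat.interval.strand, ".", attrs,
            ]) + "\n")


def read_gff(path: str | Path) -> list[FeatureRecord]:
    out: list[FeatureRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF columns")
            chrom, _src, kind, first, last, _score, strand, _frame, attrs = parts
            label = ""
            for item in attrs.split(";"):
                if item.startswith("label="):
                    label = item[len("label="):]
            interval = GenomicInterval.from_one_based(chrom, int(first), int(last), strand)
            out.append(FeatureRecord(interval=interval, kind=kind, label=label))
    return out


# --------------------------------------------------------------------------
# newick (via dendropy; supports stored as internal-node labels)
# --------------------------------------------------------------------------

def write_newick(tree, path: str | Path) -> None:
    """Write a dendropy tree; bootstrap supports travel as internal labels."""
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def read_newick(path: str | Path):
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick",
                             suppress_internal_node_taxa=True)
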