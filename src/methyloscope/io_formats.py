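"""Readers and writers for the on-disk formats the pipeline touches.

Internal coordinates are uniformly 0-based, half-open.  The only 1-based
surface is the methylation count table dialect (``pos`` column is the 1-based
position of the cytosine) and human-readable reports.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from methyloscope.errors import ParseError, ValidationError

VALID_STRANDS = ("+", "-", ".")
_FASTA_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with optional BED name/score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class MethylationCountRecord:
    """Methylated/total read counts at one cytosine (0-based forward-strand pos)."""

    chrom: str
    pos: int
    meth: int
    total: int
    strand: str = "."

    def __post_init__(self):
        if self.pos < 0:
            raise ValidationError(f"negative position {self.pos}")
        if self.meth < 0 or self.total < 0:
            raise ValidationError("counts must be non-negative")
        if self.meth > self.total:
            raise ValidationError(
                f"meth ({self.meth}) > total ({self.total}) at {self.chrom}:{self.pos}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    breed: str
    sex: str
    neutered: bool
    age_years: float
    condition: str

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be M or F, got {self.sex!r}")
        if self.age_years <= 0:
            raise ValidationError("age_years must be positive")


@dataclass(frozen=True)
class GeneModel:
    interval: GenomicInterval
    gene_id: str

    def __post_init__(self):
        if self.interval.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be + or -, got {self.interval.strand!r}"
            )


@dataclass(frozen=True)
class RepeatAnnotation:
    interval: GenomicInterval
    subfamily: str
    class_family: str = ""

    def __post_init__(self):
        if not self.subfamily:
            raise ValidationError("repeat subfamily must be non-empty")


def read_methylation_table(
    path: str | Path, dialect: str = "collapsed"
) -> list[MethylationCountRecord]:
    """Read a 5-column TSV (chrom, 1-based pos, strand, meth, total).

    ``dialect='stranded'`` keeps per-strand records untouched; collapse is a
    separate operation.  ``dialect='collapsed'`` expects strand '.' (or '+',
    which is normalized to '.').  Rows are returned sorted by (chrom, pos).
    """
    if dialect not in ("collapsed", "stranded"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[MethylationCountRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(
                    f"expected 5 tab-separated columns, got {len(fields)}", lineno
                )
            chrom, pos_s, strand, meth_s, total_s = fields
            try:
                pos1 = int(pos_s)
                meth = int(meth_s)
                total = int(total_s)
            except ValueError as exc:
                raise ParseError(f"non-integer field: {exc}", lineno) from exc
            if pos1 < 1:
                raise ParseError(f"1-based position must be >= 1, got {pos1}", lineno)
            if dialect == "collapsed":
                strand = "."
            try:
                records.append(
                    MethylationCountRecord(
                        chrom=chrom, pos=pos1 - 1, meth=meth, total=total, strand=strand
                    )
                )
            except ValidationError as exc:
                raise ParseError(str(exc), lineno) from exc
    records.sort(key=lambda r: (r.chrom, r.pos, r.strand))
    return records


def write_methylation_table(
    records: Iterable[MethylationCountRecord], path: str | Path
) -> None:
    """Write records in the 5-column 1-based TSV dialect."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f"{rec.chrom}\t{rec.pos + 1}\t{rec.strand}\t{rec.meth}\t{rec.total}\n"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6; strand is '.' when absent. Coordinates kept half-open."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("BED line needs at least 3 columns", lineno)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate: {exc}", lineno) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"bad score: {exc}", lineno) from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(
                        chrom=chrom, start=start, end=end,
                        strand=strand, name=name, score=score,
                    )
                )
            except ValidationError as exc:
                raise ParseError(str(exc), lineno) from exc
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED3 or BED6 (when any name/score/strand is set)."""
    bed6 = any(
        iv.name is not None or iv.score is not None or iv.strand != "."
        for iv in intervals
    )
    with open(path, "w") as fh:
        for iv in intervals:
            if bed6:
                name = iv.name if iv.name is not None else "."
                score = f"{iv.score:g}" if iv.score is not None else "0"
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {chrom: uppercase sequence}; alphabet {A,C,G,T,N}."""
    genome: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        bad = set(seq) - _FASTA_ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {record.id}: non-ACGTN characters {sorted(bad)}"
            )
        genome[record.id] = seq
    return genome


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_METADATA_COLUMNS = ("sample_id", "breed", "sex", "neutered", "age_years", "condition")


def read_sample_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read the sample metadata TSV (header with the documented columns)."""
    samples: list[SampleMetadata] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = set(_METADATA_COLUMNS) - set(header)
        if missing:
            raise ParseError(f"metadata missing columns {sorted(missing)}", 1)
        idx = {c: header.index(c) for c in _METADATA_COLUMNS}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            try:
                samples.append(
                    SampleMetadata(
                        sample_id=fields[idx["sample_id"]],
                        breed=fields[idx["breed"]],
                        sex=fields[idx["sex"]],
                        neutered=fields[idx["neutered"]].lower() in ("true", "1", "yes"),
                        age_years=float(fields[idx["age_years"]]),
                        condition=fields[idx["condition"]],
                    )
                )
            except (IndexError, ValueError, ValidationError) as exc:
                raise ParseError(str(exc), lineno) from exc
    ids = [s.sample_id for s in samples]
    if len(ids) != len(set(ids)):
        raise ValidationError("duplicate sample_id in metadata")
    return samples


def write_sample_metadata(samples: Sequence[SampleMetadata], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_METADATA_COLUMNS) + "\n")
        for s in samples:
            fh.write(
                f"{s.sample_id}\t{s.breed}\t{s.sex}\t{str(s.neutered).lower()}"
                f"\t{s.age_years:g}\t{s.condition}\n"
            )


def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column TSV (set_id, gene_id) into {set_id: [genes]}."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError("expected 2 tab-separated columns", lineno)
            sets.setdefault(fields[0], []).append(fields[1])
    return sets


def as_plain_interval(iv: GenomicInterval) -> GenomicInterval:
    """Strip name/score so equality reduces to coordinates + strand."""
    return dataclasses.replace(iv, name=None, score=None)
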