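"""Readers/writers for the plain-text genomics formats the pipeline touches.

This module is the single home for coordinate conventions:

* internally every interval is **0-based, half-open** (``start`` inclusive,
  ``end`` exclusive), which keeps interval arithmetic unambiguous;
* everything written for human consumption is converted to the **1-based,
  inclusive** convention used in genome-browser coordinates via
  :func:`to_report_coords`.

BED (0-based half-open) is the interchange format for regions; GFF3 is
accepted read-only for annotations.  Genomes are plain uppercase DNA over
``{A, C, G, T, N}``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, TextIO, Union

from Bio import SeqIO
from Bio.Seq import reverse_complement
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .exceptions import FormatError, ParameterError

VALID_ALPHABET = frozenset("ACGTN")

#: Annotation classes recognised for background small-RNA features.
FEATURE_CLASSES = ("rRNA", "tRNA", "snoRNA", "milRNA", "disiRNA")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return reverse_complement(seq)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with an optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ParameterError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ParameterError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of overlapping bases with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        ov = self.overlap(other)
        if ov == 0:
            return 0.0
        return min(ov / self.length, ov / other.length)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        s1, e1, _ = to_report_coords(self)
        return f"{self.chrom}:{s1}-{e1}({self.strand})"


@dataclass
class Genome:
    """A set of named chromosome sequences.

    ``mito_name``, when set, designates the mitochondrial chromosome used by
    the small-RNA classifier.
    """

    sequences: dict
    mito_name: Optional[str] = None

    def __post_init__(self):
        if not self.sequences:
            raise FormatError("genome has no sequences")
        for name, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"empty sequence for {name!r}")
            bad = set(seq) - VALID_ALPHABET
            if bad:
                raise FormatError(
                    f"sequence {name!r} contains non-ACGTN characters: {sorted(bad)}"
                )
        if self.mito_name is not None and self.mito_name not in self.sequences:
            raise ParameterError(f"mito_name {self.mito_name!r} not in genome")

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    @property
    def chrom_lengths(self) -> dict:
        return {name: len(seq) for name, seq in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def fetch(self, interval: GenomicInterval) -> str:
        """Extract the sequence of ``interval`` (reverse-complemented for '-')."""
        seq = self.sequences[interval.chrom]
        if interval.end > len(seq):
            raise ParameterError(f"interval {interval} exceeds chromosome length {len(seq)}")
        sub = seq[interval.start:interval.end]
        return revcomp(sub) if interval.strand == "-" else sub


@dataclass(frozen=True)
class AnnotatedFeature:
    """A classed genomic interval (rRNA/tRNA/snoRNA/milRNA/disiRNA)."""

    interval: GenomicInterval
    feature_class: str
    id: str

    def __post_init__(self):
        if self.feature_class not in FEATURE_CLASSES:
            raise ParameterError(
                f"unknown feature class {self.feature_class!r}; "
                f"expected one of {FEATURE_CLASSES}"
            )


def to_report_coords(interval: GenomicInterval):
    """Convert to the 1-based inclusive convention used in reports.

    Returns ``(start_1based, end_1based, length)``; the length equals
    ``end_1based - start_1based + 1``.
    """
    return interval.start + 1, interval.end, interval.end - interval.start


def _as_handle(source: Union[str, TextIO]) -> TextIO:
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def parse_fasta(source: Union[str, TextIO], mito_name: Optional[str] = None) -> Genome:
    """Parse a FASTA stream (or string) into a :class:`Genome`.

    Sequences are uppercased and line-joined; duplicate headers and
    characters outside ``{A,C,G,T,N}`` are rejected.
    """
    handle = _as_handle(source)
    sequences = {}
    for record in SeqIO.parse(handle, "fasta"):
        name = record.id
        if name in sequences:
            raise FormatError(f"duplicate FASTA header {name!r}")
        sequences[name] = str(record.seq).upper()
    if not sequences:
        raise FormatError("empty or non-FASTA stream")
    return Genome(sequences=sequences, mito_name=mito_name)


def write_fasta(genome: Genome, handle: TextIO, width: int = 70) -> None:
    for name, seq in genome.sequences.items():
        handle.write(f">{name}\n")
        for i in range(0, len(seq), width):
            handle.write(seq[i:i + width] + "\n")


FastqRecord = tuple  # (read_id, sequence, quality)


def parse_fastq(source: Union[str, TextIO]) -> list:
    """Parse a FASTQ stream into ``[(read_id, sequence, quality), ...]``.

    An empty stream yields an empty list; a sequence/quality length mismatch
    raises :class:`FormatError`.
    """
    handle = _as_handle(source)
    records = []
    try:
        for title, seq, qual in FastqGeneralIterator(handle):
            records.append((title.split()[0], seq.upper(), qual))
    except ValueError as exc:  # Biopython signals malformed records this way
        raise FormatError(str(exc)) from exc
    return records


def write_fastq(records: Iterable, handle: TextIO) -> None:
    for read_id, seq, qual in records:
        if len(seq) != len(qual):
            raise FormatError(f"sequence/quality length mismatch for {read_id!r}")
        handle.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def read_bed(source: Union[str, TextIO]):
    """Read BED3/BED6 into ``[(GenomicInterval, name), ...]`` (0-based half-open)."""
    out = []
    for lineno, line in enumerate(_as_handle(source), 1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"BED line {lineno}: fewer than 3 columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        name = fields[3] if len(fields) > 3 else f"region_{lineno}"
        strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
        out.append((GenomicInterval(chrom, start, end, strand), name))
    return out


def write_bed(entries: Iterable, handle: TextIO, header: Optional[str] = None) -> None:
    """Write ``(GenomicInterval, name[, score])`` tuples as BED6."""
    if header:
        handle.write(f"# {header}\n")
    for entry in entries:
        interval, name = entry[0], entry[1]
        score = entry[2] if len(entry) > 2 else 0
        handle.write(
            f"{interval.chrom}\t{interval.start}\t{interval.end}\t{name}\t{score}\t"
            f"{interval.strand if interval.strand != '.' else '.'}\n"
        )


def read_annotations_bed(source: Union[str, TextIO]) -> list:
    """Read an annotation BED whose name column is ``class|id`` (or just ``class``)."""
    features = []
    for i, (interval, name) in enumerate(read_bed(source)):
        if "|" in name:
            feature_class, feature_id = name.split("|", 1)
        else:
            feature_class, feature_id = name, f"{name}_{i}"
        features.append(AnnotatedFeature(interval, feature_class, feature_id))
    return features


def write_annotations_bed(features: Iterable, handle: TextIO, header: Optional[str] = None) -> None:
    write_bed(
        ((f.interval, f"{f.feature_class}|{f.id}") for f in features),
        handle,
        header=header,
    )


# GFF3 feature types accepted as annotation classes (case-sensitive, as in
# common fungal annotation files).
_GFF_TYPE_MAP = {
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "snoRNA": "snoRNA",
    "milRNA": "milRNA",
    "disiRNA": "disiRNA",
}


def read_annotations_gff3(source: Union[str, TextIO]) -> list:
    """Read annotations from GFF3 (read-only; unknown feature types are skipped).

    GFF3 is 1-based inclusive; coordinates are converted to the internal
    0-based half-open convention.
    """
    features = []
    for lineno, line in enumerate(_as_handle(source), 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise FormatError(f"GFF3 line {lineno}: expected 9 columns, got {len(fields)}")
        chrom, _src, ftype, start1, end1, _score, strand, _phase, attrs = fields
        if ftype not in _GFF_TYPE_MAP:
            continue
        fid = f"{ftype}_{lineno}"
        for item in attrs.split(";"):
            if item.startswith("ID="):
                fid = item[3:]
                break
        interval = GenomicInterval(chrom, int(start1) - 1, int(end1), strand if strand in "+-" else ".")
        features.append(AnnotatedFeature(interval, _GFF_TYPE_MAP[ftype], fid))
    return features
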