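"""Transcript annotation handling: GTF parsing, exonic-part flattening, mask matrices.

The exon-level feature unit used throughout the package is the *exonic part*:
a maximal genomic interval within one gene over which the set of covering
transcripts is constant.  Flattening a gene's transcript models into exonic
parts yields disjoint intervals whose union equals the union of all exon
bases, and each part carries the exact transcript set that covers it.

Two binary relationship matrices are derived from the parts:

* the isoform map ``R`` with ``R[i, j] = 1`` iff part *i* is contained in
  isoform *j* (equivalently, isoform *j* is in part *i*'s transcript set);
* the gene map, connecting each part to its single gene.

These matrices are consumed as fixed masks by the network layers.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "ExonicPart",
    "RelationshipMatrix",
    "GtfParseError",
    "AnnotationError",
    "parse_gtf",
    "flatten_exonic_parts",
    "build_isoform_map",
    "build_gene_map",
    "write_parts_gtf",
    "read_parts_gtf",
    "write_relationship_tsv",
    "read_relationship_tsv",
]


class GtfParseError(ValueError):
    """Raised for malformed GTF input; carries the 1-based line number."""


class AnnotationError(ValueError):
    """Raised when annotation objects violate their structural invariants."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Closed genomic interval, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise AnnotationError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise AnnotationError(
                f"end ({self.end}) precedes start ({self.start}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """One transcript isoform: an ordered list of exons on a single strand."""

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def validate(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"transcript {self.transcript_id} spans multiple chroms/strands"
            )
        prev_end = None
        for e in sorted(self.exons, key=lambda iv: iv.start):
            if prev_end is not None and e.start <= prev_end:
                raise AnnotationError(
                    f"transcript {self.transcript_id} has overlapping exons"
                )
            prev_end = e.end

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand


@dataclass(frozen=True)
class ExonicPart:
    """Disjoint interval within a gene with a constant covering transcript set."""

    part_id: str
    gene_id: str
    interval: GenomicInterval
    transcripts: frozenset[str]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"part {self.part_id} covered by no transcript")


@dataclass
class RelationshipMatrix:
    """Binary prior-knowledge mask: rows are exon features, columns isoforms or genes."""

    row_ids: list[str]
    col_ids: list[str]
    entries: np.ndarray

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries)
        if self.entries.shape != (len(self.row_ids), len(self.col_ids)):
            raise AnnotationError(
                f"matrix shape {self.entries.shape} does not match id lists "
                f"({len(self.row_ids)} x {len(self.col_ids)})"
            )
        if len(set(self.row_ids)) != len(self.row_ids):
            raise AnnotationError("duplicate row ids in relationship matrix")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise AnnotationError("duplicate col ids in relationship matrix")
        vals = np.unique(self.entries)
        if not np.all(np.isin(vals, (0, 1))):
            raise AnnotationError("relationship matrix entries must be 0 or 1")
        if self.entries.size and not np.all(self.entries.sum(axis=1) >= 1):
            raise AnnotationError("every relationship-matrix row needs >= 1 nonzero")
        self.entries = self.entries.astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.entries.shape


# ---------------------------------------------------------------------------
# GTF parsing


def _parse_attributes(attr_field: str, lineno: int) -> dict[str, str]:
    """Parse a GTF attribute column in either `key "value";` or `key=value` form."""
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().strip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk and '"' not in chunk:
            key, _, value = chunk.partition("=")
        else:
            key, _, value = chunk.partition(" ")
        key = key.strip()
        value = value.strip().strip('"')
        if not key:
            raise GtfParseError(f"line {lineno}: empty attribute key in {chunk!r}")
        attrs[key] = value
    return attrs


def parse_gtf(path: str) -> list[TranscriptModel]:
    """Read transcript models from a GTF file.

    Only ``exon`` feature records define transcripts; all other feature types
    are ignored.  Each exon record must carry ``gene_id`` and ``transcript_id``
    attributes.  Transcripts are returned in first-appearance order with exons
    sorted by start coordinate.

    Raises
    ------
    GtfParseError
        On a line with the wrong column count or an exon record missing the
        required attributes; the message names the offending line number.
    """
    transcripts: dict[str, TranscriptModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinate") from exc
            attrs = _parse_attributes(attr_s, lineno)
            if "transcript_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon record missing transcript_id")
            if "gene_id" not in attrs:
                raise GtfParseError(f"line {lineno}: exon record missing gene_id")
            tid, gid = attrs["transcript_id"], attrs["gene_id"]
            tm = transcripts.get(tid)
            if tm is None:
                tm = transcripts[tid] = TranscriptModel(tid, gid)
            elif tm.gene_id != gid:
                raise GtfParseError(
                    f"line {lineno}: transcript {tid} assigned to both "
                    f"{tm.gene_id} and {gid}"
                )
            tm.exons.append(GenomicInterval(chrom, start, end, strand))
    for tm in transcripts.values():
        tm.exons.sort(key=lambda iv: iv.start)
    return list(transcripts.values())


# ---------------------------------------------------------------------------
# Flattening


def _merged_exons(tm: TranscriptModel) -> list[GenomicInterval]:
    """Merge overlapping/adjacent exons within one transcript (malformed input)."""
    exons = sorted(tm.exons, key=lambda iv: iv.start)
    merged = [exons[0]]
    warned = False
    for e in exons[1:]:
        last = merged[-1]
        if e.start <= last.end + 1:
            if e.start <= last.end and not warned:
                logger.warning(
                    "transcript %s has overlapping exons; merging", tm.transcript_id
                )
                warned = True
            merged[-1] = GenomicInterval(
                last.chrom, last.start, max(last.end, e.end), last.strand
            )
        else:
            merged.append(e)
    return merged


def flatten_exonic_parts(transcripts: Sequence[TranscriptModel]) -> list[ExonicPart]:
    """Break one gene's exons into disjoint parts with constant transcript sets.

    A boundary sweep over all exon start/end coordinates yields elementary
    intervals; adjacent intervals covered by the same transcript set merge
    into a single part.  Parts are disjoint, sorted by (chrom, strand, start),
    and their union equals the union of all exon bases.  Part ids are
    ``<gene_id>:NNN`` with a 3-digit, 1-based ordinal.
    """
    if not transcripts:
        return []
    gene_ids = {tm.gene_id for tm in transcripts}
    if len(gene_ids) > 1:
        raise AnnotationError(
            f"flatten_exonic_parts expects one gene, got {sorted(gene_ids)}"
        )
    gene_id = transcripts[0].gene_id
    for tm in transcripts:
        tm.validate()

    parts: list[ExonicPart] = []
    groups = sorted({(tm.chrom, tm.strand) for tm in transcripts})
    for chrom, strand in groups:
        group = [tm for tm in transcripts if (tm.chrom, tm.strand) == (chrom, strand)]
        exon_sets = {tm.transcript_id: _merged_exons(tm) for tm in group}
        # boundary sweep: starts and (end+1)s delimit elementary intervals
        bounds = sorted(
            {e.start for exs in exon_sets.values() for e in exs}
            | {e.end + 1 for exs in exon_sets.values() for e in exs}
        )
        runs: list[tuple[int, int, frozenset[str]]] = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            cover = frozenset(
                tid
                for tid, exs in exon_sets.items()
                if any(e.start <= lo and hi - 1 <= e.end for e in exs)
            )
            if not cover:
                continue
            if runs and runs[-1][2] == cover and runs[-1][1] + 1 == lo:
                runs[-1] = (runs[-1][0], hi - 1, cover)
            else:
                runs.append((lo, hi - 1, cover))
        for lo, hi, cover in runs:
            parts.append(
                ExonicPart(
                    part_id="",  # assigned below once global order is fixed
                    gene_id=gene_id,
                    interval=GenomicInterval(chrom, lo, hi, strand),
                    transcripts=cover,
                )
            )

    parts.sort(key=lambda p: (p.interval.chrom, p.interval.strand, p.interval.start))
    return [
        ExonicPart(f"{gene_id}:{i + 1:03d}", p.gene_id, p.interval, p.transcripts)
        for i, p in enumerate(parts)
    ]


# ---------------------------------------------------------------------------
# Relationship matrices


def build_isoform_map(
    parts: Sequence[ExonicPart], transcripts: Sequence[TranscriptModel]
) -> RelationshipMatrix:
    """Binary exon-part x isoform matrix: 1 iff the part lies inside the isoform.

    Row order follows ``parts``; column order follows ``transcripts``.
    """
    col_ids = [tm.transcript_id for tm in transcripts]
    known = set(col_ids)
    for p in parts:
        missing = p.transcripts - known
        if missing:
            raise AnnotationError(
                f"part {p.part_id} references unknown transcripts {sorted(missing)}"
            )
    entries = np.zeros((len(parts), len(col_ids)), dtype=np.int8)
    col_index = {tid: j for j, tid in enumerate(col_ids)}
    for i, p in enumerate(parts):
        for tid in p.transcripts:
            entries[i, col_index[tid]] = 1
    return RelationshipMatrix([p.part_id for p in parts], col_ids, entries)


def build_gene_map(
    parts: Sequence[ExonicPart], gene_ids: Sequence[str]
) -> RelationshipMatrix:
    """Binary exon-part x gene matrix: exactly one 1 per row."""
    col_index = {gid: j for j, gid in enumerate(gene_ids)}
    entries = np.zeros((len(parts), len(gene_ids)), dtype=np.int8)
    for i, p in enumerate(parts):
        if p.gene_id not in col_index:
            raise AnnotationError(f"part {p.part_id} has unknown gene {p.gene_id}")
        entries[i, col_index[p.gene_id]] = 1
    return RelationshipMatrix([p.part_id for p in parts], list(gene_ids), entries)


# ---------------------------------------------------------------------------
# I/O


def write_parts_gtf(parts: Iterable[ExonicPart], path: str) -> None:
    """Write exonic parts as GTF ``exonic_part`` records (1-based inclusive)."""
    with open(path, "w") as fh:
        for p in parts:
            attrs = (
                f'gene_id "{p.gene_id}"; part_id "{p.part_id}"; '
                f'transcripts "{",".join(sorted(p.transcripts))}";'
            )
            fh.write(
                "\t".join(
                    [
                        p.interval.chrom,
                        "isomapnet",
                        "exonic_part",
                        str(p.interval.start),
                        str(p.interval.end),
                        ".",
                        p.interval.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_parts_gtf(path: str) -> list[ExonicPart]:
    """Read exonic parts written by :func:`write_parts_gtf`."""
    parts: list[ExonicPart] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 columns, got {len(fields)}"
                )
            if fields[2] != "exonic_part":
                continue
            attrs = _parse_attributes(fields[8], lineno)
            for key in ("gene_id", "part_id", "transcripts"):
                if key not in attrs:
                    raise GtfParseError(f"line {lineno}: missing attribute {key}")
            parts.append(
                ExonicPart(
                    part_id=attrs["part_id"],
                    gene_id=attrs["gene_id"],
                    interval=GenomicInterval(
                        fields[0], int(fields[3]), int(fields[4]), fields[6]
                    ),
                    transcripts=frozenset(attrs["transcripts"].split(",")),
                )
            )
    return parts


def write_relationship_tsv(rm: RelationshipMatrix, path: str, dense: bool = True) -> None:
    """Write a relationship matrix as TSV, dense (default) or (row, col, 1) triplets."""
    with open(path, "w") as fh:
        if dense:
            fh.write("feature_id\t" + "\t".join(rm.col_ids) + "\n")
            for rid, row in zip(rm.row_ids, rm.entries):
                fh.write(rid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
        else:
            fh.write("row_id\tcol_id\tvalue\n")
            rows, cols = np.nonzero(rm.entries)
            for i, j in zip(rows, cols):
                fh.write(f"{rm.row_ids[i]}\t{rm.col_ids[j]}\t1\n")


def read_relationship_tsv(path: str) -> RelationshipMatrix:
    """Read a dense relationship TSV written by :func:`write_relationship_tsv`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col_ids = header[1:]
        row_ids: list[str] = []
        rows: list[list[int]] = []
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            row_ids.append(fields[0])
            rows.append([int(v) for v in fields[1:]])
    return RelationshipMatrix(row_ids, col_ids, np.array(rows, dtype=np.int8))
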