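"""Sequence and alignment I/O plus the coordinate conventions of the pipeline.

Every module in this package exchanges intervals as 0-based, half-open
``[start, end)`` on the forward strand of the reference.  SAM input
(1-based POS) is converted on the way in; the plain-text mapping TSV
dialect defined here is already 0-based half-open.

Formats handled: FASTA/FASTQ (via Biopython), SAM read-only (via pysam),
BED3+name for interval truth sets, and a 6-column mapping TSV
(``read_id  ref_id  ref_start  ref_end  strand  identity``, comment
lines starting with ``#``) as a minimal interchange format any mapper
output can be munged into.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pysam
from Bio import SeqIO

__all__ = [
    "SeqRecord",
    "MappedRead",
    "FormatError",
    "CoordinateError",
    "revcomp",
    "read_fasta",
    "write_fasta",
    "write_fastq",
    "read_mappings",
    "write_mappings_tsv",
    "write_mappings_sam",
    "read_bed",
    "write_bed",
    "from_1based_closed",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_SEQ = re.compile(r"^[ACGTN]+$")
_CIGAR_RE = re.compile(r"(\d+)([=XIDMSH])")


class FormatError(ValueError):
    """A file violates its declared format."""


class CoordinateError(ValueError):
    """An interval falls outside its reference sequence."""


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def from_1based_closed(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based closed interval [a, b] to 0-based half-open [a-1, b)."""
    return start - 1, end


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence over {A,C,G,T,N} with optional per-base qualities."""

    id: str
    sequence: str
    quality: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"sequence id must be a non-empty token: {self.id!r}")
        if not self.sequence:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        if not _VALID_SEQ.match(self.sequence):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise FormatError(f"record {self.id!r} contains invalid characters {bad}")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"record {self.id!r}: {len(self.quality)} quality scores for "
                f"{len(self.sequence)} bases"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MappedRead:
    """A read placed on the reference.

    ``read_sequence_oriented`` is the read sequence in reference
    orientation (already reverse-complemented for '-' strand mappings).
    ``cigar`` is an extended CIGAR (=/X/I/D, I consumes the read, D the
    reference) of that oriented sequence against
    ``reference[ref_start:ref_end]``; it may be absent for TSV input and
    is then recomputed on demand downstream.  ``secondary_identity`` is
    the identity of the best alternative placement seen by the mapper
    (None when no alternative was evaluated); it is what downstream
    stages use to tell reads that are pinned to one locus from reads
    that float between repeat copies.
    """

    read_id: str
    ref_id: str
    ref_start: int
    ref_end: int
    strand: str
    identity: float
    read_sequence_oriented: Optional[str] = None
    cigar: Optional[str] = None
    secondary_identity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"read {self.read_id!r}: unknown strand {self.strand!r}")
        if not (0 <= self.ref_start < self.ref_end):
            raise CoordinateError(
                f"read {self.read_id!r}: bad interval "
                f"[{self.ref_start}, {self.ref_end})"
            )
        if not (0.0 <= self.identity <= 1.0):
            raise FormatError(f"read {self.read_id!r}: identity {self.identity} not in [0,1]")

    def is_ambiguous(self, margin: float) -> bool:
        """True when a second placement scores within ``margin`` of the best."""
        return (
            self.secondary_identity is not None
            and self.secondary_identity >= self.identity - margin
        )


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path) -> list[SeqRecord]:
    """Read FASTA or FASTQ (autodetected by the first character).

    Sequences are uppercased and U is mapped to T.  An empty file yields
    an empty list.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == "":
        return []
    if first == ">":
        fmt = "fasta"
    elif first == "@":
        fmt = "fastq"
    else:
        raise FormatError(f"{path}: line 1 does not start a FASTA or FASTQ record")
    out: list[SeqRecord] = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            seq = _normalize(str(rec.seq))
            if not seq:
                raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
            qual = None
            if fmt == "fastq":
                qual = tuple(rec.letter_annotations["phred_quality"])
            out.append(SeqRecord(id=rec.id, sequence=seq, quality=qual))
    except ValueError as exc:  # Biopython parse errors
        raise FormatError(f"{path}: {exc}") from exc
    return out


def write_fasta(records: Iterable[SeqRecord], path, width: int = 70) -> None:
    """Write records as FASTA with ``width`` bases per sequence line."""
    if width < 1:
        raise ValueError(f"line width must be >= 1, got {width}")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_fastq(records: Iterable[SeqRecord], path, default_quality: int = 30) -> None:
    """Write records as FASTQ, padding missing qualities with a constant."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.quality or (default_quality,) * len(rec.sequence)
            qstr = "".join(chr(q + 33) for q in qual)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qstr}\n")


def _read_mappings_tsv(path: Path, reference: SeqRecord) -> list[MappedRead]:
    out: list[MappedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise FormatError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, got {len(fields)}"
                )
            read_id, ref_id, s, e, strand, ident = fields
            try:
                start, end = int(s), int(e)
                identity = float(ident)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            if not (0 <= start < end <= len(reference)):
                raise CoordinateError(
                    f"{path}:{lineno}: interval [{start}, {end}) outside "
                    f"reference {reference.id!r} of length {len(reference)}"
                )
            out.append(
                MappedRead(
                    read_id=read_id,
                    ref_id=ref_id,
                    ref_start=start,
                    ref_end=end,
                    strand=strand,
                    identity=identity,
                )
            )
    return out


def _cigar_identity(cigar: str) -> float:
    cols = matches = 0
    for n, op in _CIGAR_RE.findall(cigar):
        n = int(n)
        if op in "=XIDM":
            cols += n
        if op == "=":
            matches += n
    return matches / cols if cols else 0.0


def _read_mappings_sam(path: Path, reference: SeqRecord) -> list[MappedRead]:
    import edlib

    out: list[MappedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for i, aln in enumerate(sam, 1):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            start = aln.reference_start  # pysam is already 0-based
            end = aln.reference_end
            if end is None or not (0 <= start < end <= len(reference)):
                raise CoordinateError(
                    f"{path}: record {i} ({aln.query_name!r}): interval outside "
                    f"reference of length {len(reference)}"
                )
            seq = aln.query_sequence  # SAM stores SEQ reference-oriented
            cigar = None
            identity = 1.0
            if seq is not None:
                seq = _normalize(seq)
                res = edlib.align(seq, reference.sequence[start:end], mode="NW", task="path")
                cigar = res["cigar"]
                identity = _cigar_identity(cigar)
            out.append(
                MappedRead(
                    read_id=aln.query_name,
                    ref_id=aln.reference_name or reference.id,
                    ref_start=start,
                    ref_end=end,
                    strand="-" if aln.is_reverse else "+",
                    identity=identity,
                    read_sequence_oriented=seq,
                    cigar=cigar,
                )
            )
    return out


def read_mappings(path, reference: SeqRecord) -> list[MappedRead]:
    """Read a SAM file or the 6-column mapping TSV.

    The dialect is autodetected: a first character of ``@`` means SAM,
    anything else the TSV.  All coordinates are returned 0-based
    half-open regardless of dialect.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == "@" or path.suffix.lower() == ".sam":
        return _read_mappings_sam(path, reference)
    return _read_mappings_tsv(path, reference)


def write_mappings_tsv(mappings: Iterable[MappedRead], path) -> None:
    with open(path, "w") as fh:
        fh.write("#read_id\tref_id\tref_start\tref_end\tstrand\tidentity\n")
        for m in mappings:
            fh.write(
                f"{m.read_id}\t{m.ref_id}\t{m.ref_start}\t{m.ref_end}\t"
                f"{m.strand}\t{m.identity:.6f}\n"
            )


def write_mappings_sam(mappings: Iterable[MappedRead], reference: SeqRecord, path) -> None:
    """Write minimal single-reference SAM records (oriented SEQ, =/X/I/D CIGAR)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{reference.id}\tLN:{len(reference)}\n")
        for m in mappings:
            flag = 16 if m.strand == "-" else 0
            seq = m.read_sequence_oriented or "*"
            cigar = m.cigar or (f"{len(seq)}M" if seq != "*" else "*")
            fh.write(
                f"{m.read_id}\t{flag}\t{m.ref_id}\t{m.ref_start + 1}\t255\t"
                f"{cigar}\t*\t0\t0\t{seq}\t*\n"
            )


def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Read BED3+name rows as (chrom, start, end, name) tuples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs at least 3 columns")
            name = fields[3] if len(fields) > 3 else "."
            out.append((fields[0], int(fields[1]), int(fields[2]), name))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int, str]], path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def attach_sequences(
    mappings: Sequence[MappedRead], reads: dict[str, SeqRecord]
) -> list[MappedRead]:
    """Fill ``read_sequence_oriented`` from a read set where missing."""
    out = []
    for m in mappings:
        if m.read_sequence_oriented is None:
            rec = reads.get(m.read_id)
            if rec is None:
                raise FormatError(f"mapping for unknown read {m.read_id!r}")
            seq = rec.sequence if m.strand == "+" else revcomp(rec.sequence)
            m = replace(m, read_sequence_oriented=seq)
        out.append(m)
    return out
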