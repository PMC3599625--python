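"""Assembly evaluation: totals, NG(X)/LG(X), and gap-filling statistics.

NG(X) is the contig length at which the descending cumulative contig
length first reaches X% of the *genome* size (not the assembly size);
LG(X) is the number of contigs in that prefix.  Both are undefined —
reported as None, never 0 — when the assembly never reaches the
threshold.  Gap filling is counted against the anchor set: a
pre-existing inter-anchor reference gap counts as filled when one final
contig's reference projection covers it entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import edlib

from .io_formats import SeqRecord, revcomp
from .regions import Contig

__all__ = [
    "AssemblyMetrics",
    "ngx",
    "lgx",
    "gap_fill_stats",
    "anchor_gaps",
    "compute_metrics",
    "write_metrics_tsv",
]


@dataclass(frozen=True)
class AssemblyMetrics:
    genome_size: int
    total_length: int
    contig_number: int
    ng50: Optional[int]
    lg50: Optional[int]
    gap_fill_number: int
    gap_fill_length: int

    def row(self) -> dict:
        return {
            "genome_size": self.genome_size,
            "total_length": self.total_length,
            "contig_number": self.contig_number,
            "ng50": "NA" if self.ng50 is None else self.ng50,
            "lg50": "NA" if self.lg50 is None else self.lg50,
            "gap_fill_number": self.gap_fill_number,
            "gap_fill_length": self.gap_fill_length,
        }


def _check_ngx_args(lengths: Sequence[int], genome_size: int, x: float) -> None:
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    if not (0 < x <= 100):
        raise ValueError("x must be in (0, 100]")
    if any(l < 0 for l in lengths):
        raise ValueError("contig lengths must be non-negative")


def ngx(lengths: Sequence[int], genome_size: int, x: float = 50) -> Optional[int]:
    """Contig length at which cumulative descending length reaches x% of genome."""
    _check_ngx_args(lengths, genome_size, x)
    threshold = genome_size * x / 100.0
    acc = 0
    for l in sorted(lengths, reverse=True):
        acc += l
        if acc >= threshold:
            return l
    return None


def lgx(lengths: Sequence[int], genome_size: int, x: float = 50) -> Optional[int]:
    """Number of contigs in the descending prefix that first reaches x%."""
    _check_ngx_args(lengths, genome_size, x)
    threshold = genome_size * x / 100.0
    acc = 0
    for i, l in enumerate(sorted(lengths, reverse=True), 1):
        acc += l
        if acc >= threshold:
            return i
    return None


def anchor_gaps(anchors: Sequence[Contig]) -> list[tuple[int, int]]:
    """Maximal uncovered intervals strictly between consecutive anchors."""
    placed = sorted(
        (a for a in anchors if a.ref_start is not None), key=lambda a: a.ref_start
    )
    gaps = []
    for prev, nxt in zip(placed, placed[1:]):
        if nxt.ref_start > prev.ref_end:
            gaps.append((prev.ref_end, nxt.ref_start))
    return gaps


def _project(contig: Contig, reference: SeqRecord) -> Optional[tuple[int, int]]:
    """Reference interval spanned by a contig (best of both orientations)."""
    best = None
    for seq in (contig.sequence, revcomp(contig.sequence)):
        res = edlib.align(seq, reference.sequence, mode="HW", task="locations")
        if res["editDistance"] < 0:
            continue
        if best is None or res["editDistance"] < best[0]:
            loc = min(res["locations"])
            best = (res["editDistance"], loc[0], loc[1] + 1)
    if best is None:
        return None
    ed, s, e = best
    if ed > 0.3 * len(contig.sequence):
        return None
    return s, e


def gap_fill_stats(
    anchors: Sequence[Contig],
    final: Sequence[Contig],
    reference: SeqRecord,
) -> tuple[int, int]:
    """Count and total length of inter-anchor gaps closed by the final contigs.

    Final contigs are projected onto the reference by alignment; a gap
    counts as filled when some single contig's projection covers it
    entirely.  Contigs that fail to align are skipped with a warning.
    """
    gaps = anchor_gaps(anchors)
    if not gaps:
        return 0, 0
    spans = []
    for c in final:
        span = _project(c, reference)
        if span is None:
            warnings.warn(
                f"final contig {c.id!r} does not align to the reference; "
                "skipped in gap-fill statistics"
            )
            continue
        spans.append(span)
    number = 0
    length = 0
    for gs, ge in gaps:
        if any(s <= gs and ge <= e for s, e in spans):
            number += 1
            length += int(ge - gs)
    return number, length


def compute_metrics(
    final: Sequence[Contig],
    anchors: Sequence[Contig],
    reference: SeqRecord,
    genome_size: Optional[int] = None,
) -> AssemblyMetrics:
    """The full evaluation row for one assembly."""
    gsize = genome_size if genome_size is not None else len(reference)
    lengths = [len(c) for c in final]
    n_fill, len_fill = gap_fill_stats(anchors, final, reference) if final else (0, 0)
    return AssemblyMetrics(
        genome_size=gsize,
        total_length=sum(lengths),
        contig_number=len(lengths),
        ng50=ngx(lengths, gsize, 50) if lengths else None,
        lg50=lgx(lengths, gsize, 50) if lengths else None,
        gap_fill_number=n_fill,
        gap_fill_length=len_fill,
    )


def write_metrics_tsv(rows: Sequence[dict], path) -> None:
    """One assembly per row; extra leading key columns are preserved."""
    if not rows:
        raise ValueError("no metrics rows to write")
    cols = list(rows[0])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
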