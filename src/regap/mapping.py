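"""Seed-and-extend read-to-reference mapping.

A deliberately small mapper for the re-sequencing setting this package
targets: single-end reads a few hundred bases long, a reference at most
a few megabases, and reads expected to be fully contained in the
reference.  Exact k-mer seeds are binned by alignment diagonal, the
densest diagonals on both strands are extended with edlib semi-global
alignment (the whole read against a reference window), and the best
placement by identity is reported with deterministic tie-breaking
(smallest reference coordinate, then '+' strand).

Reads from identical repeat copies score equally at every copy; the
mapper reports the smallest-coordinate placement and records the best
alternative identity (``secondary_identity``) so downstream stages can
recognise placement-ambiguous reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import edlib

from .io_formats import MappedRead, SeqRecord, revcomp, _cigar_identity

__all__ = ["MapperParams", "KmerIndex", "index_reference", "map_read", "map_reads"]


@dataclass(frozen=True)
class MapperParams:
    """Mapping thresholds.

    k: seed k-mer length; min_identity: minimum fraction of match
    columns in the reported alignment; min_aligned_fraction: minimum
    fraction of the read consumed by the alignment (the semi-global
    extension aligns the whole read, so this only bites at reference
    ends); band: slack in bases added around the seed diagonal when
    extracting the alignment window.
    """

    k: int = 15
    min_identity: float = 0.9
    min_aligned_fraction: float = 0.9
    band: int = 30

    def __post_init__(self) -> None:
        if not (5 <= self.k <= 31):
            raise ValueError("k must be in [5, 31]")
        for name in ("min_identity", "min_aligned_fraction"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.band < 1:
            raise ValueError("band must be >= 1")


class KmerIndex:
    """Forward-strand k-mer -> start positions for one reference."""

    def __init__(self, reference: SeqRecord, k: int):
        if len(reference) < k:
            raise ValueError(
                f"reference of length {len(reference)} is shorter than k={k}"
            )
        self.k = k
        self.ref_id = reference.id
        self.positions: dict[str, list[int]] = {}
        seq = reference.sequence
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            self.positions.setdefault(kmer, []).append(i)

    def __len__(self) -> int:
        return sum(len(v) for v in self.positions.values())


def index_reference(reference: SeqRecord, k: int) -> KmerIndex:
    """Build the forward-strand k-mer index (k-mers containing N are skipped)."""
    return KmerIndex(reference, k)


def _candidate_windows(
    seq: str, index: KmerIndex, band: int, max_candidates: int = 10
) -> list[tuple[int, int, int]]:
    """Diagonal-binned seed hits -> (count, win_lo, win_hi) candidates.

    Diagonals (ref_pos - read_pos) are binned at the band width; all
    bins with at least half the best bin's seed count are kept (so that
    equally good repeat-copy placements are all evaluated), up to
    ``max_candidates``, ordered by seed count then coordinate.
    """
    k = index.k
    bins: dict[int, list[int]] = {}
    for p in range(0, len(seq) - k + 1):
        hits = index.positions.get(seq[p : p + k])
        if not hits:
            continue
        for rp in hits:
            diag = rp - p
            bins.setdefault(diag // band, []).append(diag)
    if not bins:
        return []
    # merge adjacent bins so a placement straddling a bin edge counts once
    merged: dict[int, tuple[int, int, int]] = {}
    for key, diags in bins.items():
        lo, hi, n = min(diags), max(diags), len(diags)
        merged[key] = (n, lo, hi)
    scored = []
    seen = set()
    for key in merged:
        if key in seen:
            continue
        n, lo, hi = merged[key]
        nxt = key + 1
        while nxt in merged and nxt not in seen:
            n2, lo2, hi2 = merged[nxt]
            n, lo, hi = n + n2, min(lo, lo2), max(hi, hi2)
            seen.add(nxt)
            nxt += 1
        seen.add(key)
        scored.append((n, lo, hi))
    best = max(n for n, _, _ in scored)
    keep = [c for c in scored if c[0] >= best / 2]
    keep.sort(key=lambda c: (-c[0], c[1]))
    return keep[:max_candidates]


def map_read(
    read: SeqRecord,
    index: KmerIndex,
    reference: SeqRecord,
    params: MapperParams = MapperParams(),
) -> Optional[MappedRead]:
    """Place one read on the reference, or return None when unmappable.

    Both orientations are tried; each candidate diagonal is extended by
    aligning the whole (oriented) read against the implied reference
    window.  The best-identity placement meeting ``min_identity`` and
    ``min_aligned_fraction`` wins; ties go to the smallest ref_start,
    then the '+' strand.
    """
    if len(read) < index.k:
        return None
    ref = reference.sequence
    L = len(ref)
    results = []
    for strand in ("+", "-"):
        seq = read.sequence if strand == "+" else revcomp(read.sequence)
        for _count, lo, hi in _candidate_windows(seq, index, params.band):
            ws = max(0, lo - params.band)
            we = min(L, hi + len(seq) + params.band)
            if we - ws < index.k:
                continue
            max_ed = max(10, int(len(seq) * (1.0 - params.min_identity) * 2) + 10)
            res = edlib.align(seq, ref[ws:we], mode="HW", task="path", k=max_ed)
            if res["editDistance"] < 0:
                continue
            loc = min(res["locations"])
            start, end = ws + loc[0], ws + loc[1] + 1
            identity = _cigar_identity(res["cigar"])
            # the whole read is aligned by construction; the fraction
            # check only rejects placements truncated at reference ends
            if (end - start) / len(seq) < params.min_aligned_fraction:
                continue
            results.append((identity, start, strand, end, res["cigar"], seq))
    if not results:
        return None
    results.sort(key=lambda r: (-r[0], r[1], r[2]))
    identity, start, strand, end, cigar, seq = results[0]
    if identity < params.min_identity:
        return None
    secondary = None
    for alt in results[1:]:
        if abs(alt[1] - start) > len(read) // 2 or alt[2] != strand:
            secondary = alt[0]
            break
    return MappedRead(
        read_id=read.id,
        ref_id=reference.id,
        ref_start=start,
        ref_end=end,
        strand=strand,
        identity=identity,
        read_sequence_oriented=seq,
        cigar=cigar,
        secondary_identity=secondary,
    )


def map_reads(
    reads: Sequence[SeqRecord],
    reference: SeqRecord,
    params: MapperParams = MapperParams(),
    index: Optional[KmerIndex] = None,
) -> list[MappedRead]:
    """Map a read set; unmappable reads are silently dropped."""
    if index is None:
        index = index_reference(reference, params.k)
    out = []
    for read in reads:
        m = map_read(read, index, reference, params)
        if m is not None:
            out.append(m)
    return out
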