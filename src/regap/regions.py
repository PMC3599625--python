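"""Anchor contig calling, gap-size filtering, and per-region read binning.

This is the first half of the method: project the mapped reads onto the
reference as a pileup, call consensus contigs over well-covered
intervals, and then *distrust* every contig shorter than the gap-size
threshold.  Short contigs are the fingerprint of repeat-induced
assembly breaks, so their footprints — merged with any uncovered
intervals between anchors — become repeat regions, each of which is
handed its locally mapped reads for re-assembly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._kernels import encode
from .io_formats import MappedRead, SeqRecord
from .mapping import MapperParams

__all__ = [
    "Contig",
    "RepeatRegion",
    "PipelineConfig",
    "call_anchor_contigs",
    "filter_small_contigs",
    "bin_reads",
]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class Contig:
    """A consensus sequence, optionally placed on the reference."""

    id: str
    sequence: str
    ref_id: Optional[str] = None
    ref_start: Optional[int] = None
    ref_end: Optional[int] = None
    provenance: str = "anchor"  # anchor | repeat_resolved | merged
    depth_mean: float = 0.0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.id!r} has an empty sequence")
        if self.ref_start is not None and self.ref_end is not None:
            if not (self.ref_start < self.ref_end):
                raise ValueError(f"contig {self.id!r}: bad interval")
        if self.provenance not in ("anchor", "repeat_resolved", "merged"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RepeatRegion:
    """A reference interval flagged as repeat-broken, with its read bin."""

    ref_id: str
    ref_start: int
    ref_end: int
    flank: int = 0
    read_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (self.ref_start < self.ref_end):
            raise ValueError(
                f"bad region interval [{self.ref_start}, {self.ref_end})"
            )

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class PipelineConfig:
    """Tunables of the whole pipeline.

    gap_size is the central parameter: contigs shorter than this are
    treated as repeat debris and their coordinates re-assembled.  The
    500 bp default matches the typical pyrosequencing read length —
    repeats shorter than a read resolve by mapping alone.  flank=None
    means "use the mean mapped read length", which guarantees the reads
    that straddle a repeat boundary are recruited into its bin.

    max_merge_mismatch_frac bounds the per-overlap difference fraction
    accepted when merging; it must exceed twice the per-read error rate
    (two noisy reads disagree at both reads' errors), hence 0.05 for the
    default pyrosequencing error model.  edit_overlaps enables the
    indel-tolerant overlap mode, without which homopolymer indel noise
    breaks exact suffix/prefix matching at the first indel.
    """

    gap_size: int = 500
    min_depth: int = 3
    flank: Optional[int] = None
    max_iters: int = 25
    min_overlap: int = 40
    max_merge_mismatch_frac: float = 0.05
    edit_overlaps: bool = True
    ambiguity_margin: float = 0.01
    polish: bool = True
    circular: bool = False
    mapper: MapperParams = MapperParams()

    def __post_init__(self) -> None:
        if self.gap_size < 0:
            raise ValueError("gap_size must be >= 0")
        for name in ("min_depth", "max_iters", "min_overlap"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.flank is not None and self.flank < 0:
            raise ValueError("flank must be >= 0")
        if not (0.0 <= self.max_merge_mismatch_frac < 1.0):
            raise ValueError("max_merge_mismatch_frac must be in [0, 1)")


def _depth_array(mappings: Sequence[MappedRead], length: int) -> np.ndarray:
    depth = np.zeros(length + 1, dtype=np.int32)
    for m in mappings:
        depth[m.ref_start] += 1
        depth[m.ref_end] -= 1
    return np.cumsum(depth[:-1]).astype(np.int32)


def _covered_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs where the boolean mask is True."""
    if not mask.any():
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def _pileup_counts(
    mappings: Sequence[MappedRead], reference: SeqRecord
) -> np.ndarray:
    """Per-column base vote counts (L x 4) from the mapped reads.

    Each read is walked along its CIGAR; match/mismatch columns deposit
    the read base, insertions are skipped, deletions deposit nothing.
    Mappings without a CIGAR are realigned against their window first.
    """
    import edlib

    L = len(reference)
    counts = np.zeros((L, 4), dtype=np.int32)
    ref_seq = reference.sequence
    for m in mappings:
        seq = m.read_sequence_oriented
        if seq is None:
            continue
        cigar = m.cigar
        if cigar is None:
            res = edlib.align(
                seq, ref_seq[m.ref_start : m.ref_end], mode="NW", task="path"
            )
            cigar = res["cigar"]
        codes = encode(seq)
        rp, qp = m.ref_start, 0
        for num, op in _CIGAR_RE.findall(cigar):
            n = int(num)
            if op in "=XM":
                idx = np.arange(rp, min(rp + n, L))
                base_codes = codes[qp : qp + len(idx)]
                valid = base_codes < 4
                np.add.at(counts, (idx[valid], base_codes[valid]), 1)
                rp += n
                qp += n
            elif op == "I":
                qp += n
            elif op == "D":
                rp += n
    return counts


def consensus_sequence(
    counts: np.ndarray, ref_codes: np.ndarray, start: int, end: int
) -> str:
    """Majority base per column; ties (and empty columns) fall back to the
    reference base, then alphabetical order."""
    from ._kernels import decode

    votes = counts[start:end]
    best = votes.argmax(axis=1).astype(np.uint8)  # argmax -> alphabetical on ties
    maxv = votes.max(axis=1)
    ref = ref_codes[start:end]
    ref_clipped = np.minimum(ref, 3)
    ref_votes = votes[np.arange(end - start), ref_clipped]
    use_ref = (ref_votes == maxv) & (ref < 4)
    out = np.where(use_ref, ref, best).astype(np.uint8)
    return decode(out)


def call_anchor_contigs(
    mappings: Sequence[MappedRead],
    reference: SeqRecord,
    min_depth: int = 3,
) -> list[Contig]:
    """Consensus contigs over every maximal interval with pileup depth >= min_depth.

    Contigs carry their reference coordinates and are returned sorted by
    ref_start.  An empty mapping set yields no contigs.
    """
    if not mappings:
        return []
    L = len(reference)
    depth = _depth_array(mappings, L)
    runs = _covered_runs(depth >= min_depth)
    if not runs:
        return []
    counts = _pileup_counts(mappings, reference)
    ref_codes = encode(reference.sequence)
    contigs = []
    for i, (s, e) in enumerate(runs, 1):
        seq = consensus_sequence(counts, ref_codes, s, e)
        contigs.append(
            Contig(
                id=f"contig_{i}",
                sequence=seq,
                ref_id=reference.id,
                ref_start=s,
                ref_end=e,
                provenance="anchor",
                depth_mean=float(depth[s:e].mean()),
            )
        )
    return contigs


def filter_small_contigs(
    contigs: Sequence[Contig],
    reference_length: int,
    gap_size: int,
    ref_id: str = "",
) -> tuple[list[Contig], list[RepeatRegion]]:
    """Split contigs into anchors and repeat regions by the gap-size threshold.

    Contigs of length >= gap_size survive as anchors.  Every maximal
    reference interval not covered by an anchor — the footprints of the
    filtered short contigs together with uncovered coverage gaps, merged
    when adjacent — becomes one repeat region.  Anchors and regions
    alternate along the reference and partition [0, reference_length).
    """
    anchors = [c for c in contigs if len(c) >= gap_size]
    anchors.sort(key=lambda c: c.ref_start)
    if not ref_id:
        ref_id = anchors[0].ref_id if anchors else (
            contigs[0].ref_id if contigs else "ref"
        )
    regions = []
    pos = 0
    for a in anchors:
        if a.ref_start > pos:
            regions.append(RepeatRegion(ref_id=ref_id, ref_start=pos, ref_end=a.ref_start))
        pos = a.ref_end
    if pos < reference_length:
        regions.append(RepeatRegion(ref_id=ref_id, ref_start=pos, ref_end=reference_length))
    return anchors, regions


def bin_reads(
    mappings: Sequence[MappedRead], region: RepeatRegion, flank: int
) -> RepeatRegion:
    """Fill a region's read bin with every read intersecting region +/- flank."""
    ws = max(0, region.ref_start - flank)
    we = region.ref_end + flank
    ids = {m.read_id for m in mappings if m.ref_start < we and m.ref_end > ws}
    return RepeatRegion(
        ref_id=region.ref_id,
        ref_start=region.ref_start,
        ref_end=region.ref_end,
        flank=flank,
        read_ids=ids,
    )
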