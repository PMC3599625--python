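"""Stitching anchors and repeat-resolved contigs into final contigs,
and the end-to-end pipeline driver.

The stitcher walks the reference left to right.  At each junction it
tries to splice the growing contig's 3' end onto the next piece's 5'
end (either orientation) by suffix/prefix overlap consensus; when a
junction fails the current contig is closed and a new one starts.
Junction failures break the contig rather than inserting N runs — the
output is a contig set, not a scaffold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from ._kernels import encode, longest_suffix_prefix
from .io_formats import MappedRead, SeqRecord, attach_sequences, revcomp
from .local_assembly import ReadKmerIndex, RegionResult, edit_end_overlap, resolve_region
from .mapping import map_reads
from .metrics import AssemblyMetrics, compute_metrics
from .regions import (
    Contig,
    PipelineConfig,
    RepeatRegion,
    bin_reads,
    call_anchor_contigs,
    filter_small_contigs,
)

__all__ = ["stitch", "run_pipeline", "PipelineResult"]

log = logging.getLogger("regap")


class _Grow:
    """The contig being extended during the left-to-right walk."""

    __slots__ = ("seq", "depth", "n_pieces")

    def __init__(self, piece: Contig):
        self.seq = piece.sequence
        self.depth = piece.depth_mean
        self.n_pieces = 1

    def splice(self, piece: Contig, junction) -> None:
        """Apply a junction found by :func:`_end_overlap`.

        Overlap consensus keeps the higher-mean-depth side's bases
        (anchors beat repeat-resolved contigs on conflicts).
        """
        olen, pred_seq, succ_seq, cur_is_pred, succ_cut = junction
        if cur_is_pred:
            take_piece = piece.depth_mean > self.depth
            self.seq = (
                pred_seq[:-olen] + succ_seq
                if take_piece
                else pred_seq + succ_seq[succ_cut:]
            )
        else:
            take_piece = piece.depth_mean >= self.depth
            self.seq = (
                pred_seq + succ_seq[succ_cut:]
                if take_piece
                else pred_seq[:-olen] + succ_seq
            )
        grown = len(succ_seq if cur_is_pred else pred_seq) - olen
        total = len(self.seq)
        self.depth = (
            self.depth * (total - grown) + piece.depth_mean * grown
        ) / max(total, 1)
        self.n_pieces += 1


def _end_overlap(
    cur_seq: str, piece: Contig, min_overlap: int, frac: float, edit: bool
):
    """Best junction between the growing contig and the next piece.

    All four end-overlap geometries are considered (the piece may splice
    onto either end of the growing contig, in either orientation; the
    merged sequence then covers the union).  Returns ``(olen, pred_seq,
    succ_seq, cur_is_pred, succ_cut)`` with sequences already oriented
    so that ``pred_seq[-olen:]`` pairs with ``succ_seq[:succ_cut]``, or
    None when no junction qualifies.
    """
    a_f = encode(cur_seq)
    b_fs = piece.sequence
    b_rs = revcomp(piece.sequence)
    b_f = encode(b_fs)
    b_r = encode(b_rs)
    combos = (
        (a_f, b_f, cur_seq, b_fs, True),
        (a_f, b_r, cur_seq, b_rs, True),
        (b_f, a_f, b_fs, cur_seq, False),
        (b_r, a_f, b_rs, cur_seq, False),
    )
    best = None
    for pa, pb, pseq, sseq, cur_is_pred in combos:
        olen, _m = longest_suffix_prefix(pa, pb, min_overlap, frac)
        succ_cut = olen
        if olen == 0 and edit:
            got = edit_end_overlap(pseq, sseq, min_overlap, frac)
            if got is not None:
                olen, _ed, succ_cut = got
        if olen > 0 and (best is None or olen > best[0]):
            best = (olen, pseq, sseq, cur_is_pred, succ_cut)
    return best


def stitch(
    anchors: Sequence[Contig],
    region_contigs: Mapping[tuple[int, int], Sequence[Contig]],
    cfg: PipelineConfig,
) -> list[Contig]:
    """Merge anchors and per-region contigs into final contigs.

    ``region_contigs`` maps a region's (ref_start, ref_end) to its
    contigs.  Pieces are visited in reference order; within a region,
    contigs are chained greedily by best end overlap.  Region contigs
    that never splice anywhere are emitted as standalone final contigs.
    Final contigs are sorted by descending length and renamed
    ``final_1, final_2, ...``.
    """
    min_ov, frac = cfg.min_overlap, cfg.max_merge_mismatch_frac
    edit = cfg.edit_overlaps
    events: list[tuple[int, str, object]] = []
    for a in anchors:
        events.append((a.ref_start, "anchor", a))
    for key in region_contigs:
        events.append((key[0], "region", key))
    events.sort(key=lambda e: (e[0], e[1]))

    finished: list[str] = []
    leftovers: list[Contig] = []
    held: list[Contig] = []  # unplaced contigs of the region just walked
    cur: Optional[_Grow] = None
    junctions_merged = 0

    def close() -> None:
        nonlocal cur
        if cur is not None:
            finished.append(cur.seq)
            cur = None

    def chain_pool(grow: _Grow, pool: list[Contig]) -> int:
        """Greedily splice pool pieces onto grow's end; returns splice count."""
        n = 0
        while pool:
            best_i = None
            best = None
            for i, piece in enumerate(pool):
                got = _end_overlap(grow.seq, piece, min_ov, frac, edit)
                if got is not None and (best is None or got[0] > best[0]):
                    best, best_i = got, i
            if best is None:
                break
            grow.splice(pool.pop(best_i), best)
            n += 1
        return n

    for _pos, kind, obj in events:
        if kind == "region":
            leftovers.extend(held)
            pool = sorted(
                region_contigs[obj], key=lambda c: (-len(c.sequence), c.id)
            )
            if cur is None:
                cur = _Grow(pool.pop(0))
            junctions_merged += chain_pool(cur, pool)
            held = pool  # pieces that did not reach the left side
            continue
        # anchor
        anchor = obj
        if cur is None:
            cur = _Grow(anchor)
            leftovers.extend(held)
            held = []
            continue
        got = _end_overlap(cur.seq, anchor, min_ov, frac, edit)
        if got is not None:
            cur.splice(anchor, got)
            junctions_merged += 1
            leftovers.extend(held)
            held = []
            continue
        # the direct junction failed: see whether a held region contig
        # bridges into this anchor from the right side of the break
        bridged = False
        while held and not bridged:
            candidate = _Grow(held.pop(0))
            junctions_merged += chain_pool(candidate, held)
            got = _end_overlap(candidate.seq, anchor, min_ov, frac, edit)
            if got is not None:
                close()
                cur = candidate
                cur.splice(anchor, got)
                junctions_merged += 1
                bridged = True
            else:
                leftovers.append(
                    Contig(id="held", sequence=candidate.seq, provenance="merged")
                )
        if not bridged:
            close()
            cur = _Grow(anchor)
        leftovers.extend(held)
        held = []
    leftovers.extend(held)
    close()

    seqs = finished + [c.sequence for c in leftovers]
    if cfg.circular and len(seqs) == 1 and len(seqs[0]) > 1:
        a = encode(seqs[0])
        # cap the self-overlap below full length (a trivially matches itself)
        olen, _m = longest_suffix_prefix(a, a[:-1], min_ov, frac)
        if 0 < olen < len(seqs[0]):
            seqs[0] = seqs[0][:-olen]
            log.info("circular closure: trimmed %d-base terminal overlap", olen)
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), i))
    final = [
        Contig(id=f"final_{rank}", sequence=seqs[i], provenance="merged")
        for rank, i in enumerate((order), 1)
    ]
    log.info("stitch: %d junctions merged, %d final contigs", junctions_merged, len(final))
    return final


@dataclass
class PipelineResult:
    final: list[Contig]
    anchors: list[Contig]
    metrics: AssemblyMetrics
    regions: list[RegionResult] = field(default_factory=list)
    mappings: list[MappedRead] = field(default_factory=list)
    counts: dict = field(default_factory=dict)


def run_pipeline(
    reads: Sequence[SeqRecord],
    reference: SeqRecord,
    cfg: PipelineConfig = PipelineConfig(),
    mappings: Optional[Sequence[MappedRead]] = None,
) -> PipelineResult:
    """Map reads, call and filter anchors, re-assemble repeat regions, stitch.

    ``mappings`` may be supplied (SAM/TSV input) to skip the built-in
    mapper.  The whole pipeline is deterministic for fixed inputs and
    configuration.
    """
    read_store = {r.id: r for r in reads}
    if mappings is None:
        mappings = map_reads(reads, reference, cfg.mapper)
    mappings = attach_sequences(mappings, read_store)
    log.info("mapped %d / %d reads", len(mappings), len(reads))

    anchors0 = call_anchor_contigs(mappings, reference, cfg.min_depth)
    anchors, regions = filter_small_contigs(
        anchors0, len(reference), cfg.gap_size, ref_id=reference.id
    )
    log.info(
        "%d raw contigs -> %d anchors, %d repeat regions",
        len(anchors0), len(anchors), len(regions),
    )

    if cfg.flank is not None:
        flank = cfg.flank
    elif mappings:
        flank = round(
            sum(len(m.read_sequence_oriented) for m in mappings) / len(mappings)
        )
    else:
        flank = 0

    mapped_reads = {m.read_id: read_store[m.read_id] for m in mappings}
    ambiguous = {
        m.read_id for m in mappings if m.is_ambiguous(cfg.ambiguity_margin)
    }
    recruit_index = ReadKmerIndex(mapped_reads.values()) if regions else None

    region_results: list[RegionResult] = []
    region_contigs: dict[tuple[int, int], list[Contig]] = {}
    anchors_sorted = sorted(anchors, key=lambda a: a.ref_start)
    for region in regions:
        binned = bin_reads(mappings, region, flank)
        left = next(
            (a for a in reversed(anchors_sorted) if a.ref_end <= region.ref_start),
            None,
        )
        right = next(
            (a for a in anchors_sorted if a.ref_start >= region.ref_end), None
        )
        res = resolve_region(
            binned,
            mapped_reads,
            anchors_flanking=(left, right),
            cfg=cfg,
            recruit_index=recruit_index,
            recruit_pool=ambiguous | binned.read_ids,
        )
        region_results.append(res)
        if res.contigs:
            region_contigs[(region.ref_start, region.ref_end)] = res.contigs
        log.info(
            "region [%d, %d): %d reads, %d contigs, %d iterations%s",
            region.ref_start, region.ref_end, len(res.read_ids),
            len(res.contigs), res.iterations,
            "" if res.converged else " (iteration cap hit)",
        )

    final = stitch(anchors_sorted, region_contigs, cfg) if (
        anchors_sorted or region_contigs
    ) else []
    metrics = compute_metrics(final, anchors_sorted, reference)
    counts = {
        "reads_total": len(reads),
        "reads_mapped": len(mappings),
        "anchors": len(anchors_sorted),
        "regions": len(regions),
        "regions_closed": sum(1 for r in region_results if len(r.contigs) == 1),
        "final_contigs": len(final),
    }
    return PipelineResult(
        final=final,
        anchors=anchors_sorted,
        metrics=metrics,
        regions=region_results,
        mappings=list(mappings),
        counts=counts,
    )
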