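"""Greedy overlap-layout-consensus re-assembly of repeat-region read bins.

Each repeat region is assembled from its binned reads by repeatedly
merging the pair of sequences with the longest qualifying suffix/prefix
overlap (substitutions only, bounded mismatch fraction).  The assembly
is then iterated: reads from the full mapped-read set whose ends
overlap the current contig ends are recruited into the bin and the
region is re-assembled, letting contigs grow into repeat interiors
whose reads were pinned to another copy by the mapper.  Iteration stops
at a read-set fixpoint, when both flanking anchors are reached, or at
the iteration cap.

Only placement-ambiguous reads (those the mapper scored almost equally
at a second locus) are eligible for recruitment by default: reads pinned
confidently to another locus belong to that locus's anchor, and pulling
them in would graft a foreign flank onto the repeat.
"""

from __future__ import annotations

import heapq
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from ._kernels import decode, encode, longest_suffix_prefix, revcomp_codes
from .io_formats import SeqRecord, revcomp
from .regions import Contig, PipelineConfig, RepeatRegion

__all__ = [
    "Overlap",
    "best_overlap",
    "greedy_assemble",
    "resolve_region",
    "RegionResult",
    "ReadKmerIndex",
    "polish_contig",
]

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


@dataclass(frozen=True)
class Overlap:
    """A suffix(a)/prefix(b) end overlap.

    ``orientation`` is '++' when b is used as given and '+-' when b is
    reverse-complemented before the comparison.
    """

    a_id: str
    b_id: str
    a_suffix_len: int
    mismatches: int
    orientation: str


def best_overlap(
    a: str,
    b: str,
    min_overlap: int,
    max_mismatch_frac: float = 0.0,
    a_id: str = "a",
    b_id: str = "b",
) -> Optional[Overlap]:
    """Longest suffix(a)/prefix(b) match allowing substitutions only.

    Both b and its reverse complement are considered; on equal overlap
    length the forward orientation wins.  Returns None when no overlap
    of length >= ``min_overlap`` keeps its mismatch fraction within
    ``max_mismatch_frac``.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    ca = encode(a)
    cb = encode(b)
    o_f, m_f = longest_suffix_prefix(ca, cb, min_overlap, max_mismatch_frac)
    o_r, m_r = longest_suffix_prefix(
        ca, revcomp_codes(cb), min_overlap, max_mismatch_frac
    )
    if o_f == 0 and o_r == 0:
        return None
    if o_f >= o_r:
        return Overlap(a_id, b_id, o_f, m_f, "++")
    return Overlap(a_id, b_id, o_r, m_r, "+-")


class _Piece:
    """A live sequence in the greedy assembler (read or partial contig)."""

    __slots__ = ("id", "seq", "rcseq", "fwd", "rc")

    def __init__(self, pid: str, seq: str):
        self.id = pid
        self.seq = seq
        self.rcseq = revcomp(seq)
        self.fwd = encode(seq)
        self.rc = revcomp_codes(self.fwd)


def edit_end_overlap(
    pred: str, succ: str, min_overlap: int, max_diff_frac: float
) -> Optional[tuple[int, int, int]]:
    """Suffix(pred)/prefix(succ) overlap allowing indels as well as substitutions.

    The first ``min_overlap`` bases of succ are located in pred's tail
    (edlib infix alignment); the implied overlap is then verified by
    aligning pred's suffix against succ's prefix (edlib prefix-anchored
    alignment).  Returns ``(pred_suffix_len, edit_distance, succ_cut)``
    where ``succ_cut`` is the succ position at which the non-overlapping
    tail starts, or None when no overlap within the edit budget exists.
    Substitution-only overlaps are a special case; this mode exists for
    homopolymer-indel noise, where exact suffix/prefix matching breaks
    at the first indel disagreement between two reads.
    """
    import edlib

    w = min(len(pred), len(succ))
    if w < min_overlap:
        return None
    pad = int(max_diff_frac * w) + 5
    tail = pred[-min(len(pred), w + pad):]
    probe = succ[:min_overlap]
    k1 = max(2, int(max_diff_frac * min_overlap) + 2)
    res = edlib.align(probe, tail, mode="HW", task="locations", k=k1)
    if res["editDistance"] < 0:
        return None
    loc = min(res["locations"], key=lambda l: l[0])
    pred_suffix = len(tail) - loc[0]
    if pred_suffix < min_overlap:
        return None
    pred_suffix = min(pred_suffix, len(pred))
    k2 = max(2, int(max_diff_frac * pred_suffix) + 1)
    target = succ[: min(len(succ), pred_suffix + pad)]
    res2 = edlib.align(pred[-pred_suffix:], target, mode="SHW",
                       task="locations", k=k2)
    if res2["editDistance"] < 0:
        return None
    succ_cut = max(l[1] for l in res2["locations"]) + 1
    return pred_suffix, res2["editDistance"], succ_cut


def _pair_candidates(
    a: _Piece, b: _Piece, min_overlap: int, frac: float, edit: bool = False
):
    """All end-overlap geometries between two arbitrarily oriented pieces.

    Yields ``(olen, mism, pred_id, succ_id, geom, succ_cut)`` where
    ``geom`` is a two-character orientation code for (pred, succ) and
    ``succ_cut`` is where the successor's non-overlapping tail starts.
    The four distinct geometries are: a tail on b head, b tail on a
    head, tail-on-tail (succ reverse-complemented), and head-on-head
    (pred reverse-complemented).  With ``edit`` the indel-tolerant
    overlap is tried whenever exact suffix/prefix matching fails.
    """
    combos = (
        (a.fwd, b.fwd, a.seq, b.seq, a.id, b.id, "++"),
        (b.fwd, a.fwd, b.seq, a.seq, b.id, a.id, "++"),
        (a.fwd, b.rc, a.seq, b.rcseq, a.id, b.id, "+-"),
        (a.rc, b.fwd, a.rcseq, b.seq, a.id, b.id, "-+"),
    )
    for pa, pb, pseq, sseq, pid, sid, geom in combos:
        olen, mism = longest_suffix_prefix(pa, pb, min_overlap, frac)
        if olen > 0:
            yield olen, mism, pid, sid, geom, olen
        elif edit:
            got = edit_end_overlap(pseq, sseq, min_overlap, frac)
            if got is not None:
                yield got[0], got[1], pid, sid, geom, got[2]


def _any_end_overlap(
    a: _Piece, b: _Piece, min_overlap: int, frac: float, edit: bool = False
) -> bool:
    for _ in _pair_candidates(a, b, min_overlap, frac, edit):
        return True
    return False


def _drop_contained(pieces: list[_Piece], max_mismatch_frac: float) -> list[_Piece]:
    """Remove pieces whose sequence is contained in a longer piece.

    Classic OLC contained-read removal: a sequence that aligns entirely
    inside another (within the configured mismatch budget, here as an
    edit-distance budget) contributes no structure and would otherwise
    survive as a redundant singleton contig.
    """
    import edlib

    pieces = sorted(pieces, key=lambda p: (-len(p.seq), p.id))
    kept: list[_Piece] = []
    for p in pieces:
        contained = False
        budget = int(max(1, max_mismatch_frac * len(p.seq)))
        for big in kept:
            if len(big.seq) < len(p.seq):
                continue
            for query in (p.seq, revcomp(p.seq)):
                res = edlib.align(query, big.seq, mode="HW", k=budget)
                if res["editDistance"] >= 0:
                    contained = True
                    break
            if contained:
                break
        if not contained:
            kept.append(p)
    return kept


def greedy_assemble(
    reads: Sequence[SeqRecord],
    min_overlap: int,
    max_mismatch_frac: float = 0.0,
    edit_overlaps: bool = False,
) -> list[Contig]:
    """Greedy OLC assembly of a read set into contigs.

    The pair with the longest qualifying overlap is merged first (ties:
    larger combined length, then lexicographically smallest id pair;
    forward orientation preferred inside a pair).  The merged sequence
    keeps the predecessor's bases over the overlap columns and appends
    the successor's non-overlapping tail.  Contigs contained in a longer
    contig are dropped; output is sorted by descending length.
    """
    if not reads:
        return []
    pieces: dict[str, _Piece] = {}
    for rec in sorted(reads, key=lambda r: r.id):
        pieces[rec.id] = _Piece(rec.id, rec.sequence)

    heap: list = []

    def push_pairs(a: _Piece, b: _Piece) -> None:
        for olen, mism, pid, sid, geom, succ_cut in _pair_candidates(
            a, b, min_overlap, max_mismatch_frac, edit_overlaps
        ):
            total = len(a.seq) + len(b.seq)
            heapq.heappush(heap, (-olen, -total, pid, sid, geom, succ_cut))

    ids = list(pieces)
    for i, pa in enumerate(ids):
        for pb in ids[i + 1 :]:
            push_pairs(pieces[pa], pieces[pb])

    counter = 0
    while heap:
        neg_olen, neg_total, pid, sid, geom, succ_cut = heapq.heappop(heap)
        pred = pieces.get(pid)
        succ = pieces.get(sid)
        if pred is None or succ is None:
            continue  # stale entry
        pred_seq = pred.seq if geom[0] == "+" else pred.rcseq
        succ_seq = succ.seq if geom[1] == "+" else succ.rcseq
        merged_seq = pred_seq + succ_seq[succ_cut:]
        del pieces[pid], pieces[sid]
        counter += 1
        merged = _Piece(f"m{counter:06d}", merged_seq)
        for other in pieces.values():
            push_pairs(merged, other)
        pieces[merged.id] = merged

    kept = _drop_contained(list(pieces.values()), max_mismatch_frac)
    contigs = []
    for i, p in enumerate(sorted(kept, key=lambda p: (-len(p.seq), p.id)), 1):
        contigs.append(
            Contig(id=f"rr_{i}", sequence=p.seq, provenance="repeat_resolved")
        )
    return contigs


class ReadKmerIndex:
    """k-mer -> read ids over raw read sequences, for recruitment lookups.

    Reads are indexed at a small stride; lookups scan a contig end
    window (and its reverse complement) at stride 1, so any true end
    overlap of at least ``min_overlap`` bases shares several indexed
    k-mers with the window even at moderate error rates.
    """

    def __init__(self, reads: Iterable[SeqRecord], k: int = 16, stride: int = 4):
        self.k = k
        self.index: dict[str, set[str]] = {}
        self.max_len = 0
        for rec in reads:
            seq = rec.sequence
            self.max_len = max(self.max_len, len(seq))
            for i in range(0, len(seq) - k + 1, stride):
                self.index.setdefault(seq[i : i + k], set()).add(rec.id)

    def candidates(self, window: str) -> set[str]:
        out: set[str] = set()
        for seq in (window, revcomp(window)):
            for i in range(len(seq) - self.k + 1):
                hit = self.index.get(seq[i : i + self.k])
                if hit:
                    out |= hit
        return out


def _read_qualifies(
    piece: _Piece, read: _Piece, min_overlap: int, frac: float, edit: bool
) -> bool:
    """True when the read end-overlaps either end of the contig."""
    return _any_end_overlap(piece, read, min_overlap, frac, edit)


@dataclass
class RegionResult:
    """Outcome of iterative re-assembly of one repeat region."""

    region: RepeatRegion
    contigs: list[Contig]
    iterations: int
    converged: bool
    read_ids: set[str] = field(default_factory=set)


def _end_window(seq: str, side: str, width: int) -> str:
    return seq[-width:] if side == "right" else seq[:width]


def polish_contig(
    sequence: str, reads: Sequence[SeqRecord], max_divergence: float = 0.2
) -> str:
    """One pass of pileup polishing of a contig with its own reads.

    Every read is aligned (both orientations, edlib infix alignment)
    against the contig; per-column votes over {A,C,G,T,deletion} plus
    majority insertions are applied.  Ties keep the existing base.
    Reads whose best alignment diverges more than ``max_divergence``
    are ignored.
    """
    import edlib

    L = len(sequence)
    votes = np.zeros((L, 5), dtype=np.int32)
    insertions: dict[int, Counter] = {}
    for rec in reads:
        best = None
        for seq in (rec.sequence, revcomp(rec.sequence)):
            res = edlib.align(seq, sequence, mode="HW", task="path",
                              k=int(max_divergence * len(seq)))
            if res["editDistance"] < 0:
                continue
            if best is None or res["editDistance"] < best[0]:
                best = (res["editDistance"], res, seq)
        if best is None:
            continue
        _, res, seq = best
        codes = encode(seq)
        cp = min(res["locations"])[0]
        qp = 0
        for num, op in _CIGAR_RE.findall(res["cigar"]):
            n = int(num)
            if op in "=X":
                idx = np.arange(cp, min(cp + n, L))
                bc = codes[qp : qp + len(idx)]
                ok = bc < 4
                np.add.at(votes, (idx[ok], bc[ok]), 1)
                cp += n
                qp += n
            elif op == "I":
                frag = seq[qp : qp + n]
                insertions.setdefault(cp, Counter())[frag] += 1
                qp += n
            elif op == "D":
                votes[cp : min(cp + n, L), 4] += 1
                cp += n
    cov = votes.sum(axis=1)
    base_votes = votes[:, :4]
    best_code = base_votes.argmax(axis=1).astype(np.uint8)
    best_n = base_votes.max(axis=1)
    old = encode(sequence)
    old_clipped = np.minimum(old, 3)
    old_votes = base_votes[np.arange(L), old_clipped]
    keep_old = old_votes >= best_n
    new_code = np.where(keep_old, old, best_code).astype(np.uint8)
    delete = votes[:, 4] * 2 > cov
    out: list[str] = []
    for i in range(L):
        ins = insertions.get(i)
        if ins and cov[i] > 0:
            frag, n = max(ins.items(), key=lambda kv: (kv[1], kv[0]))
            if n * 2 > cov[i]:
                out.append(frag)
        if not delete[i]:
            out.append(decode(new_code[i : i + 1]))
    return "".join(out) if out else sequence


def resolve_region(
    region: RepeatRegion,
    read_store: Mapping[str, SeqRecord],
    anchors_flanking: tuple[Optional[Contig], Optional[Contig]] = (None, None),
    cfg: PipelineConfig = PipelineConfig(),
    recruit_index: Optional[ReadKmerIndex] = None,
    recruit_pool: Optional[set[str]] = None,
) -> RegionResult:
    """Iteratively assemble one repeat region from its read bin.

    ``read_store`` holds every mapped read by id (raw orientation).
    ``recruit_pool`` limits which read ids may be recruited beyond the
    initial bin; None allows the whole store (the pipeline passes the
    placement-ambiguous subset).  Assembly stops early when the region
    is spanned by one contig that end-overlaps both flanking anchors.
    """
    current = {rid for rid in region.read_ids if rid in read_store}
    if not current:
        return RegionResult(region=region, contigs=[], iterations=0, converged=True)
    pool = set(read_store) if recruit_pool is None else (recruit_pool & set(read_store))
    if recruit_index is None:
        recruit_index = ReadKmerIndex(read_store.values())
    left, right = anchors_flanking
    min_ov, frac = cfg.min_overlap, cfg.max_merge_mismatch_frac
    edit = cfg.edit_overlaps
    window_w = max(recruit_index.max_len, cfg.min_overlap)

    contigs: list[Contig] = []
    converged = False
    iterations = 0
    for iterations in range(1, cfg.max_iters + 1):
        contigs = greedy_assemble(
            [read_store[rid] for rid in sorted(current)], min_ov, frac, edit
        )
        if not contigs:
            converged = True
            break
        if left is not None and right is not None and len(contigs) == 1:
            cp = _Piece("c", contigs[0].sequence)
            hit_l = _any_end_overlap(
                _Piece("l", left.sequence[-window_w * 2 :]), cp, min_ov, frac, edit
            )
            hit_r = _any_end_overlap(
                _Piece("r", right.sequence[: window_w * 2]), cp, min_ov, frac, edit
            )
            if hit_l and hit_r:
                converged = True
                break
        if iterations == cfg.max_iters:
            break
        new_ids: set[str] = set()
        for contig in contigs:
            piece = _Piece(contig.id, contig.sequence)
            cand: set[str] = set()
            for side in ("left", "right"):
                cand |= recruit_index.candidates(
                    _end_window(contig.sequence, side, window_w)
                )
            for rid in sorted(cand - current):
                if rid not in pool:
                    continue
                r = read_store[rid]
                if _read_qualifies(piece, _Piece(rid, r.sequence), min_ov, frac, edit):
                    new_ids.add(rid)
        if not new_ids:
            converged = True
            break
        current |= new_ids

    if cfg.polish and contigs:
        bin_reads_recs = [read_store[rid] for rid in sorted(current)]
        polished = []
        for c in contigs:
            polished.append(
                Contig(
                    id=c.id,
                    sequence=polish_contig(c.sequence, bin_reads_recs),
                    provenance="repeat_resolved",
                )
            )
        contigs = polished

    tagged = [
        Contig(
            id=f"region_{region.ref_start}_{region.ref_end}_{c.id}",
            sequence=c.sequence,
            ref_id=region.ref_id,
            ref_start=region.ref_start,
            ref_end=region.ref_end,
            provenance="repeat_resolved",
            depth_mean=c.depth_mean,
        )
        for c in contigs
    ]
    return RegionResult(
        region=region,
        contigs=tagged,
        iterations=iterations,
        converged=converged,
        read_ids=current,
    )
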