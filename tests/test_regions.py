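"""Anchor calling, gap-size filtering, and read binning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regap.io_formats import MappedRead, SeqRecord
from regap.regions import (
    Contig,
    PipelineConfig,
    RepeatRegion,
    bin_reads,
    call_anchor_contigs,
    filter_small_contigs,
)


def _random_ref(length, seed=0):
    rng = np.random.default_rng(seed)
    return SeqRecord(
        id="ref", sequence="".join("ACGT"[i] for i in rng.integers(0, 4, length))
    )


def _tile(ref, start, end, read_len=100, step=10):
    """Error-free reads tiling [start, end) as MappedRead records."""
    out = []
    for i, s in enumerate(range(start, end - read_len + 1, step)):
        out.append(
            MappedRead(
                read_id=f"t{start}_{i}",
                ref_id=ref.id,
                ref_start=s,
                ref_end=s + read_len,
                strand="+",
                identity=1.0,
                read_sequence_oriented=ref.sequence[s : s + read_len],
                cigar=f"{read_len}=",
            )
        )
    return out


def test_zero_noise_tiling_yields_reference_consensus():
    """Non-overlapping exact fragments at uniform depth 10 over [0, 1000)
    produce one anchor contig identical to the reference segment."""
    ref = _random_ref(5000)
    mappings = []
    for rep in range(10):
        for s in range(0, 1000, 100):
            mappings.append(
                MappedRead(
                    read_id=f"d{rep}_{s}", ref_id=ref.id, ref_start=s,
                    ref_end=s + 100, strand="+", identity=1.0,
                    read_sequence_oriented=ref.sequence[s : s + 100], cigar="100=",
                )
            )
    contigs = call_anchor_contigs(mappings, ref, min_depth=3)
    assert len(contigs) == 1
    c = contigs[0]
    assert (c.ref_start, c.ref_end) == (0, 1000)
    assert c.sequence == ref.sequence[0:1000]
    assert c.provenance == "anchor"
    assert c.depth_mean == pytest.approx(10.0)


def _full_read(ref, rid, seq):
    return MappedRead(read_id=rid, ref_id=ref.id, ref_start=0, ref_end=len(seq),
                      strand="+", identity=1.0, read_sequence_oriented=seq,
                      cigar=f"{len(seq)}=")


def test_majority_vote_overrides_single_error():
    ref = _random_ref(300)
    good = ref.sequence
    seq = list(good)
    truth_base = seq[100]
    seq[100] = "G" if truth_base != "G" else "A"  # column votes {x, x, y}
    mappings = [
        _full_read(ref, "r1", good),
        _full_read(ref, "r2", good),
        _full_read(ref, "r3", "".join(seq)),
    ]
    (contig,) = call_anchor_contigs(mappings, ref, min_depth=3)
    assert contig.sequence[100] == truth_base
    assert contig.sequence == good


def test_disjoint_coverage_islands_become_two_contigs():
    ref = _random_ref(5000)
    mappings = _tile(ref, 0, 400) + _tile(ref, 600, 1000)
    contigs = call_anchor_contigs(mappings, ref, min_depth=3)
    assert len(contigs) == 2
    assert contigs[0].ref_end <= 600 and contigs[1].ref_start >= 500


def test_empty_mappings_give_no_contigs():
    assert call_anchor_contigs([], _random_ref(1000), 3) == []


def _contig(ref, start, end):
    return Contig(
        id=f"c{start}", sequence=ref.sequence[start:end], ref_id=ref.id,
        ref_start=start, ref_end=end, provenance="anchor",
    )


def test_filter_small_contigs_merges_debris_and_gaps():
    """Layout 2000 / gap 100 / 300 / gap 100 / 1500 with gap_size 500: the
    300-base contig and both flanking gaps merge into one repeat region."""
    ref = _random_ref(4000)
    contigs = [_contig(ref, 0, 2000), _contig(ref, 2100, 2400), _contig(ref, 2500, 4000)]
    anchors, regions = filter_small_contigs(contigs, 4000, 500)
    assert [(a.ref_start, a.ref_end) for a in anchors] == [(0, 2000), (2500, 4000)]
    assert [(r.ref_start, r.ref_end) for r in regions] == [(2000, 2500)]


def test_gap_size_zero_keeps_every_contig():
    ref = _random_ref(4000)
    contigs = [_contig(ref, 0, 2000), _contig(ref, 2100, 2400), _contig(ref, 2500, 4000)]
    anchors, regions = filter_small_contigs(contigs, 4000, 0)
    assert len(anchors) == 3
    assert [(r.ref_start, r.ref_end) for r in regions] == [(2000, 2100), (2400, 2500)]


def test_all_contigs_filtered_gives_one_whole_genome_region():
    ref = _random_ref(4000)
    contigs = [_contig(ref, 100, 300), _contig(ref, 700, 800)]
    anchors, regions = filter_small_contigs(contigs, 4000, 500)
    assert anchors == []
    assert [(r.ref_start, r.ref_end) for r in regions] == [(0, 4000)]


def test_length_equal_to_gap_size_survives():
    ref = _random_ref(2000)
    contigs = [_contig(ref, 0, 500)]
    anchors, _ = filter_small_contigs(contigs, 2000, 500)
    assert len(anchors) == 1


def _mk_read(rid, start, end):
    return MappedRead(read_id=rid, ref_id="ref", ref_start=start, ref_end=end,
                      strand="+", identity=1.0)


def test_bin_reads_interval_intersection():
    region = RepeatRegion(ref_id="ref", ref_start=1000, ref_end=1500)
    mappings = [
        _mk_read("overlapping", 880, 980),   # intersects [900, 1600)
        _mk_read("disjoint", 300, 400),
        _mk_read("inside", 1100, 1200),
    ]
    binned = bin_reads(mappings, region, flank=100)
    assert binned.read_ids == {"overlapping", "inside"}


def test_bin_reads_zero_flank_boundary():
    region = RepeatRegion(ref_id="ref", ref_start=1000, ref_end=1500)
    binned = bin_reads([_mk_read("exact", 1000, 1500)], region, flank=0)
    assert binned.read_ids == {"exact"}
    binned = bin_reads([_mk_read("left", 900, 1000)], region, flank=0)
    assert binned.read_ids == set()


@settings(deadline=None, derandomize=True, max_examples=100)
@given(st.data())
def test_anchors_and_regions_partition_the_reference(data):
    ref_len = data.draw(st.integers(min_value=100, max_value=5000))
    n = data.draw(st.integers(min_value=0, max_value=8))
    bounds = sorted(
        data.draw(
            st.lists(
                st.integers(min_value=0, max_value=ref_len),
                min_size=2 * n, max_size=2 * n, unique=True,
            )
        )
    )
    ref = _random_ref(ref_len, seed=1)
    contigs = [
        _contig(ref, bounds[2 * i], bounds[2 * i + 1])
        for i in range(n)
        if bounds[2 * i] < bounds[2 * i + 1]
    ]
    gap_size = data.draw(st.integers(min_value=0, max_value=ref_len))
    anchors, regions = filter_small_contigs(contigs, ref_len, gap_size)
    pieces = sorted(
        [(a.ref_start, a.ref_end) for a in anchors]
        + [(r.ref_start, r.ref_end) for r in regions]
    )
    pos = 0
    for s, e in pieces:
        assert s == pos and e > s
        pos = e
    assert pos == ref_len


def test_repeat_footprint_monotone_in_gap_size():
    rng = np.random.default_rng(0)
    ref = _random_ref(10_000, seed=2)
    for _ in range(25):
        cuts = np.sort(rng.choice(np.arange(1, 10_000), size=12, replace=False))
        contigs = []
        pos = 0
        for i in range(0, len(cuts) - 1, 2):
            s, e = int(cuts[i]), int(cuts[i + 1])
            if e > s:
                contigs.append(_contig(ref, s, e))
        prev = -1
        for gap_size in (0, 50, 200, 500, 1000, 5000, 10_000):
            _, regions = filter_small_contigs(contigs, 10_000, gap_size)
            footprint = sum(r.ref_end - r.ref_start for r in regions)
            assert footprint >= prev
            prev = footprint
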