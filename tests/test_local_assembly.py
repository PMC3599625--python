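"""Greedy OLC assembly, end-overlap detection, iteration, and polishing."""

import numpy as np
import pytest

from conftest import brute_force_best_overlap
from regap.io_formats import SeqRecord, revcomp
from regap.local_assembly import (
    ReadKmerIndex,
    best_overlap,
    edit_end_overlap,
    greedy_assemble,
    polish_contig,
    resolve_region,
)
from regap.regions import PipelineConfig, RepeatRegion


def _rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def test_best_overlap_spec_example():
    ov = best_overlap("ACGTACGTAA", "GTAATTTT", min_overlap=4, max_mismatch_frac=0.0)
    assert (ov.a_suffix_len, ov.mismatches, ov.orientation) == (4, 0, "++")


def test_best_overlap_identical_sequences_full_length():
    ov = best_overlap("ACGTACGTAA", "ACGTACGTAA", min_overlap=4)
    assert ov.a_suffix_len == 10


def test_best_overlap_random_pairs_none():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a, b = _rand_seq(rng, 1000), _rand_seq(rng, 1000)
        got = best_overlap(a, b, min_overlap=40, max_mismatch_frac=0.0)
        oracle = brute_force_best_overlap(a, b, 40, 0.0)
        assert (got is None) == (oracle is None)


def test_best_overlap_reverse_complement_orientation():
    rng = np.random.default_rng(1)
    a = _rand_seq(rng, 200)
    b = revcomp(a[-60:] + _rand_seq(rng, 140))  # rc(b) starts with a's tail
    ov = best_overlap(a, b, min_overlap=30)
    assert ov.orientation == "+-"
    assert ov.a_suffix_len == 60


def test_best_overlap_matches_brute_force_on_planted_overlaps():
    """Agreement with the all-offsets scanner on pairs with planted
    overlaps of random lengths, mismatch budgets, and orientations."""
    rng = np.random.default_rng(7)
    for trial in range(120):
        olen = int(rng.integers(10, 120))
        frac = float(rng.choice([0.0, 0.02, 0.05, 0.1]))
        a = _rand_seq(rng, int(rng.integers(120, 260)))
        overlap = list(a[-olen:])
        for _ in range(int(frac * olen * rng.random())):
            p = int(rng.integers(0, olen))
            overlap[p] = "ACGT"[int(rng.integers(0, 4))]
        b = "".join(overlap) + _rand_seq(rng, int(rng.integers(20, 200)))
        if rng.random() < 0.5:
            b = revcomp(b)
        got = best_overlap(a, b, min_overlap=10, max_mismatch_frac=frac)
        oracle = brute_force_best_overlap(a, b, 10, frac)
        assert (got is None) == (oracle is None)
        if got is not None:
            assert (got.a_suffix_len, got.mismatches, got.orientation) == oracle


def test_best_overlap_rejects_min_overlap_below_one():
    with pytest.raises(ValueError):
        best_overlap("ACGT", "ACGT", min_overlap=0)


def test_edit_overlap_survives_an_indel():
    rng = np.random.default_rng(3)
    a = _rand_seq(rng, 300)
    shared = a[-150:]
    # successor carries the shared segment with one deletion inside it
    b = shared[:70] + shared[71:] + _rand_seq(rng, 100)
    assert best_overlap(a, b, min_overlap=40, max_mismatch_frac=0.02) is None
    got = edit_end_overlap(a, b, min_overlap=40, max_diff_frac=0.02)
    assert got is not None
    pred_suffix, ed, succ_cut = got
    assert pred_suffix == 150
    assert ed == 1
    assert succ_cut == 149


def test_greedy_reconstructs_tiled_template():
    rng = np.random.default_rng(11)
    template = _rand_seq(rng, 60)
    reads = [
        SeqRecord(id=f"r{i}", sequence=template[s : s + 20])
        for i, s in enumerate(range(0, 41, 10))
    ]
    contigs = greedy_assemble(reads, min_overlap=5)
    assert len(contigs) == 1
    assert contigs[0].sequence in (template, revcomp(template))
    assert contigs[0].provenance == "repeat_resolved"


def test_greedy_single_read_passthrough():
    contigs = greedy_assemble([SeqRecord(id="r", sequence="ACGTACGTACGT")], 5)
    assert len(contigs) == 1
    assert contigs[0].sequence == "ACGTACGTACGT"


def test_greedy_disjoint_templates_stay_separate():
    rng = np.random.default_rng(13)
    t1, t2 = _rand_seq(rng, 80), _rand_seq(rng, 80)
    reads = [
        SeqRecord(id=f"a{i}", sequence=t1[s : s + 30]) for i, s in enumerate((0, 25, 50))
    ] + [
        SeqRecord(id=f"b{i}", sequence=t2[s : s + 30]) for i, s in enumerate((0, 25, 50))
    ]
    contigs = greedy_assemble(reads, min_overlap=5)
    assert len(contigs) == 2


def test_greedy_handles_mixed_orientations():
    rng = np.random.default_rng(17)
    template = _rand_seq(rng, 200)
    reads = []
    for i, s in enumerate(range(0, 151, 25)):
        chunk = template[s : s + 50]
        if i % 2:
            chunk = revcomp(chunk)
        reads.append(SeqRecord(id=f"r{i}", sequence=chunk))
    contigs = greedy_assemble(reads, min_overlap=10)
    assert len(contigs) == 1
    assert contigs[0].sequence in (template, revcomp(template))


def test_greedy_output_not_mutually_contained_and_spans_longest_read():
    rng = np.random.default_rng(19)
    template = _rand_seq(rng, 400)
    starts = sorted(int(rng.integers(0, 320)) for _ in range(25))
    reads = [
        SeqRecord(id=f"r{i}", sequence=template[s : s + int(rng.integers(50, 81))])
        for i, s in enumerate(starts)
    ]
    contigs = greedy_assemble(reads, min_overlap=20)
    longest_read = max(len(r.sequence) for r in reads)
    assert max(len(c) for c in contigs) >= longest_read
    assert sum(len(c) for c in contigs) <= sum(len(r.sequence) for r in reads)
    import edlib

    for i, small in enumerate(contigs):
        for big in contigs:
            if big is small or len(big) < len(small):
                continue
            for q in (small.sequence, revcomp(small.sequence)):
                assert edlib.align(q, big.sequence, mode="HW", k=0)["editDistance"] < 0


def _region_setup(seed=23):
    """A template with reads binned around its centre; store holds all reads."""
    rng = np.random.default_rng(seed)
    template = _rand_seq(rng, 1200)
    reads = {}
    for i, s in enumerate(range(0, 1101, 20)):
        rid = f"r{i:03d}"
        reads[rid] = SeqRecord(id=rid, sequence=template[s : s + 100])
    binned = {rid for rid in reads if 300 <= int(rid[1:]) * 20 <= 700}
    region = RepeatRegion(ref_id="ref", ref_start=300, ref_end=800, read_ids=binned)
    return template, reads, region


def test_resolve_region_max_iters_one_equals_plain_greedy():
    _, reads, region = _region_setup()
    cfg = PipelineConfig(max_iters=1, min_overlap=20, polish=False)
    res = resolve_region(region, reads, cfg=cfg)
    plain = greedy_assemble(
        [reads[r] for r in sorted(region.read_ids)], 20,
        cfg.max_merge_mismatch_frac, cfg.edit_overlaps,
    )
    assert [c.sequence for c in res.contigs] == [c.sequence for c in plain]
    assert res.iterations == 1


def test_resolve_region_recruits_until_fixpoint():
    template, reads, region = _region_setup()
    cfg = PipelineConfig(min_overlap=20, polish=False)
    res = resolve_region(region, reads, cfg=cfg)
    assert res.converged
    assert len(res.contigs) == 1
    # recruitment walked out of the initial bin in both directions
    assert res.contigs[0].sequence in (template, revcomp(template))
    assert len(res.read_ids) == len(reads)


def test_resolve_region_is_deterministic():
    _, reads, region = _region_setup()
    cfg = PipelineConfig(min_overlap=20)
    a = resolve_region(region, reads, cfg=cfg)
    b = resolve_region(region, reads, cfg=cfg)
    assert [c.sequence for c in a.contigs] == [c.sequence for c in b.contigs]
    assert a.read_ids == b.read_ids


def test_resolve_region_empty_bin_is_a_gap():
    region = RepeatRegion(ref_id="ref", ref_start=0, ref_end=100, read_ids=set())
    res = resolve_region(region, {}, cfg=PipelineConfig())
    assert res.contigs == []
    assert res.converged


def test_recruit_pool_restriction_is_respected():
    template, reads, region = _region_setup()
    cfg = PipelineConfig(min_overlap=20, polish=False)
    res = resolve_region(region, reads, cfg=cfg, recruit_pool=set())
    # nothing outside the bin may be recruited
    assert res.read_ids == {rid for rid in region.read_ids if rid in reads}


def test_polish_repairs_planted_errors():
    rng = np.random.default_rng(29)
    template = _rand_seq(rng, 600)
    corrupt = list(template)
    corrupt[100] = "A" if template[100] != "A" else "C"  # substitution
    del corrupt[300]                                     # deletion
    corrupt.insert(450, "G")                             # insertion
    reads = [
        SeqRecord(id=f"r{i}", sequence=template[s : s + 120])
        for i, s in enumerate(range(0, 481, 40))
    ]
    polished = polish_contig("".join(corrupt), reads)
    assert polished == template


def test_read_kmer_index_finds_overlapping_reads():
    rng = np.random.default_rng(31)
    template = _rand_seq(rng, 500)
    reads = [
        SeqRecord(id=f"r{i}", sequence=template[s : s + 100])
        for i, s in enumerate(range(0, 401, 50))
    ]
    idx = ReadKmerIndex(reads)
    hits = idx.candidates(template[180:300])
    assert {"r2", "r3", "r4"} <= hits
    assert idx.candidates(_rand_seq(rng, 120)) == set()
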