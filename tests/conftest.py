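"""Shared fixtures and small independent oracles for the test suite."""

from __future__ import annotations

import re

import edlib
import pytest

from regap.io_formats import revcomp

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def cigar_identity(cigar: str) -> float:
    cols = sum(int(n) for n, _ in _CIGAR_RE.findall(cigar))
    match = sum(int(n) for n, op in _CIGAR_RE.findall(cigar) if op == "=")
    return match / cols


def global_identity(seq: str, genome: str) -> float:
    """Match fraction of the full global alignment, best of both orientations."""
    best = 0.0
    for q in (seq, revcomp(seq)):
        res = edlib.align(q, genome, mode="NW", task="path")
        best = max(best, cigar_identity(res["cigar"]))
    return best


def brute_force_best_overlap(a: str, b: str, min_overlap: int, frac: float):
    """All-offsets scanner for the longest suffix(a)/prefix(b) overlap.

    Independent re-implementation of the overlap definition: for each
    candidate length (longest first) compare the slices directly, in b
    and then revcomp(b); forward orientation wins ties.
    """
    for olen in range(min(len(a), len(b)), min_overlap - 1, -1):
        for orient, bb in (("++", b), ("+-", revcomp(b))):
            mism = sum(
                1 for x, y in zip(a[len(a) - olen:], bb[:olen]) if x != y or x == "N"
            )
            if mism <= frac * olen:
                return olen, mism, orient
    return None


def brute_force_ngx(lengths, genome_size, x):
    ordered = sorted(lengths)[::-1]
    total = 0.0
    for i, l in enumerate(ordered):
        total += l
        if total >= genome_size * x / 100.0:
            return l, i + 1
    return None, None


@pytest.fixture(scope="session")
def repeat_truth():
    """The planted-repeat study genome: 100 kb with a dispersed family
    (2 kb unit, 3 copies) and a 3 kb-arm inverted repeat."""
    from regap.simulate import RepeatSpec, make_genome

    return make_genome(
        100_000,
        [RepeatSpec("dispersed", 2000, 3), RepeatSpec("inverted", 3000, 2)],
        seed=1,
    )


@pytest.fixture(scope="session")
def zero_noise_run(repeat_truth):
    """Full pipeline on 15x zero-noise 400-base reads from the repeat genome."""
    import copy

    from regap import PipelineConfig, run_pipeline
    from regap.simulate import ReadSimConfig, simulate_reads

    truth = copy.deepcopy(repeat_truth)
    reads = simulate_reads(
        truth, ReadSimConfig(coverage=15, len_sd=0, seed=2).zero_noise()
    )
    result = run_pipeline(reads, truth.genome, PipelineConfig())
    return truth, reads, result


@pytest.fixture(scope="session")
def noisy_run(repeat_truth):
    """Full pipeline on 20x default-error-model reads from the repeat genome."""
    import copy

    from regap import PipelineConfig, run_pipeline
    from regap.simulate import ReadSimConfig, simulate_reads

    truth = copy.deepcopy(repeat_truth)
    reads = simulate_reads(truth, ReadSimConfig(coverage=20, len_sd=0, seed=3))
    result = run_pipeline(reads, truth.genome, PipelineConfig())
    return truth, reads, result
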