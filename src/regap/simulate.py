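"""Synthetic re-sequencing data: planted-repeat genomes and pyrosequencing-like reads.

The generator emulates the situation the pipeline exists for: a known
genome that contains repeats longer than the read length — dispersed
copies, tandem arrays, or the large inverted repeat typical of
chloroplast genomes — re-sequenced with single-end 454/IonTorrent-style
reads (a few hundred bases, errors dominated by indels inside
homopolymer runs).  Everything is seeded and deterministic, and the
ground truth (repeat intervals, per-read origins) is recorded so that
mapping and assembly stages can be validated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io_formats import SeqRecord, revcomp

__all__ = ["RepeatSpec", "ReadSimConfig", "SimTruth", "make_genome", "simulate_reads"]

_BASES = "ACGT"

# minimum distance kept between planted repeat copies and from genome
# ends, so that each copy has its own unique flanking context
_PLACEMENT_MARGIN = 1000


@dataclass(frozen=True)
class RepeatSpec:
    """One repeat family to plant into the background sequence.

    kind
        ``dispersed`` — identical-unit copies at separated loci;
        ``tandem`` — copies laid head-to-tail at a single locus;
        ``inverted`` — two arms, the second the reverse complement of
        the first (copies must be 2).
    unit_length
        length of one copy/arm in bases.
    copies
        number of copies (>= 2).
    per_copy_divergence
        per-base substitution fraction applied independently to each
        copy; 0 plants byte-identical copies.
    """

    kind: str
    unit_length: int
    copies: int
    per_copy_divergence: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("dispersed", "tandem", "inverted"):
            raise ValueError(f"unknown repeat kind {self.kind!r}")
        if self.unit_length < 1:
            raise ValueError("unit_length must be >= 1")
        if self.copies < 2:
            raise ValueError("copies must be >= 2")
        if self.kind == "inverted" and self.copies != 2:
            raise ValueError("an inverted repeat has exactly 2 copies")
        if not (0.0 <= self.per_copy_divergence <= 0.05):
            raise ValueError("per_copy_divergence must be in [0, 0.05]")

    @property
    def footprint(self) -> int:
        return self.unit_length * self.copies


@dataclass(frozen=True)
class ReadSimConfig:
    """Single-end pyrosequencing read model.

    Read lengths are truncated-normal (minimum 30 bases).  Errors are
    applied per base: substitutions at ``sub_rate``; insertions and
    deletions at ``ins_rate``/``del_rate``, multiplied by
    ``homopolymer_indel_multiplier`` inside homopolymer runs of length
    >= 3 — the defining error mode of flow-based chemistries.  The
    defaults model a 454-like run at 400 bp.
    """

    coverage: float
    mean_len: int = 400
    len_sd: int = 40
    sub_rate: float = 0.001
    ins_rate: float = 0.005
    del_rate: float = 0.005
    homopolymer_indel_multiplier: float = 3.0
    seed: int = 0
    circular: bool = False

    def __post_init__(self) -> None:
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        for name in ("sub_rate", "ins_rate", "del_rate"):
            r = getattr(self, name)
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.homopolymer_indel_multiplier < 1.0:
            raise ValueError("homopolymer_indel_multiplier must be >= 1")
        if self.mean_len < 30:
            raise ValueError("mean_len must be >= 30")

    def zero_noise(self) -> "ReadSimConfig":
        """A copy of this config with all error rates set to zero."""
        return replace(self, sub_rate=0.0, ins_rate=0.0, del_rate=0.0)


@dataclass
class SimTruth:
    """A simulated genome plus everything needed to check results against it.

    ``repeat_intervals`` holds 0-based half-open ``(start, end, family)``
    tuples; all copies of one family share the family label.
    ``read_origins`` maps read id to ``(start, strand)`` of the error-free
    template the read was drawn from.
    """

    genome: SeqRecord
    repeat_intervals: list[tuple[int, int, str]] = field(default_factory=list)
    read_origins: dict[str, tuple[int, str]] = field(default_factory=dict)

    def repeat_bed(self) -> list[tuple[str, int, int, str]]:
        return [(self.genome.id, s, e, name) for s, e, name in self.repeat_intervals]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, length))


def _diverge(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hit:
        choices = [b for b in b"ACGT" if b != codes[i]]
        codes[i] = choices[rng.integers(0, 3)]
    return codes.tobytes().decode()


def _place_intervals(
    rng: np.random.Generator,
    length: int,
    sizes: Sequence[int],
    occupied: list[tuple[int, int]],
    max_attempts: int = 10_000,
) -> list[int]:
    """Pick non-overlapping start positions, margin-separated, by rejection."""
    starts = []
    for size in sizes:
        lo, hi = _PLACEMENT_MARGIN, length - size - _PLACEMENT_MARGIN
        if hi < lo:
            raise ValueError(
                f"repeat of {size} bases does not fit a genome of {length} bases"
            )
        for _ in range(max_attempts):
            s = int(rng.integers(lo, hi + 1))
            e = s + size
            if all(
                e + _PLACEMENT_MARGIN <= os or s >= oe + _PLACEMENT_MARGIN
                for os, oe in occupied
            ):
                occupied.append((s, e))
                starts.append(s)
                break
        else:
            raise ValueError(
                "could not place repeat copies without overlap; "
                "reduce the repeat footprint or enlarge the genome"
            )
    return starts


def make_genome(
    length: int,
    repeats: Sequence[RepeatSpec] = (),
    seed: int = 0,
    genome_id: str = "genome",
) -> SimTruth:
    """Build a random genome with planted repeat families.

    The background is i.i.d. uniform ACGT; each family's unit sequence
    is drawn once and its copies are written over the background at
    non-overlapping, margin-separated positions.  Deterministic for a
    fixed argument tuple.
    """
    if length < 1000:
        raise ValueError("genome length must be >= 1000")
    total = sum(r.footprint for r in repeats)
    if total >= length:
        raise ValueError(
            f"repeat footprint {total} does not fit in genome of length {length}"
        )
    rng = np.random.default_rng(seed)
    genome = list(_random_seq(rng, length))
    intervals: list[tuple[int, int, str]] = []
    occupied: list[tuple[int, int]] = []
    for fam_idx, spec in enumerate(repeats):
        family = f"{spec.kind}{fam_idx}"
        unit = _random_seq(rng, spec.unit_length)
        if spec.kind == "tandem":
            copies = [
                _diverge(rng, unit, spec.per_copy_divergence)
                for _ in range(spec.copies)
            ]
            block = "".join(copies)
            (start,) = _place_intervals(rng, length, [len(block)], occupied)
            genome[start : start + len(block)] = block
            for c in range(spec.copies):
                s = start + c * spec.unit_length
                intervals.append((s, s + spec.unit_length, family))
        else:
            seqs = []
            for c in range(spec.copies):
                s = unit if not (spec.kind == "inverted" and c == 1) else revcomp(unit)
                seqs.append(_diverge(rng, s, spec.per_copy_divergence))
            starts = _place_intervals(
                rng, length, [spec.unit_length] * spec.copies, occupied
            )
            for s, seq in zip(starts, seqs):
                genome[s : s + spec.unit_length] = seq
                intervals.append((s, s + spec.unit_length, family))
    intervals.sort()
    return SimTruth(
        genome=SeqRecord(id=genome_id, sequence="".join(genome)),
        repeat_intervals=intervals,
    )


def _run_lengths(seq: str) -> np.ndarray:
    """Length of the homopolymer run containing each position."""
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(codes)
    out = np.empty(n, dtype=np.int32)
    i = 0
    while i < n:
        j = i + 1
        while j < n and codes[j] == codes[i]:
            j += 1
        out[i:j] = j - i
        i = j
    return out


def _apply_errors(template: str, cfg: ReadSimConfig, rng: np.random.Generator) -> str:
    n = len(template)
    runs = _run_lengths(template)
    mult = np.where(runs >= 3, cfg.homopolymer_indel_multiplier, 1.0)
    p_ins = np.minimum(cfg.ins_rate * mult, 0.9)
    p_del = np.minimum(cfg.del_rate * mult, 0.9)
    sub_hit = rng.random(n) < cfg.sub_rate
    ins_hit = rng.random(n) < p_ins
    del_hit = rng.random(n) < p_del
    if not (sub_hit.any() or ins_hit.any() or del_hit.any()):
        return template
    out: list[str] = []
    for i, base in enumerate(template):
        if ins_hit[i]:
            out.append(_BASES[rng.integers(0, 4)])
        if del_hit[i]:
            continue
        if sub_hit[i]:
            choices = [b for b in _BASES if b != base]
            out.append(choices[rng.integers(0, 3)])
        else:
            out.append(base)
    return "".join(out) if out else template[:1]


def simulate_reads(
    truth: SimTruth, cfg: ReadSimConfig, id_prefix: str = "read"
) -> list[SeqRecord]:
    """Sample reads from a simulated genome and record their origins.

    The read count is ``round(coverage * genome_length / mean_len)``.
    Start positions are uniform over valid windows, strands uniform,
    lengths truncated-normal (minimum 30).  With ``cfg.circular`` the
    genome is treated as circular by letting reads run across the
    origin.  Origins (template start on the forward strand, strand) are
    written into ``truth.read_origins``.  Coverage 0 yields no reads.
    """
    rng = np.random.default_rng(cfg.seed)
    genome = truth.genome.sequence
    L = len(genome)
    n = round(cfg.coverage * L / cfg.mean_len)
    source = genome + genome[: cfg.mean_len + 4 * cfg.len_sd] if cfg.circular else genome
    reads: list[SeqRecord] = []
    for i in range(n):
        rlen = int(round(rng.normal(cfg.mean_len, cfg.len_sd))) if cfg.len_sd else cfg.mean_len
        rlen = max(30, min(rlen, L))
        start = int(rng.integers(0, L if cfg.circular else L - rlen + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        template = source[start : start + rlen]
        if strand == "-":
            template = revcomp(template)
        seq = _apply_errors(template, cfg, rng)
        rid = f"{id_prefix}{i:06d}"
        reads.append(SeqRecord(id=rid, sequence=seq))
        truth.read_origins[rid] = (start, strand)
    return reads
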