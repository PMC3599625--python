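"""Numba kernels and base-encoding helpers shared across modules.

Sequences are encoded as uint8 codes: A=0, C=1, G=2, T=3, N=4.  The
overlap kernel implements substitution-only suffix/prefix matching with
an early-exit mismatch budget, which keeps all-pairs overlap detection
fast enough for pure-Python greedy assembly at desk scale.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[_b + 32] = _i  # lowercase

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

# complement of code i; N -> N
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode an ACGTN string into uint8 codes."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


@njit(cache=False)
def longest_suffix_prefix(a: np.ndarray, b: np.ndarray, min_overlap: int,
                          max_mismatch_frac: float) -> tuple[int, int]:
    """Longest suffix(a)/prefix(b) overlap allowing substitutions only.

    Scans overlap lengths from the longest possible downwards and
    returns ``(olen, mismatches)`` for the first (= longest) overlap
    whose mismatch count satisfies ``mismatches <= max_mismatch_frac *
    olen``.  Returns ``(0, -1)`` when no overlap of length >=
    ``min_overlap`` qualifies.  N never matches anything, including N.
    """
    la = a.size
    lb = b.size
    max_olen = la if la < lb else lb
    for olen in range(max_olen, min_overlap - 1, -1):
        allowed = int(max_mismatch_frac * olen)
        off = la - olen
        mism = 0
        ok = True
        for i in range(olen):
            ca = a[off + i]
            cb = b[i]
            if ca != cb or ca == 4:
                mism += 1
                if mism > allowed:
                    ok = False
                    break
        if ok:
            return olen, mism
    return 0, -1


@njit(cache=False)
def add_interval_depth(depth: np.ndarray, starts: np.ndarray,
                       ends: np.ndarray) -> None:
    """Accumulate +1/-1 boundary markers for interval pileup depth."""
    for i in range(starts.size):
        depth[starts[i]] += 1
        depth[ends[i]] -= 1
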