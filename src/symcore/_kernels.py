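"""Numba kernels for the batch similarity search.

These are scoring-only fast paths; tracebacks (identity, coverage) always go
through the exact aligner in :mod:`symcore.similarity`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10 ** 9)

_ENCODE_LUT = np.full(256, 4, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ENCODE_LUT[ord(_c)] = _i
    _ENCODE_LUT[ord(_c.lower())] = _i

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 (A=0, C=1, G=2, T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def revcomp_encoded(arr: np.ndarray) -> np.ndarray:
    out = arr[::-1].copy()
    mask = out < 4
    out[mask] = 3 - out[mask]
    return out


@njit(cache=True)
def sw_score(a, b, match, mismatch, gap_open, gap_extend):
    """Smith-Waterman score with affine gaps (gap of length L costs open + L*extend).

    Code 4 (any non-ACGT letter) mismatches everything, including itself.
    """
    n = a.shape[0]
    m = b.shape[0]
    H = np.zeros(m + 1, dtype=np.int64)
    E = np.full(m + 1, NEG, dtype=np.int64)
    first = gap_open + gap_extend
    best = 0
    for i in range(1, n + 1):
        diag = 0
        F = NEG
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = E[j] - gap_extend
            eo = H[j] - first
            if eo > e:
                e = eo
            E[j] = e
            f = F - gap_extend
            fo = H[j - 1] - first
            if fo > f:
                f = fo
            F = f
            s = mismatch
            if ai == b[j - 1] and ai < 4:
                s = match
            h = diag + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def ungapped_diag_best(a, b, diags, match, mismatch):
    """Best ungapped-segment score over the given diagonals (diag = j - i).

    Kadane scan along each diagonal; used as a BLAST-like extension gate
    between k-mer seeding and the full affine-gap rescoring pass.
    """
    best = 0
    for d0 in range(diags.shape[0]):
        d = diags[d0]
        if d >= 0:
            i0 = 0
            j0 = d
        else:
            i0 = -d
            j0 = 0
        L = min(a.shape[0] - i0, b.shape[0] - j0)
        sc = 0
        mx = 0
        for t in range(L):
            s = mismatch
            if a[i0 + t] == b[j0 + t] and a[i0 + t] < 4:
                s = match
            sc += s
            if sc < 0:
                sc = 0
            elif sc > mx:
                mx = sc
        if mx > best:
            best = mx
    return best
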