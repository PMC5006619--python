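"""Affine-gap local alignment (Gotoh) and sequence utilities.

The forward pass is score-only with O(min(n,m)) memory; the start of the
optimal local alignment is recovered by re-running the same recursion on
the reversed prefixes ending at the optimum.  Gap scoring convention: a
gap of length L scores ``gap_open + (L - 1) * gap_extend`` (the opening
score covers the first gap column), matching Biopython's
``PairwiseAligner`` semantics so the two implementations are directly
comparable.
"""
from __future__ import annotations

from typing import Tuple

import numpy as np
from numba import njit

_COMP = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")

NEG_INF = np.int64(-(10**15))


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    lut = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
        lut[ord(chr(b).lower())] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


@njit(cache=True)
def _sw_end(a, b, match, mismatch, gap_open, gap_extend):
    """Best local score and its end position (score-only, rolling rows).

    Returns (score, end_i, end_j) where the alignment consumes
    a[:end_i] x b[:end_j] suffixes; ties resolved toward the smallest
    (end_i, end_j) in row-major order.
    """
    n, m = len(a), len(b)
    H = np.zeros(m + 1, dtype=np.int64)
    F = np.full(m + 1, NEG_INF, dtype=np.int64)  # gap consuming a (vertical)
    best = np.int64(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        diag = H[0]  # H[i-1][0] == 0
        H[0] = 0
        e = NEG_INF  # gap consuming b (horizontal, runs along j)
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = max(H[j - 1] + gap_open, e + gap_extend)
            f = max(H[j] + gap_open, F[j] + gap_extend)
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            h = diag + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            F[j] = f
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def _nw_prefix_best(a, b, match, mismatch, gap_open, gap_extend):
    """Best score over alignments anchored at (0,0) (free end), with end pos.

    Used on reversed suffix-clipped sequences to locate the local
    alignment start: the best semi-anchored score on the reversed
    sequences equals the local optimum and its end marks the start.
    """
    n, m = len(a), len(b)
    H = np.full(m + 1, NEG_INF, dtype=np.int64)
    F = np.full(m + 1, NEG_INF, dtype=np.int64)
    H[0] = 0
    best = np.int64(-(10**15))
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        diag = H[0]
        H[0] = NEG_INF
        e = NEG_INF
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = max(H[j - 1] + gap_open, e + gap_extend)
            f = max(H[j] + gap_open, F[j] + gap_extend)
            s = match if (ai == b[j - 1] and ai < 4) else mismatch
            h = diag + s
            if e > h:
                h = e
            if f > h:
                h = f
            diag = H[j]
            H[j] = h
            F[j] = f
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj


class AlignmentParams:
    """Scoring scheme for the DNA scanner (BLASTN-like defaults)."""

    def __init__(self, match: int = 1, mismatch: int = -1,
                 gap_open: int = -5, gap_extend: int = -1):
        if mismatch >= 0 or gap_open >= 0 or gap_extend >= 0:
            raise ValueError("mismatch and gap penalties must be negative")
        self.match = match
        self.mismatch = mismatch
        self.gap_open = gap_open
        self.gap_extend = gap_extend


def local_align(a: np.ndarray, b: np.ndarray, params: AlignmentParams
                ) -> Tuple[int, Tuple[int, int], Tuple[int, int]]:
    """Optimal local alignment of encoded sequences a vs b.

    Returns (score, (a_start, a_end), (b_start, b_end)); spans are
    0-based half-open.  Score 0 means no positive-scoring alignment.
    """
    score, ei, ej = _sw_end(a, b, params.match, params.mismatch,
                            params.gap_open, params.gap_extend)
    if score <= 0:
        return 0, (0, 0), (0, 0)
    ra = a[:ei][::-1].copy()
    rb = b[:ej][::-1].copy()
    back, bi, bj = _nw_prefix_best(ra, rb, params.match, params.mismatch,
                                   params.gap_open, params.gap_extend)
    # back == score by construction
    return int(score), (ei - bi, ei), (ej - bj, ej)


def identity_from_cigar(a_seq: str, b_seq: str, cigar: str) -> float:
    """Fraction of aligned columns that match, walking an edlib cigar."""
    i = j = 0
    matches = 0
    cols = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        L = int(num)
        num = ""
        if ch in "=M":
            for k in range(L):
                if a_seq[i + k] == b_seq[j + k]:
                    matches += 1
            i += L
            j += L
            cols += L
        elif ch == "X":
            i += L
            j += L
            cols += L
        elif ch == "I":  # edlib: insertion to target == consume query
            i += L
            cols += L
        elif ch == "D":
            j += L
            cols += L
    return matches / cols if cols else 0.0
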