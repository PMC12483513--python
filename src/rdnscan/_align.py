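"""Semiglobal ("glocal") alignment kernel.

Aligns a full read against any window of a reference gene: global in the
read, free end-gaps on the gene.  Scoring is match +1 / mismatch -1 /
gap -2 (linear).  The traceback prefers diagonal over read-gap over
gene-gap moves, and the best end column ties break to the leftmost — both
choices are deterministic and exercised by the pure-Python oracle in the
test suite.

Bases are encoded A=0 C=1 G=2 T=3; any other code is 4 and mismatches
everything (including itself).
"""
from __future__ import annotations

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -1
GAP = -2

_ENCODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENCODE[b] = i
for i, b in enumerate(b"acgt"):
    _ENCODE[b] = i


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def revcomp_encoded(arr: np.ndarray) -> np.ndarray:
    out = arr[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


@njit(cache=True)
def glocal_align(read: np.ndarray, gene: np.ndarray):
    """Best semiglobal alignment; returns (score, matches, columns, ref_start, ref_end)."""
    L1, L2 = read.size, gene.size
    dp = np.empty((L1 + 1, L2 + 1), dtype=np.int32)
    for j in range(L2 + 1):
        dp[0, j] = 0
    for i in range(1, L1 + 1):
        dp[i, 0] = GAP * i
        ri = read[i - 1]
        row = dp[i]
        prev = dp[i - 1]
        for j in range(1, L2 + 1):
            s = MATCH if (ri == gene[j - 1] and ri < 4) else MISMATCH
            best = prev[j - 1] + s
            up = prev[j] + GAP
            if up > best:
                best = up
            left = row[j - 1] + GAP
            if left > best:
                best = left
            row[j] = best
    jend = 0
    score = dp[L1, 0]
    for j in range(1, L2 + 1):
        if dp[L1, j] > score:
            score = dp[L1, j]
            jend = j
    i, j = L1, jend
    matches = 0
    cols = 0
    while i > 0:
        ri = read[i - 1]
        if j > 0:
            is_match = ri == gene[j - 1] and ri < 4
            s = MATCH if is_match else MISMATCH
            if dp[i, j] == dp[i - 1, j - 1] + s:
                if is_match:
                    matches += 1
                i -= 1
                j -= 1
                cols += 1
                continue
        if dp[i, j] == dp[i - 1, j] + GAP:
            i -= 1
            cols += 1
            continue
        j -= 1
        cols += 1
    return score, matches, cols, j, jend
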