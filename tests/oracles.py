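"""Independent reference implementations used only to check the package.

These deliberately use different algorithmic formulations from the package
code (prefix-scan DP instead of cell recurrences, plain set arithmetic for
containment, Gotoh scoring for the affine global aligner) so agreement is
meaningful.
"""
from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------------------
# Semiglobal alignment score (read global, reference free end-gaps),
# match +1 / mismatch -1 / gap -2 — via a per-row prefix-scan formulation.
# ---------------------------------------------------------------------------

def glocal_score(read: str, gene: str) -> int:
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    g = np.frombuffer(gene.encode(), dtype=np.uint8)
    L2 = g.size
    offsets = 2 * np.arange(L2 + 1, dtype=np.int64)
    prev = np.zeros(L2 + 1, dtype=np.int64)
    for i in range(1, r.size + 1):
        sub = np.where(g == r[i - 1], 1, -1)
        cand = np.maximum(prev[:-1] + sub, prev[1:] - 2)
        vals = np.concatenate(([-2 * i], cand))
        cur = np.maximum.accumulate(vals + offsets) - offsets
        prev = cur
    return int(prev.max())


def glocal_score_bothstrands(read: str, gene: str) -> int:
    rc = read.translate(_COMP)[::-1]
    return max(glocal_score(read, gene), glocal_score(rc, gene))


# ---------------------------------------------------------------------------
# Exact k-mer set containment by brute force.
# ---------------------------------------------------------------------------

def kmer_set(seq: str, k: int) -> set[str]:
    seq = seq.upper()
    out = set()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if any(c not in "ACGT" for c in w):
            continue
        rc = w.translate(_COMP)[::-1]
        out.add(w if w <= rc else rc)
    return out


def exact_containment(query: str, subject: str, k: int) -> float:
    q = kmer_set(query, k)
    s = kmer_set(subject, k)
    return len(q & s) / len(q)


# ---------------------------------------------------------------------------
# Affine global alignment score (Gotoh) for the triad-mapping check.
# ---------------------------------------------------------------------------

def gotoh_global_score(a: str, b: str, match: float = 2.0, mismatch: float = -1.0,
                       gap_open: float = -10.0, gap_extend: float = -0.5) -> float:
    n, m = len(a), len(b)
    NEG = -1e12
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (consumes b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    return float(max(M[n, m], X[n, m], Y[n, m]))


def gapless_score(a: str, b: str, match: float = 2.0, mismatch: float = -1.0) -> float:
    assert len(a) == len(b)
    return float(sum(match if x == y else mismatch for x, y in zip(a, b)))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
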