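"""Independent brute-force oracles used by the test suite.

Each function re-implements an operation by direct enumeration or a
closed form, deliberately sharing no code with the library paths it
checks.
"""

from __future__ import annotations

import math
import re
from fractions import Fraction

import numpy as np

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A", "N": "N"}


# --------------------------------------------------------------------------
# preprocessing


def naive_trim(sequence: str, adapter: str, min_overlap: int = 6) -> tuple[str, str | None]:
    """Regex-based leftmost adapter search allowing <= 1 mismatch."""
    best = None
    for i in range(len(sequence) - min_overlap + 1):
        overlap = min(len(adapter), len(sequence) - i)
        frag = sequence[i : i + overlap]
        mism = sum(1 for a, b in zip(frag, adapter[:overlap]) if a != b)
        if mism <= 1:
            best = i
            break
    if best is None:
        return sequence, None
    if best == 0:
        return "", "adapter_only"
    return sequence[:best], None


def naive_classify(sequence: str, quality, adapter: str,
                   min_len=18, max_len=25, max_n=0.10, min_q=20.0,
                   min_overlap=6) -> str:
    insert, label = naive_trim(sequence, adapter, min_overlap)
    if label:
        return label
    if len(insert) < min_len:
        return "too_short"
    if len(insert) > max_len:
        return "too_long"
    if len(re.findall("N", insert.upper())) / len(insert) > max_n:
        return "junk"
    if quality is not None and sum(quality[: len(insert)]) / len(insert) < min_q:
        return "low_quality"
    return "valid"


def revcomp(seq: str) -> str:
    return "".join(COMP[c] for c in reversed(seq))


# --------------------------------------------------------------------------
# duplex scoring


def _pair_penalty(m: str, t: str) -> float:
    if COMP.get(m) == t and m != "N":
        return 0.0
    if (m, t) in (("G", "T"), ("T", "G"), ("G", "U"), ("U", "G")):
        return 0.5
    return 1.0


def brute_force_duplex(mirna: str, site: str, max_gaps: int = 1,
                       seed_start: int = 2, seed_end: int = 13) -> float:
    """Enumerate all monotone alignments with <= max_gaps single-nt gaps."""
    M, S = len(mirna), len(site)
    tsite = site[::-1]  # pair miRNA position i with the i-th nt from the site 3' end
    best = [math.inf]

    def w(i):
        return 2.0 if seed_start <= i <= seed_end else 1.0

    def rec(i, j, gaps, cost):
        if cost >= best[0]:
            return
        if i == M and j == S:
            best[0] = cost
            return
        if i < M and j < S:
            rec(i + 1, j + 1, gaps, cost + _pair_penalty(mirna[i], tsite[j]) * w(i + 1))
        if gaps < max_gaps:
            if i < M:  # miRNA bulge
                rec(i + 1, j, gaps + 1, cost + 1.0 * w(i + 1))
            if j < S:  # site bulge
                rec(i, j + 1, gaps + 1, cost + 1.0 * w(i + 1))
    rec(0, 0, 0, 0.0)
    return best[0]


# --------------------------------------------------------------------------
# degradome categories


def category_oracle(position: int, profile) -> int | None:
    """Literal transcription of the category rules; None = no evidence."""
    profile = list(profile)
    c = profile[position - 1]
    if c <= 0:
        return None
    if c == 1:
        return 4
    nonzero = sorted(x for x in profile if x > 0)
    mx = nonzero[-1]
    if c == mx:
        return 0 if nonzero.count(mx) == 1 else 1
    n = len(nonzero)
    med = (nonzero[(n - 1) // 2] + nonzero[n // 2]) / 2
    return 2 if c > med else 3


# --------------------------------------------------------------------------
# network


def tom_triple_loop(adjacency: np.ndarray) -> np.ndarray:
    """Literal TOM formula with explicit loops."""
    A = adjacency.copy().astype(float)
    n = len(A)
    for i in range(n):
        A[i, i] = 0.0
    k = [sum(A[i]) for i in range(n)]
    T = np.zeros_like(A)
    for i in range(n):
        for j in range(n):
            if i == j:
                T[i, j] = 1.0
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1.0 - A[i, j])
    return T


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Exact upper-tail P(X >= k) by rational-arithmetic summation."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for x in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, x) * math.comb(N - K, n - x), denom)
    return float(total)


def adjusted_rand_index(a, b) -> float:
    """ARI from the contingency table (closed form)."""
    a = list(a)
    b = list(b)
    la, lb = sorted(set(a)), sorted(set(b))
    table = np.zeros((len(la), len(lb)), dtype=int)
    for x, y in zip(a, b):
        table[la.index(x), lb.index(y)] += 1
    n = len(a)
    sum_comb = sum(math.comb(int(v), 2) for v in table.flatten())
    sum_a = sum(math.comb(int(v), 2) for v in table.sum(axis=1))
    sum_b = sum(math.comb(int(v), 2) for v in table.sum(axis=0))
    expected = sum_a * sum_b / math.comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_comb - expected) / (max_index - expected)
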