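"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (direct enumeration, quadratic
scans) and shares no code with the package internals.
"""
from __future__ import annotations

from math import comb

import numpy as np


def brute_peaks(x, strand: str, rel_height: float = 0.75):
    """Enumerate strict (plateau) local maxima with topographic
    prominence and rel_height extents, straight from the definitions."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    out = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and x[j + 1] < x[i]:
                h = x[i]
                # left minimum up to the nearest strictly taller sample
                lmin = h
                k = i - 1
                while k >= 0 and x[k] <= h:
                    lmin = min(lmin, x[k])
                    k -= 1
                rmin = h
                k = j + 1
                while k < n and x[k] <= h:
                    rmin = min(rmin, x[k])
                    k += 1
                prom = h - max(lmin, rmin)
                th = h - rel_height * prom
                # crossing convention: walk while strictly above the
                # reference height; a sample exactly at it is the boundary
                # and is included, anything beyond is not
                left = i
                while left - 1 >= 0 and x[left - 1] > th:
                    left -= 1
                if left - 1 >= 0 and x[left - 1] == th:
                    left -= 1
                right = j
                while right + 1 < n and x[right + 1] > th:
                    right += 1
                if right + 1 < n and x[right + 1] == th:
                    right += 1
                apex = j if strand == "+" else i
                out.append(
                    dict(apex=apex, left=left, right=right + 1, height=h, prominence=prom)
                )
            i = j + 1
        else:
            i += 1
    return out


def fisher_greater_enum(bcm_ds: int, bcm_us: int, unt_ds: int, unt_us: int) -> float:
    """One-sided Fisher p by exhaustive enumeration over the
    hypergeometric support of tables with the observed margins."""
    a, b, c, d = bcm_ds, bcm_us, unt_ds, unt_us
    row1, row2, col1 = a + b, c + d, a + c
    hi = min(row1, col1)
    num = sum(comb(row1, x) * comb(row2, col1 - x) for x in range(a, hi + 1))
    den = comb(row1 + row2, col1)
    return num / den


def hypergeom_upper_enum(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n) by direct summation."""
    if k == 0:
        return 1.0
    hi = min(n, K)
    num = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, hi + 1))
    return num / comb(N, n)


def window_sum(counts, lo: int, hi: int, circular: bool) -> float:
    """Sum of counts over [lo, hi) by per-position iteration."""
    counts = np.asarray(counts, dtype=float)
    L = len(counts)
    total = 0.0
    for i in range(lo, hi):
        if circular:
            total += counts[i % L]
        elif 0 <= i < L:
            total += counts[i]
    return total


def count_within_allpairs(list_a, list_b, d: int, strand_matched: bool = True) -> int:
    """Quadratic all-pairs version of the overlap count."""
    k = 0
    for a in list_a:
        for b in list_b:
            if a.chromosome != b.chromosome:
                continue
            if strand_matched and a.strand != b.strand:
                continue
            if abs(a.position - b.position) <= d:
                k += 1
                break
    return k
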