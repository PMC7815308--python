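"""Overlap statistics between stranded genomic coordinate lists.

Two coordinate lists are compared at a distance threshold d: the count
k of list-A positions within d of a list-B position is assessed
against the genomic footprint K of list B (the number of stranded
positions within d of any B coordinate) with an upper-tail
hypergeometric test over a population of N = 2L stranded positions
(the genome is doubled to account for the two possible orientations).
The comparison is deliberately non-commutative: several A coordinates
may sit near one B coordinate, so both directions are reported.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .genome_io import GenomeSequence, GenomicPosition


@dataclasses.dataclass
class OverlapResult:
    k: int            # A coordinates within d of a B coordinate
    n: int            # size of list A
    K: int            # stranded genomic footprint of list B at threshold d
    N: int            # population: 2 x genome length (L if unstranded)
    p_value: float
    d: int = 0
    strand_matched: bool = True


def count_within(
    list_a: Sequence[GenomicPosition],
    list_b: Sequence[GenomicPosition],
    d: int,
    strand_matched: bool = True,
) -> int:
    """Number of A coordinates within distance d of any B coordinate."""
    groups: dict[tuple, np.ndarray] = {}
    for b in list_b:
        key = (b.chromosome, b.strand) if strand_matched else (b.chromosome,)
        groups.setdefault(key, []).append(b.position)  # type: ignore[arg-type]
    groups = {k: np.sort(np.asarray(v)) for k, v in groups.items()}
    k = 0
    for a in list_a:
        key = (a.chromosome, a.strand) if strand_matched else (a.chromosome,)
        arr = groups.get(key)
        if arr is None or len(arr) == 0:
            continue
        i = np.searchsorted(arr, a.position)
        near = min(
            abs(a.position - arr[j]) for j in (i - 1, i) if 0 <= j < len(arr)
        )
        if near <= d:
            k += 1
    return k


def _union_length_circular(intervals: list[tuple[int, int]], L: int) -> int:
    """Total positions covered by the union of [s, e) intervals on a
    circle of circumference L (intervals given possibly out of range)."""
    if not intervals:
        return 0
    pieces: list[tuple[int, int]] = []
    for s, e in intervals:
        if e - s >= L:
            return L
        s_, e_ = s % L, s % L + (e - s)
        if e_ <= L:
            pieces.append((s_, e_))
        else:
            pieces.append((s_, L))
            pieces.append((0, e_ - L))
    pieces.sort()
    total = 0
    cur_s, cur_e = pieces[0]
    for s, e in pieces[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    total += cur_e - cur_s
    return min(total, L)


def _union_length_linear(intervals: list[tuple[int, int]], L: int) -> int:
    clipped = [(max(0, s), min(L, e)) for s, e in intervals if min(L, e) > max(0, s)]
    if not clipped:
        return 0
    clipped.sort()
    total = 0
    cur_s, cur_e = clipped[0]
    for s, e in clipped[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    total += cur_e - cur_s
    return total


def footprint(
    list_b: Sequence[GenomicPosition],
    d: int,
    genome: GenomeSequence,
    strand_matched: bool = True,
) -> int:
    """Stranded positions within d of any B coordinate (merged union).

    Intervals [pos-d, pos+d] are merged before counting; duplicated or
    reordered input does not change the result.  With
    ``strand_matched=False`` the union is over unstranded positions.
    """
    L = len(genome)
    union = _union_length_circular if genome.circular else _union_length_linear
    if strand_matched:
        total = 0
        for strand in ("+", "-"):
            iv = [(b.position - d, b.position + d + 1) for b in list_b if b.strand == strand]
            total += union(iv, L)
        return total
    iv = [(b.position - d, b.position + d + 1) for b in list_b]
    return union(iv, L)


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), log-space summation.

    Stable for p down to ~1e-320; monotone non-increasing in k.
    """
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent parameters k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    kmax = min(n, K)
    kmin = max(k, max(0, n + K - N))
    if kmin > kmax:
        return 0.0

    def lchoose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    ks = np.arange(kmin, kmax + 1, dtype=float)
    lp = lchoose(K, ks) + lchoose(N - K, n - ks) - lchoose(N, n)
    m = float(lp.max())
    return float(min(1.0, math.exp(m) * float(np.exp(lp - m).sum())))


def compare_lists(
    list_a: Sequence[GenomicPosition],
    list_b: Sequence[GenomicPosition],
    d: int,
    genome: GenomeSequence,
    strand_matched: bool = True,
) -> OverlapResult:
    """Full one-direction comparison of list A against list B."""
    k = count_within(list_a, list_b, d, strand_matched)
    K = footprint(list_b, d, genome, strand_matched)
    N = 2 * len(genome) if strand_matched else len(genome)
    p = hypergeom_upper_tail(k, len(list_a), K, N)
    return OverlapResult(k=k, n=len(list_a), K=K, N=N, p_value=p, d=d,
                         strand_matched=strand_matched)


def write_overlap_report(
    res_ab: OverlapResult, res_ba: OverlapResult, path: str,
    name_a: str = "A", name_b: str = "B",
) -> None:
    """Both comparison directions as a TSV (the overlap count depends
    on the direction, so both are reported)."""
    with open(path, "w") as fh:
        fh.write("direction\td\tk\tn\tK\tN\tp_value\n")
        for name, r in ((f"{name_a}->{name_b}", res_ab), (f"{name_b}->{name_a}", res_ba)):
            fh.write(
                f"{name}\t{r.d}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t{r.p_value:.6g}\n"
            )
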