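"""Rho-dependent termination scoring from +/-bicyclomycin 3'-end tracks.

For a genomic position the read 3'-end counts in 800-nt strand-
oriented windows upstream and downstream are collected in the
BCM-treated and untreated samples.  The Rho score is the ratio of
ratios R = (BCM_ds/BCM_us) / (Unt_ds/Unt_us): Rho inhibition increases
readthrough, so R > 1 (and descriptively R > 2 for at least two-fold
readthrough) marks Rho-dependent termination.  Significance is a
one-sided Fisher exact test on the 2x2 table of window counts,
computed by log-space hypergeometric tail summation (stable to
p >= 1e-320).  Putative Rho termination regions are qualifying
positions (R > 1, p < 1e-4), reported as the most significant position
within an 800-nt suppression radius.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genome_io import GenomicPosition, SignalTrack

log = logging.getLogger(__name__)


@dataclasses.dataclass
class WindowCounts:
    """Read counts in the four strand-oriented windows around a position."""

    bcm_us: int
    bcm_ds: int
    unt_us: int
    unt_ds: int

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"{f.name} must be non-negative, got {v}")

    @property
    def total(self) -> int:
        return self.bcm_us + self.bcm_ds + self.unt_us + self.unt_ds


@dataclasses.dataclass
class RhoPointScore:
    position: GenomicPosition
    counts: WindowCounts
    rho_score: float  # nan when undefined (no reads at all)
    p_value: float
    low_coverage: bool = False


@dataclasses.dataclass
class RhoRegion:
    """A called Rho termination region, represented by the most
    significant qualifying position in its +/-800-nt neighborhood."""

    representative: RhoPointScore


# ---------------------------------------------------------------------------
# Window sums
# ---------------------------------------------------------------------------

def _window_sum(counts: np.ndarray, lo: int, hi: int, circular: bool) -> float:
    """Sum of counts over [lo, hi); wraps on circular genomes, truncates
    to the array on linear ones."""
    L = len(counts)
    if circular:
        if hi - lo >= L:
            return float(counts.sum())
        idx = np.arange(lo, hi) % L
        return float(counts[idx].sum())
    lo = max(lo, 0)
    hi = min(hi, L)
    if hi <= lo:
        return 0.0
    return float(counts[lo:hi].sum())


def window_counts(
    bcm_track: SignalTrack,
    unt_track: SignalTrack,
    position: GenomicPosition,
    w: int = 800,
    circular: bool = True,
) -> WindowCounts:
    """Collect the four windowed counts around one position.

    Strand-oriented half-open windows; the focal position belongs to
    the upstream window.  On +: upstream [p-w+1, p], downstream
    [p+1, p+w]; mirrored on -.
    """
    if w <= 0:
        raise ValueError(f"window size must be positive, got {w}")
    p = position.position
    if position.strand == "+":
        us = (p - w + 1, p + 1)
        ds = (p + 1, p + w + 1)
    else:
        us = (p, p + w)
        ds = (p - w, p)
    vals = []
    for track in (bcm_track, unt_track):
        vals.append(int(round(_window_sum(track.counts, *us, circular))))
        vals.append(int(round(_window_sum(track.counts, *ds, circular))))
    return WindowCounts(bcm_us=vals[0], bcm_ds=vals[1], unt_us=vals[2], unt_ds=vals[3])


# ---------------------------------------------------------------------------
# Rho score and significance
# ---------------------------------------------------------------------------

def rho_score(counts: WindowCounts) -> float:
    """Ratio of ratios R = (BCM_ds/BCM_us) / (Unt_ds/Unt_us).

    When any window count is zero, a pseudocount of +1 is added to all
    four counts (score only, never the Fisher test) so R stays finite.
    All-zero counts are undefined (nan, logged).
    """
    a, b, c, d = counts.bcm_ds, counts.bcm_us, counts.unt_ds, counts.unt_us
    if a == b == c == d == 0:
        log.info("rho_score undefined for all-zero window counts")
        return float("nan")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 1, b + 1, c + 1, d + 1
    return (a / b) / (c / d)


def _log_hypergeom_pmf(k: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeometric(N, K, n), via log-gamma."""
    k = np.asarray(k, dtype=float)

    def lchoose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return lchoose(K, k) + lchoose(N - K, n - k) - lchoose(N, n)


def _log_tail(x: int, N: int, K: int, n: int) -> float:
    """log P(X >= x) by log-space summation over the upper support."""
    kmax = min(n, K)
    kmin = max(x, max(0, n + K - N))
    if kmin > kmax:
        return -math.inf
    ks = np.arange(kmin, kmax + 1)
    lp = _log_hypergeom_pmf(ks, N, K, n)
    m = float(lp.max())
    return m + math.log(float(np.exp(lp - m).sum()))


def log10_significance(counts: WindowCounts) -> float:
    """log10 of the one-sided Fisher exact p (see :func:`significance`).

    Deep signals underflow double precision as plain probabilities; the
    log form keeps them comparable (used to rank candidate positions).
    """
    a, b, c, d = counts.bcm_ds, counts.bcm_us, counts.unt_ds, counts.unt_us
    N = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or col1 == 0 or (c + d) == 0 or (b + d) == 0:
        return 0.0
    return min(0.0, _log_tail(a, N, col1, row1) / math.log(10))


def significance(counts: WindowCounts) -> float:
    """One-sided Fisher exact p for downstream enrichment under BCM.

    The 2x2 table is [[BCM_ds, BCM_us], [Unt_ds, Unt_us]]; the p-value
    is the upper hypergeometric tail P(X >= BCM_ds) with X the
    downstream count of the BCM row given the margins, summed in log
    space (numerically stable to p >= 1e-320).  Any zero margin yields
    p = 1.0 by convention.
    """
    a, b, c, d = counts.bcm_ds, counts.bcm_us, counts.unt_ds, counts.unt_us
    for v, name in ((a, "bcm_ds"), (b, "bcm_us"), (c, "unt_ds"), (d, "unt_us")):
        if v != int(v):
            raise ValueError(f"{name} must be an integer raw count")
    return float(min(1.0, 10.0 ** log10_significance(counts)))


# ---------------------------------------------------------------------------
# Genome-wide scan
# ---------------------------------------------------------------------------

def _sliding_sums(x: np.ndarray, a: int, b: int, circular: bool) -> np.ndarray:
    """s[p] = sum_{i=p+a}^{p+b} x[i] for every p, via cumulative sums."""
    L = len(x)
    w = b - a + 1
    if circular:
        pad = np.concatenate([x[-(2 * L):], x, x])  # generous wrap padding
        # index into pad: position p maps to pad index p + L
        cs = np.concatenate([[0.0], np.cumsum(pad)])
        p = np.arange(L) + L
        return cs[p + b + 1] - cs[p + a]
    cs = np.concatenate([[0.0], np.cumsum(x)])
    p = np.arange(L)
    lo = np.clip(p + a, 0, L)
    hi = np.clip(p + b + 1, 0, L)
    return cs[hi] - cs[lo]


def _strand_windows(x: np.ndarray, strand: str, w: int, circular: bool):
    if strand == "+":
        us = _sliding_sums(x, -w + 1, 0, circular)
        ds = _sliding_sums(x, 1, w, circular)
    else:
        us = _sliding_sums(x, 0, w - 1, circular)
        ds = _sliding_sums(x, -w, -1, circular)
    return np.rint(us).astype(np.int64), np.rint(ds).astype(np.int64)


def scan_genome(
    bcm_tracks: tuple[SignalTrack, SignalTrack],
    unt_tracks: tuple[SignalTrack, SignalTrack],
    w: int = 800,
    min_total_reads: int = 20,
    circular: bool = True,
    positive_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-position Rho scores and significance over the whole genome.

    Window sums use rolling cumulative sums (O(L) per strand).
    Positions with fewer than ``min_total_reads`` raw reads across the
    four windows are skipped.  The Fisher test runs only where the Rho
    score exceeds ``positive_threshold`` (candidates); p = 1 elsewhere.

    Returns a DataFrame with columns chrom, position (0-based), strand,
    bcm_us, bcm_ds, unt_us, unt_ds, rho_score, p_value.
    """
    frames = []
    for idx, strand in ((0, "+"), (1, "-")):
        bt, ut = bcm_tracks[idx], unt_tracks[idx]
        if len(bt) != len(ut):
            raise ValueError("BCM and untreated track lengths differ")
        b_us, b_ds = _strand_windows(bt.counts, strand, w, circular)
        u_us, u_ds = _strand_windows(ut.counts, strand, w, circular)
        total = b_us + b_ds + u_us + u_ds
        keep = total >= min_total_reads
        if not keep.any():
            continue
        pos = np.flatnonzero(keep)
        a, b, c, d = b_ds[keep], b_us[keep], u_ds[keep], u_us[keep]
        # vectorized pseudocounted score
        zero = (np.minimum(np.minimum(a, b), np.minimum(c, d)) == 0)
        aa = a + zero
        bb = b + zero
        cc = c + zero
        dd = d + zero
        score = (aa / bb) / (cc / dd)
        lp = np.zeros(len(pos))
        cand = score > positive_threshold
        if cand.any():
            tables = np.stack([a[cand], b[cand], c[cand], d[cand]], axis=1)
            uniq, inv = np.unique(tables, axis=0, return_inverse=True)
            lpu = np.array(
                [log10_significance(WindowCounts(int(t[1]), int(t[0]), int(t[3]), int(t[2])))
                 for t in uniq]
            )
            lp[cand] = lpu[inv]
        p = 10.0 ** lp
        frames.append(
            pd.DataFrame(
                {
                    "chrom": bt.chromosome,
                    "position": pos,
                    "strand": strand,
                    "bcm_us": b,
                    "bcm_ds": a,
                    "unt_us": d,
                    "unt_ds": c,
                    "rho_score": score,
                    "p_value": p,
                    "log10_p": lp,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "position", "strand", "bcm_us", "bcm_ds",
                     "unt_us", "unt_ds", "rho_score", "p_value", "log10_p"]
        )
    return pd.concat(frames, ignore_index=True)


def call_regions(
    scores: pd.DataFrame, alpha: float = 1e-4, radius: int = 800,
    positive_threshold: float = 1.0,
) -> list[RhoRegion]:
    """Call Rho termination regions from a scan table.

    Positions qualify when rho_score > ``positive_threshold`` and
    p < ``alpha``.  Representatives are selected greedily in ascending
    p-value order, suppressing qualifying positions within ``radius``
    nt (same strand) of an already selected representative.
    """
    qual = scores[(scores["rho_score"] > positive_threshold) & (scores["p_value"] < alpha)]
    # rank by log10 p: deep signals underflow the plain p-value to 0 and
    # would otherwise tie arbitrarily
    sort_col = "log10_p" if "log10_p" in qual.columns else "p_value"
    qual = qual.sort_values([sort_col, "position"], kind="stable")
    regions: list[RhoRegion] = []
    chosen: dict[str, list[int]] = {"+": [], "-": []}
    for row in qual.itertuples(index=False):
        if any(abs(row.position - q) <= radius for q in chosen[row.strand]):
            continue
        chosen[row.strand].append(int(row.position))
        regions.append(RhoRegion(_row_to_point(row)))
    regions.sort(key=lambda r: (r.representative.position.position,
                                r.representative.position.strand))
    return regions


def _row_to_point(row) -> RhoPointScore:
    return RhoPointScore(
        position=GenomicPosition(row.chrom, int(row.position), row.strand),
        counts=WindowCounts(int(row.bcm_us), int(row.bcm_ds), int(row.unt_us), int(row.unt_ds)),
        rho_score=float(row.rho_score),
        p_value=float(row.p_value),
    )


def annotate_positions(
    positions: Iterable[GenomicPosition],
    bcm_tracks: tuple[SignalTrack, SignalTrack],
    unt_tracks: tuple[SignalTrack, SignalTrack],
    w: int = 800,
    min_total_reads: int = 20,
    circular: bool = True,
) -> list[RhoPointScore]:
    """Exact per-position Rho scores for arbitrary positions.

    No neighborhood suppression is applied; positions below the
    minimum-read rule are flagged ``low_coverage`` (p kept at 1).
    """
    out: list[RhoPointScore] = []
    for pos in positions:
        idx = 0 if pos.strand == "+" else 1
        wc = window_counts(bcm_tracks[idx], unt_tracks[idx], pos, w, circular)
        if wc.total < min_total_reads:
            out.append(RhoPointScore(pos, wc, float("nan"), 1.0, low_coverage=True))
            continue
        r = rho_score(wc)
        p = significance(wc) if r > 1 else 1.0
        out.append(RhoPointScore(pos, wc, r, p))
    return out


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def points_to_frame(points: Sequence[RhoPointScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [p.position.chromosome for p in points],
            "position": [p.position.position for p in points],
            "strand": [p.position.strand for p in points],
            "bcm_us": [p.counts.bcm_us for p in points],
            "bcm_ds": [p.counts.bcm_ds for p in points],
            "unt_us": [p.counts.unt_us for p in points],
            "unt_ds": [p.counts.unt_ds for p in points],
            "rho_score": [p.rho_score for p in points],
            "p_value": [p.p_value for p in points],
            "low_coverage": [p.low_coverage for p in points],
        }
    )


def write_scores_tsv(scores: pd.DataFrame, path: str) -> None:
    """TSV with 1-based positions and the paper-style column names."""
    out = scores.copy()
    out["position"] = out["position"] + 1
    out = out.rename(
        columns={"bcm_us": "BCM_us", "bcm_ds": "BCM_ds",
                 "unt_us": "Untreated_us", "unt_ds": "Untreated_ds",
                 "p_value": "significance_score"}
    )
    out.to_csv(path, sep="\t", index=False)


def write_regions_bed(regions: Sequence[RhoRegion], path: str) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            p = r.representative.position
            fh.write(
                f"{p.chromosome}\t{p.position}\t{p.position + 1}\trho{i:04d}\t0\t{p.strand}\n"
            )
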