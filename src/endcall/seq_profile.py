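"""C:G nucleotide-ratio profiles around stranded genomic positions.

Rho loads at Rut sites — C-rich, G-poor, unstructured RNA — so the
region upstream of a Rho-terminated 3' end shows an elevated C:G ratio
on the transcript's sense strand.  For each position the +/-600 nt of
sequence is taken in transcript orientation (reverse-complemented for
- strand) and tiled into non-overlapping 25-nt windows (48 windows
spanning [-600, +600)); the per-window C:G count ratio is averaged
across regions.  A matched set of random coordinates provides the
baseline.
"""
from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np

from .genome_io import GenomeSequence, GenomicPosition, reverse_complement

log = logging.getLogger(__name__)


@dataclasses.dataclass
class ProfileMatrix:
    """Per-region, per-window C:G ratios around a set of positions.

    ``offsets`` are window start offsets in transcript orientation;
    ``ratios`` is regions x windows with NaN where a window had zero G
    (excluded from the mean); ``mean_profile`` is the per-window
    mean over regions, with ``n_used`` regions contributing.
    """

    offsets: np.ndarray
    ratios: np.ndarray
    mean_profile: np.ndarray
    n_used: np.ndarray
    n_dropped: int = 0


def _oriented_sequence(genome: GenomeSequence, pos: GenomicPosition, flank: int) -> str | None:
    """The 2*flank nt surrounding ``pos`` read along the transcript.

    Transcript coordinate t in [-flank, flank) maps to genome position
    pos+t on + and pos-t on -.  Returns None when the window leaves a
    linear genome.
    """
    p = pos.position
    L = len(genome)
    if pos.strand == "+":
        lo, hi = p - flank, p + flank
    else:
        lo, hi = p - flank + 1, p + flank + 1
    if not genome.circular and (lo < 0 or hi > L):
        return None
    seq = genome.fetch(lo, hi)
    return seq if pos.strand == "+" else reverse_complement(seq)


def cg_profile(
    positions: list[GenomicPosition],
    genome: GenomeSequence,
    flank: int = 600,
    window: int = 25,
) -> ProfileMatrix:
    """C:G ratio profile in non-overlapping windows around positions.

    ``flank`` must be divisible by ``window``.  Windows with zero G are
    recorded as missing for that region and excluded from the
    cross-region mean.  On linear genomes, positions closer than
    ``flank`` to a boundary are dropped with a warning; circular
    genomes wrap.
    """
    if flank % window != 0:
        raise ValueError("flank must be divisible by window")
    nwin = 2 * flank // window
    offsets = np.arange(-flank, flank, window)
    rows = []
    dropped = 0
    for pos in positions:
        seq = _oriented_sequence(genome, pos, flank)
        if seq is None:
            dropped += 1
            continue
        arr = np.frombuffer(seq.encode(), dtype="S1").reshape(nwin, window)
        c = (arr == b"C").sum(axis=1).astype(float)
        g = (arr == b"G").sum(axis=1).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rows.append(np.where(g > 0, c / g, np.nan))
    if dropped:
        log.warning("%d positions dropped at linear-genome boundaries", dropped)
    if not rows:
        ratios = np.empty((0, nwin))
    else:
        ratios = np.vstack(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows are legitimate
        mean = np.nanmean(ratios, axis=0) if len(ratios) else np.full(nwin, np.nan)
    n_used = np.sum(~np.isnan(ratios), axis=0) if len(ratios) else np.zeros(nwin, dtype=int)
    return ProfileMatrix(offsets, ratios, mean, n_used, dropped)


def random_positions(n: int, genome: GenomeSequence, seed: int) -> list[GenomicPosition]:
    """Uniform random stranded positions, reproducible for a fixed seed."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    pos = rng.integers(0, len(genome), size=n)
    strands = rng.choice(["+", "-"], size=n)
    return [GenomicPosition(genome.name, int(p), str(s)) for p, s in zip(pos, strands)]


def write_profile_tsv(profile: ProfileMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("offset\tmean_ratio\tn_regions_used\n")
        for o, m, n in zip(profile.offsets, profile.mean_profile, profile.n_used):
            fh.write(f"{o}\t{m:.6g}\t{n}\n")
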