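"""Term-seq 3'-end peak calling and replicate combination.

Per-replicate candidate peaks come from prominence-based detection on
the dense per-base 3'-end count track (width (1, None), prominence
(None, None), relative height 0.75 — settings tuned for the high, sharp
peaks characteristic of Term-seq).  Replicates are combined with an
irreproducible-discovery-rate (IDR) style mixture model on rank-
transformed peak heights, and the reproducible peaks are curated down
to single-nucleotide consensus 3' ends: the apex is the strongest
signal nucleotide within the peak extent (ties broken toward the
strand-downstream position) and peaks within 100 bp are collapsed to
the highest-scoring member of the cluster.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .genome_io import SignalTrack

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RawPeak:
    """A candidate peak on one replicate track.

    ``left``/``right`` delimit the half-open extent (positions with
    signal >= height - rel_height * prominence, contiguous around the
    apex); ``apex`` is the strand-downstream-most maximal position.
    """

    chromosome: str
    strand: str
    left: int
    right: int
    apex: int
    height: float
    prominence: float


@dataclasses.dataclass
class MatchedPeakPair:
    peak_a: RawPeak
    peak_b: RawPeak
    score_a: float
    score_b: float
    local_idr: float | None = None
    global_idr: float | None = None


@dataclasses.dataclass
class IdrModelParams:
    """Parameters of the two-component Gaussian copula mixture."""

    pi_reproducible: float
    mu: float
    sigma: float
    rho_corr: float
    converged: bool = True
    n_iter: int = 0
    log_likelihood: float = float("nan")


@dataclasses.dataclass
class ProvisionalEnd:
    chromosome: str
    strand: str
    position: int
    score: float
    global_idr: float
    extent: tuple[int, int]


@dataclasses.dataclass
class ConsensusEnd:
    """A curated single-nucleotide 3' end."""

    chromosome: str
    strand: str
    position: int
    score: float
    global_idr: float


class IdrDegenerateError(RuntimeError):
    """Too few pairs, or degenerate scores: the mixture cannot be fitted."""


# ---------------------------------------------------------------------------
# Raw peak calling
# ---------------------------------------------------------------------------

def find_raw_peaks(
    track: SignalTrack, min_width: int = 1, rel_height: float = 0.75
) -> list[RawPeak]:
    """Detect candidate peaks on one track with scipy's prominence machinery.

    Plateau maxima yield a single candidate whose apex is the
    strand-downstream-most plateau position (largest coordinate on +,
    smallest on -).  An all-zero track yields an empty list.
    """
    x = np.asarray(track.counts, dtype=float)
    if not np.any(x > 0):
        return []
    peaks, props = sp_signal.find_peaks(
        x,
        width=(min_width, None),
        prominence=(None, None),
        rel_height=rel_height,
        plateau_size=(1, None),
    )
    out: list[RawPeak] = []
    for i in range(len(peaks)):
        if track.strand == "+":
            apex = int(props["right_edges"][i])
        else:
            apex = int(props["left_edges"][i])
        left = int(math.ceil(props["left_ips"][i]))
        right = int(math.floor(props["right_ips"][i])) + 1
        out.append(
            RawPeak(
                chromosome=track.chromosome,
                strand=track.strand,
                left=left,
                right=right,
                apex=apex,
                height=float(x[apex]),
                prominence=float(props["prominences"][i]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Replicate matching
# ---------------------------------------------------------------------------

def match_peaks(
    peaks_a: Sequence[RawPeak],
    peaks_b: Sequence[RawPeak],
    max_apex_distance: int = 100,
) -> list[MatchedPeakPair]:
    """Greedy nearest-apex one-to-one matching within ``max_apex_distance``.

    Candidate pairs are taken in order of increasing apex distance
    (ties by coordinate); each peak joins at most one pair.  Unmatched
    peaks drop out of the downstream consensus.
    """
    if not peaks_a or not peaks_b:
        return []
    cands: list[tuple[int, int, int, int]] = []
    for i, pa in enumerate(peaks_a):
        for j, pb in enumerate(peaks_b):
            d = abs(pa.apex - pb.apex)
            if d <= max_apex_distance:
                cands.append((d, pa.apex, pb.apex, i * len(peaks_b) + j))
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[MatchedPeakPair] = []
    nb = len(peaks_b)
    for d, _, _, ij in cands:
        i, j = divmod(ij, nb)
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append(
            MatchedPeakPair(peaks_a[i], peaks_b[j], peaks_a[i].height, peaks_b[j].height)
        )
    pairs.sort(key=lambda p: p.peak_a.apex)
    return pairs


# ---------------------------------------------------------------------------
# IDR mixture model
# ---------------------------------------------------------------------------

def _rank_u(scores: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Map scores to pseudo-uniform values via the empirical CDF.

    Integer peak heights carry massive ties; untied copula fitting on
    midranks collapses tied pairs onto the z1=z2 diagonal and the
    correlated component absorbs pure noise.  Ties are therefore broken
    by an infinitesimal deterministic jitter (fixed internal rng), the
    randomized-rank device standard for discrete marginals.
    """
    jitter = rng.uniform(0, 1e-6, size=scores.shape)
    ranks = sp_stats.rankdata(scores + jitter * (1 + np.abs(scores)), method="ordinal")
    return ranks / (len(scores) + 1)


def _bvn_logpdf(z1, z2, mu, sigma, rho):
    s2 = sigma * sigma
    det = s2 * s2 * (1 - rho * rho)
    a = (z1 - mu) / sigma
    b = (z2 - mu) / sigma
    q = (a * a - 2 * rho * a * b + b * b) / (1 - rho * rho)
    return -math.log(2 * math.pi) - 0.5 * math.log(det) - 0.5 * q


def fit_idr(
    pairs: Sequence[MatchedPeakPair],
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[IdrModelParams, list[MatchedPeakPair]]:
    """Fit the reproducibility mixture and annotate pairs with IDR values.

    Scores from each replicate are rank-transformed to pseudo-uniform
    and mapped to latent z-scores by inverting the fitted mixture's
    marginal CDF (pseudo-likelihood: the inverse transform is refreshed
    after each EM pass, since fixed standard-normal quantiles distort
    both components' marginals and bias the mixing weight upward).  The
    reproducible component is bivariate normal with mean (mu, mu),
    variance sigma^2 and correlation rho_corr; the irreproducible
    component is standard bivariate normal with zero correlation.
    Fitted by EM; stops at relative log-likelihood change < ``tol`` or
    ``max_iter`` total iterations (non-convergence returns the best
    iterate, flagged).

    ``local_idr`` is the posterior probability of the irreproducible
    component; ``global_idr`` is the running mean of local_idr over
    pairs sorted ascending by local_idr.

    Raises :class:`IdrDegenerateError` for < 10 pairs or degenerate
    (constant) scores; callers fall back to the presence-in-both-
    replicates criterion.
    """
    pairs = list(pairs)
    if len(pairs) < 10:
        raise IdrDegenerateError(f"only {len(pairs)} matched pairs (need >= 10)")
    sa = np.array([p.score_a for p in pairs], dtype=float)
    sb = np.array([p.score_b for p in pairs], dtype=float)
    if np.ptp(sa) == 0 or np.ptp(sb) == 0:
        raise IdrDegenerateError("constant scores in one replicate")
    rng = np.random.default_rng(0)  # internal, fixed: keeps the pipeline seed-free
    u1 = _rank_u(sa, rng)
    u2 = _rank_u(sb, rng)

    # the pseudo-likelihood surface has a diffuse local optimum that absorbs
    # noise pairs into the reproducible component; run EM from several
    # starts and keep the best fit
    starts = [
        (0.5, 1.0, 1.0, 0.5),
        (0.1, 2.0, 0.5, 0.9),
        (0.05, 2.5, 0.3, 0.95),
        (0.25, 1.5, 1.0, 0.8),
    ]
    best = None
    for init in starts:
        fit = _pseudo_em(u1, u2, init, max_iter, tol)
        if best is None or fit[0] > best[0]:
            best = fit
    ll_best, pi, mu, sigma, rho, converged, it, z1, z2 = best
    if not converged:
        log.warning("IDR EM did not converge in %d iterations", max_iter)

    log_irr = _bvn_logpdf(z1, z2, 0.0, 1.0, 0.0)  # fixed component
    log_rep = _bvn_logpdf(z1, z2, mu, sigma, rho)
    lr = np.log(pi) + log_rep
    li = np.log1p(-pi) + log_irr
    m = np.maximum(lr, li)
    log_f = m + np.log(np.exp(lr - m) + np.exp(li - m))
    local = np.exp(li - log_f)

    order = np.argsort(local, kind="stable")
    glob = np.empty_like(local)
    glob[order] = np.cumsum(local[order]) / np.arange(1, len(local) + 1)
    for p, lo, gl in zip(pairs, local, glob):
        p.local_idr = float(lo)
        p.global_idr = float(gl)
    params = IdrModelParams(pi, mu, sigma, rho, converged, it, ll_best)
    return params, pairs


def _pseudo_em(u1, u2, init, max_iter, tol, outer: int = 200):
    """One pseudo-likelihood EM run from a given (pi, mu, sigma, rho) start.

    Alternates EM passes on the latent z-scores with re-inversion of the
    pseudo-uniform ranks through the current mixture marginal
    G(z) = pi * Phi((z - mu)/sigma) + (1 - pi) * Phi(z).
    """
    pi, mu, sigma, rho = init
    z1 = sp_stats.norm.ppf(u1)
    z2 = sp_stats.norm.ppf(u2)
    prev_ll = -np.inf
    converged = False
    total_it = 0
    inner = 8  # EM passes between marginal refreshes
    for _ in range(outer):
        params_before = (pi, mu, sigma, rho)
        log_irr = _bvn_logpdf(z1, z2, 0.0, 1.0, 0.0)  # fixed component
        for _ in range(inner):
            total_it += 1
            log_rep = _bvn_logpdf(z1, z2, mu, sigma, rho)
            lr = np.log(pi) + log_rep
            li = np.log1p(-pi) + log_irr
            m = np.maximum(lr, li)
            log_f = m + np.log(np.exp(lr - m) + np.exp(li - m))
            w = np.exp(lr - log_f)  # posterior of reproducible component
            ll = float(np.sum(log_f))
            if prev_ll > -np.inf and abs(ll - prev_ll) < tol * abs(prev_ll):
                break
            prev_ll = ll
            sw = w.sum()
            if sw < 1e-8:
                break
            pi = float(np.clip(sw / len(w), 1e-3, 1 - 1e-3))
            # identifiability floors: the reproducible component must be
            # meaningfully shifted and correlated, else the fit can drift
            # onto the degenerate ridge where both components coincide and
            # pi is arbitrary
            mu = float(np.clip(np.sum(w * (z1 + z2)) / (2 * sw), 0.5, None))
            s2 = float(np.sum(w * ((z1 - mu) ** 2 + (z2 - mu) ** 2)) / (2 * sw))
            sigma = float(np.clip(math.sqrt(max(s2, 1e-6)), 1e-3, None))
            rho = float(np.sum(w * (z1 - mu) * (z2 - mu)) / (sw * sigma * sigma))
            rho = float(np.clip(rho, 0.2, 0.999))
        # refresh the latent scores under the updated marginal
        lo = min(-8.0, mu - 8 * sigma)
        hi = max(8.0, mu + 8 * sigma)
        zs = np.linspace(lo, hi, 8000)
        G = pi * sp_stats.norm.cdf((zs - mu) / sigma) + (1 - pi) * sp_stats.norm.cdf(zs)
        z1 = np.interp(u1, G, zs)
        z2 = np.interp(u2, G, zs)
        if max(abs(a - b) for a, b in zip(params_before, (pi, mu, sigma, rho))) < 1e-3:
            converged = True
            break
    # copula log-likelihood (joint minus marginal densities): comparable
    # across runs even though each run ends in its own latent scale
    log_irr = _bvn_logpdf(z1, z2, 0.0, 1.0, 0.0)
    log_rep = _bvn_logpdf(z1, z2, mu, sigma, rho)
    lr = np.log(pi) + log_rep
    li = np.log1p(-pi) + log_irr
    m = np.maximum(lr, li)
    log_f = m + np.log(np.exp(lr - m) + np.exp(li - m))
    lg1 = _mix_marginal_logpdf(z1, pi, mu, sigma)
    lg2 = _mix_marginal_logpdf(z2, pi, mu, sigma)
    cop_ll = float(np.sum(log_f - lg1 - lg2))
    return cop_ll, pi, mu, sigma, rho, converged, total_it, z1, z2


def _mix_marginal_logpdf(z, pi, mu, sigma):
    a = np.log(pi) + sp_stats.norm.logpdf(z, loc=mu, scale=sigma)
    b = np.log1p(-pi) + sp_stats.norm.logpdf(z)
    m = np.maximum(a, b)
    return m + np.log(np.exp(a - m) + np.exp(b - m))


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def _round_downstream(value: float, strand: str) -> int:
    return int(math.ceil(value)) if strand == "+" else int(math.floor(value))


def select_reproducible(
    pairs: Sequence[MatchedPeakPair], idr_threshold: float = 0.05
) -> list[ProvisionalEnd]:
    """Keep pairs with global IDR <= threshold as provisional ends.

    The provisional position is the mean of the two apexes rounded
    strand-downstream; the score is the mean of the two heights; the
    extent is the union of the matched peaks' extents.
    """
    out: list[ProvisionalEnd] = []
    for p in pairs:
        if p.global_idr is None or p.global_idr > idr_threshold:
            continue
        strand = p.peak_a.strand
        pos = _round_downstream((p.peak_a.apex + p.peak_b.apex) / 2.0, strand)
        out.append(
            ProvisionalEnd(
                chromosome=p.peak_a.chromosome,
                strand=strand,
                position=pos,
                score=(p.score_a + p.score_b) / 2.0,
                global_idr=float(p.global_idr),
                extent=(min(p.peak_a.left, p.peak_b.left), max(p.peak_a.right, p.peak_b.right)),
            )
        )
    if not out:
        log.warning("no pairs retained at IDR threshold %g", idr_threshold)
    return out


def refine_apex(
    end: ProvisionalEnd,
    tracks: Sequence[SignalTrack],
    search_extent: tuple[int, int] | None = None,
) -> int:
    """Strongest mean-across-replicates nucleotide within the peak extent.

    Ties go to the strand-downstream position (largest coordinate on +,
    smallest on -).
    """
    left, right = search_extent if search_extent is not None else end.extent
    mean = np.mean([t.counts[left:right] for t in tracks], axis=0)
    best = float(np.max(mean))
    maxima = np.flatnonzero(mean == best) + left
    return int(maxima[-1] if end.strand == "+" else maxima[0])


def collapse_clusters(
    ends: Sequence[ProvisionalEnd | ConsensusEnd], cluster_distance: int = 100
) -> list[ConsensusEnd]:
    """Single-linkage chain ends within ``cluster_distance``; keep the
    highest-scoring member per cluster (score ties strand-downstream).

    Idempotent: re-collapsing the result changes nothing.
    """
    if not ends:
        return []
    es = sorted(ends, key=lambda e: e.position)
    clusters: list[list] = [[es[0]]]
    for e in es[1:]:
        if e.position - clusters[-1][-1].position <= cluster_distance:
            clusters[-1].append(e)
        else:
            clusters.append([e])
    out: list[ConsensusEnd] = []
    for cl in clusters:
        best = max(cl, key=lambda e: e.score)
        tied = [e for e in cl if e.score == best.score]
        if len(tied) > 1:
            best = max(tied, key=lambda e: e.position) if tied[0].strand == "+" else min(
                tied, key=lambda e: e.position
            )
        out.append(
            ConsensusEnd(best.chromosome, best.strand, best.position, best.score,
                         getattr(best, "global_idr", 0.0))
        )
    return out


# ---------------------------------------------------------------------------
# End-to-end per-strand pipeline
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CallInfo:
    n_raw: tuple[int, ...] = ()
    n_pairs: int = 0
    n_retained: int = 0
    idr_params: IdrModelParams | None = None
    idr_fallback: bool = False
    single_replicate: bool = False


def call_consensus_ends(
    replicate_tracks: Sequence[SignalTrack],
    idr_threshold: float = 0.05,
    max_apex_distance: int = 100,
    cluster_distance: int = 100,
    min_width: int = 1,
    rel_height: float = 0.75,
    single_replicate: bool = False,
) -> tuple[list[ConsensusEnd], CallInfo]:
    """Call curated consensus 3' ends from replicate tracks of one strand.

    find_raw_peaks per replicate -> greedy apex matching -> IDR fit ->
    reproducible selection -> apex refinement -> 100-bp cluster
    collapse.  Deterministic and seed-free.  Exactly two replicates are
    supported; a single replicate requires ``single_replicate=True``
    (peaks pass through without IDR, flagged).
    """
    info = CallInfo()
    if len(replicate_tracks) == 1:
        if not single_replicate:
            raise ValueError(
                "one replicate given; replicate reproducibility cannot be assessed "
                "(pass single_replicate=True / --single-replicate to bypass)"
            )
        info.single_replicate = True
        raw = find_raw_peaks(replicate_tracks[0], min_width, rel_height)
        info.n_raw = (len(raw),)
        prov = [
            ProvisionalEnd(p.chromosome, p.strand, p.apex, p.height, 0.0, (p.left, p.right))
            for p in raw
        ]
        for e in prov:
            e.position = refine_apex(e, replicate_tracks)
        return collapse_clusters(prov, cluster_distance), info
    if len(replicate_tracks) != 2:
        raise ValueError("exactly two replicates are supported")

    raw_a = find_raw_peaks(replicate_tracks[0], min_width, rel_height)
    raw_b = find_raw_peaks(replicate_tracks[1], min_width, rel_height)
    info.n_raw = (len(raw_a), len(raw_b))
    pairs = match_peaks(raw_a, raw_b, max_apex_distance)
    info.n_pairs = len(pairs)
    if not pairs:
        return [], info
    try:
        params, pairs = fit_idr(pairs)
        info.idr_params = params
        prov = select_reproducible(pairs, idr_threshold)
    except IdrDegenerateError as exc:
        log.warning("IDR fallback (%s): retaining all matched pairs", exc)
        info.idr_fallback = True
        for p in pairs:
            p.local_idr = 0.0
            p.global_idr = 0.0
        prov = select_reproducible(pairs, idr_threshold)
    info.n_retained = len(prov)
    for e in prov:
        e.position = refine_apex(e, replicate_tracks)
    ends = collapse_clusters(prov, cluster_distance)
    return ends, info


def call_ends(
    replicate_pairs: Sequence[tuple[SignalTrack, SignalTrack]],
    **params,
) -> tuple[list[ConsensusEnd], dict[str, CallInfo]]:
    """Run the consensus pipeline on both strands of (fwd, rev) track pairs."""
    ends: list[ConsensusEnd] = []
    infos: dict[str, CallInfo] = {}
    for idx, strand in ((0, "+"), (1, "-")):
        tracks = [pair[idx] for pair in replicate_pairs]
        e, info = call_consensus_ends(tracks, **params)
        ends.extend(e)
        infos[strand] = info
    ends.sort(key=lambda e: (e.chromosome, e.position, e.strand))
    return ends, infos


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_consensus_ends(ends: Sequence[ConsensusEnd], prefix: str) -> tuple[str, str]:
    """Write BED6 plus a TSV (1-based positions, score, global IDR)."""
    bed = prefix + ".bed"
    tsv = prefix + ".tsv"
    max_score = max((e.score for e in ends), default=1.0) or 1.0
    with open(bed, "w") as fh:
        for i, e in enumerate(ends):
            bscore = int(round(1000 * e.score / max_score))
            fh.write(
                f"{e.chromosome}\t{e.position}\t{e.position + 1}\tend{i:05d}\t{bscore}\t{e.strand}\n"
            )
    with open(tsv, "w") as fh:
        fh.write("chrom\tposition\tstrand\tscore\tglobal_idr\n")
        for e in ends:
            fh.write(
                f"{e.chromosome}\t{e.position + 1}\t{e.strand}\t{e.score:.6g}\t{e.global_idr:.6g}\n"
            )
    return bed, tsv
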