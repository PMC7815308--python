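import numpy as np
import pytest

from endcall.end_peaks import (
    ConsensusEnd,
    IdrDegenerateError,
    MatchedPeakPair,
    ProvisionalEnd,
    RawPeak,
    call_consensus_ends,
    collapse_clusters,
    find_raw_peaks,
    fit_idr,
    match_peaks,
    refine_apex,
    select_reproducible,
)
from endcall.genome_io import SignalTrack

from _oracles import brute_peaks


def _track(counts, strand="+"):
    return SignalTrack("chr", strand, np.asarray(counts, dtype=float))


def _pairs_from_scores(s1, s2):
    return [
        MatchedPeakPair(
            RawPeak("chr", "+", i, i + 1, i, float(a), 1.0),
            RawPeak("chr", "+", i, i + 1, i, float(b), 1.0),
            float(a),
            float(b),
        )
        for i, (a, b) in enumerate(zip(s1, s2))
    ]


class TestFindRawPeaks:
    def test_isolated_impulse(self):
        (p,) = find_raw_peaks(_track([0, 0, 5, 0, 0]))
        assert (p.apex, p.height, p.prominence) == (2, 5, 5)
        assert (p.left, p.right) == (2, 3)

    def test_plateau_apex_is_strand_downstream(self):
        (p_fwd,) = find_raw_peaks(_track([0, 3, 3, 0], "+"))
        (p_rev,) = find_raw_peaks(_track([0, 3, 3, 0], "-"))
        assert p_fwd.apex == 2  # downstream-most on +
        assert p_rev.apex == 1  # downstream-most on -

    def test_two_peaks_prominence_and_extent(self):
        minor, major = find_raw_peaks(_track([0, 4, 1, 6, 0]))
        assert (minor.height, minor.prominence) == (4, 3)
        assert (major.height, major.prominence) == (6, 6)
        assert (minor.left, minor.right) == (1, 2)
        assert (major.left, major.right) == (3, 4)

    def test_all_zero_track_yields_nothing(self):
        assert find_raw_peaks(_track(np.zeros(100))) == []

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_brute_force_oracle(self, seed, strand):
        """Apex, extent, height and prominence all agree with direct
        enumeration on random integer tracks (heavy ties included)."""
        rng = np.random.default_rng(seed)
        x = rng.poisson(1.2, size=150).astype(float)
        got = find_raw_peaks(_track(x, strand))
        want = brute_peaks(x, strand)
        assert [(p.apex, p.left, p.right, p.height, p.prominence) for p in got] == [
            (w["apex"], w["left"], w["right"], w["height"], w["prominence"]) for w in want
        ]

    def test_apex_is_extent_maximum(self, rng):
        x = rng.poisson(2.0, size=300).astype(float)
        for p in find_raw_peaks(_track(x)):
            assert p.height == x[p.left:p.right].max()
            assert x[p.apex] == p.height

    def test_strand_mirror_symmetry(self, rng):
        """Reversing the track and flipping the strand mirrors every peak."""
        x = rng.poisson(1.5, size=200).astype(float)
        fwd = find_raw_peaks(_track(x, "+"))
        rev = find_raw_peaks(_track(x[::-1], "-"))
        n = len(x)
        mirrored = sorted(
            (n - 1 - p.apex, n - p.right, n - p.left, p.height, p.prominence) for p in rev
        )
        assert mirrored == sorted(
            (p.apex, p.left, p.right, p.height, p.prominence) for p in fwd
        )


class TestMatchPeaks:
    def _peaks(self, apexes):
        return [RawPeak("chr", "+", a, a + 1, a, 10.0, 10.0) for a in apexes]

    def test_nearby_apexes_pair(self):
        pairs = match_peaks(self._peaks([100]), self._peaks([103]))
        assert len(pairs) == 1

    def test_distant_apexes_do_not(self):
        assert match_peaks(self._peaks([100]), self._peaks([300])) == []

    def test_greedy_nearest_wins(self):
        pairs = match_peaks(self._peaks([100, 140]), self._peaks([125]))
        assert len(pairs) == 1
        assert pairs[0].peak_a.apex == 140  # distance 15 beats 25; 100 left unmatched

    def test_one_to_one(self, rng):
        a = self._peaks(sorted(rng.choice(2000, size=30, replace=False)))
        b = self._peaks(sorted(rng.choice(2000, size=25, replace=False)))
        pairs = match_peaks(a, b)
        assert len({id(p.peak_a) for p in pairs}) == len(pairs)
        assert len({id(p.peak_b) for p in pairs}) == len(pairs)
        assert all(abs(p.peak_a.apex - p.peak_b.apex) <= 100 for p in pairs)


class TestFitIdr:
    def test_perfect_reproducibility(self):
        rng = np.random.default_rng(5)
        s = rng.gamma(3, 10, 200)
        _, pairs = fit_idr(_pairs_from_scores(s, s))
        assert max(p.local_idr for p in pairs) < 0.05

    def test_independent_scores_are_irreproducible(self):
        rng = np.random.default_rng(6)
        a, b = rng.gamma(3, 10, 200), rng.gamma(3, 10, 200)
        params, pairs = fit_idr(_pairs_from_scores(a, b))
        assert np.median([p.local_idr for p in pairs]) > 0.5
        assert params.pi_reproducible < 0.2

    def test_mixture_parameter_recovery(self):
        rng = np.random.default_rng(0)
        n, n_rep = 500, 300
        z = rng.multivariate_normal([2.5, 2.5], [[1, 0.95], [0.95, 1]], size=n_rep)
        zi = rng.standard_normal((n - n_rep, 2))
        params, _ = fit_idr(
            _pairs_from_scores(np.r_[z[:, 0], zi[:, 0]], np.r_[z[:, 1], zi[:, 1]])
        )
        assert abs(params.pi_reproducible - 0.6) <= 0.1

    def test_global_idr_nondecreasing_in_rank(self):
        rng = np.random.default_rng(7)
        a = rng.gamma(3, 10, 300)
        b = a + rng.normal(0, 5, 300)
        _, pairs = fit_idr(_pairs_from_scores(a, np.abs(b)))
        ordered = sorted(pairs, key=lambda p: p.local_idr)
        glob = [p.global_idr for p in ordered]
        assert all(x <= y + 1e-12 for x, y in zip(glob, glob[1:]))

    def test_too_few_or_constant_scores_degenerate(self):
        with pytest.raises(IdrDegenerateError):
            fit_idr(_pairs_from_scores([1, 2], [1, 2]))
        with pytest.raises(IdrDegenerateError):
            fit_idr(_pairs_from_scores([5.0] * 20, list(range(20))))


class TestCuration:
    def _pair(self, apex_a, apex_b, strand="+", global_idr=0.01, h=10.0):
        pa = RawPeak("chr", strand, apex_a - 1, apex_a + 2, apex_a, h, h)
        pb = RawPeak("chr", strand, apex_b - 1, apex_b + 2, apex_b, h, h)
        mp = MatchedPeakPair(pa, pb, h, h)
        mp.local_idr = global_idr
        mp.global_idr = global_idr
        return mp

    def test_select_reproducible_midpoint_and_threshold(self):
        kept = select_reproducible([self._pair(100, 102)], 0.05)
        assert kept[0].position == 101
        assert select_reproducible([self._pair(100, 102, global_idr=0.2)], 0.05) == []

    def test_midpoint_rounds_strand_downstream(self):
        assert select_reproducible([self._pair(100, 103, "+")])[0].position == 102
        assert select_reproducible([self._pair(100, 103, "-")])[0].position == 101

    def test_refine_apex_tie_breaks_downstream(self):
        tracks = [_track([1, 7, 7, 2]), _track([1, 7, 7, 2])]
        fwd = ProvisionalEnd("chr", "+", 1, 7, 0.0, (0, 4))
        rev = ProvisionalEnd("chr", "-", 1, 7, 0.0, (0, 4))
        assert refine_apex(fwd, tracks) == 2
        assert refine_apex(rev, tracks) == 1

    def test_refine_single_position_extent(self):
        end = ProvisionalEnd("chr", "+", 3, 5, 0.0, (3, 4))
        assert refine_apex(end, [_track([0, 0, 0, 5, 0])]) == 3

    def _ends(self, spec):
        return [ConsensusEnd("chr", "+", p, s, 0.0) for p, s in spec]

    def test_collapse_keeps_cluster_maximum(self):
        out = collapse_clusters(self._ends([(100, 5), (150, 9), (190, 7)]))
        assert [(e.position, e.score) for e in out] == [(150, 9)]

    def test_collapse_respects_distance(self):
        out = collapse_clusters(self._ends([(100, 5), (350, 9)]))
        assert len(out) == 2

    def test_collapse_chains_transitively(self):
        out = collapse_clusters(self._ends([(0, 1), (90, 2), (180, 3)]))
        assert [(e.position, e.score) for e in out] == [(180, 3)]

    def test_collapse_idempotent_and_order_independent(self, rng):
        ends = self._ends(
            [(int(p), float(s)) for p, s in zip(rng.choice(5000, 40, replace=False),
                                                rng.gamma(2, 5, 40))]
        )
        once = collapse_clusters(ends)
        assert collapse_clusters(once) == once
        shuffled = list(ends)
        rng.shuffle(shuffled)
        assert collapse_clusters(shuffled) == once

    def test_no_survivors_within_cluster_distance(self, rng):
        ends = self._ends(
            [(int(p), float(s)) for p, s in zip(rng.choice(3000, 50, replace=False),
                                                rng.gamma(2, 5, 50))]
        )
        out = collapse_clusters(ends)
        pos = sorted(e.position for e in out)
        assert all(b - a > 100 for a, b in zip(pos, pos[1:]))


class TestCallConsensusEnds:
    def test_identical_replicates_recover_impulses(self):
        x = np.zeros(5000)
        sites = [500, 1500, 2500, 3500, 4500]
        x[sites] = 50
        ends, info = call_consensus_ends([_track(x), _track(x)])
        assert sorted(e.position for e in ends) == sites
        assert info.idr_fallback  # 5 pairs: below the 10-pair minimum

    def test_disjoint_replicates_yield_nothing(self):
        a, b = np.zeros(2000), np.zeros(2000)
        a[100] = 50
        b[1500] = 50
        ends, _ = call_consensus_ends([_track(a), _track(b)])
        assert ends == []

    def test_single_replicate_requires_escape_hatch(self):
        x = np.zeros(500)
        x[100] = 9
        with pytest.raises(ValueError, match="single"):
            call_consensus_ends([_track(x)])
        ends, info = call_consensus_ends([_track(x)], single_replicate=True)
        assert [e.position for e in ends] == [100]
        assert info.single_replicate

    def test_consensus_respects_cluster_spacing(self, consensus):
        ends, _ = consensus
        for strand in "+-":
            pos = sorted(e.position for e in ends if e.strand == strand)
            assert all(b - a > 100 for a, b in zip(pos, pos[1:]))

    def test_recovers_planted_ends(self, sim, consensus):
        """The default scenario's planted 3' ends are recovered to +/-2 nt
        with few spurious calls."""
        ends, _ = consensus
        planted = list(zip(sim.truth.position, sim.truth.strand))
        hit = sum(
            any(e.strand == s and abs(e.position - p) <= 2 for e in ends)
            for p, s in planted
        )
        assert hit / len(planted) >= 0.9
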