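import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from endcall.genome_io import GenomicPosition, SignalTrack
from endcall.rho_term import (
    WindowCounts,
    annotate_positions,
    call_regions,
    rho_score,
    scan_genome,
    significance,
    window_counts,
)

from _oracles import fisher_greater_enum, window_sum


def _track(counts, strand="+"):
    return SignalTrack("chr", strand, np.asarray(counts, dtype=float))


def _pos(p, strand="+"):
    return GenomicPosition("chr", p, strand)


class TestWindowCounts:
    def test_impulse_lands_in_upstream_window(self):
        L = 3000
        x = np.zeros(L)
        x[1000 - 5] = 10
        wc = window_counts(_track(x), _track(np.zeros(L)), _pos(1000), w=800)
        assert (wc.bcm_us, wc.bcm_ds, wc.unt_us, wc.unt_ds) == (10, 0, 0, 0)

    def test_uniform_circular_track(self):
        L = 2000
        wc = window_counts(_track(np.ones(L)), _track(np.ones(L)), _pos(100), w=800)
        assert (wc.bcm_us, wc.bcm_ds) == (800, 800)  # wraps past the origin

    def test_minus_strand_windows_mirror(self):
        L = 3000
        x = np.zeros(L)
        x[1004] = 7   # transcript-upstream of position 1000 on '-'
        x[996] = 3    # transcript-downstream
        wc = window_counts(_track(x, "-"), _track(np.zeros(L), "-"), _pos(1000, "-"))
        assert (wc.bcm_us, wc.bcm_ds) == (7, 3)

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("circular", [True, False])
    def test_matches_per_position_summation(self, rng, strand, circular):
        L = 2000
        b = rng.poisson(0.5, L).astype(float)
        u = rng.poisson(0.5, L).astype(float)
        for p in [0, 50, 700, 1000, 1999]:
            wc = window_counts(_track(b, strand), _track(u, strand),
                               _pos(p, strand), w=300, circular=circular)
            if strand == "+":
                us, ds = (p - 299, p + 1), (p + 1, p + 301)
            else:
                us, ds = (p, p + 300), (p - 300, p)
            assert wc.bcm_us == window_sum(b, *us, circular)
            assert wc.bcm_ds == window_sum(b, *ds, circular)
            assert wc.unt_us == window_sum(u, *us, circular)

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            window_counts(_track(np.ones(10)), _track(np.ones(10)), _pos(5), w=0)


class TestRhoScore:
    def test_two_fold_readthrough(self):
        assert rho_score(WindowCounts(150, 300, 120, 120)) == 2.0

    def test_equal_ratios_give_unity(self):
        assert rho_score(WindowCounts(10, 20, 5, 10)) == 1.0

    def test_pseudocount_applied_to_all_four(self):
        assert rho_score(WindowCounts(0, 50, 100, 100)) == (51 / 1) / (101 / 101)

    def test_all_zero_is_undefined(self):
        assert math.isnan(rho_score(WindowCounts(0, 0, 0, 0)))

    def test_scale_invariance_per_sample(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(1, 500, 4)
            base = rho_score(WindowCounts(a, b, c, d))
            scaled = rho_score(WindowCounts(7 * a, 7 * b, c, d))
            assert scaled == pytest.approx(base, rel=1e-12)

    def test_sample_swap_inverts(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(1, 500, 4)
            r = rho_score(WindowCounts(a, b, c, d))
            r_inv = rho_score(WindowCounts(c, d, a, b))
            assert r * r_inv == pytest.approx(1.0, rel=1e-12)


class TestSignificance:
    def test_matches_enumeration_oracle_sample(self, rng):
        for _ in range(50):
            a, b, c, d = (int(v) for v in rng.integers(0, 13, 4))
            got = significance(WindowCounts(bcm_us=b, bcm_ds=a, unt_us=d, unt_ds=c))
            if a + b == 0 or a + c == 0 or c + d == 0 or b + d == 0:
                assert got == 1.0
            else:
                assert got == pytest.approx(fisher_greater_enum(a, b, c, d), abs=1e-10)

    def test_matches_scipy_on_larger_tables(self, rng):
        for _ in range(25):
            a, b, c, d = (int(v) for v in rng.integers(1, 400, 4))
            got = significance(WindowCounts(bcm_us=b, bcm_ds=a, unt_us=d, unt_ds=c))
            ref = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert got == pytest.approx(ref, rel=1e-9)

    def test_extreme_table_equals_single_most_extreme_probability(self):
        got = significance(WindowCounts(bcm_us=0, bcm_ds=100, unt_us=100, unt_ds=0))
        assert got == pytest.approx(fisher_greater_enum(100, 0, 0, 100), rel=1e-9)

    def test_zero_margin_convention(self):
        assert significance(WindowCounts(0, 0, 10, 10)) == 1.0

    def test_monotone_in_downstream_enrichment(self):
        ps = [significance(WindowCounts(bcm_us=100, bcm_ds=a, unt_us=100, unt_ds=50))
              for a in range(50, 200, 10)]
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_deep_tail_does_not_underflow_to_garbage(self):
        p = significance(WindowCounts(bcm_us=10, bcm_ds=5000, unt_us=5000, unt_ds=10))
        assert 0 <= p < 1e-300


class TestScanGenome:
    def test_identical_samples_are_flat(self, sim):
        scores = scan_genome(sim.direct_untreated, sim.direct_untreated)
        assert (scores.rho_score == 1.0).all()
        assert (scores.p_value == 1.0).all()

    def test_agrees_with_point_queries(self, sim, rho_scores):
        sample = rho_scores.sample(50, random_state=0)
        positions = [GenomicPosition(r.chrom, int(r.position), r.strand)
                     for r in sample.itertuples()]
        pts = annotate_positions(positions, sim.direct_bcm, sim.direct_untreated)
        for row, pt in zip(sample.itertuples(), pts):
            assert (pt.counts.bcm_us, pt.counts.bcm_ds) == (row.bcm_us, row.bcm_ds)
            assert (pt.counts.unt_us, pt.counts.unt_ds) == (row.unt_us, row.unt_ds)
            assert pt.rho_score == pytest.approx(row.rho_score, rel=1e-9)
            if row.rho_score > 1:
                assert pt.p_value == pytest.approx(row.p_value, rel=1e-6, abs=1e-300)

    def test_mismatched_track_lengths_rejected(self):
        pair_a = (_track(np.ones(100)), _track(np.ones(100), "-"))
        pair_b = (_track(np.ones(80)), _track(np.ones(80), "-"))
        with pytest.raises(ValueError, match="length"):
            scan_genome(pair_a, pair_b)

    def test_planted_rho_sites_score_high(self, sim, rho_scores):
        truth = sim.truth
        by_pos = rho_scores.set_index(["position", "strand"])
        for r in truth[truth.type == "rho"].itertuples():
            row = by_pos.loc[(r.position, r.strand)]
            assert row.rho_score >= 2
            assert row.p_value < 1e-4

    def test_intrinsic_sites_score_near_unity(self, sim):
        truth = sim.truth
        intr = truth[truth.type != "rho"]
        pts = annotate_positions(
            [GenomicPosition("simchr", int(r.position), r.strand) for r in intr.itertuples()],
            sim.direct_bcm, sim.direct_untreated,
        )
        mean_r = np.mean([p.rho_score for p in pts])
        assert 0.8 <= mean_r <= 1.25


class TestCallRegions:
    def _frame(self, rows):
        return pd.DataFrame(
            rows,
            columns=["chrom", "position", "strand", "bcm_us", "bcm_ds", "unt_us",
                     "unt_ds", "rho_score", "p_value", "log10_p"],
        )

    def test_suppression_within_radius(self):
        rows = [
            ("chr", 1000, "+", 10, 40, 10, 10, 4.0, 1e-9, -9.0),
            ("chr", 1200, "+", 10, 30, 10, 10, 3.0, 1e-6, -6.0),
        ]
        regions = call_regions(self._frame(rows))
        assert len(regions) == 1
        assert regions[0].representative.position.position == 1000

    def test_distant_positions_both_reported(self):
        rows = [
            ("chr", 1000, "+", 10, 40, 10, 10, 4.0, 1e-9, -9.0),
            ("chr", 3000, "+", 10, 30, 10, 10, 3.0, 1e-6, -6.0),
        ]
        assert len(call_regions(self._frame(rows))) == 2

    def test_opposite_strands_do_not_suppress(self):
        rows = [
            ("chr", 1000, "+", 10, 40, 10, 10, 4.0, 1e-9, -9.0),
            ("chr", 1100, "-", 10, 30, 10, 10, 3.0, 1e-6, -6.0),
        ]
        assert len(call_regions(self._frame(rows))) == 2

    def test_alpha_and_positivity_filters(self):
        rows = [
            ("chr", 1000, "+", 10, 40, 10, 10, 0.9, 1e-9, -9.0),   # R <= 1
            ("chr", 3000, "+", 10, 30, 10, 10, 3.0, 1e-3, -3.0),   # p >= alpha
        ]
        assert call_regions(self._frame(rows)) == []

    def test_row_order_invariance(self, rho_scores):
        shuffled = rho_scores.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = [(r.representative.position.position, r.representative.position.strand)
             for r in call_regions(rho_scores)]
        b = [(r.representative.position.position, r.representative.position.strand)
             for r in call_regions(shuffled)]
        assert a == b


class TestAnnotatePositions:
    def test_signal_desert_flagged(self, sim):
        # intergenic deep desert: pick a position with no reads around
        pts = annotate_positions([_pos_at_desert(sim)], sim.direct_bcm,
                                 sim.direct_untreated, w=50)
        assert pts[0].low_coverage
        assert pts[0].p_value == 1.0

    def test_batch_equals_singletons(self, sim, rng):
        L = len(sim.genome)
        positions = [
            GenomicPosition("simchr", int(p), s)
            for p, s in zip(rng.integers(0, L, 100), rng.choice(["+", "-"], 100))
        ]
        batch = annotate_positions(positions, sim.direct_bcm, sim.direct_untreated)
        for pos, got in zip(positions, batch):
            (single,) = annotate_positions([pos], sim.direct_bcm, sim.direct_untreated)
            assert single.counts == got.counts
            assert (single.p_value == got.p_value) and (
                single.rho_score == got.rho_score
                or (math.isnan(single.rho_score) and math.isnan(got.rho_score))
            )


def _pos_at_desert(sim):
    combined = (
        sim.direct_bcm[0].counts + sim.direct_untreated[0].counts
    )
    window = np.convolve(combined, np.ones(101), mode="same")
    return GenomicPosition("simchr", int(np.argmin(window)), "+")
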