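"""Generator-level checks: determinism, invariants, closed-form oracles."""

import numpy as np
import pytest

import sporekit as sk
from sporekit.synth import intensity_fraction, released_fraction


class TestGenerateTruth:
    def test_deterministic_in_seed(self):
        p = sk.PopulationParams(n_spores=20, seed=7)
        a = sk.generate_truth(p)
        b = sk.generate_truth(sk.PopulationParams(n_spores=20, seed=7))
        assert [(s.x, s.y, s.t_lag, s.t_release) for s in a] == [
            (s.x, s.y, s.t_lag, s.t_release) for s in b
        ]

    def test_nongerminator_has_no_kinetics(self):
        (s,) = sk.generate_truth(sk.PopulationParams(n_spores=1, frac_germinating=0.0, seed=1))
        assert not s.germinates
        assert np.isnan(s.t_lag) and np.isnan(s.t_release) and np.isnan(s.t_lys)

    def test_time_ordering_invariant(self):
        truth = sk.generate_truth(
            sk.PopulationParams(n_spores=300, frac_germinating=1.0, seed=7)
        )
        assert len(truth) == 300
        for s in truth:
            assert s.t_lag <= s.t_release <= s.t_lys
            assert s.leak_slope * s.t_lag < 1.0
            assert 0.0 < s.i_release <= s.i_lag <= 1.0

    def test_lag_mean_matches_lognormal_closed_form(self):
        # E[lognormal(mu, s)] = exp(mu + s^2/2) ~ 10.46 min here
        p = sk.PopulationParams(
            n_spores=1000,
            frac_germinating=1.0,
            t_lag_dist=sk.DistSpec("lognormal", {"meanlog": np.log(10.0), "sdlog": 0.3}),
            seed=13,
        )
        lags = np.array([s.t_lag for s in sk.generate_truth(p)])
        expected = np.exp(np.log(10.0) + 0.3**2 / 2)
        se = lags.std(ddof=1) / np.sqrt(lags.size)
        assert abs(lags.mean() - expected) <= 3 * se

    def test_min_separation_respected(self):
        img = sk.ImagingParams(width=300, height=300)
        truth = sk.generate_truth(sk.PopulationParams(n_spores=30, seed=5), img)
        xy = np.array([(s.x, s.y) for s in truth], dtype=float)
        d2 = ((xy[:, None] - xy[None, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        assert d2.min() >= img.min_separation**2

    def test_infeasible_packing_raises(self):
        img = sk.ImagingParams(width=100, height=100)
        with pytest.raises(ValueError, match="place|capacity"):
            sk.generate_truth(sk.PopulationParams(n_spores=500, seed=0), img)


class TestRenderStack:
    def test_nongerminator_constant_amplitude(self):
        img = sk.ImagingParams(width=100, height=100, duration=10, noise_sd=0.0)
        s = sk.SporeTruth("s0", x=50, y=50, germinates=False)
        frames, _ = sk.render_stack([s], img, seed=0)
        assert frames[0, 50, 50] == frames[-1, 50, 50]
        assert frames[0, 50, 50] == img.background_level + img.spore_amplitude

    def test_center_pixel_at_release_breakpoint_exact(self):
        img = sk.ImagingParams(width=100, height=100, duration=35, noise_sd=0.0)
        s = sk.SporeTruth(
            "s0", x=50, y=50, germinates=True,
            t_lag=10.0, t_release=15.0, t_lys=30.0, leak_slope=0.0, i_release=0.4,
        )
        frames, _ = sk.render_stack([s], img, seed=0)
        # frame 60 is t = 15 min, the release breakpoint
        assert frames[60, 50, 50] == img.background_level + img.spore_amplitude * 0.4

    def test_center_trace_has_exactly_three_slope_changes(self):
        img = sk.ImagingParams(width=100, height=100, duration=40, noise_sd=0.0)
        s = sk.SporeTruth(
            "s0", x=50, y=50, germinates=True,
            t_lag=10.0, t_release=15.0, t_lys=30.0, leak_slope=0.0, i_release=0.4,
        )
        frames, _ = sk.render_stack([s], img, seed=0)
        trace = frames[:, 50, 50]
        curvature = np.diff(trace, 2)
        assert np.count_nonzero(np.abs(curvature) > 1e-9) == 3

    def test_overlapping_discs_rejected(self):
        img = sk.ImagingParams(width=100, height=100, duration=5)
        a = sk.SporeTruth("a", x=50, y=50, germinates=False)
        b = sk.SporeTruth("b", x=53, y=50, germinates=False)
        with pytest.raises(ValueError, match="overlap"):
            sk.render_stack([a, b], img, seed=0)

    def test_truncated_recording_flagged_in_roster(self):
        img = sk.ImagingParams(width=100, height=100, duration=10, noise_sd=0.0)
        s = sk.SporeTruth(
            "s0", x=50, y=50, germinates=True,
            t_lag=5.0, t_release=8.0, t_lys=20.0, leak_slope=0.0, i_release=0.4,
        )
        _, roster = sk.render_stack([s], img, seed=0)
        assert bool(roster["truncated"].iloc[0])


class TestPopulationFluorescence:
    def test_degenerate_population_flat_then_full(self):
        spores = [
            sk.SporeTruth(f"s{i}", 0, 0, True, t_lag=10.0, t_release=15.0, t_lys=30.0,
                          leak_slope=0.0, i_release=0.4)
            for i in range(10)
        ]
        curve = sk.generate_population_fluorescence(
            spores, total_signal=100.0, baseline=5.0, frame_interval=0.5, duration=20.0
        )
        assert np.allclose(curve.rfu[curve.times <= 10.0], 5.0)
        assert curve.rfu[curve.times == 15.0] == pytest.approx(105.0)
        assert curve.rfu[-1] == pytest.approx(105.0)

    def test_plateau_scales_with_germinating_fraction(self):
        truth = sk.generate_truth(
            sk.PopulationParams(n_spores=200, frac_germinating=0.5, seed=3)
        )
        curve = sk.generate_population_fluorescence(
            truth, total_signal=1000.0, baseline=50.0, duration=80.0
        )
        assert curve.rfu[-1] == pytest.approx(50.0 + 0.5 * 1000.0)

    def test_curve_equals_per_spore_summation(self):
        # independent oracle: scalar piecewise evaluation per spore/timepoint
        truth = sk.generate_truth(sk.PopulationParams(n_spores=40, seed=8))
        total, base = 500.0, 10.0
        curve = sk.generate_population_fluorescence(
            truth, total_signal=total, baseline=base, frame_interval=1.0, duration=50.0
        )
        expected = np.full_like(curve.times, base)
        for s in truth:
            for j, t in enumerate(curve.times):
                if not s.germinates:
                    continue
                if t < s.t_lag:
                    r = s.leak_slope * t
                elif t < s.t_release:
                    leaked = s.leak_slope * s.t_lag
                    r = leaked + (1 - leaked) * (t - s.t_lag) / (s.t_release - s.t_lag)
                else:
                    r = 1.0
                expected[j] += (total / len(truth)) * r
        assert np.allclose(curve.rfu, expected, rtol=1e-10)


class TestSurvivalCounts:
    def test_poisson_mean_monte_carlo(self):
        # cell (t=0, dilution 5): mean = 1e8 * 0.01 * 1e-5 = 10
        counts = np.array(
            [
                sk.generate_survival_counts(1e8, 5.0, [0.0], [5], seed=s)["count_rep1"].iloc[0]
                for s in range(1000)
            ],
            dtype=float,
        )
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - 10.0) <= 3 * se

    def test_one_d_value_is_tenfold(self):
        # at t = D the Poisson mean drops exactly 10-fold
        counts = np.array(
            [
                sk.generate_survival_counts(1e8, 5.0, [5.0], [4], seed=s)["count_rep1"].iloc[0]
                for s in range(1000)
            ],
            dtype=float,
        )
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - 10.0) <= 3 * se

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            sk.generate_survival_counts(1e8, 5.0, [-1.0], [5], seed=0)

    def test_deterministic_in_seed(self):
        a = sk.generate_survival_counts(1e8, 5.0, [0, 5], [3, 4], seed=2)
        b = sk.generate_survival_counts(1e8, 5.0, [0, 5], [3, 4], seed=2)
        assert a.equals(b)


class TestProteinSet:
    def test_counts_and_length_windows(self):
        records, labels = sk.generate_protein_set(5, 3, 2, seed=1)
        assert len(records) == 10
        for rec in records:
            if labels[rec.id] == "YetF-like":
                assert 210 <= rec.length <= 253
            elif labels[rec.id] == "2Duf-like":
                assert 285 <= rec.length <= 290
            else:
                assert not (210 <= rec.length <= 253 or 285 <= rec.length <= 290)

    def test_full_identity_returns_prototype(self):
        from sporekit.synth import YETF_PROTOTYPE

        rng = np.random.Generator(np.random.PCG64(0))
        assert sk.mutate_from_prototype(YETF_PROTOTYPE, 1.0, len(YETF_PROTOTYPE), rng) == YETF_PROTOTYPE

    def test_requested_identity_round_trip_through_aligner(self):
        from sporekit.census import global_align
        from sporekit.synth import YETF_PROTOTYPE

        rng = np.random.Generator(np.random.PCG64(3))
        for _ in range(5):
            mut = sk.mutate_from_prototype(YETF_PROTOTYPE, 0.60, 231, rng)
            pid = global_align(YETF_PROTOTYPE, mut).percent_identity
            assert 55.0 <= pid <= 65.0


class TestPiecewiseModel:
    def test_intensity_and_release_bracket_each_other(self):
        s = sk.SporeTruth(
            "s", 0, 0, True, t_lag=8.0, t_release=12.0, t_lys=20.0,
            leak_slope=0.01, i_release=0.4,
        )
        t = np.linspace(0, 25, 101)
        a = intensity_fraction(s, t)
        r = released_fraction(s, t)
        assert a[0] == 1.0 and r[0] == 0.0
        assert a[-1] == 0.0 and r[-1] == 1.0
        assert (np.diff(a) <= 1e-12).all() and (np.diff(r) >= -1e-12).all()
        # during lag the intensity drop equals the leaked fraction
        lag_mask = t <= 8.0
        assert np.allclose(1.0 - a[lag_mask], r[lag_mask])
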