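"""Data-side pipeline: filters, rate maps, phases, cycles, statistics."""

import numpy as np
import pytest

import thetaflicker.session_analysis as sa
from thetaflicker.session_analysis import (GAUSSIAN_KERNEL, SessionBundle,
                                           Trial, assign_spike_phases,
                                           band_power_ratio,
                                           correlation_thresholds,
                                           cycle_vectors, detect_flickers,
                                           lfp_theta_filter,
                                           partial_correlation_analysis,
                                           segment_by_min_phase,
                                           smooth_rate_map, speed_filter,
                                           trial_statistics)
from thetaflicker.flicker_detection import ThetaCycles
from thetaflicker.synthetic_session import synthetic_trial_stats


class TestSpeedFilter:
    def test_steady_walk_fully_valid(self):
        t = np.arange(0, 10, 0.02)
        xy = np.column_stack([10.0 * t, np.zeros_like(t)])  # 10 cm/s
        valid, speed = speed_filter(t, xy)
        assert valid.all()
        np.testing.assert_allclose(speed, 10.0)

    def test_stationary_animal_fully_invalid(self):
        t = np.arange(0, 5, 0.02)
        xy = np.full((t.size, 2), 30.0)
        valid, _ = speed_filter(t, xy)
        assert not valid.any()

    def test_gap_and_artifact_spans_masked(self):
        t = np.concatenate([np.arange(0, 1, 0.02),
                            np.arange(1.2, 2.2, 0.02)])   # 0.2 s gap at 1 s
        xy = np.column_stack([10.0 * t, np.zeros_like(t)])
        xy[80, 0] += 8.0    # ~200 cm/s glitch inside the second block
        valid, speed = speed_filter(t, xy)
        gap_left = np.argmin(np.abs(t - 0.98))
        gap_right = np.argmin(np.abs(t - 1.2))
        assert not valid[gap_left] and not valid[gap_right]
        # centered differences attribute the glitch to the neighbours
        assert not valid[79] and not valid[81]
        # far from gap and artifact: valid
        assert valid[10] and valid[95]


class TestRateMaps:
    def test_kernel_mass_is_exactly_one(self):
        assert GAUSSIAN_KERNEL.sum() == 1.0

    def test_smoothing_conserves_mass_on_interior_support(self):
        rate = np.zeros((30, 30))
        rate[10:20, 10:20] = np.arange(100).reshape(10, 10)
        visited = np.ones((30, 30), dtype=bool)
        sm = smooth_rate_map(rate, visited)
        assert sm.sum() == pytest.approx(rate.sum(), rel=5e-3)

    def test_single_interior_spike_peak_is_kernel_center(self):
        # uniform occupancy t0 per bin, one spike in one interior bin:
        # smoothed rate at that bin = 0.16 / t0
        t0 = 0.5
        rate = np.zeros((30, 30))
        rate[15, 15] = 1.0 / t0
        sm = smooth_rate_map(rate, np.ones((30, 30), dtype=bool))
        assert sm[15, 15] == pytest.approx(0.1600 / t0, rel=1e-12)

    def test_edge_renormalization_preserves_local_mean(self):
        # constant field must stay constant even at corners
        sm = smooth_rate_map(np.full((30, 30), 3.0),
                             np.ones((30, 30), dtype=bool))
        np.testing.assert_allclose(sm, 3.0, rtol=1e-12)

    def test_silent_cell_yields_zero_map(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 60, 0.02)
        ang = 2 * np.pi * 0.05 * t
        xy = np.column_stack([30 + 25 * np.cos(ang) * (1 + 0.5 * np.sin(0.3 * t)),
                              30 + 25 * np.sin(ang) * (1 + 0.5 * np.cos(0.2 * t))])
        bundle = SessionBundle(
            tracking_t=t, tracking_xy=xy,
            spikes=[np.array([]), np.array([10.0, 20.0])],
            lfp=rng.standard_normal(60 * 250), lfp_fs=250.0,
            trials=[Trial(kind="reference_A", interval=(0.0, 60.0),
                          environment="A")])
        maps = sa.compute_rate_maps(bundle)
        silent = maps.maps["A"][0]
        assert np.nanmax(silent) == 0.0


class TestLfpFilterAndPhases:
    FS = 1250.0

    def _tone(self, freq, duration=10.0):
        t = np.arange(int(duration * self.FS)) / self.FS
        return np.sin(2 * np.pi * freq * t), t

    @pytest.mark.parametrize("freq,keep", [(8.0, True), (2.0, False),
                                           (50.0, False)])
    def test_band_behavior(self, freq, keep):
        x, _ = self._tone(freq)
        y = lfp_theta_filter(x, self.FS)
        mid = np.abs(y[2000:-2000]).max()
        if keep:
            assert mid == pytest.approx(1.0, rel=0.1)
        else:
            assert mid < 0.1    # >= 20 dB down

    def test_spike_phase_convention_on_pure_tone(self):
        # cos tone: peaks at t = k/8, troughs midway
        t = np.arange(int(10 * self.FS)) / self.FS
        lfp = np.cos(2 * np.pi * 8.0 * t)
        filt = lfp_theta_filter(lfp, self.FS)
        period = 1 / 8.0
        spikes = np.array([5 * period,              # at a peak
                           5 * period + period / 2,  # at a trough
                           5 * period + period / 4])  # peak -> trough midpoint
        phases, kept = assign_spike_phases(filt, self.FS, spikes)
        assert kept.all()
        assert phases[0] == pytest.approx(0.0, abs=3.0) or \
            phases[0] == pytest.approx(360.0, abs=3.0)
        assert phases[1] == pytest.approx(180.0, abs=3.0)
        assert phases[2] == pytest.approx(90.0, abs=3.0)

    def test_min_phase_segmentation_opposite_concentration(self):
        rng = np.random.default_rng(0)
        t = np.arange(int(30 * self.FS)) / self.FS
        lfp = np.cos(2 * np.pi * 8.0 * t)
        filt = lfp_theta_filter(lfp, self.FS)
        # spikes clustered at phase 90 deg plus a sparse uniform background,
        # so the phase histogram has a unique minimum opposite the cluster
        base = np.arange(3, 200) / 8.0 + (1 / 32.0)
        cluster = base + rng.normal(0, 0.004, base.size)
        background = rng.uniform(base[0], base[-1], 150)
        spikes = np.sort(np.concatenate([cluster, background]))
        cycles = segment_by_min_phase(filt, self.FS, spikes)
        assert len(cycles) > 100
        durations = np.diff(cycles.intervals, axis=1)
        np.testing.assert_allclose(durations, 1 / 8.0, atol=0.01)
        # cut times sit in the sparse half of the cycle (not near spikes)
        cuts = cycles.intervals[:, 0]
        frac = np.mod(cuts, 1 / 8.0) * 8.0      # position within the period
        spike_frac = np.mod(base[0], 1 / 8.0) * 8.0
        dist = np.abs(((frac - spike_frac + 0.5) % 1.0) - 0.5)
        assert np.median(dist) > 0.25


class TestCycleVectors:
    def _bundle(self):
        t = np.arange(0, 20, 0.02)
        xy = np.column_stack([10.0 * np.mod(t, 4.0) + 5,
                              10.0 * np.mod(0.5 * t, 4.0) + 5])
        lfp = np.cos(2 * np.pi * 8.0 * np.arange(int(20 * 1250)) / 1250)
        return SessionBundle(
            tracking_t=t, tracking_xy=xy,
            spikes=[np.array([1.02, 1.04]), np.array([]),
                    np.array([1.01, 1.05, 1.09])],
            lfp=lfp, lfp_fs=1250.0, trials=[])

    def test_rates_from_known_counts(self):
        bundle = self._bundle()
        cycles = ThetaCycles(intervals=np.array([[1.0, 1.1], [1.1, 1.2]]),
                             fs=1250.0)
        vecs = cycle_vectors(bundle, cycles)
        np.testing.assert_allclose(vecs[0].rates, [20.0, 0.0, 30.0])
        np.testing.assert_allclose(vecs[1].rates, 0.0)

    def test_position_at_midpoint(self):
        bundle = self._bundle()
        cycles = ThetaCycles(intervals=np.array([[1.0, 1.1]]), fs=1250.0)
        v = cycle_vectors(bundle, cycles)[0]
        x = np.interp(1.05, bundle.tracking_t, bundle.tracking_xy[:, 0])
        assert v.position[0] == pytest.approx(x)


class TestThresholdsAndDetection:
    def test_percentile_convention_matches_linear_interpolation(self):
        vals = np.arange(1.0, 101.0)   # 1..100
        assert np.percentile(vals, 5.0) == pytest.approx(5.95)
        # the pipeline uses np.percentile's linear interpolation directly

    def test_proportional_vector_has_unit_correlation(self):
        a = np.array([1.0, 2.0, 5.0, 0.5])
        assert sa._pearson(3.0 * a, a) == pytest.approx(1.0)

    def _maps_and_vectors(self):
        """Two well-separated environments, hand-made expected rates."""
        rng = np.random.default_rng(3)
        n_cells = 20
        mapsA = rng.random((n_cells, 30, 30)) * 5
        mapsB = rng.random((n_cells, 30, 30)) * 5
        occ = np.ones((30, 30))
        rms = sa.RateMapSet(maps={"A": mapsA, "B": mapsB},
                            occupancy={"A": occ, "B": occ},
                            arena_origin=np.zeros(2))
        return rms, rng

    def test_detect_conjunction_rule(self):
        rms, rng = self._maps_and_vectors()
        pos = (10.0, 10.0)
        expA = rms.expected_rates("A", *pos)
        expB = rms.expected_rates("B", *pos)
        mk = lambda r: sa.CycleVector(interval=(0.0, 0.125), rates=r,
                                      position=pos)
        vecs = [mk(expB + rng.normal(0, 0.3, expB.size)),   # expresses B (old)
                mk(expA + rng.normal(0, 0.3, expA.size)),   # expresses A (new)
                mk(expA + expB)]                            # ambiguous mixture
        trial = Trial(kind="teleportation", interval=(0.0, 1.0),
                      switch_time=-1.0, env_before="B", env_after="A")
        low = {"A": 0.3, "B": 0.3}
        high = {"A": 0.3, "B": 0.3}
        events, first = detect_flickers(vecs, rms, low, high, trial)
        assert events[0].flagged            # old-map cycle
        assert not events[1].flagged        # current-map cycle
        assert not events[2].flagged        # correlated with both: conjunction fails
        assert first == 1

    def test_thresholds_separate_same_and_other(self):
        rms, rng = self._maps_and_vectors()
        refs = {"A": [], "B": []}
        for _ in range(120):
            x, y = rng.uniform(2, 58, 2)
            for env in ("A", "B"):
                exp = rms.expected_rates(env, x, y)
                refs[env].append(sa.CycleVector(
                    interval=(0.0, 0.125),
                    rates=np.clip(exp + rng.normal(0, 1.0, exp.size), 0, None),
                    position=(x, y)))
        low, high, dists = correlation_thresholds(refs, rms)
        for env in ("A", "B"):
            same = np.asarray(dists[env]["same"])
            other = np.asarray(dists[env]["other"])
            assert np.median(same) > np.median(other)
            assert low[env] == pytest.approx(np.percentile(same, 5.0))
            assert high[env] == pytest.approx(np.percentile(other, 95.0))
            # by construction ~5% of same-env cycles fall below the low bound
            frac = (same < low[env]).mean()
            assert frac == pytest.approx(0.05, abs=0.03)


class TestTrialStatistics:
    def _toy_inputs(self, n_flagged, n_cycles, invalid_frac):
        period = 0.125
        vecs, events = [], []
        rng = np.random.default_rng(0)
        for i in range(n_cycles):
            start = 10.0 + i * period
            valid = i >= int(invalid_frac * n_cycles)
            vecs.append(sa.CycleVector(interval=(start, start + period),
                                       rates=np.ones(3), position=(30.0, 30.0),
                                       valid=valid))
            events.append(sa.DataFlickerEvent(
                cycle_index=i, interval=(start, start + period),
                corr_current=0.0, corr_other=0.0, low_threshold=0,
                high_threshold=0, flagged=valid and i < n_flagged + int(
                    invalid_frac * n_cycles)))
        t = np.arange(0, 20, 0.02)
        xy = np.column_stack([30 + 10 * np.sin(t), 30 + 10 * np.cos(0.7 * t)])
        bundle = SessionBundle(tracking_t=t, tracking_xy=xy,
                               spikes=[np.arange(10, 16, 0.01)],
                               lfp=np.cos(2 * np.pi * 8 * np.arange(25000) / 1250),
                               lfp_fs=1250.0, trials=[])
        trial = Trial(kind="teleportation", interval=(5.0, 20.0),
                      switch_time=9.9, env_before="A", env_after="B")
        return bundle, trial, vecs, events

    def test_normalized_rate_formula(self):
        bundle, trial, vecs, events = self._toy_inputs(5, 40, 0.0)
        st = trial_statistics(bundle, trial, vecs, events, 0, window_s=5.0)
        assert not st.excluded
        assert st.flicker_rate == pytest.approx(5 / 5.0)

    def test_lowv_correction(self):
        bundle, trial, vecs, events = self._toy_inputs(4, 40, 0.2)
        st = trial_statistics(bundle, trial, vecs, events, 0, window_s=5.0)
        assert st.p_lowV == pytest.approx(0.2)
        assert st.flicker_rate == pytest.approx(4 / (0.8 * 5.0))

    def test_exclusion_above_half_lowv(self):
        bundle, trial, vecs, events = self._toy_inputs(2, 40, 0.6)
        st = trial_statistics(bundle, trial, vecs, events, 0, window_s=5.0)
        assert st.excluded
        assert "half" in st.reason

    def test_theta_power_ratio_of_pure_tone_near_one(self):
        # 8 Hz tone: essentially all wide-band power is in the theta band
        lfp = np.cos(2 * np.pi * 8 * np.arange(12500) / 1250)
        assert band_power_ratio(lfp, 1250.0) == pytest.approx(1.0, abs=0.05)


class TestPartialCorrelation:
    def test_flicker_equal_to_power_gives_unit_partial_r(self):
        rng = np.random.default_rng(0)
        stats = synthetic_trial_stats(40, seed=1)
        for s in stats:
            s.flicker_rate = s.theta_power   # identical up to affine map
        out = partial_correlation_analysis(stats, n_shuffles=99, seed=0)
        assert out["r_power"] == pytest.approx(1.0, abs=1e-6)
        assert out["p_power"] == pytest.approx(1 / 100)

    def test_constant_covariate_raises_by_name(self):
        stats = synthetic_trial_stats(15, seed=2)
        for s in stats:
            s.mean_rate = 2.0
        with pytest.raises(ValueError, match="mean_rate"):
            partial_correlation_analysis(stats, n_shuffles=10)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="10"):
            partial_correlation_analysis(synthetic_trial_stats(5), n_shuffles=10)

    def test_confounded_null_is_not_rejected_on_average(self):
        # power and distance share a confound but neither drives flickering:
        # p-values should be roughly uniform
        ps = []
        for rep in range(20):
            stats = synthetic_trial_stats(30, seed=100 + rep)
            out = partial_correlation_analysis(stats, n_shuffles=99,
                                               seed=rep)
            ps.append(out["p_power"])
        assert np.mean(ps) > 0.3
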