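"""Cleaning procedure: masks, thresholds, splitting, interpolation, blink
refinement, and ground-truth recovery — with brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oculomw._runs import find_runs, merge_runs, runs_to_mask
from oculomw.errors import DegenerateSignalError, ValidationError
from oculomw.preprocess import (
    BLINK,
    VALID,
    PreprocessParams,
    VelocityThresholds,
    clean_recording,
    compute_velocity_thresholds,
    conservative_blink_mask,
    detect_blink_bounds,
    flag_velocity_artifacts,
    interpolate_runs,
    pupil_velocity,
    split_artifacts,
    zero_runs,
)
from oculomw.synth import SimulationConfig, generate_session
from conftest import make_recording, match_blinks

FS = 240.0


def _pupil_with_zero_run(start_s, end_s, n_s=10.0, level=2000.0):
    pupil = np.full(int(n_s * FS), level)
    pupil[int(round(start_s * FS)):int(round(end_s * FS)) + 1] = 0.0
    return pupil


class TestConservativeMask:
    def test_padding_100ms_before_300ms_after(self):
        rec = make_recording(_pupil_with_zero_run(5.0, 5.2))
        mask, runs = conservative_blink_mask(rec)
        assert runs.shape[0] == 1
        start, end = runs[0]
        assert start / FS == pytest.approx(4.9)
        assert (end - 1) / FS == pytest.approx(5.5)

    def test_no_zeros_empty_mask(self):
        rec = make_recording(np.full(1000, 2000.0))
        mask, runs = conservative_blink_mask(rec)
        assert not mask.any() and runs.shape[0] == 0

    def test_close_runs_merge_matches_interval_union_oracle(self):
        # two zero-runs whose padded intervals end up 80 ms apart
        pupil = np.full(int(10 * FS), 2000.0)
        pupil[int(2.0 * FS):int(2.1 * FS)] = 0.0
        # padded: first ends 2.1 + 0.3 = 2.4, second starts 2.58 - 0.1 = 2.48,
        # i.e. an 80 ms gap after extension -> must merge
        pupil[int(2.58 * FS):int(2.7 * FS)] = 0.0
        rec = make_recording(pupil)
        mask, runs = conservative_blink_mask(rec)
        assert runs.shape[0] == 1
        # oracle: paint each padded interval on a boolean axis, take runs
        oracle = np.zeros(pupil.size, dtype=bool)
        for s, e in zero_runs(pupil):
            oracle[max(0, s - 24):min(pupil.size, e + 72)] = True
        # bridge gaps < 24 samples
        oruns = find_runs(oracle)
        merged = merge_runs(oruns, 24)
        np.testing.assert_array_equal(runs, merged)
        np.testing.assert_array_equal(mask, runs_to_mask(merged, pupil.size))


class TestVelocity:
    def test_constant_pupil_zero_velocity(self):
        assert np.all(pupil_velocity(np.full(50, 123.0)) == 0)

    def test_first_difference_values(self):
        np.testing.assert_array_equal(pupil_velocity([100.0, 103.0, 101.0]), [3, -2])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1e4), min_size=2, max_size=200))
    def test_matches_independent_diff_oracle(self, values):
        oracle = [b - a for a, b in zip(values, values[1:])]
        np.testing.assert_allclose(pupil_velocity(values), oracle)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            pupil_velocity([1.0])


class TestThresholds:
    def test_mean0_sd2_gives_pm3(self):
        thr = compute_velocity_thresholds(
            np.array([-2.0, 0.0, 2.0]), np.zeros(4, dtype=bool), a=1.5
        )
        assert (thr.low, thr.high) == (-3.0, 3.0)

    def test_a_zero_collapses_band(self):
        thr = compute_velocity_thresholds(
            np.array([-2.0, 0.0, 2.0]), np.zeros(4, dtype=bool), a=0.0
        )
        assert thr.low == thr.high == thr.mu

    def test_matches_bruteforce_on_masked_skewed_sample(self):
        rng = np.random.default_rng(3)
        v = rng.exponential(5.0, 500) - 2.0
        mask = rng.random(501) < 0.2
        thr = compute_velocity_thresholds(v, mask, a=1.5)
        kept = [v[i] for i in range(500) if not mask[i] and not mask[i + 1]]
        mu = sum(kept) / len(kept)
        sd = (sum((x - mu) ** 2 for x in kept) / (len(kept) - 1)) ** 0.5
        assert thr.mu == pytest.approx(mu)
        assert thr.sigma == pytest.approx(sd)
        assert thr.low == pytest.approx(mu - 1.5 * sd)
        assert thr.high == pytest.approx(mu + 1.5 * sd)

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            compute_velocity_thresholds(np.zeros(100), np.zeros(101, dtype=bool))


class TestArtifactFlagging:
    THR = VelocityThresholds(mu=0.0, sigma=1.0, a=1.5)

    def test_two_exceedances_12ms_apart_merge(self):
        v = np.zeros(100)
        v[50] = 10.0
        v[53] = -10.0  # ~12.5 ms later at 240 Hz
        runs = flag_velocity_artifacts(v, self.THR, FS)
        assert runs.shape[0] == 1

    def test_all_inside_band_no_runs(self):
        v = np.linspace(-1.4, 1.4, 100)
        assert flag_velocity_artifacts(v, self.THR, FS).shape[0] == 0

    def test_strict_inequality_at_threshold(self):
        v = np.zeros(10)
        v[4] = 1.5  # exactly at the bound: not flagged
        assert flag_velocity_artifacts(v, self.THR, FS).shape[0] == 0

    @pytest.mark.parametrize("a_small,a_big", [(0.5, 1.5), (1.0, 2.0)])
    def test_monotone_sensitivity_in_a(self, a_small, a_big):
        rng = np.random.default_rng(8)
        v = rng.normal(0, 1, 2000)
        mask = np.zeros(2001, dtype=bool)
        flagged = {}
        for a in (a_small, a_big):
            thr = compute_velocity_thresholds(v, mask, a=a)
            runs = flag_velocity_artifacts(v, thr, FS)
            flagged[a] = sum(int(e - s) for s, e in runs)
        assert flagged[a_small] >= flagged[a_big]


class TestSplitArtifacts:
    def test_spike_20ms_before_blink_absorbed(self):
        zero = np.array([[1200, 1250]])
        spike = np.array([[1200 - 5, 1200 - 4]])  # ~20 ms before the zero-run
        blink_iv, non_blink = split_artifacts(spike, zero, FS)
        assert non_blink.shape[0] == 0
        assert blink_iv.shape[0] == 1
        assert blink_iv[0, 0] == 1195 and blink_iv[0, 1] == 1250

    def test_isolated_spike_is_non_blink(self):
        zero = np.array([[1200, 1250]])
        spike = np.array([[2400, 2401]])  # 5 s away
        blink_iv, non_blink = split_artifacts(spike, zero, FS)
        assert non_blink.shape[0] == 1
        np.testing.assert_array_equal(blink_iv[0], zero[0])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_partition_exhaustive_and_exclusive(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        zero = np.sort(rng.choice(5000, size=4, replace=False))
        zero_runs_arr = np.array([[zero[0], zero[1]], [zero[2], zero[3]]])
        arts = []
        for _ in range(data.draw(st.integers(0, 8))):
            s = int(rng.integers(0, 6000))
            arts.append([s, s + int(rng.integers(1, 20))])
        arts = np.asarray(arts, dtype=np.int64).reshape(-1, 2)
        blink_iv, non_blink = split_artifacts(arts, zero_runs_arr, FS)
        window = int(round(0.1 * FS))
        for s, e in arts:
            gaps = [max(0, max(s, z0) - min(e, z1)) for z0, z1 in zero_runs_arr]
            related = min(gaps) <= window
            in_blink = any(b0 <= s and e <= b1 for b0, b1 in blink_iv)
            in_non_blink = any((s, e) == (u, v) for u, v in non_blink)
            assert in_blink == related
            assert in_non_blink == (not related)


class TestInterpolation:
    def test_linear_bridge(self):
        out = interpolate_runs(np.array([10.0, 0.0, 0.0, 16.0]), np.array([[1, 3]]))
        np.testing.assert_allclose(out, [10, 12, 14, 16])

    def test_empty_run_list_is_identity(self):
        x = np.arange(10.0)
        np.testing.assert_array_equal(interpolate_runs(x, np.empty((0, 2), int)), x)

    def test_boundary_run_filled_with_nearest(self):
        out = interpolate_runs(np.array([0.0, 0.0, 5.0, 7.0]), np.array([[0, 2]]))
        np.testing.assert_allclose(out, [5, 5, 5, 7])

    def test_full_record_run_rejected(self):
        with pytest.raises(ValidationError):
            interpolate_runs(np.zeros(5), np.array([[0, 5]]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 120)
        runs = []
        pos = 5
        while pos < 110:
            width = int(rng.integers(1, 6))
            runs.append([pos, pos + width])
            pos += width + int(rng.integers(2, 10))
        runs = np.asarray(runs)
        out = interpolate_runs(x, runs)
        oracle = x.copy()
        for s, e in runs:
            left, right = s - 1, e
            for i in range(s, e):
                frac = (i - left) / (right - left)
                oracle[i] = x[left] * (1 - frac) + x[right] * frac
        np.testing.assert_allclose(out, oracle)


class TestBlinkRefinement:
    def test_no_zero_runs_gives_empty_list(self):
        assert detect_blink_bounds(np.full(100, 2000.0), np.empty((0, 2), int), FS) == []

    def test_events_80ms_apart_merge_with_count(self):
        pupil = np.full(int(10 * FS), 2000.0)
        pupil += np.random.default_rng(0).normal(0, 5, pupil.size)
        pupil[int(3.0 * FS):int(3.1 * FS)] = 0.0
        pupil[int(3.18 * FS):int(3.3 * FS)] = 0.0  # 80 ms gap
        events = detect_blink_bounds(pupil, zero_runs(pupil), FS)
        assert len(events) == 1
        assert events[0].n_merged == 2

    def test_boundary_zero_run_clipped_and_flagged(self):
        pupil = np.full(int(5 * FS), 2000.0)
        pupil += np.random.default_rng(1).normal(0, 5, pupil.size)
        pupil[:24] = 0.0
        events = detect_blink_bounds(pupil, zero_runs(pupil), FS)
        assert len(events) == 1
        assert events[0].boundary
        assert events[0].onset == 0.0

    def test_refined_bounds_close_to_truth_with_boundary_spikes(self):
        """Synthetic blinks with <= 25%-of-baseline edge spikes: refined
        onsets/offsets land within 2 samples of the zero plateau (median)."""
        cfg = SimulationConfig(session_duration=300.0, seed=21,
                               boundary_spike_amplitude=500.0)
        bundle = generate_session(cfg)
        clean = clean_recording(bundle.recording)
        n, errs = match_blinks(bundle.ground_truth.true_blinks, clean.blinks, FS)
        assert n == len(bundle.ground_truth.true_blinks)
        assert np.median(errs) <= 2.0


class TestCleanRecording:
    def test_identity_on_clean_noiseless_data(self):
        cfg = SimulationConfig(
            session_duration=120.0, measurement_noise_sd=0.0,
            baseline_jitter_sd=0.0, blink_rate_F=0.0, blink_rate_MW=0.0,
            spurious_spike_rate=0.0, mean_MW_duration=1e9, seed=1,
        )
        bundle = generate_session(cfg)
        clean = clean_recording(bundle.recording)
        np.testing.assert_array_equal(clean.pupil, bundle.recording.pupil_area)
        assert clean.blinks == []
        assert np.all(clean.mask == VALID)

    def test_no_zero_samples_remain(self, clean_session):
        assert not np.any(clean_session.pupil == 0)

    def test_mask_partition_and_fraction_bounds(self, clean_session):
        assert set(np.unique(clean_session.mask)) <= {VALID, BLINK, 2, 3}
        f = clean_session.interpolated_fraction()
        assert 0.0 <= f <= 1.0

    def test_no_out_of_band_velocities_outside_joins(self, clean_session):
        thr = clean_session.thresholds
        v = np.diff(clean_session.pupil)
        out = (v > thr.high) | (v < thr.low)
        # exceedances may only sit at the joins of interpolated segments
        altered = clean_session.mask != VALID
        near_join = altered[:-1] | altered[1:]
        assert not np.any(out & ~near_join)

    def test_blink_recovery_on_defaults(self):
        """Two default 5-min sessions: every injected blink recovered, no
        spurious events, onsets accurate to 2 samples (median)."""
        all_errs = []
        for seed in (31, 32):
            bundle = generate_session(SimulationConfig(session_duration=300.0,
                                                       seed=seed))
            clean = clean_recording(bundle.recording)
            truth = bundle.ground_truth.true_blinks
            n, errs = match_blinks(truth, clean.blinks, FS)
            assert n / len(truth) >= 0.95
            assert n / len(clean.blinks) >= 0.95
            all_errs.extend(errs)
        assert np.median(all_errs) <= 2.0

    def test_constant_recording_is_degenerate(self):
        rec = make_recording(np.full(1000, 2000.0))
        with pytest.raises(DegenerateSignalError):
            clean_recording(rec)


class TestMergeOrderIndependence:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), gap=st.integers(1, 30))
    def test_permuting_runs_leaves_merge_invariant(self, seed, gap):
        rng = np.random.default_rng(seed)
        runs = []
        pos = 0
        for _ in range(10):
            pos += int(rng.integers(1, 40))
            width = int(rng.integers(1, 10))
            runs.append([pos, pos + width])
            pos += width
        runs = np.asarray(runs)
        merged = merge_runs(runs, gap)
        shuffled = runs[rng.permutation(len(runs))]
        np.testing.assert_array_equal(merge_runs(shuffled, gap), merged)
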