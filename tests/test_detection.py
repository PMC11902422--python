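"""Sample-entropy computation and the epoch detection state machine."""

import numpy as np
import pytest
from scipy import signal as sps

import isoemg
from isoemg.detection import SampEnParams


def brute_force_sampen(x, m, r):
    """Independent O(N^2) enumeration of matching template pairs.

    Templates of lengths m and m + 1 are both counted over the first
    N - m starting positions, Chebyshev distance, self-matches excluded.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)

    def count(length):
        c = 0
        for i in range(n - m):
            for j in range(n - m):
                if i == j:
                    continue
                d = max(abs(x[i + k] - x[j + k]) for k in range(length))
                if d <= r:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return None
    return -np.log(a / b)


class TestSampleEntropy:
    def test_constant_sequence_is_zero(self):
        assert isoemg.sample_entropy(np.full(32, 2.0), m=2, r=0.5) == 0.0

    def test_repeating_pattern_matches_oracle(self):
        x = np.tile([1.0, 2.0, 3.0], 4)  # N = 12
        expected = brute_force_sampen(x, m=2, r=0.5)
        assert isoemg.sample_entropy(x, m=2, r=0.5) == pytest.approx(
            expected, abs=1e-12
        )

    def test_uniform_noise_matches_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            x = rng.uniform(size=64)
            r = 0.25 * np.std(x)
            expected = brute_force_sampen(x, 2, r)
            assert isoemg.sample_entropy(x, 2, r) == pytest.approx(
                expected, abs=1e-12
            )

    def test_nonnegative(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x = rng.standard_normal(40)
            assert isoemg.sample_entropy(x, 2, 0.2 * np.std(x)) >= 0.0

    def test_degenerate_returns_finite_cap(self):
        # r so small that no m+1 templates match: capped, finite, positive
        x = np.arange(20.0) ** 2
        v = isoemg.sample_entropy(x, 2, 1e-12)
        assert np.isfinite(v) and v > 0

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            isoemg.sample_entropy([1.0, 2.0], m=2, r=0.5)


class TestSampEnSeries:
    @pytest.mark.parametrize("n, expected_starts", [
        (64, [0]),
        (124, [0, 30, 60]),
    ])
    def test_window_count_formula(self, n, expected_starts):
        rng = np.random.default_rng(9)
        s = isoemg.sampen_series(rng.standard_normal(n))
        assert list(s.window_start_samples) == expected_starts
        assert len(s.values) == len(expected_starts)

    def test_constant_trial_all_zero(self):
        s = isoemg.sampen_series(np.full(200, 1.0))
        np.testing.assert_array_equal(s.values, 0.0)

    def test_global_tolerance(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(500)
        s = isoemg.sampen_series(x)
        assert s.r == pytest.approx(0.25 * np.std(x))

    def test_short_trial_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            isoemg.sampen_series(np.ones(10))


def _two_burst_trial(rng, n=6000, offsets=(1000, 3600), burst_len=1500,
                     snr_db=20.0):
    """Baseline band-limited noise with noise bursts at known offsets.

    The ~50% burst duty cycle matches the alternating-curl protocol; the
    global SampEn tolerance r = 0.25 * SD(trial) relies on the bursts
    dominating the trial's variance, so sparse-activity trials need a higher
    SNR for the same contrast.
    """
    fs = 1000.0
    sos = sps.butter(4, (20, 250), btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    x /= x.std()
    gain = 10 ** (snr_db / 20.0)
    for s in offsets:
        burst = sps.sosfiltfilt(sos, rng.standard_normal(burst_len))
        burst *= np.hanning(burst_len)
        burst /= burst.std()  # unit RMS over the whole burst
        x[s : s + burst_len] += gain * burst
    return x, fs


class TestDetectEpochs:
    def test_all_zero_trial_empty(self):
        x = np.zeros(5000)
        s = isoemg.sampen_series(x)
        assert isoemg.detect_epochs(s, x) == []

    def test_two_known_bursts_recovered_at_20db(self):
        rng = np.random.default_rng(11)
        x, fs = _two_burst_trial(rng, snr_db=20.0)
        params = SampEnParams()
        smoothed = isoemg.moving_average(isoemg.half_wave_rectify(x), 5)
        series = isoemg.sampen_series(smoothed, params)
        found = isoemg.detect_epochs(series, x, params)
        assert len(found) == 2

    def test_burst_boundaries_sharp_at_high_snr(self):
        # boundary-accurate marking needs clearly dominant bursts: with the
        # 2%/1% relative thresholds the baseline entropy must sit below 1%
        # of the series maximum, which holds from roughly 24 dB up (the
        # synthetic generator's default operating point)
        rng = np.random.default_rng(11)
        x, fs = _two_burst_trial(rng, snr_db=24.0)
        params = SampEnParams()
        smoothed = isoemg.moving_average(isoemg.half_wave_rectify(x), 5)
        series = isoemg.sampen_series(smoothed, params)
        found = isoemg.detect_epochs(series, x, params)
        assert len(found) == 2
        tol = params.step * max(params.start_count, params.end_count) + params.window
        for (s, e), true_s in zip(found, (1000, 3600)):
            assert abs(s - true_s) <= tol
            assert abs(e - (true_s + 1500)) <= tol

    def test_short_burst_rejected_by_min_length(self):
        rng = np.random.default_rng(12)
        x, fs = _two_burst_trial(rng, n=3000, offsets=(1100,), burst_len=800,
                                 snr_db=26.0)
        smoothed = isoemg.moving_average(isoemg.half_wave_rectify(x), 5)
        series = isoemg.sampen_series(smoothed)
        assert isoemg.detect_epochs(series, x) == []

    def test_raising_amp_factor_never_adds_epochs(self):
        rng = np.random.default_rng(13)
        x, fs = _two_burst_trial(rng)
        smoothed = isoemg.moving_average(isoemg.half_wave_rectify(x), 5)
        series = isoemg.sampen_series(smoothed)
        counts = []
        for amp in (0.0, 0.2, 0.35, 0.6, 0.9, 1.01):
            params = SampEnParams(amp_factor=amp)
            counts.append(len(isoemg.detect_epochs(series, x, params)))
        assert counts == sorted(counts, reverse=True)

    def test_detected_intervals_disjoint_ordered_long_enough(self):
        rng = np.random.default_rng(14)
        x, fs = _two_burst_trial(rng)
        smoothed = isoemg.moving_average(isoemg.half_wave_rectify(x), 5)
        params = SampEnParams()
        found = isoemg.detect_epochs(isoemg.sampen_series(smoothed, params),
                                     x, params)
        for (s0, e0), (s1, _) in zip(found, found[1:]):
            assert e0 <= s1
        assert all(e - s > params.min_len for s, e in found)


class TestPropagateEpochs:
    def test_interval_cut_from_all_arm_channels(self):
        rng = np.random.default_rng(15)
        channels = {c: rng.standard_normal(5000) for c in ("C1", "C2", "C5", "C6")}
        out = isoemg.propagate_epochs([(1000, 3000)], channels)
        assert len(out) == 4
        assert {e.channel for e in out} == {"C1", "C2", "C5", "C6"}
        for e in out:
            assert len(e) == 2000
            np.testing.assert_array_equal(
                e.samples, channels[e.channel][1000:3000]
            )

    def test_empty_interval_list(self):
        out = isoemg.propagate_epochs([], {"C1": np.zeros(100)})
        assert len(out) == 0

    def test_out_of_bounds_raises(self):
        with pytest.raises(ValueError, match="out of bounds"):
            isoemg.propagate_epochs([(0, 200)], {"C1": np.zeros(100)})


class TestDetectTrial:
    def test_recovers_all_cycles_per_channel(self):
        prof = isoemg.SubjectProfile("S1", "amateur", seed=21)
        rec, gt = isoemg.generate_trial(prof, n_cycles=6, trial_seed=1)
        eps, log = isoemg.detect_trial(rec)
        per_channel = {}
        for e in eps:
            per_channel.setdefault(e.channel, []).append(e)
        assert set(per_channel) == set(isoemg.CHANNEL_NAMES)
        assert all(len(v) == 6 for v in per_channel.values())

    def test_boundaries_near_ground_truth(self):
        prof = isoemg.SubjectProfile("S1", "amateur", seed=22)
        rec, gt = isoemg.generate_trial(prof, n_cycles=6, trial_seed=2)
        eps, log = isoemg.detect_trial(rec)
        params = SampEnParams()
        tol = params.step * max(params.start_count, params.end_count) + params.window
        found = sorted(log["intervals"]["C1"])
        true = gt.intervals["C1"]
        assert len(found) == len(true)
        for (fs_, fe), (ts, te) in zip(found, true):
            assert abs(fs_ - ts) <= tol
            assert abs(fe - te) <= tol

    def test_thirty_epochs_per_channel_for_five_trials(self, small_epochs):
        eps, log = small_epochs
        # 2 trials x 6 cycles = 12 epochs per channel per subject here
        for counts in log["counts"].values():
            assert all(v == 12 for v in counts.values())
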