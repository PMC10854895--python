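"""Morlet power, artifact masking, baseline normalization, band averages."""

import dataclasses

import numpy as np
import pytest

from twostep_hippo import preprocess, spectral, task
from twostep_hippo.preprocess import EpochSet
from twostep_hippo.spectral import (
    EpochedTF,
    band_average,
    baseline_normalize,
    default_freqs,
    mask_peck_artifacts,
    morlet_power,
    moving_average,
    power_dynamics,
    slice_window,
)


def _tone_epochs(freq_hz, n_trials=2, amp=1.0, fs=1000.0, dur=3.5):
    t = np.arange(int(dur * fs)) / fs
    sig = amp * np.sin(2 * np.pi * freq_hz * t)
    data = np.tile(sig, (n_trials, 2, 1))
    trials = [
        task.TrialRecord(
            session_idx=0, trial_idx=i, choice=0, second_state=0, rewarded=True,
            t_s1_onset=10.0 * i + 4.0, t_step1_peck=10.0 * i + 5.0,
            t_s2_onset=10.0 * i + 5.05, t_step2_peck=10.0 * i + 5.8,
            reaction_time_s=1.0,
        )
        for i in range(n_trials)
    ]
    return EpochSet(
        data={"full": data}, fs=fs, windows={"full": (-2.5, 1.0)}, trials=trials
    )


class TestMorletPower:
    def test_tone_peaks_at_nearest_bin_fft_crosscheck(self):
        """Morlet power of a 20 Hz tone peaks at the bin nearest 20 Hz and
        dwarfs the 5 Hz bin; the peak location is cross-checked against an
        FFT periodogram oracle."""
        ep = _tone_epochs(20.0)
        tf = morlet_power(ep)
        spectrum = tf.power.mean(axis=(0, 1, 3))
        peak_freq = tf.freqs[np.argmax(spectrum)]
        # FFT oracle for the dominant frequency
        x = ep.data["full"][0, 0]
        fft_freqs = np.fft.rfftfreq(len(x), 1 / ep.fs)
        fft_peak = fft_freqs[np.argmax(np.abs(np.fft.rfft(x)))]
        nearest_bin = tf.freqs[np.argmin(np.abs(tf.freqs - fft_peak))]
        assert peak_freq == pytest.approx(nearest_bin)
        i5 = np.argmin(np.abs(tf.freqs - 5.0))
        assert spectrum.max() >= 10 * spectrum[i5]

    def test_zero_signal_zero_power(self):
        ep = _tone_epochs(20.0, amp=0.0)
        tf = morlet_power(ep)
        np.testing.assert_allclose(tf.power, 0.0, atol=1e-20)

    def test_amplitude_doubling_quadruples_power(self):
        p1 = morlet_power(_tone_epochs(20.0, amp=1.0)).power
        p2 = morlet_power(_tone_epochs(20.0, amp=2.0)).power
        np.testing.assert_allclose(p2, 4.0 * p1, rtol=1e-4)

    def test_tone_power_decays_with_log_frequency_distance(self):
        tf = morlet_power(_tone_epochs(20.0))
        spectrum = tf.power.mean(axis=(0, 1, 3))
        k = int(np.argmax(spectrum))
        within = (tf.freqs >= 10.0) & (tf.freqs <= 40.0)  # +/- 1 octave
        idx = np.nonzero(within)[0]
        up = idx[idx >= k]
        down = idx[idx <= k][::-1]
        assert np.all(np.diff(spectrum[up]) <= 1e-12)
        assert np.all(np.diff(spectrum[down]) <= 1e-12)

    def test_frequency_grid_is_log_spaced(self):
        f = default_freqs()
        assert len(f) == 50 and f[0] == 1.0 and f[-1] == pytest.approx(100.0)
        steps = np.diff(np.log(f))
        np.testing.assert_allclose(steps, steps[0], rtol=1e-9)


class TestMaskPeckArtifacts:
    def test_samples_near_pecks_masked(self, lfp_chain):
        tf = lfp_chain["tf"]
        for i, tr in enumerate(tf.trials[:5]):
            sel = np.abs(tf.times - 0.0) <= 0.05
            assert np.all(np.isnan(tf.power[i, :, :, sel]))
            t2 = tr.t_step2_peck - tr.t_step1_peck
            sel2 = np.abs(tf.times - t2) <= 0.05
            assert np.all(np.isnan(tf.power[i, :, :, sel2]))

    def test_no_pecks_in_span_identity(self):
        ep = _tone_epochs(20.0)
        tf = morlet_power(ep)
        # step-2 peck at +0.8 s is inside the span; shift window so no peck is
        masked = mask_peck_artifacts(dataclasses.replace(tf, times=tf.times - 10.0))
        np.testing.assert_array_equal(masked.power, tf.power)

    def test_masked_mean_unbiased_by_artifact(self):
        """A transient at the peck biases the unmasked mean; the masked mean
        stays within 5% of the artifact-free truth."""
        # 60 Hz carrier: the wavelet there is short enough that the +/-50 ms
        # mask covers the artifact's spectral smear
        ep = _tone_epochs(60.0, n_trials=1)
        clean_tf = morlet_power(ep)
        # inject a transient 20 ms around the step-1 peck (t = 0)
        dirty = _tone_epochs(60.0, n_trials=1)
        i0 = int((2.5 - 0.01) * ep.fs)
        dirty.data["full"][:, :, i0 : i0 + 20] += 30.0
        dirty_tf = morlet_power(dirty)
        masked_tf = mask_peck_artifacts(dirty_tf)
        sel = (clean_tf.times >= -0.5) & (clean_tf.times < 0.5)
        i60 = np.argmin(np.abs(clean_tf.freqs - 60.0))
        truth = clean_tf.power[0, 0, i60, sel].mean()
        unmasked = dirty_tf.power[0, 0, i60, sel].mean()
        masked = np.nanmean(masked_tf.power[0, 0, i60, sel])
        assert unmasked > 1.5 * truth
        assert abs(masked - truth) / truth < 0.05


class TestBaselineNormalize:
    def test_statistically_identical_epoch_normalizes_to_one(self, rng):
        power = rng.gamma(2.0, 1.0, size=(6, 4, 10, 300)).astype(np.float32)
        tf = EpochedTF(power=power, freqs=np.linspace(1, 10, 10),
                       times=np.linspace(-2.5, 0.5, 300), trials=[None] * 6)
        base = slice_window(tf, (-2.5, -2.0))
        out = baseline_normalize(tf, base)
        assert out.normalized
        assert np.nanmean(out.power) == pytest.approx(1.0, abs=0.05)

    def test_threefold_power_ratio(self):
        power = np.ones((1, 2, 3, 100), dtype=np.float32)
        times = np.linspace(-2.5, 0.99, 100)
        power[..., times >= -2.0] = 3.0
        tf = EpochedTF(power=power, freqs=np.array([1.0, 2.0, 4.0]), times=times,
                       trials=[None])
        out = baseline_normalize(tf, slice_window(tf, (-2.5, -2.0)))
        assert np.nanmean(out.power[..., times >= -2.0]) == pytest.approx(3.0)

    def test_recording_scale_invariance(self, rng):
        """Scaling the whole recording by c cancels in normalized power."""
        power = rng.gamma(2.0, 1.0, size=(3, 2, 5, 200)).astype(np.float32)
        times = np.linspace(-2.5, 0.99, 200)
        tf1 = EpochedTF(power=power, freqs=np.arange(1, 6.0), times=times, trials=[None] * 3)
        tf2 = EpochedTF(power=power * 7.3**2, freqs=np.arange(1, 6.0), times=times,
                        trials=[None] * 3)
        out1 = baseline_normalize(tf1, slice_window(tf1, (-2.5, -2.0)))
        out2 = baseline_normalize(tf2, slice_window(tf2, (-2.5, -2.0)))
        np.testing.assert_allclose(out1.power, out2.power, rtol=1e-5)

    def test_late_high_band_power_exceeds_early(self, lfp_chain):
        """The planted value-coupled bursts raise late-trial high-band
        normalized power above early trials for the rewarded states."""
        tf = lfp_chain["tf"]
        trials = tf.trials
        bp = band_average(tf, (-0.5, 0.0))
        hb = np.nanmean(bp.group("high"), axis=1)
        n = len(trials)
        choice = np.array([t.choice for t in trials])
        early = hb[(np.arange(n) < n // 3)]
        late = hb[(np.arange(n) >= 2 * n // 3) & (choice == task.S1_PLUS)]
        assert np.nanmean(late) > np.nanmean(early)


class TestBandAverage:
    def _uniform_tf(self, value=1.0):
        power = np.full((2, 3, 50, 200), value, dtype=np.float32)
        return EpochedTF(power=power, freqs=default_freqs(),
                         times=np.linspace(-1.0, 0.99, 200), trials=[None, None],
                         normalized=True)

    def test_uniform_power_every_band_one(self):
        bp = band_average(self._uniform_tf(1.0), (-0.5, 0.0))
        np.testing.assert_allclose(bp.values, 1.0)

    def test_power_at_45hz_lands_in_low_gamma(self):
        tf = self._uniform_tf(0.0)
        i45 = np.argmin(np.abs(tf.freqs - 45.0))
        tf.power[:, :, i45, :] = 100.0
        bp = band_average(tf, (-0.5, 0.0))
        bands = dict(zip(bp.bands, range(len(bp.bands))))
        assert np.all(bp.values[:, :, bands["low_gamma"]] > 50 * np.maximum(
            bp.values[:, :, bands["delta"]], 1e-9))

    def test_band_edges_as_printed(self):
        assert spectral.BANDS == {
            "delta": (1.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 12.0),
            "beta": (12.0, 30.0), "low_gamma": (30.0, 60.0), "high_gamma": (60.0, 100.0),
        }

    def test_unnormalized_input_rejected(self):
        tf = self._uniform_tf()
        tf.normalized = False
        with pytest.raises(ValueError):
            band_average(tf, (-0.5, 0.0))


class TestPowerDynamics:
    def test_smoother_preserves_constants(self):
        out = moving_average(np.full(20, 2.5), 5)
        np.testing.assert_allclose(out, 2.5)

    def test_step_input_monotone_through_step(self):
        x = np.r_[np.zeros(30), np.ones(30)]
        sm = moving_average(x, 5)
        assert np.all(np.diff(sm) >= -1e-12)
        # oracle: interior smoothed values equal the 5-point window mean
        for i in range(2, 58):
            assert sm[i] == pytest.approx(x[i - 2 : i + 3].mean())

    def test_session_curves_from_band_power(self, lfp_chain):
        tf = lfp_chain["tf"]
        bp = band_average(tf, (-0.5, 0.0))
        raw, smooth = power_dynamics(bp, "high", n_sessions=3)
        assert raw.shape == (3,) and smooth.shape == (3,)
        assert np.all(np.isfinite(raw))
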