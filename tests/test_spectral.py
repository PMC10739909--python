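"""Wavelet power, baseline z-normalization, and channel selection."""

import numpy as np
import pandas as pd
import pytest

import thetaflow as tf
from thetaflow.spectral import wavelet_freq_grid


def _epochs_from_array(data, fs=500.0, window=(-1.0, 1.0),
                       conditions=None):
    n_tr, n_t, n_ch = data.shape
    conditions = conditions or ["lure+"] * n_tr
    events = pd.DataFrame({
        "trial_id": np.arange(n_tr), "phase": ["retrieval"] * n_tr,
        "onset_s": 10.0 * np.arange(n_tr) + 5.0,
        "response_s": 10.0 * np.arange(n_tr) + 6.5,
        "condition": conditions, "correct": [1] * n_tr,
    })
    channels = pd.DataFrame({
        "label": [f"C{i+1}" for i in range(n_ch)],
        "region": ["FRO"] * n_ch, "probe": ["P1"] * n_ch,
        "contact_index": np.arange(1, n_ch + 1),
    })
    return tf.EpochSet(data=data, sfreq=fs, alignment="onset",
                       window=window, events=events, channels=channels)


def _tone_epochs(freq, amp=1.0, n_tr=2, fs=500.0, window=(-1.0, 1.0)):
    t = window[0] + np.arange(int((window[1] - window[0]) * fs)) / fs
    sig = amp * np.cos(2 * np.pi * freq * t)
    data = np.tile(sig[None, :, None], (n_tr, 1, 1))
    return _epochs_from_array(data, fs=fs, window=window)


class TestFrequencyGrid:
    def test_log_spacing_with_32_voices(self):
        cfg = tf.WaveletConfig()
        freqs = wavelet_freq_grid(cfg, 500.0)
        assert freqs[0] == pytest.approx(3.0)
        ratios = freqs[1:] / freqs[:-1]
        np.testing.assert_allclose(ratios, 2.0 ** (1 / 32), rtol=1e-12)
        assert freqs[-1] <= 200.0

    def test_grid_truncated_at_nyquist(self):
        cfg = tf.WaveletConfig()
        freqs = wavelet_freq_grid(cfg, 200.0)
        assert freqs[-1] < 100.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            tf.WaveletConfig(f_min=10.0, f_max=5.0)


class TestMorletPower:
    def test_tone_peak_at_nearest_grid_frequency(self):
        cfg = tf.WaveletConfig(f_min=3.0, f_max=20.0)
        power = tf.morlet_power(_tone_epochs(5.0), cfg)
        mid = power.power_db.shape[-1] // 2
        spectrum = power.power_db[0, 0, :, mid]
        nearest = np.argmin(np.abs(power.freqs - 5.0))
        assert np.argmax(spectrum) == nearest

    def test_double_amplitude_adds_6db(self):
        cfg = tf.WaveletConfig(f_min=3.0, f_max=20.0)
        p1 = tf.morlet_power(_tone_epochs(5.0, amp=1.0), cfg)
        p2 = tf.morlet_power(_tone_epochs(5.0, amp=2.0), cfg)
        mid = p1.power_db.shape[-1] // 2
        peak = np.argmin(np.abs(p1.freqs - 5.0))
        delta = p2.power_db[0, 0, peak, mid] - p1.power_db[0, 0, peak, mid]
        assert delta == pytest.approx(20 * np.log10(2), abs=0.05)


class TestBaselineZscore:
    def _noise_epochs(self, n_tr=12, n_ch=1, seed=0, conditions=None):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((n_tr, 1000, n_ch))
        return _epochs_from_array(data, conditions=conditions)

    def test_baseline_self_normalizes_per_condition(self):
        conds = ["lure+"] * 6 + ["lure-"] * 6
        ep = self._noise_epochs(conditions=conds)
        power = tf.morlet_power(ep, tf.WaveletConfig(f_min=4.0, f_max=8.0))
        z = tf.baseline_zscore(power, baseline_window=(-0.5, 0.0))
        cols = np.flatnonzero((z.times >= -0.5) & (z.times < 0.0))
        for cond in ("lure+", "lure-"):
            rows = z.conditions == cond
            base = z.z[rows][:, :, :, cols]
            assert abs(base.mean()) < 1e-9
            assert base.std() == pytest.approx(1.0, abs=1e-6)

    def test_planted_step_recovers_z_of_two(self):
        """A post-onset power step of 2 baseline SDs maps to z ~ 2."""
        ep = self._noise_epochs(n_tr=8)
        power = tf.morlet_power(ep, tf.WaveletConfig(f_min=4.0, f_max=6.0))
        # plant directly in dB space: mu + 2*sd after onset at one freq
        cols_base = power.time_cols((-0.5, 0.0))
        cols_post = power.time_cols((0.2, 0.8))
        base = power.power_db[:, 0, 0, cols_base]
        mu, sd = base.mean(), base.std()
        power.power_db[:, 0, 0, cols_post] = mu + 2 * sd
        z = tf.baseline_zscore(power, baseline_window=(-0.5, 0.0))
        got = z.z[:, 0, 0, cols_post].mean()
        assert got == pytest.approx(2.0, abs=0.15)

    def test_unknown_mode_rejected(self):
        ep = self._noise_epochs()
        power = tf.morlet_power(ep, tf.WaveletConfig(f_min=4.0, f_max=6.0))
        with pytest.raises(ValueError, match="mode"):
            tf.baseline_zscore(power, mode="bogus")

    def test_gain_invariance_of_z(self):
        """A global signal rescaling cancels in the dB/z pipeline."""
        ep = self._noise_epochs(n_tr=6)
        power_a = tf.morlet_power(ep, tf.WaveletConfig(f_min=4.0, f_max=6.0))
        ep_scaled = _epochs_from_array(ep.data * 7.5)
        power_b = tf.morlet_power(ep_scaled,
                                  tf.WaveletConfig(f_min=4.0, f_max=6.0))
        za = tf.baseline_zscore(power_a)
        zb = tf.baseline_zscore(power_b)
        np.testing.assert_allclose(za.z, zb.z, atol=1e-8)


class TestAverageAndOffset:
    def _zset(self, n_tr=4, seed=0, conditions=None):
        rng = np.random.default_rng(seed)
        ep = _epochs_from_array(rng.standard_normal((n_tr, 1000, 1)),
                                conditions=conditions)
        power = tf.morlet_power(ep, tf.WaveletConfig(f_min=4.0, f_max=6.0))
        return tf.baseline_zscore(power)

    def test_trace_offset_window_mean_is_zero(self):
        z = self._zset()
        traces = tf.average_and_offset(z, band=(4.0, 6.0))
        cols = np.flatnonzero((z.times >= -0.2) & (z.times < 0.0))
        for trace in traces.values():
            assert abs(trace[:, cols].mean()) < 1e-10

    def test_single_trial_average_is_that_trial(self):
        z = self._zset(n_tr=1)
        avg = tf.average_and_offset(z, offset_window=(0.0, 0.0))
        np.testing.assert_allclose(avg["lure+"], z.z[0])

    def test_opposite_trials_average_to_zero(self):
        z = self._zset(n_tr=2)
        z.z[1] = -z.z[0]
        avg = tf.average_and_offset(z, offset_window=(0.0, 0.0))
        np.testing.assert_allclose(avg["lure+"], 0.0, atol=1e-12)

    def test_empty_trials_rejected(self):
        z = self._zset(n_tr=2)
        z.z = z.z[:0]
        z.events = z.events.iloc[:0]
        with pytest.raises(ValueError, match="no retained"):
            tf.average_and_offset(z)


def _planted_responsive_epochs(seed=0, burst=True, sign=1.0, n_tr=20,
                               n_ch=1):
    """Noise epochs, optionally with a post-onset 4 Hz burst."""
    rng = np.random.default_rng(seed)
    fs = 500.0
    window = (-0.5, 1.0)
    n_t = int((window[1] - window[0]) * fs)
    t = window[0] + np.arange(n_t) / fs
    data = rng.standard_normal((n_tr, n_t, n_ch))
    if burst:
        env = (t >= 0) & (t < 1.0)
        data += sign * 3.0 * np.cos(2 * np.pi * 4.0 * t)[None, :, None] \
            * env[None, :, None]
    conds = (["repeat+", "lure-", "lure+", "new+"] * (n_tr // 4 + 1))[:n_tr]
    return _epochs_from_array(data, fs=fs, window=window, conditions=conds)


class TestCueResponsivity:
    def test_planted_burst_marks_channel_responsive(self):
        ep = _planted_responsive_epochs(burst=True)
        power = tf.morlet_power(ep, tf.WaveletConfig(f_min=3.0, f_max=8.0))
        table = tf.cue_responsivity(power, n_perm=300, seed=1)
        assert bool(table["responsive"].iloc[0])

    def test_power_decrease_is_not_responsive(self):
        """One-sided test: a post-onset decrease must not select."""
        rng = np.random.default_rng(5)
        fs, window = 500.0, (-0.5, 1.0)
        n_t = int(1.5 * fs)
        t = window[0] + np.arange(n_t) / fs
        env = (t < 0)
        data = rng.standard_normal((20, n_t, 1)) + \
            3.0 * (np.cos(2 * np.pi * 4.0 * t) * env)[None, :, None]
        conds = (["repeat+", "lure-", "lure+", "new+"] * 5)
        ep = _epochs_from_array(data, fs=fs, window=window, conditions=conds)
        power = tf.morlet_power(ep, tf.WaveletConfig(f_min=3.0, f_max=8.0))
        table = tf.cue_responsivity(power, n_perm=300, seed=2)
        assert not bool(table["responsive"].iloc[0])

    def test_null_channels_select_near_alpha(self):
        """Pure-noise channels with a single pooled test: responsive
        fraction compatible with the 5% level (binomial 95% CI)."""
        ep = _planted_responsive_epochs(burst=False, n_tr=16, n_ch=40,
                                        seed=11)
        power = tf.morlet_power(ep, tf.WaveletConfig(f_min=3.0, f_max=8.0))
        table = tf.cue_responsivity(power, conditions=(), n_perm=200,
                                    seed=3)
        rate = table["responsive"].mean()
        assert rate <= 0.15  # 40 channels at alpha=0.05: upper CI ~0.13


class TestRobustness:
    def test_effect_sign_stable_across_normalization_modes(self,
                                                           small_session):
        ds = small_session
        events = ds.events.loc[ds.events["phase"] == "retrieval"]
        epochs = tf.epoch_trials(ds.recording, events, None, "onset",
                                 (-1.0, 1.0))
        power = tf.morlet_power(epochs,
                                tf.WaveletConfig(f_min=3.0, f_max=10.0))
        post = None
        signs = []
        for mode in ("condition_baseline", "pooled_baseline",
                     "whole_recording"):
            z = tf.baseline_zscore(power, mode=mode)
            avg = tf.average_and_offset(z, band=(4.0, 5.0))
            post = z.times >= 0
            diff = (avg["lure+"][:, post] - avg["lure-"][:, post]).mean()
            signs.append(np.sign(diff))
        assert len(set(signs)) == 1

    def test_induced_effect_survives_evoked_subtraction(self,
                                                        small_session):
        ds = small_session
        events = ds.events.loc[ds.events["phase"] == "retrieval"]
        epochs = tf.epoch_trials(ds.recording, events, None, "onset",
                                 (-1.0, 1.0))
        power = tf.morlet_power(epochs,
                                tf.WaveletConfig(f_min=3.0, f_max=10.0),
                                subtract_evoked=True)
        z = tf.baseline_zscore(power)
        avg = tf.average_and_offset(z, band=(4.0, 5.0))
        post = z.times >= 0
        diff = (avg["lure+"][:, post] - avg["lure-"][:, post]).mean()
        assert diff > 0
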