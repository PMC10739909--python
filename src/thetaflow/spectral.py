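"""Morlet-wavelet power, baseline z-normalization, and channel selection.

Power is extracted with analytic Morlet wavelets (dimensionless center
frequency omega0 = 6, i.e. 6/(2*pi) in natural frequency units) on a
logarithmic grid from ``f_min`` to ``f_max`` with a fixed number of voices
per octave, converted to decibels (10*log10), and z-scored against a
condition-specific pre-stimulus baseline distribution: each trial's power
at a frequency is normalized by the mean and SD of pre-stimulus dB power
pooled over the baseline windows of trials of the *same condition*
(artifact samples excluded).  Alternative normalizations against the whole
recording or the condition-pooled baseline reproduce standard robustness
checks.

Channel selection ("cue responsivity") marks a channel task-responsive
when slow-frequency (3-6 Hz) power shows a significant post-stimulus
increase over baseline in any condition or across pooled trials
(one-sided unpaired permutation test, alpha = 0.05, uncorrected:
selection, not inference).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EpochSet

logger = logging.getLogger("thetaflow")

BASELINE_MODES = ("condition_baseline", "pooled_baseline", "whole_recording")


@dataclass
class WaveletConfig:
    """Morlet-wavelet analysis parameters.

    ``f_min``/``f_max`` bound the logarithmic frequency grid;
    ``voices_per_octave`` sets its density; ``omega0`` is the
    dimensionless wavelet center frequency (6 corresponds to a center
    frequency of 6/(2*pi) in natural units, i.e. ~6 cycles per envelope).
    """

    f_min: float = 3.0
    f_max: float = 200.0
    voices_per_octave: int = 32
    omega0: float = 6.0

    def __post_init__(self) -> None:
        if not self.f_min < self.f_max:
            raise ValueError("f_min must be below f_max")
        if self.voices_per_octave <= 0:
            raise ValueError("voices_per_octave must be positive")


def wavelet_freq_grid(cfg: WaveletConfig, sfreq: float) -> np.ndarray:
    """Logarithmic frequency grid, truncated below Nyquist with a warning."""
    n_oct = math.log2(cfg.f_max / cfg.f_min)
    k = np.arange(math.floor(n_oct * cfg.voices_per_octave) + 1)
    freqs = cfg.f_min * 2.0 ** (k / cfg.voices_per_octave)
    freqs = freqs[freqs <= cfg.f_max * (1 + 1e-12)]
    nyq = sfreq / 2.0
    if freqs[-1] >= nyq:
        logger.warning("truncating wavelet grid at Nyquist (%.1f Hz)", nyq)
        freqs = freqs[freqs < nyq]
    return freqs


@dataclass
class PowerTensor:
    """Trial x channel x frequency x time wavelet power in dB."""

    power_db: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    sfreq: float
    events: pd.DataFrame
    channels: pd.DataFrame
    alignment: str

    @property
    def conditions(self) -> np.ndarray:
        return self.events["condition"].to_numpy()

    def band_rows(self, band: tuple[float, float]) -> np.ndarray:
        """Indices of grid frequencies inside the closed band."""
        return np.flatnonzero((self.freqs >= band[0] - 1e-9)
                              & (self.freqs <= band[1] + 1e-9))

    def time_cols(self, window: tuple[float, float]) -> np.ndarray:
        """Indices of time samples in the half-open window [t0, t1)."""
        return np.flatnonzero((self.times >= window[0] - 1e-9)
                              & (self.times < window[1] - 1e-9))


@dataclass
class BaselineStats:
    """Per channel x frequency x condition baseline mean/SD of dB power."""

    mean: np.ndarray       # (n_cond, n_channels, n_freqs)
    sd: np.ndarray
    count: np.ndarray      # contributing samples per (cond, channel, freq)
    conditions: list
    mode: str
    baseline_window: tuple[float, float]


@dataclass
class ZMapSet:
    """Per-trial z-scored time-frequency maps plus their baseline stats."""

    z: np.ndarray          # (n_trials, n_channels, n_freqs, n_times)
    freqs: np.ndarray
    times: np.ndarray
    events: pd.DataFrame
    channels: pd.DataFrame
    alignment: str
    baseline: BaselineStats

    @property
    def conditions(self) -> np.ndarray:
        return self.events["condition"].to_numpy()


def morlet_power(epochs: EpochSet, cfg: WaveletConfig | None = None,
                 subtract_evoked: bool = False) -> PowerTensor:
    """Continuous wavelet transform of every trial/channel; power in dB.

    With ``subtract_evoked``, the per-channel mean evoked response across
    trials is removed before the transform so only induced power remains.
    Epochs shorter than two cycles of ``f_min`` get a logged warning (the
    lowest rows are unreliable, not removed).
    """
    from mne.time_frequency import tfr_array_morlet

    cfg = cfg or WaveletConfig()
    freqs = wavelet_freq_grid(cfg, epochs.sfreq)
    n_t = epochs.data.shape[1]
    if n_t / epochs.sfreq < 2.0 / cfg.f_min:
        logger.warning("epoch shorter than 2 cycles of f_min=%.1f Hz; "
                       "low-frequency rows are unreliable", cfg.f_min)
    data = epochs.data
    if subtract_evoked and len(data):
        data = data - data.mean(axis=0, keepdims=True)
    # mne expects (n_epochs, n_channels, n_times)
    arr = np.transpose(data, (0, 2, 1))
    # zero-pad so the longest (lowest-frequency) wavelet fits; the padded
    # margin is cropped back out (edge voxels are inside the wavelet's
    # cone of influence and should be treated with care regardless)
    from mne.time_frequency import morlet as _morlet
    max_len = max(len(w) for w in _morlet(epochs.sfreq, freqs,
                                          n_cycles=cfg.omega0))
    pad = max(0, (max_len - arr.shape[2]) // 2 + 1)
    if pad:
        arr = np.pad(arr, ((0, 0), (0, 0), (pad, pad)))
    power = tfr_array_morlet(arr, sfreq=epochs.sfreq, freqs=freqs,
                             n_cycles=cfg.omega0, output="power",
                             zero_mean=True, verbose="error")
    if pad:
        power = power[..., pad:-pad]
    # unit-gain normalization: rescale each frequency row so a tone at the
    # wavelet's center frequency yields power equal to its squared
    # amplitude (mne's L2-normalized wavelets otherwise skew spectral
    # peaks toward low frequencies on a fine log grid)
    gains = np.empty(len(freqs))
    for i, (w, f) in enumerate(zip(_morlet(epochs.sfreq, freqs,
                                           n_cycles=cfg.omega0), freqs)):
        tw = (np.arange(len(w)) - (len(w) - 1) / 2) / epochs.sfreq
        gains[i] = np.abs(np.sum(np.conj(w)
                                 * np.exp(2j * np.pi * f * tw))) / 2.0
    power = power / (gains ** 2)[None, None, :, None]
    power_db = 10.0 * np.log10(np.maximum(power, np.finfo(float).tiny))
    return PowerTensor(power_db=power_db, freqs=freqs, times=epochs.times,
                       sfreq=epochs.sfreq, events=epochs.events,
                       channels=epochs.channels, alignment=epochs.alignment)


def baseline_zscore(power: PowerTensor,
                    baseline_window: tuple[float, float] = (-0.5, 0.0),
                    mode: str = "condition_baseline",
                    sample_mask: np.ndarray | None = None) -> ZMapSet:
    """Z-score each trial's dB power against pre-stimulus baseline stats.

    ``z(t, f) = (P(t, f) - mu_cond(f)) / sigma_cond(f)`` where ``mu`` and
    ``sigma`` pool the baseline-window samples of the normalizing set:
    trials of the same condition (default), all trials
    (``pooled_baseline``), or every time point of every trial
    (``whole_recording``).  ``sample_mask`` (trial x time, True = artifact)
    excludes samples from the normalizing distribution only.
    """
    if mode not in BASELINE_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}")
    n_tr, n_ch, n_f, n_t = power.power_db.shape
    if sample_mask is None:
        sample_mask = np.zeros((n_tr, n_t), dtype=bool)
    conds = list(dict.fromkeys(power.conditions))
    cond_arr = power.conditions
    base_cols = power.time_cols(baseline_window)
    if base_cols.size == 0 and mode != "whole_recording":
        raise ValueError("baseline window contains no samples")

    mean = np.empty((len(conds), n_ch, n_f))
    sd = np.empty((len(conds), n_ch, n_f))
    count = np.empty((len(conds), n_ch, n_f), dtype=int)
    for ci, cond in enumerate(conds):
        if mode == "condition_baseline":
            rows = np.flatnonzero(cond_arr == cond)
            cols = base_cols
        elif mode == "pooled_baseline":
            rows = np.arange(n_tr)
            cols = base_cols
        else:  # whole_recording
            rows = np.arange(n_tr)
            cols = np.arange(n_t)
        keep = ~sample_mask[np.ix_(rows, cols)]          # (rows, cols)
        vals = power.power_db[np.ix_(rows, np.arange(n_ch),
                                     np.arange(n_f), cols)]
        sel = keep[:, None, None, :]
        n_keep = keep.sum()
        if n_keep < 2:
            raise ValueError(
                f"condition {cond!r}: fewer than 2 artifact-free baseline "
                "samples")
        masked = np.where(sel, vals, np.nan)
        mean[ci] = np.nanmean(masked, axis=(0, 3))
        sd[ci] = np.nanstd(masked, axis=(0, 3), ddof=0)
        count[ci] = n_keep
        if np.any(sd[ci] == 0):
            ch, fr = np.argwhere(sd[ci] == 0)[0]
            raise ValueError(
                f"zero baseline SD (condition {cond!r}, channel "
                f"{power.channels['label'].iloc[ch]!r}, "
                f"frequency {power.freqs[fr]:.2f} Hz)")

    z = np.empty_like(power.power_db)
    for ci, cond in enumerate(conds):
        rows = np.flatnonzero(cond_arr == cond)
        z[rows] = ((power.power_db[rows] - mean[ci][None, :, :, None])
                   / sd[ci][None, :, :, None])
    stats = BaselineStats(mean=mean, sd=sd, count=count, conditions=conds,
                          mode=mode, baseline_window=baseline_window)
    return ZMapSet(z=z, freqs=power.freqs, times=power.times,
                   events=power.events, channels=power.channels,
                   alignment=power.alignment, baseline=stats)


def average_and_offset(zmaps: ZMapSet,
                       band: tuple[float, float] | None = None,
                       offset_window: tuple[float, float] = (-0.2, 0.0),
                       by_condition: bool = True) -> dict:
    """Trial-average z-maps per channel, removing the pre-stimulus offset.

    The mean over ``offset_window`` (default the 0.2 s before alignment)
    is subtracted per channel and frequency row so traces start at zero at
    the alignment event.  Returns ``{condition: array}`` with shape
    (n_channels, n_freqs, n_times), or (n_channels, n_times) band traces
    averaged over the ``band`` frequency rows when ``band`` is given.
    With ``by_condition=False`` a single ``{"all": ...}`` entry pools all
    trials.
    """
    if zmaps.z.shape[0] == 0:
        raise ValueError("no retained trials to average")
    off_cols = np.flatnonzero((zmaps.times >= offset_window[0] - 1e-9)
                              & (zmaps.times < offset_window[1] - 1e-9))
    groups = (list(dict.fromkeys(zmaps.conditions)) if by_condition
              else ["all"])
    out = {}
    for cond in groups:
        rows = (np.flatnonzero(zmaps.conditions == cond)
                if by_condition else np.arange(zmaps.z.shape[0]))
        avg = zmaps.z[rows].mean(axis=0)           # (ch, f, t)
        if off_cols.size:
            avg = avg - avg[:, :, off_cols].mean(axis=2, keepdims=True)
        if band is not None:
            rows_f = np.flatnonzero((zmaps.freqs >= band[0] - 1e-9)
                                    & (zmaps.freqs <= band[1] + 1e-9))
            if rows_f.size == 0:
                raise ValueError(f"no grid frequencies inside band {band}")
            avg = avg[:, rows_f, :].mean(axis=1)   # (ch, t)
        out[cond] = avg
    return out


def _unpaired_perm_p(pre: np.ndarray, post: np.ndarray, n_perm: int,
                     rng) -> float:
    """One-sided (post > pre) unpaired permutation p-value."""
    obs = post.mean() - pre.mean()
    pooled = np.concatenate([pre, post])
    n_post = len(post)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        null = perm[:n_post].mean() - perm[n_post:].mean()
        if null >= obs:
            count += 1
    return count / n_perm


def cue_responsivity(power: PowerTensor,
                     band: tuple[float, float] = (3.0, 6.0),
                     pre_window: tuple[float, float] = (-0.3, 0.0),
                     post_window: tuple[float, float] = (0.0, 1.0),
                     conditions: tuple = ("repeat+", "lure-", "lure+",
                                          "new+"),
                     n_perm: int = 1000, alpha: float = 0.05,
                     seed: int = 0) -> pd.DataFrame:
    """Mark channels with a significant post-stimulus 3-6 Hz power increase.

    Per channel, mean band power per trial in the pre- and post-stimulus
    windows is compared with a one-sided unpaired permutation test
    (1000 permutations), run per condition and on pooled trials; the
    channel is responsive if any test rejects at ``alpha``.  Channels
    with fewer than 2 trials in every tested set are non-assessable.
    Returns a per-channel table (label, region, responsive, p_pooled,
    p_<condition>...).
    """
    rng = np.random.default_rng(seed)
    rows_f = power.band_rows(band)
    pre_cols = power.time_cols(pre_window)
    post_cols = power.time_cols(post_window)
    # per-trial per-channel mean band power
    pre_vals = power.power_db[:, :, rows_f][:, :, :, pre_cols].mean(
        axis=(2, 3))                                    # (trials, ch)
    post_vals = power.power_db[:, :, rows_f][:, :, :, post_cols].mean(
        axis=(2, 3))
    cond_arr = power.conditions
    records = []
    for ch in range(power.power_db.shape[1]):
        rec = {"label": power.channels["label"].iloc[ch],
               "region": power.channels["region"].iloc[ch]}
        pvals = {}
        assessable = False
        trial_sets = {"pooled": np.arange(len(cond_arr))}
        for cond in conditions:
            trial_sets[cond] = np.flatnonzero(cond_arr == cond)
        for name, rows in trial_sets.items():
            if len(rows) < 2:
                pvals[name] = np.nan
                continue
            assessable = True
            pvals[name] = _unpaired_perm_p(pre_vals[rows, ch],
                                           post_vals[rows, ch],
                                           n_perm, rng)
        rec["responsive"] = (assessable and
                             any(p < alpha for p in pvals.values()
                                 if np.isfinite(p)))
        rec["assessable"] = assessable
        rec.update({f"p_{k}": v for k, v in pvals.items()})
        records.append(rec)
    return pd.DataFrame(records)
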