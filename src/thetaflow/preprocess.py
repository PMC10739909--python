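"""Continuous-signal conditioning and trial epoching.

The canonical order is downsample -> notch -> Laplacian re-reference ->
artifact detection -> epoching.  All IIR filters are applied zero-phase
(forward-backward) by default: instantaneous phase feeds the transfer-
entropy analysis downstream, so phase distortion is unacceptable.  A
causal single-pass mode is available per call.  Note the effective filter
order doubles under forward-backward application.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .containers import ArtifactMask, EpochSet, RawRecording

logger = logging.getLogger("thetaflow")


def downsample(raw: RawRecording, target_fs: float) -> RawRecording:
    """Anti-alias filter and resample to ``target_fs``.

    Polyphase resampling with the default Kaiser-windowed low-pass;
    event times are expressed in seconds and are unaffected.
    """
    if target_fs > raw.sfreq:
        raise ValueError(
            f"target rate {target_fs} Hz exceeds source rate {raw.sfreq} Hz")
    if target_fs == raw.sfreq:
        return raw
    up = int(round(target_fs))
    down = int(round(raw.sfreq))
    g = math.gcd(up, down)
    out = signal.resample_poly(raw.samples, up // g, down // g, axis=0)
    return raw.copy_with(out, sfreq=target_fs)


def notch_filter(raw: RawRecording, line_freq: float = 60.0,
                 n_harmonics: int = 3, half_width: float = 1.0,
                 order: int = 2, zero_phase: bool = True) -> RawRecording:
    """Butterworth band-stop at the line frequency and its harmonics.

    A 2nd-order band-stop of +/- ``half_width`` Hz is applied at
    ``line_freq`` and each harmonic up to ``n_harmonics``; harmonics at or
    above Nyquist are skipped with a warning.
    """
    nyq = raw.sfreq / 2.0
    out = raw.samples
    for h in range(1, n_harmonics + 1):
        f0 = line_freq * h
        if f0 + half_width >= nyq:
            logger.warning("skipping notch at %.1f Hz (>= Nyquist %.1f Hz)",
                           f0, nyq)
            continue
        sos = signal.butter(order, [f0 - half_width, f0 + half_width],
                            btype="bandstop", fs=raw.sfreq, output="sos")
        if zero_phase:
            out = signal.sosfiltfilt(sos, out, axis=0)
        else:
            out = signal.sosfilt(sos, out, axis=0)
    return raw.copy_with(np.asarray(out))


def laplacian_reference(raw: RawRecording,
                        edge_mode: str = "bipolar") -> RawRecording:
    """Re-reference each contact to the mean of its probe neighbors.

    For an interior contact N on a probe, output is
    ``x[N] - (x[N-1] + x[N+1]) / 2``; neighbors are defined by
    ``contact_index`` within a probe.  Edge contacts are referenced to
    their single neighbor (``edge_mode="bipolar"``, default) or dropped
    (``edge_mode="drop"``).  Single-contact probes are dropped with a
    logged reason.
    """
    if edge_mode not in ("bipolar", "drop"):
        raise ValueError(f"unknown edge_mode {edge_mode!r}")
    chans = raw.channels
    out_cols: list[int] = []
    out_sig: list[np.ndarray] = []
    for probe, grp in chans.groupby("probe", sort=False):
        grp = grp.sort_values("contact_index")
        idx = grp.index.to_numpy()
        if len(idx) < 2:
            logger.warning("dropping single-contact probe %r", probe)
            continue
        for pos, ci in enumerate(idx):
            x = raw.samples[:, ci]
            if pos == 0 or pos == len(idx) - 1:
                if edge_mode == "drop":
                    continue
                neighbor = idx[1] if pos == 0 else idx[-2]
                ref = raw.samples[:, neighbor]
            else:
                ref = (raw.samples[:, idx[pos - 1]]
                       + raw.samples[:, idx[pos + 1]]) / 2.0
            out_cols.append(ci)
            out_sig.append(x - ref)
    if not out_sig:
        raise ValueError("no channels left after Laplacian re-referencing")
    order = np.argsort(out_cols)
    cols = [out_cols[i] for i in order]
    samples = np.column_stack([out_sig[i] for i in order])
    return RawRecording(samples, raw.sfreq,
                        chans.iloc[cols].reset_index(drop=True))


def detect_artifacts(raw: RawRecording, k_sd: float = 4.0,
                     pad_s: float = 1.0, *,
                     allow_out_of_range: bool = False) -> ArtifactMask:
    """Flag samples exceeding the channel mean +/- ``k_sd`` SD.

    Statistics are computed over the whole continuous channel.  Non-finite
    samples are treated as artifacts before thresholding.  Flags are
    dilated by +/- ``pad_s`` seconds.  The signal itself is untouched.
    ``k_sd`` outside the conventional [3, 4.5] range is rejected unless
    ``allow_out_of_range`` is set.
    """
    if not allow_out_of_range and not 3.0 <= k_sd <= 4.5:
        raise ValueError(
            f"k_sd={k_sd} outside [3, 4.5]; pass allow_out_of_range=True "
            "to override")
    x = raw.samples
    finite = np.isfinite(x)
    xf = np.where(finite, x, np.nan)
    mean = np.nanmean(xf, axis=0)
    sd = np.nanstd(xf, axis=0, ddof=0)
    zero_var = sd == 0
    if zero_var.any():
        labels = raw.channels["label"].to_numpy()[zero_var]
        logger.warning("zero-variance channels (no threshold flags): %s",
                       list(labels))
    threshold = k_sd * np.where(zero_var, np.inf, sd)
    with np.errstate(invalid="ignore"):
        over = np.abs(xf - mean) > threshold
    mask = ~finite | np.where(np.isnan(xf), False, over)
    pad = int(round(pad_s * raw.sfreq))
    if pad > 0 and mask.any():
        mask = ndimage.maximum_filter1d(
            mask.astype(np.uint8), size=2 * pad + 1, axis=0,
            mode="constant").astype(bool)
    return ArtifactMask(mask=mask, k_sd=k_sd, pad_s=pad_s, sfreq=raw.sfreq)


def _sample_index(t: float, fs: float) -> int:
    """Map time to sample index: floor(t * fs), with float-noise guard."""
    return int(math.floor(t * fs + 1e-9))


def epoch_trials(raw: RawRecording, events, mask: ArtifactMask | None,
                 alignment: str = "onset",
                 window: tuple[float, float] = (-1.0, 1.0)) -> EpochSet:
    """Extract per-trial windows, excluding artifact-contaminated trials.

    ``window`` is half-open [start, end) in seconds relative to the
    alignment event (stimulus onset or response).  A trial is excluded,
    with a recorded reason, when its window leaves the recording or when
    any window sample is flagged in ``mask``.
    """
    if alignment not in ("onset", "response"):
        raise ValueError(f"unknown alignment {alignment!r}")
    fs = raw.sfreq
    n_samp = _sample_index(window[1], fs) - _sample_index(window[0], fs)
    kept, slices, art, excl = [], [], [], []
    for _, row in events.iterrows():
        t0 = row["onset_s"] if alignment == "onset" else row["response_s"]
        if not np.isfinite(t0):
            excl.append((row["trial_id"], "no alignment timestamp"))
            continue
        i0 = _sample_index(t0 + window[0], fs)
        i1 = i0 + n_samp
        if i0 < 0 or i1 > raw.n_times:
            excl.append((row["trial_id"], "window outside recording"))
            continue
        m = (mask.mask[i0:i1] if mask is not None
             else np.zeros((n_samp, raw.n_channels), dtype=bool))
        if m.any():
            excl.append((row["trial_id"], "artifact in epoch window"))
            continue
        kept.append(row)
        slices.append(raw.samples[i0:i1])
        art.append(m.any(axis=1))
    if kept:
        data = np.stack(slices)
        artifact = np.stack(art)
        ev = pd.concat([r.to_frame().T for r in kept], ignore_index=True)
    else:
        data = np.empty((0, n_samp, raw.n_channels))
        artifact = np.empty((0, n_samp), dtype=bool)
        ev = events.iloc[:0].copy()
    exclusions = pd.DataFrame(excl, columns=["trial_id", "reason"])
    if len(exclusions):
        logger.info("excluded %d/%d trials", len(exclusions), len(events))
    return EpochSet(data=data, sfreq=fs, alignment=alignment, window=window,
                    events=ev, channels=raw.channels, exclusions=exclusions,
                    artifact=artifact)

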