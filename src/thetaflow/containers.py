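"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* signals are ``(n_times, n_channels)`` float arrays in microvolt-scale
  arbitrary units;
* all windows are half-open ``[start, end)`` in seconds relative to an
  alignment event; the sample holding time ``t`` is ``floor(t * fs)``,
  0-based;
* the channel table is a :class:`pandas.DataFrame` with columns
  ``label, region, probe, contact_index``, rows in one-to-one order with
  signal columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Neocortical region labels (orbitofrontal, frontal, temporal, cingulate,
#: insular, entorhinal/perirhinal cortex).
NC_REGIONS = ("OFC", "FRO", "TEMP", "CING", "INS", "EC/PRC")
#: Hippocampal region labels (dentate gyrus/CA3, CA1, subiculum).
HC_REGIONS = ("DG/CA3", "CA1", "SUB")
#: Regions entering phase-transfer-entropy analyses on the neocortical side.
NC_PTE_REGIONS = ("OFC", "FRO", "TEMP")

CHANNEL_COLUMNS = ("label", "region", "probe", "contact_index")
EVENT_COLUMNS = ("trial_id", "phase", "onset_s", "response_s", "condition",
                 "correct")


def validate_channels(channels: pd.DataFrame) -> pd.DataFrame:
    """Check a channel table for the required columns and unique labels."""
    missing = [c for c in CHANNEL_COLUMNS if c not in channels.columns]
    if missing:
        raise ValueError(f"channel table missing columns: {missing}")
    if channels["label"].duplicated().any():
        raise ValueError("channel labels must be unique")
    return channels.reset_index(drop=True)


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check an event table: required columns, onsets increasing per phase."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    for phase, grp in events.groupby("phase"):
        onsets = grp["onset_s"].to_numpy(float)
        if np.any(np.diff(onsets) <= 0):
            raise ValueError(f"onsets not strictly increasing in {phase!r}")
        resp = grp["response_s"].to_numpy(float)
        ok = np.isnan(resp) | (resp > onsets)
        if not ok.all():
            raise ValueError(f"response before onset in {phase!r}")
    return events.reset_index(drop=True)


@dataclass
class RawRecording:
    """Continuous multichannel signal with channel metadata.

    Parameters
    ----------
    samples : ndarray, shape (n_times, n_channels)
        Signal in microvolt-scale arbitrary units.
    sfreq : float
        Sampling rate in Hz.
    channels : DataFrame
        Channel table, rows aligned with signal columns.
    """

    samples: np.ndarray
    sfreq: float
    channels: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (n_times, n_channels)")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        self.channels = validate_channels(self.channels)
        if len(self.channels) != self.samples.shape[1]:
            raise ValueError("channel table rows must match signal columns")

    @property
    def n_times(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_times / self.sfreq

    def copy_with(self, samples: np.ndarray, *,
                  sfreq: float | None = None,
                  channels: pd.DataFrame | None = None) -> "RawRecording":
        return RawRecording(
            samples=samples,
            sfreq=self.sfreq if sfreq is None else sfreq,
            channels=self.channels if channels is None else channels,
        )


@dataclass
class ArtifactMask:
    """Boolean time x channel matrix of artifact-contaminated samples.

    Every flagged sample's +/- ``pad_s`` neighborhood is also flagged
    (dilation happens in :func:`thetaflow.preprocess.detect_artifacts`).
    """

    mask: np.ndarray
    k_sd: float
    pad_s: float
    sfreq: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def flagged_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class EpochSet:
    """Per-trial windows aligned to stimulus onset or response.

    ``data`` holds only the retained (artifact-free, in-bounds) trials;
    excluded trials are listed in ``exclusions`` with a reason.
    """

    data: np.ndarray          # (n_trials, n_times, n_channels)
    sfreq: float
    alignment: str            # "onset" | "response"
    window: tuple[float, float]
    events: pd.DataFrame      # retained trials, one row per data slice
    channels: pd.DataFrame
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["trial_id", "reason"]))
    artifact: np.ndarray | None = None   # (n_trials, n_times) bool

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trial, time, channel)")
        if self.alignment not in ("onset", "response"):
            raise ValueError(f"unknown alignment {self.alignment!r}")
        if len(self.events) != self.data.shape[0]:
            raise ValueError("event rows must match epoch count")
        if self.artifact is None:
            self.artifact = np.zeros(self.data.shape[:2], dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds relative to the alignment event."""
        n = self.data.shape[1]
        return self.window[0] + np.arange(n) / self.sfreq

    @property
    def conditions(self) -> np.ndarray:
        return self.events["condition"].to_numpy()

    def select(self, condition: str) -> "EpochSet":
        """Sub-select trials of one condition."""
        keep = self.events["condition"].to_numpy() == condition
        return EpochSet(
            data=self.data[keep],
            sfreq=self.sfreq,
            alignment=self.alignment,
            window=self.window,
            events=self.events.loc[keep].reset_index(drop=True),
            channels=self.channels,
            exclusions=self.exclusions,
            artifact=self.artifact[keep],
        )
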