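"""Synthetic LFP sessions with known ground-truth directional coupling.

The generator produces multichannel recordings that carry the statistical
structure the downstream analyses assume: a 4-5 Hz carrier whose phase can
be directionally coupled between a neocortical (NC) sender/receiver and a
hippocampal (HC) counterpart at a fixed lag, condition-dependent power
gains, 1/f background noise, 60 Hz line noise, and sporadic high-amplitude
artifacts.

Phase model
-----------
The sender phase is a noisy oscillator,

    theta_X(t+1) = theta_X(t) + omega*dt + sigma*sqrt(dt)*xi(t),

and the receiver phase relaxes toward the sender phase delayed by the
coupling lag with strength ``kappa`` (Kuramoto-style):

    theta_Y(t+1) = theta_Y(t) + omega*dt
                   + kappa*g*sin(theta_X(t-lag) - theta_Y(t))*dt
                   + sigma*sqrt(dt)*xi(t),

where ``g`` is a fixed coupling rate (rad/s) so that ``kappa`` in [0, 1]
spans "no coupling" to "tight lagged locking".  With ``kappa = 0`` the two
phases are independent by construction.  Signals are
``amplitude*cos(theta)`` plus spectrally shaped (1/f) noise; the generative
direction, lag, and gains are recorded in the dataset's ``truth`` mapping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import RawRecording, validate_channels, validate_events

CONDITIONS = ("repeat+", "lure+", "lure-", "new+")

#: fixed coupling rate g (rad/s): kappa=1 gives a ~40 ms locking time
COUPLING_GAIN = 25.0


def _per_condition(value, condition, default=None):
    """Resolve a scalar-or-mapping config field for one condition."""
    if isinstance(value, dict):
        return value.get(condition, default if default is not None else 0.0)
    return value


@dataclass
class SimConfig:
    """Parameters of the synthetic session generator.

    Attributes
    ----------
    sampling_rate : float
        Output rate in Hz.
    n_trials_per_condition : int
        Trials per condition and task phase.
    conditions : tuple of str
        Condition labels; ``+``/``-`` suffix encodes response accuracy.
    epoch_layout : dict
        Per task phase: ``(pre_s, post_s)`` stimulus epoch durations.
    iti_s : float
        Gap between one trial's window and the next trial's baseline.
    carrier_freq : float
        Oscillation frequency in Hz.
    coupling_strength : float or dict
        kappa in [0, 1], scalar or per-condition.
    coupling_direction : str or dict
        ``"nc->hc"``, ``"hc->nc"`` or ``"none"``, scalar or per-condition.
    coupling_lag_s : float
        Sender-to-receiver delay in seconds (rounded to nearest sample).
    power_gain : float or dict
        Multiplicative carrier-amplitude factor applied during the
        post-stimulus window, scalar or per-condition.
    noise_exponent : float
        1/f^beta background-noise exponent.
    noise_amp : float
        Background-noise standard deviation (carrier amplitude is 1).
    line_noise_amp : float
        60 Hz line-noise amplitude.
    artifact_rate_per_min : float
        Expected high-amplitude artifact events per minute per channel.
    phase_diffusion : float
        Phase-noise intensity sigma in rad/sqrt(s).
    response_latency_log_mu, response_latency_log_sigma : float
        Lognormal response-latency parameters (seconds scale).
    seed : int
        Master seed; identical seed + config gives byte-identical output.
    """

    sampling_rate: float = 500.0
    n_trials_per_condition: int = 15
    conditions: tuple = CONDITIONS
    epoch_layout: dict = field(default_factory=lambda: {
        "encoding": (1.0, 2.0), "retrieval": (1.0, 1.0)})
    iti_s: float = 1.0
    carrier_freq: float = 4.5
    coupling_strength: float | dict = 0.0
    coupling_direction: str | dict = "none"
    coupling_lag_s: float = 0.1
    power_gain: float | dict = 1.0
    noise_exponent: float = 1.0
    noise_amp: float = 0.5
    line_noise_amp: float = 0.1
    artifact_rate_per_min: float = 0.0
    artifact_amp: float = 15.0
    artifact_dur_s: float = 0.1
    phase_diffusion: float = 1.0
    response_latency_log_mu: float = math.log(0.7)
    response_latency_log_sigma: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        # normalize containers so JSON round-trips compare equal
        self.conditions = tuple(self.conditions)
        self.epoch_layout = {k: tuple(v)
                             for k, v in self.epoch_layout.items()}

    @property
    def lag_samples(self) -> int:
        """Coupling lag in whole samples (rounded to nearest)."""
        return int(round(self.coupling_lag_s * self.sampling_rate))

    def validate(self) -> None:
        if not self.conditions:
            raise ValueError("condition list must not be empty")
        if self.n_trials_per_condition <= 0:
            raise ValueError("n_trials_per_condition must be positive")
        for cond in self.conditions:
            kappa = _per_condition(self.coupling_strength, cond)
            if not 0.0 <= kappa <= 1.0:
                raise ValueError(f"coupling strength {kappa} for {cond!r} "
                                 "outside [0, 1]")
        shortest_post = min(post for _, post in self.epoch_layout.values())
        if self.coupling_lag_s >= shortest_post:
            raise ValueError(
                f"coupling lag {self.coupling_lag_s} s must be shorter than "
                f"the shortest post-stimulus epoch ({shortest_post} s)")


@dataclass
class SyntheticDataset:
    """A generated session: recording + events + channels + ground truth."""

    recording: RawRecording
    events: pd.DataFrame
    channels: pd.DataFrame
    truth: dict
    config: SimConfig

    def __post_init__(self) -> None:
        validate_events(self.events)
        # every epoch window must lie within the recording
        dur = self.recording.duration
        for _, row in self.events.iterrows():
            pre, post = self.config.epoch_layout[row["phase"]]
            if row["onset_s"] - pre < 0 or row["onset_s"] + post > dur:
                raise ValueError(
                    f"trial {row['trial_id']} epoch exceeds recording")


def _build_events(cfg: SimConfig, phases, rng) -> pd.DataFrame:
    """Lay out trials serially; returns the event table in seconds."""
    rows = []
    t = 0.0
    trial_id = 0
    for phase in phases:
        pre, post = cfg.epoch_layout[phase]
        # trial order: fixed interleave of conditions, deterministic shuffle
        conds = list(cfg.conditions) * cfg.n_trials_per_condition
        rng.shuffle(conds)
        for cond in conds:
            onset = t + pre
            latency = rng.lognormal(cfg.response_latency_log_mu,
                                    cfg.response_latency_log_sigma)
            if phase == "retrieval":
                # 1 s image + 0.5 s gap before the new/old prompt
                response = onset + post + 0.5 + latency
            else:
                response = onset + post + latency
            rows.append({
                "trial_id": trial_id, "phase": phase, "onset_s": onset,
                "response_s": response,
                "condition": cond, "correct": int(cond.endswith("+")),
            })
            trial_id += 1
            t = response + cfg.iti_s
    return pd.DataFrame(rows)


def _condition_profiles(cfg: SimConfig, events, n_times):
    """Per-sample coupling-strength and gain profiles from the trial layout.

    Returns (kappa_xy, kappa_yx, gain) arrays of length n_times, where
    kappa_xy acts on the HC receiver (NC -> HC) and kappa_yx on the NC
    receiver.  Coupling and gain are active during each trial's
    post-stimulus window.
    """
    fs = cfg.sampling_rate
    kxy = np.zeros(n_times)
    kyx = np.zeros(n_times)
    gain = np.ones(n_times)
    for _, row in events.iterrows():
        cond = row["condition"]
        _, post = cfg.epoch_layout[row["phase"]]
        i0 = int(math.floor(row["onset_s"] * fs))
        i1 = min(int(math.floor((row["onset_s"] + post) * fs)), n_times)
        kappa = _per_condition(cfg.coupling_strength, cond)
        direction = _per_condition(cfg.coupling_direction, cond, "none")
        if direction == "nc->hc":
            kxy[i0:i1] = kappa
        elif direction == "hc->nc":
            kyx[i0:i1] = kappa
        elif direction != "none":
            raise ValueError(f"unknown coupling direction {direction!r}")
        gain[i0:i1] = _per_condition(cfg.power_gain, cond, 1.0)
    return kxy, kyx, gain


def _coupled_phases(cfg: SimConfig, kxy, kyx, rng):
    """Simulate the NC (X) and HC (Y) latent phase trajectories."""
    n = len(kxy)
    fs = cfg.sampling_rate
    dt = 1.0 / fs
    omega = 2.0 * math.pi * cfg.carrier_freq
    sig = cfg.phase_diffusion * math.sqrt(dt)
    lag = cfg.lag_samples
    noise_x = sig * rng.standard_normal(n)
    noise_y = sig * rng.standard_normal(n)
    theta_x = np.empty(n)
    theta_y = np.empty(n)
    theta_x[0] = rng.uniform(-math.pi, math.pi)
    theta_y[0] = rng.uniform(-math.pi, math.pi)
    g = COUPLING_GAIN * dt
    step = omega * dt
    coupled = bool(np.any(kxy) or np.any(kyx))
    if not coupled:
        # independent by construction: plain phase random walks
        theta_x = theta_x[0] + np.cumsum(np.concatenate(
            ([0.0], step + noise_x[1:])))
        theta_y = theta_y[0] + np.cumsum(np.concatenate(
            ([0.0], step + noise_y[1:])))
        return theta_x, theta_y
    for t in range(n - 1):
        dx = step + noise_x[t]
        dy = step + noise_y[t]
        if t >= lag:
            if kxy[t]:
                dy += kxy[t] * g * math.sin(theta_x[t - lag] - theta_y[t])
            if kyx[t]:
                dx += kyx[t] * g * math.sin(theta_y[t - lag] - theta_x[t])
        theta_x[t + 1] = theta_x[t] + dx
        theta_y[t + 1] = theta_y[t] + dy
    return theta_x, theta_y


def _pink_noise(n, exponent, rng):
    """Spectrally shaped noise: power ~ 1/f^exponent, unit SD."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0
    out = np.fft.irfft(spec * shape, n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _inject_artifacts(sig, cfg: SimConfig, rng):
    """Add sporadic high-amplitude square bursts; Poisson event count."""
    if cfg.artifact_rate_per_min <= 0:
        return sig
    fs = cfg.sampling_rate
    n = len(sig)
    expected = cfg.artifact_rate_per_min * (n / fs) / 60.0
    n_events = rng.poisson(expected)
    width = max(int(round(cfg.artifact_dur_s * fs)), 1)
    for _ in range(n_events):
        i0 = rng.integers(0, max(n - width, 1))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        sig[i0:i0 + width] += sign * cfg.artifact_amp
    return sig


def _synthesize_channel(theta, gain, cfg: SimConfig, rng,
                        phase_jitter_sd=0.2):
    """Turn a latent phase trajectory into one channel's signal."""
    from scipy.signal import lfilter

    n = len(theta)
    fs = cfg.sampling_rate
    # small channel-specific phase jitter (AR(1)) around the latent phase
    eps = phase_jitter_sd * math.sqrt(1 - 0.99 ** 2)
    innov = eps * rng.standard_normal(n)
    innov[0] = phase_jitter_sd * rng.standard_normal()
    jitter = lfilter([1.0], [1.0, -0.99], innov)
    sig = gain * np.cos(theta + jitter)
    if cfg.noise_amp > 0:
        sig = sig + cfg.noise_amp * _pink_noise(n, cfg.noise_exponent, rng)
    if cfg.line_noise_amp > 0:
        tax = np.arange(n) / fs
        sig = sig + cfg.line_noise_amp * np.sin(
            2 * math.pi * 60.0 * tax + rng.uniform(0, 2 * math.pi))
    return _inject_artifacts(sig, cfg, rng)


def _truth(cfg: SimConfig, phases) -> dict:
    out = {"lag_s": cfg.coupling_lag_s, "carrier_freq": cfg.carrier_freq}
    for cond in cfg.conditions:
        kappa = _per_condition(cfg.coupling_strength, cond)
        direction = _per_condition(cfg.coupling_direction, cond, "none")
        if kappa == 0.0:
            direction = "none"
        out[cond] = {
            "kappa": kappa,
            "direction": direction,
            "power_gain": _per_condition(cfg.power_gain, cond, 1.0),
        }
    return out


def simulate_coupled_pair(config: SimConfig,
                          phases=("retrieval",)) -> SyntheticDataset:
    """Generate a two-channel (one NC, one HC) session.

    The NC channel is the Kuramoto sender when the configured direction is
    ``"nc->hc"`` (receiver for ``"hc->nc"``); coupling acts during each
    trial's post-stimulus window.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    events = _build_events(config, phases, rng)
    fs = config.sampling_rate
    n_times = int(math.ceil((events["response_s"].max() + config.iti_s) * fs))
    kxy, kyx, gain = _condition_profiles(config, events, n_times)
    theta_x, theta_y = _coupled_phases(config, kxy, kyx, rng)
    sig_x = _synthesize_channel(theta_x, gain, config, rng)
    sig_y = _synthesize_channel(theta_y, gain, config, rng)
    channels = pd.DataFrame({
        "label": ["NC1", "HC1"],
        "region": ["FRO", "CA1"],
        "probe": ["P1", "P2"],
        "contact_index": [1, 1],
    })
    rec = RawRecording(np.column_stack([sig_x, sig_y]), fs, channels)
    return SyntheticDataset(rec, events, channels, _truth(config, phases),
                            config)


def simulate_session(config: SimConfig, n_nc: int = 2, n_hc: int = 2,
                     phases=("encoding", "retrieval")) -> SyntheticDataset:
    """Generate a multichannel session with NC and HC channel groups.

    Each region group shares a latent phase (the coupled Kuramoto pair);
    individual channels add small independent phase jitter and their own
    1/f background, line noise, and artifacts.  Contacts are laid out on
    one probe per group so Laplacian re-referencing is applicable.
    """
    if n_nc < 1 or n_hc < 1:
        raise ValueError("need at least one NC and one HC channel")
    config.validate()
    rng = np.random.default_rng(config.seed)
    events = _build_events(config, phases, rng)
    fs = config.sampling_rate
    n_times = int(math.ceil((events["response_s"].max() + config.iti_s) * fs))
    kxy, kyx, gain = _condition_profiles(config, events, n_times)
    theta_nc, theta_hc = _coupled_phases(config, kxy, kyx, rng)

    nc_regions = ["FRO", "TEMP", "OFC"]
    hc_regions = ["CA1", "DG/CA3", "SUB"]
    labels, regions, probes, contacts, sigs = [], [], [], [], []
    for i in range(n_nc):
        labels.append(f"NC{i + 1}")
        regions.append(nc_regions[i % len(nc_regions)])
        probes.append("PNC")
        contacts.append(i + 1)
        sigs.append(_synthesize_channel(theta_nc, gain, config, rng))
    for i in range(n_hc):
        labels.append(f"HC{i + 1}")
        regions.append(hc_regions[i % len(hc_regions)])
        probes.append("PHC")
        contacts.append(i + 1)
        sigs.append(_synthesize_channel(theta_hc, gain, config, rng))
    channels = validate_channels(pd.DataFrame({
        "label": labels, "region": regions,
        "probe": probes, "contact_index": contacts,
    }))
    rec = RawRecording(np.column_stack(sigs), fs, channels)
    return SyntheticDataset(rec, events, channels, _truth(config, phases),
                            config)


# ---------------------------------------------------------------------------
# dataset writer

def write_dataset(ds: SyntheticDataset, path) -> dict:
    """Write a dataset as EDF + TSV event/channel tables + truth sidecar.

    Returns the mapping of artifact name -> file path.  Read-back through
    :func:`thetaflow.io.read_recording` reproduces the signals within EDF
    16-bit quantization and the metadata exactly.
    """
    from pathlib import Path

    from .io import write_channels, write_edf, write_events, write_truth

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = {
        "recording": path / "recording.edf",
        "events": path / "events.tsv",
        "channels": path / "channels.tsv",
        "truth": path / "truth.txt",
    }
    write_edf(ds.recording, files["recording"])
    write_events(ds.events, files["events"])
    write_channels(ds.channels, files["channels"])
    write_truth(ds.truth, files["truth"])
    return files


def flatten_truth(truth: dict, prefix: str = "") -> dict:
    """Flatten the nested truth mapping to dotted key -> scalar."""
    flat = {}
    for key, val in truth.items():
        name = f"{prefix}{key}"
        if isinstance(val, dict):
            flat.update(flatten_truth(val, prefix=f"{name}."))
        else:
            flat[name] = val
    return flat


def unflatten_truth(flat: dict) -> dict:
    out: dict = {}
    for key, val in flat.items():
        parts = key.split(".")
        node = out
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = val
    return out
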