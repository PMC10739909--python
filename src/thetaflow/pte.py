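"""Normalized directed phase transfer entropy between channel pairs.

Phase transfer entropy (PTE) quantifies how much the past phase of a
sender X reduces uncertainty about the present phase of a receiver Y
beyond what Y's own past explains:

    PTE_{X->Y} = H(Y_t | Y_{t-tau}) - H(Y_t | Y_{t-tau}, X_{t-tau}),

with Shannon entropies in bits estimated by plug-in from histogram
probability mass functions.  Bin widths follow Scott's choice,
``w = 3.49 * sigma * n^(-1/3)`` (sigma = ordinary standard deviation of
the pooled samples of that axis), with ``ceil(2*pi / w)`` bins spanning
[-pi, pi).  Each pmf pools the (Y_t, Y_{t-tau}, X_{t-tau}) triplets of
*all* retained trials rather than a single trial.  The default lag is
tau = 100 ms (50 samples at 500 Hz).

The two raw directed values are combined into a single normalized index

    nPTE = PTE_{X->Y} / (PTE_{X->Y} + PTE_{Y->X}) - 0.5  in [-0.5, 0.5],

zero meaning a symmetric (bidirectional) exchange; with the convention
X = neocortex, Y = hippocampus, positive values denote a net NC->HC bias
and negative values a net HC->NC bias.  A time-resolved variant repeats
the computation in short moving windows, and a surrogate ("chance")
analysis shuffles sender phases within trials to build a null for the
pair-averaged normalized PTE.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .containers import EpochSet

logger = logging.getLogger("thetaflow")


@dataclass
class PTEParams:
    """Parameters of the PTE estimator.

    ``lag_s`` is the prediction lag tau; ``window`` restricts the samples
    (seconds, half-open, relative to the alignment event; None = whole
    epoch); ``fot_window_s``/``fot_step_s`` configure the time-resolved
    variant.  The orientation convention is X = NC, Y = HC.
    """

    lag_s: float = 0.1
    window: tuple[float, float] | None = None
    fot_window_s: float = 0.5
    fot_step_s: float = 0.01

    def lag_samples(self, sfreq: float) -> int:
        return int(round(self.lag_s * sfreq))


@dataclass
class PhaseSeries:
    """Trial x time instantaneous phase (radians, wrapped to [-pi, pi))."""

    phase: np.ndarray           # (n_trials, n_times)
    sfreq: float
    times: np.ndarray           # seconds relative to alignment
    band: tuple[float, float]
    alignment: str
    label: str = ""

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        if self.phase.ndim != 2:
            raise ValueError("phase must be (n_trials, n_times)")


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles into [-pi, pi)."""
    return np.mod(phi + np.pi, 2 * np.pi) - np.pi


def extract_phase(epochs: EpochSet, channel: str,
                  band: tuple[float, float] = (4.0, 5.0),
                  filter_order: int = 3) -> PhaseSeries:
    """Band-limited instantaneous phase of one channel.

    Zero-phase Butterworth band-pass to ``band`` followed by the analytic
    signal (Hilbert transform); phases wrapped to [-pi, pi).  Epochs much
    shorter than a few cycles of the band's low edge make the phase
    estimate unreliable at the edges (cone of influence of the filter).
    """
    nyq = epochs.sfreq / 2.0
    if band[1] >= nyq:
        raise ValueError(f"band {band} exceeds Nyquist ({nyq:.1f} Hz)")
    labels = list(epochs.channels["label"])
    if channel not in labels:
        raise KeyError(f"unknown channel {channel!r}")
    ci = labels.index(channel)
    x = epochs.data[:, :, ci]
    sos = sps.butter(filter_order, band, btype="bandpass",
                     fs=epochs.sfreq, output="sos")
    xf = sps.sosfiltfilt(sos, x, axis=1)
    phase = wrap_phase(np.angle(sps.hilbert(xf, axis=1)))
    return PhaseSeries(phase=phase, sfreq=epochs.sfreq, times=epochs.times,
                       band=band, alignment=epochs.alignment, label=channel)


# ---------------------------------------------------------------------------
# histogram pmf estimation (Scott's choice)

def scott_bin_width(samples: np.ndarray) -> float:
    """Scott's-choice histogram bin width, w = 3.49 * sigma * n^(-1/3)."""
    samples = np.asarray(samples, dtype=float).ravel()
    n = samples.size
    if n < 2:
        raise ValueError("need at least 2 samples for Scott's rule")
    sigma = samples.std(ddof=0)
    return 3.49 * sigma * n ** (-1.0 / 3.0)


def _scott_edges(samples: np.ndarray) -> np.ndarray:
    """Bin edges over [-pi, pi) with Scott's-rule width for this axis."""
    w = scott_bin_width(samples)
    if w <= 0:
        n_bins = 1
    else:
        n_bins = max(int(math.ceil(2 * math.pi / w)), 1)
    return np.linspace(-math.pi, math.pi, n_bins + 1)


@dataclass
class PmfSet:
    """Histogram pmfs for one orientation (X = sender, Y = receiver).

    ``joint3`` is p(y_t, y_past, x_past); the marginals needed by the
    conditional-entropy chain rule are sums of the joint.  Each pmf sums
    to one.
    """

    joint3: np.ndarray          # (y_t bins, y_past bins, x_past bins)
    edges: tuple                # per-axis bin edges
    n: int                      # pooled triplet count

    @property
    def p_ypast(self) -> np.ndarray:
        return self.joint3.sum(axis=(0, 2))

    @property
    def p_yt_ypast(self) -> np.ndarray:
        return self.joint3.sum(axis=2)

    @property
    def p_ypast_xpast(self) -> np.ndarray:
        return self.joint3.sum(axis=0)

    def validate(self) -> None:
        tot = self.joint3.sum()
        if not math.isclose(tot, 1.0, abs_tol=1e-9):
            raise ValueError(f"pmf sums to {tot}, not 1")


def _collect_triplets(y: np.ndarray, x: np.ndarray, lag: int,
                      cols: np.ndarray):
    """Pool (Y_t, Y_{t-tau}, X_{t-tau}) across trials for t in cols."""
    valid = cols[cols - lag >= cols[0]]
    if valid.size == 0:
        raise ValueError("analysis window shorter than the lag")
    y_t = y[:, valid].ravel()
    y_p = y[:, valid - lag].ravel()
    x_p = x[:, valid - lag].ravel()
    return y_t, y_p, x_p


def _pmf_from_triplets(y_t, y_p, x_p) -> PmfSet:
    edges = (_scott_edges(y_t), _scott_edges(y_p), _scott_edges(x_p))
    hist, _ = np.histogramdd(np.column_stack([y_t, y_p, x_p]), bins=edges)
    n = y_t.size
    return PmfSet(joint3=hist / n, edges=edges, n=n)


def _window_cols(series: PhaseSeries,
                 window: tuple[float, float] | None) -> np.ndarray:
    if window is None:
        return np.arange(series.phase.shape[1])
    t = series.times
    return np.flatnonzero((t >= window[0] - 1e-9) & (t < window[1] - 1e-9))


def estimate_pmfs(phase_x: PhaseSeries, phase_y: PhaseSeries,
                  params: PTEParams | None = None
                  ) -> tuple[PmfSet, PmfSet]:
    """Histogram pmfs for both orientations of a channel pair.

    Returns ``(pmfs_xy, pmfs_yx)`` where ``pmfs_xy`` treats X as the
    sender.  Triplets pool every retained trial's samples inside the
    analysis window whose lagged index also falls inside the window.
    """
    params = params or PTEParams()
    if phase_x.phase.shape != phase_y.phase.shape:
        raise ValueError("phase series must share trials and time axis")
    lag = params.lag_samples(phase_x.sfreq)
    cols = _window_cols(phase_x, params.window)
    if cols.size <= lag + 1:
        raise ValueError("analysis window too short for the lag")
    yt, yp, xp = _collect_triplets(phase_y.phase, phase_x.phase, lag, cols)
    xt, xp2, yp2 = _collect_triplets(phase_x.phase, phase_y.phase, lag, cols)
    pmf_xy = _pmf_from_triplets(yt, yp, xp)
    pmf_yx = _pmf_from_triplets(xt, xp2, yp2)
    for pmf in (pmf_xy, pmf_yx):
        if min(len(e) - 1 for e in pmf.edges) < 2:
            raise ValueError(
                f"too few samples for >= 2 histogram bins (pair "
                f"{phase_x.label!r} -> {phase_y.label!r})")
    return pmf_xy, pmf_yx


# ---------------------------------------------------------------------------
# entropies and PTE

def entropy_bits(pmf: np.ndarray) -> float:
    """Shannon entropy in bits with the 0*log2(0) := 0 convention."""
    p = np.asarray(pmf, dtype=float).ravel()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _pte_one_direction(pmf: PmfSet) -> float:
    """PTE from the sender->receiver pmf via the chain rule
    H(A|B) = H(A, B) - H(B)."""
    pmf.validate()
    h_yp = entropy_bits(pmf.p_ypast)
    h_yt_yp = entropy_bits(pmf.p_yt_ypast)
    h_yp_xp = entropy_bits(pmf.p_ypast_xpast)
    h_all = entropy_bits(pmf.joint3)
    return (h_yt_yp - h_yp) - (h_all - h_yp_xp)


def pte_raw(pmfs: tuple[PmfSet, PmfSet]) -> tuple[float, float]:
    """Raw directed PTE (bits) in both orientations, (X->Y, Y->X)."""
    pmf_xy, pmf_yx = pmfs
    return _pte_one_direction(pmf_xy), _pte_one_direction(pmf_yx)


def pte_normalized(raw_xy: float, raw_yx: float) -> float:
    """Normalized PTE: raw_xy / (raw_xy + raw_yx) - 0.5, in [-0.5, 0.5].

    Positive = net X->Y (NC->HC) bias; 0 = symmetric exchange.  A
    degenerate (0, 0) raw pair maps to 0 with a logged flag so batch runs
    survive information-free windows.
    """
    if raw_xy < 0 or raw_yx < 0:
        # plug-in estimates are non-negative up to float error
        raw_xy, raw_yx = max(raw_xy, 0.0), max(raw_yx, 0.0)
    total = raw_xy + raw_yx
    if total == 0.0:
        logger.warning("degenerate PTE pair (0, 0); normalized value set "
                       "to 0")
        return 0.0
    return raw_xy / total - 0.5


def pte_pair(phase_x: PhaseSeries, phase_y: PhaseSeries,
             params: PTEParams | None = None) -> dict:
    """Time-averaged PTE of one pair: raw values (bits) and normalized."""
    params = params or PTEParams()
    pmfs = estimate_pmfs(phase_x, phase_y, params)
    raw_xy, raw_yx = pte_raw(pmfs)
    return {
        "pte_xy_bits": raw_xy,
        "pte_yx_bits": raw_yx,
        "pte_norm": pte_normalized(raw_xy, raw_yx),
    }


def pte_fot(phase_x: PhaseSeries, phase_y: PhaseSeries,
            params: PTEParams | None = None):
    """PTE as a function of time: moving-window repeats of the estimator.

    Windows of ``fot_window_s`` slide in steps of ``fot_step_s`` over the
    analysis window; each window pools triplets across trials exactly as
    the time-averaged measure does.  Stored timestamps are window
    *starts* relative to the alignment event.  Returns a DataFrame with
    columns (window_start_s, pte_xy_bits, pte_yx_bits, pte_norm).
    """
    import pandas as pd

    params = params or PTEParams()
    span = params.window
    if span is None:
        span = (float(phase_x.times[0]),
                float(phase_x.times[-1] + 1.0 / phase_x.sfreq))
    if span[1] - span[0] < params.fot_window_s - 1e-9:
        raise ValueError("analysis window shorter than the moving window")
    lag = params.lag_samples(phase_x.sfreq)
    win_samp = int(round(params.fot_window_s * phase_x.sfreq))
    if win_samp < lag + 2:
        raise ValueError("moving window shorter than lag + 2 samples")
    rows = []
    start = span[0]
    while start + params.fot_window_s <= span[1] + 1e-9:
        sub = PTEParams(lag_s=params.lag_s,
                        window=(start, start + params.fot_window_s))
        res = pte_pair(phase_x, phase_y, sub)
        res["window_start_s"] = round(start, 9)
        rows.append(res)
        start += params.fot_step_s
    return pd.DataFrame(rows)[["window_start_s", "pte_xy_bits",
                               "pte_yx_bits", "pte_norm"]]


# ---------------------------------------------------------------------------
# surrogate ("chance") analysis

@dataclass
class SurrogateNull:
    """Sender-shuffle null for the pair-averaged normalized PTE."""

    null_means: np.ndarray
    observed: float
    p_value: float
    n_iter: int
    shuffle: str = "within_trial"


def _shuffle_sender(phase: np.ndarray, rng,
                    mode: str = "within_trial") -> np.ndarray:
    """Destroy the sender's temporal structure, preserving marginals."""
    if mode == "within_trial":
        out = np.empty_like(phase)
        for tr in range(phase.shape[0]):
            out[tr] = phase[tr, rng.permutation(phase.shape[1])]
        return out
    if mode == "trial_exchange":
        return phase[rng.permutation(phase.shape[0])]
    raise ValueError(f"unknown shuffle mode {mode!r}")


def surrogate_null(pairs, params: PTEParams | None = None,
                   n_iter: int = 1000, seed: int = 0,
                   shuffle: str = "trial_exchange") -> SurrogateNull:
    """Chance analysis: shuffle every pair's sender phase series.

    ``pairs`` is a sequence of ``(phase_sender, phase_receiver)`` tuples
    (NC senders at retrieval, HC senders at encoding).  Per iteration,
    each sender's trials are re-paired with the receiver's by a random
    trial permutation (``shuffle="trial_exchange"``, default: destroys
    any sender-receiver dependence while preserving every trial's
    temporal structure, so the null is exactly exchangeable with the
    observed statistic under independence).  ``shuffle="within_trial"``
    instead permutes the sender's samples inside each trial; note that
    this also destroys the sender's autocorrelation, which biases the
    histogram plug-in estimate of both directed terms and makes the null
    mis-calibrated for smooth (band-limited) phases -- it is kept as an
    option, not the default.  The normalized sender->receiver PTE is
    recomputed for every pair and averaged per iteration;
    ``p = (# null means >= observed) / n_iter``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    params = params or PTEParams()
    rng = np.random.default_rng(seed)
    observed = float(np.mean([
        pte_pair(px, py, params)["pte_norm"] for px, py in pairs]))
    null_means = np.empty(n_iter)
    for it in range(n_iter):
        vals = []
        for px, py in pairs:
            px_sh = PhaseSeries(
                phase=_shuffle_sender(px.phase, rng, shuffle),
                sfreq=px.sfreq, times=px.times, band=px.band,
                alignment=px.alignment, label=px.label)
            vals.append(pte_pair(px_sh, py, params)["pte_norm"])
        null_means[it] = np.mean(vals)
    p = float((null_means >= observed).sum() / n_iter)
    return SurrogateNull(null_means=null_means, observed=observed,
                         p_value=p, n_iter=n_iter, shuffle=shuffle)
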