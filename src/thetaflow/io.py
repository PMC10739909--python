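"""File formats: EDF signals, TSV event/channel tables, truth sidecars.

EDF (European Data Format) reading goes through :mod:`mne`.  Writing uses a
minimal 16-bit EDF writer implemented here: signals are scaled per channel
to the int16 digital range, stored in 1-s data records, and annotated with
a ``uV`` physical dimension so standard readers recover microvolt-scale
values.  Round-tripping is lossy only through the 16-bit quantization
(per-channel correlation with the original > 0.999 for LFP-scale data).
"""

from __future__ import annotations

import datetime
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (EVENT_COLUMNS, RawRecording, validate_channels,
                         validate_events)

logger = logging.getLogger("thetaflow")

_PHASES = ("encoding", "retrieval")


# ---------------------------------------------------------------------------
# EDF writing (16-bit, 1-s data records)

def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: RawRecording, path) -> None:
    """Write a recording as a 16-bit EDF file.

    The sampling rate must be a whole number of samples per second (one
    data record per second).  The final record is padded with edge values.
    """
    path = Path(path)
    fs = rec.sfreq
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record
    n_ch = rec.n_channels
    n_rec = int(np.ceil(rec.n_times / spr))
    data = rec.samples
    if n_rec * spr > rec.n_times:
        pad = np.repeat(data[-1:, :], n_rec * spr - rec.n_times, axis=0)
        data = np.vstack([data, pad])

    pmin = data.min(axis=0)
    pmax = data.max(axis=0)
    flat = pmax - pmin <= 0
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.clip(np.round((data - pmin) * scale + dmin),
                      dmin, dmax).astype("<i2")

    now = datetime.datetime(2000, 1, 1)
    header = b"".join([
        _ascii("0", 8),
        _ascii("X X X X", 80),
        _ascii("Startdate 01-JAN-2000 X X X", 80),
        _ascii(now.strftime("%d.%m.%y"), 8),
        _ascii(now.strftime("%H.%M.%S"), 8),
        _ascii(256 * (1 + n_ch), 8),
        _ascii("", 44),
        _ascii(n_rec, 8),
        _ascii(1, 8),
        _ascii(n_ch, 4),
    ])
    labels = [str(l) for l in rec.channels["label"]]
    fields = [
        (labels, 16),
        (["" for _ in labels], 80),                      # transducer
        (["uV" for _ in labels], 8),                     # physical dimension
        ([f"{v:.8g}"[:8] for v in pmin], 8),
        ([f"{v:.8g}"[:8] for v in pmax], 8),
        ([str(dmin) for _ in labels], 8),
        ([str(dmax) for _ in labels], 8),
        (["" for _ in labels], 80),                      # prefiltering
        ([str(spr) for _ in labels], 8),
        (["" for _ in labels], 32),
    ]
    sig_header = b"".join(
        b"".join(_ascii(v, width) for v in values)
        for values, width in fields)

    # re-quantize against the truncated physical extremes actually written
    pmin_w = np.array([float(f"{v:.8g}"[:8]) for v in pmin])
    pmax_w = np.array([float(f"{v:.8g}"[:8]) for v in pmax])
    scale = (dmax - dmin) / (pmax_w - pmin_w)
    digital = np.clip(np.round((data - pmin_w) * scale + dmin),
                      dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        # records: for each second, each signal's samples contiguously
        blocks = digital.reshape(n_rec, spr, n_ch)
        fh.write(np.ascontiguousarray(
            blocks.transpose(0, 2, 1)).tobytes())


def read_recording(path, channels: pd.DataFrame | str | Path | None = None
                   ) -> RawRecording:
    """Load an EDF (or HDF5 container) recording, joining channel metadata.

    Parameters
    ----------
    path : path-like
        ``.edf`` file (read through mne) or ``.h5`` container written by
        :func:`write_container`.
    channels : DataFrame or path-like, optional
        Channel table (label, region, probe, contact_index) to join by
        label.  Channels absent from the table are dropped with a logged
        report.  Without a table, placeholder metadata is synthesized.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if isinstance(channels, (str, Path)):
        channels = read_channels(channels)

    if path.suffix.lower() == ".edf":
        import mne
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        samples = raw.get_data().T * 1e6  # mne stores uV channels in volts
        sfreq = float(raw.info["sfreq"])
        labels = list(raw.ch_names)
    elif path.suffix.lower() in (".h5", ".hdf5"):
        import h5py
        with h5py.File(path, "r") as fh:
            samples = fh["samples"][()]
            sfreq = float(fh.attrs["sfreq"])
            labels = [l.decode() if isinstance(l, bytes) else str(l)
                      for l in fh["labels"][()]]
    else:
        raise ValueError(f"unsupported recording format: {path.suffix!r}")

    if channels is None:
        table = pd.DataFrame({
            "label": labels,
            "region": ["UNK"] * len(labels),
            "probe": ["P0"] * len(labels),
            "contact_index": np.arange(1, len(labels) + 1),
        })
    else:
        channels = validate_channels(channels)
        known = set(channels["label"])
        joinable = [i for i, l in enumerate(labels) if l in known]
        dropped = [l for l in labels if l not in known]
        if dropped:
            logger.warning("dropping %d channels without metadata: %s",
                           len(dropped), dropped)
        if not joinable:
            raise ValueError("no recording channel matches the channel table")
        samples = samples[:, joinable]
        order = [labels[i] for i in joinable]
        table = (channels.set_index("label").loc[order]
                 .reset_index())
    return RawRecording(samples, sfreq, table)


# ---------------------------------------------------------------------------
# TSV tables

def write_events(events: pd.DataFrame, path) -> None:
    validate_events(events)
    cols = [c for c in events.columns]
    events.to_csv(path, sep="\t", index=False, columns=cols)


def read_events(path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    bad = ~events["phase"].isin(_PHASES)
    if bad.any():
        logger.warning("rejecting %d event rows with unknown task phase",
                       int(bad.sum()))
        events = events.loc[~bad].reset_index(drop=True)
    return validate_events(events)


def write_channels(channels: pd.DataFrame, path) -> None:
    validate_channels(channels).to_csv(path, sep="\t", index=False)


def read_channels(path) -> pd.DataFrame:
    return validate_channels(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# truth sidecar (flat key = value text)

def write_truth(truth: dict, path) -> None:
    from .simulate import flatten_truth
    flat = flatten_truth(truth)
    with open(path, "w") as fh:
        for key, val in flat.items():
            fh.write(f"{key} = {val!r}\n")


def read_truth(path) -> dict:
    import ast

    from .simulate import unflatten_truth
    flat = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition(" = ")
            flat[key] = ast.literal_eval(val)
    return unflatten_truth(flat)


# ---------------------------------------------------------------------------
# hierarchical array container (HDF5)

def write_container(path, arrays: dict, attrs: dict | None = None) -> None:
    """Write a flat mapping of name -> ndarray into an HDF5 file."""
    import h5py
    with h5py.File(path, "w") as fh:
        for name, arr in arrays.items():
            arr = np.asarray(arr)
            if arr.dtype.kind in ("U", "O"):
                arr = arr.astype("S")
            fh.create_dataset(name, data=arr)
        for key, val in (attrs or {}).items():
            fh.attrs[key] = val


def read_container(path) -> tuple[dict, dict]:
    import h5py
    arrays, attrs = {}, {}
    with h5py.File(path, "r") as fh:
        def visit(name, obj):
            if isinstance(obj, h5py.Dataset):
                arrays[name] = obj[()]
        fh.visititems(visit)
        attrs = dict(fh.attrs)
    return arrays, attrs
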