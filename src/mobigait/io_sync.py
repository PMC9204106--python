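"""On-disk formats and cross-system clock synchronization.

A mobile brain/body imaging (MoBI) platform records EEG on one device and
body sensors (EMG, 3-axis acceleration) on another; the two clock domains are
reconciled offline through a shared square synchronization pulse recorded by
both systems.  This module holds the in-memory :class:`SensorStream`
container, readers/writers for the open containers used throughout the
package (EDF for EEG, TSV for body sensors and tables, HDF5 for lead fields),
and :func:`align_streams`, the cross-correlation synchronizer.
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

from ._edf import EdfFormatError, peek_labels, write_edf

STREAM_KINDS = ("eeg", "emg", "accel", "pulse")


class AlignmentError(RuntimeError):
    """No usable pulse edges, or pulse trains that cannot be matched."""


@dataclasses.dataclass
class SensorStream:
    """A uniformly sampled multichannel recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal values. EEG is in microvolts, EMG in millivolts, acceleration
        in m/s^2; the container does not enforce units.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Unique per-channel identifiers.
    kind : {"eeg", "emg", "accel", "pulse"}
    start_time : float
        Start of the first sample in the recorder's own clock, seconds.
    """

    data: np.ndarray
    fs: float
    labels: list
    kind: str
    start_time: float = 0.0

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stream contains non-finite samples")
        self.labels = list(self.labels)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels")
        if self.kind not in STREAM_KINDS:
            raise ValueError(f"kind must be one of {STREAM_KINDS}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in the recorder clock, seconds."""
        return self.start_time + np.arange(self.n_samples) / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]

    def pick(self, labels) -> "SensorStream":
        idx = [self.labels.index(l) for l in labels]
        return dataclasses.replace(self, data=self.data[idx], labels=list(labels))

    def copy(self) -> "SensorStream":
        return dataclasses.replace(self, data=self.data.copy(),
                                   labels=list(self.labels))


@dataclasses.dataclass
class SyncReport:
    """Result of pulse-train alignment between two recorders."""

    lag: float                      # seconds, b's clock minus a's clock
    jitter: float                   # seconds, sd of per-edge residuals
    method: str = "cross-correlation"
    n_edges: int = 0

    def __post_init__(self):
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


# ---------------------------------------------------------------------------
# EDF (EEG)

def read_eeg(path) -> SensorStream:
    """Read an EDF/EDF+ file into a SensorStream (microvolts).

    The channel labels are first inspected straight from the fixed-offset
    header (duplicate labels are a hard error — downstream bookkeeping is
    label-addressed), then the data are loaded with :func:`mne.io.read_raw_edf`.
    """
    import mne

    labels = peek_labels(path)
    if len(set(labels)) != len(labels):
        raise EdfFormatError(f"{path}: duplicate channel labels in header")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as err:  # mne raises bare exceptions on bad headers
        raise EdfFormatError(f"{path}: unreadable EDF ({err})") from err
    data = raw.get_data() * 1e6  # mne returns volts for uV channels
    return SensorStream(data=data, fs=float(raw.info["sfreq"]),
                        labels=list(raw.ch_names), kind="eeg")


def write_eeg(path, stream: SensorStream) -> None:
    """Write a SensorStream (microvolt data) as EDF."""
    write_edf(path, stream.data, stream.fs, stream.labels, physical_dim="uV")


# ---------------------------------------------------------------------------
# TSV (body sensors, tables)

def read_body(path, kind: str = "emg") -> SensorStream:
    """Read a body-sensor TSV with a ``time_s`` column followed by channels."""
    df = pd.read_csv(path, sep="\t")
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required 'time_s' column")
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    if len(dt) < 1 or np.ptp(dt) > 1e-3 * np.median(dt):
        raise ValueError(f"{path}: time_s is not uniformly sampled")
    labels = [c for c in df.columns if c != "time_s"]
    return SensorStream(data=df[labels].to_numpy().T, fs=1.0 / np.median(dt),
                        labels=labels, kind=kind, start_time=float(t[0]))


def write_body(path, stream: SensorStream) -> None:
    df = pd.DataFrame({"time_s": stream.times})
    for lab, row in zip(stream.labels, stream.data):
        df[lab] = row
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# HDF5 (lead field)

def write_lead_field(path, gain: np.ndarray, grid_mm: np.ndarray,
                     spacing_mm: float, electrodes_mm: np.ndarray | None = None
                     ) -> None:
    """Store a lead field: ``gain`` (n_chan, n_src, 3), ``grid_mm`` (n_src, 3)."""
    gain = np.asarray(gain, float)
    grid_mm = np.asarray(grid_mm, float)
    if gain.ndim != 3 or gain.shape[2] != 3:
        raise ValueError("gain must have shape (n_chan, n_src, 3)")
    if grid_mm.shape != (gain.shape[1], 3):
        raise ValueError("grid_mm must have shape (n_src, 3)")
    with h5py.File(path, "w") as fh:
        fh.create_dataset("gain", data=gain)
        fh.create_dataset("grid_mm", data=grid_mm)
        fh.create_dataset("spacing_mm", data=float(spacing_mm))
        if electrodes_mm is not None:
            fh.create_dataset("electrodes_mm", data=np.asarray(electrodes_mm, float))


def read_lead_field(path):
    """Return (gain, grid_mm, spacing_mm) from the HDF5 container."""
    with h5py.File(path, "r") as fh:
        for name in ("gain", "grid_mm", "spacing_mm"):
            if name not in fh:
                raise KeyError(f"{path}: missing dataset '{name}'")
        return (fh["gain"][()], fh["grid_mm"][()], float(fh["spacing_mm"][()]))


# ---------------------------------------------------------------------------
# Synchronization

def _pulse_channel(stream: SensorStream) -> np.ndarray:
    if stream.kind == "pulse":
        return stream.data[0]
    for lab in stream.labels:
        if "pulse" in lab.lower() or lab.lower() in ("sync", "trig", "trigger"):
            return stream.channel(lab)
    raise AlignmentError("no pulse channel found (label containing 'pulse')")


def _rising_edges(x: np.ndarray, fs: float) -> np.ndarray:
    """Times of upward threshold crossings, refined by linear interpolation."""
    lo, hi = np.min(x), np.max(x)
    if hi - lo <= 0:
        return np.array([])
    thr = 0.5 * (hi + lo)
    above = x > thr
    idx = np.flatnonzero(~above[:-1] & above[1:])
    if idx.size == 0:
        return np.array([])
    frac = (thr - x[idx]) / (x[idx + 1] - x[idx])
    return (idx + frac) / fs


def align_streams(a: SensorStream, b: SensorStream, common_fs: float = 1000.0,
                  max_lag_s: float = 30.0) -> SyncReport:
    """Estimate the clock offset of stream ``b`` relative to stream ``a``.

    Both pulse channels are resampled to ``common_fs``, the lag maximizing
    their normalized cross-correlation within ``±max_lag_s`` is found (with
    parabolic sub-sample refinement), and the residual per-edge offsets after
    applying the lag give the jitter estimate.

    Returns a :class:`SyncReport` whose ``lag`` is the amount of time stream
    b's events occur *after* the same events in stream a's clock: shifting
    b's timestamps by ``-lag`` moves them into a's clock.
    """
    pa, pb = _pulse_channel(a), _pulse_channel(b)

    def to_common(x, fs):
        if abs(fs - common_fs) < 1e-9:
            return x.astype(float)
        from fractions import Fraction
        frac = Fraction(common_fs / fs).limit_denominator(10000)
        return sps.resample_poly(x.astype(float), frac.numerator, frac.denominator)

    xa, xb = to_common(pa, a.fs), to_common(pb, b.fs)
    xa = xa - xa.mean()
    xb = xb - xb.mean()
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise AlignmentError("no pulse edges detected in one of the streams")

    corr = sps.correlate(xb, xa, mode="full", method="fft")
    lags = sps.correlation_lags(len(xb), len(xa), mode="full")
    window = np.abs(lags) <= max_lag_s * common_fs
    corr, lags = corr[window], lags[window]
    k = int(np.argmax(corr))
    # parabolic peak interpolation for sub-sample lag
    if 0 < k < len(corr) - 1:
        denom = corr[k - 1] - 2 * corr[k] + corr[k + 1]
        delta = 0.5 * (corr[k - 1] - corr[k + 1]) / denom if denom != 0 else 0.0
    else:
        delta = 0.0
    lag = (lags[k] + delta) / common_fs
    # clock offset: b's sample j corresponds to a's time; account for start times
    lag_clock = lag + b.start_time - a.start_time

    ea = _rising_edges(pa, a.fs) + a.start_time
    eb = _rising_edges(pb, b.fs) + b.start_time - lag_clock
    if ea.size == 0 or eb.size == 0:
        raise AlignmentError("no pulse edges detected in one of the streams")
    # match each b edge to the nearest a edge
    j = np.searchsorted(ea, eb)
    j = np.clip(j, 1, len(ea) - 1)
    nearest = np.where(np.abs(eb - ea[j - 1]) < np.abs(eb - ea[j]), j - 1, j)
    resid = eb - ea[nearest]
    keep = np.abs(resid) < 0.1  # discard unmatched edges at the ends
    resid = resid[keep]
    jitter = float(np.std(resid)) if resid.size else 0.0
    return SyncReport(lag=float(lag_clock), jitter=jitter,
                      n_edges=int(resid.size))


def shift_into(b: SensorStream, report: SyncReport) -> SensorStream:
    """Move a body-sensor stream into the EEG clock by shifting timestamps.

    No resampling of data channels happens here; only ``start_time`` changes.
    """
    return dataclasses.replace(b, data=b.data.copy(),
                               start_time=b.start_time - report.lag)
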