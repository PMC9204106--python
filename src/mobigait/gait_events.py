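"""Gait segmentation from ankle accelerometry.

Walking is segmented into left-referenced gait cycles (left heel strike to
next left heel strike), each subdivided by right toe off, right heel strike
and left toe off.  Heel strikes appear as dominant impact peaks in the total
(Euclidean-norm) ankle acceleration; toe offs are recovered as the onset of
the subsequent swing burst.  Velocity is estimated as the drift-controlled
integral of the total acceleration.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

from .io_sync import SensorStream

log = logging.getLogger(__name__)

DURATION_BOUNDS_S = (0.5, 2.5)


class SegmentationError(RuntimeError):
    pass


@dataclasses.dataclass
class GaitEventTable:
    """Ordered per-cycle event times.

    ``cycles`` is an (n_cycles, 5) array of LHS, RTO, RHS, LTO and next-LHS
    times in seconds, strictly increasing within each row.
    """

    cycles: np.ndarray
    n_discarded: int = 0

    COLUMNS = ("t_LHS", "t_RTO", "t_RHS", "t_LTO", "t_LHS_next")

    def __post_init__(self):
        self.cycles = np.atleast_2d(np.asarray(self.cycles, float))
        if self.cycles.shape[1] != 5:
            raise ValueError("cycles must have 5 event columns")
        if np.any(np.diff(self.cycles, axis=1) <= 0):
            raise ValueError("events within a cycle must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        return self.cycles.shape[0]

    @property
    def durations(self) -> np.ndarray:
        return self.cycles[:, 4] - self.cycles[:, 0]

    def event_fractions(self) -> np.ndarray:
        """Median within-cycle fractions of RTO, RHS, LTO."""
        d = self.durations[:, None]
        return np.median((self.cycles[:, 1:4] - self.cycles[:, :1]) / d, axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cycles, columns=list(self.COLUMNS))

    def to_tsv(self, path) -> None:
        """Write BIDS-style events: onset, duration, trial_type."""
        rows = []
        for cyc in self.cycles:
            for name, t in zip(("LHS", "RTO", "RHS", "LTO"), cyc[:4]):
                rows.append({"onset": t, "duration": 0.0, "trial_type": name})
        # closing heel strike of the final cycle
        rows.append({"onset": self.cycles[-1, 4], "duration": 0.0,
                     "trial_type": "LHS"})
        pd.DataFrame(rows).sort_values("onset").to_csv(
            path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "GaitEventTable":
        df = pd.read_csv(path, sep="\t").sort_values("onset")
        lhs = df[df.trial_type == "LHS"].onset.to_numpy()
        cycles = []
        for a, b in zip(lhs[:-1], lhs[1:]):
            mid = df[(df.onset > a) & (df.onset < b)]
            try:
                rto = mid[mid.trial_type == "RTO"].onset.iloc[0]
                rhs = mid[mid.trial_type == "RHS"].onset.iloc[0]
                lto = mid[mid.trial_type == "LTO"].onset.iloc[0]
            except IndexError:
                continue
            cycles.append((a, rto, rhs, lto, b))
        if not cycles:
            raise SegmentationError(f"{path}: no complete cycles")
        return cls(cycles=np.array(cycles))


def total_acceleration(accel: SensorStream) -> SensorStream:
    """Euclidean norm of the three axes, mean-removed (gravity/bias)."""
    if accel.n_channels != 3:
        raise ValueError(
            f"total acceleration needs exactly 3 axes, got {accel.n_channels}")
    norm = np.linalg.norm(accel.data, axis=0)
    return SensorStream(data=(norm - norm.mean())[None, :], fs=accel.fs,
                        labels=["total_accel"], kind="accel",
                        start_time=accel.start_time)


def velocity_from_accel(total_accel: SensorStream,
                        highpass_hz: float = 0.3) -> SensorStream:
    """Velocity as the cumulative trapezoidal integral of total acceleration.

    A zero-phase high-pass (default 0.3 Hz) is applied first to suppress
    integration drift; pass ``highpass_hz=0`` to disable it.
    """
    if total_accel.fs < 50:
        raise ValueError("need fs >= 50 Hz for velocity estimation")
    if highpass_hz >= total_accel.fs / 2:
        raise ValueError(
            f"high-pass edge {highpass_hz} Hz at or above Nyquist")
    x = total_accel.data[0]
    if highpass_hz > 0:
        sos = sps.butter(2, highpass_hz / (total_accel.fs / 2),
                         btype="high", output="sos")
        x = sps.sosfiltfilt(sos, x)
    v = cumulative_trapezoid(x, dx=1.0 / total_accel.fs, initial=0.0)
    if highpass_hz > 0:
        # remove residual drift of the integral itself
        v = sps.sosfiltfilt(sos, v)
    return SensorStream(data=v[None, :], fs=total_accel.fs,
                        labels=["velocity"], kind="accel",
                        start_time=total_accel.start_time)


def _moving_rms(x: np.ndarray, win: int) -> np.ndarray:
    kernel = np.ones(win)
    num = np.convolve(x ** 2, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return np.sqrt(num / den)


def select_stable_segments(velocity: SensorStream, win_s: float = 4.0,
                           tol: float = 0.2, min_len_s: float = 5.0,
                           min_rms: float = 0.02) -> list:
    """Time intervals where the velocity envelope RMS is steady.

    Samples whose windowed RMS stays within ``±tol`` of the running median
    RMS — and above the absolute motion floor ``min_rms`` (m/s), which
    excludes standstill — are kept; contiguous runs shorter than
    ``min_len_s`` are dropped.  Returns a list of (t_start, t_end) tuples;
    may be empty.
    """
    fs = velocity.fs
    x = velocity.data[0]
    win = max(3, int(win_s * fs))
    rms = _moving_rms(x, win)
    med_win = max(3, int(10 * win_s * fs))
    running_med = pd.Series(rms).rolling(
        med_win, center=True, min_periods=1).median().to_numpy()
    ok = (np.abs(rms - running_med) <= tol * np.maximum(running_med, 1e-12)) \
        & (rms > min_rms)
    intervals = []
    edges = np.diff(ok.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if ok[0]:
        starts.insert(0, 0)
    if ok[-1]:
        ends.append(len(ok))
    for i0, i1 in zip(starts, ends):
        if (i1 - i0) / fs >= min_len_s:
            intervals.append((velocity.start_time + i0 / fs,
                              velocity.start_time + i1 / fs))
    return intervals


def _estimate_cadence(env: np.ndarray, fs: float) -> float:
    """Dominant stride rate from the autocorrelation of the envelope."""
    env = env - env.mean()
    ac = sps.correlate(env, env, mode="full")[len(env) - 1:]
    lo, hi = int(fs / 2.0), int(fs / 0.4)  # cycle durations 0.5-2.5 s
    hi = min(hi, len(ac) - 1)
    if hi <= lo:
        raise SegmentationError("recording too short for cadence estimation")
    k = lo + int(np.argmax(ac[lo:hi]))
    return fs / k


def _heel_strikes(tot: np.ndarray, fs: float, cadence: float) -> np.ndarray:
    dist = max(1, int(0.4 / cadence * fs))
    prom = 2.0 * np.std(tot)
    peaks, _ = sps.find_peaks(np.abs(tot), distance=dist, prominence=prom)
    return peaks / fs


def _toe_off(env: np.ndarray, fs: float, t0: float, t1: float,
             onset_frac: float = 0.3) -> float | None:
    """Onset of the swing burst inside (t0, t1): first crossing of
    ``onset_frac`` x burst peak, walking back from the burst maximum."""
    i0, i1 = int(t0 * fs), int(t1 * fs)
    if i1 - i0 < 3 or i0 < 0 or i1 > len(env):
        return None
    seg = env[i0:i1]
    pk = int(np.argmax(seg))
    thr = onset_frac * seg[pk]
    below = np.flatnonzero(seg[:pk] <= thr)
    if below.size == 0:
        return None
    return (i0 + below[-1] + 1) / fs


def detect_events(left_accel: SensorStream, right_accel: SensorStream,
                  cadence_hint: float | None = None,
                  onset_frac: float = 0.3,
                  validate_durations: bool = True) -> GaitEventTable:
    """Detect LHS/RTO/RHS/LTO events from the two ankle accelerometers.

    Heel strikes are prominence-based impact peaks of each ankle's total
    acceleration (minimum spacing 0.4 cycle); toe offs are swing-burst
    onsets at ``onset_frac`` of the burst peak.  Cycles violating event
    ordering or the 0.5-2.5 s duration bounds are discarded and counted.
    """
    for s in (left_accel, right_accel):
        if s.duration < 10:
            raise SegmentationError("need at least 10 s of acceleration data")
    tot_l = total_acceleration(left_accel).data[0]
    tot_r = total_acceleration(right_accel).data[0]
    fs = left_accel.fs

    # smooth envelopes of rectified total acceleration for burst detection
    sos = sps.butter(2, 5.0 / (fs / 2), btype="low", output="sos")
    env_l = sps.sosfiltfilt(sos, np.abs(tot_l))
    env_r = sps.sosfiltfilt(sos, np.abs(tot_r))

    if np.std(tot_l) < 1e-12 or np.std(tot_r) < 1e-12:
        raise SegmentationError("flat acceleration signal, nothing to segment")
    cadence = cadence_hint or _estimate_cadence(env_l, fs)
    lhs = _heel_strikes(tot_l, fs, cadence)
    rhs_all = _heel_strikes(tot_r, fs, cadence)
    if len(lhs) < 4 or len(rhs_all) < 3:
        raise SegmentationError(
            f"too few heel strikes detected ({len(lhs)} left, {len(rhs_all)} right)")

    cycles, discarded = [], 0
    for a, b in zip(lhs[:-1], lhs[1:]):
        dur = b - a
        inside = rhs_all[(rhs_all > a) & (rhs_all < b)]
        if len(inside) != 1:
            discarded += 1
            continue
        rhs = float(inside[0])
        # right swing burst precedes RHS; left swing burst precedes next LHS
        rto = _toe_off(env_r, fs, a + 0.02 * dur, rhs - 0.05 * dur, onset_frac)
        lto = _toe_off(env_l, fs, rhs + 0.02 * dur, b - 0.05 * dur, onset_frac)
        if rto is None or lto is None:
            discarded += 1
            continue
        row = (a, rto, rhs, lto, b)
        if np.any(np.diff(row) <= 0):
            discarded += 1
            continue
        if validate_durations and not (DURATION_BOUNDS_S[0] <= dur
                                       <= DURATION_BOUNDS_S[1]):
            discarded += 1
            continue
        cycles.append(row)
    if discarded:
        log.info("detect_events: discarded %d invalid cycles", discarded)
    if len(cycles) < 3:
        raise SegmentationError(
            f"only {len(cycles)} valid cycles found (need >= 3)")
    return GaitEventTable(cycles=np.array(cycles), n_discarded=discarded)
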