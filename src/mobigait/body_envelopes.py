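"""Trial-averaged velocity/EMG envelopes on the gait-percentage grid.

Each body signal is reduced to its Hilbert amplitude envelope at 200 Hz,
every gait cycle is piecewise-linearly time-warped so that its right toe
off, right heel strike and left toe off land on the participant-median event
percentages, and the warped cycles are averaged.  Cross-sensor
inter-dependence is quantified with Pearson correlations of the averaged
curves, Fisher z-transformed for group statistics and corrected with the
Benjamini-Hochberg false discovery rate.
"""

from __future__ import annotations

import dataclasses
import logging
from fractions import Fraction
from itertools import combinations

import numpy as np
from scipy import signal as sps
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gait_events import GaitEventTable
from .io_sync import SensorStream

log = logging.getLogger(__name__)

R_CAP = 1.0 - 1e-7  # |r| is capped here before atanh to keep z finite


def fisher_z(r):
    return np.arctanh(np.clip(r, -R_CAP, R_CAP))


def fisher_z_inv(z):
    return np.tanh(z)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (NaNs passed through)."""
    p = np.asarray(p, float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def preprocess_emg(raw: SensorStream) -> SensorStream:
    """Zero-phase 1-500 Hz band-pass, then full-wave rectification."""
    if raw.fs <= 1000:
        raise ValueError(
            f"EMG sampling rate must exceed 1000 Hz for the 1-500 Hz band, "
            f"got {raw.fs}")
    sos = sps.butter(4, [1.0 / (raw.fs / 2), 500.0 / (raw.fs / 2)],
                     btype="band", output="sos")
    data = np.abs(sps.sosfiltfilt(sos, raw.data, axis=1))
    return dataclasses.replace(raw, data=data)


def envelope(signal: SensorStream, target_fs: float = 200.0) -> SensorStream:
    """Hilbert amplitude envelope, anti-alias resampled to ``target_fs``."""
    if target_fs > signal.fs:
        raise ValueError(
            f"cannot upsample envelope: target {target_fs} > fs {signal.fs}")
    env = np.abs(sps.hilbert(signal.data, axis=1))
    if abs(target_fs - signal.fs) > 1e-9:
        frac = Fraction(target_fs / signal.fs).limit_denominator(10000)
        env = sps.resample_poly(env, frac.numerator, frac.denominator, axis=1)
    return SensorStream(data=env, fs=target_fs, labels=list(signal.labels),
                        kind=signal.kind, start_time=signal.start_time)


@dataclasses.dataclass
class CycleEnvelope:
    """A signal envelope re-expressed on the 0-100% gait-cycle grid."""

    grid: np.ndarray          # percent positions, 0..100
    per_cycle: np.ndarray     # (n_cycles, grid_n)
    mean: np.ndarray
    sensor_id: str = ""
    signal_type: str = "emg"  # "velocity" or "emg"

    def __post_init__(self):
        self.grid = np.asarray(self.grid, float)
        self.per_cycle = np.atleast_2d(np.asarray(self.per_cycle, float))
        if np.any(np.diff(self.grid) <= 0) or self.grid[0] != 0 \
                or abs(self.grid[-1] - 100) > 1e-9:
            raise ValueError("grid must increase strictly from 0 to 100")
        if not np.all(np.isfinite(self.per_cycle)):
            raise ValueError("per-cycle rows must be finite")


def warp_cycles(values: np.ndarray, times: np.ndarray,
                events: GaitEventTable, grid_n: int = 200,
                anchors: np.ndarray | None = None) -> tuple:
    """Time-warp a continuous signal into per-cycle percentage curves.

    For each gait cycle the mapping time -> percent is piecewise linear
    through (LHS, 0), (RTO, p1), (RHS, p2), (LTO, p3), (next LHS, 100), with
    (p1, p2, p3) the participant-median event percentages (or ``anchors``).
    Rows (one per usable cycle) are sampled at ``grid_n`` evenly spaced
    percentages by inverting the map and interpolating the signal.

    ``values`` may be 1-D (T,) or 2-D (k, T); returns ``(grid, per_cycle)``
    where per_cycle is (n_cycles, grid_n) or (n_cycles, k, grid_n).
    """
    if grid_n < 50:
        raise ValueError("grid_n must be at least 50")
    values = np.asarray(values, float)
    times = np.asarray(times, float)
    grid = np.linspace(0.0, 100.0, grid_n)
    if anchors is None:
        anchors = 100.0 * events.event_fractions()
    pct_nodes = np.concatenate([[0.0], np.asarray(anchors, float), [100.0]])
    rows, dropped = [], 0
    for cyc in events.cycles:
        if cyc[0] < times[0] - 1e-9 or cyc[4] > times[-1] + 1e-9:
            dropped += 1
            continue
        # invert percent -> time within this cycle
        t_grid = np.interp(grid, pct_nodes, cyc)
        if values.ndim == 1:
            rows.append(np.interp(t_grid, times, values))
        else:
            rows.append(np.stack([np.interp(t_grid, times, v) for v in values]))
    if dropped:
        log.info("warp_cycles: dropped %d cycles outside the signal span",
                 dropped)
    if not rows:
        raise ValueError("no gait cycle lies within the signal time span")
    return grid, np.array(rows)


def standardize_to_cycle(env: SensorStream, events: GaitEventTable,
                         grid_n: int = 200, channel: int = 0,
                         sensor_id: str = "", signal_type: str = "emg"
                         ) -> CycleEnvelope:
    """Warp one envelope channel onto the percentage grid and trial-average."""
    grid, per_cycle = warp_cycles(env.data[channel], env.times, events, grid_n)
    return CycleEnvelope(grid=grid, per_cycle=per_cycle,
                         mean=per_cycle.mean(axis=0),
                         sensor_id=sensor_id or str(env.labels[channel]),
                         signal_type=signal_type)


@dataclasses.dataclass
class EnvelopeCorrStats:
    """Cross-sensor envelope correlation statistics.

    ``r`` is (n_participants, n_sensors, n_sensors); group statistics are
    per unique off-diagonal pair, FDR-corrected within the whole table.
    """

    sensors: list
    r: np.ndarray
    z: np.ndarray
    group_r: np.ndarray          # tanh(mean z), (n_sensors, n_sensors)
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    mean_abs_z: np.ndarray       # per participant
    max_abs_z: np.ndarray        # per participant
    signal_type: str = "emg"


def correlate_sensors(envs_per_participant: list,
                      signal_type: str = "emg",
                      method: str = "pearson") -> EnvelopeCorrStats:
    """Group statistics of cross-sensor envelope correlations.

    Parameters
    ----------
    envs_per_participant : list of list of CycleEnvelope
        One inner list per participant, same sensor order for everyone.
    method : {"pearson", "spearman"}

    Constant envelopes give undefined correlations; those cells are NaN and
    excluded from the per-participant summaries and group tests.
    """
    n_part = len(envs_per_participant)
    sensors = [e.sensor_id for e in envs_per_participant[0]]
    n_sens = len(sensors)
    if n_sens < 2:
        raise ValueError("need at least 2 sensors")
    r = np.full((n_part, n_sens, n_sens), np.nan)
    for pi, envs in enumerate(envs_per_participant):
        if [e.sensor_id for e in envs] != sensors:
            raise ValueError("sensor sets differ across participants")
        curves = np.array([e.mean for e in envs])
        for i, j in combinations(range(n_sens), 2):
            xi, xj = curves[i], curves[j]
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                log.warning("constant envelope for %s/%s in participant %d",
                            sensors[i], sensors[j], pi)
                continue
            if method == "spearman":
                rij = stats.spearmanr(xi, xj).statistic
            else:
                rij = np.corrcoef(xi, xj)[0, 1]
            r[pi, i, j] = r[pi, j, i] = rij
        np.fill_diagonal(r[pi], 1.0)
    z = fisher_z(r)

    iu = np.triu_indices(n_sens, k=1)
    t = np.full((n_sens, n_sens), np.nan)
    p = np.full((n_sens, n_sens), np.nan)
    if n_part >= 2:
        for i, j in zip(*iu):
            zij = z[:, i, j]
            zij = zij[np.isfinite(zij)]
            if len(zij) >= 2 and np.std(zij) > 0:
                res = stats.ttest_1samp(zij, 0.0)
                t[i, j] = t[j, i] = res.statistic
                p[i, j] = p[j, i] = res.pvalue
    q = np.full_like(p, np.nan)
    q_flat = bh_fdr(p[iu])
    q[iu] = q_flat
    q.T[iu] = q_flat

    with np.errstate(invalid="ignore"):
        group_r = fisher_z_inv(np.nanmean(z, axis=0))
    np.fill_diagonal(group_r, 1.0)

    offdiag = np.abs(z[:, iu[0], iu[1]])
    import warnings as _warnings
    with _warnings.catch_warnings():
        # participants whose pairs are all undefined summarize to NaN
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean_abs_z = np.nanmean(offdiag, axis=1)
        max_abs_z = np.nanmax(offdiag, axis=1)
    return EnvelopeCorrStats(sensors=sensors, r=r, z=z, group_r=group_r,
                             t=t, p=p, q=q, mean_abs_z=mean_abs_z,
                             max_abs_z=max_abs_z, signal_type=signal_type)
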