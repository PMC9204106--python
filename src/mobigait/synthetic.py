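"""Synthetic mobile brain/body imaging (MoBI) data with known ground truth.

The generator emulates the recording setup the rest of the package analyses:
a treadmill-walking participant instrumented with high-density EEG, wireless
EMG sensors over eight leg muscles (left/right vastus medialis, biceps
femoris, tibialis anterior, gastrocnemius), two ankle accelerometers, and a
shared square synchronization pulse.  Everything is driven by a single
:class:`GaitTimeline`, so gait events, muscle activation envelopes, source
power modulations and artifact time courses are all known exactly and can be
compared against what the analysis stages recover.

Physiological phasing of the muscle templates follows the classical gait
literature: the vastus medialis fires briefly before/after its own heel
strike, the biceps femoris in terminal swing through double support, the
tibialis anterior throughout swing and the following double support, and the
gastrocnemius during stance — in antiphase with the other three.  Cortical
sources carry alpha/beta rhythms whose power drops during the contralateral
leg swing and a weaker gamma rhythm with the reverse modulation, mirroring
the sensorimotor event-related (de)synchronization pattern of walking.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sps

from .io_sync import SensorStream

MUSCLES = ("vastus", "biceps_femoris", "tibialis", "gastrocnemius")
BANDS = {"alpha": (8.0, 13.0), "beta": (13.0, 30.0), "gamma": (30.0, 50.0)}

#: raised-cosine activation windows in *own-side* gait phase
#: (own heel strike at 0, own toe off near 0.62): (center, width)
MUSCLE_WINDOWS = {
    "vastus": (0.02, 0.24),          # around own heel strike
    "biceps_femoris": (0.97, 0.24),  # terminal swing -> double support
    "tibialis": (0.87, 0.52),        # swing + following double support
    "gastrocnemius": (0.37, 0.52),   # stance / single support
}

DEFAULT_EVENT_FRACTIONS = (0.12, 0.50, 0.62)  # RTO, RHS, LTO


class TimelineError(ValueError):
    pass


@dataclasses.dataclass
class GaitTimeline:
    """Ground-truth walking timeline.

    ``cycle_starts`` holds n_cycles + 1 left-heel-strike times, so adjacent
    entries delimit full gait cycles.  ``event_fractions`` are the
    within-cycle positions of right toe off, right heel strike and left toe
    off.
    """

    cycle_starts: np.ndarray
    event_fractions: tuple = DEFAULT_EVENT_FRACTIONS
    cadence: float = 1.0
    duration_cv: float = 0.0

    def __post_init__(self):
        self.cycle_starts = np.asarray(self.cycle_starts, float)
        if np.any(np.diff(self.cycle_starts) <= 0):
            raise TimelineError("cycle starts must be strictly increasing")
        rto, rhs, lto = self.event_fractions
        if not (0 < rto < rhs < lto < 1):
            raise TimelineError(
                f"event fractions must satisfy 0 < RTO < RHS < LTO < 1, "
                f"got {self.event_fractions}")

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_starts) - 1

    @property
    def durations(self) -> np.ndarray:
        return np.diff(self.cycle_starts)

    @property
    def t_end(self) -> float:
        return float(self.cycle_starts[-1])

    def event_times(self) -> np.ndarray:
        """(n_cycles, 5) array of LHS, RTO, RHS, LTO, next-LHS times."""
        starts = self.cycle_starts[:-1]
        durs = self.durations
        rto, rhs, lto = self.event_fractions
        return np.column_stack([
            starts, starts + rto * durs, starts + rhs * durs,
            starts + lto * durs, self.cycle_starts[1:],
        ])

    def phase(self, t: np.ndarray) -> np.ndarray:
        """Left-referenced gait phase in [0, 1) at times ``t``.

        Outside the walking span the phase continues periodically at the
        nearest cycle's rate, so modulation waveforms stay well defined.
        """
        t = np.asarray(t, float)
        idx = np.clip(np.searchsorted(self.cycle_starts, t, side="right") - 1,
                      0, self.n_cycles - 1)
        starts = self.cycle_starts[idx]
        return np.mod((t - starts) / self.durations[idx], 1.0)


def make_timeline(cadence: float, n_cycles: int, duration_cv: float = 0.0,
                  seed: int = 0,
                  event_fractions: tuple = DEFAULT_EVENT_FRACTIONS
                  ) -> GaitTimeline:
    """Draw a walking timeline with jittered cycle durations.

    Durations are ``(1/cadence) * (1 + cv * eps)`` with ``eps`` standard
    normal truncated at three sigma, keeping durations positive and
    physiological.
    """
    if cadence <= 0:
        raise TimelineError(f"cadence must be positive, got {cadence}")
    if n_cycles < 1:
        raise TimelineError(f"need at least one cycle, got {n_cycles}")
    if duration_cv < 0:
        raise TimelineError("duration_cv must be non-negative")
    if duration_cv >= 0.5:
        raise TimelineError(
            f"duration_cv = {duration_cv} is non-physiological (>= 0.5)")
    rng = np.random.default_rng(seed)
    eps = np.clip(rng.standard_normal(n_cycles), -3.0, 3.0)
    durations = (1.0 / cadence) * (1.0 + duration_cv * eps)
    starts = np.concatenate([[0.0], np.cumsum(durations)])
    return GaitTimeline(cycle_starts=starts, event_fractions=event_fractions,
                        cadence=cadence, duration_cv=duration_cv)


# ---------------------------------------------------------------------------
# phase-domain templates

def _wrapped_window(phi: np.ndarray, center: float, width: float) -> np.ndarray:
    """Raised-cosine bump of given width on the circular phase axis."""
    d = np.mod(phi - center + 0.5, 1.0) - 0.5
    out = np.zeros_like(np.asarray(phi, float))
    inside = np.abs(d) < width / 2
    out[inside] = 0.5 * (1 + np.cos(2 * np.pi * d[inside] / width))
    return out


def muscle_template(phi_own: np.ndarray, muscle: str) -> np.ndarray:
    """Activation template in own-side phase (own heel strike at 0)."""
    center, width = MUSCLE_WINDOWS[muscle]
    return _wrapped_window(phi_own, center, width)


def _own_phase(phi_left: np.ndarray, side: str, rhs_frac: float) -> np.ndarray:
    if side == "left":
        return np.asarray(phi_left, float)
    return np.mod(np.asarray(phi_left, float) - rhs_frac, 1.0)


def swing_velocity_template(phi_own: np.ndarray, to_frac: float) -> np.ndarray:
    """Smooth swing-velocity bump: sin^2 over [toe off, next heel strike)."""
    phi_own = np.asarray(phi_own, float)
    u = (phi_own - to_frac) / (1.0 - to_frac)
    v = np.zeros_like(phi_own)
    inswing = (u >= 0) & (u < 1)
    v[inswing] = np.sin(np.pi * u[inswing]) ** 2
    return v


def _swing_accel(phi_own: np.ndarray, to_frac: float,
                 inv_duration: np.ndarray) -> np.ndarray:
    """Analytic time derivative of the swing-velocity template."""
    phi_own = np.asarray(phi_own, float)
    u = (phi_own - to_frac) / (1.0 - to_frac)
    a = np.zeros_like(phi_own)
    inswing = (u >= 0) & (u < 1)
    a[inswing] = (np.pi / (1.0 - to_frac)) * np.sin(2 * np.pi * u[inswing]) \
        * inv_duration[inswing]
    return a


# ---------------------------------------------------------------------------
# body sensors

@dataclasses.dataclass
class BodyTruth:
    """Ground truth returned by :func:`simulate_body` on the 0-100% grid."""

    grid: np.ndarray                     # percent positions
    emg_curves: dict                     # label -> activation curve
    velocity_curves: dict                # "left"/"right" -> swing velocity
    timeline: GaitTimeline


@dataclasses.dataclass
class BodySim:
    accel_left: SensorStream
    accel_right: SensorStream
    emg: SensorStream                    # 8 channels, one per muscle sensor
    accel_sites: dict                    # muscle label -> 3-axis SensorStream
    truth: BodyTruth


def _band_noise(n: int, fs: float, lo: float, hi: float,
                rng: np.random.Generator) -> np.ndarray:
    nyq = fs / 2
    hi = min(hi, 0.99 * nyq)
    sos = sps.butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_body(timeline: GaitTimeline, fs_accel: float = 148.0,
                  fs_emg: float = 2000.0, noise_sd: float = 0.1,
                  seed: int = 0, grid_n: int = 200,
                  impact_rel: float = 4.0) -> BodySim:
    """Simulate ankle accelerometers and the eight EMG sensors.

    Ankle acceleration is the analytic derivative of a smooth swing-velocity
    bump (near-zero during stance) plus a short damped-oscillation impact at
    each ipsilateral heel strike, distributed over three axes with gravity on
    the vertical axis.  EMG is 20-450 Hz broadband noise amplitude-modulated
    by the muscle's activation window.  ``noise_sd`` is the additive noise
    level as a fraction of each signal's modulation scale.
    """
    if fs_emg < 1024:
        raise ValueError(
            f"fs_emg must be >= 1024 Hz for the 1-500 Hz EMG band, got {fs_emg}")
    if fs_accel < 100:
        raise ValueError(f"fs_accel must be >= 100 Hz, got {fs_accel}")
    rng = np.random.default_rng(seed)
    rto, rhs, lto = timeline.event_fractions
    t_end = timeline.t_end + 1.0
    grid = np.linspace(0.0, 100.0, grid_n)
    phi_grid = grid / 100.0

    # --- ankle acceleration ------------------------------------------------
    t_acc = np.arange(int(round(t_end * fs_accel))) / fs_accel
    phi = timeline.phase(t_acc)
    idx = np.clip(np.searchsorted(timeline.cycle_starts, t_acc, "right") - 1,
                  0, timeline.n_cycles - 1)
    inv_dur = 1.0 / timeline.durations[idx]

    u_swing = np.array([0.75, 0.25, 0.61])
    u_swing /= np.linalg.norm(u_swing)
    u_imp = np.array([0.30, 0.10, 0.95])
    u_imp /= np.linalg.norm(u_imp)

    def impact_train(hs_times: np.ndarray, amp: float) -> np.ndarray:
        out = np.zeros_like(t_acc)
        klen = int(0.04 * fs_accel) + 1
        tk = np.arange(klen) / fs_accel
        kernel = amp * np.exp(-tk / 0.010) * np.sin(2 * np.pi * 40 * tk)
        for hs in hs_times:
            i0 = int(np.round(hs * fs_accel))
            if 0 <= i0 < len(out):
                j = min(klen, len(out) - i0)
                out[i0:i0 + j] += kernel[:j]
        return out

    events = timeline.event_times()

    active_acc = t_acc <= timeline.t_end  # sensors go quiet after the walk

    def accel_axes(side: str, swing_gain: float, impact_gain: float,
                   tag: str) -> SensorStream:
        phi_own = _own_phase(phi, side, rhs)
        sw = swing_gain * _swing_accel(phi_own, lto, inv_dur) * active_acc
        peak = max(np.max(np.abs(sw)), 1e-12)
        # every heel strike, including the one closing the last cycle
        hs_times = timeline.cycle_starts if side == "left" else events[:, 2]
        imp = impact_train(hs_times, impact_gain * impact_rel * peak)
        axes = np.outer(u_swing, sw) + np.outer(u_imp, imp)
        axes[2] += 9.81
        axes += noise_sd * peak * rng.standard_normal(axes.shape)
        return SensorStream(data=axes, fs=fs_accel, kind="accel",
                            labels=[f"{tag}_{ax}" for ax in "xyz"])

    streams = {side: accel_axes(side, 1.0, 1.0, f"{side}_ankle")
               for side in ("left", "right")}

    # the wireless muscle sensors also carry 3-axis accelerometers: thigh
    # sensors see an attenuated version of the leg swing, shank sensors are
    # close to the ankle trajectory; ipsilateral sensors therefore share one
    # swing pattern, which is what makes velocity envelopes strongly
    # inter-dependent within a limb
    site_gain = {"vastus": 0.5, "biceps_femoris": 0.5,
                 "tibialis": 0.9, "gastrocnemius": 0.9}
    accel_sites = {}
    for side in ("left", "right"):
        for muscle in MUSCLES:
            label = f"{muscle}_{side[0]}"
            accel_sites[label] = accel_axes(side, site_gain[muscle], 0.4,
                                            label)

    # --- EMG ---------------------------------------------------------------
    t_emg = np.arange(int(round(t_end * fs_emg))) / fs_emg
    phi_e = timeline.phase(t_emg)
    emg_rows, labels, emg_curves = [], [], {}
    baseline = 0.08
    active_emg = t_emg <= timeline.t_end
    for side in ("left", "right"):
        phi_own = _own_phase(phi_e, side, rhs)
        for muscle in MUSCLES:
            mod = baseline + muscle_template(phi_own, muscle) * active_emg
            carrier = _band_noise(len(t_emg), fs_emg, 20.0, 450.0, rng)
            row = mod * carrier + noise_sd * rng.standard_normal(len(t_emg))
            label = f"{muscle}_{side[0]}"
            emg_rows.append(row)
            labels.append(label)
            phi_own_grid = _own_phase(phi_grid, side, rhs)
            emg_curves[label] = baseline + muscle_template(phi_own_grid, muscle)
    emg = SensorStream(data=np.array(emg_rows), fs=fs_emg, labels=labels,
                       kind="emg")

    velocity_curves = {
        side: swing_velocity_template(_own_phase(phi_grid, side, rhs), lto)
        for side in ("left", "right")
    }
    truth = BodyTruth(grid=grid, emg_curves=emg_curves,
                      velocity_curves=velocity_curves, timeline=timeline)
    return BodySim(accel_left=streams["left"], accel_right=streams["right"],
                   emg=emg, accel_sites=accel_sites, truth=truth)


# ---------------------------------------------------------------------------
# lead field

class LeadFieldError(ValueError):
    pass


@dataclasses.dataclass
class LeadField:
    """Gain matrix mapping dipole moments to scalp potentials.

    ``gain`` has shape (n_channels, n_sources, 3); ``grid_mm`` holds the
    source coordinates in mm; electrodes are on the upper hemisphere of a
    95-mm head sphere.
    """

    gain: np.ndarray
    grid_mm: np.ndarray
    spacing_mm: float
    electrodes_mm: np.ndarray | None = None
    labels: list | None = None

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]


def dipole_potential(electrodes_mm: np.ndarray, source_mm: np.ndarray,
                     sigma: float = 0.33) -> np.ndarray:
    """Quasi-static potential of a unit current dipole, homogeneous conductor.

    Returns the (n_electrodes, 3) gain block: column k is the potential of a
    unit dipole along axis k.  Distances in mm are converted to metres.
    """
    d = (electrodes_mm - source_mm[None, :]) * 1e-3
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-4):
        raise LeadFieldError("electrode coincides with source position")
    return d / (4 * np.pi * sigma * r[:, None] ** 3)


def _hemisphere_electrodes(n: int, radius_mm: float = 95.0) -> np.ndarray:
    """Fibonacci-spiral electrode layout on the upper half of the head sphere."""
    i = np.arange(n)
    z = 0.15 + 0.84 * (i + 0.5) / n          # keep clear of the equator
    phi = np.pi * (1 + 5 ** 0.5) * i
    rho = np.sqrt(1 - z ** 2)
    return radius_mm * np.column_stack([rho * np.cos(phi),
                                        rho * np.sin(phi), z])


def make_lead_field(n_channels: int = 32, grid_shape=(5, 5, 4),
                    spacing_mm: float = 6.0, seed: int = 0,
                    center_mm=(0.0, 0.0, 40.0)) -> LeadField:
    """Build a synthetic lead field over a regular cuboid source grid.

    The gain is the closed-form quasi-static dipole potential evaluated at
    upper-hemisphere electrode sites and average-referenced per column.  Each
    source's 3-column orientation block is checked for full rank.
    """
    if n_channels < 8:
        raise LeadFieldError(f"need at least 8 channels, got {n_channels}")
    nx, ny, nz = grid_shape
    if nx * ny * nz < 27:
        raise LeadFieldError("need at least 27 sources")
    center = np.asarray(center_mm, float)
    ax = [(np.arange(n) - (n - 1) / 2) * spacing_mm for n in (nx, ny, nz)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]) + center

    elec = _hemisphere_electrodes(n_channels)
    gain = np.empty((n_channels, len(grid), 3))
    for v, pos in enumerate(grid):
        block = dipole_potential(elec, pos)
        block = block - block.mean(axis=0, keepdims=True)  # average reference
        if np.linalg.matrix_rank(block, tol=1e-12 * np.abs(block).max()) < 3:
            raise LeadFieldError(f"rank-deficient orientation block at voxel {v}")
        gain[:, v, :] = block
    labels = [f"E{i + 1:03d}" for i in range(n_channels)]
    return LeadField(gain=gain, grid_mm=grid, spacing_mm=spacing_mm,
                     electrodes_mm=elec, labels=labels)


# ---------------------------------------------------------------------------
# EEG

@dataclasses.dataclass
class BandProfile:
    """One rhythm of a source: oscillation amplitude (uV-scale, arbitrary
    units) and a zero-mean gait-phase power-modulation curve on the 0-100%
    grid (relative amplitude modulation; -0.4 means a 40% amplitude dip)."""

    amplitude: float
    modulation: np.ndarray

    def __post_init__(self):
        self.modulation = np.asarray(self.modulation, float)
        if not np.all(np.isfinite(self.modulation)):
            raise ValueError("modulation curve must be finite")
        self.modulation = self.modulation - self.modulation.mean()


@dataclasses.dataclass
class SourceSpec:
    """A planted cortical source: grid position, per-band rhythms, a
    broadband 1/f-like floor, and (metadata only) expected coupling signs."""

    voxel_index: int
    band_profiles: dict            # band name -> BandProfile
    broadband: float = 1.0         # amplitude of the 1-80 Hz background
    couplings: dict | None = None  # sensor label -> expected sign


@dataclasses.dataclass
class ArtifactSpec:
    """Amplitudes (component-space units) of the three artifact families."""

    ocular_rate: float = 0.25      # blinks per second
    ocular_amp: float = 30.0
    motion_amp: float = 10.0
    myogenic_amp: float = 5.0
    topographies: dict | None = None

    def __post_init__(self):
        for name in ("ocular_rate", "ocular_amp", "motion_amp", "myogenic_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclasses.dataclass
class EegTruth:
    """Everything the simulator knows: the exact mixing model X = M S + N."""

    mixing: np.ndarray             # (n_channels, n_components)
    signals: np.ndarray            # (n_components, n_samples)
    component_kinds: list          # "source" / "ocular" / "motion" / "myogenic"
    source_specs: list
    band_power_curves: dict        # (source idx, band) -> squared-amp curve
    timeline: GaitTimeline
    orientations: np.ndarray       # (n_sources, 3) dipole orientations


def _modulation_at(phi: np.ndarray, curve: np.ndarray) -> np.ndarray:
    grid = np.linspace(0.0, 1.0, len(curve))
    return np.interp(phi, grid, curve)


def _smooth_topography(n_channels: int, rng: np.random.Generator) -> np.ndarray:
    w = rng.standard_normal(n_channels)
    w = np.convolve(w, np.hanning(max(3, n_channels // 4)), mode="same")
    w -= w.mean()
    return w / np.linalg.norm(w)


def simulate_eeg(timeline: GaitTimeline, leadfield: LeadField,
                 sources: list, artifacts: ArtifactSpec | None = None,
                 fs: float = 1000.0, sensor_noise_sd: float = 0.5,
                 seed: int = 0) -> tuple[SensorStream, EegTruth]:
    """Project planted sources and artifacts to the scalp.

    Each source emits, per band, band-filtered Gaussian noise whose
    instantaneous amplitude is ``amplitude * (1 + modulation(phase))``
    (floored at 5% to stay non-negative), plus a pink-ish broadband floor.
    Dipole orientations are fixed unit vectors drawn from the seed.  Artifact
    components are topography x waveform: sparse biexponential blinks,
    step-locked near-sinusoidal motion, and 30-80 Hz broadband myogenic
    noise.  White sensor noise is added last.
    """
    rng = np.random.default_rng(seed)
    n_ch = leadfield.n_channels
    t_end = timeline.t_end + 1.0
    n = int(round(t_end * fs))
    t = np.arange(n) / fs
    phi = timeline.phase(t)

    mix_cols, sig_rows, kinds = [], [], []
    band_power_curves = {}
    orients = np.empty((len(sources), 3))
    for si, spec in enumerate(sources):
        if not (0 <= spec.voxel_index < leadfield.n_sources):
            raise LeadFieldError(
                f"source voxel index {spec.voxel_index} outside grid "
                f"(0..{leadfield.n_sources - 1})")
        o = rng.standard_normal(3)
        o /= np.linalg.norm(o)
        orients[si] = o
        wave = np.zeros(n)
        for band, prof in spec.band_profiles.items():
            lo, hi = BANDS[band]
            carrier = _band_noise(n, fs, lo, hi, rng)
            amp = prof.amplitude * np.maximum(
                1.0 + _modulation_at(phi, prof.modulation), 0.05)
            wave += amp * carrier
            band_power_curves[(si, band)] = (
                prof.amplitude * np.maximum(1.0 + prof.modulation, 0.05)) ** 2
        if spec.broadband > 0:
            # pink-ish floor: 1/sqrt(f) shaping of white noise within 1-80 Hz
            white = rng.standard_normal(n)
            spec_f = np.fft.rfft(white)
            f = np.fft.rfftfreq(n, 1 / fs)
            shape = np.zeros_like(f)
            bandmask = (f >= 1.0) & (f <= min(80.0, 0.99 * fs / 2))
            shape[bandmask] = 1.0 / np.sqrt(f[bandmask])
            floor = np.fft.irfft(spec_f * shape, n)
            floor /= max(floor.std(), 1e-12)
            wave += spec.broadband * floor
        pattern = leadfield.gain[:, spec.voxel_index, :] @ o
        mix_cols.append(pattern)
        sig_rows.append(wave)
        kinds.append("source")

    if artifacts is not None:
        topo = artifacts.topographies or {}

        def get_topo(name):
            return topo.get(name, _smooth_topography(n_ch, rng))

        if artifacts.ocular_amp > 0:
            n_blinks = rng.poisson(artifacts.ocular_rate * t_end)
            times = np.sort(rng.uniform(0, t_end, n_blinks))
            wave = np.zeros(n)
            # ~250 ms biexponential blink: 15 ms rise, 50 ms decay
            klen = int(0.25 * fs)
            tk = np.arange(klen) / fs
            kernel = np.exp(-tk / 0.05) - np.exp(-tk / 0.015)
            kernel /= kernel.max()
            for bt in times:
                i0 = int(bt * fs)
                j = min(klen, n - i0)
                if j > 0:
                    wave[i0:i0 + j] += kernel[:j]
            mix_cols.append(artifacts.ocular_amp * get_topo("ocular"))
            sig_rows.append(wave)
            kinds.append("ocular")
        if artifacts.motion_amp > 0:
            f_step = 2.0 * timeline.cadence
            wave = np.sin(2 * np.pi * f_step * t + rng.uniform(0, 2 * np.pi))
            wave += 0.4 * np.sin(4 * np.pi * f_step * t)
            mix_cols.append(artifacts.motion_amp * get_topo("motion"))
            sig_rows.append(wave)
            kinds.append("motion")
        if artifacts.myogenic_amp > 0:
            wave = _band_noise(n, fs, 30.0, 80.0, rng)
            mix_cols.append(artifacts.myogenic_amp * get_topo("myogenic"))
            sig_rows.append(wave)
            kinds.append("myogenic")

    mixing = np.column_stack(mix_cols) if mix_cols else np.zeros((n_ch, 0))
    signals = np.array(sig_rows) if sig_rows else np.zeros((0, n))
    data = mixing @ signals
    if sensor_noise_sd > 0:
        data = data + sensor_noise_sd * rng.standard_normal(data.shape)
    labels = leadfield.labels or [f"E{i + 1:03d}" for i in range(n_ch)]
    eeg = SensorStream(data=data, fs=fs, labels=list(labels), kind="eeg")
    truth = EegTruth(mixing=mixing, signals=signals, component_kinds=kinds,
                     source_specs=list(sources),
                     band_power_curves=band_power_curves, timeline=timeline,
                     orientations=orients)
    return eeg, truth


# ---------------------------------------------------------------------------
# synchronization pulse and study defaults

def make_pulse(duration: float, fs: float, period: float = 1.0,
               width: float = 0.2, amplitude: float = 1.0,
               delay: float = 0.0, edge_jitter_sd: float = 0.0,
               seed: int = 0) -> SensorStream:
    """Square synchronization pulse train as recorded by one system."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    onsets = np.arange(delay + period / 2, duration - width, period)
    if edge_jitter_sd > 0:
        onsets = onsets + rng.normal(0, edge_jitter_sd, len(onsets))
    x = np.zeros(n)
    for on in onsets:
        x[(t >= on) & (t < on + width)] = amplitude
    return SensorStream(data=x[None, :], fs=fs, labels=["PULSE"], kind="pulse")


def contralateral_modulation(grid_n: int, hemisphere: str,
                             event_fractions: tuple = DEFAULT_EVENT_FRACTIONS,
                             depth: float = -0.4) -> np.ndarray:
    """Zero-mean modulation curve: power change during the contralateral swing.

    For the left hemisphere the contralateral (right) swing spans
    [RTO, RHS] of the left-referenced cycle; for the right hemisphere the
    left swing spans [LTO, 100%].  ``depth`` < 0 plants the alpha/beta power
    decrease seen over sensorimotor cortex during walking; a positive depth
    gives the reversed (gamma-like) modulation.
    """
    rto, rhs, lto = event_fractions
    phi = np.linspace(0.0, 1.0, grid_n)
    if hemisphere == "left":
        center, width = (rto + rhs) / 2, (rhs - rto) + 0.14
    else:
        center, width = (lto + 1.0) / 2, (1.0 - lto) + 0.14
    curve = depth * _wrapped_window(phi, center, width)
    return curve - curve.mean()


def default_m1_sources(leadfield: LeadField, grid_n: int = 200,
                       depth_alphabeta: float = -0.4,
                       depth_gamma: float = 0.15,
                       amp_alpha: float = 4.0, amp_beta: float = 3.0,
                       amp_gamma: float = 1.5, broadband: float = 2.0,
                       event_fractions: tuple = DEFAULT_EVENT_FRACTIONS
                       ) -> list:
    """Bilateral sensorimotor ('M1') sources with the walking ERD/ERS pattern.

    The two source voxels are the most lateral positions in the top grid
    layer, one per hemisphere; alpha and beta power decrease during the
    contralateral swing, gamma weakly increases.
    """
    grid = leadfield.grid_mm
    top = grid[:, 2].max()
    top_idx = np.flatnonzero(np.abs(grid[:, 2] - top) < 1e-9)
    left_vox = top_idx[np.argmin(grid[top_idx, 0])]
    right_vox = top_idx[np.argmax(grid[top_idx, 0])]
    out = []
    for hemi, vox in (("left", left_vox), ("right", right_vox)):
        profiles = {
            "alpha": BandProfile(amp_alpha, contralateral_modulation(
                grid_n, hemi, event_fractions, depth_alphabeta)),
            "beta": BandProfile(amp_beta, contralateral_modulation(
                grid_n, hemi, event_fractions, depth_alphabeta)),
            "gamma": BandProfile(amp_gamma, contralateral_modulation(
                grid_n, hemi, event_fractions, depth_gamma)),
        }
        out.append(SourceSpec(voxel_index=int(vox), band_profiles=profiles,
                              broadband=broadband))
    return out
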