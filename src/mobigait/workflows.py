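"""End-to-end simulated study: generate -> segment -> clean -> reconstruct
-> correlate, for one participant or a whole group.

These functions chain the public stages exactly as the per-stage modules
expose them, so a study run exercises the same code paths a user would call.
The NKC (velocity) and NMC (EMG) pipelines share every stage except which
body envelope goes into the final correlation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import body_envelopes as be
from . import connectivity as conn
from . import eeg_clean as clean
from . import gait_events as ge
from . import source_recon as sr
from . import synthetic as syn

#: expected NMC sign pattern (Fig-8-like): for each muscle of one leg, the
#: contralateral hemisphere shows negative alpha/beta coupling and the
#: ipsilateral positive — except the gastrocnemius, whose stance-phase
#: activation is in antiphase with the other muscles, reversing both signs.
EXPECTED_NMC_SIGN = {"vastus": -1, "biceps_femoris": -1, "tibialis": -1,
                     "gastrocnemius": +1}  # sign at the *contralateral* M1


@dataclasses.dataclass
class StudyConfig:
    """Study conditions for the simulated walking experiment."""

    cadence: float = 0.9          # cycles/s
    n_cycles: int = 80            # about 90 s of walking
    duration_cv: float = 0.03
    n_channels: int = 32
    grid_shape: tuple = (5, 5, 4)
    spacing_mm: float = 6.0
    fs_eeg: float = 200.0
    fs_emg: float = 2000.0
    fs_accel: float = 148.0
    body_noise_sd: float = 0.1
    sensor_noise_sd: float = 0.5
    grid_n: int = 200
    with_artifacts: bool = True


def make_study_leadfield(cfg: StudyConfig, seed: int = 0):
    """Shared lead field, eLORETA operator and bilateral M1 ROI specs."""
    lf = syn.make_lead_field(cfg.n_channels, cfg.grid_shape, cfg.spacing_mm,
                             seed=seed)
    op = sr.eloreta_fit(lf)
    sources = syn.default_m1_sources(lf, grid_n=cfg.grid_n)
    rois = {}
    for hemi, spec in zip(("left", "right"), sources):
        rois[hemi] = sr.RoiSpec(name="M1", hemisphere=hemi,
                                center_mm=lf.grid_mm[spec.voxel_index],
                                radius_mm=6.0)
    return lf, op, rois


def run_participant(seed: int, cfg: StudyConfig, lf, op, rois) -> dict:
    """Simulate and analyse one participant; returns per-sensor results.

    The returned dict holds a long-format NMC/NKC DataFrame (sensor,
    signal_type, roi, band, r), the per-signal-type max/mean |z| envelope
    inter-dependence, and the gait table actually detected.
    """
    timeline = syn.make_timeline(cfg.cadence, cfg.n_cycles, cfg.duration_cv,
                                 seed=seed)
    body = syn.simulate_body(timeline, cfg.fs_accel, cfg.fs_emg,
                             cfg.body_noise_sd, seed=seed + 10_000)
    events = ge.detect_events(body.accel_left, body.accel_right,
                              cadence_hint=cfg.cadence)

    sources = syn.default_m1_sources(lf, grid_n=cfg.grid_n)
    artifacts = syn.ArtifactSpec() if cfg.with_artifacts else None
    eeg, truth = syn.simulate_eeg(timeline, lf, sources, artifacts,
                                  fs=cfg.fs_eeg,
                                  sensor_noise_sd=cfg.sensor_noise_sd,
                                  seed=seed + 20_000)

    # preprocessing: band-pass, staged artifact attenuation (oracle
    # decomposition from the simulator's known mixing), average reference
    eeg = clean.filter_resample(eeg, target_fs=cfg.fs_eeg)
    backend = clean.GroundTruthBackend(truth.mixing)
    eeg, _report = clean.attenuate_artifacts(eeg, backend)
    eeg = clean.average_reference(eeg)

    dipoles = sr.apply_inverse(op, eeg)
    voxel_signals = sr.collapse_all(dipoles)
    roi_signals = {h: sr.extract_roi(voxel_signals, spec, lf.grid_mm)
                   for h, spec in rois.items()}
    specs = {h: conn.gait_spectrogram(sig, cfg.fs_eeg, events,
                                      grid_n=cfg.grid_n)
             for h, sig in roi_signals.items()}

    # body envelopes: EMG (NMC) and muscle-site velocity (NKC)
    emg_env = be.envelope(be.preprocess_emg(body.emg), target_fs=200.0)
    emg_cycle = {lab: be.standardize_to_cycle(emg_env, events, cfg.grid_n,
                                              channel=i, signal_type="emg")
                 for i, lab in enumerate(emg_env.labels)}
    vel_cycle = {}
    for lab, acc in body.accel_sites.items():
        vel = ge.velocity_from_accel(ge.total_acceleration(acc))
        venv = be.envelope(vel, target_fs=vel.fs)
        vel_cycle[lab] = be.standardize_to_cycle(venv, events, cfg.grid_n,
                                                 sensor_id=lab,
                                                 signal_type="velocity")

    rows = []
    for hemi, spec in specs.items():
        for signal_type, cyc in (("emg", emg_cycle), ("velocity", vel_cycle)):
            for lab, env in cyc.items():
                profile = conn.connectivity_profile(spec, env)
                for band, r in conn.band_aggregate(spec.freqs, profile).items():
                    rows.append({"sensor": lab, "signal_type": signal_type,
                                 "roi": f"M1_{hemi}", "band": band, "r": r})
    df = pd.DataFrame(rows)

    interdep = {}
    for signal_type, cyc in (("emg", emg_cycle), ("velocity", vel_cycle)):
        stats_ = be.correlate_sensors([list(cyc.values())],
                                      signal_type=signal_type)
        interdep[signal_type] = {"mean_abs_z": float(stats_.mean_abs_z[0]),
                                 "max_abs_z": float(stats_.max_abs_z[0])}
    return {"connectivity": df, "interdependence": interdep,
            "events": events, "timeline": timeline}


def run_study(n_participants: int, seed: int,
              cfg: StudyConfig | None = None) -> dict:
    """Run the full simulated group study.

    Returns the combined long-format connectivity table (with a participant
    column), the per-participant envelope inter-dependence summaries, and
    the shared lead field objects.
    """
    cfg = cfg or StudyConfig()
    lf, op, rois = make_study_leadfield(cfg, seed=seed)
    frames, interdep = [], []
    for pi in range(n_participants):
        res = run_participant(seed + 100 * (pi + 1), cfg, lf, op, rois)
        df = res["connectivity"]
        df.insert(0, "participant", pi)
        frames.append(df)
        interdep.append(res["interdependence"])
    return {"connectivity": pd.concat(frames, ignore_index=True),
            "interdependence": interdep, "leadfield": lf, "rois": rois,
            "config": cfg}


def nmc_sign_table(connectivity: pd.DataFrame, band: str) -> pd.DataFrame:
    """Group-mean NMC of right-leg sensors at both hemispheres, one band.

    Returns a row per (muscle, hemisphere) with the recovered group-mean r
    and the expected sign (contralateral per EXPECTED_NMC_SIGN, flipped for
    ipsilateral).
    """
    emg = connectivity[(connectivity.signal_type == "emg")
                       & (connectivity.band == band)]
    rows = []
    for muscle, contra_sign in EXPECTED_NMC_SIGN.items():
        sensor = f"{muscle}_r"
        for roi, expected in (("M1_left", contra_sign),
                              ("M1_right", -contra_sign)):
            sub = emg[(emg.sensor == sensor) & (emg.roi == roi)]
            z = be.fisher_z(sub["r"].to_numpy())
            rows.append({"muscle": muscle, "roi": roi,
                         "group_r": be.fisher_z_inv(z.mean()),
                         "expected_sign": expected})
    return pd.DataFrame(rows)
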