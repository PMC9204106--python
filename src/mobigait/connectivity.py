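"""Frequency-resolved neurokinematic / neuromuscular connectivity (NKC/NMC).

A reconstructed neural signal is expanded with a continuous wavelet
transform (1-50 Hz, 6 octaves x 8 voices per octave), the per-frequency
power is warped onto the gait-percentage grid with exactly the same anchor
warping used for the body envelopes, trial-averaged and z-scored per
frequency.  Correlating the standardized power modulation with a body
envelope over the cycle grid gives one connectivity value per frequency;
band aggregates average over alpha (8-13), beta (13-30) and gamma
(30-50 Hz).  Group inference uses Fisher z, one-sample t-tests, n-way
fixed-effects ANOVAs and Benjamini-Hochberg FDR; voxel-wise connectivity
images get a vectorized balanced two-way ANOVA (band x sensor).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pywt
from scipy import stats

from .body_envelopes import CycleEnvelope, bh_fdr, fisher_z, fisher_z_inv, \
    warp_cycles
from .gait_events import GaitEventTable

BAND_EDGES = {"alpha": (8.0, 13.0), "beta": (13.0, 30.0),
              "gamma": (30.0, 50.0)}
WAVELET = "cmor1.5-1.0"


def cwt_frequencies(f_max: float = 50.0, f_min: float = 1.0,
                    octaves: int = 6, voices: int = 8) -> np.ndarray:
    """Descending-octave frequency grid, masked to [f_min, f_max]."""
    j = np.arange(octaves * voices + 1)
    freqs = f_max * 2.0 ** (-j / voices)
    return np.sort(freqs[freqs >= f_min])


@dataclasses.dataclass
class GaitSpectrogram:
    """Trial-averaged, per-frequency-standardized gait power modulation."""

    freqs: np.ndarray       # Hz, increasing, within [1, 50]
    grid: np.ndarray        # 0-100 percent positions
    power: np.ndarray       # (n_freqs, grid_n), z-scored per frequency
    raw_power: np.ndarray | None = None  # pre-standardization average

    def __post_init__(self):
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequencies must be increasing")
        if not np.all(np.isfinite(self.power)):
            raise ValueError("spectrogram power must be finite")


def gait_spectrogram(signal: np.ndarray, fs: float, events: GaitEventTable,
                     start_time: float = 0.0, grid_n: int = 200,
                     f_min: float = 1.0, f_max: float = 50.0,
                     octaves: int = 6, voices: int = 8) -> GaitSpectrogram:
    """Gait-locked wavelet power modulation of one neural signal.

    The analytic Morlet CWT magnitude squared is computed on the stated
    octave/voice grid, each frequency row is warped to the percentage grid
    (same anchors as the body envelopes), averaged over cycles and z-scored
    across the grid.
    """
    signal = np.asarray(signal, float).ravel()
    if events.n_cycles < 3:
        raise ValueError("need at least 3 gait cycles for a spectrogram")
    freqs = cwt_frequencies(f_max, f_min, octaves, voices)
    scales = pywt.central_frequency(WAVELET) * fs / freqs
    coefs, _ = pywt.cwt(signal, scales, WAVELET, sampling_period=1.0 / fs)
    power = np.abs(coefs) ** 2  # (n_freqs, T), freqs descending in `scales`

    times = start_time + np.arange(len(signal)) / fs
    # drop cycles inside the cone of influence of the slowest wavelet, where
    # boundary effects bias the power estimate
    margin = 3.0 / f_min
    inside = (events.cycles[:, 0] >= times[0] + margin) \
        & (events.cycles[:, 4] <= times[-1] - margin)
    if inside.sum() < 3:
        raise ValueError("need at least 3 gait cycles clear of the wavelet "
                         "boundary region")
    trimmed = GaitEventTable(cycles=events.cycles[inside])
    grid, per_cycle = warp_cycles(power, times, trimmed, grid_n,
                                  anchors=100.0 * events.event_fractions())
    avg = per_cycle.mean(axis=0)                    # (n_freqs, grid_n)
    sd = avg.std(axis=1, keepdims=True)
    z = (avg - avg.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    return GaitSpectrogram(freqs=freqs, grid=grid, power=z, raw_power=avg)


def connectivity_profile(spec: GaitSpectrogram,
                         body: CycleEnvelope) -> np.ndarray:
    """Pearson r between neural power and the body envelope, per frequency."""
    if spec.grid.shape != body.grid.shape or \
            not np.allclose(spec.grid, body.grid):
        raise ValueError("spectrogram and envelope grids differ")
    b = body.mean - body.mean.mean()
    bn = np.linalg.norm(b)
    P = spec.power - spec.power.mean(axis=1, keepdims=True)
    Pn = np.linalg.norm(P, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (P @ b) / (Pn * bn)
    return r


def band_aggregate(freqs: np.ndarray, profile: np.ndarray,
                   bands: dict = BAND_EDGES) -> dict:
    """Mean per-frequency r within each half-open [lo, hi) band."""
    out = {}
    for name, (lo, hi) in bands.items():
        mask = (freqs >= lo) & (freqs < hi)
        if mask.sum() < 2:
            raise ValueError(
                f"band {name} [{lo}, {hi}) covered by {mask.sum()} "
                f"frequencies; need >= 2")
        out[name] = float(np.mean(profile[mask]))
    return out


# ---------------------------------------------------------------------------
# group statistics

CELL_KEYS = ["sensor", "signal_type", "roi", "band"]


def group_stats(df: pd.DataFrame, cell_keys: list = None) -> pd.DataFrame:
    """Group-level inference on per-participant connectivity values.

    ``df`` is long-format with columns ``participant``, ``r`` and the cell
    keys (default sensor / signal_type / roi / band).  Per cell: Fisher z,
    one-sample t against zero across participants, BH-FDR q over all cells
    of the table (the declared test family).  Zero-variance cells get NaN
    statistics and a ``degenerate`` flag.
    """
    cell_keys = [k for k in (cell_keys or CELL_KEYS) if k in df.columns]
    if df["participant"].nunique() < 3:
        raise ValueError("group statistics need at least 3 participants")
    rows = []
    for keys, sub in df.groupby(cell_keys, sort=True):
        z = fisher_z(sub["r"].to_numpy())
        rec = dict(zip(cell_keys, keys if isinstance(keys, tuple) else (keys,)))
        rec["n"] = len(z)
        rec["z_mean"] = z.mean()
        rec["group_r"] = fisher_z_inv(z.mean())
        if np.std(z) > 0:
            t = stats.ttest_1samp(z, 0.0)
            rec["t"], rec["p"] = t.statistic, t.pvalue
            rec["degenerate"] = False
        elif np.allclose(z, 0):
            rec["t"], rec["p"], rec["degenerate"] = 0.0, 1.0, False
        else:
            rec["t"], rec["p"], rec["degenerate"] = np.nan, np.nan, True
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def anova_nway(df: pd.DataFrame, dv: str, factors: list,
               interaction: bool = False) -> pd.DataFrame:
    """Balanced fixed-effects ANOVA via an OLS fit with sum-to-zero coding.

    Main effects only by default (the four-way layout); ``interaction=True``
    adds all two-way interaction terms (used for the two-way analyses).
    Participants act as replicates; an unbalanced layout is rejected.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    counts = df.groupby(factors, sort=False).size()
    if counts.nunique() != 1:
        raise ValueError("unbalanced factor layout")
    terms = [f"C({f}, Sum)" for f in factors]
    if interaction:
        from itertools import combinations
        terms += [f"C({a}, Sum):C({b}, Sum)"
                  for a, b in combinations(factors, 2)]
    model = smf.ols(f"{dv} ~ " + " + ".join(terms), data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(columns={"PR(>F)": "p", "df": "df", "F": "F"})
    table.index = [i.replace("C(", "").replace(", Sum)", "")
                   for i in table.index]
    # degenerate all-equal layout: a numerically nil effect over a nil
    # residual is no effect, not an indeterminate ratio
    scale = max(df[dv].abs().max() ** 2 * len(df), 1e-300)
    zero = table["sum_sq"] < 1e-24 * scale
    table.loc[zero, "F"] = 0.0
    table.loc[zero, "p"] = 1.0
    return table


# ---------------------------------------------------------------------------
# voxel-wise images

@dataclasses.dataclass
class ConnectivityImageSet:
    """Voxel-wise group images and the band x sensor ANOVA maps."""

    bands: list
    sensors: list
    group_images: np.ndarray      # (n_bands, n_sensors, n_vox) mean r
    effects: list                 # ["band", "sensor", "band:sensor"]
    F: dict                       # effect -> (n_vox,)
    p: dict
    q: dict
    masks: dict                   # effect -> boolean (n_vox,), q < q_level
    q_level: float = 0.001
    display_threshold: float = 0.2

    def thresholded(self, band: str, sensor: str) -> np.ndarray:
        """Group image with |r| <= display threshold blanked (rendering only)."""
        img = self.group_images[self.bands.index(band),
                                self.sensors.index(sensor)].copy()
        img[np.abs(img) <= self.display_threshold] = 0.0
        return img


def _twoway_anova_vectorized(y: np.ndarray):
    """Balanced two-way ANOVA with interaction, replicates on axis 0.

    ``y`` has shape (n_rep, n_a, n_b, n_vox); returns dict of (F, p) per
    effect computed from classical sums of squares, vectorized over voxels.
    """
    n, a, b = y.shape[0], y.shape[1], y.shape[2]
    grand = y.mean(axis=(0, 1, 2))
    mean_ab = y.mean(axis=0)                      # (a, b, n_vox)
    mean_a = y.mean(axis=(0, 2))                  # (a, n_vox)
    mean_b = y.mean(axis=(0, 1))                  # (b, n_vox)
    ss_a = n * b * ((mean_a - grand) ** 2).sum(axis=0)
    ss_b = n * a * ((mean_b - grand) ** 2).sum(axis=0)
    inter = mean_ab - mean_a[:, None] - mean_b[None, :] + grand
    ss_ab = n * (inter ** 2).sum(axis=(0, 1))
    ss_e = ((y - mean_ab) ** 2).sum(axis=(0, 1, 2))
    df_a, df_b, df_ab, df_e = a - 1, b - 1, (a - 1) * (b - 1), a * b * (n - 1)
    ms_e = ss_e / df_e
    out = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for name, ss, dfn in (("band", ss_a, df_a), ("sensor", ss_b, df_b),
                              ("band:sensor", ss_ab, df_ab)):
            F = (ss / dfn) / ms_e
            out[name] = (F, stats.f.sf(F, dfn, df_e))
    return out


def connectivity_images(r: np.ndarray, bands: list, sensors: list,
                        q_level: float = 0.001,
                        display_threshold: float = 0.2
                        ) -> ConnectivityImageSet:
    """Group-average voxel images and the voxel-wise two-way ANOVA.

    ``r`` has shape (n_participants, n_bands, n_sensors, n_vox) and must be
    fully populated.  The ANOVA (band x sensor, with interaction, across
    participants) converts F-maps to p-maps, FDR-corrects across voxels per
    effect, and binarizes significance at ``q < q_level``.
    """
    r = np.asarray(r, float)
    if r.ndim != 4:
        raise ValueError("expected (participants, bands, sensors, voxels)")
    if not np.all(np.isfinite(r)):
        bad = np.argwhere(~np.isfinite(r))[0]
        raise ValueError(f"missing connectivity value at voxel {bad[3]} "
                         f"(participant {bad[0]}, band {bands[bad[1]]}, "
                         f"sensor {sensors[bad[2]]})")
    z = fisher_z(r)
    group_images = fisher_z_inv(z.mean(axis=0))
    anova = _twoway_anova_vectorized(z)
    F, p, q, masks = {}, {}, {}, {}
    for eff, (Fv, pv) in anova.items():
        F[eff], p[eff] = Fv, pv
        q[eff] = bh_fdr(pv)
        masks[eff] = q[eff] < q_level
    return ConnectivityImageSet(bands=list(bands), sensors=list(sensors),
                                group_images=group_images,
                                effects=list(anova), F=F, p=p, q=q,
                                masks=masks, q_level=q_level,
                                display_threshold=display_threshold)


def write_nifti(path, values: np.ndarray, grid_shape: tuple,
                spacing_mm: float, origin_mm=(0.0, 0.0, 0.0)) -> None:
    """Write a flat per-voxel image onto its source grid as NIfTI."""
    import nibabel as nib

    vol = np.asarray(values, float).reshape(grid_shape)
    affine = np.diag([spacing_mm] * 3 + [1.0])
    affine[:3, 3] = origin_mm
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(path))
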