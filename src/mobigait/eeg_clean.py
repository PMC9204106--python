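"""EEG preprocessing: bad channels, filtering, three-stage artifact screening.

The artifact pipeline decomposes the data three times, in a fixed order, and
zeroes components failing that stage's criterion:

1. ocular    — deflation-mode ICA; maximum kurtosis over 5-s windows > 12
2. movement  — symmetric-mode ICA; mean sample entropy over 20-s windows < 0.8
3. myogenic  — joint decomposition; band power P[30-80 Hz] > P[1-30 Hz]

Decomposition backends are pluggable: production uses scikit-learn FastICA,
tests use a ground-truth backend whose unmixing is the simulator's known
mixing, so the screening rules themselves are what gets verified.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy import signal as sps
from scipy import stats

from .io_sync import SensorStream

log = logging.getLogger(__name__)

STAGES = ("ocular", "motion", "myogenic")
KURTOSIS_THRESHOLD = 12.0       # max over 5-s windows, excess kurtosis
SAMPEN_THRESHOLD = 0.8          # mean over 20-s windows
POWER_RATIO_THRESHOLD = 1.0     # P[30-80] / P[1-30]
KURT_WIN_S = 5.0
SAMPEN_WIN_S = 20.0


class ChannelQualityError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# sample entropy

try:
    from numba import njit

    @njit(cache=True)
    def _sampen_counts(x, m, r):
        n = len(x)
        b = 0  # m-length template matches
        a = 0  # (m+1)-length matches
        for i in range(n - m):
            for j in range(i + 1, n - m):
                d = 0.0
                for k in range(m):
                    diff = abs(x[i + k] - x[j + k])
                    if diff > d:
                        d = diff
                if d <= r:
                    b += 1
                    if abs(x[i + m] - x[j + m]) <= r:
                        a += 1
        return a, b
except ImportError:  # pragma: no cover - numba is a hard dependency
    def _sampen_counts(x, m, r):
        n = len(x)
        a = b = 0
        for i in range(n - m):
            for j in range(i + 1, n - m):
                if np.max(np.abs(x[i:i + m] - x[j:j + m])) <= r:
                    b += 1
                    if abs(x[i + m] - x[j + m]) <= r:
                        a += 1
        return a, b


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy: -log of the conditional probability that sequences
    matching for m points (Chebyshev distance <= r) also match for m+1.

    ``r`` defaults to 0.2 x the signal SD.  Degenerate cases (no template
    matches, constant signal) return +inf.
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if r is None:
        r = 0.2 * np.std(x)
    if r <= 0:
        return np.inf
    a, b = _sampen_counts(x, m, float(r))
    if a == 0 or b == 0:
        return np.inf
    return float(-np.log(a / b))


# ---------------------------------------------------------------------------
# channel-level preprocessing

def repair_bad_channels(eeg: SensorStream, corr_threshold: float = 0.4,
                        var_mads: float = 5.0, k_neighbors: int = 4,
                        max_bad_frac: float = 0.25) -> tuple:
    """Detect and repair bad channels.

    A channel is bad when its median absolute correlation with the rest of
    the montage falls below ``corr_threshold`` or its log-variance deviates
    from the montage median by more than ``var_mads`` median absolute
    deviations.  Bad channels are replaced by the mean of their
    ``k_neighbors`` most-correlated good channels.

    Returns ``(repaired_stream, repaired_labels)``; raises
    :class:`ChannelQualityError` when more than ``max_bad_frac`` of the
    montage is bad.
    """
    if eeg.n_channels < 8:
        raise ValueError("bad-channel detection needs at least 8 channels")
    X = eeg.data
    with np.errstate(invalid="ignore"):
        C = np.corrcoef(X)
    C = np.nan_to_num(C, nan=0.0)
    np.fill_diagonal(C, np.nan)
    med_corr = np.nanmedian(np.abs(C), axis=1)

    logvar = np.log(np.maximum(X.var(axis=1), 1e-30))
    med = np.median(logvar)
    mad = stats.median_abs_deviation(logvar)
    var_dev = np.abs(logvar - med) / max(mad, 1e-12)

    bad = (med_corr < corr_threshold) | (var_dev > var_mads)
    bad_idx = np.flatnonzero(bad)
    if len(bad_idx) > max_bad_frac * eeg.n_channels:
        raise ChannelQualityError(
            f"{len(bad_idx)}/{eeg.n_channels} channels bad "
            f"(> {max_bad_frac:.0%}); recording unusable")
    out = eeg.copy()
    good = np.flatnonzero(~bad)
    for i in bad_idx:
        order = good[np.argsort(-np.abs(np.nan_to_num(C[i, good])))]
        nbrs = order[:k_neighbors]
        out.data[i] = X[nbrs].mean(axis=0)
        log.info("repaired channel %s from %s", eeg.labels[i],
                 [eeg.labels[j] for j in nbrs])
    return out, [eeg.labels[i] for i in bad_idx]


def filter_resample(eeg: SensorStream, band=(1.0, 80.0),
                    target_fs: float = 200.0) -> SensorStream:
    """Zero-phase band-pass (1-80 Hz) and anti-aliased resample to 200 Hz."""
    if eeg.fs < target_fs:
        raise ValueError(f"fs {eeg.fs} below target {target_fs}")
    nyq = eeg.fs / 2
    # separate high- and low-pass: a steep low-pass edge keeps content just
    # above the band (and at the post-resampling Nyquist) well attenuated
    sos_hp = sps.butter(4, band[0] / nyq, btype="high", output="sos")
    data = sps.sosfiltfilt(sos_hp, eeg.data, axis=1)
    if band[1] < nyq:
        sos_lp = sps.butter(10, band[1] / nyq, btype="low", output="sos")
        data = sps.sosfiltfilt(sos_lp, data, axis=1)
    if abs(eeg.fs - target_fs) > 1e-9:
        from fractions import Fraction
        frac = Fraction(target_fs / eeg.fs).limit_denominator(10000)
        data = sps.resample_poly(data, frac.numerator, frac.denominator, axis=1)
    return SensorStream(data=data, fs=target_fs, labels=list(eeg.labels),
                        kind="eeg", start_time=eeg.start_time)


def average_reference(eeg: SensorStream) -> SensorStream:
    """Subtract the per-sample channel mean (common average reference)."""
    if eeg.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    return dataclasses.replace(
        eeg, data=eeg.data - eeg.data.mean(axis=0, keepdims=True),
        labels=list(eeg.labels))


# ---------------------------------------------------------------------------
# component scoring

@dataclasses.dataclass
class ComponentScore:
    component_id: int
    max_win_kurtosis: float
    mean_win_sampen: float | None   # None when the record is shorter than 20 s
    band_power_ratio: float
    flagged_stage: str = "none"     # ocular / motion / myogenic / none
    degenerate: bool = False


@dataclasses.dataclass
class Decomposition:
    """Unmixed components plus the mixing needed to put them back."""

    components: np.ndarray   # (n_components, n_samples)
    mixing: np.ndarray       # (n_channels, n_components)
    mean: np.ndarray         # (n_channels,) removed before unmixing
    method: str

    def reconstruct(self, keep: np.ndarray | None = None) -> np.ndarray:
        comps = self.components if keep is None else self.components * \
            np.asarray(keep, float)[:, None]
        return self.mixing @ comps + self.mean[:, None]


def _win_view(x: np.ndarray, win: int) -> np.ndarray:
    n = len(x) // win
    return x[:n * win].reshape(n, win)


def score_components(components: np.ndarray, fs: float,
                     sampen_m: int = 2, sampen_r_frac: float = 0.2) -> list:
    """Score each component with the three stage statistics.

    Windows are non-overlapping: 5 s for kurtosis, 20 s for sample entropy
    (entropy tolerance r = ``sampen_r_frac`` x window SD).  Band powers are
    Welch-integrated over [30, 80] and [1, 30] Hz.  Components shorter than
    one entropy window get ``mean_win_sampen=None``; constant components are
    marked degenerate.
    """
    components = np.atleast_2d(components)
    kwin = max(2, int(KURT_WIN_S * fs))
    swin = int(SAMPEN_WIN_S * fs)
    # components at numerical-noise level (e.g. the residue of an already
    # removed component) carry no signal; their scale-free statistics would
    # be meaningless, so they are marked degenerate instead of scored
    variances = components.var(axis=1)
    var_floor = 1e-20 * max(variances.max(), 1e-300)
    scores = []
    for ci, comp in enumerate(components):
        if np.ptp(comp) == 0 or variances[ci] < var_floor:
            scores.append(ComponentScore(ci, np.nan, None, np.nan,
                                         degenerate=True))
            continue
        # nanmax: a window that happens to be constant has undefined kurtosis
        kmax = float(np.nanmax(stats.kurtosis(_win_view(comp, kwin), axis=1,
                                              fisher=True, bias=True)))
        if len(comp) >= swin:
            vals = []
            for w in _win_view(comp, swin):
                se = sample_entropy(w, m=sampen_m,
                                    r=sampen_r_frac * np.std(w))
                if np.isfinite(se):
                    vals.append(se)
            sampen = float(np.mean(vals)) if vals else np.inf
        else:
            log.info("component %d shorter than %g s; entropy omitted",
                     ci, SAMPEN_WIN_S)
            sampen = None
        nper = min(len(comp), int(4 * fs))
        f, pxx = sps.welch(comp, fs=fs, nperseg=nper)
        hi = np.trapezoid(pxx[(f >= 30) & (f <= 80)], f[(f >= 30) & (f <= 80)])
        lo = np.trapezoid(pxx[(f >= 1) & (f <= 30)], f[(f >= 1) & (f <= 30)])
        ratio = float(hi / lo) if lo > 0 else np.inf
        scores.append(ComponentScore(ci, kmax, sampen, ratio))
    return scores


def stage_criterion(score: ComponentScore, stage: str) -> bool:
    """Does this component fail the given stage (i.e. should be removed)?"""
    if score.degenerate:
        return False
    if stage == "ocular":
        return score.max_win_kurtosis > KURTOSIS_THRESHOLD
    if stage == "motion":
        return (score.mean_win_sampen is not None
                and score.mean_win_sampen < SAMPEN_THRESHOLD)
    if stage == "myogenic":
        return score.band_power_ratio > POWER_RATIO_THRESHOLD
    raise ValueError(f"unknown stage {stage!r}")


# ---------------------------------------------------------------------------
# decomposition backends

class FastICABackend:
    """scikit-learn FastICA; deflation mode for the ocular stage, parallel
    (symmetric) mode otherwise."""

    def __init__(self, n_components: int | None = None, max_iter: int = 500,
                 seed: int = 0):
        self.n_components = n_components
        self.max_iter = max_iter
        self.seed = seed

    def decompose(self, data: np.ndarray, stage: str) -> Decomposition:
        from sklearn.decomposition import FastICA

        algo = "deflation" if stage == "ocular" else "parallel"
        mean = data.mean(axis=1)
        ica = FastICA(n_components=self.n_components, algorithm=algo,
                      whiten="unit-variance", max_iter=self.max_iter,
                      random_state=self.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=UserWarning)
            comps = ica.fit_transform((data - mean[:, None]).T).T
        return Decomposition(components=comps, mixing=ica.mixing_,
                             mean=mean, method=f"fastica-{algo}")


class GroundTruthBackend:
    """Oracle backend: unmixing is the pseudo-inverse of a known mixing."""

    def __init__(self, mixing: np.ndarray):
        self.mixing = np.asarray(mixing, float)
        self._unmix = np.linalg.pinv(self.mixing)

    def decompose(self, data: np.ndarray, stage: str) -> Decomposition:
        mean = data.mean(axis=1)
        comps = self._unmix @ (data - mean[:, None])
        return Decomposition(components=comps, mixing=self.mixing,
                             mean=mean, method="ground-truth")


@dataclasses.dataclass
class CleaningReport:
    stages: dict        # stage -> list of ComponentScore
    removed: dict       # stage -> list of component ids
    skipped: list       # stages skipped through backend failure

    def n_removed(self) -> int:
        return sum(len(v) for v in self.removed.values())


def attenuate_artifacts(eeg: SensorStream, backend,
                        stages=STAGES) -> tuple[SensorStream, CleaningReport]:
    """Run the staged decompose / screen / reconstruct loop.

    At each stage the data are decomposed, components failing the stage's
    criterion are zeroed and the data reconstructed.  Backend failures skip
    the stage with a warning recorded in the report.
    """
    data = eeg.data.copy()
    report = CleaningReport(stages={}, removed={}, skipped=[])
    for stage in stages:
        try:
            dec = backend.decompose(data, stage)
        except Exception as err:
            log.warning("stage %s skipped: decomposition failed (%s)",
                        stage, err)
            report.skipped.append(stage)
            continue
        scores = score_components(dec.components, eeg.fs)
        flagged = [s.component_id for s in scores if stage_criterion(s, stage)]
        for s in scores:
            if s.component_id in flagged:
                s.flagged_stage = stage
        report.stages[stage] = scores
        report.removed[stage] = flagged
        if flagged:
            # subtract only the flagged components' scalp projection so the
            # residual (anything outside the decomposition span) is untouched
            data = data - dec.mixing[:, flagged] @ dec.components[flagged]
    cleaned = SensorStream(data=data, fs=eeg.fs, labels=list(eeg.labels),
                           kind="eeg", start_time=eeg.start_time)
    return cleaned, report
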