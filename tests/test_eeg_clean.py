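"""Bad channels, filtering, component screening, staged artifact removal."""

import numpy as np
import pytest
from scipy import signal as sps

from mobigait import eeg_clean as ec
from mobigait import synthetic as syn
from mobigait.io_sync import SensorStream


def brute_force_sampen(x, m, r):
    """O(N^2) template-matching sample entropy, straight from the definition."""
    n = len(x)
    a = b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if np.max(np.abs(x[i:i + m] - x[j:j + m])) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if a == 0 or b == 0:
        return np.inf
    return -np.log(a / b)


def _montage(n_ch=16, n_samp=6000, fs=200.0, seed=0):
    """Correlated EEG-like montage: a dominant shared rhythm plus weaker
    independent structure, as in volume-conducted scalp recordings."""
    rng = np.random.default_rng(seed)
    shared = rng.standard_normal(n_samp)
    minor = rng.standard_normal((3, n_samp))
    mix = 0.4 * rng.standard_normal((n_ch, 3))
    gain = 1.0 + 0.3 * rng.standard_normal(n_ch)
    data = gain[:, None] * shared + mix @ minor \
        + 0.2 * rng.standard_normal((n_ch, n_samp))
    return SensorStream(data, fs, [f"E{i:02d}" for i in range(n_ch)], "eeg")


class TestSampleEntropy:
    @pytest.mark.parametrize("m", [1, 2])
    @pytest.mark.parametrize("r_frac", [0.1, 0.2])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, m, r_frac, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(500)
        r = r_frac * np.std(x)
        fast = ec.sample_entropy(x, m=m, r=r)
        slow = brute_force_sampen(x, m, r)
        assert fast == pytest.approx(slow, abs=1e-10)

    def test_regular_signal_is_low_entropy(self):
        t = np.arange(2000) / 200.0
        se = ec.sample_entropy(np.sin(2 * np.pi * 2 * t))
        assert se < 0.4

    def test_constant_signal_degenerate(self):
        assert ec.sample_entropy(np.ones(500)) == np.inf


class TestRepairBadChannels:
    def test_planted_noise_channel_repaired(self):
        eeg = _montage()
        rng = np.random.default_rng(99)
        eeg.data[5] = rng.standard_normal(eeg.n_samples) * eeg.data.std()
        repaired, labels = ec.repair_bad_channels(eeg)
        assert labels == ["E05"]
        # repaired channel now correlates with the montage
        c = np.corrcoef(repaired.data)[5]
        c[5] = 0
        assert np.max(np.abs(c)) > 0.5

    def test_clean_montage_untouched(self):
        eeg = _montage(seed=1)
        repaired, labels = ec.repair_bad_channels(eeg)
        assert labels == []
        np.testing.assert_array_equal(repaired.data, eeg.data)

    def test_too_many_bad_channels_aborts(self):
        eeg = _montage()
        rng = np.random.default_rng(7)
        scale = eeg.data.std()
        for i in range(5):  # 5/16 > 25%
            eeg.data[i] = scale * rng.standard_normal(eeg.n_samples)
        with pytest.raises(ec.ChannelQualityError):
            ec.repair_bad_channels(eeg)


class TestFilterResample:
    def test_stopband_tone_attenuated(self):
        fs = 1000.0
        t = np.arange(int(30 * fs)) / fs
        eeg = SensorStream(np.sin(2 * np.pi * 100 * t)[None, :]
                           + 0.0 * t, fs, ["A"], "eeg")
        out = ec.filter_resample(eeg)
        assert out.fs == 200.0
        # steady-state response, away from the zero-phase edge transients
        mid = out.data[0][400:-400]
        atten = 10 * np.log10(np.var(mid) / 0.5)
        assert atten < -40

    def test_passband_tone_preserved(self):
        fs = 1000.0
        t = np.arange(int(30 * fs)) / fs
        eeg = SensorStream(np.sin(2 * np.pi * 10 * t)[None, :], fs, ["A"],
                           "eeg")
        out = ec.filter_resample(eeg)
        mid = out.data[0][400:-400]
        assert np.max(np.abs(mid)) == pytest.approx(1.0, rel=0.02)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            ec.filter_resample(SensorStream(np.zeros((1, 100)), 100.0, ["A"],
                                            "eeg"))


class TestAverageReference:
    def test_channel_mean_zero_and_idempotent(self):
        eeg = _montage()
        out = ec.average_reference(eeg)
        np.testing.assert_allclose(out.data.sum(axis=0), 0.0, atol=1e-10)
        again = ec.average_reference(out)
        np.testing.assert_allclose(again.data, out.data, atol=1e-12)

    def test_antisymmetric_pair_unchanged(self):
        x = np.random.default_rng(0).standard_normal(1000)
        eeg = SensorStream(np.vstack([x, -x]), 200.0, ["A", "B"], "eeg")
        out = ec.average_reference(eeg)
        np.testing.assert_allclose(out.data, eeg.data, atol=1e-12)


class TestScoreComponents:
    fs = 200.0

    def _tone(self, f=2.0, dur=60.0):
        t = np.arange(int(dur * self.fs)) / self.fs
        return np.sin(2 * np.pi * f * t)

    def test_sinusoid_scores(self):
        (score,) = ec.score_components(self._tone()[None, :], self.fs)
        assert score.max_win_kurtosis == pytest.approx(-1.5, abs=0.02)
        assert score.mean_win_sampen < 0.4
        assert ec.stage_criterion(score, "motion")
        assert not ec.stage_criterion(score, "ocular")

    def test_broadband_noise_is_myogenic_like(self):
        rng = np.random.default_rng(0)
        nyq = self.fs / 2
        sos = sps.butter(4, [1 / nyq, 80 / nyq * 0.99], "band", output="sos")
        x = sps.sosfiltfilt(sos, rng.standard_normal(int(60 * self.fs)))
        (score,) = ec.score_components(x[None, :], self.fs)
        # flat 1-80 Hz spectrum: P[30-80]/P[1-30] ~ 50/29 > 1
        assert score.band_power_ratio > 1
        assert ec.stage_criterion(score, "myogenic")
        assert not ec.stage_criterion(score, "motion")

    def test_blink_train_exceeds_kurtosis_threshold(self):
        rng = np.random.default_rng(1)
        n = int(60 * self.fs)
        x = 0.1 * rng.standard_normal(n)
        kernel = np.exp(-np.arange(100) / 24.0) - np.exp(-np.arange(100) / 6.0)
        for onset in rng.uniform(0, 58, 12):  # ~0.2 Hz sparse blinks
            i = int(onset * self.fs)
            x[i:i + 100] += 5 * kernel
        (score,) = ec.score_components(x[None, :], self.fs)
        assert score.max_win_kurtosis > 12
        assert ec.stage_criterion(score, "ocular")

    def test_short_record_omits_entropy(self):
        (score,) = ec.score_components(self._tone(dur=10.0)[None, :], self.fs)
        assert score.mean_win_sampen is None
        assert not ec.stage_criterion(score, "motion")

    def test_constant_component_degenerate(self):
        (score,) = ec.score_components(np.ones((1, 4000)), self.fs)
        assert score.degenerate
        for stage in ec.STAGES:
            assert not ec.stage_criterion(score, stage)


class TestAttenuateArtifacts:
    def _dataset(self, seed, artifacts=True, leadfield=None):
        lf = leadfield or syn.make_lead_field(16, (3, 3, 3), 8.0, seed=0)
        tl = syn.make_timeline(0.9, 40, 0.03, seed=seed)
        art = syn.ArtifactSpec() if artifacts else None
        return syn.simulate_eeg(tl, lf, syn.default_m1_sources(lf), art,
                                fs=200.0, sensor_noise_sd=0.3, seed=seed)

    def test_exactly_planted_components_removed(self):
        eeg, truth = self._dataset(seed=21)
        backend = ec.GroundTruthBackend(truth.mixing)
        _, report = ec.attenuate_artifacts(eeg, backend)
        expected = {stage: [i for i, k in enumerate(truth.component_kinds)
                            if k == stage] for stage in ec.STAGES}
        assert report.removed == expected

    def test_artifact_free_data_untouched(self):
        eeg, truth = self._dataset(seed=22, artifacts=False)
        backend = ec.GroundTruthBackend(truth.mixing)
        cleaned, report = ec.attenuate_artifacts(eeg, backend)
        assert report.n_removed() == 0
        np.testing.assert_array_equal(cleaned.data, eeg.data)

    def test_artifact_subspace_variance_reduced(self):
        eeg, truth = self._dataset(seed=23)
        backend = ec.GroundTruthBackend(truth.mixing)
        cleaned, _ = ec.attenuate_artifacts(eeg, backend)
        art = [i for i, k in enumerate(truth.component_kinds)
               if k != "source"]
        un = np.linalg.pinv(truth.mixing)
        before = (un[art] @ eeg.data).var(axis=1).sum()
        after = (un[art] @ cleaned.data).var(axis=1).sum()
        assert after < 0.1 * before

    def test_screening_specificity_on_artifact_free_data(self):
        """False-flag rate per stage stays below 5% over 50 seeds."""
        decisions = flags = 0
        for seed in range(50):
            eeg, truth = self._dataset(seed=300 + seed, artifacts=False)
            backend = ec.GroundTruthBackend(truth.mixing)
            _, report = ec.attenuate_artifacts(eeg, backend)
            for stage, scores in report.stages.items():
                decisions += len(scores)
                flags += len(report.removed[stage])
        assert flags / decisions <= 0.05

    def test_failed_backend_skips_stage(self):
        class Exploding:
            def decompose(self, data, stage):
                raise RuntimeError("no convergence")

        eeg, _ = self._dataset(seed=25, artifacts=False)
        cleaned, report = ec.attenuate_artifacts(eeg, Exploding())
        assert report.skipped == list(ec.STAGES)
        np.testing.assert_array_equal(cleaned.data, eeg.data)

    def test_fastica_backend_removes_planted_blink(self):
        """Library decomposition (no oracle): the blink component is found
        and removed by the kurtosis rule."""
        eeg, truth = self._dataset(seed=26)
        before = eeg.data.copy()
        backend = ec.FastICABackend(seed=0)
        cleaned, report = ec.attenuate_artifacts(eeg, backend,
                                                 stages=("ocular",))
        assert len(report.removed.get("ocular", [])) >= 1
        # blink scalp projection variance strongly reduced
        blink = truth.component_kinds.index("ocular")
        un = np.linalg.pinv(truth.mixing)
        v_before = (un[blink] @ before).var()
        v_after = (un[blink] @ cleaned.data).var()
        assert v_after < 0.3 * v_before
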