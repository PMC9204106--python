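"""Wavelet spectrograms, NKC/NMC profiles, group statistics, voxel images."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from mobigait import body_envelopes as be
from mobigait import connectivity as conn
from mobigait import gait_events as ge
from mobigait import synthetic as syn


def _events(n_cycles=30, T=1.0):
    tl = syn.make_timeline(1.0 / T, n_cycles, 0.0, seed=0)
    return tl, ge.GaitEventTable(cycles=tl.event_times())


def _envelope_from(curve):
    grid = np.linspace(0, 100, len(curve))
    return be.CycleEnvelope(grid=grid, per_cycle=curve[None, :],
                            mean=np.asarray(curve, float), sensor_id="s")


class TestCwtFrequencies:
    def test_octave_voice_grid(self):
        freqs = conn.cwt_frequencies()
        assert freqs.min() >= 1.0 and freqs.max() == 50.0
        # eight voices per octave: consecutive ratio 2^(1/8)
        np.testing.assert_allclose(freqs[1:] / freqs[:-1], 2 ** (1 / 8),
                                   rtol=1e-12)


class TestGaitSpectrogram:
    fs = 200.0

    def test_tone_peaks_at_nearest_bin_and_flat_after_zscore(self):
        tl, events = _events()
        t = np.arange(int((tl.t_end + 1) * self.fs)) / self.fs
        sig = np.sin(2 * np.pi * 10.0 * t)
        spec = conn.gait_spectrogram(sig, self.fs, events)
        peak_f = spec.freqs[np.argmax(spec.raw_power.mean(axis=1))]
        nearest = spec.freqs[np.argmin(np.abs(spec.freqs - 10.0))]
        assert peak_f == nearest
        # constant amplitude: standardized modulation stays small at 10 Hz
        row = spec.power[np.argmin(np.abs(spec.freqs - 10.0))]
        assert np.max(np.abs(row[5:-5])) < 1.5

    def test_amplitude_dip_localized_in_cycle(self):
        tl, events = _events(n_cycles=40)
        t = np.arange(int((tl.t_end + 1) * self.fs)) / self.fs
        phi = tl.phase(t)
        dip = 1.0 - 0.4 * ((phi >= 0.3) & (phi < 0.5))
        spec = conn.gait_spectrogram(dip * np.sin(2 * np.pi * 10.0 * t),
                                     self.fs, events)
        row = spec.power[np.argmin(np.abs(spec.freqs - 10.0))]
        argmin_pct = spec.grid[np.argmin(row)]
        assert 30 <= argmin_pct <= 50

    def test_averaging_shrinks_null_modulation(self):
        out = {}
        for n in (20, 200):
            tl, events = _events(n_cycles=n)
            rng = np.random.default_rng(8)
            t_len = int((tl.t_end + 1) * self.fs)
            spec = conn.gait_spectrogram(rng.standard_normal(t_len),
                                         self.fs, events)
            # raw modulation depth relative to the mean level, mid frequencies
            raw = spec.raw_power[20]
            out[n] = np.ptp(raw) / raw.mean()
        assert out[200] < out[20]

    def test_too_few_cycles_rejected(self):
        _, events = _events(n_cycles=30)
        short = ge.GaitEventTable(cycles=events.cycles[:2])
        with pytest.raises(ValueError, match="3 gait cycles"):
            conn.gait_spectrogram(np.zeros(4000), self.fs, short)


class TestConnectivityProfile:
    def _spec(self, power, grid_n=200):
        freqs = conn.cwt_frequencies()
        return conn.GaitSpectrogram(freqs=freqs,
                                    grid=np.linspace(0, 100, grid_n),
                                    power=power)

    def test_identical_and_negated_curves(self):
        rng = np.random.default_rng(0)
        curve = rng.standard_normal(200)
        freqs = conn.cwt_frequencies()
        spec = self._spec(np.tile(curve, (len(freqs), 1)))
        body = _envelope_from(curve)
        np.testing.assert_allclose(conn.connectivity_profile(spec, body), 1.0,
                                   atol=1e-12)
        spec_neg = self._spec(np.tile(-curve, (len(freqs), 1)))
        np.testing.assert_allclose(conn.connectivity_profile(spec_neg, body),
                                   -1.0, atol=1e-12)

    def test_independent_curves_stay_small(self):
        rng = np.random.default_rng(1)
        freqs = conn.cwt_frequencies()
        small = 0
        n_trials = 50
        for _ in range(n_trials):
            spec = self._spec(rng.standard_normal((len(freqs), 200)))
            body = _envelope_from(rng.standard_normal(200))
            r = conn.connectivity_profile(spec, body)
            small += np.mean(np.abs(r) < 0.2)
        assert small / n_trials > 0.99

    def test_grid_mismatch_rejected(self):
        spec = self._spec(np.zeros((len(conn.cwt_frequencies()), 200)))
        body = _envelope_from(np.random.default_rng(0).standard_normal(100))
        with pytest.raises(ValueError, match="grids differ"):
            conn.connectivity_profile(spec, body)


class TestBandAggregate:
    def test_flat_profile(self):
        freqs = conn.cwt_frequencies()
        out = conn.band_aggregate(freqs, np.full(len(freqs), 0.4))
        assert all(v == pytest.approx(0.4) for v in out.values())

    def test_alpha_only_bump(self):
        freqs = conn.cwt_frequencies()
        profile = np.where(np.abs(freqs - 10) < 1.5, 0.5, 0.0)
        out = conn.band_aggregate(freqs, profile)
        assert out["alpha"] > 0.1
        assert out["beta"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_band_coverage_rejected(self):
        freqs = conn.cwt_frequencies(f_max=12.0)
        with pytest.raises(ValueError, match="covered by 0 frequencies"):
            conn.band_aggregate(freqs, np.zeros(len(freqs)))


def _long_df(r_values, n_part):
    rows = []
    for p in range(n_part):
        for cell, r in r_values.items():
            rows.append({"participant": p, "sensor": cell, "signal_type":
                         "emg", "roi": "M1_left", "band": "alpha",
                         "r": r[p] if np.ndim(r) else r})
    return pd.DataFrame(rows)


class TestGroupStats:
    def test_all_zero_cell(self):
        df = _long_df({"a": 0.0, "b": 0.0}, n_part=6)
        out = conn.group_stats(df)
        assert np.all(out["t"] == 0.0)
        assert np.all(out["p"] == 1.0)

    def test_planted_effect_survives_fdr(self):
        rng = np.random.default_rng(9)
        z = rng.normal(0.6, 0.2, 24)
        df = _long_df({"a": np.tanh(z), "b": rng.normal(0, 0.05, 24)},
                      n_part=24)
        out = conn.group_stats(df).set_index("sensor")
        assert out.loc["a", "q"] < 0.001

    def test_needs_three_participants(self):
        df = _long_df({"a": 0.1}, n_part=2)
        with pytest.raises(ValueError, match="3 participants"):
            conn.group_stats(df)


class TestAnovaNway:
    def test_single_factor_F_equals_t_squared(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({
            "g": ["a"] * 12 + ["b"] * 12,
            "y": np.concatenate([rng.normal(0, 1, 12),
                                 rng.normal(0.8, 1, 12)]),
        })
        table = conn.anova_nway(df, "y", ["g"])
        t = sstats.ttest_ind(df.y[df.g == "a"], df.y[df.g == "b"])
        assert table.loc["g", "F"] == pytest.approx(t.statistic ** 2,
                                                    abs=1e-9)
        assert table.loc["g", "p"] == pytest.approx(t.pvalue, abs=1e-9)

    def test_identical_cells_no_effect(self):
        df = pd.DataFrame({"g": ["a", "a", "b", "b"] * 3,
                           "h": ["x", "y"] * 6,
                           "y": 1.5})
        table = conn.anova_nway(df, "y", ["g", "h"])
        assert np.all(table.loc[["g", "h"], "F"] == 0.0)
        assert np.all(table.loc[["g", "h"], "p"] == 1.0)

    def test_planted_sensor_effect_found_band_null(self):
        rng = np.random.default_rng(11)
        sensors = [f"s{i}" for i in range(4)]
        bands = ["alpha", "beta", "gamma"]
        shift = dict(zip(sensors, [0.0, 0.4, 0.8, 1.2]))
        rows = []
        for p in range(24):
            for s in sensors:
                for b in bands:
                    rows.append({"sensor": s, "band": b,
                                 "y": shift[s] + rng.normal(0, 0.3)})
        table = conn.anova_nway(pd.DataFrame(rows), "y", ["sensor", "band"])
        assert table.loc["sensor", "p"] < 0.001
        assert table.loc["band", "p"] > 0.05

    def test_unbalanced_layout_rejected(self):
        df = pd.DataFrame({"g": ["a", "a", "b"], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="unbalanced"):
            conn.anova_nway(df, "y", ["g"])


class TestConnectivityImages:
    def _null_r(self, seed, n_part=24, n_vox=50):
        rng = np.random.default_rng(seed)
        return np.tanh(rng.normal(0, 0.1, (n_part, 3, 4, n_vox)))

    def test_planted_single_voxel_sensor_effect(self):
        r = self._null_r(12)
        # sensor-dependent coupling at voxel 17 only
        shifts = np.array([-0.6, -0.2, 0.2, 0.6])
        r[:, :, :, 17] = np.tanh(
            shifts[None, None, :]
            + np.random.default_rng(13).normal(0, 0.1, (24, 3, 4)))
        imgs = conn.connectivity_images(r, ["alpha", "beta", "gamma"],
                                        ["s0", "s1", "s2", "s3"])
        assert list(np.flatnonzero(imgs.masks["sensor"])) == [17]

    def test_null_images_control_false_discoveries(self):
        total_sig = 0
        for seed in range(5):
            imgs = conn.connectivity_images(self._null_r(100 + seed),
                                            ["a", "b", "g"],
                                            ["s0", "s1", "s2", "s3"])
            total_sig += sum(m.sum() for m in imgs.masks.values())
        assert total_sig <= 1  # q < 0.001 over 50-voxel null images

    def test_identical_participants_average_to_any_one(self):
        one = self._null_r(14, n_part=1)
        r = np.repeat(one, 6, axis=0)
        imgs = conn.connectivity_images(r, ["a", "b", "g"],
                                        ["s0", "s1", "s2", "s3"])
        np.testing.assert_allclose(imgs.group_images, one[0], atol=1e-10)

    def test_voxelwise_anova_matches_anova_nway_exactly(self):
        r = self._null_r(15, n_vox=5)
        imgs = conn.connectivity_images(r, ["a", "b", "g"],
                                        ["s0", "s1", "s2", "s3"])
        vox = 3
        z = be.fisher_z(r[:, :, :, vox])
        rows = []
        for p in range(z.shape[0]):
            for bi, band in enumerate(["a", "b", "g"]):
                for si, s in enumerate(["s0", "s1", "s2", "s3"]):
                    rows.append({"band": band, "sensor": s, "z": z[p, bi, si]})
        table = conn.anova_nway(pd.DataFrame(rows), "z", ["band", "sensor"],
                                interaction=True)
        assert table.loc["band", "F"] == pytest.approx(
            imgs.F["band"][vox], rel=1e-9)
        assert table.loc["sensor", "F"] == pytest.approx(
            imgs.F["sensor"][vox], rel=1e-9)
        assert table.loc["band:sensor", "F"] == pytest.approx(
            imgs.F["band:sensor"][vox], rel=1e-9)

    def test_missing_cell_named(self):
        r = self._null_r(16)
        r[2, 1, 2, 7] = np.nan
        with pytest.raises(ValueError, match="voxel 7"):
            conn.connectivity_images(r, ["a", "b", "g"],
                                     ["s0", "s1", "s2", "s3"])

    def test_display_threshold_only_affects_rendering(self):
        r = self._null_r(17)
        imgs = conn.connectivity_images(r, ["a", "b", "g"],
                                        ["s0", "s1", "s2", "s3"])
        rendered = imgs.thresholded("a", "s0")
        raw = imgs.group_images[0, 0]
        assert np.all((rendered == 0) | (np.abs(rendered) > 0.2))
        assert np.any(np.abs(raw) <= 0.2)  # raw values kept un-blanked

    def test_nifti_written_on_grid(self, tmp_path, leadfield):
        import nibabel as nib
        values = np.arange(leadfield.n_sources, dtype=float)
        path = tmp_path / "img.nii.gz"
        conn.write_nifti(path, values, (5, 5, 4), 6.0)
        img = nib.load(str(path))
        assert img.shape == (5, 5, 4)
        np.testing.assert_allclose(np.asarray(img.dataobj).ravel(), values)
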