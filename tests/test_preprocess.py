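"""I/O round trips, calibration, region exclusion, PQN and log transform."""

import numpy as np
import pandas as pd
import pytest

from nmrage.containers import Spectrum, read_spectra, write_spectra
from nmrage.preprocess import (
    EXCLUSION_PRESETS, calibrate_ppm, calibrate_matrix, exclude_regions,
    log_transform, pqn_normalize,
)
from nmrage.synthetic import GroupSpec, simulate_cohort, render_multiplet
from nmrage.templates import tsp_template

from conftest import make_matrix, make_meta, small_design


class TestIO:
    def test_write_read_round_trip_is_identity(self, tmp_path, rng):
        m = make_matrix(rng.normal(size=(4, 200)))
        write_spectra(m, tmp_path / "x.csv", tmp_path / "x.tsv")
        back = read_spectra(tmp_path / "x.csv", tmp_path / "x.tsv")
        np.testing.assert_array_equal(back.intensities, m.intensities)
        np.testing.assert_array_equal(back.ppm, m.ppm)
        assert back.sample_ids == m.sample_ids

    def test_metadata_missing_sample_names_offender(self, tmp_path, rng):
        m = make_matrix(rng.normal(size=(3, 50)))
        write_spectra(m, tmp_path / "x.csv", tmp_path / "x.tsv")
        meta = pd.read_csv(tmp_path / "x.tsv", sep="\t")
        meta[meta.sample_id != "s01"].to_csv(tmp_path / "x.tsv", sep="\t", index=False)
        with pytest.raises(ValueError, match="s01"):
            read_spectra(tmp_path / "x.csv", tmp_path / "x.tsv")

    def test_mixed_axes_between_files_refused_with_summaries(self, tmp_path, rng):
        a = make_matrix(rng.normal(size=(2, 50)), sample_ids=["a0", "a1"])
        b = make_matrix(rng.normal(size=(2, 60)), sample_ids=["b0", "b1"])
        write_spectra(a, tmp_path / "a.csv", tmp_path / "a.tsv")
        write_spectra(b, tmp_path / "b.csv", tmp_path / "b.tsv")
        meta = pd.concat([a.meta, b.meta])
        meta.to_csv(tmp_path / "all.tsv", sep="\t", index=False)
        with pytest.raises(ValueError, match="ppm axes differ.*50 points.*60 points"):
            read_spectra([tmp_path / "a.csv", tmp_path / "b.csv"], tmp_path / "all.tsv")

    def test_duplicate_sample_ids_rejected(self, rng):
        with pytest.raises(ValueError, match="duplicated"):
            make_matrix(rng.normal(size=(2, 20)), sample_ids=["s", "s"])


class TestCalibration:
    def lorentzian_spectrum(self, center, lo=-0.2, hi=1.0, step=0.00025):
        n = int(round((hi - lo) / step)) + 1
        ppm = (lo + step * np.arange(n))[::-1]
        y = render_multiplet(center, "s", 0.0, 1.0, 10.0, ppm, 600.44)
        return Spectrum(ppm, y)

    def test_on_target_spectrum_gets_zero_shift(self):
        s = self.lorentzian_spectrum(0.0)
        out = calibrate_ppm(s, (-0.1, 0.1), 0.0)
        assert out.meta["calibration_shift_ppm"] == pytest.approx(0.0, abs=0.00025)

    def test_displaced_tsp_shifted_back_within_one_grid_step(self):
        """A TSP singlet planted at 0.004 ppm calibrated to target 0 gets
        an applied shift of -0.004 ppm."""
        s = self.lorentzian_spectrum(0.004)
        out = calibrate_ppm(s, (-0.1, 0.1), 0.0)
        assert out.meta["calibration_shift_ppm"] == pytest.approx(-0.004, abs=0.00025)
        assert abs(out.ppm[np.argmax(out.intensity)]) <= 0.00025

    def test_no_peak_above_noise_raises(self, rng):
        n = 2001
        ppm = np.linspace(1.0, -0.2, n)
        y = rng.normal(0, 1.0, n)
        y[ppm > 0.5] += 500 * np.exp(-((ppm[ppm > 0.5] - 0.8) ** 2) / 1e-4)
        with pytest.raises(ValueError, match="noise floor"):
            calibrate_ppm(Spectrum(ppm, y), (-0.1, 0.1), 0.0)

    def test_matrix_calibration_on_simulated_tsp(self):
        d = small_design(grid=(-0.2, 4.0, 0.001), add_noise_sd=0.0,
                         groups=[GroupSpec("WT", "15", 3)])
        tsp = tsp_template(0.004)
        d.templates = d.templates + [tsp]
        d.base_concentrations[tsp.name] = 50.0
        m, _ = simulate_cohort(d)
        cal = calibrate_matrix(m, (-0.1, 0.1), 0.0)
        shifts = cal.log[-1]["shifts_ppm"]
        for v in shifts.values():
            assert v == pytest.approx(-0.004, abs=0.001)


class TestExclusion:
    def test_urine_preset_retains_expected_bands(self):
        step = 0.00025
        n = int(round((10.0 - 0.5) / step)) + 1
        ppm = (0.5 + step * np.arange(n))[::-1]
        m = make_matrix(np.ones((2, n)), ppm=ppm)
        out = exclude_regions(m, "urine")
        assert out.ppm.max() == pytest.approx(10.0)
        assert out.ppm.min() == pytest.approx(0.8, abs=1e-9)
        inside_water = (out.ppm > 4.7) & (out.ppm < 4.9)
        assert not inside_water.any()
        # band endpoints themselves are retained
        for kept in (0.8, 4.7, 4.9, 10.0):
            assert np.isclose(out.ppm, kept).any()

    def test_retained_count_matches_interval_arithmetic(self):
        step = 0.00025
        n = int(round((10.0 - 0.5) / step)) + 1
        ppm = (0.5 + step * np.arange(n))[::-1]
        m = make_matrix(np.zeros((2, n)), ppm=ppm)
        out = exclude_regions(m, "urine")
        # independent counting oracle: points in [0.8,4.7] U [4.9,10.0]
        count = sum(1 for x in ppm if 0.8 <= x <= 4.7 or 4.9 <= x <= 10.0)
        assert out.n_variables == count

    def test_empty_interval_list_is_identity(self, rng):
        m = make_matrix(rng.normal(size=(2, 100)))
        out = exclude_regions(m, [])
        np.testing.assert_array_equal(out.intensities, m.intensities)

    def test_idempotent(self, rng):
        m = make_matrix(rng.normal(size=(3, 5000)), ppm=np.linspace(10.5, 0.2, 5000))
        once = exclude_regions(m, "urine")
        twice = exclude_regions(once, "urine")
        np.testing.assert_array_equal(once.intensities, twice.intensities)

    def test_inverted_interval_raises(self, rng):
        m = make_matrix(rng.normal(size=(2, 100)))
        with pytest.raises(ValueError, match="inverted"):
            exclude_regions(m, [(5.0, 3.0)])

    @pytest.mark.parametrize("preset", sorted(EXCLUSION_PRESETS))
    def test_presets_drop_their_water_band(self, preset):
        m = make_matrix(np.ones((2, 2001)), ppm=np.linspace(11.0, 0.0, 2001))
        out = exclude_regions(m, preset)
        water = EXCLUSION_PRESETS[preset][1]
        inside = (out.ppm > water[0]) & (out.ppm < water[1])
        assert not inside.any()


class TestPQN:
    def test_scaled_sample_gets_its_scale_as_factor(self, rng):
        base = np.abs(rng.normal(10, 2, 300)) + 1.0
        X = np.vstack([base, base, 3.0 * base])
        res = pqn_normalize(make_matrix(X))
        assert res.dilution_factors.iloc[2] == pytest.approx(3.0)
        np.testing.assert_allclose(res.matrix.intensities[2], base, rtol=1e-12)

    def test_identical_samples_all_factors_one(self, rng):
        base = np.abs(rng.normal(10, 2, 100)) + 1.0
        res = pqn_normalize(make_matrix(np.vstack([base] * 4)))
        np.testing.assert_allclose(res.dilution_factors.to_numpy(), 1.0)

    def test_simulated_dilutions_recovered(self):
        """Log-uniform dilutions in [0.5, 2] are recovered with r > 0.99."""
        d = small_design(groups=[GroupSpec("WT", "15", 20),
                                 GroupSpec("WT", "60", 20)], seed=21)
        m, truth = simulate_cohort(d)
        res = pqn_normalize(m)
        est = res.dilution_factors
        true = truth.dilutions.set_index("sample_id")["dilution"].loc[est.index]
        r = np.corrcoef(est, true)[0, 1]
        assert r > 0.99

    def test_self_consistency_with_same_reference(self, rng):
        X = np.abs(rng.normal(10, 3, size=(6, 400))) + 0.5
        X *= rng.uniform(0.5, 2.0, 6)[:, None]
        res1 = pqn_normalize(make_matrix(X))
        res2 = pqn_normalize(res1.matrix, reference=res1.reference_spectrum)
        assert np.max(np.abs(res2.dilution_factors.to_numpy() - 1.0)) < 1e-9

    def test_all_zero_sample_raises(self, rng):
        X = np.abs(rng.normal(size=(3, 50))) + 0.1
        X[1] = 0.0
        with pytest.raises(ValueError, match="all-zero"):
            pqn_normalize(make_matrix(X))


class TestLogTransform:
    def test_uniform_scaling_becomes_additive_shift(self, rng):
        X = np.abs(rng.normal(100, 10, size=(2, 200))) + 50
        m = make_matrix(np.vstack([X[0], 7.0 * X[0]]))
        out = log_transform(m, offset=0.0, require_normalized=False)
        diff = out.intensities[1] - out.intensities[0]
        np.testing.assert_allclose(diff, np.log(7.0), rtol=1e-9)

    def test_variance_stabilization_of_multiplicative_noise(self, rng):
        """With cv=0.2 multiplicative noise, replicate sds after the log
        are nearly height-independent (ratio < 1.5 across a 10x range)
        whereas raw-scale sds scale with the mean (~10x)."""
        heights = np.array([10.0, 100.0])
        reps = 400
        noise = rng.lognormal(mean=0.0, sigma=np.sqrt(np.log(1 + 0.04)),
                              size=(reps, 2))
        X = heights[None, :] * noise
        raw_ratio = X[:, 1].std() / X[:, 0].std()
        logX = np.log(X)
        log_ratio = logX[:, 1].std() / logX[:, 0].std()
        assert raw_ratio > 5.0
        assert max(log_ratio, 1 / log_ratio) < 1.5

    def test_zero_intensity_with_zero_offset_raises(self):
        m = make_matrix(np.array([[1.0, 0.0, 2.0], [1.0, 1.0, 1.0]]))
        with pytest.raises(ValueError, match="<= 0"):
            log_transform(m, offset=0.0, require_normalized=False)

    def test_requires_normalization_via_processing_log(self, rng):
        m = make_matrix(np.abs(rng.normal(size=(3, 40))) + 1.0)
        with pytest.raises(ValueError, match="normalized"):
            log_transform(m, offset=1.0)
        res = pqn_normalize(m)
        out = log_transform(res.matrix, offset=1.0)
        steps = [e["step"] for e in out.log]
        assert steps[-2:] == ["pqn", "log"]
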