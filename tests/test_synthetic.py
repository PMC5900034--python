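"""Generator correctness: multiplet rendering, exchange broadening,
cohort simulation and its ground truth."""

import numpy as np
import pandas as pd
import pytest

from nmrage.synthetic import (
    CohortDesign, GroupSpec, PlantedEffect, TruncationWarning,
    broadened_width, render_multiplet, simulate_cohort,
)
from nmrage.templates import default_urine_templates, templates_by_name

from conftest import small_design

FREQ = 600.44


def grid(lo=0.0, hi=5.0, step=0.00025):
    n = int(round((hi - lo) / step)) + 1
    return (lo + step * np.arange(n))[::-1]


class TestRenderMultiplet:
    def test_singlet_is_single_lorentzian_with_preserved_integral(self):
        g = grid(1.0, 3.0)
        y = render_multiplet(2.0, "s", J=7.0, fwhm=1.2, integral=5.0, grid=g, freq=FREQ)
        # one maximum, at the center
        assert g[np.argmax(y)] == pytest.approx(2.0, abs=0.0005)
        assert y.sum() * 0.00025 == pytest.approx(5.0, rel=0.01)

    def test_triplet_spacing_and_ratios_match_closed_form(self):
        J = 7.5
        g = grid(0.5, 1.6)
        y = render_multiplet(1.0, "t", J=J, fwhm=0.8, integral=1.0, grid=g, freq=FREQ)
        spacing = J / FREQ  # independent arithmetic: 7.5/600.44 ppm
        asc = g[::-1]
        ya = y[::-1]
        centers = 1.0 + np.array([-1.0, 0.0, 1.0]) * spacing
        idx = [np.argmin(np.abs(asc - c)) for c in centers]
        heights = ya[idx]
        assert heights[1] / heights[0] == pytest.approx(2.0, rel=0.02)
        assert heights[1] / heights[2] == pytest.approx(2.0, rel=0.02)
        # outer lines sit exactly J/freq from the center line
        peaks = []
        for lo, hi in [(0, idx[0] + 20), (idx[0] + 20, idx[2] - 20), (idx[2] - 20, ya.size)]:
            peaks.append(asc[lo:hi][np.argmax(ya[lo:hi])])
        assert peaks[1] - peaks[0] == pytest.approx(spacing, abs=0.0005)
        assert peaks[2] - peaks[1] == pytest.approx(spacing, abs=0.0005)

    def test_pheromone_template_markers(self):
        """The 6H6MH3O template carries its singlet at 1.209 ppm and its
        methyl triplet at 1.017 ppm."""
        tpl = templates_by_name(default_urine_templates())["6H6MH3O"]
        kinds = {(m.center, m.multiplicity) for m in tpl.multiplets}
        assert (1.209, "s") in kinds
        assert (1.017, "t") in kinds
        g = grid(0.8, 1.5)
        singlet = [m for m in tpl.multiplets if m.multiplicity == "s"][0]
        y = render_multiplet(singlet.center, "s", 0.0, singlet.fwhm, 1.0, g, FREQ)
        assert g[np.argmax(y)] == pytest.approx(1.209, abs=0.0005)

    def test_unknown_multiplicity_raises(self):
        with pytest.raises(ValueError, match="multiplicity"):
            render_multiplet(2.0, "x", 7.0, 1.0, 1.0, grid(), FREQ)

    def test_m_requires_line_list(self):
        with pytest.raises(ValueError, match="line list"):
            render_multiplet(2.0, "m", 0.0, 1.0, 1.0, grid(), FREQ)

    def test_truncation_warns(self):
        with pytest.warns(TruncationWarning):
            render_multiplet(4.999, "s", 0.0, 1.0, 1.0, grid(0.0, 5.0), FREQ)

    @pytest.mark.parametrize("mult,n_lines", [("d", 2), ("q", 4)])
    def test_doublet_quartet_line_counts(self, mult, n_lines):
        g = grid(1.5, 2.5, step=0.0005)
        y = render_multiplet(2.0, mult, J=20.0, fwhm=0.6, integral=1.0, grid=g, freq=FREQ)
        ya = y[::-1]
        apex = (ya[1:-1] > ya[:-2]) & (ya[1:-1] > ya[2:])
        assert apex.sum() == n_lines


class TestBroadenedWidth:
    def test_unbound_and_fully_bound_limits(self):
        assert broadened_width(1.36, 2.52, 0.0) == 1.36
        assert broadened_width(1.36, 2.52, 1.0) == 2.52

    def test_linear_model_inversion_recovers_bound_width(self):
        """If half the population is bound and the observed width is
        1.94 Hz while the free width is 1.36 Hz, inverting the linear
        fast-exchange model gives a bound width of 2.52 Hz."""
        free, observed, f = 1.36, 1.94, 0.5
        bound = (observed - (1 - f) * free) / f  # independent inversion
        assert bound == pytest.approx(2.52)
        assert broadened_width(free, bound, f) == pytest.approx(observed)

    def test_fraction_outside_unit_interval_raises(self):
        with pytest.raises(ValueError):
            broadened_width(1.0, 2.0, 1.5)


class TestSimulateCohort:
    def test_noise_free_groups_are_identical(self):
        d = small_design(mult_noise_cv=0.0, add_noise_sd=0.0,
                         dilution_log_range=(1.0, 1.0))
        for t in d.templates:
            assert t.shift_jitter_sd == 0 or True
        d.templates = [
            type(t)(t.name, t.multiplets, 0.0, t.bound_fraction, t.bound_fwhm)
            for t in d.templates
        ]
        m, _ = simulate_cohort(d)
        X = m.intensities
        grp = m.meta["week"].to_numpy()
        for w in np.unique(grp):
            block = X[grp == w]
            assert np.allclose(block, block[0])

    def test_same_seed_reproduces_bit_identical_matrix(self):
        d = small_design(seed=7)
        m1, t1 = simulate_cohort(d)
        m2, t2 = simulate_cohort(small_design(seed=7))
        np.testing.assert_array_equal(m1.intensities, m2.intensities)
        pd.testing.assert_frame_equal(t1.dilutions, t2.dilutions)

    def test_different_seed_differs(self):
        m1, _ = simulate_cohort(small_design(seed=1))
        m2, _ = simulate_cohort(small_design(seed=2))
        assert not np.array_equal(m1.intensities, m2.intensities)

    def test_appending_group_preserves_earlier_samples(self):
        """Per-sample RNG substreams are keyed by global sample index, so
        extending the design leaves earlier spectra bit-identical."""
        d1 = small_design(seed=3)
        d2 = small_design(seed=3)
        d2.groups = d1.groups + [GroupSpec("KO", "15", 2)]
        m1, _ = simulate_cohort(d1)
        m2, _ = simulate_cohort(d2)
        np.testing.assert_array_equal(
            m1.intensities, m2.intensities[: m1.n_samples]
        )

    def test_planted_fold_change_recovered_from_group_means(self):
        """A planted 2x citrate increase shows up as a ratio of group-mean
        citrate integrals of ~2 (within 3 CV/sqrt(n) of the target)."""
        cv, n = 0.1, 8
        d = small_design(
            groups=[GroupSpec("WT", "15", n), GroupSpec("WT", "60", n)],
            planted_effects=[
                PlantedEffect("citrate", {"week": "60"}, 1.0)
            ],
            mult_noise_cv=cv, add_noise_sd=0.0, dilution_log_range=(1.0, 1.0),
            seed=11,
        )
        m, truth = simulate_cohort(d)
        conc = truth.concentrations
        cit = conc[conc.template == "citrate"].set_index("sample_id")["concentration"]
        weeks = m.meta.set_index("sample_id")["week"]
        ratio = cit[weeks == "60"].mean() / cit[weeks == "15"].mean()
        assert abs(ratio - 2.0) < 2.0 * 3 * cv / np.sqrt(n)
        # and the rendered spectra agree: integrate the 2.56 citrate
        # doublet (band excludes the unchanged dimethylamine singlet)
        band = (m.ppm > 2.49) & (m.ppm < 2.64)
        areas = m.intensities[:, band].sum(axis=1)
        area_ratio = areas[(weeks == "60").to_numpy()].mean() / \
            areas[(weeks == "15").to_numpy()].mean()
        assert abs(area_ratio - 2.0) < 3 * 2.0 * cv / np.sqrt(n)

    def test_integral_linearity_when_noise_off(self):
        d = small_design(mult_noise_cv=0.0, add_noise_sd=0.0,
                         dilution_log_range=(1.0, 1.0),
                         groups=[GroupSpec("WT", "15", 1)])
        m1, _ = simulate_cohort(d)
        d2 = small_design(mult_noise_cv=0.0, add_noise_sd=0.0,
                          dilution_log_range=(1.0, 1.0),
                          groups=[GroupSpec("WT", "15", 1)])
        d2.base_concentrations = {k: 2 * v for k, v in d.base_concentrations.items()}
        m2, _ = simulate_cohort(d2)
        np.testing.assert_allclose(m2.intensities, 2 * m1.intensities, rtol=1e-12)

    def test_jitter_sd_matches_design(self):
        """Empirical sd of planted shifts tracks shift_jitter_sd within
        20% once a few hundred draws are pooled."""
        d = small_design(groups=[GroupSpec("WT", "15", 100)], seed=5,
                         add_noise_sd=0.0)
        _, truth = simulate_cohort(d)
        sh = truth.shifts
        cit = sh[sh.template == "citrate"]["shift_ppm"]
        tau = sh[sh.template == "taurine"]["shift_ppm"]
        pooled = np.concatenate([
            cit / 0.01, tau / 0.008,
        ])
        assert pooled.size >= 200
        assert abs(pooled.std(ddof=1) - 1.0) < 0.2

    def test_ultrafiltered_variant_sharpens_bound_signals(self):
        d = small_design(mult_noise_cv=0.0, add_noise_sd=0.0,
                         dilution_log_range=(1.0, 1.0),
                         groups=[GroupSpec("WT", "15", 1)])
        raw, _ = simulate_cohort(d)
        filt, _ = simulate_cohort(d, ultrafiltered=True)
        band = (raw.ppm > 1.19) & (raw.ppm < 1.23)  # bound pheromone singlet
        assert filt.intensities[0, band].max() > raw.intensities[0, band].max()
        # unbound trimethylamine is unchanged up to far Lorentzian tails
        # of the (sharpened) bound signals elsewhere in the spectrum
        free_band = (raw.ppm > 2.86) & (raw.ppm < 2.91)
        np.testing.assert_allclose(
            filt.intensities[0, free_band], raw.intensities[0, free_band], rtol=1e-3
        )

    def test_empty_template_list_raises(self):
        d = small_design()
        d.templates = []
        with pytest.raises(ValueError, match="template"):
            simulate_cohort(d)
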