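"""Spectrum synthesis: lineshapes, areas, matrix chemistry, cohort design."""

import math

import numpy as np
import pytest

import salixnmr as sx
from salixnmr.library import Multiplet
from salixnmr.simulate import (
    AREA_K,
    DEFAULT_EXCHANGE_RATE,
    DEFAULT_TSP_TUBE_MM,
    MatrixState,
    RenderSpec,
    SimulatorConfig,
    apply_matrix_effects,
    default_axis,
    render_multiplet,
    simulate_cohort,
    simulate_spectrum,
    _ingredients,
)


class TestRenderMultiplet:
    def test_zero_concentration(self):
        m = Multiplet(center_ppm=2.0, pattern="s", n_protons=1)
        out = render_multiplet(m, 0.0, default_axis())
        assert not out.any()

    def test_doublet_splitting_in_ppm(self):
        """J = 3.8 Hz at 600 MHz: two equal-area lines 0.00633 ppm apart."""
        m = Multiplet(center_ppm=5.0, pattern="d", j_hz=[3.8], n_protons=1,
                      fwhm_hz=0.6)
        axis = np.linspace(4.9, 5.1, 40001)  # 5e-6 ppm steps
        out = render_multiplet(m, 1.0, axis, 600.0)
        # the two apices
        apex1 = axis[np.argmax(out[: len(axis) // 2])]
        apex2 = axis[len(axis) // 2 + np.argmax(out[len(axis) // 2:])]
        assert apex2 - apex1 == pytest.approx(3.8 / 600.0, abs=2e-5)
        # symmetric about the centre
        assert (apex1 + apex2) / 2 == pytest.approx(5.0, abs=2e-5)

    def test_area_equals_conc_protons_K(self):
        """Numeric trapezoid over >= 50 FWHM recovers c * nH * K within 1%."""
        m = Multiplet(center_ppm=5.0, pattern="d", j_hz=[3.8], n_protons=3,
                      fwhm_hz=1.0)
        axis = np.linspace(4.0, 6.0, 200001)  # window ~600 FWHM wide
        out = render_multiplet(m, 2.5, axis, 600.0)
        area = np.trapezoid(out, axis)
        assert area == pytest.approx(2.5 * 3 * AREA_K, rel=0.01)

    def test_nonuniform_axis_rejected(self):
        m = Multiplet(center_ppm=1.0, pattern="s", n_protons=1)
        with pytest.raises(ValueError, match="uniform"):
            render_multiplet(m, 1.0, np.array([0.0, 0.1, 0.3]))


class TestSimulateSpectrum:
    def test_empty_composition_tsp_and_solvent_only(self, library, quiet_matrix):
        cfg = SimulatorConfig(noise_sd=0.0)
        spec = simulate_spectrum({}, library, cfg, quiet_matrix)
        # TSP peak present at 0
        tsp_h = spec.intensity[np.abs(spec.ppm) < 0.01].max()
        assert tsp_h > 100
        # nothing in a metabolite-free region away from solvent humps
        assert spec.intensity[(spec.ppm > 8.5) & (spec.ppm < 9.0)].max() < 0.5

    def test_unknown_metabolite_raises(self, library):
        with pytest.raises(KeyError):
            simulate_spectrum({"unobtainium": 1.0}, library)

    def test_sucrose_anomeric_visible(self, library):
        cfg = SimulatorConfig(noise_sd=0.5)
        spec = simulate_spectrum({"sucrose": 1.8}, library, cfg, rng=0)
        window = spec.intensity[(spec.ppm >= 5.400) & (spec.ppm <= 5.425)]
        assert window.max() > 5 * cfg.noise_sd

    def test_glucose_tsp_area_ratio(self, library, clean_config, quiet_matrix):
        """area(anomeric 1H) / area(TSP 9H) = c_glc / (9 c_TSP) within 1%."""
        from salixnmr.preprocess import integrate_region

        c_glc = 1.2
        spec = simulate_spectrum({"glucose": c_glc}, library, clean_config,
                                 quiet_matrix)
        a_glc = integrate_region(spec, 5.18, 5.26)
        a_tsp = integrate_region(spec, -0.04, 0.04)
        expected = c_glc / (9 * clean_config.tsp_conc_mM)
        assert a_glc / a_tsp == pytest.approx(expected, rel=0.01)

    def test_linearity_at_zero_noise(self, library, clean_config, quiet_matrix):
        base = simulate_spectrum({}, library, clean_config, quiet_matrix)
        s1 = simulate_spectrum({"malate": 0.7}, library, clean_config, quiet_matrix)
        s2 = simulate_spectrum({"malate": 1.4}, library, clean_config, quiet_matrix)
        np.testing.assert_allclose(
            s2.intensity - base.intensity,
            2 * (s1.intensity - base.intensity),
            rtol=1e-10, atol=1e-12,
        )

    def test_total_integral_conservation(self, library, clean_config, quiet_matrix):
        """Total spectral integral matches K * sum(c * nH) within 1%."""
        comp = {"sucrose": 1.8, "alanine": 0.3, "succinate": 0.2}
        spec = simulate_spectrum(comp, library, clean_config, quiet_matrix)
        expected = sum(
            c * library[m].n_protons_total * AREA_K for m, c in comp.items()
        ) + clean_config.tsp_conc_mM * 9 * AREA_K
        total = np.trapezoid(spec.intensity, spec.ppm)
        assert total == pytest.approx(expected, rel=0.01)

    def test_axis_invariants(self, library):
        spec = simulate_spectrum({}, library)
        assert len(spec.ppm) == 65536
        assert spec.ppm[0] <= -0.5 and spec.ppm[-1] >= 10.0
        assert np.all(np.diff(spec.ppm) > 0)


class TestMatrixEffects:
    def _catechin_specs(self, library):
        cfg = SimulatorConfig()
        return _ingredients({"catechin": 1.0}, library, cfg), cfg

    def _exchangeable_area(self, specs, library):
        exch_centres = {6.09, 6.00}
        return sum(s.area for s in specs if s.center_ppm in exch_centres)

    def test_no_standing_no_exchange(self, library):
        specs, cfg = self._catechin_specs(library)
        out = apply_matrix_effects(
            specs, MatrixState(standing_time_h=0.0, edta_mm=0.0, total_ca_mm=0.0),
            library, cfg,
        )
        assert self._exchangeable_area(out, library) == pytest.approx(
            self._exchangeable_area(specs, library)
        )

    def test_six_hours_ten_percent_left(self, library):
        """k = ln(100)/12 per h: at 6 h the exchangeable area is 10%."""
        specs, cfg = self._catechin_specs(library)
        out = apply_matrix_effects(
            specs, MatrixState(standing_time_h=6.0, edta_mm=0.0, total_ca_mm=0.0),
            library, cfg,
        )
        ratio = self._exchangeable_area(out, library) / self._exchangeable_area(
            specs, library
        )
        assert ratio == pytest.approx(math.exp(-DEFAULT_EXCHANGE_RATE * 6.0))
        assert ratio == pytest.approx(0.10, rel=1e-9)

    def test_exchange_monotone_and_others_invariant(self, library):
        specs, cfg = self._catechin_specs(library)
        areas = []
        stable_areas = []
        for t in (0.0, 1.0, 4.0, 12.0, 24.0):
            out = apply_matrix_effects(
                specs, MatrixState(standing_time_h=t, edta_mm=0.0,
                                   total_ca_mm=0.0), library, cfg,
            )
            areas.append(self._exchangeable_area(out, library))
            stable_areas.append(
                sum(s.area for s in out if s.center_ppm not in (6.09, 6.00))
            )
        assert all(a1 >= a2 for a1, a2 in zip(areas, areas[1:]))
        assert all(s == pytest.approx(stable_areas[0]) for s in stable_areas)

    def test_excess_edta_removes_broadening(self, library):
        cfg = SimulatorConfig()
        specs = _ingredients({"citrate": 1.0}, library, cfg)
        matrix = MatrixState(total_ca_mm=2.0, edta_mm=3.0)
        assert matrix.free_ca_mm == 0.0 and matrix.broadening_factor == 1.0
        out = apply_matrix_effects(specs, matrix, library, cfg)
        cit = [s for s in out if s.metabolite == "citrate"]
        for before, after in zip(specs, cit):
            assert after.fwhm_hz == pytest.approx(before.fwhm_hz)

    def test_free_ca_broadens_ca_sensitive_only(self, library):
        cfg = SimulatorConfig()
        specs = _ingredients({"citrate": 1.0, "alanine": 1.0}, library, cfg)
        matrix = MatrixState(total_ca_mm=1.5, edta_mm=0.5)
        out = apply_matrix_effects(specs, matrix, library, cfg)
        factor = 1.0 + matrix.ca_broadening_beta * 1.0
        for before, after in zip(specs, out):
            expected = factor if after.metabolite == "citrate" else 1.0
            assert after.fwhm_hz == pytest.approx(before.fwhm_hz * expected)

    def test_edta_peaks_added(self, library):
        cfg = SimulatorConfig()
        out = apply_matrix_effects(
            [], MatrixState(total_ca_mm=0.3, edta_mm=0.438), library, cfg
        )
        mets = {s.metabolite for s in out}
        assert mets == {"Ca-EDTA", "EDTA"}
        ca = sum(s.area for s in out if s.metabolite == "Ca-EDTA")
        free = sum(s.area for s in out if s.metabolite == "EDTA")
        assert ca == pytest.approx(0.3 * library["Ca-EDTA"].n_protons_total)
        assert free == pytest.approx(0.138 * library["EDTA"].n_protons_total)


class TestCohort:
    def test_same_seed_bit_identical(self):
        design = sx.CohortDesign(seed=3, n_bio=1, n_tech=2,
                                 tissues=("leaf",), positions=("top",))
        s1, m1, t1 = simulate_cohort(design)
        s2, m2, t2 = simulate_cohort(design)
        assert len(s1) == len(s2)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.intensity, b.intensity)
        assert t1.equals(t2)

    def test_zero_noise_zero_effects_identical_in_cell(self):
        design = sx.CohortDesign(seed=0, bio_cv=0.0, tech_cv_range=(0.0, 0.0),
                                 noise_sd=0.0, n_bio=2, n_tech=2,
                                 tissues=("leaf",), positions=("top",),
                                 genotypes=("Tora",))
        spectra, meta, truth = simulate_cohort(design)
        # extract mass still varies, but composition/spectra are identical
        ref = spectra[0].intensity
        for s in spectra[1:]:
            np.testing.assert_allclose(s.intensity, ref, rtol=1e-12)

    def test_design_shape(self, cohort):
        spectra, meta, truth = cohort
        assert len(spectra) == 2 * 2 * 3 * 2 * 3
        assert meta.shape[0] == 72
        assert set(meta["position"]) == {"top", "middle", "bottom"}

    def test_stem_extractable_three_fold_gradient(self, cohort):
        """Stem-top extract mass is ~2.2-3.2x stem-bottom (about three-fold)."""
        _, meta, _ = cohort
        stem = meta[meta.tissue == "stem"]
        ratio = (
            stem[stem.position == "top"].extract_mass_mg.mean()
            / stem[stem.position == "bottom"].extract_mass_mg.mean()
        )
        assert 2.2 <= ratio <= 3.2

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            sx.CohortDesign(n_tech=0)
        with pytest.raises(ValueError):
            sx.CohortDesign(prep_method="c")
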