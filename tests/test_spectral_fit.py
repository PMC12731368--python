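"""Detector resolution model, model building and spectral deconvolution."""

import numpy as np
import pytest

from xfiquant.physics_tables import line_energy
from xfiquant.spectral_fit import (
    ResolutionCalibration, Spectrum, build_model, detector_fwhm, fit_spectrum,
    reduced_chi_squared,
)
from xfiquant.synthetic import simulate_spectrum

EDGES = np.arange(5.0, 18.0 + 0.01, 0.02)


def _background(level=20.0):
    centers = 0.5 * (EDGES[:-1] + EDGES[1:])
    return level * np.exp(-(centers - 5.0) / 4.0) + 5.0


class TestDetectorFwhm:
    def test_reference_point_reproduced(self):
        assert detector_fwhm(5.9) == pytest.approx(0.123, abs=1e-6)

    def test_monotone_increasing_with_energy(self):
        es = np.linspace(1.0, 20.0, 50)
        vals = detector_fwhm(es)
        assert np.all(np.diff(vals) > 0)
        assert detector_fwhm(9.713) > 0.123

    def test_zero_fano_gives_constant_fwhm(self):
        cal = ResolutionCalibration(fano=0.0)
        assert detector_fwhm(3.0, cal) == pytest.approx(detector_fwhm(15.0, cal))

    def test_impossible_calibration_rejected(self):
        cal = ResolutionCalibration(fwhm_ref_kev=0.01, fano=0.115)
        with pytest.raises(ValueError, match="noise"):
            detector_fwhm(5.9, cal)


class TestBuildModel:
    def test_window_filters_lines(self):
        model = build_model(("Au",), (8.0, 15.0))
        energies = [l.energy for lines in model.groups.values() for l in lines]
        assert energies and all(8.0 <= e < 15.0 for e in energies)

    def test_default_set_includes_zn_ka_excludes_ni_ka(self):
        model = build_model()
        labels = {(el, l.label) for k, lines in model.groups.items()
                  for l in lines for el in [k[0]]}
        assert ("Zn", "Ka1") in labels          # 8.64 keV, inside 8-15
        assert ("Ni", "Ka1") not in labels      # 7.48 keV, below the window
        assert ("Sr", "Kb1") not in labels      # 15.8 keV, above the window

    def test_no_lines_in_window_raises(self):
        with pytest.raises(ValueError, match="window"):
            build_model(("Sr", "Rb"), (8.0, 9.0))

    def test_setup_elements_tied_across_shell(self):
        model = build_model()
        assert ("W", "L") in model.groups       # one free area for all W L lines
        assert ("Au", "La") in model.groups     # sample element per subgroup


class TestFitSpectrum:
    def test_background_only_gives_null_areas(self, rng):
        sp = simulate_spectrum({}, EDGES, rng, background=_background())
        model = build_model(("Au", "W"))
        fr = fit_spectrum(sp, model)
        for key in fr.areas:
            assert fr.areas[key] <= 2.0 * max(fr.errors[key], 1.0)

    def test_injected_gold_area_recovered_within_3_sigma(self):
        rng = np.random.default_rng(42)
        truth = 5000.0
        sp = simulate_spectrum({("Au", "L"): truth}, EDGES, rng,
                               background=_background())
        fr = fit_spectrum(sp, build_model())
        est = sum(fr.areas[("Au", g)] for g in ("La", "Lb", "Lg"))
        err = np.sqrt(sum(fr.errors[("Au", g)] ** 2 for g in ("La", "Lb", "Lg")))
        assert abs(est - truth) < 3.0 * err
        assert 0.8 < fr.redchi < 1.2

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(7)
        sp = simulate_spectrum({("Au", "L"): 2000.0}, EDGES, rng,
                               background=_background())
        model = build_model()
        a = fit_spectrum(sp, model)
        b = fit_spectrum(sp, model)
        assert a.areas == b.areas and a.redchi == b.redchi

    def test_constant_offset_shift_lands_in_background(self):
        rng = np.random.default_rng(3)
        sp = simulate_spectrum({("Au", "L"): 3000.0}, EDGES, rng,
                               background=_background())
        model = build_model(("Au", "W"))
        base = fit_spectrum(sp, model)
        shifted = Spectrum(sp.bin_edges, sp.counts + 50, sp.live_time)
        fr = fit_spectrum(shifted, model)
        # individual continuum terms are degenerate (offset vs flat
        # exponential); the identifiable quantity is the summed background
        centers = np.linspace(9.0, 14.0, 40)
        n_g = len(model.group_keys)
        bg_base = model.background(centers, base.params[n_g:])
        bg_shift = model.background(centers, fr.params[n_g:])
        assert np.median(bg_shift - bg_base) == pytest.approx(50, abs=10)
        for g in ("La", "Lb"):
            key = ("Au", g)
            tol = 2.0 * np.hypot(fr.errors[key], base.errors[key])
            assert abs(fr.areas[key] - base.areas[key]) <= max(tol, 5.0)

    def test_empty_window_counts_rejected(self):
        sp = Spectrum(EDGES, np.zeros(len(EDGES) - 1))
        with pytest.raises(ValueError, match="counts"):
            fit_spectrum(sp, build_model())


class TestEnergyRecalibration:
    def test_linear_map_through_two_reference_lines(self):
        from xfiquant.spectral_fit import recalibrate_energy
        edges = np.linspace(5.0, 15.0, 11)
        # detector reads 9.6 for the 9.713 line and 14.0 for 14.165
        out = recalibrate_energy(edges, (9.6, 9.713), (14.0, 14.165))
        gain = (14.165 - 9.713) / (14.0 - 9.6)
        np.testing.assert_allclose(out, gain * edges + (9.713 - gain * 9.6))

    def test_degenerate_references_rejected(self):
        from xfiquant.spectral_fit import recalibrate_energy
        with pytest.raises(ValueError):
            recalibrate_energy(np.linspace(5, 15, 5), (9.6, 9.7), (9.6, 14.0))


class TestReducedChiSquared:
    def test_perfect_model_gives_zero(self):
        obs = np.arange(10.0)
        assert reduced_chi_squared(obs, obs, np.ones(10), 2) == 0.0

    def test_unit_normal_residuals_give_about_one(self, rng):
        n, n_free = 400, 10
        vals = [reduced_chi_squared(rng.standard_normal(n), np.zeros(n),
                                    np.ones(n), n_free) for _ in range(1000)]
        assert np.mean(vals) == pytest.approx(n / (n - n_free), rel=0.05)

    def test_linear_in_weights(self, rng):
        obs = rng.standard_normal(50)
        mod = np.zeros(50)
        w = np.abs(rng.standard_normal(50)) + 0.1
        a = reduced_chi_squared(obs, mod, w, 3)
        b = reduced_chi_squared(obs, mod, 2.5 * w, 3)
        assert b == pytest.approx(2.5 * a, rel=1e-12)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError, match="free parameters"):
            reduced_chi_squared(np.ones(3), np.ones(3), np.ones(3), 5)
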