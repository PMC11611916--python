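import copy

import numpy as np
import pytest

from thzcryst.spectral_fit import (
    AmorphousSpectrumError,
    GaussianPeak,
    ReferenceModel,
    classify_form,
    fit_crystallinity,
    fit_reference,
    fwhm_from_width,
    quadratic,
    width_from_fwhm,
)

from conftest import make_spectrum


class TestFitReference:
    def test_recovers_known_gaussians_and_background(self, fit_grid):
        peaks = (GaussianPeak(5.0, 0.9, 0.06), GaussianPeak(3.0, 1.25, 0.05), GaussianPeak(4.0, 1.6, 0.08))
        bg = (1.0, 2.0, 1.5)
        y = sum(p(fit_grid) for p in peaks) + quadratic(bg, fit_grid)
        model = fit_reference(make_spectrum(fit_grid, y), "alpha", band_THz=(0.5, 1.8))
        for fitted, true in zip(model.peaks, peaks):
            assert fitted.G == pytest.approx(true.G, rel=1e-3)
            assert fitted.nu0_THz == pytest.approx(true.nu0_THz, rel=1e-3)
            assert fitted.dnu_THz == pytest.approx(true.dnu_THz, rel=1e-3)

    def test_alpha_form_centers_on_direct_grid(self, alpha_model, fit_grid):
        y = alpha_model.evaluate(fit_grid)
        model = fit_reference(make_spectrum(fit_grid, y), "alpha")
        np.testing.assert_allclose(model.centers_THz, (1.09, 1.20, 1.36), atol=1e-3)

    def test_monotone_quadratic_suggests_amorphous(self, fit_grid):
        y = quadratic((2.0, 3.0, 2.5), fit_grid)
        with pytest.raises(AmorphousSpectrumError, match="amorphous"):
            fit_reference(make_spectrum(fit_grid, y), "alpha")

    def test_serialization_round_trip(self, tmp_path, alpha_model):
        path = alpha_model.save(tmp_path / "alpha.json")
        back = ReferenceModel.load(path)
        assert back.form == alpha_model.form
        assert back.centers_THz == alpha_model.centers_THz
        np.testing.assert_allclose(back.background, alpha_model.background)


class TestFitCrystallinity:
    def test_noiseless_mixture_recovered_exactly(self, mixture_spectrum_factory, alpha_model, beta_model):
        fit = fit_crystallinity(mixture_spectrum_factory(0.7, 0.3), alpha_model, beta_model)
        assert fit.A == pytest.approx(0.70, abs=1e-6)
        assert fit.B == pytest.approx(0.30, abs=1e-6)

    def test_pure_quadratic_gives_zero_coefficients(self, mixture_spectrum_factory, alpha_model, beta_model):
        fit = fit_crystallinity(mixture_spectrum_factory(0.0, 0.0), alpha_model, beta_model)
        assert fit.A == pytest.approx(0.0, abs=1e-9)
        assert fit.B == pytest.approx(0.0, abs=1e-9)

    def test_alpha_reference_self_consistency(self, alpha_model, beta_model, fit_grid):
        y = alpha_model.evaluate(fit_grid)
        fit = fit_crystallinity(make_spectrum(fit_grid, y), alpha_model, beta_model)
        assert fit.A == pytest.approx(1.0, abs=1e-9)
        assert fit.B == pytest.approx(0.0, abs=1e-9)

    def test_reference_models_never_mutated(self, mixture_spectrum_factory, alpha_model, beta_model):
        before_a, before_b = copy.deepcopy(alpha_model), copy.deepcopy(beta_model)
        fit_crystallinity(mixture_spectrum_factory(0.4, 0.6), alpha_model, beta_model)
        assert alpha_model.centers_THz == before_a.centers_THz
        assert [(p.G, p.dnu_THz) for p in alpha_model.peaks] == [(p.G, p.dnu_THz) for p in before_a.peaks]
        assert [(p.G, p.dnu_THz) for p in beta_model.peaks] == [(p.G, p.dnu_THz) for p in before_b.peaks]

    @pytest.mark.parametrize("lam", [0.5, 2.0, 3.7])
    def test_linear_in_scale_on_peak_only_input(self, lam, alpha_model, beta_model, fit_grid):
        base = 0.6 * alpha_model.peak_profile(fit_grid) + 0.4 * beta_model.peak_profile(fit_grid)
        fit = fit_crystallinity(make_spectrum(fit_grid, lam * base), alpha_model, beta_model)
        assert fit.A == pytest.approx(lam * 0.6, rel=1e-9)
        assert fit.B == pytest.approx(lam * 0.4, rel=1e-9)

    def test_matches_brute_force_grid_search(self, mixture_spectrum_factory, alpha_model, beta_model, fit_grid):
        # independent oracle: scan (A, B) on a 0.01 grid, profiling out the
        # quadratic background by ordinary least squares at each grid point
        rng = np.random.default_rng(123)
        P = np.column_stack([np.ones_like(fit_grid), fit_grid, fit_grid**2])
        P_pinv = np.linalg.pinv(P)
        g1 = alpha_model.peak_profile(fit_grid)
        g2 = beta_model.peak_profile(fit_grid)
        grid = np.arange(0.0, 2.0 + 1e-12, 0.01)
        for _ in range(5):
            A_true, B_true = rng.uniform(0.05, 1.9, 2)
            spec = mixture_spectrum_factory(A_true, B_true)
            best = (np.inf, None, None)
            for A in grid:
                resid = spec.alpha_cm1[:, None] - A * g1[:, None] - np.outer(g2, grid)
                resid = resid - P @ (P_pinv @ resid)
                norms = np.sum(resid**2, axis=0)
                j = int(np.argmin(norms))
                if norms[j] < best[0]:
                    best = (norms[j], A, grid[j])
            fit = fit_crystallinity(spec, alpha_model, beta_model)
            assert fit.A == pytest.approx(best[1], abs=0.01)
            assert fit.B == pytest.approx(best[2], abs=0.01)

    def test_noise_robustness_small_sample(self, mixture_spectrum_factory, alpha_model, beta_model):
        rng = np.random.default_rng(7)
        estimates = []
        for _ in range(20):
            spec = mixture_spectrum_factory(0.7, 0.3, noise_std=0.2, rng=rng)
            fit = fit_crystallinity(spec, alpha_model, beta_model)
            estimates.append((fit.A, fit.B))
        mean = np.mean(estimates, axis=0)
        assert mean[0] == pytest.approx(0.7, rel=0.05)
        assert mean[1] == pytest.approx(0.3, rel=0.05)

    def test_rank_deficient_band_rejected(self, mixture_spectrum_factory, alpha_model, beta_model):
        with pytest.raises(ValueError, match="rank|band|densely"):
            fit_crystallinity(
                mixture_spectrum_factory(0.5, 0.5), alpha_model, beta_model, band_THz=(1.79, 1.8)
            )


class TestClassify:
    def test_pure_quadratic_is_amorphous(self, mixture_spectrum_factory, alpha_model, beta_model):
        assert classify_form(mixture_spectrum_factory(0.0, 0.0), alpha_model, beta_model) == "amorphous"

    def test_alpha_only_is_alpha(self, mixture_spectrum_factory, alpha_model, beta_model):
        assert classify_form(mixture_spectrum_factory(1.0, 0.0), alpha_model, beta_model) == "alpha"

    def test_beta_only_is_beta(self, mixture_spectrum_factory, alpha_model, beta_model):
        assert classify_form(mixture_spectrum_factory(0.0, 1.0), alpha_model, beta_model) == "beta"

    def test_balanced_mixture_is_mixed(self, mixture_spectrum_factory, alpha_model, beta_model):
        # A/B = 0.4/0.5 = 0.8 lies inside the mixed ratio window [0.5, 2]
        assert classify_form(mixture_spectrum_factory(0.4, 0.5), alpha_model, beta_model) == "mixed"


def test_width_convention_conversions():
    assert fwhm_from_width(1.0) == pytest.approx(2 * np.sqrt(np.log(2)))
    assert width_from_fwhm(fwhm_from_width(0.07)) == pytest.approx(0.07)
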