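"""Linear-combination fitting, Fisher-information uncertainty and QC."""

import numpy as np
import pytest

from mrsiglx.lcm_fit import (
    cmc,
    combined_crlb_percent,
    crlb_percent,
    estimate_snr_fwhm,
    fisher_information,
    fit_grid,
    fit_spectrum,
    quality_filter,
)
from mrsiglx.synthetic_data import (
    Composition,
    NoiseModel,
    PHANTOM_2,
    generate_phantom_spectrum,
)

QUIET = NoiseModel(noise_sd=0.0, linewidth_jitter_hz=0.0,
                   freq_jitter_sd=0.0, phase_jitter_sd=0.0)


def _phantom_spec(comp, basis, noise=QUIET, seed=0):
    return generate_phantom_spectrum(comp, basis, noise, seed).spectra[0, 0]


class TestFitSpectrum:
    def test_single_metabolite_exact_recovery(self, basis_small):
        spec = _phantom_spec(Composition({"Cr": 10.0}), basis_small)
        fit = fit_spectrum(spec, basis_small)
        assert fit.concentrations["Cr"] == pytest.approx(10.0, rel=1e-3)
        for other in ("Glu", "Gln"):
            assert fit.concentrations[other] <= 1e-3 * fit.concentrations["Cr"]

    def test_phantom2_ratios_at_te120(self, basis_te120):
        spec = _phantom_spec(PHANTOM_2, basis_te120)
        fit = fit_spectrum(spec, basis_te120)
        cr = fit.concentrations["Cr"]
        assert fit.concentrations["Glu"] / cr == pytest.approx(1.00, rel=0.02)
        assert fit.concentrations["Gln"] / cr == pytest.approx(0.50, rel=0.02)
        assert fit.concentrations["Cho"] / cr == pytest.approx(0.30, rel=0.02)

    def test_parameter_recovery_random_compositions(self, basis_small):
        # noiseless matched model: every amplitude within 0.5% over many draws
        rng = np.random.default_rng(42)
        for _ in range(20):
            truth = {m: float(rng.uniform(2.0, 20.0)) for m in ("Glu", "Gln", "Cr")}
            spec = _phantom_spec(Composition(truth), basis_small)
            fit = fit_spectrum(spec, basis_small)
            for m, c in truth.items():
                assert fit.concentrations[m] == pytest.approx(c, rel=5e-3)

    def test_residual_rms_tracks_noise_floor(self, basis_te120):
        noise = NoiseModel(noise_sd=0.0)
        from mrsiglx.synthetic_data import (
            generate_mrsi_grid, make_healthy_scene)

        scene = make_healthy_scene(grid_dims=(2, 2), voi=(2, 2))
        grid = generate_mrsi_grid(scene, basis_te120, noise, seed=5, target_snr=27.0)
        fit = fit_spectrum(grid.spectra[0, 0], basis_te120)
        sigma_freq = grid.noise_sd * np.sqrt(grid.acq.n_points)
        rms = np.sqrt(np.mean(np.abs(fit.residual) ** 2) / 2)
        assert rms == pytest.approx(sigma_freq, rel=0.10)

    def test_recovers_phase_shift_and_damping(self, basis_small):
        noise = NoiseModel(noise_sd=0.0, linewidth_jitter_hz=0.0,
                           freq_jitter_sd=2.0, phase_jitter_sd=10.0)
        spec = generate_phantom_spectrum(
            Composition({"Glu": 10.0, "Cr": 8.0}), basis_small, noise, seed=9
        ).spectra[0, 0]
        fit = fit_spectrum(spec, basis_small)
        assert fit.concentrations["Glu"] == pytest.approx(10.0, rel=0.02)
        assert abs(fit.global_shift_ppm) > 0 or abs(fit.phase0_deg) > 0

    def test_mismatched_axis_rejected(self, basis_small):
        with pytest.raises(ValueError):
            fit_spectrum(np.zeros(1024, dtype=complex), basis_small)

    def test_scale_equivariance(self, basis_te120):
        from mrsiglx.synthetic_data import generate_mrsi_grid, make_healthy_scene

        scene = make_healthy_scene(grid_dims=(2, 2), voi=(2, 2))
        grid = generate_mrsi_grid(scene, basis_te120, NoiseModel(), seed=3,
                                  target_snr=27.0)
        spec = grid.spectra[0, 0]
        k = 7.5
        f1 = fit_spectrum(spec, basis_te120)
        f2 = fit_spectrum(k * spec, basis_te120)
        for m in f1.concentrations:
            assert f2.concentrations[m] == pytest.approx(
                k * f1.concentrations[m], rel=1e-3, abs=1e-6)
        assert f2.crlb_pct["Glu"] == pytest.approx(f1.crlb_pct["Glu"], rel=0.02)
        F1 = fisher_information(f1)
        F2 = fisher_information(f2)
        names = list(f1.metabolites)
        assert cmc(F2, names, "Glu", "Gln") == pytest.approx(
            cmc(F1, names, "Glu", "Gln"), abs=0.02)


class TestFisherAndBounds:
    def test_orthogonal_basis_gives_diagonal_fisher_and_zero_cmc(self, acq):
        # two synthetic singlets far apart: columns essentially orthogonal
        from mrsiglx.spin_sim import make_basis_set

        basis = make_basis_set(["Cr", "Lac"], 120.0, acq)
        spec = _phantom_spec(Composition({"Cr": 8.0, "Lac": 4.0}), basis)
        fit = fit_spectrum(spec, basis, noise_sd=1.0)
        F = fisher_information(fit)
        names = list(fit.metabolites)
        off = abs(F[0, 1]) / np.sqrt(F[0, 0] * F[1, 1])
        assert off < 0.05
        assert abs(cmc(F, names, "Cr", "Lac")) < 0.05

    def test_noise_scaling_of_fisher(self, basis_small):
        spec = _phantom_spec(Composition({"Glu": 10.0, "Cr": 8.0}), basis_small)
        fit = fit_spectrum(spec, basis_small, noise_sd=1.0)
        F1 = fisher_information(fit, noise_sd=1.0)
        F2 = fisher_information(fit, noise_sd=2.0)
        np.testing.assert_allclose(F2, F1 / 4.0)

    def test_crlb_scalar_closed_form(self):
        # single unit-norm column: CRLB% = 100 sigma / C
        b = np.zeros((10, 1))
        b[3, 0] = 1.0
        sigma, c = 0.5, 4.0
        F = b.T @ b / sigma**2
        out = crlb_percent(F, {"X": c}, ["X"])
        assert out["X"] == pytest.approx(100 * sigma / c)
        half = crlb_percent(F, {"X": c / 2}, ["X"])
        assert half["X"] == pytest.approx(2 * out["X"])

    def test_zero_concentration_undefined_not_infinite(self):
        F = np.eye(2)
        out = crlb_percent(F, {"A": 1.0, "B": 0.0}, ["A", "B"])
        assert np.isnan(out["B"]) and np.isfinite(out["A"])

    def test_collinear_pair_cmc_near_minus_one(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(200)
        b = 0.999 * a + np.sqrt(1 - 0.999**2) * rng.standard_normal(200)
        A = np.stack([a, b], axis=1)
        F = A.T @ A
        assert cmc(F, ["a", "b"], "a", "b") <= -0.99

    def test_cmc_bounds_and_rescaling_invariance(self, fitted_healthy_te120):
        fits, _ = fitted_healthy_te120
        f = next(iter(fits.values()))
        F = fisher_information(f)
        names = list(f.metabolites)
        v = cmc(F, names, "Glu", "Gln")
        assert -1.0 <= v <= 1.0
        # joint rescale of both basis columns leaves CMC unchanged
        D = np.eye(len(names))
        gi, gj = names.index("Glu"), names.index("Gln")
        D[gi, gi] = D[gj, gj] = 3.0
        assert cmc(D @ F @ D, names, "Glu", "Gln") == pytest.approx(v, abs=1e-10)

    def test_crlb_is_a_tight_lower_bound_for_strong_singlets(self, basis_small):
        # empirical estimator SD across noisy replicates exceeds the
        # amplitude-conditioned CRLB (a lower bound) and stays within 1.5x
        # of the nuisance-marginalized bound for a well-conditioned
        # metabolite (Cr)
        from mrsiglx.lcm_fit import marginalized_covariance

        comp = Composition({"Glu": 10.84, "Gln": 2.94, "Cr": 8.0})
        noise = NoiseModel(noise_sd=2.0, linewidth_jitter_hz=0.0,
                           freq_jitter_sd=0.0, phase_jitter_sd=0.0)
        ests, crlbs, marg = [], [], []
        for seed in range(60):
            spec = _phantom_spec(comp, basis_small, noise, seed=seed)
            fit = fit_spectrum(spec, basis_small)
            ests.append(fit.concentrations["Cr"])
            crlbs.append(fit.crlb_pct["Cr"] / 100 * fit.concentrations["Cr"])
            cov = marginalized_covariance(fit, basis_small)
            marg.append(np.sqrt(cov[list(fit.metabolites).index("Cr")][
                list(fit.metabolites).index("Cr")]))
        emp_sd = np.std(ests, ddof=1)
        assert emp_sd >= 0.8 * np.mean(crlbs)       # lower bound (MC slack)
        assert np.mean(marg) >= np.mean(crlbs)      # marginal >= conditioned
        assert emp_sd <= 1.5 * np.mean(marg)        # efficiency of the fit


class TestSnrFwhmAndQc:
    def test_snr_doubles_with_concentration(self, basis_small):
        noise = NoiseModel(noise_sd=1.0, linewidth_jitter_hz=0.0,
                           freq_jitter_sd=0.0, phase_jitter_sd=0.0)
        s1 = _phantom_spec(Composition({"Cr": 10.0}), basis_small, noise, seed=2)
        s2 = _phantom_spec(Composition({"Cr": 20.0}), basis_small, noise, seed=2)
        f1 = fit_spectrum(s1, basis_small)
        f2 = fit_spectrum(s2, basis_small)
        assert f2.snr / f1.snr == pytest.approx(2.0, rel=0.05)

    def test_pure_noise_rejected_by_snr(self, basis_small):
        noise = NoiseModel(noise_sd=1.0)
        spec = _phantom_spec(Composition({}), basis_small, noise, seed=3)
        fit = fit_spectrum(spec, basis_small)
        assert fit.snr < 3.0

    def test_generator_targets_recovered(self, fitted_healthy_te120):
        fits, grid = fitted_healthy_te120
        snrs = [f.snr for f in fits.values()]
        fwhms = [f.fwhm_ppm for f in fits.values()]
        assert np.mean(snrs) == pytest.approx(27.0, rel=0.15)
        assert np.mean(fwhms) == pytest.approx(0.029, rel=0.20)

    def test_estimate_snr_fwhm_reports_fit_values(self, basis_small):
        spec = _phantom_spec(Composition({"Cr": 10.0}), basis_small)
        fit = fit_spectrum(spec, basis_small)
        assert estimate_snr_fwhm(spec, fit) == (fit.snr, fit.fwhm_ppm)

    def test_quality_filter_rules(self, basis_te120):
        from mrsiglx.synthetic_data import generate_mrsi_grid, make_healthy_scene

        scene = make_healthy_scene(grid_dims=(2, 2), voi=(2, 2))
        grid = generate_mrsi_grid(scene, basis_te120, NoiseModel(), seed=4,
                                  target_snr=27.0)
        fits = fit_grid(grid, basis_te120)
        good = fits[(0, 0)]
        import copy

        wide = copy.copy(good)
        wide.fwhm_ppm = 0.12
        faint = copy.copy(good)
        faint.snr = 2.9
        results = {(0, 0): good, (0, 1): wide, (1, 0): faint}
        accepted, reasons = quality_filter(results)
        assert (0, 0) in accepted
        assert reasons[(0, 1)] == ("fwhm",)
        assert reasons[(1, 0)] == ("snr",)

    def test_artifact_mask_rejects(self, basis_small):
        spec = _phantom_spec(Composition({"Glu": 10.0, "Gln": 3.0, "Cr": 8.0}),
                             basis_small)
        fit = fit_spectrum(spec, basis_small)
        fit2 = fit_spectrum(spec, basis_small)
        res = {(0, 0): fit, (0, 1): fit2}
        accepted, reasons = quality_filter(
            res, artifact_mask={(0, 1): True})
        assert "artifact" in reasons[(0, 1)]

    def test_combined_crlb_uses_covariance(self, fitted_healthy_te120):
        fits, _ = fitted_healthy_te120
        f = next(iter(fits.values()))
        v = combined_crlb_percent(f, ("Cho", "GPC"))
        assert np.isfinite(v) and v > 0
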