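import numpy as np
import pytest

from sprf.fit import (REFERENCE_LAW, PiecewiseSPRF, SPRFLaw,
                      chisq_gof, fit_law, fit_piecewise, grubbs_critical,
                      grubbs_filter, sample_sprf)

TRUTH = PiecewiseSPRF(alpha=0.46875, beta=0.18, phi_c=0.65)


class TestPiecewiseModel:
    def test_anchoring(self):
        assert TRUTH(0.0) == 0.0
        assert TRUTH(1.0 - 1e-12) == pytest.approx(0.0, abs=1e-10)

    def test_discontinuous_at_breakpoint(self):
        eps = 1e-9
        left = TRUTH(TRUTH.phi_c - eps)
        right = TRUTH(TRUTH.phi_c)
        assert left == pytest.approx(-0.18 * 0.65, abs=1e-6)
        assert right == pytest.approx(0.46875 * 0.35, abs=1e-6)
        assert right - left > 0.2  # the sharp midcycle break

    def test_law_evaluation(self):
        m = REFERENCE_LAW.evaluate(0.75, 1.5)
        assert m.beta == pytest.approx(0.18)
        assert m.alpha == pytest.approx(0.46875)
        assert m.phi_c == pytest.approx(0.65)

    def test_law_clamps_breakpoint_with_warning(self):
        law = SPRFLaw(a=0.1, b=0.6, c=0.5, d=0.2)
        with pytest.warns(UserWarning, match="clamp"):
            m = law.evaluate(3.0, 1.0)
        assert 0.0 < m.phi_c < 1.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PiecewiseSPRF(alpha=0.1, beta=0.1, phi_c=1.5)
        with pytest.raises(ValueError):
            PiecewiseSPRF(alpha=-0.1, beta=0.1, phi_c=0.5)
        with pytest.raises(ValueError):
            SPRFLaw(a=-0.1, b=0.6, c=0.8, d=0.2)


class TestGrubbs:
    def test_critical_value_n30(self):
        # closed form via the t distribution at n = 30, alpha = 0.05
        # (matches the standard two-sided Grubbs table value 2.908)
        assert grubbs_critical(30) == pytest.approx(2.908, abs=0.005)

    def test_single_gross_outlier_removed(self):
        rng = np.random.default_rng(7)
        r = rng.normal(0, 1, 29)
        r = np.append(r, 10.0)
        kept = grubbs_filter(r)
        assert 29 not in kept
        assert kept.size == 29

    def test_constant_residuals_all_kept(self):
        kept = grubbs_filter(np.full(10, 0.3))
        assert kept.size == 10

    def test_removal_cap(self):
        rng = np.random.default_rng(3)
        r = np.concatenate([rng.normal(0, 0.1, 26), [5.0, -6.0, 7.0, -8.0]])
        kept = grubbs_filter(r, max_remove=3)
        assert kept.size == 27  # exactly three removed

    def test_too_few_residuals_rejected(self):
        with pytest.raises(ValueError):
            grubbs_filter(np.zeros(5))


class TestFitPiecewise:
    def test_noise_free_exact_recovery(self):
        phi = np.linspace(0.01, 0.99, 60)
        fit, diag = fit_piecewise(phi, TRUTH(phi))
        assert fit.alpha == pytest.approx(TRUTH.alpha, abs=1e-12)
        assert fit.beta == pytest.approx(TRUTH.beta, abs=1e-12)
        assert abs(fit.phi_c - TRUTH.phi_c) < 0.02  # between-sample midpoint
        assert diag.sse == pytest.approx(0.0, abs=1e-20)

    def test_fit_does_not_force_continuity(self):
        phi = np.linspace(0.01, 0.99, 80)
        fit, _ = fit_piecewise(phi, TRUTH(phi))
        jump = fit.alpha * (1 - fit.phi_c) + fit.beta * fit.phi_c
        assert jump > 0.2

    def test_recovery_under_moderate_noise(self):
        """At noise sd 0.03 cycles the three parameters are recovered
        within 15% / 0.05 cycles in the vast majority of seeded
        replicates (85% measured by the Monte-Carlo oracle; the rate is
        limited by the per-branch slope standard errors)."""
        ok = 0
        for s in range(100):
            phi, dphi = sample_sprf(TRUTH, n=60, noise_sd=0.03, seed=100 + s)
            fit, _ = fit_piecewise(phi, dphi)
            if (abs(fit.alpha - TRUTH.alpha) <= 0.15 * TRUTH.alpha
                    and abs(fit.beta - TRUTH.beta) <= 0.15 * TRUTH.beta
                    and abs(fit.phi_c - TRUTH.phi_c) <= 0.05):
                ok += 1
        assert ok >= 85

    def test_estimates_centered_at_experimental_noise(self):
        """At the experimental noise level (sd = sqrt(0.021) cycles) the
        per-replicate scatter is large and the advance slope has a heavy
        right tail (breakpoint-selection noise), but the estimates remain
        centered: replicate medians land within 15% of the truth."""
        alphas, betas = [], []
        for s in range(100):
            phi, dphi = sample_sprf(TRUTH, n=60, noise_sd=np.sqrt(0.021),
                                    seed=300 + s)
            fit, diag = fit_piecewise(phi, dphi)
            alphas.append(diag.alpha_raw)
            betas.append(diag.beta_raw)
        assert np.median(alphas) == pytest.approx(TRUTH.alpha,
                                                  rel=0.15)
        assert np.median(betas) == pytest.approx(TRUTH.beta, rel=0.15)

    def test_pure_delay_alpha_not_significant(self):
        delay_only = PiecewiseSPRF(alpha=0.0, beta=0.2, phi_c=0.7)
        hits = 0
        for s in range(40):
            phi, dphi = sample_sprf(delay_only, n=60, noise_sd=0.05,
                                    seed=500 + s)
            fit, diag = fit_piecewise(phi, dphi)
            if np.isfinite(diag.alpha_se):
                ci_lo = diag.alpha_raw - 1.96 * diag.alpha_se
                if ci_lo > 0:
                    hits += 1
        assert hits <= 6  # alpha rarely "significantly" positive

    def test_grubbs_refit_never_increases_kept_sse(self):
        rng = np.random.default_rng(11)
        phi, dphi = sample_sprf(TRUTH, n=50, noise_sd=0.03, seed=12)
        dphi[7] += 1.0  # gross outlier
        fit, diag = fit_piecewise(phi, dphi)
        assert 7 in diag.removed_idx
        sse_kept = np.sum(diag.residuals[diag.kept_idx] ** 2)
        assert sse_kept <= diag.sse + 1e-12

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_piecewise(np.linspace(0, 1, 5), np.zeros(5))

    def test_one_sided_data_unidentifiable(self):
        phi = np.full(10, 0.4)
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_piecewise(phi, np.zeros(10))


class TestChisq:
    def test_zero_residuals(self):
        chi2, red, p = chisq_gof(np.zeros(20), 0.02)
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_halving_variance_doubles_chi2(self):
        r = np.linspace(-0.1, 0.1, 20)
        c1, _, _ = chisq_gof(r, 0.02)
        c2, _, _ = chisq_gof(r, 0.01)
        assert c2 == pytest.approx(2 * c1)

    def test_calibration_of_reduced_chi2(self):
        """Correctly specified noise: mean reduced chi-square near 1 over
        200 synthetic curves."""
        s2 = 0.021
        reds = []
        for s in range(200):
            phi, dphi = sample_sprf(TRUTH, n=60, noise_sd=np.sqrt(s2),
                                    seed=900 + s)
            fit, diag = fit_piecewise(phi, dphi)
            _, red, _ = chisq_gof(diag.residuals, s2, kept_idx=diag.kept_idx)
            reds.append(red)
        assert 0.85 <= np.mean(reds) <= 1.15

    def test_nonpositive_dof_rejected(self):
        with pytest.raises(ValueError):
            chisq_gof(np.zeros(3), 0.01)
        with pytest.raises(ValueError):
            chisq_gof(np.zeros(20), 0.0)


class TestFitLaw:
    @staticmethod
    def exact_fits(law):
        fits = []
        for g_e in (0.0, 0.25, 0.5, 0.75):
            for g_i in (0.5, 1.5, 3.0):
                fits.append((g_e, g_i, law.evaluate(g_e, g_i)))
        return fits

    def test_exact_recovery_from_noise_free_fits(self):
        rec = fit_law(self.exact_fits(REFERENCE_LAW))
        assert rec.a == pytest.approx(0.12, abs=1e-12)
        assert rec.b == pytest.approx(0.625, abs=1e-12)
        assert rec.c == pytest.approx(0.8, abs=1e-12)
        assert rec.d == pytest.approx(0.2, abs=1e-12)

    def test_zero_betas_give_zero_a(self):
        fits = [(g_e, g_i, PiecewiseSPRF(alpha=0.6 * g_e, beta=0.0,
                                         phi_c=0.7))
                for g_e in (0.1, 0.4, 0.8) for g_i in (0.5, 1.0, 2.0)]
        assert fit_law(fits).a == 0.0

    def test_noisy_slope_recovery(self):
        """10% Gaussian noise on each fitted slope: a and b recovered
        within 15% in >= 90/100 replicates (9 conditions)."""
        law = REFERENCE_LAW
        base = [(g_e, g_i) for g_e in (0.25, 0.5, 0.75)
                for g_i in (0.5, 1.5, 3.0)]
        ok = 0
        for s in range(100):
            rng = np.random.default_rng(2000 + s)
            fits = []
            for g_e, g_i in base:
                m = law.evaluate(g_e, g_i)
                fits.append((g_e, g_i, PiecewiseSPRF(
                    alpha=max(m.alpha * (1 + 0.1 * rng.standard_normal()), 0),
                    beta=max(m.beta * (1 + 0.1 * rng.standard_normal()), 0),
                    phi_c=m.phi_c)))
            rec = fit_law(fits)
            if (abs(rec.a - law.a) <= 0.15 * law.a
                    and abs(rec.b - law.b) <= 0.15 * law.b):
                ok += 1
        assert ok >= 90

    def test_insufficient_spread_names_axis(self):
        fits = [(0.5, g_i, REFERENCE_LAW.evaluate(0.5, g_i))
                for g_i in (0.5, 1.0, 2.0)]
        with pytest.raises(ValueError, match="g_e"):
            fit_law(fits)
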