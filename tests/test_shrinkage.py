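"""Shrinkage weight EM, combined estimator, and asymptotic intervals."""

import numpy as np
import pytest
from scipy.integrate import quad

from bernshrink import (
    BoundaryError,
    GMMParams,
    InvalidInputError,
    ShrinkageEstimate,
    UnitSample,
    asymptotic_ci,
    confidence_band,
    evaluate_shrinkage,
    evaluate_vitale,
    fit_lambda_em,
    fit_shrinkage,
    fit_vitale,
    gmm_density,
    lambda_e_step,
)


def unit_vitale(m=16):
    """Uniform weights: the Vitale density is identically 1."""
    return fit_vitale(UnitSample(np.linspace(1 / (2 * m), 1 - 1 / (2 * m), m)), m)


def standard_gmm():
    return GMMParams(np.array([1.0]), np.array([0.0]), np.array([1.0]))


class TestLambdaESTep:
    def test_identical_components_give_lambda(self, rng):
        f = rng.random(20) + 0.5
        for lam in (0.0, 0.3, 1.0):
            assert lambda_e_step(lam, f, f) == pytest.approx(np.full(20, lam))

    def test_hand_posterior(self):
        assert lambda_e_step(0.5, [2.0], [1.0])[0] == pytest.approx(2 / 3, abs=1e-15)

    def test_boundary_lambda(self):
        assert lambda_e_step(1.0, [2.0, 0.5], [1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            lambda_e_step(1.5, [1.0], [1.0])
        with pytest.raises(InvalidInputError):
            lambda_e_step(0.5, [-1.0], [1.0])


class TestLambdaEM:
    def test_identical_components_fixed_point(self, rng):
        s = UnitSample(rng.random(15))
        f = rng.random(15) + 0.2
        lam, _ = fit_lambda_em(s, f, f, lam0=0.5)
        assert lam == pytest.approx(0.5, abs=1e-15)

    def test_degenerate_second_component(self):
        s = UnitSample(np.array([0.2, 0.6]))
        lam, it = fit_lambda_em(s, np.array([1.0, 2.0]), np.zeros(2), max_iter=1)
        assert lam == pytest.approx(1.0)
        assert it == 1

    def test_iterates_stay_in_unit_interval(self, rng):
        s = UnitSample(rng.random(30))
        f1 = rng.random(30) * 5
        f2 = rng.random(30) * 5
        for k in range(1, 20):
            lam, _ = fit_lambda_em(s, f1, f2, max_iter=k)
            assert 0.0 <= lam <= 1.0

    def test_monotone_mixture_log_likelihood(self, rng):
        s = UnitSample(rng.random(30))
        f1 = rng.random(30) * 3 + 0.1
        f2 = rng.random(30) * 3 + 0.1
        lls = []
        for k in range(1, 15):
            lam, _ = fit_lambda_em(s, f1, f2, max_iter=k, tol=0.0)
            lls.append(np.sum(np.log(lam * f1 + (1 - lam) * f2)))
        assert np.all(np.diff(lls) >= -1e-10)

    def test_invalid_lam0(self, rng):
        with pytest.raises(InvalidInputError):
            fit_lambda_em(UnitSample(rng.random(5)), np.ones(5), np.ones(5), lam0=1.2)


class TestEvaluate:
    def test_convex_combination_hand_value(self):
        vit = fit_vitale(UnitSample(np.array([0.2, 0.5, 0.8])), 2)  # f1(0) = 4/3
        sigma = 1 / np.sqrt(2 * np.pi)  # N(0, sigma)(0) = 1
        gmm = GMMParams(np.array([1.0]), np.array([0.0]), np.array([sigma]))
        est = ShrinkageEstimate(lam=0.5, vitale=vit, gmm=gmm, n=3, m=2)
        assert evaluate_shrinkage(est, 0.0) == pytest.approx(7 / 6, abs=1e-12)

    def test_lambda_one_reduces_to_vitale(self, rng):
        vit = fit_vitale(UnitSample(rng.random(20)), 7)
        est = ShrinkageEstimate(lam=1.0, vitale=vit, gmm=standard_gmm(), n=20, m=7)
        x = rng.random(30)
        assert evaluate_shrinkage(est, x) == pytest.approx(evaluate_vitale(vit, x))

    def test_lambda_zero_reduces_to_gmm(self, rng):
        gmm = GMMParams(np.array([1.0]), np.array([0.4]), np.array([0.2]))
        est = ShrinkageEstimate(lam=0.0, vitale=unit_vitale(), gmm=gmm, n=16, m=16)
        x = rng.random(30)
        assert evaluate_shrinkage(est, x) == pytest.approx(gmm_density(gmm, x))

    def test_outside_unit_interval_rejected(self):
        est = ShrinkageEstimate(lam=1.0, vitale=unit_vitale(), gmm=standard_gmm(),
                                n=16, m=16)
        with pytest.raises(InvalidInputError):
            evaluate_shrinkage(est, -0.1)


class TestFitShrinkage:
    def test_uniform_data_gives_flat_density(self, rng):
        s = UnitSample(rng.random(400))
        est = fit_shrinkage(s, 3, K=1, seed=0)
        x = np.linspace(0.1, 0.9, 17)
        assert 0.0 <= est.lam <= 1.0
        assert np.all(np.abs(evaluate_shrinkage(est, x) - 1.0) < 0.3)

    def test_deterministic_replay(self, rng):
        vals = rng.random(120)
        a = fit_shrinkage(UnitSample(vals), 8, K="auto", seed=42)
        b = fit_shrinkage(UnitSample(vals), 8, K="auto", seed=42)
        assert a.lam == b.lam
        assert a.gmm.mu == pytest.approx(b.gmm.mu)

    def test_total_mass_is_lambda_weighted(self, rng):
        s = UnitSample(rng.random(150))
        est = fit_shrinkage(s, 5, K=1, seed=0)
        mass, _ = quad(lambda x: evaluate_shrinkage(est, float(x)), 0, 1, limit=200)
        gmass, _ = quad(lambda x: est.gmm_density_unit(float(x)), 0, 1, limit=200)
        assert mass == pytest.approx(est.lam + (1 - est.lam) * gmass, abs=1e-7)

    def test_heldout_option(self, rng):
        train = UnitSample(rng.random(90))
        test = UnitSample(rng.random(45))
        est = fit_shrinkage(train, 6, K=1, seed=0, heldout=test)
        assert 0.0 <= est.lam <= 1.0

    def test_limit_with_fixed_lambda_tracks_pseudo_truth(self, rng):
        # With lambda held fixed and m ~ sqrt(n / log n), the estimate at an
        # interior point approaches lam*f + (1-lam)*f2*, where f2* is the
        # best single-Gaussian fit: for Beta(2,2) data, N(0.5, sqrt(0.05)).
        from scipy.stats import beta as beta_dist

        lam = 0.4
        target = lam * beta_dist(2, 2).pdf(0.5) + (1 - lam) / np.sqrt(
            0.05 * 2 * np.pi
        )
        errs = []
        for n in (300, 3000):
            x = beta_dist(2, 2).rvs(size=n, random_state=rng)
            m = int(np.sqrt(n / np.log(n)))
            fitted = fit_shrinkage(UnitSample(x), m, K=1, seed=0)
            frozen = ShrinkageEstimate(
                lam=lam, vitale=fitted.vitale, gmm=fitted.gmm, n=n, m=m
            )
            errs.append(abs(evaluate_shrinkage(frozen, 0.5) - target))
        assert errs[1] < 0.12
        assert errs[1] < errs[0] + 0.05


class TestConfidenceInterval:
    def test_zero_width_at_lambda_zero(self):
        est = ShrinkageEstimate(lam=0.0, vitale=unit_vitale(), gmm=standard_gmm(),
                                n=100, m=16)
        lo, hi = asymptotic_ci(est, 0.3)
        assert lo == pytest.approx(hi)

    def test_band_brackets_estimate(self):
        est = ShrinkageEstimate(lam=0.7, vitale=unit_vitale(), gmm=standard_gmm(),
                                n=100, m=16)
        band = confidence_band(est, np.linspace(0.05, 0.95, 19))
        assert np.all(band.lower <= band.estimate)
        assert np.all(band.estimate <= band.upper)

    def test_boundary_and_alpha_validation(self):
        est = ShrinkageEstimate(lam=1.0, vitale=unit_vitale(), gmm=standard_gmm(),
                                n=100, m=16)
        with pytest.raises(BoundaryError):
            asymptotic_ci(est, 0.0)
        with pytest.raises(InvalidInputError):
            asymptotic_ci(est, 0.5, alpha=1.5)
        with pytest.raises(InvalidInputError):
            asymptotic_ci(est, 0.5, convention="bogus")
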