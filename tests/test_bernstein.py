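"""Bernstein basis, empirical CDF, Vitale and Guan estimators."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import beta as beta_dist

from bernshrink import (
    GuanEstimate,
    InvalidInputError,
    UnitSample,
    bernstein_basis,
    empirical_cdf,
    evaluate_guan,
    evaluate_vitale,
    fit_guan,
    fit_vitale,
)
from bernshrink.bernstein import guan_log_likelihood, _scaled_basis


@pytest.fixture
def abc_sample():
    return UnitSample(np.array([0.2, 0.5, 0.8]))


class TestEmpiricalCDF:
    @pytest.mark.parametrize("t,expected", [(0.0, 0.0), (1.0, 1.0), (0.5, 2 / 3)])
    def test_hand_values(self, abc_sample, t, expected):
        assert empirical_cdf(abc_sample, t) == pytest.approx(expected, abs=1e-15)

    def test_right_continuous_step(self, abc_sample):
        # jump exactly at an observation: F(x-) < F(x) = F(x+)
        assert empirical_cdf(abc_sample, 0.2 - 1e-12) == pytest.approx(0.0)
        assert empirical_cdf(abc_sample, 0.2) == pytest.approx(1 / 3)

    def test_monotone_on_random_sample(self, rng):
        s = UnitSample(rng.random(50))
        t = np.sort(rng.random(200))
        f = empirical_cdf(s, t)
        assert np.all(np.diff(f) >= 0)

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            UnitSample(np.array([]))


class TestBasis:
    def test_hand_values(self):
        assert bernstein_basis(7, 0, 0.0) == pytest.approx(1.0)
        assert bernstein_basis(2, 1, 0.5) == pytest.approx(0.5)

    @pytest.mark.parametrize("m", [0, 1, 5, 50, 300])
    def test_partition_of_unity(self, m, rng):
        x = rng.random(20)
        vals = bernstein_basis(m, np.arange(m + 1)[:, None], x[None, :])
        assert np.allclose(vals.sum(axis=0), 1.0, atol=1e-12)
        assert np.all(vals >= 0.0)

    def test_index_out_of_range(self):
        with pytest.raises(InvalidInputError):
            bernstein_basis(3, 4, 0.5)
        with pytest.raises(InvalidInputError):
            bernstein_basis(3, -1, 0.5)


class TestVitale:
    @pytest.mark.parametrize(
        "values,m,expected",
        [
            ([0.2, 0.5, 0.8], 2, [2 / 3, 1 / 3]),
            ([0.2, 0.5, 0.8], 1, [1.0]),
            ([0.1, 0.9], 2, [0.5, 0.5]),
        ],
    )
    def test_weights_are_cdf_increments(self, values, m, expected):
        est = fit_vitale(UnitSample(np.array(values)), m)
        assert est.weights == pytest.approx(expected, abs=1e-15)

    def test_endpoint_values(self, abc_sample):
        est = fit_vitale(abc_sample, 2)
        assert evaluate_vitale(est, 0.0) == pytest.approx(4 / 3)
        assert evaluate_vitale(est, 1.0) == pytest.approx(2 / 3)

    def test_matches_beta_mixture_oracle(self, rng):
        # f1(x) = sum_k w_k Beta(k+1, m-k)(x): independent closed form
        for m in (1, 3, 7, 20):
            est = fit_vitale(UnitSample(rng.random(30)), m)
            x = rng.random(40)
            oracle = sum(
                w * beta_dist(k + 1, m - k).pdf(x)
                for k, w in enumerate(est.weights)
            )
            assert evaluate_vitale(est, x) == pytest.approx(oracle, abs=1e-12)

    def test_density_normalized_and_nonnegative(self, rng):
        est = fit_vitale(UnitSample(rng.random(25)), 12)
        mass, _ = quad(lambda x: evaluate_vitale(est, x), 0, 1, limit=200)
        assert mass == pytest.approx(1.0, abs=1e-9)
        assert np.all(evaluate_vitale(est, np.linspace(0, 1, 101)) >= 0)

    def test_invalid_inputs(self, abc_sample):
        with pytest.raises(InvalidInputError):
            fit_vitale(abc_sample, 0)
        est = fit_vitale(abc_sample, 2)
        with pytest.raises(InvalidInputError):
            evaluate_vitale(est, 1.5)

    def test_mass_at_zero_warns_and_shrinks_weight_sum(self):
        with pytest.warns(UserWarning, match="exactly at 0"):
            s = UnitSample(np.array([0.0, 0.4, 0.8]))
        est = fit_vitale(s, 2)
        assert est.weights.sum() == pytest.approx(2 / 3)


class TestGuan:
    def test_symmetric_data_is_fixed_point(self):
        s = UnitSample(np.array([0.25, 0.75]))
        for iters in (1, 5, 50):
            est = fit_guan(s, 1, p0=np.array([0.5, 0.5]), max_iter=iters)
            assert est.p == pytest.approx([0.5, 0.5], abs=1e-14)

    def test_one_em_step_hand_computed(self):
        # B_10(0.25) = 1.5, B_11(0.25) = 0.5 -> p = (0.75, 0.25)
        est = fit_guan(
            UnitSample(np.array([0.25])), 1, p0=np.array([0.5, 0.5]), max_iter=1
        )
        assert est.p == pytest.approx([0.75, 0.25], abs=1e-14)

    def test_degree_zero_is_uniform(self, rng):
        est = fit_guan(UnitSample(rng.random(10)), 0)
        assert est.p == pytest.approx([1.0])
        assert evaluate_guan(est, 0.3) == pytest.approx(1.0)

    def test_log_likelihood_monotone(self, rng):
        s = UnitSample(rng.random(30))
        lls = [
            fit_guan(s, 5, max_iter=k, tol=0.0).log_likelihood
            for k in range(1, 12)
        ]
        assert np.all(np.diff(lls) >= -1e-10)

    def test_simplex_preserved_and_normalized(self, rng):
        s = UnitSample(rng.random(40))
        est = fit_guan(s, 8)
        assert np.all(est.p >= 0)
        assert est.p.sum() == pytest.approx(1.0, abs=1e-12)
        mass, _ = quad(lambda x: evaluate_guan(est, x), 0, 1, limit=200)
        assert mass == pytest.approx(1.0, abs=1e-9)

    def test_invalid_p0_rejected(self, abc_sample):
        with pytest.raises(InvalidInputError):
            fit_guan(abc_sample, 1, p0=np.array([0.9, 0.3]))
        with pytest.raises(InvalidInputError):
            GuanEstimate(m=1, p=np.array([0.5, 0.6]))

    def test_scaled_basis_rows_are_densities(self):
        # each B_mi integrates to 1; used by the EM update
        x = np.linspace(0, 1, 2001)
        B = _scaled_basis(4, x)
        assert np.trapezoid(B, x, axis=1) == pytest.approx(np.ones(5), abs=1e-5)

    def test_loglik_matches_direct_sum(self, rng):
        s = UnitSample(rng.random(12))
        est = fit_guan(s, 3)
        B = _scaled_basis(3, s.values)
        direct = float(np.sum(np.log(est.p @ B)))
        assert guan_log_likelihood(est.p, B) == pytest.approx(direct)
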