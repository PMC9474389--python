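"""Coxian phase-type construction, evaluation, moments, and sampling."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.stats import kstest

import phasetree as pt
from phasetree._matexp import expm_batch


def random_xyz(rng, size):
    xs = rng.uniform(0.05, 1.0, size)
    ys = rng.uniform(0.05, 0.95, size)
    zs = rng.uniform(2.0, 20.0, size)
    return zip(xs, ys, zs)


class TestBuildCoxian:
    def test_single_phase_is_unit_exponential(self):
        d = pt.build_coxian([1.0], [])
        assert d.Q == pytest.approx(np.array([[-1.0]]))
        assert d.q == pytest.approx(np.array([1.0]))

    def test_p_one_means_no_early_exit(self):
        d = pt.build_coxian([2.0, 1.0], [1.0])
        np.testing.assert_allclose(d.Q, [[-2.0, 2.0], [0.0, -1.0]])
        np.testing.assert_allclose(d.q, [0.0, 1.0])

    def test_partial_continuation(self):
        d = pt.build_coxian([2.0, 1.0], [0.5])
        np.testing.assert_allclose(d.q, [1.0, 1.0])
        assert d.Q[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(d.Q.sum(axis=1) + d.q, 0.0, atol=1e-14)

    @pytest.mark.parametrize(
        "lambdas,ps",
        [([-1.0], []), ([0.0], []), ([1.0, 1.0], [0.0]), ([1.0, 1.0], [1.5])],
    )
    def test_rejects_bad_parameters(self, lambdas, ps):
        with pytest.raises(ValueError):
            pt.build_coxian(lambdas, ps)


class TestExampleModels:
    def test_dec_exit_rates_strictly_decreasing(self):
        d = pt.ph_dec(0.1, 0.93, 10.0)
        expected = [9.3, 0.93**2 * 1.1, 0.93**3 * 1.01, 0.001]
        np.testing.assert_allclose(d.q, expected)
        assert np.all(np.diff(d.q) < 0)

    def test_inc_exit_rates_strictly_increasing(self):
        d = pt.ph_inc(1.0, 0.5, 2.0)
        np.testing.assert_allclose(d.q, [0.125, 0.25, 0.5, 2.0])
        assert np.all(np.diff(d.q) > 0)
        assert d.q[-1] == pytest.approx(2.0)  # last exit rate is z

    @pytest.mark.parametrize("build", [pt.ph_dec, pt.ph_inc])
    def test_generator_identity(self, build, rng):
        for x, y, z in random_xyz(rng, 20):
            d = build(x, y, z)
            np.testing.assert_allclose(d.Q.sum(axis=1) + d.q, 0.0, atol=1e-12)

    @pytest.mark.parametrize(
        "build,kwargs",
        [
            (pt.ph_dec, dict(x=1.5, y=0.5, z=10)),
            (pt.ph_dec, dict(x=0.5, y=1.0, z=10)),
            (pt.ph_inc, dict(x=0.5, y=0.5, z=1.0)),
        ],
    )
    def test_rejects_out_of_range(self, build, kwargs):
        with pytest.raises(ValueError):
            build(**kwargs)


class TestDistributionFunctions:
    def test_single_phase_matches_exponential(self):
        d = pt.build_coxian([2.0], [])
        t = np.linspace(0, 3, 31)
        np.testing.assert_allclose(d.pdf(t), 2.0 * np.exp(-2.0 * t), rtol=1e-10)
        np.testing.assert_allclose(d.cdf(t), 1.0 - np.exp(-2.0 * t), rtol=1e-10)
        unit = pt.build_coxian([1.0], [])
        assert unit.cdf(1.0) == pytest.approx(1.0 - np.exp(-1.0))

    def test_pdf_integrates_to_one(self):
        d = pt.ph_dec(0.3, 0.78, 10.0)
        total, err = quad(d.pdf, 0, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_pdf_at_zero_is_first_exit_rate(self):
        d = pt.ph_dec(0.1, 0.93, 10.0)
        assert d.pdf(0.0) == pytest.approx(d.alpha @ d.q)

    def test_cdf_monotone_and_derivative_matches_pdf(self):
        d = pt.ph_inc(0.4, 0.6, 3.0)
        t = np.linspace(0.05, 5.0, 60)
        c = d.cdf(t)
        assert np.all(np.diff(c) > 0)
        assert d.cdf(0.0) == 0.0
        h = 1e-5
        deriv = (d.cdf(t + h) - d.cdf(t - h)) / (2 * h)
        np.testing.assert_allclose(deriv, d.pdf(t), atol=1e-5)

    def test_negative_time_rejected(self):
        d = pt.build_coxian([1.0], [])
        for fn in (d.pdf, d.cdf):
            with pytest.raises(ValueError):
                fn(-0.1)


class TestMoments:
    def test_single_phase(self):
        d = pt.build_coxian([4.0], [])
        assert d.mean() == pytest.approx(0.25)
        assert d.variance() == pytest.approx(0.0625)
        assert d.cv() == pytest.approx(1.0)

    def test_dec_mean_closed_form_value(self):
        m1, m2 = pt.moments_dec(0.1, 0.93, 10.0)
        assert m1 == pytest.approx(2.0232, abs=1e-4)
        assert m2 == pytest.approx(3708.0, rel=1e-4)
        assert m2 >= m1**2

    @pytest.mark.parametrize(
        "build,moments", [(pt.ph_dec, pt.moments_dec), (pt.ph_inc, pt.moments_inc)]
    )
    def test_matrix_formulas_agree_with_closed_forms(self, build, moments, rng):
        for x, y, z in random_xyz(rng, 100):
            d = build(x, y, z)
            m1, m2 = moments(x, y, z)
            assert d.mean() == pytest.approx(m1, rel=1e-8)
            assert d.variance() == pytest.approx(m2 - m1**2, rel=1e-8)

    def test_dec_mean_limit_near_y_one(self):
        # as y -> 1 the first phase exits almost surely: mean -> 1/z from above
        m1, _ = pt.moments_dec(0.5, 0.999999, 10.0)
        assert 0.1 < m1 < 0.1001

    def test_inc_mean_limit(self):
        m1, _ = pt.moments_inc(1.0, 0.999999, 5.0)
        assert m1 == pytest.approx(0.5, abs=1e-4)


class TestCV:
    @pytest.mark.parametrize(
        "x,y,expected",
        [(0.1, 0.93, 30.08), (0.17, 0.88, 13.50), (0.3, 0.78, 5.56), (0.68, 0.45, 1.49)],
    )
    def test_reference_parameterizations(self, x, y, expected):
        assert pt.ph_dec(x, y, 10.0).cv() == pytest.approx(expected, abs=5e-3)

    def test_scale_invariance(self, rng):
        d = pt.ph_dec(0.3, 0.78, 10.0)
        for c in rng.uniform(0.1, 50.0, 10):
            scaled = pt.CoxianPH(alpha=d.alpha, Q=c * d.Q, q=c * d.q)
            assert scaled.cv() == pytest.approx(d.cv(), rel=1e-10)


class TestHazard:
    def test_single_phase_constant(self):
        d = pt.build_coxian([3.0], [])
        t = np.linspace(0, 5, 11)
        np.testing.assert_allclose(d.hazard(t), 3.0, rtol=1e-8)

    def test_decreasing_model_has_nonincreasing_hazard(self):
        d = pt.ph_dec(0.3, 0.78, 10.0)
        h = d.hazard(np.linspace(0, 8, 400))
        assert np.all(np.diff(h) <= 1e-10)

    def test_at_zero_equals_first_exit_rate(self):
        d = pt.ph_inc(0.5, 0.5, 4.0)
        assert d.hazard(0.0) == pytest.approx(d.alpha @ d.q)

    def test_saturation_reported_as_nan(self):
        d = pt.build_coxian([5.0], [])
        assert np.isnan(d.hazard(1e4))


class TestSampling:
    def test_single_phase_mean(self, rng):
        x = pt.build_coxian([1.0], []).sample(rng, 100_000)
        se = x.std() / np.sqrt(x.size)
        assert abs(x.mean() - 1.0) < 3 * se

    def test_dec_sample_mean_matches_closed_form(self, rng):
        d = pt.ph_dec(0.1, 0.93, 10.0)
        x = d.sample(rng, 100_000)
        m1, _ = pt.moments_dec(0.1, 0.93, 10.0)
        se = x.std() / np.sqrt(x.size)
        assert abs(x.mean() - m1) < 3 * se

    def test_empirical_cdf_close_to_analytic(self, rng):
        d = pt.ph_dec(0.68, 0.45, 10.0)
        x = d.sample(rng, 100_000)
        stat = kstest(x, d.cdf).statistic
        assert stat < 0.01


class TestBatchedExponential:
    def test_matches_scipy_on_subgenerators(self, rng):
        d = pt.ph_dec(0.17, 0.88, 10.0)
        ts = rng.uniform(0.0, 20.0, 50)
        batch = expm_batch(d.Q[None, :, :] * ts[:, None, None])
        for t, E in zip(ts, batch):
            np.testing.assert_allclose(E, expm(d.Q * t), atol=1e-12)

    def test_matches_scipy_on_random_matrices(self, rng):
        A = rng.normal(scale=2.0, size=(20, 5, 5))
        batch = expm_batch(A)
        for Ai, Ei in zip(A, batch):
            np.testing.assert_allclose(Ei, expm(Ai), rtol=1e-9, atol=1e-9)
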