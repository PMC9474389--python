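"""Tree likelihoods: phase-type, exponential, Weibull, birth-death."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import phasetree as pt


def unit_exp():
    return pt.build_coxian([1.0], [])


def random_branchdata(rng, k=5, l=6):
    return pt.BranchData(
        internal=rng.uniform(0.1, 2.0, k),
        pendant=rng.uniform(0.1, 2.0, l),
        x=rng.uniform(0.0, 1.0, k),
        age=3.0,
        x2=2.5,
    )


class TestLoglikPH:
    def test_unit_rate_toy_tree(self, toy_branchdata):
        # density e^-1 on the internal branch, survival e^-1 on each pendant
        assert pt.loglik_ph(toy_branchdata, unit_exp()) == pytest.approx(-3.0)
        assert pt.loglik_ph(
            toy_branchdata, unit_exp(), with_permutations=True
        ) == pytest.approx(-3.0)  # log(1!) = 0

    def test_single_phase_equals_exponential(self, rng):
        bd = random_branchdata(rng)
        for rate in (0.3, 1.0, 4.2):
            d = pt.build_coxian([rate], [])
            assert pt.loglik_ph(bd, d) == pytest.approx(
                pt.loglik_exp(bd, rate), rel=1e-10
            )

    def test_underflowing_branch_gives_minus_inf(self):
        bd = pt.BranchData(
            internal=np.array([1e6]),
            pendant=np.array([1.0]),
            x=np.array([0.0]),
            age=1e6,
            x2=1e6,
        )
        assert pt.loglik_ph(bd, unit_exp()) == -np.inf

    def test_treeset_sums_and_is_order_invariant(self, rng):
        bds = [random_branchdata(rng) for _ in range(3)]
        d = pt.ph_dec(0.3, 0.78, 10.0)
        total = pt.loglik_treeset(bds, d)
        assert total == pytest.approx(sum(pt.loglik_ph(b, d) for b in bds))
        assert total == pytest.approx(pt.loglik_treeset(bds[::-1], d))
        assert pt.loglik_treeset(bds[:1], d) == pytest.approx(
            pt.loglik_ph(bds[0], d)
        )


class TestLoglikExp:
    def test_hand_values(self, toy_branchdata):
        assert pt.loglik_exp(toy_branchdata, 1.0) == pytest.approx(-3.0)
        assert pt.loglik_exp(toy_branchdata, 2.0) == pytest.approx(
            math.log(2.0) - 6.0
        )

    def test_closed_form_mle_maximizes(self, rng):
        bd = random_branchdata(rng)
        mle = bd.k / (bd.internal.sum() + bd.pendant.sum())
        best = pt.loglik_exp(bd, mle)
        for rate in np.linspace(0.1, 5.0, 200):
            assert pt.loglik_exp(bd, rate) <= best + 1e-12

    def test_rejects_nonpositive_rate(self, toy_branchdata):
        with pytest.raises(ValueError):
            pt.loglik_exp(toy_branchdata, 0.0)


class TestLoglikWeibull:
    def test_shape_one_is_exponential(self, rng):
        bd = random_branchdata(rng)
        for phi in (0.5, 1.0, 3.0):
            assert pt.loglik_weibull(bd, 1.0, phi) == pytest.approx(
                pt.loglik_exp(bd, 1.0 / phi), rel=1e-12
            )

    def test_term_by_term_hand_evaluation(self, toy_branchdata):
        # psi=2, phi=1: internal density log(2 b) - b^2, pendant survival -b~^2
        expected = (math.log(2.0) - 1.0) + (-1.0) + (-1.0)
        assert pt.loglik_weibull(toy_branchdata, 2.0, 1.0) == pytest.approx(
            expected
        )

    def test_branch_order_invariance(self, rng):
        bd = random_branchdata(rng)
        shuffled = pt.BranchData(
            internal=bd.internal[::-1].copy(),
            pendant=bd.pendant[::-1].copy(),
            x=bd.x[::-1].copy(),
            age=bd.age,
            x2=bd.x2,
        )
        assert pt.loglik_weibull(bd, 1.7, 0.8) == pytest.approx(
            pt.loglik_weibull(shuffled, 1.7, 0.8)
        )

    def test_rejects_nonpositive_params(self, toy_branchdata):
        with pytest.raises(ValueError):
            pt.loglik_weibull(toy_branchdata, -1.0, 1.0)


class TestExtinctProb:
    def test_zero_death_rate(self):
        assert pt.extinct_prob(5.0, 1.0, 0.0) == 0.0

    def test_long_time_limit_is_mu_over_lam(self):
        assert pt.extinct_prob(200.0, 1.0, 0.5) == pytest.approx(0.5, abs=1e-9)

    def test_critical_case_limit(self):
        # lam = mu uses lam z / (1 + lam z); continuous with nearby rates
        assert pt.extinct_prob(1.0, 1.0, 1.0) == pytest.approx(0.5)
        for mu in (1.0 - 1e-7, 1.0 + 1e-7):
            assert pt.extinct_prob(1.0, 1.0, mu) == pytest.approx(0.5, abs=1e-6)

    def test_monotone_in_z(self):
        z = np.linspace(0.0, 10.0, 100)
        e = pt.extinct_prob(z, 1.0, 0.7)
        assert e[0] == 0.0 and np.all(np.diff(e) > 0) and e[-1] < 1.0


def ode_oracle_g(b, x, lam, mu):
    # dG/dz = -(lam+mu) G + 2 lam G E(z + x), G(0) = 1
    sol = solve_ivp(
        lambda z, G: -(lam + mu) * G + 2 * lam * G * pt.extinct_prob(z + x, lam, mu),
        (0.0, b), [1.0], rtol=1e-10, atol=1e-12, dense_output=True,
    )
    return float(sol.y[0, -1])


def ode_oracle_d(z_end, lam, mu):
    # dD/dz = -(lam+mu) D + 2 lam E(z) D, D(0) = 1
    sol = solve_ivp(
        lambda z, D: -(lam + mu) * D + 2 * lam * pt.extinct_prob(z, lam, mu) * D,
        (0.0, z_end), [1.0], rtol=1e-10, atol=1e-12,
    )
    return float(sol.y[0, -1])


class TestBirthDeathFactors:
    def test_g_pure_birth_is_exponential_survival(self):
        b = np.linspace(0.0, 4.0, 20)
        np.testing.assert_allclose(
            pt.g_branch(b, 1.3, 2.0, 0.0), np.exp(-2.0 * b), rtol=1e-12
        )

    def test_g_at_zero_is_one(self):
        assert pt.g_branch(0.0, 0.7, 1.0, 0.5) == 1.0

    def test_g_matches_ode_integration(self):
        assert pt.g_branch(1.0, 1.0, 1.0, 0.5) == pytest.approx(
            ode_oracle_g(1.0, 1.0, 1.0, 0.5), rel=1e-8
        )

    def test_d_pure_birth(self):
        assert pt.d_pendant(1.0, 1.0, 0.0) == pytest.approx(math.exp(-1.0))

    def test_d_at_zero_is_one(self):
        for lam, mu in [(1.0, 0.5), (2.0, 1.9), (0.3, 0.0)]:
            assert pt.d_pendant(0.0, lam, mu) == 1.0

    def test_d_matches_ode_integration(self):
        assert pt.d_pendant(2.0, 1.0, 0.5) == pytest.approx(
            ode_oracle_d(2.0, 1.0, 0.5), rel=1e-8
        )

    @pytest.mark.parametrize("lam,mu", [(1.0, 0.5), (2.0, 1.9), (1.0, 0.0)])
    def test_closed_forms_satisfy_their_odes(self, lam, mu):
        z = np.linspace(0.01, 5.0, 200)
        h = 1e-5
        x = 0.8
        G = pt.g_branch(z, x, lam, mu)
        dG = (pt.g_branch(z + h, x, lam, mu) - pt.g_branch(z - h, x, lam, mu)) / (2 * h)
        rhs = -(lam + mu) * G + 2 * lam * G * pt.extinct_prob(z + x, lam, mu)
        assert np.abs(dG - rhs).max() < 1e-6
        D = pt.d_pendant(z, lam, mu)
        dD = (pt.d_pendant(z + h, lam, mu) - pt.d_pendant(z - h, lam, mu)) / (2 * h)
        rhsD = -(lam + mu) * D + 2 * lam * pt.extinct_prob(z, lam, mu) * D
        assert np.abs(dD - rhsD).max() < 1e-6


class TestLoglikCrbd:
    def test_pure_birth_equals_permuted_exponential_likelihood(self, rng):
        bd = random_branchdata(rng)
        lam = 1.3
        expected = pt.loglik_ph(
            bd, pt.build_coxian([lam], []), with_permutations=True
        )
        assert pt.loglik_crbd(bd, lam, 0.0) == pytest.approx(expected, rel=1e-10)

    def test_three_tip_hand_assembly(self):
        bd = pt.BranchData(
            internal=np.array([0.5, 0.3]),
            pendant=np.array([0.4, 0.7, 1.0]),
            x=np.array([1.0, 0.7]),
            age=1.5,
            x2=1.0,
        )
        lam, mu = 1.0, 0.5
        expected = math.lgamma(3)  # log(2!)
        for b, x in zip(bd.internal, bd.x):
            expected += math.log(pt.g_branch(b, x, lam, mu)) + math.log(lam)
        for b in bd.pendant:
            expected += math.log(pt.d_pendant(b, lam, mu))
        assert pt.loglik_crbd(bd, lam, mu) == pytest.approx(expected, rel=1e-12)

    def test_diverges_as_lam_to_zero(self, rng):
        bd = random_branchdata(rng)
        vals = [pt.loglik_crbd(bd, lam, 0.1) for lam in (1.0, 0.1, 0.01, 0.001)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_missing_x_rejected(self):
        bd = pt.BranchData(
            internal=np.array([1.0, 2.0]),
            pendant=np.array([1.0]),
            x=np.array([0.5]),
            age=2.0,
            x2=1.0,
        )
        with pytest.raises(ValueError):
            pt.loglik_crbd(bd, 1.0, 0.5)


class TestLoglikNee:
    def test_pure_birth_equals_unconditioned(self, rng):
        bd = random_branchdata(rng)
        assert pt.loglik_nee(bd, 1.0, 0.0) == pytest.approx(
            pt.loglik_crbd(bd, 1.0, 0.0)
        )

    def test_conditioning_raises_likelihood(self, rng):
        bd = random_branchdata(rng)
        assert pt.loglik_nee(bd, 1.0, 0.6) > pt.loglik_crbd(bd, 1.0, 0.6)

    def test_difference_is_root_survival_term(self, rng):
        bd = random_branchdata(rng)
        lam, mu = 1.0, 0.5
        diff = pt.loglik_nee(bd, lam, mu) - pt.loglik_crbd(bd, lam, mu)
        e2 = pt.extinct_prob(bd.x2, lam, mu)
        assert diff == pytest.approx(-2.0 * math.log(1.0 - e2), rel=1e-12)
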