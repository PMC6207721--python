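"""Analytic solver: steady states, cell-cycle law, covariance, decomposition."""

import math

import numpy as np
import pytest

from redivsys.core import ConfigurationError
from redivsys import sna
from redivsys.sna import (
    birth_state,
    decompose_noise,
    division_noise,
    growth_rate_cv,
    projected_stoichiometries,
    steady_state_mean,
    stationary_covariance,
    to_bulk,
    solve,
    parameter_sensitivity,
)
from .conftest import make_toy, toy_steady_state, random_network, random_simplex_state

LN2 = math.log(2.0)


class TestSteadyState:
    @pytest.mark.parametrize("w,d,k", [(1.0, 1.0, 1.0), (0.4, 0.9, 2.2), (3.0, 0.2, 0.7)])
    def test_toy_matches_closed_form(self, w, d, k):
        net = make_toy(w, d, k)
        Xbar, lam = steady_state_mean(net)
        X_exact, lam_exact = toy_steady_state(w, d, k)
        assert np.allclose(Xbar, X_exact, rtol=1e-10)
        assert lam == pytest.approx(lam_exact, rel=1e-10)

    def test_golden_ratio_special_case(self):
        Xbar, _ = steady_state_mean(make_toy(1, 1, 1))
        assert Xbar[0] == pytest.approx((math.sqrt(5) - 1) / 2, rel=1e-12)

    def test_solution_lies_on_simplex(self, full_net, full_steady_state):
        Xbar, _ = full_steady_state
        assert abs(float(full_net.mass @ Xbar) - 1.0) < 1e-12


class TestBirthState:
    def test_one_doubling_of_cd_period(self):
        M0, O0, unit = birth_state(LN2, 1.0, 1.0)  # lambda * tau = ln 2
        assert M0 == pytest.approx(1.0)
        assert O0 == pytest.approx(1 / LN2)

    def test_zero_cd_period(self):
        M0, _, _ = birth_state(0.02, O_c=2e-9, tau_CD=0.0)
        assert M0 == pytest.approx(1.0 / (2 * 2e-9))

    def test_unit_size_independent_of_growth_rate(self):
        for lam in np.linspace(1e-3, 0.05, 7):
            M0, O0, unit = birth_state(lam, 3e-9, 55.0)
            assert M0 / O0 == pytest.approx(LN2 / 3e-9, rel=1e-14)
            assert unit == pytest.approx(LN2 / 3e-9, rel=1e-14)

    def test_overflow_guard(self):
        with pytest.raises(OverflowError):
            birth_state(10.0, 1e-9, 1e4)


class TestCovariance:
    def test_lyapunov_residual_small(self, full_net, full_steady_state, default_params):
        Xbar, lam = full_steady_state
        M0, _, _ = birth_state(lam, default_params.O_c, default_params.tau_CD)
        Sigma, J, noise = stationary_covariance(full_net, Xbar, M0, lam)
        Q = sum(noise.values())
        resid = np.max(np.abs(J @ Sigma + Sigma @ J.T + Q))
        assert resid <= 1e-8 * np.max(np.abs(Q))

    def test_doubling_birth_mass_halves_covariance(self):
        net = make_toy()
        Xbar, lam = steady_state_mean(net)
        S1, _, _ = stationary_covariance(net, Xbar, 1e4, lam)
        S2, _, _ = stationary_covariance(net, Xbar, 2e4, lam)
        assert np.allclose(S2, 0.5 * S1, rtol=1e-12, atol=1e-300)

    def test_covariance_positive_semidefinite_and_massless(self, full_net, full_steady_state, default_params):
        Xbar, lam = full_steady_state
        M0, _, _ = birth_state(lam, default_params.O_c, default_params.tau_CD)
        Sigma, _, _ = stationary_covariance(full_net, Xbar, M0, lam)
        ev = np.linalg.eigvalsh(Sigma)
        assert ev.min() >= -1e-12 * np.trace(Sigma)
        m = full_net.mass
        assert abs(float(m @ Sigma @ m)) <= 1e-10 * np.trace(Sigma) * float(m @ m)

    def test_noise_terms_orthogonal_to_mass(self):
        """Gamma m = 0 and nu_tilde_r^T m = 0: partitioning and reaction
        noise cannot move the conserved mass direction."""
        rng = np.random.default_rng(123)
        for _ in range(20):
            net = random_network(rng)
            X = random_simplex_state(rng, net)
            G = division_noise(net, X)
            gm = G @ net.mass
            assert np.max(np.abs(gm)) <= 1e-13 * max(np.max(np.abs(G)) * np.max(net.mass), 1e-30)
            nut = projected_stoichiometries(net, X)
            proj = net.mass @ nut
            assert np.max(np.abs(proj)) <= 1e-12 * max(np.max(np.abs(net.nu)) * np.max(net.mass), 1e-30)

    def test_unstable_state_rejected(self):
        # reversed-sign dynamics: x grows away from the "fixed point"
        net = make_toy()
        Xbar, lam = steady_state_mean(net)
        import redivsys.sna as S

        J = net.drift_jacobian(Xbar)
        B = S._reduced_basis(net.mass)
        with pytest.raises(S.SteadyStateError, match="unstable"):
            S._solve_lyapunov_reduced(-J, np.eye(net.N), B)


class TestGrowthRateCV:
    def test_zero_covariance_gives_zero(self, full_net, full_steady_state):
        Xbar, _ = full_steady_state
        cv2, cv = growth_rate_cv(full_net, Xbar, np.zeros((full_net.N, full_net.N)))
        assert cv2 == 0.0 and cv == 0.0

    def test_single_species_unit_log_sensitivity(self):
        """lambda = k X1 has unit log-sensitivity to X1, so
        CV^2[lambda] = Sigma_11 / X1^2."""
        net = make_toy()
        Xbar, lam = steady_state_mean(net)
        Sigma, _, _ = stationary_covariance(net, Xbar, 1e4, lam)
        cv2, _ = growth_rate_cv(net, Xbar, Sigma)
        assert cv2 == pytest.approx(Sigma[0, 0] / Xbar[0] ** 2, rel=1e-6)

    def test_growth_noise_decreases_with_mean_growth(self, default_params):
        """Fast-growing cells fluctuate less: CV[lambda] falls along the
        nutrient-quality curve."""
        df = sna.solve_curve(default_params, [0.3, 0.8, 2.0, 5.0, 12.0])
        cv = df["cv_lambda"].to_numpy()
        lam = df["lambdabar"].to_numpy()
        assert (np.diff(lam) > 0).all()
        assert (np.diff(cv) < 0).all()


class TestDecomposition:
    def test_contributions_sum_to_total(self, full_net, full_steady_state, default_params):
        Xbar, lam = full_steady_state
        M0, _, _ = birth_state(lam, default_params.O_c, default_params.tau_CD)
        table = decompose_noise(full_net, Xbar, M0)
        total = table["cv2_contribution"].sum()
        assert total == pytest.approx(table.attrs["cv2_lambda"], rel=1e-10)

    def test_zero_rate_group_contributes_nothing(self):
        net = make_toy(w=1.0, d=0.0, k=1.0)  # degradation switched off
        Xbar, lam = steady_state_mean(net)
        grouping = {"deg": [1], "rest": [0, 2, "division"]}
        table = decompose_noise(net, Xbar, 1e4, grouping=grouping)
        assert table.loc["deg", "cv2_contribution"] == pytest.approx(0.0, abs=1e-30)
        assert table.loc["rest", "fraction"] == pytest.approx(1.0, rel=1e-12)

    def test_incomplete_grouping_rejected(self, full_net, full_steady_state):
        Xbar, _ = full_steady_state
        with pytest.raises(ConfigurationError, match="partition"):
            decompose_noise(full_net, Xbar, 1e9, grouping={"some": [0, 1]})


class TestParameterSensitivity:
    def test_inactive_drug_parameter_has_zero_elasticity(self, default_params):
        table = parameter_sensitivity(default_params, parameters=["k_cm"])
        assert table.loc["k_cm", "elasticity_lambdabar"] == pytest.approx(0.0, abs=1e-6)
        assert not table.loc["k_cm", "failed"]

    def test_cv2_scales_inversely_with_birth_mass(self, full_net, full_steady_state):
        """The noise prefactor 1/(2 M0 ln 2) makes CV^2 exactly inverse in M0."""
        Xbar, lam = full_steady_state
        S1, _, _ = stationary_covariance(full_net, Xbar, 1e9, lam)
        S2, _, _ = stationary_covariance(full_net, Xbar, 2e9, lam)
        cv2_1, _ = growth_rate_cv(full_net, Xbar, S1)
        cv2_2, _ = growth_rate_cv(full_net, Xbar, S2)
        assert cv2_2 == pytest.approx(0.5 * cv2_1, rel=1e-10)

    def test_stronger_q_feedback_boosts_growth_and_damps_noise(self, default_params):
        """Weakening autoregulation (larger K_q) slows slow-condition growth
        and amplifies its fluctuations."""
        p = default_params.replace(n_s=0.8)  # slow conditions
        table = parameter_sensitivity(p, parameters=["K_q"])
        assert table.loc["K_q", "elasticity_lambdabar"] < 0
        assert table.loc["K_q", "elasticity_cv_lambda"] > 0


class TestBulk:
    def test_bulk_mass_relation(self):
        net = make_toy()
        res = solve(net, O_c=5e-5, tau_CD=0.0, M0=1.0)
        assert res.M_bulk == pytest.approx(2 * LN2)

    def test_ribosome_fraction_is_a_mass_fraction(self, default_params):
        df = sna.solve_curve(default_params, [0.5, 5.0])
        assert ((df["phi_r"] > 0) & (df["phi_r"] < 1)).all()

    def test_bulk_observables_dict(self, full_net, default_params):
        res = solve(full_net, O_c=default_params.O_c, tau_CD=default_params.tau_CD)
        bulk = to_bulk(res)
        assert bulk["M_bulk"] == pytest.approx(2 * res.M0 * LN2)
        assert 0 < bulk["phi_r"] < 1
        assert bulk["copy_numbers"]["p_r"] > 0
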