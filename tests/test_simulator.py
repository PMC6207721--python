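"""Hybrid lineage simulator: partitioning, replication control, dynamics."""

import math

import numpy as np
import pytest

from redivsys.core import CellState, ConfigurationError, PartitionRule
from redivsys.simulate import (
    SimulatorConfig,
    default_stochastic_species,
    partition_state,
    schedule_replication,
    simulate_lineage,
    simulate_lineages,
)
from redivsys import sna
from .conftest import make_toy

LN2 = math.log(2.0)


class TestPartitionState:
    def test_binomial_moments(self):
        rng = np.random.default_rng(5)
        x = np.array([400.0])
        rho = 0.37
        draws = np.array([partition_state(x, rho, rng=rng)[0] for _ in range(10_000)])
        mu, var = rho * 400, rho * (1 - rho) * 400
        assert abs(draws.mean() - mu) < 3 * math.sqrt(var / 10_000)
        assert abs(draws.var() - var) < 0.05 * var

    def test_gaussian_branch_moments_and_truncation(self):
        rng = np.random.default_rng(6)
        x = np.array([1e6])
        mask = np.array([False])
        draws = np.array([
            partition_state(x, 0.5, stochastic_mask=mask, rng=rng)[0]
            for _ in range(4000)
        ])
        assert abs(draws.mean() - 5e5) < 3 * math.sqrt(0.25 * 1e6 / 4000)
        assert draws.min() >= 0 and draws.max() <= 1e6

    def test_deterministic_half_is_exact(self):
        rule = PartitionRule(scheme="deterministic-half")
        x = np.array([10.0, 7.0, 0.0])
        assert np.array_equal(partition_state(x, 0.5, rule), x / 2)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ConfigurationError):
            partition_state(np.array([4.0]), 1.2)


class TestScheduleReplication:
    def test_initiation_doubles_origins_and_schedules_division(self):
        state = CellState(x=np.array([10.0]), M=10.0, O=1, t=5.0)
        schedule_replication(state, O_c=0.1, tau_CD=30.0)  # M * O_c = 1 >= O
        assert state.O == 2
        assert state.pending_divisions == [35.0]

    def test_no_initiation_below_threshold(self):
        state = CellState(x=np.array([5.0]), M=5.0, O=1, t=0.0)
        schedule_replication(state, O_c=0.1, tau_CD=30.0)
        assert state.O == 1 and state.pending_divisions == []

    def test_overlapping_rounds_at_fast_growth(self, full_net, default_params):
        """With lambda * tau_CD > ln 2 the queue holds several divisions."""
        Xbar, lam = sna.steady_state_mean(full_net)
        assert lam * default_params.tau_CD > LN2
        cfg = SimulatorConfig(deterministic=True, n_divisions=15, seed=0)
        traj = simulate_lineage(full_net, cfg, X0=Xbar)
        # several rounds in flight: origin count reaches >= 4
        assert traj.O.max() >= 4


class TestDeterministicMode:
    def test_cycle_matches_analytic_birth_law(self, full_net, default_params, full_steady_state):
        Xbar, lam = full_steady_state
        M0, _, _ = sna.birth_state(lam, default_params.O_c, default_params.tau_CD)
        cfg = SimulatorConfig(deterministic=True, n_divisions=16, seed=0)
        traj = simulate_lineage(full_net, cfg, X0=Xbar)
        cyc = traj.cycles()
        tail = cyc[cyc["index"] > 8]
        assert tail["doubling_time"].iloc[-1] == pytest.approx(LN2 / lam, rel=1e-3)
        assert tail["birth_mass"].iloc[-1] == pytest.approx(M0, rel=5e-2)

    def test_concentrations_remain_at_steady_state(self, full_net, full_steady_state):
        """Without noise the lineage sits exactly on the analytic means."""
        Xbar, lam = full_steady_state
        cfg = SimulatorConfig(deterministic=True, n_divisions=14, seed=0)
        traj = simulate_lineage(full_net, cfg, X0=Xbar)
        keep = traj.post_burnin
        for i, name in enumerate(full_net.species_names):
            assert np.allclose(traj.X[keep, i], Xbar[i], rtol=1e-5), name

    def test_mass_bookkeeping_exact(self, full_net, full_steady_state):
        Xbar, _ = full_steady_state
        cfg = SimulatorConfig(deterministic=True, n_divisions=12, seed=0)
        traj = simulate_lineage(full_net, cfg, X0=Xbar)
        assert np.max(np.abs(traj.X @ full_net.mass - 1.0)) < 1e-6


@pytest.fixture(scope="module")
def toy_run():
    net = make_toy(0.0693, 0.0693, 0.0693)
    Xbar, lam = sna.steady_state_mean(net)
    M0 = 1e4
    cfg = SimulatorConfig(stochastic_species=["x1", "x2"], n_divisions=60,
                          seed=21, dt_max=0.05)
    traj = simulate_lineage(net, cfg, O_c=1.0 / (2 * M0), tau_CD=0.0, X0=Xbar)
    return net, Xbar, lam, M0, traj


class TestStochasticMode:
    def test_growth_noise_close_to_analytic(self, toy_run):
        net, Xbar, lam, M0, traj = toy_run
        Sigma, _, _ = sna.stationary_covariance(net, Xbar, M0, lam)
        _, cv = sna.growth_rate_cv(net, Xbar, Sigma)
        keep = traj.post_burnin
        lam_t = traj.lam[keep]
        cv_sim = lam_t.std() / lam_t.mean()
        assert cv_sim == pytest.approx(cv, rel=0.35)  # single lineage, loose

    def test_division_rate_matches_growth(self, toy_run):
        net, Xbar, lam, M0, traj = toy_run
        div = traj.divisions
        rate = (len(div) - 1) / (div["t"].iloc[-1] - div["t"].iloc[0])
        # division frequency lambda / ln 2 per unit time
        assert rate == pytest.approx(lam / LN2, rel=0.1)

    def test_daughter_counts_never_exceed_mother(self, toy_run):
        _, _, _, _, traj = toy_run
        assert (traj.divisions["M_after"] <= traj.divisions["M_before"]).all()

    def test_mass_increases_between_divisions(self, toy_run):
        _, _, _, _, traj = toy_run
        # between consecutive samples without a division, M must not fall
        dM = np.diff(traj.M)
        same_cycle = np.diff(traj.D) == 0
        assert (dM[same_cycle] > -1e-9 * traj.M[:-1][same_cycle]).all()

    def test_seed_reproducibility(self, full_net, full_steady_state):
        Xbar, _ = full_steady_state
        cfg = SimulatorConfig(n_divisions=3, seed=9, burn_in=0)
        t1 = simulate_lineage(full_net, cfg, X0=Xbar)
        t2 = simulate_lineage(full_net, cfg, X0=Xbar)
        assert np.array_equal(t1.X, t2.X)
        t3 = simulate_lineage(full_net, SimulatorConfig(n_divisions=3, seed=10, burn_in=0),
                              X0=Xbar)
        assert not np.array_equal(t1.X, t3.X)

    def test_default_stochastic_species(self, full_net):
        assert default_stochastic_species(full_net) == ["m_t", "m_e", "c_t", "c_e"]

    def test_lineage_seeds_differ(self, full_net, full_steady_state):
        Xbar, _ = full_steady_state
        cfg = SimulatorConfig(n_divisions=2, seed=4, burn_in=0)
        trajs = list(simulate_lineages(full_net, 2, cfg, X0=Xbar))
        assert not np.array_equal(trajs[0].X[:100], trajs[1].X[:100])
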