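"""Trajectory statistics, cross-correlations and the minimal-delay graph."""

import math

import numpy as np
import pandas as pd
import pytest

from redivsys.core import ConfigurationError
from redivsys.lineage import (
    cross_correlation,
    extremal_delay,
    lineage_moments,
    minimal_delay_graph,
    rescaled_distribution,
)
from redivsys.simulate import SimulatorConfig, simulate_lineage, Trajectory
from redivsys import sna
from .conftest import make_toy


def _make_table(entries):
    """entries: {(A, B): (lag, r)}; antisymmetric closure is applied."""
    rows = []
    for (A, B), (lag, r) in entries.items():
        rows.append({"A": A, "B": B, "lag": lag, "r": r})
        rows.append({"A": B, "B": A, "lag": -lag, "r": r})
    return pd.DataFrame(rows).set_index(["A", "B"])


class TestCrossCorrelation:
    def test_self_correlation_peaks_at_zero(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(2000)
        lags, r = cross_correlation(a, a, max_lag=10, dt=1.0)
        i0 = np.argmin(np.abs(lags))
        assert r[i0] == pytest.approx(1.0, rel=1e-12)

    def test_pure_shift_recovered(self):
        rng = np.random.default_rng(1)
        base = np.convolve(rng.standard_normal(4300), np.ones(30) / 30, "valid")
        d = 17
        a, b = base[:-d], base[d:]  # b(t) = a(t + d): b LEADS... a leads b by d
        lags, r = cross_correlation(a, b, max_lag=40, dt=1.0)
        ext = extremal_delay(lags, r)
        assert ext["lag"] == pytest.approx(-d)  # B ahead of A: negative lag
        lags, r = cross_correlation(b, a, max_lag=40, dt=1.0)
        assert extremal_delay(lags, r)["lag"] == pytest.approx(d)

    def test_independent_noise_stays_below_null_bound(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(10_000), rng.standard_normal(10_000)
        _, r = cross_correlation(a, b, max_lag=50, dt=1.0)
        assert np.max(np.abs(r)) < 4 / math.sqrt(10_000)

    def test_lag_budget_enforced(self):
        a = np.zeros(100)
        with pytest.raises(ConfigurationError, match="quarter"):
            cross_correlation(a, a, max_lag=30, dt=1.0)

    def test_longer_series_tightens_null_correlations(self):
        rng = np.random.default_rng(3)
        highs = []
        for n in (2000, 32_000):
            vals = []
            for _ in range(5):
                a, b = rng.standard_normal(n), rng.standard_normal(n)
                _, r = cross_correlation(a, b, max_lag=20, dt=1.0)
                vals.append(np.abs(r).max())
            highs.append(np.mean(vals))
        assert highs[1] < highs[0]


class TestExtremalDelay:
    def test_single_peak(self):
        lags = np.arange(-5, 6, dtype=float)
        r = np.exp(-0.5 * (lags - 2.0) ** 2)
        ext = extremal_delay(lags, r)
        assert ext["lag"] == 2.0 and not ext["flat"]

    def test_tie_broken_toward_negative_lag(self):
        lags = np.arange(-5, 6, dtype=float)
        r = np.zeros_like(lags)
        r[lags == 3] = 0.8
        r[lags == -3] = 0.8
        ext = extremal_delay(lags, r)
        assert ext["lag"] == -3.0

    def test_smaller_magnitude_lag_preferred(self):
        lags = np.arange(-5, 6, dtype=float)
        r = np.zeros_like(lags)
        r[lags == 1] = -0.9
        r[lags == 4] = -0.9
        assert extremal_delay(lags, r)["lag"] == 1.0

    def test_flat_flagged(self):
        lags = np.arange(-3, 4, dtype=float)
        ext = extremal_delay(lags, np.full_like(lags, 0.2))
        assert ext["flat"] and ext["lag"] == 0.0


class TestRescaledDistribution:
    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        s = rng.gamma(20, 1.0, size=3000)
        r1, _ = rescaled_distribution(s)
        r2, ks = rescaled_distribution(7.3 * s, reference=s)
        assert np.allclose(r1, r2)
        assert ks <= 1.0 / len(s) + 1e-12  # ECDF tie-handling floor

    def test_same_distribution_collapses(self):
        rng = np.random.default_rng(5)
        a = rng.gamma(25, 2.0, 2000)
        b = rng.gamma(25, 5.0, 2000)  # same shape, different scale
        _, ks = rescaled_distribution(a, reference=b)
        assert ks < 0.05

    def test_guards(self):
        with pytest.raises(ConfigurationError):
            rescaled_distribution(np.ones(10))
        with pytest.raises(ConfigurationError):
            rescaled_distribution(np.zeros(200))


class TestMinimalDelayGraph:
    def test_chain_without_light_edge(self):
        """A->B->C by dark edges; A's second target C is reachable, so no
        light edge is added."""
        t = _make_table({("A", "B"): (1.0, 0.9), ("A", "C"): (2.0, 0.8),
                         ("B", "C"): (1.0, 0.7)})
        g = minimal_delay_graph(t).graph
        kinds = {(u, v): d["kind"] for u, v, d in g.edges(data=True)}
        assert kinds[("A", "B")] == "dark"
        assert kinds[("B", "C")] == "dark"
        assert ("A", "C") not in kinds

    def test_light_edge_to_unreachable_target(self):
        t = _make_table({("A", "B"): (1.0, 0.9), ("A", "C"): (2.0, 0.8),
                         ("B", "C"): (-1.0, 0.7)})
        g = minimal_delay_graph(t).graph
        kinds = {(u, v): d["kind"] for u, v, d in g.edges(data=True)}
        assert kinds[("A", "C")] == "light"

    def test_threshold_filters_weak_edges(self):
        t = _make_table({("A", "B"): (1.0, 0.05), ("A", "C"): (2.0, 0.8),
                         ("B", "C"): (1.0, 0.7)})
        g = minimal_delay_graph(t, r_threshold=0.1).graph
        kinds = {(u, v): d["kind"] for u, v, d in g.edges(data=True)}
        assert ("A", "B") not in kinds and kinds[("A", "C")] == "dark"

    def test_missing_pair_rejected(self):
        t = _make_table({("A", "B"): (1.0, 0.9)})
        t = t.drop(index=("B", "A"))
        with pytest.raises(ConfigurationError, match="missing"):
            minimal_delay_graph(pd.concat([t, _make_table({("A", "C"): (1.0, 0.5)})]))

    def test_pure_function_of_table(self):
        t = _make_table({("A", "B"): (1.0, 0.9), ("A", "C"): (2.0, 0.8),
                         ("B", "C"): (1.0, 0.7)})
        e1 = minimal_delay_graph(t).edges_table()
        e2 = minimal_delay_graph(t).edges_table()
        pd.testing.assert_frame_equal(e1, e2)

    def test_dot_export_mentions_all_nodes(self):
        t = _make_table({("A", "B"): (1.0, 0.9), ("A", "growth_rate"): (2.0, -0.5),
                         ("B", "growth_rate"): (1.0, 0.7)})
        dot = minimal_delay_graph(t).to_dot()
        for node in ("A", "B", "growth_rate"):
            assert node in dot


@pytest.fixture(scope="module")
def det_traj(full_net, full_steady_state):
    Xbar, _ = full_steady_state
    cfg = SimulatorConfig(deterministic=True, n_divisions=35, seed=0)
    return simulate_lineage(full_net, cfg, X0=Xbar)


class TestLineageMoments:
    def test_deterministic_trajectory_has_no_concentration_noise(self, det_traj, full_steady_state):
        out = lineage_moments(det_traj)
        Xbar, lam = full_steady_state
        assert out["series"].loc["growth_rate", "cv"] < 1e-5
        assert out["series"].loc["growth_rate", "mean"] == pytest.approx(lam, rel=1e-5)
        assert out["cycle_stats"].loc["doubling_time", "mean"] == pytest.approx(
            math.log(2) / lam, rel=1e-4)
        assert out["cycle_stats"].loc["doubling_time", "cv"] < 1e-6

    def test_short_trajectory_warns(self, full_net, full_steady_state):
        Xbar, _ = full_steady_state
        cfg = SimulatorConfig(deterministic=True, n_divisions=14, seed=0)
        traj = simulate_lineage(full_net, cfg, X0=Xbar)
        out = lineage_moments(traj)
        assert "warning" in out

    def test_burn_in_longer_than_trajectory_rejected(self, det_traj):
        with pytest.raises(ConfigurationError):
            lineage_moments(det_traj, burn_in=10_000)
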