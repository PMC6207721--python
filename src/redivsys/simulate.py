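"""Hybrid stochastic lineage simulation.

Tracks a single cell (mother-machine semantics: one daughter retained per
division) whose low-copy species fire discrete reaction events via the
next-reaction method while the abundant remainder follows ODEs; the two
couple through the shared concentrations and cell mass.  Replication
initiates whenever the origin concentration reaches ``O_c`` (i.e. mass
crosses ``O / O_c``), doubling the origins and scheduling a division a
fixed C+D period later; at division the molecules are partitioned
binomially with the drawn volume fraction and the origins halved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from . import _kernel
from .core import ConfigurationError, PartitionRule, ReactionNetwork, CellState
from .ecoli import require_integer_stoichiometry

__all__ = [
    "SimulatorConfig",
    "Trajectory",
    "simulate_lineage",
    "simulate_lineages",
    "partition_state",
    "schedule_replication",
    "default_stochastic_species",
]

LN2 = math.log(2.0)


def default_stochastic_species(net: ReactionNetwork) -> list:
    """Low-abundance species simulated discretely by default.

    The transporter/enzyme mRNAs and their ribosome complexes (or the
    bicistronic pair in the operon variant) are the only species present
    at a handful of copies; everything else is ODE material.
    """
    candidates = ("m_t", "m_e", "c_t", "c_e", "m_bi", "c_bi")
    return [s for s in candidates if s in net.index]


@dataclass
class SimulatorConfig:
    """Knobs of the hybrid scheme.

    ``propensity_refresh`` is the window over which stochastic propensities
    are held frozen against the drifting ODE state (minutes);
    ``dt_max`` the ODE substep; ``sample_dt`` the output sampling interval.
    ``deterministic`` turns off all noise sources (no discrete reactions,
    exact halving at division) so the lineage follows the deterministic
    cell cycle.  ``n_divisions`` counts divisions including burn-in.
    """

    stochastic_species: list | None = None
    propensity_refresh: float = 0.05
    dt_max: float = 0.005
    sample_dt: float = 0.1
    t_end: float | None = None
    n_divisions: int | None = None
    burn_in: int = 10
    partition: PartitionRule = field(default_factory=PartitionRule)
    deterministic: bool = False
    track_complement: bool = False
    low_copy_bound: float = 1e5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.propensity_refresh <= 0 or self.dt_max <= 0 or self.sample_dt <= 0:
            raise ConfigurationError("refresh, dt_max and sample_dt must be positive")


@dataclass
class Trajectory:
    """Sampled single-cell lineage with event logs."""

    net: ReactionNetwork
    times: np.ndarray
    X: np.ndarray            # concentrations, shape (n_samples, N)
    M: np.ndarray            # cell mass (aa)
    lam: np.ndarray          # instantaneous growth rate (per min)
    O: np.ndarray            # origin count
    D: np.ndarray            # cumulative divisions at sample time
    divisions: pd.DataFrame  # t, rho, M_before, M_after
    initiations: pd.DataFrame  # t, M, O_after
    burn_in: int = 0
    low_copy_hits: int = 0
    neg_clamps: int = 0

    def concentration(self, name: str) -> np.ndarray:
        return self.X[:, self.net.species_index(name)]

    def group_concentration(self, weights: dict) -> np.ndarray:
        """Weighted sum of species concentrations (macrovariable)."""
        out = np.zeros(len(self.times))
        for name, w in weights.items():
            out += w * self.concentration(name)
        return out

    @property
    def post_burnin(self) -> np.ndarray:
        return self.D >= self.burn_in

    def cycles(self) -> pd.DataFrame:
        """Per division-cycle statistics (birth/division mass, doubling time)."""
        div = self.divisions
        rows = []
        for i in range(1, len(div)):
            birth = div["M_after"].iloc[i - 1]
            dt = div["t"].iloc[i] - div["t"].iloc[i - 1]
            rows.append({
                "t_birth": div["t"].iloc[i - 1],
                "t_division": div["t"].iloc[i],
                "doubling_time": dt,
                "birth_mass": birth,
                "division_mass": div["M_before"].iloc[i],
                "added_mass": div["M_before"].iloc[i] - birth,
                "cycle_growth_rate": math.log(div["M_before"].iloc[i] / birth) / dt,
                "index": i,
            })
        return pd.DataFrame(rows)


def _cell_cycle_params(net, O_c, tau_CD):
    if O_c is None or tau_CD is None:
        p = getattr(net, "params", None)
        if p is None:
            raise ConfigurationError(
                "supply O_c and tau_CD for networks without attached parameters"
            )
        O_c = p.O_c if O_c is None else O_c
        tau_CD = p.tau_CD if tau_CD is None else tau_CD
    return float(O_c), float(tau_CD)


def _auto_initial_state(net, O_c, X0=None):
    """Initial counts from the analytic steady state, just below initiation."""
    from .sna import steady_state_mean

    if X0 is None:
        Xbar, lam = steady_state_mean(net)
    else:
        Xbar = np.asarray(X0, dtype=np.float64)
        lam = net.growth_rate(Xbar, check=False)
    M_init = 0.9 / O_c  # O = 1 at start; initiation at M = 1/O_c
    return Xbar * M_init, 1, lam


def simulate_lineage(
    net: ReactionNetwork,
    cfg: SimulatorConfig | None = None,
    O_c: float | None = None,
    tau_CD: float | None = None,
    initial: CellState | None = None,
    X0=None,
) -> Trajectory:
    """Simulate one lineage; see :class:`SimulatorConfig` for the knobs.

    The initial state defaults to the small-noise steady state scaled to a
    mass just below the first initiation (``X0`` overrides the solve).
    Stops after ``cfg.n_divisions`` divisions or at ``cfg.t_end``,
    whichever comes first.
    """
    cfg = cfg or SimulatorConfig()
    if net.rate_laws is None:
        raise ConfigurationError("the simulator requires template-based rate laws")
    O_c, tau_CD = _cell_cycle_params(net, O_c, tau_CD)

    stoch_names = (
        [] if cfg.deterministic
        else (cfg.stochastic_species if cfg.stochastic_species is not None
              else default_stochastic_species(net))
    )
    stoch_sp = np.zeros(net.N, dtype=np.bool_)
    for name in stoch_names:
        stoch_sp[net.species_index(name)] = True
    if stoch_names:
        require_integer_stoichiometry(net, stoch_names)

    # reactions touching any stochastic species fire discretely
    stoch_rxn = np.array(
        [r for r in range(net.R) if (net.nu[stoch_sp, r] != 0).any()],
        dtype=np.int64,
    )
    det_rxn = np.array(
        [r for r in range(net.R) if r not in set(stoch_rxn.tolist())], dtype=np.int64
    )

    if initial is not None:
        x_init = np.asarray(initial.x, dtype=np.float64).copy()
        O_init = int(initial.O)
        lam_hint = net.growth_rate(x_init / float(net.mass @ x_init), check=False)
    else:
        x_init, O_init, lam_hint = _auto_initial_state(net, O_c, X0=X0)

    n_div = cfg.n_divisions if cfg.n_divisions is not None else 10**9
    if cfg.t_end is not None:
        t_end = float(cfg.t_end)
    else:
        if cfg.n_divisions is None:
            raise ConfigurationError("set t_end or n_divisions")
        # generous cap; the kernel stops at the division count
        t_end = 4.0 * (cfg.n_divisions + 2) * LN2 / max(lam_hint, 1e-6)

    rule = cfg.partition
    kind, par, sidx = net._encoded

    out = _kernel.run_lineage(
        kind, par, sidx, net.nu, net.mass,
        stoch_rxn, det_rxn, stoch_sp,
        x_init, O_init,
        O_c, tau_CD,
        cfg.propensity_refresh, cfg.dt_max, cfg.sample_dt,
        t_end, n_div,
        rule.rho_mean, rule.rho_sd, rule.rho_bounds[0], rule.rho_bounds[1],
        cfg.deterministic or rule.scheme == "deterministic-half",
        cfg.track_complement,
        cfg.low_copy_bound, cfg.seed,
    )
    (status, _t_fin, _D_fin, low_copy_hits, neg_clamps,
     s_t, s_X, s_M, s_lam, s_O, s_D,
     div_t, div_rho, div_Mb, div_Ma, ini_t, ini_M, ini_O) = out

    if status == _kernel.STATUS_ODD_ORIGIN:
        raise ConfigurationError("odd origin count at division (cycle bookkeeping violated)")
    if status == _kernel.STATUS_BUFFER_FULL:
        raise ConfigurationError("pending-division queue overflow")

    divisions = pd.DataFrame({"t": div_t, "rho": div_rho,
                              "M_before": div_Mb, "M_after": div_Ma})
    initiations = pd.DataFrame({"t": ini_t, "M": ini_M, "O_after": ini_O})
    return Trajectory(net, s_t, s_X, s_M, s_lam, s_O, s_D,
                      divisions, initiations, burn_in=cfg.burn_in,
                      low_copy_hits=int(low_copy_hits), neg_clamps=int(neg_clamps))


def simulate_lineages(net, n_lineages, cfg=None, O_c=None, tau_CD=None, X0=None):
    """Simulate independent lineages with per-lineage seeds derived from cfg.seed.

    The steady-state initial condition is solved once and shared; yields
    :class:`Trajectory` objects lazily.
    """
    cfg = cfg or SimulatorConfig()
    from .sna import steady_state_mean

    if X0 is None:
        Xbar, _ = steady_state_mean(net)
    else:
        Xbar = np.asarray(X0, dtype=np.float64)
    seeds = np.random.SeedSequence(cfg.seed).generate_state(n_lineages) % (2**31 - 1)
    for k in range(n_lineages):
        yield simulate_lineage(
            net, dc_replace(cfg, seed=int(seeds[k])), O_c=O_c, tau_CD=tau_CD, X0=Xbar
        )


# -- small exposed operations (also exercised standalone in tests) -----


def partition_state(x, rho, rule: PartitionRule | None = None,
                    stochastic_mask=None, rng=None):
    """Partition a molecule-count vector at division; returns the daughter.

    Integer (stochastic) species draw Binomial(x_i, rho); continuous ones
    receive ``rho x_i`` plus Gaussian noise of matching binomial variance,
    truncated to [0, x_i].  With the deterministic-half rule the split is
    exact.
    """
    if not (0.0 < rho < 1.0):
        raise ConfigurationError("rho must lie in (0, 1)")
    rule = rule or PartitionRule()
    rng = rng or np.random.default_rng()
    x = np.asarray(x, dtype=np.float64)
    if rule.scheme == "deterministic-half":
        return x * rho
    if stochastic_mask is None:
        stochastic_mask = np.ones(x.shape, dtype=bool)
    out = np.empty_like(x)
    for i, xi in enumerate(x):
        if stochastic_mask[i]:
            out[i] = rng.binomial(int(round(xi)), rho)
        else:
            sd = math.sqrt(max(rho * (1.0 - rho) * xi, 0.0))
            out[i] = min(max(rng.normal(rho * xi, sd) if sd > 0 else rho * xi, 0.0), xi)
    return out


def schedule_replication(state: CellState, O_c: float, tau_CD: float) -> CellState:
    """Fire replication initiation if the origin concentration reached O_c.

    Initiation doubles the origin count and appends a division event a C+D
    period after the crossing; repeated calls support overlapping rounds
    (the pending queue holds one division per initiated round).
    """
    while state.M * O_c >= state.O:
        state.O *= 2
        state.pending_divisions.append(state.t + tau_CD)
        state.pending_divisions.sort()
    return state
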