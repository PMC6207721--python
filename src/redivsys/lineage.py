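"""Lineage trajectory statistics and noise-propagation analysis.

Time-averaged moments and CVs, per-cycle statistics with block-bootstrap
standard errors, mean-rescaled distributions with a Kolmogorov--Smirnov
collapse metric, cross-correlation functions between macrovariables, the
extremal-correlation delay (lag of maximal |r|) and the directed
minimal-delay graph summarising the order in which fluctuations travel
through the cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import ConfigurationError
from .simulate import Trajectory

__all__ = [
    "lineage_moments",
    "rescaled_distribution",
    "cross_correlation",
    "extremal_delay",
    "minimal_delay_graph",
    "DelayGraph",
    "default_macrovariables",
    "pairwise_delays",
]

GROWTH = "growth_rate"


def lineage_moments(traj: Trajectory, burn_in: int | None = None,
                    n_boot: int = 200, seed: int = 0) -> dict:
    """Time-averaged and per-cycle summary statistics of one lineage.

    Returns a dict with ``series`` (mean/CV per concentration, growth rate
    and mass), ``cycles`` (birth mass, added mass, doubling time, per-cycle
    growth rate with mean/CV) and block-bootstrap standard errors over
    division cycles for the cycle statistics.  A ``warning`` entry is set
    when fewer than 20 post-burn-in cycles are available.
    """
    burn_in = traj.burn_in if burn_in is None else burn_in
    keep = traj.D >= burn_in
    if not keep.any():
        raise ConfigurationError("trajectory shorter than the burn-in")

    rows = {}
    for i, name in enumerate(traj.net.species_names):
        x = traj.X[keep, i]
        mu = float(np.mean(x))
        rows[name] = {"mean": mu, "cv": float(np.std(x) / mu) if mu > 0 else math.nan}
    lam = traj.lam[keep]
    rows["growth_rate"] = {"mean": float(np.mean(lam)),
                           "cv": float(np.std(lam) / np.mean(lam))}
    mass = traj.M[keep]
    rows["mass"] = {"mean": float(np.mean(mass)),
                    "cv": float(np.std(mass) / np.mean(mass))}
    series = pd.DataFrame(rows).T

    cyc = traj.cycles()
    cyc = cyc[cyc["index"] > burn_in].reset_index(drop=True)
    out = {"series": series, "cycles": cyc, "n_cycles": len(cyc)}
    if len(cyc) < 20:
        out["warning"] = f"only {len(cyc)} post-burn-in cycles; SEs unreliable"
    if len(cyc) >= 2:
        rng = np.random.default_rng(seed)
        stats_rows = {}
        cols = ["birth_mass", "added_mass", "doubling_time", "cycle_growth_rate"]
        block = max(len(cyc) // 10, 1)
        for col in cols:
            v = cyc[col].to_numpy()
            means = np.empty(n_boot)
            for b in range(n_boot):
                # moving-block bootstrap over cycles
                starts = rng.integers(0, len(v) - block + 1,
                                      size=max(len(v) // block, 1))
                sample = np.concatenate([v[s:s + block] for s in starts])
                means[b] = sample.mean()
            stats_rows[col] = {
                "mean": float(v.mean()),
                "cv": float(v.std() / v.mean()),
                "se_mean": float(means.std(ddof=1)),
            }
        out["cycle_stats"] = pd.DataFrame(stats_rows).T
    return out


def rescaled_distribution(samples, reference=None):
    """Rescale samples by their mean; optionally measure collapse onto a reference.

    Returns ``(rescaled, ks)`` where ``ks`` is the two-sample KS distance
    between the mean-rescaled samples and the mean-rescaled reference
    (None when no reference is given).  Distributions whose shape depends
    on the condition only through the mean collapse to the same rescaled law.
    """
    samples = np.asarray(samples, dtype=np.float64)
    if samples.size < 100:
        raise ConfigurationError("need at least 100 samples")
    mu = samples.mean()
    if mu == 0:
        raise ConfigurationError("zero mean; cannot rescale")
    rescaled = samples / mu
    ks = None
    if reference is not None:
        reference = np.asarray(reference, dtype=np.float64)
        ks = float(stats.ks_2samp(rescaled, reference / reference.mean()).statistic)
    return rescaled, ks


def cross_correlation(a, b, max_lag: float, dt: float):
    """Normalised cross-correlation r(tau) = corr(A(t), B(t + tau)).

    Positive lags mean B trails A.  Series must share a uniform sampling
    interval ``dt``; the lag grid runs from -max_lag to +max_lag in steps
    of ``dt``.  ``max_lag`` may not exceed a quarter of the series length.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigurationError("series must be one-dimensional and equally long")
    n = a.size
    L = int(round(max_lag / dt))
    if L > n // 4:
        raise ConfigurationError("max_lag exceeds a quarter of the series length")
    ac = a - a.mean()
    bc = b - b.mean()
    sa, sb = ac.std(), bc.std()
    if sa == 0 or sb == 0:
        return np.arange(-L, L + 1) * dt, np.zeros(2 * L + 1)
    # full correlation; index k of np.correlate(bc, ac, "full") corresponds
    # to sum_t ac[t] * bc[t + k - (n-1)]
    full = np.correlate(bc, ac, "full")
    lags = np.arange(-L, L + 1)
    r = np.empty(lags.size)
    for j, k in enumerate(lags):
        r[j] = full[k + n - 1] / ((n - abs(k)) * sa * sb)
    return lags * dt, r


def extremal_delay(lags, r, flat_tol: float = 1e-12):
    """Lag of maximal |r| and the signed correlation there.

    Ties are broken toward the smallest |lag|, then toward the negative
    lag.  A flat correlation returns lag 0 with ``flat=True``.
    """
    lags = np.asarray(lags, dtype=np.float64)
    r = np.asarray(r, dtype=np.float64)
    if np.ptp(r) < flat_tol:
        i0 = int(np.argmin(np.abs(lags)))
        return {"lag": 0.0, "r": float(r[i0]), "flat": True}
    best = np.abs(r).max()
    cand = np.nonzero(np.abs(r) >= best * (1 - 1e-12))[0]
    # smallest |lag|, then negative preferred
    cand = sorted(cand, key=lambda i: (abs(lags[i]), lags[i]))
    i = cand[0]
    return {"lag": float(lags[i]), "r": float(r[i]), "flat": False}


def default_macrovariables(net) -> dict:
    """Lumped macrovariables of the cell model (mass-weighted groups).

    Ribosomes include free and translating (and drug-bound) copies; the
    mRNA groups include ribosome-bound transcripts.
    """
    names = net.species_names
    groups: dict = {}

    def add(group, name, w=1.0):
        if name in names:
            groups.setdefault(group, {})[name] = w

    if "m_bi" in names:
        add("bi-mRNA", "m_bi")
        add("bi-mRNA", "c_bi")
    else:
        add("t-mRNA", "m_t")
        add("t-mRNA", "c_t")
        add("e-mRNA", "m_e")
        add("e-mRNA", "c_e")
    add("r-mRNA", "m_r")
    add("r-mRNA", "c_r")
    add("q-mRNA", "m_q")
    add("q-mRNA", "c_q")
    add("transporters", "p_t")
    add("enzymes", "p_e")
    add("q-protein", "p_q")
    add("resource", "a")
    for name in names:
        if name == "p_r" or name.startswith("c_") or name.startswith("z_"):
            add("ribosomes", name)
    return groups


def _macro_series(traj, groups):
    series = {}
    keep = traj.post_burnin
    for gname, weights in groups.items():
        series[gname] = traj.group_concentration(weights)[keep]
    series[GROWTH] = traj.lam[keep]
    return series


def pairwise_delays(trajs, max_lag: float, groups=None, log_scale: bool = False):
    """Extremal delays and correlations between all macrovariable pairs.

    Correlations are estimated per lineage and averaged over lineages.
    Returns a DataFrame indexed by (A, B) with columns ``lag`` and ``r``;
    by construction lag(A, B) = -lag(B, A).
    """
    trajs = list(trajs)
    if not trajs:
        raise ConfigurationError("no trajectories given")
    groups = groups if groups is not None else default_macrovariables(trajs[0].net)
    dt = float(np.median(np.diff(trajs[0].times)))
    names = list(groups.keys()) + [GROWTH]

    acc: dict = {}
    for traj in trajs:
        series = _macro_series(traj, groups)
        if log_scale:
            series = {k: np.log(np.maximum(v, 1e-300)) for k, v in series.items()}
        for i, A in enumerate(names):
            for B in names[i:]:
                lags, r = cross_correlation(series[A], series[B], max_lag, dt)
                key = (A, B)
                if key in acc:
                    acc[key][1] += r
                else:
                    acc[key] = [lags, r.copy()]

    rows = []
    for (A, B), (lags, rsum) in acc.items():
        r = rsum / len(trajs)
        ext = extremal_delay(lags, r)
        rows.append({"A": A, "B": B, "lag": ext["lag"], "r": ext["r"]})
        if A != B:
            rows.append({"A": B, "B": A, "lag": -ext["lag"], "r": ext["r"]})
    return pd.DataFrame(rows).set_index(["A", "B"])


@dataclass
class DelayGraph:
    """Directed minimal-delay graph over macrovariables.

    Dark edges point from each node to the node it reaches with the
    smallest positive delay; light edges to the second-smallest target
    when that target is not already reached through subsequent dark
    steps.  Node signs record the correlation sign with growth rate.
    """

    graph: nx.DiGraph
    table: pd.DataFrame

    def edges_table(self) -> pd.DataFrame:
        rows = [
            {"A": u, "B": v, "lag": d["lag"], "r": d["r"], "kind": d["kind"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows)

    def to_dot(self) -> str:
        lines = ["digraph delays {"]
        for node, d in self.graph.nodes(data=True):
            sign = d.get("sign", 0)
            label = f"{node} ({'+' if sign > 0 else '-' if sign < 0 else '0'})"
            lines.append(f'  "{node}" [label="{label}"];')
        for u, v, d in self.graph.edges(data=True):
            style = "solid" if d["kind"] == "dark" else "dashed"
            arrow = "normal" if d["r"] >= 0 else "tee"
            lines.append(
                f'  "{u}" -> "{v}" [style={style}, arrowhead={arrow}, '
                f'label="{d["r"]:.2f}@{d["lag"]:.1f}"];'
            )
        lines.append("}")
        return "\n".join(lines)


def minimal_delay_graph(table: pd.DataFrame, r_threshold: float = 0.1) -> DelayGraph:
    """Build the minimal-delay graph from a pairwise (lag, r) table.

    For each node A the dark edge goes to the target with the smallest
    positive delay; a light edge to the second-smallest target is added
    only if that target is not reachable from A via dark edges.  Edges
    with |r| below ``r_threshold`` are omitted.  Pure function of the
    table (no randomness).
    """
    nodes = sorted({a for a, _ in table.index} | {b for _, b in table.index})
    for A in nodes:
        for B in nodes:
            if A != B and (A, B) not in table.index:
                raise ConfigurationError(f"missing pair ({A}, {B}) in the delay table")

    g = nx.DiGraph()
    for node in nodes:
        if node == GROWTH:
            sign = 1
        elif GROWTH in nodes:
            r = float(table.loc[(node, GROWTH), "r"])
            sign = int(np.sign(r)) if r != 0 else 0
        else:
            sign = 0  # no growth-rate column in the table
        g.add_node(node, sign=sign)

    candidates = {}
    for A in nodes:
        cand = []
        for B in nodes:
            if B == A:
                continue
            lag = float(table.loc[(A, B), "lag"])
            r = float(table.loc[(A, B), "r"])
            if lag > 0 and abs(r) >= r_threshold:
                cand.append((lag, B, r))
        cand.sort()
        candidates[A] = cand
        if cand:
            lag, B, r = cand[0]
            g.add_edge(A, B, lag=lag, r=r, kind="dark")

    # light edges: second-smallest delay, only when not already reached
    for A in nodes:
        if len(candidates[A]) < 2:
            continue
        lag, B, r = candidates[A][1]
        dark = nx.DiGraph((u, v) for u, v, d in g.edges(data=True) if d["kind"] == "dark")
        reachable = nx.descendants(dark, A) if A in dark else set()
        if B not in reachable:
            g.add_edge(A, B, lag=lag, r=r, kind="light")

    return DelayGraph(graph=g, table=table)
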