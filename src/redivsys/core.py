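"""Core representation of reaction--division systems.

A reaction--division system is a biochemical network whose extensive state
(molecule counts ``x``) accumulates biomass and is intermittently halved by
cell division.  Cell mass is ``M = m^T x`` where ``m`` holds per-molecule
masses (amino-acid units), intracellular concentrations are ``X = x / M``,
and the growth rate emerges from the network itself,

    lambda(X) = m^T nu f(X),

with ``nu`` the stoichiometric matrix and ``f(X)`` the vector of *intensive*
reaction rates (events per unit mass per minute).  The extensive propensity
of reaction ``r`` in a cell of mass ``M`` is ``M * f_r(X)``.

Rates are stored either as declarative rate-law templates (serialisable,
differentiable, compilable for the stochastic simulator) or as an arbitrary
callable ``rate_fn(X) -> f`` for ad-hoc networks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "RateEvaluationError",
    "RateLaw",
    "ReactionNetwork",
    "CellState",
    "PartitionRule",
    "growth_rate",
    "drift",
    "validate",
]


class ConfigurationError(ValueError):
    """Inconsistent network or parameter definition."""


class RateEvaluationError(RuntimeError):
    """A rate function returned a non-finite value."""


# Numeric codes shared with the compiled simulator kernel.
KIND_CONSTANT = 0
KIND_LINEAR = 1
KIND_MASS_ACTION = 2
KIND_HILL = 3
KIND_HILL_REPRESSED = 4
KIND_MICHAELIS = 5
KIND_TRANSLATION = 6

_KIND_CODES = {
    "constant": KIND_CONSTANT,
    "linear": KIND_LINEAR,
    "mass_action": KIND_MASS_ACTION,
    "hill_activation": KIND_HILL,
    "hill_activation_repressed": KIND_HILL_REPRESSED,
    "michaelis": KIND_MICHAELIS,
    "translation": KIND_TRANSLATION,
}
_KIND_NAMES = {v: k for k, v in _KIND_CODES.items()}

# (parameter names, species-role names) per template
_KIND_SIGNATURE = {
    "constant": (("k",), ()),
    "linear": (("k",), ("s",)),
    "mass_action": (("k",), ("s1", "s2")),
    "hill_activation": (("w", "theta"), ("a",)),
    "hill_activation_repressed": (("w", "theta", "K", "h"), ("a", "p")),
    "michaelis": (("v", "K"), ("e", "s")),
    "translation": (("gamma_max", "n", "K"), ("c", "a")),
}


@dataclass
class RateLaw:
    """One intensive rate law, one of a small set of named templates.

    ``constant``                    f = k
    ``linear``                      f = k * X[s]
    ``mass_action``                 f = k * X[s1] * X[s2]
    ``hill_activation``             f = w * X[a] / (X[a] + theta)
    ``hill_activation_repressed``   f = w * X[a]/(X[a]+theta) / (1 + (X[p]/K)**h)
    ``michaelis``                   f = v * X[e] * X[s] / (K + X[s])
    ``translation``                 f = (X[c]/n) * gamma_max * X[a]/(X[a]+K)
    """

    kind: str
    params: dict
    species: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KIND_SIGNATURE:
            raise ConfigurationError(f"unknown rate-law template {self.kind!r}")
        pnames, snames = _KIND_SIGNATURE[self.kind]
        if set(self.params) != set(pnames):
            raise ConfigurationError(
                f"{self.kind}: expected parameters {pnames}, got {tuple(self.params)}"
            )
        if set(self.species) != set(snames):
            raise ConfigurationError(
                f"{self.kind}: expected species roles {snames}, got {tuple(self.species)}"
            )


def _encode_rates(rates: Sequence[RateLaw], index: dict) -> tuple:
    """Pack rate laws into (kind, par, sidx) numeric arrays."""
    R = len(rates)
    kind = np.zeros(R, dtype=np.int64)
    par = np.zeros((R, 4), dtype=np.float64)
    sidx = np.zeros((R, 2), dtype=np.int64)
    for r, law in enumerate(rates):
        kind[r] = _KIND_CODES[law.kind]
        pnames, snames = _KIND_SIGNATURE[law.kind]
        for j, pn in enumerate(pnames):
            par[r, j] = float(law.params[pn])
        for j, sn in enumerate(snames):
            sidx[r, j] = index[law.species[sn]]
    return kind, par, sidx


def _eval_rates(kind, par, sidx, X):
    """Vectorised evaluation of encoded rate laws at concentration vector X."""
    f = np.empty(kind.shape[0], dtype=np.float64)
    for r in range(kind.shape[0]):
        k = kind[r]
        if k == KIND_CONSTANT:
            f[r] = par[r, 0]
        elif k == KIND_LINEAR:
            f[r] = par[r, 0] * X[sidx[r, 0]]
        elif k == KIND_MASS_ACTION:
            f[r] = par[r, 0] * X[sidx[r, 0]] * X[sidx[r, 1]]
        elif k == KIND_HILL:
            a = X[sidx[r, 0]]
            f[r] = par[r, 0] * a / (a + par[r, 1])
        elif k == KIND_HILL_REPRESSED:
            a = X[sidx[r, 0]]
            p = X[sidx[r, 1]]
            f[r] = (par[r, 0] * a / (a + par[r, 1])) / (1.0 + (p / par[r, 2]) ** par[r, 3])
        elif k == KIND_MICHAELIS:
            s = X[sidx[r, 1]]
            f[r] = par[r, 0] * X[sidx[r, 0]] * s / (par[r, 1] + s)
        else:  # KIND_TRANSLATION
            a = X[sidx[r, 1]]
            f[r] = (X[sidx[r, 0]] / par[r, 1]) * par[r, 0] * a / (a + par[r, 2])
    return f


def _rate_jacobian(kind, par, sidx, X, R, N):
    """Analytic d f_r / d X_i for encoded rate laws (sparse in the species)."""
    J = np.zeros((R, N))
    for r in range(R):
        k = kind[r]
        if k == KIND_LINEAR:
            J[r, sidx[r, 0]] = par[r, 0]
        elif k == KIND_MASS_ACTION:
            i, j = sidx[r, 0], sidx[r, 1]
            J[r, i] += par[r, 0] * X[j]
            J[r, j] += par[r, 0] * X[i]
        elif k == KIND_HILL:
            a = X[sidx[r, 0]]
            th = par[r, 1]
            J[r, sidx[r, 0]] = par[r, 0] * th / (a + th) ** 2
        elif k == KIND_HILL_REPRESSED:
            ia, ip = sidx[r, 0], sidx[r, 1]
            a, p = X[ia], X[ip]
            w, th, K, h = par[r, :4]
            rep = 1.0 + (p / K) ** h
            J[r, ia] = (w * th / (a + th) ** 2) / rep
            if p > 0:
                J[r, ip] = -(w * a / (a + th)) * h * (p / K) ** h / (p * rep**2)
        elif k == KIND_MICHAELIS:
            ie, isb = sidx[r, 0], sidx[r, 1]
            e, s = X[ie], X[isb]
            v, K = par[r, 0], par[r, 1]
            J[r, ie] = v * s / (K + s)
            J[r, isb] = v * e * K / (K + s) ** 2
        elif k == KIND_TRANSLATION:
            ic, ia = sidx[r, 0], sidx[r, 1]
            c, a = X[ic], X[ia]
            g, n, K = par[r, 0], par[r, 1], par[r, 2]
            J[r, ic] = (g / n) * a / (a + K)
            J[r, ia] = (c / n) * g * K / (a + K) ** 2
    return J


class ReactionNetwork:
    """Species, stoichiometry, intensive rates and per-molecule masses.

    Parameters
    ----------
    species_names
        Identifiers, length N.
    nu
        Stoichiometric matrix, shape (N, R).  Integer-valued except where a
        model genuinely uses fractional stoichiometry (e.g. resource yield);
        such reactions are rejected by the stochastic simulator.
    mass
        Per-molecule mass in amino-acid units, length N, non-negative.
    rates
        Either a sequence of :class:`RateLaw` (serialisable, differentiable)
        or a callable ``X -> f`` returning the R intensive rates.
    reaction_labels, reaction_groups
        Human-readable labels and group tags (``"transcription:t"``, ...),
        used by the noise decomposition.
    """

    def __init__(
        self,
        species_names: Sequence[str],
        nu,
        mass,
        rates,
        reaction_labels: Sequence[str] | None = None,
        reaction_groups: Sequence[str] | None = None,
    ):
        self.species_names = list(species_names)
        self.nu = np.asarray(nu, dtype=np.float64)
        self.mass = np.asarray(mass, dtype=np.float64)
        self.N = len(self.species_names)
        if self.nu.ndim != 2 or self.nu.shape[0] != self.N:
            raise ConfigurationError(
                f"nu has shape {self.nu.shape}, expected ({self.N}, R)"
            )
        self.R = self.nu.shape[1]
        if self.mass.shape != (self.N,):
            raise ConfigurationError(
                f"mass vector has length {self.mass.shape}, expected {self.N}"
            )
        self.index = {name: i for i, name in enumerate(self.species_names)}
        if len(self.index) != self.N:
            raise ConfigurationError("duplicate species names")

        if callable(rates):
            self.rate_fn: Callable | None = rates
            self.rate_laws: list[RateLaw] | None = None
            self._encoded = None
        else:
            self.rate_laws = list(rates)
            if len(self.rate_laws) != self.R:
                raise ConfigurationError(
                    f"{len(self.rate_laws)} rate laws for {self.R} reactions"
                )
            self.rate_fn = None
            self._encoded = _encode_rates(self.rate_laws, self.index)

        self.reaction_labels = (
            list(reaction_labels)
            if reaction_labels is not None
            else [f"r{r}" for r in range(self.R)]
        )
        self.reaction_groups = (
            list(reaction_groups) if reaction_groups is not None else list(self.reaction_labels)
        )
        if len(self.reaction_labels) != self.R or len(self.reaction_groups) != self.R:
            raise ConfigurationError("reaction labels/groups length mismatch")

    # -- evaluation ----------------------------------------------------

    def rate_values(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape != (self.N,):
            raise ConfigurationError(
                f"concentration vector has shape {X.shape}, expected ({self.N},)"
            )
        if self._encoded is not None:
            f = _eval_rates(*self._encoded, X)
        else:
            f = np.asarray(self.rate_fn(X), dtype=np.float64)
            if f.shape != (self.R,):
                raise ConfigurationError(
                    f"rate_fn returned shape {f.shape}, expected ({self.R},)"
                )
        bad = ~np.isfinite(f)
        if bad.any():
            r = int(np.nonzero(bad)[0][0])
            raise RateEvaluationError(
                f"non-finite rate for reaction {self.reaction_labels[r]!r} (index {r})"
            )
        return f

    def rate_jacobian(self, X) -> np.ndarray:
        """d f / d X, analytic for template-based rates, else central differences."""
        X = np.asarray(X, dtype=np.float64)
        if self._encoded is not None:
            return _rate_jacobian(*self._encoded, X, self.R, self.N)
        J = np.zeros((self.R, self.N))
        for i in range(self.N):
            h = 1e-6 * abs(X[i]) + 1e-12
            Xp, Xm = X.copy(), X.copy()
            Xp[i] += h
            Xm[i] -= h
            J[:, i] = (self.rate_values(Xp) - self.rate_values(Xm)) / (2 * h)
        return J

    def growth_rate(self, X, check: bool = True) -> float:
        return growth_rate(self, X, check=check)

    def drift(self, X, check: bool = True) -> np.ndarray:
        return drift(self, X, check=check)

    def drift_jacobian(self, X) -> np.ndarray:
        """Jacobian of ``drift`` (not restricted to the simplex)."""
        X = np.asarray(X, dtype=np.float64)
        Jf = self.rate_jacobian(X)
        f = self.rate_values(X)
        mnu = self.mass @ self.nu  # length R: mass produced per reaction event
        lam = float(mnu @ f)
        dlam = mnu @ Jf  # length N
        return self.nu @ Jf - np.outer(X, dlam) - lam * np.eye(self.N)

    # -- bookkeeping ---------------------------------------------------

    def mass_production(self) -> np.ndarray:
        """m^T nu_r per reaction (mass added per event)."""
        return self.mass @ self.nu

    def species_index(self, name: str) -> int:
        try:
            return self.index[name]
        except KeyError:
            raise ConfigurationError(f"unknown species {name!r}") from None

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        if self.rate_laws is None:
            raise ConfigurationError("networks with a callable rate_fn are not serialisable")
        return {
            "species": [
                {"name": n, "mass": float(m)}
                for n, m in zip(self.species_names, self.mass)
            ],
            "reactions": [
                {
                    "label": self.reaction_labels[r],
                    "group": self.reaction_groups[r],
                    "stoichiometry": {
                        self.species_names[i]: float(self.nu[i, r])
                        for i in np.nonzero(self.nu[:, r])[0]
                    },
                    "rate": {
                        "kind": self.rate_laws[r].kind,
                        "params": {k: float(v) for k, v in self.rate_laws[r].params.items()},
                        "species": dict(self.rate_laws[r].species),
                    },
                }
                for r in range(self.R)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionNetwork":
        names = [s["name"] for s in d["species"]]
        mass = [s["mass"] for s in d["species"]]
        index = {n: i for i, n in enumerate(names)}
        R = len(d["reactions"])
        nu = np.zeros((len(names), R))
        laws, labels, groups = [], [], []
        for r, rx in enumerate(d["reactions"]):
            for sp, coeff in rx["stoichiometry"].items():
                if sp not in index:
                    raise ConfigurationError(f"reaction {rx['label']!r}: unknown species {sp!r}")
                nu[index[sp], r] = coeff
            laws.append(RateLaw(rx["rate"]["kind"], rx["rate"]["params"], rx["rate"]["species"]))
            labels.append(rx.get("label", f"r{r}"))
            groups.append(rx.get("group", labels[-1]))
        return cls(names, nu, mass, laws, labels, groups)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ReactionNetwork":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class CellState:
    """Extensive single-cell state tracked by the simulator.

    ``x`` holds molecule counts (integer-valued for stochastically simulated
    species, continuous for ODE-tracked ones), ``M = m^T x`` the cell mass in
    amino-acid units, ``O`` the replication-origin count and
    ``pending_divisions`` the absolute times of divisions already scheduled
    by past initiation events.
    """

    x: np.ndarray
    M: float
    O: int
    pending_divisions: list = field(default_factory=list)
    t: float = 0.0
    D: int = 0

    def check(self, net: ReactionNetwork, rtol: float = 1e-6) -> None:
        M = float(net.mass @ self.x)
        if not np.isclose(M, self.M, rtol=rtol):
            raise ConfigurationError(f"mass bookkeeping violated: m^T x = {M}, M = {self.M}")
        if self.O < 1:
            raise ConfigurationError("origin count must be >= 1")
        if any(b < a for a, b in zip(self.pending_divisions, self.pending_divisions[1:])):
            raise ConfigurationError("pending divisions not sorted")


@dataclass
class PartitionRule:
    """How molecules and origins are split between daughters at division.

    The tracked daughter inherits a volume fraction ``rho`` drawn from a
    truncated normal; each molecular species is partitioned binomially with
    probability ``rho`` (or exactly ``rho * x`` for deterministic-half
    bookkeeping), origins are halved exactly.
    """

    rho_mean: float = 0.5
    rho_sd: float = 0.05
    rho_bounds: tuple = (0.3, 0.7)
    scheme: str = "binomial"  # or "deterministic-half"

    def __post_init__(self) -> None:
        if self.scheme not in ("binomial", "deterministic-half"):
            raise ConfigurationError(f"unknown partition scheme {self.scheme!r}")
        lo, hi = self.rho_bounds
        if not (0.0 < lo <= self.rho_mean <= hi < 1.0):
            raise ConfigurationError("rho bounds must satisfy 0 < lo <= mean <= hi < 1")

    def draw_rho(self, rng: np.random.Generator) -> float:
        if self.rho_sd == 0.0 or self.scheme == "deterministic-half":
            return self.rho_mean
        lo, hi = self.rho_bounds
        while True:
            rho = rng.normal(self.rho_mean, self.rho_sd)
            if lo <= rho <= hi:
                return float(rho)


# -- module-level operations ------------------------------------------


def _check_simplex(net: ReactionNetwork, X, tol: float = 1e-9):
    X = np.asarray(X, dtype=np.float64)
    if X.shape != (net.N,):
        raise ConfigurationError(
            f"concentration vector has shape {X.shape}, expected ({net.N},)"
        )
    if (X < 0).any():
        raise ConfigurationError("concentrations must be non-negative")
    mx = float(net.mass @ X)
    if abs(mx - 1.0) > tol:
        raise ConfigurationError(f"m^T X = {mx}, expected 1 within {tol}")
    return X


def growth_rate(net: ReactionNetwork, X, check: bool = True) -> float:
    """Emergent growth rate lambda(X) = m^T nu f(X), per minute."""
    X = _check_simplex(net, X) if check else np.asarray(X, dtype=np.float64)
    return float(net.mass_production() @ net.rate_values(X))


def drift(net: ReactionNetwork, X, check: bool = True) -> np.ndarray:
    """Deterministic concentration velocity nu f(X) - lambda(X) X."""
    X = _check_simplex(net, X) if check else np.asarray(X, dtype=np.float64)
    f = net.rate_values(X)
    lam = float(net.mass_production() @ f)
    return net.nu @ f - lam * X


def renormalize(net: ReactionNetwork, X) -> np.ndarray:
    """Project X back onto the simplex m^T X = 1 by global rescaling."""
    X = np.asarray(X, dtype=np.float64)
    return X / float(net.mass @ X)


def validate(net: ReactionNetwork, expect_growth: bool = True) -> list:
    """Structural checks; returns a list of violation strings (empty = valid)."""
    report = []
    if net.nu.shape != (net.N, net.R):
        report.append(f"nu shape {net.nu.shape} != ({net.N}, {net.R})")
    if net.mass.shape != (net.N,):
        report.append(f"mass vector length {net.mass.shape[0]} != N = {net.N}")
    elif (net.mass < 0).any():
        report.append("negative entries in mass vector")
    mnu = net.mass @ net.nu if net.mass.shape == (net.N,) else None
    if expect_growth and mnu is not None and not (mnu > 0).any():
        report.append("warning: no mass-producing reaction (m^T nu_r <= 0 for all r)")
    if len(net.reaction_groups) != net.R:
        report.append("reaction group tags incomplete")
    return report
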