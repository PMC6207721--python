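"""Small-noise approximation for reaction--division systems.

Expanding the jump-diffusion dynamics of concentrations around the
deterministic steady state gives, in the limit of large cell mass:

* steady-state means from the synthesis--dilution balance
  ``nu f(Xbar) = lambda(Xbar) Xbar`` on the simplex ``m^T Xbar = 1``;
* cell-cycle means from replication-initiation control at fixed origin
  concentration ``O_c`` and a fixed C+D period ``tau_CD``:
  ``M0 = exp(lambda tau_CD) / (2 O_c)``, ``O0 = exp(lambda tau_CD)/(2 ln 2)``,
  hence a constant unit size ``M0/O0 = ln 2 / O_c``;
* the time-averaged concentration covariance ``Sigma`` from a Lyapunov
  equation ``0 = J Sigma + Sigma J^T + Q`` whose inhomogeneity collects
  per-reaction noise (projected onto the mass simplex) and binomial
  partitioning noise at division;
* the growth-rate coefficient of variation as a quadratic form of the
  log-sensitivities of ``lambda`` with the scaled covariance.

Because the Lyapunov equation is linear in its inhomogeneity, the
growth-rate variance splits exactly into additive contributions of
reaction groups and of division partitioning (noise decomposition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .core import ReactionNetwork, ConfigurationError, drift as _drift

__all__ = [
    "SteadyStateError",
    "SNAResult",
    "steady_state_mean",
    "birth_state",
    "stationary_covariance",
    "growth_rate_cv",
    "decompose_noise",
    "default_grouping",
    "parameter_sensitivity",
    "to_bulk",
    "solve",
    "solve_curve",
    "saturated_growth_rate",
]

LN2 = math.log(2.0)
DBLHR = 60.0 / LN2  # per-minute rate -> doublings per hour


class SteadyStateError(RuntimeError):
    """Steady-state solve failed; carries the best residual reached."""

    def __init__(self, message: str, residual: float = math.nan):
        super().__init__(message)
        self.residual = residual


# -- steady state ------------------------------------------------------


def _newton_log(net: ReactionNetwork, X0, tol: float, max_iter: int = 120):
    """Damped Newton in log-concentrations for the on-simplex steady state.

    The drift has rank N-1 on the simplex, so the equation of the species
    carrying the most mass is replaced by the constraint ``m^T X = 1``.
    Each remaining equation is scaled by the species' gross turnover, which
    keeps the linearised system well conditioned despite concentrations
    spanning many decades.  Returns the iterate and its unscaled drift
    residual (infinity norm).
    """
    from scipy.optimize import root

    m = net.mass
    absnu = np.abs(net.nu)
    z = np.log(np.maximum(X0, 1e-300))

    def unscaled(X):
        return float(np.max(np.abs(_drift(net, X, check=False)))) + abs(m @ X - 1.0)

    best_X = np.exp(z)
    best = unscaled(best_X)
    for _ in range(6):  # rounds with refreshed row scaling
        if best <= tol:
            break
        X = np.exp(z)
        f = net.rate_values(X)
        lam = float(net.mass_production() @ f)
        scale = absnu @ f + abs(lam) * X
        scale = np.maximum(scale, np.max(scale) * 1e-14 + 1e-300)
        i0 = int(np.argmax(m * X))

        def fun(zz, scale=scale, i0=i0):
            Xz = np.exp(np.clip(zz, -250.0, 50.0))
            fz = net.rate_values(Xz)
            lamz = float(net.mass_production() @ fz)
            r = (net.nu @ fz - lamz * Xz) / scale
            r[i0] = m @ Xz - 1.0
            Jz = net.drift_jacobian(Xz) / scale[:, None]
            Jz[i0, :] = m
            return r, Jz * Xz[None, :]

        sol = root(fun, z, jac=True, method="hybr",
                   options={"xtol": 1e-14, "maxfev": 400 * net.N, "factor": 1.0})
        X_new = np.exp(np.clip(sol.x, -250.0, 50.0))
        cur = unscaled(X_new)
        if cur < best:
            best_X, best = X_new, cur
            z = sol.x
        else:
            break
    return best_X, best


def _ode_relax(net: ReactionNetwork, X0, t_end: float = 2e4):
    from scipy.integrate import solve_ivp

    def rhs(_, X):
        return _drift(net, np.maximum(X, 0.0), check=False)

    def jac(_, X):
        return net.drift_jacobian(np.maximum(X, 0.0))

    sol = solve_ivp(rhs, (0.0, t_end), X0, method="LSODA", jac=jac,
                    rtol=1e-10, atol=1e-16)
    X = np.maximum(sol.y[:, -1], 0.0)
    mx = float(net.mass @ X)
    return X / mx if mx > 0 else X


def steady_state_mean(
    net: ReactionNetwork,
    X0=None,
    tol: float = 1e-10,
    restarts: int = 10,
    seed: int = 0,
    lambda_min: float = 1e-9,
):
    """Solve the synthesis--dilution balance on the simplex.

    Returns ``(Xbar, lambdabar)`` with residual infinity-norm <= ``tol``.
    Falls back to ODE relaxation and seeded random restarts before giving
    up.  For growing networks, converged states with growth below
    ``lambda_min`` (the degenerate washout manifold of autocatalytic
    expression models) are rejected and retried from new starting points.
    """
    if X0 is None:
        if "p_r" in net.index and "a" in net.index:
            from .ecoli import initial_guess

            X0 = initial_guess(net)
        else:
            X0 = np.full(net.N, 1.0)
            X0 /= float(net.mass @ X0)
        X0 = np.maximum(X0, 1e-12)
    else:
        X0 = np.maximum(np.asarray(X0, dtype=np.float64), 1e-30)

    growing = (net.mass_production() > 0).any()

    def acceptable(X, res):
        if res > tol:
            return False
        return not growing or net.growth_rate(X, check=False) >= lambda_min

    X, res = _newton_log(net, X0, tol)
    best_X, best_res = X, res
    if not acceptable(X, res):
        X, res = _newton_log(net, _ode_relax(net, X0), tol)
        if acceptable(X, res) or res < best_res:
            best_X, best_res = X, res
    rng = np.random.default_rng(seed)
    attempt = 0
    while not acceptable(best_X, best_res) and attempt < restarts:
        pert = X0 * rng.lognormal(0.0, 1.0, size=net.N)
        pert /= float(net.mass @ pert)
        X, res = _newton_log(net, _ode_relax(net, pert, t_end=5e4), tol)
        if acceptable(X, res) or (res < best_res and not acceptable(best_X, best_res)):
            best_X, best_res = X, res
        attempt += 1
    if best_res > tol:
        raise SteadyStateError(
            f"steady-state solve did not converge (best residual {best_res:.3e})",
            residual=best_res,
        )
    if growing and net.growth_rate(best_X, check=False) < lambda_min:
        raise SteadyStateError(
            "only the non-growing (washout) state was found; "
            "supply a better initial guess X0", residual=best_res,
        )
    if (best_X < -tol).any():
        raise SteadyStateError("negative concentration at solution (model misconfiguration)")
    Xbar = np.maximum(best_X, 0.0)
    Xbar = Xbar / float(net.mass @ Xbar)
    return Xbar, net.growth_rate(Xbar)


def birth_state(lambdabar: float, O_c: float, tau_CD: float):
    """Mean birth mass, origin number and unit size from initiation control.

    ``M0 = exp(lambda tau_CD) / (2 O_c)``, ``O0 = exp(lambda tau_CD) / (2 ln 2)``;
    the unit size ``M0/O0 = ln 2 / O_c`` is independent of growth rate.
    """
    if O_c <= 0:
        raise ConfigurationError("O_c must be positive")
    ex = lambdabar * tau_CD
    if ex > 700.0:
        raise OverflowError("lambda * tau_CD too large (exponential overflow)")
    M0 = math.exp(ex) / (2.0 * O_c)
    O0 = math.exp(ex) / (2.0 * LN2)
    return M0, O0, LN2 / O_c


# -- covariance --------------------------------------------------------


def division_noise(net: ReactionNetwork, Xbar, form: str = "projected") -> np.ndarray:
    """Per-division binomial-partitioning covariance of concentrations.

    With independent Binomial(x_i, rho) partitioning, daughter
    concentrations are x_i' / (m^T x'), so each species' count noise is
    accompanied by the correlated fluctuation of the daughter mass in the
    denominator.  Propagating both gives the simplex-projected covariance

        Gamma = P diag(Xbar) P^T,   P = I - Xbar m^T,

    (per division, at the division mass, for an even split), which
    matches the sample kick variance of simulated divisions.  The mass
    direction is noise-free (``Gamma m = 0``): partitioning a fraction of
    the cell removes that fraction of every mass unit.

    ``form="diagonal-mass"`` selects the simpler moment expression
    ``X_i (delta_ij - m_i m_j X_j / sum_l m_l^2 X_l)``, which subtracts
    the mass correlation only pairwise and overestimates the kick for
    abundant mass-carrying species.
    """
    m = net.mass
    if form == "projected":
        P = np.eye(net.N) - np.outer(Xbar, m)
        return P @ np.diag(Xbar) @ P.T
    if form == "diagonal-mass":
        S = float((m**2) @ Xbar)
        return np.diag(Xbar) - np.outer(Xbar * m, m * Xbar) / S
    raise ConfigurationError(f"unknown division-noise form {form!r}")


def projected_stoichiometries(net: ReactionNetwork, Xbar) -> np.ndarray:
    """nu_tilde_r = nu_r - Xbar (m^T nu_r): reaction jumps in concentration space.

    Combines the direct stoichiometric kick with the simultaneous dilution
    kick from the mass the same event produces; both share one noise source,
    so their covariance is the outer product of the summed coefficient.
    """
    mnu = net.mass_production()
    return net.nu - np.outer(Xbar, mnu)


def _reduced_basis(m: np.ndarray) -> np.ndarray:
    return linalg.null_space(m.reshape(1, -1))


def _solve_lyapunov_reduced(J, Q, B, check_stability=True):
    Jr = B.T @ J @ B
    if check_stability:
        ev = np.linalg.eigvals(Jr)
        if (ev.real >= 0).any():
            raise SteadyStateError(
                f"unstable steady state (max Re eigenvalue {ev.real.max():.3e})"
            )
    S = linalg.solve_continuous_lyapunov(Jr, -(B.T @ Q @ B))
    S = 0.5 * (S + S.T)
    return B @ S @ B.T


def stationary_covariance(
    net: ReactionNetwork,
    Xbar,
    M0: float,
    lambdabar: float | None = None,
    include_division: bool = True,
    residual_tol: float = 1e-8,
):
    """Time-averaged concentration covariance from the Lyapunov equation.

    ``0 = J Sigma + Sigma J^T + (1/(2 M0 ln 2)) (lambda Gamma + sum_r D_r)``
    with ``D_r = nu_tilde_r nu_tilde_r^T f_r(Xbar)``.  Solved in the
    subspace orthogonal to the mass direction (where J is well conditioned)
    and embedded back; the division frequency ``lambda / ln 2`` is absorbed
    in the prefactor.

    Returns ``(Sigma, J, noise_terms)`` where ``noise_terms`` maps
    ``"division"`` and each reaction index to its share of the inhomogeneity.
    """
    Xbar = np.asarray(Xbar, dtype=np.float64)
    if lambdabar is None:
        lambdabar = net.growth_rate(Xbar, check=False)
    J = net.drift_jacobian(Xbar)
    pref = 1.0 / (2.0 * M0 * LN2)
    f = net.rate_values(Xbar)
    nut = projected_stoichiometries(net, Xbar)

    noise_terms: dict = {}
    Q = np.zeros((net.N, net.N))
    if include_division:
        Qdiv = pref * lambdabar * division_noise(net, Xbar)
        noise_terms["division"] = Qdiv
        Q = Q + Qdiv
    for r in range(net.R):
        Dr = pref * f[r] * np.outer(nut[:, r], nut[:, r])
        noise_terms[r] = Dr
        Q = Q + Dr

    B = _reduced_basis(net.mass)
    Sigma = _solve_lyapunov_reduced(J, Q, B)

    qn = np.max(np.abs(Q))
    resid = np.max(np.abs(J @ Sigma + Sigma @ J.T + Q))
    # Accept at the relative tolerance or at the double-precision floor of
    # evaluating J Sigma + Sigma J^T (cancellation of large opposing terms
    # when the Jacobian is stiff and ||Q|| << ||J|| ||Sigma||).
    floor = 100.0 * np.finfo(float).eps * np.max(np.abs(J)) * np.max(np.abs(Sigma)) * net.N
    if qn > 0 and resid > residual_tol * qn and resid > floor:
        raise SteadyStateError(
            f"Lyapunov residual {resid:.3e} exceeds {residual_tol:.1e} * ||Q||"
        )
    return Sigma, J, noise_terms


def _lambda_gradient(net: ReactionNetwork, Xbar, rel_step: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of lambda at Xbar (off-simplex perturbations)."""
    g = np.zeros(net.N)
    for i in range(net.N):
        h = rel_step * abs(Xbar[i]) + 1e-30
        Xp, Xm = Xbar.copy(), Xbar.copy()
        Xp[i] += h
        Xm[i] -= h
        g[i] = (net.growth_rate(Xp, check=False) - net.growth_rate(Xm, check=False)) / (2 * h)
    return g


def growth_rate_cv(net: ReactionNetwork, Xbar, Sigma, rel_step: float = 1e-6):
    """CV^2 of the instantaneous growth rate from concentration covariances.

    Evaluates the log-sensitivity quadratic form
    ``sum_ij (dln lambda/dln X_i) (Sigma_ij / (X_i X_j)) (dln lambda/dln X_j)``
    in its equivalent gradient form ``grad(lambda)^T Sigma grad(lambda) / lambda^2``,
    which is well defined also when some ``Xbar_i`` vanishes with zero
    sensitivity.  Returns ``(cv2, cv)``.
    """
    Xbar = np.asarray(Xbar, dtype=np.float64)
    lam = net.growth_rate(Xbar, check=False)
    grad = _lambda_gradient(net, Xbar, rel_step)
    zero = Xbar == 0.0
    if (zero & (grad != 0.0)).any():
        i = int(np.nonzero(zero & (grad != 0.0))[0][0])
        raise ConfigurationError(
            f"zero mean concentration with non-zero growth sensitivity "
            f"(species {net.species_names[i]!r})"
        )
    cv2 = float(grad @ np.asarray(Sigma) @ grad) / lam**2
    return cv2, math.sqrt(max(cv2, 0.0))


# -- noise decomposition ----------------------------------------------


def default_grouping(net: ReactionNetwork, per_sector: bool = True) -> dict:
    """Partition {division} + reactions by their group tags.

    With ``per_sector=False`` the sector suffix (after ``:``) is dropped,
    merging e.g. all transcription reactions into one group.
    """
    out: dict = {}
    for r, tag in enumerate(net.reaction_groups):
        key = tag if per_sector else tag.split(":")[0]
        out.setdefault(key, []).append(r)
    out["partitioning"] = ["division"]
    return out


def decompose_noise(
    net: ReactionNetwork,
    Xbar,
    M0: float,
    grouping: dict | None = None,
) -> pd.DataFrame:
    """Exact additive split of CV^2[lambda] into noise-source contributions.

    ``grouping`` maps group names to lists of reaction indices, with the
    string ``"division"`` standing for partitioning noise; it must be a
    partition of {division} + all reactions.  Per group the Lyapunov
    equation is re-solved with only that group's inhomogeneity; linearity
    guarantees the group covariances sum to the total and the growth-rate
    contributions to CV^2[lambda].
    """
    Xbar = np.asarray(Xbar, dtype=np.float64)
    lam = net.growth_rate(Xbar, check=False)
    Sigma, J, noise_terms = stationary_covariance(net, Xbar, M0, lam)
    if grouping is None:
        grouping = default_grouping(net)

    claimed: list = []
    for members in grouping.values():
        claimed.extend(members)
    expected = ["division"] + list(range(net.R))
    if sorted(claimed, key=str) != sorted(expected, key=str):
        raise ConfigurationError(
            "grouping is not a partition of {division} + reactions"
        )

    grad = _lambda_gradient(net, Xbar)
    B = _reduced_basis(net.mass)
    rows = []
    for name, members in grouping.items():
        Qg = np.zeros((net.N, net.N))
        for mem in members:
            Qg = Qg + noise_terms[mem]
        Sg = _solve_lyapunov_reduced(J, Qg, B, check_stability=False)
        cg = float(grad @ Sg @ grad) / lam**2
        rows.append({"group": name, "cv2_contribution": cg})
    table = pd.DataFrame(rows).set_index("group")
    total = float(table["cv2_contribution"].sum())
    table["fraction"] = table["cv2_contribution"] / total if total > 0 else 0.0
    table.attrs["cv2_lambda"] = float(grad @ Sigma @ grad) / lam**2
    return table


# -- results container and drivers ------------------------------------


@dataclass
class SNAResult:
    """Steady-state statistics of a reaction--division system."""

    net: ReactionNetwork
    Xbar: np.ndarray
    lambdabar: float               # per minute
    M0: float                      # mean birth mass (aa)
    O0: float                      # mean origin number at birth
    unit_size: float               # M0 / O0 = ln2 / O_c
    Sigma: np.ndarray
    J: np.ndarray
    noise_terms: dict = field(repr=False, default_factory=dict)
    cv2_lambda: float = math.nan
    decomposition: pd.DataFrame | None = None

    @property
    def lambdabar_dblhr(self) -> float:
        return self.lambdabar * DBLHR

    @property
    def tau(self) -> float:
        """Mean doubling time, minutes."""
        return LN2 / self.lambdabar

    @property
    def cv_lambda(self) -> float:
        return math.sqrt(max(self.cv2_lambda, 0.0))

    @property
    def M_bulk(self) -> float:
        """Population-average cell mass, neglecting within-cycle size spread."""
        return 2.0 * self.M0 * LN2

    def concentration(self, name: str) -> float:
        return float(self.Xbar[self.net.species_index(name)])

    def copy_number(self, name: str) -> float:
        """Mean molecule count per (bulk-average) cell."""
        return self.concentration(name) * self.M_bulk

    def concentration_cv(self, name: str) -> float:
        i = self.net.species_index(name)
        x = self.Xbar[i]
        return math.sqrt(max(self.Sigma[i, i], 0.0)) / x if x > 0 else math.nan


def solve(
    net: ReactionNetwork,
    O_c: float,
    tau_CD: float,
    X0=None,
    M0: float | None = None,
    decomposition: bool = False,
    grouping: dict | None = None,
    seed: int = 0,
) -> SNAResult:
    """Full small-noise solve: means, cell-cycle state, covariance, CV[lambda].

    ``M0`` may be supplied directly to bypass the replication-control birth
    law (useful for toy systems and mass-rescaling checks).
    """
    Xbar, lam = steady_state_mean(net, X0=X0, seed=seed)
    M0_law, O0, unit = birth_state(lam, O_c, tau_CD)
    if M0 is None:
        M0 = M0_law
    Sigma, J, noise_terms = stationary_covariance(net, Xbar, M0, lam)
    cv2, _ = growth_rate_cv(net, Xbar, Sigma)
    res = SNAResult(net, Xbar, lam, M0, O0, unit, Sigma, J, noise_terms, cv2)
    if decomposition:
        res.decomposition = decompose_noise(net, Xbar, M0, grouping=grouping)
    return res


def ribosomal_mass_fraction(net: ReactionNetwork, Xbar) -> float:
    """Mass fraction of ribosomes: free + translating + drug-inactivated."""
    names = [n for n in net.species_names
             if n == "p_r" or n.startswith("c_") or n.startswith("z_")]
    total = sum(net.mass[net.species_index(n)] * Xbar[net.species_index(n)] for n in names)
    return float(total)


def _phi_r_variance(net: ReactionNetwork, Xbar, Sigma) -> float:
    w = np.zeros(net.N)
    for n in net.species_names:
        if n == "p_r" or n.startswith("c_") or n.startswith("z_"):
            i = net.species_index(n)
            w[i] = net.mass[i]
    return float(w @ Sigma @ w)


def to_bulk(res: SNAResult) -> dict:
    """Bulk observables: population-average mass, ribosome fraction, copy numbers."""
    phi_r = ribosomal_mass_fraction(res.net, res.Xbar)
    var = _phi_r_variance(res.net, res.Xbar, res.Sigma)
    out = {
        "M_bulk": res.M_bulk,
        "lambdabar": res.lambdabar,
        "lambdabar_dblhr": res.lambdabar_dblhr,
        "phi_r": phi_r,
        "cv_phi_r": math.sqrt(max(var, 0.0)) / phi_r if phi_r > 0 else math.nan,
        "copy_numbers": {
            name: res.copy_number(name) for name in res.net.species_names
        },
    }
    return out


def solve_curve(
    p,
    ns_grid,
    variant: str = "full",
    decomposition: bool = False,
    grouping: dict | None = None,
    M0_scale: float = 1.0,
    X0=None,
) -> pd.DataFrame:
    """Sweep nutrient quality; one row of steady-state statistics per n_s.

    Solutions are warm-started along the grid.  ``M0_scale`` rescales the
    birth mass entering the noise prefactor (for reduced-mass checks).
    """
    from .ecoli import build_model

    rows = []
    X_first = None
    for ns in np.atleast_1d(ns_grid):
        net = build_model(p.replace(n_s=float(ns)), variant)
        try:
            Xbar, lam = steady_state_mean(net, X0=X0)
        except SteadyStateError:
            Xbar, lam = steady_state_mean(net)  # cold restart
        X0 = Xbar
        if X_first is None:
            X_first = Xbar
        M0, O0, unit = birth_state(lam, p.O_c, p.tau_CD)
        M0 *= M0_scale
        Sigma, J, noise_terms = stationary_covariance(net, Xbar, M0, lam)
        cv2, cv = growth_rate_cv(net, Xbar, Sigma)
        res = SNAResult(net, Xbar, lam, M0, O0, unit, Sigma, J, noise_terms, cv2)
        phi_r = ribosomal_mass_fraction(net, Xbar)
        var_phi = _phi_r_variance(net, Xbar, Sigma)
        row = {
            "n_s": float(ns),
            "lambdabar": lam,
            "lambdabar_dblhr": lam * DBLHR,
            "phi_r": phi_r,
            "cv_phi_r": math.sqrt(max(var_phi, 0.0)) / phi_r,
            "M0": M0,
            "O0": O0,
            "unit_size": unit,
            "M_bulk": res.M_bulk,
            "cv_lambda": cv,
            "cv2_lambda": cv2,
        }
        for name in net.species_names:
            row[f"X_{name}"] = float(Xbar[net.species_index(name)])
            row[f"copies_{name}"] = float(Xbar[net.species_index(name)] * res.M_bulk)
            row[f"cv_{name}"] = res.concentration_cv(name)
        if decomposition:
            table = decompose_noise(net, Xbar, M0, grouping=grouping)
            for g, c in table["cv2_contribution"].items():
                row[f"cv2[{g}]"] = float(c)
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["X_first"] = X_first
    return out


def saturated_growth_rate(p, variant: str = "full", ns_factor: float = 1e4,
                          X0=None, return_state: bool = False):
    """Growth rate (per min) at saturating nutrient quality."""
    from .ecoli import build_model

    net = build_model(p.replace(n_s=p.n_s * ns_factor), variant)
    Xbar, lam = steady_state_mean(net, X0=X0)
    return (lam, Xbar) if return_state else lam


def parameter_sensitivity(
    p,
    variant: str = "full",
    parameters=None,
    rel_step: float = 1e-3,
    M0: float | None = None,
) -> pd.DataFrame:
    """Elasticities d ln(target) / d ln(parameter) for mean growth and its CV.

    Each elasticity re-solves the full approximation at perturbed parameter
    values (central differences).  Failed perturbed solves are marked
    ``failed`` and the scan continues.
    """
    from .ecoli import build_model

    flat = p.flatten()
    if parameters is None:
        parameters = [k for k, v in flat.items() if v != 0]

    def targets(pp):
        net = build_model(pp, variant)
        Xbar, lam = steady_state_mean(net)
        if M0 is None:
            M0_use, _, _ = birth_state(lam, pp.O_c, pp.tau_CD)
        else:
            M0_use = M0
        Sigma, _, _ = stationary_covariance(net, Xbar, M0_use, lam)
        cv2, cv = growth_rate_cv(net, Xbar, Sigma)
        return lam, cv

    rows = []
    for name in parameters:
        v = flat[name]
        try:
            lam_p, cv_p = targets(p.replace(**{name: v * (1 + rel_step)}))
            lam_m, cv_m = targets(p.replace(**{name: v * (1 - rel_step)}))
            dln = 2.0 * rel_step
            rows.append({
                "parameter": name,
                "elasticity_lambdabar": (math.log(lam_p) - math.log(lam_m)) / dln,
                "elasticity_cv_lambda": (math.log(cv_p) - math.log(cv_m)) / dln,
                "failed": False,
            })
        except (SteadyStateError, OverflowError, ValueError):
            rows.append({
                "parameter": name,
                "elasticity_lambdabar": math.nan,
                "elasticity_cv_lambda": math.nan,
                "failed": True,
            })
    return pd.DataFrame(rows).set_index("parameter")
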