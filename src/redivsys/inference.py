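"""Parameter estimation from growth observables via the analytic solver.

The closed-form small-noise statistics make likelihood evaluations cheap
enough for ensemble MCMC: predictions of the bulk ribosomal-mass-fraction
curve and of the single-cell growth-rate noise curve are matched to
observations under independent Gaussian errors.  A synthetic-observation
generator emulates the two calibration curves so the machinery runs
without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd

from .core import ConfigurationError
from .ecoli import ParameterSet, build_model
from . import sna

__all__ = [
    "ObservationSet",
    "generate_synthetic_observations",
    "MCMCConfig",
    "FitResult",
    "fit_parameters",
    "LAMBDA_MAX_DBLHR",
]

# hard physiological constraint on saturated growth (doublings per hour)
LAMBDA_MAX_DBLHR = 3.75


@dataclass
class ObservationSet:
    """Calibration observations on a nutrient-quality grid.

    ``bulk``: one row per condition with mean growth rate (dbl/hr),
    ribosomal mass fraction and its sd.  ``single_cell``: growth rate
    (dbl/hr), CV^2 of the instantaneous growth rate and its sd.  The
    ``ns_grid`` records the conditions so model predictions can be made
    at matching nutrient qualities.
    """

    bulk: pd.DataFrame
    single_cell: pd.DataFrame
    ns_grid: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for df, cols in ((self.bulk, ("lambdabar_dblhr", "phi_r", "sd")),
                         (self.single_cell, ("lambdabar_dblhr", "cv2_lambda", "sd"))):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise ConfigurationError(f"observation table missing columns {missing}")
            if (df["sd"] <= 0).any():
                raise ConfigurationError("observation sds must be positive")

    def save(self, bulk_path, sc_path) -> None:
        self.bulk.to_csv(bulk_path, sep="\t", index=False)
        self.single_cell.to_csv(sc_path, sep="\t", index=False)


def _predict(p: ParameterSet, ns_grid, variant: str = "full", X0=None):
    df = sna.solve_curve(p, ns_grid, variant=variant, X0=X0)
    out = df[["n_s", "lambdabar_dblhr", "phi_r", "cv2_lambda"]]
    out.attrs["X_first"] = df.attrs.get("X_first")
    return out


def generate_synthetic_observations(
    p_true: ParameterSet,
    ns_grid,
    noise_sd_phi: float = 0.01,
    noise_sd_cv2: float = 0.1,
    seed: int = 0,
    variant: str = "full",
    predictions: pd.DataFrame | None = None,
) -> ObservationSet:
    """Emulate the two calibration curves with Gaussian measurement noise.

    ``noise_sd_phi`` is the absolute sd on the ribosomal mass fraction;
    ``noise_sd_cv2`` the *relative* sd on CV^2 of growth rate (scaled per
    point).  Grid points where the analytic solve fails are dropped with a
    log entry in ``provenance``.  ``predictions`` may supply a precomputed
    noise-free curve (as from :func:`redivsys.sna.solve_curve`) to avoid
    re-solving when many replicate observation sets are drawn.
    """
    rng = np.random.default_rng(seed)
    rows_b, rows_s, dropped, kept = [], [], [], []
    grid = [float(v) for v in np.atleast_1d(ns_grid)]
    if predictions is not None:
        pred_by_ns = {float(row["n_s"]): row for _, row in predictions.iterrows()}
    else:
        try:
            preds = _predict(p_true, grid, variant)
            pred_by_ns = {row["n_s"]: row for _, row in preds.iterrows()}
        except sna.SteadyStateError:
            pred_by_ns = None  # fall back to per-point solves below
    for ns_val in grid:
        if pred_by_ns is not None:
            pred = pred_by_ns[ns_val]
        else:
            try:
                pred = _predict(p_true.replace(n_s=ns_val), [ns_val], variant).iloc[0]
            except sna.SteadyStateError as err:
                dropped.append({"n_s": ns_val, "reason": str(err)})
                continue
        kept.append(float(ns_val))
        sd_cv2 = max(noise_sd_cv2 * pred["cv2_lambda"], 1e-12)
        rows_b.append({
            "lambdabar_dblhr": pred["lambdabar_dblhr"],
            "phi_r": pred["phi_r"] + (rng.normal(0.0, noise_sd_phi) if noise_sd_phi > 0 else 0.0),
            "sd": max(noise_sd_phi, 1e-12),
        })
        rows_s.append({
            "lambdabar_dblhr": pred["lambdabar_dblhr"],
            "cv2_lambda": pred["cv2_lambda"] + (rng.normal(0.0, sd_cv2) if noise_sd_cv2 > 0 else 0.0),
            "sd": sd_cv2,
        })
    return ObservationSet(
        bulk=pd.DataFrame(rows_b),
        single_cell=pd.DataFrame(rows_s),
        ns_grid=np.asarray(kept, dtype=float),
        provenance={"seed": seed, "true_params": p_true.to_dict(),
                    "dropped": dropped, "variant": variant},
    )


@dataclass
class MCMCConfig:
    walkers: int = 10
    steps: int = 400
    burn: int = 150
    seed: int = 0
    check_lambda_max: bool = True


@dataclass
class FitResult:
    samples: np.ndarray          # (n_samples, n_params), natural scale
    chain: np.ndarray            # full chain, log scale
    free_params: list
    map_estimate: dict
    acceptance_fraction: float
    n_failed_solves: int
    truth: dict | None = None

    def quantiles(self, qs=(0.05, 0.5, 0.95)) -> pd.DataFrame:
        out = {
            name: np.quantile(self.samples[:, j], qs)
            for j, name in enumerate(self.free_params)
        }
        return pd.DataFrame(out, index=[f"q{int(100 * q)}" for q in qs]).T

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=self.free_params)


DEFAULT_FREE = ["w_t", "w_e", "w_r", "w_q"]


def fit_parameters(
    obs: ObservationSet,
    p_base: ParameterSet,
    free_params: list | None = None,
    priors: dict | None = None,
    mcmc: MCMCConfig | None = None,
    variant: str = "full",
) -> FitResult:
    """Ensemble-MCMC fit of selected parameters to the observation curves.

    Parameters are sampled in log space under bounded log-uniform priors
    (default: two decades around the base value).  The likelihood is a
    product of independent Gaussians of the analytic predictions against
    the observed ribosome fractions and growth-rate CV^2; saturated growth
    above 3.75 dbl/hr is excluded by prior truncation.  Failed analytic
    solves count as rejected proposals and are reported.
    """
    free = list(free_params) if free_params is not None else list(DEFAULT_FREE)
    mcmc = mcmc or MCMCConfig()
    flat0 = p_base.flatten()
    for name in free:
        if name not in flat0:
            raise ConfigurationError(f"unknown free parameter {name!r}")

    bounds = {}
    for name in free:
        if priors and name in priors:
            bounds[name] = (math.log(priors[name][0]), math.log(priors[name][1]))
        else:
            bounds[name] = (math.log(flat0[name] / 10.0), math.log(flat0[name] * 10.0))

    ns_grid = np.asarray(obs.ns_grid, dtype=float)
    phi_obs = obs.bulk["phi_r"].to_numpy()
    phi_sd = obs.bulk["sd"].to_numpy()
    cv2_obs = obs.single_cell["cv2_lambda"].to_numpy()
    cv2_sd = obs.single_cell["sd"].to_numpy()

    failures = [0]
    warm = {"X0": None, "X0_sat": None}

    def loglike(theta):
        for val, name in zip(theta, free):
            lo, hi = bounds[name]
            if not (lo <= val <= hi):
                return -np.inf
        p = p_base.replace(**{name: math.exp(v) for name, v in zip(free, theta)})
        try:
            if mcmc.check_lambda_max:
                lam_sat, X_sat = sna.saturated_growth_rate(
                    p, variant=variant, X0=warm["X0_sat"], return_state=True)
                warm["X0_sat"] = X_sat
                if lam_sat * sna.DBLHR > LAMBDA_MAX_DBLHR:
                    return -np.inf
            pred = _predict(p, ns_grid, variant, X0=warm["X0"])
            warm["X0"] = pred.attrs.get("X_first")
        except (sna.SteadyStateError, ConfigurationError, OverflowError, ValueError):
            failures[0] += 1
            return -np.inf
        resid_phi = (pred["phi_r"].to_numpy() - phi_obs) / phi_sd
        resid_cv2 = (pred["cv2_lambda"].to_numpy() - cv2_obs) / cv2_sd
        return -0.5 * float(resid_phi @ resid_phi + resid_cv2 @ resid_cv2)

    rng = np.random.default_rng(mcmc.seed)
    ndim = len(free)
    theta0 = np.array([math.log(flat0[name]) for name in free])
    p0 = theta0[None, :] + 0.01 * rng.standard_normal((mcmc.walkers, ndim))

    sampler = emcee.EnsembleSampler(mcmc.walkers, ndim, loglike)
    sampler._random = np.random.RandomState(int(rng.integers(2**31 - 1)))
    sampler.run_mcmc(p0, mcmc.steps, progress=False)
    chain = sampler.get_chain(discard=mcmc.burn, flat=True)
    lnp = sampler.get_log_prob(discard=mcmc.burn, flat=True)
    best = int(np.argmax(lnp))
    samples = np.exp(chain)
    return FitResult(
        samples=samples,
        chain=sampler.get_chain(),
        free_params=free,
        map_estimate={name: float(samples[best, j]) for j, name in enumerate(free)},
        acceptance_fraction=float(np.mean(sampler.acceptance_fraction)),
        n_failed_solves=failures[0],
        truth=obs.provenance.get("true_params"),
    )
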