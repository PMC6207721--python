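"""Orchestration: nutrient x antibiotic scans and reproducible config runs.

Package-wide unit conventions: time in minutes, mass in amino-acid units,
concentrations per unit mass; growth rates are reported both per minute
and in doublings per hour (factor 60 / ln 2).
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ConfigurationError
from .ecoli import ParameterSet, build_model, load_default_parameters, default_fixture_checksum
from . import sna

__all__ = ["scan", "run_config"]


def scan(p: ParameterSet, ns_grid, xcm_grid, variant: str = "cm") -> dict:
    """Map mean growth and growth heterogeneity over nutrient x drug doses.

    For every (n_s, X_cm) combination the analytic solver yields the mean
    growth rate and CV of the instantaneous growth rate.  Returns matrices
    (DataFrames indexed by n_s, columns X_cm) plus, per nutrient quality,
    the dose minimising growth heterogeneity.  Failed combinations are
    recorded as NaN and the scan continues.
    """
    ns_grid = np.atleast_1d(np.asarray(ns_grid, dtype=float))
    xcm_grid = np.atleast_1d(np.asarray(xcm_grid, dtype=float))
    lam = np.full((ns_grid.size, xcm_grid.size), np.nan)
    cv = np.full((ns_grid.size, xcm_grid.size), np.nan)

    for i, ns_val in enumerate(ns_grid):
        X0 = None
        for j, xcm in enumerate(xcm_grid):
            net = build_model(p.replace(n_s=float(ns_val), X_cm=float(xcm)), variant)
            try:
                try:
                    Xbar, lam_ij = sna.steady_state_mean(net, X0=X0)
                except sna.SteadyStateError:
                    Xbar, lam_ij = sna.steady_state_mean(net)
                M0, _, _ = sna.birth_state(lam_ij, p.O_c, p.tau_CD)
                Sigma, _, _ = sna.stationary_covariance(net, Xbar, M0, lam_ij)
                _, cv_ij = sna.growth_rate_cv(net, Xbar, Sigma)
            except (sna.SteadyStateError, ConfigurationError):
                X0 = None
                continue
            X0 = Xbar
            lam[i, j] = lam_ij * sna.DBLHR
            cv[i, j] = cv_ij

    lam_df = pd.DataFrame(lam, index=ns_grid, columns=xcm_grid)
    cv_df = pd.DataFrame(cv, index=ns_grid, columns=xcm_grid)
    lam_df.index.name = cv_df.index.name = "n_s"
    lam_df.columns.name = cv_df.columns.name = "X_cm"

    min_dose = {}
    for i, ns_val in enumerate(ns_grid):
        row = cv[i]
        if np.isnan(row).all():
            min_dose[ns_val] = np.nan
        else:
            min_dose[ns_val] = float(xcm_grid[int(np.nanargmin(row))])
    return {
        "lambda_dblhr": lam_df,
        "cv_lambda": cv_df,
        "min_cv_dose": pd.Series(min_dose, name="X_cm_min_cv").rename_axis("n_s"),
    }


_TASKS = ("sna", "sweep", "scan", "simulate")


def run_config(config, outdir) -> dict:
    """Execute a JSON-described task and write outputs plus a manifest.

    The config names the model variant, the parameter source, a task from
    ``{"sna", "sweep", "scan", "simulate"}`` with its grids/sizes, and a
    seed.  All outputs are TSV; the manifest records inputs, the parameter
    fixture checksum, seeds and package versions so a run can be repeated
    bit-for-bit.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = json.load(fh)
    else:
        cfg = dict(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    task = cfg.get("task")
    if task not in _TASKS:
        raise ConfigurationError(f"config key 'task' must be one of {_TASKS}, got {task!r}")
    variant = cfg.get("variant", "full")
    seed = int(cfg.get("seed", 0))
    if "parameters" in cfg:
        p = ParameterSet.from_dict(cfg["parameters"])
        param_source = "inline"
    elif "parameter_file" in cfg:
        p = ParameterSet.load(cfg["parameter_file"])
        param_source = str(cfg["parameter_file"])
    else:
        p = load_default_parameters()
        param_source = "packaged default (synthetic)"
    if "overrides" in cfg:
        p = p.replace(**cfg["overrides"])

    outputs = []
    if task == "sna":
        df = sna.solve_curve(p, [p.n_s], variant=variant, decomposition=True)
        path = outdir / "sna.tsv"
        df.to_csv(path, sep="\t", index=False)
        outputs.append(path.name)
    elif task == "sweep":
        grid = cfg.get("ns_grid")
        if grid is None:
            raise ConfigurationError("config key 'ns_grid' required for task 'sweep'")
        df = sna.solve_curve(p, grid, variant=variant,
                             decomposition=cfg.get("decomposition", False))
        path = outdir / "sweep.tsv"
        df.to_csv(path, sep="\t", index=False)
        outputs.append(path.name)
    elif task == "scan":
        for key in ("ns_grid", "xcm_grid"):
            if key not in cfg:
                raise ConfigurationError(f"config key {key!r} required for task 'scan'")
        res = scan(p, cfg["ns_grid"], cfg["xcm_grid"],
                   variant=cfg.get("variant", "cm"))
        for name, obj in res.items():
            path = outdir / f"scan_{name}.tsv"
            obj.to_csv(path, sep="\t")
            outputs.append(path.name)
    elif task == "simulate":
        from .simulate import SimulatorConfig, simulate_lineages

        net = build_model(p, variant)
        n_cells = int(cfg.get("cells", 1))
        sim_cfg = SimulatorConfig(
            n_divisions=int(cfg.get("divisions", 20)),
            seed=seed,
            sample_dt=float(cfg.get("sample_dt", 0.1)),
        )
        for k, traj in enumerate(simulate_lineages(net, n_cells, sim_cfg)):
            frame = pd.DataFrame(traj.X, columns=net.species_names)
            frame.insert(0, "t", traj.times)
            frame["M"] = traj.M
            frame["growth_rate"] = traj.lam
            frame["O"] = traj.O
            frame["D"] = traj.D
            path = outdir / f"trajectory_{k:03d}.tsv"
            frame.to_csv(path, sep="\t", index=False)
            outputs.append(path.name)
            epath = outdir / f"events_{k:03d}.tsv"
            traj.divisions.to_csv(epath, sep="\t", index=False)
            outputs.append(epath.name)

    from . import __version__

    manifest = {
        "config": cfg,
        "task": task,
        "variant": variant,
        "seed": seed,
        "parameter_source": param_source,
        "parameters": p.to_dict(),
        "fixture_sha256": default_fixture_checksum(),
        "outputs": outputs,
        "versions": {
            "redivsys": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
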