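"""Experiment driver: sweeps, stability curves and their tables and figures."""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SWEEP_COLUMNS, ExperimentConfig, write_tables
from .demography import GroupType
from .equilibrium import SweepRecord, optimal_group_size, theta_sweep
from .stability import minimum_relatedness

__all__ = [
    "run_experiment",
    "sweep_frame",
    "per_n_frame",
    "rmin_frame",
]


def sweep_frame(records: list[SweepRecord]) -> pd.DataFrame:
    """Flatten sweep records into the canonical per-(theta, type, N) table."""
    rows = []
    for rec in records:
        for res in rec.table:
            rows.append(
                {
                    "theta": rec.theta,
                    "group_type": rec.group_type.value,
                    "N": res.strategy.n,
                    "xbar_N": res.xbar_n if res.feasible else np.nan,
                    "K_rel": res.k_rel if res.feasible else np.nan,
                    "feasible": res.feasible,
                    "is_opt": res.feasible and res.strategy.n == rec.n_opt,
                }
            )
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def per_n_frame(config: ExperimentConfig) -> pd.DataFrame:
    """Per-N equilibrium table at one fixed theta (group-size profile)."""
    params = config.params.to_params()
    records = [
        optimal_group_size(gt, config.equilibrium_theta, params, n_max=config.n_max_override)
        for gt in config.group_types
    ]
    return sweep_frame(records)


def rmin_frame(config: ExperimentConfig) -> pd.DataFrame:
    """Minimum-relatedness curve over the theta grid at optimal group size."""
    params = config.params.to_params()
    rows = []
    for theta in config.theta_grid:
        rec = optimal_group_size(GroupType.EUSOCIAL, theta, params, n_max=config.n_max_override)
        if rec.n_opt < 2:
            rows.append({"theta": theta, "N_opt": rec.n_opt, "r_min": np.nan, "defined": False})
            continue
        stab = minimum_relatedness(theta, params, n=rec.n_opt, xbar_pop=rec.xbar_at_opt)
        rows.append(
            {"theta": theta, "N_opt": rec.n_opt, "r_min": stab.r_min, "defined": stab.defined}
        )
    return pd.DataFrame(rows, columns=["theta", "N_opt", "r_min", "defined"])


def _config_hash(config: ExperimentConfig) -> str:
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_experiment(config: ExperimentConfig, make_plots: bool = True) -> dict[str, Path]:
    """Run the full analysis described by ``config`` and write its outputs.

    Produces the theta sweep (per-theta optimal group sizes and resource
    requirements), a per-N equilibrium profile at ``equilibrium_theta``, the
    minimum-relatedness curve, optional figures, and a manifest recording
    the configuration hash and library versions.  Identical configurations
    yield byte-identical CSVs.
    """
    params = config.params.to_params()
    out_dir = Path(config.output_dir)

    records = theta_sweep(config.group_types, config.theta_grid, params, n_max=config.n_max_override)
    sweep = sweep_frame(records)
    per_n = per_n_frame(config)
    rmin = rmin_frame(config)

    paths = write_tables({"sweep": sweep, "equilibrium_per_n": per_n, "rmin": rmin}, out_dir)
    outputs = {p.stem: p for p in paths}

    if make_plots:
        from .plotting import plot_per_n_profile, plot_rmin_curve, plot_theta_sweep

        outputs["sweep_plot"] = plot_theta_sweep(sweep, out_dir / "sweep.png")
        outputs["equilibrium_plot"] = plot_per_n_profile(per_n, out_dir / "equilibrium_per_n.png")
        outputs["rmin_plot"] = plot_rmin_curve(rmin, out_dir / "rmin.png")

    manifest = {
        "config": config.model_dump(mode="json"),
        "config_sha256": _config_hash(config),
        "seed": config.oracle.seed,
        "versions": {
            "groupforage": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    outputs["manifest"] = manifest_path
    return outputs
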