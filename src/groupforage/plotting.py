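"""Figure helpers for the experiment driver (conveniences; CSVs are canonical)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_theta_sweep", "plot_per_n_profile", "plot_rmin_curve"]

_MARKERS = {"egalitarian": "o", "eusocial": "^"}


def plot_theta_sweep(sweep: pd.DataFrame, path: Path) -> Path:
    """Resource requirement and optimal group size against environmental variance."""
    opt = sweep[sweep["is_opt"]]
    fig, (ax_x, ax_n) = plt.subplots(2, 1, figsize=(5, 7), sharex=True)
    for gt, block in opt.groupby("group_type"):
        ax_x.plot(block["theta"], block["xbar_N"], marker=_MARKERS[gt], label=gt)
        ax_n.plot(block["theta"], block["N"], marker=_MARKERS[gt], label=gt)
    ax_x.set_ylabel(r"resources needed $\bar{x}_{N_{opt}}$")
    ax_n.set_ylabel(r"optimal group size $N_{opt}$")
    ax_n.set_xlabel(r"environmental variance $\theta$")
    ax_x.set_xscale("log")
    ax_x.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_per_n_profile(per_n: pd.DataFrame, path: Path) -> Path:
    """Equilibrium requirement and relative carrying capacity against group size."""
    feasible = per_n[per_n["feasible"]]
    fig, (ax_x, ax_k) = plt.subplots(1, 2, figsize=(9, 4))
    for gt, block in feasible.groupby("group_type"):
        ax_x.plot(block["N"], block["xbar_N"], marker=_MARKERS[gt], label=gt)
        ax_k.plot(block["N"], block["K_rel"], marker=_MARKERS[gt], label=gt)
    ax_x.set_xlabel("group size $N$")
    ax_x.set_ylabel(r"resources needed $\bar{x}_N$")
    ax_k.set_xlabel("group size $N$")
    ax_k.set_ylabel("carrying capacity $K(N)/K(1)$")
    ax_x.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_rmin_curve(rmin: pd.DataFrame, path: Path) -> Path:
    """Minimum stabilizing relatedness against environmental variance."""
    fig, ax = plt.subplots(figsize=(5, 4))
    defined = rmin[rmin["defined"]]
    ax.plot(defined["theta"], defined["r_min"], marker="s", color="tab:red")
    ax.set_xscale("log")
    ax.set_xlabel(r"environmental variance $\theta$")
    ax.set_ylabel(r"minimum relatedness $r_{min}$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
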