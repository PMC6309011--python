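"""Equilibrium resource requirements, carrying capacity and optimal group size.

In a habitat with a fixed total resource supply, per-capita resource
availability falls as the population grows; the population settles where
per-capita natality balances per-capita mortality.  Solving that implicit
condition gives the minimal mean amount of resources ``xbar_N`` that a
strategy (group type and size ``N``) needs per individual at equilibrium.
The carrying capacity is then ``K = X / xbar_N`` for a habitat holding ``X``
resources, so the strategy that minimizes ``xbar_N`` also maximizes its
equilibrium population size — the most resource-efficient group size is the
optimal one, and ``xbar_1 / xbar_N > 1`` marks supersaturation relative to
solitary life.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .demography import GroupStrategy, GroupType, mean_mortality, natality
from .resource_model import ModelParams

__all__ = [
    "EquilibriumResult",
    "SweepRecord",
    "carrying_capacity",
    "default_theta_grid",
    "equilibrium_requirement",
    "eusocial_max_group_size",
    "optimal_group_size",
    "theta_sweep",
]

#: Relative tolerance of the bracketing root refinement.
ROOT_RTOL = 1e-12
#: Points of the geometric scan locating the sign change of ``phi - mu``.
SCAN_POINTS = 32
#: Group-size search margin beyond the eusocial feasibility bound
#: ``f_max / m_b``, so infeasibility at the boundary is confirmed, not assumed.
N_SEARCH_MARGIN = 2


@dataclass(frozen=True)
class EquilibriumResult:
    """Solution of the natality/mortality balance for one strategy.

    ``xbar_n`` is the minimal per-capita resource level at which the
    strategy's natality equals its mortality; ``feasible`` is False when no
    such level exists (the strategy cannot persist at any resource level, as
    for eusocial groups larger than ``f_max / m_b``).  ``k_rel`` is the
    carrying capacity relative to the solitary strategy, ``xbar_1 / xbar_n``,
    when the solitary requirement is known.
    """

    strategy: GroupStrategy
    theta: float
    xbar_n: float | None
    residual: float | None
    feasible: bool
    bracket: tuple[float, float] | None = None
    k_rel: float | None = None

    def with_k_rel(self, xbar_solitary: float) -> "EquilibriumResult":
        if not self.feasible:
            return self
        return EquilibriumResult(
            strategy=self.strategy,
            theta=self.theta,
            xbar_n=self.xbar_n,
            residual=self.residual,
            feasible=True,
            bracket=self.bracket,
            k_rel=xbar_solitary / self.xbar_n,
        )


@dataclass(frozen=True)
class SweepRecord:
    """Per-theta summary of a group-size scan for one group type."""

    theta: float
    group_type: GroupType
    n_opt: int
    xbar_at_opt: float
    k_rel_at_opt: float
    table: tuple[EquilibriumResult, ...] = field(repr=False, default=())


def eusocial_max_group_size(params: ModelParams) -> int:
    """Largest eusocial group size not excluded by ``f_max / N > m_b``."""
    if params.m_b == 0:
        raise ValueError("eusocial group size is unbounded at zero baseline mortality")
    return math.ceil(params.f_max / params.m_b)


def equilibrium_requirement(
    strategy: GroupStrategy,
    theta: float,
    params: ModelParams,
) -> EquilibriumResult:
    """Solve the balance ``phi(xbar) = mu(xbar)`` for the minimal root.

    Scans a geometric grid of resource levels from just above the survival
    threshold to ``o_m + 10 * c0 * f_max`` for the first sign change of
    ``phi - mu`` (natality is increasing and mortality decreasing in the
    resource level, so the root is unique) and refines it by Brent's
    bracketing method.  Infeasible strategies — where natality is bounded
    below mortality, e.g. eusocial groups with ``f_max / N <= m_b`` —
    return ``feasible=False`` rather than raising.
    """
    p = params.with_theta(theta)
    if (
        strategy.group_type is GroupType.EUSOCIAL
        and p.f_max / strategy.n <= p.m_b
    ):
        return EquilibriumResult(strategy, theta, None, None, feasible=False)

    def g(xbar: float) -> float:
        return natality(strategy, xbar, p) - mean_mortality(strategy, xbar, p)

    lo = p.o_m * (1.0 + 1e-6) if p.o_m > 0 else 1e-9
    hi = p.o_m + 10.0 * p.c0 * p.f_max
    grid = np.geomspace(lo, hi, SCAN_POINTS)
    x_prev = grid[0]
    g_prev = g(x_prev)
    if g_prev >= 0.0:
        # Root, if any, sits at or below the scan start; report the start.
        return EquilibriumResult(
            strategy, theta, float(x_prev), abs(g_prev), feasible=True,
            bracket=(float(x_prev), float(x_prev)),
        )
    for x in grid[1:]:
        g_x = g(x)
        if g_x >= 0.0:
            root = optimize.brentq(g, x_prev, x, rtol=ROOT_RTOL)
            return EquilibriumResult(
                strategy, theta, float(root), abs(g(root)), feasible=True,
                bracket=(float(x_prev), float(x)),
            )
        x_prev, g_prev = x, g_x
    return EquilibriumResult(strategy, theta, None, None, feasible=False)


def carrying_capacity(total_resources: float, xbar_n: float) -> float:
    """Equilibrium population size ``K = X / xbar_n``."""
    if not total_resources > 0:
        raise ValueError(f"total_resources must be positive, got {total_resources}")
    if not xbar_n > 0:
        raise ValueError(f"xbar_n must be positive, got {xbar_n}")
    return total_resources / xbar_n


def optimal_group_size(
    group_type: GroupType | str,
    theta: float,
    params: ModelParams,
    n_max: int | None = None,
) -> SweepRecord:
    """Exhaustively scan group sizes and return the most resource-efficient.

    Group sizes ``1 .. ceil(f_max / m_b) + 2`` (or ``n_max``) are solved one
    by one; the optimum minimizes the feasible equilibrium requirement
    ``xbar_N``, with ties broken toward the smaller group.  Because ``K = X /
    xbar_N``, the same size maximizes carrying capacity.
    """
    group_type = GroupType(group_type)
    if n_max is None:
        n_max = eusocial_max_group_size(params) + N_SEARCH_MARGIN
    results: list[EquilibriumResult] = []
    best: EquilibriumResult | None = None
    xbar_solitary: float | None = None
    for n in range(1, n_max + 1):
        res = equilibrium_requirement(GroupStrategy(group_type, n), theta, params)
        if n == 1:
            if not res.feasible:
                raise ArithmeticError(
                    f"solitary strategy infeasible at theta={theta}; no optimum exists"
                )
            xbar_solitary = res.xbar_n
        res = res.with_k_rel(xbar_solitary) if res.feasible else res
        results.append(res)
        if res.feasible and (best is None or res.xbar_n < best.xbar_n - 1e-12):
            best = res
    if best is None:
        raise ArithmeticError(f"no feasible group size for {group_type} at theta={theta}")
    return SweepRecord(
        theta=theta,
        group_type=group_type,
        n_opt=best.strategy.n,
        xbar_at_opt=best.xbar_n,
        k_rel_at_opt=best.k_rel,
        table=tuple(results),
    )


def default_theta_grid(n_points: int = 48, low: float = 0.1, high: float = 16.0) -> np.ndarray:
    """Log-spaced environmental-variance grid used for the sweeps."""
    return np.geomspace(low, high, n_points)


def theta_sweep(
    group_types: list[GroupType | str],
    theta_grid: np.ndarray | list[float],
    params: ModelParams,
    n_max: int | None = None,
) -> list[SweepRecord]:
    """One :class:`SweepRecord` per (group type, theta) pair, deterministic."""
    theta_grid = np.asarray(theta_grid, dtype=float)
    if theta_grid.size == 0:
        raise ValueError("theta_grid must be nonempty")
    if theta_grid.size > 1 and not np.all(np.diff(theta_grid) > 0):
        raise ValueError("theta_grid must be strictly increasing")
    return [
        optimal_group_size(gt, float(theta), params, n_max=n_max)
        for gt in group_types
        for theta in theta_grid
    ]
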