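"""Evolutionary stability of eusocial groups and pairwise invasibility.

Subordinates in a eusocial group never reproduce directly; their payoff is
indirect — relatedness ``r`` times the offspring the dominant produces over
the subordinate's association with the group.  A subordinate should stay
only if that indirect payoff beats what it would earn by defecting: living
as a solitary forager at the resource level set by the resident population,
plus the (reduced) indirect payoff from the group it left behind.  Both
payoffs are affine in ``r``, so the break-even relatedness ``r_min`` has a
closed form; groups are stable for ``r > r_min``.

Invasibility is assessed with lifetime reproductive success ``psi``:
a rare invader strategy grows in a resident population exactly when its
``psi``, evaluated at the resident's equilibrium resource level, exceeds 1.
Because ``psi`` increases with resource availability, the strategy with the
lowest equilibrium requirement is uninvadable — optimality (carrying-
capacity maximization) and invasibility coincide in this model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography import GroupStrategy, GroupType, lifetime_reproductive_success
from .equilibrium import equilibrium_requirement, optimal_group_size
from .resource_model import ModelParams

__all__ = [
    "InvasionCell",
    "StabilityResult",
    "inclusive_fitness_defector",
    "inclusive_fitness_subordinate",
    "invasion_fitness",
    "minimum_relatedness",
    "pairwise_invasibility_grid",
]


@dataclass(frozen=True)
class StabilityResult:
    """Minimum relatedness stabilizing a eusocial group of size ``n``.

    ``defined`` is False when no relatedness in ``[0, 1]`` balances the
    subordinate's and the defector's inclusive fitness (``r_min`` keeps the
    raw solution, possibly > 1 or negative, for diagnostics).
    """

    n: int
    theta: float
    r_min: float
    defined: bool
    phi_sub_at_rmin: float
    phi_def_at_rmin: float
    xbar_pop: float


@dataclass(frozen=True)
class InvasionCell:
    """Invasion fitness ``psi`` of a rare invader against a resident."""

    resident: GroupStrategy
    invader: GroupStrategy
    theta: float
    psi: float
    xbar_resident: float


def _eusocial_lrs(k: int, xbar_pop: float, params: ModelParams) -> float:
    """Per-capita lifetime reproductive success of a size-``k`` eusocial group.

    ``k == 1`` is the solitary forager (the eusocial rule degenerates to it).
    """
    return lifetime_reproductive_success(
        GroupStrategy(GroupType.EUSOCIAL, k), xbar_pop, params
    )


def inclusive_fitness_subordinate(
    n: int,
    theta: float,
    r: float,
    params: ModelParams,
    xbar_pop: float,
) -> float:
    """Inclusive fitness of a subordinate staying in a group of size ``n``.

    Relatedness ``r`` times the dominant's fertility ``n * phi`` accumulated
    over the subordinate's life expectancy ``1 / mu``:
    ``Phi_sub = r * n * phi(n, xbar_pop) / mu(n, xbar_pop)``.
    """
    if n < 2:
        raise ValueError("a subordinate requires a group of size >= 2")
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"relatedness must be in [0, 1], got {r}")
    p = params.with_theta(theta)
    return r * n * _eusocial_lrs(n, xbar_pop, p)


def inclusive_fitness_defector(
    n: int,
    theta: float,
    r: float,
    params: ModelParams,
    xbar_pop: float,
) -> float:
    """Inclusive fitness of a subordinate defecting to solitary life.

    Direct fitness as a solitary forager at the resident resource level,
    plus relatedness-weighted indirect fitness from the remaining group of
    size ``n - 1``:
    ``Phi_def = psi(1, xbar_pop) + r * (n-1) * phi(n-1, xbar_pop) / mu(n-1, xbar_pop)``.
    """
    if n < 2:
        raise ValueError("defection requires a group of size >= 2")
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"relatedness must be in [0, 1], got {r}")
    p = params.with_theta(theta)
    direct = _eusocial_lrs(1, xbar_pop, p)
    indirect = r * (n - 1) * _eusocial_lrs(n - 1, xbar_pop, p)
    return direct + indirect


def minimum_relatedness(
    theta: float,
    params: ModelParams,
    n: int | None = None,
    xbar_pop: float | None = None,
    tol: float = 1e-9,
) -> StabilityResult:
    """Smallest relatedness at which a eusocial group of size ``n`` is stable.

    Both inclusive-fitness expressions are affine in ``r``, so the balance
    point is ``r_min = D(1) / (n * D(n) - (n-1) * D(n-1))`` with ``D(k)`` the
    per-capita lifetime reproductive success of a size-``k`` eusocial group
    evaluated at the resident equilibrium resource level ``xbar_n`` (``D(1)``
    is the solitary value).  ``n`` defaults to the optimal eusocial group
    size at ``theta``; a single defector is assumed not to perturb resource
    availability.
    """
    p = params.with_theta(theta)
    if n is None:
        n = optimal_group_size(GroupType.EUSOCIAL, theta, params).n_opt
    if n < 2:
        raise ValueError("stability analysis requires a group of size >= 2")
    if xbar_pop is None:
        eq = equilibrium_requirement(GroupStrategy(GroupType.EUSOCIAL, n), theta, params)
        if not eq.feasible:
            raise ArithmeticError(
                f"eusocial group of size {n} infeasible at theta={theta}"
            )
        xbar_pop = eq.xbar_n
    d1 = _eusocial_lrs(1, xbar_pop, p)
    dn = _eusocial_lrs(n, xbar_pop, p)
    dn1 = _eusocial_lrs(n - 1, xbar_pop, p)
    denom = n * dn - (n - 1) * dn1
    if denom <= 0:
        return StabilityResult(
            n=n, theta=theta, r_min=np.inf, defined=False,
            phi_sub_at_rmin=np.nan, phi_def_at_rmin=np.nan, xbar_pop=xbar_pop,
        )
    r_min = d1 / denom
    defined = 0.0 <= r_min <= 1.0
    if defined:
        phi_sub = inclusive_fitness_subordinate(n, theta, r_min, params, xbar_pop)
        phi_def = inclusive_fitness_defector(n, theta, r_min, params, xbar_pop)
        assert abs(phi_sub - phi_def) <= tol * max(1.0, abs(phi_sub)), (
            "inclusive-fitness balance violated at the closed-form root"
        )
    else:
        phi_sub = phi_def = np.nan
    return StabilityResult(
        n=n, theta=theta, r_min=float(r_min), defined=defined,
        phi_sub_at_rmin=phi_sub, phi_def_at_rmin=phi_def, xbar_pop=xbar_pop,
    )


def invasion_fitness(
    invader: GroupStrategy,
    resident: GroupStrategy,
    theta: float,
    params: ModelParams,
    xbar_resident: float | None = None,
) -> InvasionCell:
    """Lifetime reproductive success of a rare invader at the resident equilibrium.

    ``psi > 1`` means the invader grows; ``psi = 1`` when invader and
    resident coincide (the defining property of the resident equilibrium).
    """
    p = params.with_theta(theta)
    if xbar_resident is None:
        eq = equilibrium_requirement(resident, theta, params)
        if not eq.feasible:
            raise ArithmeticError(f"resident strategy {resident} infeasible at theta={theta}")
        xbar_resident = eq.xbar_n
    psi = lifetime_reproductive_success(invader, xbar_resident, p)
    return InvasionCell(
        resident=resident, invader=invader, theta=theta,
        psi=psi, xbar_resident=xbar_resident,
    )


def pairwise_invasibility_grid(
    strategies: list[GroupStrategy],
    theta: float,
    params: ModelParams,
) -> list[list[InvasionCell]]:
    """Full pairwise invasion-fitness matrix (rows: invaders, columns: residents).

    The strategy with the smallest equilibrium requirement has ``psi <= 1``
    for every invader against it: minimizing ``xbar_N`` and being
    evolutionarily uninvadable single out the same strategy.
    """
    xbars = {}
    for res in strategies:
        eq = equilibrium_requirement(res, theta, params)
        if not eq.feasible:
            raise ArithmeticError(f"strategy {res} infeasible at theta={theta}")
        xbars[res] = eq.xbar_n
    return [
        [
            invasion_fitness(inv, res, theta, params, xbar_resident=xbars[res])
            for res in strategies
        ]
        for inv in strategies
    ]
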