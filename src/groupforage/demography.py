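"""Mortality, fertility and per-capita natality of foraging groups.

Resources pooled within a group are allocated first to survival — every
member needs at least the threshold amount ``o_m`` to escape starvation —
and any surplus to reproduction.  The two group types differ only in how
the reproductive surplus is used:

* *egalitarian* groups split it evenly, every member reproduces on its own
  share;
* *eusocial* groups channel the whole surplus to a single reproductive
  dominant, so the per-capita natality is the dominant's fertility divided
  by the group size.

Mortality is a step function of the resources allocated to survival (death
below the threshold, baseline mortality above it) and is identical for both
group types.  Expectations over the pooled per-capita resource law give the
mean per-capita mortality ``mu`` and natality ``phi``; their ratio is the
lifetime reproductive success ``psi = phi / mu``, the fitness measure used
in the stability analysis.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .resource_model import ModelParams, ResourceDistribution

__all__ = [
    "GroupType",
    "GroupStrategy",
    "DemographicRates",
    "fertility",
    "fertility_inverse",
    "lifetime_reproductive_success",
    "mean_mortality",
    "mortality_probability",
    "natality",
]

#: Absolute tolerance passed to the adaptive quadrature in :func:`natality`.
QUAD_EPSABS = 1e-9
#: Number of standard deviations beyond the mean at which the natality
#: integral is truncated; the Gamma tail mass beyond it is < 1e-10 and the
#: fertility integrand is bounded, so the truncation error is controlled.
QUAD_TAIL_SD = 12.0


class GroupType(str, enum.Enum):
    """Resource-allocation rule of a group."""

    EGALITARIAN = "egalitarian"
    EUSOCIAL = "eusocial"


@dataclass(frozen=True)
class GroupStrategy:
    """A competing strategy: a group type and a group size.

    At ``n == 1`` both types describe the same solitary forager.
    """

    group_type: GroupType
    n: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_type", GroupType(self.group_type))
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError(f"group size must be a positive integer, got {self.n}")


@dataclass(frozen=True)
class DemographicRates:
    """Per-capita demographic rates of a strategy at a given resource level."""

    natality: float
    mortality: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mortality <= 1.0:
            raise ValueError(f"mortality must be in [0, 1], got {self.mortality}")
        if self.natality < 0:
            raise ValueError(f"natality must be nonnegative, got {self.natality}")

    @property
    def lrs(self) -> float:
        """Lifetime reproductive success ``psi = natality / mortality``."""
        if self.mortality == 0.0:
            raise ZeroDivisionError("lifetime reproductive success diverges at zero mortality")
        return self.natality / self.mortality


def mortality_probability(x_s: float, params: ModelParams) -> float:
    """Step mortality: certain death below the survival threshold.

    Returns 1 if ``x_s < o_m`` and the baseline ``m_b`` otherwise; receiving
    exactly the threshold amount counts as survival.
    """
    if x_s < 0:
        raise ValueError(f"survival resources must be nonnegative, got {x_s}")
    return 1.0 if x_s < params.o_m else params.m_b


def _share_distribution(strategy: GroupStrategy, mean_x: float, params: ModelParams) -> ResourceDistribution:
    return ResourceDistribution(mean_x=mean_x, theta=params.theta, group_size=strategy.n)


def mean_mortality(strategy: GroupStrategy, mean_x: float, params: ModelParams) -> float:
    """Expected per-capita mortality ``mu`` of a group at resource level ``mean_x``.

    The starvation probability is the mass of the pooled per-capita law
    below the threshold ``o_m``; survivors face the baseline mortality, so
    ``mu = C + (1 - C) * m_b`` with ``C`` the pooled-share CDF at ``o_m``.
    Identical for both group types (survival shares are always egalitarian).
    """
    if not mean_x > 0:
        raise ValueError(f"mean_x must be positive, got {mean_x}")
    dist = _share_distribution(strategy, mean_x, params)
    if dist.deterministic:
        starvation = 1.0 if mean_x < params.o_m else 0.0
    else:
        starvation = float(stats.gamma.cdf(params.o_m, a=dist.shape, scale=dist.scale))
    return starvation + (1.0 - starvation) * params.m_b


def fertility(x_r: float, params: ModelParams) -> float:
    """Sigmoid fertility ``F(x_r) = f_max * (1 - exp(-x_r / (c0 * f_max)))^2``.

    Convex for small reproductive surpluses (inflection at
    ``c0 * f_max * ln 2``), saturating at ``f_max``.  Callers must clip the
    surplus at zero beforehand; negative input is a domain error.
    """
    if x_r < 0:
        raise ValueError(f"reproductive resources must be nonnegative, got {x_r}")
    return params.f_max * (1.0 - math.exp(-x_r / (params.c0 * params.f_max))) ** 2


def fertility_inverse(f: float, params: ModelParams) -> float:
    """Surplus needed for fertility ``f``: the inverse of :func:`fertility`."""
    if not 0.0 <= f < params.f_max:
        raise ValueError(f"fertility must be in [0, f_max), got {f}")
    return -params.c0 * params.f_max * math.log(1.0 - math.sqrt(f / params.f_max))


def natality(strategy: GroupStrategy, mean_x: float, params: ModelParams) -> float:
    """Expected per-capita natality ``phi`` of a group at resource level ``mean_x``.

    Egalitarian groups: ``phi = E[F(max(0, x - o_m))]`` under the pooled
    per-capita law.  Eusocial groups pool the surplus for a single dominant:
    ``phi = E[F(N * max(0, x - o_m))] / N``.  The eusocial rate is bounded
    by ``f_max / N``, which is what limits feasible eusocial group sizes.
    """
    if not mean_x > 0:
        raise ValueError(f"mean_x must be positive, got {mean_x}")
    dist = _share_distribution(strategy, mean_x, params)
    n = strategy.n
    eusocial = strategy.group_type is GroupType.EUSOCIAL

    if dist.deterministic:
        surplus = max(0.0, mean_x - params.o_m)
        if eusocial:
            return fertility(n * surplus, params) / n
        return fertility(surplus, params)

    upper = max(mean_x, params.o_m) + QUAD_TAIL_SD * math.sqrt(dist.variance)
    if upper <= params.o_m:  # no mass above the threshold within the window
        return 0.0
    shape, scale = dist.shape, dist.scale
    # log-normalization of the Gamma density, precomputed for the quadrature
    log_norm = -shape * math.log(scale) - math.lgamma(shape)
    o_m, f_max, cf = params.o_m, params.f_max, params.c0 * params.f_max
    mult = float(n) if eusocial else 1.0

    def integrand(x: float) -> float:
        if x <= 0.0:
            return 0.0
        log_pdf = log_norm + (shape - 1.0) * math.log(x) - x / scale
        surplus = mult * (x - o_m)
        return math.exp(log_pdf) * f_max * (1.0 - math.exp(-surplus / cf)) ** 2

    value, abserr = integrate.quad(
        integrand, params.o_m, upper, epsabs=QUAD_EPSABS, limit=200
    )
    if abserr > 1e-6 * max(1.0, abs(value)):
        raise ArithmeticError(
            f"natality quadrature did not converge: value={value}, abserr={abserr}, "
            f"strategy={strategy}, mean_x={mean_x}, theta={params.theta}"
        )
    return value / n if eusocial else float(value)


def lifetime_reproductive_success(
    strategy: GroupStrategy, mean_x: float, params: ModelParams
) -> float:
    """Lifetime reproductive success ``psi = phi / mu`` at resource level ``mean_x``.

    The expected offspring per period times the mean lifetime ``1 / mu``.
    Equals 1 when ``mean_x`` is the strategy's own equilibrium resource level.
    """
    mu = mean_mortality(strategy, mean_x, params)
    if mu == 0.0:
        raise ZeroDivisionError("lifetime reproductive success diverges at zero mortality")
    return natality(strategy, mean_x, params) / mu


def demographic_rates(strategy: GroupStrategy, mean_x: float, params: ModelParams) -> DemographicRates:
    """Bundle ``phi`` and ``mu`` for one strategy at one resource level."""
    return DemographicRates(
        natality=natality(strategy, mean_x, params),
        mortality=mean_mortality(strategy, mean_x, params),
    )
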