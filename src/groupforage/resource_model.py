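"""Stochastic foraging success and resource pooling in groups.

Individual foraging success over one reproductive period is modelled as a
Gamma-distributed random variable: an individual makes on average
``kappa = mean_x / theta`` foraging trips, each returning an item of mean
size ``theta``, so the total harvest has mean ``mean_x`` and variance
``mean_x * theta``.  The item size ``theta`` therefore acts as a proxy for
environmental variance: for a fixed mean intake, larger items mean fewer,
chancier successes.

When ``N`` individuals forage independently, pool their harvests and split
the pool evenly, the per-capita share is again Gamma distributed, with the
same mean but variance reduced by a factor ``1/N`` — pooling is a
variance-reduction device.  This module represents both laws (solitary and
pooled), exposes their density/CDF, and provides a reproducible sampler used
by the individual-based simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "PRESETS",
    "THETA_MIN",
    "ModelParams",
    "ResourceDistribution",
    "coefficient_of_variation",
    "pooled_share_cdf",
    "pooled_share_density",
    "sample_pooled_shares",
]

#: Below this item size the Gamma shape parameter degenerates; the
#: distribution is treated as a point mass at its mean instead.
THETA_MIN = 1e-6


@dataclass(frozen=True)
class ModelParams:
    """Demographic and environmental constants of the consumer-resource model.

    Parameters
    ----------
    f_max
        Maximal fecundity: the asymptote of the fertility function, in net
        offspring per reproductive period.
    c0
        Cost of reproduction; together with ``f_max`` it sets the resource
        scale ``c0 * f_max`` over which fertility saturates.
    m_b
        Resource-independent baseline mortality probability per period
        (predation, disease), in ``[0, 1]``.
    o_m
        Survival threshold: the amount of resources an individual must
        receive in one period to escape starvation.
    theta
        Mean resource item size, the proxy for environmental variance
        (harvest variance is ``mean_x * theta``).
    """

    f_max: float = 3.0
    c0: float = 4.0
    m_b: float = 0.1
    o_m: float = 1.0
    theta: float = 1.0

    def __post_init__(self) -> None:
        if not self.f_max > 0:
            raise ValueError(f"f_max must be positive, got {self.f_max}")
        if not self.c0 > 0:
            raise ValueError(f"c0 must be positive, got {self.c0}")
        if not 0.0 <= self.m_b <= 1.0:
            raise ValueError(f"m_b must be in [0, 1], got {self.m_b}")
        if self.o_m < 0:
            raise ValueError(f"o_m must be nonnegative, got {self.o_m}")
        if not self.theta > 0:
            raise ValueError(f"theta must be positive, got {self.theta}")

    def with_theta(self, theta: float) -> "ModelParams":
        """Return a copy with a different environmental variance."""
        return replace(self, theta=theta)


#: Named parameter sets used throughout the analysis.  ``standard`` is the
#: baseline; the other three perturb one constant each.
PRESETS: dict[str, ModelParams] = {
    "standard": ModelParams(f_max=3.0, c0=4.0, m_b=0.1, o_m=1.0),
    "increased-mortality": ModelParams(f_max=3.0, c0=4.0, m_b=0.2, o_m=1.0),
    "increased-cost": ModelParams(f_max=3.0, c0=8.0, m_b=0.1, o_m=1.0),
    "increased-fecundity": ModelParams(f_max=5.0, c0=4.0, m_b=0.1, o_m=1.0),
}


@dataclass(frozen=True)
class ResourceDistribution:
    """Per-capita resource share after pooling in a group of size ``N``.

    The law is Gamma with shape ``N * mean_x / theta`` and scale
    ``theta / N`` — mean ``mean_x``, variance ``mean_x * theta / N``.  For
    ``group_size == 1`` this is the solitary harvest distribution.  The
    ratio ``mean_x / theta`` is interpretable as a number of foraging trips
    when it is an integer, but is never rounded.
    """

    mean_x: float
    theta: float
    group_size: int = 1

    def __post_init__(self) -> None:
        if not self.mean_x > 0:
            raise ValueError(f"mean_x must be positive, got {self.mean_x}")
        if self.theta < 0:
            raise ValueError(f"theta must be nonnegative, got {self.theta}")
        if not (isinstance(self.group_size, (int, np.integer)) and self.group_size >= 1):
            raise ValueError(f"group_size must be a positive integer, got {self.group_size}")

    @property
    def deterministic(self) -> bool:
        """True when the item size is below :data:`THETA_MIN` (point mass)."""
        return self.theta < THETA_MIN

    @property
    def shape(self) -> float:
        return self.group_size * self.mean_x / self.theta

    @property
    def scale(self) -> float:
        return self.theta / self.group_size

    @property
    def variance(self) -> float:
        return self.mean_x * self.theta / self.group_size

    def frozen(self) -> stats.distributions.rv_frozen:
        """The scipy Gamma law of the per-capita share."""
        return stats.gamma(a=self.shape, scale=self.scale)


def pooled_share_density(x: float, dist: ResourceDistribution) -> float:
    """Density of the per-capita pooled resource share at ``x``.

    Raises ``ValueError`` for negative ``x``.  In the deterministic limit
    (``theta < THETA_MIN``) the law is a point mass at the mean: the density
    is 0 away from it and infinite at it.
    """
    x = float(x)
    if x < 0:
        raise ValueError(f"resource amount must be nonnegative, got {x}")
    if dist.deterministic:
        return np.inf if x == dist.mean_x else 0.0
    return float(stats.gamma.pdf(x, a=dist.shape, scale=dist.scale))


def pooled_share_cdf(x: float, dist: ResourceDistribution) -> float:
    """P(per-capita share <= x): regularized lower incomplete gamma."""
    x = float(x)
    if x < 0:
        raise ValueError(f"resource amount must be nonnegative, got {x}")
    if dist.deterministic:
        return 1.0 if x >= dist.mean_x else 0.0
    return float(stats.gamma.cdf(x, a=dist.shape, scale=dist.scale))


def coefficient_of_variation(mean_x: float, theta: float) -> float:
    """CV of an individual harvest: ``sqrt(theta / mean_x)``.

    Follows from the mean-variance relation ``sigma^2 = mean_x * theta``.
    """
    if not mean_x > 0:
        raise ValueError(f"mean_x must be positive, got {mean_x}")
    if theta < 0:
        raise ValueError(f"theta must be nonnegative, got {theta}")
    return float(np.sqrt(theta / mean_x))


def sample_pooled_shares(
    n_groups: int,
    dist: ResourceDistribution,
    seed: int,
) -> np.ndarray:
    """Draw per-capita pooled shares for ``n_groups`` independent groups.

    Each group draws ``group_size`` independent Gamma harvests
    (shape ``mean_x / theta``, scale ``theta``), pools them and divides by
    the group size.  Sampling is counter-based (Philox keyed on ``seed``
    with inverse-CDF transforms), so enlarging ``n_groups`` extends the
    sample without reshuffling earlier groups.

    Returns an array of length ``n_groups``.
    """
    if n_groups < 1:
        raise ValueError(f"n_groups must be >= 1, got {n_groups}")
    if dist.deterministic:
        return np.full(n_groups, dist.mean_x)
    gen = np.random.Generator(np.random.Philox(key=seed))
    u = gen.random((n_groups, dist.group_size))
    harvests = stats.gamma.ppf(u, a=dist.mean_x / dist.theta, scale=dist.theta)
    return harvests.mean(axis=1)
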