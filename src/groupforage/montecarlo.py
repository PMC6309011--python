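"""Individual-based simulation of foraging seasons.

An independent stochastic enactment of the model used to validate the
quadrature and closed-form results: groups forage, pool their harvests,
allocate shares to survival and reproduction, and the empirical per-capita
mortality and natality are compared against the analytic expectations.

Randomness is counter-based: a Philox generator keyed on the seed produces
one uniform per gamma harvest (via the inverse CDF) and one per baseline-
mortality draw, laid out replicate-major.  Enlarging the replicate count
therefore extends the experiment without reshuffling earlier replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .demography import GroupStrategy, GroupType
from .resource_model import ModelParams, THETA_MIN

__all__ = ["MonteCarloEstimate", "simulate_season"]


@dataclass(frozen=True)
class MonteCarloEstimate:
    """Empirical per-capita demographic rates from simulated seasons."""

    mu_hat: float
    phi_hat: float
    se_mu: float
    se_phi: float
    n_groups: int
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu_hat <= 1.0:
            raise ValueError(f"mu_hat must be in [0, 1], got {self.mu_hat}")
        if self.phi_hat < 0:
            raise ValueError(f"phi_hat must be nonnegative, got {self.phi_hat}")


def simulate_season(
    strategy: GroupStrategy,
    mean_x: float,
    params: ModelParams,
    n_groups: int,
    seed: int,
) -> MonteCarloEstimate:
    """Simulate ``n_groups`` independent groups for one reproductive period.

    Each replicate group of size ``N`` draws ``N`` Gamma harvests (shape
    ``mean_x / theta``, scale ``theta``) and pools them; every member's
    share is the per-capita pooled amount.  Members below the survival
    threshold starve (and cannot reproduce); the rest face independent
    baseline mortality ``m_b``.  The reproductive surplus
    ``x_r = max(0, share - o_m)`` is either realized per member through the
    fertility function (egalitarian) or summed and handed to a single
    dominant (eusocial), whose output is divided by ``N`` for the per-capita
    rate.  Offspring are counted as the deterministic expected fertility of
    the realized share (the expectation matches a stochastic realization).

    Baseline mortality strikes after reproduction within the period, and
    resources of members that die are not redistributed, matching the
    analytic expectations the estimate is compared against.
    """
    frac_dead, per_capita_offspring = _season_arrays(strategy, mean_x, params, n_groups, seed)
    mu_hat = float(frac_dead.mean())
    phi_hat = float(per_capita_offspring.mean())
    ddof = 1 if n_groups > 1 else 0
    se_mu = float(frac_dead.std(ddof=ddof) / math.sqrt(n_groups))
    se_phi = float(per_capita_offspring.std(ddof=ddof) / math.sqrt(n_groups))
    return MonteCarloEstimate(
        mu_hat=mu_hat, phi_hat=phi_hat, se_mu=se_mu, se_phi=se_phi,
        n_groups=n_groups, seed=seed,
    )


def _season_arrays(
    strategy: GroupStrategy,
    mean_x: float,
    params: ModelParams,
    n_groups: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-replicate (fraction dead, per-capita offspring) arrays.

    The uniform stream is laid out replicate-major — ``(n_groups, N, 2)``
    with one slot per gamma harvest and one per baseline-mortality draw —
    so the first ``m`` replicates are identical for any ``n_groups >= m``.
    """
    if n_groups < 1:
        raise ValueError(f"n_groups must be >= 1, got {n_groups}")
    if not mean_x > 0:
        raise ValueError(f"mean_x must be positive, got {mean_x}")
    n = strategy.n
    theta, o_m, m_b = params.theta, params.o_m, params.m_b

    gen = np.random.Generator(np.random.Philox(key=seed))
    u = gen.random((n_groups, n, 2))
    if theta < THETA_MIN:
        shares = np.full(n_groups, mean_x)
    else:
        harvests = stats.gamma.ppf(u[:, :, 0], a=mean_x / theta, scale=theta)
        shares = harvests.mean(axis=1)

    starved = shares < o_m  # the pooled share falls below threshold for all members at once
    baseline_dead = u[:, :, 1] < m_b
    frac_dead = np.where(starved, 1.0, baseline_dead.mean(axis=1))

    surplus = np.maximum(0.0, shares - o_m)
    if strategy.group_type is GroupType.EUSOCIAL:
        per_capita_offspring = _fertility(n * surplus, params) / n
    else:
        per_capita_offspring = _fertility(surplus, params)
    per_capita_offspring = np.where(starved, 0.0, per_capita_offspring)
    return frac_dead, per_capita_offspring


def _fertility(x_r: np.ndarray, params: ModelParams) -> np.ndarray:
    return params.f_max * (1.0 - np.exp(-x_r / (params.c0 * params.f_max))) ** 2
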