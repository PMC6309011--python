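"""Inclusive-fitness stability of eusocial groups and pairwise invasibility."""

import numpy as np
import pytest
from scipy import optimize

from groupforage import (
    GroupStrategy,
    GroupType,
    equilibrium_requirement,
    inclusive_fitness_defector,
    inclusive_fitness_subordinate,
    invasion_fitness,
    lifetime_reproductive_success,
    minimum_relatedness,
    optimal_group_size,
    pairwise_invasibility_grid,
    simulate_season,
)


@pytest.fixture(scope="module")
def eusocial_resident(standard):
    """Optimal eusocial strategy and its equilibrium at θ=2."""
    rec = optimal_group_size(GroupType.EUSOCIAL, 2.0, standard)
    return rec.n_opt, rec.xbar_at_opt


class TestSubordinateFitness:
    def test_linear_and_zero_at_unrelated(self, standard, eusocial_resident):
        n, xbar = eusocial_resident
        assert inclusive_fitness_subordinate(n, 2.0, 0.0, standard, xbar) == 0.0
        half = inclusive_fitness_subordinate(n, 2.0, 0.25, standard, xbar)
        full = inclusive_fitness_subordinate(n, 2.0, 0.5, standard, xbar)
        assert full == pytest.approx(2 * half, rel=1e-12)

    def test_full_relatedness_at_equilibrium_equals_group_size(self, standard, eusocial_resident):
        """With r=1 at the resident equilibrium, Φ_sub = N·Ψ = N."""
        n, xbar = eusocial_resident
        assert inclusive_fitness_subordinate(n, 2.0, 1.0, standard, xbar) == pytest.approx(
            n, abs=1e-6
        )

    def test_solitary_has_no_subordinates(self, standard):
        with pytest.raises(ValueError):
            inclusive_fitness_subordinate(1, 2.0, 0.5, standard, 2.0)


class TestDefectorFitness:
    def test_unrelated_defector_keeps_only_solitary_fitness(self, standard, eusocial_resident):
        n, xbar = eusocial_resident
        solitary_psi = lifetime_reproductive_success(
            GroupStrategy(GroupType.EUSOCIAL, 1), xbar, standard.with_theta(2.0)
        )
        assert inclusive_fitness_defector(n, 2.0, 0.0, standard, xbar) == pytest.approx(
            solitary_psi
        )

    def test_affine_structure_in_relatedness(self, standard):
        """For N=2 the r=1 and r=0 values differ by the solitary LRS of the
        remaining relative (a 'group' of one)."""
        xbar = equilibrium_requirement(
            GroupStrategy(GroupType.EUSOCIAL, 2), 2.0, standard
        ).xbar_n
        at0 = inclusive_fitness_defector(2, 2.0, 0.0, standard, xbar)
        at1 = inclusive_fitness_defector(2, 2.0, 1.0, standard, xbar)
        remaining = lifetime_reproductive_success(
            GroupStrategy(GroupType.EUSOCIAL, 1), xbar, standard.with_theta(2.0)
        )
        assert at1 - at0 == pytest.approx(remaining, rel=1e-10)

    def test_monte_carlo_agreement(self, standard, eusocial_resident):
        """Φ_def from simulated solitary and remaining-group rates matches."""
        n, xbar = eusocial_resident
        p = standard.with_theta(2.0)
        r = 0.5
        sol = simulate_season(GroupStrategy(GroupType.EUSOCIAL, 1), xbar, p, 100_000, seed=31)
        rem = simulate_season(GroupStrategy(GroupType.EUSOCIAL, n - 1), xbar, p, 100_000, seed=32)
        est = sol.phi_hat / sol.mu_hat + r * (n - 1) * rem.phi_hat / rem.mu_hat
        # propagate 3-SE bounds through the ratio (delta method, generous)
        se = 3 * (
            sol.se_phi / sol.mu_hat
            + sol.phi_hat * sol.se_mu / sol.mu_hat**2
            + r * (n - 1) * (rem.se_phi / rem.mu_hat + rem.phi_hat * rem.se_mu / rem.mu_hat**2)
        )
        assert inclusive_fitness_defector(n, 2.0, r, standard, xbar) == pytest.approx(
            est, abs=se
        )


class TestMinimumRelatedness:
    def test_closed_form_matches_bisection(self, standard):
        """The affine solve equals an independent root of Φ_def − Φ_sub."""
        rec = optimal_group_size(GroupType.EUSOCIAL, 1.0, standard)
        stab = minimum_relatedness(1.0, standard, n=rec.n_opt, xbar_pop=rec.xbar_at_opt)

        def gap(r):
            return inclusive_fitness_defector(
                rec.n_opt, 1.0, r, standard, rec.xbar_at_opt
            ) - inclusive_fitness_subordinate(rec.n_opt, 1.0, r, standard, rec.xbar_at_opt)

        root = optimize.bisect(gap, 0.0, 1.0, xtol=1e-12)
        assert stab.r_min == pytest.approx(root, abs=1e-10)

    def test_stability_direction_around_threshold(self, standard):
        """Slightly above r_min staying wins; slightly below, defecting wins."""
        stab = minimum_relatedness(1.0, standard)
        n, xbar = stab.n, stab.xbar_pop
        eps = 1e-3
        above = inclusive_fitness_subordinate(
            n, 1.0, stab.r_min + eps, standard, xbar
        ) - inclusive_fitness_defector(n, 1.0, stab.r_min + eps, standard, xbar)
        below = inclusive_fitness_subordinate(
            n, 1.0, stab.r_min - eps, standard, xbar
        ) - inclusive_fitness_defector(n, 1.0, stab.r_min - eps, standard, xbar)
        assert above > 0
        assert below < 0

    def test_balance_holds_at_threshold(self, standard):
        stab = minimum_relatedness(0.5, standard)
        assert stab.defined
        assert stab.phi_sub_at_rmin == pytest.approx(stab.phi_def_at_rmin, rel=1e-9)

    def test_parameter_directions(self, presets):
        """Baseline mortality raises r_min; reproduction cost and fecundity lower it."""
        theta = 2.0

        def rmin_at_opt(params):
            rec = optimal_group_size(GroupType.EUSOCIAL, theta, params)
            return minimum_relatedness(theta, params, n=rec.n_opt, xbar_pop=rec.xbar_at_opt).r_min

        base = rmin_at_opt(presets["standard"])
        assert rmin_at_opt(presets["increased-mortality"]) > base
        assert rmin_at_opt(presets["increased-cost"]) < base
        assert rmin_at_opt(presets["increased-fecundity"]) < base


class TestInvasionFitness:
    def test_resident_invading_itself_is_neutral(self, standard, eusocial_resident):
        n, _ = eusocial_resident
        res = GroupStrategy(GroupType.EUSOCIAL, n)
        cell = invasion_fitness(res, res, 2.0, standard)
        assert cell.psi == pytest.approx(1.0, abs=1e-6)

    def test_solitary_cannot_invade_optimal_eusocial(self, standard, eusocial_resident):
        """Resident groups depress resources below what solitaries need."""
        n, _ = eusocial_resident
        cell = invasion_fitness(
            GroupStrategy(GroupType.EGALITARIAN, 1),
            GroupStrategy(GroupType.EUSOCIAL, n),
            2.0,
            standard,
        )
        assert cell.psi < 1.0

    def test_sign_matches_requirement_ordering(self, standard):
        """Ψ(invader, resident) > 1 iff the invader needs fewer resources."""
        theta = 2.0
        strategies = [
            GroupStrategy(GroupType.EUSOCIAL, n) for n in (2, 8, 16)
        ] + [GroupStrategy(GroupType.EGALITARIAN, n) for n in (1, 4)]
        xbars = {
            s: equilibrium_requirement(s, theta, standard).xbar_n for s in strategies
        }
        for inv in strategies:
            for res in strategies:
                if inv == res:
                    continue
                psi = invasion_fitness(inv, res, theta, standard, xbar_resident=xbars[res]).psi
                assert (psi > 1.0) == (xbars[inv] < xbars[res])

    def test_infeasible_resident_raises(self, standard):
        with pytest.raises(ArithmeticError):
            invasion_fitness(
                GroupStrategy(GroupType.EGALITARIAN, 1),
                GroupStrategy(GroupType.EUSOCIAL, 31),
                2.0,
                standard,
            )


class TestPairwiseInvasibilityGrid:
    def test_single_strategy_grid_is_neutral(self, standard):
        grid = pairwise_invasibility_grid([GroupStrategy(GroupType.EUSOCIAL, 4)], 2.0, standard)
        assert len(grid) == 1 and len(grid[0]) == 1
        assert grid[0][0].psi == pytest.approx(1.0, abs=1e-6)

    def test_most_efficient_strategy_is_uninvadable(self, standard):
        theta = 2.0
        rec = optimal_group_size(GroupType.EUSOCIAL, theta, standard)
        strategies = [
            GroupStrategy(GroupType.EUSOCIAL, n) for n in (1, 4, rec.n_opt, 25)
        ] + [GroupStrategy(GroupType.EGALITARIAN, 4)]
        grid = pairwise_invasibility_grid(strategies, theta, standard)
        best_col = strategies.index(GroupStrategy(GroupType.EUSOCIAL, rec.n_opt))
        for row in grid:  # nobody grows against the x̄-minimizing resident
            assert row[best_col].psi <= 1.0 + 1e-6
        for i, row in enumerate(grid):  # diagonal neutrality
            assert row[i].psi == pytest.approx(1.0, abs=1e-6)
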