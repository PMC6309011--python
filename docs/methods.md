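# Methods

This note states the model implemented by `groupforage`, the numerical
procedures used to solve it, and the design decisions and limitations a user
should know before trusting the outputs.

## 1. Model

### 1.1 Resource acquisition

Time proceeds in discrete foraging periods. In each period a solitary
individual harvests an amount `x` drawn from a Gamma distribution with mean
`x̄` and variance `x̄·θ` (shape `x̄/θ`, scale `θ`). The parameter `θ` sets
environmental unpredictability; at the individual level the coefficient of
variation is `CV = sqrt(θ/x̄)`, so at `x̄ = 4` the range `θ ∈ [0.1, 16]`
spans CV from 0.16 to 2 (low to very high variance).

A group of `N` foragers pools its harvests and divides them equally. The sum
of `N` i.i.d. Gamma variables with common scale is Gamma, so the per-capita
share `x_s` follows Gamma(shape `N·x̄/θ`, scale `θ/N`): the same mean `x̄`
with variance `x̄·θ/N`. Group living is therefore modelled purely as risk
pooling — there are no synergies in acquisition and no explicit sharing costs.

### 1.2 Mortality

Survival is a step function of the per-capita share. An individual with
`x_s < o_M` starves (dies with probability 1); one with `x_s ≥ o_M` dies with
the baseline probability `M_b`. The expected per-period mortality is

```
μ(N, x̄, θ) = C + (1 − C)·M_b,   C = P(x_s < o_M)
```

with `C` the pooled-share Gamma CDF evaluated at `o_M`. Mortality is identical
for egalitarian and eusocial groups of equal size, because it depends only on
the share each member receives.

### 1.3 Reproduction

Survivors convert surplus `x_r = x_s − o_M` into expected offspring through a
sigmoid fertility function

```
F(x_r) = F_max · (1 − exp(−x_r / (c0·F_max)))².
```

`F` is zero at zero surplus, convex for small surplus (an accelerating cost of
reproduction controlled by `c0`), has its inflection at
`x_r = c0·F_max·ln 2` where `F = F_max/4`, and saturates at `F_max`. Writing
the exponential rate as `1/(c0·F_max)` rather than `1/c0` makes `c0` act as a
cost scale in units of offspring-equivalents and makes a larger `F_max` also
widen the convex region; this functional form is what all quantitative outputs
of the package refer to, and the reported checks (optimal egalitarian group
size, relatedness thresholds) are computed under it.

Per-capita natality `φ` depends on the reproductive institution:

- **Egalitarian**: every member breeds from its own share,
  `φ_eg = ∫ P_N(x)·F(x − o_M) dx` over `x > o_M`.
- **Eusocial**: only one member breeds, from the pooled surplus,
  `φ_eu = (1/N) ∫ P_N(x)·F(N·(x − o_M)) dx`.

Because `F ≤ F_max`, eusocial per-capita natality is bounded by `F_max/N`;
a eusocial group can only persist if `F_max/N > M_b`, which caps feasible
eusocial sizes at `N ≤ F_max/M_b` (30 for the standard parameters).

### 1.4 Equilibrium, carrying capacity, optimal group size

Lifetime reproductive success is `Ψ = φ/μ` (expected offspring per expected
lifetime). A strategy is at demographic equilibrium when `φ = μ`, i.e.
`Ψ = 1`. The **equilibrium resource requirement** `x̄_N` is the mean intake
solving `φ(N, x̄, θ) = μ(N, x̄, θ)`. Since `φ` is strictly increasing and `μ`
strictly non-increasing in `x̄`, the root is unique when it exists.

On a fixed total resource inflow `X`, a strategy at equilibrium supports
`K = X/x̄_N` individuals. The package reports `K_rel = x̄_1/x̄_N`, the
carrying capacity relative to solitary foragers. The **optimal group size**
`N_opt` for a given `θ` and group type is the `N` minimizing `x̄_N`
(equivalently maximizing `K_rel`); the minimizer wins ecological competition
for the common resource.

### 1.5 Stability of eusocial groups

Eusociality creates a conflict: subordinates forgo direct reproduction. With
`D(k)` the per-capita lifetime reproductive success of a k-member eusocial
group evaluated at the resident population's equilibrium intake `x̄_N`, a
subordinate's inclusive fitness from staying is `Φ_stay(r) = r·N·D(N)` (it is
related by `r` to the breeder's whole output), while defecting to breed alone
yields `Φ_leave(r) = D(1) + r·(N−1)·D(N−1)` (its own solitary success plus its
stake in the diminished group). Staying is favoured when
`Φ_stay ≥ Φ_leave`, giving the closed-form threshold

```
r_min = D(1) / (N·D(N) − (N−1)·D(N−1)),
```

defined whenever the denominator is positive. The package evaluates `D(k)` at
the resident equilibrium by default (so `D(N) = 1/N · Ψ_breeder` with
`Ψ = 1`, i.e. `N·D(N) = 1`), but `xbar_pop` may be overridden.

### 1.6 Invasion analysis

Pairwise invasibility uses `Ψ` as invasion fitness: a rare invader strategy
with `Ψ > 1` at the resident's equilibrium intake grows. The grid produced by
`pairwise_invasibility_grid` has one row per invader and one column per
resident; diagonal entries are 1 by construction (every strategy is neutral
against itself), and the strategy minimizing `x̄_N` is uninvadable.

## 2. Parameters

| Parameter | Meaning | Default (standard) | Rationale |
| --- | --- | --- | --- |
| `x̄` | mean per-capita resource intake per period (resource units) | solved, not set | the equilibrium unknown |
| `θ` | Gamma scale; environmental variance per unit mean | swept, typically 0.1–16 | spans CV 0.16–2 at `x̄ = 4` |
| `o_M` | maintenance requirement (resource units) | 1.0 | sets the resource unit |
| `M_b` | baseline per-period mortality (probability) | 0.1 | expected lifespan of 10 periods when never starving |
| `F_max` | maximum offspring per breeder per period | 3.0 | moderate fecundity; 5.0 in the `increased-fecundity` preset |
| `c0` | cost-of-reproduction scale (dimensionless multiplier of `F_max`) | 4.0 | sets the convex region of `F`; 8.0 in `increased-cost` |

Presets: `standard`, `increased-mortality` (`M_b = 0.2`), `increased-cost`
(`c0 = 8`), `increased-fecundity` (`F_max = 5`).

## 3. Numerical procedures

- **Natality integrals** use `scipy.integrate.quad` with `epsabs = 1e-9` on
  `[o_M, U]`, `U = max(x̄, o_M) + 12·sqrt(x̄θ/N)` (twelve standard deviations
  of the pooled law, beyond which the integrand is negligible since `F` is
  bounded). The integrand evaluates the Gamma log-density directly from a
  precomputed log-normalization for speed inside the scalar quadrature loop.
- **Equilibrium root**: `φ − μ` is scanned for a sign change on a 32-point
  geometric grid from `o_M·(1 + 1e−6)` to `o_M + 10·c0·F_max`, then refined
  with `scipy.optimize.brentq` (`rtol = 1e-12`). Uniqueness of the root
  (monotone `φ`, anti-monotone `μ`) makes the coarse scan sufficient.
  Eusocial sizes with `F_max/N ≤ M_b` are reported infeasible without solving.
- **Deterministic mode**: `θ < 1e-6` is treated as a point mass at `x̄`
  (closed forms replace quadrature and sampling), avoiding degenerate Gamma
  shapes.
- **Optimal group size** searches `N = 1 … N_cap + 2` where `N_cap` is the
  feasibility bound (or a user override); the +2 margin guards against an
  optimum at the cap. Ties prefer the smaller `N` (strict improvement must
  exceed `1e-12`).
- **Monte-Carlo oracle**: random numbers come from a counter-based Philox
  generator keyed on the seed, with uniforms laid out replicate-major and
  Gamma draws obtained by inverse CDF. Consequently increasing `n_groups`
  extends the replicate set without reshuffling earlier replicates, and
  results are identical across platforms for a given seed. Standard errors
  are sample standard deviations over groups divided by `sqrt(n_groups)`.
- **Within-period event order in the oracle**: starvation is evaluated first;
  non-starved individuals reproduce, then face baseline mortality. Placing
  reproduction before baseline mortality makes the simulated per-capita
  natality an unbiased estimate of the analytic `φ = E[F]`, which is the
  quantity entering the demographic balance; the alternative ordering would
  estimate `(1 − M_b)·E[F]` instead.

## 4. What the simulation emulates

`simulate_season` is a single-period individual-based realization of the model
above — group-level Gamma harvests, per-member starvation and baseline
mortality coin flips, and expected offspring per survivor. It is a validation
oracle for the quadrature/closed-form pipeline, not a fit to empirical data:
no field or laboratory measurements enter the package, and all parameter
values are theoretical defaults chosen to explore the model's regimes.

## 5. Known limitations

- Group size `N` is a fixed strategy parameter; demographic stochasticity in
  group composition (deaths shrinking a group mid-season) is not tracked.
- Relatedness `r` is an exogenous parameter of the inclusive-fitness
  comparison, not an emergent property of a genetic model.
- The invasion analysis is ecological (resource competition through `x̄`);
  it does not simulate coupled resident–invader dynamics over time.
- The fertility reading in §1.3 is a modelling choice; the alternative rate
  `1/c0` (without the `F_max` factor) changes quantitative outputs
  substantially and is not supported by the package's own consistency checks.
- Quadrature accuracy degrades for extreme shapes (`x̄/θ` very large with `θ`
  just above the deterministic threshold); the test suite covers
  `θ ∈ [1e-5, 32]`.
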