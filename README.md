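# groupforage

Analytic and simulation tools for a consumer–resource model of animal group
formation under resource variance. The package answers a classic question in
behavioural ecology: when does living in a group — sharing food equally
("egalitarian") or channelling all surplus to a single breeder ("eusocial") —
outcompete solitary foraging, and how much relatedness is needed to keep a
eusocial group stable against defection? It is aimed at researchers and
students in evolutionary ecology who want a small, fully tested reference
implementation of the model rather than a large simulation framework.

## The model in brief

Each individual forager collects a Gamma-distributed amount of resource with
mean `x̄` and variance `x̄·θ`; the scale parameter `θ` measures environmental
unpredictability (coefficient of variation `CV = sqrt(θ/x̄)`). In a group of
size `N` the members pool their harvests, so the per-capita share follows a
Gamma law with the same mean but variance `x̄·θ/N` — groups are, first of all,
variance-reduction devices.

Each time step an individual that gets less than the maintenance requirement
`o_M` starves (dies with probability 1); otherwise it dies with baseline
probability `M_b`. Survivors convert their surplus `x_r = x_s − o_M` into
offspring via a sigmoid fertility function

```
F(x_r) = F_max · (1 − exp(−x_r / (c0·F_max)))²
```

which saturates at `F_max` and has initial cost-of-reproduction steepness set
by `c0`. In an egalitarian group every member reproduces from its own share;
in a eusocial group the breeder reproduces from the pooled surplus
`N·(x_s − o_M)` and per-capita natality is that output divided by `N`.

A strategy's **equilibrium resource requirement** `x̄_N` is the mean intake at
which natality balances mortality (`φ = μ`, i.e. lifetime reproductive success
`Ψ = φ/μ = 1`). Strategies that persist on less resource support larger
populations on a fixed inflow (`K ∝ 1/x̄_N`), so the competitively dominant
group size is the one minimizing `x̄_N`. For eusocial groups the package also
computes the **minimum relatedness** `r_min` at which Hamilton-style inclusive
fitness makes staying as a subordinate at least as good as defecting to breed
alone, using per-capita lifetime reproductive success `D(k)` of a k-member
eusocial group evaluated at the resident equilibrium:

```
r_min = D(1) / (N·D(N) − (N−1)·D(N−1))
```

Every analytic rate is validated against a Monte-Carlo individual-based
oracle (`groupforage.montecarlo`) that simulates foraging seasons directly
with counter-based, reproducible random streams.

## Quick start (Python)

```python
from groupforage import (
    GroupType, optimal_group_size, minimum_relatedness, simulate_season,
    GroupStrategy,
)
from groupforage.resource_model import PRESETS

p = PRESETS["standard"]          # F_max=3, c0=4, M_b=0.1, o_M=1

# Optimal group sizes at high environmental variance (theta = 5)
eu = optimal_group_size(GroupType.EUSOCIAL, 5.0, p)
eg = optimal_group_size(GroupType.EGALITARIAN, 5.0, p)
print(eu.n_opt, round(eu.xbar_at_opt, 3), round(eu.k_rel_at_opt, 3))
# 18 2.445 1.878   — eusocial groups of 18 persist on x̄ = 2.445,
#                    supporting 1.88× the solitary population
print(eg.n_opt, round(eg.xbar_at_opt, 3))
# 13 3.27          — the best egalitarian group needs more resource

# Relatedness needed to stabilize the optimal eusocial group
st = minimum_relatedness(5.0, p, n=eu.n_opt, xbar_pop=eu.xbar_at_opt)
print(round(st.r_min, 3))        # 0.236

# Cross-check a rate pair against the individual-based oracle
est = simulate_season(GroupStrategy(GroupType.EUSOCIAL, 18),
                      eu.xbar_at_opt, p.with_theta(5.0),
                      n_groups=100_000, seed=1)
print(round(est.mu_hat, 4), round(est.phi_hat, 4))
# 0.1126 0.1128    — at equilibrium, phi ≈ mu as it must
```

## Quick start (command line)

```
groupforage sweep --theta-grid 0.25,0.5,1,2,4,8,16 --out out/      # optimal N vs theta
groupforage equilibrium --theta 5 --group-type eusocial --out out/ # x̄_N profile over N
groupforage rmin --theta-grid 0.25,1,4,16 --out out/               # r_min vs theta
groupforage invade --theta 2 --strategies eusocial:1,eusocial:8,egalitarian:4 --out out/
groupforage oracle --theta 1 --group-type egalitarian --n 4 --mean-x 4 \
    --n-groups 50000 --seed 1 --out out/
```

All subcommands accept `--preset {standard,increased-mortality,increased-cost,
increased-fecundity}` or individual overrides (`--f-max`, `--c0`, `--m-b`,
`--o-m`). Outputs are deterministic CSVs plus a `manifest.json` recording the
configuration hash and library versions.

## Package layout

| Module | Contents |
| --- | --- |
| `groupforage.resource_model` | parameter sets, Gamma pooled-share law, CV, reproducible samplers |
| `groupforage.demography` | step mortality, sigmoid fertility, natality integrals, lifetime reproductive success |
| `groupforage.equilibrium` | equilibrium requirement `x̄_N`, carrying capacity, optimal group size, θ sweeps |
| `groupforage.stability` | inclusive-fitness threshold `r_min`, pairwise invasibility (Ψ) grids |
| `groupforage.montecarlo` | individual-based oracle with counter-based random streams |
| `groupforage.config` / `experiment` / `cli` | pydantic configs, deterministic table/plot outputs, click CLI |

See `docs/methods.md` for the full mathematical statement, numerical choices
and known limitations.
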