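# Methods

## Model

One breeding season consists of `a` sequential predator attacks and `d`
non-lethal disturbances, followed by reproduction, senescence, and
replacement. The population holds exactly `N` individuals at every season
start; generations overlap, with a hard maximum age of `A` seasons and
maturity at age 1 (every individual alive at season end reproduces).

**Predation.** Each attack is realized as three draws: select a phenotype
group, select a victim uniformly within it, capture with probability `p_F`
or `p_B`. Under frequency-dependent risk sharing the F-group is selected
with probability `β·n_F / (β·n_F + n_B)`, computed on the counts left by
the previous attack (attacks are strictly sequential). The whole-population
per-attack outcome probabilities are therefore

    P(an F dies) = β·n_F·p_F / (β·n_F + n_B)
    P(a B dies)  = n_B·p_B / (β·n_F + n_B)

and one attack kills at most one individual. The frequency-independent
variant replaces the group-selection step with the fixed probability
`β/(1+β)`. Both the engine and the exact oracle consume these probabilities
from one shared function, so a disagreement between them can only come from
the stochastic machinery, which is exactly what the oracle tests probe.
Victim age is chosen uniformly over the group's individuals (the risk model
is age-blind), i.e. the age class is hit with probability proportional to
its count.

Degenerate corners are defined explicitly: an attack on a population where
the weighted denominator vanishes (`β = 0` with only F alive) kills nobody;
in frequency-independent mode an attack that selects an empty group fails
by default (`empty_group_policy="fail"`), with a `"renormalize"` switch
that redirects it to the non-empty group.

**Energy and reproduction.** Fearful survivors end the season with
`x_F = max(0, e0 − (a+d)·c)`, bold survivors with `x_B = max(0, e0 − a·c)`.
Bold individuals pay no vigilance cost during disturbances — only escape
flights cost energy. Reproductive success is `f(x) = λ·x^θ` with `θ = 1` by
default (success proportional to energy reserves); the scale `λ` cancels in
every allocation ratio and the exponent is exposed for sensitivity
analyses. The season's deaths `D` (predation kills plus the post-attack
age-`A` cohort) are replaced by exactly `D` newborns; the expected number
of F-newborns is

    W_F = D · n_F'·f(x_F)·Φ_F / (n_F'·f(x_F)·Φ_F + n_B'·f(x_B)·Φ_B)

on post-attack counts (the age-`A` cohort reproduces before removal), and
the realized number is a single `Binomial(D, W_F/D)` draw — the simplest
realization whose mean matches the expectation exactly and whose total is
exactly `D`. Newborns inherit the mother's phenotype and enter at age 1.

**Background fitness.** `Φ_F = max(0, r_F − a_FF·n_F − a_FB·n_B)` and
symmetrically for B, evaluated on post-attack counts; first subscript =
affected phenotype, second = source. With competition disabled `Φ ≡ 1`.
Clipping at zero is a guard for configurations in which the linear form
goes negative; a clipped phenotype simply gets no offspring that season.

**Zero-weight fallback.** If both phenotypes' allocation weights are zero
while survivors exist (e.g. every survivor's energy clipped to zero),
offspring are allocated proportionally to survivor counts, so the
population never silently vanishes. True extinction — the attacks killing
every individual, possible only when `a ≥ N` — is a flagged terminal
outcome, reported separately from fixation everywhere.

## The exact oracle

For `A = 1` the next season's composition depends only on the current
F-count, so the dynamics is a Markov chain on `{0, …, N}`. The within-season
attack DP enumerates all post-attack states with their exact probabilities;
composing with the binomial offspring draw yields the one-season kernel
(with an explicit extinction column, so rows sum to 1 to 1e−12). Without
competition the pure states absorb, and the fixation probabilities solve
`(I − Q)ρ = t_N` by a dense linear solve (trivial for `N ≤ ~30`). The
headline validation property is that Monte-Carlo fixation frequencies at
20,000 replicates per initial state fall inside the 99% binomial band
around these exact values, for every interior initial count, across
configurations spanning both risk modes, asymmetric selection/capture,
energy clipping, and reachable extinction.

The oracle is restricted to `A = 1` because the exact state space with
overlapping ages grows combinatorially; `A = 1` already exercises the
predation, energy, allocation, and absorption logic end to end. Age
bookkeeping with `A > 1` is covered instead by conservation properties
(population returns to `N` each season start, newborns equal deaths, no
cohort beyond age `A`) over hundreds of random configurations, and by the
neutrality test: with `c = 0`, `β = 1`, `p_F = p_B` the phenotypes are
exchangeable, the F-count is a martingale, and the fixation frequency must
equal the initial proportion.

## Parameters and reconstructed study conditions

| symbol | field | default | meaning |
|---|---|---|---|
| N | `n_total` | 100 | population size at each season start |
| A | `max_age` | 5 | maximum age, seasons |
| a | `n_attacks` | 25 | real attacks per season |
| d | `n_disturbances` | 25 | non-lethal disturbances per season |
| β | `beta` | 0.2 | relative selection probability of F |
| p_F, p_B | `p_capture_f/b` | 0.05, 0.3 | capture probability when selected |
| e0 | `energy_gain` | 10 | energy gained per season |
| c | `energy_cost_escape` | 0.1 | energy lost per escape |
| λ, θ | `repro_scale/exponent` | 1, 1 | reproductive-success function |

The experiments behind the published figures state their parameter values
only in figure panels that are not machine-readable, so the shipped
baseline above is an explicit reconstruction. It was chosen once so that
the simulator operates in the qualitative regime the study's text
describes, and the package's validation asserts exactly those qualitative
properties rather than any figure-level number:

* ρ_F ≈ 1 at `N = 30`, ≈ 0.4 at `N = 100`, ≈ 0 at `N = 200` from 50%
  founders, in both risk modes, with ρ_F monotone in the initial
  proportion;
* at moderate `N`, ρ_F peaks at an intermediate attack count (`a ≈ 40`
  here) and collapses for very few (`a = 2`) or very many (`a = 70`)
  attacks, the latter because `x_F = e0 − (a+d)c` erodes;
* ρ_F is non-increasing in the escape cost `c`.

The coexistence experiment likewise uses its own reconstructed set
(`a = d = 10`, `β = 0.7`, `p_F = 0.12`, `p_B = 0.2`, `c = 0.2`, `r_F = 2.4`,
`r_B = 1.8`, `a_FF = 0.008`, `a_FB = 0.010`, `a_BF = 0.002`,
`a_BB = 0.012`, `N ∈ {120, 180, 240}`), in the regime where the bold
phenotype's competitive effects (`a_FB`, `a_BB`) exceed the fearful one's
(`a_FF`, `a_BF`) — individuals that risk more against predators are assumed
more aggressive in competition. The baselines `r_F/r_B` are set near
`f(x_B)/f(x_F)` so the density-independent parts of the two phenotypes'
reproductive weights balance and the interior equilibrium is governed by
the competition slopes and the survival asymmetry. Under these conditions
both phenotypes persist for 2,000 seasons in every seeded run, and both the
mean fearful fraction over the trailing 100 seasons and its standard
deviation (the fluctuation strength) decrease with `N`.

A structural limitation follows from the linear-in-counts competition:
its restoring force scales with absolute abundances while the fearful
phenotype's per-capita survival advantage grows as `N` shrinks, so no fixed
coefficient set maintains coexistence at very small `N` (below ~100 under
the set above, fearfulness fixes). The coexistence population sizes are
therefore larger than the fixation-experiment sizes.

## Protocol and numerical choices

* **Replicates.** A fixation estimate runs `n_replicates` (default 1000)
  independent replicates to absorption; ρ_F is the F-fixation fraction with
  a 95% Wilson interval. Timeouts (season cap `max_seasons`, default
  100,000) and extinctions are reported separately, never folded into ρ_F.
* **Seeding.** Replicate `i` uses `SeedSequence(base_seed, spawn_key=(i,))`,
  so a replicate is fully determined by `(base_seed, i)` and replicates are
  uncorrelated. Sweep cells derive independent seeds the same way from the
  cell index, unless `pair_seeds=True` gives every cell the same stream
  (common random numbers, used for paired monotonicity comparisons).
* **Initial state.** The founder F-count is `round-half-up(init_freq_f·N)`
  (exact on 10% grids); founder ages are iid uniform on `1..A` by default —
  the study leaves the initial age composition unstated, and uniform
  assignment avoids an artificial synchronized die-off in season `A`. An
  `all_youngest` option exists for deterministic tests.
* **Coexistence runs** have fixed length (no fixation stop; a fixed
  frequency simply stays pegged) and report mean and population standard
  deviation of the F-frequency over the trailing window (default 100
  seasons, matching the published summary window) plus a persistence flag.
  How the original fluctuation strength was computed is unstated; the
  trailing-window standard deviation is this package's choice.
* **Test problem sizes.** The validation suite uses 20,000 replicates per
  initial state for the oracle gate, 300 replicates per sweep cell for the
  qualitative experiments, and 10–50 seeded repetitions for the coexistence
  statistics; these sizes put the Monte-Carlo bands well inside the effect
  sizes being asserted.

## What the tests do and do not show

The validation demonstrates internal correctness (exact-oracle equivalence,
conservation, neutrality, the analytic risk-sharing identities) and the
qualitative response surface of the model. Because every figure-level
parameter value is a reconstruction, agreement with the original study is
established at the level of its stated qualitative findings, not its
plotted curves. The model itself abstracts away predator dynamics (attack
count is exogenous and constant), individual energy heterogeneity (energy
is tracked per phenotype), spatial structure, and sexual reproduction;
conclusions about real bird populations inherit those simplifications.
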