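# fearbold

Individual-based stochastic simulation of the evolution of anti-predator
personality — fearfulness versus boldness — in a bird population of constant
size, with overlapping generations, sequential predator attacks, energy-based
reproduction, and an optional Lotka-Volterra competition mechanism that
allows the two behavioral types to coexist.

It is written for behavioral ecologists and evolutionary-game modelers who
want to study how population size, predation pressure, and the energetic
cost of escape shape the fate of a fear/bold behavioral polymorphism, and to
verify such simulations against exact small-population Markov-chain
calculations.

## The model

An asexual population of `N` individuals lives through breeding seasons.
Each individual carries one heritable pure strategy:

* **Fearful (F)** — flees at every threat, real attack or harmless
  disturbance. Hard to catch, but pays the escape cost `c` at all `a + d`
  events per season, ending with energy `x_F = max(0, e0 − (a + d)·c)`.
* **Bold (B)** — stays on alert and flees only when a threat proves to be a
  real attack. Pays `c` only `a` times (`x_B = max(0, e0 − a·c)`), but is
  easier to capture once targeted.

Each of the `a` attacks in a season selects one phenotype group, then one
victim uniformly within it, then captures the victim with probability `p_F`
or `p_B`. Under **frequency-dependent** risk sharing the F-group is selected
with probability `β·n_F / (β·n_F + n_B)` — so the per-capita kill
probability of a fearful individual at one attack is

```
P(F death) = β·p_F / (β·n_F + n_B),      P(B death) = p_B / (β·n_F + n_B),
```

which produces an emergent dilution effect: the per-capita risk of the more
numerous phenotype is shared across its members. The **frequency-independent**
variant selects the F-group with fixed probability `β / (1 + β)`. The two
modes coincide exactly when `n_F = n_B`.

At season end, `D` individuals have died: the predation kills plus everyone
who reached the maximum age `A`. Exactly `D` offspring replace them,
allocated with expectation

```
W_F = D · n_F'·f(x_F)·Φ_F / (n_F'·f(x_F)·Φ_F + n_B'·f(x_B)·Φ_B),
```

where the primes are post-attack counts, `f(x) = λ·x` is the reproductive
success, and `Φ` is an optional "background fitness" defined by analogy with
Lotka-Volterra interspecific competition,
`Φ_F = max(0, r_F − a_FF·n_F − a_FB·n_B)` (and symmetrically for B). The
realized F-offspring count is `Binomial(D, W_F/D)`; offspring inherit the
mother's phenotype and enter at age 1. Without competition the pure-F and
pure-B states are absorbing, and the **fixation frequency** `ρ_F` — the
fraction of replicate runs that end in an all-fearful population — is the
central output. With competition enabled the two types can coexist
indefinitely, fluctuating around a joint equilibrium.

For the non-overlapping-generation limit (`A = 1`) and small `N` the package
also computes the *exact* season-to-season transition kernel of the F-count
(dynamic programming over the attack sequence composed with the binomial
offspring draw) and the exact fixation probabilities from the absorbing
Markov-chain linear system — an independent oracle used throughout the test
suite to validate the stochastic engine.

## Worked example

Estimate the fixation frequency of fearfulness for the shipped baseline
scenario (`N = 100`, `A = 5`, 25 attacks and 25 disturbances per season,
`β = 0.2`, `p_F = 0.05`, `p_B = 0.3`, `e0 = 10`, `c = 0.1`, 50% fearful
founders):

```bash
fearbold fix --config src/fearbold/configs/default.json --replicates 1000 --seed 5
```

```
 n_replicates  n_f_fixed  n_b_fixed  n_timeout  n_extinct  rho_f   ci_low  ci_high
         1000        379        621          0          0  0.379 0.349448 0.409478
```

379 of 1000 replicates fixed for fearfulness (ρ_F = 0.379, 95% Wilson CI
0.35–0.41; no replicate timed out or went extinct): at this moderate
population size neither strategy dominates. Rerunning with `n_total = 30`
gives ρ_F = 1.0 and with `n_total = 200` gives ρ_F = 0.0 — fearfulness is
favored in small populations and boldness in large ones, because the energy
advantage of boldness is frequency-independent while the survival advantage
of fearfulness is diluted as `N` grows.

The same scenario from Python, plus the exact oracle on a small population:

```python
import dataclasses
from fearbold import ModelParams, estimate_fixation_frequency, exact_fixation_probability

params = ModelParams(n_total=4, max_age=1, n_attacks=2, n_disturbances=2,
                     beta=0.5, p_capture_f=0.2, p_capture_b=0.6,
                     energy_gain=10.0, energy_cost_escape=0.5)
print(exact_fixation_probability(params))
# [0.         0.47675417 0.75821032 0.91508304 1.        ]
est = estimate_fixation_frequency(
    dataclasses.replace(params, init_freq_f=0.5), n_replicates=5000)
print(est.rho_f)   # ~0.758, inside the binomial band around 0.75821
```

Other subcommands: `fearbold sweep` (fixation sweeps over `sweep_axes`
declared in the config), `fearbold coexist` (fixed-length competition runs,
see `src/fearbold/configs/coexistence.json`), and `fearbold oracle` (exact
small-`N` fixation probabilities). All outputs are CSV with a `#` header
embedding the resolved parameters.

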