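# Methods

## The model

`cbh` simulates the coevolution of genes and culture in a metapopulation of
haploid agents.  Fifty demes, linked by island-model migration, hold
individuals described by four genetic traits — brain size `b`, social-learning
probability `s`, oblique-learning probability `v`, payoff-bias ability `l` —
and one learned state variable, adaptive knowledge `a`, always bounded by
`0 ≤ a ≤ b`.  Generations are non-overlapping; each one runs four stages.

**Stage 1 — birth.**  A deme with mean knowledge `A_j` supports carrying
capacity `k_j = χ·A_j + N₀` (`χ = 10`, `N₀ = 10`): knowledge unlocks
resources, so knowledgeable demes can be larger.  The expected next-
generation size follows discrete logistic growth

    N' = N·e^ρ / (1 + (N/k_j)(e^ρ − 1)),   ρ = 0.8,

whose unique positive fixed point is `k_j`.  `round(N')` binomial trials are
allocated to parents with probabilities proportional to the sigmoid-
transformed knowledge `1/(1 + e^(−φ(a_i − A_j)))`, normalized within the
deme.  The gain `φ` is reproductive skew: `φ = 0` is an egalitarian
("monogamish") world where everyone breeds equally; large `φ` approaches
winner-takes-all breeding.  Each newborn inherits its parent's four traits;
with probability `μ` per trait, the value is redrawn from a normal centred
on the parent (SD `σ_b·b` for brains — mutation scales with size — and
absolute SDs for `s`, `v`, `l`; `s` and `v` are truncated to [0, 1], brains
are floored at 10⁻³ so costs and ratios stay defined).

**Stage 2 — learning.**  Newborns start ignorant (`a = 0`).  In Stage 2A a
newborn copies its parent with probability `s` — drawing from
`N(τ·a_parent, σ_a·τ·a_parent)`, where `τ` is transmission fidelity — or
otherwise learns asocially, drawing from `N(ζ·b, σ_a·ζ·b)`, where `ζ` is
asocial learning efficacy.  SDs scale with means (a "thought space" that
widens as knowledge grows).  Draws are clamped to `[0, b]`: knowledge can
never exceed brain capacity.  In Stage 2B the newborn learns asocially
again with probability `1 − s`, or obliquely with probability `s·v` from
one adult of its natal deme chosen payoff-biasedly — model `t` is picked
with probability proportional to `1/(1 + e^(−l(a_t − A_j)))` — and keeps a
candidate value only if it beats what Stage 2A produced.  With probability
`s − s·v` no second-round learning happens at all, which is the cost a
nascent juvenile period must overcome: `s·v`, the chance of a second,
oblique round, is the model's proxy for an extended juvenile period.

**Stage 3 — migration.**  Each newborn moves with probability `m = 0.1` to
a uniformly chosen *other* deme, keeping traits and knowledge.  Deme count
is fixed; empty demes persist at capacity `N₀` and can be recolonized.

**Stage 4 — selection.**  Each newborn dies with probability

    d = min(1, β·b²·e^(−λ·a/b)),   β = 1/10000,

so brain cost grows quadratically (an empty brain of size 100 is certain
death) and knowledge offsets it at a rate set by `λ`, the survival return
on knowledge ("richness of the ecology"); `λ = 0` means no offset.
Survivors are the next adult generation.

The default configuration starts 50 demes × 10 ignorant founders with
`b = 1`, `s = v = l = 0`; a social-start variant (`init_s = 1`) founds the
world with pure social learners.

## Downstream analysis

Each run is condensed at quasi-equilibrium into one "quasi-species" row:
time-averages of `b̄, ā, N̄` (mean deme size), `s̄, v̄, l̄` and the
per-individual mean `s·v` over the final 10% of generations (extinct runs
are averaged over the tail of their pre-extinction history), plus the
extinction rate — the fraction of all individuals ever born that died
leaving neither a genetic offspring nor a cultural learner.

The comparative pipeline mirrors the cross-species literature: variables
are `log b̄`, `log ā`, `log N̄`, `log(3 + N̄·s̄)` (social-learning incidence
as observational counts) and `s̄·v̄`.  Species are split into learning
regimes by one-dimensional k-means on `s̄` (deterministic quantile seeding;
boundaries are midpoints of adjacent cluster centres), and Pearson
correlations with Fisher-z 95% CIs are reported per regime.  A species is
*cumulative-cultural* when the upper-tail probability that a single
individual of brain size `b̄` asocially invents knowledge `ā` —
`1 − Φ((ā − ζb̄)/(σ_a·ζ·b̄))` — falls below 0.1%: knowledge that unlikely
to be invented individually must have accumulated across generations.

## Determinism and the draw-order contract

One PCG64 generator drives each run.  Every stage makes its draws in fixed
batched passes over the deme-sorted population, and every draw consumes
exactly one uniform (normal deviates, including truncated ones, are
inverse-CDF transforms; branch-unused draws are consumed and discarded).
The exact pass order is documented in `cbh.lifecycle`; a per-individual
plain-loop reference implementation in the test suite reproduces engine
states bit for bit, which pins both the algorithm and the contract.
Sweep runs derive their seeds from the base seed plus the parameter cell
and replicate index through `numpy.random.SeedSequence`, so results are
independent of execution order and sweeps can be resumed or partitioned.

## Parameters that matter

| name | meaning | default | range swept |
|---|---|---|---|
| `phi` | reproductive skew (fecundity sigmoid gain) | 0 | 0–1 |
| `tau` | transmission fidelity of social learning | 0.9 | 0.75–1.0 |
| `zeta` | asocial learning efficacy | 0.5 | 0.1–0.9 |
| `lam` | survival return on knowledge | 0 | 0–2 |
| `m` | migration probability | 0.1 | fixed |
| `mu` | per-trait mutation probability | 0.01 | fixed |
| `sigma_a` | learning-noise CV | 0.1 | fixed |
| `sigma_b` | brain-mutation CV | 0.05 | fixed |
| `sigma_s`, `sigma_v` | mutation SDs of `s`, `v` | 0.05 | fixed |
| `sigma_l` | mutation SD of `l` | 0.1 | fixed |

`χ`, `ρ`, `β`, `N₀` and the deme count are structural constants (above).
Mutation-kernel scales are not structural: they set the tempo of genetic
search, and halving or doubling them mainly rescales how many generations
any given transition takes.

## Sweep profiles and problem sizes

`full_profile()` is the full-scale study design: dense grids over the ranges
above, migration also swept, 5 replicates per cell, 200,000 generations —
cluster-scale work that this package can run but its test suite does not.

`desk_profile()` is the package's own workstation-scale design, used by the
test suite and `scripts/acceptance.py`: 3 levels per focal parameter
(φ ∈ {0, 0.1, 1}, τ ∈ {0.75, 0.875, 1}, ζ ∈ {0.1, 0.5, 0.9},
λ ∈ {0, 1, 2}), both starting conditions, 1 replicate, 3000 generations —
162 runs, roughly a quarter-hour on one core.  Two consequences of the
short horizon matter for interpretation:

- Social learning cannot mutationally assemble out of an all-asocial world
  in 3000 generations (except under extreme skew with perfect fidelity), so
  the social regime at desk scale is populated mostly by social-start runs;
  regime analyses therefore pool both starting conditions.  The full-scale
  design reaches majority-social species from asocial starts given enough
  generations, which is why its regime split does not need the pooling.
- Equilibria are "young": brain sizes in take-off cells are still growing
  at generation 3000, so desk-scale correlations are compressed relative to
  the full-scale ones.  The qualitative structure — regime boundary near
  50% social learning, three-regime cuts near 0.2/0.66, the sign pattern of
  the per-regime correlations, extinction rising with skew, brain size
  rising with ecological richness, cumulative culture confined to perfect
  fidelity — is already present.

## What the generator does and does not emulate

All data is self-generated; there is no empirical input.  The simulator
captures the coevolutionary logic — knowledge-linked carrying capacity,
fecundity and viability selection, vertical/oblique payoff-biased
transmission, island migration — under deliberately simple assumptions:
haploid genetics (no sex, recombination, dominance), a single scalar
knowledge stock (no distinct cultural traits), exogenous `τ` and `φ`, and
non-overlapping generations.  Passing tests therefore show that the
*mechanisms* produce the documented comparative patterns, not that any
particular biological taxon satisfies the model's assumptions.

## Numerical choices

- Exponents inside sigmoids/exponentials are clamped at ±700; saturation is
  exact to double precision and overflow is impossible.
- `expected_next_size` is rounded to the nearest integer for the binomial
  trial count (bias < 0.5 offspring per deme-generation).
- Oblique model choice resolves threshold ties toward the earlier adult and
  falls back to the last adult if rounding pushes the threshold past the
  total weight; an empty model pool (impossible in-engine, guarded anyway)
  means no learning.
- Degenerate draws (zero SD, e.g. copying a knowledge-free model) return
  the mean exactly; uniforms are floored at the smallest positive double so
  inverse-CDF quantiles stay finite.
- Correlations with |r| within 1e−12 of 1 are reported as exactly ±1 with a
  degenerate CI; zero-variance variables yield missing correlations.
- k-means on one dimension uses quantile initialization and a single run,
  making clustering deterministic.

## Known limitations

- The desk profile's single replicate per cell leaves per-cell averages
  equal to single runs; replicate-level averaging is exercised by unit
  tests and available to any caller who raises `replicates`.
- The payoff-bias trait `l` has no equilibrium (ever-larger `l` keeps
  helping model choice); its time-averages are descriptive only.
- Extinction-rate bookkeeping counts an individual as "passing on" if it
  has at least one birth or one cultural learner, even if every descendant
  later dies.
- With `χ = 10` fixed, deme sizes in deep take-off cells grow into the
  hundreds; runtime per generation scales linearly with population, which
  is what makes the full design cluster-scale.
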