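# Methods

## Genotype space and landscapes

A genotype is a binary sequence of `L` loci, encoded as an integer in
`[0, 2^L)` with bit `i` the allele at locus `i` (0 = wild type,
1 = mutant).  The genotype space is the `L`-dimensional hypercube with the
Hamming metric `d`; a *local maximum* is a genotype strictly fitter than
all `L` single-mutant neighbours (landscapes with neighbour fitness ties
are rejected rather than disambiguated — ties have probability zero under
all the continuous generators, and a tie in a hand-built fixture is almost
always a mistake).

Landscape models, all with non-negative fitness (required by
multiplicative selection):

* **Rough Mount Fuji (RMF)**: `F(σ) = c·d(σ, σ*) + η_σ`, with `c ≥ 0` the
  mean slope (fitness units per Hamming step), `σ*` a reference genotype
  (default: all-wild-type), and `η_σ` i.i.d. exponential with mean
  `λ ≥ 0`.  `λ/c` tunes ruggedness.  Fitness *increases* away from `σ*`,
  so a population started at `σ*` is maximally maladapted.
* **Additive**: the `λ = 0` special case; single peak at the antipode of
  `σ*`.
* **House of Cards (HoC)**: the `c = 0` special case; i.i.d. exponential
  fitness.  By exchangeability the probability that a genotype beats its
  `L` neighbours is `1/(L+1)`, the expected density of peaks — used as an
  analytic oracle in the tests.
* **NK**: locus `i` contributes a lognormal random value determined by the
  alleles at `{i, i+1, ..., i+K}` (circularly adjacent neighbourhoods);
  genotype fitness is the **sum** of the `L` contributions.  Circular
  neighbourhoods, summation (not averaging) and the lognormal location 0 /
  scale 1 defaults are the common conventions for this model; all are
  configurable.  `K = 0` gives an additive-like landscape (exactly one
  peak), `K = L−1` uncorrelated fitness.

Exponential components are drawn by inverse-CDF transform of the seeded
uniform stream, so a landscape is reproducible bit-for-bit from
`(params, seed)` across platforms.  Because floating-point addition rounds,
the generator stores the *representable residual* `η := F − c·d` rather
than the pre-rounding draw; the decomposition invariant is then bit-exact
and the distribution of the stored `η` differs from exponential by ~1 ulp.

## Finite-population dynamics

One generation of the modified Wright–Fisher model applies, in order:

1. **Mutation** (deterministic, on frequencies):
   `p' = (1−μ)p + (μ/L) A p`, with `A` the hypercube adjacency matrix and
   `μ` the genome-wide per-generation mutation probability.  Only single
   mutations per generation are modelled in the finite engine.
2. **Selection** (deterministic): `p'_σ = p_σ F_σ / F̄`, `F̄ = Σ p_τ F_τ`.
   Mean fitness after selection is `E[F²]/E[F] ≥ E[F]`.
3. **Random sampling**: each genotype count is drawn independently from
   `Poisson(N p_σ)` (cheaper than one multinomial over `2^L` cells and
   identical per-genotype expectations); the realized total `N'` is then
   forced back to `N`: surplus individuals are removed uniformly at random
   (a multivariate hypergeometric draw), a deficit is refilled by sampling
   genotypes proportionally to the realized counts (or to `p` if all
   counts are zero).  This normalization is unbiased and keeps each
   expectation at `N p_σ` to `O(1/N)`; it is one admissible reading of
   "normalize the population to keep it constant", since no unique rule is
   implied by that phrase.
4. **Recombination**: `k ~ Poisson(rN)`, truncated at `N` (and set to `N`
   deterministically when `r = 1`); `k` slots chosen uniformly without
   replacement are replaced by offspring of two parents drawn uniformly
   *with* replacement from the pre-replacement population (self-pairing
   allowed).  Offspring are built by uniform crossover: each locus from
   either parent with probability 1/2, independently.  The step preserves
   expected single-locus allele frequencies exactly.

The first two substeps act on real-valued frequencies and only the
sampling step re-integerizes: mutation and selection are flows of
population *fractions*, and all demographic noise lives in steps 3–4.
Population size is exactly `N` after every full generation (asserted over
10⁴ random parameter draws in the acceptance suite).

Default thresholds for trapping bookkeeping: a population is *trapped*
when its modal genotype is a local maximum carrying ≥ `θ_trap = 0.95` of
the individuals, and has *escaped* when that genotype's share first falls
below `θ_escape = 0.5`.  Near-fixation for trapping and loss of majority
for escape are natural scales, and both are configurable.  Escape is
detected on the trajectory records (which carry the modal genotype and its
frequency): the trapped genotype's share has dropped below `θ_escape`, or
it has lost modality — at the default `θ_escape = 0.5` the two conditions
coincide.

## Infinite-population dynamics

In the `N → ∞` limit the dynamics is the deterministic operator iteration
`p → R_r(S(M p))` on the frequency simplex, with the same substep order as
the finite engine:

* **Mutation operators.**  Order 1: `M₁ = (1−μ)I + (μ/L)A`.  All orders:
  the geometric series `Σ_m (1−μ)((μ/L)A)^m`, which converges for `μ < 1`
  to `M∞ = (1−μ)(I − (μ/L)A)⁻¹` and is exactly column-stochastic (columns
  of `(μ/L)A` sum to `μ`).  Finite order `k ≥ 2`: the series truncated at
  `k` terms, column-renormalized (truncation breaks stochasticity; the
  renormalization is a scalar because `A` is regular).
* **Selection** as in the finite engine.
* **Recombination.**  The uniform-crossover random-mating map
  `Q(p)_g = Σ_{a,b} p_a p_b Π_i [a_i = b_i ? 1{g_i=a_i} : 1/2]`, applied to
  a fraction `r`: `p → (1−r)p + rQ(p)`.  `Q` fixes point masses and all
  linkage-equilibrium product distributions and preserves single-locus
  marginals exactly.

**Walsh-basis implementation.**  The parity characters diagonalize `A`
(eigenvalue `L − 2w` on characters of popcount `w`), so every mutation
operator is diagonal in the Walsh basis and is applied with two fast
Walsh–Hadamard transforms, `O(L 2^L)` per step.  In the same basis uniform
crossover is the submask convolution
`q̂_k = 2^{−|k|} Σ_{s ⊆ k} p̂_s p̂_{k⊕s}`, computed in `O(3^L)` with a
precomputed submask index — against the naive `O(8^L)` sum.  Both
implementations are validated against an independent brute-force
triple-loop oracle at `L ≤ 4` (max abs deviation < 1e−14) and against
closed forms (`M∞` at `L = 1`, the truncated series at `L = 6`).

**Precision.**  After one generation every genotype has positive
frequency, decaying exponentially with Hamming distance from the founder;
in double precision distant genotypes can underflow and be silently lost,
which would distort escape dynamics.  The `precision` argument switches
the state and operators to mpmath arbitrary-precision reals (default 35
significant digits, per-step simplex deviation < 1e−30), capped by default
at `L = 12` since the per-step cost grows as `3^L`.  Standard mode uses
machine doubles with per-step renormalization (simplex deviation
≤ 1e−12).

## Seascapes

With probability `p_reset` per generation (checked before the generation's
substeps, so each generation is evaluated under the current environment),
all `η` are redrawn from the same exponential law and the reference moves:
*soft* reset to a uniform Hamming-1 neighbour of the old `σ*`, *hard*
reset to a uniformly random genotype.  `c`, `λ`, `L` are conserved, so the
environment is statistically stationary with mean epoch `1/p_reset`.
Environmental randomness (reset times, redraws, new references) lives on
its own RNG stream: paired recombining/non-recombining runs share the
environment stream and hence experience *identical* environments, while
their demographic streams stay independent.  With `p_reset = 0` a seascape
run is bit-identical to the static engine under shared seeds.

## Paired ensembles and seeding

All advantage measures are computed from paired runs: per run, one fresh
landscape realization, both arms (`r` and `0`) started monomorphically at
the same genotype (default `σ*`).  Reported series: `ΔF(t)` (mean of
per-pair mean-fitness differences), `ΔS(t)`, `ΔF_max(t)`, and `P₊(t)` (the
fraction of pairs with the recombining arm strictly ahead; exact ties
count 1/2 so that identical trajectories sit at the null value 0.5).  Both
`ΔS` and `ΔF` use the same pairing.

Seed schedule: stream `j` of run `k` is
`SeedSequence(master_seed, spawn_key=(k, j))` for
`j ∈ {landscape, dyn_r, dyn_nr, env}` — counter-based, so ensembles can be
extended without replaying runs, and a parameter sweep reuses the same
landscape seed for run `k` at every swept value, isolating the swept
parameter's effect.

## Observables

* Shannon entropy `S = −Σ p_σ ln p_σ` (nats), in `[0, L ln 2]`.
* Additive genetic variance: the heritable part of RMF fitness is `c·d`,
  so `V_A = c²·Var_p[d(σ, σ*)]`; the raw distance variance is available
  separately, and `V_A` is undefined for NK landscapes (no reference).
* Fitness velocity `v(t) = F̄(t) − F̄(t−1)`, optionally smoothed for
  plotting only (the default raw difference is the discrete derivative of
  `ΔF`, so sign changes of `v_r − v_nr` flag its extrema exactly).
* `F_max`: the fittest genotype *present* (count > 0; frequency > 1e−12
  in the deterministic engine).
* Escape fraction: escapes over trappings among events opened by a
  horizon; optionally normalized by a matched `r = 0` ensemble; undefined
  (raised) when no trapping occurred.
* Off-peak coefficient of variation: over all (run, generation) samples
  with the modal genotype on a local maximum, sd/mean of the number of
  individuals *not* on that genotype.  The off-peak cloud is a birth–death
  population of mean ~`Nμ`, so its cv *decreases* with mutation supply
  (~`1/√(Nμ)`), which is what the test asserts; fluctuation-dominated
  (high-cv) regimes are where recombination-assisted escape can transiently
  beat mutational escape.

## Study conditions used by the tests and the acceptance script

Problem sizes are desk scale, chosen so the full suite runs on one CPU in
minutes while every effect is resolved at ≥ 3 standard errors across runs:
`L = 10`, `N = 1000`, `μ = 0.01` (mutation supply `Nμ = 10`, several new
mutants per generation, as the paired-ensemble phenomenology requires),
`r = 1` vs `0`, 200–300 pairs, horizons of 1000–2000 generations.
Ruggedness: `λ = 1 = c` for the advantage time course (both the transient
advantage and the long-time reversal are visible), `λ = 2` for
trapping/escape statistics (more and deeper local peaks, at `L = 8`).
Seascapes: hard resets at `p_reset = 0.02` (epoch 50, shorter than the
overtaking time) vs `5·10⁻⁴` (epoch 2000, effectively static over the
window), stationary window = generations 500–2000.  The finite/infinite
consistency check (total variation ≤ 0.05 over 20 generations at
`N = 10⁵`, `L = 6`) averages over 4 landscape realizations × 5 dynamics
seeds: the limit statement is an ensemble property, and a single rugged
realization with near-degenerate competing adaptive directions can amplify
sampling noise chaotically without contradicting it.

## What the generator does and does not emulate

The synthetic landscapes capture tunable sign epistasis, the combinatorial
density of local optima, and (RMF) a global fitness gradient — the
features that drive trapping and the transitory advantage.  They do not
emulate empirical distributions of fitness effects, correlated random
components, more than two alleles per locus, linkage maps (crossover is
uniform by construction), diploidy, or demographic structure.  Passing
tests therefore demonstrate the mechanisms on these model classes, not
quantitative predictions for any real organism.

## Known limitations

* The finite engine models at most one mutation per individual per
  generation; the all-orders operator `M∞` exists only in the
  deterministic engine.  The two agree at first order in `μ`, and the
  consistency test uses `M₁` accordingly.
* Trajectory records store modal-genotype summaries, not full frequency
  snapshots; escape detection at `θ_escape > 0.5` would need the optional
  full-frequency output.
* `escape_fraction` tends to 1 as the horizon grows only on ensembles
  where every trapping eventually resolves; within finite horizons it is a
  censored ratio.
* Stationary states of the deterministic dynamics are reached by long-run
  iteration only; no spectral or fixed-point solver is provided.
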