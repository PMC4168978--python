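# recombscape

Wright–Fisher dynamics with recombination on tunably rugged fitness
landscapes and time-dependent seascapes.

## The scientific problem

Why do so many microorganisms recombine only facultatively?  On a *smooth*
fitness landscape, recombination speeds up adaptation by combining
beneficial mutations from different lineages (the Fisher–Muller effect) and
by boosting genetic variation (the Weismann effect).  On a *rugged*
landscape — one with sign epistasis and therefore multiple local fitness
peaks — recombination between individuals sitting on a peak mostly
reconstitutes the peak genotype, destroying the rare valley mutants needed
to cross to a better peak.  Recombining populations therefore adapt faster
at first but then become **trapped** at local optima, while non-recombining
populations escape by sequential mutation and eventually overtake.  The
advantage of recombination is *transitory* on static rugged landscapes, but
can be sustained indefinitely when the environment keeps changing on the
right time scale.

`recombscape` is a simulator for studying exactly this, for quantitative
and evolutionary geneticists:

* **Landscapes** on the `L`-locus binary hypercube: additive, Rough Mount
  Fuji (`F(σ) = c·d(σ, σ*) + η_σ`, with `η_σ` i.i.d. exponential with mean
  `λ` and `d` the Hamming distance to a reference genotype `σ*`), House of
  Cards (i.i.d. fitness), and Kauffman's NK model — plus exhaustive
  local-maxima analysis.
* **Finite populations**: a modified Wright–Fisher generation —
  deterministic mutation flow (`μ/L` to each single-mutant neighbour) and
  multiplicative selection (`p'_σ ∝ p_σ F_σ`) on frequencies, independent
  Poisson resampling to size `N`, then replacement of `k ~ Poisson(rN)`
  individuals by uniform-crossover offspring of random parents, where `r`
  is the recombining fraction.
* **Infinite populations**: the deterministic operator dynamics
  `p(t+1) ∝ R_r S M p(t)`, with the all-orders mutation matrix
  `M∞ = (1−μ)(I − (μ/L)A)⁻¹` (geometric series over the hypercube
  adjacency `A`), and an arbitrary-precision mode (≥ 30 significant digits)
  so that exponentially small genotype frequencies are never lost.
* **Seascapes**: the random fitness components are redrawn and `σ*` moves
  (soft reset: one Hamming step; hard reset: uniformly random) with
  probability `p_reset` per generation.
* **Observables**: mean and maximal fitness, Shannon entropy
  `S = −Σ p_σ ln p_σ`, additive genetic variance `c²·Var[d(σ, σ*)]`,
  fitness velocities, trapping/escape event detection, and the paired
  difference series `ΔF(t)`, `ΔS(t)`, `P₊(t)` between a recombining and a
  non-recombining population evolving on the *same* landscape realization.

## Worked example

Inspect one rugged Rough-Mount-Fuji realization:

```
$ recombscape landscape --L 8 --model rmf --c 1 --lam 2 --seed 7
model=rmf L=8 genotypes=256 local_maxima=21 F_max=12.7937
```

Of 256 genotypes, 21 are local fitness peaks — plenty of places for a
population to get stuck.

Run a paired ensemble (recombining `r = 1` vs non-recombining `r = 0`, both
arms on the same 50 landscape realizations, starting monomorphically at
`σ*`):

```
$ recombscape paired --L 10 --model rmf --c 1 --lam 1 \
      --N 1000 --mu 0.01 --r 1 --t-max 400 --runs 50 --seed 7
n_pairs=50 t_max=400 delta_max=0.284839 at t=32 t_zero=98
```

Read: the mean-fitness advantage of recombination `ΔF(t)` peaks at
generation 32 (`ΔF = 0.28` fitness units), and first drops to zero at
generation 98 — after which the non-recombining arm is ahead for good:
recombining populations have been trapped at local peaks.  On an additive
landscape (`--model additive`) the same command shows a much larger peak
and a long-time value of about zero instead: without sign epistasis there
is no trapping, only a small recombination load.

The same experiments are available as library calls
(`recombscape.paired_ensemble`, `recombscape.sweep`,
`recombscape.run_seascape`, ...), which also expose per-run series, trap
events and full trajectories.

## Layout

| module | contents |
| --- | --- |
| `recombscape.landscapes` | landscape generation, local maxima, serialization |
| `recombscape.finite_dynamics` | stochastic Wright–Fisher engine with recombination |
| `recombscape.infinite_dynamics` | deterministic operator dynamics, arbitrary precision |
| `recombscape.seascape` | landscape resets and seascape runs |
| `recombscape.observables` | entropy, variance, velocities, trapping, Δ-series |
| `recombscape.experiments` | paired ensembles, sweeps, seed schedule, fixtures |
| `recombscape.cli` | `recombscape` command-line interface |

See `docs/methods.md` for the model definitions, numerical choices and
known limitations.
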