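"""Finite-population Wright-Fisher engine: substeps and full runs."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from recombscape.finite_dynamics import (
    DynamicsParams,
    FinitePopulation,
    mutation_step,
    recombination_step,
    run_finite,
    sampling_step,
    selection_step,
    step_finite,
    uniform_crossover,
)
from recombscape.landscapes import (
    FitnessLandscape,
    LandscapeParams,
    generate_landscape,
    neighbor_table,
)


def random_simplex(n, rng):
    p = rng.random(n)
    return p / p.sum()


# ---------------------------------------------------------------------------
# mutation
# ---------------------------------------------------------------------------

def test_mutation_identity_at_mu_zero(rng):
    p = random_simplex(8, rng)
    assert np.array_equal(mutation_step(p, 0.0, 3), p)


def test_mutation_monomorphic_spreads_to_neighbors():
    p = np.array([1.0, 0.0, 0.0, 0.0])
    out = mutation_step(p, 0.1, 2)
    assert np.allclose(out, [0.9, 0.05, 0.05, 0.0], atol=1e-15)


def test_mutation_uniform_is_fixed_point(rng):
    p = np.full(16, 1 / 16)
    for mu in (0.01, 0.5, 1.0):
        assert np.allclose(mutation_step(p, mu, 4), p, atol=1e-15)


def test_mutation_matches_matrix_oracle(rng):
    """Against the explicit operator (1-mu) I + (mu/L) A."""
    for L in (2, 3, 4):
        n = 1 << L
        A = np.zeros((n, n))
        for g in range(n):
            for i in range(L):
                A[g ^ (1 << i), g] = 1.0
        for mu in (0.0, 0.05, 0.3, 1.0):
            M = (1 - mu) * np.eye(n) + (mu / L) * A
            p = random_simplex(n, rng)
            assert np.max(np.abs(mutation_step(p, mu, L) - M @ p)) < 1e-12


@given(data=st.data(), mu=st.floats(0, 1))
def test_mutation_conserves_mass(data, mu):
    L = data.draw(st.integers(1, 5))
    raw = data.draw(
        st.lists(st.floats(0, 1, exclude_min=False), min_size=1 << L, max_size=1 << L)
    )
    total = sum(raw)
    if total == 0:
        raw = [1.0] * (1 << L)
        total = float(1 << L)
    p = np.array(raw) / total
    assert abs(mutation_step(p, mu, L).sum() - 1.0) <= 1e-12


def test_mutation_rejects_bad_mu():
    with pytest.raises(ValueError):
        mutation_step(np.array([1.0, 0.0]), 1.5, 1)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def _flat_landscape(L, value=1.0):
    params = LandscapeParams(L=L, model="hoc", c=0.0, lam=1.0, seed=0)
    return FitnessLandscape(params=params, F=np.full(1 << L, value))


def test_selection_neutral_identity(rng):
    land = _flat_landscape(3)
    p = random_simplex(8, rng)
    assert np.allclose(selection_step(p, land), p, atol=1e-15)


def test_selection_two_genotype_arithmetic():
    params = LandscapeParams(L=1, model="hoc", c=0.0, lam=1.0, seed=0)
    land = FitnessLandscape(params=params, F=np.array([1.0, 3.0]))
    out = selection_step(np.array([0.5, 0.5]), land)
    assert np.allclose(out, [0.25, 0.75], atol=1e-15)


def test_selection_mean_fitness_never_decreases(rng):
    """Post-selection mean fitness is E[F^2]/E[F] >= E[F] (Cauchy-Schwarz)."""
    params = LandscapeParams(L=4, model="hoc", c=0.0, lam=1.0, seed=0)
    for _ in range(50):
        F = rng.random(16) + 0.01
        land = FitnessLandscape(params=params, F=F)
        p = random_simplex(16, rng)
        before = p @ F
        after = selection_step(p, land) @ F
        assert after >= before - 1e-12
        assert after == pytest.approx((p @ F**2) / before)


def test_selection_zero_mean_fitness_fails():
    params = LandscapeParams(L=1, model="hoc", c=0.0, lam=1.0, seed=0)
    land = FitnessLandscape(params=params, F=np.array([0.0, 5.0]))
    with pytest.raises(ValueError, match="mean fitness"):
        selection_step(np.array([1.0, 0.0]), land)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def test_sampling_monomorphic_and_exact_size(rng):
    p = np.zeros(8)
    p[3] = 1.0
    counts = sampling_step(p, 500, rng)
    assert counts[3] == 500 and counts.sum() == 500


def test_sampling_unbiased(rng):
    """Mean of count/N over 10,000 repetitions within 3 SE of p."""
    p = np.array([0.3, 0.25, 0.25, 0.2])
    N, reps = 1000, 10_000
    vals = np.empty(reps)
    for i in range(reps):
        vals[i] = sampling_step(p, N, rng)[0] / N
    se = vals.std(ddof=1) / np.sqrt(reps)
    assert abs(vals.mean() - 0.3) < 3 * se


def test_sampling_deterministic_given_seed():
    p = random_simplex(16, np.random.default_rng(0))
    a = sampling_step(p, 300, np.random.default_rng(42))
    b = sampling_step(p, 300, np.random.default_rng(42))
    assert np.array_equal(a, b)


def test_sampling_rejects_bad_N(rng):
    with pytest.raises(ValueError):
        sampling_step(np.array([1.0]), 0, rng)


# ---------------------------------------------------------------------------
# recombination
# ---------------------------------------------------------------------------

def test_crossover_identical_parents(rng):
    for _ in range(20):
        a = int(rng.integers(0, 16))
        assert uniform_crossover(a, a, 4, rng) == a


def test_crossover_complementary_parents_uniform(rng):
    """a=00, b=11: each offspring genotype with probability 1/4."""
    draws = [uniform_crossover(0b00, 0b11, 2, rng) for _ in range(10_000)]
    counts = np.bincount(draws, minlength=4)
    assert stats.chisquare(counts).pvalue > 0.01


def test_crossover_shared_locus_inherited(rng):
    draws = np.array([uniform_crossover(0b01, 0b00, 2, rng) for _ in range(2000)])
    assert set(draws) == {0b00, 0b01}
    assert stats.chisquare(np.bincount(draws, minlength=2)).pvalue > 0.01


def test_recombination_r_zero_is_identity(rng):
    pop = FinitePopulation(counts=np.array([5, 3, 2, 0], dtype=np.int64), N=10)
    assert recombination_step(pop, 0.0, rng) is pop


def test_recombination_monomorphic_invariant(rng):
    pop = FinitePopulation.monomorphic(3, 0b101, 200)
    out = recombination_step(pop, 1.0, rng)
    assert np.array_equal(out.counts, pop.counts)


def test_recombination_preserves_size_and_allele_frequency(rng):
    """Expected per-locus mutant frequency is unchanged (Monte Carlo)."""
    L, N, reps = 3, 1000, 10_000
    counts = np.array([300, 200, 150, 100, 100, 80, 50, 20], dtype=np.int64)
    g = np.arange(8)
    locus0 = ((g >> 0) & 1).astype(float)
    f0 = (counts * locus0).sum() / N
    pop = FinitePopulation(counts=counts, N=N)
    vals = np.empty(reps)
    for i in range(reps):
        out = recombination_step(pop, 0.5, rng)
        assert out.counts.sum() == N
        vals[i] = (out.counts * locus0).sum() / N
    se = vals.std(ddof=1) / np.sqrt(reps)
    assert abs(vals.mean() - f0) < 3 * se


def test_recombination_rejects_bad_r(rng):
    pop = FinitePopulation.monomorphic(2, 0, 10)
    with pytest.raises(ValueError):
        recombination_step(pop, 1.5, rng)


# ---------------------------------------------------------------------------
# full generations and runs
# ---------------------------------------------------------------------------

def test_step_absorbing_state(rng):
    """mu=0, r=0, flat fitness, monomorphic: nothing can change."""
    land = _flat_landscape(3)
    dp = DynamicsParams(N=100, mu=0.0, r=0.0)
    pop = FinitePopulation.monomorphic(3, 0b010, 100)
    for _ in range(20):
        pop = step_finite(pop, land, dp, rng)
        assert pop.counts[0b010] == 100
    assert pop.t == 20


def test_step_deterministic_given_seed():
    land = generate_landscape(LandscapeParams(L=4, model="rmf", c=1.0, lam=1.0, seed=1))
    dp = DynamicsParams(N=200, mu=0.05, r=0.7)
    pop = FinitePopulation.monomorphic(4, 0, 200)
    a = step_finite(pop, land, dp, np.random.default_rng(5))
    b = step_finite(pop, land, dp, np.random.default_rng(5))
    assert np.array_equal(a.counts, b.counts)


def test_population_size_exact_across_random_parameters(rng):
    """Size is exactly N after every generation, whatever the parameters."""
    for _ in range(300):
        L = int(rng.integers(1, 6))
        N = int(rng.integers(1, 500))
        dp = DynamicsParams(N=N, mu=float(rng.random()), r=float(rng.random()))
        land = generate_landscape(
            LandscapeParams(L=L, model="rmf", c=1.0, lam=1.0, seed=int(rng.integers(1 << 30)))
        )
        pop = FinitePopulation.monomorphic(L, 0, N)
        pop = step_finite(pop, land, dp, rng)
        assert pop.counts.sum() == N
        assert np.all(pop.counts >= 0)


def test_run_finite_t0_record(additive_L3):
    land, _ = additive_L3
    dp = DynamicsParams(N=100, mu=0.01, r=0.5)
    records = run_finite(land, dp, 0, rng=np.random.default_rng(0))
    assert len(records) == 1
    rec = records[0]
    assert rec.entropy == 0.0
    assert rec.mean_fitness == land.F[land.params.sigma_star]
    assert rec.modal_frequency == 1.0


def test_run_finite_records_modal_bookkeeping(additive_L3):
    land, _ = additive_L3
    dp = DynamicsParams(N=200, mu=0.05, r=0.3)
    records = run_finite(land, dp, 30, rng=np.random.default_rng(3))
    assert len(records) == 31
    for rec in records:
        assert 0 < rec.modal_frequency <= 1.0
        assert rec.max_fitness >= rec.mean_fitness - 1e-12
        assert 0 <= rec.modal_genotype < 8


def test_run_finite_climbs_additive_landscape():
    """r=0, small mu: selection pushes mean fitness up in nearly every run."""
    land = generate_landscape(
        LandscapeParams(L=6, model="additive", c=1.0, lam=0.0, seed=0)
    )
    dp = DynamicsParams(N=500, mu=0.01, r=0.0)
    climbed = 0
    for seed in range(200):
        recs = run_finite(land, dp, 500, rng=np.random.default_rng(seed))
        climbed += recs[-1].mean_fitness > recs[0].mean_fitness
    assert climbed >= 198  # >= 99% of 200 runs


def test_run_finite_trajectory_tsv(tmp_path, additive_L3):
    from recombscape.finite_dynamics import write_trajectory_tsv

    land, _ = additive_L3
    dp = DynamicsParams(N=100, mu=0.02, r=0.5)
    records = run_finite(land, dp, 10, rng=np.random.default_rng(1))
    path = tmp_path / "traj.tsv"
    write_trajectory_tsv(records, path, land.L, config={"N": 100})
    lines = path.read_text().splitlines()
    header_rows = [l for l in lines if l.startswith("#")]
    data_rows = [l for l in lines if not l.startswith("#")]
    assert len(data_rows) == 12  # header + 11 generations
    assert data_rows[0].split("\t")[0] == "t"
    assert any('"N": 100' in l for l in header_rows)
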