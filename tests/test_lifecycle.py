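"""Engine tests: initialization, the four life stages, and whole-run invariants."""

import numpy as np
import pytest

from cbh import (
    SimParams,
    initialize_population,
    run_simulation,
    step_generation,
)
from cbh.lifecycle import (
    birth_stage,
    learning_stage_2a,
    learning_stage_2b,
    migration_stage,
    selection_stage,
)
from cbh.state import Individual, Trajectory


def _rng(seed=0):
    return np.random.Generator(np.random.PCG64(seed))


# --------------------------------------------------------------------------
# Initialization
# --------------------------------------------------------------------------

def test_initialize_founding_population():
    p = SimParams()
    state = initialize_population(p, 42)
    assert state.size == 500
    assert np.all(state.a == 0.0)
    assert np.all(state.b == 1.0)
    assert np.all(state.s == 0.0)
    np.testing.assert_array_equal(state.deme_sizes(), np.full(50, 10))


def test_initialize_social_start():
    state = initialize_population(SimParams(init_s=1.0), 42)
    assert np.all(state.s == 1.0)


def test_initialize_deterministic():
    p = SimParams()
    s1, s2 = initialize_population(p, 7), initialize_population(p, 7)
    np.testing.assert_array_equal(s1.rng.random(100), s2.rng.random(100))


# --------------------------------------------------------------------------
# Stage 1: births
# --------------------------------------------------------------------------

def test_birth_stage_empty_deme(params):
    from cbh.state import Deme
    assert birth_stage(Deme(index=0), params, _rng()) == []


def test_birth_stage_counts_and_parent_bookkeeping(params):
    """Without skew every parent is equally likely; total newborns track the
    logistic expectation, and parents' offspring counters add up."""
    from cbh.state import Deme
    p = params.with_overrides(phi=0.0)
    totals = []
    for seed in range(200):
        deme = Deme(index=0, members=[Individual(b=1.0, a=0.5)
                                      for _ in range(10)])
        newborns = birth_stage(deme, p, _rng(seed))
        assert sum(ind.n_genetic_offspring for ind in deme.members) == len(newborns)
        assert all(nb.a == 0.0 for nb in newborns)
        totals.append(len(newborns))
    # E[total] = round(N') with N' = 10*e^0.8 / (1 + (10/15)(e^0.8-1)) ~ 12.3
    expect = 10 * np.e ** 0.8 / (1 + (10 / 15) * (np.e ** 0.8 - 1))
    assert np.mean(totals) == pytest.approx(expect, rel=0.1)


# --------------------------------------------------------------------------
# Stage 2: learning
# --------------------------------------------------------------------------

def test_stage_2a_branches(params):
    p = params.with_overrides(tau=1.0)
    # pure asocial learner never copies
    nb = Individual(b=10.0, s=0.0)
    parent = Individual(b=10.0, a=9.0)
    learning_stage_2a(nb, parent, p, _rng())
    assert nb.a > 0 and parent.n_cultural_learners == 0
    # pure social learner with an ignorant parent learns nothing
    nb = Individual(b=10.0, s=1.0)
    parent = Individual(b=10.0, a=0.0)
    learning_stage_2a(nb, parent, p, _rng())
    assert nb.a == 0.0 and parent.n_cultural_learners == 1
    # near-degenerate copy is capped by the learner's brain
    p2 = params.with_overrides(tau=1.0, sigma_a=1e-12)
    nb = Individual(b=3.0, s=1.0)
    learning_stage_2a(nb, Individual(b=10.0, a=2.0), p2, _rng())
    assert nb.a == pytest.approx(2.0)


def test_stage_2b_branches(params):
    # s=1, v=0: no second-round learning at all
    learner = Individual(b=10.0, a=1.0, s=1.0, v=0.0)
    pool = [Individual(b=10.0, a=9.0)]
    for seed in range(50):
        learning_stage_2b(learner, pool, params, _rng(seed))
    assert learner.a == 1.0
    # a worse candidate never overwrites (copy of a=1 model vs current a=2)
    p = params.with_overrides(tau=0.5, sigma_a=1e-12)
    learner = Individual(b=10.0, a=2.0, s=1.0, v=1.0)
    learning_stage_2b(learner, [Individual(b=10.0, a=2.0)], p, _rng())
    assert learner.a == 2.0
    # oblique copy from the pool's best model when bias is strong
    p = params.with_overrides(tau=1.0, sigma_a=1e-12)
    learner = Individual(b=10.0, a=0.0, s=1.0, v=1.0, l=50.0)
    pool = [Individual(b=10.0, a=1.0), Individual(b=10.0, a=8.0)]
    learning_stage_2b(learner, pool, p, _rng())
    assert learner.a == pytest.approx(8.0)
    assert pool[1].n_cultural_learners == 1
    # empty pool: oblique branch silently learns nothing
    learner = Individual(b=10.0, a=1.5, s=1.0, v=1.0)
    learning_stage_2b(learner, [], params, _rng())
    assert learner.a == 1.5


def test_stage_2b_unbiased_choice_is_uniform(params):
    """With l = 0 the sigmoid is flat, so model choice is uniform."""
    p = params.with_overrides(tau=1.0, sigma_a=1e-9)
    picks = []
    for seed in range(3000):
        pool = [Individual(b=10.0, a=1.0), Individual(b=10.0, a=2.0),
                Individual(b=10.0, a=3.0)]
        learner = Individual(b=10.0, a=0.0, s=1.0, v=1.0, l=0.0)
        learning_stage_2b(learner, pool, p, _rng(seed))
        picks.append(round(learner.a))
    counts = np.bincount(picks, minlength=4)[1:]
    assert stats_chisquare_ok(counts)


def stats_chisquare_ok(counts, alpha=1e-6):
    from scipy import stats
    return stats.chisquare(counts).pvalue > alpha


# --------------------------------------------------------------------------
# Stages 3 and 4
# --------------------------------------------------------------------------

def test_migration_conserves_and_m_zero_is_identity(params):
    p0 = params.with_overrides(m=0.0)
    state = initialize_population(p0, 3)
    before = state.deme.copy()
    migration_stage(state, p0)
    np.testing.assert_array_equal(state.deme, before)

    p = SimParams(m=0.1, n_demes=50, init_deme_size=200)  # 10^4 agents
    state = initialize_population(p, 3)
    before = state.deme.copy()
    ids_before = np.sort(state.ids)
    migration_stage(state, p)
    assert state.size == 10_000                      # nobody lost in transit
    np.testing.assert_array_equal(np.sort(state.ids), ids_before)
    moved = np.sum(state.deme[np.argsort(state.ids)]
                   != before[np.argsort(ids_before)])
    sd = np.sqrt(10_000 * 0.1 * 0.9)
    assert abs(moved - 1000) < 4 * sd


def test_selection_extremes(params):
    state = initialize_population(SimParams(init_b=1.0), 5)
    state.b[:] = 100.0  # empty 100-sized brains die with certainty
    selection_stage(state, params.with_overrides(lam=0.0))
    assert state.size == 0

    p = SimParams()  # b=1, a=0: survival probability 0.9999 each
    state = initialize_population(p, 5)
    selection_stage(state, p)
    assert state.size >= 490


def test_selection_ignores_knowledge_without_returns(params):
    """lam = 0: survival draws are identical whatever the knowledge."""
    p = params.with_overrides(lam=0.0)
    s1 = initialize_population(p, 9)
    s2 = initialize_population(p, 9)
    s2.a[:] = s2.b  # full brains
    selection_stage(s1, p)
    selection_stage(s2, p)
    np.testing.assert_array_equal(s1.ids, s2.ids)


# --------------------------------------------------------------------------
# Whole generations
# --------------------------------------------------------------------------

def test_step_determinism_and_fixed_demes(params):
    p = params.with_overrides(generations=0)
    states = []
    for _ in range(2):
        state = initialize_population(p, 11)
        for _ in range(5):
            state = step_generation(state, p)
        states.append(state)
    np.testing.assert_array_equal(states[0].ids, states[1].ids)
    np.testing.assert_array_equal(states[0].a, states[1].a)
    assert states[0].deme_sizes().shape == (50,)


def test_knowledge_capacity_invariant_over_generations(params):
    state = initialize_population(params, 13)
    for _ in range(20):
        state = step_generation(state, params)
        assert np.all(state.a >= 0.0)
        assert np.all(state.a <= state.b + 1e-12)
        assert np.all(state.b > 0)


def test_no_mutation_means_no_variation(params):
    p = params.with_overrides(mu=0.0)
    state = initialize_population(p, 17)
    for _ in range(10):
        state = step_generation(state, p)
    for arr, init in [(state.b, 1.0), (state.s, 0.4), (state.v, 0.3),
                      (state.l, 0.5)]:
        assert np.all(arr == init)


def test_neutral_population_tracks_carrying_capacity():
    """With no knowledge returns and no mutation, long-run deme sizes settle
    within 10% of the capacity implied by long-run knowledge."""
    p = SimParams(lam=0.0, mu=0.0, phi=0.0, zeta=0.5, generations=0)
    state = initialize_population(p, 19)
    traj = Trajectory()
    for _ in range(200):
        state = step_generation(state, p, trajectory=traj)
    df = traj.to_frame().iloc[100:]
    mean_deme_size = df["n_total"].mean() / 50
    k = 10.0 * df["mean_a"].mean() + 10.0
    assert mean_deme_size == pytest.approx(k, rel=0.10)


def test_offspring_exchangeable_without_skew():
    """phi = 0 with equal knowledge: per-parent offspring counts across many
    generations are exchangeable across parent positions."""
    from scipy import stats
    p = SimParams(phi=0.0, mu=0.0, lam=0.0, generations=0,
                  n_demes=2, init_deme_size=25)
    first, last = [], []
    for seed in range(300):
        state = initialize_population(p, seed)
        from cbh.lifecycle import _births
        *_, parent_idx, _ = _births(state, p)
        counts = np.bincount(parent_idx, minlength=state.size)
        first.append(counts[0])
        last.append(counts[24])
    ks = stats.ks_2samp(first, last)
    assert ks.pvalue > 1e-4


def test_run_simulation_contracts(params):
    r0 = run_simulation(params.with_overrides(generations=0), 23)
    assert len(r0.trajectory) == 0 and r0.final_state.size == 500

    p = params.with_overrides(generations=30)
    r = run_simulation(p, 23)
    assert len(r.trajectory) == 30
    assert not r.extinct
    assert r.bookkeeping.born >= 500
    assert 0.0 <= r.bookkeeping.extinction_rate <= 1.0
    # population column is consistent with the final state
    assert r.trajectory["n_total"].iloc[-1] == r.final_state.size


def test_global_extinction_flagged():
    # an enormous initial brain guarantees immediate global death
    p = SimParams(init_b=150.0, lam=0.0, generations=50)
    r = run_simulation(p, 1)
    assert r.extinct
    assert r.extinct_generation == 1
    assert r.final_state.size == 0
    assert len(r.trajectory) == 1


def test_social_start_dips_then_recovers():
    """Starting from all social learners in a knowledge-poor world, asocial
    learning invades early; once knowledge accumulates, social learning
    recovers (high fidelity, rich ecology)."""
    p = SimParams(lam=2.0, tau=1.0, zeta=0.7, init_s=1.0, generations=2500)
    r = run_simulation(p, 3)
    s = r.trajectory["mean_s"]
    t_min = int(s.idxmin())
    assert s.iloc[t_min] < s.iloc[0] - 0.05       # the early dip
    assert s.iloc[-200:].mean() > s.iloc[t_min] + 0.05  # the recovery
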