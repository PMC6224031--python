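"""The generational engine: birth -> learning (2A, 2B) -> migration -> selection.

Non-overlapping generations on a fixed set of demes linked by island-model
migration.  Each generation the current adults reproduce (payoff-biased
binomial fecundity under a knowledge-linked logistic cap), newborns learn
vertically from their parent or asocially (Stage 2A), then asocially again
or obliquely from payoff-chosen adults of their natal deme (Stage 2B),
migrate, and face viability selection on brain cost vs. knowledge.
Survivors become the next adult generation; the previous adults retire.

Determinism contract
--------------------
One seeded :class:`numpy.random.Generator` (PCG64) drives a run.  All draws
are made in fixed stage-batched passes over the deme-sorted population, and
every pass consumes exactly one uniform per individual (normal deviates are
inverse-CDF transforms of those uniforms; unused branch draws are consumed
and discarded).  The exact order per generation:

1.  B1  per-adult offspring counts, ``Binomial(n_j, p_i)`` in array order
2.  B2  mutation indicators, one ``(n_new, 4)`` row-major block (b, s, v, l)
3.  B3  mutation value uniforms, same shape and order
4.  L1  Stage-2A branch uniforms (social iff ``u < s``)
5.  L2  Stage-2A knowledge-value uniforms
6.  L3  Stage-2B branch uniforms (asocial iff ``u < 1-s``; oblique iff
        ``1-s <= u < 1-s+s*v``; otherwise no learning)
7.  L4  Stage-2B model-choice uniforms
8.  L5  Stage-2B knowledge-value uniforms
9.  M1  migration indicator uniforms (``u < m``)
10. M2  destination uniforms (offset ``floor(u * (D-1))``, skipping self),
        then a stable re-sort of newborns by destination deme
11. S1  survival uniforms (die iff ``u < d``)

Oblique model choice picks, for learner ``i`` with bias ``l_i``, the first
adult index ``t`` of the natal deme whose running sum of sigmoid weights
exceeds ``u * total`` (last adult if the threshold is never exceeded).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from . import core
from .core import SimParams
from .state import Deme, Individual, PopulationState, Trajectory

__all__ = [
    "Bookkeeping",
    "RunResult",
    "initialize_population",
    "birth_stage",
    "learning_stage_2a",
    "learning_stage_2b",
    "migration_stage",
    "selection_stage",
    "step_generation",
    "run_simulation",
]


@dataclass
class Bookkeeping:
    """Extinction-rate accounting across a whole run.

    An individual "passes on" iff it leaves at least one genetic offspring
    or at least one cultural learner by the time it dies; the extinction
    rate is the fraction of all individuals ever born that die without
    passing on.  Individuals still alive when the run ends stay in the
    denominator only.
    """

    born: int = 0
    non_passers: int = 0

    @property
    def extinction_rate(self) -> float:
        if self.born == 0:
            return float("nan")
        return self.non_passers / self.born


@dataclass
class RunResult:
    """Everything one simulation run produces."""

    params: SimParams
    seed: int
    trajectory: pd.DataFrame
    final_state: PopulationState
    bookkeeping: Bookkeeping
    extinct: bool
    extinct_generation: Optional[int] = None


def initialize_population(p: SimParams, seed) -> PopulationState:
    """Found the metapopulation: ``n_demes`` demes of identical naive agents.

    Every founder has brain ``init_b``, no knowledge, and the configured
    learning genotype.  The state's RNG is seeded from ``seed`` (an int or a
    :class:`numpy.random.SeedSequence`).
    """
    n = p.n_demes * p.init_deme_size
    deme = np.repeat(np.arange(p.n_demes, dtype=np.int64), p.init_deme_size)
    rng = np.random.Generator(np.random.PCG64(seed))
    return PopulationState(
        n_demes=p.n_demes,
        deme=deme,
        b=np.full(n, p.init_b),
        a=np.zeros(n),
        s=np.full(n, p.init_s),
        v=np.full(n, p.init_v),
        l=np.full(n, p.init_l),
        ids=np.arange(n, dtype=np.int64),
        rng=rng,
        t=0,
    )


# --------------------------------------------------------------------------
# Object-level stage operations (readable API; the vectorized engine below
# implements the same logic for whole populations at once)
# --------------------------------------------------------------------------

def birth_stage(deme: Deme, p: SimParams, rng) -> List[Individual]:
    """Produce the newborns of one deme from its surviving adults.

    The deme-level expected count comes from logistic growth toward the
    knowledge-linked carrying capacity; it is split over parents by
    independent binomials with payoff-biased success probabilities.
    """
    if not deme.members:
        return []
    A = deme.mean_knowledge
    k = float(core.carrying_capacity(A, p.chi, p.init_deme_size))
    n_expect = float(core.expected_next_size(deme.size, k, p.rho))
    n_trials = max(int(np.rint(n_expect)), 0)
    weights = core.selection_weights([ind.a for ind in deme.members], A, p.phi)
    newborns: List[Individual] = []
    for parent, w in zip(deme.members, weights):
        count = int(rng.binomial(n_trials, w))
        parent.n_genetic_offspring += count
        for _ in range(count):
            b2, s2, v2, l2 = core.mutate_offspring(
                parent.b, parent.s, parent.v, parent.l, p, rng)
            newborns.append(Individual(b=float(b2[0]), a=0.0, s=float(s2[0]),
                                       v=float(v2[0]), l=float(l2[0])))
    return newborns


def learning_stage_2a(newborn: Individual, parent: Individual,
                      p: SimParams, rng) -> Individual:
    """First learning round: copy the parent with probability ``s``, else invent."""
    if rng.random() < newborn.s:
        newborn.a = float(core.social_knowledge_draw(
            parent.a, newborn.b, p.tau, p.sigma_a, rng))
        parent.n_cultural_learners += 1
    else:
        newborn.a = float(core.asocial_knowledge_draw(
            newborn.b, p.zeta, p.sigma_a, rng))
    return newborn


def learning_stage_2b(learner: Individual, model_pool: List[Individual],
                      p: SimParams, rng) -> Individual:
    """Second learning round: asocial redo, payoff-biased oblique copy, or nothing.

    A candidate value only replaces the learner's knowledge if strictly
    larger.  With probability ``s - s*v`` no second-round learning happens
    at all, which is the cost an extended juvenile period must out-compete.
    """
    u = rng.random()
    if u < 1.0 - learner.s:
        cand = float(core.asocial_knowledge_draw(
            learner.b, p.zeta, p.sigma_a, rng))
    elif u < (1.0 - learner.s) + learner.s * learner.v:
        if not model_pool:
            return learner
        pool_a = np.array([ind.a for ind in model_pool])
        A = float(np.sum(pool_a)) / len(model_pool)
        weights = core.selection_weights(pool_a, A, learner.l)
        cum = np.cumsum(weights)
        pick = min(int(np.searchsorted(cum, rng.random() * cum[-1],
                                       side="right")), len(model_pool) - 1)
        model = model_pool[pick]
        cand = float(core.social_knowledge_draw(
            model.a, learner.b, p.tau, p.sigma_a, rng))
        model.n_cultural_learners += 1
    else:
        return learner
    if cand > learner.a:
        learner.a = min(cand, learner.b)
    return learner


# --------------------------------------------------------------------------
# Vectorized engine
# --------------------------------------------------------------------------

def _births(state: PopulationState, p: SimParams):
    """Stage 1 for the whole population.  Returns newborn arrays (deme-sorted,
    parent-major) plus the per-deme mean knowledge of the adult generation."""
    rng = state.rng
    sizes = state.deme_sizes()
    A = state.deme_mean_knowledge()
    k = core.carrying_capacity(A, p.chi, p.init_deme_size)
    n_expect = core.expected_next_size(sizes, k, p.rho)
    n_trials = np.rint(n_expect).astype(np.int64)

    w = core.knowledge_sigmoid(state.a, A[state.deme], p.phi)
    denom = np.bincount(state.deme, weights=w, minlength=p.n_demes)
    p_sel = w / denom[state.deme]
    counts = rng.binomial(n_trials[state.deme], p_sel)            # B1
    state.n_off += counts

    parent_idx = np.repeat(np.arange(state.size), counts)
    n_new = parent_idx.shape[0]
    if n_new == 0:
        empty = np.empty(0)
        return (np.empty(0, dtype=np.int64), empty, empty, empty, empty,
                np.empty(0, dtype=np.int64), parent_idx, A)
    b2, s2, v2, l2 = core.mutate_offspring(                       # B2, B3
        state.b[parent_idx], state.s[parent_idx], state.v[parent_idx],
        state.l[parent_idx], p, rng)
    new_deme = state.deme[parent_idx]
    new_ids = np.arange(state._next_id, state._next_id + n_new, dtype=np.int64)
    return new_deme, b2, s2, v2, l2, new_ids, parent_idx, A


def _learning(state: PopulationState, p: SimParams, new_deme, nb, ns, nv, nl,
              parent_idx, A):
    """Stages 2A and 2B for all newborns; returns their knowledge array."""
    rng = state.rng
    n_new = parent_idx.shape[0]
    if n_new == 0:
        return np.empty(0)

    # -- Stage 2A: vertical copy vs. asocial invention
    u_branch = rng.random(n_new)                                  # L1
    u_val = rng.random(n_new)                                     # L2
    social = u_branch < ns
    a_new = np.empty(n_new)
    soc = np.flatnonzero(social)
    aso = np.flatnonzero(~social)
    if soc.size:
        mean = p.tau * state.a[parent_idx[soc]]
        x = core.normal_from_uniform(u_val[soc], mean, p.sigma_a * mean)
        a_new[soc] = np.minimum(np.maximum(x, 0.0), nb[soc])
        state.n_learn += np.bincount(parent_idx[soc], minlength=state.size)
    if aso.size:
        mean = p.zeta * nb[aso]
        x = core.normal_from_uniform(u_val[aso], mean, p.sigma_a * mean)
        a_new[aso] = np.minimum(np.maximum(x, 0.0), nb[aso])

    # -- Stage 2B: asocial redo / oblique copy / nothing
    u_branch2 = rng.random(n_new)                                 # L3
    u_model = rng.random(n_new)                                   # L4
    u_val2 = rng.random(n_new)                                    # L5
    asocial2 = u_branch2 < 1.0 - ns
    oblique = (~asocial2) & (u_branch2 < (1.0 - ns) + ns * nv)

    cand2 = np.full(n_new, -np.inf)
    aso2 = np.flatnonzero(asocial2)
    if aso2.size:
        mean = p.zeta * nb[aso2]
        x = core.normal_from_uniform(u_val2[aso2], mean, p.sigma_a * mean)
        cand2[aso2] = np.minimum(np.maximum(x, 0.0), nb[aso2])
    ob = np.flatnonzero(oblique)
    if ob.size:
        sizes = state.deme_sizes()
        offsets = np.concatenate(([0], np.cumsum(sizes)[:-1]))
        m_max = int(sizes.max())
        # padded (deme, slot) -> adult knowledge, invalid slots weight 0
        a_pad = np.zeros((p.n_demes, m_max))
        slot = np.arange(state.size) - offsets[state.deme]
        a_pad[state.deme, slot] = state.a
        valid = np.arange(m_max)[None, :] < sizes[:, None]

        dj = new_deme[ob]
        z = np.clip(nl[ob, None] * (a_pad[dj] - A[dj, None]),
                    -core.EXP_CLAMP, core.EXP_CLAMP)
        w = 1.0 / (1.0 + np.exp(-z))
        w[~valid[dj]] = 0.0
        cum = np.cumsum(w, axis=1)
        thr = u_model[ob] * cum[:, -1]
        pick = np.minimum(np.sum(cum <= thr[:, None], axis=1), sizes[dj] - 1)
        model_idx = offsets[dj] + pick
        model_a = state.a[model_idx]
        mean = p.tau * model_a
        x = core.normal_from_uniform(u_val2[ob], mean, p.sigma_a * mean)
        cand2[ob] = np.minimum(np.maximum(x, 0.0), nb[ob])
        state.n_learn += np.bincount(model_idx, minlength=state.size)

    return np.where(cand2 > a_new, cand2, a_new)


def migration_stage(state: PopulationState, p: SimParams, rng=None) -> PopulationState:
    """Stage 3: each individual moves with probability ``m`` to a uniformly
    chosen *other* deme, keeping traits and knowledge; arrays are re-sorted
    by deme (stable, so within-deme order is preserved)."""
    rng = state.rng if rng is None else rng
    n = state.size
    u_mig = rng.random(n)                                         # M1
    u_dest = rng.random(n)                                        # M2
    offset = np.floor(u_dest * (p.n_demes - 1)).astype(np.int64)
    dest = (state.deme + 1 + offset) % p.n_demes
    state.deme = np.where(u_mig < p.m, dest, state.deme)
    order = np.argsort(state.deme, kind="stable")
    for name in ("deme", "b", "a", "s", "v", "l", "ids", "n_off", "n_learn"):
        setattr(state, name, getattr(state, name)[order])
    return state


def selection_stage(state: PopulationState, p: SimParams, rng=None) -> PopulationState:
    """Stage 4: independent survival, death probability from brain cost vs.
    knowledge return.  Mutates the state down to the survivors."""
    rng = state.rng if rng is None else rng
    u_die = rng.random(state.size)                                # S1
    d = core.death_probability(state.b, state.a, p.lam, p.beta)
    keep = u_die >= d
    for name in ("deme", "b", "a", "s", "v", "l", "ids", "n_off", "n_learn"):
        setattr(state, name, getattr(state, name)[keep])
    return state


def step_generation(state: PopulationState, p: SimParams,
                    trajectory: Optional[Trajectory] = None,
                    book: Optional[Bookkeeping] = None) -> PopulationState:
    """Advance one full generation and return the next adult state.

    The current adults reproduce and serve as Stage-2 models, then retire;
    newborns learn, migrate, face selection, and the survivors are the next
    generation's adults.  Empty demes persist (their capacity floor keeps
    recolonization possible).
    """
    rng = state.rng
    new_deme, nb, ns, nv, nl, new_ids, parent_idx, A = _births(state, p)
    a_new = _learning(state, p, new_deme, nb, ns, nv, nl, parent_idx, A)
    n_new = new_deme.shape[0]

    if book is not None:
        book.born += n_new
        retiring = (state.n_off == 0) & (state.n_learn == 0)
        book.non_passers += int(np.sum(retiring))

    next_state = PopulationState(
        n_demes=p.n_demes, deme=new_deme, b=nb, a=a_new, s=ns, v=nv, l=nl,
        ids=new_ids, rng=rng, t=state.t + 1,
        next_id=state._next_id + n_new)
    migration_stage(next_state, p)
    selection_stage(next_state, p)
    n_deaths = n_new - next_state.size
    if book is not None:
        # newborns dying at selection have, by construction, passed nothing on
        book.non_passers += n_deaths

    if trajectory is not None:
        n = next_state.size
        if n:
            trajectory.record(
                next_state.t, n, n_new, n_deaths,
                int(np.sum(next_state.deme_sizes() == 0)),
                float(np.mean(next_state.b)), float(np.mean(next_state.a)),
                float(np.mean(next_state.s)), float(np.mean(next_state.v)),
                float(np.mean(next_state.l)),
                float(np.mean(next_state.s * next_state.v)))
        else:
            trajectory.record(next_state.t, 0, n_new, n_deaths,
                              p.n_demes, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    return next_state


def run_simulation(p: SimParams, seed) -> RunResult:
    """Run ``p.generations`` generations (or until global extinction)."""
    state = initialize_population(p, seed)
    book = Bookkeeping(born=state.size)
    traj = Trajectory()
    extinct = False
    extinct_generation: Optional[int] = None
    for _ in range(p.generations):
        state = step_generation(state, p, trajectory=traj, book=book)
        if state.size == 0:
            extinct = True
            extinct_generation = state.t
            break
    seed_int = seed if isinstance(seed, (int, np.integer)) else -1
    return RunResult(params=p, seed=int(seed_int), trajectory=traj.to_frame(),
                     final_state=state, bookkeeping=book, extinct=extinct,
                     extinct_generation=extinct_generation)
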