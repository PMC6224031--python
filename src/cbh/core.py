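"""Pure model primitives: every equation and random kernel of the simulator.

The model couples four genetically transmitted traits -- brain size ``b``,
social-learning probability ``s``, oblique-learning probability ``v`` and
payoff-bias ability ``l`` -- with one learned quantity, adaptive knowledge
``a`` (always ``0 <= a <= b``).  Demes carry a knowledge-linked carrying
capacity, reproduction is payoff-biased through a sigmoid of knowledge,
and survival trades brain cost against knowledge returns.

Everything here is stateless.  Random kernels take a
:class:`numpy.random.Generator` and consume exactly one uniform variate per
returned value (normal deviates are produced by inverse-CDF transform), so
the draw order of any caller is easy to document and reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Tuple

import numpy as np
from scipy.special import ndtr, ndtri

__all__ = [
    "SimParams",
    "B_FLOOR",
    "EXP_CLAMP",
    "carrying_capacity",
    "expected_next_size",
    "knowledge_sigmoid",
    "selection_weights",
    "death_probability",
    "normal_from_uniform",
    "truncated_normal_from_uniform",
    "asocial_knowledge_draw",
    "social_knowledge_draw",
    "mutate_offspring",
    "asocial_invention_probability",
]

#: Lower truncation for mutated brain sizes; keeps beta*b**2 and a/b defined.
B_FLOOR = 1e-3

#: Exponent clamp used in all sigmoids/exponentials; saturation is exact in
#: double precision well before +/-700.
EXP_CLAMP = 700.0


@dataclass(frozen=True)
class SimParams:
    """All model constants and swept parameters for one simulation run.

    Defaults follow the published configuration where one is stated
    (``n_demes=50``, ``init_deme_size=10``, ``chi=10``, ``rho=0.8``,
    ``m=0.1``, ``beta=1e-4``, ``init_b=1.0``); mutation-kernel scales are
    exposed because they are exploration knobs of this implementation.
    """

    n_demes: int = 50
    init_deme_size: int = 10
    chi: float = 10.0              # knowledge -> carrying-capacity slope
    rho: float = 0.8               # generational logistic growth rate
    phi: float = 0.0               # reproductive-skew sigmoid gain, >= 0
    tau: float = 0.9               # transmission fidelity in [0, 1]
    zeta: float = 0.5              # asocial learning efficacy in (0, 1]
    lam: float = 0.0               # survival return on knowledge, >= 0
    m: float = 0.1                 # migration probability
    mu: float = 0.01               # per-trait mutation probability
    sigma_a: float = 0.1           # learning-noise coefficient of variation
    sigma_b: float = 0.05          # brain mutation CV (SD = sigma_b * b)
    sigma_s: float = 0.05          # absolute SD for s mutations
    sigma_v: float = 0.05          # absolute SD for v mutations
    sigma_l: float = 0.1           # absolute SD for l mutations
    beta: float = 1e-4             # brain-cost coefficient (c_max = beta*b^2)
    init_b: float = 1.0
    init_s: float = 0.0            # 0.0 = asocial start, 1.0 = social start
    init_v: float = 0.0
    init_l: float = 0.0
    generations: int = 200_000
    cc_threshold: float = 0.001    # cumulative-culture probability cutoff

    def __post_init__(self) -> None:
        if self.n_demes < 2:
            raise ValueError("n_demes must be >= 2 (migrants need a target)")
        if self.init_deme_size < 1:
            raise ValueError("init_deme_size must be >= 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        for name in ("chi", "rho", "sigma_a", "sigma_b", "sigma_s",
                     "sigma_v", "sigma_l", "beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("tau", "m", "mu", "init_s", "init_v"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if not 0.0 < self.zeta <= 1.0:
            raise ValueError(f"zeta must lie in (0, 1], got {self.zeta}")
        if self.phi < 0 or self.lam < 0:
            raise ValueError("phi and lam must be non-negative")
        if self.init_b <= 0:
            raise ValueError("init_b must be positive")
        if not 0.0 < self.cc_threshold < 1.0:
            raise ValueError("cc_threshold must lie in (0, 1)")

    def with_overrides(self, **kwargs) -> "SimParams":
        """Return a copy with the given fields replaced (keys validated)."""
        known = {f.name for f in fields(self)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown SimParams fields: {sorted(unknown)}")
        return replace(self, **kwargs)


# --------------------------------------------------------------------------
# Demography
# --------------------------------------------------------------------------

def carrying_capacity(A_j, chi, n0):
    """Deme carrying capacity ``k_j = chi * A_j + N_0``.

    Linear in mean deme knowledge ``A_j`` with floor ``n0`` (the founding
    deme size), so an ignorant deme still supports ``n0`` individuals.
    """
    return chi * np.asarray(A_j, dtype=float) + n0


def expected_next_size(N, k, rho):
    """Discrete logistic growth: expected offspring count next generation.

    ``N' = N e^rho / (1 + (N/k)(e^rho - 1))`` with fixed point at ``N = k``.
    """
    N = np.asarray(N, dtype=float)
    if np.any(np.asarray(k) <= 0):
        raise ValueError("carrying capacity k must be positive")
    g = np.exp(rho)
    return N * g / (1.0 + (N / k) * (g - 1.0))


# --------------------------------------------------------------------------
# Payoff-biased choice (fecundity weights and oblique model choice share it)
# --------------------------------------------------------------------------

def knowledge_sigmoid(a, center, gain):
    """Sigmoid payoff transform ``1 / (1 + exp(-gain*(a - center)))``.

    ``gain = 0`` flattens the transform to 0.5 everywhere, which makes any
    downstream normalized weighting uniform.  The exponent is clamped so the
    tails saturate instead of overflowing.
    """
    z = np.clip(np.asarray(gain, dtype=float) * (np.asarray(a, dtype=float) - center),
                -EXP_CLAMP, EXP_CLAMP)
    return 1.0 / (1.0 + np.exp(-z))


def selection_weights(values, center, gain):
    """Normalized sigmoid weights over a non-empty candidate pool."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("selection_weights requires a non-empty pool")
    w = knowledge_sigmoid(values, center, gain)
    return w / np.sum(w)


# --------------------------------------------------------------------------
# Viability selection
# --------------------------------------------------------------------------

def death_probability(b, a, lam, beta):
    """Death probability ``min(1, beta * b^2 * exp(-lam * a / b))``.

    The quadratic term is the cost of brain tissue (``beta*b^2`` reaches 1
    at the maximum sustainable empty brain); the exponential term is the
    survival return on knowledge, gated by ``lam``.
    """
    b = np.asarray(b, dtype=float)
    a = np.asarray(a, dtype=float)
    z = np.clip(-lam * a / b, -EXP_CLAMP, EXP_CLAMP)
    return np.minimum(1.0, beta * b * b * np.exp(z))


# --------------------------------------------------------------------------
# Uniform -> normal kernels (one uniform consumed per value)
# --------------------------------------------------------------------------

def normal_from_uniform(u, mean, sd):
    """Inverse-CDF normal deviate; degenerates to ``mean`` where ``sd == 0``.

    Uniforms are floored at the smallest positive double, which keeps the
    quantile finite (about -38.5 SD) so a zero SD cleanly collapses to the
    mean instead of producing 0 * inf.
    """
    u = np.maximum(np.asarray(u, dtype=float), 5e-324)
    return mean + sd * ndtri(u)


def truncated_normal_from_uniform(u, mean, sd, low=-np.inf, high=np.inf):
    """Inverse-CDF truncated normal on ``[low, high]``.

    Maps the uniform onto the CDF mass inside the interval, so truncation
    never rejects/redraws and still consumes exactly one uniform per value.
    """
    u, mean, sd = np.broadcast_arrays(np.asarray(u, dtype=float),
                                      np.asarray(mean, dtype=float),
                                      np.asarray(sd, dtype=float))
    out = np.minimum(np.maximum(mean, low), high)
    live = sd > 0
    if np.any(live):
        lo_cdf = ndtr((low - mean[live]) / sd[live]) if np.isfinite(low) else 0.0
        hi_cdf = ndtr((high - mean[live]) / sd[live]) if np.isfinite(high) else 1.0
        p = lo_cdf + u[live] * (hi_cdf - lo_cdf)
        x = mean[live] + sd[live] * ndtri(p)
        out[live] = np.minimum(np.maximum(x, low), high)
    return out


# --------------------------------------------------------------------------
# Learning draws
# --------------------------------------------------------------------------

def asocial_knowledge_draw(b, zeta, sigma_a, rng):
    """Asocially invented knowledge: ``N(zeta*b, sigma_a*zeta*b)`` clamped to [0, b].

    The SD scales with the mean ("thought space": more knowledge, more room
    to deviate).  Knowledge can never exceed the learner's own brain.
    """
    b = np.asarray(b, dtype=float)
    u = rng.random(b.shape if b.shape else None)
    mean = zeta * b
    x = normal_from_uniform(np.asarray(u), mean, sigma_a * mean)
    return np.clip(x, 0.0, b)


def social_knowledge_draw(model_a, learner_b, tau, sigma_a, rng):
    """Socially copied knowledge: ``N(tau*a_model, sigma_a*tau*a_model)`` clamped.

    Fidelity ``tau`` discounts the model's knowledge; a knowledge-free model
    transmits exactly nothing.  Clamped to the learner's brain size.
    """
    model_a = np.asarray(model_a, dtype=float)
    learner_b = np.asarray(learner_b, dtype=float)
    u = rng.random(model_a.shape if model_a.shape else None)
    mean = tau * model_a
    x = normal_from_uniform(np.asarray(u), mean, sigma_a * mean)
    return np.clip(x, 0.0, learner_b)


# --------------------------------------------------------------------------
# Genetic transmission
# --------------------------------------------------------------------------

def mutate_offspring(b, s, v, l, p: SimParams, rng) -> Tuple[np.ndarray, ...]:
    """Mutate the four genetic traits of one or more newborns.

    Each trait independently keeps the parental value with probability
    ``1 - mu``; otherwise it is redrawn from a normal centred on the parent:
    ``b`` with SD ``sigma_b * b`` (scale-free mutation), truncated below at
    a small positive floor; ``s`` and ``v`` with absolute SDs truncated to
    [0, 1]; ``l`` with absolute SD, untruncated.

    Draw order (two passes over a ``(n, 4)`` row-major block, trait columns
    ``b, s, v, l``): first the mutation indicators, then the value uniforms.
    Value uniforms are consumed for every trait whether or not it mutates.
    """
    b = np.atleast_1d(np.asarray(b, dtype=float))
    s = np.atleast_1d(np.asarray(s, dtype=float))
    v = np.atleast_1d(np.asarray(v, dtype=float))
    l = np.atleast_1d(np.asarray(l, dtype=float))
    n = b.shape[0]
    hit = rng.random((n, 4)) < p.mu
    u = rng.random((n, 4))
    b2, s2, v2, l2 = b.copy(), s.copy(), v.copy(), l.copy()
    hb, hs, hv, hl = (np.flatnonzero(hit[:, j]) for j in range(4))
    if hb.size:
        b2[hb] = truncated_normal_from_uniform(
            u[hb, 0], b[hb], p.sigma_b * b[hb], low=B_FLOOR)
    if hs.size:
        s2[hs] = truncated_normal_from_uniform(u[hs, 1], s[hs], p.sigma_s, 0.0, 1.0)
    if hv.size:
        v2[hv] = truncated_normal_from_uniform(u[hv, 2], v[hv], p.sigma_v, 0.0, 1.0)
    if hl.size:
        l2[hl] = normal_from_uniform(u[hl, 3], l[hl], p.sigma_l)
    return b2, s2, v2, l2


# --------------------------------------------------------------------------
# Cumulative-culture yardstick
# --------------------------------------------------------------------------

def asocial_invention_probability(mean_b, A, zeta, sigma_a):
    """Upper-tail probability that one asocial draw reaches knowledge ``A``.

    ``P[a >= A]`` under ``N(zeta*mean_b, sigma_a*zeta*mean_b)`` -- the chance
    that an individual with the population's mean brain size invents the
    population's mean knowledge single-handedly.  Vanishingly small values
    mark knowledge that only cumulative transmission can explain.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A < 0):
        raise ValueError("knowledge level A must be non-negative")
    mean = zeta * np.asarray(mean_b, dtype=float)
    sd = sigma_a * mean
    if np.any(mean <= 0):
        raise ValueError("mean_b must be positive")
    return ndtr(-(A - mean) / sd)
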