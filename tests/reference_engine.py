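"""Brute-force per-individual reference implementation of one generation.

Written from the engine's documented lifecycle and draw-order contract with
plain Python loops and no vectorized orchestration: its only numpy use is
the shared RNG, scalar ufuncs (exp/ndtr/ndtri are IEEE primitives, not
logic) and a stable sort.  It must reproduce the engine's state transitions
bit for bit; any divergence indicates an orchestration bug in one of them.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri

B_FLOOR = 1e-3
CLAMP = 700.0


def _sigmoid(x):
    z = min(max(x, -CLAMP), CLAMP)
    return 1.0 / (1.0 + np.exp(-z))


def _normal(u, mean, sd):
    return mean + sd * ndtri(max(u, 5e-324))


def _trunc_normal(u, mean, sd, low, high):
    if sd <= 0:
        return min(max(mean, low), high)
    lo_cdf = ndtr((low - mean) / sd) if np.isfinite(low) else 0.0
    hi_cdf = ndtr((high - mean) / sd) if np.isfinite(high) else 1.0
    x = mean + sd * ndtri(lo_cdf + u * (hi_cdf - lo_cdf))
    return min(max(x, low), high)


def reference_step(adults, p, rng, next_id):
    """Advance one generation.  ``adults`` is a list of dicts with keys
    deme, b, a, s, v, l, id (deme-sorted); returns the surviving newborns
    as the same structure (deme-sorted) plus the advanced id counter."""
    D = p.n_demes

    # per-deme adult statistics, accumulated in array order
    counts = [0] * D
    sums = [0.0] * D
    for ind in adults:
        counts[ind["deme"]] += 1
        sums[ind["deme"]] += ind["a"]
    A = [sums[j] / counts[j] if counts[j] else 0.0 for j in range(D)]
    g = np.exp(p.rho)
    n_trials = []
    for j in range(D):
        k = p.chi * A[j] + p.init_deme_size
        n_exp = counts[j] * g / (1.0 + (counts[j] / k) * (g - 1.0))
        n_trials.append(int(np.rint(n_exp)))

    # fecundity weights and their per-deme normalizers
    w = [_sigmoid(p.phi * (ind["a"] - A[ind["deme"]])) for ind in adults]
    denom = [0.0] * D
    for ind, wi in zip(adults, w):
        denom[ind["deme"]] += wi

    # B1: per-adult offspring counts in array order
    newborns = []
    for ind, wi in zip(adults, w):
        j = ind["deme"]
        n_off = int(rng.binomial(n_trials[j], wi / denom[j]))
        ind["n_off"] = n_off
        for _ in range(n_off):
            newborns.append({"deme": j, "parent": ind, "a": 0.0})
    n_new = len(newborns)

    # B2/B3: mutation indicator block then value block, row-major b,s,v,l
    hits = [[rng.random() < p.mu for _ in range(4)] for _ in range(n_new)]
    uvals = [[rng.random() for _ in range(4)] for _ in range(n_new)]
    for nb, hit, u in zip(newborns, hits, uvals):
        par = nb["parent"]
        nb["b"] = _trunc_normal(u[0], par["b"], p.sigma_b * par["b"],
                                B_FLOOR, np.inf) if hit[0] else par["b"]
        nb["s"] = _trunc_normal(u[1], par["s"], p.sigma_s, 0.0, 1.0) \
            if hit[1] else par["s"]
        nb["v"] = _trunc_normal(u[2], par["v"], p.sigma_v, 0.0, 1.0) \
            if hit[2] else par["v"]
        nb["l"] = _normal(u[3], par["l"], p.sigma_l) if hit[3] else par["l"]
        nb["id"] = next_id
        next_id += 1

    # L1/L2: Stage 2A, vertical copy vs asocial invention
    u_branch = [rng.random() for _ in range(n_new)]
    u_val = [rng.random() for _ in range(n_new)]
    for nb, ub, uv in zip(newborns, u_branch, u_val):
        if ub < nb["s"]:
            mean = p.tau * nb["parent"]["a"]
            nb["parent"]["n_learn"] = nb["parent"].get("n_learn", 0) + 1
        else:
            mean = p.zeta * nb["b"]
        nb["a"] = min(max(_normal(uv, mean, p.sigma_a * mean), 0.0), nb["b"])

    # adult lookup per deme, array order (the oblique model pools)
    pools = [[] for _ in range(D)]
    for ind in adults:
        pools[ind["deme"]].append(ind)

    # L3/L4/L5: Stage 2B, asocial redo / oblique copy / nothing
    u_branch2 = [rng.random() for _ in range(n_new)]
    u_model = [rng.random() for _ in range(n_new)]
    u_val2 = [rng.random() for _ in range(n_new)]
    for nb, ub, um, uv in zip(newborns, u_branch2, u_model, u_val2):
        if ub < 1.0 - nb["s"]:
            mean = p.zeta * nb["b"]
            cand = min(max(_normal(uv, mean, p.sigma_a * mean), 0.0), nb["b"])
        elif ub < (1.0 - nb["s"]) + nb["s"] * nb["v"]:
            pool = pools[nb["deme"]]
            if not pool:
                continue
            cum = []
            run = 0.0
            for ind in pool:
                run += _sigmoid(nb["l"] * (ind["a"] - A[nb["deme"]]))
                cum.append(run)
            thr = um * cum[-1]
            pick = len(pool) - 1
            for t, c in enumerate(cum):
                if c > thr:
                    pick = t
                    break
            model = pool[pick]
            mean = p.tau * model["a"]
            cand = min(max(_normal(uv, mean, p.sigma_a * mean), 0.0), nb["b"])
            model["n_learn"] = model.get("n_learn", 0) + 1
        else:
            continue
        if cand > nb["a"]:
            nb["a"] = cand

    # M1/M2: migration, then stable re-sort by destination deme
    u_mig = [rng.random() for _ in range(n_new)]
    u_dest = [rng.random() for _ in range(n_new)]
    for nb, um, ud in zip(newborns, u_mig, u_dest):
        if um < p.m:
            nb["deme"] = (nb["deme"] + 1 + int(np.floor(ud * (D - 1)))) % D
    newborns = [newborns[i] for i in
                sorted(range(n_new), key=lambda i: (newborns[i]["deme"], i))]

    # S1: viability selection
    u_die = [rng.random() for _ in range(n_new)]
    survivors = []
    for nb, ud in zip(newborns, u_die):
        z = min(max(-p.lam * nb["a"] / nb["b"], -CLAMP), CLAMP)
        d = min(1.0, p.beta * nb["b"] * nb["b"] * np.exp(z))
        if ud >= d:
            survivors.append(nb)
    for nb in survivors:
        nb.pop("parent", None)
    return survivors, next_id


def reference_run(p, seed, generations):
    """Run the reference engine from the standard founding population."""
    rng = np.random.Generator(np.random.PCG64(seed))
    adults = []
    next_id = 0
    for j in range(p.n_demes):
        for _ in range(p.init_deme_size):
            adults.append({"deme": j, "b": p.init_b, "a": 0.0, "s": p.init_s,
                           "v": p.init_v, "l": p.init_l, "id": next_id})
            next_id += 1
    for _ in range(generations):
        adults, next_id = reference_step(adults, p, rng, next_id)
        if not adults:
            break
    return adults
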