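"""Population containers.

The engine keeps the whole metapopulation in flat, deme-sorted numpy arrays
(one entry per living individual) for speed; :class:`Individual` and
:class:`Deme` are convenience views for object-level code and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
import pandas as pd

__all__ = ["Individual", "Deme", "PopulationState", "Trajectory"]


@dataclass
class Individual:
    """One haploid agent: four genetic traits plus learned knowledge."""

    b: float                       # brain size, > 0
    a: float = 0.0                 # adaptive knowledge, 0 <= a <= b
    s: float = 0.0                 # social-learning probability
    v: float = 0.0                 # oblique-learning probability
    l: float = 0.0                 # payoff-bias ability (unbounded)
    id: int = -1
    n_genetic_offspring: int = 0
    n_cultural_learners: int = 0


@dataclass
class Deme:
    """An indexed view of the individuals currently living in one deme."""

    index: int
    members: List[Individual] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def mean_knowledge(self) -> float:
        """Mean knowledge A_j; defined as 0 for an empty deme."""
        if not self.members:
            return 0.0
        total = 0.0
        for ind in self.members:
            total += ind.a
        return total / len(self.members)


class PopulationState:
    """Array-backed metapopulation state at one generation.

    Arrays are parallel (index = individual) and always sorted by deme, so
    per-deme reductions are contiguous segment operations.  A single seeded
    random stream drives the whole run; the engine documents its draw order.
    """

    __slots__ = ("t", "n_demes", "deme", "b", "a", "s", "v", "l",
                 "ids", "n_off", "n_learn", "rng", "_next_id")

    def __init__(self, n_demes: int, deme, b, a, s, v, l, ids, rng,
                 t: int = 0, next_id: int | None = None):
        self.t = t
        self.n_demes = n_demes
        self.deme = np.asarray(deme, dtype=np.int64)
        self.b = np.asarray(b, dtype=float)
        self.a = np.asarray(a, dtype=float)
        self.s = np.asarray(s, dtype=float)
        self.v = np.asarray(v, dtype=float)
        self.l = np.asarray(l, dtype=float)
        self.ids = np.asarray(ids, dtype=np.int64)
        self.n_off = np.zeros(self.deme.shape[0], dtype=np.int64)
        self.n_learn = np.zeros(self.deme.shape[0], dtype=np.int64)
        self.rng = rng
        self._next_id = (int(self.ids.max()) + 1 if self.ids.size else 0) \
            if next_id is None else next_id

    # -- derived quantities -------------------------------------------------

    @property
    def size(self) -> int:
        return int(self.deme.shape[0])

    def deme_sizes(self) -> np.ndarray:
        return np.bincount(self.deme, minlength=self.n_demes)

    def deme_mean_knowledge(self) -> np.ndarray:
        """A_j per deme (0 for empty demes), accumulated in array order."""
        sizes = self.deme_sizes()
        sums = np.bincount(self.deme, weights=self.a, minlength=self.n_demes)
        return np.where(sizes > 0, sums / np.maximum(sizes, 1), 0.0)

    # -- object views -------------------------------------------------------

    def get_deme(self, j: int) -> Deme:
        idx = np.flatnonzero(self.deme == j)
        members = [Individual(b=float(self.b[i]), a=float(self.a[i]),
                              s=float(self.s[i]), v=float(self.v[i]),
                              l=float(self.l[i]), id=int(self.ids[i]),
                              n_genetic_offspring=int(self.n_off[i]),
                              n_cultural_learners=int(self.n_learn[i]))
                   for i in idx]
        return Deme(index=j, members=members)

    def demes(self) -> List[Deme]:
        return [self.get_deme(j) for j in range(self.n_demes)]


class Trajectory:
    """Per-generation aggregate statistics for one run."""

    COLUMNS = ["generation", "n_total", "n_births", "n_deaths",
               "n_empty_demes", "mean_b", "mean_a", "mean_s", "mean_v",
               "mean_l", "mean_sv"]

    def __init__(self) -> None:
        self._rows: list[tuple] = []

    def record(self, generation: int, n_total: int, n_births: int,
               n_deaths: int, n_empty_demes: int, mean_b: float,
               mean_a: float, mean_s: float, mean_v: float, mean_l: float,
               mean_sv: float) -> None:
        self._rows.append((generation, n_total, n_births, n_deaths,
                           n_empty_demes, mean_b, mean_a, mean_s, mean_v,
                           mean_l, mean_sv))

    def __len__(self) -> int:
        return len(self._rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._rows, columns=self.COLUMNS)
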