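"""Parameter sweeps and per-run equilibrium summaries.

A sweep runs the simulator over a grid of the four focal parameters --
reproductive skew ``phi``, transmission fidelity ``tau``, asocial learning
efficacy ``zeta`` and survival return on knowledge ``lam`` -- with a fixed
number of replicates per cell.  Each finished run is condensed into one
"quasi-species" row: time-averaged equilibrium means of the evolving
variables over the final window of generations, plus extinction accounting
and the cumulative-culture classification.  These rows are the unit of all
downstream comparative analyses.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from . import core, lifecycle
from .core import SimParams
from .lifecycle import RunResult

__all__ = [
    "SweepSpec",
    "RUN_COLUMNS",
    "CELL_KEYS",
    "derive_seed",
    "equilibrium_summary",
    "summarize_run",
    "extinction_rate_of",
    "run_single",
    "run_sweep",
    "cell_averages",
    "desk_profile",
    "full_profile",
]

#: Columns of a runs table, fixed so CSVs round-trip predictably.
RUN_COLUMNS = [
    "phi", "tau", "zeta", "lam", "m", "init_s", "replicate", "seed",
    "mean_b", "mean_a", "mean_N", "mean_s", "mean_v", "mean_l", "mean_sv",
    "extinction_rate", "extinct", "invention_prob", "cumulative",
]

#: The parameter-cell identity of a run.
CELL_KEYS = ["phi", "tau", "zeta", "lam", "m", "init_s"]


@dataclass
class SweepSpec:
    """A sweep grid plus everything needed to reproduce it exactly."""

    phi_grid: Sequence[float]
    tau_grid: Sequence[float]
    zeta_grid: Sequence[float]
    lam_grid: Sequence[float]
    m_grid: Sequence[float] = (0.1,)
    init_s_values: Sequence[float] = (0.0,)
    replicates: int = 5
    generations: int = 200_000
    base_seed: int = 0
    window_fraction: float = 0.1
    base_params: SimParams = field(default_factory=SimParams)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for name in ("phi_grid", "tau_grid", "zeta_grid", "lam_grid",
                     "m_grid", "init_s_values"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if not 0.0 < self.window_fraction <= 1.0:
            raise ValueError("window_fraction must lie in (0, 1]")

    def cells(self) -> List[dict]:
        """All parameter cells, in deterministic grid order."""
        return [dict(zip(CELL_KEYS, combo)) for combo in itertools.product(
            self.phi_grid, self.tau_grid, self.zeta_grid, self.lam_grid,
            self.m_grid, self.init_s_values)]

    def n_runs(self) -> int:
        return len(self.cells()) * self.replicates

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["base_params"] = asdict(self.base_params)
        for key in ("phi_grid", "tau_grid", "zeta_grid", "lam_grid",
                    "m_grid", "init_s_values"):
            d[key] = list(d[key])
        return d


def derive_seed(base_seed: int, phi: float, tau: float, zeta: float,
                lam: float, m: float, init_s: float, replicate: int) -> int:
    """Platform-stable per-run seed.

    Parameters are quantized to 1e-9 and fed with the base seed and
    replicate index into a :class:`numpy.random.SeedSequence`, whose mixing
    is documented and identical on every platform.  The result is reduced
    below 2**31 so it can be logged and replayed anywhere.  Seeds depend on
    the cell's parameter values, not on execution order, so a sweep can be
    partitioned or resumed freely.
    """
    q = [int(round(x * 1_000_000_000)) for x in (phi, tau, zeta, lam, m)]
    ss = np.random.SeedSequence(
        entropy=[int(base_seed), *q, int(round(init_s)), int(replicate)])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2 ** 31))


def equilibrium_summary(traj: pd.DataFrame, window_fraction: float = 0.1,
                        n_demes: int = 50) -> dict:
    """Time-average the trajectory statistics over the final window.

    Generations after a global extinction (population 0) are excluded, so an
    extinct run is summarized over the tail of its pre-extinction history.
    ``mean_N`` is the mean deme size, total population over the fixed deme
    count.
    """
    if len(traj) == 0:
        raise ValueError("cannot summarize an empty trajectory")
    alive = traj[traj["n_total"] > 0]
    if len(alive) == 0:
        return {key: float("nan") for key in
                ("mean_b", "mean_a", "mean_N", "mean_s", "mean_v",
                 "mean_l", "mean_sv")}
    n_win = max(1, int(round(window_fraction * len(alive))))
    win = alive.iloc[-n_win:]
    return {
        "mean_b": float(win["mean_b"].mean()),
        "mean_a": float(win["mean_a"].mean()),
        "mean_N": float(win["n_total"].mean()) / n_demes,
        "mean_s": float(win["mean_s"].mean()),
        "mean_v": float(win["mean_v"].mean()),
        "mean_l": float(win["mean_l"].mean()),
        "mean_sv": float(win["mean_sv"].mean()),
    }


def extinction_rate_of(result: RunResult) -> float:
    """Fraction of all individuals ever born that died passing on neither
    genes nor knowledge (NaN if nothing was ever born)."""
    return result.bookkeeping.extinction_rate


def summarize_run(result: RunResult, replicate: int = 0,
                  window_fraction: float = 0.1) -> dict:
    """Condense one finished run into a quasi-species row (see RUN_COLUMNS)."""
    p = result.params
    row = {
        "phi": p.phi, "tau": p.tau, "zeta": p.zeta, "lam": p.lam, "m": p.m,
        "init_s": p.init_s, "replicate": replicate, "seed": result.seed,
    }
    row.update(equilibrium_summary(result.trajectory, window_fraction,
                                   n_demes=p.n_demes))
    row["extinction_rate"] = extinction_rate_of(result)
    row["extinct"] = bool(result.extinct)
    if np.isfinite(row["mean_b"]) and row["mean_b"] > 0:
        prob = float(core.asocial_invention_probability(
            row["mean_b"], row["mean_a"], p.zeta, p.sigma_a))
    else:
        prob = float("nan")
    row["invention_prob"] = prob
    row["cumulative"] = bool(np.isfinite(prob) and prob < p.cc_threshold)
    return row


def run_single(spec: SweepSpec, cell: dict, replicate: int,
               trajectory_dir: Optional[Path] = None) -> dict:
    """Execute one run of a sweep cell and summarize it.

    With ``trajectory_dir`` the per-generation trajectory is also written as
    ``trajectory_<seed>.csv`` (verbose; sweeps are summarized by default)."""
    seed = derive_seed(spec.base_seed, cell["phi"], cell["tau"], cell["zeta"],
                       cell["lam"], cell["m"], cell["init_s"], replicate)
    params = spec.base_params.with_overrides(
        phi=cell["phi"], tau=cell["tau"], zeta=cell["zeta"], lam=cell["lam"],
        m=cell["m"], init_s=cell["init_s"], generations=spec.generations)
    result = lifecycle.run_simulation(params, seed)
    if trajectory_dir is not None:
        trajectory_dir = Path(trajectory_dir)
        trajectory_dir.mkdir(parents=True, exist_ok=True)
        result.trajectory.to_csv(
            trajectory_dir / f"trajectory_{seed}.csv", index=False)
    return summarize_run(result, replicate=replicate,
                         window_fraction=spec.window_fraction)


def cell_averages(runs: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic means of the replicate rows of each parameter cell.

    Boolean flags become fractions (of replicates extinct / cumulative)."""
    df = runs.copy()
    df["extinct"] = df["extinct"].astype(float)
    df["cumulative"] = df["cumulative"].astype(float)
    value_cols = [c for c in RUN_COLUMNS
                  if c not in CELL_KEYS + ["replicate", "seed"]]
    grouped = df.groupby(CELL_KEYS, as_index=False, sort=True)
    out = grouped[value_cols].mean()
    out["n_runs"] = grouped.size()["size"].values
    return out


def run_sweep(spec: SweepSpec, out_dir: Optional[Path] = None,
              resume: bool = False, progress=None,
              save_trajectories: bool = False) -> pd.DataFrame:
    """Execute every (cell, replicate) run of the sweep.

    Returns the runs table.  With ``out_dir`` the table is written
    incrementally to ``runs.csv`` (one row appended per completed run) with
    ``cells.csv`` and ``metadata.json`` finalized at the end; with
    ``resume=True`` runs whose rows are already present are skipped, which
    makes interrupted sweeps restartable and re-runs idempotent.
    """
    done: set = set()
    rows: List[dict] = []
    runs_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        runs_path = out_dir / "runs.csv"
        if resume and runs_path.exists():
            # round_trip parsing keeps resumed rows bit-identical to the originals
            existing = pd.read_csv(runs_path, float_precision="round_trip")
            rows = existing.to_dict("records")
            done = {_run_key(r) for r in rows}
        elif runs_path.exists():
            runs_path.unlink()

    for cell in spec.cells():
        for rep in range(spec.replicates):
            key = _run_key({**cell, "replicate": rep})
            if key in done:
                continue
            traj_dir = (out_dir / "trajectories"
                        if save_trajectories and out_dir else None)
            row = run_single(spec, cell, rep, trajectory_dir=traj_dir)
            rows.append(row)
            if runs_path is not None:
                frame = pd.DataFrame([row], columns=RUN_COLUMNS)
                frame.to_csv(runs_path, mode="a", index=False,
                             header=not runs_path.exists())
        if progress is not None:
            progress(cell, len(rows), spec.n_runs())

    runs = pd.DataFrame(rows, columns=RUN_COLUMNS)
    runs = runs.sort_values(CELL_KEYS + ["replicate"]).reset_index(drop=True)
    if out_dir is not None:
        runs.to_csv(runs_path, index=False)
        cell_averages(runs).to_csv(out_dir / "cells.csv", index=False)
        meta = {"spec": spec.to_jsonable(), "n_runs": int(len(runs)),
                "columns": RUN_COLUMNS}
        (out_dir / "metadata.json").write_text(json.dumps(meta, indent=2))
    return runs


def _run_key(row: dict) -> tuple:
    return tuple(round(float(row[k]), 9) for k in CELL_KEYS) + \
        (int(row["replicate"]),)


# --------------------------------------------------------------------------
# Shipped sweep profiles
# --------------------------------------------------------------------------

def desk_profile(base_seed: int = 0, generations: int = 3000,
                 replicates: int = 1, both_starts: bool = True) -> SweepSpec:
    """Workstation-scale sweep: 3 levels of each focal parameter spanning the
    study ranges (phi in [0,1], tau in [0.75,1], zeta in [0.1,0.9],
    lam in [0,2]), migration fixed at 0.1, both starting conditions.

    Short runs cannot wait out the slow mutational build-up of social
    learning from an all-asocial start, so the social-start runs are what
    populate the social regime at this scale; the asocial-start runs anchor
    the asocial regime.  Pooling both is also how the regime histograms and
    cumulative-culture fractions are presented at full scale.
    """
    return SweepSpec(
        phi_grid=(0.0, 0.1, 1.0),
        tau_grid=(0.75, 0.875, 1.0),
        zeta_grid=(0.1, 0.5, 0.9),
        lam_grid=(0.0, 1.0, 2.0),
        init_s_values=(0.0, 1.0) if both_starts else (0.0,),
        replicates=replicates, generations=generations, base_seed=base_seed)


def full_profile(base_seed: int = 0, both_starts: bool = True) -> SweepSpec:
    """Full-scale sweep: denser grids over the same ranges, 5 replicates,
    200,000 generations.  Cluster-sized; not run by the test suite."""
    return SweepSpec(
        phi_grid=(0.0, 0.01, 0.05, 0.1, 0.25, 0.5, 1.0),
        tau_grid=(0.75, 0.8, 0.85, 0.9, 0.95, 1.0),
        zeta_grid=(0.1, 0.3, 0.5, 0.7, 0.9),
        lam_grid=(0.0, 0.5, 1.0, 1.5, 2.0),
        m_grid=(0.0, 0.1, 0.2),
        init_s_values=(0.0, 1.0) if both_starts else (0.0,),
        replicates=5, generations=200_000, base_seed=base_seed)
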