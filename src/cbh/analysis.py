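"""Comparative analysis of quasi-species tables.

Each simulation run, summarized at quasi-equilibrium, is treated as one
"species" observation.  This module reproduces the comparative workflow:
split species into learning regimes by k-means on mean social learning,
build the log-scale comparative variables used in the cross-species
literature, correlate them (Pearson r with Fisher-z 95% CIs) within each
regime, classify species as cumulative-cultural, and aggregate outcomes
over parameter levels.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from . import core

__all__ = [
    "SPECIES_VARIABLES",
    "regime_cluster",
    "derived_measures",
    "species_table",
    "pearson_with_ci",
    "correlation_table",
    "classify_cumulative",
    "aggregate_by_parameter",
]

#: Comparative variables, in the order the correlation tables use them:
#: log mean brain size, log mean knowledge, log mean group size,
#: log social-learning incidence log(3 + N*s), and the juvenile-period
#: proxy mean(s*v).
SPECIES_VARIABLES = ["log_b", "log_a", "log_N", "log_incidence", "sv"]


def regime_cluster(s_values: Sequence[float], k: int = 2
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """1-D k-means on mean social learning; returns (labels, boundaries).

    Labels are ordered by cluster center (0 = most asocial regime) and the
    boundaries are midpoints between adjacent sorted centers -- the empirical
    regime thresholds.  Initialization is deterministic quantile seeding, so
    repeated calls are identical.
    """
    x = np.asarray(s_values, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if np.unique(x).size < k:
        raise ValueError(f"need at least {k} distinct values for {k} clusters")
    if k == 1:
        return np.zeros(x.size, dtype=int), np.empty(0)
    init = np.quantile(x, (np.arange(k) + 0.5) / k).reshape(-1, 1)
    km = KMeans(n_clusters=k, init=init, n_init=1, random_state=0)
    raw = km.fit_predict(x.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    centers = np.sort(km.cluster_centers_.ravel())
    boundaries = (centers[:-1] + centers[1:]) / 2.0
    return relabel[raw], boundaries


def derived_measures(summary: dict) -> Optional[dict]:
    """Turn one quasi-species row into the comparative variables.

    Social-learning incidence follows the observational-count convention:
    multiply the probability ``s`` by mean group size ``N``, add 3, and take
    the natural log.  Rows with non-positive mean brain size, knowledge or
    group size have no defined logs and are excluded (returns None).
    """
    b, a, N = summary["mean_b"], summary["mean_a"], summary["mean_N"]
    if not (np.isfinite(b) and np.isfinite(a) and np.isfinite(N)):
        return None
    if b <= 0 or a <= 0 or N <= 0:
        return None
    return {
        "log_b": float(np.log(b)),
        "log_a": float(np.log(a)),
        "log_N": float(np.log(N)),
        "log_incidence": float(np.log(3.0 + N * summary["mean_s"])),
        "sv": float(summary["mean_sv"]),
        "s": float(summary["mean_s"]),
        "cumulative": bool(summary.get("cumulative", False)),
    }


def species_table(runs: pd.DataFrame) -> Tuple[pd.DataFrame, int]:
    """Build the species table from a runs table.

    Returns the table (one row per usable run, parameter cell retained) and
    the count of excluded runs (non-positive or undefined means).
    """
    rows: List[dict] = []
    excluded = 0
    for _, run in runs.iterrows():
        meas = derived_measures(run.to_dict())
        if meas is None:
            excluded += 1
            continue
        for key in ("phi", "tau", "zeta", "lam", "m", "init_s", "replicate"):
            if key in run:
                meas[key] = run[key]
        rows.append(meas)
    return pd.DataFrame(rows), excluded


def pearson_with_ci(x, y, alpha: float = 0.05) -> Tuple[float, float, float]:
    """Pearson r with a Fisher-z confidence interval.

    Returns (r, lo, hi); all NaN when either variable has zero variance or
    fewer than 4 paired observations (the CI needs n - 3 > 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 4 or np.std(x) == 0 or np.std(y) == 0:
        return (float("nan"),) * 3
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0 - 1e-12:  # collinear to double precision: degenerate CI
        r = float(np.sign(r))
        return r, r, r
    z = np.arctanh(r)
    half = stats.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    return r, float(np.tanh(z - half)), float(np.tanh(z + half))


def correlation_table(species: pd.DataFrame,
                      labels: Optional[np.ndarray] = None,
                      variables: Sequence[str] = tuple(SPECIES_VARIABLES),
                      ) -> Dict[str, pd.DataFrame]:
    """Pairwise Pearson correlations with 95% CIs, overall and per regime.

    Returns a dict of long-format tables keyed by ``"overall"`` and, when
    regime labels are given, ``"regime_0"``, ``"regime_1"``, ... (ascending
    social-learning order).  Each table has one row per ordered variable
    pair with columns ``var1, var2, r, ci_low, ci_high, n``.
    """
    groups: Dict[str, pd.DataFrame] = {"overall": species}
    if labels is not None:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            groups[f"regime_{lab}"] = species.iloc[np.flatnonzero(labels == lab)]
    out: Dict[str, pd.DataFrame] = {}
    for name, grp in groups.items():
        rows = []
        for i, v1 in enumerate(variables):
            for v2 in variables[i:]:
                r, lo, hi = pearson_with_ci(grp[v1], grp[v2]) \
                    if v1 != v2 else (1.0, 1.0, 1.0)
                if v1 == v2 and (len(grp) < 4 or np.std(grp[v1]) == 0):
                    r = lo = hi = float("nan")
                rows.append({"var1": v1, "var2": v2, "r": r,
                             "ci_low": lo, "ci_high": hi, "n": len(grp)})
        out[name] = pd.DataFrame(rows)
    return out


def correlation_matrix(table: pd.DataFrame,
                       variables: Sequence[str] = tuple(SPECIES_VARIABLES)
                       ) -> pd.DataFrame:
    """Pivot a long-format correlation table into a square matrix of r."""
    mat = pd.DataFrame(np.nan, index=list(variables), columns=list(variables))
    for _, row in table.iterrows():
        mat.loc[row["var1"], row["var2"]] = row["r"]
        mat.loc[row["var2"], row["var1"]] = row["r"]
    return mat


def classify_cumulative(summary: dict, threshold: float = 0.001,
                        zeta: Optional[float] = None,
                        sigma_a: Optional[float] = None) -> bool:
    """Is this species in the cumulative-culture regime?

    True when the probability that a single individual with the species'
    mean brain size asocially invents the species' mean knowledge falls
    below ``threshold`` (default 0.1%) -- knowledge that only accumulation
    over generations can plausibly explain.
    """
    b = summary["mean_b"]
    if not np.isfinite(b) or b <= 0:
        return False
    zeta = summary.get("zeta") if zeta is None else zeta
    sigma_a = summary.get("sigma_a", 0.1) if sigma_a is None else sigma_a
    prob = float(core.asocial_invention_probability(
        b, summary["mean_a"], zeta, sigma_a))
    return prob < threshold


def aggregate_by_parameter(runs: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Per-level outcome means for one swept parameter, split by the
    starting condition (``init_s``).

    Columns: parameter level, init_s, mean brain size, mean social learning,
    mean extinction rate, fraction of runs classified cumulative, run count.
    """
    if parameter not in runs.columns:
        raise ValueError(f"parameter {parameter!r} not present in runs table")
    df = runs.copy()
    df["cumulative"] = df["cumulative"].astype(float)
    grouped = df.groupby([parameter, "init_s"], as_index=False, sort=True)
    out = grouped.agg(mean_b=("mean_b", "mean"), mean_s=("mean_s", "mean"),
                      extinction_rate=("extinction_rate", "mean"),
                      fraction_cumulative=("cumulative", "mean"))
    out["n_runs"] = grouped.size()["size"].values
    return out
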