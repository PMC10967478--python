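"""Generation-stratified association statistics.

Plug counts are tallied per scan into proximal (generation <= 7),
intermediate (8-9) and distal (>= 10) groups and related to a spirometric
outcome two ways:

* **Bootstrap Spearman** — patients are resampled with replacement (all of
  a patient's scans enter together, respecting repeated measures), the
  Spearman coefficient of each group's count vs the outcome is recomputed
  per replicate, and percentile confidence intervals are formed. The
  proximal-vs-distal contrast is judged from the bootstrap distribution of
  ``r_s(proximal) - r_s(distal)``.
* **Exact linear SHAP** — an ordinary least squares fit of the outcome on
  the three counts; for a linear model the Shapley attribution of feature j
  in row i is exactly ``beta_j * (x_ij - mean_j)`` (mean-imputation value
  function), satisfying local accuracy row by row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .tree import GENERATION_GROUPS, PlugMap

__all__ = [
    "BootstrapResult",
    "ShapResult",
    "build_feature_table",
    "spearman_bootstrap",
    "linear_shap",
]

GROUP_COLUMNS = {g: f"n_{g}" for g in GENERATION_GROUPS}


@dataclass
class BootstrapResult:
    """Point estimates, percentile CIs and the proximal-distal contrast."""

    point: dict[str, float]  # group -> r_s on the full table
    ci: dict[str, tuple[float, float]]  # group -> (lo, hi) percentile CI
    diff_point: float  # r_s(proximal) - r_s(distal)
    diff_ci: tuple[float, float]
    diff_p_one_sided: float  # P(diff >= 0) under the bootstrap distribution
    replicates: int
    seed: int
    n_dropped: dict[str, int]  # replicates with undefined r_s, per group

    def covers_zero(self, group: str) -> bool:
        lo, hi = self.ci[group]
        return lo <= 0.0 <= hi


@dataclass
class ShapResult:
    """Exact per-row linear-model Shapley attributions."""

    features: list[str]
    attributions: pd.DataFrame  # one column per feature, one row per scan
    mean_abs: dict[str, float]
    coefficients: dict[str, float]
    intercept: float


def build_feature_table(
    plug_maps: Mapping[str, PlugMap],
    outcomes: pd.DataFrame,
    outcome_columns: Sequence[str] = ("outcome",),
) -> pd.DataFrame:
    """Join per-scan generation-group plug counts with outcome values.

    ``outcomes`` must carry ``scan_id`` and ``patient_id`` columns plus the
    outcome column(s). Scans with a missing outcome are dropped with a
    warning; scans without a plug map get zero counts only if present in
    ``plug_maps`` (otherwise they are unknown and dropped).
    """
    for col in ("scan_id", "patient_id"):
        if col not in outcomes.columns:
            raise ValueError(f"outcomes table lacks required column {col!r}")
    rows = []
    for scan_id, plug_map in plug_maps.items():
        counts = plug_map.group_counts
        rows.append({"scan_id": scan_id, **{GROUP_COLUMNS[g]: counts[g] for g in GENERATION_GROUPS}})
    counts_df = pd.DataFrame(rows, columns=["scan_id", *GROUP_COLUMNS.values()])
    table = counts_df.merge(outcomes, on="scan_id", how="inner")
    n_missing_map = len(outcomes) - len(table)
    if n_missing_map > 0:
        warnings.warn(f"{n_missing_map} outcome rows had no plug map and were dropped")
    before = len(table)
    table = table.dropna(subset=list(outcome_columns)).reset_index(drop=True)
    if len(table) < before:
        warnings.warn(f"{before - len(table)} scans dropped for missing outcomes")
    return table


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    r = sps.spearmanr(x, y).statistic
    return float(r)


def spearman_bootstrap(
    table: pd.DataFrame,
    outcome: str,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> BootstrapResult:
    """Patient-level bootstrap of group-wise Spearman correlations.

    Each replicate resamples patients with replacement (keeping all scans
    of a drawn patient, with multiplicity) and recomputes ``r_s`` of each
    group count against the outcome. Percentile CIs use the (alpha/2,
    1-alpha/2) quantiles. Replicates where a resampled column is constant
    have an undefined coefficient and are dropped from that group's
    distribution (counted in ``n_dropped``). A constant column in the full
    table raises.
    """
    if B < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    patients = table["patient_id"].unique()
    if len(patients) < 10:
        raise ValueError("need at least 10 patients to bootstrap")
    y_all = table[outcome].to_numpy(dtype=float)
    cols = {g: table[GROUP_COLUMNS[g]].to_numpy(dtype=float) for g in GENERATION_GROUPS}
    for g, x in cols.items():
        if np.all(x == x[0]) or np.all(y_all == y_all[0]):
            raise ValueError(f"constant column makes r_s undefined for group {g!r}")

    point = {g: _spearman(cols[g], y_all) for g in GENERATION_GROUPS}
    diff_point = point["proximal"] - point["distal"]

    rows_of = {p: np.flatnonzero(table["patient_id"].to_numpy() == p) for p in patients}
    rng = np.random.default_rng(seed)
    reps: dict[str, list[float]] = {g: [] for g in GENERATION_GROUPS}
    diff_reps: list[float] = []
    n_dropped = {g: 0 for g in GENERATION_GROUPS}
    for _ in range(B):
        drawn = rng.choice(patients, size=len(patients), replace=True)
        idx = np.concatenate([rows_of[p] for p in drawn])
        y = y_all[idx]
        rep_vals = {}
        for g in GENERATION_GROUPS:
            x = cols[g][idx]
            if np.all(x == x[0]) or np.all(y == y[0]):
                n_dropped[g] += 1
                rep_vals[g] = np.nan
            else:
                rep_vals[g] = _spearman(x, y)
                reps[g].append(rep_vals[g])
        if not (np.isnan(rep_vals["proximal"]) or np.isnan(rep_vals["distal"])):
            diff_reps.append(rep_vals["proximal"] - rep_vals["distal"])

    qs = (100 * alpha / 2, 100 * (1 - alpha / 2))
    ci = {}
    for g in GENERATION_GROUPS:
        vals = np.asarray(reps[g])
        if vals.size == 0:
            raise ValueError(f"all replicates undefined for group {g!r}")
        lo, hi = np.percentile(vals, qs)
        ci[g] = (float(lo), float(hi))
    diff_arr = np.asarray(diff_reps)
    diff_lo, diff_hi = np.percentile(diff_arr, qs)
    p_one_sided = float(np.mean(diff_arr >= 0.0))
    return BootstrapResult(
        point=point,
        ci=ci,
        diff_point=float(diff_point),
        diff_ci=(float(diff_lo), float(diff_hi)),
        diff_p_one_sided=p_one_sided,
        replicates=B,
        seed=seed,
        n_dropped=n_dropped,
    )


def linear_shap(
    table: pd.DataFrame,
    outcome: str,
    features: Sequence[str] | None = None,
) -> ShapResult:
    """Exact Shapley attributions for an OLS fit of ``outcome`` on counts.

    With a linear model and the table itself as the background
    distribution, the Shapley value of feature j in row i collapses to
    ``beta_j * (x_ij - mean_j)``; attributions per row sum to the
    prediction minus the mean prediction (local accuracy). Rank-deficient
    designs raise.
    """
    features = list(features) if features is not None else list(GROUP_COLUMNS.values())
    X = table[features].to_numpy(dtype=float)
    y = table[outcome].to_numpy(dtype=float)
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    fit = sm.OLS(y, design).fit()
    intercept = float(fit.params[0])
    beta = np.asarray(fit.params[1:], dtype=float)
    centered = X - X.mean(axis=0)
    phi = centered * beta
    attributions = pd.DataFrame(phi, columns=features, index=table.index)
    mean_abs = {f: float(np.abs(phi[:, j]).mean()) for j, f in enumerate(features)}
    coefficients = {f: float(beta[j]) for j, f in enumerate(features)}
    return ShapResult(
        features=features,
        attributions=attributions,
        mean_abs=mean_abs,
        coefficients=coefficients,
        intercept=intercept,
    )
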