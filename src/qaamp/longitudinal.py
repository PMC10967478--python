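"""Length phenotypes and longitudinal plug tracking.

Plug lengths in asthma are multimodal; a Gaussian mixture fit with AIC
model selection identifies the dominant populations, and a fixed 12 mm
threshold separates short "stubby" (<= 12 mm) from long "stringy" (> 12 mm)
phenotypes. Across paired baseline / year-3 scans, plugs occupying the same
airway branch are "persistent" (with length/volume deltas), baseline plugs
that disappear are "transient", and unmatched follow-up plugs are "new".
State transitions over {absent, stubby, stringy} summarize the dynamics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp

from .tree import PlugMap

__all__ = [
    "MixtureFit",
    "PhenotypeConfig",
    "TransitionMatrix",
    "fit_length_mixture",
    "classify_phenotype",
    "classify_lengths",
    "match_plugs",
    "transition_matrix",
    "delta_summary",
]

STATES = ("absent", "stubby", "stringy")


@dataclass
class PhenotypeConfig:
    """Length threshold separating stubby from stringy plugs."""

    stubby_threshold: float = 12.0  # mm; <= threshold is stubby

    def validate(self) -> None:
        if self.stubby_threshold <= 0:
            raise ValueError("stubby_threshold must be positive")


@dataclass
class MixtureFit:
    """One fitted Gaussian mixture over plug lengths."""

    k: int
    weights: np.ndarray
    means: np.ndarray  # mm
    sds: np.ndarray  # mm
    log_likelihood: float
    aic: float
    selected: bool = False

    @property
    def n_parameters(self) -> int:
        return 3 * self.k - 1  # k means + k variances + (k-1) free weights

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "weights": self.weights.tolist(),
            "means_mm": self.means.tolist(),
            "sds_mm": self.sds.tolist(),
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "selected": self.selected,
        }


def _em_gaussian_1d(
    x: np.ndarray,
    means: np.ndarray,  # (R, k): R parallel restarts
    sds: np.ndarray,
    weights: np.ndarray,
    tol: float,
    max_iter: int,
    variance_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Batched EM for a 1-D Gaussian mixture over parallel restarts.

    All restarts iterate together (vectorized over the restart axis) until
    each has converged in log-likelihood or ``max_iter`` is reached; the
    restart with the best log-likelihood is returned.
    """
    xr = x[None, :, None]  # (1, n, 1)
    prev_ll = np.full(len(means), -np.inf)
    ll = prev_ll.copy()
    active = np.ones(len(means), dtype=bool)
    for _ in range(max_iter):
        log_pdf = (
            np.log(weights)[:, None, :]
            - 0.5 * np.log(2.0 * np.pi * sds[:, None, :] ** 2)
            - 0.5 * ((xr - means[:, None, :]) / sds[:, None, :]) ** 2
        )  # (R, n, k)
        log_norm = logsumexp(log_pdf, axis=2)
        ll = log_norm.sum(axis=1)
        resp = np.exp(log_pdf - log_norm[:, :, None])
        nk = resp.sum(axis=1)  # (R, k)
        new_w = nk / x.size
        new_m = (resp * xr).sum(axis=1) / nk
        var = (resp * (xr - new_m[:, None, :]) ** 2).sum(axis=1) / nk
        new_s = np.sqrt(np.maximum(var, variance_floor))
        weights = np.where(active[:, None], new_w, weights)
        means = np.where(active[:, None], new_m, means)
        sds = np.where(active[:, None], new_s, sds)
        active &= np.abs(ll - prev_ll) >= tol * x.size  # tol is per sample
        prev_ll = ll
        if not active.any():
            break
    best = int(np.argmax(ll))
    return means[best], sds[best], weights[best], float(ll[best])


def _kmeans_1d(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Lloyd's k-means on scalars with a k-means++ style seeded start."""
    centers = np.empty(k)
    centers[0] = x[rng.integers(len(x))]
    for j in range(1, k):
        d2 = np.min((x[:, None] - centers[None, :j]) ** 2, axis=1)
        total = d2.sum()
        probs = d2 / total if total > 0 else np.full(len(x), 1.0 / len(x))
        centers[j] = x[rng.choice(len(x), p=probs)]
    labels = np.zeros(len(x), dtype=int)
    for _ in range(100):
        new_labels = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        for j in range(k):
            sel = x[new_labels == j]
            if len(sel):
                centers[j] = sel.mean()
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    # guard: every cluster keeps at least one point
    for j in range(k):
        if not np.any(labels == j):
            labels[np.argmin(np.abs(x - centers[j]))] = j
    return labels


def fit_length_mixture(
    lengths: Sequence[float],
    k_range: Sequence[int] = (1, 2, 3, 4, 5),
    seed: int = 0,
    n_init: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    variance_floor: float = 1e-4,  # mm^2
) -> tuple[list[MixtureFit], list[str]]:
    """EM mixture fits over ``k_range`` with the minimum-AIC fit selected.

    Each k runs EM from a quantile-spread initialization (component means at
    evenly spaced quantiles, equal weights, pooled spread) plus
    ``n_init - 1`` seeded restarts with jittered quantile positions; the
    best log-likelihood wins. Values of k whose parameter count reaches the
    sample size are skipped, with a notice. Returns (fits ordered by k,
    notices); exactly one fit has ``selected=True``.
    """
    x = np.asarray(lengths, dtype=float).reshape(-1)
    if len(x) < 10:
        raise ValueError("need at least 10 lengths to fit the mixture")
    if not set(k_range) <= set(range(1, 6)):
        raise ValueError("k_range must be a subset of 1..5")
    rng = np.random.default_rng(seed)
    sd0 = max(float(x.std()), np.sqrt(variance_floor))
    fits: list[MixtureFit] = []
    notices: list[str] = []
    for k in sorted(k_range):
        n_params = 3 * k - 1
        if len(x) <= n_params:
            notices.append(f"k={k} skipped: {len(x)} lengths <= {n_params} parameters")
            continue
        # k-means-initialized EM (the standard mixture recipe): each restart
        # hard-partitions the sample with a seeded k-means, then starts EM
        # from the partition's means / spreads / fractions.
        means0 = np.empty((n_init, k))
        sds0 = np.empty((n_init, k))
        weights0 = np.empty((n_init, k))
        for r in range(n_init):
            labels = _kmeans_1d(x, k, rng)
            for j in range(k):
                block = x[labels == j]
                means0[r, j] = block.mean()
                sds0[r, j] = max(float(block.std()), 0.05 * sd0, np.sqrt(variance_floor))
                weights0[r, j] = len(block) / len(x)
        means, sds, weights, ll = _em_gaussian_1d(
            x, means0, sds0, weights0, tol, max_iter, variance_floor
        )
        order = np.argsort(means)
        fits.append(
            MixtureFit(
                k=k,
                weights=weights[order],
                means=means[order],
                sds=sds[order],
                log_likelihood=ll,
                aic=float(2.0 * n_params - 2.0 * ll),
            )
        )
    if not fits:
        raise ValueError("no k in k_range admitted a fit")
    best_i = min(range(len(fits)), key=lambda i: fits[i].aic)
    fits[best_i].selected = True
    return fits, notices


def classify_phenotype(length_mm: float, config: PhenotypeConfig | None = None) -> str:
    """"stubby" when length <= threshold (12 mm default), else "stringy"."""
    config = config or PhenotypeConfig()
    config.validate()
    return "stubby" if length_mm <= config.stubby_threshold else "stringy"


def classify_lengths(
    lengths: Sequence[float], config: PhenotypeConfig | None = None
) -> np.ndarray:
    config = config or PhenotypeConfig()
    config.validate()
    arr = np.asarray(lengths, dtype=float)
    return np.where(arr <= config.stubby_threshold, "stubby", "stringy")


# --------------------------------------------------------------------------- matching
def _joined(plug_map: PlugMap, morph: pd.DataFrame) -> pd.DataFrame:
    df = plug_map.assignments.merge(morph, on="plug_id", how="inner")
    missing = set(plug_map.assignments["plug_id"]) - set(df["plug_id"])
    if missing:
        raise ValueError(f"morphometry rows missing for plugs {sorted(missing)}")
    return df


def match_plugs(
    baseline_map: PlugMap,
    baseline_morph: pd.DataFrame,
    followup_map: PlugMap,
    followup_morph: pd.DataFrame,
    config: PhenotypeConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Match plugs across timepoints by shared airway branch.

    A baseline plug is *persistent* iff a follow-up plug is assigned to the
    same branch; when several share a branch, pairs are resolved one-to-one
    by nearest centroid. Unmatched baseline plugs are *transient*; follow-up
    plugs on branches without a baseline plug are *new*. Returns
    ``(matches, new_plugs)``: matches carry per-plug labels, deltas (for
    persistent plugs) and phenotype states at both timepoints.
    """
    config = config or PhenotypeConfig()
    base = _joined(baseline_map, baseline_morph)
    follow = _joined(followup_map, followup_morph)
    if len(base) and len(follow):
        shared = set(base["branch_id"]) | set(follow["branch_id"])
        if not shared:
            raise ValueError("timepoints share no branch ids; trees are disjoint")

    cent = ["centroid_x", "centroid_y", "centroid_z"]
    follow_used: set[int] = set()
    pair_of: dict[int, int] = {}  # baseline plug -> followup plug
    for branch_id, b_grp in base.groupby("branch_id"):
        f_grp = follow[follow["branch_id"] == branch_id]
        if f_grp.empty:
            continue
        pairs = []
        for _, brow in b_grp.iterrows():
            for _, frow in f_grp.iterrows():
                d = np.linalg.norm(brow[cent].to_numpy(float) - frow[cent].to_numpy(float))
                pairs.append((d, int(brow["plug_id"]), int(frow["plug_id"])))
        pairs.sort()
        taken_b: set[int] = set()
        for _, bp, fp in pairs:
            if bp in taken_b or fp in follow_used:
                continue
            taken_b.add(bp)
            follow_used.add(fp)
            pair_of[bp] = fp

    follow_by_id = follow.set_index("plug_id")
    rows = []
    for _, brow in base.iterrows():
        bp = int(brow["plug_id"])
        persistent = bp in pair_of
        row = {
            "baseline_plug_id": bp,
            "followup_plug_id": pair_of.get(bp),
            "branch_id": int(brow["branch_id"]),
            "label": "persistent" if persistent else "transient",
            "baseline_length_mm": float(brow["length_mm"]),
            "baseline_volume_mm3": float(brow["volume_mm3"]),
            "baseline_state": classify_phenotype(float(brow["length_mm"]), config),
            "followup_state": "absent",
            "delta_length_mm": np.nan,
            "delta_volume_mm3": np.nan,
        }
        if persistent:
            frow = follow_by_id.loc[pair_of[bp]]
            row["followup_state"] = classify_phenotype(float(frow["length_mm"]), config)
            row["delta_length_mm"] = float(frow["length_mm"]) - row["baseline_length_mm"]
            row["delta_volume_mm3"] = float(frow["volume_mm3"]) - row["baseline_volume_mm3"]
        rows.append(row)
    match_cols = [
        "baseline_plug_id", "followup_plug_id", "branch_id", "label",
        "baseline_length_mm", "baseline_volume_mm3", "baseline_state", "followup_state",
        "delta_length_mm", "delta_volume_mm3",
    ]
    matches = pd.DataFrame(rows, columns=match_cols)

    new_rows = []
    for _, frow in follow.iterrows():
        fp = int(frow["plug_id"])
        if fp in follow_used:
            continue
        new_rows.append(
            {
                "followup_plug_id": fp,
                "branch_id": int(frow["branch_id"]),
                "length_mm": float(frow["length_mm"]),
                "volume_mm3": float(frow["volume_mm3"]),
                "state": classify_phenotype(float(frow["length_mm"]), config),
            }
        )
    new_cols = ["followup_plug_id", "branch_id", "length_mm", "volume_mm3", "state"]
    return matches, pd.DataFrame(new_rows, columns=new_cols)


@dataclass
class TransitionMatrix:
    """Counts and row-stochastic probabilities over {absent, stubby, stringy}."""

    states: tuple[str, ...]
    counts: np.ndarray  # (3, 3) int, rows = baseline state
    probabilities: np.ndarray  # rows sum to 1 where the row count > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probabilities, index=self.states, columns=self.states)


def transition_matrix(matches: pd.DataFrame, new_plugs: pd.DataFrame) -> TransitionMatrix:
    """Baseline -> follow-up state transitions, including births and deaths.

    Transient plugs transition to ``absent``; new plugs transition from
    ``absent``. The absent -> absent cell is structurally zero (unplugged
    branches are not enumerated).
    """
    idx = {s: i for i, s in enumerate(STATES)}
    counts = np.zeros((3, 3), dtype=int)
    for _, row in matches.iterrows():
        counts[idx[row["baseline_state"]], idx[row["followup_state"]]] += 1
    for _, row in new_plugs.iterrows():
        counts[idx["absent"], idx[row["state"]]] += 1
    probs = np.zeros((3, 3))
    row_sums = counts.sum(axis=1)
    nonzero = row_sums > 0
    probs[nonzero] = counts[nonzero] / row_sums[nonzero, None]
    return TransitionMatrix(states=STATES, counts=counts, probabilities=probs)


def delta_summary(matches: pd.DataFrame) -> dict:
    """Distribution of size changes among persistent plugs.

    Reports mean/sd of the length and volume deltas plus a paired
    rank-based location test against zero (Wilcoxon signed-rank; p = 1 when
    every delta is exactly zero, where the statistic is undefined).
    """
    persistent = matches[matches["label"] == "persistent"]
    out: dict = {"n_persistent": int(len(persistent))}
    for quantity, col in (("length_mm", "delta_length_mm"), ("volume_mm3", "delta_volume_mm3")):
        deltas = persistent[col].to_numpy(dtype=float)
        entry = {
            "deltas": deltas,
            "mean": float(deltas.mean()) if len(deltas) else np.nan,
            "sd": float(deltas.std(ddof=1)) if len(deltas) > 1 else np.nan,
        }
        if len(deltas) and np.any(deltas != 0):
            stat, p = sps.wilcoxon(deltas)
            entry["wilcoxon_statistic"] = float(stat)
            entry["wilcoxon_p"] = float(p)
        else:
            entry["wilcoxon_statistic"] = np.nan
            entry["wilcoxon_p"] = 1.0
        out[f"delta_{quantity}"] = entry
    return out


def mixture_fits_to_json(fits: list[MixtureFit], path: str | Path | None = None) -> str:
    text = json.dumps([f.to_dict() for f in fits], indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text
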