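"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they validate: resistance by
recursive series-parallel reduction, OLVP by an explicit nearest-neighbor
loop, and Shapley values by enumeration over all feature subsets.
"""

import itertools
import math

import numpy as np

from qaamp.functional import segment_resistance


def series_parallel_resistance(tree, plugged, config=None) -> float:
    """Effective resistance by recursive series-parallel reduction.

    Plugged terminal leaves are open circuits; children combine in
    parallel, the parent branch adds in series.
    """
    plugged = set(plugged)

    def sub(branch_id: int) -> float:
        branch = tree.branches[branch_id]
        own = segment_resistance(branch.length, branch.radius, config)
        kids = tree.children(branch_id)
        if not kids:
            return math.inf if branch_id in plugged else own
        inv = 0.0
        for k in kids:
            r = sub(k)
            if r != math.inf:
                inv += 1.0 / r
        return math.inf if inv == 0.0 else own + 1.0 / inv

    return sub(tree.root_id)


def brute_force_olvp(volume, tree, plugged_branches):
    """Per-lobe obstructed fractions by explicit nearest-terminal loops."""
    term_ids, term_pts = tree.termination_points()
    term_lobes = [tree.branches[int(i)].lobe for i in term_ids]
    out = {}
    for code, lobe in sorted(volume.lobe_legend.items()):
        idx = np.argwhere(volume.lobe_labels == code)
        if len(idx) == 0:
            continue
        lobe_mask = [i for i, lb in enumerate(term_lobes) if lb == lobe]
        centers = volume.index_to_mm(idx)
        n_obstructed = 0
        for c in centers:
            best, best_d = None, math.inf
            for i in lobe_mask:
                d = float(np.linalg.norm(term_pts[i] - c))
                if d < best_d:
                    best, best_d = i, d
            if int(term_ids[best]) in plugged_branches:
                n_obstructed += 1
        out[lobe] = (n_obstructed, len(idx))
    return out


def exact_linear_shapley(beta, x_row, x_mean):
    """Shapley values by enumeration over all 2^p subsets.

    Value function: model prediction with features outside S imputed at
    their mean — for a linear model, v(S) = b0 + sum_{j in S} beta_j x_j +
    sum_{j not in S} beta_j mean_j (intercept cancels in differences).
    """
    p = len(beta)
    phi = np.zeros(p)
    others = list(range(p))
    fact = math.factorial
    for j in range(p):
        rest = [k for k in others if k != j]
        for r in range(len(rest) + 1):
            for S in itertools.combinations(rest, r):
                w = fact(len(S)) * fact(p - len(S) - 1) / fact(p)
                with_j = sum(beta[k] * x_row[k] for k in (*S, j)) + sum(
                    beta[k] * x_mean[k] for k in others if k not in (*S, j)
                )
                without_j = sum(beta[k] * x_row[k] for k in S) + sum(
                    beta[k] * x_mean[k] for k in others if k not in S
                )
                phi[j] += w * (with_j - without_j)
    return phi


def rank_then_pearson(x, y):
    """Spearman by explicit average-rank transform + Pearson formula."""

    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r[order[i: j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))
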