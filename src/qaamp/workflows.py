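"""End-to-end phantom study: every pipeline stage chained on synthetic data.

This driver exercises the full workflow exactly as it would run on real
scans — two independent simulated readers, third-reader adjudication,
fuzzy-clustering segmentation, morphometry, airway mapping, resistance and
obstruction scoring, a paired follow-up timepoint with plug tracking, and
the per-scan feature table — on one phantom with plugs spread across
airway generations 2-6. Everything is a pure function of the seed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from . import annotations as ann
from .functional import olvp, resistance_score
from .longitudinal import delta_summary, match_plugs, transition_matrix
from .morphometry import morphometry_table
from .segmentation import GKConfig, extract_roi_volume, segment_plug
from .stats import build_feature_table
from .synthetic import (
    FollowupConfig,
    Phantom,
    PhantomSpec,
    ReaderModel,
    TreeConfig,
    generate_airway_tree,
    rasterize_phantom,
    simulate_annotations,
    simulate_followup,
)
from .tree import AirwayTree, PlugMap, map_plugs

__all__ = ["end_to_end_phantom_study", "segment_scan", "pick_disjoint_branches"]


def pick_disjoint_branches(tree: AirwayTree, generations: Sequence[int]) -> list[int]:
    """Lowest-id branch per requested generation, no ancestor/descendant pairs."""
    chosen: list[int] = []
    chosen_subtrees: set[int] = set()

    def ancestors(bid: int) -> set[int]:
        out = set()
        b = tree.branches[bid]
        while b.parent_id is not None:
            out.add(b.parent_id)
            b = tree.branches[b.parent_id]
        return out

    for gen in sorted(generations, reverse=True):
        for bid in sorted(tree.branches):
            b = tree.branches[bid]
            if b.generation != gen or bid in chosen_subtrees:
                continue
            if ancestors(bid) & set(chosen):
                continue
            chosen.append(bid)
            chosen_subtrees.update(tree.subtree_ids(bid))
            chosen_subtrees.update(ancestors(bid))
            break
        else:
            raise ValueError(f"no free branch available at generation {gen}")
    return chosen


def segment_scan(
    phantom: Phantom,
    readers: Sequence[ReaderModel],
    scan_id: str,
    gk: GKConfig | None = None,
) -> tuple[pd.DataFrame, PlugMap, ann.BurdenScores, ann.DiscordanceReport]:
    """Run one scan through readers, adjudication, segmentation and mapping.

    Discordant (single-reader) plugs are accepted by the simulated third
    reader — the phantom readers produce no false positives, so every
    discordant mark is a real plug.
    """
    set_a = simulate_annotations(phantom.plug_masks, readers[0], scan_id, "reader1")
    set_b = simulate_annotations(phantom.plug_masks, readers[1], scan_id, "reader2")
    # accept every plug either reader found alone (no false positives here)
    all_decisions = [
        ann.AdjudicationDecision(reader_id=rid, plug_label=label, verdict="accept")
        for rid, label in set_a.plug_labels + set_b.plug_labels
    ]
    consensus, report = ann.adjudicate(set_a, set_b, all_decisions)
    scores = ann.burden_scores(consensus)
    masks = {}
    for (_, label), plug_anns in sorted(consensus.plugs().items()):
        subset = extract_roi_volume(phantom.volume, plug_anns)
        masks[label] = segment_plug(subset, gk)
    morph = morphometry_table(masks, phantom.volume)
    plug_map = map_plugs(phantom.observed_tree, morph, scan_id=scan_id)
    return morph, plug_map, scores, report


def _rs_per_plug_by_generation(tree: AirwayTree, plug_map: PlugMap) -> dict[int, float]:
    out: dict[int, float] = {}
    df = plug_map.assignments
    for gen, sub in df.groupby("generation"):
        partial = PlugMap(scan_id=plug_map.scan_id, assignments=sub)
        result = resistance_score(tree, partial)
        out[int(gen)] = (
            math.inf if result.infinite_flag else result.resistance_score / len(sub)
        )
    return out


def end_to_end_phantom_study(seed: int = 0) -> dict:
    """Full two-timepoint study on a 10-plug phantom (generations 2-6).

    Returns the headline quantities of every stage; repeated calls with the
    same seed return identical results.
    """
    tree_cfg = TreeConfig(
        seed=seed, max_generation=6, root_length=11.0, root_radius=3.5,
        length_ratio=0.78, radius_ratio=2.0 ** (-1.0 / 3.0), branch_angle=35.0,
        jitter_sd=0.05, min_radius=0.5, lobe_count=4,
    )
    tree = generate_airway_tree(tree_cfg)
    target_generations = [2, 3, 3, 4, 4, 5, 5, 6, 6, 6]
    branches = pick_disjoint_branches(tree, target_generations)
    # plugs occupy most of their branch so each centroid sits nearest its
    # own branch end (full occlusion of short distal branches is realistic)
    placements = [
        (bid, 0.1, max(min(4.5, 0.8 * tree.branches[bid].length), 1.2))
        for bid in branches
    ]
    spec = PhantomSpec(
        grid_shape=(112, 112, 112), spacing=(0.5, 0.5, 0.5), plug_placements=placements
    )
    baseline = rasterize_phantom(tree, spec, seed=seed + 1)

    reader = ReaderModel(
        miss_probability=0.05, slice_skip_probability=0.05, ellipse_dilation_sd=0.5
    )
    readers = [
        dataclasses.replace(reader, seed=seed + 101),
        dataclasses.replace(reader, seed=seed + 202),
    ]
    b_morph, b_map, b_scores, b_report = segment_scan(baseline, readers, "baseline")

    rs = resistance_score(baseline.observed_tree, b_map)
    per_gen = _rs_per_plug_by_generation(baseline.observed_tree, b_map)
    obstruction = olvp(baseline.volume, baseline.observed_tree, b_map)

    followup_cfg = FollowupConfig(
        persistence_probability=0.47, length_jitter_sd=1.0, new_plug_rate=3.0,
        seed=seed + 7,
    )
    f_truth, truth_labels = simulate_followup(baseline.truth, tree, followup_cfg)
    f_placements = [
        (int(r.branch_id), float(r.start_frac), float(r.length_mm))
        for r in f_truth.itertuples()
    ]
    followup = rasterize_phantom(
        tree, dataclasses.replace(spec, plug_placements=f_placements), seed=seed + 2
    )
    f_readers = [
        dataclasses.replace(reader, seed=seed + 303),
        dataclasses.replace(reader, seed=seed + 404),
    ]
    f_morph, f_map, f_scores, _ = segment_scan(followup, f_readers, "year3")

    matches, new_plugs = match_plugs(b_map, b_morph, f_map, f_morph)
    transitions = transition_matrix(matches, new_plugs)
    deltas = delta_summary(matches)

    maps = {"baseline": b_map, "year3": f_map}
    outcomes = pd.DataFrame(
        {
            "scan_id": ["baseline", "year3"],
            "patient_id": ["p0", "p0"],
            "fev1": [85.0 - 2.0 * b_scores.plug_score, 85.0 - 2.0 * f_scores.plug_score],
        }
    )
    features = build_feature_table(maps, outcomes, outcome_columns=("fev1",))

    min_gen, max_gen = min(per_gen), max(per_gen)
    return {
        "plug_score": b_scores.plug_score,
        "slice_score": b_scores.slice_score,
        "discordant": b_report.discordant,
        "rs_percent": rs.resistance_score,
        "rs_per_plug_by_generation": per_gen,
        "rs_per_plug_most_proximal": per_gen[min_gen],
        "rs_per_plug_most_distal": per_gen[max_gen],
        "olvp_percent": obstruction.whole_lung_olvp,
        "followup_plug_score": f_scores.plug_score,
        "n_persistent": int((matches["label"] == "persistent").sum()),
        "n_transient": int((matches["label"] == "transient").sum()),
        "n_new": int(len(new_plugs)),
        "mean_delta_length_mm": deltas["delta_length_mm"]["mean"],
        "transition_counts": transitions.counts.tolist(),
        "feature_rows": len(features),
        "feature_table": features,
        "truth_labels": truth_labels,
        "matches": matches,
    }
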