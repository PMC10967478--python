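"""Length-mixture selection, phenotyping, tracking, transitions, deltas."""

import numpy as np
import pandas as pd
import pytest

from qaamp import (
    FollowupConfig,
    PhantomSpec,
    PlugMap,
    classify_lengths,
    classify_phenotype,
    delta_summary,
    fit_length_mixture,
    map_plugs,
    match_plugs,
    morphometry_table,
    rasterize_phantom,
    simulate_followup,
    transition_matrix,
)
from qaamp.tree import generation_group

MAP_COLUMNS = ["plug_id", "branch_id", "generation", "lobe", "distance_mm", "group"]


def make_map(rows):
    df = pd.DataFrame(
        [
            {
                "plug_id": pid, "branch_id": bid, "generation": 4, "lobe": "RUL",
                "distance_mm": 0.0, "group": generation_group(4),
            }
            for pid, bid in rows
        ],
        columns=MAP_COLUMNS,
    )
    return PlugMap(scan_id="s", assignments=df)


def make_morph(rows):
    return pd.DataFrame(
        [
            {
                "plug_id": pid, "length_mm": ln, "volume_mm3": vol,
                "centroid_x": cx, "centroid_y": 0.0, "centroid_z": 0.0,
            }
            for pid, ln, vol, cx in rows
        ],
        columns=["plug_id", "length_mm", "volume_mm3", "centroid_x", "centroid_y", "centroid_z"],
    )


class TestMixtureSelection:
    def test_well_separated_two_component_recovery(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(6, 2, 250), rng.normal(20, 4, 250)])
        fits, _ = fit_length_mixture(x, k_range=(1, 2, 3), seed=0)
        best = next(f for f in fits if f.selected)
        assert best.k == 2
        assert abs(best.means[0] - 6) / 6 < 0.10
        assert abs(best.means[1] - 20) / 20 < 0.10

    def test_single_gaussian_selects_one_component(self):
        rng = np.random.default_rng(1)
        fits, _ = fit_length_mixture(rng.normal(12, 3, 500), k_range=(1, 2, 3), seed=0)
        assert next(f for f in fits if f.selected).k == 1

    def test_aic_definition_consistent_with_returned_parameters(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(6, 2, 100), rng.normal(20, 4, 100)])
        fits, _ = fit_length_mixture(x, k_range=(1, 2), seed=0)
        for f in fits:
            assert f.aic == pytest.approx(2 * f.n_parameters - 2 * f.log_likelihood, rel=1e-12)
            # recompute lnL independently from the returned parameters
            pdf = np.zeros_like(x)
            for w, m, s in zip(f.weights, f.means, f.sds):
                pdf += w * np.exp(-0.5 * ((x - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
            assert np.log(pdf).sum() == pytest.approx(f.log_likelihood, rel=1e-6)
            assert f.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_small_k_skipped_with_notice(self):
        fits, notices = fit_length_mixture(np.arange(10.0) + 1, k_range=(1, 4), seed=0)
        assert [f.k for f in fits] == [1]
        assert any("k=4" in n for n in notices)

    def test_too_few_lengths_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_length_mixture([1.0, 2.0])


class TestPhenotype:
    @pytest.mark.parametrize(
        "length,expected",
        [(12.0, "stubby"), (12.01, "stringy"), (0.0, "stubby"), (40.0, "stringy")],
    )
    def test_threshold_boundaries(self, length, expected):
        assert classify_phenotype(length) == expected

    def test_classification_partitions_any_list(self):
        rng = np.random.default_rng(0)
        lengths = rng.uniform(0, 40, 200)
        states = classify_lengths(lengths)
        assert (states == "stubby").sum() + (states == "stringy").sum() == 200


class TestMatching:
    def test_identical_timepoints_all_persistent_zero_delta(self):
        pm = make_map([(0, 10), (1, 11)])
        morph = make_morph([(0, 8.0, 50.0, 1.0), (1, 20.0, 200.0, 5.0)])
        matches, new = match_plugs(pm, morph, pm, morph)
        assert (matches["label"] == "persistent").all()
        assert (matches["delta_length_mm"] == 0.0).all()
        assert len(new) == 0

    def test_empty_followup_all_transient(self):
        pm = make_map([(0, 10)])
        morph = make_morph([(0, 8.0, 50.0, 1.0)])
        empty_map = make_map([])
        empty_morph = make_morph([])
        matches, new = match_plugs(pm, morph, empty_map, empty_morph)
        assert (matches["label"] == "transient").all()
        assert len(new) == 0

    def test_swapping_timepoints_swaps_transient_and_new(self):
        base_map, base_morph = make_map([(0, 10), (1, 11)]), make_morph(
            [(0, 8.0, 50.0, 1.0), (1, 20.0, 200.0, 5.0)]
        )
        fup_map, fup_morph = make_map([(5, 11), (6, 12)]), make_morph(
            [(5, 21.0, 210.0, 5.0), (6, 9.0, 60.0, 2.0)]
        )
        fwd_matches, fwd_new = match_plugs(base_map, base_morph, fup_map, fup_morph)
        rev_matches, rev_new = match_plugs(fup_map, fup_morph, base_map, base_morph)
        fwd_transient = set(
            fwd_matches.loc[fwd_matches["label"] == "transient", "branch_id"]
        )
        rev_new_branches = set(rev_new["branch_id"])
        assert fwd_transient == rev_new_branches  # branch 10
        assert set(fwd_new["branch_id"]) == set(
            rev_matches.loc[rev_matches["label"] == "transient", "branch_id"]
        )

    def test_branch_conflict_resolved_by_nearest_centroid(self):
        base_map = make_map([(0, 10)])
        base_morph = make_morph([(0, 8.0, 50.0, 1.0)])
        fup_map = make_map([(5, 10), (6, 10)])
        fup_morph = make_morph([(5, 8.0, 50.0, 9.0), (6, 8.0, 50.0, 1.5)])
        matches, new = match_plugs(base_map, base_morph, fup_map, fup_morph)
        assert matches.iloc[0]["followup_plug_id"] == 6  # closer centroid
        assert list(new["followup_plug_id"]) == [5]

    def test_phantom_followup_labels_recovered_exactly(self, small_tree):
        spec = PhantomSpec(
            grid_shape=(96, 96, 96), spacing=(0.5, 0.5, 0.5),
            plug_placements=[(16, 0.2, 3.0), (20, 0.1, 2.5), (25, 0.2, 2.0)],
        )
        baseline = rasterize_phantom(small_tree, spec, seed=1)
        cfg = FollowupConfig(persistence_probability=0.5, length_jitter_sd=0.5,
                             new_plug_rate=2.0, seed=4)
        followup_truth, labels = simulate_followup(baseline.truth, small_tree, cfg)
        placements = [
            (int(r.branch_id), float(r.start_frac), float(r.length_mm))
            for r in followup_truth.itertuples()
        ]
        followup = rasterize_phantom(
            small_tree,
            PhantomSpec(grid_shape=(96, 96, 96), spacing=(0.5, 0.5, 0.5),
                        plug_placements=placements),
            seed=2,
        )
        b_tab = morphometry_table(baseline.plug_masks, baseline.volume)
        f_tab = morphometry_table(followup.plug_masks, followup.volume)
        b_map = map_plugs(baseline.observed_tree, b_tab)
        f_map = map_plugs(followup.observed_tree, f_tab)
        matches, new = match_plugs(b_map, b_tab, f_map, f_tab)
        got = dict(zip(matches["baseline_plug_id"], matches["label"]))
        want = dict(zip(labels["plug_id"], labels["label"]))
        assert got == want
        n_new_truth = len(followup_truth) - int((labels["label"] == "persistent").sum())
        assert len(new) == n_new_truth


class TestTransitions:
    def test_unchanged_phenotypes_are_diagonal(self):
        matches = pd.DataFrame(
            {
                "label": ["persistent", "persistent"],
                "baseline_state": ["stubby", "stringy"],
                "followup_state": ["stubby", "stringy"],
            }
        )
        tm = transition_matrix(matches, pd.DataFrame(columns=["state"]))
        off_diag = tm.counts - np.diag(np.diag(tm.counts))
        assert off_diag.sum() == 0

    def test_rows_stochastic_where_counted(self):
        matches = pd.DataFrame(
            {
                "label": ["persistent", "transient", "persistent"],
                "baseline_state": ["stubby", "stringy", "stubby"],
                "followup_state": ["stringy", "absent", "stubby"],
            }
        )
        new = pd.DataFrame({"state": ["stubby"]})
        tm = transition_matrix(matches, new)
        sums = tm.counts.sum(axis=1)
        for i in range(3):
            if sums[i] > 0:
                assert tm.probabilities[i].sum() == pytest.approx(1.0)

    def test_persistent_plus_transient_equals_baseline_count(self):
        matches = pd.DataFrame(
            {
                "label": ["persistent", "transient", "transient"],
                "baseline_state": ["stubby", "stubby", "stringy"],
                "followup_state": ["stubby", "absent", "absent"],
            }
        )
        tm = transition_matrix(matches, pd.DataFrame(columns=["state"]))
        assert tm.counts[1:, :].sum() == len(matches)  # rows stubby+stringy


class TestDeltas:
    def _matches(self, deltas):
        return pd.DataFrame(
            {
                "label": ["persistent"] * len(deltas),
                "delta_length_mm": deltas,
                "delta_volume_mm3": np.asarray(deltas) * 10.0,
            }
        )

    def test_zero_jitter_gives_all_zero_deltas_and_p_one(self):
        out = delta_summary(self._matches([0.0, 0.0, 0.0]))
        assert out["delta_length_mm"]["mean"] == 0.0
        assert out["delta_length_mm"]["wilcoxon_p"] == 1.0

    def test_mean_delta_within_clt_bound(self):
        rng = np.random.default_rng(5)
        deltas = rng.normal(0.0, 3.0, 500)
        out = delta_summary(self._matches(deltas))
        assert abs(out["delta_length_mm"]["mean"]) < 3 * 3.0 / np.sqrt(500)

    def test_sign_flip_leaves_abs_mean_unchanged(self):
        rng = np.random.default_rng(6)
        deltas = rng.normal(0.0, 2.0, 100)
        a = delta_summary(self._matches(deltas))
        b = delta_summary(self._matches(-deltas))
        assert abs(a["delta_length_mm"]["mean"]) == pytest.approx(
            abs(b["delta_length_mm"]["mean"])
        )
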