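"""Poiseuille network resistance, RS closed forms, and OLVP."""

import math

import numpy as np
import pandas as pd
import pytest
from oracles import brute_force_olvp, series_parallel_resistance

from conftest import random_tree
from qaamp import (
    FlowConfig,
    PhantomSpec,
    PlugMap,
    TreeConfig,
    effective_resistance,
    generate_airway_tree,
    map_plugs,
    morphometry_table,
    olvp,
    rasterize_phantom,
    resistance_score,
    rs_per_plug_by_group,
    segment_resistance,
)
from qaamp.tree import generation_group

MAP_COLUMNS = ["plug_id", "branch_id", "generation", "lobe", "distance_mm", "group"]


def plug_map_on(branch_gens: list[tuple[int, int]]) -> PlugMap:
    """PlugMap with one plug per (branch_id, generation) pair."""
    rows = [
        {
            "plug_id": i, "branch_id": bid, "generation": gen, "lobe": "x",
            "distance_mm": 0.0, "group": generation_group(gen),
        }
        for i, (bid, gen) in enumerate(branch_gens)
    ]
    return PlugMap(scan_id="s", assignments=pd.DataFrame(rows, columns=MAP_COLUMNS))


def symmetric_matched_tree(generations=1):
    """Symmetric tree whose child resistance equals the parent resistance.

    R ~ L / r^4, so equal resistance per generation needs
    length_ratio = radius_ratio^4.
    """
    lr = 0.5
    return generate_airway_tree(
        TreeConfig(
            seed=0, max_generation=generations, root_length=10.0, root_radius=2.0,
            length_ratio=lr, radius_ratio=lr**0.25, branch_angle=30.0,
            jitter_sd=0.0, min_radius=1e-9,
        )
    )


class TestSegmentResistance:
    def test_direct_formula(self):
        # 8 * mu * L / (pi * r^4) with L = 10 mm, r = 1 mm
        expected = 8.0 * 1.85e-5 * 0.01 / (math.pi * 1e-12)
        assert segment_resistance(10.0, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_fourth_power_radius_law(self):
        assert segment_resistance(10.0, 0.5) == pytest.approx(
            16.0 * segment_resistance(10.0, 1.0), rel=1e-12
        )

    def test_linear_in_length(self):
        assert segment_resistance(20.0, 1.0) == pytest.approx(
            2.0 * segment_resistance(10.0, 1.0), rel=1e-12
        )

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            segment_resistance(0.0, 1.0)


class TestEffectiveResistance:
    def test_single_pipe_equals_segment_resistance(self):
        tree = generate_airway_tree(
            TreeConfig(seed=0, max_generation=1, root_length=10, root_radius=2.0,
                       length_ratio=0.5, radius_ratio=0.7, jitter_sd=0.0)
        )
        # plug one child: remaining path = root + other child in series
        r_eff, q, flag = effective_resistance(tree, {1})
        expected = series_parallel_resistance(tree, {1})
        assert not flag
        assert r_eff == pytest.approx(expected, rel=1e-12)

    def test_matches_series_parallel_oracle_on_random_trees(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            tree = random_tree(rng, max_generation=6)
            terminals = tree.terminal_ids
            k = int(rng.integers(0, len(terminals) + 1))
            plugged = set(rng.choice(terminals, size=k, replace=False).tolist())
            r_eff, _, flag = effective_resistance(tree, plugged)
            expected = series_parallel_resistance(tree, plugged)
            if flag:
                assert expected == math.inf
            else:
                worst = max(worst, abs(r_eff - expected) / expected)
        assert worst < 1e-9

    def test_all_plugged_flags_infinite(self):
        tree = symmetric_matched_tree()
        r_eff, q, flag = effective_resistance(tree, set(tree.terminal_ids))
        assert flag and r_eff == math.inf and q == 0.0

    def test_non_terminal_plug_rejected(self):
        tree = symmetric_matched_tree(2)
        with pytest.raises(ValueError, match="non-terminal"):
            effective_resistance(tree, {1})


class TestResistanceScore:
    def test_no_plugs_gives_zero(self):
        result = resistance_score(symmetric_matched_tree(), plug_map_on([]))
        assert result.resistance_score == 0.0

    def test_symmetric_two_terminal_closed_form(self):
        # R0 = Rc: unplugged R = R0 + Rc/2; one plugged R = R0 + Rc
        # RS = 100 * (Rc/2) / (R0 + Rc/2) = 100/3
        result = resistance_score(symmetric_matched_tree(), plug_map_on([(1, 1)]))
        assert result.resistance_score == pytest.approx(100.0 / 3.0, rel=1e-9)

    def test_plugging_more_terminals_never_lowers_rs(self):
        tree = symmetric_matched_tree(3)
        terminals = tree.terminal_ids
        single = resistance_score(tree, plug_map_on([(terminals[0], 3)]))
        double = resistance_score(
            tree, plug_map_on([(terminals[0], 3), (terminals[1], 3)])
        )
        assert double.resistance_score >= single.resistance_score

    def test_rs_invariant_to_viscosity_and_pressure(self):
        tree = symmetric_matched_tree(2)
        pm = plug_map_on([(tree.terminal_ids[0], 2)])
        rng = np.random.default_rng(3)
        values = [
            resistance_score(
                tree, pm,
                FlowConfig(viscosity=float(rng.uniform(1e-6, 1e-3)),
                           driving_pressure=float(rng.uniform(0.1, 100.0))),
            ).resistance_score
            for _ in range(100)
        ]
        assert max(values) - min(values) < 1e-9

    def test_r_p_never_below_r_a_on_random_trees(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            tree = random_tree(rng, max_generation=5)
            terminals = tree.terminal_ids
            k = int(rng.integers(1, len(terminals) + 1))
            plugged = rng.choice(terminals, size=k, replace=False)
            pm = plug_map_on([(int(b), tree.branches[int(b)].generation) for b in plugged])
            result = resistance_score(tree, pm)
            assert result.infinite_flag or result.resistance_plugged >= result.resistance_unplugged


class TestRsPerPlugByGroup:
    def test_single_group_equals_total_rs_over_count(self):
        tree = symmetric_matched_tree(2)
        pm = plug_map_on([(t, 2) for t in tree.terminal_ids[:2]])
        total = resistance_score(tree, pm)
        per_group = rs_per_plug_by_group(tree, pm)
        assert set(per_group) == {"proximal"}
        assert per_group["proximal"] == pytest.approx(total.resistance_score / 2)

    def test_proximal_plug_outweighs_distal_plug(self):
        # deep symmetric tree: a generation-2 occlusion cuts more parallel
        # paths than a generation-5 occlusion
        tree = generate_airway_tree(
            TreeConfig(seed=0, max_generation=5, root_length=12, root_radius=3.0,
                       length_ratio=0.75, radius_ratio=2 ** (-1 / 3),
                       jitter_sd=0.0, min_radius=1e-9)
        )
        gen2 = [b.branch_id for b in tree.branches.values() if b.generation == 2][0]
        gen5 = [
            b.branch_id
            for b in tree.branches.values()
            if b.generation == 5 and gen2 in _ancestors(tree, b.branch_id)
        ][0]
        rs_gen2 = resistance_score(tree.pruned([gen2]), plug_map_on([(gen2, 2)]))
        rs_gen5 = resistance_score(tree, plug_map_on([(gen5, 5)]))
        assert rs_gen2.resistance_score > rs_gen5.resistance_score

    def test_empty_groups_omitted(self):
        tree = symmetric_matched_tree(2)
        per_group = rs_per_plug_by_group(tree, plug_map_on([(tree.terminal_ids[0], 2)]))
        assert "intermediate" not in per_group and "distal" not in per_group


def _ancestors(tree, branch_id):
    out = set()
    b = tree.branches[branch_id]
    while b.parent_id is not None:
        out.add(b.parent_id)
        b = tree.branches[b.parent_id]
    return out


class TestOlvp:
    def _phantom_pm(self, small_phantom):
        table = morphometry_table(small_phantom.plug_masks, small_phantom.volume)
        return map_plugs(small_phantom.observed_tree, table)

    def test_no_plugs_gives_zero_olvp(self, small_phantom):
        empty = PlugMap(scan_id="s", assignments=pd.DataFrame(columns=MAP_COLUMNS))
        result = olvp(small_phantom.volume, small_phantom.observed_tree, empty)
        assert result.whole_lung_olvp == 0.0
        assert all(v["OLVP_percent"] == 0.0 for v in result.per_lobe.values())

    def test_fully_plugged_lobe_reaches_100(self, small_phantom):
        tree = small_phantom.observed_tree
        lobe = "RUL"
        plugged = [
            (b, tree.branches[b].generation)
            for b in tree.terminal_ids
            if tree.branches[b].lobe == lobe
        ]
        result = olvp(small_phantom.volume, tree, plug_map_on(plugged))
        assert result.per_lobe[lobe]["OLVP_percent"] == 100.0

    def test_volume_conservation_and_weighted_mean(self, small_phantom):
        result = olvp(small_phantom.volume, small_phantom.observed_tree,
                      self._phantom_pm(small_phantom))
        total_vox = float(np.prod(small_phantom.volume.shape)) * small_phantom.volume.voxel_volume
        vt_sum = sum(v["V_t_mm3"] for v in result.per_lobe.values())
        assert vt_sum == pytest.approx(total_vox)
        weighted = 100.0 * sum(v["V_o_mm3"] for v in result.per_lobe.values()) / vt_sum
        assert result.whole_lung_olvp == pytest.approx(weighted)

    def test_matches_brute_force_oracle(self, small_phantom):
        pm = self._phantom_pm(small_phantom)
        # down-sampled volume keeps the explicit python loop oracle fast
        vol = small_phantom.volume
        from qaamp import CTVolume

        small = CTVolume(
            data=vol.data[::4, ::4, ::4], spacing=vol.spacing * 4, origin=vol.origin,
            lobe_labels=vol.lobe_labels[::4, ::4, ::4], lobe_legend=vol.lobe_legend,
        )
        result = olvp(small, small_phantom.observed_tree, pm)
        expected = brute_force_olvp(
            small, small_phantom.observed_tree, pm.plugged_branch_ids
        )
        for lobe, (n_obs, n_tot) in expected.items():
            assert result.per_lobe[lobe]["OLVP_percent"] == pytest.approx(
                100.0 * n_obs / n_tot
            )

    def test_missing_lobe_terminations_named(self, small_phantom):
        tree = small_phantom.observed_tree.pruned([1])  # cut half the tree
        with pytest.raises(ValueError, match="lobe"):
            olvp(small_phantom.volume, tree, plug_map_on([]))
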