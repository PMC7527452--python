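"""Simulator correctness: geometry closed forms, recount closure, determinism."""

from dataclasses import replace

import numpy as np
import pytest

from axoquant.synthetic_stacks import (
    GroundTruth,
    SimulationConfig,
    _union_volume_fraction,
    generate_cohort,
    place_puncta,
    render_stack,
    simulate_axons,
    simulate_stack,
)


def brute_force_unique_pairs(a, b, d):
    """Independent exhaustive greedy matcher used as the oracle."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        return []
    pairs = []
    for i in range(len(a)):
        for j in range(len(b)):
            dist = float(np.sqrt(((a[i] - b[j]) ** 2).sum()))
            if dist <= d:
                pairs.append((dist, i, j))
    pairs.sort()
    taken_a, taken_b, out = set(), set(), []
    for dist, i, j in pairs:
        if i not in taken_a and j not in taken_b:
            taken_a.add(i)
            taken_b.add(j)
            out.append((i, j, dist))
    return out


class TestSimulateAxons:
    def test_zero_axons_gives_empty_truth(self):
        cfg = SimulationConfig(n_axons=0)
        truth = simulate_axons(cfg)
        assert truth.axon_centerlines == []
        assert truth.true_volume_fraction == 0.0

    def test_straight_tube_volume_matches_cylinder_closed_form(self):
        cfg = SimulationConfig(
            box_size=(10.0, 20.0, 20.0), voxel_size=(0.25, 0.1, 0.1), n_axons=0
        )
        line = np.array([[5.0, 10.0, 0.0], [5.0, 10.0, 20.0]])
        vf = _union_volume_fraction([line], cfg)
        closed = np.pi * cfg.axon_radius**2 * 20.0 / (10.0 * 20.0 * 20.0)
        assert vf == pytest.approx(closed, rel=0.02)

    def test_two_overlapping_tubes_counted_once(self):
        cfg = SimulationConfig(
            box_size=(10.0, 20.0, 20.0), voxel_size=(0.25, 0.1, 0.1), n_axons=0
        )
        line = np.array([[5.0, 10.0, 0.0], [5.0, 10.0, 20.0]])
        assert _union_volume_fraction([line, line.copy()], cfg) == pytest.approx(
            _union_volume_fraction([line], cfg)
        )

    def test_seeded_determinism(self, small_config):
        t1 = simulate_axons(small_config)
        t2 = simulate_axons(small_config)
        assert len(t1.axon_centerlines) == len(t2.axon_centerlines)
        for a, b in zip(t1.axon_centerlines, t2.axon_centerlines):
            np.testing.assert_array_equal(a, b)

    def test_centerlines_stay_inside_box(self, small_config):
        truth = simulate_axons(small_config)
        box = np.asarray(small_config.box_size)
        for line in truth.axon_centerlines:
            assert np.all(line >= 0.0) and np.all(line <= box + 1e-9)

    def test_fat_axon_rejected(self):
        cfg = SimulationConfig(box_size=(3.0, 6.5, 6.5), voxel_size=(0.3, 0.13, 0.13),
                               axon_radius=1.6)
        with pytest.raises(ValueError, match="axon_radius"):
            simulate_axons(cfg)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(bouton_fraction=1.5),
            dict(persistence=-0.1),
            dict(varicosity_rate=-1.0),
            dict(voxel_size=(0.3, 0.0, 0.13)),
            dict(box_size=(9.1, 33.28, 33.28)),  # not a voxel multiple
            dict(post_channel="tubulin"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestPlacePuncta:
    def test_zero_rate_gives_no_varicosities_or_boutons(self, small_config):
        cfg = replace(small_config, varicosity_rate=0.0)
        truth = place_puncta(cfg, simulate_axons(cfg))
        assert len(truth.puncta_of(cfg.fiber_marker, "varicosity")) == 0
        assert len(truth.puncta_of("synaptophysin", "bouton")) == 0

    def test_all_coordinates_inside_box(self, small_config):
        truth = place_puncta(small_config, simulate_axons(small_config))
        coords = truth.puncta[["z_um", "y_um", "x_um"]].to_numpy()
        assert np.all(coords >= 0.0)
        assert np.all(coords < np.asarray(small_config.box_size))

    def test_counts_equal_list_lengths(self, small_config):
        truth = place_puncta(small_config, simulate_axons(small_config))
        kind = small_config.post_kind
        assert set(truth.true_pair_counts) == {f"serotonergic_{kind}", f"other_{kind}"}
        assert sum(truth.true_triad_counts.values()) <= len(
            truth.puncta_of("synaptophysin", "bouton")
        )

    def test_recount_closure_against_independent_oracle(self, small_config):
        """Recorded pair counts equal an exhaustive recount of emitted coordinates."""
        cfg = replace(small_config, paired_fraction=0.0, triad_fraction=0.0,
                      outside_syn_density=0.05, postsyn_density=0.05)
        truth = place_puncta(cfg, simulate_axons(cfg))
        boutons = truth.puncta_of("synaptophysin", "bouton")
        syn_out = truth.puncta[
            (truth.puncta.channel == "synaptophysin") & (truth.puncta.role != "bouton")
        ][["z_um", "y_um", "x_um"]].to_numpy(float)
        post = truth.puncta_of(cfg.post_channel)
        kind = cfg.post_kind
        d = cfg.pairing_distance
        assert truth.true_pair_counts[f"serotonergic_{kind}"] == len(
            brute_force_unique_pairs(boutons, post, d)
        )
        assert truth.true_pair_counts[f"other_{kind}"] == len(
            brute_force_unique_pairs(syn_out, post, d)
        )

    def test_constructed_pairs_are_counted(self, small_config):
        cfg = replace(small_config, paired_fraction=0.5, outside_syn_density=0.1)
        truth = place_puncta(cfg, simulate_axons(cfg))
        n_syn_out = (
            (truth.puncta.channel == "synaptophysin") & (truth.puncta.role != "bouton")
        ).sum()
        requested = int(round(0.5 * (truth.puncta.role == "syn_out").sum()))
        assert truth.true_pair_counts[f"other_{cfg.post_kind}"] >= requested
        assert n_syn_out > 0

    def test_constructed_triads_are_counted(self, small_config):
        cfg = replace(small_config, triad_fraction=0.3)
        truth = place_puncta(cfg, simulate_axons(cfg))
        n_boutons = len(truth.puncta_of("synaptophysin", "bouton"))
        assert sum(truth.true_triad_counts.values()) >= int(round(0.3 * n_boutons))


class TestRenderStack:
    def test_no_photons_no_background_no_noise_gives_zero_stack(self, small_config):
        cfg = replace(small_config, photon_scale=0.0, background=0.0, read_noise_sd=0.0)
        truth = place_puncta(cfg, simulate_axons(cfg))
        stack = render_stack(cfg, truth)
        assert stack.data.max() == 0.0

    def test_noiseless_sphere_centroid_matches_truth(self):
        cfg = SimulationConfig(
            box_size=(6.0, 6.5, 6.5), voxel_size=(0.3, 0.13, 0.13), n_axons=0,
            photon_scale=100.0, background=0.0, read_noise_sd=0.0, seed=4,
        )
        truth = simulate_axons(cfg)
        import pandas as pd

        center = np.array([3.1, 3.27, 3.33])
        truth.puncta = pd.DataFrame(
            [dict(z_um=center[0], y_um=center[1], x_um=center[2],
                  channel="synaptophysin", role="syn_out", radius_um=0.4, axon_id=-1)]
        )
        stack = render_stack(cfg, truth)
        img = stack.channel("synaptophysin").astype(float)
        voxel = np.asarray(stack.voxel_size)
        idx = np.indices(img.shape)
        centroid = np.array(
            [float((img * (idx[k] + 0.5) * voxel[k]).sum() / img.sum()) for k in range(3)]
        )
        assert np.all(np.abs(centroid - center) <= 0.5 * voxel)

    def test_fixed_seed_bit_identical(self, small_config):
        s1, _ = simulate_stack(small_config)
        s2, _ = simulate_stack(small_config)
        np.testing.assert_array_equal(s1.data, s2.data)

    def test_channel_metadata(self, small_config):
        stack, _ = simulate_stack(small_config)
        assert stack.channel_names[:3] == ["SERT", "synaptophysin", "gephyrin"]
        assert stack.voxel_size == small_config.voxel_size

    def test_undersampled_psf_warns(self, small_config):
        cfg = replace(small_config, psf_sigma=(0.01, 0.01, 0.01))
        truth = place_puncta(cfg, simulate_axons(cfg))
        with pytest.warns(UserWarning, match="undersampled"):
            render_stack(cfg, truth)

    def test_yfp_channel_added_with_omission(self, small_config):
        cfg = replace(small_config, yfp_omit_fraction=0.25)
        truth = place_puncta(cfg, simulate_axons(cfg))
        stack = render_stack(cfg, truth)
        assert "YFP" in stack.channel_names
        assert len(truth.yfp_kept_axons) == round(0.75 * cfg.n_axons)


class TestGenerateCohort:
    def test_group_multiplier_scales_axon_number_and_volume(self, small_config):
        cohort = generate_cohort(
            small_config,
            [("sham", 1.0), ("stroke", 0.5)],
            n_per_group=3,
            render=False,
        )
        assert len(cohort) == 6
        vf = {g: [] for g in ("sham", "stroke")}
        for rec in cohort:
            vf[rec["group"]].append(rec["truth"].true_volume_fraction)
            expected_axons = round(small_config.n_axons * rec["multiplier"])
            assert len(rec["truth"].axon_centerlines) == expected_axons
        ratio = np.mean(vf["stroke"]) / np.mean(vf["sham"])
        assert ratio == pytest.approx(0.5, abs=0.15)

    def test_single_group_multiplier_one_gives_replicates(self, small_config):
        cohort = generate_cohort(small_config, [("only", 1.0)], 2, render=False)
        assert len(cohort) == 2
        assert cohort[0]["config"].n_axons == small_config.n_axons
        assert cohort[0]["config"].seed != cohort[1]["config"].seed

    def test_same_master_seed_identical_cohort(self, small_config):
        c1 = generate_cohort(small_config, [("a", 1.0)], 1)
        c2 = generate_cohort(small_config, [("a", 1.0)], 1)
        np.testing.assert_array_equal(c1[0]["stack"].data, c2[0]["stack"].data)

    def test_invalid_cohort_parameters_rejected(self, small_config):
        with pytest.raises(ValueError, match="n_per_group"):
            generate_cohort(small_config, [("a", 1.0)], 0)
        with pytest.raises(ValueError, match="multiplier"):
            generate_cohort(small_config, [("a", -1.0)], 2)
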