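"""Pairing/triad calls vs exhaustive brute-force oracles; colocalization; tables."""

import numpy as np
import pytest

from axoquant.fiber_quant import FiberModel, VaricosityList
from axoquant.puncta_detection import Punctum
from axoquant.synapse_triads import (
    DensityRecord,
    SynapseCall,
    call_synapses,
    call_triads,
    colocalization_ratio,
    densities_to_frame,
    pair_within,
    tabulate_densities,
)

D = 0.6


# ---------------------------------------------------------------------------
# Independent oracles (quadratic / cubic enumeration, no spatial index)
# ---------------------------------------------------------------------------

def oracle_all_pairs(a, b, d):
    out = []
    for i in range(len(a)):
        for j in range(len(b)):
            dist = float(np.sqrt(((a[i] - b[j]) ** 2).sum()))
            if dist <= d:
                out.append((i, j, dist))
    return out


def oracle_unique_pairs(a, b, d):
    cand = sorted((dist, i, j) for i, j, dist in oracle_all_pairs(a, b, d))
    ua, ub, out = set(), set(), []
    for dist, i, j in cand:
        if i in ua or j in ub:
            continue
        ua.add(i)
        ub.add(j)
        out.append((i, j, dist))
    return out


def oracle_triads(boutons, pre, post, d, reference):
    """Enumerate bouton-pair assignments: nearest qualifying reference wins."""
    out = []
    for bi in range(len(boutons)):
        best = None
        for pj in range(len(pre)):
            d_pre = float(np.linalg.norm(boutons[bi] - pre[pj]))
            d_post = float(np.linalg.norm(boutons[bi] - post[pj]))
            if reference == "midpoint":
                ref = float(np.linalg.norm(boutons[bi] - (pre[pj] + post[pj]) / 2))
            elif reference == "nearest-member":
                ref = min(d_pre, d_post)
            else:
                ref = max(d_pre, d_post)
            if ref <= d and (best is None or ref < best[0]):
                best = (ref, pj, "presynaptic" if d_pre <= d_post else "postsynaptic")
        if best is not None:
            out.append((bi, best[1], best[2]))
    return out


def make_puncta(coords, channel="synaptophysin", compartment=None, start_id=0):
    return [
        Punctum(id=start_id + i, center=tuple(c), diameter=0.7, channel=channel,
                intensity=1.0, compartment=compartment)
        for i, c in enumerate(np.atleast_2d(coords))
    ]


class TestPairWithin:
    def test_pair_inside_threshold(self):
        assert len(pair_within([[0, 0, 0]], [[0, 0, 0.5]], D)) == 1

    def test_no_pair_beyond_threshold(self):
        assert pair_within([[0, 0, 0]], [[0, 0, 0.7]], D) == []

    def test_empty_inputs(self):
        assert pair_within([], [[0, 0, 0]], D) == []

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            pair_within([[0, 0, 0]], [[0, 0, 0]], D, mode="fuzzy")

    @pytest.mark.parametrize("mode", ["unique", "all"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_bruteforce_oracle_exactly(self, mode, seed, rng):
        local = np.random.default_rng(seed)
        a = local.uniform(0, [9, 20, 20], size=(local.integers(5, 400), 3))
        b = local.uniform(0, [9, 20, 20], size=(local.integers(5, 400), 3))
        got = pair_within(a, b, D, mode=mode)
        oracle = oracle_all_pairs(a, b, D) if mode == "all" else oracle_unique_pairs(a, b, D)
        assert len(got) == len(oracle)
        assert {(i, j) for i, j, _ in got} == {(i, j) for i, j, _ in oracle}

    def test_shrinking_distance_never_increases_count(self, rng):
        a = rng.uniform(0, 10, size=(300, 3))
        b = rng.uniform(0, 10, size=(300, 3))
        counts = [len(pair_within(a, b, d)) for d in (1.2, 0.9, 0.6, 0.3)]
        assert counts == sorted(counts, reverse=True)

    def test_unique_count_bounded_by_smaller_set(self, rng):
        a = rng.uniform(0, 3, size=(50, 3))
        b = rng.uniform(0, 3, size=(200, 3))
        assert len(pair_within(a, b, 1.0)) <= 50

    def test_translation_invariance(self, rng):
        a = rng.uniform(0, 10, size=(100, 3))
        b = rng.uniform(0, 10, size=(100, 3))
        shifted = [(i, j) for i, j, _ in pair_within(a + 5.0, b + 5.0, D)]
        assert shifted == [(i, j) for i, j, _ in pair_within(a, b, D)]


class TestCallSynapses:
    def test_no_in_fiber_synaptophysin_no_serotonergic_calls(self, rng):
        syn = make_puncta(rng.uniform(0, 5, (20, 3)), compartment="out_fiber")
        post = make_puncta(rng.uniform(0, 5, (20, 3)), channel="gephyrin", start_id=100)
        calls = call_synapses(syn, post, "inhibitory")
        assert all(c.cls == "other_inhibitory" for c in calls)

    def test_unpartitioned_synaptophysin_rejected(self):
        syn = make_puncta([[1, 1, 1]])
        with pytest.raises(ValueError, match="compartment"):
            call_synapses(syn, [], "inhibitory")

    def test_bad_post_kind_rejected(self):
        with pytest.raises(ValueError, match="post_kind"):
            call_synapses([], [], "modulatory")

    def test_call_counts_match_oracle_per_compartment(self, rng):
        n_in, n_out, n_post = 40, 60, 80
        in_xyz = rng.uniform(0, 6, (n_in, 3))
        out_xyz = rng.uniform(0, 6, (n_out, 3))
        post_xyz = rng.uniform(0, 6, (n_post, 3))
        syn = make_puncta(in_xyz, compartment="in_fiber") + make_puncta(
            out_xyz, compartment="out_fiber", start_id=1000
        )
        post = make_puncta(post_xyz, channel="psd95", start_id=5000)
        calls = call_synapses(syn, post, "excitatory")
        sero = [c for c in calls if c.cls == "serotonergic_excitatory"]
        other = [c for c in calls if c.cls == "other_excitatory"]
        assert len(sero) == len(oracle_unique_pairs(in_xyz, post_xyz, D))
        assert len(other) == len(oracle_unique_pairs(out_xyz, post_xyz, D))


class TestCallTriads:
    def bouton(self, center):
        return make_puncta([center], compartment="in_fiber")

    def synapse(self, pre, post, sid=0, cls="other_inhibitory"):
        return SynapseCall(id=sid, pre=1, post=2, distance=0.0, cls=cls,
                           pre_center=tuple(pre), post_center=tuple(post))

    def test_bouton_near_midpoint_nearer_pre_is_presynaptic(self):
        s = self.synapse((0, 0, 0.2), (0, 0, 0.7))
        triads = call_triads(self.bouton((0, 0.3, 0.25)), [s])
        assert len(triads) == 1
        assert triads[0].polarity == "presynaptic"
        assert triads[0].cls == "inhibitory"

    def test_no_other_synapses_no_triads(self):
        assert call_triads(self.bouton((0, 0, 0)), []) == []

    def test_serotonergic_pairs_ignored(self):
        s = self.synapse((0, 0, 0.2), (0, 0, 0.7), cls="serotonergic_inhibitory")
        assert call_triads(self.bouton((0, 0.3, 0.25)), [s]) == []

    def test_exact_tie_resolves_presynaptic(self):
        s = self.synapse((0, 0, -0.2), (0, 0, 0.2))
        triads = call_triads(self.bouton((0, 0.3, 0.0)), [s])
        assert triads[0].polarity == "presynaptic"

    @pytest.mark.parametrize("reference", ["midpoint", "nearest-member", "both-members"])
    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_matches_enumeration_oracle(self, reference, seed):
        local = np.random.default_rng(seed)
        boutons_xyz = local.uniform(0, 4, (30, 3))
        pre_xyz = local.uniform(0, 4, (50, 3))
        post_xyz = pre_xyz + local.normal(0, 0.2, pre_xyz.shape)
        boutons = make_puncta(boutons_xyz, compartment="in_fiber")
        synapses = [
            self.synapse(pre_xyz[k], post_xyz[k], sid=k) for k in range(len(pre_xyz))
        ]
        got = call_triads(boutons, synapses, reference=reference)
        oracle = oracle_triads(boutons_xyz, pre_xyz, post_xyz, D, reference)
        assert len(got) == len(oracle)
        assert {(t.bouton, t.synapse, t.polarity) for t in got} == {
            (boutons[bi].id, pj, pol) for bi, pj, pol in oracle
        }

    def test_unknown_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            call_triads(self.bouton((0, 0, 0)), [self.synapse((0, 0, 0), (0, 0, 0.3))],
                        reference="centroid")


class TestColocalization:
    def model(self, mask):
        return FiberModel(mask=mask, voxel_size=(0.3, 0.13, 0.13),
                          tissue_volume=float(mask.size * 0.3 * 0.13 * 0.13))

    def test_identical_masks_ratio_one(self, rng):
        mask = rng.random((10, 20, 20)) > 0.7
        assert colocalization_ratio(self.model(mask), self.model(mask.copy())) == 1.0

    def test_disjoint_masks_ratio_zero(self):
        a = np.zeros((5, 10, 10), bool)
        b = np.zeros((5, 10, 10), bool)
        a[0], b[4] = True, True
        assert colocalization_ratio(self.model(a), self.model(b)) == 0.0

    def test_empty_reference_is_nan(self):
        a = np.zeros((5, 10, 10), bool)
        b = np.ones((5, 10, 10), bool)
        assert np.isnan(colocalization_ratio(self.model(a), self.model(b)))

    def test_grid_mismatch_rejected(self):
        a = np.zeros((5, 10, 10), bool)
        b = np.zeros((5, 10, 12), bool)
        with pytest.raises(ValueError):
            colocalization_ratio(self.model(a), self.model(b))


class TestTabulate:
    def fiber(self):
        mask = np.zeros((10, 20, 20), bool)
        mask[3:5, 5:10, 5:10] = True
        return FiberModel(mask=mask, voxel_size=(0.3, 0.13, 0.13),
                          tissue_volume=float(mask.size * 0.3 * 0.13 * 0.13))

    def test_empty_inputs_give_zero_valued_records(self):
        records = tabulate_densities("m1", "sham", "CG", self.fiber())
        frame = densities_to_frame(records)
        assert (frame.value >= 0).all()
        assert set(frame.measure) >= {
            "fiber_volume_density", "varicosity_density", "bouton_density",
            "synapse_serotonergic_inhibitory", "triad_inhibitory_presynaptic",
        }
        assert frame.loc[frame.measure == "varicosity_density", "value"].item() == 0.0

    def test_duplicate_record_rejected(self):
        records = tabulate_densities("m1", "sham", "CG", self.fiber())
        with pytest.raises(ValueError, match="duplicate"):
            tabulate_densities("m1", "sham", "CG", self.fiber(), existing=records)

    def test_counts_normalized_by_tissue_volume(self):
        fiber = self.fiber()
        varis = VaricosityList(
            points=[dict(center=(1, 1, 1), diameter=0.8, intensity=5.0)] * 4,
            tissue_volume=fiber.tissue_volume,
        )
        records = tabulate_densities("m1", "sham", "CG", fiber, varicosities=varis)
        frame = densities_to_frame(records)
        got = frame.loc[frame.measure == "varicosity_density", "value"].item()
        assert got == pytest.approx(4 / fiber.tissue_volume)

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            DensityRecord("a", "g", "CG", "m", -1.0, 10.0)
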