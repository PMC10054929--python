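"""Skeleton geometry: discretization, proximities, Ld, synapses, cohorts."""

import numpy as np
import pandas as pd
import pytest

from liketolike import geometry
from liketolike.experiments import brute_force_proximities, random_scene
from liketolike.geometry import Skeleton
from liketolike.synthetic import generate_skeleton_scene


def line(n=11, spacing=1.0, offset=(0, 0, 0), compartment="dendrite"):
    verts = np.zeros((n, 3))
    verts[:, 0] = np.arange(n) * spacing
    verts += np.asarray(offset, dtype=float)
    edges = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    return Skeleton(verts, edges, compartment)


class TestDiscretize:
    def test_uniform_subdivision(self):
        skel = Skeleton([[0, 0, 0], [10, 0, 0]], [[0, 1]], "axon")
        out = geometry.discretize(skel, max_edge=1.0)
        assert len(out.edges) == 10
        assert np.isclose(out.cable_length(), 10.0)
        assert np.all(out.edge_lengths() <= 1.0 + 1e-12)

    def test_idempotent_when_already_fine(self):
        skel = line(11)
        out = geometry.discretize(skel)
        assert np.isclose(out.cable_length(), skel.cable_length())
        assert len(out.edges) == len(skel.edges)

    def test_preserves_total_length_on_random_skeletons(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            verts = rng.uniform(0, 30, size=(20, 3))
            edges = np.column_stack([np.arange(19), np.arange(1, 20)])
            skel = Skeleton(verts, edges, "axon")
            out = geometry.discretize(skel, max_edge=0.8)
            assert abs(out.cable_length() - skel.cable_length()) <= 1e-9 * skel.cable_length()
            assert np.all(out.edge_lengths() <= 0.8 + 1e-12)

    def test_zero_length_edges_dropped_with_warning(self):
        skel = Skeleton([[0, 0, 0], [0, 0, 0], [1, 0, 0]], [[0, 1], [1, 2]], "axon")
        with pytest.warns(UserWarning):
            out = geometry.discretize(skel)
        assert len(out.edges) == 1

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            Skeleton([[0, 0, 0], [1, 0, 0]], [[1, 1]], "axon")


class TestProximities:
    def test_far_apart_empty(self):
        a = line(5, compartment="axon")
        d = line(5, offset=(0, 100, 0))
        assert geometry.find_proximities(a, d).size == 0

    def test_coincident_vertices_found(self):
        a = line(3, compartment="axon")
        d = line(3)
        pairs = geometry.find_proximities(a, d, radius=5)
        assert (0, 0) in set(map(tuple, pairs))

    def test_matches_brute_force_on_random_scenes(self):
        rng = np.random.default_rng(7)
        for _ in range(8):
            axon, dend = random_scene(rng, max_vertices=200)
            fast = set(map(tuple, geometry.find_proximities(axon, dend, radius=5)))
            slow = set(map(tuple, brute_force_proximities(axon, dend, radius=5)))
            assert fast == slow

    def test_pair_set_symmetric_under_role_swap(self):
        rng = np.random.default_rng(8)
        axon, dend = random_scene(rng, max_vertices=150)
        ab = set(map(tuple, geometry.find_proximities(axon, dend, radius=5)))
        ba = set((j, i) for i, j in geometry.find_proximities(dend, axon, radius=5))
        assert ab == ba


class TestLd:
    def test_parallel_within_radius(self):
        axon = line(15, offset=(-2, 0, 0), compartment="axon")
        dend = line(11, offset=(0, 3, 0))
        assert np.isclose(geometry.compute_ld(axon, dend, radius=5), 10.0)

    def test_parallel_outside_radius(self):
        axon = line(15, offset=(-2, 0, 0), compartment="axon")
        dend = line(11, offset=(0, 6, 0))
        assert geometry.compute_ld(axon, dend, radius=5) == 0.0

    def test_monotone_in_radius(self):
        rng = np.random.default_rng(9)
        axon, dend = random_scene(rng, max_vertices=150)
        lds = [geometry.compute_ld(axon, dend, radius=r) for r in (2, 4, 6, 8)]
        assert all(a <= b + 1e-12 for a, b in zip(lds, lds[1:]))

    def test_ld_bounded_by_dendritic_cable(self):
        rng = np.random.default_rng(10)
        axon, dend = random_scene(rng, max_vertices=150)
        assert geometry.compute_ld(axon, dend) <= dend.cable_length() + 1e-9

    def test_generated_scenes_match_expected_and_oracle(self):
        scenes, synapses, expected = generate_skeleton_scene(8, np.random.default_rng(12))
        for (axon, dend), exp in zip(scenes, expected):
            ld = geometry.compute_ld(axon, dend, radius=5)
            assert np.isclose(ld, exp), (exp, ld)
            oracle_pairs = brute_force_proximities(axon, dend, radius=5)
            assert np.isclose(geometry._ld_from_pairs(dend, oracle_pairs), exp)


class TestSynapseAssignment:
    def test_scene_synapses_assigned_as_expected(self):
        scenes, synapses, expected = generate_skeleton_scene(8, np.random.default_rng(13))
        for k, (axon, dend) in enumerate(scenes):
            sub = synapses[synapses["pre_id"] == f"pre{k}"]
            if not len(sub):
                continue
            prox = geometry.make_proximity(f"pre{k}", f"post{k}", axon, dend)
            prox = geometry.assign_synapses(sub, prox, axon, dend, radius=3)
            want = set(sub.loc[sub["expected_assigned"], "synapse_id"])
            assert prox.assigned_synapse_ids == want
            assert prox.unassigned_synapse_ids == set(sub["synapse_id"]) - want

    def test_mismatched_ids_rejected(self):
        axon = line(5, compartment="axon")
        dend = line(5, offset=(0, 3, 0))
        prox = geometry.make_proximity("a", "b", axon, dend)
        syn = pd.DataFrame(
            {"synapse_id": [0], "pre_id": ["WRONG"], "post_id": ["b"],
             "x_um": [0.0], "y_um": [3.0], "z_um": [0.0]}
        )
        with pytest.raises(ValueError):
            geometry.assign_synapses(syn, prox, axon, dend)


class TestProjectionType:
    @pytest.mark.parametrize(
        "pre,post,want",
        [("V1", "V1", "V1->V1"), ("AL", "V1", "HVA->V1"), ("V1", "RL", "V1->HVA"),
         ("RL", "AL", "HVA->HVA")],
    )
    def test_labels(self, pre, post, want):
        assert geometry.projection_type(pre, post) == want

    def test_unknown_area_raises(self):
        with pytest.raises(ValueError):
            geometry.projection_type("V2", "V1")


class TestCohorts:
    def build(self):
        neurons = pd.DataFrame(
            {
                "neuron_id": [1, 2, 3, 4, 5, 6],
                "area": ["V1", "V1", "V1", "AL", "V1", "V1"],
                "cc_max": [0.9, 0.9, 0.9, 0.9, 0.3, 0.9],
                "cc_abs": [0.5, 0.5, 0.5, 0.5, 0.5, 0.1],
            }
        )
        pairs = pd.DataFrame(
            {
                "pre_id": [0] * 5,
                "post_id": [2, 3, 4, 5, 6],
                "ld_um": [4.0, 7.0, 0.0, 9.0, 2.0],
                "nsyn": [2, 0, 0, 0, 0],
            }
        )
        return neurons, pairs

    def test_hand_enumeration(self):
        neurons, pairs = self.build()
        out = geometry.build_cohorts(0, neurons, pairs, target_region="V1").set_index("post_id")
        assert out.loc[2, "cohort"] == "connected"
        # Ld > 0, no synapse, same region: ADP takes precedence over same-region
        assert out.loc[3, "cohort"] == "adp_control"
        # Ld = 0, no synapse, HVA area vs V1 target region: excluded
        assert out.loc[4, "cohort"] == "excluded"
        # below CCmax threshold: excluded despite proximity
        assert out.loc[5, "cohort"] == "excluded"
        # below CCabs threshold: excluded
        assert out.loc[6, "cohort"] == "excluded"

    def test_same_region_control(self):
        neurons, pairs = self.build()
        pairs.loc[pairs["post_id"] == 3, "ld_um"] = 0.0
        out = geometry.build_cohorts(0, neurons, pairs, target_region="V1").set_index("post_id")
        assert out.loc[3, "cohort"] == "same_region_control"

    def test_missing_presyn_raises(self):
        neurons, pairs = self.build()
        with pytest.raises(KeyError):
            geometry.build_cohorts(99, neurons, pairs, target_region="V1")
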