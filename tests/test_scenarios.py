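"""Scenario construction: scaled bending, muscle biting, extrinsic loads."""

import numpy as np
import pytest

import craniofea as cf
from craniofea.scenarios import (
    MUSCLE_NODES,
    OCCIPITAL_NODES,
    QUADRATE_NODES,
    MuscleLoad,
    ScenarioError,
    bite_reaction,
    build_bending_scenario,
    build_bite_scenario,
    build_extrinsic_scenario,
    muscle_nodal_loads,
    scaled_bending_forces,
)


def total_magnitude(scenario):
    return sum(np.linalg.norm(f) for _, f in scenario.load_case.point_loads)


class TestScaledBendingForces:
    def test_single_model_gets_baseline(self, toy_skull):
        assert scaled_bending_forces([toy_skull]) == pytest.approx([100.0])

    def test_similarity_family_scales_with_area(self):
        fam = cf.make_similar_family(cf.ToySkullSpec(), [1.0, 2.0])
        np.testing.assert_allclose(
            scaled_bending_forces(fam), [100.0, 400.0], rtol=1e-12
        )

    def test_proportional_to_area(self, toy_skull):
        # areas 10 : 20 : 15 -> forces 100 : 200 : 150
        fam = cf.make_similar_family(
            cf.ToySkullSpec(), [1.0, np.sqrt(2.0), np.sqrt(1.5)]
        )
        np.testing.assert_allclose(
            scaled_bending_forces(fam), [100.0, 200.0, 150.0], rtol=1e-12
        )

    def test_empty_list_rejected(self):
        with pytest.raises(ScenarioError):
            scaled_bending_forces([])


class TestBendingScenario:
    @pytest.mark.parametrize("position", ["anterior", "mid", "posterior"])
    def test_bilateral_layout(self, toy_skull, position):
        scen = build_bending_scenario(toy_skull, position, "bilateral", 100.0)
        assert total_magnitude(scen) == pytest.approx(100.0, rel=1e-9)
        # every load is +Z, split equally
        forces = np.array([f for _, f in scen.load_case.point_loads])
        assert np.all(forces[:, 2] > 0) and np.abs(forces[:, :2]).max() == 0.0
        assert len(set(np.round(forces[:, 2], 12))) == 1
        # 4 + 4 quadrate and 3 occipital nodes, all axes
        assert len(scen.load_case.constraints) == 2 * QUADRATE_NODES + OCCIPITAL_NODES
        assert all(mask == (True, True, True) for _, mask in scen.load_case.constraints)

    def test_unilateral_left_only(self, toy_skull):
        scen = build_bending_scenario(toy_skull, "mid", "unilateral_left", 80.0)
        loaded = {n for n, _ in scen.load_case.point_loads}
        assert loaded == set(int(i) for i in toy_skull.node_sets["palate_mid_L"])
        assert total_magnitude(scen) == pytest.approx(80.0, rel=1e-9)

    def test_zero_force_valid_and_solves_to_zero(self, toy_skull, materials):
        scen = build_bending_scenario(toy_skull, "anterior", "bilateral", 0.0)
        sol = cf.solve(toy_skull, materials, scen.load_case)
        assert sol.strain_energy == 0.0

    def test_missing_set_named(self, toy_skull):
        poor = toy_skull.copy()
        del poor.node_sets["palate_mid_L"]
        with pytest.raises(ScenarioError, match="palate_mid_L"):
            build_bending_scenario(poor, "mid", "bilateral", 1.0)


class TestMuscleLoads:
    def test_equal_division_and_sum(self, toy_skull):
        m = MuscleLoad("mAME", "L", "m_AME_origin_L", (0.0, 10.0, -20.0), 80.0)
        loads = muscle_nodal_loads(m, toy_skull)
        assert len(loads) == MUSCLE_NODES == 8
        mags = [np.linalg.norm(f) for _, f in loads]
        np.testing.assert_allclose(mags, 10.0, rtol=1e-12)
        assert sum(mags) == pytest.approx(m.force, rel=1e-9)

    def test_directions_point_at_insertion(self, toy_skull):
        insertion = np.array([3.0, 7.0, -11.0])
        m = MuscleLoad("mAME", "L", "m_AME_origin_L", tuple(insertion), 16.0)
        for n, f in muscle_nodal_loads(m, toy_skull):
            d = insertion - toy_skull.nodes[n]
            np.testing.assert_allclose(
                f / np.linalg.norm(f), d / np.linalg.norm(d), atol=1e-12
            )

    def test_collinear_origins_resultant_equals_force(self):
        """When all lines of action coincide the vector resultant is the force."""
        beam = cf.make_beam(1.0, 1.0, 8.0, 1, 1, 8)
        # the 9 nodes on the vertical edge x = y = 0 are exactly collinear
        line = np.flatnonzero((beam.nodes[:, 0] == 0.0) & (beam.nodes[:, 1] == 0.0))
        beam.node_sets["origin"] = line
        m = MuscleLoad("m", "L", "origin", (0.0, 0.0, -50.0), 64.0)
        loads = muscle_nodal_loads(m, beam)
        resultant = np.linalg.norm(sum(f for _, f in loads))
        assert resultant == pytest.approx(64.0, rel=1e-12)

    def test_small_origin_set_rejected(self, toy_skull):
        toy = toy_skull.copy()
        toy.node_sets["tiny"] = toy.node_sets["m_AME_origin_L"][:5]
        m = MuscleLoad("m", "L", "tiny", (0, 0, 0), 1.0)
        with pytest.raises(ScenarioError, match="8"):
            muscle_nodal_loads(m, toy)

    def test_coincident_insertion_rejected(self, toy_skull):
        node = toy_skull.node_sets["m_AME_origin_L"][0]
        # move the insertion onto a set node
        m = MuscleLoad(
            "m", "L", "m_AME_origin_L", tuple(toy_skull.nodes[node]), 1.0
        )
        oset = toy_skull.node_sets["m_AME_origin_L"]
        centroid = toy_skull.nodes[oset].mean(axis=0)
        # only raises if the coincident node is among the 8 selected
        dists = np.linalg.norm(toy_skull.nodes[oset] - centroid, axis=1)
        if node in oset[np.argsort(dists)][:8]:
            with pytest.raises(ScenarioError, match="zero-length"):
                muscle_nodal_loads(m, toy_skull)

    def test_selection_deterministic(self, toy_skull):
        m = MuscleLoad("m", "R", "m_AME_origin_R", (5.0, 5.0, -5.0), 8.0)
        a = muscle_nodal_loads(m, toy_skull)
        b = muscle_nodal_loads(m, toy_skull)
        assert [n for n, _ in a] == [n for n, _ in b]
        np.testing.assert_array_equal(
            np.array([f for _, f in a]), np.array([f for _, f in b])
        )


class TestBiteScenario:
    def test_bilateral_counts(self, toy_skull, toy_muscles):
        scen = build_bite_scenario(toy_skull, toy_muscles, "anterior", "bilateral")
        # 2 muscles x 2 sides x 8 nodes loaded
        assert len(scen.load_case.point_loads) == len(toy_muscles) * MUSCLE_NODES
        assert len(scen.bite_nodes) == 2
        z_only = [
            mask for _, mask in scen.load_case.constraints if mask == (False, False, True)
        ]
        assert len(z_only) == 2
        assert scen.total_applied_force == pytest.approx(
            sum(m.force for m in toy_muscles), rel=1e-9
        )

    def test_unilateral_single_bite_node(self, toy_skull, toy_muscles):
        scen = build_bite_scenario(toy_skull, toy_muscles, "mid", "unilateral_left")
        assert len(scen.bite_nodes) == 1
        assert scen.bite_nodes[0] in set(int(i) for i in toy_skull.node_sets["palate_mid_L"])

    def test_no_muscles_zero_energy(self, toy_skull, materials):
        scen = build_bite_scenario(toy_skull, [], "posterior", "bilateral")
        sol = cf.solve(toy_skull, materials, scen.load_case)
        assert sol.strain_energy == 0.0
        assert bite_reaction(sol, scen) == pytest.approx(0.0, abs=1e-12)

    def test_reaction_linearity(self, toy_skull, toy_muscles, materials):
        scen1 = build_bite_scenario(toy_skull, toy_muscles, "anterior", "bilateral")
        doubled = [
            MuscleLoad(m.name, m.side, m.origin_set, m.insertion_point, 2 * m.force)
            for m in toy_muscles
        ]
        scen2 = build_bite_scenario(toy_skull, doubled, "anterior", "bilateral")
        r1 = bite_reaction(cf.solve(toy_skull, materials, scen1.load_case), scen1)
        r2 = bite_reaction(cf.solve(toy_skull, materials, scen2.load_case), scen2)
        assert r1 > 0
        assert r2 == pytest.approx(2 * r1, rel=1e-9)

    def test_block_statics_oracle(self, materials):
        """A vertical muscle ahead of the supports on a block: the bite
        reaction is a statics readout — independent of the stiffness scale
        and carrying a sizeable share of the applied vertical force."""
        beam = cf.make_beam(4.0, 2.0, 2.0, 4, 4, 4)
        nd = beam.nodes
        top = np.flatnonzero(nd[:, 2] == 2.0)
        by_dist = top[
            np.lexsort((top, np.linalg.norm(nd[top, :2] - [0.5, 1.0], axis=1)))
        ]
        beam.node_sets["m_up_origin_L"] = by_dist[:10]
        beam.node_sets["palate_anterior_L"] = np.flatnonzero(
            (nd[:, 2] == 0.0) & (nd[:, 0] == 0.0)
        )
        far = nd[:, 0] == 4.0
        beam.node_sets["quadrate_L"] = np.flatnonzero(
            far & (nd[:, 2] <= 0.5) & (nd[:, 1] < 1.0)
        )
        beam.node_sets["quadrate_R"] = np.flatnonzero(
            far & (nd[:, 2] <= 0.5) & (nd[:, 1] > 1.0)
        )
        beam.node_sets["occipital"] = np.flatnonzero(far & (nd[:, 2] == 2.0))
        centroid = nd[beam.node_sets["m_up_origin_L"]].mean(axis=0)
        insertion = (centroid[0], centroid[1], -1e7)  # far below: straight down
        reactions = []
        for E_scale in (1.0, 100.0):
            mats = {"bone": cf.Material("bone", cf.BONE.E * E_scale, cf.BONE.nu)}
            muscles = [MuscleLoad("m_up", "L", "m_up_origin_L", insertion, 50.0)]
            scen = build_bite_scenario(beam, muscles, "anterior", "unilateral_left")
            sol = cf.solve(beam, mats, scen.load_case)
            reactions.append(bite_reaction(sol, scen))
        assert reactions[0] == pytest.approx(reactions[1], rel=1e-9)
        assert reactions[0] > 5.0


class TestExtrinsicScenarios:
    def test_pull_reactions_balance(self, toy_skull, materials):
        scen = build_extrinsic_scenario(toy_skull, "pull", 100.0)
        sol = cf.solve(toy_skull, materials, scen.load_case)
        assert sol.reactions[:, 1].sum() == pytest.approx(100.0, abs=1e-6)
        assert total_magnitude(scen) == pytest.approx(100.0, rel=1e-9)

    def test_twist_is_pure_couple(self, toy_skull):
        scen = build_extrinsic_scenario(toy_skull, "twist", 60.0)
        net = sum(f for _, f in scen.load_case.point_loads)
        np.testing.assert_allclose(net, 0.0, atol=1e-12)
        assert total_magnitude(scen) == pytest.approx(60.0, rel=1e-9)

    def test_shake_symmetric_field(self, toy_skull, materials):
        """On the mirror-symmetric skull a lateral shake gives an X-mirror-
        symmetric von Mises multiset."""
        scen = build_extrinsic_scenario(toy_skull, "shake", 100.0)
        sol = cf.solve(toy_skull, materials, scen.load_case)
        vm = sol.element_vm
        # mirror elements by matching reflected centroids
        centroids = toy_skull.nodes[toy_skull.elements].mean(axis=1)
        reflected = centroids * [-1, 1, 1]
        order = np.lexsort(centroids.T)
        order_r = np.lexsort(reflected.T)
        np.testing.assert_allclose(vm[order], vm[order_r], rtol=1e-6, atol=1e-12)

    def test_unknown_kind_rejected(self, toy_skull):
        with pytest.raises(ScenarioError):
            build_extrinsic_scenario(toy_skull, "nod", 1.0)


class TestRhamphotheca:
    def test_equal_material_identical_solution(self, toy_skull, materials):
        keratin = cf.Material("keratin", cf.BONE.E, cf.BONE.nu)
        overlaid = cf.apply_rhamphotheca(toy_skull, "beak", keratin)
        mats = dict(materials, keratin=keratin)
        scen = build_bending_scenario(toy_skull, "anterior", "bilateral", 100.0)
        a = cf.solve(toy_skull, materials, scen.load_case)
        b = cf.solve(overlaid, mats, scen.load_case)
        np.testing.assert_allclose(b.element_vm, a.element_vm, rtol=1e-9)

    def test_softer_keratin_reduces_region_stress(self, toy_skull, materials):
        keratin = cf.Material("keratin", 1000.0, 0.30)  # much softer than bone
        overlaid = cf.apply_rhamphotheca(toy_skull, "beak", keratin)
        mats = dict(materials, keratin=keratin)
        scen = build_bending_scenario(toy_skull, "anterior", "bilateral", 100.0)
        region = toy_skull.element_sets["beak"]
        a = cf.solve(toy_skull, materials, scen.load_case)
        b = cf.solve(overlaid, mats, scen.load_case)
        mean_a = cf.trim_top(np.repeat(a.element_vm[region], 4)).mean()
        mean_b = cf.trim_top(np.repeat(b.element_vm[region], 4)).mean()
        assert mean_b < mean_a

    def test_geometry_untouched(self, toy_skull):
        keratin = cf.Material("keratin", 1000.0, 0.3)
        overlaid = cf.apply_rhamphotheca(toy_skull, "beak", keratin)
        np.testing.assert_array_equal(overlaid.nodes, toy_skull.nodes)
        np.testing.assert_array_equal(overlaid.elements, toy_skull.elements)
        assert set(np.asarray(overlaid.element_material)) >= {"keratin"}

    def test_empty_region_rejected(self, toy_skull):
        with pytest.raises(ScenarioError):
            cf.apply_rhamphotheca(toy_skull, np.array([], dtype=int), cf.BONE)
        with pytest.raises(ScenarioError):
            cf.apply_rhamphotheca(toy_skull, "no_such_set", cf.BONE)


class TestBilateralSymmetry:
    def test_bilateral_bending_mirror_symmetric(self, toy_skull, materials):
        scen = build_bending_scenario(toy_skull, "anterior", "bilateral", 100.0)
        sol = cf.solve(toy_skull, materials, scen.load_case)
        centroids = toy_skull.nodes[toy_skull.elements].mean(axis=1)
        order = np.lexsort(centroids.T)
        order_r = np.lexsort((centroids * [-1, 1, 1]).T)
        np.testing.assert_allclose(
            sol.element_vm[order], sol.element_vm[order_r], rtol=1e-6, atol=1e-12
        )

    def test_unilateral_loads_left_side_harder(self, toy_skull, materials):
        """Unilateral loading breaks symmetry: the loaded (left) half's
        trimmed mean exceeds the right half's."""
        scen = build_bending_scenario(toy_skull, "mid", "unilateral_left", 100.0)
        sol = cf.solve(toy_skull, materials, scen.load_case)
        centroids = toy_skull.nodes[toy_skull.elements].mean(axis=1)
        left = centroids[:, 0] < 0
        right = centroids[:, 0] > 0
        mean_left = cf.trim_top(np.repeat(sol.element_vm[left], 4)).mean()
        mean_right = cf.trim_top(np.repeat(sol.element_vm[right], 4)).mean()
        assert mean_left > mean_right
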