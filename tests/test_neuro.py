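"""Pyramidal-cell growth: initializer, growth rules, morphometrics, SWC."""

import numpy as np
import pytest

from biodyn import neuro
from biodyn.engine import Simulation, SimulationParams
from biodyn.fields import GaussianField
from biodyn.neuro import (APICAL, BASAL, GrowthParams, NeuriteElement,
                          NeuriteGrowthParams, PyramidalCellInit,
                          build_pyramidal_simulation, extract_morphology,
                          growth_direction, init_pyramidal_cell, morphometrics,
                          population_morphometrics, swc_export, swc_import)


def bare_sim(seed=0):
    return Simulation(SimulationParams(
        rng_seed=seed, bounds=((-500, -500, -500), (500, 500, 500))))


def straight_growth(kind_overrides=None, **common):
    """Growth parameters with no randomness and no branching by default."""
    defaults = dict(w_gradient=0.0, w_previous=1.0, w_random=0.0, p_branch=0.0,
                    taper=0.0, elongation_speed=1.0)
    defaults.update(common)
    apical = GrowthParams(**{**defaults, "initial_diameter": 2.0,
                             **(kind_overrides or {}).get(APICAL, {})})
    basal = GrowthParams(**{**defaults, "initial_diameter": 1.5,
                            **(kind_overrides or {}).get(BASAL, {})})
    return NeuriteGrowthParams(apical=apical, basal=basal)


class TestInitializer:
    def test_agent_counts_and_kinds(self):
        sim = bare_sim()
        soma = init_pyramidal_cell(sim, (0, 0, 0))
        assert len(sim.population) == 5  # soma + 4 dendritic stubs
        kinds = [sim.population[i].kind for i in soma.daughter_ids]
        assert kinds.count(APICAL) == 1
        assert kinds.count(BASAL) == 3

    def test_initial_lengths_and_soma_diameter(self):
        sim = bare_sim()
        soma = init_pyramidal_cell(sim, (0, 0, 0))
        assert soma.diameter == 10.0
        for eid in soma.daughter_ids:
            assert sim.population[eid].length == pytest.approx(0.5)

    def test_apical_points_up_basal_down(self):
        sim = bare_sim()
        soma = init_pyramidal_cell(sim, (0, 0, 0))
        for eid in soma.daughter_ids:
            el = sim.population[eid]
            if el.kind == APICAL:
                np.testing.assert_allclose(el.direction, [0, 0, 1], atol=1e-12)
            else:
                assert el.direction[2] < 0


class TestGrowthDirection:
    def tip(self, direction=(0, 0, 1)):
        sim = bare_sim()
        el = NeuriteElement(APICAL, (0, 0, 0), np.asarray(direction, float),
                            2.0, parent_id=0)
        return el, sim

    def test_pure_persistence_is_straight(self):
        el, sim = self.tip((0, 1, 0))
        params = GrowthParams(w_gradient=0.0, w_previous=1.0, w_random=0.0)
        d = growth_direction(el, None, params, sim.rng)
        np.testing.assert_allclose(d, [0, 1, 0], atol=1e-12)

    def test_pure_gradient_points_to_cue(self):
        el, sim = self.tip((1, 0, 0))
        cue = GaussianField("c", amplitude=1.0, axis="z", mean=100.0, sigma=50.0)
        params = GrowthParams(w_gradient=1.0, w_previous=0.0, w_random=1e-12)
        d = growth_direction(el, cue, params, sim.rng)
        np.testing.assert_allclose(d, [0, 0, 1], atol=1e-6)

    def test_unit_norm(self):
        el, sim = self.tip()
        cue = GaussianField("c", amplitude=1.0, axis="z", mean=10.0, sigma=5.0)
        params = GrowthParams(w_gradient=1.0, w_previous=1.0, w_random=1.0)
        for _ in range(10):
            d = growth_direction(el, cue, params, sim.rng)
            assert np.linalg.norm(d) == pytest.approx(1.0, abs=1e-12)


class TestElongationAndTaper:
    def grow(self, growth, n_steps, seed=0):
        sim = bare_sim(seed)
        soma = init_pyramidal_cell(sim, (0, 0, 0), growth=growth)
        sim.run(n_steps)
        return sim, soma

    def test_total_length_exact_without_taper(self):
        """Each step adds exactly speed*dt of dendrite per active tip."""
        n = 40
        growth = straight_growth()
        sim, soma = self.grow(growth, n)
        per_tree = morphometrics(extract_morphology(sim, soma))
        for _, row in per_tree.iterrows():
            speed = growth.for_kind(row["tree_kind"]).elongation_speed
            assert row["total_length_um"] == pytest.approx(0.5 + n * speed * 1.0,
                                                           rel=1e-9)
        assert per_tree["n_branch_points"].sum() == 0

    def test_straight_growth_collinear(self):
        sim, soma = self.grow(straight_growth(), 30)
        morphology = extract_morphology(sim, soma)
        for root in morphology.roots():
            # collect the chain and check all points lie on the root line
            origin = morphology.elements[root].proximal
            axis = morphology.elements[root].distal - origin
            axis /= np.linalg.norm(axis)
            node = root
            while True:
                el = morphology.elements[node]
                offset = el.distal - origin
                cross = np.linalg.norm(np.cross(offset, axis))
                assert cross < 1e-9
                if not el.daughter_ids:
                    break
                node = el.daughter_ids[0]

    def test_taper_floor_halts_growth_permanently(self):
        growth = straight_growth(taper=0.2)  # diameter hits floor quickly
        sim, soma = self.grow(growth, 60)
        morphology = extract_morphology(sim, soma)
        lengths = {r: morphometrics(morphology)["total_length_um"].sum()
                   for r in [0]}
        total_before = morphometrics(morphology)["total_length_um"].sum()
        sim.run(20)
        total_after = morphometrics(extract_morphology(sim, soma))["total_length_um"].sum()
        assert total_after == pytest.approx(total_before, rel=1e-12)
        for el in morphology.elements.values():
            assert el.diameter >= growth.for_kind(el.kind).min_diameter - 1e-12

    def test_diameter_monotone_along_paths(self):
        growth = straight_growth(taper=0.02)
        growth.apical.p_branch = 0.05
        growth.basal.p_branch = 0.05
        growth.apical.w_random = 0.3
        growth.basal.w_random = 0.3
        sim, soma = self.grow(growth, 80, seed=3)
        morphology = extract_morphology(sim, soma)
        for el in morphology.elements.values():
            for did in el.daughter_ids:
                assert morphology.elements[did].diameter <= el.diameter + 1e-12


class TestBranching:
    def test_no_branching_keeps_paths(self):
        sim = bare_sim()
        soma = init_pyramidal_cell(sim, (0, 0, 0), growth=straight_growth())
        sim.run(50)
        per_tree = morphometrics(extract_morphology(sim, soma))
        assert per_tree["n_branch_points"].sum() == 0

    def test_certain_branching_makes_two_daughters(self):
        growth = straight_growth()
        growth.apical.p_branch = 1.0
        growth.basal.p_branch = 1.0
        sim = bare_sim()
        soma = init_pyramidal_cell(sim, (0, 0, 0), growth=growth)
        stubs = list(soma.daughter_ids)
        sim.step_once()
        for eid in stubs:
            el = sim.population[eid]
            assert len(el.daughter_ids) == 2
            assert not el.is_terminal
            for did in el.daughter_ids:
                daughter = sim.population[did]
                assert daughter.is_terminal
                ratio = growth.for_kind(el.kind).branch_diameter_ratio
                assert daughter.diameter == pytest.approx(ratio * el.diameter)
                # growth behavior was inherited by the daughters
                assert any(b.name == "neurite_growth" for b in daughter.behaviors)
            assert not any(b.name == "neurite_growth" for b in el.behaviors)

    def test_branch_angle_symmetric_about_parent_direction(self):
        growth = straight_growth()
        growth.apical.p_branch = 1.0
        growth.apical.branch_angle_deg = 40.0
        sim = bare_sim()
        soma = init_pyramidal_cell(sim, (0, 0, 0), growth=growth)
        apical = next(sim.population[i] for i in soma.daughter_ids
                      if sim.population[i].kind == APICAL)
        parent_dir = apical.direction
        sim.step_once()
        angles = []
        for did in apical.daughter_ids:
            d = sim.population[did].direction
            angles.append(np.degrees(np.arccos(np.clip(np.dot(d, parent_dir), -1, 1))))
        assert angles[0] == pytest.approx(20.0, abs=1e-6)
        assert angles[1] == pytest.approx(20.0, abs=1e-6)


class TestTreeIntegrity:
    def test_connectivity_after_growth(self):
        sim, somas = build_pyramidal_simulation(1, seed=5)
        sim.run(120)
        morphology = extract_morphology(sim, somas[0])
        for eid, el in morphology.elements.items():
            if el.parent_id is not None:
                parent = morphology.elements[el.parent_id]
                np.testing.assert_allclose(el.proximal, parent.distal, atol=1e-9)

    def test_different_seeds_differ(self):
        lengths = []
        for seed in (0, 1):
            sim, somas = build_pyramidal_simulation(1, seed=seed)
            sim.run(80)
            lengths.append(morphometrics(
                extract_morphology(sim, somas[0]))["total_length_um"].sum())
        assert lengths[0] != lengths[1]

    def test_apical_outgrows_basal_along_z(self):
        """Stronger apical gradient-following pushes the apical tree further
        along +z than any basal tree (population level)."""
        wins = 0
        n_seeds = 12
        for seed in range(n_seeds):
            sim, somas = build_pyramidal_simulation(1, seed=seed)
            sim.run(100)
            morphology = extract_morphology(sim, somas[0])
            extents = {}
            for root in morphology.roots():
                stack, top = [root], -np.inf
                while stack:
                    el = morphology.elements[stack.pop()]
                    top = max(top, el.distal[2])
                    stack.extend(el.daughter_ids)
                extents.setdefault(morphology.elements[root].kind, []).append(top)
            if extents[APICAL][0] > max(extents[BASAL]):
                wins += 1
        assert wins >= n_seeds - 1


class TestMorphometrics:
    def chain(self, morphology_cls=None):
        sim = bare_sim()
        soma = init_pyramidal_cell(
            sim, (0, 0, 0),
            init=PyramidalCellInit(n_basal=0, n_apical=1),
            growth=straight_growth())
        sim.run(9)  # stub 0.5 + 9 steps
        return sim, soma

    def test_unbranched_chain(self):
        sim, soma = self.chain()
        per_tree = morphometrics(extract_morphology(sim, soma))
        assert len(per_tree) == 1
        assert per_tree["n_branch_points"].iloc[0] == 0
        assert per_tree["total_length_um"].iloc[0] == pytest.approx(9.5)

    def test_hand_built_two_level_binary_tree(self):
        """Root bifurcates, both daughters bifurcate: 3 branch points."""
        from biodyn.neuro import CellMorphology, NeuriteRecord

        m = CellMorphology(np.zeros(3), 10.0)

        def add(idx, parent, proximal, distal):
            m.elements[idx] = NeuriteRecord(APICAL, np.array(proximal, float),
                                            np.array(distal, float), 1.0, parent)

        add(1, None, (0, 0, 0), (0, 0, 1))
        add(2, 1, (0, 0, 1), (1, 0, 2)); add(3, 1, (0, 0, 1), (-1, 0, 2))
        add(4, 2, (1, 0, 2), (2, 0, 3)); add(5, 2, (1, 0, 2), (0, 0, 3))
        add(6, 3, (-1, 0, 2), (-2, 0, 3)); add(7, 3, (-1, 0, 2), (0, 0, 3))
        for idx, el in m.elements.items():
            if el.parent_id is not None:
                m.elements[el.parent_id].daughter_ids.append(idx)
        per_tree = morphometrics(m)
        assert per_tree["n_branch_points"].iloc[0] == 3
        expected_length = 1.0 + 6 * np.sqrt(2.0)
        assert per_tree["total_length_um"].iloc[0] == pytest.approx(expected_length)

    def test_population_average_of_identical_cells(self):
        sim, soma = self.chain()
        m = extract_morphology(sim, soma)
        pop = population_morphometrics([m, m])
        assert pop["mean_tree_length_um"].nunique() == 1
        assert pop["mean_tree_length_um"].iloc[0] == pytest.approx(9.5)

    def test_cycle_detection(self):
        from biodyn.neuro import CellMorphology, NeuriteRecord

        m = CellMorphology(np.zeros(3), 10.0)
        m.elements[1] = NeuriteRecord(APICAL, np.zeros(3), np.ones(3), 1.0, 2, [2])
        m.elements[2] = NeuriteRecord(APICAL, np.ones(3), np.zeros(3), 1.0, 1, [1])
        with pytest.raises(ValueError, match="cycle|orphan"):
            morphometrics(m)


class TestSwc:
    def grown_cell(self, seed=7, steps=60):
        sim, somas = build_pyramidal_simulation(1, seed=seed)
        sim.run(steps)
        return extract_morphology(sim, somas[0])

    def test_single_soma_export(self):
        from biodyn.neuro import CellMorphology

        text = swc_export(CellMorphology(np.array([1.0, 2.0, 3.0]), 10.0))
        rows = [l for l in text.splitlines() if not l.startswith("#")]
        assert rows == ["1 1 1.000000 2.000000 3.000000 5.000000 -1"]

    def test_round_trip_byte_identical(self):
        m = self.grown_cell()
        text1 = swc_export(m)
        text2 = swc_export(swc_import(text1))
        assert text1 == text2

    def test_round_trip_preserves_morphometrics(self):
        m = self.grown_cell(seed=11)
        a = morphometrics(m).sort_values("tree_kind").reset_index(drop=True)
        b = morphometrics(swc_import(swc_export(m))) \
            .sort_values("tree_kind").reset_index(drop=True)
        np.testing.assert_allclose(a["total_length_um"], b["total_length_um"],
                                   rtol=1e-6)
        assert list(a["n_branch_points"]) == list(b["n_branch_points"])

    def test_missing_parent_rejected(self):
        text = ("1 1 0 0 0 5 -1\n"
                "2 4 0 0 1 1 9\n")
        with pytest.raises(ValueError, match="parent 9"):
            swc_import(text)
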