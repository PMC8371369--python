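"""Repeatable-superimposing merges, unit steps, propagation, two paths."""

import numpy as np
import pytest

import rrmagg as r
from rrmagg.assembly import (ClashError, IncompatibilityError, clash_census,
                             unit_step_transform)
from rrmagg.superpose import kabsch


@pytest.fixture(scope="module")
def dimer(monomer_and_annotation):
    m, ann = monomer_and_annotation
    return r.make_dimer_for_mode(m, ann, "shoulder12-β", "shoulder12-β")[0]


@pytest.fixture(scope="module")
def step():
    # screw axis well outside the dimer so consecutive units never collide
    return r.RigidTransform.about_axis(25.0, [0, 0, 1], point=[60.0, 0.0, 0.0],
                                       translation=[0.0, 0.0, 15.0])


@pytest.fixture(scope="module")
def tetramers(dimer, step):
    return r.make_periodic_tetramers(dimer, step)


class TestSuperimposeMerge:
    def test_periodic_merge_extends_by_one_unit(self, tetramers):
        tet_a, tet_b = tetramers
        merged = r.superimpose_merge(tet_a, tet_b,
                                     r.MergeSpec(shared_unit_in_a=1, shared_unit_in_b=0))
        assert len(merged) == 3
        s12 = unit_step_transform(merged, 0, 1)
        s23 = unit_step_transform(merged, 1, 2)
        assert np.abs(s12.rotation - s23.rotation).max() < 1e-6
        assert np.abs(s12.translation - s23.translation).max() < 1e-6

    def test_full_overlap_deduplicates_to_original(self, tetramers):
        tet_a, _ = tetramers
        merged = r.superimpose_merge(tet_a, tet_a.copy(),
                                     r.MergeSpec(shared_unit_in_a=0, shared_unit_in_b=0))
        assert len(merged) == len(tet_a)
        for got, want in zip(merged.units, tet_a.units):
            assert np.abs(got.coords - want.coords).max() < 1e-9

    def test_incompatible_shared_units_rejected(self, tetramers):
        tet_a, tet_b = tetramers
        rng = np.random.default_rng(0)
        noisy_first = tet_b.units[0].with_coords(
            tet_b.units[0].coords + rng.normal(0, 5.0, (len(tet_b.units[0]), 3)))
        noisy = r.Assembly([noisy_first, tet_b.units[1]], list(tet_b.unit_labels))
        with pytest.raises(IncompatibilityError):
            r.superimpose_merge(tet_a, noisy,
                                r.MergeSpec(shared_unit_in_a=1, shared_unit_in_b=0,
                                            dedup_rmsd_tol=0.5))

    def test_merge_logs_transform_and_rmsd(self, tetramers):
        tet_a, tet_b = tetramers
        merged = r.superimpose_merge(tet_a, tet_b,
                                     r.MergeSpec(shared_unit_in_a=1, shared_unit_in_b=0))
        entry = merged.transform_log()[-1]
        assert entry["op"] == "superimpose_merge"
        assert entry["shared_rmsd"] < 1e-6


class TestUnitStep:
    def test_identity_on_same_unit(self, tetramers):
        tet_a, _ = tetramers
        t = unit_step_transform(tet_a, 0, 0)
        assert np.allclose(t.rotation, np.eye(3)) and np.allclose(t.translation, 0)

    def test_reverse_direction_is_inverse(self, tetramers):
        tet_a, _ = tetramers
        fwd = unit_step_transform(tet_a, 0, 1)
        back = unit_step_transform(tet_a, 1, 0)
        comp = fwd.compose(back)
        assert np.abs(comp.rotation - np.eye(3)).max() < 1e-9
        assert np.abs(comp.translation).max() < 1e-9

    def test_recovers_constructed_step(self, tetramers, step):
        tet_a, _ = tetramers
        got = unit_step_transform(tet_a, 0, 1)
        assert np.abs(got.rotation - step.rotation).max() < 1e-9
        assert np.abs(got.translation - step.translation).max() < 1e-9


class TestPropagate:
    def test_single_unit_is_the_seed(self, dimer, step):
        asm = r.propagate(dimer, step, 1)
        assert len(asm) == 1
        assert np.abs(asm.units[0].coords - dimer.coords).max() == 0.0

    def test_periodicity_of_consecutive_steps(self, dimer, step):
        asm = r.propagate(dimer, step, 6)
        steps = [unit_step_transform(asm, i, i + 1) for i in range(5)]
        for s in steps[1:]:
            assert np.abs(s.rotation - steps[0].rotation).max() < 1e-6
            assert np.abs(s.translation - steps[0].translation).max() < 1e-6

    def test_round_trip_recovers_input_screw(self, dimer, step):
        asm = r.propagate(dimer, step, 4)
        got = r.screw_decompose(unit_step_transform(asm, 0, 1))
        want = r.screw_decompose(step)
        assert got.angle == pytest.approx(want.angle, abs=1e-6)
        assert got.rise == pytest.approx(want.rise, abs=1e-6)

    def test_pure_translation_gives_collinear_centroids(self, dimer):
        # rise exceeds the unit's z-extent so non-adjacent units stay clear
        t = r.RigidTransform(np.eye(3), np.array([0.0, 0.0, 45.0]))
        asm = r.propagate(dimer, t, 12)
        log = asm.transform_log()[0]
        assert log["twist_per_unit_deg"] == 0.0
        assert log["clashes"] == 0
        centroids = np.array([u.coords.mean(axis=0) for u in asm.units])
        spans = np.diff(centroids, axis=0)
        assert np.abs(spans - spans[0]).max() < 1e-9

    def test_self_intersection_reported_as_clash(self, dimer):
        # 120° twist with zero rise closes onto the first unit at unit 4
        t = r.RigidTransform.about_axis(120.0, [0, 0, 1], point=[60.0, 0.0, 0.0])
        with pytest.raises(ClashError):
            r.propagate(dimer, t, 4)

    def test_screw_closure_decamer_full_turn(self, dimer):
        """A 36°/8 Å step completes one turn: unit 11 sits directly above
        unit 1, displaced by ten rises along the aggregation axis."""
        t = r.RigidTransform.about_axis(36.0, [0, 0, 1], point=[80.0, 0.0, 0.0],
                                        translation=[0.0, 0.0, 8.0])
        asm = r.propagate(dimer, t, 11, on_clash="ignore")
        lifted = asm.units[0].coords + np.array([0.0, 0.0, 80.0])
        assert np.abs(asm.units[10].coords - lifted).max() < 1e-6


class TestTwoPathBuild:
    def test_paths_produce_congruent_octamers(self, tetramers):
        tet_a, tet_b = tetramers
        oct1 = r.two_path_build(tet_a, tet_b, path=1, target_units=4)
        oct2 = r.two_path_build(tet_a, tet_b, path=2, target_units=4)
        assert len(oct1) == len(oct2) == 4
        _, val = kabsch(oct2.to_structure().coords, oct1.to_structure().coords)
        assert val < 0.1

    def test_target_equal_to_seed_returns_input(self, tetramers):
        tet_a, tet_b = tetramers
        out = r.two_path_build(tet_a, tet_b, path=1, target_units=2)
        assert np.abs(out.to_structure().coords
                      - tet_a.to_structure().coords).max() == 0.0

    def test_non_overlappable_tetramers_rejected(self, tetramers, dimer, step):
        tet_a, _ = tetramers
        rng = np.random.default_rng(1)
        shifted = r.RigidTransform(np.eye(3), np.array([500.0, 0, 0]))
        far = r.Assembly([shifted.apply_structure(u) for u in tet_a.units])
        jumbled_first = far.units[0].with_coords(
            far.units[0].coords + rng.normal(0, 4.0, (len(far.units[0]), 3)))
        bad = r.Assembly([jumbled_first, far.units[1]])
        with pytest.raises(IncompatibilityError):
            r.two_path_build(tet_a, bad, path=1, target_units=4,
                             dedup_rmsd_tol=0.5)

    def test_dodecamer_growth_stays_periodic(self, tetramers):
        tet_a, tet_b = tetramers
        dodeca = r.two_path_build(tet_a, tet_b, path=1, target_units=6)
        assert len(dodeca) == 6
        steps = [unit_step_transform(dodeca, i, i + 1) for i in range(5)]
        for s in steps[1:]:
            assert np.abs(s.rotation - steps[0].rotation).max() < 1e-6
        assert clash_census(dodeca, 2.5) == 0


class TestAggregationAxisGeometry:
    def test_layer_normal_stays_perpendicular_to_screw_axis(
            self, monomer_and_annotation):
        """For a seed whose β-layer plane contains the screw axis direction,
        the layer normal remains perpendicular to the aggregation axis at
        every propagated unit (cross-β-like geometry)."""
        m, ann = monomer_and_annotation
        dimer, dann = r.make_dimer(m, ann, r.RigidTransform(
            np.eye(3), np.array([0.0, -17.9, 0.0])))
        step = r.RigidTransform.about_axis(25.0, [0, 0, 1], point=[60.0, 0.0, 0.0],
                                           translation=[0.0, 0.0, 45.0])
        axis = r.screw_decompose(step).axis_direction  # +z
        # toy layer lies in the y=0 plane → normal ±y ⊥ z by construction
        asm = r.propagate(dimer, step, 6)
        for unit in asm.units:
            ca = np.array([a.coords for a in unit.atoms
                           if a.chain_id == "A" and a.name == "CA"
                           and ann.sse_of("A", a.res_id).startswith("β")
                           and ann.domain_of("A", a.res_id) == "RRM1"])
            centered = ca - ca.mean(axis=0)
            _, _, Vt = np.linalg.svd(centered)
            normal = Vt[-1]  # least-variance direction = layer normal
            angle = r.interhelix_angle(normal, axis)
            assert abs(angle - 90.0) < 2.0
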