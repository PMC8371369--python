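"""Interaction criteria, boundary behaviour, and occupancy bookkeeping."""

import numpy as np
import pytest

import rrmagg as r
from tests.conftest import tiny_planted_structure


def _hbond_frame(da: float, angle: float) -> r.Structure:
    """Gln donor / Asn acceptor pair at an exact D–A distance and D–H–A angle."""
    from rrmagg.synthetic import _hbond_proton_position

    d = np.zeros(3)
    a = np.array([da, 0.0, 0.0])
    h = _hbond_proton_position(d, a, angle)
    atoms = [
        r.AtomRecord(1, "CA", "C", "GLN", 1, "A", (0.0, 2.0, 0.0)),
        r.AtomRecord(2, "NE2", "N", "GLN", 1, "A", tuple(d)),
        r.AtomRecord(3, "HE21", "H", "GLN", 1, "A", tuple(h)),
        r.AtomRecord(4, "CA", "C", "ASN", 1, "B", (da, 2.0, 0.0)),
        r.AtomRecord(5, "OD1", "O", "ASN", 1, "B", tuple(a)),
    ]
    return r.Structure(atoms)


def _pair_structure(res_a, atom_a, elem_a, res_b, atom_b, elem_b, distance):
    atoms = [
        r.AtomRecord(1, "CA", "C", res_a, 1, "A", (0.0, 5.0, 0.0)),
        r.AtomRecord(2, atom_a, elem_a, res_a, 1, "A", (0.0, 0.0, 0.0)),
        r.AtomRecord(3, "CA", "C", res_b, 1, "B", (distance, 5.0, 0.0)),
        r.AtomRecord(4, atom_b, elem_b, res_b, 1, "B", (distance, 0.0, 0.0)),
    ]
    return r.Structure(atoms)


def _whole(structure):
    return r.Selection(tuple(range(len(structure))))


class TestHbondCriterion:
    @pytest.mark.parametrize("da,angle,expected", [
        (3.4, 150.0, True),   # inside both criteria
        (3.6, 150.0, False),  # distance fails
        (3.4, 110.0, False),  # angle fails
        (3.5, 150.0, False),  # boundary: strict < on distance (3.5 is exact)
        (3.499, 120.5, True),
    ])
    def test_criterion_boundaries(self, da, angle, expected):
        frame = _hbond_frame(da, angle)
        sel_a = r.select(frame, "chain A")
        sel_b = r.select(frame, "chain B")
        events = r.find_hbonds(frame, sel_a, sel_b)
        assert (len(events) == 1) is expected

    def test_exclusion_at_exact_angle_equality(self):
        """A D–H–A angle exactly equal to the threshold is excluded (strict >)."""
        frame = _hbond_frame(3.4, 140.0)
        atom = {a.name: np.asarray(a.coords) for a in frame.atoms}
        hd = atom["NE2"] - atom["HE21"]
        ha = atom["OD1"] - atom["HE21"]
        realized = float(np.degrees(np.arccos(
            (hd @ ha) / (np.linalg.norm(hd) * np.linalg.norm(ha)))))
        sel_a = r.select(frame, "chain A")
        sel_b = r.select(frame, "chain B")
        at_equality = r.CriteriaConfig(hbond_dha_min=realized)
        assert r.find_hbonds(frame, sel_a, sel_b, at_equality) == []
        just_below = r.CriteriaConfig(hbond_dha_min=realized - 1e-9)
        assert len(r.find_hbonds(frame, sel_a, sel_b, just_below)) == 1

    def test_donor_without_proton_warns_and_skips(self):
        frame = _hbond_frame(3.4, 150.0)
        frame = r.Structure([a for a in frame.atoms if a.name != "HE21"])
        with pytest.warns(UserWarning, match="no attached proton"):
            events = r.find_hbonds(frame, r.select(frame, "chain A"),
                                   r.select(frame, "chain B"))
        assert events == []

    def test_equivalent_protons_collapse_to_one_wildcard_event(self):
        # Lys NZ with three protons, two of them satisfying the angle
        d = np.zeros(3)
        a = np.array([3.2, 0.0, 0.0])
        atoms = [
            r.AtomRecord(1, "CA", "C", "LYS", 1, "A", (0.0, 2.0, 0.0)),
            r.AtomRecord(2, "NZ", "N", "LYS", 1, "A", tuple(d)),
            r.AtomRecord(3, "HZ1", "H", "LYS", 1, "A", (1.0, 0.05, 0.0)),
            r.AtomRecord(4, "HZ2", "H", "LYS", 1, "A", (0.9, -0.3, 0.2)),
            r.AtomRecord(5, "HZ3", "H", "LYS", 1, "A", (-0.8, 0.5, 0.0)),
            r.AtomRecord(6, "CA", "C", "ASN", 1, "B", (3.2, 2.0, 0.0)),
            r.AtomRecord(7, "OD1", "O", "ASN", 1, "B", tuple(a)),
        ]
        frame = r.Structure(atoms)
        events = r.find_hbonds(frame, r.select(frame, "chain A"),
                               r.select(frame, "chain B"))
        assert len(events) == 1
        assert events[0].partner_a[3] == "NZ-HZ*"


class TestHydrophobicCriterion:
    @pytest.mark.parametrize("dist,expected", [
        (4.4, True), (4.6, False), (4.5, False)])  # strict < at the boundary
    def test_cc_distance_boundary(self, dist, expected):
        frame = _pair_structure("LEU", "CD1", "C", "PHE", "CZ", "C", dist)
        events = r.find_hydrophobic(frame, r.select(frame, "chain A"),
                                    r.select(frame, "chain B"))
        assert (len(events) == 1) is expected

    def test_polar_residues_and_backbone_carbons_excluded(self):
        # Ser is not apolar; a backbone carbonyl C is not a side-chain carbon
        polar = _pair_structure("SER", "CB", "C", "PHE", "CZ", "C", 4.0)
        assert r.find_hydrophobic(polar, r.select(polar, "chain A"),
                                  r.select(polar, "chain B")) == []
        backbone = _pair_structure("LEU", "CD1", "C", "PHE", "C", "C", 4.0)
        assert r.find_hydrophobic(backbone, r.select(backbone, "chain A"),
                                  r.select(backbone, "chain B")) == []

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(8)
        atoms = []
        for i in range(25):
            atoms.append(r.AtomRecord(i + 1, "CD1", "C", "LEU", i + 1, "A",
                                      tuple(rng.uniform(0, 12, 3))))
        for i in range(25):
            atoms.append(r.AtomRecord(26 + i, "CZ", "C", "PHE", i + 1, "B",
                                      tuple(rng.uniform(0, 12, 3))))
        frame = r.Structure(atoms)
        sel_a = r.select(frame, "chain A")
        sel_b = r.select(frame, "chain B")
        events = r.find_hydrophobic(frame, sel_a, sel_b)
        got = {(e.partner_a[1], e.partner_b[1]) for e in events}
        coords = frame.coords
        expected = set()
        for i in range(25):
            for j in range(25, 50):
                if np.linalg.norm(coords[i] - coords[j]) < 4.5:
                    expected.add((frame.atoms[i].res_id, frame.atoms[j].res_id))
        assert got == expected


class TestIonicCriterion:
    @pytest.mark.parametrize("dist,expected", [
        (4.8, True), (5.2, False), (5.0, False)])  # strict < at the boundary
    def test_hn_to_carboxylate_boundary(self, dist, expected):
        atoms = [
            r.AtomRecord(1, "CA", "C", "LYS", 1, "A", (0.0, 3.0, 0.0)),
            r.AtomRecord(2, "NZ", "N", "LYS", 1, "A", (-1.0, 0.0, 0.0)),
            r.AtomRecord(3, "HZ1", "H", "LYS", 1, "A", (0.0, 0.0, 0.0)),
            r.AtomRecord(4, "CA", "C", "GLU", 2, "B", (dist, 3.0, 0.0)),
            r.AtomRecord(5, "OE1", "O", "GLU", 2, "B", (dist, 0.0, 0.0)),
        ]
        events = r.find_ionic(r.Structure(atoms))
        assert (len(events) == 1) is expected

    def test_like_charges_never_interact(self):
        atoms = [
            r.AtomRecord(1, "OD1", "O", "ASP", 1, "A", (0.0, 0.0, 0.0)),
            r.AtomRecord(2, "OE1", "O", "GLU", 2, "B", (3.0, 0.0, 0.0)),
        ]
        assert r.find_ionic(r.Structure(atoms)) == []

    def test_missing_protons_fall_back_to_n_with_flag(self):
        atoms = [
            r.AtomRecord(1, "NZ", "N", "LYS", 1, "A", (0.0, 0.0, 0.0)),
            r.AtomRecord(2, "OD1", "O", "ASP", 2, "B", (4.0, 0.0, 0.0)),
        ]
        with pytest.warns(UserWarning, match="falls back"):
            events = r.find_ionic(r.Structure(atoms))
        assert len(events) == 1 and events[0].approximate


class TestOccupancy:
    def _ensemble_with_presence(self, present_frames, n_frames):
        base = tiny_planted_structure()
        xyz = np.repeat(base.coords[None], n_frames, axis=0)
        off_idx = [i for i, a in enumerate(base.atoms) if a.name == "OD1"][0]
        for k in range(n_frames):
            if k not in present_frames:
                xyz[k, off_idx] += np.array([6.0, 0.0, 0.0])
        return r.StructureEnsemble(base, xyz)

    def test_84_of_100_frames_gives_84_percent(self):
        ens = self._ensemble_with_presence(set(range(84)), 100)
        totals = r.occupancy_scan(ens, r.CriteriaConfig(),
                                  (r.select(ens.topology, "chain A"),
                                   r.select(ens.topology, "chain B")),
                                  min_occupancy=0.0)
        assert [e.occupancy for e in totals.events] == [84.0]

    def test_single_frame_occupancies_are_all_or_nothing(self):
        ens = self._ensemble_with_presence({0}, 1)
        totals = r.occupancy_scan(ens, r.CriteriaConfig(),
                                  (r.select(ens.topology, "chain A"),
                                   r.select(ens.topology, "chain B")),
                                  min_occupancy=0.0)
        assert all(e.occupancy in (0.0, 100.0) for e in totals.events)

    def test_invariant_under_frame_reordering(self):
        ens = self._ensemble_with_presence(set(range(0, 60, 2)), 60)
        perm = np.random.default_rng(3).permutation(60)
        shuffled = r.StructureEnsemble(ens.topology, ens.xyz[perm])
        args = (r.CriteriaConfig(),
                (r.select(ens.topology, "chain A"), r.select(ens.topology, "chain B")))
        a = r.occupancy_scan(ens, *args, min_occupancy=0.0)
        b = r.occupancy_scan(shuffled, *args, min_occupancy=0.0)
        assert [(e.key, e.occupancy) for e in a.events] == \
               [(e.key, e.occupancy) for e in b.events]

    def test_bernoulli_occupancy_converges(self):
        """Planted Bernoulli(p) presence recovered within 1.5% at 10^4 frames."""
        p = 0.7
        base = tiny_planted_structure(p=p)
        ens, manifest = r.make_ensemble(base, r.NoiseModel(sigma=0.0), 10_000, seed=13)
        totals = r.occupancy_scan(ens, r.CriteriaConfig(),
                                  (r.select(ens.topology, "chain A"),
                                   r.select(ens.topology, "chain B")),
                                  min_occupancy=0.0)
        hb = [e for e in totals.events if e.kind == "hbond"]
        assert len(hb) == 1
        assert abs(hb[0].occupancy - 100 * p) < 1.5
        # and the scan agrees exactly with the generator's own record
        truth = 100 * np.mean(manifest["planted"][0]["presence"])
        assert hb[0].occupancy == pytest.approx(truth, abs=1e-9)

    def test_totals_are_exact_sums_of_parts(self, dimer_ensemble):
        ens, _ = dimer_ensemble
        totals = r.occupancy_scan(ens, r.CriteriaConfig(),
                                  (r.select(ens.topology, "chain A"),
                                   r.select(ens.topology, "chain B")),
                                  min_occupancy=0.0)
        for kind, total in (("hbond", totals.hbond_total),
                            ("hydrophobic", totals.hydrophobic_total),
                            ("ionic", totals.ionic_total)):
            parts = sum(e.occupancy for e in totals.events if e.kind == kind)
            assert total == pytest.approx(parts, abs=1e-9)

    def test_reporting_floor_filters_events(self, dimer_ensemble):
        ens, manifest = dimer_ensemble
        sels = (r.select(ens.topology, "chain A"), r.select(ens.topology, "chain B"))
        floored = r.occupancy_scan(ens, r.CriteriaConfig(), sels, min_occupancy=90.0)
        assert all(e.occupancy >= 90.0 for e in floored.events)

    def test_planted_events_recovered_with_correct_identity(self, dimer_ensemble):
        ens, manifest = dimer_ensemble
        sels = (r.select(ens.topology, "chain A"), r.select(ens.topology, "chain B"))
        totals = r.occupancy_scan(ens, r.CriteriaConfig(), sels, min_occupancy=0.0)
        kinds = sorted(e.kind for e in totals.events)
        assert kinds == ["hbond", "hydrophobic", "ionic"]
        for plant in manifest["planted"]:
            truth = 100 * np.mean(plant["presence"])
            match = [e for e in totals.events if e.kind == plant["kind"]]
            assert match[0].occupancy == pytest.approx(truth, abs=1.0)
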