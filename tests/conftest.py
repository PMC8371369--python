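"""Shared fixtures: toy monomers, planted dimers, and small ensembles."""

import numpy as np
import pytest

import rrmagg as r

#: edge pairings for the five dimer binding modes and their expected labels
MODE_PLANTINGS = {
    "SaSb": (("shoulder12-α", "shoulder12-β", None), ("SαSβ", "shoulder-to-shoulder")),
    "SbSb": (("shoulder12-β", "shoulder12-β", None), ("SβSβ", "shoulder-to-shoulder")),
    "SbH1a1": (("shoulder12-β", "head-1", "α1"), ("SβH1α1-like", "shoulder-to-head")),
    "SbH1a2": (("shoulder12-β", "head-1", "α2"), ("SβH1α2-like", "shoulder-to-head")),
    "H1H1": (("head-1", "head-1", None), ("H1H1", "head-to-head")),
}


@pytest.fixture(scope="session")
def monomer_and_annotation():
    return r.make_toy_monomer(r.GeneratorSpec(seed=0))


@pytest.fixture(scope="session")
def monomer(monomer_and_annotation):
    return monomer_and_annotation[0]


@pytest.fixture(scope="session")
def annotation(monomer_and_annotation):
    return monomer_and_annotation[1]


@pytest.fixture(scope="session")
def planted_dimer(monomer_and_annotation):
    """Dimer with one planted interaction of each kind across the interface."""
    m, ann = monomer_and_annotation
    transform = r.RigidTransform(np.eye(3), np.array([0.0, -12.0, 0.0]))
    planted = [
        r.PlantedInteraction("hbond", 108, 108, 3.4, 150.0, p=0.84),
        r.PlantedInteraction("ionic", 132, 132, 4.8, p=1.0),
        r.PlantedInteraction("hydrophobic", 139, 139, 4.4, p=1.0),
    ]
    return r.make_dimer(m, ann, transform, planted)


@pytest.fixture(scope="session")
def dimer_ensemble(planted_dimer):
    """500-frame ensemble of the planted dimer with mild positional noise."""
    dimer, _ = planted_dimer
    return r.make_ensemble(dimer, r.NoiseModel(sigma=0.02), 500, seed=7)


def tiny_planted_structure(p: float = 0.7, distance: float = 3.3):
    """Minimal 6-atom structure carrying one planted hydrogen bond.

    Small enough that very long occupancy scans (10^4 frames) stay cheap.
    """
    d_pos = np.array([0.0, 0.0, 0.0])
    a_pos = np.array([distance, 0.0, 0.0])
    h_pos = d_pos + (a_pos - d_pos) / distance * 1.0  # collinear → angle 180°
    atoms = [
        r.AtomRecord(1, "CA", "C", "GLN", 1, "A", (0.0, 1.5, 0.0)),
        r.AtomRecord(2, "NE2", "N", "GLN", 1, "A", tuple(d_pos)),
        r.AtomRecord(3, "HE21", "H", "GLN", 1, "A", tuple(h_pos)),
        r.AtomRecord(4, "CA", "C", "ASN", 1, "B", (distance, 1.5, 0.0)),
        r.AtomRecord(5, "OD1", "O", "ASN", 1, "B", tuple(a_pos)),
        r.AtomRecord(6, "CB", "C", "ASN", 1, "B", (distance, 2.5, 1.0)),
    ]
    meta = {"planted": [{
        "kind": "hbond", "res_a": 1, "res_b": 1, "distance": distance,
        "angle": 180.0, "p": p, "toggle_atom": ("B", 1, "OD1"),
        "off_displacement": (6.0, 0.0, 0.0),
    }]}
    return r.Structure(atoms, meta)
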