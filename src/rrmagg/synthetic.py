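"""Deterministic, seeded generators for every input the analysis needs.

Toy two-domain monomers with annotated α1/α2 helices and β1–β5 strands,
dimers placed by known rigid transforms with planted hydrogen-bond /
hydrophobic / ionic geometries, coordinate ensembles with controlled
per-atom noise, planted correlation blocks and planted interaction
occupancies, and periodic tetramer pairs with a known screw step.

The toy monomer is a Cα trace plus minimal side-chain proxies (one
donor/acceptor/charged pseudo-atom group per planted residue) rather than an
all-atom model: it exercises the geometric criteria engine without a rotamer
builder.  Every planted quantity is recorded in a ground-truth manifest so
the analysis modules can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.distance import cdist

from .assembly import Assembly
from .core import (AtomRecord, EdgeAnnotation, Structure, StructureEnsemble,
                   default_rrm12_annotation)
from .superpose import RigidTransform, screw_decompose

__all__ = [
    "GeneratorSpec",
    "PlantedInteraction",
    "CorrelationBlock",
    "NoiseModel",
    "make_ideal_helix",
    "make_toy_monomer",
    "make_dimer",
    "make_dimer_for_mode",
    "make_ensemble",
    "make_periodic_tetramers",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Bundle of generator constants (textbook secondary-structure values)."""

    seed: int = 0
    helix_n_res: int = 12
    helix_rise: float = 1.5     # Å per residue
    helix_twist: float = 100.0  # degrees per residue
    helix_radius: float = 2.3   # Å, Cα radius
    strand_rise: float = 3.3    # Å per residue
    strand_spacing: float = 4.8  # Å between neighbouring strands


@dataclass(frozen=True)
class PlantedInteraction:
    """One interaction planted across a dimer interface.

    ``res_a`` lives on the first monomer (chain A), ``res_b`` on the second
    (chain B).  ``distance`` is realized exactly in the noise-free structure;
    ``angle`` applies to hydrogen bonds (donor–proton–acceptor).  ``p`` is
    the per-frame presence probability used by :func:`make_ensemble`.
    """

    kind: str  # hbond | hydrophobic | ionic
    res_a: int
    res_b: int
    distance: float
    angle: float = 155.0
    p: float = 1.0

    def __post_init__(self):
        if self.kind not in ("hbond", "hydrophobic", "ionic"):
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("presence probability must be in [0, 1]")


@dataclass(frozen=True)
class CorrelationBlock:
    """Atoms of these residues share one latent displacement per frame."""

    chain: str
    res_ids: tuple[int, ...]
    latent_sigma: float = 0.3  # Å per axis


@dataclass(frozen=True)
class NoiseModel:
    sigma: float = 0.1  # Å, iid per atom per axis
    blocks: tuple[CorrelationBlock, ...] = ()


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def _helix_trace(n: int, rise: float, twist_deg: float, radius: float) -> np.ndarray:
    i = np.arange(n)
    theta = np.deg2rad(twist_deg) * i
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), rise * i])


def make_ideal_helix(n_res: int = 12, rise: float = 1.5, twist: float = 100.0,
                     radius: float = 2.3, chain: str = "A", start_res: int = 1,
                     res_name: str = "ALA") -> Structure:
    """Cα trace of an ideal helix along +z (labelled sse α in metadata)."""
    if n_res < 4:
        raise ValueError("an ideal helix needs at least 4 residues")
    xyz = _helix_trace(n_res, rise, twist, radius)
    xyz = xyz - xyz.mean(axis=0)
    atoms = [AtomRecord(i + 1, "CA", "C", res_name, start_res + i, chain,
                        tuple(xyz[i])) for i in range(n_res)]
    return Structure(atoms, {"sse": "α", "rise": rise, "twist": twist})


def _rot(angle_deg: float, axis: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    axis = np.asarray(axis, float)
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / np.linalg.norm(axis)).as_matrix()


def _rotation_aligning(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector u onto unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(u @ v)
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:  # opposite: rotate 180° about any perpendicular
        perp = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.cross(u, [0.0, 1.0, 0.0])
        return _rot(180.0, perp)
    axis = np.cross(u, v)
    angle = np.degrees(np.arccos(np.clip(c, -1, 1)))
    return _rot(angle, axis)


# ---------------------------------------------------------------------------
# toy monomer
# ---------------------------------------------------------------------------

def _domain_template(spec: GeneratorSpec, ranges: dict[str, tuple[int, int]],
                     x0: float, alpha1_center: np.ndarray,
                     alpha2_center: np.ndarray) -> dict[int, np.ndarray]:
    """Local coordinates of one RRM-like domain: 5 parallel strands + 2 helices.

    Strands run along z in the y=0 plane starting at ``x0``; the two helices
    sit at the given centres, α1 vertical and α2 crossing it at ~104°.
    """
    pos: dict[int, np.ndarray] = {}
    strand_order = ["β1", "β2", "β3", "β4", "β5"]
    for k, sse in enumerate(strand_order):
        lo, hi = ranges[sse]
        n = hi - lo + 1
        z = (np.arange(n) - (n - 1) / 2.0) * spec.strand_rise
        for i, res in enumerate(range(lo, hi + 1)):
            pos[res] = np.array([x0 + k * spec.strand_spacing, 0.0, z[i]])
    for sse, center, tilt_deg in (("α1", alpha1_center, 0.0),
                                  ("α2", alpha2_center, 104.3)):
        lo, hi = ranges[sse]
        n = hi - lo + 1
        xyz = _helix_trace(n, spec.helix_rise, spec.helix_twist, spec.helix_radius)
        xyz = xyz - xyz.mean(axis=0)
        if tilt_deg:
            xyz = xyz @ _rot(tilt_deg, [0.0, 1.0, 0.0]).T
        for i, res in enumerate(range(lo, hi + 1)):
            pos[res] = center + xyz[i]
    return pos


_RRM1_RANGES = {"β1": (106, 110), "α1": (115, 126), "β2": (130, 134),
                "β3": (137, 141), "α2": (150, 161), "β4": (163, 167),
                "β5": (170, 176)}
_RRM2_RANGES = {"β1": (195, 199), "α1": (204, 215), "β2": (219, 223),
                "β3": (226, 230), "α2": (237, 248), "β4": (250, 254),
                "β5": (257, 263)}
_LINKER_RANGE = (179, 190)


def make_toy_monomer(spec: GeneratorSpec = GeneratorSpec(), chain: str = "A"
                     ) -> tuple[Structure, EdgeAnnotation]:
    """Two-pseudo-domain Cα monomer (residues 102–267) with edge annotation.

    The shape is an elongated, asymmetric slab whose four edges are extremal
    in distinct directions: the RRM1 α1/α2 head (head-1) caps the −x end, the
    RRM2 β-sheet tail (head-2) the +x end, the β-sheet layers span the −y
    face (shoulder12-β), and the α-linker plus RRM2 α2 sit on the +y face
    (shoulder12-α).
    """
    anchors: dict[int, np.ndarray] = {}
    # RRM1: sheet at x 0–19, head-1 helices capping the −x end
    anchors.update(_domain_template(spec, _RRM1_RANGES, 0.0,
                                    np.array([-6.0, 6.5, 0.0]),
                                    np.array([-2.0, 9.0, 0.0])))
    # RRM2: sheet at x 27–46, α2 on the +y face (shoulder12-α)
    anchors.update(_domain_template(spec, _RRM2_RANGES, 27.0,
                                    np.array([31.0, 7.5, 2.0]),
                                    np.array([37.5, 10.0, 0.0])))

    lo, hi = _LINKER_RANGE
    n = hi - lo + 1
    xyz = _helix_trace(n, spec.helix_rise, spec.helix_twist, spec.helix_radius)
    xyz = (xyz - xyz.mean(axis=0)) @ _rot(90.0, [0.0, 1.0, 0.0]).T  # axis → +x
    for i, res in enumerate(range(lo, hi + 1)):
        anchors[res] = np.array([23.0, 9.5, 0.0]) + xyz[i]

    # fill loops/termini by interpolation between anchors (linear extrapolation
    # at the chain ends so no two residues coincide)
    res_ids = np.arange(102, 268)
    known = np.array(sorted(anchors))
    known_xyz = np.array([anchors[r] for r in known])
    coords = np.empty((len(res_ids), 3))
    for d in range(3):
        coords[:, d] = np.interp(res_ids, known, known_xyz[:, d])
    head = res_ids < known[0]
    tail = res_ids > known[-1]
    d0 = (known_xyz[0] - known_xyz[1]) / max(known[1] - known[0], 1)
    d1 = (known_xyz[-1] - known_xyz[-2]) / max(known[-1] - known[-2], 1)
    coords[head] = known_xyz[0] + np.outer(known[0] - res_ids[head], d0)
    coords[tail] = known_xyz[-1] + np.outer(res_ids[tail] - known[-1], d1)

    atoms = [AtomRecord(i + 1, "CA", "C", "GLY", int(res_ids[i]), chain,
                        tuple(coords[i])) for i in range(len(res_ids))]
    structure = Structure(atoms, {"model": "toy-RRM12", "seed": spec.seed})
    return structure, default_rrm12_annotation(chain)


# ---------------------------------------------------------------------------
# dimers with planted interactions
# ---------------------------------------------------------------------------

#: proxy chemistry per planted kind: (res_name_a, atom_a), (res_name_b, atoms_b)
_PLANT_CHEM = {
    # acceptor on A (Asn OD1), donor on B (Gln NE2–HE21); an uncharged pair,
    # so a planted hydrogen bond never doubles as an ionic interaction
    "hbond": (("ASN", ("OD1",)), ("GLN", ("NE2", "HE21"))),
    # carboxylate O on A (Asp OD1), HN group on B (Lys NZ–HZ1)
    "ionic": (("ASP", ("OD1",)), ("LYS", ("NZ", "HZ1"))),
    # apolar side-chain carbons
    "hydrophobic": (("LEU", ("CD1",)), ("PHE", ("CZ",))),
}
_PROXY_REACH = 8.0  # Å; beyond this the backbone would have to distort > 1 Å


def _hbond_proton_position(d_pos: np.ndarray, a_pos: np.ndarray,
                           angle_deg: float) -> np.ndarray:
    """Place H at 1.0 Å from the donor with an exact D–H–A angle."""
    u = a_pos - d_pos
    d = np.linalg.norm(u)
    u = u / d
    perp = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-8:
        perp = np.cross(u, [0.0, 1.0, 0.0])
    perp = perp / np.linalg.norm(perp)

    def angle_at_h(phi: float) -> float:
        h = d_pos + np.cos(phi) * u + np.sin(phi) * perp
        v1 = d_pos - h
        v2 = a_pos - h
        c = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    if angle_deg >= 180.0 - 1e-9:
        return d_pos + u
    phi = brentq(lambda x: angle_at_h(x) - angle_deg, 1e-9, np.pi * 0.9)
    return d_pos + np.cos(phi) * u + np.sin(phi) * perp


def make_dimer(monomer: Structure, annotation: EdgeAnnotation,
               transform: RigidTransform,
               planted: list[PlantedInteraction] = ()) -> tuple[Structure, EdgeAnnotation]:
    """Second copy placed by ``transform`` (chain B), with planted geometries.

    Side-chain proxy atoms are added (and the carrying residues renamed to
    the matching amino-acid type) so every planted interaction meets its
    target distance/angle exactly in the noise-free structure.  Raises when a
    planted geometry would need a proxy farther than ~8 Å from its Cα, i.e.
    an implied backbone distortion beyond 1 Å.
    """
    atoms: list[AtomRecord] = []
    rename: dict[tuple[str, int], str] = {}
    for pi in planted:
        (res_a_name, _), (res_b_name, _) = _PLANT_CHEM[pi.kind]
        rename[("A", pi.res_a)] = res_a_name
        rename[("B", pi.res_b)] = res_b_name

    ca_pos: dict[tuple[str, int], np.ndarray] = {}
    serial = 1
    for src_chain, tr in (("A", None), ("B", transform)):
        for a in monomer.atoms:
            xyz = np.asarray(a.coords) if tr is None else tr.apply(np.asarray(a.coords))
            name = rename.get((src_chain, a.res_id), a.res_name) \
                if (src_chain, a.res_id) in rename else a.res_name
            atoms.append(AtomRecord(serial, a.name, a.element, name, a.res_id,
                                    src_chain, tuple(xyz)))
            if a.name.upper() == "CA":
                ca_pos[(src_chain, a.res_id)] = xyz
            serial += 1

    manifest = []
    for pi in planted:
        ca_a = ca_pos.get(("A", pi.res_a))
        ca_b = ca_pos.get(("B", pi.res_b))
        if ca_a is None or ca_b is None:
            raise ValueError(f"planted residue {pi.res_a}/{pi.res_b} not in monomer")
        gap_vec = ca_b - ca_a
        gap = float(np.linalg.norm(gap_vec))
        u = gap_vec / gap
        (res_a_name, atoms_a), (res_b_name, atoms_b) = _PLANT_CHEM[pi.kind]

        if pi.kind in ("hbond", "ionic"):
            # donor/basic heavy atom 1.5 Å off Cα of B toward A; the contact
            # proton 1.0 Å further; acceptor O at the exact target distance
            heavy_b = ca_b - u * 1.5
            if pi.kind == "hbond":
                acc_a = heavy_b - u * pi.distance
                proton = _hbond_proton_position(heavy_b, acc_a, pi.angle)
            else:
                proton = heavy_b - u * 1.0
                acc_a = proton - u * pi.distance
            off_a = float(np.linalg.norm(acc_a - ca_a))
            if off_a > _PROXY_REACH:
                raise ValueError(
                    f"planted {pi.kind} {pi.res_a}-{pi.res_b} unreachable: proxy "
                    f"{off_a:.1f} Å from Cα (Cα gap {gap:.1f} Å)")
            new = [("A", pi.res_a, res_a_name, atoms_a[0], "O", acc_a),
                   ("B", pi.res_b, res_b_name, atoms_b[0], "N", heavy_b),
                   ("B", pi.res_b, res_b_name, atoms_b[1], "H", proton)]
            toggle_atom = (("A", pi.res_a, atoms_a[0]))
        else:  # hydrophobic: two side-chain carbons around the midpoint
            mid = (ca_a + ca_b) / 2.0
            c_a = mid - u * (pi.distance / 2.0)
            c_b = mid + u * (pi.distance / 2.0)
            for name, pos, ca in ((atoms_a[0], c_a, ca_a), (atoms_b[0], c_b, ca_b)):
                if np.linalg.norm(pos - ca) > _PROXY_REACH:
                    raise ValueError(
                        f"planted hydrophobic {pi.res_a}-{pi.res_b} unreachable "
                        f"(Cα gap {gap:.1f} Å)")
            new = [("A", pi.res_a, res_a_name, atoms_a[0], "C", c_a),
                   ("B", pi.res_b, res_b_name, atoms_b[0], "C", c_b)]
            toggle_atom = (("A", pi.res_a, atoms_a[0]))

        for chain, res, res_name, name, element, pos in new:
            atoms.append(AtomRecord(serial, name, element, res_name, res, chain,
                                    tuple(float(v) for v in pos)))
            serial += 1
        manifest.append({
            "kind": pi.kind, "res_a": pi.res_a, "res_b": pi.res_b,
            "distance": pi.distance, "angle": pi.angle, "p": pi.p,
            "toggle_atom": toggle_atom,
            "off_displacement": tuple(float(v) for v in (-u * 6.0)),
        })

    meta = dict(monomer.metadata)
    meta["planted"] = manifest
    meta["dimer_transform"] = {"rotation": transform.rotation.tolist(),
                               "translation": transform.translation.tolist()}
    dimer = Structure(atoms, meta)
    return dimer, annotation.covering(["A", "B"])


def _edge_frame(structure: Structure, annotation: EdgeAnnotation, chain: str,
                edge: str, sse: str | None = None) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Centroid, outward direction and residue ids of one edge."""
    res_ids, coords = [], []
    body = []
    for a in structure.atoms:
        if a.chain_id != chain or a.name.upper() != "CA":
            continue
        body.append(a.coords)
        if annotation.edge_of(chain, a.res_id) == edge:
            if sse is not None and annotation.sse_of(chain, a.res_id) != sse:
                continue
            res_ids.append(a.res_id)
            coords.append(a.coords)
    if not coords:
        raise ValueError(f"edge {edge!r} (sse {sse!r}) has no residues on chain {chain}")
    centroid = np.mean(coords, axis=0)
    outward = centroid - np.mean(body, axis=0)
    nrm = np.linalg.norm(outward)
    if nrm < 1e-9:
        raise ValueError(f"edge {edge!r} centroid coincides with body centroid")
    return centroid, outward / nrm, res_ids


def make_dimer_for_mode(monomer: Structure, annotation: EdgeAnnotation,
                        edge_a: str, edge_b: str, sse_b: str | None = None,
                        n_contacts: int = 8, contact_distance: float = 4.0,
                        separation: float = 6.5) -> tuple[Structure, EdgeAnnotation]:
    """Dimer whose inter-monomer contacts lie only between two chosen edges.

    The second monomer is oriented so its ``edge_b`` faces ``edge_a``, then
    pushed along the edge normal until the closest inter-monomer Cα pair sits
    at ``separation`` — too far for accidental contacts — and ``n_contacts``
    side-chain proxy pairs are planted at ``contact_distance`` between the
    nearest facing edge residues.  ``sse_b`` restricts the B-side residues to
    one secondary-structure element (α1 vs α2 for the shoulder-to-head modes).
    """
    cen_a, out_a, res_a = _edge_frame(monomer, annotation, monomer.chain_ids[0], edge_a)
    cen_b, out_b, res_b = _edge_frame(monomer, annotation, monomer.chain_ids[0],
                                      edge_b, sse_b)
    R = _rotation_aligning(-out_b, out_a)
    all_xyz = np.array([a.coords for a in monomer.atoms])
    t0 = cen_a - R @ cen_b  # edge centroids coincident
    b0 = all_xyz @ R.T + t0

    def _min_dist(s: float) -> float:
        return float(cdist(all_xyz, b0 + s * out_a).min())

    if _min_dist(0.0) >= separation:
        s = 0.0
    else:
        s_hi = 1.0
        while _min_dist(s_hi) < separation:
            s_hi *= 1.6
            if s_hi > 500:
                raise ValueError("separation search failed to converge")
        s = brentq(lambda x: _min_dist(x) - separation, 0.0, s_hi, xtol=1e-9)
    transform = RigidTransform(R, t0 + s * out_a)

    # pick the closest facing residue pairs for planting
    pos_a = {r: np.array([a.coords for a in monomer.atoms
                          if a.res_id == r and a.name.upper() == "CA"][0])
             for r in res_a}
    pos_b = {r: transform.apply(np.array([a.coords for a in monomer.atoms
                                          if a.res_id == r and a.name.upper() == "CA"][0]))
             for r in res_b}
    ra = list(pos_a)
    rb = list(pos_b)
    D = cdist([pos_a[r] for r in ra], [pos_b[r] for r in rb])
    order = np.dstack(np.unravel_index(np.argsort(D, axis=None), D.shape))[0]
    planted, used_a, used_b = [], set(), set()
    for i, j in order:
        if len(planted) >= n_contacts:
            break
        r1, r2 = ra[int(i)], rb[int(j)]
        if r1 in used_a or r2 in used_b or D[i, j] > 2 * _PROXY_REACH:
            continue
        used_a.add(r1)
        used_b.add(r2)
        planted.append(PlantedInteraction("hydrophobic", r1, r2, contact_distance))
    # geometry may cap the number of reachable pairs; at least 4 are needed
    # for an unambiguous dominant edge pair
    if len(planted) < min(n_contacts, 4):
        raise ValueError(
            f"only {len(planted)} of {n_contacts} contacts plantable between "
            f"{edge_a} and {edge_b}")
    return make_dimer(monomer, annotation, transform, planted)


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def make_ensemble(structure: Structure, noise: NoiseModel, n_frames: int,
                  seed: int) -> tuple[StructureEnsemble, dict]:
    """Base structure + correlated Gaussian perturbations, one frame each.

    Planted interactions recorded in ``structure.metadata['planted']`` are
    toggled per frame as Bernoulli(p) by displacing their contact proxy atom
    beyond the criterion cutoff in the absent frames.  Correlation blocks add
    one shared latent displacement per block per frame.  Returns the ensemble
    and a ground-truth manifest (planted presence series, block definitions).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be ≥ 1")
    rng = np.random.default_rng(seed)
    base = structure.coords
    n_atoms = base.shape[0]
    xyz = np.repeat(base[None], n_frames, axis=0)
    if noise.sigma > 0:
        xyz += rng.normal(0.0, noise.sigma, size=xyz.shape)

    block_manifest = []
    for block in noise.blocks:
        idx = [i for i, a in enumerate(structure.atoms)
               if a.chain_id == block.chain and a.res_id in set(block.res_ids)]
        if not idx:
            raise ValueError(f"correlation block matches no atoms: {block}")
        latent = rng.normal(0.0, block.latent_sigma, size=(n_frames, 3))
        xyz[:, idx] += latent[:, None, :]
        block_manifest.append({"chain": block.chain, "res_ids": list(block.res_ids),
                               "latent_sigma": block.latent_sigma,
                               "atom_indices": idx})

    atom_lookup = {(a.chain_id, a.res_id, a.name): i
                   for i, a in enumerate(structure.atoms)}
    planted_manifest = []
    for plant in structure.metadata.get("planted", []):
        chain, res, name = plant["toggle_atom"]
        i = atom_lookup[(chain, res, name)]
        present = rng.random(n_frames) < plant["p"]
        off = np.asarray(plant["off_displacement"], dtype=float)
        xyz[~present, i] += off
        planted_manifest.append({**plant, "presence": present,
                                 "atom_index": i})

    ensemble = StructureEnsemble(structure, xyz)
    manifest = {"seed": seed, "sigma": noise.sigma,
                "planted": planted_manifest, "blocks": block_manifest}
    return ensemble, manifest


# ---------------------------------------------------------------------------
# periodic assemblies
# ---------------------------------------------------------------------------

def make_periodic_tetramers(dimer: Structure, step: RigidTransform
                            ) -> tuple[Assembly, Assembly]:
    """Two overlapping 2-unit tetramers sharing one dimer building unit.

    ``tetramer_a`` = (D, S·D) and ``tetramer_b`` = (S·D, S²·D) for the screw
    step S — so b's first unit equals a's second unit exactly, the
    precondition of the two-path octamer construction.  The step must have a
    nonzero rise.
    """
    screw = screw_decompose(step)
    if abs(screw.rise) < 1e-9:
        raise ValueError("tetramer step must have a nonzero rise")
    d1 = step.apply_structure(dimer)
    d2 = step.compose(step).apply_structure(dimer)
    tet_a = Assembly([dimer, d1], ["dimer1", "dimer2"],
                     [{"op": "make_periodic_tetramers", "member": "a"}])
    tet_b = Assembly([d1, d2], ["dimer2", "dimer3"],
                     [{"op": "make_periodic_tetramers", "member": "b"}])
    return tet_a, tet_b
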