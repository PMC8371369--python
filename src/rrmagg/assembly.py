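"""Repeatable-superimposing assembly of periodic helical oligomers.

The growth procedure mirrors how large amyloid-like models are built from
overlapping sub-oligomers: rigidly superpose a shared building unit of two
assemblies, delete the duplicate, and iterate.  For perfectly periodic seeds
every consecutive unit-step transform is identical, and its screw
decomposition yields the aggregation axis, twist per unit and rise per unit
of the resulting repeated, helical, rope-like structure.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import AtomRecord, Structure, StructureEnsemble, TopologyError
from .superpose import RigidTransform, kabsch, rmsd, screw_decompose

__all__ = [
    "Assembly",
    "MergeSpec",
    "IncompatibilityError",
    "ClashError",
    "superimpose_merge",
    "unit_step_transform",
    "propagate",
    "two_path_build",
]


class IncompatibilityError(ValueError):
    """Shared units do not superpose within tolerance."""


class ClashError(ValueError):
    """Non-adjacent units collide."""


@dataclass(frozen=True)
class MergeSpec:
    """How two assemblies share a unit during a merge."""

    shared_unit_in_a: int
    shared_unit_in_b: int
    dedup_rmsd_tol: float = 1.0   # Å, Cα RMSD below which units deduplicate
    clash_cutoff: float = 2.5     # Å, heavy-atom contact between non-adjacent units
    allow_clash: bool = False

    def __post_init__(self):
        if self.dedup_rmsd_tol <= 0 or self.clash_cutoff <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class Assembly:
    """Ordered building units (monomers or dimers) along the aggregation axis."""

    units: list[Structure]
    unit_labels: list[str] = field(default_factory=list)
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self):
        if not self.units:
            raise ValueError("assembly requires at least one unit")
        if not self.unit_labels:
            self.unit_labels = [f"unit{i + 1}" for i in range(len(self.units))]
        if len(self.unit_labels) != len(self.units):
            raise ValueError("one label per unit required")

    def __len__(self) -> int:
        return len(self.units)

    def copy(self) -> "Assembly":
        return Assembly(list(self.units), list(self.unit_labels), list(self.provenance))

    def unit_ca(self, i: int) -> np.ndarray:
        coords = [a.coords for a in self.units[i].atoms if a.name.upper() == "CA"]
        if len(coords) < 3:
            raise ValueError(f"unit {i} has fewer than 3 Cα atoms")
        return np.asarray(coords, dtype=float)

    def to_structure(self, relabel_chains: bool = True) -> Structure:
        """Flatten to one multi-chain structure (chains re-lettered A, B, …)."""
        letters = string.ascii_uppercase + string.ascii_lowercase + string.digits
        atoms: list[AtomRecord] = []
        chain_map: dict[tuple[int, str], str] = {}
        serial = 1
        for ui, unit in enumerate(self.units):
            for a in unit.atoms:
                if relabel_chains:
                    key = (ui, a.chain_id)
                    if key not in chain_map:
                        if len(chain_map) >= len(letters):
                            raise ValueError("too many chains to re-letter")
                        chain_map[key] = letters[len(chain_map)]
                    chain = chain_map[key]
                else:
                    chain = a.chain_id
                atoms.append(AtomRecord(serial, a.name, a.element, a.res_name,
                                        a.res_id, chain, a.coords))
                serial += 1
        meta = {"units": len(self.units), "unit_labels": list(self.unit_labels)}
        if relabel_chains:
            meta["chain_provenance"] = {v: f"{self.unit_labels[k[0]]}:{k[1]}"
                                        for k, v in chain_map.items()}
        return Structure(atoms, meta)

    def transform_log(self) -> list[dict]:
        return list(self.provenance)


def _check_topology(a: Structure, b: Structure) -> None:
    if a.atom_keys != b.atom_keys:
        raise TopologyError("units do not share an atom topology")


def _heavy_coords(unit: Structure) -> np.ndarray:
    return np.asarray([a.coords for a in unit.atoms if a.element.upper() != "H"],
                      dtype=float)


def clash_census(assembly: Assembly, clash_cutoff: float) -> int:
    """Heavy-atom contacts below cutoff between non-adjacent unit pairs."""
    trees = [cKDTree(_heavy_coords(u)) for u in assembly.units]
    clashes = 0
    for i in range(len(assembly)):
        for j in range(i + 2, len(assembly)):  # skip adjacent pairs
            clashes += trees[i].count_neighbors(trees[j], clash_cutoff)
    return int(clashes)


def superimpose_merge(a: Assembly, b: Assembly, spec: MergeSpec) -> Assembly:
    """Merge ``b`` into ``a`` by superposing their designated shared units.

    ``b`` is rigidly transformed so its shared unit lands on ``a``'s shared
    unit (Kabsch on all shared-unit Cα); any ``b`` unit that then duplicates
    an ``a`` unit (Cα RMSD < dedup tolerance) is removed, and the remaining
    units are inserted on the matching side.  The construction log records
    the transform and the shared-unit RMSD.
    """
    shared_a = a.units[spec.shared_unit_in_a]
    shared_b = b.units[spec.shared_unit_in_b]
    _check_topology(shared_a, shared_b)

    transform, shared_rmsd = kabsch(b.unit_ca(spec.shared_unit_in_b),
                                    a.unit_ca(spec.shared_unit_in_a))
    if shared_rmsd > spec.dedup_rmsd_tol:
        raise IncompatibilityError(
            f"shared units superpose at RMSD {shared_rmsd:.3f} Å "
            f"> tolerance {spec.dedup_rmsd_tol} Å")

    moved = [transform.apply_structure(u) for u in b.units]

    def _duplicates(unit: Structure) -> bool:
        ca = np.asarray([at.coords for at in unit.atoms if at.name.upper() == "CA"])
        for i, ua in enumerate(a.units):
            ua_ca = a.unit_ca(i)
            if ua_ca.shape == ca.shape and rmsd(ca, ua_ca) < spec.dedup_rmsd_tol:
                return True
        return False

    before, after = [], []
    for k, unit in enumerate(moved):
        if _duplicates(unit):
            continue
        lbl = b.unit_labels[k]
        (before if k < spec.shared_unit_in_b else after).append((unit, lbl))

    units = [u for u, _ in before] + list(a.units) + [u for u, _ in after]
    labels = [l for _, l in before] + list(a.unit_labels) + [l for _, l in after]
    log = list(a.provenance) + [{
        "op": "superimpose_merge",
        "shared_unit_in_a": spec.shared_unit_in_a,
        "shared_unit_in_b": spec.shared_unit_in_b,
        "shared_rmsd": round(float(shared_rmsd), 6),
        "rotation": transform.rotation.round(9).tolist(),
        "translation": transform.translation.round(9).tolist(),
        "units_added": len(before) + len(after),
    }]
    merged = Assembly(units, labels, log)
    n_clash = clash_census(merged, spec.clash_cutoff)
    if n_clash:
        msg = (f"{n_clash} heavy-atom clashes (< {spec.clash_cutoff} Å) between "
               f"non-adjacent units after merge")
        if spec.allow_clash:
            warnings.warn(msg)
        else:
            raise ClashError(msg)
    return merged


def unit_step_transform(assembly: Assembly, i: int, j: int) -> RigidTransform:
    """Kabsch transform mapping unit ``i`` onto unit ``j`` (Cα atoms)."""
    _check_topology(assembly.units[i], assembly.units[j])
    if i == j:
        return RigidTransform.identity()
    transform, _ = kabsch(assembly.unit_ca(i), assembly.unit_ca(j))
    return transform


def propagate(seed_unit: Structure, step: RigidTransform, n_units: int,
              clash_cutoff: float = 2.5, on_clash: str = "raise") -> Assembly:
    """Grow a periodic assembly: unit k = step^(k−1) applied to the seed.

    Records the screw parameters of the step (aggregation-axis direction,
    twist per unit, rise per unit) in the construction log and runs a clash
    census over all non-adjacent unit pairs.
    """
    if n_units < 1:
        raise ValueError("n_units must be ≥ 1")
    if on_clash not in ("raise", "warn", "ignore"):
        raise ValueError("on_clash must be raise|warn|ignore")
    units = [seed_unit]
    current = RigidTransform.identity()
    for _ in range(n_units - 1):
        current = step.compose(current)
        units.append(current.apply_structure(seed_unit))
    screw = screw_decompose(step)
    log = [{
        "op": "propagate",
        "n_units": n_units,
        "twist_per_unit_deg": round(float(screw.angle), 9),
        "rise_per_unit_A": round(float(screw.rise), 9),
        "axis_direction": screw.axis_direction.round(9).tolist(),
        "axis_point": screw.axis_point.round(9).tolist(),
    }]
    asm = Assembly(units, [f"unit{i + 1}" for i in range(n_units)], log)
    n_clash = clash_census(asm, clash_cutoff) if n_units > 2 else 0
    log[0]["clashes"] = int(n_clash)
    if n_clash:
        msg = (f"propagated assembly self-intersects: {n_clash} heavy-atom "
               f"contacts < {clash_cutoff} Å between non-adjacent units")
        if on_clash == "raise":
            raise ClashError(msg)
        if on_clash == "warn":
            warnings.warn(msg)
    return asm


def two_path_build(tetramer_a: Assembly, tetramer_b: Assembly, path: int,
                   target_units: int, dedup_rmsd_tol: float = 1.0,
                   clash_cutoff: float = 2.5, allow_clash: bool = False) -> Assembly:
    """Grow a large oligomer from two overlapping tetramers along one path.

    Both tetramers must decompose into two dimer building units of shared
    topology.  Path 1 repeatedly overlaps the left unit of ``tetramer_b``
    onto the right end of the growing assembly; path 2 overlaps the right
    unit onto the left end.  For consistent periodic seeds the two paths
    produce congruent oligomers.
    """
    if path not in (1, 2):
        raise ValueError("path must be 1 or 2")
    if len(tetramer_a) != 2 or len(tetramer_b) != 2:
        raise ValueError("two_path_build expects 2-unit (dimer×2) tetramers")
    if target_units < len(tetramer_a):
        raise ValueError("target_units smaller than the seed assembly")

    grown = tetramer_a.copy()
    grown.provenance = list(tetramer_a.provenance) + [{"op": "two_path_build",
                                                       "path": path,
                                                       "target_units": target_units}]
    while len(grown) < target_units:
        if path == 1:
            spec = MergeSpec(shared_unit_in_a=len(grown) - 1, shared_unit_in_b=0,
                             dedup_rmsd_tol=dedup_rmsd_tol,
                             clash_cutoff=clash_cutoff, allow_clash=allow_clash)
        else:
            spec = MergeSpec(shared_unit_in_a=0, shared_unit_in_b=1,
                             dedup_rmsd_tol=dedup_rmsd_tol,
                             clash_cutoff=clash_cutoff, allow_clash=allow_clash)
        grown = superimpose_merge(grown, tetramer_b, spec)
    return grown
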