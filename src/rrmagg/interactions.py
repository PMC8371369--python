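"""Hydrogen-bond, hydrophobic and ionic interaction detection and occupancies.

Geometric criteria (strict inequalities, as conventionally printed):

* hydrogen bond — donor–acceptor distance < 3.5 Å AND donor–proton–acceptor
  angle > 120° for at least one attached proton;
* hydrophobic contact — side-chain carbon–carbon distance < 4.5 Å between
  apolar residues;
* ionic interaction — distance < 5.0 Å between the side-chain HN group of
  Arg/Lys and a carboxylate O of Asp/Glu.

Occupancy of an interaction is the percentage of ensemble frames in which
its criterion holds.  Interface totals are sums of the per-event occupancies
of one kind and may exceed 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .core import Selection, Structure, StructureEnsemble

__all__ = [
    "CriteriaConfig",
    "InteractionEvent",
    "InterfaceTotals",
    "find_hbonds",
    "find_hydrophobic",
    "find_ionic",
    "occupancy_scan",
    "sum_occupancies",
]


@dataclass(frozen=True)
class CriteriaConfig:
    """Geometric cutoffs; defaults are the conventional MD-analysis values."""

    hbond_da_max: float = 3.5      # Å, donor–acceptor
    hbond_dha_min: float = 120.0   # degrees, donor–proton–acceptor
    hydrophobic_cc_max: float = 4.5  # Å, carbon–carbon
    ionic_max: float = 5.0         # Å, HN group to carboxylate O

    def __post_init__(self):
        for name in ("hbond_da_max", "hbond_dha_min", "hydrophobic_cc_max", "ionic_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# --- editable chemistry tables (standard amino-acid donors/acceptors) -------

#: residue → {donor heavy atom: (proton names...)}
DONORS: dict[str, dict[str, tuple[str, ...]]] = {
    "*": {"N": ("H", "HN")},  # backbone amide, any residue
    "ARG": {"NE": ("HE",), "NH1": ("HH11", "HH12"), "NH2": ("HH21", "HH22")},
    "LYS": {"NZ": ("HZ1", "HZ2", "HZ3")},
    "ASN": {"ND2": ("HD21", "HD22")},
    "GLN": {"NE2": ("HE21", "HE22")},
    "HIS": {"ND1": ("HD1",), "NE2": ("HE2",)},
    "SER": {"OG": ("HG",)},
    "THR": {"OG1": ("HG1",)},
    "TYR": {"OH": ("HH",)},
    "TRP": {"NE1": ("HE1",)},
    "CYS": {"SG": ("HG",)},
}

#: residue → acceptor heavy atoms
ACCEPTORS: dict[str, tuple[str, ...]] = {
    "*": ("O", "OXT"),  # backbone carbonyl, any residue
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
    "MET": ("SD",),
}

#: apolar residues whose side-chain carbons count as hydrophobic
APOLAR_RESIDUES = ("ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP")
_BACKBONE_CARBONS = ("C", "CA")

#: chemically equivalent protons/heavies collapsed into one wildcard label
WILDCARD_GROUPS: dict[tuple[str, str], str] = {
    ("LYS", "HZ1"): "HZ*", ("LYS", "HZ2"): "HZ*", ("LYS", "HZ3"): "HZ*",
    ("ARG", "HH11"): "HH*", ("ARG", "HH12"): "HH*",
    ("ARG", "HH21"): "HH*", ("ARG", "HH22"): "HH*",
    ("ARG", "NH1"): "NH*", ("ARG", "NH2"): "NH*",
}

#: side-chain HN groups of the basic residues (protons, with heavy fallback)
IONIC_POSITIVE = {"ARG": (("HE", "HH11", "HH12", "HH21", "HH22"), ("NE", "NH1", "NH2")),
                  "LYS": (("HZ1", "HZ2", "HZ3"), ("NZ",))}
#: carboxylate oxygens of the acidic residues
IONIC_NEGATIVE = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


def _wildcard(res_name: str, atom_name: str) -> str:
    return WILDCARD_GROUPS.get((res_name.upper(), atom_name.upper()), atom_name)


@dataclass
class InteractionEvent:
    """One detected interaction, identified by its partner atoms/groups."""

    kind: str  # hbond | hydrophobic | ionic
    partner_a: tuple  # (chain, res_id, res_name, atom-or-group label)
    partner_b: tuple
    presence: np.ndarray = field(repr=False)  # per-frame booleans
    approximate: bool = False  # e.g. ionic N–O fallback without protons

    @property
    def occupancy(self) -> float:
        """Percentage of frames in which the interaction is present."""
        return float(100.0 * np.count_nonzero(self.presence) / len(self.presence))

    @property
    def key(self) -> tuple:
        return (self.kind, self.partner_a, self.partner_b)


@dataclass
class InterfaceTotals:
    """Per-kind occupancy totals plus the contributing events."""

    events: list[InteractionEvent]
    n_frames: int
    min_occupancy: float = 0.0

    @property
    def hbond_total(self) -> float:
        return sum_occupancies(self.events, "hbond")

    @property
    def hydrophobic_total(self) -> float:
        return sum_occupancies(self.events, "hydrophobic")

    @property
    def ionic_total(self) -> float:
        return sum_occupancies(self.events, "ionic")


def sum_occupancies(events: list[InteractionEvent], kind: str) -> float:
    """Exact sum of the listed occupancies of one interaction kind (%)."""
    return float(sum(e.occupancy for e in events if e.kind == kind))


# ---------------------------------------------------------------------------
# candidate enumeration (topology-level, coordinates applied per frame)
# ---------------------------------------------------------------------------

def _index_atoms(structure: Structure):
    """(chain, res_id) → {atom name: index}."""
    table: dict[tuple[str, int], dict[str, int]] = {}
    for i, a in enumerate(structure.atoms):
        table.setdefault((a.chain_id, a.res_id), {})[a.name.upper()] = i
    return table


def _donor_candidates(structure: Structure, sel: Selection, warn: bool = True):
    """(heavy index, (proton indices), label) for donors inside a selection."""
    atom_map = _index_atoms(structure)
    chosen = set(sel.asarray().tolist())
    out = []
    for i in sorted(chosen):
        a = structure.atoms[i]
        res_table = DONORS.get(a.res_name.upper(), {})
        protons = res_table.get(a.name.upper())
        if protons is None and a.name.upper() in DONORS["*"]:
            protons = DONORS["*"][a.name.upper()]
        if protons is None:
            continue
        res_atoms = atom_map[(a.chain_id, a.res_id)]
        h_idx = [res_atoms[p] for p in protons if p in res_atoms]
        if not h_idx:
            if warn:
                warnings.warn(
                    f"donor {a.chain_id}/{a.res_name}{a.res_id}/{a.name} has no "
                    f"attached proton; pair skipped")
            continue
        groups = {_wildcard(a.res_name, structure.atoms[j].name) for j in h_idx}
        label = f"{_wildcard(a.res_name, a.name)}-{sorted(groups)[0]}"
        out.append((i, tuple(h_idx), label))
    return out


def _acceptor_candidates(structure: Structure, sel: Selection):
    out = []
    for i in sel.asarray():
        a = structure.atoms[int(i)]
        names = ACCEPTORS.get(a.res_name.upper(), ())
        if a.name.upper() in names or a.name.upper() in ACCEPTORS["*"]:
            out.append(int(i))
    return out


def _partner(structure: Structure, i: int, label: str | None = None) -> tuple:
    a = structure.atoms[i]
    return (a.chain_id, a.res_id, a.res_name, label if label is not None else a.name)


def find_hbonds(frame: Structure, donors_sel: Selection, acceptors_sel: Selection,
                criteria: CriteriaConfig = CriteriaConfig()) -> list[InteractionEvent]:
    """Hydrogen bonds between a donor selection and an acceptor selection.

    A donor–acceptor pair qualifies iff D–A < ``hbond_da_max`` and the
    D–H–A angle exceeds ``hbond_dha_min`` for at least one attached proton.
    Chemically equivalent protons are collapsed into one wildcard event.
    """
    coords = frame.coords
    donors = _donor_candidates(frame, donors_sel)
    acceptors = _acceptor_candidates(frame, acceptors_sel)
    events = []
    seen = set()
    for d_idx, h_indices, label in donors:
        d_atom = frame.atoms[d_idx]
        for a_idx in acceptors:
            a_atom = frame.atoms[a_idx]
            if (d_atom.chain_id, d_atom.res_id) == (a_atom.chain_id, a_atom.res_id):
                continue
            da = np.linalg.norm(coords[d_idx] - coords[a_idx])
            if not (da < criteria.hbond_da_max):
                continue
            ok = False
            for h_idx in h_indices:
                hd = coords[d_idx] - coords[h_idx]
                ha = coords[a_idx] - coords[h_idx]
                cosang = (hd @ ha) / (np.linalg.norm(hd) * np.linalg.norm(ha))
                angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if angle > criteria.hbond_dha_min:
                    ok = True
                    break
            if not ok:
                continue
            pa = _partner(frame, d_idx, label)
            pb = _partner(frame, a_idx)
            if (pa, pb) in seen:
                continue
            seen.add((pa, pb))
            events.append(InteractionEvent("hbond", pa, pb, np.array([True])))
    return events


def _hydrophobic_candidates(structure: Structure, sel: Selection):
    out = []
    for i in sel.asarray():
        a = structure.atoms[int(i)]
        if (a.res_name.upper() in APOLAR_RESIDUES and a.element.upper() == "C"
                and a.name.upper() not in _BACKBONE_CARBONS):
            out.append(int(i))
    return out


def find_hydrophobic(frame: Structure, sel_a: Selection, sel_b: Selection,
                     criteria: CriteriaConfig = CriteriaConfig()) -> list[InteractionEvent]:
    """Side-chain C–C contacts below the hydrophobic cutoff, keyed by atom pair."""
    ca = _hydrophobic_candidates(frame, sel_a)
    cb = _hydrophobic_candidates(frame, sel_b)
    if not ca or not cb:
        return []
    coords = frame.coords
    D = cdist(coords[ca], coords[cb])
    events = []
    for i, j in zip(*np.nonzero(D < criteria.hydrophobic_cc_max)):
        atom_a, atom_b = frame.atoms[ca[i]], frame.atoms[cb[j]]
        if (atom_a.chain_id, atom_a.res_id) == (atom_b.chain_id, atom_b.res_id):
            continue
        events.append(InteractionEvent(
            "hydrophobic", _partner(frame, ca[i]), _partner(frame, cb[j]),
            np.array([True])))
    return events


def find_ionic(frame: Structure, criteria: CriteriaConfig = CriteriaConfig(),
               sel_a: Selection | None = None,
               sel_b: Selection | None = None) -> list[InteractionEvent]:
    """Ionic interactions: Arg/Lys HN group within cutoff of Asp/Glu O.

    Events are keyed by the residue pair.  When a basic residue carries no
    side-chain protons the N atoms are used at the same cutoff and the event
    is flagged ``approximate``.
    """
    atom_map = _index_atoms(frame)
    coords = frame.coords
    allowed_a = set(sel_a.asarray().tolist()) if sel_a is not None else None
    allowed_b = set(sel_b.asarray().tolist()) if sel_b is not None else None

    positives = []  # (residue key, atom indices, approximate)
    negatives = []
    for (chain, res_id), atoms in atom_map.items():
        any_idx = next(iter(atoms.values()))
        res_name = frame.atoms[any_idx].res_name.upper()
        if res_name in IONIC_POSITIVE:
            protons, heavies = IONIC_POSITIVE[res_name]
            idx = [atoms[n] for n in protons if n in atoms]
            approx = False
            if not idx:
                idx = [atoms[n] for n in heavies if n in atoms]
                approx = True
                if idx:
                    warnings.warn(
                        f"{res_name}{res_id} lacks side-chain protons; ionic "
                        f"criterion falls back to N–O distance")
            if idx:
                positives.append(((chain, res_id, res_name), idx, approx))
        if res_name in IONIC_NEGATIVE:
            idx = [atoms[n] for n in IONIC_NEGATIVE[res_name] if n in atoms]
            if idx:
                negatives.append(((chain, res_id, res_name), idx))

    def _in(allowed, idx_list):
        return allowed is None or any(i in allowed for i in idx_list)

    events = []
    for (key_p, idx_p, approx) in positives:
        for (key_n, idx_n) in negatives:
            if key_p[:2] == key_n[:2]:
                continue
            side_ok = ((_in(allowed_a, idx_p) and _in(allowed_b, idx_n))
                       or (_in(allowed_a, idx_n) and _in(allowed_b, idx_p)))
            if not side_ok:
                continue
            dmin = cdist(coords[idx_p], coords[idx_n]).min()
            if dmin < criteria.ionic_max:
                pa = (key_n[0], key_n[1], key_n[2], "O*")   # acidic partner
                pb = (key_p[0], key_p[1], key_p[2], "HN*")  # basic partner
                events.append(InteractionEvent("ionic", pa, pb, np.array([True]),
                                               approximate=approx))
    return events


def occupancy_scan(ensemble: StructureEnsemble, criteria: CriteriaConfig,
                   interface: tuple[Selection, Selection],
                   kinds: tuple[str, ...] = ("hbond", "hydrophobic", "ionic"),
                   min_occupancy: float = 20.0) -> InterfaceTotals:
    """Scan every frame for interface interactions and report occupancies.

    Every event observed in at least one frame is tracked; events at or above
    the reporting floor (default 20%) are returned sorted by descending
    occupancy.  Totals are exact sums over the reported events of each kind.
    """
    sel_a, sel_b = interface
    n = ensemble.n_frames
    tracker: dict[tuple, np.ndarray] = {}
    flags: dict[tuple, bool] = {}

    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for k in range(n):
            frame = ensemble.frame(k)
            found: list[InteractionEvent] = []
            if "hbond" in kinds:
                found += find_hbonds(frame, sel_a, sel_b, criteria)
                found += find_hbonds(frame, sel_b, sel_a, criteria)
            if "hydrophobic" in kinds:
                found += find_hydrophobic(frame, sel_a, sel_b, criteria)
            if "ionic" in kinds:
                found += find_ionic(frame, criteria, sel_a, sel_b)
            for ev in found:
                if ev.key not in tracker:
                    tracker[ev.key] = np.zeros(n, dtype=bool)
                    flags[ev.key] = ev.approximate
                tracker[ev.key][k] = True

    events = [
        InteractionEvent(kind, pa, pb, presence, approximate=flags[(kind, pa, pb)])
        for (kind, pa, pb), presence in tracker.items()
    ]
    events = [e for e in events if e.occupancy >= min_occupancy]
    events.sort(key=lambda e: (e.kind, -e.occupancy, e.partner_a, e.partner_b))
    return InterfaceTotals(events, n, min_occupancy)
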