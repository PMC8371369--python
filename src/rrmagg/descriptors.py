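"""Geometric descriptors of RRM oligomer models.

Helix axes and inter-helix angles, mass-centre distances, β-sheet-layer
separations, and the edge-based classification of dimer binding modes
(shoulder-to-shoulder, shoulder-to-head, head-to-head).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import EdgeAnnotation, Selection, Structure, StructureEnsemble, select

__all__ = [
    "DimerMode",
    "helix_axis",
    "interhelix_angle",
    "mass_center_distance",
    "sheet_layer_distance",
    "classify_dimer_mode",
]

# atomic masses for the optional mass-weighted centroid
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
           "P": 30.974, "SE": 78.971}

#: edge-pair → (mode label, group); unordered pairs
_MODE_TABLE = {
    frozenset(["shoulder12-α", "shoulder12-β"]): ("SαSβ", "shoulder-to-shoulder"),
    frozenset(["shoulder12-β"]): ("SβSβ", "shoulder-to-shoulder"),
    frozenset(["shoulder12-β", "head-1"]): ("SβH1", "shoulder-to-head"),
    frozenset(["head-1"]): ("H1H1", "head-to-head"),
}


@dataclass
class DimerMode:
    """Classified binding mode of a two-unit dimer.

    ``label`` refines shoulder-to-head contacts into SβH1α1-like /
    SβH1α2-like according to whether α1 or α2 dominates the head-1 side of
    the interface.
    """

    label: str
    group: str
    edge_contact_counts: pd.DataFrame = field(repr=False)


def helix_axis(helix_ca: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Axis direction of a helix Cα trace, oriented N→C.

    The dominant principal direction of the centered coordinates seeds a
    cylinder-fit refinement (minimizing the variance of radial distances to
    the axis), which removes the bias plain PCA picks up from incomplete
    helical turns.  Returns (unit axis, centroid); requires ≥4 positions.
    """
    from scipy.optimize import minimize

    X = np.asarray(helix_ca, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("expected an (n, 3) coordinate array")
    if X.shape[0] < 4:
        raise ValueError("helix axis needs at least 4 Cα positions")
    centroid = X.mean(axis=0)
    Xc = X - centroid
    _, svals, Vt = np.linalg.svd(Xc)
    axis = Vt[0]

    # collinear traces: the line direction is already exact
    if svals[1] > 1e-10 * max(svals[0], 1e-30):
        def radial_var(v: np.ndarray) -> float:
            u = v / np.linalg.norm(v)
            radial = Xc - np.outer(Xc @ u, u)
            rr = np.linalg.norm(radial, axis=1)
            return float(np.var(rr))

        res = minimize(radial_var, axis, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
        if res.x @ axis > 0:  # keep the PCA hemisphere
            axis = res.x / np.linalg.norm(res.x)
        else:
            axis = -res.x / np.linalg.norm(res.x)

    if axis @ (X[-1] - X[0]) < 0:  # orient from N-terminus to C-terminus
        axis = -axis
    return axis / np.linalg.norm(axis), centroid


def interhelix_angle(axis_a: np.ndarray, axis_b: np.ndarray) -> float:
    """Angle between two axis vectors in degrees, full [0, 180] range.

    Not folded to [0, 90]: reported inter-helix angles such as 104.3° keep
    the N→C orientation of each axis.
    """
    a = np.asarray(axis_a, dtype=float)
    b = np.asarray(axis_b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-length axis vector")
    return float(np.degrees(np.arccos(np.clip((a @ b) / (na * nb), -1.0, 1.0))))


def _centroid(structure: Structure, sel: Selection, mass_weighted: bool) -> np.ndarray:
    idx = sel.asarray()
    if idx.size == 0:
        raise ValueError("empty selection")
    coords = structure.coords[idx]
    if not mass_weighted:
        return coords.mean(axis=0)
    w = np.array([_MASSES.get(structure.atoms[i].element.upper(), 12.011) for i in idx])
    return (w[:, None] * coords).sum(axis=0) / w.sum()


def mass_center_distance(structure: Structure, sel_a: Selection, sel_b: Selection,
                         mass_weighted: bool = False) -> float:
    """Euclidean distance (Å) between the centroids of two selections."""
    return float(np.linalg.norm(
        _centroid(structure, sel_a, mass_weighted)
        - _centroid(structure, sel_b, mass_weighted)))


_BETA_SSES = ("β1", "β2", "β3", "β4", "β5")


def _beta_layer_selection(structure: Structure, annotation: EdgeAnnotation,
                          chain: str, domain: str = "RRM1") -> Selection:
    sse_args = " ".join(_BETA_SSES)
    sel = select(structure, f"chain {chain} and domain {domain} and name CA "
                            f"and sse {sse_args}", annotation)
    if len(sel) == 0:
        raise ValueError(f"no annotated {domain} β-strand Cα atoms on chain {chain}")
    return sel


def sheet_layer_distance(dimer: Structure | StructureEnsemble,
                         annotation: EdgeAnnotation,
                         chains: tuple[str, str] | None = None,
                         domain: str = "RRM1"):
    """Centroid separation of the two monomers' β-sheet layers (Å).

    The layer is the Cα set of the annotated β1–β5 strands of ``domain``
    (RRM1 by default) in each monomer.  Given an ensemble, returns the
    per-frame series as an ndarray.
    """
    topo = dimer.topology if isinstance(dimer, StructureEnsemble) else dimer
    if chains is None:
        ids = topo.chain_ids
        if len(ids) != 2:
            raise ValueError(
                f"dimer has {len(ids)} chains; pass the two monomer chains explicitly")
        chains = (ids[0], ids[1])
    sa = _beta_layer_selection(topo, annotation, chains[0], domain)
    sb = _beta_layer_selection(topo, annotation, chains[1], domain)
    if isinstance(dimer, StructureEnsemble):
        ca = dimer.xyz[:, sa.asarray()].mean(axis=1)
        cb = dimer.xyz[:, sb.asarray()].mean(axis=1)
        return np.linalg.norm(ca - cb, axis=1)
    return mass_center_distance(dimer, sa, sb)


def classify_dimer_mode(dimer: Structure, annotation: EdgeAnnotation,
                        contact_cutoff: float = 4.5,
                        chains: tuple[str, str] | None = None) -> DimerMode:
    """Classify a dimer's binding mode from inter-monomer edge contacts.

    Counts residue pairs with any heavy-atom distance below ``contact_cutoff``
    (default 4.5 Å), attributes each contacting residue to its annotated
    edge, and labels the dimer by the dominant edge–edge pair.  Shoulder-to-
    head contacts are refined to SβH1α1-like / SβH1α2-like by the dominant
    secondary-structure element (α1 vs α2) on the head-1 side.
    """
    if chains is None:
        ids = dimer.chain_ids
        if len(ids) != 2:
            raise ValueError(
                f"dimer has {len(ids)} chains; pass the two monomer chains explicitly")
        chains = (ids[0], ids[1])

    heavy_a = [i for i, a in enumerate(dimer.atoms)
               if a.chain_id == chains[0] and a.element.upper() != "H"]
    heavy_b = [i for i, a in enumerate(dimer.atoms)
               if a.chain_id == chains[1] and a.element.upper() != "H"]
    if not heavy_a or not heavy_b:
        raise ValueError("both monomer chains must contain heavy atoms")
    coords = dimer.coords
    D = cdist(coords[heavy_a], coords[heavy_b])
    ii, jj = np.nonzero(D < contact_cutoff)

    edges = [e for e in ("shoulder12-α", "shoulder12-β", "head-1", "head-2", "none")]
    counts = pd.DataFrame(0, index=edges, columns=edges)
    sse_votes: dict[str, int] = {}
    contact_pairs = set()
    for i, j in zip(ii, jj):
        atom_a = dimer.atoms[heavy_a[i]]
        atom_b = dimer.atoms[heavy_b[j]]
        pair = ((atom_a.chain_id, atom_a.res_id), (atom_b.chain_id, atom_b.res_id))
        edge_a = annotation.edge_of(atom_a.chain_id, atom_a.res_id)
        edge_b = annotation.edge_of(atom_b.chain_id, atom_b.res_id)
        if pair in contact_pairs:
            continue
        contact_pairs.add(pair)
        counts.loc[edge_a, edge_b] += 1
        for chain, res, edge in ((atom_a.chain_id, atom_a.res_id, edge_a),
                                 (atom_b.chain_id, atom_b.res_id, edge_b)):
            if edge == "head-1":
                sse = annotation.sse_of(chain, res)
                sse_votes[sse] = sse_votes.get(sse, 0) + 1

    informative = counts.drop(index="none", columns="none")
    # fold unordered pairs together
    folded: dict[frozenset, int] = {}
    for ea in informative.index:
        for eb in informative.columns:
            c = int(informative.loc[ea, eb])
            if c:
                folded[frozenset([ea, eb])] = folded.get(frozenset([ea, eb]), 0) + c
    if not folded:
        return DimerMode("unclassified", "unclassified", counts)

    best_pair = max(folded, key=lambda k: folded[k])
    label, group = _MODE_TABLE.get(best_pair, ("unclassified", "unclassified"))
    if label == "SβH1":
        alpha1 = sse_votes.get("α1", 0)
        alpha2 = sse_votes.get("α2", 0)
        if alpha1 == alpha2 == 0:
            warnings.warn("head-1 contacts carry no α1/α2 annotation; "
                          "shoulder-to-head sub-label undetermined")
            label = "SβH1α1-like"
        else:
            label = "SβH1α1-like" if alpha1 >= alpha2 else "SβH1α2-like"
    return DimerMode(label, group, counts)
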