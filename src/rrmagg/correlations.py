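"""Dynamical cross-correlation maps (DCCM) over a coordinate ensemble.

C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩), with Δr the deviation of a
residue's representative atom (Cα by convention) from its ensemble-mean
position.  Values near +1 mark correlated motion (e.g. allosteric coupling
between the α1/α2 helices and the β-sheet layer of an RRM domain), values
near −1 anti-correlated motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Selection, StructureEnsemble
from .superpose import _fit_frames_to_mean

__all__ = ["DCCMatrix", "dccm", "submap"]


@dataclass
class DCCMatrix:
    """Symmetric cross-correlation matrix with residue labels."""

    values: np.ndarray = field(repr=False)
    labels: list[tuple[str, int]]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("DCCM must be square")
        if v.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.labels, names=["chain", "res_id"])
        return pd.DataFrame(self.values, index=idx, columns=idx)


def dccm(ensemble: StructureEnsemble, selection: Selection | None = None,
         fit: bool = True) -> DCCMatrix:
    """Cross-correlation map of one representative atom per residue.

    With ``fit`` the frames are first superposed onto the ensemble mean
    (two passes), removing global rigid motion.  A zero-variance atom gets
    zero off-diagonal correlations (diagonal stays 1) with a warning.
    """
    if ensemble.n_frames < 2:
        raise ValueError("DCCM requires at least 2 frames")
    if selection is None:
        idx = np.array([i for i, a in enumerate(ensemble.topology.atoms)
                        if a.name.upper() == "CA"], dtype=int)
        if idx.size == 0:
            idx = np.arange(ensemble.n_atoms)
    else:
        idx = selection.asarray()
        if idx.size == 0:
            raise ValueError("empty selection")
    labels = [(ensemble.topology.atoms[i].chain_id, ensemble.topology.atoms[i].res_id)
              for i in idx]
    if len(set(labels)) != len(labels):
        raise ValueError("selection must map one representative atom per residue")

    coords = ensemble.xyz[:, idx]
    if fit and idx.size >= 3:
        coords = _fit_frames_to_mean(coords)
    dev = coords - coords.mean(axis=0)
    cov = np.einsum("fid,fjd->ij", dev, dev) / dev.shape[0]
    var = np.diag(cov).copy()
    zero = var <= 1e-18  # Å²; numerically static atoms
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} zero-variance atoms; their correlations set to 0")
        var[zero] = 1.0
    denom = np.sqrt(np.outer(var, var))
    C = cov / denom
    C[zero, :] = 0.0
    C[:, zero] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return DCCMatrix(C, labels)


def submap(matrix: DCCMatrix, rows: list[tuple[str, int]],
           cols: list[tuple[str, int]]) -> pd.DataFrame:
    """Rectangular slice of the map by residue labels (labels preserved)."""
    if not rows or not cols:
        raise ValueError("empty row/column label list")
    df = matrix.to_frame()
    missing = [lab for lab in list(rows) + list(cols) if tuple(lab) not in df.index]
    if missing:
        raise KeyError(f"labels not in matrix: {missing[:5]}")
    return df.loc[[tuple(r) for r in rows], [tuple(c) for c in cols]]
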