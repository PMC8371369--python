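"""Rigid-body superposition, RMSD/RMSF series, and screw-axis decomposition.

A :class:`RigidTransform` (proper rotation + translation) is the currency of
assembly propagation: repeated application of one transform generates a
helical stack, and its :class:`ScrewParameters` (twist angle, axis, rise)
describe the aggregation axis of the resulting fibril-like model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Selection, Structure, StructureEnsemble

__all__ = [
    "RigidTransform",
    "ScrewParameters",
    "GeometryError",
    "kabsch",
    "rmsd",
    "rmsd_fitted",
    "rmsf",
    "screw_decompose",
    "screw_recompose",
]


class GeometryError(ValueError):
    """Raised for degenerate point configurations."""


@dataclass(frozen=True)
class RigidTransform:
    """x ↦ R·x + t with R a proper rotation (det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3×3")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation determinant is not +1 (improper rotation)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def about_axis(cls, angle_deg: float, axis: np.ndarray,
                   point: np.ndarray | None = None,
                   translation: np.ndarray | None = None) -> "RigidTransform":
        """Rotation by ``angle_deg`` about a (possibly offset) axis, then translate."""
        from scipy.spatial.transform import Rotation

        axis = np.asarray(axis, dtype=float)
        nrm = np.linalg.norm(axis)
        if nrm == 0:
            raise ValueError("zero rotation axis")
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / nrm).as_matrix()
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        if point is not None:
            p = np.asarray(point, dtype=float)
            t = t + p - R @ p
        return cls(R, t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def apply_structure(self, structure: Structure) -> Structure:
        return structure.with_coords(self.apply(structure.coords))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: first apply ``other``, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def power(self, n: int) -> "RigidTransform":
        out = RigidTransform.identity()
        base = self if n >= 0 else self.inverse()
        for _ in range(abs(n)):
            out = base.compose(out)
        return out


@dataclass(frozen=True)
class ScrewParameters:
    """Axis/angle/rise decomposition of a rigid transform.

    ``angle`` in degrees ∈ [0, 180]; ``rise`` is the signed translation along
    ``axis_direction``; ``axis_point`` is a point on the screw axis.
    """

    angle: float
    axis_direction: np.ndarray
    axis_point: np.ndarray
    rise: float

    def __post_init__(self):
        d = np.asarray(self.axis_direction, dtype=float).reshape(3)
        if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-8):
            raise ValueError("axis_direction must be unit norm")
        object.__setattr__(self, "axis_direction", d)
        object.__setattr__(self, "axis_point",
                           np.asarray(self.axis_point, dtype=float).reshape(3))


def kabsch(mobile: np.ndarray, reference: np.ndarray,
           weights: np.ndarray | None = None) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    SVD formulation with determinant correction so the result is always a
    proper rotation.  Returns the transform and the (weighted) RMSD after
    superposition.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError(f"point sets must both be (n, 3); got {P.shape}, {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise GeometryError("at least 3 points are required for superposition")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    cm = w @ P
    cr = w @ Q
    Pc = P - cm
    Qc = Q - cr
    H = (Pc * w[:, None]).T @ Qc
    U, S, Vt = np.linalg.svd(H)
    # rank-deficiency: all points collinear leaves the rotation underdetermined
    if S[1] < 1e-10 * max(S[0], 1e-30):
        raise GeometryError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    transform = RigidTransform(R, t)
    diff = transform.apply(P) - Q
    value = float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", diff, diff))))
    return transform, value


def rmsd(a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Plain (unfitted) RMSD between two equal-size coordinate sets."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise GeometryError("coordinate sets differ in shape")
    n = a.shape[0]
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, float) / np.sum(weights)
    diff = a - b
    return float(np.sqrt(np.sum(w * np.einsum("ij,ij->i", diff, diff))))


def _sel_indices(selection: Selection | np.ndarray | None, n_atoms: int) -> np.ndarray:
    if selection is None:
        return np.arange(n_atoms)
    if isinstance(selection, Selection):
        idx = selection.asarray()
    else:
        idx = np.asarray(selection, dtype=int)
    if idx.size == 0:
        raise ValueError("empty selection")
    if idx.min() < 0 or idx.max() >= n_atoms:
        raise IndexError("selection index out of range")
    return idx


def rmsd_fitted(ensemble: StructureEnsemble, selection: Selection | None = None,
                reference_frame: int = 0, fit: bool = True) -> np.ndarray:
    """Per-frame RMSD of a selection against a reference frame.

    With ``fit`` enabled every frame is first rigidly superposed onto the
    reference over the same selection, so pure rigid drift contributes zero.
    """
    idx = _sel_indices(selection, ensemble.n_atoms)
    ref = ensemble.xyz[reference_frame, idx]
    out = np.empty(ensemble.n_frames)
    for k in range(ensemble.n_frames):
        mob = ensemble.xyz[k, idx]
        if fit:
            _, out[k] = kabsch(mob, ref)
        else:
            out[k] = rmsd(mob, ref)
    return out


def _fit_frames_to_mean(coords: np.ndarray, passes: int = 2) -> np.ndarray:
    """Superpose every frame onto the running ensemble mean (iterated)."""
    fitted = coords.copy()
    for _ in range(passes):
        mean = fitted.mean(axis=0)
        for k in range(fitted.shape[0]):
            tr, _ = kabsch(fitted[k], mean)
            fitted[k] = tr.apply(fitted[k])
    return fitted


def rmsf(ensemble: StructureEnsemble, selection: Selection | None = None,
         fit_to_mean: bool = True, per_residue: bool = True):
    """Root-mean-square fluctuation about the ensemble-mean position.

    By convention the representative atom is Cα when ``selection`` picks one
    atom per residue; with ``per_residue`` the result is a pandas Series keyed
    by (chain, res_id), otherwise a per-atom array.  Frames are superposed
    onto the ensemble mean (two passes) before measuring fluctuations.
    """
    import pandas as pd

    if ensemble.n_frames < 2:
        raise ValueError("RMSF requires at least 2 frames")
    idx = _sel_indices(selection, ensemble.n_atoms)
    coords = ensemble.xyz[:, idx]
    if fit_to_mean and len(idx) >= 3:
        coords = _fit_frames_to_mean(coords)
    mean = coords.mean(axis=0)
    dev = coords - mean
    per_atom = np.sqrt(np.mean(np.sum(dev ** 2, axis=2), axis=0))
    if not per_residue:
        return per_atom
    keys = [(ensemble.topology.atoms[i].chain_id, ensemble.topology.atoms[i].res_id)
            for i in idx]
    ser = pd.Series(per_atom, index=pd.MultiIndex.from_tuples(keys, names=["chain", "res_id"]))
    # average atoms sharing a residue (e.g. backbone option)
    return ser.groupby(level=[0, 1], sort=False).apply(
        lambda v: float(np.sqrt(np.mean(np.square(v)))))


_DEGENERATE_ANGLE = 1e-8  # degrees below which the rotation is treated as none


def screw_decompose(t: RigidTransform) -> ScrewParameters:
    """Decompose a rigid transform into screw (axis, angle, rise) form.

    angle = arccos((trace R − 1)/2).  For the degenerate pure-translation
    limit the axis direction defaults to the normalized translation (or +z
    when the translation is zero), keeping the decomposition continuous.
    """
    R = t.rotation
    tr = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.degrees(np.arccos(tr)))

    if angle < _DEGENERATE_ANGLE:
        nrm = np.linalg.norm(t.translation)
        axis = t.translation / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])
        return ScrewParameters(0.0, axis, np.zeros(3), float(nrm))

    if angle > 180.0 - 1e-6:
        # axis from the eigenvector of R with eigenvalue +1
        w, v = np.linalg.eigh((R + R.T) / 2.0)
        axis = v[:, np.argmax(w)]
    else:
        axis = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
        axis = axis / (2.0 * np.sin(np.radians(angle)))
    axis = axis / np.linalg.norm(axis)
    # axis orientation is fixed by the right-hand rule for positive angle;
    # rise carries the sign (flipping the axis would invert the rotation)
    rise = float(axis @ t.translation)
    # point on the axis: solve (I − R) p = t_perp in the plane ⊥ axis
    t_perp = t.translation - (t.translation @ axis) * axis
    A = np.eye(3) - R
    p, *_ = np.linalg.lstsq(A, t_perp, rcond=None)
    p = p - (p @ axis) * axis
    return ScrewParameters(angle, axis, p, rise)


def screw_recompose(params: ScrewParameters) -> RigidTransform:
    """Rebuild the rigid transform from its screw parameters."""
    base = RigidTransform.about_axis(params.angle, params.axis_direction,
                                     point=params.axis_point)
    t = base.translation + params.rise * params.axis_direction
    return RigidTransform(base.rotation, t)
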