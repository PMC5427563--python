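"""Rigid transforms, Kabsch superposition and RMSD primitives."""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

__all__ = ["RigidTransform", "superpose", "apply_transform", "rmsd"]

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body map x -> R x + t (rotation then translation)."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-6):
            raise ValueError("rotation must be proper (det +1, no reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply `other` first, then `self`."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain paired RMSD in Angstroms; no superposition is performed."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3 or len(a) < 1:
        raise ValueError("coordinate sets must be matching (n, 3) arrays, n >= 1")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose(moving: np.ndarray, fixed: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares optimal rigid superposition (Kabsch) of paired point sets.

    Returns the proper rigid transform mapping `moving` onto `fixed` and the
    post-superposition RMSD. Reflections are excluded by the SVD sign
    correction. Requires >= 3 points spanning at least a plane.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = len(moving)
    if n < 3:
        raise ValueError("at least 3 points are required")

    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    P = moving - cm
    Q = fixed - cf
    if np.linalg.matrix_rank(P, tol=1e-8) < 2 or np.linalg.matrix_rank(Q, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")

    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    transform = RigidTransform(R, t)
    return transform, rmsd(transform.apply(moving), fixed)


def apply_transform(transform: RigidTransform, obj):
    """Apply a rigid transform to a coordinate array or a structure object.

    Structures (anything with `.residues`) are deep-copied; atom coordinates
    are mapped in place on the copy. Arrays return a transformed copy.
    """
    if isinstance(obj, np.ndarray):
        return transform.apply(obj)
    if hasattr(obj, "receptor"):  # DimerStructure
        new = copy.deepcopy(obj)
        for chain in (new.receptor, new.ligand):
            _transform_chain(transform, chain)
        return new
    if hasattr(obj, "residues"):  # ChainStructure
        new = copy.deepcopy(obj)
        _transform_chain(transform, new)
        return new
    raise TypeError(f"cannot transform object of type {type(obj).__name__}")


def _transform_chain(transform: RigidTransform, chain) -> None:
    from dockppi.structio import AtomRecord

    for res in chain.residues:
        res.atoms = [
            AtomRecord(a.atom_name, a.element, transform.apply(a.coords))
            for a in res.atoms
        ]
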