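"""Rigid-body superposition (Kabsch) under a fixed atom correspondence.

Transform convention, used everywhere in this package and stated in all
serialized output: ``y = R @ x + t`` carries coordinates expressed in the
frame of structure B into the frame of structure A.  Rotations are proper
(det +1); mirror images are never produced, since physical ligands cannot
be reflected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
import numpy as np

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "DegenerateGeometryError",
    "kabsch",
    "rmsd_under_transform",
]

CONVENTION = "y=Rx+t, B->A"


class DegenerateGeometryError(ValueError):
    """Raised when mapped points are collinear (superposition under-determined)."""


@dataclass
class RigidTransform:
    rotation: np.ndarray  # (3, 3), proper
    translation: np.ndarray  # (3,), Å

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if abs(self.rotation.T @ self.rotation - np.eye(3)).max() > 1e-8:
            raise ValueError("rotation is not orthogonal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation is improper (reflection)")

    @classmethod
    def _from_valid(cls, rotation: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        """Construct without re-validating (rotation known proper)."""
        obj = object.__new__(cls)
        obj.rotation = rotation
        obj.translation = translation
        return obj

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: first apply ``other``, then ``self``."""
        return RigidTransform._from_valid(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform._from_valid(
            self.rotation.T, -self.rotation.T @ self.translation
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "convention": CONVENTION,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["rotation"]), np.array(d["translation"]))

    @classmethod
    def from_json(cls, s: str) -> "RigidTransform":
        return cls.from_dict(json.loads(s))


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float  # Å


def _mapped(coordsA: np.ndarray, coordsB: np.ndarray, mapping) -> tuple[np.ndarray, np.ndarray]:
    coordsA = np.asarray(coordsA, dtype=float)
    coordsB = np.asarray(coordsB, dtype=float)
    pairs = mapping.pairs if hasattr(mapping, "pairs") else list(mapping)
    ia = [p[0] for p in pairs]
    ib = [p[1] for p in pairs]
    if max(ia, default=-1) >= len(coordsA) or max(ib, default=-1) >= len(coordsB):
        raise IndexError("mapping references atoms missing from the coordinate sets")
    return coordsA[ia], coordsB[ib]


def _is_collinear(points: np.ndarray, tol: float = 1e-8) -> bool:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return bool(s[1] <= tol * max(s[0], 1.0))


def kabsch(coordsA: np.ndarray, coordsB: np.ndarray, mapping) -> SuperpositionResult:
    """Optimal proper-rotation superposition of mapped B atoms onto A.

    Returns the :class:`RigidTransform` minimizing the RMSD over mapped
    pairs, together with that minimal RMSD.  Requires at least 3 mapped,
    non-collinear atoms on each side.  Implementation: SVD of the
    cross-covariance with the determinant sign correction, so the rotation
    is always proper (no reflection).
    """
    A, B = _mapped(coordsA, coordsB, mapping)
    if len(A) < 3:
        raise DegenerateGeometryError("need at least 3 mapped atoms")
    cA, cB = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - cA, B - cB
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    # collinear mapped atoms (in either set) collapse the cross-covariance
    # to rank <= 1 and leave the rotation under-determined
    if S[1] <= 1e-8 * max(S[0], 1.0) and (_is_collinear(A0) or _is_collinear(B0)):
        raise DegenerateGeometryError("mapped atoms are collinear")
    d = np.sign(np.linalg.det(Vt.T @ U.T)) or 1.0
    R = (Vt.T * np.array([1.0, 1.0, d])) @ U.T
    t = cA - R @ cB
    diff = A0 - B0 @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return SuperpositionResult(RigidTransform._from_valid(R, t), rmsd)


def rmsd_under_transform(
    coordsA: np.ndarray,
    coordsB: np.ndarray,
    mapping,
    transform: RigidTransform,
) -> float:
    """RMSD over mapped pairs after applying ``transform`` to B (no re-fit)."""
    A, B = _mapped(coordsA, coordsB, mapping)
    if len(A) < 1:
        raise ValueError("mapping is empty")
    diff = A - transform.apply(B)
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
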