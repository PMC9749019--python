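"""Rigid-body transforms (proper rotation + translation) in Angstrom units.

Both the receptor and the ligand carry a :class:`RigidTransform` during a
docking session; the nonbonded kernel maps receptor atoms into the ligand's
local frame for grid queries instead of rebuilding the ligand grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> rotation @ x + translation."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValidationError("non-finite entries in rigid transform")
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-6 or np.linalg.det(R) < 0:
            raise ValidationError("rotation must be orthonormal with det +1")

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform()

    @staticmethod
    def from_axis_angle(axis, angle_rad: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValidationError("zero rotation axis")
        k = axis / n
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)
        return RigidTransform(R, np.asarray(translation, dtype=float))

    @staticmethod
    def random(rng: np.random.Generator, max_translation: float = 1.0,
               max_angle_rad: float = np.pi) -> "RigidTransform":
        """Uniform random axis, uniform angle in [0, max_angle_rad]."""
        axis = rng.normal(size=3)
        angle = rng.uniform(0.0, max_angle_rad)
        t = rng.uniform(-max_translation, max_translation, size=3)
        return RigidTransform.from_axis_angle(axis, angle, t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N,3) array or a single 3-vector."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def is_identity(self, tol: float = 0.0) -> bool:
        return (np.abs(self.rotation - np.eye(3)).max() <= tol
                and np.abs(self.translation).max() <= tol)

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(), "translation": self.translation.tolist()}

    @staticmethod
    def from_dict(d: dict) -> "RigidTransform":
        return RigidTransform(np.asarray(d["rotation"], dtype=float),
                              np.asarray(d["translation"], dtype=float))
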