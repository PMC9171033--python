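"""Rigid (proper orthogonal) transforms and Kabsch least-squares alignment."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``p -> R p + t`` with rotation ``R`` and translation ``t``.

    ``R`` must be orthonormal with determinant +1 (no reflections); units of the
    translation follow the mesh coordinates (mm).
    """

    rotation: np.ndarray
    translation: np.ndarray
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not self._validated:
            err = np.abs(R.T @ R - np.eye(3)).max()
            if err > 1e-6:
                raise DegenerateGeometryError(
                    f"rotation matrix not orthonormal (max |R^T R - I| = {err:.2e})"
                )
            if abs(np.linalg.det(R) - 1.0) > 1e-6:
                raise DegenerateGeometryError(
                    f"rotation determinant {np.linalg.det(R):.6f} != +1 (reflection?)"
                )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), _validated=True)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply the transform to an (n, 3) array (or a single 3-vector)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
            _validated=True,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation, _validated=True)

    def with_translation(self, translation: np.ndarray) -> "RigidTransform":
        return RigidTransform(self.rotation, translation, _validated=True)


def kabsch(source: np.ndarray, target: np.ndarray, *, check_degenerate: bool = False
           ) -> RigidTransform:
    """Least-squares rigid transform mapping ``source`` points onto ``target``.

    Standard SVD (Kabsch) solution with the reflection fix.  With
    ``check_degenerate`` a collinear source/target configuration (rotation about
    the common axis unobservable) raises :class:`DegenerateGeometryError`.
    """
    P = np.asarray(source, float)
    Q = np.asarray(target, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("kabsch expects two equally shaped (n, 3) arrays")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    if check_degenerate and (S[1] <= 1e-12 * max(S[0], 1e-300) or S[0] == 0.0):
        raise DegenerateGeometryError(
            "point set effectively collinear; rigid alignment underdetermined"
        )
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    # Re-orthonormalize to keep the invariant tight under accumulated rounding.
    Ru, _, Rvt = np.linalg.svd(R)
    R = Ru @ Rvt
    return RigidTransform(R, cq - R @ cp, _validated=True)
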