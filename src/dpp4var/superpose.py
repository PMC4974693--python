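"""Rigid-body least-squares superposition (Kabsch) and RMSD.

The RMSD between two matched coordinate sets is

    RMSD = sqrt( (1/N) * sum_i chi_i^2 )

where chi_i is the post-superposition distance of the i-th atom pair
and N the number of pairs.  :func:`superpose_kabsch` returns the proper
rigid motion (rotation with determinant +1, plus translation) that
globally minimizes this quantity, computed with the SVD form of the
Kabsch algorithm including the determinant correction that excludes
reflections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Superposition", "SuperpositionError", "superpose_kabsch", "pair_combinations"]

_DEGENERACY_TOL = 1e-8


class SuperpositionError(ValueError):
    pass


@dataclass
class Superposition:
    """A fitted rigid motion ``x -> rotation @ x + translation``."""

    rotation: np.ndarray  # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)
    rmsd: float
    n_pairs: int
    residuals: np.ndarray  # per-pair distances chi_i after the transform

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation


def superpose_kabsch(moving: np.ndarray, fixed: np.ndarray) -> Superposition:
    """Least-squares fit of ``moving`` onto ``fixed``.

    Both arguments are (N, 3) arrays of matched coordinates, N >= 3 and
    not collinear.  The returned transform minimizes the RMSD over all
    proper rigid motions; the optimal translation maps the centroid of
    ``moving`` onto the centroid of ``fixed``.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise SuperpositionError(
            f"length mismatch: {moving.shape} vs {fixed.shape}"
        )
    if moving.ndim != 2 or moving.shape[1] != 3:
        raise SuperpositionError("coordinates must be (N, 3) arrays")
    n = moving.shape[0]
    if n < 3:
        raise SuperpositionError("underdetermined superposition: fewer than 3 points")

    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    mv = moving - cm
    fx = fixed - cf

    # collinear points leave a free rotation about the common axis
    for label, arr in (("moving", mv), ("fixed", fx)):
        s = np.linalg.svd(arr, compute_uv=False)
        if s[1] < _DEGENERACY_TOL * max(1.0, s[0]):
            raise SuperpositionError(
                f"underdetermined superposition: {label} points are collinear"
            )

    h = mv.T @ fx
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cf - rot @ cm

    residuals = np.linalg.norm(moving @ rot.T + trans - fixed, axis=1)
    rmsd = float(np.sqrt(np.mean(residuals**2)))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd,
                         n_pairs=n, residuals=residuals)


def pair_combinations(n_units: int) -> int:
    """Number of unordered unit pairs, n(n-1)/2."""
    if n_units < 0:
        raise ValueError("n_units must be non-negative")
    return n_units * (n_units - 1) // 2
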