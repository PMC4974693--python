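"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the superposition
oracle is a derivative-free search over rotation space (coarse
axis-angle grid followed by pattern-search refinement) with the
translation fixed at the centroid match, and the surface-area oracle is
the closed-form spherical-cap formula for two intersecting spheres.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial.transform import Rotation


def _fib_directions(n):
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    th = i * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(1.0 - z * z)
    return np.column_stack([rho * np.cos(th), rho * np.sin(th), z])


def grid_min_rmsd(moving: np.ndarray, fixed: np.ndarray) -> float:
    """Global minimum RMSD over proper rotations, by grid + refinement."""
    mv = moving - moving.mean(axis=0)
    fx = fixed - fixed.mean(axis=0)

    def rmsd_of(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        return math.sqrt(np.mean(np.sum((mv @ r.T - fx) ** 2, axis=1)))

    best_rv = np.zeros(3)
    best = rmsd_of(best_rv)
    for axis in _fib_directions(80):
        for angle in np.arange(math.radians(10), math.pi + 1e-9, math.radians(10)):
            rv = axis * angle
            v = rmsd_of(rv)
            if v < best:
                best, best_rv = v, rv

    offsets = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                        for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)], dtype=float)
    h = math.radians(5)
    while h > 1e-9:
        improved = False
        for off in offsets:
            rv = best_rv + h * off
            v = rmsd_of(rv)
            if v < best - 1e-15:
                best, best_rv = v, rv
                improved = True
        if not improved:
            h *= 0.5
    return best


def two_sphere_area(r1: float, r2: float, d: float) -> float:
    """Total exposed area of two spheres with centre distance d."""
    if d >= r1 + r2:
        return 4 * math.pi * (r1 * r1 + r2 * r2)
    if d <= abs(r1 - r2):
        big = max(r1, r2)
        return 4 * math.pi * big * big
    out = 0.0
    for a, b in ((r1, r2), (r2, r1)):
        h = a - (d * d + a * a - b * b) / (2 * d)
        out += 4 * math.pi * a * a - 2 * math.pi * a * h
    return out
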