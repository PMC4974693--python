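"""Per-residue solvent-accessible surface area (Shrake-Rupley).

Each atom is given a sphere of radius (vdW radius + probe radius)
sampled with a deterministic spherical Fibonacci lattice; a sample
point is exposed when it falls outside every neighbour's sphere, and
the atom's area is the exposed fraction of its sphere.  Residue areas
are atom sums over protein heavy atoms only — waters and the ligand
are stripped first, so the profile describes the protein surface as it
would be seen by solvent with the inhibitor removed.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import StructureUnit

__all__ = ["VDW_RADII", "SasaError", "fibonacci_sphere", "shrake_rupley",
           "residue_sasa", "ensemble_mean_sasa"]

#: van der Waals radii in Angstrom
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960


class SasaError(ValueError):
    pass


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere lattice (n_points, 3)."""
    i = np.arange(n_points)
    z = 1.0 - (2.0 * i + 1.0) / n_points
    theta = i * math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def shrake_rupley(
    coords: np.ndarray,
    elements: list[str],
    *,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii: dict[str, float] = VDW_RADII,
) -> np.ndarray:
    """Per-atom accessible area (A^2) for heavy atoms.

    Unknown elements raise :class:`SasaError` naming the element.
    """
    coords = np.asarray(coords, dtype=float)
    missing = sorted({e for e in elements if e.upper() not in radii})
    if missing:
        raise SasaError(f"no van der Waals radius for element(s): {', '.join(missing)}")
    r = np.array([radii[e.upper()] for e in elements]) + probe_radius
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * r.max()
    areas = np.zeros(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + r[i] * sphere
        exposed = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], max_reach):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 > r[j] ** 2
            if not exposed.any():
                break
        areas[i] = 4.0 * math.pi * r[i] ** 2 * exposed.sum() / n_points
    return areas


def residue_sasa(
    unit: StructureUnit,
    *,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii: dict[str, float] = VDW_RADII,
) -> dict[int, float]:
    """Exposed area per residue of one unit (waters and ligand excluded)."""
    atoms = unit.protein_atoms()
    if not atoms:
        raise SasaError(f"unit {unit.unit_id} has no protein atoms")
    coords = np.array([a.position for a in atoms])
    areas = shrake_rupley(coords, [a.element for a in atoms],
                          probe_radius=probe_radius, n_points=n_points, radii=radii)
    out: dict[int, float] = {}
    k = 0
    for res in unit.residues:
        out[res.number] = float(areas[k:k + len(res.atoms)].sum())
        k += len(res.atoms)
    return out


def ensemble_mean_sasa(
    units: list[StructureUnit],
    *,
    probe_radius: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> dict[int, float]:
    """Per-residue exposed area averaged over the units where present."""
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for u in units:
        for num, area in residue_sasa(u, probe_radius=probe_radius,
                                      n_points=n_points).items():
            sums[num] = sums.get(num, 0.0) + area
            counts[num] = counts.get(num, 0) + 1
    return {num: sums[num] / counts[num] for num in sorted(sums)}
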