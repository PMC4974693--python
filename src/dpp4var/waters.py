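"""Conserved crystallographic water detection.

Water oxygens from two superposed units are *identical* when they lie
within 1 A of each other.  Across an ensemble this pairwise notion is
extended to consensus sites by greedy centroid clustering in a common
reference frame:

1. every unit's waters are mapped into the frame of a reference unit
   via the global Calpha superposition;
2. the pooled waters are scanned for the point with the most
   neighbours within the identity radius (ties: lowest unit id, then
   lowest water serial);
3. a site is formed by taking, for each unit, its nearest pooled water
   within the radius of the seed (at most one member per unit), the
   centroid is recomputed once, members are re-assigned around it, and
   the chosen members leave the pool;
4. repeat until the pool is empty.

A site's *support* is its member count; units that deposited no waters
at all are excluded from the support denominator.  Annotation adds the
proximity flags (binding area < 4 A, ligand < 5 A, both measured in
each member's own original coordinates) and the B-factor comparison
against the member units' water and protein averages — conserved
hydration waters typically sit below both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .contacts import BindingArea
from .structure_io import Atom, StructureUnit
from .superpose import superpose_kabsch
from .variation import _shared_calpha

__all__ = ["WaterSite", "WaterSiteError", "consensus_water_sites", "annotate_water_sites"]

DEFAULT_MIN_SUPPORT_FRACTION = 0.427


class WaterSiteError(ValueError):
    pass


@dataclass
class WaterSite:
    site_id: int
    centroid: np.ndarray  # reference frame, Angstrom
    support: int
    members: dict[str, tuple[Atom, float]]  # unit_id -> (water atom, dist to centroid)
    mean_b: float = 0.0
    near_binding_area: bool | None = None
    near_ligand_count: int | None = None
    b_below_water_avg: bool | None = None
    b_below_protein_avg: bool | None = None


def _transform_waters(units, reference):
    """Pool of (unit_id, serial, transformed xyz, atom) in reference frame."""
    pool = []
    ref_id = reference.unit_id
    for u in units:
        if u.unit_id == ref_id:
            for w in u.waters:
                pool.append((u.unit_id, w.serial, np.array(w.position), w))
            continue
        shared, xr, xu = _shared_calpha(reference, u)
        if len(shared) < 3:
            raise WaterSiteError(
                f"unit {u.unit_id} shares <3 Calpha atoms with the reference"
            )
        sup = superpose_kabsch(xu, xr)
        for w in u.waters:
            pool.append((u.unit_id, w.serial, sup.apply(w.position), w))
    return pool


def consensus_water_sites(
    units: list[StructureUnit],
    *,
    reference_unit: str | None = None,
    identity_radius: float = 1.0,
    min_support: int | None = None,
    min_support_fraction: float | None = None,
) -> list[WaterSite]:
    """Greedy clustering of superposed waters into consensus sites.

    ``min_support`` (a count) takes precedence over
    ``min_support_fraction`` (applied to the number of water-bearing
    units, rounded to nearest); when neither is given the default
    fraction 0.427 is used.  Pass ``min_support=1`` to obtain every
    site.  Sites are returned sorted by support (descending), ties by
    site id (seeding order).
    """
    if identity_radius <= 0:
        raise WaterSiteError("identity_radius must be positive")
    wet_units = [u for u in units if u.waters]
    if len(wet_units) < 1:
        raise WaterSiteError("no unit has waters")
    if reference_unit is None:
        reference = units[0]
    else:
        matches = [u for u in units if u.unit_id == reference_unit]
        if not matches:
            raise WaterSiteError(f"reference unit {reference_unit!r} not found")
        reference = matches[0]
    if min_support is None:
        frac = (DEFAULT_MIN_SUPPORT_FRACTION
                if min_support_fraction is None else min_support_fraction)
        min_support = max(1, round(frac * len(wet_units)))

    pool = _transform_waters(wet_units, reference)
    sites: list[WaterSite] = []
    site_id = 0
    while pool:
        xyz = np.array([p[2] for p in pool])
        tree = cKDTree(xyz)
        neighbours = tree.query_ball_point(xyz, identity_radius)
        counts = np.array([len(nb) for nb in neighbours])
        order = sorted(
            range(len(pool)),
            key=lambda i: (-counts[i], pool[i][0], pool[i][1]),
        )
        seed_idx = order[0]

        def pick_members(center):
            cand = tree.query_ball_point(center, identity_radius)
            best_per_unit: dict[str, int] = {}
            for i in cand:
                uid = pool[i][0]
                d = np.linalg.norm(xyz[i] - center)
                j = best_per_unit.get(uid)
                if j is None or d < np.linalg.norm(xyz[j] - center) or (
                    math.isclose(d, float(np.linalg.norm(xyz[j] - center)))
                    and pool[i][1] < pool[j][1]
                ):
                    best_per_unit[uid] = i
            return sorted(best_per_unit.values())

        # centroid recomputed once after the seed pass; it stays the site
        # centre after re-assignment so every member is within the radius
        first_pass = pick_members(xyz[seed_idx])
        centroid = xyz[first_pass].mean(axis=0)
        members_idx = pick_members(centroid)
        if not members_idx:
            members_idx = first_pass
            centroid = xyz[seed_idx]
        members = {
            pool[i][0]: (pool[i][3], float(np.linalg.norm(xyz[i] - centroid)))
            for i in members_idx
        }
        sites.append(
            WaterSite(
                site_id=site_id,
                centroid=centroid,
                support=len(members),
                members=members,
                mean_b=float(np.mean([pool[i][3].b_factor for i in members_idx])),
            )
        )
        site_id += 1
        taken = set(members_idx)
        pool = [p for i, p in enumerate(pool) if i not in taken]

    sites = [s for s in sites if s.support >= min_support]
    sites.sort(key=lambda s: (-s.support, s.site_id))
    return sites


def annotate_water_sites(
    sites: list[WaterSite],
    binding_area: BindingArea | None,
    units: list[StructureUnit],
    *,
    area_cutoff: float = 4.0,
    ligand_cutoff: float = 5.0,
) -> list[WaterSite]:
    """Attach proximity and B-factor annotations to each site (in place).

    ``near_binding_area`` is true when any member water lies within
    ``area_cutoff`` of a heavy atom of an extended-set residue *in that
    member's own unit*; ``near_ligand_count`` counts member units whose
    ligand has a heavy atom within ``ligand_cutoff`` of the member
    water.  The B-factor flags compare the site's mean member B against
    the mean B of all water oxygens and of all protein heavy atoms in
    the member units.
    """
    by_id = {u.unit_id: u for u in units}
    area_set = binding_area.extended_set if binding_area is not None else set()

    area_coords: dict[str, np.ndarray] = {}
    water_b: dict[str, float] = {}
    protein_b: dict[str, float] = {}
    for u in units:
        pts = [a.position for r in u.residues if r.number in area_set for a in r.atoms]
        area_coords[u.unit_id] = np.array(pts) if pts else np.empty((0, 3))
        if u.waters:
            water_b[u.unit_id] = float(np.mean([w.b_factor for w in u.waters]))
        protein_b[u.unit_id] = float(
            np.mean([a.b_factor for a in u.protein_atoms()])
        )

    for site in sites:
        near_area = False
        near_lig = 0
        w_avgs, p_avgs = [], []
        for uid, (atom, _) in site.members.items():
            u = by_id.get(uid)
            if u is None:
                continue
            if len(area_coords[uid]) and _min_norm(area_coords[uid], atom.position) < area_cutoff:
                near_area = True
            if u.ligand is not None and len(u.ligand.atoms):
                if _min_norm(u.ligand.coords(), atom.position) < ligand_cutoff:
                    near_lig += 1
            if uid in water_b:
                w_avgs.append(water_b[uid])
            p_avgs.append(protein_b[uid])
        site.near_binding_area = near_area
        site.near_ligand_count = near_lig
        site.b_below_water_avg = bool(w_avgs) and site.mean_b < float(np.mean(w_avgs))
        site.b_below_protein_avg = bool(p_avgs) and site.mean_b < float(np.mean(p_avgs))
    return sites


def _min_norm(targets: np.ndarray, point: np.ndarray) -> float:
    return float(np.linalg.norm(targets - point, axis=1).min())
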