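"""Binding-area definition and binding-mode classification.

The inhibitor binding area is defined purely by contact frequency: a
residue belongs to the *core* set when more than ``high_fraction`` of
the distinct inhibitors have a heavy atom within ``cutoff`` of it, and
to the *extended* set above ``low_fraction``.  Distinct inhibitors are
counted once even when the same compound appears in several units, so
both the per-inhibitor fractions and raw per-unit counts are reported.

Binding modes are fixed geometric motifs observed between inhibitors
and specific active-site residues:

* **amine network** — one primary or secondary amine nitrogen of the
  inhibitor simultaneously within 4 A of a Glu205 Oepsilon, within 4 A
  of a Glu206 Oepsilon and within 5 A of the Tyr662 Oeta.
* **polar anchor** — an inhibitor O, N or halogen atom within 4 A of an
  Arg125 Neta or the Asn710 Ndelta/Odelta (the amide O/N of Asn710 swap
  between deposits, so both atoms qualify).
* **covalent Ser630** — the Ser630 Ogamma within 3 A of an inhibitor
  carbon (nitrile warheads).

The role residues are supplied through a ``site_map`` so the same
classifier runs on synthetic systems with arbitrary numbering.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .structure_io import Ligand, StructureUnit

__all__ = [
    "BindingArea",
    "BindingModeRecord",
    "ContactError",
    "DEFAULT_SITE_MAP",
    "binding_area_from_contacts",
    "classify_binding_modes",
]

HALOGENS = frozenset({"F", "CL", "BR", "I"})

#: default role numbering (the study protein's author numbering)
DEFAULT_SITE_MAP: dict[str, int] = {
    "glu205": 205,
    "glu206": 206,
    "tyr662": 662,
    "arg125": 125,
    "asn710": 710,
    "ser630": 630,
}

_ROLE_ATOMS = {
    "glu205": ("OE1", "OE2"),
    "glu206": ("OE1", "OE2"),
    "tyr662": ("OH",),
    "arg125": ("NH1", "NH2"),
    "asn710": ("ND2", "OD1"),
    "ser630": ("OG",),
}

BOND_DISTANCE = 1.8  # heavy atoms closer than this are treated as bonded


class ContactError(ValueError):
    pass


@dataclass
class BindingArea:
    per_residue_contact_fraction: dict[int, float]
    core_set: set[int]
    extended_set: set[int]
    per_unit_counts: dict[int, int]  # residue -> number of units in contact
    n_ligands: int
    n_units: int
    cutoff: float
    high_fraction: float
    low_fraction: float


@dataclass
class BindingModeRecord:
    unit_id: str
    amine_network: bool = False
    amine_atom: str | None = None
    amine_distances: dict[str, float] = field(default_factory=dict)
    polar_anchor: bool = False
    anchor_atom: str | None = None
    anchor_partner: str | None = None
    anchor_distance: float | None = None
    arg125_contact: bool = False
    asn710_contact: bool = False
    covalent_ser630: bool = False
    ser630_distance: float | None = None


def _residue_contacts(unit: StructureUnit, cutoff: float) -> set[int]:
    """Residue numbers with >=1 heavy-atom pair below cutoff to the ligand."""
    lig_xyz = unit.ligand.coords()
    out = set()
    for res in unit.residues:
        d = np.linalg.norm(
            res.coords()[:, None, :] - lig_xyz[None, :, :], axis=-1
        ).min()
        if d < cutoff:
            out.add(res.number)
    return out


def binding_area_from_contacts(
    units: list[StructureUnit],
    *,
    cutoff: float = 4.0,
    high_fraction: float = 0.70,
    low_fraction: float = 0.30,
    per_ligand: bool = True,
) -> BindingArea:
    """Contact-frequency binding area over an ensemble.

    With ``per_ligand`` (default) the denominator is the number of
    distinct ligand compounds; a compound counts as contacting a
    residue when any of its units does.  Membership uses strict
    inequality (fraction > threshold), so the degenerate thresholds
    high = low = 0 admit every residue with at least one contact.
    """
    with_lig = [u for u in units if u.ligand is not None]
    if not with_lig:
        raise ContactError("no unit carries a ligand")
    # same component id on chemically different molecules is a data error
    sizes: dict[str, int] = {}
    for u in with_lig:
        n = len(u.ligand.atoms)
        if sizes.setdefault(u.ligand.comp_id, n) != n:
            raise ContactError(
                f"ligand component {u.ligand.comp_id!r} has inconsistent atom "
                "counts across units (duplicate identifier?)"
            )
    contacts_by_unit = {u.unit_id: _residue_contacts(u, cutoff) for u in with_lig}
    all_res = sorted({r.number for u in with_lig for r in u.residues})

    unit_counts = {
        num: sum(num in c for c in contacts_by_unit.values()) for num in all_res
    }
    if per_ligand:
        groups: dict[str, list[set[int]]] = {}
        for u in with_lig:
            groups.setdefault(u.ligand.comp_id, []).append(
                contacts_by_unit[u.unit_id]
            )
        denom = len(groups)
        fractions = {
            num: sum(any(num in c for c in sets) for sets in groups.values()) / denom
            for num in all_res
        }
    else:
        denom = len(with_lig)
        fractions = {num: unit_counts[num] / denom for num in all_res}

    core = {n for n, f in fractions.items() if f > high_fraction}
    extended = {n for n, f in fractions.items() if f > low_fraction}
    return BindingArea(
        per_residue_contact_fraction=fractions,
        core_set=core,
        extended_set=extended,
        per_unit_counts=unit_counts,
        n_ligands=denom if per_ligand else len({u.ligand.comp_id for u in with_lig}),
        n_units=len(with_lig),
        cutoff=cutoff,
        high_fraction=high_fraction,
        low_fraction=low_fraction,
    )


def _role_positions(unit: StructureUnit, site_map: dict[str, int], role: str) -> np.ndarray:
    resnum = site_map[role]
    res = unit.residue_map().get(resnum)
    if res is None:
        raise ContactError(f"role {role!r} residue {resnum} absent from unit "
                           f"{unit.unit_id}")
    pos = [a.position for nm in _ROLE_ATOMS[role] for a in res.atoms if a.name == nm]
    return np.array(pos) if pos else np.empty((0, 3))


def _amine_nitrogens(ligand: Ligand) -> list[int]:
    """Indices of primary/secondary amine N atoms (1-2 heavy neighbours)."""
    xyz = ligand.coords()
    out = []
    for i, a in enumerate(ligand.atoms):
        if a.element != "N":
            continue
        d = np.linalg.norm(xyz - xyz[i], axis=1)
        neighbours = int(np.sum(d < BOND_DISTANCE)) - 1
        if 1 <= neighbours <= 2:
            out.append(i)
    return out


def _min_dist(point: np.ndarray, targets: np.ndarray) -> float:
    if len(targets) == 0:
        return float("inf")
    return float(np.linalg.norm(targets - point, axis=1).min())


def classify_binding_modes(
    unit: StructureUnit,
    site_map: dict[str, int] = DEFAULT_SITE_MAP,
    *,
    amine_cutoff: float = 4.0,
    tyr_cutoff: float = 5.0,
    anchor_cutoff: float = 4.0,
    covalent_cutoff: float = 3.0,
) -> BindingModeRecord:
    """Classify the binding modes of one inhibitor-bound unit."""
    if unit.ligand is None:
        raise ContactError(f"unit {unit.unit_id} has no ligand")
    rec = BindingModeRecord(unit_id=unit.unit_id)
    lig = unit.ligand
    xyz = lig.coords()

    glu205 = _role_positions(unit, site_map, "glu205")
    glu206 = _role_positions(unit, site_map, "glu206")
    tyr662 = _role_positions(unit, site_map, "tyr662")
    arg125 = _role_positions(unit, site_map, "arg125")
    asn710 = _role_positions(unit, site_map, "asn710")
    ser630 = _role_positions(unit, site_map, "ser630")

    best = None
    for i in _amine_nitrogens(lig):
        d205 = _min_dist(xyz[i], glu205)
        d206 = _min_dist(xyz[i], glu206)
        d662 = _min_dist(xyz[i], tyr662)
        if d205 < amine_cutoff and d206 < amine_cutoff and d662 < tyr_cutoff:
            score = d205 + d206 + d662
            if best is None or score < best[0]:
                best = (score, lig.atoms[i].name,
                        {"glu205": d205, "glu206": d206, "tyr662": d662})
    if best is not None:
        rec.amine_network = True
        rec.amine_atom = best[1]
        rec.amine_distances = best[2]

    partners = (("arg125", arg125), ("asn710", asn710))
    for i, a in enumerate(lig.atoms):
        if a.element not in ({"N", "O"} | HALOGENS):
            continue
        for role, targets in partners:
            d = _min_dist(xyz[i], targets)
            if d < anchor_cutoff:
                if role == "arg125":
                    rec.arg125_contact = True
                else:
                    rec.asn710_contact = True
                if rec.anchor_distance is None or d < rec.anchor_distance:
                    rec.polar_anchor = True
                    rec.anchor_atom = a.name
                    rec.anchor_partner = role
                    rec.anchor_distance = d

    if len(ser630):
        carbons = xyz[[i for i, a in enumerate(lig.atoms) if a.element == "C"]]
        if len(carbons):
            d = float(np.linalg.norm(
                carbons[:, None, :] - ser630[None, :, :], axis=-1).min())
            rec.ser630_distance = d
            rec.covalent_ser630 = d < covalent_cutoff
    return rec
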