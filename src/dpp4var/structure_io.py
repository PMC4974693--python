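"""Crystal-structure input and unit selection.

A *unit* is the object every downstream statistic is computed on: one
protein molecule restricted to a fixed residue span, the one inhibitor
bound at its active centre (if any), and the water oxygens in its first
hydration shell.  PDB files typically hold one, two or four copies of
the protein; :func:`build_unit` applies the selection rules (residue
span, disorder limit, ligand-at-active-centre, water distance cutoff)
to a single chain and either returns a :class:`StructureUnit` or a
:class:`UnitRejection` explaining why the chain does not qualify.

Parsing is delegated to :mod:`gemmi`; this module resolves alternate
locations, drops hydrogens and regroups atoms into plain dataclasses so
the analysis code never touches a raw PDB record again.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Residue",
    "Ligand",
    "Model",
    "StructureUnit",
    "UnitRejection",
    "PDBParseError",
    "UnitBuildError",
    "parse_pdb",
    "build_unit",
    "unit_to_pdb",
]

#: residue names recognised as water
WATER_NAMES = frozenset({"HOH", "WAT"})

#: elements dropped everywhere (all distances are between heavy atoms)
HYDROGEN_ELEMENTS = frozenset({"H", "D"})

MAIN_CHAIN_NAMES = ("N", "CA", "C")


class PDBParseError(ValueError):
    """Raised when PDB text cannot be interpreted."""


class UnitBuildError(ValueError):
    """Raised for unit-building errors that need caller intervention."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom.

    ``serial`` is the PDB serial number, kept only as a deterministic
    tie-break key; it carries no meaning of its own.
    """

    name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    b_factor: float = 0.0
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False
    serial: int = 0

    def distance(self, other: "Atom") -> float:
        return float(np.linalg.norm(self.position - other.position))


@dataclass
class Residue:
    chain_id: str
    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_main_chain(self) -> bool:
        return all(self.atom(n) is not None for n in MAIN_CHAIN_NAMES)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)


@dataclass
class Ligand:
    """A non-water heteroatom molecule (one residue group in the file)."""

    identifier: str  # unique within the file, e.g. "LIG_B900"
    comp_id: str  # chemical component code, e.g. "LIG", "715"
    atoms: list[Atom] = field(default_factory=list)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)


@dataclass
class Model:
    """Parsed file content: polymer chains, het molecules and waters."""

    chains: dict[str, dict[int, Residue]]
    ligands: list[Ligand]
    waters: list[Atom]

    def chain_ids(self) -> list[str]:
        return list(self.chains)


@dataclass
class StructureUnit:
    """One protein copy + its bound inhibitor + first-shell waters."""

    unit_id: str
    residues: list[Residue]
    ligand: Ligand | None
    waters: list[Atom]
    disordered_count: int

    def residue_map(self) -> dict[int, Residue]:
        return {r.number: r for r in self.residues}

    def calpha_map(self) -> dict[int, np.ndarray]:
        out = {}
        for r in self.residues:
            ca = r.atom("CA")
            if ca is not None:
                out[r.number] = ca.position
        return out

    def protein_atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def protein_coords(self) -> np.ndarray:
        return np.array([a.position for a in self.protein_atoms()], dtype=float)


@dataclass
class UnitRejection:
    """A chain that failed the selection rules, with the reason."""

    unit_id: str
    reason: str


def _scan_coordinate_fields(text: str) -> None:
    # gemmi is forgiving; scan first so a bad coordinate names its line
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")) and len(line) >= 54:
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fldtxt = line[lo:hi].strip()
                try:
                    val = float(fldtxt) if fldtxt else math.nan
                except ValueError:
                    raise PDBParseError(
                        f"line {lineno}: malformed coordinate field {fldtxt!r}"
                    ) from None
                if not math.isfinite(val):
                    raise PDBParseError(f"line {lineno}: non-finite coordinate")


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, ties to first altloc."""
    by_name: dict[str, list[Atom]] = {}
    for a in atoms:
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for group in by_name.values():
        group.sort(key=lambda a: (-a.occupancy, a.altloc))
        kept.append(group[0])
    kept.sort(key=lambda a: a.serial)
    return kept


def parse_pdb(text: str) -> Model:
    """Parse PDB-format text into a :class:`Model`.

    Hydrogens are removed, alternate locations resolved (highest
    occupancy wins; ties go to the lexicographically first altloc) and
    waters (HOH/WAT) separated out as their oxygen atoms.  Raises
    :class:`PDBParseError` on malformed coordinates, insertion codes or
    a model with no heavy atoms.
    """
    _scan_coordinate_fields(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise PDBParseError(str(exc)) from exc
    if len(st) == 0:
        raise PDBParseError("no model in PDB text")

    chains: dict[str, dict[int, Residue]] = {}
    ligands: list[Ligand] = []
    waters: list[Atom] = []
    n_heavy = 0

    for g_chain in st[0]:
        for g_res in g_chain:
            icode = g_res.seqid.icode
            if icode not in (" ", "", "\x00"):
                raise PDBParseError(
                    f"insertion code {icode!r} at {g_chain.name}{g_res.seqid.num} "
                    "not supported"
                )
            atoms = []
            for g_atom in g_res:
                el = g_atom.element.name.upper()
                if el in HYDROGEN_ELEMENTS:
                    continue
                altloc = g_atom.altloc if g_atom.altloc not in ("\x00",) else ""
                atoms.append(
                    Atom(
                        name=g_atom.name,
                        element=el,
                        position=np.array(
                            [g_atom.pos.x, g_atom.pos.y, g_atom.pos.z], dtype=float
                        ),
                        b_factor=float(g_atom.b_iso),
                        occupancy=float(g_atom.occ),
                        altloc=altloc,
                        is_hetero=g_res.het_flag == "H",
                        serial=int(g_atom.serial),
                    )
                )
            atoms = _resolve_altlocs(atoms)
            if not atoms:
                continue
            n_heavy += len(atoms)
            if g_res.name in WATER_NAMES or g_res.is_water():
                waters.extend(a for a in atoms if a.element == "O")
            elif g_res.het_flag == "H":
                ligands.append(
                    Ligand(
                        identifier=f"{g_res.name}_{g_chain.name}{g_res.seqid.num}",
                        comp_id=g_res.name,
                        atoms=atoms,
                    )
                )
            else:
                chains.setdefault(g_chain.name, {})[g_res.seqid.num] = Residue(
                    chain_id=g_chain.name,
                    number=g_res.seqid.num,
                    name=g_res.name,
                    atoms=atoms,
                )
    if n_heavy == 0:
        raise PDBParseError("no heavy atoms")
    return Model(chains=chains, ligands=ligands, waters=waters)


def build_unit(
    model: Model,
    chain_id: str,
    *,
    unit_id: str | None = None,
    span: tuple[int, int] = (41, 764),
    active_site_residue: int = 630,
    ligand_cutoff: float = 4.0,
    water_cutoff: float = 4.0,
    max_disordered: int = 6,
    require_ligand: bool = True,
    ligand_id: str | None = None,
) -> StructureUnit | UnitRejection:
    """Apply the unit-selection rules to one chain.

    Returns a :class:`StructureUnit` when the chain qualifies and a
    :class:`UnitRejection` when it fails a *selection* rule (too many
    disordered residues, or no ligand at the active centre while one is
    required).  Structural problems that the caller must resolve — a
    missing chain, or several candidate ligands at the active centre —
    raise :class:`UnitBuildError` instead.

    A residue of the span counts as disordered when it has no resolved
    heavy atom at all; partially resolved side chains count as present.
    The ligand is the het molecule with at least one heavy atom within
    ``ligand_cutoff`` of any heavy atom of ``active_site_residue``.
    Waters are kept when within ``water_cutoff`` of any protein heavy
    atom of the unit.
    """
    if chain_id not in model.chains:
        raise UnitBuildError(f"chain {chain_id!r} not present in model")
    uid = unit_id if unit_id is not None else chain_id
    lo, hi = span
    if lo > hi:
        raise UnitBuildError(f"invalid span {span}")
    chain = model.chains[chain_id]
    residues = [chain[n] for n in sorted(chain) if lo <= n <= hi]
    span_size = hi - lo + 1
    disordered = span_size - len(residues)
    if disordered >= max_disordered:
        return UnitRejection(uid, f"disordered residues >= {max_disordered} "
                                  f"({disordered} of {span_size} span residues missing)")

    ligand: Ligand | None = None
    if ligand_id is not None:
        matches = [l for l in model.ligands if l.identifier == ligand_id]
        if not matches:
            raise UnitBuildError(f"ligand {ligand_id!r} not found in model")
        ligand = matches[0]
    else:
        site = next((r for r in residues if r.number == active_site_residue), None)
        if site is None:
            return UnitRejection(uid, f"active-site residue {active_site_residue} unresolved")
        site_xyz = site.coords()
        candidates = []
        for lig in model.ligands:
            if not lig.atoms:
                continue
            d = np.linalg.norm(
                lig.coords()[:, None, :] - site_xyz[None, :, :], axis=-1
            ).min()
            if d < ligand_cutoff:
                candidates.append(lig)
        if len(candidates) > 1:
            names = ", ".join(l.identifier for l in candidates)
            raise UnitBuildError(
                f"{uid}: several candidate ligands at the active centre ({names}); "
                "disambiguate with ligand_id"
            )
        ligand = candidates[0] if candidates else None

    if require_ligand and ligand is None:
        return UnitRejection(uid, "no ligand at the active centre")

    prot_xyz = np.array([a.position for r in residues for a in r.atoms], dtype=float)
    unit_waters: list[Atom] = []
    if model.waters and len(prot_xyz):
        tree = cKDTree(prot_xyz)
        w_xyz = np.array([w.position for w in model.waters], dtype=float)
        dists, _ = tree.query(w_xyz, k=1)
        unit_waters = [w for w, d in zip(model.waters, dists) if d < water_cutoff]

    return StructureUnit(
        unit_id=uid,
        residues=residues,
        ligand=ligand,
        waters=unit_waters,
        disordered_count=disordered,
    )


def _gemmi_residue(name: str, number: int, atoms: Iterable[Atom], het: bool) -> gemmi.Residue:
    res = gemmi.Residue()
    res.name = name
    res.seqid = gemmi.SeqId(number, " ")
    res.het_flag = "H" if het else "A"
    for a in atoms:
        ga = gemmi.Atom()
        ga.name = a.name
        ga.element = gemmi.Element(a.element)
        ga.pos = gemmi.Position(*a.position)
        ga.occ = a.occupancy
        ga.b_iso = a.b_factor
        res.add_atom(ga)
    return res


def unit_to_pdb(unit: StructureUnit) -> str:
    """Serialize a unit back to PDB text (protein chain A, ligand B, waters W)."""
    st = gemmi.Structure()
    mod = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for r in unit.residues:
        chain.add_residue(_gemmi_residue(r.name, r.number, r.atoms, het=False))
    mod.add_chain(chain)
    if unit.ligand is not None:
        lig_chain = gemmi.Chain("B")
        lig_chain.add_residue(
            _gemmi_residue(unit.ligand.comp_id, 900, unit.ligand.atoms, het=True)
        )
        mod.add_chain(lig_chain)
    if unit.waters:
        w_chain = gemmi.Chain("W")
        for i, w in enumerate(unit.waters):
            w_chain.add_residue(_gemmi_residue("HOH", 1000 + i, [w], het=True))
        mod.add_chain(w_chain)
    st.add_model(mod)
    return st.make_pdb_string()
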