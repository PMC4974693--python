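"""Synthetic coordinate ensembles with known ground truth.

The generator emulates the statistical structure that the ensemble
analysis assumes, without any chemistry:

* a template chain — an idealized alpha-helical backbone (N, CA, C)
  carrying side-chain reporter pseudo-atoms appropriate to each
  amino-acid type;
* designated *role* residues (glu205, glu206, tyr662, arg125, asn710,
  ser630 in the study protein's sense) whose reporter atoms are placed
  at configurable distances from a ligand so the binding-mode
  classifier has planted positives;
* per-unit copies of the template with independent per-atom isotropic
  Gaussian displacement (per-residue sigma profile), an independent
  random rigid-body pose, and optionally missing ("disordered")
  residues;
* waters: planted conserved sites present in a chosen fraction of
  units with sub-Angstrom jitter and low B-factors, plus random decoy
  waters uniform in a box around the protein (kept clear of atoms)
  with high B-factors; decoys far from the protein are later discarded
  by the 4 A water-retention rule, as in real structures where only
  first-shell waters matter.

Units are emitted as legal PDB text so the pipeline is exercised
through its real I/O path.  A single :class:`numpy.random.Generator`
seeded from the spec drives every draw in a documented order (planted
site positions, then per-site support, then per unit: missing-residue
mask, protein noise, ligand noise, planted-water jitter, decoy waters,
rigid pose), so identical seeds give bit-identical ensembles.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .structure_io import StructureUnit, UnitRejection, build_unit, parse_pdb

__all__ = [
    "LigandSpec",
    "WaterSpec",
    "EnsembleSpec",
    "GroundTruth",
    "generate_ensemble",
    "generate_units",
    "write_ensemble",
]

_SEQUENCE_CYCLE = ("ALA", "SER", "VAL", "ARG", "TYR", "GLU", "ASN", "HIS", "PHE", "TRP")

# template helix geometry (statistical, not chemical)
_HELIX_RADIUS = 2.3
_HELIX_TWIST = math.radians(100.0)
_HELIX_RISE = 1.5

_SIDECHAIN_OFFSETS: dict[str, tuple[tuple[str, float, float], ...]] = {
    # name -> (atom, along outward, along perpendicular), relative to CB
    "ALA": (),
    "SER": (("OG", 1.4, 0.0),),
    "VAL": (("CG1", 1.4, 0.6), ("CG2", 1.4, -0.6)),
    "ARG": (("NH1", 4.0, 0.9), ("NH2", 4.0, -0.9)),
    "TYR": (("OH", 4.2, 0.0),),
    "GLU": (("OE1", 2.6, 0.9), ("OE2", 2.6, -0.9)),
    "ASN": (("ND2", 2.2, 0.0),),
    "HIS": (("NE2", 3.0, 0.0),),
    "PHE": (("CZ", 3.4, 0.0),),
    "TRP": (("CH2", 3.6, 0.0),),
}

_ROLE_OFFSETS = {  # relative to the active-site residue index
    "ser630": 0,
    "glu205": 3,
    "glu206": 4,
    "tyr662": 7,
    "arg125": -4,
    "asn710": -3,
}
_ROLE_TYPES = {
    "ser630": "SER",
    "glu205": "GLU",
    "glu206": "GLU",
    "tyr662": "TYR",
    "arg125": "ARG",
    "asn710": "ASN",
}


@dataclass
class LigandSpec:
    """Planted inhibitor geometry (distances in Angstrom)."""

    amine_glu205: float = 3.2
    amine_glu206: float = 3.5
    amine_tyr662: float = 4.6
    anchor_arg125: float = 3.4
    nitrile_ser630: float = 2.8
    n_decoy_atoms: int = 4
    sigma: float = 0.05  # per-atom positional noise


@dataclass
class WaterSpec:
    n_planted_sites: int = 5
    planted_presence_fraction: float = 0.8
    planted_jitter: float = 0.2  # Angstrom
    n_random_waters: int = 50
    box_size: float = 40.0
    planted_b: float = 10.0
    random_b: float = 40.0
    protein_b: float = 25.0
    min_clearance: float = 2.4  # waters never closer than this to any atom


@dataclass
class EnsembleSpec:
    n_units: int = 10
    n_residues: int = 120
    start_residue: int = 41
    # 0.2 A per-atom displacement reproduces the ~0.5 A inter-unit Calpha
    # RMSD scale typical of redundant cocrystal ensembles (RMSD ~ sigma*sqrt(6))
    sigma: float | list[float] = 0.2
    rigid_rotation_deg: float = 30.0
    rigid_translation: float = 5.0
    missing_residue_rate: float = 0.0
    ligand: LigandSpec | None = field(default_factory=LigandSpec)
    water: WaterSpec = field(default_factory=WaterSpec)
    seed: int = 0

    def sigma_profile(self) -> np.ndarray:
        if np.isscalar(self.sigma):
            return np.full(self.n_residues, float(self.sigma))
        arr = np.asarray(self.sigma, dtype=float)
        if arr.shape != (self.n_residues,):
            raise ValueError("sigma profile length must equal n_residues")
        return arr

    def validate(self) -> None:
        if self.n_residues < 16:
            raise ValueError("need at least 16 residues to place the role residues")
        if (self.sigma_profile() < 0).any():
            raise ValueError("sigma must be non-negative")
        for frac in (self.water.planted_presence_fraction, self.missing_residue_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class GroundTruth:
    unit_ids: list[str]
    sigma_per_residue: dict[int, float]
    role_map: dict[str, int]
    active_site_residue: int
    planted_sites: list[dict]  # {"position": [x,y,z], "unit_ids": [...]}
    poses: dict[str, dict]  # unit_id -> {"rotation": 3x3, "translation": 3}
    missing_residues: dict[str, list[int]]
    ligand_truth: dict | None
    span: tuple[int, int]

    def site_position_in_unit_frame(self, site_index: int, unit_id: str) -> np.ndarray:
        """Planted site centre mapped through a unit's rigid pose."""
        p = np.array(self.planted_sites[site_index]["position"])
        pose = self.poses[unit_id]
        return np.array(pose["rotation"]) @ p + np.array(pose["translation"])

    def to_json(self) -> str:
        d = asdict(self)
        d["span"] = list(self.span)
        return json.dumps(d, indent=1, sort_keys=True)


def _unit_vec(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _build_template(spec: EnsembleSpec):
    """Template atoms: list of (resnum, resname, atom_name, element, xyz)."""
    n = spec.n_residues
    idx = np.arange(n)
    ca = np.column_stack([
        _HELIX_RADIUS * np.cos(idx * _HELIX_TWIST),
        _HELIX_RADIUS * np.sin(idx * _HELIX_TWIST),
        idx * _HELIX_RISE,
    ])
    tangents = np.empty_like(ca)
    tangents[1:-1] = ca[2:] - ca[:-2]
    tangents[0] = ca[1] - ca[0]
    tangents[-1] = ca[-1] - ca[-2]
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    outward = np.column_stack([
        np.cos(idx * _HELIX_TWIST), np.sin(idx * _HELIX_TWIST), np.zeros(n)
    ])

    a_idx = n // 2
    names = {}
    for role, off in _ROLE_OFFSETS.items():
        names[a_idx + off] = _ROLE_TYPES[role]
    resnames = [names.get(i, _SEQUENCE_CYCLE[i % len(_SEQUENCE_CYCLE)]) for i in range(n)]

    atoms = []  # (res_index, atom_name, element, xyz)
    for i in range(n):
        t, o = tangents[i], outward[i]
        s = _unit_vec(np.cross(t, o))
        n_pos = ca[i] + 1.45 * _unit_vec(-t + 0.5 * s)
        c_pos = ca[i] + 1.52 * _unit_vec(t + 0.5 * s)
        cb = ca[i] + 1.53 * o
        atoms.append((i, "N", "N", n_pos))
        atoms.append((i, "CA", "C", ca[i]))
        atoms.append((i, "C", "C", c_pos))
        atoms.append((i, "CB", "C", cb))
        for name, d_out, d_perp in _SIDECHAIN_OFFSETS[resnames[i]]:
            atoms.append((i, name, name[0], cb + d_out * o + d_perp * s))
    return ca, tangents, outward, a_idx, resnames, atoms


def _plant_ligand(spec: EnsembleSpec, ca, tangents, outward, a_idx, atoms):
    """Place the ligand and retarget role reporter atoms around it.

    Returns (ligand_atoms, truth_dict); mutates ``atoms`` in place.
    """
    lig = spec.ligand
    pocket = ca[a_idx] + 7.5 * outward[a_idx]

    pos_by_key = {(i, nm): k for k, (i, nm, _, _) in enumerate(atoms)}

    def set_atom(res_idx, name, xyz):
        k = pos_by_key[(res_idx, name)]
        i, nm, el, _ = atoms[k]
        atoms[k] = (i, nm, el, xyz)

    def get_atom(res_idx, name):
        return atoms[pos_by_key[(res_idx, name)]][3]

    # amine targets point from the pocket toward each residue's CA
    for role, dist, names in (
        ("glu205", lig.amine_glu205, ("OE1", "OE2")),
        ("glu206", lig.amine_glu206, ("OE1", "OE2")),
        ("tyr662", lig.amine_tyr662, ("OH",)),
    ):
        ridx = a_idx + _ROLE_OFFSETS[role]
        u = _unit_vec(ca[ridx] - pocket)
        set_atom(ridx, names[0], pocket + dist * u)
        if len(names) > 1:
            set_atom(ridx, names[1], pocket + (dist + 1.8) * u)

    away = _unit_vec(pocket - ca[a_idx])
    ligand_atoms = [("N1", "N", pocket), ("C1", "C", pocket + 1.45 * away)]

    # nitrile carbon sits laterally offset so it does not crowd the amine
    og = get_atom(a_idx, "OG")
    lateral = pocket + 2.5 * tangents[a_idx]
    c2 = og + lig.nitrile_ser630 * _unit_vec(lateral - og)
    ligand_atoms.append(("C2", "C", c2))

    nh1 = get_atom(a_idx + _ROLE_OFFSETS["arg125"], "NH1")
    o1 = nh1 + lig.anchor_arg125 * _unit_vec(pocket - nh1)
    ligand_atoms.append(("O1", "O", o1))

    perp = _unit_vec(np.cross(away, tangents[a_idx]))
    for k in range(lig.n_decoy_atoms):
        ligand_atoms.append(
            (f"C{3 + k}", "C",
             pocket + (2.2 + 0.4 * k) * away + 0.5 * ((-1) ** k) * perp)
        )
    truth = {
        "amine_glu205": lig.amine_glu205,
        "amine_glu206": lig.amine_glu206,
        "amine_tyr662": lig.amine_tyr662,
        "anchor_arg125": lig.anchor_arg125,
        "nitrile_ser630": lig.nitrile_ser630,
        "expected_amine_network": (lig.amine_glu205 < 4.0 and
                                   lig.amine_glu206 < 4.0 and
                                   lig.amine_tyr662 < 5.0),
        "expected_polar_anchor": lig.anchor_arg125 < 4.0,
        "expected_covalent_ser630": lig.nitrile_ser630 < 3.0,
    }
    return ligand_atoms, truth


def _sample_shell_point(rng, coords, clearance, lo=2.6, hi=3.8, tries=200):
    """A point in the hydration shell: near one atom, clear of all."""
    for _ in range(tries):
        anchor = coords[rng.integers(len(coords))]
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        p = anchor + rng.uniform(lo, hi) * v
        if np.min(np.linalg.norm(coords - p, axis=1)) >= clearance:
            return p
    raise RuntimeError("could not place a water with the requested clearance")


def _sample_box_point(rng, coords, center, box_size, clearance, tries=200):
    """A point uniform in the box around ``center``, clear of all atoms."""
    for _ in range(tries):
        p = center + rng.uniform(-box_size / 2.0, box_size / 2.0, size=3)
        if np.min(np.linalg.norm(coords - p, axis=1)) >= clearance:
            return p
    raise RuntimeError("could not place a water with the requested clearance")


def _residue_to_gemmi(resnum, resname, atom_list, het, bfac_of):
    res = gemmi.Residue()
    res.name = resname
    res.seqid = gemmi.SeqId(int(resnum), " ")
    res.het_flag = "H" if het else "A"
    for name, el, xyz in atom_list:
        a = gemmi.Atom()
        a.name = name
        a.element = gemmi.Element(el)
        a.pos = gemmi.Position(*xyz)
        a.occ = 1.0
        a.b_iso = float(bfac_of(name))
        res.add_atom(a)
    return res


def generate_ensemble(spec: EnsembleSpec) -> tuple[dict[str, str], GroundTruth]:
    """Generate PDB texts (unit_id -> text) and the ground-truth record."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    sigma = spec.sigma_profile()
    start = spec.start_residue
    n = spec.n_residues
    span = (start, start + n - 1)

    ca, tangents, outward, a_idx, resnames, atoms = _build_template(spec)
    ligand_atoms: list | None = None
    ligand_truth = None
    if spec.ligand is not None:
        ligand_atoms, ligand_truth = _plant_ligand(
            spec, ca, tangents, outward, a_idx, atoms)

    role_map = {role: start + a_idx + off for role, off in _ROLE_OFFSETS.items()}
    role_indices = {a_idx + off for off in _ROLE_OFFSETS.values()}
    protein_xyz = np.array([xyz for *_, xyz in atoms])
    all_xyz = protein_xyz
    if ligand_atoms:
        all_xyz = np.vstack([protein_xyz, [xyz for _, _, xyz in ligand_atoms]])

    ws = spec.water
    # 1) planted site positions (template frame)
    site_positions = [
        _sample_shell_point(rng, protein_xyz, ws.min_clearance, 2.8, 3.6)
        for _ in range(ws.n_planted_sites)
    ]
    # re-check clearance against the ligand too
    if ligand_atoms:
        lig_xyz = np.array([xyz for _, _, xyz in ligand_atoms])
        for k, p in enumerate(site_positions):
            while np.min(np.linalg.norm(lig_xyz - p, axis=1)) < ws.min_clearance:
                p = _sample_shell_point(rng, protein_xyz, ws.min_clearance, 2.8, 3.6)
            site_positions[k] = p

    unit_ids = [f"SYN{u:03d}_A" for u in range(spec.n_units)]
    # 2) support: exactly round(fraction * n_units) units per site
    n_present = int(round(ws.planted_presence_fraction * spec.n_units))
    site_units = [
        sorted(rng.choice(spec.n_units, size=n_present, replace=False).tolist())
        for _ in range(ws.n_planted_sites)
    ]

    pdb_texts: dict[str, str] = {}
    poses: dict[str, dict] = {}
    missing: dict[str, list[int]] = {}

    for u_idx, uid in enumerate(unit_ids):
        # 3a) missing-residue mask (role residues always kept)
        keep = np.ones(n, dtype=bool)
        if spec.missing_residue_rate > 0:
            drops = rng.random(n) < spec.missing_residue_rate
            drops[list(role_indices)] = False
            keep = ~drops
        missing[uid] = [start + i for i in range(n) if not keep[i]]

        # 3b) protein noise
        noisy = []
        for (i, nm, el, xyz) in atoms:
            noisy.append((i, nm, el, xyz + rng.normal(0.0, sigma[i], size=3)))
        # 3c) ligand noise
        lig_noisy = None
        if ligand_atoms is not None:
            lig_noisy = [
                (nm, el, xyz + rng.normal(0.0, spec.ligand.sigma, size=3))
                for nm, el, xyz in ligand_atoms
            ]
        # 3d) planted waters
        unit_waters = []  # (xyz, b_factor)
        for s_idx, pos in enumerate(site_positions):
            if u_idx in site_units[s_idx]:
                p = pos + rng.normal(0.0, ws.planted_jitter, size=3)
                unit_waters.append((p, max(1.0, ws.planted_b + rng.normal(0.0, 1.0))))
        # 3e) decoy waters uniform in the box
        box_center = protein_xyz.mean(axis=0)
        for _ in range(ws.n_random_waters):
            p = _sample_box_point(rng, all_xyz, box_center, ws.box_size,
                                  ws.min_clearance)
            unit_waters.append((p, max(1.0, ws.random_b + rng.normal(0.0, 2.0))))

        # 3f) rigid pose
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = math.radians(rng.uniform(0.0, spec.rigid_rotation_deg))
        rot = _rotation_matrix(axis, angle)
        trans = rng.uniform(-spec.rigid_translation, spec.rigid_translation, size=3)
        poses[uid] = {"rotation": rot.tolist(), "translation": trans.tolist()}

        def posed(xyz):
            return rot @ xyz + trans

        protein_b = ws.protein_b

        st = gemmi.Structure()
        mod = gemmi.Model("1")
        chain = gemmi.Chain("A")
        by_res: dict[int, list] = {}
        for i, nm, el, xyz in noisy:
            if keep[i]:
                by_res.setdefault(i, []).append((nm, el, posed(xyz)))
        for i in sorted(by_res):
            chain.add_residue(_residue_to_gemmi(
                start + i, resnames[i], by_res[i], het=False,
                bfac_of=lambda _nm: protein_b))
        mod.add_chain(chain)
        if lig_noisy is not None:
            lch = gemmi.Chain("B")
            lch.add_residue(_residue_to_gemmi(
                900, "LIG", [(nm, el, posed(xyz)) for nm, el, xyz in lig_noisy],
                het=True, bfac_of=lambda _nm: protein_b))
            mod.add_chain(lch)
        if unit_waters:
            wch = gemmi.Chain("W")
            for w_idx, (wxyz, wb) in enumerate(unit_waters):
                wch.add_residue(_residue_to_gemmi(
                    1000 + w_idx, "HOH", [("O", "O", posed(wxyz))], het=True,
                    bfac_of=lambda _nm, b=wb: b))
            mod.add_chain(wch)
        st.add_model(mod)
        pdb_texts[uid] = st.make_pdb_string()

    truth = GroundTruth(
        unit_ids=unit_ids,
        sigma_per_residue={start + i: float(sigma[i]) for i in range(n)},
        role_map=role_map,
        active_site_residue=role_map["ser630"],
        planted_sites=[
            {"position": site_positions[k].tolist(),
             "unit_ids": [unit_ids[j] for j in site_units[k]]}
            for k in range(ws.n_planted_sites)
        ],
        poses=poses,
        missing_residues=missing,
        ligand_truth=ligand_truth,
        span=span,
    )
    return pdb_texts, truth


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    k = np.asarray(axis, dtype=float)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + math.sin(angle) * kx + (1 - math.cos(angle)) * (kx @ kx)


def generate_units(
    spec: EnsembleSpec,
    *,
    max_disordered: int = 6,
) -> tuple[list[StructureUnit], list[UnitRejection], GroundTruth]:
    """Generate an ensemble and run it through the real parsing path.

    Every unit is serialized to PDB text, re-parsed and passed through
    :func:`dpp4var.structure_io.build_unit` with the spec's span and
    active-site residue, so tests exercise the same I/O the pipeline
    uses on real files.
    """
    pdb_texts, truth = generate_ensemble(spec)
    units: list[StructureUnit] = []
    rejections: list[UnitRejection] = []
    for uid, text in pdb_texts.items():
        model = parse_pdb(text)
        result = build_unit(
            model,
            "A",
            unit_id=uid,
            span=truth.span,
            active_site_residue=truth.active_site_residue,
            max_disordered=max_disordered,
            require_ligand=spec.ligand is not None,
        )
        if isinstance(result, UnitRejection):
            rejections.append(result)
        else:
            units.append(result)
    return units, rejections, truth


def write_ensemble(spec: EnsembleSpec, out_dir: str | Path,
                   truth_path: str | Path | None = None) -> GroundTruth:
    """Write one PDB file per unit plus the ground-truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pdb_texts, truth = generate_ensemble(spec)
    for uid, text in pdb_texts.items():
        (out_dir / f"{uid}.pdb").write_text(text)
    if truth_path is not None:
        Path(truth_path).write_text(truth.to_json())
    return truth
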