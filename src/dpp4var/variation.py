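"""Inter-unit positional variation of Calpha atoms and side chains.

Two flavours of the same statistic.  For an atom i observed in a pair
of units k, let delta_ik be its distance between the two units after
superposition; the variation of atom i is the mean of delta_ik over the
M contributing pairs:

    variation_i = (1/M) * sum_k delta_ik

* Calpha variation uses one *global* fit per unit pair (Kabsch on all
  shared Calpha atoms), so it measures internal main-chain deformation
  after the rigid-body difference between units is removed.
* Side-chain variation refits each unit pair on the three main-chain
  atoms (N, CA, C) of the residue under study, so it measures how the
  side chain moves relative to its own local backbone frame.  The
  moving quantity is a *reporter atom*: the side-chain atom furthest
  from the main chain for that amino-acid type (Arg Neta, Tyr Oeta,
  Ser Ogamma, ...).  For types with a symmetric terminal pair (Arg
  NH1/NH2, Glu OE1/OE2, Val CG1/CG2, ...) the two per-atom variations
  are computed with fixed name correspondence and then averaged; no
  symmetry-swap minimisation is attempted.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure_io import StructureUnit
from .superpose import SuperpositionError, superpose_kabsch

__all__ = [
    "SIDECHAIN_REPORTERS",
    "VariationProfile",
    "RmsdSummary",
    "rmsd_summary",
    "calpha_variation",
    "sidechain_variation",
    "sidechain_variation_all",
]

log = logging.getLogger(__name__)

#: reporter atoms per amino-acid type: the side-chain atom(s) positioned
#: furthest from the main chain.  Multi-atom entries are averaged.
SIDECHAIN_REPORTERS: dict[str, tuple[str, ...]] = {
    "ARG": ("NH1", "NH2"),
    "TYR": ("OH",),
    "SER": ("OG",),
    "VAL": ("CG1", "CG2"),
    "ASN": ("ND2",),
    "GLU": ("OE1", "OE2"),
    "HIS": ("NE2",),
    "PHE": ("CZ",),
    "TRP": ("CH2",),
    "ALA": ("CB",),
    "CYS": ("SG",),
    "ASP": ("OD1", "OD2"),
    "GLN": ("NE2",),
    "ILE": ("CD1",),
    "LEU": ("CD1", "CD2"),
    "LYS": ("NZ",),
    "MET": ("CE",),
    "PRO": ("CG",),
    "THR": ("OG1", "CG2"),
}


class VariationError(ValueError):
    pass


@dataclass
class VariationProfile:
    """Variation of one atom (or reporter-atom set) across unit pairs."""

    residue_number: int
    amino_acid: str
    atom_role: str  # "CA" or "sidechain"
    variation: float  # Angstrom, mean of per-pair distances
    n_combinations: int  # M, pairs contributing
    per_pair_distances: list[float] | None = field(default=None, repr=False)


@dataclass
class RmsdSummary:
    pairs: pd.DataFrame  # columns unit_a, unit_b, rmsd, n_pairs
    mean: float
    maximum: float
    per_unit_mean: pd.Series


def _shared_calpha(a: StructureUnit, b: StructureUnit):
    ca_a = a.calpha_map()
    ca_b = b.calpha_map()
    shared = sorted(set(ca_a) & set(ca_b))
    xa = np.array([ca_a[n] for n in shared]) if shared else np.empty((0, 3))
    xb = np.array([ca_b[n] for n in shared]) if shared else np.empty((0, 3))
    return shared, xa, xb


def rmsd_summary(units: list[StructureUnit]) -> RmsdSummary:
    """All-pairs Calpha RMSD with ensemble summary statistics.

    For every unordered pair the shared Calpha atoms (intersection by
    residue number) are superposed and the minimized RMSD recorded.
    Pairs sharing fewer than 3 Calpha atoms are excluded with a warning.
    """
    if len(units) < 2:
        raise VariationError("need at least 2 units")
    rows = []
    for a, b in itertools.combinations(units, 2):
        shared, xa, xb = _shared_calpha(a, b)
        if len(shared) < 3:
            log.warning("pair %s/%s shares <3 Calpha atoms; excluded",
                        a.unit_id, b.unit_id)
            continue
        try:
            sup = superpose_kabsch(xb, xa)
        except SuperpositionError as exc:
            log.warning("pair %s/%s excluded: %s", a.unit_id, b.unit_id, exc)
            continue
        rows.append((a.unit_id, b.unit_id, sup.rmsd, sup.n_pairs))
    if not rows:
        raise VariationError("no unit pair shares enough Calpha atoms")
    pairs = pd.DataFrame(rows, columns=["unit_a", "unit_b", "rmsd", "n_pairs"])
    stacked = pd.concat(
        [pairs[["unit_a", "rmsd"]].rename(columns={"unit_a": "unit"}),
         pairs[["unit_b", "rmsd"]].rename(columns={"unit_b": "unit"})]
    )
    per_unit = stacked.groupby("unit")["rmsd"].mean()
    return RmsdSummary(
        pairs=pairs,
        mean=float(pairs["rmsd"].mean()),
        maximum=float(pairs["rmsd"].max()),
        per_unit_mean=per_unit,
    )


def calpha_variation(
    units: list[StructureUnit], *, keep_pair_distances: bool = False
) -> dict[int, VariationProfile]:
    """Per-residue Calpha variation from all-pairs global superposition.

    Every unordered unit pair is superposed on all shared Calpha atoms;
    each shared residue contributes one delta_ik to its own average.
    Residues present in fewer than two units are omitted (their
    variation is undefined).
    """
    if len(units) < 2:
        raise VariationError("need at least 2 units")
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    dists: dict[int, list[float]] = {}
    aa_by_res: dict[int, str] = {}
    for u in units:
        for r in u.residues:
            aa_by_res.setdefault(r.number, r.name)
    for a, b in itertools.combinations(units, 2):
        shared, xa, xb = _shared_calpha(a, b)
        if len(shared) < 3:
            continue
        sup = superpose_kabsch(xb, xa)
        deltas = np.linalg.norm(sup.apply(xb) - xa, axis=1)
        for num, d in zip(shared, deltas):
            sums[num] = sums.get(num, 0.0) + float(d)
            counts[num] = counts.get(num, 0) + 1
            if keep_pair_distances:
                dists.setdefault(num, []).append(float(d))
    return {
        num: VariationProfile(
            residue_number=num,
            amino_acid=aa_by_res.get(num, "UNK"),
            atom_role="CA",
            variation=sums[num] / counts[num],
            n_combinations=counts[num],
            per_pair_distances=dists.get(num) if keep_pair_distances else None,
        )
        for num in sorted(sums)
    }


def sidechain_variation(
    units: list[StructureUnit],
    residue_number: int,
    *,
    reporters: dict[str, tuple[str, ...]] = SIDECHAIN_REPORTERS,
    keep_pair_distances: bool = False,
) -> VariationProfile:
    """Side-chain variation of one residue in its local backbone frame.

    For each unit pair the residue's N/CA/C atoms are superposed and
    delta_ik is the (reporter-averaged) distance between reporter atoms
    after the transform.  Units missing the residue, its main chain or
    any reporter atom are excluded with a log message; an amino-acid
    type with no reporter entry raises :class:`VariationError`.
    """
    usable = []
    aa = None
    for u in units:
        res = u.residue_map().get(residue_number)
        if res is None:
            continue
        if aa is None:
            aa = res.name
        if res.name != aa:
            log.warning("unit %s: residue %d is %s (expected %s); excluded",
                        u.unit_id, residue_number, res.name, aa)
            continue
        if not res.has_main_chain():
            log.info("unit %s: residue %d lacks complete N/CA/C; excluded",
                     u.unit_id, residue_number)
            continue
        if aa not in reporters:
            raise VariationError(f"no reporter atoms defined for {aa}")
        rep = [res.atom(nm) for nm in reporters[aa]]
        if any(r is None for r in rep):
            log.info("unit %s: residue %d missing reporter atom; excluded",
                     u.unit_id, residue_number)
            continue
        main = np.array([res.atom(nm).position for nm in ("N", "CA", "C")])
        usable.append((u.unit_id, main, np.array([a.position for a in rep])))
    if aa is None:
        raise VariationError(f"residue {residue_number} absent from all units")
    if aa not in reporters:
        raise VariationError(f"no reporter atoms defined for {aa}")
    if len(usable) < 2:
        raise VariationError(
            f"residue {residue_number}: fewer than 2 usable units"
        )
    deltas = []
    for (_, main_a, rep_a), (_, main_b, rep_b) in itertools.combinations(usable, 2):
        sup = superpose_kabsch(main_b, main_a)
        deltas.append(float(np.mean(np.linalg.norm(sup.apply(rep_b) - rep_a, axis=1))))
    return VariationProfile(
        residue_number=residue_number,
        amino_acid=aa,
        atom_role="sidechain",
        variation=float(np.mean(deltas)),
        n_combinations=len(deltas),
        per_pair_distances=deltas if keep_pair_distances else None,
    )


def sidechain_variation_all(
    units: list[StructureUnit],
    *,
    reporters: dict[str, tuple[str, ...]] = SIDECHAIN_REPORTERS,
) -> pd.DataFrame:
    """Side-chain variation for every residue that supports it.

    Returns a DataFrame (residue_number, amino_acid, atom_role,
    variation_A, n_pairs) plus a per-type baseline column
    ``type_mean_A``: the unweighted mean variation over residues of the
    same amino-acid type.
    """
    numbers = sorted({r.number for u in units for r in u.residues})
    rows = []
    for num in numbers:
        try:
            p = sidechain_variation(units, num, reporters=reporters)
        except VariationError as exc:
            log.info("residue %d skipped: %s", num, exc)
            continue
        rows.append((p.residue_number, p.amino_acid, p.atom_role,
                     p.variation, p.n_combinations))
    df = pd.DataFrame(
        rows,
        columns=["residue_number", "amino_acid", "atom_role", "variation_A", "n_pairs"],
    )
    if len(df):
        df["type_mean_A"] = df.groupby("amino_acid")["variation_A"].transform("mean")
    return df
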