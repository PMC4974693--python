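import numpy as np
import pytest

from dpp4var.structure_io import Atom, Ligand, Residue, StructureUnit


def make_atom(name, element, xyz, *, b=20.0, serial=0, hetero=False):
    return Atom(name=name, element=element, position=np.asarray(xyz, dtype=float),
                b_factor=b, occupancy=1.0, altloc="", is_hetero=hetero, serial=serial)


def make_residue(number, name, atom_spec, chain="A"):
    """atom_spec: list of (atom_name, element, xyz)."""
    return Residue(chain_id=chain, number=number, name=name,
                   atoms=[make_atom(nm, el, xyz) for nm, el, xyz in atom_spec])


def make_unit(unit_id, residues, ligand=None, waters=None, disordered=0):
    return StructureUnit(unit_id=unit_id, residues=residues, ligand=ligand,
                         waters=waters or [], disordered_count=disordered)


def make_ligand(identifier, comp_id, atom_spec):
    return Ligand(identifier=identifier, comp_id=comp_id,
                  atoms=[make_atom(nm, el, xyz, hetero=True) for nm, el, xyz in atom_spec])


@pytest.fixture(scope="session")
def small_ensemble():
    """A modest synthetic ensemble shared by read-only tests."""
    from dpp4var.synthetic_data import EnsembleSpec, generate_units

    spec = EnsembleSpec(n_units=6, n_residues=48, seed=42)
    units, rejections, truth = generate_units(spec)
    assert not rejections
    return units, truth
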