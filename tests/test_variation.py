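import copy

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dpp4var.variation import (
    SIDECHAIN_REPORTERS,
    VariationError,
    calpha_variation,
    rmsd_summary,
    sidechain_variation,
)

from conftest import make_residue, make_unit


def _backbone(num, extra=(), name="SER", origin=(0.0, 0.0, 0.0)):
    o = np.asarray(origin)
    spec = [("N", "N", o + (0.0, 0.0, 0.0)),
            ("CA", "C", o + (1.4, 0.6, 0.0)),
            ("C", "C", o + (2.8, 0.0, 0.0))]
    spec += [(nm, el, o + np.asarray(xyz)) for nm, el, xyz in extra]
    return make_residue(num, name, spec)


def _chain_unit(uid, n_res=6, jitter=None, rng=None):
    residues = []
    for i in range(n_res):
        # zig-zag origins keep the Calpha trace non-collinear
        res = _backbone(41 + i, extra=[("OG", "O", (1.4, 1.8, 0.6))],
                        origin=(4.0 * i, 3.0 * (i % 2), 2.0 * (i % 3)))
        if jitter is not None:
            for a in res.atoms:
                a.position[:] = a.position + rng.normal(0, jitter, 3)
        residues.append(res)
    return make_unit(uid, residues)


def _apply_rigid(unit, rot, shift):
    u = copy.deepcopy(unit)
    for r in u.residues:
        for a in r.atoms:
            a.position[:] = rot @ a.position + shift
    return u


class TestRmsdSummary:
    def test_identical_units_give_zero(self):
        units = [_chain_unit(f"U{i}") for i in range(3)]
        s = rmsd_summary(units)
        assert s.mean == pytest.approx(0.0, abs=1e-9)
        assert s.maximum == pytest.approx(0.0, abs=1e-9)
        assert len(s.pairs) == 3

    def test_pure_rigid_motion_gives_zero(self):
        a = _chain_unit("A")
        rot = Rotation.from_euler("xyz", [30, -60, 10], degrees=True).as_matrix()
        b = _apply_rigid(a, rot, np.array([5.0, -2.0, 1.0]))
        b.unit_id = "B"
        s = rmsd_summary([a, b])
        assert s.maximum == pytest.approx(0.0, abs=1e-9)

    def test_per_unit_mean_present_for_every_unit(self):
        rng = np.random.default_rng(0)
        units = [_chain_unit(f"U{i}", jitter=0.1, rng=rng) for i in range(4)]
        s = rmsd_summary(units)
        assert set(s.per_unit_mean.index) == {u.unit_id for u in units}

    def test_needs_two_units(self):
        with pytest.raises(VariationError):
            rmsd_summary([_chain_unit("A")])


class TestCalphaVariation:
    def test_identical_units_zero_everywhere(self):
        units = [_chain_unit(f"U{i}") for i in range(3)]
        profiles = calpha_variation(units)
        assert all(p.variation == pytest.approx(0.0, abs=1e-9)
                   for p in profiles.values())
        assert all(p.n_combinations == 3 for p in profiles.values())

    def test_missing_residue_drops_from_pair_count(self):
        units = [_chain_unit(f"U{i}") for i in range(3)]
        units[2].residues = units[2].residues[:-1]  # residue 46 absent in U2
        profiles = calpha_variation(units)
        assert profiles[46].n_combinations == 1
        assert profiles[41].n_combinations == 3

    def test_variation_equals_mean_of_pair_distances(self):
        rng = np.random.default_rng(1)
        units = [_chain_unit(f"U{i}", jitter=0.2, rng=rng) for i in range(4)]
        profiles = calpha_variation(units, keep_pair_distances=True)
        for p in profiles.values():
            assert p.variation == pytest.approx(np.mean(p.per_pair_distances))
            assert len(p.per_pair_distances) == p.n_combinations

    def test_not_invariant_to_internal_deformation(self):
        # bending the chain registers as Calpha variation even though each
        # residue's local frame is intact
        a = _chain_unit("A", n_res=8)
        b = copy.deepcopy(a)
        b.unit_id = "B"
        for r in b.residues[4:]:
            for at in r.atoms:
                at.position[1] += 2.0
        profiles = calpha_variation([a, b])
        assert max(p.variation for p in profiles.values()) > 0.5


class TestSidechainVariation:
    def test_identical_units_zero(self):
        units = [_chain_unit(f"U{i}") for i in range(3)]
        p = sidechain_variation(units, 41)
        assert p.variation == pytest.approx(0.0, abs=1e-9)

    def test_chi1_rotation_matches_chord_distance(self):
        """A pure rotamer flip about the CA-CB axis moves the reporter by the
        chord of its circle about that axis."""
        extra = [("CB", "C", (1.4, 2.1, 0.0)), ("OG", "O", (2.6, 2.9, 0.4))]
        a = make_unit("A", [_backbone(41, extra=extra)])
        b = copy.deepcopy(a)
        b.unit_id = "B"
        res = b.residues[0]
        ca = res.atom("CA").position
        cb = res.atom("CB").position
        axis = (cb - ca) / np.linalg.norm(cb - ca)
        angle = np.deg2rad(120.0)
        rot = Rotation.from_rotvec(axis * angle).as_matrix()
        og = res.atom("OG")
        og.position[:] = ca + rot @ (og.position - ca)

        # analytic chord: radius of OG about the axis times 2 sin(angle/2)
        v = a.residues[0].atom("OG").position - ca
        radius = np.linalg.norm(v - (v @ axis) * axis)
        expected = 2.0 * radius * np.sin(angle / 2.0)

        p = sidechain_variation([a, b], 41)
        assert p.variation == pytest.approx(expected, abs=1e-9)

    def test_invariant_to_whole_unit_rigid_motion(self):
        rng = np.random.default_rng(2)
        units = [_chain_unit(f"U{i}", jitter=0.15, rng=rng) for i in range(3)]
        base = sidechain_variation(units, 43).variation
        rot = Rotation.from_euler("y", 75, degrees=True).as_matrix()
        moved = [_apply_rigid(units[0], rot, np.array([8.0, 1.0, -3.0]))] + units[1:]
        assert sidechain_variation(moved, 43).variation == pytest.approx(base, abs=1e-9)

    def test_planted_rotamer_disorder_ranks_higher(self):
        rng = np.random.default_rng(3)
        units = []
        for i in range(8):
            extra41 = [("OG", "O", (1.4, 1.8, 0.6))]  # fixed serine
            # mobile serine: reporter resampled on a circle about CA
            phi = rng.uniform(0, 2 * np.pi)
            extra42 = [("OG", "O", (1.4 + 1.5 * np.cos(phi), 1.8,
                                    1.5 * np.sin(phi)))]
            units.append(make_unit(f"U{i}", [
                _backbone(41, extra=extra41),
                _backbone(42, extra=extra42, origin=(6.0, 0.0, 0.0)),
            ]))
        fixed = sidechain_variation(units, 41).variation
        mobile = sidechain_variation(units, 42).variation
        assert mobile > fixed + 0.5

    def test_symmetric_reporter_pair_is_averaged(self):
        extra = [("NH1", "N", (3.0, 2.0, 0.0)), ("NH2", "N", (3.0, -1.0, 0.0))]
        a = make_unit("A", [_backbone(41, extra=extra, name="ARG")])
        b = copy.deepcopy(a)
        b.unit_id = "B"
        nh1 = b.residues[0].atom("NH1")
        nh1.position[2] += 0.8  # move one of the pair only
        p = sidechain_variation([a, b], 41)
        assert p.variation == pytest.approx(0.4, abs=1e-9)

    def test_unknown_amino_acid_is_error(self):
        units = [make_unit(f"U{i}", [_backbone(41, name="GLY")]) for i in range(2)]
        with pytest.raises(VariationError, match="reporter"):
            sidechain_variation(units, 41)

    def test_unit_missing_reporter_excluded(self):
        units = [_chain_unit(f"U{i}") for i in range(3)]
        units[0].residues[0].atoms = units[0].residues[0].atoms[:3]  # drop OG
        p = sidechain_variation(units, 41)
        assert p.n_combinations == 1  # only the U1/U2 pair remains


def test_reporter_table_covers_required_types():
    required = {
        "ARG": {"NH1", "NH2"}, "TYR": {"OH"}, "SER": {"OG"},
        "VAL": {"CG1", "CG2"}, "ASN": {"ND2"}, "GLU": {"OE1", "OE2"},
        "HIS": {"NE2"}, "PHE": {"CZ"}, "TRP": {"CH2"},
    }
    for aa, atoms in required.items():
        assert set(SIDECHAIN_REPORTERS[aa]) == atoms
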