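import numpy as np
import pytest

from dpp4var.contacts import (
    ContactError,
    binding_area_from_contacts,
    classify_binding_modes,
)

from conftest import make_ligand, make_residue, make_unit

SITE_MAP = {"glu205": 205, "glu206": 206, "tyr662": 662,
            "arg125": 125, "asn710": 710, "ser630": 630}


def _point_residue(num, name, atom, element, xyz):
    return make_residue(num, name, [(atom, element, xyz)])


def _unit_with_ligand(uid, comp_id, residue_xyz, ligand_xyz):
    residues = [_point_residue(num, "ALA", "CB", "C", xyz)
                for num, xyz in residue_xyz.items()]
    lig = make_ligand(f"{comp_id}_{uid}", comp_id, [("C1", "C", ligand_xyz)])
    return make_unit(uid, residues, ligand=lig)


class TestBindingArea:
    def test_threshold_boundary_in_fractions(self):
        unit = _unit_with_ligand("U0", "AAA",
                                 {10: (3.9, 0, 0), 11: (4.1, 0, 0)},
                                 (0.0, 0.0, 0.0))
        area = binding_area_from_contacts([unit])
        assert area.per_residue_contact_fraction == {10: 1.0, 11: 0.0}

    def test_constructed_fractions_and_membership(self):
        # 10 distinct ligands: 8 contact residue 10, 4 contact residue 11
        units = []
        for i in range(10):
            res10 = (3.0, 0, 0) if i < 8 else (9.0, 0, 0)
            res11 = (0, 3.0, 0) if i < 4 else (0, 9.0, 0)
            units.append(_unit_with_ligand(
                f"U{i}", f"L{i:02d}", {10: res10, 11: res11}, (0.0, 0.0, 0.0)))
        area = binding_area_from_contacts(units)
        assert area.per_residue_contact_fraction[10] == pytest.approx(0.8)
        assert area.per_residue_contact_fraction[11] == pytest.approx(0.4)
        assert 10 in area.core_set and 10 in area.extended_set
        assert 11 in area.extended_set and 11 not in area.core_set
        assert area.core_set <= area.extended_set
        assert area.n_ligands == 10

    def test_same_compound_in_two_units_counted_once(self):
        units = [
            _unit_with_ligand("U0", "AAA", {10: (3.0, 0, 0)}, (0.0, 0.0, 0.0)),
            _unit_with_ligand("U1", "AAA", {10: (9.0, 0, 0)}, (0.0, 0.0, 0.0)),
            _unit_with_ligand("U2", "BBB", {10: (9.0, 0, 0)}, (0.0, 0.0, 0.0)),
        ]
        area = binding_area_from_contacts(units)
        assert area.n_ligands == 2
        # compound AAA contacts in one of its units -> counts once
        assert area.per_residue_contact_fraction[10] == pytest.approx(0.5)
        assert area.per_unit_counts[10] == 1

    def test_degenerate_thresholds_admit_any_contact(self):
        unit = _unit_with_ligand("U0", "AAA",
                                 {10: (3.9, 0, 0), 11: (4.1, 0, 0)},
                                 (0.0, 0.0, 0.0))
        area = binding_area_from_contacts([unit], high_fraction=0.0,
                                          low_fraction=0.0)
        assert area.core_set == area.extended_set == {10}

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(0)
        units = [
            _unit_with_ligand(f"U{i}", f"L{i}",
                              {n: tuple(rng.uniform(-6, 6, 3)) for n in range(8)},
                              (0.0, 0.0, 0.0))
            for i in range(5)
        ]
        prev_frac, prev_core = None, None
        for cutoff in (3.0, 4.0, 5.0, 6.0):
            area = binding_area_from_contacts(units, cutoff=cutoff)
            if prev_frac is not None:
                for num, f in area.per_residue_contact_fraction.items():
                    assert f >= prev_frac[num]
                assert prev_core <= area.core_set
            prev_frac = area.per_residue_contact_fraction
            prev_core = area.core_set

    def test_order_independence(self):
        rng = np.random.default_rng(1)
        units = [
            _unit_with_ligand(f"U{i}", f"L{i}",
                              {n: tuple(rng.uniform(-6, 6, 3)) for n in range(5)},
                              (0.0, 0.0, 0.0))
            for i in range(4)
        ]
        a1 = binding_area_from_contacts(units)
        a2 = binding_area_from_contacts(list(reversed(units)))
        assert a1.per_residue_contact_fraction == a2.per_residue_contact_fraction
        assert a1.core_set == a2.core_set

    def test_exhaustive_distance_scan_oracle(self):
        rng = np.random.default_rng(2)
        units = []
        for i in range(4):
            residues = [make_residue(n, "ALA",
                                     [(f"C{k}", "C", tuple(rng.uniform(-8, 8, 3)))
                                      for k in range(3)])
                        for n in range(6)]
            lig = make_ligand(f"L{i}_x", f"L{i}",
                              [(f"C{k}", "C", tuple(rng.uniform(-8, 8, 3)))
                               for k in range(4)])
            units.append(make_unit(f"U{i}", residues, ligand=lig))
        area = binding_area_from_contacts(units, cutoff=4.0)
        # brute force: all-pairs distances, python loops
        for num in range(6):
            hits = 0
            for u in units:
                res = next(r for r in u.residues if r.number == num)
                close = any(
                    np.linalg.norm(a.position - b.position) < 4.0
                    for a in res.atoms for b in u.ligand.atoms
                )
                hits += close
            assert area.per_residue_contact_fraction[num] == pytest.approx(hits / 4)

    def test_no_ligand_is_error(self):
        unit = make_unit("U0", [_point_residue(10, "ALA", "CB", "C", (0, 0, 0))])
        with pytest.raises(ContactError, match="no unit carries a ligand"):
            binding_area_from_contacts([unit])


def _mode_unit(lig_atoms, *, d205=3.2, d206=3.5, d662=4.6):
    """Role residues on the x axis; ligand atoms given explicitly."""
    residues = [
        make_residue(205, "GLU", [("OE1", "O", (d205, 0, 0)),
                                  ("OE2", "O", (d205 + 2, 0, 0))]),
        make_residue(206, "GLU", [("OE1", "O", (0, d206, 0)),
                                  ("OE2", "O", (0, d206 + 2, 0))]),
        make_residue(662, "TYR", [("OH", "O", (0, 0, d662))]),
        make_residue(125, "ARG", [("NH1", "N", (-8.0, 0, 0)),
                                  ("NH2", "N", (-8.0, 1, 0))]),
        make_residue(710, "ASN", [("ND2", "N", (0, -8.0, 0)),
                                  ("OD1", "O", (1, -8.0, 0))]),
        make_residue(630, "SER", [("OG", "O", (0, 0, -6.0))]),
    ]
    lig = make_ligand("LIG_B900", "LIG", lig_atoms)
    return make_unit("U0", residues, ligand=lig)


class TestBindingModes:
    def test_amine_network_requires_all_three_distances(self):
        # primary amine at the origin: one bonded C neighbour
        unit = _mode_unit([("N1", "N", (0, 0, 0)), ("C1", "C", (1.4, 0, 0))])
        rec = classify_binding_modes(unit, SITE_MAP)
        assert rec.amine_network
        assert rec.amine_atom == "N1"
        assert rec.amine_distances["glu205"] == pytest.approx(3.2)

        far = _mode_unit([("N1", "N", (0, 0, 0)), ("C1", "C", (1.4, 0, 0))],
                         d662=5.2)
        assert not classify_binding_modes(far, SITE_MAP).amine_network

    def test_tertiary_amine_does_not_qualify(self):
        unit = _mode_unit([
            ("N1", "N", (0, 0, 0)),
            ("C1", "C", (1.4, 0, 0)),
            ("C2", "C", (-0.7, 1.2, 0)),
            ("C3", "C", (-0.7, -1.2, 0)),
        ])
        assert not classify_binding_modes(unit, SITE_MAP).amine_network

    def test_ligand_without_nitrogen_has_no_network(self):
        # mirrors the one inhibitor in the study set with no N atom
        unit = _mode_unit([("C1", "C", (0, 0, 0)), ("O1", "O", (1.4, 0, 0))])
        rec = classify_binding_modes(unit, SITE_MAP)
        assert not rec.amine_network

    def test_polar_anchor_via_either_partner_and_halogens(self):
        unit = _mode_unit([("C1", "C", (0, 0, 0)),
                           ("CL1", "CL", (-5.0, 0, 0))])  # 3.0 A from Arg NH1
        rec = classify_binding_modes(unit, SITE_MAP)
        assert rec.polar_anchor and rec.arg125_contact
        assert rec.anchor_partner == "arg125"
        assert rec.anchor_distance == pytest.approx(3.0)

        unit2 = _mode_unit([("C1", "C", (0, 0, 0)),
                            ("O9", "O", (0, -5.0, 0))])  # 3.0 A from Asn ND2
        rec2 = classify_binding_modes(unit2, SITE_MAP)
        assert rec2.polar_anchor and rec2.asn710_contact and not rec2.arg125_contact

    def test_covalent_ser630_uses_carbon_only(self):
        unit = _mode_unit([("C1", "C", (0, 0, -3.5)),
                           ("N1", "N", (0, 0, -4.0))])  # N is 2.0 A from OG
        rec = classify_binding_modes(unit, SITE_MAP)
        assert rec.ser630_distance == pytest.approx(2.5)
        assert rec.covalent_ser630
        far = _mode_unit([("C1", "C", (0, 0, -2.9))])  # 3.1 A from OG
        assert not classify_binding_modes(far, SITE_MAP).covalent_ser630

    def test_missing_role_residue_is_error(self):
        unit = _mode_unit([("N1", "N", (0, 0, 0)), ("C1", "C", (1.4, 0, 0))])
        unit.residues = [r for r in unit.residues if r.number != 662]
        with pytest.raises(ContactError, match="tyr662"):
            classify_binding_modes(unit, SITE_MAP)

    def test_synthetic_ensemble_modes_match_ground_truth(self, small_ensemble):
        units, truth = small_ensemble
        lt = truth.ligand_truth
        for u in units:
            rec = classify_binding_modes(u, truth.role_map)
            assert rec.amine_network == lt["expected_amine_network"]
            assert rec.polar_anchor == lt["expected_polar_anchor"]
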