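"""SASA, buried interface area and contact typing."""

import numpy as np
import pytest

from dehalokit import interface, structure, synthetic
from dehalokit.interface import (Contact, ContactKind, ContactRules,
                                 SasaParams, detect_contacts,
                                 interface_percentage, interface_report, sasa)

from conftest import random_rotation


def _atom(serial, name, element, res_name, chain, res_seq, xyz, het=False):
    return synthetic._atom(serial, name, element, res_name, chain, res_seq,
                           xyz, het=het)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        a = _atom(1, "CA", "C", "GLY", "A", 1, (0, 0, 0))
        total = sasa([a]).total
        exact = 4 * np.pi * (1.70 + 1.4) ** 2
        assert total == pytest.approx(exact, rel=0.01)

    def test_distant_atoms_sum_of_spheres(self):
        a = _atom(1, "CA", "C", "GLY", "A", 1, (0, 0, 0))
        b = _atom(2, "O", "O", "GLY", "A", 2, (100, 0, 0))
        exact = 4 * np.pi * ((1.70 + 1.4) ** 2 + (1.52 + 1.4) ** 2)
        assert sasa([a, b]).total == pytest.approx(exact, rel=0.01)

    def test_overlapping_pair_vs_dense_oracle(self):
        a = _atom(1, "CA", "C", "GLY", "A", 1, (0, 0, 0))
        b = _atom(2, "O", "O", "GLY", "A", 2, (1.8, 0, 0))
        coarse = sasa([a, b]).total
        dense = sasa([a, b], SasaParams(n_points=100000)).total
        assert coarse == pytest.approx(dense, rel=0.02)

    def test_unknown_element_falls_back_with_warning(self):
        x = _atom(1, "XX", "XX", "UNK", "A", 1, (0, 0, 0))
        with pytest.warns(UserWarning, match="fallback"):
            total = sasa([x]).total
        assert total == pytest.approx(4 * np.pi * (1.70 + 1.4) ** 2, rel=0.01)

    def test_unknown_element_error_when_fallback_disabled(self):
        x = _atom(1, "XX", "XX", "UNK", "A", 1, (0, 0, 0))
        with pytest.raises(KeyError):
            sasa([x], SasaParams(allow_fallback=False))

    def test_total_sasa_monotone_on_approach(self):
        """Surface can only be buried, never created, as groups approach."""
        a = _atom(1, "CA", "C", "GLY", "A", 1, (0, 0, 0))
        prev = np.inf
        for d in [20.0, 10.0, 6.0, 4.5, 3.4, 2.8]:
            b = _atom(2, "CA", "C", "GLY", "B", 1, (d, 0, 0))
            total = sasa([a, b]).total
            assert total <= prev + 1e-6
            prev = total

    def test_agrees_with_independent_biotite_oracle(self):
        biotite_struc = pytest.importorskip("biotite.structure")
        rng = np.random.default_rng(8)
        n = 30
        xyz = rng.uniform(0, 12, size=(n, 3))
        atoms = [_atom(i + 1, "CA", "C", "GLY", "A", i + 1, p)
                 for i, p in enumerate(xyz)]
        ours = sasa(atoms, SasaParams(n_points=2000)).total
        arr = biotite_struc.AtomArray(n)
        arr.coord = xyz.astype(np.float32)
        arr.atom_name = np.array(["CA"] * n)
        arr.element = np.array(["C"] * n)
        arr.res_name = np.array(["GLY"] * n)
        arr.res_id = np.arange(1, n + 1)
        arr.chain_id = np.array(["A"] * n)
        theirs = float(np.sum(biotite_struc.sasa(
            arr, probe_radius=1.4, point_number=2000,
            vdw_radii=np.full(n, 1.70))))
        assert ours == pytest.approx(theirs, rel=0.02)


class TestInterfaceArea:
    def test_printed_percentage_arithmetic(self):
        # PISA-convention interface/total percentages at one-decimal rounding
        assert round(interface_percentage(10907.7, 618.0), 1) == 5.7
        assert round(interface_percentage(11272.2, 957.1), 1) == 8.5
        assert round(interface_percentage(11627.2, 445.0), 1) == 3.8

    def test_far_apart_chains_zero_interface(self, chain_selector):
        model, _ = synthetic.gen_toy_dimer(separation=100.0, seed=3)
        rep = interface_report(model, chain_selector("A"), chain_selector("B"))
        assert rep.interface_area == pytest.approx(0.0, abs=1e-6)
        assert rep.contacts == []

    def test_toy_dimer_matches_generator_truth(self, chain_selector):
        model, truth = synthetic.gen_toy_dimer(seed=7)
        rep = interface_report(model, chain_selector("A"), chain_selector("B"))
        assert rep.interface_area == pytest.approx(truth["buried_area"], rel=0.03)
        assert 0 <= rep.interface_pct <= 100

    def test_symmetry_under_group_swap(self, chain_selector):
        model, _ = synthetic.gen_toy_dimer(seed=9)
        ab = interface_report(model, chain_selector("A"), chain_selector("B"))
        ba = interface_report(model, chain_selector("B"), chain_selector("A"))
        assert ab.interface_area == pytest.approx(ba.interface_area, rel=1e-6)

    def test_overlapping_groups_rejected(self, chain_selector):
        model, _ = synthetic.gen_toy_dimer(seed=9)
        with pytest.raises(ValueError, match="disjoint|overlap"):
            interface_report(model, chain_selector("A"), chain_selector("A"))


class TestContacts:
    def _pair_model(self, atom_a, atom_b, waters=()):
        return structure.StructureModel(atoms=[atom_a, atom_b, *waters])

    def test_single_hbond_at_printed_distance(self, chain_selector):
        m = self._pair_model(
            _atom(1, "O", "O", "PRO", "A", 63, (0, 0, 0)),
            _atom(2, "NH1", "N", "ARG", "B", 194, (2.75, 0, 0)))
        contacts = detect_contacts(m, chain_selector("A"), chain_selector("B"))
        assert [c.kind for c in contacts] == [ContactKind.HBOND]
        assert contacts[0].distance == pytest.approx(2.75)

    def test_single_hydrophobic_residue_pair(self, chain_selector):
        # two carbons in one Phe flanking one Leu carbon: counted once
        m = structure.StructureModel(atoms=[
            _atom(1, "CZ", "C", "PHE", "A", 65, (0, 0, 0)),
            _atom(2, "CE1", "C", "PHE", "A", 65, (0, 1.4, 0)),
            _atom(3, "CD1", "C", "LEU", "B", 190, (3.35, 0, 0))])
        contacts = detect_contacts(m, chain_selector("A"), chain_selector("B"))
        assert [c.kind for c in contacts] == [ContactKind.HYDROPHOBIC]
        assert contacts[0].distance == pytest.approx(3.35)

    def test_backbone_carbons_not_hydrophobic(self, chain_selector):
        m = self._pair_model(
            _atom(1, "CA", "C", "LEU", "A", 1, (0, 0, 0)),
            _atom(2, "CA", "C", "LEU", "B", 1, (3.5, 0, 0)))
        assert detect_contacts(m, chain_selector("A"), chain_selector("B")) == []

    def test_water_bridge_with_printed_leg_distances(self, chain_selector):
        w = _atom(9, "O", "O", "HOH", "W", 500, (0, 0, 0), het=True)
        m = self._pair_model(
            _atom(1, "O", "O", "GLU", "A", 146, (2.65, 0, 0)),
            _atom(2, "ND2", "N", "GLN", "B", 184, (-2.54, 0, 0)),
            waters=[w])
        contacts = detect_contacts(m, chain_selector("A"), chain_selector("B"))
        bridges = [c for c in contacts if c.kind is ContactKind.WATER_BRIDGE]
        assert len(bridges) == 1
        assert bridges[0].distance == (pytest.approx(2.65), pytest.approx(2.54))
        assert bridges[0].bridge_water == ("W", 500)

    def test_planted_dimer_contacts_found_exactly(self, chain_selector):
        spec = [{"kind": "HBOND", "distance": 2.75},
                {"kind": "HYDROPHOBIC", "distance": 3.35},
                {"kind": "WATER_BRIDGE", "distance": [2.65, 2.54]}]
        model, truth = synthetic.gen_toy_dimer(interface_spec=spec, seed=7)
        contacts = detect_contacts(model, chain_selector("A"), chain_selector("B"))
        kinds = sorted(c.kind.value for c in contacts)
        assert kinds == ["HBOND", "HYDROPHOBIC", "WATER_BRIDGE"]
        hb = next(c for c in contacts if c.kind is ContactKind.HBOND)
        assert hb.distance == pytest.approx(2.75, abs=0.01)

    def test_contact_list_symmetric_under_chain_swap(self, chain_selector):
        spec = [{"kind": "HBOND", "distance": 3.0},
                {"kind": "HYDROPHOBIC", "distance": 3.8}]
        model, _ = synthetic.gen_toy_dimer(interface_spec=spec, seed=4)
        ab = detect_contacts(model, chain_selector("A"), chain_selector("B"))
        ba = detect_contacts(model, chain_selector("B"), chain_selector("A"))
        assert sorted(c.kind.value for c in ab) == sorted(c.kind.value for c in ba)
        assert {(c.partner_a, c.partner_b) for c in ab} == \
            {(c.partner_b, c.partner_a) for c in ba}

    def test_contacts_invariant_under_rigid_transform(self, chain_selector):
        spec = [{"kind": "HBOND", "distance": 2.9}]
        model, _ = synthetic.gen_toy_dimer(interface_spec=spec, seed=2)
        rng = np.random.default_rng(11)
        moved = model.transformed(random_rotation(rng), rng.normal(scale=20, size=3))
        before = detect_contacts(model, chain_selector("A"), chain_selector("B"))
        after = detect_contacts(moved, chain_selector("A"), chain_selector("B"))
        assert [(c.kind, c.partner_a, c.partner_b) for c in before] == \
            [(c.kind, c.partner_a, c.partner_b) for c in after]
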