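"""Typed contact detection against brute-force oracles and hand geometry."""

import numpy as np
import pytest

from ifevol import (
    ContactConfig,
    apolar_contacts,
    atomic_contacts,
    charged_contacts,
    hydrogen_bonds,
    residue_contact_graph,
    salt_bridges,
)
from ifevol.structure import ComplexStructure, Chain, ResidueId, compute_sasa

from conftest import make_complex, make_residue


def _single_atom_res(chain, number, aa, name, element, xyz):
    return make_residue(chain, number, aa, [(name, element, xyz)])


class TestAtomicContacts:
    def test_pair_below_cutoff_detected(self):
        a = _single_atom_res("A", 1, "ALA", "CB", "C", (0, 0, 0))
        b = _single_atom_res("B", 1, "ALA", "CB", "C", (4.9, 0, 0))
        assert len(atomic_contacts(make_complex([a], [b]))) == 1

    def test_pair_above_cutoff_ignored(self):
        a = _single_atom_res("A", 1, "ALA", "CB", "C", (0, 0, 0))
        b = _single_atom_res("B", 1, "ALA", "CB", "C", (5.1, 0, 0))
        assert atomic_contacts(make_complex([a], [b])) == []

    def test_facing_grids_match_brute_force_oracle(self):
        # 3x3 grids of atoms facing at 4 A separation
        res_a, res_b = [], []
        k = 0
        for i in range(3):
            for j in range(3):
                k += 1
                res_a.append(_single_atom_res("A", k, "ALA", "CB", "C", (3.0 * i, 3.0 * j, 0)))
                res_b.append(_single_atom_res("B", k, "ALA", "CB", "C", (3.0 * i, 3.0 * j, 4.0)))
        cx = make_complex(res_a, res_b)
        found = atomic_contacts(cx)
        # O(n^2) oracle
        n_oracle = 0
        for ra in res_a:
            for rb in res_b:
                d = np.linalg.norm(ra.atoms[0].coords - rb.atoms[0].coords)
                if d <= 5.0:
                    n_oracle += 1
        assert len(found) == n_oracle

    def test_random_fixture_matches_oracle_exactly(self):
        rng = np.random.default_rng(3)
        res_a = [
            _single_atom_res("A", i + 1, "ALA", "CB", "C", tuple(rng.uniform(0, 15, 3)))
            for i in range(120)
        ]
        res_b = [
            _single_atom_res("B", i + 1, "ALA", "CB", "C", tuple(rng.uniform(0, 15, 3)))
            for i in range(120)
        ]
        cx = make_complex(res_a, res_b)
        found = {(c.rid_a, c.rid_b) for c in atomic_contacts(cx)}
        oracle = set()
        for ra in res_a:
            for rb in res_b:
                if np.linalg.norm(ra.atoms[0].coords - rb.atoms[0].coords) <= 5.0:
                    oracle.add((ra.rid, rb.rid))
        assert found == oracle

    def test_chain_swap_preserves_contacts(self, toy):
        structure, _t, analysis = toy
        swapped = ComplexStructure(
            receptor=structure.ligand, ligand=structure.receptor,
            source_id=structure.source_id,
        )
        fwd = {(c.rid_a, c.atom_a, c.rid_b, c.atom_b) for c in analysis.atomic}
        rev = {(c.rid_b, c.atom_b, c.rid_a, c.atom_a) for c in atomic_contacts(swapped)}
        assert fwd == rev


class TestResidueContactGraph:
    def test_weight_counts_atomic_contacts(self):
        a = make_residue("A", 10, "ALA", [("CB", "C", (0, 0, 0)), ("CA", "C", (1.0, 0, 0)),
                                          ("C", "C", (0, 1.0, 0))])
        b = _single_atom_res("B", 22, "ALA", "CB", "C", (0.0, 0.0, 3.0))
        edges = residue_contact_graph(atomic_contacts(make_complex([a], [b])))
        assert len(edges) == 1
        assert edges[(ResidueId("A", 10), ResidueId("B", 22))].weight == 3

    def test_empty_contacts_empty_graph(self):
        assert residue_contact_graph([]) == {}

    def test_edge_weights_sum_to_atomic_count(self, toy):
        _s, _t, analysis = toy
        assert sum(e.weight for e in analysis.residue_graph.values()) == len(analysis.atomic)


class TestChargedContacts:
    def test_salt_bridge_at_3p4(self):
        lys = make_residue("A", 1, "LYS", [("CB", "C", (0, 0, 0)), ("NZ", "N", (0, 0, 2.0))])
        glu = make_residue("B", 1, "GLU", [("OE1", "O", (0, 0, 5.4))])
        cx = make_complex([lys], [glu])
        assert (ResidueId("A", 1), ResidueId("B", 1)) in salt_bridges(cx)
        assert (ResidueId("A", 1), ResidueId("B", 1)) in charged_contacts(cx)

    def test_4p8_is_charged_but_not_salt_bridge(self):
        lys = make_residue("A", 1, "LYS", [("NZ", "N", (0, 0, 0))])
        asp = make_residue("B", 1, "ASP", [("OD2", "O", (0, 0, 4.8))])
        cx = make_complex([lys], [asp])
        assert not salt_bridges(cx)
        assert (ResidueId("A", 1), ResidueId("B", 1)) in charged_contacts(cx)

    def test_serine_og_is_not_a_charged_donor(self):
        ser = make_residue("A", 1, "SER", [("OG", "O", (0, 0, 0))])
        asp = make_residue("B", 1, "ASP", [("OD1", "O", (0, 0, 3.0))])
        assert not charged_contacts(make_complex([ser], [asp]))

    def test_salt_bridges_subset_of_charged(self, toy):
        _s, _t, analysis = toy
        assert set(analysis.salt_bridges) <= set(analysis.charged)

    def test_wider_cutoff_flag_finds_more_or_equal(self, toy):
        structure, _t, _a = toy
        assert set(charged_contacts(structure, 5.5)) <= set(charged_contacts(structure, 6.0))


class TestHydrogenBonds:
    def test_sidechain_to_backbone_accepted(self):
        # Ser OG donor 3.0 A from a backbone O, antecedent angle ~127 deg
        ser = make_residue("A", 1, "SER", [("CB", "C", (-0.9, 0, -1.2)), ("OG", "O", (0, 0, 0))])
        gly = make_residue("B", 1, "GLY", [("CA", "C", (1.0, 0, 4.0)), ("O", "O", (0, 0, 3.0))])
        hb = hydrogen_bonds(make_complex([ser], [gly]))
        assert (ResidueId("A", 1), ResidueId("B", 1)) in hb

    def test_backbone_backbone_excluded(self):
        a = make_residue("A", 1, "GLY", [("CA", "C", (1.2, 0, -1.0)), ("N", "N", (0, 0, 0))])
        b = make_residue("B", 1, "GLY", [("O", "O", (0, 0, 2.9))])
        assert not hydrogen_bonds(make_complex([a], [b]))

    def test_bad_antecedent_angle_rejected(self):
        # antecedent nearly on the acceptor side: angle ~53 deg < 90
        ser = make_residue("A", 1, "SER", [("CB", "C", (1.0, 0, 1.0)), ("OG", "O", (0, 0, 0))])
        gly = make_residue("B", 1, "GLY", [("CA", "C", (1.0, 0, 4.0)), ("O", "O", (0, 0, 3.0))])
        assert not hydrogen_bonds(make_complex([ser], [gly]))

    def test_planted_hbonds_recovered_on_toy(self, toy):
        _s, truth, analysis = toy
        for pair in truth.hbonds:
            assert pair in analysis.hbonds


class TestApolarContacts:
    def _iface_and_sasa(self, cx):
        iface = {"A": {r.rid for r in cx.receptor.residues},
                 "B": {r.rid for r in cx.ligand.residues}}
        sasa = compute_sasa(cx, "monomer", n_points=240)
        return iface, sasa

    def test_leucine_pair_at_4p2(self):
        leu = make_residue("A", 1, "LEU", [("CD1", "C", (0, 0, 0))])
        ile = make_residue("B", 1, "ILE", [("CG2", "C", (0, 0, 4.2))])
        cx = make_complex([leu], [ile])
        iface, sasa = self._iface_and_sasa(cx)
        assert (ResidueId("A", 1), ResidueId("B", 1)) in apolar_contacts(cx, iface, sasa)

    def test_charged_residue_carbon_counts(self):
        lys = make_residue("A", 1, "LYS", [("CD", "C", (0, 0, 0))])
        val = make_residue("B", 1, "VAL", [("CG1", "C", (0, 0, 4.0))])
        cx = make_complex([lys], [val])
        iface, sasa = self._iface_and_sasa(cx)
        assert (ResidueId("A", 1), ResidueId("B", 1)) in apolar_contacts(cx, iface, sasa)

    def test_buried_atom_excluded(self):
        from ifevol.structure import fibonacci_sphere

        core = [("CD1", "C", (0.0, 0.0, 0.0))]
        cage = [(f"C{i}", "C", tuple(p)) for i, p in enumerate(fibonacci_sphere(60) * 2.2)]
        leu = make_residue("A", 1, "LEU", core + cage)  # CD1 has zero monomer SASA
        val = make_residue("B", 1, "VAL", [("CG1", "C", (0, 0, 4.0))])
        cx = make_complex([leu], [val])
        iface, sasa = self._iface_and_sasa(cx)
        contacts = apolar_contacts(cx, iface, sasa)
        names = [n for pairs in contacts.values() for (n, _m, _d) in pairs]
        assert "CD1" not in names

    def test_non_interface_residues_contribute_nothing(self):
        leu = make_residue("A", 1, "LEU", [("CD1", "C", (0, 0, 0))])
        ile = make_residue("B", 1, "ILE", [("CG2", "C", (0, 0, 4.2))])
        cx = make_complex([leu], [ile])
        sasa = compute_sasa(cx, "monomer", n_points=240)
        assert apolar_contacts(cx, {"A": set(), "B": set()}, sasa) == {}

    def test_planted_lone_pairs_recovered_on_toy(self, toy):
        _s, truth, analysis = toy
        for pair in truth.lone_apolar:
            assert pair in analysis.apolar
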