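"""Apolar patch detection, merging, bundles and random nulls."""

import numpy as np
import pytest

from ifevol import detect_patches, merge_patches_across_interologs, patch_contact_bundles
from ifevol.contacts import ContactConfig
from ifevol.patches import ApolarPatch, random_patches
from ifevol.structure import ComplexStructure, ResidueId, compute_sasa

from conftest import make_complex, make_residue


def _chain_with_carbons(chain_id, residue_atoms):
    """residue_atoms: list of lists of xyz per residue (side-chain carbons)."""
    residues = []
    for i, coords in enumerate(residue_atoms, start=1):
        atoms = [(f"CD{j+1}", "C", tuple(xyz)) for j, xyz in enumerate(coords)]
        residues.append(make_residue(chain_id, i, "LEU", atoms))
    return residues


def _union_find_components(coords, cutoff):
    """Independent connected-components oracle."""
    parent = list(range(len(coords)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            if np.linalg.norm(np.array(coords[i]) - np.array(coords[j])) <= cutoff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups = {}
    for i in range(len(coords)):
        groups.setdefault(find(i), []).append(i)
    return sorted(sorted(g) for g in groups.values())


def _detect(res_a, res_b=None):
    res_b = res_b or [make_residue("B", 1, "GLY", [("CA", "C", (100, 100, 100))])]
    cx = make_complex(res_a, res_b)
    iface = {"A": {r.rid for r in res_a}, "B": {r.rid for r in res_b}}
    sasa = compute_sasa(cx, "monomer", n_points=240)
    return detect_patches(cx, iface, sasa), cx


class TestDetectPatches:
    def test_five_atoms_two_residues_one_patch(self):
        res = _chain_with_carbons("A", [
            [(0, 0, 0), (4, 0, 0), (8, 0, 0)],
            [(12, 0, 0), (16, 0, 0)],
        ])
        patches, _cx = _detect(res)
        assert len(patches["A"]) == 1
        assert patches["A"][0].size == 5

    def test_three_atoms_fail_size_rule(self):
        res = _chain_with_carbons("A", [[(0, 0, 0), (4, 0, 0)], [(8, 0, 0)]])
        patches, _cx = _detect(res)
        assert patches["A"] == []

    def test_four_atoms_single_residue_fail_residue_rule(self):
        res = _chain_with_carbons("A", [[(0, 0, 0), (2, 0, 0), (4, 0, 0), (6, 0, 0)]])
        patches, _cx = _detect(res)
        assert patches["A"] == []

    def test_two_clusters_merge_with_bridge(self):
        cluster1 = [[(0, 0, 0), (4, 0, 0)], [(2, 3, 0), (4, 3, 0)]]
        cluster2 = [[(16, 0, 0), (20, 0, 0)], [(18, 3, 0), (20, 3, 0)]]
        patches, _cx = _detect(_chain_with_carbons("A", cluster1 + cluster2))
        assert len(patches["A"]) == 2
        bridged = _chain_with_carbons("A", cluster1 + cluster2 + [[(8, 0, 0), (12, 0, 0)]])
        patches2, _cx = _detect(bridged)
        assert len(patches2["A"]) == 1

    def test_components_match_union_find_oracle(self):
        rng = np.random.default_rng(11)
        residue_atoms = [rng.uniform(0, 25, size=(2, 3)).tolist() for _ in range(20)]
        res = _chain_with_carbons("A", residue_atoms)
        patches, cx = _detect(res)
        flat = [(r.rid, a.name, tuple(a.coords)) for r in res for a in r.atoms]
        comps = _union_find_components([c for (_r, _n, c) in flat], 5.5)
        oracle = []
        for comp in comps:
            atoms = [(flat[i][0], flat[i][1]) for i in comp]
            rids = {r for r, _n in atoms}
            if len(atoms) >= 4 and len(rids) >= 2:
                oracle.append(sorted(atoms))
        found = [sorted(p.atoms) for p in patches["A"]]
        assert sorted(map(tuple, found)) == sorted(map(tuple, oracle))

    def test_planted_patch_recovered_on_toy(self, toy):
        _s, truth, analysis = toy
        for cid in ("A", "B"):
            planted = set(truth.patch_residues[cid])
            assert any(planted <= p.residues for p in analysis.patches[cid])


def _patch(side, rid_numbers, offset=0):
    atoms = [(ResidueId(side, n), f"C{k}") for k, n in enumerate(rid_numbers, start=offset)]
    return ApolarPatch(side=side, atoms=atoms)


class TestMergePatches:
    def test_single_merge_step(self):
        # A-patch overlaps b1 and b2 -> they merge, mapping becomes 1:1
        a1 = _patch("A", [1, 2, 3, 4])
        b1 = _patch("A", [1, 2])
        b2 = _patch("A", [3, 4])
        corr = {ResidueId("A", n): ResidueId("A", n) for n in range(1, 5)}
        pa, pb, mapping = merge_patches_across_interologs([a1], [b1, b2], corr)
        assert len(pb) == 1
        assert mapping == {0: 0}

    def test_disjoint_patches_unmapped(self):
        a1 = _patch("A", [1, 2, 3, 4])
        b1 = _patch("A", [10, 11, 12, 13])
        corr = {ResidueId("A", n): ResidueId("A", n) for n in range(1, 20)}
        pa, pb, mapping = merge_patches_across_interologs([a1], [b1], corr)
        assert mapping == {}
        assert len(pa) == 1 and len(pb) == 1

    def test_chain_of_overlaps_collapses(self):
        # a1-b1, a2-b1, a2-b2: everything collapses to one patch each side
        a1 = _patch("A", [1, 2])
        a2 = _patch("A", [3, 4, 5])
        b1 = _patch("A", [2, 3])
        b2 = _patch("A", [5, 6])
        corr = {ResidueId("A", n): ResidueId("A", n) for n in range(1, 10)}
        pa, pb, mapping = merge_patches_across_interologs([a1, a2], [b1, b2], corr)
        assert len(pa) == 1 and len(pb) == 1
        assert mapping == {0: 0}

    def test_mapping_injective_both_directions(self, toy_pair, identity_corr):
        _sa, _sb, _t2, aa, ab = toy_pair
        sub = {k: v for k, v in identity_corr.mapping.items() if k.chain_id == "A"}
        _pa, _pb, mapping = merge_patches_across_interologs(
            aa.patches["A"], ab.patches["A"], sub
        )
        assert len(set(mapping.values())) == len(mapping)


class TestBundles:
    def test_bundle_counts_and_participation(self, toy):
        _s, truth, analysis = toy
        bundles = patch_contact_bundles(analysis.patches, analysis.apolar, "A", "B")
        assert bundles, "planted facing patches must form at least one bundle"
        for b in bundles:
            assert b.n_apolar_contacts >= 1
            assert 0.0 < b.participation_a <= 1.0
            assert 0.0 < b.participation_b <= 1.0

    def test_no_apolar_contact_no_bundle(self):
        patches = {"A": [_patch("A", [1, 2, 3, 4])], "B": [_patch("B", [1, 2, 3, 4])]}
        assert patch_contact_bundles(patches, {}, "A", "B") == []

    def test_participation_ratio(self):
        pa = ApolarPatch(side="A", atoms=[(ResidueId("A", n), "CB") for n in (1, 2, 3, 4)])
        pb = ApolarPatch(side="B", atoms=[(ResidueId("B", n), "CB") for n in (1, 2, 3, 4)])
        apolar = {
            (ResidueId("A", 1), ResidueId("B", 1)): [("CB", "CB", 4.0)],
            (ResidueId("A", 2), ResidueId("B", 1)): [("CB", "CB", 4.1)],
        }
        bundles = patch_contact_bundles({"A": [pa], "B": [pb]}, apolar, "A", "B")
        assert len(bundles) == 1
        assert bundles[0].participation_a == pytest.approx(0.5)
        assert bundles[0].participation_b == pytest.approx(0.25)


class TestRandomPatches:
    def _run(self, toy, seed):
        structure, _truth, analysis = toy
        return random_patches(
            structure,
            analysis.interface_model.interface,
            analysis.monomer_sasa,
            analysis.patches,
            analysis.interface_model.regions,
            seed=seed,
        )

    def test_deterministic_given_seed(self, toy):
        r1 = self._run(toy, 5)
        r2 = self._run(toy, 5)
        assert {k: [p.atoms for p in v] for k, v in r1.items()} == {
            k: [p.atoms for p in v] for k, v in r2.items()
        }

    def test_size_histogram_matches_reference(self, toy):
        _s, _t, analysis = toy
        rand = self._run(toy, 7)
        for cid in ("A", "B"):
            assert sorted(p.size for p in rand[cid]) == sorted(
                p.size for p in analysis.patches[cid]
            )

    def test_generated_patches_connected(self, toy):
        structure, _t, _a = toy
        rand = self._run(toy, 9)
        for cid, plist in rand.items():
            for p in plist:
                coords = [structure.residue(r).get_atom(n).coords for r, n in p.atoms]
                comps = _union_find_components(coords, 5.5)
                assert len(comps) == 1

    def test_composition_within_one_per_class(self, toy):
        _s, _t, analysis = toy
        regions = analysis.interface_model.regions
        rand = self._run(toy, 13)
        for cid in ("A", "B"):
            for ref, rnd in zip(analysis.patches[cid], rand[cid]):
                cref = ref.region_composition(regions)
                crnd = rnd.region_composition(regions)
                for k in ("core", "support", "rim"):
                    assert abs(cref[k] - crnd[k]) <= 1
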