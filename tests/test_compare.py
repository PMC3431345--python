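"""Residue correspondence and conservation statistics."""

import numpy as np
import pytest

from ifevol import (
    chain_correspondence,
    charge_exchange,
    charge_fate,
    contact_conservation,
    identity_bin,
    min_interface_identity,
    switching_out,
)
from ifevol.compare import AlignmentMismatchError, CorrespondenceMap, kabsch_rmsd
from ifevol.structure import ResidueId
from ifevol import compare_pair

from conftest import make_complex, make_residue


def _seq_chain(chain_id, seq, offset=0.0):
    """One CA per residue along x, 3.8 A apart."""
    three = {"A": "ALA", "G": "GLY", "L": "LEU", "K": "LYS", "E": "GLU", "S": "SER",
             "D": "ASP", "R": "ARG", "V": "VAL", "F": "PHE", "T": "THR", "N": "ASN"}
    return [
        make_residue(chain_id, i + 1, three[aa], [("CA", "C", (3.8 * i, offset, 0))])
        for i, aa in enumerate(seq)
    ]


def _two_chain(seq_a, seq_b):
    return make_complex(_seq_chain("A", seq_a), _seq_chain("B", seq_b, offset=5.0))


def _nw_oracle(seq_a, seq_b, gap_open=11, gap_extend=1):
    """Independent Needleman-Wunsch with affine gaps (Gotoh), BLOSUM62."""
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    n1, n2 = len(seq_a), len(seq_b)
    neg = -1e9
    M = np.full((n1 + 1, n2 + 1), neg)
    X = np.full((n1 + 1, n2 + 1), neg)  # gap in seq_b (vertical)
    Y = np.full((n1 + 1, n2 + 1), neg)  # gap in seq_a (horizontal)
    M[0, 0] = 0.0
    for i in range(1, n1 + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, n2 + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            s = m[seq_a[i - 1], seq_b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
    # traceback for the aligned pairs
    pairs = []
    i, j = n1, n2
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    while i > 0 or j > 0:
        if state == 0:
            pairs.append((i - 1, j - 1))
            s = m[seq_a[i - 1], seq_b[j - 1]]
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1:
            state = 0 if M[i - 1, j] - gap_open >= X[i - 1, j] - gap_extend else 1
            i -= 1
        else:
            state = 0 if M[i, j - 1] - gap_open >= Y[i, j - 1] - gap_extend else 2
            j -= 1
    return sorted(pairs)


class TestChainCorrespondence:
    def test_identical_chains_identity_map(self):
        ca = _two_chain("GAKLS", "GAKLS")
        cb = _two_chain("GAKLS", "GAKLS")
        corr = chain_correspondence(ca, cb)
        assert corr.chain_identity == {"A": 100.0, "B": 100.0}
        for rid, mapped in corr.mapping.items():
            assert rid.number == mapped.number

    def test_provided_alignment_gap_unmapped(self, tmp_path):
        ca = _two_chain("GAKLS", "GG")
        cb = _two_chain("GAS", "GG")
        path = tmp_path / "aln.fasta"
        path.write_text(">a\nGAKLS\n>b\nGA--S\n")
        corr = chain_correspondence(ca, cb, alignments={("A", "A"): path})
        a_mapped = {r.number for r in corr.mapping if r.chain_id == "A"}
        assert a_mapped == {1, 2, 5}
        assert corr.source == "provided-alignment"

    def test_provided_alignment_mismatch_names_position(self, tmp_path):
        ca = _two_chain("GAKLS", "GG")
        cb = _two_chain("GAS", "GG")
        path = tmp_path / "aln.fasta"
        path.write_text(">a\nGTKLS\n>b\nGA--S\n")
        with pytest.raises(AlignmentMismatchError, match="position 2"):
            chain_correspondence(ca, cb, alignments={("A", "A"): path})

    def test_computed_alignment_matches_dp_oracle(self):
        seq_a, seq_b = "GAVLKESTRFND", "GAVLSTRFND"
        ca = _two_chain(seq_a, "GG")
        cb = _two_chain(seq_b, "GG")
        corr = chain_correspondence(ca, cb)
        pairs = sorted(
            (k.number - 1, v.number - 1)
            for k, v in corr.mapping.items()
            if k.chain_id == "A"
        )
        assert pairs == _nw_oracle(seq_a, seq_b)

    def test_superposition_rmsd_zero_for_identical(self):
        ca = _two_chain("GAKLS", "GAKLS")
        cb = _two_chain("GAKLS", "GAKLS")
        corr = chain_correspondence(ca, cb, superpose=True)
        assert corr.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_kabsch_recovers_rotated_cloud(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 3))
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        y = x @ rot.T + np.array([5.0, -3.0, 2.0])
        assert kabsch_rmsd(x, y) == pytest.approx(0.0, abs=1e-9)


def _corr(pairs):
    return CorrespondenceMap(mapping=dict(pairs), chain_pairing=[("A", "A"), ("B", "B")])


def _rid(ch, n):
    return ResidueId(ch, n)


class TestContactConservation:
    def _ids(self):
        corr = _corr({
            _rid("A", i): _rid("A", i) for i in (1, 2, 3)
        } | {_rid("B", i): _rid("B", i) for i in (1, 2, 3)})
        return corr

    def test_identical_graphs_fully_conserved(self):
        edges = {(_rid("A", 1), _rid("B", 1)): 2.0, (_rid("A", 2), _rid("B", 2)): 5.0}
        res = contact_conservation(edges, edges, self._ids())
        assert res.ratio == 1.0

    def test_disjoint_graphs_zero(self):
        ea = {(_rid("A", 1), _rid("B", 1)): 2.0}
        eb = {(_rid("A", 2), _rid("B", 2)): 3.0}
        assert contact_conservation(ea, eb, self._ids()).ratio == 0.0

    def test_weighting_rule_hand_example(self):
        # A: {(1,1'):2, (2,2'):4}; B: {(1,1'):6} -> conserved avg(2,6)=4, non 4
        ea = {(_rid("A", 1), _rid("B", 1)): 2.0, (_rid("A", 2), _rid("B", 2)): 4.0}
        eb = {(_rid("A", 1), _rid("B", 1)): 6.0}
        res = contact_conservation(ea, eb, self._ids())
        assert res.conserved_weight == pytest.approx(4.0)
        assert res.non_conserved_weight == pytest.approx(4.0)
        assert res.ratio == pytest.approx(0.5)

    def test_empty_vs_empty_is_missing_not_zero(self):
        assert contact_conservation({}, {}, self._ids()).ratio is None

    def test_unmapped_endpoints_excluded_both_sides(self):
        corr = _corr({_rid("A", 1): _rid("A", 1), _rid("B", 1): _rid("B", 1)})
        ea = {(_rid("A", 1), _rid("B", 1)): 2.0, (_rid("A", 9), _rid("B", 1)): 7.0}
        eb = {(_rid("A", 1), _rid("B", 1)): 2.0, (_rid("A", 8), _rid("B", 1)): 9.0}
        res = contact_conservation(ea, eb, corr)
        assert res.ratio == 1.0  # unmapped-residue edges never penalize

    def test_jaccard_symmetric_under_swap(self, toy_pair, identity_corr):
        _sa, _sb, _t2, aa, ab = toy_pair
        fwd = contact_conservation(
            aa.atomic_edge_weights(), ab.atomic_edge_weights(), identity_corr
        )
        rev_corr = CorrespondenceMap(
            mapping=identity_corr.reverse, chain_pairing=identity_corr.chain_pairing
        )
        rev = contact_conservation(
            ab.atomic_edge_weights(), aa.atomic_edge_weights(), rev_corr
        )
        assert fwd.ratio == pytest.approx(rev.ratio)


class TestSwitchingOut:
    def test_self_comparison_zero(self):
        iface = {_rid("A", 1), _rid("B", 1)}
        corr = _corr({r: r for r in iface})
        sw = switching_out(iface, iface, corr)
        assert sw.fraction == 0.0

    def test_displaced_rim_residue_flagged(self):
        iface_a = {_rid("A", 1), _rid("A", 2)}
        iface_b = {_rid("A", 1)}
        corr = _corr({_rid("A", 1): _rid("A", 1), _rid("A", 2): _rid("A", 2)})
        sw = switching_out(iface_a, iface_b, corr)
        assert sw.flags_a == {_rid("A", 1): False, _rid("A", 2): True}

    def test_unmapped_residues_excluded(self):
        iface_a = {_rid("A", 1), _rid("A", 2)}
        corr = _corr({_rid("A", 1): _rid("A", 1)})
        sw = switching_out(iface_a, {_rid("A", 1)}, corr)
        assert _rid("A", 2) not in sw.flags_a


class TestChargeExchange:
    def _pair(self, aa_a1, aa_a2, aa_b1, aa_b2):
        atoms = {"LYS": ("NZ", "N"), "ARG": ("NH1", "N"), "GLU": ("OE1", "O"),
                 "ASP": ("OD1", "O"), "SER": ("OG", "O")}
        def res(ch, n, aa, x):
            name, el = atoms[aa]
            return make_residue(ch, n, aa, [(name, el, (x, 0, 0))])
        ca = make_complex([res("A", 1, aa_a1, 0.0)], [res("B", 1, aa_a2, 3.0)])
        cb = make_complex([res("A", 1, aa_b1, 0.0)], [res("B", 1, aa_b2, 3.0)])
        corr = _corr({_rid("A", 1): _rid("A", 1), _rid("B", 1): _rid("B", 1)})
        e = (_rid("A", 1), _rid("B", 1))
        return charge_exchange([e], [e], corr, ca, cb)

    def test_same_polarity_conserved_not_exchange(self):
        out = self._pair("LYS", "GLU", "ARG", "ASP")
        assert out == {(_rid("A", 1), _rid("B", 1)): False}

    def test_swapped_polarity_is_exchange(self):
        out = self._pair("LYS", "GLU", "ASP", "ARG")
        assert out == {(_rid("A", 1), _rid("B", 1)): True}

    def test_lost_bridge_not_counted(self):
        atoms = {"LYS": ("NZ", "N"), "GLU": ("OE1", "O"), "SER": ("OG", "O")}
        def res(ch, n, aa, x):
            name, el = atoms[aa]
            return make_residue(ch, n, aa, [(name, el, (x, 0, 0))])
        ca = make_complex([res("A", 1, "LYS", 0.0)], [res("B", 1, "GLU", 3.0)])
        cb = make_complex([res("A", 1, "SER", 0.0)], [res("B", 1, "GLU", 3.0)])
        corr = _corr({_rid("A", 1): _rid("A", 1), _rid("B", 1): _rid("B", 1)})
        e = (_rid("A", 1), _rid("B", 1))
        out = charge_exchange([e], [], corr, ca, cb)
        assert out == {}


class TestChargeFate:
    def _base(self, b_receptor, b_ligand, iface_b):
        ca = make_complex(
            [make_residue("A", 1, "LYS", [("NZ", "N", (0, 0, 0))])],
            [make_residue("B", 1, "GLU", [("OE1", "O", (0, 0, 3.0))])],
        )
        cb = make_complex(b_receptor, b_ligand)
        corr = _corr({_rid("A", 1): _rid("A", 1), _rid("B", 1): _rid("B", 1)})
        e = (_rid("A", 1), _rid("B", 1))
        return charge_fate([e], [], corr, ca, cb, iface_b)

    def test_intra_chain_bridge_is_sb_intra(self):
        # partner mutated to Ser; Lys keeps an intra-chain bridge to Asp at 3.2
        rec = [
            make_residue("A", 1, "LYS", [("NZ", "N", (0, 0, 0))]),
            make_residue("A", 2, "ASP", [("OD1", "O", (3.2, 0, 0))]),
        ]
        lig = [make_residue("B", 1, "SER", [("OG", "O", (0, 0, 3.0))])]
        fates = self._base(rec, lig, iface_b={_rid("A", 1), _rid("B", 1)})
        assert fates[_rid("A", 1)] == "SB-intra"

    def test_long_range_partner_is_ch_inter(self):
        rec = [make_residue("A", 1, "LYS", [("NZ", "N", (0, 0, 0))])]
        lig = [
            make_residue("B", 1, "SER", [("OG", "O", (0, 0, 3.0))]),
            make_residue("B", 2, "ASP", [("OD1", "O", (5.0, 0, 0))]),
        ]
        fates = self._base(rec, lig, iface_b={_rid("A", 1), _rid("B", 1)})
        assert fates[_rid("A", 1)] == "CH-inter"

    def test_departed_residue_is_switch_out(self):
        rec = [make_residue("A", 1, "LYS", [("NZ", "N", (0, 0, 0))])]
        lig = [make_residue("B", 1, "SER", [("OG", "O", (0, 0, 3.0))])]
        fates = self._base(rec, lig, iface_b={_rid("B", 1)})  # Lys left the interface
        assert fates[_rid("A", 1)] == "switch-out"


class TestInterfaceIdentity:
    def test_bins(self):
        assert identity_bin(0.0) == "[0,30)"
        assert identity_bin(29.9) == "[0,30)"
        assert identity_bin(30.0) == "[30,50)"
        assert identity_bin(69.9) == "[50,70)"
        assert identity_bin(70.0) == "[70,100]"
        assert identity_bin(100.0) == "[70,100]"

    def test_minimum_of_two_chains(self):
        # chain A: 3/10 identical interface positions; chain B: identical
        seq_a = "AAAAAAAAAA"
        seq_b = "AAAVVVVVVV"
        ca = _two_chain(seq_a, "GGG")
        cb = _two_chain(seq_b, "GGG")
        corr = _corr(
            {_rid("A", i): _rid("A", i) for i in range(1, 11)}
            | {_rid("B", i): _rid("B", i) for i in range(1, 4)}
        )
        iface_a = set(corr.mapping)
        iface_b = set(corr.mapping.values())
        minimum, label, per = min_interface_identity(ca, cb, iface_a, iface_b, corr)
        assert minimum == pytest.approx(30.0)
        assert label == "[30,50)"
        assert per["B"] == pytest.approx(100.0)

    def test_no_mapped_interface_errors(self):
        ca = _two_chain("AA", "GG")
        cb = _two_chain("AA", "GG")
        corr = _corr({_rid("A", 1): _rid("A", 1)})
        with pytest.raises(ValueError):
            min_interface_identity(ca, cb, set(), set(), corr)

    def test_identical_complexes_100(self, toy):
        _s, _t, analysis = toy
        report = compare_pair(analysis, analysis)
        assert report.min_interface_identity == pytest.approx(100.0)
        assert report.identity_bin == "[70,100]"
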