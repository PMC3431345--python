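"""Typed inter-chain contact detection.

Atomic contacts are heavy-atom pairs across the interface within a
distance cutoff (default 5.0 Å), grouped into residue-residue edges
weighted by their atomic-contact count.  On top of these the module
types charged contacts (Arg/Lys/His side-chain N to Asp/Glu side-chain
O, default 5.5 Å), salt bridges (same pairs at 3.5 Å), hydrogen bonds
(donor-acceptor heavy atoms at 3.5 Å with an antecedent-donor-acceptor
angle of at least 90°, backbone-backbone pairs excluded) and apolar
contacts (side-chain C/S surface atoms of interface residues at 4.5 Å).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .structure import Atom, ComplexStructure, Residue, ResidueId, SasaResult

__all__ = [
    "ContactConfig",
    "AtomicContact",
    "ResidueContactEdge",
    "atomic_contacts",
    "residue_contact_graph",
    "charged_contacts",
    "salt_bridges",
    "hydrogen_bonds",
    "apolar_contacts",
    "intra_chain_charged_contacts",
]

# Side-chain charged atoms: positive N donors and negative O acceptors.
POSITIVE_N = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
NEGATIVE_O = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

# Hydrogen-bond donor/acceptor heavy atoms with antecedent for the angle test.
HB_DONORS: Dict[Tuple[str, str], str] = {}
HB_ACCEPTORS: Set[Tuple[str, str]] = set()
for _aa in "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE SER THR TRP TYR VAL".split():
    HB_DONORS[(_aa, "N")] = "CA"       # backbone amide (absent for PRO)
for _aa in "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split():
    HB_ACCEPTORS.add((_aa, "O"))       # backbone carbonyl
    HB_ACCEPTORS.add((_aa, "OXT"))
_SIDE_DONORS = {
    ("SER", "OG"): "CB", ("THR", "OG1"): "CB", ("TYR", "OH"): "CZ",
    ("ASN", "ND2"): "CG", ("GLN", "NE2"): "CD", ("LYS", "NZ"): "CE",
    ("ARG", "NE"): "CD", ("ARG", "NH1"): "CZ", ("ARG", "NH2"): "CZ",
    ("HIS", "ND1"): "CG", ("HIS", "NE2"): "CD2", ("TRP", "NE1"): "CD1",
    ("CYS", "SG"): "CB",
}
HB_DONORS.update(_SIDE_DONORS)
_SIDE_ACCEPTORS = [
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("ASN", "OD1"), ("GLN", "OE1"), ("SER", "OG"), ("THR", "OG1"),
    ("TYR", "OH"), ("HIS", "ND1"), ("HIS", "NE2"), ("MET", "SD"),
]
HB_ACCEPTORS.update(_SIDE_ACCEPTORS)


@dataclass
class ContactConfig:
    """Distance cutoffs (Å) for every contact type."""

    atomic_cutoff: float = 5.0
    charged_cutoff: float = 5.5      # 6.0 also supported by flag
    salt_bridge_cutoff: float = 3.5
    hbond_cutoff: float = 3.5
    hbond_min_angle: float = 90.0    # degrees, antecedent-donor-acceptor
    apolar_cutoff: float = 4.5
    patch_adjacency_cutoff: float = 5.5
    include_backbone_apolar: bool = False

    def __post_init__(self) -> None:
        if self.salt_bridge_cutoff > self.charged_cutoff:
            raise ValueError("salt-bridge cutoff must not exceed charged cutoff")
        for name in ("atomic_cutoff", "charged_cutoff", "salt_bridge_cutoff",
                     "hbond_cutoff", "apolar_cutoff", "patch_adjacency_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class AtomicContact:
    rid_a: ResidueId
    atom_a: str
    rid_b: ResidueId
    atom_b: str
    distance: float


@dataclass
class ResidueContactEdge:
    rid_a: ResidueId
    rid_b: ResidueId
    weight: int = 0                 # atomic contacts between the two residues
    charged: bool = False
    salt_bridge: bool = False
    hbond: bool = False
    apolar: bool = False
    apolar_atomic: int = 0

    @property
    def pair(self) -> Tuple[ResidueId, ResidueId]:
        return (self.rid_a, self.rid_b)


def _heavy_atom_table(chain_residues: Iterable[Residue]):
    rids, names, coords, atoms = [], [], [], []
    for res in chain_residues:
        if res.is_water:
            continue
        for a in res.heavy_atoms():
            rids.append(res.rid)
            names.append(a.name)
            coords.append(a.coords)
            atoms.append(a)
    return rids, names, (np.array(coords) if coords else np.empty((0, 3))), atoms


def atomic_contacts(
    structure: ComplexStructure,
    config: Optional[ContactConfig] = None,
) -> List[AtomicContact]:
    """All inter-chain heavy-atom pairs within the atomic cutoff."""
    cfg = config or ContactConfig()
    ra, na, ca, _ = _heavy_atom_table(structure.receptor.residues)
    rb, nb, cb, _ = _heavy_atom_table(structure.ligand.residues)
    out: List[AtomicContact] = []
    if len(ca) == 0 or len(cb) == 0:
        return out
    ta, tb = cKDTree(ca), cKDTree(cb)
    for i, js in enumerate(ta.query_ball_tree(tb, cfg.atomic_cutoff)):
        for j in js:
            d = float(np.linalg.norm(ca[i] - cb[j]))
            out.append(AtomicContact(ra[i], na[i], rb[j], nb[j], d))
    out.sort(key=lambda c: (c.rid_a, c.atom_a, c.rid_b, c.atom_b))
    return out


def residue_contact_graph(
    contacts: Iterable[AtomicContact],
) -> Dict[Tuple[ResidueId, ResidueId], ResidueContactEdge]:
    """Group atomic contacts into residue-pair edges weighted by count."""
    edges: Dict[Tuple[ResidueId, ResidueId], ResidueContactEdge] = {}
    for c in contacts:
        key = (c.rid_a, c.rid_b)
        edge = edges.get(key)
        if edge is None:
            edge = edges[key] = ResidueContactEdge(c.rid_a, c.rid_b)
        edge.weight += 1
    return edges


def _typed_pairs(
    structure: ComplexStructure,
    atoms_a: Dict[ResidueId, List[Atom]],
    atoms_b: Dict[ResidueId, List[Atom]],
    cutoff: float,
) -> Dict[Tuple[ResidueId, ResidueId], List[Tuple[str, str, float]]]:
    """Inter-chain atom pairs within cutoff among two pre-selected atom sets."""
    flat_a = [(rid, a) for rid, al in atoms_a.items() for a in al]
    flat_b = [(rid, a) for rid, al in atoms_b.items() for a in al]
    out: Dict[Tuple[ResidueId, ResidueId], List[Tuple[str, str, float]]] = {}
    if not flat_a or not flat_b:
        return out
    ca = np.array([a.coords for _, a in flat_a])
    cb = np.array([a.coords for _, a in flat_b])
    ta = cKDTree(ca)
    for i, js in enumerate(ta.query_ball_tree(cKDTree(cb), cutoff)):
        for j in js:
            rid_a, atom_a = flat_a[i]
            rid_b, atom_b = flat_b[j]
            d = float(np.linalg.norm(ca[i] - cb[j]))
            out.setdefault((rid_a, rid_b), []).append((atom_a.name, atom_b.name, d))
    return out


def _charged_atoms(residues: Iterable[Residue], table) -> Dict[ResidueId, List[Atom]]:
    out: Dict[ResidueId, List[Atom]] = {}
    for res in residues:
        names = table.get(res.aa_type)
        if not names:
            continue
        found = [a for a in res.heavy_atoms() if a.name in names]
        if found:
            out[res.rid] = found
    return out


def charged_contacts(
    structure: ComplexStructure,
    cutoff: float = 5.5,
) -> Dict[Tuple[ResidueId, ResidueId], List[Tuple[str, str, float]]]:
    """Inter-chain N(+)-O(−) pairs within ``cutoff``, grouped per residue pair.

    The positive side is a side-chain N of Arg/Lys/His, the negative side a
    side-chain O of Asp/Glu, in either chain orientation.  Keys are
    (receptor residue, ligand residue).
    """
    rec, lig = structure.receptor.residues, structure.ligand.residues
    pos_a, neg_a = _charged_atoms(rec, POSITIVE_N), _charged_atoms(rec, NEGATIVE_O)
    pos_b, neg_b = _charged_atoms(lig, POSITIVE_N), _charged_atoms(lig, NEGATIVE_O)
    out = _typed_pairs(structure, pos_a, neg_b, cutoff)
    for key, pairs in _typed_pairs(structure, neg_a, pos_b, cutoff).items():
        out.setdefault(key, []).extend(pairs)
    return out


def salt_bridges(
    structure: ComplexStructure,
    cutoff: float = 3.5,
) -> Dict[Tuple[ResidueId, ResidueId], List[Tuple[str, str, float]]]:
    """Charged contacts restricted to the salt-bridge distance (3.5 Å)."""
    return charged_contacts(structure, cutoff)


def intra_chain_charged_contacts(
    structure: ComplexStructure,
    chain_id: str,
    cutoff: float,
) -> Dict[Tuple[ResidueId, ResidueId], List[Tuple[str, str, float]]]:
    """N(+)-O(−) pairs within one chain (used for charge-fate scenarios)."""
    residues = structure.chain(chain_id).residues
    pos = _charged_atoms(residues, POSITIVE_N)
    neg = _charged_atoms(residues, NEGATIVE_O)
    out: Dict[Tuple[ResidueId, ResidueId], List[Tuple[str, str, float]]] = {}
    for rid_p, alist_p in pos.items():
        for rid_n, alist_n in neg.items():
            if rid_p == rid_n:
                continue
            for ap in alist_p:
                for an in alist_n:
                    d = float(np.linalg.norm(ap.coords - an.coords))
                    if d <= cutoff:
                        out.setdefault((rid_p, rid_n), []).append((ap.name, an.name, d))
    return out


def _hb_antecedent(res: Residue, donor: Atom) -> Optional[np.ndarray]:
    name = HB_DONORS.get((res.aa_type, donor.name))
    if name is not None:
        a = res.get_atom(name)
        if a is not None:
            return a.coords
    # fall back: nearest heavy atom of the same residue
    best, best_d = None, np.inf
    for a in res.heavy_atoms():
        if a.name == donor.name:
            continue
        d = float(np.linalg.norm(a.coords - donor.coords))
        if d < best_d:
            best, best_d = a.coords, d
    return best


def hydrogen_bonds(
    structure: ComplexStructure,
    cutoff: float = 3.5,
    min_angle: float = 90.0,
) -> Dict[Tuple[ResidueId, ResidueId], List[Tuple[str, str, float]]]:
    """Inter-chain donor-acceptor pairs: D-A <= cutoff, antecedent angle >= min_angle.

    Pairs where both atoms are backbone N/O are excluded.  Hydrogen
    positions are not used (structures frequently lack them).  Keys are
    (receptor residue, ligand residue); atom names are (donor, acceptor)
    with the donor possibly on either chain.
    """
    out: Dict[Tuple[ResidueId, ResidueId], List[Tuple[str, str, float]]] = {}

    def side(donor_res: Iterable[Residue], accept_res: Iterable[Residue], donor_is_receptor: bool):
        donors: List[Tuple[Residue, Atom]] = []
        for res in donor_res:
            if res.is_water:
                continue
            for a in res.heavy_atoms():
                if (res.aa_type, a.name) in HB_DONORS:
                    donors.append((res, a))
        acceptors: List[Tuple[Residue, Atom]] = []
        for res in accept_res:
            if res.is_water:
                continue
            for a in res.heavy_atoms():
                if (res.aa_type, a.name) in HB_ACCEPTORS:
                    acceptors.append((res, a))
        if not donors or not acceptors:
            return
        dc = np.array([a.coords for _, a in donors])
        ac = np.array([a.coords for _, a in acceptors])
        tree = cKDTree(ac)
        for i, js in enumerate(cKDTree(dc).query_ball_tree(tree, cutoff)):
            res_d, atom_d = donors[i]
            ante = _hb_antecedent(res_d, atom_d)
            for j in js:
                res_a, atom_a = acceptors[j]
                if atom_d.is_backbone and atom_a.is_backbone:
                    continue
                d = float(np.linalg.norm(atom_d.coords - atom_a.coords))
                if d < 1e-6:
                    continue
                if ante is not None:
                    v1 = ante - atom_d.coords
                    v2 = atom_a.coords - atom_d.coords
                    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
                    angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                    if angle < min_angle:
                        continue
                key = (
                    (res_d.rid, res_a.rid) if donor_is_receptor else (res_a.rid, res_d.rid)
                )
                out.setdefault(key, []).append((atom_d.name, atom_a.name, d))

    side(structure.receptor.residues, structure.ligand.residues, True)
    side(structure.ligand.residues, structure.receptor.residues, False)
    return out


def apolar_atom_table(
    structure: ComplexStructure,
    interface: Dict[str, Set[ResidueId]],
    monomer_sasa: SasaResult,
    include_backbone: bool = False,
    min_sasa: float = 1e-3,
) -> Dict[str, List[Tuple[ResidueId, Atom]]]:
    """Per-chain C/S surface atoms of interface residues.

    "Surface" means positive SASA in the isolated chain.  By default only
    side-chain C/S atoms are considered (see ContactConfig).
    """
    out: Dict[str, List[Tuple[ResidueId, Atom]]] = {}
    for chain in structure.chains:
        sel: List[Tuple[ResidueId, Atom]] = []
        iface = interface.get(chain.chain_id, set())
        for res in chain.residues:
            if res.rid not in iface:
                continue
            for a in res.heavy_atoms():
                if not a.is_apolar:
                    continue
                if a.is_backbone and not include_backbone:
                    continue
                if monomer_sasa.atom_sasa.get((res.rid, a.name), 0.0) > min_sasa:
                    sel.append((res.rid, a))
        out[chain.chain_id] = sel
    return out


def apolar_contacts(
    structure: ComplexStructure,
    interface: Dict[str, Set[ResidueId]],
    monomer_sasa: SasaResult,
    config: Optional[ContactConfig] = None,
) -> Dict[Tuple[ResidueId, ResidueId], List[Tuple[str, str, float]]]:
    """Inter-chain C/S-C/S pairs among surface interface atoms.

    Any residue type may contribute apolar atoms; the constraint is on
    the atoms (carbon/sulfur, surface-exposed, interface residue).
    """
    cfg = config or ContactConfig()
    table = apolar_atom_table(
        structure, interface, monomer_sasa, include_backbone=cfg.include_backbone_apolar
    )
    a_atoms: Dict[ResidueId, List[Atom]] = {}
    for rid, a in table[structure.receptor.chain_id]:
        a_atoms.setdefault(rid, []).append(a)
    b_atoms: Dict[ResidueId, List[Atom]] = {}
    for rid, a in table[structure.ligand.chain_id]:
        b_atoms.setdefault(rid, []).append(a)
    return _typed_pairs(structure, a_atoms, b_atoms, cfg.apolar_cutoff)
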