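"""Interface detection, core/support/rim classification and anchor residues.

Interface residues are those that gain at least one structural neighbour
upon complexation or make at least one inter-chain atomic contact.  Two
residues are structural neighbours when their CB atoms (CA for glycine)
lie within 8 Å; the extended-neighbour relation uses 10 Å and feeds a
burial index that is 0 at <=15 neighbours, 1 at >=24 and linear in
between.  A residue whose burial index rises by more than 0.5 on binding
is "core"; otherwise, if the mean of its monomer and complex indices
exceeds 0.6 it is "support"; everything else is "rim".  Anchors are up
to three core/support residues burying the most surface (>80 Å²).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .structure import Chain, ComplexStructure, Residue, ResidueId

__all__ = [
    "NEIGHBOR_RADIUS",
    "EXTENDED_RADIUS",
    "ANCHOR_DELTA_RASA",
    "MAX_ANCHORS",
    "ResidueBurial",
    "InterfaceModel",
    "structural_neighbors",
    "interface_residues",
    "burial_index",
    "classify_subregions",
    "interface_center_distances",
    "anchor_residues",
]

NEIGHBOR_RADIUS = 8.0
EXTENDED_RADIUS = 10.0
ANCHOR_DELTA_RASA = 80.0
MAX_ANCHORS = 3


@dataclass
class ResidueBurial:
    n_neighbors_monomer: int
    n_neighbors_complex: int

    @property
    def bi_monomer(self) -> float:
        return burial_index(self.n_neighbors_monomer)

    @property
    def bi_complex(self) -> float:
        return burial_index(self.n_neighbors_complex)


@dataclass
class InterfaceModel:
    """Per-complex interface description.

    ``regions`` maps every interface residue to ``core``/``support``/``rim``;
    ``center_distance`` holds distances to the interface geometric centre
    normalised to a maximum of 1; ``anchors`` holds at most three ids.
    """

    interface: Dict[str, Set[ResidueId]]            # per chain id
    regions: Dict[ResidueId, str]
    burials: Dict[ResidueId, ResidueBurial]
    delta_rasa: Dict[ResidueId, float]
    anchors: List[ResidueId]
    center: Optional[np.ndarray]
    center_distance: Dict[ResidueId, float]
    n_contacts: Dict[ResidueId, int] = field(default_factory=dict)

    def all_interface(self) -> Set[ResidueId]:
        out: Set[ResidueId] = set()
        for s in self.interface.values():
            out |= s
        return out

    def region(self, rid: ResidueId) -> Optional[str]:
        return self.regions.get(rid)


def _reference_points(residues: Iterable[Residue]) -> Tuple[List[ResidueId], np.ndarray]:
    ids: List[ResidueId] = []
    pts: List[np.ndarray] = []
    for res in residues:
        if res.is_water:
            continue
        p = res.reference_point()
        if p is None:
            warnings.warn(f"residue {res.rid} lacks CB and CA; excluded from neighbours")
            continue
        ids.append(res.rid)
        pts.append(p)
    return ids, (np.array(pts) if pts else np.empty((0, 3)))


def structural_neighbors(
    structure: ComplexStructure,
    radius: float = NEIGHBOR_RADIUS,
    context: str = "complex",
) -> Dict[ResidueId, Set[ResidueId]]:
    """Symmetric neighbour sets at ``radius`` over CB (CA for glycine) points.

    ``context='monomer'`` restricts pairs to the same chain;
    ``'complex'`` considers all residues of both chains.
    """
    if context not in ("monomer", "complex"):
        raise ValueError(f"unknown context {context!r}")
    groups = (
        [structure.residues()]
        if context == "complex"
        else [list(c.residues) for c in structure.chains]
    )
    out: Dict[ResidueId, Set[ResidueId]] = {}
    for residues in groups:
        ids, pts = _reference_points(residues)
        for rid in ids:
            out.setdefault(rid, set())
        if len(ids) < 2:
            continue
        tree = cKDTree(pts)
        for i, j in tree.query_pairs(radius):
            out[ids[i]].add(ids[j])
            out[ids[j]].add(ids[i])
    return out


def interface_residues(
    structure: ComplexStructure,
    contact_pairs: Iterable[Tuple[ResidueId, ResidueId]],
    neighbor_radius: float = NEIGHBOR_RADIUS,
) -> Dict[str, Set[ResidueId]]:
    """Interface residues per chain: gained a structural neighbour on
    complexation, or involved in an inter-chain residue contact."""
    mono = structural_neighbors(structure, neighbor_radius, "monomer")
    comp = structural_neighbors(structure, neighbor_radius, "complex")
    iface: Dict[str, Set[ResidueId]] = {c.chain_id: set() for c in structure.chains}
    for rid, neigh in comp.items():
        if neigh - mono.get(rid, set()):
            iface[rid.chain_id].add(rid)
    for a, b in contact_pairs:
        if a.chain_id in iface:
            iface[a.chain_id].add(a)
        if b.chain_id in iface:
            iface[b.chain_id].add(b)
    return iface


def burial_index(n_extended_neighbors: int) -> float:
    """Piecewise-linear burial index of an extended (10 Å) neighbour count."""
    n = int(n_extended_neighbors)
    if n < 0:
        raise ValueError("neighbour count must be non-negative")
    if n <= 15:
        return 0.0
    if n >= 24:
        return 1.0
    return (n - 15) / 9.0


def compute_burials(structure: ComplexStructure) -> Dict[ResidueId, ResidueBurial]:
    """Extended-neighbour counts in isolated chain and in complex."""
    mono = structural_neighbors(structure, EXTENDED_RADIUS, "monomer")
    comp = structural_neighbors(structure, EXTENDED_RADIUS, "complex")
    return {
        rid: ResidueBurial(
            n_neighbors_monomer=len(mono.get(rid, set())),
            n_neighbors_complex=len(comp.get(rid, set())),
        )
        for rid in comp
    }


def classify_subregions(
    burials: Dict[ResidueId, ResidueBurial],
    interface: Iterable[ResidueId],
) -> Dict[ResidueId, str]:
    """core if burial-index gain > 0.5; else support if mean index > 0.6; else rim."""
    regions: Dict[ResidueId, str] = {}
    for rid in interface:
        b = burials[rid]
        gain = b.bi_complex - b.bi_monomer
        if gain > 0.5:
            regions[rid] = "core"
        elif (b.bi_monomer + b.bi_complex) / 2.0 > 0.6:
            regions[rid] = "support"
        else:
            regions[rid] = "rim"
    return regions


def interface_center_distances(
    interface: Iterable[ResidueId],
    structure: ComplexStructure,
) -> Tuple[Optional[np.ndarray], Dict[ResidueId, float]]:
    """Distance of each interface residue to the interface geometric centre,
    normalised so the maximum over the interface is exactly 1.

    The centre is the centroid of the CB/CA reference points of all
    interface residues (both chains pooled).
    """
    rids = list(interface)
    pts = []
    kept = []
    for rid in rids:
        p = structure.residue(rid).reference_point()
        if p is not None:
            kept.append(rid)
            pts.append(p)
    if not kept:
        return None, {}
    pts_arr = np.array(pts)
    center = pts_arr.mean(axis=0)
    dists = np.linalg.norm(pts_arr - center, axis=1)
    dmax = dists.max()
    if dmax <= 1e-9:
        if len(kept) == 1:
            warnings.warn("single-residue interface: centre distances set to 0")
        return center, {rid: 0.0 for rid in kept}
    return center, {rid: float(d / dmax) for rid, d in zip(kept, dists)}


def anchor_residues(
    regions: Dict[ResidueId, str],
    delta_rasa_map: Dict[ResidueId, float],
    max_anchors: int = MAX_ANCHORS,
    min_delta: float = ANCHOR_DELTA_RASA,
    per_chain: bool = False,
) -> List[ResidueId]:
    """Up to three core/support residues burying the most area (>80 Å²).

    Candidates are pooled across both chains by default
    (``per_chain=True`` selects up to ``max_anchors`` per chain instead).
    Ties broken deterministically by (chain id, residue number, icode).
    """
    candidates = [
        rid
        for rid, region in regions.items()
        if region in ("core", "support") and delta_rasa_map.get(rid, 0.0) > min_delta
    ]
    candidates.sort(key=lambda r: (-delta_rasa_map[r], r.chain_id, r.number, r.icode))
    if not per_chain:
        return candidates[:max_anchors]
    out: List[ResidueId] = []
    per: Dict[str, int] = {}
    for rid in candidates:
        if per.get(rid.chain_id, 0) < max_anchors:
            out.append(rid)
            per[rid.chain_id] = per.get(rid.chain_id, 0) + 1
    return out


def build_interface_model(
    structure: ComplexStructure,
    contact_pairs: Iterable[Tuple[ResidueId, ResidueId]],
    delta_rasa_map: Dict[ResidueId, float],
    contact_counts: Optional[Dict[ResidueId, int]] = None,
    anchors_per_chain: bool = False,
) -> InterfaceModel:
    """Assemble the full per-complex interface description."""
    contact_pairs = list(contact_pairs)
    iface = interface_residues(structure, contact_pairs)
    burials = compute_burials(structure)
    all_iface = set().union(*iface.values()) if iface else set()
    regions = classify_subregions(burials, all_iface)
    center, dists = interface_center_distances(all_iface, structure)
    anchors = anchor_residues(regions, delta_rasa_map, per_chain=anchors_per_chain)
    return InterfaceModel(
        interface=iface,
        regions=regions,
        burials={rid: burials[rid] for rid in all_iface if rid in burials},
        delta_rasa={rid: delta_rasa_map.get(rid, 0.0) for rid in all_iface},
        anchors=anchors,
        center=center,
        center_distance=dists,
        n_contacts=dict(contact_counts or {}),
    )
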