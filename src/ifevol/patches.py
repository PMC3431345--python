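"""Apolar patch detection, cross-interolog merging, bundles and random nulls.

An apolar patch is a contiguous cluster of surface interface carbon and
sulfur atoms on one side of the interface: connected components of the
atom graph whose edges join atoms within an adjacency cutoff (default
5.5 Å), keeping components with at least four atoms from at least two
residues.  Two patches facing each other across the interface form a
"bundle" when at least one apolar contact joins them; bundles are the
unit at which apolar-contact conservation is strikingly higher than at
the residue level.  Random patches with matched size and sub-region
composition serve as the null model for that comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .contacts import ContactConfig, apolar_atom_table
from .structure import Atom, ComplexStructure, ResidueId, SasaResult

__all__ = [
    "ApolarPatch",
    "PatchBundle",
    "detect_patches",
    "merge_patches_across_interologs",
    "patch_contact_bundles",
    "random_patches",
]

MIN_PATCH_ATOMS = 4
MIN_PATCH_RESIDUES = 2


@dataclass
class ApolarPatch:
    side: str                                  # chain id
    atoms: List[Tuple[ResidueId, str]]         # (residue, atom name)
    provenance: List[int] = field(default_factory=list)  # indices of merged patches

    @property
    def residues(self) -> FrozenSet[ResidueId]:
        return frozenset(rid for rid, _ in self.atoms)

    @property
    def size(self) -> int:
        return len(self.atoms)

    def region_composition(self, regions: Mapping[ResidueId, str]) -> Dict[str, int]:
        comp = {"core": 0, "support": 0, "rim": 0}
        for rid in self.residues:
            r = regions.get(rid)
            if r in comp:
                comp[r] += 1
        return comp


@dataclass
class PatchBundle:
    patch_a: int                               # index into receptor-side patches
    patch_b: int                               # index into ligand-side patches
    n_apolar_contacts: int
    participation_a: float = 0.0               # fraction of patch residues contacting
    participation_b: float = 0.0


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def detect_patches(
    structure: ComplexStructure,
    interface: Dict[str, Set[ResidueId]],
    monomer_sasa: SasaResult,
    config: Optional[ContactConfig] = None,
) -> Dict[str, List[ApolarPatch]]:
    """Connected components of the per-chain C/S surface-atom graph.

    Components failing the >=4-atoms / >=2-residues rule are discarded.
    Patches are returned per chain id, sorted by decreasing size.
    """
    cfg = config or ContactConfig()
    table = apolar_atom_table(
        structure, interface, monomer_sasa, include_backbone=cfg.include_backbone_apolar
    )
    out: Dict[str, List[ApolarPatch]] = {}
    for chain in structure.chains:
        entries = table[chain.chain_id]
        patches: List[ApolarPatch] = []
        if entries:
            coords = np.array([a.coords for _, a in entries])
            uf = _UnionFind(len(entries))
            from scipy.spatial import cKDTree

            tree = cKDTree(coords)
            for i, j in tree.query_pairs(cfg.patch_adjacency_cutoff):
                uf.union(i, j)
            comps: Dict[int, List[int]] = {}
            for i in range(len(entries)):
                comps.setdefault(uf.find(i), []).append(i)
            for members in comps.values():
                atoms = [(entries[i][0], entries[i][1].name) for i in members]
                rids = {rid for rid, _ in atoms}
                if len(atoms) >= MIN_PATCH_ATOMS and len(rids) >= MIN_PATCH_RESIDUES:
                    atoms.sort()
                    patches.append(ApolarPatch(side=chain.chain_id, atoms=atoms))
        patches.sort(key=lambda p: (-p.size, p.atoms))
        out[chain.chain_id] = patches
    return out


def _merge(patches: List[ApolarPatch], idxs: List[int]) -> List[ApolarPatch]:
    """Merge the patches at ``idxs`` into one (union of members)."""
    idxs = sorted(set(idxs))
    merged_atoms: List[Tuple[ResidueId, str]] = []
    prov: List[int] = []
    for i in idxs:
        merged_atoms.extend(patches[i].atoms)
        prov.extend(patches[i].provenance or [i])
    merged = ApolarPatch(
        side=patches[idxs[0]].side,
        atoms=sorted(set(merged_atoms)),
        provenance=sorted(set(prov)),
    )
    keep = [p for k, p in enumerate(patches) if k not in idxs]
    keep.append(merged)
    keep.sort(key=lambda p: (-p.size, p.atoms))
    return keep


def merge_patches_across_interologs(
    patches_a: List[ApolarPatch],
    patches_b: List[ApolarPatch],
    correspondence: Mapping[ResidueId, ResidueId],
) -> Tuple[List[ApolarPatch], List[ApolarPatch], Dict[int, int]]:
    """Iteratively merge patches so each maps to at most one in the interolog.

    ``correspondence`` maps residues of complex A to residues of complex B
    (for the relevant chain).  Two patches overlap when they share at
    least one aligned residue.  While any patch overlaps two or more
    patches on the other side, those targets are merged; at the fixpoint
    the mapping is injective in both directions and returned as
    ``{index in merged A -> index in merged B}``.
    """
    pa, pb = list(patches_a), list(patches_b)
    for p in pa:
        if not p.provenance:
            p.provenance = []
    for _ in range(100):
        overlap_ab: Dict[int, List[int]] = {}
        overlap_ba: Dict[int, List[int]] = {}
        for i, p in enumerate(pa):
            mapped = {correspondence[r] for r in p.residues if r in correspondence}
            for j, q in enumerate(pb):
                if mapped & q.residues:
                    overlap_ab.setdefault(i, []).append(j)
                    overlap_ba.setdefault(j, []).append(i)
        multi_a = [js for js in overlap_ab.values() if len(js) > 1]
        multi_b = [is_ for is_ in overlap_ba.values() if len(is_) > 1]
        if multi_a:
            pb = _merge(pb, multi_a[0])
        elif multi_b:
            pa = _merge(pa, multi_b[0])
        else:
            mapping = {i: js[0] for i, js in overlap_ab.items()}
            return pa, pb, mapping
    raise RuntimeError("patch merging did not reach a fixpoint")


def patch_contact_bundles(
    patches: Dict[str, List[ApolarPatch]],
    apolar: Mapping[Tuple[ResidueId, ResidueId], Sequence[Tuple[str, str, float]]],
    receptor_chain: str,
    ligand_chain: str,
) -> List[PatchBundle]:
    """One bundle per patch pair joined by at least one apolar contact.

    Participation fraction = patch residues with >=1 apolar contact into
    the partner patch, over patch residues.
    """
    pa = patches.get(receptor_chain, [])
    pb = patches.get(ligand_chain, [])
    atom_to_patch_a: Dict[Tuple[ResidueId, str], int] = {}
    for i, p in enumerate(pa):
        for key in p.atoms:
            atom_to_patch_a[key] = i
    atom_to_patch_b: Dict[Tuple[ResidueId, str], int] = {}
    for j, p in enumerate(pb):
        for key in p.atoms:
            atom_to_patch_b[key] = j

    counts: Dict[Tuple[int, int], int] = {}
    contacting: Dict[Tuple[int, int], Tuple[Set[ResidueId], Set[ResidueId]]] = {}
    for (rid_a, rid_b), pairs in apolar.items():
        for (name_a, name_b, _d) in pairs:
            i = atom_to_patch_a.get((rid_a, name_a))
            j = atom_to_patch_b.get((rid_b, name_b))
            if i is None or j is None:
                continue
            counts[(i, j)] = counts.get((i, j), 0) + 1
            sa, sb = contacting.setdefault((i, j), (set(), set()))
            sa.add(rid_a)
            sb.add(rid_b)

    bundles: List[PatchBundle] = []
    for (i, j), n in sorted(counts.items()):
        sa, sb = contacting[(i, j)]
        bundles.append(
            PatchBundle(
                patch_a=i,
                patch_b=j,
                n_apolar_contacts=n,
                participation_a=len(sa) / len(pa[i].residues),
                participation_b=len(sb) / len(pb[j].residues),
            )
        )
    return bundles


def _residue_adjacency(
    entries: Sequence[Tuple[ResidueId, Atom]], cutoff: float
) -> Dict[ResidueId, Set[ResidueId]]:
    """Residue-level adjacency induced by the patch atom graph."""
    from scipy.spatial import cKDTree

    adj: Dict[ResidueId, Set[ResidueId]] = {}
    if not entries:
        return adj
    coords = np.array([a.coords for _, a in entries])
    tree = cKDTree(coords)
    for rid, _ in entries:
        adj.setdefault(rid, set())
    for i, j in tree.query_pairs(cutoff):
        ri, rj = entries[i][0], entries[j][0]
        if ri != rj:
            adj[ri].add(rj)
            adj[rj].add(ri)
    return adj


def random_patches(
    structure: ComplexStructure,
    interface: Dict[str, Set[ResidueId]],
    monomer_sasa: SasaResult,
    reference_patches: Dict[str, List[ApolarPatch]],
    regions: Mapping[ResidueId, str],
    seed: int,
    config: Optional[ContactConfig] = None,
    match_composition: bool = True,
    facing: bool = True,
    max_tries: int = 1000,
) -> Dict[str, List[ApolarPatch]]:
    """Grow random connected patches matching the real patches' sizes.

    For each real patch, a connected patch of the same atom count is
    grown from a random seed residue over the residue adjacency graph of
    surface interface C/S atoms.  With ``match_composition`` the growth is
    rejection-sampled toward matching the real patch's core/support/rim
    residue composition within ±1 per class; with ``facing`` the seed
    residue is required to carry an atom within apolar-contact reach of
    the partner side.  Reproducible given ``seed``.
    """
    cfg = config or ContactConfig()
    rng = np.random.default_rng(seed)
    table = apolar_atom_table(
        structure, interface, monomer_sasa, include_backbone=cfg.include_backbone_apolar
    )
    other = {structure.receptor.chain_id: structure.ligand.chain_id,
             structure.ligand.chain_id: structure.receptor.chain_id}

    # residues facing the partner side: any patch atom within apolar reach
    facing_ok: Dict[str, Set[ResidueId]] = {}
    for cid in other:
        ours = table[cid]
        theirs = table[other[cid]]
        ok: Set[ResidueId] = set()
        if ours and theirs:
            from scipy.spatial import cKDTree

            tree = cKDTree(np.array([a.coords for _, a in theirs]))
            hits = tree.query_ball_point(
                np.array([a.coords for _, a in ours]), cfg.apolar_cutoff
            )
            for (rid, _a), h in zip(ours, hits):
                if h:
                    ok.add(rid)
        facing_ok[cid] = ok

    out: Dict[str, List[ApolarPatch]] = {}
    for cid, refs in reference_patches.items():
        entries = table[cid]
        atoms_of: Dict[ResidueId, List[Tuple[ResidueId, str]]] = {}
        for rid, a in entries:
            atoms_of.setdefault(rid, []).append((rid, a.name))
        adj = _residue_adjacency(entries, cfg.patch_adjacency_cutoff)
        all_rids = sorted(adj)
        rand: List[ApolarPatch] = []
        for ref in refs:
            target_size = ref.size
            target_comp = ref.region_composition(regions)
            best: Optional[List[Tuple[ResidueId, str]]] = None
            best_score = np.inf
            seeds = sorted(facing_ok[cid] & set(all_rids)) if facing else all_rids
            if not seeds:
                seeds = all_rids
            if not seeds:
                warnings.warn(f"no candidate residues to grow a random patch on chain {cid}")
                continue
            for _try in range(max_tries):
                start = seeds[int(rng.integers(len(seeds)))]
                member_set = {start}
                atoms: List[Tuple[ResidueId, str]] = list(atoms_of[start])
                frontier = sorted(adj[start] - member_set)
                while len(atoms) < target_size and frontier:
                    nxt = frontier[int(rng.integers(len(frontier)))]
                    member_set.add(nxt)
                    grown = np.array(
                        [structure.residue(r).get_atom(n).coords for r, n in atoms]
                    )
                    # trim the final residue to hit the target atom count
                    # exactly, keeping the atoms closest to the grown patch
                    new_atoms = sorted(
                        atoms_of[nxt],
                        key=lambda key: float(
                            np.min(
                                np.linalg.norm(
                                    grown
                                    - structure.residue(key[0]).get_atom(key[1]).coords,
                                    axis=1,
                                )
                            )
                        ),
                    )
                    atoms.extend(new_atoms[: target_size - len(atoms)])
                    frontier = sorted((set(frontier) | adj[nxt]) - member_set)
                if len(atoms) < target_size:
                    continue  # could not reach target size from this seed
                comp = {"core": 0, "support": 0, "rim": 0}
                for rid in member_set:
                    r = regions.get(rid)
                    if r in comp:
                        comp[r] += 1
                score = sum(abs(comp[k] - target_comp[k]) for k in comp)
                if score < best_score:
                    best, best_score = atoms, score
                if not match_composition or all(
                    abs(comp[k] - target_comp[k]) <= 1 for k in comp
                ):
                    best = atoms
                    break
            if best is None:
                warnings.warn(
                    f"failed to grow a random patch of size {target_size} on chain {cid}; "
                    "emitting best effort"
                )
                continue
            rand.append(ApolarPatch(side=cid, atoms=sorted(best)))
        out[cid] = rand
    return out
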