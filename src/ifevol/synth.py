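"""Synthetic two-chain complexes and interolog pairs with planted features.

Structures are built on a jittered square lattice: each chain carries an
interface layer of residues whose pseudo side chains point across a
narrow gap at the partner chain, plus a backing layer that gives
interface residues a realistic monomer burial.  Into this scaffold the
generator plants, at known lattice cells, salt bridges (N-O at 3.0 Å),
hydrogen-bond pairs (donor-acceptor at 3.3 Å with valid antecedent
geometry), a contiguous apolar patch of leucines on each side, isolated
apolar contact pairs outside any patch, and one anchor residue whose
protruding aromatic stalk buries well over 80 Å² on binding.  Every
planted feature is recorded in a ground-truth ledger so detectors can be
validated by closure.

A derived "interolog" applies controlled evolutionary events to a copy:
BLOSUM-weighted residue substitutions (identity relabels; side-chain
geometry is not rebuilt), displacement of residues out of the interface
(switching out), and bounded lateral side-chain tip displacement that
severs (occasionally reforms) contacts without leaving the interface
(rewiring).  The exact residue correspondence is returned as ground
truth, bypassing alignment.

Feature/label tables for the logistic predictors are simulated directly
from a coefficient preset with fixed feature distributions.

Geometry of the default scaffold (Å): lattice spacing 5.2, interface
gap 7.8 between facing CA planes, backing layer 4.6 below, protruding
backbone-O tips 4.6 apart across the gap (one atomic contact per facing
residue pair), leucine side-chain carbons 4.2 apart across the gap
(apolar contacts), lateral jitter ±0.15 per residue.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .predict import FEATURE_NAMES, LogisticModel, blosum62_score
from .structure import AA3_TO_1, Atom, Chain, ComplexStructure, Residue, ResidueId

ONE_TO_THREE = {one: three for three, one in AA3_TO_1.items() if one != "X"}

__all__ = [
    "ToySpec",
    "PerturbationSpec",
    "GroundTruth",
    "build_toy_complex",
    "derive_interolog",
    "simulate_logistic_dataset",
    "write_pdb",
    "write_alignment_fasta",
]

SPACING = 5.2
Z_GAP = 7.8
BACKING_DZ = 4.6
SWITCH_SHIFT = np.array([2.6, 0.0, -3.0])   # chain A; z sign flipped for chain B
REWIRE_SHIFT = 2.5                          # lateral, Å

# Local residue templates: side chains along +z (mirrored for chain B).
# Tip atoms are those displaced by the rewiring perturbation.
_TEMPLATES: Dict[str, List[Tuple[str, str, Tuple[float, float, float]]]] = {
    "GLY": [
        ("N", "N", (-1.3, 0.0, 0.0)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (1.3, 0.0, 0.0)),
        ("O", "O", (1.3, 0.0, 1.6)),
    ],
    "SER": [
        ("N", "N", (-1.3, 0.0, 0.0)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (1.3, 0.0, 0.0)),
        ("O", "O", (1.3, 0.0, 1.6)),
        ("CB", "C", (0.0, 0.0, 1.5)),
        ("OG", "O", (0.0, 0.6, 2.25)),
    ],
    "LYS": [
        ("N", "N", (-1.3, 0.0, 0.0)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (1.3, 0.0, 0.0)),
        ("O", "O", (1.3, 0.0, 1.6)),
        ("CB", "C", (0.0, 0.0, 1.5)),
        ("NZ", "N", (0.0, 0.0, 2.4)),
    ],
    "GLU": [
        ("N", "N", (-1.3, 0.0, 0.0)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (1.3, 0.0, 0.0)),
        ("O", "O", (1.3, 0.0, 1.6)),
        ("CB", "C", (0.0, 0.0, 1.5)),
        ("OE1", "O", (0.0, 0.0, 2.4)),
    ],
    "LEU": [
        ("N", "N", (-1.3, 0.0, 0.0)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (1.3, 0.0, 0.0)),
        ("O", "O", (1.3, 0.0, 1.6)),
        ("CB", "C", (0.0, 0.0, 1.5)),
        ("CG", "C", (0.0, 0.6, 1.8)),
        ("CD1", "C", (-0.8, 0.0, 1.8)),
        ("CD2", "C", (0.8, 0.0, 1.8)),
    ],
    "PHE": [
        ("N", "N", (-1.3, 0.0, 0.0)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (1.3, 0.0, 0.0)),
        ("O", "O", (1.3, 0.0, 1.6)),
        ("CB", "C", (0.0, 0.0, 1.5)),
        ("CG", "C", (0.0, 0.0, 2.7)),
        ("CD1", "C", (-1.2, 0.0, 3.5)),
        ("CD2", "C", (1.2, 0.0, 3.5)),
        ("CE1", "C", (-1.2, 0.0, 4.9)),
        ("CE2", "C", (1.2, 0.0, 4.9)),
        ("CZ", "C", (0.0, 0.0, 5.5)),
    ],
}
_TIP_ATOMS = {
    "GLY": ("O",),
    "SER": ("OG",),
    "LYS": ("NZ",),
    "GLU": ("OE1",),
    "LEU": ("CG", "CD1", "CD2"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
}

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ToySpec:
    """Dimensions and planted-feature counts of a synthetic complex."""

    n_rows: int = 9
    n_cols: int = 9
    n_salt_bridges: int = 2
    n_hbonds: int = 2
    patch_shape: Tuple[int, int] = (2, 2)      # contiguous leucine block per side
    n_lone_apolar: int = 2                     # isolated Leu-Leu contact pairs
    with_anchor: bool = True
    spacing: float = SPACING
    jitter: float = 0.15
    seed: int = 0


@dataclass
class PerturbationSpec:
    """Evolutionary event rates applied when deriving an interolog."""

    mutation_rate: float = 0.0
    switch_rate: float = 0.0
    rewire_rate: float = 0.0
    spare_planted_patches: bool = True
    rim_bias: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mutation_rate", "switch_rate", "rewire_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GroundTruth:
    """Ledger of every planted feature, by residue id."""

    salt_bridges: List[Tuple[ResidueId, ResidueId]] = field(default_factory=list)
    hbonds: List[Tuple[ResidueId, ResidueId]] = field(default_factory=list)
    patch_residues: Dict[str, List[ResidueId]] = field(default_factory=dict)
    lone_apolar: List[Tuple[ResidueId, ResidueId]] = field(default_factory=list)
    anchor: Optional[ResidueId] = None
    pocket: List[ResidueId] = field(default_factory=list)   # partner-side leucines
    interface_cells: Dict[str, List[ResidueId]] = field(default_factory=dict)
    default_cells: Dict[str, List[ResidueId]] = field(default_factory=dict)
    grid_shape: Tuple[int, int] = (0, 0)
    cell_of: Dict[ResidueId, Tuple[str, int, int]] = field(default_factory=dict)
    rid_of_cell: Dict[Tuple[str, int, int], ResidueId] = field(default_factory=dict)
    # populated by derive_interolog:
    correspondence: Dict[ResidueId, ResidueId] = field(default_factory=dict)
    switched_out: List[ResidueId] = field(default_factory=list)
    rewired: List[ResidueId] = field(default_factory=list)
    mutated: Dict[ResidueId, str] = field(default_factory=dict)
    eligible_switch: List[ResidueId] = field(default_factory=list)

    def planted_residues(self) -> Set[ResidueId]:
        out: Set[ResidueId] = set()
        for a, b in self.salt_bridges + self.hbonds + self.lone_apolar:
            out.add(a)
            out.add(b)
        for rids in self.patch_residues.values():
            out.update(rids)
        if self.anchor:
            out.add(self.anchor)
        out.update(self.pocket)
        return out


def _make_residue(
    aa: str, chain_id: str, number: int, origin: np.ndarray, flip: bool
) -> Residue:
    atoms = []
    for name, element, (x, y, z) in _TEMPLATES[aa]:
        local = np.array([x, y, -z if flip else z])
        atoms.append(Atom(name=name, element=element, coords=origin + local))
    return Residue(chain_id=chain_id, number=number, icode="", aa_type=aa, atoms=atoms)


def _plan_cells(spec: ToySpec) -> Dict[str, List[Tuple[int, int]]]:
    """Deterministically assign planted features to interior lattice cells.

    A one-cell margin (Chebyshev distance 1) is kept between distinct
    planted groups so side-chain atoms of different features never fall
    within contact or patch-adjacency reach of each other.
    """
    interior = [
        (r, c)
        for r in range(1, spec.n_rows - 1)
        for c in range(1, spec.n_cols - 1)
    ]
    blocked: Set[Tuple[int, int]] = set()
    plan: Dict[str, List[Tuple[int, int]]] = {
        "patch": [], "anchor": [], "pocket": [], "salt_bridge": [], "hbond": [],
        "lone_apolar": [],
    }

    def block(cells: Sequence[Tuple[int, int]], margin: int = 1) -> None:
        for (r, c) in cells:
            for dr in range(-margin, margin + 1):
                for dc in range(-margin, margin + 1):
                    blocked.add((r + dr, c + dc))

    def take_block(shape: Tuple[int, int], margin: int = 1) -> List[Tuple[int, int]]:
        h, w = shape
        for (r, c) in interior:
            cells = [(r + i, c + j) for i in range(h) for j in range(w)]
            if all(x in interior and x not in blocked for x in cells):
                block(cells, margin)
                return cells
        raise ValueError(f"infeasible spec: no room for a {h}x{w} block")

    if spec.patch_shape[0] * spec.patch_shape[1] > 0:
        plan["patch"] = take_block(spec.patch_shape)
    if spec.with_anchor:
        # reserve a 3x3 zone: anchor at the centre, partner-side pocket
        # leucines on the four orthogonal neighbours
        zone = take_block((3, 3))
        r, c = zone[4]
        plan["anchor"] = [(r, c)]
        plan["pocket"] = [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
    for _ in range(spec.n_salt_bridges):
        plan["salt_bridge"].extend(take_block((1, 1)))
    for _ in range(spec.n_hbonds):
        plan["hbond"].extend(take_block((1, 1)))
    for _ in range(spec.n_lone_apolar):
        plan["lone_apolar"].extend(take_block((1, 1)))
    return plan


def build_toy_complex(spec: ToySpec) -> Tuple[ComplexStructure, GroundTruth]:
    """Build a two-chain lattice complex with planted interface features."""
    rng = np.random.default_rng(spec.seed)
    plan = _plan_cells(spec)

    # residue type per interface cell, per side
    type_a: Dict[Tuple[int, int], str] = {}
    type_b: Dict[Tuple[int, int], str] = {}
    for cell in plan["patch"]:
        type_a[cell] = type_b[cell] = "LEU"
    for cell in plan["lone_apolar"]:
        type_a[cell] = type_b[cell] = "LEU"
    for cell in plan["hbond"]:
        type_a[cell] = type_b[cell] = "SER"
    for cell in plan["salt_bridge"]:
        type_a[cell] = "LYS"
        type_b[cell] = "GLU"
    for cell in plan["anchor"]:
        type_a[cell] = "PHE"
        type_b[cell] = "GLY"
    for cell in plan["pocket"]:
        type_b[cell] = "LEU"
        type_a.setdefault(cell, "GLY")

    truth = GroundTruth(patch_residues={"A": [], "B": []},
                        interface_cells={"A": [], "B": []},
                        default_cells={"A": [], "B": []})
    chains: Dict[str, Chain] = {}
    cell_rid: Dict[Tuple[str, int, int], ResidueId] = {}
    for chain_id, flip, types in (("A", False, type_a), ("B", True, type_b)):
        residues: List[Residue] = []
        number = 0
        z0 = Z_GAP if flip else 0.0
        for r in range(spec.n_rows):
            for c in range(spec.n_cols):
                number += 1
                jx, jy = rng.uniform(-spec.jitter, spec.jitter, size=2)
                origin = np.array([c * spec.spacing + jx, r * spec.spacing + jy, z0])
                aa = types.get((r, c), "GLY")
                res = _make_residue(aa, chain_id, number, origin, flip)
                residues.append(res)
                rid = res.rid
                cell_rid[(chain_id, r, c)] = rid
                truth.cell_of[rid] = (chain_id, r, c)
                truth.rid_of_cell[(chain_id, r, c)] = rid
                truth.interface_cells[chain_id].append(rid)
                if (r, c) not in types:
                    truth.default_cells[chain_id].append(rid)
        # backing layer, away from the interface
        zb = Z_GAP + BACKING_DZ if flip else -BACKING_DZ
        for r in range(spec.n_rows):
            for c in range(spec.n_cols):
                number += 1
                jx, jy = rng.uniform(-spec.jitter, spec.jitter, size=2)
                origin = np.array([c * spec.spacing + jx, r * spec.spacing + jy, zb])
                res = _make_residue("GLY", chain_id, number, origin, not flip)
                residues.append(res)
        chains[chain_id] = Chain(chain_id=chain_id, residues=residues)

    for cell in plan["salt_bridge"]:
        truth.salt_bridges.append((cell_rid[("A", *cell)], cell_rid[("B", *cell)]))
    for cell in plan["hbond"]:
        truth.hbonds.append((cell_rid[("A", *cell)], cell_rid[("B", *cell)]))
    for cell in plan["lone_apolar"]:
        truth.lone_apolar.append((cell_rid[("A", *cell)], cell_rid[("B", *cell)]))
    for cell in plan["patch"]:
        truth.patch_residues["A"].append(cell_rid[("A", *cell)])
        truth.patch_residues["B"].append(cell_rid[("B", *cell)])
    if plan["anchor"]:
        truth.anchor = cell_rid[("A", *plan["anchor"][0])]
        truth.pocket = [cell_rid[("B", *cell)] for cell in plan["pocket"]]

    truth.grid_shape = (spec.n_rows, spec.n_cols)
    structure = ComplexStructure(
        receptor=chains["A"], ligand=chains["B"], source_id=f"toy-{spec.seed}"
    )
    return structure, truth


def derive_interolog(
    structure: ComplexStructure,
    truth: GroundTruth,
    perturbation: PerturbationSpec,
) -> Tuple[ComplexStructure, GroundTruth]:
    """Copy a toy complex and apply substitution/switch-out/rewiring events.

    Returns the perturbed complex and an updated ground-truth ledger
    carrying the exact residue correspondence (an identity map over
    residue ids, since the copy preserves numbering), the lists of
    switched/rewired/mutated residues and the eligible pool for each
    event class.  With all rates zero the derived complex is an exact
    copy: every conservation statistic is 1 and switching out is 0.
    """
    rng = np.random.default_rng(perturbation.seed)
    derived = copy.deepcopy(structure)
    new_truth = copy.deepcopy(truth)
    new_truth.correspondence = {
        res.rid: res.rid for chain in structure.chains for res in chain.residues
    }

    defaults = [rid for cid in ("A", "B") for rid in truth.default_cells.get(cid, [])]
    switch_pool = defaults
    if perturbation.rim_bias:
        # restrict switch-out eligibility to the lattice periphery, where
        # real interfaces concentrate their rim fluctuations
        n_rows, n_cols = truth.grid_shape
        switch_pool = [
            rid
            for rid in defaults
            if truth.cell_of[rid][1] in (0, n_rows - 1)
            or truth.cell_of[rid][2] in (0, n_cols - 1)
        ]
    new_truth.eligible_switch = list(switch_pool)

    # Switching out: rigid displacement away from the interface plane.
    # A default residue's only interface link is with its facing partner,
    # so the partner's backbone-O tip is redirected toward a lateral
    # neighbour of the switched residue (local rewiring accompanying the
    # switch-out); if no un-switched lateral neighbour exists the switch
    # is cancelled so the planted rate is never inflated by cascades.
    switch_mask = rng.random(len(switch_pool)) < perturbation.switch_rate
    proposed = [rid for rid, m in zip(switch_pool, switch_mask) if m]
    proposed_set = set(proposed)
    switched: List[ResidueId] = []
    compensated: Set[ResidueId] = set()
    for rid in proposed:
        chain, r, c = truth.cell_of[rid]
        other = "B" if chain == "A" else "A"
        partner = truth.rid_of_cell.get((other, r, c))
        direction = None
        if partner is not None and partner not in proposed_set:
            for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                target = truth.rid_of_cell.get((chain, r + dr, c + dc))
                if target is None or target in proposed_set:
                    continue
                # the target's own O tip must stay put: it moves if the
                # target's facing partner is itself switched out
                t_partner = truth.rid_of_cell.get((other, r + dr, c + dc))
                if t_partner is not None and t_partner in proposed_set:
                    continue
                direction = (dr, dc)
                break
            if direction is None:
                continue  # cancel: partner cannot be kept at the interface
        res = derived.residue(rid)
        shift = SWITCH_SHIFT * (np.array([1.0, 1.0, -1.0]) if chain == "B" else 1.0)
        for atom in res.atoms:
            atom.coords = atom.coords + shift
        switched.append(rid)
        if partner is not None and direction is not None:
            dr, dc = direction
            dz = 0.7 if partner.chain_id == "A" else -0.7
            tip = derived.residue(partner).get_atom("O")
            if tip is not None:
                tip.coords = tip.coords + np.array([2.5 * dc, 2.5 * dr, dz])
            compensated.add(partner)
    new_truth.switched_out = switched

    # rewiring: lateral displacement of side-chain tip atoms
    lone = [rid for pair in truth.lone_apolar for rid in pair]
    excluded = set(switched) | compensated
    rewirable = [rid for rid in defaults + lone if rid not in excluded]
    if not perturbation.spare_planted_patches:
        rewirable += [rid for cid in ("A", "B") for rid in truth.patch_residues.get(cid, [])]
    rewire_mask = rng.random(len(rewirable)) < perturbation.rewire_rate
    rewired = [rid for rid, m in zip(rewirable, rewire_mask) if m]
    for rid in rewired:
        res = derived.residue(rid)
        theta = rng.uniform(0.0, 2.0 * math.pi)
        shift = np.array([REWIRE_SHIFT * math.cos(theta), REWIRE_SHIFT * math.sin(theta), 0.0])
        for atom in res.atoms:
            if atom.name in _TIP_ATOMS.get(res.aa_type, ()):
                atom.coords = atom.coords + shift
    new_truth.rewired = rewired

    # substitutions: BLOSUM-weighted identity relabels of default cells
    mutable = [rid for rid in defaults if rid not in set(switched)]
    mut_mask = rng.random(len(mutable)) < perturbation.mutation_rate
    for rid, m in zip(mutable, mut_mask):
        if not m:
            continue
        res = derived.residue(rid)
        source = res.one_letter
        candidates = [aa for aa in AA20 if aa != source]
        weights = np.array(
            [math.exp(blosum62_score(source, aa) / 2.0) for aa in candidates]
        )
        target = candidates[int(rng.choice(len(candidates), p=weights / weights.sum()))]
        res.aa_type = ONE_TO_THREE[target]
        new_truth.mutated[rid] = res.aa_type
    return derived, new_truth


def simulate_logistic_dataset(
    n: int,
    model: LogisticModel,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate residue feature records and Bernoulli labels from a model.

    Feature distributions: sim_res from BLOSUM62 scores of uniformly
    random amino-acid pairs; sim_env ~ Normal(1.5, 1.5²); seq_id ~
    Uniform(10, 100); region ~ Categorical(core .25, support .25, rim
    .50); n_contacts ~ 1 + Poisson(8); dist_center ~ Uniform(0, 1).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    aa_idx = rng.integers(0, 20, size=(n, 2))
    scores = np.array(
        [[blosum62_score(a, b) for b in AA20] for a in AA20]
    )
    sim_res = scores[aa_idx[:, 0], aa_idx[:, 1]]
    sim_env = rng.normal(1.5, 1.5, size=n)
    seq_id = rng.uniform(10.0, 100.0, size=n)
    region_code = rng.choice(3, size=n, p=[0.25, 0.25, 0.50])
    support = (region_code == 1).astype(float)
    rim = (region_code == 2).astype(float)
    n_contacts = 1 + rng.poisson(8.0, size=n)
    dist_center = rng.uniform(0.0, 1.0, size=n)

    df = pd.DataFrame(
        {
            "sim_res": sim_res,
            "sim_env": sim_env,
            "seq_id": seq_id,
            "support": support,
            "rim": rim,
            "n_contacts": n_contacts.astype(float),
            "dist_center": dist_center,
        }
    )
    z = np.full(n, model.intercept)
    for name, beta in model.coefficients.items():
        z += beta * df[name].to_numpy()
    p = 1.0 / (1.0 + np.exp(-z))
    df["probability"] = p
    df["label"] = (rng.random(n) < p).astype(int)
    df["region"] = np.array(["core", "support", "rim"])[region_code]
    return df


def write_pdb(structure: ComplexStructure, path) -> None:
    """Write the complex as a standard PDB file (via gemmi)."""
    import gemmi

    st = gemmi.Structure()
    st.name = structure.source_id or "toy"
    model = gemmi.Model("1")
    for chain in structure.chains:
        gch = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.aa_type
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                gres.add_atom(ga)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_alignment_fasta(
    complex_a: ComplexStructure,
    complex_b: ComplexStructure,
    correspondence: Dict[ResidueId, ResidueId],
    chain_a: str,
    chain_b: str,
    path,
) -> None:
    """Write the true chain correspondence as a two-row aligned FASTA."""
    res_a = [r for r in complex_a.chain(chain_a).residues if not r.is_water]
    res_b = [r for r in complex_b.chain(chain_b).residues if not r.is_water]
    index_b = {r.rid: i for i, r in enumerate(res_b)}
    row_a: List[str] = []
    row_b: List[str] = []
    j = 0
    for r in res_a:
        target = correspondence.get(r.rid)
        if target is None or target not in index_b:
            row_a.append(r.one_letter)
            row_b.append("-")
            continue
        tj = index_b[target]
        while j < tj:
            row_a.append("-")
            row_b.append(res_b[j].one_letter)
            j += 1
        row_a.append(r.one_letter)
        row_b.append(res_b[tj].one_letter)
        j = tj + 1
    while j < len(res_b):
        row_a.append("-")
        row_b.append(res_b[j].one_letter)
        j += 1
    with open(path, "w") as fh:
        fh.write(f">{complex_a.source_id}_{chain_a}\n{''.join(row_a)}\n")
        fh.write(f">{complex_b.source_id}_{chain_b}\n{''.join(row_b)}\n")
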