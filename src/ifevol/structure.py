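"""Typed structure model, coordinate parsing and solvent accessibility.

Coordinate files (PDB or mmCIF) are parsed with gemmi into a small typed
model holding exactly the two chains of a heteromeric complex.  Solvent
accessible surface areas (SASA) are computed with a Shrake-Rupley style
numerical method using a deterministic Fibonacci-spiral point set, so the
result is seed-free and reproducible.  Buried area upon binding (delta
rASA) is the per-residue difference between the SASA of the isolated
chain and the SASA in the complex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, NamedTuple, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "ComplexStructure",
    "ResidueId",
    "SasaResult",
    "read_structure",
    "compute_sasa",
    "delta_rasa",
    "VDW_RADII",
    "StructureError",
    "UnknownChainError",
    "UnknownElementError",
]

# Fixed published element radii (Å); the reference tools use slightly
# different per-atom-type radii, small systematic differences accepted.
VDW_RADII: Dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

# Common nonstandard residues mapped to their parent amino acid.
NONSTANDARD_PARENT = {
    "MSE": "MET",
    "SEC": "CYS",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "MLY": "LYS",
    "HYP": "PRO",
    "CSO": "CYS",
}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "UNK": "X",
}


class StructureError(ValueError):
    """Problem with an input structure."""


class UnknownChainError(StructureError):
    """Requested chain id not present in the file."""


class UnknownElementError(StructureError):
    """Atom with an element that has no tabulated van der Waals radius."""


class ResidueId(NamedTuple):
    """Stable residue identifier: chain, author residue number, insertion code."""

    chain_id: str
    number: int
    icode: str = ""

    def __str__(self) -> str:  # chain:number:icode
        return f"{self.chain_id}:{self.number}:{self.icode}"


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"non-finite coordinates for atom {self.name}")

    @property
    def vdw_radius(self) -> float:
        try:
            return VDW_RADII[self.element.upper()]
        except KeyError:
            raise UnknownElementError(
                f"no van der Waals radius for element {self.element!r} (atom {self.name})"
            ) from None

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS

    @property
    def is_polar(self) -> bool:
        return self.element.upper() in ("N", "O")

    @property
    def is_apolar(self) -> bool:
        return self.element.upper() in ("C", "S")


@dataclass
class Residue:
    chain_id: str
    number: int
    icode: str
    aa_type: str
    atoms: List[Atom] = field(default_factory=list)
    is_water: bool = False

    @property
    def rid(self) -> ResidueId:
        return ResidueId(self.chain_id, self.number, self.icode)

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.aa_type, "X")

    def heavy_atoms(self) -> List[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def get_atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def reference_point(self) -> Optional[np.ndarray]:
        """CB coordinates, or CA for glycine / residues lacking CB."""
        atom = self.get_atom("CB")
        if atom is None:
            atom = self.get_atom("CA")
        return None if atom is None else atom.coords


@dataclass
class Chain:
    chain_id: str
    residues: List[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def residue_by_id(self, rid: ResidueId) -> Optional[Residue]:
        for r in self.residues:
            if r.rid == rid:
                return r
        return None


@dataclass
class ComplexStructure:
    """A two-chain complex (receptor, ligand) selected from a coordinate file."""

    receptor: Chain
    ligand: Chain
    source_id: str = ""
    resolution: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.receptor.residues or not self.ligand.residues:
            raise StructureError("both chains must be non-empty")
        if self.receptor.chain_id == self.ligand.chain_id:
            raise StructureError("chain ids must be distinct")

    @property
    def chains(self) -> Tuple[Chain, Chain]:
        return (self.receptor, self.ligand)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise UnknownChainError(f"chain {chain_id!r} not in complex")

    def residues(self) -> List[Residue]:
        return list(self.receptor.residues) + list(self.ligand.residues)

    def residue(self, rid: ResidueId) -> Residue:
        res = self.chain(rid.chain_id).residue_by_id(rid)
        if res is None:
            raise StructureError(f"residue {rid} not found")
        return res


def _resolve_altlocs(raw_atoms: List[Tuple[str, str, str, float, np.ndarray, bool]]):
    """Keep one position per atom name: the one with highest occupancy."""
    best: Dict[str, Tuple[str, str, str, float, np.ndarray, bool]] = {}
    order: List[str] = []
    for rec in raw_atoms:
        name = rec[0]
        if name not in best:
            best[name] = rec
            order.append(name)
        elif rec[3] > best[name][3]:
            best[name] = rec
    return [best[n] for n in order]


def read_structure(path, chain_pair: Tuple[str, str]) -> ComplexStructure:
    """Parse a PDB/mmCIF file and return the two requested chains.

    Waters and hydrogens are kept but flagged; alternate locations are
    resolved to the highest-occupancy record; nonstandard residues are
    mapped to their parent amino acid when tabulated, else UNK.

    Raises
    ------
    FileNotFoundError
        if the file does not exist.
    UnknownChainError
        if a requested chain id is absent.
    StructureError
        if a requested chain has no standard residue.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    present = [ch.name for ch in model]

    chains: List[Chain] = []
    for want in chain_pair:
        gch = None
        for ch in model:
            if ch.name == want:
                gch = ch
                break
        if gch is None:
            raise UnknownChainError(
                f"chain {want!r} not found in {path.name} (present: {present})"
            )
        residues: List[Residue] = []
        n_standard = 0
        for gres in gch:
            resname = gres.name
            is_water = resname in ("HOH", "WAT", "DOD")
            aa = resname if resname in STANDARD_AA else NONSTANDARD_PARENT.get(resname)
            if aa is None and not is_water:
                aa = "UNK"
            if is_water:
                aa = "UNK"
            raw = []
            for ga in gres:
                el = ga.element.name.upper()
                raw.append(
                    (
                        ga.name,
                        el,
                        ga.altloc,
                        float(ga.occ),
                        np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        el == "H" or el == "D",
                    )
                )
            atoms = [
                Atom(name=n, element=el, coords=xyz, occupancy=occ, is_hydrogen=ish)
                for (n, el, _alt, occ, xyz, ish) in _resolve_altlocs(raw)
            ]
            res = Residue(
                chain_id=want,
                number=gres.seqid.num,
                icode=(gres.seqid.icode or "").strip(),
                aa_type=aa,
                atoms=atoms,
                is_water=is_water,
            )
            if resname in STANDARD_AA or resname in NONSTANDARD_PARENT:
                n_standard += 1
            residues.append(res)
        if n_standard == 0:
            raise StructureError(
                f"chain {want!r} in {path.name} contains no standard residue"
            )
        chains.append(Chain(chain_id=want, residues=residues))

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    return ComplexStructure(
        receptor=chains[0],
        ligand=chains[1],
        source_id=st.name or path.stem,
        resolution=resolution,
    )


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

@dataclass
class SasaResult:
    context: str  # "monomer" | "complex"
    probe_radius: float
    atom_sasa: Dict[Tuple[ResidueId, str], float]
    residue_sasa: Dict[ResidueId, float]

    def residue(self, rid: ResidueId) -> float:
        return self.residue_sasa.get(rid, 0.0)


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _sasa_areas(coords: np.ndarray, radii: np.ndarray, probe: float, n_points: int) -> np.ndarray:
    """Per-atom exposed areas (Å²) by sphere-point burial counting."""
    n = len(coords)
    areas = np.zeros(n)
    if n == 0:
        return areas
    sphere = fibonacci_sphere(n_points)
    ext = radii + probe
    tree = cKDTree(coords)
    max_r = ext.max()
    for i in range(n):
        ri = ext[i]
        neigh = tree.query_ball_point(coords[i], ri + max_r)
        neigh = [j for j in neigh if j != i]
        pts = coords[i] + ri * sphere
        if neigh:
            nc = coords[neigh]
            nr = ext[neigh]
            # keep neighbours that can actually occlude
            d = np.linalg.norm(nc - coords[i], axis=1)
            close = d < ri + nr
            nc, nr = nc[close], nr[close]
            if len(nc):
                d2 = ((pts[:, None, :] - nc[None, :, :]) ** 2).sum(axis=2)
                buried = (d2 < (nr ** 2)[None, :]).any(axis=1)
                exposed = np.count_nonzero(~buried)
            else:
                exposed = n_points
        else:
            exposed = n_points
        areas[i] = 4.0 * math.pi * ri * ri * exposed / n_points
    return areas


def compute_sasa(
    structure: ComplexStructure,
    context: str,
    probe_radius: float = 1.4,
    n_points: int = 240,
    include_hetero: bool = False,
) -> SasaResult:
    """Numerical SASA of every heavy protein atom, per atom and per residue.

    ``context='monomer'`` treats each chain in isolation; ``'complex'``
    uses all atoms of both chains.  Waters and hydrogens are excluded.
    Deterministic for a fixed ``n_points``.
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    if context not in ("monomer", "complex"):
        raise ValueError(f"unknown context {context!r}")

    def atom_records(chain: Chain):
        recs = []
        for res in chain.residues:
            if res.is_water:
                continue
            if res.aa_type == "UNK" and not include_hetero and not _looks_proteic(res):
                continue
            for a in res.heavy_atoms():
                recs.append((res.rid, a.name, a.coords, a.vdw_radius))
        return recs

    atom_sasa: Dict[Tuple[ResidueId, str], float] = {}
    groups: List[List] = (
        [atom_records(structure.receptor) + atom_records(structure.ligand)]
        if context == "complex"
        else [atom_records(c) for c in structure.chains]
    )
    for recs in groups:
        if not recs:
            continue
        coords = np.array([r[2] for r in recs])
        radii = np.array([r[3] for r in recs])
        areas = _sasa_areas(coords, radii, probe_radius, n_points)
        for (rid, name, _c, _r), area in zip(recs, areas):
            atom_sasa[(rid, name)] = float(area)

    residue_sasa: Dict[ResidueId, float] = {}
    for (rid, _name), area in atom_sasa.items():
        residue_sasa[rid] = residue_sasa.get(rid, 0.0) + area
    return SasaResult(
        context=context,
        probe_radius=probe_radius,
        atom_sasa=atom_sasa,
        residue_sasa=residue_sasa,
    )


def _looks_proteic(res: Residue) -> bool:
    # UNK residues with a CA are treated as protein (nonstandard amino acids)
    return res.get_atom("CA") is not None


def delta_rasa(
    structure: ComplexStructure,
    probe_radius: float = 1.4,
    n_points: int = 240,
) -> Dict[ResidueId, float]:
    """Per-residue buried area upon binding: SASA(monomer) − SASA(complex)."""
    mono = compute_sasa(structure, "monomer", probe_radius, n_points)
    comp = compute_sasa(structure, "complex", probe_radius, n_points)
    out: Dict[ResidueId, float] = {}
    for rid, area in mono.residue_sasa.items():
        out[rid] = area - comp.residue_sasa.get(rid, 0.0)
    return out
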