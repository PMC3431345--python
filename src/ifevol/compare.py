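"""Residue correspondence between interologs and conservation statistics.

Two homologous complexes ("interologs") are compared through a 1:1
residue correspondence per chain pair, obtained either from a
user-supplied pairwise alignment or from a global sequence alignment
(BLOSUM62, gap open 11, extend 1).  Conservation of each contact type is
a weighted Jaccard index over the residue-pair contact graphs: an edge
present in both interologs contributes the average of its two atomic
contact counts to the conserved weight, an edge present in only one
contributes its own count to the non-conserved weight, and the ratio is
conserved / (conserved + non-conserved).  Both interfaces are first
restricted to residues with a structural equivalent, so alignment gaps
never masquerade as lost contacts.

The module also quantifies residues switching out of the interface,
charge exchanges in conserved salt bridges, the fate of charges orphaned
by a lost salt bridge, and the minimum interface sequence identity used
to bin interolog couples by divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .contacts import NEGATIVE_O, POSITIVE_N, intra_chain_charged_contacts
from .structure import Chain, ComplexStructure, ResidueId

__all__ = [
    "CorrespondenceMap",
    "ConservationResult",
    "chain_correspondence",
    "contact_conservation",
    "switching_out",
    "charge_exchange",
    "charge_fate",
    "min_interface_identity",
    "identity_bin",
    "kabsch_rmsd",
]

POSITIVE_AA = frozenset(POSITIVE_N)
NEGATIVE_AA = frozenset(NEGATIVE_O)

IDENTITY_BINS = ((0.0, 30.0), (30.0, 50.0), (50.0, 70.0), (70.0, 100.0))


class AlignmentMismatchError(ValueError):
    """Provided alignment sequence does not match the structure sequence."""


@dataclass
class CorrespondenceMap:
    """1:1 (partial) residue correspondence between two complexes.

    ``mapping`` sends residues of complex A to residues of complex B over
    all paired chains; only mapped residues ever enter conservation
    statistics.
    """

    mapping: Dict[ResidueId, ResidueId]
    chain_pairing: List[Tuple[str, str]]
    source: str = "computed"                      # or "provided-alignment"
    chain_identity: Dict[str, float] = field(default_factory=dict)  # % per A-chain
    rmsd: Optional[float] = None

    def __post_init__(self) -> None:
        values = list(self.mapping.values())
        if len(values) != len(set(values)):
            raise ValueError("correspondence must be bijective on its domain")

    @property
    def reverse(self) -> Dict[ResidueId, ResidueId]:
        return {v: k for k, v in self.mapping.items()}

    def mapped_a(self) -> Set[ResidueId]:
        return set(self.mapping)

    def mapped_b(self) -> Set[ResidueId]:
        return set(self.mapping.values())


def _align_pair(seq_a: str, seq_b: str) -> List[Tuple[int, int]]:
    """Global alignment (BLOSUM62, open 11, extend 1) -> aligned index pairs."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(seq_a.replace("X", "A"), seq_b.replace("X", "A"))[0]
    pairs: List[Tuple[int, int]] = []
    for (sa, ea), (sb, eb) in zip(aln.aligned[0], aln.aligned[1]):
        pairs.extend(zip(range(sa, ea), range(sb, eb)))
    return pairs


def _pairs_from_alignment_file(path, seq_a: str, seq_b: str) -> List[Tuple[int, int]]:
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"alignment file {path} must contain exactly 2 sequences")
    row_a, row_b = str(records[0].seq).upper(), str(records[1].seq).upper()
    if len(row_a) != len(row_b):
        raise ValueError(f"alignment rows in {path} differ in length")
    for row, seq, label in ((row_a, seq_a, "first"), (row_b, seq_b, "second")):
        ungapped = row.replace("-", "")
        if ungapped != seq:
            for k, (x, y) in enumerate(zip(ungapped, seq)):
                if x != y:
                    raise AlignmentMismatchError(
                        f"{label} alignment sequence mismatch at position {k + 1}: "
                        f"alignment has {x!r}, structure has {y!r}"
                    )
            raise AlignmentMismatchError(
                f"{label} alignment sequence length {len(ungapped)} != structure {len(seq)}"
            )
    pairs: List[Tuple[int, int]] = []
    i = j = 0
    for ca, cb in zip(row_a, row_b):
        if ca != "-" and cb != "-":
            pairs.append((i, j))
        if ca != "-":
            i += 1
        if cb != "-":
            j += 1
    return pairs


def kabsch_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """RMSD after optimal rigid superposition (Kabsch)."""
    x = np.asarray(x, float) - np.mean(x, axis=0)
    y = np.asarray(y, float) - np.mean(y, axis=0)
    h = x.T @ y
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = (rot @ x.T).T - y
    return float(np.sqrt((diff ** 2).sum() / len(x)))


def chain_correspondence(
    complex_a: ComplexStructure,
    complex_b: ComplexStructure,
    chain_pairing: Optional[List[Tuple[str, str]]] = None,
    alignments: Optional[Mapping[Tuple[str, str], object]] = None,
    superpose: bool = False,
) -> CorrespondenceMap:
    """Build the residue correspondence for each paired chain.

    ``chain_pairing`` lists (chain in A, chain in B); by default receptor
    pairs with receptor and ligand with ligand.  ``alignments`` may map a
    chain pair to an aligned-FASTA path (two rows: chain of A, chain of
    B); chains without a provided alignment are aligned globally.
    Identity per chain = identical aligned pairs / aligned pairs x 100.
    """
    if chain_pairing is None:
        chain_pairing = [
            (complex_a.receptor.chain_id, complex_b.receptor.chain_id),
            (complex_a.ligand.chain_id, complex_b.ligand.chain_id),
        ]
    mapping: Dict[ResidueId, ResidueId] = {}
    chain_identity: Dict[str, float] = {}
    source = "computed"
    ca_pairs: List[Tuple[np.ndarray, np.ndarray]] = []
    for cid_a, cid_b in chain_pairing:
        chain_a, chain_b = complex_a.chain(cid_a), complex_b.chain(cid_b)
        res_a = [r for r in chain_a.residues if not r.is_water]
        res_b = [r for r in chain_b.residues if not r.is_water]
        seq_a = "".join(r.one_letter for r in res_a)
        seq_b = "".join(r.one_letter for r in res_b)
        if alignments and (cid_a, cid_b) in alignments:
            pairs = _pairs_from_alignment_file(alignments[(cid_a, cid_b)], seq_a, seq_b)
            source = "provided-alignment"
        else:
            pairs = _align_pair(seq_a, seq_b)
        ident = sum(1 for i, j in pairs if seq_a[i] == seq_b[j])
        chain_identity[cid_a] = 100.0 * ident / len(pairs) if pairs else 0.0
        for i, j in pairs:
            mapping[res_a[i].rid] = res_b[j].rid
            a_ca = res_a[i].get_atom("CA")
            b_ca = res_b[j].get_atom("CA")
            if a_ca is not None and b_ca is not None:
                ca_pairs.append((a_ca.coords, b_ca.coords))
    rmsd = None
    if superpose and len(ca_pairs) >= 3:
        rmsd = kabsch_rmsd(
            np.array([p[0] for p in ca_pairs]), np.array([p[1] for p in ca_pairs])
        )
    return CorrespondenceMap(
        mapping=mapping,
        chain_pairing=list(chain_pairing),
        source=source,
        chain_identity=chain_identity,
        rmsd=rmsd,
    )


# ---------------------------------------------------------------------------
# Conservation statistics
# ---------------------------------------------------------------------------

Edge = Tuple[ResidueId, ResidueId]


@dataclass
class ConservationResult:
    conserved_weight: float
    non_conserved_weight: float
    n_conserved: int
    n_only_a: int
    n_only_b: int

    @property
    def ratio(self) -> Optional[float]:
        total = self.conserved_weight + self.non_conserved_weight
        if total <= 0:
            return None  # empty-vs-empty: missing, not 0
        return self.conserved_weight / total


def contact_conservation(
    edges_a: Mapping[Edge, float],
    edges_b: Mapping[Edge, float],
    corr: CorrespondenceMap,
    weighted: bool = True,
) -> ConservationResult:
    """Weighted Jaccard conservation of a residue-pair contact graph.

    Edges with an unmapped endpoint are discarded on both sides before
    comparison.  With ``weighted=False`` every edge counts 1 (used for
    salt bridges, charged contacts and hydrogen bonds).
    """
    mapped_a, mapped_b = corr.mapped_a(), corr.mapped_b()
    a = {
        e: (w if weighted else 1.0)
        for e, w in edges_a.items()
        if e[0] in mapped_a and e[1] in mapped_a
    }
    b = {
        e: (w if weighted else 1.0)
        for e, w in edges_b.items()
        if e[0] in mapped_b and e[1] in mapped_b
    }
    a_in_b = {(corr.mapping[e[0]], corr.mapping[e[1]]): w for e, w in a.items()}
    shared = set(a_in_b) & set(b)
    conserved = sum((a_in_b[e] + b[e]) / 2.0 for e in shared)
    non_conserved = sum(w for e, w in a_in_b.items() if e not in shared) + sum(
        w for e, w in b.items() if e not in shared
    )
    return ConservationResult(
        conserved_weight=conserved,
        non_conserved_weight=non_conserved,
        n_conserved=len(shared),
        n_only_a=len(a_in_b) - len(shared),
        n_only_b=len(b) - len(shared),
    )


@dataclass
class SwitchingOut:
    flags_a: Dict[ResidueId, bool]      # interface residues of A with mapped partner
    flags_b: Dict[ResidueId, bool]
    regions_a: Dict[ResidueId, str]
    regions_b: Dict[ResidueId, str]

    @property
    def fraction(self) -> Optional[float]:
        n = len(self.flags_a) + len(self.flags_b)
        if n == 0:
            return None
        k = sum(self.flags_a.values()) + sum(self.flags_b.values())
        return k / n

    def fraction_by_region(self) -> Dict[str, Optional[float]]:
        out: Dict[str, Optional[float]] = {}
        for region in ("core", "support", "rim"):
            n = k = 0
            for flags, regions in ((self.flags_a, self.regions_a), (self.flags_b, self.regions_b)):
                for rid, flag in flags.items():
                    if regions.get(rid) == region:
                        n += 1
                        k += int(flag)
            out[region] = (k / n) if n else None
        return out


def switching_out(
    interface_a: Set[ResidueId],
    interface_b: Set[ResidueId],
    corr: CorrespondenceMap,
    regions_a: Optional[Mapping[ResidueId, str]] = None,
    regions_b: Optional[Mapping[ResidueId, str]] = None,
) -> SwitchingOut:
    """Flag interface residues whose structural equivalent left the interface.

    A residue is flagged iff it is at the interface in one complex and
    its mapped equivalent exists but is not at the interface in the
    other.  Residues without a mapped equivalent are excluded entirely.
    """
    rev = corr.reverse
    flags_a = {
        rid: corr.mapping[rid] not in interface_b
        for rid in interface_a
        if rid in corr.mapping
    }
    flags_b = {rid: rev[rid] not in interface_a for rid in interface_b if rid in rev}
    return SwitchingOut(
        flags_a=flags_a,
        flags_b=flags_b,
        regions_a=dict(regions_a or {}),
        regions_b=dict(regions_b or {}),
    )


def _charge_sign(aa: str) -> int:
    if aa in POSITIVE_AA:
        return 1
    if aa in NEGATIVE_AA:
        return -1
    return 0


def charge_exchange(
    salt_bridges_a: Iterable[Edge],
    salt_bridges_b: Iterable[Edge],
    corr: CorrespondenceMap,
    complex_a: ComplexStructure,
    complex_b: ComplexStructure,
) -> Dict[Edge, bool]:
    """Conserved salt-bridge edges flagged True when the charges swapped sides.

    A conserved edge whose mapped residues carry the opposite signs
    (e.g. K-E becoming D-R) is a charge exchange and still counts as a
    conserved contact.
    """
    mapped = corr.mapping
    sb_b = set(salt_bridges_b)
    out: Dict[Edge, bool] = {}
    for (ra, rb) in salt_bridges_a:
        if ra not in mapped or rb not in mapped:
            continue
        image = (mapped[ra], mapped[rb])
        if image not in sb_b:
            continue
        sign_a = (_charge_sign(complex_a.residue(ra).aa_type),
                  _charge_sign(complex_a.residue(rb).aa_type))
        sign_b = (_charge_sign(complex_b.residue(image[0]).aa_type),
                  _charge_sign(complex_b.residue(image[1]).aa_type))
        out[(ra, rb)] = (
            sign_a[0] != 0
            and sign_a == (-sign_b[0], -sign_b[1])
        )
    return out


CHARGE_FATE_CATEGORIES = ("switch-out", "SB-inter", "SB-intra", "CH-inter", "CH-intra", "other")


def charge_fate(
    salt_bridges_a: Iterable[Edge],
    salt_bridges_b: Iterable[Edge],
    corr: CorrespondenceMap,
    complex_a: ComplexStructure,
    complex_b: ComplexStructure,
    interface_b: Set[ResidueId],
    charged_b: Optional[Iterable[Edge]] = None,
    sb_cutoff: float = 3.5,
    charged_cutoff: float = 5.5,
) -> Dict[ResidueId, str]:
    """Fate of residues orphaned by a lost salt bridge but remaining charged.

    For every salt bridge of complex A absent (at mapped positions) from
    complex B, each endpoint whose equivalent in B is still charged is
    assigned the first matching category: ``switch-out`` (no longer at
    interface), ``SB-inter`` (another interface salt bridge), ``SB-intra``
    (intra-chain salt bridge), ``CH-inter`` / ``CH-intra`` (longer-range
    charged contact), else ``other``.  Keys are residues of complex B.
    """
    mapped = corr.mapping
    sb_b_set = set(salt_bridges_b)
    # inter-chain charged residues of B at two cutoffs
    from .contacts import charged_contacts, salt_bridges as sb_fn

    inter_sb = {rid for e in sb_fn(complex_b, sb_cutoff) for rid in e}
    inter_ch = {rid for e in charged_contacts(complex_b, charged_cutoff) for rid in e}
    intra_sb: Set[ResidueId] = set()
    intra_ch: Set[ResidueId] = set()
    for chain in complex_b.chains:
        for e in intra_chain_charged_contacts(complex_b, chain.chain_id, sb_cutoff):
            intra_sb.update(e)
        for e in intra_chain_charged_contacts(complex_b, chain.chain_id, charged_cutoff):
            intra_ch.update(e)

    out: Dict[ResidueId, str] = {}
    for (ra, rb) in salt_bridges_a:
        if ra not in mapped or rb not in mapped:
            continue
        image = (mapped[ra], mapped[rb])
        if image in sb_b_set:
            continue  # conserved, nothing lost
        for rid_b in image:
            if _charge_sign(complex_b.residue(rid_b).aa_type) == 0:
                continue
            if rid_b not in interface_b:
                out[rid_b] = "switch-out"
            elif rid_b in inter_sb:
                out[rid_b] = "SB-inter"
            elif rid_b in intra_sb:
                out[rid_b] = "SB-intra"
            elif rid_b in inter_ch:
                out[rid_b] = "CH-inter"
            elif rid_b in intra_ch:
                out[rid_b] = "CH-intra"
            else:
                out[rid_b] = "other"
    return out


def identity_bin(identity: float) -> str:
    """Half-open bins [0,30), [30,50), [50,70), [70,100]."""
    for low, high in IDENTITY_BINS:
        if low <= identity < high or (high == 100.0 and identity == 100.0):
            return f"[{low:g},{high:g}{']' if high == 100.0 else ')'}"
    raise ValueError(f"identity {identity} out of range")


def min_interface_identity(
    complex_a: ComplexStructure,
    complex_b: ComplexStructure,
    interface_a: Set[ResidueId],
    interface_b: Set[ResidueId],
    corr: CorrespondenceMap,
) -> Tuple[float, str, Dict[str, float]]:
    """Minimum over chain pairs of percent identity at mapped interface positions.

    Positions counted are those mapped and at the interface in both
    complexes (intersection rule).  Returns (minimum %, bin label,
    per-chain %).
    """
    per_chain: Dict[str, float] = {}
    for cid_a, cid_b in corr.chain_pairing:
        n = k = 0
        for rid, rid_b in corr.mapping.items():
            if rid.chain_id != cid_a:
                continue
            if rid not in interface_a or rid_b not in interface_b:
                continue
            n += 1
            if complex_a.residue(rid).one_letter == complex_b.residue(rid_b).one_letter:
                k += 1
        if n:
            per_chain[cid_a] = 100.0 * k / n
    if not per_chain:
        raise ValueError("no mapped interface residues; interface identity undefined")
    minimum = min(per_chain.values())
    return minimum, identity_bin(minimum), per_chain
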