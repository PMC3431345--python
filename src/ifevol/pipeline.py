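"""End-to-end orchestration: per-complex analysis, pair comparison, batches.

`analyze_complex` runs the full per-complex stage: SASA and buried
areas, interface detection, sub-region classification, typed contacts,
apolar patches and anchors.  `compare_pair` takes two analysed complexes
plus a residue correspondence and produces the conservation report:
weighted Jaccard per contact type, the patch-membership split of apolar
conservation, patch-bundle conservation after cross-interolog merging,
switching out, charge exchange and charge fate, minimum interface
identity, and per-residue features scored with the two predictor
presets.  `run_batch` maps the comparison over a manifest of couples and
pools means with half-sample bootstrap confidence intervals.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import compare as cmp
from . import contacts as ct
from . import interface as ifc
from . import patches as pt
from . import predict as pr
from .stats import bootstrap_mean_ci
from .structure import ComplexStructure, ResidueId, compute_sasa, delta_rasa, read_structure

__all__ = [
    "PipelineConfig",
    "ComplexAnalysis",
    "PairReport",
    "analyze_complex",
    "compare_pair",
    "run_batch",
    "load_rate_scores",
]

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, JSON round-trippable."""

    atomic_cutoff: float = 5.0
    charged_cutoff: float = 5.5
    salt_bridge_cutoff: float = 3.5
    hbond_cutoff: float = 3.5
    hbond_min_angle: float = 90.0
    apolar_cutoff: float = 4.5
    patch_adjacency_cutoff: float = 5.5
    include_backbone_apolar: bool = False
    neighbor_radius: float = 8.0
    extended_radius: float = 10.0
    anchor_min_delta_rasa: float = 80.0
    max_anchors: int = 3
    anchors_per_chain: bool = False
    probe_radius: float = 1.4
    sasa_points: int = 240
    conservation_threshold: float = 0.5   # label rule for the conservation model
    rate_score_threshold: float = 80.0
    seed: int = 0

    def contact_config(self) -> ct.ContactConfig:
        return ct.ContactConfig(
            atomic_cutoff=self.atomic_cutoff,
            charged_cutoff=self.charged_cutoff,
            salt_bridge_cutoff=self.salt_bridge_cutoff,
            hbond_cutoff=self.hbond_cutoff,
            hbond_min_angle=self.hbond_min_angle,
            apolar_cutoff=self.apolar_cutoff,
            patch_adjacency_cutoff=self.patch_adjacency_cutoff,
            include_backbone_apolar=self.include_backbone_apolar,
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


Edge = Tuple[ResidueId, ResidueId]


@dataclass
class ComplexAnalysis:
    structure: ComplexStructure
    config: PipelineConfig
    atomic: List[ct.AtomicContact]
    residue_graph: Dict[Edge, ct.ResidueContactEdge]
    charged: Dict[Edge, list]
    salt_bridges: Dict[Edge, list]
    hbonds: Dict[Edge, list]
    apolar: Dict[Edge, list]
    interface_model: ifc.InterfaceModel
    patches: Dict[str, List[pt.ApolarPatch]]
    monomer_sasa: object
    delta_rasa: Dict[ResidueId, float]

    def atomic_edge_weights(self) -> Dict[Edge, float]:
        return {e: float(edge.weight) for e, edge in self.residue_graph.items()}

    def apolar_edge_weights(self) -> Dict[Edge, float]:
        return {e: float(len(pairs)) for e, pairs in self.apolar.items()}

    def patch_membership(self) -> Set[ResidueId]:
        out: Set[ResidueId] = set()
        for plist in self.patches.values():
            for p in plist:
                out |= p.residues
        return out

    def contact_counts(self) -> Dict[ResidueId, int]:
        counts: Dict[ResidueId, int] = {}
        for (a, b), edge in self.residue_graph.items():
            counts[a] = counts.get(a, 0) + edge.weight
            counts[b] = counts.get(b, 0) + edge.weight
        return counts


def analyze_complex(
    structure: ComplexStructure,
    config: Optional[PipelineConfig] = None,
) -> ComplexAnalysis:
    """Run the full per-complex stage (contacts, interface, patches, anchors)."""
    cfg = config or PipelineConfig()
    ccfg = cfg.contact_config()
    atomic = ct.atomic_contacts(structure, ccfg)
    graph = ct.residue_contact_graph(atomic)
    mono = compute_sasa(structure, "monomer", cfg.probe_radius, cfg.sasa_points)
    comp = compute_sasa(structure, "complex", cfg.probe_radius, cfg.sasa_points)
    drasa = {
        rid: area - comp.residue_sasa.get(rid, 0.0)
        for rid, area in mono.residue_sasa.items()
    }
    iface = ifc.interface_residues(structure, graph.keys(), cfg.neighbor_radius)
    charged = ct.charged_contacts(structure, cfg.charged_cutoff)
    sbs = ct.salt_bridges(structure, cfg.salt_bridge_cutoff)
    hbs = ct.hydrogen_bonds(structure, cfg.hbond_cutoff, cfg.hbond_min_angle)
    apol = ct.apolar_contacts(structure, iface, mono, ccfg)
    for e, pairs in apol.items():
        edge = graph.get(e)
        if edge is not None:
            edge.apolar = True
            edge.apolar_atomic = len(pairs)
    for e in charged:
        if e in graph:
            graph[e].charged = True
    for e in sbs:
        if e in graph:
            graph[e].salt_bridge = True
    for e in hbs:
        if e in graph:
            graph[e].hbond = True

    model = ifc.build_interface_model(
        structure,
        graph.keys(),
        drasa,
        contact_counts=None,
        anchors_per_chain=cfg.anchors_per_chain,
    )
    patches = pt.detect_patches(structure, model.interface, mono, ccfg)
    analysis = ComplexAnalysis(
        structure=structure,
        config=cfg,
        atomic=atomic,
        residue_graph=graph,
        charged=charged,
        salt_bridges=sbs,
        hbonds=hbs,
        apolar=apol,
        interface_model=model,
        patches=patches,
        monomer_sasa=mono,
        delta_rasa=drasa,
    )
    model.n_contacts = analysis.contact_counts()
    return analysis


@dataclass
class PairReport:
    """Conservation report for one interolog couple."""

    conservation: Dict[str, Optional[float]]
    conservation_detail: Dict[str, cmp.ConservationResult]
    switching: cmp.SwitchingOut
    charge_exchange_count: int
    charge_fate: Dict[ResidueId, str]
    min_interface_identity: float
    identity_bin: str
    chain_identity: Dict[str, float]
    features: pd.DataFrame
    correspondence: cmp.CorrespondenceMap

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "conservation": {k: v for k, v in self.conservation.items()},
            "switching_out_fraction": self.switching.fraction,
            "switching_out_by_region": self.switching.fraction_by_region(),
            "charge_exchange_count": self.charge_exchange_count,
            "charge_fate": {str(k): v for k, v in self.charge_fate.items()},
            "min_interface_identity": self.min_interface_identity,
            "identity_bin": self.identity_bin,
            "chain_identity": self.chain_identity,
        }


def _unweighted(edges: Mapping[Edge, object]) -> Dict[Edge, float]:
    return {e: 1.0 for e in edges}


def _restrict(edges: Mapping[Edge, float], keep) -> Dict[Edge, float]:
    return {e: w for e, w in edges.items() if keep(e)}


def compare_pair(
    analysis_a: ComplexAnalysis,
    analysis_b: ComplexAnalysis,
    corr: Optional[cmp.CorrespondenceMap] = None,
    alignments: Optional[Mapping[Tuple[str, str], object]] = None,
    rate_scores: Optional[Mapping[ResidueId, float]] = None,
) -> PairReport:
    """Compute the full conservation report for two analysed complexes."""
    a, b = analysis_a, analysis_b
    cfg = a.config
    if corr is None:
        corr = cmp.chain_correspondence(
            a.structure, b.structure, alignments=alignments, superpose=True
        )

    iface_a = a.interface_model.all_interface()
    iface_b = b.interface_model.all_interface()

    atomic_a, atomic_b = a.atomic_edge_weights(), b.atomic_edge_weights()
    apolar_a, apolar_b = a.apolar_edge_weights(), b.apolar_edge_weights()

    detail: Dict[str, cmp.ConservationResult] = {}
    detail["atomic"] = cmp.contact_conservation(atomic_a, atomic_b, corr, weighted=True)
    detail["apolar"] = cmp.contact_conservation(apolar_a, apolar_b, corr, weighted=True)
    detail["charged"] = cmp.contact_conservation(
        _unweighted(a.charged), _unweighted(b.charged), corr, weighted=False
    )
    detail["salt_bridge"] = cmp.contact_conservation(
        _unweighted(a.salt_bridges), _unweighted(b.salt_bridges), corr, weighted=False
    )
    detail["hbond"] = cmp.contact_conservation(
        _unweighted(a.hbonds), _unweighted(b.hbonds), corr, weighted=False
    )

    # atomic contacts involving at least one anchor residue (either interolog)
    anchors_a = set(a.interface_model.anchors)
    anchors_b = set(b.interface_model.anchors)
    anchors_b_in_a = {corr.reverse[r] for r in anchors_b if r in corr.reverse}

    def touches_anchor_a(e: Edge) -> bool:
        return bool(set(e) & (anchors_a | anchors_b_in_a))

    def touches_anchor_b(e: Edge) -> bool:
        mapped = {corr.mapping.get(r) for r in (anchors_a | anchors_b_in_a)}
        return bool(set(e) & anchors_b | (set(e) & mapped))

    detail["atomic_anchor"] = cmp.contact_conservation(
        _restrict(atomic_a, touches_anchor_a),
        _restrict(atomic_b, touches_anchor_b),
        corr,
        weighted=True,
    )

    # apolar conservation split by patch membership (both / one / none)
    in_patch_a = a.patch_membership()
    in_patch_b = b.patch_membership()

    def membership_class(e: Edge, members: Set[ResidueId]) -> int:
        return int(e[0] in members) + int(e[1] in members)

    for label, k in (("apolar_patch_both", 2), ("apolar_patch_one", 1), ("apolar_patch_none", 0)):
        detail[label] = cmp.contact_conservation(
            _restrict(apolar_a, lambda e: membership_class(e, in_patch_a) == k),
            _restrict(apolar_b, lambda e: membership_class(e, in_patch_b) == k),
            corr,
            weighted=True,
        )

    detail["patch_bundle"] = _bundle_conservation(a, b, corr)

    if rate_scores is not None:
        thr = cfg.rate_score_threshold

        def conserved_res(e: Edge) -> bool:
            return all(rate_scores.get(r, 0.0) > thr for r in e)

        def conserved_res_b(e: Edge) -> bool:
            rev = corr.reverse
            return all(
                rate_scores.get(rev.get(r), 0.0) > thr if r in rev else False for r in e
            )

        detail["atomic_conserved_residues"] = cmp.contact_conservation(
            _restrict(atomic_a, conserved_res),
            _restrict(atomic_b, conserved_res_b),
            corr,
            weighted=True,
        )

    switching = cmp.switching_out(
        iface_a, iface_b, corr, a.interface_model.regions, b.interface_model.regions
    )
    exchanges = cmp.charge_exchange(
        a.salt_bridges.keys(), b.salt_bridges.keys(), corr, a.structure, b.structure
    )
    fates = cmp.charge_fate(
        a.salt_bridges.keys(),
        b.salt_bridges.keys(),
        corr,
        a.structure,
        b.structure,
        iface_b,
        sb_cutoff=cfg.salt_bridge_cutoff,
        charged_cutoff=cfg.charged_cutoff,
    )
    min_id, id_bin, _per = cmp.min_interface_identity(
        a.structure, b.structure, iface_a, iface_b, corr
    )

    features = _pair_features(a, b, corr, min_id)

    return PairReport(
        conservation={k: v.ratio for k, v in detail.items()},
        conservation_detail=detail,
        switching=switching,
        charge_exchange_count=sum(exchanges.values()),
        charge_fate=fates,
        min_interface_identity=min_id,
        identity_bin=id_bin,
        chain_identity=dict(corr.chain_identity),
        features=features,
        correspondence=corr,
    )


def _bundle_conservation(
    a: ComplexAnalysis, b: ComplexAnalysis, corr: cmp.CorrespondenceMap
) -> cmp.ConservationResult:
    """Patch-bundle conservation after cross-interolog patch merging."""
    rec_a, lig_a = a.structure.receptor.chain_id, a.structure.ligand.chain_id
    rec_b, lig_b = b.structure.receptor.chain_id, b.structure.ligand.chain_id
    sub_rec = {k: v for k, v in corr.mapping.items() if k.chain_id == rec_a}
    sub_lig = {k: v for k, v in corr.mapping.items() if k.chain_id == lig_a}
    pa_rec, pb_rec, map_rec = pt.merge_patches_across_interologs(
        a.patches.get(rec_a, []), b.patches.get(rec_b, []), sub_rec
    )
    pa_lig, pb_lig, map_lig = pt.merge_patches_across_interologs(
        a.patches.get(lig_a, []), b.patches.get(lig_b, []), sub_lig
    )
    bundles_a = pt.patch_contact_bundles(
        {rec_a: pa_rec, lig_a: pa_lig}, a.apolar, rec_a, lig_a
    )
    bundles_b = pt.patch_contact_bundles(
        {rec_b: pb_rec, lig_b: pb_lig}, b.apolar, rec_b, lig_b
    )
    wa = {(bd.patch_a, bd.patch_b): float(bd.n_apolar_contacts) for bd in bundles_a}
    wb = {(bd.patch_a, bd.patch_b): float(bd.n_apolar_contacts) for bd in bundles_b}
    conserved = non = 0.0
    n_cons = n_a = 0
    for (i, j), w in wa.items():
        if i in map_rec and j in map_lig and (map_rec[i], map_lig[j]) in wb:
            conserved += (w + wb[(map_rec[i], map_lig[j])]) / 2.0
            n_cons += 1
        else:
            non += w
            n_a += 1
    mapped_images = {
        (map_rec[i], map_lig[j]) for (i, j) in wa if i in map_rec and j in map_lig
    }
    n_b = 0
    for (i, j), w in wb.items():
        if (i, j) not in mapped_images:
            non += w
            n_b += 1
    return cmp.ConservationResult(
        conserved_weight=conserved,
        non_conserved_weight=non,
        n_conserved=n_cons,
        n_only_a=n_a,
        n_only_b=n_b,
    )


def _pair_features(
    a: ComplexAnalysis,
    b: ComplexAnalysis,
    corr: cmp.CorrespondenceMap,
    min_identity: float,
) -> pd.DataFrame:
    """Per-residue six-feature table with predictor scores and labels.

    Rows cover mapped interface residues of complex A with at least one
    mapped contacting residue.  ``switch_out`` is the observed label;
    ``conserve`` flags residues retaining at least the configured
    fraction of their atomic-contact weight.
    """
    model = a.interface_model
    atomic_a = a.atomic_edge_weights()
    atomic_b = b.atomic_edge_weights()
    iface_b = b.interface_model.all_interface()
    rows: List[dict] = []
    for rid in sorted(model.all_interface()):
        if rid not in corr.mapping:
            continue
        try:
            fv = pr.residue_features(
                rid,
                a.structure,
                b.structure,
                corr,
                atomic_a,
                model.regions,
                model.center_distance,
                min_identity,
            )
        except (pr.ZeroContactResidueError, KeyError):
            continue
        feats = fv.as_dict()
        switch = corr.mapping[rid] not in iface_b
        conserved_w = total_w = 0.0
        for (x, y), w in atomic_a.items():
            if rid not in (x, y):
                continue
            if x not in corr.mapping or y not in corr.mapping:
                continue
            total_w += w
            image = (corr.mapping[x], corr.mapping[y])
            if image in atomic_b:
                conserved_w += w
        conserve = bool(total_w > 0 and conserved_w / total_w >= a.config.conservation_threshold)
        rows.append(
            {
                "residue": str(rid),
                "region": fv.region,
                **feats,
                "is_anchor": rid in set(model.anchors),
                "switch_out": switch,
                "conserve_contacts": conserve,
                "p_switch_out": pr.logistic_score(feats, pr.SWITCHING_OUT_MODEL),
                "p_conserve": pr.logistic_score(feats, pr.CONTACT_CONSERVATION_MODEL),
            }
        )
    return pd.DataFrame(rows)


def load_rate_scores(path) -> Dict[ResidueId, float]:
    """Read per-residue normalised evolutionary-rate scores from TSV.

    Expected columns: chain, resnum, icode (may be empty), score (0-100).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chain": str, "icode": str})
    out: Dict[ResidueId, float] = {}
    for _, row in df.iterrows():
        icode = "" if pd.isna(row.get("icode", "")) else str(row.get("icode", "")).strip()
        out[ResidueId(str(row["chain"]), int(row["resnum"]), icode)] = float(row["score"])
    return out


def run_batch(
    manifest: pd.DataFrame,
    config: Optional[PipelineConfig] = None,
) -> Tuple[pd.DataFrame, Dict[str, object], List[Tuple[str, str]]]:
    """Process a manifest of interolog couples and pool conservation means.

    Manifest columns: ``id, path_a, chains_a, path_b, chains_b`` and
    optionally ``aln_1, aln_2`` (aligned FASTA per chain pair) and
    ``rate_scores`` (TSV path).  Chains are given as ``A:B``.  Failures
    are recorded and skipped.  Returns (per-couple table, pooled summary
    with bootstrap CIs, failures).
    """
    cfg = config or PipelineConfig()
    rows: List[dict] = []
    failures: List[Tuple[str, str]] = []
    for _, entry in manifest.iterrows():
        cid = str(entry["id"])
        try:
            ca = read_structure(entry["path_a"], tuple(str(entry["chains_a"]).split(":")))
            cb = read_structure(entry["path_b"], tuple(str(entry["chains_b"]).split(":")))
            aa = analyze_complex(ca, cfg)
            ab = analyze_complex(cb, cfg)
            alignments = None
            if "aln_1" in entry and isinstance(entry.get("aln_1"), str) and entry["aln_1"]:
                pairing = list(
                    zip(str(entry["chains_a"]).split(":"), str(entry["chains_b"]).split(":"))
                )
                alignments = {pairing[0]: entry["aln_1"]}
                if "aln_2" in entry and isinstance(entry.get("aln_2"), str) and entry["aln_2"]:
                    alignments[pairing[1]] = entry["aln_2"]
            scores = None
            if "rate_scores" in entry and isinstance(entry.get("rate_scores"), str) and entry["rate_scores"]:
                scores = load_rate_scores(entry["rate_scores"])
            report = compare_pair(aa, ab, alignments=alignments, rate_scores=scores)
            row = {"id": cid, **{f"cons_{k}": v for k, v in report.conservation.items()}}
            row["switch_out"] = report.switching.fraction
            row["min_interface_identity"] = report.min_interface_identity
            rows.append(row)
        except Exception as exc:  # noqa: BLE001 - per-couple isolation
            failures.append((cid, f"{type(exc).__name__}: {exc}"))
    table = pd.DataFrame(rows)
    summary: Dict[str, object] = {"n_couples": len(rows), "n_failures": len(failures)}
    if len(rows) >= 4:
        for col in table.columns:
            if col == "id":
                continue
            vals = table[col].dropna().to_numpy(dtype=float)
            if len(vals) >= 4:
                bs = bootstrap_mean_ci(vals, seed=cfg.seed)
                summary[col] = {
                    "mean": bs.estimate,
                    "ci_low": bs.ci_low,
                    "ci_high": bs.ci_high,
                }
    return table, summary, failures
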