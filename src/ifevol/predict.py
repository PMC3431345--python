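"""Residue-level logistic predictors of switching-out and contact conservation.

Six features describe each interface residue: three sequence features
(BLOSUM62 similarity of the residue with its structural equivalent, mean
BLOSUM62 similarity of its contact environment, overall minimum percent
identity with the interolog) and three geometric features (core/support/
rim category dummy-coded with core as reference, number of atomic
contacts, normalised distance to the interface geometric centre).  Two
published coefficient sets are shipped as presets; models can also be
refit by maximum likelihood, scored by ROC/AUC and dissected with a
drop-one deviance ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .compare import CorrespondenceMap
from .structure import ComplexStructure, ResidueId

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "LogisticModel",
    "SWITCHING_OUT_MODEL",
    "CONTACT_CONSERVATION_MODEL",
    "blosum62_score",
    "residue_features",
    "feature_table",
    "logistic_score",
    "fit_logistic",
    "roc_auc",
    "deviance_ranking",
    "split_train_test",
]

FEATURE_NAMES = ("sim_res", "sim_env", "seq_id", "support", "rim", "n_contacts", "dist_center")

_BLOSUM = None


def _blosum():
    global _BLOSUM
    if _BLOSUM is None:
        from Bio.Align import substitution_matrices

        _BLOSUM = substitution_matrices.load("BLOSUM62")
    return _BLOSUM


def blosum62_score(aa1: str, aa2: str) -> float:
    """BLOSUM62 substitution score for two one-letter amino acids."""
    m = _blosum()
    a = aa1 if aa1 in m.alphabet else "X"
    b = aa2 if aa2 in m.alphabet else "X"
    return float(m[a, b])


@dataclass
class FeatureVector:
    rid: ResidueId
    sim_res: float
    sim_env: float
    seq_id: float               # percent, 0-100
    region: str                 # core | support | rim
    n_contacts: int
    dist_center: float

    def __post_init__(self) -> None:
        if self.region not in ("core", "support", "rim"):
            raise ValueError(f"unknown region {self.region!r}")
        if not (0.0 <= self.dist_center <= 1.0 + 1e-9):
            raise ValueError("dist_center must be in [0, 1]")

    def as_dict(self) -> Dict[str, float]:
        return {
            "sim_res": self.sim_res,
            "sim_env": self.sim_env,
            "seq_id": self.seq_id,
            "support": 1.0 if self.region == "support" else 0.0,
            "rim": 1.0 if self.region == "rim" else 0.0,
            "n_contacts": float(self.n_contacts),
            "dist_center": self.dist_center,
        }


@dataclass
class LogisticModel:
    """Named logistic-regression coefficients plus intercept."""

    intercept: float
    coefficients: Dict[str, float]
    standard_errors: Dict[str, float] = field(default_factory=dict)
    deviance: Optional[float] = None

    def linear_predictor(self, features: Mapping[str, float]) -> float:
        z = self.intercept
        for name, beta in self.coefficients.items():
            if name not in features:
                raise KeyError(f"missing feature {name!r}")
            z += beta * features[name]
        return z

    def predict(self, features: Mapping[str, float]) -> float:
        return 1.0 / (1.0 + math.exp(-self.linear_predictor(features)))


# Published coefficient presets (average over ten random train/test repeats).
SWITCHING_OUT_MODEL = LogisticModel(
    intercept=-1.99,
    coefficients={
        "sim_res": -0.054,
        "sim_env": -0.128,
        "seq_id": -0.0096,
        "support": 0.96,
        "rim": 1.06,
        "n_contacts": -0.122,
        "dist_center": 1.40,
    },
)

CONTACT_CONSERVATION_MODEL = LogisticModel(
    intercept=-1.32,
    coefficients={
        "sim_res": 0.112,
        "sim_env": 0.224,
        "seq_id": 0.0066,
        "support": 0.23,
        "rim": -0.21,
        "n_contacts": 0.075,
        "dist_center": -0.69,
    },
)


class ZeroContactResidueError(ValueError):
    """Residue has no atomic contact; its environment similarity is undefined."""


def residue_features(
    rid: ResidueId,
    complex_a: ComplexStructure,
    complex_b: ComplexStructure,
    corr: CorrespondenceMap,
    contact_edges: Mapping[Tuple[ResidueId, ResidueId], float],
    regions: Mapping[ResidueId, str],
    center_distance: Mapping[ResidueId, float],
    seq_id: float,
) -> FeatureVector:
    """Assemble the six-feature vector for one interface residue.

    The environment similarity is the mean BLOSUM62 score over all
    residues (both chains) in atomic contact with ``rid`` in the
    reference complex; contacts of residues without a mapped equivalent
    contribute nothing.
    """
    if rid not in corr.mapping:
        raise KeyError(f"residue {rid} has no structural equivalent")
    aa = complex_a.residue(rid).one_letter
    aa_b = complex_b.residue(corr.mapping[rid]).one_letter
    sim_res = blosum62_score(aa, aa_b)

    partners: List[ResidueId] = []
    n_contacts = 0
    for (ra, rb), w in contact_edges.items():
        if ra == rid:
            partners.append(rb)
            n_contacts += int(w)
        elif rb == rid:
            partners.append(ra)
            n_contacts += int(w)
    env_scores = [
        blosum62_score(
            complex_a.residue(p).one_letter,
            complex_b.residue(corr.mapping[p]).one_letter,
        )
        for p in partners
        if p in corr.mapping
    ]
    if not env_scores:
        raise ZeroContactResidueError(
            f"residue {rid} has no mapped contacting residue; sim_env undefined"
        )
    return FeatureVector(
        rid=rid,
        sim_res=sim_res,
        sim_env=float(np.mean(env_scores)),
        seq_id=seq_id,
        region=regions.get(rid, "rim"),
        n_contacts=n_contacts,
        dist_center=min(1.0, center_distance.get(rid, 0.0)),
    )


def feature_table(vectors: Iterable[FeatureVector]) -> pd.DataFrame:
    rows = []
    for v in vectors:
        row = {"residue": str(v.rid), "region": v.region}
        row.update(v.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def logistic_score(features: Mapping[str, float], model: LogisticModel) -> float:
    """Probability from the logistic equation; raises on a missing feature."""
    return model.predict(features)


def fit_logistic(
    x: pd.DataFrame,
    y: Sequence[int],
    feature_names: Sequence[str] = FEATURE_NAMES,
    tol: float = 1e-8,
) -> LogisticModel:
    """Maximum-likelihood logistic fit (IRLS via statsmodels).

    Returns named coefficients, their standard errors and the model
    deviance (−2 log-likelihood).  Perfect separation raises with a
    diverging-coefficient report.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("need at least one positive and one negative label")
    design = sm.add_constant(x[list(feature_names)].to_numpy(dtype=float))
    try:
        res = sm.Logit(y, design).fit(disp=0, tol=tol, maxiter=200)
    except PerfectSeparationError as exc:
        raise ValueError(f"perfect separation: coefficients diverge ({exc})") from exc
    if not res.mle_retvals.get("converged", True):
        raise ValueError("logistic fit did not converge (possible separation)")
    params = res.params
    bse = res.bse
    return LogisticModel(
        intercept=float(params[0]),
        coefficients={n: float(params[i + 1]) for i, n in enumerate(feature_names)},
        standard_errors={
            "intercept": float(bse[0]),
            **{n: float(bse[i + 1]) for i, n in enumerate(feature_names)},
        },
        deviance=float(-2.0 * res.llf),
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> Tuple[float, np.ndarray]:
    """AUC as the Mann-Whitney probability estimate, ties at half credit.

    Also returns the ROC curve points (false-positive rate,
    true-positive rate) obtained by sweeping the score threshold from
    best to worst.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="mergesort")
    tp = np.cumsum(labels[order] == 1)
    fp = np.cumsum(labels[order] == 0)
    curve = np.column_stack([fp / n_neg, tp / n_pos])
    curve = np.vstack([[0.0, 0.0], curve])
    return float(auc), curve


def deviance_ranking(
    x: pd.DataFrame,
    y: Sequence[int],
    feature_names: Sequence[str] = FEATURE_NAMES,
) -> List[Tuple[str, float]]:
    """Drop-one deviance analysis: refit without each feature in turn.

    Returns (feature, deviance increase) sorted by decreasing increase;
    the first entry is the most important feature (rank 1).
    """
    full = fit_logistic(x, y, feature_names)
    assert full.deviance is not None
    out: List[Tuple[str, float]] = []
    for name in feature_names:
        reduced = [n for n in feature_names if n != name]
        sub = fit_logistic(x, y, reduced)
        out.append((name, float(sub.deviance - full.deviance)))
    out.sort(key=lambda t: -t[1])
    return out


def split_train_test(
    couples: Sequence,
    train_fraction: float = 1.0 / 3.0,
    repeats: int = 10,
    seed: int = 0,
) -> List[Tuple[List, List]]:
    """Random couple-level train/test partitions, repeated.

    All residues of a couple stay on the same side of the split.
    Reproducible for a fixed seed.
    """
    couples = list(couples)
    if len(couples) < 3:
        raise ValueError("need at least 3 couples to split")
    n_train = max(1, int(round(len(couples) * train_fraction)))
    rng = np.random.default_rng(seed)
    splits: List[Tuple[List, List]] = []
    for _ in range(repeats):
        perm = rng.permutation(len(couples))
        train = [couples[i] for i in sorted(perm[:n_train])]
        test = [couples[i] for i in sorted(perm[n_train:])]
        splits.append((train, test))
    return splits
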