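"""Pocket-centric and residue-centric scoring of binding-site predictions.

Pocket-centric: DCA is the minimum distance from a predicted pocket's
centre to any ligand atom; DCC is the distance from the centre to the
ligand centroid.  A site counts as a hit when a pocket lands within the
threshold (4 Å by default), and success rates are hits over all annotated
sites.  Residue-centric: residues are binding when any of their atoms lies
within the labelling radius of a ligand atom; predictions are scored by a
per-structure confusion table and macro-averaged precision, recall, F1 and
MCC (per-structure terms with an undefined denominator contribute zero).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .postprocess import Pocket
from .structures import LigandCoordinates, ProteinStructure

__all__ = [
    "EvalConfig",
    "ResidueConfusion",
    "EvaluationReport",
    "dca",
    "dcc",
    "success_rates",
    "residue_confusion",
    "macro_metrics",
    "evaluate_predictions",
]


@dataclass
class EvalConfig:
    dca_threshold: float = 4.0
    dcc_threshold: float = 4.0
    matching_rule: str = "any_pocket"  # or "nearest_exclusive"
    label_radius: float = 5.0

    def __post_init__(self) -> None:
        if self.dca_threshold <= 0 or self.dcc_threshold <= 0:
            raise ValueError("distance thresholds must be positive")
        if self.matching_rule not in ("any_pocket", "nearest_exclusive"):
            raise ValueError(f"unknown matching rule {self.matching_rule!r}")


@dataclass(frozen=True)
class ResidueConfusion:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def dca(pocket_center, ligand: LigandCoordinates) -> float:
    """Minimum distance (Å) from the pocket centre to any ligand atom."""
    center = np.asarray(pocket_center, dtype=float).reshape(3)
    return float(np.min(np.linalg.norm(ligand.atom_coords - center, axis=1)))


def dcc(pocket_center, ligand: LigandCoordinates) -> float:
    """Distance (Å) from the pocket centre to the ligand centroid."""
    center = np.asarray(pocket_center, dtype=float).reshape(3)
    return float(np.linalg.norm(ligand.center - center))


def _hits_any_pocket(
    pockets: Sequence[Pocket], sites: Sequence[LigandCoordinates], metric, threshold
) -> int:
    hits = 0
    for site in sites:
        if any(metric(p.center, site) <= threshold for p in pockets):
            hits += 1
    return hits


def _hits_nearest_exclusive(
    pockets: Sequence[Pocket], sites: Sequence[LigandCoordinates], metric, threshold
) -> int:
    pairs = [
        (metric(p.center, s), pi, si)
        for pi, p in enumerate(pockets)
        for si, s in enumerate(sites)
    ]
    pairs.sort()
    used_p: set[int] = set()
    used_s: set[int] = set()
    hits = 0
    for d, pi, si in pairs:
        if d > threshold:
            break
        if pi in used_p or si in used_s:
            continue
        used_p.add(pi)
        used_s.add(si)
        hits += 1
    return hits


def success_rates(
    pockets_per_structure: Sequence[Sequence[Pocket]],
    sites_per_structure: Sequence[Sequence[LigandCoordinates]],
    config: Optional[EvalConfig] = None,
) -> tuple[float, float]:
    """(DCA rate %, DCC rate %) over all annotated sites.

    Every annotated site contributes to the denominator even when the model
    predicted nothing for its structure.
    """
    config = config or EvalConfig()
    if len(pockets_per_structure) != len(sites_per_structure):
        raise ValueError("pockets and sites must align per structure")
    total = sum(len(s) for s in sites_per_structure)
    if total == 0:
        raise ValueError("no annotated sites to score")
    hit_fn = (
        _hits_any_pocket if config.matching_rule == "any_pocket" else _hits_nearest_exclusive
    )
    dca_hits = 0
    dcc_hits = 0
    for pockets, sites in zip(pockets_per_structure, sites_per_structure):
        dca_hits += hit_fn(pockets, sites, dca, config.dca_threshold)
        dcc_hits += hit_fn(pockets, sites, dcc, config.dcc_threshold)
    return 100.0 * dca_hits / total, 100.0 * dcc_hits / total


def residue_confusion(
    pockets: Sequence[Pocket],
    structure: ProteinStructure,
    ligands: Sequence[LigandCoordinates],
    label_radius: float = 5.0,
) -> ResidueConfusion:
    """Per-structure TP/FP/TN/FN over residues.

    Actual binding residue: ≥1 atom within ``label_radius`` of a ligand atom.
    Predicted binding residue: ≥1 atom inside any predicted pocket.
    """
    residues = structure.residues()
    if not residues:
        raise ValueError("structure has no residues")
    lig_coords = (
        np.vstack([l.atom_coords for l in ligands]) if ligands else np.zeros((0, 3))
    )
    actual: set[tuple] = set()
    if len(lig_coords):
        tree = cKDTree(lig_coords)
        dmin, _ = tree.query(structure.coords_array(), k=1)
        for atom, d in zip(structure.atoms, dmin):
            if d <= label_radius:
                actual.add(atom.residue_key)
    predicted: set[tuple] = set()
    for p in pockets:
        predicted.update(p.member_residues)
    tp = fp = tn = fn = 0
    for key in residues:
        a, pr = key in actual, key in predicted
        tp += a and pr
        fp += (not a) and pr
        fn += a and (not pr)
        tn += (not a) and (not pr)
    return ResidueConfusion(tp=tp, fp=fp, tn=tn, fn=fn)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def macro_metrics(
    confusions: Sequence[ResidueConfusion],
) -> tuple[float, float, float, float]:
    """Macro-averaged (precision, recall, F1, MCC) as fractions in [0, 1].

    Each metric is computed per structure and averaged over structures;
    per-structure terms with a zero denominator contribute 0.
    """
    if not confusions:
        raise ValueError("no confusion tables to average")
    ps, rs, f1s, mccs = [], [], [], []
    for c in confusions:
        p = _safe_div(c.tp, c.tp + c.fp)
        r = _safe_div(c.tp, c.tp + c.fn)
        ps.append(p)
        rs.append(r)
        f1s.append(_safe_div(2 * p * r, p + r))
        den = np.sqrt(
            float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
        )
        mccs.append((c.tp * c.tn - c.fp * c.fn) / den if den > 0 else 0.0)
    return (
        float(np.mean(ps)),
        float(np.mean(rs)),
        float(np.mean(f1s)),
        float(np.mean(mccs)),
    )


@dataclass
class EvaluationReport:
    """Aggregate percentages plus the per-structure table."""

    success_rate_dca: float
    success_rate_dcc: float
    precision: float
    recall: float
    f1: float
    mcc: float
    per_structure: pd.DataFrame

    def to_json(self) -> str:
        return json.dumps(
            {
                "success_rate_dca": self.success_rate_dca,
                "success_rate_dcc": self.success_rate_dcc,
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "mcc": self.mcc,
                "n_structures": int(len(self.per_structure)),
            },
            indent=2,
        )

    def to_csv(self) -> str:
        table = self.per_structure.copy()
        aggregate = {
            "structure_id": "AGGREGATE",
            "dca_rate": self.success_rate_dca,
            "dcc_rate": self.success_rate_dcc,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "mcc": self.mcc,
        }
        table = pd.concat([table, pd.DataFrame([aggregate])], ignore_index=True)
        return table.to_csv(index=False)


def evaluate_predictions(
    structures: Sequence[ProteinStructure],
    pockets_per_structure: Sequence[Sequence[Pocket]],
    sites_per_structure: Sequence[Sequence[LigandCoordinates]],
    config: Optional[EvalConfig] = None,
) -> EvaluationReport:
    """Full report: success rates plus macro residue metrics, per structure."""
    config = config or EvalConfig()
    dca_rate, dcc_rate = success_rates(pockets_per_structure, sites_per_structure, config)
    confusions = []
    rows = []
    for structure, pockets, sites in zip(
        structures, pockets_per_structure, sites_per_structure
    ):
        c = residue_confusion(pockets, structure, sites, config.label_radius)
        confusions.append(c)
        p, r, f1, mcc = macro_metrics([c])
        best_dca = min(
            (dca(pk.center, s) for pk in pockets for s in sites), default=np.nan
        )
        best_dcc = min(
            (dcc(pk.center, s) for pk in pockets for s in sites), default=np.nan
        )
        rows.append(
            {
                "structure_id": structure.structure_id,
                "n_pockets": len(pockets),
                "n_sites": len(sites),
                "best_dca": best_dca,
                "best_dcc": best_dcc,
                "tp": c.tp,
                "fp": c.fp,
                "tn": c.tn,
                "fn": c.fn,
                "precision": 100.0 * p,
                "recall": 100.0 * r,
                "f1": 100.0 * f1,
                "mcc": 100.0 * mcc,
            }
        )
    precision, recall, f1, mcc = macro_metrics(confusions)
    return EvaluationReport(
        success_rate_dca=dca_rate,
        success_rate_dcc=dcc_rate,
        precision=100.0 * precision,
        recall=100.0 * recall,
        f1=100.0 * f1,
        mcc=100.0 * mcc,
        per_structure=pd.DataFrame(rows),
    )
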