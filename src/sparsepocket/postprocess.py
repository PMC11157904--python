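"""Pocket extraction: density clustering of predicted binding atoms.

Predicted binding atoms (probability ≥ threshold, mapped back from tensor
rows to source atoms) are grouped with DBSCAN — a minimum of five atoms
within 5.5 Å by default — into discrete pockets.  Neighbour queries run on
a k-d tree with a configurable leaf size.  The implementation follows the
classic DBSCAN iteration in ascending point order, which pins down the one
ambiguity of the algorithm (border points reachable from several clusters
join the first cluster discovered) so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures import ProteinStructure
from .tensorize import SparseProteinTensor

__all__ = ["PostprocessConfig", "Pocket", "density_cluster", "extract_pockets", "pockets_to_csv"]

NOISE = -1


@dataclass
class PostprocessConfig:
    probability_threshold: float = 0.5
    eps: float = 5.5
    min_samples: int = 5
    tree_leaf_size: int = 100

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_samples < 1:
            raise ValueError("min_samples must be at least 1")


@dataclass
class Pocket:
    pocket_id: int
    member_atoms: list[int]  # indices into structure.atoms, ascending
    member_residues: list[tuple]  # (chain_id, res_seq, i_code, res_name)
    center: np.ndarray  # (3,) Å — arithmetic mean of member atom coordinates

    @property
    def n_atoms(self) -> int:
        return len(self.member_atoms)


def density_cluster(
    points: np.ndarray, eps: float = 5.5, min_samples: int = 5, leaf_size: int = 100
) -> np.ndarray:
    """DBSCAN labels per point (−1 = noise), deterministic ascending order.

    A point is a core point when at least ``min_samples`` points (itself
    included) lie within ``eps``; clusters are the connected components of
    core points plus any border points they reach.  Neighbour queries are
    served by a k-d tree with the configured leaf size.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    n = len(points)
    if n == 0:
        return np.zeros(0, dtype=int)
    if not np.all(np.isfinite(points)):
        raise ValueError("non-finite coordinates in clustering input")
    tree = cKDTree(points, leafsize=leaf_size)
    neighborhoods = tree.query_ball_point(points, r=eps)
    is_core = np.array([len(nb) >= min_samples for nb in neighborhoods])
    labels = np.full(n, NOISE, dtype=int)
    cluster = 0
    for i in range(n):
        if labels[i] != NOISE or not is_core[i]:
            continue
        labels[i] = cluster
        frontier = [i]
        while frontier:
            j = frontier.pop()
            for k in sorted(neighborhoods[j]):
                if labels[k] == NOISE:
                    labels[k] = cluster
                    if is_core[k]:
                        frontier.append(k)
        cluster += 1
    return labels


def extract_pockets(
    tensor: SparseProteinTensor,
    probabilities: np.ndarray,
    structure: ProteinStructure,
    config: Optional[PostprocessConfig] = None,
) -> list[Pocket]:
    """Threshold, map tensor rows to source atoms, cluster into pockets.

    Clustering runs on the original Å atom coordinates (not the quantized
    grid).  Pockets are ordered by member count descending, ties broken by
    the smallest member atom index; noise points are dropped.
    """
    config = config or PostprocessConfig()
    probabilities = np.asarray(probabilities, dtype=float).reshape(-1)
    if len(probabilities) != tensor.n_rows:
        raise ValueError("probabilities must be row-aligned with the tensor")
    atom_idx: list[int] = []
    for row in np.flatnonzero(probabilities >= config.probability_threshold):
        atom_idx.extend(int(i) for i in tensor.atom_map[row])
    if not atom_idx:
        return []
    atom_idx = sorted(set(atom_idx))
    xyz = structure.coords_array()[atom_idx]
    labels = density_cluster(xyz, config.eps, config.min_samples, config.tree_leaf_size)
    pockets = []
    for lab in sorted(set(labels) - {NOISE}):
        members = [atom_idx[i] for i in np.flatnonzero(labels == lab)]
        residues: dict[tuple, None] = {}
        for m in members:
            residues.setdefault(structure.atoms[m].residue_key, None)
        pockets.append(
            Pocket(
                pocket_id=0,
                member_atoms=members,
                member_residues=list(residues),
                center=structure.coords_array()[members].mean(axis=0),
            )
        )
    pockets.sort(key=lambda p: (-p.n_atoms, p.member_atoms[0]))
    for i, p in enumerate(pockets):
        p.pocket_id = i + 1
    return pockets


def pockets_to_csv(pockets: Sequence[Pocket]) -> pd.DataFrame:
    """Tabular pocket summary (id, size, centre, residue list)."""
    rows = []
    for p in pockets:
        rows.append(
            {
                "pocket_id": p.pocket_id,
                "n_atoms": p.n_atoms,
                "center_x": p.center[0],
                "center_y": p.center[1],
                "center_z": p.center[2],
                "residues": ";".join(
                    f"{c}:{s}{i}:{r}" for c, s, i, r in p.member_residues
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["pocket_id", "n_atoms", "center_x", "center_y", "center_z", "residues"],
    )
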