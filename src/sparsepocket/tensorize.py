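"""Quantization of structures into sparse coordinate/feature/label tensors.

A structure becomes a sparse tensor with an N×5 integer coordinate matrix C
(columns x, y, z, t, b: quantized spatial grid coordinates, structure index,
batch index), an N×9 feature matrix F and an N×1 binary label matrix L.
Atoms falling in the same grid cell are merged: features are averaged,
labels take the maximum, and the merge is recorded in ``atom_map`` so
predictions can be projected back onto source atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .features import N_FEATURES, features_matrix
from .structures import LigandCoordinates, ProteinStructure

__all__ = [
    "TensorizeConfig",
    "SparseProteinTensor",
    "label_binding_atoms",
    "quantize",
    "batch",
    "tensorize_structure",
    "save_tensor",
    "load_tensor",
]


@dataclass
class TensorizeConfig:
    """Grid resolution (Å per unit), labelling radius (Å) and perception backend."""

    resolution: float = 1.0
    label_radius: float = 5.0
    perception_backend: str = "rules"

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.label_radius <= 0:
            raise ValueError("label_radius must be positive")


@dataclass
class SparseProteinTensor:
    """The sparse C/F/L representation of one or more structures."""

    coords: np.ndarray  # (N, 5) int32: x, y, z, t, b
    feats: np.ndarray  # (N, 9) float
    labels: np.ndarray  # (N,) uint8
    origin: np.ndarray  # (3,) Å offset of the grid corner
    resolution: float
    atom_map: list[np.ndarray] = field(default_factory=list)
    structure_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int32).reshape(-1, 5)
        self.feats = np.asarray(self.feats, dtype=float).reshape(-1, N_FEATURES)
        self.labels = np.asarray(self.labels, dtype=np.uint8).reshape(-1)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if not (len(self.coords) == len(self.feats) == len(self.labels)):
            raise ValueError("coords, feats and labels must be row-aligned")

    @property
    def n_rows(self) -> int:
        return len(self.coords)

    def row_centers(self) -> np.ndarray:
        """(N, 3) Å coordinates of the grid-cell corners (origin-anchored)."""
        return self.coords[:, :3].astype(float) * self.resolution + self.origin


def label_binding_atoms(
    structure: ProteinStructure,
    ligand: LigandCoordinates | Sequence[LigandCoordinates],
    radius: float = 5.0,
) -> np.ndarray:
    """Binary vector: 1 iff an atom lies within ``radius`` Å of any ligand atom.

    The boundary is inclusive (an atom at exactly ``radius`` is positive).
    Distances are served by a k-d tree over the ligand atoms.
    """
    ligands = [ligand] if isinstance(ligand, LigandCoordinates) else list(ligand)
    if not ligands:
        raise ValueError("at least one ligand is required for labelling")
    lig_coords = np.vstack([l.atom_coords for l in ligands])
    atom_xyz = structure.coords_array()
    if atom_xyz.shape[0] == 0:
        return np.zeros(0, dtype=np.uint8)
    tree = cKDTree(lig_coords)
    dmin, _ = tree.query(atom_xyz, k=1)
    return (dmin <= radius).astype(np.uint8)


def quantize(
    structure: ProteinStructure,
    features,
    labels: np.ndarray,
    config: Optional[TensorizeConfig] = None,
    t: int = 0,
    b: int = 0,
) -> SparseProteinTensor:
    """Quantize a featurized, labelled structure onto the integer grid.

    Grid coordinate = floor((xyz − origin)/resolution) with the origin at the
    per-structure minimum corner.  Duplicate cells are merged: feature mean,
    label max; ``atom_map`` lists the source atom indices of every row.
    """
    config = config or TensorizeConfig()
    if not isinstance(features, np.ndarray):
        features = features_matrix(features)
    labels = np.asarray(labels).reshape(-1)
    xyz = structure.coords_array()
    if len(features) != len(xyz) or len(labels) != len(xyz):
        raise ValueError("features/labels must be aligned with structure atoms")
    if len(xyz) == 0:
        raise ValueError("cannot quantize an empty structure")
    origin = xyz.min(axis=0)
    grid = np.floor((xyz - origin) / config.resolution).astype(np.int64)
    cells, inverse = np.unique(grid, axis=0, return_inverse=True)
    inverse = inverse.reshape(-1)
    n_cells = len(cells)
    counts = np.bincount(inverse, minlength=n_cells).astype(float)
    feats = np.zeros((n_cells, features.shape[1]))
    for ch in range(features.shape[1]):
        feats[:, ch] = np.bincount(inverse, weights=features[:, ch], minlength=n_cells)
    feats /= counts[:, None]
    merged_labels = np.zeros(n_cells, dtype=np.uint8)
    np.maximum.at(merged_labels, inverse, labels.astype(np.uint8))
    atom_map = [np.flatnonzero(inverse == i) for i in range(n_cells)]
    coords = np.concatenate(
        [
            cells,
            np.full((n_cells, 1), t, dtype=np.int64),
            np.full((n_cells, 1), b, dtype=np.int64),
        ],
        axis=1,
    )
    return SparseProteinTensor(
        coords=coords,
        feats=feats,
        labels=merged_labels,
        origin=origin,
        resolution=config.resolution,
        atom_map=atom_map,
        structure_id=structure.structure_id,
    )


def batch(tensors: Sequence[SparseProteinTensor]) -> SparseProteinTensor:
    """Row-concatenate tensors; ``b`` is assigned by list position, ``t`` kept."""
    if not tensors:
        raise ValueError("cannot batch an empty tensor list")
    resolutions = {float(tt.resolution) for tt in tensors}
    if len(resolutions) > 1:
        raise ValueError(f"mixed resolutions in batch: {sorted(resolutions)}")
    parts = []
    for b_idx, tensor in enumerate(tensors):
        coords = tensor.coords.copy()
        coords[:, 4] = b_idx
        parts.append(coords)
    coords = np.vstack(parts)
    feats = np.vstack([tt.feats for tt in tensors])
    labels = np.concatenate([tt.labels for tt in tensors])
    atom_map = [m for tt in tensors for m in tt.atom_map]
    return SparseProteinTensor(
        coords=coords,
        feats=feats,
        labels=labels,
        origin=tensors[0].origin,
        resolution=tensors[0].resolution,
        atom_map=atom_map,
        structure_id="+".join(tt.structure_id for tt in tensors),
    )


def tensorize_structure(
    structure: ProteinStructure,
    ligands,
    config: Optional[TensorizeConfig] = None,
    t: int = 0,
    b: int = 0,
) -> SparseProteinTensor:
    """parse → featurize → label → quantize convenience wrapper."""
    from .features import featurize_atoms

    config = config or TensorizeConfig()
    feats = featurize_atoms(structure, backend=config.perception_backend)
    labels = label_binding_atoms(structure, ligands, radius=config.label_radius)
    return quantize(structure, feats, labels, config, t=t, b=b)


def save_tensor(tensor: SparseProteinTensor, path) -> None:
    """Serialize as a compressed archive (int32 coords, float32 feats, uint8 labels)."""
    lengths = np.array([len(m) for m in tensor.atom_map], dtype=np.int32)
    flat = (
        np.concatenate(tensor.atom_map)
        if tensor.atom_map
        else np.zeros(0, dtype=np.int64)
    )
    np.savez_compressed(
        path,
        coords=tensor.coords.astype(np.int32),
        feats=tensor.feats.astype(np.float32),
        labels=tensor.labels.astype(np.uint8),
        origin=tensor.origin,
        resolution=np.array([tensor.resolution]),
        atom_map_lengths=lengths,
        atom_map_flat=flat.astype(np.int64),
        structure_id=np.array([tensor.structure_id]),
    )


def load_tensor(path) -> SparseProteinTensor:
    with np.load(path, allow_pickle=False) as data:
        lengths = data["atom_map_lengths"]
        flat = data["atom_map_flat"]
        atom_map = []
        pos = 0
        for ln in lengths:
            atom_map.append(flat[pos : pos + ln].copy())
            pos += ln
        return SparseProteinTensor(
            coords=data["coords"],
            feats=data["feats"].astype(float),
            labels=data["labels"],
            origin=data["origin"],
            resolution=float(data["resolution"][0]),
            atom_map=atom_map,
            structure_id=str(data["structure_id"][0]),
        )
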