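"""Nine-channel atomic featurization.

Each atom is described by nine channels, in this fixed order:

    0 hybridization   (1=sp, 2=sp2, 3=sp3, 0=unknown)
    1 heavy_degree    (number of bonded heavy atoms)
    2 hetero_degree   (number of bonded N/O/S/P atoms)
    3 hydrophobic     (carbon with no bonded heteroatom)
    4 aromatic
    5 partial_charge  (elementary charge)
    6 acceptor
    7 donor
    8 ring

Two perception backends exist.  The default, :class:`RuleBasedPerception`,
derives every channel from lookup tables built out of the standard amino-acid
bond topology (mid-chain convention: backbone N gains one carbon neighbour
from the preceding residue, backbone C gains one nitrogen neighbour from the
following one).  It needs no chemistry toolkit and is fully deterministic.
:class:`RDKitPerception` delegates perception (hybridization, aromaticity,
Gasteiger charges, pharmacophore donors/acceptors) to RDKit when it is
installed; it is also the independent oracle in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "N_FEATURES",
    "AtomFeatures",
    "RuleBasedPerception",
    "RDKitPerception",
    "get_backend",
    "featurize_atoms",
]

FEATURE_NAMES = (
    "hybridization",
    "heavy_degree",
    "hetero_degree",
    "hydrophobic",
    "aromatic",
    "partial_charge",
    "acceptor",
    "donor",
    "ring",
)
N_FEATURES = len(FEATURE_NAMES)

HETERO_ELEMENTS = frozenset({"N", "O", "S", "P"})


@dataclass(frozen=True)
class AtomFeatures:
    hybridization: int
    heavy_degree: int
    hetero_degree: int
    hydrophobic: int
    aromatic: int
    partial_charge: float
    acceptor: int
    donor: int
    ring: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.hybridization,
                self.heavy_degree,
                self.hetero_degree,
                self.hydrophobic,
                self.aromatic,
                self.partial_charge,
                self.acceptor,
                self.donor,
                self.ring,
            ],
            dtype=float,
        )


# ---------------------------------------------------------------------------
# amino-acid topology templates
# ---------------------------------------------------------------------------

# side-chain bonds per residue; the backbone (N-CA, CA-C, C-O, CA-CB) is shared
_SIDE_CHAIN_BONDS: dict[str, tuple[tuple[str, str], ...]] = {
    "ALA": (),
    "ARG": (("CB", "CG"), ("CG", "CD"), ("CD", "NE"), ("NE", "CZ"),
            ("CZ", "NH1"), ("CZ", "NH2")),
    "ASN": (("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")),
    "ASP": (("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")),
    "CYS": (("CB", "SG"),),
    "GLN": (("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")),
    "GLU": (("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")),
    "GLY": (),
    "HIS": (("CB", "CG"), ("CG", "ND1"), ("ND1", "CE1"), ("CE1", "NE2"),
            ("NE2", "CD2"), ("CD2", "CG")),
    "ILE": (("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")),
    "LEU": (("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")),
    "LYS": (("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")),
    "MET": (("CB", "CG"), ("CG", "SD"), ("SD", "CE")),
    "PHE": (("CB", "CG"), ("CG", "CD1"), ("CD1", "CE1"), ("CE1", "CZ"),
            ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG")),
    "PRO": (("CB", "CG"), ("CG", "CD"), ("CD", "N")),
    "SER": (("CB", "OG"),),
    "THR": (("CB", "OG1"), ("CB", "CG2")),
    "TRP": (("CB", "CG"), ("CG", "CD1"), ("CD1", "NE1"), ("NE1", "CE2"),
            ("CE2", "CD2"), ("CD2", "CG"), ("CE2", "CZ2"), ("CZ2", "CH2"),
            ("CH2", "CZ3"), ("CZ3", "CE3"), ("CE3", "CD2")),
    "TYR": (("CB", "CG"), ("CG", "CD1"), ("CD1", "CE1"), ("CE1", "CZ"),
            ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG"), ("CZ", "OH")),
    "VAL": (("CB", "CG1"), ("CB", "CG2")),
}

STANDARD_RESIDUES = frozenset(_SIDE_CHAIN_BONDS)

_AROMATIC_ATOMS: dict[str, frozenset[str]] = {
    "PHE": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ2", "CZ3", "CH2"}),
    "HIS": frozenset({"CG", "ND1", "CD2", "CE1", "NE2"}),
}

_RING_ONLY_ATOMS: dict[str, frozenset[str]] = {  # non-aromatic rings
    "PRO": frozenset({"N", "CA", "CB", "CG", "CD"}),
}

# atoms that are sp2 beyond the aromatic sets: amide/carboxylate/guanidinium
_SP2_ATOMS: dict[str, frozenset[str]] = {
    "ARG": frozenset({"NE", "CZ", "NH1", "NH2"}),
    "ASN": frozenset({"CG", "OD1", "ND2"}),
    "ASP": frozenset({"CG", "OD1", "OD2"}),
    "GLN": frozenset({"CD", "OE1", "NE2"}),
    "GLU": frozenset({"CD", "OE1", "OE2"}),
}

_DONORS: dict[str, frozenset[str]] = {
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "ASN": frozenset({"ND2"}),
    "CYS": frozenset({"SG"}),
    "GLN": frozenset({"NE2"}),
    "HIS": frozenset({"NE2"}),
    "LYS": frozenset({"NZ"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TRP": frozenset({"NE1"}),
    "TYR": frozenset({"OH"}),
}

_EXTRA_ACCEPTORS: dict[str, frozenset[str]] = {
    # all oxygens are acceptors (handled by element); HIS ND1 carries the lone pair
    "HIS": frozenset({"ND1"}),
}

# coarse partial charges (elementary charge) by atom class
_BACKBONE_CHARGES = {"N": -0.35, "CA": 0.10, "C": 0.60, "O": -0.55}
_CHARGE_BY_CLASS = {
    "carboxyl_O": -0.60,
    "hydroxyl_O": -0.40,
    "amide_O": -0.55,
    "amide_N": -0.35,
    "basic_N": 0.30,
    "aromatic_N": -0.20,
    "S": -0.15,
    "aromatic_C": 0.00,
    "C": 0.02,
}

_CARBOXYL_O = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
_HYDROXYL_O = {"SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}}
_AMIDE_O = {"ASN": {"OD1"}, "GLN": {"OE1"}}
_BASIC_N = {"LYS": {"NZ"}, "ARG": {"NE", "NH1", "NH2"}}


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return ""


def _build_adjacency(res_name: str) -> dict[str, list[str]]:
    adj: dict[str, list[str]] = {}
    bonds = [("N", "CA"), ("CA", "C"), ("C", "O")]
    side = _SIDE_CHAIN_BONDS.get(res_name, ())
    if res_name != "GLY" and res_name in _SIDE_CHAIN_BONDS:
        bonds.append(("CA", "CB"))
    bonds.extend(side)
    for a, b in bonds:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    return adj


def _charge_for(res_name: str, atom_name: str, element: str, aromatic: bool) -> float:
    if atom_name in _BACKBONE_CHARGES:
        return _BACKBONE_CHARGES[atom_name]
    if element == "O":
        if atom_name in _CARBOXYL_O.get(res_name, ()):
            return _CHARGE_BY_CLASS["carboxyl_O"]
        if atom_name in _HYDROXYL_O.get(res_name, ()):
            return _CHARGE_BY_CLASS["hydroxyl_O"]
        return _CHARGE_BY_CLASS["amide_O"]
    if element == "N":
        if atom_name in _BASIC_N.get(res_name, ()):
            return _CHARGE_BY_CLASS["basic_N"]
        if aromatic:
            return _CHARGE_BY_CLASS["aromatic_N"]
        return _CHARGE_BY_CLASS["amide_N"]
    if element == "S":
        return _CHARGE_BY_CLASS["S"]
    if element == "C":
        return _CHARGE_BY_CLASS["aromatic_C"] if aromatic else _CHARGE_BY_CLASS["C"]
    return 0.0


def _rule_features(res_name: str, atom_name: str, element: str) -> AtomFeatures:
    adj = _build_adjacency(res_name) if res_name in STANDARD_RESIDUES else {}
    neighbors = adj.get(atom_name, [])
    heavy = len(neighbors)
    hetero = sum(1 for n in neighbors if _element_of(n) in HETERO_ELEMENTS)
    # mid-chain convention: the peptide bond adds a neighbour on each side
    if atom_name == "N" and res_name in STANDARD_RESIDUES:
        heavy += 1  # preceding carbonyl carbon
    elif atom_name == "C" and res_name in STANDARD_RESIDUES:
        heavy += 1
        hetero += 1  # following amide nitrogen

    aromatic = atom_name in _AROMATIC_ATOMS.get(res_name, ())
    ring = aromatic or atom_name in _RING_ONLY_ATOMS.get(res_name, ())

    if element == "H":
        hyb = 0
    elif aromatic or atom_name in _SP2_ATOMS.get(res_name, ()):
        hyb = 2
    elif atom_name in ("C", "O", "N") and res_name in STANDARD_RESIDUES:
        hyb = 2  # amide plane: carbonyl C/O and backbone N
    elif element in ("C", "N", "O", "S"):
        hyb = 3
    else:
        hyb = 0

    hydrophobic = int(element == "C" and hetero == 0 and heavy > 0)
    donor = int(
        (atom_name == "N" and res_name in STANDARD_RESIDUES and res_name != "PRO")
        or atom_name in _DONORS.get(res_name, ())
    )
    acceptor = int(
        (element == "O") or atom_name in _EXTRA_ACCEPTORS.get(res_name, ())
    )
    charge = _charge_for(res_name, atom_name, element, aromatic)
    return AtomFeatures(
        hybridization=hyb,
        heavy_degree=heavy,
        hetero_degree=hetero,
        hydrophobic=hydrophobic,
        aromatic=int(aromatic),
        partial_charge=charge,
        acceptor=acceptor,
        donor=donor,
        ring=int(ring),
    )


_ZERO = AtomFeatures(0, 0, 0, 0, 0, 0.0, 0, 0, 0)


class RuleBasedPerception:
    """Deterministic residue/atom-name lookup featurization (no toolkit)."""

    name = "rules"

    def __call__(self, structure) -> list[AtomFeatures]:
        out = []
        unknown: set[tuple[str, str]] = set()
        for atom in structure.atoms:
            res, name, elem = atom.res_name, atom.atom_name, atom.element
            if res in STANDARD_RESIDUES and (
                name in _build_adjacency(res) or name == "OXT"
            ):
                if name == "OXT":  # C-terminal carboxylate oxygen
                    out.append(
                        AtomFeatures(2, 1, 0, 0, 0, -0.60, 1, 0, 0)
                    )
                else:
                    out.append(_rule_features(res, name, elem))
            elif elem in ("C", "N", "O", "S", "P", "H"):
                # unknown residue or atom name: isolated-atom fallback
                unknown.add((res, name))
                out.append(
                    AtomFeatures(
                        hybridization=0,
                        heavy_degree=0,
                        hetero_degree=0,
                        hydrophobic=int(elem == "C"),
                        aromatic=0,
                        partial_charge=0.0,
                        acceptor=int(elem == "O"),
                        donor=0,
                        ring=0,
                    )
                )
            else:
                unknown.add((res, name))
                out.append(_ZERO)
        if unknown:
            logger.warning(
                "rule backend: %d unknown residue/atom combinations, e.g. %s",
                len(unknown),
                sorted(unknown)[:3],
            )
        return out


class RDKitPerception:
    """Chemistry perception through RDKit (optional toolkit backend)."""

    name = "rdkit"

    def __init__(self) -> None:
        try:
            from rdkit import Chem  # noqa: F401
        except ImportError as exc:  # pragma: no cover - environment dependent
            raise ImportError("RDKit is not installed; use the 'rules' backend") from exc

    def __call__(self, structure) -> list[AtomFeatures]:
        import os

        from rdkit import Chem, RDConfig
        from rdkit.Chem import AllChem, ChemicalFeatures

        from .structures import write_structure_pdb

        block = write_structure_pdb(structure)
        mol = Chem.MolFromPDBBlock(block, sanitize=True, removeHs=False)
        if mol is None or mol.GetNumAtoms() != len(structure.atoms):
            logger.warning(
                "RDKit could not perceive %s; falling back to rule backend",
                structure.structure_id,
            )
            return RuleBasedPerception()(structure)
        AllChem.ComputeGasteigerCharges(mol)
        factory = ChemicalFeatures.BuildFeatureFactory(
            os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
        )
        donors: set[int] = set()
        acceptors: set[int] = set()
        for feat in factory.GetFeaturesForMol(mol):
            if feat.GetFamily() == "Donor":
                donors.update(feat.GetAtomIds())
            elif feat.GetFamily() == "Acceptor":
                acceptors.update(feat.GetAtomIds())
        hyb_map = {
            Chem.HybridizationType.SP: 1,
            Chem.HybridizationType.SP2: 2,
            Chem.HybridizationType.SP3: 3,
        }
        out = []
        for i, atom in enumerate(mol.GetAtoms()):
            hetero = sum(
                1 for nb in atom.GetNeighbors() if nb.GetSymbol() in HETERO_ELEMENTS
            )
            charge = atom.GetDoubleProp("_GasteigerCharge")
            if not np.isfinite(charge):
                charge = 0.0
            out.append(
                AtomFeatures(
                    hybridization=hyb_map.get(atom.GetHybridization(), 0),
                    heavy_degree=sum(
                        1 for nb in atom.GetNeighbors() if nb.GetAtomicNum() > 1
                    ),
                    hetero_degree=hetero,
                    hydrophobic=int(atom.GetSymbol() == "C" and hetero == 0
                                    and atom.GetDegree() > 0),
                    aromatic=int(atom.GetIsAromatic()),
                    partial_charge=float(charge),
                    acceptor=int(i in acceptors),
                    donor=int(i in donors),
                    ring=int(atom.IsInRing()),
                )
            )
        return out


_BACKENDS = {"rules": RuleBasedPerception, "rdkit": RDKitPerception}


def get_backend(name: str):
    try:
        return _BACKENDS[name]()
    except KeyError:
        raise ValueError(f"unknown perception backend {name!r}; choose from {sorted(_BACKENDS)}")


def featurize_atoms(structure, backend="rules") -> list[AtomFeatures]:
    """One :class:`AtomFeatures` per retained atom, in atom order."""
    if not structure.atoms:
        raise ValueError(f"structure {structure.structure_id} has no retained atoms")
    if isinstance(backend, str):
        backend = get_backend(backend)
    return backend(structure)


def features_matrix(features: list[AtomFeatures]) -> np.ndarray:
    """(N, 9) float matrix in the fixed channel order."""
    return np.array([f.as_array() for f in features], dtype=float)
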