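"""Parsing, curation and chain grouping of protein structures.

PDB files are read with a purpose-built fixed-column parser following the
wwPDB v3.3 atomic-record layout.  The parser keeps exactly the information
the downstream pipeline needs (coordinates, naming, chain/residue identity,
HETATM flags, per-MODEL atom counts and the REMARK 2 resolution) and applies
a fixed alternate-location policy so that every structure maps to one
well-defined atom list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "ProteinStructure",
    "LigandCoordinates",
    "PDBParseError",
    "CurationDecision",
    "parse_pdb",
    "parse_pdb_file",
    "apply_curation_filters",
    "group_chains",
    "extract_ligand",
    "write_structure_pdb",
    "write_pocket_pdb",
]

#: residue names treated as standard nucleotides when screening for DNA/RNA
NUCLEOTIDE_RES_NAMES = frozenset({"DA", "DT", "DG", "DC", "DU", "A", "U", "G", "C"})

# two-letter element symbols that occur in PDB files; used when the element
# column (77-78) is blank and the element must be inferred from the atom name
_TWO_LETTER_ELEMENTS = frozenset(
    {
        "BR", "CL", "FE", "MG", "MN", "ZN", "CA", "NA", "CU", "NI", "CO",
        "SE", "CD", "HG", "AS", "MO", "AL", "SI", "LI", "BE", "RB", "SR",
    }
)


class PDBParseError(ValueError):
    """Raised for malformed fixed-column records; carries the line number."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class AtomRecord:
    """One parsed ATOM/HETATM record."""

    serial: int
    atom_name: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    i_code: str
    x: float
    y: float
    z: float
    element: str
    is_het: bool

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def residue_key(self) -> tuple:
        """(chain, res_seq, i_code, res_name) identity of the parent residue."""
        return (self.chain_id, self.res_seq, self.i_code, self.res_name)


@dataclass
class ProteinStructure:
    """A parsed structure: retained atoms plus curation metadata.

    ``atoms`` holds the polymer (non-HETATM) atoms used for modelling;
    ``het_atoms`` keeps the HETATM records so ligands can be extracted for
    labelling, but they are never part of the protein tensor.
    """

    structure_id: str
    atoms: list[AtomRecord] = field(default_factory=list)
    het_atoms: list[AtomRecord] = field(default_factory=list)
    model_atom_counts: list[int] = field(default_factory=list)
    resolution: Optional[float] = None

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords_array(self) -> np.ndarray:
        """(N, 3) float array of retained-atom coordinates in Å."""
        if not self.atoms:
            return np.zeros((0, 3), dtype=float)
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def residues(self) -> list[tuple]:
        """Ordered unique residue keys of retained atoms."""
        seen: dict[tuple, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key, None)
        return list(seen)


@dataclass
class LigandCoordinates:
    """Ligand atom positions used for labelling and evaluation."""

    ligand_id: str
    atom_coords: np.ndarray  # (M, 3) Å

    def __post_init__(self) -> None:
        self.atom_coords = np.asarray(self.atom_coords, dtype=float).reshape(-1, 3)
        if self.atom_coords.shape[0] == 0:
            raise ValueError(f"ligand {self.ligand_id!r} has no atoms")
        if not np.all(np.isfinite(self.atom_coords)):
            raise ValueError(f"ligand {self.ligand_id!r} has non-finite coordinates")

    @property
    def center(self) -> np.ndarray:
        return self.atom_coords.mean(axis=0)


def _infer_element(atom_name_field: str) -> str:
    """Infer the element from columns 13-16 when column 77-78 is blank.

    Column 13 is only occupied for two-letter elements or long names, so a
    leading blank or digit means the element is the single letter in column 14.
    """
    name = atom_name_field
    two = name[:2].strip().upper()
    if len(two) == 2 and two in _TWO_LETTER_ELEMENTS:
        return two.capitalize()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    if len(line) < 54:
        raise PDBParseError("ATOM/HETATM record shorter than coordinate fields", lineno)
    try:
        serial = int(line[6:11])
    except ValueError:
        # per wwPDB, serials can overflow; fall back to a hash-free sentinel
        serial_field = line[6:11].strip()
        if not serial_field:
            raise PDBParseError("blank atom serial", lineno)
        serial = -1
    atom_name = line[12:16].strip()
    alt_loc = line[16].strip()
    res_name = line[17:20].strip()
    chain_id = line[21].strip()
    i_code = line[26].strip()
    try:
        res_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"malformed numeric field ({exc})", lineno)
    if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
        raise PDBParseError("non-finite coordinates", lineno)
    element = line[76:78].strip().capitalize() if len(line) >= 78 else ""
    if not element:
        element = _infer_element(line[12:16])
    if not element:
        raise PDBParseError("element could not be inferred from atom name", lineno)
    return AtomRecord(
        serial=serial,
        atom_name=atom_name,
        alt_loc=alt_loc,
        res_name=res_name,
        chain_id=chain_id,
        res_seq=res_seq,
        i_code=i_code,
        x=x,
        y=y,
        z=z,
        element=element,
        is_het=line.startswith("HETATM"),
    )


def _parse_remark2_resolution(line: str) -> Optional[float]:
    # "REMARK   2 RESOLUTION.    1.74 ANGSTROMS."
    if "RESOLUTION" not in line:
        return None
    tokens = line.split()
    for i, tok in enumerate(tokens):
        if tok.startswith("RESOLUTION"):
            for cand in tokens[i + 1 :]:
                try:
                    return float(cand)
                except ValueError:
                    continue
    return None


def parse_pdb(text: str, structure_id: str = "structure") -> ProteinStructure:
    """Parse PDB-format text into a :class:`ProteinStructure`.

    Only the first MODEL's atoms are retained (atom counts of every MODEL are
    recorded for curation), and only blank or ``'A'`` alternate locations are
    kept.  ATOM records become retained atoms; HETATM records are stored
    separately for ligand extraction.
    """
    if not text.strip():
        raise PDBParseError("empty PDB input")
    structure = ProteinStructure(structure_id=structure_id)
    in_model = 0  # current MODEL index (0 = implicit single model)
    model_counts: list[int] = []
    current_count = 0
    saw_model_records = False
    saw_atoms = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec in ("ATOM  ", "HETATM"):
            atom = _parse_atom_line(line, lineno)
            saw_atoms = True
            current_count += 1
            if saw_model_records and in_model != 1:
                continue  # only first MODEL retained
            if atom.alt_loc not in ("", "A"):
                continue
            if atom.is_het:
                structure.het_atoms.append(atom)
            else:
                structure.atoms.append(atom)
        elif rec == "MODEL ":
            saw_model_records = True
            in_model += 1
            current_count = 0
        elif rec == "ENDMDL":
            model_counts.append(current_count)
            current_count = 0
        elif line.startswith("REMARK   2"):
            res = _parse_remark2_resolution(line)
            if res is not None:
                structure.resolution = res
    if not saw_atoms:
        raise PDBParseError("no ATOM/HETATM records found")
    if saw_model_records:
        structure.model_atom_counts = model_counts if model_counts else [current_count]
    else:
        structure.model_atom_counts = [current_count]
    return structure


def parse_pdb_file(path, structure_id: Optional[str] = None) -> ProteinStructure:
    import os

    if structure_id is None:
        structure_id = os.path.splitext(os.path.basename(str(path)))[0]
    with open(path) as fh:
        return parse_pdb(fh.read(), structure_id=structure_id)


@dataclass(frozen=True)
class CurationDecision:
    structure_id: str
    accept: bool
    reason: str  # "ok" or the first triggered rejection reason

    def as_tsv(self) -> str:
        verdict = "accept" if self.accept else "reject"
        return f"{self.structure_id}\t{verdict}\t{self.reason}"


def apply_curation_filters(
    structure: ProteinStructure, max_resolution: float = 2.0
) -> CurationDecision:
    """Accept/reject a structure for training-set curation.

    Rejection criteria, checked in fixed order (the first hit is reported):
    resolution strictly above ``max_resolution`` Å; MODEL blocks with
    differing atom counts; any retained residue named as a standard
    nucleotide (DNA/RNA).  A missing resolution passes that criterion with a
    logged warning — the filter targets database curation, not user models.
    """
    if structure.resolution is None:
        logger.warning(
            "structure %s has no REMARK 2 resolution; resolution filter skipped",
            structure.structure_id,
        )
    elif structure.resolution > max_resolution:
        return CurationDecision(structure.structure_id, False, "resolution")
    if len(set(structure.model_atom_counts)) > 1:
        return CurationDecision(structure.structure_id, False, "model mismatch")
    for atom in structure.atoms:
        if atom.res_name in NUCLEOTIDE_RES_NAMES:
            return CurationDecision(structure.structure_id, False, "nucleic acid")
    return CurationDecision(structure.structure_id, True, "ok")


def group_chains(
    structure: ProteinStructure,
    mode: str = "single_complex",
    chains: Optional[Sequence[str]] = None,
) -> list[ProteinStructure]:
    """Split a structure into prediction units.

    ``single_complex`` keeps all retained atoms in one unit; ``per_chain``
    yields one unit per chain; ``chain_subset`` yields a single unit holding
    exactly the named chains (original atom order preserved).  HETATM records
    follow their chain.
    """
    if mode == "single_complex":
        return [structure]
    if mode == "per_chain":
        units = []
        for cid in structure.chain_ids:
            units.append(
                ProteinStructure(
                    structure_id=f"{structure.structure_id}_{cid}",
                    atoms=[a for a in structure.atoms if a.chain_id == cid],
                    het_atoms=[a for a in structure.het_atoms if a.chain_id == cid],
                    model_atom_counts=structure.model_atom_counts,
                    resolution=structure.resolution,
                )
            )
        return units
    if mode == "chain_subset":
        if not chains:
            raise ValueError("chain_subset mode requires a non-empty chain list")
        known = set(structure.chain_ids)
        for cid in chains:
            if cid not in known:
                raise ValueError(f"unknown chain identifier: {cid!r}")
        selected = set(chains)
        return [
            ProteinStructure(
                structure_id=f"{structure.structure_id}_" + "".join(chains),
                atoms=[a for a in structure.atoms if a.chain_id in selected],
                het_atoms=[a for a in structure.het_atoms if a.chain_id in selected],
                model_atom_counts=structure.model_atom_counts,
                resolution=structure.resolution,
            )
        ]
    raise ValueError(f"unknown grouping mode: {mode!r}")


def extract_ligand(
    structure: ProteinStructure,
    res_name: str,
    chain_id: Optional[str] = None,
    res_seq: Optional[int] = None,
) -> LigandCoordinates:
    """Pull a named HETATM residue out of the structure as ligand coordinates."""
    coords = [
        [a.x, a.y, a.z]
        for a in structure.het_atoms
        if a.res_name == res_name
        and (chain_id is None or a.chain_id == chain_id)
        and (res_seq is None or a.res_seq == res_seq)
    ]
    if not coords:
        raise ValueError(
            f"no HETATM atoms match ligand selector "
            f"{res_name}/{chain_id or '*'}/{res_seq if res_seq is not None else '*'}"
        )
    lig_id = res_name if chain_id is None else f"{res_name}_{chain_id}{res_seq or ''}"
    return LigandCoordinates(ligand_id=lig_id, atom_coords=np.array(coords))


def _format_atom_line(atom: AtomRecord, serial: int) -> str:
    record = "HETATM" if atom.is_het else "ATOM  "
    name = atom.atom_name
    # column 13 is reserved for two-letter elements; pad one-letter names
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    return (
        f"{record}{serial:5d} {name:<4s}{atom.alt_loc or ' ':1s}"
        f"{atom.res_name:>3s} {atom.chain_id or ' ':1s}{atom.res_seq:4d}"
        f"{atom.i_code or ' ':1s}   "
        f"{atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {atom.element.upper():>2s}"
    )


def write_structure_pdb(
    structure: ProteinStructure,
    ligands: Iterable[LigandCoordinates] = (),
    remarks: Iterable[str] = (),
) -> str:
    """Emit the structure (and optional pseudo-ligands) as fixed-column PDB."""
    lines = [f"REMARK   6 {structure.structure_id}"]
    for r in remarks:
        lines.append(f"REMARK   6 {r}")
    if structure.resolution is not None:
        lines.append(
            f"REMARK   2 RESOLUTION. {structure.resolution:7.2f} ANGSTROMS."
        )
    serial = 0
    for atom in structure.atoms:
        serial += 1
        lines.append(_format_atom_line(atom, serial))
    lines.append("TER")
    for li, lig in enumerate(ligands):
        res_name = (lig.ligand_id[:3] or "LIG").upper()
        for xyz in lig.atom_coords:
            serial += 1
            rec = AtomRecord(
                serial=serial,
                atom_name="C",
                alt_loc="",
                res_name=res_name,
                chain_id="L",
                res_seq=900 + li,
                i_code="",
                x=float(xyz[0]),
                y=float(xyz[1]),
                z=float(xyz[2]),
                element="C",
                is_het=True,
            )
            lines.append(_format_atom_line(rec, serial))
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pocket_pdb(structure: ProteinStructure, pockets: Sequence) -> str:
    """Emit predicted pockets as one ATOM block per pocket, TER-separated.

    Pocket members index into ``structure.atoms``; coordinates round-trip
    through :func:`parse_pdb` at 0.001 Å.
    """
    lines = [f"REMARK   6 predicted pockets for {structure.structure_id}"]
    serial = 0
    n = len(structure.atoms)
    for pocket in pockets:
        for idx in pocket.member_atoms:
            if not (0 <= idx < n):
                raise IndexError(
                    f"pocket {pocket.pocket_id} member index {idx} out of range (n={n})"
                )
            serial += 1
            atom = structure.atoms[idx]
            lines.append(_format_atom_line(replace(atom, is_het=False), serial))
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
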