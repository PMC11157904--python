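import numpy as np
import pytest

from sparsepocket.structures import AtomRecord, ProteinStructure


def make_atom(
    serial=1,
    atom_name="CA",
    res_name="ALA",
    chain_id="A",
    res_seq=1,
    x=0.0,
    y=0.0,
    z=0.0,
    element="C",
    is_het=False,
    alt_loc="",
    i_code="",
):
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
        is_het=is_het,
    )


def pdb_atom_line(
    serial=1,
    name="CA",
    alt_loc=" ",
    res_name="ALA",
    chain="A",
    res_seq=1,
    x=1.0,
    y=2.0,
    z=3.0,
    element="C",
    het=False,
):
    record = "HETATM" if het else "ATOM  "
    padded = name if len(name) >= 4 or len(element) == 2 else f" {name}"
    return (
        f"{record}{serial:5d} {padded:<4s}{alt_loc}{res_name:>3s} {chain}"
        f"{res_seq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
        f"          {element.upper():>2s}"
    )


@pytest.fixture
def simple_pdb_text():
    lines = [
        "REMARK   2 RESOLUTION.    1.80 ANGSTROMS.",
        pdb_atom_line(1, "N", res_name="ALA", chain="A", res_seq=1, x=0.0, y=0.0, z=0.0, element="N"),
        pdb_atom_line(2, "CA", res_name="ALA", chain="A", res_seq=1, x=1.0, y=2.0, z=3.0),
        pdb_atom_line(3, "CB", res_name="ALA", chain="A", res_seq=1, x=2.0, y=2.5, z=3.0),
        pdb_atom_line(4, "CA", res_name="GLY", chain="B", res_seq=1, x=8.0, y=8.0, z=8.0),
        pdb_atom_line(5, "C1", res_name="HEM", chain="A", res_seq=90, x=4.0, y=4.0, z=4.0, het=True),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture
def two_chain_structure():
    atoms = [
        make_atom(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, "N"),
        make_atom(2, "CA", "ALA", "A", 1, 1.5, 0.0, 0.0),
        make_atom(3, "CA", "GLY", "B", 1, 10.0, 0.0, 0.0),
        make_atom(4, "C", "GLY", "B", 1, 11.5, 0.0, 0.0),
    ]
    return ProteinStructure(
        structure_id="toy2", atoms=atoms, model_atom_counts=[4], resolution=1.5
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
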