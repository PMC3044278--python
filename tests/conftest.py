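"""Shared fixtures: hand-written PDB snippets and small analytic networks."""

from __future__ import annotations

import numpy as np
import pytest

from evtnet import ToySpec, build_network, toy_model, transition_matrix


def pdb_line(
    record: str = "ATOM",
    serial: int = 1,
    name: str = "CA",
    altloc: str = " ",
    resname: str = "GLY",
    chain: str = "A",
    resnum: int = 1,
    icode: str = " ",
    x: float = 0.0,
    y: float = 0.0,
    z: float = 0.0,
    occ: float = 1.0,
    b: float = 0.0,
    element: str = "C",
) -> str:
    """One fixed-column ATOM/HETATM record."""
    name_f = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:5d} {name_f:<4s}{altloc}{resname:>3s} {chain}"
        f"{resnum:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def two_residue_pdb() -> str:
    """GLY with 4 heavy atoms + 2 hydrogens, ALA with 5 heavy atoms, one water."""
    lines = []
    # GLY: N CA C O + 2 H
    for i, (nm, el) in enumerate([("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("H", "H"), ("HA2", "H")]):
        lines.append(pdb_line(serial=i + 1, name=nm, resname="GLY", resnum=1, x=i * 0.8, element=el))
    # ALA: N CA C O CB
    for i, (nm, el) in enumerate([("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C")]):
        lines.append(pdb_line(serial=10 + i, name=nm, resname="ALA", resnum=2, x=4.0 + i * 0.8, element=el))
    lines.append(
        pdb_line(record="HETATM", serial=20, name="O", resname="HOH", resnum=100, x=30.0, element="O")
    )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def path3_model():
    return toy_model(ToySpec("path", 3))


@pytest.fixture
def path3_network(path3_model):
    return build_network(path3_model, cutoff=8.0)


@pytest.fixture
def path3_T(path3_network):
    return transition_matrix(path3_network)


@pytest.fixture
def path3_M_expected():
    """Hand-derived EVT matrix of the unit-affinity 3-node path."""
    return np.array(
        [
            [4 / 3, 1.0, 1 / 3],
            [2 / 3, 5 / 3, 2 / 3],
            [1 / 3, 1.0, 4 / 3],
        ]
    )
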