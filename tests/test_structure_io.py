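"""Parsing PDB text into residue/ligand nodes and writing annotated output."""

import random

import numpy as np
import pytest

from evtnet import (
    StructureError,
    find_node,
    node_table,
    parse_structure,
    write_annotated_pdb,
)

from conftest import pdb_line


def test_heavy_atom_counting_excludes_hydrogens_and_waters(two_residue_pdb):
    model = parse_structure(two_residue_pdb)
    assert [n.node_id.resname for n in model.nodes] == ["GLY", "ALA"]
    assert [n.heavy_count for n in model.nodes] == [4, 5]
    for node in model.nodes:
        assert node.heavy_count == len(node.atoms)
        assert all(a.element not in ("H", "D") for a in node.atoms)


def test_water_only_input_raises():
    text = pdb_line(record="HETATM", name="O", resname="HOH", resnum=1, element="O") + "\nEND\n"
    with pytest.raises(StructureError, match="no nodes"):
        parse_structure(text)


def test_empty_chain_selection_raises(two_residue_pdb):
    with pytest.raises(StructureError, match="no nodes"):
        parse_structure(two_residue_pdb, chains={"Z"})


def test_altloc_keeps_highest_occupancy_then_code_order():
    lines = [
        pdb_line(serial=1, name="N", resname="SER", element="N"),
        pdb_line(serial=2, name="CA", altloc="A", resname="SER", occ=0.4, x=1.0),
        pdb_line(serial=3, name="CA", altloc="B", resname="SER", occ=0.6, x=2.0),
        pdb_line(serial=4, name="CB", altloc="A", resname="SER", occ=0.5, x=3.0),
        pdb_line(serial=5, name="CB", altloc="B", resname="SER", occ=0.5, x=4.0),
        pdb_line(serial=6, name="O", resname="SER", element="O", x=5.0),
        pdb_line(serial=11, name="CA", resname="GLY", resnum=2, x=6.0),
        "END",
    ]
    model = parse_structure("\n".join(lines) + "\n")
    ser = model.nodes[0]
    assert ser.heavy_count == 4  # one copy of each altloc pair
    ca = next(a for a in ser.atoms if a.name == "CA")
    assert ca.coords[0] == pytest.approx(2.0)  # occupancy 0.6 wins
    cb = next(a for a in ser.atoms if a.name == "CB")
    assert cb.coords[0] == pytest.approx(3.0)  # tie broken by altloc code order


def test_multi_model_uses_first_model_only(two_residue_pdb):
    text = "MODEL        1\n" + two_residue_pdb.replace("END\n", "ENDMDL\nMODEL        2\n")
    text += pdb_line(serial=50, name="CA", resname="VAL", resnum=9, x=50.0) + "\nENDMDL\nEND\n"
    model = parse_structure(text)
    assert [n.node_id.resname for n in model.nodes] == ["GLY", "ALA"]


def _ligand_pdb() -> str:
    lines = [
        pdb_line(serial=1, name="N", resname="LYS", resnum=296, element="N"),
        pdb_line(serial=2, name="CA", resname="LYS", resnum=296, x=1.0),
        pdb_line(serial=3, name="CB", resname="LYS", resnum=296, x=2.0),
        pdb_line(record="HETATM", serial=10, name="C1", resname="RET", resnum=401, x=3.0),
        pdb_line(record="HETATM", serial=11, name="C2", resname="RET", resnum=401, x=4.0),
        pdb_line(serial=20, name="CA", resname="GLY", resnum=1, x=8.0),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.mark.parametrize(
    "policy, expected_names",
    [("include", ["GLY", "LYS", "RET"]), ("exclude", ["GLY", "LYS"])],
)
def test_ligand_policies(policy, expected_names):
    model = parse_structure(_ligand_pdb(), ligands=policy)
    assert [n.node_id.resname for n in model.nodes] == expected_names
    if policy == "include":
        assert model.nodes[-1].is_ligand  # ligands sort last


def test_merge_map_folds_hetero_group_into_residue():
    model = parse_structure(_ligand_pdb(), merge={"RET": "A:296"})
    names = [n.node_id.resname for n in model.nodes]
    assert names == ["GLY", "LYS"]
    lys = model.nodes[names.index("LYS")]
    assert lys.heavy_count == 3 + 2  # lysine atoms plus the conjugated group
    assert len(model.merges) == 1
    # the merged node is addressable by the target residue
    assert find_node(model, "A:296") == 1


def test_merge_target_missing_raises():
    with pytest.raises(StructureError, match="A:999"):
        parse_structure(_ligand_pdb(), merge={"RET": "A:999"})


def test_node_order_invariant_under_record_shuffling(two_residue_pdb):
    model_ref = parse_structure(two_residue_pdb)
    atom_lines = [l for l in two_residue_pdb.splitlines() if l.startswith(("ATOM", "HETATM"))]
    rng = random.Random(0)
    for _ in range(3):
        rng.shuffle(atom_lines)
        model = parse_structure("\n".join(atom_lines) + "\nEND\n")
        assert model.node_ids == model_ref.node_ids
        assert list(model.heavy_counts) == list(model_ref.heavy_counts)


def test_write_annotated_pdb_sets_bfactor_column(two_residue_pdb):
    model = parse_structure(two_residue_pdb)
    out = write_annotated_pdb(model, [0.0, 1.0], two_residue_pdb)
    gly_b = {line[60:66] for line in out.splitlines() if line.startswith("ATOM") and line[17:20] == "GLY"}
    ala_b = {line[60:66] for line in out.splitlines() if line.startswith("ATOM") and line[17:20] == "ALA"}
    assert gly_b == {"  0.00"}
    assert ala_b == {"  1.00"}
    # non-node atoms (water) keep their original B-factor untouched
    water = [l for l in out.splitlines() if l[17:20] == "HOH"]
    orig = [l for l in two_residue_pdb.splitlines() if l[17:20] == "HOH"]
    assert water == orig


def test_write_annotated_pdb_roundtrip(two_residue_pdb):
    model = parse_structure(two_residue_pdb)
    out = write_annotated_pdb(model, [2.5, -1.25], two_residue_pdb)
    model2 = parse_structure(out)
    assert model2.node_ids == model.node_ids
    assert list(model2.heavy_counts) == list(model.heavy_counts)
    for a, b in zip(model.nodes, model2.nodes):
        assert np.allclose(a.coord_array(), b.coord_array())


@pytest.mark.parametrize("bad", [[0.0], [0.0, np.nan], [0.0, 1.0, 2.0]])
def test_write_annotated_pdb_rejects_bad_values(two_residue_pdb, bad):
    model = parse_structure(two_residue_pdb)
    with pytest.raises(ValueError):
        write_annotated_pdb(model, bad, two_residue_pdb)


def test_node_table_columns(two_residue_pdb):
    df = node_table(parse_structure(two_residue_pdb))
    assert list(df.columns) == ["chain", "resnum", "icode", "resname", "heavy_count", "is_ligand"]
    assert df["heavy_count"].tolist() == [4, 5]
    assert not df["is_ligand"].any()
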