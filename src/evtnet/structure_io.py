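"""Read PDB coordinate files into residue/ligand nodes and write annotated PDB back out.

A protein structure network treats each amino acid (and, optionally, each
bound ligand) as a single node carrying the coordinates of its heavy atoms
(all atoms but hydrogen/deuterium).  Waters are never nodes.  Covalently
modified residues -- e.g. a retinal Schiff-base conjugated lysine, or an
FMN chromophore that should travel with its cysteine -- can be expressed by
merging a hetero-group's atoms into a target residue node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomSite",
    "NodeID",
    "ResidueNode",
    "StructureModel",
    "StructureError",
    "parse_structure",
    "write_annotated_pdb",
    "node_table",
    "find_node",
]

#: residue names treated as water and always excluded
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


class StructureError(ValueError):
    """Raised for unusable structure input (no nodes, bad merge target, ...)."""


class NodeID(NamedTuple):
    """Identity of a network node: (chain, residue number, insertion code, residue name)."""

    chain: str
    resnum: int
    icode: str
    resname: str

    def __str__(self) -> str:  # e.g. "A:296:LYS"
        icode = self.icode.strip()
        return f"{self.chain}:{self.resnum}{icode}:{self.resname}"


@dataclass(frozen=True)
class AtomSite:
    """One heavy atom: label, element symbol and Cartesian coordinates in Å."""

    name: str
    element: str
    coords: tuple[float, float, float]
    altloc: str = ""
    is_hetero: bool = False


@dataclass
class ResidueNode:
    """A network node: one residue or ligand group with its heavy atoms.

    ``heavy_count`` is N_i, the number of heavy (non-hydrogen) atoms, used
    to size-normalise contact counts when edge affinities are computed.
    """

    node_id: NodeID
    atoms: list[AtomSite]
    is_ligand: bool = False

    @property
    def heavy_count(self) -> int:
        return len(self.atoms)

    def coord_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class StructureModel:
    """Ordered collection of residue/ligand nodes parsed from one structure.

    Node order is deterministic: protein residues sorted by (chain, residue
    number, insertion code), then unmerged ligand groups in the same order.
    """

    nodes: list[ResidueNode]
    source_id: str = ""
    merges: dict[NodeID, NodeID] = field(default_factory=dict)

    @property
    def node_ids(self) -> list[NodeID]:
        return [n.node_id for n in self.nodes]

    @property
    def heavy_counts(self) -> np.ndarray:
        return np.array([n.heavy_count for n in self.nodes], dtype=int)

    def index_of(self, node_id: NodeID) -> int:
        return self.node_ids.index(node_id)


def _is_hydrogen(atom: gemmi.Atom) -> bool:
    # element column when present; atom-name heuristic as fallback
    el = atom.element.name.upper()
    if el in ("H", "D"):
        return True
    if el not in ("", "X"):
        return False
    name = atom.name.strip().lstrip("0123456789")
    return name[:1].upper() in ("H", "D")


def _select_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """For each atom name keep exactly one altloc: highest occupancy, ties by code order."""
    by_name: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = by_name.get(atom.name)
        if prev is None:
            by_name[atom.name] = atom
        else:
            key_new = (atom.occ, -ord(atom.altloc or "\x7f"))
            key_old = (prev.occ, -ord(prev.altloc or "\x7f"))
            if key_new > key_old:
                by_name[atom.name] = atom
    return list(by_name.values())


def _residue_selector(sel: str, candidates: Sequence[NodeID]) -> NodeID:
    """Resolve a 'CHAIN:RESNUM[:ICODE]' or bare residue-name selector to a NodeID."""
    sel = sel.strip()
    if ":" in sel:
        parts = sel.split(":")
        chain = parts[0]
        num_part = parts[1]
        icode = ""
        if num_part and not num_part[-1].isdigit() and num_part[-1] != "-":
            icode = num_part[-1]
            num_part = num_part[:-1]
        resnum = int(num_part)
        if len(parts) > 2 and parts[2]:
            extra = parts[2]
            matches = [
                c
                for c in candidates
                if c.chain == chain
                and c.resnum == resnum
                and c.icode.strip() == icode
                and c.resname == extra
            ]
        else:
            matches = [
                c
                for c in candidates
                if c.chain == chain and c.resnum == resnum and c.icode.strip() == icode
            ]
    else:
        matches = [c for c in candidates if c.resname == sel]
    if not matches:
        raise StructureError(f"no residue matches selector {sel!r}")
    if len(matches) > 1:
        raise StructureError(f"selector {sel!r} is ambiguous: {[str(m) for m in matches]}")
    return matches[0]


def parse_structure(
    pdb_text: str,
    chains: Iterable[str] | None = None,
    ligands: str = "include",
    merge: Mapping[str, str] | None = None,
    source_id: str = "",
) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Parameters
    ----------
    pdb_text
        PDB-format coordinate text (ATOM/HETATM fixed columns).
    chains
        Chain identifiers to keep; ``None`` keeps all chains.
    ligands
        ``"include"`` (default) makes each non-water hetero-group its own node,
        ``"exclude"`` drops them.  Merged groups are handled before this policy.
    merge
        Mapping of hetero-group selector -> target residue selector, each either
        ``"CHAIN:RESNUM[:ICODE]"`` or a bare residue name (must be unique).  The
        group's heavy atoms are folded into the target residue's node.

    Only the first MODEL of multi-model files is used; hydrogens, waters and
    duplicate altloc copies are removed.
    """
    if ligands not in ("include", "exclude"):
        raise ValueError(f"unknown ligand policy {ligands!r}")
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise StructureError("no nodes: structure contains no coordinate records")
    model = st[0]
    chain_set = set(chains) if chains is not None else None

    raw: dict[NodeID, tuple[list[AtomSite], bool]] = {}
    for chain in model:
        if chain_set is not None and chain.name not in chain_set:
            continue
        for residue in chain:
            if residue.name in WATER_NAMES or residue.is_water():
                continue
            is_het = residue.het_flag == "H"
            atoms = [
                AtomSite(
                    name=a.name,
                    element=a.element.name or "X",
                    coords=(a.pos.x, a.pos.y, a.pos.z),
                    altloc=a.altloc if a.altloc not in ("", "\0") else "",
                    is_hetero=is_het,
                )
                for a in _select_altlocs(residue)
                if not _is_hydrogen(a)
            ]
            nid = NodeID(chain.name, residue.seqid.num, residue.seqid.icode.strip(), residue.name)
            if nid in raw:
                raw[nid][0].extend(atoms)
            else:
                raw[nid] = (atoms, is_het)

    # resolve merges before the ligand policy so merged groups survive "exclude"
    merges: dict[NodeID, NodeID] = {}
    if merge:
        het_ids = [nid for nid, (_, is_het) in raw.items() if is_het]
        all_ids = list(raw)
        for group_sel, target_sel in merge.items():
            group_id = _residue_selector(group_sel, het_ids)
            try:
                target_id = _residue_selector(target_sel, [i for i in all_ids if i != group_id])
            except StructureError as exc:
                raise StructureError(f"merge target not found: {exc}") from exc
            atoms, _ = raw.pop(group_id)
            raw[target_id][0].extend(atoms)
            merges[group_id] = target_id

    nodes: list[ResidueNode] = []
    for nid, (atoms, is_het) in raw.items():
        if is_het and ligands == "exclude":
            continue
        if not atoms:
            warnings.warn(f"dropping node {nid} with zero heavy atoms", stacklevel=2)
            continue
        nodes.append(ResidueNode(node_id=nid, atoms=atoms, is_ligand=is_het))

    # deterministic order: residues by (chain, resnum, icode); ligands last
    nodes.sort(key=lambda n: (n.is_ligand, n.node_id.chain, n.node_id.resnum, n.node_id.icode))
    if not nodes:
        raise StructureError("no nodes: selection is empty after filtering")
    return StructureModel(nodes=nodes, source_id=source_id or st.name, merges=merges)


def _line_residue_key(line: str) -> tuple[str, int, str]:
    chain = line[21]
    resnum = int(line[22:26])
    icode = line[26].strip()
    return (chain, resnum, icode)


def write_annotated_pdb(
    model: StructureModel, values: Sequence[float], pdb_text: str
) -> str:
    """Return ``pdb_text`` with each atom's B-factor replaced by its node's value.

    Atoms whose residue is not a node (waters, unselected chains) keep their
    original B-factor.  Atoms of a merged hetero-group carry the value of the
    node they were merged into.  Values are rendered in the fixed-width 6.2f
    B-factor column; everything else in the file is preserved byte for byte.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (len(model.nodes),):
        raise ValueError(
            f"value count mismatch: {values.size} values for {len(model.nodes)} nodes"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("annotation values must be finite (no NaN/inf)")

    lookup: dict[tuple[str, int, str], float] = {}
    for node, v in zip(model.nodes, values):
        nid = node.node_id
        lookup[(nid.chain, nid.resnum, nid.icode)] = float(v)
    for group_id, target_id in model.merges.items():
        key = (target_id.chain, target_id.resnum, target_id.icode)
        if key in lookup:
            lookup[(group_id.chain, group_id.resnum, group_id.icode)] = lookup[key]

    out_lines = []
    for line in pdb_text.splitlines(keepends=True):
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 66:
            key = _line_residue_key(line)
            if key in lookup:
                v = np.clip(lookup[key], -99.99, 999.99)
                line = line[:60] + f"{v:6.2f}" + line[66:]
        out_lines.append(line)
    return "".join(out_lines)


def node_table(model: StructureModel) -> pd.DataFrame:
    """Per-node summary table: chain, resnum, icode, resname, heavy_count, is_ligand."""
    return pd.DataFrame(
        {
            "chain": [n.node_id.chain for n in model.nodes],
            "resnum": [n.node_id.resnum for n in model.nodes],
            "icode": [n.node_id.icode for n in model.nodes],
            "resname": [n.node_id.resname for n in model.nodes],
            "heavy_count": [n.heavy_count for n in model.nodes],
            "is_ligand": [n.is_ligand for n in model.nodes],
        }
    )


def find_node(model: StructureModel, selector: str) -> int:
    """Index of the node matching a 'CHAIN:RESNUM[:ICODE|:NAME]' or residue-name selector."""
    nid = _residue_selector(selector, model.node_ids)
    return model.index_of(nid)
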