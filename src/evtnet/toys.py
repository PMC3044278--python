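"""Synthetic toy structures with known contact topology, and a random-walk oracle.

The generator writes PDB-format text in which each "residue" is a small
cluster of heavy atoms around a node center, with centers placed so that the
contact graph at the default 8 Å cutoff is exactly a requested topology
(path, ring, star, grid, or a custom embedded edge list).  Atom offsets come
from a seeded scrambled Sobol sequence — low-discrepancy and deterministic,
so contact counts are reproducible byte for byte.

The Monte-Carlo oracle simulates absorbing random walks directly from the
transition matrix and estimates per-node visit counts with standard errors;
it validates the fundamental-matrix and EVT computations without sharing any
code with them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .network import AffinityNetwork, TransitionMatrix, affinity_matrix
from .structure_io import StructureModel, parse_structure

__all__ = [
    "ToySpec",
    "WalkEstimate",
    "make_toy_structure",
    "toy_model",
    "random_walk_oracle",
    "random_connected_network",
    "mc_evt_row",
]

#: atoms are placed within this radius of their node center (Å)
CLUSTER_RADIUS = 0.45
#: hard cap on steps per walk, to catch non-absorbing inputs
MAX_WALK_STEPS = 10**7


@dataclass
class ToySpec:
    """Recipe for a synthetic structure with an exact contact topology.

    ``spacing`` is the center-to-center distance of bonded nodes in Å; with
    the default 7 Å and cluster radius 0.45 Å, bonded clusters always touch
    within the 8 Å cutoff and the generator verifies that no unintended edge
    appears.
    """

    topology: str
    n_nodes: int
    atoms_per_node: int | list[int] = 4
    spacing: float = 7.0
    jitter_seed: int = 0
    edges: list[tuple[int, int]] | None = None
    centers: np.ndarray | None = field(default=None, repr=False)


@dataclass
class WalkEstimate:
    """Monte-Carlo per-node mean visit counts with standard errors."""

    visits: np.ndarray
    se: np.ndarray
    n_walks: int
    seed: int


def _topology_layout(spec: ToySpec) -> tuple[np.ndarray, set[frozenset[int]]]:
    n, s = spec.n_nodes, spec.spacing
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if spec.topology == "path":
        centers = np.column_stack([np.arange(n) * s, np.zeros(n), np.zeros(n)])
        edges = {frozenset((i, i + 1)) for i in range(n - 1)}
    elif spec.topology == "ring":
        if n < 3:
            raise ValueError("ring needs at least 3 nodes")
        r = s / (2.0 * np.sin(np.pi / n))
        ang = 2.0 * np.pi * np.arange(n) / n
        centers = np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(n)])
        edges = {frozenset((i, (i + 1) % n)) for i in range(n)}
    elif spec.topology == "star":
        if n > 7:
            raise ValueError("star supports at most 6 leaves (7 nodes) at this geometry")
        axes = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
        centers = np.vstack([[0.0, 0.0, 0.0], axes[: n - 1] * s])
        edges = {frozenset((0, i)) for i in range(1, n)}
    elif spec.topology == "grid":
        rows = int(np.floor(np.sqrt(n)))
        while n % rows:
            rows -= 1
        cols = n // rows
        ii, jj = np.divmod(np.arange(n), cols)
        centers = np.column_stack([jj * s, ii * s, np.zeros(n)]).astype(float)
        edges = set()
        for k in range(n):
            if jj[k] + 1 < cols:
                edges.add(frozenset((k, k + 1)))
            if ii[k] + 1 < rows:
                edges.add(frozenset((k, k + cols)))
    elif spec.topology == "custom":
        if spec.edges is None or spec.centers is None:
            raise ValueError("custom topology requires both edges and centers")
        centers = np.asarray(spec.centers, dtype=float)
        if centers.shape != (n, 3):
            raise ValueError("centers must be an (n_nodes, 3) array")
        edges = {frozenset((int(i), int(j))) for i, j in spec.edges}
    else:
        raise ValueError(f"unknown topology {spec.topology!r}")
    return centers, edges


def _contact_edges(coords_by_node: list[np.ndarray], cutoff: float) -> set[frozenset[int]]:
    """Brute-force contact graph over atom clusters (verification only)."""
    edges = set()
    n = len(coords_by_node)
    for i in range(n):
        for j in range(i + 1, n):
            diff = coords_by_node[i][:, None, :] - coords_by_node[j][None, :, :]
            if np.any(np.sqrt((diff**2).sum(axis=2)) <= cutoff):
                edges.add(frozenset((i, j)))
    return edges


def make_toy_structure(spec: ToySpec, cutoff: float = 8.0) -> str:
    """Render a :class:`ToySpec` as PDB-format text with the exact contact topology.

    Raises if the geometry does not realise the requested edge set at the
    given cutoff (e.g. custom centers packed too tightly).
    """
    centers, want_edges = _topology_layout(spec)
    n = spec.n_nodes
    atoms = (
        [spec.atoms_per_node] * n
        if isinstance(spec.atoms_per_node, int)
        else list(spec.atoms_per_node)
    )
    if len(atoms) != n or any(a < 1 for a in atoms):
        raise ValueError("atoms_per_node must be >= 1 for every node")

    sob = qmc.Sobol(d=3, scramble=True, seed=spec.jitter_seed)
    coords_by_node = []
    with warnings.catch_warnings():
        # sample counts need not be powers of two; balance is irrelevant here
        warnings.simplefilter("ignore", UserWarning)
        for i in range(n):
            u = sob.random(atoms[i])  # in [0,1)^3
            offsets = (u - 0.5) * (2.0 * CLUSTER_RADIUS / np.sqrt(3.0))
            coords_by_node.append(centers[i] + offsets)

    got_edges = _contact_edges(coords_by_node, cutoff)
    if got_edges != want_edges:
        extra = got_edges - want_edges
        lost = want_edges - got_edges
        raise ValueError(
            f"spec is geometrically unrealizable at cutoff {cutoff} Å: "
            f"spurious edges {sorted(map(tuple, map(sorted, extra)))}, "
            f"missing edges {sorted(map(tuple, map(sorted, lost)))}"
        )

    lines = []
    serial = 1
    for i, coords in enumerate(coords_by_node):
        for a, (x, y, z) in enumerate(coords):
            name = f"C{a + 1}"
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} ALA A{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {'C':>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def toy_model(spec: ToySpec, cutoff: float = 8.0) -> StructureModel:
    """Generate and parse a toy structure in one step."""
    return parse_structure(make_toy_structure(spec, cutoff), source_id=f"toy-{spec.topology}{spec.n_nodes}")


def random_connected_network(
    n: int, seed: int, edge_prob: float = 0.5
) -> AffinityNetwork:
    """Random connected affinity network with integer contact counts.

    Draws an Erdős–Rényi graph conditioned on connectivity, random contact
    counts N_ij in 1..6 and heavy-atom counts N_i in 3..9, then applies the
    standard size-normalised affinity.  Used as fixture input for oracle
    cross-checks; not tied to any geometry.
    """
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        upper = rng.random((n, n)) < edge_prob
        adj = np.triu(upper, k=1)
        adj = adj | adj.T
        # connectivity via BFS
        seen = {0}
        frontier = [0]
        while frontier:
            v = frontier.pop()
            for w in np.flatnonzero(adj[v]):
                if w not in seen:
                    seen.add(int(w))
                    frontier.append(int(w))
        if len(seen) == n:
            break
    else:  # pragma: no cover
        raise RuntimeError("failed to draw a connected graph")
    N = np.where(adj, rng.integers(1, 7, size=(n, n)), 0)
    N = np.triu(N, k=1)
    N = N + N.T
    heavy = rng.integers(3, 10, size=n)
    return affinity_matrix(N, heavy)


def random_walk_oracle(
    T: TransitionMatrix, start, absorbing, n_walks: int, seed: int
) -> WalkEstimate:
    """Estimate expected visit counts by simulating absorbing walks.

    Every arrival at a node counts as one visit; the start node's initial
    occupancy counts, and the absorbing node is counted once on entry.  With
    ``start == absorbing`` the walk is absorbed immediately (one visit there,
    zero elsewhere).  Entirely independent of the fundamental-matrix code.
    """
    n = T.n
    s = T.nodes.index(start) if not isinstance(start, (int, np.integer)) else int(start)
    k = T.nodes.index(absorbing) if not isinstance(absorbing, (int, np.integer)) else int(absorbing)
    if n_walks < 1:
        raise ValueError("n_walks must be positive")
    rng = np.random.default_rng(seed)
    counts = np.zeros((n_walks, n), dtype=np.int64)
    counts[:, s] = 1
    if s != k:
        cum = np.cumsum(T.T, axis=1)
        cum[:, -1] = 1.0  # guard against rounding
        state = np.full(n_walks, s, dtype=np.int64)
        active = np.arange(n_walks)
        steps = 0
        while active.size:
            steps += 1
            if steps > MAX_WALK_STEPS:
                raise RuntimeError(
                    "step cap exceeded: walks are probably not being absorbed"
                )
            r = rng.random(active.size)
            nxt = (cum[state[active]] <= r[:, None]).sum(axis=1)
            state[active] = nxt
            counts[active, nxt] += 1
            active = active[nxt != k]
    visits = counts.mean(axis=0)
    se = counts.std(axis=0, ddof=1) / np.sqrt(n_walks)
    return WalkEstimate(visits=visits, se=se, n_walks=n_walks, seed=seed)


def mc_evt_row(
    T: TransitionMatrix, start, n_walks: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo estimate of one EVT-matrix row: average the oracle over all k.

    Returns ``(row, se)`` with standard errors propagated across the n
    independent absorbing-node estimates.
    """
    n = T.n
    row = np.zeros(n)
    var = np.zeros(n)
    for ki in range(n):
        est = random_walk_oracle(T, start, ki, n_walks, seed + ki)
        row += est.visits
        var += est.se**2
    return row / n, np.sqrt(var) / n
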