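"""Shortest-path visiting time (SVT): a deterministic baseline for the EVT profile.

Instead of letting the signal diffuse over all random-walk routes, SVT sends
it only along unweighted shortest paths.  For each absorbing node k every
shortest path from the initiation node to k is enumerated; a node is credited
once for every such path it lies on (the start node is excluded, the endpoint
k is counted once per path, mirroring the EVT entering-once convention).
Credits are averaged over the n choices of absorbing node so that SVT and EVT
profiles are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .network import AffinityNetwork, ConnectivityError

__all__ = ["SVTProfile", "svt_profile"]


@dataclass
class SVTProfile:
    """Per-node average shortest-path visit counts for one initiation node."""

    initiation: object
    nodes: list
    counts: np.ndarray


def _bfs_sigma(adj: list[np.ndarray], source: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Hop distances and shortest-path counts from one source (Brandes-style BFS)."""
    dist = np.full(n, -1, dtype=np.int64)
    sigma = np.zeros(n, dtype=float)
    dist[source] = 0
    sigma[source] = 1.0
    frontier = [source]
    while frontier:
        nxt: list[int] = []
        for v in frontier:
            for w in adj[v]:
                if dist[w] == -1:
                    dist[w] = dist[v] + 1
                    nxt.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
        frontier = nxt
    return dist, sigma


def svt_profile(net: AffinityNetwork, initiation) -> SVTProfile:
    """Average shortest-path visit counts from ``initiation`` to every absorbing node.

    A node j's credit for absorbing node k is the number of unweighted
    shortest initiation->k paths that contain j (all tied paths count); the
    per-node count is the credit summed over k != initiation, divided by n.
    """
    n = net.n
    s = net.nodes.index(initiation) if not isinstance(initiation, (int, np.integer)) else int(initiation)
    adj_bool = net.contact_counts > 0
    ncomp, _ = connected_components(csr_matrix(adj_bool), directed=False)
    if ncomp > 1:
        raise ConnectivityError(f"contact graph has {ncomp} components")
    adj = [np.flatnonzero(adj_bool[v]) for v in range(n)]

    dist_s, sigma_s = _bfs_sigma(adj, s, n)
    counts = np.zeros(n)
    for k in range(n):
        if k == s:
            continue
        dist_k, sigma_k = _bfs_sigma(adj, k, n)
        # paths s->k through j: sigma_s(j) * sigma_k(j) when distances add up
        on_path = dist_s + dist_k == dist_s[k]
        credit = np.where(on_path, sigma_s * sigma_k, 0.0)
        credit[s] = 0.0  # start node receives no credit
        counts += credit
    counts /= n
    return SVTProfile(initiation=net.nodes[s], nodes=list(net.nodes), counts=counts)
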