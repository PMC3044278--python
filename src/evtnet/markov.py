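"""Expected visiting time (EVT) of an absorbing random walk on a residue network.

A perturbation signal started at node i performs a random walk with one-step
probabilities T until it reaches an absorbing node k.  For a fixed k the
fundamental matrix of the absorbing chain,

    F^k = (I - T^k)^-1        (T^k: T with row and column k removed)

gives in entry (i, j) the expected number of visits to intermediate node j on
the way from i to k.  Averaging over every choice of absorbing node yields the
EVT matrix

    M = (1/n) * sum_k ext(F^k)

where ext(F^k) embeds F^k back into n x n coordinates with its k-th row set to
0 (an absorbed signal emits nothing) and its k-th column set to 1 (the
absorbing node is entered exactly once).  Row i of M is the EVT profile of
initiation node i; column sums of M are the average signal traffic, a
betweenness-like centrality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import get_lapack_funcs, lu_factor, lu_solve
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .network import AffinityNetwork, TransitionMatrix, build_network, transition_matrix
from .structure_io import StructureModel

__all__ = [
    "FundamentalMatrix",
    "EVTMatrix",
    "EVTProfile",
    "fundamental_matrix",
    "evt_matrix",
    "evt_profile",
    "zscore_profile",
    "scaled_profile",
    "profile_ratio",
    "average_evt",
    "profile_correlation_scan",
    "hop_distances",
]

#: condition number above which the absorbing-chain solve is flagged as unreliable
COND_WARN_THRESHOLD = 1e12


@dataclass
class FundamentalMatrix:
    """Fundamental matrix F = (I - T^k)^-1 for one absorbing node.

    ``F[i, j]`` is the expected number of visits to node ``kept_nodes[j]``
    by a walk started at ``kept_nodes[i]`` before absorption at ``k``; the
    start itself counts as one visit, so the diagonal is >= 1.
    """

    k: object
    F: np.ndarray
    kept_nodes: list


@dataclass
class EVTMatrix:
    """n x n expected-visiting-time matrix; row i is the profile for initiation i."""

    M: np.ndarray
    nodes: list
    cutoff: float | None = None

    @property
    def n(self) -> int:
        return self.M.shape[0]

    def profile(self, initiation) -> "EVTProfile":
        i = self.nodes.index(initiation) if not isinstance(initiation, (int, np.integer)) else int(initiation)
        raw = self.M[i].copy()
        return EVTProfile(
            initiation=self.nodes[i], nodes=list(self.nodes), raw=raw, z=zscore_profile(raw)
        )


@dataclass
class EVTProfile:
    """EVT values for one initiation node, with their per-profile z-scores."""

    initiation: object
    nodes: list
    raw: np.ndarray
    z: np.ndarray
    scaled: np.ndarray | None = field(default=None)


def fundamental_matrix(T: TransitionMatrix, k) -> FundamentalMatrix:
    """Solve (I - T^k) F = I for the fundamental matrix of absorbing node ``k``.

    Uses an LU factorisation with linear solves rather than an explicit
    inverse; warns when the estimated condition number exceeds 1e12.
    """
    ki = T.nodes.index(k) if not isinstance(k, (int, np.integer)) else int(k)
    n = T.n
    if not 0 <= ki < n:
        raise ValueError(f"absorbing node index {ki} out of range")
    mask = np.ones(n, dtype=bool)
    mask[ki] = False
    Tk = T.T[np.ix_(mask, mask)]
    Ak = np.eye(n - 1) - Tk
    anorm = np.linalg.norm(Ak, 1)
    try:
        lu, piv = lu_factor(Ak)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError(f"singular absorbing-chain system for k={T.nodes[ki]}") from exc
    (gecon,) = get_lapack_funcs(("gecon",), (lu,))
    rcond, _ = gecon(lu, anorm)
    if rcond == 0 or not np.isfinite(rcond):
        raise ValueError(
            f"singular absorbing-chain system for k={T.nodes[ki]} "
            "(is the remaining graph connected?)"
        )
    if 1.0 / rcond > COND_WARN_THRESHOLD:
        warnings.warn(
            f"absorbing-chain system for k={T.nodes[ki]} is ill-conditioned "
            f"(cond ~ {1.0 / rcond:.2e})",
            stacklevel=2,
        )
    F = lu_solve((lu, piv), np.eye(n - 1))
    if np.any(F < -1e-8):
        raise ValueError("fundamental matrix has negative entries; invalid transition matrix")
    return FundamentalMatrix(
        k=T.nodes[ki], F=F, kept_nodes=[T.nodes[i] for i in np.flatnonzero(mask)]
    )


def evt_matrix(T: TransitionMatrix, cutoff: float | None = None) -> EVTMatrix:
    """Average the extended fundamental matrices over all absorbing nodes.

    The extension conventions (absorbing row = 0, absorbing column = 1) apply
    also when the initiation node is itself the absorbing node, so every entry
    of M is at least 1/n: each node absorbs the signal in exactly one of the n
    averaged chains.
    """
    n = T.n
    if n < 2:
        raise ValueError("EVT needs at least 2 nodes")
    M = np.zeros((n, n))
    for ki in range(n):
        fm = fundamental_matrix(T, ki)
        mask = np.ones(n, dtype=bool)
        mask[ki] = False
        M[np.ix_(mask, mask)] += fm.F
        M[:, ki] += 1.0
    M /= n
    return EVTMatrix(M=M, nodes=list(T.nodes), cutoff=cutoff)


def evt_profile(
    model: StructureModel,
    initiation,
    cutoff: float | None = None,
    component_policy: str = "error",
) -> EVTProfile:
    """Full pipeline: structure -> network -> EVT profile for one initiation node."""
    from .network import DEFAULT_CUTOFF

    cutoff = DEFAULT_CUTOFF if cutoff is None else cutoff
    net = build_network(model, cutoff)
    T = transition_matrix(net, component_policy=component_policy)
    evt = evt_matrix(T, cutoff=cutoff)
    prof = evt.profile(initiation)
    prof.scaled = scaled_profile(prof.raw, prof.initiation, net)
    return prof


def zscore_profile(raw: np.ndarray) -> np.ndarray:
    """Standardise a profile to mean 0 / sd 1 (population sd, divisor n)."""
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise ValueError("z-scoring needs at least 2 values")
    sd = raw.std()
    if sd == 0:
        raise ValueError("cannot z-score a constant profile (sd = 0)")
    return (raw - raw.mean()) / sd


def hop_distances(net: AffinityNetwork, initiation) -> np.ndarray:
    """Unweighted shortest-path hop counts from the initiation node to every node."""
    i = net.nodes.index(initiation) if not isinstance(initiation, (int, np.integer)) else int(initiation)
    d = shortest_path(
        csr_matrix(net.contact_counts > 0), method="BF", unweighted=True, indices=i
    )
    return d


def scaled_profile(raw: np.ndarray, initiation, net: AffinityNetwork) -> np.ndarray:
    """Multiply each EVT value by its hop distance from the initiation node.

    Highlights residues that are both strongly visited and far from the
    perturbation site (candidate remote regulatory sites); the initiation
    node itself scales to 0.
    """
    d = hop_distances(net, initiation)
    if np.any(np.isinf(d)):
        bad = [str(net.nodes[i]) for i in np.flatnonzero(np.isinf(d))]
        raise ValueError(f"nodes unreachable from initiation: {bad}")
    return np.asarray(raw, dtype=float) * d


def profile_ratio(p_a: EVTProfile, p_b: EVTProfile) -> np.ndarray:
    """Relative EVT change between two structures' profiles: raw_a / raw_b - 1.

    Both profiles must cover the same node set (matched by node identity) and
    share the initiation node; used e.g. to compare light- and dark-state
    structures of the same protein.
    """
    if p_a.initiation != p_b.initiation:
        raise ValueError(
            f"initiation mismatch: {p_a.initiation} vs {p_b.initiation}"
        )
    if list(p_a.nodes) != list(p_b.nodes):
        only_a = [str(x) for x in p_a.nodes if x not in set(p_b.nodes)]
        only_b = [str(x) for x in p_b.nodes if x not in set(p_a.nodes)]
        if only_a or only_b:
            raise ValueError(
                f"node sets differ; only in first: {only_a}; only in second: {only_b}"
            )
        # same set, different order: align b to a
        order = [p_b.nodes.index(x) for x in p_a.nodes]
        raw_b = np.asarray(p_b.raw)[order]
    else:
        raw_b = np.asarray(p_b.raw)
    return np.asarray(p_a.raw) / raw_b - 1.0


def average_evt(evt: EVTMatrix) -> np.ndarray:
    """Average signal traffic: column sums of M over all initiation nodes.

    A betweenness-like centrality — high-traffic nodes bridge many
    site-to-site communication events.
    """
    return evt.M.sum(axis=0)


def profile_correlation_scan(
    model: StructureModel, initiation, cutoffs
) -> tuple[np.ndarray, list[float], dict[float, str]]:
    """Pearson correlations between EVT profiles computed at different cutoffs.

    Returns ``(corr, used_cutoffs, failures)`` where ``corr`` is the symmetric
    correlation matrix over ``used_cutoffs`` (unit diagonal) and ``failures``
    maps each cutoff whose network was unusable (disconnected, no contacts)
    to the reason it was excluded.
    """
    profiles = []
    used: list[float] = []
    failures: dict[float, str] = {}
    for c in cutoffs:
        try:
            prof = evt_profile(model, initiation, cutoff=float(c))
        except ValueError as exc:
            failures[float(c)] = str(exc)
            continue
        profiles.append(prof.raw)
        used.append(float(c))
    if len(profiles) < 1:
        raise ValueError(f"no cutoff produced a usable network: {failures}")
    corr = np.corrcoef(np.vstack(profiles)) if len(profiles) > 1 else np.ones((1, 1))
    corr = np.atleast_2d(corr)
    return corr, used, failures
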