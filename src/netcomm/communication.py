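"""Directed communication-efficiency matrices for weighted networks.

Four models are implemented:

``sp``
    Shortest-path efficiency ``E_sp(i,j) = 1/dist(i,j)`` on connection
    lengths — a centralized benchmark, exactly symmetric on undirected
    networks.
``nav``
    Navigation (greedy routing): forward the signal to the current node's
    neighbor closest in Euclidean distance to the target; fail on the first
    revisit.  ``E_nav(i,j) = 1/Λ_ij`` with ``Λ`` the accumulated connection
    length (or hop count in binary mode); failed routes get efficiency 0.
``dif``
    Diffusion efficiency ``E_dif(i,j) = 1/H_ij`` where ``H_ij`` is the mean
    first-passage (hitting) time of an unbiased random walker from i to j.
``si``
    Search information: ``SI_ij = -log2 P(Ω_ij)`` with ``P(Ω_ij)`` the
    probability that a random walker spontaneously follows the shortest
    path ``Ω_ij``; ``E_si = -SI`` (≤ 0, larger = more accessible route).

Navigation, diffusion, and search information are decentralized and may be
asymmetric even on undirected networks, which is the source of the
send-receive asymmetry this package quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import breadth_first_order, dijkstra

from .network import (
    ValidationError,
    WeightedNetwork,
    euclidean_distance_matrix,
    read_manifest,
    read_network,
    threshold_to_density,
    weight_to_length,
)

__all__ = [
    "MEASURES",
    "CommunicationMatrix",
    "NavigationResult",
    "CohortTensor",
    "shortest_paths",
    "canonical_shortest_path",
    "shortest_path_efficiency",
    "navigate",
    "navigation_efficiency",
    "transition_matrix",
    "diffusion_efficiency",
    "search_information_efficiency",
    "compute_measure",
    "cohort_communication",
]

MEASURES = ("sp", "nav", "dif", "si")

_PATH_TOL = 1e-12  # relative tolerance for shortest-path optimality checks


@dataclass
class CommunicationMatrix:
    """An N×N matrix of directed communication efficiencies under one model."""

    eff: np.ndarray
    measure: str
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.eff = np.asarray(self.eff, dtype=float)
        if self.measure not in MEASURES:
            raise ValidationError(f"unknown measure {self.measure!r}")


@dataclass
class NavigationResult:
    """Per-pair outcome of greedy navigation.

    ``hops`` and ``pathlength`` are ``inf`` exactly where navigation failed;
    successful paths (node index sequences) are stored in ``paths``.
    """

    hops: np.ndarray
    pathlength: np.ndarray
    paths: dict[tuple[int, int], tuple[int, ...]]


@dataclass
class CohortTensor:
    """N×N×K stack of communication (or coupling-strength) matrices."""

    values: np.ndarray
    subject_ids: list[str]
    measure: str
    labels: list[str] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"cohort tensor must be N×N×K, got {v.shape}")
        if v.shape[2] != len(self.subject_ids):
            raise ValidationError("subject_ids length does not match tensor depth")
        self.values = v

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[2]


# ---------------------------------------------------------------------------
# Shortest paths
# ---------------------------------------------------------------------------

def _lengths_to_graph(lengths: np.ndarray) -> csr_array:
    m = np.asarray(lengths, dtype=float)
    if (m[np.isfinite(m)] < 0).any():
        raise ValidationError("negative connection lengths")
    finite = np.isfinite(m)
    np.fill_diagonal(finite, False)
    g = np.where(finite, m, 0.0)
    return csr_array(g)


def shortest_paths(lengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs shortest-path distances and predecessors on a length matrix.

    Non-edges are encoded as ``inf`` in ``lengths``.  Returns ``(dist,
    predecessors)`` as produced by Dijkstra; unreachable pairs have
    ``dist = inf``.
    """
    dist, pred = dijkstra(_lengths_to_graph(lengths), directed=True,
                          return_predecessors=True)
    return dist, pred


def canonical_shortest_path(lengths: np.ndarray, dist: np.ndarray,
                            source: int, target: int) -> tuple[int, ...] | None:
    """One deterministic shortest path from ``source`` to ``target``.

    The path is rebuilt greedily from the optimality condition
    ``L(u, v) + dist(v, target) == dist(u, target)``; among co-optimal next
    steps the lowest node index wins, so the selected path is identical
    across runs and platforms.  Returns ``None`` for unreachable pairs.
    """
    if source == target:
        return (source,)
    d_t = dist[:, target]
    if not np.isfinite(d_t[source]):
        return None
    path = [source]
    u = source
    while u != target:
        row = lengths[u]
        tol = _PATH_TOL * max(1.0, d_t[u])
        with np.errstate(invalid="ignore"):
            ok = np.isfinite(row) & (np.abs(row + d_t - d_t[u]) <= tol)
        nxt = int(np.flatnonzero(ok)[0])
        path.append(nxt)
        u = nxt
    return tuple(path)


def shortest_path_efficiency(lengths: np.ndarray,
                             labels: Sequence[str] | None = None) -> CommunicationMatrix:
    """``E_sp(i,j) = 1/dist(i,j)``; 0 for unreachable pairs, 0 diagonal."""
    dist, _ = shortest_paths(lengths)
    m = np.asarray(lengths, dtype=float)
    if np.array_equal(m, m.T):
        # dist is mathematically symmetric on symmetric lengths; per-source
        # floating summation order can differ, so pick one branch exactly
        dist = np.minimum(dist, dist.T)
    with np.errstate(divide="ignore"):
        eff = np.where(np.isfinite(dist) & (dist > 0), 1.0 / dist, 0.0)
    np.fill_diagonal(eff, 0.0)
    return CommunicationMatrix(eff, "sp", labels=None if labels is None else list(labels))


# ---------------------------------------------------------------------------
# Navigation (greedy routing)
# ---------------------------------------------------------------------------

def navigate(net: WeightedNetwork, dist: np.ndarray | None = None,
             lengths: np.ndarray | None = None,
             store_paths: bool = True) -> NavigationResult:
    """Greedy spatial routing between every ordered node pair.

    At each step the signal moves from the current node to its neighbor
    closest in Euclidean distance to the target; revisiting any node means
    failure.  ``lengths=None`` accumulates hop counts; otherwise the summed
    connection lengths along the realized route.  Ties between equidistant
    neighbors are broken by lowest node index.
    """
    if dist is None:
        if net.coordinates is None:
            raise ValidationError("navigation requires node coordinates or a distance matrix")
        dist = euclidean_distance_matrix(net.coordinates)
    n = net.n_nodes
    w = net.weights
    # successor[u, t]: the neighbor of u nearest to target t (lowest index on ties)
    successor = np.full((n, n), -1, dtype=int)
    for u in range(n):
        nbrs = np.flatnonzero(w[u] > 0)
        if nbrs.size:
            successor[u] = nbrs[np.argmin(dist[nbrs], axis=0)]
    hops = np.full((n, n), np.inf)
    lam = np.full((n, n), np.inf)
    np.fill_diagonal(hops, 0.0)
    np.fill_diagonal(lam, 0.0)
    paths: dict[tuple[int, int], tuple[int, ...]] = {}
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            u, route, visited = s, [s], {s}
            total = 0.0
            ok = False
            while True:
                v = successor[u, t]
                if v < 0:
                    break
                total += 1.0 if lengths is None else lengths[u, v]
                route.append(v)
                if v == t:
                    ok = True
                    break
                if v in visited:
                    break
                visited.add(v)
                u = v
            if ok:
                hops[s, t] = len(route) - 1
                lam[s, t] = total
                if store_paths:
                    paths[(s, t)] = tuple(route)
    return NavigationResult(hops=hops, pathlength=lam, paths=paths)


def navigation_efficiency(navres: NavigationResult, binary: bool = False,
                          labels: Sequence[str] | None = None) -> CommunicationMatrix:
    """``E_nav = 1/Λ`` (or ``1/hops`` in binary mode); failures map to 0."""
    lam = navres.hops if binary else navres.pathlength
    with np.errstate(divide="ignore"):
        eff = np.where(np.isfinite(lam) & (lam > 0), 1.0 / lam, 0.0)
    np.fill_diagonal(eff, 0.0)
    return CommunicationMatrix(eff, "nav", labels=None if labels is None else list(labels))


# ---------------------------------------------------------------------------
# Random walks: transition matrix, diffusion, search information
# ---------------------------------------------------------------------------

def transition_matrix(net: WeightedNetwork) -> np.ndarray:
    """Row-stochastic random-walk transition matrix ``T_ij = W_ij / Σ_n W_in``."""
    s = net.weights.sum(axis=1)
    dead = np.flatnonzero(s == 0)
    if dead.size:
        raise ValidationError(
            f"zero-strength node {net.labels[dead[0]]!r}: random walk undefined"
        )
    return net.weights / s[:, None]


def _reaching_set(weights: np.ndarray, target: int) -> np.ndarray:
    """Indices of nodes with a directed path to ``target`` (including it)."""
    rev = csr_array((weights > 0).T.astype(float))
    order = breadth_first_order(rev, target, directed=True, return_predecessors=False)
    return np.sort(order)


def diffusion_efficiency(net: WeightedNetwork) -> tuple[CommunicationMatrix, np.ndarray]:
    """Mean first-passage times H and diffusion efficiency ``E_dif = 1/H``.

    For each target j the hitting times of all sources solve the linear
    system ``(I - T_{-j}) h = 1`` on the nodes that can reach j, where
    ``T_{-j}`` is the transition matrix restricted to those nodes with j
    removed.  Pairs that cannot reach the target get ``H = inf`` and
    efficiency 0.
    """
    n = net.n_nodes
    if n > 2048:
        raise ValidationError("dense MFPT solve limited to N <= 2048; chunk the network")
    T = transition_matrix(net)
    H = np.full((n, n), np.inf)
    np.fill_diagonal(H, 0.0)
    eye = np.eye(n)
    for j in range(n):
        reach = _reaching_set(net.weights, j)
        others = reach[reach != j]
        if others.size == 0:
            continue
        A = eye[np.ix_(others, others)] - T[np.ix_(others, others)]
        h = np.linalg.solve(A, np.ones(others.size))
        H[others, j] = h
    with np.errstate(divide="ignore"):
        eff = np.where(np.isfinite(H) & (H > 0), 1.0 / H, 0.0)
    np.fill_diagonal(eff, 0.0)
    return CommunicationMatrix(eff, "dif", labels=list(net.labels)), H


def search_information_efficiency(net: WeightedNetwork,
                                  lengths: np.ndarray | None = None,
                                  all_paths: bool = False) -> CommunicationMatrix:
    """``E_si(i,j) = -SI_ij = log2 P(Ω_ij)`` — accessibility of shortest paths.

    ``P(Ω_ij)`` is the product of random-walk transition probabilities along
    the canonical shortest path from i to j.  With ``all_paths=True`` the
    probability is summed over all co-optimal shortest paths instead.
    Unreachable pairs get ``-inf``; the diagonal is 0.
    """
    if lengths is None:
        lengths = weight_to_length(net)
    T = transition_matrix(net)
    dist, _ = shortest_paths(lengths)
    n = net.n_nodes
    eff = np.full((n, n), -np.inf)
    np.fill_diagonal(eff, 0.0)
    with np.errstate(divide="ignore"):
        logT = np.where(T > 0, np.log2(np.where(T > 0, T, 1.0)), -np.inf)
    for i in range(n):
        if all_paths:
            p = _all_shortest_path_probability(lengths, dist, T, i)
            with np.errstate(divide="ignore"):
                row = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), -np.inf)
            row[i] = 0.0
            eff[i] = row
            continue
        for j in range(n):
            if i == j or not np.isfinite(dist[i, j]):
                continue
            path = canonical_shortest_path(lengths, dist, i, j)
            eff[i, j] = sum(logT[u, v] for u, v in zip(path[:-1], path[1:]))
    return CommunicationMatrix(eff, "si", labels=list(net.labels))


def _all_shortest_path_probability(lengths: np.ndarray, dist: np.ndarray,
                                   T: np.ndarray, source: int) -> np.ndarray:
    """P(walker from ``source`` reaches j along some shortest path), all j."""
    n = dist.shape[0]
    d = dist[source]
    p = np.zeros(n)
    p[source] = 1.0
    order = np.argsort(d, kind="stable")
    for v in order:
        if v == source or not np.isfinite(d[v]):
            continue
        tol = _PATH_TOL * max(1.0, d[v])
        col = lengths[:, v]
        with np.errstate(invalid="ignore"):
            preds = np.isfinite(col) & (np.abs(d + col - d[v]) <= tol)
        p[v] = float((p[preds] * T[preds, v]).sum())
    return p


# ---------------------------------------------------------------------------
# Cohort pipeline
# ---------------------------------------------------------------------------

def compute_measure(net: WeightedNetwork, measure: str,
                    dist: np.ndarray | None = None,
                    binary_nav: bool = False) -> CommunicationMatrix:
    """Dispatch one communication measure on a (already thresholded) network."""
    if measure == "sp":
        return shortest_path_efficiency(weight_to_length(net), labels=net.labels)
    if measure == "nav":
        lengths = None if binary_nav else weight_to_length(net)
        navres = navigate(net, dist=dist, lengths=lengths, store_paths=False)
        return navigation_efficiency(navres, binary=binary_nav, labels=net.labels)
    if measure == "dif":
        return diffusion_efficiency(net)[0]
    if measure == "si":
        return search_information_efficiency(net)
    raise ValidationError(f"unknown measure {measure!r}; choose from {MEASURES}")


def cohort_communication(networks: Sequence[WeightedNetwork] | str | Path,
                         measure: str,
                         density: float | None = None,
                         binary_nav: bool = False,
                         coordinates: np.ndarray | None = None,
                         subject_ids: Sequence[str] | None = None,
                         directed: bool = False) -> CohortTensor:
    """Apply the per-subject pipeline (threshold → transform → measure)
    identically across a cohort and stack the results into an N×N×K tensor.

    ``networks`` may be a manifest file path (one matrix path per line) or a
    sequence of loaded networks sharing one node set and ordering.
    """
    if isinstance(networks, (str, Path)):
        paths = read_manifest(networks)
        nets = [read_network(p, directed=directed) for p in paths]
        ids = [Path(p).stem for p in paths]
    else:
        nets = list(networks)
        ids = [f"s{k}" for k in range(len(nets))]
    if subject_ids is not None:
        ids = [str(s) for s in subject_ids]
    if not nets:
        raise ValidationError("empty cohort")
    ref = nets[0].labels
    for sid, net in zip(ids, nets):
        if net.labels != ref:
            raise ValidationError(f"subject {sid!r} node set differs from first subject")
    dist = None
    if measure == "nav":
        coords = coordinates
        if coords is None:
            coords = nets[0].coordinates
        if coords is None:
            raise ValidationError("measure 'nav' requires node coordinates")
        dist = euclidean_distance_matrix(coords)
    slices = []
    for net in nets:
        sub = threshold_to_density(net, density) if density is not None else net
        slices.append(compute_measure(sub, measure, dist=dist, binary_nav=binary_nav).eff)
    values = np.stack(slices, axis=2)
    prov = {"measure": measure, "density": density, "binary_nav": binary_nav,
            "n_subjects": len(nets), "n_nodes": len(ref)}
    return CohortTensor(values, subject_ids=ids, measure=measure,
                        labels=list(ref), provenance=prov)
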