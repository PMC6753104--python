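"""Randomized-network null models and empirical p-values.

Three ensembles, each preserving a different aspect of the observed
connectome:

* degree-preserving rewiring — double-edge swaps that keep every node's
  degree while randomizing topology (weights travel with their edges);
* cost-preserving rewiring — degree-preserving swaps additionally
  constrained to keep the total network cost (the summed Euclidean length
  of all connections) within a tolerance of the original;
* spatial repositioning — a random permutation of the existing node
  coordinates, leaving topology untouched.

Observed statistics are compared against an ensemble with the standard
add-one empirical p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .network import ValidationError, WeightedNetwork, euclidean_distance_matrix

__all__ = [
    "NullEnsemble",
    "rewire_degree_preserving",
    "rewire_cost_preserving",
    "reposition_nodes",
    "generate_ensemble",
    "empirical_null_pvalue",
]


@dataclass
class NullEnsemble:
    """A list of randomized surrogates with generation metadata."""

    members: list
    generator: str
    seed: int | None
    info: list[dict] = field(default_factory=list)


def _edge_list(net: WeightedNetwork) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = np.triu_indices(net.n_nodes, k=1)
    mask = net.weights[iu, ju] > 0
    edges = np.stack([iu[mask], ju[mask]], axis=1)
    return edges, net.weights[iu[mask], ju[mask]].copy()


def _edges_to_weights(n: int, edges: np.ndarray, w: np.ndarray) -> np.ndarray:
    out = np.zeros((n, n))
    out[edges[:, 0], edges[:, 1]] = w
    out[edges[:, 1], edges[:, 0]] = w
    return out


def _swap_once(edges: np.ndarray, adj: set, rng: np.random.Generator) -> tuple[int, int] | None:
    """Propose one double-edge swap; return the two edge indices if valid."""
    m = edges.shape[0]
    e1, e2 = rng.integers(0, m, size=2)
    if e1 == e2:
        return None
    a, b = edges[e1]
    c, d = edges[e2]
    if rng.random() < 0.5:
        c, d = d, c
    # proposed new edges: a-d, c-b
    if a == d or c == b or a == c or b == d:
        return None
    if (min(a, d), max(a, d)) in adj or (min(c, b), max(c, b)) in adj:
        return None
    return int(e1), int(e2), int(c), int(d)  # type: ignore[return-value]


def rewire_degree_preserving(net: WeightedNetwork, n_swaps_per_edge: int = 10,
                             seed: int | None = None) -> tuple[WeightedNetwork, dict]:
    """Randomize topology with degree-preserving double-edge swaps.

    Swaps (a–b, c–d) → (a–d, c–b) are rejected if they would create
    self-loops or multi-edges; weights travel with their edges, so the
    weight multiset and every node degree are exactly preserved.  Stops
    after ``n_swaps_per_edge × |E|`` accepted swaps (a standard mixing
    budget) or a proportional attempt cap.
    """
    if net.directed:
        raise ValidationError("rewiring is implemented for undirected networks")
    edges, w = _edge_list(net)
    m = edges.shape[0]
    if m < 2:
        warnings.warn("fewer than 2 edges: nothing to rewire")
        return net.with_weights(net.weights.copy()), {"n_accepted": 0, "n_attempts": 0}
    rng = np.random.default_rng(seed)
    adj = {(int(a), int(b)) for a, b in edges}
    target = n_swaps_per_edge * m
    max_attempts = 100 * target
    accepted = attempts = 0
    while accepted < target and attempts < max_attempts:
        attempts += 1
        prop = _swap_once(edges, adj, rng)
        if prop is None:
            continue
        e1, e2, c, d = prop
        a, b = edges[e1]
        adj.discard((min(a, b), max(a, b)))
        old_c, old_d = edges[e2]
        adj.discard((min(old_c, old_d), max(old_c, old_d)))
        edges[e1] = (min(a, d), max(a, d))
        edges[e2] = (min(c, b), max(c, b))
        adj.add(tuple(edges[e1]))
        adj.add(tuple(edges[e2]))
        accepted += 1
    if accepted == 0:
        warnings.warn("no swappable edge pair found; returning input unchanged")
    out = net.with_weights(_edges_to_weights(net.n_nodes, edges, w))
    return out, {"n_accepted": accepted, "n_attempts": attempts}


def network_cost(net: WeightedNetwork, coords: np.ndarray) -> float:
    """Total network cost: sum of Euclidean distances between connected nodes."""
    dist = euclidean_distance_matrix(coords)
    iu, ju = np.triu_indices(net.n_nodes, k=1)
    mask = net.weights[iu, ju] > 0
    return float(dist[iu[mask], ju[mask]].sum())


def rewire_cost_preserving(net: WeightedNetwork, coords: np.ndarray | None = None,
                           tolerance: float = 0.025,
                           n_swaps_per_edge: int = 10,
                           seed: int | None = None,
                           max_attempts: int | None = None) -> tuple[WeightedNetwork, dict]:
    """Degree-preserving rewiring constrained to preserve total network cost.

    A proposed swap is accepted if the rewired cost stays within
    ``tolerance`` (relative) of the original cost, or if it moves the cost
    closer to the original (annealed acceptance, which lets the chain escape
    early drift).  The achieved relative cost deviation is reported.
    """
    if coords is None:
        coords = net.coordinates
    if coords is None:
        raise ValidationError("cost-preserving rewiring requires coordinates")
    dist = euclidean_distance_matrix(coords)
    edges, w = _edge_list(net)
    m = edges.shape[0]
    if m < 2:
        warnings.warn("fewer than 2 edges: nothing to rewire")
        return net.with_weights(net.weights.copy()), {"n_accepted": 0, "cost_deviation": 0.0}
    rng = np.random.default_rng(seed)
    adj = {(int(a), int(b)) for a, b in edges}
    cost0 = float(dist[edges[:, 0], edges[:, 1]].sum())
    cost = cost0
    target = n_swaps_per_edge * m
    if max_attempts is None:
        max_attempts = 200 * target
    accepted = attempts = 0
    while accepted < target and attempts < max_attempts:
        attempts += 1
        prop = _swap_once(edges, adj, rng)
        if prop is None:
            continue
        e1, e2, c, d = prop
        a, b = edges[e1]
        old_c, old_d = edges[e2]
        delta = (dist[a, d] + dist[c, b]) - (dist[a, b] + dist[old_c, old_d])
        new_cost = cost + delta
        within = abs(new_cost - cost0) / cost0 <= tolerance
        improves = abs(new_cost - cost0) < abs(cost - cost0)
        if not (within or improves):
            continue
        adj.discard((min(a, b), max(a, b)))
        adj.discard((min(old_c, old_d), max(old_c, old_d)))
        edges[e1] = (min(a, d), max(a, d))
        edges[e2] = (min(c, b), max(c, b))
        adj.add(tuple(edges[e1]))
        adj.add(tuple(edges[e2]))
        cost = new_cost
        accepted += 1
    deviation = abs(cost - cost0) / cost0
    if deviation > tolerance:
        warnings.warn(
            f"cost deviation {deviation:.4f} exceeds tolerance {tolerance}; best effort returned"
        )
    out = net.with_weights(_edges_to_weights(net.n_nodes, edges, w))
    info = {"n_accepted": accepted, "n_attempts": attempts,
            "cost_deviation": float(deviation), "cost_original": cost0,
            "cost_final": float(cost)}
    return out, info


def reposition_nodes(coords: np.ndarray, seed: int | None = None,
                     resample_uniform: bool = False) -> np.ndarray:
    """Randomly reassign node positions, leaving topology untouched.

    By default the existing coordinate rows are permuted over node
    identities, preserving the coordinate multiset and therefore the
    inter-point distance distribution.  ``resample_uniform=True`` instead
    draws fresh positions uniformly in the bounding box of the input.
    """
    c = np.atleast_2d(np.asarray(coords, dtype=float))
    rng = np.random.default_rng(seed)
    if resample_uniform:
        lo, hi = c.min(axis=0), c.max(axis=0)
        return rng.uniform(lo, hi, size=c.shape)
    return c[rng.permutation(c.shape[0])]


def generate_ensemble(net: WeightedNetwork, kind: str, n: int,
                      seed: int | None = None, **kwargs) -> NullEnsemble:
    """Generate ``n`` surrogates of one kind: 'degree', 'cost', or 'reposition'.

    Member k uses the derived seed ``seed + k`` so the ensemble is
    reproducible and members are independent.
    """
    base = 0 if seed is None else int(seed)
    members, info = [], []
    for k in range(n):
        s = base + k
        if kind == "degree":
            surrogate, meta = rewire_degree_preserving(net, seed=s, **kwargs)
        elif kind == "cost":
            surrogate, meta = rewire_cost_preserving(net, seed=s, **kwargs)
        elif kind == "reposition":
            coords = kwargs.get("coords", net.coordinates)
            if coords is None:
                raise ValidationError("repositioning requires coordinates")
            new_coords = reposition_nodes(coords, seed=s)
            surrogate = WeightedNetwork(net.weights.copy(), directed=net.directed,
                                        labels=list(net.labels), coordinates=new_coords)
            meta = {}
        else:
            raise ValidationError(f"unknown null kind {kind!r}")
        members.append(surrogate)
        info.append(meta)
    return NullEnsemble(members=members, generator=kind, seed=seed, info=info)


def empirical_null_pvalue(observed: float, nulls, side: str = "greater") -> float:
    """Add-one empirical p-value of an observed statistic against nulls.

    ``p = (1 + #{nulls at least as extreme}) / (1 + n_null)``.  ``side``
    'greater' counts nulls >= observed, 'less' counts nulls <= observed,
    'two' doubles the smaller one-sided p (capped at 1).
    """
    nulls = np.asarray(list(nulls), dtype=float)
    if nulls.size == 0:
        raise ValidationError("need at least one null value")
    n = nulls.size
    p_greater = (1 + int((nulls >= observed).sum())) / (1 + n)
    p_less = (1 + int((nulls <= observed).sum())) / (1 + n)
    if side == "greater":
        return p_greater
    if side == "less":
        return p_less
    if side == "two":
        return min(1.0, 2.0 * min(p_greater, p_less))
    raise ValidationError(f"unknown side {side!r}")
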