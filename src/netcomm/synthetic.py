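"""Synthetic networks and cohorts, plus Monte-Carlo random-walk oracles.

These generators emulate the statistical structure the asymmetry analyses
assume — spatially embedded weighted networks at a controlled connection
density, per-subject weight noise around a group network, and directed
variants with planted directionality — so every stage of the pipeline can
be exercised and validated without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .communication import CohortTensor, transition_matrix
from .network import (
    ValidationError,
    WeightedNetwork,
    connected_components,
    euclidean_distance_matrix,
)

__all__ = [
    "toy_network",
    "canonical_graph",
    "CohortSpec",
    "generate_geometric_cohort",
    "generate_directed_geometric_network",
    "generate_null_tensor",
    "noisy_subjects_from_group",
    "noisy_tensor_from_matrix",
    "monte_carlo_hitting_times",
    "monte_carlo_path_probability",
]


def toy_network() -> WeightedNetwork:
    """The six-node spatially embedded demonstration network.

    Unweighted and undirected, with nodes ``i, x, c, b, y, j`` placed in the
    plane so that greedy navigation from i to j follows i-c-b-j (3 hops,
    efficiency 1/3) while the reverse route is j-b-i (2 hops, efficiency
    1/2), the unique fewest-hop path between i and j is i-b-j, and a random
    walker leaving i picks each of i's 3 connections with probability 1/3.
    A minimal worked example of send-receive asymmetry on an undirected
    network.
    """
    labels = ["i", "x", "c", "b", "y", "j"]
    coords = np.array([
        [0.0, 0.0],    # i
        [-2.0, 0.0],   # x
        [4.0, 0.0],    # c
        [5.0, 5.0],    # b
        [6.0, 6.0],    # y
        [10.0, 0.0],   # j
    ])
    edges = [("i", "x"), ("i", "c"), ("i", "b"), ("c", "b"), ("b", "y"), ("b", "j")]
    n = len(labels)
    w = np.zeros((n, n))
    idx = {l: k for k, l in enumerate(labels)}
    for a, b in edges:
        w[idx[a], idx[b]] = w[idx[b], idx[a]] = 1.0
    return WeightedNetwork(w, directed=False, labels=labels, coordinates=coords)


def canonical_graph(kind: str, n: int) -> WeightedNetwork:
    """Unit-weight path, cycle, complete, or star graph with coordinates.

    Paths are collinear; cycles and complete graphs sit on a regular
    polygon; stars have the hub at the origin and leaves on a circle.
    Useful as closed-form substrates (e.g., mean hitting time n−1 between
    any two nodes of the complete graph).
    """
    if n < 2:
        raise ValidationError(f"need n >= 2 nodes, got {n}")
    w = np.zeros((n, n))
    if kind == "path":
        for k in range(n - 1):
            w[k, k + 1] = w[k + 1, k] = 1.0
        coords = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    elif kind == "cycle":
        if n < 3:
            raise ValidationError("a cycle needs n >= 3")
        for k in range(n):
            w[k, (k + 1) % n] = w[(k + 1) % n, k] = 1.0
        ang = 2 * np.pi * np.arange(n) / n
        coords = np.column_stack([np.cos(ang), np.sin(ang)])
    elif kind == "complete":
        w[:] = 1.0
        ang = 2 * np.pi * np.arange(n) / n
        coords = np.column_stack([np.cos(ang), np.sin(ang)])
    elif kind == "star":
        w[0, 1:] = 1.0
        w[1:, 0] = 1.0
        ang = 2 * np.pi * np.arange(n - 1) / (n - 1)
        coords = np.vstack([[0.0, 0.0], np.column_stack([np.cos(ang), np.sin(ang)])])
    else:
        raise ValidationError(f"unknown graph kind {kind!r}")
    return WeightedNetwork(w, directed=False, coordinates=coords)


@dataclass
class CohortSpec:
    """Parameters of the synthetic geometric cohort.

    Defaults describe a small spatially embedded cohort: 60 regions at 15%
    connection density (the focal density of connectome thresholding), 20
    subjects, distance-dependent connectivity with decay rate 2 per unit
    distance in the unit cube, log-normal weights assigned so longer
    connections are weaker, and 5% multiplicative per-subject weight noise.
    """

    n_nodes: int = 60
    n_subjects: int = 20
    target_density: float = 0.15
    spatial_decay: float = 2.0
    weight_mu: float = 0.0
    weight_sigma: float = 1.0
    noise_sd: float = 0.05
    edge_jitter: float = 0.0
    seed: int = 0
    max_retries: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.target_density <= 1:
            raise ValidationError("density must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise sd must be >= 0")


def _geometric_group_network(n: int, density: float, decay: float,
                             weight_mu: float, weight_sigma: float,
                             rng: np.random.Generator,
                             max_retries: int) -> WeightedNetwork:
    """One connected geometric network with distance-coupled weights."""
    m_target = int(np.floor(density * n * (n - 1) / 2))
    if m_target < n - 1:
        raise ValidationError(
            f"density {density} gives {m_target} edges; {n - 1} needed for connectivity"
        )
    for _ in range(max_retries):
        coords = rng.uniform(size=(n, 3))
        dist = euclidean_distance_matrix(coords)
        iu, ju = np.triu_indices(n, k=1)
        # sample edges with probability proportional to exp(-decay * distance):
        # keep the m_target pairs with the largest exp(-decay*d) * u scores
        score = np.exp(-decay * dist[iu, ju]) * rng.uniform(size=iu.size)
        keep = np.argsort(-score, kind="stable")[:m_target]
        w = np.zeros((n, n))
        # log-normal weights, inversely rank-associated with distance
        weights = np.sort(rng.lognormal(weight_mu, weight_sigma, size=m_target))[::-1]
        order = np.argsort(dist[iu[keep], ju[keep]], kind="stable")
        ki, kj = iu[keep][order], ju[keep][order]
        w[ki, kj] = weights
        w[kj, ki] = weights
        net = WeightedNetwork(w, directed=False, coordinates=coords)
        if connected_components(net)[0] == 1:
            return net
    raise ValidationError("could not generate a connected network within the retry budget")


def noisy_subjects_from_group(group: WeightedNetwork, n_subjects: int,
                              noise_sd: float, seed: int = 0,
                              edge_jitter: float = 0.0) -> list[WeightedNetwork]:
    """K per-subject variants of one group network.

    Each subject's weights are the group weights multiplied by i.i.d.
    log-normal noise on the upper triangle (then mirrored, so subjects stay
    symmetric).  ``edge_jitter`` optionally moves a fraction of each
    subject's edges to random unconnected pairs, emulating
    subject-specific false positives/negatives.
    """
    rng = np.random.default_rng(seed)
    n = group.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    subjects = []
    for _ in range(n_subjects):
        w = group.weights.copy()
        if noise_sd > 0:
            noise = rng.lognormal(0.0, noise_sd, size=iu.size)
            w[iu, ju] *= noise
            w[ju, iu] = w[iu, ju]
        if edge_jitter > 0:
            w = _jitter_edges(w, edge_jitter, rng)
        subjects.append(WeightedNetwork(w, directed=False,
                                        labels=list(group.labels),
                                        coordinates=None if group.coordinates is None
                                        else group.coordinates.copy()))
    return subjects


def generate_geometric_cohort(spec: CohortSpec) -> tuple[list[WeightedNetwork], WeightedNetwork]:
    """A group network plus K per-subject noisy variants.

    The group network is geometric (distance-dependent connectivity at the
    target density, long connections weaker); subjects share its topology
    with multiplicative log-normal weight noise.  Fully reproducible from
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    group = _geometric_group_network(spec.n_nodes, spec.target_density,
                                     spec.spatial_decay, spec.weight_mu,
                                     spec.weight_sigma, rng, spec.max_retries)
    subject_seed = int(rng.integers(0, 2**31 - 1))
    subjects = noisy_subjects_from_group(group, spec.n_subjects, spec.noise_sd,
                                         seed=subject_seed,
                                         edge_jitter=spec.edge_jitter)
    return subjects, group


def _jitter_edges(w: np.ndarray, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Move a fraction of edges (with their weights) to random empty pairs."""
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    present = np.flatnonzero(vals > 0)
    absent = np.flatnonzero(vals == 0)
    k = min(int(round(fraction * present.size)), absent.size)
    if k == 0:
        return w
    move = rng.choice(present, size=k, replace=False)
    dest = rng.choice(absent, size=k, replace=False)
    vals[dest] = vals[move]
    vals[move] = 0.0
    out = np.zeros_like(w)
    out[iu, ju] = vals
    out[ju, iu] = vals
    return out


def generate_directed_geometric_network(n_nodes: int = 60,
                                        reciprocity: float = 0.5,
                                        planted_fraction: float = 0.2,
                                        density: float = 0.15,
                                        extra_edges: int = 10,
                                        spatial_decay: float = 2.0,
                                        seed: int = 0) -> tuple[WeightedNetwork, np.ndarray]:
    """A directed geometric network with planted sender and receiver nodes.

    Starting from an undirected geometric substrate, each edge becomes
    reciprocal with probability ``reciprocity`` and one-way (random
    direction) otherwise.  A ``planted_fraction`` of nodes are designated
    senders and the same fraction receivers: senders gain ``extra_edges``
    outgoing-only connections to random non-neighbors, receivers gain the
    same number of incoming-only ones (at reciprocity 1 the extra
    connections are reciprocal too, so the matrix is exactly symmetric).
    Returns the network and a polarity vector (+1 sender, −1 receiver, 0
    neutral) for recovery benchmarks.
    """
    if not 0 <= reciprocity <= 1:
        raise ValidationError("reciprocity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    base = _geometric_group_network(n_nodes, density, spatial_decay, 0.0, 1.0,
                                    rng, max_retries=20)
    n = n_nodes
    iu, ju = np.triu_indices(n, k=1)
    w = np.zeros((n, n))
    mask = base.weights[iu, ju] > 0
    for a, b, wt in zip(iu[mask], ju[mask], base.weights[iu, ju][mask]):
        if rng.random() < reciprocity:
            w[a, b] = w[b, a] = wt
        elif rng.random() < 0.5:
            w[a, b] = wt
        else:
            w[b, a] = wt
    n_planted = int(round(planted_fraction * n))
    perm = rng.permutation(n)
    senders, receivers = perm[:n_planted], perm[n_planted:2 * n_planted]
    polarity = np.zeros(n, dtype=int)
    polarity[senders] = 1
    polarity[receivers] = -1
    median_w = np.median(base.weights[iu, ju][mask]) if mask.any() else 1.0
    for node, sign in [(s, 1) for s in senders] + [(r, -1) for r in receivers]:
        candidates = np.flatnonzero((w[node] == 0) & (w[:, node] == 0))
        candidates = candidates[candidates != node]
        take = candidates[rng.permutation(candidates.size)[:extra_edges]]
        for t in take:
            if rng.random() < reciprocity:
                w[node, t] = w[t, node] = median_w
            elif sign > 0:
                w[node, t] = median_w
            else:
                w[t, node] = median_w
    net = WeightedNetwork(w, directed=True, labels=list(base.labels),
                          coordinates=base.coordinates.copy())
    return net, polarity


def generate_null_tensor(n_nodes: int = 20, n_subjects: int = 20,
                         noise_sd: float = 1.0, base_scale: float = 10.0,
                         seed: int = 0) -> CohortTensor:
    """A cohort tensor with no true directionality.

    Each subject's matrix is one shared symmetric base plus i.i.d. Gaussian
    noise on every directed entry, so the pairwise differences Δ are
    symmetric about zero and any significant asymmetry is a false positive.
    Used to calibrate the type-I error of the asymmetry test.
    """
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_nodes, k=1)
    base = np.zeros((n_nodes, n_nodes))
    base[iu, ju] = rng.uniform(1.0, base_scale, size=iu.size)
    base[ju, iu] = base[iu, ju]
    values = base[:, :, None] + rng.normal(0.0, noise_sd,
                                           size=(n_nodes, n_nodes, n_subjects))
    idx = np.arange(n_nodes)
    values[idx, idx, :] = 0.0
    return CohortTensor(values, subject_ids=[f"s{k}" for k in range(n_subjects)],
                        measure="synthetic")


def noisy_tensor_from_matrix(E: np.ndarray, n_subjects: int,
                             noise_sd: float = 0.05, seed: int = 0,
                             measure: str = "coupling") -> CohortTensor:
    """K noisy subject-level copies of one directed matrix.

    Each entry is multiplied by i.i.d. log-normal noise per subject —
    a stand-in for per-individual variability around a common directed
    coupling structure (e.g., effective connectivity).
    """
    rng = np.random.default_rng(seed)
    e = np.asarray(E, dtype=float)
    n = e.shape[0]
    noise = rng.lognormal(0.0, noise_sd, size=(n, n, n_subjects))
    values = e[:, :, None] * noise
    idx = np.arange(n)
    values[idx, idx, :] = 0.0
    return CohortTensor(values, subject_ids=[f"s{k}" for k in range(n_subjects)],
                        measure=measure)


# ---------------------------------------------------------------------------
# Monte-Carlo random-walk oracles
# ---------------------------------------------------------------------------

def monte_carlo_hitting_times(net: WeightedNetwork, n_walkers: int = 10_000,
                              max_steps: int = 100_000,
                              seed: int = 0) -> tuple[np.ndarray, int]:
    """Empirical mean first-passage times from independent random walks.

    For each source node, ``n_walkers`` walkers follow the transition
    matrix; the first-visit step of every node is recorded and averaged.
    Walkers that exceed ``max_steps`` before covering the graph are
    censored (counted and warned about).  Returns ``(H_hat, n_censored)``.
    """
    T = transition_matrix(net)
    n = net.n_nodes
    cum = np.cumsum(T, axis=1)
    rng = np.random.default_rng(seed)
    H_hat = np.zeros((n, n))
    censored = 0
    for source in range(n):
        first = np.full((n_walkers, n), np.inf)
        first[:, source] = 0.0
        pos = np.full(n_walkers, source)
        active = np.arange(n_walkers)
        step = 0
        while active.size and step < max_steps:
            step += 1
            u = rng.random(active.size)
            pos[active] = (cum[pos[active]] < u[:, None]).sum(axis=1)
            rows = first[active, pos[active]]
            first[active, pos[active]] = np.minimum(rows, step)
            done = np.isfinite(first[active]).all(axis=1)
            active = active[~done]
        censored += int(active.size)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            H_hat[source] = np.nanmean(np.where(np.isfinite(first), first, np.nan), axis=0)
    if censored:
        warnings.warn(f"{censored} walkers censored at max_steps={max_steps}")
    return H_hat, censored


def monte_carlo_path_probability(net: WeightedNetwork, path,
                                 n_walkers: int = 100_000,
                                 seed: int = 0) -> float:
    """Fraction of random walkers whose first steps follow ``path`` exactly.

    An independent check of the search-information probability
    ``2^(−SI) = P(Ω)``: walkers start at ``path[0]`` and are required to
    reproduce every subsequent step.
    """
    path = list(path)
    if len(path) < 2:
        raise ValidationError("path must have at least 2 nodes")
    T = transition_matrix(net)
    cum = np.cumsum(T, axis=1)
    rng = np.random.default_rng(seed)
    alive = np.full(n_walkers, True)
    pos = np.full(n_walkers, path[0])
    for nxt in path[1:]:
        u = rng.random(n_walkers)
        stepped = (cum[pos] < u[:, None]).sum(axis=1)
        alive &= stepped == nxt
        pos = stepped
    return float(alive.mean())
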