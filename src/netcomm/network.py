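"""Connectome matrices, spatial embedding, and basic graph summaries.

A connectome is represented as a square nonnegative weight matrix ``W``
whose entries measure affinity between brain regions (streamline density,
tracer fraction, ...).  Communication measures operate on connection
*lengths*, a cost scale obtained from the weights by a monotonically
decreasing log transform, and on the Euclidean distances between region
centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components as _csgraph_components
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ValidationError",
    "WeightedNetwork",
    "read_network",
    "write_network",
    "write_matrix",
    "read_matrix",
    "read_coordinates",
    "write_coordinates",
    "read_partition",
    "read_manifest",
    "threshold_to_density",
    "weight_to_length",
    "symmetrize",
    "binarize",
    "euclidean_distance_matrix",
    "degrees_strengths",
    "participation_coefficient",
    "connected_components",
    "partition_groups",
]

#: symmetric matrices are accepted as undirected up to this absolute deviation
SYMMETRY_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when an input matrix or table violates a structural contract."""


def _default_labels(n: int) -> list[str]:
    return [f"n{k}" for k in range(n)]


@dataclass
class WeightedNetwork:
    """A weighted network with optional spatial embedding.

    Parameters
    ----------
    weights
        Square nonnegative matrix; ``weights[i, j]`` is the connection
        weight (affinity) between nodes ``i`` and ``j``.  The diagonal is
        forced to zero: all measures here are defined between distinct
        regions.
    directed
        If ``False`` the matrix must be symmetric (within ``SYMMETRY_TOL``;
        it is then symmetrized exactly).
    labels
        Unique node identifiers; defaults to ``n0, n1, ...``.
    coordinates
        Optional ``(N, d)`` node positions, ``d`` in ``{2, 3}``, in a single
        consistent length unit.  Required only by navigation and the spatial
        null models.
    """

    weights: np.ndarray
    directed: bool = False
    labels: list[str] = field(default=None)  # type: ignore[assignment]
    coordinates: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError(f"non-square weight matrix with shape {w.shape}")
        bad = np.argwhere(np.isnan(w))
        if bad.size:
            i, j = bad[0]
            raise ValidationError(f"NaN weight at cell ({i}, {j})")
        bad = np.argwhere(w < 0)
        if bad.size:
            i, j = bad[0]
            raise ValidationError(f"negative weight {w[bad[0][0], bad[0][1]]} at cell ({i}, {j})")
        np.fill_diagonal(w, 0.0)
        if not self.directed:
            dev = np.abs(w - w.T).max(initial=0.0)
            if dev > SYMMETRY_TOL:
                i, j = np.unravel_index(np.abs(w - w.T).argmax(), w.shape)
                raise ValidationError(
                    f"undirected network is asymmetric at cell ({i}, {j}): "
                    f"|W[i,j] - W[j,i]| = {dev:g} exceeds {SYMMETRY_TOL:g}"
                )
            w = (w + w.T) / 2.0
        self.weights = w
        if self.labels is None:
            self.labels = _default_labels(w.shape[0])
        else:
            self.labels = [str(x) for x in self.labels]
        if len(self.labels) != w.shape[0]:
            raise ValidationError(
                f"{len(self.labels)} labels for {w.shape[0]} nodes"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("node labels are not unique")
        if self.coordinates is not None:
            c = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
            if c.shape[0] != w.shape[0]:
                raise ValidationError(
                    f"coordinates have {c.shape[0]} rows for {w.shape[0]} nodes"
                )
            if c.shape[1] not in (2, 3):
                raise ValidationError("coordinates must be 2- or 3-dimensional")
            self.coordinates = c

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        """Number of edges (undirected pairs, or directed arcs)."""
        nz = int(np.count_nonzero(self.weights))
        return nz if self.directed else nz // 2

    def with_weights(self, weights: np.ndarray, directed: bool | None = None) -> "WeightedNetwork":
        """A copy of this network carrying a new weight matrix."""
        return WeightedNetwork(
            weights=np.asarray(weights, dtype=float).copy(),
            directed=self.directed if directed is None else directed,
            labels=list(self.labels),
            coordinates=None if self.coordinates is None else self.coordinates.copy(),
        )


# ---------------------------------------------------------------------------
# I/O: delimited text, full float precision
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: Path) -> str:
    first = path.open().readline()
    if "\t" in first:
        return "\t"
    return ","


def read_matrix(path: str | Path, delimiter: str | None = None) -> tuple[np.ndarray, list[str] | None]:
    """Read a square delimited matrix, returning ``(values, labels_or_None)``.

    An optional first row/column of labels is detected by attempting a
    numeric parse of the first row.
    """
    path = Path(path)
    delimiter = delimiter or _sniff_delimiter(path)
    raw = pd.read_csv(path, header=None, sep=delimiter, dtype=str)
    try:
        raw.iloc[0].astype(float)
        has_header = False
    except (ValueError, TypeError):
        has_header = True
    if has_header:
        df = pd.read_csv(path, header=0, index_col=0, sep=delimiter,
                         float_precision="round_trip")
        labels = [str(x) for x in df.index]
        values = df.to_numpy(dtype=float)
    else:
        labels = None
        values = raw.to_numpy(dtype=float)
    return values, labels


def read_network(path: str | Path, directed: bool = False,
                 delimiter: str | None = None,
                 coordinates: np.ndarray | None = None) -> WeightedNetwork:
    """Load and validate a connectome weight matrix from delimited text."""
    values, labels = read_matrix(path, delimiter=delimiter)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError(
            f"non-square matrix in {path}: shape {values.shape}"
        )
    return WeightedNetwork(values, directed=directed, labels=labels,
                           coordinates=coordinates)


def write_matrix(matrix: np.ndarray, path: str | Path,
                 labels: Sequence[str] | None = None,
                 delimiter: str | None = None) -> None:
    """Write a matrix as delimited text at full float precision (%.17g)."""
    path = Path(path)
    delimiter = delimiter or ("\t" if path.suffix == ".tsv" else ",")
    m = np.asarray(matrix, dtype=float)
    if labels is not None:
        df = pd.DataFrame(m, index=list(labels), columns=list(labels))
        df.to_csv(path, sep=delimiter, float_format="%.17g")
    else:
        pd.DataFrame(m).to_csv(path, sep=delimiter, float_format="%.17g",
                               header=False, index=False)


def write_network(net: WeightedNetwork, path: str | Path,
                  delimiter: str | None = None) -> None:
    write_matrix(net.weights, path, labels=net.labels, delimiter=delimiter)


def read_coordinates(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a node coordinate table with columns ``label,x,y[,z]``."""
    path = Path(path)
    delimiter = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    cols = [c.lower() for c in df.columns]
    if "label" not in cols or "x" not in cols or "y" not in cols:
        raise ValidationError(
            f"coordinate file {path} must have columns label,x,y[,z]"
        )
    df.columns = cols
    df["label"] = df["label"].astype(str)
    return df.set_index("label")


def write_coordinates(labels: Sequence[str], coordinates: np.ndarray,
                      path: str | Path, delimiter: str | None = None) -> None:
    path = Path(path)
    delimiter = delimiter or ("\t" if path.suffix == ".tsv" else ",")
    c = np.atleast_2d(np.asarray(coordinates, dtype=float))
    cols = ["x", "y", "z"][: c.shape[1]]
    df = pd.DataFrame(c, columns=cols)
    df.insert(0, "label", list(labels))
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def read_partition(path: str | Path, delimiter: str | None = None) -> dict[str, str]:
    """Read a two-column ``label,subsystem`` table into a mapping."""
    path = Path(path)
    delimiter = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter)
    if df.shape[1] < 2:
        raise ValidationError(f"partition file {path} needs two columns")
    lab, sub = df.columns[:2]
    return {str(k): str(v) for k, v in zip(df[lab], df[sub])}


def read_manifest(path: str | Path) -> list[Path]:
    """Read a cohort manifest: one matrix path per line, order = subject order."""
    base = Path(path).parent
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        p = Path(line)
        out.append(p if p.is_absolute() else base / p)
    return out


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def threshold_to_density(net: WeightedNetwork, density: float) -> WeightedNetwork:
    """Keep the strongest edges up to a target connection density.

    Retains the ``floor(density * N(N-1)/2)`` largest-weight undirected
    edges, ranked on the upper triangle, and zeroes the rest.  Ties at the
    cutoff are broken by (row, column) lexicographic order so the retained
    edge set is deterministic across platforms.
    """
    if net.directed:
        raise ValidationError("density thresholding is defined for undirected networks")
    if not 0 < density <= 1:
        raise ValidationError(f"density must be in (0, 1], got {density}")
    n = net.n_nodes
    m_target = int(np.floor(density * n * (n - 1) / 2))
    iu, ju = np.triu_indices(n, k=1)
    w = net.weights[iu, ju]
    pos = w > 0
    if m_target < 1:
        raise ValidationError(f"density {density} retains no edges for N={n}")
    # sort positive edges by (-weight, row, col)
    order = np.lexsort((ju[pos], iu[pos], -w[pos]))
    keep = order[:m_target]
    out = np.zeros_like(net.weights)
    ki, kj = iu[pos][keep], ju[pos][keep]
    out[ki, kj] = w[pos][keep]
    out[kj, ki] = w[pos][keep]
    return net.with_weights(out)


def weight_to_length(weights: np.ndarray | WeightedNetwork) -> np.ndarray:
    """Remap connection weights (affinities) to connection lengths (costs).

    ``L = -log10(W / (max(W) + min(W_>0)))`` — a monotonically decreasing
    transform that attenuates extreme weights; the offset by the smallest
    positive weight keeps the strongest connection at a strictly positive
    length.  Non-edges map to ``+inf``.
    """
    w = weights.weights if isinstance(weights, WeightedNetwork) else np.asarray(weights, float)
    pos = w > 0
    if not pos.any():
        raise ValidationError("no edges: all-zero weight matrix")
    denom = w[pos].max() + w[pos].min()
    lengths = np.full_like(w, np.inf, dtype=float)
    lengths[pos] = -np.log10(w[pos] / denom)
    np.fill_diagonal(lengths, np.inf)
    return lengths


def symmetrize(net: WeightedNetwork) -> WeightedNetwork:
    """Average a directed matrix with its transpose: ``W_u = (W_d + W_dᵀ)/2``.

    Every original connection remains traversable in both directions.
    """
    w = (net.weights + net.weights.T) / 2.0
    return WeightedNetwork(w, directed=False, labels=list(net.labels),
                           coordinates=None if net.coordinates is None else net.coordinates.copy())


def binarize(net: WeightedNetwork) -> WeightedNetwork:
    """Replace every nonzero weight with 1; the support is unchanged."""
    return net.with_weights((net.weights > 0).astype(float))


def euclidean_distance_matrix(coordinates: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between node centroids."""
    c = np.atleast_2d(np.asarray(coordinates, dtype=float))
    return squareform(pdist(c))


def degrees_strengths(net: WeightedNetwork) -> pd.DataFrame:
    """Per-node degree (edge count) and strength (weight sum).

    For directed networks, in- and out- variants are returned.
    """
    w = net.weights
    b = w > 0
    if net.directed:
        df = pd.DataFrame(
            {
                "out_degree": b.sum(axis=1),
                "in_degree": b.sum(axis=0),
                "out_strength": w.sum(axis=1),
                "in_strength": w.sum(axis=0),
            },
            index=net.labels,
        )
    else:
        df = pd.DataFrame(
            {"degree": b.sum(axis=1), "strength": w.sum(axis=1)},
            index=net.labels,
        )
    df.index.name = "node"
    return df


def partition_groups(partition: Mapping[str, str], labels: Sequence[str]) -> dict[str, np.ndarray]:
    """Map each subsystem label to the (sorted) indices of its member nodes."""
    if isinstance(partition, pd.Series):
        partition = partition.to_dict()
    missing = [l for l in labels if str(l) not in partition]
    if missing:
        raise ValidationError(f"nodes missing from partition: {missing[:5]}")
    groups: dict[str, list[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(str(partition[str(lab)]), []).append(idx)
    return {k: np.asarray(v, dtype=int) for k, v in sorted(groups.items())}


def participation_coefficient(net: WeightedNetwork, partition: Mapping[str, str],
                              weighted: bool = False) -> pd.Series:
    """Diversity of a node's connections across subsystems, in [0, 1].

    ``PC_i = 1 - sum_m (k_im / k_i)^2`` where ``k_im`` counts (or, with
    ``weighted=True``, sums the weights of) node i's connections into
    subsystem m.  Nodes without connections get 0 by convention.
    """
    groups = partition_groups(partition, net.labels)
    w = net.weights if weighted else (net.weights > 0).astype(float)
    k_total = w.sum(axis=1)
    frac_sq = np.zeros(net.n_nodes)
    with np.errstate(invalid="ignore", divide="ignore"):
        for idx in groups.values():
            k_m = w[:, idx].sum(axis=1)
            frac_sq += np.where(k_total > 0, (k_m / np.where(k_total > 0, k_total, 1)) ** 2, 0.0)
    pc = np.where(k_total > 0, 1.0 - frac_sq, 0.0)
    return pd.Series(pc, index=net.labels, name="participation")


def connected_components(net: WeightedNetwork) -> tuple[int, np.ndarray]:
    """Component count and per-node component labels.

    Weak components are used for directed networks.
    """
    g = csr_array(net.weights)
    n, labels = _csgraph_components(g, directed=net.directed, connection="weak")
    return int(n), labels
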