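"""Mutual-information network inference.

All-pairs mutual information between expression profiles is estimated with
the Kraskov-Stoegbauer-Grassberger (KSG) k-nearest-neighbour estimator
(algorithm 1, Chebyshev norm, natural-log units) and the resulting complete
graph is pruned with the ARACNE data-processing-inequality (DPI) rule: for
every unordered triple {i, j, k} the edge (i, j) is removed when

    MI(i;j) < MI(j;k) - eps   and   MI(i;j) < MI(i;k) - eps,

all triples being evaluated against the original MI matrix and marked edges
removed at once, so the result does not depend on any processing order.

The KSG estimator assumes continuous marginals; expression data carry ties,
so a deterministic, seeded uniform jitter of amplitude 1e-10 is added before
neighbour searches. Estimates are clamped at zero (true MI is non-negative;
the raw estimator is approximately unbiased and can go slightly negative for
independent pairs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy.special import digamma

from .exceptions import InputError, ParameterError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MiNetwork",
    "ksg_mutual_information",
    "pairwise_mi",
    "dpi_prune",
    "permutation_mi_floor",
    "build_network",
]

JITTER_AMPLITUDE = 1e-10


@dataclass
class MiNetwork:
    """Undirected MI-weighted graph plus the estimator parameters used."""

    graph: nx.Graph
    k_neighbors: int
    epsilon: float
    mi_floor: float | None = None
    params: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_weight(self, u, v) -> float:
        return self.graph.edges[u, v]["weight"]

    def edges(self):
        """Deterministically ordered (a, b, weight) triples with a < b."""
        rows = [tuple(sorted((u, v))) + (w,) for u, v, w in self.graph.edges(data="weight")]
        return sorted(rows)


def _jitter(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return x + rng.uniform(0.0, JITTER_AMPLITUDE, size=x.shape)


def _ksg_from_distances(dx: np.ndarray, dy: np.ndarray, k: int) -> float:
    """KSG algorithm 1 given the two marginal absolute-difference matrices."""
    n = dx.shape[0]
    dz = np.maximum(dx, dy)
    # row-wise k-th neighbour distance in the joint space; the 0 self-distance
    # occupies partition index 0, so index k is the k-th genuine neighbour
    eps = np.partition(dz, k, axis=1)[:, k]
    # strict-inequality marginal counts, excluding the point itself
    nx_ = (dx < eps[:, None]).sum(axis=1) - 1
    ny_ = (dy < eps[:, None]).sum(axis=1) - 1
    mi = digamma(k) + digamma(n) - np.mean(digamma(nx_ + 1) + digamma(ny_ + 1))
    return max(float(mi), 0.0)


def ksg_mutual_information(x, y, k_neighbors: int = 3, jitter_seed: int = 0) -> float:
    """KSG algorithm-1 MI estimate between two sample vectors, in nats.

    Symmetric in (x, y) and deterministic given the inputs and jitter seed.
    A constant input vector yields 0 with a logged warning (MI with a
    degenerate variable is 0 and the estimator is undefined there).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise InputError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < k_neighbors + 2:
        raise InputError(
            f"need at least k_neighbors + 2 = {k_neighbors + 2} samples, got {x.size}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant input vector: returning MI = 0")
        return 0.0
    # jitter streams are attached to the lexicographically smaller vector, not
    # to argument position, so ksg(x, y) == ksg(y, x) holds exactly
    a, b = (x, y) if x.tobytes() <= y.tobytes() else (y, x)
    aj = _jitter(a, np.random.default_rng([jitter_seed, 0]))
    bj = _jitter(b, np.random.default_rng([jitter_seed, 1]))
    da = np.abs(aj[:, None] - aj[None, :])
    db = np.abs(bj[:, None] - bj[None, :])
    return _ksg_from_distances(da, db, k_neighbors)


def pairwise_mi(
    matrix: ExpressionMatrix, k_neighbors: int = 3, jitter_seed: int = 0
) -> pd.DataFrame:
    """Symmetric all-pairs KSG MI matrix over the features of ``matrix``.

    Each unordered pair is estimated once; the diagonal is set to 0 and is
    ignored by downstream pruning.
    """
    m, n = matrix.n_features, matrix.n_samples
    if n < k_neighbors + 2:
        raise InputError(f"need at least {k_neighbors + 2} samples, got {n}")
    rng = np.random.default_rng(jitter_seed)
    vals = matrix.values + rng.uniform(0.0, JITTER_AMPLITUDE, size=matrix.values.shape)
    out = np.zeros((m, m))
    if m < 2:
        return pd.DataFrame(out, index=matrix.feature_ids, columns=matrix.feature_ids)
    constant = np.ptp(matrix.values, axis=1) == 0
    if constant.any():
        logger.warning("%d constant feature(s): their MI set to 0", int(constant.sum()))
    # cache per-feature |x_i - x_j| matrices when that fits comfortably in memory
    cache_ok = m * n * n * 8 <= 1_500_000_000
    dcache = [np.abs(vals[i][:, None] - vals[i][None, :]) for i in range(m)] if cache_ok else None
    for i in range(m):
        if constant[i]:
            continue
        di = dcache[i] if cache_ok else np.abs(vals[i][:, None] - vals[i][None, :])
        for j in range(i + 1, m):
            if constant[j]:
                continue
            dj = dcache[j] if cache_ok else np.abs(vals[j][:, None] - vals[j][None, :])
            out[i, j] = out[j, i] = _ksg_from_distances(di, dj, k_neighbors)
    return pd.DataFrame(out, index=matrix.feature_ids, columns=matrix.feature_ids)


def _as_matrix(mi_matrix) -> tuple[np.ndarray, list[str]]:
    if isinstance(mi_matrix, pd.DataFrame):
        return mi_matrix.to_numpy(dtype=float), [str(i) for i in mi_matrix.index]
    arr = np.asarray(mi_matrix, dtype=float)
    return arr, [f"f{i}" for i in range(arr.shape[0])]


def dpi_prune(mi_matrix, epsilon: float = 0.05, k_neighbors: int = 0) -> MiNetwork:
    """ARACNE DPI pruning of the complete MI graph.

    Every triple is tested against the original matrix and all marked edges
    removed simultaneously. Edges whose (clamped) MI is not strictly positive
    are not reported. Raises on asymmetric input.
    """
    arr, ids = _as_matrix(mi_matrix)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise InputError(f"MI matrix must be square, got shape {arr.shape}")
    if not np.allclose(arr, arr.T, atol=1e-12, equal_nan=False):
        raise InputError("MI matrix must be symmetric")
    if epsilon < 0:
        raise ParameterError("epsilon must be >= 0")
    m = arr.shape[0]
    w = arr.copy()
    np.fill_diagonal(w, -np.inf)  # excludes k == i and k == j from domination
    # dominated[i, j] iff exists k with min(M[i,k], M[j,k]) - eps > M[i,j]
    if m >= 3:
        best = np.maximum.reduce(
            [np.minimum(w[:, None, k], w[None, :, k]) for k in range(m)]
        )
        dominated = w < best - epsilon
    else:
        dominated = np.zeros_like(w, dtype=bool)
    g = nx.Graph()
    g.add_nodes_from(ids)
    iu, ju = np.triu_indices(m, k=1)
    for i, j in zip(iu, ju):
        if arr[i, j] > 0 and not dominated[i, j]:
            g.add_edge(ids[i], ids[j], weight=float(arr[i, j]))
    return MiNetwork(graph=g, k_neighbors=k_neighbors, epsilon=epsilon)


def permutation_mi_floor(
    matrix: ExpressionMatrix,
    k_neighbors: int = 3,
    n_null: int = 2000,
    seed: int = 0,
) -> float:
    """MaxT-style significance floor: max KSG MI over shuffled feature pairs.

    Each null draw picks a random ordered feature pair and permutes one
    profile, destroying any dependence while keeping both marginals; the
    maximum over ``n_null`` draws is a familywise-error-style floor for
    calling an edge real in a network of thousands of candidate pairs.
    """
    rng = np.random.default_rng(seed)
    m = matrix.n_features
    if m < 2:
        raise InputError("need at least 2 features")
    best = 0.0
    for b in range(n_null):
        i, j = rng.choice(m, size=2, replace=False)
        x = matrix.values[i]
        y = rng.permutation(matrix.values[j])
        mi = ksg_mutual_information(x, y, k_neighbors, jitter_seed=int(rng.integers(2**31)))
        best = max(best, mi)
    return best


def build_network(
    matrix: ExpressionMatrix,
    k_neighbors: int = 3,
    epsilon: float = 0.05,
    mi_floor: float | str | None = None,
    seed: int = 0,
    n_null: int = 2000,
) -> MiNetwork:
    """All-pairs KSG MI followed by DPI pruning.

    ``mi_floor`` is None (no floor; the complete MI graph enters DPI), a
    float (edges below it are zeroed before DPI), or ``"permutation"`` to
    compute :func:`permutation_mi_floor` on the input matrix.
    """
    mi = pairwise_mi(matrix, k_neighbors=k_neighbors, jitter_seed=seed)
    floor_value: float | None
    if mi_floor == "permutation":
        floor_value = permutation_mi_floor(
            matrix, k_neighbors=k_neighbors, n_null=n_null, seed=seed + 1
        )
        logger.info("permutation MI floor: %.4f nats (%d null pairs)", floor_value, n_null)
    else:
        floor_value = mi_floor
    if floor_value is not None:
        mi = mi.where(mi >= floor_value, 0.0)
    net = dpi_prune(mi, epsilon=epsilon, k_neighbors=k_neighbors)
    net.mi_floor = floor_value
    net.params = {"k_neighbors": k_neighbors, "epsilon": epsilon, "mi_floor": floor_value}
    return net
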