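"""Rank-based closeness and variation matrices.

The social measure is a *logical distance*: at every timeslot each
animal ranks all others by ascending Euclidean distance from itself
(rank 1 = nearest).  Averaging animal i's rank of animal j over time
gives the closeness matrix

    W[i, j] = (1/T) * sum_t R[i, j](t),

an asymmetric N x N matrix whose off-diagonal rows are means of
permutations of 1..N-1 (hence each row sums to N(N-1)/2 exactly).
Small W[i, j] means i kept j among its nearest neighbours.  Because
ranks are scale-invariant, W is unaffected by the herd expanding or
contracting as a whole.

The variation matrix Dv holds the population variance over time of the
reciprocal rank 1/R[i, j](t), separating stable relationships (low
variation) from fluctuating ones.

Both matrices are symmetrised for embedding/clustering by the entrywise
product with their transpose, ``D[i, j] = M[i, j] * M[j, i]``.

Convention note: row i is animal i's own view (W[i, j] = j's average
rank in i's distance list).  A printed matrix using the transposed
orientation can be accommodated with ``transpose=True`` where offered;
the product symmetrisation is identical under either orientation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import TrajectoryDataset

__all__ = [
    "pairwise_distance_matrix",
    "rank_matrix",
    "rank_tensor",
    "closeness_matrix",
    "variation_matrix",
    "symmetric_dissimilarity",
    "to_weighted_graph",
    "graph_to_closeness",
]


def pairwise_distance_matrix(dataset: TrajectoryDataset, t: int) -> np.ndarray:
    """Euclidean distance matrix (metres) between all animals at slot ``t``.

    ``t`` is a positional index into ``dataset.timeslots``.
    """
    if not -dataset.n_timeslots <= t < dataset.n_timeslots:
        raise IndexError(
            f"timeslot index {t} out of range for T={dataset.n_timeslots}"
        )
    p = dataset.positions[t]
    diff = p[:, None, :] - p[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def rank_matrix(distances: np.ndarray) -> np.ndarray:
    """Per-animal neighbour ranks from one snapshot's distance matrix.

    Row i ranks every other animal j by ascending distance from i
    (1 = nearest, N-1 = farthest); the diagonal is 0.  Ties are broken
    by animal order (the earlier identifier gets the smaller rank), so
    the result is deterministic.

    Raises
    ------
    ValueError
        If the input is not a square symmetric matrix with zero
        diagonal.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"distance matrix must be square, got {d.shape}")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must have zero diagonal")
    return _rank_rows(d[None, :, :])[0]


def _rank_rows(d: np.ndarray) -> np.ndarray:
    """Rank along the last axis of a (T, N, N) distance stack.

    Self-distance is forced below every real distance so that each
    animal occupies rank 0 in its own row; a stable double argsort then
    yields ranks 1..N-1 for the others with ties broken by index order.
    """
    d = d.copy()
    n = d.shape[-1]
    idx = np.arange(n)
    d[:, idx, idx] = -1.0
    order = np.argsort(d, axis=-1, kind="stable")
    ranks = np.empty_like(order)
    t_idx = np.arange(d.shape[0])[:, None, None]
    r_idx = np.arange(n)[None, :, None]
    ranks[t_idx, r_idx, order] = np.arange(n)[None, None, :]
    return ranks


def rank_tensor(dataset: TrajectoryDataset, chunk: int = 2048) -> np.ndarray:
    """All per-timeslot rank matrices, shape ``(T, N, N)`` (int).

    Computed in chunks of timeslots to bound memory on long recordings.
    """
    T, N = dataset.n_timeslots, dataset.n_animals
    out = np.empty((T, N, N), dtype=np.int64)
    for start in range(0, T, chunk):
        p = dataset.positions[start : start + chunk]
        diff = p[:, :, None, :] - p[:, None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1))
        out[start : start + chunk] = _rank_rows(d)
    return out


def closeness_matrix(
    dataset: TrajectoryDataset, transpose: bool = False
) -> pd.DataFrame:
    """Time-averaged rank (closeness) matrix W.

    Entry (i, j) is the mean over timeslots of animal j's rank in
    animal i's ascending distance list (1 = nearest).  Off-diagonal
    entries lie in [1, N-1], the diagonal is 0, and every row sums to
    N(N-1)/2 exactly.  Generally ``W[i, j] != W[j, i]``: the two animals
    need not value the bond equally.

    Parameters
    ----------
    transpose
        Return the transposed orientation (rows = attention an animal
        attracted rather than its own view).
    """
    ranks = rank_tensor(dataset)
    W = ranks.mean(axis=0)
    if transpose:
        W = W.T
    return pd.DataFrame(W, index=dataset.animals, columns=dataset.animals)


def variation_matrix(
    dataset: TrajectoryDataset, kind: str = "variance"
) -> pd.DataFrame:
    """Dispersion of the reciprocal rank over time (matrix Dv).

    For each ordered pair (i, j) the series ``X(t) = 1 / R[i, j](t)``
    is formed and its population variance (default) or standard
    deviation returned.  X is bounded in [1/(N-1), 1], so the variance
    is bounded by 0.25.  A static herd gives an all-zero matrix.

    Parameters
    ----------
    kind
        ``"variance"`` (population variance, default) or ``"std"``.
    """
    if kind not in ("variance", "std"):
        raise ValueError(f"kind must be 'variance' or 'std', got {kind!r}")
    ranks = rank_tensor(dataset).astype(float)
    np.einsum("tii->ti", ranks)[:] = 1.0  # avoid 1/0 on the diagonal
    recip = 1.0 / ranks
    dv = recip.var(axis=0)
    # constant rank series must give exactly 0, not summation residue;
    # the smallest true nonzero variance is far above this threshold
    dv[dv < 1e-18] = 0.0
    n = dataset.n_animals
    dv[np.arange(n), np.arange(n)] = 0.0
    if kind == "std":
        dv = np.sqrt(dv)
    return pd.DataFrame(dv, index=dataset.animals, columns=dataset.animals)


def symmetric_dissimilarity(asym: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Symmetrise an asymmetric nonnegative matrix by the entrywise
    product with its transpose: ``D[i, j] = M[i, j] * M[j, i]``.

    Applied to the closeness matrix W this gives the dissimilarity fed
    to the embedding and the agglomerative affinity (small product =
    mutually near); applied to Dv it gives the variation dissimilarity.
    """
    if isinstance(asym, pd.DataFrame):
        labels = list(asym.index)
        m = asym.to_numpy(dtype=float)
    else:
        m = np.asarray(asym, dtype=float)
        labels = [str(i) for i in range(m.shape[0])]
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix must be square, got {m.shape}")
    if np.any(m < 0):
        raise ValueError("matrix entries must be nonnegative")
    if not np.allclose(np.diag(m), 0.0):
        raise ValueError("matrix diagonal must be zero")
    return pd.DataFrame(m * m.T, index=labels, columns=labels)


def to_weighted_graph(
    W: pd.DataFrame,
    path: str | Path | None = None,
    graphml_path: str | Path | None = None,
):
    """Export the closeness matrix as a bidirectional weighted graph.

    Every ordered pair (i, j), i != j, becomes a directed edge with
    weight ``W[i, j]`` (N*(N-1) edges).  Written as a ``src,dst,weight``
    CSV edge list and optionally as GraphML.

    Returns the :class:`networkx.DiGraph`.
    """
    import networkx as nx

    labels = list(W.index)
    arr = W.to_numpy(dtype=float)
    g = nx.DiGraph()
    g.add_nodes_from(labels)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                g.add_edge(a, b, weight=float(arr[i, j]))
    if path is not None:
        rows = [
            {"src": a, "dst": b, "weight": d["weight"]}
            for a, b, d in g.edges(data=True)
        ]
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
    return g


def graph_to_closeness(path: str | Path) -> pd.DataFrame:
    """Rebuild a closeness matrix from a ``src,dst,weight`` edge list."""
    df = pd.read_csv(path, dtype={"src": str, "dst": str})
    labels = sorted(set(df["src"]) | set(df["dst"]))
    W = pd.DataFrame(0.0, index=labels, columns=labels)
    for _, row in df.iterrows():
        W.loc[row["src"], row["dst"]] = float(row["weight"])
    return W
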