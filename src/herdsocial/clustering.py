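"""Social clustering: K-means in the abstract space and a bespoke
indegree-x-outdegree agglomerative hierarchy on the closeness matrix.

K-means (with silhouette-selected K) operates on MDS coordinates and
finds bonded subgroups and socially separated singletons.  The
agglomerative clustering works directly on the asymmetric closeness
matrix W through a directed affinity: for an animal j and a cluster C,

    deg_j^-(C) = mean_{m in C} W[m, j]     (attention j attracts from C)
    deg_j^+(C) = mean_{m in C} W[j, m]     (attention j pays to C)

    A(j -> C)  = deg_j^-(C) * deg_j^+(C)

and between clusters  A(Cb -> Ca) = sum_{j in Cb} A(j -> Ca), combined
symmetrically.  With W an average rank (small = near), bonded pairs
have *small* products, so by default the pair with minimal affinity is
merged first and merge heights read as dissimilarities; ``polarity=
"max"`` preserves the literal maximum-affinity rule for users who
invert the rank convention.  This linkage is not one of the standard
single/complete/average family and its heights need not be monotonic;
inversions are logged, not suppressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .mds import Embedding

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterLabels",
    "Dendrogram",
    "kmeans_cluster",
    "silhouette_select_k",
    "cluster_degrees",
    "cluster_affinity",
    "ahc_build",
    "dendrogram_to_newick",
]


@dataclass(frozen=True)
class ClusterLabels:
    """A flat clustering of N labelled points."""

    labels: np.ndarray  # length-N integer cluster indices
    k: int
    inertia: float
    animals: tuple[str, ...]

    def members(self, cluster: int) -> tuple[str, ...]:
        return tuple(
            a for a, l in zip(self.animals, self.labels) if l == cluster
        )

    def clusters(self) -> list[tuple[str, ...]]:
        return [self.members(c) for c in range(self.k)]

    def singletons(self) -> tuple[str, ...]:
        """Animals forming a cluster of their own (socially separated)."""
        return tuple(a for c in self.clusters() if len(c) == 1 for a in c)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"animal": list(self.animals), "cluster": self.labels})


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters in order of first occurrence (0, 1, ...)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def _coords_labels(points) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(points, Embedding):
        return points.coordinates, points.labels
    arr = np.asarray(points, dtype=float)
    return arr, tuple(str(i) for i in range(arr.shape[0]))


def kmeans_cluster(
    points: Embedding | np.ndarray,
    k: int,
    seed: int = 0,
    restarts: int = 50,
) -> ClusterLabels:
    """Best-of-``restarts`` K-means on embedded points.

    Deterministic given ``seed``; labels are canonicalised to first
    occurrence order.
    """
    coords, animals = _coords_labels(points)
    n = coords.shape[0]
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must satisfy 2 <= k <= N-1 = {n - 1}, got {k}")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(coords)
    return ClusterLabels(
        labels=_canonical_labels(km.labels_),
        k=k,
        inertia=float(km.inertia_),
        animals=animals,
    )


def silhouette_select_k(
    points: Embedding | np.ndarray,
    k_range: Sequence[int] | None = None,
    seed: int = 0,
    restarts: int = 50,
) -> tuple[int, ClusterLabels, dict[int, float]]:
    """K-means with the number of clusters chosen by silhouette analysis.

    Runs :func:`kmeans_cluster` for every k in ``k_range`` (default
    2..min(8, N-2)) and returns the k with the largest mean silhouette
    width, ties resolved toward smaller k.  Also returns the silhouette
    score per candidate k for inspection.
    """
    coords, _ = _coords_labels(points)
    n = coords.shape[0]
    if n < 4:
        raise ValueError(f"silhouette selection needs N >= 4, got {n}")
    if k_range is None:
        k_range = range(2, min(8, n - 2) + 1)
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty k_range")
    scores: dict[int, float] = {}
    results: dict[int, ClusterLabels] = {}
    for k in k_range:
        res = kmeans_cluster(points, k, seed=seed, restarts=restarts)
        scores[k] = float(silhouette_score(coords, res.labels))
        results[k] = res
    best_k = min(scores, key=lambda k: (-scores[k], k))
    return best_k, results[best_k], scores


def _w_array(W) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(W, pd.DataFrame):
        return W.to_numpy(dtype=float), tuple(str(x) for x in W.index)
    arr = np.asarray(W, dtype=float)
    return arr, tuple(str(i) for i in range(arr.shape[0]))


def cluster_degrees(
    W, animal: int, cluster: Iterable[int]
) -> tuple[float, float]:
    """Average (indegree, outdegree) of one animal with respect to a
    cluster of others.

    indegree = mean over j in cluster of ``W[j, animal]`` (attention the
    animal attracts from the cluster); outdegree = mean of
    ``W[animal, j]`` (attention it pays).  The cluster must be non-empty
    and must not contain the focal animal.
    """
    arr, _ = _w_array(W)
    members = list(cluster)
    if not members:
        raise ValueError("cluster must be non-empty")
    if animal in members:
        raise ValueError("cluster must not contain the focal animal")
    indeg = float(arr[members, animal].mean())
    outdeg = float(arr[animal, members].mean())
    return indeg, outdeg


def _directed_affinity(arr: np.ndarray, src: list[int], dst: list[int]) -> float:
    """A(src -> dst) = sum over j in src of deg_j^-(dst) * deg_j^+(dst)."""
    total = 0.0
    for j in src:
        indeg = arr[dst, j].mean()
        outdeg = arr[j, dst].mean()
        total += indeg * outdeg
    return float(total)


def cluster_affinity(
    W,
    ca: Iterable[int],
    cb: Iterable[int],
    mode: str = "mean",
) -> float:
    """Symmetric affinity between two disjoint clusters.

    ``mode="mean"`` (default) averages the two directed affinities, so
    for singletons {i}, {j} it reduces to ``W[i, j] * W[j, i]``;
    ``mode="sum"`` adds them (twice the mean).  The two modes order
    cluster pairs identically.
    """
    if mode not in ("mean", "sum"):
        raise ValueError(f"mode must be 'mean' or 'sum', got {mode!r}")
    arr, _ = _w_array(W)
    a, b = list(ca), list(cb)
    if not a or not b:
        raise ValueError("clusters must be non-empty")
    if set(a) & set(b):
        raise ValueError("clusters must be disjoint")
    total = _directed_affinity(arr, b, a) + _directed_affinity(arr, a, b)
    return total / 2.0 if mode == "mean" else total


@dataclass(frozen=True)
class Dendrogram:
    """Binary merge tree over N labelled leaves.

    ``merges`` has N-1 rows ``(left, right, height, size)`` in scipy
    linkage node numbering: leaves are 0..N-1, the merge recorded in
    row r creates node N+r.  Heights are the affinity at which the two
    clusters merged and may be non-monotonic under this linkage.
    """

    merges: np.ndarray  # (N-1, 4) float
    leaves: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def merge_members(self) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
        """Leaf labels on each side of every merge, in merge order."""
        n = self.n_leaves
        sets: dict[int, tuple[str, ...]] = {i: (self.leaves[i],) for i in range(n)}
        out = []
        for r, (l, r_, _, _) in enumerate(self.merges):
            left, right = sets[int(l)], sets[int(r_)]
            out.append((left, right))
            sets[n + r] = left + right
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["left", "right", "height", "size"]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


def ahc_build(W, polarity: str = "min", mode: str = "mean") -> Dendrogram:
    """Agglomerative hierarchy on the closeness matrix W.

    Starts from singleton clusters and repeatedly merges the pair with
    the minimal (default) or maximal symmetric affinity until one
    cluster remains.  With the rank-average W, minimal product affinity
    identifies the most strongly bonded pair, and merge heights read as
    dissimilarities (bonded animals merge low).

    Ties are broken toward the lexicographically smallest node-id pair
    for determinism.
    """
    if polarity not in ("min", "max"):
        raise ValueError(f"polarity must be 'min' or 'max', got {polarity!r}")
    arr, leaves = _w_array(W)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 leaves")
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = np.zeros((n - 1, 4))
    sign = 1.0 if polarity == "min" else -1.0
    prev_height = None
    for step in range(n - 1):
        best = None
        ids = sorted(active)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                aff = cluster_affinity(arr, active[a], active[b], mode=mode)
                key = (sign * aff, a, b)
                if best is None or key < best[0]:
                    best = (key, a, b, aff)
        _, a, b, height = best
        if prev_height is not None and sign * height < sign * prev_height:
            logger.info(
                "dendrogram height inversion at step %d: %.6g after %.6g",
                step,
                height,
                prev_height,
            )
        prev_height = height
        members = active.pop(a) + active.pop(b)
        active[n + step] = members
        merges[step] = (a, b, height, len(members))
    return Dendrogram(merges=merges, leaves=leaves)


def dendrogram_to_newick(d: Dendrogram, path: str | Path | None = None) -> str:
    """Render a dendrogram as a Newick string.

    Each internal node sits at level ``height/2`` so that the two
    children of a merge at height h are h/2 away (an ultrametric-style
    layout); branch lengths are level differences, clipped at zero when
    the linkage produced an inversion.
    """
    n = d.n_leaves
    level: dict[int, float] = {i: 0.0 for i in range(n)}
    text: dict[int, str] = {i: d.leaves[i] for i in range(n)}
    for r, (l, rr, height, _) in enumerate(d.merges):
        l, rr = int(l), int(rr)
        node_level = height / 2.0
        bl = max(node_level - level[l], 0.0)
        br = max(node_level - level[rr], 0.0)
        text[n + r] = f"({text[l]}:{bl:.6g},{text[rr]}:{br:.6g})"
        level[n + r] = node_level
    newick = text[2 * n - 2] + ";"
    if path is not None:
        Path(path).write_text(newick + "\n")
    return newick
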