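"""Physical-position clustering and herd statistics.

Complements the rank-based (logical) analysis with plain geometry: at
each timeslot the N animal positions are K-means clustered (default
K = 4) and per-animal statistics are accumulated over time:

- *alone count* — timeslots spent as a singleton cluster (social
  repulsion / avoidance);
- *co-membership* — per pair, timeslots spent in the same cluster
  (large row sums mark central, influential individuals);
- *size profile* — per animal, the proportion of time spent in
  clusters of each size (herd "time budget");
- *connectors* — per cluster, the animal nearest its centroid.

Per-timeslot runs are re-seeded deterministically as ``seed + t`` so a
whole recording is reproducible without artificially correlating
consecutive snapshots.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import TrajectoryDataset

__all__ = [
    "SnapshotClustering",
    "HerdStats",
    "snapshot_clusters",
    "herd_statistics",
    "snapshot_series",
]

_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class SnapshotClustering:
    """K-means result for one timeslot."""

    timeslot: int
    labels: np.ndarray  # length-N cluster indices (first-occurrence order)
    centroids: np.ndarray  # (K', 2) metres, K' = number of non-empty clusters
    connectors: tuple[str, ...]  # per cluster, member nearest its centroid
    animals: tuple[str, ...]

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": list(self.animals),
                "cluster": self.labels,
                "connector": [
                    a in self.connectors for a in self.animals
                ],
            }
        )


@dataclass(frozen=True)
class HerdStats:
    """Aggregated spatial statistics over a recording."""

    animals: tuple[str, ...]
    alone_counts: np.ndarray  # per animal, timeslots in a singleton cluster
    comembership: np.ndarray  # (N, N) shared-cluster timeslot counts
    size_profile: np.ndarray  # (N, N) proportion of time in size-s clusters
    connector_counts: np.ndarray  # per animal, timeslots as a connector
    total_timeslots: int

    def alone_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal": list(self.animals), "alone_count": self.alone_counts}
        )

    def comembership_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.comembership, index=self.animals, columns=self.animals
        )

    def size_profile_frame(self) -> pd.DataFrame:
        cols = [f"size_{s}" for s in range(1, len(self.animals) + 1)]
        df = pd.DataFrame(self.size_profile, columns=cols)
        df.insert(0, "animal", list(self.animals))
        return df

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.alone_frame().to_csv(outdir / "alone.csv", index=False)
        self.comembership_frame().to_csv(outdir / "comembership.csv", index_label="")
        self.size_profile_frame().to_csv(
            outdir / "size_profile.csv", index=False, float_format="%.6f"
        )


def _canonical(labels: np.ndarray) -> np.ndarray:
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def snapshot_clusters(
    dataset: TrajectoryDataset,
    t: int,
    k: int = 4,
    seed: int = 0,
    restarts: int = 5,
) -> SnapshotClustering:
    """K-means on the physical positions at timeslot index ``t``.

    Connectors are the per-cluster members nearest the cluster centroid
    (ties broken by animal order).  If K-means leaves a cluster empty,
    fewer than ``k`` clusters are returned.
    """
    n = dataset.n_animals
    if k > n:
        raise ValueError(f"k={k} exceeds number of animals N={n}")
    if not -dataset.n_timeslots <= t < dataset.n_timeslots:
        raise IndexError(f"timeslot index {t} out of range")
    pts = dataset.positions[t]
    km = KMeans(
        n_clusters=k, n_init=restarts, random_state=(seed + t) % _SEED_MOD
    ).fit(pts)
    labels = _canonical(km.labels_)
    k_eff = int(labels.max()) + 1
    centroids = np.vstack([pts[labels == c].mean(axis=0) for c in range(k_eff)])
    connectors = []
    for c in range(k_eff):
        members = np.flatnonzero(labels == c)
        dists = np.linalg.norm(pts[members] - centroids[c], axis=1)
        connectors.append(dataset.animals[members[int(np.argmin(dists))]])
    return SnapshotClustering(
        timeslot=int(dataset.timeslots[t]),
        labels=labels,
        centroids=centroids,
        connectors=tuple(connectors),
        animals=dataset.animals,
    )


def herd_statistics(
    dataset: TrajectoryDataset,
    k: int = 4,
    seed: int = 0,
    restarts: int = 5,
) -> HerdStats:
    """Cluster every timeslot and accumulate the herd statistics.

    An animal is *alone* at a timeslot iff its cluster is a singleton;
    two animals are co-members iff they carry the same cluster label.
    """
    n, T = dataset.n_animals, dataset.n_timeslots
    alone = np.zeros(n, dtype=np.int64)
    comem = np.zeros((n, n), dtype=np.int64)
    size_counts = np.zeros((n, n), dtype=np.int64)  # animal x (size-1)
    connector_counts = np.zeros(n, dtype=np.int64)
    animal_index = {a: i for i, a in enumerate(dataset.animals)}
    for t in range(T):
        snap = snapshot_clusters(dataset, t, k=k, seed=seed, restarts=restarts)
        labels = snap.labels
        sizes = np.bincount(labels)
        per_animal_size = sizes[labels]
        alone += per_animal_size == 1
        size_counts[np.arange(n), per_animal_size - 1] += 1
        same = labels[:, None] == labels[None, :]
        np.fill_diagonal(same, False)
        comem += same
        for a in snap.connectors:
            connector_counts[animal_index[a]] += 1
    return HerdStats(
        animals=dataset.animals,
        alone_counts=alone,
        comembership=comem,
        size_profile=size_counts / T,
        connector_counts=connector_counts,
        total_timeslots=T,
    )


def snapshot_series(
    dataset: TrajectoryDataset,
    stride: int = 1500,
    k: int = 4,
    seed: int = 0,
    restarts: int = 5,
) -> list[SnapshotClustering]:
    """Clusterings at timeslot indices 0, stride, 2*stride, ... — the
    periodic snapshots used for visual inspection of herd layout."""
    if stride < 1:
        raise ValueError(f"stride must be >= 1, got {stride}")
    return [
        snapshot_clusters(dataset, t, k=k, seed=seed, restarts=restarts)
        for t in range(0, dataset.n_timeslots, stride)
    ]
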