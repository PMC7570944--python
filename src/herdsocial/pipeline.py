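"""One-call orchestration of the full analysis.

``run_full_analysis`` takes trajectories (from CSV or the simulator)
or a precomputed closeness matrix, runs every stage — closeness and
variation matrices, product symmetrisation, MDS embeddings, silhouette
K-means, the agglomerative hierarchy, and (when trajectories are
available) the per-timeslot spatial statistics — and writes all
artifacts plus a JSON manifest recording the seed and parameters
needed for an exact rerun.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from . import __version__
from .closeness import (
    closeness_matrix,
    symmetric_dissimilarity,
    to_weighted_graph,
    variation_matrix,
)
from .clustering import ahc_build, dendrogram_to_newick, silhouette_select_k
from .io import TrajectoryDataset, read_positions_csv, write_matrix_csv
from .mds import central_animal, classical_mds
from .simulate import SimConfig, simulate_herd
from .spatial import herd_statistics

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis", "verify_closeness"]


@dataclass(frozen=True)
class RunConfig:
    """Parameters of a pipeline run.

    Exactly one of ``input_csv``, ``simulate`` or ``from_closeness``
    must be set.  ``from_closeness`` enters the pipeline at the
    closeness matrix (useful when only a published matrix, not raw
    trajectories, is available) and skips the trajectory-derived
    stages.
    """

    outdir: Path
    input_csv: Path | None = None
    simulate: bool = False
    from_closeness: Path | None = None
    sim_config: SimConfig | None = None
    k_policy: str = "silhouette"  # "silhouette" or "fixed"
    k_social: int = 4  # used when k_policy == "fixed"
    k_spatial: int = 4
    stride: int = 1500
    seed: int = 0
    restarts: int = 50
    spatial_restarts: int = 5

    def __post_init__(self) -> None:
        sources = [
            self.input_csv is not None,
            bool(self.simulate),
            self.from_closeness is not None,
        ]
        if sum(sources) != 1:
            raise ValueError(
                "exactly one input source required: "
                "input_csv, simulate or from_closeness"
            )
        if self.k_policy not in ("silhouette", "fixed"):
            raise ValueError("k_policy must be 'silhouette' or 'fixed'")
        object.__setattr__(self, "outdir", Path(self.outdir))


def _embed_and_cluster(D, config: RunConfig, tag: str, outdir: Path, manifest):
    emb = classical_mds(D, dims=2)
    emb.to_csv(outdir / f"embedding_{tag}.csv")
    manifest["artifacts"].append(f"embedding_{tag}.csv")
    if config.k_policy == "silhouette":
        k, labels, scores = silhouette_select_k(
            emb, seed=config.seed, restarts=config.restarts
        )
        manifest[f"silhouette_{tag}"] = {str(kk): v for kk, v in scores.items()}
    else:
        from .clustering import kmeans_cluster

        k = config.k_social
        labels = kmeans_cluster(
            emb, k, seed=config.seed, restarts=config.restarts
        )
    labels.to_frame().to_csv(outdir / f"kmeans_{tag}.csv", index=False)
    manifest["artifacts"].append(f"kmeans_{tag}.csv")
    manifest[f"selected_k_{tag}"] = int(k)
    manifest[f"central_animal_{tag}"] = central_animal(emb)
    return emb, labels


def run_full_analysis(config: RunConfig) -> Path:
    """Run every stage and write artifacts under ``config.outdir``.

    Returns the output directory.  Identical configuration and seed
    reproduce byte-identical matrix outputs.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "package": "herdsocial",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "k_policy": config.k_policy,
            "k_social": config.k_social,
            "k_spatial": config.k_spatial,
            "stride": config.stride,
            "restarts": config.restarts,
            "spatial_restarts": config.spatial_restarts,
        },
        "artifacts": [],
    }

    dataset: TrajectoryDataset | None = None
    if config.from_closeness is not None:
        logger.info("stage: load closeness matrix from %s", config.from_closeness)
        from .io import read_matrix_csv

        W = read_matrix_csv(config.from_closeness)
        manifest["input"] = str(config.from_closeness)
        Dv = None
    else:
        if config.simulate:
            sim = config.sim_config or SimConfig(seed=config.seed)
            logger.info("stage: simulate herd (N=%d, T=%d)", len(sim.animals), sim.T)
            dataset, truth = simulate_herd(sim)
            truth.to_json(outdir / "ground_truth.json")
            manifest["artifacts"].append("ground_truth.json")
            manifest["input"] = "simulated"
            from .io import write_positions_csv

            write_positions_csv(dataset, outdir / "trajectories.csv")
            manifest["artifacts"].append("trajectories.csv")
        else:
            logger.info("stage: read trajectories from %s", config.input_csv)
            dataset = read_positions_csv(config.input_csv)
            manifest["input"] = str(config.input_csv)
        logger.info("stage: closeness matrix")
        W = closeness_matrix(dataset)
        logger.info("stage: variation matrix")
        Dv = variation_matrix(dataset)
        write_matrix_csv(Dv, outdir / "Dv.csv")
        manifest["artifacts"].append("Dv.csv")

    write_matrix_csv(W, outdir / "W.csv")
    manifest["artifacts"].append("W.csv")
    to_weighted_graph(W, outdir / "closeness_edges.csv")
    manifest["artifacts"].append("closeness_edges.csv")

    logger.info("stage: symmetric dissimilarities")
    D = symmetric_dissimilarity(W)
    write_matrix_csv(D, outdir / "D_closeness.csv")
    manifest["artifacts"].append("D_closeness.csv")
    if Dv is not None:
        Sv = symmetric_dissimilarity(Dv)
        write_matrix_csv(Sv, outdir / "D_variation.csv")
        manifest["artifacts"].append("D_variation.csv")

    logger.info("stage: MDS + K-means (closeness)")
    _embed_and_cluster(D, config, "closeness", outdir, manifest)
    if Dv is not None:
        logger.info("stage: MDS + K-means (variation)")
        _embed_and_cluster(Sv, config, "variation", outdir, manifest)

    logger.info("stage: agglomerative hierarchy")
    dend = ahc_build(W)
    dend.to_csv(outdir / "merges.csv")
    dendrogram_to_newick(dend, outdir / "dendrogram.nwk")
    manifest["artifacts"] += ["merges.csv", "dendrogram.nwk"]
    first_left, first_right = dend.merge_members()[0]
    manifest["first_merge"] = sorted(first_left + first_right)

    if dataset is not None:
        logger.info("stage: spatial herd statistics (T=%d)", dataset.n_timeslots)
        stats = herd_statistics(
            dataset,
            k=config.k_spatial,
            seed=config.seed,
            restarts=config.spatial_restarts,
        )
        stats.write(outdir)
        manifest["artifacts"] += ["alone.csv", "comembership.csv", "size_profile.csv"]

    manifest["runtime_s"] = round(time.time() - t0, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline finished in %.1f s", manifest["runtime_s"])
    return outdir


def verify_closeness(path: str | Path) -> dict:
    """Validate a closeness-matrix file and report its headline facts.

    Asserts: zero diagonal; every row sums to N(N-1)/2 within +-0.05;
    off-diagonal entries within [1, N-1] up to printing precision.
    Reports the first agglomerative merge pair and the MDS-central
    animal, and flags column-sum asymmetry (columns need not sum to
    N(N-1)/2 because each row, not column, is a mean of rank
    permutations).
    """
    from .io import read_matrix_csv

    W = read_matrix_csv(path)
    arr = W.to_numpy()
    n = arr.shape[0]
    expected = n * (n - 1) / 2
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    off = arr[~np.eye(n, dtype=bool)]
    report = {
        "n": n,
        "diagonal_zero": bool((abs(arr.diagonal()) < 1e-12).all()),
        "row_sums": row_sums.tolist(),
        "row_sums_ok": bool((abs(row_sums - expected) <= 0.05).all()),
        "offdiag_in_range": bool(
            (off >= 1 - 0.05).all() and (off <= n - 1 + 0.05).all()
        ),
        "column_sums": col_sums.tolist(),
        "column_sum_asymmetry": float(abs(col_sums - expected).max()),
    }
    D = symmetric_dissimilarity(W)
    emb = classical_mds(D, dims=2)
    report["central_animal"] = central_animal(emb)
    dend = ahc_build(W)
    left, right = dend.merge_members()[0]
    report["first_merge"] = sorted(left + right)
    report["first_merge_height"] = float(dend.merges[0, 2])
    report["passed"] = (
        report["diagonal_zero"]
        and report["row_sums_ok"]
        and report["offdiag_in_range"]
    )
    return report
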