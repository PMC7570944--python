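"""Classical (Torgerson) multidimensional scaling.

A symmetric dissimilarity matrix D is double-centered,

    B = -1/2 * C (D o D) C,      C = I - (1/N) 11',

and the top eigenpairs of B give coordinates X = V_k Lambda_k^{1/2}
in an abstract low-dimensional space.  The axes carry no physical
meaning; only relative distances between points do, and the
configuration is defined up to rotation/reflection.  Rank-product
dissimilarities need not be Euclidean, so retained eigenvalues can be
non-positive; such coordinate columns are set to zero with a warning
rather than taking roots of negatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["Embedding", "double_center", "classical_mds", "central_animal"]


@dataclass(frozen=True)
class Embedding:
    """MDS coordinates for N labelled points.

    ``coordinates`` has shape (N, dims) with zero column means;
    ``eigenvalues`` are the retained eigenvalues in descending order.
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        object.__setattr__(
            self, "coordinates", np.asarray(self.coordinates, dtype=float)
        )
        object.__setattr__(
            self, "eigenvalues", np.asarray(self.eigenvalues, dtype=float)
        )

    @property
    def n_points(self) -> int:
        return self.coordinates.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{k + 1}" for k in range(self.coordinates.shape[1])]
        df = pd.DataFrame(self.coordinates, columns=cols)
        df.insert(0, "animal", list(self.labels))
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    def plot(self, ax=None, annotate: bool = True):
        """Scatter the configuration with point labels (abstract axes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        x, y = self.coordinates[:, 0], self.coordinates[:, 1]
        ax.scatter(x, y)
        if annotate:
            for lbl, xi, yi in zip(self.labels, x, y):
                ax.annotate(lbl, (xi, yi), textcoords="offset points", xytext=(4, 4))
        ax.set_xlabel("dim 1 (abstract)")
        ax.set_ylabel("dim 2 (abstract)")
        return ax


def _as_matrix(D) -> tuple[np.ndarray, list[str]]:
    if isinstance(D, pd.DataFrame):
        return D.to_numpy(dtype=float), [str(x) for x in D.index]
    arr = np.asarray(D, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])]


def double_center(D: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Return ``B = -1/2 C (D o D) C`` for a symmetric zero-diagonal D.

    B is symmetric with zero row and column sums.
    """
    d, _ = _as_matrix(D)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"dissimilarity matrix must be square, got {d.shape}")
    if not np.allclose(d, d.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    n = d.shape[0]
    c = np.eye(n) - np.full((n, n), 1.0 / n)
    return -0.5 * c @ (d * d) @ c


def classical_mds(
    D: pd.DataFrame | np.ndarray, dims: int | None = 2
) -> Embedding:
    """Embed a symmetric dissimilarity matrix into ``dims`` dimensions.

    Keeps the ``dims`` algebraically largest eigenvalues of the
    double-centered matrix; ``dims=None`` keeps every strictly positive
    eigenvalue (the full configuration, useful when the leading
    eigenvalues are nearly tied and a fixed truncation would be
    arbitrary).  A retained eigenvalue <= 0 means the input is not
    Euclidean at that dimension; the corresponding coordinate column is
    zeroed and a warning issued.  Eigenvector sign is fixed so the
    first nonzero component of each axis is positive, making the output
    deterministic (still, compare configurations only after Procrustes
    alignment).
    """
    d, labels = _as_matrix(D)
    n = d.shape[0]
    B = double_center(d)
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if dims is None:
        dims = max(int((vals > 1e-9 * max(vals.max(), 1.0)).sum()), 1)
    if n < dims + 1:
        raise ValueError(f"need at least dims+1={dims + 1} points, got {n}")
    keep_vals = vals[:dims]
    keep_vecs = vecs[:, :dims].copy()
    for k in range(dims):
        col = keep_vecs[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            keep_vecs[:, k] = -col
    tol = 1e-9 * max(abs(vals).max(), 1.0)
    degenerate = keep_vals <= tol
    if degenerate.any():
        warnings.warn(
            "retained non-positive eigenvalue(s) "
            f"{keep_vals[degenerate]}: dissimilarity is not Euclidean "
            "at this dimension; affected coordinate column(s) set to zero",
            stacklevel=2,
        )
    coords = keep_vecs * np.sqrt(np.where(degenerate, 0.0, keep_vals))
    return Embedding(coordinates=coords, eigenvalues=keep_vals, labels=labels)


def central_animal(embedding: Embedding) -> str:
    """Label of the point nearest the configuration centroid.

    With a column-centered embedding the centroid is the origin, so
    this is the animal statistically closest to the rest of the group
    — the most central/influential individual.
    """
    centre = embedding.coordinates.mean(axis=0)
    d = np.linalg.norm(embedding.coordinates - centre, axis=1)
    return embedding.labels[int(np.argmin(d))]
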