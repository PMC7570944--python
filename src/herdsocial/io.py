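"""Trajectory and matrix input/output.

Trajectories are multi-animal planar position time series sampled on a
shared integer timeslot grid (one slot = one sampling interval; for a
10 Hz tracking system a slot is 0.1 s).  The slot duration is metadata
only — every downstream statistic is computed on the integer grid.

Coordinates are assumed to be already projected to planar metres; no
geodetic handling is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default CSV column names for trajectory files.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "timeslot": "timeslot",
    "animal": "animal",
    "x": "x",
    "y": "y",
}


class PositionRecord(NamedTuple):
    """One localisation fix: ``(timeslot, animal, x, y)`` in metres."""

    timeslot: int
    animal: str
    x: float
    y: float


@dataclass(frozen=True)
class TrajectoryDataset:
    """Complete-grid positions of ``N`` animals over ``T`` timeslots.

    Attributes
    ----------
    animals
        Ordered animal identifiers.  This order is fixed at ingest and
        determines the row/column order of every downstream matrix.
    timeslots
        Ordered integer timeslot indices, one per retained slot.
    positions
        Array of shape ``(T, N, 2)`` holding x/y in metres.
    slot_seconds
        Duration of one timeslot in seconds (metadata only).
    """

    animals: tuple[str, ...]
    timeslots: np.ndarray
    positions: np.ndarray
    slot_seconds: float = 0.1

    def __post_init__(self) -> None:
        animals = tuple(str(a) for a in self.animals)
        object.__setattr__(self, "animals", animals)
        ts = np.asarray(self.timeslots, dtype=np.int64)
        pos = np.asarray(self.positions, dtype=float)
        if len(set(animals)) != len(animals):
            raise ValueError("animal identifiers must be distinct")
        if len(animals) < 2:
            raise ValueError("need at least 2 animals")
        if ts.ndim != 1 or ts.size < 1:
            raise ValueError("need at least 1 timeslot")
        if np.any(ts < 0):
            raise ValueError("timeslots must be non-negative")
        if np.any(np.diff(ts) <= 0):
            raise ValueError("timeslots must be strictly increasing")
        if pos.shape != (ts.size, len(animals), 2):
            raise ValueError(
                f"positions shape {pos.shape} does not match "
                f"(T={ts.size}, N={len(animals)}, 2)"
            )
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        object.__setattr__(self, "timeslots", ts)
        object.__setattr__(self, "positions", pos)

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    @property
    def n_timeslots(self) -> int:
        return int(self.timeslots.size)

    def to_frame(self) -> pd.DataFrame:
        """Long-format ``timeslot, animal, x, y`` DataFrame."""
        T, N = self.n_timeslots, self.n_animals
        return pd.DataFrame(
            {
                "timeslot": np.repeat(self.timeslots, N),
                "animal": list(self.animals) * T,
                "x": self.positions[:, :, 0].ravel(),
                "y": self.positions[:, :, 1].ravel(),
            }
        )


def align_timeslots(
    records: Iterable[PositionRecord] | pd.DataFrame,
    animal_order: Sequence[str] | None = None,
    slot_seconds: float = 0.1,
) -> TrajectoryDataset:
    """Build a complete-grid dataset from possibly ragged records.

    Only timeslots at which *every* animal has a record are retained;
    incomplete slots are dropped (with a logged warning), never imputed.
    Duplicate ``(timeslot, animal)`` pairs are resolved by keeping the
    last record.

    Parameters
    ----------
    records
        Iterable of :class:`PositionRecord` or a DataFrame with columns
        ``timeslot, animal, x, y``.
    animal_order
        Explicit animal ordering; default is lexicographic.

    Raises
    ------
    ValueError
        If no timeslot is shared by all animals.
    """
    if isinstance(records, pd.DataFrame):
        df = records[["timeslot", "animal", "x", "y"]].copy()
    else:
        df = pd.DataFrame(records, columns=["timeslot", "animal", "x", "y"])
    if df.empty:
        raise ValueError("no position records supplied")
    df["animal"] = df["animal"].astype(str)
    df["timeslot"] = df["timeslot"].astype(np.int64)
    df = df.drop_duplicates(subset=["timeslot", "animal"], keep="last")

    animals = sorted(df["animal"].unique())
    if animal_order is not None:
        animal_order = [str(a) for a in animal_order]
        if set(animal_order) != set(animals):
            raise ValueError("animal_order must match the observed animals")
        animals = list(animal_order)

    counts = df.groupby("timeslot")["animal"].nunique()
    complete = counts.index[counts == len(animals)].to_numpy()
    n_dropped = counts.size - complete.size
    if complete.size == 0:
        raise ValueError("no timeslot is shared by all animals")
    if n_dropped:
        logger.warning(
            "dropping %d incomplete timeslot(s); %d complete slot(s) kept",
            n_dropped,
            complete.size,
        )

    sub = df[df["timeslot"].isin(complete)]
    wide_x = sub.pivot(index="timeslot", columns="animal", values="x")
    wide_y = sub.pivot(index="timeslot", columns="animal", values="y")
    wide_x = wide_x.loc[np.sort(complete), animals]
    wide_y = wide_y.loc[np.sort(complete), animals]
    positions = np.stack([wide_x.to_numpy(), wide_y.to_numpy()], axis=-1)
    return TrajectoryDataset(
        animals=tuple(animals),
        timeslots=np.sort(complete),
        positions=positions,
        slot_seconds=slot_seconds,
    )


def read_positions_csv(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    animal_order: Sequence[str] | None = None,
    slot_seconds: float = 0.1,
) -> TrajectoryDataset:
    """Read a trajectory CSV and return a complete-grid dataset.

    Parameters
    ----------
    path
        CSV file with one row per localisation fix.
    columns
        Mapping from the canonical names ``timeslot, animal, x, y`` to
        the column names used in the file (defaults to the canonical
        names themselves).

    Raises
    ------
    ValueError
        On missing columns or non-numeric coordinates (the error names
        the offending row).
    """
    path = Path(path)
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    df = df.rename(columns={v: k for k, v in colmap.items()})
    for col in ("timeslot", "x", "y"):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, plus header line
            raise ValueError(
                f"{path}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r} at line {row}"
            )
        if parsed.isna().any():
            row = int(parsed.isna().idxmax()) + 2
            raise ValueError(f"{path}: empty value in column {col!r} at line {row}")
        df[col] = parsed
    return align_timeslots(df, animal_order=animal_order, slot_seconds=slot_seconds)


def write_positions_csv(dataset: TrajectoryDataset, path: str | Path) -> None:
    """Write a dataset in the same long CSV dialect accepted by
    :func:`read_positions_csv`."""
    dataset.to_frame().to_csv(path, index=False, float_format="%.6f")


def write_matrix_csv(
    matrix: np.ndarray | pd.DataFrame,
    path: str | Path,
    labels: Sequence[str] | None = None,
    decimals: int = 6,
) -> None:
    """Write a labelled square matrix as CSV (labels as header row and
    index column).

    Raises
    ------
    ValueError
        If the matrix is not square or the labels do not match its size.
    """
    if isinstance(matrix, pd.DataFrame):
        df = matrix
        if labels is not None:
            df = pd.DataFrame(df.to_numpy(), index=labels, columns=labels)
    else:
        arr = np.asarray(matrix, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError(f"matrix must be square, got shape {arr.shape}")
        if labels is None:
            labels = [str(i) for i in range(arr.shape[0])]
        if len(labels) != arr.shape[0]:
            raise ValueError(
                f"{len(labels)} labels for a {arr.shape[0]}x{arr.shape[0]} matrix"
            )
        df = pd.DataFrame(arr, index=list(labels), columns=list(labels))
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"matrix must be square, got shape {df.shape}")
    df.to_csv(path, float_format=f"%.{decimals}f", index_label="")


def read_matrix_csv(path: str | Path) -> pd.DataFrame:
    """Read a labelled square matrix written by :func:`write_matrix_csv`."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1] or list(df.index) != list(df.columns):
        raise ValueError(f"{path}: not a labelled square matrix")
    return df.astype(float)
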