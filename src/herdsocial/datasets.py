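"""Bundled example data.

``load_cattle_closeness`` returns the published time-averaged rank
(closeness) matrix from a tracking experiment on a group of ten
yearling cattle during a 25-minute competitive feeding trial (10 Hz
localisation in a 150 x 50 m paddock).  The raw trajectories were
never deposited, so this matrix is the entry point for the worked
example: rows sum to 45 = N(N-1)/2, small entries mean mutually near
animals (the bonded pair 8-10 has the smallest reciprocal entries),
and the full embedding/clustering pipeline runs directly on it.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_matrix_csv

__all__ = ["load_cattle_closeness"]


def load_cattle_closeness() -> pd.DataFrame:
    """The 10x10 example closeness matrix W (labelled DataFrame)."""
    path = resources.files("herdsocial.data") / "cattle10_closeness.csv"
    with resources.as_file(path) as p:
        return read_matrix_csv(p)
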