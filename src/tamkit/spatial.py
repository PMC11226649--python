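"""Score-threshold subset assignment and spatial neighbourhood composition.

Cells in a spatial expression table are assigned to a macrophage subset
when their per-cell signature score is strictly above 0.8, excluded when
strictly below 0.4, and left unassigned in between (the unassigned band is
dropped from composition analyses but remains eligible as a neighbour
under its cell-type label).

Neighbourhood composition pools, over all focal cells, the cell-type
labels of each focal cell's k nearest neighbours in the (x, y) plane
(Euclidean distance, self excluded, ties at the k-th distance broken by
cell-id order), then normalises the pooled counts.  Pooling — rather than
averaging per-cell fractions — weights dense regions by their cell count.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["NeighbourComposition", "assign_by_threshold", "knn_composition",
           "knn_composition_sweep"]

MEMBER, NONMEMBER, UNASSIGNED = "member", "nonmember", "unassigned"


@dataclasses.dataclass
class NeighbourComposition:
    focal: str
    fractions: pd.Series      # neighbour label -> fraction (sums to 1)
    counts: pd.Series         # pooled neighbour label counts
    n_focal: int
    k: int


def assign_by_threshold(scores: pd.Series, hi: float = 0.8,
                        lo: float = 0.4) -> pd.Series:
    """Map scores to member / nonmember / unassigned by strict thresholds.

    ``score > hi`` is a member, ``score < lo`` a nonmember; scores in
    ``[lo, hi]`` (inclusive at both ends, matching the strict inequalities
    of the rule) stay unassigned.
    """
    if lo >= hi:
        raise ValueError(f"lo ({lo}) must be < hi ({hi})")
    out = pd.Series(UNASSIGNED, index=scores.index, name=scores.name)
    out[scores > hi] = MEMBER
    out[scores < lo] = NONMEMBER
    return out


def _neighbour_indices(coords: np.ndarray, focal_rows: np.ndarray, k: int,
                       chunk: int = 512) -> np.ndarray:
    """Indices (focal x k) of k nearest cells, self excluded.

    Rows are assumed already ordered by cell id so that the stable
    tie-break on equal distances is "by cell_id order".  Brute-force
    distances with lexicographic (distance, row) ordering guarantee an
    exact, deterministic result.
    """
    n = coords.shape[0]
    out = np.empty((focal_rows.size, k), dtype=np.int64)
    rows = np.arange(n)
    for start in range(0, focal_rows.size, chunk):
        block = focal_rows[start:start + chunk]
        d2 = ((coords[block, None, :] - coords[None, :, :]) ** 2).sum(-1)
        d2[np.arange(block.size), block] = np.inf  # exclude self
        for i in range(block.size):
            nn = np.lexsort((rows, d2[i]))[:k]
            out[start + i] = nn
    return out


def knn_composition(table: pd.DataFrame, focal: pd.Series | Sequence[str],
                    k: int = 5, label_col: str = "celltype",
                    focal_name: str | None = None) -> NeighbourComposition:
    """Pooled k-nearest-neighbour cell-type composition of a focal subset.

    Parameters
    ----------
    table
        Spatial cell table with ``cell_id``, ``x``, ``y`` and a label
        column; coordinates in micrometres.
    focal
        Boolean mask aligned with ``table`` rows, or an iterable of cell
        ids, designating the focal subset.
    k
        Neighbours per focal cell; the table must hold more than ``k``
        cells.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    required = {"cell_id", "x", "y", label_col}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"spatial table lacks columns: {sorted(missing)}")
    tab = table.sort_values("cell_id", kind="stable").reset_index(drop=True)
    n = len(tab)
    if n <= k:
        raise ValueError(f"need more than k={k} cells, got {n}")
    coords = tab[["x", "y"]].to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")

    if isinstance(focal, pd.Series) and focal.dtype == bool:
        mask = focal.reindex(table.index).to_numpy()
        ids = set(table.loc[mask, "cell_id"])
    else:
        ids = set(focal)
    focal_rows = np.flatnonzero(tab["cell_id"].isin(ids).to_numpy())
    if focal_rows.size == 0:
        raise ValueError("focal subset is empty")

    nn = _neighbour_indices(coords, focal_rows, k)
    labels = tab[label_col].astype(str).to_numpy()
    counts = pd.Series(labels[nn.ravel()]).value_counts().sort_index()
    fractions = counts / counts.sum()
    return NeighbourComposition(
        focal=focal_name or "focal", fractions=fractions, counts=counts,
        n_focal=int(focal_rows.size), k=k)


def knn_composition_sweep(table: pd.DataFrame, focal, ks: Iterable[int] = (1, 5, 10, 20),
                          label_col: str = "celltype",
                          focal_name: str | None = None) -> pd.DataFrame:
    """Neighbour composition across several k (sensitivity sweep).

    Returns a DataFrame k x neighbour-label of fractions.
    """
    rows = {}
    for k in ks:
        comp = knn_composition(table, focal, k=k, label_col=label_col,
                               focal_name=focal_name)
        rows[k] = comp.fractions
    return pd.DataFrame(rows).T.fillna(0.0).rename_axis("k")
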