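"""Spatial lattice, covariate series and occurrence-tensor construction.

The study domain is an arbitrary lattice of cells, each with a terrestrial
fraction ``A_i`` and a set of neighbours (Moore 8-connectivity on rectangular
grids). Presence-only occurrence records — possibly disaggregated from a
coarser grid with fractional weights — are aggregated into weighted count
tensors per (cell, year, dataset) for the focal species and for the
target-group (TG) species whose pooled records proxy sampling effort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OCCURRENCE_COLUMNS = ["dataset", "species", "year", "cell_id", "weight"]


@dataclass
class LatticeGrid:
    """A lattice of cells with terrestrial fractions and symmetric adjacency.

    Attributes
    ----------
    cell_ids : list of str
        Ordered external identifiers, one per cell (row-major on rectangles).
    terrestrial_prop : ndarray of shape (C,)
        Fraction of each cell that is land, ``A_i`` in [0, 1].
    neighbors : list of ndarray
        ``neighbors[i]`` holds the indices of the cells adjacent to cell
        ``i`` (excluding ``i`` itself); adjacency is symmetric.
    n_rows, n_cols : int or None
        Shape for rectangular grids; ``None`` for irregular lattices.
    """

    cell_ids: list[str]
    terrestrial_prop: np.ndarray
    neighbors: list[np.ndarray]
    n_rows: int | None = None
    n_cols: int | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.terrestrial_prop = np.asarray(self.terrestrial_prop, dtype=float)
        if self.terrestrial_prop.shape != (len(self.cell_ids),):
            raise ValueError("terrestrial_prop length must match cell_ids")
        if np.any(self.terrestrial_prop < 0) or np.any(self.terrestrial_prop > 1):
            raise ValueError("terrestrial proportions must lie in [0, 1]")
        if len(self.neighbors) != len(self.cell_ids):
            raise ValueError("neighbors length must match cell_ids")
        self.neighbors = [np.asarray(nb, dtype=int) for nb in self.neighbors]
        for i, nb in enumerate(self.neighbors):
            if i in nb:
                raise ValueError(f"cell {i} listed as its own neighbor")
            for j in nb:
                if i not in self.neighbors[j]:
                    raise ValueError("adjacency is not symmetric")
        self._index = {c: i for i, c in enumerate(self.cell_ids)}

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_neighbors(self) -> np.ndarray:
        """Number of adjacent cells per cell (3–8 on a full rectangle)."""
        return np.array([len(nb) for nb in self.neighbors])

    def cell_index(self, cell_id: str) -> int:
        return self._index[cell_id]

    def adjacency_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Flat (target, source) index arrays of all adjacent pairs (cached)."""
        if not hasattr(self, "_adj_pairs"):
            tgt = np.concatenate(self.neighbors) if self.n_cells > 1 else np.empty(0, int)
            src = np.repeat(np.arange(self.n_cells), self.n_neighbors)
            self._adj_pairs = (tgt.astype(int), src)
        return self._adj_pairs


@dataclass
class EnvSeries:
    """Per-cell, per-year environment: suitability covariates and urban cover.

    ``covariates[i, t, j]`` is covariate ``j`` (without intercept) in cell
    ``i`` during year ``years[t]``; ``urban[i, t]`` is the settlement
    fraction ``a_i`` driving human-mediated long-distance dispersal.
    """

    years: np.ndarray
    covariates: np.ndarray  # (C, T, J)
    urban: np.ndarray  # (C, T)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.covariates = np.asarray(self.covariates, dtype=float)
        self.urban = np.asarray(self.urban, dtype=float)
        C, T, _ = self.covariates.shape
        if self.urban.shape != (C, T) or len(self.years) != T:
            raise ValueError("inconsistent EnvSeries dimensions")
        if np.any(self.urban < 0) or np.any(self.urban > 1):
            raise ValueError("urban cover must lie in [0, 1]")
        if np.any(~np.isfinite(self.covariates)):
            raise ValueError("covariates contain missing values")

    @property
    def n_years(self) -> int:
        return len(self.years)

    def year_index(self, year: int) -> int:
        t = int(np.searchsorted(self.years, year))
        if t >= len(self.years) or self.years[t] != year:
            raise KeyError(f"year {year} not covered by EnvSeries")
        return t


def build_rect_grid(
    n_rows: int,
    n_cols: int,
    terrestrial_prop: np.ndarray | float = 1.0,
) -> LatticeGrid:
    """Build a rectangular lattice with Moore (8-connected) adjacency.

    Cells are ordered row-major and labelled ``r{row}c{col}``. Interior
    cells have 8 neighbours, edges 5 and corners 3; a 1x1 grid has none.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be positive")
    C = n_rows * n_cols
    terr = np.broadcast_to(np.asarray(terrestrial_prop, dtype=float), (C,)).copy()
    cell_ids = [f"r{r}c{c}" for r in range(n_rows) for c in range(n_cols)]
    neighbors: list[np.ndarray] = []
    for r in range(n_rows):
        for c in range(n_cols):
            nb = [
                rr * n_cols + cc
                for rr in range(max(r - 1, 0), min(r + 2, n_rows))
                for cc in range(max(c - 1, 0), min(c + 2, n_cols))
                if (rr, cc) != (r, c)
            ]
            neighbors.append(np.array(nb, dtype=int))
    return LatticeGrid(cell_ids, terr, neighbors, n_rows=n_rows, n_cols=n_cols)


def disaggregate_record(
    record: dict,
    fine_cells: list[str],
    decimals: int | None = 4,
) -> pd.DataFrame:
    """Split a coarse-grid record uniformly over the nested fine cells.

    Each sub-record receives weight ``1/len(fine_cells)`` (0.1111 at 4
    decimals for the quarter-degree → 9-cell case), the weights summing to
    1 before rounding. ``decimals=None`` keeps exact weights.
    """
    if not fine_cells:
        raise ValueError("fine_cells must be nonempty")
    w = 1.0 / len(fine_cells)
    if decimals is not None:
        w = round(w, decimals)
    rows = [
        {
            "dataset": record["dataset"],
            "species": record["species"],
            "year": record["year"],
            "cell_id": cell,
            "weight": w,
        }
        for cell in fine_cells
    ]
    return pd.DataFrame(rows, columns=OCCURRENCE_COLUMNS)


def build_count_tensors(
    table: pd.DataFrame,
    focal: str,
    tg_species: dict[str, list[str]],
    grid: LatticeGrid,
    years: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Aggregate weighted records into the observation and effort tensors.

    Returns ``y[i, t, d]`` (summed focal-record weights), ``N_tg[i, t, d]``
    (summed weights over each dataset's TG species, focal included) and the
    number of records dropped for falling outside the grid or year range.

    The dataset axis follows ``sorted(tg_species)``. Because every TG
    contains its focal species, ``y`` is zero wherever ``N_tg`` is zero.
    """
    years = np.asarray(years, dtype=int)
    datasets = sorted(tg_species)
    for d in datasets:
        if focal not in tg_species[d]:
            raise ValueError(f"TG of dataset {d!r} must contain the focal species")
    C, T, D = grid.n_cells, len(years), len(datasets)
    y = np.zeros((C, T, D))
    n_tg = np.zeros((C, T, D))
    year_pos = {int(yr): t for t, yr in enumerate(years)}
    ds_pos = {d: k for k, d in enumerate(datasets)}
    dropped = 0
    for row in table.itertuples(index=False):
        if row.weight <= 0:
            raise ValueError("record weights must be positive")
        t = year_pos.get(int(row.year))
        i = grid._index.get(row.cell_id)
        d = ds_pos.get(row.dataset)
        if t is None or i is None or d is None:
            dropped += 1
            continue
        if row.species in tg_species[row.dataset]:
            n_tg[i, t, d] += row.weight
        if row.species == focal:
            y[i, t, d] += row.weight
    if dropped:
        logger.info("build_count_tensors: dropped %d out-of-domain records", dropped)
    return y, n_tg, dropped


def interpolate_landcover(
    anchors: dict[int, np.ndarray],
    years: np.ndarray,
) -> np.ndarray:
    """Linearly interpolate percent-cover grids between anchor years.

    Outside the anchor range the nearest anchor pair's slope extrapolates
    the series; results are clipped to [0, 100]. A single anchor extends as
    a constant (with a warning, since no slope is defined).
    """
    years = np.asarray(years, dtype=int)
    anchor_years = sorted(anchors)
    values = np.stack([np.asarray(anchors[a], dtype=float) for a in anchor_years])
    if len(anchor_years) == 1:
        logger.warning("single land-cover anchor: extending as a constant")
        return np.tile(values[0], (len(years), 1)).T
    ay = np.asarray(anchor_years, dtype=float)
    out = np.empty((values.shape[1], len(years)))
    for t, yr in enumerate(years):
        if yr <= ay[0]:
            lo, hi = 0, 1
        elif yr >= ay[-1]:
            lo, hi = len(ay) - 2, len(ay) - 1
        else:
            hi = int(np.searchsorted(ay, yr, side="right"))
            lo = hi - 1
        frac = (yr - ay[lo]) / (ay[hi] - ay[lo])
        out[:, t] = values[lo] + frac * (values[hi] - values[lo])
    return np.clip(out, 0.0, 100.0)


def reduce_bioclim_svd(biovars: np.ndarray, n_axes: int = 2) -> np.ndarray:
    """Project centred-and-scaled bioclimatic variables on leading SVD axes.

    Each column (variable) is standardised over all (cell, year) rows, then
    the scores along the first ``n_axes`` left singular vectors are
    returned. The sign of each axis is fixed so that its largest-magnitude
    loading is positive, making the output reproducible.
    """
    X = np.asarray(biovars, dtype=float)
    if X.ndim != 2:
        raise ValueError("biovars must be a 2-D (rows x variables) matrix")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    if n_axes > min(Z.shape):
        raise ValueError(f"n_axes={n_axes} exceeds the {min(Z.shape)} available axes")
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U[:, :n_axes] * s[:n_axes]
    tol = (s[0] if s.size else 0.0) * max(Z.shape) * np.finfo(float).eps
    for j in range(n_axes):
        if s[j] <= tol:
            scores[:, j] = 0.0  # axis beyond the numerical rank carries no signal
            continue
        k = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, k] < 0:
            scores[:, j] *= -1.0
    return scores
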