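"""CSV / YAML readers and writers for the pipeline's file formats.

Everything is plain text: grids and tensors as long-format CSV, parameter
sets and run configuration as YAML. The column layouts here are the
contract between the command-line stages.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .lattice import EnvSeries, LatticeGrid, build_rect_grid

__all__ = [
    "write_grid", "read_grid",
    "write_env", "read_env",
    "write_tensor", "read_tensor",
    "write_trajectory",
    "write_params", "read_params",
]


def write_grid(grid: LatticeGrid, path: str | Path) -> None:
    rows = []
    for i, cid in enumerate(grid.cell_ids):
        r, c = (divmod(i, grid.n_cols) if grid.n_cols else (None, None))
        rows.append({"cell_id": cid, "row": r, "col": c,
                     "terrestrial_prop": grid.terrestrial_prop[i]})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_grid(path: str | Path) -> LatticeGrid:
    df = pd.read_csv(path)
    n_rows, n_cols = int(df["row"].max()) + 1, int(df["col"].max()) + 1
    order = (df["row"] * n_cols + df["col"]).to_numpy()
    terr = np.empty(n_rows * n_cols)
    terr[order] = df["terrestrial_prop"].to_numpy()
    return build_rect_grid(n_rows, n_cols, terr)


def write_env(env: EnvSeries, grid: LatticeGrid, path: str | Path) -> None:
    C, T, J = env.covariates.shape
    recs = []
    for j in range(J):
        for t in range(T):
            for i in range(C):
                recs.append((grid.cell_ids[i], int(env.years[t]), f"x{j}",
                             env.covariates[i, t, j]))
    for t in range(T):
        for i in range(C):
            recs.append((grid.cell_ids[i], int(env.years[t]), "urban",
                         env.urban[i, t]))
    pd.DataFrame(recs, columns=["cell_id", "year", "variable", "value"]).to_csv(
        path, index=False)


def read_env(path: str | Path, grid: LatticeGrid) -> EnvSeries:
    df = pd.read_csv(path)
    years = np.sort(df["year"].unique())
    cov_vars = sorted(v for v in df["variable"].unique() if v != "urban")
    C, T = grid.n_cells, len(years)
    x = np.zeros((C, T, len(cov_vars)))
    urban = np.zeros((C, T))
    tpos = {int(y): t for t, y in enumerate(years)}
    vpos = {v: j for j, v in enumerate(cov_vars)}
    for row in df.itertuples(index=False):
        i, t = grid.cell_index(row.cell_id), tpos[int(row.year)]
        if row.variable == "urban":
            urban[i, t] = row.value
        else:
            x[i, t, vpos[row.variable]] = row.value
    return EnvSeries(years, x, urban)


def write_tensor(tensor: np.ndarray, grid: LatticeGrid, years: np.ndarray,
                 datasets: list[str], path: str | Path) -> None:
    """Long-format (cell_id, year, dataset, value), zeros omitted."""
    recs = []
    idx = np.argwhere(tensor != 0)
    for i, t, d in idx:
        recs.append((grid.cell_ids[i], int(years[t]), datasets[d],
                     tensor[i, t, d]))
    pd.DataFrame(recs, columns=["cell_id", "year", "dataset", "value"]).to_csv(
        path, index=False)


def read_tensor(path: str | Path, grid: LatticeGrid, years: np.ndarray,
                datasets: list[str]) -> np.ndarray:
    df = pd.read_csv(path)
    out = np.zeros((grid.n_cells, len(years), len(datasets)))
    tpos = {int(y): t for t, y in enumerate(np.asarray(years))}
    dpos = {d: k for k, d in enumerate(datasets)}
    for row in df.itertuples(index=False):
        out[grid.cell_index(row.cell_id), tpos[int(row.year)],
            dpos[row.dataset]] = row.value
    return out


def write_trajectory(traj: np.ndarray, grid: LatticeGrid, years: np.ndarray,
                     path: str | Path) -> None:
    """Long-format (cell_id, year, age, count), zeros omitted."""
    recs = []
    for i, t, k in np.argwhere(traj != 0):
        recs.append((grid.cell_ids[i], int(years[t]), k + 1, int(traj[i, t, k])))
    pd.DataFrame(recs, columns=["cell_id", "year", "age", "count"]).to_csv(
        path, index=False)


def write_params(values: dict, path: str | Path) -> None:
    clean = {
        k: (v.tolist() if isinstance(v, np.ndarray) else v)
        for k, v in values.items()
    }
    Path(path).write_text(yaml.safe_dump(clean, sort_keys=False))


def read_params(path: str | Path) -> dict:
    raw = yaml.safe_load(Path(path).read_text())
    return {
        k: (np.asarray(v, dtype=float) if isinstance(v, list) else v)
        for k, v in raw.items()
    }
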