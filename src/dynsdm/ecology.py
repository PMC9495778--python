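"""Deterministic age-structured invasion dynamics on a lattice.

The hidden state is the integer abundance ``n[i, t, k]`` of plants of age
``k`` (1..K) in cell ``i`` during year ``t``. Each year:

* plants survive with probability ``1 - rho`` and age by one year,
  ``n[i, t+1, k] = round((1 - rho) * n[i, t, k-1])``;
* every plant of age ``k`` sheds ``f(k) = floor(M k^theta / (k_hat^theta +
  k^theta))`` seeds, zero before the maturity age ``k_hat``;
* seeds disperse through a stratified kernel: a reference share stays in
  the source cell, a share ``ds`` per neighbour moves to each adjacent
  cell, and a share ``dl * a`` (``a`` the source's urban cover) is spread
  uniformly over every non-adjacent cell — the human-mediated long-distance
  pathway; the kernel is column-normalised so all seeds land somewhere;
* arriving seeds recruit into age-1 plants limited by self-regulation
  against the cell's carrying capacity ``p * A * phi`` and filtered by the
  logistic environmental suitability ``p = expit(beta . x)``.

All rounding is half-away-from-zero so results do not depend on the parity
conventions of banker's rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import binom

from .lattice import EnvSeries, LatticeGrid

__all__ = [
    "DemographyParams",
    "DispersalParams",
    "SuitabilityParams",
    "InitialPopulationParams",
    "fecundity",
    "dispersal_matrix",
    "apply_dispersal",
    "suitability",
    "self_regulation_ratio",
    "step_transition",
    "initial_state",
    "simulate_trajectory",
    "TrajectoryDetails",
    "round_half_away",
]


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to the nearest integer, halves away from zero."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass
class DemographyParams:
    """Mortality, carrying capacity and fecundity-curve parameters.

    rho     annual death probability of any plant (age-independent);
    phi     maximum number of plants in a fully terrestrial cell;
    k_hat   age of reproductive maturity (years);
    theta   allometric scaling exponent of the fecundity curve;
    M       maximum (saturating) fecundity, seeds per plant per year.
    """

    rho: float
    phi: float
    k_hat: float
    theta: float
    M: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if min(self.phi, self.k_hat, self.theta, self.M) <= 0:
            raise ValueError("phi, k_hat, theta, M must be positive")


@dataclass
class DispersalParams:
    """Stratified dispersal: short-distance ``ds`` and long-distance ``dl``."""

    ds: float
    dl: float

    def __post_init__(self) -> None:
        if self.ds <= 0:
            raise ValueError("ds must be positive")
        if self.dl < 0:
            raise ValueError("dl must be nonnegative")

    @classmethod
    def unchecked(cls, ds: float, dl: float) -> "DispersalParams":
        """Bypass validation — for counterfactual simulations with ds = 0."""
        obj = cls.__new__(cls)
        obj.ds = ds
        obj.dl = dl
        return obj


@dataclass
class SuitabilityParams:
    """Logistic suitability coefficients, intercept first."""

    beta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))


@dataclass
class InitialPopulationParams:
    """First-year populations in the introduction cells.

    Each introduction cell ``m`` carries two free parameters: its total
    size ``pop_ini[m]`` and ``age_ratio[m]`` in (0, 1), which sets the age
    structure to a binomial(K, age_ratio) profile with mean age
    ``K * age_ratio``.
    """

    cells: np.ndarray
    pop_ini: np.ndarray
    age_ratio: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.atleast_1d(np.asarray(self.cells, dtype=int))
        self.pop_ini = np.atleast_1d(np.asarray(self.pop_ini, dtype=float))
        self.age_ratio = np.atleast_1d(np.asarray(self.age_ratio, dtype=float))
        if len(set(self.cells.tolist())) != len(self.cells):
            raise ValueError("introduction cells must be distinct")
        if not (len(self.cells) == len(self.pop_ini) == len(self.age_ratio)):
            raise ValueError("per-cell parameter arrays must align")
        if np.any(self.pop_ini <= 0):
            raise ValueError("pop_ini must be positive")
        if np.any(self.age_ratio <= 0) or np.any(self.age_ratio >= 1):
            raise ValueError("age_ratio must lie in (0, 1)")

    @property
    def n_intro(self) -> int:
        return len(self.cells)


def fecundity(
    k: np.ndarray | int,
    demog: DemographyParams,
    strict_maturity: bool = True,
) -> np.ndarray:
    """Seeds produced in a year by a plant of age ``k``.

    ``floor(M k^theta / (k_hat^theta + k^theta))`` — a sigmoid rising at
    the maturity age ``k_hat`` and saturating at ``M``. With
    ``strict_maturity`` (default) the output is forced to zero below
    ``k_hat``: the floor alone only guarantees that for moderate ``M``.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 1):
        raise ValueError("ages start at 1")
    ratio = k**demog.theta / (demog.k_hat**demog.theta + k**demog.theta)
    f = np.floor(demog.M * ratio)
    if strict_maturity:
        f = np.where(k < demog.k_hat, 0.0, f)
    return f


def _kernel_pieces(
    grid: LatticeGrid, disp_params: DispersalParams, urban: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-source normalisation D and uniform long-distance rate dl*a/D."""
    urban = np.asarray(urban, dtype=float)
    C = grid.n_cells
    n_neig = grid.n_neighbors
    ld = disp_params.dl * urban
    D = (C - 1 - n_neig) * ld + n_neig * disp_params.ds + 1.0
    return D, ld / D


def dispersal_matrix(
    grid: LatticeGrid,
    disp_params: DispersalParams,
    urban: np.ndarray,
) -> np.ndarray:
    """Dense column-stochastic kernel ``disp[i, i']`` (column = source).

    Entries are ``1/D`` for the source cell itself, ``ds/D`` for each of
    its neighbours and ``dl * a / D`` for every other cell, with ``D``
    chosen so each column sums to one: all seeds produced are distributed
    over the domain, border cells included.
    """
    C = grid.n_cells
    D, q = _kernel_pieces(grid, disp_params, urban)
    disp = np.tile(q, (C, 1))
    tgt, src = grid.adjacency_pairs()
    disp[tgt, src] = disp_params.ds / D[src]
    disp[np.arange(C), np.arange(C)] = 1.0 / D
    return disp


def apply_dispersal(
    grid: LatticeGrid,
    disp_params: DispersalParams,
    urban: np.ndarray,
    seeds_out: np.ndarray,
) -> np.ndarray:
    """Seed rain per cell without materialising the C x C kernel.

    Exploits the rank-1 structure of the long-distance block: identical to
    ``dispersal_matrix(...) @ seeds_out`` up to floating-point roundoff.
    """
    D, q = _kernel_pieces(grid, disp_params, urban)
    v = np.asarray(seeds_out, dtype=float)
    ld_total = float(q @ v)
    rain = np.full(grid.n_cells, ld_total)
    rain += v / D - q * v
    neigh_term = disp_params.ds * v / D
    for src in range(grid.n_cells):
        nb = grid.neighbors[src]
        rain[nb] += neigh_term[src]
        rain[nb] -= q[src] * v[src]
    return rain


def suitability(x: np.ndarray, suit: SuitabilityParams) -> np.ndarray:
    """Logistic suitability ``expit(beta . [1, x])`` per cell.

    ``x`` has shape (C, J); an intercept column is prepended.
    """
    x = np.asarray(x, dtype=float)
    X = np.column_stack([np.ones(x.shape[0]), x])
    if X.shape[1] != len(suit.beta):
        raise ValueError(
            f"covariate dimension {X.shape[1] - 1} does not match "
            f"beta length {len(suit.beta)} (intercept included)"
        )
    return expit(X @ suit.beta)


def self_regulation_ratio(
    capacity: np.ndarray,
    survivors: np.ndarray,
    seeds: np.ndarray,
) -> np.ndarray:
    """Share of incident seeds surviving self-regulation, in [0, 1].

    ``max(capacity - survivors, 0) / max(capacity, seeds)`` — free slots
    over seed supply, saturating so the next-year population cannot exceed
    the carrying capacity. The degenerate 0/0 case (no capacity, no seeds)
    is defined as 0.
    """
    capacity = np.asarray(capacity, dtype=float)
    survivors = np.asarray(survivors, dtype=float)
    seeds = np.asarray(seeds, dtype=float)
    denom = np.maximum(capacity, seeds)
    free = np.maximum(capacity - survivors, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, free / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(c, 0.0, 1.0)


def step_transition(
    n: np.ndarray,
    x_next: np.ndarray,
    urban_now: np.ndarray,
    grid: LatticeGrid,
    demog: DemographyParams,
    disp_params: DispersalParams,
    suit: SuitabilityParams,
    strict_maturity: bool = True,
    dense_kernel: bool = True,
    details: dict | None = None,
    kernel: np.ndarray | None = None,
    fec: np.ndarray | None = None,
) -> np.ndarray:
    """One yearly transition of the hidden state ``n`` (shape (C, K)).

    Order of computation: (a) survivors age and die; (b) the year-t state
    sheds seeds which disperse through the kernel built from year-t urban
    cover; (c) suitability is evaluated on year-t+1 covariates; (d) seeds
    recruit subject to self-regulation and suitability. If ``details`` is
    a dict it receives the intermediate fields used by the post-fit
    analyses (seed output/rain, long-distance rain share, suitability,
    self-regulation ratio, recruits).
    """
    n = np.asarray(n, dtype=float)
    C, K = n.shape
    if C != grid.n_cells:
        raise ValueError("state does not match grid")
    n_next = np.zeros_like(n)
    n_next[:, 1:] = round_half_away((1.0 - demog.rho) * n[:, :-1])

    f = fec if fec is not None else fecundity(
        np.arange(1, K + 1), demog, strict_maturity=strict_maturity)
    seeds_out = n @ f
    if kernel is not None:
        seed_rain = kernel @ seeds_out
    elif dense_kernel:
        seed_rain = dispersal_matrix(grid, disp_params, urban_now) @ seeds_out
    else:
        seed_rain = apply_dispersal(grid, disp_params, urban_now, seeds_out)

    p_next = suitability(x_next, suit)
    capacity = p_next * grid.terrestrial_prop * demog.phi
    survivors = n_next[:, 1:].sum(axis=1)
    c = self_regulation_ratio(capacity, survivors, seed_rain)
    n_next[:, 0] = round_half_away(seed_rain * c * p_next)

    if details is not None:
        # long-distance component of the rain: total minus self+neighbour
        D, q = _kernel_pieces(grid, disp_params, urban_now)
        local = seeds_out / D
        tgt, src = grid.adjacency_pairs()
        np.add.at(local, tgt, disp_params.ds * seeds_out[src] / D[src])
        details.update(
            seeds_out=seeds_out,
            seed_rain=seed_rain,
            ld_rain=np.maximum(seed_rain - local, 0.0),
            p_next=p_next,
            capacity=capacity,
            c_ratio=c,
            recruits=n_next[:, 0].copy(),
            inv_D=1.0 / D,
        )
    return n_next


def initial_state(
    init: InitialPopulationParams,
    K: int,
    n_cells: int,
) -> np.ndarray:
    """First-year state (C, K) from the introduction-cell parameters.

    In introduction cell ``m`` the count at age ``k`` (1..K) is
    ``round(pop_ini[m] * BinomPMF(k; K, age_ratio[m]))`` — the literal
    binomial profile on k = 1..K, with the unused k = 0 mass simply
    dropped (no renormalisation). All other cells start empty.
    """
    if np.any(init.cells < 0) or np.any(init.cells >= n_cells):
        raise ValueError("introduction cell index outside grid")
    n = np.zeros((n_cells, K))
    ages = np.arange(1, K + 1)
    for i, pop, ar in zip(init.cells, init.pop_ini, init.age_ratio):
        n[i] = round_half_away(pop * binom.pmf(ages, K, ar))
    return n


@dataclass
class TrajectoryDetails:
    """Per-year intermediates of a simulated trajectory (post-fit analyses).

    Arrays have shape (C, T-1); entry ``[:, t]`` describes the transition
    from year index t to t+1.
    """

    seeds_out: np.ndarray
    seed_rain: np.ndarray
    ld_rain: np.ndarray
    p_next: np.ndarray
    c_ratio: np.ndarray
    recruits: np.ndarray
    inv_D: np.ndarray
    capacity: np.ndarray = field(default=None)  # type: ignore[assignment]


def simulate_trajectory(
    init: InitialPopulationParams,
    env: EnvSeries,
    grid: LatticeGrid,
    demog: DemographyParams,
    disp_params: DispersalParams,
    suit: SuitabilityParams,
    K: int = 50,
    strict_maturity: bool = True,
    dense_kernel: bool = True,
    return_details: bool = False,
):
    """Deterministic trajectory ``n[i, t, k]`` over all years of ``env``.

    The dispersal kernel is rebuilt every year from that year's urban
    cover. Returns an array of shape (C, T, K); with ``return_details``
    also a :class:`TrajectoryDetails` of per-transition intermediates.
    """
    C, T = grid.n_cells, env.n_years
    traj = np.zeros((C, T, K))
    traj[:, 0, :] = initial_state(init, K, C)
    collected: list[dict] | None = [] if return_details else None
    fec = fecundity(np.arange(1, K + 1), demog, strict_maturity=strict_maturity)
    kernel = prev_urban = None
    for t in range(T - 1):
        det: dict | None = {} if return_details else None
        urban_t = env.urban[:, t]
        if dense_kernel:
            # the kernel only changes when the urban surface does
            if kernel is None or not np.array_equal(urban_t, prev_urban):
                kernel = dispersal_matrix(grid, disp_params, urban_t)
                prev_urban = urban_t
        traj[:, t + 1, :] = step_transition(
            traj[:, t, :],
            env.covariates[:, t + 1, :],
            urban_t,
            grid,
            demog,
            disp_params,
            suit,
            strict_maturity=strict_maturity,
            dense_kernel=dense_kernel,
            details=det,
            kernel=kernel,
            fec=fec,
        )
        if collected is not None:
            collected.append(det)  # type: ignore[arg-type]
    if not return_details:
        return traj
    stack = lambda key: np.stack([d[key] for d in collected], axis=1)  # noqa: E731
    details = TrajectoryDetails(
        seeds_out=stack("seeds_out"),
        seed_rain=stack("seed_rain"),
        ld_rain=stack("ld_rain"),
        p_next=stack("p_next"),
        c_ratio=stack("c_ratio"),
        recruits=stack("recruits"),
        inv_D=stack("inv_D"),
        capacity=stack("capacity"),
    )
    return traj, details
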