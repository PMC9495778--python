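"""Bayesian fitting of the invasion model.

The parameter vector concatenates, in a fixed layout, the initial-population
block (pop_ini and age_ratio per introduction cell), the ecological block
(rho, phi, k_hat, theta, M, ds, dl, beta), and the sampling block (one
detection rate per dataset). Sampling runs on transformed scales — log for
positive parameters, logit for probabilities, identity for the suitability
coefficients — with the transform Jacobians folded into the target density.

Inference is a component-block Gaussian random-walk Metropolis–Hastings
sampler run in successive sessions: the first session starts each chain
from independent prior draws, later sessions restart every chain from the
best draw of the previous session — a cheap way to climb a rugged
posterior surface before measuring it. Convergence is assessed with the
Brooks–Gelman corrected potential scale reduction factor (PSRF) per
parameter and its multivariate version (MPSRF).

The maturity age ``k_hat`` is proposed on a continuous latent scale and
floored (to at least 1) when the model is evaluated, so a single
Metropolis kernel handles the one integer-like parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .ecology import (
    DemographyParams,
    DispersalParams,
    InitialPopulationParams,
    SuitabilityParams,
    simulate_trajectory,
)
from .lattice import EnvSeries, LatticeGrid
from .sampling import DetectionParams, poisson_loglik, sampling_effort

__all__ = [
    "Prior",
    "default_priors",
    "ParameterMapper",
    "ModelData",
    "MCMCConfig",
    "PosteriorSamples",
    "log_prior",
    "make_log_posterior",
    "metropolis_hastings",
    "multi_session_fit",
    "gelman_rubin",
]

_TRANSFORMS = {"log", "logit", "identity"}


@dataclass
class Prior:
    """One named prior: a scipy frozen distribution applied elementwise."""

    family: str
    args: tuple

    def _frozen(self):
        # freezing a scipy distribution is expensive; do it once
        cached = getattr(self, "_dist", None)
        if cached is None:
            cached = self._dist = self._freeze()
        return cached

    def _freeze(self):
        f, a = self.family, self.args
        if f == "beta":
            return stats.beta(*a)
        if f == "lognorm":  # args = (mean of log, sd of log)
            return stats.lognorm(s=a[1], scale=np.exp(a[0]))
        if f == "norm":
            return stats.norm(*a)
        if f == "halfnorm":  # args = (scale,)
            return stats.halfnorm(scale=a[0])
        if f == "uniform":  # args = (lo, hi)
            return stats.uniform(loc=a[0], scale=a[1] - a[0])
        raise ValueError(f"unknown prior family {f!r}")

    def logpdf(self, x: np.ndarray) -> float:
        """Sum of log densities, evaluated in closed form for speed."""
        x = np.asarray(x, dtype=float)
        f, a = self.family, self.args
        if f == "beta":
            if np.any(x <= 0) or np.any(x >= 1):
                return -np.inf
            from scipy.special import betaln

            v = (a[0] - 1) * np.log(x) + (a[1] - 1) * np.log1p(-x) - betaln(*a)
        elif f == "lognorm":
            if np.any(x <= 0):
                return -np.inf
            lx = np.log(x)
            v = (-lx - np.log(a[1]) - 0.5 * np.log(2 * np.pi)
                 - (lx - a[0]) ** 2 / (2 * a[1] ** 2))
        elif f == "norm":
            v = (-np.log(a[1]) - 0.5 * np.log(2 * np.pi)
                 - (x - a[0]) ** 2 / (2 * a[1] ** 2))
        elif f == "halfnorm":
            if np.any(x < 0):
                return -np.inf
            v = (0.5 * np.log(2 / np.pi) - np.log(a[0])
                 - x**2 / (2 * a[0] ** 2))
        elif f == "uniform":
            if np.any(x < a[0]) or np.any(x > a[1]):
                return -np.inf
            v = np.full_like(x, -np.log(a[1] - a[0]))
        else:
            v = self._frozen().logpdf(x)
        return float(np.sum(v))

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return np.atleast_1d(self._frozen().rvs(size=size, random_state=rng))


def default_priors() -> dict[str, Prior]:
    """Weakly informative defaults, overridable per parameter.

    Mortality gets a Beta centred at one half; positive scale parameters
    get log-normals; dispersal rates get half-normals shrinking toward
    zero; the maturity age gets a log-normal whose mode sits slightly
    below 3 years; suitability coefficients are diffuse normals. Real
    applications should tighten these from the literature.
    """
    return {
        "pop_ini": Prior("lognorm", (np.log(50.0), 1.5)),
        "age_ratio": Prior("beta", (2.0, 6.0)),
        "rho": Prior("beta", (2.0, 2.0)),
        "phi": Prior("lognorm", (np.log(300.0), 1.0)),
        "k_hat": Prior("lognorm", (np.log(2.5) + 0.35**2, 0.35)),
        "theta": Prior("lognorm", (np.log(6.0), 0.5)),
        "M": Prior("lognorm", (np.log(600.0), 1.0)),
        "ds": Prior("halfnorm", (0.5,)),
        "dl": Prior("halfnorm", (0.2,)),
        "beta": Prior("norm", (0.0, 2.0)),
        "p_detec": Prior("lognorm", (np.log(1e-3), 1.0)),
    }


@dataclass
class ParameterMapper:
    """Fixed layout of the parameter vector, with optional frozen slots.

    ``n_intro`` introduction cells contribute ``2 * n_intro`` parameters,
    the ecological block 7 scalars plus ``n_beta`` coefficients, the
    sampling block ``n_datasets`` detection rates. Slots named in
    ``fixed`` keep their given natural-scale values and are excluded from
    the free vector the sampler sees.
    """

    n_intro: int
    n_beta: int
    n_datasets: int
    fixed: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.slots: list[tuple[str, int, str]] = [
            ("pop_ini", self.n_intro, "log"),
            ("age_ratio", self.n_intro, "logit"),
            ("rho", 1, "logit"),
            ("phi", 1, "log"),
            ("k_hat", 1, "log"),
            ("theta", 1, "log"),
            ("M", 1, "log"),
            ("ds", 1, "log"),
            ("dl", 1, "log"),
            ("beta", self.n_beta, "identity"),
            ("p_detec", self.n_datasets, "log"),
        ]
        self.fixed = {
            k: np.atleast_1d(np.asarray(v, dtype=float))
            for k, v in self.fixed.items()
        }
        names = [s[0] for s in self.slots]
        for k in self.fixed:
            if k not in names:
                raise ValueError(f"unknown fixed slot {k!r}")
        self.free_slots = [s for s in self.slots if s[0] not in self.fixed]
        self.blocks: list[tuple[str, slice]] = []
        pos = 0
        for name, size, _ in self.free_slots:
            self.blocks.append((name, slice(pos, pos + size)))
            pos += size
        self.n_free = pos
        self.free_names: list[str] = [
            name if size == 1 else f"{name}_{j}"
            for name, size, _ in self.free_slots
            for j in range(size)
        ]

    @property
    def n_params(self) -> int:
        return sum(size for _, size, _ in self.slots)

    def to_transformed(self, values: dict[str, np.ndarray]) -> np.ndarray:
        """Natural-scale dict -> free transformed vector."""
        parts = []
        for name, size, tr in self.free_slots:
            if size == 0:
                continue
            v = np.broadcast_to(np.asarray(values[name], dtype=float), (size,))
            if tr == "log":
                parts.append(np.log(v))
            elif tr == "logit":
                parts.append(logit(v))
            else:
                parts.append(v.astype(float))
        return np.concatenate(parts) if parts else np.empty(0)

    def to_natural(self, eta: np.ndarray) -> dict[str, np.ndarray]:
        """Free transformed vector -> full natural-scale dict."""
        out = {k: v.copy() for k, v in self.fixed.items()}
        for (name, _, tr), (_, sl) in zip(self.free_slots, self.blocks):
            v = np.asarray(eta[sl], dtype=float)
            if tr == "log":
                out[name] = np.exp(v)
            elif tr == "logit":
                out[name] = expit(v)
            else:
                out[name] = v.copy()
        return out

    def log_jacobian(self, eta: np.ndarray) -> float:
        """log |d(natural)/d(transformed)| of the free coordinates."""
        lj = 0.0
        for (name, _, tr), (_, sl) in zip(self.free_slots, self.blocks):
            v = eta[sl]
            if tr == "log":
                lj += float(v.sum())
            elif tr == "logit":
                lj += float((np.log(expit(v)) + np.log(expit(-v))).sum())
        return lj


def log_prior(values: dict[str, np.ndarray], priors: dict[str, Prior]) -> float:
    """Sum of natural-scale log prior densities; -inf out of support."""
    total = 0.0
    for name, v in values.items():
        if name not in priors:
            raise KeyError(f"no prior declared for slot {name!r}")
        lp = priors[name].logpdf(v)
        if not np.isfinite(lp):
            return -np.inf
        total += lp
    return total


@dataclass
class ModelData:
    """Everything the likelihood needs besides the parameters."""

    grid: LatticeGrid
    env: EnvSeries
    y: np.ndarray  # (C, T, D)
    n_tg: np.ndarray  # (C, T, D)
    intro_cells: np.ndarray
    K: int = 50
    strict_maturity: bool = True

    def __post_init__(self) -> None:
        self.intro_cells = np.atleast_1d(np.asarray(self.intro_cells, dtype=int))
        C, T = self.grid.n_cells, self.env.n_years
        if self.y.shape[:2] != (C, T) or self.n_tg.shape != self.y.shape:
            raise ValueError("tensor shapes do not match grid/env")

    def mapper(self, fixed: dict | None = None) -> ParameterMapper:
        return ParameterMapper(
            n_intro=len(self.intro_cells),
            n_beta=self.env.covariates.shape[2] + 1,
            n_datasets=self.y.shape[2],
            fixed=fixed or {},
        )


def _unpack_params(values: dict[str, np.ndarray], data: ModelData):
    demog = DemographyParams(
        rho=float(values["rho"][0]),
        phi=float(values["phi"][0]),
        k_hat=max(1.0, float(np.floor(values["k_hat"][0]))),
        theta=float(values["theta"][0]),
        M=float(values["M"][0]),
    )
    disp = DispersalParams(ds=float(values["ds"][0]), dl=float(values["dl"][0]))
    suit = SuitabilityParams(beta=values["beta"])
    init = InitialPopulationParams(
        cells=data.intro_cells,
        pop_ini=values["pop_ini"],
        age_ratio=values["age_ratio"],
    )
    det = DetectionParams(p_detec=values["p_detec"])
    return init, demog, disp, suit, det


def make_log_posterior(data: ModelData, priors: dict[str, Prior], mapper: ParameterMapper):
    """Build the transformed-scale unnormalised log-posterior callable.

    The returned function simulates the deterministic trajectory implied
    by the parameters and scores the observation tensors; it is a pure
    function of its argument, so replays are bit-identical.
    """

    def logpost(eta: np.ndarray) -> float:
        values = mapper.to_natural(eta)
        lp = log_prior(values, priors)
        if not np.isfinite(lp):
            return -np.inf
        init, demog, disp, suit, det = _unpack_params(values, data)
        traj = simulate_trajectory(
            init, data.env, data.grid, demog, disp, suit,
            K=data.K, strict_maturity=data.strict_maturity,
        )
        effort = sampling_effort(det, data.n_tg)
        return lp + mapper.log_jacobian(eta) + poisson_loglik(data.y, traj, effort)

    return logpost


@dataclass
class MCMCConfig:
    """Protocol settings for the multi-session Metropolis–Hastings run.

    Defaults mirror a full-scale protocol (three sessions of nine chains
    of 100,000 iterations, burn-in 15,000, thinning 450); desk-scale runs
    shrink every field.
    """

    n_iter: int = 100_000
    n_chains: int = 9
    n_sessions: int = 3
    burnin: int = 15_000
    thin: int = 450
    proposal_scale: float | dict[str, float] = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.burnin < self.n_iter:
            raise ValueError("burnin must satisfy 0 <= burnin < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    def scales_for(self, mapper: ParameterMapper) -> np.ndarray:
        s = np.empty(mapper.n_free)
        for name, sl in mapper.blocks:
            if isinstance(self.proposal_scale, dict):
                s[sl] = self.proposal_scale.get(name, self.proposal_scale.get("default", 0.1))
            else:
                s[sl] = self.proposal_scale
        return s


def metropolis_hastings(
    logpost,
    start: np.ndarray,
    n_iter: int,
    scales: np.ndarray,
    blocks: list[tuple[str, slice]],
    rng: np.random.Generator,
):
    """Random-scan block Gaussian random-walk Metropolis–Hastings.

    Each iteration perturbs one uniformly chosen block with independent
    Gaussian steps on the transformed scale and accepts with probability
    ``min(1, exp(delta log-posterior))``. Returns the chain of states
    (one row per iteration), their log-posterior values and the overall
    acceptance rate.
    """
    start = np.asarray(start, dtype=float)
    lp0 = logpost(start)
    if not np.isfinite(lp0):
        raise ValueError("non-finite posterior at the starting point")
    dim = len(start)
    chain = np.empty((n_iter, dim))
    lps = np.empty(n_iter)
    cur, lp_cur = start.copy(), lp0
    accepted = 0
    n_blocks = len(blocks)
    for it in range(n_iter):
        _, sl = blocks[int(rng.integers(n_blocks))]
        prop = cur.copy()
        prop[sl] = cur[sl] + rng.normal(0.0, scales[sl])
        lp_prop = logpost(prop)
        if np.log(rng.uniform()) < lp_prop - lp_cur:
            cur, lp_cur = prop, lp_prop
            accepted += 1
        chain[it] = cur
        lps[it] = lp_cur
    return chain, lps, accepted / n_iter


@dataclass
class PosteriorSamples:
    """Retained draws of the final session, on the natural scale.

    ``df`` has one row per retained draw with chain and iteration labels,
    one column per free parameter, and the log-posterior. ``raw_chains``
    keeps the full final-session transformed chains (n_chains, n_iter,
    n_free) for convergence diagnostics.
    """

    df: pd.DataFrame
    mapper: ParameterMapper
    raw_chains: np.ndarray
    acceptance: list[float]
    session_best_lp: list[float]

    @property
    def n_samples(self) -> int:
        return len(self.df)

    def natural_draws(self) -> list[dict[str, np.ndarray]]:
        """One natural-scale parameter dict per retained draw.

        Values are read straight from the stored table (no transform round
        trip, which matters for floor-sensitive parameters like k_hat).
        """
        out = []
        for _, r in self.df.iterrows():
            values = {k: v.copy() for k, v in self.mapper.fixed.items()}
            for name, size, _ in self.mapper.free_slots:
                if size == 1:
                    values[name] = np.array([r[name]])
                else:
                    values[name] = np.array(
                        [r[f"{name}_{j}"] for j in range(size)])
            out.append(values)
        return out

    def credible_interval(self, column: str, level: float = 0.9) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        v = self.df[column].to_numpy()
        return float(np.quantile(v, a)), float(np.quantile(v, 1.0 - a))


def _draw_start(mapper: ParameterMapper, priors: dict[str, Prior],
                logpost, rng: np.random.Generator, max_tries: int = 200) -> np.ndarray:
    for _ in range(max_tries):
        values = {
            name: priors[name].rvs(size, rng)
            for name, size, _ in mapper.free_slots
        }
        eta = mapper.to_transformed(values)
        if np.isfinite(logpost(eta)):
            return eta
    raise RuntimeError("could not find a finite-posterior starting point")


def multi_session_fit(
    data: ModelData,
    priors: dict[str, Prior],
    config: MCMCConfig,
    fixed: dict | None = None,
) -> PosteriorSamples:
    """Run the full multi-session protocol and return retained samples.

    Session 1 starts every chain from an independent prior draw; each
    later session restarts all chains from the highest-posterior draw seen
    in the previous one. Only the final session is burned in and thinned,
    retaining exactly ``n_chains * floor((n_iter - burnin) / thin)``
    draws.
    """
    mapper = data.mapper(fixed)
    logpost = make_log_posterior(data, priors, mapper)
    scales = config.scales_for(mapper)
    rng = np.random.default_rng(config.seed)

    best_eta, best_lp = None, -np.inf
    acceptance: list[float] = []
    session_best: list[float] = []
    final_chains = final_lps = None
    for session in range(config.n_sessions):
        chains = np.empty((config.n_chains, config.n_iter, mapper.n_free))
        lps = np.empty((config.n_chains, config.n_iter))
        for c in range(config.n_chains):
            if session == 0:
                try:
                    start = _draw_start(mapper, priors, logpost, rng)
                except RuntimeError:
                    if best_eta is None and c == 0:
                        raise RuntimeError(
                            "all chains non-finite at start; check priors/data"
                        )
                    start = best_eta
            else:
                start = best_eta
            chain, lp, acc = metropolis_hastings(
                logpost, start, config.n_iter, scales, mapper.blocks, rng
            )
            chains[c], lps[c] = chain, lp
            acceptance.append(acc)
        idx = np.unravel_index(int(np.argmax(lps)), lps.shape)
        if lps[idx] > best_lp:
            best_lp, best_eta = float(lps[idx]), chains[idx].copy()
        session_best.append(float(lps.max()))
        final_chains, final_lps = chains, lps

    keep = config.burnin + config.thin * (
        1 + np.arange((config.n_iter - config.burnin) // config.thin)
    ) - 1
    rows = []
    for c in range(config.n_chains):
        for it in keep:
            nat = mapper.to_natural(final_chains[c, it])
            row = {"chain": c, "iteration": int(it)}
            for name, size, _ in mapper.free_slots:
                if size == 1:
                    row[name] = float(nat[name][0])
                else:
                    row.update({f"{name}_{j}": float(nat[name][j]) for j in range(size)})
            row["log_posterior"] = float(final_lps[c, it])
            rows.append(row)
    df = pd.DataFrame(rows)
    return PosteriorSamples(df, mapper, final_chains, acceptance, session_best)


def gelman_rubin(chains: np.ndarray) -> dict:
    """Brooks–Gelman corrected PSRF per parameter and the joint MPSRF.

    ``chains`` has shape (m, n, p) with m >= 2 aligned chains. Univariate
    PSRFs use the degrees-of-freedom-corrected estimator
    ``sqrt((d + 3) / (d + 1) * V / W)``; the multivariate MPSRF is
    ``sqrt((n - 1)/n + (m + 1)/m * lambda_1)`` with ``lambda_1`` the
    leading eigenvalue of ``W^{-1} B / n`` — reported on the same
    square-root scale as the univariate factors. Zero-variance
    (degenerate) parameters yield NaN and are reported in ``degenerate``.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        chains = chains[:, :, None]
    m, n, p = chains.shape
    if m < 2:
        raise ValueError("need at least 2 chains")
    means = chains.mean(axis=1)  # (m, p)
    variances = chains.var(axis=1, ddof=1)  # (m, p)
    W = variances.mean(axis=0)
    B_over_n = means.var(axis=0, ddof=1)
    V = (n - 1) / n * W + (1.0 + 1.0 / m) * B_over_n
    psrf = np.full(p, np.nan)
    ok = W > 0
    # method-of-moments degrees of freedom of the pooled variance estimate
    mu_hat = means.mean(axis=0)
    var_w = variances.var(axis=0, ddof=1) / m
    b = n * B_over_n
    var_b = 2.0 * b**2 / (m - 1)
    cov_wb = np.empty(p)
    for j in range(p):
        cov_s2_x2 = np.cov(variances[:, j], means[:, j] ** 2, ddof=1)[0, 1]
        cov_s2_x = np.cov(variances[:, j], means[:, j], ddof=1)[0, 1]
        cov_wb[j] = n / m * (cov_s2_x2 - 2.0 * mu_hat[j] * cov_s2_x)
    var_V = (
        (n - 1) ** 2 * var_w
        + (1 + 1 / m) ** 2 * var_b
        + 2 * (n - 1) * (1 + 1 / m) * cov_wb
    ) / n**2
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 2.0 * V**2 / var_V
        corr = (d + 3.0) / (d + 1.0)
        psrf[ok] = np.sqrt(corr[ok] * V[ok] / W[ok])

    mpsrf = np.nan
    centered = chains - means[:, None, :]
    W_mat = np.einsum("cij,cik->jk", centered, centered) / (m * (n - 1))
    dm = means - mu_hat
    B_mat_over_n = np.einsum("cj,ck->jk", dm, dm) / (m - 1)
    try:
        lam = np.linalg.eigvals(np.linalg.solve(W_mat, B_mat_over_n))
        lam1 = float(np.max(lam.real))
        mpsrf = np.sqrt((n - 1) / n + (m + 1) / m * lam1)
    except np.linalg.LinAlgError:
        pass
    return {
        "psrf": psrf,
        "mpsrf": float(mpsrf),
        "degenerate": np.where(~ok)[0],
    }
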