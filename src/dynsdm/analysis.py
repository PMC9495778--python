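"""Post-fit analyses of the posterior sample set.

Every analysis here re-simulates the deterministic trajectory implied by
each retained posterior draw and summarises across draws:

* relative population-size percentile maps per (cell, year), with an
  "uncertain" tag where fewer than two-thirds of the draws agree on the
  percentile bin;
* invasion-syndrome maps combining per-draw growth/decline status with a
  dispersal status (does the cell seed at least one expected new plant in
  another cell this year?), again at the two-thirds agreement rule;
* global yearly series: total population, Shannon entropy of population
  across cells, total seed production, and recruits attributable to
  long-distance dispersal;
* dispersal ablation counterfactuals (dl = 0 or ds = 0 with everything
  else unchanged) reported as relative differences to the full model;
* the scaled fecundity curve f(k) / M with pointwise credible bands;
* data-deprivation validation: refit on the records up to a cutoff year
  and score later detections against non-detections with a pairwise AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .ecology import fecundity, simulate_trajectory
from .inference import (
    MCMCConfig,
    ModelData,
    PosteriorSamples,
    _unpack_params,
    multi_session_fit,
)
from .lattice import EnvSeries

__all__ = [
    "sample_trajectories",
    "population_percentile_maps",
    "invasion_syndromes",
    "global_metrics",
    "ablation_experiment",
    "fecundity_curve_summary",
    "pairwise_auc",
    "validate_data_deprivation",
]

AGREEMENT = 2.0 / 3.0  # inclusive agreement threshold across posterior draws
PERCENTILE_EDGES = (40.0, 70.0, 90.0)
BIN_LABELS = ("B1", "B2", "B3", "B4")
SYNDROMES = {
    "i": "growth, uncertain dispersal",
    "ii": "growth and dispersal",
    "iii": "dispersal, uncertain growth",
    "iv": "decline and dispersal",
    "v": "decline, uncertain dispersal",
}


def sample_trajectories(samples: PosteriorSamples, data: ModelData,
                        return_details: bool = False):
    """Re-simulate the hidden trajectory for every retained draw."""
    out = []
    for values in samples.natural_draws():
        init, demog, disp, suit, _ = _unpack_params(values, data)
        res = simulate_trajectory(
            init, data.env, data.grid, demog, disp, suit,
            K=data.K, strict_maturity=data.strict_maturity,
            return_details=return_details,
        )
        out.append(res)
    return out


def _majority_label(labels: np.ndarray, n_labels: int) -> tuple[np.ndarray, np.ndarray]:
    """Per column: modal label and whether it reaches the agreement rule."""
    S = labels.shape[0]
    counts = np.stack([(labels == b).sum(axis=0) for b in range(n_labels)])
    best = counts.argmax(axis=0)
    agreed = counts.max(axis=0) >= AGREEMENT * S
    return best, agreed


def population_percentile_maps(samples: PosteriorSamples, data: ModelData,
                               trajectories: list[np.ndarray] | None = None,
                               ) -> pd.DataFrame:
    """Percentile-bin map of relative population size per (cell, year).

    For each draw, total populations over all (cell, year) couples are
    binned at the 40th/70th/90th percentiles of that draw's own
    trajectory; a couple keeps a bin only when at least two-thirds of the
    draws agree, otherwise it is tagged "uncertain".
    """
    if trajectories is None:
        trajectories = sample_trajectories(samples, data)
    if not trajectories:
        raise ValueError("empty posterior sample set")
    C, T, _ = trajectories[0].shape
    bins = np.empty((len(trajectories), C * T), dtype=int)
    for s, traj in enumerate(trajectories):
        tot = traj.sum(axis=2).ravel()
        edges = np.percentile(tot, PERCENTILE_EDGES)
        bins[s] = np.searchsorted(edges, tot, side="left")
    best, agreed = _majority_label(bins, 4)
    labels = np.where(agreed, np.array(BIN_LABELS)[best], "uncertain")
    cells = np.repeat(np.arange(C), T)
    years = np.tile(data.env.years, C)
    return pd.DataFrame({
        "cell_id": np.array(data.grid.cell_ids)[cells],
        "year": years,
        "label": labels,
    })


def _per_draw_status(traj: np.ndarray, details) -> tuple[np.ndarray, ...]:
    """Growth/decline/dispersal booleans per (cell, transition year)."""
    tot = traj.sum(axis=2)  # (C, T)
    growth = tot[:, 1:] > tot[:, :-1]
    decline = tot[:, 1:] < tot[:, :-1]
    # expected new plants another cell grows from seeds exported by i':
    # out[i'] * sum_{i != i'} disp[i, i'] c_i p_i  (expected-recruit rule)
    cp = details.c_ratio * details.p_next  # (C, T-1)
    disperses = np.empty_like(growth)
    for t in range(growth.shape[1]):
        out_t = details.seeds_out[:, t]
        invD = details.inv_D[:, t]
        # dense column sums: disp^T @ (c*p) minus own-cell term
        # reconstructing columns from rain shares would need the kernel;
        # use the identity sum_i disp[i,i'] cp_i = (disp^T cp)[i']
        disperses[:, t] = out_t * (details.disp_T_cp[:, t] - invD * cp[:, t]) >= 1.0
    return growth, decline, disperses


def invasion_syndromes(samples: PosteriorSamples, data: ModelData,
                       sims: list | None = None) -> pd.DataFrame:
    """Five-class invasion-syndrome map per (cell, transition year).

    Growth (resp. decline) is certain when at least two-thirds of draws
    show a strictly increasing (resp. decreasing) cell population from t
    to t+1; dispersal is certain when two-thirds agree the cell's exported
    seeds are expected to establish at least one plant elsewhere. The
    (growth, dispersal) combination maps onto syndromes (i)-(v); anything
    else is "uncertain". The final year has no transition and is excluded.
    """
    from .ecology import dispersal_matrix  # local import to avoid cycle noise

    if sims is None:
        sims = sample_trajectories(samples, data, return_details=True)
    draws = samples.natural_draws()
    growth_votes = decline_votes = disp_votes = None
    for values, (traj, details) in zip(draws, sims):
        _, _, disp_params, _, _ = _unpack_params(values, data)
        T1 = traj.shape[1] - 1
        cp = details.c_ratio * details.p_next
        disp_T_cp = np.empty((data.grid.n_cells, T1))
        for t in range(T1):
            kern = dispersal_matrix(data.grid, disp_params, data.env.urban[:, t])
            disp_T_cp[:, t] = kern.T @ cp[:, t]
        details.disp_T_cp = disp_T_cp
        g, d, s = _per_draw_status(traj, details)
        if growth_votes is None:
            growth_votes = g.astype(int)
            decline_votes = d.astype(int)
            disp_votes = s.astype(int)
        else:
            growth_votes += g
            decline_votes += d
            disp_votes += s
    S = len(sims)
    g_cert = growth_votes >= AGREEMENT * S
    d_cert = decline_votes >= AGREEMENT * S
    s_cert = disp_votes >= AGREEMENT * S
    label = np.full(g_cert.shape, "uncertain", dtype=object)
    label[g_cert & ~s_cert] = "i"
    label[g_cert & s_cert] = "ii"
    label[s_cert & ~g_cert & ~d_cert] = "iii"
    label[d_cert & s_cert] = "iv"
    label[d_cert & ~s_cert] = "v"
    C, T1 = label.shape
    return pd.DataFrame({
        "cell_id": np.repeat(np.array(data.grid.cell_ids), T1),
        "year": np.tile(data.env.years[:-1], C),
        "label": label.ravel(),
    })


def shannon_entropy(pop: np.ndarray) -> float:
    """Entropy of the population distribution across cells (natural log)."""
    tot = pop.sum()
    if tot <= 0:
        return 0.0
    q = pop[pop > 0] / tot
    return float(-(q * np.log(q)).sum())


def global_metrics(samples: PosteriorSamples, data: ModelData,
                   sims: list | None = None) -> pd.DataFrame:
    """Yearly posterior series of the global invasion metrics.

    Columns: metric in {total_population, entropy, seed_production,
    ld_recruits}, year, mean, lo/hi (2.5 and 97.5 percentiles across
    draws). Seed production and LD recruits describe the transition out of
    each year and are reported for the first T-1 years; LD recruits in a
    cell are the cell's recruits apportioned by the long-distance share of
    its seed rain.
    """
    if sims is None:
        sims = sample_trajectories(samples, data, return_details=True)
    draws = samples.natural_draws()
    T = data.env.n_years
    S = len(sims)
    pop = np.empty((S, T))
    ent = np.empty((S, T))
    seeds = np.empty((S, T - 1))
    ld_rec = np.empty((S, T - 1))
    for s, (values, (traj, det)) in enumerate(zip(draws, sims)):
        tot = traj.sum(axis=2)
        pop[s] = tot.sum(axis=0)
        ent[s] = [shannon_entropy(tot[:, t]) for t in range(T)]
        seeds[s] = det.seeds_out.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(det.seed_rain > 0, det.ld_rain / det.seed_rain, 0.0)
        ld_rec[s] = (det.recruits * share).sum(axis=0)
    rows = []
    for name, arr, yrs in (
        ("total_population", pop, data.env.years),
        ("entropy", ent, data.env.years),
        ("seed_production", seeds, data.env.years[:-1]),
        ("ld_recruits", ld_rec, data.env.years[:-1]),
    ):
        lo, hi = np.percentile(arr, [2.5, 97.5], axis=0)
        for t, yr in enumerate(yrs):
            rows.append({"metric": name, "year": int(yr),
                         "mean": arr[:, t].mean(), "lo": lo[t], "hi": hi[t]})
    return pd.DataFrame(rows)


def ablation_experiment(samples: PosteriorSamples, data: ModelData,
                        mode: str) -> pd.DataFrame:
    """Counterfactual re-simulation with one dispersal pathway removed.

    ``mode`` is ``no_LD`` (dl = 0) or ``no_SD`` (ds = 0). For each draw
    the ablated and full trajectories are compared per year through the
    relative difference (ablated - full) / full of total population and of
    the across-cell Shannon entropy; the series reports the mean and the
    90% band (5th/95th percentiles) across draws. Years where the full
    model has zero population (or entropy) are masked as NaN.
    """
    if mode not in ("no_LD", "no_SD"):
        raise ValueError("mode must be 'no_LD' or 'no_SD'")
    draws = samples.natural_draws()
    T = data.env.n_years
    rel_pop = np.empty((len(draws), T))
    rel_ent = np.empty((len(draws), T))
    for s, values in enumerate(draws):
        init, demog, disp, suit, _ = _unpack_params(values, data)
        full = simulate_trajectory(init, data.env, data.grid, demog, disp,
                                   suit, K=data.K,
                                   strict_maturity=data.strict_maturity)
        if mode == "no_LD":
            ab_disp = dc_replace(disp, dl=0.0)
        else:
            # ds = 0 is outside the fitting support but valid for simulation
            from .ecology import DispersalParams

            ab_disp = DispersalParams.unchecked(0.0, disp.dl)
        ablated = simulate_trajectory(init, data.env, data.grid, demog,
                                      ab_disp, suit, K=data.K,
                                      strict_maturity=data.strict_maturity)
        ftot = full.sum(axis=2)
        atot = ablated.sum(axis=2)
        fp, ap = ftot.sum(axis=0), atot.sum(axis=0)
        fe = np.array([shannon_entropy(ftot[:, t]) for t in range(T)])
        ae = np.array([shannon_entropy(atot[:, t]) for t in range(T)])
        with np.errstate(invalid="ignore", divide="ignore"):
            rel_pop[s] = np.where(fp > 0, (ap - fp) / fp, np.nan)
            rel_ent[s] = np.where(fe > 0, (ae - fe) / fe, np.nan)
    rows = []
    for name, arr in (("population", rel_pop), ("entropy", rel_ent)):
        mean = np.nanmean(arr, axis=0)
        lo = np.nanpercentile(arr, 5.0, axis=0)
        hi = np.nanpercentile(arr, 95.0, axis=0)
        for t, yr in enumerate(data.env.years):
            rows.append({"mode": mode, "metric": name, "year": int(yr),
                         "mean": mean[t], "lo": lo[t], "hi": hi[t]})
    return pd.DataFrame(rows)


def fecundity_curve_summary(samples: PosteriorSamples, K: int = 50,
                            strict_maturity: bool = True) -> pd.DataFrame:
    """Posterior scaled fecundity curve f(k) / M per age with 95% band."""
    draws = samples.natural_draws()
    ages = np.arange(1, K + 1)
    curves = np.empty((len(draws), K))
    for s, values in enumerate(draws):
        from .ecology import DemographyParams

        demog = DemographyParams(
            rho=0.5, phi=1.0,
            k_hat=max(1.0, float(np.floor(values["k_hat"][0]))),
            theta=float(values["theta"][0]), M=float(values["M"][0]),
        )
        curves[s] = fecundity(ages, demog, strict_maturity) / demog.M
    lo, hi = np.percentile(curves, [2.5, 97.5], axis=0)
    return pd.DataFrame({
        "age": ages, "mean": curves.mean(axis=0), "lo": lo, "hi": hi,
    })


def pairwise_auc(pred_detect: np.ndarray, pred_nondetect: np.ndarray) -> float:
    """Fraction of (detection, non-detection) pairs ranked concordantly.

    Ties count one half — the Mann–Whitney convention — so identical
    predictions everywhere give 0.5.
    """
    a = np.asarray(pred_detect, dtype=float)[:, None]
    b = np.asarray(pred_nondetect, dtype=float)[None, :]
    if a.size == 0 or b.size == 0:
        return float("nan")
    wins = (a > b).sum() + 0.5 * (a == b).sum()
    return float(wins) / (a.shape[0] * b.shape[1])


@dataclass
class DeprivationResult:
    """AUC per evaluation window plus the truncated-fit posterior."""

    auc: dict[tuple[int, int], float]
    samples: PosteriorSamples


def validate_data_deprivation(
    data: ModelData,
    priors: dict,
    config: MCMCConfig,
    cutoff_year: int,
    eval_windows: list[tuple[int, int]],
    fixed: dict | None = None,
    samples: PosteriorSamples | None = None,
) -> DeprivationResult:
    """Fit on records up to ``cutoff_year``; score later windows by AUC.

    The truncated fit sees observation and effort tensors zeroed after the
    cutoff. For each window (start, end), cells with at least one focal
    record (any dataset) are the detection set and all remaining cells the
    non-detection set; both are ranked by the posterior-mean predicted
    population summed over the window. A window missing either set yields
    NaN.
    """
    years = data.env.years
    if not (years[0] <= cutoff_year < years[-1]):
        raise ValueError("cutoff_year must fall inside the study period")
    mask = years <= cutoff_year
    y_cut = data.y.copy()
    tg_cut = data.n_tg.copy()
    y_cut[:, ~mask, :] = 0.0
    tg_cut[:, ~mask, :] = 0.0
    cut_data = ModelData(grid=data.grid, env=data.env, y=y_cut, n_tg=tg_cut,
                         intro_cells=data.intro_cells, K=data.K,
                         strict_maturity=data.strict_maturity)
    if samples is None:
        samples = multi_session_fit(cut_data, priors, config, fixed=fixed)
    trajs = sample_trajectories(samples, cut_data)
    mean_pop = np.mean([t.sum(axis=2) for t in trajs], axis=0)  # (C, T)
    auc: dict[tuple[int, int], float] = {}
    for start, end in eval_windows:
        wmask = (years >= start) & (years <= end)
        detected = data.y[:, wmask, :].sum(axis=(1, 2)) > 0
        pred = mean_pop[:, wmask].sum(axis=1)
        auc[(start, end)] = pairwise_auc(pred[detected], pred[~detected])
    return DeprivationResult(auc, samples)
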