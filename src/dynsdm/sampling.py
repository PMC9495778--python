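"""Presence-only observation model.

Weighted record counts ``y[i, t, d]`` are modelled as Poisson draws with
mean ``n[i, t] * o[i, t, d]``, where the sampling effort ``o = p_detec[d] *
N_tg[i, t, d]`` scales the target-group record count of dataset ``d`` by a
dataset-level detection rate. This is the small-probability limit of every
plant in the cell being reported independently with probability ``o``.

Because disaggregated records carry fractional weights, the log-likelihood
uses the gamma-function continuous extension of the Poisson log-pmf.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.special import gammaln

__all__ = [
    "DetectionParams",
    "sampling_effort",
    "poisson_loglik",
    "simulate_observations",
    "NEG_SENTINEL",
]

# finite stand-in for -inf so MCMC arithmetic stays well defined
NEG_SENTINEL = -1.0e10


@dataclass
class DetectionParams:
    """Per-dataset detection rates ``p_detec[d] > 0``."""

    p_detec: np.ndarray

    def __post_init__(self) -> None:
        self.p_detec = np.atleast_1d(np.asarray(self.p_detec, dtype=float))
        if np.any(self.p_detec <= 0):
            raise ValueError("detection rates must be positive")

    @property
    def n_datasets(self) -> int:
        return len(self.p_detec)


def sampling_effort(det: DetectionParams, n_tg: np.ndarray) -> np.ndarray:
    """Effort ``o[i, t, d] = p_detec[d] * N_tg[i, t, d]`` (zero where TG is)."""
    n_tg = np.asarray(n_tg, dtype=float)
    if n_tg.shape[-1] != det.n_datasets:
        raise ValueError("dataset axis does not match detection parameters")
    return n_tg * det.p_detec


def poisson_loglik(y: np.ndarray, traj: np.ndarray, effort: np.ndarray) -> float:
    """Continuous-Poisson log-likelihood of the weighted counts.

    ``lambda[i, t, d] = (sum_k n[i, t, k]) * o[i, t, d]``; each term is
    ``y log(lambda) - lambda - lgamma(y + 1)``. A cell with zero predicted
    rate contributes 0 when no record is observed there, and the large
    negative sentinel when one is — an impossible observation under the
    model, which auto-rejects such parameter proposals.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("observed counts must be nonnegative")
    n_tot = np.asarray(traj, dtype=float).sum(axis=2)
    lam = n_tot[:, :, None] * np.asarray(effort, dtype=float)
    if y.shape != lam.shape:
        raise ValueError("tensor shapes do not align")
    pos = lam > 0
    ll = 0.0
    with np.errstate(divide="ignore"):
        terms = y[pos] * np.log(lam[pos]) - lam[pos] - gammaln(y[pos] + 1.0)
    ll += float(terms.sum())
    if np.any(y[~pos] > 0):
        ll += NEG_SENTINEL * int(np.count_nonzero(y[~pos] > 0))
    return ll


def simulate_observations(
    traj: np.ndarray,
    det: DetectionParams,
    n_tg: np.ndarray,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw an observation tensor from the Poisson sampling model.

    The Poisson approximation assumes per-plant reporting probabilities
    ``o`` well below one; a warning is raised if any effort exceeds 0.1.
    """
    rng = np.random.default_rng(seed)
    o = sampling_effort(det, n_tg)
    if np.any(o > 0.1):
        warnings.warn(
            "sampling effort o > 0.1 somewhere; the Poisson approximation "
            "to per-plant binomial sampling degrades",
            stacklevel=2,
        )
    lam = np.asarray(traj, dtype=float).sum(axis=2)[:, :, None] * o
    return rng.poisson(lam).astype(float)
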