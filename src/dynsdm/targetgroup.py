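"""Greedy target-group (TG) selection.

The TG of a dataset is the species set whose pooled records proxy the
dataset's sampling effort in space and time. Starting from the focal
species, species are added greedily: first those covering the most new
(cell, year) volumes (Phase A), then — once coverage cannot grow — those
increasing the Shannon entropy of how TG richness spreads over volumes
(Phase B), stopping when no candidate raises it. The entropy criterion
favours spatially even TGs, countering richness hotspots that would
otherwise masquerade as sampling effort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["select_target_group", "richness_entropy", "TGSelection"]

Volume = tuple  # (cell_id, year)


def richness_entropy(
    richness: dict[Volume, int], variant: str = "mass"
) -> float:
    """Shannon entropy of TG richness across spatio-temporal volumes.

    ``mass`` (default): entropy of the richness-mass distribution
    ``r_v / sum(r)`` over volumes — maximal when richness is even in space
    and time. ``histogram``: entropy of the frequencies of distinct
    richness values. Natural logarithm; empty input gives 0.
    """
    r = np.array([v for v in richness.values() if v > 0], dtype=float)
    if r.size == 0:
        return 0.0
    if variant == "mass":
        p = r / r.sum()
    elif variant == "histogram":
        _, counts = np.unique(r, return_counts=True)
        p = counts / counts.sum()
    else:
        raise ValueError(f"unknown entropy variant {variant!r}")
    return float(-(p * np.log(p)).sum())


@dataclass
class TGSelection:
    """Selected species in order, with a per-step trace."""

    species: list[str]
    trace: pd.DataFrame


def select_target_group(
    volumes: dict[str, set],
    focal: str,
    entropy_variant: str = "mass",
) -> TGSelection:
    """Select the TG species for one dataset.

    Parameters
    ----------
    volumes : dict
        Per species, the set of (cell, year) volumes it occupies in the
        dataset.
    focal : str
        The focal species; always selected first so that the focal count
        tensor is zero wherever the TG effort tensor is.
    entropy_variant : str
        Entropy definition used in Phase B (see :func:`richness_entropy`).

    The selection is deterministic: ties are broken by lexicographic
    species id.
    """
    if focal not in volumes:
        raise KeyError(f"focal species {focal!r} absent from the volume map")
    remaining = sorted(s for s in volumes if s != focal)
    selected = [focal]
    richness: dict[Volume, int] = {}
    for v in volumes[focal]:
        richness[v] = richness.get(v, 0) + 1
    covered = set(volumes[focal])
    rows = [
        {
            "step": 0,
            "species": focal,
            "new_volumes": len(covered),
            "entropy": richness_entropy(richness, entropy_variant),
        }
    ]

    def admit(sp: str) -> None:
        for v in volumes[sp]:
            richness[v] = richness.get(v, 0) + 1
        covered.update(volumes[sp])
        selected.append(sp)
        remaining.remove(sp)

    step = 0
    while remaining:
        step += 1
        # Phase A: maximise newly covered (cell, year) volumes
        gains = [(len(volumes[sp] - covered), sp) for sp in remaining]
        best_gain = max(g for g, _ in gains)
        if best_gain > 0:
            sp = min(sp for g, sp in gains if g == best_gain)
            new = best_gain
        else:
            # Phase B: maximise the richness entropy, strict increase required
            h_now = richness_entropy(richness, entropy_variant)
            best_h, sp = -np.inf, None
            for cand in remaining:
                trial = dict(richness)
                for v in volumes[cand]:
                    trial[v] = trial.get(v, 0) + 1
                h = richness_entropy(trial, entropy_variant)
                if h > best_h or (h == best_h and (sp is None or cand < sp)):
                    best_h, sp = h, cand
            if sp is None or best_h <= h_now:
                break
            new = 0
        admit(sp)
        rows.append(
            {
                "step": step,
                "species": sp,
                "new_volumes": new,
                "entropy": richness_entropy(richness, entropy_variant),
            }
        )
    return TGSelection(selected, pd.DataFrame(rows))
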