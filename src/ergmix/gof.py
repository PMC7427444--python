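"""Simulation-based goodness of fit.

Simulate graphs at the fitted parameters, then compare every model-term
statistic and every edgewise-shared-partner bin of the observed graph to
the simulated distribution (min/mean/max and a two-sided Monte-Carlo
p-value with add-one correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ergm import DyadDesign, FitResult
from .graph_core import BrainGraph, NodeAttributeTable, esp_distribution
from .model import ModelSpec

__all__ = ["GofReport", "gof_report", "mc_pvalue"]


def mc_pvalue(observed: float, sims: Sequence[float]) -> float:
    """Two-sided Monte-Carlo p-value with add-one correction.

    p = min(1, 2 * min[(#{sim >= obs}+1)/(n+1), (#{sim <= obs}+1)/(n+1)])
    """
    sims = np.asarray(sims, dtype=float)
    if sims.size == 0:
        raise ValueError("mc_pvalue requires at least one simulated value")
    n = sims.size
    upper = (np.sum(sims >= observed) + 1) / (n + 1)
    lower = (np.sum(sims <= observed) + 1) / (n + 1)
    return float(min(1.0, 2.0 * min(upper, lower)))


@dataclass
class GofReport:
    """Observed-vs-simulated summary per statistic row."""

    table: pd.DataFrame  # columns: statistic, observed, min, mean, max, p_value
    n_sims: int
    seed: int

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _esp_array(g: BrainGraph, max_sp: int) -> np.ndarray:
    return esp_distribution(g).as_array(max_sp)


def gof_report(
    fit: FitResult,
    g_observed: BrainGraph,
    attrs: NodeAttributeTable,
    spec: ModelSpec,
    n_sims: int = 1000,
    seed: int = 0,
    burn_in: int | None = None,
    thinning: int | None = None,
) -> GofReport:
    """Simulate ``n_sims`` graphs at the fitted theta and tabulate fit.

    Rows: one per model term plus one per ESP bin (esp0 .. up to the
    largest shared-partner count seen in observed or simulated graphs).
    Refuses non-converged fits.
    """
    if not fit.converged:
        raise ValueError("refusing goodness-of-fit on a non-converged fit")
    design = DyadDesign(attrs, spec)
    n = design.n
    # simulate graphs, tracking both term stats and ESP histograms
    from .ergm import _init_masks, _run_chain
    from .graph_core import bitmasks_to_adjacency

    rng = np.random.default_rng(seed)
    burn_in = 10 * n * n if burn_in is None else burn_in
    thinning = n * n if thinning is None else thinning
    masks = _init_masks(design, rng)
    theta = np.asarray(fit.theta, dtype=float)
    _run_chain(design, theta, masks, burn_in, rng)
    sim_stats = np.empty((n_sims, design.p))
    sim_esps: list[np.ndarray] = []
    max_sp = n - 2
    for s in range(n_sims):
        _run_chain(design, theta, masks, thinning, rng)
        sim_stats[s] = design.stats_from_masks(masks)
        sim_esps.append(
            _esp_array(BrainGraph(bitmasks_to_adjacency(masks, n)), max_sp)
        )
    sim_esp = np.asarray(sim_esps)

    obs_stats = design.stats_from_masks(g_observed.neighbor_masks())
    obs_esp = _esp_array(g_observed, max_sp)

    # trim ESP rows beyond anything ever observed
    top = max(
        int(np.max(np.nonzero(obs_esp)[0], initial=0)),
        int(np.max(np.nonzero(sim_esp.max(axis=0))[0], initial=0)),
    )

    rows = []
    for k, name in enumerate(design.term_names):
        col = sim_stats[:, k]
        rows.append(
            {
                "statistic": name,
                "observed": obs_stats[k],
                "min": col.min(),
                "mean": col.mean(),
                "max": col.max(),
                "p_value": mc_pvalue(obs_stats[k], col),
            }
        )
    for b in range(top + 1):
        col = sim_esp[:, b]
        rows.append(
            {
                "statistic": f"esp{b}",
                "observed": float(obs_esp[b]),
                "min": col.min(),
                "mean": col.mean(),
                "max": col.max(),
                "p_value": mc_pvalue(float(obs_esp[b]), col),
            }
        )
    return GofReport(table=pd.DataFrame(rows), n_sims=n_sims, seed=seed)
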