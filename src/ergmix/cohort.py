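"""Synthetic structural + functional graph cohorts with known parameters.

A cohort mimics the study design: per subject one structural graph (a
stochastic blockmodel over label blocks, calibrated to a target density
range) and per session one functional graph drawn from the complete-model
ERGM at scenario-specific parameters, with the edges coefficient tuned so
realized functional density lands in the configured range.  Everything is
a pure function of the configuration, including its seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .ergm import DyadDesign, _init_masks, _run_chain
from .graph_core import (
    BrainGraph,
    NodeAttributeTable,
    bitmasks_to_adjacency,
    density,
    validate_graph,
    write_adjacency,
    write_attributes,
)
from .model import ModelSpec
from .structural import attach_structural

logger = logging.getLogger(__name__)

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "Cohort",
    "gen_parcellation",
    "gen_structural_graph",
    "gen_functional_cohort",
]

RSN_LABELS = (
    "default",
    "dorsal_attention",
    "frontoparietal",
    "limbic",
    "somatomotor",
    "ventral_attention",
    "visual",
)

#: n_cortical split near-equally over the RSN labels, plus two subcortical blocks
DEFAULT_CENSUS: dict[str, tuple[int, str]] = {
    **{lab: (0, "cortical") for lab in RSN_LABELS},
    "thalamus": (14, "subcortical"),
    "basal_ganglia": (6, "subcortical"),
}

# scenario parameters for the complete-model generator; the conscious-like
# scenario has the stronger triadic-closure and structural coefficients
SCENARIOS: dict[str, dict[str, float]] = {
    "conscious_like": {
        "gwesp": 0.45,
        "nodecov.struct_degree": 0.12,
        "nodecov.struct_efficiency": 0.08,
        "nodecov.struct_clustering": 0.08,
        "nodematch.latent": 0.20,
        "mix_within": 0.35,
        "mix_between": 0.0,
    },
    "unconscious_like": {
        "gwesp": 0.10,
        "nodecov.struct_degree": 0.03,
        "nodecov.struct_efficiency": 0.02,
        "nodecov.struct_clustering": 0.02,
        "nodematch.latent": 0.05,
        "mix_within": 0.35,
        "mix_between": 0.0,
    },
}


def _default_census(n_cortical: int = 134) -> dict[str, tuple[int, str]]:
    census = dict(DEFAULT_CENSUS)
    base, extra = divmod(n_cortical, len(RSN_LABELS))
    for k, lab in enumerate(RSN_LABELS):
        census[lab] = (base + (1 if k < extra else 0), "cortical")
    return census


@dataclass
class CohortConfig:
    n_subjects: int = 12
    n_sessions: int = 2
    n_nodes: int = 154
    census: dict[str, tuple[int, str]] | None = None
    structural_density: tuple[float, float] = (0.0531, 0.0632)
    functional_density: tuple[float, float] = (0.1039, 0.1524)
    scenario: str = "conscious_like"
    theta_overrides: dict[str, float] = field(default_factory=dict)
    gwesp_decay: float = 0.5
    latent_k: int | str = 3
    sbm_within_ratio: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.census is None:
            if self.n_nodes == 154:
                self.census = _default_census(134)
            else:
                # scale the default proportions to a smaller parcellation
                census = {}
                n_thal = max(1, round(self.n_nodes * 14 / 154))
                n_bg = max(1, round(self.n_nodes * 6 / 154))
                n_cort = self.n_nodes - n_thal - n_bg
                base, extra = divmod(n_cort, len(RSN_LABELS))
                for k, lab in enumerate(RSN_LABELS):
                    census[lab] = (base + (1 if k < extra else 0), "cortical")
                census["thalamus"] = (n_thal, "subcortical")
                census["basal_ganglia"] = (n_bg, "subcortical")
                self.census = census
        total = sum(c for c, _ in self.census.values())
        if total != self.n_nodes:
            raise ValueError(
                f"label census sums to {total}, expected n_nodes={self.n_nodes}"
            )
        for rng_ in (self.structural_density, self.functional_density):
            if not (0.0 < rng_[0] < rng_[1] < 1.0):
                raise ValueError(f"density range {rng_} not inside (0,1)")
        if self.scenario not in SCENARIOS and self.scenario != "custom":
            raise ValueError(f"unknown scenario {self.scenario!r}")

    def scenario_theta(self) -> dict[str, float]:
        base = dict(SCENARIOS.get(self.scenario, SCENARIOS["conscious_like"]))
        base.update(self.theta_overrides)
        return base

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "census" in raw and raw["census"] is not None:
            raw["census"] = {k: tuple(v) for k, v in raw["census"].items()}
        for key in ("structural_density", "functional_density"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def gen_parcellation(config: CohortConfig) -> pd.DataFrame:
    """Node label table: rsn_label and cortical_group columns, census order."""
    rows = []
    for lab in sorted(config.census):
        count, group = config.census[lab]
        rows += [{"rsn_label": lab, "cortical_group": group}] * count
    return pd.DataFrame(rows)


def gen_structural_graph(config: CohortConfig, subject_seed: int) -> BrainGraph:
    """Label-block stochastic blockmodel hitting the structural density range."""
    rng = np.random.default_rng(subject_seed)
    parc = gen_parcellation(config)
    labs = parc["rsn_label"].to_numpy()
    n = config.n_nodes
    lo, hi = config.structural_density
    target = float(rng.uniform(lo, hi))
    same = labs[:, None] == labs[None, :]
    iu, ju = np.triu_indices(n, k=1)
    same_d = same[iu, ju]
    n_dyads = len(iu)
    r = config.sbm_within_ratio
    f_in = same_d.mean()
    # expected density = p_out * (f_out + r * f_in)  ->  solve for p_out
    p_out = target / ((1 - f_in) + r * f_in)
    for attempt in range(40):
        p_in = min(0.999, r * p_out)
        probs = np.where(same_d, p_in, p_out)
        edges = rng.random(n_dyads) < probs
        adj = np.zeros((n, n), dtype=np.int8)
        adj[iu[edges], ju[edges]] = 1
        adj += adj.T
        g = BrainGraph(adjacency=adj)
        d = density(g)
        if lo <= d <= hi:
            return g
        p_out *= target / max(d, 1e-9)
    raise ValueError(
        f"could not realize structural density in [{lo}, {hi}] "
        f"after 40 attempts (last {d:.4f})"
    )


@dataclass
class GroundTruth:
    """Generating parameters per subject-session; regenerates the cohort."""

    term_names: tuple[str, ...]
    gwesp_decay: float
    entries: list[dict]  # subject_id, session, theta, struct_seed, func_seed

    def theta_for(self, subject_id: str, session: str) -> np.ndarray:
        for e in self.entries:
            if e["subject_id"] == subject_id and e["session"] == session:
                return np.asarray(e["theta"])
        raise KeyError((subject_id, session))

    def to_json(self) -> str:
        return json.dumps(
            {
                "term_names": list(self.term_names),
                "gwesp_decay": self.gwesp_decay,
                "entries": self.entries,
            },
            indent=2,
        )


@dataclass
class Cohort:
    config: CohortConfig
    structural: dict[str, BrainGraph]  # per subject
    attributes: dict[str, NodeAttributeTable]  # per subject (with covariates)
    functional: dict[tuple[str, str], BrainGraph]  # per (subject, session)
    ground_truth: GroundTruth

    @property
    def subjects(self) -> list[str]:
        return sorted(self.structural)

    @property
    def sessions(self) -> list[tuple[str, str]]:
        return sorted(self.functional)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sub, g in self.structural.items():
            write_adjacency(g, out / f"{sub}_structural.csv")
            write_attributes(self.attributes[sub], out / f"{sub}_attributes.tsv")
        for (sub, ses), g in self.functional.items():
            write_adjacency(g, out / f"{sub}_{ses}_functional.csv")
        (out / "ground_truth.json").write_text(self.ground_truth.to_json())


def _theta_vector(
    design: DyadDesign, params: Mapping[str, float], edges: float
) -> np.ndarray:
    theta = np.zeros(design.p)
    theta[0] = edges
    w_in = params.get("mix_within", 0.0)
    w_bt = params.get("mix_between", 0.0)
    for k, name in enumerate(design.term_names):
        if name.startswith("mix."):
            _, a, b = name.split(".", 2)
            theta[k] = w_in if a == b else w_bt
        elif name.startswith("nodecov.") or name.startswith("nodematch."):
            theta[k] = params.get(name, 0.0)
        elif name.startswith("gwesp"):
            theta[k] = params.get("gwesp", 0.0)
    return theta


def _tune_edges_theta(
    design: DyadDesign,
    params: Mapping[str, float],
    target: float,
    rng: np.random.Generator,
    max_iter: int = 12,
) -> tuple[float, list[int]]:
    """Tune the edges coefficient so chain density approaches ``target``.

    Starts from the dyad-independent closed form, then applies damped
    logit corrections measured on short chains.  Returns the coefficient
    and the final chain state (re-used to seed the production draw).
    """
    from scipy.optimize import brentq

    n = design.n
    # static gwesp column is zero, so this is the dyad-independent part only
    eta_rest = design.static[:, 1:] @ _theta_vector(design, params, 0.0)[1:]

    def mean_dens(te: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(te + eta_rest))))) - target

    theta_e = brentq(mean_dens, -20.0, 20.0)
    masks = _init_masks(design, rng, init_density=target)
    short_burn = 4 * n * n
    probe = max(1, n * n // 2)
    for _ in range(max_iter):
        theta = _theta_vector(design, params, theta_e)
        _run_chain(design, theta, masks, short_burn, rng)
        dens = []
        for _ in range(4):
            _run_chain(design, theta, masks, probe, rng)
            e = sum(m.bit_count() for m in masks) // 2
            dens.append(e / design.n_dyads)
        realized = float(np.mean(dens))
        realized = min(max(realized, 1e-6), 1 - 1e-6)
        err = math.log(target / (1 - target)) - math.log(realized / (1 - realized))
        if abs(err) < 0.08:
            return theta_e, masks
        theta_e += 0.8 * err
        short_burn = 2 * n * n
    return theta_e, masks


def gen_functional_cohort(config: CohortConfig) -> Cohort:
    """Generate the full cohort: structural graphs, covariate tables, and
    ERGM-sampled functional graphs with recorded generating parameters."""
    root = np.random.default_rng(config.seed)
    struct_seeds = root.integers(0, 2**31 - 1, size=config.n_subjects)
    func_seeds = root.integers(
        0, 2**31 - 1, size=(config.n_subjects, config.n_sessions)
    )
    params = config.scenario_theta()
    spec = ModelSpec("complete", config.gwesp_decay)
    lo, hi = config.functional_density

    structural: dict[str, BrainGraph] = {}
    attributes: dict[str, NodeAttributeTable] = {}
    functional: dict[tuple[str, str], BrainGraph] = {}
    entries: list[dict] = []
    term_names: tuple[str, ...] = ()

    parc = gen_parcellation(config)
    for s in range(config.n_subjects):
        sub = f"S{s + 1:03d}"
        sgraph = gen_structural_graph(config, int(struct_seeds[s]))
        structural[sub] = sgraph
        table = attach_structural(
            parc, sgraph, k=config.latent_k, seed=int(struct_seeds[s]) % 2**16
        )
        attrs = NodeAttributeTable(table)
        attributes[sub] = attrs
        design = DyadDesign(attrs, spec)
        term_names = design.term_names
        for t in range(config.n_sessions):
            ses = f"ses{t + 1}"
            seed = int(func_seeds[s, t])
            rng = np.random.default_rng(seed)
            target = float(rng.uniform(lo + 0.2 * (hi - lo), hi - 0.2 * (hi - lo)))
            ok = False
            for attempt in range(4):
                theta_e, masks = _tune_edges_theta(design, params, target, rng)
                theta = _theta_vector(design, params, theta_e)
                _run_chain(design, theta, masks, 2 * design.n * design.n, rng)
                adj = bitmasks_to_adjacency(masks, design.n)
                g = validate_graph(adj)
                if lo <= density(g) <= hi:
                    ok = True
                    break
                logger.info(
                    "%s/%s attempt %d density %.4f outside [%.4f, %.4f]",
                    sub, ses, attempt, density(g), lo, hi,
                )
            if not ok:
                raise ValueError(
                    f"density tuning failed for {sub}/{ses}: "
                    f"realized {density(g):.4f} not in [{lo}, {hi}]"
                )
            functional[(sub, ses)] = g
            entries.append(
                {
                    "subject_id": sub,
                    "session": ses,
                    "theta": [float(v) for v in theta],
                    "struct_seed": int(struct_seeds[s]),
                    "func_seed": seed,
                }
            )
    gt = GroundTruth(
        term_names=term_names, gwesp_decay=config.gwesp_decay, entries=entries
    )
    return Cohort(
        config=config,
        structural=structural,
        attributes=attributes,
        functional=functional,
        ground_truth=gt,
    )
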