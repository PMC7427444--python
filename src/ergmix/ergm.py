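"""ERGM estimation and simulation.

The probability model is P(Y=y) = exp(theta . g(y)) / c(theta) for the
statistic vector g(y) of :func:`ergmix.graph_core.compute_statistics`.
Estimation routes: maximum pseudo-likelihood (logistic regression of dyad
states on change statistics; exact MLE for dyad-independent specs) and a
Geyer-Thompson importance-sampling MCMC-MLE refinement.  Simulation is a
Metropolis-Hastings sampler over uniformly proposed dyad toggles, with the
adjacency held as per-node integer bitmasks so the inner loop stays in
cheap integer arithmetic.

An exhaustive enumeration over all graphs on n <= 5 nodes serves as the
exact oracle for sampler and change-statistic tests.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .graph_core import (
    BrainGraph,
    NodeAttributeTable,
    adjacency_to_bitmasks,
    bitmasks_to_adjacency,
)
from .model import STRUCT_COVARIATES, ModelSpec, mixing_cells

logger = logging.getLogger(__name__)

__all__ = [
    "DyadDesign",
    "FitResult",
    "ExactDistribution",
    "MCMCControl",
    "DegenerateFitError",
    "change_statistics",
    "mple_fit",
    "mcmcmle_fit",
    "sample_graphs",
    "sample_statistics",
    "chain_state_counts",
    "enumerate_exact",
]


class DegenerateFitError(RuntimeError):
    """Design-matrix rank deficiency or separation in the pseudo-likelihood."""


# ---------------------------------------------------------------------------
# dyad design: everything about the term set that does not depend on y


class DyadDesign:
    """Precomputed per-dyad structure for one (attrs, spec) pair.

    All change statistics except GWESP are independent of the graph state;
    they are assembled once into ``static`` (n_dyads x p, GWESP column
    zero).  The GWESP column is filled per toggle from the current state.
    """

    def __init__(self, attrs: NodeAttributeTable, spec: ModelSpec):
        self.attrs = attrs
        self.spec = spec
        self.n = len(attrs)
        n = self.n
        self.iu, self.ju = np.triu_indices(n, k=1)
        self.n_dyads = len(self.iu)
        labs = attrs.labels
        self.term_names = tuple(spec.term_names(attrs.rsn_label))
        p = len(self.term_names)
        self.p = p

        cells = mixing_cells(attrs.rsn_label)
        n_labs = len(labs)
        cell_col = np.full((n_labs, n_labs), -1, dtype=np.int64)
        for col, (a, b) in enumerate(cells[1:], start=1):
            ia, ib = labs.index(a), labs.index(b)
            cell_col[ia, ib] = cell_col[ib, ia] = col
        code = attrs.label_index
        self.dyad_cell_col = cell_col[code[self.iu], code[self.ju]]

        static = np.zeros((self.n_dyads, p))
        static[:, 0] = 1.0  # edges
        hit = self.dyad_cell_col >= 0
        static[np.nonzero(hit)[0], self.dyad_cell_col[hit]] = 1.0
        col = 1 + (len(cells) - 1)
        self.cov_base_col = col if spec.has_structural else -1
        if spec.has_structural:
            self.covariates = {
                c: (
                    attrs.zscored_covariate(c)
                    if spec.standardize_covariates
                    else attrs.covariate(c)
                )
                for c in STRUCT_COVARIATES
            }
            for c in STRUCT_COVARIATES:
                x = self.covariates[c]
                static[:, col] = x[self.iu] + x[self.ju]
                col += 1
            clus = attrs.latent_cluster
            self.cluster = np.asarray(clus)
            static[:, col] = (self.cluster[self.iu] == self.cluster[self.ju]).astype(
                float
            )
            col += 1
        else:
            self.covariates = {}
            self.cluster = None
        self.gwesp_col = col if spec.has_gwesp else -1
        self.static = static

        decay = spec.gwesp_decay
        self.decay = decay
        q = 1.0 - math.exp(-decay)
        self.e_lam = math.exp(decay)
        # q**p lookup; shared-partner counts never exceed n-2
        self.pow_table = [q**k for k in range(n + 1)]

        # dyad index lookup: dyad_of[i][j] for i != j
        d_index = np.zeros((n, n), dtype=np.int64)
        d_index[self.iu, self.ju] = np.arange(self.n_dyads)
        d_index += d_index.T
        self.dyad_index = d_index

    # -- GWESP toggle delta -------------------------------------------------

    def gwesp_delta(self, masks: list[int], i: int, j: int) -> float:
        """Change in GWESP from adding edge (i, j); the edge must be absent
        from ``masks`` (callers strip it first when toggling off)."""
        ai, aj = masks[i], masks[j]
        cn = ai & aj
        c = cn.bit_count()
        pow_table = self.pow_table
        delta = self.e_lam * (1.0 - pow_table[c])
        while cn:
            low = cn & -cn
            k = low.bit_length() - 1
            cn ^= low
            mk = masks[k]
            delta += pow_table[(ai & mk).bit_count()]
            delta += pow_table[(aj & mk).bit_count()]
        return delta

    # -- full statistic vector from a bitmask state -------------------------

    def stats_from_masks(self, masks: Sequence[int]) -> np.ndarray:
        g = np.zeros(self.p)
        n = self.n
        nm = 0
        gw = 0.0
        n_edges = 0
        code = self.attrs.label_index
        cell_col = self.dyad_cell_col
        d_index = self.dyad_index
        has_struct = self.spec.has_structural
        has_gwesp = self.spec.has_gwesp
        cluster = self.cluster
        pow_table = self.pow_table
        for i in range(n):
            hi = masks[i] >> (i + 1)
            j = i + 1
            while hi:
                if hi & 1:
                    n_edges += 1
                    col = cell_col[d_index[i, j]]
                    if col >= 0:
                        g[col] += 1.0
                    if has_struct and cluster[i] == cluster[j]:
                        nm += 1
                    if has_gwesp:
                        c = (masks[i] & masks[j]).bit_count()
                        gw += 1.0 - pow_table[c]
                hi >>= 1
                j += 1
        g[0] = float(n_edges)
        if has_struct:
            deg = np.array([m.bit_count() for m in masks], dtype=float)
            base = self.cov_base_col
            for k, c in enumerate(STRUCT_COVARIATES):
                g[base + k] = float(deg @ self.covariates[c])
            g[base + 3] = float(nm)
        if has_gwesp:
            g[self.gwesp_col] = self.e_lam * gw
        return g


def change_statistics(
    g: BrainGraph,
    attrs: NodeAttributeTable,
    spec: ModelSpec,
    dyad: tuple[int, int],
    design: DyadDesign | None = None,
) -> np.ndarray:
    """g(y + ij) - g(y - ij): the toggle delta for one dyad.

    Computed incrementally: all terms except GWESP come from the static
    design row; the GWESP delta uses the shared-partner neighborhood of
    the dyad with the edge removed.
    """
    i, j = dyad
    if i == j:
        raise ValueError(f"dyad ({i},{j}) is a self-loop")
    if design is None:
        design = DyadDesign(attrs, spec)
    d = design.dyad_index[i, j]
    delta = design.static[d].copy()
    if spec.has_gwesp:
        masks = list(g.neighbor_masks())
        if (masks[i] >> j) & 1:
            masks[i] &= ~(1 << j)
            masks[j] &= ~(1 << i)
        delta[design.gwesp_col] = design.gwesp_delta(masks, i, j)
    return delta


# ---------------------------------------------------------------------------
# fit results


@dataclass
class FitResult:
    """Estimated theta with Wald inference for one model on one graph."""

    term_names: tuple[str, ...]
    theta: np.ndarray
    std_err: np.ndarray
    z: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    alpha: float
    method: str  # "MPLE" or "MCMC-MLE"
    converged: bool
    seed: int | None = None
    notes: str = ""

    @classmethod
    def from_theta(
        cls,
        term_names: Sequence[str],
        theta: np.ndarray,
        cov: np.ndarray | None,
        alpha: float,
        method: str,
        converged: bool,
        seed: int | None = None,
        notes: str = "",
    ) -> "FitResult":
        from scipy.stats import norm

        theta = np.asarray(theta, dtype=float)
        k = len(theta)
        if converged and cov is not None:
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            with np.errstate(divide="ignore", invalid="ignore"):
                z = np.where(se > 0, theta / se, np.nan)
            p = 2.0 * norm.sf(np.abs(z))
            sig = p < alpha
        else:
            # inference withheld for non-converged / degenerate fits
            se = np.full(k, np.nan)
            z = np.full(k, np.nan)
            p = np.full(k, np.nan)
            sig = np.zeros(k, dtype=bool)
        return cls(
            term_names=tuple(term_names),
            theta=theta,
            std_err=se,
            z=z,
            p_value=p,
            significant=np.asarray(sig, dtype=bool),
            alpha=alpha,
            method=method,
            converged=converged,
            seed=seed,
            notes=notes,
        )

    def term(self, name: str) -> int:
        return self.term_names.index(name)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": list(self.term_names),
                "estimate": self.theta,
                "std_err": self.std_err,
                "z": self.z,
                "p_value": self.p_value,
                "significant": self.significant,
            }
        )

    def to_json(self) -> str:
        payload = {
            "method": self.method,
            "converged": bool(self.converged),
            "alpha": self.alpha,
            "seed": self.seed,
            "notes": self.notes,
            "terms": {
                name: {
                    "estimate": _jsonable(self.theta[k]),
                    "std_err": _jsonable(self.std_err[k]),
                    "z": _jsonable(self.z[k]),
                    "p_value": _jsonable(self.p_value[k]),
                    "significant": bool(self.significant[k]),
                }
                for k, name in enumerate(self.term_names)
            },
        }
        return json.dumps(payload, indent=2)


def _jsonable(x: float) -> float | None:
    return None if not np.isfinite(x) else float(x)


# ---------------------------------------------------------------------------
# maximum pseudo-likelihood


def _mple_design(
    g: BrainGraph, design: DyadDesign
) -> tuple[np.ndarray, np.ndarray]:
    x = design.static.copy()
    if design.spec.has_gwesp:
        masks = g.neighbor_masks()
        col = np.empty(design.n_dyads)
        for d in range(design.n_dyads):
            i, j = int(design.iu[d]), int(design.ju[d])
            mi, mj = masks[i], masks[j]
            if (mi >> j) & 1:
                masks[i] = mi & ~(1 << j)
                masks[j] = mj & ~(1 << i)
                col[d] = design.gwesp_delta(masks, i, j)
                masks[i], masks[j] = mi, mj
            else:
                col[d] = design.gwesp_delta(masks, i, j)
        x[:, design.gwesp_col] = col
    y = g.adjacency[design.iu, design.ju].astype(float)
    return x, y


def _logistic_mle(
    x: np.ndarray, y: np.ndarray, term_names: Sequence[str], ridge: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Newton-Raphson logistic MLE; returns (beta, covariance).

    A positive ``ridge`` adds an L2 penalty that keeps estimates finite
    under separation (the penalized optimum always exists).
    """
    n, p = x.shape
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        # name terms whose removal restores full rank
        bad = []
        for k in range(p):
            keep = [c for c in range(p) if c != k]
            if np.linalg.matrix_rank(x[:, keep]) == rank:
                bad.append(term_names[k])
        raise DegenerateFitError(
            f"design matrix rank {rank} < {p}; aliased terms: {bad}"
        )
    def loglik(b):
        eta = x @ b
        return float(y @ eta - np.logaddexp(0.0, eta).sum() - 0.5 * ridge * b @ b)

    beta = np.zeros(p)
    pen = ridge * np.eye(p)
    ll = loglik(beta)
    for _ in range(200):
        eta = np.clip(x @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = x.T @ (y - mu) - ridge * beta
        hess = (x * w[:, None]).T @ x + pen
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise DegenerateFitError(f"singular Hessian: {exc}") from exc
        # step halving keeps the (penalized) log-likelihood monotone
        new_beta = beta + step
        ll_new = loglik(new_beta)
        halvings = 0
        while ll_new < ll and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            ll_new = loglik(new_beta)
            halvings += 1
        beta, ll = new_beta, ll_new
        if np.max(np.abs(step)) < 1e-10:
            break
        if ridge == 0.0 and np.max(np.abs(beta)) > 40:
            sep = [term_names[k] for k in np.nonzero(np.abs(beta) > 40)[0]]
            raise DegenerateFitError(f"separation suspected for terms: {sep}")
    eta = np.clip(x @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    hess = (x * w[:, None]).T @ x + pen
    return beta, np.linalg.inv(hess)


#: |estimate| beyond which a (penalized) coefficient is treated as diverged
_SEPARATION_BOUND = 10.0


def mple_fit(
    g: BrainGraph,
    attrs: NodeAttributeTable,
    spec: ModelSpec,
    alpha: float = 0.05,
    design: DyadDesign | None = None,
    on_separation: str = "error",
) -> FitResult:
    """Maximum pseudo-likelihood: logistic regression of dyad states on
    change statistics.  Exact MLE when the spec is dyad-independent.

    ``on_separation="error"`` raises :class:`DegenerateFitError` naming the
    offending terms (mixing cells with no observed edges have infinite
    estimates).  ``"flag"`` instead refits with a small ridge penalty and
    reports the diverged terms with infinite standard errors and
    ``significant=False``, which keeps downstream audits running.
    """
    attrs.check_alignment(g)
    if design is None:
        design = DyadDesign(attrs, spec)
    x, y = _mple_design(g, design)
    try:
        beta, cov = _logistic_mle(x, y, design.term_names)
        sep = np.zeros(design.p, dtype=bool)
        notes = ""
    except DegenerateFitError as exc:
        if on_separation != "flag" or "separation" not in str(exc):
            raise
        beta, cov = _logistic_mle(x, y, design.term_names, ridge=1e-3)
        sep = np.abs(beta) > _SEPARATION_BOUND
        if sep.any():
            notes = "separated terms (flagged non-significant): " + ", ".join(
                design.term_names[k] for k in np.nonzero(sep)[0]
            )
            logger.warning("%s", notes)
        else:
            notes = "ridge-stabilized fit (transient separation signal)"
    fit = FitResult.from_theta(
        design.term_names, beta, cov, alpha, "MPLE", converged=True, notes=notes
    )
    if sep.any():
        fit.std_err[sep] = np.inf
        fit.z[sep] = 0.0
        fit.p_value[sep] = 1.0
        fit.significant[sep] = False
    return fit


# ---------------------------------------------------------------------------
# Metropolis sampler


def _run_chain(
    design: DyadDesign,
    theta: np.ndarray,
    masks: list[int],
    n_steps: int,
    rng: np.random.Generator,
    record_steps: Sequence[int] = (),
    count_states: bool = False,
) -> tuple[list[np.ndarray], np.ndarray | None, list[int]]:
    """Run ``n_steps`` uniform dyad-toggle Metropolis steps in place.

    Returns (recorded statistic vectors, per-state visit counts or None,
    final masks).  ``record_steps`` must be sorted ascending.  State
    counting (for the exact-distribution cross-check) tallies the graph
    code after every step and is only sensible for tiny n.
    """
    n = design.n
    n_dyads = design.n_dyads
    eta_static = design.static @ theta
    has_gwesp = design.spec.has_gwesp
    theta_g = float(theta[design.gwesp_col]) if has_gwesp else 0.0
    iu = design.iu
    ju = design.ju
    gwesp_delta = design.gwesp_delta

    counts = np.zeros(1 << n_dyads, dtype=np.int64) if count_states else None
    code = 0
    if count_states:
        for d in range(n_dyads):
            if (masks[int(iu[d])] >> int(ju[d])) & 1:
                code |= 1 << d

    records: list[np.ndarray] = []
    rec_iter = iter(record_steps)
    next_rec = next(rec_iter, -1)

    exp = math.exp
    block = 1 << 15
    step = 0
    low_dens, high_dens = 0, 0
    while step < n_steps:
        m = min(block, n_steps - step)
        dd = rng.integers(0, n_dyads, size=m)
        uu = rng.random(size=m)
        for t in range(m):
            d = int(dd[t])
            i = int(iu[d])
            j = int(ju[d])
            mi = masks[i]
            present = (mi >> j) & 1
            if present:
                masks[i] = mi & ~(1 << j)
                masks[j] &= ~(1 << i)
            if has_gwesp and theta_g != 0.0:
                dg = gwesp_delta(masks, i, j)
            else:
                dg = 0.0
            lr = eta_static[d] + theta_g * dg
            if present:
                lr = -lr
            if lr >= 0.0 or uu[t] < exp(lr):
                if not present:
                    masks[i] = mi | (1 << j)
                    masks[j] |= 1 << i
                if counts is not None:
                    code ^= 1 << d
            elif present:  # rejected removal: restore
                masks[i] = mi
                masks[j] |= 1 << i
            if counts is not None:
                counts[code] += 1
            step += 1
            if step == next_rec:
                records.append(design.stats_from_masks(masks))
                next_rec = next(rec_iter, -1)
        # degeneracy watch: sustained near-empty/near-complete states
        e = sum(mm.bit_count() for mm in masks) // 2
        dens = e / n_dyads
        if dens < 0.01:
            low_dens += 1
        elif dens > 0.99:
            high_dens += 1
    if low_dens > 2 or high_dens > 2:
        logger.warning(
            "chain spent %d blocks near-empty and %d near-complete; "
            "model may be degenerate",
            low_dens,
            high_dens,
        )
    return records, counts, masks


def _init_masks(
    design: DyadDesign, rng: np.random.Generator, init_density: float = 0.1
) -> list[int]:
    n = design.n
    a = (rng.random((n, n)) < init_density).astype(np.int8)
    a = np.triu(a, 1)
    a = a + a.T
    return adjacency_to_bitmasks(a)


def sample_graphs(
    theta: np.ndarray,
    attrs: NodeAttributeTable,
    spec: ModelSpec,
    n_nodes: int | None = None,
    n_steps: int | None = None,
    burn_in: int | None = None,
    thinning: int | None = None,
    seed: int = 0,
    init: BrainGraph | None = None,
) -> list[BrainGraph]:
    """Draw graphs from the ERGM at ``theta`` by Metropolis dyad toggles.

    Defaults: burn-in 10 n^2 steps, thinning n^2.  Reproducible under
    ``seed``.
    """
    design = DyadDesign(attrs, spec)
    n = design.n
    if n_nodes is not None and n_nodes != n:
        raise ValueError("n_nodes must match the attribute table size")
    burn_in = 10 * n * n if burn_in is None else burn_in
    thinning = n * n if thinning is None else thinning
    if n_steps is None:
        n_steps = burn_in + 10 * thinning
    if n_steps <= burn_in:
        raise ValueError("n_steps must exceed burn_in")
    rng = np.random.default_rng(seed)
    masks = (
        list(init.neighbor_masks()) if init is not None else _init_masks(design, rng)
    )
    graphs: list[BrainGraph] = []
    record_steps = list(range(burn_in + thinning, n_steps + 1, thinning))
    # reuse the chain but snapshot masks instead of stats
    step_prev = 0
    for rec in record_steps:
        _run_chain(design, np.asarray(theta, float), masks, rec - step_prev, rng)
        step_prev = rec
        graphs.append(BrainGraph(bitmasks_to_adjacency(masks, n)))
    return graphs


def sample_statistics(
    theta: np.ndarray,
    design: DyadDesign,
    n_samples: int,
    burn_in: int | None = None,
    thinning: int | None = None,
    seed: int = 0,
    init_masks: list[int] | None = None,
) -> tuple[np.ndarray, list[int]]:
    """Sampled statistic vectors (n_samples x p) plus the final chain state."""
    n = design.n
    burn_in = 10 * n * n if burn_in is None else burn_in
    thinning = n * n if thinning is None else thinning
    rng = np.random.default_rng(seed)
    masks = list(init_masks) if init_masks is not None else _init_masks(design, rng)
    record_steps = [burn_in + (k + 1) * thinning for k in range(n_samples)]
    records, _, masks = _run_chain(
        design, np.asarray(theta, float), masks, record_steps[-1], rng, record_steps
    )
    return np.asarray(records), masks


def chain_state_counts(
    theta: np.ndarray,
    attrs: NodeAttributeTable,
    spec: ModelSpec,
    n_steps: int,
    burn_in: int = 0,
    seed: int = 0,
) -> np.ndarray:
    """Visit counts per graph code over a chain (tiny n only).

    Graph codes index dyads in ``np.triu_indices`` order, matching
    :func:`enumerate_exact`.
    """
    design = DyadDesign(attrs, spec)
    if design.n_dyads > 20:
        raise ValueError("state counting is limited to <= 20 dyads")
    rng = np.random.default_rng(seed)
    masks = _init_masks(design, rng)
    if burn_in:
        _run_chain(design, np.asarray(theta, float), masks, burn_in, rng)
    _, counts, _ = _run_chain(
        design, np.asarray(theta, float), masks, n_steps, rng, count_states=True
    )
    return counts


# ---------------------------------------------------------------------------
# exact enumeration oracle (n <= 5)


@dataclass
class ExactDistribution:
    """Exhaustive ERGM distribution over all graphs on n <= 5 nodes."""

    n_nodes: int
    statistics: np.ndarray  # (2^d, p)
    log_probs: np.ndarray  # (2^d,)
    log_normalizer: float
    term_names: tuple[str, ...]

    @property
    def probs(self) -> np.ndarray:
        return np.exp(self.log_probs)

    def expected_statistics(self) -> np.ndarray:
        return self.probs @ self.statistics


def enumerate_exact(
    theta: np.ndarray,
    attrs: NodeAttributeTable,
    spec: ModelSpec,
    n_nodes: int | None = None,
) -> ExactDistribution:
    from scipy.special import logsumexp

    design = DyadDesign(attrs, spec)
    n = design.n
    if n_nodes is not None and n_nodes != n:
        raise ValueError("n_nodes must match the attribute table size")
    if n > 5:
        raise ValueError(f"exact enumeration limited to n <= 5, got {n}")
    theta = np.asarray(theta, dtype=float)
    n_dyads = design.n_dyads
    stats = np.empty((1 << n_dyads, design.p))
    iu, ju = design.iu, design.ju
    for code in range(1 << n_dyads):
        masks = [0] * n
        for d in range(n_dyads):
            if (code >> d) & 1:
                i, j = int(iu[d]), int(ju[d])
                masks[i] |= 1 << j
                masks[j] |= 1 << i
        stats[code] = design.stats_from_masks(masks)
    logw = stats @ theta
    log_c = float(logsumexp(logw))
    return ExactDistribution(
        n_nodes=n,
        statistics=stats,
        log_probs=logw - log_c,
        log_normalizer=log_c,
        term_names=design.term_names,
    )


# ---------------------------------------------------------------------------
# MCMC-MLE (Geyer-Thompson importance-sampling refinement)


@dataclass
class MCMCControl:
    burn_in: int | None = None  # default 10 n^2
    thinning: int | None = None  # default n^2
    n_samples: int = 120
    se_samples: int = 240
    max_iter: int = 20
    tol: float = 1e-3
    t_ratio_tol: float = 0.3  # observed-vs-simulated mean, in simulated SDs
    step_max: float = 0.5  # trust-region cap on ||theta_new - theta_old||_inf


def _t_ratios(g_obs: np.ndarray, sims: np.ndarray) -> np.ndarray:
    gap = np.abs(g_obs - sims.mean(axis=0))
    sd = sims.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(sd > 0, gap / sd, np.where(gap == 0, 0.0, np.inf))


def _gt_update(
    theta0: np.ndarray, sims: np.ndarray, g_obs: np.ndarray, step_max: float
) -> np.ndarray:
    """Maximize the importance-sampled log-likelihood ratio around theta0."""
    theta = theta0.copy()
    for _ in range(50):
        lw = sims @ (theta - theta0)
        lw -= lw.max()
        w = np.exp(lw)
        w /= w.sum()
        mean = w @ sims
        centered = sims - mean
        cov = (centered * w[:, None]).T @ centered
        grad = g_obs - mean
        try:
            step = np.linalg.solve(cov + 1e-8 * np.eye(len(theta)), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(cov, grad, rcond=None)[0]
        norm = np.max(np.abs(step))
        if norm > step_max:
            step *= step_max / norm
        theta = theta + step
        # keep theta inside the trust region of the simulated sample
        off = np.max(np.abs(theta - theta0))
        if off > step_max:
            theta = theta0 + (theta - theta0) * (step_max / off)
            break
        if norm < 1e-8:
            break
    return theta


def mcmcmle_fit(
    g: BrainGraph,
    attrs: NodeAttributeTable,
    spec: ModelSpec,
    alpha: float = 0.05,
    seed: int = 0,
    control: MCMCControl | None = None,
) -> FitResult:
    """MCMC maximum likelihood initialized at the pseudo-likelihood estimate.

    Dyad-independent specs (no GWESP) fall back to MPLE, where the
    pseudo-likelihood *is* the likelihood.  Non-convergence or sampler
    degeneracy yields ``converged=False`` with inference withheld.
    """
    attrs.check_alignment(g)
    design = DyadDesign(attrs, spec)
    try:
        mple = mple_fit(
            g, attrs, spec, alpha=alpha, design=design, on_separation="flag"
        )
    except DegenerateFitError as exc:
        logger.warning("MPLE initializer degenerate: %s", exc)
        return FitResult.from_theta(
            design.term_names,
            np.full(design.p, np.nan),
            None,
            alpha,
            "MCMC-MLE",
            converged=False,
            seed=seed,
            notes=f"degenerate pseudo-likelihood initializer: {exc}",
        )
    if spec.dyad_independent:
        mple.method = "MCMC-MLE"
        mple.notes = "dyad-independent spec: MPLE is the exact MLE"
        mple.seed = seed
        logger.info("spec %s is dyad-independent; using MPLE", spec.name)
        return mple

    control = control or MCMCControl()
    n = design.n
    burn_in = control.burn_in if control.burn_in is not None else 10 * n * n
    # a dyad sweep is ~n^2/2 toggles; use several sweeps between samples
    thinning = control.thinning if control.thinning is not None else 3 * n * n
    g_obs = design.stats_from_masks(g.neighbor_masks())
    # clamp diverged initializer components to a range the sampler tolerates
    theta = np.clip(mple.theta.copy(), -8.0, 8.0)
    masks = list(g.neighbor_masks())  # start chains at the observed graph
    rng_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=control.max_iter + 1)

    converged = False
    notes = ""
    for it in range(control.max_iter):
        sims, masks = sample_statistics(
            theta,
            design,
            control.n_samples,
            burn_in=burn_in if it == 0 else burn_in // 4,
            thinning=thinning,
            seed=int(rng_seeds[it]),
            init_masks=masks,
        )
        edge_counts = sims[:, 0]
        if edge_counts.max() == 0 or edge_counts.min() >= design.n_dyads:
            notes = "degenerate chain (empty or complete graphs)"
            break
        # scale-free stopping rule: at the MLE the observed statistics sit
        # at the simulated mean, so small t-ratios mean theta is converged
        # to within Monte-Carlo precision
        t_ratios = _t_ratios(g_obs, sims)
        theta_new = _gt_update(theta, sims, g_obs, control.step_max)
        rel = np.max(np.abs(theta_new - theta) / (np.abs(theta) + 1.0))
        if np.max(t_ratios) < control.t_ratio_tol and it > 0:
            converged = True
            notes = f"t-ratio criterion met at iteration {it}"
            break
        theta = theta_new
        if rel < control.tol:
            converged = True
            break
    else:
        notes = "max iterations reached without convergence"

    if not converged and not notes.startswith("degenerate"):
        # final check at a larger sample size: iteration noise may have
        # masked convergence that a bigger simulation can confirm
        sims, masks = sample_statistics(
            theta,
            design,
            control.se_samples,
            burn_in=burn_in // 4,
            thinning=thinning,
            seed=int(rng_seeds[-1]) ^ 0x5EED,
            init_masks=masks,
        )
        t_ratios = _t_ratios(g_obs, sims)
        if np.max(t_ratios) < control.t_ratio_tol:
            converged = True
            notes = "t-ratio criterion met at final large-sample check"

    if not converged:
        return FitResult.from_theta(
            design.term_names,
            theta,
            None,
            alpha,
            "MCMC-MLE",
            converged=False,
            seed=seed,
            notes=notes or "non-convergence",
        )

    sims, _ = sample_statistics(
        theta,
        design,
        control.se_samples,
        burn_in=burn_in // 4,
        thinning=thinning,
        seed=int(rng_seeds[-1]),
        init_masks=masks,
    )
    fisher = np.cov(sims.T)
    try:
        cov = np.linalg.inv(fisher)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(fisher)
        notes = (notes + "; " if notes else "") + "singular Fisher information"
    return FitResult.from_theta(
        design.term_names,
        theta,
        cov,
        alpha,
        "MCMC-MLE",
        converged=True,
        seed=seed,
        notes=notes,
    )
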