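"""Multinomial logistic regression of error category on subject group.

Full-likelihood Newton-Raphson fit with Wald standard errors from the
inverse observed information; coefficients are reported both on the
log-odds scale and as odds ratios.  The reference outcome category
("none" = pooled TP/TN) and the reference group carry no parameters.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = ["RateModelResult", "fit_multinomial", "multinomial_loglik"]


def _design(
    groups: Sequence[str], reference_group: str
) -> tuple[np.ndarray, list[str]]:
    levels = sorted(set(groups))
    if reference_group not in levels:
        raise ValueError(f"reference group {reference_group!r} not observed")
    others = [g for g in levels if g != reference_group]
    x = np.ones((len(groups), 1 + len(others)))
    arr = np.asarray(groups)
    for k, g in enumerate(others, start=1):
        x[:, k] = (arr == g).astype(float)
    return x, ["constant"] + others


def multinomial_loglik(
    beta: np.ndarray, x: np.ndarray, y_idx: np.ndarray, n_cat: int
) -> float:
    """Log-likelihood at beta ((n_cat-1) x k); category 0 is the reference."""
    eta = np.zeros((x.shape[0], n_cat))
    eta[:, 1:] = x @ beta.T
    lse = np.log(np.exp(eta - eta.max(axis=1, keepdims=True)).sum(axis=1))
    lse += eta.max(axis=1)
    return float(np.sum(eta[np.arange(len(y_idx)), y_idx] - lse))


@dataclass
class RateModelResult:
    outcome_categories: tuple[str, ...]  # non-reference, fitted order
    reference_outcome: str
    predictors: tuple[str, ...]
    coef: np.ndarray  # (C-1, k) log-odds
    std_err: np.ndarray
    log_likelihood: float
    n_observations: int
    converged: bool
    separation_flags: np.ndarray  # bool (C-1, k)

    @property
    def odds_ratio(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def n_parameters(self) -> int:
        return int(self.coef.size)

    @property
    def aic(self) -> float:
        return 2 * self.n_parameters - 2 * self.log_likelihood

    @property
    def p_value(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.std_err > 0, self.coef / self.std_err, np.nan)
        return 2.0 * norm.sf(np.abs(z))

    def stars(self) -> np.ndarray:
        p = self.p_value
        out = np.full(p.shape, "", dtype=object)
        out[p < 0.05] = "*"
        out[p < 0.01] = "**"
        out[p < 0.001] = "***"
        return out

    def as_frame(self) -> pd.DataFrame:
        """Table layout: odds-ratio row per category with SE row beneath."""
        rows = []
        stars = self.stars()
        for c, cat in enumerate(self.outcome_categories):
            rows.append(
                {"category": cat, "row": "odds_ratio"}
                | {
                    pred: f"{self.odds_ratio[c, k]:.4g}{stars[c, k]}"
                    for k, pred in enumerate(self.predictors)
                }
            )
            rows.append(
                {"category": cat, "row": "std_err"}
                | {
                    pred: f"({self.std_err[c, k]:.4g})"
                    for k, pred in enumerate(self.predictors)
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.as_frame().to_csv(path, index=False)

    def to_json(self) -> str:
        payload = {
            "reference_outcome": self.reference_outcome,
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "n_observations": self.n_observations,
            "converged": self.converged,
            "categories": {
                cat: {
                    pred: {
                        "coef": float(self.coef[c, k]),
                        "std_err": float(self.std_err[c, k]),
                        "odds_ratio": float(self.odds_ratio[c, k]),
                        "separation": bool(self.separation_flags[c, k]),
                    }
                    for k, pred in enumerate(self.predictors)
                }
                for c, cat in enumerate(self.outcome_categories)
            },
        }
        return json.dumps(payload, indent=2)


def fit_multinomial(
    observations: Sequence[tuple[str, str]],
    reference_outcome: str = "none",
    reference_group: str | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> RateModelResult:
    """Newton-Raphson multinomial logit on (outcome, group) pairs.

    Convergence: gradient infinity-norm < ``tol``.  Empty cells causing
    separation are flagged (coefficient driven to +/-inf) rather than
    raised; their standard errors are reported as inf.
    """
    if not observations:
        raise ValueError("no observations")
    outcomes = [o for o, _ in observations]
    groups = [g for _, g in observations]
    cats = sorted(set(outcomes))
    if reference_outcome not in cats:
        raise ValueError(f"reference outcome {reference_outcome!r} not observed")
    if len(cats) < 2:
        raise ValueError("need at least 2 outcome categories")
    cats = [reference_outcome] + [c for c in cats if c != reference_outcome]
    cat_idx = {c: i for i, c in enumerate(cats)}
    y_idx = np.array([cat_idx[o] for o in outcomes])
    if reference_group is None:
        reference_group = sorted(set(groups))[0]
    x, predictors = _design(groups, reference_group)

    n, k = x.shape
    n_cat = len(cats)
    m = n_cat - 1
    beta = np.zeros((m, k))
    cap = 30.0
    converged = False
    ll_prev = -np.inf
    for _ in range(max_iter):
        eta = np.zeros((n, n_cat))
        eta[:, 1:] = x @ beta.T
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        p /= p.sum(axis=1, keepdims=True)
        ind = np.zeros((n, n_cat))
        ind[np.arange(n), y_idx] = 1.0
        resid = ind[:, 1:] - p[:, 1:]  # (n, m)
        grad = (resid.T @ x).ravel()  # (m*k,)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        hess = np.zeros((m * k, m * k))
        for c in range(m):
            for d in range(m):
                w = p[:, c + 1] * ((1.0 if c == d else 0.0) - p[:, d + 1])
                hess[c * k : (c + 1) * k, d * k : (d + 1) * k] = (
                    x * w[:, None]
                ).T @ x
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        new_beta = beta + step.reshape(m, k)
        # step halving keeps the log-likelihood non-decreasing
        ll_new = multinomial_loglik(new_beta, x, y_idx, n_cat)
        halvings = 0
        while ll_new < ll_prev and halvings < 30:
            step *= 0.5
            new_beta = beta + step.reshape(m, k)
            ll_new = multinomial_loglik(new_beta, x, y_idx, n_cat)
            halvings += 1
        beta = np.clip(new_beta, -cap, cap)
        ll_prev = multinomial_loglik(beta, x, y_idx, n_cat)

    # diverging estimates flatten the gradient long before the clip bound,
    # so anything far outside a plausible log-odds range is separation
    separation = np.abs(beta) >= 15.0
    if separation.any():
        logger.warning(
            "separation detected for %d coefficient(s); estimates diverge",
            int(separation.sum()),
        )
    ll = multinomial_loglik(beta, x, y_idx, n_cat)

    # observed information at the optimum
    eta = np.zeros((n, n_cat))
    eta[:, 1:] = x @ beta.T
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    hess = np.zeros((m * k, m * k))
    for c in range(m):
        for d in range(m):
            w = p[:, c + 1] * ((1.0 if c == d else 0.0) - p[:, d + 1])
            hess[c * k : (c + 1) * k, d * k : (d + 1) * k] = (x * w[:, None]).T @ x
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None)).reshape(m, k)
    except np.linalg.LinAlgError:
        se = np.full((m, k), np.inf)
    se[separation] = np.inf

    return RateModelResult(
        outcome_categories=tuple(cats[1:]),
        reference_outcome=reference_outcome,
        predictors=tuple(predictors),
        coef=beta,
        std_err=se,
        log_likelihood=ll,
        n_observations=n,
        converged=converged,
        separation_flags=separation,
    )
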