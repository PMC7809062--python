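"""One-covariate Cox proportional-hazards fits for feature screening.

The screen fits each standardized feature on its own by Newton-Raphson
maximization of the Breslow partial likelihood and keeps features whose
Wald p-value falls below alpha.  No multiplicity correction is applied
by design: the point of the companion FWER calculator is to quantify
exactly what that choice costs on a bank of >1400 features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["CoxFit", "cox_partial_loglik", "fit_univariate_cox", "univariate_cox_screen"]


@dataclass(frozen=True)
class CoxFit:
    """Result of a single-covariate proportional-hazards fit."""

    coef: float          # log hazard ratio per 1-unit covariate increase
    se: float
    z: float
    p_value: float
    n_iter: int
    converged: bool


def _risk_set_sums(x: np.ndarray, time: np.ndarray, event: np.ndarray, beta: float):
    """Log-likelihood, score and information with Breslow tie handling."""
    order = np.argsort(-time, kind="stable")  # decreasing time
    x, time, event = x[order], time[order], event[order]
    w = np.exp(beta * x)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * x)
    s2 = np.cumsum(w * x * x)
    # ties: every subject with the same time belongs to the same risk set,
    # so each position must see the cumulative sum over its full tie group
    _, inv, counts = np.unique(-time, return_inverse=True, return_counts=True)
    last = np.cumsum(counts) - 1  # index of last member of each tie group
    s0, s1, s2 = s0[last][inv], s1[last][inv], s2[last][inv]
    d = event == 1
    loglik = float(np.sum(beta * x[d] - np.log(s0[d])))
    score = float(np.sum(x[d] - s1[d] / s0[d]))
    info = float(np.sum(s2[d] / s0[d] - (s1[d] / s0[d]) ** 2))
    return loglik, score, info


def cox_partial_loglik(x, time, event, beta: float) -> float:
    """Breslow partial log-likelihood at a given coefficient value."""
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    return _risk_set_sums(x, time, event, beta)[0]


def fit_univariate_cox(x, time, event, max_iter: int = 50, tol: float = 1e-9) -> CoxFit:
    """Newton-Raphson fit of a one-covariate Cox model.

    Step-halving guards the rare non-concave step; convergence is
    declared on the score falling below ``tol`` (scaled by n events).
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if (time <= 0).any():
        raise ValueError("survival times must be positive")
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events in survival data")

    beta = 0.0
    loglik, score, info = _risk_set_sums(x, time, event, beta)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        if info <= 0:
            break
        step = score / info
        new_beta = beta + step
        new_ll, new_score, new_info = _risk_set_sums(x, time, event, new_beta)
        halvings = 0
        while new_ll < loglik - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _risk_set_sums(x, time, event, new_beta)
            halvings += 1
        beta, loglik, score, info = new_beta, new_ll, new_score, new_info
        if abs(score) < tol * max(1.0, n_events):
            converged = True
            break
    se = float(1.0 / np.sqrt(info)) if info > 0 else np.inf
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return CoxFit(coef=float(beta), se=se, z=float(z), p_value=p,
                  n_iter=it, converged=converged)


def univariate_cox_screen(features, time, event, alpha: float = 0.05,
                          feature_names=None) -> list[str]:
    """Screen each standardized feature with its own Cox fit.

    Returns the names of features with Wald p < alpha.  Zero-variance
    features cannot be fit and are skipped with a log entry.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be 2-D (samples x features)")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(x.shape[1])]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if event.sum() == 0:
        raise ValueError("no events in survival data")

    selected = []
    for j, name in enumerate(feature_names):
        col = x[:, j]
        sd = col.std()
        if sd == 0:
            logger.info("skipping zero-variance feature %r", name)
            continue
        fit = fit_univariate_cox((col - col.mean()) / sd, time, event)
        if fit.p_value < alpha:
            selected.append(name)
    return selected
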