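"""Metrics and diagnostics for fitted sparse mixtures.

* misclassification rate (MCR) under the optimal matching of estimated to
  true labels,
* Mahalanobis mean-squared error of the identified component-mean draws
  against the true means, scaled by the true component precisions,
* posterior quantile summaries of the shrinkage factors ``lambda_j`` (a
  small posterior ``lambda_j`` flags a cluster-irrelevant variable),
* the per-sweep allocation-probability trace of a single observation,
  a diagnostic of how often superfluous components attract mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from scipy import linalg
from scipy.optimize import linear_sum_assignment

from .model import Dataset
from .sampler import Trace, _log_densities

__all__ = [
    "EvalReport",
    "misclassification_rate",
    "optimal_matching",
    "mse_mu",
    "shrinkage_summary",
    "allocation_probability_trace",
]


@dataclass
class EvalReport:
    """One row of a simulation-study results table."""

    K_hat: int
    M0: int
    M0_rho: float
    MCR: Optional[float] = None
    MSE_mu: Optional[float] = None
    e0_hat: Optional[float] = None
    e0_fixed: Optional[float] = None
    lambda_summary: Optional[Dict] = None
    acceptance_rate_e0: Optional[float] = None

    def to_dict(self) -> Dict:
        out = {
            "e0_hat": self.e0_hat,
            "e0_fixed": self.e0_fixed,
            "K_hat": self.K_hat,
            "M0": self.M0,
            "M0_rho": self.M0_rho,
            "MCR": self.MCR,
            "MSE_mu": self.MSE_mu,
        }
        if self.lambda_summary is not None:
            out["lambda_summary"] = self.lambda_summary
        if self.acceptance_rate_e0 is not None:
            out["acceptance_rate_e0"] = self.acceptance_rate_e0
        return out


# ---------------------------------------------------------------------------


def _confusion(estimated: np.ndarray, truth: np.ndarray) -> tuple:
    est_labels = np.unique(estimated)
    true_labels = np.unique(truth)
    C = np.zeros((est_labels.size, true_labels.size), dtype=np.int64)
    for a, la in enumerate(est_labels):
        mask = estimated == la
        for b, lb in enumerate(true_labels):
            C[a, b] = np.sum(truth[mask] == lb)
    return C, est_labels, true_labels


def optimal_matching(estimated: np.ndarray, truth: np.ndarray) -> Dict:
    """Injective matching of estimated to true labels maximizing agreement
    (Hungarian algorithm on the confusion matrix)."""
    estimated = np.asarray(estimated)
    truth = np.asarray(truth)
    if estimated.shape != truth.shape:
        raise ValueError("label vectors must have equal length")
    C, est_labels, true_labels = _confusion(estimated, truth)
    rows, cols = linear_sum_assignment(-C)
    return {est_labels[a]: true_labels[b] for a, b in zip(rows, cols)}


def misclassification_rate(estimated: np.ndarray, truth: np.ndarray) -> float:
    """Minimum misclassified fraction over all injective label matchings."""
    estimated = np.asarray(estimated)
    truth = np.asarray(truth)
    if estimated.shape != truth.shape:
        raise ValueError("label vectors must have equal length")
    C, _, _ = _confusion(estimated, truth)
    rows, cols = linear_sum_assignment(-C)
    matched = C[rows, cols].sum()
    return float(1.0 - matched / truth.shape[0])


def mse_mu(
    identified_mu: np.ndarray,
    mu_true: np.ndarray,
    Sigma_true: np.ndarray,
    matching: Optional[Dict] = None,
) -> float:
    """Mahalanobis MSE of identified component-mean draws.

    ``sum_k (1/M_tilde) sum_m (mu_k^(m) - mu_k^true)'
    (Sigma_k^true)^{-1} (mu_k^(m) - mu_k^true)``

    ``matching`` maps each estimated component index to its true
    component (e.g. from :func:`optimal_matching` on the final
    partition); identity by default.  Unmatched estimated components are
    skipped, following the rule that the error is computed only over
    matched components.
    """
    identified_mu = np.asarray(identified_mu)
    M_tilde, K_hat, r = identified_mu.shape
    if M_tilde == 0:
        raise ValueError("no identified draws (M_tilde = 0)")
    if matching is None:
        matching = {k: k for k in range(min(K_hat, mu_true.shape[0]))}
    total = 0.0
    for k_est, k_true in matching.items():
        if k_est >= K_hat or k_true >= mu_true.shape[0]:
            continue
        L = linalg.cholesky(Sigma_true[k_true], lower=True)
        dev = linalg.solve_triangular(
            L, (identified_mu[:, k_est, :] - mu_true[k_true]).T, lower=True
        )
        total += float(np.einsum("ji,ji->", dev, dev) / M_tilde)
    return total


def shrinkage_summary(lambda_draws: np.ndarray) -> Dict:
    """Per-variable quantiles of the shrinkage-factor draws.

    Returns quantiles (2.5, 25, 50, 75, 97.5 percent) per variable and
    the variable ordering by descending median (most cluster-relevant
    first).
    """
    lambda_draws = np.asarray(lambda_draws)
    if lambda_draws.ndim != 2:
        raise ValueError("expected (M, r) draws")
    qs = np.percentile(lambda_draws, [2.5, 25, 50, 75, 97.5], axis=0)
    medians = qs[2]
    order = np.argsort(-medians, kind="stable")
    return {
        "quantiles": {
            "2.5%": qs[0],
            "25%": qs[1],
            "50%": qs[2],
            "75%": qs[3],
            "97.5%": qs[4],
        },
        "median": medians,
        "order_by_median": order,
    }


def allocation_probability_trace(
    trace: Trace, dataset: Dataset, obs_index: int
) -> np.ndarray:
    """Per-sweep normalized allocation probabilities of one observation.

    Row ``m`` is ``eta_k^(m) N(y_i | mu_k^(m), Sigma_k^(m))`` normalized
    over ``k``; rows sum to 1.
    """
    y = dataset.y[obs_index : obs_index + 1]
    M, K = trace.eta.shape
    out = np.empty((M, K))
    tiny = np.finfo(float).tiny
    for m in range(M):
        logp = np.log(np.maximum(trace.eta[m], tiny)) + _log_densities(
            y, trace.mu[m], trace.Sigma[m]
        )[0]
        logp -= logp.max()
        p = np.exp(logp)
        out[m] = p / p.sum()
    return out
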