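"""End-to-end convenience: fit, estimate K0, identify, evaluate.

Glue used by the replication harness, the CLI and the tests; each step is
the corresponding public function of the dedicated module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .evaluate import (
    EvalReport,
    misclassification_rate,
    mse_mu,
    optimal_matching,
    shrinkage_summary,
)
from .identify import (
    IdentifiedPosterior,
    extract_point_process,
    final_partition,
    k_centroids_mahalanobis,
    relabel_trace,
)
from .k0 import K0Posterior, k0_posterior
from .model import Dataset, PriorConfig
from .sampler import McmcOptions, Trace, run_mcmc

__all__ = ["FitResult", "fit"]


@dataclass
class FitResult:
    """Everything a fitted sparse mixture produces."""

    trace: Trace
    k0: K0Posterior
    identified: Optional[IdentifiedPosterior]
    partition: Optional[np.ndarray]
    assignment_freq: Optional[np.ndarray]
    report: EvalReport


def fit(
    dataset: Dataset,
    prior: PriorConfig,
    opts: McmcOptions,
    mu_true: Optional[np.ndarray] = None,
    Sigma_true: Optional[np.ndarray] = None,
    euclidean: bool = False,
) -> FitResult:
    """Run the full pipeline on one dataset.

    When the dataset carries true labels, the misclassification rate is
    computed from the final partition; when the true component means and
    covariances are supplied *and* the estimated number of non-empty
    components matches their number, the Mahalanobis MSE of the
    identified mean draws is computed as well.
    """
    trace = run_mcmc(dataset, prior, opts)
    k0 = k0_posterior(trace)
    identified = None
    partition = None
    freq = None
    mcr = None
    mse = None
    try:
        pps = extract_point_process(trace, k0.mode)
        cs = k_centroids_mahalanobis(
            pps.points,
            k0.mode,
            seed=opts.seed,
            identity_dispersions=euclidean,
        )
        identified = relabel_trace(trace, pps, cs)
        if identified.M_tilde > 0 and trace.S is not None:
            partition, freq = final_partition(identified)
    except ValueError:
        pass

    matching = None
    if partition is not None and dataset.labels_true is not None:
        true_codes = np.unique(dataset.labels_true, return_inverse=True)[1]
        mcr = misclassification_rate(partition, true_codes)
        matching = optimal_matching(partition, true_codes)
    if (
        identified is not None
        and identified.M_tilde > 0
        and mu_true is not None
        and Sigma_true is not None
        and k0.mode == mu_true.shape[0]
    ):
        mse = mse_mu(identified.mu, mu_true, Sigma_true, matching)

    report = EvalReport(
        K_hat=k0.mode,
        M0=k0.M0,
        M0_rho=identified.M0_rho if identified is not None else float("nan"),
        MCR=mcr,
        MSE_mu=mse,
        e0_hat=float(np.median(trace.e0)) if prior.e0_random else None,
        e0_fixed=prior.e0_fixed,
        lambda_summary=(
            shrinkage_summary(trace.lam)
            if prior.mean_prior == "normal_gamma"
            else None
        ),
        acceptance_rate_e0=(
            trace.acceptance_rate_e0 if prior.e0_random else None
        ),
    )
    return FitResult(
        trace=trace,
        k0=k0,
        identified=identified,
        partition=partition,
        assignment_freq=freq,
        report=report,
    )
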