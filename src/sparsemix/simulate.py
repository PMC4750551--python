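"""Synthetic-data generators and the replication harness.

The study conditions are 4-component 4-variate Gaussian mixtures with
means ``mu_1 = (2, -2, 0, 0)'``, ``mu_2 = -mu_1``, ``mu_3 = (2, 2, 0, 0)'``,
``mu_4 = -mu_3`` and identity covariances: variables 1-2 carry the cluster
structure, variables 3-4 are homogeneous noise.  Weights are either equal
``(0.25, 0.25, 0.25, 0.25)`` or unequal ``(0.02, 0.33, 0.33, 0.32)`` (the
first component generates only 2% of the data).  A bivariate 2-component
illustration (means ``(-2, 0)'`` and ``(2, 0)'``, identity covariances,
equal weights) exercises the empty-component diagnostics.  Reference
sample size is ``N = 1000`` per dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import linalg

from .model import Dataset, default_priors
from .pipeline import fit
from .sampler import McmcOptions

__all__ = [
    "MixtureTruth",
    "StudyResult",
    "preset",
    "simulate_mixture",
    "replicate_study",
]

PRESETS = ("equal_weights", "unequal_weights", "bivariate_illustration")


@dataclass
class MixtureTruth:
    """Generating mixture parameters."""

    means: np.ndarray  # (K_true, r)
    covs: np.ndarray  # (K_true, r, r)
    weights: np.ndarray  # (K_true,)

    def __post_init__(self) -> None:
        if not np.isclose(self.weights.sum(), 1.0) or np.any(self.weights < 0):
            raise ValueError("weights must lie on the simplex")
        for cov in self.covs:
            linalg.cholesky(cov, lower=True)

    @property
    def K_true(self) -> int:
        return self.means.shape[0]


def preset(name: str) -> MixtureTruth:
    """Named generating mixtures of the simulation setups."""
    if name == "equal_weights" or name == "unequal_weights":
        mu1 = np.array([2.0, -2.0, 0.0, 0.0])
        mu3 = np.array([2.0, 2.0, 0.0, 0.0])
        means = np.stack([mu1, -mu1, mu3, -mu3])
        covs = np.broadcast_to(np.eye(4), (4, 4, 4)).copy()
        weights = (
            np.full(4, 0.25)
            if name == "equal_weights"
            else np.array([0.02, 0.33, 0.33, 0.32])
        )
        return MixtureTruth(means=means, covs=covs, weights=weights)
    if name == "bivariate_illustration":
        means = np.array([[-2.0, 0.0], [2.0, 0.0]])
        covs = np.broadcast_to(np.eye(2), (2, 2, 2)).copy()
        return MixtureTruth(means=means, covs=covs, weights=np.array([0.5, 0.5]))
    raise ValueError(f"unknown preset {name!r}; choose one of {PRESETS}")


def simulate_mixture(truth: MixtureTruth, N: int, seed: int) -> Dataset:
    """Draw ``N`` labeled observations from the mixture."""
    rng = np.random.default_rng(seed)
    labels = rng.choice(truth.K_true, size=N, p=truth.weights)
    z = rng.standard_normal((N, truth.means.shape[1]))
    chols = np.array([linalg.cholesky(c, lower=True) for c in truth.covs])
    y = truth.means[labels] + np.einsum("nij,nj->ni", chols[labels], z)
    return Dataset(y, labels_true=labels)


# ---------------------------------------------------------------------------
# Replication harness
# ---------------------------------------------------------------------------


@dataclass
class Cell:
    """One (prior, K, e0 mode) cell of a results table."""

    mean_prior: str  # "standard" | "normal_gamma"
    K: int
    e0_fixed: Optional[float] = None  # None -> e0 ~ Gamma(10, 10K)

    def label(self) -> str:
        e0 = "random" if self.e0_fixed is None else f"{self.e0_fixed:g}"
        return f"{self.mean_prior}:K={self.K}:e0={e0}"


@dataclass
class StudyResult:
    """Aggregated replication results, one row per cell."""

    rows: List[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def replicate_study(
    preset_name: str,
    grid: List[Cell],
    replicates: int,
    opts: McmcOptions,
    N: int = 1000,
) -> StudyResult:
    """Simulate/fit/evaluate over a grid of prior settings.

    Per replicate: draw a dataset, fit the sparse mixture, estimate the
    number of non-empty components, identify the draws and score MCR and
    Mahalanobis MSE against the generating parameters.  Replicate ``i``
    of every cell uses the same dataset (seeded from the master seed and
    ``i``) so cells are paired; per-replicate failures are recorded, not
    fatal.
    """
    truth = preset(preset_name)
    result = StudyResult()
    for cell_idx, cell in enumerate(grid):
        reps = []
        failures = 0
        for i in range(replicates):
            data_seed = int(
                np.random.SeedSequence([opts.seed, i]).generate_state(1)[0]
                % (2**31)
            )
            run_seed = int(
                np.random.SeedSequence([opts.seed, cell_idx, i]).generate_state(1)[0]
                % (2**31)
            )
            dataset = simulate_mixture(truth, N, seed=data_seed)
            prior = default_priors(
                dataset,
                K=cell.K,
                mean_prior=cell.mean_prior,
                e0_fixed=cell.e0_fixed,
                e0_a=None if cell.e0_fixed is not None else 10.0,
            )
            run_opts = McmcOptions(
                M=opts.M,
                burnin=opts.burnin,
                seed=run_seed,
                mh_log_step=opts.mh_log_step,
                store_allocations=True,
                permute=opts.permute,
            )
            try:
                res = fit(
                    dataset,
                    prior,
                    run_opts,
                    mu_true=truth.means,
                    Sigma_true=truth.covs,
                )
                reps.append(res.report)
            except Exception:
                failures += 1
        if not reps:
            if replicates:
                result.rows.append(
                    {"cell": cell.label(), "replicates": 0, "failures": failures}
                )
            continue

        k_hats = [r.K_hat for r in reps]
        vals, counts = np.unique(k_hats, return_counts=True)
        K_hat = int(vals[np.argmax(counts)])
        n_agree = int(counts.max())

        def _avg(key):
            xs = [getattr(r, key) for r in reps if getattr(r, key) is not None]
            return float(np.mean(xs)) if xs else None

        result.rows.append(
            {
                "cell": cell.label(),
                "prior": cell.mean_prior,
                "K": cell.K,
                "e0_fixed": cell.e0_fixed,
                "e0_hat": _avg("e0_hat"),
                "K_hat": K_hat,
                "K_hat_agree": n_agree,
                "M0": _avg("M0"),
                "M0_rho": _avg("M0_rho"),
                "MCR": _avg("MCR"),
                "MSE_mu": _avg("MSE_mu"),
                "replicates": len(reps),
                "failures": failures,
            }
        )
    return result
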