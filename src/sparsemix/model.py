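"""Domain types, data-dependent default priors, and density primitives.

The model is a finite mixture of ``K`` multivariate Gaussians fitted to an
``N x r`` data matrix.  ``K`` is chosen deliberately larger than the number
of clusters one expects ("overfitting mixture"); a sparse symmetric
Dirichlet prior ``eta ~ Dir(e0, ..., e0)`` with small ``e0`` then empties
the superfluous components during MCMC.  Component means carry either

* the *standard* prior ``mu_k ~ N(b0, B0)`` with ``b0 = median(y)`` and
  ``B0 = R0 = Diag(R_1^2, ..., R_r^2)`` (``R_j`` the per-variable data
  range), or
* the *normal-gamma* shrinkage prior, a hierarchical scale-mixture
  ``mu_k | lambda, b0 ~ N(b0, Lambda R0 Lambda)`` with
  ``Lambda = Diag(sqrt(lambda_1), ..., sqrt(lambda_r))``,
  ``lambda_j ~ Gamma(nu1, nu2)`` and ``b0 ~ N(m0, M0)``.  Small posterior
  ``lambda_j`` shrinks all component means together in dimension ``j`` and
  flags the variable as cluster-irrelevant.

Component precisions follow the conjugate hierarchy
``Sigma_k^{-1} ~ W(c0, C0)``, ``C0 ~ W(g0, G0)`` under the Wishart
convention fixed below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import gammaln, kve

__all__ = [
    "Dataset",
    "PriorConfig",
    "ChainState",
    "default_priors",
    "log_component_density",
    "normal_gamma_log_marginal",
    "sample_wishart",
    "read_dataset",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """Observation matrix plus the data-dependent quantities the priors use.

    Parameters
    ----------
    y
        ``(N, r)`` matrix of continuous observations (one row per
        observation).
    labels_true
        Optional length-``N`` integer vector of ground-truth cluster
        labels, used only for evaluation.

    Attributes
    ----------
    R
        Per-variable range ``R_j = max_i y_ij - min_i y_ij``; drives the
        default prior scales.  Constant columns (``R_j = 0``) are rejected.
    med
        Per-variable median, the default prior centre ``b0``.
    """

    y: np.ndarray
    labels_true: Optional[np.ndarray] = None
    R: np.ndarray = field(init=False)
    med: np.ndarray = field(init=False)
    columns: Optional[list] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 2:
            raise ValueError("y must be a 2-d (N, r) array")
        if self.y.shape[0] < 1 or self.y.shape[1] < 1:
            raise ValueError("need at least one observation and one variable")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("y contains non-finite values")
        self.R = self.y.max(axis=0) - self.y.min(axis=0)
        bad = np.flatnonzero(self.R <= 0)
        if bad.size:
            names = (
                [self.columns[j] for j in bad]
                if self.columns is not None
                else list(bad)
            )
            raise ValueError(
                f"constant column(s) {names}: per-variable range must be "
                "positive for the data-dependent priors"
            )
        self.med = np.median(self.y, axis=0)
        if self.labels_true is not None:
            self.labels_true = np.asarray(self.labels_true)
            if self.labels_true.shape != (self.y.shape[0],):
                raise ValueError("labels_true must have length N")

    @property
    def N(self) -> int:
        return self.y.shape[0]

    @property
    def r(self) -> int:
        return self.y.shape[1]


@dataclass
class PriorConfig:
    """All fixed hyperparameters of the sparse-mixture prior.

    ``e0`` is either fixed (``e0_fixed``) or random with hyperprior
    ``e0 ~ Gamma(a, a*K)`` (``e0_a = a``), which has prior mean ``1/K`` so
    that for large ``K`` the Dirichlet prior approximates a Dirichlet
    process with unit concentration.  Exactly one of the two must be set.

    When ``mean_prior == "standard"`` the shrinkage fields (``nu1``,
    ``nu2``, ``m0``, ``M0_inv``) are ignored.
    """

    K: int
    mean_prior: str  # "standard" | "normal_gamma"
    e0_fixed: Optional[float]
    e0_a: Optional[float]
    nu1: float
    nu2: float
    m0: np.ndarray
    M0_inv: np.ndarray
    b0_fixed: np.ndarray
    R0_diag: np.ndarray  # (R_1^2, ..., R_r^2)
    c0: float
    g0: float
    G0: np.ndarray

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.mean_prior not in ("standard", "normal_gamma"):
            raise ValueError(f"unknown mean_prior {self.mean_prior!r}")
        if (self.e0_fixed is None) == (self.e0_a is None):
            raise ValueError("specify exactly one of e0_fixed / e0_a")
        if self.e0_fixed is not None and self.e0_fixed <= 0:
            raise ValueError("e0 must be > 0")
        if self.e0_a is not None and self.e0_a <= 0:
            raise ValueError("a must be > 0")
        for name in ("nu1", "nu2", "c0", "g0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if np.any(self.R0_diag <= 0):
            raise ValueError("R0 must be positive definite")

    @property
    def r(self) -> int:
        return self.R0_diag.shape[0]

    @property
    def e0_random(self) -> bool:
        return self.e0_a is not None


@dataclass
class ChainState:
    """One sweep's worth of parameters of the Gibbs sampler.

    ``S`` holds 0-based allocations in ``{0, ..., K-1}``; ``Nk`` is its
    histogram.  ``Sigma_inv`` caches the precision draws (the covariance
    update samples precisions directly).
    """

    S: np.ndarray  # (N,) int
    eta: np.ndarray  # (K,)
    mu: np.ndarray  # (K, r)
    Sigma: np.ndarray  # (K, r, r)
    Sigma_inv: np.ndarray  # (K, r, r)
    C0: np.ndarray  # (r, r)
    lam: np.ndarray  # (r,)
    b0: np.ndarray  # (r,)
    e0: float
    Nk: np.ndarray  # (K,)

    def validate(self, N: Optional[int] = None) -> None:
        """Check the state invariants; used in tests and debug mode."""
        K = self.eta.shape[0]
        if not np.isclose(self.eta.sum(), 1.0) or np.any(self.eta < 0):
            raise AssertionError("eta must lie on the simplex")
        if np.any(self.lam <= 0):
            raise AssertionError("lambda_j must be > 0")
        if self.e0 <= 0:
            raise AssertionError("e0 must be > 0")
        counts = np.bincount(self.S, minlength=K)
        if not np.array_equal(counts, self.Nk):
            raise AssertionError("Nk must equal the histogram of S")
        if N is not None and self.Nk.sum() != N:
            raise AssertionError("Nk must sum to N")
        for k in range(K):
            linalg.cholesky(self.Sigma[k], lower=True)


# ---------------------------------------------------------------------------
# Default priors
# ---------------------------------------------------------------------------


def default_priors(
    dataset: Dataset,
    K: int,
    mean_prior: str = "standard",
    e0_fixed: Optional[float] = None,
    e0_a: Optional[float] = None,
) -> PriorConfig:
    """Data-dependent default hyperparameters.

    Defaults: ``b0 = m0 = median(y)``; ``R0 = Diag(R_1^2, ..., R_r^2)``;
    ``c0 = 2.5 + (r-1)/2``; ``g0 = 0.5 + (r-1)/2``;
    ``G0 = (100 g0 / c0) Diag(1/R_1^2, ..., 1/R_r^2)``;
    ``nu1 = nu2 = 0.5`` (marginal prior variance of ``mu_kj`` equal to
    ``R_j^2``, excess kurtosis ``3/nu1 = 6``); improper flat prior on
    ``b0`` (``M0^{-1} = 0``).

    If neither ``e0_fixed`` nor ``e0_a`` is given, the gamma hyperprior
    ``e0 ~ Gamma(10, 10 K)`` with prior mean ``1/K`` is used.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    r = dataset.r
    if e0_fixed is None and e0_a is None:
        e0_a = 10.0
    c0 = 2.5 + (r - 1) / 2.0
    g0 = 0.5 + (r - 1) / 2.0
    R0_diag = dataset.R**2
    G0 = (100.0 * g0 / c0) * np.diag(1.0 / R0_diag)
    return PriorConfig(
        K=K,
        mean_prior=mean_prior,
        e0_fixed=e0_fixed,
        e0_a=e0_a,
        nu1=0.5,
        nu2=0.5,
        m0=dataset.med.copy(),
        M0_inv=np.zeros((r, r)),
        b0_fixed=dataset.med.copy(),
        R0_diag=R0_diag,
        c0=c0,
        g0=g0,
        G0=G0,
    )


# ---------------------------------------------------------------------------
# Density primitives
# ---------------------------------------------------------------------------


def log_component_density(y: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> float:
    """Log multivariate normal density ``log N(y | mu, Sigma)``.

    Evaluated via the Cholesky factor of ``Sigma``; a non-SPD ``Sigma``
    raises (no silent jitter at the density level).
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    r = y.shape[-1]
    try:
        L = linalg.cholesky(Sigma, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("Sigma is not symmetric positive definite") from exc
    dev = linalg.solve_triangular(L, (y - mu).T, lower=True)
    logdet = np.log(np.diagonal(L)).sum()
    return float(-0.5 * r * _LOG_2PI - logdet - 0.5 * np.sum(dev * dev, axis=0))


def normal_gamma_log_marginal(
    mu_col: np.ndarray, b0j: float, nu1: float, nu2: float, Rj: float
) -> float:
    """Closed-form log marginal prior of one column of component means.

    Integrating the per-variable scale ``lambda_j ~ Gamma(nu1, nu2)`` out
    of ``mu_kj | lambda_j ~ N(b0j, lambda_j R_j^2)`` gives

    ``pi(mu_1j..mu_Kj | b0) = nu2^nu1 / ((2 pi)^{K/2} Gamma(nu1) R_j^K)
    * 2 K_{p_K}(sqrt(a_j b_j)) (b_j/a_j)^{p_K/2}``

    with ``a_j = 2 nu2``, ``p_K = nu1 - K/2``,
    ``b_j = sum_k (mu_kj - b0j)^2 / R_j^2`` and ``K_alpha`` the modified
    Bessel function of the second kind.  The ``R_j^{-K}`` factor makes this
    a proper density over the mean values themselves.

    The degenerate case ``b_j = 0`` has a finite limit only for
    ``p_K > 0`` (``Gamma(p_K) (2/a_j)^{p_K}`` replacing the Bessel term);
    otherwise a ``ValueError`` is raised rather than returning NaN.
    """
    if nu1 <= 0 or nu2 <= 0 or Rj <= 0:
        raise ValueError("nu1, nu2, Rj must be > 0")
    mu_col = np.asarray(mu_col, dtype=float)
    K = mu_col.shape[0]
    aj = 2.0 * nu2
    pK = nu1 - K / 2.0
    bj = float(np.sum((mu_col - b0j) ** 2) / Rj**2)
    base = (
        nu1 * np.log(nu2)
        - 0.5 * K * _LOG_2PI
        - gammaln(nu1)
        - K * np.log(Rj)
    )
    if bj == 0.0:
        if pK <= 0:
            raise ValueError(
                "degenerate b_j = 0 with p_K <= 0: the marginal diverges"
            )
        return float(base + gammaln(pK) + pK * np.log(2.0 / aj))
    x = np.sqrt(aj * bj)
    # kve(v, x) = K_v(x) * exp(x), stable for large x
    log_bessel = np.log(kve(pK, x)) - x
    return float(base + np.log(2.0) + log_bessel + 0.5 * pK * (np.log(bj) - np.log(aj)))


# ---------------------------------------------------------------------------
# Wishart sampling under the project-wide convention
# ---------------------------------------------------------------------------


def sample_wishart(rng: np.random.Generator, nu: float, rate: np.ndarray) -> np.ndarray:
    """Draw from ``W(nu, rate)`` with density ``|X|^{nu-(r+1)/2} exp(-tr(rate X))``.

    Under this (shape, rate-matrix) convention ``E[X] = nu * rate^{-1}``;
    it maps onto the textbook Wishart with ``df = 2 nu`` and scale matrix
    ``rate^{-1} / 2``, sampled here by Bartlett decomposition.  Requires
    ``2 nu > r - 1`` and an SPD ``rate``.
    """
    rate = np.asarray(rate, dtype=float)
    r = rate.shape[0]
    df = 2.0 * nu
    if df <= r - 1:
        raise ValueError("degrees of freedom too small for a proper Wishart")
    try:
        L_rate = linalg.cholesky(rate, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("rate matrix is not SPD") from exc
    # scale = rate^{-1}/2, so chol(scale) = L_rate^{-T} / sqrt(2)
    L_scale = linalg.solve_triangular(L_rate, np.eye(r), lower=True, trans="T") / np.sqrt(2.0)
    A = np.zeros((r, r))
    diag_idx = np.arange(r)
    A[diag_idx, diag_idx] = np.sqrt(rng.chisquare(df - diag_idx))
    if r > 1:
        tril = np.tril_indices(r, -1)
        A[tril] = rng.standard_normal(len(tril[0]))
    LA = L_scale @ A
    return LA @ LA.T


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_dataset(path: str, label_column: Optional[str] = None) -> Dataset:
    """Read a CSV/TSV file (header row, numeric columns) into a Dataset.

    The delimiter is sniffed from the extension (``.tsv`` -> tab).  If
    ``label_column`` is given, that column is split off as the true-label
    vector for evaluation.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not in file")
        labels = df[label_column].to_numpy()
        df = df.drop(columns=[label_column])
    if not all(np.issubdtype(t, np.number) for t in df.dtypes):
        raise ValueError("all non-label columns must be numeric")
    return Dataset(df.to_numpy(dtype=float), labels_true=labels, columns=list(df.columns))
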