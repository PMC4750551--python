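"""MCMC estimation by data augmentation and Gibbs sampling.

One sweep updates, in this fixed order:

1. allocations ``S_i ~ Categorical(eta_k N(y_i | mu_k, Sigma_k))``,
2. weights ``eta ~ Dir(e0 + N_1, ..., e0 + N_K)``,
3. means ``mu_k ~ N(b_k, B_k)`` (conjugate; empty components draw from
   the prior ``N(b0, B0)``),
4. precisions ``Sigma_k^{-1} ~ W(c0 + N_k/2, C0 + scatter_k/2)`` and the
   hierarchical scale ``C0 ~ W(g0 + K c0, G0 + sum_k Sigma_k^{-1})``,
5. under the normal-gamma prior: the per-variable shrinkage factors
   ``lambda_j ~ GIG(a_j, b_j, p_K)`` and the prior centre ``b0``,
6. if ``e0`` is random: one log-random-walk Metropolis-Hastings step on
   the conditional ``p(e0|eta) ∝ p(e0) Gamma(K e0)/Gamma(e0)^K
   (prod_k eta_k)^{e0-1}``,
7. a uniformly random permutation of the component labels, drawn from its
   own random substream so it can be disabled without shifting any other
   draw.

Occupancy counts ``N_k`` and the number of non-empty components
``K0 = K - #{k : N_k = 0}`` are recorded every retained sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import linalg
from scipy.special import gammaln
from scipy.stats import geninvgauss
from sklearn.cluster import KMeans

from .model import ChainState, Dataset, PriorConfig, sample_wishart

__all__ = [
    "McmcOptions",
    "Trace",
    "init_chain",
    "update_allocations",
    "update_weights",
    "update_means",
    "update_covariances",
    "update_lambda",
    "update_b0",
    "update_e0",
    "permute_labels",
    "run_mcmc",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
_ETA_FLOOR = float(np.finfo(float).tiny)


@dataclass
class McmcOptions:
    """Sampler run lengths and tuning constants.

    ``M`` retained sweeps after ``burnin`` discarded ones.  The
    reference-scale settings are ``M=10000, burnin=2000``; reduced runs
    remain valid at ``M=3000, burnin=1000``.  ``mh_log_step`` is the
    standard deviation of the log-random-walk proposal for ``e0``.
    """

    M: int = 10000
    burnin: int = 2000
    seed: int = 0
    mh_log_step: float = 0.5
    store_allocations: bool = True
    permute: bool = True
    debug_validate: bool = False

    def __post_init__(self) -> None:
        if self.M < 1 or self.burnin < 0:
            raise ValueError("M >= 1 and burnin >= 0 required")
        if self.mh_log_step <= 0:
            raise ValueError("mh_log_step must be > 0")


@dataclass
class Trace:
    """Retained draws, sweep-major."""

    mu: np.ndarray  # (M, K, r)
    Sigma: np.ndarray  # (M, K, r, r)
    eta: np.ndarray  # (M, K)
    lam: np.ndarray  # (M, r)
    e0: np.ndarray  # (M,)
    Nk: np.ndarray  # (M, K)
    K0: np.ndarray  # (M,)
    S: Optional[np.ndarray]  # (M, N) int16, present iff stored
    acceptance_rate_e0: float
    prior: PriorConfig
    options: McmcOptions

    @property
    def M(self) -> int:
        return self.mu.shape[0]

    @property
    def K(self) -> int:
        return self.mu.shape[1]


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def _B0_diag(state_lam: np.ndarray, prior: PriorConfig) -> np.ndarray:
    """Diagonal of B0: R0 under the standard prior, Diag(R_j^2 lambda_j)
    under the normal-gamma prior."""
    if prior.mean_prior == "normal_gamma":
        return prior.R0_diag * state_lam
    return prior.R0_diag


def init_chain(dataset: Dataset, prior: PriorConfig, seed: int) -> ChainState:
    """Initial state from a K-means classification.

    Component moments come from within-cluster sample moments; clusters
    too small for a stable covariance fall back to the overall data
    covariance (regularized).  ``lambda_j = 1``, ``b0 = median(y)``,
    ``e0`` at its fixed value or prior mean ``1/K``, ``C0`` at the prior
    mean ``g0 G0^{-1}`` of its own prior.
    """
    K, N, r = prior.K, dataset.N, dataset.r
    if K > N:
        raise ValueError("K must not exceed the number of observations")
    km = KMeans(n_clusters=K, n_init=3, random_state=seed)
    S = km.fit_predict(dataset.y).astype(np.int64)
    Nk = np.bincount(S, minlength=K)
    eta = np.maximum(Nk / N, 1e-10)
    eta = eta / eta.sum()

    overall_cov = np.cov(dataset.y, rowvar=False).reshape(r, r)
    overall_cov += 1e-6 * np.trace(overall_cov) / r * np.eye(r)
    mu = np.empty((K, r))
    Sigma = np.empty((K, r, r))
    for k in range(K):
        members = dataset.y[S == k]
        mu[k] = members.mean(axis=0) if len(members) else dataset.med
        if len(members) > r:
            cov = np.cov(members, rowvar=False).reshape(r, r)
            cov += 1e-6 * np.trace(overall_cov) / r * np.eye(r)
            try:
                linalg.cholesky(cov, lower=True)
                Sigma[k] = cov
            except linalg.LinAlgError:
                Sigma[k] = overall_cov
        else:
            Sigma[k] = overall_cov
    Sigma_inv = np.array([linalg.inv(Sigma[k]) for k in range(K)])
    e0 = prior.e0_fixed if prior.e0_fixed is not None else 1.0 / K
    C0 = prior.g0 * linalg.inv(prior.G0)
    return ChainState(
        S=S,
        eta=eta,
        mu=mu,
        Sigma=Sigma,
        Sigma_inv=Sigma_inv,
        C0=C0,
        lam=np.ones(r),
        b0=dataset.med.copy(),
        e0=float(e0),
        Nk=Nk,
    )


# ---------------------------------------------------------------------------
# Full conditionals
# ---------------------------------------------------------------------------


def _log_densities(y: np.ndarray, mu: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """(N, K) matrix of log N(y_i | mu_k, Sigma_k)."""
    N, r = y.shape
    K = mu.shape[0]
    out = np.empty((N, K))
    for k in range(K):
        L = linalg.cholesky(Sigma[k], lower=True)
        dev = linalg.solve_triangular(L, (y - mu[k]).T, lower=True)
        out[:, k] = (
            -0.5 * r * _LOG_2PI
            - np.log(np.diagonal(L)).sum()
            - 0.5 * np.einsum("ji,ji->i", dev, dev)
        )
    return out


def allocation_log_probs(state: ChainState, y: np.ndarray) -> np.ndarray:
    """Unnormalized log allocation probabilities log(eta_k) + log N(.)."""
    return np.log(np.maximum(state.eta, _ETA_FLOOR)) + _log_densities(
        y, state.mu, state.Sigma
    )


def update_allocations(
    state: ChainState, dataset: Dataset, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw each ``S_i`` from Categorical ∝ eta_k N(y_i|mu_k, Sigma_k).

    Computed in log space with per-observation max subtraction.
    """
    logp = allocation_log_probs(state, dataset.y)
    m = logp.max(axis=1)
    if not np.all(np.isfinite(m)):
        i = int(np.flatnonzero(~np.isfinite(m))[0])
        raise FloatingPointError(
            f"all component densities underflow for observation {i}"
        )
    p = np.exp(logp - m[:, None])
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(dataset.N)
    S = (p.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(np.int64)
    Nk = np.bincount(S, minlength=state.eta.shape[0])
    return S, Nk


def update_weights(
    Nk: np.ndarray, e0: float, rng: np.random.Generator
) -> np.ndarray:
    """eta ~ Dirichlet(e0 + N_1, ..., e0 + N_K).

    Drawn via normalized gammas to behave gracefully for tiny ``e0``.
    """
    g = rng.gamma(shape=np.asarray(Nk, dtype=float) + e0)
    total = g.sum()
    if total <= 0:  # pragma: no cover - requires all-zero gamma draws
        g = np.full(len(Nk), 1.0)
        total = g.sum()
    return g / total


def update_means(
    state: ChainState,
    dataset: Dataset,
    prior: PriorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Conjugate draw mu_k ~ N(b_k, B_k).

    ``B_k = (B0^{-1} + N_k Sigma_k^{-1})^{-1}`` and
    ``b_k = B_k (B0^{-1} b0 + Sigma_k^{-1} N_k ybar_k)``; for an empty
    component this is exactly the prior ``N(b0, B0)``.
    """
    K, r = prior.K, dataset.r
    B0_inv_diag = 1.0 / _B0_diag(state.lam, prior)
    b0 = state.b0 if prior.mean_prior == "normal_gamma" else prior.b0_fixed
    mu = np.empty((K, r))
    z = rng.standard_normal((K, r))
    for k in range(K):
        nk = state.Nk[k]
        prec = np.diag(B0_inv_diag).copy()
        rhs = B0_inv_diag * b0
        if nk > 0:
            ybar = dataset.y[state.S == k].mean(axis=0)
            prec += nk * state.Sigma_inv[k]
            rhs = rhs + nk * (state.Sigma_inv[k] @ ybar)
        prec = 0.5 * (prec + prec.T)
        try:
            L = linalg.cholesky(prec, lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError(f"non-SPD posterior precision for component {k}") from exc
        bk = linalg.cho_solve((L, True), rhs)
        mu[k] = bk + linalg.solve_triangular(L, z[k], lower=True, trans="T")
    return mu


def update_covariances(
    state: ChainState,
    dataset: Dataset,
    prior: PriorConfig,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw the precisions and the hierarchical Wishart scale.

    ``Sigma_k^{-1} ~ W(c0 + N_k/2, C0 + scatter_k/2)`` with
    ``scatter_k = sum_{i: S_i=k} (y_i - mu_k)(y_i - mu_k)'``, then
    ``C0 ~ W(g0 + K c0, G0 + sum_k Sigma_k^{-1})``.  Empty components
    reduce to prior draws ``W(c0, C0)``.
    """
    K, r = prior.K, dataset.r
    Sigma = np.empty((K, r, r))
    Sigma_inv = np.empty((K, r, r))
    for k in range(K):
        nk = state.Nk[k]
        rate = state.C0.copy()
        if nk > 0:
            dev = dataset.y[state.S == k] - state.mu[k]
            rate = rate + 0.5 * (dev.T @ dev)
        rate = 0.5 * (rate + rate.T)
        prec = sample_wishart(rng, prior.c0 + nk / 2.0, rate)
        Sigma_inv[k] = prec
        L = linalg.cholesky(prec, lower=True)
        Linv = linalg.solve_triangular(L, np.eye(r), lower=True)
        Sigma[k] = Linv.T @ Linv
    C0 = sample_wishart(
        rng, prior.g0 + K * prior.c0, prior.G0 + Sigma_inv.sum(axis=0)
    )
    return Sigma, Sigma_inv, C0


def gig_params(
    mu: np.ndarray, b0: np.ndarray, prior: PriorConfig
) -> Tuple[float, np.ndarray, float]:
    """(a_j, b_j vector, p_K) of the GIG full conditional of lambda_j."""
    K = mu.shape[0]
    aj = 2.0 * prior.nu2
    pK = prior.nu1 - K / 2.0
    Rj2 = prior.R0_diag
    bj = np.sum((mu - b0) ** 2, axis=0) / Rj2
    return aj, bj, pK


def update_lambda(
    mu: np.ndarray,
    b0: np.ndarray,
    prior: PriorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw lambda_j ~ GIG(a_j, b_j, p_K), density ∝ x^{p-1} e^{-(a x + b/x)/2}.

    scipy's ``geninvgauss(p, c)`` has density ∝ x^{p-1} e^{-c(x+1/x)/2};
    the three-parameter family maps onto it with ``c = sqrt(a b)`` and
    scale ``sqrt(b/a)``.
    """
    if prior.mean_prior != "normal_gamma":
        raise ValueError("shrinkage factors exist only under the normal-gamma prior")
    aj, bj, pK = gig_params(mu, b0, prior)
    if np.any(bj < 1e-300):
        if pK <= 0:
            raise ValueError("degenerate GIG: b_j ~ 0 with p_K <= 0")
        bj = np.maximum(bj, 1e-300)
    lam = geninvgauss.rvs(
        pK, np.sqrt(aj * bj), scale=np.sqrt(bj / aj), random_state=rng
    )
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    if np.any(lam <= 0) or not np.all(np.isfinite(lam)):
        raise FloatingPointError("GIG draw out of support")
    return lam


def update_b0(
    mu: np.ndarray,
    lam: np.ndarray,
    prior: PriorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Conjugate draw of the hierarchical prior centre b0.

    ``b0 ~ N(B_n (M0^{-1} m0 + B0^{-1} sum_k mu_k), B_n)`` with
    ``B_n = (M0^{-1} + K B0^{-1})^{-1}``.  With the improper flat prior
    ``M0^{-1} = 0`` this is ``N(mean_k mu_k, B0/K)``.
    """
    if prior.mean_prior != "normal_gamma":
        raise ValueError("b0 is fixed under the standard prior")
    K, r = mu.shape
    B0_inv_diag = 1.0 / (prior.R0_diag * lam)
    prec = prior.M0_inv + K * np.diag(B0_inv_diag)
    prec = 0.5 * (prec + prec.T)
    rhs = prior.M0_inv @ prior.m0 + B0_inv_diag * mu.sum(axis=0)
    L = linalg.cholesky(prec, lower=True)
    mean = linalg.cho_solve((L, True), rhs)
    return mean + linalg.solve_triangular(
        L, rng.standard_normal(r), lower=True, trans="T"
    )


def log_e0_target(e0: float, eta: np.ndarray, prior: PriorConfig) -> float:
    """Log conditional density of e0 given the weights (up to a constant).

    ``log p(e0) + log Gamma(K e0) - K log Gamma(e0)
    + (e0 - 1) sum_k log eta_k`` with the Gamma(a, aK) hyperprior and
    weights floored at the smallest positive normal before the log.
    """
    if e0 <= 0:
        return -np.inf
    K = prior.K
    a = prior.e0_a
    log_eta = np.log(np.maximum(eta, _ETA_FLOOR))
    return float(
        (a - 1.0) * np.log(e0)
        - a * K * e0
        + gammaln(K * e0)
        - K * gammaln(e0)
        + (e0 - 1.0) * log_eta.sum()
    )


def update_e0(
    eta: np.ndarray,
    e0: float,
    prior: PriorConfig,
    mh_log_step: float,
    rng: np.random.Generator,
) -> Tuple[float, bool]:
    """One log-random-walk MH step on e0.

    Proposal ``e0' = e0 exp(tau z)``, ``z ~ N(0,1)``; the acceptance ratio
    carries the Jacobian of the log transform,
    ``min(1, target(e0') e0' / (target(e0) e0))``.
    """
    if not prior.e0_random:
        raise ValueError("e0 is fixed; no MH step required")
    cur = log_e0_target(e0, eta, prior)
    if not np.isfinite(cur):
        raise FloatingPointError("non-finite e0 target at current state")
    prop = e0 * np.exp(mh_log_step * rng.standard_normal())
    log_ratio = log_e0_target(prop, eta, prior) - cur + np.log(prop) - np.log(e0)
    if np.log(rng.random()) < log_ratio:
        return float(prop), True
    return float(e0), False


def permute_labels(state: ChainState, rng: np.random.Generator) -> ChainState:
    """Apply a uniformly random permutation of {1..K} to all labeled fields.

    The mixture likelihood of the state is unchanged; only the labeling
    moves, which lets the sampler visit all K! symmetric posterior modes.
    """
    K = state.eta.shape[0]
    perm = rng.permutation(K)
    inv = np.empty(K, dtype=np.int64)
    inv[perm] = np.arange(K)
    state.eta = state.eta[perm]
    state.mu = state.mu[perm]
    state.Sigma = state.Sigma[perm]
    state.Sigma_inv = state.Sigma_inv[perm]
    state.Nk = state.Nk[perm]
    state.S = inv[state.S]
    return state


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def run_mcmc(dataset: Dataset, prior: PriorConfig, opts: McmcOptions) -> Trace:
    """Run ``burnin + M`` sweeps and return the retained draws.

    Fully reproducible given ``opts.seed``; the random permutation step
    uses a separate substream so disabling it does not shift other draws.
    """
    N, r, K = dataset.N, dataset.r, prior.K
    root = np.random.SeedSequence(opts.seed)
    main_ss, perm_ss, init_ss = root.spawn(3)
    rng = np.random.default_rng(main_ss)
    rng_perm = np.random.default_rng(perm_ss)
    state = init_chain(dataset, prior, seed=int(init_ss.generate_state(1)[0] % (2**31)))

    M = opts.M
    trace_mu = np.empty((M, K, r))
    trace_Sigma = np.empty((M, K, r, r))
    trace_eta = np.empty((M, K))
    trace_lam = np.empty((M, r))
    trace_e0 = np.empty(M)
    trace_Nk = np.empty((M, K), dtype=np.int32)
    trace_K0 = np.empty(M, dtype=np.int32)
    trace_S = (
        np.empty((M, N), dtype=np.int16) if opts.store_allocations else None
    )
    n_acc = 0
    n_mh = 0

    total = opts.burnin + M
    for sweep in range(total):
        try:
            state.S, state.Nk = update_allocations(state, dataset, rng)
            state.eta = update_weights(state.Nk, state.e0, rng)
            state.mu = update_means(state, dataset, prior, rng)
            state.Sigma, state.Sigma_inv, state.C0 = update_covariances(
                state, dataset, prior, rng
            )
            if prior.mean_prior == "normal_gamma":
                state.lam = update_lambda(state.mu, state.b0, prior, rng)
                state.b0 = update_b0(state.mu, state.lam, prior, rng)
            if prior.e0_random:
                state.e0, accepted = update_e0(
                    state.eta, state.e0, prior, opts.mh_log_step, rng
                )
                n_mh += 1
                n_acc += accepted
            if opts.permute:
                state = permute_labels(state, rng_perm)
            else:
                rng_perm.permutation(K)  # keep the substream aligned
        except Exception as exc:
            raise RuntimeError(f"sweep {sweep}: {exc}") from exc
        if opts.debug_validate:
            state.validate(N)
        m = sweep - opts.burnin
        if m >= 0:
            trace_mu[m] = state.mu
            trace_Sigma[m] = state.Sigma
            trace_eta[m] = state.eta
            trace_lam[m] = state.lam
            trace_e0[m] = state.e0
            trace_Nk[m] = state.Nk
            trace_K0[m] = K - int(np.sum(state.Nk == 0))
            if trace_S is not None:
                trace_S[m] = state.S

    return Trace(
        mu=trace_mu,
        Sigma=trace_Sigma,
        eta=trace_eta,
        lam=trace_lam,
        e0=trace_e0,
        Nk=trace_Nk,
        K0=trace_K0,
        S=trace_S,
        acceptance_rate_e0=(n_acc / n_mh) if n_mh else float("nan"),
        prior=prior,
        options=opts,
    )
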