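# Methods

## Model

`N` observations `y_i` in `R^r` follow a finite mixture of `K`
multivariate Gaussians with weights `eta` on the simplex.  `K` is an
upper bound chosen by the user (an *overfitting* mixture); the model's
job is to empty the superfluous components.  Priors:

* `eta ~ Dir(e0, ..., e0)`.  Asymptotic theory for overfitting mixtures
  says the posterior empties extra components when `e0` is below half the
  dimension of the component parameter; in finite samples far smaller
  values are needed.  Two modes are supported: `e0` fixed (default
  `0.01`-`0.001` territory) and `e0 ~ Gamma(a, a K)` with `a = 10`, whose
  prior mean `1/K` matches the Dirichlet-process limit with unit
  concentration.  Smaller `a` lets `e0` drift large and superfluous
  components stop emptying.
* Means, *standard* prior: `mu_k ~ N(b0, B0)` with `b0 = median(y)`,
  `B0 = R0 = Diag(R_1^2, ..., R_r^2)`, `R_j` the observed range of
  variable `j`.
* Means, *normal-gamma* prior: `mu_k | lambda, b0 ~ N(b0, Lambda R0
  Lambda)`, `Lambda = Diag(sqrt(lambda_1), ..., sqrt(lambda_r))`,
  `lambda_j ~ Gamma(nu1, nu2)`, `b0 ~ N(m0, M0)` with the improper choice
  `M0^{-1} = 0`, `m0 = median(y)`.  Defaults `nu1 = nu2 = 0.5`: the
  marginal variance of `mu_kj` is then exactly `R_j^2` (as under the
  standard prior) while the marginal has excess kurtosis `3/nu1 = 6` —
  sharper at `b0` and heavier-tailed than a Laplace prior, so
  homogeneous dimensions shrink hard without biasing separated ones.
  The closed-form marginal of one mean column involves the modified
  Bessel function `K_{p_K}` with `p_K = nu1 - K/2`, `a_j = 2 nu2`,
  `b_j = sum_k (mu_kj - b0j)^2 / R_j^2`; the implementation includes the
  `R_j^{-K}` normalization that the scale-mixture integral carries, so
  the function is a proper density (verified against adaptive quadrature
  to 1e-6 relative error).
* Covariances: `Sigma_k^{-1} ~ W(c0, C0)`, `C0 ~ W(g0, G0)` with
  `c0 = 2.5 + (r-1)/2`, `g0 = 0.5 + (r-1)/2`,
  `G0 = (100 g0 / c0) Diag(1/R_1^2, ..., 1/R_r^2)`.  Wishart convention,
  fixed project-wide: `W(nu, Lambda)` has density
  `|X|^{nu-(r+1)/2} exp(-tr(Lambda X))`, hence `E[X] = nu Lambda^{-1}`
  (equivalently the textbook Wishart with `df = 2 nu`, scale
  `Lambda^{-1}/2`).  The `c0` formula only makes sense under this
  convention.  Proper prior draws require `2 c0 > r - 1`, which holds for
  `r < 6`; beyond that only occupied components are sampled stably.

## Sampling

Data augmentation with allocations `S_i`; one sweep updates, in order:
allocations (categorical, log-space with max subtraction, weights floored
at the smallest positive normal), weights (`Dir(e0 + N_1, ..., e0 +
N_K)`, via normalized gammas so tiny `e0` behaves), means (conjugate
normal; an empty component reduces exactly to its prior, which is the
mechanism that lets shrunken empty components re-capture observations),
precisions and the hierarchical scale `C0` (Wishart, Bartlett
decomposition), then under the normal-gamma prior the shrinkage factors
(`lambda_j ~ GIG(2 nu2, b_j, p_K)`, drawn through
`scipy.stats.geninvgauss` with the scale mapping `c = sqrt(a b)`,
`scale = sqrt(b/a)`) and the centre `b0` (conjugate; with `M0^{-1} = 0`
it is `N(mean_k mu_k, B0/K)`), then for random `e0` one log-random-walk
Metropolis-Hastings step (default step `tau = 0.5`, acceptance ~0.4-0.6
in the study conditions; the acceptance ratio includes the Jacobian
`e0'/e0`), and finally a uniformly random permutation of the component
labels.  The permutation uses its own random substream, so disabling it
(useful for the overfitted-component illustration, where implicit
identification is wanted) does not shift any other draw.  Update order
within a sweep is a reproducibility convention, not a statistical choice.

Initialization: K-means classification (scikit-learn, 3 restarts),
within-cluster moments with fallback to the overall covariance for
clusters smaller than `r + 1`, `lambda_j = 1`, `e0` at its fixed value or
prior mean, `C0` at its prior mean `g0 G0^{-1}`.

## Estimating the number of clusters

Each retained sweep records `K0 = K - #{k : N_k = 0}`; relative
frequencies estimate `Pr(K0 = h | y)` and the posterior mode (ties broken
downward, for parsimony) is the point estimate `K_hat`.  The full
distribution is always reported — it is typically right-skewed, which is
exactly why mean-type estimators are avoided.  Weight-thresholding is
deliberately not offered as an estimator.

## Identification

Sweeps with `K0 = K_hat` contribute the mean draws of their non-empty
components to a point set (`K_hat` points per sweep, `K_hat x M0` total).
These are clustered into `K_hat` groups by K-centroids with
cluster-specific Mahalanobis distances `d_k(x) = sqrt((x - c_k)'
S_k^{-1} (x - c_k))`, alternating nearest-centroid assignment with
moment updates (`c_k` = within-cluster mean, `S_k` = within-cluster
covariance, regularized by `1e-8 tr(S_k)/n I`; clusters below `n + 1`
members fall back to the covariance of all points; an emptied cluster is
re-seeded at the point farthest from its centroid).

Two numerical facts shape the implementation, both verified by
enumeration on small point sets:

* The sum of assigned distances is *nearly invariant to the partition*
  when every cluster is measured by its own covariance (the mean
  within-cluster Mahalanobis distance is ~`sqrt(n)` regardless of the
  grouping), and small-cluster fallbacks can make degenerate partitions
  its literal minimum.  The raw objective is therefore recorded and kept
  monotone (the loop stops, reverting one step, if it would rise), but
  restarts are ranked by the determinant-scaled sum
  `sum_i d(x_i) det(S(x_i))^{1/(2n)}`, which is scale-free; its brute-force
  minimum over partitions is the generating partition on separated test
  clouds.
* Distances under an arbitrary initial metric are not comparable to
  moment-based ones, so each restart performs one Euclidean assignment
  from its greedy farthest-point seeds and converts to within-cluster
  moments before the Mahalanobis loop starts.  Restart `j` seeds from the
  `j`-th farthest point from the overall centroid (10 restarts), making
  the procedure deterministic and invariant to the input point order.
  (A published variant starts from MAP estimates of per-component prior
  hyperparameters this model does not have; the deterministic seeding
  replaces it.)

A sweep whose `K_hat` points land in `K_hat` distinct clusters gets its
draws (means, and with them covariances, weights and allocations)
reordered by that assignment; other sweeps are discarded.  The discarded
fraction `M0_rho` is reported as a separation diagnostic.  Weight draws
are carried over unrenormalized.  The final partition assigns each
observation its modal relabeled component over the `M_tilde` identified
sweeps (ties toward the smaller label).

## Evaluation

* `MCR`: misclassified fraction under the optimal injective matching of
  estimated to true labels (Hungarian algorithm on the confusion matrix;
  exhaustive enumeration is used only as a test oracle).
* `MSE_mu`: `sum_k mean_m (mu_k^(m) - mu_k^true)' (Sigma_k^true)^{-1}
  (mu_k^(m) - mu_k^true)` over identified draws, components matched to
  truth by the same matching as `MCR`; computed only when `K_hat` equals
  the true component count.  For real data the "true" values can be Bayes
  estimates from a fixed-allocation run.
* Shrinkage summaries: per-variable quantiles of the `lambda_j` draws and
  the ordering by median (cluster-relevant variables first).
* Allocation-probability traces of a single observation diagnose how
  much mass a superfluous component attracts under each mean prior.

## Synthetic study conditions

The generator reproduces the study designs exactly: four Gaussians in
`r = 4` with means `(2,-2,0,0)`, `(-2,2,0,0)`, `(2,2,0,0)`, `(-2,-2,0,0)`
and identity covariances — variables 1-2 carry the clusters, variables
3-4 are pure noise — with weights either equal or `(0.02, 0.33, 0.33,
0.32)` (a 2% component, ~20 observations per dataset of `N = 1000`,
count multinomial), plus a bivariate two-component setup (means
`(±2, 0)`, equal weights) for the empty-component illustration.  What the
generator does *not* emulate: non-Gaussian clusters, unequal or
correlated covariances, outliers, missing data.  Passing tests show the
machinery recovers a well-specified Gaussian mixture; they say nothing
about robustness to component misspecification.

Reference chain lengths are `M = 10000` after `burnin = 2000` with ten
datasets per condition.  The package's reduced defaults — three to ten
datasets, `M = 3000-4000` after `burnin = 1000-2000` — keep a full study
in minutes on one CPU; `scripts/acceptance.py` uses 4 replicates at
`M = 4000/2000` (equal weights), 10 replicates at `M = 3000/1000`
(unequal weights, whose MSE average is heavy-tailed through the 2%
component's `1/n_1`), and single fits at `M = 3000/2000` for the
overfitting-`K` recovery checks.  The `--full-scale` flag of
`sparsemix replicate` restores the reference scale.

## Known limitations

* The per-dataset Mahalanobis MSE in the unequal-weights design is
  dominated by the 2% component and varies several-fold across datasets;
  averages over ~10 datasets still carry meaningful simulation error, and
  small averages (3 replicates) should not be over-read.
* Under the normal-gamma prior with random `e0`, the number of non-empty
  components is systematically overestimated — shrunken empty components
  sit near the data and re-capture observations.  This is a property of
  the model, reproduced deliberately as a negative control; the remedy is
  a fixed, very small `e0` (0.01 down to 1e-5 as `K` grows).
* `Sigma_k` draws for empty components need `2 c0 > r - 1` (`r < 6`
  under the default `c0`); high-dimensional use would need a larger `c0`
  or a different empty-component convention.
* The identification step assumes clusters differ in their means (only
  means are clustered); mixtures separated only in covariance would need
  clustering on other parameter subsets.
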