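# Methods

## Model

Counts `y_ij` for sample `i` and taxon `j` arise in three layers: a latent
multivariate normal `z_i ~ N(mu, Sigma)`; abundances
`a_ij = exp(z_ij)` when `z_ij > delta_j` and `0` otherwise; and multinomial
read sampling `y_i ~ M(N_i, a_i / sum_k a_ik)` at library size `N_i`. The
threshold `delta_j` gives taxon `j` a structural-zero probability
`s_j = Phi_{mu_j, Sigma_jj}(delta_j)`; sampling zeros additionally arise
when a small proportion meets a finite library size. Conditional
independence between taxa is encoded by zeros of `Sigma^-1`, whose support
is the association network of interest.

The model assumes (a) zeros are dominated by true absence rather than
undersampling — reasonable for deeply sequenced shotgun data, less so for
shallow 16S libraries; (b) log abundances are jointly Gaussian above the
threshold; (c) a diagonal working covariance suffices for the marginal
estimation step (the dependence structure is only recovered afterwards, by
the penalized estimators).

## Transform

The zero-preserving clr maps nonzero entries to
`log y_ij − mean_k{log y_ik : y_ik ≠ 0}` and zeros to exactly `0`. It is
invariant to per-sample rescaling even with zeros present (the classical
clr with a pseudocount is not), at the price of centering over a
row-dependent subset. The zero mask, not the transformed value, is
authoritative for "was zero": a count of 1 can legitimately transform to a
value that collides with 0. The transform accepts real-valued input so the
invariance can be exercised with non-integer scale factors; file readers
still enforce integer counts.

## Estimation

With a diagonal working covariance the marginal likelihood for taxon `j`
factorizes: zeros contribute `log Phi_{mu, sigma2}(delta_hat_j)` and
nonzero entries the normal log-density of the transformed value. The
threshold estimate is the minimum transformed nonzero value (an order
statistic that converges to the truth from above). `(mu, sigma2)` are then
maximized by L-BFGS-B on `(mu, log sigma2)` from moment starts (mean and
MLE variance of the nonzero entries), gradient tolerance 1e-8; taxa with
no zeros reduce to the closed-form Gaussian MLE and carry a
`delta_hat = -inf` sentinel. Failures fall back to the moment estimates
with `converged = False`; variances are floored at 1e-4 so single-value
taxa stay usable.

Imputation is the posterior mean: observed entries pass through; a zero
becomes `E[z | z <= delta_hat_j] = mu_hat − sigma_hat · phi(alpha)/Phi(alpha)`
with `alpha = (delta_hat − mu_hat)/sigma_hat`, evaluated through
`logpdf − logcdf` so the Mills ratio stays finite arbitrarily far in the
lower tail. An optional correction to the diagonal of the imputed second
moment exists in the literature; it is deliberately not applied here, as
it shifts variance away from the covariance information the structure
estimators rely on.

## Structure inference

Columns of the reconstructed latent matrix are standardized to zero mean
and unit variance, so penalties are comparable across taxa and the
neighborhood estimator is invariant to column scaling. The penalty grid is
50 log-spaced values from `lambda_max` (the largest absolute off-diagonal
correlation, at which both estimators return the empty graph) down to
`lambda_max / 100`. Graphical lasso is solved per grid point by coordinate
descent (tolerance 1e-3, 100 iterations — supports are insensitive to the
duality gap at this scale); grid points are solved independently, which
makes the path trivially reproducible. Neighborhood selection runs one
lasso path per node under the `(1/2n)·RSS + lambda·l1` objective with
union ("or") symmetrization by default.

Solution-path supports are only approximately nested in floating point, so
the edge ranking uses each pair's *first-entry* penalty (largest `lambda`
at which it ever appears), with ties broken by absolute partial
correlation (glasso) or maximal absolute regression coefficient (MB) at
that penalty, then by index order; never-selected pairs form a terminal
tie block with score zero, so the ranking always covers all `p(p−1)/2`
pairs and recall reaches 1. Taxa observed in no sample are dropped before
inference and re-enter the ranking in that terminal block. Model selection
of a single graph (e.g. stability selection) is intentionally out of
scope: evaluation consumes the whole ranked path.

## Simulators

Ground-truth graphs: `band` (nearest index-neighbors at minimal bandwidth,
trimmed to `e` edges), `erdos_renyi` (`e` pairs uniform without
replacement; the benchmark uses `e = p`, so the expected network degree is
2), and `scale_free` (Barabási–Albert attachment with m=1, i.e. `p−1`
edges, topped up with uniformly random extra edges — an approximation
documented rather than hidden). Edge weights of the precision skeleton are
uniform on [0.3, 0.7] with random sign; the diagonal is the closed-form
shift `c = (lam_max − kappa·lam_min)/(kappa − 1)` of the skeleton's extreme
eigenvalues, which makes the precision positive definite with condition
number exactly `kappa` (default 100). The covariance is not re-standardized
to a correlation matrix afterwards, since that would destroy the targeted
condition number.

Generator defaults are the study conditions: `mu_j ~ unif(0, 3)`; library
sizes negative binomial with mean 1.5e6 and size 5 (variance
`mean + mean^2/size`); per-taxon sparsity `s_j ~ unif(0, 0.9)` in the
varying-sparsity protocol, which brings the global zero fraction of the
counts to ≈45%; and in the controlled-sparsity protocol the deterministic
profile `s_j = min((j/p)^t, 0.99)` with `t` root-solved so `mean(s) =`
target within 1e-6 (the cap is needed because `s_p = 1` for every `t`
otherwise, and it keeps every target below 0.99 reachable; the profile is
shuffled across taxa so sparsity is independent of graph position).
Thresholds follow as normal quantiles `delta_j = Phi^-1_{mu_j,Sigma_jj}(s_j)`.
A sample whose abundances are all zero is redrawn once and then rejected
loudly — silently dropping it would bias `n`. The NorTA comparator draws
`z ~ N(0, Sigma)`, pushes each coordinate through its marginal normal cdf
and then through the inverse cdf of a zero-inflated negative binomial
(mean `e^{mu_j}`, size 10, zero mass `s_j`); it has no multinomial step
and is therefore not compositional, by design.

All randomness descends from one integer seed through
`numpy.random.SeedSequence` spawning (graph, precision weights,
parameters, counts are separate streams; benchmark cells hash their cell
coordinates with CRC32 into the spawn key), so every experiment is
replayable.

What the simulators do *not* emulate: real taxonomic profiling noise
(mapping ambiguity, chimeras), taxon-correlated sequencing bias,
longitudinal structure, and marginals fitted to any real cohort. Passing
benchmarks therefore demonstrates correct recovery *under the model and
its comparator*, not performance on real gut microbiomes.

## Evaluation

AUPR over ranked-edge prefixes is the headline metric (true edges are ~2%
of pairs at `e = p = 100`, so ROC area is inflated by the negatives);
AUROC and precision@50 are reported alongside. Tied pairs are consumed as
blocks, so both areas are invariant to arbitrary order within a tie; the
PR curve is anchored at recall 0 with the first block's precision and
integrated by trapezoid. A uniformly random ranking concentrates at the
prevalence `e / C(p,2)` and the perfect ranking at 1 — both ends are
asserted in the test suite. Assortativity is Newman's categorical
coefficient on the edge mixing matrix; its label-permutation null carries
a small negative bias of order `1/e`, visible in the tests. Edge-set
overlap truncates each method's ranking to its top k and counts every
intersection region exactly.

## Problem sizes

The default benchmark cell is p=100, n=300 with 10 replicates and a
50-point grid — minutes on one CPU; the full study grid (p up to 500, n up
to 2000, three topologies, both generators) is reachable through
configuration. The test suite runs reduced instances chosen so the whole
suite completes in a few minutes while still exercising every contract at
the stated tolerances (condition number to 1e-6, truncated-mean closed
form to 1e-8 against quadrature, scale invariance to 1e-12).

## Known limitations

* The marginal MLE can drift to extreme `(mu, sigma2)` for taxa with very
  few nonzero observations under heavy truncation; estimates stay finite
  (variance floor, moment fallback) but are not reliable below ~10 nonzero
  values.
* `scale_free` with `e > p − 1` departs from pure preferential attachment.
* The one-step EM stops after a single E-step by design; iterating is
  possible but changes the estimator studied here.
* Supports along a glasso path can momentarily lose an edge as the penalty
  decreases; first-entry ranking absorbs this, but support sizes are only
  approximately monotone.
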