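# Methods

## Model and estimator

Node signals are modeled as draws from a multivariate Gaussian whose
precision matrix Ω encodes the direct-connectivity graph: ω_ij = 0 exactly
when nodes i and j are conditionally independent given the rest, and the
partial correlation is ρ_ij = −ω_ij/√(ω_ii ω_jj) (matrix form
−D^{−1/2}ΩD^{−1/2} + 2I, D = diag Ω; both are computed and cross-checked to
1e−12).

Ω is estimated by constrained L1 minimization: minimize ‖Ω‖₁ subject to
|Σ̂Ω − I|_∞ ≤ λ. The program decouples into one LP per column (split
β = u − v, u, v ≥ 0; objective Σ(u+v); 2M inequality rows). All M column
LPs share a constraint structure and are batched into a single
block-diagonal sparse LP solved with HiGHS (scipy.optimize.linprog); along
a tuning grid only the right-hand side changes, so the structure is built
once per covariance. The column solutions are symmetrized by keeping, for
each (i, j) pair, the entry of smaller absolute value with its sign. A
literal signed minimum would systematically favor negative entries; the
minimum-magnitude reading is the standard convention and is what this
package implements.

Numerical choices: covariance divisor T−1 (recorded in output metadata);
LP solver tolerance left at HiGHS defaults (~1e−9); entries with
|ω̂_ij| ≤ 1e−6 (`zero_tol`) are treated as structural zeros when counting
edges — above solver noise, below any simulated signal. Positive
definiteness is flagged by an eigenvalue check; non-PD estimates are still
transformed to partial correlations (with a warning, entries unclipped,
since clipping would corrupt downstream effect sizes). Singular
covariances are not silently repaired: infeasible columns raise an error
naming them, with an optional explicit `diag_perturb` escape hatch.

## Tuning-parameter selection

The density criterion Dens(Ω̂) = Σ_ij |ω̂_ij| (diagonal included) is
evaluated over a decreasing log-spaced grid, by default 30 points from 0.4
down to 1e−10 — the search range used in large-cohort applications of
this estimator; the grid is user-overridable and the package makes no
claim that any particular study used exactly this spacing. Dens is
non-increasing in λ up to solver slack (the feasible set only relaxes),
rising from near zero (empty graph) to a plateau at the unconstrained
estimate.

* Plateau rule: the largest grid λ such that every grid value at or below
  it has density within relative ε (default 0.01) of the profile maximum.
  An optional early-stopping sweep halts the profile once the density has
  grown by at most a relative ε over the last 3 grid points.
* Fractional-density rule: argmin over the grid of |Dens(λ) − p·Dens_max|,
  ties broken toward the larger λ (the sparser model).

Comparators:

* AIC/BIC: score(λ) = T·(−log|Ω̂(λ)| + tr(Σ̂Ω̂(λ))) + penalty, penalty
  2·d(λ) (AIC) or d(λ)·log T (BIC), d(λ) = number of entries above
  `zero_tol` (diagonal included, symmetric pairs counted twice); non-PD
  estimates score +∞. The fit term is minus twice the Gaussian
  log-likelihood of the T observations up to constants; the sample-size
  factor is deliberate — without it the penalty dwarfs the fit term at
  small M and the criteria degenerate to always choosing the sparsest
  grid point, which contradicts both the standard definition and the
  well-documented tendency of these criteria to over-select edges.
* k-fold CV (k = 5): time points split into contiguous blocks (respecting
  temporal autocorrelation); per fold the estimator is fit on the training
  covariance and scored on the held-out block's covariance (divisor =
  block length − 1) with either the negative log-likelihood
  −log|Ω̂| + tr(Σ̂_val Ω̂) − M or the trace-L2 loss Σ_i ((Σ̂_val Ω̂)_ii − 1)².
  Both losses share the same fold fits. The trace-L2 loss uses only the
  diagonal of the validation residual, as commonly defined for this
  estimator; it is consequently insensitive to off-diagonal structure and
  behaves conservatively (sparse selections) when validation blocks are
  short.

All selections are deterministic given the inputs; CV folds are
deterministic by the contiguous-block rule.

## Synthetic-data generator

The generator produces Y = X + Z (T × M): rows of X iid N(0, Σ_s) with
Σ_s = Ω⁻¹ − τ²I carrying the network structure, and columns of Z iid
stationary AR(1) with variance τ² and adjacent correlation γ (default
0.3). τ² is set to half the inverse largest eigenvalue of Ω, which makes
Σ_s positive definite by construction (λ_min(Ω⁻¹) = 2τ²) and gives Y the
marginal spatial covariance Ω⁻¹ exactly. The AR(1) component is sampled
exactly at stationarity (first row N(0, τ²), then the recursion); X uses
the symmetric eigendecomposition square root of Σ_s.

Random sparse precision matrices are drawn on the standardized scale:
unit diagonal; a uniformly random symmetric off-diagonal support with
exactly the nearest even count to `sparsity_level · M(M−1)` nonzeros; raw
magnitudes uniform in [0.4, 0.8] with random signs; and the whole
off-diagonal block rescaled so the smallest eigenvalue of Ω equals 0.1.
This near-boundary scaling was chosen — over the more common
diagonal-dominance recipe (diagonal = absolute row sum + margin) — because
diagonal dominance dilutes the partial correlations as density grows
(|ρ| ≈ 0.1 at the densest levels tested), leaving edges undetectable at
T = 50; the near-boundary construction keeps |ρ| ≈ 0.1–0.5, as strong as
each sparsity pattern permits. On this scale ρ_ij = −ω_ij directly.

What the generator emulates: the spatial precision structure and
first-order temporal autocorrelation of parcellated resting-state node
series. What it does not: hemodynamic response shapes, measurement
artifacts, global-signal confounds, subject heterogeneity, or nonstationa-
rity. Benchmark results therefore speak to support recovery under the
stated covariance model, not to preprocessing-related effects in real
data.

## Benchmark

The simulation study crosses nine off-diagonal sparsity levels (0.29,
0.36, 0.47, 0.49, 0.56, 0.76, 0.87, 0.89, 0.93) with replicate datasets
(M = 10, T = 50) and seven selection rules (plateau, density fractions
0.45 and 0.75, AIC, BIC, CV with both losses). Per replicate one
constrained-L1 path over the grid serves the density rules and the
information criteria, and one set of fold paths serves both CV losses;
each rule's selected estimate is converted to partial correlations and
scored against the truth by edge MSE (upper-triangle mean squared error),
sensitivity (true edges detected at `zero_tol`), and specificity (true
zeros retained; reported missing when a level has no true-zero edges).
Support is judged on the symmetrized estimate; the partial-correlation
and precision supports coincide. λ is selected per replicate on that
replicate's covariance. Replicate seeds are spawned deterministically
from one root seed, so reports are bitwise reproducible and any run can
be replayed alone. The default acceptance-scale study uses 50 replicates
per level (~8 minutes on one CPU); the shapes of the results are stable
from roughly 20 replicates on.

Pattern under these conditions: the plateau rule selects dense estimates
(sensitivity near 1, specificity near 0); AIC and the
negative-log-likelihood CV lean dense but, being correctly penalized /
validated, still prune some edges; BIC prunes harder; the trace-L2 CV is
strongly conservative because its loss ignores off-diagonal validation
structure; the p = 0.45 density rule gives the lowest edge MSE and a mean
of averaged sensitivity and specificity around 0.7.

## Group-level comparison

Per-subject connectivity values at each edge are Fisher-z transformed and
summarized by the effect size mean(z)/SD(z) (SD divisor S−1; edges with
zero variance across subjects are reported missing). Thresholding
|effect| (default 0.5) in the full- and partial-correlation maps yields
the four categories (partial-only / full-only / both / neither), with
per-category sign consistency of the mean-z values — consistency is an
empirical quantity, not structural: an edge significant in both maps can
still disagree in sign. Module-wise agreement between two averaged
networks uses Spearman rank correlation within each of the K(K+1)/2
module-pair edge blocks (blocks with fewer than 3 edges or all-tied
values reported missing), summarized by within- vs between-module means
and a two-sample Wilcoxon rank-sum p-value — the rank-sum test is this
package's documented choice for that contrast. The sparsity-shrinkage
comparison classifies edges under two density settings into significant/
moderate positive/negative and null bands (cuts at 0.3 and 0.5) and
reports class-transition counts and per-class retention.

## Known limitations

* The constrained-L1 LP grows as M² variables per covariance; the batched
  HiGHS formulation is comfortable to a few hundred nodes but the package
  is not tuned for thousands.
* Group averaging is a plain entrywise mean by default (Fisher-z
  averaging available as an option for full correlations).
* The benchmark's absolute accuracy numbers depend on the generator
  recipe (support placement, magnitude range, boundary margin, γ), which
  published studies of this estimator typically do not fully specify;
  patterns across methods are the robust output, exact magnitudes are
  recipe-dependent.
* No thresholding/binarization of correlation matrices and no imaging
  preprocessing: node time series are the entry point.
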