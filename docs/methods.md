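# Methods

## Model

A subject is a realization `c(1..I)` of a discrete random sequence of ECG
features (default `I = 14`).  For each disease class `k` the package builds
a *generalized canonical decomposition*: an ordered dictionary of monomials

    C^{xi_g}(nu - r_{g-1}) ... C^{xi_1}(nu),    nu = 1..I,

is orthogonalized sequentially under the empirical inner product
`<a, b> = (1/L) sum_l a_l b_l` over the class's `L` training realizations.
Monomial `m` contributes a coefficient `P_m` (the residual of its centered
value `Y_m` given all earlier non-degenerate coefficients), a variance
`D_m = E[P_m^2]`, and coordinate functions `omega[a][m] = E[P_a Y_m]/D_a`.
The recursions

    E[P_a Y_m] = E[Y_a Y_m] - sum_{b<a} omega[b][a] E[P_b Y_m]
    D_m        = E[Y_m^2]   - sum_a   E[P_a Y_m]^2 / D_a

consume only mixed sample moments; all moments are estimated with
denominator `L` (maximum-likelihood convention), which keeps the empirical
Gram matrix of monomials exactly positive semidefinite.  Orthogonalization
needs cross-moments of *pairs* of dictionary monomials, i.e. total degree up
to `2(N-1)`; they are computed directly from the sample with no order cap.

### Dictionary

The dictionary is parameterized by the order `N` (default 4) and the total
degree bound `B` (default `N - 1`; the per-factor bound cascade printed for
the monomial array resolves to "positive powers summing to at most N - 1"
— the only reading consistent with the named block-2 decision coefficient).
Blocks `nu = 1..I` each contain every monomial with `g <= min(nu, N-1, B)`
factors, strictly increasing lags `<= nu - 1`, and positive powers of total
degree `<= B`.  Within a block, monomials sort by (factor count, total
degree, descending power at `nu`, lexicographic on lags then powers); the
*decision coefficient* of a block is its last non-degenerate monomial,
which for `N = 4` is `C^3(1)`, then `C(2)C^2(1)`, then
`C(3)C(2)C(1)`-type triples whose lagged factors sit at the earliest time
points.  The linear dictionary (`B = 1`) and the polynomial dictionary
(single-time powers `1..N_p`, default `N_p = 3`) are strict subsets.

### Classifier

Training pools a single per-feature standardization across all classes
(a fixed invertible per-feature affine map cannot change the per-class
argmax, while conditioning of degree-6 moments improves enormously), then
builds one canonical model and one Parzen density per decision coefficient
per class.  A test realization is decomposed separately under *each*
class's model — the densities are class-conditional, so the coefficients
must be — and assigned to the class with the largest sum of decision-
coefficient log densities.  Ties break to the smallest label.  An optional
novelty flag labels a realization "unknown" when its best log-likelihood
falls below a threshold (default: off; when armed, the 1st percentile of
the per-class training log-likelihoods).

### Density estimation

Parzen estimates with a Gaussian kernel; bandwidth by Silverman's robust
rule `h = 0.9 min(sd, IQR/1.34) L^{-1/5}` (pluggable; an Epanechnikov
kernel is also registered).  A zero-spread sample falls back to a fixed
narrow bandwidth of 1e-3.  Log-evaluation floors the density at 1e-300 so a
single out-of-support coefficient cannot produce `-inf`; note that at this
level one floored factor still contributes ~-690 nats and can dominate the
comparison between classes (see Limitations).

## Numerical choices

* **Degeneracy.** A coefficient is degenerate when its residual variance
  falls below `var_tol = 1e-10` times the monomial's raw second moment
  (raw, not centered, so constant columns whose centered moment is pure
  roundoff are caught).  Degenerate coefficients are excluded from all
  later conditioning and carry the value 0.
* **Sample-rank budget.** Over `L` realizations at most `L - 1` centered
  columns can be linearly independent, so once `L - 1` coefficients are
  active every later monomial is marked degenerate outright.  This is an
  exact rank bound, not a heuristic; it protects the recursion from
  floating-point noise at rank exhaustion.  Consequence: at the full
  experimental shape (I=14, N=4: 679 monomials, L=200) blocks beyond ~9
  have no usable coefficient.  The decision rule then runs over the blocks
  usable in *every* class (logged per class); training fails only if no
  block is usable at all.  `select_decision_coefficients` retains a strict
  mode that raises on any fully degenerate block.
* **Two computational routes.** The production path evaluates the moment
  recursions streaming over the ordered dictionary, forming one centered
  cross-moment column per target (a unit-triangular solve per monomial) and
  never materializing the Gram matrix.  The verification path
  (`gram_schmidt_oracle`) materializes the centered monomial columns and
  runs modified Gram-Schmidt in realization space.  The two are
  algebraically identical and numerically independent; the suite requires
  agreement of `omega`, `D` and the degeneracy flags to 1e-8 on randomized
  instances.
* **Extraction/reconstruction.** Coefficient extraction is a unit-
  triangular solve against the active `omega` block; reconstruction of the
  first component is its exact algebraic inverse, so
  extract-then-reconstruct is the identity to ~1e-15.

## Independence diagnostics

Pairwise Pearson chi-square on `bins x bins` (default 4) marginal-quantile
bins — invariant under monotone transforms of either coefficient — with
Holm's step-down rule controlling the family-wise error over all decision-
coefficient pairs at `alpha = 0.05`.  The test needs at least `5 bins^2`
pairs (an expected-count budget of about five per cell).  Order selection
returns the smallest candidate `N` whose report accepts.  The cited
alternative independence criterion in the source literature is not
specifiable from the text; a permutation test on binned mutual information
(`mutual_information_pvalue`) fills the same role as an optional
binning-robust second check.

## Synthetic generator

Each class follows a lag-1 recursion: `c(1)` from the initial distribution,
then

    c(i) = offset(i) + alpha(i) z(i-1) + beta(i) (q(i-1)^2 - mean q^2)
           + sigma(i) eps(i),

with `z` the batch-centered previous value and `q = clip(z/sd(z), +-3)` its
saturated standardization.  The quadratic term is exactly mean-zero per
batch and injects third-order cross structure `E[z(i-1)^2 z(i)] != 0` that
no second-order model can represent.  The saturation is load-bearing: a
quadratic map on the raw lagged value has no stable fixed point for its
fourth-moment feedback and overflows within a few steps at any useful
coupling strength, while the clipped standardized driver keeps the sequence
stationary with bounded (if heavy) tails.  Innovations are Gaussian by
default (uniform and Laplace available), unit variance.

Benchmarks:

* `gaussian_shift` (default K=3, L_train=200, L_test=500, separation 2.0):
  jointly Gaussian classes differing only in mean — the setting where the
  linear decomposition is already adequate.
* `quadratic_coupling` (default K=2, L_train=1000, L_test=500,
  `beta = +-0.4`, `alpha = 0.3`): mirror-image class pairs.  The second
  class of a pair is generated from the *negated*, batch-centered
  innovations of the first, which makes the pair exact mirror images:
  per-index means and variances agree exactly (reported by
  `second_order_report`) and third-order cross-moments have exactly
  opposite sign.  L_train=1000 exceeds the 679-entry order-4 dictionary so
  the full decomposition is identifiable.

What the generator does **not** emulate: PQRST morphology, measurement
noise structure, inter-feature physiological constraints, or any
property of real ECG archives.  Passing benchmarks therefore demonstrates
the statistical machinery — whitening, criterion ordering on controlled
moment structure, diagnostic direction — not clinical performance.

## Problem sizes

The test suite uses I <= 6 and L in the low hundreds for unit properties,
20 seeded replicates at the benchmarks' default sizes for comparative
properties, 200 replicates for the chi-square calibration, and one full
K=9 / L=200 / I=14 / N=4 run for capacity and serialization parity.
`scripts/acceptance.py` uses ten seeded replicates per benchmark and the
same calibration and capacity sizes.

## Known limitations

* **The decision rule discards information.**  The product rule keeps one
  coefficient per block — the most conditioned, largest-lag monomial.  On
  the included lag-1-coupled benchmark this retains only part of the class
  signal: a diagnostic product over *all* coefficients separates the
  classes far better than the 14-coefficient rule, and a conditional-
  likelihood-ratio benchmark better still.  Two visible consequences,
  measured by the acceptance suite: the nonlinear criterion's margin over
  the linear one on `quadratic_coupling` is real but modest, and the
  single-time polynomial criterion — whose decision coefficient `p_i^{(3)}`
  happens to retain the marginal asymmetry — can outperform the full
  nonlinear rule at these conditions.  On `gaussian_shift` the same
  information loss makes the nonlinear criterion trail the linear one by
  several points rather than matching it.
* **Decision coefficients are not independent in general.**  Different
  blocks' decision monomials share the earliest features as common
  factors, so their residuals are exactly uncorrelated yet
  scale-dependent; the chi-square diagnostic detects this even on i.i.d.
  Gaussian features for `N >= 3`.  Within this construction only the
  linear coefficient set can test independent, so the diagnostic's
  practical use is the rejection direction (detecting that a linear model
  is inadequate), not certifying adequacy of the generalized model.
* **Small-sample degeneracy.**  With `L = 200` and the full order-4
  dictionary, the sample-rank budget truncates the model and near-boundary
  coefficients are over-conditioned (training residual spread far below
  test spread), degrading density calibration.  A training set several
  times the dictionary size is advisable.
* The density floor bounds but does not neutralize out-of-support
  evidence; one floored factor outweighs typical in-support evidence from
  all other blocks.
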