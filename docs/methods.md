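# Methods

## Model

Let `x_ij` be a scalar measurement (e.g. voxel FA) for subject `i = 1..n` at
voxel `j = 1..N`, with all subjects measured on a common, pre-aligned voxel
set.  After voxelwise standardization `z_ij = (x_ij − x̄_j)/s_j` (sample mean
and n−1 standard deviation over subjects at each voxel), all `nN`
standardized values are pooled and modelled as i.i.d. draws from an
m-component Gaussian mixture with a shared standard deviation:

    f(z) = Σ_k τ(k) φ((z − μ_k)/σ)/σ,   μ_1 < … < μ_m,  Σ_k τ(k) = 1.

The equal-variance constraint makes the components differ only by location,
which is what gives the mixing weights their interpretation as shape
coordinates: weight moved to the low-mean component lowers the mean and
skews the distribution right, weight 1/2:1/2 on the extreme components
maximizes variance, and so on.  The model dimension is `d = 2m` (m means,
m − 1 free weights, one variance), and m is chosen by minimizing
`AIC = 2d − 2 log L`.

Subject- and group-level structure is recovered *a posteriori*.  The
posterior membership of observation `z_ij` in component k is
`τ_ij(k) = τ(k)φ_k(z_ij)/Σ_l τ(l)φ_l(z_ij)`.  Subject i's mixing vector is
the voxel average `τ_i(k) = (1/N)Σ_j τ_ij(k)`; group g's is the subject
average `τ*_g(k) = (1/n_g)Σ_{i∈g} τ_i(k)`.  Subject and group density
estimates re-weight the shared components by these vectors, so a group curve
is by construction the pointwise mean of its subjects' curves.  Groups are
compared on `τ_i(k)` (default: the highest-mean component) with
Kruskal–Wallis rank tests — one per non-reference group against the
reference, plus an omnibus test across all groups with χ² degrees of freedom
G − 1.  Pairwise p-values are reported raw, with an optional Holm column; a
single-test report with an F-like df pair is sometimes seen for two-group
rank tests in other software, but this package uses the standard χ²
approximation throughout.

Because all subjects contribute to one pooled fit, the subject-level mixing
estimates are posterior quantities shrunk toward the global weights; at
moderate component separation the between-group contrasts in estimated
`τ_i(k)` are therefore somewhat attenuated relative to the generative
contrasts.  This is a property of the a-posteriori estimator, not a bug, and
it is shared by the rank tests' inputs in both groups, so test calibration
is unaffected.

## Estimation

**EM.**  The E-step computes memberships with log-sum-exp stabilization; the
M-step sets each mean to its membership-weighted data average, the shared
variance to the membership-weighted mean squared deviation pooled over all
components with the `nN` (maximum-likelihood) denominator, and the weights
to the grand mean of memberships.  Components are re-sorted to ascending
means after every M-step, which resolves label switching deterministically.
A component whose total membership weight falls below 1e−10 raises a
component-collapse error naming the component and iteration.

**Acceleration.**  Plain EM converges linearly at a rate set by the missing
component information and is impractically slow for overlapping components
at cohort scale (hundreds of thousands of observations).  The fit therefore
applies SQUAREM-style extrapolation: every two EM steps a squared
extrapolation candidate is formed in unconstrained coordinates
(μ, log σ, log τ) and accepted only if it does not decrease the
log-likelihood.  The recorded likelihood trace is non-decreasing, and every
accepted step is at least as good as the plain double step.  Two kernels
implement the elementary step: an m = 2 specialization using the fact that
the log posterior odds are linear in z, and a fused single-pass kernel
(numba-compiled when available, with a pure-numpy fallback) whose
log-likelihood is accumulated with Kahan compensation so the monotonicity
diagnostics are meaningful at tolerance 1e−8.

**Self-consistent weights.**  At a tolerance-converged EM point the reported
weights (from the last M-step) and the grand mean of memberships recomputed
at the reported parameters differ by the order of the stopping tolerance.
After convergence the weights are refined to the fixed point
τ = grand-mean(memberships(μ, σ, τ)) — a coordinate ascent on a likelihood
that is concave in τ, solved by Newton iteration on the stationarity
condition and polished by plain iteration of the exact E-step code path
until the iterate is bitwise stationary.  The refinement never decreases
the likelihood, and it makes the identity "all-subjects group τ* equals the
fitted global τ" hold exactly (to the bit) rather than approximately; the
grand mean is accumulated voxels-then-subjects, matching the downstream
subject/group estimators' reduction order.

**Initialization and stopping.**  Default initialization is deterministic:
means at the k/(m+1) data quantiles, σ the sample standard deviation, τ
uniform.  `select_m` additionally runs (by default) 5 seeded random restarts
per candidate m (means drawn from the data) and keeps the best likelihood.
Iteration stops when the log-likelihood improves by less than 1e−8
(absolute) or after 500 elementary EM steps; both are configurable.  AIC
ties break toward smaller m.  A model with more components than distinct
data values is rejected up front.

**Order selection in practice.**  AIC admits an extra component whenever it
buys a log-likelihood gain above 2.  For an overfitted equal-variance
component this generalized likelihood-ratio gain does not vanish with sample
size, so with a thorough multi-start search AIC selects one spurious extra
component in roughly 10–15% of replicates even on cleanly separable
two-component data of several thousand observations.  Users who need an
order decision more conservative than AIC should inspect the reported
m → AIC table rather than the argmin alone.

## Numerical and interface choices

- Voxels non-finite for any subject are dropped for all subjects
  (complete-case by voxel): the pooled likelihood and the per-voxel
  standardization both need a common voxel set.  Zero-variance voxels are
  dropped at standardization.  Both counts are logged.
- NIfTI ingestion linearizes mask voxels in Fortran (x-fastest) order,
  fixed and documented so voxel column order is reproducible.
- Standard errors for `τ*_g(k)`: between-subject sample standard deviation
  of `τ_i(k)` within the group divided by √n_g — subjects are the unit of
  analysis.  Reported as missing for singleton groups.
- Density curves are evaluated on `[min z − 4σ, max z + 4σ]` with 512 points
  by default.
- Output tables carry ≥ 10 significant digits so re-reading reproduces
  values exactly; a fixed seed reproduces byte-identical outputs.

## Synthetic cohorts

The generator emulates the data-generating structure the method assumes,
with known truth at every level:

1. Subject mixing vectors are logistic-normal perturbations of their group's
   mean vector: independent N(0, `subject_tau_sd`) noise on the log-weights,
   re-normalized by softmax.  The default `subject_tau_sd = 0.2` implies a
   between-subject standard deviation of τ_i(2) of about 0.04 for weights
   near 0.25, the magnitude consistent with group standard errors of
   0.008–0.018 at n_g = 7 in FA cohorts of this design.
2. Per voxel, a component label is drawn from the subject's mixing vector
   and the standardized-truth value from the corresponding Gaussian — so the
   truth matrix is an exact draw from the pooled mixture.
3. The raw value is an affine per-voxel distortion
   `x_ij = a_j + b_j z_ij`, `a_j ~ N(0, 0.5)`, `b_j ~ U(0.8, 1.25)`,
   emulating regional location/scale heterogeneity.  Voxelwise
   standardization removes it exactly within each voxel column (the
   standardized column is a deterministic affine image of the truth column),
   which is what makes the normalization step falsifiable in tests.

Presets: `paper_like` (4 groups × 7 subjects, 20,000 voxels,
μ = (−0.26, 0.78), σ = 0.87, group τ(2) means 0.2723, 0.2663, 0.2519,
0.2127), `null` (identical mixing in all groups, for calibration), and
`separable` (μ = ±3, σ = 1, for order-selection studies).

What the generator does *not* emulate: spatial autocorrelation between
voxels, scanner noise, registration error, bounded support of FA, or
non-Gaussian component shapes.  Passing tests therefore demonstrate
correctness of the estimator and its calibration under the model's own
assumptions, not robustness to those real-data features.

With per-voxel statistics estimated from only n subjects, voxelwise
z-scoring is itself noisy: the per-voxel scale estimate inflates the
standardized values by E[√((n−1)/χ²_{n−1})] (≈ 4% at n = 28), a small
deterministic bias of the normalization step, not of the mixture estimator.
Simulation checks of estimator bias are therefore run on the generator's
standardized-truth matrix; the normalization step is validated separately
by its exactness and affine-invariance properties.

## Problem sizes used in the test suite

Parameter-recovery replicates use the full `paper_like` size
(28 × 20,000, 50 replicates); order-selection replicates use ~5,000 pooled
observations (100 replicates per scenario); Kruskal–Wallis calibration uses
28 subjects × 200 voxels (2,000 replicates) — calibration depends on
exchangeability of subjects, not on voxel count; small-instance oracle
comparisons use ≤ 100 observations against a multi-start Nelder–Mead
maximization of the same likelihood.

## Known limitations

- Inter-subject voxel correspondence is assumed given (pre-aligned input);
  no registration is attempted.
- Discrimination between groups requires m ≥ 2; if one Gaussian suffices,
  the approach has no shape coordinates to compare.
- Unequal-variance and non-Gaussian mixtures are out of scope.
- For heavily overfitted orders (m well above the generative order) the
  bitwise τ self-consistency may degrade to ~1e−13 agreement if the polish
  iteration hits its cap; at the selected order it is exact in all tested
  configurations.
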