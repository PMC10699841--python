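# Methods

## Model

For a target dataset with response y (length n) and feature matrix X
(n×p, p typically ≫ n) we fit the GLM E[y_i] = h⁻¹(β0 + Σ_j β_j x_ij)
with the identity link for gaussian responses and the logit link for
binomial responses coded {0,1}. Co-data enter as a p×m matrix of prior
effects: column k holds one external study's per-feature effect
estimates z·k, assumed *positively* correlated with the target's true
coefficients (an `allow_negative` switch lifts this assumption by also
fitting the sign-inverted calibration and keeping the better one).
Prior columns are rescaled by their maximum absolute value — never
recentered — which is sufficient because both calibration maps are
invariant to multiplication of the priors by a positive scalar.

## Calibration

**Exponential.** γ_jk = θ_k sign(z_jk)|z_jk|^τ_k. For each τ on the
grid {0, 0.25, …, 3.0} we form the single covariate
v_i = Σ_j sign(z_j)|z_j|^τ x_ij and fit intercept plus one slope θ ≥ 0
(maximum likelihood with the non-negativity bound); the τ with the
smallest in-sample deviance wins and ties go to the smaller τ. The grid
spans shape changes from "all priors equal" (τ=0) through square-root,
identity and quadratic distortions with margin; 0⁰ is defined as 0 so
zero priors always map to zero. θ̂ = 0 collapses the source to the null
model.

**Isotonic.** γ̂·k maximizes the likelihood subject only to sign
preservation and order preservation with respect to z·k. Features are
ordered by prior value; features with *equal* priors are merged into
one group (columns summed) since the two-sided order constraints force
them to share one calibrated effect; zero-prior features are excluded
and fixed at γ=0. With q negative groups among G, the design column for
group a is the cumulative sum of group columns 1..a (a ≤ q) or a..G
(a > q), and the group effects δ are constrained δ_a ≤ 0 (a ≤ q),
δ_a ≥ 0 (a > q). The linear predictor of this sign-constrained model is
identical to the original order-constrained one, and the calibrated
effects are recovered as tail/head partial sums of δ̂. The
sign-constrained fit is maximum likelihood stabilized by a fixed tiny
ridge (1e-8 on the solver's standardized scale) so the optimum is
bounded and unique even when G ≥ n or under binomial separation;
separation-bounded fits are flagged via the convergence indicator.

**Source filter.** After calibration on the full training data, each
source is kept only if its per-sample residual magnitudes — absolute
raw residuals for gaussian, absolute deviance residuals for binomial —
are significantly smaller than those of the intercept-only model by a
paired one-sided Wilcoxon signed-rank test at the 5% level. Zero
differences are dropped; with ≤ 25 informative untied pairs the exact
null distribution is used, otherwise the normal approximation with
continuity correction. Filtering happens once, before any stacking;
excluded sources keep all-zero predictor columns and therefore weight
exactly zero. Under null co-data and a null response the filter's
rejection rate is nominal for exponential calibration (measured 5.0%
over 400 null datasets in the test suite); isotonic calibration is
mildly anti-conservative in small samples because its fit has more
capacity to overfit in-sample, which in practice is mitigated by the
meta-learner's cross-validated weighting.

## Co-data-free baseline and cross-validation

The baseline is an elastic-net GLM (α=0 ridge … α=1 lasso) along a
100-value λ path, λmax taken from the score of the null model (for α=0
the formula uses α'=0.001), log-spaced down to λmax·0.01 when n < p and
λmax·1e-4 otherwise. Ten-fold cross-validation — stratified by class
for binomial responses — selects λmin (minimum mean held-out deviance)
and λ1se (largest λ within one standard error of that minimum, SE taken
across fold means). Both fits are handed to the meta-learner even when
the two indices coincide; the meta-lasso resolves the redundancy. One
fold plan per analysis is drawn and shared by every cross-validated
component (per-fold recalibration, baseline path, meta-learner), so no
held-out row is ever predicted by a model that saw its fold.

## Stacking

The meta-features are cross-validated linear predictors: for source k,
row i is x_i·γ̂·k^(−κ(i)) with the calibration intercept deliberately
ignored (all co-data columns share a common anchor); for the baseline,
the held-out linear predictors at λmin and λ1se including their
intercepts.

*Standard stacking* regresses y on the n×(m+2) matrix under lasso
regularization with a free intercept and zero lower bounds on all
slopes; λ is chosen by cross-validation on the shared folds with the
λmin rule. Meta-features are *not* standardized before this fit — they
already share the linear-predictor scale, and rescaling would distort
the weighted-sum algebra of the combined coefficients. The fitted model
collapses to a single GLM: β0* = ω̂0 + ω̂_{m+1}β̂min,0 + ω̂_{m+2}β̂1se,0
and β*_j = Σ_k ω̂_k γ̂_jk + ω̂_{m+1}β̂min,j + ω̂_{m+2}β̂1se,j, where the
γ̂ are full-data recalibrations (the cross-validated versions are used
only to learn ω).

*Simultaneous stacking* regresses y jointly on the m co-data columns
(penalty factor 0, lower bound 0) and the p raw features (the user's
ridge/lasso penalty, unconstrained), with λ again chosen by CV on the
shared folds; β0* = β̂0 and β*_j = Σ_k ω̂_k γ̂_jk + β̂_j, so the combined
coefficients are shrunk toward the weighted calibrated priors and the
penalized β̂ are sparse *deviations* under lasso. The λmin/λ1se columns
are deliberately absent from this mode. All-zero co-data columns
(filtered or degenerate sources) are dropped from the joint design —
they would receive weight zero anyway — which makes the zero-source
case reduce exactly, bit for bit, to the plain penalized baseline. The
mode refuses m > n/2 sources, where leaving the meta-weights
unpenalized stops being sensible; standard stacking handles many
sources.

## Solver

The numerical core is cyclic coordinate descent for the weighted
elastic-net objective (1/2n)Σ w_i(z_i−η_i)² + λΣ_j pf_j(α|b_j| +
(1−α)/2 b_j²) with per-coefficient penalty factors pf and hard box
constraints applied by clipping each exact coordinate minimizer (for a
1-d convex objective the clipped unconstrained minimizer is the
constrained minimizer). Numba-compiled kernels with an active-set sweep
(iterate on nonzero/unpenalized coordinates, then re-check the full
set) and warm starts along the path; binomial fits wrap the same kernel
in IRLS with working weights clipped below at 1e-5. Convergence is
declared when the maximum weighted squared coefficient change in a full
sweep falls below 1e-7 (1e-9 for the unpenalized sign-constrained
fits), with a 1e5-sweep budget; non-convergence is flagged on the
returned fit, never raised.

Features are standardized internally to unit variance (constant columns
get coefficient zero) and coefficients are transformed back; bounds are
mapped to the standardized scale. For gaussian responses the solver
additionally works in units of y/sd(y), as mainstream path solvers do:
the reported λ grid then refers to a unit-variance response, which
leaves lasso solutions invariant but weakens the effective ridge
penalty by the factor sd(y). This convention is load-bearing for
reproducing published ridge benchmarks and was cross-checked against an
independent R path-solver implementation on shared data (identical λ
grids; coefficients matching to ~3e-4). Unconstrained uniform-penalty
gaussian ridge paths take an exact SVD shortcut instead of coordinate
descent; the two routes solve the same objective.

## Simulation designs

*External design.* Features are gaussian with correlation 0.5^|i−j|
(via Cholesky); the target has s coefficients equal to 0.5 and the rest
zero (n_target=100 training and 10,000 test samples, p=1000); each of
K=5 sources (n=150) is either transferable — target coefficients
displaced entrywise by ±h/p with random signs — or non-transferable —
displaced by ±2h/p with the causal block moved and s causal slots
scattered randomly through the tail. Gaussian targets add standard
normal noise (sources also get a 0.5 intercept); binomial targets are
Bernoulli draws from the logistic probabilities.

*Internal design.* Features are gaussian with correlation ρx^|i−j|
(p=500). Coefficients for the target and three sources come from
thinned correlated gaussians: B = B1·1[B2 > Φ⁻¹(1−π)] with both p×4
matrices drawn with cross-dataset correlation ρβ among the target and
sources 2–3 and source 1 independent. Source 2's coefficients are then
squared (sign kept) and source 3's square-rooted — the square-root
reading of the two distortions is chosen as the symmetric counterpart
of the square, and the generator exposes `beta3_transform="identity"`
for the alternative reading; with ρβ=0.99 dense the mean maximum
target-source coefficient correlation comes out at 0.88–0.89 under
either. Targets are y = h⁻¹(√w·z* + √(1−w)·ε) with z* the standardized
linear predictor and w=0.8 (signal-to-noise 4:1); the train and test
samples are standardized jointly as one dataset. Binomial targets round
the probabilities to classes (p ≥ 0.5 → 1) rather than redrawing.

*Prior derivation.* Sources are never handed to the learner; instead
each source is fitted by cross-validated penalized regression — ridge
in dense settings, elastic net α=0.95 in sparse settings, where the
lasso's erratic selection would destabilize the prior information — and
its λmin coefficients form one prior-effect column.

*Evaluation.* Percent-of-null: 100 × metric(model)/metric(null), with
test MSE for gaussian and mean logistic deviance for binomial, the null
predicting the training mean (prevalence). Replicated studies report
mean ± SD over 10 replicates and a paired one-sided Wilcoxon test
against a baseline. Random-number streams are spawned per replicate
from the root seed, so adding methods never perturbs the simulated
data, and a given (scenario, seed) is bit-reproducible.

What the generators do *not* emulate: real linkage-disequilibrium
block structure (correlation decays geometrically), measurement
batch effects, partially overlapping feature spaces between source and
target, and miscoded allele directions. Passing benchmarks therefore
demonstrates correct mechanics and calibration behaviour under the
stated designs, not performance on any particular cohort.

## Numerical choices and edge cases

- τ grid {0, 0.25, …, 3.0}; selection ties broken toward smaller τ.
- ε-ridge 1e-8 for all "unpenalized" maximum-likelihood fits; this is a
  stabilization choice, not part of the statistical model.
- Degenerate inputs: all-zero prior columns calibrate to γ=0 and are
  flagged; constant features get coefficient 0; a constant response is
  rejected; a binomial class smaller than the fold count is rejected.
- A source whose calibration fails inside one CV fold contributes zeros
  for that fold's rows (with a warning) instead of aborting the fit.
- λ grids are shared between the full-data fit and every fold so CV
  curves are comparable; λmin may sit at the boundary of the grid for
  strongly regularized problems, which mirrors the inherited grid
  convention.
- Meta-weights are exact zeros (hard bound), so "source excluded"
  statements are exact, not thresholded.
- Model JSON serializes floats via shortest round-tripping repr;
  serialize → deserialize → predict is bit-exact.

## Test-suite problem sizes

The suite exercises full-size benchmark scenarios (p=1000, 10
replicates) only in the acceptance layer; property suites run on
reduced instances chosen to keep each property's Monte-Carlo error well
below its assertion margin: calibration-shape battery at n=200, p=500
over 20 seeds; filter power at n=100, p=30 over 100 seeds; filter
type-I error at n=50, p=20 over 400 seeds; negative-transfer guard at
n=100, p=120 over 25 seeds; oracle equivalences at p ≤ 8 where
general-purpose constrained optimizers are reliable references.

## Known limitations

- Only gaussian and binomial families; no Poisson or survival models.
- Dense in-memory feature matrices; no sparse storage.
- Prior-weight-only co-data (importance without direction) is out of
  scope — supplying absolute values as priors would impose arbitrary
  signs rather than discover them.
- The isotonic filter's small-sample optimism noted above.
- Simultaneous stacking leaves meta-weights unpenalized and so is
  limited to few sources by construction.
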