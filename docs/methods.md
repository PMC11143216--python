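# Methods

## Model

The package implements a generative model for post-TAVR mortality over four
variable blocks: tabular covariates `A` (d_A dims, mixed continuous/binary),
a compact image representation `f = f(I; ω)` (d_f = 16 by default), manual
CT measurements `J` (d_J dims, continuous), and a binary outcome `Y`. The
joint factorizes along a DAG in which `A` influences `f` and `Y`, and `f`
influences `J` and `Y`:

```
p(A, f, J, Y) = p(Y | A, f) · p(J | f) · p(f | A) · p(A).
```

Both conditional Gaussians carry *isotropic* covariances (σ_I², σ_J²): full
covariances would add O(d²) parameters that registry-sized cohorts cannot
support. The outcome head reads the **residual** `f − βᵀA` next to `A`
itself, so the image contributes only what the covariates do not already
predict, and tabular effects are not double-counted through the feature
mean. `p(A)` is a fully factorized prior whose hyperparameters are set once
per training fold by maximum marginal likelihood (sample means, ML
variances, observed Bernoulli fractions) and then held fixed; Bernoulli
rates are clipped to [1e-3, 1−1e-3] so a degenerate fold can never produce
infinite log-likelihoods. Continuous variances get a 1e-6 floor for the same
reason.

Measurements act as *auxiliary outputs*: they are modelled, never required
as inputs. With the image present, `J` and `Y` are conditionally independent
given `f`, so predictions ignore `J` entirely. With the image missing, the
Gaussian posterior `p(f | A, J_obs)` routes whatever measurements exist into
the outcome — the auxiliary structure is what lets a measurements-only
patient be scored at all.

## Marginalization

For each row, the likelihood is the density of exactly what was observed:

* **missing J dims** — dropped (output variables);
* **missing image** — `f` integrated analytically: the evidence becomes
  `N(J_obs; φ_oᵀβᵀA, σ_I²φ_oᵀφ_o + σ_J²I)` on the observed measurement
  block, and the outcome factor becomes a sigmoid of a Gaussian, closed with
  the scaled probit (below);
* **missing continuous A dims** — integrated against their Gaussian priors;
  they enter every factor linearly, so the algebra stays Gaussian
  (linear-Gaussian conditioning on whichever of `f`/`J_obs` is observed);
* **missing binary A dims** — enumerated over all 2^k assignments weighted
  by prior rates (outermost loop, log-sum-exp accumulation; k > 20 raises
  rather than silently exploding).

With nothing missing the result reduces **exactly** to the complete-data
log-joint — the probit correction vanishes at zero variance — and the test
suite asserts this to 1e-10. The implementation is a single vectorized
evaluator over rows grouped by missingness pattern; the one-observation API
(`marginal_log_joint`, `predictive_outcome`) is a thin wrapper over the same
code path. Small SPD systems (≤ d_f + k) are solved by explicit inverse with
a 1e-9 diagonal jitter fallback; explicit inverses rather than Cholesky
because the complex-step path (below) needs complex-*symmetric* algebra.

### The probit closure

`E[σ(g)]` for Gaussian `g ~ N(m, v)` is approximated by
`σ(m / √(1 + π/8·v))`, the standard scaled-probit closure; the π/8 constant
matches the sigmoid's slope at the origin. Its accuracy deserves precision:
the *pointwise* gap between `σ(x)` and `Φ(√(π/8)x)` is ≤ 0.0095, but the
composite convolution error is slightly larger — the true maximum over
m ∈ [−6, 6], v ∈ [0, 25] is **0.0131**, attained at m = 6, v ≈ 10.5
(verified against both 64-node Gauss–Hermite and adaptive quadrature). At
the argument scales the fitted model actually produces (|m| ≲ 3, v ≲ 5) the
error stays below 0.005. The acceptance study reports the measured grid
maximum; the Monte-Carlo agreement study budgets the closure as a
per-instance error allowance of 0.01·p(obs), where p(obs) =
p(obs, Y=1) + p(obs, Y=0) is closure-exact because the probit terms cancel
in the sum.

### Monte-Carlo oracles

`mc_marginal_oracle` samples all missing variables from their generative
priors and averages the *exact* density of the observed block (exact
logistic sigmoid — approximation-free), reporting the estimate and its
standard error; `mc_predictive_oracle` is the self-normalized analogue with
a delta-method standard error. These oracles are the independent reference
for every closed-form path; they share no code with it beyond the elementary
densities.

## Training

The objective is the mean negative marginal log-joint of each training row
under its own pattern. Complete rows therefore use the full four-factor
log-joint *including* `p(f|A)` — without that term β would be unidentified
from complete data. One asymmetry is deliberate: the gradient flowing into
the **feature extractor** ω excludes the `p(f|A)` term and keeps only the
outcome and measurement terms. With a trainable deterministic extractor, the
full-likelihood gradient admits a degenerate optimum — ω collapses `f` onto
βᵀA while σ_I → 0 sends the likelihood to +∞ — and in experiments that
collapse is exactly what happens, erasing the image signal. Restricting ω's
objective to the predictive terms removes the pathology while the
probabilistic parameters continue to see the full likelihood.

Gradients of the probabilistic parameters are computed by **complex-step
differentiation**: every operation in the likelihood is analytic, so
evaluating at θ + i·h·e_p (h = 1e-20) and taking Im/h gives the partial
derivative to machine precision, with no subtractive cancellation. All
perturbed parameter vectors are evaluated in one vectorized pass along a
leading batch axis (chunked, default 64 at a time, to bound memory). The
test suite checks these gradients against central finite differences to
1e-4 relative. The tiny reference backbone (average-pool to 4×4×4 →
linear map to D) is linear, so its vector-Jacobian product is exact and
hand-written; it is checked against finite differences too.

Optimization is Adam (β₁ = 0.9, β₂ = 0.999) with early stopping on the
validation objective and best-validation parameters returned. Defaults:
lr 1e-3 (probabilistic) / 1e-4 (backbone), batch 32, patience 10. The
validation studies instead use full-batch Adam at lr 0.05 with a cosine
decay to lr/20 — with exact full-batch gradients this converges smoothly in
a few hundred epochs, and the decay prevents terminal oscillation from
confusing the early-stopping rule. σ_I and σ_J are optimized as logarithms;
initialization is N(0, 0.01²) for the link and head weights, the training
log-odds for b_Y, and 1.0 for both noise scales. Fits are bitwise
deterministic given the seed. Joint backbone training requires complete
covariates on image rows (the analytic feature gradient assumes them);
feature-given training supports arbitrary missingness.

### Normalization

Continuous covariates are z-scored with *training-fold* statistics; binary
covariates stay {0,1}. Measurements are **scaled but not centred**: the
measurement link φᵀf carries no intercept, so centring `J` would introduce
an offset the model cannot represent and demonstrably biases φ (scale-only
normalization leaves φ recoverable to ≈ 1% relative RMSE in the recovery
study, versus ≈ 30% with centring). Covariate centring is harmless — it
moves only the implicit intercepts, which b_Y and σ_I absorb — and
necessary for conditioning with covariates like age.

## ROI extraction

Five aortic centerline landmarks (root → ascending aorta, mm) are
interpolated by a cubic smoothing spline against a chord-length parameter
(`scipy.interpolate.splprep`). The smoothing residual budget defaults to
*adaptive*: the largest value on a decreasing ladder whose maximum
landmark-to-curve deviation stays within 2 mm — half the reported ~4 mm
localization error of automatic landmark placement, so localization noise is
absorbed without the curve drifting off the anatomy. 64 stations are placed
at equal arc length (inverted from a dense arc-length table); at each, a
64×64 slice is resampled perpendicular to the unit tangent by trilinear
interpolation, with the in-plane x-axis the normalized projection of the
sagittal axis onto the slice plane (Gram–Schmidt; axial-axis fallback when
the tangent is parallel to it, logged). Out-of-volume samples are filled
with −1000 HU (air) and counted. In-plane spacing defaults to 1 mm (the
physical slice extent is not prescribed by the protocol and is
configurable); slice spacing is total arc length / 63. Intensities are
clipped to [−200, 800] HU and min-max scaled before the backbone.

## Synthetic data

The generator samples exactly the model hierarchy — it is the generative
reading of the DAG, so fitted-model correctness can be judged against known
truth. Missingness is imposed afterwards: MCAR with per-variable rates, or
MAR with per-row probability σ(c₀ + c·z(driver)) driven by an always-observed
age-like covariate (c₀ bisected to hit the target average rate). Images drop
as a whole (the model assumes an image is either complete or absent), the
outcome is never masked. The `registry` preset mirrors the cohort this
model targets: 25 covariates (10 continuous / 15 binary), 15 measurements,
16 features, n = 1449, 49% missing images, and an outcome intercept
calibrated by bisection to 44% prevalence.

Tube phantoms render an analytic curve (straight/arc/helix) as a tube of
configurable radius, edge softness and noise on a voxel grid, with landmarks
placed exactly on the curve — every geometric claim about the straightening
is tested against these closed-form constructions. A fixed invertible map
encodes a 16-vector into 16 slice-band radii
(radius_k = 6 mm + 1.2 mm·f_k by default), which is how the end-to-end
"planted image signal" experiments plant ground truth a backbone can
recover.

What the generator deliberately does *not* emulate: real CT anatomy,
calcification texture, inter-covariate correlation (the model itself assumes
a factorized p(A)), measurement-specific noise scales, or
informative-missingness beyond MAR. Passing tests therefore demonstrate the
*mechanics* — marginalization exactness, unbiased fitting, geometric
fidelity — not clinical performance on real registries, which the original
cohort's access restrictions put out of reach here.

## Validation studies and their sizes

All studies live in `tavrisk.experiments`, seeded and deterministic; the
test suite asserts on them and `scripts/acceptance.py` reports them.

* **Marginal vs MC** — d_A=4, d_f=3, d_J=2; 100 instances per missingness
  class; 200k MC samples; tolerance 3·stderr + 0.01·p(obs).
* **Probit closure** — 61×51 grid, 64-node Gauss–Hermite.
* **Recovery** — n = 5000, d_A=6 (4 continuous / 2 binary, moderate
  Bernoulli rates), d_f=4, d_J=3, 30% MCAR on covariates and measurements.
  Planted outcome weights |α_A| = 1.0 (odds ratio ≈ 2.7) with ‖α_I‖ = 0.45:
  chosen so the 0.15 relative-RMSE budget sits clearly above the logistic
  estimator's own noise floor (≈ 0.08–0.10 here) — a recovery study with
  tolerance at the noise floor would measure luck, not correctness — while
  staying in the regime where the probit closure's bias is negligible.
  Held-out comparison on a fresh 2000-row cohort.
* **Auxiliary benefit** — 10 seeds, informative measurements (σ_J = 0.3),
  49% missing images, n = 600/150/600 train/val/test, paired full-vs-ablated
  AUROC.
* **Marginalization vs imputation/deletion** — 20 seeds, tabular-only truth,
  30% MCAR, n = 1100 per seed; deletion fits on complete rows and scores
  test rows with training-mean imputation (the only way a deleted-row model
  can score incomplete patients).
* **ROI geometry** — 64³ phantoms; the rigid-motion check uses a smooth-edged
  arc on an 80³ grid with 0.5 mm in-plane sampling so every ROI sample stays
  inside the volume in both frames (otherwise the out-of-volume fill, not
  the resampler, would dominate the comparison).
* **Importance** — n = 600, 5 covariates, k = 5 folds; one covariate carries
  the dominant weight, one is inert (zero outcome weight, zero feature
  link); the exact-zero inert check uses the generating parameters.

## Known limitations

* The probit closure is the single deliberate approximation; its worst-case
  grid error (0.0131) slightly exceeds the often-quoted pointwise 0.01, and
  with very strong effects (per-coefficient |α| ≳ 2 on standardized data)
  its accumulated score bias becomes measurable in the ML estimates.
* Enumeration over jointly-missing binary covariates is exponential
  (capped at 2²⁰ terms); cohorts with many simultaneously-missing binary
  variables per row would need a different strategy.
* p(A) is fully factorized; strongly correlated covariates should be
  filtered or transformed first, as the application this model comes from
  also assumes.
* Joint backbone training supports the tiny linear reference backbone;
  large pretrained 3D networks integrate through precomputed feature caches
  rather than in-process fine-tuning.
* Missing-data handling assumes MCAR/MAR; under MNAR the marginal likelihood
  is no longer the right objective.
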