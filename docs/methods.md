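# Methods

## Model and penalty

`sgleeg` fits a multinomial logistic regression to fused multichannel EEG
features under a sparse group lasso penalty.  With N trials, p channels and d
features per channel, the design matrix is N × (p·d) with each channel's d
columns contiguous; labels take M ≥ 2 values and the largest class value is
the reference of the logit parametrization, so the free coefficients form a
(p·d) × (M−1) matrix β.  The fitted objective is

    F(β) = −ℓ(β) + λ (1−α) Σ_J w_J ‖β^{(J)}‖₂ + λ α ‖β‖₁

with ℓ the (sum, not mean) multinomial log-likelihood.  A group J is one
channel's block of d × (M−1) free coefficients; this keeps the reference-class
convention consistent across the group.  Group weights default to w_J = 1;
`sqrt_size` weighting (w_J = √(d·(M−1))) is available via
`SolverSettings.group_weight_mode` for users who prefer the conventional
group-lasso scaling.

An unpenalized per-class intercept is included by default (`fit_intercept`),
initialized at the intercept-only maximum-likelihood point (log class-odds).
It can be disabled for a fully literal penalized model, but without it λ_max
is not meaningful on data with unbalanced classes.

Features are z-scored with training statistics before penalized fitting
(zero-variance columns get unit scale).  The standardizer is stored in the
fitted model and re-applied at prediction time; a common λ across feature
families as heterogeneous as band powers (variance ∝ amplitude⁴) and AR
coefficients (O(1)) is meaningless without it.

## Parameter estimation

Three nested, fully deterministic loops:

* **Outer — coordinate gradient descent.**  At the current iterate the smooth
  loss f = −ℓ is replaced by the quadratic model built from its exact
  gradient q = Xᵀ(P_free − Y_free) and a block-diagonal curvature with one
  exact Hessian block per channel group,
  (H_JJ)[(j,m),(j′,m′)] = Σ_i x_ij x_ij′ (diag(p_i) − p_i p_iᵀ)[m,m′],
  cross-group curvature zero.  The penalized quadratic subproblem is solved
  by the middle loop; the step Δ = β̂ − β̃ is then subjected to Armijo
  backtracking (contraction 0.5, sufficient decrease 1e−4, full step tried
  first) on the **true** penalized objective.  Because the accepted step near
  convergence is the full step to the subproblem solution, zeros produced by
  thresholding survive as exact zeros in the returned coefficients.

  Within-group curvature is kept exact because fused features of one channel
  are strongly correlated (wavelet energies vs band powers, r ≈ 0.9): a
  diagonal or per-feature curvature model overshoots so badly on such data
  that the line search only accepts steps of t ≈ 0.03–0.1 and the outer loop
  needs thousands of iterations; with exact group blocks full steps are
  accepted and a 12-point λ path on 59-channel data converges in seconds.
  The intercept block, being unpenalized, is minimized in closed form (one
  ridge-guarded linear solve per outer iteration).

* **Middle — blockwise coordinate descent.**  Groups are visited in a fixed
  cyclic order.  For each group the gradient at the group's zero point,
  g^(J) = q^(J) − H_JJ β̃^(J), feeds the standard sparse-group-lasso
  subgradient test: the group is exactly zero iff
  ‖T(g^(J), λα)‖₂ ≤ λ(1−α) w_J, where T is elementwise soft thresholding.
  Groups failing the test are minimized by the inner loop.  Since curvature
  carries no cross-group terms, the subproblems are independent and the sweep
  converges immediately; the loop structure is retained for generality.

* **Inner — modified cyclic coordinate descent.**  Each scalar coordinate of
  an active group minimizes ω(b) = c·b + h b²/2 + γ√(b² + r) + ξ|b| with
  c the coordinate's linear term, h ≥ 0 its curvature, r the squared norm of
  the group's other coefficients, γ = λ(1−α)w_J, ξ = λα.  Branches: h = 0
  returns 0; r = 0 or γ = 0 reduce to soft thresholding at ξ+γ (resp. ξ);
  |c| ≤ ξ returns 0; otherwise the stationarity condition
  c + ξs + hb + γb(b²+r)^{−1/2} = 0 with s = −sign(c), strictly increasing in
  b, has a unique root, found by a safeguarded Newton iteration inside an
  analytic bracket
  [−(|c|−ξ)/h, 0] (or its mirror image) — a bracketing root finder that is
  deterministic and never leaves the bracket.  Cyclic coordinate descent can
  stall exactly at zero when several moderate gradient entries jointly
  violate the zero test but none individually exceeds ξ+γ; in that case the
  group is pushed off zero along the soft-thresholded negative gradient
  Δ_i = −T(g_i, ξ) with a backtracking search for a step making the penalized
  quadratic negative, and coordinate descent resumes.

**Tolerances and limits** (`SolverSettings`): outer 1e−6 relative objective
change (the accepted convergence step must also be a full step), middle and
inner 1e−8 absolute coefficient change, maxima 200/200/1000 iterations.  An
optional `kkt_tol` keeps the outer loop running until the maximum violation
of the sparse-group-lasso subgradient conditions falls below it — used when
solutions are compared against high-precision references.  The curvature
diagonal is floored at 1e−12 so coordinates with vanishing observed
information can still move; this perturbs only the quadratic *model* (the
fixed point satisfies the exact optimality conditions regardless, because the
curvature multiplies β − β̃).  Non-finite objectives abort with a diagnostic;
hitting the iteration limit returns a flagged, never silent, result.

λ_max — the head of the regularization path — is computed from the same
subgradient test evaluated at the intercept-only solution: in closed form at
α ∈ {0, 1} and by bisection on the monotone test condition otherwise.  Path
fits are warm-started from the previous λ (β = 0 at the head).

## Cross-validated selection

`cross_validate` builds, per α in the grid, a geometric λ path from λ_max
down to `lambda_min_ratio`·λ_max (defaults: 5 α values {0, .25, .5, .75, 1},
50 λ, ratio 0.01, as a general-purpose default), assigns stratified folds
(default 10, seed 0), standardizes per training fold, fits the warm-started
path, and scores held-out accuracy and deviance.  The chosen (α, λ)
maximizes mean held-out accuracy, with ties broken toward larger λ (sparser)
and then larger α; the final model is refit on the full training set at the
chosen pair, warm-started down its path.  "Highest training accuracy" is
read as highest mean held-out-fold accuracy — the literal training accuracy
would always favor the smallest λ.

Two options matter when the goal is *support identification* rather than raw
accuracy:

* `selection_rule="1se"` picks the sparsest (largest-λ) cell whose mean score
  is within one standard error (computed across folds at the best cell) of
  the best — the usual rule when CV curves are flat near their optimum.
* `relaxed=True` scores each fold fit after refitting its support by plain
  (unpenalized) maximum-likelihood logistic regression, cached per distinct
  support along the path.  This removes the shrinkage bias that otherwise
  makes the exact-support λ score worse than denser ones.  Supports larger
  than half the training-fold size are scored as-is (an unpenalized refit
  would be unstable there).

Both default to off; the defaults reproduce the plain wrapped protocol.  In
the package's own recovery experiment (20 groups × 5 features, 3 active
groups at density 0.6 and magnitude 1.5, n = 400, α = 0.5, 12-point λ grid to
0.05·λ_max, 10 folds), relaxed scoring with the 1se rule recovers the exact
active-group set in 50/50 seeds with mean within-group nonzero-pattern F1 of
0.99, whereas the plain max-accuracy rule recovers it in ~40% — accuracy has
granularity 1/N per fold and its noise systematically favors denser fits.
Held-out *deviance* was evaluated as a selection score and rejected:
shrinkage makes sparse penalized fits under-confident, so deviance decreases
monotonically toward dense λ; it is still reported in the `cv_table`.

Selection is the exact nonzero pattern: a feature is selected iff any of its
M−1 coefficients is nonzero, a channel iff any feature of its block is.
Evaluation applies the stored standardization and predicts the argmax
probability class, ties broken toward the lower class index.

## Feature extraction

Per channel, concatenated in this fixed order (d = 70 under defaults):

* **Band power (5).**  PSD integrated over 2–4, 4–8, 8–12, 12–18, 18–30 Hz.
  Estimator: Welch with a 1 s Hann window and 50% overlap (appropriate for
  ~4 s EEG segments; a periodogram is selectable).  Bands are half-open
  [lo, hi) so adjacent bands do not double-count the shared edge bin.  Bands
  above Nyquist and signals shorter than the Welch window raise errors naming
  the constraint.
* **Time statistics (4).**  Mean, standard deviation (population, ddof 0),
  mean |first difference|, mean |second difference|.
* **AR coefficients (6).**  AR(6) via Burg's method (low-variance on short
  segments; Yule–Walker selectable), noise variance excluded, convention
  x_t = a₁x_{t−1} + … + e_t.  Constant signals are rejected as degenerate.
* **Wavelet features (55).**  Six-level Db4 DWT with symmetric signal
  extension.  Energies (sum of squared coefficients) of the 7 terminal sets
  {cA6, cD6..cD1}, plus 4 statistics for each of the 12 per-level vectors
  {cA1..cA6, cD1..cD6}: Shannon entropy −Σ q ln q with q_i = c_i²/Σc²
  (0·ln 0 := 0), log-energy entropy Σ ln(c_i² + ε) with ε = 1e−12 guarding
  zero coefficients, and mean and variance of the Teager–Kaiser operator
  ψ(c_n) = c_n² − c_{n−1}c_{n+1}.  The 7 + 48 = 55 layout is one of two
  readings of the sub-band feature set; the alternative that computes the 4
  statistics only on the 7 terminal vectors (7 + 28 = 35 dimensions) is
  selectable via `wavelet_mode="terminal"`.  Six levels on a 400-sample
  signal exceed the conservative max-level heuristic; boundary effects are
  handled by the extension mode and the signal must have at least 2⁶ samples.

Resampling (e.g. 1000 Hz → 100 Hz) is polyphase FIR with linear edge padding
(preserves DC levels at the boundaries); upsampling is out of scope.

## Synthetic data

`gen_eeg_trials` emulates the *shape and contrast* of a two-class
motor-imagery recording: 59 channels × 400 samples at 100 Hz by default, all
channels carrying independent 1/f (exponent 1) Gaussian noise of unit scale,
and three central channels adding a sinusoid with per-trial random frequency
(uniform in 8–12 Hz) and phase, scaled 2.0 vs 0.5 by class — so band power,
not phase, carries the class information, as in ERD/ERS.  It is a
statistical stand-in, not a physiological model: no volume conduction or
channel correlation, no artifacts, no nonstationarity.  Passing tests on it
demonstrates the selection machinery, not performance on real EEG.

`gen_design` is the solver-recovery testbed: standard-normal X, a known
group-sparse coefficient matrix (active groups, within-group density,
magnitude with random signs), labels sampled from the multinomial logistic
law at that matrix.  Both generators are bitwise-reproducible functions of
their spec and seed.

## Verification problem sizes

The test suite and `scripts/acceptance.py` use sizes chosen to exercise every
code path at desk scale: oracle comparisons on n = 50, 4 groups × 3 features,
M ∈ {2, 3}, all five α values; support recovery over 50 generator seeds at
the testbed's default conditions; the end-to-end pipeline on the default
59-channel simulation with 100 trials per class, a single-α (0.5) 12-point λ
path and 10 folds.  The independent references are a proximal-gradient
(FISTA) solver with the exact sparse-group-lasso proximal operator run to
~1e−14 relative objective change, scikit-learn's L1 logistic regression
(saga) at the α = 1 endpoint, and golden-section minimization in extended
precision for the inner scalar subproblem.

## Known limitations

* Groups must be contiguous column blocks; overlapping or scattered groups
  are not supported.
* The multinomial loss is the only loss; no class weights.
* CV selection assumes exchangeable trials; no session/block-aware folds.
* No screening rules: every group is tested each sweep, fine at p ≈ 60
  channels but wasteful at thousands of groups.
* The relaxed scoring refit falls back to penalized scores for supports
  larger than half the training fold, which re-introduces shrinkage bias in
  that (dense) regime.
* `read_trials`/`write_trials` target the package's own CSV/.mat layouts, not
  any competition-specific schema; EDF/BIDS readers are future work.
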