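# Methods

## Data model

Long-format subject-visit records: outcome at follow-up visits `1..J`
(missing allowed, always as explicit rows), baseline outcome and other
covariates (never missing), treatment arm, and per-subject ICE annotation:
`ice_visit` = the last visit before the intercurrent event (`0` if the ICE
precedes the first follow-up, unset if no ICE), and `ice_strategy` in
{MAR, CR, J2R, CIR}.  The outcome column is modelled as-is; for
change-from-baseline analyses the caller supplies change scores and keeps
the baseline measurement as a covariate (the simulator does exactly this).

Two masks drive the pipeline. `obs_mask` marks outcomes that exist; these
are *always* used by the imputation conditioning and the analysis.
`fit_mask` additionally removes observed post-ICE values from the
imputation-model fit: always for intervention-arm subjects with a
reference-based strategy (their post-ICE data contradict the
reference-based assumption being imposed), and for all other subjects with
an ICE when `drop_post_ice_control=True` (the default, so an ICE changes
the fitted data identically in both arms).  Setting it to `False` keeps
control/MAR post-ICE data in the fit, appropriate when control-arm
post-ICE outcomes are believed MAR.

## Imputation model (MMRM)

`Y_i = X_i β + ε_i`, `ε_i ~ N(0, Σ[obs_i, obs_i])` with one unstructured
J×J covariance shared by both arms.  Default mean model:
`arm * C(visit) + baseline + baseline:C(visit)`.  Estimation is REML by
default (ML available).  Separate per-arm covariances are not supported:
combining them into a reference-based marginal covariance requires a
different construction, and silently pooling would be wrong.

Numerics: Σ = LLᵀ with log-diagonal Cholesky parameterisation
(positive-definite by construction); β profiled out by GLS; subjects
grouped by missingness pattern so an objective evaluation is one small
Cholesky per pattern plus batched products.  Optimisation is Fisher
scoring with the analytic gradient and the expected information (closed
form via the rank-two structure of ∂Σ/∂L), with backtracking line search
and an L-BFGS fallback; convergence at gradient max-norm < 1e-5 or a
relative objective change < 1e-12, iteration cap 200.  Starting covariance:
pairwise-complete covariance of OLS residuals, eigenvalues clipped at 1e-6
of the largest.  Resampling re-fits warm-start at the full-data Σ̂ and use
a gradient tolerance of 1e-3; on the trial sizes exercised here this
changes leave-one-out estimates in the eighth decimal, far below the
resampling variability, while roughly halving the cost.  Fits that exhaust
the iteration budget raise `ConvergenceError`; the caller decides policy
(hard error in the jackknife, redraw in the bootstrap, drop-and-count in
the simulation harness).

## Marginal distributions and completion

With μ_i = X_i β̂ and μ_ref,i = X_ref,i β̂ (the design with arm recoded to
control, covariates unchanged):

- MAR, and every control-arm subject: μ̃ = μ_i;
- CR: μ̃ = μ_ref,i;
- J2R: μ̃_j = μ_i,j for j ≤ t̃, μ_ref,i,j for j > t̃;
- CIR: μ̃_j = μ_i,j for j ≤ t̃, μ_i,t̃ + (μ_ref,i,j − μ_ref,i,t̃) after.

Σ̃ = Σ̂ for every method (common-covariance case).  For `t̃ = 0` the CIR
anchor is the baseline itself; on the change-from-baseline scale both
trajectories are 0 there, so CIR (like J2R) reduces to CR — this is the
exact continuation of the formula, not an approximation.  Missing entries
are completed with the conditional-normal mean using a shared
Cholesky-based solve per missingness pattern; a condition-number guard
(1e12) rejects numerically singular observed blocks.  Random conditional
draws (mean plus Schur-complement noise) exist for validation only: the
package's estimator is the deterministic conditional mean, which the tests
verify equals the average of many random single imputations (ANCOVA is
linear in the outcome, so averaging imputations commutes with estimation).

## Analysis and inference

ANCOVA at the analysis visit (default: final visit): one row per subject,
completed outcome regressed on intercept, treatment indicator and the
analysis covariates (default: the baseline outcome).  θ̂ is the treatment
coefficient.

Jackknife (default): n full pipeline re-runs each leaving one subject out;
`se_jack = sqrt((n−1)/n · Σ(θ̂₋ᵢ − θ̄)²)`; Wald z = (θ̂ − θ₀)/se with
normal-approximation p-values and CIs.  Deterministic and invariant to
subject order and worker count (replicates are reduced by stable index).

Bootstrap: B subject-level resamples drawn *within* each arm, preserving
the allocation; the resampling unit is the subject.  B defaults to 999 (the
practical minimum; p-values near a decision boundary warrant ~10,000).
Each resample slot has its own seed stream, so a non-convergent resample is
replaced without disturbing the others; replacements are counted and more
than 10·B is an error.  Rubin's rules are deliberately absent: imputations
here are generated conditional on the REML estimate, for which Rubin's
variance combination does not apply, and for reference-based methods it
would over-state the repeated-sampling variance — the resampling SEs target
the frequentist variance directly.

## Simulator

Two arms of `n_per_arm` (default 100) subjects, visits at months
0, 2, …, 12; month 0 is baseline.  Outcome at time t (years):
`mean_arm(t) + b0 + b1·t + e`, with (b0, b1) bivariate normal
(SD 5 and 5/year, correlation 0.25) and residual SD 2.5 — marginal SD 5.59
at baseline rising to 8.29 at month 12.  Control mean: 50 + 10t.  Active
mean under the alternative: identical to control through month 4, slope
halved to 5/year afterwards; under the null the arms share the control
trajectory.

Study-drug discontinuation is drawn after every visit from a logistic
model in that visit's observed outcome, absorbing once it occurs.  The
per-draw probability at the reference outcome (50) compounds a *monthly*
base hazard of 1.5% (control) / 2.5% (active) over the 2-month
between-visit interval, i.e. base = 1 − (1 − p_month)²; the odds multiply
by 1.5 per 10 points above the reference, linearly on the log-odds scale
(no flooring below the reference).  This reading of the discontinuation
design was fixed by calibration against the scenario's documented
operating points — cumulative discontinuation ≈ 24% in control and the
treatment-policy effect −2.59 (active-arm mean change 7.41 vs 10.00) — all
of which the default scenario reproduces; a literal per-visit reading of
the same percentages yields roughly half the documented discontinuation.
The calibration could not reconcile every documented proportion
simultaneously: the active-arm rate under the alternative comes out near
34% where ~31% is documented, a known residual discrepancy surfaced by one
red calibration check in the test suite.

After discontinuation the active-arm mean follows the *control* slope from
the discontinuation visit onward (a CIR-type mechanism, so CIR is the
correctly-specified imputation method and its estimand equals the
treatment-policy truth); random effects and residuals are untouched;
control-arm trajectories are unaffected.  With probability 0.75 all
outcomes after the discontinuation visit are missing ("dropout");
otherwise post-ICE outcomes are retained (retrieved dropout).
Discontinuation at month 12 has no downstream visit: it counts toward
discontinuation proportions but sets no ICE fields.  The harness models
change from baseline, excludes observed post-ICE data from the imputation
model (both arms), includes it in the analysis, and assigns the method
under test as every discontinuer's strategy.

What the simulator does not emulate: intermittent missed visits,
per-arm covariance heterogeneity, baseline imbalance, rescue-medication
ICEs with their own strategy, or non-normal outcomes.  Passing tests
therefore demonstrate correctness of the pipeline under a well-specified
multivariate-normal world, not robustness to model misspecification.

## Problem sizes and tolerances in the checks

The replicate studies in `tests/` and `scripts/acceptance.py` run at desk
scale, chosen to finish in minutes on one core: 2,000 point-estimation
replicates (Monte-Carlo SE of an SD estimate ≈ 1.6%), 300–500 replicates
with a full 200-fit jackknife each, 10⁵–10⁶ subjects for generative
truths.  Tolerances follow from those sizes: means within 3–4 Monte-Carlo
SEs, SDs and mean SEs within 6%, the SE-vs-SD calibration ratio within 3%,
and the type-I error within 3 Monte-Carlo SEs (±2.9% at 500 replicates).

## Known limitations

- Inference validity relies on the analysis estimator being linear in the
  completed outcomes (general linear models); binary/count outcomes are out
  of scope.
- Missing baseline covariates are rejected, not imputed.
- One covariance for both arms; see above.
- The jackknife is O(n) model fits per analysis and the bootstrap O(B);
  both parallelise over replicates (`n_jobs`).
- Reference-based assumptions are strong and unverifiable from observed
  data; where post-ICE data exist, comparing them graphically against
  their conditional means is a worthwhile diagnostic.
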