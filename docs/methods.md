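# Methods

This note documents the models, conventions and numerical choices in
`fincee`, and what the synthetic-data conditions do and do not establish.

## CEE exposure model

A controlled exposure experiment (CEE) has three equal phases
(pre-exposure, exposure, post-exposure; default 30 min each).  During the
exposure phase an MFAS or PRN signal is projected once every 25 s, with
the source level ramped in 3 dB increments from 160 dB RMS re 1 µPa·m to
a maximum of 210 dB (MFAS) or 206 dB (PRN).  Because 210 − 160 is not a
multiple of 3, the last increment is partial (…205, 208, 210); control
CEEs contain no transmissions.  The protocol does not pin down the ping
duration or the time of the first ping within the phase; both are
configurable, defaulting to 1.0 s and t = 0.

Received levels use spherical spreading only, RL = SL − k·log10(range)
with k = 20 by default (configurable); absorption is negligible at the
3.5–4 kHz band over the ~1 km ranges involved, and the study measured RL
on-tag rather than prescribing a propagation model, so a simple monotone
model suffices for synthesis.  A ping's sound exposure level is
SEL = RL + 10·log10(duration); cumulative SEL is the running energy sum
10·log10 Σ 10^(SEL/10), in dB re 1 µPa²·s.  Ranges below 1 m are outside
the model's domain and rejected.

Per-dive exposure covariates (max / mean / min RL over the pings whose
transmission time falls inside the dive, cSEL at dive end, binary
exposure flag, CEE phase of the dive start) are exactly 0 when no ping
overlaps the dive; the mean is an arithmetic mean of dB values (an
energy mean is not used, matching the "average received level" sense of
a level average).

## Dive segmentation and metrics

A dive is a maximal run of depth strictly greater than 3 m with at least
two samples; a sample at exactly 3 m is surface (the boundary convention
is ours — the threshold itself is standard).  The bottom phase is the
set of samples deeper than 85% of the dive's maximum depth (a common
biologging convention, configurable); descent runs from the dive start
to the first bottom sample, ascent from the last bottom sample to the
dive end, so descent + bottom + ascent can never exceed the dive time.
Angular summaries are circular means and wrapped first-to-last
differences over descent and ascent; the turning rate is the mean
absolute wrapped heading increment per second; the HMM's turning angle
is the wrapped net heading change over the dive, in (−π, π].  Lunges and
breaths are consumed as annotated event streams (counts of events inside
the dive, and in the following surface interval, respectively);
detection from accelerometry is out of scope.

## Context hidden Markov model

**Observation model.**  Five streams per dive, conditionally independent
given the state: gamma (dive time), gamma (max depth), Poisson (lunges),
gamma (speed over ground), von Mises (turning angle).  Gamma streams
require strictly positive data; values ≤ 0 are floored at 1e−6 with a
logged warning.  κ = 0 recovers the circular uniform.

**Hidden process.**  Each whale belongs to one of K latent contexts
(state-switching regimes) drawn with probabilities π; contexts carry
their own transition intercepts and initial state distributions, while
emission parameters are shared across contexts (as implied by
warm-starting emissions from a baseline model).  Off-diagonal transition
logits are η_ij + Σ_c β_ij,c·x_c with the diagonal as reference; the
covariate at dive t governs the transition *into* dive t.  The phase
covariate enters as two dummies (reference = before).  Continuous RL
covariates are standardized by the mean and standard deviation over
exposed dives before entering the logits (raw ~100–160 dB values
overflow the link); coefficients are reported on the working scale with
the standardization stored alongside.

**Likelihood and fitting.**  The dataset log likelihood is
Σ_w log Σ_k π_k L_wk with L_wk the exact forward-recursion likelihood of
whale w under context k (scaled recursion; log-sum-exp over contexts).
Fitting maximizes over unconstrained working parameters (logs for
positive parameters, multinomial logits with a reference category for
probability vectors, unconstrained von Mises mean) using L-BFGS-B with
the *exact analytic score*: by the Fisher identity the score equals the
expected complete-data score under the forward–backward posteriors, so
one gradient costs a constant multiple of one likelihood evaluation.
Convergence uses the optimizer's relative-change criterion (ftol 1e−11,
gtol 1e−6, 500-iteration cap).  Multi-start: emission start values come
from a depth-quantile moment split of the data (jittered on restarts, or
warm-started from a baseline fit's emissions), transition logits from
N(−1.5, 0.7).  The `fit_hmm` default of 50 starts is a desk-scale
default; the recovery and selection studies in the test suite use a
single moment-initialized start, which the pilot fits showed reaches the
same optimum on these well-separated synthetic conditions.  A
jitter-restart utility re-optimizes from perturbed non-emission
parameters to guard against nearby local maxima.

**Identification and labels.**  After fitting, states are relabelled by
descending mean maximum depth (state 1 = deepest) and contexts by
descending π, making labels reproducible.  Biological labels should be
read off the emission means, not the indices: in the three-state
repertoire used for synthesis (deep feeding 180 m / many lunges,
non-feeding 15 m / no lunges, shallow feeding 50 m), the non-feeding
state is the *shallowest* and thus sorts last.

**Selection and inference.**  AIC = −2·loglik + 2·p ranks candidate
structures (number of contexts 1–6, covariate choice, shared vs
per-context effects), ties broken toward fewer parameters.  The
parameter count is 9N emissions + K·N(N−1) intercepts + K·(N−1)
initials + (K−1) mixing + d·N(N−1)·(K if per-context else 1) covariate
coefficients.  Wald intervals use the observed information obtained by
central differences of the analytic score at the optimum (step 1e−5
scaled); a singular information matrix falls back to the pseudo-inverse
with a non-identifiability warning.  Local decoding mixes per-context
forward–backward posteriors with the context posteriors
∝ π_k·L_wk; the most probable state takes the argmax with ties to the
lower index.

## PCA and additive response models

Per metric category the correlation matrix (standardized metrics —
units are incommensurate) is eigendecomposed; components are ordered by
variance and signs fixed so each column's largest-magnitude loading is
positive.  Axes explaining strictly more than 10% of variance are
retained (component 1 always, logged if below threshold).

Each retained axis is regressed on parametric treatment terms plus
penalized B-spline smooths of the received-level covariates (two
variants: the all-dive phase model with s(maxRL), s(cSEL), s(avgRL);
and the exposure-only model with s(maxRL), s(minRL), s(cSEL) — the two
smooth sets differ deliberately, mirroring the two published formulas).
Three numerical choices matter here and are deliberate:

* **Rank-scale splines.**  RL covariates have a point mass at 0
  (unexposed dives) and a gap up to the lowest exposed level; with
  equally spaced knots, interior basis functions have no supporting data
  and the penalized fit is singular.  Splines are therefore built on the
  empirical-rank (quantile) scale — the usual quantile knot placement,
  a monotone reparameterization that leaves term tests and monotonicity
  statements unchanged — and partial effects are mapped back to dB.
* **Ridge whale intercept.**  Whale identity enters as an all-level
  dummy block with an identity penalty (a random intercept in penalized
  form) whose shrinkage weight is chosen by GCV along with the spline
  penalties.  Fixed whale dummies would be exactly collinear with
  whale-level terms (treatment type, behavioural state) and make them
  untestable.
* **Term tests.**  Penalty weights come from a deterministic
  coordinate-descent GCV grid (10⁻¹…10⁸, two sweeps).  Term-level
  inference uses drop-one-term approximate F tests (refit without the
  term; F from the residual-sum-of-squares increase on the term's
  effective degrees of freedom), which stay defined under the strong
  concurvity among the RL covariates, plus a joint F test of the whole
  RL smooth block (`rl_joint`).  Under concurvity the single-term
  deletions share a common RL effect among the remaining smooths and
  understate it; the block test answers the block-level question
  (does received level influence the response at all?).

Adjusted fit quality is 1 − (1 − R²)(n − 1)/(n − edf − 1) with edf the
total effective degrees of freedom.

## Severity survival analysis

Each exposure CEE contributes one observation per severity band
(low = expert scores 1–3, moderate = 4–6; no high-band responses were
observed, so that band is not modelled): an event at the cSEL printed at
the change point when the band was reached, otherwise right-censoring at
the CEE's maximum printed cSEL.  Conventions, all switchable:

* a moderate response implies a change of at least low severity, so it
  also fires the low stratum at the same dose;
* the one changed-but-unscored CEE described as a moderate change is
  coded as a moderate-band event at its printed cSEL;
* a parenthetical secondary score in the same band does not add a row
  (only the first occurrence per stratum enters);
* for the one low-only responder, the moderate stratum is censored at
  the printed change-point cSEL — the largest dose at which the absence
  of a moderate response is documented (the exposure-maximum cSEL for
  that CEE is not published);
* controls are excluded from hazard fitting: the signal-type covariate
  is undefined for them, and no control elicited any response.

Cumulative SEL plays the role of time in stratified Cox models with
coefficients shared across strata (marginal, WLW-style; stratum
interactions available).  Coefficients are estimated by Newton–Raphson
on the stratified Breslow partial likelihood (Efron tie handling is
available via lifelines); model-based SEs come from the inverse
partial-likelihood information and correlation-robust SEs from a grouped
(leave-one-whale-out) jackknife, variance (g−1)/g·Σ(θ̂_(i)−θ̄)².  The
null model's AIC is −2× the partial log likelihood at β = 0 with zero
parameters.  Proportional hazards are tested with the
Grambsch–Therneau scaled-Schoenfeld score test against the rank of the
event dose, using the full variance including the β-estimation
cross-term.  Dose–response curves are 1 − exp(−H₀(cSEL)·e^{x'β}) from
the Breslow baseline cumulative hazard per stratum; below the observed
dose range the cumulative hazard is exactly 0, above it the curve is
flat (evaluation clamps to the largest dose, flagged).  Pointwise
intervals use the jackknife variance of log H.

The Mahalanobis change metric averages the behaviour metrics into
consecutive windows (default 300 s), estimates the baseline mean and
covariance from pre-exposure windows, and reports
√((x−μ)ᵀS⁻¹(x−μ)) per window; a ridge of `regularization·tr(S)/p` is
added when S is near-singular and forced when there are fewer baseline
windows than metrics.

## Synthetic-data conditions

The generator defines the conditions under which the pipeline is
exercised; they were fixed once, at the study's scale, before the test
assertions were frozen:

* **HMM recovery**: 30 whales × 150 dives (20 × 150 for the two-state
  check), three states with well-separated emission means (dive times
  420/240/120 s, depths 180/50/15 m, lunge rates 5/2/0.1), two contexts
  with distinct switching intensity (all off-diagonal intercepts −2 vs
  −1), equal mixing; the shared exposure coefficient (true value 1.0)
  acts on the non-feeding → deep-feeding logit with the covariate 0
  outside exposure and 0.5–1.5 during it.  Coverage of the 95% Wald
  interval is assessed over 50 replicates, AIC selection of K over 20.
* **Group-level models**: 21 whales (the study's sample size) × 100
  dives cycling through MFAS/PRN/CONTROL; the protocol ping schedule
  propagated over a lognormal range walk around 1 km (σ = 0.05 per
  ping); response = 0.06·max(maxRL − 110, 0) + whale effects (sd 0.4)
  + unit noise, giving fitted adjusted R² ≈ 0.42–0.45 — the magnitude
  reported for the real dive-metric axis (≈ 0.49).  Null calibration
  uses the same design with a zero effect.
* **Severity survival**: the real published severity table is itself the
  input (packaged fixture); simulation is used only for estimator-bias
  checks (unit-exponential dose baseline, log hazard ratio 0.8,
  censoring at dose 2, 40 replicates of 60 CEEs).

What passing these tests shows — and does not.  The synthetic dives are
serially generated from the very model family being fitted, with
well-separated states, no tag-record gaps, no measurement error in RL,
and whales exchangeable within context.  Real tag records violate all
of these to some degree (state overlap, autocorrelated residuals within
states, dive-cycle constraints, on-tag RL measurement noise).  The
suite therefore establishes correctness of the estimators and the
qualitative detectability of the published response patterns under
faithful conditions, not field-data effect sizes.  Real-data quantities
that depend on the authors' raw tag records (PCA loadings, the K = 5
context selection, the 130 dB mean MaxRL, variance-explained
percentages) are out of scope by design.

## Reproducibility

Every stochastic operation takes an explicit seed; the pipeline derives
per-stage sub-seeds from the master seed by hashing, and an identical
configuration reproduces an identical run report (hash-checked in the
tests).  Problem sizes in the test suite (replicate counts above, single
moment-initialized optimizer starts for the replicate studies) are the
package's desk-scale choices; all thresholds are stated in the tests
themselves.
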