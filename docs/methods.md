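# Methods

This note records the models, numerical choices and study designs behind
`jointmsm`, and what the synthetic-data checks do and do not establish.

## Panel likelihood for multistate processes

Both model families are time-homogeneous continuous-time Markov chains
observed at clinic visits only.  The contribution of one process is the
product over consecutive visit pairs of `[exp(Q·Δt)]_{s_j, s_{j+1}}`,
conditioning on the state at the first visit.  Covariates are piecewise
constant: the interval `(t_j, t_{j+1}]` uses the values recorded at visit
`j` (covariates change "state" immediately after a visit).  There is no
exact-event-time term anywhere: damage is interval-censored like every other
transition.

Two implementations exist side by side.  `ctmc.path_probability` builds the
generator per interval and uses scipy's scaling-and-squaring matrix
exponential — fully general, used as the reference.  The fitting engines use
exact closed forms instead: the four-state progressive chain factorizes into
exponential stages (with an `expm1`-based stable evaluation of the
near-degenerate difference quotients), and the three-state chain's transient
2×2 block has real eigenvalues `T/2 ± h`, giving
`exp(Mt) = e1+e2 cosh/sinh` combinations in which every exponential lies in
(0, 1], so nothing can overflow.  Engine and reference agree to ~1e−11 per
entry (tested), and the engines accumulate everything in log space.

## Four-state paired-damage model with gamma frailty

* State space per joint location: 1 neither damaged, 2 right only, 3 left
  only, 4 both; transitions 1→2, 1→3, 2→4, 3→4.  The direct 1→4 intensity is
  structurally zero (composability of the left/right subprocesses), yet an
  observed 1→4 panel move has positive probability through the two-step
  paths; in damaged-joint counts it counts two newly damaged joints.
* Frailty: `U_k ~ gamma(1/θ, 1/θ)` (unit mean, variance θ), multiplying all
  transition intensities of a patient's 14 location processes.  The marginal
  patient likelihood is `∫ ∏_l P(path_l | u) f(u; θ) du`.
* Quadrature: generalized Gauss–Laguerre with the gamma weight absorbed by
  `u = θx` (weight `x^{1/θ−1}e^{−x}`), weights normalized to sum to one so
  the Γ(1/θ) factor never materializes.  For θ ≲ 6·10⁻³ the raw weights
  overflow double precision and the rule falls back to Gauss–Legendre on the
  gamma CDF (probability integral transform), which is uniformly stable;
  this covers the θ→0 continuity limit.  Default 30 nodes.  When the data
  carry many events per patient the frailty posterior concentrates away from
  the prior and more nodes are needed; the fit therefore re-evaluates the
  optimum with doubled nodes and warns if the log-likelihood moves by more
  than 1e−6 (the recovery studies below use 60 nodes for this reason).  An
  adaptive `scipy.integrate.quad` mode exists on
  `marginal_patient_loglik` for small cross-checks.
* Optimization: BFGS on the unconstrained vector (log baselines, offsets γ,
  coefficients, log θ), gradient by central differences (step
  1e−6·(1+|x|)), gradient tolerance 1e−5.  Default initial values: log crude
  transition rates (events over person-time in the origin state, half-event
  correction), offsets at log crude-rate ratios, coefficients 0, log θ = 0.
* Inference: Hessian of the negative log-likelihood by central finite
  differences (step 1e−5·(1+|x|)); naive covariance is its inverse.  θ's
  interval is formed on the log scale and exponentiated, as are baseline
  intensities; intensity-ratio CIs are the exponentials of
  coefficient-interval endpoints.  Boundary solutions (an intensity or θ
  collapsing to zero) are flagged on the result, never masked.
* Missing activity is handled by patient-level complete-case filtering when
  (and only when) the covariate design uses activity; values are never
  imputed.

The first-order behaviour of the marginal likelihood near θ = 0 is worth
noting: it differs from the frailty-free likelihood by a term linear in θ
whose coefficient grows with the cohort's event load, so "θ ≈ 0 equals no
frailty" holds to 1e−4 only for θ small relative to that curvature (the
tests use θ = 1e−8 on an eventful cohort; the identity is exact in the
limit and the linear scaling has been verified down to θ = 1e−10).

## Three-state activity–damage model with sandwich variance

* State space per joint: 1 no damage & inactive, 2 no damage & active,
  3 damaged (absorbing); transitions 1↔2, 1→3, 2→3.  Follow-up of a joint
  stops at the first visit where damage is observed.
* Working independence: the total log-likelihood is the sum over all 28
  joints of all patients.  Per-patient score vectors are computed by central
  differences of the per-patient log-likelihood contributions; the robust
  covariance is `A⁻¹BA⁻¹` with `A` the observed information and
  `B = Σ_k s_k s_kᵀ`, evaluated by symmetric solves (no explicit inverse);
  ill-conditioning triggers a warning carrying the condition number.
* `λ0_23 = λ0_13·e^γ` ties the two damage intensities; Wald tests
  (`wald_test`) use either covariance against χ² with rank-of-contrast
  degrees of freedom.
* Time epochs: piecewise-constant epoch indicators on selected transitions.
  By default each inter-visit interval is assigned the epoch of its left
  endpoint — consistent with covariate carry-forward, and exactly nested in
  the homogeneous model (zero epoch effects reproduce its log-likelihood to
  1e−10).  A configuration switch (`exact_epoch_split`) instead splits each
  interval at the epoch boundaries and chains the per-segment matrices; the
  default is the approximation, the switch is for sensitivity analysis.
  The "ever active" covariate is the indicator that activity was recorded at
  the current or any earlier visit for that joint; the opposite-damage
  covariate is the contralateral joint's damage state at the same visit;
  both are carried forward like all covariates.  The joint-type factor has
  five levels (finger MCP/PIP/DIP, thumb MCP, thumb PIP) with a configurable
  reference level (default: finger metacarpophalangeal).

## Synthetic cohort generator

The simulator emulates the structure of a large psoriatic-arthritis clinic
cohort; its defaults are the cohort's published structure, and quantities
the literature does not pin down are free configuration:

* 517 patients, all 28 hand joints undamaged at entry.
* Visit schedule: per-patient i.i.d. lognormal gaps with median 0.525 years
  and σ = 1.04 — chosen so the mean gap is ≈ 10.8 months with the heavy
  right tail the cohort shows (SD ≈ 15 months); visit counts
  `clip(1 + Geometric(p = 0.109), 2, 47)`, median 7.
* Damage truth: baselines λ0_12 = 0.0028, λ0_13 = 0.0027 per year with
  contralateral offsets γ24 = 1.82, γ34 = 1.39 and frailty variance
  θ = 3.81 (the fitted values of the models this package implements);
  activity effects default to zero.
* Activity: a per-joint reversible chain none ↔ tender-only ↔ effused with
  onset 0.09, resolution 1.5, escalation 0.6, de-escalation 1.2 per year.
  The real joint-activity dynamics are unpublished; these values give brief
  recurrent episodes and are explicitly free parameters.
* Frailty multiplies the damage hazards (as in the fitted model).  A switch
  (`frailty_on_activity`) extends it to the activity intensities, making u a
  patient-level time change; intensity ratios are invariant to u in that
  case.
* Two covariate-generation modes: `model-faithful` (damage hazards respond
  to activity as sampled at the most recent visit — the fitted carry-forward
  models are then correctly specified) and `continuous-hazard` (hazards see
  the latent activity state; with tender→effused escalation switched off and
  equal tender/effusion effects the per-joint three-state process is then
  exactly Markov, which the three-state recovery studies rely on).
* Simulation is event-driven with interval-wise competing exponentials,
  exact within each constant-hazard segment (hazards change only at
  covariate change points and at contralateral damage events).  All event
  times are continuous draws, so no two subprocess events coincide.
* The generator emits the coarsened panel *and* the full latent history
  (frailty draws, activity trajectories, exact damage times) so fitted
  models and tables can be checked against the generating truth; both the
  four-state (paired) and three-state (per-joint) views derive from the one
  history.  Identical configuration and seed reproduce the dataset
  byte-for-byte.

What passing these checks shows — and what it does not: the simulator
produces correctly specified data for both fitted families, so the recovery
and calibration results validate the estimation machinery, not the clinical
adequacy of the models.  Real cohorts add features the generator omits by
design: informative visit timing, treatment effects, patient-level
covariates (e.g. erythrocyte sedimentation rate), misclassification of
damage, and activity dynamics that need not be Markov.

## Study designs used by the test suite

Problem sizes are scaled-down versions of the cohort design, chosen for
event yield (rare-event rates at desk scale would leave parameters barely
identified):

* **Four-state recovery** (nominal-coverage check): 50 replicate cohorts of
  200 patients, 5 annual visits, shared baselines λ = 0.05/year,
  γ24 = γ34 = 1, θ = 1; fits with 60 quadrature nodes.  Each generating
  parameter must lie in its 95% CI in at least 90% of replicates.
* **Sandwich calibration**: 200 replicate cohorts of 150 patients, 6
  half-yearly visits, activity onset 0.8/resolution 1.5, inactive-state
  damage rate 0.01, γ = 2, patient frailty θ = 2 on the damage hazards.
  Robust and naive coverages of γ and of the baseline damage intensity are
  compared.  One caveat this study surfaced deserves record: a *shared
  multiplicative* frailty largely cancels in the within-patient contrast
  γ = log(λ23/λ13) — both of a patient's damage rates scale with the same
  u — so naive intervals for γ are only mildly anticonservative under this
  mechanism (the clustering hits the baseline *levels*, not the ratio),
  while heavy event loads instead attenuate the population-averaged γ
  through dynamic frailty selection.  The robust intervals stay close to
  nominal throughout; expecting naive γ-coverage to collapse under a pure
  shared frailty is not supported by this generator.
* **Wald null calibration**: 200 replicates of 40-patient cohorts with
  γ = 0 truth; the robust Wald test of γ rejects at close to the nominal 5%.
* **Oracles**: matrix exponentials against a Kolmogorov-forward ODE
  integration (1e−8), panel path probabilities against 10⁵ direct
  competing-exponential simulations (3 binomial SEs), the frailty marginal
  against the closed form `(1+θλt)^{−1/θ}` (1e−8) and against 10⁶-draw
  Monte-Carlo integration (3 MC SEs).

## Known limitations

* Baseline intensities are time-homogeneous within epochs; no splines or
  semi-Markov sojourn effects.
* The frailty is gamma and shared across a patient's processes; no discrete
  mixtures, no frailty in the three-state model (robust variance is used
  there instead).
* The engines support the covariate designs the builders emit; arbitrary
  user covariates go through the general (slower) `ctmc` route.
* Per-location baselines are supported but expensive to estimate well at
  desk scale; the shipped studies use shared baselines.
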