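# Methods

## The problem

`riskvalid` validates models that assign each woman an absolute h-year
risk of breast cancer (probability of diagnosis within h years of risk
assessment), against prospective cohort follow-up in which three things
can happen before the horizon: the cancer is diagnosed, the subject dies
of another cause, or observation ends (censoring).  Validation has two
parts: *calibration* (do assigned risks match observed event
probabilities in groups?) and *discrimination* (do future cases get
higher assigned risks than noncases?).

## Observed absolute risk under competing mortality

The "observed" risk of a group is

    pi = ∫₀ʰ I_B(t) · exp(−∫₀ᵗ (I_B(u) + I_D(u)) du) dt ,

where I_B and I_D are the cause-specific hazards of breast cancer and of
death from other causes.  Death is a competing risk, not censoring: a
woman who dies cannot later be diagnosed, and pi is the probability of
diagnosis *before* death and within h years.  When the death rate is
negligible this reduces to 1 − exp(−∫I_B) ≈ ∫I_B.

Both hazards are estimated by Nelson–Aalen increments on the grid of
distinct event times t_j ≤ h:

    dΛ̂_B(t_j) = (BC events at t_j) / (at risk just before t_j),

and likewise dΛ̂_D.  The integral is realized as the Aalen–Johansen
plug-in

    π̂ = Σ_{t_j ≤ h} Ŝ(t_j⁻) · dΛ̂_B(t_j),   Ŝ(t) = Π_{t_j ≤ t} (1 − dΛ̂_B − dΛ̂_D),

which is exact for step-function hazards and is the standard
competing-risks cumulative-incidence estimator.  Without censoring before
h and without deaths it collapses to (events within h)/n.

Numerical conventions:

- Subjects censored at exactly t remain at risk at t; a subject censored
  at exactly the horizon counts as fully observed and event-free.
- A BC event and a death tied at the same time share the same pre-time
  risk set (within-time order BC-then-death; π̂ is unaffected because
  only the shared denominator and the joint survival update enter).
- Follow-up beyond the horizon is truncated inside the estimators; raw
  observed times are preserved at I/O.  Subjects whose cancer occurred
  after the horizon are therefore event-free through the horizon — the
  natural reading for an h-year risk, flagged here because registry data
  could be coded either way.

Confidence intervals are nonparametric percentile bootstrap over
subjects (default 2,000 resamples, seeded).  A closed-form competing-risk
variance would require choosing among several asymptotic approximations;
the bootstrap avoids that and extends unchanged to ratios and subgroup
contrasts.  The interval is clipped to contain the point estimate (this
matters only in degenerate lattice cases such as zero events).  Family
correlation between relatives in registry cohorts is deliberately
ignored, as is conventional when the proportion of related pairs is
small.

## Calibration

Subjects are grouped into near-equal quantile groups of a model's
assigned risk (quartiles by default; sizes differ by at most one, larger
groups first, ties broken by a stable (risk, subject_id) sort so
partitions are reproducible).  For each group the mean assigned risk r̄_g
is compared with the observed π̂_g — the competing-risks estimate above,
*not* a raw event fraction, so the comparison remains valid under
censoring.  The goodness-of-fit statistic is

    HL = Σ_g n_g (π̂_g − r̄_g)² / (r̄_g (1 − r̄_g)) ,

referred to χ² with df = number of groups.  The df-equals-groups
convention (not groups − 2) is the external-validation one: the models
were fit elsewhere, so no parameter-count correction applies.

Covariate subgroup tables report n, observed risk with bootstrap CI,
each model's mean assigned risk, and the observed/assigned ratio (>1
means under-prediction).  A subgroup is flagged as significantly
miscalibrated when its mean assigned risk falls outside the observed
risk's 95% CI — a pragmatic criterion chosen because the bootstrap CI is
already computed and makes no additional variance assumptions.

## Discrimination

Cases are subjects with breast cancer within the horizon; noncases are
subjects observed event-free through the horizon.  Subjects censored
before the horizon are excluded, which is valid when censoring is
unrelated to risk.  Competing deaths within the horizon count as
noncases by default — they were observed not to develop breast cancer
within h years — with a switch (`death_as_noncase=False`) to exclude
them instead, since registry analyses differ on this point.

A case's risk percentile (CRP) is the mid-rank percentile of her
assigned risk among noncase risks:

    CRP_i = (#{noncases < r_i} + ½·#{noncases = r_i}) / #noncases .

With mid-ranks, mean(CRP) equals the Mann–Whitney AUC exactly (the
probability a random case outranks a random noncase, ties ½), which in
turn equals the trapezoidal area under the empirical ROC.  The ROC is
computed at every distinct threshold with strict-inequality
classification; sensitivity at a target specificity is the fraction of
cases with CRP strictly above the target.  AUC CIs are stratified
bootstrap (cases and noncases resampled separately, seeded).

Two models are compared case-by-case through their paired CRPs with the
Wilcoxon signed-rank test: zero differences dropped, mid-ranks for tied
magnitudes, exact null distribution (rank convolution, equivalent to
enumerating all 2ⁿ sign assignments) for ≤25 nonzero pairs, and a normal
approximation with continuity and tie corrections beyond.  The exact
path is implemented here because standard library routines decline
exact p-values in the presence of ties, which CRPs produce routinely.
Counts of cases above/below the CRP diagonal accompany the test.

## Synthetic cohorts

The validation cohorts this pipeline targets (high-risk breast-cancer
family registries) are not public, so the test bed is a seeded
simulator with known ground truth:

1. Each subject's true h-year risk π_i is drawn from a configurable
   family — by default a log-normal on the risk scale, truncated to
   (0, 0.99) by resampling, giving the long right tail characteristic of
   risk-continuum cohorts.
2. π_i is converted to a constant cancer hazard λ_B,i by inverting
   π = λ_B/(λ_B+λ_D)·(1 − e^{−(λ_B+λ_D)h}) (analytic when λ_D = 0,
   Brent root-finding otherwise, forward error ≤ 1e−10).
3. Cancer and death times are independent exponentials; censoring is an
   administrative cut-off plus exponential dropout, independent of risk
   (the assumption under which the estimators are valid).  The earliest
   of the three is recorded with its type.
4. Model assigners produce clip(factor · π_i · exp(ε − s²/2), 0, 1] with
   ε ~ N(0, s²).  The noise is mean-one on the risk scale, so
   `calibration_factor` alone sets the assigned/true ratio (0.5 =
   two-fold under-prediction) while `noise_sd` degrades discrimination.

All draws come from one seeded generator in a fixed documented order, so
a seed determines the cohort byte-for-byte.  Two categorical covariates
are emitted for subgroup mechanics: `risk_group` (median split of true
risk) and `stratum` (an independent fair coin).

**Between-model correlation.**  Both assigners share the log-true-risk
term and add independent noises, so their risk-scale Pearson correlation
is (e^{τ²}−1)/√((e^{τ²+s₁²}−1)(e^{τ²+s₂²}−1)) with τ² the log-risk
variance.  Given a `target_risk_correlation`, the noise of models with
`noise_sd=None` is solved in closed form; explicitly-set noises are
kept.  The asymmetric allocation matters: weak correlation requires a
lot of noise, and noise placed on a factor-1 model destroys its
*quantile* calibration (a Berkson-type effect — the top assigned
quartile regresses to the mean).  The preset therefore puts the
correlation-driving noise on the under-predicting assigner and only mild
noise (0.15) on the near-calibrated one, reproducing the empirical
pattern of one poorly and one approximately calibrated model.  Clipping
at 1 trims the heaviest right-tail draws and lifts the realized
correlation slightly (~+0.015 at preset settings); tests use a tolerance
band that covers this.

**Registry-like preset** (`bcfr_like_config`): n = 1,857, horizon 10
years, true risks LogNormal(μ=−2.953, σ=0.6) on the risk scale (mean
≈ 6.3%), death hazard 0.0044/yr, administrative censoring at 14.5 years
plus dropout 0.076/yr, assigner factors 0.51 and 0.88, correlation
target 0.34.  These values were set once so that, in expectation over
seeds, a cohort shows ≈83 cancers and ≈55 competing deaths within 10
years, roughly half the cohort censored before 10 years, mean follow-up
≈8.2 years, and mean assigned risks ≈3.2% and ≈5.5% — the structure of
the motivating registry cohort.  Monte-Carlo s.d. of the event counts is
≈8.

What the simulator does **not** emulate: age-varying baseline hazards,
covariate-dependent hazards beyond what flows through true risk,
family/pedigree correlation, and real risk-model feature structure (the
assigners are stochastic perturbations of truth, not fitted models).
Passing tests therefore demonstrate the correctness and operating
characteristics of the *estimators and tests* under the stated
data-generating assumptions, not the clinical performance of any actual
risk model.

## Operating-characteristic studies (test problem sizes)

The statistical acceptance tests run at sizes chosen to make their
Monte-Carlo error small relative to the asserted bands:

- Constant-hazard parameter recovery: one cohort of n = 50,000
  (λ_B = 0.005, λ_D = 0.003, dropout 0.05, admin 12y); the replication
  s.d. of π̂ (1.1e−3, measured over 30 independent seeds of the same
  design) defines the 3-SE band.
- HL size/power: 1,000 replicates of n = 2,000 with a perfectly
  calibrated and a 0.5-factor assigner (no censoring or deaths, so the
  observed risk is a clean binomial proportion and the nominal χ²
  reference applies).  Expected size is slightly below 5% because
  within-quartile risk spread deflates the statistic by a factor
  ≈ 1 − s²_π/(p̄q̄).
- Bootstrap coverage: 1,000 replicates of an n = 400 group at true
  π = 0.15 with competing mortality and moderate dropout — a top-risk-
  quartile-like design.  Percentile-bootstrap coverage of a cumulative
  incidence approaches the nominal 95% as the expected event count
  grows; with only ~25 events per group it sits nearer 93%, so the
  nominal-coverage check is run where its premise holds (~55 events) and
  the low-event behavior is recorded here as a limitation.

## Known limitations

- The percentile bootstrap undercovers slightly for groups with few
  events (see above); BCa or variance-stabilized intervals could improve
  this and would slot into `absolute_risk_ci` without API change.
- Hazards are estimated without smoothing; π̂ is consistent but the
  increment lists themselves are noisy in small groups.
- The HL reference distribution treats observed risks as independent
  binomial-like proportions; under heavy censoring the effective
  information per subject is lower and the test is mildly conservative.
- The constant-hazard inversion makes each subject's risk exact over the
  full horizon but flat in time; calendar-time or age effects are out of
  scope.
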