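# Methods

This note documents the statistical model, the synthetic data-generating
process, the numerical choices, and the known limitations of `nursevam`.

## Outcome construction and cohort assembly

An encounter is one patient × one 12-hour shift (day 07:00–19:00, night
19:00–07:00). Encounter *i* is CAABU-free (Y_i = 1) unless a *confirmed*
CAABU culture for that patient is time-stamped in the attribution window
(shift_end + 24 h, shift_end + 48 h] — lower bound exclusive, upper bound
inclusive, reading the CDC rule's "24 hour minimum gap" strictly and its
"48 hour maximum limit" inclusively. Both endpoints are parameters of
`label_outcomes`. A single event therefore flags the triggering shift and,
about half the time, the preceding shift (whose window extends 48 h).
Unconfirmed cultures are ignored everywhere.

Exclusions, applied in order and each counted in the exclusion log:
patients with a confirmed CAABU/CAUTI report at or before ICU admission are
removed entirely; encounters ending at or after a patient's first confirmed
report are removed (first-event censoring — the retention rule that keeps
only pre-report care); float nurses are removed from encounter nurse sets
(the encounter survives if another nurse remains); nurses linked to fewer
than 45 encounters (the power-analysis minimum, configurable) leave the
modeled roster, and their encounters survive only when a roster nurse
co-attended. Encounters whose attribution window extends past ICU discharge
are retained with Y = 1 unless an event is recorded; no discharge censoring
is applied. The split into estimation and validation halves is by discharge
*date* (strictly before the cutoff → estimation; on/after → validation),
with the roster threshold re-applied within each half.

## The value-added model

logit P(Y_i = 1) = α + Σ_j β_j N_ij + x_iᵀ γ, with a multi-hot nurse block
(all attending nurses' indicators set to 1) and the covariates listed in the
README. Reference categories follow the study design (female, medical
admission, no prior admission, MDC "DDs of Nervous System", uninsured,
Sunday, night shift, neurological ICU); "Missing" MDC is a real 22nd level.
If a mandated reference level is absent from a sample, or all of its rows
share one outcome (which sends the intercept to infinity — reference-side
separation), the builder falls back to the largest usable level with a
warning and records the actual references. One roster nurse is a
seeded-random reference.

**Estimation.** Newton–Raphson with step-halving on the (optionally
penalized) Bernoulli log-likelihood; convergence when the relative
log-likelihood change is below 1e-8 with a vanishing gradient, capped at 200
iterations. Perfectly-predicting 0/1 covariate columns (either side of the
split outcome-constant) are merged with their reference category before
fitting, as conventional packages do.

**Separation and the centered nurse ridge.** Nurses whose encounters are all
CAABU-free make the unpenalized MLE diverge. The default fit
(`penalty=None` → λ = 1e-4 × n) keeps every nurse by adding a *centered*
ridge on the nurse block: λ·Σ_j (e_j − ē)², where e runs over all J roster
nurses and ē is their mean, plus a weak λ/J pull of ē itself toward zero to
keep the block identified against the intercept. Two properties motivated
this form over a plain diagonal ridge. First, a diagonal ridge shrinks every
nurse toward the arbitrary reference nurse. Second — and specific to
multi-hot designs — with two-nurse encounters present, a reference-dropped
nurse block spans a genuinely different model for every reference choice, so
no penalty on the dropped-column parameterization can be reference-invariant.
Penalized fits therefore restore the reference nurse's own indicator column
and penalize the full block symmetrically; the fit, the margins, and the
joint test are then exactly invariant to the reference draw. `penalty=0`
reproduces conventional ML: the reference column stays dropped and separated
nurse columns are removed (their rates reported as missing).

**Inference.** Sandwich covariance clustered on patients by default (a
patient's encounters share the event window and the single possible event);
`cluster_level="encounter"` degenerates to heteroskedasticity-robust. Two
flavors: `cr2` (default) is the bias-reduced Bell–McCaffrey estimator —
per-cluster scores are adjusted by the inverse symmetric square root of
I − H_gg on the W^{1/2}-scaled design — which keeps test sizes close to
nominal when events are sparse within clusters; `cr1` is the conventional
Stata-style estimator with the G/(G−1)·(N−1)/(N−K) factor. Only two ICUs
exist, so unit-level clustering has no asymptotics; the unit enters as a
fixed effect.

**Predictive margins.** Nurse *j*'s rate is 100 × the sample mean of
inv-logit(η_i) with nurse *j*'s indicator set to 1 and, by default, every
other nurse indicator set to 0 (a pure single-nurse counterfactual;
`mode="observed"` leaves co-attending indicators at observed values —
the two differ only through multi-nurse encounters). Standard errors are
delta-method under the clustered covariance. The margin is computed over
*all* encounters, so differences between nurses reflect only their
coefficients, not their case-mix.

**Tests.** The joint nurse test is a Wald chi-square that all nurse effects
are equal (df = J − 1): for unpenalized fits the classical all-coefficients-
zero test; for penalized full-block fits the same null expressed as
difference contrasts against the reference. The AUC comparison fits the
covariate-only and full models by plain ML (same separation pre-drop) —
nesting then guarantees the in-sample AUC gain is nonnegative — and obtains
a one-sided p-value by resampling patients with replacement (999 draws by
default, seeded) and recomputing both AUCs from the fitted scores. Scores
are not refit under resampling; the test addresses sampling variability of
the AUC difference, not refitting variability.

## Rate diagnostics and projections

Moments use (n−1) variance, unbiased skewness, and Pearson kurtosis
(normal = 3). Normality is tested by Kolmogorov–Smirnov with the Lilliefors
correction by default (mean and SD are estimated), with plain KS available.
Quartiles are rank-based with quartile 1 the lowest rates; group sizes
differ by at most one, remainders going to quartiles 1 and 3 first (94
nurses → 24/23/24/23); ties break by nurse id, deterministically, with a
warning when a tie spans a boundary. The avoidable-case projection is
round(|mean(Q1 rates) − median(all rates)|/100 × shifts-per-nurse × #Q1
nurses), with the relative reduction expressed against observed cases — the
counterfactual of lifting the lowest quartile to the median.

## Cross-sample validation

*Balance tests* operationalize "were last period's nurse rates associated
with this period's patient assignments?": nurses split at their median
estimation rate; each validation patient classified high/low by the mean
rate of their attending nurses; Welch t-tests on patient-level continuous
and binary covariates and chi-square tests (rare categories lumped at
expected count < 5) for MDC and insurance. Patients — not nurse-level means,
which share patients and are therefore not independent — are the units, which
keeps the tests near nominal size under true random assignment.

*Weighted correlation*: Pearson over common nurses with weights equal to
summed encounter counts across both halves; the zero-correlation t-test uses
effective-n = (Σw)²/Σw² degrees of freedom.

*k-medians*: 2-D points (estimation rate, validation rate), Canberra
distance Σ|x−y|/(|x|+|y|) (0/0 terms contribute 0), initialized from the
estimation-half quartiles, component-wise median updates. The component
median is not the exact Canberra minimizer, so an update that would raise a
cluster's cost is rejected — the objective is then nonincreasing by
construction. An emptied cluster re-seeds at the point farthest from its
assigned median.

*Transition matrix*: quartiles are recomputed independently per half. A
nurse-level weighted multinomial logistic regression of the period-2
quartile on saturated period-1 quartile indicators is fitted by Newton
iteration; its predictive margins per period-1 quartile equal the weighted
conditional frequencies (the saturated-MLE identity, used as the oracle in
tests). Weights (encounter counts) are normalized to sum to the number of
nurses so confidence intervals are on the nurse scale; 95% CIs are
delta-method from the inverse Hessian (pseudo-inverted when empty cells
flatten it). Each cell is tested against 0.25 one-tailed (alternative
p > 0.25) by a proportion score test on the row's effective n, the
chi-square statistic signed by direction.

## The synthetic EHR generator

The generator emulates the study conditions: a 19-bed medical and a 16-bed
neurological ICU; 57 + 53 staff nurses plus 3 float nurses; 365 days in two
consecutive halves; 12-hour shifts; a 1:2 nurse-to-patient ratio; mean ICU
stays of 5.5/4.6 days (geometric in whole shifts); Poisson arrivals tuned to
85% occupancy — with a 1.12 compensation for admission blocking and horizon
truncation so realized volume matches the study's ≈21,700 patient-shifts —
with a bed gate at admission only (mid-stay census may board above the
licensed count, absorbed by overloading on-duty nurses; the staffing error is
reserved for structurally impossible configurations). Patient covariates
match the published sample margins (55% male, age 60 ± 16.6, ≈52% surgical,
the published insurance and MDC mixes including 16% "Missing").

Events are per-encounter Bernoulli draws on
logit p = baseline + covariate effects − mean(attending nurses' effects),
taking each patient's first success; the confirmed report is stamped
uniformly 24–48 h after the triggering shift's end, which is exactly the
labeling window (the nurses 24–48 h before a report *are* that shift's
nurses). Latent nurse effects are i.i.d. Normal(0, sd²) on the CAABU-free
log-odds scale — positive = protective — with sd defaulting to 0.3. The
baseline log-odds (−4.55) is calibrated so that 11–13% of patients acquire
an event, matching the published 11.41%/12.89% half-year rates; covariate
effects are modest (age +0.015/yr, prior admission +0.25, medical ICU +0.15,
dwell time +0.002/h ≈ 5%/day, kidney/urinary MDC +0.3, surgical −0.10) and
fully overridable. 1.6% of patients carry a pre-admission confirmed report
(exercising the exclusion rule), ~1% of events progress to CAUTI records,
1% of patients get an unconfirmed culture (which assembly must ignore), and
5% of encounters have a second nurse. `assignment_bias` ∈ [−1, 1] rank-matches
protective nurses to high-acuity (older) patients; 0 (default) is random
assignment. Everything derives from `numpy.random.default_rng([seed, stage])`
streams: identical configs give byte-identical CSV extracts.

What the generator does **not** emulate: antibiotic treatment and its
feedback on culture rates, CAUTI symptom progression, readmissions (each
patient is independent), seasonality (the study found none between halves),
inter-hospital transfers, nurse schedules with realistic rostering (duty
nurses are sampled fresh each shift), and catheter insertion/removal within
a stay (all patients are catheterized throughout). Passing tests therefore
demonstrate correctness of the *estimators* under the assumed
data-generating process, not robustness to real-EHR messiness such as
informative staffing or measurement error in culture timing.

## Monte-Carlo problem sizes and what the suite shows

The acceptance-style checks scale the study conditions to run in minutes on
one CPU, as the package's own choice of test size: type-I calibration uses
two units of 3 nurses/6 beds over 730 days (500 replicates) — the
configuration with the most events per nurse the 1:2 staffing ratio permits.
Under a true null every balance test rejects at 3.6–6.2%, inside the nominal
band. Transition persistence uses 16 nurses over 32 beds (50 replicates),
where a latent SD of 0.4 yields a mean same-quartile probability ≈0.42
versus 0.25 under the null, and the null transition cells average 0.25.

Two checks fail by construction of the statistics, not by coding error, and
are left failing deliberately:

*Joint Wald size.* The cluster-robust Wald test rejects a true null in
~11% of the 500 calibration replicates (nominal 5%). The statistic matches
an independent statsmodels computation to machine precision, and the
model-based Wald (~3%) and likelihood-ratio test (~3%) are calibrated on the
same fits — the inflation is the known heavy right tail of sandwich-variance
Wald statistics when events are sparse (≈18 per nurse here; the 1:2 staffing
ratio caps events per nurse per year, so no configuration of this design is
much richer). The CR2 covariance reduces but does not remove it. Joint-test
p-values near the threshold should be read accordingly; the LR test is the
better-calibrated alternative when a penalized fit is not needed.

*Recovery at study scale.* At the study's own scale (94 nurses, ~8,500
encounters per half, latent SD 0.3) the per-nurse information is ~1.4
events, so the noise SD of a nurse coefficient (~0.9–1.2) dominates the
latent signal; the attainable Spearman correlation between true effects and
estimated rates is ≈0.2–0.35, and the suite's recovery check at a 0.5
threshold fails (0/50 replicates reach it) by design of the conditions, not
of the estimator — recovery rises as information rises. This is the
quantitative face of a real substantive caveat: individual-nurse rate
estimates from a single six-month sample are noisy, which is precisely why
the split-sample validation layer exists.

## Known limitations

- The ridge default (λ = 1e-4 × n on the nurse block) is a pragmatic
  separation remedy, not an empirical-Bayes variance estimate; no
  random-effects/shrinkage-optimal alternative is provided.
- The AUC bootstrap holds fitted scores fixed; a full refit bootstrap would
  be substantially slower and is not implemented.
- The one-tailed 0.25 tests use a normal approximation on the row's
  effective n; exact binomial versions are not provided.
- Quartile cutpoint *values* are reported from `numpy.quantile`, while
  membership is rank-based; with heavy ties near a boundary the reported
  cutpoints may not separate the groups (a warning is emitted).
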