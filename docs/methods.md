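# Methods

## Scope and endpoints

The package analyzes cohorts of advanced epithelial ovarian cancer treated
with neoadjuvant chemotherapy (NACT) and interval debulking surgery (IDS).
Time zero is the start of first treatment (NACT initiation). Overall
survival (OS) is time to death; progression-free survival (PFS) is time to
recurrence or death, whichever comes first — the composite is our choice,
made explicit because clinical reports often leave it implicit. Horizon
analyses use 3 years = 1095 days and 5 years = 1825 days.

## Cutoff derivation

Each of the seven markers (pre-treatment neutrophil %, lymphocyte %,
lymphocyte count; post-NACT neutrophil %, lymphocyte %, lymphocyte count,
platelet count) is dichotomized against overall mortality by the Youden
criterion. Candidate thresholds are midpoints between consecutive distinct
observed values plus sentinels outside the range; this matches the
published cutoffs, which carry one more decimal than the underlying
laboratory values. The abnormal side is closed (value = cutoff is
abnormal); with midpoint cutoffs no observed value lies on the boundary, so
the convention is observationally neutral. Ties on J are broken toward the
threshold labelling fewer subjects abnormal — the more specific rule —
purely for determinism.

AUC is the trapezoidal area of the empirical curve, which equals the
Mann–Whitney U statistic divided by n₊ n₋ with ties counted ½ (an identity
the test suite checks by brute-force pair counting). The AUC p-value uses
the tie-corrected normal approximation of U without continuity correction,
the convention of the major commercial statistics packages.

Missingness is handled complete-case **per marker**: a record lacking the
pre-treatment panel still contributes its post-NACT values. This follows
from the published table arithmetic, whose pre-treatment metrics are only
consistent with smaller denominators (43 dead / 24 alive) than the full
cohort (44 / 28). When scoring, a missing marker contributes zero and the
number of available markers is recorded per patient, so users can opt into
complete-case scoring instead; the alternative (dropping the patient) would
shrink the scored cohort, which the published analyses did not do.

## The composite score and its threshold

The score counts abnormal markers (0–7). Its high/low threshold is
re-derived by the same Youden procedure on the score's own ROC and reported
as the smallest integer t with high ⇔ score ≥ t. The derivation method for
the published threshold (4) is not documented beyond the value itself;
mirroring the marker procedure is the natural default and reproduces 4 as
the modal threshold under the calibrated generator. Cutoffs are derived
once against mortality and reused for the PFS evaluation.

## Association statistics

Odds ratios use the cross-product with 95% Wald (log-normal) intervals.
The Haldane–Anscombe 0.5 correction is applied only when a cell is zero:
the published values match the uncorrected cross-product on every non-zero
table. Published percentages and ratios are displayed truncated (not
rounded) to two decimals — e.g. 27/33 prints as 81.81, 2.0952 as 2.09 —
so the display layer truncates; full-precision values are kept everywhere
else. The published univariate "risk ratios" are numerically odds ratios
(every value matches the cross-product on the reconstructed counts), and
are treated as such.

Logistic regression is Newton-type maximum likelihood via statsmodels,
wrapped to report Wald z-tests and to fail loudly on (quasi-)complete
separation (any |β| > 15). For a single binary predictor, exp(β̂) equals
the cross-product odds ratio to numerical precision — a dual-route identity
the tests assert at 10⁻⁶. The multivariable model fits exactly the
predictors the caller lists (no stepwise selection; the original selection
rule is undocumented).

Two-group comparisons run Shapiro–Wilk on each group at α = 0.05; both
normal → two-sided Student t, otherwise Mann–Whitney U with tie-corrected
normal approximation, with the routing decision recorded. Groups under 3
force the rank test. The blood–tissue correlation uses Spearman's rank
correlation (the original method is unnamed; rank correlation is the robust
default for count data).

## Survival analysis

Kaplan–Meier estimation and the unweighted two-group log-rank test are
implemented directly (at-risk counts and per-group observed/expected are
first-class outputs); lifelines serves as an independent cross-check in the
test suite, not as the implementation. Ties follow the standard
product-limit convention: events precede censorings at the same time.
Horizon restriction administratively censors at the horizon. The companion
binary endpoint counts within-horizon events as positive and event-free
follow-up reaching the horizon as negative; subjects censored alive before
the horizon cannot be classified and are excluded, with the exclusion count
reported so analyses remain auditable.

## Synthetic cohort generator

Real patient-level data are unavailable, so the generator produces cohorts
with the statistical structure the analysis assumes:

- **Markers.** Each marker's standardized severity is
  s = λf + γu + δε with patient frailty f, a family component u shared by
  the pre and post values of the same marker, and independent noise
  (λ² + γ² + δ² = 1). Counts are generated on the log scale (positivity);
  percentage pairs are rejection-resampled — the whole latent vector of an
  infeasible row is redrawn — so neutrophil % + lymphocyte % ≤ 100 holds in
  every record without boundary spikes. A pre-treatment platelet value is
  generated for schema completeness (it is stored, never scored).
- **True cutoffs.** Defaults place each marker's generative threshold at
  the published cutoff value, at the severity quantile matching the
  published abnormal prevalence (e.g. 54/72 abnormal for the post-NACT
  lymphocyte count). Recovery of these thresholds by the Youden procedure
  is a tested property.
- **Mortality.** Death is Bernoulli with logit p = β₀ + β₁ k, where k is
  the true abnormal-marker count and β₁ (`latent_effect`, default 0.60
  log-odds per abnormal marker) is the quantity the recovery tests
  estimate. β₀ is solved per cohort so the expected mortality equals the
  target (0.611), unless an explicit `death_intercept` pins the model
  down — the deterministic limit used by the separable-regime tests.
- **Survival.** Deaths get Weibull times (shape 1.4, scale 900 d)
  accelerated by exp(−0.25·(k − 3.5)); survivors get uniform
  administrative censoring over 400–4500 days, spanning short and long
  follow-up as in a 14-year accrual window. PFS is a Beta-distributed
  fraction (mean 0.6) of OS for progressors; 25% of survivors recur.
- **Tissue lymphocytes.** TIL counts (24/72 of patients) are negative
  binomial with log-mean linear in the pre-treatment peripheral lymphocyte
  count, giving the qualitative positive blood–tissue correlation; no
  published effect size exists to calibrate the slope, so it is a free
  config parameter with a plausible default.
- **Demographics** (age, BMI, parity, stage, subtype, surgical outcome,
  treatment-to-surgery interval) follow the published cohort table's
  marginals, with mild frailty links for stage and surgical outcome.

Calibration targets (n = 72; mortality 61.1%; per-marker AUC ≈ 0.65–0.69;
modal score threshold 4; 5/72 missing pre-treatment panels; 24/72 with
TILs) fix the frailty loading at 0.60, pre/post correlation 0.55 and latent
effect 0.60; these were set by simulation against the targets and then
frozen. Everything is deterministic given the seed; each generation stage
draws from its own spawned stream so adding a stage never perturbs earlier
draws.

What the generator does **not** emulate: chemotherapy-cycle dynamics,
tumour response, per-subtype marker distributions, or any real-data
peculiarity (batch effects, measurement rounding beyond two decimals,
informative censoring). Passing tests therefore demonstrate that the
pipeline recovers the structure it assumes — not that the score will
perform identically on new clinical data.

## Worked-example reconstruction

The published summary tables over-determine their inputs: with the
complete-case group sizes, the printed sensitivity and specificity pin down
all four 2×2 cells per marker (tp = round(Se·n_dead), tn = round(Sp·n_alive)),
from which PPV, NPV and the univariate odds ratio with its Wald interval
all follow. All 52 derivable printed values reproduce exactly under the
truncation display rule. The pre-treatment denominators (43/24) are the
unique pair, no larger than the cohort's 44/28, for which all printed
pre-treatment metrics are simultaneously exact rational fractions. The
multivariable estimates and the survival curves themselves require
patient-level data and are out of reach at desk scale; they are exercised
on synthetic cohorts instead.

## Problem sizes and numerics

Simulation-based checks use 500 replicate cohorts for mortality
calibration and latent-effect CI coverage, and 200 for threshold and AUC
calibration — enough that binomial noise on a 95% coverage estimate is
about ±1 percentage point. Oracle identities (AUC ≡ U-statistic, Youden ≡
exhaustive scan) are asserted to 10⁻¹²; the logistic/odds-ratio identity to
10⁻⁶ (iterative optimizer tolerance). Degenerate inputs fail loudly:
single-class outcomes, constant markers, all-missing scores, empty groups
and diverging logistic fits all raise typed errors rather than returning
NaN.

## Known limitations

- The Youden threshold estimator converges slowly (cube-root-n); on
  72-patient cohorts marker cutoffs carry substantial sampling noise, which
  is faithfully visible in the simulation results.
- Wald intervals are used throughout because they are what the published
  tables used; they are anti-conservative for small cells (no Firth or
  exact intervals, by design scope).
- No Cox regression: the published "hazard ratios" come from logistic
  models, and the package reproduces that analysis rather than replacing it.
- The score's missing-marker rule (contribute zero, track availability)
  biases scores downward for incompletely measured patients; the
  availability field exists precisely so users can filter.
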