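# Methods

This note documents the statistical procedures implemented in
`nashtriage`, the assumptions behind the synthetic cohort generator, the
numerical conventions, and the design choices made where more than one
defensible option existed.

## Endpoint and cohort model

The binary endpoint throughout is *at-risk NASH*: NAFLD activity score
(NAS) ≥ 4 together with liver fibrosis stage ≥ 2 on biopsy. Both
thresholds are configurable (`EndpointSpec`); raising `fibrosis_min` to 3
or 4 generalizes the endpoint to at-risk NASH with advanced fibrosis or
cirrhosis. The rule is conjunctive and monotone in both histology axes,
and it is an error—not a silent default—to evaluate it on a patient with
missing histology.

Cohort selection mirrors a biopsy-anchored screening design: patients
with a biopsy-to-blood gap above 90 days are excluded (boundary
inclusive: 90 days is retained), and by default only complete cases for
*all* registered score inputs are kept, so every test is evaluated on
exactly the same subjects — the property paired comparisons rely on.
Exclusions are tallied per reason (`gap`, `missing:<field>`); a record
failing several checks is counted once, by the first reason in a fixed
order, so the tally partitions the exclusions. The age split assigns the
boundary age (default 65) to the older group.

## Scores

Six tests are implemented as pure functions of a patient record (units:
AST/ALT IU/L, platelets 10⁹/L, albumin g/dL, A2M g/L, HbA1c %, ELF
analytes ng/mL, miR-34a-5p as a positive fold change). Two conventions
deserve note:

- **NFS IFG/diabetes indicator.** The impaired-fasting-glycemia rule is
  not standardized in the score's common printings; here the indicator is
  1 if the diabetes flag is set or, when a fasting glucose is present,
  glucose ≥ 5.6 mmol/L (the ADA IFG lower bound). The threshold is a
  package convention and is overridable per call. Albumin above
  10 g/dL triggers a unit-sanity error (a value that large is almost
  certainly g/L) unless explicitly overridden.
- **NIS4 / NIS2+ coefficients.** The clinical β are proprietary. The
  shipped set (`synthetic-calibration-v1`) was obtained once by logistic
  regression of the endpoint on the score's covariates in a default
  generator cohort (n = 20 000, recorded seed), then frozen in
  `data/coefficients.json` with a provenance string. Identities that do
  not depend on β (bounds, monotonicity, sex coding, invariance of NIS2+
  to A2M and HbA1c) are tested symbolically with hand-set coefficients.

Positivity is `score ≥ cutoff` everywhere. The registry carries the
published operating cutoffs: NIS4 (0.36, 0.63), NIS2+ (0.46, 0.68),
FIB-4 (1.30, 2.67), NFS (−1.46, 0.68), ELF (7.70, 9.80), and the
sex-specific ALT upper limit of normal as a single cutoff.

## Triage metrics and intervals

Dual-cutoff triage dichotomizes the **full** cohort at each cutoff (the
intermediate zone is never excluded from the denominator), and the zone
counts satisfy `n_below_low + n_intermediate + n_above_high = n` by
construction; single-cutoff tests have an empty intermediate zone.
Sensitivity, specificity, PPV and NPV are wrapped in 95 % Wilson score
intervals **with continuity correction** (Newcombe's closed form), with
the lower limit pinned to 0 at k = 0 and the upper to 100 at k = n.
Zero-denominator metrics return an explicit `undefined` marker rather
than 0 or 100, and reports render the marker; a one-subject denominator
(estimate 100.0, interval (5.5, 100.0)) renders honestly rather than
being suppressed.

Report formatting rounds percentages half-up to 1 decimal and AUROC to
2 decimals; computation is always at full precision and rounding is a
rendering concern only.

## ROC inference

- **AUROC** is the tie-aware Mann–Whitney probability, computed via
  mid-ranks in O(n log n); it equals the trapezoidal area under the
  empirical ROC curve (integrated in the curve's own cutoff order —
  re-sorting operating points by false-positive rate would scramble
  vertical segments created by ties).
- **Bootstrap CIs** are percentile 2.5/97.5 limits over (default 1000)
  resamples, stratified by outcome so class counts are preserved;
  unstratified resampling is available, with single-class resamples
  redrawn up to a hard cap. Fully deterministic given a seed.
- **Paired DeLong test**: per-subject placement values (structural
  components) give the 2 × 2 covariance of the paired AUROC estimators;
  `z = (A₁ − A₂)/√(v₁ + v₂ − 2c)` is referred to the standard normal,
  two-sided. A non-positive variance of the difference (e.g. identical
  scores) is flagged degenerate with p = 1. The normal (not t)
  reference and two-sided p at α = 0.05 are used throughout.
- **Youden cutoff**: candidates are midpoints between adjacent distinct
  scores plus ∓∞ sentinels — the grid on which "< cutoff" vs "≥ cutoff"
  is unambiguous for every subject; ties in J break toward the smallest
  cutoff (maximizing rule-out sensitivity at equal J). Cutoffs are
  derived on the full cohort and then applied to subgroups
  (`apply_derived_cutoff` keeps derivation and evaluation cohorts
  explicit), mirroring the design in which a single operating point is
  chosen once and assessed per age group.

## Paired comparisons

- **McNemar** on discordant calls, restricted to endpoint-positives for
  sensitivity and endpoint-negatives for specificity. The continuity-
  corrected statistic uses the unconditional `(|b−c|−1)²/(b+c)`
  convention of R's `mcnemar.test` (verified against statsmodels). The
  correction is applied to intermediate-zone proportion comparisons and
  is off by default for sensitivity/specificity; both are switchable.
  No discordant pairs → degenerate, p = 1.
- **Generalized score test for PPV/NPV** (predictive values condition on
  the test result, so the compared subject sets differ between tests and
  McNemar does not apply): the marginal-regression construction for
  paired designs of Leisenring, Alonzo & Pepe (2000). Each subject
  contributes one record per test whose call matches the target, the
  intercept direction is projected out of the score for the
  test-indicator coefficient, and the statistic `U²/V` uses the
  subject-level cluster-robust variance `V = Σᵢ eᵢ²`. The robust
  variance is essential: subjects called positive by *both* tests have a
  different disease probability than singly-called subjects even when
  the marginal predictive values are equal, and a model-based binomial
  variance is markedly anticonservative (observed type-I ≈ 0.11 vs the
  nominal 0.05 in null simulations). With disjoint call sets the
  statistic coincides with the classical two-proportion score test
  asymptotically (robust vs model-based variance differ at O(1/n));
  with identical calls it is degenerate with p = 1. NPV comparison is
  PPV comparison of the negated calls against the complemented outcome.
- p-values render to 4 decimals, with values below 10⁻⁴ shown as
  `<0.0001`. No multiplicity adjustment is applied.

## Synthetic cohort generator

The generator emulates a biopsy-anchored metabolic-risk screening
population; its defaults are the study conditions every test and the
acceptance script run under:

- n = 2053 with 410/2053 of patients aged ≥ 65 (ages ~N(69, 3) truncated
  to 65–75 in the older stratum, ~N(50, 10) truncated to 18–64 below).
- Endpoint prevalence 752/1643 (< 65) and 193/410 (≥ 65).
- Sex mix: 50 % male among older at-risk vs 73 % among older
  non-at-risk patients; 62 % male otherwise. Diabetes 44 %/59 % by class
  in the older stratum.
- Histology is drawn from class-conditional category weights
  (at-risk mass only on stages ≥ 2 and NAS ≥ 4 — infeasible weights are
  a configuration error; category weights are normalized and NAS
  category mass is spread uniformly over integer values). Non-at-risk
  (stage, NAS) pairs are rejection-sampled off the endpoint region, so
  generated histology can never contradict the label.
- Biomarkers are log-normal when summarized by median (IQR) — AST, ALT,
  miR-34a, YKL-40, A2M, HA, PIIINP, TIMP-1, FPG — with
  `μ = ln(median)`, `σ = ln(q3/q1)/(2·z₀.₇₅)`, and normal when
  summarized by mean ± SD (platelets, BMI, HbA1c, albumin; draws
  floored away from zero). Class-conditional parameters for AST, ALT,
  platelets, BMI, HbA1c and FPG in the ≥ 65 stratum follow published
  summaries; miR-34a, YKL-40, A2M, albumin and the ELF analytes have no
  public class-conditional summaries and are synthetic choices (the ELF
  components were picked so the implied ELF score mean/SD is plausible,
  ≈ 9.7 ± 0.8 vs ≈ 10.3 ± 1.0 by class). Parameters for the < 65
  stratum shift the ≥ 65 class-conditional locations so the mixture
  median tracks the younger marginals.
- **Dependence structure**: within a class, biomarkers are independent
  on the transformed scale except for a shared latent disease-severity
  factor (loading 0.5) on miR-34a, YKL-40, AST and ALT. Fully
  independent markers would make composite scores unrealistically
  strong; the single loading is the minimal structure under which AUROC
  calibration is meaningful. The true joint correlation structure is
  unknowable from published marginals — this is a stated assumption,
  not an inference.
- The biopsy–blood gap is uniform on 0–90 days and independent of
  everything else (which also makes it a convenient built-in pure-noise
  variable: its AUROC against the endpoint is ~0.5).

`calibrate_to_auroc` scales the class-conditional location contrast of a
score's input biomarkers by a single factor α (log scale for lognormal
markers), root-finding (Brent) on a fixed-seed calibration cohort of
n = 20 000 until the score's AUROC hits its configured target
(default 0.83 for NIS2+ in the ≥ 65 stratum) within ± 0.01. The same
seed is reused across α evaluations, so the objective is a smooth,
monotone function and the procedure is deterministic given the seed.
A target of 0.5 returns α = 0 (identical classes in the score's inputs)
without the tolerance check: the class-conditional sex mix — a NIS2+
covariate — leaves a residual AUROC of ≈ 0.53 that biomarker scaling
cannot remove. Unreachable targets raise a calibration error carrying
the achieved value.

Generation is deterministic given (config, seed); biomarker draws are
consumed in sorted-name order so determinism survives config
serialization (JSON manifests sort keys). Fixtures are written as CSV
plus a JSON manifest (config, seed, SHA-256) and regenerate
byte-identically.

**What passing tests on synthetic data do and do not show.** The
generator reproduces marginal summaries, prevalence, the endpoint-
histology consistency and one calibrated AUROC; it does not model assay
noise, biopsy reading variability, site effects, non-monotone
biomarker–severity relationships, or the true biomarker correlation
matrix. Passing tests therefore validate the *statistical machinery*
(metrics, intervals, tests, cutoff logic) exactly, and the *pipeline's
behaviour* under realistic-looking data — they are not evidence about
the clinical performance of any real test.

## Numerical choices and problem sizes

- Wilson-CC in closed form; interval limits clipped to [0, 100].
- Logistic evaluated in the numerically safe branch form; composite
  scores are strictly inside (0, 1).
- Bootstrap and simulation sizes in the test suite are chosen to keep
  the full suite under a minute while leaving Monte-Carlo bands tight
  enough to detect calibration errors: 2000 null simulations for the
  DeLong and generalized-score type-I checks, 200–500 random instances
  for the oracle-equality checks, n = 5000 cohorts for parameter
  recovery, and one n = 20 000 calibration run.
- Degenerate inputs are first-class: single-class subgroups are skipped
  with no fabricated numbers, zero-denominator metrics are `undefined`,
  zero-variance comparisons are `degenerate` with p = 1, and
  single-cutoff tests render `—` for the intermediate-zone cells.

## Known limitations

- The shipped NIS4/NIS2+ coefficients are synthetic; absolute score
  values and cutoff crossings are not comparable to the clinical assays,
  only the pipeline's behaviour is.
- The generalized score test is implemented for the paired-design
  predictive-value comparison only (no covariates, no weighting).
- The bootstrap is percentile-only; BCa intervals are not implemented.
- Table-style rounding is half-up; a source that rounded half-even could
  differ in the last printed digit for exact .05 boundaries.
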