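# Methods

## Problem setting

During neoadjuvant chemotherapy (NAC) for early-stage breast cancer, serial
DCE-MRI can track tumor burden non-invasively. Patients whose imaging
suggests a pathologic complete response (pCR, no residual invasive disease
at surgery) may be candidates to stop chemotherapy early and proceed to
surgery — but only if the prediction's positive predictive value (PPV) is
high, because a false positive interrupts a treatment the patient would
have benefited from. This package implements that chain: functional tumor
volume (FTV) measurement, subtype-specific logistic models of pCR, and
probability-threshold selection constrained by minimum PPV.

## FTV measurement

Each exam contributes pre-contrast (S0), early post-contrast (~2 min 30 s,
S1) and late post-contrast (~7 min 30 s, S2) volumes. Per voxel,

* percent enhancement PE = (S1 − S0)/S0 × 100,
* signal enhancement ratio SER = (S1 − S0)/(S2 − S0).

FTV is the summed volume (cc) of voxels inside a rectangular VOI with
PE strictly above `pe_min` (default 70%) and SER strictly above `ser_min`
(default 0). Numerical choices:

* Voxels with S0 ≤ 0 (undefined PE) or S2 = S0 (undefined SER) are invalid
  and never segmented; the maps carry NaN there, which fails every strict
  comparison without special-casing.
* Washout below baseline (S2 < S0 while S1 > S0) gives SER < 0 and fails
  the default criterion — an algebraic consequence, not an extra rule: for
  enhancing voxels, SER > 0 ⇔ S2 > S0.
* Inequalities are strict; a voxel exactly at a threshold is excluded.
* The VOI and thresholds are keyed to the patient, fixed at baseline, and
  applied unchanged to T1/T2. Per-patient threshold overrides exist (a
  reader may adjust the baseline segmentation visually) but there is no
  automatic threshold optimizer.
* Coordinates are 0-based, half-open `[lo, hi)` boxes, axis order (x, y, z)
  matching the voxel-size order.
* `percent_change(ftv_ref=0)` returns NaN as an explicit undefined
  sentinel. Such patients count as missing-FTV in the exclusion audit and
  never enter modelling; the sentinel is never silently coerced to 0.

A note on printed worked examples: percent changes recomputed from rounded
volumes can differ in the last digit from values computed on unrounded
volumes (e.g. 38 cc → 3 cc gives −92.1% from the rounded inputs). Tests
assert the arithmetic of the function, not transcription of any particular
rounding.

## Synthetic data

The phantom generator builds a three-phase exam with an ellipsoidal lesion
whose pre-noise PE/SER are exact by construction (S1 from the PE level, S2
from the SER level), on a weakly enhancing background with persistent
kinetics. It returns the ground-truth lattice, so segmentation can be
checked for exact mask equality; with additive noise the recovery is only
approximate, which the tests exercise separately. The phantom emulates
segmentation arithmetic only — not breast anatomy, coil profiles,
motion, or fat-suppression failures — so phantom-level passes say nothing
about reader variability or acquisition quality on real exams.

The cohort generator draws, per patient: subtype from a categorical mix
(defaults 40/16/9/35% over HR+/HER2−, HR+/HER2+, HR−/HER2+, TN), pCR from
a per-subtype Bernoulli rate (defaults 20/39/66/45% — the two HER2
mid-rates are back-computed from the fact that PPV at the all-positive
threshold equals prevalence, and are approximations), baseline FTV from a
log-normal (log-mean 3.2 ≈ 25 cc median, log-sd 0.9, all subtypes), and
FTV percent changes at T1/T2 from a correlated bivariate Gaussian with
group-specific means and spreads, truncated below at −100% by joint
resampling (a tumor cannot lose more than its whole volume).

Default effect sizes: T2 change means −85% (pCR) vs −50% (non-pCR) with
sds 40 vs 60; T1 means −55% vs −30% with the same sds; T1–T2 correlation
0.6. Responders cluster near total volume loss while non-responders
scatter widely, hence the asymmetric spreads. These values were fixed once
so that the single-predictor discrimination lands near AUC 0.72 under
truncation — the level such trial cohorts report — rather than at the
implausibly clean separation a narrow spread would give; the correlation
keeps multivariate models from accumulating AUC from what is really one
longitudinal signal. All parameters are configurable in `CohortSpec`; all
randomness flows from its single seed, and identical seeds reproduce
byte-identical CSVs (fixed float formatting).

What the cohort generator does not emulate: treatment-arm effects, lymph
node status, enrollment drift, inter-site FTV variability, and any real
correlation between baseline FTV and outcome (baseline FTV is simulated
as uninformative, which is also why selection should usually drop it).

## Models and selection

Logistic regression (maximum likelihood, `statsmodels`) predicts pCR from
untransformed FTV variables — percent changes in percent units, baseline
FTV in cc — so predicted-probability thresholds stay on the clinical
reporting scale. Complete separation is flagged, refit by BFGS, and the
saturated probabilities kept usable rather than aborting.

Candidate predictor sets are the 7 non-empty subsets of
{dftv_t1, dftv_t2, ftv_t0}. Each is scored by mean held-out AUC over
stratified 5-fold cross-validation (folds shared across candidates, seeded
from config). AUC is the Mann–Whitney rank statistic, ties counted half.
The winner is refit on all records.

Selection ties: a cross-validated mean AUC is a noisy estimate, so
candidates within `tie_tol = 0.01` AUC of the best are treated as tied and
resolved toward fewer predictors, then lexicographic order. Without this
tolerance, supersets of the true predictor set win on CV noise roughly
half the time; with it, selection is stable and minimal, mirroring how
extra FTV variables are dropped in practice when they add no real AUC.
Whether selection uses cross-validated or in-sample AUC is configurable;
cross-validation is the default. The full-cohort model uses FTV variables
only (no subtype indicators).

Records with undefined percent change are excluded before fitting. Scopes
with fewer minority-class records than folds are reported as
"insufficient data" and skipped, not fatal — tiny subtype strata are
expected in this design.

## Threshold analysis

A patient is predicted pCR when their modelled probability is at or above
a cutoff t (the ≥ rule guarantees that t = 0 predicts everyone positive,
giving sensitivity 100% and PPV equal to prevalence). The curve evaluates
every distinct predicted probability plus 0. PPV is not monotone in t, so
the selection rule is: the smallest candidate t with PPV(t) ≥ the required
level. Since sensitivity is non-increasing in t, this maximizes
sensitivity subject to the PPV constraint; exhaustive-scan equivalence is
asserted in tests. When no cutoff attains the level the selection is the
+Inf sentinel — nobody is ever predicted pCR, sensitivity 0 — serialized
as the literal string "+Inf" in reports.

Sensitivity intervals are 95% Wald, p̂ ± 1.96·√(p̂(1−p̂)/n), clipped to
[0, 100]; n is the true-pCR count of the evaluated stratum. Wald is a
deliberate, simple choice consistent with the interval widths such reports
print; it degenerates to zero width at p̂ ∈ {0, 1}.

The decision rule per patient: below the threshold (or any probability
against +Inf) → continue NAC; at/above → early-surgery candidate;
at/above with a core biopsy confirming no residual invasive disease →
early-surgery recommended. The biopsy enters only as this confirmation
flag; modelling biopsy histopathology is out of scope.

Thresholds reported by the pipeline come from the full-cohort predictions
of the CV-selected, refit model (not from resampled predictions).

## Cohort statistics

Fisher's exact test uses the probability-mass two-sided rule: sum the
probabilities, under fixed margins, of every table no more probable than
the observed one (relative tie tolerance 1e−7). The 2×2 case delegates to
`scipy.stats.fisher_exact`. The r×c case enumerates all tables with the
observed margins recursively over the smaller dimension — feasible
whenever the table count stays under the configured bound (default 2×10⁶;
a 4×2 table with a 77-patient margin enumerates ~80k tables in well under
a second) — and otherwise directs the caller to the Monte-Carlo mode,
which samples tables under fixed margins (Patefield's algorithm via
`scipy.stats.random_table`) and estimates the same tail with the add-one
estimator plus its binomial standard error. The enumerator's total
probability mass and its agreement with the 2×2 path are tested, and its
p-value for the 4×2 subtype table is checked against a frozen reference
value (0.1748) from an independent exact implementation.

The two-sided t-test from group summaries is Welch's with Satterthwaite
degrees of freedom (`scipy.stats.ttest_ind_from_stats`). Note that a
summary-based p-value can differ from one computed on raw paired-up data;
the summary version is what this package reports.

## Pipeline

`run_pipeline` chains: input (synthetic cohort, cohort CSV, or NIfTI image
manifest → FTV table) → exclusion audit (missing outcome/receptor first,
then missing FTV, in that fixed order) → per-scope model selection →
threshold curves and selections at the configured PPV levels (default
50/70/90) → per-patient decisions → report bundle (models.json,
threshold_report.csv, implications.csv, decisions.csv, run_log.json with
seed, config hash and per-stage counts). Identical config + seed gives
byte-identical reports. The default synthetic run uses n = 5000, which
keeps every stage under a second while leaving subtype strata large enough
for stable 5-fold selection.

## Known limitations

* Wald intervals undercover near sensitivity 0 or 100%; no bootstrap or
  score intervals are provided.
* The synthetic cohort cannot reproduce finite-sample quirks of any real
  trial's threshold table (e.g. a low-prevalence stratum achieving PPV 50
  at a modest cutoff through local tail noise); at n = 5000 the attainable
  PPV ceiling binds earlier, and whether a 90% level ends in +Inf or a
  negligible-sensitivity cutoff depends on the outcome of the top-ranked
  patients — the end-to-end tests assert the pattern at that qualitative
  level only.
* Exact r×c Fisher is exponential in table dimensions; wide tables with
  large margins need the Monte-Carlo mode.
* No registration, motion handling, DICOM ingestion, or phase selection
  from longer dynamic series: inputs are pre-selected, co-registered
  volumes.
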