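# Methods

This note documents the statistical model behind `b12status`, the parameters
that matter, the synthetic-data generator's scope, and the numerical and
design choices made where more than one defensible option existed.

## The combined indicator and its constants

The combined indicator of vitamin B-12 status (cB-12) aggregates circulating
markers and age into one score whose sign and magnitude track B-12 adequacy.
The 4-marker form is the log ratio of "good" to "bad" markers,

    4cB-12 = log10[(holoTC · B-12) / (MMA · tHcy)] − age_factor(age),

and the package implements the holoTC-free 3-marker form as the parametric
family

    3cB-12 = e_b·log10(B-12) + e_m·log10(MMA) + e_t·log10(tHcy)
             + offset − age_factor(age),
    age_factor(age) = Σ_k c_k (age/100)^k,

with e_b > 0 and e_m, e_t < 0 enforced. The numeric constants are **explicit
configuration** (`Cb12Constants`, shipped as
`src/b12status/constants/cb12_constants.yaml`, versioned and echoed into
every results manifest); no computation runs without a constants object. The
packaged defaults — exponents (1, −1, −1), offset +0.95, age factor
0.5·(age/100)² — are the package's own documented transcription choice for
the modified indicator: they keep the published 4-marker log-ratio skeleton,
recentre the holoTC-free scale so that a marker-adequate adult population
sits near +0.5 with a 2–5% tail at or below the inadequate boundary, and
subtract a mildly convex age term (0.02 at age 20, 0.36 at age 85) matching
the observation that MMA and tHcy drift upward with age independent of B-12
status. Analyses of real data should replace the file with constants
verified against the combined-indicator source publications (Fedosov et
al.); the equations' exact published coefficients were not available when
the defaults were fixed, which is why they are configuration rather than
code. Status classification is boundary-inclusive: cB-12 ≤ −0.5 is
*inadequate* (the epidemiological low + transitional region combined),
> −0.5 *adequate*. No folate correction is implemented, and deliberately no
flag for one exists — median folate in the target population is
post-fortification high, and an untested code path is worse than an absent
one.

Renal function uses the race-free CKD-EPI creatinine equation (2021
coefficients, a `CkdEpiParams` configuration echoed into outputs):
eGFR = 142·min(Scr/κ,1)^α·max(Scr/κ,1)^(−1.200)·0.9938^age·(1.012 if female),
κ = 0.7/0.9 and α = −0.241/−0.302 for females/males. *Normal* renal function
requires eGFR ≥ 60 mL/(min × 1.73 m²) (boundary inclusive) **and** absent
albuminuria; the albuminuria helper threshold (ACR ≥ 30 mg/g) is likewise
configuration.

## Cohort construction

Exclusions run in a fixed order, each record attributed to the first failed
criterion: (1) incomplete marker panel, (2) age < 20 y, (3) pregnancy or
lactation — missing flags count as *not* pregnant/lactating, mirroring
survey skip patterns where exclusions apply only when eligibility is
explicitly met — and (4) abnormal renal function, applied only under the
`normal_only` restriction (the all-adults subanalysis skips it). Records
whose renal inputs are missing cannot be classified and fall at step 4 under
`normal_only`. The cascade is idempotent and its attrition log is part of
every result bundle.

## Design-based estimation

Proportions are domain ratio estimators `p̂ = Σwy/Σw`; their SEs come from
stratified with-replacement Taylor linearization (PSU totals of the
linearized scores `wᵢ(yᵢ−p̂)/Σ_domain w`, records outside the domain
contributing zeros so the design structure is preserved), and 95% CIs are
computed on the logit scale with z = 1.959964 and back-transformed. A
degenerate estimate (0 or 1, or zero SE) is returned with a collapsed CI and
a `degenerate` flag rather than a fabricated interval.

The bootstrap is the Rao–Wu–Yue rescaled stratified-PSU bootstrap: in each
stratum of n_h PSUs, n_h − 1 PSUs are drawn with replacement and a record's
replicate weight is its base weight times (n_h/(n_h−1))·(draw count), which
is unbiased for the base weight. With the NHANES-style two PSUs per stratum
each replicate doubles one PSU and zeroes the other. Strata with a single
PSU raise an error instructing collapse. Percentile CIs use linear
interpolation between order statistics (numpy's default quantile rule) and
require ≥ 50 finite replicates. Paired comparisons use the percentile
two-sided p-value `2·min(P(Δ≤0), P(Δ≥0))` floored at 1/B — a studentized
variant would also have been defensible; the percentile form is what is
implemented and labelled. The replicate count defaults to B = 2000 and is
scaled down (B = 200) in tests and in the acceptance script.

## ROC, AUC, and optimum cutoffs

Candidate thresholds are the unique observed marker values (not midpoints),
and positivity is strict — `> t` for markers elevated in deficiency (MMA,
tHcy), `< t` for B-12 — matching how cutoffs such as ">229 nmol/L" are
written; ties in the score change classification together. The trapezoidal
area under the resulting curve equals the weighted pair-concordance
statistic; the test suite asserts that identity to 1e−12 rather than
assuming it. Single-marker "models" are the concentrations themselves (hence
invariant to monotone transforms); multi-marker scores are linear predictors
of survey-weighted logistic regressions (weighted ML via IRLS, statsmodels
GLM with `var_weights`) on log10 concentrations — the markers are
right-skewed, and the log transform is recorded here because the choice is
not forced. Non-convergence or separation triggers a flagged ridge refit
(`irls-ridge-fallback`), never a silent failure.

The optimum cutoff minimizes the Euclidean distance to the (0,1) corner of
the ROC plane; exact ties break toward higher specificity, the conservative
choice in a low-prevalence population where false positives dominate. The
cutoff's CI re-derives the optimum on every bootstrap replicate (the
interval is for the cutoff itself, not for Se/Sp at a frozen cutoff); Se and
Sp at the chosen cutoff carry Taylor-logit CIs.

## Prevalence adjustment

Apparent prevalence on the validation cycle is corrected with the
Rogan–Gladen estimator, π̂ = (p̂ + Sp − 1)/(Se + Sp − 1), using Se/Sp
re-estimated on the training cycle so no data are used twice. Estimates are
clamped to [0,1] with an explicit flag. The CI combines the three variances
(apparent, Se, Sp — training and validation treated as independent) by the
delta method on the adjusted scale and reports logit-transformed bounds,
consistent with the package's other intervals; near-uninformative cutoffs
(Se + Sp − 1 small) therefore produce very wide intervals, and
Se + Sp ≤ 1 is an error, not a number. The reference row (status defined by
the indicator itself) carries Se = Sp = 1 by construction, so its apparent
and adjusted prevalences coincide. Percentages exist internally as
proportions; the ×100 rendering happens only in the reporting layer.

## The synthetic-data generator

`generate_population` draws, per record: a latent inadequate/adequate class
(Bernoulli at `prevalence_inadequate`, default 0.03); correlated log10
marker triples from class-specific means — defaults (2.60, 2.09, 0.90) for
adequate and (2.18, 2.55, 1.22) for inadequate, i.e. geometric means of
~400 vs 150 pmol/L B-12, ~125 vs 355 nmol/L MMA, ~8 vs 17 µmol/L tHcy — with
SDs (0.22, 0.20, 0.17) and correlations (−0.30, −0.25, +0.35) for
(B-12,MMA), (B-12,tHcy), (MMA,tHcy); an MMA age trend of +0.02 log10 per
decade centred at age 50; a renal-impairment subgroup (rate 0.08) with
+0.15/+0.12 log10 shifts on MMA/tHcy independent of class; uniform ages
20–85; 1:1 sex; pregnancy/lactation only among females 20–44 (rate 0.06);
and log-normal weights with CV 0.5 around equal allocation. Creatinine and
albuminuria are generated **backwards** from the intended renal flag by
exact inversion of the CKD-EPI classifier, so ground truth survives the
cohort module. The default design is 15 strata × 2 PSUs × 120 records;
`split_cycles` assigns whole strata to the training/validation cycles
(default ⅔ training) and rescales each cycle's weights to the parent
population total, mirroring how multi-year and single-cycle survey weights
each represent the same population.

The class separations and SDs were calibrated once so that, against the
computed 3cB-12 reference, the single-marker weighted AUCs land at ≈0.94
(B-12), 0.96 (MMA), 0.93 (tHcy) — the mid-0.9 regime with MMA strongest that
the analysis is designed for — with a reference prevalence of ~4%. That
calibration is a fixture choice, not a scientific claim about any real
population. The generator deliberately does **not** emulate nonresponse
adjustment, post-stratification or raking, oversampling of subgroups,
missing-data patterns, assay noise or between-cycle method effects; passing
tests therefore demonstrate correctness of the estimators under the stated
design, not robustness to those real-data features.

## Problem sizes and numerical details

Tests and the acceptance script run at desk scale: populations of 480–3600
records, B = 60–200 bootstrap replicates, 50–300 Monte-Carlo repetitions for
the stochastic checks (cutoff recovery at n = 5000 over 50 seeds; prevalence
round-trip over 200 repetitions; CI coverage over 300 populations). GLM fits
use statsmodels defaults with `maxiter=100`. Determinism: every stochastic
component takes an explicit seed (numpy `default_rng`; child seeds via
`SeedSequence`), and a repeated run with the same configuration produces
byte-identical result bundles — manifests carry configuration, constants
version, CKD-EPI coefficients, bootstrap method label, and seed, but no
timestamps.

## Known limitations

- The shipped cB-12 constants are a transcription-family choice suitable for
  the synthetic workflow; real-data use requires externally verified
  constants (see above).
- holoTC-based forms are implemented (4cB-12) but untested against real
  holoTC distributions; no cystatin-C eGFR variants or legacy race
  coefficient are provided.
- Adjusted-prevalence CIs use one specific variance combination (delta
  method + logit); other propagation choices would give different widths,
  which is why the method label is embedded in every output row.
- No sex- or age-stratified cutoff derivation; no smoothed/binormal ROC,
  partial AUC, DeLong variance, finite-population corrections, BRR or
  jackknife.
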