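# Methods

## The estimating equations and their domains

Both LDL-C estimators are computed in mg/dL.  The Friedewald formula
`LDL = TC − HDL − TG/5` assumes a fixed TG:VLDL-C ratio of 5 and is flagged
invalid when TG exceeds 400 mg/dL (the boundary value 400 itself is still
valid, matching the usual "exceeds 400" phrasing).  The Sampson–NIH
polynomial `LDL = TC/0.948 − HDL/0.971 − (TG/8.56 + TG·nonHDL/2140 −
TG²/16100) − 9.44` was fitted to β-quantification and is flagged invalid above
TG 800 mg/dL.  Its constants are mg/dL-specific, so the package computes it in
mg/dL only and converts other-unit inputs first.

Non-positive calculated values are returned **unclipped** and flagged
(`reason="nonpositive"`).  Clipping would bias any difference-based analysis;
downstream, Bland–Altman keeps such values and only excludes TG-domain
violations, while the screening classifier uses the raw calculated value
regardless of flags (a laboratory system would likewise report *some* number).

Unit conversion uses 38.67 mg/dL per mmol/L for cholesterol and 88.57 for
triglycerides (standard molar masses).  The conventional mmol/L Friedewald
divisor 2.2 is a rounding of 5 · 88.57/38.67 ≈ 2.29 applied to a different
unit scale; computing in mmol/L with 2.2 and converting back reproduces the
mg/dL value only to within ~1 mg/dL, which the tests document as the expected
residual of the convention, not an implementation error.

## Bland–Altman agreement

For paired series the difference is always `first − second`, and the pipeline
passes `(direct, calculated)`, so underestimation by an equation appears as a
*positive* bias.  The implementation uses the n−1 sample SD and the normal
z = 1.96 for both the limits of agreement (bias ± 1.96·SD) and the bias CI
(bias ± 1.96·SD/√n); at cohort sizes near 2000 the t quantile differs only in
the fourth decimal, and the z convention matches how such limits are normally
reported.  `bias_pct_of_range = 100·bias/(ULoA − LLoA)` quantifies how much of
the disagreement band is pure systematic shift.  For identical series the
ratio is undefined and reported as 0.  The method×age interaction is
summarized model-free as an OLS regression of the paired differences on
(age − 13), with a normal-theory slope CI; no robust mixed model is fitted
(single measurement per subject per method, no repeated-measures structure to
exploit).

## Dyslipidemia rule and diagnostic report

A subject is dyslipidemic when LDL-C > 100 mg/dL (strict inequality — the
boundary value is healthy) **or** TG ≥ 100 mg/dL below age 10 / TG ≥ 130 mg/dL
from 10 to 18 (inclusive cutoffs).  Ages are real-valued; age 10.0 exactly uses
the older cutoff ("under 10" is strict).  The rule applies to ages 2–18;
out-of-window subjects raise a distinct exclusion signal and are counted, never
silently labelled healthy.

Truth labels come from the direct assay, predictions from the calculated LDL
with the *same* TG term.  Because the TG criterion is shared, every
TG-elevated panel is a concordant positive, and all discordance is carried by
the LDL comparison — this is exactly the mechanism behind the extreme
false-negative/false-positive asymmetry, and the tests assert it by
construction.

Metric conventions: accuracy CI is exact Clopper–Pearson; the no-information
rate is the larger truth-class fraction and `p_accuracy_gt_nir` is the
one-sided exact binomial tail P(X ≥ correct); kappa uses row×column chance
agreement; McNemar uses the continuity-corrected statistic
`(|fp−fn|−1)²/(fp+fn)` on 1 df with p = 1 when no discordant pairs exist.
Metrics with an empty margin are NaN, never 0.  All of these are cross-checked
in the tests against independent implementations (scikit-learn's kappa,
statsmodels' McNemar, scipy's binomial test) on hundreds of random matrices.

## Descriptive statistics

Quartiles use linear interpolation between order statistics (numpy's default,
"type 7") — the convention of the R ecosystem such analyses are usually run
in.  The rank-sum test uses exact enumeration up to a combined n of 12 without
ties, otherwise the midrank normal approximation with tie and continuity
corrections (scipy's Mann–Whitney).  The 2×2 chi-square is Pearson *without*
Yates correction, which is what reproduces the published sex-by-age p = 0.035
from the printed counts (the corrected statistic gives ≈ 0.039).  No
multiplicity adjustment is applied across table rows.

## Synthetic cohort generator

The generator emulates the *marginal* structure of a hospital pediatric
screening cohort (n = 1982 default): sex ~ Bernoulli(0.5156); integer ages
2–17 drawn from a categorical distribution whose piecewise-linear CDF is
anchored at the target quartiles (9, 13, 15); TG log-normal with
log-SD = (ln 111 − ln 60)/(2·0.6745) = 0.456 so the printed IQR is
reproduced under log-normality; TC and HDL normal with SD = IQR/1.349; TC
shifted −8 mg/dL in the ≥13-year group and recentred so the overall median is
unchanged; HDL truncated to [20, TC − 25].  The direct measurement is then
generated *from* the Friedewald value: `direct = friedewald +
N(16.27 + 0.12·(age − 13), 10.4)`, truncated to ≥ 1 mg/dL.  Injecting the
offset at a single point means the Sampson–NIH method's behaviour (offset
~15 mg/dL, its own age interaction) *emerges* from the equations rather than
being forced, mirroring the empirical finding that both equations share one
systematic offset.  Panels whose direct-LDL floor is unreachable (deep
negative Friedewald values in the log-normal TG tail) have their lipids
resampled wholesale, keeping sex and age; each truncation is capped at 100
rounds before erroring.

Draws come from one seeded numpy `default_rng` (PCG64) in a fixed order
(sex, age, TG, TC, HDL, offset), so a config + seed pins the cohort exactly.

**Calibration choice.**  The generator draws TC and HDL independently (real
panels correlate them positively), which inflates the spread of the derived
LDL values relative to a real cohort.  With the TC centre at the emulated
cohort's 153 mg/dL this pushes the dyslipidemia truth-prevalence to ~0.60
instead of the ~0.50 a screening cohort of this composition shows.  Since
prevalence is the diagnostically decisive property, the default
`tc_median = 147` trades a ~4 % low TC median for a prevalence of ~0.53 and a
direct-LDL median of ~91 mg/dL; the derivation is analytic (normal-tail
arithmetic on the configured SDs), not a fit.  An explicit TC–HDL correlation
hook was considered and left out to keep the generator's assumptions minimal.
`age_effect_ldl` (−0.37 mg/dL/yr) documents the cohort-level direct-LDL age
trend the defaults aim at; it is not injected directly — the trend arises from
the TC age-group shift.

**What the generator does not emulate:** TC–TG–HDL correlations beyond the
structural one through non-HDL, fractional ages (supported on read, not
generated), repeated measures per subject, assay-specific heteroscedasticity,
and outlier contamination.  Passing tests on synthetic cohorts therefore
demonstrate that the *pipeline* recovers injected structure at realistic n and
noise — not that real pediatric data obey these distributions.

## Problem sizes and numerical choices

Simulation-based tests use n = 2000 cohorts with fixed seeds (seed 1 in the
test suite, seed 0 in the analysis drivers) — large enough that the injected
bias (SE ≈ 0.23 mg/dL) and age slope (SE ≈ 0.03/yr) are recovered well inside
their tolerance bands, small enough that the whole suite runs in seconds.
Monte-Carlo property tests (rank-sum type-I error over 200 replicates, power
over 100 replicates, 500 random confusion matrices, 1000 random panels for
equation-oracle equivalence) are likewise seeded.  Exact identities
(LoA = bias ± 1.96·SD, balanced accuracy = mean of sensitivity/specificity)
are asserted to 1e−12; oracle equivalences to 1e−9.

## Known limitations

- The dyslipidemia rule is the fixed-cutoff screening definition; percentile-
  based age/sex reference tables are out of scope.
- Martin–Hopkins estimation (the 180-cell TG:VLDL factor table) is not
  implemented.
- Bland–Altman is the single-measurement variant: no repeated-measures or
  regression-based (proportional-bias) limits.
- The generator reproduces marginals and one injected bias structure only; it
  is a test harness for the pipeline, not a population model of pediatric
  lipids.
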