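# Methods

## Model and scope

The package estimates, per district, the births that contraception averted
over a 3-year reference window. The identifying assumption is a district
level log-linear relation between the total fertility rate and the
contraceptive prevalence rate,

    log TFR_i = β0 + β1 CPR_i + ε_i,

with all other proximate determinants of fertility held fixed and the
current contraceptive prevalence taken to have prevailed throughout the
window. The counterfactual "no contraception" state keeps each district's
residual ε_i and removes only the CPR term, so districts retain their
idiosyncratic fertility level. Nothing here is causal at the individual
level: the regression sees only district aggregates, and so does the
counterfactual.

## Observed TFR and its confidence interval

TFR is computed directly from birth histories by the direct method. The
window is the 36 calendar months strictly before the interview month
(the interview month itself is excluded). Exposure splitting is exact
integer-month arithmetic on century-month codes (CMC = (year−1900)·12 +
month): each woman's window is intersected with the CMC interval of each
5-year age group of her life; completed age uses floor division by 12, and
ties at group boundaries go to the older group (a woman of completed age 20
is in 20–24). Months outside ages 15–49 contribute nothing. Births are
attributed to the mother's age group at the birth month. Everything is
weighted by the sampling weight; TFR is invariant to uniform weight
rescaling.

The 95% CI is model-based: group birth counts are treated as independent
Poisson counts given exposure, one log-rate per group, giving
Var(log TFR) = Σ_a (5·ASFR_a)² / births_a / TFR² by the delta method
(groups without births are excluded; with no births anywhere the CI is
undefined and returned as (0, 0) with a warning). The interval is lognormal:
TFR·exp(±z·SE). No survey-design (cluster/stratum) variance is attempted;
on the simulator's Poisson-generated data the interval covers the planted
TFR for ~94% of districts, within the expected band for a delta-method
interval.

CPR is the weighted percentage of currently married women 15–49 whose
`using_any_method` flag is set; couple-level use is collapsed into that one
flag. Districts with no married women get a flagged NaN, never a silent 0.

## Robust counterfactual fits

OLS of log TFR on CPR initializes an IRLS procedure: scale is
MAD(residuals)/0.6745, weights are Huber (k = 1.345) until the maximum
coefficient change is below 1e−8, then bisquare (c = 4.685) to the same
tolerance, at most 50 iterations per stage. Non-convergence returns the
last iterate flagged `converged=False` with a warning. If the residual
scale is numerically zero (data on an exact line) the OLS solution is
returned with unit weights — reweighting zero residuals is a 0/0. The
tuning constants give ~95% Gaussian efficiency and are exposed as options;
the exact robust routine behind the published analysis is not stated
anywhere, so this Stata-`rreg`-like scheme is a documented choice, and
statsmodels' bisquare M-estimator is used as an independent cross-check in
the tests rather than as the implementation.

Method 1 classifies districts into quadrants at TFR 2.2 (the national
level) and CPR 50%. "Below" means ≤ for TFR and "above" means ≥ for CPR,
so the corner point (2.2, 50) lands in group 3 (low fertility, high
prevalence); the published grouping language is ambiguous at the boundary
and this convention is fixed here. Each occupied group needs ≥ 3 districts.
Method 2 is the single pooled fit. If a fitted slope comes out positive the
resulting negative PIB is reported as-is with a warning — transparency over
truncation.

The births-averted formula is implemented as BA = (PIB/100)·B, carried in
the same unit as the window birth total B. Published tabulations of this
quantity print a "×1000" in the formula but satisfy BA = (PIB/100)·B
exactly when both are read in thousands, which fixes the "×1000" as a
units annotation rather than a multiplier; this package keeps the unit of
whatever B it is given.

## Aggregation and sensitivity

State/national BA is the sum of district BA; aggregate PIB divides by the
summed births, i.e. a births-weighted mean of district PIBs. The reporting
counts use TFR < 2.1 (replacement level, strict) and CPR > 50 (strict) —
deliberately different thresholds from the Method-1 grouping, both
configurable. Sensitivity summaries quantile the district PIBs by method
within TFR ≤ 2.1 / > 2.1 strata using type-7 (linear interpolation)
quantiles, flag skew by the sign of mean − median, and report the
coefficient of variation of BA as 100·SD/mean with the n−1 denominator.

## Synthetic population

The generator emulates the essentials of a DHS-style individual recode:
women 15–49 nested in districts nested in states, CMC dates, a
currently-married flag, an any-method use flag, and unit weights. Defaults
are the study conditions: 640 districts (32 × 20), CPR uniform on
2.7–84.8% (the observed national range), the pooled law
(β0, β1) = (1.199, −0.0083) with district residual sd 0.1, interview at
CMC 1393 (January 2016). Ages are uniform across the seven 5-year groups at
month resolution. Marriage is Bernoulli(0.72) — roughly the national share
of currently married women 15–49 in the emulated survey round — and
contraceptive use is Bernoulli(CPR_true/100) among married women.

Births are drawn per woman from a piecewise-constant Poisson process whose
age-group rates follow a fixed normalized schedule shape
(0.055, 0.27, 0.31, 0.19, 0.10, 0.055, 0.02; a typical peak at 20–29)
rescaled so 5·ΣASFR equals the district's planted TFR. Only married women
bear simulated births, so their rates carry a 1/0.72 factor keeping the
all-women TFR unbiased for the planted value. Reproducibility comes from
per-district substreams seeded by (seed, district_id): enlarging a
simulation never perturbs existing districts.

What the simulator does **not** reproduce: any individual-level causal link
from a woman's own contraceptive use to her own births (the law is planted
at district level — exactly what the downstream regression can see, and
the published analysis gives no micro-mechanism to copy); household and
cluster structure, nonresponse, and informative weights; realistic age
pyramids or marriage-by-age gradients; method mix and use-effectiveness.
Passing recovery tests therefore shows the estimators are correct for
their estimands, not that the log-linear law holds in any real population.

One structural consequence worth knowing: when data are generated from the
*pooled* law, the Method-1 quadrant boundaries nearly coincide along the
line (TFR = 2.2 maps to CPR ≈ 49.5), so groups 1 and 4 are thin slivers
populated by noise selection. Their group-specific slopes are then
attenuated or even sign-flipped — the warning fires by design — and
Method 1's national total falls below Method 2's. This mirrors the
heterogeneity argument the two-method comparison is meant to expose, but it
means group-level slope recovery is only tested on data generated with
genuinely group-specific laws.

## Problem sizes and tolerances

Unit tests use 24–100 district fixtures; recovery tests use 640 districts
(noise-free recovery to ≥ 6 decimals, σ_ε = 0.1 recovery within 3 SE);
CI coverage uses 500 districts × 300 women; the exposure oracle compares
1,000 random women against a month-by-month brute force, exactly — the
vectorized and brute-force paths aggregate with identical floating-point
operations so agreement is bitwise, not approximate. The analysis drivers
and acceptance script simulate 640 districts × 500 women, which runs in
seconds while keeping per-district Monte-Carlo error (~0.2 births/woman)
small against the planted signal.

## Known limitations

- No survey-design variance anywhere; CIs are model-based Poisson.
- The counterfactual inherits every limitation of the log-linear law:
  no other proximate determinants, no method mix, prevalence assumed
  constant over the window.
- Robust intercepts are not separately validated against any external
  figure; only the correction slopes and the closed-form identities are.
- Districts with zero married women or zero TFR are flagged and excluded
  from the fits rather than imputed.
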