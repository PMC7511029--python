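# avert

District-level counterfactual estimation of **births averted by
contraception** from survey birth histories, for demographers and health
planners who need small-area answers to the question *"how many more births
would this district have seen if no one used contraception?"*

## The method

Across districts, observed fertility and contraceptive prevalence follow a
log-linear law

```
log TFR_i = β0 + β1 · CPR_i + ε_i        (β1 < 0)
```

where `TFR_i` is the total fertility rate estimated directly from women's
birth histories over the 36 months before interview (`TFR = 5 Σ_a ASFR_a`
over the seven 5-year age groups, with a Poisson/delta-method 95% CI) and
`CPR_i` is the weighted share of currently married women 15–49 using any
contraceptive method.

The line is fitted by **robust regression** (iteratively reweighted least
squares, Huber then bisquare weights with MAD scale) so outlying districts
do not distort the slope. Each district's *potential* TFR — fertility at
zero contraceptive use, keeping the district's own residual — is

```
TFRP_i = TFR_i · exp(c · CPR_i),   c = −β̂1
```

from which the percentage increase in births and births averted follow:

```
PIB_i = 100 · (TFRP_i − TFR_i) / TFR_i        BA_i = (PIB_i / 100) · B_i
```

with `B_i` the district's births in the window. Two variants are provided:
**Method 1** stratifies districts into four TFR/CPR quadrants (thresholds
2.2 and 50%) with one robust fit per group; **Method 2** uses a single
pooled fit. District BA sums to state and national totals, whose PIB is the
births-weighted mean of district PIBs.

Individual-level survey microdata of this kind are access-restricted, so the
package ships a synthetic-population generator that plants a known
(β0, β1, σ_ε) law and emits woman-level records (CMC dates, marital and
use flags, weights); every pipeline stage is validated by parameter
recovery against the planted truth.

## Worked example

```sh
python analysis/01_simulate.py        # 640 districts, 500 women each
python analysis/02_estimate.py
python analysis/03_counterfactual.py
python analysis/04_aggregate.py
python analysis/05_sensitivity.py
```

The drivers print, among other things:

```
estimated 640 districts
observed TFR range 1.07-3.97, CPR range 2.0-88.4%
95% CI covers the planted TFR in 93.8% of districts

pooled OLS:    log TFR = 1.1897 -0.00823 * CPR
method 2 pooled (n=640): correction slope +0.00823 (planted 0.00830)

method 1: national BA 12,997 of 64,390 births -> PIB 20.18%
method 2: national BA 26,163 of 64,390 births -> PIB 40.63%

method 1, tfr<=2.1 (n=238): PIB quartiles 31.4/40.0/47.0%, mean 36.3% (skew: left)
method 2, tfr<=2.1 (n=238): PIB quartiles 56.2/73.2/87.6%, mean 71.3% (skew: left)
```

Read: the pooled fit recovers the planted slope (−0.0083) to the third
decimal; absent contraception this synthetic country would have seen ~20%
(stratified) to ~41% (pooled) more births over three years; and the pooled
method systematically exceeds the stratified one, most strongly in
below-replacement districts — the heterogeneity that motivates Method 1.

The same pipeline is scriptable end to end:

```sh
avert run --out artifacts/ --seed 7            # console entry point
```

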