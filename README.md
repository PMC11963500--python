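# mmrproj

Scenario projection of the maternal mortality ratio (MMR) for low- and
middle-income countries (LMICs): joinpoint trend analysis of 2000–2020 MMR
series, four intervention-coverage scale-up scenarios to 2030, and a
cause-and-intervention impact model that attributes additional maternal
lives saved to fourteen maternal health interventions.

The package is aimed at epidemiologists and health planners who want to ask
"what if coverage of these interventions were scaled up?" for a panel of
countries, and at methodologists who want a small, fully tested, seedable
implementation of the underlying arithmetic.

## The model

**Trend phase.** For each country the 2000–2020 MMR series is fit by
joinpoint regression: continuous piecewise-linear regression of ln(MMR) on
calendar year with breakpoints restricted to observed years. Each segment
reports an annual percent change, APC = (e^β − 1)·100, and a year range is
summarised by the length-weighted average annual percent change,
AAPC = (exp(Σ wₛβₛ / Σ wₛ) − 1)·100. Countries are classified by comparing
the 2015–2020 APC with the 2000–2015 AAPC: *increasing* (recent APC > 0),
*stalled* (recent decline slower than before 2015), or *declining*.

**Impact phase.** With baseline MMR *M*, live births *B*, cause-of-death
share *p_c*, and an intervention with coverage change *ΔC*, efficacy *E*
and affected fraction *AF* against cause *c*:

    estimated MMR = M · (1 − p_c · ΔC · E · AF)
    lives saved   = B · (M / 100,000) · p_c · ΔC · E · AF

Multiple interventions acting on one cause combine multiplicatively on the
residual deaths (D_c · Π(1 − eᵢ), with eᵢ = ΔCᵢ·Eᵢ·AFᵢ), and the cause's
total deaths averted are attributed to interventions in proportion to their
independent savings. Coverage changes come from four scenarios: S0 no
scale-up, S1 +2 percentage points/year, S2 +5 pp/year (both capped at
100%), S3 universal coverage (95% by 2030). 80% uncertainty intervals are
propagated from the baseline interval by the estimated/baseline MMR ratio.

The maternal-death cause taxonomy is closed: antepartum, intrapartum and
postpartum hemorrhage (an aggregate hemorrhage share is split 24% / 3% /
73%), hypertensive disorders, sepsis, abortion, other direct, and indirect
causes.

A seeded generator (`mmrproj.synthetic_panel`) produces 126-country panels
with the statistical structure this analysis assumes — piecewise log-linear
MMR trends by income-group band, Dirichlet cause shares, per-intervention
baseline coverage — plus the latent ground truth for recovery testing.

> The packaged intervention registry carries **placeholder** efficacy and
> affected-fraction values (labelled in `mmrproj/data/`). Real analyses
> must supply sourced values via `--interventions my_values.json`.

## Worked example

```
$ mmrproj simulate --seed 42 --n-countries 6 --out panel
wrote 6 countries to panel/
$ mmrproj fit-trends --panel panel --out trends.csv
fitted 6 countries: {'declining': 5, 'stalled': 1}
$ mmrproj project --panel panel --out proj
wrote 24 projection rows to proj/projections.csv
$ mmrproj report --panel panel --out rep
wrote 16 summary rows to rep/summary.csv
```

`trends.csv` holds one row per country with its breakpoint years, segment
APCs, AAPC, 2015–2020 APC and classification:

```
iso3,region,income_group,breakpoints,segment_apcs,aapc_2000_2020,apc_2015_2020,classification
S000,AFR,low,2014,2.0295;-4.7209,-0.044357195861843834,-4.408535141460868,declining
S002,AFR,low,2006;2012,-7.3424;-4.2453;-0.6830,-3.7896572195632805,-0.23698718610561942,stalled
```

(S000's MMR rose 2.0%/yr to 2014 then fell 4.7%/yr; S002's decline slowed
from −7.3%/yr to −0.7%/yr, so it is classified as stalled.)

The world rows of `rep/summary.csv` give the births-weighted group MMR per
scenario with its 80% UI, the percent reduction versus no scale-up, and
total lives saved in 2030:

```
region,income_group,scenario,n_countries,mmr,ui_low,ui_high,pct_reduction_vs_s0,lives_saved,meets_sdg_3_1
world,all,0,6,518.82,465.63,572.01,0.0,0.0,False
world,all,1,6,424.90,381.34,468.46,18.10,6123.17,False
world,all,2,6,328.06,294.43,361.70,36.77,12436.37,False
world,all,3,6,262.06,235.19,288.92,49.49,16739.88,False
```

So on this small synthetic panel, universal coverage roughly halves the
2030 MMR (−49.5%) and averts ~16,740 maternal deaths in 2030, but the group
remains far above the SDG 3.1 threshold of 70 per 100,000 — these numbers
describe the synthetic panel and the placeholder effectiveness values, not
any real country group.

The same operations are available as library calls
(`generate_panel`, `fit_joinpoint`, `classify_trend`, `project`,
`aggregate`, …); see the module docstrings.

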