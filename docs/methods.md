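# Methods

## Scope and model structure

`mmrproj` projects the maternal mortality ratio (MMR, maternal deaths per
100,000 live births among women 15–49) for a panel of low- and
middle-income countries under coverage scale-up scenarios for fourteen
maternal health interventions. The analysis has three phases: (i) joinpoint
trend analysis of each country's 2000–2020 MMR series with a stall/increase
classification, (ii) a cause-of-death profile over a closed eight-cause
taxonomy, and (iii) projection of MMR and additional maternal lives saved
to 2030 under four coverage scenarios, with 80% uncertainty intervals and
regional/income-group aggregation.

Key simplifying assumptions, shared by LiST-style cohort arithmetic:

- Background (non-intervention) mortality is frozen at the 2020 baseline in
  all four scenarios; only intervention coverage changes. The sensitivity
  mode instead extrapolates the 2015–2020 APC with coverage frozen.
- Live births are held constant at their baseline value; there is no
  demographic projection.
- Intervention effects are independent across causes and combine
  multiplicatively within a cause (see below); there are no interactions,
  quality gradients, or herd effects.

## Cause taxonomy and hemorrhage decomposition

The cause set is closed: antepartum/intrapartum/postpartum hemorrhage,
hypertensive disorders, sepsis, abortion, other direct, indirect. Sources
reporting a single hemorrhage aggregate are split 24% / 3% / 73%
(antepartum / intrapartum / postpartum), the fixed partition used
throughout. The postpartum component is computed as the remainder so the
three components sum to the aggregate exactly. Unknown cause labels are
errors, never silently dropped, because the impact formulas index by cause.

## The intervention registry

Fourteen interventions: one periconceptual (safe abortion services), three
pregnancy (tetanus toxoid, micronutrient supplementation, hypertensive
disorder case management), ten childbirth (clean birth environment, MgSO₄
for eclampsia, antibiotics for PROM, antibiotics for maternal sepsis,
assisted vaginal delivery, uterotonics for postpartum hemorrhage, manual
removal of placenta, removal of retained products of conception, cesarean
delivery, blood transfusion). Each carries per-cause efficacy and affected
fraction in [0, 1].

The packaged default values are **placeholders** (efficacies 0.5–0.9,
affected fractions 1.0, cause mappings chosen for plausibility). Published
effectiveness databases license their own values; an analysis intended to
say anything about the real world must supply them via a JSON config. The
placeholders exist so the pipeline is runnable and testable end to end.

## Joinpoint trend model

ln(MMR) is modelled as continuous piecewise-linear in calendar year.
Breakpoints are restricted to observed (integer) years, at most three, with
at least three observations per segment (a breakpoint observation counts
toward both adjacent segments). For each candidate breakpoint count k, all
admissible placements are enumerated and fit by least squares on a hinge
basis; 21 annual points make exhaustive search cheap (< 500 placements at
k = 3).

**Model-size selection.** The breakpoint count is chosen by nested-model
F-tests on the best placement per count: accept count k when the F-test of
best-k against best-(k−1) (2 numerator df per added joinpoint, residual df
n − 2 − 2k) is significant at α = 0.05 Bonferroni-corrected by the number
of admissible placements searched at stage k; the selected count is the
largest significant k, evaluated without early stopping because a single
joinpoint can fail to improve a down-up-down series that two joinpoints fit
decisively. We initially used BIC with the usual 2(k+1)·ln(n)/n penalty,
but at n = 21 its fixed penalty is regularly beaten by noise-driven RSS
gains (≈19% spurious-joinpoint rate at observation noise sd 0.005), whereas
the F-test scales the evidence by the residual degrees of freedom; the
switch raised ground-truth recovery from ~81% to 97–99% on 200-series
experiments. Ties and degenerate perfect fits are handled by flooring the
RSS at 10⁻¹⁸ per observation, which makes all numerically perfect fits
compare equal so parsimony wins.

APC = (e^slope − 1)·100 per segment; AAPC over a window is the
length-weighted geometric average of segment slopes. The classification
rule refits a single segment to the 2015–2020 window (rather than reusing
the selected segmentation) so the 2015 pivot is honored even when no
breakpoint falls there: *increasing* if that APC > 0, *stalled* if it is
non-positive but less negative than the 2000–2015 AAPC, *declining*
otherwise.

## Scenarios

S0 holds coverage at baseline (2024). S1/S2 add 2/5 percentage points per
year, capped at 100%. "Increased by 2%" is read as absolute percentage
points — the convention of coverage scale-up analyses and the reading under
which a 100% cap is meaningful; a relative-growth reading is available via
`increment_is_relative=True`. S3 interpolates linearly from baseline to 95%
at 2030 and never reduces coverage already above 95%. Trajectories are
monotone non-decreasing and coverage change is scenario coverage minus
baseline coverage, always ≥ 0 for the built-ins.

**Scenario ordering caveat.** Universal coverage (S3) does not dominate the
+5 pp/yr scenario (S2) intervention-by-intervention: from baseline b, S2's
2030 coverage change is min(b + 0.30, 1) − b while S3's is
max(0.95 − b, 0), so S2 exceeds S3 whenever b > 0.65. On realistic panels
the aggregate over fourteen interventions almost always orders
MMR(S3) ≤ MMR(S2) because low-coverage interventions contribute the largest
gains, but it is not a mathematical invariant; with the default generator
(coverage uniform on 0.2–0.9) a 126-country panel typically has 0–2
countries where S3's aggregate MMR slightly exceeds S2's. The acceptance
script reports the observed violation count rather than hiding it.

## Impact arithmetic

Baseline deaths D = B·M/100,000 are split over causes by the cause profile.
For cause c, each targeting intervention i contributes effect
e_ic = ΔC_i·E_ic·AF_ic, residual deaths are D_c·Π_i(1 − e_ic), and the
averted deaths D_c·(1 − Π(1 − e_ic)) are attributed to interventions
proportionally to their independent savings D_c·e_ic. This cascade is
order-independent, keeps residuals non-negative for any registry, sums
attribution exactly to the total averted, and reduces to the two printed
single-intervention formulas when one intervention targets the cause.

Lives saved are reported as annual deaths averted in the horizon year
(default 2030); a cumulative 2025–2030 mode sums the annual figures over
the scale-up period.

**Uncertainty.** The 2020 80% UI is mmr ± 1.2816·se (10th/90th normal
percentiles), lower bound floored just above zero. Projection UIs scale
both baseline bounds by the estimated/baseline MMR ratio — the simplest
rule consistent with deriving 2030 intervals from the 2020 interval; it
preserves the interval's relative width and ignores uncertainty in the
intervention parameters themselves.

**Aggregation.** Group MMR is births-weighted: Σ deaths / Σ live births ×
100,000 — the standard way to aggregate a ratio indicator; an unweighted
country mean would let small countries dominate. Group percent reductions
are recomputed from aggregated MMRs, and group UI bounds are
births-weighted means of country bounds.

## Synthetic panel generator

The generator emulates the structure, not the values, of real multi-country
inputs: 126 countries allocated over six WHO regions × three income groups
(allocation table loosely mirroring the real LMIC distribution); 2020 MMR
drawn log-uniformly within income-group bands (low 300–700, lower-middle
70–400, upper-middle 10–170); a piecewise log-linear latent trend built
backwards from the 2020 anchor with 0–2 breakpoints, segments of ≥ 6 years
and APCs in [−8%, +3%]; log-normal observation noise (sd 0.01 on ln MMR);
Dirichlet cause shares (concentration 50 around plausible means, hemorrhage
drawn as an aggregate then decomposed); coverage uniform on 0.2–0.9; 2020
relative SE 8%; live births log-uniform on 20,000–3,000,000. Adjacent
segment APCs differ by ≥ 2 pp so that breakpoints are identifiable — a
deliberate generator property that real series do not guarantee.

Each country uses a dedicated random substream keyed by (seed, index), so
records are bit-reproducible and independent of generation order.

What passing tests on this generator do *not* show: robustness to
non-log-linear trends, COVID-type level shocks, correlated errors across
countries or years, missing years, or real effectiveness values. Trend
recovery results in particular are conditional on the generator's
identifiability guarantees.

## Numerical choices

- All fractions live in [0, 1] internally; percent only at I/O boundaries.
- Shares must sum to 1 within 1e-9 (1e-6 at the CSV boundary to tolerate
  decimal round-tripping); conservation of deaths is checked to 1e-6.
- RSS floor 1e-18 per observation in model selection (see above);
  selection ties break toward fewer breakpoints.
- Joinpoint search: max 3 breakpoints, min 3 observations per segment,
  α = 0.05 with per-stage Bonferroni correction.
- Problem sizes used in the shipped experiments: the default 126-country
  panel for projection properties, 200 series at noise sd 0.005 for trend
  recovery, 1,000 draws for the formula-identity and Monte-Carlo UI checks
  — sizes at which the checked quantities are stable to well within their
  test tolerances.

## Known limitations

- Placeholder effectiveness values: shipped numbers demonstrate mechanics
  only.
- No inference on APCs (no confidence intervals or permutation tests); the
  F-test selection controls model size, not published significance claims.
- UI propagation ignores parameter uncertainty and between-country
  correlation; aggregated UIs are means of country bounds, not a joint
  posterior.
- The stall classification compares point estimates; near-zero differences
  between pre- and post-2015 rates flip classes under small perturbations.
- Countries are generated and projected independently; no spillovers,
  no common shocks, constant live births.
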