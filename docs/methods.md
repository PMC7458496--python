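# Methods

## Scope and inputs

`swiburden` estimates the annual economic and care burden of sternal-wound
infections (SWIs) after CABG at a country's procedure volume, and prices
value-based purchasing (VBP) contracts for preventive interventions. One
country is described by ten parameters, all in 2017 US$ where monetary:
annual CABG volume; superficial and deep SWI incidence (percent of
procedures); readmission probability given a post-discharge SWI; additional
length of stay (LOS) for superficial and deep SWIs; daily ICU and
general-ward (GW) costs; and baseline ICU and GW stays. `cabg_per_100k` is
an alternative entry route for volume (converted with a user-supplied
population) and does not count toward inclusion.

Data handling follows three pinned rules:

* **Multi-study merge** — when several studies report the same quantity the
  midpoint of the reported range, `(min + max)/2`, is used. With more than
  two studies this still spans the extremes; a mean-based merge can be
  substituted by the caller before table assembly if preferred.
* **Inclusion** — countries with at least 5 of the 10 parameters observed
  enter the model.
* **Imputation** — missing cells take the cross-country median of the
  field; the field's cross-country IQR is stored with the cell and later
  used as its uncertainty range in the PSA. Quartiles are linear
  interpolation between order statistics (numpy default, "type 7")
  everywhere in the package.

## Incidence model

Cumulative SWI incidence is a Hill curve
`F(t) = α + θ t^η/(K^η + t^η)` (percent of patients; α = 2.96e-30,
θ = 6.93, η = 1.08, K = 23.73 days). The shape is shared across countries;
each country's curve is multiplied by `observed incidence / F(30)` so that
the scaled curve hits the country's total SWI incidence at the 30-day
reference point (configurable; 30 d is the follow-up at which national
incidences are typically reported). The curve is converted to a fraction and
differenced into daily conditional hazards
`h(t) = (F(t) − F(t−1))/(1 − F(t−1))`; the product identity
`1 − Π(1−h) = F` holds to 1e-12 on the daily grid and is asserted in tests.
The severity split (deep share of all SWIs) is applied as a time-constant
proportional split of the hazard — no severity-specific timing information
exists in the source data. Countries reporting only a total incidence must
supply an assumed deep share explicitly; there is no silent default.

## Care-pathway Markov model

Daily cycles over a 90-day horizon (configurable; K = 23.73 d puts the
curve's half-maximum near day 24, so 90 days captures >85% of the
asymptote). States:

```
ICU_VENT → ICU → GW → HOME                    (baseline, at risk)
ICU_INF_S/D → GW_INF_S/D → SSWI/DSWI_CARE     (infected, baseline completes first)
HOME → READMIT → SSWI/DSWI_CARE               (post-discharge onset, readmitted)
HOME → HOME_POST_SWI                          (post-discharge onset, not readmitted)
SSWI/DSWI_CARE → HOME_POST_SWI;  DSWI_CARE → DEAD
```

Design choices, in order of consequence:

* **Additional LOS is truly additional.** An inpatient who develops an SWI
  first completes the remainder of the baseline ICU/GW stay in an infected
  track (same exit rates, no further first-SWI hazard), then serves the
  severity-specific SWI-care stay. Because geometric dwells are memoryless,
  the expected realized excess stay equals the stated additional-LOS input
  (up to horizon truncation, and death during deep-SWI care). Routing
  infected patients directly into care would silently cancel part of the
  extra stay against the forfeited baseline remainder.
* **Dwell times are geometric** with mean equal to the stated LOS (exit
  probability 1/mean; sub-day stays exit after one cycle). Only mean LOS
  values are available, and a geometric dwell is the one-parameter Markov
  representation of a mean.
* **First SWI only.** The cumulative curve describes first infections, so
  post-SWI patients (HOME_POST_SWI) leave the risk set. This bookkeeping
  state is the reason the hazard calibration reproduces the curve exactly.
* **Readmission** — SWI onset at home triggers readmission with the country
  probability; the admission day (READMIT) is costed at the GW rate and the
  care stay follows with the same additional-LOS dwell, i.e. readmission
  LOS is included in, not added to, the additional-LOS inputs.
  Non-readmitted home-onset cases are counted as events but carry no
  modeled bed-day burden (outpatient wound care is outside scope).
* **Mortality** — a daily death probability applies in deep-SWI care only,
  solved from the competing-risks identity `CFR = d/(d + (1−d)p_exit)` so
  the episode case fatality equals a configurable target (default 15%, the
  midpoint of the 7–35% range reported for deep SWIs). Background and
  superficial-SWI mortality are zero: the model measures SWI-attributable
  excess against a baseline in which the same cohort survives.
* **Ventilation** is the first ICU day (ICU_VENT); no ventilation-specific
  cost exists among the inputs, so it is costed as an ICU day.
* **Deep-SWI care setting** — 20% of deep-care days in an ICU bed by
  default (configurable); deep infections routinely require ICU-level care
  but predominantly ward-based convalescence.

The deterministic cohort engine propagates occupancy fractions (row sums
conserved to 1e-9, transition rows to 1e-12). A patient-level Monte-Carlo
simulator draws trajectories from the same matrices and is used as an
independent oracle: on every accumulator the two engines agree within
sampling error (asserted at 4 SE with n = 50 000).

**Event accounting.** SWI events count all first infections — inpatient
onset plus post-discharge onset, readmitted or not — matching how published
per-country event columns relate to procedure volumes. The *hospital SWI
rate* `r_swi` used by the VBP calculator is narrower: inpatient events plus
readmissions, the events a hospital sees and pays for.

## Burden

Excess ICU days, excess GW days and readmission admission days are
differences between the SWI run and a zero-hazard baseline run of the same
model; each component is costed at the country's daily rate (readmission
days at the GW rate — no readmission-specific cost input exists). The three
components sum to the total exactly. Mean cost per SWI divides by all
events (null, not zero, when there are none); mean SWI cost per CABG divides
by procedures. Cross-country summaries aggregate unrounded values; rounding
to whole dollars is presentation-only.

## Probabilistic sensitivity analysis

Each of the default 52 iterations (a study-design default, not a constant)
redraws all ten parameters and reruns calibration → pathway → burden:

* gamma for costs, LOS and volume (mean = point estimate; SD = 20% of the
  mean by default);
* beta for incidences (on the fraction scale) and probabilities, matched by
  mean, with the SD truncated to keep the parameterization feasible;
* imputed cells use their stored cross-country IQR as the central 50%
  interval (SD = width/1.349, the normal IQR→SD conversion).

Every (country, draw, field) triple owns an independent seeded substream,
so pinning or adding one field never perturbs another's draws, and a fixed
seed gives bit-identical summaries. Summaries report median, range, type-7
IQR and sample SD (ddof = 1).

## VBP calculator

With relative risk `RR`, cost per SWI `C`, hospital rate `r`, purchase share
`S_PUR`, savings share `S_SAV`, `N_INT` interventions and `N_PT`
patients/yr:

```
CIPP = (1−RR)·C·r·(S_PUR/100)/N_INT
VBP  = [r·N_PT·C·(1−RR) − CIPP·N_INT·N_PT]/(100·N_INT)·S_SAV
hospital savings = gross − purchase − N_INT·VBP,  gross = r·N_PT·C·(1−RR)
```

The published typeset formulas are ambiguous about grouping; this
reconstruction reproduces the published hospital worked example to the cent
(CIPP US$16.81, VBP US$14 121.84 with the rounded CIPP) and is adopted as
canonical. At the computed CIPP the bracket equals `gross·(1−S_PUR/100) ≥ 0`,
and savings + payouts + purchase = gross exactly (asserted on 1000 random
scenarios). A CIPP above break-even yields a negative VBP, reported with a
warning, never clamped. The published prose figure for the worked example's
annual hospital savings (US$87 036) is not reproducible from any grouping of
the stated formulas (the identity above gives US$98 852.88); it is
documented here and excluded from verification. Scenario constants:
scenario 1 = 50% purchase share, 2 interventions, 15% savings share;
scenario 2 = 30%, 2, 25%; both at RR = 0.8 and 1000 CABG/yr.

## Synthetic country generator

The study's extraction table is not deposited, so tests and examples run on
synthetic countries drawn from the published ranges: CABG rate
6.4–61.4/100k (times a log-uniform population of 5–330M), total SWI
incidence 2.8–10.4%, deep incidence 0.8–3.4% (capped at 90% of total),
superficial additional LOS 2–49 d, deep additional LOS 14–66 d (the upper
bound is the longest published national average; the lower bound reflects
that mediastinitis care is measured in weeks, and deep care is constrained
to be at least as long as superficial), daily costs log-uniform over
ICU 800–8000 and GW 150–2500 US$ (Brazil-like to Japan-like magnitudes),
readmission probability 0.1–0.5, baseline ICU 1–4 d and GW 4–10 d.
Non-cost fields are uniform — the least-assuming choice when only extremes
are published. The generator stores the pre-missingness ground truth so
imputation and calibration recovery can be scored.

What the generator does **not** emulate: real inter-parameter correlations
across countries (cost structures correlate with LOS and volume in reality),
country-specific severity timing, and any within-country heterogeneity.
Passing tests therefore demonstrate the *engine's* correctness and the
plausibility of its output ranges, not agreement with any real country's
burden.

## Numerical choices and degenerate inputs

* Quartiles: type 7 everywhere; sample SD with ddof = 1.
* Hazards clipped to [0, 1]; a curve reaching 100% inside the horizon is an
  error, as is a non-positive calibration denominator.
* LOS ≤ 1 day gives a one-cycle dwell (exit probability capped at 1).
* Zero SWI events → cost per SWI is null; zero total incidence → deep share
  0 and a hazard of exactly 0, reducing the model to the baseline pathway.
* Horizon truncation: stays still open at day 90 stop accruing; with
  default LOS magnitudes this loses <1% of expected days, but extreme
  LOS (≥50 d) near the horizon end loses more — extend the horizon for
  such inputs.
* Problem sizes in the shipped tests are chosen for tight statistical
  checks at interactive runtimes: Monte-Carlo oracle at n = 50 000,
  calibration recovery over 200 binomial replicates of n = 100 000,
  conservation over 100 random models, PSA at the default 52 iterations.

## Known limitations

* The state machine is a reconstruction of a prose-described care pathway;
  the original model's internals are not public.
* Patient-level risk factors (obesity, diabetes) are not modeled beyond
  what country-level incidence encodes.
* Sub-90-day readmission is tied to SWI onset only; unrelated readmissions
  are out of scope.
* PSA distribution families and spreads are a modeling convention; the
  original analysis did not state its own.
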