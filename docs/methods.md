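# Methods

## Model overview

`mammocea` implements a closed-cohort state-transition (Markov) model of
population mammography screening. A hypothetical cohort of 10,000 women
enters at age 50 and is followed for 50 annual cycles without
replenishment. Screening is offered biennially between ages 50 and 69
inclusive (10 rounds) under one of three reading workflows that differ
only in test characteristics and per-scan price:

| strategy      | sensitivity | specificity | per-scan cost (SGD) |
|---------------|------------:|------------:|--------------------:|
| conventional (double reading) | 0.691 | 0.954 | 110.00 |
| AI companion (one radiologist + AI) | 0.715 | 0.968 | 97.50 |
| AI standalone | 0.805 | 0.893 | 80.00 |

The per-scan prices are linked by a fee-substitution rule: the
double-read price contains two radiologist reading fees; the companion
workflow replaces one fee with the AI service fee (SGD 5), the
standalone workflow replaces both. A single read fee of SGD 17.50 makes
all three printed prices mutually consistent
(110 − 17.50 + 5 = 97.50; 110 − 2×17.50 + 5 = 80), and the package
stores the fee explicitly so the rule is checkable in both directions.

## State space and cycle composition

States: Healthy; undiagnosed (preclinical) cancer by stage 0–IV;
diagnosed (treatment year) by stage; remission (surveillance) by stage;
a single stage-invariant recurrence state; death from breast cancer;
death from other causes. Both death states are absorbing.

Within a cycle, competing events are composed multiplicatively in a
fixed order — other-cause death, breast-cancer death, screen detection
(screening cycles only), clinical/interval detection, stage
progression, onset — so each later event is conditioned on the earlier
ones not occurring. This guarantees valid rows (each sums to one by
construction, checked to 1e−9) without any rate-to-probability
conversion ambiguity. Interval cancers are not a separate state: they
are undiagnosed→diagnosed transitions through clinical detection in
non-screening years or after a false-negative screen, tallied
separately for reporting.

Structural moves: women diagnosed in cycle *t* spend one cycle in the
diagnosed (treatment) state and then move deterministically to
stage-specific remission; remission can relapse into recurrence at a
stage-at-diagnosis-specific annual rate; recurrence survivors return to
remission after one cycle of recurrence treatment. Because the
recurrence state is stage-invariant, the stage at diagnosis is no
longer known at that point; survivors are routed to Remission(IV),
treating recurrent disease as clinically advanced. This slightly
overstates post-recurrence surveillance cost relative to routing to a
lower stage; the recurrence flow is small, so the effect on incremental
results is second-order.

Breast-cancer mortality applies to undiagnosed and diagnosed disease by
stage and to recurrence at its own rate; women in remission face only
other-cause mortality (breast-cancer death after remission requires a
relapse first).

Burn-in: the cohort starts all-Healthy at age 49 and runs one
pre-screening cycle (no screening), so preclinical prevalence exists at
the first round. Cycle tallies start at age 50; burn-in deaths appear
in the initial occupancy but not in event tallies, and the
microsimulation mirrors this convention.

Screening eligibility covers Healthy and undiagnosed women only;
diagnosed/remission/recurrence women are under clinical surveillance,
whose cost is booked by the economics module rather than as mammogram
events. Compliance is by default an independent per-round attendance
probability applied to the eligible pool (a cohort-expectation model);
a fixed-attender variant — the compliant fraction is a fixed subgroup
attending every round — is available via `policy.fixed_attenders` and
is implemented by splitting the cohort into always- and never-attend
subcohorts.

## Economics

Per cycle *t* (discount factor `1/(1+r)^t`, r = 3%/year):

- screening cost = mammograms × per-scan price;
- work-up cost = recalls (TP + FP) × (ultrasound + biopsy fraction × biopsy);
- treatment cost = diagnosed occupancy × stage cost (stage 0–IV);
- remission surveillance = remission occupancy × remission fraction × stage cost;
- recurrence management = recurrence occupancy × stage-invariant annual cost;
- QALYs = occupancy × state utility (dead = 0).

Costs and QALYs are booked at cycle start with the same discount
exponent; asymmetric timing would shift ICERs artefactually. A
half-cycle correction (half weight on the first and last cycle's
state-occupancy terms, events untouched) is available and off by
default. Accumulation is additive over disjoint cycle ranges on the
global discount clock.

Incremental analysis reports Δcost, ΔQALYs, the ICER when ΔQALYs ≠ 0,
and net monetary benefit `WTP × ΔQALYs − Δcost` at the configured
willingness-to-pay (SGD 50,000/QALY, ≈ 1 GDP per capita). A
cost-saving, QALY-gaining comparison is labelled *dominant* and the
signed (negative) ratio is still reported, i.e. savings per QALY
gained; equal-QALY comparisons get a dominance-by-cost label and no
ratio. Reported ICERs always come from full-precision totals — dividing
independently rounded cost and QALY cells generally does not reproduce
a full-precision ICER, which is why tables carry a full-precision JSON
companion.

## Uncertainty analysis

**One-way (tornado) DSA.** Each listed parameter is set to 0.9× and
1.1× its base value (others at base) and the full pipeline is rerun;
the two ICERs versus conventional reading are tabulated and sorted by
range width. Probabilities pushed outside [0, 1] are clipped with a
logged warning, never silently. The default parameter list covers the
test characteristics and per-scan costs of both compared strategies,
compliance, biopsy cost, stage-I treatment cost, and the recurrence and
stage-I utilities. When a perturbation flips the sign of ΔQALYs the
ICER jumps across ±∞ and the base-case ICER can fall outside the
tabulated range; the table records this (`contains_base`) and logs it
rather than hiding it — with ratio statistics this is a feature of the
measure, not a bug of the model.

**PSA.** Each of 10,000 Monte Carlo draws resamples every cost
parameter from a Gamma distribution (mean = base value) and every
utility from a Beta distribution (mean = base value, absolute
SD = 0.05), with shape parameters from the method of moments
(Beta: ν = m(1−m)/s² − 1, α = mν, β = (1−m)ν; Gamma: shape = (m/s)²,
scale = s²/m). An absolute SD of 0.05 is meaningful for utilities but
not for SGD amounts, so cost dispersion is a coefficient of variation
of 0.05; both dispersions are configuration-exposed
(`uncertainty.cost_cv`, `uncertainty.utility_sd`). Structural
parameters — sensitivity, specificity, compliance, transition
probabilities, and the dimensionless remission/biopsy fractions — are
held fixed. Draws use one root seed with per-draw child streams and
common random parameters across strategies within a draw, which reduces
CEAC variance because the strategies share the same world state.

Because the sampled parameters do not enter the transition dynamics,
the cohort trace is invariant across draws: `run_psa` computes each
strategy's trace once per compliance scenario and repeats only the
economic accumulation per draw. This is an exact factorization, not an
approximation. Draws producing non-finite totals are rejected and
logged; more than 1% rejections aborts the analysis.

**CEAC.** At each point of the WTP grid (default 0–100,000 SGD in
2,500-SGD steps, covering the decision-relevant landmarks) the strategy
maximising NMB is counted across draws; probabilities sum to one per
WTP by construction. Scenarios at 20/40/80% compliance probe the
sensitivity of the ranking to participation.

## Synthetic natural history

No registry-grade parameter table ships with the package; the
`synthetic` module generates complete, internally consistent bundles
instead, and its defaults define the reference scenario:

- **onset**: logistic in age, `scale/(1+exp(−(a−62)/8))` with scale
  0.003/year, rising from ≈0.0005/year at 49 to ≈0.003/year at 90;
  cumulative lifetime onset over ages 49–99 ≈ 9.7%, i.e. near the
  familiar 1-in-10-to-13 lifetime risk;
- **preclinical dwell**: mean sojourn 2 / 1.5 / 1.5 / 1.25 years in
  stages 0–III (annual progression = 1/dwell); stage IV does not
  progress;
- **clinical detection**: 0.05 × 2^stage per year (0.05 → 0.8),
  non-decreasing in stage — later-stage disease presents more readily;
- **breast-cancer mortality**: 0.002 × 3.2^stage per year
  (0.002 → 0.21); recurrence 0.12/year;
- **other-cause mortality**: Gompertz-like, 0.0025 × e^{0.085(a−50)},
  registry-like in shape and non-decreasing in age;
- **costs**: stage treatment 20,000 × 1.35^stage SGD (20,000 → 66,430),
  remission surveillance 10% of stage cost per year, recurrence
  30,000 SGD/year, ultrasound 180, biopsy 1,000 (50% of recalls),
  non-decreasing in stage;
- **utilities**: healthy/undiagnosed 0.98, diagnosed by stage
  0.94/0.90/0.84/0.74/0.60, remission 0.88, recurrence 0.68. The
  healthy utility is 0.98 rather than 1.0 because the PSA draws every
  utility from a Beta with SD 0.05, which is undefined at mean 1.

A `jitter` knob perturbs the scale-type parameters multiplicatively
from the spec's seed, generating families of distinct bundles that
still satisfy every validation invariant — used by the property tests.
The generator never clips: any spec producing a probability above one
raises an error naming the offending age or stage.

What the generator does *not* emulate: calendar-period trends in
incidence or treatment, age-dependence of test characteristics,
overdiagnosis of indolent lesions, ethnic or socioeconomic
heterogeneity, and correlation between attendance and risk. Passing
tests therefore demonstrate the correctness and internal consistency of
the machinery on a realistic synthetic world, not the calibration of
any particular national programme; with the reference defaults the
diagnostic-event magnitudes (≈38,000 mammograms, ≈1,700 vs ≈1,200 vs
≈4,000 false positives across the three strategies at 40% compliance)
are of the magnitude reported for screening programmes of this design,
because they are driven mostly by the printed test characteristics.

## Microsimulation oracle

`synthetic.microsimulate` simulates n independent individual life
histories with per-cycle Bernoulli events in exactly the cohort
engine's composition order (including the untallied burn-in year) and
scales tallies to the cohort size, with per-tally Monte Carlo standard
errors from the person-level variance. At n = 200,000 every cohort
tally — mammograms, TP/FP/TN/FN, detections by stage and mode, onsets,
deaths by cause — agrees within three standard errors across all three
strategies and all three compliance scenarios; this is the package's
central validation that the closed-form expectation engine and the
stochastic process it claims to summarise are the same model.

## Numerical choices

- conservation checked every cycle: total occupancy must stay within
  1e−6 persons of the cohort size (double precision leaves ~1e−9 drift);
- transition rows checked to 1e−9 at build time;
- NMB argmax ties broken by first index (strategy insertion order);
  ties have measure zero under continuous PSA draws;
- money kept as full-precision floats; rounding (2 d.p. money, 1 d.p.
  QALYs) only at report time, with full precision in companion JSON;
- all randomness flows from `numpy.random.SeedSequence` roots; reruns
  with the same seed are bit-identical.

## Known limitations

- Psychological disutility of false positives and overdiagnosis is not
  modelled; false positives carry work-up costs only.
- Test characteristics are fixed scalars — no reader variability, no
  AI threshold tuning, no age dependence.
- The recurrence state forgets stage at diagnosis (see above).
- Treatment lasts exactly one cycle; no treatment-phase granularity.
- The synthetic reference world is plausible but uncalibrated; absolute
  costs/QALYs should be read as model output for the reference
  scenario, not as forecasts for any specific health system.

## Problem sizes

Default analyses: 10,000-person cohort expectation over 50 cycles
(milliseconds); tornado over 11 parameters (≈0.1 s); PSA with 10,000
draws × 3 compliance scenarios (≈5 s); microsimulation oracle at
n = 200,000 per strategy/compliance combination (≈1 s each). The test
suite runs the full grid of nine microsimulation comparisons.
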