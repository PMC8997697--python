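# Methods

## Model structure

The model is an individual-level state-transition (Markov) simulation with
a 3-month cycle and a lifetime horizon capped at 20 years (80 cycles).
Health states are: event-free; post-MI; post-ACS; post-stable-angina;
post-stroke; post-TIA; post-heart-failure; post-serious-fall; post-AKI;
dead. Dead is absorbing. Only the **first** serious event changes state:
afterwards the patient keeps that state's mortality multiplier and
long-term costs, and the only remaining cycle risks are death and minor
adverse events (no recurrent events, no treatment changes after an event,
no terminal-care costs).

### Competing risks within a cycle

Per-cause per-cycle probabilities (death, CHD event, cerebrovascular
event, heart failure, serious adverse event, minor adverse event) are
treated as independent causes and combined into a single multinomial:
P(no event) = Π(1 − p_i), and cause *i* receives probability
(1 − Π(1 − p_j)) · p_i / Σp_j. This keeps the total at most 1 for any
parameter draw and reduces to the marginals when probabilities are small.
A sequential-draw alternative was considered and rejected because it makes
cause priority an implicit modelling choice; the product construction is
order-free.

### Timing conventions

Events sit at cycle midpoints, consistent with the half-cycle correction:

- the new state's utility multiplier and the acute event cost apply in the
  event cycle;
- long-term post-event care costs start the **following** cycle (keyed to
  the state at cycle start), so the event cycle is never double-charged;
- the cycle in which a patient dies accrues **half** of its recurring
  utility and cost, at the pre-death state's utility. One-off visit costs
  (safety/reinstatement, which fall early in their cycle) are charged in
  full.
- the half-cycle correction itself is implemented as midpoint discounting:
  the cycle-k accrual is valued at (k + ½) × 0.25 years. For per-cycle
  accruals this is equivalent in effect to the classic
  half-credit-first/last-cycle scheme and simpler to reason about;
  switching `half_cycle_correction` off values accruals at cycle starts.

### Hazards and the treatment effect

All time-scale conversions use a constant hazard within the band:
`prob_rescale(p, from, to) = 1 − (1−p)^(to/from)`. The prior-CVD
multiplier (1.5) and the post-event standardized mortality ratios act on
the hazard (log-survival) scale, e.g. post-stroke per-cycle death is
1 − (1 − qx)^(2.72 × 0.25); this keeps every probability in [0, 1] for any
multiplier.

Medication reduction raises systolic BP by `delta_sbp_mmhg` (base 3.4,
95% CI 1.0–5.8, the trial's intention-to-treat difference). Relative
risks quoted at `reference_delta_mmhg` are rescaled by log-linear
interpolation RR^(Δ/Δ_ref). In the bundled base configuration
`reference_delta_mmhg = 3.4`: the tabulated RRs (CHD 1.009, stroke/TIA
1.108, HF 1.290, adverse events 0.685) are taken to correspond to the
trial's own BP difference, so interpolation is the identity in the base
case and scales the RRs in ΔSBP scenarios (e.g. the lower-CI 1.0 mmHg
run applies RR^(1/3.4)). Users who read the tabulated RRs as
meta-analysis values at a different BP contrast set `reference_delta_mmhg`
accordingly; it is a required config value precisely because this reading
is ambiguous.

The effect is applied arm-wide (intention-to-treat): patients who do not
maintain the reduction still carry the arm-level RRs, and
`maintained_reduction` (Bernoulli 0.663 at entry) affects only the
prescription-cost stream and the reinstatement visit. RRs revert to
exactly 1 after `effect_duration_years` (step function, no taper);
the base case is lifetime.

CVD events split CHD:cerebrovascular 50:50; the subtype (MI/ACS/angina,
stroke/TIA) comes from sex × age-band tables (75–84, 85+, looked up at the
patient's **current** age, which advances 0.25 y per cycle). Serious
adverse events split fall:AKI 0.52:0.48. Minor adverse events pick one of
the five minor types uniformly (their composition is not published); they
change no state and can recur. Whether CVD events carry an acute case
fatality separate from the SMR mechanism is not specified in the source
material; the model uses SMR-adjusted mortality only.

## Mortality

Background mortality is an annual life-table probability `qx_noncvd` by
single year of age and sex with circulatory deaths removed (to avoid
double-counting CVD deaths, which the event pathway models). The bundled
table (`lifetable_synthetic.csv`) is a **synthetic** Gompertz
approximation of England & Wales 2016–2018 non-circulatory mortality,
qx = 0.75 · b · e^(s·(age−80)) with (b, s) = (0.058, 0.095) for men and
(0.046, 0.100) for women, capped at 0.7, ages 80–110; ages beyond the
table use the terminal row. Supply a real table with
`--lifetable` (CSV `age,sex,qx_noncvd`) for applied work.

## Utilities

Baseline EQ-5D index 0.769. Post-event multipliers: stroke 0.629, MI
0.778, ACS 0.77, stable angina 0.88, HF 0.68, serious fall 0.797.
Annual decrements: TIA 0.103 and the minor-event decrements (hypotension
0.029, others 0.1) last one month and are averaged into the event cycle
(QALY loss = decrement/12). The AKI decrement (0.15) is read as an
absolute reduction of the utility score applied every cycle for life, per
the source's "applied every 3 months for life". Utility is floored at 0
(no worse-than-dead states). No age- or time-trend in utility beyond
modelled events.

## Costs

GBP at 2017/18 prices. Routine: 0.8 consultations per 3-month cycle
(published assumption) × unit cost, plus per-drug prescription costs for
the drugs actually dispensed that cycle. The reduction arm adds a 4-week
safety visit (cycle 1) and, for non-maintainers, one reinstatement visit.
Acute event costs accrue in the event cycle; long-term per-cycle care
costs in post-event states. **Every unit cost in the bundled table is a
placeholder** (order-of-magnitude UK reference costs) carrying the
provenance flag `non-paper-default`; the published analysis's unit-cost
appendix is not publicly available. Minor adverse events cost 0 by
default (configurable). Discount rate 3.5%/year for both costs and
outcomes.

## Synthetic cohort generator

Emulates the baseline structure of the deprescribing-trial population —
adults ≥ 80 on ≥ 2 antihypertensives:

| dimension | distribution | published target | non-published choice |
|---|---|---|---|
| age | 80 + gamma offset | mean 84.8 y | SD 3.5 y |
| sex | Bernoulli | 51.5% male | — |
| prior CVD (0/1/2+) | categorical | 42.9/29.5/27.6% | — |
| EQ-5D index | normal truncated at 1 | mean 0.769 | SD 0.2; location calibrated so the *truncated* mean hits 0.769 |
| 10-y CVD risk | beta | "patient specific" | mean 0.35, concentration 10 |
| frailty | Bernoulli | — | 50% frail |
| drug count | categorical | ≥ 2 | 2 or 3, equiprobable |

Dimensions are drawn independently; the joint distribution (e.g. the
age–risk correlation that a risk score would induce) is unknowable from
published moments, so passing calibration tests shows the *marginals* are
right, not the dependence structure — subgroup results by frailty or
comorbidity should be read accordingly. 10-year risk is consumed directly
(a risk-score calculation from covariates is out of scope); a
`ten_year_cvd_risk` column in a user cohort CSV overrides the generator.

## Probabilistic sensitivity analysis

Each uncertain parameter carries a distribution: beta for probabilities
and utilities, gamma for costs, lognormal for relative risks and SMRs.
With a 95% CI, lognormal specs match the median to the point estimate and
take σ = (ln hi − ln lo)/(2·1.96) (for wide CIs the lognormal mean then
exceeds the point estimate — the cost of preserving the quoted CI);
beta/gamma specs moment-match the mean with SE = CI width/3.92. Without a
CI, SE = 20% of the mean (a standard convention; overridable per
parameter). Draws violating a hard bound (probability outside [0, 1],
SMR < 1) are redrawn up to 100 times and then raise — never silently
truncated. `delta_sbp_mmhg` is held fixed in PSA: the published analysis
attaches lognormals to the RRs (which carry the BP-effect uncertainty) and
does not state that ΔSBP itself was redrawn.

Each PSA iteration redraws parameters, generates a fresh cohort
(parameter + first-order uncertainty, the default for patient-level
models; `fresh_cohort_per_iteration=False` pins the cohort), and runs both
arms under common random numbers. The within-simulation stream is also
pinned across iterations so iteration-to-iteration variation reflects
parameter and cohort uncertainty only. CEAC ties (net-benefit difference
exactly 0) split 0.5/0.5.

## Threshold analysis

Bisection on fixed-seed, common-random-number runs (noise must be pinned
for bisection to converge). The search objective is the net-monetary-
benefit difference g(x) = WTP·ΔQ(x) − ΔC(x) rather than the raw ICER:
g has the same root (where the ICER equals the WTP) but no pole where ΔQ
changes sign, so the bracket check is robust even when the usual-care arm
moves from cost-effective to dominated across the bracket. The reported
result carries the ICER achieved at the threshold and a convergence flag
(tolerance ±£250/QALY by default; with finite n the simulated ICER is a
step function of the parameter, which bounds the achievable tolerance).
The generic `bisect_threshold` works on any deterministic ICER function.

A dedicated parameter `treatment_effect.reduction_utility_gain_annual`
(base 0) adds an annual utility gain to reduction-arm patients, enabling
the "minimum utility gain from taking one fewer drug" threshold analysis.

## Numerical and implementation choices

- Single-precision-safe vectorized engine: all patients advance together,
  one multinomial draw block per cycle; 100,000 patients × 80 cycles run
  in a few seconds on one core.
- Common random numbers: both arms consume identically-shaped draw blocks
  every cycle (even after everyone is dead), so the streams stay aligned
  and the null model (ΔSBP = 0, equal costs) yields *exactly* zero
  increments.
- Degenerate inputs: probability 1 maps to 1 under rescaling; 10-year risk
  0 gives zero CVD hazard in both arms; empty cohorts and n = 0 requests
  are rejected; ages beyond the life table use its terminal row.
- Test problem sizes: the state-transition oracle comparison uses 20,000
  patients, cohort calibration 100,000, the event-rate oracle 100,000
  one-year replicates, PSA determinism checks a few hundred patients —
  each chosen so the Monte-Carlo SE is far below the assertion tolerance
  while the whole suite stays fast.

## Known limitations

- Unit costs are placeholders; every cost-denominated output (ICER level,
  cost thresholds) is conditional on a user-supplied cost table.
- The synthetic life table approximates, not reproduces, national
  non-circulatory mortality.
- Independence across cohort dimensions; no covariate-level risk scoring.
- No recurrent events, post-event treatment changes, terminal-care costs,
  or competing non-CVD morbidity beyond the life table — the same
  simplifications as the modelled analysis.
- The adverse-event RR (0.685) applies as a single arm-level multiplier
  regardless of how many drugs were withdrawn.
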