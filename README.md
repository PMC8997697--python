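# deprescribe

A patient-level Markov cost-utility model of **antihypertensive
deprescribing** (withdrawal of one blood-pressure-lowering drug) versus
usual care in adults aged 80 and over taking two or more antihypertensives.
It is written for health economists and methodologists who want a tested,
scriptable re-implementation of this class of decision model: a discrete
3-month-cycle microsimulation with probabilistic and deterministic
sensitivity analysis, cost-effectiveness acceptability curves, and
threshold (bisection) analysis.

## The model

Each simulated patient enters event-free at age ≥ 80 with an individual
10-year cardiovascular risk *R*, sex, prior-CVD count, EQ-5D utility and
drug count, and walks through 3-month cycles to death or 20 years. Within
a cycle the competing causes are background (non-circulatory) death, a
coronary heart disease event (MI / acute coronary syndrome / stable
angina), a cerebrovascular event (stroke / TIA), heart failure, a serious
drug-related adverse event (serious fall or acute kidney injury), or a
minor adverse event. Independent per-cause probabilities *p_i* are
combined into one multinomial draw with
P(none) = Π(1 − *p_i*) and each cause weighted by its marginal.

All time-scale conversions assume a constant hazard within the band:
an annual probability *p* becomes 1 − (1 − *p*)^(t) over *t* years, so the
per-cycle CVD probability is 1 − (1 − R)^(m·0.25/10) with *m* = 1.5 for
patients with prior CVD. Deprescribing raises systolic BP by Δ = 3.4 mmHg
(trial ITT difference at 12 weeks); literature relative risks quoted at a
reference BP difference Δ_ref are rescaled by log-linear interpolation,

    RR(Δ) = RR_ref^(Δ / Δ_ref),

and applied to the reduction arm's event hazards while the effect lasts
(lifetime in the base case). The first serious event moves the patient
permanently to a post-event state whose mortality hazard is multiplied by
a standardized mortality ratio (e.g. stroke 2.72, heart failure 2.17).

QALYs accrue as utility × cycle length, with multiplicative post-event
state utilities (e.g. heart failure 0.68 × baseline 0.769), one-month
transient disutilities for TIA and minor events, and a lifelong absolute
decrement after acute kidney injury. Costs cover primary-care
consultations (0.8 per cycle), prescriptions, the deprescribing safety and
reinstatement visits, and acute plus long-term event care. Costs and QALYs
are discounted at 3.5%/year with a half-cycle correction (mid-cycle
valuation). The incremental cost-effectiveness ratio is

    ICER = (C_usual − C_reduction) / (Q_usual − Q_reduction),

and PSA attaches beta distributions to probabilities and utilities, gamma
to costs, and lognormal to relative risks and SMRs, summarized as a CEAC.

Individual patient data for the source trial are not public, so the
`cohort` module generates synthetic populations matching the published
baseline moments (mean age 84.8 y, 51.5% male, prior-CVD split
42.9/29.5/27.6%, mean EQ-5D 0.769); a user cohort CSV can replace it.
**The unit-cost table is a placeholder**: the published analysis's cost
appendix is not in the public domain, so the bundled costs are
order-of-magnitude UK 2017/18 reference values, every entry flagged
`non-paper-default`. Cost-side conclusions (ICER magnitude, cost
thresholds) therefore depend on supplying your own cost YAML via
`--costs`; event counts and QALY differences do not.

## Worked example

```bash
deprescribe simulate --n 20000 --seed 42 --out results/
```

prints (placeholder cost table; your numbers vary with seed and costs):

```
          strategy  cost qalys incremental_cost incremental_qalys icer    label
Reduced medication 4,043 4.156             None              None None     None
        Usual care 4,007 4.244              -36             0.088 None dominant

                             event reduction usual_care difference
                     Heart failure    23,130     18,690      4,440
            Coronary heart disease    13,015     13,375       -360
  Stroke/Transient ischemic attack    14,150     13,170        980
Serious drug-related adverse event     5,730      8,380     -2,650
  Minor drug-related adverse event    68,775    100,840    -32,065
```

Reading this: over a lifetime horizon the average patient under usual care
gains 0.088 more discounted QALYs than under medication reduction, because
the modest sustained BP rise produces more heart failure (+4,440 per
100,000) and stroke/TIA (+980) events, which the reduction in drug-related
adverse events (−2,650 serious, −32,065 minor) does not offset. With the
placeholder costs the extra event care also makes reduction slightly more
expensive, so usual care is labelled *dominant* here; with realistic drug
and visit costs the comparison becomes a cost–QALY tradeoff quantified by
the ICER. The positive `difference` column means more events under
medication reduction.

Other entry points (`deprescribe COMMAND --help` for flags):

```bash
deprescribe psa --n 5000 --iterations 200 --seed 1 --out results/   # ce_plane.csv + ceac.csv
deprescribe threshold --parameter event_risks.sae_annual_risk --wtp 20000 \
    --bracket 0.0174 0.9 --n 4000 --seed 31 --out results/
deprescribe scenarios --n 10000 --seed 1 --out results/             # deterministic sensitivity set
deprescribe cohort --n 100000 --seed 1 --out results/
```

The same operations are available as library functions
(`deprescribe.run_base_case`, `run_psa`, `compute_ceac`,
`threshold_search`, `run_scenarios`, ...).

## Layout

- `src/deprescribe/parameters.py` — parameter loading/validation, PSA
  distribution fitting, bundled base-case YAML and synthetic life table
- `src/deprescribe/cohort.py` — synthetic cohort generator and CSV reader
- `src/deprescribe/risk_engine.py` — per-cycle probability mathematics
- `src/deprescribe/microsim.py` — the vectorized patient-level engine
- `src/deprescribe/econ.py` — utilities, costs, discounting
- `src/deprescribe/cea.py` — ICER/dominance, PSA, CEAC, thresholds, scenarios
- `src/deprescribe/reporting.py`, `cli.py` — tables and the `deprescribe` CLI
- `docs/methods.md` — modelling assumptions and design choices in detail
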