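# Methods

## Model structure

`markovcea` implements a four-state Markov cohort model for comparing two
treatment strategies in third-line HER2-positive metastatic breast cancer.
The states are stable disease (SD), remission (RE), progressive disease
(PD) and death (DE, absorbing), with cycle length 21 days (one
chemotherapy cycle) and a 5-year horizon. Permitted transitions are
SD→{SD, RE, PD}, RE→{RE, PD}, PD→{PD, DE}; everything else is a
structural zero. A cohort occupancy vector is pushed through the 4×4
transition matrix each cycle; costs and quality-adjusted life-years
(QALYs) are accrued from state occupancy and discounted at 3% per year,
`(1 + r)^(-t·Δ/365.25)` for cycle index `t` of length `Δ` days.

The horizon is truncated to whole cycles, `n = floor(5 × 365.25 / 21) = 86`
(≈ 4.94 years), so the simulation never exceeds the stated horizon. The
initial distribution defaults to 100% SD. The source trial population
entered in a mix of health states that was never published, so this
default is an explicit, configurable assumption — absolute cohort totals
therefore cannot be expected to match the published summary figures, and
the test suite checks structural properties (conservation, absorption,
closed-form oracles) instead.

## Transition probabilities (DEALE conversion)

Median survival summaries are converted to constant hazards and then to
per-cycle probabilities (the declining-exponential, DEALE, approximation:
a median `m` implies rate `ln 2 / m`, and a rate `r` over cycle length `t`
gives `p = 1 − exp(−r·t)`). With the cycle length expressed as 0.75
months (`CYCLE_MONTH_FACTOR`, configurable):

| transition | formula |
|---|---|
| SD→RE | `1 − exp(−RR/3)`, `RR = (OS − PFS)/OS` |
| RE→PD | `1 − exp(−0.75·ln2 / DoR)` |
| PD→DE | `1 − exp(−0.75·ln2 / (OS − PFS))` |
| SD→PD | `4 ×` (RE→PD) |

Self-transitions are the row complements. The ×4 stable→relapse
multiplier and the `/3` scale in the response formula are retained as
named constants exactly as the source model defines them; neither has a
published derivation. The multiplier caps RE→PD at 0.25, below which the
SD row would leave the simplex; the synthetic generator keeps DoR ≥ 3
months, which bounds the SD row sum below 0.92 for any response fraction.

### Rounding modes

The published model works with three-decimal probabilities. Four modes
are provided: `full_precision` (no intermediate rounding), `round_3dp`
(round half away from zero before complements/multiples are formed),
`truncate_3dp`, and `published_3dp`. The published table is internally
consistent only under a mixed convention — rounding for the RR- and
(OS−PFS)-based primitives but truncation for the DoR-based one (its L+C
value computes to 0.0887 and is printed 0.088, which then propagates to
the printed 0.352/0.912/0.440 row entries). `published_3dp` encodes that
mix and reproduces every printed entry exactly; pure rounding differs
only in the DoR-based primitive and its three derived entries.

## Accrual conventions

QALYs use the half-cycle correction in its trapezoidal
(Sonnenberg–Beck) form: half weight on the initial and final occupancy
vectors, full weight between. With the correction off, accrual counts
start-of-cycle membership over the `n` cycles, which is the convention
the geometric closed-form oracle assumes. The corrected total always
lies between the start- and end-of-cycle conventions (property-tested).

Costs (USD, 2022 prices):

* **Drug acquisition** accrues per cycle in SD and RE (on treatment until
  progression). Units per administration are `ceil(dose / unit_size)` —
  tablets are not split — with body-surface-area scaling (default
  1.67 m²) for per-m² dosing.
* **Recurring care** costs are per-year amounts scaled by `21/365.25` per
  cycle: hospitalization and concomitant medications in PD, health
  examinations in SD/RE. The source analysis never states the accrual
  period of these amounts; per-year is this package's reading and is the
  single largest modelling assumption, exposed in the config schema.
* **One-time costs at entry** (undiscounted, cycle 0): expected
  adverse-event management cost, `Σ incidence × per-event cost` over the
  grade-3/4 events, and the loperamide prophylaxis schedule of the
  neratinib arm (4 mg loading, 2 mg q4h for 3 days, then 2 mg q6h for the
  rest of the first cycle → 92 tablets; a q8h reading, 74 tablets, is a
  schedule parameter). Severe toxicity concentrates in the first cycles,
  which motivates the one-time treatment.
* Death accrues neither cost nor utility.

Utilities map SD→0.74 (no recurrence, on chemotherapy), RE→0.85, PD→0.5,
DE→0. Published utilities without a four-state counterpart
(post-chemotherapy 0.94, first-year local recurrence 0.74) are carried in
the config for provenance but never enter the accrual.

A consequence of deriving costs from unit inputs is worth stating
plainly: drug cost is proportional to pre-progression survival, so the
arm with the better transition structure (neratinib+capecitabine) accrues
*more* drug cost, and the bundled scenario's base case yields a positive
ICER (≈ $55.8k/QALY) rather than the dominance the published summary
reports. The published aggregate cost rows are not derivable from its own
printed unit prices and dosing, and are deliberately not used as inputs;
the package reports its computed economics next to the published figures
so the divergence is visible.

## Economics

ICER `= ΔC/ΔE` with the sign preserved and a cost-effectiveness-plane
quadrant tag attached (a bare negative ratio is ambiguous); `ΔE = 0` is
tagged, never thrown. NMB `= λ·E − C` at willingness-to-pay λ, default
$36,000/QALY = 3× the 2022 Chinese per-capita GDP ($12,000). Decision
tiers follow the GDP banding (below 1× GDP cost-effective, 1–3×
acceptable, above 3× not worthwhile), with dominance short-circuiting
and the banding inverted in the cost-saving/QALY-losing quadrant (savings
per QALY forgone above the threshold favour the strategy). When QALYs are
gained, `NMB_A > NMB_B ⇔ ICER < λ` exactly; this identity is
property-tested.

## Sensitivity analysis

**Parameter registry.** Every input with a sensitivity range participates.
Transition probabilities are arm-specific; utilities and unit costs that
the source tables print once for both arms are treated as *shared*
parameters, varied and sampled jointly (varying each arm's PD utility
independently lets ΔQALY cross zero and the ICER explode — an artifact,
not model uncertainty). The annual discount rate joins the one-way
analysis at ±10%.

**Complement convention.** Varying one transition probability lets the
same-row self-transition absorb the change, keeping rows stochastic.
Varying a self-transition directly is mapped onto its constituents
(RE→RE onto RE→PD; PD→PD onto PD→DE; SD→SD rescales both SD outflows
proportionally). A variation that breaks a row beyond repair is flagged
in the tornado table, not raised.

**One-way DSA** re-evaluates the full two-arm pipeline at each
parameter's low and high bound and sorts by the absolute ICER swing. At
the base value every parameter reproduces the base case (regression
property). In the bundled scenario the widest bars belong to the
relapse→death probabilities: because cost tracks effect under unit-derived
accrual, the ICER is most sensitive to parameters that move the small
QALY increment in the denominator — not to the remission-persistence
probability the published tornado ranks first from its dominant base case.

**PSA** is second-order Monte Carlo, default 1,000 draws from a seeded
`numpy.random.Generator`. Distributions are method-of-moments fits with
mean equal to the base value and the sensitivity range read as a 95%
interval, `sd = (high − low)/3.92`: beta for probabilities and utilities,
gamma for costs, a point mass for degenerate ranges; an infeasible beta
variance raises a fit error with guidance. Draws are sampled
independently per parameter (matching the source's practice); a draw that
violates row-stochasticity is resampled and counted, and more than 1%
invalid draws aborts. Identical seeds give bit-identical results.
Discount-rate uncertainty is excluded from PSA (the beta/gamma families
cover probability, utility and proportion/cost uncertainty only).

**CE plane and CEAC.** Draws are classified against the WTP line into
dominant / more-effective-below-WTP / more-effective-above-WTP /
cost-saving-favourable / comparator-favoured, with exact ties reported as
their own `indifferent` category. The acceptability curve evaluates, at
each WTP on a grid (default 0–64,000), the fraction of draws in which a
strategy's NMB is strictly the larger, ties split evenly — the two
curves sum to 1 pointwise by construction.

## Synthetic scenarios

`generate_scenario` draws structurally valid two-arm bundles: OS uniform
(default 12–40 months), PFS as a uniform fraction of OS (0.2–0.8, so
OS > PFS holds by construction rather than rejection), DoR in
[3, 2×PFS] months, utilities, dosing, adverse-event profiles and care
costs from configurable ranges, with the ±10% (probabilities, costs) /
±20% (utilities, clamped to [0, 1]) range conventions and family tags
attached. Generated bundles round-trip through the YAML schema and fit
PSA distributions without error. The generator emulates the *statistical
shape* of the reference inputs, not patient-level data: no Kaplan–Meier
curves, no correlation between parameters, no background mortality — so
passing sweeps demonstrate structural correctness of the pipeline, not
clinical realism of any particular draw. `generate_edge_cases` adds named
stress bundles (near-immortal, near-instant death, the ×4-rule boundary,
zero-cost, full-utility).

## Numerical choices

* Three-decimal rounding uses `decimal.Decimal` (half-away-from-zero or
  truncation), avoiding binary-float round-half-even surprises.
* Row sums are validated to 1e-9 on matrix construction and 1e-10 along
  the cohort trace; the engine-vs-matrix-power oracle agrees to 1e-10.
* Problem sizes in the test suite: the oracle sweep uses 1,000 random
  4×4 stochastic matrices over ≤ 10 cycles; the invariant sweep runs
  1,000 generated scenarios through both arms at the full 86-cycle
  horizon; PSA tests use 8–60 draws (reproducibility is seed-exact, so
  small draw counts suffice).
* `ΔE = 0` comparisons, ties at the WTP line, and degenerate (point-mass)
  distributions are all handled as tagged categories rather than special
  numeric values.

## Known limitations

* Constant hazards over the whole horizon (medians-only DEALE input); no
  parametric survival fitting, tunnel states, microsimulation or
  background all-cause mortality.
* Two strategies only; no efficiency frontier over ≥ 3 arms, no
  EVPI/EVPPI, no correlated PSA sampling.
* Prices are fixed 2022 USD; no inflation or currency machinery.
* The initial state distribution and cost-accrual periodicity of the
  source analysis are unknown; both are explicit configuration here, and
  conclusions that depend on them (absolute totals, cost direction
  between arms) should be read as conditional on those settings.
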