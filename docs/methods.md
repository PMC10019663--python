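# Methods

## Model structure and assumptions

The evaluation is a cohort-expectation decision tree over the fortnight
following an initial, at-scene-resolved hypoglycaemic attack. Patients are
partitioned by stage-1 response (three strata in the HS2 arm, two under
standard care); each stratum carries its own per-fortnight recurrence
incident rate and, conditional on recurrence, channel probabilities for
phoning 999, phoning 111 or self-managing. The model assumes perfect
severity triage at both dispatch desks and that EMS clinicians attend only
severe recurrences; consequently every 999/111 contact passes through a
severity node with a single arm-wide severity probability, and severe
contacts map onto three secondary-care outcomes (convey + admit,
convey only, discharge at scene). Enumerating terminals gives 10 pathways
per stratum — 30 in the HS2 arm, 20 under standard care, of which 18 and 12
contain an EMS attendance. The tree is evaluated as an expectation; there is
no microsimulation and at most one recurrence is costed per fortnight.

Time to recurrence is exponential, so the recurrence probability is
1 − e^(−r). The rate trio (r_HS2, r_HS2e, r_NA) = (0.75, 0.9, 1.0) encodes
full, partial and no intervention success; standard-care action-takers reuse
r_HS2 (their tabulated recurrence probability equals the read+action
value), and deterministic analyses require r_HS2 ≤ r_HS2e ≤ r_NA < 1.65,
the upper end of the published incidence range (42,890 episodes per 1,000
person-years → 42,890 × 10⁻³ / 26 per person-fortnight).

## Calibration

The severity probabilities p₄/q₄ are not free inputs: they are the ratio of
the trial-observed repeat EMS-attendance rate to the arm's "attendance
mass" Σᵢ Pᵢ = Σ stage-1 share × recurrence probability × (P999 + P111).
This makes the modelled probability of repeat attendance equal the observed
rate identically (the round-trip is exact to machine precision, and tested
as such), and it is re-done inside every probabilistic draw. Calibration
fails loudly (rather than clipping) when a drawn repeat rate exceeds the
attainable mass; excluded draws are counted and reported.

## Costs

Unit costs (2018–19 prices) live in a 17-item schedule; model states carry
one assigned cost each plus a provider tag (EMS, IUC, primary care,
secondary care). A pathway's cost is the sum of its states' costs — e.g. a
111-routed severe recurrence accrues the 111 call, the redirected 999 call,
and its stage-3 outcome. Two derived state costs are recomputed from their
published construction rather than hard-coded: the self-managed recurrence
(disposition mix over not-admitted ED attendances and free self-care,
£25.03 for booklet-read-and-acted patients, £33.54 otherwise) and the
intervention cost (booklet £1.60 + crew time at £2.55/min). The baseline
intervention cost is the published per-patient constant £9.95; the
arithmetic recomputation at the 3.3-minute weighted median administration
time (£10.02) is available through `intervention_cost` but deliberately not
substituted, because the published downstream results use £9.95.

Provider attribution of composite states is configurable because the
published account motivates but does not fully specify it. Defaults: 999
call, HTR, STC, STR and the intervention itself → EMS; 111 call, redirected
999 call and the "111 pathways" disposition bundle → IUC (an option splits
the bundle between secondary and primary care per its construction); GP
consultations → primary care; ED/admission and self-transport-to-ED → 
secondary care.

### Reproduction status of the published cost table

The probability side of the model reproduces the published figures to the
printed digit (calibrated 0.113/0.121; outcome distributions 42.4/53.1/4.5
and 39.4/55.1/5.5; relative risk reduction 7.6%; efficacy p = 0.33). The
cost side does not: evaluating the stated structure with the stated state
costs yields per-patient totals of £82.02 (HS2) and £74.95 (standard care)
against published £49.79/£40.50, and the published IUC row (£0.41/£0.54) is
an order of magnitude below any attribution consistent with the stated 111
costs. The package therefore treats the published cost-side values as
comparison values: `CEResults.reference_comparison()` recomputes all of
them and tabulates deviations. Two computed regularities are worth noting
(both are outputs of the pipeline, not assumptions): the arm *difference*
in cost deviates by a constant (≈ £2.22 per patient), and the sensitivity
ICERs for the intervention-cost scenarios shift from baseline by exactly
the published increments (±£3.25 or +£8.48 of intervention cost divided by
the effect difference), so the discrepancy behaves like an unprinted
element of the published cost model that largely cancels in increments,
not like a structural disagreement.

## Cost-utility

Utility follows a stepped pathway: constant at baseline unless recurrence
occurs at time T within the fortnight, after which it is reduced by a
severity-specific societal decrement with no recovery inside the window.
Decrements are day/night averaged with the observed 28% daytime share:
Δ_NS = 0.28·0.004 + 0.72·0.007 = 0.00616 and Δ_S = 0.0584 (printed as 0.006
and 0.058). T is triangular on (0, 14) days with mode at 2 days; its
closed-form contribution is E[(14 − T)/14] = 13/21. The annualisation
factor multiplying the decrement terms defaults to 9/182 ≈ 0.0495 — the
value backed out of the published £/QALY — and is a configuration
parameter, folded as factor = annual_scale × E[(14 − T)/14] so that a
Monte-Carlo integration over T checks the closed form genuinely. The
alternative literature decrement pair (0.014, 0.047) ships as a constant
but is off by default. No discounting or multi-year extrapolation is
applied: a single fortnight is annualised.

## Probabilistic sensitivity analysis

10,000 draws by default. The three incident rates are independently
triangular on (0, 1.65) with modes at their baseline values — independence
is taken literally, so draws may violate the deterministic ordering; a
configuration flag enables rejection sampling of r_HS2 < r_HS2e < r_NA for
users who prefer the constrained reading. Repeat-attendance rates are
binomial proportions at the trial arm sizes (707 at 4.5%, 1674 at 5.5%).
All other parameters stay at baseline. Each draw rebuilds both arms,
recalibrates severities, and records cost and effect differences scaled to
100 patients (matching the plane's baseline annotation convention). A
zero-width triangular support collapses sampling to the modes, which —
together with a large-n binomial surrogate — is how the PSA's consistency
with the deterministic baseline is verified. A single root seed drives one
`numpy` Generator; identical seeds give bit-identical output.

## Cost-minimisation

Fortnight cycles with GP consultation as the absorbing event. Cycle 1 is
the full economic model; "read + action" (HS2) and "action taken"
(standard care) begin absorbed, having consulted in cycle 1. From cycle 2,
transient strata absorb with common probability pGP ∈ {0.3, 0.4, 0.5},
paying the £39 consultation once; continuation costs replicate each
stratum's first-cycle recurrence-management expectation (one-off stage-1
costs excluded — they are incurred once; a flag includes them). Absorbed
patients accrue the standard-care action-taker's management expectation in
both arms, making the absorbed state arm-symmetric per patient; a flag
switches to zero post-absorption accrual, which changes cost levels but,
because absorbed masses differ between arms, can also shift the crossing
cycle — the default is the symmetric accrual. Newly absorbing patients pay
the consultation and the absorbed accrual in their absorption cycle. The
first cycle at which the HS2 cumulative cost is strictly below standard
care is recorded; iteration stops when absorption exceeds 95% in both arms
or after six cycles (the fortnights within the 90-day secondary horizon).
The crossing probability by completed cycle (1–5) and pGP is the
proportion over first-cycle parameter draws sampled exactly as in the PSA.

At baseline parameters the chains cross at cycle 3 for all three pGP
values. One behavioural nuance the package reports honestly: the published
claim that a higher consultation rate lowers the crossing chance at *every*
cycle holds here from cycle 3 onward, but at cycle 2 the larger
newly-absorbing standard-care mass paying the once-only £39 can invert the
ordering marginally; the corresponding test asserts the late-cycle
ordering.

## Synthetic trial generator

The generator emulates only the aggregates the model consumes: per-arm
Bernoulli repeat flags at the trial sizes and rates (707 at 4.5%, 1674 at
5.5%), Bernoulli daytime stratum at 28%, Bernoulli conveyance at 60%, and
at-scene durations that are log-normal (σ = 0.45) around a 35-minute
median — a realistic at-scene time for a resolved hypoglycaemia episode —
with the intervention arm's median shifted additively by 6.6 minutes in the
daytime stratum and 2.0 overnight. Only the median differences are
anchored by observation; the base median and spread are this package's
realism choices, and medians (not means) are estimated downstream to match.
The generator reproduces no calendar, operational or patient-identifiable
structure, so passing the recovery tests demonstrates estimator/pipeline
consistency, not robustness to real-world messiness (missingness,
clustering by station or season, non-stationary rates).

## Numerical choices

- Probabilities from rates use `expm1`/`log1p` for small-rate accuracy.
- Distribution and mix validity are enforced at 1e-9; evaluator agreement
  (pathway enumeration vs recursive fold vs an algebraic oracle in the
  tests) at 1e-9; calibration round-trips and Markov mass conservation at
  1e-12.
- Boundary points of the cost-effectiveness plane (a zero difference) are
  assigned to the north/east side deterministically; with continuous draws
  they have probability zero.
- ICERs with a zero effect difference are returned as undefined (None plus
  a flag), never as ±inf; dominance is flagged so negative ratios are not
  misread as magnitudes.
- Currency is reported at 2 dp and percentages at 1 dp in summaries;
  machine outputs carry full precision. £/QALY is additionally rounded to
  2 significant figures, the convention used for the published figure.
- Monte-Carlo problem sizes in the shipped tests: 10,000 draws for the PSA
  and cost-minimisation checks (the published simulation size), 10⁶ draws
  for the T-integration check, 250–300 replicates for the type-I-error
  check; these sizes give Monte-Carlo standard errors well inside the
  asserted bands.

## Known limitations

- The published per-provider cost table cannot be reproduced from printed
  information (see above); all cost-level comparisons are reported as
  deviations by design.
- The eligible-population and efficacy inputs are taken as given trial
  aggregates; no uncertainty is propagated through them outside the PSA's
  binomial component.
- The model costs at most one recurrence per fortnight and does not model
  repeat 999 contact after self-management failure, mirroring the tree it
  re-implements.
- The 9/182 annualisation factor is adopted for consistency with the
  published cost-utility result; its derivation is not documented in the
  source material, so it is exposed as a parameter rather than asserted as
  a modelling truth.
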