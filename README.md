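# hs2econ

Economic evaluation of **"'Hypos' can strike twice" (HS2)** — a leaflet-based
referral intervention handed out by ambulance clinicians after they resolve a
hypoglycaemic episode at scene — against standard emergency-medical-services
(EMS) care, from the perspective of the UK NHS at 2018–19 prices.

The package is aimed at health economists and trial statisticians who want a
tested, fully parameterised re-implementation of the model: every analysis is
a pure function of a configuration object that mirrors the published cost and
probability tables, and every intermediate (all 50 decision-tree pathways,
provider-attributed costs, calibrated probabilities) is exported for audit.

## The model

A three-stage decision tree describes the fortnight after an initial,
at-scene-resolved attack:

1. **Stage 1 — response to the initial attack.** HS2 patients split into
   *booklet read + action taken* (p₁₁ = 0.4125, includes a GP consultation),
   *read only* (p₁₂ = 0.3375) and *no actions*; standard care into *action
   taken* (q₁ = 0.25) and *no action*.
2. **Stage 2 — recurrence and its management.** With exponential time to
   incident, the per-fortnight recurrence probability is 1 − e^(−r) with rates
   r = 0.75 / 0.9 / 1.0 by stage-1 response (bounded by r_max = 1.65, the top
   of the published incidence range). A recurrence is managed by phoning 999,
   phoning 111, or self-managing. Dispatch triages severity perfectly and EMS
   attend only severe recurrences: each 999/111 contact is severe with
   probability p₄ (q₄ under standard care).
3. **Stage 3 — secondary care.** An attended severe recurrence is conveyed
   (p₅ = 0.6) and then admitted (p₆ = 1/3) or not; otherwise discharged at
   scene.

p₄ and q₄ are **calibrated** so the modelled repeat EMS-attendance
probability equals the trial-observed rates (4.5% of 707 intervention
episodes, 5.5% of 1674 standard-care episodes):
p₄ = 0.045 / Σᵢ Pᵢ = 0.113, q₄ = 0.055 / Σᵢ Pᵢ = 0.121, where Σᵢ Pᵢ sums
stage-1 share × recurrence probability × call probability over patient types.

On top of the tree sit:

- **baseline cost-effectiveness** — expected per-patient cost by service
  provider, the probability of no recurrence, and the ICER in £ per episode
  of recurrent hypoglycaemia avoided;
- **cost-utility** — a stepped utility pathway drops by a severity- and
  time-of-day-averaged societal decrement at the (triangular) recurrence time
  with no recovery inside the fortnight; annualised, the QALY difference is
  (9/182)·(Δ_NS·ΔpNS + Δ_S·ΔpS);
- **one-way sensitivity** — intervention cost (£6.70 out-of-hours to £18.43
  in-hours), the recurrence rate r_HS2 (0.375–0.9) and the HS2 severe
  recurrence rate (3.5–5.5%), as tornado data;
- **probabilistic sensitivity analysis** — 10,000 draws with triangular
  incident rates on (0, 1.65) and binomial repeat rates, per-draw
  recalibration, and quadrant shares of the cost-effectiveness plane;
- **cost-minimisation** — an absorbing-Markov extension in fortnight cycles
  where GP consultation (probability pGP ∈ {0.3, 0.4, 0.5} per cycle) is the
  absorbing event, reporting the probability that the HS2 arm's cumulative
  cost has fallen strictly below standard care after n cycles;
- **a synthetic trial generator** producing episode-level tables (arm,
  repeat-within-14-days, time-of-day stratum, conveyance, at-scene duration)
  with the trial's statistical structure, so the whole estimation pipeline is
  testable without external data.

## Worked example

```python
from hs2econ import HypoglycaemiaCEModel

results = HypoglycaemiaCEModel().fit()
print(results.summary())
```

```
Recurrent hypoglycaemia cost-effectiveness model (fortnight horizon)
====================================================================
                                       HS2   Standard care
--------------------------------------------------------------------
cost EMS (GBP)                       31.66           24.99
cost IUC (GBP)                       12.75           15.15
cost primary care (GBP)              16.09            9.75
cost secondary care (GBP)            21.53           25.06
cost total (GBP)                     82.02           74.95
P(no recurrence) (%)                  42.4            39.4
severity probability                 0.113           0.121
--------------------------------------------------------------------
cost difference (GBP/patient)            7.07
effect difference (probability)        0.0300
relative risk reduction (%)               7.6
ICER (GBP/recurrence avoided)          235.34
QALY difference (per patient-year)  3.498e-05
cost per QALY (GBP, 2 sf)              200000
efficacy z-test                    z = -0.973, p = 0.33
====================================================================
```

Reading the output: the intervention arm avoids recurrence slightly more
often (42.4% vs 39.4%, a 7.6% relative risk reduction that is not
statistically significant, p = 0.33) but costs more per patient, so avoiding
one recurrent episode costs a few hundred pounds — and, per QALY, far beyond
any NHS commissioning threshold. The probability side of the model (outcome
distributions, calibrated severities, efficacy test) reproduces the published
evaluation to the printed digit. The cost side intentionally does **not**
match the published per-patient totals: the published provider attribution of
composite states is under-specified, so this package evaluates the *stated*
structure and tabulates the deviations instead of tuning to the printed
table — see `results.reference_comparison()` and `docs/methods.md`.

The same analyses are available from the shell:

```bash
hs2econ run-all --seed 1 --out out/          # everything + deviation table
hs2econ run-psa --seed 1 --n 10000 --out out/
hs2econ simulate-trial --seed 1 --out out/
```

Each run writes machine-readable CSV/JSON plus a `manifest.json` recording
the resolved configuration hash, seed and output list. A YAML configuration
mirroring the published tables can be dumped via
`python -c "import hs2econ; hs2econ.save_config(hs2econ.default_parameters(), 'config.yaml')"`,
edited, and passed back with `--config`.

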