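# Methods

This note documents the model, its numerical choices, the synthetic
reference inputs and what the test suite does and does not establish.

## Model structure

The model is a discrete-time Markov cohort model with a 6-week cycle
(one year = 52.18 weeks, so a cycle is 6/52.18 ≈ 0.115 years) and a
lifetime horizon capped at age 110 (runs truncate earlier if the live
cohort falls below 10⁻⁹ persons). States are enumerated per treatment arm:

- `baseline` AF on the assigned therapy (apixaban or VKA) or on ASA after
  a switch;
- `holiday` — a single-cycle drug interruption after a non-HS
  intracranial hemorrhage for patients who stay on their anticoagulant;
- `post_is` and `post_hs` by severity (mild/moderate/severe) and
  first/recurrent flag; `post_is` keeps the current therapy, `post_hs` is
  maintenance-only;
- `post_se` (keeps therapy) and `post_mi` (maintenance-only), both
  absorbing apart from death;
- `dead`.

Bleeding events (other ICH, other MB, CRNM) are *not* separate tunnel
states: they are annotated transitions whose survivors are routed
immediately to their destination (stay on therapy, with a drug-holiday
cycle after other ICH, or switch to ASA). This is equivalent for state
occupancy because a bleed changes nothing about the next cycle's risk set
beyond the therapy assignment, and it keeps the matrix small; the
utility/cost consequences of bleeds are accounted from the per-cycle event
flows that the cohort engine records alongside occupancy.

Only baseline and holiday states generate primary events; post-stroke
states generate the single permitted recurrent stroke (2.97%/year after
IS, 2.17%/year after HS; recurrence severity mirrors first strokes under
apixaban) and mortality. Patients discontinuing treatment for other
reasons switch to ASA; the ASA discontinuation rate is zero in the
reference configuration because ASA is already the fallback therapy.

## Transition probabilities

- **Rate → probability.** p = 1 − exp(−(r/100)·t). Chosen because it is
  the standard conversion in decision-analytic modelling; validated in
  tests against a 10⁴-sub-step compounding oracle to 10⁻⁶.
- **Competing events.** Within a cycle every event rate becomes a
  cause-specific hazard; the total event probability 1 − exp(−Σh) is
  allocated in proportion h_i/Σh. This is order-independent, preserves
  row-stochasticity, and makes each flow weakly decreasing in any other
  event's rate.
- **Mortality layering.** Other-cause mortality is layered as an
  independent risk: p_d = 1 − exp(−h_d), all other destinations scaled by
  1 − p_d. During the first 1.8 years (the trial period) the other-cause
  rate is the therapy-specific trial rate; afterwards it is a sex-weighted
  (35.3% female) life-table rate times a state-specific excess multiplier
  (AF baseline, stroke by severity, MI, SE). The multiplicative layering
  matches an exhaustive micro-step enumeration of a two-event cycle
  exactly in the limit, which the tests verify.
- **TTR adjustment.** The four INR-control-dependent events (IS, ICH,
  other MB, CRNM) take their rates from cTTR strata. The base case uses
  the stratum containing the population mean TTR (72.48% → the
  66.02–76.51% band); scenarios select other strata or the unweighted
  stratum mean ("equal distribution across clinics"). "Equally
  distributed" is interpreted as an unweighted mean of stratum rates; a
  mixed-cohort simulation would be the alternative reading. Linear
  interpolation on stratum midpoints is available as a config option
  (`ttr_policy: interpolate`).
- **CHADS₂ weighting.** The population IS rate is the stratum rate times
  the cohort-weighted mean of per-score multipliers. The reference
  multipliers are normalised so that the trial-like cohort mix gives a
  factor of exactly 1 (the trial rates already reflect that mix).
- **Age escalation.** Rates scale by factor^((age − 70)/10); age advances
  one whole year every ⌈52.18/6⌉ = 9 cycles because life tables are
  annual.
- **Drug holiday.** The interrupted cycle uses the ASA rate profile as
  the closest available stand-in for "no anticoagulant effect" (the model
  has no untreated rate set), accrues no drug cost and no treatment
  utility decrement, then returns to the interrupted therapy.

## Economic accounting

Discounting is stepwise annual after a discount-free first year: a cycle
starting at time t years carries (1+r)^(−⌈t−1⌉), with r = 4% for costs
and 1.5% for effects. No half-cycle correction is applied by default (the
source analysis does not state one); `half_cycle_correction: true`
averages start- and end-of-cycle occupancy.

Utilities: baseline AF utility; joint AF/event utilities are
multiplicative by default (u_AF · u_event) because the published joint
estimator is not reproduced in the source material; `minimum` is offered
as an alternative. Treatment decrements apply while actively medicated;
bleed decrements apply additively for their configured duration rounded
up to whole cycles, charged against the expected event flows (survivor
flows only). Per-cycle state utility is clamped to [0, 1] before bleed
decrements are subtracted, so QALYs ≤ LYs always holds; with extreme
decrement configurations QALYs could in principle go slightly negative,
which validation flags via the decrement bounds.

Costs: drug and routine care per person-cycle (routine care in every
alive state); INR monitoring on VKA person-cycles only; the VKA drug cost
is the 80:20 acenocoumarol:phenprocoumon usage-weighted average; acute
event costs at the cycle of occurrence; long-term maintenance monthly
costs in post-stroke and post-MI states. ICERs are computed from
full-precision internals; rounding to whole euros happens only at
rendering — which is why a published ICER can legitimately differ from
the ratio of its rounded table cells.

## Uncertainty analyses

- **Tornado.** One parameter at a time replaced by mean ± 1.96·SE
  (clamped to its natural domain), full deterministic model re-run.
- **PSA.** Gamma for rates, beta for utilities, log-normal for costs,
  all parameterised by method of moments from (mean, SE); a 95% CI in a
  config is converted to an SE assuming normality on the natural scale.
  Parameters are drawn independently (no published correlation
  structure); both arms are evaluated on the same draw. Each parameter
  owns a seed substream derived from (master seed, CRC32 of its path), so
  adding a parameter does not perturb existing draws and a fixed seed
  reproduces results bit-identically. Default 2,000 iterations.
- **CEAC.** Fraction of draws with strictly positive net monetary
  benefit λ·ΔQALY − ΔCost; ties at zero count as not cost-effective
  (a zero-measure event under continuous draws). Default thresholds
  €20,000 and €30,000 per QALY.

## Synthetic reference inputs

The generator embeds every anchor printed in the source analysis: cohort
age 70, 35.3% female, CHADS₂ distribution (7, 27, 25, 20, 12, 7, 2)%,
mean TTR 72.48%, the cTTR stratum rates of the scenario table (the
unprinted base-case stratum is recovered from the equal-mix row as
4·mix − Σ(other three), e.g. VKA IS 0.967), recurrence risks 2.97%/2.17%
per year, the 80:20 VKA mix, 4%/1.5% discounting, 6-week cycle, cohort of
1,000, 2,000 PSA iterations and WTP thresholds €20,000/€30,000.

Everything else — per-CHADS₂ multipliers, MI/SE/discontinuation rates,
severity splits, case fatalities, post-bleed stay fractions, excess
mortality multipliers, utilities, costs, the life table — lives only in
supplementary material or prior model publications and is filled with
synthetic placeholders chosen once to be order-of-magnitude plausible
(several are shaped on ratios implied by the printed event tallies; the
utility SE of 10% of the mean and the cost CV of 0.25 are stated in the
source's supplementary captions). The life table is a synthetic Gompertz
(rate = level·e^{0.095·(age−70)} per 100 py, male level 1.6, female 1.1,
terminal closure at the age cap). Consequently the package's absolute
results (ICER ≈ €14,400/QALY on the reference fixture) characterise the
model under these documented placeholder conditions, not the published
estimates; passing tests establish the correctness of the machinery —
conversions, composition, conservation, accounting identities,
reproducibility — and the qualitative structure (apixaban: fewer
ICH/CRNM events, higher acquisition cost, lower monitoring cost), not
agreement with any published absolute number.

What the generator also does not emulate: patient-level heterogeneity
(the cohort is homogeneous apart from the CHADS₂ mixture entering as a
rate multiplier), calendar trends in prices or mortality, adherence
dynamics, and correlation between uncertain parameters.

## Problem sizes used by the tests and the acceptance script

The acceptance script runs the deterministic base case (26 states × 369
cycles per arm), a 2,000-iteration PSA and five scenario runs — about two
minutes on one CPU. The test suite uses a 200,000-trajectory
microsimulation oracle on a 4-state excerpt, a 50-parameter-set
perturbation sweep for row-stochasticity, and short PSAs (≤30
iterations) for reproducibility checks.

## Known limitations

- One recurrent stroke per trajectory; no multiple thromboembolic events.
- Post-stroke/post-SE/post-MI states generate no bleeding or MI events;
  only recurrence and mortality (a common simplification that slightly
  favours neither arm symmetrically).
- The equal-mix scenario is an unweighted stratum mean, not a simulated
  mixed cohort.
- Bleed decrements are charged to event flows, not tracked per occupant,
  so a decrement outlasting a decedent's survival is not trimmed (the
  error is second-order in the event probabilities).
- The societal perspective (productivity losses) is out of scope.
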