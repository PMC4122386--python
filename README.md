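# oacce — oral anticoagulation cost-effectiveness model

A lifetime Markov cohort model comparing **apixaban** with **vitamin-K
antagonists (VKAs)** for stroke prevention in non-valvular atrial
fibrillation (AF), from the Dutch healthcare payer's perspective. It is
aimed at health-economic modellers who want a fully tested, scriptable
implementation of this class of decision model: risk adjustment for INR
control quality (time in therapeutic range, TTR), CHADS₂-weighted baseline
stroke risk, age-escalating event rates, and the standard economic and
uncertainty machinery (QALYs, life years, costs, ICER, tornado diagrams,
probabilistic sensitivity analysis with CEACs, cTTR scenario analyses).

## The model

A closed cohort (1,000 patients, age 70, 35.3% female, mean TTR 72.48%)
starts in the AF baseline state on apixaban or VKA and moves every 6-week
cycle between health states: ischemic stroke (IS) and hemorrhagic stroke
(HS) by severity (mild/moderate/severe/fatal, one recurrent stroke
allowed), systemic embolism (SE) and myocardial infarction (MI) (both
absorbing until death), other intracranial hemorrhage (ICH), other major
bleeding (MB, gastrointestinal or not), clinically relevant non-major
(CRNM) bleeding, other treatment discontinuation (switch to ASA), and
death.

Annual event rates r (per 100 patient-years) become per-cycle
probabilities by exponential conversion, p = 1 − exp(−(r/100)·t) with
t = 6/52.18 years. Within a cycle, competing events are composed
cause-specifically — each rate contributes a hazard hᵢ, the overall event
probability 1 − exp(−Σh) is split in proportion hᵢ/Σh — and other-cause
mortality (trial-based for the first 1.8 years, life-table with
state-specific excess multipliers afterwards) is layered multiplicatively,
so every transition row is exactly stochastic. Rates of the
INR-control-dependent events (IS, ICH, other MB, CRNM) come from cTTR
strata; the IS rate is additionally weighted over the cohort's CHADS₂
distribution.

Costs (drug, routine care, INR monitoring on VKA only, acute event, and
long-term maintenance) and effects (joint AF/event utilities with additive
bleed and treatment decrements) accrue per cycle, discounted at 4% and
1.5% per year after the first year. The headline output is the incremental
cost-effectiveness ratio ICER = ΔCost/ΔQALY.

The published analysis this model re-implements draws many inputs from
supplementary material that is not reproduced here; those values ship as
clearly documented synthetic placeholders in the fixture generator (see
`docs/methods.md`), so absolute results are *not* a reproduction of the
published numbers, while the model structure, the printed anchor values
and all qualitative behaviour are.

## Worked example

```python
from oacce import generate_reference_paramset, run_base_case
from oacce.reporting import render_ce_summary, format_ce_summary

params = generate_reference_paramset()          # printed anchors + placeholders
result = run_base_case(params)                  # apixaban vs VKA
print(format_ce_summary(render_ce_summary(result, params=params, seed=2014)))
```

prints

```
treatment  cost qalys   lys delta_cost delta_qaly delta_ly icer_per_qaly icer_per_ly    label
      vka 17886  9.23 12.78          -          -        -             -           -
 apixaban 20572  9.42 12.93       2686       0.19     0.14         14448       18746 tradeoff
# seed=2014 config_hash=3b62c1312c743c0e
```

Read: on the synthetic reference inputs, apixaban costs €2,686 more per
patient over a lifetime but yields 0.19 extra quality-adjusted life years,
an ICER of €14,448 per QALY — a trade-off a payer with a willingness to
pay of €20,000/QALY would accept. Per-arm event tables, tornado sweeps,
the PSA cost-effectiveness plane/CEAC and the cTTR scenario grid are
available through the library (`tornado`, `run_psa`, `ceac`,
`run_scenarios`) or the CLI:

```bash
oacce run --out out/            # base case; uses the built-in reference config
oacce psa --iterations 2000 --seed 1 --out out/ --plot
oacce scenarios --out out/
oacce tornado --out out/
oacce fixtures --out out/       # write the reference YAML to edit your own
```

Exit codes: 0 success, 1 configuration/validation error, 2 runtime error.

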