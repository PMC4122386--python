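"""Synthetic reference parameter sets.

The complete input set of the published Dutch analysis spans supplementary
tables that print only a subset of values in the main text. This module
generates internally consistent :class:`~oacce.params.ModelParameters`
fixtures that embed every printed anchor — the cohort profile (age 70,
35.3% female, CHADS2 mix, mean TTR 72.48%), the cTTR stratum rates of the
scenario table, the recurrent-stroke risks (2.97/2.17 %/year), the 80:20
acenocoumarol:phenprocoumon mix, 4%/1.5% discounting, the 6-week cycle,
cohort of 1,000, 2,000 PSA iterations and WTP thresholds of €20,000 and
€30,000 — and fills every unprinted value with documented, order-of-
magnitude-plausible placeholders. Placeholders are synthetic stand-ins, not
published estimates.

The base-case cTTR stratum (66.02% ≤ cTTR < 76.51%, containing the Dutch
mean TTR of 72.48%) is not printed directly; its rates are recovered from
the equal-mix scenario as ``4·mix − Σ(other three strata)``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .params import ModelParameters, params_from_dict

#: Cohort CHADS2 distribution (score -> percent of patients).
_CHADS2_PERCENT = {1: 7, 2: 27, 3: 25, 4: 20, 5: 12, 6: 7, 7: 2}

#: Scenario-table rates of the TTR-dependent events (annual, per 100 py).
#: The fourth (base-case) stratum is implied by the equal-mix row.
_STRATA = [
    ("cTTR<52.38%", 0.0, 0.5238,
     {"apixaban": {"ischemic_stroke": 1.213, "ich": 0.292, "other_mb": 0.999, "crnm": 1.271},
      "vka": {"ischemic_stroke": 1.787, "ich": 0.959, "other_mb": 1.765, "crnm": 2.622}}),
    ("52.38%<=cTTR<66.02%", 0.5238, 0.6602,
     {"apixaban": {"ischemic_stroke": 1.316, "ich": 0.502, "other_mb": 1.384, "crnm": 1.788},
      "vka": {"ischemic_stroke": 1.159, "ich": 0.912, "other_mb": 2.093, "crnm": 2.657}}),
    ("66.02%<=cTTR<76.51%", 0.6602, 0.7651, None),  # derived from the equal mix
    ("cTTR>=76.51%", 0.7651, 1.0,
     {"apixaban": {"ischemic_stroke": 0.738, "ich": 0.181, "other_mb": 2.442, "crnm": 3.043},
      "vka": {"ischemic_stroke": 0.831, "ich": 0.708, "other_mb": 2.857, "crnm": 3.364}}),
]
_EQUAL_MIX = {
    "apixaban": {"ischemic_stroke": 1.044, "ich": 0.330, "other_mb": 1.790, "crnm": 2.083},
    "vka": {"ischemic_stroke": 1.186, "ich": 0.800, "other_mb": 2.270, "crnm": 2.995},
}

#: Untreated-population annual stroke risk by CHADS2 score (per 100 py),
#: used only to shape the relative per-score multipliers (placeholder).
_CHADS2_RAW_RISK = {1: 2.8, 2: 4.0, 3: 5.9, 4: 8.5, 5: 12.5, 6: 18.2, 7: 25.0}


@dataclass(frozen=True)
class FixtureSpec:
    """Controls fixture generation.

    ``perturbation_scale`` is the log-scale SD of the multiplicative noise
    used by :func:`generate_perturbed_paramsets`. The ``embed_*`` toggles
    select which printed anchors are embedded; switching one off replaces
    the block with generic round-number placeholders (useful for testing
    the plumbing independently of the anchored values).
    """

    seed: int = 2014
    perturbation_scale: float = 0.1
    embed_cohort_profile: bool = True
    embed_ttr_strata: bool = True
    embed_recurrence: bool = True
    embed_vka_mix: bool = True
    embed_discounting: bool = True
    embed_wtp: bool = True


def _base_stratum_rates() -> dict:
    """Recover the unprinted base-case stratum from the equal-mix row."""
    out: dict[str, dict[str, float]] = {}
    for th in ("apixaban", "vka"):
        out[th] = {}
        for ev in ("ischemic_stroke", "ich", "other_mb", "crnm"):
            others = sum(s[3][th][ev] for s in _STRATA if s[3] is not None)
            out[th][ev] = round(4.0 * _EQUAL_MIX[th][ev] - others, 6)
    return out


def _chads2_multipliers(weights_pct: dict[int, float]) -> dict[int, float]:
    """Per-score stroke multipliers normalised so the cohort-weighted mean
    is exactly 1 (the trial rates already reflect the trial's score mix)."""
    total = sum(weights_pct.values())
    weights = {k: v / total for k, v in weights_pct.items()}
    mean = sum(weights[s] * _CHADS2_RAW_RISK[s] for s in weights)
    return {s: _CHADS2_RAW_RISK[s] / mean for s in weights}


def generate_life_table(max_age: int, spec: FixtureSpec | None = None) -> dict:
    """Synthetic Gompertz non-cardiovascular mortality rates per 100 py.

    Smooth, monotone in age, covering both sexes from age 40 to
    ``max_age``; the terminal age carries an effectively certain death rate
    so a cohort capped at ``max_age`` goes extinct. Synthetic stand-in for
    a national life table.
    """
    max_age = int(max_age)
    if max_age <= 41:
        raise ValueError("max_age must exceed the table start age")
    table: dict[str, dict[int, float]] = {"male": {}, "female": {}}
    for sex, level in (("male", 1.6), ("female", 1.1)):
        for age in range(40, max_age + 1):
            table[sex][age] = round(level * float(np.exp(0.095 * (age - 70))), 6)
    for sex in table:
        table[sex][max_age] = 1.0e4  # terminal closure: certain death
    return table


def _uncertainty_block(raw: dict) -> dict:
    """PSA descriptors: gamma on rates (15% CV placeholder), beta on
    utilities (10% SD of the mean), log-normal on costs (CV 0.25)."""
    unc: dict[str, dict] = {}

    def add(path: str, dist: str, mean: float, cv: float) -> None:
        if mean > 0 and not (dist == "beta" and mean >= 1.0):
            unc[path] = {"dist": dist, "se": round(cv * mean, 10)}

    base_idx = next(i for i, s in enumerate(_STRATA) if s[3] is None)
    for th in ("apixaban", "vka"):
        for ev in ("ischemic_stroke", "ich", "other_mb", "crnm"):
            mean = raw["rates"]["ttr_strata"][base_idx]["rates"][th][ev]
            add(f"rates.ttr_strata.{base_idx}.rates.{th}.{ev}", "gamma", mean, 0.15)
        for ev in ("mi", "se", "discontinuation"):
            add(f"rates.{th}.{ev}", "gamma", raw["rates"][th][ev], 0.15)
    for ev in ("ischemic_stroke", "ich", "other_mb", "crnm", "mi", "se"):
        add(f"rates.asa.{ev}", "gamma", raw["rates"]["asa"][ev], 0.15)

    add("utilities.baseline_af", "beta", raw["utilities"]["baseline_af"], 0.10)
    for key, mean in raw["utilities"]["events"].items():
        add(f"utilities.events.{key}", "beta", mean, 0.10)

    for key, mean in raw["costs"]["drug_per_cycle"].items():
        add(f"costs.drug_per_cycle.{key}", "lognormal", mean, 0.25)
    add("costs.routine_care_per_cycle", "lognormal", raw["costs"]["routine_care_per_cycle"], 0.25)
    add("costs.inr_monitoring_per_cycle", "lognormal", raw["costs"]["inr_monitoring_per_cycle"], 0.25)
    for key, mean in raw["costs"]["acute"].items():
        add(f"costs.acute.{key}", "lognormal", mean, 0.25)
    for key, mean in raw["costs"]["long_term_monthly"].items():
        add(f"costs.long_term_monthly.{key}", "lognormal", mean, 0.25)
    return unc


def reference_dict(spec: FixtureSpec | None = None) -> dict:
    """The reference configuration as a plain dict (pre-validation)."""
    spec = spec or FixtureSpec()

    strata = []
    base_rates = _base_stratum_rates()
    for label, lo, hi, rates in _STRATA:
        strata.append(
            {"label": label, "lower": lo, "upper": hi,
             "rates": copy.deepcopy(rates) if rates is not None else copy.deepcopy(base_rates)}
        )
    if not spec.embed_ttr_strata:
        flat = {"apixaban": {"ischemic_stroke": 1.0, "ich": 0.3, "other_mb": 2.0, "crnm": 2.0},
                "vka": {"ischemic_stroke": 1.0, "ich": 0.6, "other_mb": 2.0, "crnm": 3.0}}
        strata = [{"label": "all", "lower": 0.0, "upper": 1.0, "rates": flat}]
        base_rates = flat

    cohort = {
        "start_age": 70 if spec.embed_cohort_profile else 65,
        "fraction_female": 0.353 if spec.embed_cohort_profile else 0.5,
        "cohort_size": 1000,
        "chads2_weights": dict(_CHADS2_PERCENT) if spec.embed_cohort_profile else {2: 50, 3: 50},
        "mean_ttr": 0.7248 if spec.embed_cohort_profile else 0.70,
    }

    raw = {
        "schema_version": 1,
        "cohort": cohort,
        "rates": {
            # TTR-dependent entries equal the base-case stratum; MI, SE,
            # discontinuation and trial-period mortality are placeholders.
            "apixaban": {**base_rates["apixaban"], "mi": 0.53, "se": 0.09,
                         "discontinuation": 13.0, "other_cause_mortality": 1.9},
            "vka": {**base_rates["vka"], "mi": 0.61, "se": 0.10,
                    "discontinuation": 13.5, "other_cause_mortality": 2.0},
            "asa": {"ischemic_stroke": 3.48, "ich": 0.30, "other_mb": 0.90, "crnm": 2.00,
                    "mi": 0.90, "se": 0.40, "discontinuation": 0.0, "other_cause_mortality": 2.2},
            "ttr_strata": strata,
        },
        "modifiers": {
            "chads2_multipliers": _chads2_multipliers(cohort["chads2_weights"]),
            "age_factor_stroke": 1.40,
            "age_factor_bleeding": 1.50,
            "age_factor_mi": 1.30,
            "hs_fraction_of_ich": 0.63,
            "gi_fraction_of_other_mb": 0.38,
            # mild/moderate/severe/fatal splits (placeholders shaped on the
            # event tallies of the published cohort table)
            "stroke_severity_is": {
                "apixaban": [0.396, 0.344, 0.135, 0.125],
                "vka": [0.379, 0.363, 0.140, 0.118],
                "asa": [0.379, 0.363, 0.140, 0.118],
            },
            "stroke_severity_hs": {
                "apixaban": [0.174, 0.278, 0.160, 0.388],
                "vka": [0.163, 0.164, 0.163, 0.510],
                "asa": [0.163, 0.164, 0.163, 0.510],
            },
            "case_fatality": {"se": 0.094, "mi": 0.158, "other_ich": 0.13, "other_mb": 0.02, "crnm": 0.0},
            "post_bleed_stay": {"other_ich": 0.50, "other_mb": 0.75, "crnm": 0.90},
            "recurrence_annual_risk_pct": (
                {"post_is": 2.97, "post_hs": 2.17} if spec.embed_recurrence else {"post_is": 3.0, "post_hs": 2.0}
            ),
            "excess_mortality": {"af": 1.2, "stroke_mild": 1.8, "stroke_moderate": 2.5,
                                 "stroke_severe": 4.0, "mi": 2.0, "se": 2.0},
            "trial_period_years": 1.8,
        },
        "utilities": {
            "baseline_af": 0.779,
            "events": {"stroke_mild": 0.80, "stroke_moderate": 0.55, "stroke_severe": 0.35,
                       "mi": 0.84, "se": 0.81},
            "bleed_decrements": {
                "other_ich": {"decrement": 0.15, "duration_days": 42},
                "other_mb": {"decrement": 0.10, "duration_days": 14},
                "crnm": {"decrement": 0.04, "duration_days": 2},
            },
            "treatment_decrements": {"apixaban": 0.002, "vka": 0.013, "asa": 0.002},
            "joint_method": "multiplicative",
        },
        "costs": {
            "price_year": 2013,
            "drug_per_cycle": {"apixaban": 92.40, "acenocoumarol": 4.20, "phenprocoumon": 6.30, "asa": 1.26},
            "vka_mix": ({"acenocoumarol": 0.8, "phenprocoumon": 0.2} if spec.embed_vka_mix
                        else {"acenocoumarol": 0.5, "phenprocoumon": 0.5}),
            "routine_care_per_cycle": 24.0,
            "inr_monitoring_per_cycle": 16.0,
            "acute": {
                "is_mild": 16000.0, "is_moderate": 42000.0, "is_severe": 52000.0, "is_fatal": 2200.0,
                "hs_mild": 16000.0, "hs_moderate": 42000.0, "hs_severe": 52000.0, "hs_fatal": 2200.0,
                "se": 3600.0, "se_fatal": 0.0,
                "mi": 3800.0, "mi_fatal": 0.0,
                "other_ich": 16000.0, "other_ich_fatal": 0.0,
                "other_mb_gi": 4000.0, "other_mb_non_gi": 4000.0, "other_mb_fatal": 0.0,
                "crnm": 25.0, "crnm_fatal": 0.0,
            },
            "long_term_monthly": {"stroke_mild": 70.0, "stroke_moderate": 350.0,
                                  "stroke_severe": 700.0, "mi": 80.0},
            "inflation_index": {2009: 100.0, 2010: 101.3, 2011: 103.7, 2012: 106.3, 2013: 108.9},
        },
        "settings": {
            "cycle_length_weeks": 6.0,
            "max_age": 110.0,
            "discount_rate_costs": 0.04 if spec.embed_discounting else 0.03,
            "discount_rate_effects": 0.015 if spec.embed_discounting else 0.03,
            "discount_free_years": 1.0,
            "wtp_thresholds": [20000.0, 30000.0] if spec.embed_wtp else [50000.0],
            "psa_iterations": 2000,
            "seed": spec.seed,
            "half_cycle_correction": False,
            "ttr_policy": "population",
        },
        "life_table": generate_life_table(110, spec),
    }
    raw["uncertainty"] = _uncertainty_block(raw)
    return raw


def generate_reference_paramset(spec: FixtureSpec | None = None) -> ModelParameters:
    """Fully validated reference parameter set embedding all printed anchors."""
    return params_from_dict(reference_dict(spec))


def generate_perturbed_paramsets(spec: FixtureSpec, n: int) -> list[ModelParameters]:
    """``n`` valid parameter sets with multiplicative log-normal noise of
    scale ``spec.perturbation_scale`` on rates, utilities and costs.

    Utilities are clamped into [0, 1]; structural quantities (splits,
    fractions, settings) are left at reference values so every set passes
    validation by construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(spec.seed)
    scale = spec.perturbation_scale
    out = []
    for _ in range(n):
        raw = reference_dict(spec)

        def jitter(x: float) -> float:
            return float(x * np.exp(rng.normal(0.0, scale))) if scale > 0 else float(x)

        for th in ("apixaban", "vka", "asa"):
            for ev, v in raw["rates"][th].items():
                raw["rates"][th][ev] = jitter(v)
        for st in raw["rates"]["ttr_strata"]:
            for th in st["rates"]:
                for ev in st["rates"][th]:
                    st["rates"][th][ev] = jitter(st["rates"][th][ev])
        u = raw["utilities"]
        u["baseline_af"] = min(1.0, jitter(u["baseline_af"]))
        for key in u["events"]:
            u["events"][key] = min(1.0, jitter(u["events"][key]))
        for key in u["bleed_decrements"]:
            u["bleed_decrements"][key]["decrement"] = min(1.0, jitter(u["bleed_decrements"][key]["decrement"]))
        c = raw["costs"]
        for group in ("drug_per_cycle", "acute", "long_term_monthly"):
            for key in c[group]:
                c[group][key] = jitter(c[group][key])
        c["routine_care_per_cycle"] = jitter(c["routine_care_per_cycle"])
        c["inr_monitoring_per_cycle"] = jitter(c["inr_monitoring_per_cycle"])
        # re-derive PSA descriptors so they track the perturbed means
        # (and drop beta descriptors whose mean clamped to 1)
        raw["uncertainty"] = _uncertainty_block(raw)
        out.append(params_from_dict(raw))
    return out


def reference_config_path() -> Path:
    """Path of the committed reference configuration YAML."""
    return Path(str(resources.files("oacce").joinpath("data/reference_nl_2013.yaml")))
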