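"""Model parameters: domain types, configuration I/O and validation.

The full input set of the decision model — cohort profile, annual event
rates per therapy (optionally stratified by clinic time-in-therapeutic-range,
cTTR), risk modifiers, utilities, costs, life table and analysis settings —
lives in a single :class:`ModelParameters` object read from a versioned
YAML/JSON configuration file.

Conventions
-----------
* Event rates and mortality rates are **annual rates per 100 person-years**.
* Proportions/fractions are on [0, 1]; CHADS2 weights may be given as
  percentages in the file and are normalised to proportions on load.
* Costs are plain decimals in euros at ``costs.price_year`` prices; rounding
  to whole euros happens only at report-rendering time.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Literal, Mapping, Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator
from pydantic import ValidationError as _PydanticValidationError

from .errors import DataError, DomainError, InvalidParameterError, SchemaError
from .paths import get_by_path

THERAPIES = ("apixaban", "vka", "asa")
#: Events whose trial rates depend on the quality of INR control.
TTR_DEPENDENT_EVENTS = ("ischemic_stroke", "ich", "other_mb", "crnm")
EVENT_FIELDS = (
    "ischemic_stroke",
    "ich",
    "other_mb",
    "crnm",
    "mi",
    "se",
    "discontinuation",
)
SEVERITIES = ("mild", "moderate", "severe", "fatal")


class _Base(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class CohortProfile(_Base):
    """Who enters the model: an ARISTOTLE-like cohort of anticoagulated
    non-valvular AF patients."""

    start_age: float
    fraction_female: float
    cohort_size: float
    #: CHADS2 score -> proportion of the cohort (normalised on load).
    chads2_weights: dict[int, float]
    #: Population mean time in therapeutic range (proportion).
    mean_ttr: float

    @field_validator("chads2_weights")
    @classmethod
    def _normalise_weights(cls, v: dict[int, float]) -> dict[int, float]:
        total = sum(v.values())
        if total <= 0:
            raise ValueError("chads2_weights must have a positive sum")
        return {int(k): float(w) / total for k, w in sorted(v.items())}


class TherapyRates(_Base):
    """Annual event rates per 100 patient-years while on one therapy."""

    ischemic_stroke: float
    ich: float
    other_mb: float
    crnm: float
    mi: float
    se: float
    discontinuation: float
    #: Non-cardiovascular mortality observed during the trial period.
    other_cause_mortality: float


class TtrStratum(_Base):
    """Rates of the TTR-dependent events inside one cTTR band."""

    label: str
    lower: float  # inclusive, proportion
    upper: float  # exclusive, proportion
    rates: dict[str, dict[str, float]]  # therapy -> event -> rate


class EventRateSet(_Base):
    apixaban: TherapyRates
    vka: TherapyRates
    asa: TherapyRates
    ttr_strata: list[TtrStratum] = []

    def for_therapy(self, therapy: str) -> TherapyRates:
        return getattr(self, therapy)


class BleedDecrement(_Base):
    decrement: float
    duration_days: float


class StrokeSeveritySplits(_Base):
    """Mild/moderate/severe/fatal proportions per therapy."""

    apixaban: list[float]
    vka: list[float]
    asa: list[float]

    def for_therapy(self, therapy: str) -> list[float]:
        return getattr(self, therapy)


class RiskModifiers(_Base):
    #: Stroke rate multipliers per CHADS2 score, relative to the trial mix.
    chads2_multipliers: dict[int, float]
    #: Per-decade escalation of stroke, bleeding (ICH/other MB/CRNM) and MI risk.
    age_factor_stroke: float
    age_factor_bleeding: float
    age_factor_mi: float
    #: Fraction of intracranial haemorrhages that are haemorrhagic strokes.
    hs_fraction_of_ich: float
    #: Fraction of other major bleeds that are gastrointestinal.
    gi_fraction_of_other_mb: float
    stroke_severity_is: StrokeSeveritySplits
    stroke_severity_hs: StrokeSeveritySplits
    #: Case fatality among events not covered by a severity split.
    case_fatality: dict[str, float]  # se, mi, other_ich, other_mb, crnm
    #: Probability of staying on the initial therapy after a survivable bleed
    #: (complement switches to ASA).
    post_bleed_stay: dict[str, float]  # other_ich, other_mb, crnm
    #: Annual recurrent-stroke risk (%/year) after first IS / first HS.
    recurrence_annual_risk_pct: dict[str, float]  # post_is, post_hs
    #: Multipliers on other-cause mortality by health state.
    excess_mortality: dict[str, float]  # af, stroke_mild/_moderate/_severe, mi, se
    trial_period_years: float


class UtilitySet(_Base):
    baseline_af: float
    #: Comorbid event-state utilities, combined with the AF utility.
    events: dict[str, float]  # stroke_mild/_moderate/_severe, mi, se
    bleed_decrements: dict[str, BleedDecrement]  # other_ich, other_mb, crnm
    treatment_decrements: dict[str, float]  # apixaban, vka, asa
    joint_method: Literal["multiplicative", "minimum"] = "multiplicative"


class CostSet(_Base):
    price_year: int
    drug_per_cycle: dict[str, float]  # apixaban, acenocoumarol, phenprocoumon, asa
    vka_mix: dict[str, float]  # acenocoumarol/phenprocoumon usage proportions
    routine_care_per_cycle: float
    inr_monitoring_per_cycle: float
    acute: dict[str, float]
    long_term_monthly: dict[str, float]  # stroke_mild/_moderate/_severe, mi
    inflation_index: dict[int, float] = {}


class AnalysisSettings(_Base):
    cycle_length_weeks: float = 6.0
    max_age: float = 110.0
    discount_rate_costs: float = 0.04
    discount_rate_effects: float = 0.015
    discount_free_years: float = 1.0
    wtp_thresholds: list[float] = [20_000.0, 30_000.0]
    psa_iterations: int = 2000
    seed: int = 2014
    half_cycle_correction: bool = False
    #: TTR policy for the base case: "population" (stratum containing the
    #: cohort mean TTR), "equal_mix", "interpolate", or "stratum:<label>".
    ttr_policy: str = "population"


class Uncertainty(_Base):
    """Distributional descriptor for one PSA-flagged parameter.

    Either ``se`` or ``ci95`` must be given; a 95% CI is converted to an SE
    assuming normality on the parameter's natural scale.
    """

    dist: Literal["gamma", "beta", "lognormal"]
    se: Optional[float] = None
    ci95: Optional[tuple[float, float]] = None

    @model_validator(mode="after")
    def _resolve_se(self) -> "Uncertainty":
        if self.se is None:
            if self.ci95 is None:
                raise ValueError("uncertainty descriptor needs 'se' or 'ci95'")
            lo, hi = self.ci95
            object.__setattr__(self, "se", (hi - lo) / (2 * 1.959963984540054))
        return self


class LifeTable(_Base):
    """Annual non-cardiovascular mortality rates per 100 person-years by
    integer age and sex."""

    male: dict[int, float]
    female: dict[int, float]

    def rate(self, age: float, fraction_female: float) -> float:
        a = int(age)
        try:
            rm = self.male[a]
            rf = self.female[a]
        except KeyError:
            raise DataError(f"life table does not cover age {a}")
        return (1.0 - fraction_female) * rm + fraction_female * rf


class ModelParameters(_Base):
    """Complete, immutable model input set."""

    schema_version: int
    cohort: CohortProfile
    rates: EventRateSet
    modifiers: RiskModifiers
    utilities: UtilitySet
    costs: CostSet
    settings: AnalysisSettings
    life_table: LifeTable
    #: dotted parameter path -> uncertainty descriptor (defines the PSA set).
    uncertainty: dict[str, Uncertainty] = {}


# ---------------------------------------------------------------------------
# validation


class ValidationIssue(BaseModel):
    path: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"{self.path}: {self.message}"


class ValidationReport(BaseModel):
    issues: list[ValidationIssue] = []

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, path: str, message: str) -> None:
        self.issues.append(ValidationIssue(path=path, message=message))

    def to_json(self) -> str:
        return json.dumps([i.model_dump() for i in self.issues], indent=2)

    def __str__(self) -> str:
        return "\n".join(str(i) for i in self.issues) or "(no issues)"


def _check_fraction(report: ValidationReport, path: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        report.add(path, f"fraction {value} outside [0, 1]")


def validate_parameters(params: ModelParameters) -> ValidationReport:
    """Check every model invariant; returns a report (empty iff valid).

    Structural problems (wrong types, missing keys) are caught earlier by the
    schema; this function enforces the cross-field scientific invariants.
    """
    r = ValidationReport()
    c = params.cohort
    if not (0.0 < c.mean_ttr < 1.0):
        r.add("cohort.mean_ttr", f"mean TTR {c.mean_ttr} must be in (0, 1)")
    if c.cohort_size <= 0:
        r.add("cohort.cohort_size", "cohort size must be positive")
    if c.start_age <= 0:
        r.add("cohort.start_age", "start age must be positive")
    _check_fraction(r, "cohort.fraction_female", c.fraction_female)
    wsum = sum(c.chads2_weights.values())
    if abs(wsum - 1.0) > 1e-9:
        r.add("cohort.chads2_weights", f"weights sum to {wsum}, expected 1")
    if any(w < 0 for w in c.chads2_weights.values()):
        r.add("cohort.chads2_weights", "negative weight")

    for th in THERAPIES:
        tr = params.rates.for_therapy(th)
        for ev in EVENT_FIELDS + ("other_cause_mortality",):
            v = getattr(tr, ev)
            if v < 0:
                r.add(f"rates.{th}.{ev}", f"rate {v} must be >= 0")
    for i, st in enumerate(params.rates.ttr_strata):
        if not (st.lower < st.upper):
            r.add(f"rates.ttr_strata.{i}", "stratum bounds must satisfy lower < upper")
        for th in ("apixaban", "vka"):
            tbl = st.rates.get(th)
            if tbl is None:
                r.add(f"rates.ttr_strata.{i}.rates", f"missing therapy {th!r}")
                continue
            for ev in TTR_DEPENDENT_EVENTS:
                if ev not in tbl:
                    r.add(f"rates.ttr_strata.{i}.rates.{th}", f"missing event {ev!r}")
                elif tbl[ev] < 0:
                    r.add(f"rates.ttr_strata.{i}.rates.{th}.{ev}", "negative rate")

    m = params.modifiers
    for score, w in c.chads2_weights.items():
        if w > 0 and score not in m.chads2_multipliers:
            r.add("modifiers.chads2_multipliers", f"no multiplier for CHADS2 score {score}")
    for name in ("age_factor_stroke", "age_factor_bleeding", "age_factor_mi"):
        if getattr(m, name) <= 0:
            r.add(f"modifiers.{name}", "age factor must be > 0")
    _check_fraction(r, "modifiers.hs_fraction_of_ich", m.hs_fraction_of_ich)
    _check_fraction(r, "modifiers.gi_fraction_of_other_mb", m.gi_fraction_of_other_mb)
    for kind, splits in (("stroke_severity_is", m.stroke_severity_is), ("stroke_severity_hs", m.stroke_severity_hs)):
        for th in THERAPIES:
            sp = splits.for_therapy(th)
            if len(sp) != 4 or any(x < 0 for x in sp):
                r.add(f"modifiers.{kind}.{th}", "severity split needs 4 non-negative entries")
            elif abs(sum(sp) - 1.0) > 1e-9:
                r.add(f"modifiers.{kind}.{th}", f"severity split sums to {sum(sp)}, expected 1")
    for key, v in m.case_fatality.items():
        _check_fraction(r, f"modifiers.case_fatality.{key}", v)
    for key, v in m.post_bleed_stay.items():
        _check_fraction(r, f"modifiers.post_bleed_stay.{key}", v)
    for key in ("post_is", "post_hs"):
        v = m.recurrence_annual_risk_pct.get(key)
        if v is None:
            r.add("modifiers.recurrence_annual_risk_pct", f"missing {key!r}")
        elif not (0.0 <= v < 100.0):
            r.add(f"modifiers.recurrence_annual_risk_pct.{key}", f"annual risk {v}% outside [0, 100)")
    for key, v in m.excess_mortality.items():
        if v < 0:
            r.add(f"modifiers.excess_mortality.{key}", "multiplier must be >= 0")
    if m.trial_period_years <= 0:
        r.add("modifiers.trial_period_years", "trial period must be > 0")

    u = params.utilities
    _check_fraction(r, "utilities.baseline_af", u.baseline_af)
    for key, v in u.events.items():
        _check_fraction(r, f"utilities.events.{key}", v)
    for key, bd in u.bleed_decrements.items():
        if bd.decrement < 0:
            r.add(f"utilities.bleed_decrements.{key}.decrement", "decrement must be >= 0")
        if bd.duration_days <= 0:
            r.add(f"utilities.bleed_decrements.{key}.duration_days", "duration must be > 0")
    for key, v in u.treatment_decrements.items():
        if v < 0:
            r.add(f"utilities.treatment_decrements.{key}", "decrement must be >= 0")

    co = params.costs
    for group in ("drug_per_cycle", "acute", "long_term_monthly"):
        for key, v in getattr(co, group).items():
            if v < 0:
                r.add(f"costs.{group}.{key}", f"cost {v} must be >= 0")
    if co.routine_care_per_cycle < 0:
        r.add("costs.routine_care_per_cycle", "cost must be >= 0")
    if co.inr_monitoring_per_cycle < 0:
        r.add("costs.inr_monitoring_per_cycle", "cost must be >= 0")
    mix_sum = sum(co.vka_mix.values())
    if abs(mix_sum - 1.0) > 1e-9 or any(v < 0 for v in co.vka_mix.values()):
        r.add("costs.vka_mix", f"usage mix must be non-negative and sum to 1 (got {mix_sum})")

    s = params.settings
    if s.cycle_length_weeks <= 0:
        r.add("settings.cycle_length_weeks", "cycle length must be > 0")
    if s.discount_rate_costs < 0 or s.discount_rate_effects < 0:
        r.add("settings.discount_rate_costs", "discount rates must be >= 0")
    if s.psa_iterations < 1:
        r.add("settings.psa_iterations", "PSA iterations must be >= 1")
    if s.max_age <= c.start_age:
        r.add("settings.max_age", "max age must exceed cohort start age")

    for a in range(int(c.start_age), int(s.max_age) + 1):
        if a not in params.life_table.male or a not in params.life_table.female:
            r.add("life_table", f"missing age {a} for at least one sex")
            break
    for sex in ("male", "female"):
        if any(v < 0 for v in getattr(params.life_table, sex).values()):
            r.add(f"life_table.{sex}", "negative mortality rate")

    for path, desc in params.uncertainty.items():
        try:
            value = get_by_path(params, path)
        except Exception:
            r.add(f"uncertainty.{path}", "path does not resolve to a parameter")
            continue
        if not isinstance(value, (int, float)):
            r.add(f"uncertainty.{path}", "path does not address a scalar parameter")
            continue
        if desc.se is not None and desc.se < 0:
            r.add(f"uncertainty.{path}", "SE must be >= 0")
        if desc.dist == "beta" and not (0.0 < value < 1.0):
            r.add(f"uncertainty.{path}", f"beta-distributed mean {value} outside (0, 1)")
    return r


# ---------------------------------------------------------------------------
# configuration I/O


def _load_raw(path: str | Path) -> dict:
    p = Path(path)
    if not p.exists():
        raise SchemaError(f"configuration file not found: {p}")
    text = p.read_text()
    try:
        if p.suffix.lower() == ".json":
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text)
    except Exception as exc:
        raise SchemaError(f"could not parse configuration {p}: {exc}") from exc
    if not isinstance(raw, dict):
        raise SchemaError(f"configuration root must be a mapping ({p})")
    return raw


def params_from_dict(raw: Mapping[str, Any]) -> ModelParameters:
    """Build and fully validate :class:`ModelParameters` from a plain dict."""
    try:
        params = ModelParameters.model_validate(raw)
    except _PydanticValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(x) for x in err["loc"])
            lines.append(f"{loc}: {err['msg']}")
        raise SchemaError("configuration schema error:\n" + "\n".join(lines)) from exc
    report = validate_parameters(params)
    if not report.ok:
        raise InvalidParameterError(report)
    return params


def load_model_config(path: str | Path) -> ModelParameters:
    """Read a YAML/JSON configuration file into a validated parameter set."""
    return params_from_dict(_load_raw(path))


def save_model_config(params: ModelParameters, path: str | Path) -> None:
    """Serialise a parameter set to YAML (round-trips through
    :func:`load_model_config`)."""
    data = params.model_dump(mode="json")
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def config_hash(params: ModelParameters) -> str:
    """Stable sha256 of the canonical JSON dump, for report provenance."""
    blob = json.dumps(params.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# input-level cost preprocessing


def weighted_vka_drug_cost(
    price_acenocoumarol: float, price_phenprocoumon: float, mix: Mapping[str, float]
) -> float:
    """Usage-mix-weighted VKA drug cost per cycle.

    The Dutch market splits VKA use between acenocoumarol and phenprocoumon
    (80%:20% in the reference configuration)."""
    if price_acenocoumarol < 0 or price_phenprocoumon < 0:
        raise DomainError("drug prices must be >= 0")
    wa = mix.get("acenocoumarol", 0.0)
    wp = mix.get("phenprocoumon", 0.0)
    if wa < 0 or wp < 0 or abs(wa + wp - 1.0) > 1e-9:
        raise DomainError(f"usage mix must be non-negative and sum to 1, got {dict(mix)}")
    return wa * price_acenocoumarol + wp * price_phenprocoumon


def inflate_cost(
    cost: float, from_year: int, to_year: int, index: Mapping[int, float]
) -> float:
    """Rescale a cost between price years with a consumer-price-index series.

    Multiplicative over consecutive spans: inflating a→b then b→c equals a→c.
    """
    if cost < 0:
        raise DomainError("cost must be >= 0")
    if from_year == to_year:
        return cost
    lo, hi = min(from_year, to_year), max(from_year, to_year)
    for year in range(lo, hi + 1):
        if year not in index:
            raise DataError(f"inflation index missing year {year}")
    return cost * index[to_year] / index[from_year]
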