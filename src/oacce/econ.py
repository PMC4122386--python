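"""Economic outcomes: discounted QALYs, life years, costs and the ICER.

Utility accrual
---------------
Each alive person-cycle contributes ``u · Δt · d(c)`` QALYs, where ``u`` is
the state utility (baseline AF utility, or the joint AF/event utility in
post-event states, minus the treatment-specific decrement, clamped to
[0, 1]), ``Δt`` the cycle length in years and ``d(c)`` the effects
discount factor. Bleeding events additionally subtract their configured
utility decrement for the configured duration (rounded up to whole cycles),
applied to the expected event flow. Life years accrue one per person-year
alive, discounted at the effects rate.

Cost accrual
------------
Drug and routine-care costs accrue per person-cycle on therapy; INR
monitoring accrues on VKA person-cycles only; acute event costs accrue per
expected event at the cycle of occurrence; long-term monthly maintenance
costs accrue per person-cycle spent in post-stroke and post-MI states. All
costs are discounted at the cost rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cohort import CohortTrace, EventTally, discount_factor, run_cohort, tally_events
from .errors import ConfigurationError
from .params import AnalysisSettings, CostSet, ModelParameters, UtilitySet, weighted_vka_drug_cost
from .risk import build_transition_model
from .states import EventKey, Therapy


def joint_state_utility(u_af: float, u_event: float, method: str = "multiplicative") -> float:
    """Utility of living with AF and a comorbid event state jointly.

    ``multiplicative`` (default) returns ``u_af · u_event``; ``minimum``
    returns the smaller of the two.
    """
    if not (0.0 <= u_af <= 1.0 and 0.0 <= u_event <= 1.0):
        raise ConfigurationError("utilities must be in [0, 1]")
    if method == "multiplicative":
        return u_af * u_event
    if method == "minimum":
        return min(u_af, u_event)
    raise ConfigurationError(f"unknown joint-utility method {method!r}")


def _state_utility(state, utilities: UtilitySet) -> float:
    u_af = utilities.baseline_af
    if state.kind in ("baseline", "holiday"):
        u = u_af
    elif state.kind in ("post_is", "post_hs"):
        u = joint_state_utility(u_af, utilities.events[f"stroke_{state.severity}"], utilities.joint_method)
    elif state.kind == "post_se":
        u = joint_state_utility(u_af, utilities.events["se"], utilities.joint_method)
    elif state.kind == "post_mi":
        u = joint_state_utility(u_af, utilities.events["mi"], utilities.joint_method)
    else:
        return 0.0
    # treatment decrements apply while actively on an antithrombotic; the
    # drug-holiday cycle and maintenance-only states carry none
    if state.kind != "holiday" and state.therapy in (Therapy.APIXABAN, Therapy.VKA, Therapy.ASA):
        u -= utilities.treatment_decrements[state.therapy.value]
    return min(1.0, max(0.0, u))


_BLEED_KEYS = {
    "other_ich": [EventKey("other_ich", None, False)],
    "other_mb": [EventKey("other_mb", "gi", False), EventKey("other_mb", "non_gi", False)],
    "crnm": [EventKey("crnm", None, False)],
}


def accrue_qalys(
    trace: CohortTrace, utilities: UtilitySet, settings: AnalysisSettings
) -> tuple[float, float]:
    """Discounted (QALYs, LYs) per patient."""
    model = trace.model
    cy = trace.cycle_years
    n = trace.n_cycles
    d_eff = np.array([discount_factor(c, settings.discount_rate_effects, settings) for c in range(n)])
    pt = trace.person_time()  # [n, S] person-years

    u_state = np.array([_state_utility(s, utilities) for s in model.states.states])
    qalys = float(d_eff @ (pt @ u_state))

    alive_py = pt[:, [i for i, s in enumerate(model.states.states) if s.alive]].sum(axis=1)
    lys = float(d_eff @ alive_py)

    # additive bleed decrements for their configured duration (whole cycles)
    for bleed, keys in _BLEED_KEYS.items():
        spec = utilities.bleed_decrements.get(bleed)
        if spec is None or spec.decrement == 0:
            continue
        dur_cycles = max(1, math.ceil(spec.duration_days / (settings.cycle_length_weeks * 7.0) - 1e-12))
        flow = np.zeros(n)
        for key in keys:
            flow += trace.flows_for(key)
        # decrement persists dur_cycles cycles from the event cycle onwards
        d_pad = np.concatenate([d_eff, np.zeros(dur_cycles)])
        window = np.array([d_pad[c : c + dur_cycles].sum() for c in range(n)])
        qalys -= float(spec.decrement * cy * (flow @ window))

    return qalys / trace.cohort_size, lys / trace.cohort_size


_ACUTE_KEY_MAP: list[tuple[EventKey, str]] = [
    (EventKey("se", None, False), "se"),
    (EventKey("se", None, True), "se_fatal"),
    (EventKey("mi", None, False), "mi"),
    (EventKey("mi", None, True), "mi_fatal"),
    (EventKey("other_ich", None, False), "other_ich"),
    (EventKey("other_ich", None, True), "other_ich_fatal"),
    (EventKey("other_mb", "gi", False), "other_mb_gi"),
    (EventKey("other_mb", "non_gi", False), "other_mb_non_gi"),
    (EventKey("other_mb", None, True), "other_mb_fatal"),
    (EventKey("crnm", None, False), "crnm"),
    (EventKey("crnm", None, True), "crnm_fatal"),
]
for _ev, _prefix in (("is", "is"), ("hs", "hs")):
    for _rec in (False, True):
        for _sev in ("mild", "moderate", "severe"):
            _ACUTE_KEY_MAP.append((EventKey(_ev, _sev, False, _rec), f"{_prefix}_{_sev}"))
        _ACUTE_KEY_MAP.append((EventKey(_ev, None, True, _rec), f"{_prefix}_fatal"))


def accrue_costs(trace: CohortTrace, costs: CostSet, settings: AnalysisSettings) -> dict:
    """Discounted cost breakdown per patient.

    Returns a nested dict: ``drug``, ``routine_care``, ``inr_monitoring``,
    ``acute`` (by event type), ``long_term`` (by state type) and ``total``.
    """
    model = trace.model
    n = trace.n_cycles
    cy = trace.cycle_years
    d_cost = np.array([discount_factor(c, settings.discount_rate_costs, settings) for c in range(n)])
    pt = trace.person_time() / cy  # person-cycles [n, S]

    vka_cost = weighted_vka_drug_cost(
        costs.drug_per_cycle["acenocoumarol"], costs.drug_per_cycle["phenprocoumon"], costs.vka_mix
    )
    drug_of = {
        Therapy.APIXABAN: costs.drug_per_cycle["apixaban"],
        Therapy.VKA: vka_cost,
        Therapy.ASA: costs.drug_per_cycle["asa"],
        Therapy.NONE: 0.0,
    }

    drug = routine = inr = 0.0
    long_term: dict[str, float] = {}
    for i, s in enumerate(model.states.states):
        if not s.alive:
            continue
        pc = float(d_cost @ pt[:, i])  # discounted person-cycles
        routine += pc * costs.routine_care_per_cycle
        # drug and INR monitoring only while actively medicated (not during
        # the drug holiday and not in maintenance-only states)
        if s.kind != "holiday" and s.therapy is not None:
            drug += pc * drug_of[s.therapy]
            if s.therapy == Therapy.VKA:
                inr += pc * costs.inr_monitoring_per_cycle
        if s.kind in ("post_is", "post_hs"):
            monthly = costs.long_term_monthly[f"stroke_{s.severity}"]
            label = f"{'is' if s.kind == 'post_is' else 'hs'}_{s.severity}" + ("_recurrent" if s.recurrent else "")
            long_term[label] = long_term.get(label, 0.0) + pc * monthly * cy * 12.0
        elif s.kind == "post_mi":
            monthly = costs.long_term_monthly["mi"]
            long_term["mi"] = long_term.get("mi", 0.0) + pc * monthly * cy * 12.0

    acute: dict[str, float] = {}
    for key, cost_key in _ACUTE_KEY_MAP:
        unit = costs.acute.get(cost_key, 0.0)
        val = float(unit * (trace.flows_for(key) @ d_cost))
        acute[key.label] = acute.get(key.label, 0.0) + val

    size = trace.cohort_size
    breakdown = {
        "drug": drug / size,
        "routine_care": routine / size,
        "inr_monitoring": inr / size,
        "acute": {k: v / size for k, v in sorted(acute.items())},
        "long_term": {k: v / size for k, v in sorted(long_term.items())},
    }
    breakdown["total"] = (
        breakdown["drug"]
        + breakdown["routine_care"]
        + breakdown["inr_monitoring"]
        + sum(breakdown["acute"].values())
        + sum(breakdown["long_term"].values())
    )
    return breakdown


@dataclass
class ArmOutcome:
    """Per-arm discounted totals per patient, plus the event tally."""

    arm: Therapy
    cost_total: float
    cost_breakdown: dict
    qalys: float
    lys: float
    tally: Optional[EventTally] = None
    trace: Optional[CohortTrace] = field(default=None, repr=False)


def evaluate_arm(params: ModelParameters, arm: Therapy | str, keep_trace: bool = False) -> ArmOutcome:
    """Run the full deterministic model for one arm."""
    arm = Therapy(arm)
    model = build_transition_model(params, arm)
    trace = run_cohort(model, params.settings, params.cohort.cohort_size)
    qalys, lys = accrue_qalys(trace, params.utilities, params.settings)
    breakdown = accrue_costs(trace, params.costs, params.settings)
    return ArmOutcome(
        arm=arm,
        cost_total=breakdown["total"],
        cost_breakdown=breakdown,
        qalys=qalys,
        lys=lys,
        tally=tally_events(trace),
        trace=trace if keep_trace else None,
    )


@dataclass
class CEResult:
    """Incremental cost-effectiveness of reference vs comparator."""

    reference: ArmOutcome
    comparator: ArmOutcome
    delta_cost: float
    delta_qalys: float
    delta_lys: float
    icer_per_qaly: Optional[float]
    icer_per_ly: Optional[float]
    label: str  # dominant | dominated | tradeoff | equal


def compute_icer(reference: ArmOutcome, comparator: ArmOutcome) -> CEResult:
    """Incremental analysis: reference minus comparator.

    The ICER is reported only in trade-off quadrants; dominance is labelled
    otherwise. Both ratios are computed from full-precision internals.
    """
    dc = reference.cost_total - comparator.cost_total
    dq = reference.qalys - comparator.qalys
    dl = reference.lys - comparator.lys
    if dc == 0.0 and dq == 0.0:
        label, icer_q = "equal", None
    elif dc < 0.0 and dq > 0.0:
        label, icer_q = "dominant", None
    elif dc > 0.0 and dq < 0.0:
        label, icer_q = "dominated", None
    elif dq == 0.0:
        label, icer_q = ("dominated" if dc > 0 else "dominant"), None
    else:
        label, icer_q = "tradeoff", dc / dq
    icer_l = dc / dl if (label == "tradeoff" and dl != 0.0) else None
    return CEResult(
        reference=reference,
        comparator=comparator,
        delta_cost=dc,
        delta_qalys=dq,
        delta_lys=dl,
        icer_per_qaly=icer_q,
        icer_per_ly=icer_l,
        label=label,
    )


def run_base_case(params: ModelParameters) -> CEResult:
    """Apixaban vs VKA on the configured parameter set."""
    apix = evaluate_arm(params, Therapy.APIXABAN)
    vka = evaluate_arm(params, Therapy.VKA)
    return compute_icer(apix, vka)
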