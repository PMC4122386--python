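"""Risk engine: from annual event rates to per-cycle transition matrices.

The engine converts annual event rates (per 100 patient-years) into
per-cycle transition probabilities for every health state, therapy and age,
layering on top of each other:

* TTR adjustment — trial rates of the INR-control-dependent events (IS,
  ICH, other MB, CRNM bleeding) are replaced by the rates of the configured
  cTTR stratum (or an equal mix / interpolation across strata);
* CHADS2 weighting — the population IS rate is scaled by the
  cohort-weighted mean of per-score stroke multipliers;
* age escalation — per-decade multipliers for stroke, bleeding and MI risk;
* severity and fatality splits, recurrence, post-event therapy switching;
* mortality layering — other-cause mortality (trial-based during the trial
  period, life-table after) times a state-specific excess multiplier.

Rate→probability conversion is exponential, ``p = 1 − exp(−r·t)``, the
standard assumption in decision-analytic modelling. Within a cycle,
competing events are composed cause-specifically: each rate becomes a
cycle hazard ``h_i``, the overall event probability is ``1 − exp(−Σh)``,
and event *i* receives the fraction ``h_i/Σh`` of it. Other-cause death is
then layered multiplicatively as an independent risk, which keeps every row
exactly stochastic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    DataError,
    DomainError,
    ModelLogicError,
)
from .params import (
    TTR_DEPENDENT_EVENTS,
    EventRateSet,
    ModelParameters,
    RiskModifiers,
)
from .states import EventKey, State, StateSpace, Therapy, all_event_keys

#: Calendar-exact annualisation: one year = 52.18 weeks.
WEEKS_PER_YEAR = 52.18


def cycle_years(cycle_length_weeks: float) -> float:
    return cycle_length_weeks / WEEKS_PER_YEAR


def cycles_per_age_step(cycle_length_weeks: float) -> int:
    """Age advances one whole year every this many cycles (life tables are
    annual)."""
    return math.ceil(WEEKS_PER_YEAR / cycle_length_weeks)


def rate_to_cycle_probability(rate: float, cycle_length_weeks: float) -> float:
    """Exponential conversion of an annual rate per 100 person-years to a
    per-cycle probability: ``p = 1 − exp(−(rate/100)·(weeks/52.18))``."""
    if rate < 0:
        raise DomainError(f"rate must be >= 0, got {rate}")
    if cycle_length_weeks <= 0:
        raise DomainError("cycle length must be > 0")
    return -math.expm1(-(rate / 100.0) * cycle_years(cycle_length_weeks))


def _cycle_hazard(rate: float, cycle_length_weeks: float) -> float:
    if rate < 0:
        raise DomainError(f"rate must be >= 0, got {rate}")
    return (rate / 100.0) * cycle_years(cycle_length_weeks)


def chads2_weighted_stroke_rate(
    weights: Mapping[int, float], per_score_rates: Mapping[int, float]
) -> float:
    """Population stroke rate as the CHADS2-weighted mean of per-score rates.

    ``weights`` must be normalised proportions; every score with positive
    weight needs a rate."""
    total = 0.0
    for score, w in weights.items():
        if w == 0:
            continue
        if score not in per_score_rates:
            raise DataError(f"no stroke rate for CHADS2 score {score}")
        total += w * per_score_rates[score]
    return total


def age_escalate(
    rate: float, baseline_age: float, current_age: float, factor_per_decade: float
) -> float:
    """Escalate a rate by ``factor^((age − baseline)/10)``."""
    if factor_per_decade <= 0:
        raise DomainError("age factor must be > 0")
    return rate * factor_per_decade ** ((current_age - baseline_age) / 10.0)


def split_ich(ich_rate: float, hs_fraction: float) -> tuple[float, float]:
    """Partition the ICH rate into haemorrhagic stroke and other ICH."""
    if not (0.0 <= hs_fraction <= 1.0):
        raise DomainError("HS fraction must be in [0, 1]")
    hs = ich_rate * hs_fraction
    return hs, ich_rate - hs


def apply_severity_and_fatality(
    event_flow: float,
    severity_split: Sequence[float],
    fatality: Sequence[float] | float = 0.0,
) -> tuple[list[float], list[float]]:
    """Split an event flow into per-severity non-fatal and fatal components.

    Returns ``(nonfatal, fatal)`` lists of the same length as the split;
    their joint sum equals ``event_flow``.
    """
    if event_flow < 0:
        raise DomainError("event flow must be >= 0")
    if abs(sum(severity_split) - 1.0) > 1e-9 or any(s < 0 for s in severity_split):
        raise DomainError(f"severity split must be non-negative and sum to 1, got {list(severity_split)}")
    if isinstance(fatality, (int, float)):
        fatality = [float(fatality)] * len(severity_split)
    if len(fatality) != len(severity_split):
        raise DomainError("fatality proportions must match the severity split length")
    nonfatal, fatal = [], []
    for s, f in zip(severity_split, fatality):
        if not (0.0 <= f <= 1.0):
            raise DomainError("fatality proportions must be in [0, 1]")
        nonfatal.append(event_flow * s * (1.0 - f))
        fatal.append(event_flow * s * f)
    return nonfatal, fatal


def ttr_adjust_rates(
    rates: EventRateSet,
    ttr_policy: str,
    population_ttr: Optional[float] = None,
) -> EventRateSet:
    """Resolve the TTR-dependent event rates according to a policy.

    Policies: ``"population"`` (stratum containing the population mean TTR),
    ``"equal_mix"`` (unweighted mean across strata, emulating patients
    spread equally over clinics), ``"interpolate"`` (linear interpolation on
    stratum midpoints at the population TTR) or ``"stratum:<label>"``.
    Only apixaban and VKA rates are stratified; ASA rates pass through.
    """
    strata = rates.ttr_strata
    if not strata:
        if ttr_policy in ("population", "equal_mix"):
            return rates  # rates already reflect the intended INR control
        raise ConfigurationError("no cTTR strata configured")

    def adjusted(event_of: Mapping[str, Mapping[str, float]]) -> EventRateSet:
        data = rates.model_dump()
        for th in ("apixaban", "vka"):
            for ev in TTR_DEPENDENT_EVENTS:
                data[th][ev] = event_of[th][ev]
        return EventRateSet.model_validate(data)

    if ttr_policy.startswith("stratum:"):
        label = ttr_policy.split(":", 1)[1]
        for st in strata:
            if st.label == label:
                return adjusted(st.rates)
        raise ConfigurationError(f"unknown cTTR stratum {label!r}")

    if ttr_policy == "equal_mix":
        mix = {
            th: {ev: float(np.mean([st.rates[th][ev] for st in strata])) for ev in TTR_DEPENDENT_EVENTS}
            for th in ("apixaban", "vka")
        }
        return adjusted(mix)

    if ttr_policy == "population":
        if population_ttr is None:
            raise ConfigurationError("population TTR required for policy 'population'")
        for st in strata:
            if st.lower <= population_ttr < st.upper:
                return adjusted(st.rates)
        raise ConfigurationError(f"population TTR {population_ttr} outside all configured strata")

    if ttr_policy == "interpolate":
        if population_ttr is None:
            raise ConfigurationError("population TTR required for policy 'interpolate'")
        ordered = sorted(strata, key=lambda st: (st.lower + st.upper) / 2.0)
        mids = [(st.lower + st.upper) / 2.0 for st in ordered]
        out: dict[str, dict[str, float]] = {}
        for th in ("apixaban", "vka"):
            out[th] = {}
            for ev in TTR_DEPENDENT_EVENTS:
                ys = [st.rates[th][ev] for st in ordered]
                out[th][ev] = float(np.interp(population_ttr, mids, ys))
        return adjusted(out)

    raise ConfigurationError(f"unknown TTR policy {ttr_policy!r}")


def recurrence_probability(
    post_state: str,
    modifiers: RiskModifiers,
    cycle_length_weeks: float,
    already_recurred: bool = False,
) -> float:
    """Per-cycle probability of the single permitted recurrent stroke.

    ``post_state`` is ``"post_is"`` or ``"post_hs"``; the corresponding
    annual risks (2.97%/2.17% per year in the reference configuration) are
    converted exponentially to the cycle length."""
    if already_recurred:
        raise ModelLogicError("state has already had its one recurrent stroke")
    if post_state not in ("post_is", "post_hs"):
        raise ModelLogicError(f"recurrence undefined for state {post_state!r}")
    annual = modifiers.recurrence_annual_risk_pct[post_state]
    return rate_to_cycle_probability(annual, cycle_length_weeks)


@dataclass(frozen=True)
class TherapyAssignment:
    therapy: Therapy
    holiday: bool
    probability: float


def post_event_therapy(
    event: str, current_therapy: Therapy, modifiers: RiskModifiers
) -> list[TherapyAssignment]:
    """Therapy (possibly probabilistic) after surviving an event.

    IS/SE survivors stay on the assigned anticoagulant; HS/MI survivors move
    to maintenance only; bleed survivors split between staying (with a
    one-cycle drug holiday after a non-HS ICH) and switching to ASA; other
    treatment discontinuation always switches to ASA.
    """
    if event in ("is", "se"):
        return [TherapyAssignment(current_therapy, False, 1.0)]
    if event in ("hs", "mi"):
        return [TherapyAssignment(Therapy.NONE, False, 1.0)]
    if event in ("other_ich", "other_mb", "crnm"):
        stay = modifiers.post_bleed_stay[event]
        if not (0.0 <= stay <= 1.0):
            raise DomainError("post-bleed stay fraction must be in [0, 1]")
        holiday = event == "other_ich"
        out = []
        if stay > 0:
            out.append(TherapyAssignment(current_therapy, holiday, stay))
        if stay < 1:
            out.append(TherapyAssignment(Therapy.ASA, False, 1.0 - stay))
        return out
    if event == "discontinuation":
        return [TherapyAssignment(Therapy.ASA, False, 1.0)]
    raise ModelLogicError(f"unknown event type {event!r}")


def layer_mortality(
    row: np.ndarray,
    other_cause_rate: float,
    excess_multiplier: float,
    cycle_length_weeks: float,
    dead_index: int,
) -> np.ndarray:
    """Add other-cause mortality to a transition row, competing-risk style.

    Death is layered as an independent risk: every destination (including
    prior fatal-event flow into ``dead``) is scaled by the cycle survival
    probability and the death probability is added to ``dead``. The row
    remains stochastic to machine precision.
    """
    if excess_multiplier < 0:
        raise DomainError("excess-mortality multiplier must be >= 0")
    p_dead = rate_to_cycle_probability(other_cause_rate * excess_multiplier, cycle_length_weeks)
    out = row * (1.0 - p_dead)
    out[dead_index] += p_dead
    return out


# ---------------------------------------------------------------------------
# transition-model assembly


@dataclass
class Block:
    """Transition matrix and event-flow annotations for one (age, trial
    period) combination."""

    matrix: np.ndarray  # [S, S]
    flows: np.ndarray  # [K, S]: per-individual event probability by origin state


@dataclass
class TransitionModel:
    states: StateSpace
    event_keys: list[EventKey]
    blocks: dict[tuple[int, bool], Block]
    block_of_cycle: list[tuple[int, bool]]
    cycle_length_weeks: float
    arm: Therapy
    start_age: float

    @property
    def n_cycles(self) -> int:
        return len(self.block_of_cycle)

    @property
    def cycle_years(self) -> float:
        return cycle_years(self.cycle_length_weeks)

    def matrix_at(self, cycle: int) -> np.ndarray:
        return self.blocks[self.block_of_cycle[cycle]].matrix

    def flows_at(self, cycle: int) -> np.ndarray:
        return self.blocks[self.block_of_cycle[cycle]].flows

    def age_at(self, cycle: int) -> int:
        return self.block_of_cycle[cycle][0]

    def check_rows(self, tol: float = 1e-12) -> None:
        for key, block in self.blocks.items():
            sums = block.matrix.sum(axis=1)
            if np.max(np.abs(sums - 1.0)) > tol or np.min(block.matrix) < -tol:
                raise ModelLogicError(f"non-stochastic transition row in block {key}")

    def to_long_frame(self):
        """Long-format audit export: state_from, state_to, age, arm, probability."""
        import pandas as pd

        rows = []
        seen = set()
        for cyc in range(self.n_cycles):
            key = self.block_of_cycle[cyc]
            if key in seen:
                continue
            seen.add(key)
            age, in_trial = key
            m = self.blocks[key].matrix
            for i, si in enumerate(self.states.states):
                for j, sj in enumerate(self.states.states):
                    if m[i, j] != 0.0:
                        rows.append(
                            {
                                "state_from": si.label,
                                "state_to": sj.label,
                                "age": age,
                                "in_trial": in_trial,
                                "arm": self.arm.value,
                                "probability": m[i, j],
                            }
                        )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, index=False)


_SEVERITIES = ("mild", "moderate", "severe")


def build_transition_model(params: ModelParameters, arm: Therapy | str) -> TransitionModel:
    """Assemble the full age-dependent transition model for one arm."""
    arm = Therapy(arm)
    space = StateSpace(arm)
    keys = all_event_keys()
    kidx = {k: i for i, k in enumerate(keys)}
    S, K = len(space), len(keys)
    m = params.modifiers
    settings = params.settings
    cl = settings.cycle_length_weeks
    cy = cycle_years(cl)
    cps = cycles_per_age_step(cl)
    start_age = params.cohort.start_age

    eff = ttr_adjust_rates(params.rates, settings.ttr_policy, params.cohort.mean_ttr)
    chads2_factor = chads2_weighted_stroke_rate(
        params.cohort.chads2_weights, m.chads2_multipliers
    )

    def other_cause_rate(state: State, in_trial: bool, age: int) -> float:
        if in_trial:
            th = state.therapy if state.therapy in (Therapy.APIXABAN, Therapy.VKA, Therapy.ASA) else arm
            return eff.for_therapy(th.value).other_cause_mortality
        return params.life_table.rate(age, params.cohort.fraction_female)

    def excess(state: State) -> float:
        if state.kind in ("baseline", "holiday"):
            return m.excess_mortality["af"]
        if state.kind in ("post_is", "post_hs"):
            return m.excess_mortality[f"stroke_{state.severity}"]
        if state.kind == "post_se":
            return m.excess_mortality["se"]
        if state.kind == "post_mi":
            return m.excess_mortality["mi"]
        return 0.0

    def event_row(state: State, age: int) -> tuple[np.ndarray, np.ndarray]:
        """Row and event flows before mortality layering."""
        row = np.zeros(S)
        flows = np.zeros(K)
        i_self = space.idx(state)
        dead = space.dead_index

        if state.kind == "dead":
            row[dead] = 1.0
            return row, flows

        if state.kind in ("baseline", "holiday"):
            th = state.therapy
            assert th is not None
            # During a drug holiday the anticoagulant effect is absent; the
            # ASA rate profile stands in for the unprotected risk level.
            rate_th = "asa" if state.kind == "holiday" else th.value
            tr = eff.for_therapy(rate_th)
            esc_s = m.age_factor_stroke ** ((age - start_age) / 10.0)
            esc_b = m.age_factor_bleeding ** ((age - start_age) / 10.0)
            esc_m = m.age_factor_mi ** ((age - start_age) / 10.0)
            hs_rate, oich_rate = split_ich(tr.ich * esc_b, m.hs_fraction_of_ich)
            hazards = {
                "is": _cycle_hazard(tr.ischemic_stroke * chads2_factor * esc_s, cl),
                "hs": _cycle_hazard(hs_rate, cl),
                "other_ich": _cycle_hazard(oich_rate, cl),
                "other_mb": _cycle_hazard(tr.other_mb * esc_b, cl),
                "crnm": _cycle_hazard(tr.crnm * esc_b, cl),
                "mi": _cycle_hazard(tr.mi * esc_m, cl),
                "se": _cycle_hazard(tr.se, cl),
                "discontinuation": 0.0 if state.kind == "holiday" else _cycle_hazard(tr.discontinuation, cl),
            }
            H = sum(hazards.values())
            p_any = -math.expm1(-H) if H > 0 else 0.0
            flow = {ev: (h / H * p_any if H > 0 else 0.0) for ev, h in hazards.items()}

            def route_survivors(event: str, amount: float, dest_kind: str | None = None, severity: str | None = None):
                """Send survivors of *event* to their post-event destinations."""
                for asg in post_event_therapy(event, th, m):
                    p = amount * asg.probability
                    if p == 0.0:
                        continue
                    if event in ("is",):
                        row[space.idx(State("post_is", asg.therapy, severity, False))] += p
                    elif event == "hs":
                        row[space.idx(State("post_hs", Therapy.NONE, severity, False))] += p
                    elif event == "se":
                        row[space.idx(State("post_se", asg.therapy))] += p
                    elif event == "mi":
                        row[space.idx(State("post_mi", Therapy.NONE))] += p
                    elif asg.holiday:
                        row[space.idx(State("holiday", asg.therapy))] += p
                    else:
                        row[space.idx(State("baseline", asg.therapy))] += p

            # strokes: four-way severity split, fatal component explicit
            for ev, splits in (("is", m.stroke_severity_is), ("hs", m.stroke_severity_hs)):
                nonfatal, fatal = apply_severity_and_fatality(
                    flow[ev], splits.for_therapy(rate_th if state.kind == "holiday" else th.value),
                    [0.0, 0.0, 0.0, 1.0],
                )
                for sev, p in zip(_SEVERITIES, nonfatal[:3]):
                    route_survivors(ev, p, severity=sev)
                    flows[kidx[EventKey(ev, sev, False, False)]] += p
                # fourth split entry is fatal; remainder of the flow dies
                row[dead] += flow[ev] - sum(nonfatal[:3])
                flows[kidx[EventKey(ev, None, True, False)]] += flow[ev] - sum(nonfatal[:3])

            # events with scalar case fatality
            for ev in ("se", "mi", "other_ich", "other_mb", "crnm"):
                cf = m.case_fatality.get(ev, 0.0)
                f_total = flow[ev]
                f_fatal = f_total * cf
                f_surv = f_total - f_fatal
                row[dead] += f_fatal
                flows[kidx[EventKey(ev, None, True, False)]] += f_fatal
                if ev == "other_mb":
                    flows[kidx[EventKey(ev, "gi", False, False)]] += f_surv * m.gi_fraction_of_other_mb
                    flows[kidx[EventKey(ev, "non_gi", False, False)]] += f_surv * (1.0 - m.gi_fraction_of_other_mb)
                else:
                    flows[kidx[EventKey(ev, None, False, False)]] += f_surv
                route_survivors(ev, f_surv)

            f_disc = flow["discontinuation"]
            if f_disc > 0:
                flows[kidx[EventKey("discontinuation", None, False, False)]] += f_disc
                route_survivors("discontinuation", f_disc)

            # holiday survivors without an event resume the interrupted therapy
            remainder = 1.0 - p_any
            if state.kind == "holiday":
                row[space.idx(State("baseline", th))] += remainder
            else:
                row[i_self] += remainder
            return row, flows

        if state.kind in ("post_is", "post_hs"):
            if state.recurrent:
                row[i_self] = 1.0
                return row, flows
            ev = "is" if state.kind == "post_is" else "hs"
            p_rec = recurrence_probability(state.kind, m, cl)
            # recurrent-stroke severity mirrors first strokes under apixaban
            split = (m.stroke_severity_is if ev == "is" else m.stroke_severity_hs).apixaban
            nonfatal, _ = apply_severity_and_fatality(p_rec, split, [0.0, 0.0, 0.0, 1.0])
            for sev, p in zip(_SEVERITIES, nonfatal[:3]):
                if ev == "is":
                    row[space.idx(State("post_is", state.therapy, sev, True))] += p
                else:
                    row[space.idx(State("post_hs", Therapy.NONE, sev, True))] += p
                flows[kidx[EventKey(ev, sev, False, True)]] += p
            p_fatal = p_rec - sum(nonfatal[:3])
            row[dead] += p_fatal
            flows[kidx[EventKey(ev, None, True, True)]] += p_fatal
            row[i_self] += 1.0 - p_rec
            return row, flows

        if state.kind in ("post_se", "post_mi"):
            row[i_self] = 1.0  # absorbing apart from layered mortality
            return row, flows

        raise ModelLogicError(f"unhandled state kind {state.kind!r}")

    # distinct (age, in_trial) combinations actually visited
    max_age = int(settings.max_age)
    n_cycles = (max_age - int(start_age) + 1) * cps
    block_of_cycle: list[tuple[int, bool]] = []
    for c in range(n_cycles):
        age = int(start_age) + c // cps
        in_trial = c * cy < m.trial_period_years
        block_of_cycle.append((age, in_trial))

    blocks: dict[tuple[int, bool], Block] = {}
    for key in dict.fromkeys(block_of_cycle):
        age, in_trial = key
        matrix = np.zeros((S, S))
        fmat = np.zeros((K, S))
        for i, state in enumerate(space.states):
            row, flows = event_row(state, age)
            if state.kind != "dead":
                rate0 = other_cause_rate(state, in_trial, age)
                p_dead = rate_to_cycle_probability(rate0 * excess(state), cl)
                row = row * (1.0 - p_dead)
                row[space.dead_index] += p_dead
                flows = flows * (1.0 - p_dead)
            matrix[i] = row
            fmat[:, i] = flows
        blocks[key] = Block(matrix=matrix, flows=fmat)

    model = TransitionModel(
        states=space,
        event_keys=keys,
        blocks=blocks,
        block_of_cycle=block_of_cycle,
        cycle_length_weeks=cl,
        arm=arm,
        start_age=start_age,
    )
    model.check_rows()
    return model
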