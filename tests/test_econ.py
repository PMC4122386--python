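"""Economic outcomes: utilities, accrual, ICER."""

import numpy as np
import pytest

from oacce import (
    ConfigurationError,
    Therapy,
    accrue_costs,
    accrue_qalys,
    compute_icer,
    joint_state_utility,
)
from oacce.cohort import CohortTrace, run_cohort
from oacce.econ import ArmOutcome
from oacce.params import AnalysisSettings, UtilitySet
from oacce.risk import Block, TransitionModel
from oacce.states import EventKey, State, StateSpace, Therapy as Th, all_event_keys

from _oracles import make_constant_model


class TestJointUtility:
    def test_identity_comorbidity(self):
        assert joint_state_utility(0.73, 1.0) == pytest.approx(0.73)

    def test_multiplicative(self):
        assert joint_state_utility(0.8, 0.5, "multiplicative") == pytest.approx(0.40)

    def test_minimum(self):
        assert joint_state_utility(0.8, 0.5, "minimum") == 0.5

    def test_multiplicative_below_min(self):
        assert joint_state_utility(0.9, 0.6) <= min(0.9, 0.6)

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigurationError):
            joint_state_utility(0.8, 0.5, "harmonic")


def _manual_trace(arm, occupancy_by_label, n_cycles, cycle_weeks, flows=None, cohort_size=1.0):
    """Hand-built trace: constant occupancy, optional event flows."""
    space = StateSpace(arm)
    keys = all_event_keys()
    S = len(space)
    occ = np.zeros((n_cycles + 1, S))
    for label, persons in occupancy_by_label.items():
        idx = next(i for i, s in enumerate(space.states) if s.label == label)
        occ[:, idx] = persons
    fl = np.zeros((len(keys), n_cycles))
    if flows:
        for (key, cyc), v in flows.items():
            fl[keys.index(key), cyc] = v
    model = TransitionModel(
        states=space,
        event_keys=keys,
        blocks={},
        block_of_cycle=[(70, True)] * n_cycles,
        cycle_length_weeks=cycle_weeks,
        arm=arm,
        start_age=70.0,
    )
    settings = AnalysisSettings(cycle_length_weeks=cycle_weeks, discount_rate_costs=0.0, discount_rate_effects=0.0)
    return CohortTrace(model=model, occupancy=occ, event_flows=fl, cohort_size=cohort_size, settings=settings), settings


def _plain_utilities(**overrides):
    base = dict(
        baseline_af=1.0,
        events={"stroke_mild": 1.0, "stroke_moderate": 1.0, "stroke_severe": 1.0, "mi": 1.0, "se": 1.0},
        bleed_decrements={},
        treatment_decrements={"apixaban": 0.0, "vka": 0.0, "asa": 0.0},
        joint_method="multiplicative",
    )
    base.update(overrides)
    return UtilitySet.model_validate(base)


class TestAccrueQalys:
    def test_perfect_health_one_year(self):
        # one person, utility 1, no discounting: QALY = LY = 1 over a year
        trace, settings = _manual_trace(Th.VKA, {"baseline:vka": 1.0}, n_cycles=1, cycle_weeks=52.18)
        q, l = accrue_qalys(trace, _plain_utilities(), settings)
        assert q == pytest.approx(1.0) and l == pytest.approx(1.0)

    def test_half_year_at_utility_08(self):
        # 26.09 weeks alive at utility 0.8 → 0.4 QALYs
        trace, settings = _manual_trace(Th.VKA, {"baseline:vka": 1.0}, n_cycles=1, cycle_weeks=26.09)
        q, _ = accrue_qalys(trace, _plain_utilities(baseline_af=0.8), settings)
        assert q == pytest.approx(0.4)

    def test_single_cycle_bleed_decrement(self):
        # a CRNM decrement of 0.1 lasting one cycle removes 0.1·(6/52.18) QALYs
        flows = {(EventKey("crnm", None, False), 0): 1.0}
        trace, settings = _manual_trace(
            Th.VKA, {"baseline:vka": 1.0}, n_cycles=4, cycle_weeks=6.0, flows=flows
        )
        utils_plain = _plain_utilities()
        utils_bleed = _plain_utilities(
            bleed_decrements={"crnm": {"decrement": 0.1, "duration_days": 42}}
        )
        q0, _ = accrue_qalys(trace, utils_plain, settings)
        q1, _ = accrue_qalys(trace, utils_bleed, settings)
        assert q0 - q1 == pytest.approx(0.1 * 6.0 / 52.18, abs=1e-12)

    def test_qalys_never_exceed_lys(self, ref_params, apix_outcome, vka_outcome):
        for outcome in (apix_outcome, vka_outcome):
            assert 0.0 <= outcome.qalys <= outcome.lys

    def test_zero_discount_no_events_qalys_equal_person_years(self):
        m = make_constant_model(np.eye(2), n_cycles=10)
        settings = AnalysisSettings(discount_rate_costs=0.0, discount_rate_effects=0.0)
        trace = run_cohort(m, settings, cohort_size=1.0)
        # fake model states are baseline states on apixaban with utility 1
        q, l = accrue_qalys(trace, _plain_utilities(), settings)
        assert q == pytest.approx(l)
        assert l == pytest.approx(10 * 6.0 / 52.18)


class TestAccrueCosts:
    def test_zero_costs_zero_breakdown(self, ref_params):
        trace, settings = _manual_trace(Th.VKA, {"baseline:vka": 1.0}, n_cycles=2, cycle_weeks=6.0)
        costs = ref_params.costs.model_copy(
            update={
                "drug_per_cycle": {k: 0.0 for k in ref_params.costs.drug_per_cycle},
                "routine_care_per_cycle": 0.0,
                "inr_monitoring_per_cycle": 0.0,
                "acute": {k: 0.0 for k in ref_params.costs.acute},
                "long_term_monthly": {k: 0.0 for k in ref_params.costs.long_term_monthly},
            }
        )
        assert accrue_costs(trace, costs, settings)["total"] == 0.0

    def test_inr_monitoring_only_on_vka(self, ref_params):
        trace_v, settings = _manual_trace(Th.VKA, {"baseline:vka": 1.0}, n_cycles=1, cycle_weeks=6.0)
        trace_a, _ = _manual_trace(Th.APIXABAN, {"baseline:apixaban": 1.0}, n_cycles=1, cycle_weeks=6.0)
        inr_v = accrue_costs(trace_v, ref_params.costs, settings)["inr_monitoring"]
        inr_a = accrue_costs(trace_a, ref_params.costs, settings)["inr_monitoring"]
        assert inr_v == pytest.approx(ref_params.costs.inr_monitoring_per_cycle)
        assert inr_a == 0.0

    def test_single_event_acute_cost(self, ref_params):
        flows = {(EventKey("is", "moderate", False), 0): 1.0}
        trace, settings = _manual_trace(
            Th.VKA, {"baseline:vka": 1.0}, n_cycles=1, cycle_weeks=6.0, flows=flows
        )
        bd = accrue_costs(trace, ref_params.costs, settings)
        assert bd["acute"]["is:moderate:nonfatal"] == pytest.approx(ref_params.costs.acute["is_moderate"])

    def test_breakdown_sums_to_total(self, apix_outcome, vka_outcome):
        for outcome in (apix_outcome, vka_outcome):
            bd = outcome.cost_breakdown
            parts = (
                bd["drug"] + bd["routine_care"] + bd["inr_monitoring"]
                + sum(bd["acute"].values()) + sum(bd["long_term"].values())
            )
            assert parts == pytest.approx(bd["total"], abs=0.5)
            assert all(v >= 0 for v in bd["acute"].values())

    def test_raising_drug_cost_raises_total(self, ref_params):
        from oacce import evaluate_arm
        from oacce.fixtures import reference_dict
        from oacce.params import params_from_dict

        raw = reference_dict()
        raw["costs"]["drug_per_cycle"]["apixaban"] *= 1.5
        dearer = params_from_dict(raw)
        base = evaluate_arm(ref_params, Therapy.APIXABAN)
        more = evaluate_arm(dearer, Therapy.APIXABAN)
        assert more.cost_total > base.cost_total
        assert more.qalys == pytest.approx(base.qalys, abs=1e-12)


def _stub(arm, cost, qalys, lys):
    return ArmOutcome(arm=arm, cost_total=cost, cost_breakdown={}, qalys=qalys, lys=lys)


class TestComputeIcer:
    def test_published_table_arithmetic(self):
        """The rounded per-arm totals imply Δ€1,852 and 0.18 QALYs; their
        ratio (≈€10,289) differs from an ICER computed from unrounded
        internals, which is why full precision is kept until rendering."""
        res = compute_icer(_stub(Th.APIXABAN, 20205.0, 7.18, 10.44), _stub(Th.VKA, 18353.0, 7.00, 10.26))
        assert res.delta_cost == pytest.approx(1852.0)
        assert res.delta_qalys == pytest.approx(0.18)
        assert res.icer_per_qaly == pytest.approx(1852.0 / 0.18, abs=1.0)
        assert abs(res.icer_per_qaly - 10289.0) < 1.0
        assert res.label == "tradeoff"

    def test_equal_arms(self):
        res = compute_icer(_stub(Th.APIXABAN, 100.0, 5.0, 6.0), _stub(Th.VKA, 100.0, 5.0, 6.0))
        assert res.label == "equal" and res.icer_per_qaly is None

    def test_dominance_labels(self):
        dom = compute_icer(_stub(Th.APIXABAN, 90.0, 5.1, 6.0), _stub(Th.VKA, 100.0, 5.0, 6.0))
        assert dom.label == "dominant" and dom.icer_per_qaly is None
        ded = compute_icer(_stub(Th.APIXABAN, 110.0, 4.9, 6.0), _stub(Th.VKA, 100.0, 5.0, 6.0))
        assert ded.label == "dominated" and ded.icer_per_qaly is None

    def test_zero_effect_labels_without_ratio(self):
        res = compute_icer(_stub(Th.APIXABAN, 110.0, 5.0, 6.0), _stub(Th.VKA, 100.0, 5.0, 6.0))
        assert res.icer_per_qaly is None and res.label == "dominated"
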