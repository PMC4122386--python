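"""Risk engine: rate conversion, adjustments, routing, transition assembly."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oacce import (
    ConfigurationError,
    DataError,
    DomainError,
    ModelLogicError,
    Therapy,
    age_escalate,
    apply_severity_and_fatality,
    build_transition_model,
    chads2_weighted_stroke_rate,
    layer_mortality,
    post_event_therapy,
    rate_to_cycle_probability,
    recurrence_probability,
    split_ich,
    ttr_adjust_rates,
)
from oacce.fixtures import reference_dict
from oacce.params import params_from_dict

from _oracles import microstep_probability, microstep_two_event


class TestRateConversion:
    def test_zero_rate(self):
        assert rate_to_cycle_probability(0.0, 6.0) == 0.0

    def test_one_year_cycle_half_hazard(self):
        # rate 50/100py over a full 52.18-week year: 1 − e^−0.5
        assert rate_to_cycle_probability(50.0, 52.18) == pytest.approx(0.3935, abs=1e-4)

    @pytest.mark.parametrize("rate", [0.0, 0.5, 1.159, 1.787, 5.0, 13.5, 25.0, 50.0])
    def test_agrees_with_microstep_oracle(self, rate):
        p = rate_to_cycle_probability(rate, 6.0)
        assert p == pytest.approx(microstep_probability(rate, 6.0), abs=1e-6)

    def test_negative_rate_rejected(self):
        with pytest.raises(DomainError):
            rate_to_cycle_probability(-1.0, 6.0)

    @given(r1=st.floats(0, 50), r2=st.floats(0, 50))
    def test_monotone_and_bounded(self, r1, r2):
        p1, p2 = (rate_to_cycle_probability(r, 6.0) for r in (r1, r2))
        assert 0.0 <= p1 < 1.0
        if r1 <= r2:
            assert p1 <= p2


class TestChads2Weighting:
    def test_point_mass(self):
        assert chads2_weighted_stroke_rate({2: 1.0}, {2: 4.2}) == 4.2

    def test_cohort_weights_match_explicit_loop(self, ref_params):
        weights = ref_params.cohort.chads2_weights
        rates = {s: 1.0 + 0.5 * s for s in range(1, 8)}
        explicit = 0.0
        for score in weights:
            explicit += weights[score] * rates[score]
        assert chads2_weighted_stroke_rate(weights, rates) == pytest.approx(explicit, abs=1e-12)

    def test_constant_rates_are_invariant(self):
        weights = {s: 1.0 / 7 for s in range(1, 8)}
        assert chads2_weighted_stroke_rate(weights, {s: 3.3 for s in range(1, 8)}) == pytest.approx(3.3)

    def test_missing_score_raises(self):
        with pytest.raises(DataError):
            chads2_weighted_stroke_rate({2: 0.5, 3: 0.5}, {2: 1.0})

    def test_reference_multipliers_average_to_one(self, ref_params):
        factor = chads2_weighted_stroke_rate(
            ref_params.cohort.chads2_weights, ref_params.modifiers.chads2_multipliers
        )
        assert factor == pytest.approx(1.0, abs=1e-9)


class TestTtrAdjustment:
    def test_high_control_stratum_lookup(self, ref_params):
        adj = ttr_adjust_rates(ref_params.rates, "stratum:cTTR>=76.51%")
        assert adj.vka.ischemic_stroke == pytest.approx(0.831)
        assert adj.apixaban.ich == pytest.approx(0.181)

    def test_population_policy_selects_containing_stratum(self, ref_params):
        adj = ttr_adjust_rates(ref_params.rates, "population", population_ttr=0.7248)
        # the stratum 66.02–76.51% rates are implied by the equal-mix row
        assert adj.vka.ischemic_stroke == pytest.approx(0.967, abs=1e-9)

    def test_equal_mix_is_unweighted_mean(self, ref_params):
        adj = ttr_adjust_rates(ref_params.rates, "equal_mix")
        strata = ref_params.rates.ttr_strata
        mean = np.mean([st.rates["vka"]["ischemic_stroke"] for st in strata])
        assert adj.vka.ischemic_stroke == pytest.approx(mean, abs=1e-12)
        assert adj.vka.ischemic_stroke == pytest.approx(1.186, abs=1e-9)

    def test_single_stratum_identity(self, ref_params):
        data = ref_params.rates.model_dump()
        data["ttr_strata"] = [data["ttr_strata"][0]]
        from oacce.params import EventRateSet

        rates = EventRateSet.model_validate(data)
        adj = ttr_adjust_rates(rates, "equal_mix")
        assert adj.vka.ischemic_stroke == pytest.approx(1.787)

    def test_population_ttr_outside_strata_raises(self, ref_params):
        data = ref_params.rates.model_dump()
        for st_ in data["ttr_strata"]:
            st_["upper"] = min(st_["upper"], 0.9)
        from oacce.params import EventRateSet

        with pytest.raises(ConfigurationError):
            ttr_adjust_rates(EventRateSet.model_validate(data), "population", population_ttr=0.95)

    def test_unknown_stratum_raises(self, ref_params):
        with pytest.raises(ConfigurationError):
            ttr_adjust_rates(ref_params.rates, "stratum:does-not-exist")


class TestSimpleAdjustments:
    def test_age_escalation(self):
        assert age_escalate(2.0, 70, 70, 1.4) == 2.0
        assert age_escalate(2.0, 70, 80, 1.4) == pytest.approx(2.8)
        assert age_escalate(2.0, 70, 93, 1.0) == 2.0

    def test_split_ich(self):
        assert split_ich(2.0, 0.6) == (pytest.approx(1.2), pytest.approx(0.8))
        assert split_ich(3.0, 1.0) == (3.0, 0.0)
        assert split_ich(3.0, 0.0) == (0.0, 3.0)

    def test_severity_and_fatality_partition(self):
        nonfatal, fatal = apply_severity_and_fatality(0.01, [0.4, 0.35, 0.13, 0.12], 0.0)
        assert nonfatal == pytest.approx([0.004, 0.0035, 0.0013, 0.0012])
        assert sum(nonfatal) + sum(fatal) == pytest.approx(0.01, abs=1e-12)

    def test_degenerate_split(self):
        nonfatal, _ = apply_severity_and_fatality(0.2, [1.0, 0.0, 0.0, 0.0], 0.0)
        assert nonfatal[0] == pytest.approx(0.2)
        nonfatal, fatal = apply_severity_and_fatality(0.0, [0.25] * 4, 0.5)
        assert sum(nonfatal) == sum(fatal) == 0.0

    def test_bad_split_rejected(self):
        with pytest.raises(DomainError):
            apply_severity_and_fatality(0.1, [0.5, 0.5, 0.5, 0.5], 0.0)

    @given(
        flow=st.floats(0, 1),
        split=st.lists(st.floats(0.01, 1), min_size=4, max_size=4),
        fat=st.floats(0, 1),
    )
    def test_partition_property(self, flow, split, fat):
        total = sum(split)
        split = [s / total for s in split]
        nonfatal, fatal = apply_severity_and_fatality(flow, split, fat)
        assert sum(nonfatal) + sum(fatal) == pytest.approx(flow, abs=1e-9)


class TestRecurrence:
    def test_zero_risk(self, ref_params):
        data = ref_params.modifiers.model_copy(
            update={"recurrence_annual_risk_pct": {"post_is": 0.0, "post_hs": 0.0}}
        )
        assert recurrence_probability("post_is", data, 6.0) == 0.0

    def test_matches_microstep_oracle(self, ref_params):
        p = recurrence_probability("post_is", ref_params.modifiers, 6.0)
        assert p == pytest.approx(microstep_probability(2.97, 6.0), abs=1e-6)

    def test_post_hs_strictly_below_post_is(self, ref_params):
        p_is = recurrence_probability("post_is", ref_params.modifiers, 6.0)
        p_hs = recurrence_probability("post_hs", ref_params.modifiers, 6.0)
        assert p_hs < p_is

    def test_second_recurrence_is_a_logic_error(self, ref_params):
        with pytest.raises(ModelLogicError):
            recurrence_probability("post_is", ref_params.modifiers, 6.0, already_recurred=True)


class TestPostEventTherapy:
    def test_stroke_survivors_stay_on_therapy(self, ref_params):
        (asg,) = post_event_therapy("is", Therapy.APIXABAN, ref_params.modifiers)
        assert asg.therapy == Therapy.APIXABAN and not asg.holiday and asg.probability == 1.0

    def test_discontinuation_switches_to_asa(self, ref_params):
        (asg,) = post_event_therapy("discontinuation", Therapy.VKA, ref_params.modifiers)
        assert asg.therapy == Therapy.ASA

    def test_hs_and_mi_to_maintenance_only(self, ref_params):
        for ev in ("hs", "mi"):
            (asg,) = post_event_therapy(ev, Therapy.VKA, ref_params.modifiers)
            assert asg.therapy == Therapy.NONE

    def test_full_stay_ich_gets_drug_holiday(self, ref_params):
        mods = ref_params.modifiers.model_copy(
            update={"post_bleed_stay": {"other_ich": 1.0, "other_mb": 0.75, "crnm": 0.9}}
        )
        (asg,) = post_event_therapy("other_ich", Therapy.APIXABAN, mods)
        assert asg.therapy == Therapy.APIXABAN and asg.holiday and asg.probability == 1.0

    def test_bleed_allocation_probabilities_sum_to_one(self, ref_params):
        for ev in ("other_ich", "other_mb", "crnm"):
            assignments = post_event_therapy(ev, Therapy.VKA, ref_params.modifiers)
            assert sum(a.probability for a in assignments) == pytest.approx(1.0)

    def test_unknown_event_rejected(self, ref_params):
        with pytest.raises(ModelLogicError):
            post_event_therapy("meteor_strike", Therapy.VKA, ref_params.modifiers)


class TestLayerMortality:
    def test_zero_rate_leaves_row_unchanged(self):
        row = np.array([0.9, 0.1, 0.0])
        out = layer_mortality(row, 0.0, 1.0, 6.0, dead_index=2)
        assert np.allclose(out, row)

    def test_unit_multiplier_equals_other_cause_alone(self):
        row = np.array([1.0, 0.0, 0.0])
        out = layer_mortality(row, 5.0, 1.0, 6.0, dead_index=2)
        assert out[2] == pytest.approx(rate_to_cycle_probability(5.0, 6.0))

    def test_two_event_enumeration_oracle(self):
        # toy row: event at 20/100py, other-cause death at 5/100py
        p_event = rate_to_cycle_probability(20.0, 6.0)
        row = np.array([1.0 - p_event, p_event, 0.0])
        out = layer_mortality(row, 5.0, 1.0, 6.0, dead_index=2)
        stay, in_a, dead = microstep_two_event(20.0, 5.0, 6.0)
        assert out[2] == pytest.approx(dead, abs=1e-5)
        assert out[1] == pytest.approx(in_a, abs=1e-5)
        assert out[0] == pytest.approx(stay, abs=1e-5)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)


def _silent_params():
    """All event rates zero, no mortality: the cohort should never move."""
    raw = reference_dict()
    for th in ("apixaban", "vka", "asa"):
        for ev in raw["rates"][th]:
            raw["rates"][th][ev] = 0.0
    for st_ in raw["rates"]["ttr_strata"]:
        for th in st_["rates"]:
            for ev in st_["rates"][th]:
                st_["rates"][th][ev] = 0.0
    for sex in ("male", "female"):
        raw["life_table"][sex] = {a: 0.0 for a in raw["life_table"][sex]}
    raw["uncertainty"] = {}
    return params_from_dict(raw)


class TestBuildTransitionModel:
    def test_rows_are_stochastic_everywhere(self, ref_params):
        for arm in (Therapy.APIXABAN, Therapy.VKA):
            model = build_transition_model(ref_params, arm)
            for block in model.blocks.values():
                sums = block.matrix.sum(axis=1)
                assert np.max(np.abs(sums - 1.0)) <= 1e-12
                assert block.matrix.min() >= 0.0

    def test_zero_rates_give_identity_on_baseline(self):
        model = build_transition_model(_silent_params(), Therapy.APIXABAN)
        entry = model.states.entry_index
        for block in model.blocks.values():
            row = block.matrix[entry]
            assert row[entry] == pytest.approx(1.0, abs=1e-12)

    def test_identical_rates_give_identical_arms(self, ref_params):
        raw = reference_dict()
        raw["rates"]["vka"] = dict(raw["rates"]["apixaban"])
        for st_ in raw["rates"]["ttr_strata"]:
            st_["rates"]["vka"] = dict(st_["rates"]["apixaban"])
        raw["modifiers"]["stroke_severity_is"]["vka"] = raw["modifiers"]["stroke_severity_is"]["apixaban"]
        raw["modifiers"]["stroke_severity_hs"]["vka"] = raw["modifiers"]["stroke_severity_hs"]["apixaban"]
        raw["uncertainty"] = {}
        params = params_from_dict(raw)
        ma = build_transition_model(params, Therapy.APIXABAN)
        mv = build_transition_model(params, Therapy.VKA)
        for key in ma.blocks:
            assert np.allclose(ma.blocks[key].matrix, mv.blocks[key].matrix, atol=1e-15)

    def test_se_and_mi_states_are_absorbing(self, ref_params):
        model = build_transition_model(ref_params, Therapy.VKA)
        dead = model.states.dead_index
        for i, state in enumerate(model.states.states):
            if state.kind in ("post_se", "post_mi"):
                for block in model.blocks.values():
                    row = block.matrix[i]
                    mass_elsewhere = row.sum() - row[i] - row[dead]
                    assert mass_elsewhere == pytest.approx(0.0, abs=1e-15)

    def test_event_flow_monotone_in_own_rate(self, ref_params):
        raw = reference_dict()
        base = params_from_dict(raw)
        raw2 = reference_dict()
        raw2["rates"]["vka"]["mi"] *= 2.0
        boosted = params_from_dict(raw2)
        from oacce.states import EventKey

        mb = build_transition_model(base, Therapy.VKA)
        mh = build_transition_model(boosted, Therapy.VKA)
        k = mb.event_keys.index(EventKey("mi", None, False))
        entry = mb.states.entry_index
        key = mb.block_of_cycle[0]
        assert mh.blocks[key].flows[k, entry] > mb.blocks[key].flows[k, entry]

    def test_spot_check_baseline_row_composition(self, ref_params):
        """One baseline row recomposed by hand from the sub-operations."""
        model = build_transition_model(ref_params, Therapy.APIXABAN)
        key = model.block_of_cycle[0]  # age 70, in trial
        entry = model.states.entry_index
        row = model.blocks[key].matrix[entry]

        m = ref_params.modifiers
        tr = ttr_adjust_rates(ref_params.rates, "population", 0.7248).apixaban
        cyc = 6.0 / 52.18
        hs_rate, oich_rate = split_ich(tr.ich, m.hs_fraction_of_ich)
        hazards = {
            "is": tr.ischemic_stroke * cyc / 100,
            "hs": hs_rate * cyc / 100,
            "other_ich": oich_rate * cyc / 100,
            "other_mb": tr.other_mb * cyc / 100,
            "crnm": tr.crnm * cyc / 100,
            "mi": tr.mi * cyc / 100,
            "se": tr.se * cyc / 100,
            "disc": tr.discontinuation * cyc / 100,
        }
        H = sum(hazards.values())
        p_any = 1 - math.exp(-H)
        p_dead_oc = rate_to_cycle_probability(
            tr.other_cause_mortality * m.excess_mortality["af"], 6.0
        )
        # expected flow into the post-MI state: MI survivors scaled by cycle survival
        flow_mi = hazards["mi"] / H * p_any * (1 - m.case_fatality["mi"]) * (1 - p_dead_oc)
        from oacce.states import State

        i_mi = model.states.idx(State("post_mi", Therapy.NONE))
        assert row[i_mi] == pytest.approx(flow_mi, rel=1e-12)
        # expected stay probability: no-event remainder plus bleed survivors
        # who stay on therapy (other MB and CRNM; ICH stayers go on holiday)
        stay_mb = hazards["other_mb"] / H * p_any * (1 - m.case_fatality["other_mb"]) * m.post_bleed_stay["other_mb"]
        stay_crnm = hazards["crnm"] / H * p_any * (1 - m.case_fatality["crnm"]) * m.post_bleed_stay["crnm"]
        expected_stay = (1 - p_any + stay_mb + stay_crnm) * (1 - p_dead_oc)
        assert row[entry] == pytest.approx(expected_stay, rel=1e-12)

    def test_long_format_export(self, ref_params, tmp_path):
        model = build_transition_model(ref_params, Therapy.VKA)
        df = model.to_long_frame()
        assert set(df.columns) == {"state_from", "state_to", "age", "in_trial", "arm", "probability"}
        assert (df["arm"] == "vka").all()
        grouped = df.groupby(["state_from", "age", "in_trial"])["probability"].sum()
        assert np.allclose(grouped, 1.0, atol=1e-9)
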