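"""Per-item risk rules, component aggregation, and rule variants."""
import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lifescreen import (
    RiskLevel,
    aggregate_component,
    get_variant,
    load_schema,
    score_assessment,
    score_blood_pressure,
    score_bmi,
    score_categorical_item,
    score_lab,
    score_nutrition_frequencies,
    score_smoking_block,
    score_waist,
    validate_response,
)
from lifescreen.rules import FOOD_FIELDS

LOW, MOD, REL, NS = (RiskLevel.LOW, RiskLevel.MODERATE, RiskLevel.RELEVANT,
                     RiskLevel.NOT_SCORED)
EPS = 0.01


class TestRiskLevel:
    def test_ordering_and_colors(self):
        assert LOW < MOD < REL
        assert [lv.color for lv in (LOW, MOD, REL, NS)] == [
            "green", "yellow", "orange", "none"]

    def test_not_scored_has_no_rank(self):
        with pytest.raises(ValueError):
            NS < LOW  # noqa: B015


class TestNumericBoundaries:
    """Threshold-eps / threshold / threshold+eps land in the printed bands."""

    @pytest.mark.parametrize("bmi, expected", [
        (18.5 - EPS, MOD), (18.5, LOW), (18.5 + EPS, LOW),
        (25.0 - EPS, LOW), (25.0, MOD), (25.0 + EPS, MOD),
        (30.0 - EPS, MOD), (30.0, REL), (30.0 + EPS, REL),
        (22.0, LOW),
    ])
    def test_bmi(self, bmi, expected):
        assert score_bmi(bmi) is expected

    @pytest.mark.parametrize("waist, sex, expected", [
        (94 - EPS, "male", LOW), (94, "male", MOD), (94 + EPS, "male", MOD),
        (102 - EPS, "male", MOD), (102, "male", MOD), (102 + EPS, "male", REL),
        (80 - EPS, "female", LOW), (80, "female", MOD), (80 + EPS, "female", MOD),
        (88 - EPS, "female", MOD), (88, "female", MOD), (88 + EPS, "female", REL),
        (93.9, "male", LOW), (88.5, "female", REL),
    ])
    def test_waist(self, waist, sex, expected):
        assert score_waist(waist, sex) is expected

    @pytest.mark.parametrize("sbp, dbp, expected", [
        (130 - EPS, 70, LOW), (130, 70, MOD), (130 + EPS, 70, MOD),
        (140 - EPS, 70, MOD), (140, 70, REL), (140 + EPS, 70, REL),
        (120, 85 - EPS, LOW), (120, 85, MOD), (120, 85 + EPS, MOD),
        (120, 90 - EPS, MOD), (120, 90, REL), (120, 90 + EPS, REL),
        (120, 80, LOW), (132, 80, MOD), (120, 92, REL),
    ])
    def test_blood_pressure_is_disjunctive(self, sbp, dbp, expected):
        assert score_blood_pressure(sbp, dbp) is expected

    @pytest.mark.parametrize("value, lab, expected", [
        (110 - EPS, "glycemia", LOW), (110, "glycemia", MOD),
        (110 + EPS, "glycemia", MOD),
        (126 - EPS, "glycemia", MOD), (126, "glycemia", REL),
        (126 + EPS, "glycemia", REL),
        (190 - EPS, "cholesterol", LOW), (190, "cholesterol", MOD),
        (190 + EPS, "cholesterol", MOD),
        (240 - EPS, "cholesterol", MOD), (240, "cholesterol", REL),
        (240 + EPS, "cholesterol", REL),
        (125.9, "glycemia", MOD), (240, "cholesterol", REL),
    ])
    def test_labs(self, value, lab, expected):
        assert score_lab(value, lab) is expected

    @pytest.mark.parametrize("category, expected", [
        ("normal", LOW), ("high", MOD), ("unknown", NS)])
    def test_lab_category_fallback(self, category, expected):
        assert score_lab(category, "glycemia") is expected
        assert score_lab(category, "cholesterol") is expected


class TestCategoricalRules:
    @pytest.mark.parametrize("item, answer, expected", [
        ("2.1", "yes", REL), ("2.2", "lt30", REL), ("2.2", "30to60", MOD),
        ("2.2", "gt60", LOW), ("2.3", "no", REL),
        ("2.4", "one_or_two", LOW), ("2.4", "three_or_more", LOW),
        ("3.1", "strongly_disagree", REL), ("3.1", "neutral", MOD),
        ("3.1", "agree", LOW), ("3.1", "prefer_not_to_answer", NS),
        ("3.2", "none", REL), ("3.2", "one_or_two", MOD),
        ("3.2", "three_to_five", LOW), ("3.2", "six_or_more", LOW),
        ("3.3.1", "no", MOD), ("3.3.3", "not_applicable", NS),
        ("3.3.4", "no", LOW),
        ("4.1", "no", MOD),
        ("6.3", "lt_1y", REL), ("6.3", "1_to_5y", MOD),
        ("6.3", "5_to_10y", MOD), ("6.3", "gt_10y", LOW),
        ("6.4", "yes", MOD), ("6.7", "yes", REL),
        ("7.2", "lt5h", REL), ("7.3", "4_or_more", REL),
        ("7.4", "yes", REL), ("7.5", "yes", REL),
        ("8.1", "yes", MOD), ("8.2", "more_than_five", REL),
        ("8.3", "yes", MOD), ("8.4", "reasonable", MOD), ("8.4", "very_bad", REL),
    ])
    def test_table_lookup(self, item, answer, expected):
        assert score_categorical_item(item, answer) is expected

    def test_unknown_pair_raises(self):
        with pytest.raises(KeyError):
            score_categorical_item("2.1", "maybe")
        with pytest.raises(KeyError):
            score_categorical_item("9.9", "yes")

    def test_totality_over_all_domains(self, schema):
        """Every in-domain answer maps to exactly one level, both variants."""
        from lifescreen.rules import _ruleset
        table = _ruleset()["categorical"]
        for variant in ("as_printed", "narrative_corrected"):
            for item_id, cells in table.items():
                for answer in cells:
                    risk = score_categorical_item(item_id, answer, variant)
                    assert isinstance(risk, RiskLevel)

    def test_variants_differ_only_on_illicit_use_item(self):
        from lifescreen.rules import _ruleset
        table = _ruleset()["categorical"]
        diffs = []
        for item_id, cells in table.items():
            for answer in cells:
                a = score_categorical_item(item_id, answer, "as_printed")
                b = score_categorical_item(item_id, answer, "narrative_corrected")
                if a is not b:
                    diffs.append((item_id, answer, a, b))
        assert diffs == [("6.6", "no", MOD, LOW)]


class TestNutrition:
    BASE = dict(zip(FOOD_FIELDS, ["times_4_6_per_week"] * 5 +
                    ["lt_once_per_week", "never"]))

    def test_healthy_week_is_low(self):
        assert score_nutrition_frequencies(self.BASE) is LOW

    def test_intermediate_is_moderate(self):
        freqs = dict.fromkeys(FOOD_FIELDS, "times_1_3_per_week")
        assert score_nutrition_frequencies(freqs) is MOD

    def test_never_vegetables_is_relevant(self):
        freqs = dict(self.BASE, food_vegetables_fruit="never")
        assert score_nutrition_frequencies(freqs) is REL

    def test_frequent_sweets_is_relevant(self):
        freqs = dict(self.BASE, food_sweets="times_4_6_per_week")
        assert score_nutrition_frequencies(freqs) is REL

    def test_vegan_exemption_neutralizes_animal_groups(self):
        vegan = dict(self.BASE, food_milk_products="never",
                     food_fish_meat_eggs="never")
        assert score_nutrition_frequencies(vegan) is REL
        assert score_nutrition_frequencies(vegan, exemption=True) is MOD

    def test_exemption_does_not_cover_vegetables(self):
        freqs = dict(self.BASE, food_vegetables_fruit="never")
        assert score_nutrition_frequencies(freqs, exemption=True) is REL

    def test_incomplete_grid_not_scored(self):
        freqs = dict(self.BASE)
        del freqs["food_sweets"]
        assert score_nutrition_frequencies(freqs) is NS


class TestSmokingBlock:
    def test_long_quit_ex_smoker_is_low_by_default(self):
        scores, block = score_smoking_block("no", "yes", "gt_10y")
        assert block is LOW
        by_id = {s.item_id: s for s in scores}
        assert by_id["6.2"].risk is NS  # superseded by the cessation answer
        assert by_id["6.3"].risk is LOW

    def test_long_quit_ex_smoker_stays_moderate_as_printed(self):
        _, block = score_smoking_block("no", "yes", "gt_10y", "as_printed")
        assert block is MOD

    def test_recent_quitter_is_relevant(self):
        _, block = score_smoking_block("no", "yes", "lt_1y")
        assert block is REL

    def test_current_smoker_is_relevant(self):
        _, block = score_smoking_block("yes", None, None)
        assert block is REL

    def test_never_smoker_is_low(self):
        _, block = score_smoking_block("no", "no", None)
        assert block is LOW

    def test_quit_answer_without_ex_smoker_status_raises(self):
        with pytest.raises(ValueError):
            score_smoking_block("yes", "yes", "gt_10y")

    def test_supersession_is_the_only_block_level_variant_difference(self):
        answers = [("yes", "no", None), ("yes", "yes", None), ("no", "no", None),
                   ("no", "yes", None)]
        for a61, a62, a63 in answers:
            _, printed = score_smoking_block(a61, a62, a63, "as_printed")
            _, corrected = score_smoking_block(a61, a62, a63,
                                               "narrative_corrected")
            assert printed is corrected  # differences require a 6.3 answer


def verbal_aggregate(levels):
    """Independent restatement of the stated aggregation rule.

    Three exhaustive, mutually exclusive clauses over the scored answers:
    relevant if at least one is orange; moderate if at least one is yellow
    and none orange; low if all are green.  No scored answer: not scored.
    """
    scored = [lv for lv in levels if lv is not NS]
    if not scored:
        return NS
    if any(lv is REL for lv in scored):
        return REL
    if any(lv is MOD for lv in scored):
        return MOD
    assert all(lv is LOW for lv in scored)
    return LOW


class TestAggregation:
    @pytest.mark.parametrize("levels, expected", [
        ([LOW, LOW, LOW], LOW),
        ([LOW, MOD, LOW], MOD),
        ([LOW, MOD, REL], REL),
        ([NS, NS], NS),
        ([], NS),
    ])
    def test_examples(self, levels, expected):
        assert aggregate_component(levels) is expected

    def test_exhaustive_oracle_equivalence(self):
        """Enumerate every level combination up to 6 items against the oracle."""
        levels = (LOW, MOD, REL, NS)
        for k in range(7):
            for combo in itertools.product(levels, repeat=k):
                assert aggregate_component(list(combo)) is \
                    verbal_aggregate(combo), combo

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from([LOW, MOD, REL, NS]), min_size=1, max_size=8),
           st.data())
    def test_monotone_under_single_item_escalation(self, levels, data):
        """Raising one item's risk never lowers the component aggregate."""
        escalation = {LOW: MOD, MOD: REL}
        candidates = [i for i, lv in enumerate(levels) if lv in escalation]
        if not candidates:
            return
        i = data.draw(st.sampled_from(candidates))
        before = aggregate_component(levels)
        raised = list(levels)
        raised[i] = escalation[raised[i]]
        after = aggregate_component(raised)
        if before is not NS:
            assert after >= before


class TestAssessment:
    def test_textbook_low_risk_respondent(self, low_risk_record):
        results = score_assessment(validate_response(low_risk_record))
        assert [r.aggregate for r in results] == [LOW] * 8

    def test_single_rule_perturbation(self, low_risk_record):
        low_risk_record["glycemia"] = 130
        results = score_assessment(validate_response(low_risk_record))
        assert results[0].aggregate is REL
        assert results[0].sub_block_risks["glycemia"] is REL
        assert [r.aggregate for r in results[1:]] == [LOW] * 7

    def test_numeric_lab_takes_precedence_over_category(self, low_risk_record):
        low_risk_record["glycemia_category"] = "high"
        results = score_assessment(validate_response(low_risk_record))
        assert results[0].sub_block_risks["glycemia"] is LOW  # 90 mg/dl wins

    def test_category_fallback_when_no_number(self, low_risk_record):
        del low_risk_record["glycemia"]
        low_risk_record["glycemia_category"] = "high"
        results = score_assessment(validate_response(low_risk_record))
        assert results[0].sub_block_risks["glycemia"] is MOD

    def test_all_missing_gives_not_scored_everywhere(self):
        results = score_assessment(validate_response({}))
        assert [r.aggregate for r in results] == [NS] * 8

    def test_vas_never_contributes_risk(self, low_risk_record):
        low_risk_record["health_vas"] = 0  # worst imaginable health
        results = score_assessment(validate_response(low_risk_record))
        assert results[7].aggregate is LOW
        vas_score = [s for s in results[7].item_scores if s.item_id == "8.5"][0]
        assert vas_score.risk is NS

    def test_component_one_uses_derived_bmi(self, low_risk_record):
        low_risk_record.update(weight=95, height=1.75)  # BMI 31.02
        results = score_assessment(validate_response(low_risk_record))
        assert results[0].sub_block_risks["bmi_wc"] is REL

    def test_deterministic(self, low_risk_record):
        resp = validate_response(low_risk_record)
        assert score_assessment(resp) == score_assessment(resp)

    def test_component_six_sub_blocks(self, low_risk_record):
        low_risk_record.update(smokes="no", smoked_before="yes",
                               quit_smoking="1_to_5y", alcohol="yes",
                               drugs_before="yes")
        results = score_assessment(validate_response(low_risk_record))
        sub = results[5].sub_block_risks
        assert sub == {"smoking": MOD, "drinking": MOD, "illicit": REL}
        assert results[5].aggregate is REL
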