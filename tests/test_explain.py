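import pytest

from gcmed import (
    AudienceProfile,
    CellValue,
    ExplanationPlan,
    GraphCode,
    GENERIC_PROFILE,
    MEDICAL_PROFILE,
    PATIENT_PROFILE,
    PRESENCE,
    derivation,
    diff,
    explaining_code,
    plan_clauses,
    render,
)
from gcmed.explain import DerivationError, parse_english
from gcmed.graph_code import GraphCodeError
from gcmed.synthetic_data import TimelineSpec, make_timeline

from conftest import random_code


def presence_code(terms, asset_id="x"):
    gc = GraphCode(dictionary=list(terms), asset_id=asset_id)
    for t in terms:
        gc.set_cell(t, t, PRESENCE)
    return gc


@pytest.fixture
def scene_profile():
    return AudienceProfile(
        name="scene",
        labels={"hat": "the hat", "head": "the head", "person": "the person"},
        phrases={"5": "is above", "3": "belongs to", "4": "is a"},
    )


@pytest.fixture
def bp_diff():
    tl = make_timeline(
        TimelineSpec(
            "P1",
            events=(("January", "blood-pressure", 140), ("July", "blood-pressure", 155)),
        )
    )
    return diff(tl.snapshots[0][1], tl.snapshots[1][1], labels=("January", "July"))


class TestExplainingCode:
    def test_equal_codes_give_empty_esgc_and_no_difference_sentence(self):
        x = random_code(1)
        esgc = explaining_code(x, x)
        assert len(esgc) == 0
        plan = ExplanationPlan(source=esgc, mode="result_comparison", audience=MEDICAL_PROFILE)
        assert render(plan) == MEDICAL_PROFILE.no_change_sentence + "."

    def test_contained_query_leaves_result_only_terms(self):
        result = presence_code(["a", "b", "c"], "r")
        query = presence_code(["a"], "q")
        esgc = explaining_code(result, query)
        assert esgc.term_set == {"b", "c"}

    def test_two_frsgcs_differing_in_bmi_and_blood_pressure(self):
        shared = ["patient", "name"]
        a = presence_code(shared + ["BMI", "blood-pressure"], "a")
        b = presence_code(shared, "b")
        esgc = explaining_code(a, b)
        assert esgc.term_set == {"BMI", "blood-pressure"}


class TestRender:
    def test_blood_pressure_sentence_verbatim_for_medical_audience(self, bp_diff):
        plan = ExplanationPlan(source=bp_diff, mode="timeline_diff", audience=MEDICAL_PROFILE)
        text = render(plan)
        assert "between January and July, the blood pressure increased from 140 to 155" in text

    def test_patient_audience_changes_surface_only(self, bp_diff):
        plan = ExplanationPlan(source=bp_diff, mode="timeline_diff", audience=PATIENT_PROFILE)
        text = render(plan)
        assert "your blood pressure increased from 140 to 155" in text

    def test_decrease_direction(self):
        tl = make_timeline(
            TimelineSpec("P1", events=(("t1", "BMI", 31), ("t2", "BMI", 27)))
        )
        d = diff(tl.snapshots[0][1], tl.snapshots[1][1], labels=("t1", "t2"))
        text = render(ExplanationPlan(source=d, mode="timeline_diff", audience=MEDICAL_PROFILE))
        assert "decreased from 31 to 27" in text

    def test_hat_above_head_clause(self, scene_profile):
        esgc = presence_code(["hat", "head"])
        esgc.set_cell("hat", "head", CellValue.rel(5))
        plan = ExplanationPlan(source=esgc, mode="result_membership", audience=scene_profile)
        assert render(plan) == "the hat is above the head."

    def test_one_clause_per_off_diagonal_cell_in_dictionary_order(self, scene_profile):
        esgc = presence_code(["hat", "head", "person"])
        esgc.set_cell("hat", "head", CellValue.rel(5))
        esgc.set_cell("head", "person", CellValue.rel(5))
        clauses = plan_clauses(esgc, scene_profile)
        assert [c.text for c in clauses] == [
            "the hat is above the head",
            "the head is above the person",
        ]
        assert len(clauses) == len(list(esgc.off_diagonal_cells()))

    def test_discrete_cell_verbalizes_its_value(self):
        esgc = presence_code(["blood-pressure", "P1"])
        esgc.set_cell("blood-pressure", "P1", CellValue.discrete(140))
        (clause,) = plan_clauses(esgc, MEDICAL_PROFILE)
        assert clause.text == "blood pressure has a value of 140"

    def test_missing_label_falls_back_with_warning(self, caplog):
        esgc = presence_code(["tissue density", "scan"])
        esgc.set_cell("tissue density", "scan", CellValue.rel(3))
        with caplog.at_level("WARNING"):
            (clause,) = plan_clauses(esgc, MEDICAL_PROFILE)
        assert "tissue density" in clause.text
        assert any("label" in r.message for r in caplog.records)

    def test_render_deterministic(self, bp_diff):
        plan = ExplanationPlan(source=bp_diff, mode="timeline_diff", audience=MEDICAL_PROFILE)
        assert render(plan) == render(plan)

    def test_swapping_profile_keeps_explained_cells(self, scene_profile):
        esgc = presence_code(["hat", "head"])
        esgc.set_cell("hat", "head", CellValue.rel(5))
        a = plan_clauses(esgc, scene_profile)
        b = plan_clauses(esgc, GENERIC_PROFILE)
        assert len(a) == len(b)
        assert [tuple(s for s, _ in c.parts) for c in a] == [
            tuple(s for s, _ in c.parts) for c in b
        ]

    def test_mode_source_consistency_enforced(self, bp_diff):
        with pytest.raises(GraphCodeError):
            ExplanationPlan(source=bp_diff, mode="result_membership", audience=MEDICAL_PROFILE)
        with pytest.raises(GraphCodeError):
            ExplanationPlan(source=presence_code(["a"]), mode="timeline_diff",
                            audience=MEDICAL_PROFILE)


class TestDerivation:
    def test_english_ps_tree_for_hat_above_head(self):
        tree = parse_english("the hat is above the head")
        assert tree.symbol == "S"
        assert [c.symbol for c in tree.children] == ["NP", "VP"]
        vp = tree.children[1]
        assert [c.symbol for c in vp.children] == ["V", "PP"]
        pp = vp.children[1]
        assert [c.symbol for c in pp.children] == ["PR", "NP"]
        np = tree.children[0]
        assert [c.symbol for c in np.children] == ["DET", "N"]
        assert tree.sentence == "the hat is above the head"

    def test_single_label_answer_is_one_node_expansion(self):
        from gcmed.explain import Clause

        tree = derivation(Clause(parts=(("LBL", "BMI"),)))
        assert tree.symbol == "dict_answer" and tree.sentence == "BMI"

    def test_unparseable_clause_names_first_unmatched_symbol(self):
        with pytest.raises(DerivationError, match="hatstand.*N|N.*hatstand"):
            parse_english("the hatstand is above the head")
        with pytest.raises(DerivationError):
            parse_english("the hat is above")

    @pytest.mark.parametrize("seed", range(8))
    def test_every_rendered_clause_has_a_valid_derivation(self, seed, scene_profile):
        esgc = random_code(seed)
        for clause in plan_clauses(esgc, scene_profile):
            tree = derivation(clause)
            assert tree.sentence == clause.text

    def test_clause_leaves_concatenate_to_the_sentence(self, scene_profile):
        esgc = presence_code(["hat", "head"])
        esgc.set_cell("hat", "head", CellValue.rel(5))
        (clause,) = plan_clauses(esgc, scene_profile)
        tree = derivation(clause)
        assert " ".join(tree.leaves()) == clause.text == "the hat is above the head"


class TestProfiles:
    def test_json_round_trip(self, tmp_path):
        path = tmp_path / "profile.json"
        path.write_text(MEDICAL_PROFILE.to_json())
        back = AudienceProfile.from_json(path)
        assert back.name == "medical"
        assert back.phrases == MEDICAL_PROFILE.phrases
        assert back.change_template == MEDICAL_PROFILE.change_template

    def test_patient_bmi_label_is_didactic(self):
        assert PATIENT_PROFILE.labels["BMI"].startswith("BMI is the body mass index")
        assert PATIENT_PROFILE.phrases["3"] == "Your value is"
        assert MEDICAL_PROFILE.phrases["3"] == "has a value of"
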