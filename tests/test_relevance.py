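import math

import pytest

from gcmed import (
    CellValue,
    GraphCode,
    GraphCodeCollection,
    GraphCodeError,
    PRESENCE,
    build_stop_code,
    collection_tfidf,
    edit_stop_code,
    feature_relevant,
    frsgc_hist,
    gc_tfidf,
    m_abt,
    m_dis,
    m_rel,
    row_weight,
)
from gcmed.synthetic_data import CollectionSpec, TimelineSpec, make_collection, make_timeline

from conftest import random_code


def presence_code(terms, asset_id):
    gc = GraphCode(dictionary=list(terms), asset_id=asset_id)
    for t in terms:
        gc.set_cell(t, t, PRESENCE)
    return gc


@pytest.fixture
def shared_unique_coll():
    """Six codes: terms s0..s3 in all, one unique term per code with one
    relationship from the unique term to s0."""
    codes = []
    for e in range(6):
        terms = [f"s{k}" for k in range(4)] + [f"u{e}"]
        gc = presence_code(terms, f"a{e}")
        gc.set_cell(f"u{e}", "s0", CellValue.rel(3))
        codes.append(gc)
    return GraphCodeCollection(codes)


class TestRowWeightAndDiscrimination:
    def test_printed_matrix_row_counts(self, table1_code):
        # row "Eye Distance 3 3 1 0 0": two non-empty off-diagonal cells
        assert row_weight(table1_code, "Eye Distance") == 2
        # row "Face 1 1 0 0 0 0": none
        assert row_weight(table1_code, "Face 1") == 0

    def test_isolated_term_has_zero_weight(self):
        gc = presence_code(["lonely"], "x")
        assert row_weight(gc, "lonely") == 0

    def test_unknown_term_is_an_error(self, table1_code):
        with pytest.raises(GraphCodeError):
            row_weight(table1_code, "nose")

    def test_m_dis_on_printed_matrix(self, table1_code):
        assert m_dis(table1_code, "Eye Distance", "Face 1") == 2
        assert m_dis(table1_code, "Face 1", "Face 1") == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_antisymmetry_on_random_codes(self, seed):
        gc = random_code(seed)
        terms = gc.dictionary
        for i in terms:
            for j in terms:
                assert m_dis(gc, i, j) == -m_dis(gc, j, i)


class TestTfidf:
    def test_ubiquitous_term_scores_zero_regardless_of_weight(self, shared_unique_coll):
        for gc in shared_unique_coll:
            assert gc_tfidf("s0", gc, shared_unique_coll) == 0.0

    def test_unique_term_with_weight(self, shared_unique_coll):
        gc = shared_unique_coll.codes[0]
        # u0 occurs in 1 of 6 codes with row weight 1
        assert gc_tfidf("u0", gc, shared_unique_coll) == pytest.approx(math.log(6))

    def test_weight_floor_for_isolated_terms(self):
        # term "h" in 3 of 6 codes, never with relationships: weight floors at 1
        codes = [presence_code(["h", f"x{e}"] if e < 3 else [f"x{e}"], f"a{e}") for e in range(6)]
        coll = GraphCodeCollection(codes)
        assert gc_tfidf("h", codes[0], coll) == pytest.approx(math.log(2))

    def test_row_weight_scales_tfidf(self, shared_unique_coll):
        gc = shared_unique_coll.codes[0]
        gc.set_cell("u0", "s1", CellValue.rel(4))  # weight now 2
        assert gc_tfidf("u0", gc, shared_unique_coll) == pytest.approx(2 * math.log(6))

    def test_zero_tfidf_iff_ubiquitous(self, shared_unique_coll):
        n = len(shared_unique_coll)
        for term in shared_unique_coll.terms():
            zero = collection_tfidf(term, shared_unique_coll) == 0.0
            assert zero == (shared_unique_coll.df(term) == n)


class TestMRel:
    def test_self_relevance_is_zero(self, shared_unique_coll):
        assert m_rel("s1", "s1", shared_unique_coll) == 0.0

    def test_ubiquitous_vs_unique_is_negative(self, shared_unique_coll):
        assert m_rel("s0", "u3", shared_unique_coll) < 0

    def test_consistent_with_brute_force_table(self, shared_unique_coll):
        coll = shared_unique_coll
        table = {t: collection_tfidf(t, coll) for t in coll.terms()}
        for i in coll.terms():
            for j in coll.terms():
                assert m_rel(i, j, coll) == pytest.approx(table[i] - table[j])


class TestStopCode:
    def test_shared_terms_are_exactly_the_stop_code(self):
        coll = make_collection(CollectionSpec(6, 24, 12, density=0.3, seed=7))
        report = build_stop_code(coll, 0.0)
        assert sorted(report.stop_code.dictionary) == [f"shared_{k:03d}" for k in range(24)]
        assert all(report.per_term[t].tfidf == 0.0 for t in report.stop_code.dictionary)

    def test_identical_codes_stop_the_full_dictionary(self):
        base = random_code(5)
        codes = []
        for k in range(3):
            c = base.copy()
            c.asset_id = f"a{k}"
            codes.append(c)
        report = build_stop_code(GraphCodeCollection(codes))
        assert report.stop_code.term_set == base.term_set

    def test_threshold_adds_lowest_decile(self):
        # 100 unique terms with increasing row weights -> strictly increasing tfidf
        codes = []
        n_terms = 50
        for e in range(2):
            terms = ["common"] + [f"t{e}_{k:02d}" for k in range(n_terms)]
            partners = [f"p{e}_{k:02d}" for k in range(n_terms)]
            gc = presence_code(terms + partners, f"a{e}")
            for k in range(n_terms):
                for j in range(k + 1):
                    gc.set_cell(f"t{e}_{k:02d}", partners[j], CellValue.rel(2))
            codes.append(gc)
        coll = GraphCodeCollection(codes)
        report = build_stop_code(coll, threshold_fraction=0.10)
        table = {t: r.tfidf for t, r in report.per_term.items()}
        nonzero = sorted((tfidf, t) for t, tfidf in table.items() if tfidf != 0.0)
        expected = {t for t, tfidf in table.items() if tfidf == 0.0}
        expected |= {t for _tf, t in nonzero[: int(0.10 * len(nonzero))]}
        assert report.stop_code.term_set == expected

    def test_deterministic_for_fixed_inputs(self, shared_unique_coll):
        a = build_stop_code(shared_unique_coll, 0.2)
        b = build_stop_code(shared_unique_coll, 0.2)
        assert a.stop_code.dictionary == b.stop_code.dictionary
        assert a.to_json() == b.to_json()

    def test_small_collection_and_bad_threshold_rejected(self, shared_unique_coll):
        with pytest.raises(GraphCodeError):
            build_stop_code(GraphCodeCollection(shared_unique_coll.codes[:1]))
        with pytest.raises(GraphCodeError):
            build_stop_code(shared_unique_coll, threshold_fraction=1.0)

    def test_report_table_exports(self, shared_unique_coll):
        report = build_stop_code(shared_unique_coll)
        frame = report.to_frame()
        assert set(frame.columns) == {"term", "df", "weight", "tfidf", "stopped"}
        assert frame.loc[frame.term == "s0", "stopped"].item()


class TestEditStopCode:
    def test_noop_edit_is_identity(self, shared_unique_coll):
        report = build_stop_code(shared_unique_coll)
        assert edit_stop_code(report).term_set == report.stop_code.term_set

    def test_added_term_present(self, shared_unique_coll):
        report = build_stop_code(shared_unique_coll)
        edited = edit_stop_code(report, add_terms=["software version"])
        assert "software version" in edited.term_set

    def test_add_then_remove_is_identity(self, shared_unique_coll):
        report = build_stop_code(shared_unique_coll)
        edited = edit_stop_code(report, add_terms=["software version"])
        report2 = build_stop_code(shared_unique_coll)
        report2.stop_code = edited
        back = edit_stop_code(report2, remove_terms=["software version"])
        assert back.term_set == report.stop_code.term_set

    def test_unknown_removal_logged_not_fatal(self, shared_unique_coll, caplog):
        report = build_stop_code(shared_unique_coll)
        with caplog.at_level("WARNING"):
            edit_stop_code(report, remove_terms=["ghost"])
        assert any("ghost" in r.message for r in caplog.records)


class TestFeatureRelevant:
    def test_reproduces_collection_compression(self):
        coll = make_collection(CollectionSpec(6, 24, 12, density=0.3, seed=7))
        report = build_stop_code(coll, 0.0)
        fr = feature_relevant(coll.codes[0], report.stop_code)
        assert len(fr) == 12 and fr.n_cells == 144
        assert coll.codes[0].n_cells == 1296

    def test_empty_stop_is_identity(self):
        x = random_code(2)
        assert feature_relevant(x, GraphCode(dictionary=[])).structurally_equal(x)

    def test_idempotent(self, shared_unique_coll):
        report = build_stop_code(shared_unique_coll)
        once = feature_relevant(shared_unique_coll.codes[0], report.stop_code)
        twice = feature_relevant(once, report.stop_code)
        assert twice.structurally_equal(once)
        assert not once.term_set & report.stop_code.term_set


class TestAboutness:
    def test_fully_stopped_code_scores_zero(self):
        gc = presence_code(["a", "b"], "x")
        assert m_abt(gc, presence_code(["a", "b"], "stop")) == 0.0

    def test_empty_stop_scores_one(self):
        gc = presence_code(["a", "b"], "x")
        assert m_abt(gc, GraphCode(dictionary=[])) == 1.0

    def test_surviving_fraction(self):
        terms = [f"t{k}" for k in range(36)]
        gc = presence_code(terms, "x")
        stop = presence_code(terms[:24], "stop")
        assert m_abt(gc, stop) == pytest.approx(1 / 3)

    def test_empty_code_is_an_error(self):
        with pytest.raises(GraphCodeError):
            m_abt(GraphCode(dictionary=[]), GraphCode(dictionary=[]))


class TestHistoryRelevance:
    def make_timelines(self, n=5, emerging="COVID-19"):
        tls = []
        for p in range(n):
            events = [
                ("2020-01", "blood-pressure", 120 + p),
                ("2020-06", emerging, "positive"),
                ("2020-06", f"private-{p}", p),
            ]
            tls.append(make_timeline(TimelineSpec(f"P{p}", events=tuple(events))))
        return tls

    def test_emerging_term_tops_document_frequency(self):
        report = frsgc_hist(self.make_timelines(), window=("2020-01", "2020-06"))
        dfs = {t: r.df for t, r in report.per_term.items()}
        assert dfs["COVID-19"] == max(dfs.values()) == 5

    def test_no_changes_gives_empty_baseline(self):
        tls = [
            make_timeline(TimelineSpec("P0", events=(("a", "x", 1), ("b", "x", 1))))
        ]
        report = frsgc_hist(tls, window=("a", "b"))
        assert report.per_term == {}

    def test_scripted_changes_match_hand_built_union(self):
        from gcmed import diff, patient_code_at, project_diff, union_all

        tls = self.make_timelines(n=3)
        report = frsgc_hist(tls, window=("2020-01", "2020-06"))
        projections = [
            project_diff(
                diff(patient_code_at(tl, "2020-01"), patient_code_at(tl, "2020-06"))
            )
            for tl in tls
        ]
        expected_terms = set().union(*(p.term_set for p in projections))
        assert set(report.per_term) == expected_terms

    def test_no_diffable_timeline_is_an_error(self):
        tl = make_timeline(TimelineSpec("P0", events=(("a", "x", 1),)))
        with pytest.raises(GraphCodeError):
            frsgc_hist([tl], window=("zz", "zzz"))
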