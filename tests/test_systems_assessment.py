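import pytest
from hypothesis import given
from hypothesis import strategies as st

from iccm_dqa import (
    AssessmentQuestion,
    AssessmentResponse,
    ConfigError,
    ValidationError,
    load_questionnaire,
    load_responses,
    render_radar,
    score,
    spider_chart_data,
    validate_responses,
)
from iccm_dqa.systems_assessment import DEFAULT_DIMENSIONS, SIXTH_DIMENSION

from conftest import small_config
from iccm_dqa import load_system_map


def response(q, site, value, note=""):
    if value in (1, 2) and not note:
        note = "reason"
    return AssessmentResponse(question_id=q, site_id=site, score=value, note=note)


@pytest.fixture
def questions(small_system):
    return load_questionnaire(system=small_system)


class TestQuestionnaire:
    def test_default_bank_covers_every_dimension_at_every_level(self, questions, small_system):
        for dim in DEFAULT_DIMENSIONS + [SIXTH_DIMENSION]:
            for lv in small_system.levels:
                assert any(
                    q.dimension == dim and lv.id in q.applicable_levels
                    for q in questions
                ), (dim, lv.id)

    def test_electronic_entry_questions_drop_without_the_feature(self, small_system):
        # no level declares electronic_entry in the small system
        questions = load_questionnaire(system=small_system)
        assert not any(q.requires_feature == "electronic_entry" for q in questions)

    def test_electronic_entry_questions_kept_only_where_declared(self):
        cfg = small_config()
        cfg["levels"][2]["features"] = ["electronic_entry"]  # district only
        system = load_system_map(cfg)
        questions = load_questionnaire(system=system)
        (q,) = [q for q in questions if q.requires_feature == "electronic_entry"]
        assert q.applicable_levels == frozenset({"district"})

    def test_unknown_dimension_rejected(self, small_system):
        with pytest.raises(ConfigError, match="foo"):
            load_questionnaire(
                [{"id": "q1", "dimension": "foo", "text": "?"}], system=small_system
            )


class TestScoring:
    def test_all_threes_everywhere(self, questions, small_system):
        responses = [
            response(q.id, "f1", 3) for q in questions if "facility" in q.applicable_levels
        ]
        card = score(responses, questions, small_system)
        assert all(mean == 3.0 for mean, _ in card.by_site.values())
        assert all(mean == 3.0 for mean, _ in card.overall.values())

    def test_mean_of_three_two_one_is_two(self, questions, small_system):
        qs = [q for q in questions if q.dimension == "data_management"][:3]
        responses = [response(q.id, "f1", v) for q, v in zip(qs, (3, 2, 1))]
        card = score(responses, questions, small_system)
        assert card.by_site[("data_management", "f1")] == (2.0, 3)

    def test_level_mean_pools_items(self, questions, small_system):
        # f1 scores {3,2}, f2 scores {2,1}: pooled level mean = 8/4 = 2.0
        qs = [q for q in questions if q.dimension == "me_structures"][:2]
        responses = [
            response(qs[0].id, "f1", 3), response(qs[1].id, "f1", 2),
            response(qs[0].id, "f2", 2), response(qs[1].id, "f2", 1),
        ]
        card = score(responses, questions, small_system)
        assert card.by_level[("me_structures", "facility")] == (2.0, 4)

    def test_pooled_vs_site_means_differ_with_unequal_item_counts(self, questions, small_system):
        qs = [q for q in questions if q.dimension == "me_structures"][:2]
        responses = [
            response(qs[0].id, "f1", 3), response(qs[1].id, "f1", 3),
            response(qs[0].id, "f2", 1),
        ]
        pooled = score(responses, questions, small_system)
        site_means = score(responses, questions, small_system, aggregation="site_means")
        assert pooled.by_level[("me_structures", "facility")][0] == pytest.approx(7 / 3)
        assert site_means.by_level[("me_structures", "facility")][0] == pytest.approx(2.0)

    def test_na_responses_never_change_any_mean(self, questions, small_system):
        qs = [q for q in questions if q.dimension == "data_collection_forms"][:2]
        responses = [response(qs[0].id, "f1", 3), response(qs[1].id, "f1", 2)]
        base = score(responses, questions, small_system)
        with_na = score(
            responses + [response(qs[0].id, "f2", None), response(qs[1].id, "d1", None)],
            questions,
            small_system,
        )
        assert with_na.by_site == base.by_site
        assert with_na.by_level == base.by_level
        assert with_na.overall == base.overall

    def test_low_score_without_note_rejected_listing_ids(self, questions, small_system):
        bad = AssessmentResponse(question_id=questions[0].id, site_id="f1", score=1, note="")
        with pytest.raises(ValidationError, match=questions[0].id):
            score([bad], questions, small_system)

    def test_all_means_within_scale_bounds(self, questions, small_system):
        responses = [
            response(q.id, site, 1 + (i + j) % 3)
            for i, q in enumerate(questions)
            for j, site in enumerate(["f1", "f2", "d1"])
        ]
        card = score(responses, questions, small_system)
        for cell in (*card.by_site.values(), *card.by_level.values(), *card.overall.values()):
            assert 1.0 <= cell[0] <= 3.0

    @given(st.permutations(range(6)))
    def test_scorecard_invariant_under_response_permutation(self, order):
        system = load_system_map(small_config())
        questions = load_questionnaire(system=system)
        qs = [q for q in questions if q.dimension == "me_structures"][:2]
        responses = [
            response(qs[0].id, "f1", 3), response(qs[1].id, "f1", 1),
            response(qs[0].id, "f2", 2), response(qs[1].id, "f2", 2),
            response(qs[0].id, "d1", 1), response(qs[1].id, "d1", 3),
        ]
        base = score(responses, questions, system)
        shuffled = score([responses[i] for i in order], questions, system)
        assert base.by_level == shuffled.by_level and base.overall == shuffled.overall

    def test_level_mean_is_item_weighted_mean_of_site_means(self, questions, small_system):
        qs = [q for q in questions if q.dimension == "national_links"]
        responses = [
            response(qs[0].id, "f1", 3),
            response(qs[0].id, "f2", 1),
        ] + [response(q.id, "f1", 2) for q in questions if q.dimension == "me_structures"]
        card = score(responses, questions, small_system)
        for (dim, level), (mean, n) in card.by_level.items():
            sites = [
                (m, k) for (d, s), (m, k) in card.by_site.items()
                if d == dim and small_system.site(s).level_id == level
            ]
            weighted = sum(m * k for m, k in sites) / sum(k for _, k in sites)
            assert mean == pytest.approx(weighted)


class TestSpiderChart:
    def test_overall_series_covers_dimensions_in_order(self, questions, small_system):
        responses = [
            response(q.id, "f1", 3) for q in questions if "facility" in q.applicable_levels
        ]
        card = score(responses, questions, small_system)
        series = spider_chart_data(card, grain="overall")
        assert [d for d, _ in series] == card.dimensions
        assert all(v == 3.0 for _, v in series)

    def test_dimension_without_items_yields_gap_not_zero(self, questions, small_system):
        qs = [q for q in questions if q.dimension == "me_structures"][:1]
        card = score([response(qs[0].id, "f1", 2)], questions, small_system)
        series = dict(spider_chart_data(card, grain="overall",
                                        dimensions=["me_structures", "data_use"]))
        assert series["me_structures"] == 2.0 and series["data_use"] is None

    def test_six_dimension_series(self, questions, small_system):
        responses = [
            response(q.id, "f1", 3) for q in questions if "facility" in q.applicable_levels
        ]
        card = score(responses, questions, small_system)
        series = spider_chart_data(
            card, grain="overall", dimensions=DEFAULT_DIMENSIONS + [SIXTH_DIMENSION]
        )
        assert len(series) == 6

    def test_radar_renders_to_file(self, questions, small_system, tmp_path):
        responses = [
            response(q.id, "f1", 2) for q in questions if "facility" in q.applicable_levels
        ]
        card = score(responses, questions, small_system)
        out = tmp_path / "spider.svg"
        render_radar(spider_chart_data(card), out)
        assert out.stat().st_size > 0


class TestResponseIO:
    def test_csv_round_trip_with_na(self, tmp_path):
        path = tmp_path / "responses.csv"
        path.write_text(
            "question_id,site_id,score,note\n"
            "mes1,f1,3,\n"
            "mes2,f1,2,stock register missing\n"
            "ind1,f1,NA,\n"
        )
        responses = load_responses(path)
        assert [r.score for r in responses] == [3, 2, None]
        validate_responses(responses, load_questionnaire())

    def test_out_of_scale_score_rejected(self, tmp_path):
        path = tmp_path / "responses.csv"
        path.write_text("question_id,site_id,score,note\nmes1,f1,4,\n")
        with pytest.raises(ValidationError, match="must be 1, 2, 3 or NA"):
            load_responses(path)
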