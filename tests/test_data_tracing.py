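import datetime as dt
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from iccm_dqa import (
    Period,
    SummaryReport,
    TracingError,
    availability_by_level,
    consistency_ratio,
    consistency_results,
    differences,
    load_reports,
    reporting_performance,
    timeliness,
    trace_from_counts,
    trace_indicator,
    write_reports,
)
from iccm_dqa.synthetic_data import TABLE4_COUNT_COLUMNS, table4_fixture

PERIOD = Period("2016-01", "2016-03")


def report(site, level, month, counts, about=None, submitted=None):
    return SummaryReport(
        site_id=site,
        level_id=level,
        period_month=month,
        counts=counts,
        about_site_id=about,
        submission_date=submitted,
    )


class TestDifferences:
    def test_published_malaria_example_reproduced(self):
        counts, printed = table4_fixture()
        trace = trace_from_counts(
            counts,
            TABLE4_COUNT_COLUMNS,
            group_column="district",
            facility_column="facility",
        )
        for row, (_, want) in zip(trace.rows, printed.iterrows()):
            assert list(row.stepwise) == [
                want["diff_chw_summary_minus_register"],
                want["diff_supervisor_summary_minus_chw_summary"],
                want["diff_national_his_minus_supervisor_summary"],
            ]
            assert row.end_to_end == want["diff_national_his_minus_register"]

    def test_identical_counts_give_zero_differences(self):
        step, end = differences([42, 42, 42, 42])
        assert step == [0, 0, 0] and end == 0

    def test_missing_count_propagates_as_missing(self):
        step, end = differences([10, None, 12, 15])
        assert step == [None, None, 3] and end == 5
        step, end = differences([None, 5, 5, 5])
        assert end is None

    @given(st.lists(st.one_of(st.none(), st.integers(0, 10_000)), min_size=2, max_size=6))
    def test_telescoping_identity(self, counts):
        step, end = differences(counts)
        if all(c is not None for c in counts):
            assert end == sum(step)


class TestConsistencyRatio:
    @pytest.mark.parametrize(
        "verified,reported,ratio,label",
        [
            (100, 100, 1.0, "agreement"),
            (110, 100, 1.1, "under-reporting"),
            (80, 100, 0.8, "over-reporting"),
        ],
    )
    def test_direction_rule(self, verified, reported, ratio, label):
        got_ratio, got_label = consistency_ratio(verified, reported)
        assert got_ratio == pytest.approx(ratio) and got_label == label

    def test_missing_and_zero_denominator_sentinels(self):
        assert consistency_ratio(None, 100) == (None, "undefined")
        assert consistency_ratio(0, 0) == (None, "undefined")
        ratio, label = consistency_ratio(5, 0)
        assert math.isinf(ratio) and label == "under-reporting"

    @given(st.integers(1, 10**6))
    def test_equal_counts_always_agree(self, x):
        assert consistency_ratio(x, x) == (1.0, "agreement")

    def test_aggregate_is_ratio_of_sums(self):
        counts, _ = table4_fixture()
        trace = trace_from_counts(counts, TABLE4_COUNT_COLUMNS, facility_column="facility")
        results = consistency_results(trace)
        agg = next(
            r for r in results
            if r.scope_id == "__all__" and r.lower == "register" and r.higher == "chw_summary"
        )
        assert agg.verified_or_summed == counts["register"].sum()
        assert agg.reported == counts["chw_summary"].sum()
        assert agg.ratio == pytest.approx(counts["register"].sum() / counts["chw_summary"].sum())


class TestTraceIndicator:
    def _reports(self, system, per_chw=4):
        """Fully consistent reports for the small 4-level system."""
        out = []
        months = PERIOD.months()
        for fid, chws in {"f1": ["c1", "c2", "c3"], "f2": ["c4", "c5"]}.items():
            for m in months:
                for c in chws:
                    out.append(report(c, "community", m, {"malaria_treated": per_chw}))
                total = per_chw * len(chws)
                out.append(report(fid, "facility", m, {"malaria_treated": total}))
                out.append(report("d1", "district", m, {"malaria_treated": total}, about=fid))
                out.append(report("national", "national", m, {"malaria_treated": total}, about=fid))
        return out

    def _entries(self, per_chw=4):
        from test_register_verification import entry

        out = []
        for c in ["c1", "c2", "c3", "c4", "c5"]:
            for month in (1, 2, 3):
                for _ in range(per_chw):
                    out.append(
                        entry(treatments={"act"}, symptoms={"fever"},
                              diagnostics={"rdt": "positive"}, chw=c,
                              date=dt.date(2016, month, 10))
                    )
        return out

    def test_consistent_system_traces_to_zero_differences(self, small_system):
        from iccm_dqa import default_rules

        trace = trace_indicator(
            small_system, self._entries(), self._reports(small_system),
            "malaria_treated", PERIOD, "national", rules=default_rules(),
        )
        assert [r.facility_id for r in trace.rows] == ["f1", "f2"]
        f1 = trace.rows[0]
        assert f1.counts == (36, 36, 36, 36, 36)  # 3 CHWs x 3 months x 4
        assert all(d == 0 for d in f1.stepwise) and f1.end_to_end == 0
        for res in consistency_results(trace):
            assert res.ratio == 1.0 and res.label == "agreement"

    def test_blank_cell_flags_row_and_leaves_aggregate(self, small_system):
        from iccm_dqa import default_rules

        reports = self._reports(small_system)
        # blank one CHW monthly count: the community cell for f1 goes missing
        idx = next(
            i for i, r in enumerate(reports)
            if r.site_id == "c1" and r.period_month == "2016-02"
        )
        reports[idx] = report("c1", "community", "2016-02", {"malaria_treated": None})
        trace = trace_indicator(
            small_system, self._entries(), reports,
            "malaria_treated", PERIOD, "national", rules=default_rules(),
        )
        f1 = trace.rows[0]
        assert f1.has_missing and f1.counts[1] is None
        assert f1.stepwise[0] is None
        agg = [
            r for r in consistency_results(trace)
            if r.scope_id == "__all__" and r.lower == "register"
        ]
        # aggregate over the register->community pair excludes the broken row
        assert agg[0].verified_or_summed == trace.rows[1].counts[0]

    def test_absent_indicator_field_names_the_level(self, small_system):
        from iccm_dqa import default_rules

        reports = self._reports(small_system)
        idx = next(i for i, r in enumerate(reports) if r.level_id == "district")
        bad = reports[idx]
        reports[idx] = report(bad.site_id, "district", bad.period_month, {}, about=bad.about)
        with pytest.raises(TracingError, match="district"):
            trace_indicator(
                small_system, self._entries(), reports,
                "malaria_treated", PERIOD, "national", rules=default_rules(),
            )

    def test_reports_round_trip(self, small_system, tmp_path):
        reports = self._reports(small_system)
        path = tmp_path / "reports.csv"
        write_reports(reports, path)
        assert load_reports(path) == reports


class TestReportingPerformance:
    def _reports(self):
        """12 of 15 expected CHW reports found, 9 of them complete."""
        out = []
        missing = {("c1", "2016-01"), ("c2", "2016-02"), ("c3", "2016-03")}
        incomplete = {("c4", "2016-01"), ("c4", "2016-02"), ("c5", "2016-03")}
        for c in ["c1", "c2", "c3", "c4", "c5"]:
            for m in PERIOD.months():
                if (c, m) in missing:
                    continue
                value = None if (c, m) in incomplete else 7
                out.append(report(c, "community", m, {"malaria_treated": value}))
        return out

    def test_hand_counted_availability_and_completeness(self, small_system):
        results = reporting_performance(small_system, self._reports(), PERIOD)
        level = availability_by_level(results)["community"]
        assert (level.expected, level.available, level.complete) == (15, 12, 9)
        assert level.pct_available == pytest.approx(80.0)
        assert level.pct_complete == pytest.approx(60.0)  # denominator = expected

    def test_available_denominator_flag(self, small_system):
        results = reporting_performance(
            small_system, self._reports(), PERIOD,
            completeness_denominator="available",
        )
        level = availability_by_level(results, completeness_denominator="available")["community"]
        assert level.pct_complete == pytest.approx(100.0 * 9 / 12)

    def test_zero_expected_guarded_with_sentinel(self, small_system):
        results = reporting_performance(small_system, [], Period("2016-01", "2016-01"))
        inactive = [r for r in results if r.expected == 0]
        assert all(r.pct_available is None for r in inactive)

    def test_full_reporting_scores_100(self, small_system):
        full = [
            report(c, "community", m, {"malaria_treated": 3})
            for c in ["c1", "c2", "c3", "c4", "c5"]
            for m in PERIOD.months()
        ]
        level = availability_by_level(reporting_performance(small_system, full, PERIOD))["community"]
        assert level.pct_available == 100.0 and level.pct_complete == 100.0

    def test_invariant_under_report_reordering(self, small_system):
        reports = self._reports()
        a = reporting_performance(small_system, reports, PERIOD)
        b = reporting_performance(small_system, list(reversed(reports)), PERIOD)
        assert a == b


class TestTimeliness:
    def test_missing_dates_make_level_not_assessable(self):
        reports = [report("c1", "community", "2016-01", {"x": 1}) for _ in range(4)]
        result = timeliness(reports, deadline_day=5)["community"]
        assert not result.assessable and result.pct_on_time is None

    def test_three_of_four_on_time(self):
        dates = [dt.date(2016, 2, 3), dt.date(2016, 2, 5), dt.date(2016, 2, 4), dt.date(2016, 2, 9)]
        reports = [
            report("c1", "community", "2016-01", {"x": 1}, submitted=d) for d in dates
        ]
        result = timeliness(reports, deadline_day=5)["community"]
        assert result.assessable and result.pct_on_time == pytest.approx(75.0)

    def test_deadline_bound_is_closed(self):
        reports = [
            report("c1", "community", "2016-01", {"x": 1}, submitted=dt.date(2016, 2, 5))
        ]
        assert timeliness(reports, deadline_day=5)["community"].pct_on_time == 100.0
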