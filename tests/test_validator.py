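"""Compliance-auditor soundness, fault sensitivity and reporting."""

import json

import pytest

from brapiref import (
    Connection,
    FixtureConfig,
    ReferenceServer,
    ServerConfig,
    WSGITransport,
    generate_fixture,
    render_report,
    run_suite,
)
from brapiref.client import RecordingTransport
from brapiref.errors import InvalidParameterError
from brapiref.validator import Report, TestCase, build_catalog, detect_endpoints, run_test


def connection_for(app, **kwargs):
    return Connection("http://testserver", transport=WSGITransport(app), **kwargs)


class TestSoundness:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_reference_server_is_fully_compliant(self, seed):
        app = ReferenceServer(generate_fixture(FixtureConfig(seed=seed)))
        report = run_suite(connection_for(app))
        fails = [r for r in report.results if r.outcome == "fail"]
        assert fails == [], render_report(report)
        assert report.counts()["skip"] == 0
        assert report.compliant

    def test_every_catalog_case_lists_at_least_one_check(self):
        for case in build_catalog():
            assert case.checks


FAULT_TO_CHECK = {
    "omit-total-pages": "body_validity",
    "pagination-off-by-one": "body_validity",
    "detail-id-mismatch": "reference_match",
    "wrong-media-type": "content_type",
    "details-extra-key": "body_validity",
}


class TestSensitivity:
    @pytest.mark.parametrize("fault", sorted(FAULT_TO_CHECK))
    def test_each_injected_fault_is_detected_by_its_named_check(self, fault):
        app = ReferenceServer(config=ServerConfig(faults=frozenset({fault})))
        report = run_suite(connection_for(app))
        assert not report.compliant
        failed_checks = {
            check
            for result in report.results
            for check, outcome in result.check_outcomes.items()
            if outcome == "fail"
        }
        assert FAULT_TO_CHECK[fault] in failed_checks


class TestDiscoveryAndSkips:
    def test_reference_server_schedules_everything(self, app, conn):
        descriptors = detect_endpoints(conn)
        assert {(d["call"], d["methods"][0]) for d in descriptors} == {
            (r.path, r.method) for r in app.routes
        }

    def test_unadvertised_calls_are_skipped_and_never_requested(self, store):
        class PartialServer(ReferenceServer):
            def call_descriptors(self):
                return [d for d in super().call_descriptors()
                        if d["call"] in ("calls", "crops")]

        app = PartialServer(store)
        recording = RecordingTransport(WSGITransport(app))
        report = run_suite(Connection("http://testserver", transport=recording))
        outcomes = {r.test_id: r.outcome for r in report.results}
        assert outcomes["calls-list"] == "pass"
        assert outcomes["crops-list"] == "pass"
        skipped = [t for t, o in outcomes.items() if o == "skip"]
        assert len(skipped) == len(outcomes) - 2
        requested = {r["url"].split("/brapi/v1/")[1].split("?")[0] for r in recording.requests}
        assert requested <= {"calls", "crops"}

    def test_unreachable_host_yields_untestable_report(self):
        report = run_suite(Connection("http://127.0.0.1:1", timeout=0.5))
        assert report.untestable and not report.compliant
        assert "calls" in report.reason

    def test_non_envelope_calls_endpoint_is_untestable(self):
        def junk_app(environ, start_response):
            start_response("200 OK", [("Content-Type", "application/json")])
            return [b'{"hello": "world"}']

        report = run_suite(Connection("http://t", transport=WSGITransport(junk_app)))
        assert report.untestable

    def test_missing_harvest_cascades_to_skip_not_fail(self, conn):
        catalog = [
            TestCase(id="needs-ghost", category="Germplasm",
                     call="germplasm/{ghost}", advertised="germplasm/{germplasmDbId}",
                     requires=("ghost",), source="nobody"),
        ]
        report = run_suite(conn, catalog=catalog)
        assert report.results[0].outcome == "skip"
        assert "ghost" in report.results[0].message


class TestRunTest:
    def test_identity_check_passes_only_for_the_true_identifier(self, conn):
        case = TestCase(
            id="id-check", category="Germplasm", call="germplasm/1",
            advertised="germplasm/{germplasmDbId}",
            reference={"result.germplasmDbId": "1"},
        )
        assert run_test(conn, case, {}).outcome == "pass"
        wrong = TestCase(
            id="id-check-wrong", category="Germplasm", call="germplasm/2",
            advertised="germplasm/{germplasmDbId}",
            reference={"result.germplasmDbId": "1"},
        )
        result = run_test(conn, wrong, {})
        assert result.outcome == "fail"
        assert result.check_outcomes["reference_match"] == "fail"

    def test_harvested_value_feeds_the_next_case(self, conn):
        context = {}
        harvesting = TestCase(
            id="h", category="Germplasm", call="germplasm-search",
            advertised="germplasm-search",
            harvest={"germplasm_id": "result.data.0.germplasmDbId"},
        )
        assert run_test(conn, harvesting, context).outcome == "pass"
        assert context["germplasm_id"] == "1"
        chained = TestCase(
            id="c", category="Germplasm", call="germplasm/{germplasm_id}",
            advertised="germplasm/{germplasmDbId}", requires=("germplasm_id",),
            reference={"result.germplasmDbId": "{germplasm_id}"},
        )
        assert run_test(conn, chained, context).outcome == "pass"


class TestReporting:
    def test_aggregates_sum_to_executed_tests(self, conn):
        report = run_suite(conn)
        totals = report.counts()
        assert totals["pass"] + totals["fail"] + totals["skip"] == len(report.results)
        for resource, counts in report.aggregates().items():
            assert sum(counts.values()) == len(report.by_resource()[resource])

    def test_tree_render_shows_per_resource_aggregates(self):
        report = Report(base_url="http://x", timestamp="t")
        from brapiref.validator import TestResult

        report.results = [
            TestResult("a", "Germplasm", "pass"),
            TestResult("b", "Germplasm", "pass"),
        ]
        text = render_report(report, "tree")
        assert "Germplasm: 2/2 passed" in text
        assert "COMPLIANT" in text

    def test_failing_check_renders_observed_vs_expected(self, store):
        app = ReferenceServer(store, ServerConfig(faults=frozenset({"detail-id-mismatch"})))
        report = run_suite(connection_for(app))
        text = render_report(report, "tree")
        assert "x reference_match" in text
        assert "expected" in text and "observed" in text

    def test_json_render_round_trips(self, conn):
        report = run_suite(conn)
        rendered = render_report(report, "json")
        recovered = Report.from_json(json.loads(rendered))
        assert recovered.counts() == report.counts()
        assert recovered.aggregates() == report.aggregates()
        assert recovered.compliant == report.compliant

    def test_unknown_format_is_rejected(self, conn):
        with pytest.raises(InvalidParameterError):
            render_report(Report(base_url="x", timestamp="t"), "pdf")
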