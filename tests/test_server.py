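"""HTTP-level behavior of the reference server."""

import json
from collections import Counter

import pytest

from brapiref import (
    Connection,
    ReferenceServer,
    ServerConfig,
    WSGITransport,
    check_auth,
    fetch_page,
    iterate_all,
    validate_envelope,
)
from brapiref.errors import StatusError
from brapiref.server import TABLE1_CATEGORY_COUNTS, Request

from conftest import sample_requests


def get_json(app, path, query="", method="GET", body=None):
    transport = WSGITransport(app)
    url = f"http://testserver{path}" + (f"?{query}" if query else "")
    payload = json.dumps(body).encode() if body is not None else None
    response = transport.request(method, url, {}, payload, 10)
    return response.status, response.content_type, json.loads(response.body)


class TestRouting:
    def test_locations_listing_is_a_details_envelope(self, app):
        status, ctype, doc = get_json(app, "/brapi/v1/locations")
        assert status == 200 and ctype == "application/json"
        assert set(doc["result"]) == {"data"}
        assert doc["metadata"]["pagination"]["currentPage"] == 0
        assert len(doc["result"]["data"]) == doc["metadata"]["pagination"]["totalCount"]

    def test_trials_filtered_by_program(self, app):
        program_id = app.store.all("program")[0]["programDbId"]
        _, _, doc = get_json(app, "/brapi/v1/trials", f"programDbId={program_id}")
        expected = [t for t in app.store.all("trial") if t["programDbId"] == program_id]
        assert doc["result"]["data"] == expected

    def test_trials_filtered_by_unknown_program_is_empty_200(self, app):
        status, _, doc = get_json(app, "/brapi/v1/trials", "programDbId=nope")
        assert status == 200 and doc["result"]["data"] == []

    def test_germplasm_one_identity(self, app):
        status, _, doc = get_json(app, "/brapi/v1/germplasm/1")
        assert status == 200
        assert doc["result"]["germplasmDbId"] == "1"
        assert doc["metadata"]["pagination"] == {
            "pageSize": 0, "currentPage": 0, "totalCount": 0, "totalPages": 0,
        }

    def test_absent_id_is_404_with_status_entry_and_null_result(self, app):
        status, _, doc = get_json(app, "/brapi/v1/germplasm/999999")
        assert status == 404
        assert doc["result"] is None
        assert len(doc["metadata"]["status"]) == 1
        assert doc["metadata"]["status"][0]["code"] == "404"
        assert validate_envelope(doc) == []

    def test_unknown_path_is_404(self, app):
        status, _, doc = get_json(app, "/brapi/v1/teleporters")
        assert status == 404 and doc["result"] is None

    def test_path_outside_brapi_prefix_is_404(self, app):
        status, _, _ = get_json(app, "/v1/germplasm")
        assert status == 404

    def test_unknown_filter_field_is_400(self, app):
        status, _, doc = get_json(app, "/brapi/v1/germplasm", "warpFactor=9")
        assert status == 400 and doc["metadata"]["status"][0]["code"] == "400"

    @pytest.mark.parametrize("query", ["pageSize=0", "pageSize=-2", "page=-1", "page=abc"])
    def test_bad_paging_parameters_are_400(self, app, query):
        status, _, _ = get_json(app, "/brapi/v1/germplasm", query)
        assert status == 400

    def test_out_of_range_page_is_200_empty_with_truthful_totals(self, app):
        status, _, doc = get_json(app, "/brapi/v1/germplasm", "page=99&pageSize=10")
        assert status == 200
        assert doc["result"]["data"] == []
        pagination = doc["metadata"]["pagination"]
        assert pagination["currentPage"] == 99
        assert pagination["totalCount"] == app.store.count("germplasm")
        assert doc["metadata"]["status"]  # informational entry

    def test_base_path_is_honored(self, store):
        app = ReferenceServer(store, ServerConfig(base_path="maize-db-01"))
        status, _, _ = get_json(app, "/maize-db-01/brapi/v1/locations")
        assert status == 200
        status, _, _ = get_json(app, "/brapi/v1/locations")
        assert status == 404

    def test_wrong_method_is_405(self, app):
        status, _, _ = get_json(app, "/brapi/v1/locations", method="POST", body={})
        assert status == 405


class TestAuth:
    def test_check_auth_modes(self):
        open_config = ServerConfig()
        token_config = ServerConfig(auth_mode="token", tokens=("secret1",))
        assert check_auth({}, open_config) == "authorized"
        assert check_auth({"authorization": "Bearer secret1"}, token_config) == "authorized"
        assert check_auth({}, token_config) == "unauthorized"
        assert check_auth({"authorization": "Bearer wrong"}, token_config) == "unauthorized"

    def test_token_mode_rejects_and_accepts_over_http(self, store):
        app = ReferenceServer(store, ServerConfig(auth_mode="token", tokens=("secret1",)))
        status, _, doc = get_json(app, "/brapi/v1/germplasm")
        assert status == 401 and doc["result"] is None
        connection = Connection("http://testserver", token="secret1",
                                transport=WSGITransport(app))
        doc = fetch_page(connection, "germplasm")
        assert doc["result"]["data"]


class TestRoster:
    def test_category_counts_match_the_standard(self, app):
        counts = Counter(route.category for route in app.routes)
        assert dict(counts) == TABLE1_CATEGORY_COUNTS

    def test_calls_is_self_describing(self, conn):
        doc = fetch_page(conn, "calls", page_size=1000)
        descriptors = doc["result"]["data"]
        assert any(d["call"] == "calls" for d in descriptors)
        assert all(d["versions"] for d in descriptors)
        assert all(d["methods"] for d in descriptors)

    def test_calls_category_counts_equal_printed_counts(self, conn):
        descriptors = list(iterate_all(conn, "calls"))
        counts = Counter(d["category"] for d in descriptors)
        assert dict(counts) == TABLE1_CATEGORY_COUNTS

    def test_calls_datatype_filter(self, app, conn):
        doc = fetch_page(conn, "calls", {"dataType": "text/csv"}, page_size=1000)
        calls = [d["call"] for d in doc["result"]["data"]]
        assert calls == ["phenotypes-search/csv"]
        status, _, _ = get_json(app, "/brapi/v1/calls", "dataType=application/xml")
        assert status == 400


class TestEveryRoute:
    def test_every_route_serves_a_valid_envelope(self, app):
        """Fuzz the full roster: each call, exercised with identifiers from
        the fixture store, must answer 200 with a contract-valid envelope."""
        for route, path, body in sample_requests(app):
            status, ctype, doc = get_json(
                app, f"/brapi/v1/{path}", method=route.method, body=body
            )
            assert status == 200, f"{route.method} {path} -> {status}: {doc}"
            assert ctype == "application/json"
            assert validate_envelope(doc) == [], f"{route.method} {path}"


class TestPageConcatenation:
    @pytest.mark.parametrize("call", ["germplasm", "markers-search", "locations", "calls"])
    @pytest.mark.parametrize("page_size", [1, 3, 7, 1000])
    def test_walking_all_pages_equals_the_unpaginated_result(self, conn, call, page_size):
        full = fetch_page(conn, call, page_size=100000)["result"]["data"]
        walked = list(iterate_all(conn, call, page_size=page_size))
        assert walked == full


class TestDatafiles:
    def test_small_tables_stay_inline(self, app):
        request = Request(method="GET", path="/")
        rows = [[i, i * 2] for i in range(10)]
        inline, datafiles = app.emit_datafile(request, "t", ["a", "b"], rows, threshold=1000)
        assert inline == rows and datafiles == []

    def test_large_tables_are_exported_and_fetchable(self, app):
        request = Request(method="GET", path="/")
        rows = [[i, i * 2] for i in range(2000)]
        inline, datafiles = app.emit_datafile(request, "t", ["a", "b"], rows, threshold=1000)
        assert inline is None and len(datafiles) == 1
        name = datafiles[0].rsplit("/", 1)[1]
        status, ctype, body = app._serve_datafile(name)
        assert status == 200 and ctype == "text/tab-separated-values"
        lines = body.decode().splitlines()
        assert len(lines) == 2001 and lines[0] == "a\tb"

    def test_threshold_zero_always_exports(self, app):
        request = Request(method="GET", path="/")
        inline, datafiles = app.emit_datafile(request, "t", ["a"], [[1]], threshold=0)
        assert inline is None and len(datafiles) == 1

    def test_phenotype_tsv_export_round_trip(self, app, conn):
        doc = fetch_page(conn, "phenotypes-search/tsv", method="POST", body={})
        assert len(doc["metadata"]["datafiles"]) == 1
        name = doc["metadata"]["datafiles"][0].rsplit("/", 1)[1]
        status, ctype, body = app._serve_datafile(name)
        assert status == 200
        lines = body.decode().splitlines()
        # one header line plus one row per observation unit
        assert len(lines) == 1 + app.store.count("observation_unit")


class TestWrites:
    def test_observations_post_creates_records(self, app, conn):
        unit = app.store.all("observation_unit")[0]
        variable = app.store.all("observation_variable")[0]
        before = app.store.count("observation")
        doc = fetch_page(
            conn, f"studies/{unit['studyDbId']}/observationunits", method="POST",
            body={"observations": [{"observationUnitDbId": unit["observationUnitDbId"],
                                    "observationVariableDbId": variable["observationVariableDbId"],
                                    "value": "3.14"}]},
        )
        assert app.store.count("observation") == before + 1
        assert doc["result"]["data"][0]["value"] == "3.14"

    def test_observation_put_updates_in_place(self, app, conn):
        observation = app.store.all("observation")[0]
        unit = app.store.get("observation_unit", observation["observationUnitDbId"])
        fetch_page(
            conn, f"studies/{unit['studyDbId']}/observations", method="PUT",
            body={"observations": [{"observationDbId": observation["observationDbId"],
                                    "observationUnitDbId": observation["observationUnitDbId"],
                                    "observationVariableDbId": observation["observationVariableDbId"],
                                    "value": "42.0"}]},
        )
        assert observation["value"] == "42.0"

    def test_write_against_foreign_unit_is_400(self, app, conn):
        study = app.store.all("study")[0]
        foreign_unit = next(
            u for u in app.store.all("observation_unit")
            if u["studyDbId"] != study["studyDbId"]
        )
        with pytest.raises(StatusError) as err:
            fetch_page(
                conn, f"studies/{study['studyDbId']}/observationunits", method="POST",
                body={"observations": [{"observationUnitDbId": foreign_unit["observationUnitDbId"],
                                        "observationVariableDbId": "1", "value": "1"}]},
            )
        assert err.value.http_status == 400

    def test_vendor_order_lifecycle_starts_registered(self, app, conn):
        sample = app.store.all("sample")[0]
        doc = fetch_page(conn, "vendor/plates", method="POST",
                         body={"clientId": "c9",
                               "plates": [{"plateName": "P9",
                                           "sampleDbIds": [sample["sampleDbId"]]}]})
        order_id = doc["result"]["orderDbId"]
        status_doc = fetch_page(conn, f"vendor/orders/{order_id}/status")
        assert status_doc["result"]["status"] == "registered"
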