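"""Shared fixtures: a fresh fixture store and an in-process server per test.

Write calls mutate the in-memory store, so server-backed fixtures are
function-scoped; generation is fast enough that this costs little.
"""

from __future__ import annotations

import pytest

from brapiref import Connection, FixtureConfig, ReferenceServer, WSGITransport, generate_fixture


@pytest.fixture
def store():
    return generate_fixture(FixtureConfig())


@pytest.fixture
def app(store):
    return ReferenceServer(store)


@pytest.fixture
def conn(app):
    return Connection("http://testserver", transport=WSGITransport(app))


def sample_requests(app):
    """One concrete request per route of *app*, path params filled with
    identifiers that exist in its store (used to exercise every call)."""
    store = app.store
    first = lambda kind, field: (store.all(kind)[0][field] if store.all(kind) else "1")
    params = {
        "germplasmDbId": "1",
        "markerDbId": first("marker", "markerDbId"),
        "markerProfileDbId": first("marker_profile", "markerProfileDbId"),
        "trialDbId": first("trial", "trialDbId"),
        "studyDbId": first("study", "studyDbId"),
        "traitDbId": first("trait", "traitDbId"),
        "observationVariableDbId": first("observation_variable", "observationVariableDbId"),
        "mapDbId": first("genome_map", "mapDbId"),
        "locationDbId": first("location", "locationDbId"),
        "sampleDbId": first("sample", "sampleDbId"),
        "plateDbId": first("vendor_plate", "plateDbId"),
        "orderDbId": first("vendor_order", "orderDbId"),
        "linkageGroupId": (store.all("map_position")[0]["linkageGroupName"]
                           if store.all("map_position") else "LG1"),
    }
    unit = store.all("observation_unit")[0]
    variable = store.all("observation_variable")[0]
    bodies = {
        ("studies/{studyDbId}/observationunits", "POST"): {
            "observations": [{"observationUnitDbId": unit["observationUnitDbId"],
                              "observationVariableDbId": variable["observationVariableDbId"],
                              "value": "5.0"}]},
        ("studies/{studyDbId}/observationunits", "PUT"): {
            "observations": [{"observationUnitDbId": unit["observationUnitDbId"],
                              "observationVariableDbId": variable["observationVariableDbId"],
                              "value": "6.0"}]},
        ("studies/{studyDbId}/observations", "PUT"): {
            "observations": [{"observationUnitDbId": unit["observationUnitDbId"],
                              "observationVariableDbId": variable["observationVariableDbId"],
                              "value": "6.5"}]},
        ("studies/{studyDbId}/layout", "PUT"): {
            "layout": [{"observationUnitDbId": unit["observationUnitDbId"],
                        "positionCoordinateX": "5"}]},
        ("samples", "PUT"): {
            "observationUnitDbId": unit["observationUnitDbId"],
            "plateName": "PLATE-T", "well": "A1"},
        ("vendor/plates", "POST"): {
            "clientId": "tests",
            "plates": [{"plateName": "VP-T",
                        "sampleDbIds": [params["sampleDbId"]]}]},
    }
    out = []
    for route in app.routes:
        # requests that exercise the first unit of the matched study must use
        # that study; pin studyDbId to the unit's own study for write routes
        fill = dict(params)
        if (route.path, route.method) in bodies:
            fill["studyDbId"] = unit["studyDbId"]
        path = route.path
        for name, value in fill.items():
            path = path.replace("{" + name + "}", value)
        out.append((route, path, bodies.get((route.path, route.method))))
    return out
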