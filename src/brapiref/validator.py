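"""Compliance auditor for BrAPI v1 endpoints.

The validator discovers a server's capabilities through the ``/calls``
meta-endpoint and only tests the calls the server advertises.  Each test
issues one HTTP request and evaluates an independent set of checks:

status_code
    the HTTP status equals the expected one (200 for every bundled case);
content_type
    the response is served as JSON;
body_validity
    the body is a valid response envelope of the expected pattern,
    including pagination arithmetic;
schema_match
    entity records conform to the shipped per-entity JSON schema;
data_types
    identifier fields are text and ``data`` is an array;
reference_match
    response values agree with the request — a detail call echoes the
    requested identifier (the record fetched as ``germplasm/1`` must carry
    ``germplasmDbId`` "1"), the first page reports ``currentPage`` 0, a
    filtered listing only returns matching records.

Chained cases harvest identifiers from earlier responses (the first
``germplasmDbId`` of a search seeds the detail call); when a harvest
source fails or is skipped, dependent cases skip rather than fail, so one
broken call does not avalanche through the report.  Results are grouped
and aggregated per REST resource; a server is compliant when no executed
test fails.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from typing import Any, Mapping, Optional

from .client import Connection, RawResponse, request_raw
from .core_model import (
    PATTERN_DETAILS,
    PATTERN_MASTER,
    PATTERN_MASTER_DETAILS,
    ENTITY_KINDS,
    classify_result_pattern,
    validate_envelope,
)
from .errors import BrapiError, InvalidParameterError, MalformedResultError
from .schema import check as schema_check
from .schema import load_schema

__all__ = [
    "TestCase",
    "TestResult",
    "Report",
    "build_catalog",
    "detect_endpoints",
    "run_test",
    "run_suite",
    "render_report",
]

ALL_CHECKS = (
    "status_code",
    "content_type",
    "body_validity",
    "data_types",
    "schema_match",
    "reference_match",
)

#: sentinel expected value: the referenced location must exist and be non-null
ANY = "__any__"


@dataclass
class TestCase:
    """One scripted request plus the checks to run on its response."""

    __test__ = False  # not a pytest item despite the name

    id: str
    category: str
    call: str  # path template; "{key}" placeholders resolve from context
    advertised: str  # roster path this case exercises (matched against /calls)
    method: str = "GET"
    params: dict = field(default_factory=dict)
    body: Optional[dict] = None
    checks: tuple = ("status_code", "content_type", "body_validity", "data_types")
    expected_status: int = 200
    expected_pattern: Optional[str] = None
    expected_entity: Optional[str] = None
    #: response path -> expected value ("{key}" templates allowed, ANY sentinel)
    reference: dict = field(default_factory=dict)
    #: context key -> response path to harvest for downstream cases
    harvest: dict = field(default_factory=dict)
    #: context keys that must be present before this case can run
    requires: tuple = ()
    #: id of the case expected to produce the required context (reporting only)
    source: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.checks:
            raise InvalidParameterError(f"test case {self.id} lists no checks")
        if self.expected_entity is not None:
            self.checks = tuple(dict.fromkeys(self.checks + ("schema_match",)))
        if self.reference:
            self.checks = tuple(dict.fromkeys(self.checks + ("reference_match",)))


@dataclass
class TestResult:
    __test__ = False  # not a pytest item despite the name

    test_id: str
    category: str
    outcome: str  # pass | fail | skip
    check_outcomes: dict = field(default_factory=dict)  # check -> pass | fail
    observed: dict = field(default_factory=dict)
    message: str = ""

    def to_json(self) -> dict:
        return {
            "test_id": self.test_id,
            "category": self.category,
            "outcome": self.outcome,
            "check_outcomes": dict(self.check_outcomes),
            "observed": dict(self.observed),
            "message": self.message,
        }

    @classmethod
    def from_json(cls, doc: Mapping) -> "TestResult":
        return cls(
            doc["test_id"],
            doc["category"],
            doc["outcome"],
            dict(doc.get("check_outcomes", {})),
            dict(doc.get("observed", {})),
            doc.get("message", ""),
        )


@dataclass
class Report:
    """Per-resource tree of test results with aggregates."""

    base_url: str
    timestamp: str
    results: list = field(default_factory=list)
    untestable: bool = False
    reason: str = ""

    def by_resource(self) -> dict[str, list[TestResult]]:
        tree: dict[str, list[TestResult]] = {}
        for result in self.results:
            tree.setdefault(result.category, []).append(result)
        return tree

    def aggregates(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for resource, results in self.by_resource().items():
            counts = {"pass": 0, "fail": 0, "skip": 0}
            for result in results:
                counts[result.outcome] += 1
            out[resource] = counts
        return out

    def counts(self) -> dict[str, int]:
        total = {"pass": 0, "fail": 0, "skip": 0}
        for counts in self.aggregates().values():
            for key in total:
                total[key] += counts[key]
        return total

    @property
    def compliant(self) -> bool:
        return not self.untestable and self.counts()["fail"] == 0

    def to_json(self) -> dict:
        return {
            "base_url": self.base_url,
            "timestamp": self.timestamp,
            "untestable": self.untestable,
            "reason": self.reason,
            "compliant": self.compliant,
            "counts": self.counts(),
            "resources": {
                resource: {
                    **self.aggregates()[resource],
                    "tests": [r.to_json() for r in results],
                }
                for resource, results in self.by_resource().items()
            },
        }

    @classmethod
    def from_json(cls, doc: Mapping) -> "Report":
        results = []
        for resource in doc.get("resources", {}).values():
            for entry in resource.get("tests", []):
                results.append(TestResult.from_json(entry))
        return cls(
            base_url=doc["base_url"],
            timestamp=doc["timestamp"],
            results=results,
            untestable=doc.get("untestable", False),
            reason=doc.get("reason", ""),
        )


# ---------------------------------------------------------------------------
# response navigation


def _dig(document: Any, path: str):
    """Resolve a dotted path; integer segments index arrays, ``*`` fans out.

    Returns ``(found, value)``; with ``*`` the value is the list of matches
    (found is False when any intermediate step is missing).
    """
    current = document
    segments = path.split(".")
    for i, segment in enumerate(segments):
        if segment == "*":
            if not isinstance(current, list):
                return False, None
            rest = ".".join(segments[i + 1:])
            values = []
            for element in current:
                if rest:
                    found, value = _dig(element, rest)
                    if not found:
                        return False, None
                    values.append(value)
                else:
                    values.append(element)
            return True, values
        if isinstance(current, list):
            try:
                index = int(segment)
            except ValueError:
                return False, None
            if not 0 <= index < len(current):
                return False, None
            current = current[index]
        elif isinstance(current, dict):
            if segment not in current:
                return False, None
            current = current[segment]
        else:
            return False, None
    return True, current


def _resolve(value: Any, context: Mapping[str, Any]) -> Any:
    if isinstance(value, str):
        return value.format_map(context)
    if isinstance(value, dict):
        return {k: _resolve(v, context) for k, v in value.items()}
    if isinstance(value, list):
        return [_resolve(v, context) for v in value]
    return value


def _entity_violations(document: Any, kind: str) -> list:
    """Entity-schema violations only (envelope problems are body_validity)."""
    result = document.get("result") if isinstance(document, dict) else None
    if not isinstance(result, dict):
        return []
    try:
        pattern = classify_result_pattern(result)
    except MalformedResultError:
        return []
    schema = load_schema(ENTITY_KINDS[kind][0])
    out = []
    if pattern in (PATTERN_DETAILS, PATTERN_MASTER_DETAILS):
        for i, record in enumerate(result["data"]):
            out.extend(schema_check(record, schema, f"$.result.data[{i}]"))
    else:
        out.extend(schema_check(result, schema, "$.result"))
    return out


def _data_type_violations(document: Any) -> list[str]:
    """Identifier fields must be text; ``data`` must be an array."""
    problems: list[str] = []

    def walk(value: Any, where: str) -> None:
        if isinstance(value, dict):
            for key, sub in value.items():
                if key == "data" and not isinstance(sub, list):
                    problems.append(f"{where}.data is not an array")
                elif key.endswith("DbId"):
                    if sub is not None and not isinstance(sub, str):
                        problems.append(f"{where}.{key} is {type(sub).__name__}, not text")
                else:
                    walk(sub, f"{where}.{key}")
            return
        if isinstance(value, list):
            for i, sub in enumerate(value):
                walk(sub, f"{where}[{i}]")

    result = document.get("result") if isinstance(document, dict) else None
    if result is not None:
        walk(result, "$.result")
    return problems


# ---------------------------------------------------------------------------
# operations


def detect_endpoints(connection: Connection) -> list[dict]:
    """Call descriptors advertised by the server's ``/calls`` meta-endpoint.

    Raises :class:`BrapiError` subclasses when the endpoint is absent or
    does not speak the envelope protocol; the caller turns that into an
    untestable report rather than a crash.
    """
    probe = Connection(
        connection.base_url,
        token=connection.token,
        timeout=connection.timeout,
        transport=connection.transport,
        strict=False,
    )
    descriptors: list[dict] = []
    page = 0
    while True:
        response = request_raw(probe, "calls", {"page": page, "pageSize": 1000})
        if response.status != 200:
            raise InvalidParameterError(f"/calls answered HTTP {response.status}")
        document = response.json()
        result = document.get("result") if isinstance(document, dict) else None
        data = result.get("data") if isinstance(result, dict) else None
        if not isinstance(data, list):
            raise InvalidParameterError("/calls did not return a data array")
        descriptors.extend(d for d in data if isinstance(d, dict))
        pagination = (document.get("metadata") or {}).get("pagination") or {}
        total_pages = pagination.get("totalPages", 0)
        if not isinstance(total_pages, int) or page >= total_pages - 1:
            return descriptors
        page += 1


def run_test(
    connection: Connection, case: TestCase, context: dict[str, Any]
) -> TestResult:
    """Execute one case, evaluating every listed check independently."""
    missing = [key for key in case.requires if key not in context]
    if missing:
        return TestResult(
            case.id,
            case.category,
            "skip",
            message=f"harvested input {missing} unavailable"
            + (f" (source test {case.source})" if case.source else ""),
        )

    call = case.call.format_map(context)
    params = _resolve(case.params, context)
    body = _resolve(case.body, context) if case.body is not None else None

    try:
        response = request_raw(connection, call, params, method=case.method, body=body)
    except BrapiError as exc:
        return TestResult(
            case.id,
            case.category,
            "fail",
            check_outcomes={c: "fail" for c in case.checks},
            message=f"transport failure: {exc}",
        )

    outcomes: dict[str, str] = {}
    observed: dict[str, Any] = {"http_status": response.status, "content_type": response.content_type}
    messages: list[str] = []

    document: Any = None
    parse_error: Optional[str] = None
    try:
        document = response.json()
    except BrapiError as exc:
        parse_error = str(exc)

    for check_name in case.checks:
        ok = True
        if check_name == "status_code":
            ok = response.status == case.expected_status
            if not ok:
                messages.append(
                    f"status_code: expected {case.expected_status}, observed {response.status}"
                )
        elif check_name == "content_type":
            ok = response.content_type.split(";")[0].strip() == "application/json"
            if not ok:
                messages.append(f"content_type: expected application/json, observed {response.content_type!r}")
        elif document is None:
            ok = False
            messages.append(f"{check_name}: no parseable JSON body ({parse_error})")
        elif check_name == "body_validity":
            violations = validate_envelope(document, expected_pattern=case.expected_pattern)
            ok = not violations
            if not ok:
                observed["body_violations"] = [str(v) for v in violations]
                messages.append(f"body_validity: {violations[0]}")
        elif check_name == "schema_match":
            violations = _entity_violations(document, case.expected_entity)
            ok = not violations
            if not ok:
                observed["schema_violations"] = [str(v) for v in violations]
                messages.append(f"schema_match: {violations[0]}")
        elif check_name == "data_types":
            problems = _data_type_violations(document)
            ok = not problems
            if not ok:
                observed["type_violations"] = problems
                messages.append(f"data_types: {problems[0]}")
        elif check_name == "reference_match":
            for path, expected_template in case.reference.items():
                expected = _resolve(expected_template, context)
                found, actual = _dig(document, path)
                if expected == ANY:
                    good = found and actual is not None
                elif isinstance(actual, list) and not isinstance(expected, list):
                    good = found and all(v == expected for v in actual)
                else:
                    good = found and actual == expected
                if not good:
                    ok = False
                    observed[f"reference:{path}"] = actual if found else "<absent>"
                    messages.append(
                        f"reference_match: {path} expected {expected!r}, observed "
                        + (repr(actual) if found else "nothing")
                    )
        outcomes[check_name] = "pass" if ok else "fail"

    if document is not None:
        for key, path in case.harvest.items():
            found, value = _dig(document, path)
            if found and value is not None:
                context[key] = value

    failed = [c for c, o in outcomes.items() if o == "fail"]
    return TestResult(
        case.id,
        case.category,
        "fail" if failed else "pass",
        check_outcomes=outcomes,
        observed=observed,
        message="; ".join(messages),
    )


def run_suite(
    base_url_or_connection,
    token: Optional[str] = None,
    only_category: Optional[str] = None,
    catalog: Optional[list] = None,
) -> Report:
    """Discover, schedule and run the full battery; aggregate per resource."""
    if isinstance(base_url_or_connection, Connection):
        connection = base_url_or_connection
    else:
        connection = Connection(base_url_or_connection, token=token)
    timestamp = _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")

    try:
        descriptors = detect_endpoints(connection)
    except BrapiError as exc:
        return Report(
            base_url=connection.base_url,
            timestamp=timestamp,
            untestable=True,
            reason=f"calls meta-endpoint unusable: {exc}",
        )

    advertised: set[tuple[str, str]] = set()
    for descriptor in descriptors:
        call = descriptor.get("call")
        for method in descriptor.get("methods", []):
            if isinstance(call, str) and isinstance(method, str):
                advertised.add((call.strip("/"), method.upper()))

    cases = list(catalog) if catalog is not None else build_catalog()
    if only_category is not None:
        cases = [c for c in cases if c.category == only_category]

    context: dict[str, Any] = {}
    results: list[TestResult] = []
    for case in cases:
        if (case.advertised, case.method) not in advertised:
            results.append(
                TestResult(
                    case.id, case.category, "skip",
                    message=f"call {case.advertised!r} [{case.method}] not advertised by /calls",
                )
            )
            continue
        results.append(run_test(connection, case, context))
    return Report(base_url=connection.base_url, timestamp=timestamp, results=results)


def render_report(report: Report, format: str = "tree") -> str:
    """Render as an indented text tree or loss-less JSON."""
    if format == "json":
        return json.dumps(report.to_json(), indent=2)
    if format != "tree":
        raise InvalidParameterError(f"unknown report format {format!r}")
    lines = [f"BrAPI compliance report for {report.base_url} ({report.timestamp})"]
    if report.untestable:
        lines.append(f"  UNTESTABLE: {report.reason}")
        return "\n".join(lines)
    aggregates = report.aggregates()
    for resource, results in report.by_resource().items():
        counts = aggregates[resource]
        executed = counts["pass"] + counts["fail"]
        lines.append(
            f"  {resource}: {counts['pass']}/{executed} passed"
            + (f", {counts['skip']} skipped" if counts["skip"] else "")
        )
        for result in results:
            lines.append(f"    [{result.outcome.upper():4s}] {result.test_id}")
            if result.outcome == "fail":
                for check_name, outcome in result.check_outcomes.items():
                    if outcome == "fail":
                        lines.append(f"      x {check_name}")
                if result.message:
                    lines.append(f"      {result.message}")
            elif result.outcome == "skip" and result.message:
                lines.append(f"      {result.message}")
    totals = report.counts()
    lines.append(
        f"  overall: {'COMPLIANT' if report.compliant else 'NOT COMPLIANT'} "
        f"({totals['pass']} pass, {totals['fail']} fail, {totals['skip']} skip)"
    )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# the bundled test battery


def build_catalog() -> list[TestCase]:
    """The full scripted battery, one or more cases per roster call.

    Cases appear in dependency order: every harvested value is produced by
    an earlier case.
    """
    cases: list[TestCase] = []
    add = cases.append

    # Calls ---------------------------------------------------------------
    add(TestCase(
        id="calls-list", category="Calls", call="calls", advertised="calls",
        params={"pageSize": 1000},
        expected_pattern=PATTERN_DETAILS, expected_entity="call_descriptor",
        reference={"metadata.pagination.currentPage": 0,
                   "result.data.*.versions.0": ANY},
    ))
    # Crops ---------------------------------------------------------------
    add(TestCase(
        id="crops-list", category="Crops", call="crops", advertised="crops",
        expected_pattern=PATTERN_DETAILS,
    ))
    # Germplasm -----------------------------------------------------------
    add(TestCase(
        id="germplasm-list", category="Germplasm", call="germplasm",
        advertised="germplasm", expected_pattern=PATTERN_DETAILS,
        expected_entity="germplasm",
        reference={"metadata.pagination.currentPage": 0},
    ))
    add(TestCase(
        id="germplasm-search-get", category="Germplasm", call="germplasm-search",
        advertised="germplasm-search", expected_pattern=PATTERN_DETAILS,
        expected_entity="germplasm",
        harvest={"germplasm_id": "result.data.0.germplasmDbId"},
    ))
    add(TestCase(
        id="germplasm-search-post", category="Germplasm", call="germplasm-search",
        advertised="germplasm-search", method="POST", body={},
        expected_pattern=PATTERN_DETAILS, expected_entity="germplasm",
    ))
    add(TestCase(
        id="germplasm-detail", category="Germplasm", call="germplasm/{germplasm_id}",
        advertised="germplasm/{germplasmDbId}", requires=("germplasm_id",),
        source="germplasm-search-get",
        expected_pattern=PATTERN_MASTER, expected_entity="germplasm",
        reference={"result.germplasmDbId": "{germplasm_id}"},
    ))
    add(TestCase(
        id="germplasm-identity-1", category="Germplasm", call="germplasm/1",
        advertised="germplasm/{germplasmDbId}",
        expected_pattern=PATTERN_MASTER, expected_entity="germplasm",
        reference={"result.germplasmDbId": "1",
                   "metadata.pagination.pageSize": 0,
                   "metadata.pagination.currentPage": 0,
                   "metadata.pagination.totalCount": 0,
                   "metadata.pagination.totalPages": 0},
    ))
    add(TestCase(
        id="germplasm-pedigree", category="Germplasm",
        call="germplasm/{germplasm_id}/pedigree",
        advertised="germplasm/{germplasmDbId}/pedigree",
        requires=("germplasm_id",), source="germplasm-search-get",
        expected_pattern=PATTERN_MASTER,
        reference={"result.germplasmDbId": "{germplasm_id}"},
    ))
    add(TestCase(
        id="germplasm-progeny", category="Germplasm",
        call="germplasm/{germplasm_id}/progeny",
        advertised="germplasm/{germplasmDbId}/progeny",
        requires=("germplasm_id",), source="germplasm-search-get",
        expected_pattern=PATTERN_MASTER_DETAILS,
        reference={"result.germplasmDbId": "{germplasm_id}"},
    ))
    add(TestCase(
        id="germplasm-markerprofiles", category="Germplasm",
        call="germplasm/{germplasm_id}/markerprofiles",
        advertised="germplasm/{germplasmDbId}/markerprofiles",
        requires=("germplasm_id",), source="germplasm-search-get",
        expected_pattern=PATTERN_DETAILS, expected_entity="marker_profile",
        reference={"result.data.*.germplasmDbId": "{germplasm_id}"},
    ))
    add(TestCase(
        id="germplasm-mcpd", category="Germplasm",
        call="germplasm/{germplasm_id}/mcpd",
        advertised="germplasm/{germplasmDbId}/mcpd",
        requires=("germplasm_id",), source="germplasm-search-get",
        expected_pattern=PATTERN_MASTER, expected_entity="germplasm",
        reference={"result.germplasmDbId": "{germplasm_id}"},
    ))
    # Germplasm Attributes ------------------------------------------------
    add(TestCase(
        id="attributes-list", category="Germplasm Attributes", call="attributes",
        advertised="attributes", expected_pattern=PATTERN_DETAILS,
        expected_entity="attribute",
    ))
    add(TestCase(
        id="attribute-categories", category="Germplasm Attributes",
        call="attributes/categories", advertised="attributes/categories",
        expected_pattern=PATTERN_DETAILS, expected_entity="attribute_category",
    ))
    add(TestCase(
        id="germplasm-attributes", category="Germplasm Attributes",
        call="germplasm/{germplasm_id}/attributes",
        advertised="germplasm/{germplasmDbId}/attributes",
        requires=("germplasm_id",), source="germplasm-search-get",
        expected_pattern=PATTERN_MASTER_DETAILS,
        reference={"result.germplasmDbId": "{germplasm_id}"},
    ))
    # Markers -------------------------------------------------------------
    add(TestCase(
        id="markers-search-get", category="Markers", call="markers-search",
        advertised="markers-search", expected_pattern=PATTERN_DETAILS,
        expected_entity="marker",
        harvest={"marker_id": "result.data.0.markerDbId"},
    ))
    add(TestCase(
        id="markers-search-post", category="Markers", call="markers-search",
        advertised="markers-search", method="POST", body={},
        expected_pattern=PATTERN_DETAILS, expected_entity="marker",
    ))
    add(TestCase(
        id="marker-detail", category="Markers", call="markers/{marker_id}",
        advertised="markers/{markerDbId}", requires=("marker_id",),
        source="markers-search-get",
        expected_pattern=PATTERN_MASTER, expected_entity="marker",
        reference={"result.markerDbId": "{marker_id}"},
    ))
    # Marker Profiles -----------------------------------------------------
    add(TestCase(
        id="markerprofiles-list", category="Marker Profiles", call="markerprofiles",
        advertised="markerprofiles", expected_pattern=PATTERN_DETAILS,
        expected_entity="marker_profile",
        harvest={"profile_id": "result.data.0.markerProfileDbId"},
    ))
    add(TestCase(
        id="markerprofile-detail", category="Marker Profiles",
        call="markerprofiles/{profile_id}",
        advertised="markerprofiles/{markerProfileDbId}",
        requires=("profile_id",), source="markerprofiles-list",
        expected_pattern=PATTERN_MASTER_DETAILS,
        reference={"result.markerProfileDbId": "{profile_id}"},
    ))
    add(TestCase(
        id="allelematrices-list", category="Marker Profiles", call="allelematrices",
        advertised="allelematrices", expected_pattern=PATTERN_DETAILS,
        expected_entity="allele_matrix",
    ))
    add(TestCase(
        id="allelematrix-search-get", category="Marker Profiles",
        call="allelematrix-search", advertised="allelematrix-search",
        params={"markerProfileDbId": "{profile_id}"},
        requires=("profile_id",), source="markerprofiles-list",
        expected_pattern=PATTERN_DETAILS, expected_entity="allele_call",
        reference={"result.data.*.markerProfileDbId": "{profile_id}"},
    ))
    add(TestCase(
        id="allelematrix-search-post", category="Marker Profiles",
        call="allelematrix-search", advertised="allelematrix-search",
        method="POST", body={"markerProfileDbId": "{profile_id}"},
        requires=("profile_id",), source="markerprofiles-list",
        expected_pattern=PATTERN_DETAILS, expected_entity="allele_call",
    ))
    # Programs ------------------------------------------------------------
    add(TestCase(
        id="programs-list", category="Programs", call="programs",
        advertised="programs", expected_pattern=PATTERN_DETAILS,
        expected_entity="program",
        harvest={"program_id": "result.data.0.programDbId"},
    ))
    add(TestCase(
        id="programs-search-post", category="Programs", call="programs-search",
        advertised="programs-search", method="POST", body={},
        expected_pattern=PATTERN_DETAILS, expected_entity="program",
    ))
    # Trials --------------------------------------------------------------
    add(TestCase(
        id="trials-list", category="Trials", call="trials", advertised="trials",
        expected_pattern=PATTERN_DETAILS, expected_entity="trial",
        harvest={"trial_id": "result.data.0.trialDbId"},
    ))
    add(TestCase(
        id="trials-filter-by-program", category="Trials", call="trials",
        advertised="trials", params={"programDbId": "{program_id}"},
        requires=("program_id",), source="programs-list",
        expected_pattern=PATTERN_DETAILS, expected_entity="trial",
        reference={"result.data.*.programDbId": "{program_id}"},
    ))
    add(TestCase(
        id="trial-detail", category="Trials", call="trials/{trial_id}",
        advertised="trials/{trialDbId}", requires=("trial_id",),
        source="trials-list",
        expected_pattern=PATTERN_MASTER, expected_entity="trial",
        reference={"result.trialDbId": "{trial_id}"},
    ))
    # Studies -------------------------------------------------------------
    add(TestCase(
        id="studies-search-get", category="Studies", call="studies-search",
        advertised="studies-search", expected_pattern=PATTERN_DETAILS,
        expected_entity="study",
        harvest={"study_id": "result.data.0.studyDbId"},
    ))
    add(TestCase(
        id="studies-search-post", category="Studies", call="studies-search",
        advertised="studies-search", method="POST", body={},
        expected_pattern=PATTERN_DETAILS, expected_entity="study",
    ))
    add(TestCase(
        id="study-detail", category="Studies", call="studies/{study_id}",
        advertised="studies/{studyDbId}", requires=("study_id",),
        source="studies-search-get",
        expected_pattern=PATTERN_MASTER, expected_entity="study",
        reference={"result.studyDbId": "{study_id}"},
    ))
    add(TestCase(
        id="study-germplasm", category="Studies",
        call="studies/{study_id}/germplasm",
        advertised="studies/{studyDbId}/germplasm",
        requires=("study_id",), source="studies-search-get",
        expected_pattern=PATTERN_DETAILS, expected_entity="germplasm",
    ))
    add(TestCase(
        id="study-observationvariables", category="Studies",
        call="studies/{study_id}/observationvariables",
        advertised="studies/{studyDbId}/observationvariables",
        requires=("study_id",), source="studies-search-get",
        expected_pattern=PATTERN_DETAILS, expected_entity="observation_variable",
        harvest={"variable_id": "result.data.0.observationVariableDbId"},
    ))
    add(TestCase(
        id="study-observationunits-get", category="Studies",
        call="studies/{study_id}/observationunits",
        advertised="studies/{studyDbId}/observationunits",
        requires=("study_id",), source="studies-search-get",
        expected_pattern=PATTERN_DETAILS, expected_entity="observation_unit",
        harvest={"unit_id": "result.data.0.observationUnitDbId"},
        reference={"result.data.*.studyDbId": "{study_id}"},
    ))
    add(TestCase(
        id="study-observationunits-post", category="Studies",
        call="studies/{study_id}/observationunits",
        advertised="studies/{studyDbId}/observationunits", method="POST",
        body={"observations": [{"observationUnitDbId": "{unit_id}",
                                "observationVariableDbId": "{variable_id}",
                                "value": "7.5"}]},
        requires=("study_id", "unit_id", "variable_id"),
        source="study-observationunits-get",
        expected_pattern=PATTERN_DETAILS, expected_entity="observation",
        reference={"result.data.*.observationUnitDbId": "{unit_id}"},
    ))
    add(TestCase(
        id="study-observationunits-put", category="Studies",
        call="studies/{study_id}/observationunits",
        advertised="studies/{studyDbId}/observationunits", method="PUT",
        body={"observations": [{"observationUnitDbId": "{unit_id}",
                                "observationVariableDbId": "{variable_id}",
                                "value": "8.0"}]},
        requires=("study_id", "unit_id", "variable_id"),
        source="study-observationunits-get",
        expected_pattern=PATTERN_DETAILS, expected_entity="observation",
    ))
    add(TestCase(
        id="study-table", category="Studies", call="studies/{study_id}/table",
        advertised="studies/{studyDbId}/table",
        requires=("study_id",), source="studies-search-get",
        expected_pattern=PATTERN_MASTER_DETAILS,
        reference={"result.studyDbId": "{study_id}", "result.headerRow": ANY},
    ))
    add(TestCase(
        id="study-layout-get", category="Studies",
        call="studies/{study_id}/layout",
        advertised="studies/{studyDbId}/layout",
        requires=("study_id",), source="studies-search-get",
        expected_pattern=PATTERN_DETAILS,
    ))
    add(TestCase(
        id="study-layout-put", category="Studies",
        call="studies/{study_id}/layout",
        advertised="studies/{studyDbId}/layout", method="PUT",
        body={"layout": [{"observationUnitDbId": "{unit_id}",
                          "positionCoordinateX": "9"}]},
        requires=("study_id", "unit_id"), source="study-observationunits-get",
        expected_pattern=PATTERN_DETAILS,
    ))
    add(TestCase(
        id="study-observations-get", category="Studies",
        call="studies/{study_id}/observations",
        advertised="studies/{studyDbId}/observations",
        requires=("study_id",), source="studies-search-get",
        expected_pattern=PATTERN_DETAILS, expected_entity="observation",
        harvest={"observation_id": "result.data.0.observationDbId",
                 "observation_unit_id": "result.data.0.observationUnitDbId",
                 "observation_variable_id": "result.data.0.observationVariableDbId"},
    ))
    add(TestCase(
        id="study-observations-put", category="Studies",
        call="studies/{study_id}/observations",
        advertised="studies/{studyDbId}/observations", method="PUT",
        body={"observations": [{"observationDbId": "{observation_id}",
                                "observationUnitDbId": "{observation_unit_id}",
                                "observationVariableDbId": "{observation_variable_id}",
                                "value": "8.1"}]},
        requires=("study_id", "observation_id", "observation_unit_id",
                  "observation_variable_id"),
        source="study-observations-get",
        expected_pattern=PATTERN_DETAILS, expected_entity="observation",
        reference={"result.data.0.observationDbId": "{observation_id}",
                   "result.data.0.value": "8.1"},
    ))
    add(TestCase(
        id="seasons-list", category="Studies", call="seasons", advertised="seasons",
        expected_pattern=PATTERN_DETAILS, expected_entity="season",
    ))
    add(TestCase(
        id="studytypes-list", category="Studies", call="studytypes",
        advertised="studytypes",
        expected_pattern=PATTERN_DETAILS, expected_entity="study_type",
    ))
    add(TestCase(
        id="observationlevels-list", category="Studies", call="observationlevels",
        advertised="observationlevels", expected_pattern=PATTERN_DETAILS,
    ))
    add(TestCase(
        id="study-observationunits-table", category="Studies",
        call="studies/{study_id}/observationunits/table",
        advertised="studies/{studyDbId}/observationunits/table",
        requires=("study_id",), source="studies-search-get",
        expected_pattern=PATTERN_DETAILS,
    ))
    # Phenotypes ----------------------------------------------------------
    add(TestCase(
        id="phenotypes-search-post", category="Phenotypes",
        call="phenotypes-search", advertised="phenotypes-search", method="POST",
        body={}, expected_pattern=PATTERN_DETAILS,
    ))
    add(TestCase(
        id="phenotypes-search-get", category="Phenotypes",
        call="phenotypes-search", advertised="phenotypes-search",
        expected_pattern=PATTERN_DETAILS,
    ))
    add(TestCase(
        id="phenotypes-search-table", category="Phenotypes",
        call="phenotypes-search/table", advertised="phenotypes-search/table",
        method="POST", body={}, expected_pattern=PATTERN_MASTER_DETAILS,
        reference={"result.headerRow": ANY},
    ))
    add(TestCase(
        id="phenotypes-search-tsv", category="Phenotypes",
        call="phenotypes-search/tsv", advertised="phenotypes-search/tsv",
        method="POST", body={}, expected_pattern=PATTERN_MASTER,
        reference={"metadata.datafiles.0": ANY},
    ))
    add(TestCase(
        id="phenotypes-search-csv", category="Phenotypes",
        call="phenotypes-search/csv", advertised="phenotypes-search/csv",
        method="POST", body={}, expected_pattern=PATTERN_MASTER,
        reference={"metadata.datafiles.0": ANY},
    ))
    # Traits --------------------------------------------------------------
    add(TestCase(
        id="traits-list", category="Traits", call="traits", advertised="traits",
        expected_pattern=PATTERN_DETAILS, expected_entity="trait",
        harvest={"trait_id": "result.data.0.traitDbId"},
    ))
    add(TestCase(
        id="trait-detail", category="Traits", call="traits/{trait_id}",
        advertised="traits/{traitDbId}", requires=("trait_id",),
        source="traits-list",
        expected_pattern=PATTERN_MASTER, expected_entity="trait",
        reference={"result.traitDbId": "{trait_id}"},
    ))
    # Observation Variables -----------------------------------------------
    add(TestCase(
        id="variables-list", category="Observation Variables", call="variables",
        advertised="variables", expected_pattern=PATTERN_DETAILS,
        expected_entity="observation_variable",
    ))
    add(TestCase(
        id="variable-detail", category="Observation Variables",
        call="variables/{variable_id}",
        advertised="variables/{observationVariableDbId}",
        requires=("variable_id",), source="study-observationvariables",
        expected_pattern=PATTERN_MASTER, expected_entity="observation_variable",
        reference={"result.observationVariableDbId": "{variable_id}"},
    ))
    add(TestCase(
        id="variables-search-post", category="Observation Variables",
        call="variables-search", advertised="variables-search", method="POST",
        body={}, expected_pattern=PATTERN_DETAILS,
        expected_entity="observation_variable",
    ))
    add(TestCase(
        id="variables-datatypes", category="Observation Variables",
        call="variables/datatypes", advertised="variables/datatypes",
        expected_pattern=PATTERN_DETAILS,
    ))
    add(TestCase(
        id="ontologies-list", category="Observation Variables", call="ontologies",
        advertised="ontologies", expected_pattern=PATTERN_DETAILS,
        expected_entity="ontology",
    ))
    # Genome Maps ---------------------------------------------------------
    add(TestCase(
        id="maps-list", category="Genome Maps", call="maps", advertised="maps",
        expected_pattern=PATTERN_DETAILS, expected_entity="genome_map",
        harvest={"map_id": "result.data.0.mapDbId"},
    ))
    add(TestCase(
        id="map-detail", category="Genome Maps", call="maps/{map_id}",
        advertised="maps/{mapDbId}", requires=("map_id",), source="maps-list",
        expected_pattern=PATTERN_MASTER, expected_entity="genome_map",
        reference={"result.mapDbId": "{map_id}"},
    ))
    add(TestCase(
        id="map-positions", category="Genome Maps",
        call="maps/{map_id}/positions", advertised="maps/{mapDbId}/positions",
        requires=("map_id",), source="maps-list",
        expected_pattern=PATTERN_DETAILS, expected_entity="map_position",
        harvest={"linkage_group": "result.data.0.linkageGroupName"},
    ))
    add(TestCase(
        id="map-positions-group", category="Genome Maps",
        call="maps/{map_id}/positions/{linkage_group}",
        advertised="maps/{mapDbId}/positions/{linkageGroupId}",
        requires=("map_id", "linkage_group"), source="map-positions",
        expected_pattern=PATTERN_DETAILS, expected_entity="map_position",
        reference={"result.data.*.linkageGroupName": "{linkage_group}"},
    ))
    # Location ------------------------------------------------------------
    add(TestCase(
        id="locations-list", category="Location", call="locations",
        advertised="locations", expected_pattern=PATTERN_DETAILS,
        expected_entity="location",
        reference={"metadata.pagination.currentPage": 0},
        harvest={"location_id": "result.data.0.locationDbId"},
    ))
    add(TestCase(
        id="location-detail", category="Location", call="locations/{location_id}",
        advertised="locations/{locationDbId}", requires=("location_id",),
        source="locations-list",
        expected_pattern=PATTERN_MASTER, expected_entity="location",
        reference={"result.locationDbId": "{location_id}",
                   "metadata.pagination.pageSize": 0,
                   "metadata.pagination.currentPage": 0,
                   "metadata.pagination.totalCount": 0,
                   "metadata.pagination.totalPages": 0},
    ))
    # Samples -------------------------------------------------------------
    add(TestCase(
        id="samples-search-get", category="Samples", call="samples-search",
        advertised="samples-search", expected_pattern=PATTERN_DETAILS,
        expected_entity="sample",
        harvest={"sample_id": "result.data.0.sampleDbId",
                 "sample_unit_id": "result.data.0.observationUnitDbId"},
    ))
    add(TestCase(
        id="samples-search-post", category="Samples", call="samples-search",
        advertised="samples-search", method="POST", body={},
        expected_pattern=PATTERN_DETAILS, expected_entity="sample",
    ))
    add(TestCase(
        id="sample-detail", category="Samples", call="samples/{sample_id}",
        advertised="samples/{sampleDbId}", requires=("sample_id",),
        source="samples-search-get",
        expected_pattern=PATTERN_MASTER, expected_entity="sample",
        reference={"result.sampleDbId": "{sample_id}"},
    ))
    add(TestCase(
        id="samples-put", category="Samples", call="samples",
        advertised="samples", method="PUT",
        body={"sampleDbId": "{sample_id}", "observationUnitDbId": "{sample_unit_id}",
              "plateName": "PLATE-V", "well": "H12", "takenBy": "validator"},
        requires=("sample_id", "sample_unit_id"), source="samples-search-get",
        expected_pattern=PATTERN_MASTER, expected_entity="sample",
        reference={"result.sampleDbId": "{sample_id}"},
    ))
    # Vendor Samples ------------------------------------------------------
    add(TestCase(
        id="vendor-orders-list", category="Vendor Samples", call="vendor/orders",
        advertised="vendor/orders", expected_pattern=PATTERN_DETAILS,
        expected_entity="vendor_order",
        harvest={"vendor_order_id": "result.data.0.orderDbId",
                 "vendor_plate_id": "result.data.0.plates.0"},
    ))
    add(TestCase(
        id="vendor-plate-detail", category="Vendor Samples",
        call="vendor/plates/{vendor_plate_id}",
        advertised="vendor/plates/{plateDbId}",
        requires=("vendor_plate_id",), source="vendor-orders-list",
        expected_pattern=PATTERN_MASTER, expected_entity="vendor_plate",
        reference={"result.plateDbId": "{vendor_plate_id}"},
    ))
    add(TestCase(
        id="vendor-plates-post", category="Vendor Samples", call="vendor/plates",
        advertised="vendor/plates", method="POST",
        body={"clientId": "validator",
              "plates": [{"plateName": "VP-1", "sampleDbIds": ["{sample_id}"]}]},
        requires=("sample_id",), source="samples-search-get",
        expected_pattern=PATTERN_MASTER,
        reference={"result.orderDbId": ANY},
    ))
    add(TestCase(
        id="vendor-order-status", category="Vendor Samples",
        call="vendor/orders/{vendor_order_id}/status",
        advertised="vendor/orders/{orderDbId}/status",
        requires=("vendor_order_id",), source="vendor-orders-list",
        expected_pattern=PATTERN_MASTER,
        reference={"result.orderDbId": "{vendor_order_id}",
                   "result.status": ANY},
    ))
    add(TestCase(
        id="vendor-order-results", category="Vendor Samples",
        call="vendor/orders/{vendor_order_id}/results",
        advertised="vendor/orders/{orderDbId}/results",
        requires=("vendor_order_id",), source="vendor-orders-list",
        expected_pattern=PATTERN_DETAILS,
    ))

    # every harvested key must be produced by an earlier case
    produced: set[str] = set()
    for case in cases:
        for key in case.requires:
            if key not in produced:
                raise InvalidParameterError(
                    f"catalog order broken: {case.id} needs {key!r} before it is harvested"
                )
        produced.update(case.harvest)
    return cases
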