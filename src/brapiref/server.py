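"""Reference HTTP service exposing the full BrAPI v1 call roster.

The server is a plain WSGI application backed by an in-memory fixture
:class:`~brapiref.fixtures.Store`.  Every URL follows the standard grammar
``http(s)://host[/basePath]/brapi/v1/<call>`` and every response — including
errors — is a response envelope.  Error responses carry the all-zero
pagination block, a ``null`` result and one explanatory status entry.

The call roster is organised into the sixteen standard categories; the
per-category call counts are part of the conformance surface and are
checked by the bundled validator through the ``/calls`` meta-endpoint.
A path served with distinct GET and POST semantics counts as two calls.

For conformance-tool development the server can be started with deliberate
protocol faults (:data:`KNOWN_FAULTS`), each of which breaks exactly one
aspect of the wire contract.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Iterable, Mapping, Optional
from urllib.parse import parse_qs

from .core_model import (
    ALL_ZERO_PAGINATION,
    Pagination,
    ResponseEnvelope,
    Status,
    make_envelope,
)
from .errors import ConfigurationError, InvalidParameterError
from .fixtures import FixtureConfig, Store, generate_fixture, get_by_id, search
from .pagination import paginate

__all__ = [
    "ServerConfig",
    "Request",
    "Route",
    "ReferenceServer",
    "check_auth",
    "KNOWN_FAULTS",
    "TABLE1_CATEGORY_COUNTS",
]

#: printed per-category call counts the roster must reproduce
TABLE1_CATEGORY_COUNTS = {
    "Calls": 1,
    "Crops": 1,
    "Germplasm": 8,
    "Germplasm Attributes": 3,
    "Markers": 3,
    "Marker Profiles": 5,
    "Programs": 2,
    "Trials": 2,
    "Studies": 17,
    "Phenotypes": 5,
    "Traits": 2,
    "Observation Variables": 5,
    "Genome Maps": 4,
    "Location": 2,
    "Samples": 4,
    "Vendor Samples": 5,
}

#: deliberate protocol faults for validator-sensitivity testing
KNOWN_FAULTS = frozenset(
    {
        "omit-total-pages",      # paginated responses lose the totalPages key
        "pagination-off-by-one", # totalPages reported one too high
        "detail-id-mismatch",    # detail calls return a mangled identifier
        "wrong-media-type",      # responses served as text/plain
        "details-extra-key",     # details results gain a stray sibling key
    }
)

JSON_TYPE = "application/json"
TSV_TYPE = "text/tab-separated-values"
CSV_TYPE = "text/csv"


@dataclass(frozen=True)
class ServerConfig:
    base_path: str = ""
    auth_mode: str = "open"  # "open" | "token"
    tokens: tuple[str, ...] = ()
    default_page_size: int = 1000
    max_page_size: Optional[int] = None  # no cap by default
    datafile_threshold: int = 10_000
    datafile_dir: Optional[str] = None
    faults: frozenset = frozenset()
    version_tags: tuple[str, ...] = ("1.0", "1.3")

    def __post_init__(self) -> None:
        if "brapi" in self.base_path.split("/"):
            raise ConfigurationError("base_path must not contain a 'brapi' segment")
        if self.auth_mode not in ("open", "token"):
            raise ConfigurationError(f"unknown auth mode {self.auth_mode!r}")
        unknown = set(self.faults) - KNOWN_FAULTS
        if unknown:
            raise ConfigurationError(f"unknown fault flags {sorted(unknown)}")


@dataclass
class Request:
    """Transport-independent view of one HTTP request."""

    method: str
    path: str
    query: dict[str, list[str]] = field(default_factory=dict)
    body: Optional[dict] = None
    headers: dict[str, str] = field(default_factory=dict)  # lower-cased names
    base_url: str = "http://testserver"


@dataclass(frozen=True)
class Route:
    path: str  # template relative to /brapi/v1/, e.g. "germplasm/{germplasmDbId}"
    method: str
    category: str
    handler: Callable
    versions: tuple[str, ...]

    def match(self, segments: list[str]) -> Optional[dict[str, str]]:
        template = self.path.split("/")
        if len(template) != len(segments):
            return None
        params: dict[str, str] = {}
        for want, have in zip(template, segments):
            if want.startswith("{") and want.endswith("}"):
                params[want[1:-1]] = have
            elif want != have:
                return None
        return params


def check_auth(headers: Mapping[str, str], config: ServerConfig) -> str:
    """``"authorized"`` or ``"unauthorized"`` for the given request headers.

    Open mode always authorizes.  Token mode requires an
    ``Authorization: Bearer <token>`` header carrying an accepted token.
    """
    if config.auth_mode == "open":
        return "authorized"
    value = headers.get("authorization", "")
    if value.startswith("Bearer ") and value[len("Bearer "):] in config.tokens:
        return "authorized"
    return "unauthorized"


class _HandlerError(Exception):
    def __init__(self, status: int, message: str):
        self.status = status
        self.message = message


class ReferenceServer:
    """WSGI application serving a fixture store under the v1 URL scheme."""

    def __init__(self, store: Optional[Store] = None, config: Optional[ServerConfig] = None):
        self.store = store if store is not None else generate_fixture(FixtureConfig())
        self.config = config or ServerConfig()
        self._datafile_dir: Optional[str] = self.config.datafile_dir
        self._datafile_counter = 0
        self.routes: list[Route] = self._build_routes()

    # ------------------------------------------------------------------ WSGI
    def __call__(self, environ, start_response):
        request = self._request_from_environ(environ)
        status, content_type, body = self.dispatch(request)
        import http.client

        reason = http.client.responses.get(status, "Unknown")
        start_response(
            f"{status} {reason}",
            [("Content-Type", content_type), ("Content-Length", str(len(body)))],
        )
        return [body]

    @staticmethod
    def _request_from_environ(environ) -> Request:
        headers = {}
        for key, value in environ.items():
            if key.startswith("HTTP_"):
                headers[key[5:].replace("_", "-").lower()] = value
        if "CONTENT_TYPE" in environ:
            headers["content-type"] = environ["CONTENT_TYPE"]
        body = None
        try:
            length = int(environ.get("CONTENT_LENGTH") or 0)
        except ValueError:
            length = 0
        if length:
            raw = environ["wsgi.input"].read(length)
            try:
                body = json.loads(raw) if raw.strip() else None
            except json.JSONDecodeError:
                body = {"__invalid_json__": True}
        scheme = environ.get("wsgi.url_scheme", "http")
        host = environ.get("HTTP_HOST") or environ.get("SERVER_NAME", "testserver")
        return Request(
            method=environ["REQUEST_METHOD"].upper(),
            path=environ.get("PATH_INFO", "/"),
            query=parse_qs(environ.get("QUERY_STRING", "")),
            body=body,
            headers=headers,
            base_url=f"{scheme}://{host}",
        )

    # -------------------------------------------------------------- dispatch
    def dispatch(self, request: Request) -> tuple[int, str, bytes]:
        """Route a request and return ``(status, content type, body bytes)``."""
        path = request.path
        if not path.startswith("/"):
            path = "/" + path

        # datafiles are hosted outside the brapi call space
        if path.startswith("/datafiles/") and request.method == "GET":
            return self._serve_datafile(path[len("/datafiles/"):])

        prefix = (f"/{self.config.base_path}" if self.config.base_path else "") + "/brapi/v1/"
        if not path.startswith(prefix):
            status, envelope = self._error(404, f"no BrAPI call at {request.path!r}")
            return self._finish(status, envelope)

        if check_auth(request.headers, self.config) == "unauthorized":
            status, envelope = self._error(401, "missing or invalid bearer token")
            return self._finish(status, envelope)

        if isinstance(request.body, dict) and request.body.get("__invalid_json__"):
            status, envelope = self._error(400, "request body is not valid JSON")
            return self._finish(status, envelope)

        segments = [s for s in path[len(prefix):].split("/") if s != ""]
        matched_other_method = False
        for route in self.routes:
            params = route.match(segments)
            if params is None:
                continue
            if route.method != request.method:
                matched_other_method = True
                continue
            try:
                status, envelope = route.handler(request, params)
            except InvalidParameterError as exc:
                status, envelope = self._error(400, str(exc))
            except _HandlerError as exc:
                status, envelope = self._error(exc.status, exc.message)
            except OSError as exc:  # datafile write failure
                status, envelope = self._error(500, f"datafile export failed: {exc}")
            return self._finish(status, envelope)
        if matched_other_method:
            status, envelope = self._error(405, f"method {request.method} not allowed here")
        else:
            status, envelope = self._error(404, f"unknown call {'/'.join(segments)!r}")
        return self._finish(status, envelope)

    def _finish(self, status: int, envelope: ResponseEnvelope) -> tuple[int, str, bytes]:
        doc = envelope.to_json()
        faults = self.config.faults
        result = doc.get("result")
        paginated = isinstance(result, dict) and "data" in result
        if "omit-total-pages" in faults and paginated:
            doc["metadata"]["pagination"].pop("totalPages", None)
        if "pagination-off-by-one" in faults and paginated:
            doc["metadata"]["pagination"]["totalPages"] = (
                doc["metadata"]["pagination"].get("totalPages", 0) + 1
            )
        if (
            "details-extra-key" in faults
            and isinstance(result, dict)
            and set(result) == {"data"}
        ):
            result["extra"] = "unexpected"
        content_type = "text/plain" if "wrong-media-type" in faults else JSON_TYPE
        return status, content_type, json.dumps(doc, ensure_ascii=False).encode("utf-8")

    # ------------------------------------------------------------- envelopes
    def _error(self, status: int, message: str) -> tuple[int, ResponseEnvelope]:
        envelope = make_envelope(
            None, ALL_ZERO_PAGINATION, status=[Status(str(status), message)]
        )
        return status, envelope

    def _paging(self, request: Request) -> tuple[int, int]:
        def pick(name: str) -> Optional[str]:
            if name in request.query:
                return request.query[name][0]
            if isinstance(request.body, dict) and name in request.body:
                return str(request.body[name])
            return None

        def as_int(name: str, raw: str) -> int:
            try:
                return int(raw)
            except ValueError:
                raise InvalidParameterError(f"{name} must be an integer, got {raw!r}")

        raw_page, raw_size = pick("page"), pick("pageSize")
        page = as_int("page", raw_page) if raw_page is not None else 0
        size = as_int("pageSize", raw_size) if raw_size is not None else self.config.default_page_size
        if page < 0:
            raise InvalidParameterError(f"page must be >= 0, got {page}")
        if size < 1:
            raise InvalidParameterError(f"pageSize must be >= 1, got {size}")
        if self.config.max_page_size is not None:
            size = min(size, self.config.max_page_size)
        return page, size

    _RESERVED_PARAMS = {"page", "pageSize", "dataType", "format"}

    def _filters(self, request: Request) -> dict[str, Any]:
        filters: dict[str, Any] = {}
        for key, values in request.query.items():
            if key not in self._RESERVED_PARAMS:
                filters[key] = values[0]
        if isinstance(request.body, dict):
            for key, value in request.body.items():
                if key not in self._RESERVED_PARAMS:
                    filters[key] = value
        return filters

    def _list_envelope(
        self,
        request: Request,
        records: list,
        master: Optional[dict] = None,
        datafiles: Iterable[str] = (),
    ) -> tuple[int, ResponseEnvelope]:
        page, size = self._paging(request)
        slice_, pagination = paginate(records, page, size)
        statuses: list[Status] = []
        if pagination.total_pages > 0 and page >= pagination.total_pages:
            statuses.append(
                Status("200", f"page {page} is past the last page {pagination.total_pages - 1}")
            )
        result: dict[str, Any] = dict(master) if master else {}
        result["data"] = slice_
        return 200, make_envelope(result, pagination, statuses, datafiles)

    def _master_envelope(self, record: dict, datafiles: Iterable[str] = ()) -> tuple[int, ResponseEnvelope]:
        return 200, make_envelope(dict(record), ALL_ZERO_PAGINATION, datafiles=datafiles)

    def _detail_record(self, kind: str, db_id: str) -> dict:
        record = get_by_id(self.store, kind, db_id)
        if record is None:
            raise _HandlerError(404, f"{kind} {db_id!r} not found")
        record = dict(record)
        if "detail-id-mismatch" in self.config.faults:
            from .core_model import ENTITY_KINDS

            id_field = ENTITY_KINDS[kind][1] if kind in ENTITY_KINDS else None
            if id_field and id_field in record:
                record[id_field] = record[id_field] + "-x"
        return record

    # ------------------------------------------------------------- datafiles
    def emit_datafile(
        self,
        request: Request,
        name: str,
        header: list[str],
        rows: list[list],
        threshold: Optional[int] = None,
        sep: str = "\t",
    ) -> tuple[Optional[list[list]], list[str]]:
        """Inline *rows* or export them to a server-hosted delimited file.

        When the table exceeds *threshold* rows the full table (one header
        line plus all rows) is written under the datafile directory and its
        URL is returned for the ``metadata.datafiles`` array; the inline
        result is then ``None``.  ``threshold`` 0 always exports.
        """
        if threshold is None:
            threshold = self.config.datafile_threshold
        if len(rows) <= threshold and threshold != 0:
            return rows, []
        if self._datafile_dir is None:
            self._datafile_dir = tempfile.mkdtemp(prefix="brapiref-datafiles-")
        self._datafile_counter += 1
        ext = "csv" if sep == "," else "tsv"
        filename = f"{name}-{self._datafile_counter}.{ext}"
        path = os.path.join(self._datafile_dir, filename)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(sep.join(str(h) for h in header) + "\n")
            for row in rows:
                fh.write(sep.join("" if v is None else str(v) for v in row) + "\n")
        return None, [f"{request.base_url}/datafiles/{filename}"]

    def _serve_datafile(self, filename: str) -> tuple[int, str, bytes]:
        if self._datafile_dir is None or "/" in filename or ".." in filename:
            return 404, "text/plain", b"no such datafile"
        path = os.path.join(self._datafile_dir, filename)
        if not os.path.exists(path):
            return 404, "text/plain", b"no such datafile"
        with open(path, "rb") as fh:
            content = fh.read()
        ctype = CSV_TYPE if filename.endswith(".csv") else TSV_TYPE
        return 200, ctype, content

    # ---------------------------------------------------------------- roster
    def _build_routes(self) -> list[Route]:
        versions = self.config.version_tags
        routes: list[Route] = []

        def add(path: str, method: str, category: str, handler: Callable) -> None:
            routes.append(Route(path, method, category, handler, versions))

        def listing(kind: str) -> Callable:
            def handler(request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
                records = search(self.store, kind, self._filters(request))
                return self._list_envelope(request, records)

            return handler

        def detail(kind: str, param: str) -> Callable:
            def handler(request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
                return self._master_envelope(self._detail_record(kind, params[param]))

            return handler

        # Calls -------------------------------------------------------------
        add("calls", "GET", "Calls", self._h_calls)
        # Crops -------------------------------------------------------------
        add("crops", "GET", "Crops", self._h_crops)
        # Germplasm ---------------------------------------------------------
        add("germplasm", "GET", "Germplasm", listing("germplasm"))
        add("germplasm-search", "GET", "Germplasm", listing("germplasm"))
        add("germplasm-search", "POST", "Germplasm", listing("germplasm"))
        add("germplasm/{germplasmDbId}", "GET", "Germplasm", detail("germplasm", "germplasmDbId"))
        add("germplasm/{germplasmDbId}/pedigree", "GET", "Germplasm", self._h_pedigree)
        add("germplasm/{germplasmDbId}/progeny", "GET", "Germplasm", self._h_progeny)
        add("germplasm/{germplasmDbId}/markerprofiles", "GET", "Germplasm", self._h_germplasm_profiles)
        add("germplasm/{germplasmDbId}/mcpd", "GET", "Germplasm", detail("germplasm", "germplasmDbId"))
        # Germplasm Attributes ----------------------------------------------
        add("attributes", "GET", "Germplasm Attributes", listing("attribute"))
        add("attributes/categories", "GET", "Germplasm Attributes", listing("attribute_category"))
        add("germplasm/{germplasmDbId}/attributes", "GET", "Germplasm Attributes", self._h_germplasm_attributes)
        # Markers -----------------------------------------------------------
        add("markers-search", "GET", "Markers", listing("marker"))
        add("markers-search", "POST", "Markers", listing("marker"))
        add("markers/{markerDbId}", "GET", "Markers", detail("marker", "markerDbId"))
        # Marker Profiles ---------------------------------------------------
        add("markerprofiles", "GET", "Marker Profiles", listing("marker_profile"))
        add("markerprofiles/{markerProfileDbId}", "GET", "Marker Profiles", self._h_markerprofile_detail)
        add("allelematrices", "GET", "Marker Profiles", listing("allele_matrix"))
        add("allelematrix-search", "GET", "Marker Profiles", self._h_allelematrix_search)
        add("allelematrix-search", "POST", "Marker Profiles", self._h_allelematrix_search)
        # Programs ----------------------------------------------------------
        add("programs", "GET", "Programs", listing("program"))
        add("programs-search", "POST", "Programs", listing("program"))
        # Trials ------------------------------------------------------------
        add("trials", "GET", "Trials", listing("trial"))
        add("trials/{trialDbId}", "GET", "Trials", detail("trial", "trialDbId"))
        # Studies -----------------------------------------------------------
        add("studies-search", "GET", "Studies", listing("study"))
        add("studies-search", "POST", "Studies", listing("study"))
        add("studies/{studyDbId}", "GET", "Studies", detail("study", "studyDbId"))
        add("studies/{studyDbId}/germplasm", "GET", "Studies", self._h_study_germplasm)
        add("studies/{studyDbId}/observationvariables", "GET", "Studies", self._h_study_variables)
        add("studies/{studyDbId}/observationunits", "GET", "Studies", self._h_study_units)
        add("studies/{studyDbId}/observationunits", "POST", "Studies", self._h_study_observations_write)
        add("studies/{studyDbId}/observationunits", "PUT", "Studies", self._h_study_observations_write)
        add("studies/{studyDbId}/table", "GET", "Studies", self._h_study_table)
        add("studies/{studyDbId}/layout", "GET", "Studies", self._h_study_layout)
        add("studies/{studyDbId}/layout", "PUT", "Studies", self._h_study_layout_put)
        add("studies/{studyDbId}/observations", "GET", "Studies", self._h_study_observations)
        add("studies/{studyDbId}/observations", "PUT", "Studies", self._h_study_observations_write)
        add("seasons", "GET", "Studies", listing("season"))
        add("studytypes", "GET", "Studies", listing("study_type"))
        add("observationlevels", "GET", "Studies", self._h_observation_levels)
        add("studies/{studyDbId}/observationunits/table", "GET", "Studies", self._h_study_units_table)
        # Phenotypes --------------------------------------------------------
        add("phenotypes-search", "POST", "Phenotypes", self._h_phenotypes_search)
        add("phenotypes-search", "GET", "Phenotypes", self._h_phenotypes_search)
        add("phenotypes-search/table", "POST", "Phenotypes", self._h_phenotypes_table)
        add("phenotypes-search/tsv", "POST", "Phenotypes", self._h_phenotypes_tsv)
        add("phenotypes-search/csv", "POST", "Phenotypes", self._h_phenotypes_csv)
        # Traits ------------------------------------------------------------
        add("traits", "GET", "Traits", listing("trait"))
        add("traits/{traitDbId}", "GET", "Traits", detail("trait", "traitDbId"))
        # Observation Variables ---------------------------------------------
        add("variables", "GET", "Observation Variables", listing("observation_variable"))
        # the literal path must precede the placeholder route: first match wins
        add("variables/datatypes", "GET", "Observation Variables", self._h_variable_datatypes)
        add("variables/{observationVariableDbId}", "GET", "Observation Variables",
            detail("observation_variable", "observationVariableDbId"))
        add("variables-search", "POST", "Observation Variables", listing("observation_variable"))
        add("ontologies", "GET", "Observation Variables", listing("ontology"))
        # Genome Maps -------------------------------------------------------
        add("maps", "GET", "Genome Maps", listing("genome_map"))
        add("maps/{mapDbId}", "GET", "Genome Maps", detail("genome_map", "mapDbId"))
        add("maps/{mapDbId}/positions", "GET", "Genome Maps", self._h_map_positions)
        add("maps/{mapDbId}/positions/{linkageGroupId}", "GET", "Genome Maps", self._h_map_positions)
        # Location ----------------------------------------------------------
        add("locations", "GET", "Location", listing("location"))
        add("locations/{locationDbId}", "GET", "Location", detail("location", "locationDbId"))
        # Samples -----------------------------------------------------------
        add("samples-search", "GET", "Samples", listing("sample"))
        add("samples-search", "POST", "Samples", listing("sample"))
        add("samples/{sampleDbId}", "GET", "Samples", detail("sample", "sampleDbId"))
        add("samples", "PUT", "Samples", self._h_sample_put)
        # Vendor Samples ----------------------------------------------------
        add("vendor/plates", "POST", "Vendor Samples", self._h_vendor_plates_post)
        add("vendor/plates/{plateDbId}", "GET", "Vendor Samples", detail("vendor_plate", "plateDbId"))
        add("vendor/orders", "GET", "Vendor Samples", listing("vendor_order"))
        add("vendor/orders/{orderDbId}/status", "GET", "Vendor Samples", self._h_vendor_order_status)
        add("vendor/orders/{orderDbId}/results", "GET", "Vendor Samples", self._h_vendor_order_results)

        # route templates must be unique per method
        seen = set()
        for route in routes:
            key = (route.path, route.method)
            if key in seen:
                raise ConfigurationError(f"duplicate route {key}")
            seen.add(key)
        return routes

    def call_descriptors(self) -> list[dict]:
        """One descriptor per (path, method) pair, mirroring the roster."""
        out = []
        for route in self.routes:
            datatypes = [JSON_TYPE]
            if route.path.endswith("/tsv"):
                datatypes.append(TSV_TYPE)
            if route.path.endswith("/csv"):
                datatypes.append(CSV_TYPE)
            out.append(
                {
                    "call": route.path,
                    "category": route.category,
                    "methods": [route.method],
                    "datatypes": datatypes,
                    "versions": list(route.versions),
                }
            )
        return out

    # --------------------------------------------------------- call handlers
    def _h_calls(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        descriptors = self.call_descriptors()
        wanted = request.query.get("dataType", [None])[0]
        if wanted is not None:
            known = {JSON_TYPE, TSV_TYPE, CSV_TYPE}
            if wanted not in known:
                raise InvalidParameterError(f"unknown dataType {wanted!r}; known: {sorted(known)}")
            descriptors = [d for d in descriptors if wanted in d["datatypes"]]
        return self._list_envelope(request, descriptors)

    def _h_crops(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        return self._list_envelope(request, list(self.store.crops))

    def _h_pedigree(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        record = self._detail_record("germplasm", params["germplasmDbId"])
        p1, p2 = self.store.parents.get(params["germplasmDbId"], (None, None))
        return self._master_envelope(
            {
                "germplasmDbId": record["germplasmDbId"],
                "pedigree": record["pedigree"],
                "parent1DbId": p1,
                "parent2DbId": p2,
            }
        )

    def _h_progeny(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        record = self._detail_record("germplasm", params["germplasmDbId"])
        wanted = params["germplasmDbId"]
        children = []
        for child_id, (p1, p2) in self.store.parents.items():
            if wanted == p1:
                children.append({"germplasmDbId": child_id, "parentType": "FEMALE"})
            elif wanted == p2:
                children.append({"germplasmDbId": child_id, "parentType": "MALE"})
        return self._list_envelope(
            request, children, master={"germplasmDbId": record["germplasmDbId"]}
        )

    def _h_germplasm_profiles(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        self._detail_record("germplasm", params["germplasmDbId"])
        profiles = search(self.store, "marker_profile", {"germplasmDbId": params["germplasmDbId"]})
        return self._list_envelope(request, profiles)

    def _h_germplasm_attributes(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        record = self._detail_record("germplasm", params["germplasmDbId"])
        values = [
            {"attributeDbId": row["attributeDbId"], "value": row["value"]}
            for row in self.store.all("attribute_value")
            if row["germplasmDbId"] == params["germplasmDbId"]
        ]
        return self._list_envelope(
            request, values, master={"germplasmDbId": record["germplasmDbId"]}
        )

    def _h_markerprofile_detail(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        record = self._detail_record("marker_profile", params["markerProfileDbId"])
        calls = [
            {"markerDbId": row["markerDbId"], "alleleCall": row["alleleCall"]}
            for row in self.store.all("allele_call")
            if row["markerProfileDbId"] == params["markerProfileDbId"]
        ]
        return self._list_envelope(request, calls, master=record)

    def _h_allelematrix_search(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        filters = self._filters(request)
        allowed = {"markerDbId", "markerProfileDbId", "matrixDbId"}
        unknown = set(filters) - allowed
        if unknown:
            raise InvalidParameterError(f"unknown filter fields {sorted(unknown)}")
        filters.pop("matrixDbId", None)  # single fixture matrix holds all calls
        rows = search(self.store, "allele_call", filters)
        fmt = request.query.get("format", [None])[0]
        if isinstance(request.body, dict):
            fmt = request.body.get("format", fmt)
        table = [[r["markerDbId"], r["markerProfileDbId"], r["alleleCall"]] for r in rows]
        threshold = 0 if fmt == "tsv" else None
        inline, datafiles = self.emit_datafile(
            request, "allelematrix", ["markerDbId", "markerProfileDbId", "alleleCall"],
            table, threshold=threshold,
        )
        if inline is None:
            return self._list_envelope(request, [], datafiles=datafiles)
        return self._list_envelope(request, rows)

    def _study_units(self, study_id: str) -> list[dict]:
        return search(self.store, "observation_unit", {"studyDbId": study_id})

    def _h_study_germplasm(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        self._detail_record("study", params["studyDbId"])
        seen: list[dict] = []
        ids = set()
        for unit in self._study_units(params["studyDbId"]):
            if unit["germplasmDbId"] not in ids:
                ids.add(unit["germplasmDbId"])
                seen.append(self.store.get("germplasm", unit["germplasmDbId"]))
        return self._list_envelope(request, seen)

    def _study_observations_list(self, study_id: str) -> list[dict]:
        unit_ids = {u["observationUnitDbId"] for u in self._study_units(study_id)}
        return [
            o for o in self.store.all("observation") if o["observationUnitDbId"] in unit_ids
        ]

    def _h_study_variables(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        self._detail_record("study", params["studyDbId"])
        observed = []
        ids = set()
        for obs in self._study_observations_list(params["studyDbId"]):
            if obs["observationVariableDbId"] not in ids:
                ids.add(obs["observationVariableDbId"])
                observed.append(self.store.get("observation_variable", obs["observationVariableDbId"]))
        return self._list_envelope(request, observed)

    def _h_study_units(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        self._detail_record("study", params["studyDbId"])
        return self._list_envelope(request, self._study_units(params["studyDbId"]))

    def _h_study_observations(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        self._detail_record("study", params["studyDbId"])
        return self._list_envelope(request, self._study_observations_list(params["studyDbId"]))

    def _h_study_observations_write(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        """POST creates observations; PUT upserts by observationDbId.

        Mutations touch only the in-memory store and are lost on restart.
        """
        self._detail_record("study", params["studyDbId"])
        body = request.body if isinstance(request.body, dict) else {}
        entries = body.get("observations")
        if not isinstance(entries, list):
            raise InvalidParameterError("body must carry an 'observations' list")
        unit_ids = {u["observationUnitDbId"] for u in self._study_units(params["studyDbId"])}
        affected = []
        for entry in entries:
            if not isinstance(entry, dict):
                raise InvalidParameterError("each observation must be an object")
            unit_id = entry.get("observationUnitDbId")
            if unit_id not in unit_ids:
                raise InvalidParameterError(
                    f"observationUnitDbId {unit_id!r} is not a unit of study {params['studyDbId']!r}"
                )
            variable_id = entry.get("observationVariableDbId")
            if self.store.get("observation_variable", variable_id) is None:
                raise InvalidParameterError(f"unknown observationVariableDbId {variable_id!r}")
            existing = (
                self.store.get("observation", entry.get("observationDbId"))
                if entry.get("observationDbId")
                else None
            )
            if existing is not None:
                existing["value"] = str(entry.get("value"))
                if entry.get("observationTimeStamp"):
                    existing["observationTimeStamp"] = entry["observationTimeStamp"]
                affected.append(existing)
            else:
                record = self.store.add(
                    "observation",
                    {
                        "observationDbId": self.store.next_id("observation"),
                        "observationUnitDbId": unit_id,
                        "observationVariableDbId": variable_id,
                        "value": str(entry.get("value")),
                        "observationTimeStamp": entry.get("observationTimeStamp"),
                    },
                )
                affected.append(record)
        return self._list_envelope(request, affected)

    def _study_table(self, study_id: str) -> tuple[list[str], list[str], list[list]]:
        units = self._study_units(study_id)
        observations = self._study_observations_list(study_id)
        variable_ids = sorted({o["observationVariableDbId"] for o in observations}, key=int)
        values: dict[tuple[str, str], str] = {
            (o["observationUnitDbId"], o["observationVariableDbId"]): o["value"]
            for o in observations
        }
        header = ["observationUnitDbId", "germplasmDbId", "replicate", "blockNumber"]
        rows = []
        for unit in units:
            row: list = [
                unit["observationUnitDbId"],
                unit["germplasmDbId"],
                unit["replicate"],
                unit["blockNumber"],
            ]
            row.extend(values.get((unit["observationUnitDbId"], v)) for v in variable_ids)
            rows.append(row)
        return header, variable_ids, rows

    def _h_study_table(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        self._detail_record("study", params["studyDbId"])
        header, variable_ids, rows = self._study_table(params["studyDbId"])
        return self._list_envelope(
            request,
            rows,
            master={
                "studyDbId": params["studyDbId"],
                "headerRow": header,
                "observationVariableDbIds": variable_ids,
            },
        )

    def _h_study_units_table(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        self._detail_record("study", params["studyDbId"])
        header, variable_ids, rows = self._study_table(params["studyDbId"])
        records = [dict(zip(header + variable_ids, row)) for row in rows]
        return self._list_envelope(request, records)

    def _h_study_layout(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        self._detail_record("study", params["studyDbId"])
        layout = [
            {
                "observationUnitDbId": u["observationUnitDbId"],
                "germplasmDbId": u["germplasmDbId"],
                "replicate": u["replicate"],
                "blockNumber": u["blockNumber"],
                "positionCoordinateX": u["positionCoordinateX"],
                "positionCoordinateY": u["positionCoordinateY"],
            }
            for u in self._study_units(params["studyDbId"])
        ]
        return self._list_envelope(request, layout)

    def _h_study_layout_put(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        self._detail_record("study", params["studyDbId"])
        body = request.body if isinstance(request.body, dict) else {}
        entries = body.get("layout")
        if not isinstance(entries, list):
            raise InvalidParameterError("body must carry a 'layout' list")
        units = {u["observationUnitDbId"]: u for u in self._study_units(params["studyDbId"])}
        for entry in entries:
            unit = units.get(entry.get("observationUnitDbId")) if isinstance(entry, dict) else None
            if unit is None:
                raise InvalidParameterError(
                    f"unknown observationUnitDbId {entry.get('observationUnitDbId')!r} in layout"
                )
            for key in ("positionCoordinateX", "positionCoordinateY", "replicate", "blockNumber"):
                if key in entry:
                    unit[key] = entry[key]
        return self._h_study_layout(request, params)

    def _h_observation_levels(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        return self._list_envelope(request, list(self.store.observation_levels))

    def _phenotype_records(self, filters: Mapping[str, Any]) -> list[dict]:
        allowed = {"germplasmDbId", "studyDbId", "observationVariableDbId"}
        unknown = set(filters) - allowed
        if unknown:
            raise InvalidParameterError(f"unknown filter fields {sorted(unknown)}")
        records = []
        for unit in self.store.all("observation_unit"):
            if filters.get("germplasmDbId") not in (None, unit["germplasmDbId"]):
                continue
            if filters.get("studyDbId") not in (None, unit["studyDbId"]):
                continue
            observations = [
                {
                    "observationDbId": o["observationDbId"],
                    "observationVariableDbId": o["observationVariableDbId"],
                    "value": o["value"],
                    "observationTimeStamp": o["observationTimeStamp"],
                }
                for o in self.store.all("observation")
                if o["observationUnitDbId"] == unit["observationUnitDbId"]
                and filters.get("observationVariableDbId")
                in (None, o["observationVariableDbId"])
            ]
            if filters.get("observationVariableDbId") is not None and not observations:
                continue
            record = dict(unit)
            record["observations"] = observations
            records.append(record)
        return records

    def _h_phenotypes_search(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        return self._list_envelope(request, self._phenotype_records(self._filters(request)))

    def _phenotype_table(self, filters: Mapping[str, Any]) -> tuple[list[str], list[str], list[list]]:
        records = self._phenotype_records(filters)
        variable_ids = sorted(
            {o["observationVariableDbId"] for r in records for o in r["observations"]},
            key=int,
        )
        header = ["observationUnitDbId", "studyDbId", "germplasmDbId"]
        rows = []
        for record in records:
            values = {o["observationVariableDbId"]: o["value"] for o in record["observations"]}
            row: list = [record["observationUnitDbId"], record["studyDbId"], record["germplasmDbId"]]
            row.extend(values.get(v) for v in variable_ids)
            rows.append(row)
        return header, variable_ids, rows

    def _h_phenotypes_table(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        header, variable_ids, rows = self._phenotype_table(self._filters(request))
        return self._list_envelope(
            request,
            rows,
            master={"headerRow": header, "observationVariableDbIds": variable_ids},
        )

    def _phenotypes_export(
        self, request: Request, sep: str, name: str
    ) -> tuple[int, ResponseEnvelope]:
        header, variable_ids, rows = self._phenotype_table(self._filters(request))
        _, datafiles = self.emit_datafile(
            request, name, header + variable_ids, rows, threshold=0, sep=sep
        )
        return 200, make_envelope({}, ALL_ZERO_PAGINATION, datafiles=datafiles)

    def _h_phenotypes_tsv(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        return self._phenotypes_export(request, "\t", "phenotypes")

    def _h_phenotypes_csv(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        return self._phenotypes_export(request, ",", "phenotypes")

    def _h_variable_datatypes(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        seen: list[str] = []
        for variable in self.store.all("observation_variable"):
            dt = variable["scale"]["dataType"]
            if dt not in seen:
                seen.append(dt)
        return self._list_envelope(request, seen)

    def _h_map_positions(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        self._detail_record("genome_map", params["mapDbId"])
        rows = [
            {k: v for k, v in row.items() if k != "mapDbId"}
            for row in self.store.all("map_position")
            if row["mapDbId"] == params["mapDbId"]
        ]
        group = params.get("linkageGroupId")
        if group is not None:
            rows = [r for r in rows if r["linkageGroupName"] == group]
            if not rows:
                raise _HandlerError(404, f"no positions for linkage group {group!r}")
        return self._list_envelope(request, rows)

    def _h_sample_put(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        body = request.body if isinstance(request.body, dict) else {}
        unit = self.store.get("observation_unit", body.get("observationUnitDbId"))
        if unit is None:
            raise InvalidParameterError(
                f"unknown observationUnitDbId {body.get('observationUnitDbId')!r}"
            )
        sample_id = body.get("sampleDbId") or self.store.next_id("sample")
        record = self.store.get("sample", sample_id)
        fields = {
            "sampleDbId": sample_id,
            "germplasmDbId": unit["germplasmDbId"],
            "observationUnitDbId": unit["observationUnitDbId"],
            "plateName": body.get("plateName"),
            "well": body.get("well"),
            "takenBy": body.get("takenBy"),
            "sampleTimestamp": body.get("sampleTimestamp"),
        }
        if record is None:
            record = self.store.add("sample", fields)
        else:
            record.update(fields)
        return self._master_envelope(record)

    def _h_vendor_plates_post(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        body = request.body if isinstance(request.body, dict) else {}
        plates = body.get("plates")
        if not isinstance(plates, list) or not plates:
            raise InvalidParameterError("body must carry a non-empty 'plates' list")
        plate_ids = []
        for entry in plates:
            if not isinstance(entry, dict):
                raise InvalidParameterError("each plate must be an object")
            sample_ids = entry.get("sampleDbIds", [])
            for sample_id in sample_ids:
                if self.store.get("sample", sample_id) is None:
                    raise InvalidParameterError(f"unknown sampleDbId {sample_id!r}")
            record = self.store.add(
                "vendor_plate",
                {
                    "plateDbId": self.store.next_id("vendor_plate"),
                    "plateName": entry.get("plateName"),
                    "sampleDbIds": list(sample_ids),
                },
            )
            plate_ids.append(record["plateDbId"])
        order = self.store.add(
            "vendor_order",
            {
                "orderDbId": self.store.next_id("vendor_order"),
                "clientId": body.get("clientId"),
                "plates": plate_ids,
                "status": "registered",
                "results": [],
            },
        )
        return self._master_envelope({"orderDbId": order["orderDbId"]})

    def _h_vendor_order_status(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        record = self._detail_record("vendor_order", params["orderDbId"])
        return self._master_envelope({"orderDbId": record["orderDbId"], "status": record["status"]})

    def _h_vendor_order_results(self, request: Request, params: dict) -> tuple[int, ResponseEnvelope]:
        record = self._detail_record("vendor_order", params["orderDbId"])
        return self._list_envelope(request, list(record["results"]))


def serve_forever(server: ReferenceServer, port: int = 8080):  # pragma: no cover
    """Serve over real HTTP with the stdlib WSGI server (blocks)."""
    from wsgiref.simple_server import make_server

    httpd = make_server("", port, server)
    httpd.serve_forever()
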