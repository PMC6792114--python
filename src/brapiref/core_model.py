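"""The BrAPI v1 wire contract: response envelope, result patterns, entities.

Every call in the standard answers with the same JSON envelope::

    {"metadata": {"pagination": {...}, "status": [...], "datafiles": [...]},
     "result": {...}}

The ``result`` payload follows exactly one of three patterns:

master
    a flat record for a single entity (no ``data`` key);
details
    a single ``data`` array of records and nothing else;
master/details
    parent-entity fields plus a ``data`` array of children.

Whenever a ``data`` array is present the response is paginated and the
array's length is bounded by ``metadata.pagination.pageSize``.  Single-entity
responses carry the all-zero pagination block.

This module defines the envelope types, builds and classifies results, and
validates arbitrary parsed JSON documents against the contract and against
the shipped per-entity schemas.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Optional, Sequence

from .errors import ContractViolationError, MalformedResultError
from .schema import Violation, check, load_schema

__all__ = [
    "Pagination",
    "Status",
    "Metadata",
    "ResponseEnvelope",
    "PATTERN_MASTER",
    "PATTERN_DETAILS",
    "PATTERN_MASTER_DETAILS",
    "ENTITY_KINDS",
    "make_envelope",
    "classify_result_pattern",
    "validate_envelope",
]

PATTERN_MASTER = "master"
PATTERN_DETAILS = "details"
PATTERN_MASTER_DETAILS = "master_details"

#: entity kind -> (schema file, primary identifier field)
ENTITY_KINDS: dict[str, tuple[str, str]] = {
    "germplasm": ("germplasm", "germplasmDbId"),
    "program": ("program", "programDbId"),
    "trial": ("trial", "trialDbId"),
    "study": ("study", "studyDbId"),
    "location": ("location", "locationDbId"),
    "observation_variable": ("observation_variable", "observationVariableDbId"),
    "trait": ("trait", "traitDbId"),
    "observation_unit": ("observation_unit", "observationUnitDbId"),
    "observation": ("observation", "observationDbId"),
    "marker": ("marker", "markerDbId"),
    "marker_profile": ("marker_profile", "markerProfileDbId"),
    "allele_call": ("allele_call", "markerDbId"),
    "allele_matrix": ("allele_matrix", "matrixDbId"),
    "genome_map": ("genome_map", "mapDbId"),
    "map_position": ("map_position", "markerDbId"),
    "sample": ("sample", "sampleDbId"),
    "vendor_order": ("vendor_order", "orderDbId"),
    "vendor_plate": ("vendor_plate", "plateDbId"),
    "attribute": ("attribute", "attributeDbId"),
    "attribute_category": ("attribute_category", "attributeCategoryDbId"),
    "ontology": ("ontology", "ontologyDbId"),
    "season": ("season", "seasonDbId"),
    "study_type": ("study_type", "studyTypeDbId"),
    "call_descriptor": ("call_descriptor", "call"),
}


@dataclass(frozen=True)
class Pagination:
    """The four-field block that governs every ``data`` array.

    Pages are zero-indexed: the first page is page zero.  ``total_pages``
    is the ceiling of ``total_count / page_size`` whenever ``page_size`` is
    positive.  Single-entity responses use the all-zero block.
    """

    page_size: int = 0
    current_page: int = 0
    total_count: int = 0
    total_pages: int = 0

    def __post_init__(self) -> None:
        for name in ("page_size", "current_page", "total_count", "total_pages"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise ContractViolationError(f"{name} must be a non-negative integer, got {v!r}")

    def to_json(self) -> dict:
        return {
            "pageSize": self.page_size,
            "currentPage": self.current_page,
            "totalCount": self.total_count,
            "totalPages": self.total_pages,
        }

    @classmethod
    def from_json(cls, doc: Mapping[str, int]) -> "Pagination":
        return cls(doc["pageSize"], doc["currentPage"], doc["totalCount"], doc["totalPages"])

    @property
    def is_all_zero(self) -> bool:
        return (self.page_size, self.current_page, self.total_count, self.total_pages) == (0, 0, 0, 0)


#: the block single-entity responses must carry
ALL_ZERO_PAGINATION = Pagination(0, 0, 0, 0)


@dataclass(frozen=True)
class Status:
    """One status/log entry: a short machine ``code`` plus a human ``message``."""

    code: str
    message: str

    def __post_init__(self) -> None:
        if self.code is None or self.message is None:
            raise ContractViolationError("status code and message must be non-null")

    def to_json(self) -> dict:
        return {"code": self.code, "message": self.message}


@dataclass(frozen=True)
class Metadata:
    pagination: Pagination = ALL_ZERO_PAGINATION
    status: tuple[Status, ...] = ()
    datafiles: tuple[str, ...] = ()

    def to_json(self) -> dict:
        return {
            "pagination": self.pagination.to_json(),
            "status": [s.to_json() for s in self.status],
            "datafiles": list(self.datafiles),
        }


@dataclass(frozen=True)
class ResponseEnvelope:
    """The top-level wire object: exactly ``metadata`` and ``result``.

    ``result`` is ``None`` only on error responses.
    """

    metadata: Metadata
    result: Optional[dict]

    def to_json(self) -> dict:
        return {"metadata": self.metadata.to_json(), "result": self.result}

    def serialize(self) -> str:
        return json.dumps(self.to_json(), ensure_ascii=False)


def classify_result_pattern(result: Mapping[str, Any]) -> str:
    """Assign a well-formed result to exactly one of the three patterns.

    details iff the only key is ``data``; master/details iff ``data`` plus
    other keys; master otherwise.  A ``data`` key holding anything but a
    list is malformed.
    """
    if not isinstance(result, Mapping):
        raise MalformedResultError(f"result must be an object, got {type(result).__name__}")
    if "data" in result:
        if not isinstance(result["data"], list):
            raise MalformedResultError("result key 'data' must be a list")
        return PATTERN_DETAILS if set(result) == {"data"} else PATTERN_MASTER_DETAILS
    return PATTERN_MASTER


def make_envelope(
    result: Optional[Mapping[str, Any]],
    pagination: Pagination = ALL_ZERO_PAGINATION,
    status: Iterable[Status] = (),
    datafiles: Iterable[str] = (),
) -> ResponseEnvelope:
    """Assemble a contract-consistent envelope around *result*.

    Raises :class:`ContractViolationError` when a present ``data`` array is
    longer than ``pagination.page_size`` — the pagination block must always
    bound the payload it describes.
    """
    if result is not None:
        pattern = classify_result_pattern(result)
        if pattern in (PATTERN_DETAILS, PATTERN_MASTER_DETAILS):
            n = len(result["data"])
            if n > pagination.page_size:
                raise ContractViolationError(
                    f"data array length {n} exceeds pageSize {pagination.page_size}"
                )
        result = dict(result)
    return ResponseEnvelope(
        metadata=Metadata(
            pagination=pagination,
            status=tuple(status),
            datafiles=tuple(datafiles),
        ),
        result=result,
    )


def _check_pagination_arithmetic(pag: Mapping[str, Any], path: str) -> list[Violation]:
    out: list[Violation] = []
    keys = ("pageSize", "currentPage", "totalCount", "totalPages")
    if not all(isinstance(pag.get(k), int) and not isinstance(pag.get(k), bool) for k in keys):
        return out  # typing already reported by the schema pass
    page_size, current, total, pages = (pag[k] for k in keys)
    if page_size > 0:
        expect = math.ceil(total / page_size)
        if pages != expect:
            out.append(
                Violation(
                    f"{path}.totalPages",
                    "pagination_arithmetic",
                    f"totalPages is {pages} but ceiling({total}/{page_size}) is {expect}",
                )
            )
    return out


def validate_envelope(
    document: Any,
    expected_entity: Optional[str] = None,
    expected_pattern: Optional[str] = None,
) -> list[Violation]:
    """Check a parsed JSON value against the envelope contract.

    Returns the full list of violations in document order; an empty list
    means the document is a valid envelope.  ``expected_entity`` (a key of
    :data:`ENTITY_KINDS`) additionally validates the entity payload —
    ``data`` records for list responses, the master fields otherwise —
    against the shipped schema.  ``expected_pattern`` additionally requires
    the result to follow that specific pattern.
    """
    out = check(document, load_schema("envelope"))
    if out and any(v.code == "wrong_type" and v.path == "$" for v in out):
        return out

    meta = document.get("metadata")
    if isinstance(meta, dict) and isinstance(meta.get("pagination"), dict):
        out.extend(_check_pagination_arithmetic(meta["pagination"], "$.metadata.pagination"))

    result = document.get("result") if isinstance(document, dict) else None
    # a page at/after the end is legal only for a legitimately empty slice
    # (servers answer out-of-range page requests with truthful totals); a
    # populated data array on such a page is impossible
    if isinstance(meta, dict) and isinstance(meta.get("pagination"), dict):
        pag = meta["pagination"]
        pages, current = pag.get("totalPages"), pag.get("currentPage")
        if (
            isinstance(pages, int) and isinstance(current, int)
            and not isinstance(pages, bool) and not isinstance(current, bool)
            and pages > 0 and current >= pages
        ):
            data = result.get("data") if isinstance(result, dict) else None
            if not isinstance(data, list) or data:
                out.append(
                    Violation(
                        "$.metadata.pagination.currentPage",
                        "page_out_of_range",
                        f"currentPage {current} not below totalPages {pages}",
                    )
                )
    pattern: Optional[str] = None
    if isinstance(result, dict):
        if "data" in result and not isinstance(result["data"], list):
            out.append(Violation("$.result.data", "wrong_type", "'data' must be an array"))
        else:
            pattern = classify_result_pattern(result)

    if expected_pattern is not None and pattern != expected_pattern:
        out.append(
            Violation(
                "$.result",
                "wrong_pattern",
                f"expected {expected_pattern} pattern, found {pattern or 'null result'}",
            )
        )

    # data length must respect the advertised page size
    if (
        pattern in (PATTERN_DETAILS, PATTERN_MASTER_DETAILS)
        and isinstance(meta, dict)
        and isinstance(meta.get("pagination"), dict)
    ):
        page_size = meta["pagination"].get("pageSize")
        if isinstance(page_size, int) and not isinstance(page_size, bool):
            n = len(result["data"])
            if n > page_size:
                out.append(
                    Violation(
                        "$.result.data",
                        "data_exceeds_page",
                        f"data has {n} records but pageSize is {page_size}",
                    )
                )

    if expected_entity is not None:
        schema_name, _ = ENTITY_KINDS[expected_entity]
        entity_schema = load_schema(schema_name)
        if pattern in (PATTERN_DETAILS, PATTERN_MASTER_DETAILS):
            for i, record in enumerate(result["data"]):
                out.extend(check(record, entity_schema, f"$.result.data[{i}]"))
        elif pattern == PATTERN_MASTER:
            out.extend(check(result, entity_schema, "$.result"))

    # deterministic ordering: sort by first appearance is already guaranteed
    # by construction (single left-to-right traversal per pass); passes are
    # appended in a fixed order.
    return out
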