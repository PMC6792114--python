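"""A small structural checker for the JSON Schema dialect shipped in-repo.

The schema files under :mod:`brapiref.schemas` use a deliberately narrow
subset of JSON Schema keywords — ``type``, ``properties``, ``required``,
``additionalProperties``, ``items``, ``enum`` and ``minimum`` — which is all
the wire contract needs: key presence, key absence and primitive types.
This module evaluates that subset and reports every violation in document
order, so two runs over the same document always produce the same list.

Violations are data, not exceptions: a well-formed check of a broken
document returns a non-empty list and never raises.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Any

__all__ = ["Violation", "check", "load_schema", "available_schemas"]


@dataclass(frozen=True)
class Violation:
    """One structural defect found in a document.

    path    JSON-pointer-like location, e.g. ``$.metadata.pagination``
    code    short machine token (``missing_key``, ``wrong_type`` ...)
    message human-readable explanation
    """

    path: str
    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.path}: [{self.code}] {self.message}"


# JSON type name -> python predicate.  bool is deliberately excluded from
# integer/number: JSON booleans are not numbers even though Python's bool
# subclasses int.
def _is_type(value: Any, name: str) -> bool:
    if name == "object":
        return isinstance(value, dict)
    if name == "array":
        return isinstance(value, list)
    if name == "string":
        return isinstance(value, str)
    if name == "integer":
        return isinstance(value, int) and not isinstance(value, bool)
    if name == "number":
        return isinstance(value, (int, float)) and not isinstance(value, bool)
    if name == "boolean":
        return isinstance(value, bool)
    if name == "null":
        return value is None
    raise ValueError(f"unknown schema type {name!r}")


def _type_name(value: Any) -> str:
    if isinstance(value, bool):
        return "boolean"
    if isinstance(value, dict):
        return "object"
    if isinstance(value, list):
        return "array"
    if isinstance(value, str):
        return "string"
    if isinstance(value, int):
        return "integer"
    if isinstance(value, float):
        return "number"
    if value is None:
        return "null"
    return type(value).__name__


def check(instance: Any, schema: dict, path: str = "$") -> list[Violation]:
    """Evaluate *schema* against *instance*, returning violations in
    document order (an empty list means the instance conforms)."""
    out: list[Violation] = []

    allowed = schema.get("type")
    if allowed is not None:
        names = [allowed] if isinstance(allowed, str) else list(allowed)
        if not any(_is_type(instance, n) for n in names):
            out.append(
                Violation(
                    path,
                    "wrong_type",
                    f"expected {' or '.join(names)}, got {_type_name(instance)}",
                )
            )
            return out  # child keywords are meaningless on the wrong type

    if "enum" in schema and instance not in schema["enum"]:
        out.append(
            Violation(path, "not_in_enum", f"{instance!r} not one of {schema['enum']!r}")
        )

    if isinstance(instance, (int, float)) and not isinstance(instance, bool):
        minimum = schema.get("minimum")
        if minimum is not None and instance < minimum:
            out.append(
                Violation(path, "below_minimum", f"{instance} < minimum {minimum}")
            )

    if isinstance(instance, dict):
        props = schema.get("properties", {})
        for key in schema.get("required", []):
            if key not in instance:
                out.append(Violation(path, "missing_key", f"required key {key!r} absent"))
        for key, value in instance.items():
            if key in props:
                out.extend(check(value, props[key], f"{path}.{key}"))
            elif schema.get("additionalProperties") is False:
                out.append(
                    Violation(f"{path}.{key}", "unexpected_key", f"key {key!r} not allowed")
                )

    if isinstance(instance, list) and "items" in schema:
        for i, item in enumerate(instance):
            out.extend(check(item, schema["items"], f"{path}[{i}]"))

    return out


_SCHEMA_CACHE: dict[str, dict] = {}


def load_schema(name: str) -> dict:
    """Load a shipped schema file (``name`` without the ``.json`` suffix)."""
    if name not in _SCHEMA_CACHE:
        ref = resources.files("brapiref.schemas").joinpath(name + ".json")
        _SCHEMA_CACHE[name] = json.loads(ref.read_text(encoding="utf-8"))
    return _SCHEMA_CACHE[name]


def available_schemas() -> list[str]:
    """Names of all shipped schema files."""
    out = []
    for entry in resources.files("brapiref.schemas").iterdir():
        if entry.name.endswith(".json"):
            out.append(entry.name[: -len(".json")])
    return sorted(out)
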