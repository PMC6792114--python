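"""Deterministic synthetic breeding dataset backing the reference server.

The generator fabricates a small but referentially closed world: breeding
programs containing trials containing studies at named locations; germplasm
accessions with MCPD-style passport fields and pedigree links; observation
variables as trait/method/scale triples; field observations on plot-level
observation units; a marker panel with per-germplasm marker profiles and an
allele matrix; a genetic map; samples on plates and vendor orders.

The data are completely fabricated and structural, not biological: names
come from fixed word lists shipped in this module and every random draw
flows through one seeded generator, so the same configuration always
produces a byte-identical store on every platform.  Identifiers are small
decimal strings ("1", "2", ...) per entity kind, so the dataset always
contains a germplasm record with ``germplasmDbId`` "1".
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Optional

from .core_model import ENTITY_KINDS
from .errors import ConfigurationError, InvalidParameterError
from .schema import load_schema

__all__ = ["FixtureConfig", "Store", "generate_fixture", "get_by_id", "search"]

# ---------------------------------------------------------------------------
# word lists (fixed, in-repo: reproducible across platforms)

CROP_TAXA = {
    "maize": ("Zea", "mays"),
    "cassava": ("Manihot", "esculenta"),
    "wheat": ("Triticum", "aestivum"),
    "rice": ("Oryza", "sativa"),
    "banana": ("Musa", "acuminata"),
    "potato": ("Solanum", "tuberosum"),
    "sorghum": ("Sorghum", "bicolor"),
    "yam": ("Dioscorea", "rotundata"),
}

_SITES = [
    ("Ithaca", "US", 42.44, -76.50),
    ("Los Banos", "PH", 14.17, 121.24),
    ("Ibadan", "NG", 7.38, 3.90),
    ("Texcoco", "MX", 19.53, -98.85),
    ("Lima", "PE", -12.05, -77.04),
    ("Montpellier", "FR", 43.61, 3.88),
    ("Gatersleben", "DE", 51.82, 11.28),
    ("Hyderabad", "IN", 17.39, 78.49),
    ("Dundee", "GB", 56.46, -2.97),
    ("Palmira", "CO", 3.54, -76.30),
]

_INSTITUTES = ["COR001", "CIM002", "IRR003", "CIP004", "IIT005", "ICR006", "JHI007", "IPK008"]
_COUNTRIES = ["US", "MX", "PH", "NG", "PE", "FR", "DE", "IN", "KE", "CO"]
_OBJECTIVES = [
    "drought tolerance",
    "yield stability",
    "disease resistance",
    "nutritional quality",
    "early maturity",
]
_PEOPLE = ["A. Breeder", "M. Curator", "J. Fieldtech", "R. Phenotyper", "S. Sampler"]
# MCPD biological status of accession codes (wild .. advanced cultivar)
_BIO_STATUS = ["100", "110", "200", "300", "400", "410", "500"]
_ANALYSIS_METHODS = ["GBS", "DArTseq", "SNP-chip"]

# trait, method, scale name, scale data type, valid values
_TRAIT_DEFS = [
    ("plant height", "ruler from soil to flag leaf", "centimetre", "numerical", (40.0, 250.0)),
    ("grain yield", "plot combine weight at 12.5% moisture", "t/ha", "numerical", (0.5, 12.0)),
    ("days to flowering", "days from sowing to 50% anthesis", "day", "numerical", (45.0, 120.0)),
    ("disease severity", "visual score of leaf symptoms", "1-9 score", "ordinal", (1.0, 9.0)),
    ("plant vigor", "visual score of early growth", "1-5 score", "ordinal", (1.0, 5.0)),
    ("kernel weight", "weight of 1000 kernels", "gram", "numerical", (100.0, 450.0)),
    ("root yield", "fresh root weight per plot", "kg/plot", "numerical", (1.0, 60.0)),
    ("dry matter content", "oven drying of root sample", "percent", "numerical", (15.0, 45.0)),
    ("lodging incidence", "fraction of lodged plants", "percent", "numerical", (0.0, 100.0)),
    ("plant stand", "count of established plants", "count", "numerical", (10.0, 60.0)),
]

_SEASON_DEFS = [("dry", 2015), ("wet", 2015), ("dry", 2016), ("wet", 2016)]
_STUDY_TYPES = ["phenotyping", "genotyping", "nursery"]
_OBSERVATION_LEVELS = ["plot", "plant"]

# foreign-key field -> referenced store kind.  extractDbId points at an
# external lab system and has no referent here; it is deliberately absent.
FOREIGN_KEYS: dict[str, str] = {
    "germplasmDbId": "germplasm",
    "programDbId": "program",
    "trialDbId": "trial",
    "studyDbId": "study",
    "locationDbId": "location",
    "observationVariableDbId": "observation_variable",
    "observationUnitDbId": "observation_unit",
    "observationDbId": "observation",
    "traitDbId": "trait",
    "methodDbId": "method",
    "scaleDbId": "scale",
    "markerDbId": "marker",
    "markerProfileDbId": "marker_profile",
    "matrixDbId": "allele_matrix",
    "mapDbId": "genome_map",
    "sampleDbId": "sample",
    "orderDbId": "vendor_order",
    "plateDbId": "vendor_plate",
    "attributeDbId": "attribute",
    "attributeCategoryDbId": "attribute_category",
    "ontologyDbId": "ontology",
    "seasonDbId": "season",
    "studyTypeDbId": "study_type",
}
#: list-valued foreign keys: field -> referenced kind (each element resolves)
FOREIGN_KEY_LISTS: dict[str, str] = {
    "sampleDbIds": "sample",
    "plates": "vendor_plate",
}

#: id field per store kind (entity kinds plus generator-internal kinds)
ID_FIELDS: dict[str, str] = {kind: idf for kind, (_, idf) in ENTITY_KINDS.items()}
ID_FIELDS.update({"method": "methodDbId", "scale": "scaleDbId"})
#: row tables keyed by composite/no identifier
ROW_KINDS = {"allele_call", "map_position", "attribute_value"}


@dataclass(frozen=True)
class FixtureConfig:
    """Entity counts and the seed that fix one synthetic dataset exactly."""

    seed: int = 42
    programs: int = 2
    trials_per_program: int = 2
    studies_per_trial: int = 2
    locations: int = 4
    germplasm: int = 25
    variables: int = 10
    markers: int = 50
    marker_profiles: int = 10
    samples: int = 20
    maps: int = 1
    observation_units_per_study: int = 6
    crops: tuple[str, ...] = ("maize", "cassava")

    def validate(self) -> None:
        for name in (
            "programs", "trials_per_program", "studies_per_trial", "locations",
            "germplasm", "variables", "markers", "marker_profiles", "samples",
            "maps", "observation_units_per_study",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"count {name} must be >= 0")
        if self.germplasm > 0 and not self.crops:
            raise ConfigurationError("germplasm requested but no crops configured")
        for crop in self.crops:
            if crop not in CROP_TAXA:
                raise ConfigurationError(f"unknown crop {crop!r}; known: {sorted(CROP_TAXA)}")


class Store:
    """In-memory, insertion-ordered collections of every entity kind.

    Keyed kinds are indexed by their ``…DbId`` field; row kinds (allele
    calls, map positions, attribute values) are plain ordered tables.
    """

    def __init__(self) -> None:
        self._tables: dict[str, list[dict]] = {}
        self._index: dict[str, dict[str, dict]] = {}
        self.crops: list[str] = []
        self.observation_levels: list[str] = list(_OBSERVATION_LEVELS)
        # germplasmDbId -> (parent1 id, parent2 id); backs pedigree/progeny
        self.parents: dict[str, tuple[Optional[str], Optional[str]]] = {}

    # -- mutation ----------------------------------------------------------
    def add(self, kind: str, record: dict) -> dict:
        table = self._tables.setdefault(kind, [])
        table.append(record)
        if kind not in ROW_KINDS:
            id_field = ID_FIELDS[kind]
            self._index.setdefault(kind, {})[record[id_field]] = record
        return record

    # -- access ------------------------------------------------------------
    def kinds(self) -> list[str]:
        return list(self._tables)

    def all(self, kind: str) -> list[dict]:
        return list(self._tables.get(kind, []))

    def count(self, kind: str) -> int:
        return len(self._tables.get(kind, []))

    def get(self, kind: str, db_id: str) -> Optional[dict]:
        return self._index.get(kind, {}).get(db_id)

    def next_id(self, kind: str) -> str:
        return str(len(self._tables.get(kind, [])) + 1)

    def to_json(self) -> dict:
        """Full serializable image of the store (used for determinism checks
        and the fixture-dump CLI)."""
        out: dict[str, Any] = {"crop": list(self.crops),
                               "observation_level": list(self.observation_levels)}
        for kind in sorted(self._tables):
            out[kind] = self._tables[kind]
        return out

    # -- integrity ---------------------------------------------------------
    def referential_violations(self) -> list[str]:
        """Scan every record for dangling foreign identifiers.

        Returns one message per dangling reference; an empty list means the
        store is referentially closed.
        """
        problems: list[str] = []

        def walk(value: Any, where: str) -> None:
            if isinstance(value, dict):
                for key, sub in value.items():
                    if key in FOREIGN_KEYS and isinstance(sub, str):
                        if self.get(FOREIGN_KEYS[key], sub) is None:
                            problems.append(f"{where}.{key} -> {sub!r} ({FOREIGN_KEYS[key]}) dangling")
                    elif key in FOREIGN_KEY_LISTS and isinstance(sub, list):
                        for element in sub:
                            if isinstance(element, str) and self.get(FOREIGN_KEY_LISTS[key], element) is None:
                                problems.append(
                                    f"{where}.{key} -> {element!r} ({FOREIGN_KEY_LISTS[key]}) dangling"
                                )
                    else:
                        walk(sub, f"{where}.{key}")
            elif isinstance(value, list):
                for i, sub in enumerate(value):
                    walk(sub, f"{where}[{i}]")

        for kind, table in self._tables.items():
            for i, record in enumerate(table):
                walk(record, f"{kind}[{i}]")
        return problems


def get_by_id(store: Store, kind: str, db_id: str) -> Optional[dict]:
    """Record of *kind* whose identifier equals *db_id*, or ``None``."""
    if kind not in ID_FIELDS or kind in ROW_KINDS:
        raise InvalidParameterError(f"unknown entity kind {kind!r}")
    return store.get(kind, db_id)


def _known_fields(store: Store, kind: str) -> set[str]:
    if kind in ENTITY_KINDS:
        return set(load_schema(ENTITY_KINDS[kind][0])["properties"])
    table = store.all(kind)
    return set(table[0]) if table else set()


def search(store: Store, kind: str, filters: Mapping[str, Any]) -> list[dict]:
    """Exact-match conjunction over *filters*, in stable insertion order.

    A filter on a list-valued field matches records whose list contains the
    value.  An empty filter map returns every record of the kind.
    """
    if kind not in set(ID_FIELDS) | ROW_KINDS:
        raise InvalidParameterError(f"unknown entity kind {kind!r}")
    known = _known_fields(store, kind)
    for key in filters:
        if key not in known:
            raise InvalidParameterError(f"unknown filter field {key!r} for kind {kind!r}")

    def matches(record: dict) -> bool:
        for key, wanted in filters.items():
            have = record.get(key)
            if isinstance(have, list):
                if wanted not in have:
                    return False
            elif have != wanted:
                return False
        return True

    return [r for r in store.all(kind) if matches(r)]


# ---------------------------------------------------------------------------
# generation


def _timestamp(day_offset: int, minute: int = 0) -> str:
    # fixed base date keeps fixtures stable; explicit UTC offset per contract
    base_day = 1 + day_offset % 28
    month = 6 + (day_offset // 28) % 3
    return f"2016-{month:02d}-{base_day:02d}T{8 + minute % 10:02d}:{minute % 60:02d}:00+00:00"


def generate_fixture(config: FixtureConfig = FixtureConfig()) -> Store:
    """Build the complete synthetic store for *config*.

    Identical configurations (including the seed) produce byte-identical
    stores; every foreign identifier resolves within the returned store.
    """
    config.validate()
    rng = random.Random(config.seed)
    store = Store()
    store.crops = list(config.crops)

    # --- seasons / study types / ontologies (small vocabularies) ----------
    for season, year in _SEASON_DEFS:
        store.add("season", {
            "seasonDbId": store.next_id("season"), "season": season, "year": year,
        })
    for name in _STUDY_TYPES:
        store.add("study_type", {"studyTypeDbId": store.next_id("study_type"), "name": name})
    store.add("ontology", {"ontologyDbId": "1", "ontologyName": "Crop Ontology", "version": "4.0"})

    # --- locations ---------------------------------------------------------
    for i in range(config.locations):
        name, country, lat, lon = _SITES[i % len(_SITES)]
        if i >= len(_SITES):
            name = f"{name} station {i // len(_SITES) + 1}"
        store.add("location", {
            "locationDbId": store.next_id("location"),
            "name": name, "countryCode": country,
            "latitude": lat, "longitude": lon,
        })

    # --- program / trial / study hierarchy ---------------------------------
    for p in range(config.programs):
        crop = config.crops[p % len(config.crops)] if config.crops else "maize"
        program = store.add("program", {
            "programDbId": store.next_id("program"),
            "name": f"{crop} improvement program {p + 1}",
            "abbreviation": f"{crop[:2].upper()}P{p + 1}",
            "objective": rng.choice(_OBJECTIVES),
        })
        for t in range(config.trials_per_program):
            trial = store.add("trial", {
                "trialDbId": store.next_id("trial"),
                "programDbId": program["programDbId"],
                "trialName": f"{program['abbreviation']} trial {2015 + t}",
                "studies": [],
            })
            for s in range(config.studies_per_trial):
                season = rng.choice(store.all("season"))
                location = rng.choice(store.all("location")) if store.count("location") else None
                if location is None:
                    raise ConfigurationError("studies require at least one location")
                study = store.add("study", {
                    "studyDbId": store.next_id("study"),
                    "trialDbId": trial["trialDbId"],
                    "locationDbId": location["locationDbId"],
                    "studyName": f"{trial['trialName']} env {s + 1}",
                    "studyType": rng.choice(_STUDY_TYPES),
                    "seasons": [f"{season['season']} {season['year']}"],
                })
                trial["studies"].append({
                    "studyDbId": study["studyDbId"],
                    "studyName": study["studyName"],
                })

    # --- germplasm with pedigree links --------------------------------------
    parents: dict[str, tuple[Optional[str], Optional[str]]] = {}
    for g in range(config.germplasm):
        crop = config.crops[g % len(config.crops)]
        genus, species = CROP_TAXA[crop]
        db_id = store.next_id("germplasm")
        name = f"{crop[:2].upper()}{g + 1:03d}"
        pedigree = None
        p1 = p2 = None
        if g >= 2 and rng.random() < 0.6:
            # cross of two earlier accessions of the same crop when possible
            earlier = [r for r in store.all("germplasm")
                       if r["commonCropName"] == crop] or store.all("germplasm")
            p1r, p2r = rng.sample(earlier, 2) if len(earlier) >= 2 else (earlier[0], earlier[0])
            p1, p2 = p1r["germplasmDbId"], p2r["germplasmDbId"]
            pedigree = f"{p1r['germplasmName']}/{p2r['germplasmName']}"
        store.add("germplasm", {
            "germplasmDbId": db_id,
            "germplasmName": name,
            "accessionNumber": f"ACC{g + 1:04d}",
            "genus": genus,
            "species": species,
            "countryOfOriginCode": rng.choice(_COUNTRIES),
            "pedigree": pedigree,
            "biologicalStatusOfAccessionCode": rng.choice(_BIO_STATUS),
            "instituteCode": rng.choice(_INSTITUTES),
            "synonyms": [f"{name}-syn"] if rng.random() < 0.3 else [],
            "commonCropName": crop,
        })
        parents[db_id] = (p1, p2)
    store.parents = parents

    # --- germplasm attributes ----------------------------------------------
    for cat in ("agronomic", "morphological"):
        store.add("attribute_category", {
            "attributeCategoryDbId": store.next_id("attribute_category"), "name": cat,
        })
    for name, cat, datatype in (
        ("seed color", "2", "categorical"),
        ("growth habit", "2", "categorical"),
        ("maturity class", "1", "categorical"),
    ):
        store.add("attribute", {
            "attributeDbId": store.next_id("attribute"),
            "name": name, "attributeCategoryDbId": cat, "datatype": datatype,
        })
    _ATTR_VALUES = {
        "1": ["white", "yellow", "red"],
        "2": ["erect", "spreading"],
        "3": ["early", "medium", "late"],
    }
    for germ in store.all("germplasm"):
        for attr in store.all("attribute"):
            if rng.random() < 0.5:
                store.add("attribute_value", {
                    "germplasmDbId": germ["germplasmDbId"],
                    "attributeDbId": attr["attributeDbId"],
                    "value": rng.choice(_ATTR_VALUES[attr["attributeDbId"]]),
                })

    # --- observation variables (trait + method + scale) ---------------------
    for v in range(config.variables):
        trait_name, method_desc, scale_name, data_type, (lo, hi) = _TRAIT_DEFS[v % len(_TRAIT_DEFS)]
        trait = store.add("trait", {
            "traitDbId": store.next_id("trait"),
            "name": trait_name,
            "description": f"{trait_name} of the plot",
        })
        method = store.add("method", {
            "methodDbId": store.next_id("method"),
            "name": f"{trait_name} measurement",
            "description": method_desc,
        })
        scale = store.add("scale", {
            "scaleDbId": store.next_id("scale"),
            "name": scale_name,
            "dataType": data_type,
            "validValues": {"min": lo, "max": hi, "categories": []},
        })
        store.add("observation_variable", {
            "observationVariableDbId": store.next_id("observation_variable"),
            "name": f"{trait_name} - {scale_name}",
            "trait": dict(trait),
            "method": dict(method),
            "scale": dict(scale),
        })

    # --- observation units and observations ---------------------------------
    germplasm_pool = store.all("germplasm")
    variable_pool = store.all("observation_variable")
    for study in store.all("study"):
        for u in range(config.observation_units_per_study):
            if not germplasm_pool:
                break
            germ = rng.choice(germplasm_pool)
            unit = store.add("observation_unit", {
                "observationUnitDbId": store.next_id("observation_unit"),
                "studyDbId": study["studyDbId"],
                "germplasmDbId": germ["germplasmDbId"],
                "replicate": 1 + u % 2,
                "blockNumber": 1 + u // 2,
                "positionCoordinateX": str(1 + u % 3),
                "positionCoordinateY": str(1 + u // 3),
            })
            for variable in variable_pool[:3]:
                lo = variable["scale"]["validValues"]["min"]
                hi = variable["scale"]["validValues"]["max"]
                value = round(rng.uniform(lo, hi), 1)
                store.add("observation", {
                    "observationDbId": store.next_id("observation"),
                    "observationUnitDbId": unit["observationUnitDbId"],
                    "observationVariableDbId": variable["observationVariableDbId"],
                    "value": str(value),
                    "observationTimeStamp": _timestamp(u, len(store.all("observation"))),
                })

    # --- markers, profiles, allele matrix ------------------------------------
    bases = "ACGT"
    for m in range(config.markers):
        ref = rng.choice(bases)
        alt = rng.choice([b for b in bases if b != ref])
        store.add("marker", {
            "markerDbId": store.next_id("marker"),
            "defaultDisplayName": f"mk{m + 1:04d}",
            "type": "SNP",
            "refAlt": [ref, alt],
            "synonyms": [f"snp_{m + 1}"] if rng.random() < 0.2 else [],
        })
    markers = store.all("marker")
    if config.marker_profiles > 0 and not germplasm_pool:
        raise ConfigurationError("marker profiles require germplasm")
    for p in range(config.marker_profiles):
        germ = rng.choice(germplasm_pool)
        profile_id = store.next_id("marker_profile")
        calls = 0
        for marker in markers:
            ref, alt = marker["refAlt"]
            roll = rng.random()
            if roll < 0.45:
                call = ref
            elif roll < 0.90:
                call = alt
            elif roll < 0.95:
                call = f"{ref}/{alt}"
            else:
                call = "-"
            if call != "-":
                calls += 1
            store.add("allele_call", {
                "markerDbId": marker["markerDbId"],
                "markerProfileDbId": profile_id,
                "alleleCall": call,
            })
        store.add("marker_profile", {
            "markerProfileDbId": profile_id,
            "germplasmDbId": germ["germplasmDbId"],
            "extractDbId": f"ext-{p + 1}",
            "analysisMethod": rng.choice(_ANALYSIS_METHODS),
            "resultCount": calls,
        })
    if config.marker_profiles > 0:
        store.add("allele_matrix", {
            "matrixDbId": "1",
            "name": "default allele matrix",
            "description": "all fixture marker profiles by all markers",
        })

    # --- genome maps ---------------------------------------------------------
    for m in range(config.maps):
        map_id = store.next_id("genome_map")
        group_names = [f"LG{i + 1}" for i in range(3)]
        per_group: dict[str, list[dict]] = {g: [] for g in group_names}
        position = 0.0
        for marker in markers:
            group = rng.choice(group_names)
            position = round(rng.uniform(0.0, 180.0), 1)
            row = store.add("map_position", {
                "mapDbId": map_id,
                "markerDbId": marker["markerDbId"],
                "linkageGroupName": group,
                "location": position,
            })
            per_group[group].append(row)
        store.add("genome_map", {
            "mapDbId": map_id,
            "name": f"consensus map {m + 1}",
            "type": "genetic",
            "linkageGroups": [
                {
                    "linkageGroupName": g,
                    "markerCount": len(rows),
                    "maxPosition": max((r["location"] for r in rows), default=0.0),
                }
                for g, rows in per_group.items()
            ],
        })

    # --- samples and vendor orders -------------------------------------------
    units = store.all("observation_unit")
    wells = "ABCDEFGH"
    for s in range(config.samples):
        if not units:
            break
        unit = rng.choice(units)
        store.add("sample", {
            "sampleDbId": store.next_id("sample"),
            "germplasmDbId": unit["germplasmDbId"],
            "observationUnitDbId": unit["observationUnitDbId"],
            "plateName": f"PLATE-{1 + s // 8}",
            "well": f"{wells[s % 8]}{1 + s // 8}",
            "takenBy": rng.choice(_PEOPLE),
            "sampleTimestamp": _timestamp(s, s * 7),
        })
    samples = store.all("sample")
    if samples:
        by_plate: dict[str, list[str]] = {}
        for sample in samples:
            by_plate.setdefault(sample["plateName"], []).append(sample["sampleDbId"])
        for plate_name, sample_ids in by_plate.items():
            store.add("vendor_plate", {
                "plateDbId": store.next_id("vendor_plate"),
                "plateName": plate_name,
                "sampleDbIds": sample_ids,
            })
        plates = [p["plateDbId"] for p in store.all("vendor_plate")]
        store.add("vendor_order", {
            "orderDbId": "1", "clientId": "client-1",
            "plates": plates[: max(1, len(plates) // 2)],
            "status": "registered", "results": [],
        })
        store.add("vendor_order", {
            "orderDbId": "2", "clientId": "client-1",
            "plates": plates[max(1, len(plates) // 2):] or plates[:1],
            "status": "completed",
            "results": ["https://vendor.example/orders/2/results.tsv"],
        })

    return store


def dump_store(store: Store, directory) -> list[str]:
    """Write one JSON file per entity kind into *directory*; returns paths."""
    import os

    os.makedirs(directory, exist_ok=True)
    written = []
    for kind, table in store.to_json().items():
        path = os.path.join(directory, f"{kind}.json")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(table, fh, indent=1, sort_keys=True)
            fh.write("\n")
        written.append(path)
    return written
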