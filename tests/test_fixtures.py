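"""Deterministic generation, querying and referential closure of fixtures."""

import json
import random
import subprocess
import sys

import pytest

from brapiref import FixtureConfig, generate_fixture, get_by_id, search
from brapiref.errors import ConfigurationError, InvalidParameterError


class TestGeneration:
    def test_same_config_twice_gives_byte_identical_stores(self):
        a = generate_fixture(FixtureConfig(seed=7))
        b = generate_fixture(FixtureConfig(seed=7))
        assert json.dumps(a.to_json(), sort_keys=True) == json.dumps(b.to_json(), sort_keys=True)

    def test_cross_process_determinism(self):
        """A second interpreter with the same config builds the same store."""
        code = (
            "import json;"
            "from brapiref import FixtureConfig, generate_fixture;"
            "print(json.dumps(generate_fixture(FixtureConfig(seed=5, germplasm=6,"
            " markers=5, marker_profiles=2, samples=4)).to_json(), sort_keys=True))"
        )
        out = subprocess.run([sys.executable, "-c", code], capture_output=True, text=True, check=True)
        local = generate_fixture(FixtureConfig(seed=5, germplasm=6, markers=5,
                                               marker_profiles=2, samples=4))
        assert json.loads(out.stdout) == json.loads(json.dumps(local.to_json(), sort_keys=True))

    def test_counts_multiply_through_the_hierarchy(self):
        store = generate_fixture(FixtureConfig(programs=2, trials_per_program=3, studies_per_trial=2))
        assert store.count("program") == 2
        assert store.count("trial") == 6
        assert store.count("study") == 12

    def test_requested_counts_are_exact(self):
        config = FixtureConfig(germplasm=11, markers=7, marker_profiles=3,
                               variables=4, samples=5, locations=2, maps=2)
        store = generate_fixture(config)
        assert store.count("germplasm") == 11
        assert store.count("marker") == 7
        assert store.count("marker_profile") == 3
        assert store.count("observation_variable") == 4
        assert store.count("sample") == 5
        assert store.count("location") == 2
        assert store.count("genome_map") == 2
        assert store.count("allele_call") == 7 * 3

    def test_germplasm_one_always_exists(self):
        store = generate_fixture(FixtureConfig())
        record = get_by_id(store, "germplasm", "1")
        assert record is not None and record["germplasmDbId"] == "1"

    def test_inconsistent_config_is_rejected(self):
        with pytest.raises(ConfigurationError):
            FixtureConfig(germplasm=5, crops=()).validate()
        with pytest.raises(ConfigurationError):
            FixtureConfig(markers=-1).validate()


def brute_force_dangling_scan(store):
    """Independent reference scan: collect every *DbId field anywhere in the
    store and look each value up in the index directly."""
    from brapiref.fixtures import FOREIGN_KEYS, FOREIGN_KEY_LISTS

    dangling = []

    def visit(node):
        if isinstance(node, dict):
            for key, value in node.items():
                if key in FOREIGN_KEYS and isinstance(value, str):
                    if store.get(FOREIGN_KEYS[key], value) is None:
                        dangling.append((key, value))
                elif key in FOREIGN_KEY_LISTS and isinstance(value, list):
                    for element in value:
                        if store.get(FOREIGN_KEY_LISTS[key], element) is None:
                            dangling.append((key, element))
                else:
                    visit(value)
        elif isinstance(node, list):
            for element in node:
                visit(element)

    for kind in store.kinds():
        for record in store.all(kind):
            visit(record)
    return dangling


class TestReferentialClosure:
    def test_default_store_has_no_dangling_references(self):
        store = generate_fixture(FixtureConfig())
        assert store.referential_violations() == []
        assert brute_force_dangling_scan(store) == []

    def test_scan_detects_a_planted_dangling_reference(self):
        store = generate_fixture(FixtureConfig())
        store.all("trial")[0]["programDbId"] = "no-such-program"
        assert store.referential_violations() != []
        assert brute_force_dangling_scan(store) != []

    def test_closure_holds_over_randomized_configs(self):
        """20 random configurations, seeds drawn from a fixed meta-seed."""
        meta = random.Random(20240501)
        for _ in range(20):
            config = FixtureConfig(
                seed=meta.randrange(1_000_000),
                programs=meta.randint(0, 3),
                trials_per_program=meta.randint(0, 3),
                studies_per_trial=meta.randint(0, 3),
                locations=meta.randint(1, 5),
                germplasm=meta.randint(1, 15),
                variables=meta.randint(0, 6),
                markers=meta.randint(0, 12),
                marker_profiles=meta.randint(0, 4),
                samples=meta.randint(0, 8),
                maps=meta.randint(0, 2),
            )
            store = generate_fixture(config)
            assert store.referential_violations() == [], f"dangling refs for {config}"


class TestQueries:
    def test_get_by_id_resolves_every_generated_study(self, store):
        for study in store.all("study"):
            assert get_by_id(store, "study", study["studyDbId"]) is study

    def test_get_by_id_missing_and_unknown_kind(self, store):
        assert get_by_id(store, "germplasm", "no-such-id") is None
        with pytest.raises(InvalidParameterError):
            get_by_id(store, "spaceship", "1")

    def test_search_filter_equals_client_side_filtering(self, store):
        """Oracle equivalence for every single-field exact filter that occurs
        in the data."""
        for kind, field in [
            ("trial", "programDbId"),
            ("study", "trialDbId"),
            ("study", "locationDbId"),
            ("marker_profile", "germplasmDbId"),
            ("germplasm", "commonCropName"),
            ("observation_unit", "studyDbId"),
        ]:
            everything = search(store, kind, {})
            for value in {r[field] for r in everything}:
                expected = [r for r in everything if r[field] == value]
                assert search(store, kind, {field: value}) == expected

    def test_empty_filter_returns_all_in_generation_order(self, store):
        records = search(store, "germplasm", {})
        assert [r["germplasmDbId"] for r in records] == [str(i + 1) for i in range(len(records))]

    def test_unmatched_filter_value_gives_empty_list(self, store):
        assert search(store, "trial", {"programDbId": "nonexistent"}) == []

    def test_unknown_filter_field_raises(self, store):
        with pytest.raises(InvalidParameterError):
            search(store, "trial", {"warpFactor": "9"})

    def test_list_valued_fields_match_by_membership(self, store):
        germ = next(r for r in store.all("germplasm") if r["synonyms"])
        hits = search(store, "germplasm", {"synonyms": germ["synonyms"][0]})
        assert germ in hits
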