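"""Response-envelope construction, pattern classification and validation."""

import json

import pytest
from hypothesis import given, settings, strategies as st

from brapiref import (
    ALL_ZERO_PAGINATION,
    Pagination,
    Status,
    classify_result_pattern,
    make_envelope,
    validate_envelope,
)
from brapiref.errors import ContractViolationError, MalformedResultError


class TestMakeEnvelope:
    def test_single_entity_gets_all_zero_pagination(self):
        envelope = make_envelope({"locationDbId": "1", "name": "Ithaca"}, ALL_ZERO_PAGINATION)
        doc = envelope.to_json()
        assert set(doc) == {"metadata", "result"}
        assert doc["metadata"]["pagination"] == {
            "pageSize": 0, "currentPage": 0, "totalCount": 0, "totalPages": 0,
        }

    def test_empty_listing_keeps_empty_arrays_not_null(self):
        envelope = make_envelope({"data": []}, Pagination(10, 0, 0, 0))
        doc = envelope.to_json()
        assert doc["result"]["data"] == []
        assert doc["metadata"]["status"] == []
        assert doc["metadata"]["datafiles"] == []

    def test_master_details_shape(self):
        result = {"studyDbId": "s1", "data": [{"observationDbId": "1"}, {"observationDbId": "2"}]}
        envelope = make_envelope(result, Pagination(2, 0, 2, 1), [Status("200", "success")])
        doc = envelope.to_json()
        assert doc["result"]["studyDbId"] == "s1"
        assert len(doc["result"]["data"]) == 2
        assert doc["metadata"]["status"] == [{"code": "200", "message": "success"}]

    def test_data_longer_than_page_size_is_rejected(self):
        with pytest.raises(ContractViolationError):
            make_envelope({"data": [1, 2, 3]}, Pagination(2, 0, 3, 2))

    def test_defaults_are_empty_lists(self):
        doc = make_envelope({"x": 1}).to_json()
        assert doc["metadata"]["status"] == []
        assert doc["metadata"]["datafiles"] == []


class TestClassifyResultPattern:
    @pytest.mark.parametrize(
        "result, expected",
        [
            ({"data": [1, 2]}, "details"),
            ({"data": []}, "details"),
            ({"germplasmDbId": "1", "germplasmName": "x"}, "master"),
            ({}, "master"),
            ({"studyDbId": "s1", "data": [1]}, "master_details"),
        ],
    )
    def test_partition(self, result, expected):
        assert classify_result_pattern(result) == expected

    def test_data_must_be_a_list(self):
        with pytest.raises(MalformedResultError):
            classify_result_pattern({"data": "not-a-list"})

    def test_non_object_is_malformed(self):
        with pytest.raises(MalformedResultError):
            classify_result_pattern([1, 2, 3])


class TestValidateEnvelope:
    def test_valid_envelopes_of_all_patterns(self):
        for result, pagination in [
            ({"locationDbId": "1"}, ALL_ZERO_PAGINATION),
            ({"data": [{"a": 1}, {"a": 2}]}, Pagination(10, 0, 2, 1)),
            ({"studyDbId": "s", "data": [{"a": 1}]}, Pagination(5, 0, 1, 1)),
        ]:
            doc = make_envelope(result, pagination).to_json()
            assert validate_envelope(doc) == []

    def test_missing_metadata_is_one_named_violation(self):
        violations = validate_envelope({"result": {}})
        assert len(violations) == 1
        assert "metadata" in violations[0].message

    def test_missing_pagination_key_is_flagged(self):
        doc = make_envelope({"data": []}, Pagination(10, 0, 0, 0)).to_json()
        del doc["metadata"]["pagination"]["totalPages"]
        violations = validate_envelope(doc)
        assert len(violations) == 1
        assert "totalPages" in violations[0].message

    def test_pagination_arithmetic_mismatch_is_flagged(self):
        doc = make_envelope({"data": [1]}, Pagination(10, 0, 1, 1)).to_json()
        doc["metadata"]["pagination"]["totalPages"] = 2
        assert any(v.code == "pagination_arithmetic" for v in validate_envelope(doc))

    def test_populated_page_past_the_end_is_impossible(self):
        doc = make_envelope({"data": [1]}, Pagination(10, 0, 1, 1)).to_json()
        doc["metadata"]["pagination"]["currentPage"] = 5
        doc["metadata"]["pagination"]["totalPages"] = 1
        assert any(v.code == "page_out_of_range" for v in validate_envelope(doc))

    def test_empty_out_of_range_page_with_truthful_totals_is_legal(self):
        doc = make_envelope({"data": []}, Pagination(2, 9, 5, 3)).to_json()
        assert validate_envelope(doc) == []

    def test_data_exceeding_page_size_is_flagged(self):
        doc = make_envelope({"data": [1, 2]}, Pagination(2, 0, 2, 1)).to_json()
        doc["metadata"]["pagination"]["pageSize"] = 1
        codes = {v.code for v in validate_envelope(doc)}
        assert "data_exceeds_page" in codes

    def test_wrong_pattern_is_flagged_when_expected(self):
        doc = make_envelope({"extra": "x", "data": []}, Pagination(10, 0, 0, 0)).to_json()
        assert any(
            v.code == "wrong_pattern"
            for v in validate_envelope(doc, expected_pattern="details")
        )

    def test_null_result_is_a_valid_error_body(self):
        doc = make_envelope(None, ALL_ZERO_PAGINATION, [Status("404", "not found")]).to_json()
        assert validate_envelope(doc) == []

    def test_entity_schema_is_applied_to_data_records(self):
        doc = make_envelope(
            {"data": [{"locationDbId": 7, "name": "x", "countryCode": "US",
                       "latitude": 1.0, "longitude": 2.0}]},
            Pagination(10, 0, 1, 1),
        ).to_json()
        violations = validate_envelope(doc, expected_entity="location")
        assert any("locationDbId" in v.path for v in violations)


# -- round-trip property -----------------------------------------------------

_record = st.dictionaries(
    st.sampled_from(["germplasmDbId", "name", "value"]),
    st.one_of(st.text(max_size=8), st.integers(0, 99), st.none()),
    min_size=1,
)


@st.composite
def _consistent_envelope(draw):
    pattern = draw(st.sampled_from(["master", "details", "master_details"]))
    if pattern == "master":
        return make_envelope(draw(_record), ALL_ZERO_PAGINATION)
    records = draw(st.lists(_record, max_size=5))
    page_size = draw(st.integers(max(1, len(records)), 10))
    total = len(records)
    pagination = Pagination(page_size, 0, total, -(-total // page_size))
    result = {"data": records}
    if pattern == "master_details":
        result = {"parentDbId": "p1", "data": records}
    return make_envelope(result, pagination)


@settings(max_examples=100, derandomize=True)
@given(_consistent_envelope())
def test_round_trip_serialization_yields_zero_violations(envelope):
    """Any consistently built envelope survives serialize -> parse -> validate."""
    reparsed = json.loads(envelope.serialize())
    assert validate_envelope(reparsed) == []
    assert classify_result_pattern(reparsed["result"]) in (
        "master", "details", "master_details",
    )
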