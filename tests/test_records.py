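"""Unit tests for the typed metadata records and their invariants."""

import datetime as dt
import uuid

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pydantic import ValidationError

from provtrace import (
    STEWARD_SENTINEL,
    DataElementRecord,
    DataOwner,
    DataScript,
    DataSteward,
    DataStore,
    GovernancePolicy,
    LineageChain,
    ProvenanceRecord,
    parse_status_log,
    validate_element_record,
)
from provtrace.records import StatusLogError, ensure_utc

UTC = dt.timezone.utc


def test_box2_record_is_valid(box2_record):
    assert validate_element_record(box2_record) == []


@pytest.mark.parametrize("field", ["element_id", "name", "source_store", "destination_store"])
def test_empty_required_field_is_one_violation(box2_record, field):
    rec = box2_record.model_copy(update={field: "  "})
    report = validate_element_record(rec)
    assert [v.field for v in report] == [field]


def test_status_log_parses_to_status_and_date():
    status, day = parse_status_log("passed date 12.May2022")
    assert status == "passed"
    assert day == dt.date(2022, 5, 12)


@pytest.mark.parametrize("text", [
    "", "passed", "date 12.May2022", "passed 12.May2022", "passed date",
    "passed date someday", "passed date 2022", "passed date 99.May2022",
    "passed date 12.Mayy2022", "passed date 12-May-2022", "12.May2022 date passed",
    "passed  date", "ok date 32.01.2022", "ok date 2022-13-01", "ok date ..",
    "done date May2022", "done date 12/05/2022", "x y z", "passed date 0.0.0",
    "verified on 12.May2022",
])
def test_malformed_status_log_rejected_and_flagged(box2_record, text):
    # the parser is the oracle: every string it rejects must surface as a
    # status_log violation on the enclosing record
    with pytest.raises(StatusLogError):
        parse_status_log(text)
    report = validate_element_record(box2_record.model_copy(update={"status_log": text}))
    assert any(v.field == "status_log" for v in report)


@pytest.mark.parametrize("text,expected_day", [
    ("passed date 01.02.2023", dt.date(2023, 2, 1)),
    ("failed date 2022-05-12", dt.date(2022, 5, 12)),
    ("passed date 12.May.2022", dt.date(2022, 5, 12)),
])
def test_status_log_accepts_common_date_spellings(text, expected_day):
    assert parse_status_log(text)[1] == expected_day


_text = st.text(st.characters(blacklist_categories=("Cs",)), max_size=30)


@settings(max_examples=50, derandomize=True)
@given(
    element_id=_text.filter(str.strip), name=_text.filter(str.strip),
    description=_text, source_variable=_text, steward_name=_text,
)
def test_element_record_json_round_trip(element_id, name, description,
                                        source_variable, steward_name):
    rec = DataElementRecord(
        element_id=element_id, name=name, description=description,
        source_store="stg", source_variable=source_variable,
        destination_store="dwh", steward_name=steward_name,
    )
    again = DataElementRecord.model_validate_json(rec.model_dump_json())
    assert again == rec


@pytest.mark.parametrize("obj,cls", [
    (GovernancePolicy(document_name="DIC_ETL-ST.pdf", version="v1", status="approved"),
     GovernancePolicy),
    (DataOwner(department="DIC", responsible_person="Dr. Weber"), DataOwner),
    (DataSteward(name="no name given"), DataSteward),
    (DataStore(store_name="stg_sap_vitalis", role="input"), DataStore),
    (DataScript(script_name="etl_st.py", version="v1", creator="MZ",
                verified_at=dt.datetime(2023, 2, 3, 6, 1, 34, tzinfo=UTC)), DataScript),
])
def test_dimension_types_round_trip_losslessly(obj, cls):
    assert cls.model_validate_json(obj.model_dump_json()) == obj


def test_steward_sentinel_applied_and_survives_round_trip():
    for missing in (None, "", "   "):
        steward = DataSteward(name=missing)
        assert steward.name == STEWARD_SENTINEL
    again = DataSteward.model_validate_json(DataSteward(name=None).model_dump_json())
    assert again.name == STEWARD_SENTINEL


def test_owner_requires_some_identity():
    with pytest.raises(ValidationError):
        DataOwner(department="", responsible_person=" ")
    assert DataOwner(department="DIC").label == "DIC"


def test_store_uuid_is_deterministic_and_urn_rendered():
    a = DataStore(store_name="dwh_vitalis", role="output")
    b = DataStore(store_name="dwh_vitalis", role="input")
    assert a.store_id == b.store_id  # same system, same identifier
    assert a.urn == f"urn:uuid:{a.store_id}"
    assert uuid.UUID(str(a.store_id))  # valid UUID


def test_script_verification_always_populated():
    with pytest.raises(ValidationError):
        DataScript(script_name="x.py", version="v1", verification_status="  ")
    s = DataScript(script_name="x.py", version="v1")
    assert s.verification_status and s.verified_at.tzinfo is not None


def test_provenance_record_rejects_time_travel(box2_record):
    kw = dict(
        record_id=1, element=box2_record,
        policy=GovernancePolicy(document_name="p", version="1"),
        owner=DataOwner(department="DIC"), steward=DataSteward(),
        input_store=DataStore(store_name="stg", role="input"),
        output_store=DataStore(store_name="dwh", role="output"),
        script=DataScript(script_name="x.py", version="v1"),
    )
    t = dt.datetime(2023, 2, 3, 6, 1, 34, tzinfo=UTC)
    rec = ProvenanceRecord(occurred_at=t, recorded_at=t, **kw)
    assert rec.recorded_at >= rec.occurred_at
    with pytest.raises(ValidationError):
        ProvenanceRecord(occurred_at=t, recorded_at=t - dt.timedelta(seconds=1), **kw)


def test_ensure_utc_normalizes_naive_and_space_separated():
    t = ensure_utc("2023-02-03 06:01:34")
    assert t == dt.datetime(2023, 2, 3, 6, 1, 34, tzinfo=UTC)
    offset = ensure_utc("2023-02-03T07:01:34+01:00")
    assert offset == t


def _step(box2, record_id, t, src, dst):
    return ProvenanceRecord(
        record_id=record_id,
        element=box2.model_copy(update={"source_store": src, "destination_store": dst}),
        policy=GovernancePolicy(document_name="p", version="1"),
        owner=DataOwner(department="DIC"), steward=DataSteward(),
        input_store=DataStore(store_name=src, role="input"),
        output_store=DataStore(store_name=dst, role="output"),
        script=DataScript(script_name="x.py", version="v1"),
        occurred_at=t, recorded_at=t,
    )


def test_lineage_chain_continuity_and_ordering(box2_record):
    t0 = dt.datetime(2023, 1, 1, tzinfo=UTC)
    steps = [
        _step(box2_record, 1, t0, "staging", "dwh"),
        _step(box2_record, 2, t0 + dt.timedelta(minutes=1), "dwh", "rdr"),
    ]
    chain = LineageChain(element_id="syst_blood_pressure", steps=steps)
    assert chain.is_continuous and len(chain) == 2

    broken = LineageChain(element_id="syst_blood_pressure", steps=[
        steps[0], _step(box2_record, 3, t0 + dt.timedelta(minutes=2), "fhir", "rdr")])
    assert broken.continuity_breaks() == [(1, "dwh", "fhir")]

    with pytest.raises(ValidationError):
        LineageChain(element_id="x", steps=list(reversed(steps)))
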