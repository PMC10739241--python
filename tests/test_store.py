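"""Unit and property tests for the append-only capture store."""

import sqlite3

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from provtrace import (
    ContinuityWarning,
    DataOwner,
    DataScript,
    DataSteward,
    ElementValidationError,
    GovernancePolicy,
    StoreConfigurationError,
    StoreUsageError,
    close_session,
    init_store,
    open_session,
    record_element,
)
from provtrace.fixtures import DEMO_OWNER, DEMO_POLICY, DEMO_SCRIPT


def test_fresh_store_is_empty(store):
    assert store.count_records() == 0


def test_init_is_idempotent_and_preserves_data(tmp_path, box2_record):
    db = tmp_path / "p.db"
    first = init_store(db)
    s = first.open_session("run1", script=DEMO_SCRIPT, policy=DEMO_POLICY)
    s.record(box2_record)
    s.close()
    first.close()

    again = init_store(db)  # same schema, no data loss
    assert again.count_records() == 1
    again.close()


def test_unusable_location_raises_configuration_error(tmp_path):
    with pytest.raises(StoreConfigurationError) as err:
        init_store(tmp_path)  # a directory is not a database file
    assert str(tmp_path) in str(err.value)


def test_session_dimensions_round_trip(store):
    session = store.open_session(
        pipeline_name="etl_vitals",
        script=DataScript(script_name="etl_st.py", version="v1", creator="MZ"),
        policy=GovernancePolicy(document_name="DIC_ETL-ST.pdf", version="v1",
                                status="approved"),
        steward=DataSteward(name="Hr. Koch"),
        owner=DataOwner(department="DIC"),
    )
    session.close()
    rows = store._conn.execute(
        "SELECT script_name, version, creator FROM script").fetchall()
    assert rows == [("etl_st.py", "v1", "MZ")]
    rows = store._conn.execute(
        "SELECT document_name, version, status FROM policy").fetchall()
    assert rows == [("DIC_ETL-ST.pdf", "v1", "approved")]


def test_same_policy_two_sessions_one_dimension_row(store):
    for name in ("run1", "run2"):
        store.open_session(name, script=DEMO_SCRIPT, policy=DEMO_POLICY).close()
    assert store._conn.execute("SELECT COUNT(*) FROM policy").fetchone()[0] == 1
    assert store._conn.execute("SELECT COUNT(*) FROM session").fetchone()[0] == 2


def test_omitted_steward_stored_as_sentinel(store, box2_record):
    session = store.open_session("run", script=DEMO_SCRIPT, policy=DEMO_POLICY)
    rec = session.record(box2_record)
    session.close()
    assert rec.steward.name == "no name given"
    assert store._conn.execute("SELECT name FROM steward").fetchone()[0] == "no name given"


def test_record_element_links_stores(session, box2_record):
    rec = record_element(session, box2_record)
    assert rec.input_store.store_name == "stg_sap_vitalis"
    assert rec.output_store.store_name == "dwh_vitalis"
    assert rec.record_id == 1
    assert rec.recorded_at >= rec.occurred_at


def test_same_element_twice_appends_two_records(store, session, box2_record):
    first = session.record(box2_record)
    second = session.record(box2_record)
    assert first.record_id != second.record_id
    session.close()
    assert store.count_records(element_id=box2_record.element_id) == 2


def test_invalid_record_rejected_with_report(session, box2_record):
    bad = box2_record.model_copy(update={"element_id": "", "status_log": "nope"})
    with pytest.raises(ElementValidationError) as err:
        session.record(bad)
    assert {v.field for v in err.value.report} == {"element_id", "status_log"}


def test_close_session_summary_and_rejection(store, box2_record):
    session = store.open_session("run", script=DEMO_SCRIPT, policy=DEMO_POLICY)
    empty = store.open_session("empty", script=DEMO_SCRIPT, policy=DEMO_POLICY)
    assert close_session(empty).records_written == 0

    for _ in range(5):
        session.record(box2_record)
    summary = session.close()
    assert summary.records_written == 5
    assert summary.duration.total_seconds() >= 0

    with pytest.raises(StoreUsageError):
        session.record(box2_record)
    with pytest.raises(StoreUsageError):
        session.close()


def test_open_session_requires_store_handle():
    with pytest.raises(StoreUsageError):
        open_session(object(), "run", DEMO_SCRIPT, DEMO_POLICY)


def test_trace_three_stage_chain(store, box2_record):
    session = store.open_session("run", script=DEMO_SCRIPT, policy=DEMO_POLICY)
    for src, dst in (("staging", "dwh"), ("dwh", "fhir"), ("fhir", "rdr")):
        session.record(box2_record.model_copy(
            update={"source_store": src, "destination_store": dst}))
    session.close()

    chain = store.trace_element(box2_record.element_id)
    assert len(chain) == 3
    assert chain.is_continuous
    hops = [(s.input_store.store_name, s.output_store.store_name) for s in chain.steps]
    assert hops == [("staging", "dwh"), ("dwh", "fhir"), ("fhir", "rdr")]


def test_trace_unknown_element_is_empty_chain(store):
    chain = store.trace_element("does_not_exist")
    assert chain.steps == [] and len(chain) == 0


def test_trace_single_record_trivially_continuous(store, session, box2_record):
    session.record(box2_record)
    session.close()
    chain = store.trace_element(box2_record.element_id)
    assert len(chain) == 1 and chain.is_continuous


def test_trace_broken_store_continuity_warns(store, session, box2_record):
    session.record(box2_record.model_copy(
        update={"source_store": "staging", "destination_store": "dwh"}))
    session.record(box2_record.model_copy(
        update={"source_store": "fhir", "destination_store": "rdr"}))
    session.close()
    with pytest.warns(ContinuityWarning, match="dwh"):
        chain = store.trace_element(box2_record.element_id)
    assert not chain.is_continuous


def test_count_records_filters(store, box2_record):
    s1 = store.open_session("a", script=DEMO_SCRIPT, policy=DEMO_POLICY)
    s2 = store.open_session("b", script=DEMO_SCRIPT, policy=DEMO_POLICY)
    other = box2_record.model_copy(update={"element_id": "heart_rate_0001",
                                           "name": "heart_rate"})
    for _ in range(3):
        s1.record(box2_record)
    for _ in range(2):
        s2.record(other)
    s1.close(), s2.close()
    assert store.count_records() == 5
    assert store.count_records(element_name="syst_blood_pressure") == 3
    assert store.count_records(element_name="heart_rate") == 2
    assert store.count_records(session=s2) == 2


@settings(max_examples=20, derandomize=True, deadline=None)
@given(sizes=st.lists(st.integers(min_value=0, max_value=5), min_size=1, max_size=4))
def test_count_equals_total_writes_for_any_session_interleaving(tmp_path_factory,
                                                               sizes):
    store = init_store(tmp_path_factory.mktemp("prop") / "p.db")
    rec_template = None
    from provtrace.fixtures import builtin_element_types
    rec_template = builtin_element_types()[0].template
    sessions = [store.open_session(f"s{i}", script=DEMO_SCRIPT, policy=DEMO_POLICY)
                for i in range(len(sizes))]
    # interleave round-robin across open sessions
    remaining = list(sizes)
    while any(remaining):
        for i, session in enumerate(sessions):
            if remaining[i]:
                session.record(rec_template)
                remaining[i] -= 1
    total = sum(s.close().records_written for s in sessions)
    assert total == sum(sizes)
    assert store.count_records() == sum(sizes)
    store.close()


def test_append_only_triggers_block_mutation(store, session, box2_record):
    session.record(box2_record)
    session.close()
    with pytest.raises(sqlite3.DatabaseError):
        store._conn.execute("UPDATE provenance SET quality_status = 'bad'")
    with pytest.raises(sqlite3.DatabaseError):
        store._conn.execute("DELETE FROM provenance")
    with pytest.raises(sqlite3.DatabaseError):
        store._conn.execute("UPDATE element SET name = 'x'")


def test_audit_hashes_pass_after_workload_and_catch_tampering(store, box2_record):
    session = store.open_session("run", script=DEMO_SCRIPT, policy=DEMO_POLICY)
    for _ in range(10):
        session.record(box2_record)
    session.close()
    assert store.verify_audit() == []
    assert store.verify_references() == []

    # bypass the trigger the way an out-of-band actor would, then tamper
    store._conn.execute("DROP TRIGGER provenance_no_update")
    store._conn.execute("UPDATE provenance SET quality_status = 'bad' WHERE id = 3")
    store._conn.commit()
    assert store.verify_audit() == [3]


def test_flushed_records_survive_simulated_process_kill(tmp_path, box2_record):
    db = tmp_path / "p.db"
    store = init_store(db)
    session = store.open_session("run", script=DEMO_SCRIPT, policy=DEMO_POLICY)
    for _ in range(5):
        session.record(box2_record)
    session.flush()
    store._conn.close()  # hard kill: no session close, no final commit

    reopened = init_store(db)
    assert reopened.count_records() == 5
    assert reopened.verify_audit() == []
    reopened.close()


def test_batch_commit_inside_tight_loop(tmp_path, box2_record):
    db = tmp_path / "p.db"
    store = init_store(db, batch_size=10)
    session = store.open_session("run", script=DEMO_SCRIPT, policy=DEMO_POLICY)
    for _ in range(25):
        session.record(box2_record)
    # 20 rows auto-flushed; the 5-row tail is still pending
    other = sqlite3.connect(db)
    committed = other.execute("SELECT COUNT(*) FROM provenance").fetchone()[0]
    other.close()
    assert committed == 20
    session.close()
    assert store.count_records() == 25


def test_record_ids_resume_after_reopen(tmp_path, box2_record):
    db = tmp_path / "p.db"
    store = init_store(db)
    session = store.open_session("run", script=DEMO_SCRIPT, policy=DEMO_POLICY)
    last = [session.record(box2_record).record_id for _ in range(3)][-1]
    session.close()
    store.close()

    store = init_store(db)
    session = store.open_session("run2", script=DEMO_SCRIPT, policy=DEMO_POLICY)
    assert session.record(box2_record).record_id == last + 1
    session.close()
    store.close()
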