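"""Append-only relational provenance store and the 3-line capture API.

The integration contract for an ETL pipeline is three library statements —
``init_store``, ``open_session``, ``close_session`` — plus exactly one
``record_element`` call per data element.  Everything else (schema
creation, dimension deduplication, batching, audit hashing) happens behind
those four calls.

Persistence is a single-file SQLite database (widely available, zero
setup); the schema mirrors the record types in :mod:`provtrace.records`.
Provenance and element rows are append-only: the public API has no update
or delete, SQLite triggers abort any UPDATE/DELETE on those tables, and a
sha256 of each provenance row is captured at insert and re-checked by
:meth:`ProvenanceStore.verify_audit`.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import sqlite3
import uuid
from pathlib import Path
from typing import Iterable, Optional

from pydantic import BaseModel

from .records import (
    STEWARD_SENTINEL,
    UTC,
    DataElementRecord,
    DataOwner,
    DataScript,
    DataSteward,
    DataStore,
    GovernancePolicy,
    LineageChain,
    PolicyStatus,
    ProvenanceRecord,
    StoreRole,
    Violation,
    ensure_utc,
    validate_element_record,
)


class StoreConfigurationError(Exception):
    """The store location is unusable (unwritable path, bad descriptor)."""


class StoreUsageError(Exception):
    """The API was called out of contract (closed session, double close...)."""


class ElementValidationError(ValueError):
    """An element record failed validation; carries the full report."""

    def __init__(self, report: list[Violation]):
        self.report = report
        detail = "; ".join(f"{v.field}: {v.reason}" for v in report)
        super().__init__(f"element record invalid — {detail}")


class StoreIntegrityError(Exception):
    """A persisted record has a dangling dimension reference or a bad hash."""


class ContinuityWarning(UserWarning):
    """A lineage chain has a broken store link (emitted, not raised)."""


_SCHEMA = """
CREATE TABLE IF NOT EXISTS policy (
    id INTEGER PRIMARY KEY,
    document_name TEXT NOT NULL,
    version TEXT NOT NULL,
    status TEXT NOT NULL,
    UNIQUE (document_name, version)
);
CREATE TABLE IF NOT EXISTS owner (
    id INTEGER PRIMARY KEY,
    department TEXT NOT NULL,
    responsible_person TEXT NOT NULL,
    UNIQUE (department, responsible_person)
);
CREATE TABLE IF NOT EXISTS steward (
    id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE
);
CREATE TABLE IF NOT EXISTS data_store (
    id INTEGER PRIMARY KEY,
    store_name TEXT NOT NULL UNIQUE,
    store_uuid TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS script (
    id INTEGER PRIMARY KEY,
    script_name TEXT NOT NULL,
    version TEXT NOT NULL,
    creator TEXT NOT NULL,
    verification_status TEXT NOT NULL,
    verified_at TEXT NOT NULL,
    UNIQUE (script_name, version)
);
CREATE TABLE IF NOT EXISTS session (
    session_id TEXT PRIMARY KEY,
    pipeline_name TEXT NOT NULL,
    script_id INTEGER NOT NULL REFERENCES script(id),
    policy_id INTEGER NOT NULL REFERENCES policy(id),
    steward_id INTEGER NOT NULL REFERENCES steward(id),
    owner_id INTEGER NOT NULL REFERENCES owner(id),
    opened_at TEXT NOT NULL,
    closed_at TEXT,
    records_written INTEGER NOT NULL DEFAULT 0
);
CREATE TABLE IF NOT EXISTS element (
    id INTEGER PRIMARY KEY,
    element_id TEXT NOT NULL,
    name TEXT NOT NULL,
    description TEXT NOT NULL,
    source_store TEXT NOT NULL,
    source_variable TEXT NOT NULL,
    destination_store TEXT NOT NULL,
    destination_variable TEXT NOT NULL,
    transformation_description TEXT NOT NULL,
    quality_check_description TEXT NOT NULL,
    status_log TEXT NOT NULL,
    sop_name TEXT NOT NULL,
    sop_version TEXT NOT NULL,
    sop_status TEXT NOT NULL,
    steward_name TEXT NOT NULL,
    value_digest TEXT
);
CREATE TABLE IF NOT EXISTS provenance (
    id INTEGER PRIMARY KEY,
    element_rowid INTEGER NOT NULL REFERENCES element(id),
    policy_id INTEGER NOT NULL REFERENCES policy(id),
    owner_id INTEGER NOT NULL REFERENCES owner(id),
    steward_id INTEGER NOT NULL REFERENCES steward(id),
    input_store_id INTEGER NOT NULL REFERENCES data_store(id),
    output_store_id INTEGER NOT NULL REFERENCES data_store(id),
    script_id INTEGER NOT NULL REFERENCES script(id),
    session_id TEXT NOT NULL REFERENCES session(session_id),
    quality_status TEXT NOT NULL,
    occurred_at TEXT NOT NULL,
    recorded_at TEXT NOT NULL,
    row_hash TEXT NOT NULL
);
CREATE INDEX IF NOT EXISTS idx_element_eid ON element(element_id);
CREATE INDEX IF NOT EXISTS idx_prov_recorded ON provenance(recorded_at);
CREATE INDEX IF NOT EXISTS idx_prov_element ON provenance(element_rowid);
CREATE TRIGGER IF NOT EXISTS provenance_no_update BEFORE UPDATE ON provenance
BEGIN SELECT RAISE(ABORT, 'provenance rows are append-only'); END;
CREATE TRIGGER IF NOT EXISTS provenance_no_delete BEFORE DELETE ON provenance
BEGIN SELECT RAISE(ABORT, 'provenance rows are append-only'); END;
CREATE TRIGGER IF NOT EXISTS element_no_update BEFORE UPDATE ON element
BEGIN SELECT RAISE(ABORT, 'element rows are append-only'); END;
CREATE TRIGGER IF NOT EXISTS element_no_delete BEFORE DELETE ON element
BEGIN SELECT RAISE(ABORT, 'element rows are append-only'); END;
"""


def _row_hash(values: Iterable[object]) -> str:
    payload = "\x1f".join("" if v is None else str(v) for v in values)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()


class SessionSummary(BaseModel):
    """What a closed session did: rows written and wall-clock duration."""

    session_id: uuid.UUID
    pipeline_name: str
    records_written: int
    opened_at: dt.datetime
    closed_at: dt.datetime

    @property
    def duration(self) -> dt.timedelta:
        return self.closed_at - self.opened_at


class CaptureSession:
    """One instrumented pipeline run: fixed dimensions, many element rows.

    Created by :meth:`ProvenanceStore.open_session`; call :meth:`record`
    once per data element and :meth:`close` when the pipeline stage ends.
    """

    def __init__(
        self,
        store: "ProvenanceStore",
        pipeline_name: str,
        script: DataScript,
        policy: GovernancePolicy,
        steward: DataSteward,
        owner: DataOwner,
    ):
        self.store = store
        self.session_id = uuid.uuid4()
        self.pipeline_name = pipeline_name
        self.script = script
        self.policy = policy
        self.steward = steward
        self.owner = owner
        self.opened_at = dt.datetime.now(UTC)
        self.closed_at: Optional[dt.datetime] = None
        self.records_written = 0
        self._pending = 0

        cur = store._conn.cursor()
        self._script_id = store._upsert(
            cur,
            "script",
            ("script_name", "version", "creator", "verification_status", "verified_at"),
            (script.script_name, script.version, script.creator,
             script.verification_status, script.verified_at.isoformat()),
            key=("script_name", "version"),
        )
        self._policy_id = store._upsert(
            cur, "policy", ("document_name", "version", "status"),
            (policy.document_name, policy.version, policy.status.value),
            key=("document_name", "version"),
        )
        self._steward_id = store._upsert(cur, "steward", ("name",), (steward.name,), key=("name",))
        self._owner_id = store._upsert(
            cur, "owner", ("department", "responsible_person"),
            (owner.department, owner.responsible_person),
            key=("department", "responsible_person"),
        )
        cur.execute(
            "INSERT INTO session (session_id, pipeline_name, script_id, policy_id,"
            " steward_id, owner_id, opened_at) VALUES (?,?,?,?,?,?,?)",
            (str(self.session_id), pipeline_name, self._script_id, self._policy_id,
             self._steward_id, self._owner_id, self.opened_at.isoformat()),
        )
        store._conn.commit()

    @property
    def closed(self) -> bool:
        return self.closed_at is not None

    def record(
        self,
        rec: DataElementRecord,
        occurred_at: dt.datetime | str | None = None,
        quality_status: str = "good",
    ) -> ProvenanceRecord:
        """Persist one element's processing step as a new provenance row.

        This is the single per-element statement of the integration
        contract.  ``occurred_at`` may be supplied by the ETL engine and
        wins over the capture clock; ``quality_status`` is a free-text
        testimony placeholder defaulting to ``"good"``.
        """
        if self.closed:
            raise StoreUsageError(f"session {self.session_id} is closed")
        report = validate_element_record(rec)
        if report:
            raise ElementValidationError(report)

        store = self.store
        recorded_at = dt.datetime.now(UTC)
        occurred = ensure_utc(occurred_at) or recorded_at
        in_store_id = store._store_dim(rec.source_store)
        out_store_id = store._store_dim(rec.destination_store)

        cur = store._conn.cursor()
        cur.execute(
            "INSERT INTO element (element_id, name, description, source_store,"
            " source_variable, destination_store, destination_variable,"
            " transformation_description, quality_check_description, status_log,"
            " sop_name, sop_version, sop_status, steward_name, value_digest)"
            " VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
            (rec.element_id, rec.name, rec.description, rec.source_store,
             rec.source_variable, rec.destination_store, rec.destination_variable,
             rec.transformation_description, rec.quality_check_description,
             rec.status_log, rec.sop_name, rec.sop_version, rec.sop_status,
             rec.steward_name, rec.value_digest),
        )
        element_rowid = cur.lastrowid
        record_id = store._next_record_id
        store._next_record_id += 1
        row = (record_id, element_rowid, self._policy_id, self._owner_id,
               self._steward_id, in_store_id, out_store_id, self._script_id,
               str(self.session_id), quality_status,
               occurred.isoformat(), recorded_at.isoformat())
        cur.execute(
            "INSERT INTO provenance (id, element_rowid, policy_id, owner_id,"
            " steward_id, input_store_id, output_store_id, script_id, session_id,"
            " quality_status, occurred_at, recorded_at, row_hash)"
            " VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?)",
            row + (_row_hash(row),),
        )
        self.records_written += 1
        self._pending += 1
        if self._pending >= store.batch_size:
            self.flush()

        return ProvenanceRecord(
            record_id=record_id,
            element=rec,
            policy=self.policy,
            owner=self.owner,
            steward=self.steward,
            input_store=DataStore(store_name=rec.source_store, role=StoreRole.input),
            output_store=DataStore(store_name=rec.destination_store, role=StoreRole.output),
            script=self.script,
            quality_status=quality_status,
            occurred_at=occurred,
            recorded_at=recorded_at,
        )

    def flush(self) -> None:
        """Commit any batched rows; durable once this returns."""
        self.store._conn.commit()
        self._pending = 0

    def close(self) -> SessionSummary:
        """Seal the session; further ``record`` calls are rejected."""
        if self.closed:
            raise StoreUsageError(f"session {self.session_id} already closed")
        self.closed_at = dt.datetime.now(UTC)
        # session bookkeeping rows are mutable on purpose; only provenance
        # and element rows carry the append-only triggers
        self.store._conn.execute(
            "UPDATE session SET closed_at = ?, records_written = ? WHERE session_id = ?",
            (self.closed_at.isoformat(), self.records_written, str(self.session_id)),
        )
        self.flush()
        return SessionSummary(
            session_id=self.session_id,
            pipeline_name=self.pipeline_name,
            records_written=self.records_written,
            opened_at=self.opened_at,
            closed_at=self.closed_at,
        )


class ProvenanceStore:
    """Handle to an initialized provenance database.

    Parameters
    ----------
    location:
        Path of the SQLite file, or ``":memory:"`` for an ephemeral store.
    batch_size:
        Rows per transparent commit inside tight ``record`` loops; the
        per-element call stays a single statement either way.
    """

    def __init__(self, location: str | Path, batch_size: int = 1000):
        self.location = str(location)
        self.batch_size = max(1, int(batch_size))
        try:
            self._conn = sqlite3.connect(self.location)
            self._conn.execute("PRAGMA journal_mode=WAL")
            self._conn.execute("PRAGMA synchronous=NORMAL")
            self._conn.execute("PRAGMA foreign_keys=ON")
            self._conn.executescript(_SCHEMA)
            self._conn.commit()
        except sqlite3.Error as exc:
            raise StoreConfigurationError(
                f"cannot initialize provenance store at {self.location!r}: {exc}"
            ) from exc
        self._store_ids: dict[str, int] = {}
        row = self._conn.execute("SELECT COALESCE(MAX(id), 0) FROM provenance").fetchone()
        self._next_record_id = row[0] + 1

    # -- dimension helpers -------------------------------------------------

    def _upsert(self, cur: sqlite3.Cursor, table: str, cols: tuple[str, ...],
                values: tuple, key: tuple[str, ...]) -> int:
        cur.execute(
            f"INSERT OR IGNORE INTO {table} ({', '.join(cols)})"
            f" VALUES ({', '.join('?' * len(cols))})", values)
        where = " AND ".join(f"{k} = ?" for k in key)
        keyvals = tuple(values[cols.index(k)] for k in key)
        cur.execute(f"SELECT id FROM {table} WHERE {where}", keyvals)
        return cur.fetchone()[0]

    def _store_dim(self, store_name: str) -> int:
        sid = self._store_ids.get(store_name)
        if sid is None:
            cur = self._conn.cursor()
            cur.execute(
                "INSERT OR IGNORE INTO data_store (store_name, store_uuid) VALUES (?, ?)",
                (store_name, str(DataStore(store_name=store_name, role=StoreRole.input).store_id)),
            )
            cur.execute("SELECT id FROM data_store WHERE store_name = ?", (store_name,))
            sid = cur.fetchone()[0]
            self._store_ids[store_name] = sid
        return sid

    # -- public API --------------------------------------------------------

    def open_session(
        self,
        pipeline_name: str,
        script: DataScript,
        policy: GovernancePolicy,
        steward: DataSteward | str | None = None,
        owner: DataOwner | None = None,
    ) -> CaptureSession:
        """Start an instrumented pipeline run with its fixed dimensions.

        Dimension rows (script, policy, steward, owner) are deduplicated by
        natural key, so repeated runs under the same SOP share one row.  A
        missing steward becomes the ``"no name given"`` sentinel.
        """
        if isinstance(steward, str):
            steward = DataSteward(name=steward)
        elif steward is None:
            steward = DataSteward(name=STEWARD_SENTINEL)
        if owner is None:
            owner = DataOwner(department="unknown")
        return CaptureSession(self, pipeline_name, script, policy, steward, owner)

    def count_records(
        self,
        element_name: str | None = None,
        element_id: str | None = None,
        session: CaptureSession | SessionSummary | None = None,
    ) -> int:
        """Exact provenance row count, optionally filtered by element type
        (``name``), element id, or capturing session."""
        sql = ["SELECT COUNT(*) FROM provenance p JOIN element e ON e.id = p.element_rowid"]
        clauses, params = [], []
        if element_name is not None:
            clauses.append("e.name = ?")
            params.append(element_name)
        if element_id is not None:
            clauses.append("e.element_id = ?")
            params.append(element_id)
        if session is not None:
            clauses.append("p.session_id = ?")
            params.append(str(session.session_id))
        if clauses:
            sql.append("WHERE " + " AND ".join(clauses))
        return self._conn.execute(" ".join(sql), params).fetchone()[0]

    _RECORD_SQL = (
        "SELECT p.id, p.quality_status, p.occurred_at, p.recorded_at,"
        " e.element_id, e.name, e.description, e.source_store, e.source_variable,"
        " e.destination_store, e.destination_variable, e.transformation_description,"
        " e.quality_check_description, e.status_log, e.sop_name, e.sop_version,"
        " e.sop_status, e.steward_name, e.value_digest,"
        " pol.document_name, pol.version, pol.status,"
        " ow.department, ow.responsible_person, st.name,"
        " sc.script_name, sc.version, sc.creator, sc.verification_status, sc.verified_at,"
        " ins.store_name, outs.store_name"
        " FROM provenance p"
        " JOIN element e ON e.id = p.element_rowid"
        " JOIN policy pol ON pol.id = p.policy_id"
        " JOIN owner ow ON ow.id = p.owner_id"
        " JOIN steward st ON st.id = p.steward_id"
        " JOIN script sc ON sc.id = p.script_id"
        " JOIN data_store ins ON ins.id = p.input_store_id"
        " JOIN data_store outs ON outs.id = p.output_store_id"
    )

    def _hydrate(self, row: tuple) -> ProvenanceRecord:
        return ProvenanceRecord(
            record_id=row[0],
            quality_status=row[1],
            occurred_at=row[2],
            recorded_at=row[3],
            element=DataElementRecord(
                element_id=row[4], name=row[5], description=row[6],
                source_store=row[7], source_variable=row[8],
                destination_store=row[9], destination_variable=row[10],
                transformation_description=row[11], quality_check_description=row[12],
                status_log=row[13], sop_name=row[14], sop_version=row[15],
                sop_status=row[16], steward_name=row[17], value_digest=row[18],
            ),
            policy=GovernancePolicy(document_name=row[19], version=row[20],
                                    status=PolicyStatus(row[21])),
            owner=DataOwner(department=row[22], responsible_person=row[23]),
            steward=DataSteward(name=row[24]),
            script=DataScript(script_name=row[25], version=row[26], creator=row[27],
                              verification_status=row[28], verified_at=row[29]),
            input_store=DataStore(store_name=row[30], role=StoreRole.input),
            output_store=DataStore(store_name=row[31], role=StoreRole.output),
        )

    def fetch_records(
        self,
        element_id: str | None = None,
        limit: int | None = None,
    ) -> list[ProvenanceRecord]:
        """Hydrate persisted rows back into fully-resolved records,
        ordered by recorded_at then record id (read-only)."""
        sql = self._RECORD_SQL
        params: list = []
        if element_id is not None:
            sql += " WHERE e.element_id = ?"
            params.append(element_id)
        sql += " ORDER BY p.recorded_at, p.id"
        if limit is not None:
            sql += " LIMIT ?"
            params.append(limit)
        return [self._hydrate(r) for r in self._conn.execute(sql, params)]

    def trace_element(self, element_id: str) -> LineageChain:
        """Reconstruct one element's full processing history.

        An unknown id yields an empty chain.  If the chain violates store
        continuity (the element left store X but next appeared from Y), a
        :class:`ContinuityWarning` naming each broken link is emitted and
        the chain is still returned for inspection.
        """
        chain = LineageChain(element_id=element_id, steps=self.fetch_records(element_id=element_id))
        breaks = chain.continuity_breaks()
        if breaks:
            import warnings

            detail = "; ".join(
                f"step {k}: output store {out!r} != next input store {inp!r}"
                for k, out, inp in breaks
            )
            warnings.warn(ContinuityWarning(f"lineage of {element_id!r} broken — {detail}"))
        return chain

    def verify_audit(self) -> list[int]:
        """Re-hash every provenance row against its insert-time sha256.

        Returns the ids of tampered rows; an empty list means the
        append-only audit passes.
        """
        bad: list[int] = []
        for row in self._conn.execute(
            "SELECT id, element_rowid, policy_id, owner_id, steward_id,"
            " input_store_id, output_store_id, script_id, session_id,"
            " quality_status, occurred_at, recorded_at, row_hash FROM provenance"
        ):
            if _row_hash(row[:-1]) != row[-1]:
                bad.append(row[0])
        return bad

    def verify_references(self) -> list[int]:
        """Full join scan for dangling dimension references; returns the
        ids of provenance rows whose references do not all resolve."""
        resolved = {r[0] for r in self._conn.execute(
            "SELECT p.id FROM provenance p" + self._RECORD_SQL.split("FROM provenance p", 1)[1]
        )}
        every = {r[0] for r in self._conn.execute("SELECT id FROM provenance")}
        return sorted(every - resolved)

    def close(self) -> None:
        self._conn.commit()
        self._conn.close()

    def __enter__(self) -> "ProvenanceStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def init_store(location: str | Path, batch_size: int = 1000) -> ProvenanceStore:
    """Create or open a provenance store; schema creation is idempotent."""
    return ProvenanceStore(location, batch_size=batch_size)


def open_session(store: ProvenanceStore, pipeline_name: str, script: DataScript,
                 policy: GovernancePolicy, steward: DataSteward | str | None = None,
                 owner: DataOwner | None = None) -> CaptureSession:
    """Functional alias for :meth:`ProvenanceStore.open_session`."""
    if not isinstance(store, ProvenanceStore):
        raise StoreUsageError("open_session requires an initialized store handle")
    return store.open_session(pipeline_name, script, policy, steward, owner)


def record_element(session: CaptureSession, rec: DataElementRecord, **kw) -> ProvenanceRecord:
    """Functional alias for :meth:`CaptureSession.record`."""
    return session.record(rec, **kw)


def close_session(session: CaptureSession) -> SessionSummary:
    """Functional alias for :meth:`CaptureSession.close`."""
    return session.close()
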