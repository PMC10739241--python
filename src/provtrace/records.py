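"""Typed metadata records for element-level provenance capture.

The vocabulary follows the contextual/technical metadata levels used in
clinical data integration centres (DICs): governance (SOP name/version/
status), owner (department / responsible person), steward, store (input or
output system), script (the ETL program and its verification status), the
data element itself, and the provenance row that ties one processing step
of one element to all of the above.

Only metadata about elements is ever held here — names, descriptions,
store and variable names — never patient values.  Callers who need to bind
a trace to a concrete value may supply an opaque ``value_digest``.
"""

from __future__ import annotations

import datetime as dt
import re
import uuid
from enum import Enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

UTC = dt.timezone.utc

#: Sentinel stored whenever no steward name is supplied; it is a real stored
#: string, never an absent value, so that responsibility gaps stay visible.
STEWARD_SENTINEL = "no name given"

#: Identifier system under which store UUIDs are rendered in exports.
URN_SYSTEM = "urn:ietf:rfc:3986"

#: Namespace for deterministic store UUIDs (uuid5 of the store name).
_STORE_UUID_NS = uuid.UUID("af4c9a56-5a4b-4a0e-9f50-1c6b6f1b2a77")


class StatusLogError(ValueError):
    """Raised when a status_log string cannot be parsed into (status, date)."""


def ensure_utc(value: dt.datetime | str | None) -> Optional[dt.datetime]:
    """Normalize a timestamp to an aware ISO-8601 datetime in UTC.

    Accepts aware or naive datetimes and ISO-like strings (including the
    ``"2023-02-03 06:01:34"`` space-separated form); naive inputs are taken
    to be UTC.  Unambiguous, contemporaneous time is an ALCOA+ requirement,
    so everything persisted goes through here.
    """
    if value is None:
        return None
    if isinstance(value, str):
        value = dt.datetime.fromisoformat(value)
    if value.tzinfo is None:
        return value.replace(tzinfo=UTC)
    return value.astimezone(UTC)


_STATUS_LOG_RE = re.compile(r"^\s*(?P<status>[A-Za-z][\w-]*)\s+date\s+(?P<date>\S+)\s*$")
_STATUS_DATE_FORMATS = ("%d.%b%Y", "%d.%b.%Y", "%d.%m.%Y", "%Y-%m-%d")


def parse_status_log(text: str) -> tuple[str, dt.date]:
    """Parse a status_log string into ``(status_token, date)``.

    The canonical shape is ``"passed date 12.May2022"`` — a verification
    status token followed by the literal word ``date`` and a day.  A few
    common date spellings are accepted; anything else raises
    :class:`StatusLogError`.
    """
    m = _STATUS_LOG_RE.match(text or "")
    if not m:
        raise StatusLogError(f"status_log not of the form '<status> date <date>': {text!r}")
    raw = m.group("date")
    for fmt in _STATUS_DATE_FORMATS:
        try:
            return m.group("status"), dt.datetime.strptime(raw, fmt).date()
        except ValueError:
            continue
    raise StatusLogError(f"status_log date not parseable: {raw!r}")


class Violation(BaseModel):
    """One invariant violation found while validating a record."""

    model_config = ConfigDict(frozen=True)

    field: str
    reason: str


class DataElementRecord(BaseModel):
    """One data element's metadata for one processing step.

    This is the single input shape an instrumented pipeline hands to the
    capture API: where the element came from, where it went, what was done
    to it, how it was checked, and which governance artefacts applied.
    """

    model_config = ConfigDict(validate_assignment=True)

    element_id: str
    name: str
    description: str = ""
    source_store: str
    source_variable: str = ""
    destination_store: str
    destination_variable: str = ""
    transformation_description: str = "copy"
    quality_check_description: str = ""
    status_log: str = ""
    sop_name: str = ""
    sop_version: str = ""
    sop_status: str = ""
    steward_name: str = STEWARD_SENTINEL
    value_digest: Optional[str] = None


def validate_element_record(rec: DataElementRecord) -> list[Violation]:
    """Check a record against the storable-element invariants.

    Violations are data, not exceptions: the result lists every problem
    with field name and reason, and an empty list means the record may be
    persisted.
    """
    report: list[Violation] = []
    for field in ("element_id", "name", "source_store", "destination_store"):
        if not getattr(rec, field).strip():
            report.append(Violation(field=field, reason="must be non-empty"))
    try:
        parse_status_log(rec.status_log)
    except StatusLogError as exc:
        report.append(Violation(field="status_log", reason=str(exc)))
    return report


class PolicyStatus(str, Enum):
    draft = "draft"
    approved = "approved"
    retired = "retired"


class GovernancePolicy(BaseModel):
    """A governance document (SOP or regulation) by name, version and status."""

    model_config = ConfigDict(frozen=True)

    document_name: str
    version: str
    status: PolicyStatus = PolicyStatus.approved

    @property
    def natural_key(self) -> tuple[str, str]:
        return (self.document_name, self.version)


class DataOwner(BaseModel):
    """The department and/or responsible person owning the source patient data."""

    model_config = ConfigDict(frozen=True)

    department: str = ""
    responsible_person: str = ""

    @model_validator(mode="after")
    def _one_field_set(self) -> "DataOwner":
        if not (self.department.strip() or self.responsible_person.strip()):
            raise ValueError("at least one of department/responsible_person must be non-empty")
        return self

    @property
    def label(self) -> str:
        return " / ".join(p for p in (self.department, self.responsible_person) if p) or "unknown"


class DataSteward(BaseModel):
    """The person maintaining the pipeline; absent names become the sentinel."""

    model_config = ConfigDict(frozen=True)

    name: str = STEWARD_SENTINEL

    @field_validator("name", mode="before")
    @classmethod
    def _sentinel_for_missing(cls, v: object) -> object:
        if v is None or (isinstance(v, str) and not v.strip()):
            return STEWARD_SENTINEL
        return v


class StoreRole(str, Enum):
    input = "input"
    output = "output"


class DataStore(BaseModel):
    """An input or output data system (staging area, DWH, repository, ...).

    ``store_id`` defaults to a uuid5 of the store name so the same system
    always carries the same identifier across sessions and exports.
    """

    model_config = ConfigDict(frozen=True)

    store_name: str
    role: StoreRole
    store_id: uuid.UUID = None  # type: ignore[assignment]

    @model_validator(mode="before")
    @classmethod
    def _default_uuid(cls, data: dict) -> dict:
        if isinstance(data, dict) and data.get("store_id") is None:
            data = dict(data)
            data["store_id"] = uuid.uuid5(_STORE_UUID_NS, str(data.get("store_name", "")))
        return data

    @property
    def urn(self) -> str:
        """The UUID rendered under the URN scheme used by the exporters."""
        return f"urn:uuid:{self.store_id}"


class DataScript(BaseModel):
    """The ETL program: name, version, creator, and its verification state.

    Verification status and timestamp are mandatory — an unverified script
    is recorded as such, never silently.
    """

    model_config = ConfigDict(frozen=True)

    script_name: str
    version: str
    creator: str = ""
    verification_status: str = "verified"
    verified_at: dt.datetime = Field(default_factory=lambda: dt.datetime.now(UTC))

    @field_validator("verification_status")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("verification_status must be populated")
        return v

    @field_validator("verified_at", mode="after")
    @classmethod
    def _utc(cls, v: dt.datetime) -> dt.datetime:
        return ensure_utc(v)

    @property
    def natural_key(self) -> tuple[str, str]:
        return (self.script_name, self.version)


class ProvenanceRecord(BaseModel):
    """One persisted, immutable trace row: one element, one processing step.

    Links the element record to governance, owner, steward, input/output
    stores and script, with the quality testimony and both timestamps
    (when the ETL action happened vs. when the trace was captured).
    """

    model_config = ConfigDict(frozen=True)

    record_id: int
    element: DataElementRecord
    policy: GovernancePolicy
    owner: DataOwner
    steward: DataSteward
    input_store: DataStore
    output_store: DataStore
    script: DataScript
    quality_status: str = "good"
    occurred_at: dt.datetime
    recorded_at: dt.datetime

    @field_validator("occurred_at", "recorded_at", mode="after")
    @classmethod
    def _utc(cls, v: dt.datetime) -> dt.datetime:
        return ensure_utc(v)

    @model_validator(mode="after")
    def _contemporaneous(self) -> "ProvenanceRecord":
        if self.recorded_at < self.occurred_at:
            raise ValueError("recorded_at must be >= occurred_at")
        return self


class LineageChain(BaseModel):
    """Time-ordered trace of one element across pipeline stages."""

    element_id: str
    steps: list[ProvenanceRecord] = Field(default_factory=list)

    @model_validator(mode="after")
    def _ordered(self) -> "LineageChain":
        times = [s.recorded_at for s in self.steps]
        if any(a > b for a, b in zip(times, times[1:])):
            raise ValueError("steps must be sorted by recorded_at, non-decreasing")
        return self

    def __len__(self) -> int:
        return len(self.steps)

    def continuity_breaks(self) -> list[tuple[int, str, str]]:
        """Store-continuity check between consecutive steps.

        Returns ``(step_index, previous_output_store, next_input_store)``
        for every link where the element left one store and reappeared
        from a different one; empty list means the chain is continuous.
        """
        breaks: list[tuple[int, str, str]] = []
        for k in range(1, len(self.steps)):
            prev_out = self.steps[k - 1].output_store.store_name
            next_in = self.steps[k].input_store.store_name
            if prev_out != next_in:
                breaks.append((k, prev_out, next_in))
        return breaks

    @property
    def is_continuous(self) -> bool:
        return not self.continuity_breaks()
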