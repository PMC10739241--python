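"""HL7 FHIR R5 Provenance resource: model, validation and mapping.

The pydantic models below encode the R5 Provenance structure definition —
required elements (``target`` 1..*, ``agent`` 1..* each with ``who``),
the closed value set for ``entity.role``, FHIR ``dateTime``/``instant``
lexical forms, and ``extra="forbid"`` so misspelled elements (a classic
source of silently-invalid resources) are rejected.  Constructing a
:class:`Provenance` *is* validation; :func:`validate_fhir` wraps that for
documents from elsewhere.

The mapping from a provenance record follows the metadata levels:
governance → ``policy`` + the DIC ``location`` reference, owner →
``authorization`` (v3-ActReason ``TRANSRCH``, research use) and the
steward's ``onBehalfOf``, steward → ``agent.who.display``, stores →
``entity.what`` / ``target`` with ``urn:ietf:rfc:3986``-system
identifiers, script → ``activity`` (ISO 21089 lifecycle code) +
``basedOn``, and the trace row itself → ``id`` / ``occurredDateTime`` /
``recorded``.  Patient/encounter references are emitted only when the
caller supplies pseudonymous references — never synthesized.
"""

from __future__ import annotations

import re
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .records import URN_SYSTEM, ProvenanceRecord

V3_ACT_REASON = "http://terminology.hl7.org/CodeSystem/v3-ActReason"
ISO_21089_LIFECYCLE = "http://terminology.hl7.org/CodeSystem/iso-21089-lifecycle"
PARTICIPANT_TYPE = "http://terminology.hl7.org/CodeSystem/provenance-participant-type"

#: Research-use authorization code emitted for the data owner level.
TRANSRCH_CODE = "TRANSRCH"

_FHIR_DATETIME_RE = re.compile(
    r"^\d{4}(-\d{2}(-\d{2}(T\d{2}:\d{2}:\d{2}(\.\d+)?(Z|[+-]\d{2}:\d{2}))?)?)?$"
)
_FHIR_INSTANT_RE = re.compile(
    r"^\d{4}-\d{2}-\d{2}T\d{2}:\d{2}:\d{2}(\.\d+)?(Z|[+-]\d{2}:\d{2})$"
)

#: transformation_description → ISO 21089 record-lifecycle code.  The code
#: system has no entry for most free-text descriptions, so unknown ones
#: fall back to the generic "transform" code with the description kept in
#: CodeableConcept.text.
_LIFECYCLE_LOOKUP = {
    "copy": ("originate", "Originate/Retain Record Lifecycle Event"),
    "averaging": ("transform", "Transform/Translate Record Lifecycle Event"),
    "transform": ("transform", "Transform/Translate Record Lifecycle Event"),
    "merge": ("merge", "Merge Record Lifecycle Event"),
    "pseudonymize": ("deidentify", "De-Identify (Anononymize) Record Lifecycle Event"),
    "transmit": ("transmit", "Transmit Record Lifecycle Event"),
}
_LIFECYCLE_DEFAULT = ("transform", "Transform/Translate Record Lifecycle Event")


class FhirValidationError(ValueError):
    """A document failed R5 Provenance validation; message carries the path."""


class _Element(BaseModel):
    model_config = ConfigDict(extra="forbid", populate_by_name=True)


class Coding(_Element):
    system: Optional[str] = None
    code: Optional[str] = None
    display: Optional[str] = None


class CodeableConcept(_Element):
    coding: list[Coding] = Field(default_factory=list)
    text: Optional[str] = None


class Identifier(_Element):
    use: Optional[str] = None
    system: Optional[str] = None
    value: Optional[str] = None


class Reference(_Element):
    reference: Optional[str] = None
    type: Optional[str] = None
    identifier: Optional[Identifier] = None
    display: Optional[str] = None

    @model_validator(mode="after")
    def _not_empty(self) -> "Reference":
        if not (self.reference or self.identifier or self.display or self.type):
            raise ValueError("Reference must carry reference, identifier, display or type")
        return self


class CodeableReference(_Element):
    concept: Optional[CodeableConcept] = None
    reference: Optional[Reference] = None


class ProvenanceAgent(_Element):
    type: Optional[CodeableConcept] = None
    role: list[CodeableConcept] = Field(default_factory=list)
    who: Reference
    onBehalfOf: Optional[Reference] = None


class ProvenanceEntity(_Element):
    role: Literal["revision", "quotation", "source", "instantiates", "removal"]
    what: Reference
    agent: list[ProvenanceAgent] = Field(default_factory=list)


class Provenance(_Element):
    """FHIR R5 Provenance resource (signature element not modelled)."""

    resourceType: Literal["Provenance"] = "Provenance"
    id: Optional[str] = None
    target: list[Reference] = Field(min_length=1)
    occurredDateTime: Optional[str] = None
    recorded: Optional[str] = None
    policy: list[str] = Field(default_factory=list)
    location: Optional[Reference] = None
    authorization: list[CodeableReference] = Field(default_factory=list)
    activity: Optional[CodeableConcept] = None
    basedOn: list[Reference] = Field(default_factory=list)
    patient: Optional[Reference] = None
    encounter: Optional[Reference] = None
    agent: list[ProvenanceAgent] = Field(min_length=1)
    entity: list[ProvenanceEntity] = Field(default_factory=list)

    @field_validator("occurredDateTime")
    @classmethod
    def _datetime_lexical(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and not _FHIR_DATETIME_RE.match(v):
            raise ValueError(f"not a FHIR dateTime: {v!r}")
        return v

    @field_validator("recorded")
    @classmethod
    def _instant_lexical(cls, v: Optional[str]) -> Optional[str]:
        if v is not None and not _FHIR_INSTANT_RE.match(v):
            raise ValueError(f"not a FHIR instant: {v!r}")
        return v


def validate_fhir(document: dict) -> Provenance:
    """Validate a JSON-shaped document against the R5 Provenance structure.

    Returns the parsed resource or raises :class:`FhirValidationError`
    whose message names the failing element path(s).
    """
    try:
        return Provenance.model_validate(document)
    except Exception as exc:  # pydantic.ValidationError
        raise FhirValidationError(str(exc)) from exc


def lifecycle_activity(transformation_description: str) -> CodeableConcept:
    """ISO 21089 lifecycle coding for a free-text transformation description."""
    code, display = _LIFECYCLE_LOOKUP.get(
        transformation_description.strip().lower(), _LIFECYCLE_DEFAULT)
    return CodeableConcept(
        coding=[Coding(system=ISO_21089_LIFECYCLE, code=code, display=display)],
        text=transformation_description,
    )


def _fhir_instant(ts) -> str:
    return ts.isoformat()


def map_to_fhir(
    record: ProvenanceRecord,
    policy_base: str = "http://example.org/policy/",
    patient: Optional[Reference] = None,
    encounter: Optional[Reference] = None,
) -> Provenance:
    """Map one resolved provenance record to a valid R5 Provenance resource."""
    el = record.element
    policy_uri = (
        policy_base
        + "/".join(p for p in (record.policy.document_name, record.policy.version) if p)
    ).replace(" ", "%20")
    target = Reference(
        identifier=Identifier(system=URN_SYSTEM, value=str(record.output_store.store_id)),
        display=record.output_store.store_name,
    )
    steward_agent = ProvenanceAgent(
        type=CodeableConcept(coding=[Coding(system=PARTICIPANT_TYPE, code="custodian")]),
        who=Reference(display=record.steward.name),
        onBehalfOf=Reference(display=record.owner.label),
    )
    script_agent = ProvenanceAgent(
        type=CodeableConcept(coding=[Coding(system=PARTICIPANT_TYPE, code="performer")]),
        who=Reference(display=f"{record.script.script_name} {record.script.version}"),
    )
    source_entity = ProvenanceEntity(
        role="source",
        what=Reference(
            identifier=Identifier(system=URN_SYSTEM, value=str(record.input_store.store_id)),
            display=record.input_store.store_name,
        ),
    )
    return Provenance(
        id=str(record.record_id),
        target=[target],
        occurredDateTime=_fhir_instant(record.occurred_at),
        recorded=_fhir_instant(record.recorded_at),
        policy=[policy_uri],
        location=Reference(reference="DIC"),
        authorization=[CodeableReference(concept=CodeableConcept(
            coding=[Coding(system=V3_ACT_REASON, code=TRANSRCH_CODE)]))],
        activity=lifecycle_activity(el.transformation_description),
        basedOn=[Reference(reference="ServiceRequest")],
        patient=patient,
        encounter=encounter,
        agent=[steward_agent, script_agent],
        entity=[source_entity],
    )
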