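"""Synthetic element catalogue and demo ETL driver.

Seven fixed data-element types mimic the composition of a typical clinical
data-integration repository.  Type 1 is the canonical systolic blood
pressure definition; the other six (diastolic BP, heart rate, serum
potassium, ICD diagnosis, medication order, admission date) are
illustrative templates invented for this package.  Only metadata is
generated — element names, store names, check descriptions — never
patient values, so the generator emulates catalogue shape and scale, not
clinical distributions.

The demo ETL walks every element through the standard DIC integration
stages (staging → data warehouse → FHIR server → research data
repository), recording one provenance row per element per stage hop.
"""

from __future__ import annotations

import json
import random
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from pydantic import BaseModel, ConfigDict

from .records import DataElementRecord, DataOwner, DataScript, DataSteward, GovernancePolicy
from .store import ProvenanceStore, SessionSummary

#: Standard integration stages of a data integration centre.
DEFAULT_STAGES = ("staging", "dwh", "fhir", "rdr")

#: Fixed demo dimensions used by the demo pipeline.
DEMO_SCRIPT = DataScript(script_name="etl_st.py", version="v1", creator="MZ",
                         verification_status="verified")
DEMO_POLICY = GovernancePolicy(document_name="DIC_ETL-ST.pdf", version="v1",
                               status="approved")
DEMO_STEWARD = DataSteward(name="Hr. Koch")
DEMO_OWNER = DataOwner(department="DIC", responsible_person="Dr. Weber")


class ElementTypeDef(BaseModel):
    """One of the built-in element templates, numbered 1..7."""

    model_config = ConfigDict(frozen=True)

    index: int
    template: DataElementRecord


_BOX_TEMPLATE = DataElementRecord(
    element_id="syst_blood_pressure",
    name="syst_blood_pressure",
    description="Systolic Blood Pressure",
    source_store="stg_sap_vitalis",
    source_variable="SysBP",
    destination_store="dwh_vitalis",
    destination_variable="SBP",
    transformation_description="copy",
    quality_check_description="range check 80-160",
    status_log="passed date 12.May2022",
    sop_name="SOP p",
    sop_version="v1.5",
    sop_status="approved",
    steward_name="no name given",
)

_EXTRA_TEMPLATES = [
    # illustrative clinical element templates (synthetic, not from any source system)
    dict(element_id="diast_blood_pressure", name="diast_blood_pressure",
         description="Diastolic Blood Pressure", source_store="stg_sap_vitalis",
         source_variable="DiaBP", destination_store="dwh_vitalis",
         destination_variable="DBP", transformation_description="copy",
         quality_check_description="range check 40-120",
         status_log="passed date 12.May2022", sop_name="SOP p", sop_version="v1.5",
         sop_status="approved"),
    dict(element_id="heart_rate", name="heart_rate", description="Heart Rate",
         source_store="stg_sap_vitalis", source_variable="HR",
         destination_store="dwh_vitalis", destination_variable="HR_BPM",
         transformation_description="copy", quality_check_description="range check 30-220",
         status_log="passed date 13.May2022", sop_name="SOP p", sop_version="v1.5",
         sop_status="approved"),
    dict(element_id="lab_potassium", name="lab_potassium",
         description="Serum Potassium", source_store="stg_lab_swisslab",
         source_variable="K_SER", destination_store="dwh_lab",
         destination_variable="POTASSIUM", transformation_description="unit conversion mmol/l",
         quality_check_description="range check 2.5-7.0",
         status_log="passed date 02.Jun2022", sop_name="SOP lab", sop_version="v2.0",
         sop_status="approved"),
    dict(element_id="icd_diagnosis", name="icd_diagnosis",
         description="ICD-10-GM Diagnosis Code", source_store="stg_sap_diagnosis",
         source_variable="ICD_CODE", destination_store="dwh_diagnosis",
         destination_variable="ICD10GM", transformation_description="terminology mapping",
         quality_check_description="code list check ICD-10-GM 2022",
         status_log="passed date 20.Jun2022", sop_name="SOP dx", sop_version="v1.0",
         sop_status="approved"),
    dict(element_id="medication_order", name="medication_order",
         description="Medication Order", source_store="stg_meona_medication",
         source_variable="ORDER_ID", destination_store="dwh_medication",
         destination_variable="MED_ORDER", transformation_description="copy",
         quality_check_description="ATC code present",
         status_log="passed date 01.Jul2022", sop_name="SOP med", sop_version="v1.1",
         sop_status="approved"),
    dict(element_id="admission_date", name="admission_date",
         description="Hospital Admission Date", source_store="stg_sap_case",
         source_variable="ADM_DT", destination_store="dwh_case",
         destination_variable="ADMISSION_DATE", transformation_description="date normalization",
         quality_check_description="not in future", status_log="passed date 05.Jul2022",
         sop_name="SOP case", sop_version="v1.0", sop_status="approved"),
]


def builtin_element_types() -> list[ElementTypeDef]:
    """The 7 built-in element type definitions; type 1 is systolic BP."""
    defs = [ElementTypeDef(index=1, template=_BOX_TEMPLATE)]
    defs += [ElementTypeDef(index=i, template=DataElementRecord(**t))
             for i, t in enumerate(_EXTRA_TEMPLATES, start=2)]
    return defs


def generate_elements(
    types: Sequence[ElementTypeDef],
    n_per_type: int,
    seed: int = 0,
    uuid_ids: bool = False,
) -> Iterator[DataElementRecord]:
    """Yield ``n_per_type`` element records per type, ids collision-free.

    Default ids are ``{type_name}_{ordinal:04d}`` (1-based), which makes
    the stream trivially seed-deterministic and reproducible; pass
    ``uuid_ids=True`` for seeded random UUID identifiers instead.
    """
    if n_per_type < 0:
        raise ValueError(f"n_per_type must be >= 0, got {n_per_type}")
    rng = random.Random(seed)
    for tdef in types:
        for ordinal in range(1, n_per_type + 1):
            if uuid_ids:
                eid = f"{tdef.template.name}_{rng.getrandbits(128):032x}"
            else:
                eid = f"{tdef.template.name}_{ordinal:04d}"
            yield tdef.template.model_copy(update={"element_id": eid})


def dump_jsonl(records: Iterable[DataElementRecord], path: str | Path) -> int:
    """Dump element records as JSON-Lines; returns the record count."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.model_dump_json() + "\n")
            n += 1
    return n


def load_jsonl(path: str | Path) -> list[DataElementRecord]:
    """Load element records from a JSON-Lines dump."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                out.append(DataElementRecord.model_validate(json.loads(line)))
    return out


def run_demo_etl(
    store: ProvenanceStore,
    elements: Iterable[DataElementRecord],
    stages: Sequence[str] = DEFAULT_STAGES,
    script: DataScript = DEMO_SCRIPT,
    policy: GovernancePolicy = DEMO_POLICY,
    steward: DataSteward = DEMO_STEWARD,
    owner: DataOwner = DEMO_OWNER,
) -> list[SessionSummary]:
    """Drive every element through consecutive stage pairs.

    For k stages each element is recorded k-1 times (one session per stage
    transition, source/destination overridden to that pair), so n elements
    yield n*(k-1) provenance records and a fully reconstructable lineage
    chain per element.
    """
    stages = list(stages)
    if len(stages) < 2:
        raise ValueError("need at least one stage transition (>= 2 stage names)")
    elements = list(elements)
    summaries: list[SessionSummary] = []
    for src, dst in zip(stages, stages[1:]):
        session = store.open_session(
            pipeline_name=f"demo_etl:{src}->{dst}",
            script=script, policy=policy, steward=steward, owner=owner,
        )
        for el in elements:
            session.record(el.model_copy(update={
                "source_store": src,
                "destination_store": dst,
                "source_variable": el.source_variable,
                "destination_variable": el.destination_variable,
            }))
        summaries.append(session.close())
    return summaries
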