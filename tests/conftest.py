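import pytest

from provtrace import DataElementRecord, init_store
from provtrace.fixtures import DEMO_OWNER, DEMO_POLICY, DEMO_SCRIPT, DEMO_STEWARD


@pytest.fixture
def box2_record() -> DataElementRecord:
    """The canonical systolic blood pressure element definition."""
    return DataElementRecord(
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


@pytest.fixture
def store(tmp_path):
    s = init_store(tmp_path / "provenance.db")
    yield s
    s.close()


@pytest.fixture
def session(store):
    return store.open_session(
        pipeline_name="test_pipeline",
        script=DEMO_SCRIPT,
        policy=DEMO_POLICY,
        steward=DEMO_STEWARD,
        owner=DEMO_OWNER,
    )
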