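"""Minimal instrumented ETL pipeline.

The whole integration contract is visible in ``run``: three setup/teardown
library statements, and exactly one statement per data element inside the
loop.  Everything else in a real pipeline is the pipeline's own code.
"""

from provtrace import init_store
from provtrace.fixtures import DEMO_POLICY, DEMO_SCRIPT


def run(db_path, elements):
    store = init_store(db_path)
    session = store.open_session("minimal_etl", script=DEMO_SCRIPT, policy=DEMO_POLICY)
    for rec in elements:
        session.record(rec)
    summary = session.close()
    return store, summary
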