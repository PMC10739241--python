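"""Human-readable renderings (text log, Mermaid) and export-file writers.

Every writer takes an output path and an ``overwrite`` flag; exports are
strictly read-only with respect to the store.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

from .fhir import map_to_fhir
from .prov import DEFAULT_BASE_IRI, build_prov_graph, serialize_prov
from .records import LineageChain, ProvenanceRecord

LOG_HEADER = "recorded_at\telement_id\tsource->destination\ttransformation\tquality\tscript"

EXPORT_FORMATS = ("fhir-json", "rdf-xml", "jsonld", "log")

_SUFFIX = {"fhir-json": ".json", "rdf-xml": ".rdf", "jsonld": ".jsonld", "log": ".log"}


class RenderUsageError(ValueError):
    """Rendering was requested on input it cannot represent (empty chain...)."""


def render_log(records: Sequence[ProvenanceRecord]) -> str:
    """One tab-separated line per record, ordered by recorded_at then id."""
    lines = [LOG_HEADER]
    for rec in sorted(records, key=lambda r: (r.recorded_at, r.record_id)):
        el = rec.element
        lines.append("\t".join([
            rec.recorded_at.isoformat(),
            el.element_id,
            f"{el.source_store}->{el.destination_store}",
            el.transformation_description,
            rec.quality_status,
            f"{rec.script.script_name} {rec.script.version}",
        ]))
    return "\n".join(lines) + "\n"


def _node_id(index: int) -> str:
    return f"S{index}"


def render_mermaid(chain: LineageChain) -> str:
    """Left-to-right Mermaid flowchart of one element's store hops.

    One node per distinct store (in order of first appearance), one edge
    per step labelled with its transformation description.
    """
    if not chain.steps:
        raise RenderUsageError("cannot render an empty lineage chain")
    node_ids: dict[str, str] = {}

    def node(store_name: str) -> str:
        if store_name not in node_ids:
            node_ids[store_name] = _node_id(len(node_ids))
        return node_ids[store_name]

    edges = []
    for step in chain.steps:
        src = node(step.input_store.store_name)
        dst = node(step.output_store.store_name)
        label = step.element.transformation_description.replace('"', "'")
        edges.append(f'    {src} -->|"{label}"| {dst}')
    lines = ["flowchart LR"]
    lines += [f'    {nid}["{name}"]' for name, nid in node_ids.items()]
    lines += edges
    return "\n".join(lines) + "\n"


def _write(path: Path, text: str, overwrite: bool) -> Path:
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"refusing to overwrite {path} (pass overwrite=True)")
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(text, encoding="utf-8")
    return path


def export_records(
    records: Sequence[ProvenanceRecord],
    fmt: str,
    path: str | Path,
    overwrite: bool = False,
    base_iri: str = DEFAULT_BASE_IRI,
) -> Path:
    """Write records to one export file in the requested format.

    ``fhir-json`` writes a JSON array with one R5 Provenance resource per
    record; ``rdf-xml``/``jsonld`` serialize the merged PROV graph;
    ``log`` writes the text log.
    """
    if fmt == "fhir-json":
        docs = [map_to_fhir(r).model_dump(exclude_none=True) for r in records]
        text = json.dumps(docs, indent=2)
    elif fmt in ("rdf-xml", "jsonld"):
        text = serialize_prov(build_prov_graph(records, base_iri=base_iri), fmt,
                              base_iri=base_iri)
    elif fmt == "log":
        text = render_log(records)
    else:
        raise RenderUsageError(f"unknown export format {fmt!r}; expected one of {EXPORT_FORMATS}")
    return _write(Path(path), text, overwrite)


def write_mermaid(chain: LineageChain, path: str | Path, overwrite: bool = False) -> Path:
    """Write the Mermaid flowchart for one lineage chain to a .mmd file."""
    return _write(Path(path), render_mermaid(chain), overwrite)


def default_export_name(fmt: str, stem: str = "provenance") -> str:
    return stem + _SUFFIX.get(fmt, ".txt")
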