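"""W3C PROV view of provenance records and its RDF serializations.

The mapping rule per record: the transformation is one ``prov:Activity``;
the element at its input store and at its output store are two
``prov:Entity`` nodes joined by ``prov:wasDerivedFrom``; the steward
(person), owner (organization) and script (software) are ``prov:Agent``
nodes associated with the activity, with the steward acting on behalf of
the owner; the governing SOP rides along as a ``prov:Plan`` inside the
steward's qualified association.  Nodes are merged across records by IRI,
so a steward shared by two records is one agent node.

RDF output is written and read here directly (RDF/XML via
``xml.etree.ElementTree``, JSON-LD in expanded form).  IRIs are minted for
every node — there are no blank nodes — so graph isomorphism between
dialects reduces to triple-set equality, which :func:`graphs_isomorphic`
exploits.
"""

from __future__ import annotations

import datetime as dt
import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Literal, Optional, Sequence
from urllib.parse import quote

from .records import ProvenanceRecord

PROV_NS = "http://www.w3.org/ns/prov#"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS_NS = "http://www.w3.org/2000/01/rdf-schema#"
XSD_NS = "http://www.w3.org/2001/XMLSchema#"

#: Default namespace under which node IRIs are minted; configurable so
#: exports from different deployments stay mergeable.
DEFAULT_BASE_IRI = "https://example.org/provtrace/"

RDF_TYPE = RDF_NS + "type"
RDFS_LABEL = RDFS_NS + "label"

DIALECTS = ("rdf-xml", "jsonld")


class ExportDialectError(ValueError):
    """Unknown serialization dialect requested."""


class RelationKind(str, Enum):
    used = "used"
    wasGeneratedBy = "wasGeneratedBy"
    wasAssociatedWith = "wasAssociatedWith"
    actedOnBehalfOf = "actedOnBehalfOf"
    wasDerivedFrom = "wasDerivedFrom"


AgentCategory = Literal["person", "organization", "software"]

_AGENT_CLASS = {
    "person": PROV_NS + "Person",
    "organization": PROV_NS + "Organization",
    "software": PROV_NS + "SoftwareAgent",
}


@dataclass(frozen=True)
class EntityNode:
    iri: str
    label: str
    attributes: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class ActivityNode:
    iri: str
    label: str
    start: Optional[dt.datetime] = None
    end: Optional[dt.datetime] = None


@dataclass(frozen=True)
class AgentNode:
    iri: str
    label: str
    category: AgentCategory


@dataclass(frozen=True)
class Relation:
    kind: RelationKind
    source: str
    target: str
    #: IRI of a prov:Plan attached via a qualified association (SOP/policy).
    plan: Optional[str] = None


class ProvGraphError(ValueError):
    """The graph violates a PROV structural invariant."""


@dataclass
class ProvGraph:
    """Entities, activities, agents and their typed relations."""

    entities: dict[str, EntityNode] = field(default_factory=dict)
    activities: dict[str, ActivityNode] = field(default_factory=dict)
    agents: dict[str, AgentNode] = field(default_factory=dict)
    relations: list[Relation] = field(default_factory=list)
    plans: dict[str, str] = field(default_factory=dict)  # iri -> label

    def node_iris(self) -> set[str]:
        return set(self.entities) | set(self.activities) | set(self.agents)

    def relation_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rel in self.relations:
            counts[rel.kind.value] = counts.get(rel.kind.value, 0) + 1
        return counts

    def validate(self) -> None:
        """Check endpoint resolution and used/wasGeneratedBy completeness."""
        nodes = self.node_iris()
        for rel in self.relations:
            for end in (rel.source, rel.target):
                if end not in nodes:
                    raise ProvGraphError(f"relation {rel.kind.value} endpoint not in graph: {end}")
        used_on = {r.target for r in self.relations if r.kind is RelationKind.used
                   and r.source in self.activities}
        # `used` edges run activity -> entity, so the activity is the source
        used_by = {r.source for r in self.relations if r.kind is RelationKind.used}
        gen_for = {r.target for r in self.relations if r.kind is RelationKind.wasGeneratedBy}
        for iri in self.activities:
            if iri not in used_by:
                raise ProvGraphError(f"activity without a used edge: {iri}")
            if iri not in gen_for:
                raise ProvGraphError(f"activity without a wasGeneratedBy edge: {iri}")


def _mint(base: str, *parts: str) -> str:
    return base + "/".join(quote(p, safe="") for p in parts)


def build_prov_graph(
    records: Sequence[ProvenanceRecord], base_iri: str = DEFAULT_BASE_IRI
) -> ProvGraph:
    """Map resolved provenance records onto a merged PROV graph.

    Per record: one activity, input and output entities, three agents
    (steward/owner/script), edges ``used``, ``wasGeneratedBy``,
    ``wasDerivedFrom``, three ``wasAssociatedWith`` and one
    ``actedOnBehalfOf``; the SOP is the plan of the steward association.
    """
    g = ProvGraph()
    for rec in records:
        el = rec.element
        in_iri = _mint(base_iri, "entity", el.source_store, el.element_id)
        out_iri = _mint(base_iri, "entity", el.destination_store, el.element_id)
        act_iri = _mint(base_iri, "activity", str(rec.record_id))
        steward_iri = _mint(base_iri, "agent", "steward", rec.steward.name)
        owner_iri = _mint(base_iri, "agent", "owner", rec.owner.label)
        script_iri = _mint(base_iri, "agent", "script",
                           rec.script.script_name, rec.script.version)
        plan_iri = _mint(base_iri, "plan", rec.policy.document_name, rec.policy.version)

        g.entities.setdefault(in_iri, EntityNode(
            iri=in_iri, label=f"{el.element_id}@{el.source_store}",
            attributes=(("variable", el.source_variable), ("store", el.source_store)),
        ))
        g.entities.setdefault(out_iri, EntityNode(
            iri=out_iri, label=f"{el.element_id}@{el.destination_store}",
            attributes=(("variable", el.destination_variable),
                        ("store", el.destination_store),
                        ("qualityCheck", el.quality_check_description)),
        ))
        g.activities.setdefault(act_iri, ActivityNode(
            iri=act_iri, label=el.transformation_description,
            start=rec.occurred_at, end=rec.recorded_at,
        ))
        g.agents.setdefault(steward_iri, AgentNode(steward_iri, rec.steward.name, "person"))
        g.agents.setdefault(owner_iri, AgentNode(owner_iri, rec.owner.label, "organization"))
        g.agents.setdefault(script_iri, AgentNode(
            script_iri, f"{rec.script.script_name} {rec.script.version}", "software"))
        g.plans.setdefault(
            plan_iri, f"{rec.policy.document_name} {rec.policy.version}")

        g.relations.append(Relation(RelationKind.used, act_iri, in_iri))
        g.relations.append(Relation(RelationKind.wasGeneratedBy, out_iri, act_iri))
        g.relations.append(Relation(RelationKind.wasDerivedFrom, out_iri, in_iri))
        g.relations.append(Relation(RelationKind.wasAssociatedWith, act_iri, steward_iri,
                                    plan=plan_iri))
        g.relations.append(Relation(RelationKind.wasAssociatedWith, act_iri, owner_iri))
        g.relations.append(Relation(RelationKind.wasAssociatedWith, act_iri, script_iri))
        g.relations.append(Relation(RelationKind.actedOnBehalfOf, steward_iri, owner_iri))
    g.validate() if records else None
    return g


# -- triple model ---------------------------------------------------------

#: A triple object: ("iri", value) or ("literal", lexical, datatype_iri).
TripleObject = tuple
Triple = tuple[str, str, TripleObject]


def _lit(value: str, datatype: str = XSD_NS + "string") -> TripleObject:
    return ("literal", value, datatype)


def _iri(value: str) -> TripleObject:
    return ("iri", value)


def graph_to_triples(graph: ProvGraph, base_iri: str = DEFAULT_BASE_IRI) -> set[Triple]:
    """Flatten a PROV graph into RDF triples using PROV-O vocabulary."""
    attr_ns = base_iri + "attr#"
    triples: set[Triple] = set()
    for ent in graph.entities.values():
        triples.add((ent.iri, RDF_TYPE, _iri(PROV_NS + "Entity")))
        triples.add((ent.iri, RDFS_LABEL, _lit(ent.label)))
        for key, val in ent.attributes:
            if val:
                triples.add((ent.iri, attr_ns + key, _lit(val)))
    for act in graph.activities.values():
        triples.add((act.iri, RDF_TYPE, _iri(PROV_NS + "Activity")))
        triples.add((act.iri, RDFS_LABEL, _lit(act.label)))
        if act.start is not None:
            triples.add((act.iri, PROV_NS + "startedAtTime",
                         _lit(act.start.isoformat(), XSD_NS + "dateTime")))
        if act.end is not None:
            triples.add((act.iri, PROV_NS + "endedAtTime",
                         _lit(act.end.isoformat(), XSD_NS + "dateTime")))
    for ag in graph.agents.values():
        triples.add((ag.iri, RDF_TYPE, _iri(PROV_NS + "Agent")))
        triples.add((ag.iri, RDF_TYPE, _iri(_AGENT_CLASS[ag.category])))
        triples.add((ag.iri, RDFS_LABEL, _lit(ag.label)))
    for iri, label in graph.plans.items():
        triples.add((iri, RDF_TYPE, _iri(PROV_NS + "Plan")))
        triples.add((iri, RDF_TYPE, _iri(PROV_NS + "Entity")))
        triples.add((iri, RDFS_LABEL, _lit(label)))
    assoc_n = 0
    for rel in graph.relations:
        triples.add((rel.source, PROV_NS + rel.kind.value, _iri(rel.target)))
        if rel.plan is not None:
            # qualified association carrying the SOP as prov:Plan
            assoc_n += 1
            assoc_iri = rel.source + f"/association/{assoc_n}"
            triples.add((rel.source, PROV_NS + "qualifiedAssociation", _iri(assoc_iri)))
            triples.add((assoc_iri, RDF_TYPE, _iri(PROV_NS + "Association")))
            triples.add((assoc_iri, PROV_NS + "agent", _iri(rel.target)))
            triples.add((assoc_iri, PROV_NS + "hadPlan", _iri(rel.plan)))
    return triples


# -- RDF/XML --------------------------------------------------------------

def _split_iri(iri: str) -> tuple[str, str]:
    cut = max(iri.rfind("#"), iri.rfind("/"))
    return iri[: cut + 1], iri[cut + 1:]


def _triples_to_rdfxml(triples: set[Triple]) -> str:
    root = ET.Element(ET.QName(RDF_NS, "RDF"))
    by_subject: dict[str, list[Triple]] = {}
    for t in sorted(triples):
        by_subject.setdefault(t[0], []).append(t)
    for subject, ts in by_subject.items():
        desc = ET.SubElement(root, ET.QName(RDF_NS, "Description"))
        desc.set(ET.QName(RDF_NS, "about"), subject)
        for _, pred, obj in ts:
            ns, local = _split_iri(pred)
            el = ET.SubElement(desc, ET.QName(ns, local))
            if obj[0] == "iri":
                el.set(ET.QName(RDF_NS, "resource"), obj[1])
            else:
                if obj[2] != XSD_NS + "string":
                    el.set(ET.QName(RDF_NS, "datatype"), obj[2])
                el.text = obj[1]
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True)


def _rdfxml_to_triples(text: str) -> set[Triple]:
    root = ET.fromstring(text)
    if root.tag != f"{{{RDF_NS}}}RDF":
        raise ValueError("not an RDF/XML document")
    triples: set[Triple] = set()
    for desc in root:
        subject = desc.get(f"{{{RDF_NS}}}about")
        for el in desc:
            pred = el.tag[1:].replace("}", "")
            resource = el.get(f"{{{RDF_NS}}}resource")
            if resource is not None:
                triples.add((subject, pred, _iri(resource)))
            else:
                datatype = el.get(f"{{{RDF_NS}}}datatype") or XSD_NS + "string"
                triples.add((subject, pred, _lit(el.text or "", datatype)))
    return triples


# -- JSON-LD (expanded form) ----------------------------------------------

def _triples_to_jsonld(triples: set[Triple]) -> str:
    by_subject: dict[str, dict] = {}
    for subject, pred, obj in sorted(triples):
        node = by_subject.setdefault(subject, {"@id": subject})
        if pred == RDF_TYPE and obj[0] == "iri":
            node.setdefault("@type", []).append(obj[1])
            continue
        values = node.setdefault(pred, [])
        if obj[0] == "iri":
            values.append({"@id": obj[1]})
        elif obj[2] == XSD_NS + "string":
            values.append({"@value": obj[1]})
        else:
            values.append({"@value": obj[1], "@type": obj[2]})
    return json.dumps(list(by_subject.values()), indent=2, sort_keys=True)


def _jsonld_to_triples(text: str) -> set[Triple]:
    nodes = json.loads(text)
    triples: set[Triple] = set()
    for node in nodes:
        subject = node["@id"]
        for pred, values in node.items():
            if pred == "@id":
                continue
            if pred == "@type":
                for t in values:
                    triples.add((subject, RDF_TYPE, _iri(t)))
                continue
            for v in values:
                if "@id" in v:
                    triples.add((subject, pred, _iri(v["@id"])))
                else:
                    triples.add((subject, pred,
                                 _lit(v["@value"], v.get("@type", XSD_NS + "string"))))
    return triples


def serialize_prov(graph: ProvGraph, dialect: str,
                   base_iri: str = DEFAULT_BASE_IRI) -> str:
    """Serialize a PROV graph to ``rdf-xml`` or ``jsonld`` text."""
    if graph.relations or graph.node_iris():
        graph.validate()
    triples = graph_to_triples(graph, base_iri=base_iri)
    if dialect == "rdf-xml":
        return _triples_to_rdfxml(triples)
    if dialect == "jsonld":
        return _triples_to_jsonld(triples)
    raise ExportDialectError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def parse_prov(text: str, dialect: str) -> set[Triple]:
    """Parse a serialized PROV document back into its triple set."""
    if dialect == "rdf-xml":
        return _rdfxml_to_triples(text)
    if dialect == "jsonld":
        return _jsonld_to_triples(text)
    raise ExportDialectError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def graphs_isomorphic(a: set[Triple], b: set[Triple]) -> bool:
    """Triple-set equality; exact isomorphism because no blank nodes exist."""
    return a == b
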