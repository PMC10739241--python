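# Methods

## The capture model

`provtrace` records *hybrid* provenance at the level of individual data
elements: part of each trace is manual annotation carried on the element
record (descriptions of the transformation and quality check, SOP
references, a status log), part is collected automatically at capture time
(timestamps, session dimensions, record identity, row hashes). One
provenance row represents one processing step of one element and resolves
seven references — element, governance policy, owner, steward, input
store, output store, script — plus a quality testimony and two
timestamps:

- `occurred_at` — when the ETL action happened. The caller (the ETL
  engine) may supply it and then wins; otherwise the capture clock is
  used. `recorded_at` — when the trace was captured, always the library
  clock. The invariant `recorded_at ≥ occurred_at` is enforced.
- All timestamps are normalized to ISO-8601 with an explicit UTC offset
  on ingest (naive inputs are taken as UTC): contemporaneous,
  unambiguous time is an ALCOA+ data-integrity attribute.

The library stores metadata *about* elements only — names, store and
variable names, free-text descriptions — never patient values. Callers
may attach an opaque `value_digest` if they need to bind a trace to a
concrete value without storing it.

`quality_status` is deliberately a free-text placeholder defaulting to
`"good"`: quality *assessment* is a separate concern; the trace only
carries the testimony slot for it.

A missing steward name is stored as the literal sentinel `"no name
given"` rather than NULL, so unassigned responsibility remains a visible,
queryable fact.

## Persistence and the append-only guarantee

The default backend is a single-file SQLite database (any deployment can
point the same schema at another relational engine; nothing beyond
standard SQL is used). Schema creation is idempotent. Dimension rows are
deduplicated by natural key — (name, version) for scripts and policies,
full name for stewards/owners, store name for stores — which keeps the
provenance graph joinable across sessions.

Append-only is enforced in depth:

1. the public API exposes no update or delete for provenance/element rows;
2. SQLite triggers `RAISE(ABORT)` on any UPDATE or DELETE of those tables;
3. a sha256 over the full row content is captured at insert time and
   re-verified by `verify_audit()`; `verify_references()` re-checks by
   full join scan that every dimension reference resolves.

Record ids are assigned by the library from a monotonic counter seeded
with `MAX(id)` at store open, so the hash can cover the id without a
post-insert update (which the triggers would forbid anyway).

**Batching and durability.** Inserts are committed transparently every
`batch_size` rows (default 1,000) and on session close, so the
per-element call stays a single statement at bulk-load speed (~60 µs per
record in this environment). Consequence: "durable" means *flushed* —
rows committed before a hard process kill survive reopening; an
uncommitted tail inside the current batch can be lost, as in any
relational backend. `Session.flush()` is public for pipelines that need a
tighter durability point. Session bookkeeping rows (close timestamp,
record count) are mutable by design; only trace content is append-only.

## Standards mappings

**W3C PROV.** Per record: one activity (labelled with the transformation
description, start/end from the two timestamps), two entities (the
element at input and at output store) with `wasDerivedFrom` output→input,
three agents (steward = `prov:Person`, owner = `prov:Organization`,
script = `prov:SoftwareAgent`), edges `used`, `wasGeneratedBy`, three
`wasAssociatedWith` and one `actedOnBehalfOf`. The SOP is modelled as a
`prov:Plan` inside the steward's qualified association — the
W3C-idiomatic way to say "this agent executed the activity following this
plan". Nodes are merged across records by IRI; IRIs are minted under a
configurable base namespace as `base + type-prefix + percent-encoded
natural key`, so exports from the same deployment merge stably.

RDF is written and parsed in-package (RDF/XML via `ElementTree`, JSON-LD
in expanded form) rather than through an RDF library, which is not
available in the target environment. The serializers emit no blank nodes
— every node, including qualified associations, has a minted IRI — so
graph isomorphism between dialects is decidable by exact triple-set
equality, which is what `graphs_isomorphic` checks.

**FHIR R5 Provenance.** The metadata levels map as: governance →
`policy` (a minted uri) and the `location` reference `"DIC"`; owner →
`authorization` (v3-ActReason code `TRANSRCH`, research use) and the
steward agent's `onBehalfOf`; steward → `agent.who.display`; stores →
`entity` (role `source`, input store) and `target` (output store), both
identified under system `urn:ietf:rfc:3986` with the store's
deterministic UUID (uuid5 of the store name); script → `activity` and
`basedOn`, plus a `performer` agent. The `activity` coding uses the
ISO 21089 record-lifecycle code system via a small lookup from the
free-text transformation description ("copy" → `originate`, unknown
descriptions → `transform`), with the original description always
preserved in `CodeableConcept.text` so the coding stays inside the code
system without losing information. Patient/encounter references are
emitted only if the caller supplies pseudonymous references — never
synthesized.

Validation is a hand-built pydantic encoding of the R5 Provenance
structure definition: required cardinalities (`target` 1..*, `agent` 1..*
with mandatory `who`), the closed `entity.role` value set, FHIR
`dateTime`/`instant` lexical forms, and `extra="forbid"` so misspelled
element names are rejected. It is a faithful subset, not the full FHIR
validation stack: slicing, profiles and terminology expansion are out of
scope, so a green validation establishes structural R5 conformance of the
emitted elements, not conformance to an arbitrary profile.

## Synthetic data

The generator emulates the *shape and scale* of a DIC element catalogue:
7 fixed element types (systolic blood pressure is the canonical,
fully-annotated one; diastolic BP, heart rate, serum potassium, ICD
diagnosis, medication order and admission date are illustrative
templates), each instantiated `n` times with ids `{type}_{ordinal:04d}` —
deterministic, collision-free at 100,000 per type, with an optional
seeded-UUID mode. It does not emulate real clinical value distributions
(no values exist at all), missingness, or source-system heterogeneity; a
green test therefore establishes the capture/export machinery's
correctness and scale behaviour, not clinical realism.

The demo ETL drives every element through the standard integration
stages `staging → dwh → fhir → rdr` (one capture session per stage
transition, k−1 records per element for k stages), which is what the
lineage-recall checks reconstruct against.

## Runtime experiment

Each block size gets a fresh store (mirroring per-machine isolation,
replayed sequentially); the per-element time is the `record` loop alone,
the per-record time additionally includes store creation, session
dimension writes and commits — the two are reported separately because
whether dimension upserts count toward "one record" is a design choice.
Wall time comes from `time.perf_counter` (monotonic). Database growth is
the file-size delta in kilobytes and must be monotone non-decreasing in
block size.

Absolute timings are hardware-bound and are not asserted anywhere; the
claim under test is *near-linear scaling*: the slope of a least-squares
fit of log total capture time vs. log block size over
{1, 10, 100, 1000, 10000} must lie in a configurable band, default
[0.8, 1.2]. In this environment the measured slope is ≈ 0.81–0.83: the
sub-linear deviation comes from one-time costs in a block's first few
calls (cold caches, first dimension lookups) that amortize away in larger
blocks.

## Numerical and degenerate-input choices

- `status_log` parsing requires `<status> date <day>`; accepted day
  spellings are `12.May2022`, `12.May.2022`, `01.02.2023`, `2022-05-12`.
  Anything else is a validation *finding* (violation list), not an
  exception — violations are data.
- Empty lineage chains are a valid query result (unknown element id);
  broken store continuity in a chain emits a `ContinuityWarning` naming
  each broken link but still returns the chain for inspection.
- Rendering an empty chain as Mermaid, an unknown export dialect, and a
  sub-3-row linearity fit are usage errors (exceptions).
- Log lines and hydrated record lists are ordered by `recorded_at` with
  `record_id` as the tie-break, making exports deterministic under equal
  timestamps.
- The linearity fit floors total times at 1 ps before taking logs to stay
  defined for pathological zero-duration rows.

## Known limitations

- Access control is delegated to deployment; "analyzable by an authorized
  user" is a file-permission / database-grant concern here.
- The FHIR validator is a structural subset (see above).
- Durability of the current uncommitted batch is bounded by `batch_size`.
- The Mermaid output is checked structurally (node/edge grammar shape),
  not by executing a Mermaid renderer.
- Multi-machine benchmark orchestration and memory profiling are out of
  scope; the experiment replays block isolation sequentially on one host.
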