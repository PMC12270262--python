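"""Entity/relationship schema and the annotated triple store.

The graph is a typed multigraph: nodes are namespaced entities drawn from a
closed set of ten kinds (nine data-driven kinds plus the disease hub), edges
are subject-predicate-object triples drawn from a closed set of eleven
predicates, each legal only for a declared (subject kind, object kind) pair.
Both entities and triples carry open key->value annotation maps.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = [
    "ENTITY_KINDS",
    "DEFAULT_SCHEMA",
    "Entity",
    "Triple",
    "KnowledgeGraph",
    "SchemaError",
    "IntegrityError",
]

SCHEMA_VERSION = "1"

#: Closed set of entity kinds, in the canonical reporting order.
ENTITY_KINDS: tuple[str, ...] = (
    "disease",
    "protein",
    "drug",
    "biological_process",
    "molecular_function",
    "pathway",
    "variant",
    "assay",
    "adverse_event",
    "mechanism_of_action",
)

#: Default predicate schema: predicate -> set of legal (subject kind, object kind)
#: pairs.  Eleven predicates; the three drug->protein predicates encode the
#: direction of pharmacological action, ``targets`` being the miscellaneous
#: catch-all.  The table is passed to :class:`KnowledgeGraph` and may be
#: replaced wholesale by callers needing different labels.
DEFAULT_SCHEMA: dict[str, frozenset[tuple[str, str]]] = {
    "associated_with": frozenset({("disease", "protein")}),
    "increases": frozenset({("drug", "protein")}),
    "decreases": frozenset({("drug", "protein")}),
    "targets": frozenset({("drug", "protein")}),
    "participates_in": frozenset({("protein", "biological_process")}),
    "has_function": frozenset({("protein", "molecular_function")}),
    "part_of": frozenset({("protein", "pathway")}),
    "tested_in": frozenset({("drug", "assay")}),
    "has_adverse_effect": frozenset({("drug", "adverse_event")}),
    "has_moa": frozenset({("drug", "mechanism_of_action")}),
    "has_variant": frozenset({("protein", "variant")}),
}

DRUG_PROTEIN_PREDICATES = ("increases", "decreases", "targets")

_DRUGGABILITY_VALUES = {"yes", "no", "unknown"}


class SchemaError(ValueError):
    """A triple violates the declared predicate/kind schema."""


class IntegrityError(ValueError):
    """The graph breaks referential integrity or kind closure."""


EntityKey = tuple[str, str]


@dataclass
class Entity:
    """A namespaced node. Keyed case-sensitively on (namespace, identifier)."""

    namespace: str
    identifier: str
    label: str = ""
    kind: str = "protein"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.namespace or not self.identifier:
            raise ValueError("entity namespace and identifier must be non-empty")
        if self.kind not in ENTITY_KINDS:
            raise ValueError(f"unknown entity kind {self.kind!r}")
        drug = self.metadata.get("druggability")
        if isinstance(drug, list):  # merged conflicting annotations
            drug = next((d for d in drug if d not in _DRUGGABILITY_VALUES), None)
        if drug is not None and drug not in _DRUGGABILITY_VALUES:
            raise ValueError(f"druggability must be one of {_DRUGGABILITY_VALUES}, got {drug!r}")
        if not self.label:
            self.label = self.identifier

    @property
    def key(self) -> EntityKey:
        return (self.namespace, self.identifier)

    @property
    def curie(self) -> str:
        return f"{self.namespace}:{self.identifier}"


@dataclass
class Triple:
    """A subject-predicate-object statement with relation-level annotations."""

    subject: EntityKey
    predicate: str
    object: EntityKey
    annotations: dict = field(default_factory=dict)

    @property
    def key(self) -> tuple[EntityKey, str, EntityKey]:
        return (self.subject, self.predicate, self.object)


def _merge_value(old, new):
    """Merge a metadata/annotation value without dropping information.

    Equal values collapse; conflicting scalars accumulate into a list of
    distinct values (order of first appearance).
    """
    if old == new:
        return old
    old_list = old if isinstance(old, list) else [old]
    if isinstance(new, list):
        new_items = new
    else:
        new_items = [new]
    merged = list(old_list)
    for item in new_items:
        if item not in merged:
            merged.append(item)
    return merged if len(merged) > 1 else merged[0]


def merge_maps(base: dict, extra: Mapping) -> dict:
    out = dict(base)
    for k, v in extra.items():
        out[k] = _merge_value(out[k], v) if k in out else v
    return out


class KnowledgeGraph:
    """Triple store with provenance and a pluggable predicate schema.

    Entities are upserted by (namespace, identifier); triples are keyed on
    (subject, predicate, object) with annotation maps merged on collision, so
    re-adding an identical triple is a no-op.
    """

    def __init__(
        self,
        provenance: dict | None = None,
        schema: Mapping[str, frozenset[tuple[str, str]]] | None = None,
    ) -> None:
        self.schema = dict(schema) if schema is not None else dict(DEFAULT_SCHEMA)
        self.schema_version = SCHEMA_VERSION
        self.entities: dict[EntityKey, Entity] = {}
        self.triples: dict[tuple[EntityKey, str, EntityKey], Triple] = {}
        self.provenance: dict = provenance or {}
        self.provenance.setdefault("created", _dt.datetime.now(_dt.timezone.utc).isoformat())

    # -- construction -----------------------------------------------------

    def add_entity(self, entity: Entity) -> Entity:
        """Upsert an entity, merging metadata (conflicts kept as lists)."""
        existing = self.entities.get(entity.key)
        if existing is None:
            self.entities[entity.key] = entity
            return entity
        if entity.kind != existing.kind:
            raise IntegrityError(
                f"entity {entity.curie} re-added with kind {entity.kind!r}, "
                f"already present as {existing.kind!r}"
            )
        existing.metadata = merge_maps(existing.metadata, entity.metadata)
        if entity.label and existing.label == existing.identifier:
            existing.label = entity.label
        return existing

    def add_triple(
        self,
        subject: Entity,
        predicate: str,
        obj: Entity,
        annotations: Mapping | None = None,
    ) -> "KnowledgeGraph":
        pairs = self.schema.get(predicate)
        if pairs is None:
            raise SchemaError(
                f"unknown predicate {predicate!r}; legal predicates: {sorted(self.schema)}"
            )
        if (subject.kind, obj.kind) not in pairs:
            raise SchemaError(
                f"predicate {predicate!r} not legal for "
                f"({subject.kind!r}, {obj.kind!r}); legal pairs: {sorted(pairs)}"
            )
        annotations = dict(annotations or {})
        pchembl = annotations.get("pchembl_value")
        if pchembl is not None and not (
            isinstance(pchembl, (int, float)) and pchembl > 0
        ):
            raise ValueError(f"pchembl_value annotation must be > 0, got {pchembl!r}")
        s = self.add_entity(subject)
        o = self.add_entity(obj)
        key = (s.key, predicate, o.key)
        existing = self.triples.get(key)
        if existing is None:
            self.triples[key] = Triple(s.key, predicate, o.key, annotations)
        else:
            existing.annotations = merge_maps(existing.annotations, annotations)
        return self

    # -- queries ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.entities)

    @property
    def n_entities(self) -> int:
        return len(self.entities)

    @property
    def n_triples(self) -> int:
        return len(self.triples)

    def entity(self, namespace: str, identifier: str) -> Entity:
        return self.entities[(namespace, identifier)]

    def iter_triples(self) -> Iterator[Triple]:
        return iter(self.triples.values())

    def entities_of_kind(self, kind: str) -> list[Entity]:
        return [e for e in self.entities.values() if e.kind == kind]

    def summarize(self) -> dict:
        """Per-kind entity counts (canonical kind order) plus triple count.

        Counts always cover every kind (zeros included) and sum to the total
        entity count.
        """
        by_kind = {kind: 0 for kind in ENTITY_KINDS}
        for e in self.entities.values():
            by_kind[e.kind] += 1
        return {"entities": by_kind, "n_entities": len(self.entities), "n_triples": len(self.triples)}

    def subgraph(
        self,
        kinds: Iterable[str] | None = None,
        predicates: Iterable[str] | None = None,
    ) -> "KnowledgeGraph":
        """Graph restricted to triples matching the kind and/or predicate filter.

        A triple is retained iff both endpoints' kinds are in ``kinds`` (when
        given) and its predicate is in ``predicates`` (when given).  Only
        endpoints of retained triples are carried over — no orphans.
        """
        if kinds is None and predicates is None:
            raise ValueError("subgraph filter must not be empty: give kinds and/or predicates")
        kinds = set(kinds) if kinds is not None else None
        predicates = set(predicates) if predicates is not None else None
        out = KnowledgeGraph(provenance={"parent": self.provenance.get("disease_ids"),
                                         "filter": {"kinds": sorted(kinds) if kinds else None,
                                                    "predicates": sorted(predicates) if predicates else None}},
                             schema=self.schema)
        for triple in self.triples.values():
            s = self.entities[triple.subject]
            o = self.entities[triple.object]
            if kinds is not None and (s.kind not in kinds or o.kind not in kinds):
                continue
            if predicates is not None and triple.predicate not in predicates:
                continue
            out.add_triple(
                Entity(s.namespace, s.identifier, s.label, s.kind, dict(s.metadata)),
                triple.predicate,
                Entity(o.namespace, o.identifier, o.label, o.kind, dict(o.metadata)),
                dict(triple.annotations),
            )
        return out

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        """Check referential integrity and schema closure; raise on breach."""
        for (skey, pred, okey), triple in self.triples.items():
            if skey not in self.entities or okey not in self.entities:
                raise IntegrityError(f"dangling triple endpoint in {triple.key}")
            pairs = self.schema.get(pred)
            s, o = self.entities[skey], self.entities[okey]
            if pairs is None or (s.kind, o.kind) not in pairs:
                raise IntegrityError(
                    f"observed illegal combination ({s.kind}, {pred}, {o.kind})"
                )
        summary = self.summarize()
        if sum(summary["entities"].values()) != len(self.entities):
            raise IntegrityError("per-kind counts do not sum to entity total")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "provenance": self.provenance,
            "schema": {p: sorted(list(pair) for pair in pairs) for p, pairs in self.schema.items()},
            "entities": [
                {
                    "namespace": e.namespace,
                    "identifier": e.identifier,
                    "label": e.label,
                    "kind": e.kind,
                    "metadata": e.metadata,
                }
                for e in sorted(self.entities.values(), key=lambda e: e.key)
            ],
            "triples": [
                {
                    "subject": list(t.subject),
                    "predicate": t.predicate,
                    "object": list(t.object),
                    "annotations": t.annotations,
                }
                for t in sorted(self.triples.values(), key=lambda t: t.key)
            ],
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "KnowledgeGraph":
        schema = {
            p: frozenset(tuple(pair) for pair in pairs)
            for p, pairs in payload.get("schema", {}).items()
        } or None
        kg = cls(provenance=dict(payload.get("provenance", {})), schema=schema)
        kg.schema_version = payload.get("schema_version", SCHEMA_VERSION)
        for rec in payload["entities"]:
            kg.add_entity(
                Entity(rec["namespace"], rec["identifier"], rec.get("label", ""),
                       rec["kind"], dict(rec.get("metadata", {})))
            )
        for rec in payload["triples"]:
            skey = tuple(rec["subject"])
            okey = tuple(rec["object"])
            key = (skey, rec["predicate"], okey)
            kg.triples[key] = Triple(skey, rec["predicate"], okey, dict(rec.get("annotations", {})))
        kg.validate()
        return kg
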