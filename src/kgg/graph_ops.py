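"""Post-build graph algebra: merge, per-kind intersection, identifier
normalization, PDB structure summaries and format export/import."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .core_model import ENTITY_KINDS, Entity, KnowledgeGraph, Triple, merge_maps
from .sources.base import SourceBackend

EXPORT_FORMATS = ("graphml", "csv", "json", "bel")


class ExportFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# merge
# ---------------------------------------------------------------------------

def merge(a: KnowledgeGraph, b: KnowledgeGraph) -> KnowledgeGraph:
    """Union of two graphs: entities keyed on (namespace, identifier), triples
    deduplicated on (subject, predicate, object) with annotations merged."""
    if a.schema_version != b.schema_version:
        raise ValueError(
            f"schema version mismatch: {a.schema_version!r} vs {b.schema_version!r}")
    out = KnowledgeGraph(
        provenance={"parents": [a.provenance.get("disease_ids"),
                                b.provenance.get("disease_ids")],
                    "operation": "merge"},
        schema={**a.schema, **b.schema},
    )
    for source in (a, b):
        for e in source.entities.values():
            out.add_entity(Entity(e.namespace, e.identifier, e.label, e.kind,
                                  dict(e.metadata)))
        for t in source.iter_triples():
            existing = out.triples.get(t.key)
            if existing is None:
                out.triples[t.key] = Triple(t.subject, t.predicate, t.object,
                                            dict(t.annotations))
            else:
                existing.annotations = merge_maps(existing.annotations, t.annotations)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# per-kind intersection with identifier normalization
# ---------------------------------------------------------------------------

@dataclass
class KindComparison:
    shared: list[str]
    unique_a: int
    unique_b: int

    @property
    def n_shared(self) -> int:
        return len(self.shared)


@dataclass
class ComparisonReport:
    """Per-kind shared/unique identifier counts plus the normalization log."""

    by_kind: dict[str, KindComparison]
    mapped: int = 0
    unmapped: list[str] = field(default_factory=list)

    def shared_counts(self) -> dict[str, int]:
        return {k: c.n_shared for k, c in self.by_kind.items()}

    def to_dict(self) -> dict:
        return {
            "by_kind": {k: {"shared": c.shared, "n_shared": c.n_shared,
                            "unique_a": c.unique_a, "unique_b": c.unique_b}
                        for k, c in self.by_kind.items()},
            "normalization": {"mapped": self.mapped, "unmapped": self.unmapped},
        }

    def venn_table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"kind": k, "shared": c.n_shared, "unique_a": c.unique_a, "unique_b": c.unique_b}
            for k, c in self.by_kind.items()
        ])


def load_mapping_table(path: str | Path) -> dict[str, str]:
    """Two-column old_id -> new_id table (TSV/CSV); duplicate old ids are an error."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#",
                     names=["old_id", "new_id"], dtype=str)
    if df["old_id"].duplicated().any():
        dupes = df.loc[df["old_id"].duplicated(), "old_id"].tolist()
        raise ValueError(f"mapping table has duplicate old ids: {dupes}")
    return dict(zip(df["old_id"], df["new_id"]))


def shared_entities(
    a: KnowledgeGraph,
    b: KnowledgeGraph,
    mapping: Optional[Mapping[str, str]] = None,
) -> ComparisonReport:
    """Per-kind identifier intersection, after normalizing b through ``mapping``.

    Identifiers of b found in the mapping are replaced before intersecting;
    identifiers absent from the mapping are compared as-is and reported in the
    normalization log (never silently dropped).  Comparison is on identifier
    within kind — variants on rsid only, drugs on the (normalized) compound id.
    """
    if mapping is not None:
        values = list(mapping.keys())
        if len(values) != len(set(values)):
            raise ValueError("mapping table has duplicate old ids")
    ids_a: dict[str, set[str]] = {k: set() for k in ENTITY_KINDS}
    ids_b: dict[str, set[str]] = {k: set() for k in ENTITY_KINDS}
    for e in a.entities.values():
        ids_a[e.kind].add(e.identifier)
    mapped = 0
    unmapped: list[str] = []
    for e in b.entities.values():
        ident = e.identifier
        if mapping is not None:
            if ident in mapping:
                ident = mapping[ident]
                mapped += 1
            else:
                unmapped.append(ident)
        ids_b[e.kind].add(ident)
    by_kind = {}
    for kind in ENTITY_KINDS:
        shared = sorted(ids_a[kind] & ids_b[kind])
        by_kind[kind] = KindComparison(
            shared=shared,
            unique_a=len(ids_a[kind]) - len(shared),
            unique_b=len(ids_b[kind]) - len(shared),
        )
    return ComparisonReport(by_kind=by_kind, mapped=mapped, unmapped=sorted(unmapped))


# ---------------------------------------------------------------------------
# PDB structure summary
# ---------------------------------------------------------------------------

@dataclass
class ProteinStructure:
    uniprot_id: str
    n_pdb: int
    n_xray: int

    @property
    def has_any_structure(self) -> bool:
        return self.n_pdb > 0


@dataclass
class StructureSummary:
    proteins: list[ProteinStructure]

    @property
    def with_structure(self) -> list[ProteinStructure]:
        return [p for p in self.proteins if p.has_any_structure]

    @property
    def without_structure(self) -> list[ProteinStructure]:
        return [p for p in self.proteins if not p.has_any_structure]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"uniprot_id": p.uniprot_id, "n_pdb": p.n_pdb, "n_xray": p.n_xray,
             "has_any_structure": p.has_any_structure}
            for p in self.proteins
        ])


def _is_xray(method: str) -> bool:
    return "x-ray" in method.lower().replace(" ", "-")


def structure_summary(uniprot_ids: Sequence[str], backend: SourceBackend) -> StructureSummary:
    """Per-protein PDB / X-ray structure counts; structureless proteins are
    listed explicitly with zero counts."""
    annotations = {a.uniprot_id: a for a in backend.fetch_protein_annotations(uniprot_ids)}
    proteins = []
    for uid in uniprot_ids:
        ann = annotations.get(uid)
        pdb = ann.pdb if ann else []
        proteins.append(ProteinStructure(
            uniprot_id=uid,
            n_pdb=len(pdb),
            n_xray=sum(1 for p in pdb if _is_xray(p.method)),
        ))
    return StructureSummary(proteins=proteins)


def drug_target_proteins(kg: KnowledgeGraph) -> list[str]:
    """UniProt ids of proteins targeted by a drug in the graph (the
    clinical-trial restriction applied before structure lookup)."""
    uniprots = set()
    for t in kg.iter_triples():
        if t.predicate in ("increases", "decreases", "targets"):
            protein = kg.entities[t.object]
            uid = protein.metadata.get("uniprot_id") or (
                protein.identifier if protein.namespace == "UNIPROT" else None)
            if uid:
                uniprots.add(uid)
    return sorted(uniprots)


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def _node_id(key: tuple[str, str]) -> str:
    return f"{key[0]}:{key[1]}"


def to_networkx(kg: KnowledgeGraph) -> nx.MultiDiGraph:
    g = nx.MultiDiGraph()
    for e in sorted(kg.entities.values(), key=lambda e: e.key):
        g.add_node(_node_id(e.key), namespace=e.namespace, identifier=e.identifier,
                   label=e.label, kind=e.kind, metadata=json.dumps(e.metadata, sort_keys=True))
    for t in sorted(kg.iter_triples(), key=lambda t: t.key):
        g.add_edge(_node_id(t.subject), _node_id(t.object), key=t.predicate,
                   predicate=t.predicate,
                   annotations=json.dumps(t.annotations, sort_keys=True))
    return g


def from_networkx(g: nx.MultiDiGraph) -> KnowledgeGraph:
    kg = KnowledgeGraph(provenance={"imported": True})
    for _node, attrs in g.nodes(data=True):
        kg.add_entity(Entity(attrs["namespace"], attrs["identifier"],
                             attrs.get("label", ""), attrs["kind"],
                             json.loads(attrs.get("metadata", "{}"))))
    for u, v, attrs in g.edges(data=True):
        ukey = tuple(u.split(":", 1))
        vkey = tuple(v.split(":", 1))
        pred = attrs["predicate"]
        kg.triples[(ukey, pred, vkey)] = Triple(
            ukey, pred, vkey, json.loads(attrs.get("annotations", "{}")))
    kg.validate()
    return kg


_BEL_FUNC = {
    "disease": "path",
    "protein": "p",
    "drug": "a",
    "biological_process": "bp",
    "molecular_function": "act",
    "pathway": "path",
    "variant": "g",
    "assay": "a",
    "adverse_event": "path",
    "mechanism_of_action": "bp",
}


def _bel_term(e: Entity) -> str:
    label = e.label.replace('"', "'")
    return f'{_BEL_FUNC[e.kind]}({e.namespace}:"{e.identifier}" ! "{label}")'


def to_bel_script(kg: KnowledgeGraph) -> str:
    """Line-per-triple BEL-style text with SET blocks for annotations."""
    lines = ["# BEL script rendering", f"# entities: {kg.n_entities}  triples: {kg.n_triples}"]
    for t in sorted(kg.iter_triples(), key=lambda t: t.key):
        s = kg.entities[t.subject]
        o = kg.entities[t.object]
        for k in sorted(t.annotations):
            v = t.annotations[k]
            lines.append(f'SET {k} = "{v}"')
        lines.append(f"{_bel_term(s)} {t.predicate} {_bel_term(o)}")
        for k in sorted(t.annotations):
            lines.append(f"UNSET {k}")
    return "\n".join(lines) + "\n"


def _csv_tables(kg: KnowledgeGraph) -> tuple[pd.DataFrame, pd.DataFrame]:
    nodes = pd.DataFrame([
        {"id:ID": _node_id(e.key), ":LABEL": e.kind, "namespace": e.namespace,
         "identifier": e.identifier, "label": e.label,
         "metadata": json.dumps(e.metadata, sort_keys=True)}
        for e in sorted(kg.entities.values(), key=lambda e: e.key)
    ])
    annotation_keys = sorted({k for t in kg.iter_triples() for k in t.annotations})
    edges = pd.DataFrame([
        {":START_ID": _node_id(t.subject), ":END_ID": _node_id(t.object),
         ":TYPE": t.predicate,
         **{k: json.dumps(t.annotations[k]) if isinstance(t.annotations.get(k), (list, dict))
            else t.annotations.get(k) for k in annotation_keys}}
        for t in sorted(kg.iter_triples(), key=lambda t: t.key)
    ])
    if nodes.empty:
        nodes = pd.DataFrame(columns=["id:ID", ":LABEL", "namespace", "identifier",
                                      "label", "metadata"])
    if edges.empty:
        edges = pd.DataFrame(columns=[":START_ID", ":END_ID", ":TYPE"])
    return nodes, edges


def export(kg: KnowledgeGraph, fmt: str, out: str | Path) -> list[Path]:
    """Write the graph in one of graphml / csv / json / bel.

    ``out`` is a file path (csv: a directory receiving nodes.csv/edges.csv).
    Returns the written paths.
    """
    if fmt not in EXPORT_FORMATS:
        raise ExportFormatError(
            f"unknown export format {fmt!r}; supported: {', '.join(EXPORT_FORMATS)}")
    out = Path(out)
    if fmt == "csv":
        out.mkdir(parents=True, exist_ok=True)
        nodes, edges = _csv_tables(kg)
        node_path, edge_path = out / "nodes.csv", out / "edges.csv"
        nodes.to_csv(node_path, index=False)
        edges.to_csv(edge_path, index=False)
        return [node_path, edge_path]
    out.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "graphml":
        nx.write_graphml(to_networkx(kg), out)
    elif fmt == "json":
        out.write_text(json.dumps(kg.to_dict(), indent=2, sort_keys=True))
    elif fmt == "bel":
        out.write_text(to_bel_script(kg))
    return [out]


def load(path: str | Path, fmt: str | None = None) -> KnowledgeGraph:
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".")
    if fmt == "graphml":
        return from_networkx(nx.read_graphml(path, force_multigraph=True))
    if fmt == "json":
        return KnowledgeGraph.from_dict(json.loads(path.read_text()))
    raise ExportFormatError(f"cannot import format {fmt!r}; supported: graphml, json")
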