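"""Source-record filtering, action-type normalization and KG compilation.

The build runs fetch -> filter -> classify -> add_triple for each disease id
and unions the result into one graph.  Filter semantics are deliberately
pinned: association-score and phase cuts are inclusive (``>=``), the assay
confidence cut is an exact match, and the pChEMBL cut is strict (``>``).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .core_model import Entity, KnowledgeGraph
from .sources.base import SourceBackend, UnknownDiseaseError
from .sources.records import (
    ActivityRecord,
    DrugRecord,
    TargetAssociation,
    VariantRecord,
)

logger = logging.getLogger(__name__)

# Action-type normalization onto the three drug->protein predicates.  The
# increase/decrease vocabularies are closed; everything else (modulator,
# opener, sequestering agent, and any future type) is miscellaneous activity
# and maps to the ``targets`` catch-all.  Matching is case-insensitive and
# the original action type is preserved as a triple annotation by the build.
INCREASE_ACTIONS = frozenset({
    "POSITIVE ALLOSTERIC MODULATOR", "AGONIST", "ACTIVATOR", "PARTIAL ACTIVATOR",
})
DECREASE_ACTIONS = frozenset({
    "INHIBITOR", "NEGATIVE ALLOSTERIC MODULATOR", "ANTAGONIST", "BLOCKER",
})


def classify_action(action_type: Optional[str]) -> str:
    """Map a mechanism action type to increases / decreases / targets."""
    norm = (action_type or "").strip().upper()
    if norm in INCREASE_ACTIONS:
        return "increases"
    if norm in DECREASE_ACTIONS:
        return "decreases"
    return "targets"


class BuildConfig(BaseModel):
    """Filter thresholds and scope of a KG build."""

    disease_ids: list[str]
    score_threshold: float = Field(default=0.0, ge=0.0, le=1.0)
    min_phase: int = Field(default=1, ge=1, le=4)
    pchembl_min: float = 6.0
    confidence_required: int = Field(default=9, ge=0, le=9)
    assay_types: set[str] = Field(default_factory=lambda: {"B", "F"})
    organism: str = "Homo sapiens"
    include_viral: bool = False
    taxonomy_ids: list[int] = Field(default_factory=list)
    #: when true, drop drugs whose target did not survive the score cut
    strict_targets: bool = False

    @field_validator("assay_types", mode="before")
    @classmethod
    def _norm_assay_types(cls, v):
        words = {"biological": "B", "functional": "F", "adme": "A", "physicochemical": "P"}
        out = set()
        for item in v:
            item = str(item).strip()
            out.add(words.get(item.lower(), item.upper()))
        return out


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_targets(assocs: Sequence[TargetAssociation], threshold: float) -> list[TargetAssociation]:
    """Keep associations with score >= threshold, preserving order."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"score threshold must be in [0,1], got {threshold}")
    return [a for a in assocs if a.association_score >= threshold]


def filter_drugs_by_phase(drugs: Sequence[DrugRecord], min_phase: int) -> list[DrugRecord]:
    """Keep drugs with a *known* max phase >= min_phase.

    Unknown-phase drugs (recorded as null/0 upstream) are excluded at any
    threshold.
    """
    if min_phase not in (1, 2, 3, 4):
        raise ValueError(f"min_phase must be in 1..4, got {min_phase}")
    return [d for d in drugs if d.max_phase is not None and d.max_phase >= min_phase]


def filter_activities(records: Sequence[ActivityRecord], cfg: BuildConfig) -> list[ActivityRecord]:
    """Assay filter: organism match, assay type in set, confidence exactly
    equal to the required score, and pChEMBL strictly greater than the cut.

    Records missing a pChEMBL value are dropped and counted in the log.
    """
    kept: list[ActivityRecord] = []
    n_missing = 0
    for a in records:
        if a.pchembl_value is None:
            n_missing += 1
            continue
        if (a.target_organism == cfg.organism
                and a.assay_type in cfg.assay_types
                and a.confidence_score == cfg.confidence_required
                and a.pchembl_value > cfg.pchembl_min):
            kept.append(a)
    if n_missing:
        logger.info("filter_activities: dropped %d records missing pchembl_value", n_missing)
    logger.info("filter_activities: %d in, %d kept", len(records), len(kept))
    return kept


def filter_variants_in_gene(
    records: Sequence[VariantRecord],
    side_output: str | Path | None = None,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Keep SNPs detected within a gene; the full table is a side output.

    A record is in-gene iff it carries a gene symbol and its type is not
    intergenic.  The unfiltered table (with metadata) is returned and, when a
    path is given, written as CSV.
    """
    kept = [v for v in records
            if v.gene_symbol is not None and v.variant_type != "intergenic"]
    full = pd.DataFrame([{
        "rsid": v.rsid, "gene_symbol": v.gene_symbol, "variant_type": v.variant_type,
        "association_score": v.association_score, **v.metadata,
    } for v in records])
    if side_output is not None:
        Path(side_output).parent.mkdir(parents=True, exist_ok=True)
        full.to_csv(side_output, index=False)
    logger.info("filter_variants_in_gene: %d in, %d kept", len(records), len(kept))
    return kept, full


# ---------------------------------------------------------------------------
# entity constructors
# ---------------------------------------------------------------------------

def normalize_event_name(name: str) -> str:
    return name.strip().lower()


def _protein_entity(symbol: str, uniprot_id: str | None, **metadata) -> Entity:
    meta = {k: v for k, v in metadata.items() if v is not None}
    if uniprot_id:
        meta["uniprot_id"] = uniprot_id
        meta["uniprot_url"] = f"https://www.uniprot.org/uniprotkb/{uniprot_id}"
    return Entity("HGNC", symbol, label=symbol, kind="protein", metadata=meta)


def _drug_entity(drug: DrugRecord) -> Entity:
    meta = {
        "drug_type": drug.drug_type,
        "chembl_url": f"https://www.ebi.ac.uk/chembl/compound_report_card/{drug.chembl_id}",
    }
    if drug.max_phase is not None:
        meta["max_phase"] = drug.max_phase
    if drug.smiles:
        meta["smiles"] = drug.smiles
    if drug.trial_ids:
        meta["trial_ids"] = list(drug.trial_ids)
    if drug.warnings:
        meta["warnings"] = [f"{w.toxicity_class}|{w.warning_type}" for w in drug.warnings]
    return Entity("CHEMBL", drug.chembl_id, label=drug.preferred_name or drug.chembl_id,
                  kind="drug", metadata=meta)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def build_kg(
    cfg: BuildConfig,
    backend: SourceBackend,
    out_dir: str | Path | None = None,
) -> tuple[KnowledgeGraph, dict[str, Path]]:
    """Compile one KnowledgeGraph from the configured diseases.

    Every intermediate fetch result is persisted as a CSV side file when
    ``out_dir`` is given.  All disease ids are resolved before any graph
    mutation; an unresolvable id aborts the build.
    """
    for disease_id in cfg.disease_ids:
        if backend.resolve_disease(disease_id) is None:
            raise UnknownDiseaseError(f"disease id not resolvable by backend: {disease_id}")

    kg = KnowledgeGraph(provenance={
        "disease_ids": list(cfg.disease_ids),
        "backend": backend.name,
        "config": cfg.model_dump(mode="json"),
    })
    side_files: dict[str, Path] = {}
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    def _emit(disease_id: str, family: str, df: pd.DataFrame) -> None:
        if out_path is None:
            return
        path = out_path / f"{disease_id.replace(':', '_')}_{family}.csv"
        df.to_csv(path, index=False)
        side_files[f"{disease_id}:{family}"] = path

    for disease_id in cfg.disease_ids:
        _build_one_disease(kg, cfg, backend, disease_id, _emit, out_path)

    kg.validate()
    return kg, side_files


def _build_one_disease(kg: KnowledgeGraph, cfg: BuildConfig, backend: SourceBackend,
                       disease_id: str, _emit, out_path: Path | None) -> None:
    hit = backend.resolve_disease(disease_id)
    disease = Entity("MONDO" if disease_id.startswith("MONDO") else disease_id.split(":", 1)[0],
                     disease_id.split(":", 1)[1], label=hit.name, kind="disease",
                     metadata={"description": hit.description})
    kg.add_entity(disease)

    # -- proteins ---------------------------------------------------------
    targets = backend.fetch_targets(disease_id)
    _emit(disease_id, "targets", pd.DataFrame([t.model_dump() for t in targets]))
    if out_path is not None and targets:
        scores = pd.Series([t.association_score for t in targets])
        hist = scores.value_counts(bins=10, sort=False)
        hist_df = pd.DataFrame({"bin": hist.index.astype(str), "count": hist.values})
        hist_path = out_path / f"{disease_id.replace(':', '_')}_score_histogram.csv"
        hist_df.to_csv(hist_path, index=False)

    kept_targets = filter_targets(targets, cfg.score_threshold)
    logger.info("%s: %d/%d targets kept at score >= %s",
                disease_id, len(kept_targets), len(targets), cfg.score_threshold)
    symbol_by_uniprot = {t.uniprot_id: t.hgnc_symbol for t in targets}
    assoc_by_uniprot = {t.uniprot_id: t for t in targets}
    kept_uniprots = {t.uniprot_id for t in kept_targets}
    for t in kept_targets:
        protein = _protein_entity(
            t.hgnc_symbol, t.uniprot_id,
            ensembl_gene_id=t.ensembl_gene_id or None,
            druggability=t.druggability,
        )
        kg.add_triple(disease, "associated_with", protein,
                      {"association_score": t.association_score})

    # -- drugs ------------------------------------------------------------
    drugs = backend.fetch_drugs(disease_id)
    _emit(disease_id, "drugs", pd.DataFrame([d.model_dump(exclude={"warnings", "adverse_events"})
                                             for d in drugs]))
    kept_drugs = filter_drugs_by_phase(drugs, cfg.min_phase)
    logger.info("%s: %d/%d drugs kept at phase >= %d",
                disease_id, len(kept_drugs), len(drugs), cfg.min_phase)

    mechanisms = backend.fetch_mechanisms([d.chembl_id for d in kept_drugs])
    _emit(disease_id, "mechanisms", pd.DataFrame([m.model_dump() for m in mechanisms]))
    mech_by_drug: dict[str, list] = {}
    for m in mechanisms:
        mech_by_drug.setdefault(m.chembl_id, []).append(m)

    placed_drugs: list[DrugRecord] = []
    for drug in kept_drugs:
        if drug.target_uniprot_id is None:
            logger.info("%s: drug %s has no target in this disease context; skipped",
                        disease_id, drug.chembl_id)
            continue
        if cfg.strict_targets and drug.target_uniprot_id not in kept_uniprots:
            logger.info("%s: drug %s target %s below score threshold; skipped (strict)",
                        disease_id, drug.chembl_id, drug.target_uniprot_id)
            continue
        uniprot = drug.target_uniprot_id
        symbol = symbol_by_uniprot.get(uniprot, uniprot)
        assoc = assoc_by_uniprot.get(uniprot)
        protein = _protein_entity(symbol, uniprot,
                                  druggability=assoc.druggability if assoc else None)
        mechs = mech_by_drug.get(drug.chembl_id, [])
        mech = next((m for m in mechs if m.target_uniprot_id in (None, uniprot)),
                    mechs[0] if mechs else None)
        action = mech.action_type if mech else None
        annotations = {"max_phase": drug.max_phase, "disease_id": disease_id}
        if action is not None:
            annotations["action_type"] = action
        kg.add_triple(_drug_entity(drug), classify_action(action), protein, annotations)
        placed_drugs.append(drug)

        drug_entity = kg.entity("CHEMBL", drug.chembl_id)
        for m in mechs:
            moa_label = m.moa_label or m.action_type.title()
            moa = Entity("MOA", normalize_event_name(moa_label).replace(" ", "_"),
                         label=moa_label, kind="mechanism_of_action")
            kg.add_triple(drug_entity, "has_moa", moa, {"action_type": m.action_type})
        for ae in drug.adverse_events:
            event = Entity("ADVERSE_EVENT", normalize_event_name(ae.event_name).replace(" ", "_"),
                           label=ae.event_name, kind="adverse_event")
            kg.add_triple(drug_entity, "has_adverse_effect", event,
                          {"count": ae.count, "loglr": ae.loglr})

    # -- assays -----------------------------------------------------------
    activities = backend.fetch_activities([d.chembl_id for d in placed_drugs])
    _emit(disease_id, "activities", pd.DataFrame([a.model_dump() for a in activities]))
    for act in filter_activities(activities, cfg):
        drug_entity = kg.entity("CHEMBL", act.molecule_chembl_id)
        assay = Entity("CHEMBL", act.assay_chembl_id, kind="assay",
                       metadata={"assay_type": act.assay_type})
        kg.add_triple(drug_entity, "tested_in", assay,
                      {"assay_type": act.assay_type, "pchembl_value": act.pchembl_value})

    # -- variants ---------------------------------------------------------
    variants = backend.fetch_variants(disease_id)
    side = (out_path / f"{disease_id.replace(':', '_')}_variants_full.csv"
            if out_path is not None else None)
    kept_variants, _full = filter_variants_in_gene(variants, side_output=side)
    for v in kept_variants:
        assoc = next((t for t in targets if t.hgnc_symbol == v.gene_symbol), None)
        protein = _protein_entity(v.gene_symbol, assoc.uniprot_id if assoc else None,
                                  druggability=assoc.druggability if assoc else None)
        variant = Entity("DBSNP", v.rsid, kind="variant",
                         metadata={"variant_type": v.variant_type, **v.metadata})
        kg.add_triple(protein, "has_variant", variant,
                      {"association_score": v.association_score})

    # -- viral proteins ---------------------------------------------------
    viral_annotations = []
    if cfg.include_viral and cfg.taxonomy_ids:
        viral_annotations = backend.fetch_viral_proteins(cfg.taxonomy_ids)
        for ann in viral_annotations:
            kg.add_entity(Entity("UNIPROT", ann.uniprot_id,
                                 label=ann.protein_name or ann.uniprot_id, kind="protein",
                                 metadata={"viral": True}))

    # -- GO / Reactome / PDB annotation pass ------------------------------
    uniprot_by_key = {}
    for e in kg.entities_of_kind("protein"):
        uid = e.metadata.get("uniprot_id") or (e.identifier if e.namespace == "UNIPROT" else None)
        if uid:
            uniprot_by_key[uid] = e
    annotations_list = backend.fetch_protein_annotations(
        sorted(set(uniprot_by_key) - {a.uniprot_id for a in viral_annotations}))
    annotations_list = list(annotations_list) + list(viral_annotations)
    _emit(disease_id, "protein_annotations",
          pd.DataFrame([a.model_dump() for a in annotations_list]))
    for ann in annotations_list:
        protein = uniprot_by_key.get(ann.uniprot_id)
        if protein is None:
            continue
        for go_id, term in ann.go_bp:
            bp = Entity("GO", go_id, label=term, kind="biological_process",
                        metadata={"url": f"https://amigo.geneontology.org/amigo/term/{go_id}"})
            kg.add_triple(protein, "participates_in", bp)
        for go_id, term in ann.go_mf:
            mf = Entity("GO", go_id, label=term, kind="molecular_function",
                        metadata={"url": f"https://amigo.geneontology.org/amigo/term/{go_id}"})
            kg.add_triple(protein, "has_function", mf)
        for reactome_id, name in ann.reactome:
            pw = Entity("REACTOME", reactome_id, label=name, kind="pathway")
            kg.add_triple(protein, "part_of", pw, {"reactome_id": reactome_id})
        if ann.pdb:
            protein.metadata = dict(protein.metadata)
            protein.metadata["pdb"] = [
                {"pdb_id": p.pdb_id, "method": p.method, "resolution": p.resolution}
                for p in ann.pdb
            ]
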