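"""Seeded offline source backend with a ground-truth manifest.

``generate_fixture`` produces a backend serving synthetic-but-schema-faithful
records for one disease, together with a manifest recording every raw record
and per-record flags (default activity-filter pass/fail, variant in-gene),
so downstream filters and the compiled graph have independently known
expected values.  The manifest is a pure function of the config (which
embeds the seed): identical configs yield byte-identical JSON manifests.

SMILES are drawn from a bundled table of real drug structures with frozen
descriptor columns, so chemistry-free tests can still assert on profiles.
"""

from __future__ import annotations

import csv
import json
import random
from importlib import resources
from typing import Optional, Sequence

from pydantic import BaseModel, Field

from .base import (
    SourceBackend,
    UnknownDiseaseError,
    require_chembl,
    require_curie,
    require_uniprot,
)
from .records import (
    ActivityRecord,
    AdverseEvent,
    DiseaseHit,
    DrugRecord,
    MechanismRecord,
    PDBEntry,
    ProteinAnnotation,
    TargetAssociation,
    VariantRecord,
    Warning_,
)

# Action types sampled by the fixture; spans all three normalization buckets.
_ACTION_TYPES = (
    "INHIBITOR", "ANTAGONIST", "BLOCKER", "NEGATIVE ALLOSTERIC MODULATOR",
    "AGONIST", "ACTIVATOR", "POSITIVE ALLOSTERIC MODULATOR", "PARTIAL ACTIVATOR",
    "MODULATOR", "OPENER", "SEQUESTERING AGENT", "BINDING AGENT",
)

_PDB_METHODS = ("X-ray", "NMR", "EM")

_VARIANT_TYPES_IN_GENE = ("intron", "missense", "synonymous", "stop_gained", "3_prime_UTR")


def load_reference_molecules() -> list[dict]:
    """Bundled real-drug SMILES table with frozen descriptor oracle columns."""
    with resources.files("kgg.sources").joinpath("data/reference_molecules.csv").open() as fh:
        rows = list(csv.DictReader(fh))
    for row in rows:
        for key, value in row.items():
            if key in ("name", "smiles"):
                continue
            row[key] = float(value) if "." in value or "e" in value else int(value)
    return rows


class FixtureConfig(BaseModel):
    """Knobs of the synthetic source; all counts >= 0, fully deterministic."""

    seed: int = 0
    disease_id: str = "MONDO:0000001"
    disease_name: str = "synthetic disease"
    n_proteins: int = Field(default=30, ge=0)
    score_min: float = Field(default=0.0, ge=0.0, le=1.0)
    score_max: float = Field(default=1.0, ge=0.0, le=1.0)
    protein_index_start: int = Field(default=0, ge=0)  # shift id range to plant overlaps
    n_drugs: int = Field(default=12, ge=0)
    #: weight of phases None(unknown),1,2,3,4 when sampling max_phase
    phase_weights: tuple[float, float, float, float, float] = (0.1, 0.2, 0.3, 0.2, 0.2)
    drug_type_weights: dict[str, float] = Field(
        default_factory=lambda: {"small molecule": 0.8, "antibody": 0.1,
                                 "protein": 0.05, "unknown": 0.05})
    mean_go_bp: int = Field(default=3, ge=0)
    mean_go_mf: int = Field(default=2, ge=0)
    mean_reactome: int = Field(default=2, ge=0)
    n_pathway_pool: int = Field(default=8, ge=0)
    mean_pdb: float = Field(default=1.0, ge=0)
    n_variants: int = Field(default=10, ge=0)
    in_gene_fraction: float = Field(default=0.7, ge=0.0, le=1.0)
    activities_per_drug: int = Field(default=4, ge=0)
    pchembl_min: float = 4.0
    pchembl_max: float = 9.0
    missing_pchembl_rate: float = Field(default=0.1, ge=0.0, le=1.0)
    druggability_weights: dict[str, float] = Field(
        default_factory=lambda: {"yes": 0.4, "no": 0.2, "unknown": 0.4})
    cross_drug_rate: float = Field(default=0.5, ge=0.0, le=1.0)
    max_cross_drugs: int = Field(default=3, ge=0)
    viral: bool = False
    taxonomy_ids: list[int] = Field(default_factory=list)
    n_viral_proteins: int = Field(default=3, ge=0)


def _weighted_choice(rng: random.Random, weights: dict) -> str:
    keys = list(weights)
    return rng.choices(keys, weights=[weights[k] for k in keys], k=1)[0]


class FixtureBackend(SourceBackend):
    """In-memory backend serving the generated records."""

    name = "fixture"

    def __init__(self, config: FixtureConfig, payload: dict) -> None:
        self.config = config
        self._p = payload

    # -- lookups ----------------------------------------------------------

    def disease_lookup(self, keyword: str) -> list[DiseaseHit]:
        if not keyword:
            raise ValueError("keyword must be non-empty")
        hit = self._p["disease"]
        if keyword.lower() in hit.name.lower() or keyword == hit.disease_id:
            return [hit]
        return []

    def resolve_disease(self, disease_id: str) -> Optional[DiseaseHit]:
        require_curie(disease_id)
        hit = self._p["disease"]
        return hit if disease_id == hit.disease_id else None

    def _for_disease(self, disease_id: str, key: str):
        require_curie(disease_id)
        if disease_id != self._p["disease"].disease_id:
            return []
        return list(self._p[key])

    def fetch_targets(self, disease_id: str) -> list[TargetAssociation]:
        return self._for_disease(disease_id, "targets")

    def fetch_drugs(self, disease_id: str) -> list[DrugRecord]:
        return self._for_disease(disease_id, "drugs")

    def fetch_variants(self, disease_id: str) -> list[VariantRecord]:
        return self._for_disease(disease_id, "variants")

    def fetch_protein_annotations(self, uniprot_ids: Sequence[str]) -> list[ProteinAnnotation]:
        for uid in uniprot_ids:
            require_uniprot(uid)
        table = self._p["annotations"]
        return [table[uid] for uid in uniprot_ids if uid in table]

    def fetch_mechanisms(self, chembl_ids: Sequence[str]) -> list[MechanismRecord]:
        for cid in chembl_ids:
            require_chembl(cid)
        wanted = set(chembl_ids)
        return [m for m in self._p["mechanisms"] if m.chembl_id in wanted]

    def fetch_activities(self, chembl_ids: Sequence[str]) -> list[ActivityRecord]:
        for cid in chembl_ids:
            require_chembl(cid)
        wanted = set(chembl_ids)
        return [a for a in self._p["activities"] if a.molecule_chembl_id in wanted]

    def fetch_viral_proteins(self, taxonomy_ids: Sequence[int]) -> list[ProteinAnnotation]:
        out = []
        for tax in taxonomy_ids:
            out.extend(self._p["viral"].get(int(tax), []))
        return out

    def fetch_drugs_for_target(self, uniprot_id: str) -> list[DrugRecord]:
        require_uniprot(uniprot_id)
        return list(self._p["cross_drugs"].get(uniprot_id, []))


def generate_fixture(config: FixtureConfig) -> tuple[FixtureBackend, dict]:
    """Build (backend, manifest) deterministically from the config."""
    rng = random.Random(config.seed)
    molecules = load_reference_molecules()

    disease = DiseaseHit(disease_id=config.disease_id, name=config.disease_name,
                         description="seeded fixture disease", match_score=1.0)

    # proteins ------------------------------------------------------------
    targets: list[TargetAssociation] = []
    for i in range(config.n_proteins):
        idx = config.protein_index_start + i
        drugg = _weighted_choice(rng, config.druggability_weights)
        targets.append(TargetAssociation(
            hgnc_symbol=f"GENE{idx:05d}",
            uniprot_id=f"P{idx:05d}",
            ensembl_gene_id=f"ENSG{idx:011d}",
            association_score=round(rng.uniform(config.score_min, config.score_max), 6),
            druggability=drugg,
        ))

    # drugs + mechanisms --------------------------------------------------
    drugs: list[DrugRecord] = []
    mechanisms: list[MechanismRecord] = []
    phases = [None, 1, 2, 3, 4]
    for j in range(config.n_drugs):
        chembl_id = f"CHEMBL{9000000 + config.protein_index_start + j}"
        dtype = _weighted_choice(rng, config.drug_type_weights)
        phase = rng.choices(phases, weights=config.phase_weights, k=1)[0]
        mol = rng.choice(molecules)
        target = rng.choice(targets).uniprot_id if targets else None
        action = rng.choice(_ACTION_TYPES)
        n_ae = rng.randint(0, 3)
        drugs.append(DrugRecord(
            chembl_id=chembl_id,
            preferred_name=mol["name"] if dtype == "small molecule" else f"biologic-{j}",
            drug_type=dtype,
            max_phase=phase,
            target_uniprot_id=target,
            trial_ids=[f"NCT{rng.randint(10_000_000, 99_999_999)}"] if phase else [],
            smiles=mol["smiles"] if dtype == "small molecule" else None,
            warnings=[Warning_(toxicity_class="hepatotoxicity", warning_type="black box")]
            if rng.random() < 0.2 else [],
            adverse_events=[
                AdverseEvent(event_name=f"event {rng.randint(0, 20)}",
                             count=rng.randint(1, 500),
                             loglr=round(rng.uniform(0.1, 8.0), 3))
                for _ in range(n_ae)
            ],
        ))
        if target is not None:
            mechanisms.append(MechanismRecord(
                chembl_id=chembl_id, action_type=action,
                moa_label=f"{action.title()} of {target}",
                target_uniprot_id=target))

    # activities ----------------------------------------------------------
    activities: list[ActivityRecord] = []
    for drug in drugs:
        for k in range(config.activities_per_drug):
            missing = rng.random() < config.missing_pchembl_rate
            activities.append(ActivityRecord(
                molecule_chembl_id=drug.chembl_id,
                assay_chembl_id=f"CHEMBL{8000000 + rng.randint(0, 99999)}",
                assay_type=rng.choice(("B", "F", "A", "P")),
                target_organism=rng.choice(("Homo sapiens", "Homo sapiens",
                                            "Rattus norvegicus", "Mus musculus")),
                confidence_score=rng.choice((9, 9, 9, 8, 7, 5, 0)),
                pchembl_value=None if missing else round(
                    rng.uniform(config.pchembl_min, config.pchembl_max), 2),
            ))

    # annotations ---------------------------------------------------------
    pathway_pool = [(f"R-HSA-{100000 + k}", f"pathway {k}")
                    for k in range(config.n_pathway_pool)]
    annotations: dict[str, ProteinAnnotation] = {}
    for t in targets:
        n_bp = rng.randint(0, 2 * config.mean_go_bp)
        n_mf = rng.randint(0, 2 * config.mean_go_mf)
        n_rp = min(rng.randint(0, 2 * config.mean_reactome), len(pathway_pool))
        n_pdb = rng.randint(0, max(1, round(2 * config.mean_pdb)))
        annotations[t.uniprot_id] = ProteinAnnotation(
            uniprot_id=t.uniprot_id,
            protein_name=f"protein {t.hgnc_symbol}",
            gene_symbol=t.hgnc_symbol,
            go_bp=[(f"GO:{rng.randint(1, 99999):07d}", f"process {rng.randint(0, 999)}")
                   for _ in range(n_bp)],
            go_mf=[(f"GO:{rng.randint(100000, 199999):07d}", f"function {rng.randint(0, 999)}")
                   for _ in range(n_mf)],
            reactome=rng.sample(pathway_pool, n_rp),
            pdb=[PDBEntry(pdb_id=f"{rng.randint(1, 9)}{rng.choice('ABCDEFXYZ')}"
                          f"{rng.choice('ABCDEFXYZ')}{rng.randint(0, 9)}",
                          method=rng.choice(_PDB_METHODS),
                          resolution=round(rng.uniform(1.2, 4.5), 2))
                 for _ in range(n_pdb)],
        )

    # variants ------------------------------------------------------------
    variants: list[VariantRecord] = []
    for v in range(config.n_variants):
        in_gene = rng.random() < config.in_gene_fraction and targets
        if in_gene:
            gene = rng.choice(targets).hgnc_symbol
            vtype = rng.choice(_VARIANT_TYPES_IN_GENE)
        else:
            gene = None
            vtype = "intergenic"
        variants.append(VariantRecord(
            rsid=f"rs{rng.randint(1_000, 99_999_999)}",
            gene_symbol=gene, variant_type=vtype,
            association_score=round(rng.uniform(0.0, 1.0), 6),
            metadata={"p_value": 10 ** -rng.uniform(5, 30)},
        ))

    # viral proteins ------------------------------------------------------
    viral: dict[int, list[ProteinAnnotation]] = {}
    if config.viral:
        for tax in config.taxonomy_ids:
            viral[int(tax)] = [
                ProteinAnnotation(
                    uniprot_id=f"Q{tax % 10}{rng.randint(100, 999)}{v}",
                    protein_name=f"viral protein {tax}-{v}",
                    go_bp=[(f"GO:{rng.randint(1, 99999):07d}", "viral process")],
                )
                for v in range(config.n_viral_proteins)
            ]

    # cross-disease drugs (repurposing path) ------------------------------
    cross_drugs: dict[str, list[DrugRecord]] = {}
    for t in targets:
        if rng.random() < config.cross_drug_rate:
            n = rng.randint(1, max(1, config.max_cross_drugs))
            cross_drugs[t.uniprot_id] = [
                DrugRecord(
                    chembl_id=f"CHEMBL{7000000 + rng.randint(0, 99999)}",
                    preferred_name=f"xdrug-{t.uniprot_id}-{x}",
                    drug_type="small molecule",
                    max_phase=rng.choice((1, 2, 3, 4)),
                    target_uniprot_id=t.uniprot_id,
                    smiles=rng.choice(molecules)["smiles"],
                )
                for x in range(n)
            ]

    payload = {
        "disease": disease, "targets": targets, "drugs": drugs,
        "mechanisms": mechanisms, "activities": activities,
        "annotations": annotations, "variants": variants,
        "viral": viral, "cross_drugs": cross_drugs,
    }
    manifest = _build_manifest(config, payload)
    return FixtureBackend(config, payload), manifest


def _passes_default_activity_filter(a: ActivityRecord) -> bool:
    # the default assay filter: human, B/F, confidence exactly 9, pChEMBL > 6
    return (a.target_organism == "Homo sapiens" and a.assay_type in {"B", "F"}
            and a.confidence_score == 9
            and a.pchembl_value is not None and a.pchembl_value > 6.0)


def _build_manifest(config: FixtureConfig, payload: dict) -> dict:
    """Plain-JSON ground truth for every raw record plus per-record flags."""
    mech_by_drug = {}
    for m in payload["mechanisms"]:
        mech_by_drug.setdefault(m.chembl_id, []).append(m)
    manifest = {
        "config": json.loads(config.model_dump_json()),
        "disease": payload["disease"].model_dump(),
        "targets": [t.model_dump() for t in payload["targets"]],
        "drugs": [
            {**d.model_dump(),
             "action_types": [m.action_type for m in mech_by_drug.get(d.chembl_id, [])]}
            for d in payload["drugs"]
        ],
        "mechanisms": [m.model_dump() for m in payload["mechanisms"]],
        "activities": [
            {**a.model_dump(), "passes_default_filter": _passes_default_activity_filter(a)}
            for a in payload["activities"]
        ],
        "variants": [
            {**v.model_dump(),
             "in_gene": v.gene_symbol is not None and v.variant_type != "intergenic"}
            for v in payload["variants"]
        ],
        "annotations": {uid: ann.model_dump() for uid, ann in payload["annotations"].items()},
        "viral": {str(tax): [a.model_dump() for a in anns]
                  for tax, anns in payload["viral"].items()},
        "cross_disease_drugs": {uid: [d.model_dump() for d in ds]
                                for uid, ds in payload["cross_drugs"].items()},
    }
    return manifest


def manifest_json(manifest: dict) -> str:
    """Canonical (byte-stable) JSON rendering of a manifest."""
    return json.dumps(manifest, sort_keys=True, separators=(",", ":"))
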