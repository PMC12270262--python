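"""Normalized source-record payloads.

Every raw field consumed downstream of a source client appears in exactly one
of these record types, regardless of whether the backend is a live HTTP
client or the seeded offline fixture.
"""

from __future__ import annotations

import re
from typing import Optional

from pydantic import BaseModel, Field, field_validator

_RSID_RE = re.compile(r"^rs[0-9]+$")
_CURIE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9.]*:\S+$")


class DiseaseHit(BaseModel):
    """One row of a disease-lookup result, ranked by relevance."""

    disease_id: str
    name: str
    description: str = ""
    match_score: float = 0.0

    @field_validator("disease_id")
    @classmethod
    def _curie_shaped(cls, v: str) -> str:
        if not _CURIE_RE.match(v):
            raise ValueError(f"disease_id must be CURIE-shaped, got {v!r}")
        return v


class TargetAssociation(BaseModel):
    """Disease-associated protein with its aggregate evidence score."""

    hgnc_symbol: str
    uniprot_id: str
    ensembl_gene_id: str = ""
    association_score: float = Field(ge=0.0, le=1.0)
    druggability: Optional[str] = None  # yes / no / None (unknown)

    @field_validator("druggability")
    @classmethod
    def _norm_druggability(cls, v):
        if v is None:
            return None
        v = v.strip().lower()
        if v not in {"yes", "no", "unknown"}:
            raise ValueError(f"druggability must be yes/no/unknown, got {v!r}")
        return None if v == "unknown" else v


class Warning_(BaseModel):
    toxicity_class: str
    warning_type: str


class AdverseEvent(BaseModel):
    event_name: str
    count: int = Field(ge=0)
    loglr: float


class DrugRecord(BaseModel):
    """A disease-context drug with trial, warning and side-effect payload."""

    chembl_id: str
    preferred_name: str = ""
    drug_type: str = "small molecule"
    max_phase: Optional[int] = None  # None == unknown phase
    target_uniprot_id: Optional[str] = None
    trial_ids: list[str] = Field(default_factory=list)
    smiles: Optional[str] = None
    warnings: list[Warning_] = Field(default_factory=list)
    adverse_events: list[AdverseEvent] = Field(default_factory=list)

    @field_validator("max_phase", mode="before")
    @classmethod
    def _phase_range(cls, v):
        if v in (None, 0, "0", ""):
            return None  # phase 0 / null -> unknown
        v = int(v)
        if not 1 <= v <= 4:
            raise ValueError(f"max_phase must be in 1..4 when known, got {v}")
        return v


class ActivityRecord(BaseModel):
    """One assay measurement of a molecule (ChEMBL activity resource shape)."""

    molecule_chembl_id: str
    assay_chembl_id: str
    assay_type: str  # single-letter code: B, F, A, P, U ...
    target_organism: str = ""
    confidence_score: int = Field(ge=0, le=9)
    pchembl_value: Optional[float] = None

    @field_validator("assay_type")
    @classmethod
    def _norm_assay_type(cls, v: str) -> str:
        v = v.strip()
        words = {"biological": "B", "functional": "F", "adme": "A", "physicochemical": "P"}
        return words.get(v.lower(), v.upper())


class MechanismRecord(BaseModel):
    """Mechanism-of-action assignment for a molecule on a target."""

    chembl_id: str
    action_type: str
    moa_label: str = ""
    target_uniprot_id: Optional[str] = None

    @field_validator("action_type")
    @classmethod
    def _upper(cls, v: str) -> str:
        return v.strip().upper()


class VariantRecord(BaseModel):
    """A disease-associated SNP with its genic context."""

    rsid: str
    gene_symbol: Optional[str] = None
    variant_type: str = "intron"
    association_score: float = 0.0
    metadata: dict = Field(default_factory=dict)

    @field_validator("rsid")
    @classmethod
    def _rsid_shape(cls, v: str) -> str:
        if not _RSID_RE.match(v):
            raise ValueError(f"rsid must match rs[0-9]+, got {v!r}")
        return v


class PDBEntry(BaseModel):
    pdb_id: str
    method: str = "X-ray"
    resolution: Optional[float] = None

    @field_validator("pdb_id")
    @classmethod
    def _four_chars(cls, v: str) -> str:
        if len(v) != 4:
            raise ValueError(f"PDB ids are 4 characters, got {v!r}")
        return v


class ProteinAnnotation(BaseModel):
    """GO / Reactome / PDB cross-references of one protein."""

    uniprot_id: str
    protein_name: str = ""
    gene_symbol: Optional[str] = None
    go_bp: list[tuple[str, str]] = Field(default_factory=list)
    go_mf: list[tuple[str, str]] = Field(default_factory=list)
    reactome: list[tuple[str, str]] = Field(default_factory=list)
    pdb: list[PDBEntry] = Field(default_factory=list)

    @field_validator("go_bp", "go_mf")
    @classmethod
    def _go_prefixed(cls, v):
        for go_id, _term in v:
            if not go_id.startswith("GO:"):
                raise ValueError(f"GO ids must be GO:-prefixed, got {go_id!r}")
        return v
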