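"""Source-backend abstraction shared by live clients and the fixture backend."""

from __future__ import annotations

import abc
import re
from typing import Optional, Sequence

from .records import (
    ActivityRecord,
    DiseaseHit,
    DrugRecord,
    MechanismRecord,
    ProteinAnnotation,
    TargetAssociation,
    VariantRecord,
)

_CURIE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9.]*:\S+$")
_UNIPROT_RE = re.compile(r"^[A-NR-Z][0-9][A-Z0-9]{3}[0-9]([A-Z0-9]{4})?$|^[OPQ][0-9][A-Z0-9]{3}[0-9]$")
_CHEMBL_RE = re.compile(r"^CHEMBL[0-9]+$")


class InvalidIdentifierError(ValueError):
    """Raised before any network call when a query id is malformed."""


class TransportError(RuntimeError):
    """Backend unreachable / HTTP failure, with endpoint context."""


class UnknownDiseaseError(KeyError):
    """A disease id could not be resolved by the backend."""


def require_curie(disease_id: str) -> str:
    if not _CURIE_RE.match(disease_id or ""):
        raise InvalidIdentifierError(f"not a CURIE-shaped disease id: {disease_id!r}")
    return disease_id


def require_uniprot(uniprot_id: str) -> str:
    if not _UNIPROT_RE.match(uniprot_id or ""):
        raise InvalidIdentifierError(f"not a UniProt accession: {uniprot_id!r}")
    return uniprot_id


def require_chembl(chembl_id: str) -> str:
    if not _CHEMBL_RE.match(chembl_id or ""):
        raise InvalidIdentifierError(f"not a ChEMBL id: {chembl_id!r}")
    return chembl_id


class SourceBackend(abc.ABC):
    """Normalized record delivery for the build pipeline.

    Implementations must return records in the shared schemas whatever the
    underlying transport; unknown-but-well-formed ids yield empty results.
    """

    name: str = "abstract"

    @abc.abstractmethod
    def disease_lookup(self, keyword: str) -> list[DiseaseHit]:
        """Rank disease hits for a free-text keyword. Empty list is valid."""

    @abc.abstractmethod
    def resolve_disease(self, disease_id: str) -> Optional[DiseaseHit]:
        """Resolve a CURIE to its disease record, or None if unknown."""

    @abc.abstractmethod
    def fetch_targets(self, disease_id: str) -> list[TargetAssociation]: ...

    @abc.abstractmethod
    def fetch_drugs(self, disease_id: str) -> list[DrugRecord]: ...

    @abc.abstractmethod
    def fetch_protein_annotations(self, uniprot_ids: Sequence[str]) -> list[ProteinAnnotation]: ...

    @abc.abstractmethod
    def fetch_mechanisms(self, chembl_ids: Sequence[str]) -> list[MechanismRecord]: ...

    @abc.abstractmethod
    def fetch_activities(self, chembl_ids: Sequence[str]) -> list[ActivityRecord]: ...

    @abc.abstractmethod
    def fetch_variants(self, disease_id: str) -> list[VariantRecord]: ...

    @abc.abstractmethod
    def fetch_viral_proteins(self, taxonomy_ids: Sequence[int]) -> list[ProteinAnnotation]: ...

    @abc.abstractmethod
    def fetch_drugs_for_target(self, uniprot_id: str) -> list[DrugRecord]:
        """Drugs targeting a protein in *any* disease context (repurposing)."""
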