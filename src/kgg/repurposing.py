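"""Pathway-neighborhood target expansion and repurposing-candidate retrieval.

Pipeline: (1) rank pathways by how many of their member proteins are targeted
by clinical-trial drugs in the graph; (2) expand the neighborhood of chosen
pathways to member proteins not yet targeted in this disease, dropping those
explicitly annotated non-druggable; (3) rank candidates by pathway
multiplicity; (4) query the source backend for late-phase drugs hitting the
candidates in any other disease context.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .core_model import DRUG_PROTEIN_PREDICATES, EntityKey, KnowledgeGraph
from .sources.base import SourceBackend


@dataclass
class PathwayNeighborhood:
    """Trial-target and expansion-candidate proteins of one pathway."""

    pathway_id: str
    trial_proteins: list[str]
    candidate_proteins: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.trial_proteins) & set(self.candidate_proteins)
        if overlap:
            raise ValueError(f"candidates overlap trial targets: {sorted(overlap)}")


@dataclass
class RepurposingCandidate:
    chembl_id: str
    preferred_name: str
    protein: str
    max_phase: int
    source_context: str = "other-disease clinical trials"


def _phase_known(value) -> bool:
    if isinstance(value, list):  # merged annotation collision keeps all values
        return any(_phase_known(v) for v in value)
    return isinstance(value, int) and value >= 1


def trial_target_proteins(kg: KnowledgeGraph) -> set[EntityKey]:
    """Proteins with >= 1 incoming drug edge whose drug has a known phase >= 1."""
    out: set[EntityKey] = set()
    for t in kg.iter_triples():
        if t.predicate in DRUG_PROTEIN_PREDICATES and _phase_known(
                t.annotations.get("max_phase")):
            out.add(t.object)
    return out


def _pathway_members(kg: KnowledgeGraph) -> dict[EntityKey, set[EntityKey]]:
    members: dict[EntityKey, set[EntityKey]] = {}
    for t in kg.iter_triples():
        if t.predicate == "part_of":
            members.setdefault(t.object, set()).add(t.subject)
    return members


def trial_target_pathway_ranking(kg: KnowledgeGraph) -> list[tuple[str, int]]:
    """Pathways ranked by number of member proteins under clinical-trial drugs.

    A protein counts once per pathway but contributes to every pathway it is
    on.  Descending by count, ties broken lexicographically by pathway id.
    Pathways with zero trial-target members are omitted.
    """
    trial = trial_target_proteins(kg)
    counts = []
    for pathway, members in _pathway_members(kg).items():
        n = len(members & trial)
        if n:
            counts.append((pathway[1], n))
    return sorted(counts, key=lambda item: (-item[1], item[0]))


def _druggability(kg: KnowledgeGraph, key: EntityKey) -> str:
    value = kg.entities[key].metadata.get("druggability")
    if isinstance(value, list):  # merged conflicting annotations: worst case wins
        return "no" if "no" in value else value[0]
    return value or "unknown"


def expand_candidates(kg: KnowledgeGraph, pathways: Sequence[str]) -> list[PathwayNeighborhood]:
    """Per pathway: members split into trial targets and druggable candidates.

    Candidates are pathway members that are not trial targets anywhere in the
    graph and are not explicitly annotated druggability == "no"; unknown
    druggability is retained.
    """
    members_by_pathway = _pathway_members(kg)
    by_id = {key[1]: key for key in members_by_pathway}
    trial = trial_target_proteins(kg)
    out = []
    for pathway_id in pathways:
        key = by_id.get(pathway_id)
        if key is None:
            raise KeyError(f"pathway {pathway_id!r} not present in the graph")
        members = members_by_pathway[key]
        trial_here = sorted(m[1] for m in members & trial)
        candidates = sorted(
            m[1] for m in members - trial
            if _druggability(kg, m) != "no"
        )
        out.append(PathwayNeighborhood(pathway_id, trial_here, candidates))
    return out


def rank_candidates_by_pathway_count(
    neighborhoods: Sequence[PathwayNeighborhood],
) -> list[tuple[str, int]]:
    """Candidate proteins ranked by how many input pathways they sit on."""
    counts: dict[str, int] = {}
    for nb in neighborhoods:
        for protein in set(nb.candidate_proteins):
            counts[protein] = counts.get(protein, 0) + 1
    return sorted(counts.items(), key=lambda item: (-item[1], item[0]))


def find_repurposing_drugs(
    proteins: Sequence[str],
    backend: SourceBackend,
    min_phase: int = 3,
) -> dict[str, list[RepurposingCandidate]]:
    """Late-phase drugs targeting each protein in any disease context.

    ``proteins`` are UniProt accessions.  An empty list for a protein is a
    valid result and stays in the report with zero candidates.
    """
    if min_phase not in (1, 2, 3, 4):
        raise ValueError(f"min_phase must be in 1..4, got {min_phase}")
    out: dict[str, list[RepurposingCandidate]] = {}
    for uid in proteins:
        drugs = backend.fetch_drugs_for_target(uid)
        out[uid] = [
            RepurposingCandidate(
                chembl_id=d.chembl_id, preferred_name=d.preferred_name,
                protein=uid, max_phase=d.max_phase)
            for d in drugs
            if d.max_phase is not None and d.max_phase >= min_phase
        ]
    return out
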