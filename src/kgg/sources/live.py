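"""Live HTTP source clients with a replayable on-disk response cache.

Every request is cached to one JSON file keyed by a hash of the request, so a
build re-run against the same cache directory is fully reproducible and test
suites never need the network once a cache is recorded.

These clients follow the public response schemas of the upstream services
(OpenTargets GraphQL, UniProt REST, ChEMBL REST, GWAS Central REST) and
normalize them into the shared record types.  They are exercised only in
online smoke runs; offline correctness is carried by the fixture backend,
which serves the same record types through the same interface.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional, Sequence

from .base import (
    SourceBackend,
    TransportError,
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

logger = logging.getLogger(__name__)

OPENTARGETS_GRAPHQL = "https://api.platform.opentargets.org/api/v4/graphql"
UNIPROT_REST = "https://rest.uniprot.org/uniprotkb"
CHEMBL_REST = "https://www.ebi.ac.uk/chembl/api/data"
GWAS_CENTRAL = "https://www.gwascentral.org/api"

#: disease-specific protein-protein interactions are deliberately not part of
#: the schema; the IID client exists only as a stub behind this flag.
ENABLE_IID_STUB = False


def iid_client_stub(*_args, **_kwargs):
    if not ENABLE_IID_STUB:
        raise NotImplementedError("IID PPI retrieval is not part of the KG schema")
    raise NotImplementedError("IID client is a stub; no PPI edges are modeled")


class ResponseCache:
    """One JSON file per request hash under the cache directory."""

    def __init__(self, cache_dir: str | Path) -> None:
        self.root = Path(cache_dir)
        self.root.mkdir(parents=True, exist_ok=True)

    def _path(self, key: str) -> Path:
        return self.root / f"{key}.json"

    @staticmethod
    def key(method: str, url: str, payload) -> str:
        blob = json.dumps([method, url, payload], sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def get(self, key: str):
        path = self._path(key)
        if path.exists():
            return json.loads(path.read_text())
        return None

    def put(self, key: str, value) -> None:
        self._path(key).write_text(json.dumps(value, sort_keys=True))


class LiveBackend(SourceBackend):
    """HTTP-backed source clients (OpenTargets / UniProt / ChEMBL / GWAS Central)."""

    name = "live"

    def __init__(self, cache_dir: str | Path = ".kgg_cache", *,
                 opentargets_url: str = OPENTARGETS_GRAPHQL,
                 uniprot_url: str = UNIPROT_REST,
                 chembl_url: str = CHEMBL_REST,
                 gwas_url: str = GWAS_CENTRAL,
                 retries: int = 3, backoff: float = 1.5, timeout: float = 30.0) -> None:
        self.cache = ResponseCache(cache_dir)
        self.opentargets_url = opentargets_url
        self.uniprot_url = uniprot_url
        self.chembl_url = chembl_url
        self.gwas_url = gwas_url
        self.retries = retries
        self.backoff = backoff
        self.timeout = timeout

    # -- transport --------------------------------------------------------

    def _request(self, method: str, url: str, *, params=None, json_body=None):
        import requests

        payload = {"params": params, "json": json_body}
        key = self.cache.key(method, url, payload)
        cached = self.cache.get(key)
        if cached is not None:
            return cached
        last_exc: Exception | None = None
        for attempt in range(self.retries):
            try:
                resp = requests.request(method, url, params=params, json=json_body,
                                        timeout=self.timeout)
                resp.raise_for_status()
                data = resp.json()
                self.cache.put(key, data)
                return data
            except Exception as exc:  # noqa: BLE001 - wrapped below with context
                last_exc = exc
                sleep = self.backoff * (2 ** attempt)
                logger.warning("request to %s failed (%s); retrying in %.1fs",
                               url, exc, sleep)
                time.sleep(sleep)
        raise TransportError(f"{method} {url} failed after {self.retries} attempts: {last_exc}")

    def _graphql(self, query: str, variables: dict):
        data = self._request("POST", self.opentargets_url,
                             json_body={"query": query, "variables": variables})
        if "errors" in data:
            raise TransportError(f"OpenTargets GraphQL error: {data['errors']}")
        return data["data"]

    # -- disease ----------------------------------------------------------

    _SEARCH_QUERY = """
    query Search($q: String!) {
      search(queryString: $q, entityNames: ["disease"]) {
        hits { id name description score }
      }
    }"""

    _DISEASE_QUERY = """
    query Disease($id: String!) { disease(efoId: $id) { id name description } }"""

    def disease_lookup(self, keyword: str) -> list[DiseaseHit]:
        if not keyword:
            raise ValueError("keyword must be non-empty")
        data = self._graphql(self._SEARCH_QUERY, {"q": keyword})
        hits = []
        for h in data["search"]["hits"]:
            hits.append(DiseaseHit(
                disease_id=h["id"].replace("_", ":", 1),
                name=h.get("name", ""), description=h.get("description") or "",
                match_score=float(h.get("score") or 0.0)))
        return hits

    def resolve_disease(self, disease_id: str) -> Optional[DiseaseHit]:
        require_curie(disease_id)
        data = self._graphql(self._DISEASE_QUERY, {"id": disease_id.replace(":", "_")})
        d = data.get("disease")
        if not d:
            return None
        return DiseaseHit(disease_id=disease_id, name=d.get("name", ""),
                          description=d.get("description") or "", match_score=1.0)

    # -- targets & drugs (association endpoint aggregates descendants) ----

    _TARGETS_QUERY = """
    query Targets($id: String!, $index: Int!) {
      disease(efoId: $id) {
        associatedTargets(page: {index: $index, size: 500}) {
          count
          rows {
            score
            target { approvedSymbol id proteinIds { id source } }
          }
        }
      }
    }"""

    def fetch_targets(self, disease_id: str) -> list[TargetAssociation]:
        require_curie(disease_id)
        out: list[TargetAssociation] = []
        index = 0
        while True:
            data = self._graphql(self._TARGETS_QUERY,
                                 {"id": disease_id.replace(":", "_"), "index": index})
            block = (data.get("disease") or {}).get("associatedTargets") or {}
            rows = block.get("rows", [])
            for row in rows:
                target = row["target"]
                uniprot = next((p["id"] for p in target.get("proteinIds", [])
                                if p.get("source") == "uniprot_swissprot"), None)
                if uniprot is None:
                    continue
                out.append(TargetAssociation(
                    hgnc_symbol=target["approvedSymbol"],
                    uniprot_id=uniprot,
                    ensembl_gene_id=target["id"],
                    association_score=float(row["score"])))
            if not rows or len(out) >= int(block.get("count", 0)):
                break
            index += 1
        return out

    _DRUGS_QUERY = """
    query Drugs($id: String!, $cursor: String) {
      disease(efoId: $id) {
        knownDrugs(size: 500, cursor: $cursor) {
          cursor
          rows {
            drug { id name drugType }
            phase
            ctIds
            target { proteinIds { id source } }
          }
        }
      }
    }"""

    def fetch_drugs(self, disease_id: str) -> list[DrugRecord]:
        require_curie(disease_id)
        out: list[DrugRecord] = []
        cursor = None
        while True:
            data = self._graphql(self._DRUGS_QUERY,
                                 {"id": disease_id.replace(":", "_"), "cursor": cursor})
            block = (data.get("disease") or {}).get("knownDrugs") or {}
            rows = block.get("rows", [])
            for row in rows:
                target = row.get("target") or {}
                uniprot = next((p["id"] for p in target.get("proteinIds", [])
                                if p.get("source") == "uniprot_swissprot"), None)
                out.append(DrugRecord(
                    chembl_id=row["drug"]["id"],
                    preferred_name=row["drug"].get("name", ""),
                    drug_type=(row["drug"].get("drugType") or "unknown").lower(),
                    max_phase=row.get("phase"),
                    target_uniprot_id=uniprot,
                    trial_ids=list(row.get("ctIds") or []),
                    smiles=None,  # filled from ChEMBL molecule resource on demand
                ))
            cursor = block.get("cursor")
            if not rows or not cursor:
                break
        return out

    # -- UniProt ----------------------------------------------------------

    def fetch_protein_annotations(self, uniprot_ids: Sequence[str]) -> list[ProteinAnnotation]:
        out = []
        for uid in uniprot_ids:
            require_uniprot(uid)
        for uid in uniprot_ids:
            entry = self._request("GET", f"{self.uniprot_url}/{uid}.json")
            out.append(self._parse_uniprot_entry(entry))
        return out

    @staticmethod
    def _parse_uniprot_entry(entry: dict) -> ProteinAnnotation:
        go_bp, go_mf, reactome, pdb = [], [], [], []
        for xref in entry.get("uniProtKBCrossReferences", []):
            db = xref.get("database")
            if db == "GO":
                term = next((p["value"] for p in xref.get("properties", [])
                             if p.get("key") == "GoTerm"), "")
                if term.startswith("P:"):
                    go_bp.append((xref["id"], term[2:]))
                elif term.startswith("F:"):
                    go_mf.append((xref["id"], term[2:]))
            elif db == "Reactome":
                name = next((p["value"] for p in xref.get("properties", [])
                             if p.get("key") == "PathwayName"), "")
                reactome.append((xref["id"], name))
            elif db == "PDB":
                method = next((p["value"] for p in xref.get("properties", [])
                               if p.get("key") == "Method"), "")
                res = next((p["value"] for p in xref.get("properties", [])
                            if p.get("key") == "Resolution"), "")
                try:
                    resolution = float(res.rstrip(" A")) if res and res != "-" else None
                except ValueError:
                    resolution = None
                pdb.append(PDBEntry(pdb_id=xref["id"], method=method, resolution=resolution))
        genes = entry.get("genes") or [{}]
        return ProteinAnnotation(
            uniprot_id=entry["primaryAccession"],
            protein_name=(entry.get("proteinDescription", {}).get("recommendedName", {})
                          .get("fullName", {}).get("value", "")),
            gene_symbol=genes[0].get("geneName", {}).get("value"),
            go_bp=go_bp, go_mf=go_mf, reactome=reactome, pdb=pdb)

    def fetch_viral_proteins(self, taxonomy_ids: Sequence[int]) -> list[ProteinAnnotation]:
        out: list[ProteinAnnotation] = []
        for tax in taxonomy_ids:
            data = self._request(
                "GET", f"{self.uniprot_url}/search",
                params={"query": f"organism_id:{int(tax)} AND reviewed:true",
                        "format": "json", "size": 500})
            for entry in data.get("results", []):
                out.append(self._parse_uniprot_entry(entry))
        return out

    # -- ChEMBL -----------------------------------------------------------

    def fetch_mechanisms(self, chembl_ids: Sequence[str]) -> list[MechanismRecord]:
        for cid in chembl_ids:
            require_chembl(cid)
        out: list[MechanismRecord] = []
        for chunk_start in range(0, len(chembl_ids), 50):
            chunk = chembl_ids[chunk_start:chunk_start + 50]
            data = self._request(
                "GET", f"{self.chembl_url}/mechanism.json",
                params={"molecule_chembl_id__in": ",".join(chunk), "limit": 1000})
            for m in data.get("mechanisms", []):
                out.append(MechanismRecord(
                    chembl_id=m["molecule_chembl_id"],
                    action_type=m.get("action_type") or "UNKNOWN",
                    moa_label=m.get("mechanism_of_action") or "",
                    target_uniprot_id=None))
        return out

    def fetch_activities(self, chembl_ids: Sequence[str]) -> list[ActivityRecord]:
        for cid in chembl_ids:
            require_chembl(cid)
        out: list[ActivityRecord] = []
        for cid in chembl_ids:
            offset = 0
            while True:
                data = self._request(
                    "GET", f"{self.chembl_url}/activity.json",
                    params={"molecule_chembl_id": cid, "limit": 1000, "offset": offset})
                acts = data.get("activities", [])
                for a in acts:
                    pchembl = a.get("pchembl_value")
                    out.append(ActivityRecord(
                        molecule_chembl_id=cid,
                        assay_chembl_id=a["assay_chembl_id"],
                        assay_type=a.get("assay_type") or "U",
                        target_organism=a.get("target_organism") or "",
                        confidence_score=int(a.get("assay_confidence_score") or 0),
                        pchembl_value=float(pchembl) if pchembl else None))
                meta = data.get("page_meta") or {}
                offset += len(acts)
                if not acts or not meta.get("next"):
                    break
        return out

    def fetch_drugs_for_target(self, uniprot_id: str) -> list[DrugRecord]:
        require_uniprot(uniprot_id)
        data = self._request(
            "GET", f"{self.chembl_url}/mechanism.json",
            params={"target_chembl_id__in": "", "limit": 1000,
                    "molecule_chembl_id__isnull": "false",
                    "target_components__accession": uniprot_id})
        out = []
        for m in data.get("mechanisms", []):
            out.append(DrugRecord(
                chembl_id=m["molecule_chembl_id"],
                preferred_name=m.get("molecule_pref_name") or "",
                drug_type="small molecule",
                max_phase=m.get("max_phase"),
                target_uniprot_id=uniprot_id))
        return out

    # -- GWAS Central ------------------------------------------------------

    def fetch_variants(self, disease_id: str) -> list[VariantRecord]:
        require_curie(disease_id)
        data = self._request("GET", f"{self.gwas_url}/studies",
                             params={"disease": disease_id, "format": "json"})
        out: list[VariantRecord] = []
        for rec in data.get("associations", []):
            rsid = rec.get("rsid") or rec.get("variant_id")
            if not rsid:
                continue
            out.append(VariantRecord(
                rsid=rsid,
                gene_symbol=rec.get("gene") or None,
                variant_type=rec.get("variant_type") or "intergenic",
                association_score=float(rec.get("score") or 0.0),
                metadata={"p_value": rec.get("p_value"), "source_score": rec.get("score")}))
        return out
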