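"""Shared fixtures and independent brute-force oracles.

The oracle functions below recompute expected values by direct linear scans
over the raw fixture manifest (plain dicts), deliberately not sharing any
code path with the package's build/filter/analysis implementations.
"""

from __future__ import annotations

import pytest

from kgg.build import BuildConfig
from kgg.sources import FixtureConfig, generate_fixture


@pytest.fixture()
def fixture_pair():
    backend, manifest = generate_fixture(FixtureConfig(seed=11, n_proteins=25, n_drugs=10,
                                                       activities_per_drug=6, n_variants=12))
    return backend, manifest


@pytest.fixture()
def built_kg(fixture_pair):
    from kgg.build import build_kg

    backend, manifest = fixture_pair
    cfg = BuildConfig(disease_ids=[manifest["disease"]["disease_id"]])
    kg, _ = build_kg(cfg, backend)
    return kg, manifest, cfg


# ---------------------------------------------------------------------------
# brute-force oracles over the raw manifest
# ---------------------------------------------------------------------------

def scan_targets(manifest, threshold):
    return [t for t in manifest["targets"] if t["association_score"] >= threshold]


def scan_drugs(manifest, min_phase):
    return [d for d in manifest["drugs"]
            if d["max_phase"] is not None and d["max_phase"] >= min_phase]


def scan_activities(manifest, cfg: BuildConfig, molecule_ids=None):
    out = []
    for a in manifest["activities"]:
        if molecule_ids is not None and a["molecule_chembl_id"] not in molecule_ids:
            continue
        if a["pchembl_value"] is None:
            continue
        if (a["target_organism"] == cfg.organism
                and a["assay_type"] in cfg.assay_types
                and a["confidence_score"] == cfg.confidence_required
                and a["pchembl_value"] > cfg.pchembl_min):
            out.append(a)
    return out


def scan_variants_in_gene(manifest):
    return [v for v in manifest["variants"]
            if v["gene_symbol"] is not None and v["variant_type"] != "intergenic"]


def _classify(action):
    action = (action or "").strip().upper()
    if action in {"POSITIVE ALLOSTERIC MODULATOR", "AGONIST", "ACTIVATOR",
                  "PARTIAL ACTIVATOR"}:
        return "increases"
    if action in {"INHIBITOR", "NEGATIVE ALLOSTERIC MODULATOR", "ANTAGONIST", "BLOCKER"}:
        return "decreases"
    return "targets"


def expected_composition(manifest, cfg: BuildConfig) -> dict:
    """Expected per-kind entity counts of build_kg, by direct enumeration."""
    symbols = {t["uniprot_id"]: t["hgnc_symbol"] for t in manifest["targets"]}
    kept_targets = scan_targets(manifest, cfg.score_threshold)
    kept_uniprots = {t["uniprot_id"] for t in kept_targets}

    drugs = []
    for d in scan_drugs(manifest, cfg.min_phase):
        if d["target_uniprot_id"] is None:
            continue
        if cfg.strict_targets and d["target_uniprot_id"] not in kept_uniprots:
            continue
        drugs.append(d)
    drug_ids = {d["chembl_id"] for d in drugs}

    protein_uniprots = set(kept_uniprots)
    protein_uniprots |= {d["target_uniprot_id"] for d in drugs}

    kept_variants = scan_variants_in_gene(manifest)
    gene_uniprots = {u for u, s in symbols.items()
                     if s in {v["gene_symbol"] for v in kept_variants}}
    protein_uniprots |= gene_uniprots

    moas = set()
    for m in manifest["mechanisms"]:
        if m["chembl_id"] in drug_ids:
            label = m["moa_label"] or m["action_type"].title()
            moas.add(label.strip().lower().replace(" ", "_"))

    adverse = set()
    for d in drugs:
        for ae in d["adverse_events"]:
            adverse.add(ae["event_name"].strip().lower().replace(" ", "_"))

    assays = {a["assay_chembl_id"] for a in scan_activities(manifest, cfg, drug_ids)}

    go_bp, go_mf, pathways = set(), set(), set()
    for uid in protein_uniprots:
        ann = manifest["annotations"].get(uid)
        if ann is None:
            continue
        go_bp |= {g[0] for g in ann["go_bp"]}
        go_mf |= {g[0] for g in ann["go_mf"]}
        pathways |= {r[0] for r in ann["reactome"]}

    n_viral = 0
    if cfg.include_viral:
        for tax in cfg.taxonomy_ids:
            viral = manifest["viral"].get(str(tax), [])
            n_viral += len(viral)
            for ann in viral:
                go_bp |= {g[0] for g in ann["go_bp"]}
                go_mf |= {g[0] for g in ann["go_mf"]}
                pathways |= {r[0] for r in ann["reactome"]}

    return {
        "disease": 1,
        "protein": len({symbols[u] for u in protein_uniprots}) + n_viral,
        "drug": len(drug_ids),
        "biological_process": len(go_bp),
        "molecular_function": len(go_mf),
        "pathway": len(pathways),
        "variant": len({v["rsid"] for v in kept_variants}),
        "assay": len(assays),
        "adverse_event": len(adverse),
        "mechanism_of_action": len(moas),
    }
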