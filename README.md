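# kgg

Build disease-specific knowledge graphs from curated bioinformatics sources
and run downstream analyses on them: graph comparison and merging,
drug-likeness profiling, PDB structure summaries, and pathway-neighborhood
drug repurposing.

A graph holds up to ten kinds of namespaced entities (disease, protein, drug,
biological process, molecular function, pathway, variant, assay, adverse
event, mechanism of action) connected by eleven typed predicates. Drug-to-
protein edges are normalized to `increases` / `decreases` / `targets`
depending on the pharmacological action type, with the original action kept
as an edge annotation.

## Layout

- `kgg.core_model` — entity/predicate schema, the annotated triple store,
  summaries and subgraphs.
- `kgg.sources` — the source-backend abstraction: normalized record types,
  live HTTP clients with an on-disk response cache (OpenTargets GraphQL,
  UniProt, ChEMBL, GWAS Central), and a fully deterministic seeded fixture
  backend with a ground-truth manifest for offline testing.
- `kgg.build` — filters (association score, clinical phase, assay
  organism/type/confidence/pChEMBL, in-gene variants), action-type
  classification and KG compilation with CSV side files.
- `kgg.graph_ops` — merge, per-kind shared-entity reports with identifier
  normalization (e.g. CHEBI→ChEMBL via a mapping table), PDB structure
  summaries, and GraphML / JSON / node-edge CSV / BEL-script export.
- `kgg.druglikeness` — RDKit descriptor profiles and the five-filter battery
  (Ghose, Lipinski rule of five, QED, REOS, Veber). QED is an in-house
  weighted-geometric-mean-of-desirabilities implementation.
- `kgg.repurposing` — pathway ranking by clinical-trial target membership,
  neighborhood expansion to druggable non-trial proteins, and late-phase
  cross-disease drug retrieval.

## CLI

```bash
kgg lookup parkinson                                   # disease id lookup
kgg build --disease MONDO:0005180 --score 0.0 --min-phase 1 --out runs/pd/
kgg build --disease MONDO:0000001 --fixture 42 --out runs/demo/   # offline
kgg merge runs/a/kg.graphml runs/b/kg.graphml -o runs/merged/
kgg compare runs/a/kg.json runs/b/kg.json --map chebi2chembl.tsv
kgg structures --kg runs/pd/kg.json -o structures.csv
kgg druglikeness --in drugs.csv --out report/
kgg repurpose --kg runs/pd/kg.json --top-pathways 10 --min-phase 3 --out report/
```

`--fixture` takes either an integer seed or a JSON fixture-config file and
switches every subcommand to the offline backend. Live clients cache every
response as JSON under `--cache-dir`, so builds replay byte-identically.

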