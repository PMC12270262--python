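import pandas as pd
import pytest
from hypothesis import given, strategies as st

from conftest import (
    expected_composition,
    scan_activities,
    scan_drugs,
    scan_targets,
    scan_variants_in_gene,
)
from kgg.build import (
    BuildConfig,
    build_kg,
    classify_action,
    filter_activities,
    filter_drugs_by_phase,
    filter_targets,
    filter_variants_in_gene,
)
from kgg.core_model import DRUG_PROTEIN_PREDICATES
from kgg.sources import (
    ActivityRecord,
    DrugRecord,
    FixtureConfig,
    TargetAssociation,
    UnknownDiseaseError,
    VariantRecord,
    generate_fixture,
)


class TestClassifyAction:
    @pytest.mark.parametrize("action", [
        "POSITIVE ALLOSTERIC MODULATOR", "AGONIST", "ACTIVATOR", "PARTIAL ACTIVATOR"])
    def test_increases(self, action):
        assert classify_action(action) == "increases"

    @pytest.mark.parametrize("action", [
        "INHIBITOR", "NEGATIVE ALLOSTERIC MODULATOR", "ANTAGONIST", "BLOCKER"])
    def test_decreases(self, action):
        assert classify_action(action) == "decreases"

    @pytest.mark.parametrize("action", ["MODULATOR", "OPENER", "SEQUESTERING AGENT"])
    def test_miscellaneous(self, action):
        assert classify_action(action) == "targets"

    def test_unknown_defaults_to_targets(self):
        assert classify_action("SOME_NEW_TYPE") == "targets"
        assert classify_action(None) == "targets"
        assert classify_action("") == "targets"

    def test_case_insensitive(self):
        assert classify_action("inhibitor") == "decreases"
        assert classify_action("Agonist") == "increases"

    @given(st.text(max_size=40))
    def test_total_and_case_insensitive(self, text):
        result = classify_action(text)
        assert result in DRUG_PROTEIN_PREDICATES
        assert result == classify_action(text.lower()) == classify_action(text.upper())


def _assoc(score, i=0):
    return TargetAssociation(hgnc_symbol=f"G{i}", uniprot_id=f"P{i:05d}",
                             association_score=score)


class TestFilterTargets:
    def test_threshold_zero_identity(self):
        assocs = [_assoc(s, i) for i, s in enumerate([0.0, 0.4, 1.0])]
        assert filter_targets(assocs, 0.0) == assocs

    def test_threshold_one_keeps_only_perfect(self):
        assocs = [_assoc(s, i) for i, s in enumerate([0.3, 1.0, 0.99])]
        assert [a.association_score for a in filter_targets(assocs, 1.0)] == [1.0]

    def test_order_preserved(self):
        assocs = [_assoc(s, i) for i, s in enumerate([0.9, 0.1, 0.8, 0.5])]
        kept = filter_targets(assocs, 0.4)
        assert [a.association_score for a in kept] == [0.9, 0.8, 0.5]

    def test_matches_manifest_scan(self, fixture_pair):
        _, manifest = fixture_pair
        assocs = [TargetAssociation(**t) for t in manifest["targets"]]
        assert len(filter_targets(assocs, 0.3)) == len(scan_targets(manifest, 0.3))

    @given(st.floats(min_value=0, max_value=1), st.floats(min_value=0, max_value=1))
    def test_monotone_in_threshold(self, t1, t2):
        assocs = [_assoc(s / 10, i) for i, s in enumerate(range(11))]
        lo, hi = sorted([t1, t2])
        assert len(filter_targets(assocs, hi)) <= len(filter_targets(assocs, lo))


class TestFilterDrugsByPhase:
    def _drugs(self, phases):
        return [DrugRecord(chembl_id=f"CHEMBL{i}", max_phase=p)
                for i, p in enumerate(phases)]

    def test_min_phase_two_keeps_two_to_four(self):
        kept = filter_drugs_by_phase(self._drugs([1, 2, 3, 4]), 2)
        assert [d.max_phase for d in kept] == [2, 3, 4]

    def test_min_phase_one_keeps_all_known(self):
        drugs = self._drugs([1, 2, None, 4])
        assert len(filter_drugs_by_phase(drugs, 1)) == 3

    @pytest.mark.parametrize("min_phase", [1, 2, 3, 4])
    def test_unknown_phase_always_excluded(self, min_phase):
        assert filter_drugs_by_phase(self._drugs([None]), min_phase) == []

    def test_invalid_min_phase(self):
        with pytest.raises(ValueError):
            filter_drugs_by_phase([], 0)


def _activity(**kw):
    base = dict(molecule_chembl_id="CHEMBL1", assay_chembl_id="CHEMBL2",
                assay_type="B", target_organism="Homo sapiens",
                confidence_score=9, pchembl_value=7.2)
    base.update(kw)
    return ActivityRecord(**base)


class TestFilterActivities:
    cfg = BuildConfig(disease_ids=["MONDO:0000001"])

    def test_defaults(self):
        assert self.cfg.pchembl_min == 6.0
        assert self.cfg.confidence_required == 9
        assert self.cfg.assay_types == {"B", "F"}
        assert self.cfg.organism == "Homo sapiens"

    def test_pchembl_exactly_six_dropped(self):
        assert filter_activities([_activity(pchembl_value=6.0)], self.cfg) == []

    def test_pchembl_above_six_kept(self):
        assert len(filter_activities([_activity(pchembl_value=6.01)], self.cfg)) == 1

    def test_confidence_eight_dropped(self):
        assert filter_activities([_activity(confidence_score=8)], self.cfg) == []

    def test_wrong_organism_dropped(self):
        assert filter_activities([_activity(target_organism="Rattus norvegicus")],
                                 self.cfg) == []

    def test_adme_assay_dropped_functional_kept(self):
        assert filter_activities([_activity(assay_type="A")], self.cfg) == []
        assert len(filter_activities([_activity(assay_type="F")], self.cfg)) == 1

    def test_missing_pchembl_dropped(self):
        assert filter_activities([_activity(pchembl_value=None)], self.cfg) == []

    def test_matches_manifest_flags(self, fixture_pair):
        _, manifest = fixture_pair
        records = [ActivityRecord(**{k: v for k, v in a.items()
                                     if k != "passes_default_filter"})
                   for a in manifest["activities"]]
        kept = filter_activities(records, self.cfg)
        assert len(kept) == sum(a["passes_default_filter"] for a in manifest["activities"])


class TestFilterVariantsInGene:
    def test_intergenic_excluded_but_in_side_file(self, tmp_path):
        records = [
            VariantRecord(rsid="rs1", gene_symbol=None, variant_type="intergenic"),
            VariantRecord(rsid="rs2", gene_symbol="SNCA", variant_type="missense"),
        ]
        side = tmp_path / "variants_full.csv"
        kept, full = filter_variants_in_gene(records, side_output=side)
        assert [v.rsid for v in kept] == ["rs2"]
        written = pd.read_csv(side)
        assert set(written["rsid"]) == {"rs1", "rs2"}
        assert len(full) == 2

    def test_intergenic_type_with_gene_still_excluded(self):
        records = [VariantRecord(rsid="rs3", gene_symbol="CUX2", variant_type="intergenic")]
        kept, _ = filter_variants_in_gene(records)
        assert kept == []

    def test_matches_manifest(self, fixture_pair):
        _, manifest = fixture_pair
        records = [VariantRecord(**{k: v for k, v in rec.items() if k != "in_gene"})
                   for rec in manifest["variants"]]
        kept, _ = filter_variants_in_gene(records)
        assert len(kept) == len(scan_variants_in_gene(manifest))


class TestBuildKg:
    def test_composition_matches_manifest_oracle(self, built_kg):
        kg, manifest, cfg = built_kg
        assert kg.summarize()["entities"] == expected_composition(manifest, cfg)

    def test_unresolvable_disease_hard_error(self, fixture_pair):
        backend, _ = fixture_pair
        with pytest.raises(UnknownDiseaseError):
            build_kg(BuildConfig(disease_ids=["MONDO:4040404"]), backend)

    def test_degenerate_config_is_legal(self):
        cfg_fix = FixtureConfig(seed=13, n_proteins=4, n_drugs=3, score_max=0.5,
                                n_variants=0)
        backend, _ = generate_fixture(cfg_fix)
        cfg = BuildConfig(disease_ids=[cfg_fix.disease_id], score_threshold=1.0,
                          min_phase=4)
        kg, _ = build_kg(cfg, backend)
        kg.validate()
        assert kg.summarize()["entities"]["disease"] == 1

    def test_monotone_in_score_threshold(self, fixture_pair):
        backend, manifest = fixture_pair
        disease = manifest["disease"]["disease_id"]
        prev = None
        for threshold in (0.0, 0.3, 0.6, 1.0):
            kg, _ = build_kg(BuildConfig(disease_ids=[disease],
                                         score_threshold=threshold), backend)
            counts = kg.summarize()["entities"]
            if prev is not None:
                assert all(counts[k] <= prev[k] for k in counts)
            prev = counts

    def test_monotone_in_min_phase(self, fixture_pair):
        backend, manifest = fixture_pair
        disease = manifest["disease"]["disease_id"]
        prev = None
        for phase in (1, 2, 3, 4):
            kg, _ = build_kg(BuildConfig(disease_ids=[disease], min_phase=phase),
                             backend)
            counts = kg.summarize()["entities"]
            if prev is not None:
                assert all(counts[k] <= prev[k] for k in counts)
            prev = counts

    def test_no_dangling_drug_or_assay(self, built_kg):
        kg, _, _ = built_kg
        drug_with_target = {t.subject for t in kg.iter_triples()
                            if t.predicate in DRUG_PROTEIN_PREDICATES}
        for e in kg.entities_of_kind("drug"):
            assert e.key in drug_with_target
        assay_with_edge = {t.object for t in kg.iter_triples()
                           if t.predicate == "tested_in"}
        for e in kg.entities_of_kind("assay"):
            assert e.key in assay_with_edge

    def test_action_type_kept_as_annotation(self, built_kg):
        kg, manifest, _ = built_kg
        actions = {m["chembl_id"]: m["action_type"] for m in manifest["mechanisms"]}
        seen = 0
        for t in kg.iter_triples():
            if t.predicate in DRUG_PROTEIN_PREDICATES:
                chembl_id = t.subject[1]
                if chembl_id in actions:
                    assert t.annotations["action_type"] == actions[chembl_id]
                    seen += 1
        assert seen > 0

    def test_side_files_written(self, fixture_pair, tmp_path):
        backend, manifest = fixture_pair
        disease = manifest["disease"]["disease_id"]
        kg, side = build_kg(BuildConfig(disease_ids=[disease]), backend,
                            out_dir=tmp_path)
        for family in ("targets", "drugs", "mechanisms", "activities",
                       "protein_annotations"):
            path = tmp_path / f"{disease.replace(':', '_')}_{family}.csv"
            assert path.exists(), family
        assert (tmp_path / f"{disease.replace(':', '_')}_variants_full.csv").exists()
        targets_df = pd.read_csv(side[f"{disease}:targets"])
        assert len(targets_df) == len(manifest["targets"])

    def test_multi_disease_union(self):
        fix_a = FixtureConfig(seed=31, disease_id="MONDO:0000011", n_proteins=8,
                              n_drugs=4, protein_index_start=0)
        fix_b = FixtureConfig(seed=32, disease_id="MONDO:0000022", n_proteins=8,
                              n_drugs=4, protein_index_start=4)
        backend_a, _ = generate_fixture(fix_a)
        backend_b, _ = generate_fixture(fix_b)

        from kgg.sources import SourceBackend

        # serve both diseases through one backend by routing on disease id
        class Routing(SourceBackend):
            name = "routing"

            def _route(self, disease_id):
                return backend_a if disease_id == fix_a.disease_id else backend_b

            def disease_lookup(self, keyword):
                return backend_a.disease_lookup(keyword) + backend_b.disease_lookup(keyword)

            def resolve_disease(self, disease_id):
                return (backend_a.resolve_disease(disease_id)
                        or backend_b.resolve_disease(disease_id))

            def fetch_targets(self, disease_id):
                return self._route(disease_id).fetch_targets(disease_id)

            def fetch_drugs(self, disease_id):
                return self._route(disease_id).fetch_drugs(disease_id)

            def fetch_variants(self, disease_id):
                return self._route(disease_id).fetch_variants(disease_id)

            def fetch_protein_annotations(self, uniprot_ids):
                seen = {}
                for b in (backend_a, backend_b):
                    for ann in b.fetch_protein_annotations(uniprot_ids):
                        seen.setdefault(ann.uniprot_id, ann)
                return list(seen.values())

            def fetch_mechanisms(self, chembl_ids):
                return (backend_a.fetch_mechanisms(chembl_ids)
                        + backend_b.fetch_mechanisms(chembl_ids))

            def fetch_activities(self, chembl_ids):
                return (backend_a.fetch_activities(chembl_ids)
                        + backend_b.fetch_activities(chembl_ids))

            def fetch_viral_proteins(self, taxonomy_ids):
                return []

            def fetch_drugs_for_target(self, uniprot_id):
                return (backend_a.fetch_drugs_for_target(uniprot_id)
                        + backend_b.fetch_drugs_for_target(uniprot_id))

        kg, _ = build_kg(BuildConfig(disease_ids=[fix_a.disease_id, fix_b.disease_id]),
                         Routing())
        kg.validate()
        assert kg.summarize()["entities"]["disease"] == 2
        # shared protein-index range must be deduplicated, not double counted
        kg_a, _ = build_kg(BuildConfig(disease_ids=[fix_a.disease_id]), backend_a)
        kg_b, _ = build_kg(BuildConfig(disease_ids=[fix_b.disease_id]), backend_b)
        assert kg.n_entities <= kg_a.n_entities + kg_b.n_entities

    def test_viral_proteins_included(self):
        cfg_fix = FixtureConfig(seed=17, viral=True, taxonomy_ids=[11676, 11709],
                                n_viral_proteins=3)
        backend, manifest = generate_fixture(cfg_fix)
        cfg = BuildConfig(disease_ids=[cfg_fix.disease_id], include_viral=True,
                          taxonomy_ids=[11676, 11709])
        kg, _ = build_kg(cfg, backend)
        assert kg.summarize()["entities"] == expected_composition(manifest, cfg)
        viral_ids = {a["uniprot_id"] for tax in ("11676", "11709")
                     for a in manifest["viral"][tax]}
        present = {e.identifier for e in kg.entities_of_kind("protein")
                   if e.namespace == "UNIPROT"}
        assert viral_ids <= present
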