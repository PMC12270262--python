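import pytest

from kgg.build import BuildConfig, build_kg
from kgg.core_model import Entity, KnowledgeGraph
from kgg.repurposing import (
    PathwayNeighborhood,
    expand_candidates,
    find_repurposing_drugs,
    rank_candidates_by_pathway_count,
    trial_target_pathway_ranking,
    trial_target_proteins,
)
from kgg.sources import FixtureConfig, generate_fixture


def protein(symbol, druggability=None):
    meta = {"druggability": druggability} if druggability else {}
    return Entity("HGNC", symbol, kind="protein", metadata=meta)


def pathway(pid):
    return Entity("REACTOME", pid, kind="pathway")


def drug(cid, phase=3):
    return Entity("CHEMBL", cid, kind="drug", metadata={"max_phase": phase})


def planted_kg():
    """5 proteins on pathway PW1: 2 trial targets, 1 druggability-no,
    2 retainable candidates."""
    kg = KnowledgeGraph()
    for symbol in ("A", "B", "C", "D", "E"):
        kg.add_triple(protein(symbol), "part_of", pathway("PW1"))
    kg.add_triple(drug("CHEMBL1"), "decreases", protein("A"), {"max_phase": 4})
    kg.add_triple(drug("CHEMBL2"), "increases", protein("B"), {"max_phase": 2})
    kg.add_entity(protein("C", druggability="no"))
    kg.add_entity(protein("D", druggability="yes"))
    # E has no druggability annotation: retained
    return kg


class TestPathwayRanking:
    def test_no_drugs_empty_ranking(self):
        kg = KnowledgeGraph()
        kg.add_triple(protein("A"), "part_of", pathway("PW1"))
        assert trial_target_pathway_ranking(kg) == []

    def test_planted_counts(self):
        assert trial_target_pathway_ranking(planted_kg()) == [("PW1", 2)]

    def test_protein_on_two_pathways_counts_in_both(self):
        kg = KnowledgeGraph()
        kg.add_triple(protein("A"), "part_of", pathway("PW1"))
        kg.add_triple(protein("A"), "part_of", pathway("PW2"))
        kg.add_triple(drug("CHEMBL1"), "targets", protein("A"), {"max_phase": 3})
        assert trial_target_pathway_ranking(kg) == [("PW1", 1), ("PW2", 1)]

    def test_unknown_phase_drug_not_a_trial_target(self):
        kg = KnowledgeGraph()
        kg.add_triple(protein("A"), "part_of", pathway("PW1"))
        kg.add_triple(drug("CHEMBL1", phase=None), "targets", protein("A"),
                      {"max_phase": None})
        assert trial_target_pathway_ranking(kg) == []

    def test_matches_brute_force_on_fixture(self, built_kg):
        kg, _, _ = built_kg
        ranking = dict(trial_target_pathway_ranking(kg))
        # brute force over the triple list
        trial = set()
        for t in kg.iter_triples():
            if t.predicate in ("increases", "decreases", "targets"):
                phase = t.annotations.get("max_phase")
                phases = phase if isinstance(phase, list) else [phase]
                if any(isinstance(p, int) and p >= 1 for p in phases):
                    trial.add(t.object)
        expected = {}
        for t in kg.iter_triples():
            if t.predicate == "part_of" and t.subject in trial:
                expected[t.object[1]] = expected.get(t.object[1], 0) + 1
        assert ranking == expected

    def test_ordering_deterministic(self):
        kg = KnowledgeGraph()
        for pid in ("PWB", "PWA"):
            kg.add_triple(protein("A"), "part_of", pathway(pid))
        kg.add_triple(drug("CHEMBL1"), "targets", protein("A"), {"max_phase": 3})
        assert trial_target_pathway_ranking(kg) == [("PWA", 1), ("PWB", 1)]


class TestExpandCandidates:
    def test_planted_two_candidates(self):
        nbs = expand_candidates(planted_kg(), ["PW1"])
        assert len(nbs) == 1
        assert nbs[0].trial_proteins == ["A", "B"]
        assert nbs[0].candidate_proteins == ["D", "E"]

    def test_all_trial_targets_empty_candidates(self):
        kg = KnowledgeGraph()
        kg.add_triple(protein("A"), "part_of", pathway("PW1"))
        kg.add_triple(drug("CHEMBL1"), "targets", protein("A"), {"max_phase": 3})
        nbs = expand_candidates(kg, ["PW1"])
        assert nbs[0].candidate_proteins == []

    def test_unknown_pathway_raises(self):
        with pytest.raises(KeyError):
            expand_candidates(planted_kg(), ["PW404"])

    def test_disjointness_invariant(self, built_kg):
        kg, _, _ = built_kg
        ranking = trial_target_pathway_ranking(kg)
        if not ranking:
            pytest.skip("fixture produced no trial pathways")
        nbs = expand_candidates(kg, [p for p, _ in ranking])
        for nb in nbs:
            assert not set(nb.trial_proteins) & set(nb.candidate_proteins)

    def test_explicit_no_removed_unknown_retained(self, built_kg):
        kg, manifest, _ = built_kg
        druggability = {t["hgnc_symbol"]: t["druggability"] for t in manifest["targets"]}
        ranking = trial_target_pathway_ranking(kg)
        if not ranking:
            pytest.skip("fixture produced no trial pathways")
        for nb in expand_candidates(kg, [p for p, _ in ranking]):
            for symbol in nb.candidate_proteins:
                assert druggability.get(symbol) != "no"

    def test_neighborhood_invariant_enforced(self):
        with pytest.raises(ValueError):
            PathwayNeighborhood("PW1", ["A"], ["A", "B"])


class TestCandidateRanking:
    def test_single_neighborhood_all_ones(self):
        nb = PathwayNeighborhood("PW1", [], ["X", "Y"])
        assert rank_candidates_by_pathway_count([nb]) == [("X", 1), ("Y", 1)]

    def test_multiplicity_and_tie_break(self):
        nbs = [PathwayNeighborhood("PW1", [], ["X", "Y"]),
               PathwayNeighborhood("PW2", [], ["Y", "Z"])]
        assert rank_candidates_by_pathway_count(nbs) == [("Y", 2), ("X", 1), ("Z", 1)]

    def test_stable_under_permutation(self):
        nbs = [PathwayNeighborhood("PW1", [], ["X", "Y"]),
               PathwayNeighborhood("PW2", [], ["Y", "Z"]),
               PathwayNeighborhood("PW3", [], ["Z"])]
        assert (rank_candidates_by_pathway_count(nbs)
                == rank_candidates_by_pathway_count(list(reversed(nbs))))


class TestFindRepurposingDrugs:
    def test_phase_filter(self, fixture_pair):
        backend, manifest = fixture_pair
        for uid, drugs in manifest["cross_disease_drugs"].items():
            hits = find_repurposing_drugs([uid], backend, min_phase=3)
            expected = {d["chembl_id"] for d in drugs if d["max_phase"] >= 3}
            assert {c.chembl_id for c in hits[uid]} == expected

    def test_protein_without_drugs_in_report_with_zero(self, fixture_pair):
        backend, manifest = fixture_pair
        without = [t["uniprot_id"] for t in manifest["targets"]
                   if t["uniprot_id"] not in manifest["cross_disease_drugs"]]
        if not without:
            pytest.skip("every fixture protein has cross-disease drugs")
        hits = find_repurposing_drugs(without[:2], backend)
        assert all(hits[uid] == [] for uid in without[:2])

    def test_min_phase_monotone(self, fixture_pair):
        backend, manifest = fixture_pair
        uids = sorted(manifest["cross_disease_drugs"])
        for phase_lo, phase_hi in ((1, 2), (2, 3), (3, 4)):
            lo = find_repurposing_drugs(uids, backend, min_phase=phase_lo)
            hi = find_repurposing_drugs(uids, backend, min_phase=phase_hi)
            for uid in uids:
                assert {c.chembl_id for c in hi[uid]} <= {c.chembl_id for c in lo[uid]}

    def test_invalid_min_phase(self, fixture_pair):
        backend, _ = fixture_pair
        with pytest.raises(ValueError):
            find_repurposing_drugs([], backend, min_phase=0)


class TestEndToEndPipeline:
    def test_pipeline_equals_brute_force(self):
        fix = FixtureConfig(seed=77, n_proteins=20, n_drugs=15, n_pathway_pool=6,
                            mean_reactome=3, cross_drug_rate=0.8)
        backend, manifest = generate_fixture(fix)
        cfg = BuildConfig(disease_ids=[fix.disease_id])
        kg, _ = build_kg(cfg, backend)

        # --- independent brute-force enumeration over the manifest ---
        symbols = {t["uniprot_id"]: t["hgnc_symbol"] for t in manifest["targets"]}
        uniprots = {s: u for u, s in symbols.items()}
        druggability = {t["hgnc_symbol"]: t["druggability"] for t in manifest["targets"]}
        trial_targets = set()
        for d in manifest["drugs"]:
            if d["max_phase"] is not None and d["max_phase"] >= 1 and d["target_uniprot_id"]:
                trial_targets.add(symbols[d["target_uniprot_id"]])
        # protein symbols present in the graph (kept targets at threshold 0 = all)
        graph_proteins = {t["hgnc_symbol"] for t in manifest["targets"]}
        membership = {}  # pathway -> set of symbols
        for uid, ann in manifest["annotations"].items():
            if symbols[uid] not in graph_proteins:
                continue
            for rid, _name in ann["reactome"]:
                membership.setdefault(rid, set()).add(symbols[uid])
        expected_ranking = sorted(
            ((rid, len(members & trial_targets)) for rid, members in membership.items()
             if members & trial_targets),
            key=lambda item: (-item[1], item[0]))

        ranking = trial_target_pathway_ranking(kg)
        assert ranking == expected_ranking

        pathways = [rid for rid, _ in ranking[:3]]
        nbs = expand_candidates(kg, pathways)
        for nb in nbs:
            members = membership[nb.pathway_id]
            expected_candidates = sorted(
                s for s in members - trial_targets if druggability.get(s) != "no")
            assert nb.candidate_proteins == expected_candidates

        ranked = rank_candidates_by_pathway_count(nbs)
        counts = {}
        for nb in nbs:
            for s in nb.candidate_proteins:
                counts[s] = counts.get(s, 0) + 1
        assert ranked == sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))

        candidate_uids = [uniprots[s] for s, _ in ranked]
        hits = find_repurposing_drugs(candidate_uids, backend, min_phase=3)
        for uid in candidate_uids:
            expected = {d["chembl_id"]
                        for d in manifest["cross_disease_drugs"].get(uid, [])
                        if d["max_phase"] >= 3}
            assert {c.chembl_id for c in hits[uid]} == expected

    def test_trial_targets_never_candidates(self, built_kg):
        kg, _, _ = built_kg
        trial = {key[1] for key in trial_target_proteins(kg)}
        ranking = trial_target_pathway_ranking(kg)
        if not ranking:
            pytest.skip("fixture produced no trial pathways")
        for nb in expand_candidates(kg, [p for p, _ in ranking]):
            assert not set(nb.candidate_proteins) & trial
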