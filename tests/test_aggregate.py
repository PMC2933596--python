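"""Query orchestration, the six-section report, and its XML/JSON forms."""

import json
import shutil

import numpy as np
import pytest
from lxml import etree

from chemlinker import (
    Conformer,
    EngineConfig,
    QueryError,
    SimilarityHit,
    fixture_fingerprint,
    load_store,
    partition_outcomes,
    report_to_dict,
    report_to_json,
    report_to_xml,
    run_query,
)
from chemlinker.aggregate import SECTION_ORDER
from chemlinker.datastore import AssayOutcome


@pytest.fixture(scope="module")
def planted_report(fixture_store):
    store, manifest = fixture_store
    conformer = Conformer("query", np.array(manifest["query_conformer"]))
    return run_query(manifest["query_smiles"], store, query_conformer=conformer), manifest


class TestRunQuery:
    def test_planted_family_appears_in_every_hit_section(self, planted_report):
        report, manifest = planted_report
        for chain in manifest["chains"]:
            cid = chain["compound_id"]
            active = [a for a in report.active_assay_hits if a.compound_id == cid]
            assert [a.assay_id for a in active] == [chain["active_assay_id"]]
            assert active[0].similarity == pytest.approx(chain["similarity"], abs=0)
            assert [a.disease for a in active[0].diseases] == [chain["disease"]]
            inactive = [a for a in report.inactive_similars if a.compound_id == cid]
            assert [a.assay_id for a in inactive] == [chain["inactive_assay_id"]]
            assert chain["drug_id"] in [d.drug_id for d in report.active_drug_hits]
            assert chain["chemgene_target"] in [
                r.target for r in report.chemogenomics_similars if r.compound_id == cid
            ]
            assert chain["pathway_id"] in [
                p.pathway_id for p in report.systems_similars if p.compound_id == cid
            ]
            assert chain["paper_id"] in [p.paper_id for p in report.literature_similars]

    def test_shape_neighbour_is_the_planted_rigid_copy(self, planted_report):
        report, manifest = planted_report
        assert report.shape_neighbours[0].compound_id == manifest["shape_neighbour_id"]
        assert report.shape_neighbours[0].distance < 1e-8

    def test_no_decoy_ever_reported(self, planted_report):
        report, manifest = planted_report
        decoys = set(manifest["decoy_compound_ids"])
        reported = (
            {a.compound_id for a in report.active_assay_hits}
            | {d.compound_id for d in report.active_drug_hits}
            | {r.compound_id for r in report.chemogenomics_similars}
            | {p.compound_id for p in report.systems_similars}
            | {c for lit in report.literature_similars for c, _ in lit.compounds}
            | {a.compound_id for a in report.inactive_similars}
        )
        assert not (reported & decoys)

    def test_no_similarity_below_threshold(self, planted_report):
        report, _ = planted_report
        threshold = report.metadata["config"]["similarity_threshold"]
        sims = (
            [a.similarity for a in report.active_assay_hits]
            + [d.similarity for d in report.active_drug_hits]
            + [r.similarity for r in report.chemogenomics_similars]
            + [p.similarity for p in report.systems_similars]
            + [s for lit in report.literature_similars for _, s in lit.compounds]
            + [a.similarity for a in report.inactive_similars]
        )
        assert sims and min(sims) >= threshold

    def test_dissimilar_query_gives_empty_hit_sections_but_predictions(self, fixture_store):
        store, _ = fixture_store
        report = run_query("[Xx]nohit[Xx]", store)
        assert report.active_assay_hits == [] and report.inactive_similars == []
        assert report.chemogenomics_similars == [] and report.systems_similars == []
        assert report.literature_similars == [] and report.active_drug_hits == []
        assert len(report.predictive_models) == 40
        assert set(report_to_dict(report)["sections"]) == set(SECTION_ORDER)

    def test_query_identical_to_stored_compound_reports_similarity_one(self, tmp_path):
        smiles = "c1ccccc1CCO"
        fp = fixture_fingerprint(smiles)
        (tmp_path / "compounds.tsv").write_text(
            "compound_id\tsmiles\tfingerprint_hex\tpopcount\n"
            f"SELF\t{smiles}\t{fp.to_hex()}\t{fp.popcount}\n"
        )
        report = run_query(smiles, load_store(tmp_path))
        hits = {a.compound_id for a in report.active_assay_hits}
        # no outcome table: the self hit shows up via drug/relation joins only if
        # present; assert through the raw search path instead
        assert hits == set()
        from chemlinker import search_2d
        store = load_store(tmp_path)
        found = search_2d(fp, store.index, EngineConfig().similarity_threshold)
        assert [(h.compound_id, h.similarity) for h in found] == [("SELF", 1.0)]

    def test_empty_smiles_raises_query_error(self, fixture_store):
        store, _ = fixture_store
        with pytest.raises(QueryError):
            run_query("  ", store)

    def test_determinism_for_fixed_inputs(self, fixture_store):
        store, manifest = fixture_store
        a = report_to_json(run_query(manifest["query_smiles"], store))
        b = report_to_json(run_query(manifest["query_smiles"], store))
        assert a == b

    def test_max_hits_per_section_truncates_by_rank(self, fixture_store):
        store, manifest = fixture_store
        config = EngineConfig(max_hits_per_section=1)
        report = run_query(manifest["query_smiles"], store, config)
        best = max(c["similarity"] for c in manifest["chains"])
        assert len(report.active_assay_hits) == 1
        assert report.active_assay_hits[0].similarity == pytest.approx(best, abs=0)
        for section in (report.active_drug_hits, report.chemogenomics_similars,
                        report.systems_similars, report.literature_similars,
                        report.inactive_similars):
            assert len(section) <= 1

    def test_removing_a_table_changes_only_its_section(self, fixture_store_dir, tmp_path):
        src, manifest = fixture_store_dir
        dst = tmp_path / "store"
        shutil.copytree(src, dst)
        (dst / "pathways.tsv").unlink()
        full = report_to_dict(run_query(manifest["query_smiles"], load_store(src)))
        reduced = report_to_dict(run_query(manifest["query_smiles"], load_store(dst)))
        assert reduced["sections"]["systems_similars"] == []
        for name in SECTION_ORDER:
            if name != "systems_similars":
                assert reduced["sections"][name] == full["sections"][name]


class TestPartitionOutcomes:
    def test_hit_active_in_one_assay_inactive_in_another(self):
        hit = SimilarityHit("C1", 0.9)
        outcomes = [
            AssayOutcome("A1", "C1", "active", 50.0),
            AssayOutcome("A2", "C1", "inactive", None),
        ]
        active, inactive = partition_outcomes([hit], outcomes)
        assert [(h.compound_id, o.assay_id) for h, o in active] == [("C1", "A1")]
        assert [(h.compound_id, o.assay_id) for h, o in inactive] == [("C1", "A2")]

    def test_inconclusive_excluded_from_both(self):
        hit = SimilarityHit("C1", 0.9)
        active, inactive = partition_outcomes(
            [hit], [AssayOutcome("A1", "C1", "inconclusive", None)]
        )
        assert active == [] and inactive == []

    def test_empty_hits(self):
        assert partition_outcomes([], [AssayOutcome("A1", "C1", "active", 1.0)]) == ([], [])


class TestSerialization:
    def test_xml_has_six_sections_in_fixed_order(self, planted_report):
        report, manifest = planted_report
        doc = etree.fromstring(report_to_xml(report).encode())
        names = [s.get("name") for s in doc.findall("sections/section")]
        assert names == list(SECTION_ORDER)
        active = doc.find("sections/section[@name='active_similars']")
        assay_ids = {el.get("assay_id") for el in active.findall("assay_hit")}
        assert manifest["chains"][0]["active_assay_id"] in assay_ids

    def test_every_hit_element_carries_compound_and_similarity(self, planted_report):
        report, _ = planted_report
        doc = etree.fromstring(report_to_xml(report).encode())
        for tag in ("assay_hit", "drug_hit", "relation", "pathway"):
            for el in doc.iter(tag):
                assert el.get("compound_id") and el.get("similarity")

    def test_xml_round_trips_byte_identically(self, planted_report):
        report, _ = planted_report
        text = report_to_xml(report)
        reparsed = etree.tostring(
            etree.fromstring(text.encode()), xml_declaration=True, encoding="UTF-8"
        ).decode("utf-8")
        assert reparsed == text

    def test_empty_report_is_well_formed_with_six_empty_sections(self, fixture_store):
        store, _ = fixture_store
        report = run_query("[Xx]nohit[Xx]", store, EngineConfig())
        doc = etree.fromstring(report_to_xml(report).encode())
        sections = doc.findall("sections/section")
        assert [s.get("name") for s in sections] == list(SECTION_ORDER)
        for section in sections:
            if section.get("name") != "predictive_models":
                assert len(section) == 0
        payload = json.loads(report_to_json(report))
        for name in SECTION_ORDER:
            if name != "predictive_models":
                assert payload["sections"][name] == []

    def test_json_and_xml_agree_on_similarity_triples(self, planted_report):
        report, _ = planted_report
        doc = etree.fromstring(report_to_xml(report).encode())
        xml_triples = set()
        for section in doc.findall("sections/section"):
            name = section.get("name")
            for el in section.iter():
                if el.get("compound_id") and el.get("similarity"):
                    xml_triples.add((name, el.get("compound_id"), float(el.get("similarity"))))
        payload = json.loads(report_to_json(report))
        json_triples = set()
        for name, entries in payload["sections"].items():
            for entry in entries:
                if "compound_id" in entry and "similarity" in entry:
                    json_triples.add((name, entry["compound_id"], entry["similarity"]))
                for sub in entry.get("compounds", []):
                    json_triples.add((name, sub["compound_id"], sub["similarity"]))
        assert json_triples == xml_triples

    def test_json_bytes_deterministic(self, planted_report):
        report, _ = planted_report
        assert report_to_json(report) == report_to_json(report)

    def test_provenance_chain_nested_in_xml(self, planted_report):
        report, manifest = planted_report
        doc = etree.fromstring(report_to_xml(report).encode())
        chain = manifest["chains"][0]
        hit = doc.find(
            f"sections/section[@name='active_similars']/assay_hit[@assay_id='{chain['active_assay_id']}']"
        )
        links = hit.findall("disease/provenance/chain/link")
        assert [(l.get("kind"), l.get("id")) for l in links] == [
            ("assay", chain["active_assay_id"]),
            ("go", chain["go_id"]),
            ("gene", chain["gene"]),
            ("disease", chain["disease"]),
        ]
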