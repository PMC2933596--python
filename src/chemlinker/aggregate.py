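"""Query orchestration and the six-section aggregate report.

One query run takes a SMILES string, fingerprints it, finds similar
compounds in the store at the configured Tanimoto threshold, and fans the
hits out across the evidence tables: bioassay outcomes (split into active
and inactive), drug records, chemical-gene/disease relations, pathway
relations, and literature links.  Assay descriptions, drug usage texts and
paper titles/abstracts are tagged with Gene Ontology terms and chained
through genes to diseases.  The configured activity predictor is always run.
The result is a report with exactly six sections in fixed order —
predictive models, activities of similar compounds, chemogenomics,
systems/pathways, literature, inactivities of similar compounds —
serializable to XML or JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

from lxml import etree

from .annotate import DiseaseAnnotation, GOMatch, extract_go_terms, text_to_diseases
from .chem_core import (
    Fingerprint,
    SimilarityHit,
    resolve_fingerprint_backend,
    search_2d,
)
from .config import EngineConfig
from .datastore import AssayOutcome, DataStore
from .errors import InvalidInputError, QueryError
from .predictors import ActivityPrediction, get_predictor
from .shape3d import Conformer, search_3d

logger = logging.getLogger(__name__)

SECTION_ORDER = (
    "predictive_models",
    "active_similars",
    "chemogenomics_similars",
    "systems_similars",
    "literature_similars",
    "inactive_similars",
)


@dataclass(frozen=True)
class AssayAssociation:
    """A similar compound together with one bioassay it was tested in."""

    compound_id: str
    similarity: float
    assay_id: str
    assay_name: str
    outcome: str
    score: float | None
    diseases: tuple[DiseaseAnnotation, ...] = ()


@dataclass(frozen=True)
class DrugAssociation:
    compound_id: str
    similarity: float
    drug_id: str
    name: str
    usage_description: str
    source: str
    go_matches: tuple[GOMatch, ...] = ()
    diseases: tuple[DiseaseAnnotation, ...] = ()


@dataclass(frozen=True)
class RelationAssociation:
    compound_id: str
    similarity: float
    target: str
    target_kind: str
    relation: str
    source: str


@dataclass(frozen=True)
class PathwayAssociation:
    compound_id: str
    similarity: float
    pathway_id: str
    pathway_name: str
    enzyme: str | None


@dataclass(frozen=True)
class LiteratureAssociation:
    """One paper with every similar compound it mentions (collapsed per paper)."""

    paper_id: str
    title: str
    compounds: tuple[tuple[str, float], ...]
    best_similarity: float
    title_go: tuple[GOMatch, ...] = ()
    abstract_go: tuple[GOMatch, ...] = ()


@dataclass(frozen=True)
class ShapeNeighbour:
    compound_id: str
    distance: float


@dataclass
class AggregateReport:
    """The aggregated answer for one query: six sections, fixed order."""

    query_smiles: str
    query_fingerprint: Fingerprint
    predictive_models: list[ActivityPrediction] = field(default_factory=list)
    active_assay_hits: list[AssayAssociation] = field(default_factory=list)
    active_drug_hits: list[DrugAssociation] = field(default_factory=list)
    shape_neighbours: list[ShapeNeighbour] = field(default_factory=list)
    chemogenomics_similars: list[RelationAssociation] = field(default_factory=list)
    systems_similars: list[PathwayAssociation] = field(default_factory=list)
    literature_similars: list[LiteratureAssociation] = field(default_factory=list)
    inactive_similars: list[AssayAssociation] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    @property
    def section_names(self) -> tuple[str, ...]:
        return SECTION_ORDER


def partition_outcomes(
    hits: Sequence[SimilarityHit],
    outcomes: Sequence[AssayOutcome],
) -> tuple[list[tuple[SimilarityHit, AssayOutcome]], list[tuple[SimilarityHit, AssayOutcome]]]:
    """Route (hit, assay outcome) pairs into active and inactive partitions.

    A hit tested in several assays appears once per assay; inconclusive
    outcomes are excluded from both partitions.
    """
    by_compound: dict[str, list[AssayOutcome]] = {}
    for outcome in outcomes:
        by_compound.setdefault(outcome.compound_id, []).append(outcome)
    active: list[tuple[SimilarityHit, AssayOutcome]] = []
    inactive: list[tuple[SimilarityHit, AssayOutcome]] = []
    for hit in hits:
        for outcome in by_compound.get(hit.compound_id, ()):
            if outcome.outcome == "active":
                active.append((hit, outcome))
            elif outcome.outcome == "inactive":
                inactive.append((hit, outcome))
    return active, inactive


def _truncate(name: str, entries: list, limit: int) -> list:
    if len(entries) > limit:
        logger.info("section %s truncated from %d to %d entries", name, len(entries), limit)
        return entries[:limit]
    return entries


def run_query(
    smiles: str,
    store: DataStore,
    config: EngineConfig | None = None,
    *,
    query_conformer: Conformer | None = None,
    fingerprinter: Callable[[str], Fingerprint] | None = None,
    timestamp: str | None = None,
) -> AggregateReport:
    """Execute the full aggregation pipeline for one query compound."""
    config = config or EngineConfig()
    if not smiles or not smiles.strip():
        raise QueryError(f"empty query SMILES {smiles!r}")
    if fingerprinter is None:
        fingerprinter = resolve_fingerprint_backend(config.fingerprint_backend)
    try:
        query_fp = fingerprinter(smiles)
    except InvalidInputError as exc:
        raise QueryError(f"cannot fingerprint query {smiles!r}: {exc}") from exc

    hits = search_2d(
        query_fp, store.index, config.similarity_threshold,
        strict=config.strict_threshold,
    )
    sim_of = {h.compound_id: h.similarity for h in hits}

    # -- assay outcomes, split active/inactive ------------------------------
    active_pairs, inactive_pairs = partition_outcomes(hits, store.outcomes)
    disease_cache: dict[str, tuple[DiseaseAnnotation, ...]] = {}

    def assay_assoc(hit: SimilarityHit, outcome: AssayOutcome) -> AssayAssociation:
        assay = store.assays.get(outcome.assay_id)
        if assay is not None and outcome.assay_id not in disease_cache:
            _, anns = text_to_diseases(
                ("assay", assay.assay_id), assay.description, store, config
            )
            disease_cache[outcome.assay_id] = tuple(anns)
        return AssayAssociation(
            compound_id=hit.compound_id,
            similarity=hit.similarity,
            assay_id=outcome.assay_id,
            assay_name=assay.name if assay else "",
            outcome=outcome.outcome,
            score=outcome.score,
            diseases=disease_cache.get(outcome.assay_id, ()),
        )

    key = lambda a: (-a.similarity, a.compound_id, a.assay_id)
    active_assays = sorted((assay_assoc(h, o) for h, o in active_pairs), key=key)
    inactive_assays = sorted((assay_assoc(h, o) for h, o in inactive_pairs), key=key)

    # -- drug hits -----------------------------------------------------------
    drug_hits: list[DrugAssociation] = []
    for drug in store.drugs:
        if drug.compound_id not in sim_of:
            continue
        matches, anns = text_to_diseases(
            ("drug", drug.drug_id), drug.usage_description, store, config
        )
        drug_hits.append(
            DrugAssociation(
                drug.compound_id, sim_of[drug.compound_id], drug.drug_id,
                drug.name, drug.usage_description, drug.source,
                tuple(matches), tuple(anns),
            )
        )
    drug_hits.sort(key=lambda d: (-d.similarity, d.compound_id, d.drug_id))

    # -- chemogenomics and pathway relations ---------------------------------
    relations = sorted(
        (
            RelationAssociation(r.compound_id, sim_of[r.compound_id], r.target,
                                r.target_kind, r.relation, r.source)
            for r in store.chemgene
            if r.compound_id in sim_of
        ),
        key=lambda r: (-r.similarity, r.compound_id, r.target, r.relation),
    )
    pathway_hits = sorted(
        (
            PathwayAssociation(p.compound_id, sim_of[p.compound_id], p.pathway_id,
                               p.pathway_name, p.enzyme)
            for p in store.pathways
            if p.compound_id in sim_of
        ),
        key=lambda p: (-p.similarity, p.compound_id, p.pathway_id),
    )

    # -- literature, one entry per paper --------------------------------------
    papers: list[LiteratureAssociation] = []
    for paper in store.literature:
        matching = sorted(
            ((cid, sim_of[cid]) for cid in paper.compound_ids if cid in sim_of),
            key=lambda t: (-t[1], t[0]),
        )
        if not matching:
            continue
        title_go = tuple(extract_go_terms(paper.title, store.go_lexicon))
        abstract_go = tuple(extract_go_terms(paper.abstract, store.go_lexicon))
        papers.append(
            LiteratureAssociation(
                paper.paper_id, paper.title, tuple(matching),
                matching[0][1], title_go, abstract_go,
            )
        )
    papers.sort(key=lambda p: (-p.best_similarity, p.paper_id))

    # -- predictor and 3D neighbours ------------------------------------------
    predictions = get_predictor(config).predict(smiles, query_fp)
    neighbours: list[ShapeNeighbour] = []
    if query_conformer is not None and store.conformers:
        neighbours = [
            ShapeNeighbour(cid, dist)
            for cid, dist in search_3d(query_conformer, store, config.k_3d)
        ]
    elif query_conformer is None:
        logger.info("no query conformer supplied; 3D neighbours omitted from the report")

    limit = config.max_hits_per_section
    report = AggregateReport(
        query_smiles=smiles,
        query_fingerprint=query_fp,
        predictive_models=predictions,
        active_assay_hits=_truncate("active_similars/assays", active_assays, limit),
        active_drug_hits=_truncate("active_similars/drugs", drug_hits, limit),
        shape_neighbours=neighbours,
        chemogenomics_similars=_truncate("chemogenomics_similars", relations, limit),
        systems_similars=_truncate("systems_similars", pathway_hits, limit),
        literature_similars=_truncate("literature_similars", papers, limit),
        inactive_similars=_truncate("inactive_similars", inactive_assays, limit),
        metadata={
            "store": store.identity(),
            "config": config.to_dict(),
            **({"timestamp": timestamp} if timestamp is not None else {}),
        },
    )
    return report


# -- serialization -----------------------------------------------------------


def _fmt(x: float) -> str:
    return repr(float(x))


def _disease_xml(parent: etree._Element, ann: DiseaseAnnotation) -> None:
    el = etree.SubElement(parent, "disease", name=ann.disease, score=_fmt(ann.score))
    for gene in ann.genes:
        etree.SubElement(el, "gene", symbol=gene)
    prov = etree.SubElement(el, "provenance")
    for chain in ann.provenance:
        chain_el = etree.SubElement(prov, "chain")
        for kind, identifier in chain:
            etree.SubElement(chain_el, "link", kind=kind, id=identifier)


def _go_xml(parent: etree._Element, match: GOMatch, field_name: str | None = None) -> None:
    attrs = {"go_id": match.go_id, "text": match.matched_text,
             "start": str(match.start), "end": str(match.end)}
    if field_name:
        attrs["field"] = field_name
    etree.SubElement(parent, "go_match", **attrs)


def _assay_xml(parent: etree._Element, a: AssayAssociation) -> None:
    attrs = {
        "compound_id": a.compound_id, "similarity": _fmt(a.similarity),
        "assay_id": a.assay_id, "assay_name": a.assay_name, "outcome": a.outcome,
    }
    if a.score is not None:
        attrs["score"] = _fmt(a.score)
    el = etree.SubElement(parent, "assay_hit", **attrs)
    for ann in a.diseases:
        _disease_xml(el, ann)


def report_to_xml(report: AggregateReport) -> str:
    """Serialize a report to XML with one element per section in fixed order.

    The document is stable: serializing, parsing and re-serializing yields
    byte-identical text.
    """
    root = etree.Element("report")
    etree.SubElement(
        root, "query", smiles=report.query_smiles,
        fingerprint_popcount=str(report.query_fingerprint.popcount),
        fingerprint_hex=report.query_fingerprint.to_hex(),
    )
    meta = etree.SubElement(root, "metadata")
    if "store" in report.metadata:
        etree.SubElement(meta, "store", identity=str(report.metadata["store"]))
    if "timestamp" in report.metadata:
        etree.SubElement(meta, "timestamp", value=str(report.metadata["timestamp"]))
    cfg = etree.SubElement(meta, "config")
    for k, v in report.metadata.get("config", {}).items():
        etree.SubElement(cfg, "entry", key=str(k), value=str(v))

    sections = etree.SubElement(root, "sections")

    sec = etree.SubElement(sections, "section", name="predictive_models")
    for p in report.predictive_models:
        el = etree.SubElement(
            sec, "prediction", target=p.target_name, panel=p.panel,
            probability=_fmt(p.probability), color=p.color,
        )
        if p.confusion_metrics:
            etree.SubElement(
                el, "confusion",
                **{k: _fmt(v) for k, v in p.confusion_metrics.items()},
            )

    sec = etree.SubElement(sections, "section", name="active_similars")
    for a in report.active_assay_hits:
        _assay_xml(sec, a)
    for d in report.active_drug_hits:
        el = etree.SubElement(
            sec, "drug_hit", compound_id=d.compound_id, similarity=_fmt(d.similarity),
            drug_id=d.drug_id, name=d.name, source=d.source,
        )
        usage = etree.SubElement(el, "usage")
        usage.text = d.usage_description
        for m in d.go_matches:
            _go_xml(el, m)
        for ann in d.diseases:
            _disease_xml(el, ann)
    for n in report.shape_neighbours:
        etree.SubElement(
            sec, "shape_neighbour", compound_id=n.compound_id, distance=_fmt(n.distance)
        )

    sec = etree.SubElement(sections, "section", name="chemogenomics_similars")
    for r in report.chemogenomics_similars:
        etree.SubElement(
            sec, "relation", compound_id=r.compound_id, similarity=_fmt(r.similarity),
            target=r.target, target_kind=r.target_kind, relation=r.relation,
            source=r.source,
        )

    sec = etree.SubElement(sections, "section", name="systems_similars")
    for p in report.systems_similars:
        attrs = {
            "compound_id": p.compound_id, "similarity": _fmt(p.similarity),
            "pathway_id": p.pathway_id, "pathway_name": p.pathway_name,
        }
        if p.enzyme:
            attrs["enzyme"] = p.enzyme
        etree.SubElement(sec, "pathway", **attrs)

    sec = etree.SubElement(sections, "section", name="literature_similars")
    for lit in report.literature_similars:
        el = etree.SubElement(
            sec, "paper", paper_id=lit.paper_id, title=lit.title,
            best_similarity=_fmt(lit.best_similarity),
        )
        for cid, sim in lit.compounds:
            etree.SubElement(el, "compound", compound_id=cid, similarity=_fmt(sim))
        for m in lit.title_go:
            _go_xml(el, m, "title")
        for m in lit.abstract_go:
            _go_xml(el, m, "abstract")

    sec = etree.SubElement(sections, "section", name="inactive_similars")
    for a in report.inactive_similars:
        _assay_xml(sec, a)

    return etree.tostring(root, xml_declaration=True, encoding="UTF-8").decode("utf-8")


def _disease_dict(ann: DiseaseAnnotation) -> dict:
    return {
        "disease": ann.disease,
        "score": ann.score,
        "genes": list(ann.genes),
        "provenance": [
            [{"kind": kind, "id": identifier} for kind, identifier in chain]
            for chain in ann.provenance
        ],
    }


def _go_dict(m: GOMatch) -> dict:
    return {"go_id": m.go_id, "text": m.matched_text, "start": m.start, "end": m.end}


def _assay_dict(a: AssayAssociation) -> dict:
    return {
        "kind": "assay",
        "compound_id": a.compound_id,
        "similarity": a.similarity,
        "assay_id": a.assay_id,
        "assay_name": a.assay_name,
        "outcome": a.outcome,
        "score": a.score,
        "diseases": [_disease_dict(x) for x in a.diseases],
    }


def report_to_dict(report: AggregateReport) -> dict:
    """The report as plain nested dicts/lists with stable key order."""
    return {
        "query": {
            "smiles": report.query_smiles,
            "fingerprint_popcount": report.query_fingerprint.popcount,
            "fingerprint_hex": report.query_fingerprint.to_hex(),
        },
        "metadata": report.metadata,
        "sections": {
            "predictive_models": [
                {
                    "target": p.target_name,
                    "panel": p.panel,
                    "probability": p.probability,
                    "color": p.color,
                    "confusion_metrics": dict(p.confusion_metrics) if p.confusion_metrics else None,
                }
                for p in report.predictive_models
            ],
            "active_similars": (
                [_assay_dict(a) for a in report.active_assay_hits]
                + [
                    {
                        "kind": "drug",
                        "compound_id": d.compound_id,
                        "similarity": d.similarity,
                        "drug_id": d.drug_id,
                        "name": d.name,
                        "usage_description": d.usage_description,
                        "source": d.source,
                        "go_matches": [_go_dict(m) for m in d.go_matches],
                        "diseases": [_disease_dict(x) for x in d.diseases],
                    }
                    for d in report.active_drug_hits
                ]
                + [
                    {"kind": "shape", "compound_id": n.compound_id, "distance": n.distance}
                    for n in report.shape_neighbours
                ]
            ),
            "chemogenomics_similars": [
                {
                    "kind": "relation",
                    "compound_id": r.compound_id,
                    "similarity": r.similarity,
                    "target": r.target,
                    "target_kind": r.target_kind,
                    "relation": r.relation,
                    "source": r.source,
                }
                for r in report.chemogenomics_similars
            ],
            "systems_similars": [
                {
                    "kind": "pathway",
                    "compound_id": p.compound_id,
                    "similarity": p.similarity,
                    "pathway_id": p.pathway_id,
                    "pathway_name": p.pathway_name,
                    "enzyme": p.enzyme,
                }
                for p in report.systems_similars
            ],
            "literature_similars": [
                {
                    "kind": "paper",
                    "paper_id": lit.paper_id,
                    "title": lit.title,
                    "best_similarity": lit.best_similarity,
                    "compounds": [
                        {"compound_id": cid, "similarity": sim}
                        for cid, sim in lit.compounds
                    ],
                    "title_go": [_go_dict(m) for m in lit.title_go],
                    "abstract_go": [_go_dict(m) for m in lit.abstract_go],
                }
                for lit in report.literature_similars
            ],
            "inactive_similars": [_assay_dict(a) for a in report.inactive_similars],
        },
    }


def report_to_json(report: AggregateReport) -> str:
    """Serialize a report to JSON; same content as the XML form, stable bytes."""
    return json.dumps(report_to_dict(report), indent=2, ensure_ascii=False)
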