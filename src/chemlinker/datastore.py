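"""Loading, validation and indexing of the local evidence tables.

The engine works against a "store": a directory of flat tab-separated tables
standing in for the databases a production deployment would mirror — a
compound table with fingerprints (required), plus optional bioassay
descriptions and outcomes, drug records, literature links, a Gene Ontology
term lexicon, GO-to-gene mappings, a gene x disease association-score matrix,
chemical-gene/disease relations, pathway relations, and 3D conformers.
Loading parses every table that is present, checks referential integrity
against the compound table, and builds the popcount index used by the pruned
2D search; :func:`validate_store` re-checks all invariants and returns issues
as data rather than exceptions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .annotate import GOLexicon
from .chem_core import BitcountIndex, Fingerprint, build_bitcount_index
from .config import EngineConfig
from .errors import InvalidInputError, StoreError
from .shape3d import Conformer, usr_descriptor

logger = logging.getLogger(__name__)

OUTCOME_VOCABULARY = frozenset({"active", "inactive", "inconclusive"})
DRUG_SOURCES = frozenset({"drugbank-like", "mrtd-like"})
RELATION_SOURCES = frozenset({"ctd-like", "chembl-like"})
TARGET_KINDS = frozenset({"gene", "disease", "enzyme-activity"})


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    smiles: str
    fingerprint: Fingerprint


@dataclass(frozen=True)
class AssayRecord:
    assay_id: str
    name: str
    description: str


@dataclass(frozen=True)
class AssayOutcome:
    assay_id: str
    compound_id: str
    outcome: str
    score: float | None = None


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    compound_id: str
    name: str
    usage_description: str
    source: str


@dataclass(frozen=True)
class LiteratureRecord:
    paper_id: str
    title: str
    abstract: str
    compound_ids: tuple[str, ...]


@dataclass(frozen=True)
class ChemGeneRelation:
    compound_id: str
    target: str
    target_kind: str
    relation: str
    source: str


@dataclass(frozen=True)
class PathwayRelation:
    compound_id: str
    pathway_id: str
    pathway_name: str
    enzyme: str | None = None


class GeneDiseaseMatrix:
    """Gene x disease association scores in [0, 1].

    Row labels are gene symbols, columns disease names.  Lookups during
    annotation are case-insensitive on the gene symbol; the canonical symbol
    (as spelled in the table) is what appears in reported provenance.
    """

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame
        self._by_casefold = {str(g).casefold(): str(g) for g in frame.index}

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self.frame.index]

    @property
    def diseases(self) -> list[str]:
        return [str(d) for d in self.frame.columns]

    def resolve_gene(self, symbol: str) -> str | None:
        return self._by_casefold.get(symbol.casefold())

    def score(self, gene: str, disease: str) -> float:
        canonical = self.resolve_gene(gene)
        if canonical is None:
            raise KeyError(gene)
        return float(self.frame.at[canonical, disease])

    @classmethod
    def empty(cls) -> "GeneDiseaseMatrix":
        return cls(pd.DataFrame(dtype=float))


@dataclass
class ValidationIssue:
    table: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.table}] {self.message}"


@dataclass
class DataStore:
    """The loaded, indexed collection of evidence tables."""

    source_dir: Path
    compounds: dict[str, CompoundRecord]
    index: BitcountIndex
    conformers: dict[str, Conformer] = field(default_factory=dict)
    assays: dict[str, AssayRecord] = field(default_factory=dict)
    assay_list: list[AssayRecord] = field(default_factory=list)
    outcomes: list[AssayOutcome] = field(default_factory=list)
    drugs: list[DrugRecord] = field(default_factory=list)
    literature: list[LiteratureRecord] = field(default_factory=list)
    go_lexicon: GOLexicon = field(default_factory=lambda: GOLexicon({}))
    go_genes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    gene_disease: GeneDiseaseMatrix = field(default_factory=GeneDiseaseMatrix.empty)
    chemgene: list[ChemGeneRelation] = field(default_factory=list)
    pathways: list[PathwayRelation] = field(default_factory=list)
    shape_descriptors: dict[str, np.ndarray] = field(default_factory=dict)

    def identity(self) -> str:
        return f"{self.source_dir.name}:{len(self.compounds)}compounds"

    def outcomes_for(self, compound_id: str) -> list[AssayOutcome]:
        return [o for o in self.outcomes if o.compound_id == compound_id]


# -- table readers ----------------------------------------------------------


def _read_table(path: Path, columns: list[str]) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise StoreError(f"{path}: failed to parse: {exc}") from exc
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise StoreError(f"{path}: missing required columns {missing}")
    return frame


def _row_err(path: Path, row: int, message: str) -> StoreError:
    # +2: one for the header line, one for 1-based numbering.
    return StoreError(f"{path}:{row + 2}: {message}")


def _load_compounds(path: Path, length: int) -> dict[str, CompoundRecord]:
    frame = _read_table(path, ["compound_id", "smiles", "fingerprint_hex", "popcount"])
    compounds: dict[str, CompoundRecord] = {}
    for i, row in enumerate(frame.itertuples(index=False)):
        cid = str(row.compound_id)
        if not cid:
            raise _row_err(path, i, "empty compound_id")
        if cid in compounds:
            raise _row_err(path, i, f"duplicate compound_id {cid!r}")
        try:
            fp = Fingerprint.from_hex(str(row.fingerprint_hex), length=length)
        except InvalidInputError as exc:
            raise _row_err(path, i, f"bad fingerprint for {cid!r}: {exc}") from exc
        try:
            declared = int(row.popcount)
        except ValueError as exc:
            raise _row_err(path, i, f"non-integer popcount {row.popcount!r}") from exc
        if declared != fp.popcount:
            raise _row_err(
                path, i,
                f"declared popcount {declared} != actual {fp.popcount} for {cid!r}",
            )
        compounds[cid] = CompoundRecord(cid, str(row.smiles), fp)
    return compounds


def _load_assays(path: Path) -> list[AssayRecord]:
    frame = _read_table(path, ["assay_id", "name", "description"])
    return [
        AssayRecord(str(r.assay_id), str(r.name), str(r.description))
        for r in frame.itertuples(index=False)
    ]


def _load_outcomes(path: Path) -> list[AssayOutcome]:
    frame = _read_table(path, ["assay_id", "compound_id", "outcome", "score"])
    outcomes: list[AssayOutcome] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        outcome = str(row.outcome)
        if outcome not in OUTCOME_VOCABULARY:
            raise _row_err(
                path, i,
                f"outcome {outcome!r} not in {sorted(OUTCOME_VOCABULARY)}",
            )
        score_text = str(row.score)
        score: float | None
        if score_text == "":
            score = None
        else:
            try:
                score = float(score_text)
            except ValueError as exc:
                raise _row_err(path, i, f"non-numeric score {score_text!r}") from exc
        outcomes.append(AssayOutcome(str(row.assay_id), str(row.compound_id), outcome, score))
    return outcomes


def _load_drugs(path: Path) -> list[DrugRecord]:
    frame = _read_table(path, ["drug_id", "compound_id", "name", "usage_description", "source"])
    drugs: list[DrugRecord] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        source = str(row.source)
        if source not in DRUG_SOURCES:
            raise _row_err(path, i, f"drug source {source!r} not in {sorted(DRUG_SOURCES)}")
        drugs.append(
            DrugRecord(str(row.drug_id), str(row.compound_id), str(row.name),
                       str(row.usage_description), source)
        )
    return drugs


def _load_literature(path: Path) -> list[LiteratureRecord]:
    frame = _read_table(path, ["paper_id", "title", "abstract", "compound_ids"])
    papers: list[LiteratureRecord] = []
    for r in frame.itertuples(index=False):
        ids = tuple(c for c in str(r.compound_ids).split(";") if c)
        papers.append(LiteratureRecord(str(r.paper_id), str(r.title), str(r.abstract), ids))
    return papers


def _load_go_lexicon(path: Path) -> GOLexicon:
    frame = _read_table(path, ["go_id", "term_text"])
    pairs = [(str(r.go_id), str(r.term_text)) for r in frame.itertuples(index=False)]
    for i, (go_id, term) in enumerate(pairs):
        if not term.strip():
            raise _row_err(path, i, f"empty term_text for {go_id!r}")
    return GOLexicon.from_pairs(pairs)


def _load_go_genes(path: Path) -> dict[str, tuple[str, ...]]:
    frame = _read_table(path, ["go_id", "gene"])
    mapping: dict[str, list[str]] = {}
    for r in frame.itertuples(index=False):
        mapping.setdefault(str(r.go_id), []).append(str(r.gene))
    return {k: tuple(v) for k, v in mapping.items()}


def _load_gene_disease(path: Path) -> GeneDiseaseMatrix:
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise StoreError(f"{path}: failed to parse: {exc}") from exc
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise StoreError(f"{path}: non-numeric score: {exc}") from exc
    return GeneDiseaseMatrix(frame)


def _load_chemgene(path: Path) -> list[ChemGeneRelation]:
    frame = _read_table(path, ["compound_id", "target", "target_kind", "relation", "source"])
    relations: list[ChemGeneRelation] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        kind = str(row.target_kind)
        if kind not in TARGET_KINDS:
            raise _row_err(path, i, f"target_kind {kind!r} not in {sorted(TARGET_KINDS)}")
        source = str(row.source)
        if source not in RELATION_SOURCES:
            raise _row_err(path, i, f"source {source!r} not in {sorted(RELATION_SOURCES)}")
        relations.append(
            ChemGeneRelation(str(row.compound_id), str(row.target), kind,
                             str(row.relation), source)
        )
    return relations


def _load_pathways(path: Path) -> list[PathwayRelation]:
    frame = _read_table(path, ["compound_id", "pathway_id", "pathway_name", "enzyme"])
    return [
        PathwayRelation(str(r.compound_id), str(r.pathway_id), str(r.pathway_name),
                        str(r.enzyme) or None)
        for r in frame.itertuples(index=False)
    ]


def _load_conformers_tsv(path: Path) -> dict[str, Conformer]:
    conformers: dict[str, Conformer] = {}
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if lineno == 1 and raw.startswith("compound_id"):
            continue
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) != 2:
            raise StoreError(f"{path}:{lineno}: expected 2 tab-separated fields")
        cid, coord_text = parts
        try:
            points = [
                [float(x) for x in triple.split(":")]
                for triple in coord_text.split(";")
                if triple
            ]
            conformers[cid] = Conformer(cid, np.asarray(points))
        except (ValueError, InvalidInputError) as exc:
            raise StoreError(f"{path}:{lineno}: bad coordinates: {exc}") from exc
    return conformers


def _load_conformers_sdf(path: Path) -> dict[str, Conformer]:
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover - rdkit is an optional extra
        raise StoreError(f"{path}: reading SDF conformers requires rdkit") from exc
    conformers: dict[str, Conformer] = {}
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise StoreError(f"{path}: record {i + 1} could not be parsed")
        if not mol.GetNumConformers():
            raise StoreError(f"{path}: record {i + 1} has no 3D coordinates")
        cid = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        if not cid:
            raise StoreError(f"{path}: record {i + 1} has an empty title line")
        coords = mol.GetConformer().GetPositions()
        conformers[cid] = Conformer(cid, np.asarray(coords, dtype=float))
    return conformers


# -- store assembly ---------------------------------------------------------

_OPTIONAL_TABLES = (
    "assays.tsv", "outcomes.tsv", "drugs.tsv", "literature.tsv",
    "go_lexicon.tsv", "go_genes.tsv", "gene_disease.tsv",
    "chemgene.tsv", "pathways.tsv",
)


def load_store(store_dir: str | Path, config: EngineConfig | None = None) -> DataStore:
    """Load and index every table present under ``store_dir``.

    ``compounds.tsv`` is required; every other table is optional and its
    absence merely leaves the corresponding report section empty (logged).
    Dangling compound references and malformed rows are load errors.
    """
    config = config or EngineConfig()
    store_dir = Path(store_dir)
    compounds_path = store_dir / "compounds.tsv"
    if not compounds_path.is_file():
        raise StoreError(f"required table {compounds_path} not found")

    compounds = _load_compounds(compounds_path, config.fingerprint_length)
    index = build_bitcount_index(
        [(cid, rec.fingerprint) for cid, rec in compounds.items()],
        length=config.fingerprint_length,
    )
    store = DataStore(source_dir=store_dir, compounds=compounds, index=index)

    for name in _OPTIONAL_TABLES:
        path = store_dir / name
        if not path.is_file():
            logger.info("optional table %s absent; its section will be empty", name)
            continue
        if name == "assays.tsv":
            store.assay_list = _load_assays(path)
            for assay in store.assay_list:
                if assay.assay_id in store.assays:
                    logger.warning("duplicate assay_id %r in %s", assay.assay_id, path)
                else:
                    store.assays[assay.assay_id] = assay
        elif name == "outcomes.tsv":
            store.outcomes = _load_outcomes(path)
        elif name == "drugs.tsv":
            store.drugs = _load_drugs(path)
        elif name == "literature.tsv":
            store.literature = _load_literature(path)
        elif name == "go_lexicon.tsv":
            store.go_lexicon = _load_go_lexicon(path)
        elif name == "go_genes.tsv":
            store.go_genes = _load_go_genes(path)
        elif name == "gene_disease.tsv":
            store.gene_disease = _load_gene_disease(path)
        elif name == "chemgene.tsv":
            store.chemgene = _load_chemgene(path)
        elif name == "pathways.tsv":
            store.pathways = _load_pathways(path)

    sdf = store_dir / "conformers.sdf"
    tsv = store_dir / "conformers.tsv"
    if sdf.is_file():
        store.conformers = _load_conformers_sdf(sdf)
    elif tsv.is_file():
        store.conformers = _load_conformers_tsv(tsv)
    else:
        logger.info("no conformers table; 3D search unavailable for this store")
    store.shape_descriptors = {
        cid: usr_descriptor(conf) for cid, conf in store.conformers.items()
    }

    dangling = sorted(_dangling_compound_refs(store))
    if dangling:
        raise StoreError(
            "tables reference compound_ids missing from compounds.tsv: "
            + ", ".join(f"{cid} ({table})" for cid, table in dangling)
        )

    _flag_repeated_outcomes(store)
    return store


def _dangling_compound_refs(store: DataStore) -> Iterable[tuple[str, str]]:
    known = store.compounds.keys()
    for o in store.outcomes:
        if o.compound_id not in known:
            yield o.compound_id, "outcomes.tsv"
    for d in store.drugs:
        if d.compound_id not in known:
            yield d.compound_id, "drugs.tsv"
    for p in store.literature:
        for cid in p.compound_ids:
            if cid not in known:
                yield cid, "literature.tsv"
    for r in store.chemgene:
        if r.compound_id not in known:
            yield r.compound_id, "chemgene.tsv"
    for p in store.pathways:
        if p.compound_id not in known:
            yield p.compound_id, "pathways.tsv"
    for cid in store.conformers:
        if cid not in known:
            yield cid, "conformers"


def _flag_repeated_outcomes(store: DataStore) -> None:
    seen: dict[tuple[str, str], set[str]] = {}
    for o in store.outcomes:
        key = (o.assay_id, o.compound_id)
        outcomes = seen.setdefault(key, set())
        if outcomes and o.outcome not in outcomes:
            logger.warning(
                "assay %s / compound %s recorded with multiple distinct outcomes",
                o.assay_id, o.compound_id,
            )
        outcomes.add(o.outcome)


def validate_store(store: DataStore) -> list[ValidationIssue]:
    """Re-check every store invariant; the empty list means consistent."""
    issues: list[ValidationIssue] = []

    for cid, rec in store.compounds.items():
        fp = rec.fingerprint
        if fp.length != store.index.length:
            issues.append(ValidationIssue(
                "compounds.tsv", f"{cid}: fingerprint length {fp.length} != index {store.index.length}"
            ))

    # bitcount index consistency
    indexed = {cid for cid, _ in store.index.all_entries()}
    if indexed != set(store.compounds):
        issues.append(ValidationIssue("index", "bitcount index does not cover the compound table"))
    for pop, entries in store.index.buckets.items():
        for cid, fp in entries:
            if fp.popcount != pop:
                issues.append(ValidationIssue("index", f"{cid}: in bucket {pop} but popcount {fp.popcount}"))

    seen_assays: set[str] = set()
    for assay in store.assay_list:
        if assay.assay_id in seen_assays:
            issues.append(ValidationIssue("assays.tsv", f"duplicate assay_id {assay.assay_id!r}"))
        seen_assays.add(assay.assay_id)

    seen_pairs: set[tuple[str, str, str]] = set()
    for o in store.outcomes:
        if o.outcome not in OUTCOME_VOCABULARY:
            issues.append(ValidationIssue("outcomes.tsv", f"outcome {o.outcome!r} outside vocabulary"))
        triple = (o.assay_id, o.compound_id, o.outcome)
        if triple in seen_pairs:
            issues.append(ValidationIssue(
                "outcomes.tsv",
                f"exact duplicate outcome row assay={o.assay_id} compound={o.compound_id} outcome={o.outcome}",
            ))
        seen_pairs.add(triple)
        if o.assay_id not in store.assays and store.assay_list:
            issues.append(ValidationIssue("outcomes.tsv", f"unknown assay_id {o.assay_id!r}"))

    frame = store.gene_disease.frame
    if frame.size:
        if frame.index.duplicated().any():
            for g in frame.index[frame.index.duplicated()]:
                issues.append(ValidationIssue("gene_disease.tsv", f"duplicate gene label {g!r}"))
        if frame.columns.duplicated().any():
            for d in frame.columns[frame.columns.duplicated()]:
                issues.append(ValidationIssue("gene_disease.tsv", f"duplicate disease label {d!r}"))
        bad = (frame.lt(0.0) | frame.gt(1.0)) & frame.notna()
        for gene in frame.index[bad.any(axis=1)]:
            for disease in frame.columns[bad.loc[gene]]:
                issues.append(ValidationIssue(
                    "gene_disease.tsv",
                    f"score {frame.at[gene, disease]} out of [0,1] at gene={gene!r}, disease={disease!r}",
                ))

    for go_id in store.go_lexicon.go_ids():
        if not GOLexicon.valid_go_id(go_id):
            issues.append(ValidationIssue("go_lexicon.tsv", f"malformed go_id {go_id!r}"))
    for go_id in store.go_genes:
        if not GOLexicon.valid_go_id(go_id):
            issues.append(ValidationIssue("go_genes.tsv", f"malformed go_id {go_id!r}"))

    for cid, table in sorted(set(_dangling_compound_refs(store))):
        issues.append(ValidationIssue(table, f"dangling compound_id {cid!r}"))

    return issues
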