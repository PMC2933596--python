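"""Gene Ontology text tagging and the assay -> GO -> gene -> disease chain.

Free text (bioassay descriptions, drug usage descriptions, paper titles and
abstracts) is scanned against a lexicon of Gene Ontology term phrases using
case-insensitive, word-boundary-respecting exact matching; overlapping
candidate matches are resolved longest-first, then leftmost.  Matched GO
identifiers map to genes through an explicit GO->gene table, and genes map to
diseases through a gene x disease association-score matrix.  A disease's
score is the maximum over its supporting genes, and every reported annotation
carries the full provenance chain that produced it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .config import EngineConfig
from .errors import InvalidInputError

logger = logging.getLogger(__name__)

_GO_ID_RE = re.compile(r"^GO:\d{7}$")

ProvenanceLink = tuple[str, str]          # (source_kind, identifier)
ProvenanceChain = tuple[ProvenanceLink, ...]


class GOLexicon:
    """Mapping of term phrases to GO identifiers (``GO:`` + 7 digits)."""

    def __init__(self, entries: dict[str, str]):
        # keys stored casefolded; original spelling is irrelevant to matching
        self.entries = {term.casefold(): go_id for term, go_id in entries.items()}

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "GOLexicon":
        """Build from (go_id, term_text) rows as stored in go_lexicon.tsv."""
        return cls({term: go_id for go_id, term in pairs})

    @staticmethod
    def valid_go_id(go_id: str) -> bool:
        return bool(_GO_ID_RE.match(go_id))

    def go_ids(self) -> list[str]:
        return sorted(set(self.entries.values()))

    def __len__(self) -> int:
        return len(self.entries)

    def __bool__(self) -> bool:
        return bool(self.entries)


@dataclass(frozen=True)
class GOMatch:
    """One lexicon phrase located in a text, with its 0-based half-open span."""

    go_id: str
    matched_text: str
    start: int
    end: int


@dataclass(frozen=True)
class DiseaseAnnotation:
    """A disease linked to some evidence, with score and provenance.

    ``score`` is the maximum gene-disease association score over the
    supporting genes; ``provenance`` holds one chain per distinct evidence
    path (e.g. assay -> GO term -> gene -> disease), each ending at the
    disease.
    """

    disease: str
    score: float
    genes: tuple[str, ...]
    provenance: tuple[ProvenanceChain, ...]


def extract_go_terms(text: str, lexicon: GOLexicon) -> list[GOMatch]:
    """Locate lexicon phrases in free text.

    Matching is case-insensitive and exact at word boundaries (a phrase never
    matches inside a longer word).  Where candidate matches overlap, the
    longest wins, then the leftmost; surviving matches are returned ordered
    by span start.
    """
    if not text or not lexicon:
        return []
    candidates: list[GOMatch] = []
    for term, go_id in lexicon.entries.items():
        pattern = re.compile(
            r"(?<!\w)" + re.escape(term) + r"(?!\w)", re.IGNORECASE
        )
        for m in pattern.finditer(text):
            candidates.append(GOMatch(go_id, text[m.start():m.end()], m.start(), m.end()))
    # longest first, then leftmost; greedy selection of non-overlapping spans
    candidates.sort(key=lambda c: (-(c.end - c.start), c.start, c.go_id))
    chosen: list[GOMatch] = []
    for cand in candidates:
        if all(cand.end <= other.start or cand.start >= other.end for other in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda c: c.start)
    return chosen


def genes_to_diseases(
    genes: Sequence[str],
    matrix,  # GeneDiseaseMatrix (duck-typed to avoid a circular import)
    min_score: float,
) -> list[DiseaseAnnotation]:
    """Diseases supported by any of the given genes at score >= ``min_score``.

    For each disease the reported score is the maximum over the given genes;
    an annotation lists every gene individually reaching the floor for that
    disease.  Genes absent from the matrix are skipped with a logged notice.
    Results sort by score descending, then disease name ascending.
    """
    if not len(genes):
        return []
    resolved: list[str] = []
    seen: set[str] = set()
    for g in genes:
        canonical = matrix.resolve_gene(g)
        if canonical is None:
            logger.info("gene %r absent from the gene-disease matrix; skipped", g)
            continue
        if canonical not in seen:
            seen.add(canonical)
            resolved.append(canonical)
    if not resolved:
        return []
    sub = matrix.frame.loc[resolved]
    annotations: list[DiseaseAnnotation] = []
    for disease in matrix.diseases:
        col = sub[disease]
        best = float(col.max())
        if best < min_score:
            continue
        supporting = tuple(sorted(str(g) for g in col.index[col >= min_score]))
        chains = tuple(
            (("gene", g), ("disease", disease)) for g in supporting
        )
        annotations.append(DiseaseAnnotation(disease, best, supporting, chains))
    annotations.sort(key=lambda a: (-a.score, a.disease))
    return annotations


def _chains_through(
    head: ProvenanceLink,
    matched_go_ids: Sequence[str],
    go_genes: dict[str, tuple[str, ...]],
    annotation: DiseaseAnnotation,
    matrix,
) -> tuple[ProvenanceChain, ...]:
    """Expand one disease annotation into full head -> GO -> gene -> disease chains."""
    supporting = set(annotation.genes)
    chains: list[ProvenanceChain] = []
    for go_id in matched_go_ids:
        for gene in go_genes.get(go_id, ()):
            canonical = matrix.resolve_gene(gene)
            if canonical in supporting:
                chains.append(
                    (head, ("go", go_id), ("gene", canonical), ("disease", annotation.disease))
                )
    return tuple(sorted(set(chains)))


def text_to_diseases(
    head: ProvenanceLink,
    text: str,
    store,  # DataStore (duck-typed)
    config: EngineConfig,
) -> tuple[list[GOMatch], list[DiseaseAnnotation]]:
    """Run the full chain from a piece of evidence text to disease annotations.

    ``head`` identifies the evidence source (e.g. ``("assay", "A123")``) and
    becomes the first link of every provenance chain.  Returns the GO matches
    and the deduplicated disease annotations; missing lexicon/map/matrix
    tables degrade to empty output.
    """
    if not store.go_lexicon or not store.go_genes or not store.gene_disease.frame.size:
        return [], []
    matches = extract_go_terms(text, store.go_lexicon)
    if not matches:
        return [], []
    matched_go_ids: list[str] = []
    for m in matches:
        if m.go_id not in matched_go_ids:
            matched_go_ids.append(m.go_id)
    genes: list[str] = []
    for go_id in matched_go_ids:
        for gene in store.go_genes.get(go_id, ()):
            if gene not in genes:
                genes.append(gene)
    base = genes_to_diseases(genes, store.gene_disease, config.disease_min_score)
    annotated = [
        DiseaseAnnotation(
            a.disease, a.score, a.genes,
            _chains_through(head, matched_go_ids, store.go_genes, a, store.gene_disease),
        )
        for a in base
    ]
    return matches, annotated


def assay_to_diseases(assay, store, config: EngineConfig) -> list[DiseaseAnnotation]:
    """Diseases inferred from an assay description via GO terms and gene scores.

    Composition of :func:`extract_go_terms` on the description, the GO->gene
    table, and :func:`genes_to_diseases`; each annotation's provenance chains
    record assay -> GO term -> gene -> disease in order.  Two GO terms
    converging on one disease yield a single annotation whose provenance
    lists both chains.
    """
    _, annotations = text_to_diseases(
        ("assay", assay.assay_id), assay.description, store, config
    )
    return annotations
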