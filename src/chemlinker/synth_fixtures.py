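"""Seeded generator of complete, referentially intact fixture stores.

The generator writes every table the engine reads, with two kinds of
content: *planted chains* — compounds whose fingerprint is constructed to
hit an exact rational Tanimoto to a designated query, wired through an
active assay (whose description embeds a GO lexicon phrase), an inactive
assay, a drug record, a chemical-gene relation, a pathway relation, a
literature link, and a gene-disease score, so that a query run must surface
each finding in its expected report section — and *decoys*, records tied to
compounds kept at least 0.05 below the similarity threshold, which must
never appear.  A JSON manifest records the query and every expected finding.

Exact target similarities are achieved with integer arithmetic: for a target
written as a reduced fraction num/den and a query with q bits set, a
multiplier m is chosen so the planted fingerprint shares c = num*m of the
query's bits and has union u = den*m with it, giving Tanimoto exactly
c/u = num/den.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np

from .chem_core import Fingerprint, fixture_fingerprint, tanimoto
from .errors import GenerationError, InvalidInputError
from .shape3d import Conformer, apply_rigid_transform, random_rigid_transform

_SMILES_FRAGMENTS = (
    "C", "CC", "N", "O", "c1ccccc1", "C(=O)", "CN", "CO", "S", "Cl", "F",
    "C(=O)O", "c1ccncc1", "N(C)C", "OC",
)

_WORDS = (
    "inhibition", "of", "kinase", "activity", "in", "cultured", "cells",
    "measuring", "response", "to", "compound", "treatment", "screen",
    "luminescence", "assay", "dose", "series", "profiling", "panel",
)


@dataclass(frozen=True)
class PlantedChain:
    """One end-to-end relationship to plant: similarity, GO term, gene, disease."""

    target_similarity: str = "0.9"   # parsed exactly, e.g. "0.9" -> 9/10
    disease_score: float = 0.9

    def fraction(self) -> Fraction:
        frac = Fraction(self.target_similarity)
        if not (0 < frac <= 1):
            raise InvalidInputError(
                f"target similarity must be in (0, 1], got {self.target_similarity}"
            )
        return frac


@dataclass(frozen=True)
class FixtureSpec:
    """Counts, seed and planted chains for one generated store."""

    seed: int = 0
    n_compounds: int = 150           # decoy compounds
    n_assays: int = 15
    n_drugs: int = 8
    n_papers: int = 12
    n_genes: int = 25
    n_diseases: int = 10
    fingerprint_length: int = 166
    similarity_threshold: float = 0.85
    decoy_margin: float = 0.05
    planted_chains: tuple[PlantedChain, ...] = (
        PlantedChain("0.9", 0.9),
        PlantedChain("0.875", 0.7),
    )

    def __post_init__(self) -> None:
        for name in ("n_compounds", "n_assays", "n_drugs", "n_papers",
                     "n_genes", "n_diseases"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be positive")


def random_conformer(n_atoms: int, seed: int, compound_id: str = "conf") -> Conformer:
    """Seeded uniform random points in a 10 Å box; deterministic per seed."""
    if n_atoms < 1:
        raise InvalidInputError(f"n_atoms must be >= 1, got {n_atoms}")
    rng = random.Random(seed)
    coords = [[rng.uniform(-5.0, 5.0) for _ in range(3)] for _ in range(n_atoms)]
    return Conformer(compound_id, np.asarray(coords))


def _derive_seed(*parts: object) -> int:
    digest = hashlib.sha256(":".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _random_smiles(rng: random.Random) -> str:
    return "".join(rng.choice(_SMILES_FRAGMENTS) for _ in range(rng.randint(3, 8)))


def _random_words(rng: random.Random, n: int) -> str:
    return " ".join(rng.choice(_WORDS) for _ in range(n))


def _solve_exact_overlap(frac: Fraction, q: int, length: int) -> tuple[int, int] | None:
    """Find (intersection c, planted popcount b) with c/(q+b-c) == frac exactly.

    Writes the target as num/den in lowest terms and searches the multiplier m
    such that c = num*m <= q, union u = den*m is in [q, length].  Returns None
    when no integer m fits.
    """
    num, den = frac.numerator, frac.denominator
    m_lo = -(-q // den)                 # ceil(q / den): union must cover the query
    m_hi = min(q // num, length // den)
    for m in range(m_lo, m_hi + 1):
        c, u = num * m, den * m
        b = u - q + c
        if 1 <= b <= length and c <= b and (b - c) <= (length - q):
            return c, b
    return None


def _planted_fingerprint(
    rng: random.Random, query: Fingerprint, c: int, b: int
) -> Fingerprint:
    shared = rng.sample(sorted(query.on_bits), c)
    off = sorted(set(range(query.length)) - query.on_bits)
    extra = rng.sample(off, b - c)
    return Fingerprint(frozenset(shared + extra), length=query.length)


def _write(path: Path, header: str, rows: list[str]) -> None:
    path.write_text("\n".join([header] + rows) + "\n", encoding="utf-8")


def _coords_text(conf: Conformer) -> str:
    return ";".join(":".join(repr(float(x)) for x in point) for point in conf.coords)


def generate_fixture_store(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write a complete store under ``out_dir`` and return its manifest.

    The manifest (also written as ``manifest.json``) records the designated
    query SMILES and conformer, and for each planted chain the exact expected
    similarity and the identifiers that must surface in each report section.
    The designated query itself is never written into the store, so a spec
    with zero planted chains yields all-empty hit sections.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    length = spec.fingerprint_length
    fractions = [chain.fraction() for chain in spec.planted_chains]

    # Redraw the query until every planted target similarity is exactly
    # achievable for its hashed popcount (integer feasibility).
    query_smiles, query_fp, solutions = "", None, []
    for attempt in range(1000):
        candidate = _random_smiles(rng) + ("" if attempt == 0 else f"C{attempt}")
        fp = fixture_fingerprint(candidate, length)
        sols = [_solve_exact_overlap(frac, fp.popcount, length) for frac in fractions]
        if all(s is not None for s in sols):
            query_smiles, query_fp, solutions = candidate, fp, sols
            break
    if query_fp is None:
        raise GenerationError(
            "no query fingerprint admits the requested target similarities "
            f"{[str(f) for f in fractions]} at length {length}"
        )

    threshold_cap = spec.similarity_threshold - spec.decoy_margin
    for frac in fractions:
        if float(frac) <= threshold_cap:
            raise GenerationError(
                f"planted similarity {frac} would fall into the decoy band "
                f"(<= {threshold_cap})"
            )

    compounds: dict[str, tuple[str, Fingerprint]] = {}
    chains_manifest: list[dict] = []
    assay_rows: list[tuple[str, str, str]] = []
    outcome_rows: list[tuple[str, str, str, str]] = []
    drug_rows: list[tuple[str, str, str, str, str]] = []
    paper_rows: list[tuple[str, str, str, str]] = []
    lexicon_rows: list[tuple[str, str]] = []
    go_gene_rows: list[tuple[str, str]] = []
    chemgene_rows: list[tuple[str, str, str, str, str]] = []
    pathway_rows: list[tuple[str, str, str, str]] = []

    # -- planted chains ------------------------------------------------------
    planted_genes: list[str] = []
    planted_diseases: list[tuple[str, float]] = []
    for i, (chain, frac, sol) in enumerate(zip(spec.planted_chains, fractions, solutions)):
        c, b = sol  # type: ignore[misc]
        cid = f"CP{i:03d}"
        fp = _planted_fingerprint(rng, query_fp, c, b)
        smiles = _random_smiles(rng)
        compounds[cid] = (smiles, fp)

        go_id = f"GO:{1000000 + i:07d}"
        go_term = f"planted process {i}"
        gene = f"GENE_P{i}"
        disease = f"Disease_P{i}"
        lexicon_rows.append((go_id, go_term))
        go_gene_rows.append((go_id, gene))
        planted_genes.append(gene)
        planted_diseases.append((disease, chain.disease_score))

        active_assay = f"A_ACT{i:03d}"
        inactive_assay = f"A_INA{i:03d}"
        assay_rows.append(
            (active_assay, f"Planted active assay {i}",
             f"Assay measuring {go_term} response after compound treatment")
        )
        assay_rows.append(
            (inactive_assay, f"Planted inactive assay {i}",
             f"Counter screen {_random_words(rng, 4)}")
        )
        outcome_rows.append((active_assay, cid, "active", f"{rng.uniform(60, 99):.1f}"))
        outcome_rows.append((inactive_assay, cid, "inactive", ""))

        drug_id = f"DR_P{i:03d}"
        drug_rows.append(
            (drug_id, cid, f"planteddrug{i}",
             f"Indicated for disorders of {go_term} regulation", "drugbank-like")
        )
        paper_id = f"PMID_P{i:06d}"
        paper_rows.append(
            (paper_id, f"Role of {go_term} in disease models",
             f"We study compound {cid} and its effect on {go_term}.", cid)
        )
        chemgene_rows.append((cid, gene, "gene", "increases-expression", "ctd-like"))
        pathway_rows.append(
            (cid, f"path:{i:04d}", f"Planted pathway {i}", f"EC 1.1.1.{i + 1}")
        )
        chains_manifest.append({
            "compound_id": cid,
            "similarity": float(frac),
            "similarity_exact": f"{frac.numerator}/{frac.denominator}",
            "intersection": c,
            "popcount": b,
            "active_assay_id": active_assay,
            "inactive_assay_id": inactive_assay,
            "drug_id": drug_id,
            "paper_id": paper_id,
            "pathway_id": f"path:{i:04d}",
            "chemgene_target": gene,
            "go_id": go_id,
            "go_term": go_term,
            "gene": gene,
            "disease": disease,
            "disease_score": chain.disease_score,
        })

    # -- decoys --------------------------------------------------------------
    decoy_ids: list[str] = []
    for i in range(spec.n_compounds):
        cid = f"CD{i:04d}"
        for _ in range(200):
            smiles = _random_smiles(rng) + f"N{i}"
            fp = fixture_fingerprint(smiles, length)
            if tanimoto(query_fp, fp) <= threshold_cap:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise GenerationError(f"could not draw a decoy below {threshold_cap}")
        compounds[cid] = (smiles, fp)
        decoy_ids.append(cid)

    n_lex_decoys = max(5, spec.n_genes // 3)
    for i in range(n_lex_decoys):
        lexicon_rows.append((f"GO:{2000000 + i:07d}", f"decoy process {i}"))
    decoy_genes = [f"GENE_D{i}" for i in range(spec.n_genes)]
    for i, gene in enumerate(decoy_genes):
        go_gene_rows.append((f"GO:{2000000 + i % n_lex_decoys:07d}", gene))

    for i in range(spec.n_assays):
        aid = f"A_DEC{i:03d}"
        term = f" decoy process {i % n_lex_decoys} " if i % 3 == 0 else " "
        assay_rows.append(
            (aid, f"Decoy assay {i}", f"{_random_words(rng, 3)}{term}{_random_words(rng, 3)}")
        )
        cid = decoy_ids[rng.randrange(len(decoy_ids))]
        outcome = ("active", "inactive", "inconclusive")[i % 3]
        outcome_rows.append((aid, cid, outcome, f"{rng.uniform(0, 100):.1f}"))
    for i in range(spec.n_drugs):
        cid = decoy_ids[rng.randrange(len(decoy_ids))]
        drug_rows.append(
            (f"DR_D{i:03d}", cid, f"decoydrug{i}", _random_words(rng, 6),
             "drugbank-like" if i % 2 == 0 else "mrtd-like")
        )
    for i in range(spec.n_papers):
        cid = decoy_ids[rng.randrange(len(decoy_ids))]
        paper_rows.append(
            (f"PMID_D{i:06d}", f"Decoy title {_random_words(rng, 3)}",
             f"Decoy abstract {_random_words(rng, 6)}", cid)
        )
    for i in range(max(3, spec.n_compounds // 30)):
        cid = decoy_ids[rng.randrange(len(decoy_ids))]
        chemgene_rows.append(
            (cid, decoy_genes[rng.randrange(len(decoy_genes))], "gene",
             "decreases-expression", "chembl-like")
        )
        pathway_rows.append((cid, f"path:9{i:03d}", f"Decoy pathway {i}", ""))

    # -- gene x disease matrix ----------------------------------------------
    diseases = [d for d, _ in planted_diseases] + [
        f"Disease_D{i}" for i in range(spec.n_diseases)
    ]
    genes = planted_genes + decoy_genes
    matrix_rows: list[str] = []
    for gene in genes:
        scores: list[float] = []
        for disease in diseases:
            planted = next(
                (s for g, (d, s) in zip(planted_genes, planted_diseases)
                 if g == gene and d == disease),
                None,
            )
            if planted is not None:
                scores.append(planted)
            elif gene in planted_genes:
                # keep every other disease safely under the reporting floor
                scores.append(round(rng.uniform(0.01, 0.40), 3))
            else:
                scores.append(round(rng.uniform(0.0, 1.0), 3))
        matrix_rows.append("\t".join([gene] + [f"{s:g}" for s in scores]))

    # -- conformers ----------------------------------------------------------
    query_conformer = random_conformer(
        rng.randint(8, 16), _derive_seed(spec.seed, "query-conf"), "query"
    )
    conformer_rows: list[str] = []
    shape_neighbour_id = chains_manifest[0]["compound_id"] if chains_manifest else None
    np_rng = np.random.default_rng(_derive_seed(spec.seed, "rigid"))
    for cid in sorted(compounds):
        if cid == shape_neighbour_id:
            rot, trans = random_rigid_transform(np_rng)
            conf = apply_rigid_transform(
                Conformer(cid, query_conformer.coords), rot, trans
            )
        else:
            conf = random_conformer(
                random.Random(_derive_seed(spec.seed, "conf", cid)).randint(4, 20),
                _derive_seed(spec.seed, "coords", cid), cid,
            )
        conformer_rows.append(f"{cid}\t{_coords_text(conf)}")

    # -- write everything ----------------------------------------------------
    _write(
        out_dir / "compounds.tsv",
        "compound_id\tsmiles\tfingerprint_hex\tpopcount",
        [
            f"{cid}\t{smiles}\t{fp.to_hex()}\t{fp.popcount}"
            for cid, (smiles, fp) in sorted(compounds.items())
        ],
    )
    _write(out_dir / "assays.tsv", "assay_id\tname\tdescription",
           ["\t".join(r) for r in sorted(assay_rows)])
    _write(out_dir / "outcomes.tsv", "assay_id\tcompound_id\toutcome\tscore",
           ["\t".join(r) for r in sorted(outcome_rows)])
    _write(out_dir / "drugs.tsv", "drug_id\tcompound_id\tname\tusage_description\tsource",
           ["\t".join(r) for r in sorted(drug_rows)])
    _write(out_dir / "literature.tsv", "paper_id\ttitle\tabstract\tcompound_ids",
           ["\t".join(r) for r in sorted(paper_rows)])
    _write(out_dir / "go_lexicon.tsv", "go_id\tterm_text",
           ["\t".join(r) for r in sorted(lexicon_rows)])
    _write(out_dir / "go_genes.tsv", "go_id\tgene",
           ["\t".join(r) for r in sorted(go_gene_rows)])
    _write(out_dir / "gene_disease.tsv", "\t".join(["gene"] + diseases), matrix_rows)
    _write(out_dir / "chemgene.tsv", "compound_id\ttarget\ttarget_kind\trelation\tsource",
           ["\t".join(r) for r in sorted(chemgene_rows)])
    _write(out_dir / "pathways.tsv", "compound_id\tpathway_id\tpathway_name\tenzyme",
           ["\t".join(r) for r in sorted(pathway_rows)])
    _write(out_dir / "conformers.tsv", "compound_id\tcoords", conformer_rows)

    manifest = {
        "seed": spec.seed,
        "fingerprint_length": length,
        "similarity_threshold": spec.similarity_threshold,
        "query_smiles": query_smiles,
        "query_popcount": query_fp.popcount,
        "query_conformer": [[float(x) for x in p] for p in query_conformer.coords],
        "shape_neighbour_id": shape_neighbour_id,
        "chains": chains_manifest,
        "decoy_compound_ids": decoy_ids,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
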