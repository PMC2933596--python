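# chemlinker

An offline engine for probing the potential biology of a query compound.
Given a SMILES string, it finds structurally similar compounds in a local
collection of chemical/biological tables, chains those hits through bioassay
descriptions, Gene Ontology terms and genes to diseases, and aggregates
everything into a six-section report (predictive models, activities of
similar compounds, chemogenomics relations, pathway relations, literature,
inactivities of similar compounds) serialized as XML or JSON.  It is aimed
at drug-discovery informaticians who want similarity-based evidence
gathering — "what do compounds like this one do?" — over data they control,
with every reported association carrying its full provenance chain.

## The method

**2D similarity with bound pruning.** Compounds carry fixed-length binary
structural-key fingerprints (166 keys by default).  Similarity between
fingerprints A and B is the Tanimoto coefficient

    T(A, B) = |A ∩ B| / |A ∪ B|.

Searching at a threshold *t* uses the popcount bound: for fingerprints with
*a* and *b* bits set,

    T(A, B) ≤ min(a, b) / (a + b − min(a, b)),

so the search buckets compounds by popcount and never scans a bucket whose
bound falls below *t*.  The pruned search is exact — identical output, set
and order, to an exhaustive scan.  The default threshold is 0.85, the
conventional cutoff for the similar-property principle (structurally similar
molecules tend to share biological properties).

**3D shape similarity.** A conformer is summarised by the ultrafast shape
recognition signature: from each of four reference points (centroid, atom
closest to the centroid, atom farthest from it, atom farthest from that
atom), the distance distribution over all atoms is reduced to its mean,
standard deviation and cube-rooted third central moment — 12 numbers,
invariant under rotation and translation.  Shape similarity between
conformers is the Euclidean distance between their 12-vectors.

**Evidence chaining.**  Assay descriptions, drug usage texts and paper
titles/abstracts are tagged with Gene Ontology terms by dictionary phrase
matching (case-insensitive, word-boundary aware, longest match first).  GO
terms map to genes via an explicit table, and genes map to diseases through
a gene × disease association-score matrix; a disease's score is the maximum
over its supporting genes, reported when it reaches a floor (default 0.5)
together with the complete assay → GO → gene → disease chain.

**Predictions.**  Per-target activity probabilities (e.g. 40 tumor cell
lines grouped by panel) come from a pluggable predictor and are colour-coded
red (p ≥ 0.7), yellow (0.6 ≤ p < 0.7) or grey (p < 0.6); a seeded
deterministic reference predictor is bundled so the pipeline runs
self-contained.

## Worked example

Generate a synthetic store with two planted relationship chains, then query
it with the designated query compound recorded in the manifest:

```
$ chemlinker fixtures --out demo --seed 42 --n-compounds 60
wrote store to demo; query SMILES: CCCC(=O)Oc1ccccc1OONC(=O)O (2 planted chains)

$ chemlinker query --smiles 'CCCC(=O)Oc1ccccc1OONC(=O)O' --store demo --format json
```

Reading the JSON sections (abridged):

```
active assay hits: [('CP000', 0.9, 'A_ACT000'), ('CP001', 0.875, 'A_ACT001')]
diseases:          [('Disease_P0', 0.9), ('Disease_P1', 0.7)]
drugs:             [('DR_P000', 0.9), ('DR_P001', 0.875)]
inactive:          [('CP000', 'A_INA000'), ('CP001', 'A_INA001')]
chemogenomics:     [('CP000', 'GENE_P0', 'increases-expression'), ...]
pathways:          [('CP000', 'path:0000'), ('CP001', 'path:0001')]
literature:        [('PMID_P000000', 0.9), ('PMID_P000001', 0.875)]
predictions:       [('REN-1', 0.476, 'grey'), ('REN-2', 0.471, 'grey'), ...]
```

Compound `CP000` was constructed to sit at Tanimoto exactly 0.9 to the
query (an exact integer ratio of intersection to union); it surfaces as
active in assay `A_ACT000`, whose description contains a GO lexicon phrase
linking it — via gene `GENE_P0` and an association score of 0.9 — to
`Disease_P0`, and it reappears with its drug record, chemogenomics relation,
pathway and paper.  Decoy compounds, all held at least 0.05 below the 0.85
threshold, never appear.  The same run as XML nests the full provenance
chain under each disease element.

The library surface mirrors the CLI: `load_store`, `run_query`,
`report_to_xml` / `report_to_json`, plus the individual building blocks
(`search_2d`, `usr_descriptor`, `search_3d`, `extract_go_terms`,
`genes_to_diseases`, `generate_fixture_store`).

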