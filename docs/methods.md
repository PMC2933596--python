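# Methods

## Scope and model

chemlinker re-creates, as a self-contained local library and CLI, an
aggregation pipeline for similarity-based compound annotation.  The model
rests on the similar-property principle: compounds whose structural
fingerprints are highly similar to a query are taken as proxies for the
query's possible biology, and every property recorded for them — assay
outcomes, drug usage, gene/disease relations, pathway membership,
literature co-occurrence — is gathered into one report.  The engine makes
no causal claims; it surfaces evidence with provenance so a scientist can
judge corroboration and conflict.

## 2D similarity and pruning

Fingerprints are fixed-length binary structural-key vectors; the default
length is 166 keys, the size of the classic MACCS-style public key set.  No
bit-compatibility with any particular key catalogue is claimed: fingerprint
generation is a pluggable backend.  Two backends ship:

- `fixture-hash` (default): a SHA-256-seeded choice of bit positions per
  SMILES, giving stable popcounts of roughly L/4–L/2.  It carries no
  chemistry and exists so the whole engine, including stores produced by
  the fixture generator, runs without a chemistry toolkit.
- `maccs`: RDKit's MACCS keys (167 bits with bit 0 unused, shifted down to
  a 166-vector) for real structures.

Similarity is Tanimoto |A∩B|/|A∪B|, computed on integer bit masks.  Two
all-zero fingerprints get similarity 0 by default (`empty_similarity`):
structureless entities are uninformative rather than identical.

Threshold search uses the popcount bound min(a,b)/(a+b−min(a,b)): compounds
are bucketed by popcount, and a bucket is skipped when its bound falls
below the threshold (below-or-equal under a strict threshold).  Because
the bound dominates Tanimoto for every pair it covers, pruning is lossless;
tests compare pruned output against an exhaustive scan at full order.  Hits
are reported at similarity ≥ threshold by default, with a `strict_threshold`
switch for strictly-greater semantics — the non-strict default keeps exact
matches (a stored copy of the query at similarity 1.0) representable.
Ordering is always similarity descending, compound id ascending, so reports
are deterministic.

Fingerprints serialize to hex big-endian with bit 0 as the least
significant bit of the last digit, zero-padded to ceil(L/4) digits; the
compound table stores a declared popcount which is cross-checked at load.

## 3D shape descriptors

The 12-value signature follows the ultrafast-shape-recognition convention:
reference points are the centroid, the atom closest to the centroid, the
atom farthest from the centroid, and the atom farthest from that atom, with
ties broken by lowest atom index; each reference contributes the mean,
population standard deviation and signed cube root of the population third
central moment of the all-atom distance set.  Population (not sample)
moments are used so small-molecule values are exact and testable by hand.
All atoms present in the input record are used; no element filtering.

One numerical point matters: the third central moment of a symmetric
distance set is exactly zero, but `np.power(x, 3)` is not exactly
antisymmetric, and the cube root turns a 1e-15 residue into a 1e-5
descriptor error.  Cubes are therefore formed by explicit multiplication
(`c*c*c`), which cancels exactly; with that, descriptors are invariant
under random rigid motions to better than 1e-12 relative in practice
(tests assert 1e-8).

Similarity between descriptors is plain Euclidean distance — reported as a
distance, ascending, rather than remapped to a bounded similarity; any
transform is left to callers.  `search_3d` returns the k nearest
conformers, ties broken by compound id, and equals an exhaustive scan by
construction (it is one, over cached descriptors; the store precomputes a
descriptor per conformer at load).

## Data store

All relational tables are TSV with header rows — a transparent flat-file
dialect chosen because no portable schema exists for the production
databases this stands in for.  `compounds.tsv` is required; everything else
(assays, outcomes, drugs, literature, GO lexicon, GO→gene map, gene×disease
matrix, chem–gene relations, pathways, conformers as SDF or TSV) is
optional and degrades to an empty report section with a logged notice.
Loading fails fast on malformed rows (with file and line), on outcome
strings outside {active, inactive, inconclusive}, and on any reference to a
compound id absent from the compound table.  Softer invariants — duplicate
assay ids, gene–disease scores outside [0,1], malformed GO ids, exact
duplicate outcome rows — are reported as data by `validate_store` rather
than thrown, so a store can be audited in one pass.  Identifiers are
case-sensitive except gene symbols, which are resolved case-insensitively
during annotation only, with the matrix's spelling reported as canonical.

## Annotation chain

GO recognition is dictionary phrase matching: case-insensitive exact
phrases at word boundaries, overlapping candidates resolved longest-first
then leftmost, output ordered by span start.  This was chosen over
stemming or statistical concept recognition because it is deterministic,
dependency-free and exactly testable; the cost is sensitivity to surface
form, which the lexicon must absorb.  GO→gene linkage is an explicit table
rather than ontology traversal — explicit inputs over hidden inference.

Gene-to-disease scoring takes, per disease, the maximum association score
over the implicated genes (the strongest single piece of support), keeps
diseases at or above `disease_min_score` (default 0.5 — the matrix scores
live in [0,1] and 0.5 is the natural "more likely than not" floor; the
threshold the original annotation tool used is not published), and retains
every gene individually reaching the floor.  Each annotation carries one
provenance chain per distinct evidence path (head → GO id → gene →
disease), so two GO terms converging on one disease yield a single
annotation with both chains.  The same path runs for assay descriptions,
drug usage descriptions and paper titles/abstracts.

## Predictors and colour coding

Activity predictions are a plug-in contract: anything with a `predict`
method mapping (SMILES, fingerprint) to per-target probabilities.  The
production models this mirrors (tumor-cell-line random forests, toxicity
rules) are not reproducible from published information, so the package
ships a seeded reference predictor — per target, a pseudo-random bit mask
M_t, probability |fp ∩ M_t| / |M_t| — which preserves the report structure,
determinism and colour-coding semantics end to end.  Colours: red p ≥ 0.7,
yellow 0.6 ≤ p < 0.7, grey p < 0.6, both cutoffs configurable; the colour
is a monotone step function of probability, asserted as an invariant on
every emitted prediction.  Confusion metrics are pass-through metadata.
The default target list is 40 pseudo cell lines across nine panels (renal,
non-small cell lung, breast, colon, melanoma, leukemia, ovarian, prostate,
CNS), matching the production report's layout.

## Report

Six sections, fixed order: predictive_models, active_similars (assay
actives plus drug hits plus, when a query conformer is supplied, 3D
neighbours), chemogenomics_similars, systems_similars, literature_similars,
inactive_similars.  All six are always present, possibly empty.  Literature
entries are collapsed one-per-paper with the list of matching compounds.
Sections are truncated by rank at `max_hits_per_section` (default 100,
logged).  The XML serialization is unindented and attribute-ordered, so
parse → re-serialize is byte-identical; JSON carries the same content with
stable key order.  The report's metadata timestamp is an optional caller
argument (the CLI supplies wall-clock time); the library default omits it
so identical inputs give identical bytes.

## Synthetic stores

The fixture generator is first-class: it emulates a small deployment's
tables with planted ground truth.  Planted similarities are exact by
integer construction — a target written as a reduced fraction num/den is
realised by choosing a multiplier m with intersection c = num·m and union
u = den·m against the query's q on-bits (feasibility requires an integer m
in [q/den, min(q/num, L/den)]; the query SMILES is redrawn until every
requested target is feasible for its hashed popcount, and an infeasible
request raises a generation error).  Default planted chains sit at 0.9 and
7/8 = 0.875, both above the 0.85 threshold.  Decoy compounds use the hash
fingerprint of their own SMILES, redrawn until at most threshold − 0.05
(default margin) from the query, so boundary floating-point behaviour can
never flip a decoy into a hit.  Planted genes score below 0.45 for every
non-planted disease so the expected annotation set is exact.  One planted
compound's conformer is a random rigid transform of the query conformer,
giving a known first-ranked 3D neighbour.  Generation is fully driven by
the seed and writes files in sorted order, so equal specs produce
byte-identical directories.

What the generator does **not** emulate: real chemistry (SMILES are
syntactically plausible but arbitrary, and planted fingerprints are
constructed rather than derived from their SMILES), realistic GO or
gene–disease content, realistic popcount distributions, or scale.  Passing
tests therefore demonstrate the correctness of the search, chaining and
reporting machinery — exactness of pruning, invariance of descriptors,
recall of planted relationships, determinism of outputs — not retrieval
quality on real databases.

## Problem sizes and numerical choices

The test suite exercises the pruned search on 10,000 random fingerprints ×
50 queries × thresholds {0.70, 0.85, 0.95} against a vectorised exhaustive
oracle; the bound property on 10,000 random pairs; descriptor invariance on
100 conformers × 10 rigid transforms (rtol 1e-8); 3D search against brute
force on 100-conformer sets; and full planted-chain recall over five
generator seeds.  The acceptance script uses 5,000 fingerprints × 60
searches and three seeds end to end, sizes chosen to finish in seconds
while leaving the measured properties unchanged.  Known limitations:
dictionary-only GO tagging, max-aggregation (no evidence combination across
genes), no conformer generation, and no claim of key-set compatibility with
any production fingerprint system.
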