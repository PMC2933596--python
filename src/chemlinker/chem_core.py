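"""2D structural fingerprints, Tanimoto similarity and bound-pruned exact search.

A compound is represented by a fixed-length binary structural-key fingerprint
(166 bits by default, MACCS-style).  Similarity between two fingerprints A and B
is the Tanimoto coefficient |A∩B| / |A∪B|.  Searching a large compound table at
a similarity threshold t is accelerated with the Swamidass–Baldi popcount bound:
for fingerprints with a and b bits set, no pair can exceed

    min(a, b) / (a + b - min(a, b)),

so whole popcount buckets whose bound falls below t are skipped without ever
touching their fingerprints.  The pruned search is exact: it returns precisely
the hits an exhaustive scan would.
"""

from __future__ import annotations

import hashlib
import logging
import random
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

DEFAULT_FINGERPRINT_LENGTH = 166

FingerprintBackend = Callable[[str], "Fingerprint"]


@dataclass(frozen=True)
class Fingerprint:
    """A fixed-length binary structural-key vector.

    Parameters
    ----------
    on_bits:
        Positions of the set bits; every position p satisfies 0 <= p < length.
    length:
        Total number of keys in the catalogue (default 166).
    """

    on_bits: frozenset[int]
    length: int = DEFAULT_FINGERPRINT_LENGTH

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise InvalidInputError(f"fingerprint length must be positive, got {self.length}")
        bits = frozenset(self.on_bits)
        object.__setattr__(self, "on_bits", bits)
        for p in bits:
            if not (0 <= p < self.length):
                raise InvalidInputError(
                    f"bit position {p} outside [0, {self.length})"
                )
        mask = 0
        for p in bits:
            mask |= 1 << p
        object.__setattr__(self, "_mask", mask)

    @property
    def mask(self) -> int:
        """The fingerprint as a single integer bit mask (bit 0 = LSB)."""
        return self._mask  # type: ignore[attr-defined]

    @property
    def popcount(self) -> int:
        return len(self.on_bits)

    # -- serialization ------------------------------------------------------
    # Hex layout: big-endian, bit 0 is the least-significant bit of the last
    # hex digit; the string is zero-padded to ceil(length / 4) digits.

    def to_hex(self) -> str:
        width = -(-self.length // 4)
        return format(self.mask, f"0{width}x")

    @classmethod
    def from_hex(cls, hex_string: str, length: int = DEFAULT_FINGERPRINT_LENGTH) -> "Fingerprint":
        width = -(-length // 4)
        if len(hex_string) != width:
            raise InvalidInputError(
                f"hex fingerprint must have {width} digits for length {length}, "
                f"got {len(hex_string)!r} digits"
            )
        try:
            mask = int(hex_string, 16)
        except ValueError as exc:
            raise InvalidInputError(f"invalid hex fingerprint {hex_string!r}") from exc
        if mask >> length:
            raise InvalidInputError("hex fingerprint has bits set beyond its length")
        bits = frozenset(p for p in range(length) if mask >> p & 1)
        return cls(on_bits=bits, length=length)


@dataclass(frozen=True)
class SimilarityHit:
    """One compound retrieved by a similarity search."""

    compound_id: str
    similarity: float
    source_table: str = "compounds"


@dataclass
class SearchStats:
    """Pruning diagnostics filled in by :func:`search_2d`."""

    buckets_total: int = 0
    buckets_scanned: int = 0
    buckets_skipped: int = 0
    compounds_scanned: int = 0


def tanimoto(fp_a: Fingerprint, fp_b: Fingerprint, *, empty_value: float = 0.0) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| of two equal-length fingerprints.

    Two all-zero fingerprints have no information to compare; their similarity
    is defined as ``empty_value`` (0 by default: structureless entities are
    treated as uninformative rather than identical).
    """
    if fp_a.length != fp_b.length:
        raise InvalidInputError(
            f"fingerprint length mismatch: {fp_a.length} vs {fp_b.length}"
        )
    union = (fp_a.mask | fp_b.mask).bit_count()
    if union == 0:
        return empty_value
    return (fp_a.mask & fp_b.mask).bit_count() / union


def max_attainable_similarity(a: int, b: int) -> float:
    """Upper bound on Tanimoto between any fingerprints with popcounts a and b.

    The intersection can be at most min(a, b), in which case the union is
    a + b - min(a, b); hence min(a, b) / (a + b - min(a, b)).  Returns 0 when
    either popcount is zero.
    """
    if a < 0 or b < 0:
        raise InvalidInputError(f"popcounts must be non-negative, got a={a}, b={b}")
    m = min(a, b)
    if m == 0:
        return 0.0
    return m / (a + b - m)


@dataclass
class BitcountIndex:
    """Compounds bucketed by fingerprint popcount, enabling bound pruning."""

    length: int
    buckets: dict[int, list[tuple[str, Fingerprint]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return sum(len(v) for v in self.buckets.values())

    def all_entries(self) -> Iterable[tuple[str, Fingerprint]]:
        for b in sorted(self.buckets):
            yield from self.buckets[b]


def build_bitcount_index(
    compounds: Sequence[tuple[str, Fingerprint]],
    length: int | None = None,
) -> BitcountIndex:
    """Bucket (compound_id, fingerprint) pairs by popcount, preserving input order.

    All fingerprints must share one length; a mix raises ``InvalidInputError``.
    """
    if length is None:
        length = compounds[0][1].length if compounds else DEFAULT_FINGERPRINT_LENGTH
    index = BitcountIndex(length=length)
    for compound_id, fp in compounds:
        if fp.length != length:
            raise InvalidInputError(
                f"compound {compound_id!r} has fingerprint length {fp.length}, "
                f"expected {length}"
            )
        index.buckets.setdefault(fp.popcount, []).append((compound_id, fp))
    return index


def search_2d(
    query: Fingerprint,
    index: BitcountIndex,
    threshold: float,
    *,
    strict: bool = False,
    source_table: str = "compounds",
    stats: SearchStats | None = None,
) -> list[SimilarityHit]:
    """Exact threshold similarity search with Swamidass–Baldi bucket pruning.

    Returns every indexed compound whose Tanimoto to the query is >= threshold
    (or strictly > when ``strict``), sorted by similarity descending with ties
    broken by compound_id ascending.  Popcount buckets whose bound is below the
    threshold are never scanned; pruning cannot remove a true hit because the
    bound dominates the Tanimoto of every pair it covers.
    """
    if not (0.0 < threshold <= 1.0):
        raise InvalidInputError(f"threshold must be in (0, 1], got {threshold}")
    if query.length != index.length:
        raise InvalidInputError(
            f"query fingerprint length {query.length} does not match index length "
            f"{index.length}"
        )
    a = query.popcount
    hits: list[SimilarityHit] = []
    if stats is not None:
        stats.buckets_total = len(index.buckets)
    for b, entries in index.buckets.items():
        bound = max_attainable_similarity(a, b)
        prunable = bound <= threshold if strict else bound < threshold
        if prunable:
            if stats is not None:
                stats.buckets_skipped += 1
            continue
        if stats is not None:
            stats.buckets_scanned += 1
            stats.compounds_scanned += len(entries)
        for compound_id, fp in entries:
            sim = tanimoto(query, fp)
            keep = sim > threshold if strict else sim >= threshold
            if keep:
                hits.append(SimilarityHit(compound_id, sim, source_table))
    hits.sort(key=lambda h: (-h.similarity, h.compound_id))
    return hits


# -- fingerprint backends ---------------------------------------------------


def fixture_fingerprint(smiles: str, length: int = DEFAULT_FINGERPRINT_LENGTH) -> Fingerprint:
    """Deterministic hash-derived fingerprint for a SMILES string.

    Stands in for a structural-key generator so the engine is exercisable
    without a chemistry toolkit: the SHA-256 digest of the SMILES seeds the
    choice of bit positions, giving a stable, well-spread popcount (roughly a
    quarter to a half of the keys for the default length).  It carries no
    structural meaning and makes no bit-compatibility claim.
    """
    if not smiles or not smiles.strip():
        raise InvalidInputError("cannot fingerprint an empty SMILES string")
    digest = hashlib.sha256(smiles.encode("utf-8")).digest()
    rng = random.Random(int.from_bytes(digest[:8], "big"))
    lo = max(1, length // 4)
    hi = max(lo, length // 2)
    pop = lo + digest[8] % (hi - lo + 1)
    bits = frozenset(rng.sample(range(length), pop))
    return Fingerprint(on_bits=bits, length=length)


def maccs_fingerprint(smiles: str, length: int = DEFAULT_FINGERPRINT_LENGTH) -> Fingerprint:
    """166-key MACCS fingerprint computed with RDKit (real-chemistry backend).

    RDKit's MACCS implementation uses 167 bits with bit 0 permanently unset;
    positions are shifted down by one so the result is a standard 166-key
    vector.  Requires the optional ``rdkit`` dependency.
    """
    if length != DEFAULT_FINGERPRINT_LENGTH:
        raise InvalidInputError("the MACCS backend produces 166-key fingerprints only")
    from rdkit import Chem
    from rdkit.Chem import MACCSkeys

    mol = Chem.MolFromSmiles(smiles) if smiles and smiles.strip() else None
    if mol is None:
        raise InvalidInputError(f"RDKit could not parse SMILES {smiles!r}")
    bv = MACCSkeys.GenMACCSKeys(mol)
    bits = frozenset(p - 1 for p in bv.GetOnBits() if p >= 1)
    return Fingerprint(on_bits=bits, length=length)


FINGERPRINT_BACKENDS: dict[str, FingerprintBackend] = {
    "fixture-hash": fixture_fingerprint,
    "maccs": maccs_fingerprint,
}


def resolve_fingerprint_backend(name: str) -> FingerprintBackend:
    try:
        return FINGERPRINT_BACKENDS[name]
    except KeyError:
        raise InvalidInputError(
            f"unknown fingerprint backend {name!r}; "
            f"available: {sorted(FINGERPRINT_BACKENDS)}"
        ) from None
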