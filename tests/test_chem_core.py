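"""Fingerprints, Tanimoto similarity, the popcount bound, and pruned search."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemlinker import (
    Fingerprint,
    InvalidInputError,
    SearchStats,
    build_bitcount_index,
    fixture_fingerprint,
    max_attainable_similarity,
    search_2d,
    tanimoto,
)

L = 166


def fp(*bits, length=L):
    return Fingerprint(frozenset(bits), length=length)


def random_fp(rng, length=L, lo=1, hi=None):
    hi = hi or length
    return Fingerprint(frozenset(rng.sample(range(length), rng.randint(lo, hi))), length)


bit_sets = st.frozensets(st.integers(min_value=0, max_value=L - 1), max_size=L)


class TestFingerprint:
    def test_rejects_out_of_range_bits(self):
        with pytest.raises(InvalidInputError):
            Fingerprint(frozenset({L}), length=L)
        with pytest.raises(InvalidInputError):
            Fingerprint(frozenset({-1}), length=L)

    @given(bits=bit_sets)
    @settings(max_examples=50, derandomize=True)
    def test_hex_round_trip(self, bits):
        original = Fingerprint(bits, length=L)
        restored = Fingerprint.from_hex(original.to_hex(), length=L)
        assert restored == original
        assert len(original.to_hex()) == -(-L // 4)

    def test_from_hex_rejects_wrong_width_and_stray_bits(self):
        with pytest.raises(InvalidInputError):
            Fingerprint.from_hex("ff", length=L)
        with pytest.raises(InvalidInputError):
            # 42 hex digits but with a bit above position 165
            Fingerprint.from_hex("8" + "0" * 41, length=L)


class TestTanimoto:
    @pytest.mark.parametrize(
        "a_bits, b_bits, expected",
        [
            ({1, 5, 99}, {1, 5, 99}, 1.0),          # identity
            ({0, 1}, {2, 3}, 0.0),                  # disjoint
            ({1, 2, 3, 4}, {3, 4, 5, 6, 7, 8}, 0.25),  # |∩|=2, |∪|=8
        ],
    )
    def test_hand_counted_examples(self, a_bits, b_bits, expected):
        assert tanimoto(fp(*a_bits), fp(*b_bits)) == expected

    def test_both_empty_is_zero_and_configurable(self):
        assert tanimoto(fp(), fp()) == 0.0
        assert tanimoto(fp(), fp(), empty_value=1.0) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            tanimoto(fp(1), fp(1, length=64))

    @given(a=bit_sets, b=bit_sets)
    @settings(max_examples=200, derandomize=True)
    def test_symmetry_range_and_bound(self, a, b):
        fa, fb = Fingerprint(a, L), Fingerprint(b, L)
        t = tanimoto(fa, fb)
        assert t == tanimoto(fb, fa)
        assert 0.0 <= t <= 1.0
        assert t <= max_attainable_similarity(len(a), len(b)) + 1e-15

    def test_agrees_with_rdkit_on_random_pairs(self):
        rdkit = pytest.importorskip("rdkit")
        from rdkit import DataStructs
        from rdkit.DataStructs.cDataStructs import ExplicitBitVect

        rng = random.Random(11)
        for _ in range(50):
            fa, fb = random_fp(rng), random_fp(rng)
            bva, bvb = ExplicitBitVect(L), ExplicitBitVect(L)
            for p in fa.on_bits:
                bva.SetBit(p)
            for p in fb.on_bits:
                bvb.SetBit(p)
            assert tanimoto(fa, fb) == pytest.approx(
                DataStructs.TanimotoSimilarity(bva, bvb), abs=1e-12
            )


class TestBound:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(10, 10, 1.0), (5, 15, 5 / 15), (0, 7, 0.0), (7, 0, 0.0), (0, 0, 0.0)],
    )
    def test_examples(self, a, b, expected):
        assert max_attainable_similarity(a, b) == expected

    def test_negative_rejected(self):
        with pytest.raises(InvalidInputError):
            max_attainable_similarity(-1, 5)

    def test_equality_when_one_set_contains_the_other(self):
        rng = random.Random(3)
        for _ in range(100):
            big = random_fp(rng, lo=10)
            sub = Fingerprint(
                frozenset(rng.sample(sorted(big.on_bits), rng.randint(1, big.popcount))), L
            )
            assert tanimoto(big, sub) == max_attainable_similarity(big.popcount, sub.popcount)


class TestBitcountIndex:
    def test_empty_list(self):
        assert build_bitcount_index([]).buckets == {}

    def test_buckets_by_popcount_preserving_order(self):
        entries = [("a", fp(1, 2, 3, 4)), ("b", fp(5, 6, 7, 8)), ("c", fp(*range(7)))]
        index = build_bitcount_index(entries)
        assert [cid for cid, _ in index.buckets[4]] == ["a", "b"]
        assert [cid for cid, _ in index.buckets[7]] == ["c"]
        assert build_bitcount_index(entries).buckets == index.buckets  # deterministic

    def test_mixed_lengths_rejected(self):
        with pytest.raises(InvalidInputError):
            build_bitcount_index([("a", fp(1)), ("b", fp(1, length=64))])


def brute_force(query, entries, threshold, strict=False):
    hits = []
    for cid, f in entries:
        t = tanimoto(query, f)
        if (t > threshold) if strict else (t >= threshold):
            hits.append((cid, t))
    hits.sort(key=lambda h: (-h[1], h[0]))
    return hits


@pytest.fixture(scope="module")
def indexed():
    rng = random.Random(42)
    entries = [(f"C{i:04d}", random_fp(rng)) for i in range(1000)]
    return entries, build_bitcount_index(entries)


class TestSearch2D:
    def test_self_match_at_threshold_one(self, indexed):
        entries, index = indexed
        cid, f = entries[17]
        hits = search_2d(f, index, 1.0)
        assert any(h.compound_id == cid and h.similarity == 1.0 for h in hits)

    def test_empty_index(self):
        assert search_2d(fp(1, 2), build_bitcount_index([]), 0.5) == []

    @pytest.mark.parametrize("threshold", [0.7, 0.85, 0.95])
    @pytest.mark.parametrize("strict", [False, True])
    def test_matches_exhaustive_scan(self, indexed, threshold, strict):
        entries, index = indexed
        rng = random.Random(threshold)
        for _ in range(10):
            q = random_fp(rng)
            got = [(h.compound_id, h.similarity)
                   for h in search_2d(q, index, threshold, strict=strict)]
            assert got == brute_force(q, entries, threshold, strict)

    def test_pruning_skips_buckets(self, indexed):
        _, index = indexed
        stats = SearchStats()
        search_2d(fixture_fingerprint("CCO"), index, 0.95, stats=stats)
        assert stats.buckets_skipped >= 1
        assert stats.buckets_scanned + stats.buckets_skipped == stats.buckets_total

    def test_threshold_monotonicity(self, indexed):
        entries, index = indexed
        q = random_fp(random.Random(9))
        previous = None
        for threshold in (0.5, 0.6, 0.7, 0.8, 0.9):
            ids = {h.compound_id for h in search_2d(q, index, threshold)}
            if previous is not None:
                assert ids <= previous
            previous = ids

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_bad_threshold_rejected(self, indexed, bad):
        _, index = indexed
        with pytest.raises(InvalidInputError):
            search_2d(fp(1), index, bad)


def test_fixture_fingerprint_is_deterministic_and_rejects_empty():
    a = fixture_fingerprint("c1ccccc1O")
    assert a == fixture_fingerprint("c1ccccc1O")
    assert 1 <= a.popcount <= L
    with pytest.raises(InvalidInputError):
        fixture_fingerprint("   ")
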