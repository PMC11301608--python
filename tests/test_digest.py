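"""Minimizer selection, the affine hash, and collection digests."""

import numpy as np
import pytest

from memtax import (
    DEFAULT_SCHEME,
    DigestScheme,
    build_collection,
    digest_collection,
    digest_pattern,
    digest_sequence,
    hash_kmer,
    select_minimizers,
)
from memtax.digest import digest_bits, parse_ascii, render_ascii

from helpers import occurrences


class TestHash:
    @pytest.mark.parametrize(
        "kmer,expected", [("AAA", 3937), ("ACG", 1475), ("TTT", 4675)]
    )
    def test_printed_formula(self, kmer, expected):
        assert hash_kmer(kmer) == expected

    def test_bad_character(self):
        with pytest.raises(ValueError):
            hash_kmer("ACN")

    def test_wrong_width(self):
        with pytest.raises(ValueError):
            hash_kmer("ACGT")

    def test_injective_on_default_scheme(self):
        from itertools import product

        hashes = {hash_kmer("".join(t)) for t in product("ACGT", repeat=3)}
        assert len(hashes) == 64

    def test_non_coprime_hash_rejected(self):
        with pytest.raises(ValueError, match="injective"):
            DigestScheme(k=3, hash_a=2, hash_m=64)


class TestSelectMinimizers:
    def test_small_window_example(self):
        assert select_minimizers("ACGTACGT", DigestScheme(k=3, w=2)) == [0, 2, 4]

    def test_single_kmer(self):
        assert select_minimizers("ACG", DEFAULT_SCHEME) == [0]

    def test_shorter_than_k(self):
        assert select_minimizers("AC", DEFAULT_SCHEME) == []

    def test_equal_hashes_take_leftmost(self):
        # two k-mers with equal hash: only one full window, leftmost wins
        assert select_minimizers("AAAA", DigestScheme(k=3, w=2)) == [0]

    def test_matches_bruteforce_window_scan(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            seq = "".join(np.array(list("ACGT"))[rng.integers(4, size=40)])
            scheme = DigestScheme(k=3, w=int(rng.integers(2, 8)))
            h = [hash_kmer(seq[j : j + 3], scheme) for j in range(len(seq) - 2)]
            nk = len(h)
            expected = set()
            if nk <= scheme.w:
                expected.add(int(np.argmin(h)))
            else:
                for i in range(nk - scheme.w + 1):
                    window = h[i : i + scheme.w]
                    expected.add(i + window.index(min(window)))
            assert select_minimizers(seq, scheme) == sorted(expected)

    def test_window_guarantee(self):
        """Every window of w k-mer positions contains a selected position,
        so consecutive selections are at most w apart."""
        rng = np.random.default_rng(0)
        for _ in range(500):
            seq = "".join(np.array(list("ACGT"))[rng.integers(4, size=100)])
            sel = select_minimizers(seq, DEFAULT_SCHEME)
            nk = 100 - DEFAULT_SCHEME.k + 1
            assert sel, "at least one minimizer"
            gaps = np.diff([-1] + sel + [nk])
            assert gaps.max() <= DEFAULT_SCHEME.w
            for i in range(nk - DEFAULT_SCHEME.w + 1):
                assert any(i <= j < i + DEFAULT_SCHEME.w for j in sel)

    def test_deterministic(self):
        seq = "ACGTACGGTTACGATCGT"
        assert select_minimizers(seq) == select_minimizers(seq)


class TestDigestSequence:
    def test_repeat_structure(self):
        xs = digest_sequence("ACGTACGT", DigestScheme(k=3, w=2))
        assert len(xs) == 3
        assert xs[0] == xs[2]  # both are ACG

    def test_shorter_than_k_empty(self):
        assert len(digest_sequence("AC")) == 0

    def test_pattern_same_algorithm(self):
        seq = "ACGGATTACCAGTTACGGAT"
        assert np.array_equal(digest_pattern(seq), digest_sequence(seq))


class TestDigestCollection:
    def test_identical_genomes_identical_blocks(self):
        coll = build_collection([("a", "ACGTACGT"), ("b", "ACGTACGT")])
        dc = digest_collection(coll, DigestScheme(k=3, w=2))
        half = len(dc.tokens) // 2
        assert dc.tokens[:half] == dc.tokens[half:]
        assert dc.tokens.count("$") == 2
        assert len(dc.tokens[:half]) == 4  # 3 codes + separator

    def test_genome_shorter_than_k_contributes_separator(self):
        coll = build_collection([("a", "AC")])
        dc = digest_collection(coll)
        assert dc.tokens == ["$"]

    def test_alphabet_at_most_64(self):
        rng = np.random.default_rng(1)
        seqs = [
            ("g%d" % i, "".join(np.array(list("ACGT"))[rng.integers(4, size=300)]))
            for i in range(5)
        ]
        dc = digest_collection(build_collection(seqs))
        assert dc.alphabet_size <= 64
        # dense codes decode to distinct k-mer values
        assert len(set(dc.alphabet_x)) == dc.alphabet_size

    def test_full_genome_pattern_occurs_at_its_block(self):
        """The digest of a whole genome matches the collection digest exactly
        where that genome's block lies."""
        rng = np.random.default_rng(2)
        seqs = [
            ("g%d" % i, "".join(np.array(list("ACGT"))[rng.integers(4, size=120)]))
            for i in range(4)
        ]
        coll = build_collection(seqs)
        dc = digest_collection(coll)
        block_starts = []
        pos = 0
        for g in range(4):
            block_starts.append(pos)
            pos = dc.tokens.index("$", pos) + 1
        for g, (_, seq) in enumerate(seqs):
            pat = dc.encode_pattern(seq)
            occ = occurrences(dc.tokens, pat)
            assert block_starts[g] in occ

    def test_minimizer_positions_decode(self):
        coll = build_collection([("a", "ACGGATTACCAGTTACGGATTT")])
        scheme = DigestScheme(k=3, w=4)
        dc = digest_collection(coll, scheme)
        seq = coll.sequences()[0]
        codes = [t for t in dc.tokens if t != "$"]
        for pos, code in zip(dc.minimizer_positions[0], codes):
            from memtax.digest import kmer_value

            assert kmer_value(seq[pos : pos + 3]) == dc.alphabet_x[code]


class TestAsciiRendering:
    def test_round_trip(self):
        xs = [0, 24, 63, 2, 16]
        assert parse_ascii(render_ascii(xs)) == xs

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            parse_ascii("\x7f")

    def test_digest_bits(self):
        assert digest_bits(21, 64) == 126
        assert digest_bits(10, 4) == 20
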