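"""MEM tables: matching statistics, contraction, emission vs brute force."""

import random

import numpy as np

from memtax import (
    DigestScheme,
    ModeIndex,
    brute_force_mem_table,
    build_index,
    compute_matching_statistics,
    contract_to_extendable,
    digest_collection,
    emit_mems,
    find_mems,
)
from memtax.fm import SAInterval

from helpers import distinct_substrings, mem_tuples, mutated_read, random_collection


class TestMatchingStatistics:
    def test_hand_example(self):
        idx = build_index("ACAT$")
        ms, _ = compute_matching_statistics(idx, idx.alphabet.encode_pattern("CATT"))
        assert list(ms) == [3, 2, 1, 1]

    def test_absent_symbols_give_zero(self):
        idx = build_index("ACAT$")
        ms, _ = compute_matching_statistics(idx, idx.alphabet.encode_pattern("GGG"))
        assert list(ms) == [0, 0, 0]

    def test_unknown_code_breaks_match(self):
        idx = build_index("ACAT$")
        codes = np.array([idx.alphabet.code("A"), -1, idx.alphabet.code("C")])
        ms, _ = compute_matching_statistics(idx, codes)
        assert list(ms) == [1, 0, 1]


class TestContraction:
    def test_symbol_absent_from_bwt_gives_whole_interval(self):
        idx = build_index("AAAA$")
        iv = SAInterval(2, 3)
        niv, depth = contract_to_extendable(idx, iv, 2, idx.alphabet.code("G"))
        assert niv == idx.whole_interval() and depth == 0

    def test_contraction_matches_bruteforce_prefix_rule(self):
        """After contraction to depth d with character c, the depth-d prefix
        of the old match is preceded by c somewhere in the text, and d is
        the longest such prefix length."""
        rng = random.Random(9)
        for _ in range(40):
            coll = random_collection(rng, max_docs=3, min_len=15, max_len=40)
            idx = build_index(coll.text)
            # pick a random occurring pattern as the current match
            seq = coll.text.replace("$", "A")
            st = rng.randint(0, len(seq) - 6)
            pat = coll.text[st : st + rng.randint(2, 6)]
            if "$" in pat:
                continue
            iv = idx.whole_interval()
            for ch in reversed(pat):
                iv = idx.backward_step(iv, idx.alphabet.code(ch))
            if iv.empty:
                continue
            c = rng.choice("ACGT")
            code = idx.alphabet.code(c)
            if not idx.backward_step(iv, code).empty:
                continue  # contraction precondition: no c precedes the match
            niv, depth = contract_to_extendable(idx, iv, len(pat), code)
            # oracle: longest l such that c + pat[:l] occurs in the text
            best = 0
            for l in range(len(pat), -1, -1):
                if c + pat[:l] in coll.text:
                    best = l
                    break
            assert depth == best
            if best > 0:
                assert not idx.backward_step(niv, code).empty


class TestEmission:
    def test_hand_example(self):
        idx = build_index("ACAT$")
        table = find_mems(idx, idx.alphabet.encode_pattern("CATT"))
        assert mem_tuples(table) == [(0, 3, 1, 1, 0, 0), (3, 1, 3, 3, 0, 0)]

    def test_empty_table_when_nothing_matches(self):
        idx = build_index("ACAT$")
        table = find_mems(idx, idx.alphabet.encode_pattern("GGG"))
        assert table.mems == [] and table.longest_length == 0

    def test_min_mem_length_filters(self):
        idx = build_index("ACAT$")
        table = find_mems(idx, idx.alphabet.encode_pattern("CATT"), min_mem_length=2)
        assert [m.length for m in table.mems] == [3]

    def test_read_equal_to_genome_is_single_spanning_mem(self):
        coll_text = "ACGTTGCA$GGGG$"
        idx = build_index(coll_text)
        table = find_mems(idx, idx.alphabet.encode_pattern("ACGTTGCA"))
        assert len(table.mems) == 1
        m = table.mems[0]
        assert (m.read_start, m.length, m.first_doc, m.last_doc) == (0, 8, 0, 0)


class TestOracleEquivalence:
    def test_full_and_digest_modes_match_brute_force(self):
        """FM-based MEM tables equal exhaustive enumeration, on the raw text
        and on minimizer digests of it."""
        rng = random.Random(0)
        scheme = DigestScheme(k=3, w=3)
        for trial in range(40):
            coll = random_collection(rng)
            read, _ = mutated_read(rng, coll, length=30)
            full = ModeIndex.build(coll, "full")
            assert mem_tuples(full.mem_table(read)) == mem_tuples(
                brute_force_mem_table(coll.text, read)
            ), f"trial {trial} full mode"
            dig = ModeIndex.build(coll, "digest", scheme=scheme)
            dc = digest_collection(coll, scheme)
            assert mem_tuples(dig.mem_table(read)) == mem_tuples(
                brute_force_mem_table(dc.tokens, dc.encode_pattern(read))
            ), f"trial {trial} digest mode"

    def test_no_mem_nested_in_another(self):
        rng = random.Random(4)
        for _ in range(30):
            coll = random_collection(rng)
            read, _ = mutated_read(rng, coll, length=25)
            table = ModeIndex.build(coll, "full").mem_table(read)
            spans = [(m.read_start, m.read_start + m.length) for m in table.mems]
            for a in spans:
                for b in spans:
                    if a != b:
                        assert not (a[0] <= b[0] and b[1] <= a[1])

    def test_kernel_mode_preserves_short_pattern_doc_ranges(self):
        """For patterns up to kmax occurring in the collection, the kernel
        index reports the same first/last documents as the full index."""
        rng = random.Random(6)
        kmax = 4
        for _ in range(20):
            coll = random_collection(rng, max_docs=4, min_len=15, max_len=40)
            full = ModeIndex.build(coll, "full")
            kern = ModeIndex.build(coll, "kernel", kmax=kmax)
            pats = distinct_substrings(coll.text.replace("$", " "), kmax)
            pats = {p for p in pats if " " not in p}
            for pat in pats:
                tf = full.mem_table(pat)
                tk = kern.mem_table(pat)
                # the whole pattern occurs, so it is one spanning MEM
                mf = [m for m in tf.mems if m.read_start == 0 and m.length == len(pat)]
                mk = [m for m in tk.mems if m.read_start == 0 and m.length == len(pat)]
                assert mf and mk
                assert (mf[0].first_doc, mf[0].last_doc) == (
                    mk[0].first_doc,
                    mk[0].last_doc,
                )
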