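"""Naive reference implementations shared by the test suite.

Everything here is written as directly as possible (sorting suffixes,
scanning arrays, enumerating substrings) and is deliberately independent
of the package's index machinery: these are the oracles the fast paths
are checked against.
"""

from __future__ import annotations

import random

from memtax import build_collection
from memtax.fm import Alphabet


def random_collection(rng: random.Random, max_docs: int = 4,
                      min_len: int = 20, max_len: int = 60):
    ndocs = rng.randint(1, max_docs)
    seqs = [
        (f"g{i}", "".join(rng.choice("ACGT") for _ in range(rng.randint(min_len, max_len))))
        for i in range(ndocs)
    ]
    return build_collection(seqs)


def mutated_read(rng: random.Random, collection, length: int = 25,
                 max_subs: int = 3) -> tuple[str, int]:
    """A read drawn from one genome with a few random substitutions."""
    doc = rng.randrange(collection.num_docs)
    seq = collection.sequences()[doc]
    length = min(length, len(seq))
    start = rng.randint(0, len(seq) - length)
    read = list(seq[start : start + length])
    for _ in range(rng.randint(0, max_subs)):
        p = rng.randrange(len(read))
        read[p] = rng.choice("ACGT")
    return "".join(read), doc


# ---------------------------------------------------------------------------
# Suffix-structure oracles over encoded integer texts (sentinel appended).


def encode_with_sentinel(text: str, alphabet: Alphabet) -> list[int]:
    return list(alphabet.encode(text)) + [0]


def naive_suffix_array(codes: list[int]) -> list[int]:
    return sorted(range(len(codes)), key=lambda i: codes[i:])


def naive_bwt(codes: list[int], sa: list[int]) -> list[int]:
    n1 = len(codes)
    return [codes[(i - 1) % n1] for i in sa]


def naive_lcp(codes: list[int], sa: list[int]) -> list[int]:
    out = [-1]
    for i in range(1, len(sa)):
        a, b = codes[sa[i - 1] :], codes[sa[i] :]
        l = 0
        while l < len(a) and l < len(b) and a[l] == b[l]:
            l += 1
        out.append(l)
    return out


def naive_psv(lcp: list[int], t: int) -> int:
    for j in range(t - 1, -1, -1):
        if lcp[j] < lcp[t]:
            return j
    return 0


def naive_nsv(lcp: list[int], t: int) -> int:
    for j in range(t + 1, len(lcp)):
        if lcp[j] < lcp[t]:
            return j
    return len(lcp)


def naive_range_min(vals, i: int, j: int) -> tuple[int, int]:
    best_pos, best = i, vals[i]
    for t in range(i + 1, j + 1):
        if vals[t] < best:
            best_pos, best = t, vals[t]
    return best_pos, best


def occurrences(text, pattern) -> list[int]:
    """Start positions of token-wise matches of ``pattern`` in ``text``."""
    n, m = len(text), len(pattern)
    return [
        p for p in range(n - m + 1)
        if all(text[p + t] == pattern[t] for t in range(m))
    ]


def distinct_substrings(text: str, max_len: int) -> set[str]:
    out: set[str] = set()
    for l in range(1, max_len + 1):
        for i in range(len(text) - l + 1):
            out.add(text[i : i + l])
    return out


def mem_tuples(table) -> list[tuple]:
    return [
        (m.read_start, m.length, m.first_pos, m.last_pos, m.first_doc, m.last_doc)
        for m in table.mems
    ]


# ---------------------------------------------------------------------------
# Kernel oracles.


def brute_kept_positions(text: str, kmax: int) -> set[int]:
    """Kept positions by direct enumeration of kmax-mer occurrences."""
    kept: set[int] = set()
    occ: dict[str, list[int]] = {}
    for j in range(len(text) - kmax + 1):
        window = text[j : j + kmax]
        if "$" in window:
            continue
        occ.setdefault(window, []).append(j)
    for positions in occ.values():
        for j in (positions[0], positions[-1]):
            kept.update(range(j, j + kmax))
    docs, start = [], 0
    for i, c in enumerate(text):
        if c == "$":
            kept.add(i)
            docs.append((start, i))
            start = i + 1
    for s, e in docs:
        if e - s < kmax:
            kept.update(range(s, e))
    return kept


def kmer_set(text: str, k: int) -> set[str]:
    """Separator-free k-mers of a (possibly kernelized) text."""
    out = set()
    for i in range(len(text) - k + 1):
        window = text[i : i + k]
        if "$" not in window and "#" not in window:
            out.add(window)
    return out
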