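"""MEM tables via right-to-left matching statistics with LCP contraction.

The matching statistic MS[i] of a read is the length of the longest prefix
of ``read[i..]`` occurring in the indexed text.  We compute MS right to
left: keep the BWT interval of the current match and try a backward step
with the next character to the left; when the step fails, contract the
match to its longest prefix that *is* preceded by that character somewhere
in the text, located through the nearest BWT occurrences of the character
and a range-minimum / PSV / NSV dance on the LCP array.

A MEM starts at read position i iff MS[i] >= 1 and MS[i-1] <= MS[i]
(extending one character left leaves the text).  For each MEM, the
range-extrema of its suffix-array interval give the first and last
occurrence positions, and separator ranks turn those into a document
range [first_doc, last_doc] -- the object the classifier consumes.

``brute_force_mem_table`` re-derives the whole table by explicit substring
scanning and is the reference semantics for every MEM test in the suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np

from .fm import AugmentedIndex, EMPTY_INTERVAL, SAInterval

__all__ = [
    "MEM",
    "MEMTable",
    "compute_matching_statistics",
    "contract_to_extendable",
    "emit_mems",
    "find_mems",
    "brute_force_mem_table",
]


@dataclass(frozen=True)
class MEM:
    """One maximal exact match of a read against the indexed text."""

    read_start: int
    length: int
    interval: SAInterval
    first_pos: int
    last_pos: int
    first_doc: int
    last_doc: int

    @property
    def doc_range(self) -> tuple[int, int]:
        return (self.first_doc, self.last_doc)


@dataclass
class MEMTable:
    """All MEMs of one read, ordered by read offset, plus the MS array."""

    read_id: str
    mems: list[MEM]
    ms: np.ndarray

    @property
    def longest_length(self) -> int:
        return max((m.length for m in self.mems), default=0)

    def longest_mems(self) -> list[MEM]:
        L = self.longest_length
        return [m for m in self.mems if m.length == L] if L else []


def contract_to_extendable(
    index: AugmentedIndex, iv: SAInterval, depth: int, c: int
) -> tuple[SAInterval, int]:
    """Contract a match to its longest prefix preceded somewhere by ``c``.

    ``iv`` is the interval of the current match (depth characters) and
    contains no BWT copy of ``c``.  The nearest copies of ``c`` above and
    below the interval bound the candidates: the shared-prefix length with
    the previous copy at BWT position p is ``min lcp[p+1..lo]`` and with
    the next copy at q is ``min lcp[hi+1..q]``.  The longer candidate wins
    (ties prefer the previous-copy side); the enclosing interval of that
    prefix is ``[psv(t), nsv(t) - 1]`` for the leftmost argmin position t.
    If ``c`` does not occur in the BWT at all, the result is the whole
    interval at depth 0.
    """
    p, q = index.bwt_nearest_occurrence(iv, c)
    best_val = -1
    best_t = None
    if p is not None:
        t, val = index.lcp_range_min(p + 1, iv.lo)
        best_val, best_t = val, t
    if q is not None:
        t, val = index.lcp_range_min(iv.hi + 1, q)
        if val > best_val:
            best_val, best_t = val, t
    if best_t is None:
        return index.whole_interval(), 0
    new_iv = SAInterval(index.psv(best_t), index.nsv(best_t) - 1)
    return new_iv, int(best_val)


def compute_matching_statistics(
    index: AugmentedIndex, pattern_codes: np.ndarray
) -> tuple[np.ndarray, list[SAInterval]]:
    """MS array and per-position SA interval (at depth MS[i]) of a pattern.

    ``pattern_codes`` is the alphabet-encoded read; codes outside the
    alphabet (e.g. -1) break matches, giving MS 0 at their positions.
    """
    m = len(pattern_codes)
    ms = np.zeros(m, dtype=np.int64)
    intervals: list[SAInterval] = [EMPTY_INTERVAL] * m
    iv = index.whole_interval()
    depth = 0
    whole = index.whole_interval()
    for i in range(m - 1, -1, -1):
        c = int(pattern_codes[i])
        if c < 1 or c > index.alphabet.size:
            ms[i] = 0
            intervals[i] = whole
            iv, depth = whole, 0
            continue
        while True:
            stepped = index.backward_step(iv, c)
            if not stepped.empty:
                iv, depth = stepped, depth + 1
                break
            if depth == 0 and iv == whole:
                break  # c occurs nowhere in the text
            iv, depth = contract_to_extendable(index, iv, depth, c)
        ms[i] = depth
        intervals[i] = iv
    return ms, intervals


def emit_mems(
    ms: np.ndarray,
    intervals: Sequence[SAInterval],
    index: AugmentedIndex,
    read_id: str = "read",
    min_mem_length: int = 1,
) -> MEMTable:
    """Turn matching statistics into the MEM table.

    Position i starts a MEM iff MS[i] >= min_mem_length and
    MS[i-1] <= MS[i]; interval extrema and separator ranks fill in the
    occurrence positions and document range.
    """
    mems: list[MEM] = []
    for i in range(len(ms)):
        L = int(ms[i])
        if L < max(1, min_mem_length):
            continue
        if i > 0 and ms[i - 1] > L:
            continue
        iv = intervals[i]
        first_pos, last_pos = index.sa_range_extrema(iv)
        mems.append(
            MEM(
                read_start=i,
                length=L,
                interval=iv,
                first_pos=first_pos,
                last_pos=last_pos,
                first_doc=index.doc_of_position(first_pos),
                last_doc=index.doc_of_position(last_pos),
            )
        )
    return MEMTable(read_id=read_id, mems=mems, ms=np.asarray(ms))


def find_mems(
    index: AugmentedIndex,
    pattern_codes: np.ndarray,
    read_id: str = "read",
    min_mem_length: int = 1,
) -> MEMTable:
    """Convenience wrapper: matching statistics then MEM emission."""
    ms, intervals = compute_matching_statistics(index, pattern_codes)
    return emit_mems(ms, intervals, index, read_id=read_id, min_mem_length=min_mem_length)


def brute_force_mem_table(
    text: Sequence[Hashable],
    read: Sequence[Hashable],
    sep: Hashable = "$",
    read_id: str = "read",
    min_mem_length: int = 1,
) -> MEMTable:
    """Reference MEM table by exhaustive scanning (test oracle).

    Token-wise comparison over any symbol type; separators and run symbols
    in ``text`` simply never equal read symbols.  Positions and document
    indices refer to the token text, exactly as in the index-based path.
    """
    n, m = len(text), len(read)
    match_len = [[0] * n for _ in range(m)]
    for i in range(m):
        row = match_len[i]
        for p in range(n):
            l = 0
            while i + l < m and p + l < n and text[p + l] == read[i + l]:
                l += 1
            row[p] = l
    ms = np.zeros(m, dtype=np.int64)
    for i in range(m):
        ms[i] = max(match_len[i], default=0)
    sep_before = np.zeros(n + 1, dtype=np.int64)
    for p in range(n):
        sep_before[p + 1] = sep_before[p] + (1 if text[p] == sep else 0)
    mems: list[MEM] = []
    for i in range(m):
        L = int(ms[i])
        if L < max(1, min_mem_length):
            continue
        if i > 0 and ms[i - 1] > L:
            continue
        occ = [p for p in range(n) if match_len[i][p] >= L]
        first_pos, last_pos = min(occ), max(occ)
        mems.append(
            MEM(
                read_start=i,
                length=L,
                interval=EMPTY_INTERVAL,
                first_pos=first_pos,
                last_pos=last_pos,
                first_doc=int(sep_before[first_pos]),
                last_doc=int(sep_before[last_pos]),
            )
        )
    return MEMTable(read_id=read_id, mems=mems, ms=ms)
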