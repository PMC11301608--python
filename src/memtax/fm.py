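"""Augmented FM-index over a genome collection or a lossy representation of it.

The index couples the classic FM-index (BWT + backward search) with the
auxiliary structures needed for maximal-exact-match computation on top of
matching statistics:

* access / rank / select on the BWT,
* range-minimum and range-maximum over the suffix array,
* range-minimum, previous-smaller-value (PSV) and next-smaller-value (NSV)
  over the LCP array,
* rank over the bitvector marking the ``$`` genome separators.

One implementation serves four text modes -- the raw concatenation, its
KATKA kernel, a minimizer digest, and a kernel of a digest -- the only
mode-specific part being the registered alphabet.  Everything is stored as
plain numpy arrays; at the scales this package targets the ``O(log n)``
query contracts are met with room to spare and exact equivalence with naive
scans is what the test-suite checks.

A sentinel symbol smaller than every alphabet symbol is appended to the
text before suffix sorting, so for a text of length ``n`` the suffix array
has ``n + 1`` entries and the whole-text BWT interval is ``[0, n]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "Alphabet",
    "DNA_ALPHABET",
    "SAInterval",
    "AugmentedIndex",
    "build_index",
    "suffix_array",
    "kasai_lcp",
]

#: Symbol order shared by the raw and kernel modes: the separator sorts
#: below the run-replacement symbol, which sorts below the bases.
DNA_SYMBOLS = ("$", "#", "A", "C", "G", "T")


class Alphabet:
    """Ordered symbol table; code 0 is reserved for the implicit sentinel.

    Symbols may be characters (DNA modes) or small integers (digest modes,
    where each symbol is a dense minimizer code).  Symbol ``i`` of the table
    is encoded as integer ``i + 1``.
    """

    def __init__(self, symbols: Sequence[Hashable]):
        self.symbols = tuple(symbols)
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("duplicate symbols in alphabet")
        self._code = {s: i + 1 for i, s in enumerate(self.symbols)}

    @property
    def size(self) -> int:
        """Number of symbols, excluding the sentinel."""
        return len(self.symbols)

    def code(self, symbol: Hashable) -> int:
        """Code of ``symbol``, or -1 if it is not in the table."""
        return self._code.get(symbol, -1)

    def encode(self, seq: Iterable[Hashable]) -> np.ndarray:
        """Encode a text; raises on symbols outside the table."""
        seq = seq if isinstance(seq, (str, list, tuple)) else list(seq)
        out = np.fromiter((self._code.get(s, -1) for s in seq), dtype=np.int64)
        if out.size and out.min() < 1:
            bad = [s for s in seq if s not in self._code]
            raise ValueError(f"symbols not in alphabet: {sorted(set(map(str, bad)))[:5]}")
        return out

    def encode_pattern(self, seq: Iterable[Hashable]) -> np.ndarray:
        """Encode a pattern; unknown symbols become -1 (they match nothing)."""
        return np.fromiter((self._code.get(s, -1) for s in seq), dtype=np.int64)

    def decode(self, codes: Iterable[int]) -> list:
        return [self.symbols[c - 1] for c in codes]

    def to_jsonable(self) -> list:
        return list(self.symbols)

    @classmethod
    def from_jsonable(cls, obj: list) -> "Alphabet":
        return cls([s if isinstance(s, str) else int(s) for s in obj])


DNA_ALPHABET = Alphabet(DNA_SYMBOLS)


class SAInterval(NamedTuple):
    """Inclusive interval ``[lo, hi]`` of suffix-array positions."""

    lo: int
    hi: int

    @property
    def empty(self) -> bool:
        return self.lo > self.hi

    def __len__(self) -> int:
        return 0 if self.empty else self.hi - self.lo + 1


EMPTY_INTERVAL = SAInterval(0, -1)


def suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array of an integer sequence by prefix doubling.

    ``codes`` must already include the terminal sentinel as its unique
    minimum.  Runs in O(n log^2 n) via ``np.lexsort``; the naive
    sort-all-suffixes construction is kept in the tests as the oracle.
    """
    n = len(codes)
    rank = np.asarray(codes, dtype=np.int64).copy()
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        new_rank = np.empty(n, dtype=np.int64)
        diff = (rank[order][1:] != rank[order][:-1]) | (
            key2[order][1:] != key2[order][:-1]
        )
        new_rank[order] = np.concatenate(([0], np.cumsum(diff)))
        rank = new_rank
        if rank.max() == n - 1:
            return order.astype(np.int64)
        k *= 2


def kasai_lcp(codes: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """LCP array from the suffix array by Kasai's inversion.

    ``lcp[i]`` is the longest common prefix of suffixes ``sa[i-1]`` and
    ``sa[i]``; ``lcp[0]`` is set to the -1 sentinel so PSV is total.
    """
    n = len(sa)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and codes[i + h] == codes[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    lcp[0] = -1
    return lcp


class _RangeArgExtremum:
    """Sparse table answering leftmost-arg-min (or -max) in O(1)."""

    def __init__(self, values: np.ndarray, maximum: bool = False):
        vals = np.asarray(values, dtype=np.int64)
        self.values = -vals if maximum else vals
        self.maximum = maximum
        n = len(vals)
        levels = [np.arange(n, dtype=np.int64)]
        j = 1
        while (1 << j) <= n:
            prev = levels[-1]
            half = 1 << (j - 1)
            m = n - (1 << j) + 1
            left = prev[:m]
            right = prev[half : half + m]
            take_right = self.values[right] < self.values[left]
            levels.append(np.where(take_right, right, left))
            j += 1
        self._levels = levels

    def query(self, i: int, j: int) -> tuple[int, int]:
        """Leftmost position of the extremum in ``values[i..j]`` and its value."""
        if i > j:
            raise ValueError(f"bad range [{i}, {j}]")
        k = (j - i + 1).bit_length() - 1
        a = self._levels[k][i]
        b = self._levels[k][j - (1 << k) + 1]
        va, vb = self.values[a], self.values[b]
        pos = b if (vb < va or (vb == va and b < a)) else a
        val = int(self.values[pos])
        return int(pos), -val if self.maximum else val


def _psv_nsv(lcp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-positions previous/next *strictly* smaller value over the LCP array.

    Two independent monotonic-stack scans; equal values must not satisfy
    either query, so each scan pops ``>=``.
    """
    n1 = len(lcp)
    psv = np.zeros(n1, dtype=np.int64)
    nsv = np.full(n1, n1, dtype=np.int64)
    stack: list[int] = []
    for t in range(n1):
        while stack and lcp[stack[-1]] >= lcp[t]:
            stack.pop()
        psv[t] = stack[-1] if stack else 0
        stack.append(t)
    stack.clear()
    for t in range(n1 - 1, -1, -1):
        while stack and lcp[stack[-1]] >= lcp[t]:
            stack.pop()
        nsv[t] = stack[-1] if stack else n1
        stack.append(t)
    return psv, nsv


@dataclass
class AugmentedIndex:
    """The augmented FM-index; build with :func:`build_index`."""

    codes: np.ndarray  # encoded text with trailing sentinel 0
    alphabet: Alphabet
    sa: np.ndarray
    bwt: np.ndarray
    lcp: np.ndarray
    C: np.ndarray  # C[c] = number of symbols with code < c
    mode: str = "full"
    params: dict = field(default_factory=dict)
    _occ: dict = field(default_factory=dict, repr=False)
    _sep_positions: np.ndarray | None = field(default=None, repr=False)
    _lcp_rmq: _RangeArgExtremum | None = field(default=None, repr=False)
    _sa_rmin: _RangeArgExtremum | None = field(default=None, repr=False)
    _sa_rmax: _RangeArgExtremum | None = field(default=None, repr=False)
    _psv: np.ndarray | None = field(default=None, repr=False)
    _nsv: np.ndarray | None = field(default=None, repr=False)

    # -- basic geometry -------------------------------------------------

    @property
    def n(self) -> int:
        """Length of the indexed text, excluding the sentinel."""
        return len(self.codes) - 1

    @property
    def num_docs(self) -> int:
        return len(self._sep_positions) if self._sep_positions is not None else 0

    def whole_interval(self) -> SAInterval:
        return SAInterval(0, self.n)

    # -- BWT rank / backward search -------------------------------------

    def rank_bwt(self, c: int, i: int) -> int:
        """Occurrences of code ``c`` in ``bwt[0..i-1]``."""
        pos = self._occ.get(c)
        if pos is None:
            return 0
        return int(np.searchsorted(pos, i, side="left"))

    def backward_step(self, iv: SAInterval, c: int) -> SAInterval:
        """One step of backward search: interval of ``c`` + current pattern.

        Unknown codes give the empty interval rather than raising, so the
        matching-statistics loop can treat them uniformly.
        """
        if iv.empty or c not in self._occ:
            return EMPTY_INTERVAL
        base = int(self.C[c])
        lo = base + self.rank_bwt(c, iv.lo)
        hi = base + self.rank_bwt(c, iv.hi + 1) - 1
        return SAInterval(lo, hi) if lo <= hi else EMPTY_INTERVAL

    def bwt_nearest_occurrence(
        self, iv: SAInterval, c: int
    ) -> tuple[int | None, int | None]:
        """Nearest copies of ``c`` in the BWT outside ``[lo, hi]``.

        Returns (greatest ``p < lo`` with ``bwt[p] == c`` or None,
        least ``q > hi`` with ``bwt[q] == c`` or None).
        """
        pos = self._occ.get(c)
        if pos is None or len(pos) == 0:
            return None, None
        i = int(np.searchsorted(pos, iv.lo, side="left"))
        prev = int(pos[i - 1]) if i > 0 else None
        j = int(np.searchsorted(pos, iv.hi, side="right"))
        nxt = int(pos[j]) if j < len(pos) else None
        return prev, nxt

    # -- SA / LCP range queries ------------------------------------------

    def sa_range_extrema(self, iv: SAInterval) -> tuple[int, int]:
        """Smallest and largest text positions among ``sa[lo..hi]``."""
        if iv.empty:
            raise ValueError("sa_range_extrema on empty interval")
        _, mn = self._sa_rmin.query(iv.lo, iv.hi)
        _, mx = self._sa_rmax.query(iv.lo, iv.hi)
        return mn, mx

    def lcp_range_min(self, i: int, j: int) -> tuple[int, int]:
        """Leftmost position of the minimum of ``lcp[i..j]`` and the minimum."""
        if not (1 <= i <= j <= self.n):
            raise ValueError(f"bad LCP range [{i}, {j}]")
        return self._lcp_rmq.query(i, j)

    def psv(self, t: int) -> int:
        """Greatest ``j < t`` with ``lcp[j] < lcp[t]`` (total; ``lcp[0] = -1``)."""
        if not (1 <= t <= self.n):
            raise ValueError(f"psv position {t} out of range")
        return int(self._psv[t])

    def nsv(self, t: int) -> int:
        """Least ``j > t`` with ``lcp[j] < lcp[t]``, or ``n + 1`` if none."""
        if not (1 <= t <= self.n):
            raise ValueError(f"nsv position {t} out of range")
        return int(self._nsv[t])

    # -- documents -------------------------------------------------------

    def doc_of_position(self, pos: int) -> int:
        """0-based genome index of text position ``pos``: the number of
        separators strictly before it."""
        if not (0 <= pos < self.n):
            raise ValueError(f"position {pos} out of range [0, {self.n})")
        return int(np.searchsorted(self._sep_positions, pos, side="left"))

    # -- serialization ---------------------------------------------------

    def _meta(self) -> dict:
        return {
            "format_version": 1,
            "mode": self.mode,
            "params": self.params,
            "alphabet": self.alphabet.to_jsonable(),
            "n": self.n,
            "num_docs": self.num_docs,
            "text_dtype": "u1" if self.alphabet.size < 255 else "u2",
            "int_dtype": "<i4",
        }

    def _components(self) -> dict[str, bytes]:
        text_dtype = np.uint8 if self.alphabet.size < 255 else np.uint16
        meta = json.dumps(self._meta(), indent=1).encode()
        return {
            "meta.json": meta,
            "text.bin": self.codes.astype(text_dtype).tobytes(),
            "sa.bin": self.sa.astype("<i4").tobytes(),
            "lcp.bin": self.lcp.astype("<i4").tobytes(),
            "bwt.bin": self.bwt.astype(text_dtype).tobytes(),
            "b.bin": np.packbits(
                np.isin(np.arange(self.n), self._sep_positions)
            ).tobytes(),
        }

    def serialized_size_bytes(self) -> int:
        """Total bytes of all serialized components (stable across runs)."""
        return sum(len(b) for b in self._components().values())

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, blob in self._components().items():
            (directory / name).write_bytes(blob)

    @classmethod
    def load(cls, directory: str | Path) -> "AugmentedIndex":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        text_dtype = np.uint8 if meta["text_dtype"] == "u1" else np.uint16
        codes = np.frombuffer((directory / "text.bin").read_bytes(), dtype=text_dtype)
        alphabet = Alphabet.from_jsonable(meta["alphabet"])
        # text.bin stores the sentinel-terminated text; rebuild from the
        # sentinel-free part so every derived structure is reconstructed.
        return build_index_from_codes(
            codes.astype(np.int64)[:-1], alphabet, meta["mode"], meta["params"]
        )


def build_index_from_codes(
    codes: np.ndarray, alphabet: Alphabet, mode: str = "full", params: dict | None = None
) -> AugmentedIndex:
    """Build every component from an already-encoded text (sentinel excluded)."""
    codes = np.asarray(codes, dtype=np.int64)
    if codes.size == 0:
        raise ValueError("cannot index an empty text")
    if codes.min() < 1 or codes.max() > alphabet.size:
        raise ValueError("text contains symbols outside the registered alphabet")
    full = np.concatenate([codes, [0]])
    sa = suffix_array(full)
    bwt = full[(sa - 1) % len(full)]
    counts = np.bincount(full, minlength=alphabet.size + 1)
    C = np.concatenate([[0], np.cumsum(counts)])[: alphabet.size + 1]
    lcp = kasai_lcp(full, sa)
    idx = AugmentedIndex(
        codes=full,
        alphabet=alphabet,
        sa=sa,
        bwt=bwt,
        lcp=lcp,
        C=C,
        mode=mode,
        params=dict(params or {}),
    )
    idx._occ = {
        int(c): np.flatnonzero(bwt == c) for c in np.unique(bwt) if c != 0
    }
    sep_code = alphabet.code("$")
    idx._sep_positions = np.flatnonzero(codes == sep_code)
    idx._lcp_rmq = _RangeArgExtremum(lcp)
    idx._sa_rmin = _RangeArgExtremum(sa)
    idx._sa_rmax = _RangeArgExtremum(sa, maximum=True)
    idx._psv, idx._nsv = _psv_nsv(lcp)
    return idx


def build_index(
    text: Sequence[Hashable],
    alphabet: Alphabet | None = None,
    mode: str = "full",
    params: dict | None = None,
) -> AugmentedIndex:
    """Build the augmented FM-index of ``text``.

    ``text`` is a string (raw or kernel modes) or a sequence of tokens
    (digest modes); symbols must all be registered in ``alphabet``
    (default: the DNA alphabet ``$ < # < A < C < G < T``).
    """
    if alphabet is None:
        alphabet = DNA_ALPHABET
    return build_index_from_codes(alphabet.encode(text), alphabet, mode, params)
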