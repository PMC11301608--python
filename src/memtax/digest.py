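"""Minimizer digests (winnowing) of sequences, collections and patterns.

A digest replaces a DNA sequence by the ordered list of its window
minimizers: position ``j`` is selected iff some window of ``w`` consecutive
k-mer positions containing ``j`` has its leftmost hash minimum at ``j``.
The default scheme is width-3 minimizers in windows of 10 under the affine
hash ``h(x) = (2544 x + 3937) mod 8863``, with a k-mer read as a base-4
number (A=0, C=1, G=2, T=3).

Digest characters are dense ranks of the underlying k-mer value over the
set of k-mers actually selected somewhere in the collection -- not raw
hashes -- so character identity is collision-free by construction; the
hash only decides which positions are selected.  With k=3 the digest
alphabet has at most 64 symbols.  The classic ASCII rendering (codes 37
upward, one printable character per possible k-mer) is provided for
display and round-trips through :func:`parse_ascii`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .collection import GenomeCollection

__all__ = [
    "DigestScheme",
    "DEFAULT_SCHEME",
    "DigestedCollection",
    "hash_kmer",
    "kmer_value",
    "select_minimizers",
    "digest_sequence",
    "digest_collection",
    "digest_pattern",
    "render_ascii",
    "parse_ascii",
    "digest_bits",
]

_BASE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class DigestScheme:
    """Parameters of the minimizer scheme.

    k: minimizer width in bases; w: window size in k-mer positions;
    (hash_a, hash_b, hash_m): the affine hash; display_base: first ASCII
    code used by the printable rendering.
    """

    k: int = 3
    w: int = 10
    hash_a: int = 2544
    hash_b: int = 3937
    hash_m: int = 8863
    display_base: int = 37

    def __post_init__(self):
        if self.k < 1 or self.w < 1 or self.hash_m <= 0:
            raise ValueError("invalid scheme: need k >= 1, w >= 1, m > 0")
        if 4**self.k <= self.hash_m and math.gcd(self.hash_a, self.hash_m) != 1:
            raise ValueError(
                "hash is not injective on k-mers: gcd(a, m) != 1 although 4^k <= m"
            )

    def hash(self, x: int) -> int:
        return (self.hash_a * x + self.hash_b) % self.hash_m

    def to_jsonable(self) -> dict:
        return {
            "k": self.k, "w": self.w, "hash_a": self.hash_a,
            "hash_b": self.hash_b, "hash_m": self.hash_m,
            "display_base": self.display_base,
        }

    @classmethod
    def from_jsonable(cls, obj: dict) -> "DigestScheme":
        return cls(**obj)


DEFAULT_SCHEME = DigestScheme()


def kmer_value(kmer: str) -> int:
    """The k-mer as a base-4 number with A=0, C=1, G=2, T=3."""
    x = 0
    for c in kmer:
        if c not in _BASE:
            raise ValueError(f"invalid base {c!r} in k-mer {kmer!r}")
        x = x * 4 + _BASE[c]
    return x


def hash_kmer(kmer: str, scheme: DigestScheme = DEFAULT_SCHEME) -> int:
    """Affine hash of a width-k k-mer."""
    if len(kmer) != scheme.k:
        raise ValueError(f"k-mer {kmer!r} does not have width {scheme.k}")
    return scheme.hash(kmer_value(kmer))


def _kmer_values(seq: str, k: int) -> np.ndarray:
    """Base-4 values of all k-mers of ``seq`` (vectorized)."""
    codes = np.fromiter((_BASE[c] for c in seq), dtype=np.int64, count=len(seq))
    if len(seq) < k:
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    return windows @ powers


def select_minimizers(
    seq: str, scheme: DigestScheme = DEFAULT_SCHEME
) -> list[int]:
    """Sorted start offsets of the selected minimizer k-mers of ``seq``.

    Position ``j`` is selected iff it is the leftmost hash minimum of some
    window of ``w`` consecutive k-mer positions containing it.  A sequence
    with fewer than ``w`` k-mers uses a single window over all of them;
    shorter than ``k``, it has no minimizers.
    """
    xs = _kmer_values(seq, scheme.k)
    nk = len(xs)
    if nk == 0:
        return []
    h = (scheme.hash_a * xs + scheme.hash_b) % scheme.hash_m
    if nk <= scheme.w:
        return [int(np.argmin(h))]
    windows = np.lib.stride_tricks.sliding_window_view(h, scheme.w)
    # np.argmin takes the leftmost minimum, which is exactly the tie rule.
    picks = windows.argmin(axis=1) + np.arange(len(windows))
    return np.unique(picks).tolist()


def digest_sequence(
    seq: str, scheme: DigestScheme = DEFAULT_SCHEME
) -> np.ndarray:
    """The digest of ``seq``: selected k-mers' base-4 values, in position order."""
    xs = _kmer_values(seq, scheme.k)
    if len(xs) == 0:
        return np.empty(0, dtype=np.int64)
    return xs[np.asarray(select_minimizers(seq, scheme), dtype=np.int64)]


def digest_pattern(read: str, scheme: DigestScheme = DEFAULT_SCHEME) -> np.ndarray:
    """Digest of a read/pattern; same algorithm and scheme as the references."""
    return digest_sequence(read, scheme)


@dataclass
class DigestedCollection:
    """Per-genome digests joined by ``$``, over a dense digest alphabet.

    ``tokens`` is the digested collection as a list mixing dense integer
    codes and the separator string ``'$'``; ``alphabet_x`` lists, sorted,
    the k-mer values present, so dense code c decodes to ``alphabet_x[c]``.
    """

    tokens: list
    scheme: DigestScheme
    alphabet_x: list[int]
    minimizer_positions: list[list[int]]  # per genome, genome-local offsets
    names: list[str] = field(default_factory=list)

    @property
    def num_docs(self) -> int:
        return len(self.minimizer_positions)

    @property
    def alphabet_size(self) -> int:
        return len(self.alphabet_x)

    def _dense(self) -> dict[int, int]:
        return {x: c for c, x in enumerate(self.alphabet_x)}

    def encode_pattern(self, read: str) -> list[int]:
        """Digest a read and map it into the collection's dense alphabet.

        K-mers never selected anywhere in the collection get code -1: they
        cannot match any digest character.
        """
        dense = self._dense()
        return [dense.get(int(x), -1) for x in digest_pattern(read, self.scheme)]

    def doc_of_token_position(self, pos: int) -> int:
        if not (0 <= pos < len(self.tokens)):
            raise ValueError(f"position {pos} out of range")
        return sum(1 for t in self.tokens[:pos] if t == "$")


def digest_collection(
    collection: GenomeCollection, scheme: DigestScheme = DEFAULT_SCHEME
) -> DigestedCollection:
    """Digest every genome and join the digests with ``$`` separators.

    A genome with no k-mers contributes an empty block; its ``$`` is still
    emitted so document numbering is preserved.
    """
    per_doc_positions: list[list[int]] = []
    per_doc_xs: list[np.ndarray] = []
    present: set[int] = set()
    for seq in collection.sequences():
        pos = select_minimizers(seq, scheme)
        xs = _kmer_values(seq, scheme.k)
        sel = xs[np.asarray(pos, dtype=np.int64)] if pos else np.empty(0, np.int64)
        per_doc_positions.append(pos)
        per_doc_xs.append(sel)
        present.update(int(x) for x in sel)
    alphabet_x = sorted(present)
    dense = {x: c for c, x in enumerate(alphabet_x)}
    tokens: list = []
    for sel in per_doc_xs:
        tokens.extend(dense[int(x)] for x in sel)
        tokens.append("$")
    return DigestedCollection(
        tokens=tokens,
        scheme=scheme,
        alphabet_x=alphabet_x,
        minimizer_positions=per_doc_positions,
        names=list(collection.names),
    )


def render_ascii(xs: Sequence[int], scheme: DigestScheme = DEFAULT_SCHEME) -> str:
    """Printable rendering: k-mer value x becomes ``chr(display_base + x)``.

    Only meaningful when ``4^k`` symbols fit in the printable range (k=3:
    ASCII 37..100).
    """
    return "".join(chr(scheme.display_base + int(x)) for x in xs)


def parse_ascii(s: str, scheme: DigestScheme = DEFAULT_SCHEME) -> list[int]:
    """Inverse of :func:`render_ascii`; validates the symbol range."""
    out = []
    for ch in s:
        x = ord(ch) - scheme.display_base
        if not (0 <= x < 4**scheme.k):
            raise ValueError(f"character {ch!r} outside the digest rendering range")
        out.append(x)
    return out


def min_consecutive_minimizer_span(
    n_strings: int,
    length: int = 30,
    scheme: DigestScheme = DEFAULT_SCHEME,
    seed: int = 0,
) -> int | None:
    """Minimum source-character span of two consecutive minimizers, by
    randomized search over ``n_strings`` uniform DNA strings.

    The span runs from the start of the first selected k-mer through the
    end of the next one: ``p2 - p1 + k``.  Selected positions are distinct,
    so ``k + 1`` is a hard floor and the search stops early on reaching it
    (the result is unchanged).  Returns None if no string yields two
    minimizers.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    best: int | None = None
    floor = scheme.k + 1
    for _ in range(n_strings):
        seq = "".join(bases[rng.integers(4, size=length)])
        sel = select_minimizers(seq, scheme)
        if len(sel) < 2:
            continue
        span = min(b - a for a, b in zip(sel, sel[1:])) + scheme.k
        if best is None or span < best:
            best = span
            if best <= floor:
                break
    return best


def digest_bits(num_symbols: int, alphabet_size: int) -> int:
    """Bits needed to store a digest of ``num_symbols`` fixed-width symbols."""
    if alphabet_size < 2:
        return 0
    return num_symbols * math.ceil(math.log2(alphabet_size))
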