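"""Order-kmax KATKA kernels of collections and of minimizer digests.

The kernel of a collection keeps exactly the characters lying inside the
first occurrence or the last occurrence of every distinct separator-free
kmax-mer, plus every ``$``; each maximal run of omitted characters is
replaced by a single run symbol ``#``, except runs adjacent to a ``$`` (or
to a text boundary), which are removed outright -- patterns never contain
``$``, so no match can span such a run anyway.

The construction preserves, for every k <= kmax, the set of k-mers of the
collection and the documents of each k-mer's first and last occurrence,
which is all the MEM-range classifier consumes.

The same algorithm runs unchanged over a minimizer digest: the tokens are
then dense minimizer codes, the separator is still ``$`` and the run
symbol is a dedicated token outside the digest alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

from .collection import GenomeCollection

__all__ = [
    "KernelizedText",
    "mark_first_last",
    "kernelize_tokens",
    "build_kernel",
    "kernel_doc_of_position",
]


@dataclass
class KernelizedText:
    """A kernelized collection; ``text`` is a string in DNA mode."""

    text: str
    kmax: int
    source_length: int
    kept_positions_count: int
    num_docs: int

    def doc_of_position(self, pos: int) -> int:
        return kernel_doc_of_position(self, pos)


def _doc_spans(tokens: Sequence[Hashable], sep: Hashable) -> list[tuple[int, int]]:
    """Half-open [start, end) spans of the documents between separators."""
    spans = []
    start = 0
    for i, t in enumerate(tokens):
        if t == sep:
            spans.append((start, i))
            start = i + 1
    return spans


def mark_first_last(
    tokens: Sequence[Hashable], kmax: int, sep: Hashable = "$"
) -> list[bool]:
    """Keep-mask over ``tokens``: True where a position survives kernelization.

    A position is kept iff it lies inside the first or the last occurrence
    (over the whole concatenation) of some distinct separator-free
    kmax-mer, or it is a separator, or its document is shorter than kmax
    (short documents are kept verbatim so k-mer preservation holds for
    every k up to the document length).
    """
    if kmax < 1:
        raise ValueError("kmax must be >= 1")
    n = len(tokens)
    keep = [False] * n
    is_str = isinstance(tokens, str)
    first: dict = {}
    last: dict = {}
    for j in range(n - kmax + 1):
        window = tokens[j : j + kmax] if is_str else tuple(tokens[j : j + kmax])
        if sep in window:
            continue
        if window not in first:
            first[window] = j
        last[window] = j
    for j in first.values():
        keep[j : j + kmax] = [True] * kmax
    for j in last.values():
        keep[j : j + kmax] = [True] * kmax
    for i, t in enumerate(tokens):
        if t == sep:
            keep[i] = True
    for start, end in _doc_spans(tokens, sep):
        if end - start < kmax:
            keep[start:end] = [True] * (end - start)
    return keep


def kernelize_tokens(
    tokens: Sequence[Hashable],
    kmax: int,
    sep: Hashable = "$",
    run_symbol: Hashable = "#",
) -> tuple[list, int]:
    """Kernelize a token sequence; returns (output tokens, kept count).

    Maximal omitted runs become one ``run_symbol`` each unless adjacent to
    a separator or a text boundary, in which case they are dropped.
    """
    keep = mark_first_last(tokens, kmax, sep=sep)
    n = len(tokens)
    out: list = []
    kept = 0
    i = 0
    while i < n:
        if keep[i]:
            out.append(tokens[i])
            kept += 1
            i += 1
            continue
        j = i
        while j < n and not keep[j]:
            j += 1
        left_boundary = i == 0 or tokens[i - 1] == sep
        right_boundary = j == n or tokens[j] == sep
        if not (left_boundary or right_boundary):
            out.append(run_symbol)
        i = j
    return out, kept


def build_kernel(collection: GenomeCollection | str, kmax: int) -> KernelizedText:
    """Order-kmax KATKA kernel of a genome collection (or its raw text)."""
    text = collection if isinstance(collection, str) else collection.text
    out, kept = kernelize_tokens(text, kmax)
    return KernelizedText(
        text="".join(out),
        kmax=kmax,
        source_length=len(text),
        kept_positions_count=kept,
        num_docs=text.count("$"),
    )


def kernel_doc_of_position(kernel: KernelizedText | str, pos: int) -> int:
    """Document index at a kernel position: separators seen strictly before.

    If there are i separators to the left of the first kernel occurrence of
    a k-mer, the collection's first occurrence of that k-mer is in document
    i (0-based) -- and symmetrically for last occurrences.
    """
    text = kernel if isinstance(kernel, str) else kernel.text
    if not (0 <= pos < len(text)):
        raise ValueError(f"position {pos} out of range [0, {len(text)})")
    return text.count("$", 0, pos)
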