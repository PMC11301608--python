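"""Reading references and reads, and building the concatenated collection.

A genome collection is the concatenation of the reference sequences in
tree (FASTA) order, each terminated by a single ``$`` separator.  Document
(genome) indices are 0-based; the genome a text position belongs to is the
number of ``$`` strictly before it.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomeCollection",
    "read_fasta",
    "read_reads",
    "build_collection",
    "doc_of_position",
]

_BASES = "ACGT"
# IUPAC degenerate codes and the bases each may stand for.
_IUPAC = {
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT", "U": "T",
}


@dataclass
class GenomeCollection:
    """Concatenated genome text ``seq0 $ seq1 $ ... $`` with boundaries."""

    text: str
    names: list[str]
    doc_starts: list[int]

    @property
    def n(self) -> int:
        """Total length of the collection, separators included."""
        return len(self.text)

    @property
    def num_docs(self) -> int:
        return len(self.names)

    def sequences(self) -> list[str]:
        """The individual genome sequences, separator-free."""
        parts = self.text.split("$")
        assert parts[-1] == ""
        return parts[:-1]

    def doc_of_position(self, pos: int) -> int:
        return doc_of_position(self.text, pos)

    def validate(self) -> None:
        if self.text.count("$") != self.num_docs or len(self.doc_starts) != self.num_docs:
            raise ValueError("separator count inconsistent with document count")
        if self.doc_starts and self.doc_starts[0] != 0:
            raise ValueError("first document must start at offset 0")
        if any(b <= a for a, b in zip(self.doc_starts, self.doc_starts[1:])):
            raise ValueError("doc_starts must be strictly increasing")
        if any(not s for s in self.sequences()):
            raise ValueError("empty genome in collection")


def _parse_error_line(path: Path) -> int | None:
    """Line number of the first structural FASTA problem, if any."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            return None if line.startswith(">") else lineno
    return 1  # empty file


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(name, uppercased sequence)`` pairs.

    Order is preserved; lowercase is folded; an empty record or a file that
    does not start with a header raises ``ValueError`` naming the line.
    """
    path = Path(path)
    bad = _parse_error_line(path)
    if bad is not None:
        raise ValueError(f"{path}: line {bad}: expected FASTA header '>'")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record '{rec.id}' has an empty sequence")
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def read_reads(path: str | Path) -> list[tuple[str, str]]:
    """Read reads from FASTA or FASTQ (qualities ignored), sniffed from content."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]


def _resolve_degenerate(name: str, seq: str) -> str:
    """Replace IUPAC degenerate codes by pseudo-random compatible bases.

    The generator is seeded from the record name alone, so replacement is
    reproducible regardless of the record's position in the file.
    """
    if all(c in _BASES for c in seq):
        return seq
    rng = np.random.default_rng(zlib.crc32(name.encode()) & 0x7FFFFFFF)
    out = []
    for c in seq:
        if c in _BASES:
            out.append(c)
        elif c in _IUPAC:
            choices = _IUPAC[c]
            out.append(choices[rng.integers(len(choices))])
        else:
            raise ValueError(f"record '{name}': unsupported character {c!r}")
    return "".join(out)


def build_collection(seqs: Iterable[tuple[str, str]]) -> GenomeCollection:
    """Concatenate genomes left-to-right with ``$`` separators.

    Degenerate IUPAC codes are resolved deterministically per record so the
    collection alphabet is exactly {A, C, G, T, $}.
    """
    names: list[str] = []
    doc_starts: list[int] = []
    parts: list[str] = []
    offset = 0
    for name, seq in seqs:
        if not seq:
            raise ValueError(f"record '{name}' has an empty sequence")
        if "$" in seq or "#" in seq:
            raise ValueError(f"record '{name}' contains a reserved separator character")
        seq = _resolve_degenerate(name, seq.upper())
        names.append(name)
        doc_starts.append(offset)
        parts.append(seq + "$")
        offset += len(seq) + 1
    if not names:
        raise ValueError("cannot build a collection from zero sequences")
    coll = GenomeCollection(text="".join(parts), names=names, doc_starts=doc_starts)
    coll.validate()
    return coll


def doc_of_position(text: str, pos: int) -> int:
    """0-based genome index at ``pos``: the number of ``$`` strictly before it."""
    if not (0 <= pos < len(text)):
        raise ValueError(f"position {pos} out of range [0, {len(text)})")
    return text.count("$", 0, pos)
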