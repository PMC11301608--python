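"""One index surface over the four text modes.

``ModeIndex.build`` turns a genome collection into an augmented FM-index
over:

* ``full`` -- the raw concatenation;
* ``kernel`` -- its order-kmax KATKA kernel;
* ``digest`` -- its minimizer digest (k, w, hash);
* ``digest-kernel`` -- the order-kmax kernel of the digest.

Querying a read digests and/or encodes it to match the indexed text, then
computes its MEM table.  The bundle serializes to a directory (index
arrays, metadata, genome names, optional taxonomy copy) and loads back
without rebuilding from FASTA.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .collection import GenomeCollection
from .digest import DEFAULT_SCHEME, DigestScheme, DigestedCollection, digest_collection
from .fm import Alphabet, AugmentedIndex, DNA_ALPHABET, build_index
from .kernel import build_kernel, kernelize_tokens
from .mems import MEMTable, find_mems

__all__ = ["ModeIndex", "MODES"]

MODES = ("full", "kernel", "digest", "digest-kernel")

#: Run-replacement token used when kernelizing a digest (its alphabet is
#: integer codes, so a string token can never collide with it).
DIGEST_RUN_SYMBOL = "#"


def _digest_alphabet(size: int) -> Alphabet:
    """sentinel < $ < run symbol < dense codes ascending."""
    return Alphabet(("$", "#") + tuple(range(size)))


@dataclass
class ModeIndex:
    """An augmented FM-index plus the mode-specific query pipeline."""

    mode: str
    params: dict
    index: AugmentedIndex
    names: list[str]
    scheme: DigestScheme | None = None
    alphabet_x: list[int] | None = None  # digest modes: dense code -> k-mer value
    minimizer_positions: list[list[int]] | None = None  # digest mode only

    # -- construction ----------------------------------------------------

    @classmethod
    def build(
        cls,
        collection: GenomeCollection,
        mode: str = "full",
        kmax: int | None = None,
        w: int | None = None,
        k: int = 3,
        scheme: DigestScheme | None = None,
    ) -> "ModeIndex":
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
        params: dict = {}
        if mode == "full":
            idx = build_index(collection.text, DNA_ALPHABET, mode="full")
            return cls("full", params, idx, list(collection.names))
        if mode == "kernel":
            if kmax is None:
                raise ValueError("kernel mode needs kmax")
            kern = build_kernel(collection, kmax)
            params = {"kmax": kmax}
            idx = build_index(kern.text, DNA_ALPHABET, mode="kernel", params=params)
            return cls("kernel", params, idx, list(collection.names))
        # digest-based modes
        if scheme is None:
            kw = {"k": k}
            if w is not None:
                kw["w"] = w
            scheme = DigestScheme(**kw)
        digested = digest_collection(collection, scheme)
        tokens = digested.tokens
        params = {"k": scheme.k, "w": scheme.w}
        if mode == "digest-kernel":
            if kmax is None:
                raise ValueError("digest-kernel mode needs kmax")
            tokens, _ = kernelize_tokens(tokens, kmax, sep="$", run_symbol=DIGEST_RUN_SYMBOL)
            params["kmax"] = kmax
        alphabet = _digest_alphabet(digested.alphabet_size)
        idx = build_index(tokens, alphabet, mode=mode, params=params)
        return cls(
            mode, params, idx, list(collection.names),
            scheme=scheme, alphabet_x=list(digested.alphabet_x),
            minimizer_positions=(
                digested.minimizer_positions if mode == "digest" else None
            ),
        )

    # -- querying --------------------------------------------------------

    def encode_read(self, read: str) -> np.ndarray:
        """Alphabet codes of a read in this index's text space.

        DNA modes encode characters directly; digest modes digest the read
        first and map selected k-mers through the dense alphabet.  Symbols
        or k-mers absent from the index alphabet become -1 and break
        matches.
        """
        if self.mode in ("full", "kernel"):
            return self.index.alphabet.encode_pattern(read.upper())
        dense = {x: c for c, x in enumerate(self.alphabet_x)}
        from .digest import digest_pattern

        xs = digest_pattern(read.upper(), self.scheme)
        # dense code c is alphabet symbol int(c) -> index code 3 + c
        return np.array(
            [3 + dense[int(x)] if int(x) in dense else -1 for x in xs],
            dtype=np.int64,
        )

    def mem_table(self, read: str, read_id: str = "read", min_mem_length: int = 1) -> MEMTable:
        codes = self.encode_read(read)
        return find_mems(self.index, codes, read_id=read_id, min_mem_length=min_mem_length)

    def approx_source_span(self, mem) -> tuple[int, int, int] | None:
        """Digest mode only: (doc, start, end) genome-local source span of a
        MEM's first occurrence, via the recorded minimizer positions.

        Approximate and for reporting only: the span covers the selected
        k-mers' source extents at the occurrence, not an exact alignment.
        Returns None in other modes (kernelized digests lose positional
        mapping by construction).
        """
        if self.mode != "digest" or self.minimizer_positions is None:
            return None
        doc = self.index.doc_of_position(mem.first_pos)
        # token-space start of this document's digest block
        sep_positions = self.index._sep_positions
        block_start = 0 if doc == 0 else int(sep_positions[doc - 1]) + 1
        off = mem.first_pos - block_start
        positions = self.minimizer_positions[doc]
        start = positions[off]
        end = positions[off + mem.length - 1] + self.scheme.k - 1
        return doc, start, end

    def serialized_size_bytes(self) -> int:
        return self.index.serialized_size_bytes() + len(self._meta_json())

    # -- persistence -----------------------------------------------------

    def _meta_json(self) -> bytes:
        meta = {
            "mode": self.mode,
            "params": self.params,
            "scheme": self.scheme.to_jsonable() if self.scheme else None,
            "alphabet_x": self.alphabet_x,
            "minimizer_positions": self.minimizer_positions,
        }
        return json.dumps(meta, indent=1).encode()

    def save(self, directory: str | Path, taxonomy_path: str | Path | None = None) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.index.save(directory)
        (directory / "mode.json").write_bytes(self._meta_json())
        (directory / "names.tsv").write_text(
            "".join(f"{i}\t{n}\n" for i, n in enumerate(self.names))
        )
        if taxonomy_path is not None:
            shutil.copy(taxonomy_path, directory / Path(taxonomy_path).name)

    @classmethod
    def load(cls, directory: str | Path) -> "ModeIndex":
        directory = Path(directory)
        meta = json.loads((directory / "mode.json").read_text())
        idx = AugmentedIndex.load(directory)
        names = [
            line.split("\t")[1]
            for line in (directory / "names.tsv").read_text().splitlines()
        ]
        scheme = DigestScheme.from_jsonable(meta["scheme"]) if meta["scheme"] else None
        return cls(
            mode=meta["mode"], params=meta["params"], index=idx, names=names,
            scheme=scheme, alphabet_x=meta["alphabet_x"],
            minimizer_positions=meta.get("minimizer_positions"),
        )
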