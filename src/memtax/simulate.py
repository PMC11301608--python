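"""Synthetic phylogeny fixtures and simulated reads.

The fixture generator emulates the shape of a curated rRNA reference
database at reduced scale: a random bifurcating tree whose leaves carry
sequences derived from a common root by per-branch substitution at a fixed
divergence rate, so related taxa share long exact stretches while distant
taxa do not.

Reads follow the substitution-only protocol: a uniform start inside one
genome, fixed read length, and exactly ``round(error_rate * length)``
distinct positions substituted to a different base -- 200 bp reads at 1%
error carry exactly two mismatches.  Reads never straddle genome
boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .collection import GenomeCollection, build_collection
from .taxonomy import TaxonomyTree

__all__ = ["SimulatedRead", "generate_fixture", "simulate_reads"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    source_doc: int
    start: int
    mutated_positions: tuple[int, ...]
    seed: int


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitution at probability ``rate``, always to a new base."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for p in hits:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(3)]
    return out


def generate_fixture(
    n_taxa: int,
    seq_length: int = 1000,
    divergence: float = 0.05,
    seed: int = 0,
) -> tuple[GenomeCollection, TaxonomyTree]:
    """Random bifurcating phylogeny with sequences evolved from one root.

    Each child's sequence is its parent's mutated at the per-site
    ``divergence`` rate, so sequence distance grows with tree distance.
    Leaves become the genomes, concatenated in left-to-right tree order.
    Deterministic under ``seed``.
    """
    if n_taxa < 2:
        raise ValueError("need at least two taxa")
    if not (0 <= divergence < 1):
        raise ValueError("divergence must be in [0, 1)")
    rng = np.random.default_rng(seed)
    parent: dict[str, str] = {}
    sequences: dict[str, np.ndarray] = {}
    leaves: list[str] = []
    counter = [0]

    def grow(node: str, n_leaves: int) -> None:
        if n_leaves == 1:
            leaves.append(node)
            return
        n_left = int(rng.integers(1, n_leaves))
        for side, n_sub in (("0", n_left), ("1", n_leaves - n_left)):
            counter[0] += 1
            child = f"n{counter[0]}"
            parent[child] = node
            sequences[child] = _mutate(sequences[node], divergence, rng)
            grow(child, n_sub)

    root = "n0"
    parent[root] = root
    sequences[root] = _BASES[rng.integers(4, size=seq_length)]
    grow(root, n_taxa)
    names = [f"g{i:04d}" for i in range(len(leaves))]
    relabel = dict(zip(leaves, names))
    parent = {relabel.get(n, n): relabel.get(p, p) for n, p in parent.items()}
    seqs = [(relabel[leaf], "".join(sequences[leaf])) for leaf in leaves]
    collection = build_collection(seqs)
    tree = TaxonomyTree(
        parent=parent, leaf_of_name={n: n for n in names}, doc_names=names
    )
    return collection, tree


def simulate_reads(
    collection: GenomeCollection,
    reads_per_doc: int = 500,
    length: int = 200,
    error_rate: float = 0.01,
    seed: int = 0,
) -> list[SimulatedRead]:
    """Simulated substitution-error reads with full provenance.

    For each genome: ``reads_per_doc`` reads of ``length`` bases, start
    uniform in ``[0, |genome| - length]``, with exactly
    ``round(error_rate * length)`` distinct positions substituted.
    Genomes shorter than ``length`` are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    n_mut = round(error_rate * length)
    reads: list[SimulatedRead] = []
    for doc, seq in enumerate(collection.sequences()):
        if len(seq) < length:
            warnings.warn(
                f"genome {collection.names[doc]} shorter than read length; skipped"
            )
            continue
        for r in range(reads_per_doc):
            start = int(rng.integers(0, len(seq) - length + 1))
            read = np.array(list(seq[start : start + length]))
            positions = tuple(
                sorted(int(p) for p in rng.choice(length, size=n_mut, replace=False))
            )
            for p in positions:
                choices = [b for b in "ACGT" if b != read[p]]
                read[p] = choices[rng.integers(3)]
            reads.append(
                SimulatedRead(
                    read_id=f"{collection.names[doc]}_r{r}",
                    sequence="".join(read),
                    source_doc=doc,
                    start=start,
                    mutated_positions=positions,
                    seed=seed,
                )
            )
    return reads
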