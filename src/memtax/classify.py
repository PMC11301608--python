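"""Classifying MEM document ranges and whole reads.

A MEM's [first_doc, last_doc] range is judged against the read's true
source genome g:

* ``TP`` -- the range is exactly [g, g];
* ``FP`` -- non-empty but excludes g;
* ``VP`` (vague positive) -- contains g and at least one other genome;
* ``FN`` -- empty (possible only in digest modes, where a read's digest
  characters may not occur in the collection digest at all).

A read is a true positive iff its longest MEM is a TP -- or, on a tie,
iff *all* of its longest MEMs are TPs.  Membership in the range is by
integer interval: genomes strictly between first and last need not
actually contain the MEM; the range is an over-approximation by design.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .mems import MEMTable

__all__ = ["RangeVerdict", "ReadVerdict", "classify_range", "classify_read"]

#: The four range verdicts.
RangeVerdict = str
TP, FP, VP, FN = "TP", "FP", "VP", "FN"


@dataclass
class ReadVerdict:
    """Read-level outcome, with diagnostics about the longest MEMs."""

    read_id: str
    is_true_positive: bool
    longest_mem_length: int
    longest_mem_verdicts: list[RangeVerdict]
    aggregate_label: str

    @property
    def n_longest(self) -> int:
        return len(self.longest_mem_verdicts)


def classify_range(
    first_doc: int | None, last_doc: int | None, source_doc: int
) -> RangeVerdict:
    """Verdict of one [first_doc, last_doc] range against the source genome."""
    if first_doc is None or last_doc is None:
        return FN
    if first_doc > last_doc:
        raise ValueError(f"invalid range [{first_doc}, {last_doc}]")
    if first_doc == last_doc == source_doc:
        return TP
    if first_doc <= source_doc <= last_doc:
        return VP
    return FP


def classify_read(table: MEMTable, source_doc: int) -> ReadVerdict:
    """Read verdict from the longest MEM(s) of its MEM table.

    True positive iff the table is non-empty and every longest MEM
    classifies TP.  The aggregate label (diagnostic only) is FN for an
    empty table, TP for true positives, else the majority verdict among
    the longest MEMs (ties prefer VP over FP).
    """
    longest = table.longest_mems()
    verdicts = [classify_range(m.first_doc, m.last_doc, source_doc) for m in longest]
    is_tp = bool(verdicts) and all(v == TP for v in verdicts)
    if not verdicts:
        label = FN
    elif is_tp:
        label = TP
    else:
        counts = Counter(verdicts)
        label = max(counts, key=lambda v: (counts[v], v == VP, v))
    return ReadVerdict(
        read_id=table.read_id,
        is_true_positive=is_tp,
        longest_mem_length=table.longest_length,
        longest_mem_verdicts=verdicts,
        aggregate_label=label,
    )
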