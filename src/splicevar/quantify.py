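"""Relative expression of canonical and aberrant transcript variants.

Junction-supported variants (canonical splicing, exon skipping, cryptic
sites) are measured in junction reads; intron retention is measured as the
median depth of the retained intron.  The two evidence units are treated
as commensurate and normalised jointly:

    relative_expression_i = evidence_i / sum_j evidence_j

This equivalence (reads ~ median depth) is an explicit modelling
assumption, recorded in every table.  Only filter-passing events enter the
table; the aberrant:canonical ratio is reported alongside the normalised
fraction because published per-sample percentages can follow either
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .junctions import SpliceEventCall
from .retention import IRCall


@dataclass
class VariantEntry:
    label: str
    evidence_units: float  # junction reads, or median intron depth
    evidence_basis: str  # "junction_count" | "median_intron_depth"
    relative_expression: float
    aberrant_to_canonical_ratio: Optional[float] = None


@dataclass
class VariantExpressionTable:
    sample_id: str
    entries: list[VariantEntry] = field(default_factory=list)

    def as_rows(self) -> list[dict]:
        return [dict(e.__dict__) for e in self.entries]

    @property
    def canonical_fraction(self) -> float:
        return next(
            e.relative_expression for e in self.entries if e.label == "canonical"
        )

    def fraction_of(self, label: str) -> float:
        for e in self.entries:
            if e.label == label:
                return e.relative_expression
        raise KeyError(label)


def estimate_relative_expression(
    canonical_junction_reads: float,
    events: list[SpliceEventCall],
    ir_calls: list[IRCall],
    sample_id: str = "sample",
) -> VariantExpressionTable:
    """Normalise per-variant evidence into relative expression fractions.

    ``canonical_junction_reads`` is the read count on the canonical
    junction(s) of the affected intron(s) -- the mean when two introns are
    affected.  ``events`` should contain filter-passing junction events and
    ``ir_calls`` called retention events only.
    """
    if canonical_junction_reads < 0:
        raise ValueError("canonical evidence must be >= 0")
    items: list[tuple[str, float, str]] = [
        ("canonical", float(canonical_junction_reads), "junction_count")
    ]
    for ev in events:
        items.append((ev.description, float(ev.supporting_reads), "junction_count"))
    for ir in ir_calls:
        items.append(
            (f"intron retention ({ir.intron_id})", float(ir.median_depth),
             "median_intron_depth")
        )
    total = sum(units for _, units, _ in items)
    if total <= 0:
        raise ValueError("no expression evidence in any variant")

    canonical = float(canonical_junction_reads)
    entries = [
        VariantEntry(
            label=label,
            evidence_units=units,
            evidence_basis=basis,
            relative_expression=units / total,
            aberrant_to_canonical_ratio=(
                None if label == "canonical"
                else (units / canonical if canonical > 0 else float("inf"))
            ),
        )
        for label, units, basis in items
    ]
    # deterministic ordering: decreasing expression, canonical first on ties
    entries.sort(key=lambda e: (-e.relative_expression, e.label != "canonical", e.label))
    return VariantExpressionTable(sample_id=sample_id, entries=entries)
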