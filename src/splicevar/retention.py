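"""Intron-retention quantification.

The IR ratio of an intron is defined here as

    ir_ratio = median_intronic_depth / (median_intronic_depth + canonical_junction_reads)

where depth counts only bases covered by non-gapped alignment segments
(a read splicing across the intron contributes nothing) and the median is
taken over *measurable* bases, i.e. bases not excluded by an optional BED
mask of low-complexity / ambiguously mappable regions.  Retention is
called when ir_ratio exceeds 0.1 (strict) and every measurable base is
covered by at least three reads.  Fully masked introns are nonmeasurable;
for those a coverage-only fallback ignores the mask, reports the median
depth over all intron bases, and applies the same thresholds, with the
method recorded so reports can distinguish the two routes.

Medians over an even number of bases use the lower-median convention, so
reported depths are integers whenever per-base depths are.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pysam

from .junctions import DetectionConfig, _use_read, open_alignments


@dataclass
class IRConfig:
    min_ir_ratio: float = 0.1  # strict: ratio must exceed this
    min_base_depth: int = 3

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class IntronCoverage:
    intron_id: str
    depth: np.ndarray  # per-base depth, length = intron length
    measurable_mask: np.ndarray  # bool, True = eligible
    median_depth: float
    fraction_ge: float  # fraction of measurable bases with depth >= min_base_depth
    nonmeasurable: bool


@dataclass
class IRCall:
    intron_id: str
    ir_ratio: float
    called: bool
    method: str  # "ratio_based" | "coverage_fallback"
    median_depth: float
    fraction_ge: float
    canonical_junction_reads: int


def lower_median(values: np.ndarray) -> float:
    """Median with the lower of the two central values for even counts."""
    if len(values) == 0:
        return 0.0
    return float(np.sort(values)[(len(values) - 1) // 2])


def _read_bed_mask(mask_bed: str, contig: str, start: int, end: int) -> np.ndarray:
    """Boolean array over [start, end): True where the base is masked out."""
    masked = np.zeros(end - start, dtype=bool)
    with open(mask_bed) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if f[0] != contig:
                continue
            m0, m1 = max(int(f[1]), start), min(int(f[2]), end)
            if m1 > m0:
                masked[m0 - start : m1 - start] = True
    return masked


def compute_intron_coverage(
    alignments: str | pysam.AlignmentFile,
    intron: tuple[str, int, int],
    mask_bed: Optional[str] = None,
    config: Optional[DetectionConfig] = None,
    ir_config: Optional[IRConfig] = None,
    intron_id: Optional[str] = None,
) -> IntronCoverage:
    """Per-base depth over an intron from non-gapped alignment segments."""
    config = config or DetectionConfig()
    ir_config = ir_config or IRConfig()
    contig, start, end = intron
    if end <= start:
        raise ValueError(f"empty intron interval {contig}:{start}-{end}")
    af = open_alignments(alignments) if isinstance(alignments, str) else alignments
    depth = np.zeros(end - start, dtype=np.int64)
    for read in af.fetch(contig, start, end):
        if not _use_read(read, config):
            continue
        # aligned (M/=/X) blocks only; N gaps contribute nothing
        for b0, b1 in read.get_blocks():
            lo, hi = max(b0, start), min(b1, end)
            if hi > lo:
                depth[lo - start : hi - start] += 1
    measurable = np.ones(end - start, dtype=bool)
    if mask_bed is not None:
        measurable = ~_read_bed_mask(mask_bed, contig, start, end)
    nonmeasurable = not measurable.any()
    eligible = depth[measurable]
    return IntronCoverage(
        intron_id=intron_id or f"{contig}:{start}-{end}",
        depth=depth,
        measurable_mask=measurable,
        median_depth=lower_median(eligible),
        fraction_ge=float((eligible >= ir_config.min_base_depth).mean()) if len(eligible) else 0.0,
        nonmeasurable=nonmeasurable,
    )


def compute_ir_ratio(
    cov: IntronCoverage,
    canonical_junction_reads: int,
    ir_config: Optional[IRConfig] = None,
) -> IRCall:
    """Ratio-based intron-retention call.

    A zero denominator yields ratio 0 (not called); the ratio threshold is
    a strict inequality, and every measurable base must reach the minimum
    depth.  Nonmeasurable introns are never called by this route -- use
    :func:`fallback_coverage_quant`.
    """
    ir_config = ir_config or IRConfig()
    if canonical_junction_reads < 0:
        raise ValueError("canonical_junction_reads must be >= 0")
    denom = cov.median_depth + canonical_junction_reads
    ratio = cov.median_depth / denom if denom > 0 else 0.0
    called = (
        not cov.nonmeasurable
        and ratio > ir_config.min_ir_ratio
        and cov.fraction_ge == 1.0
    )
    return IRCall(
        intron_id=cov.intron_id,
        ir_ratio=ratio,
        called=called,
        method="ratio_based",
        median_depth=cov.median_depth,
        fraction_ge=cov.fraction_ge,
        canonical_junction_reads=canonical_junction_reads,
    )


def fallback_coverage_quant(
    alignments: str | pysam.AlignmentFile,
    intron: tuple[str, int, int],
    canonical_junction_reads: int,
    config: Optional[DetectionConfig] = None,
    ir_config: Optional[IRConfig] = None,
    intron_id: Optional[str] = None,
) -> IRCall:
    """Coverage-only retention quantification for nonmeasurable introns.

    Ignores any mask, computes the median depth over every intron base, and
    applies the same ratio and per-base depth thresholds.
    """
    ir_config = ir_config or IRConfig()
    cov = compute_intron_coverage(
        alignments, intron, mask_bed=None, config=config,
        ir_config=ir_config, intron_id=intron_id,
    )
    denom = cov.median_depth + canonical_junction_reads
    ratio = cov.median_depth / denom if denom > 0 else 0.0
    called = ratio > ir_config.min_ir_ratio and cov.fraction_ge == 1.0
    return IRCall(
        intron_id=cov.intron_id,
        ir_ratio=ratio,
        called=called,
        method="coverage_fallback",
        median_depth=cov.median_depth,
        fraction_ge=cov.fraction_ge,
        canonical_junction_reads=canonical_junction_reads,
    )
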