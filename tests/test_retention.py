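"""Intron-retention coverage, IR ratio thresholds, and the coverage fallback."""

import numpy as np
import pytest

from conftest import sam_pileup, write_sam
from splicevar.consequence import EventType, SpliceEvent
from splicevar.retention import (
    IRConfig,
    IntronCoverage,
    compute_intron_coverage,
    compute_ir_ratio,
    fallback_coverage_quant,
    lower_median,
)
from splicevar.simulate import SimSpec, SimVariant, simulate_reads


def _intron_g(model, k):
    g = sorted(model.t_interval_to_g(*model.intron_t(k)))
    return (model.contig, g[0], g[1])


def test_empty_intron_coverage(toy_gene, tmp_path):
    m = toy_gene.model
    sam = write_sam(str(tmp_path / "empty.sam"), m.contig,
                    m.genome.contig_length(m.contig), [(0, "50M")])
    cov = compute_intron_coverage(sam, _intron_g(m, 2))
    assert cov.median_depth == 0
    assert cov.fraction_ge == 0.0


def test_median_depth_equals_pileup_recount(toy_gene, sim_dir):
    """106 intron-spanning reads: median equals a by-hand pileup (=106)."""
    m = toy_gene.model
    spec = SimSpec(
        seed=3,
        variants=[SimVariant(SpliceEvent(EventType.INTRON_RETENTION, 2), 1.0)],
        total_informative_reads=106, intron=2,
    )
    sam, truths = simulate_reads(spec, m, f"{sim_dir}/ret106.sam")
    contig, g0, g1 = _intron_g(m, 2)
    cov = compute_intron_coverage(sam, (contig, g0, g1))
    oracle = sam_pileup(sam, g0, g1)
    assert list(cov.depth) == oracle
    assert cov.median_depth == lower_median(np.array(oracle)) == 106
    assert truths[0].expected_median_depth == 106


def test_spliced_reads_contribute_no_intron_depth(toy_gene, sim_dir):
    m = toy_gene.model
    spec = SimSpec(seed=4, variants=[SimVariant(None, 1.0)],
                   total_informative_reads=80, intron=2)
    sam, _ = simulate_reads(spec, m, f"{sim_dir}/canonical_ir.sam")
    cov = compute_intron_coverage(sam, _intron_g(m, 2))
    assert cov.median_depth == 0


def test_fully_masked_intron_is_nonmeasurable(toy_gene, sim_dir, tmp_path):
    m = toy_gene.model
    contig, g0, g1 = _intron_g(m, 2)
    mask = tmp_path / "mask.bed"
    mask.write_text(f"{contig}\t{g0}\t{g1}\n")
    spec = SimSpec(
        seed=5,
        variants=[SimVariant(SpliceEvent(EventType.INTRON_RETENTION, 2), 1.0)],
        total_informative_reads=40, intron=2,
    )
    sam, _ = simulate_reads(spec, m, f"{sim_dir}/ret_masked.sam")
    cov = compute_intron_coverage(sam, (contig, g0, g1), mask_bed=str(mask))
    assert cov.nonmeasurable
    assert not compute_ir_ratio(cov, 0).called
    # the coverage fallback ignores the mask and calls deep uniform retention
    fb = fallback_coverage_quant(sam, (contig, g0, g1), canonical_junction_reads=10)
    assert fb.method == "coverage_fallback"
    assert fb.called and fb.median_depth == 40


def _cov(median, fraction=1.0, n=60):
    depth = np.full(n, median)
    return IntronCoverage("i", depth, np.ones(n, bool), float(median), fraction, False)


@pytest.mark.parametrize(
    "median,junctions,ratio,called",
    [
        (0, 100, 0.0, False),
        (10, 90, 0.10, False),  # strict inequality at the 0.1 threshold
        (30, 70, 0.30, True),
        (0, 0, 0.0, False),  # zero denominator
    ],
)
def test_ir_ratio_thresholds(median, junctions, ratio, called):
    call = compute_ir_ratio(_cov(median), junctions)
    assert call.ir_ratio == pytest.approx(ratio)
    assert call.called is called


def test_min_base_depth_gates_the_call():
    """Ratio above threshold but one measurable base below 3x: not called."""
    call = compute_ir_ratio(_cov(30, fraction=59 / 60), 70)
    assert call.ir_ratio == pytest.approx(0.30)
    assert not call.called


def test_negative_junction_count_rejected():
    with pytest.raises(ValueError):
        compute_ir_ratio(_cov(10), -1)


def test_ir_ratio_monotonicity():
    for j in (0, 10, 100):
        ratios = [compute_ir_ratio(_cov(d), j).ir_ratio for d in range(0, 50, 5)]
        assert ratios == sorted(ratios)
    for d in (1, 10, 40):
        ratios = [compute_ir_ratio(_cov(d), j).ir_ratio for j in range(0, 200, 20)]
        assert ratios == sorted(ratios, reverse=True)


def test_fallback_agrees_with_ratio_method_when_unmasked(toy_gene, sim_dir):
    m = toy_gene.model
    spec = SimSpec(
        seed=6,
        variants=[SimVariant(None, 0.5),
                  SimVariant(SpliceEvent(EventType.INTRON_RETENTION, 2), 0.5)],
        total_informative_reads=120, intron=2,
    )
    sam, _ = simulate_reads(spec, m, f"{sim_dir}/ret_both.sam")
    contig, g0, g1 = _intron_g(m, 2)
    cov = compute_intron_coverage(sam, (contig, g0, g1))
    ratio_call = compute_ir_ratio(cov, 60)
    fb_call = fallback_coverage_quant(sam, (contig, g0, g1), 60)
    assert fb_call.median_depth == ratio_call.median_depth
    assert fb_call.ir_ratio == pytest.approx(ratio_call.ir_ratio)
    assert fb_call.called == ratio_call.called


def test_retention_fraction_recovery(toy_gene, sim_dir):
    """Estimated IR ratio recovers the simulated retention fraction +/-0.05."""
    m = toy_gene.model
    for f in (0.1, 0.3, 0.5):
        for seed in range(3):
            spec = SimSpec(
                seed=100 + seed,
                variants=[SimVariant(None, 1 - f),
                          SimVariant(SpliceEvent(EventType.INTRON_RETENTION, 2), f)],
                total_informative_reads=200, intron=2,
            )
            sam, _ = simulate_reads(spec, m, f"{sim_dir}/rec_{f}_{seed}.sam")
            contig, g0, g1 = _intron_g(m, 2)
            cov = compute_intron_coverage(sam, (contig, g0, g1))
            it = sorted(m.t_interval_to_g(*m.intron_t(2)))
            from splicevar.junctions import extract_junctions

            recs = extract_junctions(sam, (m.contig, m.span_start, m.span_end))
            canonical = sum(
                r.read_count for r in recs if (r.gap_start, r.gap_end) == tuple(it)
            )
            call = compute_ir_ratio(cov, canonical)
            assert call.ir_ratio == pytest.approx(f, abs=0.05)
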