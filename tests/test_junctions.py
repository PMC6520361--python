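"""Junction extraction, event calling, filters, and cryptic-site scanning."""

import pytest

from conftest import sam_gap_counts, write_sam
from splicevar.consequence import EventType, SpliceEvent
from splicevar.junctions import (
    DetectionConfig,
    JunctionRecord,
    annotate_junction,
    detect_events,
    event_junction_t,
    extract_junctions,
    scan_cryptic_sites,
)
from splicevar.mutations import classify_splice_mutation, parse_hgvs_c
from splicevar.simulate import SimSpec, SimVariant, simulate_reads


def _toy_region(gene):
    m = gene.model
    return (m.contig, m.span_start, m.span_end)


def test_no_gapped_reads_yields_empty_list(toy_gene, tmp_path):
    m = toy_gene.model
    sam = write_sam(
        str(tmp_path / "nogap.sam"), m.contig,
        m.genome.contig_length(m.contig),
        [(m.span_start + 5, "100M"), (m.span_start + 40, "100M")],
    )
    assert extract_junctions(sam, _toy_region(toy_gene)) == []


def test_junction_counts_equal_direct_gap_count(toy_gene, sim_dir):
    """Extracted counts match a by-hand CIGAR recount of the SAM text."""
    m = toy_gene.model
    spec = SimSpec(
        seed=7,
        variants=[SimVariant(None, 1.0)],
        total_informative_reads=100,
        intron=1,
    )
    sam, _ = simulate_reads(spec, m, f"{sim_dir}/canon100.sam")
    recs = extract_junctions(sam, _toy_region(toy_gene))
    assert len(recs) == 1
    assert recs[0].read_count == 100
    oracle = sam_gap_counts(sam)
    assert {(r.gap_start, r.gap_end): r.read_count for r in recs} == oracle


def test_canonical_only_sample_has_no_aberrant_junctions(toy_gene, sim_dir):
    m = toy_gene.model
    spec = SimSpec(seed=8, variants=[SimVariant(None, 1.0)],
                   total_informative_reads=200, intron=2)
    sam, _ = simulate_reads(spec, m, f"{sim_dir}/canon_only.sam")
    recs = extract_junctions(sam, _toy_region(toy_gene))
    for r in recs:
        annotate_junction(r, m)
    assert all(r.annotation == "canonical" for r in recs)
    mut = parse_hgvs_c(f"c.{m.exon(2).coding_end_c}+1G>A")
    classify_splice_mutation(mut, m)
    assert detect_events(recs, m, mut) == []


def _junction_for(model, event):
    t0, t1 = event_junction_t(model, event)
    g0, g1 = sorted(model.t_interval_to_g(t0, t1))
    return g0, g1


def _make_records(model, canonical_reads, aberrant_event, aberrant_reads, intron=2):
    it = sorted(model.t_interval_to_g(*model.intron_t(intron)))
    recs = [JunctionRecord(model.contig, it[0], it[1], canonical_reads)]
    if aberrant_event is not None:
        g0, g1 = _junction_for(model, aberrant_event)
        recs.append(JunctionRecord(model.contig, g0, g1, aberrant_reads))
    return recs


@pytest.fixture
def toy_mut(toy_gene):
    m = toy_gene.model
    mut = parse_hgvs_c(f"c.{m.exon(3).coding_start_c}-1G>A")
    classify_splice_mutation(mut, m)
    return mut


def test_low_read_support_fails_filter(toy_gene, toy_mut):
    """An aberrant junction backed by four reads never passes."""
    m = toy_gene.model
    ev = SpliceEvent(EventType.EXON_SKIPPING, 3)
    recs = _make_records(m, 40, ev, 4)
    calls = detect_events(recs, m, toy_mut)
    assert len(calls) == 1 and not calls[0].passes_filters


def test_low_fraction_fails_filter(toy_gene, toy_mut):
    """Six reads out of 200 relevant (3%) fail the >=5% rule."""
    m = toy_gene.model
    ev = SpliceEvent(EventType.EXON_SKIPPING, 3)
    recs = _make_records(m, 194, ev, 6)
    calls = detect_events(recs, m, toy_mut)
    assert calls[0].supporting_reads == 6
    assert calls[0].fraction_of_relevant == pytest.approx(0.03)
    assert not calls[0].passes_filters


def test_passing_call_on_thirty_percent_mixture(toy_gene, sim_dir, toy_mut):
    m = toy_gene.model
    spec = SimSpec(
        seed=9,
        variants=[SimVariant(None, 0.7),
                  SimVariant(SpliceEvent(EventType.EXON_SKIPPING, 3), 0.3)],
        total_informative_reads=300, intron=2,
    )
    sam, _ = simulate_reads(spec, m, f"{sim_dir}/skip30.sam")
    recs = extract_junctions(sam, _toy_region(toy_gene))
    calls = detect_events(recs, m, toy_mut)
    passing = [c for c in calls if c.passes_filters]
    assert len(passing) == 1
    assert passing[0].event == SpliceEvent(EventType.EXON_SKIPPING, 3)


def test_filters_are_monotone(toy_gene, toy_mut):
    """Raising min_reads or min_fraction never increases passing calls."""
    m = toy_gene.model
    recs = _make_records(m, 100, SpliceEvent(EventType.CRYPTIC_ACCEPTOR, 2, 12), 30)
    previous = None
    for min_reads in (1, 5, 20, 40):
        calls = detect_events(recs, m, toy_mut, DetectionConfig(min_reads=min_reads))
        n = sum(c.passes_filters for c in calls)
        assert previous is None or n <= previous
        previous = n
    previous = None
    for min_fraction in (0.01, 0.05, 0.2, 0.5):
        calls = detect_events(
            recs, m, toy_mut, DetectionConfig(min_fraction=min_fraction)
        )
        n = sum(c.passes_filters for c in calls)
        assert previous is None or n <= previous
        previous = n


def test_control_subtraction(toy_gene, toy_mut):
    """Events present at similar fractions in the control never pass."""
    m = toy_gene.model
    ev = SpliceEvent(EventType.CRYPTIC_DONOR, 2, -9)
    case = _make_records(m, 70, ev, 30)
    control = _make_records(m, 75, ev, 25)
    calls = detect_events(case, m, toy_mut, control=control)
    assert calls[0].present_in_control and not calls[0].passes_filters
    # without the control the same evidence passes
    calls = detect_events(_make_records(m, 70, ev, 30), m, toy_mut)
    assert calls[0].passes_filters


def test_cryptic_scan_exon5_and_intron6(tp53_model):
    """Sequence scan finds the engineered acceptors: +21 bp into exon 5
    (AG ending at c.396) and 49 bp upstream of the intron 6 acceptor."""
    exon5 = scan_cryptic_sites(tp53_model, intron=4, side="acceptor", window_bp=30)
    exonic = [c for c in exon5 if c.location == "exonic"]
    assert exonic and exonic[0].distance == 21
    t396 = tp53_model.c_to_t(396)
    assert exonic[0].t_junction == t396 + 1  # junction after the AG at c.395-396

    intron6 = scan_cryptic_sites(tp53_model, intron=6, side="acceptor", window_bp=60)
    assert any(c.distance == -49 for c in intron6)

    assert scan_cryptic_sites(tp53_model, intron=6, side="acceptor", window_bp=0) == []
    # ordering by |distance|
    dists = [abs(c.distance) for c in intron6]
    assert dists == sorted(dists)
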