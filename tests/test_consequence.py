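"""Variant-transcript reconstruction and protein-consequence prediction."""

import pytest

from splicevar.consequence import (
    EventType,
    ProteinClass,
    SpliceEvent,
    annotate_named_isoform,
    predict_consequence,
    reconstruct_variant_transcript,
)
from splicevar.gene_model import GeneModelError
from splicevar.tp53 import COHORT

_STOPS = ("TAA", "TAG", "TGA")


# ------------------------------------------------ independent translation oracle


def _oracle_variant_cds(model, event):
    """Assemble the variant CDS by direct string surgery on the spliced CDS
    and intron sequences -- a separate route from the chain-based
    reconstruction under test."""
    cds = model.cds_sequence()
    k = event.index
    if event.event_type is EventType.EXON_SKIPPING:
        e = model.exon(k)
        return cds[: e.coding_start_c - 1] + cds[e.coding_end_c :]
    end = model.exon(k).coding_end_c
    intron = model.intron_sequence(k)
    if event.event_type is EventType.INTRON_RETENTION:
        return cds[:end] + intron + cds[end:]
    if event.event_type is EventType.CRYPTIC_ACCEPTOR:
        if event.offset < 0:
            return cds[:end] + intron[event.offset:] + cds[end:]
        return cds[:end] + cds[end + event.offset :]
    if event.event_type is EventType.CRYPTIC_DONOR:
        if event.offset < 0:
            return cds[: end + event.offset] + cds[end:]
        return cds[:end] + intron[: event.offset] + cds[end:]
    raise AssertionError(event)


def _oracle_flags(model, event):
    var = _oracle_variant_cds(model, event)
    frame = (len(var) - model.cds_end_c) % 3 != 0
    stop_end = None
    for i in range(0, len(var) - len(var) % 3, 3):
        if var[i : i + 3] in _STOPS:
            stop_end = i + 3
            break
    premature = stop_end is not None and stop_end < len(var)
    return frame, premature, var


# ---------------------------------------------------------------- reconstruction


def test_exon3_skip_removes_22_bases(tp53_model):
    v = reconstruct_variant_transcript(tp53_model, SpliceEvent(EventType.EXON_SKIPPING, 3))
    assert v.cds_offset_change == -22


def test_intron7_retention_inserts_full_intron(tp53_model):
    v = reconstruct_variant_transcript(tp53_model, SpliceEvent(EventType.INTRON_RETENTION, 7))
    assert v.cds_offset_change == tp53_model.intron_length(7) == 130
    # retained intron appears contiguously between exons 7 and 8
    assert v.cds_sequence == _oracle_variant_cds(
        tp53_model, SpliceEvent(EventType.INTRON_RETENTION, 7)
    )


def test_cryptic_acceptor_appends_49_intronic_bases(tp53_model):
    ev = SpliceEvent(EventType.CRYPTIC_ACCEPTOR, 6, -49)
    v = reconstruct_variant_transcript(tp53_model, ev)
    assert v.cds_offset_change == 49
    intron6 = tp53_model.intron_sequence(6)
    start_exon7 = tp53_model.exon(7).coding_start_c
    assert v.cds_sequence[start_exon7 - 1 : start_exon7 - 1 + 49] == intron6[-49:]


def test_terminal_exon_events_rejected(tp53_model):
    with pytest.raises(GeneModelError):
        reconstruct_variant_transcript(tp53_model, SpliceEvent(EventType.EXON_SKIPPING, 11))
    with pytest.raises(GeneModelError):
        reconstruct_variant_transcript(tp53_model, SpliceEvent(EventType.INTRON_RETENTION, 11))


# -------------------------------------------------------- published-cohort truth

#: expected (frame_disturbed, premature_stop, protein_class) per sample/variant;
#: the sample 8 cryptic-acceptor row is the sequence-computed consequence (the
#: 24 removed bases are a multiple of three), flagged as discordant with the
#: published frame annotation for that row
EXPECTED = {
    (1, 0): (True, True, ProteinClass.TRUNCATED),
    (2, 0): (False, False, ProteinClass.INFRAME_LOSS),
    (3, 0): (True, True, ProteinClass.TRUNCATED),
    (4, 0): (False, False, ProteinClass.INFRAME_LOSS),
    (5, 0): (False, True, ProteinClass.TRUNCATED),
    (5, 1): (True, True, ProteinClass.TRUNCATED),
    (6, 0): (False, True, ProteinClass.TRUNCATED),
    (6, 1): (True, True, ProteinClass.TRUNCATED),
    (7, 0): (False, False, ProteinClass.INFRAME_LOSS),
    (8, 0): (True, True, ProteinClass.TRUNCATED),
    (8, 1): (False, False, ProteinClass.INFRAME_LOSS),
    (9, 0): (False, True, ProteinClass.TRUNCATED),
    (10, 0): (False, True, ProteinClass.TRUNCATED),
    (10, 1): (True, True, ProteinClass.TRUNCATED),
    (11, 0): (True, True, ProteinClass.TRUNCATED),
    (11, 1): (True, True, ProteinClass.TRUNCATED),
    (12, 0): (True, True, ProteinClass.TRUNCATED),
    (12, 1): (True, True, ProteinClass.TRUNCATED),
}


@pytest.mark.parametrize("sample_no,variant_i", sorted(EXPECTED))
def test_cohort_variant_consequences(sample_no, variant_i, tp53_model):
    sample = next(s for s in COHORT if s.sample_no == sample_no)
    event = sample.events[variant_i]
    cons = predict_consequence(
        reconstruct_variant_transcript(tp53_model, event), tp53_model
    )
    frame, ptc, cls = EXPECTED[(sample_no, variant_i)]
    assert cons.frame_disturbed is frame
    assert cons.premature_stop is ptc
    assert cons.protein_class is cls


def test_inframe_loss_amino_acid_counts(tp53_model):
    """Cryptic SA 21 bp into exon 5 loses 7 AAs; 24 bp into exon 8 loses 9."""
    c5 = predict_consequence(
        reconstruct_variant_transcript(tp53_model, SpliceEvent(EventType.CRYPTIC_ACCEPTOR, 4, 21)),
        tp53_model,
    )
    assert c5.aa_lost == 7
    c8 = predict_consequence(
        reconstruct_variant_transcript(tp53_model, SpliceEvent(EventType.CRYPTIC_ACCEPTOR, 7, 24)),
        tp53_model,
    )
    assert c8.aa_lost == 9


def test_samples_without_events_are_full_length(tp53_model):
    for sample in COHORT:
        if not sample.events:
            cons = predict_consequence(
                reconstruct_variant_transcript(tp53_model, None), tp53_model
            )
            assert cons.protein_class is ProteinClass.FULL_LENGTH
            assert not cons.frame_disturbed and not cons.premature_stop


# ------------------------------------------------------------ exhaustive oracle


def test_flags_match_translation_oracle_exhaustively(toy_gene, tp53_model):
    """Every single-exon skip and every intron retention of both the toy gene
    and the synthetic reference agrees with the string-surgery oracle."""
    for model in (toy_gene.model, tp53_model):
        numbers = model.exon_numbers
        events = [SpliceEvent(EventType.EXON_SKIPPING, k) for k in numbers[1:-1]]
        events += [SpliceEvent(EventType.INTRON_RETENTION, k) for k in numbers[:-1]]
        for ev in events:
            cons = predict_consequence(
                reconstruct_variant_transcript(model, ev), model
            )
            frame, ptc, var = _oracle_flags(model, ev)
            assert cons.frame_disturbed is frame, ev
            assert cons.premature_stop is ptc, ev
            assert reconstruct_variant_transcript(model, ev).cds_sequence == var


def test_inframe_skip_without_stop_is_inframe_loss(toy_gene):
    """Toy exons are 150 bp (a multiple of 3): skipping never shifts frame."""
    m = toy_gene.model
    cons = predict_consequence(
        reconstruct_variant_transcript(m, SpliceEvent(EventType.EXON_SKIPPING, 2)), m
    )
    assert not cons.frame_disturbed
    if not cons.premature_stop:
        assert cons.protein_class is ProteinClass.INFRAME_LOSS
        assert cons.aa_lost == 50


# -------------------------------------------------------------- named isoforms


def test_p53psi_label_requires_exact_event():
    assert annotate_named_isoform(SpliceEvent(EventType.CRYPTIC_ACCEPTOR, 6, -49)) == "p53ψ"
    assert annotate_named_isoform(SpliceEvent(EventType.CRYPTIC_ACCEPTOR, 7, 24)) is None
    assert annotate_named_isoform(SpliceEvent(EventType.CRYPTIC_ACCEPTOR, 6, -48)) is None
    assert annotate_named_isoform(None) is None


def test_p53psi_is_truncated_with_ptc(tp53_model):
    ev = SpliceEvent(EventType.CRYPTIC_ACCEPTOR, 6, -49)
    cons = predict_consequence(reconstruct_variant_transcript(tp53_model, ev), tp53_model)
    assert annotate_named_isoform(ev) == "p53ψ"
    assert cons.premature_stop and cons.protein_class is ProteinClass.TRUNCATED
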