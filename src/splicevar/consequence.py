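"""Aberrant-transcript reconstruction and protein-consequence prediction.

Given a transcript model and a splice-event descriptor (exon skipping,
intron retention, or use of a cryptic donor/acceptor site), this module
assembles the implied variant mRNA, translates it from the canonical start
codon, and reports whether the reading frame is disturbed, whether a
premature termination codon (PTC) appears, how many canonical amino acids
are lost, and the predicted protein class.

A premature stop codon is any in-frame stop strictly 5' of the canonical
termination codon.  Nonsense-mediated decay is not modelled: predictions
describe the encoded protein assuming the transcript is translated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Optional

from Bio.Seq import Seq

from .gene_model import GeneModelError, TranscriptModel


class EventType(str, Enum):
    EXON_SKIPPING = "exon_skipping"
    INTRON_RETENTION = "intron_retention"
    CRYPTIC_ACCEPTOR = "cryptic_acceptor"
    CRYPTIC_DONOR = "cryptic_donor"


@dataclass(frozen=True)
class SpliceEvent:
    """Declared or detected splice alteration, relative to one transcript.

    ``index`` is the exon number for skipping and the intron number
    (intron *k* follows exon *k*) for retention and cryptic sites.
    ``offset`` applies to cryptic sites only and is measured in transcript
    direction from the canonical junction: for an acceptor, negative values
    move into the intron (``-49`` = 49 bases of intron retained) and
    positive values into the downstream exon (``+21`` = 21 exonic bases
    lost); for a donor, negative values move into the upstream exon and
    positive into the intron.
    """

    event_type: EventType
    index: int
    offset: int = 0

    def describe(self) -> str:
        if self.event_type is EventType.EXON_SKIPPING:
            return f"exon {self.index} skipping"
        if self.event_type is EventType.INTRON_RETENTION:
            return f"intron {self.index} retention"
        side = "SA" if self.event_type is EventType.CRYPTIC_ACCEPTOR else "SD"
        where = "intron" if (
            (self.event_type is EventType.CRYPTIC_ACCEPTOR) == (self.offset < 0)
        ) else "exon"
        return f"cryptic {side} {where} side, {self.offset:+d} bp from intron {self.index} junction"


@dataclass
class VariantTranscript:
    event: Optional[SpliceEvent]
    chain_t: list[tuple[int, int]]  # pre-mRNA blocks, transcript order
    exon_chain: list[tuple[int, int]]  # same blocks, genomic coordinates
    mrna_sequence: Optional[str]
    cds_sequence: Optional[str]
    cds_offset_change: int
    removed_c: Optional[tuple[int, int]] = None  # canonical coding bases lost


class ProteinClass(str, Enum):
    FULL_LENGTH = "full_length"
    TRUNCATED = "truncated"
    INFRAME_LOSS = "inframe_loss"
    FRAMESHIFT_NO_PTC = "frameshift_no_ptc"


@dataclass
class ProteinConsequence:
    frame_disturbed: bool
    premature_stop: bool
    aa_lost: int
    protein_class: ProteinClass
    ptc_position: Optional[int] = None  # 1-based codon index of the PTC
    named_isoform: Optional[str] = None


# ----------------------------------------------------------- reconstruction


def reconstruct_variant_transcript(
    model: TranscriptModel, event: Optional[SpliceEvent]
) -> VariantTranscript:
    """Assemble the exon chain and mRNA implied by one splice event.

    With ``event=None`` the canonical transcript is returned.
    """
    chain = [[e.t0, e.t1] for e in model.exons]
    removed_c: Optional[tuple[int, int]] = None

    if event is not None:
        if event.event_type is EventType.EXON_SKIPPING:
            exon = model.exon(event.index)
            i = model.exons.index(exon)
            if i == 0 or i == len(model.exons) - 1:
                raise GeneModelError("cannot skip the first or last exon")
            removed_c = (exon.coding_start_c, exon.coding_end_c)
            del chain[i]
        elif event.event_type is EventType.INTRON_RETENTION:
            i = model.exons.index(model.exon(event.index))
            if i == len(model.exons) - 1:
                raise GeneModelError(f"no intron {event.index} on this transcript")
            chain[i][1] = chain[i + 1][1]
            del chain[i + 1]
        elif event.event_type is EventType.CRYPTIC_ACCEPTOR:
            i = model.exons.index(model.exon(event.index))
            if i == len(model.exons) - 1:
                raise GeneModelError(f"no intron {event.index} on this transcript")
            nxt = model.exons[i + 1]
            _check_shift(event.offset, model.intron_length(event.index), nxt.length)
            chain[i + 1][0] += event.offset
            if event.offset > 0:
                removed_c = (nxt.coding_start_c, nxt.coding_start_c + event.offset - 1)
        elif event.event_type is EventType.CRYPTIC_DONOR:
            exon = model.exon(event.index)
            i = model.exons.index(exon)
            if i == len(model.exons) - 1:
                raise GeneModelError(f"no intron {event.index} on this transcript")
            _check_shift(event.offset, exon.length, model.intron_length(event.index))
            chain[i][1] += event.offset
            if event.offset < 0:
                removed_c = (exon.coding_end_c + event.offset + 1, exon.coding_end_c)
        else:  # pragma: no cover
            raise ValueError(f"unknown event type {event.event_type}")

    chain_t = [(a, b) for a, b in chain]
    exon_chain = [model.t_interval_to_g(a, b) for a, b in chain_t]
    length = sum(b - a for a, b in chain_t)
    change = length - sum(e.length for e in model.exons)

    mrna = cds = None
    if model.genome is not None:
        mrna = "".join(model.premrna_slice(a, b) for a, b in chain_t)
        cds = _cds_of_chain(model, chain_t, mrna)

    return VariantTranscript(
        event=event,
        chain_t=chain_t,
        exon_chain=exon_chain,
        mrna_sequence=mrna,
        cds_sequence=cds,
        cds_offset_change=change,
        removed_c=removed_c,
    )


def _check_shift(offset: int, upstream_room: int, downstream_room: int) -> None:
    if offset == 0:
        raise GeneModelError("cryptic-site offset must be non-zero")
    if offset < 0 and -offset >= upstream_room:
        raise GeneModelError(f"cryptic offset {offset} exceeds available {upstream_room} bases")
    if offset > 0 and offset >= downstream_room:
        raise GeneModelError(f"cryptic offset {offset} exceeds available {downstream_room} bases")


def _cds_of_chain(model: TranscriptModel, chain_t: list[tuple[int, int]], mrna: str) -> str:
    """Variant coding sequence: assembled mRNA from the canonical start codon."""
    t_start = model.c_to_t(1)
    consumed = 0
    for a, b in chain_t:
        if a <= t_start < b:
            return mrna[consumed + (t_start - a):]
        consumed += b - a
    raise GeneModelError("canonical start codon removed by the event")


# ----------------------------------------------------------------- prediction

STOP_CODONS = ("TAA", "TAG", "TGA")


def translate_until_stop(cds: str) -> tuple[str, Optional[int]]:
    """Translate codon-by-codon; return (peptide, 1-based stop codon index).

    The trailing partial codon of a frameshifted sequence is ignored.
    ``None`` stop index means no stop codon was encountered.
    """
    peptide = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if codon in STOP_CODONS:
            return "".join(peptide), i // 3 + 1
        peptide.append(str(Seq(codon).translate()))
    return "".join(peptide), None


def predict_consequence(
    variant: VariantTranscript, model: TranscriptModel
) -> ProteinConsequence:
    """Predict the protein-level consequence of a reconstructed variant."""
    if variant.event is None:
        return ProteinConsequence(False, False, 0, ProteinClass.FULL_LENGTH)

    frame_disturbed = variant.cds_offset_change % 3 != 0

    aa_lost = 0
    if variant.removed_c is not None:
        a, b = variant.removed_c
        aa_lost = (b - 1) // 3 - (a - 1) // 3 + 1

    if variant.cds_sequence is None:
        raise GeneModelError(
            "premature-stop evaluation requires genomic sequence on the model"
        )
    cds = variant.cds_sequence
    _, stop_idx = translate_until_stop(cds)
    premature = stop_idx is not None and 3 * stop_idx < len(cds)

    if premature:
        protein_class = ProteinClass.TRUNCATED
    elif frame_disturbed:
        protein_class = ProteinClass.FRAMESHIFT_NO_PTC
    elif aa_lost > 0:
        protein_class = ProteinClass.INFRAME_LOSS
    else:
        protein_class = ProteinClass.FULL_LENGTH

    return ProteinConsequence(
        frame_disturbed=frame_disturbed,
        premature_stop=premature,
        aa_lost=aa_lost,
        protein_class=protein_class,
        ptc_position=stop_idx if premature else None,
    )


# ------------------------------------------------------------ named isoforms


@dataclass(frozen=True)
class NamedIsoform:
    label: str
    event_type: EventType
    index: int
    offset: int = 0


def load_isoform_catalog(path: Optional[str] = None) -> list[NamedIsoform]:
    """Load a named-isoform catalog (JSON); defaults to the packaged one.

    The packaged catalog carries the p53ψ entry: a cryptic acceptor 49 bp
    upstream of the canonical intron 6 acceptor of TP53.
    """
    if path is None:
        text = resources.files("splicevar").joinpath("data/named_isoforms.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    entries = json.loads(text)
    return [
        NamedIsoform(
            label=e["label"],
            event_type=EventType(e["event_type"]),
            index=int(e["index"]),
            offset=int(e.get("offset", 0)),
        )
        for e in entries
    ]


def annotate_named_isoform(
    event: Optional[SpliceEvent],
    catalog: Optional[list[NamedIsoform]] = None,
) -> Optional[str]:
    """Return the catalog label for an exactly matching event, else None."""
    if event is None:
        return None
    if catalog is None:
        catalog = load_isoform_catalog()
    for iso in catalog:
        if (
            iso.event_type == event.event_type
            and iso.index == event.index
            and iso.offset == event.offset
        ):
            return iso.label
    return None
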