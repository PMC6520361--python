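"""Splice-junction extraction and aberrant-event calling from aligned reads.

A *junction read* is an aligned read whose CIGAR contains an N (skipped
reference) operation; each N operation is one observation of a splice
junction.  Junctions are annotated against the transcript model as
canonical, exon skipping (both ends canonical but non-adjacent), or cryptic
donor/acceptor (one end canonical).  Aberrant events are kept when they are
supported by at least ``min_reads`` reads, account for at least
``min_fraction`` of all junction reads around the mutated intron, and are
not present in an optional control sample at the same thresholds.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass
from typing import Optional

import pysam

from .consequence import EventType, SpliceEvent
from .gene_model import TranscriptModel
from .mutations import SpliceMutation


@dataclass
class DetectionConfig:
    """Evidence thresholds for aberrant-variant calling.

    ``min_reads``/``min_fraction`` implement the >=5-read and >=5%-of-
    relevant-reads filters; ``search_window_bp`` bounds how far from the
    mutated intron junction ends are considered relevant.
    """

    min_reads: int = 5
    min_fraction: float = 0.05
    search_window_bp: int = 500
    min_mapping_quality: int = 1
    count_duplicates: bool = False

    def __post_init__(self):
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if not 0 < self.min_fraction < 1:
            raise ValueError("min_fraction must be in (0, 1)")

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class JunctionRecord:
    contig: str
    gap_start: int  # genomic, 0-based: first skipped reference base
    gap_end: int  # genomic, 0-based half-open
    read_count: int
    annotation: str = "unannotated"
    event: Optional[SpliceEvent] = None

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.contig, self.gap_start, self.gap_end)


@dataclass
class SpliceEventCall:
    event: SpliceEvent
    junction: JunctionRecord
    supporting_reads: int
    fraction_of_relevant: float
    passes_filters: bool
    present_in_control: bool
    description: str


class AlignmentInputError(ValueError):
    pass


# ------------------------------------------------------------------ file I/O


def open_alignments(path: str) -> pysam.AlignmentFile:
    """Open SAM/BAM with random access; plain SAM is converted on the fly.

    Region queries need a coordinate-sorted, indexed BAM; text SAM input is
    sorted and indexed into a temporary BAM first.
    """
    if not os.path.exists(path):
        raise AlignmentInputError(f"alignment file not found: {path}")
    if path.endswith(".sam"):
        tmpdir = tempfile.mkdtemp(prefix="splicevar_")
        bam = os.path.join(tmpdir, os.path.basename(path)[:-4] + ".bam")
        pysam.sort("-o", bam, path)
        pysam.index(bam)
        return pysam.AlignmentFile(bam, "rb")
    af = pysam.AlignmentFile(path, "rb")
    if not af.has_index():
        try:
            pysam.index(path)
            af = pysam.AlignmentFile(path, "rb")
        except Exception as exc:  # unsorted input
            raise AlignmentInputError(
                f"{path}: no index and indexing failed ({exc}); "
                "provide coordinate-sorted input"
            ) from exc
    return af


def _use_read(read: pysam.AlignedSegment, config: DetectionConfig) -> bool:
    if read.is_unmapped or read.is_secondary or read.is_supplementary:
        return False
    if read.is_duplicate and not config.count_duplicates:
        return False
    return read.mapping_quality >= config.min_mapping_quality


# --------------------------------------------------------------- extraction


def extract_junctions(
    alignments: str | pysam.AlignmentFile,
    region: tuple[str, int, int],
    config: Optional[DetectionConfig] = None,
) -> list[JunctionRecord]:
    """Count distinct gap (CIGAR N) operations among reads overlapping region.

    A read spanning two junctions contributes one count to each (arc-count
    semantics).
    """
    config = config or DetectionConfig()
    contig, start, end = region
    if end <= start:
        raise AlignmentInputError(f"empty region {contig}:{start}-{end}")
    af = open_alignments(alignments) if isinstance(alignments, str) else alignments
    if contig not in af.references:
        raise AlignmentInputError(f"contig {contig!r} not in alignment header")
    counts: dict[tuple[int, int], int] = {}
    for read in af.fetch(contig, start, end):
        if not _use_read(read, config):
            continue
        pos = read.reference_start
        for op, length in read.cigartuples or []:
            if op in (0, 7, 8, 2):  # M, =, X, D consume reference
                pos += length
            elif op == 3:  # N: splice gap
                counts[(pos, pos + length)] = counts.get((pos, pos + length), 0) + 1
                pos += length
    return [
        JunctionRecord(contig, g0, g1, n)
        for (g0, g1), n in sorted(counts.items())
    ]


# --------------------------------------------------------------- annotation


def annotate_junction(rec: JunctionRecord, model: TranscriptModel) -> JunctionRecord:
    """Label a junction against the model's canonical introns (in place)."""
    try:
        t0, t1 = model.g_interval_to_t(rec.gap_start, rec.gap_end)
    except Exception:
        rec.annotation = "unrelated"
        return rec
    donors = {}  # t of first intronic base -> intron number
    acceptors = {}  # t one past last intronic base -> intron number
    for k in model.intron_numbers():
        it0, it1 = model.intron_t(k)
        donors[it0] = k
        acceptors[it1] = k
    if t0 in donors and t1 in acceptors:
        kd, ka = donors[t0], acceptors[t1]
        if kd == ka:
            rec.annotation = "canonical"
            rec.event = None
        else:
            # exons strictly between the two canonical junction ends are skipped
            skipped = [e.index for e in model.exons if t0 < e.t0 and e.t1 < t1]
            rec.annotation = "exon_skipping"
            rec.event = SpliceEvent(EventType.EXON_SKIPPING, skipped[0])
    elif t0 in donors:
        k = donors[t0]
        it0, it1 = model.intron_t(k)
        rec.annotation = "cryptic_acceptor"
        rec.event = SpliceEvent(EventType.CRYPTIC_ACCEPTOR, k, t1 - it1)
    elif t1 in acceptors:
        k = acceptors[t1]
        it0, it1 = model.intron_t(k)
        rec.annotation = "cryptic_donor"
        rec.event = SpliceEvent(EventType.CRYPTIC_DONOR, k, t0 - it0)
    else:
        rec.annotation = "unrelated"
    return rec


def mutated_intron(mut: SpliceMutation, model: TranscriptModel) -> int:
    """Intron affected by a classified splice mutation (intron k follows exon k)."""
    if mut.side is None or mut.adjacent_exon is None:
        from .mutations import classify_splice_mutation

        classify_splice_mutation(mut, model)
    if mut.side == "donor":
        return mut.adjacent_exon
    prev = [e.index for e in model.exons if e.index < mut.adjacent_exon]
    if not prev:
        raise ValueError(f"no intron precedes exon {mut.adjacent_exon}")
    return prev[-1]


# ----------------------------------------------------------------- detection


def detect_events(
    junctions: list[JunctionRecord],
    model: TranscriptModel,
    mut: SpliceMutation,
    config: Optional[DetectionConfig] = None,
    control: Optional[list[JunctionRecord]] = None,
) -> list[SpliceEventCall]:
    """Call aberrant splice events around the mutated intron.

    The >=5% denominator counts all junction reads -- canonical included --
    with either splice end inside the mutated intron's search window.
    """
    config = config or DetectionConfig()
    k = mutated_intron(mut, model)
    it0, it1 = model.intron_t(k)
    w = config.search_window_bp
    lo, hi = it0 - w, it1 + w

    def in_window(rec: JunctionRecord) -> bool:
        try:
            t0, t1 = model.g_interval_to_t(rec.gap_start, rec.gap_end)
        except Exception:
            return False
        return lo <= t0 <= hi or lo <= t1 <= hi

    for rec in junctions:
        if rec.annotation == "unannotated":
            annotate_junction(rec, model)
    relevant = [rec for rec in junctions if in_window(rec)]
    denom = sum(rec.read_count for rec in relevant)

    control_passing: set[tuple[str, int, int]] = set()
    if control:
        for rec in control:
            if rec.annotation == "unannotated":
                annotate_junction(rec, model)
        c_relevant = [rec for rec in control if in_window(rec)]
        c_denom = sum(rec.read_count for rec in c_relevant)
        for rec in c_relevant:
            if rec.annotation in ("exon_skipping", "cryptic_acceptor", "cryptic_donor"):
                frac = rec.read_count / c_denom if c_denom else 0.0
                if rec.read_count >= config.min_reads and frac >= config.min_fraction:
                    control_passing.add(rec.key)

    calls = []
    for rec in relevant:
        if rec.annotation not in ("exon_skipping", "cryptic_acceptor", "cryptic_donor"):
            continue
        frac = rec.read_count / denom if denom else 0.0
        in_ctrl = rec.key in control_passing
        passes = (
            rec.read_count >= config.min_reads
            and frac >= config.min_fraction
            and not in_ctrl
        )
        calls.append(
            SpliceEventCall(
                event=rec.event,
                junction=rec,
                supporting_reads=rec.read_count,
                fraction_of_relevant=frac,
                passes_filters=passes,
                present_in_control=in_ctrl,
                description=rec.event.describe(),
            )
        )
    calls.sort(key=lambda c: -c.supporting_reads)
    return calls


# -------------------------------------------------------- junction geometry


def event_junction_t(model: TranscriptModel, event: SpliceEvent) -> tuple[int, int]:
    """Pre-mRNA gap ``[t0, t1)`` spliced out by an event's junction."""
    if event.event_type is EventType.EXON_SKIPPING:
        exon = model.exon(event.index)
        i = model.exons.index(exon)
        if i == 0 or i == len(model.exons) - 1:
            raise ValueError("cannot skip a terminal exon")
        return model.exons[i - 1].t1, model.exons[i + 1].t0
    it0, it1 = model.intron_t(event.index)
    if event.event_type is EventType.INTRON_RETENTION:
        return it0, it1  # the junction *lost*; retention reads have no gap
    if event.event_type is EventType.CRYPTIC_ACCEPTOR:
        return it0, it1 + event.offset
    if event.event_type is EventType.CRYPTIC_DONOR:
        return it0 + event.offset, it1
    raise ValueError(event.event_type)


def canonical_junction_t(model: TranscriptModel, intron: int) -> tuple[int, int]:
    return model.intron_t(intron)


# ------------------------------------------------------------- cryptic scan


@dataclass
class CrypticSiteCandidate:
    side: str  # "donor" | "acceptor"
    distance: int  # signed bases from the canonical junction, transcript dir
    location: str  # "intronic" | "exonic"
    t_junction: int  # pre-mRNA junction position the site would create
    genomic: int  # genomic coordinate of the junction's exon-side base
    dinucleotide: str = ""


def scan_cryptic_sites(
    model: TranscriptModel,
    intron: int,
    side: str,
    window_bp: int,
) -> list[CrypticSiteCandidate]:
    """Enumerate candidate GT (donor) / AG (acceptor) sites near a junction.

    For the acceptor side, distance < 0 means the AG lies inside the intron
    (upstream of the canonical acceptor, more intron retained); distance > 0
    means it lies inside the downstream exon (exonic bases lost).  For the
    donor side, distance < 0 is exonic and distance > 0 intronic.  Candidates
    are ordered by increasing |distance|.
    """
    if model.genome is None:
        raise ValueError("cryptic-site scanning requires genomic sequence")
    if side not in ("donor", "acceptor"):
        raise ValueError(f"side must be 'donor' or 'acceptor', got {side!r}")
    if window_bp <= 0:
        return []
    seq = model.premrna_sequence()
    it0, it1 = model.intron_t(intron)
    out = []
    if side == "acceptor":
        canonical = it1  # t of the first base of the downstream exon
        for j in range(max(it0 + 3, canonical - window_bp), min(len(seq), canonical + window_bp + 1)):
            if j == canonical or j < 2:
                continue
            if seq[j - 2 : j] == "AG":
                d = j - canonical
                out.append(
                    CrypticSiteCandidate(
                        side="acceptor",
                        distance=d,
                        location="intronic" if d < 0 else "exonic",
                        t_junction=j,
                        genomic=model.t_to_g(j),
                        dinucleotide="AG",
                    )
                )
    else:
        canonical = it0  # t of the first intronic base
        for j in range(max(2, canonical - window_bp), min(len(seq) - 1, it1 - 3, canonical + window_bp + 1)):
            if j == canonical:
                continue
            if seq[j : j + 2] == "GT":
                d = j - canonical
                out.append(
                    CrypticSiteCandidate(
                        side="donor",
                        distance=d,
                        location="exonic" if d < 0 else "intronic",
                        t_junction=j,
                        genomic=model.t_to_g(j - 1),
                        dinucleotide="GT",
                    )
                )
    out.sort(key=lambda c: (abs(c.distance), c.distance))
    return out
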