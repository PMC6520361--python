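"""Gene/transcript models and coordinate conversion.

Loads a single transcript (exon + CDS features) from GTF/GFF3 plus a genomic
FASTA and exposes conversions between three coordinate systems:

* **genomic** -- 0-based, half-open, on the annotated contig;
* **pre-mRNA** (``t``) -- 0-based along the unspliced transcript in
  transcript orientation (position 0 is the first base of the first exon,
  regardless of genomic strand);
* **CDS / HGVS c.** -- 1-based over the spliced coding sequence, with
  intronic positions written as ``c.X+n`` (after a donor) or ``c.X-n``
  (before an acceptor).

Minus-strand genes are converted to transcript orientation once, at load
time; every downstream operation works in pre-mRNA space and converts back
to genomic coordinates only at the alignment-file boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import gffutils
import pyfaidx


class CoordinateError(ValueError):
    """A coordinate falls outside the region where a conversion is defined."""


class GeneModelError(ValueError):
    """The annotation is missing or internally inconsistent."""


COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class GenomeSequence:
    """Bounds-checked random access to a genomic FASTA (via pyfaidx)."""

    def __init__(self, fasta_path: str):
        self._fasta = pyfaidx.Fasta(fasta_path, as_raw=True, sequence_always_upper=True)

    def contig_length(self, contig: str) -> int:
        if contig not in self._fasta:
            raise CoordinateError(f"unknown contig {contig!r}")
        return len(self._fasta[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return bases of ``[start, end)`` (0-based) on the forward strand."""
        n = self.contig_length(contig)
        if not (0 <= start <= end <= n):
            raise CoordinateError(
                f"interval [{start}, {end}) outside contig {contig!r} of length {n}"
            )
        return str(self._fasta[contig][start:end])

    def fetch_rc(self, contig: str, start: int, end: int) -> str:
        """Return the reverse complement of ``[start, end)``."""
        return reverse_complement(self.fetch(contig, start, end))


@dataclass
class ExonInterval:
    """One exon in transcript order.

    ``start``/``end`` are genomic (0-based, half-open); ``coding_start_c`` /
    ``coding_end_c`` give the 1-based inclusive CDS span covered by the exon
    (``None`` for fully noncoding exons).  ``cds_start``/``cds_end`` bound
    the genomic CDS portion of the exon.
    """

    index: int
    start: int
    end: int
    coding_start_c: Optional[int] = None
    coding_end_c: Optional[int] = None
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    # pre-mRNA span, filled by TranscriptModel
    t0: int = field(default=0, repr=False)
    t1: int = field(default=0, repr=False)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_coding(self) -> bool:
        return self.coding_start_c is not None


class TranscriptModel:
    """A single transcript: ordered exons, CDS bounds and sequence access."""

    def __init__(
        self,
        transcript_id: str,
        contig: str,
        strand: str,
        exons: list[ExonInterval],
        genome: Optional[GenomeSequence] = None,
    ):
        if strand not in "+-":
            raise GeneModelError(f"strand must be '+' or '-', got {strand!r}")
        self.transcript_id = transcript_id
        self.contig = contig
        self.strand = strand
        self.genome = genome
        # order exons in transcript direction
        self.exons = sorted(exons, key=lambda e: e.start, reverse=(strand == "-"))
        self._index_premrna()
        self._by_number = {e.index: e for e in self.exons}
        self.validate()

    # ------------------------------------------------------------------ setup

    def _index_premrna(self) -> None:
        self.span_start = min(e.start for e in self.exons)
        self.span_end = max(e.end for e in self.exons)
        t = self.g_to_t(self.exons[0].start if self.strand == "+" else self.exons[0].end - 1)
        assert t == 0
        for e in self.exons:
            g_first = e.start if self.strand == "+" else e.end - 1
            e.t0 = self.g_to_t(g_first)
            e.t1 = e.t0 + e.length

    def validate(self) -> None:
        exons = self.exons
        for e in exons:
            if e.end <= e.start:
                raise GeneModelError(f"exon {e.index}: end <= start")
        for a, b in zip(exons, exons[1:]):
            if b.t0 <= a.t1:
                raise GeneModelError(
                    f"exons {a.index}/{b.index} overlap or are out of transcript order"
                )
        coding = self.coding_exons
        if coding:
            expect = 1
            for e in coding:
                if e.coding_start_c != expect:
                    raise GeneModelError(
                        f"CDS spans not contiguous at exon {e.index}: "
                        f"expected c.{expect}, got c.{e.coding_start_c}"
                    )
                expect = e.coding_end_c + 1
            if self.cds_end_c % 3 != 0:
                raise GeneModelError(f"CDS length {self.cds_end_c} not a multiple of 3")
            if self.genome is not None:
                cds = self.cds_sequence()
                if cds[:3] != "ATG":
                    raise GeneModelError("spliced CDS does not begin with ATG")
                if cds[-3:] not in ("TAA", "TAG", "TGA"):
                    raise GeneModelError("spliced CDS does not end with a stop codon")

    # -------------------------------------------------------------- properties

    @property
    def coding_exons(self) -> list[ExonInterval]:
        return [e for e in self.exons if e.is_coding]

    @property
    def cds_start_c(self) -> int:
        return 1

    @property
    def cds_end_c(self) -> int:
        return self.coding_exons[-1].coding_end_c

    @property
    def premrna_length(self) -> int:
        return self.span_end - self.span_start

    def exon(self, number: int) -> ExonInterval:
        try:
            return self._by_number[number]
        except KeyError:
            raise GeneModelError(f"no exon numbered {number} on {self.transcript_id}")

    @property
    def exon_numbers(self) -> list[int]:
        return [e.index for e in self.exons]

    # ------------------------------------------- pre-mRNA <-> genomic mapping

    def t_to_g(self, t: int) -> int:
        if not 0 <= t < self.premrna_length:
            raise CoordinateError(f"pre-mRNA position {t} outside transcript")
        if self.strand == "+":
            return self.span_start + t
        return self.span_end - 1 - t

    def g_to_t(self, g: int) -> int:
        if not self.span_start <= g < self.span_end:
            raise CoordinateError(
                f"genomic position {g} outside transcript span "
                f"[{self.span_start}, {self.span_end})"
            )
        if self.strand == "+":
            return g - self.span_start
        return self.span_end - 1 - g

    def t_interval_to_g(self, t0: int, t1: int) -> tuple[int, int]:
        """Map pre-mRNA ``[t0, t1)`` to a genomic ``(start, end)`` interval."""
        if self.strand == "+":
            return self.span_start + t0, self.span_start + t1
        return self.span_end - t1, self.span_end - t0

    def g_interval_to_t(self, g0: int, g1: int) -> tuple[int, int]:
        if self.strand == "+":
            return g0 - self.span_start, g1 - self.span_start
        return self.span_end - g1, self.span_end - g0

    # ------------------------------------------------------------------ introns

    def intron_numbers(self) -> list[int]:
        return [e.index for e in self.exons[:-1]]

    def intron_t(self, number: int) -> tuple[int, int]:
        """Pre-mRNA span ``[t0, t1)`` of the intron following exon ``number``."""
        e = self.exon(number)
        i = self.exons.index(e)
        if i == len(self.exons) - 1:
            raise GeneModelError(f"no intron follows the last exon ({number})")
        return e.t1, self.exons[i + 1].t0

    def intron_genomic(self, number: int) -> tuple[int, int]:
        t0, t1 = self.intron_t(number)
        return self.t_interval_to_g(t0, t1)

    def intron_length(self, number: int) -> int:
        t0, t1 = self.intron_t(number)
        return t1 - t0

    # ------------------------------------------------------- c. <-> genomic

    def _exon_cds_t0(self, e: ExonInterval) -> int:
        """Pre-mRNA position of the exon's first coding base."""
        if self.strand == "+":
            return e.t0 + (e.cds_start - e.start)
        return e.t0 + (e.end - e.cds_end)

    def c_to_t(self, pos: int, offset: int = 0) -> int:
        """Resolve HGVS ``c.pos(+/-offset)`` to a pre-mRNA coordinate."""
        if not 1 <= pos <= self.cds_end_c:
            raise CoordinateError(f"c.{pos} beyond CDS end c.{self.cds_end_c}")
        hit = None
        for e in self.coding_exons:
            if e.coding_start_c <= pos <= e.coding_end_c:
                hit = e
                break
        assert hit is not None
        if offset == 0:
            return self._exon_cds_t0(hit) + (pos - hit.coding_start_c)
        if offset > 0:
            if pos != hit.coding_end_c:
                raise CoordinateError(f"c.{pos}+{offset}: c.{pos} is not an exon 3' end")
            n = self.intron_length(hit.index)
            if offset > n:
                raise CoordinateError(f"donor offset +{offset} exceeds intron length {n}")
            return hit.t1 + offset - 1
        # offset < 0
        if pos != hit.coding_start_c:
            raise CoordinateError(f"c.{pos}{offset}: c.{pos} is not an exon 5' start")
        i = self.exons.index(hit)
        if i == 0:
            raise CoordinateError(f"no intron precedes exon {hit.index}")
        n = self.intron_length(self.exons[i - 1].index)
        if -offset > n:
            raise CoordinateError(f"acceptor offset {offset} exceeds intron length {n}")
        return hit.t0 + offset

    def c_to_genomic(self, pos: int, offset: int = 0) -> int:
        return self.t_to_g(self.c_to_t(pos, offset))

    def t_to_c(self, t: int) -> tuple[int, int]:
        """Inverse of :meth:`c_to_t`; returns ``(c_position, offset)``."""
        for i, e in enumerate(self.exons):
            if e.t0 <= t < e.t1:
                if not e.is_coding:
                    raise CoordinateError(f"position in noncoding exon {e.index}")
                d = t - self._exon_cds_t0(e)
                if not 0 <= d <= e.coding_end_c - e.coding_start_c:
                    raise CoordinateError(f"position in untranslated part of exon {e.index}")
                return e.coding_start_c + d, 0
            if i + 1 < len(self.exons) and e.t1 <= t < self.exons[i + 1].t0:
                nxt = self.exons[i + 1]
                d_donor = t - e.t1 + 1
                d_acceptor = nxt.t0 - t
                if d_donor <= d_acceptor:
                    return e.coding_end_c, d_donor
                return nxt.coding_start_c, -d_acceptor
        raise CoordinateError(f"pre-mRNA position {t} outside transcript")

    def genomic_to_c(self, g: int) -> tuple[int, int]:
        return self.t_to_c(self.g_to_t(g))

    # ---------------------------------------------------------------- sequence

    def _require_genome(self) -> GenomeSequence:
        if self.genome is None:
            raise GeneModelError("no genomic sequence loaded for this transcript")
        return self.genome

    def premrna_sequence(self) -> str:
        genome = self._require_genome()
        if self.strand == "+":
            return genome.fetch(self.contig, self.span_start, self.span_end)
        return genome.fetch_rc(self.contig, self.span_start, self.span_end)

    def premrna_slice(self, t0: int, t1: int) -> str:
        g0, g1 = self.t_interval_to_g(t0, t1)
        genome = self._require_genome()
        if self.strand == "+":
            return genome.fetch(self.contig, g0, g1)
        return genome.fetch_rc(self.contig, g0, g1)

    def cds_sequence(self) -> str:
        parts = []
        for e in self.coding_exons:
            t0 = self._exon_cds_t0(e)
            parts.append(self.premrna_slice(t0, t0 + e.coding_end_c - e.coding_start_c + 1))
        return "".join(parts)

    def intron_sequence(self, number: int) -> str:
        t0, t1 = self.intron_t(number)
        return self.premrna_slice(t0, t1)


# ---------------------------------------------------------------------- loader


def _detect_dialect(path: str) -> str:
    return "gff3" if path.endswith((".gff", ".gff3")) else "gtf"


def load_gene_model(
    annotation_file: str, fasta: str, transcript_id: str
) -> TranscriptModel:
    """Load ``transcript_id`` from a GTF/GFF3 + genomic FASTA pair.

    Exons are numbered from the ``exon_number`` attribute when present, else
    positionally (1-based, transcript direction). CDS features must be
    contained in exons.
    """
    if not os.path.exists(annotation_file):
        raise GeneModelError(f"annotation file not found: {annotation_file}")
    db = gffutils.create_db(
        annotation_file,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    def _tid(feat) -> Optional[str]:
        for key in ("transcript_id", "Parent"):
            if key in feat.attributes:
                val = feat.attributes[key]
                return val[0] if isinstance(val, list) else val
        return None

    exon_feats = [f for f in db.features_of_type("exon") if _tid(f) == transcript_id]
    cds_feats = [f for f in db.features_of_type("CDS") if _tid(f) == transcript_id]
    if not exon_feats:
        raise GeneModelError(f"transcript {transcript_id!r} not found in {annotation_file}")
    strand = exon_feats[0].strand
    contig = exon_feats[0].seqid
    genome = GenomeSequence(fasta)

    # gffutils keeps 1-based inclusive coordinates; convert to 0-based half-open
    exons = []
    for f in sorted(exon_feats, key=lambda f: f.start, reverse=(strand == "-")):
        number = None
        if "exon_number" in f.attributes:
            number = int(f.attributes["exon_number"][0])
        exons.append(ExonInterval(index=number or 0, start=f.start - 1, end=f.end))
    if any(e.index == 0 for e in exons):
        for i, e in enumerate(exons, start=1):
            e.index = i

    # attach CDS sub-intervals to their exons
    cds = sorted(((f.start - 1, f.end) for f in cds_feats), key=lambda iv: iv[0])
    for c0, c1 in cds:
        hit = [e for e in exons if e.start <= c0 and c1 <= e.end]
        if not hit:
            raise GeneModelError(
                f"CDS [{c0}, {c1}) of {transcript_id!r} not contained in any exon"
            )
        e = hit[0]
        if e.cds_start is not None:
            raise GeneModelError(f"multiple CDS features in exon {e.index}")
        e.cds_start, e.cds_end = c0, c1

    # assign c. spans cumulatively in transcript order
    c = 0
    for e in exons:  # already in transcript order
        if e.cds_start is None:
            continue
        n = e.cds_end - e.cds_start
        e.coding_start_c = c + 1
        e.coding_end_c = c + n
        c += n
    if c == 0:
        raise GeneModelError(f"transcript {transcript_id!r} has no CDS features")

    return TranscriptModel(transcript_id, contig, strand, exons, genome)
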