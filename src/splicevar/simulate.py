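"""Synthetic gene models and aligned-read simulation with known truth.

Reads are emitted *pre-aligned* (sorted SAM): junction-spanning reads carry
an N CIGAR operation over the spliced-out interval, intron-retaining reads
align contiguously across the intron, and per-variant read counts follow
the requested mixture proportions exactly (largest-remainder rounding), so
every downstream quantity has a closed-form expectation.  Sequencing-error
and fragment-bias models are deliberately absent: junction counts and
median depths, the quantities measured downstream, do not require them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pysam

from .consequence import EventType, SpliceEvent
from .gene_model import TranscriptModel, load_gene_model, reverse_complement
from .junctions import event_junction_t
from .tp53 import write_cohort_fixture as make_cohort_fixture  # noqa: F401

_STOPS = ("TAA", "TAG", "TGA")
_CODONS = [
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOPS
]


@dataclass
class SimulatedGene:
    model: TranscriptModel
    gtf_path: str
    fasta_path: str


def simulate_gene(
    seed: int,
    n_exons: int = 4,
    exon_lengths: Optional[list[int]] = None,
    intron_lengths: Optional[list[int]] = None,
    outdir: str = ".",
    strand: str = "+",
    contig: str = "toy_contig",
    transcript_id: str = "TOY.1",
) -> SimulatedGene:
    """Generate a toy coding gene and write it as GTF + FASTA.

    Every intron is GT..AG, the CDS is a multiple of three starting ATG and
    ending TAA with no internal in-frame stop, and the construction is
    deterministic given ``seed``.
    """
    if n_exons < 2:
        raise ValueError("need at least two exons")
    exon_lengths = exon_lengths or [150] * n_exons
    intron_lengths = intron_lengths or [60] * (n_exons - 1)
    if len(exon_lengths) != n_exons or len(intron_lengths) != n_exons - 1:
        raise ValueError("exon/intron length lists do not match n_exons")
    if any(l < 6 for l in exon_lengths) or any(l < 8 for l in intron_lengths):
        raise ValueError("infeasible exon/intron lengths")
    cds_len = sum(exon_lengths)
    if cds_len % 3 != 0:
        raise ValueError(f"total CDS length {cds_len} is not a multiple of 3")

    rng = np.random.default_rng(seed)
    codons = ["ATG"] + [
        _CODONS[i] for i in rng.integers(0, len(_CODONS), size=cds_len // 3 - 2)
    ] + ["TAA"]
    cds = "".join(codons)

    introns = []
    for li in intron_lengths:
        body = "".join("ACGT"[i] for i in rng.integers(0, 4, size=li - 4))
        introns.append("GT" + body + "AG")

    premrna, pos = [], 0
    for i, el in enumerate(exon_lengths):
        premrna.append(cds[pos : pos + el])
        pos += el
        if i < n_exons - 1:
            premrna.append(introns[i])
    premrna = "".join(premrna)

    flank = 100
    f5 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=flank))
    f3 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=flank))
    genome = f5 + (premrna if strand == "+" else reverse_complement(premrna)) + f3

    # exon pre-mRNA spans -> 1-based GTF coordinates
    P = len(premrna)
    lines = []
    t = 0
    for i, el in enumerate(exon_lengths):
        t0, t1 = t, t + el
        if strand == "+":
            g1, g2 = flank + t0 + 1, flank + t1
        else:
            g1, g2 = flank + P - t1 + 1, flank + P - t0
        attrs = f'gene_id "TOY"; transcript_id "{transcript_id}"; exon_number "{i + 1}";'
        for feat in ("exon", "CDS"):
            lines.append(f"{contig}\tsplicevar_sim\t{feat}\t{g1}\t{g2}\t.\t{strand}\t.\t{attrs}")
        t = t1 + (intron_lengths[i] if i < n_exons - 1 else 0)

    os.makedirs(outdir, exist_ok=True)
    fasta_path = os.path.join(outdir, f"toy_{seed}_{strand.replace('-', 'm')}.fa")
    gtf_path = os.path.join(outdir, f"toy_{seed}_{strand.replace('-', 'm')}.gtf")
    with open(fasta_path, "w") as fh:
        fh.write(f">{contig}\n")
        for i in range(0, len(genome), 70):
            fh.write(genome[i : i + 70] + "\n")
    with open(gtf_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")

    model = load_gene_model(gtf_path, fasta_path, transcript_id)
    return SimulatedGene(model=model, gtf_path=gtf_path, fasta_path=fasta_path)


# ------------------------------------------------------------------- mixtures


@dataclass
class SimVariant:
    """One mixture component: ``event=None`` is the canonical transcript."""

    event: Optional[SpliceEvent]
    fraction: float

    @property
    def label(self) -> str:
        return "canonical" if self.event is None else self.event.describe()


@dataclass
class TruthRecord:
    label: str
    true_fraction: float
    scheduled_reads: int
    expected_junction: Optional[tuple[int, int]] = None  # genomic gap
    expected_median_depth: Optional[int] = None


@dataclass
class SimSpec:
    seed: int
    variants: list[SimVariant]
    total_informative_reads: int = 300
    read_length: int = 100
    intron: int = 1  # the mutated/affected intron (intron k follows exon k)
    anchor_min: int = 10

    def __post_init__(self):
        total = sum(v.fraction for v in self.variants)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"variant fractions sum to {total}, expected 1")
        if self.total_informative_reads <= 0:
            raise ValueError("zero reads requested")


def _apportion(fractions: list[float], total: int) -> list[int]:
    """Largest-remainder apportionment; deterministic, sums to total."""
    raw = [f * total for f in fractions]
    counts = [int(x) for x in raw]
    order = sorted(range(len(raw)), key=lambda i: (raw[i] - counts[i], -i), reverse=True)
    for i in order[: total - sum(counts)]:
        counts[i] += 1
    return counts


def simulate_reads(
    spec: SimSpec, model: TranscriptModel, out_sam: str
) -> tuple[str, list[TruthRecord]]:
    """Emit a coordinate-sorted SAM realising the requested mixture.

    Canonical and junction-altering variants produce single-gap junction
    reads over the affected intron; intron-retention variants produce
    contiguous reads that each span the entire intron when the read length
    allows (``read_length >= intron + 2*anchor_min``, making the median
    intronic depth equal the scheduled read count exactly), else reads
    placed uniformly inside the intron.  A truth TSV is written next to
    the SAM.
    """
    rng = np.random.default_rng(spec.seed)
    R = spec.read_length
    counts = _apportion([v.fraction for v in spec.variants], spec.total_informative_reads)

    # a canonical transcript covers every junction: emit canonical reads on
    # the mutated intron and on both introns flanking any skipped exon, so
    # per-junction canonical depth matches the mixture proportion
    canonical_introns = {spec.intron}
    for v in spec.variants:
        if v.event is not None and v.event.event_type is EventType.EXON_SKIPPING:
            exon = model.exon(v.event.index)
            i = model.exons.index(exon)
            if i > 0:
                canonical_introns.add(model.exons[i - 1].index)
            if i < len(model.exons) - 1:
                canonical_introns.add(exon.index)
    canonical_introns = sorted(k for k in canonical_introns if k in model.intron_numbers())

    genome = model.genome
    contig_len = genome.contig_length(model.contig)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": model.contig, "LN": contig_len}],
    }

    records: list[tuple[int, pysam.AlignedSegment]] = []
    truths: list[TruthRecord] = []
    hdr = pysam.AlignmentHeader.from_dict(header)
    name_i = 0

    def add_read(blocks_t: list[tuple[int, int]], name: str) -> None:
        g_blocks = sorted(model.t_interval_to_g(a, b) for a, b in blocks_t)
        seg = pysam.AlignedSegment(hdr)
        seg.query_name = name
        seg.reference_id = 0
        seg.reference_start = g_blocks[0][0]
        seg.mapping_quality = 60
        cig = []
        seq = []
        prev_end = None
        for g0, g1 in g_blocks:
            if prev_end is not None:
                cig.append((3, g0 - prev_end))
            cig.append((0, g1 - g0))
            seq.append(genome.fetch(model.contig, g0, g1))
            prev_end = g1
        seg.cigartuples = cig
        seg.query_sequence = "".join(seq)
        seg.flag = 0
        records.append((seg.reference_start, seg))

    for v, n in zip(spec.variants, counts):
        truth = TruthRecord(label=v.label, true_fraction=v.fraction, scheduled_reads=n)
        if v.event is None:
            # one read per canonical junction per scheduled transcript
            gaps = [model.intron_t(j) for j in canonical_introns]
            truth.expected_junction = tuple(sorted(model.t_interval_to_g(*gaps[0])))
            for _ in range(n):
                for t0, t1 in gaps:
                    a = int(rng.integers(spec.anchor_min, R - spec.anchor_min + 1))
                    name_i += 1
                    add_read([(t0 - a, t0), (t1, t1 + (R - a))], f"r{name_i}")
        elif v.event.event_type is not EventType.INTRON_RETENTION:
            t0, t1 = event_junction_t(model, v.event)
            truth.expected_junction = tuple(sorted(model.t_interval_to_g(t0, t1)))
            for _ in range(n):
                a = int(rng.integers(spec.anchor_min, R - spec.anchor_min + 1))
                name_i += 1
                add_read([(t0 - a, t0), (t1, t1 + (R - a))], f"r{name_i}")
        else:
            it0, it1 = model.intron_t(v.event.index)
            li = it1 - it0
            if R >= li + 2 * spec.anchor_min:
                truth.expected_median_depth = n
                for _ in range(n):
                    a = int(rng.integers(spec.anchor_min, R - li - spec.anchor_min + 1))
                    name_i += 1
                    add_read([(it0 - a, it0 - a + R)], f"r{name_i}")
            else:
                if R > li:
                    raise ValueError(
                        "read length must either span the intron with anchors or fit inside it"
                    )
                for _ in range(n):
                    s = int(rng.integers(it0, it1 - R + 1))
                    name_i += 1
                    add_read([(s, s + R)], f"r{name_i}")
        truths.append(truth)

    records.sort(key=lambda x: x[0])
    with pysam.AlignmentFile(out_sam, "wh", header=header) as out:
        for _, seg in records:
            out.write(seg)

    truth_path = out_sam + ".truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("label\ttrue_fraction\tscheduled_reads\texpected_junction\texpected_median_depth\n")
        for t in truths:
            jc = f"{t.expected_junction[0]}-{t.expected_junction[1]}" if t.expected_junction else "."
            md = t.expected_median_depth if t.expected_median_depth is not None else "."
            fh.write(f"{t.label}\t{t.true_fraction}\t{t.scheduled_reads}\t{jc}\t{md}\n")
    return out_sam, truths
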