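"""End-to-end per-sample pipeline and cohort reporting.

``run_sample_pipeline`` goes from aligned reads + gene model + one splice
mutation to a machine-readable report: mutation classification, junction
events (passing and failed, with evidence), the intron-retention call,
relative variant expression, and per-variant protein consequences.  All
thresholds applied are echoed in the report's config snapshot, and reports
are deterministic for fixed inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Union

import yaml

from . import __version__
from .consequence import (
    EventType,
    SpliceEvent,
    annotate_named_isoform,
    load_isoform_catalog,
    predict_consequence,
    reconstruct_variant_transcript,
)
from .gene_model import TranscriptModel, load_gene_model
from .junctions import (
    DetectionConfig,
    JunctionRecord,
    annotate_junction,
    detect_events,
    extract_junctions,
    mutated_intron,
)
from .mutations import classify_splice_mutation, parse_hgvs_c, round_percent, summarize_cohort
from .quantify import estimate_relative_expression
from .retention import IRConfig, compute_intron_coverage, compute_ir_ratio, fallback_coverage_quant


@dataclass
class PipelineConfig:
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    ir: IRConfig = field(default_factory=IRConfig)

    def as_dict(self) -> dict:
        return {"detection": self.detection.as_dict(), "ir": self.ir.as_dict()}

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            detection=DetectionConfig(**raw.get("detection", {})),
            ir=IRConfig(**raw.get("ir", {})),
        )


class PipelineError(RuntimeError):
    """Stage-labelled pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _stage(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc


def canonical_junction_reads(
    junctions: list[JunctionRecord], model: TranscriptModel, intron: int
) -> int:
    it = tuple(sorted(model.t_interval_to_g(*model.intron_t(intron))))
    return sum(
        r.read_count for r in junctions if (r.gap_start, r.gap_end) == it
    )


def run_sample_pipeline(
    bam: str,
    annotation: str,
    fasta: str,
    transcript_id: str,
    mutation: str,
    config: Optional[PipelineConfig] = None,
    control_bam: Optional[str] = None,
    mask_bed: Optional[str] = None,
    sample_id: str = "sample",
) -> dict:
    """Run mutation -> events -> IR -> quantification -> consequences.

    Returns a JSON-serialisable report.  Samples with no passing aberrant
    evidence report ``aberrant_present: false`` and a full-length protein.
    """
    config = config or PipelineConfig()
    model = _stage("gene_model", load_gene_model, annotation, fasta, transcript_id)
    mut = _stage("mutation_parse", parse_hgvs_c, mutation)
    cls = _stage("mutation_classify", classify_splice_mutation, mut, model)
    k = _stage("mutation_classify", mutated_intron, mut, model)

    ig0, ig1 = model.intron_genomic(k)
    w = config.detection.search_window_bp
    region = (model.contig, max(0, ig0 - w), ig1 + w)

    junctions = _stage("junction_extract", extract_junctions, bam, region, config.detection)
    for rec in junctions:
        annotate_junction(rec, model)
    control_junctions = None
    if control_bam:
        control_junctions = _stage(
            "junction_extract_control", extract_junctions, control_bam, region, config.detection
        )
    calls = _stage(
        "event_detect", detect_events, junctions, model, mut, config.detection, control_junctions
    )

    canon_reads = canonical_junction_reads(junctions, model, k)
    cov = _stage(
        "intron_coverage",
        compute_intron_coverage,
        bam,
        (model.contig, ig0, ig1),
        mask_bed,
        config.detection,
        config.ir,
        f"intron_{k}",
    )
    if cov.nonmeasurable:
        ir = _stage(
            "intron_retention_fallback",
            fallback_coverage_quant,
            bam,
            (model.contig, ig0, ig1),
            canon_reads,
            config.detection,
            config.ir,
            f"intron_{k}",
        )
    else:
        ir = _stage("intron_retention", compute_ir_ratio, cov, canon_reads, config.ir)

    passing = [c for c in calls if c.passes_filters]
    called_ir = [ir] if ir.called else []

    # canonical evidence: mean canonical-junction reads over affected introns
    affected = {k}
    for c in passing:
        if c.event.event_type is EventType.EXON_SKIPPING:
            exon = model.exon(c.event.index)
            i = model.exons.index(exon)
            if i > 0:
                affected.add(model.exons[i - 1].index)
            if i < len(model.exons) - 1:
                affected.add(exon.index)
    canon_evidence = sum(
        canonical_junction_reads(junctions, model, j)
        for j in sorted(affected)
        if j in model.intron_numbers()
    ) / len(affected)

    expression = None
    if passing or called_ir or canon_evidence > 0:
        expression = _stage(
            "quantify",
            estimate_relative_expression,
            canon_evidence,
            passing,
            called_ir,
            sample_id,
        )

    catalog = load_isoform_catalog()
    consequences = []
    for c in passing:
        variant = _stage("consequence", reconstruct_variant_transcript, model, c.event)
        cons = _stage("consequence", predict_consequence, variant, model)
        cons.named_isoform = annotate_named_isoform(c.event, catalog)
        consequences.append((c, cons))
    ir_consequences = []
    for irc in called_ir:
        ev = SpliceEvent(EventType.INTRON_RETENTION, k)
        variant = _stage("consequence", reconstruct_variant_transcript, model, ev)
        cons = _stage("consequence", predict_consequence, variant, model)
        cons.named_isoform = annotate_named_isoform(ev, catalog)
        ir_consequences.append((ev, cons))

    aberrant_present = bool(passing or called_ir)
    report = {
        "tool_version": __version__,
        "sample_id": sample_id,
        "mutation": {
            "hgvs_c": mutation,
            "edit_type": mut.edit_type.value,
            "site_class": cls.site_class.value,
            "is_consensus_point": cls.is_consensus_point,
            "adjacent_exon": cls.adjacent_exon,
            "side": cls.side,
            "offset": cls.offset,
            "mutated_intron": k,
        },
        "events": [
            {
                "description": c.description,
                "event_type": c.event.event_type.value,
                "index": c.event.index,
                "offset": c.event.offset,
                "junction": [c.junction.gap_start, c.junction.gap_end],
                "supporting_reads": c.supporting_reads,
                "fraction_of_relevant": round(c.fraction_of_relevant, 6),
                "passes_filters": c.passes_filters,
                "present_in_control": c.present_in_control,
            }
            for c in calls
        ],
        "intron_retention": {
            "intron_id": ir.intron_id,
            "ir_ratio": round(ir.ir_ratio, 6),
            "median_depth": ir.median_depth,
            "fraction_bases_at_min_depth": round(ir.fraction_ge, 6),
            "called": ir.called,
            "method": ir.method,
            "canonical_junction_reads": ir.canonical_junction_reads,
        },
        "expression": (
            {
                "evidence_note": "junction reads and median intron depth normalised jointly",
                "entries": expression.as_rows(),
            }
            if expression
            else None
        ),
        "consequences": [
            {
                "variant": c.description,
                "frame_disturbed": cons.frame_disturbed,
                "premature_stop": cons.premature_stop,
                "ptc_codon": cons.ptc_position,
                "aa_lost": cons.aa_lost,
                "protein_class": cons.protein_class.value,
                "named_isoform": cons.named_isoform,
            }
            for c, cons in consequences
        ]
        + [
            {
                "variant": ev.describe(),
                "frame_disturbed": cons.frame_disturbed,
                "premature_stop": cons.premature_stop,
                "ptc_codon": cons.ptc_position,
                "aa_lost": cons.aa_lost,
                "protein_class": cons.protein_class.value,
                "named_isoform": cons.named_isoform,
            }
            for ev, cons in ir_consequences
        ],
        "aberrant_present": aberrant_present,
        "protein_summary": (
            "full_length" if not aberrant_present else "see consequences"
        ),
        "config": config.as_dict(),
    }
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True, ensure_ascii=False)


# ------------------------------------------------------------ cohort summary


def summarize_cohort_reports(
    source: Union[list[dict], str],
    model: Optional[TranscriptModel] = None,
) -> dict:
    """Summarise a cohort from pipeline reports or from a mutation fixture.

    ``source`` is either a list of ``run_sample_pipeline`` reports or the
    path of a TSV with columns ``sample_id, splice_mutation, hgvs_c,
    variants`` (``variants`` holding semicolon-separated event descriptors
    or ``none``).  Classification tallies require ``model`` in the TSV case.
    """
    if isinstance(source, str):
        rows = []
        with open(source) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
        if not rows:
            raise ValueError("empty mutation list")
        n_variants = []
        for r in rows:
            v = r.get("variants", "none")
            n_variants.append(0 if v in ("", "none") else len(v.split(";")))
        summary = None
        if model is not None:
            classified = []
            for r in rows:
                m = parse_hgvs_c(r["hgvs_c"])
                classified.append((m, classify_splice_mutation(m, model)))
            summary = summarize_cohort(classified).as_dict()
    else:
        if not source:
            raise ValueError("empty report list")
        n_variants = [len(rep["consequences"]) for rep in source]
        summary = None

    n = len(n_variants)
    n_aberrant = sum(1 for x in n_variants if x >= 1)
    n_two = sum(1 for x in n_variants if x == 2)
    return {
        "n_samples": n,
        "n_with_aberrant_variants": n_aberrant,
        "pct_with_aberrant_variants": round_percent(n_aberrant, n),
        "n_with_two_aberrant_variants": n_two,
        "mutation_summary": summary,
    }


# --------------------------------------------------------------- text output


def render_text_sashimi(
    junctions: list[JunctionRecord],
    model: TranscriptModel,
    region: Optional[tuple[str, int, int]] = None,
    intron_depth: Optional[dict[str, float]] = None,
) -> str:
    """Deterministic monospace listing of junction arcs with read counts."""
    recs = []
    for rec in junctions:
        if region is not None:
            contig, lo, hi = region
            if rec.contig != contig or rec.gap_end <= lo or rec.gap_start >= hi:
                continue
        if rec.annotation == "unannotated":
            annotate_junction(rec, model)
        recs.append(rec)
    if not recs and not intron_depth:
        return ""
    recs.sort(key=lambda r: (r.gap_start, r.gap_end))
    lines = []
    for rec in recs:
        marker = "=" if rec.annotation == "canonical" else "~"
        lines.append(
            f"  {rec.contig}:{rec.gap_start}-{rec.gap_end} "
            f"{marker * 3} {rec.annotation:<16} reads={rec.read_count}"
        )
    for name, depth in sorted((intron_depth or {}).items()):
        lines.append(f"  {name} median_depth={depth}")
    return "\n".join(lines)


# ---------------------------------------------------------------- tabulation


def cohort_classification(
    fixture_path: str, model: TranscriptModel
) -> tuple[list[dict], dict]:
    """Classify every fixture row; returns (per-row table, cohort summary)."""
    rows = []
    classified = []
    with open(fixture_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            r = dict(zip(header, line.rstrip("\n").split("\t")))
            m = parse_hgvs_c(r["hgvs_c"])
            c = classify_splice_mutation(m, model)
            classified.append((m, c))
            rows.append(
                {
                    "sample_id": r.get("sample_id"),
                    "hgvs_c": r["hgvs_c"],
                    "site_class": c.site_class.value,
                    "is_consensus_point": c.is_consensus_point,
                    "adjacent_exon": c.adjacent_exon,
                    "side": c.side,
                    "offset": c.offset,
                }
            )
    return rows, summarize_cohort(classified).as_dict()
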