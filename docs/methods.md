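# Methods

## Scope and model

`splicevar` analyses one transcript at a time. A `TranscriptModel` holds
ordered exons with genomic (0-based, half-open) and CDS (HGVS c., 1-based)
coordinates plus sequence access; minus-strand genes are converted to
transcript orientation once at load time, and all junction, coverage, and
reconstruction arithmetic happens in pre-mRNA coordinates, converting back
to genomic coordinates only at the alignment-file boundary. This single
conversion point is deliberate: the motivating gene (TP53) is minus-strand,
and strand sign errors are the dominant failure mode in this kind of code.

Intron *k* denotes the intron following exon *k*. HGVS intronic positions
`c.X+n` / `c.X−n` anchor on coding exon boundaries; UTR-containing exons
are representable but only coding exons participate in c.-space and
consequence logic.

## Mutation classification

A splice mutation is classified from its parsed span and intronic anchor:

* **consensus point** — a single-base substitution *or* single-base
  deletion at offset ±1/±2 (the invariant GT/AG dinucleotides). Counting
  single-base deletions as point mutations is required for internal
  consistency of cohort tallies that mix both.
* **splice region** — any other event whose intronic anchor lies within
  the first/last ten intron bases (the sequencing window that defines a
  splice mutation here). Multi-base events never count as consensus
  points.
* **boundary spanning** — multi-base events touching bases on both sides
  of an exon/intron boundary. Purely intronic multi-base events (e.g. an
  insertion between offsets +3 and +4) are classified splice-region, since
  boundary involvement of the inserted content is not derivable from the
  HGVS string.

Donor-side mutations are assigned to the exon they terminate, acceptor-side
mutations to the exon they precede; anchors deeper than ±10 are rejected as
out of scope. Percentages in summaries are rounded to whole percent, half
away from zero.

## Junction events

Each CIGAR `N` operation is one junction observation; a read spanning two
junctions contributes to both (arc-count semantics, matching what a Sashimi
view displays). Reads are filtered to primary, non-duplicate alignments
with mapping quality ≥ 1 — the conventional browser defaults — and every
threshold is echoed in the report's config snapshot.

The ≥ 5 % denominator ("relevant reads") is the sum of junction reads,
canonical included, with either splice end within `search_window_bp`
(default 500, comfortably containing cryptic sites tens of bases from the
canonical junction) of the mutated intron. Intron-retention depth is *not*
part of this denominator; retention has its own thresholds. Control
subtraction marks an event `present_in_control` when the same junction
passes the same read-count and fraction filters in the control sample.

Cryptic-site scanning enumerates AG (acceptor) or GT (donor) dinucleotides
within a window of the canonical junction on both the intronic and exonic
side, ordered by absolute distance. It serves annotation and consequence
prediction; it is not itself an event caller.

## Intron retention

`IR ratio = median_depth / (median_depth + canonical_junction_reads)`,
with per-base depth taken from aligned (non-gap) segments only, the median
over measurable bases, and the lower-median convention for even counts (so
integer depths give integer medians). A retention call requires the ratio
to *exceed* 0.1 and every measurable base to reach depth ≥ 3. Nonmeasurable
bases come from a user-supplied BED mask; automatic mappability computation
is out of scope. A fully masked intron triggers the coverage-only fallback,
which ignores the mask, applies the same thresholds, and records
`method = coverage_fallback` so reports distinguish the two routes. The
ratio definition is fixed and printed here because external retention
tools do not publish a single canonical formula; exact numeric parity with
any specific tool is not claimed.

A consequence of the strict 0.1 threshold worth knowing: a mixture whose
true retention fraction is exactly 10 % and whose evidence is noise-free
produces a ratio of exactly 0.1 and is — correctly — not called. The IR
ratio itself remains the estimator of the retained fraction regardless of
the call.

## Relative expression

Junction read counts and median intron depth are normalised jointly as
commensurate evidence units; this equivalence is an explicit assumption
(both approximate per-variant coverage depth under uniform coverage) and
is stated in every expression table. Canonical evidence is the read count
on the canonical junction of the affected intron, or the mean over both
flanking introns when an exon-skipping event implicates two. Only
filter-passing events enter the table; failed events are reported
separately with `passes_filters = false`. Fractions sum to 1 and are
scale-invariant; the aberrant:canonical ratio is reported alongside
because per-sample percentages in the literature ambiguously follow either
convention.

## Protein consequences

An event descriptor (skip exon *k* / retain intron *k* / cryptic site at a
signed offset from an intron's canonical junction) is applied to the exon
chain, the variant mRNA assembled in transcript orientation, and the
variant CDS translated codon-by-codon from the canonical start.

* `frame_disturbed` ⇔ net coding-length change mod 3 ≠ 0.
* `premature_stop` ⇔ the first stop codon ends strictly before the end of
  the variant CDS (frame-preserved variants end at the canonical stop, so
  this is exactly "a stop 5′ of the canonical termination codon").
* `aa_lost` counts canonical codons whose identity is destroyed by removed
  coding bases — including codons straddling a new junction — and is 0 for
  pure insertions (retention, intronic cryptic acceptors).
* protein class: truncated (PTC), frameshift without PTC, in-frame loss,
  or full length. Nonsense-mediated decay is not modelled; predictions
  describe the encoded protein assuming translation.

Named isoforms are matched by exact event identity against a JSON catalog;
the packaged catalog contains p53ψ (cryptic acceptor, intron 6, −49 bp).
Declared events (from a cohort table) and detected events (from reads)
share one descriptor type, so the consequence engine is testable without
alignments.

## Synthetic reference and what it does (not) show

The real TP53 mRNA record is not redistributed. The package instead
*constructs* a synthetic minus-strand gene (clearly labelled synthetic in
file names and docstrings) whose coding-exon architecture matches the
clinical c.-description layout — coding exons 2–11, CDS boundaries at
c.74/75, 96/97, 375/376, 559/560, 672/673, 782/783, 919/920, 993/994,
1100/1101, CDS end c.1182 — and whose intron lengths and engineered
dinucleotide/stop placements realise the documented consequence of every
cohort variant: frame-preserving retention of introns 4, 6 and 8 with
in-intron stops, frame-shifting retention of introns 5 and 7, the cryptic
acceptors 21 bp into exon 5 (AG ending at c.396; codon-aligned loss of 7
amino acids), 24 bp into exon 8 (loss of 9 codon identities, frame
preserved), the cryptic donor 20 bp inside exon 5, and the p53ψ acceptor
49 bp inside intron 6 with an immediate in-frame stop in the retained
segment. Construction is validated at build time by independent string
assembly and codon-walk translation, with deterministic rejection sampling
from a fixed master seed.

Consequently, consequence *flags* on this reference are architectural
facts (frame arithmetic, engineered stops) and transfer to the real gene
exactly insofar as the real exon/intron lengths match the documented
boundaries; base-resolved quantities with no published anchor (e.g. the
exact PTC codon index inside a retained intron) are properties of the
synthetic sequence only.

## Read simulator

The simulator emits pre-aligned, coordinate-sorted SAM. Mixture
proportions are realised exactly by largest-remainder apportionment;
junction reads carry a single `N` gap with anchors of at least 10 bases;
canonical reads are placed on every junction a canonical transcript would
cover within the affected region (one read per junction per scheduled
transcript), so per-junction canonical depth matches the mixture
proportion. Retention reads span the whole intron when
`read_length ≥ intron + 2·anchor` (making median depth equal the scheduled
read count exactly) and otherwise tile uniformly inside it. No sequencing
errors, quality models, or fragment-length distributions are simulated:
the measured quantities (gap counts, per-base depth medians) do not depend
on them, which also means passing tests say nothing about alignment
ambiguity, soft-clipping, or mappability artefacts in real data.

Default test problem sizes — toy genes of 3–5 exons (150 bp exons, 60 bp
introns), mixtures of 200–300 informative reads, ten seeds per recovery
setting — were chosen as the smallest scales at which every expectation is
exact or the ±0.05 recovery band is meaningful.

## Numerical and degenerate-input choices

* Zero IR denominator ⇒ ratio 0, not called. All-zero evidence in the
  expression table is an error rather than NaNs.
* Deep-intronic bases equidistant from both exons resolve to the donor
  side in c. notation; genomic→c.→genomic round-trips are the identity at
  every pre-mRNA base.
* Expression tables order variants by decreasing fraction with canonical
  first on ties; reports serialise with sorted keys, so identical inputs
  give byte-identical JSON.
* Cohort fixtures preserve the published HGVS dialects (en dashes,
  spaces, `del1`/`ins6` suffixes) and the parser normalises them.

## Known limitations

Single-transcript models only (no multi-isoform deconvolution, TPM/FPKM,
or cross-sample normalisation); no NMD modelling; no statistical testing
of differential splicing; the control comparison is qualitative
(threshold-based presence), mirroring how an unmatched normal sample is
typically used; cryptic-site scanning considers dinucleotides only, not
full splice-site strength models.
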