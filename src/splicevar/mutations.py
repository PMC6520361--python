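"""Parsing and classification of splice-site mutations in HGVS c. notation.

The parser is deliberately tolerant of the dialects found in clinical
tables: en-dashes and Unicode minus signs for the acceptor offset, optional
spaces before the substituted bases, and length-only suffixes such as
``del1``, ``del14`` or ``ins6``.

Classification follows the convention used for TP53 splice-mutation
cohorts: a mutation is a *consensus splice-site point mutation* when a
single base at intronic offset +/-1 or +/-2 is substituted or deleted;
events with intronic anchors deeper in the intron (up to the ten-base
splice-region window) are *splice-region* mutations, and multi-base events
touching bases on both sides of an exon/intron boundary are
*boundary-spanning*.  Donor-side mutations are assigned to the exon they
terminate, acceptor-side mutations to the exon they precede.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .gene_model import TranscriptModel

#: intronic window sequenced around each exon; anchors deeper than this are
#: out of scope for splice classification
SPLICE_REGION_WINDOW = 10


class HgvsParseError(ValueError):
    pass


class EditType(str, Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    INSERTION_OR_DUPLICATION = "insertion_or_duplication"
    DELINS = "delins"


class SiteClass(str, Enum):
    CONSENSUS_DONOR = "consensus_donor"
    CONSENSUS_ACCEPTOR = "consensus_acceptor"
    SPLICE_REGION_DONOR = "splice_region_donor"
    SPLICE_REGION_ACCEPTOR = "splice_region_acceptor"
    BOUNDARY_SPANNING = "boundary_spanning"


@dataclass(frozen=True)
class CPos:
    """One HGVS c. position: CDS base plus optional intronic offset."""

    pos: int
    offset: int = 0

    def __str__(self) -> str:
        if self.offset == 0:
            return f"c.{self.pos}"
        return f"c.{self.pos}{self.offset:+d}"


@dataclass
class SpliceMutation:
    hgvs_c: str
    edit_type: EditType
    span_start: CPos
    span_end: CPos
    length: int
    ref: Optional[str] = None
    alt: Optional[str] = None
    # filled by classify_splice_mutation
    adjacent_exon: Optional[int] = None
    side: Optional[str] = None  # "donor" | "acceptor"
    offset: Optional[int] = None

    @property
    def is_single_base(self) -> bool:
        return self.length == 1


@dataclass
class SpliceClassification:
    site_class: SiteClass
    is_consensus_point: bool
    adjacent_exon: int
    side: str
    offset: int


# --------------------------------------------------------------------- parser

# dialect normalisation: en dash / minus sign -> '-', drop spaces after "c."
_DASHES = {"–": "-", "—": "-", "−": "-"}

_POS = r"(?P<{p}pos>\d+)(?P<{p}off>[+-]\d+)?"
_ONE = re.compile(_POS.format(p="a") + r"$")
_RANGE = re.compile(_POS.format(p="a") + "_" + _POS.format(p="b") + r"$")


def _normalize(hgvs: str) -> str:
    s = hgvs.strip()
    for k, v in _DASHES.items():
        s = s.replace(k, v)
    return s.replace(" ", "")


def _parse_cpos(token: str, context: str) -> tuple[CPos, Optional[CPos]]:
    m = _RANGE.match(token)
    if m:
        a = CPos(int(m.group("apos")), int(m.group("aoff") or 0))
        b = CPos(int(m.group("bpos")), int(m.group("boff") or 0))
        return a, b
    m = _ONE.match(token)
    if m:
        return CPos(int(m.group("apos")), int(m.group("aoff") or 0)), None
    raise HgvsParseError(f"cannot parse position token {token!r} in {context!r}")


def parse_hgvs_c(hgvs: str) -> SpliceMutation:
    """Parse an HGVS c. description into a :class:`SpliceMutation`.

    Supported forms (with dialect tolerance)::

        c.376-1G>A        substitution
        c.559+1del1       single-base deletion, length suffix
        c.560-9_564del14  range deletion
        c.782+3_782+4ins6 insertion (length-only)
        c.75_77delinsTT   deletion-insertion
    """
    s = _normalize(hgvs)
    if not s.startswith("c."):
        raise HgvsParseError(f"{hgvs!r}: HGVS c. description must begin with 'c.'")
    body = s[2:]

    m = re.match(r"^(?P<loc>[0-9+_-]+)(?P<rest>[A-Za-z].*)$", body)
    if not m:
        raise HgvsParseError(f"{hgvs!r}: no edit operation found")
    loc, rest = m.group("loc"), m.group("rest")
    a, b = _parse_cpos(loc, hgvs)

    sub = re.match(r"^(?P<ref>[ACGT]+)>(?P<alt>[ACGT]+)$", rest)
    if sub:
        ref, alt = sub.group("ref"), sub.group("alt")
        if b is None:
            b = a if len(ref) == 1 else None
        if b is None:
            raise HgvsParseError(f"{hgvs!r}: multi-base substitution needs a range")
        return SpliceMutation(hgvs, EditType.SUBSTITUTION, a, b, len(ref), ref, alt)

    delins = re.match(r"^delins(?P<alt>[ACGT]+)$", rest)
    if delins:
        b = b or a
        length = _span_length(a, b)
        return SpliceMutation(hgvs, EditType.DELINS, a, b, length, alt=delins.group("alt"))

    dele = re.match(r"^del(?P<what>[ACGT]+|\d+)?$", rest)
    if dele:
        b = b or a
        what = dele.group("what")
        length = _span_length(a, b)
        if what is not None:
            stated = len(what) if what.isalpha() else int(what)
            if b is not a and stated != length:
                raise HgvsParseError(
                    f"{hgvs!r}: deletion length {stated} does not match span {length}"
                )
            length = stated if b is a else length
        return SpliceMutation(hgvs, EditType.DELETION, a, b, length,
                              ref=what if what and what.isalpha() else None)

    ins = re.match(r"^(?:ins|dup)(?P<what>[ACGT]+|\d+)$", rest)
    if ins:
        what = ins.group("what")
        length = len(what) if what.isalpha() else int(what)
        b = b or a
        return SpliceMutation(hgvs, EditType.INSERTION_OR_DUPLICATION, a, b, length,
                              alt=what if what.isalpha() else None)

    raise HgvsParseError(f"{hgvs!r}: unrecognised edit token {rest!r}")


def _span_length(a: CPos, b: CPos) -> int:
    """Length of an affected span when both ends sit near one boundary.

    Exact only when the two ends are anchored on the same exon boundary
    (both intronic on one side, or intronic-to-exonic across one junction),
    which is the only case a splice-region table produces.
    """
    if a.offset and b.offset and (a.offset > 0) == (b.offset > 0) and a.pos == b.pos:
        return abs(b.offset - a.offset) + 1
    if a.offset < 0 and b.offset == 0:
        # e.g. c.560-9_564: |-9| intronic bases plus exonic run from the
        # acceptor boundary (b.pos - boundary + 1); boundary = a.pos
        return -a.offset + (b.pos - a.pos + 1)
    if a.offset == 0 and b.offset > 0:
        return (b.pos - a.pos + 1) + b.offset
    if a.offset == 0 and b.offset == 0:
        return b.pos - a.pos + 1
    raise HgvsParseError(f"cannot derive span length for {a}_{b}")


# ----------------------------------------------------------------- classifier


def _anchor(mut: SpliceMutation, model: TranscriptModel) -> tuple[str, int, int]:
    """Return (side, adjacent_exon, offset) for the mutation's intronic anchor."""
    ends = [p for p in (mut.span_start, mut.span_end) if p.offset != 0]
    if not ends:
        raise ValueError(
            f"{mut.hgvs_c}: no intronic bases affected; exonic events are out of "
            "scope for splice classification"
        )
    first = ends[0]
    if first.offset > 0:
        exon = _exon_with_coding_end(model, first.pos)
        return "donor", exon, first.offset
    exon = _exon_with_coding_start(model, first.pos)
    return "acceptor", exon, first.offset


def _exon_with_coding_end(model: TranscriptModel, c: int) -> int:
    for e in model.coding_exons:
        if e.coding_end_c == c:
            return e.index
    raise ValueError(f"c.{c} is not the 3' coding end of any exon")


def _exon_with_coding_start(model: TranscriptModel, c: int) -> int:
    for e in model.coding_exons:
        if e.coding_start_c == c:
            return e.index
    raise ValueError(f"c.{c} is not the 5' coding start of any exon")


def classify_splice_mutation(
    mut: SpliceMutation, model: TranscriptModel
) -> SpliceClassification:
    """Classify a parsed mutation against a transcript model (in place too).

    Raises ``ValueError`` when the intronic anchor lies deeper than the
    ten-base splice-region window.
    """
    side, exon, offset = _anchor(mut, model)
    if abs(offset) > SPLICE_REGION_WINDOW:
        raise ValueError(
            f"{mut.hgvs_c}: intronic anchor {offset:+d} outside the "
            f"{SPLICE_REGION_WINDOW}-base splice-region window"
        )
    spans_boundary = (
        (mut.span_start.offset != 0) != (mut.span_end.offset != 0)
    ) and mut.span_start != mut.span_end

    is_consensus_point = (
        mut.is_single_base
        and mut.edit_type in (EditType.SUBSTITUTION, EditType.DELETION)
        and abs(offset) in (1, 2)
    )
    if is_consensus_point:
        site_class = (
            SiteClass.CONSENSUS_DONOR if side == "donor" else SiteClass.CONSENSUS_ACCEPTOR
        )
    elif spans_boundary:
        site_class = SiteClass.BOUNDARY_SPANNING
    else:
        site_class = (
            SiteClass.SPLICE_REGION_DONOR
            if side == "donor"
            else SiteClass.SPLICE_REGION_ACCEPTOR
        )

    mut.side = side
    mut.adjacent_exon = exon
    mut.offset = offset
    return SpliceClassification(site_class, is_consensus_point, exon, side, offset)


# -------------------------------------------------------------------- summary


@dataclass
class CohortSummary:
    n_mutations: int
    n_consensus_point: int
    n_donor_consensus: int
    n_acceptor_consensus: int
    n_substitutions_at_consensus: int
    n_single_base_deletions_at_consensus: int
    n_adjacent_exons_5_to_8: int
    pct_adjacent_exons_5_to_8: int
    per_exon: dict[int, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["per_exon"] = {str(k): v for k, v in sorted(self.per_exon.items())}
        return d


def summarize_cohort(
    classified: list[tuple[SpliceMutation, SpliceClassification]]
) -> CohortSummary:
    """Tally a classified splice-mutation cohort.

    Percentages are rounded to the nearest whole percent (round-half-up).
    """
    if not classified:
        raise ValueError("cannot summarise an empty mutation list")
    n = len(classified)
    cons = [(m, c) for m, c in classified if c.is_consensus_point]
    per_exon = Counter(c.adjacent_exon for _, c in classified)
    n_5_to_8 = sum(v for k, v in per_exon.items() if 5 <= k <= 8)
    return CohortSummary(
        n_mutations=n,
        n_consensus_point=len(cons),
        n_donor_consensus=sum(1 for _, c in cons if c.side == "donor"),
        n_acceptor_consensus=sum(1 for _, c in cons if c.side == "acceptor"),
        n_substitutions_at_consensus=sum(
            1 for m, _ in cons if m.edit_type is EditType.SUBSTITUTION
        ),
        n_single_base_deletions_at_consensus=sum(
            1 for m, _ in cons if m.edit_type is EditType.DELETION
        ),
        n_adjacent_exons_5_to_8=n_5_to_8,
        pct_adjacent_exons_5_to_8=round_percent(n_5_to_8, n),
        per_exon=dict(per_exon),
    )


def round_percent(numerator: int, denominator: int) -> int:
    """Whole-percent rounding, half away from zero (81% for 13/16)."""
    if denominator == 0:
        raise ValueError("zero denominator")
    x = 100.0 * numerator / denominator
    return int(x + 0.5)
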