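import pysam
import pytest

from splicevar.simulate import simulate_gene
from splicevar.tp53 import load_reference_model, write_cohort_fixture


@pytest.fixture(scope="session")
def tp53_dir(tmp_path_factory):
    return str(tmp_path_factory.mktemp("tp53_ref"))


@pytest.fixture(scope="session")
def tp53_model(tp53_dir):
    return load_reference_model(tp53_dir)


@pytest.fixture(scope="session")
def cohort_tsv(tmp_path_factory):
    path = tmp_path_factory.mktemp("cohort") / "cohort.tsv"
    return write_cohort_fixture(str(path))


@pytest.fixture(scope="session")
def toy_gene(tmp_path_factory):
    """4 exons x 150 bp, 60 bp introns, plus strand."""
    return simulate_gene(1, n_exons=4, outdir=str(tmp_path_factory.mktemp("toy")))


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    return str(tmp_path_factory.mktemp("sims"))


# ------------------------------------------------------ independent oracles


def sam_gap_counts(sam_path: str) -> dict[tuple[int, int], int]:
    """Count splice gaps by direct CIGAR inspection of the SAM text."""
    import re

    counts: dict[tuple[int, int], int] = {}
    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.split("\t")
            pos = int(f[3]) - 1
            for length, op in re.findall(r"(\d+)([MIDNSHP=X])", f[5]):
                length = int(length)
                if op in "MD=X":
                    pos += length
                elif op == "N":
                    key = (pos, pos + length)
                    counts[key] = counts.get(key, 0) + 1
                    pos += length
    return counts


def sam_pileup(sam_path: str, start: int, end: int) -> list[int]:
    """Per-base depth over [start, end) from aligned (M) segments, by hand."""
    import re

    depth = [0] * (end - start)
    with open(sam_path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            f = line.split("\t")
            pos = int(f[3]) - 1
            for length, op in re.findall(r"(\d+)([MIDNSHP=X])", f[5]):
                length = int(length)
                if op in "M=X":
                    for p in range(max(pos, start), min(pos + length, end)):
                        depth[p - start] += 1
                    pos += length
                elif op in "DN":
                    pos += length
    return depth


def write_sam(path: str, contig: str, contig_len: int, rows: list[tuple[int, str]]):
    """Write a minimal coordinate-sorted SAM from (pos0, cigar) tuples."""
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": contig, "LN": contig_len}]}
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for i, (pos, cigar) in enumerate(sorted(rows)):
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = f"m{i}"
            seg.reference_id = 0
            seg.reference_start = pos
            seg.mapping_quality = 60
            seg.cigarstring = cigar
            length = sum(
                int(n) for n, op in __import__("re").findall(r"(\d+)([MIS=X])", cigar)
            )
            seg.query_sequence = "A" * length
            seg.flag = 0
            out.write(seg)
    return path
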