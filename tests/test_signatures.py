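"""Signature extraction from CIGARs, split reads, and whole files."""

import warnings

import pysam
import pytest

from svclique.model import ContractViolation
from svclique.signatures import (
    MissingIndexError,
    ParseError,
    ensure_indexed_bam,
    extract_signatures,
    parse_cigar_signatures,
    parse_split_signatures,
    segment_view,
    spanning_read_count,
)

OPS = {c: i for i, c in enumerate("MIDNSHP=X")}


def cig(text):
    import re

    return tuple(
        (OPS[m.group(2)], int(m.group(1)))
        for m in re.finditer(r"(\d+)([MIDNSHP=X])", text)
    )


def seg(start, cigar, chrom="chr1", strand="+", read="r1",
        primary=True, supplementary=False, mapq=60):
    return segment_view(read, chrom, start, strand, cig(cigar), mapq,
                        primary, supplementary)


# ---------------------------------------------------------------------------
# gapped signatures
# ---------------------------------------------------------------------------

class TestCigarSignatures:
    def test_deletion_run(self):
        sigs = parse_cigar_signatures(seg(1000, "100M50D100M"), min_sv_size=50)
        assert len(sigs) == 1
        s = sigs[0]
        assert (s.svtype, s.start, s.end, s.length, s.origin) == ("DEL", 1100, 1150, 50, "gap")

    def test_no_gap_ops(self):
        assert parse_cigar_signatures(seg(0, "200M")) == []

    def test_insertion_run(self):
        sigs = parse_cigar_signatures(seg(0, "100M60I100M"), min_sv_size=50)
        assert len(sigs) == 1
        s = sigs[0]
        assert (s.svtype, s.start, s.end, s.length) == ("INS", 100, 100, 60)

    def test_below_size_threshold_ignored(self):
        assert parse_cigar_signatures(seg(0, "100M49D100M"), min_sv_size=50) == []

    def test_nearby_same_type_gaps_merged(self):
        # two 60 bp deletions 100 bp apart < merge_gap 150: union span
        sigs = parse_cigar_signatures(
            seg(0, "100M60D100M60D100M"), min_sv_size=50, merge_gap=150
        )
        assert len(sigs) == 1
        assert (sigs[0].start, sigs[0].end) == (100, 320)

        # far apart: kept separate
        sigs = parse_cigar_signatures(
            seg(0, "100M60D400M60D100M"), min_sv_size=50, merge_gap=150
        )
        assert [s.start for s in sigs] == [100, 560]

    def test_nearby_insertions_merged_with_summed_length(self):
        sigs = parse_cigar_signatures(
            seg(0, "100M60I50M70I100M"), min_sv_size=50, merge_gap=150
        )
        assert len(sigs) == 1
        assert (sigs[0].start, sigs[0].length) == (100, 130)

    def test_soft_clips_produce_nothing(self):
        assert parse_cigar_signatures(seg(0, "500S200M300S")) == []

    def test_malformed_cigar_names_read(self):
        bad = seg(0, "100M")
        object.__setattr__(bad, "cigar", ((0, 100), (2, -5)))
        with pytest.raises(ParseError, match="r1"):
            parse_cigar_signatures(bad)


# ---------------------------------------------------------------------------
# split signatures
# ---------------------------------------------------------------------------

class TestSplitSignatures:
    def test_reference_gap_is_deletion(self):
        a = seg(1000, "1000M1000S")
        b = seg(5000, "1000S1000M", supplementary=True)
        sigs = parse_split_signatures([a, b])
        assert len(sigs) == 1
        assert (sigs[0].svtype, sigs[0].start, sigs[0].end) == ("DEL", 2000, 5000)

    def test_reference_overlap_is_duplication_over_junction_span(self):
        a = seg(1000, "1000M1000S")  # [1000,2000)
        b = seg(1500, "1000S1000M", supplementary=True)  # [1500,2500)
        sigs = parse_split_signatures([a, b])
        assert len(sigs) == 1
        assert (sigs[0].svtype, sigs[0].start, sigs[0].end) == ("DUP", 1500, 2000)

    def test_different_chromosomes_is_translocation(self):
        a = seg(1000, "1000M1000S", chrom="chr1")
        b = seg(800, "1000S1000M", chrom="chr7", supplementary=True)
        sigs = parse_split_signatures([a, b])
        assert len(sigs) == 1
        s = sigs[0]
        assert s.svtype == "TRA"
        assert (s.chrom, s.start) == ("chr1", 2000)
        assert (s.chrom2, s.pos2) == ("chr7", 800)
        assert s.strand_pair == "++"

    def test_opposite_strand_is_inversion(self):
        a = seg(1000, "1000M2000S")  # forward flank, ends at 2000
        b = seg(2000, "1000S2000M1000S", strand="-", supplementary=True)
        sigs = parse_split_signatures([a, b])
        assert len(sigs) == 1
        assert (sigs[0].svtype, sigs[0].start, sigs[0].end) == ("INV", 2000, 4000)

    def test_query_gap_over_anchored_segments_is_insertion(self):
        # 300 unaligned query bases between abutting reference segments
        a = seg(1000, "1000M1300S")
        b = seg(2000, "1300S1000M", supplementary=True)
        sigs = parse_split_signatures([a, b])
        assert len(sigs) == 1
        s = sigs[0]
        assert (s.svtype, s.start, s.length) == ("INS", 2000, 300)

    def test_three_segment_insertion_with_distant_middle(self):
        a = seg(1000, "1000M1400S")
        m = seg(900_000, "1000S400M", supplementary=True)
        c = seg(2010, "1400S1000M", supplementary=True)
        sigs = parse_split_signatures([a, m, c], ins_anchor_dist=100)
        assert len(sigs) == 1
        s = sigs[0]
        assert (s.svtype, s.start, s.length) == ("INS", 2000, 400)

    def test_single_segment_is_not_an_error(self):
        assert parse_split_signatures([seg(0, "100M")]) == []

    def test_mixed_read_ids_rejected(self):
        with pytest.raises(ContractViolation):
            parse_split_signatures([seg(0, "100M100S"), seg(500, "100S100M", read="other")])

    def test_gap_beyond_max_sv_size_ignored(self):
        a = seg(1000, "1000M1000S")
        b = seg(5_000_000, "1000S1000M", supplementary=True)
        assert parse_split_signatures([a, b], max_sv_size=1_000_000) == []


# ---------------------------------------------------------------------------
# whole-file extraction
# ---------------------------------------------------------------------------

def _write_sam(path, records, chroms=(("chr1", 1_000_000),)):
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": l} for n, l in chroms],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for name, flag, tid, pos, cigar, tags in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.flag = flag
            a.reference_id = tid
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigarstring = cigar
            for tag, value in tags:
                a.set_tag(tag, value)
            out.write(a)


def test_extract_single_gapped_deletion(tmp_path):
    sam = tmp_path / "one.sam"
    _write_sam(sam, [("r1", 0, 0, 1000, "100M50D100M", [])])
    bam = ensure_indexed_bam(sam, tmp_path)
    sigs = extract_signatures(bam)
    assert len(sigs) == 1
    (s,) = sigs.group(("DEL", "chr1"))
    assert (s.start, s.end) == (1100, 1150)


def test_extract_split_signatures_via_sa_tag(small_del_bam, small_del_signatures):
    _, sim = small_del_bam
    truth = sim.truth[0]
    dels = small_del_signatures.group(("DEL", "chr1"))
    assert len(dels) >= 5
    assert all((s.start, s.end) == (truth.start, truth.end) for s in dels)
    assert all(s.origin == "split" for s in dels)


def test_extract_split_signatures_without_sa_tags(tmp_path, small_del_bam):
    """Fallback read-name grouping gives the same split signatures."""
    bam, _ = small_del_bam
    stripped = tmp_path / "nosa.sam"
    with pysam.AlignmentFile(bam, "rb") as fin, pysam.AlignmentFile(
        str(stripped), "wh", template=fin
    ) as fout:
        for read in fin.fetch():
            read.set_tag("SA", None)
            fout.write(read)
    sigs = extract_signatures(ensure_indexed_bam(stripped, tmp_path))
    ref = extract_signatures(bam)
    assert [
        (s.start, s.end, s.read_id) for s in sigs.group(("DEL", "chr1"))
    ] == [(s.start, s.end, s.read_id) for s in ref.group(("DEL", "chr1"))]


def test_extract_empty_file_warns(tmp_path):
    sam = tmp_path / "empty.sam"
    _write_sam(sam, [])
    bam = ensure_indexed_bam(sam, tmp_path)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        sigs = extract_signatures(bam)
    assert len(sigs) == 0
    assert any("no mapped reads" in str(w.message) for w in caught)


def test_missing_index_error_has_remediation_hint(tmp_path):
    sam = tmp_path / "plain.sam"
    _write_sam(sam, [("r1", 0, 0, 1000, "100M", [])])
    with pytest.raises(MissingIndexError, match="samtools|ensure_indexed_bam"):
        extract_signatures(sam)


def test_extraction_deterministic_across_thread_counts(small_del_bam):
    bam, _ = small_del_bam
    one = extract_signatures(bam, threads=1)
    four = extract_signatures(bam, threads=4)
    again = extract_signatures(bam, threads=1)
    assert one == four == again


def test_mapq_filter_drops_low_quality_reads(tmp_path):
    sam = tmp_path / "mapq.sam"
    header_records = [("r1", 0, 0, 1000, "100M60D100M", [])]
    _write_sam(sam, header_records)
    # rewrite with low mapq
    text = sam.read_text().replace("\t60\t", "\t5\t")
    sam.write_text(text)
    bam = ensure_indexed_bam(sam, tmp_path)
    assert len(extract_signatures(bam, min_mapq=20)) == 0
    assert len(extract_signatures(bam, min_mapq=0)) == 1


def test_cigar_conservation_on_fixture(small_del_signatures):
    """DEL signatures never outrun reference span; INS consume none."""
    for _, sigs in small_del_signatures.groups():
        for s in sigs:
            if s.svtype == "INS":
                assert s.end == s.start
            else:
                assert s.end > s.start


# ---------------------------------------------------------------------------
# spanning reads
# ---------------------------------------------------------------------------

def test_spanning_read_count_on_fixture(small_del_bam):
    bam, sim = small_del_bam
    truth = sim.truth[0]
    # at a locus far from the deletion every read is a plain primary
    far = truth.start - 100_000
    n = spanning_read_count(bam, "chr1", far)
    assert n >= 10  # ~20x coverage
    with pysam.AlignmentFile(bam, "rb") as aln:
        direct = len(
            {
                r.query_name
                for r in aln.fetch("chr1", far, far + 1)
                if not (r.is_secondary or r.is_supplementary)
                and r.reference_start <= far < r.reference_end
            }
        )
    assert n == direct


def test_spanning_read_count_outside_alignments(tmp_path):
    sam = tmp_path / "sparse.sam"
    _write_sam(sam, [("r1", 0, 0, 1000, "500M", [])])
    bam = ensure_indexed_bam(sam, tmp_path)
    assert spanning_read_count(bam, "chr1", 100_000) == 0


def test_spanning_read_count_unknown_chromosome_warns(small_del_bam):
    bam, _ = small_del_bam
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        assert spanning_read_count(bam, "chrX", 1000) == 0
    assert caught


def test_spanning_read_count_dedups_primary_and_supplementary(tmp_path):
    sam = tmp_path / "dedup.sam"
    _write_sam(
        sam,
        [
            ("r1", 0, 0, 1000, "500M500S", []),
            ("r1", 0x800, 0, 1200, "500S500M", []),
            ("r2", 0, 0, 900, "600M", []),
        ],
    )
    bam = ensure_indexed_bam(sam, tmp_path)
    assert spanning_read_count(bam, "chr1", 1250) == 2
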