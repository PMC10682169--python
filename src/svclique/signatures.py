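"""Extraction of SV signatures from long-read alignments.

Two signature categories are parsed:

* gapped alignments — insertion/deletion runs inside a CIGAR string;
* split alignments — a read mapped as a primary plus supplementary
  segments, whose junction geometry encodes deletions, duplications,
  inversions, insertions and translocations.

All coordinates are 0-based half-open. Secondary and duplicate-flagged
records are ignored; supplementary segments are located through the SA
auxiliary tag of the primary record, falling back to grouping clipped
records by read name when SA tags are absent.
"""

from __future__ import annotations

import re
import warnings
from concurrent.futures import ThreadPoolExecutor
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Set

import pysam

from .model import AlignedSegmentView, ContractViolation, SvSignature, SignatureSet

# pysam CIGAR op codes
_CMATCH, _CINS, _CDEL, _CREF_SKIP, _CSOFT, _CHARD, _CPAD, _CEQUAL, _CDIFF = range(9)
_REF_OPS = {_CMATCH, _CDEL, _CREF_SKIP, _CEQUAL, _CDIFF}
_QUERY_OPS = {_CMATCH, _CINS, _CSOFT, _CEQUAL, _CDIFF}
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_OP_CODE = {c: i for i, c in enumerate("MIDNSHP=X")}


class ParseError(ValueError):
    pass


class MissingIndexError(FileNotFoundError):
    pass


# ---------------------------------------------------------------------------
# segment views
# ---------------------------------------------------------------------------

def _clip_lengths(cigar) -> tuple:
    left = right = 0
    for op, ln in cigar:
        if op in (_CSOFT, _CHARD):
            left += ln
        else:
            break
    for op, ln in reversed(cigar):
        if op in (_CSOFT, _CHARD):
            right += ln
        else:
            break
    return left, right


def _read_length(cigar) -> int:
    return sum(ln for op, ln in cigar if op in _QUERY_OPS or op == _CHARD)


def segment_view(
    read_id: str,
    chrom: str,
    ref_start: int,
    strand: str,
    cigar: Sequence,
    mapq: int,
    is_primary: bool,
    is_supplementary: bool,
) -> AlignedSegmentView:
    """Build an orientation-normalized view from raw record fields."""
    cigar = tuple((int(op), int(ln)) for op, ln in cigar)
    for op, ln in cigar:
        if ln <= 0 or op > _CDIFF:
            raise ParseError(f"malformed CIGAR in read {read_id!r}: op={op} len={ln}")
    ref_span = sum(ln for op, ln in cigar if op in _REF_OPS)
    rl = _read_length(cigar)
    left, right = _clip_lengths(cigar)
    if strand == "+":
        qs, qe = left, rl - right
    else:
        qs, qe = right, rl - left
    return AlignedSegmentView(
        read_id=read_id,
        chrom=chrom,
        ref_start=ref_start,
        ref_end=ref_start + ref_span,
        strand=strand,
        cigar=cigar,
        is_primary=is_primary,
        is_supplementary=is_supplementary,
        query_start=qs,
        query_end=qe,
        mapq=mapq,
    )


def view_from_pysam(read: pysam.AlignedSegment) -> AlignedSegmentView:
    return segment_view(
        read_id=read.query_name,
        chrom=read.reference_name,
        ref_start=read.reference_start,
        strand="-" if read.is_reverse else "+",
        cigar=read.cigartuples,
        mapq=read.mapping_quality,
        is_primary=not (read.is_secondary or read.is_supplementary),
        is_supplementary=read.is_supplementary,
    )


def _parse_sa_tag(read_id: str, sa: str, min_mapq: int) -> List[AlignedSegmentView]:
    views = []
    for entry in sa.rstrip(";").split(";"):
        if not entry:
            continue
        fields = entry.split(",")
        if len(fields) < 6:
            raise ParseError(f"malformed SA entry in read {read_id!r}: {entry!r}")
        rname, pos, strand, cig, mapq = fields[0], int(fields[1]), fields[2], fields[3], int(fields[4])
        if mapq < min_mapq:
            continue
        cigar = tuple(
            (_OP_CODE[m.group(2)], int(m.group(1))) for m in _CIGAR_RE.finditer(cig)
        )
        if not cigar:
            raise ParseError(f"malformed SA CIGAR in read {read_id!r}: {cig!r}")
        views.append(
            segment_view(
                read_id, rname, pos - 1, strand, cigar, mapq,
                is_primary=False, is_supplementary=True,
            )
        )
    return views


# ---------------------------------------------------------------------------
# gapped (CIGAR) signatures
# ---------------------------------------------------------------------------

def parse_cigar_signatures(
    seg: AlignedSegmentView, min_sv_size: int = 50, merge_gap: int = 150
) -> List[SvSignature]:
    """DEL/INS signatures from insertion and deletion runs in one CIGAR.

    Same-type gapped signatures closer than ``merge_gap`` bp on the
    reference are merged (union span for deletions; summed length anchored
    at the leftmost gap for insertions) to undo aligner fragmentation of a
    single event. Soft/hard clips produce nothing here.
    """
    raw: List[SvSignature] = []
    ref = seg.ref_start
    for op, ln in seg.cigar:
        if ln <= 0 or op > _CDIFF:
            raise ParseError(f"malformed CIGAR in read {seg.read_id!r}")
        if op == _CDEL and ln >= min_sv_size:
            raw.append(
                SvSignature("DEL", seg.chrom, ref, ref + ln, seg.read_id, "gap", length=ln)
            )
        elif op == _CINS and ln >= min_sv_size:
            raw.append(
                SvSignature("INS", seg.chrom, ref, ref, seg.read_id, "gap", length=ln)
            )
        if op in _REF_OPS:
            ref += ln
    return _merge_gapped(raw, merge_gap)


def _merge_gapped(sigs: List[SvSignature], merge_gap: int) -> List[SvSignature]:
    out: List[SvSignature] = []
    for svtype in ("DEL", "INS"):
        group = sorted((s for s in sigs if s.svtype == svtype), key=lambda s: s.start)
        cur = None
        for s in group:
            if cur is None:
                cur = s
                continue
            if s.start - (cur.end if svtype == "DEL" else cur.start) < merge_gap:
                if svtype == "DEL":
                    cur = SvSignature(
                        "DEL", cur.chrom, cur.start, max(cur.end, s.end),
                        cur.read_id, "gap", length=max(cur.end, s.end) - cur.start,
                    )
                else:
                    cur = SvSignature(
                        "INS", cur.chrom, cur.start, cur.start,
                        cur.read_id, "gap", length=cur.length + s.length,
                    )
            else:
                out.append(cur)
                cur = s
        if cur is not None:
            out.append(cur)
    return sorted(out, key=lambda s: (s.start, s.svtype))


# ---------------------------------------------------------------------------
# split-read signatures
# ---------------------------------------------------------------------------

def _inner_first(seg: AlignedSegmentView) -> int:
    """Junction-adjacent reference coordinate of a query-first segment."""
    return seg.ref_end if seg.strand == "+" else seg.ref_start


def _inner_second(seg: AlignedSegmentView) -> int:
    """Junction-adjacent reference coordinate of a query-second segment."""
    return seg.ref_start if seg.strand == "+" else seg.ref_end


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _tra_signature(a: AlignedSegmentView, b: AlignedSegmentView) -> SvSignature:
    bp1, s1 = _inner_first(a), a.strand
    bp2, s2 = _inner_second(b), b.strand
    c1, c2 = a.chrom, b.chrom
    if c1 > c2:
        # canonical orientation: read the junction from the other side
        c1, c2 = c2, c1
        bp1, bp2 = bp2, bp1
        s1, s2 = _flip(s2), _flip(s1)
    return SvSignature(
        "TRA", c1, bp1, bp1 + 1, a.read_id, "split",
        chrom2=c2, pos2=bp2, strand_pair=s1 + s2,
    )


def parse_split_signatures(
    segments_of_read: Sequence[AlignedSegmentView],
    min_sv_size: int = 50,
    max_sv_size: int = 1_000_000,
    ins_anchor_dist: int = 100,
) -> List[SvSignature]:
    """Signatures from the junction geometry of a split read.

    For query-consecutive segment pairs on one chromosome and strand, a
    reference gap is a deletion, a reference overlap a (tandem) duplication,
    and a query gap over a near-zero reference gap an insertion; opposite
    strands give an inversion and different chromosomes a translocation.
    A three-segment read whose outer segments are closely mapped while the
    middle maps elsewhere is also an insertion (of the middle query span).
    """
    if len(segments_of_read) < 2:
        return []
    read_id = segments_of_read[0].read_id
    if any(s.read_id != read_id for s in segments_of_read):
        raise ContractViolation("parse_split_signatures: mixed read ids")
    segs = sorted(segments_of_read, key=lambda s: (s.query_start, s.query_end))

    out: List[SvSignature] = []
    consumed_middle: Set[int] = set()

    # three-segment insertions: outer segments anchor, middle maps far away
    for i in range(len(segs) - 2):
        a, m, c = segs[i], segs[i + 1], segs[i + 2]
        if a.chrom != c.chrom or a.strand != c.strand:
            continue
        if a.strand == "+":
            anchor_gap = c.ref_start - a.ref_end
            anchor = a.ref_end
        else:
            anchor_gap = a.ref_start - c.ref_end
            anchor = a.ref_start
        middle_span = c.query_start - a.query_end
        distant = m.chrom != a.chrom or (
            min(abs(m.ref_start - anchor), abs(m.ref_end - anchor))
            > 10 * ins_anchor_dist
        )
        if abs(anchor_gap) <= ins_anchor_dist and middle_span >= min_sv_size and distant:
            out.append(
                SvSignature(
                    "INS", a.chrom, anchor, anchor, read_id, "split",
                    length=middle_span,
                )
            )
            consumed_middle.add(i + 1)

    for i in range(len(segs) - 1):
        if i in consumed_middle or i + 1 in consumed_middle:
            continue
        a, b = segs[i], segs[i + 1]
        if a.chrom != b.chrom:
            out.append(_tra_signature(a, b))
            continue
        if a.strand != b.strand:
            bp_a = _inner_first(a)
            bp_b = b.ref_end if b.strand == "-" else b.ref_start
            lo, hi = min(bp_a, bp_b), max(bp_a, bp_b)
            if min_sv_size <= hi - lo <= max_sv_size:
                out.append(
                    SvSignature(
                        "INV", a.chrom, lo, hi, read_id, "split",
                        length=hi - lo, strand_pair=a.strand + b.strand,
                    )
                )
            continue
        inner_a, inner_b = _inner_first(a), _inner_second(b)
        ref_gap = inner_b - inner_a if a.strand == "+" else inner_a - inner_b
        query_gap = b.query_start - a.query_end
        if query_gap >= min_sv_size and abs(ref_gap) <= ins_anchor_dist:
            anchor = min(inner_a, inner_b)
            out.append(
                SvSignature("INS", a.chrom, anchor, anchor, read_id, "split", length=query_gap)
            )
        elif min_sv_size <= ref_gap <= max_sv_size and query_gap < min_sv_size:
            lo, hi = (inner_a, inner_b) if a.strand == "+" else (inner_b, inner_a)
            out.append(
                SvSignature("DEL", a.chrom, lo, hi, read_id, "split", length=hi - lo)
            )
        elif -max_sv_size <= ref_gap <= -min_sv_size and query_gap < min_sv_size:
            lo, hi = (inner_b, inner_a) if a.strand == "+" else (inner_a, inner_b)
            out.append(
                SvSignature("DUP", a.chrom, lo, hi, read_id, "split", length=hi - lo)
            )
    return out


# ---------------------------------------------------------------------------
# whole-file extraction
# ---------------------------------------------------------------------------

def _open_alignment(path) -> pysam.AlignmentFile:
    path = str(path)
    mode = "r" if path.endswith(".sam") else "rb"
    return pysam.AlignmentFile(path, mode)


def _require_index(aln: pysam.AlignmentFile, path) -> None:
    try:
        ok = aln.check_index()
    except (AttributeError, ValueError):
        ok = False
    if not ok:
        raise MissingIndexError(
            f"{path} has no index; create one with ensure_indexed_bam() or "
            f"'samtools sort' followed by 'samtools index'"
        )


def ensure_indexed_bam(path, workdir=None) -> str:
    """Return a coordinate-sorted, indexed BAM for ``path``.

    SAM input (or an unindexed BAM) is sorted and indexed into ``workdir``
    (defaults to the input's directory); already-indexed BAMs are returned
    unchanged.
    """
    path = Path(path)
    if path.suffix == ".bam":
        with pysam.AlignmentFile(str(path), "rb") as aln:
            try:
                if aln.check_index():
                    return str(path)
            except (AttributeError, ValueError):
                pass
        try:
            pysam.index(str(path))
            return str(path)
        except pysam.SamtoolsError:
            pass
    workdir = Path(workdir) if workdir is not None else path.parent
    workdir.mkdir(parents=True, exist_ok=True)
    out = workdir / (path.stem + ".sorted.bam")
    pysam.sort("-o", str(out), str(path))
    pysam.index(str(out))
    return str(out)


def _record_ok(read: pysam.AlignedSegment, min_mapq: int) -> bool:
    return (
        not read.is_unmapped
        and not read.is_secondary
        and not read.is_duplicate
        and read.mapping_quality >= min_mapq
        and read.cigartuples is not None
    )


def _has_large_clip(cigar, min_sv_size: int) -> bool:
    left, right = _clip_lengths(cigar)
    return max(left, right) >= min_sv_size


def _extract_chrom(
    path: str,
    chrom: str,
    min_mapq: int,
    min_sv_size: int,
    max_sv_size: int,
    merge_gap: int,
    ins_anchor_dist: int,
):
    """Signatures from one chromosome plus clipped records for the SA-less
    fallback grouping."""
    sigs: List[SvSignature] = []
    fallback_views: List[AlignedSegmentView] = []
    sa_read_ids: Set[str] = set()
    with _open_alignment(path) as aln:
        for read in aln.fetch(chrom):
            if not _record_ok(read, min_mapq):
                continue
            view = view_from_pysam(read)
            sigs.extend(parse_cigar_signatures(view, min_sv_size, merge_gap))
            if read.is_supplementary:
                if not read.has_tag("SA"):
                    fallback_views.append(view)
                continue
            if read.has_tag("SA"):
                sa_read_ids.add(read.query_name)
                mates = _parse_sa_tag(read.query_name, read.get_tag("SA"), min_mapq)
                segments = [view] + mates
                sigs.extend(
                    parse_split_signatures(
                        segments, min_sv_size, max_sv_size, ins_anchor_dist
                    )
                )
            elif _has_large_clip(view.cigar, min_sv_size):
                fallback_views.append(view)
    return sigs, fallback_views, sa_read_ids


def extract_signatures(
    alignment_file,
    min_mapq: int = 20,
    min_sv_size: int = 50,
    max_sv_size: int = 1_000_000,
    merge_gap: int = 150,
    ins_anchor_dist: int = 100,
    sample: Optional[str] = None,
    threads: int = 1,
) -> SignatureSet:
    """Extract all gapped and split signatures from an indexed alignment file.

    The per-chromosome scans may run concurrently; the output is identical
    for any thread count (signatures are deduplicated per read/type/interval
    and canonically sorted).
    """
    path = str(alignment_file)
    with _open_alignment(path) as aln:
        _require_index(aln, path)
        stats = aln.get_index_statistics()
        chroms = [s.contig for s in stats if s.mapped > 0]
        mapped_total = sum(s.mapped for s in stats)

    sset = SignatureSet(sample=sample or Path(path).name)
    if mapped_total == 0:
        warnings.warn(f"{path} contains no mapped reads; empty signature set")
        return sset.finalize()

    args = (min_mapq, min_sv_size, max_sv_size, merge_gap, ins_anchor_dist)
    if threads > 1 and len(chroms) > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(
                pool.map(lambda c: _extract_chrom(path, c, *args), chroms)
            )
    else:
        results = [_extract_chrom(path, c, *args) for c in chroms]

    fallback: List[AlignedSegmentView] = []
    sa_ids: Set[str] = set()
    for sigs, fb, ids in results:
        sset.extend(sigs)
        fallback.extend(fb)
        sa_ids.update(ids)

    # SA-less split reads: group remaining clipped records by read name
    by_read: dict = {}
    for v in fallback:
        if v.read_id not in sa_ids:
            by_read.setdefault(v.read_id, []).append(v)
    for read_id in sorted(by_read):
        views = by_read[read_id]
        if len(views) >= 2:
            sset.extend(
                parse_split_signatures(views, min_sv_size, max_sv_size, ins_anchor_dist)
            )
    return sset.finalize()


# ---------------------------------------------------------------------------
# read counting at breakpoints
# ---------------------------------------------------------------------------

def spanning_read_count(alignment_file, chrom: str, pos: int, min_mapq: int = 20) -> int:
    """Distinct reads whose primary alignment covers ``pos`` at ``min_mapq``."""
    close = False
    if isinstance(alignment_file, pysam.AlignmentFile):
        aln = alignment_file
    else:
        aln = _open_alignment(str(alignment_file))
        close = True
    try:
        if chrom not in aln.references:
            warnings.warn(f"chromosome {chrom!r} absent from alignment header")
            return 0
        _require_index(aln, alignment_file)
        ids = set()
        for read in aln.fetch(chrom, max(0, pos), pos + 1):
            if (
                not read.is_unmapped
                and not read.is_secondary
                and not read.is_supplementary
                and not read.is_duplicate
                and read.mapping_quality >= min_mapq
                and read.reference_start <= pos < read.reference_end
            ):
                ids.add(read.query_name)
        return len(ids)
    finally:
        if close:
            aln.close()


def crossing_read_ids(
    aln: pysam.AlignmentFile, chrom: str, pos: int, min_mapq: int = 20
) -> Set[str]:
    """Reads whose primary alignment crosses strictly through ``pos``.

    A read clipped or split exactly at ``pos`` does not cross: crossing
    requires aligned reference bases on both sides of the junction
    (ref_start < pos < ref_end). Gapped-signature reads cross via their
    deletion run, so supporters must be removed by read id by the caller.
    """
    if chrom not in aln.references:
        return set()
    ids = set()
    if pos <= 0:
        return ids
    for read in aln.fetch(chrom, pos - 1, pos + 1):
        if (
            not read.is_unmapped
            and not read.is_secondary
            and not read.is_supplementary
            and not read.is_duplicate
            and read.mapping_quality >= min_mapq
            and read.reference_start < pos < read.reference_end
        ):
            ids.add(read.query_name)
    return ids
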