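"""VCF 4.2 emission of germline/somatic calls and truth-set reading.

Internal coordinates are 0-based half-open; this module is the only place
where the 1-based VCF convention appears. Deletions, insertions,
duplications and inversions are written as symbolic-allele records;
translocations as mated BND pairs.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import pysam

from .model import GenotypeCall, SomaticCall, SvCluster, TruthRecord

_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based, inclusive)">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed SV length">',
    '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads (cluster size)">',
    '##INFO=<ID=COHESION,Number=1,Type=Float,Description="Edge density of the signature cluster">',
    '##INFO=<ID=STDEV_POS,Number=1,Type=Float,Description="Standard deviation of member start coordinates">',
    '##INFO=<ID=STDEV_END,Number=1,Type=Float,Description="Standard deviation of member end coordinates">',
    '##INFO=<ID=PVAL,Number=1,Type=Float,Description="Somatic Fisher exact p-value">',
    '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">',
    '##FILTER=<ID=notsomatic,Description="Fisher p-value above the somatic alpha">',
    '##FILTER=<ID=lowqual,Description="Low genotype quality">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality (phred)">',
    '##FORMAT=<ID=DV,Number=1,Type=Integer,Description="Variant-supporting reads">',
    '##FORMAT=<ID=DR,Number=1,Type=Integer,Description="Reference-supporting reads">',
]

_ALT_LINES = [
    '##ALT=<ID=DEL,Description="Deletion">',
    '##ALT=<ID=INS,Description="Insertion">',
    '##ALT=<ID=DUP,Description="Tandem duplication">',
    '##ALT=<ID=INV,Description="Inversion">',
]


def _fmt_sample(gt: Optional[GenotypeCall]) -> str:
    if gt is None or gt.gt == "./.":
        return "./.:0:0:0"
    return f"{gt.gt}:{gt.gq}:{gt.v}:{gt.n - gt.v}"


def _bnd_alt(strand_pair: str, mate_chrom: str, mate_pos1: int) -> str:
    s1, s2 = strand_pair[0], strand_pair[1]
    br = "[" if s2 == "+" else "]"
    mate = f"{br}{mate_chrom}:{mate_pos1}{br}"
    return f"N{mate}" if s1 == "+" else f"{mate}N"


def _cluster_info(c: SvCluster, extra: str = "") -> str:
    info = (
        f"SUPPORT={c.support};COHESION={c.cohesion:.4f};"
        f"STDEV_POS={c.start_sd:.2f};STDEV_END={c.end_sd:.2f}"
    )
    return info + extra


def _records_for_call(
    c: SvCluster,
    gt: Optional[GenotypeCall],
    idx: int,
    qual: str,
    filt: str,
    extra_info: str = "",
) -> List[Tuple[str, int, str]]:
    """(chrom, pos0, line-without-chrom/pos) tuples; POS added at write time."""
    sample = _fmt_sample(gt)
    if c.svtype == "TRA":
        sp = c.strand_pair or "++"
        id1, id2 = f"SV{idx}_1", f"SV{idx}_2"
        alt1 = _bnd_alt(sp, c.chrom2, c.pos2 + 1)
        sp_rev = {"+": "-", "-": "+"}
        alt2 = _bnd_alt(sp_rev[sp[1]] + sp_rev[sp[0]], c.chrom, c.start + 1)
        base = _cluster_info(c, extra_info)
        rec1 = (
            c.chrom, c.start,
            f"{id1}\tN\t{alt1}\t{qual}\t{filt}\t"
            f"SVTYPE=BND;MATEID={id2};{base}\tGT:GQ:DV:DR\t{sample}",
        )
        rec2 = (
            c.chrom2, c.pos2,
            f"{id2}\tN\t{alt2}\t{qual}\t{filt}\t"
            f"SVTYPE=BND;MATEID={id1};{base}\tGT:GQ:DV:DR\t{sample}",
        )
        return [rec1, rec2]
    if c.svtype == "INS":
        end1 = c.start + 1  # END = POS for insertions
        svlen = c.length
    else:
        end1 = c.end
        svlen = -(c.end - c.start) if c.svtype == "DEL" else (c.end - c.start)
    info = (
        f"SVTYPE={c.svtype};END={end1};SVLEN={svlen};" + _cluster_info(c, extra_info)
    )
    return [
        (
            c.chrom, c.start,
            f"SV{idx}\tN\t<{c.svtype}>\t{qual}\t{filt}\t{info}\tGT:GQ:DV:DR\t{sample}",
        )
    ]


def write_vcf(
    calls,
    out_path,
    mode: str = "germline",
    sample_name: str = "SAMPLE",
    contigs: Optional[Sequence[Tuple[str, int]]] = None,
    alpha: float = 0.001,
    emit_all: bool = False,
) -> None:
    """Write calls as VCF 4.2.

    ``calls`` is a list of ``(SvCluster, GenotypeCall)`` pairs in germline
    mode, or of :class:`SomaticCall` in somatic mode (where records failing
    the somatic alpha are dropped unless ``emit_all``).
    """
    if mode not in ("germline", "somatic"):
        raise ValueError("mode must be 'germline' or 'somatic'")

    records: List[Tuple[str, int, str]] = []
    seen_chroms: List[str] = []
    idx = 0
    for call in calls:
        idx += 1
        if mode == "germline":
            cluster, gt = call
            qual = str(gt.gq) if gt.gt != "./." else "."
            recs = _records_for_call(cluster, gt, idx, qual, "PASS")
        else:
            cluster = call.cluster
            if not call.is_somatic and not emit_all:
                continue
            q = min(999, round(-10 * math.log10(max(call.p_value, 1e-300))))
            filt = "PASS" if call.is_somatic else "notsomatic"
            recs = _records_for_call(
                cluster, call.genotype, idx, str(q), filt,
                extra_info=f";PVAL={call.p_value:.6g}",
            )
        records.extend(recs)
        for chrom, *_ in recs:
            if chrom not in seen_chroms:
                seen_chroms.append(chrom)

    if contigs is None:
        contigs = [(c, None) for c in sorted(seen_chroms)]
    contig_order = {name: i for i, (name, _) in enumerate(contigs)}
    records.sort(key=lambda r: (contig_order.get(r[0], len(contig_order)), r[1]))

    with open(out_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=svclique\n")
        for name, length in contigs:
            if length:
                fh.write(f"##contig=<ID={name},length={length}>\n")
            else:
                fh.write(f"##contig=<ID={name}>\n")
        for line in _ALT_LINES + _HEADER_LINES:
            fh.write(line + "\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample_name}\n"
        )
        for chrom, pos0, rest in records:
            fh.write(f"{chrom}\t{pos0 + 1}\t{rest}\n")


# ---------------------------------------------------------------------------
# truth / call reading
# ---------------------------------------------------------------------------

_SVTYPES = {"DEL", "INS", "DUP", "INV", "TRA", "BND"}
_BND_TOKENS = ("[", "]")


def _parse_bnd_mate(alt: str) -> Tuple[str, int, str]:
    """(mate_chrom, mate_pos0, strand_pair) from a BND ALT string."""
    for br in _BND_TOKENS:
        if br in alt:
            inner = alt.split(br)[1]
            chrom, pos = inner.rsplit(":", 1)
            s1 = "+" if alt[0] not in _BND_TOKENS else "-"
            s2 = "+" if br == "[" else "-"
            return chrom, int(pos) - 1, s1 + s2
    raise ValueError(f"unparseable BND ALT {alt!r}")


def _truth_from_tsv(path) -> List[TruthRecord]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 columns")
            chrom, start, end, svtype, gt, somatic = fields[:6]
            if svtype not in _SVTYPES:
                raise ValueError(f"{path}:{lineno}: unknown svtype {svtype!r}")
            try:
                start, end = int(start), int(end)
                somatic_flag = bool(int(somatic))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            length = int(fields[6]) if len(fields) > 6 and fields[6] != "." else end - start
            chrom2 = fields[7] if len(fields) > 7 and fields[7] != "." else None
            pos2 = int(fields[8]) if len(fields) > 8 and fields[8] != "." else None
            out.append(
                TruthRecord(chrom, start, end, svtype, length, gt, somatic_flag,
                            chrom2=chrom2, pos2=pos2)
            )
    return out


def _truth_from_vcf(path) -> List[TruthRecord]:
    out = []
    seen_mates = set()
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            svtype = rec.info.get("SVTYPE")
            if svtype is None:
                continue
            somatic = "PVAL" in rec.info and "PASS" in rec.filter
            gt = "./."
            if rec.samples:
                s = rec.samples[0]
                if s.get("GT") and None not in s["GT"]:
                    gt = "/".join(str(a) for a in s["GT"])
            if svtype == "BND":
                if rec.id in seen_mates:
                    continue
                mate = rec.info.get("MATEID")
                if mate:
                    seen_mates.add(mate)
                chrom2, pos2, _ = _parse_bnd_mate(str(rec.alts[0]))
                out.append(
                    TruthRecord(rec.chrom, rec.pos - 1, rec.pos, "TRA", 1, gt,
                                somatic, chrom2=chrom2, pos2=pos2)
                )
                continue
            start = rec.pos - 1
            svlen = rec.info.get("SVLEN")
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            if svtype == "INS":
                end = start
                length = abs(svlen or 0)
            else:
                # htslib rewrites rlen/stop for symbolic alleles from SVLEN,
                # so reconstruct the span from SVLEN directly when present
                end = start + abs(svlen) if svlen else rec.stop
                length = end - start
            out.append(TruthRecord(rec.chrom, start, end, svtype, length, gt, somatic))
    return out


def read_truth(path) -> List[TruthRecord]:
    """Read a truth/call set from VCF or the BED-like TSV defined here,
    normalized to 0-based half-open records."""
    path = Path(path)
    if path.suffix in (".vcf", ".bcf") or str(path).endswith(".vcf.gz"):
        return _truth_from_vcf(path)
    return _truth_from_tsv(path)
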