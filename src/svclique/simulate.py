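"""Synthetic long-read alignment fixtures with implanted SVs.

The generator works at the alignment level: instead of simulating bases
and re-aligning them, it places reads on each haplotype and writes the
alignment records (CIGAR gaps, primary/supplementary splits with SA tags)
that a long-read aligner would produce over the implanted events. Noisy
alignment of real long reads is modeled directly by jittering breakpoints
per signature (``jitter_sd``) and by injecting spurious gapped signatures
at a per-read rate (``noise_signature_rate``).

Deletions and insertions below ``split_threshold`` (1 kb) produce gapped
CIGAR signatures, larger ones split alignments; duplications, inversions
and translocations always split. Heterozygous events are carried by one of
two haplotypes, with haplotype labels alternating along the chromosome so
allelic sampling is balanced at fixture scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .model import TruthRecord

SPLIT_THRESHOLD = 1000  # DEL/INS at or above this size produce split records
MARGIN = 200  # minimum aligned flank around a junction, bp


class SimConfigError(ValueError):
    pass


@dataclass
class SvSpec:
    """One event to implant. Positions may be left for auto-placement."""

    svtype: str
    size: int
    zygosity: str = "het"  # "het" | "hom"
    somatic: bool = False
    chrom: Optional[str] = None
    pos: Optional[int] = None
    chrom2: Optional[str] = None
    pos2: Optional[int] = None


@dataclass
class SimConfig:
    genome: Sequence[Tuple[str, int]] = (("chr1", 5_000_000),)
    coverage: float = 20.0
    read_length_mean: int = 10_000
    sv_spec: Sequence[SvSpec] = ()
    jitter_sd: float = 10.0
    noise_signature_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.coverage <= 0:
            raise SimConfigError("coverage must be positive")
        if not self.genome:
            raise SimConfigError("genome must contain at least one chromosome")
        for ev in self.sv_spec:
            if ev.svtype != "TRA" and ev.size < 50:
                raise SimConfigError("SV sizes must be >= 50 bp")
            if ev.svtype == "TRA" and len(self.genome) < 2:
                raise SimConfigError("translocations require >= 2 chromosomes")


@dataclass
class PlacedEvent:
    svtype: str
    chrom: str
    start: int
    end: int
    size: int
    zygosity: str
    somatic: bool
    chrom2: Optional[str] = None
    pos2: Optional[int] = None

    def truth(self) -> TruthRecord:
        gt = "0/1" if self.zygosity == "het" else "1/1"
        return TruthRecord(
            chrom=self.chrom,
            start=self.start,
            end=self.end,
            svtype=self.svtype,
            length=self.size,
            genotype=gt,
            somatic=self.somatic,
            chrom2=self.chrom2,
            pos2=self.pos2,
        )


@dataclass
class SimResult:
    test_sam: str
    control_sam: str
    truth_path: str
    truth: List[TruthRecord]
    config: SimConfig


# ---------------------------------------------------------------------------
# event placement
# ---------------------------------------------------------------------------

def place_events(config: SimConfig) -> List[PlacedEvent]:
    """Assign genomic positions to the configured events.

    Events without explicit coordinates are spread evenly over the first
    chromosome (translocation partners over the last chromosome), keeping
    every pair separated by at least twice the largest event size plus two
    read lengths so no read touches two events.
    """
    genome = dict(config.genome)
    main_chrom, main_len = config.genome[0]
    tra_chrom, tra_len = config.genome[-1]
    events: List[PlacedEvent] = []

    auto = [ev for ev in config.sv_spec if ev.pos is None]
    explicit = [ev for ev in config.sv_spec if ev.pos is not None]
    max_size = max((ev.size for ev in config.sv_spec if ev.svtype != "TRA"), default=0)
    required_sep = 2 * max_size + 2 * config.read_length_mean

    margin = 50_000 if main_len > 200_000 else max(2 * config.read_length_mean, 20_000)
    usable = main_len - 2 * margin - max_size
    if auto:
        if usable <= 0 or (len(auto) > 1 and usable / (len(auto) - 1) < required_sep):
            raise SimConfigError(
                f"{len(auto)} events do not fit chromosome {main_chrom} "
                f"({main_len} bp) with separation {required_sep} bp"
            )
        anchors = np.linspace(margin, margin + usable, num=len(auto)).astype(int)
    else:
        anchors = []

    n_tra = sum(1 for ev in auto if ev.svtype == "TRA")
    tra_margin = min(50_000, tra_len // 5)
    tra_positions = (
        np.linspace(tra_margin, tra_len - tra_margin, num=max(n_tra, 1)).astype(int)
        if n_tra
        else []
    )
    tra_i = 0
    for ev, anchor in zip(auto, anchors):
        if ev.svtype == "TRA":
            events.append(
                PlacedEvent(
                    "TRA", main_chrom, int(anchor), int(anchor) + 1, 1,
                    ev.zygosity, ev.somatic,
                    chrom2=tra_chrom, pos2=int(tra_positions[tra_i]),
                )
            )
            tra_i += 1
        else:
            end = int(anchor) + (0 if ev.svtype == "INS" else ev.size)
            events.append(
                PlacedEvent(
                    ev.svtype, main_chrom, int(anchor), end, ev.size,
                    ev.zygosity, ev.somatic,
                )
            )
    for ev in explicit:
        if ev.chrom not in genome:
            raise SimConfigError(f"unknown chromosome {ev.chrom!r}")
        end = ev.pos + (0 if ev.svtype == "INS" else ev.size)
        if end + 2 * config.read_length_mean > genome[ev.chrom]:
            raise SimConfigError(f"event at {ev.chrom}:{ev.pos} does not fit")
        events.append(
            PlacedEvent(
                ev.svtype, ev.chrom, ev.pos, end,
                1 if ev.svtype == "TRA" else ev.size,
                ev.zygosity, ev.somatic, chrom2=ev.chrom2, pos2=ev.pos2,
            )
        )
    events.sort(key=lambda e: (e.chrom, e.start))
    for a, b in zip(events, events[1:]):
        if a.chrom == b.chrom and b.start - a.end < required_sep:
            raise SimConfigError(
                f"events at {a.chrom}:{a.start} and {b.chrom}:{b.start} are "
                f"closer than the required separation ({required_sep} bp)"
            )
    return events


# ---------------------------------------------------------------------------
# per-read record construction
# ---------------------------------------------------------------------------

@dataclass
class _Rec:
    chrom: str
    pos: int
    cigar: str
    reverse: bool = False
    supplementary: bool = False
    sa: Optional[str] = None


_CIG_PART = __import__("re").compile(r"(-?\d+)([MIDS])")


def _valid_cigar(cigar: str) -> bool:
    """All op lengths positive and at least one aligned (M) base.

    Jitter can push a junction past a read end, producing zero or negative
    segment lengths; such records are rejected and the read falls back to a
    plain reference alignment.
    """
    parts = _CIG_PART.findall(cigar)
    return (
        bool(parts)
        and all(int(n) > 0 for n, _ in parts)
        and any(op == "M" for _, op in parts)
    )


def _one(chrom: str, pos: int, cigar: str, reverse: bool = False) -> Optional[List[_Rec]]:
    if pos < 0 or not _valid_cigar(cigar):
        return None
    return [_Rec(chrom, pos, cigar, reverse)]


def _split_pair(
    chrom1: str, pos1: int, cig1: str, chrom2: str, pos2: int, cig2: str,
    rev1: bool = False, rev2: bool = False,
) -> Optional[List[_Rec]]:
    if min(pos1, pos2) < 0 or not (_valid_cigar(cig1) and _valid_cigar(cig2)):
        return None
    s1 = "-" if rev1 else "+"
    s2 = "-" if rev2 else "+"
    sa1 = f"{chrom2},{pos2 + 1},{s2},{cig2},60,0;"
    sa2 = f"{chrom1},{pos1 + 1},{s1},{cig1},60,0;"
    return [
        _Rec(chrom1, pos1, cig1, rev1, False, sa1),
        _Rec(chrom2, pos2, cig2, rev2, True, sa2),
    ]


def _jit(rng, sd: float) -> int:
    return int(round(rng.normal(0.0, sd))) if sd > 0 else 0


def _reads_for_event(
    ev: PlacedEvent, p: int, rl: int, rng, jitter_sd: float
) -> Optional[List[_Rec]]:
    """Alignment records for an ALT-haplotype read anchored at reference
    position ``p``; None means the read does not interact with the event."""
    s, e, size = ev.start, ev.end, ev.size
    m = MARGIN

    if ev.svtype == "DEL":
        if p >= s:
            return None
        left = s - p
        if left >= rl:
            return None
        s_, e_ = s + _jit(rng, jitter_sd), e + _jit(rng, jitter_sd)
        left_ = s_ - p
        right_ = rl - left_
        if left_ < 1 or right_ < 1 or e_ <= s_:
            return None
        if left_ < m:
            return _one(ev.chrom, e_, f"{left_}S{right_}M")
        if right_ < m:
            return _one(ev.chrom, p, f"{left_}M{right_}S")
        if size < SPLIT_THRESHOLD:
            return _one(ev.chrom, p, f"{left_}M{e_ - s_}D{right_}M")
        return _split_pair(
            ev.chrom, p, f"{left_}M{right_}S", ev.chrom, e_, f"{left_}S{right_}M"
        )

    if ev.svtype == "INS":
        if p >= s:
            return None
        left = s - p
        if left >= rl:
            return None
        s_ = s + _jit(rng, jitter_sd)
        size_ = max(50, size + _jit(rng, jitter_sd))
        left_ = s_ - p
        right_ = rl - left_ - size_
        if left_ < 1:
            return None
        if left_ < m:
            if right_ < m:
                return None
            return _one(ev.chrom, s_, f"{rl - right_}S{right_}M")
        if right_ < m:
            return _one(ev.chrom, p, f"{left_}M{rl - left_}S")
        if size < SPLIT_THRESHOLD:
            return _one(ev.chrom, p, f"{left_}M{size_}I{right_}M")
        return _split_pair(
            ev.chrom, p, f"{left_}M{rl - left_}S",
            ev.chrom, s_, f"{left_ + size_}S{right_}M",
        )

    if ev.svtype == "DUP":
        # tandem duplication: junction from end of the unit back to its start
        if p >= e:
            return None
        left = e - p
        if left >= rl:
            return None
        s_, e_ = s + _jit(rng, jitter_sd), e + _jit(rng, jitter_sd)
        left_ = e_ - p
        right_ = rl - left_
        if left_ < 1 or right_ < 1 or e_ <= s_:
            return None
        if left_ < m:
            return _one(ev.chrom, s_, f"{left_}S{right_}M")
        if right_ < m:
            return _one(ev.chrom, p, f"{left_}M{right_}S")
        return _split_pair(
            ev.chrom, p, f"{left_}M{right_}S", ev.chrom, s_, f"{left_}S{right_}M"
        )

    if ev.svtype == "INV":
        if p + rl <= s or p >= e:
            return None
        s_, e_ = s + _jit(rng, jitter_sd), e + _jit(rng, jitter_sd)
        if e_ <= s_:
            return None
        if p <= s_ - m and p + rl >= e_ + m:
            left = s_ - p
            mid = e_ - s_
            right = rl - left - mid
            if right < 1:
                return None
            return _split_pair(
                ev.chrom, p, f"{left}M{rl - left}S",
                ev.chrom, s_, f"{right}S{mid}M{left}S",
                rev1=False, rev2=True,
            )
        if p >= s_ and p + rl <= e_:
            # fully inside: maps contiguously onto the mirrored interval
            start = s_ + e_ - p - rl
            if start < 0:
                return None
            return _one(ev.chrom, start, f"{rl}M", reverse=True)
        if p < s_ < p + rl:
            left = s_ - p
            if left < m:
                return None
            return _one(ev.chrom, p, f"{left}M{rl - left}S")
        if p < e_ < p + rl:
            tail = p + rl - e_
            if tail < m:
                return None
            return _one(ev.chrom, e_, f"{rl - tail}S{tail}M")
        return None

    if ev.svtype == "TRA":
        bp1 = ev.start
        if p >= bp1:
            return None
        left = bp1 - p
        if left >= rl:
            return None
        bp1_ = bp1 + _jit(rng, jitter_sd)
        bp2_ = ev.pos2 + _jit(rng, jitter_sd)
        left_ = bp1_ - p
        right_ = rl - left_
        if left_ < 1 or right_ < 1 or bp2_ < 0:
            return None
        if left_ < m:
            return _one(ev.chrom2, bp2_, f"{left_}S{right_}M")
        if right_ < m:
            return _one(ev.chrom, p, f"{left_}M{right_}S")
        return _split_pair(
            ev.chrom, p, f"{left_}M{right_}S",
            ev.chrom2, bp2_, f"{left_}S{right_}M",
        )

    raise SimConfigError(f"unknown svtype {ev.svtype!r}")


def _noise_records(chrom: str, p: int, rl: int, rng) -> List[_Rec]:
    """A spurious small gapped signature inside an otherwise plain read."""
    size = int(rng.integers(50, 200))
    offset = int(rng.integers(MARGIN, rl - MARGIN - size))
    if rng.random() < 0.5:
        return [_Rec(chrom, p, f"{offset}M{size}D{rl - offset}M")]
    return [_Rec(chrom, p, f"{offset}M{size}I{rl - offset - size}M")]


# ---------------------------------------------------------------------------
# sample generation
# ---------------------------------------------------------------------------

def _sample_records(
    config: SimConfig, events: List[PlacedEvent], rng
) -> List[Tuple[str, str, _Rec]]:
    """(read_id, chrom, record) triples for one sample."""
    out: List[Tuple[str, str, _Rec]] = []
    by_chrom: dict = {}
    for ev in events:
        by_chrom.setdefault(ev.chrom, []).append(ev)

    for chrom, length in config.genome:
        chrom_events = sorted(by_chrom.get(chrom, []), key=lambda e: e.start)
        n_reads = int(round(config.coverage * length / config.read_length_mean))
        starts = np.sort(rng.integers(0, max(1, length - 500), size=n_reads))
        lengths = np.clip(
            rng.normal(config.read_length_mean, config.read_length_mean * 0.1, n_reads),
            500, None,
        ).astype(int)
        for i in range(n_reads):
            p = int(starts[i])
            rl = int(min(lengths[i], length - p))
            if rl < 500:
                continue
            hap = i % 2
            read_id = f"{chrom}_{i:06d}"
            recs = None
            for ev in chrom_events:
                if ev.start - 2 * config.read_length_mean > p + rl:
                    break
                carried = ev.zygosity == "hom" or hap == 1
                if not carried:
                    continue
                recs = _reads_for_event(ev, p, rl, rng, config.jitter_sd)
                if recs is not None:
                    break
            if recs is None:
                if (
                    config.noise_signature_rate > 0
                    and rl >= 2 * MARGIN + 300
                    and rng.random() < config.noise_signature_rate
                ):
                    recs = _noise_records(chrom, p, rl, rng)
                else:
                    recs = [_Rec(chrom, p, f"{rl}M")]
            out.append((read_id, chrom, recs[0]))
            for r in recs[1:]:
                out.append((read_id, r.chrom, r))
    return out


def _write_sam(path, config: SimConfig, triples) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in config.genome],
    }
    tid = {name: i for i, (name, _) in enumerate(config.genome)}
    rows = []
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for read_id, chrom, rec in triples:
            a = pysam.AlignedSegment(out.header)
            a.query_name = read_id
            a.reference_id = tid[rec.chrom]
            a.reference_start = rec.pos
            a.mapping_quality = 60
            a.cigarstring = rec.cigar
            flag = 0
            if rec.reverse:
                flag |= 0x10
            if rec.supplementary:
                flag |= 0x800
            a.flag = flag
            if rec.sa:
                a.set_tag("SA", rec.sa)
            rows.append((a.reference_id, a.reference_start, a.query_name, a))
        rows.sort(key=lambda t: t[:3])
        for *_, a in rows:
            out.write(a)


def write_truth_tsv(truth: Sequence[TruthRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tsvtype\tgenotype\tsomatic\tlength\tchrom2\tpos2\n")
        for t in truth:
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.svtype}\t{t.genotype}\t"
                f"{1 if t.somatic else 0}\t{t.length}\t"
                f"{t.chrom2 or '.'}\t{t.pos2 if t.pos2 is not None else '.'}\n"
            )


def simulate_pair(config: SimConfig, outdir) -> SimResult:
    """Write a test/control SAM pair plus the truth table.

    Somatic events appear only in the test sample; everything else is
    shared. With a fixed seed the output files are byte-identical across
    runs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    events = place_events(config)
    germline = [ev for ev in events if not ev.somatic]

    seq = np.random.SeedSequence(config.seed)
    rng_test, rng_ctrl = [np.random.default_rng(s) for s in seq.spawn(2)]

    test_sam = outdir / "test.sam"
    control_sam = outdir / "control.sam"
    _write_sam(test_sam, config, _sample_records(config, events, rng_test))
    _write_sam(control_sam, config, _sample_records(config, germline, rng_ctrl))

    truth = [ev.truth() for ev in events]
    truth_path = outdir / "truth.tsv"
    write_truth_tsv(truth, truth_path)
    return SimResult(str(test_sam), str(control_sam), str(truth_path), truth, config)


def downsample(sam_in, sam_out, fraction: float, seed: int = 0) -> None:
    """Keep each read (all its records together) with probability ``fraction``."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    decisions: dict = {}
    with pysam.AlignmentFile(str(sam_in), "r") as fin, pysam.AlignmentFile(
        str(sam_out), "wh", template=fin
    ) as fout:
        for read in fin.fetch(until_eof=True):
            keep = decisions.get(read.query_name)
            if keep is None:
                keep = bool(rng.random() < fraction)
                decisions[read.query_name] = keep
            if keep:
                fout.write(read)


# ---------------------------------------------------------------------------
# canonical benchmark configurations (the study conditions)
# ---------------------------------------------------------------------------

def germline_benchmark_spec() -> List[SvSpec]:
    """20 germline events, 4 per subtype, sizes 100 bp - 5 kb, het/hom mix.

    All duplications are heterozygous: the junction allele fraction of a
    homozygous tandem duplication is ~2/3 (diluted by reads from the extra
    copy) and is not separable from 0/1 by junction evidence alone.
    """
    spec = [
        SvSpec("DEL", 100, "het"), SvSpec("DEL", 500, "hom"),
        SvSpec("DEL", 2000, "het"), SvSpec("DEL", 5000, "hom"),
        SvSpec("INS", 100, "hom"), SvSpec("INS", 300, "het"),
        SvSpec("INS", 1000, "het"), SvSpec("INS", 5000, "hom"),
        SvSpec("DUP", 200, "het"), SvSpec("DUP", 500, "het"),
        SvSpec("DUP", 1500, "het"), SvSpec("DUP", 5000, "het"),
        SvSpec("INV", 200, "het"), SvSpec("INV", 500, "hom"),
        SvSpec("INV", 1500, "het"), SvSpec("INV", 5000, "hom"),
        SvSpec("TRA", 1, "het"), SvSpec("TRA", 1, "hom"),
        SvSpec("TRA", 1, "het"), SvSpec("TRA", 1, "hom"),
    ]
    return spec


def germline_benchmark_config(
    coverage: float = 20.0, jitter_sd: float = 0.0, seed: int = 0
) -> SimConfig:
    return SimConfig(
        genome=(("chr1", 5_000_000), ("chr2", 1_000_000)),
        coverage=coverage,
        sv_spec=germline_benchmark_spec(),
        jitter_sd=jitter_sd,
        noise_signature_rate=0.0,
        seed=seed,
    )


def somatic_benchmark_spec() -> List[SvSpec]:
    """10 tumor-only heterozygous events plus 10 shared germline events.

    Tumor-only events are junction-rich types/sizes so every supporting
    read observes the full junction; shared events mix zygosities.
    """
    tumor_only = [
        SvSpec("DEL", 120, "het", somatic=True),
        SvSpec("DEL", 400, "het", somatic=True),
        SvSpec("DEL", 1500, "het", somatic=True),
        SvSpec("DEL", 3000, "het", somatic=True),
        SvSpec("INS", 150, "het", somatic=True),
        SvSpec("INS", 400, "het", somatic=True),
        SvSpec("INS", 800, "het", somatic=True),
        SvSpec("DUP", 600, "het", somatic=True),
        SvSpec("INV", 800, "het", somatic=True),
        SvSpec("TRA", 1, "het", somatic=True),
    ]
    shared = [
        SvSpec("DEL", 200, "het"), SvSpec("DEL", 1000, "hom"),
        SvSpec("INS", 300, "het"), SvSpec("INS", 600, "hom"),
        SvSpec("DUP", 400, "het"), SvSpec("DUP", 800, "het"),
        SvSpec("INV", 300, "hom"), SvSpec("INV", 2000, "het"),
        SvSpec("TRA", 1, "het"), SvSpec("TRA", 1, "hom"),
    ]
    # interleave so tumor-only and shared events alternate along the chromosome
    out = []
    for a, b in zip(tumor_only, shared):
        out.extend((a, b))
    return out


def somatic_benchmark_config(
    coverage: float = 30.0, jitter_sd: float = 10.0, seed: int = 0
) -> SimConfig:
    return SimConfig(
        genome=(("chr1", 5_000_000), ("chr2", 1_000_000)),
        coverage=coverage,
        sv_spec=somatic_benchmark_spec(),
        jitter_sd=jitter_sd,
        noise_signature_rate=0.01,
        seed=seed,
    )


def shared_event_spec(n_events: int) -> List[SvSpec]:
    """n shared (germline) DEL/INS events for type-I-error replication."""
    sizes = (100, 200, 300, 500, 800)
    out = []
    for i in range(n_events):
        svtype = "DEL" if i % 2 == 0 else "INS"
        zyg = "het" if i % 4 < 2 else "hom"
        out.append(SvSpec(svtype, sizes[i % len(sizes)], zyg, somatic=False))
    return out


def tumor_only_event_spec(n_events: int) -> List[SvSpec]:
    """n tumor-only heterozygous DEL/INS events for power estimation."""
    sizes = (100, 150, 200, 300, 400, 600, 800)
    out = []
    for i in range(n_events):
        svtype = "DEL" if i % 2 == 0 else "INS"
        out.append(SvSpec(svtype, sizes[i % len(sizes)], "het", somatic=True))
    return out
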