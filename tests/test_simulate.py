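"""The synthetic alignment generator: determinism, fidelity, contracts."""

import pysam
import pytest

from svclique.signatures import ensure_indexed_bam, extract_signatures
from svclique.simulate import (
    SimConfig,
    SimConfigError,
    SvSpec,
    downsample,
    simulate_pair,
)


def tiny_config(**kw):
    defaults = dict(
        genome=(("chr1", 300_000),),
        coverage=10,
        sv_spec=[SvSpec("DEL", 500, "het", pos=150_000, chrom="chr1")],
        jitter_sd=0.0,
        noise_signature_rate=0.0,
        seed=0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def test_fixed_seed_gives_byte_identical_output(tmp_path):
    a = simulate_pair(tiny_config(), tmp_path / "a")
    b = simulate_pair(tiny_config(), tmp_path / "b")
    assert open(a.test_sam, "rb").read() == open(b.test_sam, "rb").read()
    assert open(a.control_sam, "rb").read() == open(b.control_sam, "rb").read()
    c = simulate_pair(tiny_config(seed=1), tmp_path / "c")
    assert open(a.test_sam, "rb").read() != open(c.test_sam, "rb").read()


def test_zero_jitter_signatures_hit_exact_truth_interval(small_del_bam, small_del_signatures):
    _, sim = small_del_bam
    truth = sim.truth[0]
    dels = small_del_signatures.group(("DEL", "chr1"))
    assert len(dels) >= 5
    for s in dels:
        assert (s.start, s.end) == (truth.start, truth.end)


def test_truth_table_lists_every_event(tmp_path):
    from svclique.simulate import germline_benchmark_config
    from svclique.vcf_io import read_truth

    cfg = germline_benchmark_config(coverage=20, jitter_sd=0, seed=9)
    sim = simulate_pair(cfg, tmp_path)
    truth = read_truth(sim.truth_path)
    assert len(truth) == 20
    by_type = {t: sum(1 for r in truth if r.svtype == t) for t in ("DEL", "INS", "DUP", "INV", "TRA")}
    assert all(v == 4 for v in by_type.values())

    bam = ensure_indexed_bam(sim.test_sam, tmp_path)
    sigs = extract_signatures(bam)
    assert len(sigs) / len(truth) >= 5  # >= 5 supporting signatures per event on average


def test_realized_coverage_close_to_configured(small_del_bam):
    bam, sim = small_del_bam
    genome_len = sum(l for _, l in sim.config.genome)
    total = 0
    with pysam.AlignmentFile(bam, "rb") as aln:
        for read in aln.fetch():
            if not read.is_supplementary:
                total += read.infer_read_length() or read.query_alignment_length
    assert total / genome_len == pytest.approx(sim.config.coverage, rel=0.10)


def test_sam_is_valid_sorted_with_consistent_sa_tags(small_del_bam):
    bam, _ = small_del_bam
    with pysam.AlignmentFile(bam, "rb") as aln:
        last = -1
        supplementary = {}
        primaries = {}
        for read in aln.fetch("chr1"):
            assert read.reference_start >= last
            last = read.reference_start
            if read.has_tag("SA"):
                (primaries if not read.is_supplementary else supplementary)[
                    read.query_name
                ] = read
        assert supplementary and primaries
        for name, prim in primaries.items():
            supp = supplementary[name]
            chrom, pos, strand, cigar, _, _ = prim.get_tag("SA").rstrip(";").split(",")
            assert (chrom, int(pos) - 1, cigar) == (
                supp.reference_name, supp.reference_start, supp.cigarstring,
            )


def test_event_spacing_violation_raises_before_writing(tmp_path):
    cfg = tiny_config(
        sv_spec=[SvSpec("DEL", 500, "het")] * 40  # cannot fit 300 kb
    )
    with pytest.raises(SimConfigError, match="separation|fit"):
        simulate_pair(cfg, tmp_path)
    assert not (tmp_path / "test.sam").exists()


def test_translocation_requires_two_chromosomes():
    with pytest.raises(SimConfigError, match="chromosomes"):
        tiny_config(sv_spec=[SvSpec("TRA", 1, "het")])


def test_sub_50bp_events_rejected():
    with pytest.raises(SimConfigError, match="50"):
        tiny_config(sv_spec=[SvSpec("DEL", 30, "het")])


class TestDownsample:
    def test_fraction_one_is_identity(self, small_del_bam, tmp_path):
        _, sim = small_del_bam
        out = tmp_path / "kept.sam"
        downsample(sim.test_sam, out, 1.0, seed=1)
        with pysam.AlignmentFile(sim.test_sam) as a, pysam.AlignmentFile(str(out)) as b:
            assert sum(1 for _ in a.fetch(until_eof=True)) == sum(
                1 for _ in b.fetch(until_eof=True)
            )

    def test_kept_count_within_binomial_interval(self, tmp_path):
        cfg = tiny_config(coverage=40, sv_spec=[], seed=5)
        sim = simulate_pair(cfg, tmp_path / "deep")
        out = tmp_path / "half.sam"
        downsample(sim.test_sam, out, 0.5, seed=2)
        with pysam.AlignmentFile(sim.test_sam) as a:
            n_in = len({r.query_name for r in a.fetch(until_eof=True)})
        with pysam.AlignmentFile(str(out)) as b:
            n_out = len({r.query_name for r in b.fetch(until_eof=True)})
        # binomial 99.9% interval around n_in/2
        sd = (n_in * 0.25) ** 0.5
        assert abs(n_out - n_in / 2) < 3.3 * sd

    def test_split_read_records_kept_or_dropped_together(self, small_del_bam, tmp_path):
        _, sim = small_del_bam
        out = tmp_path / "ds.sam"
        downsample(sim.test_sam, out, 0.5, seed=3)
        with pysam.AlignmentFile(str(out)) as aln:
            names = {}
            for read in aln.fetch(until_eof=True):
                names.setdefault(read.query_name, set()).add(read.is_supplementary)
        with pysam.AlignmentFile(sim.test_sam) as aln:
            full = {}
            for read in aln.fetch(until_eof=True):
                full.setdefault(read.query_name, set()).add(read.is_supplementary)
        for name, kinds in names.items():
            assert kinds == full[name]

    def test_invalid_fraction(self, small_del_bam, tmp_path):
        _, sim = small_del_bam
        with pytest.raises(ValueError):
            downsample(sim.test_sam, tmp_path / "x.sam", 0.0, seed=1)
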