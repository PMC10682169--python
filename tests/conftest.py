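"""Shared fixtures: synthetic alignment benchmarks generated at test time.

The heavyweight fixtures (full simulated pipelines) are session-scoped so
the end-to-end acceptance tests and the per-module tests share one run.
"""

from __future__ import annotations

import pytest

from svclique.config import RunConfig
from svclique.evaluate import match_and_score
from svclique.pipeline import run_germline, run_somatic
from svclique.signatures import ensure_indexed_bam, extract_signatures
from svclique.simulate import (
    SimConfig,
    SvSpec,
    germline_benchmark_config,
    simulate_pair,
    somatic_benchmark_config,
)
from svclique.vcf_io import read_truth


class PipelineRun:
    def __init__(self, sim, calls, truth, result):
        self.sim = sim
        self.calls = calls  # list of (SvCluster, GenotypeCall)
        self.truth = truth
        self.result = result  # EvalResult vs full truth

    @property
    def clusters(self):
        return [c for c, _ in self.calls]

    @property
    def genotypes(self):
        return [g for _, g in self.calls]


def _run_germline_benchmark(tmpdir, jitter_sd, seed, coverage=20.0):
    cfg = germline_benchmark_config(coverage=coverage, jitter_sd=jitter_sd, seed=seed)
    sim = simulate_pair(cfg, tmpdir)
    calls = run_germline(sim.test_sam, RunConfig(), workdir=tmpdir)
    truth = read_truth(sim.truth_path)
    result = match_and_score(
        [c for c, _ in calls], truth, call_genotypes=[g.gt for _, g in calls]
    )
    return PipelineRun(sim, calls, truth, result)


@pytest.fixture(scope="session")
def germline_exact(tmp_path_factory):
    """20-event germline benchmark at 20x with zero breakpoint jitter."""
    tmp = tmp_path_factory.mktemp("germline_exact")
    return _run_germline_benchmark(tmp, jitter_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def germline_jittered(tmp_path_factory):
    """Same benchmark with 10 bp breakpoint jitter per signature."""
    tmp = tmp_path_factory.mktemp("germline_jitter")
    return _run_germline_benchmark(tmp, jitter_sd=10.0, seed=3)


@pytest.fixture(scope="session")
def somatic_run(tmp_path_factory):
    """30x/30x tumor/normal benchmark: 10 tumor-only + 10 shared events."""
    tmp = tmp_path_factory.mktemp("somatic")
    cfg = somatic_benchmark_config(seed=2)
    sim = simulate_pair(cfg, tmp)
    calls = run_somatic(sim.test_sam, sim.control_sam, RunConfig(), workdir=tmp)
    truth = read_truth(sim.truth_path)
    return sim, calls, truth


@pytest.fixture(scope="session")
def small_del_bam(tmp_path_factory):
    """One heterozygous 3 kb deletion at 20x, zero jitter (split signatures)."""
    tmp = tmp_path_factory.mktemp("small_del")
    cfg = SimConfig(
        genome=(("chr1", 300_000),),
        coverage=20,
        sv_spec=[SvSpec("DEL", 3000, "het", pos=150_000, chrom="chr1")],
        jitter_sd=0.0,
        noise_signature_rate=0.0,
        seed=7,
    )
    sim = simulate_pair(cfg, tmp)
    bam = ensure_indexed_bam(sim.test_sam, tmp)
    return bam, sim


@pytest.fixture(scope="session")
def small_del_signatures(small_del_bam):
    bam, _ = small_del_bam
    return extract_signatures(bam)
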