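"""End-to-end germline and somatic calling pipelines.

Thin orchestration over the extraction, clustering, genotyping and somatic
modules; both entry points accept SAM or BAM input (SAM and unindexed BAM
are sorted/indexed into a working directory first) and return the in-memory
calls alongside writing a VCF when requested.
"""

from __future__ import annotations

import logging
import tempfile
from pathlib import Path
from typing import List, Optional, Tuple

import pysam

from .clustering import call_germline
from .config import RunConfig
from .genotyping import genotype_clusters
from .model import GenotypeCall, SomaticCall, SvCluster
from .signatures import ensure_indexed_bam, extract_signatures
from .somatic import call_somatic
from .vcf_io import write_vcf

logger = logging.getLogger("svclique")


def _prepare(path, workdir) -> str:
    return ensure_indexed_bam(path, workdir)


def _contigs(bam) -> list:
    with pysam.AlignmentFile(bam, "rb") as aln:
        return list(zip(aln.references, aln.lengths))


def _extract(bam, config: RunConfig, sample=None):
    return extract_signatures(
        bam,
        min_mapq=config.min_mapq,
        min_sv_size=config.min_sv_size,
        max_sv_size=config.max_sv_size,
        merge_gap=config.merge_gap,
        ins_anchor_dist=config.ins_anchor_dist,
        sample=sample,
        threads=config.threads,
    )


def run_germline(
    alignment,
    config: Optional[RunConfig] = None,
    out_vcf=None,
    sample_name: str = "SAMPLE",
    workdir=None,
) -> List[Tuple[SvCluster, GenotypeCall]]:
    """extract -> cluster -> genotype (-> VCF)."""
    config = config or RunConfig()
    logger.info("germline run, config %s: %s", config.digest(), config.to_json())
    with tempfile.TemporaryDirectory() as tmp:
        bam = _prepare(alignment, workdir or tmp)
        sigs = _extract(bam, config, sample=sample_name)
        clusters = call_germline(sigs, config)
        calls = genotype_clusters(
            clusters, bam, config.genotype_model(), config.min_mapq
        )
        if out_vcf is not None:
            write_vcf(
                calls, out_vcf, mode="germline", sample_name=sample_name,
                contigs=_contigs(bam),
            )
    return calls


def run_somatic(
    test_alignment,
    control_alignment,
    config: Optional[RunConfig] = None,
    out_vcf=None,
    sample_name: str = "TUMOR",
    emit_all: bool = False,
    workdir=None,
) -> List[SomaticCall]:
    """germline on the test sample -> control matching -> Fisher (-> VCF)."""
    config = config or RunConfig()
    logger.info("somatic run, config %s: %s", config.digest(), config.to_json())
    with tempfile.TemporaryDirectory() as tmp:
        control_bam = _prepare(control_alignment, workdir or tmp)
        test_bam = _prepare(test_alignment, workdir or tmp)
        test_sigs = _extract(test_bam, config, sample=sample_name)
        test_clusters = call_germline(test_sigs, config)
        control_sigs = _extract(control_bam, config, sample="CONTROL")
        calls = call_somatic(
            test_clusters, test_bam, control_bam, control_sigs, config
        )
        genotyped = genotype_clusters(
            [c.cluster for c in calls], test_bam, config.genotype_model(),
            config.min_mapq,
        )
        for call, (_, gt) in zip(calls, genotyped):
            call.genotype = gt
        if out_vcf is not None:
            write_vcf(
                calls, out_vcf, mode="somatic", sample_name=sample_name,
                contigs=_contigs(test_bam), alpha=config.alpha, emit_all=emit_all,
            )
    return calls
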