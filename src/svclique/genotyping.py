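"""Diploid genotyping of SV clusters.

A maximum-likelihood Bayesian classifier over three genotype states: the
number of variant-supporting reads v out of n informative reads at the
breakpoint is modeled as Binomial(n, p_g) with p = epsilon for 0/0,
0.5 for 0/1 and 1 - epsilon for 1/1, where epsilon is the signature
noise rate. Posteriors combine the binomial likelihoods with (by default
uniform) genotype priors; GQ is the phred-scaled probability that the
argmax genotype is wrong.
"""

from __future__ import annotations

import math
from typing import List, Sequence, Tuple

import pysam
from scipy.stats import binom

from .config import GenotypeModel
from .model import ContractViolation, GenotypeCall, SvCluster
from .signatures import _open_alignment, crossing_read_ids

_GT_LABELS = ("0/0", "0/1", "1/1")

NO_CALL = GenotypeCall(gt="./.", v=0, n=0, gq=0, posteriors=(0.0, 0.0, 0.0))


def genotype(v: int, n: int, model: GenotypeModel | None = None) -> GenotypeCall:
    """Genotype from v supporting out of n informative reads.

    Ties favour the genotype with smaller alternate-allele dosage. Raises
    on n = 0; callers emit ./. for uncovered loci.
    """
    model = model or GenotypeModel()
    if n < 1:
        raise ContractViolation("genotype requires n >= 1 (no-call otherwise)")
    if not 0 <= v <= n:
        raise ContractViolation("genotype requires 0 <= v <= n")
    probs = (model.epsilon, 0.5, 1.0 - model.epsilon)
    likes = [binom.pmf(v, n, p) for p in probs]
    weighted = [l * p for l, p in zip(likes, model.priors)]
    total = sum(weighted)
    if total == 0.0:  # numerically degenerate at extreme n: use log-space
        logs = [
            binom.logpmf(v, n, p) + math.log(pr)
            for p, pr in zip(probs, model.priors)
        ]
        m = max(logs)
        weighted = [math.exp(x - m) for x in logs]
        total = sum(weighted)
    post = tuple(w / total for w in weighted)
    best = max(range(3), key=lambda i: (post[i], -i))
    err = max(1.0 - post[best], 1e-10)
    gq = min(99, round(-10.0 * math.log10(err)))
    return GenotypeCall(gt=_GT_LABELS[best], v=v, n=n, gq=gq, posteriors=post)


def genotype_clusters(
    clusters: Sequence[SvCluster],
    alignment_file,
    model: GenotypeModel | None = None,
    min_mapq: int = 20,
) -> List[Tuple[SvCluster, GenotypeCall]]:
    """Attach a genotype to every cluster.

    v is the cluster support; n = v plus the number of distinct
    non-supporting reads whose primary alignment crosses straight through
    the start breakpoint (first breakpoint for translocations). Reads
    clipped or split exactly at the junction carry the variant and are not
    counted as reference evidence.
    """
    model = model or GenotypeModel()
    out = []
    with _open_alignment(str(alignment_file)) as aln:
        for cluster in clusters:
            v = cluster.support
            crossing = crossing_read_ids(aln, cluster.chrom, cluster.start, min_mapq)
            n = v + len(crossing - set(cluster.read_ids))
            if n < 1:
                out.append((cluster, NO_CALL))
            else:
                out.append((cluster, genotype(v, n, model)))
    return out
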