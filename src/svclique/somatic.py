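"""Somatic SV calling from a test/control (tumor/matched-normal) pair.

Clusters called in the test sample are compared against the raw signature
set of the control: control reads whose signatures still exceed the
similarity threshold against the cluster's median representation count as
variant evidence in the control. A one-sided Fisher's exact test on the
resulting 2x2 read table (variant/reference x test/control) scores each
cluster; p-values below alpha (default 0.001) are somatic.
"""

from __future__ import annotations

import warnings
from fractions import Fraction
from math import comb
from typing import List, Optional, Sequence, Set

from scipy.stats import fisher_exact as _scipy_fisher

from .config import NroParams, RunConfig
from .model import ContingencyTable, SomaticCall, SvCluster, SignatureSet
from .nro import similarity
from .signatures import _open_alignment, crossing_read_ids


def match_control_read_ids(
    cluster: SvCluster, control_set: SignatureSet, params: NroParams
) -> Set[str]:
    """Control read ids with >= 1 same-type signature matching the cluster."""
    rep = cluster.as_signature()
    ids: Set[str] = set()
    for sig in control_set.group(rep.group_key()):
        if sig.read_id in ids:
            continue
        if similarity(rep, sig, params) > params.nro_threshold:
            ids.add(sig.read_id)
    return ids


def match_control_signatures(
    cluster: SvCluster, control_set: SignatureSet, params: NroParams
) -> int:
    """Number of distinct control reads supporting the cluster's event."""
    return len(match_control_read_ids(cluster, control_set, params))


def fisher_exact_greater(table: ContingencyTable, two_sided: bool = False) -> float:
    """Fisher's exact p-value for the variant-read proportion being greater
    in the test sample than in the control (or two-sided on request).

    Degenerate margins (a sample with no reads) return p = 1 with a warning.
    """
    if table.n_vrt + table.n_rrt == 0 or table.n_vrc + table.n_rrc == 0:
        warnings.warn("degenerate contingency margin (sample with no reads); p = 1")
        return 1.0
    _, p = _scipy_fisher(
        [[table.n_vrt, table.n_rrt], [table.n_vrc, table.n_rrc]],
        alternative="two-sided" if two_sided else "greater",
    )
    return float(p)


def fisher_exact_oracle(table: ContingencyTable) -> float:
    """One-sided p by direct hypergeometric enumeration in exact rational
    arithmetic. Independent test oracle; not used by the pipeline."""
    a, b, c, d = table.n_vrt, table.n_rrt, table.n_vrc, table.n_rrc
    r1, r2 = a + b, c + d
    col1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0:
        return 1.0
    denom = comb(n, col1)
    total = Fraction(0)
    for k in range(a, min(r1, col1) + 1):
        if col1 - k <= r2:
            total += Fraction(comb(r1, k) * comb(r2, col1 - k), denom)
    return float(total)


def _bh_adjust(pvals: Sequence[float]) -> List[float]:
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, pvals[idx] * m / rank)
        adj[idx] = val
        prev = val
    return adj


def call_somatic(
    test_clusters: Sequence[SvCluster],
    test_alignment,
    control_alignment,
    control_set: SignatureSet,
    config: Optional[RunConfig] = None,
) -> List[SomaticCall]:
    """Score every test cluster for somatic status.

    Per cluster: N_VRT = support; N_RRT = non-supporting test reads crossing
    the start breakpoint; N_VRC = matched control reads; N_RRC = control
    reads crossing the breakpoint that are not matched as variant carriers.
    """
    config = config or RunConfig()
    params = config.control_nro_params()
    calls: List[SomaticCall] = []
    with _open_alignment(str(test_alignment)) as test_aln, _open_alignment(
        str(control_alignment)
    ) as ctrl_aln:
        for cluster in test_clusters:
            n_vrt = cluster.support
            test_cross = crossing_read_ids(
                test_aln, cluster.chrom, cluster.start, config.min_mapq
            )
            n_rrt = len(test_cross - set(cluster.read_ids))
            ctrl_ids = match_control_read_ids(cluster, control_set, params)
            n_vrc = len(ctrl_ids)
            ctrl_cross = crossing_read_ids(
                ctrl_aln, cluster.chrom, cluster.start, config.min_mapq
            )
            n_rrc = len(ctrl_cross - ctrl_ids)
            table = ContingencyTable(n_vrt, n_rrt, n_vrc, n_rrc)
            p = fisher_exact_greater(table, two_sided=config.two_sided)
            calls.append(SomaticCall(cluster, table, p, p < config.alpha))
    if config.bh_correction and calls:
        adjusted = _bh_adjust([c.p_value for c in calls])
        for call, q in zip(calls, adjusted):
            call.p_value = q
            call.is_somatic = q < config.alpha
    calls.sort(key=lambda c: (c.cluster.chrom, c.cluster.start, c.cluster.svtype))
    return calls
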