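"""From per-chromosome signature graphs to SV clusters.

Maximal cliques of the thresholded similarity graph are treated as
candidate events. Signatures shared between overlapping cliques are
resolved greedily (largest clique first), clusters whose median intervals
still exceed the similarity threshold are merged, and each surviving
cluster is summarized by median breakpoints plus dispersion and cohesion
statistics used for quality filtering.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from statistics import mean, pstdev
from typing import List, Sequence

import networkx as nx

from .config import NroParams, RunConfig
from .model import ContractViolation, SvCluster, SvSignature, SignatureSet
from .nro import build_graph, maximal_cliques, similarity


def _lower_median(values: Sequence[int]) -> int:
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def _mode(values: Sequence[int]) -> int:
    counts: dict = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    return min(v for v, c in counts.items() if c == best)


def _edge_count(graph: nx.Graph, nodes: Sequence[int]) -> int:
    nodeset = set(nodes)
    return sum(1 for u, v in graph.edges(nodeset) if u in nodeset and v in nodeset)


def _build_cluster(
    signatures: Sequence[SvSignature], members: Sequence[int], graph: nx.Graph
) -> SvCluster:
    sigs = [signatures[i] for i in members]
    svtype = sigs[0].svtype
    k = len(sigs)
    if svtype == "TRA":
        starts = [s.start for s in sigs]
        ends = [s.pos2 for s in sigs]
    else:
        starts = [s.start for s in sigs]
        ends = [s.end for s in sigs]
    length = _lower_median([s.length for s in sigs])
    start = _lower_median(starts)
    if svtype == "TRA":
        end, pos2 = start + 1, _lower_median(ends)
    elif svtype == "INS":
        end, pos2 = start, None
    else:
        end, pos2 = _lower_median(ends), None
        length = end - start if svtype != "INS" else length
    cohesion = 1.0 if k == 1 else _edge_count(graph, members) / (k * (k - 1) / 2)
    return SvCluster(
        svtype=svtype,
        chrom=sigs[0].chrom,
        start=start,
        end=end,
        length=length,
        support=len({s.read_id for s in sigs}),
        read_ids=frozenset(s.read_id for s in sigs),
        cohesion=cohesion,
        start_mean=mean(starts),
        start_mode=_mode(starts),
        start_sd=pstdev(starts),
        end_mean=mean(ends),
        end_mode=_mode(ends),
        end_sd=pstdev(ends),
        chrom2=sigs[0].chrom2,
        pos2=pos2,
        strand_pair=sigs[0].strand_pair,
        members=tuple(sorted(members)),
    )


def cliques_to_clusters(
    signatures: Sequence[SvSignature],
    cliques: Sequence,
    graph: nx.Graph,
    params: NroParams,
    min_support: int = 2,
) -> List[SvCluster]:
    """Resolve clique overlaps and summarize each surviving clique.

    Cliques are processed by descending size (ties: smaller median start
    first); each signature joins at most one cluster, and cliques falling
    below ``min_support`` after removal of already-used signatures are
    dropped. Clusters whose median intervals are still mutually similar
    above the threshold are then merged (this is where cohesion < 1 becomes
    informative: it is the edge density of the merged member set in the
    original graph).
    """
    n = len(signatures)
    for c in cliques:
        if any(i < 0 or i >= n for i in c):
            raise ContractViolation("clique references unknown signature index")

    def med_start(c):
        return _lower_median([signatures[i].start for i in c])

    ordered = sorted(cliques, key=lambda c: (-len(c), med_start(c), tuple(sorted(c))))
    used: set = set()
    clusters: List[SvCluster] = []
    for c in ordered:
        members = [i for i in sorted(c) if i not in used]
        if len(members) < min_support and len(members) < len(c):
            continue
        if not members:
            continue
        used.update(members)
        clusters.append(_build_cluster(signatures, members, graph))

    return _merge_similar(signatures, clusters, graph, params)


def _merge_similar(
    signatures: Sequence[SvSignature],
    clusters: List[SvCluster],
    graph: nx.Graph,
    params: NroParams,
) -> List[SvCluster]:
    if len(clusters) < 2:
        return clusters
    meta = nx.Graph()
    meta.add_nodes_from(range(len(clusters)))
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            s = similarity(
                clusters[i].as_signature(), clusters[j].as_signature(), params
            )
            if s > params.nro_threshold:
                meta.add_edge(i, j)
    out: List[SvCluster] = []
    for comp in nx.connected_components(meta):
        comp = sorted(comp)
        if len(comp) == 1:
            out.append(clusters[comp[0]])
        else:
            members = sorted({m for i in comp for m in clusters[i].members})
            out.append(_build_cluster(signatures, members, graph))
    out.sort(key=lambda c: (c.start, c.end, c.svtype))
    return out


def filter_clusters(
    clusters: Sequence[SvCluster],
    min_support: int = 2,
    max_sd: float = float("inf"),
    min_cohesion: float = 0.0,
) -> List[SvCluster]:
    """Quality filter on support, breakpoint dispersion, and cohesion."""
    return [
        c
        for c in clusters
        if c.support >= min_support
        and c.start_sd <= max_sd
        and c.end_sd <= max_sd
        and c.cohesion >= min_cohesion
    ]


def _call_group(sigs, params: NroParams, config: RunConfig) -> List[SvCluster]:
    graph = build_graph(sigs, params)
    cliques = maximal_cliques(graph)
    clusters = cliques_to_clusters(sigs, cliques, graph, params, config.min_support)
    return filter_clusters(
        clusters, config.min_support, config.max_sd, config.min_cohesion
    )


def call_germline(
    signature_set: SignatureSet, config: RunConfig | None = None
) -> List[SvCluster]:
    """Cluster every (svtype, chromosome) group — chromosome pair for
    translocations — and return the concatenated, canonically sorted calls.

    Deterministic for any thread count.
    """
    config = config or RunConfig()
    params = config.nro_params()
    groups = [sigs for _, sigs in signature_set.groups()]
    if config.threads > 1 and len(groups) > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            results = list(pool.map(lambda g: _call_group(g, params, config), groups))
    else:
        results = [_call_group(g, params, config) for g in groups]
    clusters = [c for r in results for c in r]
    clusters.sort(key=lambda c: (c.chrom, c.start, c.svtype, c.end))
    return clusters


def clusters_to_tsv(clusters: Sequence[SvCluster], path) -> None:
    """BED-like debugging dump (chrom, start, end, svtype, support, cohesion)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tsvtype\tsupport\tcohesion\n")
        for c in clusters:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.svtype}\t{c.support}\t{c.cohesion:.4f}\n"
            )
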