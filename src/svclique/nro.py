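"""Normalized reciprocal overlap (NRO), the thresholded signature graph,
and maximal-clique enumeration.

The similarity between two same-type signatures i and j is

    NRO_ij = 2*Overlap/(L_i + L_j) - (NO_i + NO_j)/NO_Norm

where L_i, L_j are the signature sizes, Overlap the size of their shared
span, NO_i/NO_j the sizes of their non-overlapping parts, and NO_Norm a
normalization constant (default 1000 bp). The first term is a symmetric
reciprocal-overlap ratio; the second penalizes absolute disagreement, which
is what lets a single threshold work for both 100 bp and multi-kb events.

Insertions are compared on the pseudo-interval [start, start+length);
translocations on a pair of fixed-width windows around the two breakpoints,
taking the worse (minimum) of the two window similarities.
"""

from __future__ import annotations

from itertools import combinations
from typing import List, Sequence, Set

import networkx as nx

from .config import NroParams
from .model import ContractViolation, SvSignature


def _interval_nro(s1: int, e1: int, s2: int, e2: int, no_norm: float) -> float:
    l1 = e1 - s1
    l2 = e2 - s2
    overlap = max(0, min(e1, e2) - max(s1, s2))
    no1 = l1 - overlap
    no2 = l2 - overlap
    return 2.0 * overlap / (l1 + l2) - (no1 + no2) / no_norm


def _interval_classical_ro(s1: int, e1: int, s2: int, e2: int) -> float:
    """Classical reciprocal overlap: min of the two overlap ratios."""
    l1 = e1 - s1
    l2 = e2 - s2
    overlap = max(0, min(e1, e2) - max(s1, s2))
    if l1 == 0 or l2 == 0:
        return 0.0
    return min(overlap / l1, overlap / l2)


def _check_comparable(sig_i: SvSignature, sig_j: SvSignature) -> None:
    if sig_i.svtype != sig_j.svtype:
        raise ContractViolation(
            f"cannot compare signatures of type {sig_i.svtype} and {sig_j.svtype}"
        )
    if sig_i.svtype == "TRA":
        pair_i = tuple(sorted((sig_i.chrom, sig_i.chrom2)))
        pair_j = tuple(sorted((sig_j.chrom, sig_j.chrom2)))
        if pair_i != pair_j:
            raise ContractViolation("TRA signatures on different chromosome pairs")
    elif sig_i.chrom != sig_j.chrom:
        raise ContractViolation("signatures on different chromosomes")


def _tra_breakpoints(sig: SvSignature) -> tuple:
    """Breakpoints of a TRA signature keyed by sorted chromosome name."""
    a = (sig.chrom, sig.start)
    b = (sig.chrom2, sig.pos2)
    return tuple(sorted((a, b)))


def nro(sig_i: SvSignature, sig_j: SvSignature, params: NroParams) -> float:
    """NRO between two same-type signatures on the same chromosome group.

    Symmetric, bounded above by 1, and negative for sufficiently disjoint
    intervals.
    """
    return similarity(sig_i, sig_j, params, criterion="nro")


def classical_ro(sig_i: SvSignature, sig_j: SvSignature, params: NroParams) -> float:
    """Classical reciprocal overlap under the same interval conventions."""
    return similarity(sig_i, sig_j, params, criterion="classical")


def similarity(
    sig_i: SvSignature,
    sig_j: SvSignature,
    params: NroParams,
    criterion: str | None = None,
) -> float:
    _check_comparable(sig_i, sig_j)
    criterion = criterion or params.criterion

    def score(s1, e1, s2, e2):
        if criterion == "classical":
            return _interval_classical_ro(s1, e1, s2, e2)
        return _interval_nro(s1, e1, s2, e2, params.no_norm)

    if sig_i.svtype == "TRA":
        hw = params.tra_halfwidth
        bps_i = _tra_breakpoints(sig_i)
        bps_j = _tra_breakpoints(sig_j)
        vals = []
        for (ci, pi), (cj, pj) in zip(bps_i, bps_j):
            if ci != cj:  # mixed same-pair orientation; treat as disjoint
                return -2.0 * hw / params.no_norm
            vals.append(score(pi - hw, pi + hw, pj - hw, pj + hw))
        return min(vals)

    s1, e1 = sig_i.interval
    s2, e2 = sig_j.interval
    return score(s1, e1, s2, e2)


def build_graph(
    signatures: Sequence[SvSignature], params: NroParams
) -> nx.Graph:
    """Thresholded similarity graph over a single signature group.

    Nodes are signature indices; an edge (i, j) exists iff the similarity is
    strictly greater than ``params.nro_threshold``. Candidate pairs are
    pruned with a sorted sweep: any edge requires a positive overlap (the
    threshold is positive), so only pairs whose intervals (or first-breakpoint
    windows, for TRA) intersect are evaluated. The result is identical to
    exhaustive all-pairs evaluation.
    """
    g = nx.Graph()
    g.add_nodes_from(range(len(signatures)))
    if len(signatures) < 2:
        return g
    thr = params.nro_threshold

    if signatures[0].svtype == "TRA":
        hw = params.tra_halfwidth
        order = sorted(
            range(len(signatures)), key=lambda k: _tra_breakpoints(signatures[k])[0][1]
        )
        for a in range(len(order)):
            i = order[a]
            pi = _tra_breakpoints(signatures[i])[0][1]
            for b in range(a + 1, len(order)):
                j = order[b]
                pj = _tra_breakpoints(signatures[j])[0][1]
                if pj - pi >= 2 * hw:
                    break
                w = similarity(signatures[i], signatures[j], params)
                if w > thr:
                    g.add_edge(i, j, weight=w)
        return g

    order = sorted(range(len(signatures)), key=lambda k: signatures[k].interval)
    for a in range(len(order)):
        i = order[a]
        _, e1 = signatures[i].interval
        for b in range(a + 1, len(order)):
            j = order[b]
            s2, _ = signatures[j].interval
            if s2 >= e1:
                break
            w = similarity(signatures[i], signatures[j], params)
            if w > thr:
                g.add_edge(i, j, weight=w)
    return g


def build_graph_exhaustive(
    signatures: Sequence[SvSignature], params: NroParams
) -> nx.Graph:
    """All-pairs reference construction (used to guard the pruned sweep)."""
    g = nx.Graph()
    g.add_nodes_from(range(len(signatures)))
    for i, j in combinations(range(len(signatures)), 2):
        w = similarity(signatures[i], signatures[j], params)
        if w > params.nro_threshold:
            g.add_edge(i, j, weight=w)
    return g


def _canonical(cliques) -> List[Set[int]]:
    ordered = sorted(
        (tuple(sorted(c)) for c in cliques), key=lambda t: (-len(t), t)
    )
    return [set(t) for t in ordered]


def maximal_cliques(graph: nx.Graph) -> List[Set[int]]:
    """All maximal cliques, sorted by size (descending) then lexicographically.

    Enumeration is Bron-Kerbosch with pivoting as implemented by networkx,
    which matches the degeneracy-ordered enumeration family in output
    (equivalence to a brute-force oracle is property-tested).
    """
    if graph.number_of_nodes() == 0:
        return []
    return _canonical(nx.find_cliques(graph))


def brute_force_cliques(graph: nx.Graph) -> List[Set[int]]:
    """Maximal cliques by exhaustive subset checking. Test oracle only."""
    nodes = list(graph.nodes)
    if len(nodes) > 20:
        raise ValueError("brute_force_cliques refuses graphs with > 20 nodes")
    cliques = []
    for r in range(1, len(nodes) + 1):
        for subset in combinations(nodes, r):
            if all(graph.has_edge(u, v) for u, v in combinations(subset, 2)):
                cliques.append(set(subset))
    maximal = [
        c
        for c in cliques
        if not any(c < other for other in cliques)
    ]
    return _canonical(maximal)
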