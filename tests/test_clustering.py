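"""Clique resolution, cluster statistics, filtering, and germline calling."""

import pytest

from svclique.clustering import (
    call_germline,
    cliques_to_clusters,
    clusters_to_tsv,
    filter_clusters,
)
from svclique.config import NroParams, RunConfig
from svclique.model import ContractViolation, SvSignature, SignatureSet
from svclique.nro import build_graph, maximal_cliques

P = NroParams()


def sig(start, end, read, svtype="DEL", chrom="chr1"):
    return SvSignature(svtype, chrom, start, end, read, "gap", length=end - start)


def cluster_group(sigs, params=P, min_support=2):
    graph = build_graph(sigs, params)
    cliques = maximal_cliques(graph)
    return cliques_to_clusters(sigs, cliques, graph, params, min_support)


def test_identical_signatures_form_one_tight_cluster():
    sigs = [sig(1000, 2000, f"r{i}") for i in range(5)]
    clusters = cluster_group(sigs)
    assert len(clusters) == 1
    c = clusters[0]
    assert (c.support, c.cohesion, c.start_sd, c.start, c.end) == (5, 1.0, 0.0, 1000, 2000)
    assert c.read_ids == frozenset(f"r{i}" for i in range(5))


def test_breakpoints_are_medians_of_member_coordinates():
    sigs = [sig(998, 2000, "a"), sig(1000, 2000, "b"), sig(1003, 2000, "c")]
    clusters = cluster_group(sigs)
    assert len(clusters) == 1
    assert clusters[0].start == 1000
    assert clusters[0].start_mean == pytest.approx((998 + 1000 + 1003) / 3)
    assert clusters[0].start_mode == 998  # all unique: smallest value wins


def test_even_member_count_uses_lower_median():
    sigs = [sig(1000, 2000, "a"), sig(1002, 2000, "b")]
    clusters = cluster_group(sigs)
    assert clusters[0].start == 1000


def test_disjoint_cliques_stay_separate():
    sigs = [sig(1000, 2000, "a"), sig(1000, 2000, "b"),
            sig(50_000, 51_000, "c"), sig(50_000, 51_000, "d")]
    clusters = cluster_group(sigs)
    assert len(clusters) == 2
    assert {c.start for c in clusters} == {1000, 50_000}


def test_signatures_assigned_to_at_most_one_cluster():
    # 6 tight + 1 bridge signature reachable from both groups
    # (NRO bridge<->group = 0.82 > 0.8; group<->group = 0.64 < 0.8)
    sigs = (
        [sig(1000, 2000, f"a{i}") for i in range(3)]
        + [sig(1120, 2120, f"b{i}") for i in range(3)]
        + [sig(1060, 2060, "bridge")]
    )
    clusters = cluster_group(sigs, P)
    assert len(clusters) == 2
    members = [m for c in clusters for m in c.members]
    assert len(members) == len(set(members))
    assert sum(c.support for c in clusters) <= len(sigs)


def test_unknown_clique_index_rejected():
    sigs = [sig(0, 100, "a")]
    graph = build_graph(sigs, P)
    with pytest.raises(ContractViolation):
        cliques_to_clusters(sigs, [{0, 7}], graph, P)


def test_filter_clusters_rules():
    sigs = [sig(1000, 2000, "a"), sig(1000, 2000, "b")]
    (keep,) = cluster_group(sigs)
    lone = cluster_group([sig(9000, 9100, "z")], min_support=1)[0]
    assert filter_clusters([keep, lone], min_support=2) == [keep]
    assert filter_clusters([keep, lone], min_support=1) == [keep, lone]

    wide = cluster_group(
        [sig(1000 + 40 * i, 2000, f"w{i}") for i in range(3)],
        NroParams(nro_threshold=0.5),
    )[0]
    assert wide.start_sd > 30
    assert filter_clusters([wide], min_support=2, max_sd=30.0) == []


def test_similar_fragment_clusters_are_merged_with_informative_cohesion():
    # a 50 bp drift chain: NRO(offset d) = 1 - 3d/1000, so at threshold
    # 0.92 edges exist iff d <= 20. Greedy clique resolution fragments the
    # chain, but the fragment medians (offset 20) still exceed the
    # threshold, so the fragments merge back with cohesion < 1.
    sigs = [sig(d, d + 1000, f"r{d}") for d in (0, 10, 20, 30, 40)]
    clusters = cluster_group(sigs, NroParams(nro_threshold=0.92))
    assert len(clusters) == 1
    c = clusters[0]
    assert c.support == 5
    assert c.cohesion == pytest.approx(0.7)


def test_two_distant_deletions_never_merge(tmp_path):
    sset = SignatureSet()
    for i in range(10):
        sset.add(sig(10_000, 13_000, f"a{i}"))
        sset.add(sig(23_000, 26_000, f"b{i}"))
    sset.finalize()
    clusters = call_germline(sset, RunConfig())
    assert len(clusters) == 2
    assert all(c.support == 10 for c in clusters)


def test_call_germline_empty_input():
    assert call_germline(SignatureSet().finalize(), RunConfig()) == []


def test_call_germline_thread_invariance(germline_jittered):
    from svclique.signatures import ensure_indexed_bam, extract_signatures

    bam = ensure_indexed_bam(germline_jittered.sim.test_sam)
    sigs = extract_signatures(bam)
    seq = call_germline(sigs, RunConfig(threads=1))
    par = call_germline(sigs, RunConfig(threads=4))
    assert seq == par


def test_cluster_breakpoint_accuracy_tracks_jitter(germline_jittered):
    """Median breakpoints stay within 3 jitter-sd of truth for support >= 5."""
    jitter = germline_jittered.sim.config.jitter_sd
    matched = dict(germline_jittered.result.matches)
    clusters = germline_jittered.clusters
    truth = germline_jittered.truth
    checked = 0
    for ci, ti in matched.items():
        c, t = clusters[ci], truth[ti]
        if c.support >= 5 and c.svtype == t.svtype:
            assert abs(c.start - t.start) <= 3 * jitter
            checked += 1
    assert checked >= 10


def test_clusters_tsv_dump(tmp_path):
    sigs = [sig(1000, 2000, "a"), sig(1000, 2000, "b")]
    clusters = cluster_group(sigs)
    out = tmp_path / "clusters.tsv"
    clusters_to_tsv(clusters, out)
    lines = out.read_text().strip().splitlines()
    assert lines[0].startswith("#chrom")
    assert lines[1].split("\t")[:4] == ["chr1", "1000", "2000", "DEL"]
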