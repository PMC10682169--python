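"""Scoring call sets against a truth set.

A call matches a truth event of the same type when their classical
reciprocal overlap — min(overlap/L_call, overlap/L_truth) — is at least
``min_ro`` (default 50%). Insertions, which occupy no reference span, match
when their anchors lie within 1 kb and their length ratio reaches
``min_ro``; translocations when both breakpoints agree within a fixed
window. Matching is greedy 1-to-1 by descending overlap score and is
deterministic under permutation of the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

INS_ANCHOR_DIST = 1000
TRA_HALFWIDTH = 500


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    per_type: Dict[str, "EvalResult"] = field(default_factory=dict)
    gt_concordance: Optional[float] = None
    matches: List[Tuple[int, int]] = field(default_factory=list)


def _rates(tp: int, fp: int, fn: int) -> Tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return precision, recall, f1


def _svtype(rec) -> str:
    t = rec.svtype
    return "TRA" if t == "BND" else t


def _pair_score(call, truth) -> Optional[float]:
    """Overlap score in [0, 1], or None when the pair cannot match."""
    t = _svtype(call)
    if t == "TRA":
        if call.chrom2 is None or truth.chrom2 is None:
            return None
        a = sorted([(call.chrom, call.start), (call.chrom2, call.pos2)])
        b = sorted([(truth.chrom, truth.start), (truth.chrom2, truth.pos2)])
        score = 1.0
        for (ca, pa), (cb, pb) in zip(a, b):
            if ca != cb:
                return None
            d = abs(pa - pb)
            if d >= 2 * TRA_HALFWIDTH:
                return None
            score = min(score, (2 * TRA_HALFWIDTH - d) / (2 * TRA_HALFWIDTH))
        return score
    if call.chrom != truth.chrom:
        return None
    if t == "INS":
        if abs(call.start - truth.start) > INS_ANCHOR_DIST:
            return None
        l1, l2 = max(call.length, 1), max(truth.length, 1)
        return min(l1, l2) / max(l1, l2)
    l1 = call.end - call.start
    l2 = truth.end - truth.start
    if l1 <= 0 or l2 <= 0:
        return None
    overlap = max(0, min(call.end, truth.end) - max(call.start, truth.start))
    return overlap / max(l1, l2)


def match_and_score(
    calls: Sequence,
    truth: Sequence,
    min_ro: float = 0.5,
    type_strict: bool = True,
    call_genotypes: Optional[Sequence[str]] = None,
) -> EvalResult:
    """Greedy 1-to-1 matching of calls to truth events.

    ``calls`` and ``truth`` are any records with chrom/start/end/svtype/
    length (and chrom2/pos2 for translocations), e.g. SvCluster or
    TruthRecord. A call is a true positive iff it matches a same-type truth
    event (when ``type_strict``) with score >= ``min_ro``.
    """
    candidates = []
    for ci, call in enumerate(calls):
        for ti, tru in enumerate(truth):
            if type_strict and _svtype(call) != _svtype(tru):
                continue
            score = _pair_score(call, tru)
            if score is not None and score >= min_ro:
                candidates.append((-score, ci, ti))
    candidates.sort()
    used_calls: set = set()
    used_truth: set = set()
    matches: List[Tuple[int, int]] = []
    for _, ci, ti in candidates:
        if ci in used_calls or ti in used_truth:
            continue
        used_calls.add(ci)
        used_truth.add(ti)
        matches.append((ci, ti))

    tp = len(matches)
    fp = len(calls) - tp
    fn = len(truth) - tp
    precision, recall, f1 = _rates(tp, fp, fn)

    per_type: Dict[str, EvalResult] = {}
    types = sorted({_svtype(r) for r in list(calls) + list(truth)})
    for t in types:
        t_calls = {i for i, c in enumerate(calls) if _svtype(c) == t}
        t_truth = {i for i, r in enumerate(truth) if _svtype(r) == t}
        t_tp = sum(1 for ci, ti in matches if ci in t_calls)
        t_fp = len(t_calls) - t_tp
        t_fn = len(t_truth) - t_tp
        p, r, f = _rates(t_tp, t_fp, t_fn)
        per_type[t] = EvalResult(t_tp, t_fp, t_fn, p, r, f)

    gt_conc = None
    if call_genotypes is not None:
        agree = total = 0
        for ci, ti in matches:
            tg = getattr(truth[ti], "genotype", None)
            cg = call_genotypes[ci]
            if tg in ("0/1", "1/1") and cg in ("0/0", "0/1", "1/1"):
                total += 1
                agree += tg == cg
        gt_conc = agree / total if total else None

    return EvalResult(tp, fp, fn, precision, recall, f1, per_type, gt_conc, matches)


def write_metrics_tsv(result: EvalResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("svtype\ttp\tfp\tfn\tprecision\trecall\tf1\n")
        fh.write(
            f"ALL\t{result.tp}\t{result.fp}\t{result.fn}\t"
            f"{result.precision:.4f}\t{result.recall:.4f}\t{result.f1:.4f}\n"
        )
        for t, r in sorted(result.per_type.items()):
            fh.write(
                f"{t}\t{r.tp}\t{r.fp}\t{r.fn}\t"
                f"{r.precision:.4f}\t{r.recall:.4f}\t{r.f1:.4f}\n"
            )
        if result.gt_concordance is not None:
            fh.write(f"#genotype_concordance\t{result.gt_concordance:.4f}\n")
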