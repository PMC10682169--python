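# Methods

This note documents the models and procedures implemented in `svclique`,
the parameters that matter, the design choices made where the design was
genuinely open, what the synthetic fixtures do and do not emulate, and the
known limitations. No empirical claim here goes beyond what the test suite
and `scripts/acceptance.py` compute.

## Signature extraction (`svclique.signatures`)

An SV leaves one of two alignment footprints on each supporting read:

* **gapped**: an insertion (`I`) or deletion (`D`) run inside the CIGAR of
  a single record, produced when the event is small enough for the
  aligner's gap model;
* **split**: the read is mapped as a primary plus supplementary segments,
  and the junction geometry of query-consecutive segment pairs encodes the
  event — a reference gap is a deletion, opposite strands an inversion,
  different chromosomes a translocation, a reference overlap a tandem
  duplication, and a query gap over abutting reference segments (or a
  three-segment read whose middle maps far away) an insertion.

Conventions and parameters:

* coordinates are 0-based half-open everywhere; only the VCF writer
  converts to 1-based.
* `min_sv_size = 50` bp (the conventional SV floor), `min_mapq = 20`,
  `max_sv_size = 1 Mb` for intra-chromosomal split pairs; all configurable.
* same-type gapped signatures on one read closer than `merge_gap = 150` bp
  are merged (union span for DEL; summed length, leftmost anchor for INS)
  to undo aligner fragmentation of a single event.
* secondary and duplicate-flagged records are ignored; supplementary
  segments are taken from the primary record's SA tag, with a fallback
  that groups heavily clipped records by read name when SA tags are
  absent. Gapped signatures are also parsed from supplementary records.
* the split **duplication** interval is `[second.ref_start, first.ref_end)`
  — the span between the junction's two breakpoints. For a tandem-dup
  junction read this equals the duplicated unit regardless of how far the
  read extends past the junction; using the set intersection of the two
  segments instead would yield read-length-dependent partial intervals
  that fragment the cluster.
* the three-segment insertion rule requires the outer segments to map
  within `ins_anchor_dist = 100` bp and the middle to map to another
  chromosome or > 10 × `ins_anchor_dist` away.

## NRO similarity and clique clustering (`svclique.nro`, `svclique.clustering`)

For two same-type signatures with sizes `L_i, L_j`, shared span `Overlap`,
and non-overlapping parts `NO_i, NO_j`:

`NRO = 2·Overlap/(L_i+L_j) − (NO_i+NO_j)/NO_Norm`, with `NO_Norm = 1000`
bp and edge threshold 0.8 by default (strictly greater-than; the
similarity is bounded above by 1 and may be negative for disjoint
intervals). Insertions use the pseudo-interval `[start, start+length)` so
that nearby anchors with similar inserted lengths score high.
Translocations use ±`tra_halfwidth` (500 bp) windows around each
breakpoint, taking the minimum of the two window scores, and are only
compared within one chromosome pair and strand-pair orientation.

Why it works at both scales: the first term is the symmetric (Dice-style)
overlap ratio, more forgiving of small length differences than the
classical min-ratio; the second term charges disagreement in *absolute*
bases, so a 30 bp smear costs a 100 bp and a 5 kb event the same 0.03
while classical reciprocal overlap charges 30% vs 0.6%. Conversely a
large absolute disagreement (two different nearby events) drives NRO
steeply negative, which a loose classical threshold would tolerate.

Clustering per (svtype, chromosome) group — per chromosome pair and
orientation for translocations:

1. thresholded similarity graph (a sorted-interval sweep prunes candidate
   pairs; any edge needs positive overlap, so the result is provably
   identical to exhaustive all-pairs and is additionally property-tested);
2. maximal cliques via Bron–Kerbosch with pivoting (networkx), property-
   tested against an exhaustive subset-enumeration oracle;
3. greedy resolution of overlapping cliques, largest first (ties: smaller
   median start), each signature joining at most one cluster; cliques that
   fall below `min_support` after removal of used signatures are dropped;
4. a merge pass: clusters whose median intervals are still mutually
   similar above the threshold are unioned (connected components, one
   round). This is where the **cohesion** statistic (realized edges among
   members / k(k−1)/2) becomes informative — a pure clique has cohesion 1,
   a merged cluster less.

Cluster coordinates are the member medians (lower median for even counts,
giving deterministic integer breakpoints); mean, mode (smallest value on
ties) and population standard deviation of both breakpoints are kept for
filtering. Default filters: `min_support = 2`, no sd or cohesion cut
(`max_sd = ∞`, `min_cohesion = 0`).

## Genotyping (`svclique.genotyping`)

A three-state Bayes classifier under diploidy. With `v` variant-supporting
reads out of `n` informative reads, the likelihood of genotype `g` is
`Binomial(v; n, p_g)` with `p = ε, 0.5, 1−ε` for 0/0, 0/1, 1/1, where
`ε = 0.1` is the signature noise rate; priors default to uniform. The call
is the posterior argmax (ties favor the smaller alternate dosage) and
`GQ = −10·log10(1 − max posterior)`, capped at 99.

`v` is the cluster support. `n = v` plus the number of distinct
non-supporting reads whose primary alignment **crosses** the start
breakpoint (first breakpoint for translocations) — crossing meaning
aligned reference bases on both sides (`ref_start < pos < ref_end`). A
read clipped or split exactly at the junction is variant evidence, not
reference evidence, so it must not inflate the reference count; counting
every primary that merely touches the position would make homozygous
split-signature events (large deletions, insertions, inversions) look
heterozygous. The library also exposes `spanning_read_count` (distinct
primaries covering a position), which is the simpler statistic used for
coverage checks.

## Somatic calling (`svclique.somatic`)

Tumor clusters are computed by the germline module. For each cluster, the
matched normal's signature set is searched for same-type signatures with
NRO above the (independently configurable, default 0.8) control threshold
against the cluster's median representation; matching is counted in
distinct control reads. The 2×2 table is then

|            | variant reads | reference reads |
|------------|---------------|-----------------|
| tumor      | `N_VRT` = support | `N_RRT` = non-supporting crossers |
| normal     | `N_VRC` = matched controls | `N_RRC` = control crossers minus matches |

scored with a one-sided Fisher exact test (alternative: variant proportion
greater in tumor), `scipy.stats.fisher_exact`, cross-checked in the test
suite against an exact rational-arithmetic hypergeometric enumeration.
Degenerate margins (a sample with no reads at the locus) give `p = 1`.
Clusters with `p < α` (default 0.001) are somatic. The one-sided
alternative matches the purpose — detecting tumor-specific events; a
two-sided mode and an optional Benjamini–Hochberg correction exist but are
off by default (raw p-value thresholding is the method's operating point).

## Synthetic fixtures (`svclique.simulate`)

The generator works at the **alignment level**: it does not simulate bases
or re-align them; it places reads and directly writes the records a
long-read aligner would produce over each implanted event (gapped CIGARs
below a 1 kb `split_threshold` for DEL/INS, SA-tagged primary/
supplementary splits otherwise and for DUP/INV/TRA). Alignment noise is
modeled where it matters for clustering: breakpoints are jittered per
signature with rounded Gaussian noise (`jitter_sd`, default 10 bp —
matching the tens-of-bp breakpoint scatter of real long-read alignments),
and spurious small gapped signatures are injected at `noise_signature_rate`
(default 0.01/read). Reads whose junction flank would be shorter than
200 bp are clipped at the junction instead of carrying a signature, as an
aligner would do.

Defaults mirror the benchmark design this package targets: a 5 Mb
chromosome, 10 kb mean read length (sd 10%), uniform read placement,
heterozygous events carried by one of two haplotypes with haplotype labels
alternating along the chromosome (exact ~50/50 allelic sampling at fixture
scale — binomial sampling noise in allele counts is deliberately absent so
that fixture genotypes are unambiguous; the genotype model itself is
stress-tested separately under true binomial sampling). Somatic events
appear only in the test sample of a pair. Events are auto-placed evenly
with a minimum separation of twice the largest event plus two read
lengths, so no read touches two events; violations raise before anything
is written. Output is coordinate-sorted SAM (`SEQ='*'`, consistent SA
tags) plus a TSV truth table; fixed seeds give byte-identical files.

The canonical study conditions:

* **germline benchmark**: 20 events, 4 per subtype, sizes on the
  100 bp–5 kb grid, het/hom mix, at 20×. All four duplications are
  heterozygous: a homozygous tandem duplication has a junction allele
  fraction of ~2/3 (reads from the extra copy cross the breakpoint without
  seeing the junction), which junction evidence alone cannot separate from
  0/1 — a documented genotyping limitation rather than a fixture bug.
* **somatic benchmark**: 10 tumor-only heterozygous + 10 shared events at
  30×/30×, jitter 10 bp. Tumor-only events use junction-rich types/sizes
  (≤ 3 kb; no near-read-length insertions/inversions): a heterozygous
  event whose support is halved by a full-span requirement cannot reach
  p < 0.001 at 30× under a one-sided Fisher test (with ~30 informative
  tumor reads and a clean control, p < 0.001 needs ≥ 9–10 supporting
  reads), which is a property of the statistic, not of the caller.
* **type-I / power replicates**: 500 shared events (5 × 100) and 200
  tumor-only events on 5 Mb at 30×/30× for the somatic error-rate and
  sensitivity estimates.

What passing these fixtures does *not* show about real data: there is no
base-level error model, no mapping ambiguity or repeat-induced mis-splits,
no coverage bias, no multi-read chimeras, and noise signatures are placed
uniformly rather than clustered at repeats. The fixtures validate the
clustering/statistics machinery, not aligner behavior.

## Evaluation (`svclique.evaluate`)

Calls match truth events of the same type greedily, 1-to-1, by descending
classical reciprocal overlap `min(Overlap/L_call, Overlap/L_truth)`, with
a 50% floor. Insertions (no reference span) match on anchor distance
≤ 1 kb *and* length ratio ≥ the floor; translocations on chromosome-pair
identity with both breakpoints inside ±500 bp windows. Precision, recall
and F1 use the 0-denominator-gives-0 convention; genotype concordance
among true positives is reported separately rather than folded into F1.

## Numerical and determinism choices

* every pipeline stage is deterministic and thread-count-invariant:
  per-chromosome work is merged and canonically sorted, signature sets are
  deduplicated per (read, type, interval) and sorted, clique output is
  canonicalized (size-descending, then lexicographic);
* tie-breaks are always toward the smaller value (medians, modes, genotype
  dosage);
* Fisher p-values come from scipy's exact routine; agreement with exact
  rational enumeration is ≤ 1e−12 on the tested table range;
* genotype posteriors fall back to log-space when the linear-space
  likelihoods underflow at extreme `n`.

## Known limitations

* homozygous tandem duplications genotype as 0/1 (junction allele fraction
  ~2/3; see above);
* translocation junctions are modeled/called from one side; reciprocal
  partner junctions are not reconstructed;
* no purity/subclonality model in somatic mode — the Fisher test assumes
  the tumor sample's variant fraction is what the reads show;
* insertion sequences are not assembled; only anchor and length are
  reported;
* complex/nested events (e.g. inverted duplications) are emitted as their
  component signatures, not reconstructed.
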