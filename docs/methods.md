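# Methods

This note documents the models and procedures implemented in `polysv`, the
parameter defaults and why they were chosen, the design decisions taken
where the underlying methodology left room, and the limits of what the
synthetic data can demonstrate.

## Data model and coordinates

All user-facing coordinates are VCF-style: 1-based, inclusive. Interval
arithmetic (gene overlap, windows) converts to 0-based half-open internally
at the point of use. An insertion is a point event (`end == pos`, inserted
length only in `svlen`); deletions and inversions span `[pos, end]` with
`svlen = end − pos`. Deletion SVLEN is written negative on export and
stored as a magnitude internally (sign-magnitude convention of the caller
dialect). Records whose SUPTYPE is absent are treated as split-read-only —
the conservative reading, since such calls then fail the AL requirement.
FILTER values other than PASS/UNRESOLVED map to UNRESOLVED with a warning.
Translocation records missing END/SVLEN are normalized to `end = pos`,
`svlen = 1`; the default filter discards translocations regardless.

## Quality filter

A call survives iff all of: type not in {TRA, DUP}; FILTER = PASS;
within-alignment (AL) evidence present; 30 ≤ svlen ≤ 30 000. The size
bounds are policy defaults matching the studied size range and can be
disabled (`min_size=None`, `max_size=None`); the filter itself is a
pointwise predicate, hence idempotent and order-independent, which the
tests assert. Size classes: *small* = [30, 10 000], *mid* =
(10 000, 30 000]. The two published range descriptions overlap at 10 kb; a
half-open upper convention was chosen so the classes partition the range.
The median for even counts is the midpoint of the central pair.

## Merging and force-calling

Merging reimplements the semantics of a SURVIVOR-style merge with
"maximum distance between breakpoints" d = 1000 bp, type-aware, strand- and
size-agnostic: within each (chromosome, type) stratum, two records link
when both |Δpos| ≤ d and |Δend| ≤ d, and clusters are the transitive
closure (single linkage). The implementation scans records sorted by `pos`
with a sliding window (only candidates with Δpos ≤ d can link), which the
tests prove equal to an O(n²) union-find oracle. Every unmatched record is
a singleton cluster ("minimum supporting callers = 1"). Representative
coordinates are member medians (half-up integer rounding).

Force-calling is geometric re-genotyping against the merged set, not a
re-examination of raw reads: a record supports a cluster of its own type
when both breakpoints land within d of the representatives, and each record
supports at most one cluster — the nearest by |Δpos| + |Δend|, ties to the
leftmost representative, for determinism. Concordance between two force-
called presence vectors is `100 · n_both / n_total`, one decimal.

## Annotation

Gene overlap uses the ≥ 1 bp intersection rule (the bedtools-intersect
default a practitioner would use). An SV overlapping several genes counts
toward each of them but remains a single event in genome-wide totals. An
intragenic SV is exonic if it overlaps at least one exon base, else
intronic; a non-genic SV within the promoter flank (default 2000 bp,
strand-aware, configurable — the convention for an undefined "putative
promoter" distance) upstream of a 5′ end is a promoter hit. Window counts
tile each chromosome with 1-Mbp windows from position 1 and count each SV
once, in the window containing its left breakpoint; this keeps per-
chromosome window sums equal to call counts (counting spanning SV in every
overlapped window would not).

Subgenome rates divide per-chromosome counts by chromosome length in Mbp
and compare A- vs C-subgenome chromosomes with a two-sided Wilcoxon
rank-sum test — distribution-free and exact at the chromosome counts
involved (exact method used when both sides have ≤ 12 chromosomes and no
ties; identical values on all chromosomes return p = 1 directly). Group
gene sets are unions over member samples by default (matching "genes
carrying SV in <ecotype> accessions"); Venn regions are reported for up to
four groups, pairwise intersections beyond that. QTL candidates are the
genes in the interval carrying SV in exactly one of the two samples
(symmetric difference; shared genes dropped), with optional keyword
filtering of annotation text; interval length is reported in Mbp to one
decimal.

## Read-depth CNV

Per-base depth is summarized as medians of non-overlapping 1000-bp blocks
(final block truncated). Per chromosome, the median and *population*
standard deviation of block medians set the duplication threshold
`median + k·sd` with k = 1 by default. The published description of this
threshold is ambiguous; "block median above the chromosome median by more
than one standard deviation" is the reading adopted here, with k exposed.
Population rather than sample SD keeps results bit-stable and the two are
indistinguishable at thousands of blocks. Adjacent flagged blocks merge
into segments. A deletion-side call (below `median − k·sd`) exists behind
`direction="loss"` but is off by default, since the method as published
calls only duplications.

Note a property of this thresholding: under pure homoscedastic noise with
no true CNV, ~16% of blocks exceed `median + 1·sd` by construction, so
isolated single-block calls on quiet chromosomes are expected noise; real
duplications announce themselves as long runs, and their depth excess
inflates the chromosome sd, which suppresses noise calls on the same
chromosome. Raising k trades sensitivity for specificity monotonically
(asserted by test).

Whole-chromosome loss — the situation where a chromosome is deleted and
replaced by its homoeolog — is flagged when a chromosome's median block
depth is below `loss_fraction` (default 0.1) of the genome-wide median
block depth. The 0.1 default separates residual mis-mapping depth (a few
percent of the mean) from genuine single-copy presence.

## Presence/absence phylogeny

The binary matrix has no missing-data state: force-called absence is 0, by
construction of the merged set. PHYLIP export is relaxed sequential with
names sanitized and truncated to 10 characters; collisions are
disambiguated with numeric suffixes (an error is raised only if
disambiguation is impossible). Tree inference for internal use is
neighbor-joining on Hamming proportions (fraction of differing matrix
columns), via scikit-bio, with negative NJ branch lengths clamped to zero
and midpoint rooting when a rooted topology is needed. Full maximum-
likelihood inference with model selection is deliberately out of scope —
the PHYLIP export keeps external ML tools usable — but NJ suffices for the
testable claim, namely that planted sample groups come out monophyletic.
Monophyly of a group is assessed as the existence of its split in the
midpoint-rooted tree.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes:

* **Genome**: 4 chromosomes (A01 10 Mbp, A02 8 Mbp, C01 10 Mbp, C02
  8 Mbp), subgenome inferred from the name prefix. Gene models: 40
  genes/Mbp (a deliberately reduced density that still leaves realistic
  intergenic space at desk scale), gene spans 1.5–3.5 kb with 4 exons,
  placed one per equal-width slot so genes never overlap and counts are
  exact.
* **Panel**: 3 groups (winter, semi-winter, spring) × 4 samples. Each group
  shares 60 events; each sample adds 15 private events — a shared fraction
  of 0.8, which is the regime in which ecotype clustering from SV is
  claimed testable. 22% of events are planted inside a random gene.
* **Sizes**: log-normal with median 300 bp and σ_log = 1.3, clamped to
  [30, 30 000] — a simple declared family reproducing the reported scale
  (per-sample medians ~300 bp, range up to tens of kb). The generated
  median stays within ±15% of the target across seeds (asserted).
* **Subgenome bias**: A-chromosome placement rate scaled ×1.3 relative to
  C, matching the direction and order of the reported A > C excess.
* **Decoys**: fractions of the raw call set — 28% UNRESOLVED, 15%
  split-read-only, 7% TRA, 7% DUP — so the default filter removes ~57% of
  raw calls, inside the published 54–59% removal band. Decoys are labelled
  in the truth set but indistinguishable in the emitted VCF.
* **Jitter**: each sample observes each true event with breakpoints
  perturbed by rounded N(0, 50 bp) — well inside the 1000-bp merge radius,
  emulating platform breakpoint noise between ONT and PacBio.
* **Coverage**: mean 30× with N(0, 2) noise held constant over 100-bp
  chunks (long-read depth is autocorrelated; chunk width 1 gives i.i.d.
  per-base noise and is used in the CNV oracle tests), planted
  duplications multiplying depth by their fold, and lost chromosomes
  scaled to 2% of the mean.
* **Determinism**: every stage draws from its own
  `default_rng([seed, stage])` stream, so regenerating any product is
  bit-identical and marginal counts are fixed by the parameters, not by
  chance. Events are placed with a 2.5-kb minimum spacing so distinct
  planted events never co-cluster by accident.

What passing tests on this data do **not** show: robustness to reference
mis-assembly artefacts with spatial structure, platform-specific error
asymmetry beyond symmetric jitter, nested or overlapping SV, genotype
errors in force-calling from raw reads, or realistic gene density and
length distributions. The generator is a correctness harness, not a
benchmark of biological realism.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline on the
36-Mbp default panel and use scaled-down instances elsewhere (2-Mbp
chromosomes for CNV replicates, hundreds of records for merge oracles,
20–100 seeded replicates for the statistical properties); these sizes are
the package's declared desk-scale study conditions. Percentages are
rounded to one decimal where reported as such. Median representatives use
half-up integer rounding; NJ ties resolve by scikit-bio's deterministic
input-order behaviour; the pipeline writes all intermediates and a
timestamp-free run log so re-runs are bit-identical.

## Known limitations

* Breakpoint refinement, insertion consensus sequences and translocation
  merging are not implemented (translocations are filtered by design).
* Force-calling is geometric; it cannot rescue a variant the caller never
  emitted in a sample.
* The merged cluster count of a two-platform comparison depends on linkage
  chains and is not simple union arithmetic of the two call sets; only the
  merge semantics, not any particular published total, are reproducible.
* CNV calling assumes roughly uniform coverage; GC bias and mappability
  are not modelled, and no ploidy-aware copy-number genotyping is done.
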