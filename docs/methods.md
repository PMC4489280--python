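# Methods

This note documents the models and numerical choices behind `wescnv`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Observation model

The caller works on per-target read counts from whole-exome capture.  The
signal of copy number $c$ at a target is the depth ratio between patient and
a diploid reference, $\approx c/2$, but raw depth is confounded by total
sequencing depth, per-target capture efficiency, and GC-dependent bias.  The
normalization chain removes these in order:

* **Sample normalization** divides each count by the sample total, removing
  depth.  All-zero samples are rejected as degenerate.
* **Pooled reference**: the arithmetic mean of the *normalized* control
  profiles.  Normalizing before averaging makes the reference depth-free;
  averaging raw counts would weight deep controls more.  Per-target capture
  efficiency cancels in the patient/reference ratio.
* **GC correction** divides each raw ratio by the median ratio of its GC
  bin.  Bin width 0.02 (50 bins over [0,1]) balances resolution against bin
  occupancy on exome-sized grids (~400 targets/bin at 20 000 targets);
  bins with fewer than 10 unmasked targets fall back to the global median,
  so sparse GC extremes are never corrected by their own noise.  Median,
  not mean, so a patient's own CNVs do not drag the correction.  Setting
  `gc_method: none` skips the division (useful when the reference already
  shares the patient's bias).
* **log2 + median re-centering** maps a copy-number doubling to +1 and pins
  the genome-wide median at 0, absorbing any residual global scale.  The
  whole chain is invariant under rescaling of the raw ratios.

Masking: targets with reference value exactly 0 carry no information and
are masked (excluded, never re-included).  A patient zero against a
positive reference becomes a pseudo-ratio $\varepsilon / r_i$ with
$\varepsilon$ = half the smallest positive normalized patient value,
preserving the homozygous-deletion signal without $-\infty$.

## Segmentation HMM

States are integer copy numbers (default 0–4).  Emissions are Gaussian at
$\log_2(c/2)$ with one shared variance; copy 0 uses $\log_2(0.05)$, a
residual-coverage floor reflecting off-target and mismapped reads.
Transitions are distance-independent with self-transition probability
0.99 — at typical exome spacing this encodes an expected segment length of
~100 targets while still allowing 5-target events with strong evidence; the
initial distribution puts 0.9 on diploid.  Chromosomes are independent
chains; masked targets are spliced out so the chain connects consecutive
unmasked targets.

Numerics: forward–backward uses per-step scaling; Viterbi runs in log
space.  Both are batched across chromosome chains, padded to the longest
chain with unit-emission steps — because the transition matrix is
row-stochastic, padded steps leave the scaled recursions and the
log-likelihood of real steps exactly unchanged.  Viterbi likelihood ties
break toward the copy number closest to 2, then the lower one
(conservative toward diploid).  Both routines are verified against
exhaustive path enumeration in the test suite.

**EM calibration.**  Only the shared variance and a single additive offset
of all means (a baseline shift absorbing residual normalization error) are
re-estimated; the $\log_2(c/2)$ spacing is physics, not a free parameter.
The (offset, state) decomposition is multimodal: an offset near half the
state spacing can equally be read as a baseline shift or a genome-wide
state change.  EM therefore starts from the best of the candidate offsets
that align the data mean with each state (scored by one forward–backward
pass; ties prefer the smaller shift), then iterates to convergence
(relative tolerance 1e−6, max 50 iterations, variance floored at 1e−4).
Within a run the log-likelihood is non-decreasing.  EM requires ≥ 50
unmasked targets; below that the initial model is used as-is.

**Calls and scores.**  Maximal Viterbi runs of one non-diploid state with
at least `min_targets` (default 3 — single- and two-exon depth calls are
noise-dominated) become calls.  The reliability score is 100 × the mean
posterior probability of the call's state over its targets; it lives on a
0–100 scale and the default filter keeps score > 80 (strict).  Copy
number 2 is never emitted; gain/loss follows copy number >2 / <2.

## Shared CNVs

Calls from different samples on one chromosome share when they overlap by
≥ 1 bp in the same direction; copy numbers need not be identical (a cn 0
and a cn 1 loss can share a region).  Overlap components whose members
have no common intersection are split greedily left-to-right into maximal
sub-groups that do.  A solitary call reports share count 1.

## Annotation

* Gene models come from BED (0-based half-open) or GFF3 `gene` features
  (via gffutils); duplicate gene ids collapse to their spanning interval.
* A gene is CNV-associated when the covered fraction of its length exceeds
  `min_coverage` (default 0.9, strict, mirroring the score filter).
* Known-CNV catalogs are read as 1-based inclusive TSV (chrom, start, end,
  id, optional gain/loss type); a call matches at reciprocal overlap ≥ 0.5
  (the field's conventional cutoff), optionally also requiring direction
  agreement (`--match-type`).
* Enrichment is the one-sided Fisher exact test, $p = P(X \ge k)$ for
  $X \sim \mathrm{Hypergeom}(N, K, n)$ with the background universe being
  the genes of the supplied gene-model file; term sets are intersected
  with the background first, terms with $k = 0$ are skipped, and
  Bonferroni multiplies by the number of *tested* terms.  Over-representation
  is inherently one-sided, and an explicit background keeps the test
  reproducible across annotation sources.
* Per-gene side tables (first column = gene id) are left-joined onto gene
  hits while preserving sample attribution; duplicate rows concatenate
  with `;`, absent genes render `.`.

## Synthetic cohorts

The generator emulates the *depth* signal of an exome capture:

* 20 000 targets of 150 bp over 22 autosome labels, geometric inter-target
  gaps (mean 10 kb), per-target GC ~ Beta(5, 5) — an exome-like grid with
  most targets at mid-GC;
* counts ~ NegativeBinomial(mean $= d \cdot (c/2) \cdot b(g)$, size $r$)
  with depth $d$ = 100, dispersion $r$ = 20 by default;
  $b(g) = \exp(0.3 \cdot 4 (g - 0.5))$, normalized to mean 1, gives a
  realistic ~2.4-fold depth range across the GC spectrum.  Copy 0
  contributes a residual factor 0.05 rather than zero;
* 10 patients each carry 10 planted segments (5–50 targets, copy number
  uniform in {0, 1, 3, 4}), placed without overlap inside a single
  chromosome and separated by at least 2 diploid targets — abutting
  same-direction segments would be indistinguishable from one longer
  segment for any read-depth method, making the truth ill-posed; 10
  controls are fully diploid.  One integer seed drives everything.

What it does **not** emulate: mappability and capture-kit batch effects,
replication-timing waves, sex chromosomes and mixed-sex cohorts, somatic
subclonality and fractional copy numbers, and correlated noise between
neighboring targets.  Passing the benchmark shows the detection chain is
correct and well-calibrated under the declared noise model, not that real
exomes are this clean.

## Benchmark conditions

The evaluator matches calls to truth at 50% reciprocal overlap, same
sample and direction; F = 2PR/(P+R).  Degenerate conventions are explicit:
empty truth → recall 1; no calls → precision 1 if truth is empty, else 0;
copy-number accuracy is 1 when no pairs matched (vacuous).

The committed headline-benchmark conditions
(`simulation.benchmark_config()`: depth 200, dispersion 200, all else
default) are chosen so that every plantable segment class is comfortably
above the caller's detection limit.  At depth 100 / dispersion 20 the
per-target log2 sd is ≈ 0.37, and the expected Viterbi evidence of the
hardest class — a 5-target single-copy gain, amplitude 0.585 — is of the
same order as the ~12-log-unit transition penalty of the 0.99 stay
probability, so individual low draws can lose such a segment.  That
detection limit is a property of any read-depth caller at that noise
level; the benchmark is meant to measure the correctness of the pipeline,
and under the committed conditions the minimum per-sample F-measure is
1.0 across a wide range of seeds (~2 s per run on one CPU).  The default
`SimConfig` keeps the noisier conditions for general use.

## Limitations

* The reliability score is a posterior-mean heuristic on a 0–100 scale;
  it is well-calibrated only insofar as the Gaussian HMM fits the data.
* Distance-independent transitions ignore inter-target spacing; a
  distance-dependent kernel is a natural extension hook.
* All chromosomes are treated as diploid baselines; chrX/chrY calls in
  mixed-sex cohorts against a single-sex reference will be systematically
  shifted and should be interpreted with care.
* Breakpoints are resolved only to target boundaries.
* No BAM/CRAM handling: producing the count and GC tables from alignments
  is upstream of this package's input contract.
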