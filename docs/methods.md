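# Methods

## Pipeline model

`asescope` operates entirely on peak-level inputs (BED-family text formats,
0-based half-open coordinates throughout). The analysis chain is:

1. **Active enhancers.** DNase peaks are kept if they overlap (≥1 bp) an
   H3K27ac peak and their interval stays clear of the closed window
   [TSS − 2.5 kb, TSS + 2.5 kb] around every annotated TSS. The overlap
   criterion is 1 shared bp after optional symmetric window expansion
   (start clamped at 0, no right clamp), matching bedtools-window
   semantics. TSS proximity is measured edge-to-point by default; a
   center-to-point variant is available (`tss_distance_from="center"`).

2. **Occupancy score.** Each factor's peaks are intersected with the active
   enhancers; when several peaks of one factor hit one enhancer the
   maximum signalValue is used (robust to peak fragmentation; `sum`/`mean`
   are exposed). Zeros are recorded for unbound enhancer/factor pairs, then
   each factor column is min–max scaled over all enhancers including the
   zeros. OS(E) = N_E × Σ_f Signal_E(f), with N_E counting raw > 0 — so the
   enhancer carrying a factor's minimum bound signal (normalized to 0)
   still counts as bound, and a constant column normalizes to all zeros
   rather than all ones so a ubiquitous flat factor contributes no
   asymmetric weight. Histone marks are not meant to enter the OS matrix;
   the matrix builder takes whatever factor list it is given.

3. **Inflection cutoff.** Ranked ascending as y(0..n−1), the reference
   (diagonal) slope is s\* = (max − min)/n. The cutoff rank is the tangency
   point of a line of slope s\* slid against the curve from below, computed
   as argmin_k [y(k) − s\*·k]. Ties resolve to the largest rank, so a
   constant curve cuts at its maximum with nothing above; a minimizer at
   rank 0 means the curve rises at least as steeply as the diagonal from
   the start (e.g. an exactly linear curve) — no elbow exists and the
   cutoff is the maximum. We use this closed-form tangency rather than
   local finite differences because discrete slopes of sorted heavy-tailed
   data are noisy at both extremes: a single wide gap between the two
   smallest order statistics, or an accidental near-tie high in the tail,
   would otherwise throw the cutoff to one end of the curve. Calls are
   strict: only values strictly above the cutoff value are above the
   elbow.

4. **Classic SE comparator.** H3K27ac peaks are stitched when the gap to
   the growing region is ≤ 12.5 kb (no TSS exclusion inside stitching,
   mirroring a tss_exclusion_zone_size of 0); region signal is the sum of
   member-peak signalValues (the original density integration is not
   available at peak level — all comparisons are internal rankings, so
   only the order matters). Regions strictly above the inflection cutoff of
   ranked total signal are classic SEs.

5. **Four-way classification.** high-occupancy ∧ SE-overlap → dSE;
   high-occupancy alone → aSE; SE-overlap alone → cSE; neither → rEh.
   SE overlap is plain (window 0) intersection. The labels always partition
   the active set.

6. **Footprints.** Cell-type footprints are kept only if they overlap a
   consensus footprint. A footprint belongs to every enhancer it overlaps
   and keeps its own (unclipped) width; inter-footprint distances are
   edge-to-edge gaps of start-sorted footprints floored at 0 (midpoint
   distance available). A footprint's DBD family is that of its
   highest-bitscore motif match, bitscore ties breaking to the
   lexicographically smallest family name for determinism. A TF binds an
   enhancer *directly* when its ChIP peak overlaps the enhancer and the
   enhancer carries a footprint of the TF's own DBD family; otherwise
   indirectly. An anchoring TF for a class binds strictly more than 50% of
   the class's enhancers and is direct at strictly more than 50% of those
   bound.

7. **Chromatin clusters.** Loop arms are annotated with enhancers and TSSs
   within a 1 kb window (the bedtools-window default). Loops are adjacent
   when they share an enhancer id or gene id on either arm — shared
   identity, not mere proximity — and clusters are the connected
   components. Metrics follow the printed definitions: unique-enhancer
   count, summed contacts, span = max(arm end) − min(arm start); span is NA
   for trans-chromosomal clusters. Target genes require FPKM strictly > 2,
   with genes missing from the expression table treated as unexpressed.
   Cluster labels are non-exclusive ("aSE-containing", …); label pairs are
   compared metric-by-metric with the Wilcoxon rank-sum test.

8. **Predictor.** Enhancers ranked by one factor's signal (zeros when
   absent). The operating point is the two-step cutoff: the global
   inflection g of the ranked curve, then a local inflection recomputed on
   the sub-curve of scores ≤ g with g as the new reference maximum (the
   local cutoff can never exceed g). ROC sweeps descending unique scores
   with ties grouped (AUC equals the tie-adjusted Mann–Whitney statistic
   over n⁺·n⁻); predicted positives use strict >, consistent with every
   other cutoff in the package. Two factors are combined by summing
   min–max-normalized signals (min and product are exposed; which rule the
   combined predictor "should" use is a genuinely open design point — sum
   is the least committal monotone pooling).

## Statistical conventions

The rank-sum test is two-sided Mann–Whitney with midrank ties: exact
enumeration when both samples have ≤ 8 observations and no ties, normal
approximation with tie correction otherwise; two identical constant samples
return p = 1. All group comparisons in the package go through this one
function.

## Synthetic-data generator

The generator plants the structure the analysis assumes and nothing more;
its defaults are the package's study conditions:

- 500 enhancers on 4 × 50 Mb chromosomes in fractions
  aSE 0.05 / dSE 0.02 / cSE 0.13 / rEh 0.80; 300 genes; 15 factors
  (MED1, P300 and 13 sequence-specific TFs with cycling DBD families).
- cSE/dSE enhancers sit in runs of ~8 with 2–10 kb gaps (well under the
  12.5 kb stitching distance) so the classic-SE caller can recover them;
  aSE and rEh enhancers are isolated (aSE > 1 Mb from any run, rEh > 20 kb
  from anything, beyond stitching range). TSSs keep > 8 kb clearance from
  planted enhancers. 5% additional promoter-proximal decoy DNase+H3K27ac
  peaks are planted within ±2 kb of a TSS so the TSS-exclusion filter has
  something to catch.
- Binding: per factor, Bernoulli with p = 0.85 (aSE/dSE), 0.45 (cSE),
  0.25 (rEh). Peak signals are log-normal, log-location 1.0 and σ = 0.5,
  shifted +1.5 on the log scale at high-occupancy classes. H3K27ac at run
  members is shifted +0.75 — classic SE regions carry high H3K27ac by
  definition, and without it run recovery would hinge on run length alone.
- Footprints: per-enhancer Poisson counts (mean 6 high / 2 low), widths
  Normal(18, 3) vs Normal(12, 3) bp, families biased toward NR/C2H2 at
  high classes; 90% of footprints appear in the consensus set. Bitscores
  are Normal(12, 3) for all classes.
- Loops: per-enhancer degree Poisson(5 high / 1 low) to one of the few
  nearest genes; contacts 1 + Poisson(8 high / 2 low). Partner choice is
  deliberately local so the loop graph does not collapse into one giant
  component. Expression is log-normal (log-location 1, σ 1), +1.0 for genes
  looped to a high-occupancy enhancer (FPKM units).

All randomness flows from one `numpy` generator seeded by `seed`; a fixed
seed reproduces byte-identical files.

**What passing on synthetic data does and does not show.** The generator
reproduces class separation, run geometry, decoys, footprint/loop/expression
direction — the features the pipeline's logic depends on. It does not model
read-level noise, peak-caller artifacts, copy-number effects, correlated
factor binding (factors are conditionally independent given class), motif
sequence content, or realistic loop-length distributions; recovery rates
here therefore validate the machinery, not dataset-specific performance on
real cell lines.

## Numerical choices and degenerate inputs

- Strict `>` defines every positive call (above OS cutoff, above SE signal
  cutoff, predicted positive, FPKM expressed, anchoring percentages).
- `find_inflection` demands ≥ 3 values; constant input cuts at the constant.
  The rule is equivariant under positive affine maps (tested).
- Duplicate intervals are preserved everywhere; deduplication is never
  implicit.
- Fewer than 3 stitched regions → no SE called (warning).
- Empty enhancer classes are skipped with a warning in anchoring calls and
  cluster comparisons; a TF with unknown DBD family can only bind
  indirectly.
- Trans-chromosomal loops are accepted; only span is NA for their clusters.
- BEDPE contact counts are read from column 8 and floored at 1.

## Problem sizes

Tests and the acceptance script run the generator at its defaults
(500 enhancers, 15 factors, ~90 clusters per bundle) over a handful of
seeds; brute-force oracle comparisons use 1,000 random instances of size
≤ ~40 per engine. These sizes were chosen to exercise every code path with
comfortable statistical margins.

## Known limitations

- ROSE region signal is a sum of peak signalValues, not integrated read
  density; rankings agree with density-based ROSE only insofar as peak
  signals track density.
- The OS cutoff is a single global elbow; datasets whose OS curve has no
  clear two-regime structure will yield liberal or conservative cutoffs
  (the no-elbow guard then calls nothing high rather than everything).
- Footprint motif annotations are consumed as given; no motif scanning or
  bias correction is performed.
- Cluster building requires exact shared ids; two loops whose arms overlap
  the same locus but were annotated to different enhancers do not join.
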