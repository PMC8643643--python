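# asescope

Discovery and characterization of **autonomous super-enhancers (aSEs)** from
peak-level epigenomic data.

Classic super-enhancer (SE) callers such as ROSE define SEs as long stitched
runs of enhancers ranked by a single mark (typically H3K27ac), which by
construction misses isolated enhancers that are nonetheless bound by an
exceptionally dense array of transcription factors and co-factors. `asescope`
ranks every active enhancer by a multi-factor **occupancy score** and
classifies enhancers into four classes depending on whether they are
high-occupancy and whether they fall inside a classic ROSE SE region:

| class | high occupancy | inside classic SE region |
|-------|----------------|--------------------------|
| aSE (autonomous SE) | yes | no |
| dSE (dual SE)       | yes | yes |
| cSE (constituent SE)| no  | yes |
| rEh (regular enhancer) | no | no |

It is aimed at regulatory-genomics analysts working with ENCODE-style
narrowPeak, BED, BEDPE and expression tables.

## The occupancy score

Active enhancers are DNase-seq peaks that overlap an H3K27ac peak and lie
more than 2.5 kb from every transcription start site. For each active
enhancer *E* and each TF/co-factor ChIP-seq dataset *f*, the peak
signalValue is recorded (0 when *f* has no overlapping peak) and min–max
normalized per factor. The occupancy score is

```
OS(E) = N_E × Σ_f Signal_E(f)
```

where *N_E* is the number of factors bound at *E* and *Signal_E(f)* the
normalized signal. Enhancers are ranked by OS and everything strictly above
the ranked curve's tangent/inflection point — the point where the curve's
slope reaches (max − min)/n, exactly the ROSE cutoff geometry — is called
high-occupancy.

Downstream characterization includes DNase-footprint statistics per class
(count, width, inter-footprint spacing, motif bitscore, DNA-binding-domain
family assignment, direct vs indirect TF binding, anchoring-TF calls),
clustering of Hi-C/ChIA-PET loops into connected components linked by shared
enhancers/TSSs with per-cluster metrics and FPKM > 2 target genes, and a
single-factor (or two-factor combined) signal-ranking predictor of aSE/dSE
membership evaluated by ROC/AUC with a two-step (global→local) inflection
cutoff.

A seeded synthetic-data generator plants ground-truth enhancer classes with
the statistical structure the analysis assumes (stitched cSE/dSE runs,
isolated aSEs, promoter-proximal decoys, class-dependent binding, footprint,
loop and expression models), so the entire pipeline is testable without any
external download.

## Worked example

```python
from asescope import GeneratorConfig, simulate, run_pipeline, recovery_report
from asescope.pipeline import evaluate_dnase_predictor

bundle = simulate(GeneratorConfig(seed=7))
result = run_pipeline(bundle)

print("active enhancers:", len(result.active))
print("classic SE regions:", sum(result.classic_se.is_se))
print("OS cutoff:", round(result.classes.cutoff_os, 2))
print("class counts:", result.classes.counts())

report = recovery_report(bundle.truth, result.classes)
print("recall of planted high-occupancy enhancers:", round(report["high_recall"], 3))

ev = evaluate_dnase_predictor(bundle, result)
print("DNase-signal AUC vs planted truth:", round(ev.auc, 3))
```

prints

```
active enhancers: 500
classic SE regions: 18
OS cutoff: 7.83
class counts: {'aSE': 26, 'dSE': 16, 'cSE': 67, 'rEh': 391}
recall of planted high-occupancy enhancers: 1.0
DNase-signal AUC vs planted truth: 0.976
```

The 500 planted enhancers all survive the active-enhancer filters (the
planted promoter-proximal decoys are removed), ROSE recovers the planted
stitched runs as 18 SE regions, and 42 enhancers (8.4%) exceed the OS
cutoff of 7.83 — 26 outside classic SE regions (aSE) and 16 inside (dSE).
Every planted high-occupancy enhancer is recovered, and ranking enhancers by
DNase signal alone separates planted aSE∪dSE from the rest with AUC 0.976.

The same stages are scriptable from the shell:

```
asescope simulate --seed 7 --outdir sim/
asescope enhancers --dnase sim/dnase.narrowPeak --h3k27ac sim/h3k27ac.narrowPeak \
    --tss sim/tss.tsv --out active.narrowPeak
asescope rose --h3k27ac sim/h3k27ac.narrowPeak --out classicSE.bed
asescope clusters --loops sim/loops.bedpe --enhancers active.narrowPeak \
    --tss sim/tss.tsv --expr sim/expr.tsv --out clusters.tsv
```

## Layout

- `asescope.io_core` — interval types, narrowPeak/BED/TSS/FASTA IO, the
  overlap engine, GC/CpG composition, rank-sum test
- `asescope.enhancer_catalog` — active-enhancer calling, peak stitching,
  classic ROSE SE calls
- `asescope.occupancy` — signal matrix, OS, inflection cutoff, 4-way
  classification
- `asescope.footprints` — consensus filtering, footprint statistics, DBD
  assignment, direct/indirect binding, anchoring TFs
- `asescope.clusters3d` — loop-arm annotation, cluster building, metrics,
  target genes, class comparisons
- `asescope.predictor` — two-step cutoff, ROC/AUC, factor combination
- `asescope.synthetic_data` — the seeded generator and truth-recovery report
- `asescope.pipeline` — end-to-end orchestration
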