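"""Self-contained synthetic inputs with planted enhancer classes.

The generator emulates the statistical structure the pipeline assumes in
real DNase/ChIP/Hi-C data, with known ground truth:

* four planted enhancer classes — aSE-like (high occupancy, isolated),
  dSE-like (high occupancy, inside stitched runs), cSE-like (ordinary
  occupancy, inside runs), rEh (ordinary occupancy, isolated);
* cSE/dSE enhancers laid out in runs with inter-peak gaps well under the
  12.5 kb ROSE stitching distance so the classic-SE caller can recover them,
  aSE enhancers > 1 Mb from any run;
* promoter-proximal decoy DNase peaks planted within ±2 kb of a TSS, which
  the active-enhancer TSS-exclusion filter must remove;
* per-factor binding probabilities and log-normal peak signals with a
  class-dependent location shift, so planted high-occupancy enhancers are
  separable on the occupancy-score curve;
* class-dependent footprint density and width, chromatin loops
  preferentially anchored at high-occupancy enhancers, and expression
  elevated for genes looped to them.

Everything is drawn from one seeded generator; the same seed reproduces a
byte-identical file bundle.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .clusters3d import Loop
from .footprints import Footprint
from .io_core import (
    GenomicInterval,
    Peak,
    PeakSet,
    TssRecord,
    write_narrowpeak,
    write_tss_table,
)
from .occupancy import EnhancerClassification

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticBundle",
    "ConfigError",
    "simulate",
    "generate",
    "write_bundle",
    "recovery_report",
]

HIGH_CLASSES = ("aSE", "dSE")
DBD_FAMILIES = ("NR", "C2H2", "bZIP", "HMG", "Forkhead")


class ConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic bundle.

    Class fractions, binding probabilities, signal shifts, footprint and
    loop/expression parameters define the planted structure; geometry fields
    (chromosome count/length, spacing) only control feasibility of the
    layout.
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 50_000_000
    n_enhancers: int = 500
    # planted class fractions in the order (aSE, dSE, cSE, rEh)
    class_fractions: tuple[float, float, float, float] = (0.05, 0.02, 0.13, 0.80)
    n_factors: int = 15
    n_genes: int = 300
    run_size: int = 8
    decoy_fraction: float = 0.05
    # per-class factor binding probability
    p_bind_high: float = 0.85
    p_bind_cse: float = 0.45
    p_bind_reh: float = 0.25
    # log-normal peak signal model
    signal_log_mu: float = 1.0
    signal_log_sigma: float = 0.5
    high_log_shift: float = 1.5  # added to log-location at aSE/dSE
    h3k27ac_run_log_shift: float = 0.75  # run members carry classic-SE-level H3K27ac
    # footprint model
    fp_mean_high: float = 6.0
    fp_mean_low: float = 2.0
    fp_width_mu_high: float = 18.0
    fp_width_mu_low: float = 12.0
    fp_width_sigma: float = 3.0
    consensus_keep_prob: float = 0.9
    # loop model
    loop_degree_high: float = 5.0
    loop_degree_low: float = 1.0
    loop_contacts_lambda_high: float = 8.0
    loop_contacts_lambda_low: float = 2.0
    # expression model
    expr_log_mu: float = 1.0
    expr_log_sigma: float = 1.0
    expr_high_log_shift: float = 1.0
    # geometry
    enhancer_width_mu: float = 500.0
    enhancer_width_sigma: float = 100.0

    def validate(self) -> None:
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ConfigError("class_fractions must sum to 1")
        for name in (
            "n_chroms", "chrom_length", "n_enhancers", "n_factors", "n_genes", "run_size",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in (
            "fp_mean_high", "fp_mean_low", "fp_width_mu_high", "fp_width_mu_low",
            "loop_degree_high", "loop_degree_low",
            "loop_contacts_lambda_high", "loop_contacts_lambda_low",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


@dataclass
class SyntheticTruth:
    """Planted ground truth: the recovery target for the pipeline."""

    classes: dict[str, str]  # enhancer id -> planted class
    binding: dict[str, list[bool]]  # enhancer id -> per-factor bound indicator
    dnase_signal: dict[str, float]
    decoy_ids: list[str]
    run_intervals: list[tuple[str, int, int]]  # planted stitched-run spans
    genes_linked_to_high: list[str]
    config: GeneratorConfig

    def high_ids(self) -> set[str]:
        return {e for e, c in self.classes.items() if c in HIGH_CLASSES}


@dataclass
class SyntheticBundle:
    config: GeneratorConfig
    dnase: PeakSet
    h3k27ac: PeakSet
    factors: list[PeakSet]
    footprints: list[Footprint]
    consensus: list[GenomicInterval]
    loops: list[Loop]
    tss: list[TssRecord]
    expression: dict[str, float]
    tf_dbd: dict[str, str]
    truth: SyntheticTruth


@dataclass
class _Enhancer:
    chrom: str
    start: int
    end: int
    cls: str
    in_run: bool
    run_idx: int  # -1 when not in a run

    @property
    def eid(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def _class_counts(cfg: GeneratorConfig) -> dict[str, int]:
    fa, fd, fc, _ = cfg.class_fractions
    n = cfg.n_enhancers
    counts = {
        "aSE": int(round(fa * n)),
        "dSE": int(round(fd * n)),
        "cSE": int(round(fc * n)),
    }
    counts["rEh"] = n - sum(counts.values())
    if counts["rEh"] < 0:
        raise ConfigError("class fractions leave no room for rEh")
    return counts


def _draw_width(rng: np.random.Generator, cfg: GeneratorConfig) -> int:
    w = rng.normal(cfg.enhancer_width_mu, cfg.enhancer_width_sigma)
    return int(np.clip(round(w), 250, 900))


def _place_layout(
    rng: np.random.Generator, cfg: GeneratorConfig
) -> tuple[list[_Enhancer], list[TssRecord], list[tuple[str, int, int]]]:
    """Lay out runs, isolated enhancers and genes along the chromosomes.

    Isolation rules: run/aSE entities are followed by >1 Mb of clearance so
    aSE-like enhancers never stitch with (or sit near) a run; rEh spacing
    exceeds the 12.5 kb stitching distance; TSSs keep >5 kb clearance from
    every planted (non-decoy) enhancer.
    """
    counts = _class_counts(cfg)
    member_labels = ["dSE"] * counts["dSE"] + ["cSE"] * counts["cSE"]
    rng.shuffle(member_labels)
    runs: list[list[str]] = [
        member_labels[i : i + cfg.run_size]
        for i in range(0, len(member_labels), cfg.run_size)
    ]
    if len(runs) >= 2 and len(runs[-1]) < 2:  # avoid degenerate single-peak runs
        runs[-2].extend(runs.pop())

    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    items_per_chrom: dict[str, list[tuple]] = {c: [] for c in chroms}
    for i, run in enumerate(runs):
        items_per_chrom[chroms[i % cfg.n_chroms]].append(("run", run))
    for i in range(counts["aSE"]):
        items_per_chrom[chroms[i % cfg.n_chroms]].append(("aSE", None))
    for i in range(counts["rEh"]):
        items_per_chrom[chroms[i % cfg.n_chroms]].append(("rEh", None))
    for i in range(cfg.n_genes):
        items_per_chrom[chroms[i % cfg.n_chroms]].append(("gene", i))

    enhancers: list[_Enhancer] = []
    tss: list[TssRecord] = []
    run_spans: list[tuple[str, int, int]] = []
    run_counter = 0
    for chrom in chroms:
        items = items_per_chrom[chrom]
        rng.shuffle(items)
        cursor = 200_000 + int(rng.integers(0, 50_000))
        for kind, payload in items:
            if kind == "run":
                run_start = cursor
                for lbl in payload:
                    w = _draw_width(rng, cfg)
                    enhancers.append(_Enhancer(chrom, cursor, cursor + w, lbl, True, run_counter))
                    cursor += w + int(rng.integers(2_000, 10_001))
                run_spans.append((chrom, run_start, enhancers[-1].end))
                run_counter += 1
                cursor += 1_050_000 + int(rng.integers(0, 200_000))
            elif kind == "aSE":
                w = _draw_width(rng, cfg)
                enhancers.append(_Enhancer(chrom, cursor, cursor + w, "aSE", False, -1))
                cursor += w + 1_050_000 + int(rng.integers(0, 200_000))
            elif kind == "rEh":
                w = _draw_width(rng, cfg)
                enhancers.append(_Enhancer(chrom, cursor, cursor + w, "rEh", False, -1))
                cursor += w + 20_000 + int(rng.integers(0, 10_000))
            else:  # gene
                strand = "+" if rng.random() < 0.5 else "-"
                tss.append(TssRecord(f"gene_{payload:04d}", chrom, cursor, strand))
                cursor += 8_000 + int(rng.integers(0, 4_000))
        if cursor > cfg.chrom_length:
            raise ConfigError(
                f"layout overflows {chrom}: needs {cursor} bp of {cfg.chrom_length}"
            )
    return enhancers, tss, run_spans


def _factor_labels(cfg: GeneratorConfig) -> list[str]:
    base = ["MED1", "P300"]
    extra = [f"TF_{i:02d}" for i in range(1, cfg.n_factors - 1)]
    return (base + extra)[: cfg.n_factors]


def _tf_dbd_map(labels: Sequence[str]) -> dict[str, str]:
    # MED1/P300 are cofactors without a sequence-specific DBD
    mapping: dict[str, str] = {}
    k = 0
    for lbl in labels:
        if lbl in ("MED1", "P300"):
            continue
        mapping[lbl] = DBD_FAMILIES[k % len(DBD_FAMILIES)]
        k += 1
    return mapping


def simulate(config: GeneratorConfig | None = None) -> SyntheticBundle:
    """Draw one synthetic bundle (in memory) from the generator model."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    enhancers, tss, run_spans = _place_layout(rng, cfg)
    labels = _factor_labels(cfg)
    tf_dbd = _tf_dbd_map(labels)

    p_bind = {"aSE": cfg.p_bind_high, "dSE": cfg.p_bind_high,
              "cSE": cfg.p_bind_cse, "rEh": cfg.p_bind_reh}

    def log_signal(shift: float) -> float:
        return float(np.exp(rng.normal(cfg.signal_log_mu + shift, cfg.signal_log_sigma)))

    # --- DNase + H3K27ac peaks at every planted enhancer
    dnase_peaks: list[Peak] = []
    h3k_peaks: list[Peak] = []
    dnase_signal: dict[str, float] = {}
    for i, e in enumerate(enhancers):
        shift = cfg.high_log_shift if e.cls in HIGH_CLASSES else 0.0
        sv = log_signal(shift)
        dnase_signal[e.eid] = sv
        iv = GenomicInterval(e.chrom, e.start, e.end)
        dnase_peaks.append(Peak(iv, f"dnase_{i:04d}", sv))
        k_shift = cfg.h3k27ac_run_log_shift if e.in_run else 0.0
        h3k_peaks.append(
            Peak(
                GenomicInterval(e.chrom, max(0, e.start - 200), e.end + 200),
                f"h3k_{i:04d}",
                log_signal(k_shift),
            )
        )

    # --- promoter-proximal decoys (must be removed by TSS exclusion)
    n_decoys = int(round(cfg.decoy_fraction * cfg.n_enhancers))
    if n_decoys > len(tss):
        raise ConfigError("more decoys requested than genes available")
    decoy_ids: list[str] = []
    decoy_gene_idx = rng.choice(len(tss), size=n_decoys, replace=False)
    for j, gi in enumerate(sorted(decoy_gene_idx.tolist())):
        t = tss[gi]
        offset = int(rng.integers(-2_000, 1_601))
        start = max(0, t.position + offset)
        iv = GenomicInterval(t.chrom, start, start + 400)
        decoy_ids.append(f"{iv.chrom}:{iv.start}-{iv.end}")
        dnase_peaks.append(Peak(iv, f"decoy_{j:03d}", log_signal(0.0)))
        h3k_peaks.append(
            Peak(GenomicInterval(iv.chrom, max(0, iv.start - 100), iv.end + 100),
                 f"h3k_decoy_{j:03d}", log_signal(0.0))
        )

    # --- per-factor binding and peaks
    binding: dict[str, list[bool]] = {e.eid: [] for e in enhancers}
    factor_sets: list[PeakSet] = []
    for f, lbl in enumerate(labels):
        peaks: list[Peak] = []
        for i, e in enumerate(enhancers):
            bound = bool(rng.random() < p_bind[e.cls])
            binding[e.eid].append(bound)
            if bound:
                shift = cfg.high_log_shift if e.cls in HIGH_CLASSES else 0.0
                q = max(1, (e.end - e.start) // 4)
                iv = GenomicInterval(e.chrom, e.start + q, e.end - q)
                peaks.append(Peak(iv, f"{lbl}_{i:04d}", log_signal(shift)))
        factor_sets.append(PeakSet(peaks, label=lbl))

    # --- footprints with class-dependent density/width + consensus set
    fam_p_high = np.array([0.35, 0.35, 0.10, 0.10, 0.10])
    fam_p_low = np.full(5, 0.2)
    footprints: list[Footprint] = []
    consensus: list[GenomicInterval] = []
    for e in enhancers:
        high = e.cls in HIGH_CLASSES
        mean = cfg.fp_mean_high if high else cfg.fp_mean_low
        mu_w = cfg.fp_width_mu_high if high else cfg.fp_width_mu_low
        count = int(rng.poisson(mean))
        width = e.end - e.start
        slot = width // count if count else 0
        if count and slot < 12:  # enhancer too small for that many footprints
            count = max(1, width // 12)
            slot = width // count
        fam_p = fam_p_high if high else fam_p_low
        for s in range(count):
            fw = int(np.clip(round(rng.normal(mu_w, cfg.fp_width_sigma)), 5, max(6, slot - 2)))
            jitter = int(rng.integers(0, max(1, slot - fw)))
            start = e.start + s * slot + jitter
            fam = DBD_FAMILIES[int(rng.choice(5, p=fam_p))]
            bits = float(np.clip(rng.normal(12.0, 3.0), 1.0, None))
            matches = [(f"{fam}_motif", fam, round(bits, 3))]
            if rng.random() < 0.3:
                fam2 = DBD_FAMILIES[int(rng.integers(0, 5))]
                matches.append(
                    (f"{fam2}_motif", fam2, round(max(0.5, bits - abs(rng.normal(2.0, 1.0))), 3))
                )
            footprints.append(Footprint(GenomicInterval(e.chrom, start, start + fw), matches))
            if rng.random() < cfg.consensus_keep_prob:
                pad = int(rng.integers(0, 4))
                consensus.append(
                    GenomicInterval(e.chrom, max(0, start - pad), start + fw + pad)
                )
    # background consensus intervals far from anything in particular
    for _ in range(cfg.n_enhancers // 10):
        c = f"chr{int(rng.integers(1, cfg.n_chroms + 1))}"
        s = int(rng.integers(0, cfg.chrom_length - 100))
        consensus.append(GenomicInterval(c, s, s + int(rng.integers(8, 30))))
    footprints.sort(key=lambda fp: (fp.interval.chrom, fp.interval.start, fp.interval.end))
    consensus.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))

    # --- loops: enhancer-to-nearby-gene, degree and contacts by class
    tss_by_chrom: dict[str, list[TssRecord]] = {}
    for t in tss:
        tss_by_chrom.setdefault(t.chrom, []).append(t)
    for lst in tss_by_chrom.values():
        lst.sort(key=lambda t: t.position)
    loops: list[Loop] = []
    genes_high: set[str] = set()
    for e in enhancers:
        high = e.cls in HIGH_CLASSES
        degree = int(rng.poisson(cfg.loop_degree_high if high else cfg.loop_degree_low))
        genes = tss_by_chrom.get(e.chrom, [])
        if not genes or degree == 0:
            continue
        positions = [t.position for t in genes]
        idx = int(np.searchsorted(positions, e.center))
        lo, hi = max(0, idx - 2), min(len(genes), idx + 2)
        for _ in range(degree):
            t = genes[int(rng.integers(lo, hi))]
            lam = cfg.loop_contacts_lambda_high if high else cfg.loop_contacts_lambda_low
            contacts = 1 + int(rng.poisson(lam))
            left = GenomicInterval(e.chrom, max(0, e.center - 500), e.center + 500)
            right = GenomicInterval(t.chrom, max(0, t.position - 500), t.position + 500)
            loops.append(Loop(left, right, contacts))
            if high:
                genes_high.add(t.gene_id)

    # --- expression: elevated for genes looped to high-occupancy enhancers
    expression: dict[str, float] = {}
    for t in tss:
        shift = cfg.expr_high_log_shift if t.gene_id in genes_high else 0.0
        expression[t.gene_id] = float(
            np.exp(rng.normal(cfg.expr_log_mu + shift, cfg.expr_log_sigma))
        )

    truth = SyntheticTruth(
        classes={e.eid: e.cls for e in enhancers},
        binding=binding,
        dnase_signal=dnase_signal,
        decoy_ids=decoy_ids,
        run_intervals=run_spans,
        genes_linked_to_high=sorted(genes_high),
        config=cfg,
    )
    return SyntheticBundle(
        config=cfg,
        dnase=PeakSet(dnase_peaks, label="DNase"),
        h3k27ac=PeakSet(h3k_peaks, label="H3K27ac"),
        factors=factor_sets,
        footprints=footprints,
        consensus=consensus,
        loops=loops,
        tss=tss,
        expression=expression,
        tf_dbd=tf_dbd,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, str]:
    """Write the bundle as the pipeline's standard text inputs.

    Emits dnase.narrowPeak, h3k27ac.narrowPeak, factor_<label>.narrowPeak,
    footprints.bed (BED6 + motif_id, dbd_family, bitscore), consensus.bed,
    loops.bedpe, tss.tsv, expr.tsv, tf_dbd.tsv, genome.fa and truth.json.
    Returns the path of each file keyed by role.
    """
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    def p(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    write_narrowpeak(bundle.dnase, p("dnase.narrowPeak"))
    write_narrowpeak(bundle.h3k27ac, p("h3k27ac.narrowPeak"))
    for ps in bundle.factors:
        write_narrowpeak(ps, p(f"factor_{ps.label}.narrowPeak"))
    with open(p("footprints.bed"), "w") as fh:
        for i, fp in enumerate(bundle.footprints):
            iv = fp.interval
            if fp.motif_matches:
                for motif, fam, bits in fp.motif_matches:
                    fh.write(
                        f"{iv.chrom}\t{iv.start}\t{iv.end}\tfp_{i:05d}\t0\t.\t{motif}\t{fam}\t{bits:g}\n"
                    )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tfp_{i:05d}\t0\t.\n")
    with open(p("consensus.bed"), "w") as fh:
        for iv in bundle.consensus:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    with open(p("loops.bedpe"), "w") as fh:
        for i, lp in enumerate(bundle.loops):
            fh.write(
                f"{lp.left.chrom}\t{lp.left.start}\t{lp.left.end}\t"
                f"{lp.right.chrom}\t{lp.right.start}\t{lp.right.end}\t"
                f"loop_{i:05d}\t{lp.contacts}\n"
            )
    write_tss_table(bundle.tss, p("tss.tsv"))
    with open(p("expr.tsv"), "w") as fh:
        fh.write("gene_id\tfpkm\n")
        for t in bundle.tss:
            fh.write(f"{t.gene_id}\t{bundle.expression[t.gene_id]:.6g}\n")
    with open(p("tf_dbd.tsv"), "w") as fh:
        fh.write("tf_label\tdbd_family\n")
        for tf, fam in bundle.tf_dbd.items():
            fh.write(f"{tf}\t{fam}\n")
    # small random FASTA for sequence-composition exercises
    rng = np.random.default_rng(bundle.config.seed + 101)
    with open(p("genome.fa"), "w") as fh:
        for name in ("seqA", "seqB"):
            seq = "".join(rng.choice(list("ACGTN"), size=2000, p=[0.24, 0.26, 0.26, 0.23, 0.01]))
            fh.write(f">{name}\n")
            for k in range(0, len(seq), 60):
                fh.write(seq[k : k + 60] + "\n")
    with open(p("truth.json"), "w") as fh:
        t = bundle.truth
        json.dump(
            {
                "config": dataclasses.asdict(t.config),
                "classes": t.classes,
                "binding": t.binding,
                "dnase_signal": {k: round(v, 6) for k, v in t.dnase_signal.items()},
                "decoy_ids": t.decoy_ids,
                "run_intervals": t.run_intervals,
                "genes_linked_to_high": t.genes_linked_to_high,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    return paths


def generate(config: GeneratorConfig | None = None, outdir: str = "synthetic") -> SyntheticBundle:
    """Simulate a bundle and write it under ``outdir``."""
    bundle = simulate(config)
    write_bundle(bundle, outdir)
    return bundle


def recovery_report(
    truth: SyntheticTruth, classes: EnhancerClassification
) -> dict:
    """Precision/recall of the pipeline's high-occupancy (aSE ∪ dSE) calls
    against the planted classes, plus the full 4×4 confusion matrix.

    The classification must cover exactly the planted non-decoy enhancers.
    """
    called = dict(zip(classes.enhancer_ids, classes.labels))
    planted = truth.classes
    if set(called) != set(planted):
        raise ValueError(
            f"enhancer universe mismatch: {len(called)} called vs {len(planted)} planted"
        )
    order = ("aSE", "dSE", "cSE", "rEh")
    confusion = {p: {c: 0 for c in order} for p in order}
    for eid, p_cls in planted.items():
        confusion[p_cls][called[eid]] += 1

    true_high = {e for e, c in planted.items() if c in HIGH_CLASSES}
    called_high = {e for e, c in called.items() if c in HIGH_CLASSES}
    tp = len(true_high & called_high)
    precision = tp / len(called_high) if called_high else 0.0
    recall = tp / len(true_high) if true_high else 0.0
    per_class = {}
    for cls in order:
        t = {e for e, c in planted.items() if c == cls}
        c = {e for e, cc in called.items() if cc == cls}
        inter = len(t & c)
        per_class[cls] = {
            "precision": inter / len(c) if c else 0.0,
            "recall": inter / len(t) if t else 0.0,
            "n_planted": len(t),
            "n_called": len(c),
        }
    return {
        "high_precision": precision,
        "high_recall": recall,
        "per_class": per_class,
        "confusion": confusion,
    }
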