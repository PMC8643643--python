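"""Core genomic-interval plumbing shared by every pipeline stage.

Coordinates are 0-based half-open (BED convention) throughout. The module
provides the narrowPeak/BED/TSS/FASTA readers, the interval-overlap engine
used for every peak-vs-peak and peak-vs-point intersection in the pipeline,
GC/CpG composition, and the Wilcoxon rank-sum test used for all group
comparisons.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "Peak",
    "PeakSet",
    "TssRecord",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_tss_table",
    "write_tss_table",
    "read_fasta",
    "overlap_pairs",
    "sequence_composition",
    "rank_sum_test",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic span."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def expanded(self, pad: int) -> "GenomicInterval":
        """Pad both sides by ``pad`` bp, clamping the start at 0."""
        return GenomicInterval(self.chrom, max(0, self.start - pad), self.end + pad, self.strand)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A scored peak (narrowPeak semantics: signal_value is column 7)."""

    interval: GenomicInterval
    name: str = "."
    signal_value: float = 1.0
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if not np.isfinite(self.signal_value) or self.signal_value < 0:
            raise ValueError(f"invalid signal value {self.signal_value} for peak {self.name}")


class PeakSet:
    """An ordered, coordinate-sorted collection of peaks for one assay/factor."""

    def __init__(self, peaks: Iterable[Peak], label: str = "") -> None:
        self.peaks: list[Peak] = sorted(
            peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
        )
        self.label = label

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]

    def signal_values(self) -> np.ndarray:
        return np.array([p.signal_value for p in self.peaks], dtype=float)

    def __repr__(self) -> str:
        return f"PeakSet(label={self.label!r}, n={len(self)})"


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site as a 0-based point."""

    gene_id: str
    chrom: str
    position: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"negative TSS position for {self.gene_id}")


class ParseError(ValueError):
    pass


def _parse_int(token: str, path: str, lineno: int, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer {what} {token!r}") from None


def read_narrowpeak(
    path,
    label: str = "",
    signal_column: int | None = None,
) -> PeakSet:
    """Read an ENCODE narrowPeak (BED6+4) or plain BED file into a PeakSet.

    Parameters
    ----------
    path
        Input file. 10-column files are parsed as narrowPeak (signalValue =
        column 7, summit = column 10). Shorter BED files take their signal
        from ``signal_column`` (1-based) if given; with no signal column
        available every peak gets signal 1.0 and a warning is logged.
    """
    peaks: list[Peak] = []
    warned = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            start = _parse_int(fields[1], str(path), lineno, "start")
            end = _parse_int(fields[2], str(path), lineno, "end")
            if start >= end or start < 0:
                raise ParseError(f"{path}:{lineno}: invalid span {start}-{end}")
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-." else "."
            if len(fields) >= 10:
                signal = float(fields[6])
                summit = _parse_int(fields[9], str(path), lineno, "summit")
            elif signal_column is not None:
                if len(fields) < signal_column:
                    raise ParseError(f"{path}:{lineno}: missing signal column {signal_column}")
                signal = float(fields[signal_column - 1])
                summit = -1
            else:
                if not warned:
                    logger.warning("%s: no signal column; assigning signal 1.0", path)
                    warned = True
                signal = 1.0
                summit = -1
            peaks.append(
                Peak(GenomicInterval(chrom, start, end, strand), name, signal, summit)
            )
    return PeakSet(peaks, label=label or str(path))


def write_narrowpeak(peaks: PeakSet, path) -> None:
    """Write a PeakSet as canonical 10-column narrowPeak (round-trips exactly)."""
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t0\t{iv.strand}\t"
                f"{p.signal_value:g}\t-1\t-1\t{p.summit_offset}\n"
            )


def read_tss_table(path) -> list[TssRecord]:
    """Read a TSV of (gene_id, chrom, position, strand); header optional."""
    records: list[TssRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "gene_id":  # header
                continue
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            records.append(
                TssRecord(fields[0], fields[1], _parse_int(fields[2], str(path), lineno, "position"), fields[3])
            )
    return records


def write_tss_table(records: Sequence[TssRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tposition\tstrand\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.chrom}\t{r.position}\t{r.strand}\n")


def read_fasta(path) -> dict[str, str]:
    """Read a (small) FASTA into a chrom → sequence dict."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def _tree_by_chrom(intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for j, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)
    return trees


def overlap_pairs(
    a: PeakSet | Sequence[GenomicInterval],
    b: PeakSet | Sequence[GenomicInterval],
    window_bp: int = 0,
) -> list[tuple[int, int]]:
    """All (i, j) index pairs where a_i padded by ``window_bp`` shares ≥1 bp with b_j.

    ``window_bp = 0`` is plain intersection; 1000 reproduces the
    bedtools-window default gap used for loop-arm annotation. Each qualifying
    pair is reported exactly once, sorted by (i, j).
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    a_ivs = a.intervals() if isinstance(a, PeakSet) else list(a)
    b_ivs = b.intervals() if isinstance(b, PeakSet) else list(b)
    trees = _tree_by_chrom(b_ivs)
    out: list[tuple[int, int]] = []
    for i, iv in enumerate(a_ivs):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        lo = max(0, iv.start - window_bp)
        hi = iv.end + window_bp
        for hit in tree.overlap(lo, hi):
            out.append((i, hit.data))
    out.sort()
    return out


def overlapping_indices(
    a: PeakSet | Sequence[GenomicInterval],
    b: PeakSet | Sequence[GenomicInterval],
    window_bp: int = 0,
) -> set[int]:
    """Indices in ``a`` hit by at least one interval of ``b``."""
    return {i for i, _ in overlap_pairs(a, b, window_bp)}


def sequence_composition(
    seq_source: Mapping[str, str],
    intervals: PeakSet | Sequence[GenomicInterval],
) -> list[tuple[float, float]]:
    """Per-interval (GC%, CpG%).

    GC% = 100·(#G + #C)/width; CpG% = 100·(#CG dinucleotides)/(width − 1)
    (0 for width-1 intervals). Case-insensitive; N counts as non-GC and
    interrupts CpG dinucleotides.
    """
    ivs = intervals.intervals() if isinstance(intervals, PeakSet) else list(intervals)
    out: list[tuple[float, float]] = []
    for iv in ivs:
        seq = seq_source.get(iv.chrom)
        if seq is None or iv.end > len(seq):
            raise IndexError(f"interval {iv.chrom}:{iv.start}-{iv.end} beyond sequence end")
        sub = seq[iv.start : iv.end].upper()
        gc = 100.0 * (sub.count("G") + sub.count("C")) / len(sub)
        cpg = 100.0 * sub.count("CG") / (len(sub) - 1) if len(sub) > 1 else 0.0
        out.append((gc, cpg))
    return out


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test.

    Exact enumeration when both samples have ≤ 8 observations and no ties;
    normal approximation with midrank tie correction otherwise. Returns
    (U statistic for x, two-sided p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        # identical constant samples: no evidence against the null
        u = x.size * y.size / 2.0
        return u, 1.0
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
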