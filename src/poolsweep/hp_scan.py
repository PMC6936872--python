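"""Sliding-window pooled-heterozygosity scan for selective sweeps.

For each sliding window (default 150 kb with 75 kb step, i.e. 50 %
overlap) the pooled heterozygosity over the SNVs it contains is

    Hp = 2 * (sum nMAJ) * (sum nMIN) / (sum nMAJ + sum nMIN)^2

where nMAJ/nMIN are major/minor allele read counts per SNV. Hp lies in
[0, 0.5]; sweeps depress it. Window values are Z-transformed over all
scored windows, ZHp = (Hp - mean) / sd, and windows with -ZHp at or above
a threshold (default 4) are merged into selection signatures and
annotated with overlapping genes.

Windows that contain no SNV get no Hp and are excluded from the
Z-transform: a window without callable SNVs carries no evidence, and
scoring it as Hp = 0 would fake the strongest possible sweep signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from operator import attrgetter
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
from intervaltree import IntervalTree

from .pool_io import GeneInterval, GenomeLayout, SnvRecord

__all__ = [
    "ScanConfig",
    "Window",
    "WindowStat",
    "ZSummary",
    "Signature",
    "DegenerateInputError",
    "make_windows",
    "window_hp",
    "z_transform",
    "scan_pool",
    "merge_significant_windows",
    "annotate_signatures",
    "write_window_stats",
    "write_signatures_bed",
    "write_signatures_tsv",
]


class DegenerateInputError(ValueError):
    """Z-transform input with < 2 finite values or zero spread."""


@dataclass(frozen=True)
class ScanConfig:
    """Window geometry and significance threshold for the scan."""

    window_size: int = 150_000
    step: int = 75_000
    z_threshold: float = 4.0

    def __post_init__(self):
        if self.window_size <= 0 or self.step <= 0:
            raise ValueError("window_size and step must be positive")
        if self.step > self.window_size:
            raise ValueError("step must not exceed window_size")


@dataclass(frozen=True)
class Window:
    """A genomic window, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")

    def overlaps(self, other: "Window") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class WindowStat:
    """Hp and its Z-score for one window; ``hp`` is NaN when no SNV falls in it."""

    window: Window
    n_snvs: int
    hp: float
    zhp: float = math.nan

    @property
    def neg_zhp(self) -> float:
        return -self.zhp


@dataclass(frozen=True)
class ZSummary:
    """Mean/sd (population sd) used by a Z-transform and the window count."""

    mean: float
    sd: float
    n_windows_used: int


@dataclass
class Signature:
    """Merged run of significant windows, annotated with overlapping genes."""

    chrom: str
    start: int
    end: int
    peak_neg_z: float
    n_windows: int
    genes: list[str] = field(default_factory=list)


def make_windows(layout: GenomeLayout, config: ScanConfig) -> list[Window]:
    """Enumerate sliding windows over every chromosome of ``layout``.

    Windows start at 0 and advance by ``step``. A window is emitted while
    it contributes at least one full step of new sequence
    (``start + step <= length``); the terminal window is truncated at the
    chromosome end. A chromosome shorter than one step still gets a
    single truncated window so no sequence is silently dropped.
    """
    windows = []
    for chrom, length in layout:
        start = 0
        while start + config.step <= length:
            windows.append(Window(chrom, start, min(start + config.window_size, length)))
            start += config.step
        if not windows or windows[-1].chrom != chrom:
            windows.append(Window(chrom, 0, length))
    return windows


def window_hp(snvs: Sequence[SnvRecord]) -> float:
    """Pooled heterozygosity of one window's SNVs; NaN for an empty window."""
    if not snvs:
        return math.nan
    s_maj = sum(r.n_maj for r in snvs)
    s_min = sum(r.n_min for r in snvs)
    return 2.0 * s_maj * s_min / (s_maj + s_min) ** 2


def z_transform(values: Sequence[float]) -> tuple[np.ndarray, ZSummary]:
    """Z-score ``values`` about their mean with population sd.

    Missing entries (NaN/None) are excluded from mean and sd and stay
    missing in the output. Fewer than two finite values, or all finite
    values equal, raises :class:`DegenerateInputError`.
    """
    arr = np.array(
        [math.nan if v is None else float(v) for v in values], dtype=float
    )
    finite = np.isfinite(arr)
    n = int(finite.sum())
    if n < 2:
        raise DegenerateInputError("need at least 2 non-missing values")
    mu = float(arr[finite].mean())
    sigma = float(arr[finite].std(ddof=0))
    if sigma == 0.0:
        raise DegenerateInputError("zero spread: all non-missing values equal")
    z = np.full_like(arr, math.nan)
    z[finite] = (arr[finite] - mu) / sigma
    return z, ZSummary(mu, sigma, n)


def _window_index(
    snvs: Sequence[SnvRecord], windows: Sequence[Window]
) -> list[list[int]]:
    """For each window, indices of the SNVs inside it (0-based positions)."""
    by_chrom: dict[str, list[int]] = {}
    pos0 = [r.pos - 1 for r in snvs]
    for i, r in enumerate(snvs):
        by_chrom.setdefault(r.chrom, []).append(i)
    for idx in by_chrom.values():
        idx.sort(key=lambda i: pos0[i])
    out = []
    for w in windows:
        idx = by_chrom.get(w.chrom, [])
        positions = [pos0[i] for i in idx]
        lo = np.searchsorted(positions, w.start, side="left")
        hi = np.searchsorted(positions, w.end, side="left")
        out.append(idx[lo:hi])
    return out

def scan_pool(
    snvs: Sequence[SnvRecord],
    layout: GenomeLayout,
    config: ScanConfig = ScanConfig(),
) -> tuple[list[WindowStat], ZSummary]:
    """Run the full windowed Hp scan for one pool.

    Returns per-window statistics (with ZHp filled in for scored windows)
    and the Z-transform summary. SNV-free windows are reported with
    ``n_snvs == 0`` and NaN scores.
    """
    windows = make_windows(layout, config)
    index = _window_index(snvs, windows)
    maj = np.array([r.n_maj for r in snvs], dtype=float)
    mnr = np.array([r.n_min for r in snvs], dtype=float)
    stats = []
    for w, idx in zip(windows, index):
        if idx:
            s_maj, s_min = maj[idx].sum(), mnr[idx].sum()
            hp = 2.0 * s_maj * s_min / (s_maj + s_min) ** 2
        else:
            hp = math.nan
        stats.append(WindowStat(w, len(idx), hp))
    z, summary = z_transform([s.hp for s in stats])
    for s, zi in zip(stats, z):
        s.zhp = float(zi)
    return stats, summary


def merge_significant_windows(
    stats: Sequence[WindowStat],
    threshold: float,
    score: Callable = attrgetter("neg_zhp"),
) -> list[Signature]:
    """Merge overlapping/abutting windows with ``score >= threshold``.

    ``score`` defaults to -ZHp (low heterozygosity); the FST scan passes
    ``attrgetter("zfst")`` to reuse the same merging for high
    differentiation. Significance is one-sided.
    """
    hits = [
        s
        for s in stats
        if math.isfinite(score(s)) and score(s) >= threshold
    ]
    hits.sort(key=lambda s: (s.window.chrom, s.window.start))
    signatures: list[Signature] = []
    for s in hits:
        w = s.window
        if (
            signatures
            and signatures[-1].chrom == w.chrom
            and w.start <= signatures[-1].end  # overlap or abut (gap 0)
        ):
            sig = signatures[-1]
            sig.end = max(sig.end, w.end)
            sig.peak_neg_z = max(sig.peak_neg_z, score(s))
            sig.n_windows += 1
        else:
            signatures.append(Signature(w.chrom, w.start, w.end, score(s), 1))
    return signatures


def annotate_signatures(
    signatures: Sequence[Signature],
    gene_intervals: Sequence[GeneInterval],
    layout: Optional[GenomeLayout] = None,
) -> list[Signature]:
    """Attach names of genes overlapping each signature by >= 1 bp.

    Gene names are listed in order of gene start. Intervals on
    chromosomes absent from ``layout`` (when given) are skipped with a
    warning.
    """
    import warnings

    trees: dict[str, IntervalTree] = {}
    for g in gene_intervals:
        if layout is not None and g.chrom not in layout:
            warnings.warn(f"annotation on unknown sequence {g.chrom!r} skipped")
            continue
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g.name)
    out = []
    for sig in signatures:
        hits = trees.get(sig.chrom, IntervalTree()).overlap(sig.start, sig.end)
        genes = [iv.data for iv in sorted(hits, key=lambda iv: (iv.begin, iv.data))]
        out.append(
            Signature(sig.chrom, sig.start, sig.end, sig.peak_neg_z, sig.n_windows, genes)
        )
    return out


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_window_stats(path: Union[str, Path], stats: Sequence[WindowStat]) -> None:
    """Per-window TSV: chrom, start, end, n_snvs, hp, zhp, neg_zhp."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tn_snvs\thp\tzhp\tneg_zhp\n")
        for s in stats:
            hp = f"{s.hp:.6f}" if math.isfinite(s.hp) else "NA"
            z = f"{s.zhp:.6f}" if math.isfinite(s.zhp) else "NA"
            nz = f"{s.neg_zhp:.6f}" if math.isfinite(s.zhp) else "NA"
            fh.write(
                f"{s.window.chrom}\t{s.window.start}\t{s.window.end}\t"
                f"{s.n_snvs}\t{hp}\t{z}\t{nz}\n"
            )


def write_signatures_bed(path: Union[str, Path], signatures: Sequence[Signature]) -> None:
    """BED6 export; name = peak score, score = peak scaled to [0, 1000]."""
    with open(path, "w") as fh:
        for sig in signatures:
            score = max(0, min(1000, int(round(sig.peak_neg_z * 100))))
            fh.write(
                f"{sig.chrom}\t{sig.start}\t{sig.end}\t"
                f"{sig.peak_neg_z:.4f}\t{score}\t.\n"
            )


def write_signatures_tsv(path: Union[str, Path], signatures: Sequence[Signature]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tpeak_neg_z\tn_windows\tgenes\n")
        for sig in signatures:
            fh.write(
                f"{sig.chrom}\t{sig.start}\t{sig.end}\t{sig.peak_neg_z:.6f}\t"
                f"{sig.n_windows}\t{','.join(sig.genes)}\n"
            )
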