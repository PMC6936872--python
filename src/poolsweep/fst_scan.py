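"""Per-site pairwise FST between two pools, aggregated in sliding windows.

FST is the classical total/subpopulation heterozygosity partition: with
major-allele read frequencies p_a, p_b in the two pools and
p_bar = (p_a + p_b) / 2,

    HT  = 2 * p_bar * (1 - p_bar)
    HS  = (2 p_a (1 - p_a) + 2 p_b (1 - p_b)) / 2
    FST = (HT - HS) / HT          (0 when HT = 0)

This is a plain read-frequency estimator: HT - HS equals 2 Var(p) >= 0,
so FST always lies in [0, 1] and no clamping is needed. No pool-size or
coverage unbiasedness correction is applied; pool sizes are kept on
:class:`~poolsweep.pool_io.PoolSpec` should one be added.

Window values are coverage-weighted means of per-site FST (weight =
min of the two pools' coverages, so a site is never trusted beyond its
thinner pool); an unweighted mean is available for sensitivity checks.
Z-transformation and signature merging reuse the Hp-scan machinery, with
significance one-sided on +ZFST (high differentiation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from operator import attrgetter
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .pool_io import SnvFilter, SyncSite, _ACGT_SYNC_IDX, BASE_ORDER
from .hp_scan import Window, ZSummary, z_transform

__all__ = [
    "FstSiteStat",
    "FstWindowStat",
    "FST_FILTER",
    "site_fst",
    "sites_from_sync",
    "window_fst",
    "write_site_fst",
    "write_window_fst",
]

# the differentiation scan uses laxer coverage limits than the Hp scan:
# min coverage 4, max 50, minor-allele support 2
FST_FILTER = SnvFilter(min_coverage=4, max_coverage=50, min_count=2)


@dataclass
class FstSiteStat:
    """Per-site FST with the pool frequencies and coverages behind it."""

    chrom: str
    pos: int  # 1-based
    p_a: float
    p_b: float
    coverage_a: int
    coverage_b: int
    fst: float


@dataclass
class FstWindowStat:
    """Coverage-weighted window FST and its Z-score."""

    window: Window
    n_sites: int
    fst: float
    zfst: float = math.nan


def site_fst(
    counts_a: Sequence[int],
    counts_b: Sequence[int],
    snv_filter: SnvFilter = FST_FILTER,
    chrom: str = "",
    pos: int = 0,
) -> Optional[FstSiteStat]:
    """FST at one site from two pools' count sextets, or ``None``.

    The site is used iff it is biallelic across the union of both pools,
    each pool's coverage lies in ``[min_coverage, max_coverage]``, and the
    combined minor-allele count is at least ``min_count``.
    """
    a4 = [counts_a[i] for i in _ACGT_SYNC_IDX]
    b4 = [counts_b[i] for i in _ACGT_SYNC_IDX]
    tot = [x + y for x, y in zip(a4, b4)]
    nz = [k for k in range(4) if tot[k] > 0]
    if len(nz) != 2:
        return None
    cov_a, cov_b = sum(a4), sum(b4)
    if not (snv_filter.min_coverage <= cov_a <= snv_filter.max_coverage):
        return None
    if not (snv_filter.min_coverage <= cov_b <= snv_filter.max_coverage):
        return None
    # major allele by combined counts, tie kept stable in A<C<G<T order
    k_maj, k_min = sorted(nz, key=lambda k: -tot[k])
    if tot[k_min] < snv_filter.min_count:
        return None
    p_a = a4[k_maj] / cov_a
    p_b = b4[k_maj] / cov_b
    p_bar = (p_a + p_b) / 2.0
    ht = 2.0 * p_bar * (1.0 - p_bar)
    hs = (2.0 * p_a * (1.0 - p_a) + 2.0 * p_b * (1.0 - p_b)) / 2.0
    fst = 0.0 if ht == 0.0 else (ht - hs) / ht
    return FstSiteStat(chrom, pos, p_a, p_b, cov_a, cov_b, fst)


def sites_from_sync(
    sites: Iterable[SyncSite],
    index_a: int,
    index_b: int,
    snv_filter: SnvFilter = FST_FILTER,
) -> list[FstSiteStat]:
    """Per-site FST for one pool pair over a sync stream."""
    out = []
    for site in sites:
        stat = site_fst(
            site.counts[index_a],
            site.counts[index_b],
            snv_filter,
            chrom=site.chrom,
            pos=site.pos,
        )
        if stat is not None:
            out.append(stat)
    return out


def window_fst(
    sites: Sequence[FstSiteStat],
    windows: Sequence[Window],
    weighted: bool = True,
) -> tuple[list[FstWindowStat], ZSummary]:
    """Aggregate per-site FST into windows and Z-transform.

    Window value = sum(w_i fst_i) / sum(w_i), w_i = min(coverage_a,
    coverage_b) (or 1 when ``weighted`` is off). Windows without sites are
    missing; a genome with zero spread in window FST (e.g. identical
    pools) raises the Z-transform's degenerate-input error.
    """
    by_chrom: dict[str, list[FstSiteStat]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    for lst in by_chrom.values():
        lst.sort(key=lambda s: s.pos)
    stats = []
    for w in windows:
        lst = by_chrom.get(w.chrom, [])
        positions = [s.pos - 1 for s in lst]
        lo = np.searchsorted(positions, w.start, side="left")
        hi = np.searchsorted(positions, w.end, side="left")
        chunk = lst[lo:hi]
        if chunk:
            weights = [
                min(s.coverage_a, s.coverage_b) if weighted else 1.0 for s in chunk
            ]
            value = sum(wi * s.fst for wi, s in zip(weights, chunk)) / sum(weights)
        else:
            value = math.nan
        stats.append(FstWindowStat(w, len(chunk), value))
    z, summary = z_transform([s.fst for s in stats])
    for s, zi in zip(stats, z):
        s.zfst = float(zi)
    return stats, summary


def write_site_fst(path: Union[str, Path], sites: Sequence[FstSiteStat]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tp_a\tp_b\tcoverage_a\tcoverage_b\tfst\n")
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.p_a:.6f}\t{s.p_b:.6f}\t"
                f"{s.coverage_a}\t{s.coverage_b}\t{s.fst:.6f}\n"
            )


def write_window_fst(path: Union[str, Path], stats: Sequence[FstWindowStat]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tn_sites\tfst\tzfst\n")
        for s in stats:
            fst = f"{s.fst:.6f}" if math.isfinite(s.fst) else "NA"
            z = f"{s.zfst:.6f}" if math.isfinite(s.zfst) else "NA"
            fh.write(
                f"{s.window.chrom}\t{s.window.start}\t{s.window.end}\t"
                f"{s.n_sites}\t{fst}\t{z}\n"
            )
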