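"""Readers/writers for pool-seq file dialects and SNV record construction.

The on-disk formats handled here are the plain tab-separated dialects used
throughout pooled resequencing work:

* ``sync`` -- PoPoolation2-style per-site base counts, one ``A:T:C:G:N:del``
  sextet per pool (1-based positions);
* samtools-depth tables (``chrom  pos  depth``, 1-based, per-base);
* chromosome-length tables (``chrom  length``);
* gene annotation intervals as BED (0-based half-open) or GFF3 (1-based
  inclusive, converted on import);
* GATK ``VariantsToTable``-style genotype tables for individually sequenced
  cohorts (``CHROM  POS  REF`` plus one ``X/Y`` genotype column per animal).

All internal interval arithmetic is 0-based half-open; sync and depth
positions are 1-based on disk, matching each format's convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "PoolSpec",
    "SyncSite",
    "SnvRecord",
    "SnvFilter",
    "DepthTrack",
    "GeneInterval",
    "SyncFormatError",
    "DepthFormatError",
    "read_sync",
    "write_sync",
    "sync_to_snvs",
    "genotypes_to_counts",
    "read_depth_table",
    "write_depth_table",
    "read_layout",
    "write_layout",
    "read_gene_intervals",
]

# sync sextet base order (PoPoolation2): A, T, C, G, N, deletion
SYNC_BASES = ("A", "T", "C", "G", "N", "del")
# substitution bases in fixed tie-break order
BASE_ORDER = ("A", "C", "G", "T")
# index of each substitution base within a sync sextet
_ACGT_SYNC_IDX = (0, 2, 3, 1)  # A, C, G, T


class SyncFormatError(ValueError):
    """Malformed sync line (wrong column count or non-integer count)."""


class DepthFormatError(ValueError):
    """Malformed depth-table line (wrong columns or negative depth)."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome/scaffold names with lengths in base pairs."""

    chromosomes: tuple[tuple[str, int], ...]

    def __init__(self, chromosomes: Iterable[tuple[str, int]]):
        chroms = tuple((str(n), int(l)) for n, l in chromosomes)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate sequence names in layout")
        for name, length in chroms:
            if length <= 0:
                raise ValueError(f"non-positive length for {name!r}: {length}")
        object.__setattr__(self, "chromosomes", chroms)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def __iter__(self):
        return iter(self.chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return any(n == chrom for n, _ in self.chromosomes)


@dataclass(frozen=True)
class PoolSpec:
    """A sequenced DNA pool: ``n_chromosomes = 2 * n_individuals``.

    The chromosome count is what enters the pooled sampling model (it is
    the GATK ``--ploidy`` / PoPoolation2 ``--pool-size`` figure: e.g. 12
    diploid animals pooled -> 24 chromosomes).
    """

    pool_id: str
    n_individuals: int

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("pool must contain at least one individual")

    @property
    def n_chromosomes(self) -> int:
        return 2 * self.n_individuals


@dataclass
class SyncSite:
    """One sync line: per-pool ``A:T:C:G:N:del`` count sextets at a site."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    counts: tuple[tuple[int, int, int, int, int, int], ...]


@dataclass
class SnvRecord:
    """A biallelic SNV in one pool, as major/minor allele read counts."""

    chrom: str
    pos: int  # 1-based
    pool_id: str
    n_maj: int
    n_min: int
    major_base: str
    minor_base: str

    def __post_init__(self):
        if self.n_maj < self.n_min or self.n_min < 1:
            raise ValueError("require n_maj >= n_min >= 1")
        if self.major_base == self.minor_base:
            raise ValueError("major and minor base must differ")


@dataclass(frozen=True)
class SnvFilter:
    """Coverage and minor-allele-support thresholds for calling a site.

    Defaults are the heterozygosity-scan settings (min coverage 15, max
    coverage 50 -- suppressing collapsed-repeat artifacts -- and at least
    3 reads supporting the minor allele).
    """

    min_coverage: int = 15
    max_coverage: int = 50
    min_count: int = 3

    def __post_init__(self):
        if not (0 < self.min_coverage <= self.max_coverage):
            raise ValueError("require 0 < min_coverage <= max_coverage")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


@dataclass
class DepthTrack:
    """Per-position (or per-bin) read depth along one chromosome.

    ``depth[i]`` is the mean depth of the i-th bin; with ``bin_size == 1``
    bin i covers the 1-based position ``i + 1``.
    """

    chrom: str
    depth: np.ndarray
    bin_size: int = 1

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if np.any(self.depth < 0):
            raise ValueError("depth must be non-negative")

    @property
    def mean(self) -> float:
        return float(self.depth.mean()) if self.depth.size else 0.0


@dataclass(frozen=True)
class GeneInterval:
    """A named annotation interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str


# ---------------------------------------------------------------------------
# sync
# ---------------------------------------------------------------------------

def read_sync(path: Union[str, Path], pools: Sequence[PoolSpec]) -> Iterator[SyncSite]:
    """Stream :class:`SyncSite` records from a PoPoolation2 sync file.

    The file must carry one count sextet per declared pool, in ``pools``
    order. Malformed lines raise :class:`SyncFormatError` naming the line.
    """
    n_pools = len(pools)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3 + n_pools:
                raise SyncFormatError(
                    f"line {lineno}: expected {3 + n_pools} columns "
                    f"({n_pools} pools), got {len(fields)}"
                )
            chrom, pos_s, ref = fields[:3]
            try:
                pos = int(pos_s)
                sextets = tuple(
                    tuple(int(c) for c in f.split(":")) for f in fields[3:]
                )
            except ValueError as exc:
                raise SyncFormatError(f"line {lineno}: non-integer count ({exc})")
            for s in sextets:
                if len(s) != 6:
                    raise SyncFormatError(
                        f"line {lineno}: count sextet has {len(s)} fields"
                    )
                if any(c < 0 for c in s):
                    raise SyncFormatError(f"line {lineno}: negative count")
            yield SyncSite(chrom, pos, ref, sextets)


def write_sync(path: Union[str, Path], sites: Iterable[SyncSite]) -> None:
    with open(path, "w") as fh:
        for site in sites:
            sextets = "\t".join(":".join(str(c) for c in s) for s in site.counts)
            fh.write(f"{site.chrom}\t{site.pos}\t{site.ref_base}\t{sextets}\n")


def sync_to_snvs(
    site: SyncSite,
    pool: PoolSpec,
    snv_filter: SnvFilter,
    pool_index: int = 0,
) -> Optional[SnvRecord]:
    """Call a biallelic SNV for one pool at one sync site, or ``None``.

    Only A/C/G/T counts are considered (``N`` and deletion counts are
    ignored -- the upstream callers emit substitutions only). A record is
    returned iff the pool's A+C+G+T coverage lies in
    ``[min_coverage, max_coverage]``, exactly two bases have nonzero
    counts, and the minor count is at least ``min_count``. A count tie
    keeps both alleles, the major chosen by fixed base order A<C<G<T.
    """
    sextet = site.counts[pool_index]
    acgt = [(BASE_ORDER[k], sextet[_ACGT_SYNC_IDX[k]]) for k in range(4)]
    nonzero = [(b, c) for b, c in acgt if c > 0]
    if len(nonzero) != 2:
        return None
    coverage = nonzero[0][1] + nonzero[1][1]
    if not (snv_filter.min_coverage <= coverage <= snv_filter.max_coverage):
        return None
    # stable sort: on a tie the base earlier in A<C<G<T stays major
    (maj_b, maj_c), (min_b, min_c) = sorted(nonzero, key=lambda bc: -bc[1])
    if min_c < snv_filter.min_count:
        return None
    return SnvRecord(site.chrom, site.pos, pool.pool_id, maj_c, min_c, maj_b, min_b)


# ---------------------------------------------------------------------------
# genotype tables (individually sequenced cohorts)
# ---------------------------------------------------------------------------

def genotypes_to_counts(
    table: Union[str, Path, pd.DataFrame],
    pool_id: str = "cohort",
    filter_no_calls: bool = True,
) -> Iterator[SnvRecord]:
    """Convert a genotype table into major/minor allele counts per site.

    ``table`` is a ``VariantsToTable``-style frame: columns ``CHROM``,
    ``POS``, ``REF`` followed by one genotype column per individual, each
    entry ``X/Y`` (alleles) or ``./.`` (no call). Homozygotes contribute 2
    to their allele, heterozygotes 1 to each. Sites with any missing
    genotype are dropped when ``filter_no_calls`` is set (the cohort
    analogue of requiring zero no-calls); monomorphic sites yield nothing
    and rows with more than two observed alleles are skipped with a
    warning.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", dtype=str)
    fixed = {"CHROM", "POS", "REF"}
    gt_cols = [c for c in table.columns if c not in fixed]
    for _, row in table.iterrows():
        counts: dict[str, int] = {}
        missing = False
        for col in gt_cols:
            gt = str(row[col])
            alleles = gt.replace("|", "/").split("/")
            if len(alleles) != 2 or "." in alleles:
                missing = True
                continue
            for a in alleles:
                counts[a] = counts.get(a, 0) + 1
        if missing and filter_no_calls:
            continue
        if len(counts) > 2:
            warnings.warn(
                f"non-biallelic site {row['CHROM']}:{row['POS']} skipped",
                stacklevel=2,
            )
            continue
        if len(counts) < 2:
            continue  # monomorphic
        (maj_b, maj_c), (min_b, min_c) = sorted(
            counts.items(), key=lambda bc: (-bc[1], bc[0])
        )
        yield SnvRecord(
            str(row["CHROM"]), int(row["POS"]), pool_id, maj_c, min_c, maj_b, min_b
        )


# ---------------------------------------------------------------------------
# depth tables
# ---------------------------------------------------------------------------

def read_depth_table(
    path: Union[str, Path],
    layout: Optional[GenomeLayout] = None,
) -> dict[str, DepthTrack]:
    """Read a samtools-depth table (``chrom  pos  depth``) into per-base tracks.

    With a :class:`GenomeLayout`, tracks span the full chromosome and
    positions absent from the file get depth 0; without one, the track
    spans positions 1..max(pos) seen for that chromosome.
    """
    per_chrom: dict[str, list[tuple[int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise DepthFormatError(f"line {lineno}: expected 3 columns")
            chrom, pos_s, depth_s = fields
            try:
                pos, depth = int(pos_s), float(depth_s)
            except ValueError as exc:
                raise DepthFormatError(f"line {lineno}: {exc}")
            if depth < 0:
                raise DepthFormatError(f"line {lineno}: negative depth")
            per_chrom.setdefault(chrom, []).append((pos, depth))
    tracks = {}
    for chrom, entries in per_chrom.items():
        entries.sort()
        length = layout.length_of(chrom) if layout else entries[-1][0]
        arr = np.zeros(length)
        for pos, depth in entries:
            arr[pos - 1] = depth
        tracks[chrom] = DepthTrack(chrom, arr, bin_size=1)
    return tracks


def write_depth_table(
    path: Union[str, Path],
    tracks: Union[DepthTrack, Iterable[DepthTrack], dict[str, DepthTrack]],
    omit_zero: bool = False,
) -> None:
    """Write per-base tracks in samtools-depth dialect.

    ``omit_zero`` drops zero-depth rows (``samtools depth`` default);
    otherwise every position is written, giving exact round trips.
    """
    if isinstance(tracks, DepthTrack):
        tracks = [tracks]
    elif isinstance(tracks, dict):
        tracks = list(tracks.values())
    with open(path, "w") as fh:
        for track in tracks:
            if track.bin_size != 1:
                raise ValueError("depth tables are per-base (bin_size 1)")
            for i, depth in enumerate(track.depth, start=1):
                if omit_zero and depth == 0:
                    continue
                d = int(depth) if float(depth).is_integer() else depth
                fh.write(f"{track.chrom}\t{i}\t{d}\n")


# ---------------------------------------------------------------------------
# layouts and annotation intervals
# ---------------------------------------------------------------------------

def read_layout(path: Union[str, Path]) -> GenomeLayout:
    """Read a two-column ``chrom  length`` table (e.g. a .fai slice)."""
    chroms = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            chroms.append((fields[0], int(fields[1])))
    return GenomeLayout(chroms)


def write_layout(path: Union[str, Path], layout: GenomeLayout) -> None:
    with open(path, "w") as fh:
        for name, length in layout:
            fh.write(f"{name}\t{length}\n")


def read_gene_intervals(path: Union[str, Path]) -> list[GeneInterval]:
    """Read gene intervals from BED (3+ columns) or GFF3.

    GFF3 ``gene`` features are converted to 0-based half-open; the name is
    taken from ``Name=``, ``gene=`` or ``ID=`` in that order. BED names
    come from column 4 (or ``chrom:start-end`` when absent).
    """
    path = Path(path)
    intervals: list[GeneInterval] = []
    is_gff = path.suffix.lower() in {".gff", ".gff3"}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("##gff-version"):
            is_gff = True
        fh.seek(0)
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if is_gff:
                if len(fields) < 9 or fields[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                )
                name = attrs.get("Name") or attrs.get("gene") or attrs.get("ID", "")
                intervals.append(
                    GeneInterval(fields[0], int(fields[3]) - 1, int(fields[4]), name)
                )
            else:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = (
                    fields[3]
                    if len(fields) > 3 and fields[3]
                    else f"{chrom}:{start}-{end}"
                )
                intervals.append(GeneInterval(chrom, start, end, name))
    return intervals
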