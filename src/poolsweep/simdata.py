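"""Synthetic pool-seq, CNV and expression data with known truth.

Every downstream module is exercised against data from this generator:

* ``simulate_pool_sync`` draws pooled allele counts under neutral
  diversity and inside selective sweeps. Neutral population minor-allele
  frequencies follow the standard neutral site-frequency shape (density
  proportional to 1/x on the grid {1/2N ... 0.5}). Inside a sweep region
  the minor frequency is scaled down by (1 - reduction); pooled sampling
  is two-stage -- chromosomes drawn binomially from the population
  frequency, then reads drawn binomially from the pool frequency at
  Poisson depth -- so at strong reductions most swept sites lose their
  minor allele in the pool altogether (the frequency is effectively
  floored to zero with probability about the reduction), mirroring the
  emptied-out windows a real sweep leaves.
* ``build_published_allele`` returns the six rearranged coat-color alleles
  (two at the KIT locus, four at the agouti/ASIP locus) with their
  published segment lengths, placed on synthetic chromosomes, plus a
  wildtype identity walk.
* ``simulate_depth_and_junctions`` turns an allele walk into the
  evidence the CNV caller consumes: per-base Poisson depth at
  lambda x per-base multiplicity, and one junction record per
  non-reference adjacency.
* ``simulate_expression_counts`` draws gamma-Poisson (negative binomial)
  gene counts with group-dependent means and jittered library sizes.

All outputs are bit-reproducible from the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .pool_io import BASE_ORDER, GenomeLayout, PoolSpec, SyncSite
from .cnv_caller import (
    JunctionEnd,
    JunctionRecord,
    StructuralAllele,
    WalkSegment,
    _assign_copy_indices,
    walk_multiplicity,
)
from .pool_io import DepthTrack

__all__ = [
    "SweepRegion",
    "SimConfig",
    "SimResult",
    "PUBLISHED_ALLELES",
    "simulate_pool_sync",
    "build_published_allele",
    "simulate_depth_and_junctions",
    "simulate_expression_counts",
    "simulate_asip_experiment",
]

# sync sextet slot per substitution base
_SYNC_SLOT = {"A": 0, "T": 1, "C": 2, "G": 3}


@dataclass(frozen=True)
class SweepRegion:
    """A region whose minor-allele frequencies are reduced by ``reduction``."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    reduction: float

    def __post_init__(self):
        if not (0.0 <= self.reduction <= 1.0):
            raise ValueError("reduction must lie in [0, 1]")
        if self.start >= self.end:
            raise ValueError("empty sweep region")


@dataclass
class SimConfig:
    """Parameters of a pooled-sequencing simulation.

    ``mean_depth`` is the Poisson read-depth mean per pool (the study
    design this emulates sequenced each pool to ~30x); ``snv_density`` is
    segregating sites per kb.
    """

    layout: GenomeLayout
    pools: Sequence[PoolSpec]
    seed: int = 0
    mean_depth: float = 30.0
    snv_density: float = 1.0
    sweeps: Sequence[SweepRegion] = field(default_factory=tuple)

    def __post_init__(self):
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not self.pools:
            raise ValueError("at least one pool required")
        for sw in self.sweeps:
            if sw.chrom not in self.layout:
                raise ValueError(f"sweep region on unknown sequence {sw.chrom!r}")
            if sw.end > self.layout.length_of(sw.chrom):
                raise ValueError(
                    f"sweep region {sw.chrom}:{sw.start}-{sw.end} exceeds layout"
                )


@dataclass
class SimResult:
    """Simulated sync sites plus the per-site and per-region truth tables."""

    sites: list[SyncSite]
    truth: pd.DataFrame
    regions: pd.DataFrame


def _unique_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """``n`` distinct 1-based positions, reproducibly."""
    n = min(n, length)
    draw = rng.integers(1, length + 1, size=int(n * 1.3) + 16)
    pos = np.unique(draw)
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=n)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(rng.choice(pos, size=n, replace=False))


def simulate_pool_sync(config: SimConfig) -> SimResult:
    """Simulate per-site pooled base counts for every configured pool."""
    rng = np.random.default_rng(config.seed)
    two_n_max = max(p.n_chromosomes for p in config.pools)
    j_grid = np.arange(1, two_n_max // 2 + 1)
    weights = (1.0 / j_grid) / np.sum(1.0 / j_grid)
    freq_grid = j_grid / two_n_max

    sites: list[SyncSite] = []
    truth_rows = {
        "chrom": [], "pos": [], "ref": [], "alt": [], "freq": [], "swept": []
    }
    pool_freq_cols: dict[str, list[float]] = {p.pool_id: [] for p in config.pools}

    for chrom, length in config.layout:
        n_sites = int(rng.poisson(length * config.snv_density / 1000.0))
        if n_sites == 0:
            continue
        pos = _unique_positions(rng, length, n_sites)
        freq = rng.choice(freq_grid, size=pos.size, p=weights)
        swept = np.zeros(pos.size, dtype=bool)
        for sw in config.sweeps:
            if sw.chrom != chrom:
                continue
            inside = (pos - 1 >= sw.start) & (pos - 1 < sw.end)
            freq[inside] *= 1.0 - sw.reduction
            swept |= inside
        ref_idx = rng.integers(0, 4, size=pos.size)
        alt_idx = (ref_idx + rng.integers(1, 4, size=pos.size)) % 4

        pool_counts = []
        for pool in config.pools:
            two_n = pool.n_chromosomes
            copies = rng.binomial(two_n, freq)
            pfreq = copies / two_n
            depth = rng.poisson(config.mean_depth, size=pos.size)
            alt_reads = rng.binomial(depth, pfreq)
            pool_counts.append((depth - alt_reads, alt_reads))
            pool_freq_cols[pool.pool_id].extend(pfreq.tolist())

        for i in range(pos.size):
            sextets = []
            for ref_reads, alt_reads in pool_counts:
                s = [0, 0, 0, 0, 0, 0]
                s[_SYNC_SLOT[BASE_ORDER[ref_idx[i]]]] = int(ref_reads[i])
                s[_SYNC_SLOT[BASE_ORDER[alt_idx[i]]]] += int(alt_reads[i])
                sextets.append(tuple(s))
            sites.append(
                SyncSite(chrom, int(pos[i]), BASE_ORDER[ref_idx[i]], tuple(sextets))
            )
        truth_rows["chrom"].extend([chrom] * pos.size)
        truth_rows["pos"].extend(pos.tolist())
        truth_rows["ref"].extend(BASE_ORDER[k] for k in ref_idx)
        truth_rows["alt"].extend(BASE_ORDER[k] for k in alt_idx)
        truth_rows["freq"].extend(freq.tolist())
        truth_rows["swept"].extend(swept.tolist())

    truth = pd.DataFrame(truth_rows)
    for pool_id, col in pool_freq_cols.items():
        truth[f"pool_freq_{pool_id}"] = col
    regions = pd.DataFrame(
        [(sw.chrom, sw.start, sw.end, sw.reduction) for sw in config.sweeps],
        columns=["chrom", "start", "end", "reduction"],
    )
    return SimResult(sites, truth, regions)


# ---------------------------------------------------------------------------
# the six published CNV alleles on synthetic chromosomes
# ---------------------------------------------------------------------------

# KIT-locus chromosome: the ~100 kb amplified unit sits downstream of the
# gene; the Barbari donor fragment comes from 19 Mb further downstream.
_KIT_LAYOUT = GenomeLayout([("chr6_sim", 19_600_000)])
_KIT_UNIT = (200_000, 300_000)  # ~100 kb tandem unit shared by both alleles
_KIT_DEL = (241_860, 258_140)  # 16,280 bp central deletion (Barbari)
_KIT_DONOR = (19_241_860, 19_264_562)  # 22,702 bp donor, 19 Mb downstream

# agouti (ASIP) locus chromosome and the four amplified units
_ASIP_LAYOUT = GenomeLayout([("chr13_sim", 10_000_000)])
_AWT_UNIT = (500_000, 654_677)  # 154,677 bp, triplicated (white/tan)
_ASM_UNIT = (400_000, 413_433)  # 13,433 bp, 8 copies (Swiss markings)
_AB_UNIT = (474_500, 520_180)  # 45,680 bp, 5 copies (badgerface)
_APC_LEFT = (446_504, 474_500)  # 27,996 bp, triplicated flank (peacock)
_APC_RIGHT = (520_180, 561_987)  # 41,807 bp, triplicated flank (peacock)

PUBLISHED_ALLELES = ("wildtype", "ANG_KIT", "BAR_KIT", "A_wt", "A_sm", "A_b", "A_pc")


def _tandem_walk(
    layout: GenomeLayout, blocks: Sequence[tuple[int, int, int]]
) -> list[tuple[str, int, int]]:
    """Identity walk with contiguous (start, end, copies) blocks expanded."""
    chrom, length = layout.chromosomes[0]
    pieces: list[tuple[str, int, int]] = []
    cursor = 0
    for start, end, copies in blocks:
        if cursor < start:
            pieces.append((chrom, cursor, start))
        pieces.extend([(chrom, start, end)] * copies)
        cursor = end
    if cursor < length:
        pieces.append((chrom, cursor, length))
    return pieces


def _split_pieces(
    pieces: list[tuple[str, int, int]], cuts: dict[str, Sequence[int]]
) -> list[tuple[str, int, int]]:
    out = []
    for chrom, a, b in pieces:
        inner = sorted(c for c in cuts.get(chrom, ()) if a < c < b)
        bounds = [a] + inner + [b]
        out.extend((chrom, x, y) for x, y in zip(bounds, bounds[1:]))
    return out


def build_published_allele(name: str) -> StructuralAllele:
    """Return one of the published structural alleles (or wildtype).

    ``ANG_KIT``: head-to-tail triplication of the ~100 kb unit downstream
    of KIT. ``BAR_KIT``: duplication of the same unit, each copy carrying
    a 16,280 bp central deletion replaced by a 22,702 bp donor fragment
    from 19 Mb downstream. ``A_wt``: triplication of a 154,677 bp unit;
    ``A_sm``: 8 tandem copies of 13,433 bp; ``A_b``: 5 tandem copies of
    45,680 bp; ``A_pc``: 4 tandem copies of the same 45,680 bp unit
    flanked by triplicated 27,996 bp and 41,807 bp segments. The layout
    the walk lives on is attached to the returned allele.
    """
    if name == "wildtype":
        chrom, length = _ASIP_LAYOUT.chromosomes[0]
        pieces = [(chrom, 0, length)]
        layout = _ASIP_LAYOUT
    elif name == "ANG_KIT":
        pieces = _tandem_walk(_KIT_LAYOUT, [(*_KIT_UNIT, 3)])
        layout = _KIT_LAYOUT
    elif name == "BAR_KIT":
        chrom = _KIT_LAYOUT.names[0]
        u_s, u_e = _KIT_UNIT
        d_s, d_e = _KIT_DEL
        f_s, f_e = _KIT_DONOR
        copy = [(chrom, u_s, d_s), (chrom, f_s, f_e), (chrom, d_e, u_e)]
        pieces = (
            [(chrom, 0, u_s)]
            + copy
            + copy
            + [(chrom, u_e, f_s), (chrom, f_s, f_e), (chrom, f_e, _KIT_LAYOUT.length_of(chrom))]
        )
        layout = _KIT_LAYOUT
    elif name == "A_wt":
        pieces = _tandem_walk(_ASIP_LAYOUT, [(*_AWT_UNIT, 3)])
        layout = _ASIP_LAYOUT
    elif name == "A_sm":
        pieces = _tandem_walk(_ASIP_LAYOUT, [(*_ASM_UNIT, 8)])
        layout = _ASIP_LAYOUT
    elif name == "A_b":
        pieces = _tandem_walk(_ASIP_LAYOUT, [(*_AB_UNIT, 5)])
        layout = _ASIP_LAYOUT
    elif name == "A_pc":
        pieces = _tandem_walk(
            _ASIP_LAYOUT,
            [(*_APC_LEFT, 3), (*_AB_UNIT, 4), (*_APC_RIGHT, 3)],
        )
        layout = _ASIP_LAYOUT
    else:
        raise ValueError(f"unknown allele {name!r}; choose from {PUBLISHED_ALLELES}")
    segments = _assign_copy_indices(
        [WalkSegment(c, a, b) for c, a, b in pieces]
    )
    return StructuralAllele(name, segments, layout=layout)


def simulate_depth_and_junctions(
    allele: StructuralAllele,
    mean_depth: float = 30.0,
    seed: int = 0,
) -> tuple[dict[str, DepthTrack], list[JunctionRecord]]:
    """Depth tracks and junction records for a pool fixed for ``allele``.

    Per-base expected depth is ``mean_depth`` times the walk's source
    multiplicity, observed depth Poisson. Every unique non-reference
    adjacency in the walk yields one junction record with read-pair
    support drawn Poisson(mean_depth / 2), at least 1.
    """
    if allele.layout is None:
        raise ValueError("allele carries no layout")
    rng = np.random.default_rng(seed)
    mult = walk_multiplicity(allele, allele.layout)
    tracks = {
        chrom: DepthTrack(chrom, rng.poisson(m * mean_depth).astype(float))
        for chrom, m in mult.items()
    }
    adjacencies: dict[tuple[str, int, str, int], int] = {}
    for a, b in zip(allele.segments, allele.segments[1:]):
        if a.chrom == b.chrom and b.start == a.end:
            continue  # reference-colinear
        key = (a.chrom, a.end, b.chrom, b.start + 1)
        adjacencies[key] = adjacencies.get(key, 0) + 1
    junctions = []
    for (chrom_e, e, chrom_s, s), _count in sorted(adjacencies.items()):
        support = max(1, int(rng.poisson(mean_depth / 2.0)))
        junctions.append(
            JunctionRecord(
                JunctionEnd(chrom_e, e, "right_of"),
                JunctionEnd(chrom_s, s, "left_of"),
                support,
            )
        )
    return tracks, junctions


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def simulate_expression_counts(
    design: pd.DataFrame,
    gene_means: pd.DataFrame,
    dispersion: float = 0.1,
    seed: int = 0,
    lib_jitter: float = 0.20,
) -> pd.DataFrame:
    """Negative-binomial (gamma-Poisson) counts for a genes x samples design.

    ``design`` needs columns ``sample`` and ``group``; ``gene_means`` is
    genes x groups (expected counts at nominal library size). Each
    sample's library is jittered by a uniform factor in
    ``[1 - lib_jitter, 1 + lib_jitter]``. Dispersion 0 gives plain
    Poisson counts.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if (gene_means.to_numpy() <= 0).any():
        raise ValueError("gene means must be positive")
    rng = np.random.default_rng(seed)
    counts = {}
    for _, row in design.iterrows():
        mu = gene_means[row["group"]].to_numpy(dtype=float)
        lib_factor = rng.uniform(1.0 - lib_jitter, 1.0 + lib_jitter)
        mu = mu * lib_factor
        if dispersion == 0:
            counts[row["sample"]] = rng.poisson(mu)
        else:
            lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
            counts[row["sample"]] = rng.poisson(lam)
    return pd.DataFrame(counts, index=gene_means.index)


def simulate_asip_experiment(
    n_pairs: int = 3,
    n_genes: int = 2000,
    eu_mean: float = 25.0,
    pheo_mean: float = 500.0,
    dispersion: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired-skin expression experiment with an agouti-like target gene.

    Each animal contributes a eumelanistic and a pheomelanistic skin
    sample; background genes share means across groups while the target
    gene ``ASIP`` has group-dependent means (default 20-fold higher in
    pheomelanistic skin). Returns (counts, design); design columns are
    sample, animal, group (= skin pigmentation).
    """
    rng = np.random.default_rng(seed)
    genes = [f"gene_{i:04d}" for i in range(n_genes - 1)] + ["ASIP"]
    base = np.exp(rng.normal(4.0, 1.5, size=n_genes - 1)) + 1.0
    gene_means = pd.DataFrame(
        {
            "eumelanistic": np.append(base, eu_mean),
            "pheomelanistic": np.append(base, pheo_mean),
        },
        index=genes,
    )
    rows = []
    for k in range(n_pairs):
        rows.append((f"animal{k}_eu", f"animal{k}", "eumelanistic"))
        rows.append((f"animal{k}_pheo", f"animal{k}", "pheomelanistic"))
    design = pd.DataFrame(rows, columns=["sample", "animal", "group"])
    counts = simulate_expression_counts(
        design, gene_means, dispersion=dispersion, seed=seed + 1
    )
    return counts, design
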