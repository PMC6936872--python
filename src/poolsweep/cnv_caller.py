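"""Read-depth CNV calling and structural-allele reconstruction.

Copy-number evidence comes in two forms that this module combines:

* **depth**: per-base coverage, normalized by the genome-wide mean so
  that relative coverage r estimates copies per haplotype in a pool fixed
  for an allele (r = 3 over a tandem triplication). Binned, median-
  smoothed and segmented into integer copy-number calls.
* **junctions**: discordant read-pair joins between two genomic ends,
  each end a (chrom, pos, side) with side ``left_of``/``right_of`` the
  base at ``pos`` (1-based). A join from ``right_of(e)`` back to
  ``left_of(s)`` with s <= e on the same chromosome is the signature of a
  head-to-tail tandem array; a forward skip is a deletion; a join to a
  locus >= 1 Mb away (or another chromosome) marks a distant insertion.

``reconstruct_allele`` walks the reference, consuming junctions: tandem
joins are traversed (copy number - 1) extra times, deletion joins skip
sequence, and paired distant-insertion joins splice a donor segment in.
The result is an ordered segment walk whose per-base multiplicity must
agree with the depth-derived copy-number calls; disagreement raises an
inconsistency error naming the violated segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.ndimage import median_filter

from .pool_io import DepthTrack, GenomeLayout

__all__ = [
    "DISTANT_THRESHOLD",
    "RelativeCoverageTrack",
    "CnvSegment",
    "JunctionEnd",
    "JunctionRecord",
    "WalkSegment",
    "StructuralAllele",
    "RearrangementSummary",
    "InconsistentWalkError",
    "relative_coverage",
    "segment_copy_number",
    "classify_junction",
    "tandem_unit_length",
    "reconstruct_allele",
    "walk_multiplicity",
    "summarize_rearrangements",
    "read_junctions",
    "write_junctions",
    "write_cnv_segments",
    "write_allele_walk",
]

# two ends at least this far apart (or on different chromosomes) are a
# distant insertion; the donor loci seen in practice sit many Mb away
DISTANT_THRESHOLD = 1_000_000

TANDEM = "tandem_head_to_tail"
DELETION = "deletion"
DISTANT = "distant_insertion"
COLINEAR = "reference_colinear"
OTHER = "other"


class InconsistentWalkError(ValueError):
    """No segment walk consistent with the junction/copy-number evidence."""


@dataclass
class RelativeCoverageTrack:
    """Binned coverage relative to the genome-wide mean depth."""

    chrom: str
    bin_size: int
    r: np.ndarray
    length: int  # bp spanned by the bins (last bin may be partial)

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        if np.any(self.r < 0):
            raise ValueError("relative coverage must be non-negative")


@dataclass
class CnvSegment:
    """A constant-copy-number segment (0-based half-open), CN per haplotype."""

    chrom: str
    start: int
    end: int
    mean_r: float
    copy_number: int


@dataclass(frozen=True)
class JunctionEnd:
    chrom: str
    pos: int  # 1-based base adjacent to the join
    side: str  # "left_of" or "right_of"

    def __post_init__(self):
        if self.side not in ("left_of", "right_of"):
            raise ValueError(f"bad side {self.side!r}")


@dataclass
class JunctionRecord:
    """A breakpoint join between two genomic ends with read-pair support."""

    left_end: JunctionEnd
    right_end: JunctionEnd
    support: int = 1
    junction_class: Optional[str] = None

    def __post_init__(self):
        if self.support < 1:
            raise ValueError("support must be >= 1")

    @property
    def source(self) -> JunctionEnd:
        """The ``right_of`` end: sequence departs rightward from this base."""
        return self.left_end if self.left_end.side == "right_of" else self.right_end

    @property
    def target(self) -> JunctionEnd:
        """The ``left_of`` end: sequence resumes at this base."""
        return self.left_end if self.left_end.side == "left_of" else self.right_end


@dataclass(frozen=True)
class WalkSegment:
    """One step of a structural-allele walk through reference coordinates."""

    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    orientation: str = "+"
    copy_index: int = 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class StructuralAllele:
    """An ordered walk of reference segments describing a rearranged allele."""

    name: str
    segments: list[WalkSegment]
    layout: Optional[GenomeLayout] = None

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)


@dataclass
class RearrangementSummary:
    """Unique rearrangement events recovered from an allele walk.

    ``tandems``: (chrom, unit_start, unit_end, copies); ``deletions``:
    (chrom, skip_start, skip_end, length); ``insertions``: (donor_chrom,
    start, end, length). All coordinates 0-based half-open.
    """

    tandems: list[tuple[str, int, int, int]] = field(default_factory=list)
    deletions: list[tuple[str, int, int, int]] = field(default_factory=list)
    insertions: list[tuple[str, int, int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# coverage normalization and segmentation
# ---------------------------------------------------------------------------

def relative_coverage(
    tracks: Union[DepthTrack, dict[str, DepthTrack]],
    layout: GenomeLayout,
    bin_size: int = 1000,
) -> Union[RelativeCoverageTrack, dict[str, RelativeCoverageTrack]]:
    """Bin depth and divide by the genome-wide mean depth.

    The genome-wide mean is total read depth over total layout length, so
    chromosomes (or positions) without depth data count as zero coverage.
    A dict of tracks yields a dict of relative tracks.
    """
    single = isinstance(tracks, DepthTrack)
    track_map = {tracks.chrom: tracks} if single else dict(tracks)
    for t in track_map.values():
        if t.bin_size != 1:
            raise ValueError("relative_coverage expects per-base tracks")
    total_depth = sum(float(t.depth.sum()) for t in track_map.values())
    genome_mean = total_depth / layout.total_length
    if genome_mean == 0:
        raise ValueError("genome-wide mean depth is zero")
    out = {}
    for chrom, t in track_map.items():
        n = len(t.depth)
        edges = np.arange(0, n, bin_size)
        sums = np.add.reduceat(t.depth, edges)
        widths = np.minimum(edges + bin_size, n) - edges
        out[chrom] = RelativeCoverageTrack(
            chrom, bin_size, sums / widths / genome_mean, length=n
        )
    return out[tracks.chrom] if single else out


def segment_copy_number(
    rel: RelativeCoverageTrack,
    min_len: int = 5000,
    smooth_bins: int = 5,
) -> list[CnvSegment]:
    """Median-smooth relative coverage and call integer copy-number segments.

    Each bin gets round(smoothed r); runs of equal copy number are merged
    and runs shorter than ``min_len`` are absorbed into the neighboring
    run with the closer copy number. Only segments with CN != 1 are
    returned (``mean_r`` is the raw, unsmoothed mean over the segment).
    """
    if min_len < rel.bin_size:
        raise ValueError("min_len must be at least one bin")
    smoothed = median_filter(rel.r, size=smooth_bins, mode="nearest")
    cn = np.maximum(np.rint(smoothed), 0).astype(int)
    # runs as [start_bin, end_bin, cn]
    runs: list[list[int]] = []
    for i, c in enumerate(cn):
        if runs and runs[-1][2] == c:
            runs[-1][1] = i + 1
        else:
            runs.append([i, i + 1, int(c)])
    min_bins = -(-min_len // rel.bin_size)  # ceil

    def merge_equal(runs):
        out = []
        for r in runs:
            if out and out[-1][2] == r[2]:
                out[-1][1] = r[1]
            else:
                out.append(r)
        return out

    while len(runs) > 1:
        short = [
            (r[1] - r[0], i) for i, r in enumerate(runs) if r[1] - r[0] < min_bins
        ]
        if not short:
            break
        _, i = min(short)
        neighbors = []
        if i > 0:
            neighbors.append(i - 1)
        if i < len(runs) - 1:
            neighbors.append(i + 1)
        j = min(
            neighbors,
            key=lambda k: (abs(runs[k][2] - runs[i][2]), -(runs[k][1] - runs[k][0])),
        )
        runs[i][2] = runs[j][2]  # absorbed: takes neighbor's copy number
        runs = merge_equal(runs)
    segments = []
    for start_bin, end_bin, c in runs:
        if c == 1:
            continue
        start = start_bin * rel.bin_size
        end = min(end_bin * rel.bin_size, rel.length)
        segments.append(
            CnvSegment(
                rel.chrom, start, end, float(rel.r[start_bin:end_bin].mean()), c
            )
        )
    return segments


# ---------------------------------------------------------------------------
# junction classification
# ---------------------------------------------------------------------------

def classify_junction(junction: JunctionRecord) -> str:
    """Assign a junction class from its end coordinates and sides.

    With the join read as right_of(e) -> left_of(s): different
    chromosomes or |s - e| >= 1 Mb -> ``distant_insertion``; s = e + 1 ->
    ``reference_colinear``; s < e (walking back into already-passed
    sequence) -> ``tandem_head_to_tail``; s > e + 1 -> ``deletion`` of
    the skipped s - e - 1 bases; anything else -> ``other``.
    """
    sides = {junction.left_end.side, junction.right_end.side}
    if sides != {"left_of", "right_of"}:
        return OTHER
    e = junction.source.pos
    s = junction.target.pos
    if junction.source.chrom != junction.target.chrom or abs(s - e) >= DISTANT_THRESHOLD:
        return DISTANT
    if s == e + 1:
        return COLINEAR
    if s < e:
        return TANDEM
    if s > e + 1:
        return DELETION
    return OTHER


def tandem_unit_length(junction: JunctionRecord) -> int:
    """Amplified-unit length implied by a head-to-tail junction (e - s + 1)."""
    if classify_junction(junction) != TANDEM:
        raise ValueError("not a tandem head-to-tail junction")
    return junction.source.pos - junction.target.pos + 1


# ---------------------------------------------------------------------------
# allele reconstruction
# ---------------------------------------------------------------------------

def _tandem_copies(segments: Sequence[CnvSegment], chrom: str, s0: int, e0: int) -> int:
    """Copy number of the tandem unit [s0, e0): the CN!=1 call with max overlap."""
    best, best_ov = None, 0
    for seg in segments:
        if seg.chrom != chrom or seg.copy_number == 1:
            continue
        ov = min(seg.end, e0) - max(seg.start, s0)
        if ov > best_ov:
            best, best_ov = seg, ov
    if best is None or best.copy_number < 2:
        raise InconsistentWalkError(
            f"no copy-number call supports a tandem unit at {chrom}:{s0}-{e0}"
        )
    return best.copy_number


def _pair_insertions(
    distant: list[JunctionRecord],
) -> list[tuple[JunctionRecord, JunctionRecord]]:
    """Pair distant-insertion junctions into (splice-in, splice-back) couples.

    Splice-in A and splice-back B pair when A's target and B's source
    bracket the same donor locus and B returns just downstream of A's
    departure point.
    """
    pairs = []
    unused = list(distant)
    while unused:
        a = unused.pop(0)
        match = None
        for b in unused:
            donor_ok = (
                b.source.chrom == a.target.chrom
                and 0 <= b.source.pos - a.target.pos < DISTANT_THRESHOLD
            )
            return_ok = (
                b.target.chrom == a.source.chrom
                and 0 < b.target.pos - a.source.pos < DISTANT_THRESHOLD
            )
            if donor_ok and return_ok:
                match = b
                break
        if match is None:
            # maybe a is the splice-back of some later splice-in
            for b in unused:
                donor_ok = (
                    a.source.chrom == b.target.chrom
                    and 0 <= a.source.pos - b.target.pos < DISTANT_THRESHOLD
                )
                return_ok = (
                    a.target.chrom == b.source.chrom
                    and 0 < a.target.pos - b.source.pos < DISTANT_THRESHOLD
                )
                if donor_ok and return_ok:
                    match = b
                    a, match = b, a
                    break
        if match is None:
            raise InconsistentWalkError(
                f"unpaired distant-insertion junction at "
                f"{a.source.chrom}:{a.source.pos}"
            )
        unused.remove(match)
        pairs.append((a, match))
    return pairs


def _split_at(segments: list[WalkSegment], cuts: dict[str, set[int]]) -> list[WalkSegment]:
    """Split walk segments at every cut position falling strictly inside them."""
    out = []
    for seg in segments:
        inner = sorted(c for c in cuts.get(seg.chrom, ()) if seg.start < c < seg.end)
        bounds = [seg.start] + inner + [seg.end]
        for a, b in zip(bounds, bounds[1:]):
            out.append(WalkSegment(seg.chrom, a, b, seg.orientation))
    return out


def _assign_copy_indices(segments: list[WalkSegment]) -> list[WalkSegment]:
    seen: dict[tuple[str, int, int], int] = {}
    out = []
    for seg in segments:
        key = (seg.chrom, seg.start, seg.end)
        seen[key] = seen.get(key, 0) + 1
        out.append(WalkSegment(seg.chrom, seg.start, seg.end, seg.orientation, seen[key]))
    return out


def walk_multiplicity(allele: StructuralAllele, layout: GenomeLayout) -> dict[str, np.ndarray]:
    """Per-base source multiplicity of a walk, one array per chromosome."""
    mult = {chrom: np.zeros(length, dtype=np.int32) for chrom, length in layout}
    for seg in allele.segments:
        mult[seg.chrom][seg.start:seg.end] += 1
    return mult


def reconstruct_allele(
    segments: Sequence[CnvSegment],
    junctions: Sequence[JunctionRecord],
    layout: GenomeLayout,
    name: str = "reconstructed",
) -> StructuralAllele:
    """Reconstruct a structural allele walk from CN calls and junctions.

    The walk traverses every layout chromosome in order. At a tandem
    junction the unit is repeated to the copy number called over it; a
    deletion junction skips the deleted reference; paired distant-
    insertion junctions splice the donor segment between the breakpoints
    (taken on every pass, so a splice inside a tandem unit appears in
    every copy). The resulting per-base multiplicity is checked against
    the copy-number calls (modal multiplicity over each called segment).
    """
    classed = []
    for j in junctions:
        c = classify_junction(j)
        if c == COLINEAR:
            continue
        if c == OTHER:
            raise InconsistentWalkError(
                f"unusable junction {j.left_end} -> {j.right_end}"
            )
        classed.append((j, c))

    tandem_remaining: dict[int, int] = {}
    # departures[chrom] -> list of (source_pos_1based, kind, payload), sorted
    departures: dict[str, list[tuple[int, str, tuple]]] = {}

    def add_departure(chrom: str, pos: int, kind: str, payload: tuple):
        departures.setdefault(chrom, []).append((pos, kind, payload))

    pairs = _pair_insertions([j for j, c in classed if c == DISTANT])
    for idx, (j, c) in enumerate(classed):
        if c == TANDEM:
            s0 = j.target.pos - 1
            e0 = j.source.pos
            copies = _tandem_copies(segments, j.source.chrom, s0, e0)
            tandem_remaining[idx] = copies - 1
            add_departure(j.source.chrom, j.source.pos, TANDEM, (s0, idx))
        elif c == DELETION:
            add_departure(j.source.chrom, j.source.pos, DELETION, (j.target.pos - 1,))
    for a, b in pairs:
        donor = (a.target.chrom, a.target.pos - 1, b.source.pos)
        add_departure(a.source.chrom, a.source.pos, DISTANT, (donor, b.target.pos - 1))
    for lst in departures.values():
        lst.sort(key=lambda d: (d[0], d[1]))

    cuts: dict[str, set[int]] = {}
    for chrom, lst in departures.items():
        for pos, kind, payload in lst:
            cuts.setdefault(chrom, set()).add(pos)
            if kind == TANDEM:
                cuts[chrom].add(payload[0])
            elif kind == DELETION:
                cuts[chrom].add(payload[0])
            else:
                (dchrom, ds0, de0), resume = payload
                cuts.setdefault(dchrom, set()).update((ds0, de0))
                cuts[chrom].add(resume)

    walk: list[WalkSegment] = []
    max_steps = 1_000_000
    for chrom, length in layout:
        deps = departures.get(chrom, [])
        pos = 0
        steps = 0
        while pos < length:
            steps += 1
            if steps > max_steps:
                raise InconsistentWalkError(f"walk on {chrom} does not terminate")
            # next actionable departure with source base index >= pos
            action = None
            for dpos, kind, payload in deps:
                if dpos - 1 < pos:
                    continue
                if kind == TANDEM and tandem_remaining[payload[1]] <= 0:
                    continue
                action = (dpos, kind, payload)
                break
            if action is None:
                walk.append(WalkSegment(chrom, pos, length))
                break
            dpos, kind, payload = action
            if dpos > pos:
                walk.append(WalkSegment(chrom, pos, dpos))
            if kind == TANDEM:
                tandem_remaining[payload[1]] -= 1
                pos = payload[0]
            elif kind == DELETION:
                pos = payload[0]
            else:
                (dchrom, ds0, de0), resume = payload
                walk.append(WalkSegment(dchrom, ds0, de0))
                pos = resume

    walk = _assign_copy_indices(_split_at(walk, cuts))
    allele = StructuralAllele(name, walk, layout=layout)

    mult = walk_multiplicity(allele, layout)
    for seg in segments:
        observed = mult[seg.chrom][seg.start:seg.end]
        if observed.size == 0:
            continue
        modal = int(np.bincount(observed).argmax())
        if modal != seg.copy_number:
            raise InconsistentWalkError(
                f"segment {seg.chrom}:{seg.start}-{seg.end} called CN="
                f"{seg.copy_number} but walk multiplicity is {modal}"
            )
    return allele


def summarize_rearrangements(allele: StructuralAllele) -> RearrangementSummary:
    """Recover the unique rearrangement events encoded in a walk.

    Tandem arrays are read off back-jump adjacencies (copies = number of
    identical back jumps + 1). A segment whose both flanks lie >= 1 Mb
    away (or on another chromosome) is a spliced-in donor; the reference
    skipped between the bases flanking the splice (or skipped by a plain
    forward jump) is a deletion.
    """
    segs = allele.segments
    summary = RearrangementSummary()
    tandem_counts: dict[tuple[str, int, int], int] = {}
    deletions: set[tuple[str, int, int]] = set()
    insertions: set[tuple[str, int, int]] = set()

    def far(chrom_a: str, pos_a: int, chrom_b: str, pos_b: int) -> bool:
        return chrom_a != chrom_b or abs(pos_b - pos_a) >= DISTANT_THRESHOLD

    i = 0
    while i < len(segs) - 1:
        a, b = segs[i], segs[i + 1]
        if not far(a.chrom, a.end, b.chrom, b.start):
            if b.start < a.end:  # back jump: tandem unit [b.start, a.end)
                key = (a.chrom, b.start, a.end)
                tandem_counts[key] = tandem_counts.get(key, 0) + 1
            elif b.start > a.end:  # forward skip: deletion
                deletions.add((a.chrom, a.end, b.start))
            i += 1
            continue
        # b is far from a: spliced donor if the walk returns near a after b
        if i + 2 < len(segs):
            c = segs[i + 2]
            if far(b.chrom, b.end, c.chrom, c.start) and not far(
                a.chrom, a.end, c.chrom, c.start
            ):
                insertions.add((b.chrom, b.start, b.end))
                if c.start > a.end:
                    deletions.add((a.chrom, a.end, c.start))
                i += 2
                continue
        i += 1
    summary.tandems = [
        (chrom, s, e, n + 1) for (chrom, s, e), n in sorted(tandem_counts.items())
    ]
    summary.deletions = [(c, s, e, e - s) for c, s, e in sorted(deletions)]
    summary.insertions = [(c, s, e, e - s) for c, s, e in sorted(insertions)]
    return summary


# ---------------------------------------------------------------------------
# file dialects
# ---------------------------------------------------------------------------

def read_junctions(path: Union[str, Path]) -> list[JunctionRecord]:
    """Junction TSV: chrom1, pos1, side1, chrom2, pos2, side2, support."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom1\t"):
                continue
            c1, p1, s1, c2, p2, s2, sup = line.split("\t")
            out.append(
                JunctionRecord(
                    JunctionEnd(c1, int(p1), s1),
                    JunctionEnd(c2, int(p2), s2),
                    int(sup),
                )
            )
    return out


def write_junctions(path: Union[str, Path], junctions: Iterable[JunctionRecord]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom1\tpos1\tside1\tchrom2\tpos2\tside2\tsupport\n")
        for j in junctions:
            a, b = j.left_end, j.right_end
            fh.write(
                f"{a.chrom}\t{a.pos}\t{a.side}\t{b.chrom}\t{b.pos}\t{b.side}\t"
                f"{j.support}\n"
            )


def write_cnv_segments(path: Union[str, Path], segments: Iterable[CnvSegment]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tmean_r\tcopy_number\n")
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.mean_r:.4f}\t{s.copy_number}\n")


def write_allele_walk(path: Union[str, Path], allele: StructuralAllele) -> None:
    """Ordered-segment TSV: source chrom, start, end, orientation, copy index."""
    with open(path, "w") as fh:
        fh.write(f"#allele\t{allele.name}\ttotal_length\t{allele.total_length}\n")
        fh.write("chrom\tstart\tend\torientation\tcopy_index\n")
        for seg in allele.segments:
            fh.write(
                f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.orientation}\t"
                f"{seg.copy_index}\n"
            )
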