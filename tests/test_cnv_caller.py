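"""Coverage normalization, segmentation, junction logic and reconstruction."""

import numpy as np
import pytest

import poolsweep as ps
from poolsweep.cnv_caller import (
    COLINEAR,
    DELETION,
    DISTANT,
    OTHER,
    TANDEM,
    InconsistentWalkError,
    JunctionEnd,
    JunctionRecord,
    RelativeCoverageTrack,
    read_junctions,
    write_junctions,
)


def junction(chrom_e, e, chrom_s, s, support=10):
    return JunctionRecord(
        JunctionEnd(chrom_e, e, "right_of"), JunctionEnd(chrom_s, s, "left_of"), support
    )


class TestRelativeCoverage:
    def test_three_times_genome_mean(self):
        layout = ps.GenomeLayout([("amp", 1_000), ("rest", 3_000)])
        tracks = {
            "amp": ps.DepthTrack("amp", np.full(1_000, 90.0)),
            "rest": ps.DepthTrack("rest", np.full(3_000, 10.0)),
        }
        rel = ps.relative_coverage(tracks, layout, bin_size=100)
        assert np.allclose(rel["amp"].r, 3.0)  # 90x against a 30x genome mean

    def test_baseline_is_one(self):
        layout = ps.GenomeLayout([("c", 5_000)])
        rel = ps.relative_coverage(ps.DepthTrack("c", np.full(5_000, 30.0)), layout, 500)
        assert np.allclose(rel.r, 1.0)

    def test_half_and_half(self):
        layout = ps.GenomeLayout([("c", 2_000)])
        depth = np.concatenate([np.full(1_000, 20.0), np.full(1_000, 40.0)])
        rel = ps.relative_coverage(ps.DepthTrack("c", depth), layout, 1_000)
        assert rel.r == pytest.approx([2 / 3, 4 / 3])

    def test_total_depth_conserved(self):
        rng = np.random.default_rng(8)
        depth = rng.poisson(30, 10_000).astype(float)
        layout = ps.GenomeLayout([("c", 10_000)])
        rel = ps.relative_coverage(ps.DepthTrack("c", depth), layout, 1_000)
        mean = depth.sum() / 10_000
        assert rel.r.mean() * mean * 10_000 == pytest.approx(depth.sum())

    def test_zero_mean_is_error(self):
        layout = ps.GenomeLayout([("c", 100)])
        with pytest.raises(ValueError, match="mean depth is zero"):
            ps.relative_coverage(ps.DepthTrack("c", np.zeros(100)), layout, 10)


class TestSegmentation:
    def track(self, r, bin_size=1_000):
        return RelativeCoverageTrack("c", bin_size, np.asarray(r, float), len(r) * bin_size)

    def test_clean_plateau(self):
        segs = ps.segment_copy_number(self.track([1, 1, 1, 3, 3, 3, 3, 1, 1]), 2_000, 3)
        assert [(s.start, s.end, s.copy_number) for s in segs] == [(3_000, 7_000, 3)]

    @pytest.mark.parametrize("noisy", [2.6, 2.4])
    def test_median_filter_removes_single_bin_noise(self, noisy):
        r = [1, 1, 1, 3, 3, noisy, 3, 3, 1, 1, 1]
        segs = ps.segment_copy_number(self.track(r), 2_000, 3)
        assert [(s.start, s.end, s.copy_number) for s in segs] == [(3_000, 8_000, 3)]

    def test_all_baseline_empty(self):
        rng = np.random.default_rng(1)
        segs = ps.segment_copy_number(self.track(1 + rng.normal(0, 0.05, 50)), 2_000, 5)
        assert segs == []

    def test_short_runs_absorbed(self):
        # one-bin CN=2 blip, below min_len, disappears into the baseline
        r = [1] * 10 + [2] + [1] * 10
        segs = ps.segment_copy_number(self.track(r), 3_000, 1)
        assert segs == []

    def test_deletion_called_as_cn_zero(self):
        r = [1] * 5 + [0] * 5 + [1] * 5
        segs = ps.segment_copy_number(self.track(r), 2_000, 3)
        assert [(s.start, s.end, s.copy_number) for s in segs] == [(5_000, 10_000, 0)]


class TestClassifyJunction:
    @pytest.mark.parametrize(
        "j, expected",
        [
            (junction("c", 70_900_000, "c", 70_800_000), TANDEM),  # back jump
            (junction("c", 100_000, "c", 116_281), DELETION),  # skips 16,280 bp
            (junction("c", 100_000, "c", 19_100_000), DISTANT),  # 19 Mb downstream
            (junction("c", 100_000, "other", 50), DISTANT),
            (junction("c", 100_000, "c", 100_001), COLINEAR),
            (junction("c", 100_000, "c", 100_000), OTHER),
        ],
    )
    def test_classes(self, j, expected):
        assert ps.classify_junction(j) == expected

    def test_same_sided_ends_unclassifiable(self):
        j = JunctionRecord(
            JunctionEnd("c", 10, "right_of"), JunctionEnd("c", 50, "right_of")
        )
        assert ps.classify_junction(j) == OTHER

    def test_deletion_skip_length(self):
        j = junction("c", 100_000, "c", 116_281)
        assert j.target.pos - j.source.pos - 1 == 16_280

    def test_tandem_unit_length(self):
        assert ps.tandem_unit_length(junction("c", 300_000, "c", 200_001)) == 100_000
        with pytest.raises(ValueError):
            ps.tandem_unit_length(junction("c", 100, "c", 300))


class TestReconstruction:
    def test_simple_tandem_expansion(self):
        layout = ps.GenomeLayout([("c", 100_000)])
        seg = ps.CnvSegment("c", 20_000, 30_000, 3.0, 3)
        allele = ps.reconstruct_allele([seg], [junction("c", 30_000, "c", 20_001)], layout)
        unit = [(s.start, s.end) for s in allele.segments if (s.start, s.end) == (20_000, 30_000)]
        assert len(unit) == 3
        assert allele.total_length == 100_000 + 2 * 10_000  # extra = 2*(e-s+1)

    def test_walk_multiplicity_matches_copy_number(self):
        layout = ps.GenomeLayout([("c", 100_000)])
        seg = ps.CnvSegment("c", 20_000, 30_000, 3.0, 3)
        allele = ps.reconstruct_allele([seg], [junction("c", 30_000, "c", 20_001)], layout)
        mult = ps.walk_multiplicity(allele, layout)["c"]
        assert (mult[20_000:30_000] == 3).all()
        assert (mult[:20_000] == 1).all() and (mult[30_000:] == 1).all()

    def test_tandem_without_supporting_segment_is_inconsistent(self):
        layout = ps.GenomeLayout([("c", 100_000)])
        with pytest.raises(InconsistentWalkError, match="no copy-number call"):
            ps.reconstruct_allele([], [junction("c", 30_000, "c", 20_001)], layout)

    def test_copy_number_conflict_names_segment(self):
        layout = ps.GenomeLayout([("c", 100_000)])
        # depth says 4 copies at the unit, but also CN=2 over a region the
        # 4-copy walk covers twice -- contradiction at the second segment
        segs = [
            ps.CnvSegment("c", 20_000, 30_000, 4.0, 4),
            ps.CnvSegment("c", 40_000, 60_000, 2.0, 2),
        ]
        with pytest.raises(InconsistentWalkError, match="40000-60000"):
            ps.reconstruct_allele(segs, [junction("c", 30_000, "c", 20_001)], layout)

    def test_unpaired_distant_insertion_is_inconsistent(self):
        layout = ps.GenomeLayout([("c", 30_000_000)])
        with pytest.raises(InconsistentWalkError, match="unpaired"):
            ps.reconstruct_allele([], [junction("c", 100_000, "c", 20_000_000)], layout)

    @pytest.mark.parametrize("name", ps.PUBLISHED_ALLELES)
    def test_exact_evidence_roundtrip(self, name):
        """Reconstruction from noiseless evidence reproduces every allele walk."""
        allele = ps.build_published_allele(name)
        _, junctions = ps.simulate_depth_and_junctions(allele, seed=0)
        mult = ps.walk_multiplicity(allele, allele.layout)
        segs = []
        for chrom, m in mult.items():
            edges = np.flatnonzero(np.diff(m)) + 1
            bounds = [0, *edges.tolist(), len(m)]
            for a, b in zip(bounds, bounds[1:]):
                if m[a] != 1:
                    segs.append(ps.CnvSegment(chrom, a, b, float(m[a]), int(m[a])))
        recon = ps.reconstruct_allele(segs, junctions, allele.layout, name)
        assert recon.segments == allele.segments
        assert recon.total_length == allele.total_length


class TestSummaryAndIo:
    def test_barbari_deletion_and_donor_recovered(self):
        allele = ps.build_published_allele("BAR_KIT")
        summary = ps.summarize_rearrangements(allele)
        assert [t[3] for t in summary.tandems] == [2]
        assert [d[3] for d in summary.deletions] == [16_280]
        assert [i[3] for i in summary.insertions] == [22_702]

    def test_junction_tsv_roundtrip(self, tmp_path):
        junctions = [
            junction("c", 300_000, "c", 200_001, support=14),
            junction("c", 100_000, "d", 5_000, support=3),
        ]
        path = tmp_path / "j.tsv"
        write_junctions(path, junctions)
        assert read_junctions(path) == junctions
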