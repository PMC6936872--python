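"""Generator contracts: reproducibility, sweep behaviour, allele evidence."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

import poolsweep as ps
from poolsweep.cnv_caller import DISTANT, TANDEM


POOL = ps.PoolSpec("breed", 12)


def called_snvs(sim, pool=POOL, snv_filter=ps.SnvFilter()):
    return [
        r for r in (ps.sync_to_snvs(s, pool, snv_filter) for s in sim.sites) if r
    ]


class TestPoolSync:
    def test_bit_reproducible_from_seed(self):
        layout = ps.GenomeLayout([("c", 500_000)])
        cfg = ps.SimConfig(layout, [POOL], seed=3)
        a, b = ps.simulate_pool_sync(cfg), ps.simulate_pool_sync(cfg)
        assert a.sites == b.sites
        pd.testing.assert_frame_equal(a.truth, b.truth)
        c = ps.simulate_pool_sync(ps.SimConfig(layout, [POOL], seed=4))
        assert a.sites != c.sites

    def test_sweep_region_outside_layout_rejected(self):
        layout = ps.GenomeLayout([("c", 100_000)])
        with pytest.raises(ValueError, match="exceeds layout"):
            ps.SimConfig(
                layout, [POOL], sweeps=(ps.SweepRegion("c", 0, 200_000, 0.5),)
            )
        with pytest.raises(ValueError, match="unknown sequence"):
            ps.SimConfig(
                layout, [POOL], sweeps=(ps.SweepRegion("x", 0, 50_000, 0.5),)
            )

    def test_complete_sweep_empties_windows(self):
        layout = ps.GenomeLayout([("c", 1_500_000)])
        region = ps.SweepRegion("c", 600_000, 750_000, 1.0)
        cfg = ps.SimConfig(layout, [POOL], seed=5, sweeps=(region,))
        sim = ps.simulate_pool_sync(cfg)
        assert (sim.truth.loc[sim.truth.swept, "freq"] == 0).all()
        stats, _ = ps.scan_pool(called_snvs(sim), layout)
        (swept,) = [s for s in stats if s.window.start == 600_000]
        assert swept.n_snvs == 0 and math.isnan(swept.zhp)

    def test_zero_reduction_indistinguishable_from_background(self):
        layout = ps.GenomeLayout([("c", 15_000_000)])
        region_starts = [75_000 * i for i in (40, 100, 160)]
        sweeps = tuple(
            ps.SweepRegion("c", s, s + 150_000, 0.0) for s in region_starts
        )
        sim = ps.simulate_pool_sync(ps.SimConfig(layout, [POOL], seed=9, sweeps=sweeps))
        stats, _ = ps.scan_pool(called_snvs(sim), layout)
        in_region = [
            s.hp for s in stats if s.window.start in region_starts and not math.isnan(s.hp)
        ]
        background = [
            s.hp
            for s in stats
            if not math.isnan(s.hp)
            and all(abs(s.window.start - r) > 150_000 for r in region_starts)
        ]
        assert mannwhitneyu(in_region, background).pvalue > 0.01

    def test_strong_sweep_reduces_truth_heterozygosity(self):
        """At 95 % reduction the truth-table window heterozygosity collapses."""
        layout = ps.GenomeLayout([("c", 30_000_000)])
        sweeps = tuple(
            ps.SweepRegion("c", 75_000 * i, 75_000 * i + 150_000, 0.95)
            for i in (60, 200, 340)
        )
        sim = ps.simulate_pool_sync(ps.SimConfig(layout, [POOL], seed=7, sweeps=sweeps))
        het = 2 * sim.truth.freq * (1 - sim.truth.freq)
        ratio = het[sim.truth.swept].mean() / het[~sim.truth.swept].mean()
        assert ratio < 0.20
        assert ratio == pytest.approx(0.066054, abs=1e-6)  # frozen regression value

    def test_read_frequency_tracks_population_frequency(self):
        """Pool read frequencies average to the drawn population frequencies."""
        layout = ps.GenomeLayout([("c", 10_000_000)])
        cfg = ps.SimConfig(layout, [POOL], seed=2, mean_depth=10_000.0)
        sim = ps.simulate_pool_sync(cfg)
        slots = {"A": 0, "T": 1, "C": 2, "G": 3}
        read_freq = []
        for site, alt in zip(sim.sites, sim.truth.alt):
            sextet = site.counts[0]
            read_freq.append(sextet[slots[alt]] / sum(sextet))
        assert np.mean(read_freq) == pytest.approx(sim.truth.freq.mean(), rel=0.01)


class TestPaperAlleles:
    def test_wildtype_identity(self):
        allele = ps.build_published_allele("wildtype")
        assert allele.total_length == allele.layout.total_length
        mult = ps.walk_multiplicity(allele, allele.layout)
        assert all((m == 1).all() for m in mult.values())

    def test_swiss_markings_eight_copies(self):
        allele = ps.build_published_allele("A_sm")
        mult = ps.walk_multiplicity(allele, allele.layout)["chr13_sim"]
        assert (mult[400_000:413_433] == 8).all()
        assert allele.total_length - allele.layout.total_length == 7 * 13_433

    def test_peacock_multiplicity_profile(self):
        allele = ps.build_published_allele("A_pc")
        mult = ps.walk_multiplicity(allele, allele.layout)["chr13_sim"]
        left, center, right = (446_504, 474_500), (474_500, 520_180), (520_180, 561_987)
        assert (mult[slice(*left)] == 3).all()
        assert (mult[slice(*center)] == 4).all()
        assert (mult[slice(*right)] == 3).all()

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown allele"):
            ps.build_published_allele("A_xx")


class TestDepthAndJunctions:
    def test_wildtype_flat_depth_no_junctions(self):
        allele = ps.build_published_allele("wildtype")
        tracks, junctions = ps.simulate_depth_and_junctions(allele, 30.0, seed=1)
        assert junctions == []
        assert tracks["chr13_sim"].mean == pytest.approx(30.0, rel=0.01)

    def test_triplication_plateau_and_junction(self):
        allele = ps.build_published_allele("ANG_KIT")
        tracks, junctions = ps.simulate_depth_and_junctions(allele, 30.0, seed=1)
        depth = tracks["chr6_sim"].depth
        assert depth[200_000:300_000].mean() == pytest.approx(90.0, rel=0.02)
        assert depth[:200_000].mean() == pytest.approx(30.0, rel=0.02)
        assert [ps.classify_junction(j) for j in junctions] == [TANDEM]

    def test_barbari_donor_runs_at_three_lambda(self):
        allele = ps.build_published_allele("BAR_KIT")
        tracks, _ = ps.simulate_depth_and_junctions(allele, 30.0, seed=1)
        donor = tracks["chr6_sim"].depth[19_241_860:19_264_562]
        assert donor.mean() == pytest.approx(90.0, rel=0.02)  # native + 2 splices
        deleted = tracks["chr6_sim"].depth[241_860:258_140]
        assert deleted.mean() == 0.0

    @pytest.mark.parametrize("name", ["ANG_KIT", "BAR_KIT", "A_sm", "A_pc"])
    def test_generated_junctions_classify_as_walk_implies(self, name):
        allele = ps.build_published_allele(name)
        _, junctions = ps.simulate_depth_and_junctions(allele, seed=0)
        classes = {ps.classify_junction(j) for j in junctions}
        assert classes <= {TANDEM, DISTANT}
        assert TANDEM in classes


class TestExpression:
    def design(self, n=3):
        rows = [(f"s{i}_{g}", f"a{i}", g) for i in range(n) for g in ("eu", "pheo")]
        return pd.DataFrame(rows, columns=["sample", "animal", "group"])

    def test_zero_dispersion_is_poisson(self):
        genes = [f"g{i}" for i in range(400)]
        means = pd.DataFrame({"eu": np.full(400, 200.0), "pheo": np.full(400, 200.0)},
                             index=genes)
        counts = ps.simulate_expression_counts(
            self.design(1), means, dispersion=0.0, seed=3, lib_jitter=0.0
        )
        for col in counts:
            m = counts[col].mean()
            assert abs(m - 200.0) < 3 * math.sqrt(200.0 / 400)
            # Poisson: variance ~ mean, far below the NB variance at disp 0.1
            assert counts[col].var() < 2 * 200.0

    def test_twentyfold_mean_ratio_recovered(self):
        counts, design = ps.simulate_asip_experiment(
            n_pairs=3, eu_mean=25.0, pheo_mean=500.0, dispersion=0.1, seed=0
        )
        eu = design.loc[design.group == "eumelanistic", "sample"]
        pheo = design.loc[design.group == "pheomelanistic", "sample"]
        ratio = counts.loc["ASIP", pheo].mean() / counts.loc["ASIP", eu].mean()
        assert 15.0 <= ratio <= 25.0

    def test_equal_means_give_unit_fold_change(self):
        """No systematic fold change between groups with identical means.

        With dispersion 0.1 and n = 5 pairs the group-mean log ratio of a
        single gene has sd ~ sqrt(2(phi + 1/mu)/n) ~ 0.2, so one draw is
        bounded at 3 sigma while the geometric mean over independent
        replicates must sit tightly around 1.
        """
        genes = [f"g{i}" for i in range(1_000)] + ["target"]
        base = np.append(
            np.exp(np.random.default_rng(1).normal(4, 1, 1_000)), 1_000.0
        )
        means = pd.DataFrame({"eu": base, "pheo": base}, index=genes)
        eu = [f"s{i}_eu" for i in range(5)]
        pheo = [f"s{i}_pheo" for i in range(5)]
        three_sigma = 3 * math.sqrt(2 * (0.1 + 1 / 1_000.0) / 5)
        logs = []
        for seed in range(5):
            counts = ps.simulate_expression_counts(self.design(5), means, 0.1, seed=seed)
            norm = ps.normalized_expression(counts, ps.tmm_factors(counts))
            ratio = norm.loc["target", pheo].mean() / norm.loc["target", eu].mean()
            assert abs(math.log(ratio)) <= three_sigma
            logs.append(math.log(ratio))
        assert 0.8 <= math.exp(np.mean(logs)) <= 1.25
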