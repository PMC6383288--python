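"""Cohort simulator: determinism, bottleneck direction, sweeps, phenotypes, I/O."""

import numpy as np
import pytest

from peachpop.diversity import windowed_pi, windowed_tajimas_d
from peachpop.genio import make_windows, read_intervals, read_vcf
from peachpop.simulate import (
    PopPlan,
    QTLSpec,
    SimConfig,
    SweepSpec,
    simulate_cohort,
    simulate_phenotype,
    write_cohort,
)


def single_pop_config(seed, n=60, generations=20, length=500_000, mu=1e-7):
    return SimConfig(
        n_chromosomes=1,
        chrom_length_bp=length,
        mu=mu,
        recomb_rate=2e-7,
        selfing_rate=0.0,
        pop_plan=[PopPlan("pop", n, generations, None)],
        sample_sizes={"pop": 30},
        seed=seed,
    )


class TestConfigValidation:
    def test_rejects_bad_plans(self):
        with pytest.raises(ValueError, match="founder count"):
            SimConfig(pop_plan=[PopPlan("a", 1, 10, None)], sample_sizes={})
        with pytest.raises(ValueError, match="parent"):
            SimConfig(pop_plan=[PopPlan("a", 5, 10, None), PopPlan("b", 5, 10, "zzz")],
                      sample_sizes={})
        with pytest.raises(ValueError, match="root"):
            SimConfig(pop_plan=[PopPlan("a", 5, 10, None), PopPlan("b", 5, 10, None)],
                      sample_sizes={})

    def test_rejects_out_of_bounds_sweep(self):
        with pytest.raises(ValueError, match="out of bounds"):
            SimConfig(sweep_spec=[SweepSpec("chr1", 10_000_000, 0.2, "landrace")])

    def test_rejects_oversized_sample(self):
        with pytest.raises(ValueError, match="exceeds"):
            single = single_pop_config(0)
            SimConfig(pop_plan=single.pop_plan, n_chromosomes=1,
                      chrom_length_bp=500_000, sample_sizes={"pop": 1000})

    def test_rejects_bad_heritability(self):
        with pytest.raises(ValueError, match="heritability"):
            SimConfig(heritability=0.0)


class TestSeedDeterminism:
    def test_identical_config_identical_output(self):
        cfg1 = single_pop_config(42)
        cfg2 = single_pop_config(42)
        g1, _, t1 = simulate_cohort(cfg1)
        g2, _, t2 = simulate_cohort(cfg2)
        np.testing.assert_array_equal(g1.genotypes, g2.genotypes)
        np.testing.assert_array_equal(g1.pos, g2.pos)
        assert t1.realized_group_pi == t2.realized_group_pi

    def test_different_seeds_differ(self):
        g1, _, _ = simulate_cohort(single_pop_config(1))
        g2, _, _ = simulate_cohort(single_pop_config(2))
        assert g1.n_sites != g2.n_sites or not np.array_equal(g1.genotypes, g2.genotypes)


class TestNeutralExpectations:
    def test_pi_concentrates_near_equilibrium(self):
        """Single-population neutral runs: genome pi ~= 4 N mu within 3 SE."""
        n, mu = 60, 1e-7
        vals = [
            simulate_cohort(single_pop_config(100 + k, n=n, mu=mu))[2]
            .realized_group_pi["pop"]
            for k in range(20)
        ]
        expected = 4 * n * mu
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expected) < 3 * se + 0.05 * expected

    def test_mean_tajimas_d_near_zero(self):
        ds = []
        for k in range(20):
            g, popmap, _ = simulate_cohort(single_pop_config(200 + k))
            wins = make_windows(g.chrom_lengths)
            track = windowed_tajimas_d(g, popmap.samples_in("pop"), wins)
            ds.append(np.nanmean(track.value[track.mask]))
        assert abs(np.mean(ds)) < 0.5


class TestBottleneck:
    def test_bottleneck_reduces_diversity(self):
        ratios = []
        for seed in range(3):
            cfg = SimConfig(
                n_chromosomes=1, chrom_length_bp=500_000, mu=1e-7, recomb_rate=2e-7,
                selfing_rate=0.0,
                pop_plan=[PopPlan("wild", 100, 10, None),
                          PopPlan("landrace", 20, 60, "wild")],
                sample_sizes={"wild": 30, "landrace": 20}, seed=seed,
            )
            _, _, truth = simulate_cohort(cfg)
            ratios.append(truth.realized_group_pi["wild"] / truth.realized_group_pi["landrace"])
        assert np.mean(ratios) > 1.5

    def test_size_ordering_implies_pi_ordering(self):
        ok = 0
        for seed in range(5):
            cfg = SimConfig(
                n_chromosomes=1, chrom_length_bp=400_000, mu=1e-7, recomb_rate=2e-7,
                selfing_rate=0.0,
                pop_plan=[PopPlan("wild", 120, 10, None),
                          PopPlan("landrace", 40, 80, "wild"),
                          PopPlan("improved", 15, 40, "landrace")],
                sample_sizes={"wild": 30, "landrace": 25, "improved": 15}, seed=seed,
            )
            _, _, truth = simulate_cohort(cfg)
            pi = truth.realized_group_pi
            ok += pi["wild"] > pi["landrace"] >= pi["improved"]
        assert ok >= 4  # >= 90% expected; allow one drift reversal in five


class TestSweeps:
    def test_planted_sweep_erases_local_diversity(self):
        """Median over replicate cohorts: pi inside the truth interval falls
        below half the genome-wide level (single replicates can retain an
        escaped haplotype, so the typical behaviour is what is asserted)."""
        from peachpop.genio import WindowSpec
        from .conftest import sweep_cohort_config

        ratios = []
        for seed in (11, 12, 13, 14, 15):
            g, popmap, truth = simulate_cohort(sweep_cohort_config(seed))
            iv = truth.sweep_intervals[0]
            assert iv.start <= 500_000 - 1 < iv.end  # focal position inside truth
            land = popmap.samples_in("landrace")
            inside = windowed_pi(g, land, [WindowSpec(iv.chrom, iv.start, iv.end)]).value[0]
            ratios.append(inside / truth.realized_group_pi["landrace"])
        assert np.median(ratios) < 0.5

    def test_sweep_not_established_raises(self):
        from peachpop.simulate import SweepNotEstablishedError

        cfg = SimConfig(
            n_chromosomes=1, chrom_length_bp=200_000, mu=1e-7, recomb_rate=1e-7,
            pop_plan=[PopPlan("pop", 30, 50, None)],
            sweep_spec=[SweepSpec("chr1", 100_000, 1e-6, "pop")],
            sample_sizes={"pop": 10}, seed=0, max_sweep_retries=0,
        )
        with pytest.raises(SweepNotEstablishedError):
            simulate_cohort(cfg)


class TestPhenotype:
    def test_full_heritability_is_exact_genetic_value(self, two_pop_cohort):
        g, _, _ = two_pop_cohort
        qtl = [(3, 1.0), (10, -0.5)]
        y = simulate_phenotype(g, qtl, heritability=1.0, seed=0)
        expected = 1.0 * g.genotypes[:, 3] - 0.5 * g.genotypes[:, 10]
        np.testing.assert_allclose(y, expected.astype(float))

    def test_low_heritability_decorrelates(self, two_pop_cohort):
        g, _, _ = two_pop_cohort
        qtl = [(3, 1.0)]
        gval = g.genotypes[:, 3].astype(float)
        corrs = [np.corrcoef(simulate_phenotype(g, qtl, 0.01, seed=s), gval)[0, 1] ** 2
                 for s in range(10)]
        assert np.mean(corrs) < 0.15

    def test_ols_recovers_effect_size(self):
        cfg = single_pop_config(33, n=250, generations=10, length=1_000_000)
        cfg.sample_sizes = {"pop": 250}
        g, _, _ = simulate_cohort(cfg)
        maf = g.genotypes.mean(axis=0) / 2
        site = int(np.argmin(np.abs(maf - 0.4)))
        slopes = []
        for s in range(5):
            y = simulate_phenotype(g, [(site, 1.0)], heritability=0.5, seed=s)
            x = g.genotypes[:, site].astype(float)
            slopes.append(np.polyfit(x, y, 1)[0])
        assert np.mean(slopes) == pytest.approx(1.0, abs=0.2)

    def test_zero_genetic_variance_errors(self, two_pop_cohort):
        g, _, _ = two_pop_cohort
        mono = np.full(g.n_samples, 1.0)
        with pytest.raises(ValueError, match="variance"):
            simulate_phenotype(g, [(0, 0.0)], heritability=0.5, seed=0)


class TestWriteCohort:
    def test_roundtrip_and_truth_bed(self, tmp_path, two_pop_cohort):
        g, popmap, truth = two_pop_cohort
        paths = write_cohort((g, popmap, truth), tmp_path / "out")
        g2 = read_vcf(paths["vcf"], chrom_lengths=g.chrom_lengths)
        np.testing.assert_array_equal(g.genotypes, g2.genotypes)
        ivs = read_intervals(paths["truth_bed"])
        assert len(ivs) == len(truth.sweep_intervals)
        assert all(iv.start < iv.end for iv in ivs)
        starts = [iv.start for iv in ivs if iv.chrom == "chr1"]
        assert starts == sorted(starts)

    def test_empty_sweep_spec_gives_empty_bed(self, tmp_path):
        cfg = single_pop_config(3)
        cohort = simulate_cohort(cfg)
        paths = write_cohort(cohort, tmp_path / "empty")
        assert read_intervals(paths["truth_bed"]) == []
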