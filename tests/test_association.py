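"""Kinship, REML variance components, GLS scan, peaks."""

import numpy as np
import pytest

from peachpop.association import (
    KinshipMatrix,
    bonferroni_threshold,
    call_peaks,
    fit_null_model,
    genomic_inflation,
    kinship_matrix,
    scan_snps,
)
from .conftest import make_matrix, random_matrix


def oracle_kinship(G):
    """Brute-force per-pair IBS mean with pairwise-complete deletion."""
    n = G.shape[0]
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            shared = (G[i] >= 0) & (G[j] >= 0)
            K[i, j] = np.mean(1 - np.abs(G[i, shared] - G[j, shared]) / 2)
    return K


class TestKinship:
    def test_identical_rows_give_one(self):
        g = make_matrix(np.tile(np.array([0, 1, 2, 1], dtype=np.int8), (2, 1)))
        K = kinship_matrix(g)
        assert K.values[0, 1] == pytest.approx(1.0)

    def test_opposite_homozygotes_give_zero(self):
        g = make_matrix(np.array([[0, 0, 0], [2, 2, 2]], dtype=np.int8))
        assert kinship_matrix(g).values[0, 1] == pytest.approx(0.0)

    def test_matches_bruteforce_with_missing(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            g = random_matrix(rng, n_samples=5, n_sites=10, missing_rate=0.2)
            K = kinship_matrix(g)
            np.testing.assert_allclose(K.values, oracle_kinship(g.genotypes), atol=1e-12)

    def test_no_shared_calls_errors(self):
        geno = np.array([[0, -1], [-1, 2]], dtype=np.int8)
        with pytest.raises(ValueError, match="shares no"):
            kinship_matrix(make_matrix(geno))


def simulated_kinship(rng, n, blocks=4):
    """Block-structured PSD similarity matrix for variance-component tests."""
    labels = rng.integers(0, blocks, n)
    K = 0.5 + 0.5 * (labels[:, None] == labels[None, :]).astype(float)
    np.fill_diagonal(K, 1.0)
    return K


class TestNullModel:
    def test_pure_noise_gives_low_heritability(self):
        rng = np.random.default_rng(1)
        n = 150
        K = KinshipMatrix(simulated_kinship(rng, n), [f"s{i}" for i in range(n)])
        ratios = []
        for s in range(8):
            y = np.random.default_rng(s).standard_normal(n)
            ratios.append(fit_null_model(y, K).heritability)
        assert np.mean(ratios) < 0.1

    def test_recovers_moderate_heritability(self):
        rng = np.random.default_rng(2)
        n = 200
        Kv = simulated_kinship(rng, n)
        L = np.linalg.cholesky(Kv + 1e-8 * np.eye(n))
        K = KinshipMatrix(Kv, [f"s{i}" for i in range(n)])
        ests = []
        for s in range(12):
            r2 = np.random.default_rng(100 + s)
            u = L @ r2.standard_normal(n)
            e = r2.standard_normal(n)
            y = u + e  # sigma_g2 = sigma_e2 = 1 -> h2 = 0.5
            ests.append(fit_null_model(y, K).heritability)
        assert np.mean(ests) == pytest.approx(0.5, abs=0.15)

    def test_identity_kinship_flagged_unidentifiable(self):
        n = 50
        K = KinshipMatrix(np.eye(n), [f"s{i}" for i in range(n)])
        fit = fit_null_model(np.random.default_rng(0).standard_normal(n), K)
        assert not fit.delta_identifiable

    def test_nonfinite_phenotype_rejected(self):
        K = KinshipMatrix(np.eye(3), ["a", "b", "c"])
        with pytest.raises(ValueError):
            fit_null_model(np.array([1.0, np.nan, 0.0]), K)


class TestScan:
    def _cohort(self, seed=3, n=120, m=300):
        rng = np.random.default_rng(seed)
        freqs = rng.uniform(0.1, 0.9, m)
        geno = ((rng.random((n, m)) < freqs) .astype(np.int8)
                + (rng.random((n, m)) < freqs).astype(np.int8))
        return make_matrix(geno, positions=np.arange(1, m + 1) * 1000,
                           chrom_len=(m + 2) * 1000)

    def test_identity_kinship_matches_ols(self):
        import statsmodels.api as sm

        g = self._cohort()
        n = g.n_samples
        y = np.random.default_rng(9).standard_normal(n)
        K = KinshipMatrix(np.eye(n), g.samples)
        fit = fit_null_model(y, K)
        res = scan_snps(g, y, fit, K)
        for j in (0, 57, 123):
            ols = sm.OLS(y, sm.add_constant(g.genotypes[:, j].astype(float))).fit()
            assert res.table["p"].iloc[j] == pytest.approx(ols.pvalues[1], abs=1e-8)
            assert res.table["beta"].iloc[j] == pytest.approx(ols.params[1], abs=1e-8)

    def test_monomorphic_snp_p_one(self):
        g = self._cohort()
        geno = g.genotypes.copy()
        geno[:, 5] = 1
        g2 = make_matrix(geno, positions=g.pos, chrom_len=400_000)
        y = np.random.default_rng(4).standard_normal(g2.n_samples)
        K = KinshipMatrix(np.eye(g2.n_samples), g2.samples)
        fit = fit_null_model(y, K)
        with pytest.warns(UserWarning, match="monomorphic"):
            res = scan_snps(g2, y, fit, K)
        assert res.table["p"].iloc[5] == 1.0

    def test_kinship_correction_controls_inflation(self):
        """Structured phenotype null: lambda with kinship correction is
        closer to 1 than without it."""
        rng = np.random.default_rng(12)
        n, m = 160, 400
        labels = np.repeat([0, 1], n // 2)
        f = np.empty((2, m))
        f[0] = rng.uniform(0.1, 0.9, m)
        f[1] = np.clip(f[0] + rng.normal(0, 0.25, m), 0.02, 0.98)
        geno = np.empty((n, m), dtype=np.int8)
        for i, lab in enumerate(labels):
            geno[i] = (rng.random(m) < f[lab]).astype(np.int8) + \
                      (rng.random(m) < f[lab]).astype(np.int8)
        g = make_matrix(geno, positions=np.arange(1, m + 1) * 500, chrom_len=(m + 2) * 500)
        y = labels * 1.0 + rng.standard_normal(n) * 0.5  # phenotype follows structure
        K = kinship_matrix(g)
        fit = fit_null_model(y, K)
        lam_corr = genomic_inflation(scan_snps(g, y, fit, K).table["p"])
        KI = KinshipMatrix(np.eye(n), g.samples)
        fitI = fit_null_model(y, KI)
        lam_naive = genomic_inflation(scan_snps(g, y, fitI, KI).table["p"])
        assert abs(lam_corr - 1.0) < abs(lam_naive - 1.0)
        assert lam_naive > 1.5  # structure must actually inflate the naive scan


class TestBonferroni:
    @pytest.mark.parametrize("n,expected", [(1_000_000, 5e-8), (1, 0.05),
                                            (1_562_500, 3.2e-8)])
    def test_threshold_values(self, n, expected):
        p, neglog = bonferroni_threshold(n)
        assert p == pytest.approx(expected)
        assert neglog == pytest.approx(-np.log10(expected))

    def test_rejects_zero(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


class TestPeaks:
    def _assoc(self, positions, pvals, chrom="chr1"):
        import pandas as pd

        from peachpop.association import AssociationResult

        t = pd.DataFrame({
            "chrom": chrom, "pos": positions, "ref": "A", "alt": "G",
            "maf": 0.3, "beta": 1.0, "se": 0.1, "stat": 5.0, "p": pvals,
        })
        return AssociationResult(table=t, n_snps=len(t), alpha=0.05, p_threshold=1e-6)

    def test_nearby_snps_merge(self):
        a = self._assoc([100_000, 150_000], [1e-9, 1e-8])
        assert len(call_peaks(a)) == 1

    def test_distant_snps_split(self):
        a = self._assoc([100_000, 250_000], [1e-9, 1e-8])
        assert len(call_peaks(a)) == 2

    def test_peaks_partition_significant_snps(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.choice(10_000_000, 60, replace=False))
        pv = 10.0 ** rng.uniform(-12, -2, 60)
        a = self._assoc(pos, pv)
        peaks = call_peaks(a)
        assert sum(p["n_snps"] for p in peaks) == int((pv < a.p_threshold).sum())
        for pk in peaks:
            assert pk["start"] <= pk["lead_pos"] <= pk["end"]
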