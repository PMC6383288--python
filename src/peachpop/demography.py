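"""Effective-size estimation and the heterozygosity-excess bottleneck test.

Effective size comes from the mutation-drift relation theta = 4 Ne mu L
applied literally as printed in the source analyses (the factor L is a
generation-time scaling; the formula is applied as stated, and the unit
question is documented in the methods note).

The bottleneck test compares, locus by locus, the observed expected
heterozygosity He with its mutation-drift-equilibrium expectation
conditioned on the observed allele count and sample size. After a
recent bottleneck, rare alleles are lost faster than He declines, so
polymorphic loci show He excess. For biallelic loci the conditional
equilibrium distribution depends only on the coalescent tree shape (one
mutation placed proportionally to branch length), which makes the
infinite-allele (IAM), stepwise (SMM) and two-phase (TPM) mutation
models coincide; the mutation-model argument is accepted for interface
parity and its inertness for SNPs is documented.

The test statistic is the one-sided Wilcoxon signed-rank statistic on
(He_obs - He_eq); its null distribution is calibrated by Monte Carlo
draws from the same conditional coalescent spectrum, because the
conditional He distribution is strongly right-skewed and the textbook
normal approximation is badly miscalibrated in this regime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .genio import GenotypeMatrix

MUTATION_MODELS = ("IAM", "SMM", "TPM")


def effective_size_from_theta(theta: float, mu: float, L: float):
    """Invert theta = 4 Ne mu L. Returns ``(Ne, 2Ne)``."""
    if theta <= 0 or mu <= 0 or L <= 0:
        raise ValueError("theta, mu and L must all be positive")
    ne = theta / (4.0 * mu * L)
    return ne, 2.0 * ne


@dataclass
class BottleneckTestResult:
    model: str
    p_multistep: float | None
    p_value: float
    statistic: float
    n_loci: int
    n_iterations: int
    per_locus: pd.DataFrame  # He_obs, He_eq, sd_eq, standardized difference

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _coalescent_folded_weights(n: int, n_iter: int, rng) -> np.ndarray:
    """Branch-length-weighted folded frequency spectrum conditioned on one
    segregating site in a sample of ``n`` haplotypes.

    Simulates ``n_iter`` Kingman coalescent trees, accumulating for each
    derived-allele count j the total branch length subtending j leaves;
    a single mutation falls on a branch with probability proportional to
    length pooled over trees, so the folded minor-count distribution is
    the normalized, folded accumulation.
    """
    t_j = np.zeros(n)  # index j = descendants of a branch (1..n-1 used)
    for _ in range(n_iter):
        sizes = np.ones(n, dtype=np.int64)
        m = n
        while m > 1:
            t = rng.exponential(2.0 / (m * (m - 1)))
            t_j += t * np.bincount(sizes[:m], minlength=n)
            i, j = rng.choice(m, size=2, replace=False)
            if i > j:
                i, j = j, i
            sizes[i] += sizes[j]
            sizes[j] = sizes[m - 1]
            m -= 1
    folded = np.zeros(n // 2 + 1)
    for j in range(1, n):
        folded[min(j, n - j)] += t_j[j]
    w = folded[1:]
    return w / w.sum()


def _he_classes(n: int) -> np.ndarray:
    """Unbiased He for folded minor count j = 1..n//2 in n alleles."""
    j = np.arange(1, n // 2 + 1, dtype=float)
    p = j / n
    return (n / (n - 1.0)) * 2.0 * p * (1.0 - p)


def _signed_rank_statistic(diffs: np.ndarray) -> float:
    """One-sided Wilcoxon signed-rank statistic W+ (sum of positive ranks)."""
    d = diffs[diffs != 0]
    if d.size == 0:
        return 0.0
    ranks = rankdata(np.abs(d))
    return float(ranks[d > 0].sum())


def heterozygosity_excess_test(
    g: GenotypeMatrix,
    samples,
    model: str = "IAM",
    p_multistep: float | None = 0.3,
    n_loci: int = 1000,
    n_iter: int = 1000,
    seed: int = 0,
    n_null: int = 999,
) -> BottleneckTestResult:
    """Heterozygosity-excess bottleneck test on a random set of SNP loci.

    For each sampled locus, observed He = n/(n-1) (1 - sum p^2) is
    compared with the equilibrium expectation conditioned on two alleles
    and the locus's called sample size; the one-sided (excess) Wilcoxon
    signed-rank P value is calibrated by ``n_null`` Monte Carlo draws of
    ``n_loci`` He values from the conditional spectrum.
    """
    model = model.upper()
    if model not in MUTATION_MODELS:
        raise ValueError(f"model must be one of {MUTATION_MODELS}")
    if model == "TPM" and p_multistep is None:
        raise ValueError("TPM requires p_multistep")
    rng = np.random.default_rng(seed)
    idx = g.sample_indices(samples)
    alt, n = g.allele_counts(idx)
    poly = (alt > 0) & (alt < n) & (n >= 4)
    sites = np.flatnonzero(poly)
    if sites.size < 50:
        raise ValueError(f"need >= 50 polymorphic loci, got {sites.size}")
    if n_loci > sites.size:
        warnings.warn(f"only {sites.size} polymorphic loci available; using all")
        chosen = sites
    else:
        chosen = rng.choice(sites, size=n_loci, replace=False)

    a, m = alt[chosen], n[chosen]
    p_obs = a / m
    he_obs = (m / (m - 1.0)) * (1.0 - p_obs**2 - (1.0 - p_obs) ** 2)

    # conditional equilibrium spectrum per distinct called-allele count;
    # for k = 2 alleles the IAM/SMM/TPM distinction is inert
    spectra: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for n_al in np.unique(m):
        w = _coalescent_folded_weights(int(n_al), n_iter, rng)
        spectra[int(n_al)] = (w, _he_classes(int(n_al)))

    he_eq = np.empty(chosen.size)
    sd_eq = np.empty(chosen.size)
    for i, n_al in enumerate(m):
        w, he_c = spectra[int(n_al)]
        mu_c = float(w @ he_c)
        he_eq[i] = mu_c
        sd_eq[i] = float(np.sqrt(w @ (he_c - mu_c) ** 2))

    diffs = he_obs - he_eq
    w_obs = _signed_rank_statistic(diffs)

    # Monte Carlo null: draw locus sets from the conditional spectrum
    n_counts = np.array([int(x) for x in m])
    w_null = np.empty(n_null)
    for b in range(n_null):
        sim_he = np.empty(chosen.size)
        for n_al, (w, he_c) in spectra.items():
            mask = n_counts == n_al
            k = int(mask.sum())
            if k:
                sim_he[mask] = rng.choice(he_c, size=k, p=w)
        w_null[b] = _signed_rank_statistic(sim_he - he_eq)
    p_value = (1.0 + (w_null >= w_obs).sum()) / (n_null + 1.0)

    per_locus = pd.DataFrame(
        {
            "site_index": chosen,
            "n_alleles": m,
            "he_obs": he_obs,
            "he_eq": he_eq,
            "sd_eq": sd_eq,
            "std_diff": (he_obs - he_eq) / np.where(sd_eq > 0, sd_eq, np.nan),
        }
    )
    return BottleneckTestResult(
        model=model,
        p_multistep=p_multistep if model == "TPM" else None,
        p_value=float(p_value),
        statistic=w_obs,
        n_loci=int(chosen.size),
        n_iterations=n_iter,
        per_locus=per_locus,
    )
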