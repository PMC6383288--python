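"""Shared fixtures: small deterministic cohorts and genotype matrices."""

import numpy as np
import pytest

from peachpop.genio import GenotypeMatrix
from peachpop.simulate import (
    PopPlan,
    SimConfig,
    SweepSpec,
    default_domestication_config,
    simulate_cohort,
)


def make_matrix(genotypes, positions=None, chrom="chr1", chrom_len=None, samples=None):
    """GenotypeMatrix from a plain (samples x sites) list/array."""
    geno = np.asarray(genotypes, dtype=np.int8)
    n, m = geno.shape
    pos = np.asarray(positions if positions is not None else np.arange(1, m + 1) * 10,
                     dtype=np.int64)
    return GenotypeMatrix(
        genotypes=geno,
        chrom=np.full(m, chrom, dtype=object),
        pos=pos,
        ref=np.full(m, "A", dtype=object),
        alt=np.full(m, "G", dtype=object),
        samples=samples or [f"s{i}" for i in range(n)],
        chrom_lengths={chrom: chrom_len or int(pos.max()) + 10},
    )


def random_matrix(rng, n_samples=8, n_sites=20, missing_rate=0.0, chrom_len=None):
    geno = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    if missing_rate:
        mask = rng.random(geno.shape) < missing_rate
        geno[mask] = -1
    pos = np.sort(rng.choice(np.arange(1, (chrom_len or 10 * n_sites + 50)), size=n_sites,
                             replace=False))
    return make_matrix(geno, positions=pos, chrom_len=chrom_len)


@pytest.fixture(scope="session")
def default_cohort():
    """The bundled domestication-scenario cohort (seed 1)."""
    return simulate_cohort(default_domestication_config(seed=1))


def sweep_cohort_config(seed):
    """Wild -> landrace scenario with one strong sweep completing at sampling."""
    return SimConfig(
        n_chromosomes=1,
        chrom_length_bp=1_000_000,
        mu=5e-8,
        recomb_rate=2e-7,
        selfing_rate=0.0,
        pop_plan=[PopPlan("wild", 200, 10, None), PopPlan("landrace", 100, 150, "wild")],
        sweep_spec=[SweepSpec("chr1", 500_000, 0.5, "landrace", 70)],
        sample_sizes={"wild": 40, "landrace": 40},
        seed=seed,
    )


@pytest.fixture(scope="session")
def two_pop_cohort():
    """Small wild -> landrace cohort with one planted sweep (fast)."""
    return simulate_cohort(sweep_cohort_config(11))
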