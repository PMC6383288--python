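"""Frozen study-condition experiments: sweep recovery, GWAS calibration,
and bottleneck-test calibration.

These functions define the simulation conditions under which the
package's detection machinery is evaluated; the same definitions back
the test suite and the reproduction script so that reported numbers
always come from one place. Problem sizes are desk scale (a 2 x 2 Mb
genome, hundreds of diploids) with mutation and recombination rates
inflated accordingly; docs/methods.md discusses what these conditions
do and do not establish about full-genome data.
"""

from __future__ import annotations

import numpy as np

from .association import fit_null_model, kinship_matrix, scan_snps
from .demography import heterozygosity_excess_test
from .diversity import rod_track, windowed_pi
from .genio import filter_by_maf, make_windows
from .simulate import (
    PopPlan,
    SimConfig,
    SweepSpec,
    matrix_from_tree_sequence,
    simulate_cohort,
    simulate_phenotype,
)
from .sweepscan import call_sweeps, clr_scan, folded_sfs, top_quantile_threshold

SWEEP_POSITIONS = [
    ("chr1", 400_000),
    ("chr1", 1_200_000),
    ("chr2", 300_000),
    ("chr2", 1_000_000),
    ("chr2", 1_700_000),
]


def recovery_study_config(seed: int) -> SimConfig:
    """Domestication scenario for sweep recovery: wild (N=800, coalescent
    standing variation) -> landrace (N=400, 250 generations) with five
    sweeps at s=0.2 selected from the founding of the landrace."""
    return SimConfig(
        n_chromosomes=2,
        chrom_length_bp=2_000_000,
        mu=5e-8,
        recomb_rate=2e-7,
        selfing_rate=0.0,
        pop_plan=[PopPlan("wild", 800, 10, None), PopPlan("landrace", 400, 250, "wild")],
        sweep_spec=[SweepSpec(c, p, 0.2, "landrace", 250) for c, p in SWEEP_POSITIONS],
        sample_sizes={"wild": 50, "landrace": 50},
        seed=seed,
    )


def sweep_recovery_experiment(n_replicates: int = 10, base_seed: int = 1,
                              clr_grid: int = 200, clr_margin: int = 400_000) -> dict:
    """ROD top-5% recovery of planted sweeps plus CLR localization.

    A truth interval counts as recovered when it intersects a called
    sweep region; CLR localization asks whether the argmax of the scan
    around the focal position lies within 100 kb of it.
    """
    n_truth = n_recovered = 0
    n_localized = n_scanned = 0
    per_replicate = []
    for rep in range(n_replicates):
        cfg = recovery_study_config(base_seed + rep)
        g, popmap, truth = simulate_cohort(cfg)
        windows = make_windows(g.chrom_lengths)
        wild = popmap.samples_in("wild")
        land = popmap.samples_in("landrace")
        rod = rod_track(windowed_pi(g, wild, windows), windowed_pi(g, land, windows))
        threshold, _ = top_quantile_threshold(rod, 0.05)
        sweeps = call_sweeps(rod, threshold, source="domestication")
        background = folded_sfs(g, g.sample_indices(land))
        hits = 0
        for iv, (chrom, focal) in zip(truth.sweep_intervals, SWEEP_POSITIONS):
            recovered = any(
                s.chrom == iv.chrom and s.start < iv.end and s.end > iv.start
                for s in sweeps
            )
            n_truth += 1
            if not recovered:
                continue
            n_recovered += 1
            hits += 1
            length = cfg.chrom_length_bp
            region = (chrom, max(0, focal - 1 - clr_margin), min(length, focal - 1 + clr_margin))
            try:
                track = clr_scan(g, land, region, grid_n=clr_grid, background=background)
            except ValueError:
                continue
            n_scanned += 1
            if abs(track.argmax_position() - (focal - 1)) <= 100_000:
                n_localized += 1
        per_replicate.append(hits)
    return {
        "n_replicates": n_replicates,
        "n_truth": n_truth,
        "n_recovered": n_recovered,
        "recovery_fraction": n_recovered / n_truth,
        "clr_localized_fraction": (n_localized / n_scanned) if n_scanned else np.nan,
        "n_clr_scanned": n_scanned,
        "recovered_per_replicate": per_replicate,
    }


def gwas_study_cohort(seed: int):
    """Single-population cohort for GWAS calibration: 300 diploids on the
    2 x 2 Mb genome with SNP density giving a few thousand testable sites."""
    cfg = SimConfig(
        n_chromosomes=2,
        chrom_length_bp=2_000_000,
        mu=1.5e-7,
        recomb_rate=2e-7,
        selfing_rate=0.0,
        pop_plan=[PopPlan("pop", 300, 10, None)],
        sample_sizes={"pop": 300},
        seed=seed,
    )
    g, _, _ = simulate_cohort(cfg)
    return filter_by_maf(g, 0.05)


def gwas_calibration_experiment(seed: int = 1, n_power_reps: int = 10,
                                qtl_variance: float = 0.2) -> dict:
    """Type-I error on a permuted phenotype and top-5 rank power for a
    planted QTL explaining ``qtl_variance`` of the phenotypic variance."""
    g = gwas_study_cohort(seed)
    K = kinship_matrix(g)
    rng = np.random.default_rng(seed)

    maf = np.minimum(g.genotypes.mean(axis=0) / 2, 1 - g.genotypes.mean(axis=0) / 2)
    candidates = np.flatnonzero(maf > 0.2)
    top5 = 0
    for rep in range(n_power_reps):
        site = int(rng.choice(candidates))
        y = simulate_phenotype(g, [(site, 1.0)], heritability=qtl_variance,
                               seed=seed * 1000 + rep)
        fit = fit_null_model(y, K)
        res = scan_snps(g, y, fit, K)
        rank = int((res.table["p"] < res.table["p"].iloc[site]).sum())
        top5 += rank < 5

    y_perm = rng.permutation(y)
    fit = fit_null_model(y_perm, K)
    res = scan_snps(g, y_perm, fit, K)
    type1 = float((res.table["p"] < 0.05).mean())
    return {
        "n_snps": g.n_sites,
        "type1_rate": type1,
        "power_top5": top5 / n_power_reps,
        "n_power_reps": n_power_reps,
    }


def _msprime_equilibrium(seed: int, n_diploids: int = 50):
    import msprime

    ts = msprime.sim_ancestry(samples=n_diploids, population_size=1000,
                              sequence_length=2_000_000, recombination_rate=5e-7,
                              random_seed=seed)
    mts = msprime.sim_mutations(ts, rate=3e-8, random_seed=seed + 10_000,
                                model=msprime.BinaryMutationModel())
    return matrix_from_tree_sequence(mts)


def _msprime_bottleneck(seed: int, n_diploids: int = 50, fold: int = 10,
                        duration: int = 50):
    import msprime

    dem = msprime.Demography()
    dem.add_population(name="p", initial_size=1000 // fold)
    dem.add_population_parameters_change(time=duration, population="p", initial_size=1000)
    ts = msprime.sim_ancestry(samples=n_diploids, demography=dem,
                              sequence_length=2_000_000, recombination_rate=5e-7,
                              random_seed=seed)
    mts = msprime.sim_mutations(ts, rate=3e-8, random_seed=seed + 20_000,
                                model=msprime.BinaryMutationModel())
    return matrix_from_tree_sequence(mts)


def bottleneck_calibration_experiment(base_seed: int = 1, n_eq_reps: int = 50,
                                      n_bott_reps: int = 10, n_loci: int = 1000,
                                      n_iter: int = 1000) -> dict:
    """False-positive rate at mutation-drift equilibrium and power against
    a recent 10-fold bottleneck, both under the IAM at alpha = 0.05."""
    eq_p = []
    for rep in range(n_eq_reps):
        g = _msprime_equilibrium(base_seed + rep)
        res = heterozygosity_excess_test(g, g.samples, model="IAM", n_loci=n_loci,
                                         n_iter=n_iter, seed=base_seed + rep)
        eq_p.append(res.p_value)
    bott_p = []
    for rep in range(n_bott_reps):
        g = _msprime_bottleneck(base_seed + 500 + rep)
        res = heterozygosity_excess_test(g, g.samples, model="IAM", n_loci=n_loci,
                                         n_iter=n_iter, seed=base_seed + 500 + rep)
        bott_p.append(res.p_value)
    eq_p, bott_p = np.array(eq_p), np.array(bott_p)
    return {
        "false_positive_rate": float((eq_p < 0.05).mean()),
        "n_equilibrium_reps": n_eq_reps,
        "power": float((bott_p < 0.05).mean()),
        "n_bottleneck_reps": n_bott_reps,
    }
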