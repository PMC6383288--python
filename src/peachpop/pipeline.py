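"""End-to-end orchestration: cohort (simulated or ingested) -> windowed
diversity -> ROD -> sweep calls -> CLR confirmation -> LD decay ->
demography -> GWAS -> sweep/QTL/peak overlap -> JSON report.

The stage sequence mirrors a domestication-genomics study: diversity
ratios quantify the bottlenecks, ROD top-quantile scans call
domestication (wild/landrace) and improvement (landrace/improved)
sweeps plus group-specific comparisons, CLR scans confirm called
regions, LD curves contrast groups, the mutation-drift relation turns
wild diversity into an effective size, the heterozygosity-excess test
checks the bottleneck, and a mixed-model GWAS locates planted QTLs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, demography, diversity, lddecay, sweepscan
from .genio import GenotypeMatrix, PopulationMap, make_windows, read_intervals, read_vcf
from .simulate import SimConfig, default_domestication_config, simulate_cohort, simulate_phenotype

log = logging.getLogger("peachpop")

MU_PRINTED = 7.77e-9   # per-generation substitution rate used for Ne scaling
GEN_TIME_PRINTED = 3.0


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    sim: SimConfig | None = None
    vcf: str | None = None
    samples_tsv: str | None = None
    intervals_bed: str | None = None
    out_dir: str = "peachpop_run"
    window_size: int = 100_000
    window_step: int = 10_000
    top_q: float = 0.05
    comparisons: list[tuple[str, str, str]] | None = None
    ld_groups: list[str] | None = None
    ld_max_dist: int = 200_000
    ld_min_maf: float = 0.05
    ld_pair_budget: int = 200_000
    gwas_maf: float = 0.05
    gwas_alpha: float = 0.05
    clr_grid: int = 200
    clr_margin: int = 200_000
    bottleneck_group: str = "landrace"
    bottleneck_n_loci: int = 1000
    bottleneck_n_iter: int = 300
    run_gwas: bool = True
    run_bottleneck: bool = True
    run_clr: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.top_q < 0.5:
            raise ValueError("top_q must lie in (0, 0.5)")
        if self.sim is None and self.vcf is None:
            self.sim = default_domestication_config(seed=self.seed)

    def config_hash(self) -> str:
        fields = _jsonable(asdict(self))
        fields.pop("out_dir", None)  # output location is not part of the science
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _default_comparisons(groups: dict) -> list[tuple[str, str, str]]:
    comps = []
    if "wild" in groups and "landrace" in groups:
        comps.append(("domestication", "wild", "landrace"))
    improved = [g for g in groups if g.startswith("improved")]
    if "landrace" in groups and improved:
        for gi in improved:
            comps.append((f"improvement_{gi.removeprefix('improved_')}", "landrace", gi))
    return comps


def load_or_simulate(config: RunConfig):
    """Return (GenotypeMatrix, PopulationMap, CohortTruth | None)."""
    if config.vcf is not None:
        g = read_vcf(config.vcf)
        popmap = PopulationMap.from_tsv(config.samples_tsv)
        popmap.validate_against(g)
        return g, popmap, None
    return simulate_cohort(config.sim)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write artifacts under ``config.out_dir``.

    Returns the report dictionary (also written as ``report.json``).
    Reports are deterministic for a fixed config: timestamps are
    deliberately excluded.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
    }

    g, popmap, truth = load_or_simulate(config)
    groups = popmap.groups()
    comparisons = config.comparisons or _default_comparisons(groups)
    for _, num, den in comparisons:
        for grp in (num, den):
            if grp not in groups:
                raise ValueError(f"comparison group {grp!r} missing from population map")
    log.info("cohort: %d samples, %d sites, groups %s",
             g.n_samples, g.n_sites, {k: len(v) for k, v in groups.items()})
    report["cohort"] = {
        "n_samples": g.n_samples,
        "n_sites": g.n_sites,
        "groups": {k: len(v) for k, v in groups.items()},
    }

    windows = make_windows(g.effective_lengths(), config.window_size, config.window_step)

    # --- windowed diversity per group -------------------------------------
    pi_tracks: dict[str, diversity.WindowStatTrack] = {}
    pi_summary: dict[str, dict] = {}
    for label, members in groups.items():
        track = diversity.windowed_pi(g, members, windows)
        track.to_tsv(out / f"pi_{label}.tsv")
        pi_tracks[label] = track
        pi_summary[label] = diversity.track_summary(track)
        pi_summary[label]["genome_pi"] = diversity.genome_pi(g, members)
    report["pi"] = pi_summary
    report["stages"].append("pi")

    ratios = {}
    for name, num, den in comparisons:
        ratios[name] = pi_summary[num]["genome_pi"] / pi_summary[den]["genome_pi"]
    report["pi_ratios"] = ratios

    # --- Tajima's D and F_ST for the primary contrast ---------------------
    if "wild" in groups and "landrace" in groups:
        d_track = diversity.windowed_tajimas_d(g, groups["landrace"], windows)
        d_track.to_tsv(out / "tajimas_d_landrace.tsv")
        fst_track = diversity.windowed_fst(g, groups["wild"], groups["landrace"], windows)
        fst_track.to_tsv(out / "fst_wild_landrace.tsv")
        report["tajimas_d_landrace_mean"] = diversity.track_summary(d_track)["mean"]
        report["fst_wild_landrace"] = diversity.track_summary(fst_track)["weighted_mean"]
        report["stages"] += ["tajimas_d", "fst"]

    # --- ROD scans and sweep calls ----------------------------------------
    sweeps_by_comparison: dict[str, list[sweepscan.SweepRegion]] = {}
    rod_report = {}
    for name, num, den in comparisons:
        rod = diversity.rod_track(pi_tracks[num], pi_tracks[den])
        rod.to_tsv(out / f"rod_{name}.tsv")
        threshold, n_above = sweepscan.top_quantile_threshold(rod, config.top_q)
        sweeps = sweepscan.call_sweeps(rod, threshold, source=name)
        sweeps_by_comparison[name] = sweeps
        sweepscan.sweeps_to_frame(sweeps).to_csv(out / f"sweeps_{name}.tsv", sep="\t", index=False)
        rod_report[name] = {
            "threshold": threshold,
            "n_windows_above": n_above,
            "n_sweeps": len(sweeps),
            "sweep_span_bp": int(sum(s.length for s in sweeps)),
            "mean_rod_unmasked": float(np.nanmean(rod.value[rod.mask])),
        }
        log.info("%s: threshold %.3f, %d sweeps", name, threshold, len(sweeps))
    report["rod"] = rod_report
    report["stages"].append("rod_sweeps")

    # shared/specific sweeps between improvement comparisons
    imp_names = [n for n in sweeps_by_comparison if n.startswith("improvement")]
    if len(imp_names) >= 2:
        report["improvement_overlap"] = sweepscan.sweep_set_overlap(
            sweeps_by_comparison[imp_names[0]], sweeps_by_comparison[imp_names[1]]
        )
    if "domestication" in sweeps_by_comparison and imp_names:
        merged_imp = [s for n in imp_names for s in sweeps_by_comparison[n]]
        report["domestication_improvement_overlap"] = sweepscan.sweep_set_overlap(
            sweeps_by_comparison["domestication"], merged_imp
        )

    # --- CLR confirmation inside called sweeps ----------------------------
    if config.run_clr:
        clr_report = {}
        for name, num, den in comparisons:
            rows = []
            backgrounds: dict[str, tuple] = {}
            den_members = groups[den]
            key = den
            if key not in backgrounds:
                backgrounds[key] = sweepscan.folded_sfs(g, g.sample_indices(den_members))
            for s in sweeps_by_comparison[name]:
                chrom_len = g.effective_lengths()[s.chrom]
                region = (
                    s.chrom,
                    max(0, s.start - config.clr_margin),
                    min(chrom_len, s.end + config.clr_margin),
                )
                try:
                    track = sweepscan.clr_scan(
                        g, den_members, region, grid_n=config.clr_grid,
                        background=backgrounds[key],
                    )
                except ValueError:
                    continue
                rows.append(
                    {
                        "chrom": s.chrom, "sweep_start": s.start, "sweep_end": s.end,
                        "clr_max": float(track.clr.max()),
                        "clr_argmax": track.argmax_position(),
                    }
                )
            df = pd.DataFrame(rows)
            df.to_csv(out / f"clr_{name}.tsv", sep="\t", index=False)
            clr_report[name] = {
                "n_scanned": len(rows),
                "median_clr_max": float(df["clr_max"].median()) if len(df) else np.nan,
            }
        report["clr"] = clr_report
        report["stages"].append("clr")

    # --- LD decay per group ------------------------------------------------
    ld_report = {}
    for label in (config.ld_groups or list(groups)):
        curve = lddecay.ld_decay_curve(
            g, groups[label], max_dist=config.ld_max_dist,
            min_maf=config.ld_min_maf, pair_budget=config.ld_pair_budget,
            seed=config.seed,
        )
        curve.to_tsv(out / f"ld_{label}.tsv")
        try:
            hd = lddecay.half_decay_distance(curve)
        except ValueError:
            hd = {"distance_bp": None, "reached": False, "half_level": np.nan}
        ld_report[label] = {
            "half_decay_bp": hd["distance_bp"],
            "reached": hd["reached"],
            "definition": "first fall of isotonically smoothed curve to half its maximum bin",
        }
    report["ld"] = ld_report
    report["stages"].append("ld")

    # --- demography --------------------------------------------------------
    theta_group = "wild" if "wild" in groups else next(iter(groups))
    theta = pi_summary[theta_group]["genome_pi"]
    ne, two_ne = demography.effective_size_from_theta(theta, MU_PRINTED, GEN_TIME_PRINTED)
    report["demography"] = {
        "theta_source_group": theta_group,
        "theta": theta,
        "Ne": ne,
        "2Ne": two_ne,
    }
    if config.run_bottleneck and config.bottleneck_group in groups:
        try:
            bt = demography.heterozygosity_excess_test(
                g, groups[config.bottleneck_group], model="IAM",
                n_loci=config.bottleneck_n_loci, n_iter=config.bottleneck_n_iter,
                seed=config.seed,
            )
            bt.per_locus.to_csv(out / "bottleneck_loci.tsv", sep="\t", index=False)
            report["demography"]["bottleneck_test"] = {
                "group": config.bottleneck_group,
                "model": bt.model,
                "p_value": bt.p_value,
                "n_loci": bt.n_loci,
            }
        except ValueError as e:
            report["demography"]["bottleneck_test"] = {"skipped": str(e)}
    report["stages"].append("demography")

    # --- GWAS on simulated phenotype ---------------------------------------
    if config.run_gwas and truth is not None and truth.qtl_effects:
        y = simulate_phenotype(
            g, truth.qtl_effects, config.sim.heritability, seed=config.seed + 1
        )
        from .genio import filter_by_maf

        site_keep = np.flatnonzero(
            np.nan_to_num(
                np.minimum(*_af_pair(g)), nan=-1.0
            ) >= config.gwas_maf
        )
        gf = g.take_sites(site_keep)
        K = association.kinship_matrix(gf)
        fit = association.fit_null_model(y, K)
        assoc = association.scan_snps(gf, y, fit, K, alpha=config.gwas_alpha)
        assoc.table.to_csv(out / "gwas_trait.tsv", sep="\t", index=False)
        peaks = association.call_peaks(assoc)
        qtl_pos = {(g.chrom[i], int(g.pos[i])) for i, _ in truth.qtl_effects}
        recovered = 0
        for chrom, pos in qtl_pos:
            for pk in peaks:
                if pk["chrom"] == chrom and pk["start"] - 100_000 <= pos <= pk["end"] + 100_000:
                    recovered += 1
                    break
        report["gwas"] = {
            "n_snps": assoc.n_snps,
            "p_threshold": assoc.p_threshold,
            "neglog10_threshold": assoc.neglog10_threshold,
            "heritability_estimate": fit.heritability,
            "n_peaks": len(peaks),
            "n_qtl_planted": len(qtl_pos),
            "n_qtl_recovered": recovered,
            "lambda": association.genomic_inflation(assoc.table["p"]),
        }
        report["stages"].append("gwas")

        # sweep-peak overlap
        if sweeps_by_comparison:
            all_sweeps = [s for lst in sweeps_by_comparison.values() for s in lst]
            peak_ivs = [
                sweepscan.Interval(pk["chrom"], pk["start"], max(pk["end"], pk["start"] + 1),
                                   name=f"peak{i}", category="gwas_peak")
                for i, pk in enumerate(peaks)
            ]
            if peak_ivs:
                ov = sweepscan.annotate_sweeps(all_sweeps, peak_ivs)
                report["gwas"]["peaks_in_sweeps"] = int(ov.n_intervals_hit)

    # --- truth-based evaluation (simulated cohorts only) --------------------
    if truth is not None and truth.sweep_intervals:
        from .genio import write_intervals

        write_intervals(truth.sweep_intervals, out / "truth_sweeps.bed")
        all_sweeps = [s for lst in sweeps_by_comparison.values() for s in lst]
        ov = sweepscan.annotate_sweeps(all_sweeps, truth.sweep_intervals)
        report["sweep_truth_recovery"] = {
            "n_truth": ov.n_intervals,
            "n_recovered": ov.n_intervals_hit,
            "fraction": ov.n_intervals_hit / ov.n_intervals,
        }
    if truth is not None:
        report["realized_group_pi"] = truth.realized_group_pi

    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    log.info("report written to %s", report_path)
    return report


def _af_pair(g: GenotypeMatrix):
    alt, n = g.allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return af, 1.0 - af
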