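#!/usr/bin/env python
"""Windowed diversity, ROD scans and sweep calls on the simulated cohort.

Reads results/cohort/ (run 01 first), computes 100-kb/10-kb windowed pi
per group, Tajima's D, Weir-Cockerham F_ST, the domestication and
improvement ROD tracks, and calls sweeps as merged runs of windows above
the top-5% threshold. Writes tracks and sweep tables to results/scan/.
"""

from pathlib import Path

import numpy as np

from peachpop.diversity import (
    genome_pi,
    rod_track,
    track_summary,
    windowed_fst,
    windowed_pi,
    windowed_tajimas_d,
)
from peachpop.genio import PopulationMap, make_windows, read_vcf
from peachpop.sweepscan import call_sweeps, sweeps_to_frame, top_quantile_threshold

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "scan"
CHROM_LENGTHS = {"chr1": 2_000_000, "chr2": 2_000_000}


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    g = read_vcf(ROOT / "cohort" / "cohort.vcf", chrom_lengths=CHROM_LENGTHS)
    popmap = PopulationMap.from_tsv(ROOT / "cohort" / "samples.tsv")
    windows = make_windows(g.effective_lengths())
    groups = popmap.groups()

    tracks = {}
    for label, members in groups.items():
        tracks[label] = windowed_pi(g, members, windows)
        tracks[label].to_tsv(OUT / f"pi_{label}.tsv")
        print(f"pi[{label}] genome-wide = {genome_pi(g, members):.3e} /bp")

    d = windowed_tajimas_d(g, groups["landrace"], windows)
    d.to_tsv(OUT / "tajimas_d_landrace.tsv")
    print(f"mean Tajima's D (landrace) = {track_summary(d)['mean']:.2f}")

    fst = windowed_fst(g, groups["wild"], groups["landrace"], windows)
    fst.to_tsv(OUT / "fst_wild_landrace.tsv")
    print(f"weighted F_ST wild vs landrace = {track_summary(fst)['weighted_mean']:.2f}")

    comparisons = [
        ("domestication", "wild", "landrace"),
        ("improvement_eastern", "landrace", "improved_eastern"),
        ("improvement_western", "landrace", "improved_western"),
    ]
    for name, num, den in comparisons:
        rod = rod_track(tracks[num], tracks[den])
        rod.to_tsv(OUT / f"rod_{name}.tsv")
        thr, n_above = top_quantile_threshold(rod, 0.05)
        sweeps = call_sweeps(rod, thr, source=name)
        sweeps_to_frame(sweeps).to_csv(OUT / f"sweeps_{name}.tsv", sep="\t", index=False)
        span = sum(s.length for s in sweeps)
        print(f"{name}: ROD threshold {thr:.2f} -> {len(sweeps)} sweeps "
              f"spanning {span / 1e6:.2f} Mb ({span / sum(CHROM_LENGTHS.values()):.1%} of genome)")


if __name__ == "__main__":
    main()
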