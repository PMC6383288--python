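"""Windowed diversity statistics: nucleotide diversity pi, Tajima's D,
Weir-Cockerham F_ST, and the reduction-of-diversity (ROD) ratio.

All statistics run on sliding windows (default 100 kb / 10 kb step) over a
:class:`~peachpop.genio.GenotypeMatrix`. Missing genotypes are handled
per site using only the called alleles. pi is reported per bp with the
full window length as denominator (the convention of the windowed-pi
tools this mirrors); a per-segregating-site mode exists but is not the
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, WindowSpec


@dataclass
class WindowStatTrack:
    """Per-window statistic values with coverage metadata.

    ``mask`` is True for valid windows; masked windows carry NaN values
    and are excluded from downstream quantile computations.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    value: np.ndarray
    n_sites: np.ndarray
    n_samples_effective: np.ndarray
    mask: np.ndarray
    statistic: str = ""

    def __post_init__(self):
        n = len(self.chrom)
        for name in ("start", "end", "value", "n_sites", "n_samples_effective", "mask"):
            if len(getattr(self, name)) != n:
                raise ValueError("track arrays must share length")

    def __len__(self) -> int:
        return len(self.chrom)

    def windows(self) -> list[WindowSpec]:
        return [WindowSpec(c, int(s), int(e)) for c, s, e in zip(self.chrom, self.start, self.end)]

    def same_windows(self, other: "WindowStatTrack") -> bool:
        return (
            len(self) == len(other)
            and (self.chrom == other.chrom).all()
            and (self.start == other.start).all()
            and (self.end == other.end).all()
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "value": self.value,
                "n_sites": self.n_sites,
                "n_eff": self.n_samples_effective,
                "mask": self.mask.astype(int),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, statistic: str = "") -> "WindowStatTrack":
        df = pd.read_csv(path, sep="\t")
        return cls(
            chrom=df["chrom"].to_numpy(dtype=object),
            start=df["start"].to_numpy(np.int64),
            end=df["end"].to_numpy(np.int64),
            value=df["value"].to_numpy(float),
            n_sites=df["n_sites"].to_numpy(np.int64),
            n_samples_effective=df["n_eff"].to_numpy(float),
            mask=df["mask"].to_numpy(bool),
            statistic=statistic,
        )


def site_diversity(alt_count, called_alleles):
    """Per-site nucleotide diversity 2a(n-a)/(n(n-1)).

    This is the unbiased mean pairwise difference at one biallelic site
    with ``a`` alt alleles among ``n`` called alleles. Sites with fewer
    than 2 called alleles contribute 0.
    """
    a = np.asarray(alt_count, dtype=float)
    n = np.asarray(called_alleles, dtype=float)
    if (a > n).any() or (a < 0).any():
        raise ValueError("require 0 <= alt_count <= called_alleles")
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * a * (n - a) / (n * (n - 1.0))
    return np.where(n >= 2, pi, 0.0)


def _window_slices(g: GenotypeMatrix, windows):
    """Yield (window index, site index array) using 1-based SNP positions."""
    by_chrom = {}
    for c in g.chromosomes():
        idx = np.flatnonzero(g.chrom == c)
        by_chrom[c] = (idx, g.pos[idx])
    for w_i, w in enumerate(windows):
        if w.chrom not in by_chrom:
            yield w_i, np.empty(0, dtype=np.intp)
            continue
        idx, pos = by_chrom[w.chrom]
        # window [start, end) in 0-based == positions start+1 .. end in 1-based
        lo = np.searchsorted(pos, w.start + 1, side="left")
        hi = np.searchsorted(pos, w.end, side="right")
        yield w_i, idx[lo:hi]


def _empty_track(windows, statistic):
    n = len(windows)
    return WindowStatTrack(
        chrom=np.array([w.chrom for w in windows], dtype=object),
        start=np.array([w.start for w in windows], dtype=np.int64),
        end=np.array([w.end for w in windows], dtype=np.int64),
        value=np.full(n, np.nan),
        n_sites=np.zeros(n, dtype=np.int64),
        n_samples_effective=np.zeros(n, dtype=float),
        mask=np.ones(n, dtype=bool),
        statistic=statistic,
    )


def windowed_pi(g: GenotypeMatrix, samples, windows, per_bp: bool = True) -> WindowStatTrack:
    """Windowed nucleotide diversity for a sample subset.

    Window value = sum of per-site diversity over SNPs in the window,
    divided by the window length in bp (``per_bp=True``, default) or by
    the number of contributing segregating sites.
    """
    idx = g.sample_indices(samples)
    alt, n = g.allele_counts(idx)
    pi_site = site_diversity(alt, n)
    seg = (alt > 0) & (alt < n) & (n >= 2)
    track = _empty_track(windows, "pi")
    for w_i, sites in _window_slices(g, windows):
        s = pi_site[sites].sum()
        nseg = int(seg[sites].sum())
        denom = (windows[w_i].size if per_bp else max(nseg, 1))
        track.value[w_i] = s / denom
        track.n_sites[w_i] = nseg
        track.n_samples_effective[w_i] = (n[sites].mean() / 2.0) if sites.size else 0.0
    return track


def tajima_constants(n: int):
    """Tajima (1989) normalization constants for n sampled haplotypes."""
    if n < 4:
        raise ValueError("Tajima's D requires >= 4 haplotypes")
    i = np.arange(1, n)
    a1 = (1.0 / i).sum()
    a2 = (1.0 / i**2).sum()
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, a2, b1, b2, c1, c2, e1, e2


def tajimas_d(pi_sum: float, n_seg: int, n_haplotypes: int) -> float:
    """Tajima's D from the pairwise-diversity sum and segregating-site count."""
    if n_seg == 0:
        return np.nan
    a1, _, _, _, _, _, e1, e2 = tajima_constants(n_haplotypes)
    var = e1 * n_seg + e2 * n_seg * (n_seg - 1)
    if var <= 0:
        return np.nan
    return (pi_sum - n_seg / a1) / np.sqrt(var)


def windowed_tajimas_d(g: GenotypeMatrix, samples, windows) -> WindowStatTrack:
    """Windowed Tajima's D on segregating sites with >= 4 called alleles.

    The haplotype count per window is twice the mean number of called
    diploids over used sites, rounded down (data are unphased dosages).
    Windows with no usable segregating sites or non-positive variance
    term are masked.
    """
    idx = g.sample_indices(samples)
    alt, n = g.allele_counts(idx)
    usable = (n >= 4) & (alt > 0) & (alt < n)
    pi_site = site_diversity(alt, n)
    track = _empty_track(windows, "tajimas_d")
    for w_i, sites in _window_slices(g, windows):
        sites = sites[usable[sites]]
        nseg = sites.size
        track.n_sites[w_i] = nseg
        if nseg == 0:
            track.mask[w_i] = False
            continue
        n_hap = int(np.floor(n[sites].mean()))
        track.n_samples_effective[w_i] = n_hap / 2.0
        d = tajimas_d(float(pi_site[sites].sum()), nseg, n_hap)
        track.value[w_i] = d
        if not np.isfinite(d):
            track.mask[w_i] = False
    return track


def fst_components(alt1, n1, het1, alt2, n2, het2):
    """Weir & Cockerham (1984) per-site variance components (a, b, c).

    ``alt*`` are alt-allele counts, ``n*`` called allele counts (2x
    diploids) and ``het*`` observed heterozygote counts per population.
    """
    alt1 = np.asarray(alt1, float)
    n1 = np.asarray(n1, float)
    alt2 = np.asarray(alt2, float)
    n2 = np.asarray(n2, float)
    het1 = np.asarray(het1, float)
    het2 = np.asarray(het2, float)
    r = 2.0
    # diploid sample sizes
    m1, m2 = n1 / 2.0, n2 / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        p1, p2 = alt1 / n1, alt2 / n2
        nbar = (m1 + m2) / r
        nc = (r * nbar - (m1**2 + m2**2) / (r * nbar)) / (r - 1.0)
        pbar = (m1 * p1 + m2 * p2) / (r * nbar)
        s2 = (m1 * (p1 - pbar) ** 2 + m2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        h1 = het1 / m1
        h2 = het2 / m2
        hbar = (m1 * h1 + m2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (1.0 / (nbar - 1.0)) * (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    ok = (m1 >= 1) & (m2 >= 1) & (nbar > 1) & (nc > 0)
    zero = np.zeros_like(pbar)
    return (
        np.where(ok, a, zero),
        np.where(ok, b, zero),
        np.where(ok, c, zero),
        ok,
    )


def windowed_fst(g: GenotypeMatrix, samples_a, samples_b, windows) -> WindowStatTrack:
    """Windowed Weir-Cockerham F_ST between two sample groups.

    Aggregation is ratio-of-sums: sum(a) / sum(a+b+c) over polymorphic
    sites in the window. Negative values are reported, not clamped;
    windows with zero denominator are masked.
    """
    ia = g.sample_indices(samples_a)
    ib = g.sample_indices(samples_b)
    alt1, n1 = g.allele_counts(ia)
    alt2, n2 = g.allele_counts(ib)
    het1 = (g.genotypes[ia] == 1).sum(axis=0)
    het2 = (g.genotypes[ib] == 1).sum(axis=0)
    a, b, c, ok = fst_components(alt1, n1, het1, alt2, n2, het2)
    # only sites polymorphic in the pooled pair of groups are informative
    tot_alt = alt1 + alt2
    tot_n = n1 + n2
    poly = ok & (tot_alt > 0) & (tot_alt < tot_n)
    track = _empty_track(windows, "fst")
    for w_i, sites in _window_slices(g, windows):
        sites = sites[poly[sites]]
        track.n_sites[w_i] = sites.size
        num = a[sites].sum()
        den = (a[sites] + b[sites] + c[sites]).sum()
        if sites.size == 0 or den == 0:
            track.mask[w_i] = False
            continue
        track.value[w_i] = num / den
        track.n_samples_effective[w_i] = float((n1[sites] + n2[sites]).mean() / 2.0)
    return track


def rod_track(
    pi_numerator: WindowStatTrack,
    pi_denominator: WindowStatTrack,
    min_sites: int = 3,
    epsilon: float = 1e-6,
) -> WindowStatTrack:
    """Reduction-of-diversity ratio pi_A / pi_B per window.

    Windows where the denominator diversity falls below ``epsilon`` (per
    bp), where either input window is masked, or where either group has
    fewer than ``min_sites`` segregating sites are masked: a ratio over
    vanishing diversity is unbounded and carries no rank information.
    """
    if not pi_numerator.same_windows(pi_denominator):
        raise ValueError("ROD requires identical window grids")
    n = len(pi_numerator)
    valid = (
        pi_numerator.mask
        & pi_denominator.mask
        & (pi_denominator.value >= epsilon)
        & (pi_numerator.n_sites >= min_sites)
        & (pi_denominator.n_sites >= min_sites)
    )
    value = np.full(n, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        value[valid] = pi_numerator.value[valid] / pi_denominator.value[valid]
    return WindowStatTrack(
        chrom=pi_numerator.chrom.copy(),
        start=pi_numerator.start.copy(),
        end=pi_numerator.end.copy(),
        value=value,
        n_sites=np.minimum(pi_numerator.n_sites, pi_denominator.n_sites),
        n_samples_effective=pi_denominator.n_samples_effective.copy(),
        mask=valid,
        statistic="rod",
    )


def genome_pi(g: GenotypeMatrix, samples) -> float:
    """Genome-wide pi per bp: total pairwise diversity over total genome length."""
    idx = g.sample_indices(samples)
    alt, n = g.allele_counts(idx)
    total_len = sum(g.effective_lengths().values())
    return float(site_diversity(alt, n).sum() / total_len)


def track_summary(track: WindowStatTrack) -> dict:
    """Length-weighted and plain means over unmasked windows."""
    m = track.mask & np.isfinite(track.value)
    if not m.any():
        return {"mean": np.nan, "weighted_mean": np.nan, "n_windows": 0}
    lengths = (track.end - track.start)[m].astype(float)
    v = track.value[m]
    return {
        "mean": float(v.mean()),
        "weighted_mean": float((v * lengths).sum() / lengths.sum()),
        "n_windows": int(m.sum()),
    }
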