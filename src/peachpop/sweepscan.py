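"""Selective-sweep calling from ROD tracks, composite-likelihood-ratio
confirmation scans, and sweep/QTL interval arithmetic.

Sweep calling follows the top-quantile rule: windows whose ROD value
strictly exceeds the empirical 95th percentile (``q=0.05``) of unmasked
windows are selected and merged into maximal regions. The CLR scan
contrasts a sweep model against the genome-wide background site
frequency spectrum on a grid of positions, in the SweepFinder/SweeD
lineage: a site at distance d from the swept position escapes the sweep
with probability 1 - exp(-alpha*d); escaped sites draw their folded
frequency class from the background spectrum, non-escaped sites are
driven into the extreme (folded singleton) class. alpha is maximised
per grid point over a log-spaced grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import WindowStatTrack
from .genio import GenotypeMatrix, Interval


@dataclass
class SweepRegion:
    """A called sweep: merged run of above-threshold windows."""

    chrom: str
    start: int
    end: int
    peak_value: float
    mean_value: float
    n_windows: int
    source: str = "."

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("sweep region end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    def as_interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end,
                        name=f"{self.source}_{self.chrom}_{self.start}", category=self.source)


@dataclass
class CLRTrack:
    """Composite likelihood ratios on a position grid along one region."""

    chrom: str
    positions: np.ndarray
    clr: np.ndarray
    alpha_hat: np.ndarray

    def argmax_position(self) -> int:
        return int(self.positions[int(np.argmax(self.clr))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos": self.positions, "clr": self.clr,
             "alpha": self.alpha_hat}
        )


@dataclass
class OverlapReport:
    """Per-interval overlap of (QTL/gene) intervals with called sweeps."""

    rows: pd.DataFrame            # interval name, chrom, start, end, n_sweeps, overlap_bp
    n_intervals: int
    n_intervals_hit: int
    total_overlap_bp: int
    sweep_span_bp: int

    @property
    def fraction_sweep_span_overlapped(self) -> float:
        return self.total_overlap_bp / self.sweep_span_bp if self.sweep_span_bp else 0.0


def top_quantile_threshold(track: WindowStatTrack, q: float = 0.05):
    """Threshold for the "top q" windows of an ROD track.

    Returns ``(threshold, n_above)`` where threshold is the empirical
    (1-q) quantile (type-7 linear interpolation) over unmasked window
    values and ``n_above`` counts windows strictly above it.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    values = track.value[track.mask & np.isfinite(track.value)]
    if values.size < 20:
        raise ValueError(f"need >= 20 unmasked windows, got {values.size}")
    threshold = float(np.quantile(values, 1.0 - q))
    return threshold, int((values > threshold).sum())


def call_sweeps(track: WindowStatTrack, threshold: float, source: str = ".") -> list[SweepRegion]:
    """Merge windows with value strictly above ``threshold`` into sweep regions.

    Overlapping or book-ended selected windows on the same chromosome
    merge into maximal regions; masked windows are never selected.
    """
    sel = track.mask & np.isfinite(track.value) & (track.value > threshold)
    regions: list[SweepRegion] = []
    order = np.lexsort((track.start, np.asarray(track.chrom, dtype=str)))
    cur = None
    for i in order:
        if not sel[i]:
            continue
        c, s, e, v = track.chrom[i], int(track.start[i]), int(track.end[i]), float(track.value[i])
        if cur is not None and c == cur["chrom"] and s <= cur["end"]:
            cur["end"] = max(cur["end"], e)
            cur["values"].append(v)
        else:
            if cur is not None:
                regions.append(_finish_region(cur, source))
            cur = {"chrom": c, "start": s, "end": e, "values": [v]}
    if cur is not None:
        regions.append(_finish_region(cur, source))
    return regions


def _finish_region(cur, source) -> SweepRegion:
    vals = cur["values"]
    return SweepRegion(
        chrom=cur["chrom"], start=cur["start"], end=cur["end"],
        peak_value=max(vals), mean_value=float(np.mean(vals)),
        n_windows=len(vals), source=source,
    )


def folded_sfs(g: GenotypeMatrix, sample_idx=None, n_min_call_fraction: float = 1.0):
    """Genome-wide folded site-frequency spectrum of fully-called sites.

    Returns ``(n_alleles, probs)`` where probs[j] is the probability of
    folded minor count j (j = 1 .. n//2), smoothed with a 0.5
    pseudo-count per class.
    """
    alt, n = g.allele_counts(sample_idx)
    n_full = int(n.max()) if n.size else 0
    if n_full < 4:
        raise ValueError("need >= 4 called alleles for an SFS")
    use = n >= int(np.ceil(n_min_call_fraction * n_full))
    a = alt[use]
    folded = np.minimum(a, n[use] - a)
    folded = folded[(folded > 0)]
    counts = np.bincount(folded, minlength=n_full // 2 + 1)[1 : n_full // 2 + 1]
    probs = (counts + 0.5) / (counts + 0.5).sum()
    return n_full, probs


def clr_scan(
    g: GenotypeMatrix,
    samples,
    region: tuple[str, int, int],
    grid_n: int = 2000,
    alpha_grid: np.ndarray | None = None,
    background: tuple[int, np.ndarray] | None = None,
) -> CLRTrack:
    """Composite likelihood ratio scan over ``region`` (chrom, start0, end0).

    The background folded SFS is estimated from the whole dataset for
    the same samples unless supplied. At each of ``grid_n`` grid
    positions x the sweep log-likelihood sums, over polymorphic sites i
    at distance d_i with folded class j_i,
    ln[ p_e p_bg(j_i) + (1-p_e) p_sweep(j_i) ], with escape probability
    p_e = 1 - exp(-alpha d_i); the CLR at x is the maximum over alpha of
    the log-likelihood gain over the background model (never negative:
    alpha -> infinity recovers the background).
    """
    chrom, start, end = region
    if end <= start:
        raise ValueError("empty region")
    idx = g.sample_indices(samples)
    if background is None:
        background = folded_sfs(g, idx)
    n_full, p_bg = background
    k_max = n_full // 2

    in_reg = (g.chrom == chrom) & (g.pos - 1 >= start) & (g.pos - 1 < end)
    alt, n = g.allele_counts(idx)
    full = (n == n_full) & (alt > 0) & (alt < n)
    usable = in_reg & full
    n_sites = int(usable.sum())
    if n_sites < 10:
        raise ValueError(f"need >= 10 fully-called segregating sites in region, got {n_sites}")
    folded = np.minimum(alt[usable], n_full - alt[usable])
    pos = (g.pos[usable] - 1).astype(float)

    if (folded == 1).sum() == 0:
        warnings.warn("no singletons in region: degenerate SFS for the sweep class")

    # sweep class: all mass on the folded singleton class, lightly smoothed
    p_sw = np.full(k_max, 1e-4)
    p_sw[0] = 1.0
    p_sw /= p_sw.sum()

    # genome-wide density of observable (fully-called polymorphic) sites:
    # sites are modelled as a marked Poisson process so that the scan can
    # use the absence of polymorphism inside a swept core as evidence
    lambda0 = full.sum() / sum(g.effective_lengths().values())
    w_keep = 0.1  # visible fraction of non-escaped sites (extreme class)

    if alpha_grid is None:
        alpha_grid = np.geomspace(1e-6, 1.0, 25)

    if grid_n == 1:
        grid = np.array([(start + end) / 2.0])
    else:
        step = (end - start) / grid_n
        grid = start + step * (np.arange(grid_n) + 0.5)

    clr = np.zeros(grid.size)
    alpha_hat = np.zeros(grid.size)
    pb = p_bg[folded - 1]
    ps = p_sw[folded - 1]
    span = end - start
    for gi, x in enumerate(grid):
        d = np.abs(pos - x)
        pe = 1.0 - np.exp(-np.outer(d, alpha_grid))          # sites x alphas
        marks = np.log(pe * pb[:, None] + (1.0 - pe) * (w_keep * ps)[:, None]).sum(axis=0)
        # expected deficit of sites: integral of (1 - survival) over the region
        with np.errstate(over="ignore"):
            int_exp = (
                2.0 - np.exp(-alpha_grid * (x - start)) - np.exp(-alpha_grid * (end - x))
            ) / alpha_grid
        int_survival = (span - int_exp) + w_keep * int_exp   # integral of pe + w_keep (1-pe)
        ll = marks - lambda0 * int_survival
        ll_bg = np.log(pb).sum() - lambda0 * span
        best = int(np.argmax(ll))
        clr[gi] = max(0.0, ll[best] - ll_bg)
        alpha_hat[gi] = alpha_grid[best]
    return CLRTrack(chrom=chrom, positions=grid.astype(np.int64), clr=clr, alpha_hat=alpha_hat)


def _merge_intervals(ivs):
    """Merge (start, end) pairs per chromosome into disjoint sorted runs."""
    by_chrom: dict[str, list[list[int]]] = {}
    for c, s, e in ivs:
        by_chrom.setdefault(c, []).append([s, e])
    merged: dict[str, list[tuple[int, int]]] = {}
    for c, lst in by_chrom.items():
        lst.sort()
        out = [lst[0][:]]
        for s, e in lst[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[c] = [(s, e) for s, e in out]
    return merged


def _overlap_bp(merged_a: dict, merged_b: dict) -> int:
    total = 0
    for c in merged_a:
        if c not in merged_b:
            continue
        a, b = merged_a[c], merged_b[c]
        i = j = 0
        while i < len(a) and j < len(b):
            lo = max(a[i][0], b[j][0])
            hi = min(a[i][1], b[j][1])
            if hi > lo:
                total += hi - lo
            if a[i][1] < b[j][1]:
                i += 1
            else:
                j += 1
    return total


def _span(merged: dict) -> int:
    return sum(e - s for ivs in merged.values() for s, e in ivs)


def annotate_sweeps(sweeps, intervals, min_overlap_bp: int = 1) -> OverlapReport:
    """Overlap (QTL/gene) intervals with called sweeps.

    An interval counts as hit when its total overlap with the merged
    sweep span is at least ``min_overlap_bp`` (default 1 bp); an
    interval spanning several sweeps is counted once with its overlap
    summed.
    """
    sweep_merged = _merge_intervals([(s.chrom, s.start, s.end) for s in sweeps]) if sweeps else {}
    rows = []
    total_overlap = 0
    for iv in intervals:
        mine = {iv.chrom: [(iv.start, iv.end)]}
        ob = _overlap_bp(mine, sweep_merged)
        n_sw = sum(
            1 for s in sweeps
            if s.chrom == iv.chrom and s.start < iv.end and s.end > iv.start
        )
        rows.append((iv.name, iv.chrom, iv.start, iv.end, n_sw, ob, ob >= min_overlap_bp))
        total_overlap += ob
    df = pd.DataFrame(
        rows, columns=["name", "chrom", "start", "end", "n_sweeps", "overlap_bp", "hit"]
    )
    return OverlapReport(
        rows=df,
        n_intervals=len(intervals),
        n_intervals_hit=int(df["hit"].sum()) if len(df) else 0,
        total_overlap_bp=int(total_overlap),
        sweep_span_bp=_span(sweep_merged),
    )


def sweep_set_overlap(sweeps_a, sweeps_b) -> dict:
    """Interval-arithmetic comparison of two sweep sets.

    Returns spans, shared bp, union bp (= span_a + span_b - shared), and
    the fraction of set A's span that is shared. Inputs are merged
    first, so overlapping regions within a set are not double counted.
    """
    def as_tuples(sweeps):
        out = []
        for s in sweeps:
            if isinstance(s, (SweepRegion, Interval)):
                out.append((s.chrom, s.start, s.end))
            else:
                out.append(tuple(s))
        return out

    ma = _merge_intervals(as_tuples(sweeps_a)) if sweeps_a else {}
    mb = _merge_intervals(as_tuples(sweeps_b)) if sweeps_b else {}
    span_a, span_b = _span(ma), _span(mb)
    shared = _overlap_bp(ma, mb)
    return {
        "span_a_bp": span_a,
        "span_b_bp": span_b,
        "shared_bp": shared,
        "union_bp": span_a + span_b - shared,
        "fraction_a_shared": shared / span_a if span_a else 0.0,
    }


def sweeps_to_frame(sweeps) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom, "start": s.start, "end": s.end,
                "peak": s.peak_value, "mean": s.mean_value,
                "n_windows": s.n_windows, "source": s.source,
            }
            for s in sweeps
        ]
    )
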