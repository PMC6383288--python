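"""Linkage-disequilibrium decay from unphased genotypes.

r^2 between site pairs is computed from EM-estimated haplotype
frequencies over the 3x3 genotype table (the double-heterozygote cell
is the only phase-ambiguous one); squared dosage correlation is the
documented fallback when EM does not converge. Pairwise r^2 values are
binned by physical distance into a decay curve; the half-decay distance
is read off the isotonically smoothed curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, filter_by_maf

EM_TOL = 1e-8
EM_MAX_ITER = 1000


@dataclass
class LDDecayCurve:
    """Mean r^2 per physical-distance bin."""

    bin_start: np.ndarray
    bin_end: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    max_dist: int

    def populated(self) -> np.ndarray:
        return self.n_pairs > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_bp": self.bin_start,
                "bin_end_bp": self.bin_end,
                "mean_r2": self.mean_r2,
                "n_pairs": self.n_pairs,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _em_r2_batch(n00, n01, n02, n10, n11, n12, n20, n21, n22):
    """Vectorised EM for haplotype frequencies over many 3x3 tables.

    Cell n_ab counts individuals with dosage a at site 1 and b at site
    2 (dosage = copies of the alt allele). Returns (r2, converged).
    """
    counts = [np.asarray(c, dtype=float) for c in
              (n00, n01, n02, n10, n11, n12, n20, n21, n22)]
    n00, n01, n02, n10, n11, n12, n20, n21, n22 = counts
    n_ind = sum(counts)
    two_n = 2.0 * n_ind
    pA = (2 * (n20 + n21 + n22) + (n10 + n11 + n12)) / two_n  # alt freq site 1
    pB = (2 * (n02 + n12 + n22) + (n01 + n11 + n21)) / two_n
    # haplotype counts certain from all cells except the double het:
    # hap AB (alt-alt), Ab, aB, ab
    c_ab = 2 * n22 + n21 + n12          # AB
    c_aB = 2 * n20 + n21 + n10          # Ab (alt at 1, ref at 2)
    c_rb = 2 * n02 + n01 + n12          # aB
    c_rr = 2 * n00 + n01 + n10          # ab
    f = np.stack([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    f = np.clip(f, 1e-12, None)
    converged = np.zeros(n_ind.shape, dtype=bool)
    for _ in range(EM_MAX_ITER):
        # P(double het is AB/ab) vs (Ab/aB)
        coupling = f[0] * f[3]
        repulsion = f[1] * f[2]
        h = coupling / np.clip(coupling + repulsion, 1e-300, None)
        new = np.stack([
            (c_ab + n11 * h),
            (c_aB + n11 * (1 - h)),
            (c_rb + n11 * (1 - h)),
            (c_rr + n11 * h),
        ]) / two_n
        delta = np.abs(new - f).max(axis=0)
        f = np.clip(new, 1e-12, None)
        newly = delta < EM_TOL
        converged |= newly
        if converged.all():
            break
    fAB = f[0]
    d = fAB - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, d * d / denom, np.nan)
    return np.clip(r2, 0.0, 1.0), converged


def _dosage_r2(ga, gb):
    """Squared Pearson correlation of dosages (fallback when EM fails)."""
    ok = (ga >= 0) & (gb >= 0)
    if ok.sum() < 2:
        return np.nan
    a, b = ga[ok].astype(float), gb[ok].astype(float)
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def genotype_r2(site_i, site_j, min_samples: int = 20) -> float:
    """EM haplotype-frequency r^2 between two dosage vectors.

    Samples missing either genotype are excluded pairwise; returns NaN
    when either site is monomorphic after pairwise deletion.
    """
    ga = np.asarray(site_i, dtype=np.int8)
    gb = np.asarray(site_j, dtype=np.int8)
    ok = (ga >= 0) & (gb >= 0)
    if ok.sum() < min_samples:
        raise ValueError(f"need >= {min_samples} samples called at both sites")
    ga, gb = ga[ok], gb[ok]
    if len(set(ga.tolist())) < 2 or len(set(gb.tolist())) < 2:
        return np.nan
    cells = [( (ga == a) & (gb == b) ).sum() for a in (0, 1, 2) for b in (0, 1, 2)]
    r2, conv = _em_r2_batch(*[np.array([c]) for c in cells])
    if not conv[0]:
        return _dosage_r2(ga, gb)
    return float(r2[0])


def _pair_tables(G, idx_a, idx_b):
    """3x3 genotype tables for site pairs (columns idx_a vs idx_b of G)."""
    ga = G[:, idx_a].T  # pairs x samples
    gb = G[:, idx_b].T
    valid = (ga >= 0) & (gb >= 0)
    code = np.where(valid, ga * 3 + gb, 9)
    cells = [(code == k).sum(axis=1) for k in range(9)]
    return cells


def ld_decay_curve(
    g: GenotypeMatrix,
    samples,
    max_dist: int = 200_000,
    min_maf: float = 0.05,
    bin_bp: int = 1_000,
    pair_budget: int = 2_000_000,
    seed: int = 0,
    chunk: int = 20_000,
) -> LDDecayCurve:
    """Binned LD-decay curve for one sample group.

    All intra-chromosomal pairs within ``max_dist`` are evaluated, or a
    seeded uniform subsample of ``pair_budget`` pairs when there are
    more. Sites are MAF-filtered within the group first.
    """
    sub = filter_by_maf(g.take_samples(list(samples)), min_maf)
    G = sub.genotypes
    pairs_i, pairs_j, dists = [], [], []
    for c in sub.chromosomes():
        idx = np.flatnonzero(sub.chrom == c)
        pos = sub.pos[idx]
        for k in range(idx.size):
            hi = np.searchsorted(pos, pos[k] + max_dist, side="right")
            js = np.arange(k + 1, hi)
            if js.size:
                pairs_i.append(np.full(js.size, idx[k]))
                pairs_j.append(idx[js])
                dists.append(pos[js] - pos[k])
    if not pairs_i:
        warnings.warn("no qualifying site pairs for LD curve")
        edges = np.arange(0, max_dist + bin_bp, bin_bp)
        nb = len(edges) - 1
        return LDDecayCurve(edges[:-1], edges[1:], np.full(nb, np.nan),
                            np.zeros(nb, dtype=int), max_dist)
    pi = np.concatenate(pairs_i)
    pj = np.concatenate(pairs_j)
    dd = np.concatenate(dists)
    if pi.size > pair_budget:
        rng = np.random.default_rng(seed)
        keep = rng.choice(pi.size, size=pair_budget, replace=False)
        pi, pj, dd = pi[keep], pj[keep], dd[keep]

    nb = int(np.ceil(max_dist / bin_bp))
    sums = np.zeros(nb)
    counts = np.zeros(nb, dtype=np.int64)
    for lo in range(0, pi.size, chunk):
        sl = slice(lo, lo + chunk)
        cells = _pair_tables(G, pi[sl], pj[sl])
        r2, conv = _em_r2_batch(*cells)
        # EM non-convergence fallback: dosage correlation, site by site
        bad = np.flatnonzero(~conv & np.isfinite(r2))
        for b in bad:
            r2[b] = _dosage_r2(G[:, pi[sl][b]], G[:, pj[sl][b]])
        ok = np.isfinite(r2)
        bins = np.minimum((dd[sl][ok] - 1) // bin_bp, nb - 1).astype(int)
        np.add.at(sums, bins, r2[ok])
        np.add.at(counts, bins, 1)
    edges = np.arange(0, (nb + 1) * bin_bp, bin_bp)
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LDDecayCurve(edges[:-1], edges[1:], mean_r2, counts, max_dist)


def _pava_nonincreasing(y, w):
    """Pool-adjacent-violators: weighted least-squares non-increasing fit."""
    blocks = [[y[i], w[i], 1] for i in range(len(y))]  # value, weight, size
    out = []
    for b in blocks:
        out.append(b)
        while len(out) > 1 and out[-2][0] < out[-1][0]:
            v2, w2, s2 = out.pop()
            v1, w1, s1 = out.pop()
            wt = w1 + w2
            out.append([(v1 * w1 + v2 * w2) / wt, wt, s1 + s2])
    fitted = np.empty(len(y))
    k = 0
    for v, _, s in out:
        fitted[k : k + s] = v
        k += s
    return fitted


def half_decay_distance(curve: LDDecayCurve) -> dict:
    """Distance at which smoothed mean r^2 first falls to half its maximum.

    The curve is smoothed with a non-increasing isotonic fit (weighted
    by pair counts); the crossing is linearly interpolated between the
    flanking bin positions (bin starts). Returns a dict with keys
    ``distance_bp``, ``reached`` and ``half_level``.
    """
    pop = curve.populated() & np.isfinite(curve.mean_r2)
    if pop.sum() < 3:
        raise ValueError("need >= 3 populated bins")
    x = curve.bin_start[pop].astype(float)
    y = curve.mean_r2[pop]
    w = curve.n_pairs[pop].astype(float)
    smooth = _pava_nonincreasing(y, w)
    top = float(smooth.max())
    half = top / 2.0
    if top == 0 or (smooth > half).all():
        return {"distance_bp": int(curve.max_dist), "reached": False, "half_level": half}
    below = np.flatnonzero(smooth <= half)
    k = below[0]
    if k == 0 or smooth[k] == half:
        return {"distance_bp": int(x[k]), "reached": True, "half_level": half}
    x0, x1 = x[k - 1], x[k]
    y0, y1 = smooth[k - 1], smooth[k]
    frac = (y0 - half) / (y0 - y1) if y0 != y1 else 0.0
    return {"distance_bp": int(round(x0 + frac * (x1 - x0))), "reached": True, "half_level": half}
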