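"""Mixed-linear-model GWAS in the EMMAX style.

The phenotype model is y = X b + u + e with u ~ N(0, sigma_g^2 K) for an
IBS kinship matrix K and e ~ N(0, sigma_e^2 I). Variance components are
estimated once by REML on the null model (no SNP) via the spectral
decomposition of K; every SNP is then tested by generalized least
squares with the covariance fixed from the null fit — the approximation
the EMMAX program introduced. Missing genotypes are mean-imputed per
SNP for testing only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genio import GenotypeMatrix


@dataclass
class KinshipMatrix:
    values: np.ndarray
    samples: list[str]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.samples):
            raise ValueError("kinship must be square over the sample list")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")
        self.values = v


@dataclass
class MLMFit:
    sigma_g2: float
    sigma_e2: float
    loglik: float
    delta_identifiable: bool = True

    @property
    def delta(self) -> float:
        """Variance ratio sigma_e^2 / sigma_g^2."""
        return self.sigma_e2 / self.sigma_g2 if self.sigma_g2 > 0 else np.inf

    @property
    def heritability(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else np.nan


@dataclass
class AssociationResult:
    table: pd.DataFrame  # chrom pos ref alt maf beta se stat p
    n_snps: int
    alpha: float
    p_threshold: float
    maf_filter: float | None = None

    @property
    def neglog10_threshold(self) -> float:
        return -np.log10(self.p_threshold)


def kinship_matrix(g: GenotypeMatrix, samples=None) -> KinshipMatrix:
    """Mean IBS similarity: K_ij = mean over SNPs of 1 - |g_i - g_j| / 2,
    pairwise-complete over SNPs called in both samples."""
    ids = list(samples) if samples is not None else list(g.samples)
    idx = g.sample_indices(ids)
    G = g.genotypes[idx]
    if G.shape[0] < 2 or G.shape[1] < 1:
        raise ValueError("need >= 2 samples and >= 1 SNP")
    valid = (G >= 0)
    # sum |gi - gj| over shared SNPs via dosage-class indicator products
    A = [(valid & (G == c)).astype(np.float64) for c in (0, 1, 2)]
    n_shared = valid.astype(np.float64) @ valid.T.astype(np.float64)
    if (n_shared == 0).any():
        raise ValueError("some sample pair shares no called SNPs")
    absdiff = np.zeros_like(n_shared)
    for a in range(3):
        for b in range(3):
            if a != b:
                absdiff += abs(a - b) * (A[a] @ A[b].T)
    K = 1.0 - absdiff / (2.0 * n_shared)
    K = (K + K.T) / 2.0
    return KinshipMatrix(values=K, samples=ids)


def _reml_loglik(log_delta, lam, yt, xt):
    """Restricted log-likelihood of delta = sigma_e^2/sigma_g^2 (profiled)."""
    delta = np.exp(log_delta)
    d = lam + delta
    w = 1.0 / d
    xtw = xt * w[:, None]
    xx = xt.T @ xtw
    beta = np.linalg.solve(xx, xtw.T @ yt)
    r = yt - xt @ beta
    n, p = xt.shape
    rss = float(r @ (w * r))
    sig = rss / (n - p)
    _, logdet_xx = np.linalg.slogdet(xx)
    ll = -0.5 * (
        (n - p) * (np.log(2 * np.pi * sig) + 1.0)
        + np.log(d).sum()
        + logdet_xx
    )
    return ll, sig, delta


def fit_null_model(y, kinship: KinshipMatrix, covariates=None, ridge: float = 1e-6) -> MLMFit:
    """REML variance components for the null mixed model (intercept plus
    optional covariates), via eigendecomposition of K and a 1-D search
    over delta.

    With K proportional to the identity the likelihood is flat in delta
    (sigma_g and sigma_e are jointly unidentifiable); the fit is flagged
    through ``delta_identifiable=False``.
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise ValueError("phenotype contains non-finite values")
    n = y.size
    K = kinship.values
    if K.shape[0] != n:
        raise ValueError("phenotype length must match kinship dimension")
    X = np.ones((n, 1))
    if covariates is not None:
        X = np.column_stack([X, np.asarray(covariates, dtype=float)])
    lam, U = np.linalg.eigh(K + ridge * np.eye(n))
    lam = np.maximum(lam, 0.0)
    yt, xt = U.T @ y, U.T @ X

    grid = np.linspace(-10.0, 10.0, 41)
    lls = np.array([_reml_loglik(g, lam, yt, xt)[0] for g in grid])
    flat = lls.max() - lls.min() < 1e-6
    best = grid[int(np.argmax(lls))]
    res = optimize.minimize_scalar(
        lambda g: -_reml_loglik(g, lam, yt, xt)[0],
        bounds=(best - 1.0, best + 1.0),
        method="bounded",
    )
    ll, sig_g, delta = _reml_loglik(res.x, lam, yt, xt)
    return MLMFit(
        sigma_g2=float(sig_g),
        sigma_e2=float(sig_g * delta),
        loglik=float(ll),
        delta_identifiable=not flat,
    )


def scan_snps(
    g: GenotypeMatrix,
    y,
    nullfit: MLMFit,
    kinship: KinshipMatrix,
    alpha: float = 0.05,
    ridge: float = 1e-6,
) -> AssociationResult:
    """Per-SNP generalized least squares with covariance fixed from the
    null REML fit; Wald t test per SNP, Bonferroni threshold alpha/n."""
    ids = kinship.samples
    idx = g.sample_indices(ids)
    y = np.asarray(y, dtype=float)
    n = len(ids)
    if y.size != n:
        raise ValueError("phenotype length must match kinship samples")
    lam, U = np.linalg.eigh(kinship.values + ridge * np.eye(n))
    lam = np.maximum(lam, 0.0)
    w = 1.0 / (lam + nullfit.delta if np.isfinite(nullfit.delta) else lam + 1.0)
    if not np.isfinite(nullfit.delta):
        # pure-noise null fit: covariance reduces to a multiple of K + I
        w = 1.0 / (lam + 1.0)

    G = g.genotypes[idx].astype(float)
    G[G < 0] = np.nan
    col_mean = np.nanmean(G, axis=0)
    mono = np.nanstd(G, axis=0) == 0
    if mono.any():
        warnings.warn(f"{int(mono.sum())} monomorphic SNPs tested; p set to 1")
    G = np.where(np.isnan(G), col_mean, G)

    yt = U.T @ y
    ones_t = U.T @ np.ones(n)
    Gt = U.T @ G

    # weighted regression of yt on [1, g] with weights w, vectorised per SNP
    s00 = float(ones_t @ (w * ones_t))
    s0y = float(ones_t @ (w * yt))
    syy = float(yt @ (w * yt))
    s0g = Gt.T @ (w * ones_t)
    sgy = Gt.T @ (w * yt)
    sgg = np.einsum("ij,i,ij->j", Gt, w, Gt)

    det = s00 * sgg - s0g**2
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (s00 * sgy - s0g * s0y) / det
        rss = syy - (s0y * (sgg * s0y - s0g * sgy) + sgy * (s00 * sgy - s0g * s0y)) / det
        dof = n - 2
        sigma2 = rss / dof
        se = np.sqrt(sigma2 * s00 / det)
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=dof)
    p = np.where(mono | ~np.isfinite(tstat), 1.0, p)
    beta = np.where(mono, 0.0, beta)

    alt, ncall = g.allele_counts(idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = alt / np.maximum(ncall, 1)
    maf = np.minimum(af, 1 - af)
    table = pd.DataFrame(
        {
            "chrom": g.chrom,
            "pos": g.pos,
            "ref": g.ref,
            "alt": g.alt,
            "maf": maf,
            "beta": beta,
            "se": se,
            "stat": tstat,
            "p": np.clip(p, np.nextafter(0, 1), 1.0),
        }
    )
    p_thr, _ = bonferroni_threshold(g.n_sites, alpha)
    return AssociationResult(table=table, n_snps=g.n_sites, alpha=alpha, p_threshold=p_thr)


def bonferroni_threshold(n_snps: int, alpha: float = 0.05):
    """Genome-wide threshold alpha / n_snps; returns (p, -log10 p)."""
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    p = alpha / n_snps
    return p, -np.log10(p)


def call_peaks(assoc: AssociationResult, p_threshold: float | None = None,
               merge_dist: int = 100_000) -> list[dict]:
    """Cluster significant SNPs within ``merge_dist`` on a chromosome into
    association peaks; the lead SNP is the minimum-p member."""
    thr = assoc.p_threshold if p_threshold is None else p_threshold
    sig = assoc.table[assoc.table["p"] < thr].sort_values(["chrom", "pos"])
    peaks: list[dict] = []
    cur = None
    for _, row in sig.iterrows():
        if cur is not None and row["chrom"] == cur["chrom"] and row["pos"] - cur["end"] <= merge_dist:
            cur["end"] = int(row["pos"])
            cur["n_snps"] += 1
            if row["p"] < cur["lead_p"]:
                cur["lead_p"] = float(row["p"])
                cur["lead_pos"] = int(row["pos"])
        else:
            if cur is not None:
                peaks.append(cur)
            cur = {
                "chrom": row["chrom"], "start": int(row["pos"]), "end": int(row["pos"]),
                "lead_pos": int(row["pos"]), "lead_p": float(row["p"]), "n_snps": 1,
            }
    if cur is not None:
        peaks.append(cur)
    return peaks


def genomic_inflation(p_values) -> float:
    """Genomic inflation factor lambda: median chi-square over its null median."""
    p = np.asarray(p_values, dtype=float)
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
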