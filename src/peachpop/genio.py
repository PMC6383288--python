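"""Genotype and interval I/O: VCF ingestion, MAF filtering, sliding windows, BED intervals.

Coordinate conventions: VCF positions are 1-based (kept as-is in
:class:`GenotypeMatrix.pos`); windows and intervals are 0-based half-open,
as in BED. Genotypes are diploid alt-allele dosages in {0, 1, 2} with
``-1`` for missing; missing calls are never imputed here — each downstream
statistic defines its own missing-data handling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

GROUP_WILD = "wild"
GROUP_LANDRACE = "landrace"
GROUP_IMPROVED_EASTERN = "improved_eastern"
GROUP_IMPROVED_WESTERN = "improved_western"


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes for a cohort, samples x sites.

    Attributes
    ----------
    genotypes : int8 array, shape (n_samples, n_sites)
        Alt-allele dosage 0/1/2, ``-1`` for missing.
    chrom, pos, ref, alt : per-site metadata; ``pos`` is 1-based (VCF).
    samples : ordered sample identifiers.
    chrom_lengths : optional declared chromosome lengths (bp); windowed
        statistics fall back to the last SNP position when absent.
    """

    genotypes: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    samples: list[str]
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.samples = list(self.samples)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples x sites)")
        if self.genotypes.shape != (len(self.samples), len(self.pos)):
            raise ValueError("genotype matrix shape does not match metadata")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes restricted to {0,1,2,-1}")
        for c in self.chromosomes():
            p = self.pos[self.chrom == c]
            if p.size > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def sample_indices(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in ids], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in matrix") from None

    def take_samples(self, ids) -> "GenotypeMatrix":
        idx = self.sample_indices(ids)
        return replace(self, genotypes=self.genotypes[idx], samples=list(ids))

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self,
            genotypes=self.genotypes[:, idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
        )

    def allele_counts(self, sample_idx=None):
        """Per-site (alt allele count, called allele count) over a sample subset."""
        g = self.genotypes if sample_idx is None else self.genotypes[sample_idx]
        called = g >= 0
        alt = np.where(called, g, 0).sum(axis=0)
        n = 2 * called.sum(axis=0)
        return alt.astype(np.int64), n.astype(np.int64)

    def effective_lengths(self) -> dict[str, int]:
        """Declared chromosome lengths, or last SNP position as fallback."""
        if self.chrom_lengths:
            return dict(self.chrom_lengths)
        return {c: int(self.pos[self.chrom == c].max()) for c in self.chromosomes()}


@dataclass
class PopulationMap:
    """sample id -> group label (wild / landrace / improved_* / custom)."""

    assignments: dict[str, str]

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, g in self.assignments.items():
            out.setdefault(g, []).append(s)
        return out

    def samples_in(self, *group_labels: str) -> list[str]:
        members = self.groups()
        out: list[str] = []
        for g in group_labels:
            if g not in members:
                raise KeyError(f"group {g!r} not present in population map")
            out.extend(members[g])
        return out

    def validate_against(self, g: GenotypeMatrix) -> None:
        known = set(g.samples)
        missing = [s for s in self.assignments if s not in known]
        if missing:
            raise ValueError(f"{len(missing)} mapped samples absent from matrix: {missing[:5]}")

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"sample": list(self.assignments), "group": list(self.assignments.values())}
        ).to_csv(path, sep="\t", index=False, header=False)

    @classmethod
    def from_tsv(cls, path) -> "PopulationMap":
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
        return cls(dict(zip(df["sample"], df["group"])))


@dataclass(frozen=True)
class WindowSpec:
    """One sliding window, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("window end must exceed start")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Interval:
    """Named genomic interval (QTL / gene / sweep), 0-based half-open."""

    chrom: str
    start: int
    end: int
    name: str = "."
    category: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"interval start >= end: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start


def make_windows(chrom_lengths: dict[str, int], size: int = 100_000, step: int = 10_000):
    """Tile chromosomes with sliding windows (default 100 kb / 10 kb).

    A window is emitted iff its start lies within the chromosome; the last
    window is truncated at the chromosome end.
    """
    if step <= 0 or size < step:
        raise ValueError("require size >= step > 0")
    windows: list[WindowSpec] = []
    for chrom, length in chrom_lengths.items():
        length = int(length)
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}")
        for start in range(0, length, step):
            windows.append(WindowSpec(chrom, start, min(start + size, length)))
    return windows


def read_vcf(path, region: tuple[str, int, int] | None = None, biallelic_only: bool = True,
             chrom_lengths: dict[str, int] | None = None) -> GenotypeMatrix:
    """Read GT fields of a VCF(.gz) into a :class:`GenotypeMatrix`.

    Multiallelic and non-SNP records are dropped (count reported via a
    warning); missing genotypes are preserved. ``region`` is an optional
    (chrom, start0, end0) half-open filter.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    if not vcf.samples:
        raise ValueError(f"{path}: VCF has no samples")
    chroms, poss, refs, alts, rows = [], [], [], [], []
    n_dropped = 0
    for v in vcf:
        if region is not None:
            c, s0, e0 = region
            if v.CHROM != c or not (s0 < v.POS <= e0):
                continue
        if biallelic_only and (len(v.ALT) != 1 or not v.is_snp):
            n_dropped += 1
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=missing
        gt = v.gt_types.astype(np.int8)
        gt[gt == 3] = MISSING
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0] if v.ALT else ".")
        rows.append(gt)
    if n_dropped:
        warnings.warn(f"{path}: dropped {n_dropped} multiallelic/non-SNP records")
    geno = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.empty((len(vcf.samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        genotypes=geno,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        samples=list(vcf.samples),
        chrom_lengths=chrom_lengths,
    )


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal standards-conformant VCF v4.2 with GT only."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=peachpop\n')
        if g.chrom_lengths:
            for c, ln in g.chrom_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.samples) + "\n")
        for j in range(g.n_sites):
            cells = "\t".join(gt_strings[int(x)] for x in g.genotypes[:, j])
            fh.write(
                f"{g.chrom[j]}\t{g.pos[j]}\t.\t{g.ref[j]}\t{g.alt[j]}\t.\tPASS\t.\tGT\t{cells}\n"
            )


def minor_allele_frequency(g: GenotypeMatrix, sample_idx=None) -> np.ndarray:
    """Per-site minor-allele frequency among non-missing alleles (NaN if no calls)."""
    alt, n = g.allele_counts(sample_idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    return np.minimum(p, 1.0 - p)


def filter_by_maf(g: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Retain sites with minor-allele frequency >= ``min_maf`` (boundary kept).

    Mirrors the removal rule "MAF < cutoff" of the source analyses.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    maf = minor_allele_frequency(g)
    keep = np.nan_to_num(maf, nan=-1.0) >= min_maf - 1e-12
    if not keep.any():
        warnings.warn("MAF filter removed every site")
    return g.take_sites(keep)


def read_intervals(path, format: str = "bed"):
    """Read BED3/BED4 (or 4-column TSV) into sorted 0-based half-open Intervals."""
    if format not in ("bed", "tsv"):
        raise ValueError(f"unsupported interval format {format!r}")
    path = Path(path)
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            name = parts[3] if len(parts) > 3 else "."
            category = parts[4] if len(parts) > 4 else "."
            intervals.append(Interval(chrom, start, end, name, category))
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def write_intervals(intervals, path) -> None:
    """Write intervals as BED4(+category), sorted, 0-based half-open."""
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for iv in ivs:
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.name]
            if iv.category != ".":
                cols.append(iv.category)
            fh.write("\t".join(cols) + "\n")
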