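"""Forward-in-time Wright-Fisher cohort simulator.

Emulates a single-origin crop domestication scenario: a wild progenitor
population at mutation-drift equilibrium, a strong domestication
bottleneck into a landrace population, and a weaker improvement
bottleneck into improved (eastern / western) populations. Selective
sweeps are planted as new positive mutations in a target population;
additive QTLs and phenotypes provide a GWAS substrate.

Mechanics: diploid, random mating with selfing permitted, discrete
generations, per-generation Poisson mutation and crossover counts,
multiplicative per-site fitness 1 : 1+s/2 : 1+s. Standing variation of
the root population is initialized from a neutral coalescent
(:mod:`msprime`) at the root's configured size, which is an equilibrium
burn-in at a fraction of the forward cost; every subsequent generation,
all selection and all sampling are forward Wright-Fisher. Mutation and
recombination rates are inflated relative to per-nucleotide rates in
real genomes so that desk-scale chromosomes (default 2 x 2 Mb) carry a
realistic SNP density.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .genio import (
    GenotypeMatrix,
    Interval,
    PopulationMap,
    write_intervals,
    write_vcf,
)


class SweepNotEstablishedError(RuntimeError):
    """Raised when a planted sweep mutation is repeatedly lost to drift."""


@dataclass(frozen=True)
class PopPlan:
    """One population phase: label, constant diploid size, duration, parent label."""

    label: str
    size: int
    generations: int
    parent: str | None = None


@dataclass(frozen=True)
class SweepSpec:
    """A planted sweep: new mutation at ``pos`` (1-based bp) under additive
    selection ``s`` in ``population``.

    ``lead_generations`` is the number of generations before the end of
    the target population's phase at which the mutation is introduced;
    by default it is set to ~1.3x the expected conditional fixation time
    (4/s) ln(2N), so the sweep completes close to the sampling time and
    its hitchhiking footprint is not eroded by post-sweep mutation.
    """

    chrom: str
    pos: int
    s: float
    population: str
    lead_generations: int | None = None


@dataclass(frozen=True)
class QTLSpec:
    """A planted additive QTL anchored at ``pos`` (snapped to the nearest
    common SNP of the realized cohort)."""

    chrom: str
    pos: int
    effect: float


@dataclass
class SimConfig:
    n_chromosomes: int = 2
    chrom_length_bp: int = 2_000_000
    mu: float = 1.0e-7
    recomb_rate: float = 1.0e-7
    selfing_rate: float = 0.5
    pop_plan: list[PopPlan] = field(default_factory=lambda: [
        PopPlan("wild", 150, 40, None),
        PopPlan("landrace", 60, 300, "wild"),
        PopPlan("improved_eastern", 35, 60, "landrace"),
        PopPlan("improved_western", 35, 60, "landrace"),
    ])
    sweep_spec: list[SweepSpec] = field(default_factory=list)
    qtl_spec: list[QTLSpec] = field(default_factory=list)
    sample_sizes: dict[str, int] = field(default_factory=lambda: {
        "wild": 50, "landrace": 50, "improved_eastern": 35, "improved_western": 35,
    })
    heritability: float = 0.6
    seed: int = 0
    max_sweep_retries: int = 100

    def __post_init__(self):
        if self.n_chromosomes < 1 or self.chrom_length_bp < 1:
            raise ValueError("need at least one chromosome of positive length")
        if not 0.0 < self.heritability <= 1.0:
            raise ValueError("heritability must be in (0, 1]")
        if not 0.0 <= self.selfing_rate <= 1.0:
            raise ValueError("selfing_rate must be in [0, 1]")
        labels = [p.label for p in self.pop_plan]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate population labels")
        for p in self.pop_plan:
            if p.size < 2:
                raise ValueError(f"{p.label}: founder count must be >= 2")
            if p.generations < 1:
                raise ValueError(f"{p.label}: generations must be >= 1")
            if p.parent is not None and p.parent not in labels[: labels.index(p.label)]:
                raise ValueError(f"{p.label}: parent {p.parent!r} must be defined earlier")
        roots = [p for p in self.pop_plan if p.parent is None]
        if len(roots) != 1:
            raise ValueError("exactly one root population required")
        chrom_names = set(self.chrom_names())
        for sw in self.sweep_spec:
            if sw.chrom not in chrom_names or not 1 <= sw.pos <= self.chrom_length_bp:
                raise ValueError(f"sweep position out of bounds: {sw}")
            if sw.population not in labels:
                raise ValueError(f"sweep targets unknown population {sw.population!r}")
            if sw.s <= 0:
                raise ValueError("selection coefficient must be positive")
        for q in self.qtl_spec:
            if q.chrom not in chrom_names or not 1 <= q.pos <= self.chrom_length_bp:
                raise ValueError(f"QTL position out of bounds: {q}")
        for label, k in self.sample_sizes.items():
            if label not in labels:
                raise ValueError(f"sample_sizes references unknown population {label!r}")
            size = next(p.size for p in self.pop_plan if p.label == label)
            if not 1 <= k <= size:
                raise ValueError(f"{label}: sample size {k} exceeds population size {size}")

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chrom_names()}


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort: planted sweep intervals,
    realized QTL site indices/effects, and realized genome-wide pi."""

    sweep_intervals: list[Interval]
    qtl_effects: list[tuple[int, float]]
    realized_group_pi: dict[str, float]


class _ChromState:
    """Haplotypes of one population on one chromosome."""

    __slots__ = ("H", "positions", "fixed")

    def __init__(self, H, positions, fixed):
        self.H = H                    # (2N, S) uint8
        self.positions = positions    # (S,) int64, sorted, 1-based bp
        self.fixed = fixed            # set of positions fixed for the derived allele

    def copy_rows(self, hap_rows):
        return _ChromState(self.H[hap_rows].copy(), self.positions.copy(), set(self.fixed))


class _Sweep:
    __slots__ = ("chrom_idx", "pos", "s", "start_gen", "retries", "established")

    def __init__(self, chrom_idx, pos, s, start_gen):
        self.chrom_idx = chrom_idx
        self.pos = pos
        self.s = s
        self.start_gen = start_gen
        self.retries = 0
        self.established = False


def _init_root_population(rng, cfg: SimConfig, N: int) -> list[_ChromState]:
    """Neutral-coalescent standing variation for the root population."""
    import msprime

    # partial selfing raises inbreeding F = sigma/(2 - sigma) and lowers
    # the coalescent effective size to N / (1 + F)
    f_inbreeding = cfg.selfing_rate / (2.0 - cfg.selfing_rate)
    ne_init = max(2.0, N / (1.0 + f_inbreeding))
    states = []
    for _ in range(cfg.n_chromosomes):
        seed_anc = int(rng.integers(1, 2**31 - 1))
        seed_mut = int(rng.integers(1, 2**31 - 1))
        ts = msprime.sim_ancestry(
            samples=N,
            population_size=ne_init,
            sequence_length=cfg.chrom_length_bp,
            recombination_rate=cfg.recomb_rate,
            random_seed=seed_anc,
        )
        mts = msprime.sim_mutations(
            ts, rate=cfg.mu, random_seed=seed_mut, model=msprime.BinaryMutationModel()
        )
        cols, poss = [], []
        for var in mts.variants():
            geno = var.genotypes
            if len(var.alleles) > 2 or geno.max() > 1:
                continue
            c = geno.sum()
            if c == 0 or c == 2 * N:
                continue
            cols.append(geno.astype(np.uint8))
            poss.append(int(var.site.position) + 1)
        if cols:
            H = np.array(cols, dtype=np.uint8).T
            positions = np.array(poss, dtype=np.int64)
        else:
            H = np.empty((2 * N, 0), dtype=np.uint8)
            positions = np.empty(0, dtype=np.int64)
        states.append(_ChromState(H, positions, set()))
    return states


def _sweep_dosage_fitness(states, sweeps, N, max_retries, rng):
    """Ensure sweep alleles are present (re-introducing lost ones) and
    return per-diploid fitness. Returns None when no sweep is active."""
    active = []
    for sw in sweeps:
        st = states[sw.chrom_idx]
        if sw.pos in st.fixed:
            sw.established = True
            continue
        j = np.searchsorted(st.positions, sw.pos)
        present = j < len(st.positions) and st.positions[j] == sw.pos
        if not present:
            sw.retries += 1
            if sw.retries > max_retries:
                raise SweepNotEstablishedError(
                    f"sweep at {sw.pos} lost {max_retries} times; increase s or retries"
                )
            hap = int(rng.integers(0, 2 * N))
            col = np.zeros((2 * N, 1), dtype=np.uint8)
            col[hap, 0] = 1
            st.H = np.concatenate([st.H[:, :j], col, st.H[:, j:]], axis=1)
            st.positions = np.insert(st.positions, j, sw.pos)
        active.append(sw)
    if not active:
        return None
    w = np.ones(N)
    for sw in active:
        st = states[sw.chrom_idx]
        j = np.searchsorted(st.positions, sw.pos)
        dos = st.H[0::2, j].astype(float) + st.H[1::2, j].astype(float)
        w *= 1.0 + (sw.s / 2.0) * dos
    return w


def _evolve(rng, states, N, generations, cfg: SimConfig, sweeps):
    """Forward Wright-Fisher evolution of one population, in place."""
    L = cfg.chrom_length_bp
    n_hap = 2 * N
    for gen in range(generations):
        active_sweeps = [sw for sw in sweeps if gen >= sw.start_gen]
        w = _sweep_dosage_fitness(states, active_sweeps, N, cfg.max_sweep_retries, rng)
        # one diploid offspring = two gametes; with probability selfing_rate
        # both gametes come from the same (fitness-weighted) parent
        if w is None:
            parents = rng.integers(0, N, size=(N, 2))
        else:
            parents = rng.choice(N, size=(N, 2), p=w / w.sum())
        if cfg.selfing_rate > 0:
            selfed = rng.random(N) < cfg.selfing_rate
            parents[selfed, 1] = parents[selfed, 0]
        parent_idx = parents.reshape(-1)
        for st in states:
            start_hap = rng.integers(0, 2, size=n_hap)
            n_co = rng.poisson(cfg.recomb_rate * L, size=n_hap)
            H_new = st.H[2 * parent_idx + start_hap]
            if st.positions.size:
                for gidx in np.flatnonzero(n_co > 0):
                    breaks = np.sort(rng.integers(1, L + 1, size=n_co[gidx]))
                    seg = np.searchsorted(breaks, st.positions, side="left")
                    hap_sel = (start_hap[gidx] + seg) % 2
                    p = parent_idx[gidx]
                    H_new[gidx] = np.where(hap_sel % 2 == 0, st.H[2 * p], st.H[2 * p + 1])
            st.H = H_new
            # new mutations (infinite-sites on a finite integer grid;
            # collisions with standing sites are skipped)
            n_mut = rng.poisson(cfg.mu * L * n_hap)
            if n_mut:
                mpos = rng.integers(1, L + 1, size=n_mut)
                mhap = rng.integers(0, n_hap, size=n_mut)
                mpos, first = np.unique(mpos, return_index=True)
                mhap = mhap[first]
                if st.positions.size:
                    j = np.searchsorted(st.positions, mpos)
                    occupied = (j < st.positions.size) & (
                        st.positions[np.minimum(j, st.positions.size - 1)] == mpos
                    )
                else:
                    occupied = np.zeros(mpos.size, dtype=bool)
                in_fixed = np.array([int(p) in st.fixed for p in mpos]) if st.fixed else np.zeros(mpos.size, dtype=bool)
                fresh = ~occupied & ~in_fixed
                mpos, mhap = mpos[fresh], mhap[fresh]
                if mpos.size:
                    newcols = np.zeros((n_hap, mpos.size), dtype=np.uint8)
                    newcols[mhap, np.arange(mpos.size)] = 1
                    st.positions = np.concatenate([st.positions, mpos])
                    st.H = np.concatenate([st.H, newcols], axis=1)
                    order = np.argsort(st.positions, kind="stable")
                    st.positions = st.positions[order]
                    st.H = st.H[:, order]
            # purge lost sites; move fixed sites to the fixed set
            counts = st.H.sum(axis=0)
            fixed_now = counts == n_hap
            if fixed_now.any():
                st.fixed.update(int(p) for p in st.positions[fixed_now])
            keep = (counts > 0) & ~fixed_now
            if not keep.all():
                st.H = st.H[:, keep]
                st.positions = st.positions[keep]
    # a sweep allele must survive its population's phase
    for sw in sweeps:
        st = states[sw.chrom_idx]
        if sw.pos in st.fixed:
            sw.established = True
        else:
            j = np.searchsorted(st.positions, sw.pos)
            sw.established = bool(j < len(st.positions) and st.positions[j] == sw.pos)


def _sweep_truth_halfwidth(s: float, r: float, n_target: int) -> int:
    """Hitchhiking footprint scale for a stochastic sweep.

    A linked lineage at distance d escapes the sweep with probability
    e(d) ~ 1 - exp(-r d T), where T = integral of (1-p) over the sweep
    sojourn; for an additive sweep from a single copy T ~= (2/s)
    (ln(2Ns) + 2), the +2 covering the drift-dominated establishment
    phase. Relative diversity after the sweep is ~ e(2-e), which drops
    below one half for e < 0.3, i.e. within ~1/3 of the e-folding
    distance: that half-erasure distance is the truth half-width.
    """
    alpha = max(2.0 * n_target * s, np.e)
    t_exposed = (2.0 / s) * (np.log(alpha) + 2.0)
    return max(10_000, int(1.0 / (3.0 * r * t_exposed)))


def simulate_cohort(config: SimConfig):
    """Simulate a multi-population cohort.

    Returns ``(GenotypeMatrix, PopulationMap, CohortTruth)``. Genotypes
    are alt-dosages at sites segregating in the pooled sample, positions
    sorted and 1-based per chromosome. Identical configs (same seed)
    produce bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = config.chrom_names()
    chrom_index = {c: i for i, c in enumerate(chrom_names)}
    pop_gens = {p.label: p.generations for p in config.pop_plan}
    pop_sizes_by_label = {p.label: p.size for p in config.pop_plan}
    sweeps_by_pop: dict[str, list[_Sweep]] = {}
    for sw in config.sweep_spec:
        gens = pop_gens[sw.population]
        if sw.lead_generations is None:
            n2 = 2 * pop_sizes_by_label[sw.population]
            lead = int(np.ceil(1.3 * (4.0 / sw.s) * np.log(n2)))
        else:
            lead = sw.lead_generations
        start_gen = max(0, gens - lead)
        sweeps_by_pop.setdefault(sw.population, []).append(
            _Sweep(chrom_index[sw.chrom], sw.pos, sw.s, start_gen)
        )

    pop_states: dict[str, list[_ChromState]] = {}
    pop_sizes = {p.label: p.size for p in config.pop_plan}
    for plan in config.pop_plan:
        if plan.parent is None:
            states = _init_root_population(rng, config, plan.size)
        else:
            parent_states = pop_states[plan.parent]
            parent_n = pop_sizes[plan.parent]
            founders = rng.choice(parent_n, size=plan.size, replace=plan.size > parent_n)
            hap_rows = np.empty(2 * plan.size, dtype=np.intp)
            hap_rows[0::2] = 2 * founders
            hap_rows[1::2] = 2 * founders + 1
            states = [st.copy_rows(hap_rows) for st in parent_states]
        _evolve(rng, states, plan.size, plan.generations, config,
                sweeps_by_pop.get(plan.label, []))
        pop_states[plan.label] = states

    # draw diploid samples per population
    sample_ids: list[str] = []
    assignments: dict[str, str] = {}
    sampled_rows: dict[str, np.ndarray] = {}
    for plan in config.pop_plan:
        k = config.sample_sizes.get(plan.label, 0)
        if k == 0:
            continue
        picks = np.sort(rng.choice(plan.size, size=k, replace=False))
        hap_rows = np.empty(2 * k, dtype=np.intp)
        hap_rows[0::2] = 2 * picks
        hap_rows[1::2] = 2 * picks + 1
        sampled_rows[plan.label] = hap_rows
        for j in range(k):
            sid = f"{plan.label}_{j:03d}"
            sample_ids.append(sid)
            assignments[sid] = plan.label

    # assemble dosage matrix over the union of sites
    geno_cols, chrom_col, pos_col = [], [], []
    for ci, cname in enumerate(chrom_names):
        union = set()
        for label in sampled_rows:
            st = pop_states[label][ci]
            union.update(int(p) for p in st.positions)
            union.update(st.fixed)
        union_pos = np.array(sorted(union), dtype=np.int64)
        if union_pos.size == 0:
            continue
        blocks = []
        for plan in config.pop_plan:
            label = plan.label
            if label not in sampled_rows:
                continue
            st = pop_states[label][ci]
            hap = st.H[sampled_rows[label]]
            k = hap.shape[0] // 2
            dos = np.zeros((k, union_pos.size), dtype=np.int8)
            if st.positions.size:
                j = np.searchsorted(union_pos, st.positions)
                seg_dos = hap[0::2].astype(np.int8) + hap[1::2].astype(np.int8)
                dos[:, j] = seg_dos
            if st.fixed:
                jf = np.searchsorted(union_pos, np.array(sorted(st.fixed), dtype=np.int64))
                dos[:, jf] = 2
            blocks.append(dos)
        dosage = np.vstack(blocks)
        alt = dosage.sum(axis=0)
        segregating = (alt > 0) & (alt < 2 * dosage.shape[0])
        geno_cols.append(dosage[:, segregating])
        pos_col.append(union_pos[segregating])
        chrom_col.append(np.full(int(segregating.sum()), cname, dtype=object))

    genotypes = (
        np.concatenate(geno_cols, axis=1)
        if geno_cols
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    pos = np.concatenate(pos_col) if pos_col else np.empty(0, dtype=np.int64)
    chrom = np.concatenate(chrom_col) if chrom_col else np.empty(0, dtype=object)
    g = GenotypeMatrix(
        genotypes=genotypes,
        chrom=chrom,
        pos=pos,
        ref=np.full(pos.size, "A", dtype=object),
        alt=np.full(pos.size, "G", dtype=object),
        samples=sample_ids,
        chrom_lengths=config.chrom_lengths(),
    )
    popmap = PopulationMap(assignments)

    # ground truth
    L = config.chrom_length_bp
    truth_intervals = []
    for sw in config.sweep_spec:
        w = _sweep_truth_halfwidth(sw.s, config.recomb_rate, pop_sizes[sw.population])
        start = max(0, sw.pos - 1 - w)
        end = min(L, sw.pos + w)
        truth_intervals.append(
            Interval(sw.chrom, start, end, name=f"sweep_{sw.chrom}_{sw.pos}",
                     category=sw.population)
        )
    qtl_effects = []
    from .diversity import site_diversity  # local import to avoid cycle at module load

    for q in config.qtl_spec:
        on_chrom = np.flatnonzero(g.chrom == q.chrom)
        if on_chrom.size == 0:
            raise ValueError(f"no segregating site available for QTL {q}")
        alt, n = g.allele_counts()
        maf = np.minimum(alt / np.maximum(n, 1), 1 - alt / np.maximum(n, 1))
        common = on_chrom[maf[on_chrom] >= 0.05]
        pool = common if common.size else on_chrom
        site = int(pool[np.argmin(np.abs(g.pos[pool] - q.pos))])
        qtl_effects.append((site, float(q.effect)))

    realized_pi = {}
    groups = popmap.groups()
    total_len = config.n_chromosomes * L
    for label, members in groups.items():
        idx = g.sample_indices(members)
        alt, n = g.allele_counts(idx)
        realized_pi[label] = float(site_diversity(alt, n).sum() / total_len)

    return g, popmap, CohortTruth(truth_intervals, qtl_effects, realized_pi)


def simulate_phenotype(g: GenotypeMatrix, qtl_effects, heritability: float, seed: int):
    """Additive phenotype: sum of effect x dosage plus Gaussian noise
    scaled so that genetic variance / total variance = heritability."""
    if not 0.0 < heritability <= 1.0:
        raise ValueError("heritability must be in (0, 1]")
    rng = np.random.default_rng(seed)
    genetic = np.zeros(g.n_samples)
    for site, effect in qtl_effects:
        dos = g.genotypes[:, site].astype(float)
        dos[dos < 0] = np.nan
        dos = np.where(np.isnan(dos), np.nanmean(dos), dos)
        genetic += effect * dos
    var_g = float(np.var(genetic))
    if var_g == 0.0:
        if heritability > 0 and qtl_effects:
            raise ValueError("zero genetic variance with positive heritability")
        return rng.standard_normal(g.n_samples)
    if heritability == 1.0:
        return genetic
    noise_sd = np.sqrt(var_g * (1.0 - heritability) / heritability)
    return genetic + rng.normal(0.0, noise_sd, size=g.n_samples)


def write_cohort(cohort, out_dir, phenotypes: dict | None = None) -> dict[str, Path]:
    """Write a simulated cohort: VCF v4.2, sample map TSV, truth BED,
    phenotype TSV, and a truth JSON. Returns the paths written."""
    g, popmap, truth = cohort
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "samples": out / "samples.tsv",
        "truth_bed": out / "truth_sweeps.bed",
        "truth_json": out / "truth.json",
    }
    write_vcf(g, paths["vcf"])
    popmap.to_tsv(paths["samples"])
    write_intervals(truth.sweep_intervals, paths["truth_bed"])
    with open(paths["truth_json"], "w") as fh:
        json.dump(
            {
                "qtl_effects": [[int(i), float(e)] for i, e in truth.qtl_effects],
                "realized_group_pi": truth.realized_group_pi,
            },
            fh,
            indent=2,
        )
    if phenotypes:
        import pandas as pd

        df = pd.DataFrame({"sample": g.samples})
        for trait, values in phenotypes.items():
            df[trait] = np.asarray(values)
        paths["phenotypes"] = out / "phenotypes.tsv"
        df.to_csv(paths["phenotypes"], sep="\t", index=False)
    return paths


def matrix_from_tree_sequence(ts, chrom: str = "chr1", prefix: str = "s") -> GenotypeMatrix:
    """Convert a diploid msprime/tskit tree sequence with mutations into a
    :class:`GenotypeMatrix` (biallelic sites only)."""
    cols, poss = [], []
    for var in ts.variants():
        geno = var.genotypes
        if len(var.alleles) > 2 or geno.max() > 1:
            continue
        c = int(geno.sum())
        if c == 0 or c == geno.size:
            continue
        cols.append((geno[0::2] + geno[1::2]).astype(np.int8))
        poss.append(int(var.site.position) + 1)
    k = ts.num_samples // 2
    geno = np.array(cols, dtype=np.int8).T if cols else np.empty((k, 0), dtype=np.int8)
    pos = np.array(poss, dtype=np.int64)
    return GenotypeMatrix(
        genotypes=geno,
        chrom=np.full(pos.size, chrom, dtype=object),
        pos=pos,
        ref=np.full(pos.size, "A", dtype=object),
        alt=np.full(pos.size, "G", dtype=object),
        samples=[f"{prefix}_{i:03d}" for i in range(k)],
        chrom_lengths={chrom: int(ts.sequence_length)},
    )


def default_domestication_config(seed: int = 0) -> SimConfig:
    """The study-condition default: strong domestication bottleneck
    (diversity ratio ~= 3), weak improvement bottleneck (~= 1.2), two
    domestication sweeps, one improvement sweep per improved group, and
    two additive QTLs for a quantitative trait."""
    return SimConfig(
        sweep_spec=[
            SweepSpec("chr1", 500_000, 0.2, "landrace"),
            SweepSpec("chr2", 1_500_000, 0.2, "landrace"),
            SweepSpec("chr1", 1_400_000, 0.5, "improved_eastern"),
            SweepSpec("chr2", 500_000, 0.5, "improved_western"),
        ],
        qtl_spec=[
            QTLSpec("chr1", 800_000, 1.0),
            QTLSpec("chr2", 1_000_000, 0.6),
        ],
        heritability=0.6,
        seed=seed,
    )
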