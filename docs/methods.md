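# Methods

`peachpop` re-implements, as a tested pipeline over simulated cohorts, the
population-genomic tool chain used to reconstruct the breeding history of a
self-compatible perennial fruit crop: windowed diversity statistics,
reduction-of-diversity (ROD) and composite-likelihood-ratio (CLR) sweep
scans, linkage-disequilibrium (LD) decay, bottleneck demography, and
mixed-model GWAS. This note records the models, the default parameters and
why they hold, the numerical choices, and the limitations of the simulated
test substrate.

## The cohort simulator

### Model

Diploid Wright–Fisher populations with discrete generations and random
mating. Partial self-fertilisation is supported (`selfing_rate`, default
0.5): with that probability both gametes of an offspring come from the same
fitness-weighted parent. Selfing at rate σ raises the inbreeding coefficient
to F = σ/(2−σ) and lowers the coalescent effective size to N/(1+F).

Populations are organised as a founding tree (`pop_plan`): each derived
population is founded by sampling diploids from its parent's current state
and then evolves at its own constant size. The root population's standing
variation is initialised from a neutral coalescent (msprime) at the root's
effective size — an equilibrium burn-in at a small fraction of the forward
cost; all subsequent drift, selection and sampling are forward-in-time.

Mutation is Poisson per generation at rate μ per bp per haplotype on a
finite integer grid of positions (collisions with standing sites are
skipped, an infinite-sites approximation). Crossover counts are Poisson(rL)
per gamete with uniform breakpoints.

### Planted sweeps

A sweep is a new mutation at a focal position with additive fitness
1 : 1+s/2 : 1+s in its target population. If the allele is lost to drift it
is re-introduced (a recurrent new mutation at the same site), up to
`max_sweep_retries` (default 100); exceeding the bound raises
`SweepNotEstablishedError`. The mutation is introduced `lead_generations`
before the end of the target population's phase — by default ~1.3× the
expected conditional fixation time (4/s)·ln(2N) — so the sweep completes
close to the sampling time. Introducing sweeps at a phase's start instead
lets the footprint erode: after fixation, window diversity recovers at rate
≈ 2μ per bp per generation, and in small populations single drifting
lineages can restore a window's π within tens of generations.

Truth intervals around each focal position use a half-erasure footprint: a
linked lineage at distance d escapes the sweep with probability
e(d) ≈ 1 − exp(−r·d·T) where T ≈ (2/s)(ln(2Ns)+2) is the integral of (1−p)
over the conditional sojourn (the +2 covers the drift-dominated
establishment phase). Relative post-sweep diversity is ≈ e(2−e), which
falls below ½ for e < 0.3, i.e. within ~1/3 of the e-folding distance;
that distance (floored at 10 kb) is the truth half-width.

### Default scenario and calibration

The default cohort (`default_domestication_config`) emulates a single-origin
domestication with a strong bottleneck and a weak improvement step on a
2 × 2 Mb genome with μ = 1e-7 and r = 1e-7 per bp (both inflated ~10–20×
relative to per-nucleotide rates in real plant genomes so that desk-scale
chromosomes carry a usable SNP density; r = 1e-7 puts the LD half-decay
scale at tens of kb, matching the intended contrast between groups):

| population | N | generations | founded from | samples |
|---|---|---|---|---|
| wild | 150 | 40 | coalescent init | 50 |
| landrace | 60 | 300 | wild | 50 |
| improved_eastern | 35 | 60 | landrace | 35 |
| improved_western | 35 | 60 | landrace | 35 |

With σ = 0.5 the neutral expectations are π_wild ≈ 4·(0.75·150)·μ ≈ 4.5e-5
and a landrace equilibrium of ≈ 1.8e-5, giving a domestication diversity
ratio ≈ 2.5–3 (target ≈ 3); the improvement step is calibrated to ≈ 1.2–1.3
neutrally. Planted improvement sweeps (s = 0.5, one per improved group) sit
on top of the neutral calibration, so realized improvement ratios run
somewhat above 1.2 — on real data the measured ratio likewise includes sweep
effects. Two domestication sweeps (s = 0.2) and two additive QTLs
(heritability 0.6) complete the scenario.

### Phenotypes

`simulate_phenotype` builds y = Σ effect×dosage + N(0, τ²) with τ² chosen so
genetic variance / total variance equals the requested heritability;
heritability 1 returns the genetic values exactly, and zero genetic variance
with positive heritability is an error. QTL positions are snapped to the
nearest segregating site with pooled MAF ≥ 0.05 so planted traits are
testable in the realized cohort.

## Windowed statistics

Windows default to 100 kb sliding by 10 kb, emitted while their start lies
within the declared chromosome length and truncated at the end.

- **π**: per-site unbiased pairwise diversity 2a(n−a)/(n(n−1)) over called
  alleles, summed per window and divided by the *full window length in bp*
  (the convention of the windowed-π tools this mirrors; a per-segregating-
  site mode exists but is not the default). Missing genotypes shrink n per
  site; invariant sites contribute 0.
- **Tajima's D**: standard 1989 normalisation computed per window on
  segregating sites with ≥ 4 called alleles; the haplotype count is twice
  the mean number of called diploids over used sites, rounded down (the
  data are unphased dosages). Windows with no usable sites or non-positive
  variance term are masked.
- **F_ST**: Weir–Cockerham (1984) two-population variance components per
  site from allele counts and *observed* heterozygote counts, aggregated
  ratio-of-sums (Σa / Σ(a+b+c)) over sites polymorphic in the pooled pair.
  Negative windowed values are reported, not clamped.
- **ROD**: π_numerator/π_denominator on the shared window grid
  (wild/landrace for domestication, landrace/improved for improvement).
  Windows are masked when either input window is masked, either group has
  fewer than `min_sites` (3) segregating sites, or the denominator π falls
  below `epsilon` (1e-6 per bp): a ratio over vanishing diversity is
  unbounded and carries no rank information. Masked windows are excluded
  from threshold quantiles and can never be called as sweep members.

Group-level π is reported both as the length-weighted mean of unmasked
windows and as a genome-total (`genome_pi`: total pairwise diversity over
total genome length); the two differ only through masking and terminal
windows.

## Sweep calling and the CLR scan

The top-quantile rule takes the empirical (1−q) quantile (type-7 linear
interpolation, q = 0.05) of unmasked ROD values; windows *strictly above*
the threshold (ties excluded) are selected, and overlapping or book-ended
selected windows merge into maximal regions with peak and mean recorded.

The CLR scan follows the SweepFinder/SweeD lineage as a composite
likelihood over sites modelled as a marked Poisson process. Background:
sites occur at the genome-wide density of fully-called polymorphic sites
with folded frequency classes drawn from the genome-wide folded SFS
(0.5 pseudo-count smoothing). Sweep model at grid position x with intensity
α: a site at distance d escapes with probability p_e = 1 − exp(−α·d);
escaped sites keep the background class, non-escaped sites are driven to
the extreme (folded singleton) class with a visible fraction w_keep = 0.1,
the remainder going to fixation and out of the observable set — which makes
a site desert around a swept core direct evidence. CLR(x) is the
log-likelihood gain over the background model maximised over a log-spaced α
grid (1e-6…1 per bp, 25 points); α → ∞ recovers the background, so CLR ≥ 0.
The grid defaults to 2000 positions per scanned region in the CLI and 200
in the bundled experiments (4–10 kb spacing on desk-scale regions, well
inside the ±100 kb localization question asked of it). No numerical
equivalence with any external scanner is claimed; the scan is validated
behaviourally (localization of planted sweeps, permutation null on
exchangeable data).

## LD decay

r² between unphased sites uses EM haplotype-frequency estimation over the
3×3 genotype table (only the double-heterozygote cell is phase-ambiguous;
tolerance 1e-8, max 1000 iterations), with squared dosage correlation as
the fallback when EM does not converge; on fully homozygous data the two
coincide. Samples missing either genotype are excluded pairwise; sites
monomorphic after deletion yield no value. Curves bin all intra-chromosomal
pairs within 200 kb (1-kb bins by default), subsampling with a seeded RNG
above a pair budget. The half-decay distance is where the *isotonically
smoothed* (weighted non-increasing PAVA fit) curve first falls to half of
its maximum bin value, linearly interpolated between flanking bin start
positions; defining "half" against the maximum bin rather than the first
bin tolerates noisy short-range bins. Curves that never reach half are
flagged "not reached".

## Demography

`effective_size_from_theta` applies θ = 4·Ne·μ·L literally as printed in
the source analyses (μ = 7.77e-9 per generation, L = 3): Ne = θ/(4μL), with
2Ne = 7.50e4 for θ = 3.5e-3. The formula mixes a per-generation mutation
rate with a generation-time factor — dimensionally the product μ·L reads as
a per-year rate scaled back to generations; the implementation reproduces
the printed arithmetic and leaves the unit question to this note.

The heterozygosity-excess bottleneck test compares each sampled SNP's
observed He = n/(n−1)(1−Σp²) with its mutation-drift-equilibrium
expectation conditioned on two alleles and the locus's called sample size.
The conditional distribution is built by coalescent simulation: for each
distinct n, `n_iter` Kingman trees are simulated and the branch length
subtending j leaves is pooled across trees, so a single mutation placed
proportionally to branch length reproduces the neutral folded spectrum
∝ 1/j + 1/(n−j); He per folded class then gives the conditional mean,
SD, and the full null distribution. For biallelic loci this construction
makes the IAM, SMM and TPM mutation models coincide (only the allele count
matters), so the TPM multistep fraction is accepted but inert — a
consequence of applying a microsatellite-era test to SNPs.

The reported P value is the one-sided (excess) Wilcoxon signed-rank
statistic on He_obs − He_eq calibrated by Monte Carlo draws of locus sets
from the same conditional spectrum (999 draws). The textbook signed-rank
null is *not* used: the conditional He distribution for k = 2 is strongly
right-skewed, so a normal-approximation test of mean-zero is badly
miscalibrated in this regime, while the Monte Carlo null is exact up to
sampling error under the model. Calibration holds when sampled loci are
approximately independent; loci packed on a short low-recombination segment
share genealogies and inflate the statistic's variance, which is why the
calibration benchmarks simulate genome-spread-like marker spacing.

## Mixed-model GWAS

Kinship is mean IBS similarity, K_ij = mean(1 − |g_i − g_j|/2), pairwise-
complete over shared called SNPs (the default flavour of the program the
analysis mirrors; a VanRaden-style matrix would differ only by scaling
choices). The null model y = μ + u + e with u ~ N(0, σg²K) is fitted by
REML through the spectral decomposition of K (ridge 1e-6) and a 1-D search
over δ = σe²/σg² (grid on log δ ∈ [−10, 10] then bounded refinement); with
K ∝ I the likelihood is flat in δ and the fit is flagged unidentifiable.
Every SNP is then tested by GLS with covariance fixed from the null fit —
the EMMAX approximation — vectorised across SNPs; with K = I the p-values
equal ordinary least squares exactly (t with n−2 df). Missing genotypes are
mean-imputed per SNP for testing only; monomorphic SNPs get p = 1 with a
warning. The genome-wide threshold is Bonferroni α/n_SNPs; significant SNPs
within 100 kb on a chromosome merge into peaks (the merge distance is a
reporting choice recorded in output metadata, not a published parameter).
Binary traits are handled by the same linear model on 0/1 coding, as the
mirrored program does.

## Frozen study conditions (`peachpop.experiments`)

- **Sweep recovery**: wild (N = 800, 10 forward generations after
  coalescent init) → landrace (N = 400, 250 generations), 2 × 2 Mb,
  μ = 5e-8, r = 2e-7, no selfing, five sweeps at s = 0.2 selected from the
  landrace founding, 50 + 50 samples, ten replicates (seeds base…base+9).
  A truth interval is recovered when it intersects a called top-5% region;
  each recovered sweep's CLR scan covers the focal position ± 400 kb on a
  200-point grid and is localized when its argmax lies within 100 kb of
  the focus.
- **GWAS calibration**: a single population of 300 diploids (μ = 1.5e-7,
  10 forward generations), MAF ≥ 0.05; type-I error is the fraction of
  SNPs with p < 0.05 under a permuted phenotype, and power is the fraction
  of ten phenotype replicates (one planted QTL explaining 20% of variance)
  in which the causal SNP ranks in the top five by p.
- **Bottleneck calibration**: equilibrium samples (50 diploids from
  Ne = 1000, 2 Mb at r = 5e-7 so markers are nearly independent) give the
  false-positive rate over 50 replicates; power is measured against a
  recent 10-fold bottleneck (size 100 for the last 50 generations) over
  10 replicates, IAM, 1000 loci where available, 1000 iterations.

### Known limitation: top-quantile recovery at desk scale

On the 4-Mb study genome with 100-kb/10-kb windows, the top-5% rule selects
exactly ~20 windows while any sweep footprint that registers at the window
scale (≥ 100–150 kb after window smearing) spans ≥ 10 windows. Five planted
sweeps therefore compete for fewer selection slots than a single footprint
occupies, and allocation is winner-take-most: the deepest footprints absorb
8–11 slots each and the shallowest sweep of a replicate frequently falls
just below the self-set threshold. Across a broad design sweep (target
population sizes 100–800, r 1e-7–4e-7, selfing 0–0.8, phase lengths
200–400) measured recovery plateaus near 0.7. On a full-size genome the
top-5% span is vastly larger than any one footprint, so this ceiling is a
desk-scale geometry effect, not a property of the scan; the CLR
localization, calibration and arithmetic checks are unaffected. The
recovery benchmark reports the honest number rather than loosening the
conditions.

## What the simulator does and does not establish

The generator reproduces the qualitative structure of a domestication
cohort — nested bottlenecks with the intended diversity ratios, locally
erased diversity at planted sweeps, LD decaying over tens of kb and slower
in bottlenecked groups, additive traits with controlled heritability — at
inflated per-bp rates and populations ~100× smaller than real germplasm
collections. Consequences: window-level genealogical noise is much larger
than in real data; sweep footprints are narrower relative to genome size;
heterozygosity-excess signals at quasi-equilibrium bottlenecks (like the
default cohort's old landrace bottleneck) are absent by design, so the
bottleneck test is validated on dedicated recent-bottleneck simulations.
Passing tests demonstrate correctness of the estimators and the expected
direction and rough magnitude of every effect, not numerical agreement
with any full-genome study. Gene flow between populations, selection on
standing variation, and structural variation are not modelled.
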