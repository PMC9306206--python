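# Methods

This note documents the models and estimators trigene implements, the
numerical and design choices behind them, what the synthetic-data generator
does and does not emulate, and the problem sizes used by the validation
suite and `scripts/acceptance.py`.

## The simulation engine (`trigene.simdata`)

The engine is a discrete-generation diploid Wright–Fisher forward
simulation.  Populations are panmictic pools of `2N` haplotypes; each
offspring draws two gametes, each gamete from a uniformly chosen parent in
its source population (selfing permitted, as in the standard WF model).
Migration acts per gamete: with probability `m[recipient][donor]` the
gamete's parent is drawn from the donor instead.  Splits are reverse-time
merges realised forward in time: the derived population first samples its
founders from the ancestral pool at the split generation.  Bottlenecks are
temporary overrides of the size schedule.

Genomes are sets of independent regions ("chromosomes"). Mutation is
infinite-sites: new sites arise at Poisson(`2N·µ·L`) per generation at
uniform coordinates and are tracked sparsely as matrix columns; globally
lost or fixed columns are pruned every generation.  Recombination has two
parts: free recombination between regions (an independent phase bit per
gamete and region) and Poisson crossovers within regions at `r` per base.
The derived allele is always known, so the ancestral allele is emitted as
the REF/AA allele.

**Equilibrium initialisation.**  The root population starts at
mutation–drift equilibrium: the number of segregating sites is drawn with
mean `θL·Σ_{i<2N} 1/i` and population frequency counts `i` with probability
∝ 1/i — the neutral equilibrium frequency spectrum.  A configurable burn-in
(default `2N` generations) then runs before the oldest demographic event.
Allele-frequency statistics (π, FST, f3, D, PBS) are accurate with short
burn-ins because frequencies start at equilibrium; linkage disequilibrium
builds up from zero, so LD analyses use the full default burn-in.  The
validation suite checks the engine against Watterson's `E[S] = θ·Σ1/i`, the
diversity expectation `E[π] = 4Nµ`, and an independent msprime coalescent
run of the same model.

**Rescaling.**  A `rescale_factor` Q divides sizes and times and multiplies
µ, r and m, preserving the scaled parameters (4Nµ, 4Nr, 4Nm, t/N) that
govern diversity, differentiation and LD.  Models are stated in natural
units and rescaled internally; the default demo factor keeps every rescaled
size at or below 1000 diploids.  Events shorter than one rescaled
generation (for example a 15-generation bottleneck under Q = 50) collapse
to a single generation — the main distortion rescaling introduces, along
with coarser drift granularity.

**What the generator does not emulate:** sequencing error, depth-dependent
genotype quality (depth and missingness are injected independently by
explicit corruption options), variable mutation/recombination rate along
the genome, selection acting through allele dynamics (positive controls are
created by resampling target-population genotypes at a shifted frequency),
and phasing.  Passing tests therefore demonstrate estimator correctness and
calibration under the stated model, not robustness to real-data artefacts.

## Differentiation

Per-site Weir–Cockerham (1984) components `a, b, c` are computed for
population pairs (r = 2) from called diploid genotypes, including the
observed-heterozygosity terms; sample sizes are per-site (missing calls
excluded sitewise).  Aggregation is the ratio of averages `Σa/Σ(a+b+c)`;
sites monomorphic across the pair are excluded from both sums.  Negative
aggregates are reported as computed and clamped to zero only where a
distance or branch length is required (NJ trees, the `−log(1−FST)`
transform).  π is the unbiased per-site mean pairwise difference
`2p̂q̂·n/(n−1)` averaged over sites with ≥2 called alleles.  NJ trees are
built with scikit-bio's neighbor-joining on the pairwise FST matrix.

## f3 and D

Both statistics are computed from population allele frequencies, so
unpolarised VCFs work.  f3(T; A, B) uses the unbiased per-site estimator
`(p̂_T−p̂_A)(p̂_T−p̂_B) − p̂_T(1−p̂_T)/(n_T−1)` with `n_T` the called
allele copies in the target.  D uses the frequency (ABBA–BABA ratio) form
with the outgroup as the fourth population.  Standard errors come from a
weighted delete-one block jackknife (Busing et al. 1999) over contiguous
5 cM blocks (configurable), weighted by per-block usable SNP counts; blocks
never span chromosomes.  A degenerate jackknife (all blocks identical) is
flagged rather than reported as an infinite Z.  The validation suite checks
antisymmetry, ref/alt-swap and reordering invariance, the Busing formulas
against a scalar transcription, type-I control (|Z| > 3 in ≤1% of neutral
replicates, and sd(Z) ≈ 1, which verifies the jackknife SE against the
empirical sampling spread), and ≥90% power against a simulated
introgression pulse.

## PBS selection scan

Gene-level PBS aggregates WC FST by ratio of averages over the gene's
usable SNPs (usable = polymorphic in at least one of the three
populations), clamps each FST into `[0, 1−1e−8]`, transforms to
`T = −log(1−FST)` and takes `PBS = (T_AB + T_AC − T_BC)/2`.  The
alternative aggregation (mean of single-SNP PBS) is available via
`per_snp_mean=True`.  Contributing-variant extraction (`major_variants`)
computes single-site PBS and keeps values strictly above 0.1; there,
usability is polymorphism across the union of the three populations so that
a fixed difference — the most extreme single-SNP signal — is retained.

**Empirical null.**  `build_null` simulates neutral genes under the study
demography until every requested SNPs-per-gene bin holds `n_sim` PBS values
(bins: one per count 1–69, then 5-wide bins with [95,100] absorbing the
boundary).  P-values are `(1 + #{null ≥ observed}) / (1 + n_sim)`; the
pseudocount keeps extreme genes testable against thresholds.  Two modes
exist: per-bin length targeting (general), and a matched-length mode used
whenever the scored genes share one mutational target size.  The matched
mode matters: conditioning on the realised SNP count makes the neutral PBS
distribution depend on the gene's target size (a high count at a small
target implies a large genealogy), so per-bin calibration is exact only
when null and scored genes share the length distribution.  The calibration
study verifies uniformity (Kolmogorov–Smirnov) of p-values for neutral
genes scored against an independently seeded matched null.

Scan designs follow the study logic: shared signals are genes with
P < 0.01 in at least two populations (plus the all-population
intersection); the divergent design scans each target against each sister
population as the second reference with a fixed third, flagging genes with
P < 0.01 in at least two of the three comparisons; the enrichment input set
is the strict intersection at P < 0.05.  The PBS site filter keeps sites
with mean depth above 50 and missingness below 5%.

## LD-decay demography

Composite (genotype-dosage) r² is computed for all same-chromosome SNP
pairs closer than 0.25 cM, binned at 0.01 cM, adjusted by `−1/n`
(n = diploid sample size), and inverted per bin as
`Ne = [(1/r²_adj) − 2] / (4c)` with time horizon `t = 1/(2c)` generations.
Pairs spanning a genetic-map gap above 1 cM are excluded.  The MAF floor
for LD pairs defaults to 0.10: the inversion assumes the Sved-type
expectation `r² ≈ 1/(2 + 4Nc)`, which describes common-variant pairs;
including rarer variants depresses the bin means and inflates Ne severalfold
(verified against an independent coalescent simulator as well as the
internal engine).  Divergence time is `T = 2·Ne·FST` with Ne the average of
the two populations' harmonic-mean Ne over bins whose horizon falls in the
current window; the window is re-centred on `[T/2, 2T]` until T stabilises
(5% tolerance, ≤20 iterations), so only distance categories relevant to the
divergence depth contribute.  Like the original method, the estimator runs
low when FST is large enough that `FST ≈ T/2N` saturates; the validation
suite requires recovery within a factor of two on a clean split (observed
ratios ≈ 0.5–0.7) and Ne recovery within ±30% for a constant-size
population.  LD pruning is the greedy windowed rule: 1000 bp windows
advanced by a fixed SNP step; within a window the later-position member of
any pair with r² > 0.2 is removed.

## ROH

A two-state HMM per individual and chromosome: HW (genotypes follow
Hardy–Weinberg at the site's cohort allele frequency) and AZ (homozygotes
with probabilities proportional to allele frequencies).  Observed genotypes
pass through a symmetric error channel with probability `10^(−phred/10)`
(default phred 30 → 10⁻³), i.e. the observed genotype differs from the true
one with that probability, split evenly between the two alternatives.
Transitions between consecutive sites are `1 − exp(−a·d)` with per-base
rates `a_hw→az = 5e−9` and `a_az→hw = 5e−8` and `d` the inter-site
distance; these are free parameters calibrated on the planted-segment
suite, not matched to any external tool's unpublished defaults.  Viterbi
decoding yields non-overlapping maximal AZ runs reported from first to last
AZ site (internal gaps count toward length), which is what per-class length
totals require.  Classes: short < 1 Mb, medium 1–5 Mb (both boundaries
inclusive), long > 5 Mb.

## Variant classes

Novel = absent from every supplied catalog (chrom:pos:ref:alt keys; real
dbSNP/ExAC-scale catalogs are user-supplied, never bundled).  Singleton =
within-scope alternate allele count exactly one, so a single heterozygote;
a homozygous carrier (count two) is retained.  LOF = HIGH impact, or
missense with SIFT strictly below 0.05 and PolyPhen strictly above 0.446;
a missing score fails its condition.  Population-specific novel variants
are defined by carriage in exactly one population.

## Validation problem sizes

All validation simulations run in rescaled units chosen for one desk CPU;
replicate designs batch unlinked regions in a single engine run and group
them into replicates (statistically identical to independent runs).

- **WC oracle**: 500 random instances, ≤10 sites, ≤12 diploids per
  population, 10% missing calls; components must match a scalar
  transcription of the 1984 formulas to 1e−12.
- **PBS identity**: 10⁴ random FST triples, `PBS_A + PBS_B = T_AB` to 1e−12.
- **Null calibration**: three-population null demography (target/second/
  third ≈ 80/160/100 rescaled diploids, splits at 6 and 20 rescaled
  generations, the deeper one being the 2000-generation European–East-Asian
  divergence under Q = 100); genes of 1.8 kb target size giving 3–10 usable
  SNPs; n_sim = 5000 per bin; ≥2000 neutral genes scored.
- **Power**: 50 genes injected with a +0.5 target-frequency shift at all
  SNPs, 50 matched neutral controls, same null.
- **D statistic**: four populations of N = 50, splits at 8/35/55
  generations, 45 unlinked 10 kb regions and 25 diploids per population per
  replicate; introgression arm adds a Z→X pulse of m = 0.11 over the last 6
  generations (≈50% ancestry); 200 replicates per arm.
- **f3 ordering**: close partner split 10, distant 30, outgroup 60
  generations; 20 regions per replicate; 100 replicates.
- **LD recovery**: constant Ne = 500, 20 Mb at 1 cM/Mb, n = 50, burn-in
  1000 generations; divergence: Ne = 500 split 500 generations ago, 15 Mb.
- **ROH**: 20 Mb chromosome at one common SNP per 2 kb; planted fully
  homozygous segments of 0.5/2/8 Mb with 10⁻³ genotype error.
- **Demo**: the seven-population Western-Yunnan cartoon (deep outgroup;
  TBN basal to (ACH, JIP); DEA basal to (DAI, HAN); TBN→ACH/JIP and
  HAN↔DAI gene flow; recent bottlenecks in ACH/JIP/DEA) under Q = 50,
  300 unlinked 9 kb regions, 15 diploids per population, 10 replicates.

## Known limitations

- Forward rescaling coarsens drift and collapses very recent events; the
  demo's 15-generation bottlenecks act as a single rescaled generation.
- The null store must be built under the same demography, sample sizes and
  gene-length distribution as the scan it calibrates; the store records its
  triple, model hash and seed so bindings are explicit.
- The LD-decay Ne inversion is biased upward at small `4Nc` even with the
  MAF floor, and divergence times run low at large FST — both inherent to
  the estimator, not to this implementation.
- The ROH transition rates are free parameters; per-sample depth/quality
  aware emissions (genotype likelihoods) are not implemented.
- D/f3 assume unlinked-enough blocks for the jackknife; extremely long-range
  LD (recent admixture) would require larger blocks than the 5 cM default.
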