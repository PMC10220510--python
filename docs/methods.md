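# Methods

## The system being modelled

`symevol` targets experimental evolution of a bacterium through serial
plant-nodulation cycles. Each cycle has two compartments. In the external
compartment (the rhizosphere) the population experiences a transient burst of
hypermutagenesis. Host entry then imposes a drastic selective bottleneck:
each root nodule is founded by a single cell, and genotypes compete for the
B available nodules in proportion to their *nodulation competitiveness*
(`c`). Inside its nodule, a founder's clone grows to a carrying capacity
proportional to its *within-host proliferation* (`p`). Harvested nodules are
pooled, diluted, and used to inoculate the next cycle. Both traits live in
(0, 1], 1 being the theoretical optimum; population fitness is defined as
the product of the two trait summaries, split into low (< 1e-5), mid, and
high (> 1e-3) iso-fitness domains (strict inequalities; boundary values
classify as mid).

## Life-cycle simulator

State is kept per *genotype* (a clonal lineage with an abundance count),
never per cell, so rhizosphere sizes of 10^6–10^7 cost nothing. One cycle
under the default `bottleneck_first` ordering is:

1. **Hypermutagenesis** — each genotype spawns `Poisson(abundance × U)`
   single-cell mutant genotypes; total abundance is conserved. A mutation
   multiplies `c` and/or `p` by a drawn factor, clamped at 1. The burst is
   collapsed to one per-cycle rate `U` (default 0.01 per cell per cycle,
   i.e. ~10^4 new genotypes in a 10^6-cell rhizosphere). Much lower rates
   make host-entry establishment (probability ≈ B × U × E[effect] per cycle)
   so rare that nothing adapts within 50 cycles, which contradicts the
   observed behaviour of this class of experiment; the chosen value produces
   realistic sweep dynamics while staying cheap.
2. **Host entry** — a multinomial draw of exactly `B` founders with genotype
   weights `abundance × c`. Within-nodule populations are strictly clonal
   (no in-nodule mutation).
3. **Proliferation and pooling** — a nodule founded by genotype g yields
   `round(K_max × p_g)` cells (at least 1; `K_max` default 10^6, a realistic
   per-nodule carrying capacity). The pool is resampled multinomially to
   `rhizosphere_size`, which preserves expected frequencies and mimics the
   crush–dilute–reinoculate transfer rather than deterministic rounding.

The `proliferation_first` ordering instead amplifies the mutated rhizosphere
population in proportion to `p` (multinomial resample with weights
`abundance × p`) *before* the competitiveness-weighted bottleneck, after
which every nodule contributes `K_max` cells uniformly. Under this ordering
a new mutant's establishment probability scales with the product of its two
trait effects; under `bottleneck_first` it scales with the competitiveness
effect only — this asymmetry is the mechanism behind the headline result.

### Mutation architecture

A mutation affects `c` only, `p` only, or both (probabilities 0.45 / 0.45 /
0.10, independent factor draws when pleiotropic). With probability 0.1 a
factor is beneficial, log-uniform on [1, 10^4]; otherwise deleterious,
log-uniform on [10^-4, 1]. The wide range matters qualitatively: ancestors
start 10^4-fold below the trait optimum, and with effects capped at 10^2 a
single mutation could never move fitness out of the low domain, while the
founding bias of a competitiveness mutant (≈ B × effect / rhizosphere_size)
would stay linear in the effect at every bottleneck size. With effects up to
10^4 that founding probability saturates at 1 for strong mutants when
B = 3000, which removes the establishment bias at wide bottlenecks — the
regime in which selection on the two traits becomes symmetric. All
architecture parameters are exposed in `MutationArchitecture` /
`EffectDistribution` and in the flat config file.

### Summaries

Per cycle the simulator records the abundance-weighted median of each trait
(mean selectable via `summary_stat`), their product as fitness, and the
fitness domain. Every mutation censused in the post-harvest population gets
a sparse frequency track (mutations lost before their first census are
implicitly all-zero). *Selected* mutations are those whose track ever
reaches 30%; each is reported with its fold effect (`c`-factor divided by
`p`-factor) and the fitness domain of the population in the cycle it arose
(the census preceding its origin, not the cycle it crossed 30%).

Reproducibility: one master seed drives everything; replicate seeds are
derived from it through a seed sequence, and a fixed seed gives bit-identical
results.

## Trajectory cohorts

Whole-population sequencing yields a mutations × sampled-cycles frequency
matrix per lineage (the emulated design: five lineages sampled every other
cycle to cycle 35). Mutations reaching 30% are clustered by hierarchical
agglomerative clustering of their trajectory rows, cut at height 0.3.
Default distance is Euclidean with complete linkage — the generic defaults
of the clustering routine this analysis is usually run with; both are
configurable since cohort composition can be sensitive to them. Unsequenced
cycles are linearly interpolated before clustering (a distance needs
complete vectors); singleton cohorts are allowed. A cohort is *fixed* when
its mean trajectory exceeds 90%. Clonal interference is summarised as the
fraction of 30%-risers whose final observed frequency falls back below the
5% detection threshold ("extinction" is operationalised as
below-detection, since sequencing cannot distinguish rare from absent);
with no risers the fraction is undefined (NaN), not zero. New-mutation
rates divide by elapsed cycles, not by the number of sampling points.

## Gene-level parallelism (G scores)

With `N_tot` independent coding mutations over genes of lengths `L_i`
(total `L_tot`), gene i expects `E_i = N_tot · L_i / L_tot` hits and scores
`G_i = 2 N_i ln(N_i / E_i)` (0 at `N_i = 0`; negative when under-hit). An
independent mutation is one unique (lineage, replicon, position, alt)
combination at ≥5% frequency — the same site in two lineages counts twice,
repeated listings once; intergenic rows are excluded, as are rows whose
gene is absent from the annotation (logged). The null redistributes `N_tot`
hits multinomially by length, 1000 times by default; per-gene Z scores get
one-sided upper-tail normal P values (the question is over-representation
only), Bonferroni-adjusted. The normal tail, rather than an empirical
quantile of the 1000 simulations, is what makes extremely small P values
expressible. Genes never hit in any simulation have undefined Z and receive
a conservative P = 1. The genome-wide sum of G is tested the same way
against the null sums. The per-gene normal approximation is mildly
anti-conservative for very short genes (discrete counts, skewed G); at
genome scale (≈5000 genes, under one expected hit per gene) the realised
Bonferroni type-I rate stays below the nominal 0.01.

## Competitive indexes

`CI = (test_out / ref_out) / (test_in / ref_in)`, scale-invariant, shared by
all assay types (nodule pools, nodule occupancy, medium, rhizosphere) with
the assay as metadata. A zero reference or inoculum count makes the CI
undefined; undefined values are excluded from means and logged, never
imputed. Significance against CI = 1 uses a one-sided Student t-test: when
every replicate exceeds 1 the inverses are tested below 1 (the reciprocal
scale is better behaved for strongly competitive strains); otherwise the
CIs are tested directly, one-sided in the direction of the sample mean —
the direction is not prescribed when replicates straddle 1, so the branch
taken is reported. Zero-variance samples get P = 1 at the null value and
P = 0 otherwise. Strain-level P values are Benjamini–Hochberg adjusted;
verdicts are beneficial / deleterious / neutral at the adjusted 0.05 level.
Within-host proliferation (single-strain per-nodule counts) is compared
with a two-sided Wilcoxon rank-sum test and a mean-ratio gain factor.

Note the per-replicate CI is a ratio estimator: its finite-sample mean
exceeds the true CI (Jensen's inequality via the reciprocal of the
reference count). At 96 nodules the relative bias is ≈ +2% at CI = 1 and
≈ +6% at CI = 4, vanishing as the assay grows. The tests therefore check
the estimator against its exact binomial-enumeration expectation, not
against the true CI, and separately check that the bias shrinks with assay
size.

## Synthetic data: what it does and does not emulate

Generators produce (i) cohort-structured logistic sweeps — midpoints spread
over the time course with jitter, random steepness, optional
peak-then-decline interference, shared by cohort members up to independent
truncated-normal noise per point; (ii) mutation tables over length-annotated
synthetic genomes with multinomial length-proportional hits and planted
per-gene enrichment multipliers; (iii) binomial nodule-occupancy counts with
a known true CI (a nodule hosts the test strain with probability
CI·r / (1 + CI·r), r the inoculum ratio). Every generated record carries a
serializable truth object. Logistic sweeps are deliberately not simulator
output, so clustering correctness is testable independently of the
evolution model; `sim_to_tables` bridges the two for end-to-end runs.

Not emulated: read-level sequencing noise beyond the per-point frequency
noise (no coverage model by default), per-nodule resolution of population
frequencies, linkage between mutations in the trajectory generator, and any
plant-side biology. Passing recovery tests therefore demonstrates the
statistics, not robustness to alignment or variant-calling artefacts.

## Problem sizes used in the shipped checks

Simulation ensembles use 100 replicates × 50 cycles per bottleneck
condition (B ∈ {10, 100, 3000} plus the reversed ordering at B = 10) with a
10^6-cell rhizosphere. Cohort recovery uses 50 generator seeds (3 cohorts
of 5, noise SD 0.03); parallelism power and type-I use 5000 genes with
N_tot = 3000 and 1000 randomizations; CI recovery uses 10^4 replicates of a
96-nodule assay per true CI. On one CPU the full acceptance run takes a few
minutes, dominated by the simulation ensembles.

## Known limitations

- The per-cycle mutation rate `U` and the effect-size distribution are
  package defaults chosen for qualitative realism (see above), not fitted
  values; quantitative fold-effect magnitudes depend on them.
- Cohort clustering defaults (Euclidean, complete linkage) are one
  reasonable choice among several; published cohort sizes from any real
  dataset may not be exactly reproducible under them.
- The G-score machinery assumes a homogeneous per-base hit rate within
  coding regions; mutational spectrum heterogeneity along the genome is not
  corrected for.
- Nodule co-occupancy (>1 strain per nodule) is not modelled anywhere.
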