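# Methods

## The data model: what a chimeric, mixoploid genotype is

A gametophytic blade of a bladed Bangiaceae species develops from the four
meiotic products of one conchospore, so genotyping a blade pools up to
four haploid genotypes; blades can additionally be diploid or tetraploid
chimeras. Fragment analysis of such a blade reports, per microsatellite
locus, the **set of distinct allele sizes present** — between 1 and 8 —
with no information on copy number (dosage) or on the ploidy of the tissue
genotyped. All of `mixopop` is organised around this observed-set
representation (`GenotypeDataset`): alleles are positive integer sizes on
a repeat-unit grid, a cell is a set or missing, and nothing downstream
ever pretends to know dosage it does not have.

Because the four tetrad products jointly carry every allele copy of the
parental sporophyte, the observed set of a fully sampled, dropout-free
blade equals the sporophyte's distinct-allele set: at most 2 distinct
alleles for a diploid sporophyte, 4 for a tetraploid, 8 for an octoploid.
This *tetrad-union rule* is the bridge between the simulator's latent
sporophytes and the observable data.

## Assumed-ploidy recoding

`recode_dataset(ds, m, seed)` produces the dataset "as m-ploid",
m ∈ {2, 4, 8}. Cells with more than m distinct alleles are reduced to a
uniformly drawn m-subset. The draw is keyed by
(seed, individual_id, locus_name) through a CRC32-seeded generator, so the
retained subset for a cell is independent of processing order and
reproducible across platforms; subsets are enumerated in lexicographic
allele order and indexed by the seeded stream. Recoding never invents
alleles and never changes missingness. A cell is flagged
`ambiguous_dosage` iff 1 < |retained| < m: a single allele is an
unambiguous homozygote, and |retained| = m forces one copy each, so only
the intermediate cases carry dosage uncertainty.

Because downstream statistics depend on the subsampling draw, analyses
accept a `replicates` count (default 10) and report the spread over
replicate dosage resolutions alongside the spread over loci.

## ML dosage correction (EM)

For one population × locus at assumed ploidy m, the observed data are
phenotypes φ (allele sets). The model: a genotype is a multiset of m
gametes drawn i.i.d. from the population frequencies p (the
Hardy–Weinberg analogue for ploidy m), and a phenotype is compatible with
exactly the multisets whose support equals φ (presence/absence is taken as
correctly observed; dropout is a simulator concept, not a likelihood
term). The EM:

* E-step: posterior weights over compatible multisets, proportional to the
  multinomial prior m!/(∏c_a!) ∏ p_a^{c_a};
* M-step: p ← expected allele counts / (m·n).

Initialisation is uniform over the observed alleles; convergence is
max |Δp| < 1e-8 with a 10 000-iteration cap (flagged, best estimate
returned, if hit). The log-likelihood trace is stored and asserted
non-decreasing in tests. At m = 2 every phenotype has a single compatible
genotype and one M-step reproduces allele counting exactly. Selfing and
double reduction are not modelled; the prior is free random union of
gametes.

### A property worth knowing

On truly diploid data coded at a higher assumed ploidy, the ML fit
systematically *deflates* gene diversity (by roughly 0.05–0.13 in H_S in
our simulations, growing with allelic richness): the polyploid HWE
likelihood can only explain the observed excess of single-allele
phenotypes by skewing the frequencies. The same downward shift from 2× to
4×/8× appears in real diversity tables produced this way. Diversity values
are therefore comparable *within* a coding, not across codings — unlike
the AMOVA F_CT, which is stable across codings (below).

## Diversity

H_S = 1 − Σ p² from the EM frequencies, averaged over loci per population;
EN = 1/(1 − H_S) applied to the locus-averaged H_S, so the EN/H_S
bijection holds exactly at that level; SDs reported over loci. H_S is
deliberately uncorrected for sample size: the finite-sample correction
needs a defined number of allele copies, which dosage ambiguity does not
provide. Tools that apply a small-sample correction will differ slightly.

## Pairwise differentiation

Per locus for a pair of populations: H̄_S is the mean of the two
within-population diversities and H_T the diversity of the mean frequency
vector. G_ST = (H_T − H̄_S)/H_T; Jost's D = 2(H_T − H̄_S)/(1 − H̄_S)
(pairwise factor k/(k−1) = 2). Multi-locus G_ST is the ratio of locus
sums (averages), per Nei; multi-locus D is the harmonic mean of per-locus
D, which tends to 0 as any locus value does — per-locus values are stored
raw, including small-sample negatives. H_T = 0 (shared monomorphism)
defines the statistic as 0.

## Four-level AMOVA

Levels: within individuals (w) / among individuals within populations (c)
/ among populations within groups (b) / among groups (a). Each individual
is expanded to m allele copies per locus; an ambiguous cell is resolved by
a uniform draw over its compatible dosage multisets, per replicate — this
resampling matches the spirit of the recoding itself and keeps the ANOVA
machinery standard (an EM-posterior-weighted variant was considered and
set aside to keep the estimator design simple and the replicate spread
interpretable). Distance between allele copies is 0/1 identity in state;
a stepwise (repeat-count) metric would weight size differences and is not
used.

Sums of squares use the standard pairwise-distance identity
SS = (1/n)Σ_{i<j} d_ij (for 0/1 distance this equals (n − Σc²/n)/2), with
method-of-moments expected mean squares. Copies per individual are
constant (= m), so the individual-level coefficient is exactly m; the
population/group coefficients use the standard unequal-size formulas
k₃ = (N − Σ_g Σ_{p∈g} n_p²/n_g)/(P − G),
k₅ = (Σ_g Σ_{p∈g} n_p²/n_g − Σ n_p²/N)/(G − 1),
k₆ = (N − Σ n_g²/N)/(G − 1). Loci are combined by pooling SS and df
(df-weighted coefficients when missingness makes per-locus coefficients
differ — identical to the exact computation on complete data); per-locus
components are retained for SDs over loci. Components may be negative and
are propagated, not truncated.

F-statistics: F_CT = σ²_a/σ²_tot, F_SC = σ²_b/(σ²_b+σ²_c+σ²_w),
F_IS = σ²_c/(σ²_c+σ²_w), F_IT = (σ²_a+σ²_b+σ²_c)/σ²_tot. A 0/0 ratio
(every lower level monomorphic) is reported as 0; zero total variance
yields NaN with a warning. A group containing a single population makes
σ²_b inestimable and raises an error advising a merge or drop.

**No permutation p-values are produced.** The groupings tested here are
themselves derived from the genetic data (cluster assignments), so testing
them against permutations of that data would be circular; the AMOVA is
used descriptively, to compare the *strength* of alternative groupings and
codings.

Note that F_IS and F_IT are strongly coding-dependent by construction
(cycling/dosage expansion manufactures within-individual copies), while
F_CT and F_SC — ratios among the between-unit components — are the
quantities stable across assumed ploidies. The cross-coding F_CT spread on
simulated chimeric data is below 0.01 in our default conditions.

## PCA

Individuals × (locus, allele) matrix of within-individual relative
frequencies: each retained allele gets weight 1/|retained| at its locus.
Missing loci are imputed with the individual's population column means
(global mean as fallback) rather than the global mean, so missingness
cannot mimic between-population structure. Columns are centered;
coordinates come from the SVD; axis signs are fixed by making the
smallest-index near-maximal loading positive (floating-point-tie safe), so
row order never changes the result.

## ΔK and ancestry tables

ΔK(K) = mean over replicates of |L(K+1) − 2L(K) + L(K−1)|, divided by the
sample SD (ddof = 1) of L(K) over replicates, with replicates paired by
index across a consecutive K range; undefined at the boundary Ks; zero SD
raises (the division is undefined — add replicates or jitter). Mean
per-population ancestries average over individuals and replicates after
greedy correlation matching of cluster columns to the first replicate;
matches with correlation < 0.5 warn about unresolved label switching. The
MCMC clustering itself is external: the package writes its input files
(one row per allele copy, unknown dosage filled by cycling the observed
alleles — a `missing_fill` variant codes the extra copies as missing
instead — missing = −9) and parameter files, and parses its output.

## Haplotype networks

Identical sequences merge into haplotypes labelled A, B, … in order of
first appearance. Default ambiguity policy excludes from comparison any
column where *any* record carries a non-ACGT(/gap) character; gaps are a
fifth state by default (the target alignments are coding and gap-free).
Distances are Hamming counts over compared sites. The network grows
Kruskal-style over distance classes; all edges joining components that
were distinct before the class is processed are kept (ties retained), so
the edge set always contains a minimum spanning tree. The optional
`max_steps` cap excludes longer edges and can leave divergent haplotypes
isolated — a deliberate, documented stand-in for a statistical-parsimony
connection limit, whose probability recursion is not re-implemented here.

## The simulator

Frequencies: per locus, a hyper-ancestral vector ~ symmetric Dirichlet(1)
over `alleles_per_locus` sizes on the grid offset + k·repeat_unit;
species pools drift from it by a Balding–Nichols step with parameter
`species_divergence`; clusters from species with `fct_sim`; populations
from clusters with `fsc_sim` (Dirichlet(p·(1−F)/F); F = 0 copies the
parent; zero-frequency alleles stay zero). These parameters are recovered
by the corresponding AMOVA components, which is the simulator's main
design goal and is asserted in tests (F_CT within 0.05 of 0.25, F_SC
within 0.03 of 0.10 under the test conditions).

Individuals: sporophyte ploidy ~ `ploidy_weights` over {2, 4, 8}; each
locus gets m/2 maternal + m/2 paternal gamete draws; with probability
`hybrid_fraction` the paternal gametes come from a random population of
the other species. The blade phenotype is the distinct-allele set with
each allele independently dropped with `dropout_prob` (one parameter
subsumes PCR dropout and unsampled chimera sectors; a locus losing all
alleles is missing). `selfing_rate` is reserved: with a single
un-subdivided gamete pool per population it cannot change the sampling
distribution, so it is accepted and ignored.

cpDNA: one root sequence per species (roots differ at ~1% of sites, floor
8 — two well-separated plastid clades); each population's pool holds the
species root plus `cp_haps_per_pool − 1` single-substitution derivatives
(star-like, shallow intraspecific variation; no recombination). Maternal
inheritance; hybrid-lineage individuals carry the *other* species' root
haplotype with probability `introgression_prob`.

Default conditions (two species × two regional clusters × five populations
× 22 blades = 440 individuals, 10 loci, 8 possible alleles,
`species_divergence` = 0.30 giving among-species F_CT ≈ 0.25 at the 2×
coding, `fct_sim` = 0.10 and `fsc_sim` = 0.07 giving within-species
F_SC ≈ 0.16, mixed ploidies 0.50/0.35/0.15, 2% hybrids, 5% dropout,
1141-bp cpDNA) were chosen once to emulate a realistic two-species
Northeast-Atlantic-style survey and are not tuned per analysis.

What the simulator does **not** emulate: coalescent ancestry and drift
history (frequencies are one Dirichlet draw, so the evolutionary variance
across loci is larger than a shared demographic history would give),
linkage, microsatellite mutation during the pedigree, selection, spatial
geography, within-blade mixtures of sporophyte ploidies (the observable
union is identical, so only the union is modelled), and genotyping
artefacts beyond symmetric dropout. Passing tests therefore demonstrate
estimator correctness under the stated model, not robustness to every
real-data pathology.

## Numerical choices and degenerate inputs

* EM: tol 1e-8 on max frequency change, max_iter 10 000, uniform
  initialisation; log-sum-exp guarded weights.
* Subset draws: lexicographic enumeration + seeded index (stable across
  platforms and processing order).
* AMOVA: SS pooled over loci before components; negative components
  propagated; 0/0 F-ratios reported 0; zero-variance data NaN + warning.
* Allele binning: nearest grid point, exact half-unit ties rounded down,
  sizes below the offset clamp to the offset.
* PCA: SVD with deterministic sign convention; population-mean imputation.
* ΔK: sample SD (ddof 1); replicate pairing by index.
* Problem sizes in tests and the acceptance script (440 × 10 loci for the
  robustness replay; 500 tetraploids for EM recovery; 160 individuals for
  parameter recovery) are the package's default study conditions and keep
  a full run in seconds on one core.

## Known limitations

* F_IS (and any inbreeding inference) is undefined at m > 2 from
  presence/absence data alone; values produced by the AMOVA's dosage
  resampling at 4×/8× reflect the resolution scheme, not biology, and the
  library deliberately offers no dosage-free F_IS estimator.
* H_S lacks a small-sample correction (see above) and shifts downward when
  the assumed ploidy exceeds the true one.
* The ΔK statistic cannot evaluate K = 1 or K = K_max, and inherits all
  the usual caveats of likelihood-based K selection.
* The network cap is a user parameter, not a parsimony probability
  computation.
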