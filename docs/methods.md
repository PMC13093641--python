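# Methods

`demogscape` re-implements, as a tested pipeline, the computational core of
a two-population landscape- and demographic-genomic analysis of a
medium-dispersal forest ungulate sampled along a north–south gradient:
ddRAD-style SNP filtering, summary statistics, structured-coalescent
simulation, SFS composite-likelihood demographic model selection,
landscape-resistance and Mantel analyses, and a PCA-based selection scan.
Everything runs end-to-end on synthetic data with known generative truth.

## The demographic model family

Two demes (north, south) descend from an ancestral population of effective
size `N_anc` that splits `T_div` years ago. Post-divergence histories are a
2 x 6 factorial family: deme sizes either constant or changing once per
deme (`N_old -> N_recent` at `T_change`), crossed with gene-flow regimes
none / early-only / recent-only / constant / rate-change / interrupted
(on–off–on around a hiatus), giving 12 scenarios. Parameters are expressed
in natural units — years, diploid effective sizes, per-generation migration
probabilities — and converted to generations with a generation time of
2.5 years. The per-site mutation rate is 2.38e-9 per generation; loci are
300 bp and unlinked with no intra-locus recombination (appropriate for
short RAD loci). Divergence times are constrained to 20,000–100,000 years.

The shipped best-fit parameterization is the changed-size / interrupted-flow
scenario: `N_anc = 534,000`; divergence 66,033 years ago; post-divergence
sizes 28,407 (south) and 57,679 (north), expanding to 190,000 at 41,000
years and 81,000 at 32,000 years respectively; gene flow with backward
rates 8.19e-3 (north→south) and 4.25e-3 (south→north), interrupted between
45,820 and 30,660 years ago. Two printed variants of the hiatus bounds
exist in the source material; the figure-caption pair above parameterizes
the fixture and both pairs are kept as named constants.

**Migration-rate convention.** Rates are carried as backward lineage-jump
probabilities: `m_ns` is the per-generation probability that a southern
lineage's ancestor was northern, matching the MIG-matrix convention of
SFS-based inference tools, so printed rates are usable directly. A helper
converts forward fractions under conservative migration (the two coincide
there). Printed sizes are interpreted as diploid individuals
(`size_units="diploid"`, coalescence rate C(k,2)/(2N)); a `"haploid"`
switch covers gene-copy conventions.

## Coalescent engine

The simulator is a backward-time Markov jump chain on lineage
configurations: within an epoch, a deme holding `k` lineages coalesces at
rate `k(k-1)/2 / (2N_d)` per generation and each lineage migrates at the
epoch's backward rate; at `T_div` all lineages enter the ancestral deme.
The continuous-time exponential approximation to discrete Wright–Fisher
generations is used (error O(1/N)). The event loop is numba-compiled
(~2–4k genealogies/s for 40-sample models). Mutations are infinite-sites:
Poisson(mu L x branch length) per branch.

Per-locus randomness comes from a `SeedSequence` stream indexed by locus,
so locus `i` is identical regardless of the total locus count
(counter-mode fan-out). Genotype emission pairs haplotypes into diploids
randomly within demes.

For expected spectra the mutational expectation is taken analytically:
each branch contributes its length x mu L to the joint frequency class of
its subtended leaves (a Rao–Blackwellization of mutation sprinkling),
which substantially reduces Monte-Carlo variance at no cost in bias.
Validated against msprime on constant-size, bottleneck and
divergence-with-migration histories (total-variation distance of the mean
normalized SFS at Monte-Carlo resolution), and against closed forms:
E[T2] = 2N; E[pi] = 4N mu; singleton spectrum proportional to 1/i; island
model pair coalescence times E[T_w] = 4N and E[T_b] = 4N + 1/(2m). Note
msprime's `ploidy=1` populations coalesce at rate 1/size, so its sizes are
supplied as gene copies (2N) in the cross-checks.

## Composite-likelihood inference

The observed statistic is the folded joint SFS (ancestral states are
unpolarized in ddRAD data; unfolded spectra are available for simulation
work). The likelihood is the multinomial composite likelihood over
polymorphic cells, `log10 L = sum O_ij log10 p_ij`, with `p` the
probability-normalized Monte-Carlo expected spectrum. Zero cells are
floored at `1/(10 x n_sims x n_cells)` and renormalized so observed mass
never meets a zero probability. AIC is `2k - 2 ln(10) log10 L`.

**ECM.** Maximization is cyclic conditional 1-D optimization. Size and
rate parameters (log scale) are updated by argmax over an 11-point log
grid spanning 6-fold around the current value; time parameters use bounded
golden section. Common random numbers are reused within a cycle.

**Path reweighting.** The expensive part of profiling and ECM is the
expected spectrum per candidate parameter value. For candidates that share
the reference's divergence time and allow no migration while the reference
is merged, one genealogy ensemble simulated at the reference is *exactly*
reweighted to every candidate: the log path density of any two-deme history
that is piecewise constant on a fixed time partition is linear in per-cell
sufficient statistics (coalescence and migration counts; integrals of
k(k-1)/2, k0 k1 and k per cell), so the log importance weights for a whole
grid are one matrix product. Spectra are self-normalized importance
averages with an effective-sample-size guard (default 150–200): low-ESS
candidates fall back to direct simulation. This realizes common random
numbers at the path level — likelihood *differences* along a profile share
all genealogical noise — and makes otherwise-unusable Monte-Carlo budgets
informative. Divergence-time grids admit no dominating reference when
ancient gene flow runs up to the merger, so those profiles are evaluated
by direct simulation (20,000 genealogies per grid point by default).

**Profile recovery.** `profile_suite` simulates one observed SFS from the
fixture (default 2,000 loci, 20+20 haploid samples, Poisson mutations) and
profiles each parameter on a 25-point grid (log for sizes/rates, linear
across the 20–100 ky bound for the divergence time), all other parameters
held at truth; the estimate is the grid argmax. Grid points structurally
inconsistent with the held parameters (e.g. a divergence time inside the
fixed hiatus) receive zero likelihood. At this study scale the strongly
identified parameters (ancestral size, recent sizes, rates, divergence
time) recover within a few grid steps; the mid-epoch sizes are weakly
identified and their argmax varies by roughly ±30% across observed-data
realizations — a property of the data size, not of the estimator.

**Model selection.** `model_select` runs independent ECM fits per
scenario, then re-evaluates every scenario's best point with a shared
high-precision seed (10,000 simulations) so the AIC comparison is made on
a common Monte-Carlo footing. Self-consistency is exercised at a reduced
budget (1,200 loci, 14+14 samples, 3 ECM cycles x 250 simulations,
scenarios 1/4/7/12): the generative interrupted-flow scenario is expected
to rank first by AIC in at least 7 of 10 replicates. These problem sizes
are the package's test-scale defaults; the full-budget settings of the
original workflow (40 cycles, 100,000 simulations, 100 runs) remain plain
arguments.

## Landscape and matrix tests

Slope (degrees) is reclassified by a right-continuous step function on the
published band edges (≤10° → 1, ≤40° → 1.5, ≤60° → 4, ≤80° → 6, else 10;
the published bands leave gaps, resolved by assigning each gap to the next
band's value). Land use maps Forest 1, Grassland 2, Bare 2, Agricultural 3,
InlandWater 5, BuiltUp 10. The combined surface is the cell-wise product
by default (independent impedances multiply; sum and max are available).
Least-cost distances are Dijkstra on the 8-connected lattice with edge
weight = mean cell resistance x cell size (x sqrt 2 diagonally), exact
against exhaustive path enumeration on toy grids. Geographic distances are
haversine on a 6,371 km sphere. Environmental dissimilarity is Bray–Curtis
on min–max-scaled variables by default (Euclidean on z-scores available).
The climate-variable filter greedily resolves every pair with |r| > 0.7 by
keeping the variable whose single-variable distance matrix correlates
better with genetic distance.

Mantel tests correlate lower-triangle entries (Pearson default, Spearman
optional) with simultaneous row/column permutations; the partial test uses
Legendre's residual-permutation method with the covariate removed by least
squares. Defaults: 10,000 permutations; sampling-year covariates enter as
|year_i - year_j| matrices. Type-I error is calibrated in the test suite
(1,000 null replicates within the binomial 95% band at alpha = 0.05).

## Selection scan

The scan follows the pcadapt recipe: PCA of the mean-imputed,
binomial-SD-scaled dosage matrix; per-SNP multiple regression of scaled
dosages on the top-K scores; Mahalanobis distance of the K z-scores under
a robust covariance (correlation shape from the data, per-component MAD
scales — deliberately lighter than a full minimum-covariance-determinant
fit); genomic-inflation correction lambda = median(D²)/chi²_K(0.5) (which
preserves p-value ranks); Benjamini–Hochberg q-values with outliers at
q < 0.01. K is the caller's choice. Calibration: lambda within 10% of 1 on
null data; on 20 planted high-differentiation SNPs among 5,000 neutral
ones (two-deme Balding–Nichols background, F_ST 0.02), mean power ≥ 50%
at empirical false-discovery proportion ≤ 0.2 over 10 replicates.

## Synthetic study bundles

`generate_study(seed)` emulates the study's sampling design: 23 + 23
diploids from the two source populations plus 25 admixed individuals
(one haplotype from each deme), genotypes drawn from the best-fit history
at 2,000 loci; coordinates on a north–south latitudinal gradient with
admixed individuals intermediate; sampling years across a 25-year span;
bioclim-style variables (diurnal range, temperature seasonality, annual
range, driest-month precipitation, precipitation seasonality analogues) as
linear functions of latitude plus site noise; slope and land-use rasters
(ESRI ASCII, 5 km cells) over the sampling region. Twenty loci are
re-drawn under an elevated-divergence variant (divergence time x 6,
migration off) and recorded in the truth record as planted outliers —
migration is suppressed there because, at the best-fit rates, Nm >> 1
would erase any differentiation a deeper split could plant. The truth
record regenerates the bundle bit-identically.

What the generator does *not* emulate: linked sites and LD decay within
loci, allele-dropout and coverage-driven missingness, sequencing error,
spatially continuous (isolation-by-distance within demes) genetic
structure, and real climate–terrain covariance. Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
model, not robustness to those real-data artifacts.

## Numerical choices and limitations

- LD pruning drops the lower-MAF member of each violating pair (ties keep
  the earlier position); r² is the squared Pearson correlation of dosages
  over jointly called individuals (composite LD — the data are unphased),
  0 when fewer than three joint calls.
- Coordinates are VCF 1-based throughout; window arithmetic is inclusive.
- The SFS fold adds each cell to its mirror, halving exact-half cells.
- Hypergeometric projection masses are accumulated as real numbers.
- Euclidean genetic distances over jointly called sites are rescaled by
  sqrt(S/S_joint), unbiased for the squared distance under missingness at
  random.
- Monomorphic corners are excluded from all likelihoods; whether the
  original tool's likelihood includes the monomorphic class is not
  documented, so the multinomial-over-polymorphic form is used and stated.
- Profile grids centered at the generative values presume truth is known —
  they are a recovery diagnostic, not a data-analysis procedure.
- The single-CPU problem sizes quoted above (ensembles of 20–30k paths,
  10–20k direct simulations per divergence-time grid point) were chosen to
  keep full runs in minutes; all are plain arguments.
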