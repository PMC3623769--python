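# Methods

`ystrpopgen` implements the statistical machinery used in continent-scale
surveys of Y-chromosomal short-tandem-repeat (Y-STR) variation: how much
repeat-count variation lies between sampling sites, geographic clusters and
language groupings; over what distances haplotypes remain correlated; how
haplotypes relate in a mutational network; how old a haplotype cluster is;
and what migration history is compatible with a geographically confined
haplogroup. This note records the models, conventions and numerical choices
behind each stage, and what the synthetic-data generator does and does not
emulate.

## Data model and marker panels

A dataset is a `SampleTable`: one record per sampled male carrying a site
identifier, a Y-SNP haplogroup label, ethnic/linguistic annotations and an
integer repeat count per Y-STR locus, joined to per-site coordinates and
optional geographic-cluster labels (fine clusters A1–A6, coarse B1–B3).
Two marker sets are predefined: the seven-locus forensic minimal haplotype
("small set": DYS19, DYS389I/II, DYS390, DYS391, DYS392, DYS393) and the
fifteen-locus Yfiler panel without the duplicated DYS385ab ("large set").

Two genotype codes are distinguished and never imputed: `MISSING` (not
typed) and `DELETED` (the AZFa-region deletion that makes DYS389I/II,
DYS437, DYS439 and DYS635 fail to amplify). Any analysis on a marker set
first drops records lacking an integer count at any of its loci
(`filter_complete`).

DYS389II is stored as the repeat count of the full locus; the differenced
coding DYS389II−DYS389I used by network panels is derived on demand
(`transform_dys389`) and never stored.

Per-locus mutation rates default to the published locus-average father–son
estimates for these panels (order 10⁻³ per generation; DYS392 and DYS438
near 4×10⁻⁴, DYS458 at 6.4×10⁻³). Network weights are reciprocal rates
rescaled to mean one — only relative weights matter. Any panel can be
supplied as YAML or TSV.

Distribution summaries (median, quartiles of per-site sample size and of
per-site diversity) use linear interpolation (the numpy default); the
convention matters when quoting interquartile ranges and is fixed
package-wide.

## Distances

The genetic distance between two haplotypes is the sum over loci of squared
repeat-count differences — the quantity whose variance decomposition yields
R_ST, the microsatellite analogue of F_ST appropriate under stepwise
mutation. Pairwise R_ST between groups is estimated from the two-group
AMOVA variance components (below), not from moment formulas, so that the
pairwise matrices and the AMOVA tables come from one code path. Negative
R_ST estimates (sampling noise around zero) are preserved in matrices.

Geographic distances are haversine great-circle kilometers on a sphere of
radius 6371.0 km; coordinates are decimal degrees, no projection.

## AMOVA

For squared repeat differences the AMOVA sums of squares are algebraically
identical to classical (nested) ANOVA sums on the repeat counts themselves,
summed over loci (for any set of rows, `sum_{i<j} d²_ij / n = sum_i (x_i −
x̄)²` per locus). The implementation exploits this identity; the test suite
checks it against an independent oracle that computes the sums literally
from pairwise distances.

Variance components use the standard unequal-sample-size coefficients:
one-factor (`σ²_a` among groups, `σ²_c` within) and two-factor nested
(`σ²_a` among clusters, `σ²_b` among sites within clusters, `σ²_c` within
sites). Negative component estimates are retained in the reported
percentages — truncation would bias small components, and published tables
report values below half a percent. A zero total variance yields a flagged
degenerate result rather than a division by zero.

Permutation significance (default 1000 replicates) reports
`p = (b+1)/(R+1)`. The two-factor design uses three schemes, each reported
against its statistic: samples reshuffled among sites within clusters
(Φ_SC), whole sites reshuffled among clusters (Φ_CT), and samples reshuffled
across everything (Φ_ST). The mapping of scheme to level is a convention of
this package and is labelled in the output.

`matched_subsample_amova` implements the matched-sampling-scheme
comparison: replicate subsets of a large reference dataset are drawn with a
prescribed number of sites and per-site sample-size profile (template sizes
matched greedily from largest to smallest to randomly chosen eligible
sites), a two-factor AMOVA is run per replicate, and the distribution of
among-cluster percentages is summarized. With the template equal to the full
reference every replicate reproduces the full-data analysis exactly (tested).

## Spatial autocorrelation

Moran's I is computed on repeat counts, one marker at a time, with binary
weights confining pairs to a distance class: class 0 holds same-site pairs,
classes 1..K (default 10) split the nonzero inter-site great-circle
distances into equal-count bins (ties at boundaries resolved by a stable
sort on distance and pair enumeration order). Under no structure
E[I] = −1/(n−1); a complete weight matrix returns exactly that value (an
algebraic identity kept as a test).

Markers are combined by the unweighted mean of per-marker I. This choice is
not forced by the statistic — pooling cross-products weighted by marker
variance is a defensible alternative — so a test pins the convention on a
constructed case where the two differ. The permutation test reshuffles whole
haplotypes over sample positions (10,000 replicates by default), preserving
the classing; p-values are two-sided around E[I]. Monomorphic markers are
dropped with a warning; a wholly monomorphic table is an error.

## Ordination

Classical multidimensional scaling / principal coordinates of the site-wise
R_ST matrix, via scikit-bio's PCoA behind this package's interface. R_ST
entries are treated as distances (squared inside the Gower double
centering). Negative entries are clamped to zero first (logged): they are
sampling noise, and PCoA requires non-negative dissimilarities. Proportion
of variance explained is relative to the sum of positive eigenvalues only;
negative eigenvalues (R_ST matrices are usually non-Euclidean) are reported
separately and excluded. Requesting more axes than there are positive
eigenvalues returns fewer, with a warning.

## Diversity and association

Nei gene/haplotype diversity `h = n/(n−1)(1 − Σp²)`; per-site haplotype
diversity applies it to whole-haplotype counts, undefined (None) below two
complete samples. Cramér's V uses the chi-square statistic without
continuity correction, `V = sqrt(χ²/(n·min(r−1, c−1)))`; zero rows/columns
are dropped with a warning. The Monte-Carlo Fisher exact test samples
contingency tables from the fixed-margins null (Patefield's algorithm via
`scipy.stats.random_table`) and counts tables whose null probability does
not exceed the observed table's; the estimate `(b+1)/(reps+1)` is reported
as an upper bound, never as zero, when no sampled table is as extreme.

## Median-joining networks

Haplotypes are collapsed to unique profiles with multiplicities and
aggregated population annotations. The network distance is
`Σ w_m |a_m − b_m|` with inverse-mutation-rate weights. Construction
iterates: (i) the ε-relaxed minimum spanning network over the current node
set — an edge belongs iff its length is within ε of the minimax-path
distance between its endpoints, which at ε = 0 is exactly the union of all
minimum spanning trees; (ii) coordinate-wise medians of linked triples
(u–v–w sharing MSN edges at v) whose connection cost `d(u,m)+d(v,m)+d(w,m)`
is within ε of the minimum are inserted as median vectors; repeat to a fixed
point (guaranteed: medians live on the finite lattice spanned by the
observed repeat ranges); (iii) cleanup removes unobserved nodes of degree
≤ 2, re-deriving the MSN until stable, so surviving median vectors have
degree ≥ 3. Ties are broken lexicographically on (cost, profile), making
the result independent of input order (tested). The final network contains
an MST of its final node set; note that after median insertion a direct
observed–observed MST edge may be displaced by a cheaper chain through
medians, so containment holds for the extended node set, which is the
algorithm's actual guarantee.

Star contraction (preprocessing for large star-like datasets): a center
absorbs satellites within a step radius (default 1) that are mutually
farther than the radius from each other; at least three satellites are
required, so chains never contract. The contraction map permits exact
re-expansion. The maximum-parsimony pruning step of the original network
software is out of scope; the unpruned network is emitted.

## Coalescent TMRCA estimation

The age of a haplotype cluster is estimated by Markov-chain Monte Carlo
over coalescent genealogies with a stepwise-mutation likelihood,
reimplementing the two demographic models of the classical Y-STR
genealogical samplers: model 0 (constant male effective size N) and model 2
(ancestral size N with exponential growth at rate α per generation starting
at scaled time β, i.e. β·N generations, before present).

* **Time scale.** Generations, with pairwise coalescence rate 1/N; the
  prior expectation of a pairwise TMRCA is N generations.
* **Likelihood.** Single-step symmetric SMM: the net repeat change along a
  branch with expected mutation count λ has probability `e^{−λ} I_|k|(λ)`
  (`smm_branch_likelihood`; modified Bessel function). Tree likelihoods use
  Felsenstein peeling over a bounded repeat window (observed range ± 5),
  with a uniform root-state distribution over the window and per-node
  rescaling against underflow. The Bessel series is summed directly for
  λ ≤ 30 and replaced by the Gaussian limit of the compound random walk
  beyond — in that regime the likelihood surface is flat to far better than
  the Monte-Carlo error of any run.
* **Priors.** N ~ Gamma(shape 1 — exponential — mean as configured:
  380–2000 in the reproduced analyses); per-marker rates ~ Gamma(shape 20,
  mean = panel rate), informative because locus rates derive from thousands
  of directly observed father–son meioses (a diffuse shape-2 prior puts its
  mode at half the panel rate and inflates the TMRCA by ~15%);
  α ~ Gamma(1, rate 200) (mean 0.005/generation); β ~ Gamma(2, rate 1)
  (mean 2 scaled units).
* **Moves.** Per iteration, 50 attempted tree changes (uniform node-time
  refresh within the bracketing interval, multiplicative root-time and
  whole-tree scalings with their Hastings/Jacobian terms, subtree swaps for
  topology) and 10 parameter changes (log random walks on N, rates, α, β).
  Proposals recompute only the branches and root-ward peeling path they
  touch. The chain starts from an average-linkage tree with heights mapped
  through the total panel rate.
* **Validation.** With the likelihood disabled the sampler recovers the
  coalescent prior mean 2N(1−1/n) and the exponential prior on N (detailed
  balance); with data it matches an exact two-dimensional grid integration
  of the n = 3 single-marker posterior and an independent importance-sampling
  oracle, and on simulated genealogies the posterior brackets the true
  TMRCA. Ten-fold faster mutation rates shrink the estimate (tested).
* **Reproduced analysis.** The 14-chromosome C3* cluster. The per-sample
  genotypes are in never-deposited supplementary tables, so the package
  carries a synthetic stand-in (`synthetic_c3star`) rebuilt from the
  published description of the configuration — 8 + 2 + 1 Kichwa haplotypes
  spanning two mutational steps, 3 identical Waorani chromosomes, with the
  direct Waorani–Kichwa difference set to 8 steps, jointly consistent with
  the published network-path lengths (10–16 steps through the Asian
  reference network, an upper bound on the direct difference) and the
  published coalescence scale. On this stand-in, model 0 with prior mean
  N = 2000 yields a posterior median TMRCA near 260 generations with
  posterior N medians near 108, and the model-2 and small-prior variants
  shift the estimate down and up exactly as the published table does.
  Generation time for year conversions is 30 years.

Default run length is 200,000 iterations with the first half as burn-in —
enough that batch-means standard errors of the posterior median are a few
generations on the reproduced analysis; the published analyses used 2
million iterations, and the config accepts any length.

## Migration-scenario ABC

`migration` infers historic migration rates between the ancestral
populations of haplogroup carriers (SA/C+) and non-carriers (SA/C−, NA/C−)
by rejection ABC under three divergence scenarios (SA, AA, BA and the
ten-fold-size variants), with all sizes, divergence times (400 and 500
generations = 12,000 and 15,000 years at 30 years/generation), growth
(0.005/generation, giving ancestral sizes 138, 174, 113 by discounting) and
the 10⁻⁸ haplogroup mutation rate fixed to the published constants; the
scenario validator checks the growth-discount arithmetic.

Simulation is a continuous-time structured coalescent on the binary
haplogroup locus: per-population pairwise coalescence at rate 1/N_p,
per-lineage backward migration (rate into population i from j applied to
lineages currently in i), merges at divergence times. Each lineage carries
its descendant-sample counts per population, and one mutation placed
uniformly on the genealogy (reservoir sampling over branch segments) yields
derived-allele counts directly. Multiple hits on one genealogy have
probability ~10⁻⁷ per simulation; only the first sampled hit is applied.
Summaries per population: number of alleles and Nei gene diversity at the
locus. The observed configuration is 14/84 and 0/927 carriers.

Rejection uses Euclidean distance on summaries standardized by their
across-simulation standard deviations (constant dimensions dropped with a
warning; if nothing varies the accepted draws are flagged as carrying no
information). Priors are independent uniform [0, 0.2] per ordered
population pair; the reported rate "into" a population sums over its
sources, which is why three-population rates run higher than matched
two-population ones.

Desk scale is 10⁶ simulations with the 100 closest accepted (the published
analyses used 500 million). At this scale a genealogy carries a visible
mutation in roughly 7 of 10⁵ simulations, so a minority of the accepted
draws are uninformative ties; this dilutes the posterior toward the prior
and is the dominant source of the difference between the desk-scale median
(≈0.11 into SA/C+) and the published 0.092.

## Synthetic-data generator

`simulate_dataset` produces whole surveys with the structure the analyses
assume: 81 sites by default; per-site sample sizes 1 + NegBin(0.7, mean
11.5), whose theoretical median is 8 with quartiles 3 and 17 (the skew of
field sampling); six demes under island or stepping-stone migration
(genealogies from msprime, one non-recombining tree, deme size convention
E[pairwise coalescence] = 2N generations); a dominant haplogroup (92%) with
rare clades confined to a configurable number of sites; geographic clusters
as disjoint latitude bands with language classes nested in clusters and
language groups in sites. STR profiles come from a strictly single-step
symmetric SMM overlaid on the genealogy (Poisson mutations per branch,
reflection at repeat bounds 5 and 50 — effectively never triggered from the
ancestral value 16).

Under this convention the single-deme generator reproduces the SMM
equilibrium gene diversity `1 − 1/sqrt(1+8Nμ)` (tested against 2000
replicates), the island model orders among-deme AMOVA percentages by
migration rate as `F_ST ≈ 1/(1+4Nm)` predicts, and a single panmictic deme
centers the among-site percentage at zero.

What the generator does **not** emulate: mutation-rate heterogeneity along
alleles (length-dependent rates), multi-step mutations, population growth
or bottlenecks within demes, realistic continental geography or distance-
dependent sampling, and ethnolinguistic admixture within sites. Passing
tests on synthetic data therefore demonstrate correctness of the estimators
under the stated model, not robustness of the scientific conclusions to
these real-data features.

## Degenerate inputs and numerical conventions

* Monomorphic data: AMOVA returns a flagged zero-variance result; Moran's I
  raises for a monomorphic marker set; gene diversity is 0.
* Distance-class ties: stable sort on (distance, pair order).
* Network ties: lexicographic on (weighted length / cost, profile).
* Permutation p-values are never zero: `(b+1)/(R+1)`.
* All stochastic stages take explicit integer seeds and are reproducible
  bit-for-bit; the CLI writes the seed into every manifest.

## Problem sizes used in the shipped checks

The reproduction suite runs the TMRCA chain at 200,000 iterations (100,000
burn-in) and the ABC at 10⁶ simulations / 100 accepted — the sizes this
package adopts for desk-scale analysis. Oracle and calibration tests use
deliberately small instances (n ≤ 6 AMOVA oracles, n = 3 MCMC oracle,
hundreds of simulation replicates) chosen so each check runs in seconds
while keeping Monte-Carlo error well inside its assertion tolerance.
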