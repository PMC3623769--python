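# ystrpopgen

Population-structure analysis of Y-chromosomal short-tandem-repeat (Y-STR)
haplotypes sampled across georeferenced sites — the statistical toolkit
behind continent-scale surveys of male-lineage variation, such as the study
of 1,011 native South American males from 81 sites that asked whether
Y-chromosomal variation tracks geography and language (it largely does not),
dated the locally confined C3* haplogroup cluster in Ecuador, and bounded
the migration rates compatible with its absence elsewhere in the Americas.

It is written for population geneticists who have a haplotype table (sample,
site, Y-SNP haplogroup, linguistic labels, repeat counts per locus) plus
site coordinates, and who want the standard battery of analyses from one
reproducible, scriptable package:

* **AMOVA on R_ST** — one- and two-factor (clusters / sites / samples)
  analysis of molecular variance on squared repeat differences
  `d²(a,b) = Σ_m (a_m − b_m)²`, with unequal-n variance components, Φ/R
  statistics, permutation p-values `(b+1)/(R+1)`, and a matched-subsampling
  scheme that re-samples a reference dataset to a target study's site-size
  profile;
* **Spatial autocorrelation** — Moran's I of repeat counts over great-circle
  distance classes (class 0 = same site, K equal-count classes beyond), null
  expectation `E[I] = −1/(n−1)`, haplotype-reshuffling permutation test;
* **Ordination** — principal coordinates of pairwise R_ST between sites with
  variance-explained per axis;
* **Diversity & association** — Nei gene/haplotype diversity
  `h = n/(n−1)(1 − Σp²)`, Cramér's V, Monte-Carlo Fisher exact tests;
* **Median-joining networks** — weighted (inverse mutation rate) networks
  with median-vector insertion and star contraction;
* **Coalescent TMRCA** — Bayesian MCMC for the age of a haplotype cluster
  under the single-step stepwise mutation model,
  `P(net change = k | λ) = e^{−λ} I_|k|(λ)`, with constant-size and
  growth demographies (models 0 and 2);
* **Migration ABC** — structured-coalescent simulation of
  divergence-with-migration scenarios and rejection ABC on haplogroup
  allele counts and gene diversity;
* **Synthetic surveys** — a generator producing whole datasets with the
  structure the analyses assume (skewed site sizes, dominant haplogroup,
  rare site-confined clades, languages nested in geography, SMM haplotypes
  on msprime genealogies), so every stage is testable without any download.

## Worked example

```python
from ystrpopgen import SimConfig, amova_one_factor, cramers_v
from ystrpopgen.simulate import simulate_dataset
from ystrpopgen.markers import SMALL_SET
from ystrpopgen.studydata import HAPLOGROUP_LANGUAGE_CLASS_COUNTS

# association between haplogroup and language class, from the published
# 5x5 cross-tabulation of all 1011 samples
print(round(cramers_v(HAPLOGROUP_LANGUAGE_CLASS_COUNTS), 4))   # 0.1999

# a synthetic 40-site survey: 4 demes exchanging ~0.1% migrants/generation
cfg = SimConfig(n_sites=40, n_demes=4, deme_size=400.0, migration_rate=0.001,
                rare_clades={"Q1a3": (0.06, 3), "C3*": (0.02, 1)},
                dominant_frequency=0.92, seed=1)
table, sites = simulate_dataset(cfg)            # 430 samples

res = amova_one_factor(table, table.grouping("site"), SMALL_SET,
                       permutations=999, seed=2)
print({k: round(v, 1) for k, v in res.percentages.items()}, res.p_values)
# {'among': 6.1, 'within': 93.9} {'Phi_ST': 0.003}
```

The Cramér's V of 0.1999 is the published association between haplogroup
and language class (printed as 0.20). In the synthetic survey, 6.1% of the
Y-STR variance lies between sampling sites (Φ_ST = 0.061, permutation
p = 0.003) — genuine but weak structure, as expected for demes exchanging
migrants at a rate of 10⁻³ per generation.

The same analyses run from the shell:

```bash
ystrpopgen simulate --config sim.yaml --seed 7 --out data/
ystrpopgen amova   --haplotypes data/haplotypes.tsv --sites data/sites.tsv \
                   --design two --group-by site --cluster-by cluster_A \
                   --permutations 1000 --seed 1 --out results/
ystrpopgen autocorr --haplotypes data/haplotypes.tsv --sites data/sites.tsv \
                    --permutations 10000 --seed 1 --out results/
ystrpopgen tmrca   --model 0 --prior-n 2000 --iters 200000 --burnin 100000 \
                   --seed 1 --out results/
ystrpopgen abc     --scenario SA --sims 1000000 --accept 100 --seed 1 --out results/
```

Every subcommand writes a manifest (inputs, parameters, seeds) next to its
results; rerunning with the same manifest reproduces the outputs
byte-for-byte.

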