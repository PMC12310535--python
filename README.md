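# clankin

Kinship, uniparental-lineage and runs-of-homozygosity analysis for
reconstructing the social organization of a small ancient community from
pseudo-haploid genotype data — with a synthetic two-clan community generator
providing exact ground truth for every inference stage.

## The problem

Ancient-DNA studies of cemetery populations ask social questions with
genetic data: were people buried by descent group? Through which line was
descent reckoned? Did the community marry within itself? The data are
unforgiving — one randomly sampled allele per site per individual
(pseudo-haploid calls), heavy missingness, no phased diploid genotypes — so
the field works with robust summary statistics:

- **Pairwise mismatch (P0)**: the fraction of non-matching pseudo-haploid
  calls between two individuals in 1-Mb windows. For a pair whose genome
  fractions in 0/1/2-haplotype identity-by-descent states are
  (k₀, k₁, k₂), the expected P0 normalized by the unrelated baseline is
  1 − k₁/4 − k₂/2: 1 for unrelated pairs, 0.875 for second degree, 0.75 for
  first degree, 0.5 for identical genomes. The classification cutoffs
  0.90625 / 0.8125 / 0.625 are the midpoints between those expectations;
  the baseline is the cohort median of mean P0.
- **Relationship-model likelihoods**: per-window P0 modelled as a normal
  mixture over IBD states with weights (k₀, k₁, k₂), separating
  relationships of equal expected P0 by the window-level variance they
  induce; a log-likelihood ratio > 1 against the unrelated model marks a
  call reliable.
- **Uniparental lineages**: mtDNA (maternal) and Y (paternal) haplogroups,
  assigned by similarity score against the theoretical ancestral/derived
  allele states of a haplogroup tree, with a ≥ 1,000-called-SNP QC rule;
  lineage composition summarized by Simpson's diversity index
  (plain 1 − Σpᵢ², or unbiased 1 − Σnᵢ(nᵢ−1)/(N(N−1))).
- **ROH and effective population size**: a diploid's runs of homozygosity
  are chromosome tracts delimited by recombination events whose two
  haplotypes coalesce in a common ancestor. With coalescent rate
  λ = 1/(2Nₑ), the expected number of tracts of (Morgan) length l per
  Morgan of map is n(l) = 8λ/(2l + λ)³; binned tract counts (4–8, 8–12,
  12–20 cM) give a Poisson maximum-likelihood estimate of Nₑ with a
  profile-likelihood confidence interval. Individuals with > 40 cM of ROH
  in segments > 20 cM are excluded as recently inbred.
- **Cemetery statistics**: permutation test of matriline–cemetery
  association, Welch t plus label-permutation comparison of intra- versus
  inter-cemetery cumulative IBD, and a Mantel test of burial distance
  against genetic distance.

Because real collections of this kind are access-restricted, the package
ships a first-class synthetic community generator: a pedigree with
configurable clans, endogamy and burial rules; Poisson-crossover gene
dropping of founder haplotypes along a genetic map; and exact truth tables
(pedigree degrees, IBD and ROH segments, uniparental lineages) against
which every stage is validated.

## Worked example

The numbered drivers under `analysis/` run the full study on a simulated
two-clan community (two matrilineal clans, matriclan burial, endogamy 0.8,
60k sites at 50% missingness on a 22-autosome map):

```
python analysis/01_simulate_community.py
python analysis/02_kinship.py
python analysis/03_uniparental.py
python analysis/04_roh_ne.py
python analysis/05_clanstats.py
```

Step 2 prints, for the default seed:

```
cohort baseline P0 (median over 27028 pairs): 0.3293
mismatch classes: {'UNRELATED': 24653, 'SECOND': 1646, 'FIRST': 729}
degree-1 recovery: 721/798 = 90.4%
degree-2 recovery: 1543/3124 = 49.4%
pairs sharing > 100 cM of IBD (>= 12 cM segments): 96.3% of 20234 sharing pairs
```

First-degree pairs are recovered at 90%; second-degree recovery collapses
to 49% because in this heavily endogamous cohort the median pair is itself
related, which biases the P0 baseline downward — the documented failure
mode of median normalization (see `docs/methods.md`). Step 5 then prints
the social-structure result:

```
matriline-cemetery association: 233/233 on the modal matriline, permutation p = 0.0002
intra vs inter cumulative IBD: 625 vs 550 cM (Welch t = 9.3, permutation p = 0.001)
Mantel within N: r = -0.005, p = 0.81 (burial position does not track genetic distance)
burial-organization call: matrilineal-consistent
```

Every individual lies in the cemetery of their matriline, within-cemetery
pairs share more IBD than cross-cemetery pairs, and burial position within
a cemetery is independent of genetic distance — the matrilineal-clan
signature.

The same stages are scriptable through the CLI:

```
$ clankin uniparental simpson --counts 44,2 --estimator plain
0.083176
$ clankin roh expect --ne 500
[4,8) cM   7.8061
[8,12) cM  1.4247
[12,20) cM 0.7074
$ clankin run --config configs/demo.yaml --out out/ --seed 5
```

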