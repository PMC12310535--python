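# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical choices that matter. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The synthetic community

The generator produces a pedigree, not genotype noise dressed as one:
inference stages are validated against segment-level truth read directly off
the gene-dropped haplotypes.

**Pedigree.** Generation 0 consists of founding mothers split between
`n_clans` matrilineal clans (default 2, labelled N and S); all founding
mothers of a clan share an mtDNA lineage but carry mutually unrelated
autosomal founder haplotypes — they stand for an established matriline whose
genealogical connections predate the simulated window. Reproduction runs
through the community's women, the defining property of matrilineal
continuity: each mother takes an internal husband of her own generation with
probability `endogamy_prob` (full-sib unions avoided by default, other-clan
husbands preferred — moiety-style exogamy between clans inside an endogamous
community), otherwise an external male founder carrying two fresh haplotypes
and a fresh Y lineage. Generation-1 fathers are external by necessity, since
generation 0 holds only the founding mothers. Husbands are monogamous while
unmarried candidates remain; when the pool is exhausted, polygyny is
permitted before giving up, and an impossible pool at `endogamy_prob = 1`
raises an error naming the generation. Children take the mother's matriline
and mt lineage, sons the father's Y lineage; offspring counts are Poisson
(`offspring_mean`, default 2.4). An optional `max_generation_size` caps each
generation by random subsampling, which is what makes long-run
constant-size closed populations simulable. Burial follows `burial_rule`:
matriclan (cemetery = matriline), patriclan, or random; burial coordinates
are a Gaussian scatter (sd 4 m) around per-cemetery centres 40 m apart.

**Gene dropping.** Founders carry whole-chromosome haplotype tiles. Each
meiosis draws a Poisson number of crossovers with mean equal to the map
length in Morgans, breakpoints uniform on the cM axis, no interference.
All coordinates are half-open `[start, end)` cM, 0-based; physical
positions follow from a constant per-chromosome cM/bp rate. The default map
has 22 autosomes totalling ~35.3 Morgans; tests use a 3-chromosome
2.4-Morgan toy map for speed.

**Truth tables.** IBD states between two diploids are computed on the
union of tile breakpoints: IBD2 where the haplotypes match pairwise, IBD1
where exactly one founder haplotype is shared; ROH where an individual's
two haplotypes carry the same founder haplotype. Pedigree degrees come from
the recursive kinship coefficient φ with the band rule: degree d when
φ ∈ (1.5·2^−(d+2), 1.5·2^−(d+1)], identical/self 0, beyond degree 6
unrelated. The band rule is deterministic on purpose — truth tables must
not depend on realized recombination.

**Genotypes.** SNP positions are drawn uniformly per chromosome
(proportional to physical length); founder alternate-allele frequencies
follow Beta(0.5, 0.5) truncated to [0.05, 0.95], a folded-spectrum shape
with the truncation keeping mismatch statistics informative at panel-like
sites. Pseudo-haploidization samples one allele per site per individual,
flips it with `error_rate` (default 0.005) and masks it with
`missing_rate` (default 0.5, the scale of low-coverage capture data).

**mtDNA.** Sequences are modelled as mutated-position sets on a
16,569-position circular reference; clans are seeded `clan_mt_divergence`
(default 6) private positions apart, echoing the few-base separation seen
between established matrilines, and each maternal transmission adds a fresh
singleton with probability `mt_mut_prob` (default 0.005 ≈ whole-molecule
per-generation rate).

**What the generator does not emulate:** sequencing reads, post-mortem
damage, contamination, reference bias, the X chromosome, population splits
beyond the external-husband mechanism, or genealogy deeper than the
simulated generations. The last point matters for Nₑ (below). Passing
tests therefore show correctness of the statistics under clean
pseudo-haploid sampling, not robustness to damage-driven artefacts.

## Kinship

P0 is computed in non-overlapping windows of fixed physical span (default
1 Mb) over sites where both individuals are called; windows with fewer than
`min_overlap` (default 20) jointly-called sites are dropped, bounding
per-window variance, and the pair mean is unweighted across retained
windows. Classification divides the mean by a baseline — by default the
cohort median of mean P0 — and applies the strict-less-than cutoffs
0.625 / 0.8125 / 0.90625. The median-baseline assumption (the median pair
is unrelated) is exactly wrong in heavily endogamous cohorts: the baseline
shrinks toward related values and second-degree pairs drift across the
0.90625 boundary. The worked example in the README shows the collapse
(49% second-degree recovery at endogamy 0.8), and `read_classify` accepts
an external baseline for cohorts where a better anchor exists. The
recovery acceptance check runs at moderate endogamy (0.5), where the
median pair is genuinely unrelated, because it is meant to measure the
classifier under its own assumptions rather than the assumption violation.

The model-likelihood classifier treats each retained window's P0 as a
normal mixture over IBD states with weights (k₀, k₁, k₂) and state means
(b, 0.75b, 0.5b); the variance is the binomial m(1−m)/n inflated by a free
factor (default 1.5) absorbing error and linkage clustering. This is a
transparent windowed simplification with the same k-vector semantics as
the field's HMM tools, not a reimplementation of one; at panel densities
of ~10–20 sites per Mb window it separates first degree from unrelated
sharply but parent-child from sibling only through window variance, which
the test suite checks as a variance ordering rather than a classification
claim. The model library includes a third-degree model (0.75, 0.25, 0);
mismatch classes stop at SECOND as the cutoff construction dictates.

## Uniparental lineages

A haplogroup's theoretical genotype is derived at exactly the markers on
its root path, ancestral elsewhere. The similarity score divides matches by
markers compared, so samples of different coverage are comparable; calls
that are neither ancestral nor derived count against every haplogroup
(conservative), and ties are reported as ambiguous rather than broken.
The QC rule requires ≥ 1,000 called markers by default (configurable, since
toy trees have far fewer). Matrilines are the connected components of the
zero-pairwise-difference graph over mtDNA sequences.

Simpson's diversity is exposed in both forms because printed values in
this literature mix them: the unbiased estimator (1 − Σnᵢ(nᵢ−1)/(N(N−1)))
is the default for small male cohorts, where "all distinct" should read 1
exactly; the plain form (1 − Σpᵢ²) is used for mtDNA frequency
compositions. Which estimator a given published value used is often not
stated; reproducing a printed 0.08 from 44:2 requires the plain form, while
a printed 1 from three singletons requires the unbiased form.

## ROH and effective population size

At any fixed position, a diploid's two haplotypes coalesce at time
t ~ Exp(λ), λ = 1/(2Nₑ) (the continuous-time limit of the discrete
geometric; error O(1/Nₑ)). Breakpoints arrive along the chromosome at rate
2t per Morgan. The simulator is a marginal-preserving renewal process: the
chromosome-start tract draws t from the pointwise Exp(λ) marginal, and each
subsequent tract draws from the size-biased Gamma(2, λ), because
breakpoints fall preferentially where TMRCA is high. This is the choice
that makes the process stationary: it reproduces the Exp(λ) marginal at
every position and the tract-count density n(l) = 8λ/(2l + λ)³ exactly
(the plain-Exp redraw, by contrast, overshoots medium-ROH counts severely
and washes out Nₑ sensitivity — the inspection paradox in action). TMRCA
correlations across breakpoints are ignored, as in sequentially-Markov
approximations generally; only the marginal spectrum enters the binning,
so the closed-form oracle stays exact. The msprime cross-check in the test
suite confirms the spectrum against an independent ancestry simulator
within the approximation's tolerance.

Expected bin counts integrate n(l)(L − l)⁺ in closed form per chromosome:
the (L − l)⁺ weight counts tracts delimited by two recombination events on
both sides, and the simulator-versus-oracle comparisons therefore count
interior tracts only, excluding chromosome-end-truncated tracts that the
simulator also returns.

Nₑ is fitted by independent-Poisson likelihood over the 4–8, 8–12 and
12–20 cM bins (totals over retained individuals), maximized on a log grid
from 50 to 20,000 refined by bounded scalar optimization; the 95% CI is
the profile region within 1.92 log-likelihood units of the maximum.
All-zero counts yield an explicitly unbounded upper limit. The inbreeding
exclusion removes individuals with > 40 cM of ROH in segments > 20 cM
(threshold configurable — 50 cM appears as an alternative convention in
the literature this follows), and > 100 cM of such segments flags close
consanguinity.

Truth-ROH from a pedigree only G generations deep misses coalescence older
than G, most of the 4–8 cM spectrum when G is small; Nₑ fitted to a
shallow community is therefore an overestimate, which the analysis driver
states when it happens. The closed-population cross-check runs 45
generations at capped census size, where the fitted Nₑ lands within a
factor of 2 of census (census and effective size are not equal; the band
is wide by design).

## Cemetery statistics

The association statistic counts individuals whose matriline is the modal
matriline of their own cemetery; the null shuffles cemetery labels, and
all permutation p-values use +1 smoothing (defaults: 9,999 permutations in
the pipeline, fewer in desk-scale drivers). The intra/inter comparison
reports the Welch t-test as is conventional, but flags it as
anti-conservative for pair data (pairs sharing an individual are not
independent); the headline number is the label-permutation p, which
preserves the dependence structure by shuffling individual cemetery labels
and recomputing the mean difference. The Mantel test correlates
within-cemetery burial distance with genetic distance
(1 − cumulative IBD / map length), permuting individual identities jointly
in rows and columns; constant coordinates or distances produce an explicit
degenerate result. The burial-organization call is
"matrilineal-consistent" when the association p < 0.01 and mean mtDNA
diversity per cemetery is below mean Y diversity.

## Numerical choices and problem sizes

- Ties at classification cutoffs: strict less-than throughout.
- Windows are physical (bp); segments genetic (cM); EIGENSTRAT .snp files
  store Morgans, converted only at the file boundary. The .geno alphabet is
  {0, 2, 9} — never 1 — because a single sampled allele is stored in a
  diploid container.
- Permutation and simulation seeds are explicit arguments everywhere; a
  (config, seed) pair reproduces byte-identical pipeline reports.
- Calibration checks use the sizes at which their targets are sharp while
  staying at desk scale: 50k-site pairs for the expected-P0 identity,
  1,000 diploids per Nₑ for the simulator-versus-oracle comparison, 50
  replicates of 1,000 diploids for CI coverage, a ~180-individual
  community with 50 sampled for degree recovery, and 20 communities per
  burial rule for discrimination.

## Known limitations

Median-baseline bias under strong endogamy (documented above, by design);
no damage/contamination modelling; the windowed likelihood cannot separate
sibling from parent-child at sparse panels; Nₑ from shallow pedigrees is
biased upward; the coalescent tract process ignores TMRCA correlations
across breakpoints; uniform site placement rather than a real panel's
density profile.
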