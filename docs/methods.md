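# Methods

## The model

`loopqtl` treats gene regulation in cis as a chain of observable
statements: a variant within 1 Mb of a gene associates with its
expression (a cis-eQTL); the variant sits in a restriction fragment that
physically interacts with the fragment containing the gene's promoter (a
looping cis-eQTL); the variant, or a tight LD proxy of it, is a
genome-wide-significant GWAS hit; and the gene's expression tracks the
phenotype. A gene satisfying all four statements in two independent
cohorts is a strong mechanistic candidate. The package implements each
statement as a separately testable stage and a cascade that composes
them.

### Coordinates and fragments

All coordinates are 0-based half-open. The restriction-fragment map is an
exact partition of each chromosome (checked on load); point-to-fragment
assignment is binary search over fragment starts, and the same rule is
used for SNPs as for interaction endpoints. A gene's promoter fragment is
the fragment containing its TSS (plus any explicitly baited fragments);
interactions are stored with fixed bait/other-end roles because the
capture design is asymmetric. Interaction calls are consumed, not made:
rows below the caller's significance score (default 5) are dropped at
load and the threshold is recorded in the run log.

### Cis-eQTL mapping

Hard QC precedes association: imputation info ≥ 0.8, MAF ≥ 5% (always
recomputed from dosages), and an exact Hardy–Weinberg test p > 10⁻⁵ on
hard calls obtained by rounding dosages. The HWE test enumerates the
conditional distribution of the heterozygote count given allele counts in
log space — an exact test, not the χ² approximation, because the filter
operates in the far tail. Expression is inverse normal transformed per
gene (Φ⁻¹((rank − ½)/n), average ranks on ties); every QC-passing variant
with position in [gene start − 1 Mb, gene end + 1 Mb) is tested by OLS of
transformed expression on dosage plus covariates (the first three genetic
PCs of the centered dosage matrix by default). Gene-level significance is
per-gene Bonferroni on the minimum cis p — a deterministic stand-in for
adaptive-permutation gene-level criteria, configurable via `egene_alpha`.
Replication keeps a pair iff the same variant–gene pair passes the same
criterion in the second cohort *and* the effect signs agree; pairs absent
from the replication scan are counted, not raised.

### Partitioned cis-expression heritability

Within each gene's cis window, LD scores restricted to annotation
category C are ℓ(j, C) = Σ_k r̂²_jk a_C(k), with r̂² the squared Pearson
correlation of dosages in the analysis panel itself (self-term included).
An optional small-sample adjustment r̂²_adj = r̂² − (1 − r̂²)/(n − 2),
floored at 0, is available but off by default. Variant rows from all gene
regions are pooled into a single least-squares fit of χ²_j on
{N·ℓ(j, C)} with a free intercept (expected ≈ 1); pooling into one global
τ̄ vector is our declared choice where per-gene fits averaged afterwards
would also have been defensible — a single regression matches the single
reported enrichment value per category and is far more stable at desk
scale. Heteroskedasticity weights (1/ℓ(j, base)) sit behind a flag and
are off by default.

Because the focal annotation (variants in promoter-interacting fragments
∩ open chromatin) changes per gene, category sizes are aggregated as a
weighted overlap matrix, M̄_{C′∩C} = Σ_i |C′ ∩ C in region i| / NSNP_i.
The proportion of cis h² in C′ is Σ_C τ̄_C M̄_{C′∩C} / Σ_C τ̄_C M̄_C
(reported as-is, possibly negative, when a τ̂ is negative), and
enrichment divides it by the average SNP proportion M̄_{C′}/M̄_base.
Uncertainty comes from a delete-one-block jackknife over contiguous gene
blocks (20 by default): gene regions, not variants, are the exchangeable
unit, since deleting variants would break region structure. SE =
√((B−1)/B · Σ_b (θ_(b) − θ̄)²); p = 2(1 − Φ(|est − null|/SE)) with null 1
for enrichment and 0 for τ. A constant statistic across blocks yields
SE = 0 and, at the null, p = 1.

The pipeline's default categories are base, interacting-fragment, and
interacting-fragment ∩ open-chromatin. If the last two coincide on any
delete-one-block subset (possible when every interacting variant is in
open chromatin), the redundant middle category is dropped and logged
rather than letting the jackknife regression degenerate. A fixed
multi-annotation baseline catalogue is out of scope; categories are
user-suppliable annotation sets.

### Looping cis-eQTLs and permutation enrichment

A replicated pair (v, g) is looping iff some interaction has bait in g's
promoter fragments and other end equal to v's fragment; SNPs inside the
bait fragment itself are excluded — the construct is distal regulation,
and promoter-proximal association needs no loop to explain it. Whether a
promoter-proximal SNP should count is genuinely open; exclusion is the
conservative reading and is flagged here rather than asserted as the only
one.

Enrichment of eGenes among looping genes is tested by resampling: the
observed statistic is the fraction of eGenes with ≥ 1 promoter
interaction whose other end contains ≥ 1 of that gene's significant
cis-eQTLs; null draws are equal-size random gene subsets of the tested
universe, each gene keeping its own interaction/variant geometry and
scored by overlap with any of its cis variants; p uses the add-one
estimator (1 + #{null ≥ obs})/(1 + n_perm), with counts compared as
integers so ties are deterministic. The resampling scheme itself is a
declared design choice — reported permutation p-values in this literature
rarely specify what was shuffled — and its calibration is verified by the
label-randomized-null suite rather than assumed.

### GWAS overlap and phenotype correlation

LD proxies use composite (dosage) r², not haplotype r²: it is what a
genotype-matrix pipeline can compute deterministically, and at the r² >
0.80 threshold the two rarely disagree. Both printed thresholds are
strict inequalities (r² > 0.80, GWAS p < 5×10⁻⁸); the proxy search
window is 1 Mb each side. Candidate rows record the total proxy count and
the count inside the specific interacting fragment — the refinement the
loop provides.

BMI is adjusted for age and age² by OLS and the residuals inverse normal
transformed; expression is log transformed (natural log, pseudocount
10⁻⁶ — the source analyses leave base and zero-handling unstated) and
residualized on the technical-factor matrix per gene. Pearson
correlations are Bonferroni-controlled at the replicated-eGene family
size; effect sizes come from the full-vs-null F-test adding BMI to
age/age²/technical covariates (identical to the squared coefficient
t-test for the single added regressor, which the tests assert).
Replication uses a fixed-effects regression — family-structure mixed
models are out of scope because twin data are not simulated — with
Bonferroni over the genes actually tested and a required concordant
direction. Percentages in the cascade report are rounded half away from
zero to one decimal; note that two of the published counterpart figures
(576/4332 printed as 13.4%, 386068/487679 as 79.0%) cannot be reproduced
by any standard rounding rule, so this package prints 13.3% and 79.2% on
those fixtures.

## The synthetic cohorts

The generator emulates the statistical structure the cascade assumes, at
desk scale, with every planted fact recorded in a truth ledger.

- **Genome**: 60 genes on 3 chromosomes, TSSs 2.4 Mb apart so ±1 Mb cis
  windows never overlap; HindIII-like fragments (mean 4 kb, uniform
  0.5–1.5× around it); 40 variants per gene within ±150 kb of the TSS.
- **Genotypes**: two independent haplotypes per sample from a latent
  Gaussian AR(1) copula (blocks of 5, ρ = 0.9 by default) thresholded at
  the MAF quantile — closed-form control of LD decay without coalescent
  machinery. Hardy–Weinberg holds by construction; config flags inject
  HWE-violating (heterozygote-excess) and low-info variants to exercise
  the QC filter.
- **Cohorts**: n = 335 discovery and n = 720 replication — the sample
  sizes of the adipose study design this emulates — sharing variant
  definitions and planted effect signs; the replication cohort redraws
  all noise from separate sub-streams, and a config knob flips a chosen
  fraction of effect signs to create deliberate concordance failures.
- **Expression**: for planted genes (half of all genes), the causal
  variant explains 15% of latent log-expression variance by default
  (population scaling, so the sample share fluctuates as it should);
  technical factors (14, as in the emulated design) and Gaussian noise
  share the remainder. Values are emitted as exp(latent + baseline), an
  FPKM-like positive scale, so the pipeline's log step is genuinely
  exercised. Setting `expression_noise = 0` makes expression an exact
  affine function of dosage.
- **Loops and annotation**: 60% of planted genes get an interaction from
  their promoter fragment to the causal variant's fragment plus an
  open-chromatin interval over the variant; the rest are decoys whose
  causal variant is in no interacting fragment. Every gene also gets
  decoy interactions to variant-free fragments.
- **Phenotype and GWAS**: BMI-like value = Σ driver effects ×
  standardized driver log-expression + 0.10·age − 0.0008·age² + N(0,
  1.5²), ages uniform on 45–74 years. The five driver genes are looping
  planted genes; their causal variants become GWAS index SNPs with p
  drawn log-uniform in [10⁻²⁵, 10⁻⁹], while null GWAS rows draw p
  uniform on (0, 1).

What the generator does *not* emulate: recombination-map realism,
population structure, trans effects, splice variation, cell-type
heterogeneity in expression, genuinely shared LD between GWAS panels and
the cohort, or family structure. Passing tests therefore demonstrate that
the machinery is correct and calibrated under the planted model, not that
the cascade's error rates transfer to real tissue data.

### Heritability-study generator

The partitioned-regression suites use a dedicated region generator:
LD blocks of random size 2–12 at ρ = 0.8 (LD-score variation across
variants is what identifies τ against the free intercept — with
independent variants the base LD score is nearly constant and the
regression is ill-posed), per-variant effects β ~ N(0, σ²_C) with the
focal category (1% of variants) carrying 20× the average per-SNP
heritability, total cis h² = 0.3, 200 genes × 100 variants × 500
samples. Under this construction the true focal enrichment equals the
multiplier exactly, so recovery can be asserted against 20.

## Numerical choices and degenerate inputs

- p-values are floored at 10⁻³⁰⁰; Pearson r is clipped away from ±1
  before the t transform.
- The inverse normal transform requires ≥ 3 distinct values and errors on
  near-constant input; zero-variance genes in the correlation stage are
  recorded as non-significant with a reason instead of raising.
- Missing dosages are mean-imputed per variant at load (fraction logged);
  monomorphic variants are removed by the MAF filter, never raised.
- Rank-deficient designs (collinear categories, collinear technical
  factors) raise errors naming the offending pair.
- All randomness descends from one top-level seed through named
  sub-streams (`SeedSequence([seed, stream])`); reruns are byte-identical,
  which the suite asserts file by file.

## Problem sizes

Defaults are chosen so a full demo runs in ~20 s and the entire test
suite in about a minute on one CPU: 60 genes / 2,400 variants / two
cohorts for the cascade; 200 × 100 × 500 with 50 seeds for enrichment
recovery; 200 runs × 1,000 permutations for permutation calibration; all
genotype-count configurations with n ≤ 50 for the exact-HWE enumeration
check. These sizes are the package's own scaling choices; every
constant is a config field and can be raised.

## Known limitations

- The permutation scheme and the jackknife blocking unit are declared
  design choices, not inferences of any particular published pipeline.
- Composite-LD r² differs slightly from haplotype r² for proxies near
  the threshold.
- The weighted-overlap regression pools all regions; per-gene τ
  heterogeneity is averaged over, and enrichment estimates at small gene
  counts are noisy (the demo's jackknife SE is wide by design honesty,
  not a defect).
- Only the dosage-TSV genotype path is implemented; a VCF front end
  would be a thin addition but is not present.
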