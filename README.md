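# loopqtl

Regulatory variants rarely announce which gene they control: a GWAS hit
typically sits in non-coding sequence, surrounded by dozens of SNPs in
tight linkage disequilibrium, a megabase away from several plausible
targets. `loopqtl` implements an integrative prioritization cascade for
exactly this situation, built around promoter Capture Hi-C (pCHi-C):
if a cis-eQTL SNP lies inside a restriction fragment that physically
loops to the fragment containing its target gene's promoter, the loop
itself nominates the gene — and the interacting fragment shrinks the
credible set from the full LD block to the handful of SNPs it contains.

The package is aimed at statistical geneticists and regulatory-genomics
analysts who want a tested, fully synthetic-data-backed implementation of
the cascade: every stage can be exercised end to end on simulated cohorts
with known planted structure, without any controlled-access data.

## What it computes

**Partitioned cis-expression heritability.** For each gene, per-variant
association χ² statistics from the cis scan are regressed on
category-restricted LD scores ℓ(j, C) = Σ_k r²_jk · a_C(k) computed
within the ±1 Mb cis window, pooled across genes with a free intercept:

    E[χ²_j] = 1 + N · Σ_C τ_C · ℓ(j, C)

Because the focal annotation (variants in promoter-interacting fragments,
restricted to open chromatin) differs per gene, the genome-wide overlap
matrix of standard stratified LD-score regression is replaced by a
**weighted overlap matrix** M̄ = Σ_gene i M_i / NSNP_i, giving

    prop_h²(C′) = Σ_C τ̄_C M̄_{C′∩C} / Σ_C τ̄_C M̄_C
    enrichment(C′) = prop_h²(C′) / (M̄_{C′} / M̄_base)

with delete-one-gene-block jackknife standard errors and Z-based
p-values.

**The prioritization cascade.**

1. Variant QC (info ≥ 0.8, MAF ≥ 5%, exact Hardy–Weinberg p > 10⁻⁵) and
   per-gene cis-eQTL scans (±1 Mb, inverse-normal-transformed expression,
   genetic PCs as covariates); eGenes by per-gene Bonferroni.
2. Replication: same variant–gene pair significant in the second cohort
   with a concordant direction of effect.
3. Looping cis-eQTLs: SNP in the other-end fragment of an interaction
   whose bait is the target gene's own promoter fragment
   (promoter-proximal SNPs excluded); eGene enrichment by permutation.
4. GWAS overlap: genome-wide-significant variants (p < 5×10⁻⁸) expanded
   to LD proxies (r² > 0.80) and intersected with looping cis-eQTLs.
5. BMI correlation: age/age²-adjusted, inverse-normal-transformed BMI
   against technical-factor-corrected log expression, Bonferroni over the
   replicated-eGene family, full-vs-null F-test effect sizes, and
   direction-concordant replication.

A synthetic-cohort generator (`loopqtl.simulate`) emits every input the
cascade consumes — fragment map, interactions, dosages, expression,
phenotype, GWAS table — with a truth ledger of planted causal variants,
looping geometry, and phenotype-driver genes.

## Worked example

```
loopqtl demo --seed 2018 --out-dir results/demo
```

or equivalently, script by script:

```
python analysis/01_simulate_cohorts.py   --out-dir results/analysis
python analysis/02_map_cis_eqtls.py      --out-dir results/analysis
python analysis/03_partition_heritability.py --out-dir results/analysis
python analysis/04_call_looping_eqtls.py --out-dir results/analysis
python analysis/05_overlap_gwas.py       --out-dir results/analysis
python analysis/06_prioritize_genes.py   --out-dir results/analysis
```

At the default seed the run prints, among other things:

```
31 eGenes; 94 of 104 significant pairs (90.4%) replicated with a
concordant direction; 30 replicated eGenes enter the downstream cascade.

Open chromatin within promoter interactions: 46.1% of cis-expression
heritability from 0.76% of SNPs per region (enrichment 61.0, jackknife
SE 31.9, p = 0.06).

18 of 30 replicated eGenes (60.0%) loop to one of their own cis-eQTL
SNPs (permutation p = 0.000999, 1000 permutations).

5 genes are tagged by a genome-wide-significant variant through a
looping cis-eQTL.

Cascade: egenes:31 -> replicated_egenes:30 -> looping_egenes:18 ->
bmi_correlated:5 -> bmi_replicated:5 -> gwas_candidates:5
```

Reading: of 60 simulated genes, 30 carry a planted cis effect and are
recovered as replicated eGenes; the 18 genes whose causal variant was
planted inside an interacting open-chromatin fragment are exactly the
looping eGenes (60% of eGenes versus 30% of the gene universe, hence the
permutation p at its floor); the focal annotation captures a large share
of cis heritability from well under 1% of SNPs; and the five
phenotype-driver genes — the only ones given genome-wide-significant
GWAS signals in LD with their looping cis-eQTLs — survive every stage,
while no decoy gene does. The per-gene outputs (`partition.tsv`,
`looping.tsv`, `gwas_candidates.tsv`, `candidate_genes.tsv`,
`cascade.json`) land in the run directory.

## Layout

- `src/loopqtl/` — the library: `genome` (fragment maps, intervals),
  `simulate` (synthetic cohorts + truth ledger), `eqtl` (QC and cis
  scans), `heritability` (partitioned LD-score regression), `loops`
  (looping eQTLs, permutation enrichment), `gwas` (LD proxies,
  candidates), `prioritize` (BMI correlation and cascade report),
  `pipeline`/`cli` (stage orchestration).
- `analysis/` — numbered narrative drivers over the same stage functions.
- `docs/methods.md` — the model, simulation design, and numerical
  choices.
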