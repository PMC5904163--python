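"""Synthetic two-cohort study generator with a known truth ledger.

Emulates the statistical structure the downstream cascade assumes: a
restriction-fragment map, genes with baited promoter fragments, LD-blocked
genotypes (Gaussian-copula AR(1) haplotypes), cis-regulated expression on
an FPKM-like positive scale, promoter interactions placing causal variants
in open-chromatin other-end fragments, GWAS summary statistics in LD with
planted variants, and a BMI-like phenotype driven by a chosen gene subset.

Two cohorts (discovery and replication) share variant definitions and
planted effect signs, so replication-concordance filtering has a
well-defined truth; the replication cohort redraws all noise from a
separate sub-stream. Every emitted file is byte-identical under a fixed
seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import io as lio
from .eqtl import GenotypeMatrix
from .genome import (AnnotationSet, FragmentMap, GeneModel, GenomicInterval,
                     Interaction, digest_genome)

__all__ = [
    "SimulationConfig",
    "TruthLedger",
    "Cohort",
    "SimulatedStudy",
    "simulate_study",
    "write_study",
    "simulate_h2_regions",
]


@dataclass
class SimulationConfig:
    """Knobs of the planted-signal study; defaults are the demo conditions.

    Cohort sizes mirror the discovery/replication sample sizes of the
    adipose study design (335 and 720); ages are uniform on 45-74 years;
    14 technical factors act on log expression only.
    """

    seed: int = 2018
    n_discovery: int = 335
    n_replication: int = 720
    n_genes: int = 60
    n_chromosomes: int = 3
    gene_spacing: int = 2_400_000
    region_halfwidth: int = 150_000
    gene_length: int = 20_000
    fragment_size_mean: int = 4_000
    n_variants_per_gene: int = 40
    ld_block_size: int = 5
    ld_rho: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_maf_min: float = 0.15
    frac_planted: float = 0.5
    cis_var_share: float = 0.15
    expression_noise: float = 1.0
    frac_looping: float = 0.6
    n_decoy_interactions: int = 2
    n_drivers: int = 5
    driver_effect: float = 1.0
    age_lin: float = 0.10
    age_quad: float = -0.0008
    phenotype_noise_sd: float = 1.5
    n_technical: int = 14
    tech_effect_sd: float = 0.10
    gwas_n: int = 340_000
    n_gwas_null: int = 200
    hwe_violating_fraction: float = 0.0
    low_info_fraction: float = 0.0
    sign_flip_fraction: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo < hi < 0.5 or (0 < lo < 0.5 and hi == 0.5)):
            raise ValueError(f"MAF bounds must satisfy 0 < lo < hi <= 0.5, got {self.maf_range}")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("LD correlation rho must be in [0, 1)")


@dataclass
class TruthLedger:
    """What was planted, for use as an oracle by tests and reports."""

    causal_variant: dict[str, str] = field(default_factory=dict)
    true_beta: dict[str, float] = field(default_factory=dict)
    looping_genes: list[str] = field(default_factory=list)
    decoy_genes: list[str] = field(default_factory=list)
    driver_genes: list[str] = field(default_factory=list)
    driver_effects: dict[str, float] = field(default_factory=dict)
    gwas_causal_variants: list[str] = field(default_factory=list)
    replication_sign_flipped: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLedger":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class Cohort:
    name: str
    genotypes: GenotypeMatrix
    expression: pd.DataFrame          # genes x samples, FPKM-like positive scale
    phenotype: pd.DataFrame           # sample, bmi, age, tf1..tfK


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    fragments: FragmentMap
    genes: list[GeneModel]
    interactions: list[Interaction]
    annotation: AnnotationSet
    discovery: Cohort
    replication: Cohort
    gwas: pd.DataFrame
    truth: TruthLedger


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def _copula_haplotypes(rng: np.random.Generator, n: int, mafs: np.ndarray,
                       block_size: int, rho: float) -> np.ndarray:
    """Dosages from two AR(1)-latent haplotypes thresholded at MAF quantiles."""
    m = mafs.size
    dosage = np.zeros((n, m))
    thresholds = sps.norm.ppf(mafs)
    for _ in range(2):
        z = np.empty((n, m))
        for start in range(0, m, block_size):
            stop = min(start + block_size, m)
            z[:, start] = rng.standard_normal(n)
            for j in range(start + 1, stop):
                z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        dosage += z < thresholds
    return dosage


def simulate_genotypes(cfg: SimulationConfig, mafs: np.ndarray, n_samples: int,
                       rng: np.random.Generator,
                       hwe_violator: np.ndarray | None = None) -> np.ndarray:
    """Dosage matrix (samples x variants); genes are independent LD regions."""
    m_per = cfg.n_variants_per_gene
    cols = []
    for g in range(cfg.n_genes):
        sl = slice(g * m_per, (g + 1) * m_per)
        cols.append(_copula_haplotypes(rng, n_samples, mafs[sl],
                                       cfg.ld_block_size, cfg.ld_rho))
    dosage = np.concatenate(cols, axis=1)
    if hwe_violator is not None and hwe_violator.any():
        # excess heterozygosity: no homozygous-alt genotypes at these sites
        for j in np.flatnonzero(hwe_violator):
            p_het = min(2 * mafs[j], 0.95)
            dosage[:, j] = rng.random(n_samples) < p_het
    return dosage


def _simulate_expression(cfg: SimulationConfig, genes: list[GeneModel],
                         variant_ids: list[str], dosage: np.ndarray,
                         truth: TruthLedger, betas: dict[str, float],
                         tech: np.ndarray, tech_w: np.ndarray,
                         base_level: np.ndarray,
                         rng: np.random.Generator) -> pd.DataFrame:
    """FPKM-like expression: exp(latent), latent = beta * std dosage + rest.

    The causal variant explains ``cis_var_share`` of the latent variance in
    the population; technical factors and Gaussian noise share the rest,
    jointly scaled by ``expression_noise``.
    """
    vidx = {v: j for j, v in enumerate(variant_ids)}
    n = dosage.shape[0]
    latent = np.zeros((len(genes), n))
    for gi, gene in enumerate(genes):
        w = tech_w[gi]
        nongenetic = tech @ w + rng.standard_normal(n)
        nongenetic /= np.sqrt(float(w @ w) + 1.0)
        beta = betas.get(gene.gene_id, 0.0)
        genetic = 0.0
        if beta != 0.0:
            j = vidx[truth.causal_variant[gene.gene_id]]
            x = dosage[:, j]
            maf = min(x.mean() / 2, 1 - x.mean() / 2)
            sd = np.sqrt(max(2 * maf * (1 - maf), 1e-12))
            genetic = beta * (x - x.mean()) / sd
        share = min(beta**2, 0.999)
        latent[gi] = genetic + cfg.expression_noise * np.sqrt(1 - share) * nongenetic
    fpkm = np.exp(latent + base_level[:, None])
    return pd.DataFrame(fpkm, index=[g.gene_id for g in genes],
                        columns=[f"s{i}" for i in range(n)])


def simulate_phenotype(cfg: SimulationConfig, expression: pd.DataFrame,
                       tech: np.ndarray, truth: TruthLedger,
                       rng: np.random.Generator) -> pd.DataFrame:
    """BMI-like value = sum of driver-gene effects + age + age^2 + noise."""
    n = expression.shape[1]
    age = rng.uniform(45, 74, n)
    bmi = 27.0 + cfg.age_lin * age + cfg.age_quad * age**2
    for gene in truth.driver_genes:
        z = np.log(expression.loc[gene].to_numpy())
        z = (z - z.mean()) / z.std()
        bmi = bmi + truth.driver_effects[gene] * z
    bmi = bmi + cfg.phenotype_noise_sd * rng.standard_normal(n)
    out = pd.DataFrame({"sample": expression.columns, "bmi": bmi, "age": age})
    for k in range(cfg.n_technical):
        out[f"tf{k + 1}"] = tech[:, k]
    return out


def simulate_gwas(cfg: SimulationConfig, truth: TruthLedger,
                  variants: pd.DataFrame,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Summary statistics: planted index SNPs far below 5e-8, nulls uniform."""
    meta = variants.set_index("variant")
    rows = []
    for gene in truth.driver_genes:
        v = truth.causal_variant[gene]
        p = 10.0 ** (-rng.uniform(9.0, 25.0))
        effect = np.sign(truth.true_beta[gene] * truth.driver_effects[gene])
        effect = effect * rng.uniform(0.02, 0.08)
        rows.append((v, meta.at[v, "chrom"], int(meta.at[v, "pos"]), p,
                     "bmi", effect))
    causal = set(truth.causal_variant.values())
    null_pool = [v for v in variants["variant"] if v not in causal]
    nulls = rng.choice(null_pool, size=min(cfg.n_gwas_null, len(null_pool)),
                       replace=False)
    for v in nulls:
        rows.append((v, meta.at[v, "chrom"], int(meta.at[v, "pos"]),
                     float(rng.uniform()), "bmi",
                     float(rng.normal(0, 0.01))))
    gwas = pd.DataFrame(rows, columns=["variant", "chrom", "pos", "p",
                                       "trait", "effect"])
    return gwas.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Generate the full two-cohort study with its truth ledger."""
    layout_rng = _rng(cfg.seed, 0)

    # genome layout: genes round-robin over chromosomes, far enough apart
    # that +-1 Mb cis windows never overlap
    genes_per_chrom = -(-cfg.n_genes // cfg.n_chromosomes)
    margin = 1_200_000
    chrom_len = margin * 2 + genes_per_chrom * cfg.gene_spacing
    chrom_lengths = {f"chr{c + 1}": chrom_len for c in range(cfg.n_chromosomes)}

    # HindIII-like digest: fragment lengths uniform around the mean
    cut_sites: dict[str, list[int]] = {}
    for chrom, length in chrom_lengths.items():
        gaps = layout_rng.uniform(0.5, 1.5, int(2.2 * length / cfg.fragment_size_mean))
        pos = np.cumsum(gaps * cfg.fragment_size_mean).astype(int)
        cut_sites[chrom] = [int(p) for p in np.unique(pos[(pos > 0) & (pos < length)])]
    fragments = digest_genome(chrom_lengths, cut_sites)

    genes: list[GeneModel] = []
    variant_rows: list[tuple] = []
    mafs = np.empty(cfg.n_genes * cfg.n_variants_per_gene)
    for g in range(cfg.n_genes):
        chrom = f"chr{g % cfg.n_chromosomes + 1}"
        slot = g // cfg.n_chromosomes
        tss = margin + slot * cfg.gene_spacing
        strand = "+" if g % 2 == 0 else "-"
        if strand == "+":
            start, end = tss, tss + cfg.gene_length
        else:
            start, end = tss + 1 - cfg.gene_length, tss + 1
        genes.append(GeneModel.from_coords(f"gene{g:03d}", chrom, start, end,
                                           strand, tss=tss, fragment_map=fragments))
        pos = np.sort(layout_rng.choice(
            np.arange(tss - cfg.region_halfwidth, tss + cfg.region_halfwidth),
            size=cfg.n_variants_per_gene, replace=False))
        for j, p in enumerate(pos):
            k = g * cfg.n_variants_per_gene + j
            mafs[k] = layout_rng.uniform(*cfg.maf_range)
            variant_rows.append((f"snp_{chrom}_{p}", chrom, int(p), "A", "G",
                                 mafs[k], 1.0))
    variants = pd.DataFrame(variant_rows, columns=["variant", "chrom", "pos",
                                                   "ref", "alt", "maf", "info"])
    if cfg.low_info_fraction > 0:
        low = layout_rng.random(len(variants)) < cfg.low_info_fraction
        variants.loc[low, "info"] = layout_rng.uniform(0.3, 0.79, int(low.sum()))
    hwe_violator = layout_rng.random(len(variants)) < cfg.hwe_violating_fraction

    # plant cis effects; the first planted genes loop, a following batch
    # gets decoy-only geometry
    truth = TruthLedger()
    n_planted = int(round(cfg.frac_planted * cfg.n_genes))
    n_looping = int(round(cfg.frac_looping * n_planted))
    planted_idx = list(range(n_planted))  # contiguous for readability
    betas: dict[str, float] = {}
    interactions: list[Interaction] = []
    annot_intervals: list[GenomicInterval] = []
    occupied = set()  # fragments containing any variant
    for g in range(cfg.n_genes):
        chrom = genes[g].body.chrom
        sl = slice(g * cfg.n_variants_per_gene, (g + 1) * cfg.n_variants_per_gene)
        occupied.update(fragments.assign_many(
            chrom, variants["pos"].to_numpy()[sl]).tolist())
    for rank, g in enumerate(planted_idx):
        gene = genes[g]
        sl = slice(g * cfg.n_variants_per_gene, (g + 1) * cfg.n_variants_per_gene)
        sub = variants.iloc[sl]
        fid_of = fragments.assign_many(gene.body.chrom, sub["pos"].to_numpy())
        distal = (
            (~np.isin(fid_of, list(gene.promoter_fragment_ids)))
            & (np.abs(sub["pos"].to_numpy() - gene.tss) > 5 * cfg.fragment_size_mean)
            & (sub["maf"].to_numpy() >= cfg.causal_maf_min)
            & ~hwe_violator[sl]
            & (sub["info"].to_numpy() >= 0.8)
        )
        choice = layout_rng.choice(np.flatnonzero(distal))
        vrow = sub.iloc[choice]
        sign = 1.0 if layout_rng.random() < 0.5 else -1.0
        truth.causal_variant[gene.gene_id] = vrow["variant"]
        beta = sign * np.sqrt(cfg.cis_var_share)
        truth.true_beta[gene.gene_id] = float(beta)
        betas[gene.gene_id] = float(beta)
        causal_fid = int(fid_of[choice])
        if rank < n_looping:
            for bait in sorted(gene.promoter_fragment_ids):
                interactions.append(Interaction(bait, causal_fid,
                                                float(layout_rng.uniform(5, 15))))
            annot_intervals.append(GenomicInterval(
                gene.body.chrom, int(vrow["pos"]) - 200, int(vrow["pos"]) + 300))
            truth.looping_genes.append(gene.gene_id)
        else:
            truth.decoy_genes.append(gene.gene_id)
    # decoy interactions for every gene: promoter -> variant-free fragments
    for gene in genes:
        bait = min(gene.promoter_fragment_ids)
        lo = fragments.assign(gene.body.chrom, gene.tss - cfg.region_halfwidth)
        hi = fragments.assign(gene.body.chrom, gene.tss + cfg.region_halfwidth)
        pool = [f for f in range(lo, hi + 1)
                if f not in occupied and f != bait]
        for f in layout_rng.choice(pool, size=min(cfg.n_decoy_interactions,
                                                  len(pool)), replace=False):
            interactions.append(Interaction(bait, int(f),
                                            float(layout_rng.uniform(5, 15))))
    annotation = AnnotationSet("dhs", annot_intervals)

    truth.driver_genes = truth.looping_genes[: cfg.n_drivers]
    for gene in truth.driver_genes:
        sign = 1.0 if layout_rng.random() < 0.5 else -1.0
        truth.driver_effects[gene] = float(sign * cfg.driver_effect)
    truth.gwas_causal_variants = [truth.causal_variant[g]
                                  for g in truth.driver_genes]
    if cfg.sign_flip_fraction > 0:
        planted_genes = sorted(betas)
        n_flip = int(round(cfg.sign_flip_fraction * len(planted_genes)))
        truth.replication_sign_flipped = list(
            layout_rng.choice(planted_genes, size=n_flip, replace=False))

    # per-gene technical weights and baseline, shared across cohorts
    tech_w = layout_rng.normal(0.0, cfg.tech_effect_sd,
                               (cfg.n_genes, cfg.n_technical))
    base_level = layout_rng.normal(2.0, 1.0, cfg.n_genes)

    variant_ids = list(variants["variant"])
    cohorts = {}
    for stream, (name, n) in enumerate(
            [("discovery", cfg.n_discovery), ("replication", cfg.n_replication)],
            start=1):
        geno_rng = _rng(cfg.seed, 10 + stream)
        expr_rng = _rng(cfg.seed, 20 + stream)
        phen_rng = _rng(cfg.seed, 30 + stream)
        dosage = simulate_genotypes(cfg, mafs, n, geno_rng, hwe_violator)
        cohort_betas = dict(betas)
        if name == "replication":
            for gene in truth.replication_sign_flipped:
                cohort_betas[gene] = -cohort_betas[gene]
        tech = expr_rng.standard_normal((n, cfg.n_technical))
        expression = _simulate_expression(cfg, genes, variant_ids, dosage, truth,
                                          cohort_betas, tech, tech_w, base_level,
                                          expr_rng)
        expression.columns = [f"{name[0]}{i}" for i in range(n)]
        phenotype = simulate_phenotype(cfg, expression, tech, truth, phen_rng)
        gm = GenotypeMatrix(list(expression.columns), variants.copy(), dosage)
        cohorts[name] = Cohort(name, gm, expression, phenotype)

    gwas = simulate_gwas(cfg, truth, variants, _rng(cfg.seed, 40))
    return SimulatedStudy(cfg, fragments, genes, interactions, annotation,
                          cohorts["discovery"], cohorts["replication"],
                          gwas, truth)


def write_study(study: SimulatedStudy, outdir: str | Path) -> None:
    """Emit every downstream input format plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lio.write_fragment_map(outdir / "fragments.bed", study.fragments)
    lio.write_genes(outdir / "genes.tsv", study.genes)
    bait_genes = {}
    for g in study.genes:
        for fid in g.promoter_fragment_ids:
            bait_genes[fid] = g.gene_id
    lio.write_interactions(outdir / "interactions.tsv", study.interactions,
                           study.fragments, bait_genes)
    lio.write_bed(outdir / "dhs.bed", study.annotation.intervals)
    for cohort in (study.discovery, study.replication):
        cohort.genotypes.write(outdir / f"variants_{cohort.name}.tsv",
                               outdir / f"dosages_{cohort.name}.tsv")
        lio.write_matrix(outdir / f"expression_{cohort.name}.tsv",
                         cohort.expression.rename_axis("gene"))
        lio.write_table(outdir / f"phenotype_{cohort.name}.tsv", cohort.phenotype)
    lio.write_table(outdir / "gwas.tsv", study.gwas)
    study.truth.to_json(outdir / "truth.json")


def simulate_h2_regions(n_genes: int, n_variants: int, n_samples: int,
                        h2: float, focal_multiplier: float, focal_frac: float,
                        seed: int, ld_rho: float = 0.8,
                        block_range: tuple[int, int] = (2, 12)) -> list[dict]:
    """Per-gene cis regions with a focal annotation carrying amplified
    per-SNP heritability.

    Each region has ``n_variants`` dosages in LD blocks of random size
    (copula AR(1) at ``ld_rho``; MAF uniform on 0.1-0.5), so LD scores
    vary across variants the way they do in real cis windows. A fraction
    ``focal_frac`` of variants is focal and its per-SNP heritability is
    ``focal_multiplier`` times the regional average, so the true
    enrichment of the focal category equals the multiplier. Effects are
    drawn N(0, sigma_C^2) per variant. Returns one dict per gene with
    dosages, phenotype, and the m x 2 annotation matrix (base, focal).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 99]))
    m_focal = max(1, int(round(focal_frac * n_variants)))
    share_focal = focal_multiplier * m_focal / n_variants
    if share_focal >= 1:
        raise ValueError("focal category would exceed total heritability")
    var_focal = share_focal * h2 / m_focal
    var_back = (1 - share_focal) * h2 / (n_variants - m_focal)
    regions = []
    for _ in range(n_genes):
        mafs = rng.uniform(0.1, 0.5, n_variants)
        thresholds = sps.norm.ppf(mafs)
        X = np.zeros((n_samples, n_variants))
        for _hap in range(2):
            z = np.empty((n_samples, n_variants))
            j = 0
            while j < n_variants:
                b = min(int(rng.integers(*block_range)), n_variants - j)
                z[:, j] = rng.standard_normal(n_samples)
                for k in range(j + 1, j + b):
                    z[:, k] = (ld_rho * z[:, k - 1]
                               + np.sqrt(1 - ld_rho**2)
                               * rng.standard_normal(n_samples))
                j += b
            X += z < thresholds
        Xs = (X - X.mean(0)) / np.maximum(X.std(0), 1e-9)
        focal = np.zeros(n_variants, dtype=bool)
        focal[rng.choice(n_variants, m_focal, replace=False)] = True
        sigma = np.where(focal, np.sqrt(var_focal), np.sqrt(var_back))
        beta = rng.standard_normal(n_variants) * sigma
        y = Xs @ beta + np.sqrt(max(1 - h2, 1e-9)) * rng.standard_normal(n_samples)
        annot = np.column_stack([np.ones(n_variants), focal.astype(float)])
        regions.append({"dosages": X, "y": y, "annot": annot})
    return regions
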