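"""Variant QC, cis-eQTL mapping, and cross-cohort replication.

The association scan regresses rank-normalized expression on alt-allele
dosage plus covariates, gene by gene, for every QC-passing variant within
1 Mb of either gene end. Gene-level significance uses a per-gene Bonferroni
criterion on the minimum cis p-value; replication requires the same
variant-gene pair to be significant in the second cohort with a matching
direction of effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GeneModel
from .stats import P_FLOOR, hwe_exact_test, inverse_normal_transform, ols_fit

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["variant", "chrom", "pos", "ref", "alt", "maf", "info"]
EQTL_COLUMNS = ["variant", "gene", "beta", "se", "p", "n"]


@dataclass
class GenotypeMatrix:
    """Sample x variant dosage matrix with per-variant metadata.

    ``variants`` carries columns variant/chrom/pos/ref/alt/maf/info; the
    MAF column is always recomputed from the dosages so it stays consistent
    with the data actually analysed. Missing dosages are mean-imputed per
    variant at construction (fraction logged).
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.samples) or m != len(self.variants):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        miss = np.isnan(self.dosages)
        if miss.any():
            frac = miss.mean()
            logger.info("mean-imputing %.3f%% missing dosages", 100 * frac)
            col_mean = np.nanmean(self.dosages, axis=0)
            idx = np.where(miss)
            self.dosages[idx] = col_mean[idx[1]]
        if self.dosages.size and (self.dosages.min() < 0
                                  or self.dosages.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        self.variants = self.variants.reset_index(drop=True).copy()
        freq = self.dosages.mean(axis=0) / 2.0
        self.variants["maf"] = np.minimum(freq, 1.0 - freq)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self) -> pd.Index:
        return pd.Index(self.variants["variant"])

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.samples, self.variants.loc[mask].reset_index(drop=True),
            self.dosages[:, np.asarray(mask)],
        )

    def write(self, variants_path: str | Path, dosages_path: str | Path) -> None:
        self.variants[VARIANT_COLUMNS].to_csv(variants_path, sep="\t", index=False)
        df = pd.DataFrame(self.dosages.T, index=self.variants["variant"],
                          columns=self.samples)
        df.to_csv(dosages_path, sep="\t", index_label="variant")

    @classmethod
    def read(cls, variants_path: str | Path,
             dosages_path: str | Path) -> "GenotypeMatrix":
        variants = pd.read_csv(variants_path, sep="\t")
        dosages = pd.read_csv(dosages_path, sep="\t", index_col=0)
        if list(dosages.index) != list(variants["variant"]):
            raise ValueError("variant order differs between metadata and dosage files")
        return cls(list(dosages.columns), variants, dosages.to_numpy().T)


def filter_variants(gm: GenotypeMatrix, maf_min: float = 0.05,
                    hwe_p_min: float = 1e-5,
                    info_min: float = 0.8) -> GenotypeMatrix:
    """Apply the imputation-QC inclusion criteria.

    A variant is retained iff MAF >= maf_min, imputation info >= info_min
    and the exact Hardy-Weinberg test p-value (on hard calls obtained by
    rounding dosages) exceeds hwe_p_min. Monomorphic variants fall out via
    MAF = 0.
    """
    hard = np.rint(gm.dosages).astype(int)
    hwe_p = np.array([
        hwe_exact_test(int((col == 0).sum()), int((col == 1).sum()),
                       int((col == 2).sum()))
        for col in hard.T
    ])
    keep = (
        (gm.variants["maf"].to_numpy() >= maf_min)
        & (gm.variants["info"].to_numpy() >= info_min)
        & (hwe_p > hwe_p_min)
    )
    logger.info("variant QC: %d of %d retained (MAF>=%.3g, info>=%.3g, HWE p>%.3g)",
                int(keep.sum()), gm.n_variants, maf_min, info_min, hwe_p_min)
    return gm.subset_variants(keep)


def genetic_pcs(gm: GenotypeMatrix, n_pcs: int = 3) -> np.ndarray:
    """Leading principal components of the centered dosage matrix (SVD)."""
    X = gm.dosages - gm.dosages.mean(axis=0)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    return u[:, :n_pcs] * s[:n_pcs]


def map_cis_eqtls(gm: GenotypeMatrix, expression: pd.DataFrame,
                  genes: list[GeneModel], covariates: np.ndarray | None = None,
                  cis_window: int = 1_000_000,
                  transform: bool = True) -> pd.DataFrame:
    """Per-gene cis association scan.

    For each gene, every variant with position in
    [gene.start - cis_window, gene.end + cis_window) is tested by OLS of
    the inverse-normal-transformed expression on dosage plus covariates
    (with intercept). Returns a table with columns variant/gene/beta/se/p/n.
    Genes with no cis variants yield no rows (logged). ``transform=False``
    skips the rank normalization for expression that is already on the
    analysis scale.
    """
    n = gm.n_samples
    if list(expression.columns) != list(gm.samples):
        raise ValueError("expression samples do not match genotype samples")
    cov = np.empty((n, 0)) if covariates is None else np.asarray(covariates, float)
    if cov.ndim == 1:
        cov = cov[:, None]
    base = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(base) < base.shape[1]:
        raise ValueError("covariates are rank deficient")
    chroms = gm.variants["chrom"].to_numpy()
    positions = gm.variants["pos"].to_numpy()
    vids = gm.variants["variant"].to_numpy()
    rows: list[tuple] = []
    for gene in genes:
        if gene.gene_id not in expression.index:
            continue
        in_cis = (
            (chroms == gene.body.chrom)
            & (positions >= gene.body.start - cis_window)
            & (positions < gene.body.end + cis_window)
        )
        idx = np.flatnonzero(in_cis)
        if idx.size == 0:
            logger.info("gene %s has no cis variants", gene.gene_id)
            continue
        y = expression.loc[gene.gene_id].to_numpy(dtype=float)
        if transform:
            y = inverse_normal_transform(y)
        for j in idx:
            X = np.column_stack([base, gm.dosages[:, j]])
            beta, se, p, _ = ols_fit(y, X)
            rows.append((vids[j], gene.gene_id, beta[-1], se[-1], p[-1], n))
    return pd.DataFrame(rows, columns=EQTL_COLUMNS)


def call_egenes(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Gene-level significance by per-gene Bonferroni on the minimum cis p.

    A gene is an eGene iff min_p <= alpha / n_variants_tested. Returns one
    row per gene with its lead (minimum-p) variant.
    """
    if results.empty:
        raise ValueError("no cis-eQTL results to summarize")
    recs = []
    for gene, grp in results.groupby("gene", sort=True):
        i = grp["p"].idxmin()
        m = len(grp)
        recs.append((gene, m, results.at[i, "variant"], results.at[i, "p"],
                     alpha / m, bool(results.at[i, "p"] <= alpha / m)))
    return pd.DataFrame(recs, columns=["gene", "n_variants", "lead_variant",
                                       "min_p", "threshold", "is_egene"])


def significant_pairs(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """All variant-gene pairs passing the per-gene Bonferroni threshold."""
    thr = results.groupby("gene")["p"].transform("size")
    return results.loc[results["p"] <= alpha / thr].reset_index(drop=True)


def replicate_concordance(discovery_pairs: pd.DataFrame,
                          replication_results: pd.DataFrame,
                          alpha_rep: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Retain discovery pairs significant and direction-concordant in replication.

    A pair is kept iff the same (variant, gene) passes the replication
    cohort's per-gene Bonferroni criterion at ``alpha_rep`` and the effect
    signs agree. Pairs absent from the replication scan are dropped and
    counted, not raised.
    """
    rep_sig = significant_pairs(replication_results, alpha_rep)
    rep_idx = rep_sig.set_index(["variant", "gene"])["beta"]
    keys = list(zip(discovery_pairs["variant"], discovery_pairs["gene"]))
    present = np.array([k in rep_idx.index for k in keys])
    rep_beta = np.array([rep_idx[k] if ok else np.nan
                         for k, ok in zip(keys, present)])
    concordant = present & (np.sign(rep_beta) == np.sign(discovery_pairs["beta"]))
    retained = discovery_pairs.loc[concordant].reset_index(drop=True)
    tested_keys = set(map(tuple, replication_results[["variant", "gene"]].to_numpy()))
    n_absent = sum(1 for k in keys if k not in tested_keys)
    stats = {
        "n_discovery_pairs": len(discovery_pairs),
        "n_retained": len(retained),
        "n_absent_from_replication": n_absent,
    }
    return retained, stats
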