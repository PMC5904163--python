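"""Looping cis-eQTL definition and permutation enrichment of eGenes.

A cis-eQTL SNP is "looping" for its target gene when both criteria hold:
the SNP falls inside the other-end fragment of a significant promoter
interaction, and the bait of that interaction is the target gene's own
promoter fragment. SNPs inside the bait fragment itself (promoter
proximal) are excluded: the construct is distal regulation through a
chromosomal loop.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import FragmentMap, GeneModel, Interaction

__all__ = [
    "find_looping_eqtls",
    "permutation_enrichment_core",
    "permutation_egene_enrichment",
]

LOOPING_COLUMNS = ["variant", "gene", "bait_fragment", "oe_fragment",
                   "score", "beta", "p", "distance"]


def find_looping_eqtls(pairs: pd.DataFrame, interactions: list[Interaction],
                       fragments: FragmentMap,
                       genes: list[GeneModel],
                       variant_positions: pd.DataFrame) -> pd.DataFrame:
    """Intersect eQTL pairs with promoter interactions at fragment level.

    ``pairs`` carries significant, replicated variant-gene associations
    (columns variant/gene/beta/p at minimum); ``variant_positions`` maps
    variant id to chrom/pos. One output row per (pair, matching
    interaction), with the midpoint distance between bait and other-end
    fragments; output order is canonical (sorted), so it does not depend
    on input ordering.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    by_bait: dict[int, list[Interaction]] = {}
    for ia in interactions:
        by_bait.setdefault(ia.bait_fragment_id, []).append(ia)
    vmeta = variant_positions.set_index("variant")
    rows = []
    for rec in pairs.itertuples():
        gene = gene_by_id.get(rec.gene)
        if gene is None:
            continue
        vfid = fragments.assign(str(vmeta.at[rec.variant, "chrom"]),
                                int(vmeta.at[rec.variant, "pos"]))
        if vfid is None or vfid in gene.promoter_fragment_ids:
            continue
        for bait in gene.promoter_fragment_ids:
            for ia in by_bait.get(bait, []):
                if ia.other_end_fragment_id != vfid:
                    continue
                dist = abs(fragments.fragment(bait).midpoint
                           - fragments.fragment(vfid).midpoint)
                rows.append((rec.variant, rec.gene, bait, vfid, ia.score,
                             rec.beta, rec.p, dist))
    out = pd.DataFrame(rows, columns=LOOPING_COLUMNS)
    return (out.sort_values(["gene", "variant", "bait_fragment", "oe_fragment"],
                            kind="mergesort").reset_index(drop=True))


def permutation_enrichment_core(egene_looping: np.ndarray,
                                universe_looping: np.ndarray,
                                n_perm: int,
                                rng: np.random.Generator) -> tuple[float, float]:
    """Permutation p for the observed fraction of looping eGenes.

    ``egene_looping`` holds the per-eGene overlap indicator;
    ``universe_looping`` the per-gene indicator over the tested universe.
    Null draws resample gene subsets of the eGene-set size from the
    universe; the p-value uses the add-one estimator
    (1 + #{null >= observed}) / (1 + n_perm). Counts are compared as
    integers so exact ties are handled deterministically.
    """
    egene_looping = np.asarray(egene_looping, dtype=bool)
    universe_looping = np.asarray(universe_looping, dtype=bool)
    k, n = egene_looping.size, universe_looping.size
    if k == 0:
        raise ValueError("eGene set is empty")
    if k > n:
        raise ValueError("eGene set larger than the tested universe")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    obs_count = int(egene_looping.sum())
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    null_counts = universe_looping[idx].sum(axis=1)
    p = (1 + int((null_counts >= obs_count).sum())) / (1 + n_perm)
    return obs_count / k, p


def _has_looping_overlap(gene: GeneModel, variant_pos: np.ndarray,
                         by_bait: dict[int, set[int]],
                         fragments: FragmentMap) -> bool:
    oe_sets = [by_bait.get(b) for b in gene.promoter_fragment_ids]
    oe_all: set[int] = set().union(*(s for s in oe_sets if s)) if any(oe_sets) else set()
    oe_all -= set(gene.promoter_fragment_ids)
    if not oe_all or variant_pos.size == 0:
        return False
    fids = fragments.assign_many(gene.body.chrom, variant_pos)
    return bool(np.isin(fids, list(oe_all)).any())


def permutation_egene_enrichment(egenes: list[str], universe: list[str],
                                 interactions: list[Interaction],
                                 genes: list[GeneModel],
                                 fragments: FragmentMap,
                                 sig_variant_pos: dict[str, np.ndarray],
                                 all_variant_pos: dict[str, np.ndarray],
                                 n_perm: int = 10_000,
                                 seed: int = 0) -> dict:
    """Observed looping-eGene fraction and its permutation p-value.

    The observed statistic is the fraction of eGenes with at least one
    promoter interaction whose other end contains at least one of the
    gene's significant cis-eQTL SNPs. Null draws are equal-size random
    gene subsets of the tested universe, scored by the fraction with any
    promoter interaction overlapping any of that gene's cis variant
    positions (each gene keeps its own interaction/variant geometry).
    """
    if not set(egenes) <= set(universe):
        raise ValueError("eGene set must be a subset of the tested universe")
    by_bait: dict[int, set[int]] = {}
    for ia in interactions:
        by_bait.setdefault(ia.bait_fragment_id, set()).add(ia.other_end_fragment_id)
    gene_by_id = {g.gene_id: g for g in genes}
    empty = np.empty(0, dtype=int)
    egene_flags = np.array([
        _has_looping_overlap(gene_by_id[g], np.asarray(sig_variant_pos.get(g, empty)),
                             by_bait, fragments) for g in egenes
    ])
    universe_flags = np.array([
        _has_looping_overlap(gene_by_id[g], np.asarray(all_variant_pos.get(g, empty)),
                             by_bait, fragments) for g in universe
    ])
    rng = np.random.default_rng(seed)
    observed, p = permutation_enrichment_core(egene_flags, universe_flags,
                                              n_perm, rng)
    return {"observed_fraction": observed, "n_egenes": len(egenes),
            "n_universe": len(universe), "n_perm": n_perm, "p": p,
            "seed": seed}
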