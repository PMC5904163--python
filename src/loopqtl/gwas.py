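"""LD-proxy expansion of GWAS index variants and overlap with looping
cis-eQTLs.

An index variant's proxies are the panel variants within a window whose
squared dosage correlation with the index exceeds a strict threshold
(r2 > 0.80 by default, matching the printed criterion); the index belongs
to its own proxy set with r2 = 1. A gene becomes a GWAS candidate when a
genome-wide-significant variant (p < 5e-8, strict) has a proxy that is a
looping cis-eQTL of that gene; the refinement counts record how many
proxies exist in total and how many fall inside the specific interacting
fragment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eqtl import GenotypeMatrix
from .genome import FragmentMap

__all__ = ["ld_r2", "ProxySet", "find_proxies", "gwas_looping_candidates"]

CANDIDATE_COLUMNS = ["gene", "trait", "index_variant", "gwas_p", "n_proxies",
                     "n_proxies_in_fragment", "looping_variants"]


def ld_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (composite LD)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("dosage vectors must share length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("monomorphic dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))


@dataclass
class ProxySet:
    """LD proxies of one index variant: {variant id: r2}, all > threshold."""

    index: str
    proxies: dict[str, float]
    r2_min: float

    def __post_init__(self) -> None:
        self.proxies.setdefault(self.index, 1.0)

    def __len__(self) -> int:
        return len(self.proxies)

    def __contains__(self, variant: str) -> bool:
        return variant in self.proxies


def find_proxies(index_variants: list[str], gm: GenotypeMatrix,
                 r2_min: float = 0.80,
                 window: int = 1_000_000) -> dict[str, ProxySet]:
    """Proxy sets for each index variant from the genotype panel.

    Proxies are panel variants within ``window`` bp of the index with
    r2 strictly above ``r2_min``. An index absent from the panel raises,
    naming it.
    """
    vindex = {v: j for j, v in enumerate(gm.variants["variant"])}
    chroms = gm.variants["chrom"].to_numpy()
    positions = gm.variants["pos"].to_numpy()
    vids = gm.variants["variant"].to_numpy()
    out: dict[str, ProxySet] = {}
    for iv in index_variants:
        if iv not in vindex:
            raise KeyError(f"index variant {iv!r} absent from the genotype panel")
        j = vindex[iv]
        near = np.flatnonzero(
            (chroms == chroms[j]) & (np.abs(positions - positions[j]) <= window)
        )
        x = gm.dosages[:, j]
        if x.std() == 0:
            raise ValueError(f"index variant {iv!r} is monomorphic")
        proxies: dict[str, float] = {iv: 1.0}
        for k in near:
            if k == j or gm.dosages[:, k].std() == 0:
                continue
            r2 = ld_r2(x, gm.dosages[:, k])
            if r2 > r2_min:
                proxies[str(vids[k])] = r2
        out[iv] = ProxySet(iv, proxies, r2_min)
    return out


def gwas_looping_candidates(gwas: pd.DataFrame,
                            proxy_sets: dict[str, ProxySet],
                            looping: pd.DataFrame,
                            fragments: FragmentMap,
                            variant_positions: pd.DataFrame,
                            p_threshold: float = 5e-8) -> pd.DataFrame:
    """Genes whose looping cis-eQTLs tag a genome-wide-significant variant.

    For each GWAS row with p strictly below ``p_threshold``, gene g is a
    candidate iff some proxy of the variant is a looping cis-eQTL of g.
    Counts: total proxies of the index, and proxies falling inside the
    interacting other-end fragment(s) through which g loops to the signal.
    """
    vmeta = variant_positions.set_index("variant")
    loop_by_variant: dict[str, list[tuple[str, int]]] = {}
    for rec in looping.itertuples():
        loop_by_variant.setdefault(rec.variant, []).append((rec.gene,
                                                            rec.oe_fragment))
    rows = []
    for rec in gwas.itertuples():
        if not rec.p < p_threshold:
            continue
        pset = proxy_sets.get(rec.variant)
        if pset is None:
            continue
        hits: dict[str, set[int]] = {}
        loop_vars: dict[str, set[str]] = {}
        for proxy in sorted(pset.proxies):
            for gene, oe in loop_by_variant.get(proxy, []):
                hits.setdefault(gene, set()).add(oe)
                loop_vars.setdefault(gene, set()).add(proxy)
        for gene in sorted(hits):
            oe_frags = hits[gene]
            n_in_frag = 0
            for proxy in pset.proxies:
                fid = fragments.assign(str(vmeta.at[proxy, "chrom"]),
                                       int(vmeta.at[proxy, "pos"]))
                if fid in oe_frags:
                    n_in_frag += 1
            rows.append((gene, rec.trait, rec.variant, rec.p, len(pset),
                         n_in_frag, ",".join(sorted(loop_vars[gene]))))
    out = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    return (out.sort_values(["gene", "index_variant"], kind="mergesort")
            .reset_index(drop=True))
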