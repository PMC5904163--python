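"""Stage orchestration: simulate -> eqtl -> h2 -> loops -> gwas-overlap ->
prioritize -> report.

Each stage reads its upstream files from the run directory and writes its
own outputs there, logging input/output counts and the criterion applied
for every filter. A single top-level seed drives every stage through named
sub-streams, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .eqtl import (GenotypeMatrix, call_egenes, filter_variants, genetic_pcs,
                   map_cis_eqtls, replicate_concordance, significant_pairs)
from .genome import FragmentMap
from .gwas import find_proxies, gwas_looping_candidates
from .heritability import (CisRegion, compute_ld_scores, marginal_chi2,
                           partition_heritability)
from .loops import find_looping_eqtls, permutation_egene_enrichment
from .prioritize import (adjust_expression, adjust_phenotype,
                         assemble_cascade_report, correlate_bmi, lm_bmi_ftest,
                         replicate_correlations)
from .simulate import SimulationConfig, TruthLedger, simulate_study, write_study

logger = logging.getLogger(__name__)

STAGES = ["simulate", "eqtl", "h2", "loops", "gwas-overlap", "prioritize",
          "report"]


@dataclass
class RunConfig:
    """All thresholds of the cascade, at their published defaults."""

    seed: int = 2018
    out_dir: str = "results/demo"
    maf_min: float = 0.05
    hwe_p_min: float = 1e-5
    info_min: float = 0.8
    cis_window: int = 1_000_000
    interaction_score_min: float = 5.0
    r2_min: float = 0.80
    gwas_p_threshold: float = 5e-8
    egene_alpha: float = 0.05
    replication_alpha: float = 0.05
    bmi_alpha: float = 0.05
    bmi_replication_alpha: float = 0.05
    n_genetic_pcs: int = 3
    n_perm: int = 1000
    n_jackknife_blocks: int = 20
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        # one top-level seed feeds every stage
        self.simulation.seed = self.seed

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        d["simulation"]["maf_range"] = list(d["simulation"]["maf_range"])
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        sim = d.pop("simulation", {})
        if "maf_range" in sim:
            sim["maf_range"] = tuple(sim["maf_range"])
        return cls(simulation=SimulationConfig(**sim), **d)


def _setup_run_log(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    root = logging.getLogger("loopqtl")
    path = out_dir / "run.log"
    if not any(isinstance(h, logging.FileHandler)
               and Path(getattr(h, "baseFilename", "")) == path.resolve()
               for h in root.handlers):
        handler = logging.FileHandler(path)
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
        root.addHandler(handler)
        root.setLevel(logging.INFO)


def _require(out_dir: Path, files: list[str], producer: str) -> None:
    for f in files:
        if not (out_dir / f).exists():
            raise FileNotFoundError(
                f"missing {f!r}; run the {producer!r} stage first"
            )


def _load_inputs(cfg: RunConfig, out_dir: Path):
    sim = out_dir / "sim"
    fragments = lio.read_fragment_map(sim / "fragments.bed")
    genes = lio.read_genes(sim / "genes.tsv", fragments)
    interactions = lio.read_interactions(sim / "interactions.tsv", fragments,
                                         score_min=cfg.interaction_score_min)
    annotation = lio.read_annotation_bed(sim / "dhs.bed", "dhs")
    return fragments, genes, interactions, annotation


def _filtered_genotypes(cfg: RunConfig, out_dir: Path,
                        cohort: str) -> GenotypeMatrix:
    sim = out_dir / "sim"
    gm = GenotypeMatrix.read(sim / f"variants_{cohort}.tsv",
                             sim / f"dosages_{cohort}.tsv")
    return filter_variants(gm, cfg.maf_min, cfg.hwe_p_min, cfg.info_min)


def stage_simulate(cfg: RunConfig, out_dir: Path) -> None:
    study = simulate_study(cfg.simulation)
    write_study(study, out_dir / "sim")
    logger.info("simulate: %d genes, %d fragments, %d interactions, "
                "cohorts n=%d/%d", len(study.genes), len(study.fragments),
                len(study.interactions), cfg.simulation.n_discovery,
                cfg.simulation.n_replication)


def stage_eqtl(cfg: RunConfig, out_dir: Path) -> None:
    _require(out_dir, ["sim/genes.tsv"], "simulate")
    fragments, genes, _, _ = _load_inputs(cfg, out_dir)
    results = {}
    for cohort in ("discovery", "replication"):
        gm = _filtered_genotypes(cfg, out_dir, cohort)
        expression = lio.read_matrix(out_dir / "sim" / f"expression_{cohort}.tsv")
        pcs = genetic_pcs(gm, cfg.n_genetic_pcs)
        res = map_cis_eqtls(gm, expression, genes, pcs, cfg.cis_window)
        lio.write_table(out_dir / f"eqtl_{cohort}.tsv", res)
        logger.info("eqtl[%s]: %d variant-gene tests (cis window %d bp)",
                    cohort, len(res), cfg.cis_window)
        results[cohort] = res
    egenes = call_egenes(results["discovery"], cfg.egene_alpha)
    lio.write_table(out_dir / "egenes.tsv", egenes)
    disc_sig = significant_pairs(results["discovery"], cfg.egene_alpha)
    replicated, stats = replicate_concordance(disc_sig, results["replication"],
                                              cfg.replication_alpha)
    lio.write_table(out_dir / "pairs_replicated.tsv", replicated)
    egene_set = set(egenes.loc[egenes["is_egene"], "gene"])
    replicated_egenes = sorted(egene_set & set(replicated["gene"]))
    stats.update({
        "n_egenes": int(egenes["is_egene"].sum()),
        "n_replicated_egenes": len(replicated_egenes),
        "replicated_egenes": replicated_egenes,
    })
    with open(out_dir / "eqtl_summary.json", "w") as fh:
        json.dump(stats, fh, indent=1, sort_keys=True)
    logger.info("eqtl: %d eGenes; %d/%d significant pairs replicated "
                "(direction + per-gene Bonferroni)", stats["n_egenes"],
                stats["n_retained"], stats["n_discovery_pairs"])


def stage_h2(cfg: RunConfig, out_dir: Path) -> None:
    _require(out_dir, ["eqtl_discovery.tsv"], "eqtl")
    fragments, genes, interactions, annotation = _load_inputs(cfg, out_dir)
    gm = _filtered_genotypes(cfg, out_dir, "discovery")
    res = lio.read_table(out_dir / "eqtl_discovery.tsv")
    vmeta = gm.variants.set_index("variant")
    vcol = {v: j for j, v in enumerate(gm.variants["variant"])}
    oe_by_bait: dict[int, set[int]] = {}
    for ia in interactions:
        oe_by_bait.setdefault(ia.bait_fragment_id, set()).add(
            ia.other_end_fragment_id)
    categories = ["base", "pchic", "pchic_dhs"]
    regions: list[CisRegion] = []
    for gene in genes:
        sub = res[res["gene"] == gene.gene_id]
        if sub.empty:
            continue
        oe: set[int] = set()
        for bait in gene.promoter_fragment_ids:
            oe |= oe_by_bait.get(bait, set())
        oe -= set(gene.promoter_fragment_ids)
        if not oe:
            continue  # only genes with >=1 significant promoter interaction
        vids = list(sub["variant"])
        pos = vmeta.loc[vids, "pos"].to_numpy()
        chrom = gene.body.chrom
        fids = fragments.assign_many(chrom, pos)
        in_pchic = np.isin(fids, list(oe))
        in_dhs = annotation.contains_many(chrom, pos)
        annot = np.column_stack([np.ones(len(vids)), in_pchic.astype(float),
                                 (in_pchic & in_dhs).astype(float)])
        chi2 = (sub["beta"].to_numpy() / sub["se"].to_numpy()) ** 2
        region = CisRegion(gene.gene_id, chi2, annot)
        cols = [vcol[v] for v in vids]
        region.ld = compute_ld_scores(gm.dosages[:, cols], annot)
        regions.append(region)
    # the pchic and pchic_dhs columns coincide when every interacting
    # variant sits in open chromatin; that must also hold in every
    # delete-one-block jackknife subset, else the regression degenerates
    has_distinct = np.array([bool(np.any(r.annot[:, 1] != r.annot[:, 2]))
                             for r in regions])
    B = min(cfg.n_jackknife_blocks, len(regions))
    edges = np.linspace(0, len(regions), B + 1).astype(int)
    separable = all(
        has_distinct[: edges[b]].any() or has_distinct[edges[b + 1]:].any()
        for b in range(B)
    )
    if not separable:
        logger.info("h2: pchic and pchic_dhs annotations coincide in a "
                    "jackknife subset; dropping the redundant category")
        categories = ["base", "pchic_dhs"]
        for r in regions:
            r.annot = r.annot[:, [0, 2]]
            r.ld = r.ld[:, [0, 2]]
    part = partition_heritability(regions, gm.n_samples, categories,
                                  n_blocks=cfg.n_jackknife_blocks)
    lio.write_table(out_dir / "partition.tsv", part)
    focal = part.set_index("category").loc["pchic_dhs"]
    logger.info("h2: %d regions; focal enrichment %.2f (SE %.2f), "
                "prop_h2 %.4f from prop_snps %.4f", len(regions),
                focal["enrichment"], focal["se"], focal["prop_h2"],
                focal["prop_snps"])


def stage_loops(cfg: RunConfig, out_dir: Path) -> None:
    _require(out_dir, ["pairs_replicated.tsv", "eqtl_summary.json"], "eqtl")
    fragments, genes, interactions, _ = _load_inputs(cfg, out_dir)
    replicated = lio.read_table(out_dir / "pairs_replicated.tsv")
    res = lio.read_table(out_dir / "eqtl_discovery.tsv")
    with open(out_dir / "eqtl_summary.json") as fh:
        summary = json.load(fh)
    gm = _filtered_genotypes(cfg, out_dir, "discovery")
    looping = find_looping_eqtls(replicated, interactions, fragments, genes,
                                 gm.variants)
    lio.write_table(out_dir / "looping.tsv", looping)
    vpos = gm.variants.set_index("variant")["pos"]
    sig_pos = {g: grp["variant"].map(vpos).to_numpy()
               for g, grp in replicated.groupby("gene")}
    all_pos = {g: grp["variant"].map(vpos).to_numpy()
               for g, grp in res.groupby("gene")}
    universe = sorted(all_pos)
    egenes = [g for g in summary["replicated_egenes"] if g in all_pos]
    enr = permutation_egene_enrichment(
        egenes, universe, interactions, genes, fragments, sig_pos, all_pos,
        n_perm=cfg.n_perm, seed=cfg.seed)
    enr["n_looping_egenes"] = int(round(enr["observed_fraction"]
                                        * enr["n_egenes"]))
    with open(out_dir / "loop_enrichment.json", "w") as fh:
        json.dump(enr, fh, indent=1, sort_keys=True)
    logger.info("loops: %d looping pairs; %d/%d looping eGenes "
                "(observed %.3f, permutation p=%.3g, %d perms)",
                len(looping), enr["n_looping_egenes"], enr["n_egenes"],
                enr["observed_fraction"], enr["p"], cfg.n_perm)


def stage_gwas_overlap(cfg: RunConfig, out_dir: Path) -> None:
    _require(out_dir, ["looping.tsv"], "loops")
    fragments, _, _, _ = _load_inputs(cfg, out_dir)
    gwas = lio.read_table(out_dir / "sim" / "gwas.tsv")
    looping = lio.read_table(out_dir / "looping.tsv")
    gm = _filtered_genotypes(cfg, out_dir, "discovery")
    panel_ids = set(gm.variants["variant"])
    sig = gwas[gwas["p"] < cfg.gwas_p_threshold]
    indices = [v for v in sig["variant"] if v in panel_ids]
    skipped = len(sig) - len(indices)
    if skipped:
        logger.info("gwas-overlap: %d significant GWAS variants absent from "
                    "the QC-passing panel", skipped)
    proxies = find_proxies(indices, gm, cfg.r2_min, cfg.cis_window)
    candidates = gwas_looping_candidates(gwas, proxies, looping, fragments,
                                         gm.variants, cfg.gwas_p_threshold)
    lio.write_table(out_dir / "gwas_candidates.tsv", candidates)
    logger.info("gwas-overlap: %d significant GWAS variants (p<%g), "
                "%d candidate gene-locus pairs", len(indices),
                cfg.gwas_p_threshold, len(candidates))


def stage_prioritize(cfg: RunConfig, out_dir: Path) -> None:
    _require(out_dir, ["eqtl_summary.json", "looping.tsv",
                       "gwas_candidates.tsv"], "gwas-overlap")
    _, genes, _, _ = _load_inputs(cfg, out_dir)
    with open(out_dir / "eqtl_summary.json") as fh:
        summary = json.load(fh)
    egenes_tbl = lio.read_table(out_dir / "egenes.tsv")
    looping = lio.read_table(out_dir / "looping.tsv")
    candidates = lio.read_table(out_dir / "gwas_candidates.tsv")

    data = {}
    for cohort in ("discovery", "replication"):
        phen = lio.read_table(out_dir / "sim" / f"phenotype_{cohort}.tsv")
        expr = lio.read_matrix(out_dir / "sim" / f"expression_{cohort}.tsv")
        tech = phen[[c for c in phen.columns if c.startswith("tf")]].to_numpy()
        data[cohort] = {
            "phen": phen, "expr": expr, "tech": tech,
            "adj_bmi": adjust_phenotype(phen),
            "adj_expr": adjust_expression(expr, tech),
        }

    replicated_egenes = summary["replicated_egenes"]
    looping_egenes = sorted(set(looping["gene"]) & set(replicated_egenes))
    d = data["discovery"]
    corr = correlate_bmi(d["adj_expr"].loc[looping_egenes], d["adj_bmi"],
                         n_family_tests=max(len(replicated_egenes), 1),
                         alpha=cfg.bmi_alpha)
    correlated = corr[corr["significant"]].reset_index(drop=True)
    logger.info("prioritize: %d/%d looping eGenes BMI-correlated at "
                "p < %.3g/%d", len(correlated), len(looping_egenes),
                cfg.bmi_alpha, len(replicated_egenes))

    # full-vs-null F-test effect sizes in the discovery cohort
    age = d["phen"]["age"].to_numpy()
    covs = np.column_stack([age, age**2, d["tech"]])
    lm_rows = []
    for gene in correlated["gene"]:
        logx = np.log(d["expr"].loc[gene].to_numpy() + 1e-6)
        beta, se, p = lm_bmi_ftest(logx, d["phen"]["bmi"].to_numpy(), covs)
        lm_rows.append((gene, beta, se, p))
    lm_tbl = pd.DataFrame(lm_rows, columns=["gene", "beta", "se", "p_lm"])

    r = data["replication"]
    verdicts, rep_summary = replicate_correlations(
        correlated, r["adj_expr"], r["adj_bmi"], alpha=cfg.bmi_replication_alpha)
    replicated_bmi = sorted(verdicts.loc[verdicts["replicated"], "gene"])
    logger.info("prioritize: %d/%d BMI correlations replicated (rate %s%%)",
                rep_summary["n_replicated"], rep_summary["n_tested"],
                rep_summary["replication_rate_pct"])

    candidate_genes = sorted(set(candidates["gene"]) & set(replicated_bmi))
    stages = {
        "egenes": sorted(egenes_tbl.loc[egenes_tbl["is_egene"], "gene"]),
        "replicated_egenes": replicated_egenes,
        "looping_egenes": looping_egenes,
        "bmi_correlated": sorted(correlated["gene"]),
        "bmi_replicated": replicated_bmi,
        "gwas_candidates": candidate_genes,
    }
    chrom_of = {g.gene_id: g.body.chrom for g in genes}
    info = (corr.set_index("gene")[["r", "p"]]
            .join(lm_tbl.set_index("gene"))
            .join(verdicts.set_index("gene")[["beta_rep", "se_rep", "p_rep",
                                              "direction_match"]]))
    trait = candidates.groupby("gene")["trait"].agg(
        lambda s: ",".join(sorted(set(s))))
    info = info.join(trait.rename("gwas_trait"))
    table, cascade = assemble_cascade_report(stages, info)
    table.insert(1, "chrom", table["gene"].map(chrom_of))
    lio.write_table(out_dir / "candidate_genes.tsv", table)
    cascade["bmi_replication"] = rep_summary
    with open(out_dir / "cascade.json", "w") as fh:
        json.dump(cascade, fh, indent=1, sort_keys=True)
    logger.info("prioritize: cascade counts %s", cascade["counts"])


def stage_report(cfg: RunConfig, out_dir: Path) -> dict:
    _require(out_dir, ["cascade.json"], "prioritize")
    with open(out_dir / "cascade.json") as fh:
        cascade = json.load(fh)
    for prev_cur, t in cascade["transitions"].items():
        logger.info("report: %s: %d -> %d (%.1f%%)", prev_cur, t["from"],
                    t["to"], t["pct"])
    return cascade


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "eqtl": stage_eqtl,
    "h2": stage_h2,
    "loops": stage_loops,
    "gwas-overlap": stage_gwas_overlap,
    "prioritize": stage_prioritize,
    "report": stage_report,
}


def run_stage(name: str, cfg: RunConfig):
    """Run one pipeline stage; unknown names list the valid stages."""
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; valid stages: {STAGES}")
    out_dir = Path(cfg.out_dir)
    _setup_run_log(out_dir)
    cfg.to_yaml(out_dir / "config.yaml")  # config echoed verbatim
    logger.info("=== stage %s (seed %d) ===", name, cfg.seed)
    return _STAGE_FUNCS[name](cfg, out_dir)


def run_demo(cfg: RunConfig) -> dict:
    """End-to-end run on a freshly simulated cohort; returns the cascade."""
    for name in STAGES[:-1]:
        run_stage(name, cfg)
    return run_stage("report", cfg)
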