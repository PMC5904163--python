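"""Phenotype adjustment, expression-BMI correlation, replication, and the
final gene-prioritization cascade report.

BMI is adjusted for age and age^2 by OLS and the residuals are inverse
normal transformed; expression is log transformed (natural log, pseudocount
1e-6) and residualized on the technical-factor matrix per gene. Pearson
correlations are Bonferroni-controlled at the size of the replicated eGene
family; effect sizes come from a full-versus-null F-test adding BMI to the
covariate model. Replication in the second cohort requires a Bonferroni
p-value and a matching direction of effect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import P_FLOOR, inverse_normal_transform, ols_fit, round_pct

__all__ = [
    "adjust_phenotype",
    "adjust_expression",
    "bonferroni_threshold",
    "correlate_bmi",
    "lm_bmi_ftest",
    "replicate_correlations",
    "assemble_cascade_report",
]

LOG_PSEUDOCOUNT = 1e-6


def adjust_phenotype(phenotype: pd.DataFrame) -> np.ndarray:
    """Inverse-normal-transformed residuals of BMI on [1, age, age^2]."""
    if len(phenotype) < 4:
        raise ValueError("need at least 4 samples")
    age = phenotype["age"].to_numpy(dtype=float)
    if np.ptp(age) == 0:
        raise ValueError("age is constant; adjustment is degenerate")
    X = np.column_stack([np.ones(len(age)), age, age**2])
    beta, *_ = np.linalg.lstsq(X, phenotype["bmi"].to_numpy(dtype=float),
                               rcond=None)
    resid = phenotype["bmi"].to_numpy(dtype=float) - X @ beta
    return inverse_normal_transform(resid)


def adjust_expression(fpkm: pd.DataFrame,
                      technical: np.ndarray) -> pd.DataFrame:
    """Per-gene residuals of log(FPKM + eps) on the technical factors."""
    T = np.asarray(technical, dtype=float)
    if T.ndim == 1:
        T = T[:, None]
    n = fpkm.shape[1]
    if T.shape[0] != n:
        raise ValueError("technical factor rows must match samples")
    X = np.column_stack([np.ones(n), T])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        cc = np.corrcoef(T, rowvar=False)
        for a in range(T.shape[1]):
            for b in range(a + 1, T.shape[1]):
                if abs(cc[a, b]) > 1 - 1e-12:
                    raise ValueError(
                        f"technical factors {a} and {b} are collinear"
                    )
        raise ValueError("technical factor matrix is rank deficient")
    logx = np.log(fpkm.to_numpy(dtype=float) + LOG_PSEUDOCOUNT)
    beta, *_ = np.linalg.lstsq(X, logx.T, rcond=None)
    resid = logx.T - X @ beta
    return pd.DataFrame(resid.T, index=fpkm.index, columns=fpkm.columns)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    return alpha / n_tests


def correlate_bmi(adj_expression: pd.DataFrame, adj_bmi: np.ndarray,
                  n_family_tests: int, alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of each gene with adjusted BMI, flagged at the
    Bonferroni threshold alpha / n_family_tests."""
    y = np.asarray(adj_bmi, dtype=float)
    n = y.size
    if adj_expression.shape[1] != n or n < 4:
        raise ValueError("expression and BMI must share >= 4 aligned samples")
    thr = bonferroni_threshold(alpha, n_family_tests)
    rows = []
    for gene, expr in adj_expression.iterrows():
        x = expr.to_numpy(dtype=float)
        if x.std() == 0:
            rows.append((gene, np.nan, np.nan, False, "zero variance"))
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        r_c = min(max(r, -1 + 1e-16), 1 - 1e-16)
        t = r_c * np.sqrt((n - 2) / (1 - r_c**2))
        p = max(float(2 * sps.t.sf(abs(t), n - 2)), P_FLOOR)
        rows.append((gene, r, p, bool(p < thr), ""))
    return pd.DataFrame(rows, columns=["gene", "r", "p", "significant", "note"])


def lm_bmi_ftest(expression: np.ndarray, bmi: np.ndarray,
                 covariates: np.ndarray) -> tuple[float, float, float]:
    """BMI effect on expression from the full model, with the p-value of
    the full-versus-null F-test (equal to the coefficient t-test for a
    single added regressor)."""
    y = np.asarray(expression, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    n = y.size
    X_full = np.column_stack([np.ones(n), C, np.asarray(bmi, dtype=float)])
    X_null = X_full[:, :-1]
    beta, se, _, df_full = ols_fit(y, X_full)
    resid_full = y - X_full @ np.linalg.lstsq(X_full, y, rcond=None)[0]
    resid_null = y - X_null @ np.linalg.lstsq(X_null, y, rcond=None)[0]
    rss_full = float(resid_full @ resid_full)
    rss_null = float(resid_null @ resid_null)
    f = (rss_null - rss_full) / max(rss_full / df_full, 1e-300)
    p = max(float(sps.f.sf(f, 1, df_full)), P_FLOOR)
    return float(beta[-1]), float(se[-1]), p


def replicate_correlations(discovery: pd.DataFrame,
                           rep_expression: pd.DataFrame,
                           rep_bmi: np.ndarray,
                           alpha: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Test discovery genes in the replication cohort.

    Each gene present in the replication expression matrix is regressed on
    adjusted BMI (fixed effects); it replicates iff its F-test p-value is
    below alpha / n_tested and the direction of effect matches the
    discovery correlation. Genes absent from replication are counted
    separately, not treated as failures of the test.
    """
    present = [g for g in discovery["gene"] if g in rep_expression.index]
    absent = [g for g in discovery["gene"] if g not in rep_expression.index]
    n_tested = len(present)
    thr = bonferroni_threshold(alpha, n_tested) if n_tested else np.nan
    no_cov = np.empty((len(rep_bmi), 0))
    disc_dir = discovery.set_index("gene")["r"]
    rows = []
    for gene in present:
        beta, se, p = lm_bmi_ftest(rep_expression.loc[gene].to_numpy(),
                                   rep_bmi, no_cov)
        same_dir = bool(np.sign(beta) == np.sign(disc_dir[gene]))
        rows.append((gene, beta, se, p, same_dir,
                     bool(p < thr and same_dir)))
    verdicts = pd.DataFrame(rows, columns=["gene", "beta_rep", "se_rep",
                                           "p_rep", "direction_match",
                                           "replicated"])
    n_rep = int(verdicts["replicated"].sum()) if n_tested else 0
    summary = {
        "n_discovery": len(discovery),
        "n_tested": n_tested,
        "n_absent": len(absent),
        "n_replicated": n_rep,
        "replication_rate_pct": round_pct(n_rep, n_tested) if n_tested else np.nan,
    }
    return verdicts, summary


def assemble_cascade_report(stages: dict[str, list[str]],
                            gene_info: pd.DataFrame | None = None
                            ) -> tuple[pd.DataFrame, dict]:
    """Final candidate table and the cascade counts summary.

    ``stages`` maps stage name to the genes surviving it, in cascade
    order; each stage must be a subset of the previous one (offenders are
    listed otherwise). The summary records the count at every stage and
    the percentage retained at each transition (one decimal, half away
    from zero). ``gene_info`` (indexed by gene) is joined onto the table.
    """
    names = list(stages)
    sets = {name: set(stages[name]) for name in names}
    for prev, cur in zip(names, names[1:]):
        extra = sorted(sets[cur] - sets[prev])
        if extra:
            raise ValueError(
                f"stage {cur!r} contains genes absent from {prev!r}: {extra}"
            )
    stage_of: dict[str, str] = {}
    for name in names:
        for g in sets[name]:
            stage_of[g] = name  # later stages overwrite: furthest stage wins
    table = pd.DataFrame({
        "gene": sorted(stage_of),
        "stage": [stage_of[g] for g in sorted(stage_of)],
    })
    if gene_info is not None:
        table = table.join(gene_info, on="gene")
    counts = {name: len(sets[name]) for name in names}
    transitions = {
        f"{prev}->{cur}": {
            "from": counts[prev],
            "to": counts[cur],
            "pct": round_pct(counts[cur], counts[prev]) if counts[prev] else np.nan,
        }
        for prev, cur in zip(names, names[1:])
    }
    return table, {"counts": counts, "transitions": transitions}
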