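"""Shared statistical primitives: rank-based normalization, the exact
Hardy-Weinberg test on genotype counts, a small OLS helper, and the
reporting rounding rule used throughout the cascade."""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps

__all__ = [
    "inverse_normal_transform",
    "hwe_exact_test",
    "ols_fit",
    "round_pct",
    "format_pct",
    "P_FLOOR",
]

P_FLOOR = 1e-300  # underflow floor for reported p-values


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform, Phi^-1((rank - 0.5) / n).

    Ties receive average ranks; requires at least three distinct values
    (the transform is undefined for a near-constant vector).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if np.unique(values).size < 3:
        raise ValueError("inverse normal transform needs >= 3 distinct values")
    ranks = sps.rankdata(values, method="average")
    return sps.norm.ppf((ranks - 0.5) / values.size)


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg equilibrium p-value from genotype counts.

    Enumerates the conditional distribution of the heterozygote count given
    the allele counts (Wigginton-style) in log space and sums the
    probabilities of all configurations no more likely than the observed
    one. Monomorphic variants return p = 1.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("no genotyped samples")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    # heterozygote count shares parity with the rare-allele count
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    lgamma = math.lgamma
    log_probs = np.array([
        lgamma(n + 1)
        - lgamma((n_rare - h) // 2 + 1)
        - lgamma(h + 1)
        - lgamma(n - (n_rare + h) // 2 + 1)
        + h * math.log(2.0)
        for h in hets
    ])
    log_probs -= log_probs.max()
    probs = np.exp(log_probs)
    probs /= probs.sum()
    p_obs = probs[hets == n_het]
    if p_obs.size == 0:  # parity mismatch: impossible configuration
        raise ValueError(
            f"het count {n_het} incompatible with rare-allele count {n_rare}"
        )
    return float(min(1.0, probs[probs <= p_obs[0] * (1 + 1e-12)].sum()))


def ols_fit(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """OLS of y on X (no implicit intercept): beta, SE, two-sided t-test p, df."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    df = n - k
    if df <= 0:
        raise ValueError(f"zero residual degrees of freedom (n={n}, k={k})")
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as e:
        raise ValueError("rank-deficient design matrix") from e
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), np.inf)
    p = np.maximum(2.0 * sps.t.sf(np.abs(t), df), P_FLOOR)
    return beta, se, p, df


def round_pct(numer: float, denom: float) -> float:
    """Percentage 100*a/b rounded to one decimal, half away from zero."""
    if denom == 0:
        return float("nan")
    x = 100.0 * numer / denom
    return math.copysign(math.floor(abs(x) * 10 + 0.5) / 10.0, x)


def format_pct(numer: float, denom: float) -> str:
    return f"{round_pct(numer, denom):.1f}%"
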