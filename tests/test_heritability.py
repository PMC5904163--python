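"""Partitioned cis-heritability machinery against independent oracles."""

import numpy as np
import pytest

from loopqtl.heritability import (CisRegion, compute_ld_scores, enrichment,
                                  jackknife, marginal_chi2,
                                  partition_heritability, proportion_h2,
                                  regress_partitioned,
                                  weighted_overlap_matrix)


def _region(chi2, annot, ld=None, gene="g"):
    reg = CisRegion(gene, np.asarray(chi2, float), np.asarray(annot, float))
    if ld is not None:
        reg.ld = np.asarray(ld, float)
    return reg


def brute_force_prop_and_enrichment(regions_annot, tau, focal):
    """Independent evaluation of the weighted-overlap ratio definitions:
    explicit per-gene loops, no matrix algebra shared with the package."""
    n_cat = regions_annot[0].shape[1]
    mbar = [[0.0] * n_cat for _ in range(n_cat)]
    for A in regions_annot:
        m = A.shape[0]
        for c1 in range(n_cat):
            for c2 in range(n_cat):
                count = sum(1 for j in range(m) if A[j, c1] and A[j, c2])
                mbar[c1][c2] += count / m
    numer = sum(tau[c] * mbar[focal][c] for c in range(n_cat))
    denom = sum(tau[c] * mbar[c][c] for c in range(n_cat))
    prop = numer / denom
    prop_snps = mbar[focal][focal] / mbar[0][0]
    return prop, prop / prop_snps


class TestLdScores:
    def test_perfectly_correlated_pair(self):
        x = np.array([0.0, 0, 1, 1, 2, 2])
        X = np.column_stack([x, x.copy()])
        annot = np.ones((2, 1))
        ld = compute_ld_scores(X, annot)
        np.testing.assert_allclose(ld, [[2.0], [2.0]], atol=1e-12)

    def test_exactly_orthogonal_variants_self_term_only(self):
        X = np.array([[0.0, 0], [0, 2], [2, 0], [2, 2]])  # r = 0 exactly
        annot = np.array([[1.0, 1], [1, 0]])
        ld = compute_ld_scores(X, annot)
        np.testing.assert_allclose(ld, [[1, 1], [1, 0]], atol=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        X = rng.integers(0, 3, size=(60, 30)).astype(float)
        annot = np.column_stack([np.ones(30),
                                 rng.random(30) < 0.3]).astype(float)
        ld = compute_ld_scores(X, annot)
        m = 30
        expect = np.zeros((m, 2))
        for j in range(m):
            for k in range(m):
                r = np.corrcoef(X[:, j], X[:, k])[0, 1]
                for c in range(2):
                    expect[j, c] += r * r * annot[k, c]
        np.testing.assert_allclose(ld, expect, atol=1e-10)

    def test_base_dominates_subcategories(self, rng):
        X = rng.integers(0, 3, size=(50, 12)).astype(float)
        annot = np.column_stack([np.ones(12), rng.random(12) < 0.5])
        ld = compute_ld_scores(X, annot.astype(float))
        assert np.all(ld[:, 0] >= ld[:, 1] - 1e-12)

    def test_monomorphic_variant_rejected(self):
        X = np.column_stack([np.zeros(10), np.arange(10) % 3])
        with pytest.raises(ValueError, match="monomorphic"):
            compute_ld_scores(X, np.ones((2, 1)))


class TestOverlapMatrix:
    def test_single_gene_fraction(self):
        annot = np.array([[1.0, 1], [1, 0], [1, 0]])  # 3 variants, 1 in C
        mbar = weighted_overlap_matrix([_region([1, 1, 1], annot)])
        assert mbar[1, 1] == pytest.approx(1 / 3)
        assert mbar[0, 0] == pytest.approx(1.0)
        assert mbar[0, 1] == pytest.approx(1 / 3)

    def test_sums_over_genes(self):
        a1 = np.array([[1.0, 1], [1, 0], [1, 0]])
        a2 = np.array([[1.0, 1], [1, 1]])  # both variants in C
        mbar = weighted_overlap_matrix([_region([1, 1, 1], a1),
                                        _region([1, 1], a2)])
        assert mbar[1, 1] == pytest.approx(1 / 3 + 1.0)
        assert mbar[0, 0] == pytest.approx(2.0)  # base diagonal = gene count

    def test_symmetric_and_bounded(self, rng):
        regs = []
        for _ in range(4):
            m = int(rng.integers(3, 8))
            annot = np.column_stack([np.ones(m), rng.random(m) < 0.5,
                                     rng.random(m) < 0.3]).astype(float)
            regs.append(_region(np.ones(m), annot))
        mbar = weighted_overlap_matrix(regs)
        np.testing.assert_allclose(mbar, mbar.T, atol=1e-12)
        for a in range(3):
            for b in range(3):
                assert mbar[a, b] <= min(mbar[a, a], mbar[b, b]) + 1e-12


class TestEquationRatios:
    def test_hand_worked_two_category_example(self):
        # one gene, 4 variants, 1 in C; tau = (1, 2)
        annot = np.array([[1.0, 1], [1, 0], [1, 0], [1, 0]])
        mbar = weighted_overlap_matrix([_region([1] * 4, annot)])
        tau = np.array([1.0, 2.0])
        assert proportion_h2(tau, mbar, 1) == pytest.approx(0.5)
        assert enrichment(tau, mbar, 1) == pytest.approx(2.0)

    def test_focal_base_is_identity(self):
        annot = np.array([[1.0, 1], [1, 0], [1, 0], [1, 0]])
        mbar = weighted_overlap_matrix([_region([1] * 4, annot)])
        tau = np.array([0.7, 1.3])
        assert proportion_h2(tau, mbar, 0) == pytest.approx(1.0)
        assert enrichment(tau, mbar, 0) == pytest.approx(1.0)

    def test_zero_focal_tau_collapses_to_snp_share(self):
        annot = np.array([[1.0, 1], [1, 0], [1, 0], [1, 0]])
        mbar = weighted_overlap_matrix([_region([1] * 4, annot)])
        tau = np.array([1.0, 0.0])
        assert proportion_h2(tau, mbar, 1) == pytest.approx(
            mbar[1, 1] / mbar[0, 0])
        assert enrichment(tau, mbar, 1) == pytest.approx(1.0)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(25):
            n_cat = int(rng.integers(2, 5))
            n_gene = int(rng.integers(1, 6))
            annots = []
            for _ in range(n_gene):
                m = int(rng.integers(2, 7))
                A = (rng.random((m, n_cat)) < 0.5).astype(float)
                A[:, 0] = 1.0
                annots.append(A)
            tau = rng.uniform(0.1, 2.0, n_cat)
            focal = int(rng.integers(0, n_cat))
            regs = [_region(np.ones(A.shape[0]), A) for A in annots]
            mbar = weighted_overlap_matrix(regs)
            prop_bf, enr_bf = brute_force_prop_and_enrichment(annots, tau,
                                                              focal)
            assert proportion_h2(tau, mbar, focal) == pytest.approx(
                prop_bf, abs=1e-12)
            if mbar[focal, focal] > 0:
                assert enrichment(tau, mbar, focal) == pytest.approx(
                    enr_bf, abs=1e-12)


class TestRegression:
    def test_noise_free_tau_recovered_exactly(self, rng):
        n_samples = 400
        tau = np.array([5e-4, 2e-3])
        regs = []
        for _ in range(10):
            m = 15
            X = rng.integers(0, 3, size=(50, m)).astype(float)
            X += (X.std(0) == 0)[None, :] * rng.integers(0, 2, (50, m))
            annot = np.column_stack([np.ones(m), rng.random(m) < 0.4])
            ld = compute_ld_scores(X, annot.astype(float))
            chi2 = 1 + n_samples * ld @ tau
            regs.append(_region(chi2, annot, ld=ld))
        tau_hat, intercept = regress_partitioned(regs, n_samples)
        np.testing.assert_allclose(tau_hat, tau, atol=1e-9)
        assert intercept == pytest.approx(1.0, abs=1e-9)

    def test_collinear_categories_named(self, rng):
        m = 10
        flag = (rng.random(m) < 0.5).astype(float)
        annot = np.column_stack([np.ones(m), flag, flag])
        X = rng.integers(0, 3, size=(40, m)).astype(float)
        ld = compute_ld_scores(X, annot)
        reg = _region(np.ones(m), annot, ld=ld)
        with pytest.raises(ValueError, match="'dup1'.*'dup2'"):
            regress_partitioned([reg], 100, ["base", "dup1", "dup2"])

    def test_null_simulation_tau_near_zero(self):
        from loopqtl.simulate import simulate_h2_regions
        raw = simulate_h2_regions(n_genes=100, n_variants=40, n_samples=300,
                                  h2=1e-9, focal_multiplier=1.0,
                                  focal_frac=0.05, seed=5)
        regs = []
        for d in raw:
            chi2 = marginal_chi2(d["y"], d["dosages"])
            reg = CisRegion("g", chi2, d["annot"])
            reg.ld = compute_ld_scores(d["dosages"], d["annot"])
            regs.append(reg)

        def tau_stat(c):
            def stat(rr):
                return regress_partitioned(rr, 300)[0][c]
            return stat

        for c in range(2):
            est, se, _, _ = jackknife(regs, tau_stat(c), n_blocks=20)
            assert abs(est) < 2 * se + 1e-6


class TestJackknife:
    def test_constant_statistic_zero_se(self):
        regs = [_region([1.0], np.ones((1, 1))) for _ in range(10)]
        est, se, z, p = jackknife(regs, lambda rr: 3.14, n_blocks=5, null=3.14)
        assert se == 0.0 and p == 1.0

    def test_sample_mean_matches_closed_form(self):
        values = np.array([2.0, 4.0, 4.5, 7.0, 1.0, 3.0, 6.0, 5.5])
        regs = [_region([v], np.ones((1, 1)), gene=f"g{i}")
                for i, v in enumerate(values)]

        def mean_stat(rr):
            return float(np.mean([r.chi2[0] for r in rr]))

        est, se, _, _ = jackknife(regs, mean_stat, n_blocks=len(values))
        # delete-one jackknife SE of the mean equals s / sqrt(B)
        assert est == pytest.approx(values.mean())
        assert se == pytest.approx(values.std(ddof=1) / np.sqrt(len(values)),
                                   abs=1e-12)

    def test_too_few_blocks_rejected(self):
        regs = [_region([1.0], np.ones((1, 1)))]
        with pytest.raises(ValueError, match="blocks"):
            jackknife(regs, lambda rr: 1.0, n_blocks=1)


class TestScalingInvariance:
    def test_expression_scale_leaves_partition_unchanged(self, rng):
        from loopqtl.simulate import simulate_h2_regions
        raw = simulate_h2_regions(n_genes=30, n_variants=30, n_samples=200,
                                  h2=0.3, focal_multiplier=5.0,
                                  focal_frac=0.1, seed=2)

        def run(scale):
            regs = []
            for d in raw:
                chi2 = marginal_chi2(scale * d["y"], d["dosages"])
                reg = CisRegion("g", chi2, d["annot"])
                reg.ld = compute_ld_scores(d["dosages"], d["annot"])
                regs.append(reg)
            return partition_heritability(regs, 200, ["base", "focal"],
                                          n_blocks=10)

        a, b = run(1.0), run(37.5)
        for col in ("tau", "prop_h2", "enrichment", "se", "p", "prop_snps"):
            np.testing.assert_allclose(a[col], b[col], atol=1e-9)
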