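"""BMI adjustment, correlation testing, replication, and the cascade."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from loopqtl.prioritize import (adjust_expression, adjust_phenotype,
                                assemble_cascade_report, bonferroni_threshold,
                                correlate_bmi, lm_bmi_ftest,
                                replicate_correlations)
from loopqtl.stats import P_FLOOR, inverse_normal_transform


def _phen(bmi, age):
    return pd.DataFrame({"sample": [f"s{i}" for i in range(len(bmi))],
                         "bmi": bmi, "age": age})


class TestAdjustPhenotype:
    def test_age_independent_bmi_rank_identical(self, rng):
        bmi = rng.normal(27, 4, 200)
        age = rng.uniform(45, 74, 200)
        out = adjust_phenotype(_phen(bmi, age))
        expect = inverse_normal_transform(bmi - np.polyval(
            np.polyfit(age, bmi, 2), age))
        # with zero age effect planted, ranks follow raw BMI closely
        assert sps.spearmanr(out, bmi).statistic > 0.95
        np.testing.assert_allclose(out, expect, atol=1e-10)

    def test_age_effect_projected_out(self, rng):
        age = rng.uniform(45, 74, 100)
        noise = rng.normal(0, 1e-4, 100)
        bmi = 2 * age + noise
        out = adjust_phenotype(_phen(bmi, age))
        resid = noise - np.polyval(np.polyfit(age, noise, 2), age)
        assert sps.spearmanr(out, resid).statistic == pytest.approx(1.0)

    def test_planted_age_coefficients_recovered(self, rng):
        import statsmodels.api as sm
        age = rng.uniform(45, 74, 500)
        bmi = 27 + 0.1 * age - 0.0008 * age**2 + rng.normal(0, 1.5, 500)
        X = sm.add_constant(np.column_stack([age, age**2]))
        fit = sm.OLS(bmi, X).fit()
        assert abs(fit.params[1] - 0.1) < 2 * fit.bse[1]
        assert abs(fit.params[2] + 0.0008) < 2 * fit.bse[2]

    def test_constant_age_rejected(self):
        with pytest.raises(ValueError, match="age"):
            adjust_phenotype(_phen(np.arange(5.0), np.full(5, 50.0)))


class TestAdjustExpression:
    def test_zero_technical_effect_gives_centered_log(self, rng):
        fpkm = pd.DataFrame(np.exp(rng.normal(2, 1, (3, 50))),
                            index=list("abc"))
        tech = rng.normal(size=(50, 4))
        out = adjust_expression(fpkm, tech)
        logx = np.log(fpkm.to_numpy() + 1e-6)
        assert np.allclose(out.mean(axis=1), 0, atol=1e-10)
        # residualizing on independent factors barely changes the signal
        for i in range(3):
            assert np.corrcoef(out.iloc[i], logx[i])[0, 1] > 0.9

    def test_expression_equal_exp_factor_projected_to_zero(self, rng):
        tech = rng.normal(size=(40, 2))
        fpkm = pd.DataFrame(np.exp(tech[:, 0])[None, :], index=["g"])
        out = adjust_expression(fpkm, tech)
        # residual bounded by the pseudocount's perturbation of the log
        assert np.abs(out.to_numpy()).max() < 1e-4

    def test_zero_fpkm_handled_by_pseudocount(self, rng):
        fpkm = pd.DataFrame(np.zeros((1, 10)), index=["g"])
        fpkm.iloc[0, :5] = 1.0
        out = adjust_expression(fpkm, rng.normal(size=(10, 1)))
        assert np.isfinite(out.to_numpy()).all()

    def test_collinear_factors_named(self, rng):
        t = rng.normal(size=40)
        tech = np.column_stack([t, 2 * t])
        fpkm = pd.DataFrame(np.exp(rng.normal(size=(1, 40))), index=["g"])
        with pytest.raises(ValueError, match="0 and 1"):
            adjust_expression(fpkm, tech)


class TestCorrelateBmi:
    def test_bonferroni_family_of_replicated_egenes(self):
        assert bonferroni_threshold(0.05, 4332) == pytest.approx(
            1.15e-5, rel=5e-3)

    def test_identical_vectors_r_one(self, rng):
        y = rng.normal(size=30)
        expr = pd.DataFrame(y[None, :], index=["g"])
        out = correlate_bmi(expr, y, n_family_tests=10)
        assert out.at[0, "r"] == pytest.approx(1.0)
        assert out.at[0, "p"] < 1e-100

    def test_three_point_worked_example(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0, 1.0]], index=["g"])
        out = correlate_bmi(expr, np.array([2.0, 4.0, 5.0, 2.0]),
                            n_family_tests=1)
        # 3-point pattern x=[1,2,3], y=[2,4,5] duplicated start point
        expect = sps.pearsonr([1, 2, 3, 1], [2, 4, 5, 2]).statistic
        assert out.at[0, "r"] == pytest.approx(expect, abs=1e-6)

    def test_pearson_r_value_direct_arithmetic(self):
        r = sps.pearsonr([1, 2, 3], [2, 4, 5]).statistic
        assert r == pytest.approx(0.9820, abs=1e-4)

    def test_zero_variance_gene_flagged_not_raised(self, rng):
        expr = pd.DataFrame(np.vstack([np.ones(20), rng.normal(size=20)]),
                            index=["flat", "ok"])
        out = correlate_bmi(expr, rng.normal(size=20), n_family_tests=2)
        flat = out.set_index("gene").loc["flat"]
        assert not flat["significant"] and flat["note"] == "zero variance"

    def test_pearson_p_equals_univariate_ftest(self, rng):
        y = rng.normal(size=50)
        x = 0.3 * y + rng.normal(size=50)
        expr = pd.DataFrame(x[None, :], index=["g"])
        p_corr = correlate_bmi(expr, y, n_family_tests=1).at[0, "p"]
        _, _, p_f = lm_bmi_ftest(x, y, np.empty((50, 0)))
        assert p_corr == pytest.approx(p_f, rel=1e-10)


class TestLmFtest:
    def test_f_equals_t_squared(self, rng):
        n = 80
        cov = rng.normal(size=(n, 3))
        bmi = rng.normal(size=n)
        y = 0.2 * bmi + cov @ [0.1, -0.2, 0.3] + rng.normal(size=n)
        beta, se, p = lm_bmi_ftest(y, bmi, cov)
        t2 = (beta / se) ** 2
        df = n - 5
        p_t = 2 * sps.t.sf(np.sqrt(t2), df)
        assert p == pytest.approx(p_t, rel=1e-10)

    def test_noise_free_dependence_floors_p(self, rng):
        n = 50
        bmi = rng.normal(size=n)
        beta, _, p = lm_bmi_ftest(2.0 * bmi, bmi, np.empty((n, 0)))
        assert beta == pytest.approx(2.0)
        assert p == P_FLOOR


class TestReplication:
    def _fixture(self, rng, n_pass=42, n_fail=12, n=300):
        """54 tested genes: n_pass concordant strong, n_fail discordant."""
        bmi = rng.normal(size=n)
        genes, rows = {}, []
        for i in range(n_pass + n_fail):
            g = f"g{i:02d}"
            sign = 1.0 if i % 2 == 0 else -1.0
            rows.append((g, sign * 0.5, 1e-8))
            if i < n_pass:
                genes[g] = sign * bmi + 0.3 * rng.normal(size=n)
            else:  # wrong direction in replication
                genes[g] = -sign * bmi + 0.3 * rng.normal(size=n)
        discovery = pd.DataFrame(rows, columns=["gene", "r", "p"])
        rep_expr = pd.DataFrame(genes).T
        return discovery, rep_expr, bmi

    def test_replication_rate_printed_at_one_decimal(self, rng):
        discovery, rep_expr, bmi = self._fixture(rng)
        verdicts, summary = replicate_correlations(discovery, rep_expr, bmi)
        assert summary["n_tested"] == 54
        assert summary["n_replicated"] == 42
        assert summary["replication_rate_pct"] == 77.8

    def test_direction_mismatch_with_tiny_p_not_replicated(self, rng):
        discovery, rep_expr, bmi = self._fixture(rng)
        verdicts = replicate_correlations(discovery, rep_expr, bmi)[0]
        failed = verdicts[~verdicts["direction_match"]]
        assert len(failed) == 12
        assert (failed["p_rep"] < 1e-6).all()      # strong but wrong sign
        assert not failed["replicated"].any()

    def test_absent_genes_counted_separately(self, rng):
        discovery, rep_expr, bmi = self._fixture(rng, n_pass=3, n_fail=1)
        discovery = pd.concat([discovery, pd.DataFrame(
            [("missing", 0.5, 1e-9)], columns=discovery.columns)])
        _, summary = replicate_correlations(discovery, rep_expr, bmi)
        assert summary["n_absent"] == 1 and summary["n_tested"] == 4

    def test_planted_drivers_replicate_in_synthetic_cohorts(self, demo_run):
        import json
        _, out, _ = demo_run
        cascade = json.loads((out / "cascade.json").read_text())
        rep = cascade["bmi_replication"]
        assert rep["n_replicated"] >= 0.9 * rep["n_tested"]


class TestCascadeReport:
    def test_transition_percentages(self):
        stages = {
            "egenes": [f"g{i}" for i in range(4332)],
            "looping": [f"g{i}" for i in range(576)],
            "bmi": [f"g{i}" for i in range(54)],
        }
        _, summary = assemble_cascade_report(stages)
        assert summary["transitions"]["egenes->looping"]["pct"] == 13.3
        assert summary["transitions"]["looping->bmi"]["pct"] == 9.4

    def test_empty_stage_valid(self):
        stages = {"a": ["g1", "g2"], "b": []}
        table, summary = assemble_cascade_report(stages)
        assert summary["counts"]["b"] == 0
        assert summary["transitions"]["a->b"]["pct"] == 0.0

    def test_non_subset_stage_lists_offenders(self):
        stages = {"a": ["g1"], "b": ["g1", "gX"]}
        with pytest.raises(ValueError, match="gX"):
            assemble_cascade_report(stages)

    def test_furthest_stage_recorded(self):
        stages = {"a": ["g1", "g2", "g3"], "b": ["g1", "g2"], "c": ["g2"]}
        table, _ = assemble_cascade_report(stages)
        assert dict(zip(table["gene"], table["stage"])) == {
            "g1": "b", "g2": "c", "g3": "a"}
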