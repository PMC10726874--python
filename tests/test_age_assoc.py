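"""Sex-adjusted partial correlation, moderated t, and the dual-criterion call."""

import numpy as np
import pandas as pd
import pytest

from gerotarget import age_assoc, synthio
from gerotarget.age_assoc import (
    AgeAssocError,
    call_age_associated,
    de_old_young,
    partial_pearson,
    partial_pearson_table,
    tsg_enrichment_test,
)

from conftest import make_study


def residual_partial_corr(age, expr, sex):
    """Oracle: Pearson correlation of the residuals of age-on-sex and
    expr-on-sex simple regressions."""
    X = np.column_stack([np.ones_like(sex, dtype=float), sex])
    ra = age - X @ np.linalg.lstsq(X, age, rcond=None)[0]
    re = expr - X @ np.linalg.lstsq(X, expr, rcond=None)[0]
    return np.corrcoef(ra, re)[0, 1]


class TestPartialPearson:
    def test_expression_identical_to_age_gives_r_one(self):
        res = partial_pearson([1, 2, 3, 4], [1, 2, 3, 4], [0, 1, 0, 1])
        assert res.r_partial == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_expression_gives_r_zero(self):
        age = np.array([1.0, 2.0, 3.0, 4.0])
        sex = np.array([0.0, 1.0, 1.0, 0.0])
        expr = np.array([1.0, -3.0, 3.0, -1.0])  # orthogonal to age and sex
        res = partial_pearson(age, expr, sex)
        assert res.r_partial == pytest.approx(0.0, abs=1e-12)

    def test_matches_residual_regression_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = 20
            age = rng.uniform(20, 80, n)
            sex = rng.integers(0, 2, n).astype(float)
            expr = rng.normal(0, 1, n) + 0.02 * age + 0.3 * sex
            res = partial_pearson(age, expr, sex)
            assert res.r_partial == pytest.approx(
                residual_partial_corr(age, expr, sex), abs=1e-10
            )

    def test_constant_expression_rejected(self):
        with pytest.raises(AgeAssocError):
            partial_pearson([1, 2, 3, 4], [5, 5, 5, 5], [0, 1, 0, 1])

    def test_vectorized_table_matches_scalar(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 30))
        study = make_study(X, ages=rng.uniform(20, 80, 30), sexes=rng.integers(0, 2, 30))
        table = partial_pearson_table(study)
        for i, gene in enumerate(study.gene_ids):
            res = partial_pearson(
                study.samples["age"], X[i], study.samples["sex"], gene
            )
            row = table[table["gene_id"] == gene].iloc[0]
            assert row["r_partial"] == pytest.approx(res.r_partial, abs=1e-12)
            assert row["p_corr"] == pytest.approx(res.p_value, abs=1e-12)


class TestDeOldYoung:
    def test_constant_gene_has_zero_logfc_p_one(self):
        X = np.vstack([np.full(12, 3.0), np.random.default_rng(0).normal(size=12)])
        ages = np.array([30] * 6 + [65] * 6)
        out = de_old_young(make_study(X, ages=ages))
        row = out.iloc[0]
        assert row["logfc"] == pytest.approx(0.0, abs=1e-12)
        assert row["p_value"] == pytest.approx(1.0)

    def test_beta_matches_normal_equations_on_six_samples(self):
        # young values (1,2,3), old values (3,4,5), sex balanced
        ages = np.array([30, 35, 40, 65, 70, 75])
        sexes = np.array([0, 1, 0, 1, 0, 1])
        y = np.array([1.0, 2.0, 3.0, 3.0, 4.0, 5.0])
        X = np.column_stack([np.ones(6), (ages >= 60).astype(float), sexes])
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)[1]
        out = de_old_young(make_study(y[None, :], ages=ages, sexes=sexes), prior_df=0)
        assert out["logfc"].iloc[0] == pytest.approx(beta_oracle, abs=1e-10)

    def test_middle_aged_samples_excluded(self):
        ages = np.array([30, 40, 55, 55, 65, 75])
        out = de_old_young(make_study(np.random.default_rng(1).normal(size=(3, 6)),
                                      ages=ages))
        assert (out["n"] == 4).all()

    def test_zero_prior_df_equals_ols_t(self):
        rng = np.random.default_rng(9)
        n = 40
        ages = rng.uniform(20, 80, n)
        sexes = rng.integers(0, 2, n)
        Y = rng.normal(size=(60, n))
        study = make_study(Y, ages=ages, sexes=sexes)
        out = de_old_young(study, prior_df=0)
        keep = (ages >= 60) | (ages < 50)
        X = np.column_stack(
            [np.ones(keep.sum()), (ages[keep] >= 60).astype(float), sexes[keep]]
        )
        H = np.linalg.inv(X.T @ X)
        for i in range(60):
            y = Y[i, keep]
            beta = H @ X.T @ y
            resid = y - X @ beta
            s2 = resid @ resid / (keep.sum() - 3)
            t_oracle = beta[1] / np.sqrt(s2 * H[1, 1])
            assert out["t"].iloc[i] == pytest.approx(t_oracle, abs=1e-8)

    def test_moderated_df_exceeds_ordinary_df(self):
        rng = np.random.default_rng(10)
        ages = np.concatenate([rng.uniform(20, 49, 20), rng.uniform(60, 79, 20)])
        study = make_study(rng.normal(size=(200, 40)), ages=ages)
        out = de_old_young(study)
        assert (out["moderated_df"] >= 40 - 3).all()

    def test_empty_stratum_rejected(self):
        with pytest.raises(AgeAssocError):
            de_old_young(make_study(np.ones((2, 4)), ages=[30, 35, 40, 45]))


class TestCallAgeAssociated:
    def _frames(self, p_corr, p_de, logfc):
        pc = pd.DataFrame({"gene_id": ["g1"], "r_partial": [0.5],
                           "p_corr": [p_corr], "n": [100]})
        de = pd.DataFrame({"gene_id": ["g1"], "logfc": [logfc], "p_value": [p_de]})
        return pc, de

    def test_one_criterion_failing_blocks_call(self):
        calls = call_age_associated(*self._frames(0.04, 0.06, 1.0))
        assert not calls["is_age_associated"].iloc[0]

    def test_both_criteria_with_negative_logfc_calls_down(self):
        calls = call_age_associated(*self._frames(0.01, 0.01, -2.0))
        row = calls.iloc[0]
        assert row["is_age_associated"] and row["direction"] == "down"

    def test_mismatched_gene_sets_rejected(self):
        pc, de = self._frames(0.01, 0.01, 1.0)
        de["gene_id"] = ["g2"]
        with pytest.raises(AgeAssocError, match="g2"):
            call_age_associated(pc, de)


class TestRecovery:
    def test_planted_age_genes_recovered_with_correct_direction(self):
        """Sensitivity >= 90% and direction agreement >= 95% at the default
        effect size and 150 samples per tissue."""
        cfg = synthio.SyntheticConfig(n_genes=800, samples_per_tissue=150, seed=21)
        truth = synthio.planted_truth(cfg)
        study = synthio.generate_tissue_study(cfg, 0, truth)
        calls = age_assoc.age_association_table(study).set_index("gene_id")
        planted = truth.age_slopes
        called = [g for g in planted if calls.loc[g, "is_age_associated"]]
        assert len(called) / len(planted) >= 0.90
        agree = [
            g for g in called
            if (calls.loc[g, "direction"] == "up") == (planted[g] > 0)
        ]
        assert len(agree) / len(called) >= 0.95


class TestTsgChi2:
    @staticmethod
    def _calls(tsg_assoc, tsg_not, other_assoc, other_not):
        rows = []
        idx = 0
        for n, assoc, prefix in [
            (tsg_assoc, True, "T"), (tsg_not, False, "T"),
            (other_assoc, True, "O"), (other_not, False, "O"),
        ]:
            for _ in range(n):
                rows.append({"gene_id": f"{prefix}{idx}", "tissue": "t0",
                             "is_age_associated": assoc})
                idx += 1
        return pd.DataFrame(rows)

    def test_identical_proportions_give_zero_chi2(self):
        calls = self._calls(10, 90, 10, 90)
        tsg = [g for g in calls["gene_id"] if g.startswith("T")]
        res = tsg_enrichment_test(calls, tsg)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_closed_form_pearson_statistic(self):
        calls = self._calls(30, 70, 10, 90)
        tsg = [g for g in calls["gene_id"] if g.startswith("T")]
        res = tsg_enrichment_test(calls, tsg)
        a, b, c, d = 30, 70, 10, 90
        n = a + b + c + d
        chi2_oracle = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        assert res.chi2 == pytest.approx(chi2_oracle, abs=1e-10)

    def test_symmetric_under_row_swap(self):
        calls = self._calls(30, 70, 10, 90)
        tsg = [g for g in calls["gene_id"] if g.startswith("T")]
        other = [g for g in calls["gene_id"] if g.startswith("O")]
        assert tsg_enrichment_test(calls, tsg).chi2 == pytest.approx(
            tsg_enrichment_test(calls, other).chi2
        )
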