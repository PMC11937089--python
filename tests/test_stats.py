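"""The normality-gated statistics tree and its primitives."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from drivevigil.stats import (FeatureMatrix, analyze_feature,
                              conover_posthoc, feature_correlations,
                              friedman_test, gg_epsilon, holm_adjust,
                              paired_tests, rm_anova, shapiro_gate)
from drivevigil.synth import CohortConfig, sample_feature_table


def matrix(y, modes=("PAD", "Manual")):
    n = y.shape[0]
    return FeatureMatrix(y, list(modes), [f"S{i}" for i in range(n)])


class TestHolm:
    def test_step_down_example(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.02, 0.04]),
                                   [0.03, 0.04, 0.04])

    def test_single_test_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.03]), [0.03])

    def test_against_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 15)
        _, adj, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(holm_adjust(p), adj)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_monotone_and_never_below_raw(self, p):
        adj = holm_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestShapiroGate:
    def test_normal_cells_parametric(self, rng):
        y = rng.normal(size=(28, 2, 6))
        assert shapiro_gate(matrix(y))["path"] == "parametric"

    def test_exponential_cell_flips_nonparametric(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = rng.normal(size=(28, 2, 6))
            y[:, 0, 0] = rng.exponential(size=28) ** 2
            if shapiro_gate(matrix(y))["path"] == "nonparametric":
                hits += 1
        assert hits >= 8

    def test_constant_cell_nonparametric(self, rng):
        y = rng.normal(size=(10, 2, 6))
        y[:, 1, 3] = 5.0
        g = shapiro_gate(matrix(y))
        assert g["path"] == "nonparametric"
        assert g["cells"]["Manual/T4"] == 0.0


class TestGGEpsilon:
    def test_two_levels_exactly_one(self, rng):
        assert gg_epsilon(rng.normal(size=(10, 2))) == 1.0

    def test_bounds(self, rng):
        for k in (3, 4, 6):
            eps = gg_epsilon(rng.normal(size=(15, k)))
            assert 1.0 / (k - 1) - 1e-12 <= eps <= 1.0

    def test_brute_force_oracle(self, rng):
        """Direct eigenvalue formula on the double-centered covariance."""
        x = rng.normal(size=(14, 5)) @ rng.normal(size=(5, 5))
        S = np.cov(x, rowvar=False)
        H = np.eye(5) - np.ones((5, 5)) / 5
        lam = np.linalg.eigvalsh(H @ S @ H)
        expected = lam.sum() ** 2 / (4 * np.sum(lam ** 2))
        assert gg_epsilon(x) == pytest.approx(expected)

    def test_matches_pingouin(self, rng):
        import pingouin as pg
        x = rng.normal(size=(20, 6)) * np.array([1, 1, 2, 2, 3, 3])
        df = pd.DataFrame(x, columns=[f"T{j}" for j in range(6)])
        assert gg_epsilon(x) == pytest.approx(float(pg.epsilon(df)),
                                              abs=1e-10)


class TestMauchly:
    def test_spherical_data_rarely_rejected(self):
        from drivevigil.stats import mauchly_sphericity
        rng = np.random.default_rng(0)
        ps = [mauchly_sphericity(rng.normal(size=(28, 6)))[1]
              for _ in range(50)]
        assert np.mean(np.asarray(ps) < 0.05) <= 0.15

    def test_strong_nonsphericity_rejected(self):
        from drivevigil.stats import mauchly_sphericity
        rng = np.random.default_rng(1)
        x = rng.normal(size=(28, 6)).cumsum(axis=1)  # random-walk structure
        w, p = mauchly_sphericity(x)
        assert p < 1e-4 and w < 1.0

    def test_two_levels_trivially_spherical(self):
        from drivevigil.stats import mauchly_sphericity
        rng = np.random.default_rng(2)
        assert mauchly_sphericity(rng.normal(size=(12, 2))) == (1.0, 1.0)


class TestRmAnova:
    def test_two_level_factor_equals_squared_paired_t(self, rng):
        y = rng.normal(size=(15, 2, 6)) + rng.normal(size=(15, 1, 1))
        eff = {e["effect"]: e for e in rm_anova(matrix(y))}
        d = y[:, 0, :].mean(axis=1) - y[:, 1, :].mean(axis=1)
        t = sps.ttest_rel(y[:, 0, :].mean(axis=1),
                          y[:, 1, :].mean(axis=1)).statistic
        assert eff["mode"]["stat"] == pytest.approx(t ** 2)
        assert eff["mode"]["epsilon"] == 1.0

    def test_matches_pingouin_two_way(self, rng):
        import pingouin as pg
        n, b = 13, 6
        y = rng.normal(size=(n, 2, b)) + 0.4 * np.arange(b) / b
        mine = {e["effect"]: e for e in rm_anova(matrix(y))}
        rows = [{"s": i, "m": m, "t": k, "y": y[i, j, k]}
                for i in range(n) for j, m in enumerate("AB")
                for k in range(b)]
        aov = pg.rm_anova(dv="y", within=["m", "t"], subject="s",
                          data=pd.DataFrame(rows), detailed=True)
        for src, key in (("m", "mode"), ("t", "time"),
                         ("m * t", "mode x time")):
            row = aov[aov.Source == src].iloc[0]
            assert mine[key]["stat"] == pytest.approx(float(row.F))
            assert mine[key]["epsilon"] == pytest.approx(float(row.eps))
            assert mine[key]["p_gg"] == pytest.approx(float(row.p_GG_corr))
            assert mine[key]["p_uncorrected"] == pytest.approx(
                float(row.p_unc))

    def test_null_f_distribution_center(self):
        fs = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            y = rng.normal(size=(12, 2, 6)) + rng.normal(size=(12, 1, 1))
            fs.append(rm_anova(matrix(y))[0]["stat"])
        # F(1, 11) has mean df2/(df2-2) = 11/9
        assert np.mean(fs) == pytest.approx(11 / 9, abs=0.6)

    def test_missing_cells_rejected(self, rng):
        fm = matrix(rng.normal(size=(10, 2, 6)))
        fm.data[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova(fm)


class TestFriedmanConover:
    def test_identical_columns_null(self):
        x = np.tile(np.random.default_rng(0).normal(size=(10, 1)), (1, 4))
        f = friedman_test(x)
        assert f["stat"] == 0.0 and f["p"] == 1.0
        ph = conover_posthoc(x)
        assert (ph["stat"] == 0.0).all() and (ph["p_raw"] == 1.0).all()

    def test_two_levels_directed_to_wilcoxon(self, rng):
        with pytest.raises(ValueError, match="Wilcoxon"):
            friedman_test(rng.normal(size=(10, 2)))

    @pytest.mark.parametrize("n,k,df", [(28, 3, 54), (26, 6, 125),
                                        (27, 6, 130)])
    def test_conover_df_formula(self, n, k, df, rng):
        ph = conover_posthoc(rng.normal(size=(n, k)))
        assert (ph["df"] == df).all()
        assert df == (n - 1) * (k - 1)

    def test_conover_hand_computed_example(self):
        """Independent re-derivation of the Conover statistic on a tiny
        fixed block design."""
        x = np.array([[1.0, 2.0, 3.0],
                      [1.5, 2.5, 3.5],
                      [2.0, 1.0, 3.0],
                      [1.0, 3.0, 2.0]])
        ranks = np.array([sps.rankdata(r) for r in x])
        R = ranks.sum(axis=0)
        n, k = x.shape
        A = np.sum(ranks ** 2)
        C = n * k * (k + 1) ** 2 / 4
        T1 = (k - 1) * np.sum((R - n * (k + 1) / 2) ** 2) / (A - C)
        df = (n - 1) * (k - 1)
        denom = np.sqrt(2 * n * (A - C) * (1 - T1 / (n * (k - 1))) / df)
        expected_01 = (R[0] - R[1]) / denom
        ph = conover_posthoc(x)
        got = ph[ph["pair"] == "T1 vs T2"]["stat"].iloc[0]
        assert got == pytest.approx(expected_01)

    def test_strong_effect_detected(self, rng):
        x = rng.normal(size=(20, 3)) + np.array([0.0, 1.0, 2.0])
        f = friedman_test(x)
        assert f["p"] < 0.001
        ph = conover_posthoc(x)
        assert ph[ph["pair"] == "T1 vs T3"]["p_holm"].iloc[0] < 0.01


class TestPairedTests:
    def test_wilcoxon_identical_samples(self, rng):
        x = rng.normal(size=12)
        out = paired_tests([("a", x, x.copy())], method="wilcoxon")
        assert out["p_raw"].iloc[0] == 1.0

    def test_zero_variance_t_rejected(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError):
            paired_tests([("a", x, x + 1.0)], method="t")

    def test_holm_applied_across_pairs(self, rng):
        pairs = [(f"p{i}", rng.normal(size=10), rng.normal(size=10))
                 for i in range(4)]
        out = paired_tests(pairs, method="t")
        np.testing.assert_allclose(out["p_holm"],
                                   holm_adjust(out["p_raw"].to_numpy()))


class TestCorrelations:
    def _tables(self, x, y, sections=6):
        rows_a, rows_b = [], []
        for i in range(x.shape[0]):
            for s in range(sections):
                rows_a.append({"subject": i, "section": s + 1,
                               "value": x[i, s]})
                rows_b.append({"subject": i, "section": s + 1,
                               "value": y[i, s]})
        return pd.DataFrame(rows_a), pd.DataFrame(rows_b)

    def test_perfect_linear_relation(self, rng):
        x = rng.normal(size=(10, 6))
        a, b = self._tables(x, 2 * x + 1)
        out = feature_correlations(a, b)
        np.testing.assert_allclose(out["r"], 1.0)

    def test_df_reporting(self, rng):
        x = rng.normal(size=(27, 6))
        a, b = self._tables(x, rng.normal(size=(27, 6)))
        out = feature_correlations(a, b)
        assert (out["df"] == 25).all()
        x = rng.normal(size=(21, 6))
        a, b = self._tables(x, rng.normal(size=(21, 6)))
        assert (feature_correlations(a, b)["df"] == 19).all()

    def test_null_distribution_bound(self):
        """Independent normals, n = 21: |r| < 0.45 in at least 95 % of
        seeds (null distribution of r at df = 19)."""
        hits = 0
        trials = 100
        for seed in range(trials):
            rng = np.random.default_rng(seed)
            x, y = rng.normal(size=(2, 21))
            r = sps.pearsonr(x, y).statistic
            if abs(r) < 0.45:
                hits += 1
        assert hits >= 95

    def test_too_few_subjects_missing(self, rng):
        x = rng.normal(size=(2, 6))
        a, b = self._tables(x, x)
        out = feature_correlations(a, b)
        assert out["r"].isna().all()


class TestAnalyzeFeature:
    def test_injected_mode_effect_recovered(self):
        cohort = CohortConfig(n_subjects=28)
        table = sample_feature_table(
            base=-98.0, mode_delta=1.24,
            time_profile=[0.0, 0.68, 1.05, 1.12, 1.18, 1.33],
            cohort=cohort, rng=np.random.default_rng(5), feature="alpha")
        rep = analyze_feature(table, "alpha")
        mode = rep.effect("mode")
        time = rep.effect("time")
        assert mode["p"] < 0.01 and time["p"] < 0.01
        piv = table.pivot_table(index="subject", columns="condition",
                                values="value")
        assert (piv["PAD"] - piv["Manual"]).mean() > 0

    def test_heavy_tailed_takes_nonparametric_path(self):
        cohort = CohortConfig(n_subjects=28)
        rng = np.random.default_rng(3)
        table = sample_feature_table(0.0, 0.0, [0.0] * 6, cohort, rng)
        table["value"] = rng.standard_cauchy(len(table)) ** 2
        rep = analyze_feature(table, "heavy")
        assert rep.path == "nonparametric"

    def test_report_serializes(self, tmp_path):
        cohort = CohortConfig(n_subjects=10)
        table = sample_feature_table(0.0, 2.0, [0.0] * 6, cohort,
                                     np.random.default_rng(1))
        rep = analyze_feature(table, "demo")
        rep.to_json(tmp_path / "r.json")
        import json
        doc = json.loads((tmp_path / "r.json").read_text())
        assert doc["feature"] == "demo"
        assert rep.summary()

    def test_one_mode_time_only_design(self, rng):
        rows = [{"subject": i, "condition": "Manual", "section": s + 1,
                 "value": rng.normal() + 0.3 * s}
                for i in range(20) for s in range(6)]
        rep = analyze_feature(pd.DataFrame(rows), "rmse")
        assert any(o["effect"].startswith("time") for o in rep.omnibus)
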