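import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from soilfoodweb import ecostats


class TestAnovaTukeyLetters:
    def test_three_group_example(self):
        values = [1, 2, 3, 2, 3, 4, 10, 11, 12]
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        res = ecostats.anova_tukey_letters(values, labels)
        assert set(res.letters["A"]) & set(res.letters["B"])
        assert not set(res.letters["C"]) & set(res.letters["A"])
        assert not set(res.letters["C"]) & set(res.letters["B"])
        assert res.p < 0.001

    def test_null_case_shares_letter(self):
        rng = np.random.default_rng(0)
        values = 5.0 + 0.01 * rng.standard_normal(12)
        labels = np.repeat(["a", "b", "c"], 4)
        res = ecostats.anova_tukey_letters(values, labels)
        assert all(v == res.letters["a"] for v in res.letters.values())

    def test_label_permutation_consistent(self):
        rng = np.random.default_rng(1)
        values = np.concatenate(
            [rng.normal(m, 1, 4) for m in (0.0, 0.5, 8.0)]
        )
        labels = np.repeat(["G1", "G2", "G3"], 4)
        res1 = ecostats.anova_tukey_letters(values, labels)
        relabel = {"G1": "X", "G2": "Y", "G3": "Z"}
        res2 = ecostats.anova_tukey_letters(
            values, [relabel[l] for l in labels]
        )
        for old, new in relabel.items():
            assert res1.letters[old] == res2.letters[new]

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ecostats.anova_tukey_letters(
                [1.0, 1.0, 2.0, 2.0], ["a", "a", "b", "b"]
            )

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ecostats.anova_tukey_letters([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestSpearman:
    def frame(self, **cols):
        return pd.DataFrame(cols)

    def test_monotone_perfect(self):
        X = self.frame(x=[1, 2, 3, 4, 5])
        Yup = self.frame(y=[10, 20, 30, 40, 50])
        Ydown = self.frame(y=[5, 4, 3, 2, 1])
        rho, _ = ecostats.spearman_matrix(X, Yup)
        assert rho.iloc[0, 0] == pytest.approx(1.0)
        rho, _ = ecostats.spearman_matrix(X, Ydown)
        assert rho.iloc[0, 0] == pytest.approx(-1.0)

    def test_hand_value(self):
        X = self.frame(x=[1, 2, 3, 4, 5])
        Y = self.frame(y=[2, 1, 4, 3, 5])
        rho, _ = ecostats.spearman_matrix(X, Y)
        assert rho.iloc[0, 0] == pytest.approx(0.8)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        X, Y = self.frame(x=x), self.frame(y=y)
        rho1, p1 = ecostats.spearman_matrix(X, Y)
        rho2, p2 = ecostats.spearman_matrix(
            self.frame(x=np.exp(x)), self.frame(y=y**3)
        )
        assert rho1.iloc[0, 0] == pytest.approx(rho2.iloc[0, 0], abs=1e-12)

    def test_constant_variable_warns_nan(self):
        X = self.frame(x=[1.0, 1.0, 1.0, 1.0, 1.0])
        Y = self.frame(y=[1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.warns(UserWarning, match="constant"):
            rho, p = ecostats.spearman_matrix(X, Y)
        assert np.isnan(rho.iloc[0, 0])

    def test_pairwise_missing_handled(self):
        X = self.frame(x=[1, 2, 3, 4, 5, np.nan])
        Y = self.frame(y=[2, 1, 4, 3, 5, 100])
        rho, _ = ecostats.spearman_matrix(X, Y)
        assert rho.iloc[0, 0] == pytest.approx(0.8)

    def test_bh_adjustment_monotone(self):
        p = pd.DataFrame([[0.01, 0.04], [0.03, 0.5]])
        adj = ecostats.bh_adjust(p)
        assert (adj.to_numpy() >= p.to_numpy() - 1e-15).all()


class TestVariancePartition:
    def test_identical_predictor_sets(self):
        """Perfect redundancy: everything explained lands in b."""
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(30, 3))
        X = rng.normal(size=(30, 2))
        res = ecostats.variance_partition(Y, X, X.copy())
        assert res.a == pytest.approx(0.0, abs=1e-9)
        assert res.c == pytest.approx(0.0, abs=1e-9)
        assert res.b == pytest.approx(res.adj_r2["X1"], abs=1e-9)

    def test_fraction_identities_random(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(25, 4))
        X1 = rng.normal(size=(25, 3))
        X2 = rng.normal(size=(25, 2))
        res = ecostats.variance_partition(Y, X1, X2)
        assert res.a + res.b + res.c + res.d == pytest.approx(1.0, abs=1e-9)
        assert res.a + res.b == pytest.approx(res.adj_r2["X1"], abs=1e-9)
        assert res.b + res.c == pytest.approx(res.adj_r2["X2"], abs=1e-9)

    def test_single_response_matches_multiple_regression(self):
        """Redundancy R2 on one response equals ordinary OLS R2."""
        rng = np.random.default_rng(4)
        X1 = rng.normal(size=(40, 2))
        X2 = rng.normal(size=(40, 2))
        y = X1 @ [1.0, -2.0] + rng.normal(size=40)
        res = ecostats.variance_partition(y, X1, X2)
        X = np.column_stack([np.ones(40), X1])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        r2_ols = 1 - resid.var() / y.var()
        assert res.r2["X1"] == pytest.approx(r2_ols, abs=1e-9)

    def test_pure_x1_structure_recovered(self):
        rng = np.random.default_rng(6)
        n = 100
        X1 = rng.normal(size=(n, 3))
        X2 = rng.normal(size=(n, 3))
        Y = X1 @ rng.normal(size=(3, 2))
        res = ecostats.variance_partition(Y, X1, X2)
        assert res.a == pytest.approx(1.0, abs=0.05)
        assert abs(res.b) < 0.05 and abs(res.c) < 0.05

    def test_within_set_rank_deficiency_reported(self):
        rng = np.random.default_rng(7)
        X1 = pd.DataFrame(rng.normal(size=(20, 2)), columns=["u", "v"])
        X1["w"] = X1["u"] + X1["v"]
        X2 = pd.DataFrame(rng.normal(size=(20, 2)), columns=["p", "q"])
        Y = rng.normal(size=(20, 2))
        with pytest.raises(ValueError, match="rank-deficient"):
            ecostats.variance_partition(Y, X1, X2)

    def test_too_few_rows_rejected(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError, match="total predictors"):
            ecostats.variance_partition(
                rng.normal(size=(5, 1)),
                rng.normal(size=(5, 2)),
                rng.normal(size=(5, 2)),
            )


class TestEnvfit:
    def scores(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(size=(n, 2)), columns=["A1", "A2"]
        )

    def test_perfect_fit(self):
        S = self.scores()
        V = pd.DataFrame({"v": S["A1"]})
        res = ecostats.envfit_permutation(S, V, n_perm=99, seed=1)
        assert res.loc["v", "r2"] == pytest.approx(1.0, abs=1e-9)
        assert res.loc["v", "p"] == pytest.approx(1 / 100)

    def test_determinism(self):
        S = self.scores(seed=2)
        V = pd.DataFrame({"v": np.random.default_rng(3).normal(size=20)})
        r1 = ecostats.envfit_permutation(S, V, n_perm=199, seed=5)
        r2 = ecostats.envfit_permutation(S, V, n_perm=199, seed=5)
        assert r1.equals(r2)

    def test_p_bounds(self):
        S = self.scores(seed=4)
        rng = np.random.default_rng(9)
        V = pd.DataFrame({f"v{i}": rng.normal(size=20) for i in range(5)})
        res = ecostats.envfit_permutation(S, V, n_perm=49, seed=0)
        assert (res["p"] >= 1 / 50 - 1e-12).all()
        assert (res["p"] <= 1.0 + 1e-12).all()

    def test_constant_variable_nan(self):
        S = self.scores(seed=5)
        V = pd.DataFrame({"v": np.ones(20)})
        with pytest.warns(UserWarning, match="constant"):
            res = ecostats.envfit_permutation(S, V, n_perm=9, seed=0)
        assert np.isnan(res.loc["v", "r2"])

    def test_r2_matches_ols(self):
        S = self.scores(seed=6)
        rng = np.random.default_rng(10)
        y = S["A1"] * 2 + rng.normal(size=20)
        res = ecostats.envfit_permutation(
            S, pd.DataFrame({"y": y}), n_perm=9, seed=0
        )
        lr = sps.linregress(S["A1"], y)
        X = np.column_stack([np.ones(20), S.to_numpy()])
        beta, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
        resid = y.to_numpy() - X @ beta
        r2 = 1 - resid.var() / y.to_numpy().var()
        assert res.loc["y", "r2"] == pytest.approx(r2, abs=1e-9)
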