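import numpy as np
import pytest

from fronteat import RFEATRegressor, mtry_count, rfeat_efficiency
from fronteat.rfeat import tune_rfeat
from conftest import make_table, random_table


class TestMtryRules:
    @pytest.mark.parametrize("rule,m,s,n_t,expected", [
        ("BREIMAN", 5, 1, 36, 1),          # floor(5/3)
        ("breiman", 9, 1, 36, 3),
        ("DEA1", 20, 1, 36, 17),           # floor(36/2 - 1)
        ("DEA1", 5, 1, 36, 5),             # clamped to m
        ("DEA2", 20, 1, 36, 11),           # floor(36/3 - 1)
        ("DEA3", 20, 2, 36, 9),            # floor(36/4)
        ("DEA4", 20, 1, 36, 11),           # min(36, 11)
        ("DEA1", 5, 3, 4, 1),              # negative -> clamped to 1
    ])
    def test_rule_arithmetic_and_clamping(self, rule, m, s, n_t, expected):
        assert mtry_count(rule, m, s, n_t) == expected

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            mtry_count("DEA9", 3, 1, 10)


class TestForestFit:
    def test_single_tree_forest_equals_its_tree(self, rng):
        t = random_table(rng, n=20, m=2, s=1)
        f = RFEATRegressor(n_estimators=1, n_min=5, random_state=3).fit(t.X, t.Y[:, 0])
        q = rng.uniform(0, 11, size=(30, 2))
        np.testing.assert_allclose(f.predict(q), f.estimators_[0].predict(q)[:, 0])

    def test_identical_seed_reproduces_forest(self, rng):
        t = random_table(rng, n=20, m=2, s=1)
        f1 = RFEATRegressor(n_estimators=10, n_min=5, random_state=7).fit(t.X, t.Y[:, 0])
        f2 = RFEATRegressor(n_estimators=10, n_min=5, random_state=7).fit(t.X, t.Y[:, 0])
        for a, b in zip(f1.bootstrap_indices_, f2.bootstrap_indices_):
            np.testing.assert_array_equal(a, b)
        q = rng.uniform(0, 11, size=(20, 2))
        np.testing.assert_array_equal(f1.predict(q), f2.predict(q))
        assert f1.oob_error_ == f2.oob_error_

    def test_forest_prediction_is_mean_of_trees(self, rng):
        t = random_table(rng, n=25, m=2, s=2)
        f = RFEATRegressor(n_estimators=15, n_min=5, random_state=0).fit(t.X, t.Y)
        q = rng.uniform(0, 11, size=(40, 2))
        manual = np.mean([tr.predict(q) for tr in f.estimators_], axis=0)
        np.testing.assert_allclose(f.predict(q), manual, rtol=1e-12)

    def test_forest_predictor_monotone(self, rng):
        t = random_table(rng, n=25, m=2, s=1)
        f = RFEATRegressor(n_estimators=20, n_min=5, random_state=1).fit(t.X, t.Y[:, 0])
        a = rng.uniform(0, 11, size=(200, 2))
        b = a + rng.uniform(0, 3, size=(200, 2))
        assert (f.predict(b) >= f.predict(a) - 1e-12).all()

    def test_bootstrap_omission_allows_non_envelopment(self):
        # one extreme DMU: any bootstrap omitting it yields trees below its y
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        y = np.array([1.0, 1.1, 1.2, 1.3, 1.4, 5.0])
        t = make_table(X, y)
        f = RFEATRegressor(n_estimators=60, n_min=2, random_state=2).fit(X, y)
        phi = rfeat_efficiency(f, t)
        assert phi.min() < 1.0


class TestOOB:
    def test_oob_fraction_near_closed_form(self):
        n = 36
        rng = np.random.default_rng(12)
        t = random_table(rng, n=n, m=3, s=1)
        f = RFEATRegressor(n_estimators=200, n_min=7, random_state=12).fit(t.X, t.Y[:, 0])
        frac = np.mean([(~f._inbag[q]).mean() for q in range(200)])
        assert frac == pytest.approx((1 - 1 / n) ** n, abs=0.05)

    def test_zero_residual_data_gives_zero_oob_error(self):
        X = np.linspace(1, 10, 20)[:, None]
        y = np.full(20, 4.0)  # constant output: every tree predicts it exactly
        f = RFEATRegressor(n_estimators=15, n_min=3, random_state=0).fit(X, y)
        curve = f.oob_error_curve()
        assert all(e == 0.0 for _, e in curve if np.isfinite(e))

    def test_final_curve_value_matches_direct_oob_error(self, rng):
        t = random_table(rng, n=20, m=2, s=1)
        f = RFEATRegressor(n_estimators=25, n_min=5, random_state=4).fit(t.X, t.Y[:, 0])
        # independent direct evaluation of the generalization error
        errs = []
        for i in range(t.n):
            K = f.oob_sets_[i]
            if K.size == 0:
                continue
            pred = np.mean([f.estimators_[q].predict(t.X[i][None, :])[0] for q in K],
                           axis=0)
            errs.append(((t.Y[i] - pred) ** 2).sum())
        direct = float(np.mean(errs))
        assert f.oob_error_curve()[-1][1] == pytest.approx(direct, rel=1e-10)

    def test_curve_defined_and_finite_for_every_prefix(self, rng):
        t = random_table(rng, n=15, m=2, s=1)
        f = RFEATRegressor(n_estimators=30, n_min=4, random_state=9).fit(t.X, t.Y[:, 0])
        curve = f.oob_error_curve()
        assert len(curve) == 30
        assert all(np.isfinite(e) for _, e in curve[5:])


class TestPermutationImportance:
    def test_constant_column_has_exactly_zero_increase(self, rng):
        n = 30
        x1 = rng.uniform(1, 10, n)
        const = np.full(n, 3.0)
        y = 1 + x1 ** 0.5 * np.exp(-np.abs(rng.normal(0, 0.1, n)))
        t = make_table(np.column_stack([x1, const]), y)
        f = RFEATRegressor(n_estimators=40, n_min=5, random_state=5).fit(t.X, t.Y[:, 0])
        imp = f.permutation_importance(random_state=5)
        assert imp.scores.iloc[1] == 0.0

    def test_frontier_variable_has_largest_increase(self):
        rng = np.random.default_rng(21)
        n = 40
        x1 = rng.uniform(1, 10, n)
        noise = rng.uniform(1, 10, n)
        y = 2 + x1 ** 0.8 * np.exp(-np.abs(rng.normal(0, 0.05, n)))
        t = make_table(np.column_stack([x1, noise]), y)
        f = RFEATRegressor(n_estimators=100, n_min=5, random_state=21).fit(t.X, t.Y[:, 0])
        imp = f.permutation_importance(random_state=21)
        assert imp.scores.idxmax() == "x1"

    def test_zero_baseline_error_reports_undefined(self):
        X = np.linspace(1, 10, 15)[:, None]
        y = np.full(15, 2.0)
        f = RFEATRegressor(n_estimators=10, n_min=3, random_state=0).fit(X, y)
        with pytest.warns(UserWarning):
            imp = f.permutation_importance()
        assert imp.scores.isna().all()

    def test_duplicated_column_does_not_beat_original(self):
        rng = np.random.default_rng(31)
        n = 40
        x1 = rng.uniform(1, 10, n)
        y = 2 + x1 ** 0.8 * np.exp(-np.abs(rng.normal(0, 0.05, n)))
        base = make_table(x1[:, None], y)
        fb = RFEATRegressor(n_estimators=80, n_min=5, random_state=31).fit(base.X, y)
        base_inc = fb.permutation_importance(random_state=31).scores.iloc[0]
        dup = make_table(np.column_stack([x1, x1]), y)
        fd = RFEATRegressor(n_estimators=80, n_min=5, random_state=31).fit(dup.X, y)
        dup_inc = fd.permutation_importance(random_state=31).scores
        assert dup_inc.max() <= base_inc + 10.0  # masking: shared credit, stochastic tol


class TestTuning:
    def test_single_combo_grid(self, rng):
        t = random_table(rng, n=20, m=2, s=1)
        best, table = tune_rfeat(t, [(5, 10, "BREIMAN")], rng_seed=1)
        assert best == (5, 10, "BREIMAN")
        assert len(table) == 1

    def test_oob_rmse_squares_to_curve_final_value(self, rng):
        t = random_table(rng, n=20, m=2, s=1)
        _, table = tune_rfeat(t, [(5, 20, "BREIMAN")], rng_seed=2)
        f = RFEATRegressor(n_estimators=20, n_min=5, mtry="BREIMAN",
                           random_state=2).fit(t.X, t.Y)
        assert table["oob_rmse"].iloc[0] ** 2 == pytest.approx(
            f.oob_error_curve()[-1][1], rel=1e-10)

    def test_seeded_rerun_reproduces_table(self, rng):
        t = random_table(rng, n=20, m=2, s=1)
        grid = [(4, 10, "BREIMAN"), (6, 10, "DEA1")]
        _, t1 = tune_rfeat(t, grid, rng_seed=3)
        _, t2 = tune_rfeat(t, grid, rng_seed=3)
        assert t1.equals(t2)


def test_serialization_roundtrip(rng):
    t = random_table(rng, n=15, m=2, s=1)
    f = RFEATRegressor(n_estimators=8, n_min=4, random_state=6).fit(t.X, t.Y[:, 0])
    clone = RFEATRegressor.from_dict(f.to_dict())
    q = rng.uniform(0, 11, size=(20, 2))
    np.testing.assert_allclose(clone.predict(q), f.predict(q))
    assert clone.oob_error_ == pytest.approx(f.oob_error_, rel=1e-12)
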