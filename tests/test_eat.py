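import numpy as np
import pytest
from hypothesis import given, strategies as st

from fronteat import EATHyperparams, EATRegressor, grow_tree, prune_tree
from fronteat.eat import eat_importance, tune_eat, Tree
from conftest import make_table, random_table


def root_split_oracle(X, y, numstop):
    """Exhaustive scoring of every (variable, threshold) candidate at the
    root, where backups are empty so child estimates are plain maxima."""
    n = len(X)
    best = None
    for j in range(X.shape[1]):
        for s in np.unique(X[:, j])[1:]:
            lmask = X[:, j] < s
            if lmask.sum() == 0 or (~lmask).sum() == 0:
                continue
            el, er = y[lmask].max(), y[~lmask].max()
            er = max(el, er)
            err = (((y[lmask] - el) ** 2).sum() + ((y[~lmask] - er) ** 2).sum()) / n
            if best is None or err < best[0] - 1e-12:
                best = (err, j, s)
    return best


class TestGrowth:
    def test_root_split_matches_exhaustive_oracle(self, four_point_table):
        t = four_point_table
        est = EATRegressor(numstop=2, prune=False).fit(t.X, t.Y[:, 0])
        root = est.tree_.nodes[0]
        _, j, s = root_split_oracle(t.X, t.Y[:, 0], 2)
        assert (root.split_var, root.split_val) == (j, s)
        assert (root.split_var, root.split_val) == (0, 4.0)

    @given(st.integers(0, 15))
    def test_random_root_split_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n=12, m=2, s=1)
        est = EATRegressor(numstop=12, prune=False).fit(t.X, t.Y[:, 0])
        root = est.tree_.nodes[0]
        _, j, s = root_split_oracle(t.X, t.Y[:, 0], 12)
        assert (root.split_var, root.split_val) == (j, s)

    def test_node_below_numstop_not_split(self):
        t = make_table([[1.0]], [2.0])
        tree = grow_tree(t, EATHyperparams(numstop=2, fold=2))
        assert tree.n_nodes == 1
        np.testing.assert_allclose(tree.nodes[0].fest, [2.0])
        assert tree.R_T == 0.0

    def test_constant_output_splits_tiebreak_to_first_candidate(self):
        t = make_table([[1.0, 9.0], [2.0, 5.0], [3.0, 7.0], [4.0, 1.0]],
                       [3.0, 3.0, 3.0, 3.0])
        tree = grow_tree(t, EATHyperparams(numstop=4, fold=2, max_depth=1))
        root = tree.nodes[0]
        assert root.split_var == 0 and root.split_val == 2.0
        assert tree.R_T == 0.0

    def test_depth_limit_one_gives_three_nodes(self, rng):
        t = random_table(rng, n=20, m=2, s=1)
        tree = grow_tree(t, EATHyperparams(numstop=2, fold=2, max_depth=1))
        assert tree.n_nodes == 3
        assert tree.n_leaves == 2

    def test_splits_never_increase_training_error(self):
        for seed in range(10):
            t = random_table(np.random.default_rng(seed), n=30, m=2, s=1)
            tree = grow_tree(t, EATHyperparams(numstop=3, fold=2))
            for nd in tree.interior():
                child_sum = tree.nodes[nd.left].R + tree.nodes[nd.right].R
                assert child_sum <= nd.R + 1e-9

    def test_error_bookkeeping_consistent(self, rng):
        t = random_table(rng, n=30, m=3, s=2)
        tree = grow_tree(t, EATHyperparams(numstop=4, fold=2))
        recomputed = sum(
            ((t.Y[nd.obs] - nd.fest) ** 2).sum() / tree.N for nd in tree.leaves())
        assert tree.R_T == pytest.approx(recomputed, rel=1e-12)


class TestPredict:
    def test_two_leaf_step_function(self):
        t = make_table([[1.0], [2.0]], [4.0, 6.0])
        est = EATRegressor(numstop=2, prune=False).fit(t.X, t.Y[:, 0])
        assert est.predict(np.array([[1.9]]))[0] == 4.0
        assert est.predict(np.array([[2.0]]))[0] == 6.0

    def test_point_beyond_all_training_data_gets_global_max(self, rng):
        t = random_table(rng, n=25, m=3, s=2)
        est = EATRegressor(numstop=3, prune=False).fit(t.X, t.Y)
        big = t.X.max(axis=0) + 1.0
        np.testing.assert_allclose(est.predict(big[None, :])[0], t.Y.max(axis=0))

    def test_envelope_covers_every_observation(self, rng):
        for _ in range(5):
            t = random_table(rng, n=30, m=2, s=2)
            est = EATRegressor(numstop=4, prune=False).fit(t.X, t.Y)
            pred = est.predict(t.X)
            assert (pred >= t.Y - 1e-9).all()

    @given(st.integers(0, 10))
    def test_monotone_in_every_input(self, seed):
        rng = np.random.default_rng(seed)
        t = random_table(rng, n=30, m=2, s=1)
        est = EATRegressor(numstop=3, prune=False).fit(t.X, t.Y[:, 0])
        a = rng.uniform(0, 11, size=(200, 2))
        b = a + rng.uniform(0, 3, size=(200, 2))
        assert (est.predict(b) >= est.predict(a) - 1e-12).all()


class TestPruning:
    def test_single_node_tree_unchanged(self):
        t = make_table([[1.0], [1.0]], [2.0, 3.0])
        tree = grow_tree(t, EATHyperparams(numstop=2, fold=2))
        pruned = prune_tree(tree, t.X, t.Y, fold=2)
        assert pruned.n_nodes == 1

    def test_pruning_never_adds_leaves(self, rng):
        for _ in range(5):
            t = random_table(rng, n=30, m=2, s=1)
            tree = grow_tree(t, EATHyperparams(numstop=3, fold=5))
            pruned = prune_tree(tree, t.X, t.Y, fold=5, rng_seed=1)
            assert pruned.n_leaves <= tree.n_leaves

    def test_fold_larger_than_n_rejected(self):
        t = make_table([[1.0], [2.0]], [1.0, 2.0])
        tree = grow_tree(t, EATHyperparams(numstop=2, fold=2))
        with pytest.raises(ValueError):
            prune_tree(tree, t.X, t.Y, fold=5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_one_step_frontier_pruned_to_two_leaves(self, seed):
        xs = np.linspace(0.0, 1.0, 40, endpoint=False)
        ys = np.where(xs < 0.5, 1.0, 2.0)
        est = EATRegressor(numstop=5, fold=5, random_state=seed).fit(xs[:, None], ys)
        assert est.tree_.n_leaves == 2
        assert est.predict(np.array([[0.2]]))[0] == 1.0
        assert est.predict(np.array([[0.8]]))[0] == 2.0


class TestImportance:
    def test_single_split_variable_gets_100(self):
        xs = np.linspace(0.0, 1.0, 30, endpoint=False)
        noise = np.zeros((30, 1)) + 0.5  # constant second input never splits
        X = np.column_stack([xs, noise])
        ys = np.where(xs < 0.5, 1.0, 2.0)
        t = make_table(X, ys)
        imp = eat_importance(t, EATHyperparams(numstop=5, fold=5))
        assert imp.scores.iloc[0] == 100.0
        assert imp.scores.iloc[1] == 0.0

    def test_no_split_tree_warns_all_zero(self):
        t = make_table([[1.0], [1.0]], [2.0, 2.0])
        with pytest.warns(UserWarning):
            imp = eat_importance(t, EATHyperparams(numstop=2, fold=2))
        assert (imp.scores == 0).all()

    def test_frontier_variable_dominates_pure_noise(self):
        rng = np.random.default_rng(7)
        n = 60
        x1 = rng.uniform(1, 10, n)
        x2 = rng.uniform(1, 10, n)  # irrelevant
        y = 2 + x1 ** 0.7
        t = make_table(np.column_stack([x1, x2]), y)
        imp = eat_importance(t, EATHyperparams(numstop=5, fold=5))
        assert imp.scores.iloc[0] == 100.0
        assert imp.scores.iloc[0] > imp.scores.iloc[1]

    def test_max_normalization_is_exactly_100(self, rng):
        t = random_table(rng, n=30, m=3, s=1)
        imp = eat_importance(t, EATHyperparams(numstop=3, fold=5))
        if (imp.scores > 0).any():
            assert imp.scores.max() == 100.0


class TestTuning:
    def test_single_combo_grid(self, rng):
        t = random_table(rng, n=20, m=2, s=1)
        hp = EATHyperparams(numstop=5, fold=3)
        best, table = tune_eat(t, [hp])
        assert best is hp
        assert len(table) == 1

    def test_paper_grid_fits_six_models(self, rng):
        t = random_table(rng, n=30, m=2, s=1)
        grid = [EATHyperparams(numstop=ns, fold=f)
                for ns in (3, 5, 7) for f in (5, 7)]
        _, table = tune_eat(t, grid, rng_seed=3)
        assert len(table) == 6
        assert (table["rmse"] >= 0).all()

    def test_reproducible_under_same_seed(self, rng):
        t = random_table(rng, n=25, m=2, s=1)
        grid = [EATHyperparams(numstop=ns, fold=3) for ns in (3, 5)]
        _, t1 = tune_eat(t, grid, rng_seed=11)
        _, t2 = tune_eat(t, grid, rng_seed=11)
        assert t1.equals(t2)


class TestSerialization:
    def test_json_roundtrip_preserves_predictions(self, rng):
        t = random_table(rng, n=25, m=2, s=2)
        est = EATRegressor(numstop=4, fold=3, random_state=0).fit(t.X, t.Y)
        clone = Tree.from_dict(est.tree_.to_dict())
        q = rng.uniform(0, 11, size=(50, 2))
        np.testing.assert_allclose(clone.predict(q), est.tree_.predict(q))


class TestSklearnInterface:
    def test_get_set_params_roundtrip(self):
        est = EATRegressor()
        params = est.get_params()
        est.set_params(numstop=7, fold=3)
        assert est.numstop == 7
        with pytest.raises(ValueError):
            est.set_params(bogus=1)
        assert set(params) == {"numstop", "fold", "max_depth", "prune", "random_state"}

    def test_feature_importances_sum_to_one(self, rng):
        t = random_table(rng, n=30, m=3, s=1)
        est = EATRegressor(numstop=4, fold=3, random_state=0).fit(t.X, t.Y[:, 0])
        if est.feature_importances_.sum() > 0:
            assert est.feature_importances_.sum() == pytest.approx(1.0)
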