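import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from mkbmc import (
    cc_matrix,
    fit,
    kernel_score,
    predict_proba,
    read_newick,
    rho_max,
    similarity_tscore,
    solve_weights,
    tune_rho,
)
from mkbmc.kernels import KernelMatrix
from mkbmc.model import FitConfig, MKBMCModel, _fit_logistic


class TestCCMatrix:
    def test_definition(self):
        cc = cc_matrix([1, 1, 0])
        expected = [[0, 1, -1], [1, 0, -1], [-1, -1, 0]]
        np.testing.assert_array_equal(cc, expected)

    def test_symmetric_and_sum(self, rng):
        y = rng.integers(0, 2, size=12)
        y[:2] = [0, 1]
        cc = cc_matrix(y)
        np.testing.assert_array_equal(cc, cc.T)
        n1 = y.sum()
        n0 = len(y) - n1
        same = n1 * (n1 - 1) + n0 * (n0 - 1)
        assert cc.sum() == same - 2 * n1 * n0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cc_matrix([1, 1, 1])


class TestKernelScore:
    def test_diagonal_kernel_scores_zero(self):
        K = np.eye(3)
        assert kernel_score(K, cc_matrix([1, 1, 0])) == 0.0

    def test_all_ones_kernel_equals_cc_sum(self):
        cc = cc_matrix([1, 1, 0])
        assert kernel_score(np.ones((3, 3)), cc) == cc.sum() == -2

    def test_linearity_in_offdiagonal_shift(self, rng):
        y = np.r_[np.ones(4, int), np.zeros(4, int)]
        cc = cc_matrix(y)
        K = rng.random((8, 8))
        K = (K + K.T) / 2
        shifted = K + 0.3 * (1 - np.eye(8))
        assert kernel_score(shifted, cc) == pytest.approx(
            kernel_score(K, cc) + 0.3 * cc.sum()
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            kernel_score(np.ones((2, 2)), cc_matrix([1, 0, 1]))


def entropy_objective(w, S, rho):
    wl = np.where(w > 0, w * np.log(np.where(w > 0, w, 1.0)), 0.0)
    return -(w * S).sum() + rho * wl.sum()


class TestSolveWeights:
    def test_symmetric_scores_split_evenly(self):
        np.testing.assert_allclose(
            solve_weights([3.0, 3.0], 2.0).values, [0.5, 0.5]
        )

    def test_two_kernel_closed_form(self):
        w = solve_weights([1.0, 0.0], 1.0).values
        e = np.e
        np.testing.assert_allclose(w, [e / (1 + e), 1 / (1 + e)], atol=1e-12)

    def test_large_rho_limit_uniform(self):
        w = solve_weights([1.0, 0.0], 1e9).values
        np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-6)

    def test_rho_zero_argmax_and_tie_split(self):
        np.testing.assert_array_equal(
            solve_weights([2.0, 5.0, 1.0], 0.0).values, [0, 1, 0]
        )
        np.testing.assert_allclose(
            solve_weights([5.0, 5.0, 1.0], 0.0).values, [0.5, 0.5, 0]
        )

    @settings(derandomize=True, max_examples=40)
    @given(
        S=st.lists(st.floats(-50, 50), min_size=2, max_size=6),
        rho=st.floats(0.05, 100.0),
    )
    def test_beats_random_simplex_points(self, S, rho):
        S = np.asarray(S)
        w = solve_weights(S, rho).values
        obj = entropy_objective(w, S, rho)
        rng = np.random.default_rng(0)
        rand = rng.dirichlet(np.ones(len(S)), size=1000)
        rand_obj = np.array([entropy_objective(r, S, rho) for r in rand])
        assert obj <= rand_obj.min() + 1e-9

    @settings(derandomize=True, max_examples=40)
    @given(S=st.lists(st.floats(-5, 5), min_size=2, max_size=5, unique=True))
    def test_entropy_nondecreasing_in_rho_and_order_preserved(self, S):
        from hypothesis import assume

        S = np.asarray(S)
        assume(np.diff(np.sort(S)).min() > 1e-3)
        ent = []
        for rho in [0.1, 0.5, 1, 5, 20]:
            w = solve_weights(S, rho).values
            wl = w[w > 0]
            ent.append(-(wl * np.log(wl)).sum())
            assert (np.argsort(S).tolist() == np.argsort(w).tolist())
        assert all(b >= a - 1e-12 for a, b in zip(ent, ent[1:]))


class TestRhoMax:
    def test_equal_scores_return_one(self):
        assert rho_max([2.0, 2.0, 2.0]) == 1.0

    def test_unit_gap_needs_rho_sixteen(self):
        assert rho_max([1.0, 0.0]) == 16.0

    def test_nondecreasing_in_score_spread(self):
        spreads = [0.5, 1, 2, 4, 8, 32]
        values = [rho_max([s, 0.0]) for s in spreads]
        assert all(b >= a for a, b in zip(values, values[1:]))


class TestSimilarityTscore:
    def test_hand_welch_value(self):
        k = np.array([0.9, 0.8, 0.1, 0.2])
        y = np.array([1, 1, 0, 0])
        assert similarity_tscore(k, y) == pytest.approx(
            0.7 / np.sqrt(0.005 / 2 + 0.005 / 2)
        )

    def test_identical_groups_score_zero(self):
        k = np.array([0.3, 0.7, 0.3, 0.7])
        y = np.array([1, 1, 0, 0])
        assert similarity_tscore(k, y) == 0.0

    def test_label_swap_negates(self, rng):
        k = rng.random(10)
        y = np.r_[np.ones(5, int), np.zeros(5, int)]
        assert similarity_tscore(k, y) == pytest.approx(
            -similarity_tscore(k, 1 - y)
        )

    def test_leave_self_out(self):
        k = np.array([1.0, 0.9, 0.8, 0.1, 0.2, 0.3])
        y = np.array([1, 1, 1, 0, 0, 0])
        with_self = similarity_tscore(k, y)
        without = similarity_tscore(k, y, self_index=0)
        assert with_self != without

    def test_too_few_per_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            similarity_tscore([0.5, 0.5, 0.5], [1, 0, 0])

    def test_zero_variance_warns_and_returns_zero(self):
        k = np.array([0.5, 0.5, 0.2, 0.2])
        with pytest.warns(UserWarning, match="zero variance"):
            t = similarity_tscore(k, [1, 1, 0, 0])
        assert t == 0.0


class TestLogistic:
    def test_recovers_known_coefficients(self, rng):
        t = rng.standard_normal(4000)
        y = (rng.random(4000) < expit(0.5 + 1.5 * t)).astype(int)
        b0, b1 = _fit_logistic(t, y)
        assert b0 == pytest.approx(0.5, abs=0.15)
        assert b1 == pytest.approx(1.5, abs=0.15)

    def test_separation_clamped(self):
        t = np.r_[np.ones(10), -np.ones(10)]
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        with pytest.warns(UserWarning, match="separation"):
            b0, b1 = _fit_logistic(t, y)
        assert b1 == 30.0


def _kernel_from_scores(vals, ids):
    return KernelMatrix(np.asarray(vals), ids, ids, 1.0, "toy")


def _make_class_kernel(y, inside, outside, noise_rng=None):
    y = np.asarray(y)
    K = np.where(y[:, None] == y[None, :], inside, outside).astype(float)
    if noise_rng is not None:
        eps = noise_rng.uniform(-0.02, 0.02, size=K.shape)
        K = np.clip(K + (eps + eps.T) / 2, 0.01, 1.0)
    np.fill_diagonal(K, 1.0)
    return K


class TestTuneRho:
    def test_grid_has_eleven_values_starting_at_zero(self, rng):
        y = rng.permutation(np.repeat([0, 1], 25))
        K = _make_class_kernel(y, 0.9, 0.1, rng)
        ids = list(range(50))
        best, grid, _ = tune_rho([_kernel_from_scores(K, ids)] * 2, y, seed=0)
        assert len(grid) == 11 and grid[0] == 0.0

    def test_identical_informative_kernels_tie_to_rho_max(self, rng):
        y = rng.permutation(np.repeat([0, 1], 30))
        K = _make_class_kernel(y, 0.9, 0.1, rng)
        ids = list(range(60))
        kernels = [_kernel_from_scores(K, ids), _kernel_from_scores(K.copy(), ids)]
        best, grid, aucs = tune_rho(kernels, y, seed=1)
        assert np.allclose(aucs, aucs[0])
        assert best == grid[-1]

    def test_informative_kernel_outweighs_noise(self, rng):
        n = 200
        y = rng.permutation(np.repeat([0, 1], n // 2))
        K_info = _make_class_kernel(y, 0.85, 0.15, rng)
        noise = rng.uniform(0.2, 0.8, size=(n, n))
        K_noise = np.clip((noise + noise.T) / 2, 0.01, 1.0)
        np.fill_diagonal(K_noise, 1.0)
        ids = list(range(n))
        kernels = [
            _kernel_from_scores(K_info, ids),
            _kernel_from_scores(K_noise, ids),
        ]
        best, _, _ = tune_rho(kernels, y, seed=2)
        S = np.array([kernel_score(K, cc_matrix(y)) for K in kernels])
        w = solve_weights(S, best).values
        assert w[0] > 0.5


@pytest.fixture(scope="module")
def fitted(small_sim):
    train, test = small_sim
    model = fit(
        train.counts, train.tree, train.metadata, FitConfig(seed=7, rho=1.0)
    )
    return model, train, test


class TestFitPredict:
    def test_weights_form_probability_vector(self, fitted):
        model, _, _ = fitted
        assert (model.weights >= 0).all()
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_sample_order_permutation_invariance(self, fitted, rng):
        model, train, test = fitted
        perm = rng.permutation(len(train.counts))
        model2 = fit(
            train.counts.iloc[perm], train.tree,
            train.metadata.iloc[perm], FitConfig(seed=7, rho=1.0),
        )
        np.testing.assert_allclose(model2.weights, model.weights, atol=1e-9)
        p1 = predict_proba(model, test.counts)
        p2 = predict_proba(model2, test.counts)
        np.testing.assert_allclose(p1.values, p2.values, atol=1e-9)

    def test_probabilities_in_unit_interval(self, fitted):
        model, _, test = fitted
        p = predict_proba(model, test.counts)
        assert ((p > 0) & (p < 1)).all()

    def test_no_test_leakage(self, fitted):
        model, _, test = fitted
        full = predict_proba(model, test.counts)
        alone = predict_proba(model, test.counts.iloc[[3]])
        assert alone.iloc[0] == pytest.approx(full.iloc[3], abs=1e-12)

    def test_duplicated_case_scores_above_duplicated_control(self):
        # two disjoint-support groups, fully separable by every metric
        tree = read_newick(
            "((L1:1,L2:1):1,(L3:1,L4:1):1);"
        )
        rng = np.random.default_rng(0)
        rows, labels = [], []
        for i in range(20):
            case = i % 2 == 1
            base = np.array([0.6, 0.4, 0.0, 0.0]) if case else np.array(
                [0.0, 0.0, 0.4, 0.6]
            )
            jitter = rng.dirichlet([40, 40]) if case else rng.dirichlet([40, 40])
            row = base.copy()
            row[row > 0] = jitter * 1.0
            rows.append(row)
            labels.append(int(case))
        tab = pd.DataFrame(
            rows, index=[f"s{i}" for i in range(20)],
            columns=["L1", "L2", "L3", "L4"],
        )
        meta = pd.DataFrame({"label": labels}, index=tab.index)
        model = fit(tab, tree, meta, FitConfig(seed=0, rho=1.0))
        test_tab = tab.iloc[[1, 0]].copy()
        test_tab.index = ["dup_case", "dup_ctrl"]
        p = predict_proba(model, test_tab)
        assert p["dup_case"] > p["dup_ctrl"]

    def test_json_round_trip_preserves_predictions(self, fitted, tmp_path):
        model, _, test = fitted
        path = tmp_path / "model.json"
        model.to_json(str(path))
        loaded = MKBMCModel.from_json(str(path))
        np.testing.assert_allclose(loaded.weights, model.weights)
        p1 = predict_proba(model, test.counts)
        p2 = predict_proba(loaded, test.counts)
        np.testing.assert_allclose(p1.values, p2.values, atol=1e-9)

    def test_covariate_kernel_enters_model(self, small_sim, rng):
        train, test = small_sim
        meta = train.metadata.copy()
        meta["age"] = rng.normal(50, 10, size=len(meta))
        model = fit(
            train.counts, train.tree, meta,
            FitConfig(seed=3, rho=1.0, covariates=("age",)),
        )
        assert "covariate:age" in model.kernel_names
        assert len(model.weights) == 5
        meta_test = pd.DataFrame(
            {"age": rng.normal(50, 10, size=len(test.counts))},
            index=test.counts.index,
        )
        p = predict_proba(model, test.counts, meta_test)
        assert ((p > 0) & (p < 1)).all()
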