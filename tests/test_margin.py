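import numpy as np
import pytest
from scipy.optimize import minimize

from ema import (
    DegenerateFoldError,
    Hyperplane,
    SyntheticConfig,
    build_relevance_list,
    fit_max_margin,
    generate_synthetic,
    geometric_margin,
    loo_error_margin,
    margin_curve,
    reorder,
)
from conftest import make_dataset

LARGE_C = 1e6


def hard_margin_qp(X, y):
    """Independent oracle: primal hard-margin QP via SLSQP.

    minimise 0.5 ||w||^2  s.t.  y_j (<w, x_j> + b) >= 1;
    the geometric margin of the optimum is 1 / ||w||.
    """
    n, d = X.shape

    def obj(z):
        return 0.5 * z[:d] @ z[:d]

    def jac(z):
        g = np.zeros(d + 1)
        g[:d] = z[:d]
        return g

    cons = {
        "type": "ineq",
        "fun": lambda z: y * (X @ z[:d] + z[d]) - 1.0,
        "jac": lambda z: np.c_[y[:, None] * X, y],
    }
    # feasible-ish start: centroid separator
    w0 = X[y == 1].mean(0) - X[y == -1].mean(0)
    z0 = np.r_[w0, 0.0] * 10
    res = minimize(obj, z0, jac=jac, constraints=[cons], method="SLSQP",
                   options={"maxiter": 500, "ftol": 1e-12})
    assert res.success, res.message
    return 1.0 / np.linalg.norm(res.x[:d])


def random_separable(rng, n, d, gap=1.0):
    """Two Gaussian clouds pushed apart until linearly separable."""
    for _ in range(100):
        y = np.r_[np.full(n // 2, -1), np.full(n - n // 2, 1)]
        X = rng.normal(size=(n, d))
        X[y == 1] += gap
        try:
            hard_margin_qp(X, y)
        except AssertionError:
            gap *= 1.5
            continue
        return X, y
    raise RuntimeError("could not build separable instance")


class TestFitMaxMargin:
    def test_symmetric_two_point_problem(self, dataset_factory):
        ds = dataset_factory([[-1.0], [1.0]], [-1, 1])
        plane = fit_max_margin(ds, C=LARGE_C)
        m = geometric_margin(plane, ds.values, ds.labels)
        assert m == pytest.approx(1.0, abs=1e-6)
        # boundary at x = 0
        assert plane.bias / np.linalg.norm(plane.weights) == pytest.approx(0, abs=1e-6)

    def test_duplicate_pattern_leaves_hyperplane_unchanged(self, separable_ds):
        plane = fit_max_margin(separable_ds, C=LARGE_C)
        dup = make_dataset(
            np.vstack([separable_ds.values, separable_ds.values[:1]]),
            np.r_[separable_ds.labels, separable_ds.labels[0]],
        )
        plane2 = fit_max_margin(dup, C=LARGE_C)
        w1 = plane.weights / np.linalg.norm(plane.weights)
        w2 = plane2.weights / np.linalg.norm(plane2.weights)
        np.testing.assert_allclose(w1, w2, atol=1e-5)

    def test_single_class_rejected(self, dataset_factory):
        with pytest.warns(UserWarning):
            ds = dataset_factory([[0.0], [1.0]], [1, 1])
        with pytest.raises(DegenerateFoldError):
            fit_max_margin(ds)

    @pytest.mark.parametrize("seed", range(20))
    def test_margin_matches_hard_margin_qp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 21))
        d = int(rng.integers(2, 6))
        X, y = random_separable(rng, n, d, gap=2.0)
        ds = make_dataset(X, y)
        plane = fit_max_margin(ds, C=LARGE_C)
        ours = geometric_margin(plane, X, y)
        oracle = hard_margin_qp(X, y)
        assert ours == pytest.approx(oracle, rel=1e-4)


class TestGeometricMargin:
    def test_unit_case(self):
        plane = Hyperplane(weights=[1.0], bias=0.0)
        m = geometric_margin(plane, [[-1.0], [1.0]], [-1, 1])
        assert m == 1.0

    def test_scale_invariance_of_hyperplane(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        y = np.where(rng.uniform(size=10) < 0.5, -1, 1)
        plane = Hyperplane(weights=[0.5, -1.0, 2.0], bias=0.3)
        double = Hyperplane(weights=2 * plane.weights, bias=2 * plane.bias)
        assert geometric_margin(double, X, y) == pytest.approx(
            geometric_margin(plane, X, y), rel=1e-12
        )

    def test_translation_invariance_of_pattern_set(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 4))
        y = np.r_[np.full(4, -1), np.full(4, 1)]
        ds = make_dataset(X, y)
        plane = fit_max_margin(ds, C=LARGE_C)
        m0 = geometric_margin(plane, X, y)
        shift = rng.normal(size=4)
        ds2 = make_dataset(X + shift, y)
        plane2 = fit_max_margin(ds2, C=LARGE_C)
        assert geometric_margin(plane2, X + shift, y) == pytest.approx(m0, rel=1e-4)

    def test_equals_brute_force_signed_distances(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 5))
        y = np.where(rng.uniform(size=15) < 0.5, -1, 1)
        plane = Hyperplane(weights=rng.normal(size=5), bias=rng.normal())
        brute = min(
            yi * (xi @ plane.weights + plane.bias) / np.linalg.norm(plane.weights)
            for xi, yi in zip(X, y)
        )
        assert geometric_margin(plane, X, y) == pytest.approx(brute, rel=1e-12)

    def test_correct_only_excludes_negative_margins(self):
        plane = Hyperplane(weights=[1.0], bias=0.0)
        X = np.array([[-2.0], [0.5], [1.0]])
        y = np.array([-1, -1, 1])  # second pattern misclassified
        assert geometric_margin(plane, X, y) == pytest.approx(-0.5)
        assert geometric_margin(plane, X, y, correct_only=True) == pytest.approx(1.0)

    def test_no_correct_pattern_is_degenerate(self):
        plane = Hyperplane(weights=[1.0], bias=0.0)
        with pytest.raises(DegenerateFoldError):
            geometric_margin(plane, [[1.0]], [-1], correct_only=True)


class TestLooErrorMargin:
    def test_symmetric_four_point_set(self, dataset_factory):
        # {(-1, y=-1) x2, (+1, y=+1) x2}: every fold leaves a symmetric or
        # shifted-but-equivalent problem with margin 1.
        ds = dataset_factory([[-1.0], [-1.0], [1.0], [1.0]], [-1, -1, 1, 1])
        assert loo_error_margin(ds, C=LARGE_C) == pytest.approx(1.0, abs=1e-6)

    def test_equals_mean_of_per_fold_margins(self, separable_ds):
        n = separable_ds.n_samples
        folds = []
        for j in range(n):
            keep = np.ones(n, bool)
            keep[j] = False
            sub = make_dataset(separable_ds.values[keep], separable_ds.labels[keep])
            plane = fit_max_margin(sub, C=100.0)
            folds.append(
                geometric_margin(plane, sub.values, sub.labels, correct_only=True)
            )
        assert loo_error_margin(separable_ds, C=100.0) == pytest.approx(
            np.mean(folds), rel=1e-10
        )

    def test_sample_order_invariance(self, separable_ds):
        perm = np.random.default_rng(9).permutation(separable_ds.n_samples)
        shuffled = make_dataset(
            separable_ds.values[perm], separable_ds.labels[perm]
        )
        assert loo_error_margin(shuffled) == pytest.approx(
            loo_error_margin(separable_ds), rel=1e-6
        )

    def test_positive_on_separable_folds_with_large_C(self, separable_ds):
        assert loo_error_margin(separable_ds, C=LARGE_C) > 0

    def test_too_few_samples_rejected(self, dataset_factory):
        ds = dataset_factory([[-1.0], [1.0]], [-1, 1])
        with pytest.raises(ValueError):
            loo_error_margin(ds)


class TestMarginCurve:
    @pytest.fixture(scope="class")
    def ordered_ds(self):
        train, _ = generate_synthetic(SyntheticConfig(d_total=40, seed=31))
        return reorder(train, build_relevance_list(train))

    def test_each_point_equals_direct_loo_call(self, ordered_ds):
        curve = margin_curve(ordered_ds, f_max=6)
        for i in (1, 3, 6):
            direct = loo_error_margin(ordered_ds, genes=range(i))
            assert curve.values[i - 1] == pytest.approx(direct, rel=1e-12)

    def test_genes_beyond_f_max_have_no_effect(self, ordered_ds):
        curve_a = margin_curve(ordered_ds, f_max=5)
        truncated = ordered_ds.restrict(range(10))
        curve_b = margin_curve(truncated, f_max=5)
        np.testing.assert_allclose(curve_a.values, curve_b.values, rtol=1e-12)

    def test_relevant_segment_grows_faster_than_background_segment(self):
        # the knee property that makes critical-point estimation possible
        for seed in (101, 102, 103):
            train, _ = generate_synthetic(SyntheticConfig(seed=seed))
            ordered = reorder(train, build_relevance_list(train))
            W = margin_curve(ordered, f_max=60).values
            slope_R = (W[19] - W[0]) / 19
            slope_I = (W[59] - W[29]) / 30
            assert slope_R > slope_I

    def test_f_max_validated(self, ordered_ds):
        with pytest.raises(ValueError):
            margin_curve(ordered_ds, f_max=ordered_ds.n_genes + 1)
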