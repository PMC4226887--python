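import numpy as np
import pytest
from scipy.special import logsumexp

from conftest import maxent_objective_oracle, random_maxent_instance
from oroniche.grid import Grid, PipelineError
from oroniche.maxent import (
    FeatureSet,
    MaxentModel,
    build_features,
    default_feature_classes,
    fit_maxent,
    load_model,
    regularized_gain,
    train_replicates,
)
from oroniche.terrain import PredictorStack


def toy_stack(n=20, seed=0, categorical=False):
    rng = np.random.default_rng(seed)
    grids = {
        "A": Grid(rng.normal(100, 30, (n, n)), cell_size=1.0),
        "B": Grid(rng.normal(-5, 2, (n, n)), cell_size=1.0),
        "C": Grid(rng.random((n, n)) * 1000, cell_size=1.0),
    }
    cats = set()
    if categorical:
        grids["LAND"] = Grid(rng.integers(1, 7, (n, n)), cell_size=1.0)
        cats = {"LAND"}
    return PredictorStack(grids=grids, categorical=cats)


def sample_cells(rng, n_cells, shape):
    idx = rng.choice(shape[0] * shape[1], size=n_cells, replace=False)
    return idx // shape[1], idx % shape[1]


class TestFeatures:
    def test_linear_only_feature_count(self):
        stack = toy_stack()
        rng = np.random.default_rng(0)
        bg = sample_cells(rng, 50, stack.reference.shape)
        fs = build_features(stack, bg, classes={"linear"})
        assert fs.n_features == 3
        assert all(d.kind == "linear" for d in fs.descriptors)

    def test_categorical_expands_to_indicators(self):
        stack = toy_stack(categorical=True)
        rng = np.random.default_rng(1)
        bg = sample_cells(rng, 200, stack.reference.shape)
        fs = build_features(stack, bg, classes={"linear"})
        cat = [d for d in fs.descriptors if d.kind == "category"]
        assert len(cat) == 6  # one indicator per land-cover category

    def test_linear_rescaling_hits_unit_interval(self):
        stack = toy_stack()
        rng = np.random.default_rng(2)
        bg = sample_cells(rng, 80, stack.reference.shape)
        fs = build_features(stack, bg, classes={"linear"})
        F = fs.at_cells(*bg)
        # min/max scan oracle: background min -> 0, max -> 1, cell by cell
        V = stack.sample(*bg)
        for j, d in enumerate(fs.descriptors):
            col = stack.names.index(d.variable)
            expected = (V[:, col] - V[:, col].min()) / np.ptp(V[:, col])
            np.testing.assert_allclose(F[:, j], expected)
        assert F.min() == pytest.approx(0.0) and F.max() == pytest.approx(1.0)

    def test_hinge_knots_at_background_quantiles(self):
        stack = toy_stack()
        rng = np.random.default_rng(3)
        bg = sample_cells(rng, 100, stack.reference.shape)
        fs = build_features(stack, bg, classes={"hinge"}, hinge_knots=5)
        knots = [d.knot for d in fs.descriptors if d.variable == "A"]
        v = stack.sample(*bg)[:, 0]
        expected = np.quantile(v, np.arange(1, 6) / 6)
        np.testing.assert_allclose(sorted(knots), sorted(expected))

    def test_default_classes_depend_on_sample_size(self):
        assert default_feature_classes(15) == {"linear", "quadratic", "hinge"}
        assert default_feature_classes(10) == {"linear", "quadratic"}


class TestFit:
    def test_constant_feature_gives_uniform_raw(self):
        X = np.ones((30, 1))
        model = fit_maxent(None, X, np.arange(5), beta=1.0)
        raw = np.exp(-model.log_z) * np.ones(30)
        np.testing.assert_allclose(raw, 1 / 30)
        assert model.coefs[0] == 0.0

    def test_unregularized_two_cell_concentrates_mass(self):
        # presences all at the feature-1 cell: ML pushes the mass there
        X = np.array([[0.0], [1.0]])
        X = np.vstack([X, [[1.0]] * 4])  # presences (4 copies of cell 1)
        model = fit_maxent(None, X, np.arange(2, 6), beta=0.0, max_iter=2000)
        raw = np.exp(X[:2] @ model.coefs - model.log_z)
        assert raw[1] / (raw[0] + raw[1]) > 0.99

    def test_matches_convex_optimizer_oracle(self):
        rng = np.random.default_rng(7)
        for i in range(5):
            X, pidx = random_maxent_instance(rng, max_cells=120)
            beta = [0.5, 1.0, 2.0][i % 3]
            model = fit_maxent(None, X, pidx, beta=beta, max_iter=20000, tol=1e-12)
            _, f_oracle = maxent_objective_oracle(X, pidx, model.lambdas)
            assert abs(model.objective - f_oracle) < 1e-6

    def test_normalization_and_kkt_box(self):
        rng = np.random.default_rng(8)
        X, pidx = random_maxent_instance(rng)
        model = fit_maxent(None, X, pidx, beta=1.0, max_iter=20000, tol=1e-12)
        eta = X @ model.coefs
        raw = np.exp(eta - model.log_z)
        assert abs(raw.sum() - 1.0) < 1e-9
        # every feature expectation sits inside the lambda box
        gap = np.abs(raw @ X - model.presence_mean)
        assert np.all(gap <= model.lambdas + 1e-6)

    def test_sparsity_non_increasing_in_beta(self):
        rng = np.random.default_rng(9)
        X, pidx = random_maxent_instance(rng, max_cells=150)
        nnz = [fit_maxent(None, X, pidx, beta=b, max_iter=20000, tol=1e-12).n_nonzero
               for b in (0.5, 1.0, 2.0, 4.0)]
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))

    def test_too_few_presences_rejected(self):
        with pytest.raises(PipelineError):
            fit_maxent(None, np.random.default_rng(0).random((10, 2)), [1], beta=1.0)


class TestPredict:
    def _uniform_model(self, n=10):
        return MaxentModel(
            feature_set=None, coefs=np.zeros(1), lambdas=np.zeros(1), beta=1.0,
            log_z=np.log(n), entropy=np.log(n), objective=np.log(n), n_support=n,
            converged=True, n_iter=1)

    def test_uniform_model_logistic_is_half(self):
        m = self._uniform_model(17)
        F = np.zeros((17, 1))
        np.testing.assert_allclose(m.raw_from_features(F), 1 / 17)
        np.testing.assert_allclose(m.logistic_from_features(F), 0.5)

    def test_logistic_monotone_in_raw(self):
        m = self._uniform_model()
        F = np.linspace(-3, 3, 50).reshape(-1, 1)
        m.coefs = np.array([1.0])
        raw = m.raw_from_features(F)
        logi = m.logistic_from_features(F)
        order = np.argsort(raw)
        assert np.all(np.diff(logi[order]) > 0)

    def test_two_cell_hand_computation(self):
        # raw = (1/4, 3/4): eta = (0, ln 3), Z = 4
        w = np.array([np.log(3.0)])
        log_z = logsumexp([0.0, np.log(3.0)])
        H = -(0.25 * np.log(0.25) + 0.75 * np.log(0.75))
        m = MaxentModel(feature_set=None, coefs=w, lambdas=np.zeros(1), beta=1.0,
                        log_z=log_z, entropy=H, objective=0.0, n_support=2,
                        converged=True, n_iter=1)
        F = np.array([[0.0], [1.0]])
        np.testing.assert_allclose(m.raw_from_features(F), [0.25, 0.75])
        expected = np.array([0.25 * np.e ** H / (1 + 0.25 * np.e ** H),
                             0.75 * np.e ** H / (1 + 0.75 * np.e ** H)])
        np.testing.assert_allclose(m.logistic_from_features(F), expected)


class TestGain:
    def test_uniform_model_gain_zero(self):
        X = np.ones((25, 1))
        model = fit_maxent(None, X, np.arange(5), beta=1.0)
        assert regularized_gain(model) == pytest.approx(0.0)

    def test_informative_model_gain_positive(self):
        rng = np.random.default_rng(10)
        X = rng.random((60, 2))
        pidx = np.argsort(X[:, 0])[-8:]  # presences at high feature values
        model = fit_maxent(None, X, pidx, beta=0.5)
        assert regularized_gain(model) > 0

    def test_gain_matches_definition_on_toy_model(self):
        # cross-check the objective-based gain against the definition:
        # mean ln raw at presences - ln(1/N) - penalty
        X = np.array([[0.0], [0.3], [0.7], [1.0], [1.0], [0.9]])
        pidx = np.array([3, 4, 5])
        model = fit_maxent(None, X, pidx, beta=1.0, tol=1e-12, max_iter=10000)
        raw = np.exp(X @ model.coefs - model.log_z)
        direct = (np.mean(np.log(raw[pidx])) + np.log(len(X))
                  - float(model.lambdas @ np.abs(model.coefs)))
        assert regularized_gain(model) == pytest.approx(direct, abs=1e-9)


class TestReplicates:
    def _setup(self, m=8, seed=0):
        stack = toy_stack(n=25, seed=seed)
        rng = np.random.default_rng(seed)
        bg = sample_cells(rng, 150, stack.reference.shape)
        pres = sample_cells(rng, m, stack.reference.shape)
        fs = build_features(stack, bg, pres, classes={"linear", "quadratic"})
        return fs, pres, bg

    def test_split_arithmetic(self):
        fs, pres, bg = self._setup(m=8)
        runs = train_replicates(fs, pres, bg, n_replicates=1, test_fraction=0.25,
                                seed=1)
        assert len(runs[0].train_idx) == 6 and len(runs[0].test_idx) == 2

    def test_same_seed_identical_splits(self):
        fs, pres, bg = self._setup(m=12)
        a = train_replicates(fs, pres, bg, n_replicates=3, seed=5)
        b = train_replicates(fs, pres, bg, n_replicates=3, seed=5)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.test_idx, rb.test_idx)
            np.testing.assert_array_equal(ra.model.coefs, rb.model.coefs)

    def test_fifty_replicates_have_distinct_splits(self):
        fs, pres, bg = self._setup(m=74, seed=2)
        runs = train_replicates(fs, pres, bg, n_replicates=50, seed=3,
                                max_iter=50, tol=1e-4)
        signatures = {tuple(r.test_idx) for r in runs}
        assert len(signatures) == 50

    def test_too_few_presences_named_minimum(self):
        fs, pres, bg = self._setup(m=2)
        with pytest.raises(PipelineError, match="at least"):
            train_replicates(fs, pres, bg, n_replicates=1, test_fraction=0.25)


def test_model_text_roundtrip(tmp_path):
    stack = toy_stack(n=15, seed=4, categorical=True)
    rng = np.random.default_rng(4)
    bg = sample_cells(rng, 120, stack.reference.shape)
    pres = sample_cells(rng, 20, stack.reference.shape)
    fs = build_features(stack, bg, pres, classes={"linear", "quadratic", "hinge"},
                        hinge_knots=4)
    F_bg, F_p = fs.at_cells(*bg), fs.at_cells(*pres)
    X = np.vstack([F_bg, F_p])
    model = fit_maxent(fs, X, np.arange(len(F_bg), len(X)), beta=1.0)
    model.to_text(tmp_path / "m.txt")
    back = load_model(tmp_path / "m.txt", stack)
    np.testing.assert_allclose(back.coefs, model.coefs)
    np.testing.assert_allclose(back.predict_cells(*bg), model.predict_cells(*bg))
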