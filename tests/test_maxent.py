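import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import spearmanr

from sdmbaseline.features import (FeatureDescriptor, FeatureMatrix,
                                  auto_classes, expand_features)
from sdmbaseline.layers import GridSpec, Layer, LayerStack
from sdmbaseline.maxent import (MaxentModel, fit_maxent, predict,
                                regularization, run_replicates)
from sdmbaseline.occurrence import CellOccurrences
from sdmbaseline.synthetic import (SimulationConfig, VirtualSpecies,
                                   generate_layers, sample_occurrences)
from sdmbaseline.occurrence import snap_and_deduplicate


def objective(lam, F_p, F_bg, betas):
    """The regularized maxent objective, written independently."""
    lam = np.atleast_1d(np.asarray(lam, float))
    return (-(F_p @ lam).mean() + logsumexp(F_bg @ lam)
            + np.abs(betas * lam).sum())


def grid_search_minimize(F_p, F_bg, betas, span=6.0, n_pts=25, n_zoom=8):
    """Dense, iteratively refined grid search over the identical objective.

    Independent of the package's optimizer: evaluates the objective on a
    full cartesian grid per zoom level.
    """
    k = F_bg.shape[1]
    lo = np.full(k, -span)
    hi = np.full(k, span)
    best = np.zeros(k)
    for _ in range(n_zoom):
        axes = [np.linspace(lo[j], hi[j], n_pts) for j in range(k)]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        vals = np.array([objective(p, F_p, F_bg, betas) for p in pts])
        best = pts[int(np.argmin(vals))]
        width = (hi - lo) / (n_pts - 1)
        lo, hi = best - 2 * width, best + 2 * width
    return best


def tiny_features(values):
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    desc = [FeatureDescriptor((f"f{j}",), "linear") for j in range(k)]
    return FeatureMatrix(values=values, descriptors=desc,
                         cell_ids=np.arange(n), grid_shape=(1, n))


class TestFeatureTiers:
    @pytest.mark.parametrize("n, expected", [
        (8, ["linear"]),
        (12, ["linear", "quadratic"]),
        (20, ["linear", "quadratic", "hinge"]),
        (120, ["linear", "quadratic", "hinge", "product", "threshold"]),
    ])
    def test_auto_tiers(self, n, expected):
        assert auto_classes(n) == expected

    def test_small_sample_gets_linear_only(self, small_stack):
        fm = expand_features(small_stack.subset(["grad_ns"]), n_presence=8)
        assert [d.klass for d in fm.descriptors] == ["linear"]

    def test_categorical_expands_to_indicators(self, small_stack):
        fm = expand_features(small_stack.subset(["zone"]), n_presence=8)
        assert [d.klass for d in fm.descriptors] == ["category"] * 3
        assert set(np.unique(fm.values)) <= {0.0, 1.0}
        # each cell belongs to exactly one category
        np.testing.assert_array_equal(fm.values.sum(axis=1), 1.0)

    def test_constant_layer_dropped_with_warning(self, small_grid):
        stack = LayerStack(small_grid,
                           [Layer("flat", "continuous", np.ones(small_grid.shape))])
        with pytest.warns(UserWarning, match="constant"):
            fm = expand_features(stack, n_presence=50)
        assert fm.n_features == 0

    def test_features_scaled_to_unit_interval(self, small_stack):
        fm = expand_features(small_stack, n_presence=120)
        assert fm.values.min() >= 0.0 and fm.values.max() <= 1.0


class TestFit:
    def test_no_features_gives_uniform(self):
        fm = tiny_features(np.empty((20, 0)))
        m = fit_maxent(np.arange(5), np.arange(20), fm)
        np.testing.assert_allclose(m.q_background, 1 / 20, atol=1e-12)

    def test_infinite_regularization_gives_uniform(self):
        rng = np.random.default_rng(0)
        fm = tiny_features(rng.uniform(size=(20, 1)))
        m = fit_maxent(np.arange(5), np.arange(20), fm, betas=np.array([1e9]))
        assert abs(m.lambdas[0]) < 1e-12
        np.testing.assert_allclose(m.q_background, 1 / 20, atol=1e-12)

    def test_one_binary_feature_matches_1d_grid_search(self):
        """N=20 cells, presences only where the feature is 1, beta=0.1."""
        vals = np.zeros((20, 1))
        vals[:8, 0] = 1.0
        fm = tiny_features(vals)
        presence = np.arange(5)  # all feature = 1
        betas = np.array([0.1])
        m = fit_maxent(presence, np.arange(20), fm, betas=betas, tol=1e-10,
                       max_iter=2000)
        # dense 1-D scan, refined
        grid = np.linspace(-6, 6, 200001)
        obj = (-(vals[presence, 0].mean() * grid)
               + logsumexp(np.outer(vals[:, 0], grid), axis=0)
               + 0.1 * np.abs(grid))
        lam_star = grid[np.argmin(obj)]
        assert abs(m.lambdas[0] - lam_star) < 1e-4

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_dense_grid_search(self, k):
        rng = np.random.default_rng(k)
        n = 60
        vals = rng.uniform(size=(n, k))
        fm = tiny_features(vals)
        presence = rng.choice(n, size=12, replace=False)
        betas = np.full(k, 0.05)
        m = fit_maxent(presence, np.arange(n), fm, betas=betas, tol=1e-12,
                       max_iter=5000)
        lam_star = grid_search_minimize(vals[presence], vals, betas)
        assert np.max(np.abs(m.lambdas - lam_star)) < 1e-3

    def test_raw_distribution_conserved(self):
        rng = np.random.default_rng(7)
        fm = tiny_features(rng.normal(size=(50, 3)) % 1.0)
        m = fit_maxent(rng.choice(50, 10, replace=False), np.arange(50), fm)
        assert abs(m.q_background.sum() - 1.0) < 1e-9

    def test_objective_monotone_and_below_uniform(self):
        rng = np.random.default_rng(3)
        fm = tiny_features(rng.uniform(size=(40, 2)))
        m = fit_maxent(rng.choice(40, 8, replace=False), np.arange(40), fm)
        tr = m.objective_trace
        assert (np.diff(tr) <= 1e-10).all()
        assert tr[-1] <= tr[0] + 1e-12  # J(0) is the uniform-model objective

    def test_no_presences_is_error(self):
        fm = tiny_features(np.zeros((5, 1)))
        with pytest.raises(ValueError, match="presence"):
            fit_maxent(np.array([], dtype=int), np.arange(5), fm)

    def test_nonfinite_features_error(self):
        vals = np.ones((5, 1))
        vals[2] = np.nan
        fm = tiny_features(vals)
        with pytest.raises(ValueError, match="non-finite"):
            fit_maxent(np.arange(2), np.arange(5), fm)


class TestPredict:
    def test_uniform_model_constant_logistic(self):
        fm = tiny_features(np.empty((10, 0)))
        m = fit_maxent(np.arange(3), np.arange(10), fm)
        s = predict(m, fm)
        vals = s.logistic.ravel()
        assert np.allclose(vals, vals[0])

    def test_three_cell_hand_computation(self):
        """q = (0.5, 0.3, 0.2): H and the logistic transform computed by
        hand must match the model-built surface."""
        q = np.array([0.5, 0.3, 0.2])
        # one feature whose weighted exponential reproduces q exactly:
        # eta = ln q  =>  lambda = 1, f = ln q
        f = np.log(q).reshape(3, 1)
        fm = tiny_features(f)
        H = -(q * np.log(q)).sum()
        model = MaxentModel(
            lambdas=np.array([1.0]), betas=np.array([0.0]),
            descriptors=fm.descriptors, background_rows=np.arange(3),
            q_background=q, log_z=0.0, entropy=H,
        )
        s = predict(model, fm)
        np.testing.assert_allclose(s.raw.ravel(), q, atol=1e-12)
        c = np.exp(H)
        expected_logistic = c * q / (1 + c * q)
        np.testing.assert_allclose(s.logistic.ravel(), expected_logistic,
                                   atol=1e-12)

    def test_logistic_strictly_increasing_in_raw(self):
        rng = np.random.default_rng(5)
        fm = tiny_features(rng.uniform(size=(30, 2)))
        m = fit_maxent(rng.choice(30, 6, replace=False), np.arange(30), fm)
        s = predict(m, fm)
        order = np.argsort(s.raw.ravel())
        assert (np.diff(s.logistic.ravel()[order]) >= 0).all()

    def test_descriptor_mismatch_rejected(self):
        fm1 = tiny_features(np.random.default_rng(0).uniform(size=(10, 1)))
        m = fit_maxent(np.arange(3), np.arange(10), fm1)
        fm2 = FeatureMatrix(values=fm1.values,
                            descriptors=[FeatureDescriptor(("other",), "linear")],
                            cell_ids=fm1.cell_ids, grid_shape=fm1.grid_shape)
        with pytest.raises(ValueError, match="descriptors"):
            predict(m, fm2)


class TestReplicates:
    @pytest.mark.parametrize("n, n_test, n_train", [(25, 10, 15), (10, 4, 6)])
    def test_split_sizes(self, n, n_test, n_train, synthetic_stack):
        cfg, stack = synthetic_stack
        rng = np.random.default_rng(0)
        ids = rng.choice(stack.grid.n_cells, size=n, replace=False)
        cells = CellOccurrences("sp", frozenset(int(i) for i in ids), n)
        ens = run_replicates(cells, stack, n_rep=2, seed=1)
        for rep in ens.replicates:
            assert len(rep.test_cells) == n_test
            assert len(rep.train_cells) == n_train
            assert not set(rep.test_cells) & set(rep.train_cells)
            assert set(rep.test_cells) | set(rep.train_cells) == set(cells.cell_ids)

    def test_below_minimum_cells_rejected(self, synthetic_stack):
        _, stack = synthetic_stack
        cells = CellOccurrences("sp", frozenset(range(9)), 9)
        with pytest.raises(ValueError, match="at least 10"):
            run_replicates(cells, stack, n_rep=1, seed=0)

    def test_same_seed_reproducible(self, synthetic_stack):
        _, stack = synthetic_stack
        rng = np.random.default_rng(2)
        ids = rng.choice(stack.grid.n_cells, size=15, replace=False)
        cells = CellOccurrences("sp", frozenset(int(i) for i in ids), 15)
        a = run_replicates(cells, stack, n_rep=3, seed=9)
        b = run_replicates(cells, stack, n_rep=3, seed=9)
        assert a.summary_rows() == b.summary_rows()
        np.testing.assert_array_equal(a.mean_logistic_surface(),
                                      b.mean_logistic_surface())

    def test_niche_recovery_rank_correlation(self):
        """A specialist's fitted surface ranks cells like the true niche."""
        cfg = SimulationConfig(n_rows=40, n_cols=40, seed=11)
        stack = generate_layers(cfg)
        sp = VirtualSpecies("spec", -10.0, {"env0": 5.0, "env1": -4.0, "env2": 3.0},
                            {"region0": {1: 1.0}})
        occ = sample_occurrences(sp, stack, 100, cfg=cfg, seed=21)
        cells = snap_and_deduplicate(occ, stack.grid)["spec"]
        ens = run_replicates(cells, stack, n_rep=3, seed=4)
        true = sp.true_suitability(stack)
        rho = spearmanr(true.ravel(), ens.mean_logistic_surface().ravel()).statistic
        assert rho > 0.9
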