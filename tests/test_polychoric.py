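import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from healthvuln import (
    DegenerateVariableError,
    OrdinalDataset,
    ValidationError,
    estimate_polychoric_rho,
    estimate_thresholds,
    polychoric_matrix,
)
from healthvuln.polychoric import (
    bvn_cdf,
    nearest_psd_correlation,
    pair_loglik,
    _contingency,
)


def _discretize(z, cuts):
    return 1 + np.searchsorted(np.asarray(cuts), z, side="right")


def grid_search_rho(x, y, step=0.01):
    """Independent ML oracle: exhaustive scan of the same multinomial
    likelihood over a dense rho grid."""
    tx, ty = estimate_thresholds(x), estimate_thresholds(y)
    table = _contingency(x, y)
    grid = np.round(np.arange(-0.99, 0.99 + step / 2, step), 10)
    lls = [pair_loglik(table, tx, ty, r) for r in grid]
    return float(grid[int(np.argmax(lls))])


class TestBvnCdf:
    @pytest.mark.parametrize("rho", [-0.95, -0.5, 0.0, 0.3, 0.7, 0.95, 0.999])
    def test_matches_scipy_rectangle_integrator(self, rho, rng):
        h = rng.normal(size=20)
        k = rng.normal(size=20)
        mvn = multivariate_normal([0, 0], [[1, rho], [rho, 1]])
        ref = np.array([mvn.cdf([a, b]) for a, b in zip(h, k)])
        # scipy's rectangle integrator itself carries ~1e-8 noise
        assert np.abs(bvn_cdf(h, k, rho) - ref).max() < 1e-6

    def test_independence_factorises(self):
        h = np.array([-1.0, 0.0, 1.5])
        assert np.allclose(bvn_cdf(h, h, 0.0), norm.cdf(h) ** 2)


class TestThresholds:
    def test_even_binary_split_gives_zero(self):
        x = np.array([1] * 50 + [2] * 50)
        assert np.allclose(estimate_thresholds(x), [0.0])

    def test_uniform_quartiles_are_symmetric(self):
        x = np.repeat([1, 2, 3, 4], 25)
        t = estimate_thresholds(x)
        assert np.allclose(t, [norm.ppf(0.25), 0.0, norm.ppf(0.75)])

    def test_tabulated_inverse_normal(self):
        # 15.87% below the cut -> threshold at about -1
        x = np.array([1] * 1587 + [2] * 8413)
        assert abs(estimate_thresholds(x)[0] - (-1.0)) < 1e-3

    def test_single_category_degenerate(self):
        with pytest.raises(DegenerateVariableError):
            estimate_thresholds(np.ones(20, dtype=int))

    def test_thresholds_strictly_increasing(self, rng):
        x = rng.integers(1, 6, size=500)
        t = estimate_thresholds(x)
        assert np.all(np.diff(t) > 0)


class TestPairEstimation:
    def test_perfect_concordance_hits_upper_bound(self):
        x = np.repeat([1, 2, 3, 4], 15)
        est = estimate_polychoric_rho(x, x)
        assert est.rho >= 0.99

    def test_independent_large_samples_near_zero(self, rng):
        x = rng.integers(1, 5, size=20000)
        y = rng.integers(1, 5, size=20000)
        assert abs(estimate_polychoric_rho(x, y).rho) < 0.05

    def test_recovers_true_rho_and_matches_grid_oracle(self, rng):
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=5000)
        x = _discretize(z[:, 0], [-0.5, 0.5])
        y = _discretize(z[:, 1], [-0.5, 0.5])
        est = estimate_polychoric_rho(x, y)
        assert 0.55 <= est.rho <= 0.65
        assert abs(est.rho - grid_search_rho(x, y)) <= 0.01

    @pytest.mark.parametrize("true_rho", [-0.7, -0.2, 0.35, 0.8])
    def test_two_step_matches_grid_oracle_across_rho(self, true_rho, rng):
        z = rng.multivariate_normal([0, 0], [[1, true_rho], [true_rho, 1]], size=800)
        x = _discretize(z[:, 0], [-0.8, 0.0, 0.9])
        y = _discretize(z[:, 1], [-0.3, 0.6])
        est = estimate_polychoric_rho(x, y)
        assert abs(est.rho - grid_search_rho(x, y)) <= 0.01

    def test_symmetric_in_arguments(self, rng):
        z = rng.multivariate_normal([0, 0], [[1, 0.4], [0.4, 1]], size=300)
        x = _discretize(z[:, 0], [-0.5, 0.5])
        y = _discretize(z[:, 1], [0.0])
        assert estimate_polychoric_rho(x, y).rho == pytest.approx(
            estimate_polychoric_rho(y, x).rho, abs=1e-5
        )

    def test_short_vectors_rejected(self):
        with pytest.raises(ValidationError):
            estimate_polychoric_rho(np.array([1, 2] * 4), np.array([1, 2] * 4))

    def test_mean_bias_small_over_replicates(self):
        """Estimator consistency: mean bias below 0.03 per true rho over
        200 replicates at n = 500."""
        cuts_x, cuts_y = [-0.5, 0.5], [-0.6, 0.4]
        for true_rho in (-0.5, 0.0, 0.5):
            errs = []
            for seed in range(200):
                r = np.random.default_rng(1000 + seed)
                z = r.multivariate_normal([0, 0], [[1, true_rho], [true_rho, 1]], size=500)
                x = _discretize(z[:, 0], cuts_x)
                y = _discretize(z[:, 1], cuts_y)
                errs.append(estimate_polychoric_rho(x, y).rho - true_rho)
            assert abs(np.mean(errs)) < 0.03


class TestMatrix:
    def _dataset(self, levels, max_levels=None):
        levels = np.asarray(levels)
        k = levels.shape[1]
        return OrdinalDataset(
            [f"C{i}" for i in range(levels.shape[0])],
            levels,
            [f"f{j}" for j in range(k)],
            max_levels or [int(levels[:, j].max()) for j in range(k)],
            max_levels or [int(levels[:, j].max()) for j in range(k)],
        )

    def test_independent_factors_near_zero_no_smoothing(self, rng):
        levels = np.column_stack(
            [rng.integers(1, 5, size=5000), rng.integers(1, 4, size=5000)]
        )
        res = polychoric_matrix(self._dataset(levels))
        assert abs(res.corr[0, 1]) < 0.05
        assert not res.smoothed
        assert all(res.converged.values())

    def test_duplicated_factor_near_unity(self, rng):
        x = rng.integers(1, 5, size=200)
        res = polychoric_matrix(self._dataset(np.column_stack([x, x])))
        assert res.corr[0, 1] >= 0.99
        assert np.allclose(np.diag(res.corr), 1.0)

    def test_reference_dataset_structure(self, reference_levels):
        res = polychoric_matrix(reference_levels)
        assert res.corr.shape == (4, 4)
        assert np.allclose(res.corr, res.corr.T)
        assert np.allclose(np.diag(res.corr), 1.0)
        assert np.abs(res.corr).max() <= 1.0
        assert all(res.converged.values())
        assert np.linalg.eigvalsh(res.corr).min() >= -1e-10
        # one threshold set per factor, observed categories - 1 cut-points
        for j, name in enumerate(res.factor_names):
            n_cats = np.unique(reference_levels.levels[:, j]).size
            assert res.thresholds[name].size == n_cats - 1

    def test_degenerate_variable_excluded_and_reported(self, rng):
        levels = np.column_stack(
            [rng.integers(1, 4, size=50), np.ones(50, dtype=int), rng.integers(1, 3, size=50)]
        )
        res = polychoric_matrix(self._dataset(levels, max_levels=[3, 3, 2]))
        assert res.excluded == ["f1"]
        assert res.corr.shape == (2, 2)

    def test_psd_smoothing_repairs_indefinite_matrix(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(bad).min() < 0
        fixed = nearest_psd_correlation(bad)
        assert np.linalg.eigvalsh(fixed).min() >= 0
        assert np.allclose(np.diag(fixed), 1.0)
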