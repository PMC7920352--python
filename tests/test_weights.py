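"""Variance-function and working-correlation estimation, weight matrices."""

import numpy as np
import pytest

from dosevary import (SimulationDesign, SplineBasis, WorkingCorrelation,
                      build_weight_matrix, estimate_correlation,
                      estimate_variance_function, fit_low_dim_model,
                      rational_quadratic, simulate_panel)
from dosevary.weights import VarianceFunction, WeightModel


def z_only_mean(panel, truth):
    """Mean response under the covariates-only part of the generating model."""
    mean = np.zeros(panel.n_obs)
    for k in range(panel.Z.shape[1]):
        mean += panel.Z[panel.unit_index, k] * truth.beta[k](panel.dose_fraction)
    return mean


def make_z_only_panel(n_units, noise, seed, n_active=0, rho=None, poly=False):
    """Panel whose response is the z-only mean plus supplied iid noise SD.

    With ``poly=True`` the covariate curves are replaced by cubics, which
    the spline basis reproduces exactly (for zero-noise interpolation
    checks).
    """
    design = SimulationDesign(n_units=n_units, n_genes=4, n_active=n_active)
    panel, truth = simulate_panel(design, seed=seed)
    rng = np.random.default_rng(seed + 1)
    if poly:
        polys = [lambda d, k=k: 1.0 - 0.1 * k * d + 0.05 * k * d ** 2 - 0.02 * d ** 3
                 for k in range(panel.Z.shape[1])]
        truth = type(truth)(active=truth.active, gamma={}, beta=polys,
                            design=truth.design)
    mean = z_only_mean(panel, truth)
    if rho is None:
        panel.response = mean + noise * rng.standard_normal(panel.n_obs)
    else:
        a, ell = rho
        eps = np.empty(panel.n_obs)
        for rows in panel.unit_rows():
            d = panel.dose_fraction[rows]
            H = np.abs(d[:, None] - d[None, :])
            R = rational_quadratic(H, a, ell)
            eps[rows] = noise * rng.multivariate_normal(np.zeros(len(d)), R,
                                                        method="cholesky")
        panel.response = mean + eps
    return panel, truth


class TestLowDimFit:
    def test_zero_noise_exact_interpolation(self):
        """Truth inside the spline space + zero noise -> exact fit."""
        panel, truth = make_z_only_panel(80, noise=0.0, seed=0, poly=True)
        basis = SplineBasis.from_data(panel.dose_fraction)
        low = fit_low_dim_model(panel, basis)
        assert np.max(np.abs(low.residuals)) < 1e-10

    def test_residuals_orthogonal_to_design(self):
        panel, _ = make_z_only_panel(60, noise=0.3, seed=1)
        basis = SplineBasis.from_data(panel.dose_fraction)
        low = fit_low_dim_model(panel, basis)
        # normal equations: residuals orthogonal to every design column
        assert np.max(np.abs(low.design.T @ low.residuals)) < 1e-8

    def test_rank_deficient_design_names_block(self, tiny_panel):
        import copy
        panel = copy.copy(tiny_panel)
        panel.Z = tiny_panel.Z.copy()
        panel.Z[:, 2] = panel.Z[:, 1]          # duplicate a covariate column
        basis = SplineBasis.from_data(panel.dose_fraction)
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_low_dim_model(panel, basis)


class TestVarianceFunction:
    def test_homoscedastic_recovery(self):
        """Unit-variance noise at 500 units: sup-norm error < 0.15 on the grid."""
        panel, _ = make_z_only_panel(500, noise=1.0, seed=2)
        basis = SplineBasis.from_data(panel.dose_fraction)
        low = fit_low_dim_model(panel, basis)
        V = estimate_variance_function(low.residuals, panel.dose_fraction, basis)
        grid = np.unique(panel.dose_fraction)
        assert np.max(np.abs(V(grid) - 1.0)) < 0.15

    def test_zero_residuals_floor(self):
        panel, _ = make_z_only_panel(30, noise=0.0, seed=3)
        basis = SplineBasis.from_data(panel.dose_fraction)
        V = estimate_variance_function(np.zeros(panel.n_obs), panel.dose_fraction,
                                       basis, floor=1e-8)
        grid = np.linspace(panel.dose_fraction.min(), 1.0, 50)
        assert np.allclose(V(grid), 1e-8)

    def test_increasing_variance_recovered_monotone(self):
        from scipy.stats import spearmanr
        design = SimulationDesign(n_units=500, n_genes=4, n_active=0, sigma=0.5)
        panel, _ = simulate_panel(design, seed=4)      # V(d) = 0.25 (1+d)^2
        basis = SplineBasis.from_data(panel.dose_fraction)
        low = fit_low_dim_model(panel, basis)
        V = estimate_variance_function(low.residuals, panel.dose_fraction, basis)
        grid = np.unique(panel.dose_fraction)
        rho = spearmanr(grid, V(grid)).statistic
        assert rho > 0.9


class TestCorrelation:
    def test_independence_structure(self):
        corr = WorkingCorrelation("independence")
        assert np.array_equal(corr.matrix([0.1, 0.5, 1.0]), np.eye(3))

    def test_parameter_recovery(self):
        """(a, l) = (2, 0.3) errors at 1000 units: length-scale within 0.1."""
        panel, _ = make_z_only_panel(1000, noise=1.0, seed=5, rho=(2.0, 0.3))
        basis = SplineBasis.from_data(panel.dose_fraction)
        low = fit_low_dim_model(panel, basis)
        V = estimate_variance_function(low.residuals, panel.dose_fraction, basis)
        corr = estimate_correlation(low.residuals, panel.dose_fraction,
                                    panel.unit_index, V, "rational_quadratic")
        assert corr.structure == "rational_quadratic"
        assert abs(corr.params[1] - 0.3) < 0.1

    def test_uncorrelated_noise_fits_near_identity(self):
        panel, _ = make_z_only_panel(500, noise=1.0, seed=6)
        basis = SplineBasis.from_data(panel.dose_fraction)
        low = fit_low_dim_model(panel, basis)
        V = estimate_variance_function(low.residuals, panel.dose_fraction, basis)
        corr = estimate_correlation(low.residuals, panel.dose_fraction,
                                    panel.unit_index, V, "rational_quadratic")
        R = corr.matrix(np.unique(panel.dose_fraction))
        off = R - np.diag(np.diag(R))
        assert np.max(np.abs(off)) < 0.1

    def test_all_singleton_units_fall_back(self):
        basis = SplineBasis(degree=3, interior=(0.5,), boundary=(0.0, 1.0))
        V = VarianceFunction.constant(basis, 1.0)
        with pytest.warns(UserWarning):
            corr = estimate_correlation([0.1, -0.2], [0.2, 0.9], [0, 1], V,
                                        "rational_quadratic")
        assert corr.structure == "independence"


class TestWeightMatrix:
    def setup_method(self):
        self.basis = SplineBasis(degree=3, interior=(0.5,), boundary=(0.0, 1.0))

    def test_identity_case(self):
        V = VarianceFunction.constant(self.basis, 1.0)
        W = build_weight_matrix(V, WorkingCorrelation("independence"),
                                [0.1, 0.3, 0.6, 1.0])
        assert np.allclose(W, np.eye(4) / 4)

    def test_scalar_case(self):
        V = VarianceFunction.constant(self.basis, 4.0)
        W = build_weight_matrix(V, WorkingCorrelation("independence"), [0.5])
        assert W.shape == (1, 1)
        assert W[0, 0] == pytest.approx(0.25)

    def test_psd_and_symmetric(self):
        V = VarianceFunction.constant(self.basis, 2.0)
        corr = WorkingCorrelation("rational_quadratic", (2.0, 0.3))
        W = build_weight_matrix(V, corr, [0.05, 0.1, 0.4, 0.8, 1.0])
        assert np.allclose(W, W.T)
        assert np.min(np.linalg.eigvalsh(W)) >= -1e-12

    def test_permutation_equivariance(self):
        V = VarianceFunction.constant(self.basis, 2.0)
        corr = WorkingCorrelation("rational_quadratic", (2.0, 0.3))
        d = np.array([0.1, 0.4, 0.9])
        perm = [2, 0, 1]
        W = build_weight_matrix(V, corr, d)
        Wp = build_weight_matrix(V, corr, d[perm])
        P = np.eye(3)[perm]
        assert np.allclose(Wp, P @ W @ P.T)

    def test_whitener_squares_to_weight(self):
        V = VarianceFunction.constant(self.basis, 2.0)
        wm = WeightModel(V, WorkingCorrelation("rational_quadratic", (2.0, 0.3)))
        d = [0.1, 0.4, 0.9]
        S = wm.whitener(d)
        assert np.allclose(S @ S, wm.weight_matrix(d))
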