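"""SCAD penalty analytics and group-SCAD optimization."""

import numpy as np
import pytest

from dosevary import (SimulationDesign, SplineBasis, cross_validate_lambda,
                      estimate_weight_model, fit_gscad, lambda_grid,
                      scad_derivative, scad_penalty, simulate_panel)
from dosevary.gscad import ScadParams, _GscadProblem, assign_folds
from dosevary.splines import build_vc_design
from dosevary.weights import WeightModel


class TestScadPenalty:
    def test_zero(self):
        assert scad_penalty(0.0, lam=1.0, alpha=3.7) == 0.0

    def test_branch_continuity_at_lam(self):
        lam, alpha = 1.3, 3.7
        left = lam * lam                      # linear branch at u = lam
        mid = -(lam ** 2 - 2 * alpha * lam * lam + lam ** 2) / (2 * (alpha - 1))
        assert left == pytest.approx(mid)
        assert scad_penalty(lam, lam, alpha) == pytest.approx(lam ** 2)

    def test_middle_branch_value(self):
        # -(u^2 - 2*alpha*lam*u + lam^2) / (2 (alpha-1)) at u=2, lam=1, alpha=3.7
        assert scad_penalty(2.0, 1.0, 3.7) == pytest.approx(9.8 / 5.4)

    def test_plateau(self):
        assert scad_penalty(3.7, 1.0, 3.7) == pytest.approx(2.35)
        assert scad_penalty(50.0, 1.0, 3.7) == pytest.approx(2.35)

    @pytest.mark.parametrize("point", ["lam", "alpha_lam"])
    def test_derivative_continuity(self, point):
        lam, alpha, h = 0.8, 3.7, 1e-7
        u = lam if point == "lam" else alpha * lam
        left = (scad_penalty(u, lam, alpha) - scad_penalty(u - h, lam, alpha)) / h
        right = (scad_penalty(u + h, lam, alpha) - scad_penalty(u, lam, alpha)) / h
        assert abs(left - right) < 1e-6

    def test_derivative_formula(self):
        lam, alpha = 1.0, 3.7
        assert scad_derivative(0.0, lam, alpha) == lam
        assert scad_derivative(0.5, lam, alpha) == lam
        assert scad_derivative(2.0, lam, alpha) == pytest.approx((3.7 - 2.0) / 2.7)
        assert scad_derivative(5.0, lam, alpha) == 0.0

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            scad_penalty(-0.1, 1.0, 3.7)
        with pytest.raises(ValueError):
            scad_penalty(1.0, 1.0, 2.0)
        with pytest.raises(ValueError):
            ScadParams(lam=-1.0)


@pytest.fixture(scope="module")
def small_problem():
    design = SimulationDesign(n_units=50, n_genes=12, n_active=3)
    panel, truth = simulate_panel(design, seed=21)
    basis = SplineBasis.from_data(panel.dose_fraction)
    wm = estimate_weight_model(panel, basis, "rational_quadratic")
    genes = np.arange(panel.n_genes)
    return panel, truth, basis, wm, genes


class TestFitGscad:
    def test_lambda_zero_matches_normal_equations(self, small_problem):
        """Unpenalized fit equals a brute-force whitened least squares."""
        panel, _, basis, wm, genes = small_problem
        fit = fit_gscad(panel, basis, genes, wm, lam=0.0)
        vc = build_vc_design(panel, basis, genes=genes)
        Mt, yt = wm.whiten_rows(panel, [vc.matrix, panel.response])
        theta, *_ = np.linalg.lstsq(Mt, yt, rcond=None)
        ours = np.concatenate([fit.coef_z, fit.etas.ravel()])
        assert np.max(np.abs(ours - theta)) < 1e-6

    def test_above_lambda_max_all_zero(self, small_problem):
        panel, _, basis, wm, genes = small_problem
        prob = _GscadProblem(panel, basis, genes, wm)
        lam_max = float(np.max(prob.group_grad_norms(prob.yp)))
        fit = fit_gscad(panel, basis, genes, wm, lam=1.01 * lam_max)
        assert np.all(fit.etas == 0.0)
        zeta_only, _ = prob.zeta_only()
        assert np.allclose(fit.coef_z, zeta_only, atol=1e-8)

    def test_objective_trace_non_increasing(self, small_problem):
        panel, _, basis, wm, genes = small_problem
        grid = lambda_grid(panel, basis, genes, wm, n_lambda=5, lambda_min_ratio=0.05)
        for lam in grid:
            fit = fit_gscad(panel, basis, genes, wm, lam=float(lam))
            trace = np.array(fit.objective_trace)
            assert np.all(np.diff(trace) <= 1e-8 * np.maximum(1.0, np.abs(trace[:-1])))

    def test_group_norm_monotone_in_lambda(self):
        """Total selected-group norm shrinks as the penalty grows."""
        for seed in range(10):
            design = SimulationDesign(n_units=40, n_genes=8, n_active=2)
            panel, _ = simulate_panel(design, seed=200 + seed)
            basis = SplineBasis.from_data(panel.dose_fraction)
            wm = WeightModel.identity(basis)
            genes = np.arange(panel.n_genes)
            grid = lambda_grid(panel, basis, genes, wm, n_lambda=6,
                               lambda_min_ratio=0.05)
            totals = [fit_gscad(panel, basis, genes, wm, lam=float(l)).group_norms.sum()
                      for l in grid]
            diffs = np.diff(totals)        # grid descends, norms should grow
            assert np.all(diffs >= -1e-8)

    def test_selection_on_small_instance(self, small_problem):
        panel, truth, basis, wm, genes = small_problem
        grid = lambda_grid(panel, basis, genes, wm, n_lambda=15,
                           lambda_min_ratio=1e-2)
        cv = cross_validate_lambda(panel, basis, genes, wm, lam_grid=grid,
                                   folds=5, seed=3)
        fit = fit_gscad(panel, basis, genes, wm, lam=cv.lam)
        assert set(truth.active.tolist()) <= set(fit.selected.tolist())


class TestCrossValidation:
    def test_single_lambda_grid(self, small_problem):
        panel, _, basis, wm, genes = small_problem
        cv = cross_validate_lambda(panel, basis, genes, wm, lam_grid=[0.7],
                                   folds=4, seed=0)
        assert cv.lam == 0.7

    def test_deterministic_given_seed(self, small_problem):
        panel, _, basis, wm, genes = small_problem
        cv1 = cross_validate_lambda(panel, basis, genes, wm, n_lambda=8,
                                    lambda_min_ratio=0.05, folds=4, seed=5)
        cv2 = cross_validate_lambda(panel, basis, genes, wm, n_lambda=8,
                                    lambda_min_ratio=0.05, folds=4, seed=5)
        assert cv1.lam == cv2.lam
        assert np.array_equal(cv1.fold_labels, cv2.fold_labels)
        assert np.array_equal(cv1.cv_mean, cv2.cv_mean)

    def test_noiseless_selects_exactly_active(self):
        # zero noise, and the two active shapes (constant, linear) lie
        # exactly inside the cubic spline space, so the optimal
        # selection is unambiguous
        design = SimulationDesign(n_units=60, n_genes=15, n_active=2, sigma=0.0)
        panel, truth = simulate_panel(design, seed=31)
        basis = SplineBasis.from_data(panel.dose_fraction)
        wm = estimate_weight_model(panel, basis, "rational_quadratic")
        genes = np.arange(panel.n_genes)
        cv = cross_validate_lambda(panel, basis, genes, wm, n_lambda=20,
                                   lambda_min_ratio=1e-3, folds=5, seed=1)
        fit = fit_gscad(panel, basis, genes, wm, lam=cv.lam)
        assert set(fit.selected.tolist()) == set(truth.active.tolist())

    def test_fold_assignment_stratified(self, small_problem):
        panel, _, basis, wm, genes = small_problem
        labels = assign_folds(panel, folds=5, seed=2)
        assert len(labels) == panel.n_units
        assert set(labels) == set(range(5))
        # every fold sees every drug (each drug has >= 5 units here)
        for drug in set(panel.drug_ids.tolist()):
            mask = panel.drug_ids == drug
            assert set(labels[mask]) == set(range(5))

    def test_too_few_units_raises(self, tiny_panel):
        basis = SplineBasis.from_data(tiny_panel.dose_fraction)
        wm = WeightModel.identity(basis)
        with pytest.raises(ValueError, match="fold"):
            cross_validate_lambda(tiny_panel, basis, [0], wm, folds=10, seed=0)
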