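"""Effect summaries, prediction evaluation, IC50 extraction, fold change."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dosevary import (CoefficientCurve, SplineBasis, classify_sign, effect_auc,
                      fit_sigmoid_ic50, fold_change, prediction_accuracy,
                      spearman_dose_effect)
from dosevary.postprocess import DOSE_RANGE_SPLIT


def curve(values, lo=0.0, hi=1.0):
    v = np.asarray(values, dtype=float)
    return CoefficientCurve(np.linspace(lo, hi, len(v)), v)


class TestEffectAuc:
    def test_constant(self):
        g = np.linspace(0, 1, 101)
        assert effect_auc(CoefficientCurve(g, np.full(101, -2.5))) == pytest.approx(2.5)

    def test_linear(self):
        g = np.linspace(0, 1, 101)
        assert effect_auc(CoefficientCurve(g, g)) == pytest.approx(0.5, abs=1e-4)

    def test_zero(self):
        assert effect_auc(curve(np.zeros(11))) == 0.0

    @given(c=st.floats(-10, 10))
    @settings(max_examples=30, deadline=None)
    def test_homogeneity(self, c):
        g = np.linspace(0, 1, 51)
        v = np.sin(3 * g) - 0.4
        base = effect_auc(CoefficientCurve(g, v))
        assert effect_auc(CoefficientCurve(g, c * v)) == pytest.approx(abs(c) * base)


class TestSignAndSpearman:
    def test_signs(self):
        g = np.linspace(0, 1, 11)
        assert classify_sign(CoefficientCurve(g, g + 0.1)) == "+"
        assert classify_sign(CoefficientCurve(g, -g - 0.2)) == "-"
        assert classify_sign(CoefficientCurve(g, g - 0.5)) == "0"

    def test_monotone_curves(self):
        g = np.linspace(0, 1, 101)
        assert spearman_dose_effect(CoefficientCurve(g, np.exp(g)))[0] == pytest.approx(1.0)
        assert spearman_dose_effect(CoefficientCurve(g, -g ** 3))[0] == pytest.approx(-1.0)

    def test_symmetric_parabola_zero(self):
        # integer-exact symmetric values: tied ranks cancel the rank
        # covariance exactly
        g = np.arange(101) / 100.0
        v = -((np.arange(101) - 50.0) ** 2)
        rho, defined = spearman_dose_effect(CoefficientCurve(g, v))
        assert defined
        assert abs(rho) < 1e-10

    def test_constant_curve_flagged(self):
        rho, defined = spearman_dose_effect(curve(np.ones(11)))
        assert (rho, defined) == (0.0, False)

    def test_grid_refinement_stability(self):
        """Sign and monotonicity of smooth spline curves do not depend on
        refining the evaluation grid beyond the default 101 points."""
        basis = SplineBasis(degree=3, interior=(0.4,), boundary=(0.0, 1.0))
        coef = np.array([0.1, 0.5, 0.9, 1.4, 2.0])     # monotone coefficients
        for n in (101, 1001):
            g = np.linspace(0, 1, n)
            c = CoefficientCurve(g, basis(g) @ coef)
            assert classify_sign(c) == "+"
            assert spearman_dose_effect(c)[0] == pytest.approx(1.0, abs=1e-6)
        mixed = np.array([-1.0, 0.5, 1.0, -0.5, -1.5])
        signs = {classify_sign(CoefficientCurve(np.linspace(0, 1, n),
                                                basis(np.linspace(0, 1, n)) @ mixed))
                 for n in (101, 1001)}
        assert signs == {"0"}


def prediction_table(n_cells, n_drugs, n_doses, seed=0, perfect=False):
    rng = np.random.default_rng(seed)
    rows = []
    doses = 2.0 ** -np.arange(n_doses - 1, -1, -1.0)
    for c in range(n_cells):
        for k in range(n_drugs):
            obs = rng.uniform(0, 1, n_doses)
            pred = obs if perfect else np.full(n_doses, 0.5)
            for j in range(n_doses):
                rows.append(dict(cell_line=f"c{c}", drug=f"d{k}",
                                 dose_fraction=doses[j],
                                 observed=obs[j], predicted=pred[j]))
    return pd.DataFrame(rows)


class TestPredictionAccuracy:
    def test_perfect_predictor(self):
        t = prediction_table(20, 3, 5, perfect=True)
        m = prediction_accuracy(t)
        assert m.mae == 0.0
        assert (m.acc_drug_dose, m.acc_drug, m.acc_dose, m.acc_dose_range) == \
            (100.0, 100.0, 100.0, 100.0)

    def test_constant_predictor_binomial_baseline(self):
        """Best-drug accuracy of an uninformative predictor over 5 drugs
        with uniformly random observed winners is ~20%."""
        t = prediction_table(2000, 5, 5, seed=1)
        m = prediction_accuracy(t)
        assert m.acc_drug == pytest.approx(20.0, abs=4.0)

    def test_dose_range_threshold(self):
        assert 0.25 <= DOSE_RANGE_SPLIT < 0.5
        rows = []
        for (obs_best, pred_best, expect) in [(0.25, 0.3125, True),
                                              (0.25, 0.5, False)]:
            t = pd.DataFrame({
                "cell_line": ["c"] * 3, "drug": ["d"] * 3,
                "dose_fraction": [0.25, 0.3125, 0.5],
                "observed": [0.0 if d == obs_best else 1.0 for d in [0.25, 0.3125, 0.5]],
                "predicted": [0.0 if d == pred_best else 1.0 for d in [0.25, 0.3125, 0.5]],
            })
            m = prediction_accuracy(t)
            assert (m.acc_dose_range == 100.0) is expect

    def test_single_drug_cell_line_skipped_for_drug_scenario(self):
        t = prediction_table(5, 1, 4, perfect=True)
        m = prediction_accuracy(t)
        assert np.isnan(m.acc_drug)
        assert m.acc_dose == 100.0


class TestSigmoidIC50:
    @staticmethod
    def logistic(d, lo, hi, m, h):
        return lo + (hi - lo) / (1.0 + (d / m) ** h)

    def test_exact_logistic_recovery(self):
        g = np.linspace(0.01, 1, 101)
        y = self.logistic(g, 0.1, 1.0, 0.2, 2.0)
        fit = fit_sigmoid_ic50(CoefficientCurve(g, y))
        assert not fit.extrapolated
        assert fit.ic50 == pytest.approx(0.2, abs=1e-3)

    def test_flat_curve_extrapolated(self):
        g = np.linspace(0.01, 1, 20)
        fit = fit_sigmoid_ic50(CoefficientCurve(g, np.ones(20)))
        assert fit.extrapolated

    def test_more_potent_curve_reduces_ic50(self):
        """Curves that reach their half effect at lower doses yield a
        smaller fitted IC50, monotonically across 10 instances."""
        g = np.linspace(0.01, 1, 101)
        prev = np.inf
        for k in range(10):
            y = self.logistic(g, 0.2, 1.0, 0.4 - 0.03 * k, 2.0)
            fit = fit_sigmoid_ic50(CoefficientCurve(g, y))
            assert fit.ic50 <= prev + 1e-6
            prev = fit.ic50

    def test_nonfinite_raises(self):
        g = np.linspace(0.01, 1, 10)
        y = np.ones(10)
        y[3] = np.nan
        with pytest.raises(ValueError):
            fit_sigmoid_ic50(CoefficientCurve(g, y))


class TestFoldChange:
    def setup_method(self):
        self.expr = pd.DataFrame({"gA": [2.0, 2.0, 1.0, 1.0],
                                  "gB": [3.0, 3.0, 3.0, 3.0]},
                                 index=["c1", "c2", "c3", "c4"])
        self.mut = np.array([True, True, False, False])

    def test_ratio(self):
        assert fold_change(self.expr, self.mut, "gA") == pytest.approx(2.0)

    def test_identical_groups(self):
        assert fold_change(self.expr, self.mut, "gB") == pytest.approx(1.0)

    def test_swap_gives_reciprocal(self):
        fc = fold_change(self.expr, self.mut, "gA")
        assert fold_change(self.expr, ~self.mut, "gA") == pytest.approx(1.0 / fc)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            fold_change(self.expr, np.array([True] * 4), "gA")
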