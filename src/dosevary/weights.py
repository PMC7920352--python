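"""Dose-varying variance, working correlation, and per-unit weights.

The regression errors are heteroscedastic in dose, ``Var(eps | d) =
V(d)``, and potentially correlated within an experimental unit (the
repeated measurements of one dilution series).  Both stages of the
pipeline use weighted least squares with per-unit weight matrices

    W_i = (1 / n_i) * Vhat_i^{-1/2} R_i(phi)^{-1} Vhat_i^{-1/2}

where ``Vhat_i`` is the diagonal of estimated variances at the unit's
doses and ``R_i(phi)`` is a working correlation: either independence
(identity) or a rational-quadratic family

    R(h) = (1 + h^2 / (2 a l^2))^(-a),   h = |d_ij - d_ik|.

Estimation is a one-time preliminary step: fit the covariates-only
varying-coefficient model by ordinary least squares, bin the squared
residuals by distinct dose fraction and smooth them over dose with the
spline basis (variance), then fit ``(a, l)`` by least squares against
pooled lag correlations of the standardized residuals.

All weighted objectives are computed by whitening: with ``S_i`` the
symmetric square root of ``W_i``, the objective ``sum_i r_i' W_i r_i``
is the squared norm of the stacked whitened residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .splines import SplineBasis, build_vc_design

__all__ = ["VarianceFunction", "WorkingCorrelation", "WeightModel", "LowDimFit",
           "rational_quadratic", "fit_low_dim_model", "estimate_variance_function",
           "estimate_correlation", "build_weight_matrix", "estimate_weight_model"]


def rational_quadratic(h, a: float, ell: float) -> np.ndarray:
    """Rational-quadratic correlation ``(1 + h^2/(2 a ell^2))^(-a)``."""
    h = np.asarray(h, dtype=float)
    return (1.0 + h ** 2 / (2.0 * a * ell ** 2)) ** (-a)


@dataclass
class VarianceFunction:
    """Smooth nonnegative variance over the dose domain, spline-coded."""

    basis: SplineBasis
    coef: np.ndarray
    floor: float = 1e-8

    def __call__(self, d) -> np.ndarray:
        v = self.basis(d) @ self.coef
        return np.maximum(v, self.floor)

    @classmethod
    def constant(cls, basis: SplineBasis, value: float, floor: float = 1e-8) -> "VarianceFunction":
        # partition of unity: equal coefficients give a constant function
        return cls(basis, np.full(basis.n_basis, float(value)), floor)


@dataclass
class WorkingCorrelation:
    """Within-unit working correlation structure.

    ``structure`` is ``"independence"`` (no parameters) or
    ``"rational_quadratic"`` with ``params = (a, ell)``.

    ``nugget`` mixes a small independent component into the working
    matrix, ``R_work = (1 - nugget) R + nugget I``.  On log-spaced
    dilution series adjacent doses sit at lags of ~1/256, where a
    fitted rational-quadratic correlation approaches 1 and its inverse
    amplifies any error in the estimated variance function by
    ``1/(1 - rho)`` (easily 10^3-10^4).  The nugget — the standard
    technical-noise component of assay error models — caps that
    amplification at ``1/nugget`` while costing almost no efficiency.
    """

    structure: str
    params: tuple[float, ...] = ()
    nugget: float = 0.05

    def __post_init__(self):
        if self.structure not in ("independence", "rational_quadratic"):
            raise ValueError(f"unknown correlation structure {self.structure!r}")
        if self.structure == "rational_quadratic":
            if len(self.params) != 2 or min(self.params) <= 0:
                raise ValueError("rational_quadratic needs params (a, ell) > 0")
        if not (0 <= self.nugget < 1):
            raise ValueError("nugget must lie in [0, 1)")

    def matrix(self, doses) -> np.ndarray:
        d = np.asarray(doses, dtype=float)
        if self.structure == "independence":
            return np.eye(len(d))
        a, ell = self.params
        H = np.abs(d[:, None] - d[None, :])
        R = rational_quadratic(H, a, ell)
        return (1.0 - self.nugget) * R + self.nugget * np.eye(len(d))


@dataclass
class LowDimFit:
    """OLS fit of the covariates-only varying-coefficient model."""

    coef: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    design: np.ndarray


def fit_low_dim_model(panel, basis: SplineBasis) -> LowDimFit:
    """Ordinary least squares for the z-only varying-coefficient model.

    This is the preliminary fit whose residuals feed the variance and
    correlation estimators.  Raises on rank deficiency, naming the
    offending covariate block.
    """
    design = build_vc_design(panel, basis, genes=())
    M = design.matrix
    if M.shape[1] >= M.shape[0]:
        raise ValueError("low-dimensional design has more columns than rows")
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # name the first block whose removal restores full column rank
        for name, sl in design.blocks.items():
            keep = np.ones(M.shape[1], dtype=bool)
            keep[sl] = False
            if np.linalg.matrix_rank(M[:, keep]) == rank:
                raise np.linalg.LinAlgError(
                    f"singular low-dimensional design: block {name!r} is collinear")
        raise np.linalg.LinAlgError("singular low-dimensional design")
    coef, *_ = np.linalg.lstsq(M, panel.response, rcond=None)
    fitted = M @ coef
    return LowDimFit(coef=coef, fitted=fitted, residuals=panel.response - fitted, design=M)


def estimate_variance_function(residuals, doses, basis: SplineBasis,
                               floor: float = 1e-8) -> VarianceFunction:
    """Estimate ``V(d)`` from preliminary residuals.

    Squared residuals are averaged within each distinct dose fraction
    (the screened assays use a small discrete set of dilution
    fractions), smoothed across dose by unpenalized projection onto the
    spline basis, and floored at ``floor``.
    """
    r = np.asarray(residuals, dtype=float)
    d = np.asarray(doses, dtype=float)
    uniq, inv = np.unique(d, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least two distinct doses to estimate V(d)")
    sums = np.bincount(inv, weights=r ** 2)
    counts = np.bincount(inv)
    means = sums / counts
    coef = basis.project(uniq, means)
    return VarianceFunction(basis=basis, coef=coef, floor=floor)


def estimate_correlation(residuals, doses, unit_index, variance: VarianceFunction,
                         structure: str = "rational_quadratic",
                         lag_decimals: int = 10) -> WorkingCorrelation:
    """Moment-style estimation of the working correlation.

    Standardized residuals ``e = r / sqrt(Vhat(d))`` are formed; for
    every within-unit pair the product ``e_j * e_k`` is pooled by dose
    lag ``h = |d_j - d_k|`` and the empirical lag correlations are fit
    by least squares with the rational-quadratic curve.  With
    ``structure="independence"`` the identity is returned directly.
    """
    if structure == "independence":
        return WorkingCorrelation("independence")
    r = np.asarray(residuals, dtype=float)
    d = np.asarray(doses, dtype=float)
    unit_index = np.asarray(unit_index, dtype=int)
    e = r / np.sqrt(variance(d))

    lags: dict[float, list[float]] = {}
    n_units = unit_index.max() + 1
    any_pairs = False
    for i in range(n_units):
        rows = np.flatnonzero(unit_index == i)
        if len(rows) < 2:
            continue
        any_pairs = True
        ei, di = e[rows], d[rows]
        for j in range(len(rows)):
            for k in range(j + 1, len(rows)):
                h = round(abs(di[j] - di[k]), lag_decimals)
                lags.setdefault(h, []).append(ei[j] * ei[k])
    if not any_pairs:
        warnings.warn("no unit has repeated doses; falling back to independence")
        return WorkingCorrelation("independence")

    hs = np.array(sorted(lags))
    rho = np.array([np.mean(lags[h]) for h in hs])
    rho = np.clip(rho, -1.0, 1.0)

    def resid(theta):
        a, ell = theta
        return rational_quadratic(hs, a, ell) - rho

    sol = least_squares(resid, x0=[1.0, 0.5], bounds=([1e-3, 1e-3], [50.0, 10.0]))
    a, ell = sol.x
    return WorkingCorrelation("rational_quadratic", (float(a), float(ell)))


def build_weight_matrix(variance: VarianceFunction, correlation: WorkingCorrelation,
                        doses) -> np.ndarray:
    """Per-unit weight matrix ``W_i = Vd^{-1/2} R^{-1} Vd^{-1/2} / n_i``."""
    d = np.asarray(doses, dtype=float)
    n_i = len(d)
    v = variance(d)
    R = correlation.matrix(d)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        warnings.warn("working correlation numerically singular; ridge-repairing")
        Rinv = np.linalg.inv(R + 1e-8 * np.eye(n_i))
    s = 1.0 / np.sqrt(v)
    W = (s[:, None] * Rinv * s[None, :]) / n_i
    return 0.5 * (W + W.T)


@dataclass
class WeightModel:
    """Variance function + working correlation, yielding ``W_i`` per unit."""

    variance: VarianceFunction
    correlation: WorkingCorrelation

    def weight_matrix(self, doses) -> np.ndarray:
        return build_weight_matrix(self.variance, self.correlation, doses)

    def whitener(self, doses) -> np.ndarray:
        """Symmetric square root ``S_i`` of ``W_i`` (so ``r'Wr = |S r|^2``)."""
        W = self.weight_matrix(doses)
        vals, vecs = np.linalg.eigh(W)
        vals = np.maximum(vals, 0.0)
        return (vecs * np.sqrt(vals)) @ vecs.T

    def whiten_rows(self, panel, arrays):
        """Apply ``S_i`` unit-wise to stacked row arrays.

        ``arrays`` is a sequence of ``(N, ...)`` arrays aligned with the
        panel rows; returns the whitened copies.  Whiteners are cached
        per distinct dose pattern (typically only two patterns occur).
        """
        outs = [np.array(a, dtype=float, copy=True) for a in arrays]
        cache: dict[tuple, np.ndarray] = {}
        for rows in panel.unit_rows():
            key = tuple(panel.dose_fraction[rows])
            S = cache.get(key)
            if S is None:
                S = self.whitener(panel.dose_fraction[rows])
                cache[key] = S
            for out in outs:
                out[rows] = S @ out[rows]
        return outs

    @classmethod
    def identity(cls, basis: SplineBasis) -> "WeightModel":
        """Unit variance, independence: reduces WLS to per-unit-scaled OLS."""
        return cls(VarianceFunction.constant(basis, 1.0), WorkingCorrelation("independence"))


def estimate_weight_model(panel, basis: SplineBasis, structure: str = "rational_quadratic",
                          variance_floor: float = 1e-8) -> WeightModel:
    """One-shot weight-model estimation from the covariates-only fit."""
    low = fit_low_dim_model(panel, basis)
    var = estimate_variance_function(low.residuals, panel.dose_fraction, basis,
                                     floor=variance_floor)
    corr = estimate_correlation(low.residuals, panel.dose_fraction, panel.unit_index,
                                var, structure=structure)
    return WeightModel(variance=var, correlation=corr)
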