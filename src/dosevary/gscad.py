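"""Stage two: group-SCAD penalized estimation over the screened genes.

The criterion is

    (1/2) * sum_i (y_i - yhat_i)' W_i (y_i - yhat_i)
        + sum_{g in screened} p_{lam,alpha}(||eta_g||_2)

where ``eta_g`` are the L spline coefficients of gene ``g``'s effect
curve (selected or dropped as one group), the covariate blocks are
unpenalized, and ``p_{lam,alpha}`` is the SCAD penalty: linear (lasso
slope ``lam``) up to ``lam``, a quadratic transition up to
``alpha * lam``, then flat at ``(alpha + 1) * lam^2 / 2`` so large
effects are not shrunk.

The optimizer is a local linear approximation (LLA): each outer step
majorizes SCAD at the current group norms by weighted group-lasso
penalties ``omega_g = p'_{lam,alpha}(||eta_g||)`` and solves the
resulting convex problem by block coordinate descent with exact group
updates.  The unpenalized covariate block is profiled out exactly (QR
projection), so the descent runs over gene groups only.  The first
majorization is taken at the origin (``omega_g = lam``, a global SCAD
majorizer), which makes ``lambda_max`` — the smallest ``lam`` zeroing
every group on the first step — well defined.  Single fits at a given
``lam`` are solved by continuation: a short warm-started path from
``lambda_max`` down to the target, which keeps the iterate sparse and
the descent fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .splines import SplineBasis
from .weights import WeightModel

__all__ = ["ScadParams", "GscadFit", "CVResult", "scad_penalty", "scad_derivative",
           "fit_gscad", "lambda_grid", "cross_validate_lambda", "assign_folds"]


# --------------------------------------------------------------------------
# SCAD penalty
# --------------------------------------------------------------------------

def scad_penalty(u, lam: float, alpha: float = 3.7):
    """SCAD penalty value at nonnegative ``u``.

    Piecewise: ``lam*u`` on ``[0, lam]``; ``-(u^2 - 2*alpha*lam*u +
    lam^2) / (2*(alpha - 1))`` on ``[lam, alpha*lam]``; constant
    ``(alpha + 1)*lam^2 / 2`` beyond.  Continuous with continuous first
    derivative.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("SCAD argument must be nonnegative")
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if alpha <= 2:
        raise ValueError("alpha must exceed 2")
    out = np.where(
        u <= lam, lam * u,
        np.where(u <= alpha * lam,
                 -(u ** 2 - 2 * alpha * lam * u + lam ** 2) / (2 * (alpha - 1)),
                 (alpha + 1) * lam ** 2 / 2))
    return float(out) if out.ndim == 0 else out


def scad_derivative(u, lam: float, alpha: float = 3.7):
    """Derivative ``p'_{lam,alpha}(u)``: ``lam`` near zero, decaying to 0."""
    u = np.asarray(u, dtype=float)
    out = np.where(u <= lam, lam,
                   np.where(u <= alpha * lam,
                            (alpha * lam - u) / (alpha - 1),
                            0.0))
    return float(out) if out.ndim == 0 else out


@dataclass
class ScadParams:
    lam: float
    alpha: float = 3.7

    def __post_init__(self):
        if self.lam < 0 or self.alpha <= 2:
            raise ValueError("need lam >= 0 and alpha > 2")


# --------------------------------------------------------------------------
# Whitened problem and block coordinate descent
# --------------------------------------------------------------------------

class _GscadProblem:
    """Whitened design pieces for one panel / gene subset.

    Holds the whitened covariate design ``Zt``, per-gene blocks ``C``
    and their projections ``Cp`` onto the orthogonal complement of the
    covariate span (used by the descent), plus cached factorizations.
    """

    def __init__(self, panel, basis: SplineBasis, genes, weight_model: WeightModel,
                 project: bool = True):
        self.genes = np.asarray(list(genes), dtype=int)
        self.L = basis.n_basis
        B = basis(panel.dose_fraction)
        Zrows = panel.Z[panel.unit_index]
        p1 = Zrows.shape[1]
        Zdes = np.empty((panel.n_obs, p1 * self.L))
        for k in range(p1):
            Zdes[:, k * self.L:(k + 1) * self.L] = Zrows[:, k:k + 1] * B
        self.Zt, self.Bt, self.yt = weight_model.whiten_rows(panel, [Zdes, B, panel.response])
        xcols = panel.X[panel.unit_index][:, self.genes]            # (N, Gs)
        self.C = np.ascontiguousarray(
            self.Bt[None, :, :] * xcols.T[:, :, None])              # (Gs, N, L)
        self.xcols = xcols
        self.G_zz = self.Zt.T @ self.Zt
        # ridge keeps the factorization valid when a covariate level is
        # absent from a subset (e.g. a CV fold), where G_zz is singular
        ridge = 1e-9 * max(1.0, float(self.G_zz.diagonal().max()))
        self.chol_zz = cho_factor(self.G_zz + ridge * np.eye(self.G_zz.shape[0]))

        if not project:
            return
        # profile out the unpenalized covariate block: descent operates in
        # the orthogonal complement of span(Zt)
        Q, _ = np.linalg.qr(self.Zt)
        self.Qz = Q
        self.yp = self.yt - Q @ (Q.T @ self.yt)
        nG = len(self.genes)
        self.Cp = np.empty_like(self.C)
        self.ZtC = np.empty((nG, self.Zt.shape[1], self.L))
        self.eigvals = np.empty((nG, self.L))
        self.eigvecs = np.empty((nG, self.L, self.L))
        for j in range(nG):
            Cj = self.C[j]
            self.Cp[j] = Cj - Q @ (Q.T @ Cj)
            self.ZtC[j] = self.Zt.T @ Cj
            A = self.Cp[j].T @ self.Cp[j]
            w, V = np.linalg.eigh(A)
            self.eigvals[j] = np.maximum(w, 0.0)
            self.eigvecs[j] = V

    @property
    def n_groups(self) -> int:
        return len(self.genes)

    def zeta_only(self):
        """Covariates-only WLS fit and its (projected) residual."""
        zeta = cho_solve(self.chol_zz, self.Zt.T @ self.yt)
        return zeta, self.yt - self.Zt @ zeta

    def recover_zeta(self, etas) -> np.ndarray:
        """Optimal covariate coefficients given the gene coefficients."""
        rhs = self.Zt.T @ self.yt
        for j in range(self.n_groups):
            if np.any(etas[j]):
                rhs = rhs - self.ZtC[j] @ etas[j]
        return cho_solve(self.chol_zz, rhs)

    def group_grad_norms(self, rp) -> np.ndarray:
        """``||Cp_g' rp||`` for every group at projected residual ``rp``.

        For ``rp`` orthogonal to the covariate span this equals
        ``||C_g' rp||``, computed with one gemm.
        """
        G = (self.xcols * rp[:, None]).T @ self.Bt        # (Gs, L)
        return np.linalg.norm(G, axis=1)


def _solve_group(eigvals, eigvecs, b, omega, ridge=1e-10, tol=1e-12):
    """Exact minimizer of ``0.5 eta'A eta - b'eta + omega ||eta||``.

    Uses the eigendecomposition of ``A``; the norm ``t = ||eta||`` solves
    the scalar secular equation ``sum b_i^2 / (lam_i t + omega)^2 = 1``,
    found by Newton from below (the iteration is monotone because the
    equation's left side is decreasing and convex in ``t``).
    """
    nb = np.linalg.norm(b)
    lam = eigvals + ridge
    if omega <= 0.0:
        bt = eigvecs.T @ b
        return eigvecs @ (bt / lam)
    if nb <= omega:
        return np.zeros(len(b))
    bt = eigvecs.T @ b
    bt2 = bt ** 2
    t = 0.0
    for _ in range(200):
        denom = lam * t + omega
        frac = bt2 / denom ** 2
        g = 1.0 - frac.sum()
        if g >= -tol:
            break
        gp = 2.0 * np.sum(bt2 * lam / denom ** 3)
        if gp <= 0.0:
            break
        t += -g / gp
    denom = lam * t + omega
    return eigvecs @ (bt * t / denom)


def _penalized_rss(rp, etas, lam, alpha):
    norms = np.linalg.norm(etas, axis=1) if len(etas) else np.zeros(0)
    pen = float(np.sum(scad_penalty(norms, lam, alpha))) if len(etas) else 0.0
    return 0.5 * float(rp @ rp) + pen


def _bcd(prob: _GscadProblem, omega, etas, rp, tol=1e-6, max_sweeps=500):
    """Block coordinate descent for the weighted group-lasso subproblem
    (covariate block profiled out).

    Cycles over the currently active groups with exact group updates;
    on inner convergence checks the KKT conditions of every inactive
    group and admits violators.  Also stops when a full sweep no longer
    reduces the subproblem objective measurably.
    """
    active = {j for j in range(prob.n_groups) if np.any(etas[j]) or omega[j] <= 0.0}
    sweeps = 0
    converged = False
    prev_obj = np.inf
    while sweeps < max_sweeps:
        sweeps += 1
        max_change = 0.0
        for j in sorted(active):
            Cj = prob.Cp[j]
            old = etas[j]
            b = Cj.T @ rp + (prob.eigvecs[j] * prob.eigvals[j]) @ (prob.eigvecs[j].T @ old)
            new = _solve_group(prob.eigvals[j], prob.eigvecs[j], b, omega[j])
            diff = old - new
            if np.any(diff):
                rp = rp + Cj @ diff
                max_change = max(max_change, float(np.max(np.abs(diff))))
            etas[j] = new
        active = {j for j in active if np.any(etas[j]) or omega[j] <= 0.0}
        obj = 0.5 * float(rp @ rp) + float(
            np.sum(omega * np.linalg.norm(etas, axis=1)))
        stalled = prev_obj - obj <= 1e-12 * max(1.0, abs(prev_obj))
        prev_obj = obj
        if max_change < tol or stalled:
            norms = prob.group_grad_norms(rp)
            violators = [j for j in range(prob.n_groups)
                         if j not in active and norms[j] > omega[j] * (1 + 1e-9) + 1e-12]
            if not violators:
                converged = True
                break
            active.update(violators)
    return etas, rp, sweeps, converged


@dataclass
class GscadFit:
    """Result of one group-SCAD fit."""

    genes: np.ndarray            # gene indices (into the panel) in group order
    coef_z: np.ndarray           # (p+1)*L unpenalized coefficients
    etas: np.ndarray             # (Gs, L) penalized group coefficients
    lam: float
    alpha: float
    objective: float
    objective_trace: list = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0

    @property
    def selected(self) -> np.ndarray:
        """Gene indices with a nonzero estimated effect curve."""
        mask = np.linalg.norm(self.etas, axis=1) > 0
        return self.genes[mask]

    @property
    def group_norms(self) -> np.ndarray:
        return np.linalg.norm(self.etas, axis=1)


def _fit_on_problem(prob: _GscadProblem, lam: float, alpha: float,
                    warm=None, tol=1e-6, max_outer=25, max_sweeps=500) -> GscadFit:
    if lam == 0.0:
        # penalty vanishes: closed-form weighted least squares
        D = np.concatenate([prob.Zt] + [prob.C[j] for j in range(prob.n_groups)], axis=1)
        theta, *_ = np.linalg.lstsq(D, prob.yt, rcond=None)
        c0 = prob.Zt.shape[1]
        zeta = theta[:c0]
        etas = theta[c0:].reshape(prob.n_groups, prob.L)
        r = prob.yt - D @ theta
        obj = _penalized_rss(r, etas, lam, alpha)
        return GscadFit(genes=prob.genes, coef_z=zeta, etas=etas, lam=lam,
                        alpha=alpha, objective=obj, objective_trace=[obj],
                        converged=True, n_iter=0)

    if warm is not None:
        etas = warm.copy()
    else:
        etas = np.zeros((prob.n_groups, prob.L))
    rp = prob.yp.copy()
    for j in range(prob.n_groups):
        if np.any(etas[j]):
            rp = rp - prob.Cp[j] @ etas[j]

    omega = np.full(prob.n_groups, lam)      # first majorization at the origin
    trace: list[float] = []
    total_sweeps = 0
    converged = False
    prev = etas.ravel().copy()
    for _ in range(max_outer):
        etas, rp, sweeps, inner_ok = _bcd(prob, omega, etas, rp,
                                          tol=tol, max_sweeps=max_sweeps)
        total_sweeps += sweeps
        trace.append(_penalized_rss(rp, etas, lam, alpha))
        cur = etas.ravel()
        change = float(np.max(np.abs(cur - prev))) if len(cur) else 0.0
        new_omega = scad_derivative(np.linalg.norm(etas, axis=1), lam, alpha)
        stable = np.max(np.abs(new_omega - omega)) < 1e-12 if len(omega) else True
        prev = cur.copy()
        omega = new_omega
        if inner_ok and (change < tol or stable):
            converged = True
            break
    zeta = prob.recover_zeta(etas)
    return GscadFit(genes=prob.genes, coef_z=zeta, etas=etas, lam=lam, alpha=alpha,
                    objective=trace[-1], objective_trace=trace,
                    converged=converged, n_iter=total_sweeps)


# --------------------------------------------------------------------------
# Public fitting interfaces
# --------------------------------------------------------------------------

def fit_gscad(panel, basis: SplineBasis, genes, weight_model: WeightModel,
              lam: float, alpha: float = 3.7, tol: float = 1e-6,
              max_outer: int = 25, max_sweeps: int = 500) -> GscadFit:
    """Fit the group-SCAD criterion for one penalty size ``lam``.

    ``genes`` is the screened gene index set; covariate blocks are never
    penalized.  ``lam = 0`` returns the exact weighted least-squares
    solution.  Positive ``lam`` below ``lambda_max`` is reached by a
    short warm-started continuation path from ``lambda_max``.
    Non-convergence returns the best iterate with ``converged=False``.
    """
    prob = _GscadProblem(panel, basis, genes, weight_model)
    warm = None
    if lam > 0.0 and prob.n_groups:
        lam_max = float(np.max(prob.group_grad_norms(prob.yp)))
        if 0.0 < lam < lam_max:
            for l in np.geomspace(lam_max, lam, 8)[:-1]:
                pre = _fit_on_problem(prob, float(l), alpha, warm=warm,
                                      tol=max(tol, 1e-4), max_outer=max_outer,
                                      max_sweeps=max_sweeps)
                warm = pre.etas
    return _fit_on_problem(prob, lam, alpha, warm=warm, tol=tol,
                           max_outer=max_outer, max_sweeps=max_sweeps)


def lambda_grid(panel, basis, genes, weight_model, n_lambda: int = 50,
                lambda_min_ratio: float = 1e-3) -> np.ndarray:
    """Descending log-spaced grid from ``lambda_max`` (all groups zero)."""
    prob = _GscadProblem(panel, basis, genes, weight_model)
    return _lambda_grid_on_problem(prob, n_lambda, lambda_min_ratio)


def _lambda_grid_on_problem(prob, n_lambda, lambda_min_ratio):
    lam_max = float(np.max(prob.group_grad_norms(prob.yp)))
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def _path_on_problem(prob, grid, alpha, tol=1e-6, max_outer=25, max_sweeps=500):
    """Warm-started fits along a descending ``lam`` grid."""
    fits = []
    warm = None
    for lam in grid:
        fit = _fit_on_problem(prob, float(lam), alpha, warm=warm, tol=tol,
                              max_outer=max_outer, max_sweeps=max_sweeps)
        warm = fit.etas
        fits.append(fit)
    return fits


def assign_folds(panel, folds: int, seed: int) -> np.ndarray:
    """Unit-level fold labels, stratified by drug.

    All doses of a unit stay together; within each drug the units are
    shuffled (seeded) and dealt round-robin so every fold sees every
    drug.
    """
    if panel.n_units < folds:
        raise ValueError("fewer units than folds")
    rng = np.random.default_rng(seed)
    labels = np.empty(panel.n_units, dtype=int)
    offset = 0
    for drug in sorted(set(panel.drug_ids.tolist())):
        idx = np.flatnonzero(panel.drug_ids == drug)
        rng.shuffle(idx)
        labels[idx] = (np.arange(len(idx)) + offset) % folds
        offset += len(idx)
    return labels


@dataclass
class CVResult:
    lam: float
    grid: np.ndarray
    cv_mean: np.ndarray
    cv_folds: np.ndarray         # (folds, len(grid))
    fold_labels: np.ndarray


def cross_validate_lambda(panel, basis: SplineBasis, genes, weight_model: WeightModel,
                          lam_grid=None, n_lambda: int = 50,
                          lambda_min_ratio: float = 1e-3, folds: int = 5,
                          seed: int = 0, alpha: float = 3.7, cv_tol: float = 1e-4,
                          max_outer: int = 25, max_sweeps: int = 500) -> CVResult:
    """Choose ``lam`` by unit-level K-fold cross-validation.

    The CV error for a held-out fold is the whitened mean squared
    prediction error ``(1/n_test) sum_i r_i' W_i r_i`` under the shared
    weight model.  Fold fits along the penalty path use a slightly
    looser inner tolerance (``cv_tol``) than the final fit; the
    returned ``lam`` minimizes the mean CV error, ties going to the
    larger ``lam``.
    """
    genes = np.asarray(list(genes), dtype=int)
    if lam_grid is None:
        full_prob = _GscadProblem(panel, basis, genes, weight_model)
        lam_grid = _lambda_grid_on_problem(full_prob, n_lambda, lambda_min_ratio)
    lam_grid = np.sort(np.asarray(lam_grid, dtype=float))[::-1]

    labels = assign_folds(panel, folds, seed)
    errors = np.zeros((folds, len(lam_grid)))
    for f in range(folds):
        train = np.flatnonzero(labels != f)
        test = np.flatnonzero(labels == f)
        tr_prob = _GscadProblem(panel.subset_units(train), basis, genes, weight_model)
        te_prob = _GscadProblem(panel.subset_units(test), basis, genes, weight_model,
                                project=False)
        fits = _path_on_problem(tr_prob, lam_grid, alpha, tol=cv_tol,
                                max_outer=max_outer, max_sweeps=max_sweeps)
        for m, fit in enumerate(fits):
            r = te_prob.yt - te_prob.Zt @ fit.coef_z
            for j in range(te_prob.n_groups):
                if np.any(fit.etas[j]):
                    r = r - te_prob.C[j] @ fit.etas[j]
            errors[f, m] = float(r @ r) / len(test)
    cv_mean = errors.mean(axis=0)
    best = int(np.argmin(cv_mean))          # grid descends: first minimum = largest lam
    return CVResult(lam=float(lam_grid[best]), grid=lam_grid, cv_mean=cv_mean,
                    cv_folds=errors, fold_labels=labels)
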