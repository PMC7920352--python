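"""Stage one: weighted marginal screening of genes.

Each gene ``g`` is fitted marginally — covariate curves plus that single
gene's dose-effect curve — by weighted least squares, and scored by the
weighted mean squared error

    u_g = (1/n) * sum_i (y_i - yhat_i^(g))' W_i (y_i - yhat_i^(g)).

A *smaller* utility means the gene explains more of the dose-response
signal.  Genes are ranked by ascending utility (ties broken by gene
index) and the first ``tau_n = floor(nu * n / ln n)`` are retained for
the penalized selection stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .splines import SplineBasis
from .weights import WeightModel

__all__ = ["MarginalFit", "ScreeningResult", "screening_threshold",
           "fit_marginal_model", "compute_utility", "rank_and_screen", "screen_genes"]


@dataclass
class MarginalFit:
    """Weighted marginal fit for one gene."""

    gene: int
    coef_z: np.ndarray       # (p+1)*L covariate-block coefficients
    coef_gene: np.ndarray    # L gene-block coefficients
    fitted: np.ndarray       # (N,) fitted values on the original scale
    utility: float


@dataclass
class ScreeningResult:
    """Utilities, ranking, and the screened gene set."""

    utilities: np.ndarray    # (G,)
    ranking: np.ndarray      # (G,) gene indices sorted by ascending utility
    screened: np.ndarray     # first min(tau, G) of the ranking, sorted ascending
    tau: int

    def to_frame(self, gene_names=None):
        import pandas as pd
        G = len(self.utilities)
        rank_of = np.empty(G, dtype=int)
        rank_of[self.ranking] = np.arange(1, G + 1)
        keep = np.zeros(G, dtype=int)
        keep[self.screened] = 1
        return pd.DataFrame({
            "gene": gene_names if gene_names is not None else np.arange(G),
            "utility": self.utilities,
            "rank": rank_of,
            "screened": keep,
        })


def screening_threshold(n: int, nu: int = 2) -> int:
    """Submodel size ``tau_n = floor(nu * n / ln n)`` for ``n`` units.

    The natural logarithm is used; e.g. ``n = 3805, nu = 2`` gives 923.
    """
    if n < 2:
        raise ValueError("need at least 2 units")
    if nu < 1:
        raise ValueError("nu must be a positive integer")
    return math.floor(nu * n / math.log(n))


class _WhitenedPanel:
    """Whitened response, covariate design and basis shared across genes."""

    def __init__(self, panel, basis: SplineBasis, weight_model: WeightModel):
        self.panel = panel
        self.basis = basis
        L = basis.n_basis
        B = basis(panel.dose_fraction)                      # (N, L)
        Zrows = panel.Z[panel.unit_index]                   # (N, p+1)
        p1 = Zrows.shape[1]
        Zdes = np.empty((panel.n_obs, p1 * L))
        for k in range(p1):
            Zdes[:, k * L:(k + 1) * L] = Zrows[:, k:k + 1] * B
        self.Zt, self.Bt, self.yt = weight_model.whiten_rows(
            panel, [Zdes, B, panel.response])
        self.Xrows = panel.X[panel.unit_index]              # (N, G), not whitened:
        # expression is constant within a unit, so whitening commutes with
        # the row-wise scaling by x_ig and is applied to the basis instead.
        self.G_zz = self.Zt.T @ self.Zt
        self.G_zy = self.Zt.T @ self.yt
        self.yy = float(self.yt @ self.yt)
        self.L = L

    def solve_gene(self, g: int):
        """Normal-equations WLS solve for covariates + gene ``g``.

        Returns ``(theta_z, theta_g, rss)`` on the whitened scale.  A
        gene that is identically zero degenerates to the covariates-only
        fit (its block drops out).
        """
        x = self.Xrows[:, g]
        C = self.Bt * x[:, None]
        if not np.any(x):
            theta = np.linalg.lstsq(self.Zt, self.yt, rcond=None)[0]
            rss = self.yy - float(self.G_zy @ theta)
            return theta, np.zeros(self.L), max(rss, 0.0)
        Zx = self.Zt.T @ C
        A = np.block([[self.G_zz, Zx], [Zx.T, C.T @ C]])
        b = np.concatenate([self.G_zy, C.T @ self.yt])
        try:
            theta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                f"singular marginal design for gene index {g} (constant or collinear gene)")
        rss = self.yy - float(b @ theta)
        c0 = self.Zt.shape[1]
        return theta[:c0], theta[c0:], max(rss, 0.0)


def fit_marginal_model(panel, basis: SplineBasis, gene: int,
                       weight_model: WeightModel) -> MarginalFit:
    """Weighted marginal varying-coefficient fit for one gene."""
    wp = _WhitenedPanel(panel, basis, weight_model)
    theta_z, theta_g, rss = wp.solve_gene(gene)
    B = basis(panel.dose_fraction)
    Zrows = panel.Z[panel.unit_index]
    L = basis.n_basis
    fitted = np.zeros(panel.n_obs)
    for k in range(Zrows.shape[1]):
        fitted += Zrows[:, k] * (B @ theta_z[k * L:(k + 1) * L])
    fitted += panel.X[panel.unit_index, gene] * (B @ theta_g)
    return MarginalFit(gene=gene, coef_z=theta_z, coef_gene=theta_g,
                       fitted=fitted, utility=rss / panel.n_units)


def compute_utility(y, yhat, panel, weight_model: WeightModel) -> float:
    """Weighted mean squared error ``(1/n) sum_i r_i' W_i r_i``."""
    r = np.asarray(y, dtype=float) - np.asarray(yhat, dtype=float)
    total = 0.0
    for rows in panel.unit_rows():
        W = weight_model.weight_matrix(panel.dose_fraction[rows])
        ri = r[rows]
        total += float(ri @ W @ ri)
    return total / panel.n_units


def rank_and_screen(utilities, tau: int) -> ScreeningResult:
    """Rank genes by ascending utility and keep the first ``min(tau, G)``.

    Ties are broken by ascending gene index (stable sort), so the result
    is deterministic.
    """
    u = np.asarray(utilities, dtype=float)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    ranking = np.argsort(u, kind="stable")
    keep = ranking[:min(tau, len(u))]
    return ScreeningResult(utilities=u, ranking=ranking,
                           screened=np.sort(keep), tau=int(tau))


def screen_genes(panel, basis: SplineBasis, weight_model: WeightModel,
                 nu: int = 2, tau: int | None = None) -> ScreeningResult:
    """Run the full marginal screening stage over all genes.

    The shared whitened pieces are computed once; each gene then costs a
    small normal-equations solve.  ``tau`` defaults to
    ``screening_threshold(panel.n_units, nu)``.
    """
    if tau is None:
        tau = screening_threshold(panel.n_units, nu)
    wp = _WhitenedPanel(panel, basis, weight_model)
    n = panel.n_units
    utilities = np.empty(panel.n_genes)
    for g in range(panel.n_genes):
        _, _, rss = wp.solve_gene(g)
        utilities[g] = rss / n
    return rank_and_screen(utilities, tau)
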