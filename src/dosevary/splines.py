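"""B-spline bases and varying-coefficient design matrices.

Each smooth coefficient function (the intercept curve, each drug /
tissue contrast curve, and each gene's dose-effect curve) is expanded in
a clamped B-spline basis on the observed dose-fraction domain.  With
degree ``q`` and ``K`` interior knots the basis has ``L = K + q + 1``
functions (standard clamped counting).  The applied default is cubic
with one interior knot at the median observed dose, giving ``L = 5``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineBasis", "VCDesign", "interior_knot_count", "knots_from_data",
           "build_vc_design"]


def interior_knot_count(n: int, degree: int) -> int:
    """Rule-of-thumb interior knot count ``floor(n ** (1 / (2q + 3)))``.

    ``n`` is a sample size and ``degree`` the spline degree.  Callers may
    override the result; the applied default configuration is one
    interior knot with cubic splines.
    """
    if n < 1 or degree < 1:
        raise ValueError("need n >= 1 and degree >= 1")
    # guard against float round-off on exact powers (e.g. 512 ** (1/9))
    raw = n ** (1.0 / (2 * degree + 3))
    k = math.floor(raw + 1e-12)
    return max(k, 1)


def knots_from_data(doses: Sequence[float], n_interior: int) -> tuple[np.ndarray, tuple[float, float]]:
    """Interior knots at sample quantiles of the pooled observed doses.

    For ``K`` interior knots the locations are the ``i / (K + 1)``
    quantiles (linear interpolation), so ``K = 1`` places the single
    knot at the median.  Boundary knots sit at the min/max observed
    dose.  Returns ``(interior, (lo, hi))``.
    """
    d = np.asarray(doses, dtype=float)
    if n_interior < 1:
        raise ValueError("need at least one interior knot")
    if len(np.unique(d)) < 2:
        raise ValueError("need at least two distinct dose values")
    probs = np.arange(1, n_interior + 1) / (n_interior + 1)
    interior = np.quantile(d, probs)
    return interior, (float(d.min()), float(d.max()))


@dataclass(frozen=True)
class SplineBasis:
    """Clamped B-spline basis of a given degree on a dose-fraction domain."""

    degree: int
    interior: tuple[float, ...]
    boundary: tuple[float, float]

    def __post_init__(self):
        lo, hi = self.boundary
        knots = (lo, *self.interior, hi)
        if not np.all(np.diff(knots) > 0):
            raise ValueError("knots must be strictly increasing between boundaries")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")

    @classmethod
    def from_data(cls, doses: Sequence[float], degree: int = 3,
                  n_interior: int = 1) -> "SplineBasis":
        interior, boundary = knots_from_data(doses, n_interior)
        return cls(degree=degree, interior=tuple(float(x) for x in interior),
                   boundary=boundary)

    @property
    def n_basis(self) -> int:
        """Number of basis functions, ``L = K + q + 1``."""
        return len(self.interior) + self.degree + 1

    @property
    def knot_vector(self) -> np.ndarray:
        lo, hi = self.boundary
        q = self.degree
        return np.concatenate([[lo] * (q + 1), self.interior, [hi] * (q + 1)])

    def __call__(self, d) -> np.ndarray:
        """Evaluate all ``L`` basis functions at doses ``d`` -> ``(m, L)``.

        Values are nonnegative and each row sums to 1 (partition of
        unity).  Evaluation outside ``[lo, hi]`` raises: the model never
        extrapolates beyond the administered dose range.
        """
        d = np.atleast_1d(np.asarray(d, dtype=float))
        lo, hi = self.boundary
        if np.any(d < lo - 1e-12) or np.any(d > hi + 1e-12):
            raise ValueError(f"dose outside basis domain [{lo}, {hi}]")
        d = np.clip(d, lo, hi)
        t = self.knot_vector
        B = BSpline(t, np.eye(self.n_basis), self.degree, extrapolate=False)(d)
        # scipy returns NaN exactly at the right boundary with
        # extrapolate=False; the clamped basis is right-continuous there.
        at_hi = d == hi
        if np.any(at_hi):
            row = np.zeros(self.n_basis)
            row[-1] = 1.0
            B[at_hi] = row
        return B

    def project(self, d, values) -> np.ndarray:
        """Unpenalized least-squares projection of ``values`` observed at
        doses ``d`` onto the basis; returns the ``L`` coefficients."""
        B = self(d)
        coef, *_ = np.linalg.lstsq(B, np.asarray(values, dtype=float), rcond=None)
        return coef


@dataclass
class VCDesign:
    """Stacked varying-coefficient design matrix with a block index map.

    One block of ``L`` columns per low-dimensional covariate (intercept
    first) followed by one block per included gene; block ``k`` of row
    ``(i, j)`` holds ``z_ik * B_l(d_ij)``, a gene block holds
    ``x_ig * B_l(d_ij)``.
    """

    matrix: np.ndarray
    blocks: dict[str, slice]
    basis: SplineBasis

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def block(self, name: str) -> np.ndarray:
        return self.matrix[:, self.blocks[name]]


def build_vc_design(panel, basis: SplineBasis, genes: Sequence[int] = ()) -> VCDesign:
    """Build the varying-coefficient design for a panel and gene subset.

    ``genes`` are integer column indices into ``panel.X``; an empty
    subset yields the low-dimensional (covariates-only) design.
    """
    B = basis(panel.dose_fraction)                       # (N, L)
    L = basis.n_basis
    Zrows = panel.Z[panel.unit_index]                    # (N, p+1)
    Xrows = panel.X[panel.unit_index][:, list(genes)] if len(genes) else np.empty((panel.n_obs, 0))
    p1 = Zrows.shape[1]
    cols = (p1 + len(genes)) * L
    M = np.empty((panel.n_obs, cols))
    blocks: dict[str, slice] = {}
    for k in range(p1):
        sl = slice(k * L, (k + 1) * L)
        M[:, sl] = Zrows[:, k:k + 1] * B
        blocks[panel.z_names[k]] = sl
    for j, g in enumerate(genes):
        sl = slice((p1 + j) * L, (p1 + j + 1) * L)
        M[:, sl] = Xrows[:, j:j + 1] * B
        blocks[panel.gene_names[g]] = sl
    return VCDesign(matrix=M, blocks=blocks, basis=basis)
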