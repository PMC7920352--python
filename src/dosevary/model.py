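"""Model and results objects tying the two-stage pipeline together.

``DoseVaryingCoefficientModel`` wraps a :class:`~dosevary.panel.DoseResponsePanel`
with a spline basis and weight settings; ``fit()`` runs the full
pipeline — preliminary covariates-only fit, variance / working
correlation estimation, weighted marginal screening, and CV-tuned
group-SCAD selection — and returns a ``DoseVaryingResults`` object
carrying estimates, effect summaries, bootstrap uncertainty, prediction
and a text ``summary()``.

Example
-------
>>> from dosevary import SimulationDesign, simulate_panel
>>> from dosevary import DoseVaryingCoefficientModel
>>> panel, truth = simulate_panel(SimulationDesign(n_genes=50), seed=1)
>>> res = DoseVaryingCoefficientModel(panel).fit(seed=1)
>>> res.selected_genes          # doctest: +SKIP
['gene0012', ...]
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gscad import (CVResult, GscadFit, _GscadProblem, _fit_on_problem,
                    cross_validate_lambda, fit_gscad)
from .panel import DoseResponsePanel, assemble_panel
from .postprocess import (CoefficientCurve, GeneEffectSummary, PredictionMetrics,
                          classify_sign, effect_auc, fold_change,
                          prediction_accuracy, spearman_dose_effect)
from .screening import ScreeningResult, screen_genes, screening_threshold
from .splines import SplineBasis
from .weights import WeightModel, estimate_weight_model

__all__ = ["DoseVaryingCoefficientModel", "DoseVaryingResults", "BootstrapSummary"]


class DoseVaryingCoefficientModel:
    """Dose-varying coefficient regression with two-stage gene selection.

    Parameters
    ----------
    panel : DoseResponsePanel
        Assembled dose-response panel.
    basis : SplineBasis, optional
        Basis for every coefficient curve; defaults to a cubic spline
        with one interior knot at the median observed dose fraction.
    correlation : {"rational_quadratic", "independence"}
        Working within-unit correlation structure for the weights.
    variance_floor : float
        Lower bound applied to the estimated variance function.
    """

    def __init__(self, panel: DoseResponsePanel, basis: SplineBasis | None = None,
                 correlation: str = "rational_quadratic", variance_floor: float = 1e-8):
        self.panel = panel
        self.basis = basis if basis is not None else SplineBasis.from_data(
            panel.dose_fraction, degree=3, n_interior=1)
        self.correlation = correlation
        self.variance_floor = variance_floor
        self._weight_model: WeightModel | None = None

    @classmethod
    def from_frames(cls, records: pd.DataFrame, expression: pd.DataFrame,
                    annotations: pd.DataFrame | None = None, **kwargs) -> "DoseVaryingCoefficientModel":
        """Build directly from raw long-format assay records (see
        :func:`dosevary.panel.assemble_panel` for the table layouts)."""
        panel_kw = {k: kwargs.pop(k) for k in ("codebook", "factors", "reference")
                    if k in kwargs}
        panel = assemble_panel(records, expression, annotations, **panel_kw)
        return cls(panel, **kwargs)

    @property
    def weight_model(self) -> WeightModel:
        """Weight model, estimated once on first access."""
        if self._weight_model is None:
            self._weight_model = estimate_weight_model(
                self.panel, self.basis, structure=self.correlation,
                variance_floor=self.variance_floor)
        return self._weight_model

    def fit(self, nu: int = 2, tau: int | None = None, lam: float | str = "cv",
            alpha: float = 3.7, folds: int = 5, seed: int = 0,
            n_lambda: int = 50, lambda_min_ratio: float = 1e-3,
            tol: float = 1e-6) -> "DoseVaryingResults":
        """Run screening then group-SCAD selection.

        ``lam="cv"`` tunes the penalty by unit-level K-fold
        cross-validation (folds stratified by drug, seeded); a float
        fixes it.  ``tau`` overrides the screening threshold
        ``floor(nu * n / ln n)``.
        """
        wm = self.weight_model
        screening = screen_genes(self.panel, self.basis, wm, nu=nu, tau=tau)
        genes = screening.screened
        cv = None
        if lam == "cv":
            cv = cross_validate_lambda(self.panel, self.basis, genes, wm,
                                       n_lambda=n_lambda,
                                       lambda_min_ratio=lambda_min_ratio,
                                       folds=folds, seed=seed, alpha=alpha)
            lam_val = cv.lam
        else:
            lam_val = float(lam)
        fit = fit_gscad(self.panel, self.basis, genes, wm, lam=lam_val,
                        alpha=alpha, tol=tol)
        return DoseVaryingResults(model=self, screening=screening, gscad=fit, cv=cv)

    def fit_unpenalized(self, genes, panel: DoseResponsePanel | None = None) -> GscadFit:
        """Weighted least-squares fit of covariates + a fixed gene set
        (the refit used by the bootstrap)."""
        panel = panel if panel is not None else self.panel
        prob = _GscadProblem(panel, self.basis, genes, self.weight_model)
        return _fit_on_problem(prob, 0.0, 3.7)


@dataclass
class BootstrapSummary:
    """Unit-resampling bootstrap of the unpenalized refit."""

    genes: list[str]
    auc_sd: dict[str, float]
    bands: dict[str, np.ndarray]       # name -> (2, len(grid)) lower/upper
    grid: np.ndarray
    n_boot: int


class DoseVaryingResults:
    """Estimates and summaries from a fitted two-stage model."""

    def __init__(self, model: DoseVaryingCoefficientModel, screening: ScreeningResult,
                 gscad: GscadFit, cv: CVResult | None = None):
        self.model = model
        self.screening = screening
        self.gscad = gscad
        self.cv = cv

    # ---- selection --------------------------------------------------------
    @property
    def selected_gene_indices(self) -> np.ndarray:
        return self.gscad.selected

    @property
    def selected_genes(self) -> list[str]:
        return [self.model.panel.gene_names[g] for g in self.gscad.selected]

    # ---- coefficient curves ----------------------------------------------
    def dose_grid(self, n: int = 101) -> np.ndarray:
        lo, hi = self.model.basis.boundary
        return np.linspace(lo, hi, n)

    def _coef_for(self, term: str) -> np.ndarray:
        panel = self.model.panel
        L = self.model.basis.n_basis
        if term in panel.z_names:
            k = panel.z_names.index(term)
            return self.gscad.coef_z[k * L:(k + 1) * L]
        if term in panel.gene_names:
            g = panel.gene_names.index(term)
            pos = np.flatnonzero(self.gscad.genes == g)
            if not len(pos):
                raise KeyError(f"gene {term!r} was not in the screened set")
            return self.gscad.etas[pos[0]]
        raise KeyError(f"unknown term {term!r}")

    def coefficient_curve(self, term: str, grid: np.ndarray | None = None) -> CoefficientCurve:
        """Estimated coefficient function for a covariate or gene."""
        grid = self.dose_grid() if grid is None else np.asarray(grid, float)
        values = self.model.basis(grid) @ self._coef_for(term)
        return CoefficientCurve(grid=grid, values=values, name=term)

    # ---- effect table -----------------------------------------------------
    def gene_effects(self, bootstrap: BootstrapSummary | None = None,
                     mutant_column: str | None = None,
                     mutant_level=None) -> pd.DataFrame:
        """Per-selected-gene effect table: AUC (descending), bootstrap SD,
        sign, Spearman monotonicity, optional mutant-vs-wild-type mean
        fold change on the raw expression scale."""
        panel = self.model.panel
        fc_mask = None
        if mutant_column is not None and panel.expression_raw is not None:
            per_cell = panel.annotations.groupby(panel.cell_line_ids)[mutant_column].first()
            cells = panel.expression_raw.index
            fc_mask = per_cell.reindex(cells).to_numpy() == mutant_level
        rows = []
        for name in self.selected_genes:
            curve = self.coefficient_curve(name)
            rho, defined = spearman_dose_effect(curve)
            fc = None
            if fc_mask is not None and fc_mask.any() and not fc_mask.all():
                fc = fold_change(panel.expression_raw, fc_mask, name)
            rows.append(GeneEffectSummary(
                gene=name, auc=effect_auc(curve),
                auc_sd=None if bootstrap is None else bootstrap.auc_sd.get(name),
                sign=classify_sign(curve), spearman=rho, spearman_defined=defined,
                fold_change=fc))
        df = pd.DataFrame([vars(r) for r in rows])
        if len(df):
            df = df.sort_values("auc", ascending=False, kind="stable").reset_index(drop=True)
        return df

    # ---- bootstrap ---------------------------------------------------------
    def bootstrap(self, B: int = 200, seed: int = 0, grid_size: int = 101) -> BootstrapSummary:
        """Resample units with replacement and refit the unpenalized
        weighted model on the fixed selected gene set.

        Returns the bootstrap SD of each selected gene's curve AUC and
        pointwise 2.5/97.5 percentile bands for every term.
        """
        if B < 2:
            raise ValueError("need at least 2 bootstrap replicates")
        panel = self.model.panel
        rng = np.random.default_rng(seed)
        grid = self.dose_grid(grid_size)
        Bg = self.model.basis(grid)
        genes = self.gscad.selected
        L = self.model.basis.n_basis
        names_z = panel.z_names
        names_g = [panel.gene_names[g] for g in genes]
        curves = {name: np.empty((B, len(grid))) for name in names_z + names_g}
        aucs = {name: np.empty(B) for name in names_g}
        for b in range(B):
            idx = rng.integers(0, panel.n_units, size=panel.n_units)
            bp = panel.subset_units(idx)
            fit = self.model.fit_unpenalized(genes, panel=bp)
            for k, name in enumerate(names_z):
                curves[name][b] = Bg @ fit.coef_z[k * L:(k + 1) * L]
            for j, name in enumerate(names_g):
                vals = Bg @ fit.etas[j]
                curves[name][b] = vals
                aucs[name][b] = effect_auc(CoefficientCurve(grid, vals))
        bands = {name: np.percentile(c, [2.5, 97.5], axis=0) for name, c in curves.items()}
        auc_sd = {name: float(a.std(ddof=1)) for name, a in aucs.items()}
        return BootstrapSummary(genes=names_g, auc_sd=auc_sd, bands=bands,
                                grid=grid, n_boot=B)

    # ---- prediction --------------------------------------------------------
    def predict(self, z: np.ndarray, x: np.ndarray | None = None,
                grid: np.ndarray | None = None) -> CoefficientCurve:
        """Predicted mean response curve for one unit.

        ``z`` is a codebook-encoded covariate vector (intercept first);
        ``x`` a standardized expression vector over all panel genes (or
        None for a baseline cell line at average expression).
        """
        grid = self.dose_grid() if grid is None else np.asarray(grid, float)
        Bg = self.model.basis(grid)
        L = self.model.basis.n_basis
        z = np.asarray(z, dtype=float)
        if len(z) != self.model.panel.n_covariates:
            raise ValueError("z has the wrong length for the training codebook")
        vals = np.zeros(len(grid))
        for k in range(len(z)):
            if z[k] != 0:
                vals += z[k] * (Bg @ self.gscad.coef_z[k * L:(k + 1) * L])
        if x is not None:
            x = np.asarray(x, dtype=float)
            for j, g in enumerate(self.gscad.genes):
                if np.any(self.gscad.etas[j]) and x[g] != 0:
                    vals += x[g] * (Bg @ self.gscad.etas[j])
        return CoefficientCurve(grid=grid, values=vals, name="prediction")

    def predict_panel(self, panel: DoseResponsePanel | None = None) -> np.ndarray:
        """Predicted mean response at every observed row of a panel."""
        panel = panel if panel is not None else self.model.panel
        B = self.model.basis(panel.dose_fraction)
        L = self.model.basis.n_basis
        Zrows = panel.Z[panel.unit_index]
        if Zrows.shape[1] != self.model.panel.n_covariates:
            raise ValueError("panel covariates do not match the training codebook")
        yhat = np.zeros(panel.n_obs)
        for k in range(Zrows.shape[1]):
            yhat += Zrows[:, k] * (B @ self.gscad.coef_z[k * L:(k + 1) * L])
        Xrows = panel.X[panel.unit_index]
        for j, g in enumerate(self.gscad.genes):
            if np.any(self.gscad.etas[j]):
                yhat += Xrows[:, g] * (B @ self.gscad.etas[j])
        return yhat

    def evaluate(self, panel: DoseResponsePanel | None = None) -> PredictionMetrics:
        """MAE and argmin-matching accuracies on a (held-out) panel."""
        panel = panel if panel is not None else self.model.panel
        yhat = self.predict_panel(panel)
        table = pd.DataFrame({
            "cell_line": panel.cell_line_ids[panel.unit_index],
            "drug": panel.drug_ids[panel.unit_index],
            "dose_fraction": panel.dose_fraction,
            "observed": panel.response,
            "predicted": yhat,
        })
        return prediction_accuracy(table)

    # ---- reporting ---------------------------------------------------------
    def summary(self) -> str:
        """Plain-text fit summary."""
        panel = self.model.panel
        wm = self.model.weight_model
        lines = [
            "Dose-varying coefficient model (two-stage selection)",
            "=" * 56,
            f"units: {panel.n_units}    observations: {panel.n_obs}    genes: {panel.n_genes}",
            f"basis: B-spline degree={self.model.basis.degree}, interior knots="
            f"{list(self.model.basis.interior)}, L={self.model.basis.n_basis}",
            f"working correlation: {wm.correlation.structure} "
            f"{tuple(round(p, 4) for p in wm.correlation.params)}",
            f"screening: tau={self.screening.tau}, retained {len(self.screening.screened)} genes",
            f"gSCAD: lambda={self.gscad.lam:.6g}, alpha={self.gscad.alpha}, "
            f"selected {len(self.gscad.selected)} genes, converged={self.gscad.converged}",
        ]
        eff = self.gene_effects()
        if len(eff):
            lines.append("-" * 56)
            lines.append(f"{'gene':<14}{'AUC':>8}  {'sign':<5}{'spearman':>9}")
            for _, r in eff.head(15).iterrows():
                lines.append(f"{r.gene:<14}{r.auc:>8.3f}  {r.sign:<5}{r.spearman:>9.3f}")
        return "\n".join(lines)
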