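"""Effect summaries and predictive evaluation for fitted models.

Selected genes are summarized the way practitioners read dose-varying
effects: the area under the absolute coefficient curve (AUC, larger =
stronger effect, well defined also for mixed-sign curves), a bootstrap
standard deviation of that area, the effect sign over the dose range
(``+`` everywhere positive, ``-`` everywhere negative, ``0`` mixed),
and the Spearman correlation of the curve with dose as a monotonicity
index.  Predictive evaluation covers mean absolute error plus four
argmin-matching accuracies (best drug-dose pair, best drug, best dose,
best dose range split at 31.25% of the maximum dose), and a
four-parameter sigmoid fit extracts IC50 from predicted curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import spearmanr

__all__ = ["CoefficientCurve", "GeneEffectSummary", "PredictionMetrics", "IC50Fit",
           "effect_auc", "classify_sign", "spearman_dose_effect", "prediction_accuracy",
           "fit_sigmoid_ic50", "fold_change", "DOSE_RANGE_SPLIT"]

#: dose-fraction split between the "low" and "high" dose range buckets
DOSE_RANGE_SPLIT = 0.3125


@dataclass
class CoefficientCurve:
    """A coefficient function evaluated on a dose grid."""

    grid: np.ndarray
    values: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.grid) != len(self.values):
            raise ValueError("grid and values must align")
        if len(self.grid) >= 2 and not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")


def effect_auc(curve: CoefficientCurve) -> float:
    """Trapezoidal integral of ``|curve|`` over the dose grid.

    The absolute value makes the area positive for mixed-sign curves,
    so it ranks effect magnitude regardless of direction.
    """
    if len(curve.grid) < 2:
        raise ValueError("need at least 2 grid points")
    return float(np.trapezoid(np.abs(curve.values), curve.grid))


def classify_sign(curve: CoefficientCurve) -> str:
    """``"+"`` if the curve stays positive, ``"-"`` if negative, else ``"0"``."""
    lo, hi = float(np.min(curve.values)), float(np.max(curve.values))
    if lo > 0:
        return "+"
    if hi < 0:
        return "-"
    return "0"


def spearman_dose_effect(curve: CoefficientCurve) -> tuple[float, bool]:
    """Spearman correlation between dose and curve value.

    Returns ``(rho, defined)``; a constant curve has no rank
    correlation and yields ``(0.0, False)``.
    """
    if len(curve.grid) < 3:
        raise ValueError("need at least 3 grid points")
    if np.all(curve.values == curve.values[0]):
        return 0.0, False
    rho = spearmanr(curve.grid, curve.values).statistic
    if np.isnan(rho):
        return 0.0, False
    return float(rho), True


@dataclass
class GeneEffectSummary:
    """One row of the gene-effect table."""

    gene: str
    auc: float
    auc_sd: float | None
    sign: str
    spearman: float
    spearman_defined: bool = True
    fold_change: float | None = None


# --------------------------------------------------------------------------
# Predictive evaluation
# --------------------------------------------------------------------------

@dataclass
class PredictionMetrics:
    """MAE and the four argmin-matching scenario accuracies (percent)."""

    mae: float
    acc_drug_dose: float      # best drug-dose pair per cell line
    acc_drug: float           # best drug per cell line
    acc_dose: float           # best dose per unit (cell line-drug)
    acc_dose_range: float     # best dose range per unit (split at 31.25%)
    n_cell_lines: int = 0
    n_units: int = 0

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "acc_drug_dose": self.acc_drug_dose,
            "acc_drug": self.acc_drug,
            "acc_dose": self.acc_dose,
            "acc_dose_range": self.acc_dose_range,
            "n_cell_lines": self.n_cell_lines,
            "n_units": self.n_units,
        }


def prediction_accuracy(table: pd.DataFrame) -> PredictionMetrics:
    """Evaluate dose-response predictions against observations.

    ``table`` has one row per observation with columns ``cell_line``,
    ``drug``, ``dose_fraction``, ``observed``, ``predicted``.  "Most
    effective" means the lowest (normalized viability) response; argmin
    ties resolve to the first row in table order, identically for
    observed and predicted.  Accuracies are percentages of cell lines
    (pair / drug scenarios) or units (dose scenarios) where the
    predicted argmin matches the observed one.  Cell lines treated with
    a single drug are skipped in the best-drug scenario.
    """
    req = {"cell_line", "drug", "dose_fraction", "observed", "predicted"}
    if not req <= set(table.columns):
        raise ValueError(f"prediction table needs columns {sorted(req)}")
    t = table.reset_index(drop=True)
    mae = float(np.mean(np.abs(t["observed"] - t["predicted"])))

    hit_pair, hit_drug = [], []
    for _, grp in t.groupby("cell_line", sort=False):
        obs_row = grp["observed"].idxmin()
        pred_row = grp["predicted"].idxmin()
        same_pair = (grp.loc[obs_row, "drug"] == grp.loc[pred_row, "drug"]
                     and grp.loc[obs_row, "dose_fraction"] == grp.loc[pred_row, "dose_fraction"])
        hit_pair.append(same_pair)
        if grp["drug"].nunique() >= 2:
            hit_drug.append(grp.loc[obs_row, "drug"] == grp.loc[pred_row, "drug"])

    hit_dose, hit_range = [], []
    n_units = 0
    for _, grp in t.groupby(["cell_line", "drug"], sort=False):
        n_units += 1
        obs_d = grp.loc[grp["observed"].idxmin(), "dose_fraction"]
        pred_d = grp.loc[grp["predicted"].idxmin(), "dose_fraction"]
        hit_dose.append(obs_d == pred_d)
        hit_range.append((obs_d <= DOSE_RANGE_SPLIT) == (pred_d <= DOSE_RANGE_SPLIT))

    def pct(hits):
        return 100.0 * float(np.mean(hits)) if hits else float("nan")

    return PredictionMetrics(
        mae=mae,
        acc_drug_dose=pct(hit_pair),
        acc_drug=pct(hit_drug),
        acc_dose=pct(hit_dose),
        acc_dose_range=pct(hit_range),
        n_cell_lines=t["cell_line"].nunique(),
        n_units=n_units,
    )


# --------------------------------------------------------------------------
# IC50 from a predicted curve
# --------------------------------------------------------------------------

@dataclass
class IC50Fit:
    ic50: float                  # dose fraction, clipped to the curve domain
    extrapolated: bool           # curve never crosses half-viability in-domain
    params: dict = field(default_factory=dict)


def fit_sigmoid_ic50(curve: CoefficientCurve) -> IC50Fit:
    """Four-parameter sigmoid fit ``y = lo + (hi - lo) / (1 + (d/m)^h)``.

    ``m`` is the dose of half-maximal effect (IC50 on the fraction
    scale).  When the fitted curve never reaches its half level inside
    the observed dose domain, ``m`` is clipped to the domain and the
    result flagged as extrapolated.
    """
    d = curve.grid
    y = curve.values
    if len(d) < 4:
        raise ValueError("need at least 4 grid points")
    if not np.all(np.isfinite(y)):
        raise ValueError("curve values must be finite")

    lo0, hi0 = float(np.min(y)), float(np.max(y))
    dmin, dmax = float(d[0]), float(d[-1])

    def sigmoid(dd, lo, hi, m, h):
        return lo + (hi - lo) / (1.0 + (dd / m) ** h)

    span = hi0 - lo0
    if span < 1e-12:
        return IC50Fit(ic50=dmax, extrapolated=True,
                       params={"lower": lo0, "upper": hi0, "m": dmax, "h": np.nan})
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                sigmoid, d, y,
                p0=[lo0, hi0, float(np.median(d)), 1.0],
                bounds=([lo0 - abs(span), hi0 - abs(span), 1e-6, 0.05],
                        [lo0 + abs(span), hi0 + abs(span), 1e3, 50.0]),
                maxfev=20000)
    except RuntimeError:
        return IC50Fit(ic50=dmax, extrapolated=True,
                       params={"lower": lo0, "upper": hi0, "m": dmax, "h": np.nan})
    lo, hi, m, h = (float(v) for v in popt)
    fitted = sigmoid(d, lo, hi, m, h)
    half = (lo + hi) / 2.0
    crosses = (fitted.min() - 1e-9) <= half <= (fitted.max() + 1e-9)
    in_domain = dmin <= m <= dmax
    extrap = not (crosses and in_domain)
    return IC50Fit(ic50=float(np.clip(m, dmin, dmax)), extrapolated=extrap,
                   params={"lower": lo, "upper": hi, "m": m, "h": h})


# --------------------------------------------------------------------------
# Fold change
# --------------------------------------------------------------------------

def fold_change(expression: pd.DataFrame, mutant: np.ndarray, gene: str) -> float:
    """Mean expression in mutant cell lines over mean in wild-type.

    Computed on the original (unstandardized) expression scale.
    ``mutant`` is a boolean mask aligned with the rows (cell lines) of
    ``expression``.
    """
    mutant = np.asarray(mutant, dtype=bool)
    if len(mutant) != len(expression):
        raise ValueError("mutant mask must align with expression rows")
    if not mutant.any() or mutant.all():
        raise ValueError("both mutant and wild-type groups must be non-empty")
    vals = expression[gene].to_numpy(dtype=float)
    wt_mean = float(vals[~mutant].mean())
    if wt_mean == 0.0:
        raise ValueError("wild-type mean expression is zero")
    return float(vals[mutant].mean()) / wt_mean
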