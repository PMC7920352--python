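"""Synthetic GDSC-like panels with known truth, and the Monte Carlo
selection-performance harness.

The generator emulates the structure of a large drug-sensitivity screen:
experimental units are cell line-drug pairs measured over a dilution
series (a mix of 9-point 2-fold and 5-point 4-fold series, roughly
2:1 as in the screen the model targets), with responses drawn from the
dose-varying coefficient model

    y_ij = sum_k z_ik beta_k(d_ij) + sum_{g in A} x_ig gamma_g(d_ij) + eps_ij

where only a small active set ``A`` of genes has a nonzero effect
curve.  Expression is multivariate normal with exchangeable correlation
across genes; errors are heteroscedastic in dose with optional
rational-quadratic within-unit correlation.  Every random draw descends
from one seed through a per-replicate counter scheme, so runs are
reproducible and parallel-safe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .panel import CovariateCodebook, DoseResponsePanel
from .weights import rational_quadratic

__all__ = ["SimulationDesign", "ConfusionCounts", "simulate_panel",
           "evaluate_selection", "run_simulation_study", "coefficient_library"]


def coefficient_library(amplitude: float = 1.0) -> list[Callable]:
    """Smooth effect-curve shapes: constant, linear, sine, Gaussian bump."""
    a = amplitude
    return [
        lambda d, a=a: np.full_like(np.asarray(d, float), a),
        lambda d, a=a: a * np.asarray(d, float),
        lambda d, a=a: a * np.sin(np.pi * np.asarray(d, float)),
        lambda d, a=a: a * np.exp(-((np.asarray(d, float) - 0.5) ** 2) / 0.05),
    ]


@dataclass
class SimulationDesign:
    """Parameters of one synthetic study condition.

    Defaults mirror the scaled study condition used throughout: 190
    units, 886 genes, 6 active genes with strong smooth effects, a 2:1
    mix of 9-point 2-fold and 5-point 4-fold dilution series, five
    drugs and three tissues, exchangeably correlated expression, and
    dose-increasing noise ``V(d) = sigma^2 (1 + d)^2`` with
    rational-quadratic within-unit correlation ``(a, l) = (2, 0.3)``.

    ``units_per_cell_line`` controls how many drugs each cell line is
    paired with.  The default 1 emulates subsampling units from a large
    screen (a moderate subsample contains almost no repeated cell
    lines); raising it towards ``n_drugs`` emulates the full screen
    where every cell line is tested with every drug — and sharply
    reduces the number of distinct expression profiles, which makes
    marginal screening genuinely harder.

    ``amplitude`` sets the effect size of every active gene on a common
    scale: each library shape is rescaled so that its root mean square
    over the panel's observed dose fractions equals ``amplitude``.
    Without this, shapes whose mass sits at high doses (linear, bump)
    would be much weaker than flat shapes under the log-spaced dilution
    designs, and "strong signal" would silently mean different things
    per shape.  The default 0.5 is roughly four times the RMS noise
    standard deviation (``sigma = 0.1`` gives noise SD 0.1-0.2 across
    the dose range), a strong-signal regime.
    """

    n_units: int = 190
    n_genes: int = 886
    n_active: int = 6
    amplitude: float = 0.5          # RMS of each active effect curve (see below)
    frac_nine_point: float = 0.66
    n_drugs: int = 5
    n_tissues: int = 3
    units_per_cell_line: int = 1
    rho_x: float = 0.2
    sigma: float = 0.1
    correlation: str = "rational_quadratic"       # error-generating structure
    corr_a: float = 2.0
    corr_ell: float = 0.3
    mutation_rate: float = 0.3

    def __post_init__(self):
        if not (0 <= self.rho_x < 1):
            raise ValueError("rho_x must be in [0, 1)")
        if self.n_active > self.n_genes:
            raise ValueError("|active set| cannot exceed the number of genes")
        if self.correlation not in ("independence", "rational_quadratic"):
            raise ValueError("correlation must be independence or rational_quadratic")


@dataclass
class SimulationTruth:
    """Generating truth stored alongside a simulated panel."""

    active: np.ndarray                        # active gene indices
    gamma: dict[int, Callable]                # gene index -> effect function
    beta: list[Callable]                      # one function per z column
    design: SimulationDesign


def _beta_functions(design: SimulationDesign) -> list[Callable]:
    """Covariate effect curves: declining viability baseline plus small
    drug/tissue contrasts cycling through a fixed shape library."""
    shapes = [
        lambda d: 0.10 * np.sin(np.pi * np.asarray(d, float)),
        lambda d: -0.10 * np.asarray(d, float),
        lambda d: 0.15 * np.asarray(d, float) ** 2,
        lambda d: np.full_like(np.asarray(d, float), 0.05),
        lambda d: -0.05 * np.cos(np.pi * np.asarray(d, float)),
    ]
    betas = [lambda d: 1.0 - 0.8 * np.asarray(d, float)]     # intercept curve
    n_contrasts = (design.n_drugs - 1) + (design.n_tissues - 1) + 1  # + mutation
    for j in range(n_contrasts):
        betas.append(shapes[j % len(shapes)])
    return betas


def _dose_series(nine_point: bool) -> np.ndarray:
    if nine_point:
        return 2.0 ** -np.arange(8, -1, -1.0)     # 1/256 ... 1, 9 points
    return 4.0 ** -np.arange(4, -1, -1.0)         # 1/256 ... 1, 5 points


def simulate_panel(design: SimulationDesign, seed: int) -> tuple[DoseResponsePanel, SimulationTruth]:
    """Draw one panel from the design; identical seeds give identical panels."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    n, G = design.n_units, design.n_genes

    # units: cell line-drug pairs; drugs cycle within each cell line so
    # a cell line never repeats a drug, and across units so drug
    # frequencies stay balanced
    upc = min(design.units_per_cell_line, design.n_drugs)
    n_cells = int(np.ceil(n / upc))
    cell_ids = [f"CL{c:04d}" for c in range(n_cells)]
    drug_ids_all = [f"drug{k}" for k in range(design.n_drugs)]
    units = [(cell_ids[u // upc], drug_ids_all[u % design.n_drugs])
             for u in range(n)]

    tissues = rng.integers(0, design.n_tissues, size=n_cells)
    mutant = rng.random(n_cells) < design.mutation_rate

    # expression: exchangeable correlation across genes via a shared factor,
    # on a microarray-like raw scale (gene-specific positive means)
    gene_means = rng.uniform(4.0, 10.0, size=G)
    shared = rng.standard_normal(n_cells)
    noise = rng.standard_normal((n_cells, G))
    latent = np.sqrt(design.rho_x) * shared[:, None] + np.sqrt(1 - design.rho_x) * noise
    raw = gene_means[None, :] + latent
    gene_names = [f"gene{g:04d}" for g in range(G)]
    expression = pd.DataFrame(raw, index=cell_ids, columns=gene_names)
    std_vals = (raw - raw.mean(axis=0)) / np.where(raw.std(axis=0) == 0, 1, raw.std(axis=0))

    # dose patterns: first ~66% of units get the 9-point series (fixed
    # assignment so the mix is exact, shuffled by rng for arbitrary order)
    nine = np.zeros(n, dtype=bool)
    nine[: int(round(design.frac_nine_point * n))] = True
    rng.shuffle(nine)
    unit_doses = [_dose_series(b) for b in nine]
    unit_index = np.repeat(np.arange(n), [len(d) for d in unit_doses])
    dose = np.concatenate(unit_doses)

    # truth: active effect curves, RMS-normalized over the observed doses
    active = np.sort(rng.choice(G, size=design.n_active, replace=False))
    library = coefficient_library(1.0)
    gamma = {}
    for j, g in enumerate(active):
        shape = library[j % len(library)]
        rms = float(np.sqrt(np.mean(shape(dose) ** 2)))
        scale = (-1.0) ** j * design.amplitude / rms
        gamma[int(g)] = (lambda d, f=shape, s=scale: s * f(d))
    betas = _beta_functions(design)

    # covariates
    cell_of = np.array([cell_ids.index(c) for c, _ in units])
    annot = pd.DataFrame({
        "drug": [dr for _, dr in units],
        "tissue": [f"tissue{tissues[ci]}" for ci in cell_of],
        "braf_status": ["mutant" if mutant[ci] else "wild_type" for ci in cell_of],
    })
    codebook = CovariateCodebook(
        levels={"drug": drug_ids_all,
                "tissue": [f"tissue{t}" for t in range(design.n_tissues)],
                "braf_status": ["mutant", "wild_type"]},
        reference={"drug": "drug0", "tissue": "tissue0", "braf_status": "mutant"})
    Z = codebook.encode(annot)
    if Z.shape[1] != len(betas):
        raise RuntimeError("covariate coding and beta library out of sync")

    X_units = std_vals[cell_of]
    mean = np.zeros(len(dose))
    for k in range(Z.shape[1]):
        mean += Z[unit_index, k] * betas[k](dose)
    for g, f in gamma.items():
        mean += X_units[unit_index, g] * f(dose)

    eps = np.zeros(len(dose))
    for i, d_i in enumerate(unit_doses):
        rows = slice(*np.searchsorted(unit_index, [i, i + 1]))
        sd = design.sigma * (1.0 + d_i)
        if design.sigma == 0.0:
            pass
        elif design.correlation == "independence":
            eps[rows] = sd * rng.standard_normal(len(d_i))
        else:
            H = np.abs(d_i[:, None] - d_i[None, :])
            R = rational_quadratic(H, design.corr_a, design.corr_ell)
            cov = sd[:, None] * R * sd[None, :]
            eps[rows] = rng.multivariate_normal(np.zeros(len(d_i)), cov,
                                                method="cholesky")

    panel = DoseResponsePanel(
        unit_ids=np.array([f"{c}:{dr}" for c, dr in units], dtype=object),
        cell_line_ids=np.array([c for c, _ in units], dtype=object),
        drug_ids=np.array([dr for _, dr in units], dtype=object),
        unit_index=unit_index,
        dose_fraction=dose,
        response=mean + eps,
        Z=Z,
        z_names=codebook.column_names,
        X=X_units,
        gene_names=gene_names,
        annotations=annot,
        codebook=codebook,
        expression_raw=expression,
        expr_mean=raw.mean(axis=0),
        expr_std=raw.std(axis=0),
    )
    return panel, SimulationTruth(active=active, gamma=gamma, beta=betas, design=design)


# --------------------------------------------------------------------------
# Selection performance
# --------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    """Gene-level selection confusion counts (sum to G)."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    @property
    def tpr(self) -> float:
        pos = self.TP + self.FN
        return self.TP / pos if pos else float("nan")

    @property
    def fpr(self) -> float:
        neg = self.FP + self.TN
        return self.FP / neg if neg else float("nan")


def evaluate_selection(selected, active, n_genes: int) -> ConfusionCounts:
    """Confusion counts of a selected gene set against the active truth."""
    selected = set(int(g) for g in selected)
    active = set(int(g) for g in active)
    universe = set(range(n_genes))
    if not selected <= universe or not active <= universe:
        raise ValueError("gene indices must lie in [0, n_genes)")
    tp = len(selected & active)
    fp = len(selected - active)
    fn = len(active - selected)
    return ConfusionCounts(TP=tp, FP=fp, TN=n_genes - tp - fp - fn, FN=fn)


def _replicate_seed(master_seed: int, rep: int) -> np.random.SeedSequence:
    """Counter-scheme sub-seed: replicate ``rep`` of master ``master_seed``."""
    return np.random.SeedSequence([master_seed, 1, rep])


def run_simulation_study(design: SimulationDesign, reps: int, seed: int = 0,
                         nus: Sequence[int] = (1, 2),
                         structures: Sequence[str] = ("independence", "rational_quadratic"),
                         n_lambda: int = 30, lambda_min_ratio: float = 1e-2,
                         folds: int = 5, alpha: float = 3.7) -> pd.DataFrame:
    """Monte Carlo study of the full two-stage pipeline.

    For each scenario (screening-threshold multiplier ``nu`` crossed
    with working-correlation structure) and each replicate, a fresh
    panel is drawn, the pipeline (weights -> screening -> CV-tuned
    group SCAD) is run, and gene-level confusion counts are recorded;
    the table reports their means and standard deviations, plus the
    fraction of replicates in which screening already retained the full
    active set (sure-screening coverage).

    Replicate ``r`` uses the sub-seed ``SeedSequence([seed, 1, r])`` for
    data and derives its CV fold seed from it, so scenarios share data
    across the same replicate index and runs parallelize safely.
    """
    from .model import DoseVaryingCoefficientModel

    rows = []
    for nu in nus:
        for structure in structures:
            counts = []
            screen_cover = []
            for rep in range(reps):
                ss = _replicate_seed(seed, rep)
                data_seed, cv_seed = (int(s) % (2 ** 31) for s in ss.generate_state(2))
                panel, truth = simulate_panel(design, seed=data_seed)
                model = DoseVaryingCoefficientModel(panel, correlation=structure)
                res = model.fit(nu=nu, alpha=alpha, folds=folds, seed=cv_seed,
                                n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio)
                screened = set(res.screening.screened.tolist())
                screen_cover.append(set(truth.active.tolist()) <= screened)
                counts.append(evaluate_selection(res.selected_gene_indices,
                                                 truth.active, design.n_genes))
            arr = np.array([[c.TP, c.FP, c.TN, c.FN] for c in counts], dtype=float)
            rows.append({
                "nu": nu, "structure": structure, "reps": reps,
                "TP": arr[:, 0].mean(), "FP": arr[:, 1].mean(),
                "TN": arr[:, 2].mean(), "FN": arr[:, 3].mean(),
                "TP_sd": arr[:, 0].std(ddof=1) if reps > 1 else 0.0,
                "FP_sd": arr[:, 1].std(ddof=1) if reps > 1 else 0.0,
                "TN_sd": arr[:, 2].std(ddof=1) if reps > 1 else 0.0,
                "FN_sd": arr[:, 3].std(ddof=1) if reps > 1 else 0.0,
                "TPR": arr[:, 0].mean() / design.n_active,
                "FPR": arr[:, 1].mean() / (design.n_genes - design.n_active),
                "screen_coverage": float(np.mean(screen_cover)),
            })
    return pd.DataFrame(rows)
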