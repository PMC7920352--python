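# dosevary

Dose-varying coefficient regression for transcriptome-wide association
with anticancer drug response.

## The problem

Cell-line drug screens (such as the Genomics of Drug Sensitivity in
Cancer) measure the viability of hundreds of cancer cell lines treated
with a drug over a short dilution series — typically nine 2-fold or
five 4-fold dilutions below a per-drug maximum concentration.  Classical
analyses collapse each dilution series into a single summary (IC50,
AUC) and regress that on molecular features, discarding how an
association changes with dose.  `dosevary` instead models the whole
response curve and asks, for each of thousands of genes, *how the
effect of its baseline expression on viability varies with dose*.

## The model

For experimental unit *i* (one cell line–drug pair) with normalized
viability *y<sub>ij</sub>* at dose fraction *d<sub>ij</sub>* ∈ (0, 1]:

    y_ij = Σ_k z_ik β_k(d_ij) + Σ_g x_ig γ_g(d_ij) + ε_ij

* **z<sub>i</sub>** — intercept plus dummy-coded drug, tissue and
  mutation-status covariates, always in the model;
* **x<sub>i</sub>** — standardized expression of *G* genes (*G* ≫ *n*),
  assumed sparse: only a few γ<sub>g</sub> are nonzero;
* **β<sub>k</sub>(·), γ<sub>g</sub>(·)** — smooth coefficient curves,
  expanded in a clamped cubic B-spline basis (one interior knot at the
  median observed dose, L = 5 basis functions);
* **ε<sub>ij</sub>** — mean-zero errors with dose-dependent variance
  V(d) and within-unit correlation.

Estimation is weighted least squares with per-unit weight matrices
W<sub>i</sub> = V̂<sub>i</sub><sup>−1/2</sup> R<sub>i</sub>(φ̂)<sup>−1</sup> V̂<sub>i</sub><sup>−1/2</sup> / n<sub>i</sub>,
where V̂(d) is estimated from preliminary covariates-only residuals and
R(φ) is a working correlation (independence or rational-quadratic,
R(h) = (1 + h²/(2aℓ²))<sup>−a</sup> in the dose lag h).

Gene selection is two-stage:

1. **Screening** — each gene is fit marginally; its utility is the
   weighted mean squared error u<sub>g</sub> = (1/n) Σ<sub>i</sub>
   (y<sub>i</sub> − ŷ<sub>i</sub><sup>(g)</sup>)ᵀ W<sub>i</sub>
   (y<sub>i</sub> − ŷ<sub>i</sub><sup>(g)</sup>).  The
   τ<sub>n</sub> = ⌊ν·n/ln n⌋ genes with the smallest utilities survive.
2. **Group-SCAD selection** — over the screened genes, minimize
   ½ Σ w-weighted squared error + Σ<sub>g</sub> p<sub>λ,α</sub>(‖η<sub>g</sub>‖),
   where η<sub>g</sub> are gene *g*'s five spline coefficients (one
   group per gene) and p is the SCAD penalty (lasso slope λ near zero,
   flat beyond αλ so large effects are unbiased).  λ is chosen by
   unit-level 5-fold cross-validation; the optimizer is a local linear
   approximation solved by block coordinate descent.

Selected genes are summarized by the area under |γ̂<sub>g</sub>| (AUC),
its unit-bootstrap standard deviation, the effect sign over the dose
range, and the Spearman correlation of the curve with dose
(monotonicity).  Prediction utilities include full-curve prediction,
best drug/dose accuracy metrics, and sigmoid-fit IC50 extraction.

## Worked example

Everything runs end-to-end on synthetic screens with known truth:

```python
from dosevary import DoseVaryingCoefficientModel, SimulationDesign, simulate_panel

design = SimulationDesign(n_units=120, n_genes=60, n_active=4, units_per_cell_line=5)
panel, truth = simulate_panel(design, seed=11)

model = DoseVaryingCoefficientModel(panel, correlation="rational_quadratic")
results = model.fit(nu=2, seed=11, n_lambda=30, lambda_min_ratio=1e-2)
print(results.summary())
```

```
Dose-varying coefficient model (two-stage selection)
========================================================
units: 120    observations: 916    genes: 60
basis: B-spline degree=3, interior knots=[0.0625], L=5
working correlation: rational_quadratic (2.8609, 0.2647)
screening: tau=50, retained 50 genes
gSCAD: lambda=0.886505, alpha=3.7, selected 12 genes, converged=True
--------------------------------------------------------
gene               AUC  sign  spearman
gene0050         1.049  0       -0.575
gene0016         0.572  0       -0.161
gene0015         0.402  -       -1.000
gene0012         0.373  +       -0.704
gene0034         0.008  +       -0.050
...
```

The four planted genes (`gene0012`, `gene0015`, `gene0016`,
`gene0050`) head the ranking; the remaining selections have AUC at or
below their bootstrap noise level:

```python
boot = results.bootstrap(B=100, seed=11)
table = results.gene_effects(bootstrap=boot, mutant_column="braf_status",
                             mutant_level="mutant")
print(table.head(5).to_string(index=False))
```

```
    gene      auc   auc_sd sign  spearman  spearman_defined  fold_change
gene0050 1.049446 0.033557    0 -0.574712              True     0.901694
gene0016 0.571521 0.020203    0 -0.160594              True     0.868968
gene0015 0.401937 0.027305    - -1.000000              True     0.940560
gene0012 0.372994 0.021996    + -0.703809              True     0.907886
gene0034 0.008453 0.013249    + -0.049983              True     0.928935
```

Reading the first row: gene0050's effect curve has area 1.05 (±0.03),
mixed sign over the dose range (it crosses zero), and a mildly
decreasing trend with dose.  `fold_change` is the mutant/wild-type mean
expression ratio on the raw scale.  In-sample predictive evaluation:

```python
m = results.evaluate()
# MAE 0.1251 | best drug-dose 25.0% | best drug 25.0% | best dose 93.3% | dose range 95.0%
```

MAE is on the normalized-viability scale; the four accuracies are the
percentage of cell lines (or units) whose observed most-effective
drug–dose pair, drug, dose, and dose range (≤ vs > 31.25% of the
maximum dose) match the model's prediction.

The same pipeline is available from the shell:

```bash
dosevary simulate --seed 11 --out panel.json
dosevary screen   --panel panel.json --nu 2 --out ranking.tsv
dosevary select   --panel panel.json --ranking ranking.tsv --seed 11 --out fit.json
dosevary summarize --panel panel.json --fit fit.json --bootstrap 200 --seed 11 --out summary.tsv
dosevary run      --config config.yaml        # all stages, reproducible artifacts
```

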