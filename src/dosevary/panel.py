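"""Data model for dose-response panels.

A *panel* holds everything the dose-varying coefficient model needs:

* per experimental unit (one cell line treated with one drug) a short
  dilution series of dose fractions ``d_i1 < ... < d_in_i`` in ``(0, 1]``
  and the matching normalized viability responses ``y_ij``;
* a low-dimensional covariate vector ``z_i`` (intercept + dummy-coded
  drug / tissue / mutation-status effects);
* a high-dimensional expression vector ``x_i`` (one value per gene,
  standardized across cell lines).

Raw fluorescence readouts are normalized against the per-unit blank
(``BR``, empty well) and zero-dose control (``CR``, untreated well):

    y = (R - BR) / (CR - BR)

so ``y ≈ 1`` means untreated growth and ``y ≈ 0`` means no signal above
blank.  The transformation is affine and deliberately *not* clamped to
``[0, 1]``: assay noise legitimately produces values slightly outside.
Doses are expressed as fractions of each drug's maximum screening
concentration so different drugs share one dose domain.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateControlError",
    "InvalidUnitError",
    "CodebookError",
    "CovariateCodebook",
    "DoseResponsePanel",
    "normalize_response",
    "rescale_dose",
    "encode_covariates",
    "assemble_panel",
]


class DegenerateControlError(ValueError):
    """Zero-dose control equals the blank: the affine map is undefined."""


class InvalidUnitError(ValueError):
    """Control below blank: the unit's normalization would flip sign."""


class CodebookError(KeyError):
    """An annotation level is absent from the covariate codebook."""


def normalize_response(R, BR, CR):
    """Normalize a raw response against blank and zero-dose control.

    Parameters
    ----------
    R, BR, CR : float or array-like
        Raw response, blank response, and zero-dose control response of
        the same experimental unit (fluorescence units).

    Returns
    -------
    float or ndarray
        ``(R - BR) / (CR - BR)``, unclamped.

    Raises
    ------
    DegenerateControlError
        If ``CR == BR`` anywhere.
    InvalidUnitError
        If ``CR < BR`` anywhere (the unit should be rejected upstream).
    """
    R = np.asarray(R, dtype=float)
    BR = np.asarray(BR, dtype=float)
    CR = np.asarray(CR, dtype=float)
    span = CR - BR
    if np.any(span == 0.0):
        raise DegenerateControlError("zero-dose control equals blank (CR == BR)")
    if np.any(span < 0.0):
        raise InvalidUnitError("zero-dose control below blank (CR < BR)")
    out = (R - BR) / span
    if out.ndim == 0:
        return float(out)
    return out


def rescale_dose(dose, max_dose):
    """Convert a raw concentration to a fraction of the maximum dose.

    Returns ``dose / max_dose`` in ``(0, 1]``; raises ``ValueError`` for
    non-positive doses or doses above the maximum.
    """
    dose = np.asarray(dose, dtype=float)
    max_dose = np.asarray(max_dose, dtype=float)
    if np.any(dose <= 0.0):
        raise ValueError("dose must be strictly positive")
    if np.any(dose > max_dose):
        raise ValueError("dose exceeds the stated maximum dose")
    out = dose / max_dose
    if out.ndim == 0:
        return float(out)
    return out


class CovariateCodebook:
    """Reference-level (dummy) coding scheme for the low-dimensional covariates.

    Each factor (drug, tissue, mutation status, ...) has an ordered list
    of levels and exactly one *reference* level.  A unit at the reference
    level of every factor maps to ``z = (1, 0, ..., 0)``; every
    non-reference level contributes one 0/1 dummy column.
    """

    def __init__(self, levels: Mapping[str, Sequence], reference: Mapping[str, object] | None = None):
        reference = dict(reference or {})
        self.factors: dict[str, list] = {}
        self.reference: dict[str, object] = {}
        for name, levs in levels.items():
            levs = list(dict.fromkeys(levs))  # preserve order, drop dups
            ref = reference.get(name, levs[0])
            if ref not in levs:
                raise CodebookError(f"reference level {ref!r} not among levels of {name!r}")
            self.factors[name] = levs
            self.reference[name] = ref

    @classmethod
    def from_annotations(cls, annotations: pd.DataFrame, factors: Sequence[str] | None = None,
                         reference: Mapping[str, object] | None = None) -> "CovariateCodebook":
        """Build a codebook from a per-unit annotation table.

        ``factors`` defaults to every column of ``annotations``; levels
        are taken in sorted order so the codebook does not depend on row
        order; the reference defaults to the first sorted level.
        """
        if factors is None:
            factors = list(annotations.columns)
        levels = {f: sorted(annotations[f].unique().tolist()) for f in factors}
        return cls(levels, reference)

    @property
    def column_names(self) -> list[str]:
        names = ["intercept"]
        for f, levs in self.factors.items():
            names += [f"{f}[{lev}]" for lev in levs if lev != self.reference[f]]
        return names

    @property
    def n_columns(self) -> int:
        return 1 + sum(len(levs) - 1 for levs in self.factors.values())

    def encode(self, annotations: pd.DataFrame) -> np.ndarray:
        """Encode an annotation table into the ``(n, p+1)`` design ``Z``."""
        n = len(annotations)
        Z = np.zeros((n, self.n_columns))
        Z[:, 0] = 1.0
        col = 1
        for f, levs in self.factors.items():
            vals = annotations[f].to_numpy()
            known = set(levs)
            unseen = [v for v in pd.unique(vals) if v not in known]
            if unseen:
                raise CodebookError(f"unseen level(s) {unseen!r} for factor {f!r}")
            for lev in levs:
                if lev == self.reference[f]:
                    continue
                Z[:, col] = (vals == lev).astype(float)
                col += 1
        return Z

    def to_dict(self) -> dict:
        return {"factors": {k: list(v) for k, v in self.factors.items()},
                "reference": dict(self.reference)}

    @classmethod
    def from_dict(cls, d: dict) -> "CovariateCodebook":
        return cls(d["factors"], d["reference"])


def encode_covariates(annotations: pd.DataFrame, codebook: CovariateCodebook) -> np.ndarray:
    """Functional alias for :meth:`CovariateCodebook.encode`."""
    return codebook.encode(annotations)


@dataclass
class DoseResponsePanel:
    """Assembled long-format dose-response panel.

    Rows are grouped contiguously by unit and sorted by increasing dose
    fraction within each unit.  ``X`` holds expression standardized to
    mean 0 / variance 1 across the distinct cell lines; the raw
    expression matrix is retained for fold-change summaries.
    """

    unit_ids: np.ndarray          # (n,) unit identifiers
    cell_line_ids: np.ndarray     # (n,)
    drug_ids: np.ndarray          # (n,)
    unit_index: np.ndarray        # (N,) int, row -> unit position
    dose_fraction: np.ndarray     # (N,) float in (0, 1]
    response: np.ndarray          # (N,) normalized response
    Z: np.ndarray                 # (n, p+1)
    z_names: list[str]
    X: np.ndarray                 # (n, G) standardized expression
    gene_names: list[str]
    annotations: pd.DataFrame     # per-unit annotation table (n rows)
    codebook: CovariateCodebook
    expression_raw: pd.DataFrame | None = None   # cell lines x genes
    expr_mean: np.ndarray | None = None
    expr_std: np.ndarray | None = None

    # ---- basic dimensions -------------------------------------------------
    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_obs(self) -> int:
        return len(self.response)

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.Z.shape[1]

    @property
    def n_per_unit(self) -> np.ndarray:
        return np.bincount(self.unit_index, minlength=self.n_units)

    def unit_rows(self) -> list[np.ndarray]:
        """Row indices of each unit, in unit order (rows are contiguous)."""
        starts = np.searchsorted(self.unit_index, np.arange(self.n_units))
        ends = np.searchsorted(self.unit_index, np.arange(self.n_units), side="right")
        return [np.arange(s, e) for s, e in zip(starts, ends)]

    def validate(self) -> None:
        if not np.all(np.diff(self.unit_index) >= 0):
            raise ValueError("rows are not grouped by unit")
        for rows in self.unit_rows():
            d = self.dose_fraction[rows]
            if len(d) < 2:
                raise ValueError("modeled units need at least 2 doses")
            if not np.all(np.diff(d) > 0):
                raise ValueError("dose fractions must be strictly increasing within unit")
        if np.any(self.dose_fraction <= 0) or np.any(self.dose_fraction > 1):
            raise ValueError("dose fractions must lie in (0, 1]")
        if not np.allclose(self.Z[:, 0], 1.0):
            raise ValueError("first column of Z must be the intercept")

    # ---- subsetting -------------------------------------------------------
    def subset_units(self, idx: Sequence[int]) -> "DoseResponsePanel":
        """Return a panel with units ``idx`` (repeats allowed, e.g. bootstrap).

        Repeated units are relabelled with a suffix so unit ids stay unique.
        """
        idx = np.asarray(idx, dtype=int)
        rows_by_unit = self.unit_rows()
        new_rows = []
        new_unit_index = []
        new_unit_ids = []
        for new_i, old_i in enumerate(idx):
            r = rows_by_unit[old_i]
            new_rows.append(r)
            new_unit_index.append(np.full(len(r), new_i))
            uid = self.unit_ids[old_i]
            count = np.sum(idx[:new_i] == old_i)
            new_unit_ids.append(uid if count == 0 else f"{uid}#b{count}")
        rows = np.concatenate(new_rows) if new_rows else np.array([], dtype=int)
        return DoseResponsePanel(
            unit_ids=np.array(new_unit_ids, dtype=object),
            cell_line_ids=self.cell_line_ids[idx],
            drug_ids=self.drug_ids[idx],
            unit_index=np.concatenate(new_unit_index) if new_unit_index else np.array([], dtype=int),
            dose_fraction=self.dose_fraction[rows],
            response=self.response[rows],
            Z=self.Z[idx],
            z_names=list(self.z_names),
            X=self.X[idx],
            gene_names=list(self.gene_names),
            annotations=self.annotations.iloc[idx].reset_index(drop=True),
            codebook=self.codebook,
            expression_raw=self.expression_raw,
            expr_mean=self.expr_mean,
            expr_std=self.expr_std,
        )

    # ---- serialization ----------------------------------------------------
    def to_json(self, path) -> None:
        """Serialize the panel to a single JSON file (bit-exact round trip)."""
        payload = {
            "unit_ids": self.unit_ids.tolist(),
            "cell_line_ids": self.cell_line_ids.tolist(),
            "drug_ids": self.drug_ids.tolist(),
            "unit_index": self.unit_index.tolist(),
            "dose_fraction": self.dose_fraction.tolist(),
            "response": self.response.tolist(),
            "Z": self.Z.tolist(),
            "z_names": self.z_names,
            "X": self.X.tolist(),
            "gene_names": self.gene_names,
            "annotations": self.annotations.to_dict(orient="list"),
            "codebook": self.codebook.to_dict(),
            "expression_raw": None if self.expression_raw is None else {
                "index": self.expression_raw.index.tolist(),
                "columns": self.expression_raw.columns.tolist(),
                "values": self.expression_raw.to_numpy().tolist(),
            },
            "expr_mean": None if self.expr_mean is None else self.expr_mean.tolist(),
            "expr_std": None if self.expr_std is None else self.expr_std.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "DoseResponsePanel":
        with open(path) as fh:
            d = json.load(fh)
        raw = d["expression_raw"]
        return cls(
            unit_ids=np.array(d["unit_ids"], dtype=object),
            cell_line_ids=np.array(d["cell_line_ids"], dtype=object),
            drug_ids=np.array(d["drug_ids"], dtype=object),
            unit_index=np.array(d["unit_index"], dtype=int),
            dose_fraction=np.array(d["dose_fraction"], dtype=float),
            response=np.array(d["response"], dtype=float),
            Z=np.array(d["Z"], dtype=float),
            z_names=list(d["z_names"]),
            X=np.array(d["X"], dtype=float),
            gene_names=list(d["gene_names"]),
            annotations=pd.DataFrame(d["annotations"]),
            codebook=CovariateCodebook.from_dict(d["codebook"]),
            expression_raw=None if raw is None else pd.DataFrame(
                np.array(raw["values"], dtype=float), index=raw["index"], columns=raw["columns"]),
            expr_mean=None if d["expr_mean"] is None else np.array(d["expr_mean"], dtype=float),
            expr_std=None if d["expr_std"] is None else np.array(d["expr_std"], dtype=float),
        )


def standardize_expression(expression: pd.DataFrame):
    """Standardize each gene to mean 0, variance 1 across cell lines.

    Constant genes get standard deviation 1 so they standardize to 0
    rather than NaN (they carry no information either way).
    """
    vals = expression.to_numpy(dtype=float)
    mean = vals.mean(axis=0)
    std = vals.std(axis=0, ddof=0)
    std = np.where(std == 0.0, 1.0, std)
    return (vals - mean) / std, mean, std


def assemble_panel(records: pd.DataFrame, expression: pd.DataFrame,
                   annotations: pd.DataFrame | None = None,
                   codebook: CovariateCodebook | None = None,
                   factors: Sequence[str] | None = None,
                   reference: Mapping[str, object] | None = None) -> DoseResponsePanel:
    """Assemble a :class:`DoseResponsePanel` from raw long-format records.

    Parameters
    ----------
    records : DataFrame
        Columns ``unit_id, cell_line_id, drug_id, dose, max_dose,
        response, blank`` and either a ``control`` column or zero-dose
        rows (``dose == 0``) supplying the zero-dose control response.
    expression : DataFrame
        Cell lines (index) x genes (columns), raw continuous values.
    annotations : DataFrame, optional
        Per cell line (index) annotation columns (tissue, mutation
        flags, ...) joined onto units.
    codebook : CovariateCodebook, optional
        Covariate coding; built from the data when omitted (drug plus
        every annotation column, sorted levels, first level reference
        unless ``reference`` overrides).

    Notes
    -----
    Zero-dose rows are consumed as controls only and never become
    regression rows; units with fewer than two positive doses, or with
    a control at or below the blank, are excluded with a warning.
    """
    req = {"unit_id", "cell_line_id", "drug_id", "dose", "max_dose", "response", "blank"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"records table missing columns: {sorted(missing)}")

    units, cells, drugs = [], [], []
    doses_per_unit, y_per_unit = [], []
    dropped: list[tuple[object, str]] = []
    for uid, grp in records.groupby("unit_id", sort=True):
        cell = grp["cell_line_id"].iloc[0]
        drug = grp["drug_id"].iloc[0]
        blank = float(grp["blank"].iloc[0])
        zero = grp[grp["dose"] <= 0]
        if "control" in grp.columns and grp["control"].notna().any():
            control = float(grp["control"].dropna().iloc[0])
        elif len(zero):
            control = float(zero["response"].iloc[0])
        else:
            dropped.append((uid, "no zero-dose control"))
            continue
        grp = grp[grp["dose"] > 0]
        if len(grp) < 2:
            dropped.append((uid, "fewer than 2 positive doses"))
            continue
        if control <= blank:
            dropped.append((uid, "control at or below blank"))
            continue
        d = rescale_dose(grp["dose"].to_numpy(float), grp["max_dose"].to_numpy(float))
        y = normalize_response(grp["response"].to_numpy(float), blank, control)
        order = np.argsort(d)
        d, y = d[order], y[order]
        if len(np.unique(d)) != len(d):
            dropped.append((uid, "duplicate dose fractions"))
            continue
        units.append(uid)
        cells.append(cell)
        drugs.append(drug)
        doses_per_unit.append(d)
        y_per_unit.append(y)

    if dropped:
        warnings.warn(f"excluded {len(dropped)} unit(s): {dropped[:5]}{'...' if len(dropped) > 5 else ''}")
    if not units:
        raise ValueError("no valid units after assembly")

    missing_cells = sorted({c for c in cells if c not in expression.index})
    if missing_cells:
        raise KeyError(f"cell line(s) missing from expression matrix: {missing_cells[:5]}")

    X_std, mean, std = standardize_expression(expression)
    expr_std_df = pd.DataFrame(X_std, index=expression.index, columns=expression.columns)
    X = expr_std_df.loc[cells].to_numpy(float)

    annot = pd.DataFrame({"drug": drugs})
    if annotations is not None:
        joined = annotations.loc[cells].reset_index(drop=True)
        annot = pd.concat([annot, joined], axis=1)
    if codebook is None:
        codebook = CovariateCodebook.from_annotations(annot, factors=factors, reference=reference)
    Z = codebook.encode(annot)

    return DoseResponsePanel(
        unit_ids=np.array(units, dtype=object),
        cell_line_ids=np.array(cells, dtype=object),
        drug_ids=np.array(drugs, dtype=object),
        unit_index=np.repeat(np.arange(len(units)), [len(d) for d in doses_per_unit]),
        dose_fraction=np.concatenate(doses_per_unit),
        response=np.concatenate(y_per_unit),
        Z=Z,
        z_names=codebook.column_names,
        X=X,
        gene_names=list(expression.columns),
        annotations=annot,
        codebook=codebook,
        expression_raw=expression,
        expr_mean=mean,
        expr_std=std,
    )
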