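"""Shared fixtures: small hand-built and simulated panels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from dosevary import DoseVaryingCoefficientModel, SimulationDesign, simulate_panel
from dosevary.weights import WeightModel


def make_records(n_units=4, n_doses=5, seed=0, blank=1.0, control=9.0):
    """Raw long-format assay records for `n_units` units on a 4-fold series."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_units):
        cell = f"CL{i % max(2, n_units // 2):02d}"
        drug = f"drug{i % 2}"
        maxd = 10.0
        for j in range(n_doses):
            dose = maxd * 4.0 ** -(n_doses - 1 - j)
            resp = blank + (control - blank) * (1.0 - 0.5 * dose / maxd) + rng.normal(0, 0.1)
            rows.append(dict(unit_id=f"u{i:02d}", cell_line_id=cell, drug_id=drug,
                             dose=dose, max_dose=maxd, response=resp,
                             blank=blank, control=control))
    return pd.DataFrame(rows)


def make_expression(cells, n_genes=10, seed=1):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.uniform(4, 10, size=(len(cells), n_genes)),
                        index=cells, columns=[f"g{k}" for k in range(n_genes)])


@pytest.fixture(scope="session")
def tiny_panel():
    """4 units x 5 doses, 10 genes."""
    from dosevary import assemble_panel
    rec = make_records()
    expr = make_expression(sorted(rec["cell_line_id"].unique()))
    annot = pd.DataFrame({"tissue": ["skin", "lung"]},
                         index=sorted(rec["cell_line_id"].unique()))
    return assemble_panel(rec, expr, annot)


@pytest.fixture(scope="session")
def sim_small():
    """Simulated panel small enough for repeated fitting in tests."""
    design = SimulationDesign(n_units=60, n_genes=30, n_active=3)
    return simulate_panel(design, seed=7)


@pytest.fixture(scope="session")
def sim_small_model(sim_small):
    panel, _ = sim_small
    return DoseVaryingCoefficientModel(panel, correlation="rational_quadratic")


@pytest.fixture(scope="session")
def identity_weights(sim_small_model):
    return WeightModel.identity(sim_small_model.basis)
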