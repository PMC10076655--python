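"""Shared fixtures: small synthetic layouts, cell tables and cohorts.

Everything is generated programmatically with fixed seeds; nothing is read
from disk except what the tests themselves write to tmp_path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tilquant.synthetic import (
    SyntheticCohortParams,
    generate_cohort,
    sample_cells,
    sample_core_geometry,
)


@pytest.fixture(scope="session")
def small_params() -> SyntheticCohortParams:
    return SyntheticCohortParams(seed=7)


@pytest.fixture(scope="session")
def layout(small_params):
    rng = np.random.default_rng(11)
    return sample_core_geometry(small_params, rng, core_id="core-1")


@pytest.fixture(scope="session")
def polemut_cells(small_params, layout) -> pd.DataFrame:
    rng = np.random.default_rng(12)
    return sample_cells(layout, "POLEmut", small_params, rng, case_id="POLEmut-001")


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two cases per TCGA group, two cores each: bookkeeping-scale cohort."""
    params = SyntheticCohortParams(
        seed=21,
        n_cases_per_group={"POLEmut": 2, "MMRdef": 2, "NSMP": 2, "p53abn": 2},
        cores_per_case=2,
    )
    tables, cohort, layouts = generate_cohort(params)
    return params, tables, cohort, layouts


def make_cell(
    dapi=120.0,
    area=30.0,
    cd3=(8.0, 20.0),
    cd8=(8.0, 20.0),
    panck=10.0,
    x=10.0,
    y=10.0,
) -> dict:
    """Hand-built single-cell feature dict on the 8-bit scale."""
    return {
        "core_id": "c",
        "case_id": "k",
        "x_um": x,
        "y_um": y,
        "nucleus_area_um2": area,
        "nucleus_mean_dapi": dapi,
        "cyto_mean_cd3": cd3[0],
        "cyto_max_cd3": cd3[1],
        "cyto_mean_cd8": cd8[0],
        "cyto_max_cd8": cd8[1],
        "cyto_mean_panck": panck,
        "cyto_max_panck": panck * 1.4,
    }
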