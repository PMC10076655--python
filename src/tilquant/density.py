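"""Per-core and per-case lymphocyte density profiles.

A *region density* is the count of marker-positive cells in one compartment
of one core divided by that compartment's area in mm².  Compartments flagged
excluded (below the minimum-area rule) contribute neither counts nor area:
their densities are missing, and the "total" region is the sum of retained
compartments only.  Per case, densities are aggregated as the unweighted
mean across the cores in which the region is present.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import CD3_POSITIVE, CD8_POSITIVE, COMPARTMENTS, MARKERS, REGIONS
from .spatial import CompartmentMap

_POSITIVE_SETS = {"CD3": set(CD3_POSITIVE), "CD8": set(CD8_POSITIVE)}


def core_region_densities(cells: pd.DataFrame, cmap: CompartmentMap,
                          area_weighted_total: bool = True) -> pd.DataFrame:
    """Marker counts, areas and densities per compartment for one core.

    ``cells`` must carry ``phenotype`` and ``compartment``.  CD3 counts all
    CD3-positive cells irrespective of CD8 status; CD8 counts double
    positives plus CD3-negative CD8-positives.  Returns a long-format frame
    with columns ``core_id, case_id, marker, region, count, area_mm2,
    density_per_mm2, pct_of_cells, pct_of_nontumor`` (densities missing for
    excluded regions).
    """
    if cells["phenotype"].isna().any():
        raise ValueError("cells must be phenotyped before density computation")
    if cells["compartment"].isna().any():
        raise ValueError("cells must carry compartment labels")
    unknown = set(cells["compartment"].dropna()) - set(COMPARTMENTS)
    if unknown:
        raise ValueError(f"cells reference unknown region(s): {sorted(unknown)}")

    case_id = cells["case_id"].iloc[0] if len(cells) else ""
    retained = [r for r in COMPARTMENTS if r not in cmap.excluded]
    rows = []
    for marker in MARKERS:
        positive = cells["phenotype"].isin(_POSITIVE_SETS[marker])
        nucleated = ~cells["phenotype"].isin(["Artifact"])
        nontumor = nucleated & ~cells["phenotype"].isin(["Tumor"])
        for region in REGIONS:
            if region == "total":
                count = int((positive & cells["compartment"].isin(retained)).sum())
                area = float(sum(cmap.areas_mm2[r] for r in retained))
                n_all = int((nucleated & cells["compartment"].isin(retained)).sum())
                n_nt = int((nontumor & cells["compartment"].isin(retained)).sum())
                present = len(retained) > 0
            else:
                in_region = cells["compartment"] == region
                count = int((positive & in_region).sum())
                area = float(cmap.areas_mm2[region])
                n_all = int((nucleated & in_region).sum())
                n_nt = int((nontumor & in_region).sum())
                present = region not in cmap.excluded
            if present and area > 0:
                density = count / area
            else:
                count, area, density = (np.nan, np.nan, np.nan)
                n_all = n_nt = 0
            rows.append(
                {
                    "core_id": cmap.core_id,
                    "case_id": case_id,
                    "marker": marker,
                    "region": region,
                    "count": count,
                    "area_mm2": area,
                    "density_per_mm2": density,
                    "pct_of_cells": 100.0 * count / n_all if n_all else np.nan,
                    "pct_of_nontumor": 100.0 * count / n_nt if n_nt else np.nan,
                }
            )
    return pd.DataFrame(rows)


def aggregate_case(core_densities: pd.DataFrame) -> pd.DataFrame:
    """Per-case mean of per-core densities.

    The mean is unweighted over the cores in which each marker × region is
    present; regions missing from every core stay missing.  Returns one row
    per case_id × marker × region with ``mean_density_per_mm2`` and
    ``n_cores_contributing``.
    """
    if len(core_densities) == 0:
        raise ValueError("no core densities to aggregate")
    grouped = core_densities.groupby(["case_id", "marker", "region"], sort=False)
    out = grouped["density_per_mm2"].agg(
        mean_density_per_mm2="mean", n_cores_contributing="count"
    ).reset_index()
    out.loc[out["n_cores_contributing"] == 0, "mean_density_per_mm2"] = np.nan
    return out


def case_profile_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pivot long-format case profiles to one row per case with
    ``{marker}_{region}`` density columns (e.g. ``CD8_intratumoral``)."""
    wide = profiles.pivot_table(
        index="case_id",
        columns=["marker", "region"],
        values="mean_density_per_mm2",
        aggfunc="first",
    )
    wide.columns = [f"{m}_{r}" for m, r in wide.columns]
    return wide.reset_index()
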