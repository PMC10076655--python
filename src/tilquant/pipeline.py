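"""End-to-end orchestration: phenotype -> tumor mask -> zonation ->
densities -> per-case profiles.

This is the programmatic equivalent of running the CLI subcommands in
sequence on every core of a cohort.
"""

from __future__ import annotations

import pandas as pd

from .density import aggregate_case, case_profile_matrix, core_region_densities
from .phenotype import ThresholdConfig, apply_phenotyping
from .spatial import SpatialConfig, assign_compartments, build_tumor_mask, compute_compartments


def analyze_core(
    cells: pd.DataFrame,
    core_boundary,
    threshold_cfg: ThresholdConfig,
    spatial_cfg: SpatialConfig | None = None,
    tumor_mask=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run one core through phenotyping, zonation and density computation.

    Returns ``(labelled_cells, region_densities)``.  When ``tumor_mask`` is
    given it is used directly; otherwise the mask is rebuilt from the
    Tumor-phenotyped cells.
    """
    spatial_cfg = spatial_cfg or SpatialConfig()
    labelled, _ = apply_phenotyping(cells, threshold_cfg)
    core_id = str(cells["core_id"].iloc[0]) if len(cells) else "core"
    if tumor_mask is None:
        tumor = build_tumor_mask(labelled, core_boundary, spatial_cfg)
    else:
        tumor = build_tumor_mask(None, core_boundary, spatial_cfg, mask=tumor_mask)
    cmap = compute_compartments(tumor, core_boundary, spatial_cfg, core_id=core_id)
    zoned = assign_compartments(labelled, cmap)
    densities = core_region_densities(zoned, cmap)
    return zoned, densities


def analyze_cohort(
    core_tables: dict[str, pd.DataFrame],
    core_boundaries: dict,
    threshold_cfg: ThresholdConfig,
    spatial_cfg: SpatialConfig | None = None,
    tumor_masks: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyze every core of a cohort and aggregate per case.

    Returns ``(per_core_densities, per_case_profiles)`` in long format; use
    :func:`tilquant.density.case_profile_matrix` for the wide per-case view.
    """
    per_core = []
    for core_id, cells in core_tables.items():
        mask = tumor_masks.get(core_id) if tumor_masks else None
        _, dens = analyze_core(
            cells, core_boundaries[core_id], threshold_cfg, spatial_cfg, tumor_mask=mask
        )
        per_core.append(dens)
    core_densities = pd.concat(per_core, ignore_index=True)
    profiles = aggregate_case(core_densities)
    return core_densities, profiles
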