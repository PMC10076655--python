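"""Rule-based phenotyping of detected cells from per-channel intensity
features.

A cell is called positive for a marker when its nucleus/cytoplasm features
clear fixed intensity thresholds on the native scan scale.  Two shipped
threshold sets correspond to the two staining/scanning protocols supported:
an 8-bit Opal-stained panel and a 16-bit Alexa-stained panel (the latter
defines no PanCK criterion, so tumor calls are unavailable unless one is
configured).  Lymphocyte calls additionally pass an anatomical gate —
lymphocyte-sized nucleus with dense chromatin — which rejects
erythrocyte-autofluorescence artifacts that are bright in the marker
channels but carry little or no DAPI signal.

Final labels form a partition with precedence
lymphocyte > tumor > stroma > artifact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    CD3_POSITIVE,
    CD8_POSITIVE,
    IntensityScale,
    SCALE_8BIT,
    SCALE_16BIT,
)


@dataclass(frozen=True)
class MarkerThresholds:
    """Cytoplasmic intensity criteria for one marker; ``None`` = criterion
    absent (skipped, not treated as 0)."""

    cyto_mean_min: float | None = None
    cyto_max_min: float | None = None


@dataclass(frozen=True)
class ThresholdConfig:
    scale: IntensityScale
    nucleus_mean_dapi_min: float
    cd3: MarkerThresholds
    cd8: MarkerThresholds
    panck: MarkerThresholds
    #: Anatomical lymphocyte gate: maximum nucleus area for a lymphocyte call.
    lymphocyte_max_nucleus_area_um2: float = 45.0
    #: Minimum chromatin (DAPI mean) for a lymphocyte call; defaults to the
    #: DAPI validity threshold, i.e. no extra stringency unless configured.
    chromatin_min_dapi_mean: float | None = None
    #: If True, PanCK positivity outranks lymphocyte marker positivity.
    tumor_overrides_lymphocyte: bool = False

    def __post_init__(self) -> None:
        lim = self.scale.max_value
        for name, value in [
            ("nucleus_mean_dapi_min", self.nucleus_mean_dapi_min),
            ("cd3.cyto_mean_min", self.cd3.cyto_mean_min),
            ("cd3.cyto_max_min", self.cd3.cyto_max_min),
            ("cd8.cyto_mean_min", self.cd8.cyto_mean_min),
            ("cd8.cyto_max_min", self.cd8.cyto_max_min),
            ("panck.cyto_mean_min", self.panck.cyto_mean_min),
        ]:
            if value is not None and not (0 <= value <= lim):
                raise ValueError(f"threshold {name}={value} outside [0, {lim}]")

    @property
    def chromatin_min(self) -> float:
        return (
            self.nucleus_mean_dapi_min
            if self.chromatin_min_dapi_mean is None
            else self.chromatin_min_dapi_mean
        )


#: 8-bit Opal-panel thresholds (testing-cohort protocol).
THRESHOLDS_8BIT = ThresholdConfig(
    scale=SCALE_8BIT,
    nucleus_mean_dapi_min=35,
    cd3=MarkerThresholds(cyto_mean_min=36, cyto_max_min=96),
    cd8=MarkerThresholds(cyto_mean_min=33, cyto_max_min=116),
    panck=MarkerThresholds(cyto_mean_min=61),
)

#: 16-bit Alexa-panel thresholds (validation-cohort protocol); no PanCK
#: criterion is defined for this panel, so tumor calls are unavailable.
THRESHOLDS_16BIT = ThresholdConfig(
    scale=SCALE_16BIT,
    nucleus_mean_dapi_min=2364,
    cd3=MarkerThresholds(cyto_mean_min=1968, cyto_max_min=5595),
    cd8=MarkerThresholds(cyto_mean_min=1213, cyto_max_min=9161),
    panck=MarkerThresholds(),
)

_REQUIRED_FEATURES = (
    "nucleus_mean_dapi",
    "nucleus_area_um2",
    "cyto_mean_cd3",
    "cyto_max_cd3",
    "cyto_mean_cd8",
    "cyto_max_cd8",
    "cyto_mean_panck",
)


def _marker_positive(mean, mx, thr: MarkerThresholds):
    """Vectorized marker positivity; absent criteria are skipped.  NA
    features fail the criterion (treated as not positive)."""
    ok = np.ones(np.shape(mean), dtype=bool)
    if thr.cyto_mean_min is not None:
        ok &= np.nan_to_num(np.asarray(mean, dtype=float), nan=-np.inf) >= thr.cyto_mean_min
    if thr.cyto_max_min is not None:
        ok &= np.nan_to_num(np.asarray(mx, dtype=float), nan=-np.inf) >= thr.cyto_max_min
    if thr.cyto_mean_min is None and thr.cyto_max_min is None:
        ok &= False  # no criterion defined -> never positive
    return ok


def classify_cells(cells: pd.DataFrame, cfg: ThresholdConfig) -> pd.Series:
    """Vectorized phenotype assignment; returns a string Series aligned with
    ``cells`` containing one final label per cell."""
    for feat in _REQUIRED_FEATURES:
        if feat not in cells.columns:
            raise ValueError(f"missing required feature column {feat!r}")

    dapi = cells["nucleus_mean_dapi"].to_numpy(dtype=float)
    area = cells["nucleus_area_um2"].to_numpy(dtype=float)
    dapi_valid = dapi >= cfg.nucleus_mean_dapi_min

    cd3 = dapi_valid & _marker_positive(cells["cyto_mean_cd3"], cells["cyto_max_cd3"], cfg.cd3)
    cd8 = dapi_valid & _marker_positive(cells["cyto_mean_cd8"], cells["cyto_max_cd8"], cfg.cd8)
    panck_mx = cells["cyto_max_panck"] if "cyto_max_panck" in cells.columns else np.nan
    panck = dapi_valid & _marker_positive(cells["cyto_mean_panck"], panck_mx, cfg.panck)

    # Anatomical lymphocyte gate: size and chromatin density.
    lymph_gate = (area <= cfg.lymphocyte_max_nucleus_area_um2) & (dapi >= cfg.chromatin_min)
    lymph = (cd3 | cd8) & lymph_gate
    if cfg.tumor_overrides_lymphocyte:
        lymph &= ~panck

    labels = np.full(len(cells), "Artifact", dtype=object)
    stroma = dapi_valid & ~cd3 & ~cd8 & ~panck
    labels[stroma] = "Stroma"
    labels[panck & ~lymph] = "Tumor"
    labels[lymph & cd3 & ~cd8] = "CD3only"
    labels[lymph & cd3 & cd8] = "CD3CD8"
    labels[lymph & ~cd3 & cd8] = "CD8only"
    return pd.Series(labels, index=cells.index, dtype="string")


def classify_cell(cell, cfg: ThresholdConfig) -> str:
    """Phenotype a single cell (mapping or Series of features)."""
    df = pd.DataFrame([dict(cell)])
    return str(classify_cells(df, cfg).iloc[0])


def apply_phenotyping(cells: pd.DataFrame, cfg: ThresholdConfig) -> tuple[pd.DataFrame, dict]:
    """Label every cell and return (labelled table, summary counts).

    The summary reports CD3+ (all CD3-positive cells irrespective of CD8),
    CD8+ (double positives plus the rare CD3-negative CD8-positive cells),
    tumor/stroma/artifact counts and the fraction of CD8+ cells that are also
    CD3+ (co-positivity).
    """
    out = cells.copy()
    out["phenotype"] = classify_cells(cells, cfg)
    counts = out["phenotype"].value_counts()
    n_cd3 = int(counts.reindex(CD3_POSITIVE, fill_value=0).sum())
    n_cd8 = int(counts.reindex(CD8_POSITIVE, fill_value=0).sum())
    n_double = int(counts.get("CD3CD8", 0))
    summary = {
        "n_cells": int(len(out)),
        "cd3_positive": n_cd3,
        "cd8_positive": n_cd8,
        "cd3cd8_double": n_double,
        "cd8_only": int(counts.get("CD8only", 0)),
        "tumor": int(counts.get("Tumor", 0)),
        "stroma": int(counts.get("Stroma", 0)),
        "artifact": int(counts.get("Artifact", 0)),
        "cd8_in_cd3_fraction": (n_double / n_cd8) if n_cd8 else float("nan"),
    }
    return out, summary
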