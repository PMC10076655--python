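"""Readers and writers for the tabular, image and geometry artifacts of the
pipeline.

All delimited-text tables are CSV or TSV with a header line; the delimiter is
auto-detected from the first line.  Intensities are kept on their native scan
scale (8-bit or 16-bit) and never rescaled implicitly.  Coordinates are microns
from the core image top-left, y increasing downward.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml
from shapely.geometry import mapping as shapely_mapping, shape as shapely_shape
from shapely.geometry.base import BaseGeometry

from .model import (
    CELL_NUMERIC_COLUMNS,
    CELL_OPTIONAL_COLUMNS,
    CELL_REQUIRED_COLUMNS,
    CHANNELS,
    COHORT_OPTIONAL_COLUMNS,
    COHORT_REQUIRED_COLUMNS,
    COHORTS,
    COMPARTMENTS,
    PHENOTYPES,
    TCGA_GROUPS,
    IntensityScale,
    SchemaError,
    VocabularyError,
)

# Spellings accepted on input for TCGA subgroups (report-style variants
# normalised to the canonical tokens).
_TCGA_ALIASES = {
    "polemut": "POLEmut",
    "pole mut.": "POLEmut",
    "pole mut": "POLEmut",
    "pole mutated": "POLEmut",
    "mmrdef": "MMRdef",
    "mmr def.": "MMRdef",
    "mmr def": "MMRdef",
    "mmr deficient": "MMRdef",
    "nsmp": "NSMP",
    "p53abn": "p53abn",
    "p53 abn.": "p53abn",
    "p53 abn": "p53abn",
    "p53 abnormal": "p53abn",
}

_BOOL_ALIASES = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, "t": True, "f": False,
}

# Column aliases for QuPath-style detection exports.
_QUPATH_COLUMN_MAP = {
    "TMA core": "core_id",
    "Image": "core_id",
    "Centroid X µm": "x_um",
    "Centroid Y µm": "y_um",
    "Nucleus: Area": "nucleus_area_um2",
    "Nucleus: DAPI mean": "nucleus_mean_dapi",
    "Cytoplasm: CD3 mean": "cyto_mean_cd3",
    "Cytoplasm: CD3 max": "cyto_max_cd3",
    "Cytoplasm: CD8 mean": "cyto_mean_cd8",
    "Cytoplasm: CD8 max": "cyto_max_cd8",
    "Cytoplasm: PanCK mean": "cyto_mean_panck",
    "Cytoplasm: PanCK max": "cyto_max_panck",
}


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if first.count("\t") > first.count(",") else ","


def read_cell_table(path, dialect: str = "generic") -> pd.DataFrame:
    """Read a per-cell detection table.

    Parameters
    ----------
    path : str or Path
        CSV/TSV file with one row per detected cell.
    dialect : {"generic", "qupath_like"}
        ``generic`` expects the canonical column names; ``qupath_like``
        additionally maps common QuPath measurement-export headers onto them.

    Returns
    -------
    pandas.DataFrame
        Validated cell table.  Unknown columns are preserved untouched;
        missing optional ``phenotype``/``compartment`` columns are created
        empty (NA).
    """
    path = Path(path)
    if dialect not in ("generic", "qupath_like"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    if dialect == "qupath_like":
        df = df.rename(columns=_QUPATH_COLUMN_MAP)
        if "case_id" not in df.columns and "core_id" in df.columns:
            df["case_id"] = df["core_id"].astype(str).str.rsplit("-", n=1).str[0]
    missing = [c for c in CELL_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table {path} is missing required column(s): {missing}")
    for col in CELL_NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"non-numeric value in column {col!r} at row {row}: {df[col].iloc[row]!r}"
            )
        df[col] = coerced.astype(float)
    for col in ("phenotype", "compartment"):
        if col not in df.columns:
            df[col] = pd.Series(pd.NA, index=df.index, dtype="string")
        else:
            df[col] = df[col].astype("string")
    vocab = {"phenotype": PHENOTYPES, "compartment": COMPARTMENTS}
    for col, allowed in vocab.items():
        present = df[col].dropna()
        bad_vals = sorted(set(present) - set(allowed))
        if bad_vals:
            raise VocabularyError(
                f"column {col!r} contains {bad_vals}; allowed values: {list(allowed)}"
            )
    if (df["nucleus_area_um2"] <= 0).any():
        raise SchemaError("nucleus_area_um2 must be > 0 for every cell")
    if (df[["x_um", "y_um"]] < 0).any().any():
        raise SchemaError("cell coordinates must be non-negative microns")
    return df


def write_cell_table(cells: pd.DataFrame, path) -> None:
    """Write a cell table as CSV (canonical column names, full precision)."""
    ordered = [c for c in CELL_REQUIRED_COLUMNS + CELL_OPTIONAL_COLUMNS if c in cells.columns]
    extras = [c for c in cells.columns if c not in ordered]
    cells[ordered + extras].to_csv(path, index=False)


def _normalize_tcga(value: str) -> str:
    key = str(value).strip().lower()
    if key in _TCGA_ALIASES:
        return _TCGA_ALIASES[key]
    raise VocabularyError(
        f"unknown TCGA subgroup {value!r}; allowed values: {list(TCGA_GROUPS)}"
    )


def read_cohort_metadata(path) -> pd.DataFrame:
    """Read per-case cohort metadata (molecular subgroup, staging, survival).

    Categorical fields are mapped onto controlled vocabularies; unknown
    categories and duplicated case ids raise.  The invariant
    ``tcga == POLEmut  <=>  not pole_wt`` is enforced.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path))
    missing = [c for c in COHORT_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table {path} is missing required column(s): {missing}")
    if df["case_id"].duplicated().any():
        dupes = sorted(df.loc[df["case_id"].duplicated(), "case_id"].unique())
        raise SchemaError(f"duplicate case_id values: {dupes}")
    df["case_id"] = df["case_id"].astype(str)
    df["tcga"] = df["tcga"].map(_normalize_tcga)
    bad_cohort = sorted(set(df["cohort"].astype(str)) - set(COHORTS))
    if bad_cohort:
        raise VocabularyError(f"unknown cohort value(s) {bad_cohort}; allowed: {list(COHORTS)}")
    if df["pole_wt"].dtype == object:
        df["pole_wt"] = df["pole_wt"].astype(str).str.strip().str.lower().map(_BOOL_ALIASES)
        if df["pole_wt"].isna().any():
            raise VocabularyError("pole_wt must be boolean")
    df["pole_wt"] = df["pole_wt"].astype(bool)
    inconsistent = (df["tcga"] == "POLEmut") == df["pole_wt"]
    if inconsistent.any():
        cases = df.loc[inconsistent, "case_id"].tolist()
        raise SchemaError(f"pole_wt inconsistent with tcga=POLEmut for case(s): {cases}")
    for col in ("rfs_months", "os_months", "age"):
        if col in df.columns and (pd.to_numeric(df[col], errors="coerce") < 0).any():
            raise SchemaError(f"{col} must be non-negative")
    return df


def write_cohort_metadata(cohort: pd.DataFrame, path) -> None:
    ordered = [c for c in COHORT_REQUIRED_COLUMNS + COHORT_OPTIONAL_COLUMNS if c in cohort.columns]
    extras = [c for c in cohort.columns if c not in ordered]
    cohort[ordered + extras].to_csv(path, index=False)


def read_core_image(path) -> tuple[np.ndarray, IntensityScale]:
    """Read a 4-channel core TIFF.

    Returns the image as ``(4, H, W)`` in canonical channel order
    (DAPI, CD3, CD8, PanCK) plus the native :class:`IntensityScale` inferred
    from the sample format.  Channel-last files are transposed; files whose
    channel count is not 4 raise.
    """
    img = tifffile.imread(str(path))
    if img.ndim != 3:
        raise SchemaError(f"expected a 3-dimensional multichannel TIFF, got shape {img.shape}")
    if img.shape[0] == 4:
        pass
    elif img.shape[-1] == 4:
        img = np.moveaxis(img, -1, 0)
    else:
        raise SchemaError(f"expected 4 channels (DAPI, CD3, CD8, PanCK), got shape {img.shape}")
    if img.dtype == np.uint8:
        scale = IntensityScale(8)
    elif img.dtype == np.uint16:
        scale = IntensityScale(16)
    else:
        raise SchemaError(f"unsupported sample format {img.dtype}; expected uint8 or uint16")
    return img, scale


def write_core_image(image: np.ndarray, path) -> None:
    """Write a ``(4, H, W)`` uint8/uint16 image as a multichannel TIFF."""
    if image.ndim != 3 or image.shape[0] != 4:
        raise ValueError(f"expected a (4, H, W) image, got shape {image.shape}")
    tifffile.imwrite(str(path), image, photometric="minisblack", planarconfig="separate")


# --- region geometry (GeoJSON) --------------------------------------------


def write_regions_geojson(regions: Mapping[str, BaseGeometry], path,
                          properties: Mapping[str, Mapping] | None = None) -> None:
    """Write named regions (tumor mask, compartments) as a GeoJSON
    FeatureCollection in micron coordinates."""
    features = []
    for name, geom in regions.items():
        props = {"name": name}
        if properties and name in properties:
            props.update(properties[name])
        features.append(
            {"type": "Feature", "properties": props, "geometry": shapely_mapping(geom)}
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_regions_geojson(path) -> dict[str, BaseGeometry]:
    with open(path, "r", encoding="utf-8") as fh:
        collection = json.load(fh)
    regions = {}
    for feature in collection.get("features", []):
        name = feature.get("properties", {}).get("name")
        geom = shapely_shape(feature["geometry"])
        if not geom.is_valid:
            raise SchemaError(f"region {name!r} is not a valid geometry")
        regions[name] = geom
    return regions


def load_config(path) -> dict:
    """Load a YAML configuration file with one section per pipeline stage."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
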