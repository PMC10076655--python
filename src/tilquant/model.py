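"""Core vocabulary and light-weight containers shared by all pipeline stages.

The pipeline's canonical in-memory containers are plain :class:`pandas.DataFrame`
objects with documented column schemas (a *cell table* holds one detected cell
per row, a *cohort table* one case per row).  This module centralises the
column names, the controlled vocabularies and the intensity-scale bookkeeping
so that every stage validates against a single source of truth.
"""

from __future__ import annotations

from dataclasses import dataclass

# Fluorescence channels, in canonical order.
CHANNELS = ("dapi", "cd3", "cd8", "panck")

# Final, mutually exclusive phenotype labels.
PHENOTYPES = ("CD3only", "CD3CD8", "CD8only", "Tumor", "Stroma", "Artifact")

#: Phenotypes counted as CD3-positive (CD3 status irrespective of CD8).
CD3_POSITIVE = ("CD3only", "CD3CD8")
#: Phenotypes counted as CD8-positive (double positives enter as CD8+).
CD8_POSITIVE = ("CD3CD8", "CD8only")

# Tissue compartments relative to the tumor region of a core.
COMPARTMENTS = ("intratumoral", "close", "distant")
#: Compartments plus the whole-core aggregate used in per-core reports.
REGIONS = COMPARTMENTS + ("total",)

MARKERS = ("CD3", "CD8")

# TCGA molecular subgroups of endometrial carcinoma.
TCGA_GROUPS = ("POLEmut", "MMRdef", "NSMP", "p53abn")

COHORTS = ("testing", "validation")

# --- cell-table schema -----------------------------------------------------

#: Columns every cell table must carry.
CELL_REQUIRED_COLUMNS = (
    "core_id",
    "case_id",
    "x_um",
    "y_um",
    "nucleus_area_um2",
    "nucleus_mean_dapi",
    "cyto_mean_cd3",
    "cyto_max_cd3",
    "cyto_mean_cd8",
    "cyto_max_cd8",
    "cyto_mean_panck",
)

#: Optional columns; created (empty) on read when absent.
CELL_OPTIONAL_COLUMNS = (
    "nucleus_mean_cd3",
    "nucleus_mean_cd8",
    "nucleus_mean_panck",
    "cyto_max_panck",
    "phenotype",
    "compartment",
)

CELL_NUMERIC_COLUMNS = tuple(
    c
    for c in CELL_REQUIRED_COLUMNS + CELL_OPTIONAL_COLUMNS
    if c not in ("core_id", "case_id", "phenotype", "compartment")
)

# --- cohort-table schema ---------------------------------------------------

COHORT_REQUIRED_COLUMNS = ("case_id", "cohort", "tcga", "pole_wt")

COHORT_OPTIONAL_COLUMNS = (
    "histotype",
    "grade",
    "pT",
    "pN",
    "lvi",
    "vi",
    "melf",
    "age",
    "rfs_months",
    "rfs_event",
    "os_months",
    "os_event",
)


@dataclass(frozen=True)
class IntensityScale:
    """Native intensity scale of a scan (8-bit testing / 16-bit validation)."""

    bit_depth: int

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")

    @property
    def max_value(self) -> int:
        return 255 if self.bit_depth == 8 else 65535


SCALE_8BIT = IntensityScale(8)
SCALE_16BIT = IntensityScale(16)


class SchemaError(ValueError):
    """A table is missing required columns or violates the declared schema."""


class VocabularyError(ValueError):
    """A categorical value is outside its controlled vocabulary."""
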