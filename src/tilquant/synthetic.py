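"""Synthetic TMA cohorts with the statistical structure the analysis assumes.

The generator emulates circular tissue-microarray cores (1.5 mm testing-like
or 1.2 mm validation-like punches) containing lobulated tumor regions, and
populates the three tissue compartments with piecewise-homogeneous Poisson
point patterns of lymphocytes, tumor cells, stromal cells and
erythrocyte-like autofluorescence artifacts.  Per-cell intensity features are
drawn from a phenotype-conditioned model calibrated so that re-phenotyping by
the shipped threshold rules recovers the generating labels, and CD8+ cells
are CD3+ with a configurable co-positivity (default 99.81%).

Group-level density medians default to a table reflecting the published
pattern for the four TCGA subgroups: POLE-mutated tumors carry the densest
infiltrates (and uniquely high *intra-tumoral* CD8+), NSMP the sparsest,
with MMR-deficient and p53-abnormal tumors in between; within a core, CD3+
density peaks in the 50 µm close band and is lowest inside the tumor.
Survival times are exponential with group-specific hazards (POLEmut best,
p53abn worst) purely to exercise the prognostic harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import MultiPolygon, Point, Polygon
from shapely.ops import unary_union

from .model import CHANNELS, IntensityScale, TCGA_GROUPS
from .spatial import CompartmentMap, SpatialConfig, compute_compartments, core_disc

# --- default calibration ---------------------------------------------------

#: Default group x marker x region density medians (cells/mm²).  Orderings:
#: total CD3 medians POLEmut > MMRdef > p53abn > NSMP; CD3 within a core
#: close > distant > intratumoral; intra-tumoral CD8 sharply elevated in
#: POLEmut (well above the 50/mm² pretest cut-off) and lowest in p53abn.
DEFAULT_DENSITY_MEDIANS = {
    "POLEmut": {
        "CD3": {"intratumoral": 350.0, "close": 500.0, "distant": 380.0},
        "CD8": {"intratumoral": 300.0, "close": 250.0, "distant": 150.0},
    },
    "MMRdef": {
        "CD3": {"intratumoral": 150.0, "close": 280.0, "distant": 180.0},
        "CD8": {"intratumoral": 90.0, "close": 140.0, "distant": 80.0},
    },
    "p53abn": {
        "CD3": {"intratumoral": 80.0, "close": 150.0, "distant": 120.0},
        "CD8": {"intratumoral": 20.0, "close": 90.0, "distant": 60.0},
    },
    "NSMP": {
        "CD3": {"intratumoral": 60.0, "close": 150.0, "distant": 100.0},
        "CD8": {"intratumoral": 25.0, "close": 55.0, "distant": 40.0},
    },
}

#: Monthly exponential hazards for the survival harness (RFS, OS).
DEFAULT_HAZARDS = {
    "POLEmut": {"rfs": 0.0010, "os": 0.0008},
    "MMRdef": {"rfs": 0.0040, "os": 0.0030},
    "NSMP": {"rfs": 0.0050, "os": 0.0040},
    "p53abn": {"rfs": 0.0150, "os": 0.0120},
}


@dataclass(frozen=True)
class IntensityModel:
    """Phenotype-conditioned feature distributions on the 8-bit scale.

    Values are (mu, sigma, lo, hi) for clipped normals.  Clipping keeps every
    draw on the correct side of the shipped 8-bit threshold rules, so
    re-phenotyping recovers the generating label; for 16-bit output all
    intensities are multiplied by 257.
    """

    lymph_dapi: tuple = (120.0, 15.0, 60.0, 200.0)
    lymph_area: tuple = (30.0, 5.0, 12.0, 44.0)
    tumor_dapi: tuple = (100.0, 15.0, 50.0, 180.0)
    tumor_area: tuple = (75.0, 12.0, 50.0, 120.0)
    stroma_dapi: tuple = (90.0, 15.0, 45.0, 160.0)
    stroma_area: tuple = (38.0, 6.0, 15.0, 60.0)
    artifact_dapi: tuple = (12.0, 5.0, 0.0, 25.0)
    artifact_area: tuple = (25.0, 8.0, 8.0, 44.0)
    marker_pos_mean: tuple = (150.0, 15.0, 110.0, 220.0)
    marker_pos_max: tuple = (190.0, 15.0, 150.0, 255.0)
    marker_neg_mean: tuple = (8.0, 4.0, 0.0, 22.0)
    marker_neg_max: tuple = (20.0, 8.0, 0.0, 60.0)
    panck_pos_mean: tuple = (130.0, 20.0, 90.0, 220.0)
    artifact_marker_mean: tuple = (120.0, 20.0, 80.0, 200.0)


def _draw(rng: np.random.Generator, spec: tuple, n: int) -> np.ndarray:
    mu, sigma, lo, hi = spec
    return np.clip(rng.normal(mu, sigma, size=n), lo, hi)


@dataclass(frozen=True)
class SyntheticCohortParams:
    """Generator settings for one synthetic cohort.

    Defaults describe a testing-like cohort: 1.5 mm cores, six cores per
    case, a tumor occupying roughly 61% of the core area, and the default
    density-median table above with log-scale case-level dispersion 0.5 and
    core-level jitter 0.2.
    """

    n_cases_per_group: dict = field(
        default_factory=lambda: {"POLEmut": 3, "MMRdef": 19, "NSMP": 30, "p53abn": 8}
    )
    core_diameter_um: float = 1500.0
    cores_per_case: int = 6
    tumor_fraction_range: tuple = (0.52, 0.68)
    density_medians: dict = field(default_factory=lambda: DEFAULT_DENSITY_MEDIANS)
    density_dispersion: float = 0.5
    core_jitter: float = 0.2
    cd8_in_cd3_copositivity: float = 0.9981
    tumor_cell_density_per_mm2: float = 800.0
    stroma_cell_density_per_mm2: float = 400.0
    artifact_fraction: float = 0.02
    n_stroma_blobs: int = 20
    stroma_blob_radius_um: tuple = (70.0, 130.0)
    intensity_model: IntensityModel = field(default_factory=IntensityModel)
    bit_depth: int = 8
    spatial: SpatialConfig = field(default_factory=SpatialConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.cd8_in_cd3_copositivity <= 1.0):
            raise ValueError("copositivity must be in [0, 1]")
        lo, hi = self.tumor_fraction_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("tumor_fraction_range must lie in (0, 1]")
        for g, table in self.density_medians.items():
            for marker, regions in table.items():
                for region, v in regions.items():
                    if v < 0:
                        raise ValueError(f"negative density median for {g}/{marker}/{region}")

    @property
    def scale(self) -> IntensityScale:
        return IntensityScale(self.bit_depth)

    @property
    def intensity_factor(self) -> float:
        return 1.0 if self.bit_depth == 8 else 257.0


@dataclass
class CoreLayout:
    core_id: str
    core: Polygon
    tumor: Polygon | MultiPolygon
    compartments: CompartmentMap


# --- geometry --------------------------------------------------------------


def sample_core_geometry(
    params: SyntheticCohortParams, rng: np.random.Generator, core_id: str = "core"
) -> CoreLayout:
    """Sample a core disc whose tumor region is the disc minus a set of
    stromal blobs.

    Carcinoma cores are mostly epithelial nests interleaved with stromal
    channels, so the generator subtracts random stromal disks from the core
    and rescales their radii (bisection) until the realized tumor-area
    fraction matches a target drawn from ``tumor_fraction_range``.  With the
    default blob geometry a 61% tumor fraction reproduces roughly the
    61/24/15 intratumoral/close/distant split typical of tumor-center
    punches.  Raises after bounded retries if the fraction cannot be
    realized.
    """
    r = params.core_diameter_um / 2.0
    disc = core_disc(params.core_diameter_um)
    target = rng.uniform(*params.tumor_fraction_range)
    lo_r, hi_r = params.stroma_blob_radius_um
    for _ in range(8):
        centers = []
        while len(centers) < params.n_stroma_blobs:
            x, y = rng.uniform(0, 2 * r, size=2)
            if (x - r) ** 2 + (y - r) ** 2 <= r**2:
                centers.append((x, y))
        radii = rng.uniform(lo_r, hi_r, size=params.n_stroma_blobs)

        def stroma(mult: float):
            return unary_union(
                [Point(c).buffer(rad * mult, quad_segs=24) for c, rad in zip(centers, radii)]
            )

        def frac(mult: float) -> float:
            return disc.difference(stroma(mult)).area / disc.area

        lo_m, hi_m = 0.01, 8.0
        if frac(hi_m) > target or frac(lo_m) < target:
            continue  # target unreachable with this blob draw
        for _ in range(44):
            mid = 0.5 * (lo_m + hi_m)
            if frac(mid) > target:
                lo_m = mid
            else:
                hi_m = mid
        tumor = disc.difference(stroma(lo_m))
        realized = tumor.area / disc.area
        if abs(realized - target) <= 0.01 or (
            params.tumor_fraction_range[0] <= realized <= params.tumor_fraction_range[1]
        ):
            cmap = compute_compartments(tumor, disc, params.spatial, core_id=core_id)
            return CoreLayout(core_id=core_id, core=disc, tumor=tumor, compartments=cmap)
    raise RuntimeError(
        f"could not realize tumor fraction in {params.tumor_fraction_range} "
        f"after bounded retries"
    )


def _sample_points_in(geom, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside a polygonal region (rejection from its bbox)."""
    if n == 0 or geom.is_empty:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = geom.bounds
    frac = max(geom.area / ((maxx - minx) * (maxy - miny)), 1e-3)
    pts = []
    need = n
    while need > 0:
        m = int(need / frac * 1.3) + 16
        xs = rng.uniform(minx, maxx, size=m)
        ys = rng.uniform(miny, maxy, size=m)
        keep = shapely.contains_xy(geom, xs, ys)
        got = np.column_stack([xs[keep], ys[keep]])
        pts.append(got[:need])
        need -= len(got[:need])
    return np.concatenate(pts, axis=0)


# --- cells -----------------------------------------------------------------


def _sample_features(
    phenotypes: np.ndarray, params: SyntheticCohortParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw nucleus/cytoplasm features conditioned on phenotype labels."""
    m = params.intensity_model
    n = len(phenotypes)
    ph = pd.Series(phenotypes)
    is_lymph = ph.isin(["CD3only", "CD3CD8", "CD8only"]).to_numpy()
    is_tumor = (ph == "Tumor").to_numpy()
    is_stroma = (ph == "Stroma").to_numpy()
    is_artifact = (ph == "Artifact").to_numpy()
    cd3_pos = ph.isin(["CD3only", "CD3CD8"]).to_numpy()
    cd8_pos = ph.isin(["CD3CD8", "CD8only"]).to_numpy()

    dapi = np.empty(n)
    area = np.empty(n)
    for mask, dspec, aspec in [
        (is_lymph, m.lymph_dapi, m.lymph_area),
        (is_tumor, m.tumor_dapi, m.tumor_area),
        (is_stroma, m.stroma_dapi, m.stroma_area),
        (is_artifact, m.artifact_dapi, m.artifact_area),
    ]:
        k = int(mask.sum())
        dapi[mask] = _draw(rng, dspec, k)
        area[mask] = _draw(rng, aspec, k)

    def marker(pos_mask: np.ndarray, artifact_bright: bool) -> tuple[np.ndarray, np.ndarray]:
        mean = _draw(rng, m.marker_neg_mean, n)
        mx = _draw(rng, m.marker_neg_max, n)
        k = int(pos_mask.sum())
        mean[pos_mask] = _draw(rng, m.marker_pos_mean, k)
        mx[pos_mask] = _draw(rng, m.marker_pos_max, k)
        if artifact_bright:
            k = int(is_artifact.sum())
            mean[is_artifact] = _draw(rng, m.artifact_marker_mean, k)
            mx[is_artifact] = np.clip(mean[is_artifact] * 1.5, 0, 255)
        return mean, mx

    cd3_mean, cd3_max = marker(cd3_pos, artifact_bright=True)
    cd8_mean, cd8_max = marker(cd8_pos, artifact_bright=False)
    panck_mean = _draw(rng, m.marker_neg_mean, n)
    panck_mean[is_tumor] = _draw(rng, m.panck_pos_mean, int(is_tumor.sum()))
    panck_mean[is_artifact] = _draw(rng, m.artifact_marker_mean, int(is_artifact.sum()))
    panck_max = np.clip(panck_mean * 1.4, 0, 255)

    f = params.intensity_factor
    return pd.DataFrame(
        {
            "nucleus_area_um2": area,
            "nucleus_mean_dapi": dapi * f,
            "cyto_mean_cd3": cd3_mean * f,
            "cyto_max_cd3": cd3_max * f,
            "cyto_mean_cd8": cd8_mean * f,
            "cyto_max_cd8": cd8_max * f,
            "cyto_mean_panck": panck_mean * f,
            "cyto_max_panck": panck_max * f,
        }
    )


def sample_cells(
    layout: CoreLayout,
    group: str,
    params: SyntheticCohortParams,
    rng: np.random.Generator,
    case_id: str = "case",
    case_multiplier: float = 1.0,
) -> pd.DataFrame:
    """Sample one core's cell table for a given TCGA subgroup.

    Lymphocytes follow a homogeneous Poisson process per compartment at the
    group/marker/region median rate scaled by the case-level multiplier and a
    per-core log-normal jitter; CD8+ status is thinned from the CD3/CD8 rates
    so the configured co-positivity holds in expectation.  Tumor cells are
    confined to the tumor region; stromal cells populate the close and
    distant compartments; erythrocyte-like artifacts land anywhere in the
    disc at ``artifact_fraction`` of the nucleated count.
    """
    if group not in TCGA_GROUPS:
        raise ValueError(f"unknown TCGA group {group!r}")
    cmap = layout.compartments
    medians = params.density_medians[group]
    jitter = float(np.exp(rng.normal(0.0, params.core_jitter))) if params.core_jitter else 1.0
    mult = case_multiplier * jitter

    rows_xy, rows_ph, rows_comp = [], [], []

    for region in ("intratumoral", "close", "distant"):
        geom = cmap.regions[region]
        area_mm2 = cmap.areas_mm2[region]
        if area_mm2 <= 0:
            continue
        lam_cd3 = medians["CD3"][region] * mult
        lam_cd8 = medians["CD8"][region] * mult
        copos = params.cd8_in_cd3_copositivity
        lam = {
            "CD3CD8": lam_cd8 * copos,
            "CD8only": lam_cd8 * (1.0 - copos),
            "CD3only": max(lam_cd3 - lam_cd8 * copos, 0.0),
        }
        for ph, rate in lam.items():
            k = int(rng.poisson(rate * area_mm2))
            if k:
                rows_xy.append(_sample_points_in(geom, k, rng))
                rows_ph += [ph] * k
                rows_comp += [region] * k
        if region == "intratumoral":
            k = int(rng.poisson(params.tumor_cell_density_per_mm2 * area_mm2))
            if k:
                rows_xy.append(_sample_points_in(geom, k, rng))
                rows_ph += ["Tumor"] * k
                rows_comp += [region] * k
        else:
            k = int(rng.poisson(params.stroma_cell_density_per_mm2 * area_mm2))
            if k:
                rows_xy.append(_sample_points_in(geom, k, rng))
                rows_ph += ["Stroma"] * k
                rows_comp += [region] * k

    n_nucleated = len(rows_ph)
    k_art = int(rng.poisson(params.artifact_fraction * n_nucleated))
    if k_art:
        art_xy = _sample_points_in(layout.core, k_art, rng)
        art_comp = [
            _compartment_of(x, y, cmap) for x, y in art_xy
        ]
        rows_xy.append(art_xy)
        rows_ph += ["Artifact"] * k_art
        rows_comp += art_comp

    if rows_ph:
        xy = np.concatenate(rows_xy, axis=0)
    else:
        xy = np.empty((0, 2))
    cells = pd.DataFrame({"x_um": xy[:, 0], "y_um": xy[:, 1]})
    cells.insert(0, "case_id", case_id)
    cells.insert(0, "core_id", layout.core_id)
    features = _sample_features(np.asarray(rows_ph, dtype=object), params, rng)
    cells = pd.concat([cells.reset_index(drop=True), features.reset_index(drop=True)], axis=1)
    cells["phenotype"] = pd.Series(rows_ph, dtype="string")
    cells["compartment"] = pd.Series(rows_comp, dtype="string")
    return cells


def _compartment_of(x: float, y: float, cmap: CompartmentMap) -> str:
    from .spatial import assign_compartment

    return assign_compartment(x, y, cmap)


# --- rendering -------------------------------------------------------------


def render_core_image(
    cells: pd.DataFrame,
    layout: CoreLayout,
    params: SyntheticCohortParams,
    rng: np.random.Generator,
    pixel_size_um: float = 1.0,
) -> np.ndarray:
    """Render a 4-channel fluorescence-like image of a core.

    Nuclei are painted as disks in DAPI at each cell's DAPI feature value
    (lightly blurred to a soft profile); marker channels paint cytoplasmic
    annuli at bright positive or dim negative levels matching the cell's
    features; erythrocyte-like artifacts are bright blobs in the CD3 and
    PanCK channels with almost no DAPI.  Output is uint8/uint16 ``(4, H, W)``
    with mild background noise.
    """
    px = pixel_size_um
    size = int(np.ceil(layout.core.bounds[3] / px)) + 1
    img = np.zeros((len(CHANNELS), size, size), dtype=np.float64)
    yy, xx = np.mgrid[0:size, 0:size]

    def paint_disk(channel: int, cx: float, cy: float, radius_um: float, value: float):
        r_px = max(radius_um / px, 1.0)
        ci, cj = cy / px, cx / px
        j0, j1 = max(int(cj - r_px) - 1, 0), min(int(cj + r_px) + 2, size)
        i0, i1 = max(int(ci - r_px) - 1, 0), min(int(ci + r_px) + 2, size)
        sub = (xx[i0:i1, j0:j1] - cj) ** 2 + (yy[i0:i1, j0:j1] - ci) ** 2 <= r_px**2
        region = img[channel, i0:i1, j0:j1]
        np.maximum(region, np.where(sub, value, 0.0), out=region)

    def paint_ring(channel: int, cx: float, cy: float, r_in_um: float, r_out_um: float,
                   value: float):
        r_in, r_out = r_in_um / px, max(r_out_um / px, r_in_um / px + 1.0)
        ci, cj = cy / px, cx / px
        j0, j1 = max(int(cj - r_out) - 1, 0), min(int(cj + r_out) + 2, size)
        i0, i1 = max(int(ci - r_out) - 1, 0), min(int(ci + r_out) + 2, size)
        d2 = (xx[i0:i1, j0:j1] - cj) ** 2 + (yy[i0:i1, j0:j1] - ci) ** 2
        sub = (d2 <= r_out**2) & (d2 >= (0.5 * r_in) ** 2)
        region = img[channel, i0:i1, j0:j1]
        np.maximum(region, np.where(sub, value, 0.0), out=region)

    f = params.intensity_factor
    for row in cells.itertuples():
        r_nuc = float(np.sqrt(row.nucleus_area_um2 / np.pi))
        ph = row.phenotype
        if ph == "Artifact":
            paint_disk(0, row.x_um, row.y_um, r_nuc, row.nucleus_mean_dapi / f)
            paint_disk(1, row.x_um, row.y_um, r_nuc + 1.5, row.cyto_mean_cd3 / f)
            paint_disk(3, row.x_um, row.y_um, r_nuc + 1.5, row.cyto_mean_panck / f)
            continue
        # slight over-painting compensates edge dilution after blurring
        paint_disk(0, row.x_um, row.y_um, r_nuc, min(row.nucleus_mean_dapi / f * 1.25, 255))
        ring = (r_nuc, r_nuc + 2.5)
        paint_ring(1, row.x_um, row.y_um, *ring, row.cyto_max_cd3 / f * 0.95)
        paint_ring(2, row.x_um, row.y_um, *ring, row.cyto_max_cd8 / f * 0.95)
        paint_ring(3, row.x_um, row.y_um, *ring, row.cyto_mean_panck / f * 1.1)

    img[0] = ndimage.gaussian_filter(img[0], sigma=0.7 / px)
    noise = rng.normal(2.0, 1.0, size=img.shape).clip(0, 6)
    img = np.clip(img + noise, 0, 255)
    if params.bit_depth == 8:
        return img.astype(np.uint8)
    return (img * 257.0).clip(0, 65535).astype(np.uint16)


# --- cohort ----------------------------------------------------------------


def generate_cohort(
    params: SyntheticCohortParams,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, dict[str, CoreLayout]]:
    """Generate a full synthetic cohort.

    Returns ``(core_tables, cohort_metadata, layouts)``: one cell table and
    one :class:`CoreLayout` per core, plus per-case metadata with molecular
    subgroup, POLE status and exponential survival fields.
    """
    rng = np.random.default_rng(params.seed)
    core_tables: dict[str, pd.DataFrame] = {}
    layouts: dict[str, CoreLayout] = {}
    meta_rows = []
    cohort_name = "testing" if params.core_diameter_um >= 1350 else "validation"
    for group in TCGA_GROUPS:
        n_cases = params.n_cases_per_group.get(group, 0)
        for i in range(n_cases):
            case_id = f"{group}-{i + 1:03d}"
            case_mult = (
                float(np.exp(rng.normal(0.0, params.density_dispersion)))
                if params.density_dispersion
                else 1.0
            )
            for j in range(params.cores_per_case):
                core_id = f"{case_id}-c{j + 1}"
                layout = sample_core_geometry(params, rng, core_id=core_id)
                layouts[core_id] = layout
                core_tables[core_id] = sample_cells(
                    layout, group, params, rng, case_id=case_id, case_multiplier=case_mult
                )
            hz = DEFAULT_HAZARDS[group]
            censor = rng.uniform(60.0, 120.0)
            rfs_t = rng.exponential(1.0 / hz["rfs"])
            os_t = rng.exponential(1.0 / hz["os"])
            meta_rows.append(
                {
                    "case_id": case_id,
                    "cohort": cohort_name,
                    "tcga": group,
                    "pole_wt": group != "POLEmut",
                    "age": int(rng.integers(45, 85)),
                    "rfs_months": round(min(rfs_t, censor), 1),
                    "rfs_event": int(rfs_t <= censor),
                    "os_months": round(min(os_t, censor), 1),
                    "os_event": int(os_t <= censor),
                }
            )
    cohort = pd.DataFrame(meta_rows)
    return core_tables, cohort, layouts
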