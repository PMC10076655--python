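# Methods

This note describes, in the package's own terms, every computational
method implemented in `tilquant`.

## 1. Input data model

The pipeline operates on three artifact types (`tilquant.io`):

- **Cell tables** (CSV/TSV, delimiter auto-detected): one row per
  detected cell with micron coordinates (`x_um`, `y_um`), nucleus area
  and mean DAPI intensity, and cytoplasmic mean/max intensities per
  marker channel (CD3, CD8, PanCK).  Intensities stay on the native scan
  scale (8-bit: 0–255, or 16-bit: 0–65535) and are never rescaled
  implicitly.  A `qupath_like` dialect maps common detection-export
  headers onto the canonical names.
- **Cohort metadata**: one row per case with molecular subgroup
  (POLEmut / MMRdef / NSMP / p53abn, report-style spellings normalized),
  a `pole_wt` flag (consistency with the subgroup is enforced) and
  optional survival fields.
- **Core images**: 4-channel TIFFs (DAPI, CD3, CD8, PanCK), channel-first
  or channel-last, uint8 or uint16.

## 2. Image analysis

*Auto-thresholding* (`tilquant.imaging`).  Two classic histogram methods:
the **mean** threshold (the rounded intensity-weighted mean gray level)
and the **maximum-entropy** (Kapur) threshold — the gray level `t`
maximizing the sum of Shannon entropies of the two normalized class
histograms (levels ≤ t vs > t), ties broken toward the lower `t`.  The
implementation is vectorized over candidate thresholds via cumulative
sums and is verified against a naive exhaustive search.

*Nucleus detection.*  A standard watershed recipe on the DAPI channel:
Gaussian smoothing (σ = 1 µm), global foreground threshold (background
≤ t, foreground > t), Euclidean distance transform, local-maxima seeds
separated by ≥ 4 µm, seeded watershed, then a refinement step that takes
each object's boundary at its half-peak contour.  The refinement step
matters because a global signal/background threshold also captures the
blur halo around each nucleus; cutting at half of the object's own peak
keeps measured areas faithful to the underlying nucleus regardless of how
low the global threshold sits.  Objects outside 7–250 µm² are discarded.

*Feature measurement.*  Per nucleus: the mean intensity of every channel
over the nucleus pixels, plus cytoplasmic mean and max over a 2 µm
annulus obtained by label expansion, so annuli are clipped against
neighboring cells and never overlap.

## 3. Phenotyping

Cells are classified by inclusive intensity thresholds
(`tilquant.phenotype`).  The shipped 8-bit rule set requires nucleus DAPI
mean ≥ 35 for any nucleated call; CD3 positivity requires cytoplasmic
mean ≥ 36 **and** max ≥ 96; CD8 positivity mean ≥ 33 and max ≥ 116;
tumor cells require PanCK mean ≥ 61.  The 16-bit rule set uses
native-scale analogues (nucleus ≥ 2364; CD3 1968/5595; CD8 1213/9161) and
defines **no** PanCK criterion — absent criteria are skipped, not treated
as zero, so the 16-bit rules never call Tumor.  Precedence: lymphocyte
calls (CD3/CD8-positive with a lymphocyte-sized nucleus ≤ 45 µm²) beat
Tumor, then Stroma; marker-bright cells with a dim or oversized nucleus
are Artifacts (e.g. erythrocyte autofluorescence).  CD8 positivity is
expected to be almost entirely a subset of CD3 positivity; the residual
CD8-only fraction is still counted as CD8+.

## 4. Spatial zonation

All geometry is vector-based (shapely polygons, micron coordinates).  A
tumor mask is built as the union of 25 µm disks around Tumor-phenotyped
cells, morphologically closed (±30 µm buffer) and clipped to the core
disc; a precomputed mask can be supplied instead.  The core is split into
three compartments: **intratumoral** (inside the mask, boundary
inclusive), **close** (outside, within ≤ 50 µm of the boundary — the
boundary band is inclusive at exactly 50 µm), and **distant** (beyond).
Regions smaller than 0.01 mm² (including absent regions) are flagged
excluded and yield missing — never inflated — densities.  Point
assignment is vectorized and verified against a 1 µm rasterized
distance-transform brute force.

## 5. Densities and per-case profiles

Per core and compartment, cell counts for CD3+ (CD3only + CD3CD8) and
CD8+ (CD3CD8 + CD8only) are divided by the compartment area (cells/mm²);
a `total` row pools counts and areas over retained compartments.
Per-case profiles are unweighted means over the cores contributing a
non-missing value for each marker × region; the wide profile matrix has
one `{marker}_{region}` column per combination (e.g. `CD8_intratumoral`).

## 6. The POLE wild-type pretest

A case with mean intra-tumoral CD8+ density strictly below 50 cells/mm²
is predicted *POLE* wild-type; at or above the cut-off it remains a
sequencing candidate; a missing density is indeterminate and fails safe
toward sequencing.  Diagnostic convention: the positive event is a
POLE-mutated case retained for sequencing, so sensitivity is the fraction
of POLEmut cases retained and specificity the fraction of wild-type cases
screened out.  Reported alongside: the fraction of all cases spared
sequencing, and the POLEmut yield of sequencing before (prevalence) and
after preselection.  ROC analysis treats POLEmut as the positive class
with density as the score; AUC is the trapezoidal area (equal to the
Mann–Whitney U statistic divided by n₁·n₂) and two data-driven cut-offs
are reported — the largest cut-off retaining every POLEmut case
(max-specificity-at-full-sensitivity, the default criterion) and the
Youden-optimal cut-off.

## 7. Cohort statistics

Density distributions are heavily skewed, so group comparisons are
nonparametric: Mann–Whitney U for two groups; Kruskal–Wallis for more,
followed by pairwise post-hoc tests (two-sample median test by default,
rank-based alternative by flag) with Bonferroni adjustment
`p_adj = min(1, m·p)`.  Method agreement uses tie-corrected Spearman rank
correlation.  Survival uses Kaplan–Meier curves per group with the
k-group log-rank test; the first-pass prognostic grouping dichotomizes a
density at its pooled median.

## 8. Synthetic cohort generator

Each core is a disc (default 1.5 mm diameter) whose tumor region is the
disc minus a union of ~20 stromal blobs (radii 70–130 µm); the blob radii
are scaled by bisection until the tumor fraction hits a target drawn from
0.52–0.68, which reproduces a realistic intratumoral/close/distant area
split of roughly 61/24/15%.  Cell positions follow independent Poisson
point processes per compartment: tumor cells intratumoral (800/mm²),
stromal cells outside (400/mm²), and lymphocytes at subgroup-specific
per-compartment median densities (POLEmut densest intratumorally, p53abn
and NSMP sparsest).  Lymphocyte phenotypes are obtained by Poisson
thinning with a configured CD8-in-CD3 co-positivity of 99.81%.  Biological
variability enters as a log-normal case-level multiplier (σ = 0.5) shared
across markers plus per-core jitter (σ = 0.2).  Intensity features are
drawn from clipped normal distributions chosen so that re-applying the
threshold rules reproduces the generating phenotype deterministically.
Optionally, cores are rendered as 4-channel images (nuclei as soft DAPI
disks, cytoplasmic marker annuli, artifact blobs, background noise) so
the full image-analysis path can be validated by round-trip.  Survival
times are exponential with subgroup-specific monthly hazards.

## 9. Validation strategy

Every stage is tested against an independent oracle rather than against
itself: closed-form annulus areas and rasterized zonation for geometry;
exhaustive search for thresholds; hand-computed ratios for diagnostics;
scipy/lifelines cross-checks and power/type-I simulations for statistics;
and generator-label recovery through both the feature path and the
rendered-image path.  Cohort-level behavior is validated on seeded
synthetic cohorts: configured subgroup orderings are recovered with
Kruskal–Wallis p < 0.001 and the data-driven full-sensitivity cut-off
falls between the configured wild-type and POLEmut intra-tumoral CD8
medians.
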