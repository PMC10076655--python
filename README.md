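# tilquant

Spatial quantification of CD3+/CD8+ tumor-infiltrating lymphocytes on
multiplex-immunofluorescence tissue-microarray cores, and a density-based
pretest that predicts *POLE* wild-type endometrial carcinoma before
sequencing.

## Scientific problem

Molecular classification of endometrial carcinoma distinguishes four
subgroups — *POLE*-mutated (POLEmut), mismatch-repair deficient (MMRdef),
p53-abnormal (p53abn) and "no specific molecular profile" (NSMP).
Identifying the POLEmut subgroup requires sequencing the *POLE*
exonuclease domain, which is the costliest step of the workup and is
negative in the large majority of cases.  POLEmut tumors are, however,
strongly immunogenic: they carry dense intra-tumoral cytotoxic (CD8+)
infiltrates.  A *low* intra-tumoral CD8+ density therefore argues against
a *POLE* mutation and can spare the sequencing assay.

`tilquant` implements that idea end to end:

1. **Image analysis** — histogram auto-thresholding (maximum-entropy and
   mean), watershed nucleus detection on the DAPI channel, and per-cell
   nucleus/cytoplasm intensity measurement over a fixed-width annulus.
2. **Phenotyping** — rule-based cell classification from nucleus and
   cytoplasm intensities (DAPI, CD3, CD8, PanCK) with separate 8-bit and
   16-bit rule sets; cells are labelled CD3only / CD3CD8 / CD8only /
   Tumor / Stroma / Artifact.
3. **Spatial zonation** — a vector tumor mask built from PanCK+ cells
   splits each circular core into *intratumoral*, *close* (≤ 50 µm from
   the tumor boundary) and *distant* (> 50 µm) compartments; regions
   below 0.01 mm² are excluded from density estimation.
4. **Densities** — per-core counts and densities (cells/mm²) per marker ×
   compartment, averaged into per-case profiles.
5. **Pretest** — per-case mean intra-tumoral CD8+ density below
   50 cells/mm² predicts *POLE* wild-type; diagnostic metrics, ROC
   analysis and sequencing-triage arithmetic are reported.
6. **Cohort statistics** — rank-based group comparisons across molecular
   subgroups, Spearman method agreement, and Kaplan–Meier/log-rank
   survival analysis.
7. **Synthetic cohorts** — a seeded generator of realistic TMA cores
   (vector tumor geometry, per-compartment Poisson point processes with
   case- and core-level dispersion, intensity features, optional rendered
   4-channel images) used for validation throughout.

## Running the tests

```bash
python -m pytest -q tests/
```

The suite (139 tests, ~3 minutes) checks every stage against independent
oracles: closed-form geometry, rasterized brute-force zonation, exhaustive
Kapur threshold search, hand-computed diagnostic ratios, and round-trips
through rendered synthetic images.

## Worked example

Generate a small synthetic cohort (two cases per subgroup, two cores per
case), push it through the full pipeline and apply the pretest:

```python
from tilquant import (
    PretestConfig, SyntheticCohortParams, THRESHOLDS_8BIT,
    analyze_cohort, case_profile_matrix, classify_cases,
    diagnostic_metrics, generate_cohort,
)

params = SyntheticCohortParams(
    seed=7,
    n_cases_per_group={"POLEmut": 2, "MMRdef": 2, "NSMP": 2, "p53abn": 2},
    cores_per_case=2,
)
tables, cohort, layouts = generate_cohort(params)
bounds = {core_id: layout.core for core_id, layout in layouts.items()}
_, profiles_long = analyze_cohort(tables, bounds, THRESHOLDS_8BIT)
profiles = case_profile_matrix(profiles_long)
print(profiles[["case_id", "CD8_intratumoral", "CD3_intratumoral", "CD3_total"]]
      .round(1).to_string(index=False))
```

```
    case_id  CD8_intratumoral  CD3_intratumoral  CD3_total
 MMRdef-001              30.4              49.1       54.6
 MMRdef-002             253.8             439.7      514.4
   NSMP-001              22.8              50.2       65.4
   NSMP-002              34.5              82.3      103.8
POLEmut-001             279.0             333.1      356.5
POLEmut-002             573.6             696.7      769.1
 p53abn-001              18.4              66.1       86.9
 p53abn-002              14.6              53.2       64.2
```

Both POLEmut cases show the expected dense intra-tumoral CD8+ infiltrate.
Applying the 50 cells/mm² pretest:

```python
calls = cohort.merge(classify_cases(profiles, PretestConfig()), on="case_id")
print(diagnostic_metrics(calls["prediction"], calls["pole_wt"]).rounded())
```

```
{'tp': 2, 'fn': 0, 'tn': 5, 'fp': 1, 'n': 8, 'n_indeterminate': 0,
 'sensitivity_pct': 100.0, 'specificity_pct': 83.3, 'ppv_native_pct': 25.0,
 'ppv_preselected_pct': 66.7, 'excluded_fraction_pct': 62.5}
```

All POLEmut cases are retained for sequencing (sensitivity 100%) while
5 of 6 wild-type cases are screened out below the cut-off.

### Command line

The same pipeline is available as CLI subcommands:

```bash
tilquant simulate --seed 5 --out sim/ --render
tilquant segment  --image sim/POLEmut-001-c1.tiff --out cells.csv
tilquant phenotype --cells cells.csv --scale 8bit --out pheno.csv
tilquant zonate   --cells pheno.csv --out zones.geojson --cells-out zoned.csv
tilquant density  --cells zoned.csv --out densities.csv --case-out profiles.csv
tilquant pretest  --profiles profiles.csv --cohort sim/cohort.csv --out pretest.json
tilquant stats    --profiles profiles.csv --cohort sim/cohort.csv --out stats.json
```

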