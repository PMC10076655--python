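"""The intra-tumoral CD8+ density pretest for POLE wild-type.

POLE-mutated endometrial carcinomas carry dense intra-tumoral cytotoxic
infiltrates, so a *low* intra-tumoral CD8+ density argues against a POLE
mutation.  The pretest predicts POLE wild-type when the per-case mean
intra-tumoral CD8+ density falls below a cut-off (default 50 cells/mm²);
cases at or above the cut-off remain sequencing candidates.

Convention for diagnostic metrics: the *positive* event is a POLE-mutated
case retained for sequencing (density >= cut-off).  Sensitivity is the
fraction of POLE-mutated cases retained; specificity the fraction of
wild-type cases screened out below the cut-off.  This is the convention
under which the pretest's published-style headline numbers (100% sensitivity
at roughly half of wild-types excluded) are arithmetically consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

PREDICTED_POLEWT = "predicted_POLEwt"
SEQUENCE_CANDIDATE = "sequence_candidate"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class PretestConfig:
    marker: str = "CD8"
    region: str = "intratumoral"
    cutoff_cells_per_mm2: float = 50.0

    def __post_init__(self) -> None:
        if self.cutoff_cells_per_mm2 <= 0:
            raise ValueError("cutoff must be positive")

    @property
    def density_column(self) -> str:
        return f"{self.marker}_{self.region}"


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Confusion counts and derived rates for the pretest.

    tp: POLEmut at/above cut-off (retained); fn: POLEmut below cut-off
    (missed); tn: POLEwt below cut-off (correctly excluded); fp: POLEwt
    retained.  ``n_indeterminate`` counts cases without a usable density.
    Percentages are on the 0-100 scale.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    n_indeterminate: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def sensitivity_pct(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity_pct(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def ppv_native_pct(self) -> float:
        """POLEmut prevalence: yield of sequencing every case."""
        return 100.0 * (self.tp + self.fn) / self.n if self.n else float("nan")

    @property
    def ppv_preselected_pct(self) -> float:
        """POLEmut yield among cases retained for sequencing."""
        retained = self.tp + self.fp
        return 100.0 * self.tp / retained if retained else float("nan")

    @property
    def excluded_fraction_pct(self) -> float:
        """Fraction of all cases spared sequencing (below cut-off)."""
        return 100.0 * (self.tn + self.fn) / self.n if self.n else float("nan")

    def rounded(self) -> dict:
        """All rates to 1 decimal, as reported."""
        return {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "n": self.n,
            "n_indeterminate": self.n_indeterminate,
            "sensitivity_pct": round(self.sensitivity_pct, 1),
            "specificity_pct": round(self.specificity_pct, 1),
            "ppv_native_pct": round(self.ppv_native_pct, 1),
            "ppv_preselected_pct": round(self.ppv_preselected_pct, 1),
            "excluded_fraction_pct": round(self.excluded_fraction_pct, 1),
        }


def classify_case(density: float | None, cfg: PretestConfig) -> str:
    """Pretest call for one case from its mean density.

    Below the cut-off predicts POLE wild-type; at or above the cut-off the
    case stays a sequencing candidate (the rule is a strict ``<``).  A
    missing density is indeterminate — never silently wild-type.
    """
    if density is None or (isinstance(density, float) and np.isnan(density)):
        return INDETERMINATE
    return PREDICTED_POLEWT if density < cfg.cutoff_cells_per_mm2 else SEQUENCE_CANDIDATE


def classify_cases(profiles: pd.DataFrame, cfg: PretestConfig) -> pd.DataFrame:
    """Apply the pretest to a wide per-case profile matrix
    (``case_id`` + ``{marker}_{region}`` columns)."""
    col = cfg.density_column
    if col not in profiles.columns:
        raise ValueError(f"profiles lack density column {col!r}")
    dens = profiles[col].astype(float)
    pred = np.where(
        dens.isna(), INDETERMINATE,
        np.where(dens < cfg.cutoff_cells_per_mm2, PREDICTED_POLEWT, SEQUENCE_CANDIDATE),
    )
    return pd.DataFrame(
        {"case_id": profiles["case_id"], "density": dens, "prediction": pred}
    )


def diagnostic_metrics(predictions: pd.Series, pole_wt: pd.Series) -> DiagnosticMetrics:
    """Confusion-count metrics from per-case predictions and POLE status.

    ``predictions`` holds pretest calls; ``pole_wt`` is True for wild-type.
    Indeterminate cases are excluded from the confusion table but counted.
    """
    predictions = pd.Series(predictions).reset_index(drop=True)
    pole_wt = pd.Series(pole_wt).astype(bool).reset_index(drop=True)
    if len(predictions) == 0:
        raise ValueError("no predictions supplied")
    if len(predictions) != len(pole_wt):
        raise ValueError("predictions and truth differ in length")
    determinate = predictions != INDETERMINATE
    retained = predictions == SEQUENCE_CANDIDATE
    mut = ~pole_wt
    return DiagnosticMetrics(
        tp=int((determinate & retained & mut).sum()),
        fn=int((determinate & ~retained & mut).sum()),
        tn=int((determinate & ~retained & ~mut).sum()),
        fp=int((determinate & retained & ~mut).sum()),
        n_indeterminate=int((~determinate).sum()),
    )


def metrics_from_counts(tp: int, fn: int, tn: int, fp: int) -> DiagnosticMetrics:
    """Build metrics directly from published-style confusion counts."""
    return DiagnosticMetrics(tp=tp, fn=fn, tn=tn, fp=fp)


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_cutoff_max_spec_at_full_sens: float
    optimal_cutoff_youden: float


def roc_analysis(densities: pd.Series, is_pole_mut: pd.Series) -> RocResult:
    """Empirical ROC of a density as a marker of POLE mutation.

    POLE-mutated is the positive class and higher density votes for it.
    AUC is the trapezoidal area, equal to the Mann-Whitney U statistic
    divided by n1·n2.  Two cut-off criteria are reported: the largest
    cut-off retaining every POLE-mutated case (sensitivity 100%, i.e. the
    minimum density among mutated cases) and the Youden-optimal cut-off.
    """
    dens = pd.Series(densities).astype(float)
    truth = pd.Series(is_pole_mut).astype(bool)
    ok = ~dens.isna()
    dens, truth = dens[ok], truth[ok]
    if truth.all() or (~truth).all():
        raise ValueError("ROC analysis requires both POLEmut and POLEwt cases")
    fpr, tpr, thr = roc_curve(truth.to_numpy(), dens.to_numpy())
    auc = float(np.trapezoid(tpr, fpr))
    sens = tpr
    spec = 1.0 - fpr
    # Largest cutoff with full sensitivity: the pretest retains density >= c,
    # so c = min density among mutated cases.
    full_sens_cutoff = float(dens[truth].min())
    youden = sens + spec - 1.0
    youden_cutoff = float(thr[int(np.argmax(youden))])
    return RocResult(
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        optimal_cutoff_max_spec_at_full_sens=full_sens_cutoff,
        optimal_cutoff_youden=youden_cutoff,
    )


def triage_workflow(
    cohort: pd.DataFrame,
    profiles: pd.DataFrame,
    cfg: PretestConfig,
    eligible: pd.Series,
) -> dict:
    """Sequencing-triage arithmetic over the eligible subset of a cohort.

    ``eligible`` flags the cases that would otherwise go to sequencing
    (clinical-pathological pre-filtering is an input, not computed here).
    Reports how many eligible cases the pretest excludes versus sends on,
    and the resulting POLEmut yield among the retained.
    """
    merged = cohort.merge(classify_cases(profiles, cfg), on="case_id", how="left")
    merged["prediction"] = merged["prediction"].fillna(INDETERMINATE)
    elig = merged[np.asarray(eligible, dtype=bool)]
    n = len(elig)
    if n == 0:
        return {
            "n_eligible": 0, "n_excluded": 0, "n_to_sequencing": 0,
            "excluded_pct": float("nan"), "ppv_retained_pct": float("nan"),
        }
    excluded = elig["prediction"] == PREDICTED_POLEWT
    retained = ~excluded  # indeterminates fail safe toward sequencing
    n_excl = int(excluded.sum())
    n_ret = int(retained.sum())
    mut_ret = int((retained & (elig["tcga"] == "POLEmut")).sum())
    return {
        "n_eligible": n,
        "n_excluded": n_excl,
        "n_to_sequencing": n_ret,
        "excluded_pct": round(100.0 * n_excl / n, 1),
        "ppv_retained_pct": round(100.0 * mut_ret / n_ret, 1) if n_ret else float("nan"),
    }
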