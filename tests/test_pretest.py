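import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from tilquant.pretest import (
    INDETERMINATE,
    PREDICTED_POLEWT,
    SEQUENCE_CANDIDATE,
    PretestConfig,
    classify_case,
    classify_cases,
    diagnostic_metrics,
    metrics_from_counts,
    roc_analysis,
    triage_workflow,
)

CFG = PretestConfig()


class TestClassifyCase:
    @pytest.mark.parametrize(
        "density,expected",
        [
            (6.0, PREDICTED_POLEWT),       # a density this low argues for wild-type
            (98.0, SEQUENCE_CANDIDATE),
            (50.0, SEQUENCE_CANDIDATE),    # rule is a strict "< 50"
            (49.999, PREDICTED_POLEWT),
            (None, INDETERMINATE),
            (float("nan"), INDETERMINATE),
        ],
    )
    def test_cutoff_rule(self, density, expected):
        assert classify_case(density, CFG) == expected

    def test_vectorized_matches_scalar(self):
        profiles = pd.DataFrame(
            {"case_id": ["a", "b", "c"], "CD8_intratumoral": [6.0, 98.0, np.nan]}
        )
        calls = classify_cases(profiles, CFG)
        assert list(calls["prediction"]) == [
            PREDICTED_POLEWT, SEQUENCE_CANDIDATE, INDETERMINATE,
        ]


class TestDiagnosticMetrics:
    def test_random_counts_match_hand_ratios(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            tp, fn, tn, fp = rng.integers(0, 50, size=4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            m = metrics_from_counts(int(tp), int(fn), int(tn), int(fp))
            assert m.sensitivity_pct == pytest.approx(100 * tp / (tp + fn))
            assert m.specificity_pct == pytest.approx(100 * tn / (tn + fp))
            assert m.excluded_fraction_pct == pytest.approx(
                100 * (tn + fn) / (tp + fn + tn + fp)
            )

    def test_degenerate_all_retained(self):
        preds = pd.Series([SEQUENCE_CANDIDATE] * 10)
        truth = pd.Series([False] * 2 + [True] * 8)  # 2 POLEmut, 8 wt
        m = diagnostic_metrics(preds, truth)
        assert m.sensitivity_pct == 100.0
        assert m.specificity_pct == 0.0

    def test_indeterminates_counted_not_classified(self):
        preds = pd.Series([PREDICTED_POLEWT, INDETERMINATE, SEQUENCE_CANDIDATE])
        truth = pd.Series([True, True, False])
        m = diagnostic_metrics(preds, truth)
        assert m.n == 2 and m.n_indeterminate == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_metrics(pd.Series(dtype=object), pd.Series(dtype=bool))


class TestRocAnalysis:
    def test_perfect_separation_auc_one(self):
        dens = pd.Series([200.0, 300, 250, 10, 20, 5])
        mut = pd.Series([True, True, True, False, False, False])
        roc = roc_analysis(dens, mut)
        assert roc.auc == pytest.approx(1.0)

    def test_auc_equals_mann_whitney_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n1, n0 = rng.integers(3, 25, size=2)
            d_mut = rng.exponential(100, size=n1)
            d_wt = rng.exponential(60, size=n0)
            dens = pd.Series(np.concatenate([d_mut, d_wt]))
            mut = pd.Series([True] * n1 + [False] * n0)
            roc = roc_analysis(dens, mut)
            u = mannwhitneyu(d_mut, d_wt, alternative="two-sided").statistic
            assert roc.auc == pytest.approx(u / (n1 * n0), abs=1e-10)

    def test_shuffled_labels_auc_near_half(self):
        rng = np.random.default_rng(2)
        dens = pd.Series(rng.exponential(80, size=200))
        mut = pd.Series(rng.permutation([True] * 100 + [False] * 100))
        roc = roc_analysis(dens, mut)
        assert roc.auc == pytest.approx(0.5, abs=0.05)

    def test_full_sens_cutoff_is_min_mut_density(self):
        dens = pd.Series([120.0, 80, 300, 30, 60, 45])
        mut = pd.Series([True, True, True, False, False, False])
        roc = roc_analysis(dens, mut)
        assert roc.optimal_cutoff_max_spec_at_full_sens == 80.0
        # applying that cutoff retains all mutated cases
        cfg = PretestConfig(cutoff_cells_per_mm2=roc.optimal_cutoff_max_spec_at_full_sens)
        retained = dens >= cfg.cutoff_cells_per_mm2
        assert retained[mut].all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis(pd.Series([1.0, 2.0]), pd.Series([True, True]))


class TestCutoffSweepMonotonicity:
    def test_sweep_monotone(self):
        rng = np.random.default_rng(3)
        dens = pd.Series(np.concatenate([rng.lognormal(5.5, 0.6, 20),
                                         rng.lognormal(3.5, 0.8, 180)]))
        wt = pd.Series([False] * 20 + [True] * 180)
        excl, sens, spec = [], [], []
        for cutoff in [5, 10, 25, 50, 100, 200, 400]:
            cfg = PretestConfig(cutoff_cells_per_mm2=cutoff)
            profiles = pd.DataFrame({"case_id": range(200), "CD8_intratumoral": dens})
            preds = classify_cases(profiles, cfg)["prediction"]
            m = diagnostic_metrics(preds, wt)
            excl.append(m.excluded_fraction_pct)
            sens.append(m.sensitivity_pct)
            spec.append(m.specificity_pct)
        assert excl == sorted(excl)
        assert sens == sorted(sens, reverse=True)
        assert spec == sorted(spec)


class TestTriageWorkflow:
    def _cohort(self, n_below, n_total, n_mut_below=0, n_mut=0):
        n_above = n_total - n_below
        tcga = (
            ["POLEmut"] * n_mut_below + ["NSMP"] * (n_below - n_mut_below)
            + ["POLEmut"] * (n_mut - n_mut_below) + ["NSMP"] * (n_above - (n_mut - n_mut_below))
        )
        dens = [10.0] * n_below + [100.0] * n_above
        cohort = pd.DataFrame(
            {
                "case_id": [str(i) for i in range(n_total)],
                "tcga": tcga,
                "pole_wt": [t != "POLEmut" for t in tcga],
            }
        )
        profiles = pd.DataFrame(
            {"case_id": [str(i) for i in range(n_total)], "CD8_intratumoral": dens}
        )
        return cohort, profiles

    def test_published_style_triage_fraction(self):
        # 218 eligible cases of which 72 fall below the cut-off
        cohort, profiles = self._cohort(n_below=72, n_total=218, n_mut=7)
        report = triage_workflow(cohort, profiles, CFG, pd.Series([True] * 218))
        assert report["excluded_pct"] == 33.0
        assert report["n_to_sequencing"] == 146

    def test_no_eligible_cases(self):
        cohort, profiles = self._cohort(n_below=5, n_total=10)
        report = triage_workflow(cohort, profiles, CFG, pd.Series([False] * 10))
        assert report["n_eligible"] == 0

    def test_all_eligible_matches_diagnostic_metrics(self):
        cohort, profiles = self._cohort(n_below=40, n_total=100, n_mut=5)
        report = triage_workflow(cohort, profiles, CFG, pd.Series([True] * 100))
        preds = classify_cases(profiles, CFG)["prediction"]
        m = diagnostic_metrics(preds, cohort["pole_wt"])
        assert report["excluded_pct"] == round(m.excluded_fraction_pct, 1)
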