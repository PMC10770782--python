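import numpy as np
import pandas as pd
import pytest

from cawarn.errors import ConfigError, ContractError, DataError
from cawarn.evaluate import (
    auprc,
    auroc,
    bootstrap_ci,
    brier,
    confusion_metrics,
    kfold_cv,
    kfold_cv_table,
    lead_time_curve,
)
from conftest import FAST_MODEL


# ---------------------------------------------------------------- oracles

def oracle_auroc(scores, labels):
    """Pairwise Mann-Whitney loop with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def oracle_auprc(scores, labels):
    """Average precision summed over unique descending thresholds."""
    n_pos = sum(labels)
    pairs = sorted(zip(scores, labels), key=lambda x: -x[0])
    ap, tp, fp, prev_recall = 0.0, 0, 0, 0.0
    i = 0
    while i < len(pairs):
        j = i
        while j < len(pairs) and pairs[j][0] == pairs[i][0]:
            tp += pairs[j][1]
            fp += 1 - pairs[j][1]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


class TestConfusionMetrics:
    def test_perfect(self):
        m = confusion_metrics([0, 1, 1, 0], [0, 1, 1, 0])
        assert all(m[k] == 1.0 for k in ("precision", "sensitivity", "specificity", "f1"))

    def test_all_negative_predictions(self):
        m = confusion_metrics([1, 1, 0], [0, 0, 0])
        assert m["sensitivity"] == 0.0
        assert m["specificity"] == 1.0
        assert m["precision"] == 0.0
        assert "precision" in m["undefined"]

    def test_hand_computed(self):
        # TP=2, FP=1, FN=0, TN=1
        m = confusion_metrics([1, 1, 0, 0], [1, 1, 1, 0])
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["sensitivity"] == 1.0
        assert m["specificity"] == 0.5
        assert m["f1"] == pytest.approx(0.8)

    def test_length_mismatch_raises(self):
        with pytest.raises(ContractError):
            confusion_metrics([1, 0], [1])


class TestRankMetrics:
    def test_auroc_perfect_and_reversed(self):
        scores = [0.2, 0.3, 0.6, 0.9]
        assert auroc(scores, [0, 0, 1, 1]) == 1.0
        assert auroc(scores, [1, 1, 0, 0]) == 0.0

    def test_single_class_raises(self):
        with pytest.raises(DataError):
            auroc([0.1, 0.2], [1, 1])
        with pytest.raises(DataError):
            auprc([0.1, 0.2], [0, 0])

    @pytest.mark.parametrize("seed", range(25))
    def test_auroc_auprc_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        scores = np.round(rng.random(n), 1)  # coarse rounding forces ties
        labels = rng.integers(0, 2, n)
        if len(set(labels)) < 2:
            labels[:2] = [0, 1]
        assert auroc(scores, labels) == pytest.approx(oracle_auroc(scores, labels), abs=1e-12)
        assert auprc(scores, labels) == pytest.approx(oracle_auprc(scores.tolist(), labels.tolist()), abs=1e-12)

    def test_auroc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        a = auroc(scores, labels)
        assert auroc(np.exp(5 * scores), labels) == pytest.approx(a)
        assert auroc(np.log(scores + 1e-9), labels) == pytest.approx(a)

    def test_auprc_of_random_scores_near_prevalence(self):
        rng = np.random.default_rng(1)
        n = 2000
        labels = (rng.random(n) < 0.1).astype(int)
        scores = rng.random(n)
        assert auprc(scores, labels) == pytest.approx(0.1, abs=0.05)


class TestBrier:
    def test_exact_predictions(self):
        assert brier([0.0, 1.0], [0, 1]) == 0.0

    def test_coin_flip(self):
        assert brier([0.5, 0.5], [0, 1]) == 0.25

    def test_arithmetic(self):
        assert brier([0.8, 0.2], [1, 0]) == pytest.approx(0.04)

    def test_out_of_range_raises(self):
        with pytest.raises(ContractError):
            brier([1.2], [1])


class TestBootstrap:
    def test_constant_metric_degenerate_ci(self):
        lo, hi = bootstrap_ci([0.9, 0.9, 0.1, 0.1], [1, 1, 0, 0], "auroc", n_boot=200, seed=0)
        assert lo == hi == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_ci_contains_point_estimate(self, seed):
        rng = np.random.default_rng(seed)
        n = 80
        scores = rng.random(n)
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        point = auroc(scores, labels)
        lo, hi = bootstrap_ci(scores, labels, "auroc", n_boot=300, seed=seed)
        assert lo <= point <= hi

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        scores, labels = rng.random(50), rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        assert bootstrap_ci(scores, labels, "auroc", 150, seed=7) == bootstrap_ci(
            scores, labels, "auroc", 150, seed=7
        )

    def test_too_few_iterations_raises(self):
        with pytest.raises(ConfigError):
            bootstrap_ci([0.1, 0.9], [0, 1], "auroc", n_boot=10)


class TestKFold:
    @pytest.fixture(scope="class")
    def report_and_labels(self, small_grids):
        grids, labels = small_grids
        report = kfold_cv(grids, labels, k=5, model_config=FAST_MODEL, seed=2, compute_ci=False)
        return report, labels

    def test_folds_partition_all_stays(self, report_and_labels):
        report, labels = report_and_labels
        assert len(report.fold_metrics) == 5
        assert set(report.oof_scores.index) == set(labels)
        assert not report.oof_scores.isna().any()

    def test_metrics_in_unit_interval(self, report_and_labels):
        report, _ = report_and_labels
        cols = ["precision", "sensitivity", "specificity", "f1", "auroc", "auprc", "brier"]
        assert ((report.fold_metrics[cols] >= 0) & (report.fold_metrics[cols] <= 1)).all().all()

    def test_deterministic(self, small_grids):
        grids, labels = small_grids
        a = kfold_cv(grids, labels, k=3, model_config=FAST_MODEL, seed=4, compute_ci=False)
        b = kfold_cv(grids, labels, k=3, model_config=FAST_MODEL, seed=4, compute_ci=False)
        pd.testing.assert_frame_equal(a.fold_metrics, b.fold_metrics)
        pd.testing.assert_series_equal(a.oof_scores, b.oof_scores)

    def test_class_too_small_for_k_raises(self, small_grids):
        grids, labels = small_grids
        with pytest.raises(ConfigError, match="smaller k"):
            kfold_cv(grids, labels, k=50, model_config=FAST_MODEL)

    def test_stratification_balanced(self, small_grids):
        grids, labels = small_grids
        report = kfold_cv(grids, labels, k=5, model_config=FAST_MODEL, seed=2, compute_ci=False)
        # reconstruct fold memberships from oof order is not possible; check
        # instead that every fold saw both classes (implied by defined AUROC)
        assert report.fold_metrics["auroc"].notna().all()

    def test_table_variant_agrees_structurally(self, small_grids):
        grids, labels = small_grids
        from cawarn.preprocess import apply_normalizer, fit_normalizer
        from cawarn.features import assemble_feature_table

        stats = fit_normalizer(grids)
        ft = assemble_feature_table([apply_normalizer(g, stats) for g in grids], labels)
        report = kfold_cv_table(ft, k=3, model_config=FAST_MODEL, seed=1, compute_ci=False)
        assert len(report.fold_metrics) == 3
        assert set(report.oof_scores.index) == set(ft.X.index)


class TestLeadTime:
    @pytest.fixture(scope="class")
    def lead_cohort(self):
        from cawarn.simulate import SimConfig, generate_cohort

        cfg = SimConfig(
            n_stays=80, ca_fraction=0.3, effect_size=2.0,
            onset_hours_before_end=3.0, lead_reserve_hours=5, seed=13,
        )
        return generate_cohort(cfg)

    def test_lead_one_matches_standard_pipeline(self, lead_cohort):
        """Lead 1 is by definition the standard window: same AUROC as
        running kfold_cv on the last-24h grids directly."""
        from cawarn.config import PipelineConfig
        from cawarn.pipeline import preprocess_cohort

        grids, labels = preprocess_cohort(lead_cohort.records, lead_cohort.labels, PipelineConfig())
        direct = kfold_cv(grids, labels, k=3, model_config=FAST_MODEL, seed=6, compute_ci=False)
        curve = lead_time_curve(
            lead_cohort.records, lead_cohort.labels, leads=(1,), T=24, k=3,
            model_config=FAST_MODEL, seed=6,
        )
        assert curve["mean_auroc"][1] == pytest.approx(direct.summary["auroc"]["mean"])

    def test_reuse_model_mode_runs_and_pairs_folds(self, lead_cohort):
        curve = lead_time_curve(
            lead_cohort.records, lead_cohort.labels, leads=(1, 6), T=24, k=3,
            model_config=FAST_MODEL, seed=6, reuse_model=True,
        )
        assert set(curve["per_fold"].columns) == {1, 6}
        assert len(curve["per_fold"]) == 3
        assert all(0.0 <= v <= 1.0 for v in curve["mean_auroc"].values())

    def test_insufficient_span_raises(self, lead_cohort):
        from cawarn.errors import DataError

        with pytest.raises(DataError, match="span"):
            lead_time_curve(
                lead_cohort.records, lead_cohort.labels, leads=(1, 12), T=24, k=3,
                model_config=FAST_MODEL, seed=6,
            )
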