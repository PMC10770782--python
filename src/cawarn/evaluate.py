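"""Cross-validated evaluation, bootstrap intervals and lead-time curves.

Metrics follow the usual early-warning reporting set: precision,
sensitivity, specificity, F1 at the Youden operating point, plus AUROC
(Mann-Whitney convention with half credit for ties), AUPRC (average
precision) and the Brier score.  Cross-validation is stratified at stay
level; within each training fold, a nested stratified 80/20 split feeds
early stopping and threshold selection, and per-channel normalization
statistics are fit on that fold's training stays only, so no test
information leaks into preprocessing, model fitting or thresholding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from cawarn.errors import ConfigError, ContractError, DataError
from cawarn.features import DEFAULT_RESOLUTIONS, FeatureTable, featurize_many
from cawarn.model import ModelConfig, predict, train
from cawarn.preprocess import apply_normalizer, build_grid, fit_normalizer

logger = logging.getLogger(__name__)

THRESHOLD_METRICS = ("precision", "sensitivity", "specificity", "f1")
SCORE_METRICS = ("auroc", "auprc", "brier")


@dataclass
class EvalReport:
    """Per-fold and aggregate cross-validation results."""

    fold_metrics: pd.DataFrame  # one row per fold
    summary: dict  # metric -> {"mean": ..., "sd": ...}
    ci: dict  # metric -> (lower, upper), bootstrap 95%
    oof_scores: pd.Series  # pooled out-of-fold probabilities by stay
    oof_labels: pd.Series
    config: dict = field(default_factory=dict)
    lead_curve: dict | None = None  # lead hours -> mean AUROC


def confusion_metrics(labels, predictions) -> dict:
    """Precision, sensitivity, specificity and F1 from binary vectors.

    Ratios with a zero denominator are reported as 0 and listed under the
    ``undefined`` key.
    """
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape:
        raise ContractError("labels and predictions differ in length")
    tp = int(((y == 1) & (p == 1)).sum())
    fp = int(((y == 0) & (p == 1)).sum())
    fn = int(((y == 1) & (p == 0)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    undefined = []

    def _ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    precision = _ratio(tp, tp + fp, "precision")
    sensitivity = _ratio(tp, tp + fn, "sensitivity")
    specificity = _ratio(tn, tn + fp, "specificity")
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "f1")
    if undefined:
        logger.warning("metrics with zero denominator reported as 0: %s", undefined)
    return {
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "f1": f1,
        "undefined": undefined,
    }


def _check_two_classes(labels) -> None:
    if len(np.unique(np.asarray(labels))) < 2:
        raise DataError("metric requires both classes to be present")


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC: the probability a random positive outscores a
    random negative, with 0.5 credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_two_classes(labels)
    ranks = rankdata(scores)
    n_pos = int((labels == 1).sum())
    n_neg = labels.size - n_pos
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Area under the precision-recall step curve (average precision)."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def brier(scores, labels) -> float:
    """Mean squared difference between predicted probability and outcome."""
    scores = np.asarray(scores, dtype=float)
    if (scores < 0).any() or (scores > 1).any():
        raise ContractError("Brier score requires probabilities in [0, 1]")
    return float(np.mean((scores - np.asarray(labels)) ** 2))


_METRIC_FNS = {"auroc": auroc, "auprc": auprc, "brier": brier}


def bootstrap_ci(scores, labels, metric, n_boot: int = 1000, seed: int = 0):
    """Percentile 95% CI of a metric over stratified bootstrap resamples.

    Positives and negatives are resampled separately so each replicate
    keeps both classes; deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ConfigError("n_boot must be >= 100")
    fn = _METRIC_FNS[metric] if isinstance(metric, str) else metric
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = np.nonzero(labels == 1)[0]
    neg = np.nonzero(labels == 0)[0]
    if pos.size == 0 or neg.size == 0:
        raise DataError("bootstrap CI requires both classes")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, size=pos.size, replace=True), rng.choice(neg, size=neg.size, replace=True)]
        )
        stats[b] = fn(scores[idx], labels[idx])
    lower, upper = np.percentile(stats, [2.5, 97.5])
    return float(lower), float(upper)


def _fold_assignment(stay_ids, y, k, seed):
    if k < 2:
        raise ConfigError("k must be >= 2")
    counts = pd.Series(y).value_counts()
    if counts.min() < k:
        raise ConfigError(
            f"smallest class has {counts.min()} members, fewer than k={k}; choose a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(stay_ids)), y))


def _run_fold(grids_by_id, stay_ids, y, train_idx, test_idx, model_config, resolutions, seed):
    """Train on one fold (nested early-stopping split) and score its test set."""
    train_ids = [stay_ids[i] for i in train_idx]
    test_ids = [stay_ids[i] for i in test_idx]
    y_train = y[train_idx]
    inner_train, inner_val = train_test_split(
        train_ids, test_size=0.2, stratify=y_train, random_state=seed
    )
    stats = fit_normalizer(grids_by_id[s] for s in train_ids)
    label_map = dict(zip(stay_ids, y))

    def _table(ids) -> FeatureTable:
        X = featurize_many((apply_normalizer(grids_by_id[s], stats) for s in ids), resolutions)
        lab = pd.Series([int(label_map[s]) for s in X.index], index=X.index, name="label")
        return FeatureTable(X=X, y=lab)

    model = train(_table(inner_train), _table(inner_val), model_config)
    test_ft = _table(test_ids)
    scores = predict(model, test_ft.X)
    return model, test_ft, scores, stats


def kfold_cv(
    grids,
    labels: dict,
    k: int = 10,
    model_config: ModelConfig | None = None,
    resolutions=DEFAULT_RESOLUTIONS,
    seed: int = 0,
    n_boot: int = 1000,
    compute_ci: bool = True,
) -> EvalReport:
    """Stratified k-fold cross-validation of the full modelling stage.

    ``grids`` are imputed but *un-normalized* per-stay grids; normalization
    is fit inside each training fold.  Thresholded metrics use each fold's
    own Youden threshold (selected on the nested validation split).
    """
    model_config = model_config if model_config is not None else ModelConfig()
    grids_by_id = {g.stay_id: g for g in grids}
    stay_ids = sorted(grids_by_id)
    missing = [s for s in stay_ids if s not in labels]
    if missing:
        raise DataError(f"stays without labels: {missing[:5]}")
    y = np.array([int(labels[s]) for s in stay_ids])
    folds = _fold_assignment(stay_ids, y, k, seed)

    rows = []
    oof_scores = pd.Series(index=pd.Index(stay_ids, name="stay_id"), dtype=float)
    for fold_no, (train_idx, test_idx) in enumerate(folds):
        model, test_ft, scores, _ = _run_fold(
            grids_by_id, stay_ids, y, train_idx, test_idx, model_config, resolutions, seed + fold_no
        )
        y_test = test_ft.y.to_numpy()
        preds = (scores >= model.decision_threshold).astype(int)
        row = {"fold": fold_no, **{m: v for m, v in confusion_metrics(y_test, preds).items() if m != "undefined"}}
        row["auroc"] = auroc(scores, y_test)
        row["auprc"] = auprc(scores, y_test)
        row["brier"] = brier(scores, y_test)
        row["threshold"] = model.decision_threshold
        row["best_iteration"] = model.best_iteration
        rows.append(row)
        oof_scores.loc[test_ft.X.index] = scores

    fold_metrics = pd.DataFrame(rows).set_index("fold")
    metric_cols = list(THRESHOLD_METRICS) + list(SCORE_METRICS)
    summary = {
        m: {"mean": float(fold_metrics[m].mean()), "sd": float(fold_metrics[m].std(ddof=1))}
        for m in metric_cols
    }
    oof_labels = pd.Series(y, index=oof_scores.index, name="label")
    ci = {}
    if compute_ci:
        for m in ("auroc", "auprc"):
            ci[m] = bootstrap_ci(oof_scores.to_numpy(), y, m, n_boot=n_boot, seed=seed)
    return EvalReport(
        fold_metrics=fold_metrics,
        summary=summary,
        ci=ci,
        oof_scores=oof_scores,
        oof_labels=oof_labels,
        config={
            "k": k,
            "seed": seed,
            "n_boot": n_boot,
            "resolutions": sorted(set(resolutions)),
            "model": model_config.__dict__.copy(),
        },
    )


def kfold_cv_table(
    ft: FeatureTable,
    k: int = 10,
    model_config: ModelConfig | None = None,
    seed: int = 0,
    n_boot: int = 1000,
    compute_ci: bool = True,
) -> EvalReport:
    """Cross-validation directly on an already-built feature table.

    Used when features arrive from disk (CLI ``evaluate``); note that any
    normalization baked into such a table was fit once on all stays, so
    prefer :func:`kfold_cv` on grids when leakage control matters.
    """
    model_config = model_config if model_config is not None else ModelConfig()
    stay_ids = list(ft.X.index)
    y = ft.y.to_numpy()
    folds = _fold_assignment(stay_ids, y, k, seed)
    rows = []
    oof_scores = pd.Series(index=ft.X.index, dtype=float)
    for fold_no, (train_idx, test_idx) in enumerate(folds):
        inner_train, inner_val = train_test_split(
            train_idx, test_size=0.2, stratify=y[train_idx], random_state=seed + fold_no
        )

        def _sub(idx) -> FeatureTable:
            return FeatureTable(X=ft.X.iloc[idx], y=ft.y.iloc[idx])

        model = train(_sub(inner_train), _sub(inner_val), model_config)
        test_ft = _sub(test_idx)
        scores = predict(model, test_ft.X)
        y_test = test_ft.y.to_numpy()
        preds = (scores >= model.decision_threshold).astype(int)
        row = {"fold": fold_no, **{m: v for m, v in confusion_metrics(y_test, preds).items() if m != "undefined"}}
        row["auroc"] = auroc(scores, y_test)
        row["auprc"] = auprc(scores, y_test)
        row["brier"] = brier(scores, y_test)
        row["threshold"] = model.decision_threshold
        row["best_iteration"] = model.best_iteration
        rows.append(row)
        oof_scores.iloc[test_idx] = scores
    fold_metrics = pd.DataFrame(rows).set_index("fold")
    metric_cols = list(THRESHOLD_METRICS) + list(SCORE_METRICS)
    summary = {
        m: {"mean": float(fold_metrics[m].mean()), "sd": float(fold_metrics[m].std(ddof=1))}
        for m in metric_cols
    }
    ci = {}
    if compute_ci:
        for m in ("auroc", "auprc"):
            ci[m] = bootstrap_ci(oof_scores.to_numpy(), y, m, n_boot=n_boot, seed=seed)
    return EvalReport(
        fold_metrics=fold_metrics,
        summary=summary,
        ci=ci,
        oof_scores=oof_scores,
        oof_labels=ft.y.copy(),
        config={"k": k, "seed": seed, "n_boot": n_boot, "model": model_config.__dict__.copy()},
    )


def _window_records(records: pd.DataFrame, start: float, T: int) -> pd.DataFrame:
    sel = records[(records["time_hours"] >= start) & (records["time_hours"] < start + T)].copy()
    sel["time_hours"] = sel["time_hours"] - start
    return sel


def lead_time_curve(
    records: pd.DataFrame,
    labels: dict,
    leads=(1, 2, 3, 4, 5, 6),
    T: int = 24,
    model_config: ModelConfig | None = None,
    resolutions=DEFAULT_RESOLUTIONS,
    k: int = 10,
    seed: int = 0,
    ranges: dict | None = None,
    bands: dict | None = None,
    reuse_model: bool = False,
):
    """AUROC as a function of lead time before the event horizon.

    Records must span at least ``T + max(leads) - 1`` hours.  For lead L the
    observation window is re-anchored to end L hours before the (implicit)
    event at one hour past the record span, and the whole pipeline —
    normalization, featurization, training, thresholding — is re-run with
    identical fold assignment, giving paired per-fold AUROCs across leads.
    Stays that lose a whole channel in any re-anchored window are excluded
    everywhere (count logged).

    With ``reuse_model=True`` the model (and normalizer) trained at lead 1
    is reused to score every lead's re-anchored test windows instead of
    retraining per lead.
    """
    model_config = model_config if model_config is not None else ModelConfig()
    span = int(np.ceil(records["time_hours"].max()))
    max_lead = max(leads)
    if span < T + max_lead - 1:
        raise DataError(
            f"records span {span} h but lead {max_lead} with a {T} h window needs {T + max_lead - 1} h"
        )
    grids_per_lead: dict = {}
    bad_stays: set = set()
    for lead in leads:
        start = span - T - (lead - 1)
        windowed = _window_records(records, start, T)
        lead_grids = {}
        for stay_id, stay_records in windowed.groupby("stay_id", sort=True):
            try:
                lead_grids[str(stay_id)] = build_grid(stay_records, str(stay_id), T, ranges, bands)
            except DataError:
                bad_stays.add(str(stay_id))
        missing = set(labels) - set(lead_grids)
        bad_stays |= missing
        grids_per_lead[lead] = lead_grids
    if bad_stays:
        logger.info("lead-time evaluation excluded %d stay(s) with empty windows", len(bad_stays))

    keep = sorted(set(labels) - bad_stays)
    kept_labels = {s: labels[s] for s in keep}
    per_fold = {}
    if reuse_model:
        if 1 not in leads:
            raise ConfigError("reuse_model requires lead 1 (the training anchor) among leads")
        y = np.array([int(kept_labels[s]) for s in keep])
        folds = _fold_assignment(keep, y, k, seed)
        grids1 = grids_per_lead[1]
        per_fold = {lead: [] for lead in leads}
        for fold_no, (train_idx, test_idx) in enumerate(folds):
            model, _, _, stats = _run_fold(
                grids1, keep, y, train_idx, test_idx, model_config, resolutions, seed + fold_no
            )
            test_ids = [keep[i] for i in test_idx]
            y_test = y[test_idx]
            for lead in leads:
                X = featurize_many(
                    (apply_normalizer(grids_per_lead[lead][s], stats) for s in test_ids), resolutions
                )
                per_fold[lead].append(auroc(predict(model, X), y_test))
        per_fold = {lead: pd.Series(v, name="auroc") for lead, v in per_fold.items()}
    else:
        for lead in leads:
            grids = [grids_per_lead[lead][s] for s in keep]
            report = kfold_cv(
                grids,
                kept_labels,
                k=k,
                model_config=model_config,
                resolutions=resolutions,
                seed=seed,
                compute_ci=False,
            )
            per_fold[lead] = report.fold_metrics["auroc"]
    mean_auroc = {lead: float(series.mean()) for lead, series in per_fold.items()}
    return {
        "mean_auroc": mean_auroc,
        "per_fold": pd.DataFrame(per_fold),
        "excluded": len(bad_stays),
    }
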