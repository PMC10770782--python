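"""End-to-end orchestration: simulate -> preprocess -> featurize -> train
-> evaluate (-> lead-time curve, -> attributions)."""

from __future__ import annotations

import logging

import pandas as pd

from cawarn import io as cio
from cawarn.config import PipelineConfig
from cawarn.errors import DataError
from cawarn.evaluate import EvalReport, kfold_cv, lead_time_curve
from cawarn.explain import attribute, temporal_importance, top_features
from cawarn.features import FeatureTable, featurize_many
from cawarn.model import train
from cawarn.preprocess import apply_normalizer, build_grid, fit_normalizer
from cawarn.simulate import generate_cohort
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)


def _load_or_simulate(config: PipelineConfig):
    if config.records_path is not None:
        if config.labels_path is None:
            raise DataError("records_path given without labels_path")
        records = cio.read_observations(config.records_path)
        labels = cio.read_labels(config.labels_path)
        logger.info("loaded %d records for %d stays", len(records), len(labels))
        return records, labels
    cohort = generate_cohort(config.sim)
    logger.info(
        "simulated %d stays (%d CA) with %d records",
        len(cohort.labels),
        sum(cohort.labels.values()),
        len(cohort.records),
    )
    return cohort.records, cohort.labels


def preprocess_cohort(records: pd.DataFrame, labels: dict, config: PipelineConfig):
    """Per-stay preprocessing of the last ``window_hours`` of each record.

    Returns imputed, un-normalized grids keyed by stay; stays whose window
    contains no observation for some channel are excluded (count logged),
    mirroring the exclusion-flow bookkeeping of cohort construction.
    """
    import math

    span = math.ceil(float(records["time_hours"].max()))
    start = float(max(0, span - config.window_hours))
    windowed = records[records["time_hours"] >= start].copy()
    windowed["time_hours"] = (windowed["time_hours"] - start).clip(lower=0.0)
    # Guard against float edge landing exactly on T.
    windowed = windowed[windowed["time_hours"] < config.window_hours]
    grids = {}
    excluded = 0
    for stay_id, stay_records in windowed.groupby("stay_id", sort=True):
        try:
            grids[str(stay_id)] = build_grid(
                stay_records, str(stay_id), config.window_hours, config.ranges, config.bands
            )
        except DataError:
            excluded += 1
    excluded += len(set(labels) - set(grids))
    if excluded:
        logger.info("preprocessing excluded %d stay(s)", excluded)
    kept = {s: labels[s] for s in grids if s in labels}
    return [grids[s] for s in kept], kept


def run_pipeline(config: PipelineConfig):
    """Execute every stage and return (EvalReport, extras).

    ``extras`` carries the interpretability outputs: the top-20 feature
    ranking and the temporal-importance matrix from a model trained on a
    stratified 80/20 split of the whole cohort.  Deterministic given the
    config's seeds.
    """
    records, labels = _load_or_simulate(config)
    grids, kept_labels = preprocess_cohort(records, labels, config)
    report: EvalReport = kfold_cv(
        grids,
        kept_labels,
        k=config.k,
        model_config=config.model,
        resolutions=tuple(config.resolutions),
        seed=config.cv_seed,
        n_boot=config.n_boot,
    )
    report.config["pipeline"] = config.to_dict()

    if config.leads:
        curve = lead_time_curve(
            records,
            kept_labels,
            leads=tuple(config.leads),
            T=config.window_hours,
            model_config=config.model,
            resolutions=tuple(config.resolutions),
            k=config.k,
            seed=config.cv_seed,
            ranges=config.ranges,
            bands=config.bands,
        )
        report.lead_curve = curve["mean_auroc"]

    # Interpretability pass: one model on a stratified split of the cohort.
    stay_ids = [g.stay_id for g in grids]
    y = [kept_labels[s] for s in stay_ids]
    train_ids, val_ids = train_test_split(stay_ids, test_size=0.2, stratify=y, random_state=config.cv_seed)
    by_id = {g.stay_id: g for g in grids}
    stats = fit_normalizer(by_id[s] for s in train_ids)

    def _table(ids) -> FeatureTable:
        X = featurize_many((apply_normalizer(by_id[s], stats) for s in ids), tuple(config.resolutions))
        return FeatureTable(X=X, y=pd.Series([int(kept_labels[s]) for s in X.index], index=X.index, name="label"))

    model = train(_table(train_ids), _table(val_ids), config.model)
    model.normalization = stats
    attr = attribute(model, _table(val_ids))
    extras = {
        "model": model,
        "top_features": top_features(attr, k=min(20, len(model.feature_names))),
        "temporal_importance": temporal_importance(attr),
    }
    return report, extras
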