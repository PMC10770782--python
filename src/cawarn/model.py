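"""Cost-sensitive gradient-boosted tree classifier with Youden-J thresholding.

Arrest events are rare (a few percent of stays), so the boosted ensemble
is trained with per-sample weights that penalize errors on the positive
class (default weight 100).  Boosting monitors AUROC on a held-out
validation split, stops after a patience window without improvement, and
is reset to its best iteration.  The operating threshold is then chosen on
the same validation split by maximizing the Youden J statistic
(sensitivity + specificity - 1).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import lightgbm as lgb
import numpy as np
import pandas as pd

from cawarn.errors import ConfigError, ContractError, DataError
from cawarn.features import FeatureTable
from cawarn.preprocess import NormalizationStats


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the boosted ensemble.

    ``ca_class_weight=100``, ``learning_rate=0.04`` and a 500-round early
    stopping patience are the protocol defaults; tree-shape parameters stay
    at library defaults.  ``single_tree_baseline`` truncates the ensemble
    to one tree, giving the decision-tree reference model.
    """

    ca_class_weight: float = 100.0
    learning_rate: float = 0.04
    early_stopping_rounds: int = 500
    n_trees_max: int = 500
    num_leaves: int = 31
    min_data_in_leaf: int = 20
    max_bin: int = 63
    seed: int = 0
    single_tree_baseline: bool = False

    def __post_init__(self) -> None:
        if self.ca_class_weight <= 0:
            raise ConfigError("ca_class_weight must be > 0")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        if self.early_stopping_rounds < 1:
            raise ConfigError("early_stopping_rounds must be >= 1")
        if self.n_trees_max < 1:
            raise ConfigError("n_trees_max must be >= 1")


@dataclass
class TrainedModel:
    """Fitted ensemble plus everything needed to score new stays."""

    booster: lgb.Booster
    feature_names: list
    decision_threshold: float
    best_iteration: int
    config: ModelConfig
    normalization: NormalizationStats | None = None
    best_val_auroc: float = float("nan")


def _check_classes(y: pd.Series, split: str) -> None:
    if len(set(y.unique())) < 2:
        raise DataError(f"{split} split contains a single class; both classes are required")


def train(train_ft: FeatureTable, val_ft: FeatureTable, config: ModelConfig | None = None) -> TrainedModel:
    """Fit the weighted ensemble with AUROC-monitored early stopping.

    Deterministic given ``config.seed`` (training is single-threaded with
    deterministic histogram construction).
    """
    cfg = config if config is not None else ModelConfig()
    if train_ft.names != val_ft.names:
        raise ContractError("feature names differ between train and validation splits")
    _check_classes(train_ft.y, "training")
    _check_classes(val_ft.y, "validation")

    w_train = np.where(train_ft.y.to_numpy() == 1, cfg.ca_class_weight, 1.0)
    w_val = np.where(val_ft.y.to_numpy() == 1, cfg.ca_class_weight, 1.0)
    dtrain = lgb.Dataset(train_ft.X.to_numpy(), label=train_ft.y.to_numpy(), weight=w_train)
    dval = lgb.Dataset(val_ft.X.to_numpy(), label=val_ft.y.to_numpy(), weight=w_val, reference=dtrain)

    params = {
        "objective": "binary",
        "metric": "auc",
        "learning_rate": cfg.learning_rate,
        "num_leaves": cfg.num_leaves,
        "min_data_in_leaf": cfg.min_data_in_leaf,
        "max_bin": cfg.max_bin,
        "seed": cfg.seed,
        "deterministic": True,
        "force_row_wise": True,
        "num_threads": 1,
        "verbosity": -1,
    }
    n_rounds = 1 if cfg.single_tree_baseline else cfg.n_trees_max
    history: dict = {}
    callbacks = [lgb.record_evaluation(history)]
    if not cfg.single_tree_baseline:
        callbacks.append(lgb.early_stopping(cfg.early_stopping_rounds, verbose=False))
    booster = lgb.train(
        params,
        dtrain,
        num_boost_round=n_rounds,
        valid_sets=[dval],
        valid_names=["valid"],
        callbacks=callbacks,
    )
    val_auc = np.asarray(history["valid"]["auc"], dtype=float)
    # Reset to the iteration with the best validation AUROC, whether or not
    # the patience window triggered.
    best_iteration = int(np.argmax(val_auc)) + 1
    best_val_auroc = float(val_auc[best_iteration - 1])

    val_scores = booster.predict(val_ft.X.to_numpy(), num_iteration=best_iteration)
    threshold = select_threshold_youden(val_scores, val_ft.y.to_numpy())
    return TrainedModel(
        booster=booster,
        feature_names=list(train_ft.names),
        decision_threshold=float(threshold),
        best_iteration=best_iteration,
        config=cfg,
        best_val_auroc=best_val_auroc,
    )


def select_threshold_youden(scores, labels) -> float:
    """Score cut maximizing J = sensitivity + specificity - 1.

    Exhaustive scan over observed score values; a point is predicted
    positive when its score >= threshold.  Ties in J break toward the lower
    threshold (higher sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(set(np.unique(labels))) < 2:
        raise DataError("Youden threshold selection needs both classes")
    order = np.argsort(scores, kind="mergesort")
    s_sorted = scores[order]
    y_sorted = labels[order]
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    cum_pos = np.cumsum(y_sorted == 1)
    cum_neg = np.cumsum(y_sorted == 0)
    candidates = np.unique(s_sorted)
    idx = np.searchsorted(s_sorted, candidates, side="left")  # count of scores < candidate
    pos_below = np.where(idx > 0, cum_pos[idx - 1], 0)
    neg_below = np.where(idx > 0, cum_neg[idx - 1], 0)
    sens = (n_pos - pos_below) / n_pos
    spec = neg_below / n_neg
    j = sens + spec - 1.0
    return float(candidates[int(np.argmax(j))])


def predict(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    """Probability of arrest in the next hour for each row of ``X``.

    Column names must match training names in order — no silent reordering.
    """
    if list(X.columns) != model.feature_names:
        raise ContractError("feature name/order mismatch between input and trained model")
    return model.booster.predict(X.to_numpy(), num_iteration=model.best_iteration)


def classify(model: TrainedModel, X: pd.DataFrame) -> np.ndarray:
    """Binary decision: positive iff probability >= decision threshold."""
    return (predict(model, X) >= model.decision_threshold).astype(int)


def save_model(model: TrainedModel, out_dir) -> None:
    """Persist the ensemble (library-native text) plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model.booster.save_model(str(out / "ensemble.txt"))
    sidecar = {
        "feature_names": model.feature_names,
        "decision_threshold": model.decision_threshold,
        "best_iteration": model.best_iteration,
        "best_val_auroc": model.best_val_auroc,
        "config": asdict(model.config),
    }
    if model.normalization is not None:
        sidecar["normalization"] = {
            "channels": model.normalization.channels,
            "means": model.normalization.means.tolist(),
            "sds": model.normalization.sds.tolist(),
        }
    (out / "model.json").write_text(json.dumps(sidecar, indent=2))


def load_model(in_dir) -> TrainedModel:
    """Inverse of :func:`save_model`; reloaded models score identically."""
    src = Path(in_dir)
    booster = lgb.Booster(model_file=str(src / "ensemble.txt"))
    sidecar = json.loads((src / "model.json").read_text())
    stats = None
    if "normalization" in sidecar:
        ns = sidecar["normalization"]
        stats = NormalizationStats(
            channels=ns["channels"], means=np.array(ns["means"]), sds=np.array(ns["sds"])
        )
    return TrainedModel(
        booster=booster,
        feature_names=sidecar["feature_names"],
        decision_threshold=sidecar["decision_threshold"],
        best_iteration=sidecar["best_iteration"],
        config=ModelConfig(**sidecar["config"]),
        normalization=stats,
        best_val_auroc=sidecar.get("best_val_auroc", float("nan")),
    )
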