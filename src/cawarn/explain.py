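"""Additive per-feature attributions and interpretability summaries.

Attributions are exact tree-path contributions computed by traversing the
fitted ensemble (the polynomial-time tree implementation of Shapley
additive values): for every stay, the base value plus the per-feature
contributions reconstructs the model's raw margin exactly.  Two summaries
mirror common clinical-interpretability reporting: a top-k ranking by mean
absolute attribution, and a temporal heat-map matrix obtained by parsing
hour spans out of the feature-name grammar.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from cawarn.errors import ContractError, DataError
from cawarn.features import FeatureTable
from cawarn.model import TrainedModel

_SPAN_RE = re.compile(r"^(?P<channel>.+)_(?P<start>\d+)-(?P<end>\d+)h_(?P<stat>\w+)$")


@dataclass
class AttributionTable:
    """Per-stay, per-feature additive contributions to the raw margin."""

    values: pd.DataFrame  # index = stay_id, columns = feature names
    base: pd.Series  # per-stay expected raw margin

    @property
    def names(self) -> list:
        return list(self.values.columns)


def attribute(model: TrainedModel, features: FeatureTable) -> AttributionTable:
    """Exact tree-path additive attributions for every stay.

    Satisfies base + sum(contributions) = raw model margin per stay.
    """
    if features.names != model.feature_names:
        raise ContractError("feature name/order mismatch between table and model")
    contrib = model.booster.predict(
        features.X.to_numpy(), num_iteration=model.best_iteration, pred_contrib=True
    )
    values = pd.DataFrame(contrib[:, :-1], index=features.X.index, columns=features.names)
    base = pd.Series(contrib[:, -1], index=features.X.index, name="base")
    return AttributionTable(values=values, base=base)


def top_features(attr: AttributionTable, k: int = 20) -> pd.DataFrame:
    """Features ranked by mean absolute attribution, ties broken by name.

    The default k=20 matches the usual summary size for global feature
    impact reports.
    """
    if attr.values.empty:
        raise DataError("attribution table is empty")
    if k > attr.values.shape[1]:
        raise DataError(f"k={k} exceeds the {attr.values.shape[1]} available features")
    mean_abs = attr.values.abs().mean(axis=0)
    ranked = (
        mean_abs.rename("mean_abs_attribution")
        .reset_index()
        .rename(columns={"index": "feature"})
        .sort_values(["mean_abs_attribution", "feature"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return ranked.head(k)


def temporal_importance(attr: AttributionTable) -> pd.DataFrame:
    """Mean-|attribution| accumulated into (hour-span, channel) cells.

    Hour spans are parsed from the feature-name grammar
    (``RR_18-24h_median`` -> span "18-24h", channel "RR"); names without a
    parseable span (whole-window similarity and weighted-matrix features)
    are collected under an "other" row rather than dropped.
    """
    if attr.values.empty:
        raise DataError("attribution table is empty")
    mean_abs = attr.values.abs().mean(axis=0)
    cells: dict = {}
    for name, value in mean_abs.items():
        m = _SPAN_RE.match(name)
        if m:
            span = f"{m.group('start')}-{m.group('end')}h"
            channel = m.group("channel")
            key = (span, channel)
        else:
            key = ("other", "other")
        cells[key] = cells.get(key, 0.0) + float(value)
    spans = sorted(
        {s for s, _ in cells},
        key=lambda s: (s == "other", int(s.split("-")[0]) if s != "other" else 0, s),
    )
    channels = sorted({c for _, c in cells})
    matrix = pd.DataFrame(0.0, index=pd.Index(spans, name="span"), columns=channels)
    for (span, channel), value in cells.items():
        matrix.loc[span, channel] = value
    return matrix
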