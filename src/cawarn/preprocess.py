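"""From irregular observations to a fully imputed, normalized hourly grid.

The stages mirror standard early-warning data preparation: physiologically
implausible values are removed, observations are averaged into 1-hour
buckets, gaps are filled by nearest-later-value (LOCB) then
nearest-earlier-value (LOCF) imputation, hourly early-warning subscores
(0-3 bands) are derived from temperature and SpO2, and every channel is
z-scored with statistics estimated on training stays only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cawarn.channels import (
    DEFAULT_ACCEPTABLE_RANGES,
    DEFAULT_EWS_BANDS,
    GRID_CHANNELS,
    VITAL_CHANNELS,
)
from cawarn.errors import ConfigError, ContractError, DataError

logger = logging.getLogger(__name__)


@dataclass
class RegularGrid:
    """One stay as a T x C matrix: T hourly steps, C = 9 channels."""

    stay_id: str
    values: np.ndarray  # (T, C), fully imputed
    channels: list

    @property
    def T(self) -> int:
        return self.values.shape[0]


@dataclass
class NormalizationStats:
    """Per-channel mean/SD, estimated on training stays only."""

    channels: list
    means: np.ndarray
    sds: np.ndarray


def remove_outliers(records: pd.DataFrame, ranges: dict | None = None) -> pd.DataFrame:
    """Drop records whose value falls outside the acceptable closed interval.

    Order is preserved; the number of dropped records is logged.
    """
    ranges = ranges if ranges is not None else DEFAULT_ACCEPTABLE_RANGES
    unknown = set(records["channel"].unique()) - set(ranges)
    if unknown:
        raise DataError(f"no acceptable range for channel(s): {sorted(unknown)}")
    lo = records["channel"].map({ch: r[0] for ch, r in ranges.items()})
    hi = records["channel"].map({ch: r[1] for ch, r in ranges.items()})
    keep = (records["value"] >= lo) & (records["value"] <= hi)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("outlier filter removed %d of %d records", dropped, len(records))
    return records.loc[keep]


def bucketize(records: pd.DataFrame, T: int) -> np.ndarray:
    """Average one stay's observations into T 1-hour buckets per channel.

    Returns a (T, 7) array over the vital channels with NaN marking empty
    buckets.  Bucket t covers the half-open interval [t, t+1).
    """
    if T not in (12, 24):
        raise ConfigError("T must be 12 or 24")
    grid = np.full((T, len(VITAL_CHANNELS)), np.nan)
    if len(records) == 0:
        return grid
    times = records["time_hours"].to_numpy()
    if (times < 0).any() or (times >= T).any():
        stays = records.loc[(times < 0) | (times >= T), "stay_id"].unique()
        raise DataError(f"observation time outside [0, {T}) for stay(s): {list(stays)}")
    hour = times.astype(int)
    ch_index = records["channel"].map({ch: i for i, ch in enumerate(VITAL_CHANNELS)})
    if ch_index.isna().any():
        bad = records.loc[ch_index.isna(), "channel"].unique()
        raise DataError(f"unknown channel(s): {list(bad)}")
    values = records["value"].to_numpy(dtype=float)
    sums = np.zeros((T, len(VITAL_CHANNELS)))
    counts = np.zeros((T, len(VITAL_CHANNELS)))
    np.add.at(sums, (hour, ch_index.to_numpy(dtype=int)), values)
    np.add.at(counts, (hour, ch_index.to_numpy(dtype=int)), 1.0)
    with np.errstate(invalid="ignore"):
        grid = np.where(counts > 0, sums / np.where(counts > 0, counts, 1.0), np.nan)
    return grid


def impute(grid: np.ndarray, fallback_means: np.ndarray | None = None, stay_id: str = "?") -> np.ndarray:
    """Fill missing buckets: nearest later value first (LOCB), then nearest
    earlier value for trailing gaps (LOCF).

    A channel with no observation at all raises a :class:`DataError` unless
    ``fallback_means`` supplies a per-channel population mean to use instead
    (the pooled-mean fallback, logged when applied).
    """
    out = np.asarray(grid, dtype=float).copy()
    all_missing = np.isnan(out).all(axis=0)
    if all_missing.any():
        missing_names = [VITAL_CHANNELS[i] for i in np.nonzero(all_missing)[0] if i < len(VITAL_CHANNELS)]
        if fallback_means is None:
            raise DataError(
                f"stay {stay_id}: channel(s) {missing_names or list(np.nonzero(all_missing)[0])} "
                "have no observations; pass fallback means to allow empty channels"
            )
        for i in np.nonzero(all_missing)[0]:
            out[:, i] = fallback_means[i]
        logger.info("stay %s: filled empty channel(s) %s with population means", stay_id, missing_names)
    df = pd.DataFrame(out)
    df = df.bfill().ffill()
    return df.to_numpy()


def ews_subscore(channel: str, value, bands: dict | None = None):
    """Band score in {0,1,2,3} for a TEMP or SPO2 value.

    Scalar in, scalar out; array in, array out.  Values must already be
    inside the acceptable range (run the outlier filter first).
    """
    bands = bands if bands is not None else DEFAULT_EWS_BANDS
    if channel not in bands:
        raise ConfigError(f"no EWS band table for channel {channel}")
    lo, hi = DEFAULT_ACCEPTABLE_RANGES[channel]
    arr = np.asarray(value, dtype=float)
    if (arr < lo).any() or (arr > hi).any():
        raise DataError(f"{channel} value outside acceptable range [{lo}, {hi}]")
    table = bands[channel]
    scores = np.full(arr.shape, table["above"], dtype=int)
    assigned = np.zeros(arr.shape, dtype=bool)
    for bound, score in table["bounds"]:
        mask = (~assigned) & (arr <= bound)
        scores[mask] = score
        assigned |= mask
    return scores if np.ndim(value) else int(scores)


def build_grid(
    records: pd.DataFrame,
    stay_id: str,
    T: int,
    ranges: dict | None = None,
    bands: dict | None = None,
    fallback_means: np.ndarray | None = None,
) -> RegularGrid:
    """Full per-stay preprocessing: filter, bucketize, impute, append EWS.

    The result is the un-normalized 9-channel grid; z-scoring happens
    separately so its statistics can come from training stays only.
    """
    filtered = remove_outliers(records, ranges)
    vitals = impute(bucketize(filtered, T), fallback_means=fallback_means, stay_id=stay_id)
    temp_i = VITAL_CHANNELS.index("TEMP")
    spo2_i = VITAL_CHANNELS.index("SPO2")
    ews_temp = ews_subscore("TEMP", vitals[:, temp_i], bands).astype(float)
    ews_spo2 = ews_subscore("SPO2", vitals[:, spo2_i], bands).astype(float)
    values = np.column_stack([vitals, ews_temp, ews_spo2])
    return RegularGrid(stay_id=stay_id, values=values, channels=list(GRID_CHANNELS))


def cohort_to_grids(
    records: pd.DataFrame,
    T: int,
    ranges: dict | None = None,
    bands: dict | None = None,
) -> dict:
    """Preprocess every stay in a long-format record table.

    Returns ``{stay_id: RegularGrid}``; stays are processed independently.
    """
    grids = {}
    for stay_id, stay_records in records.groupby("stay_id", sort=True):
        grids[str(stay_id)] = build_grid(stay_records, str(stay_id), T, ranges, bands)
    return grids


def fit_normalizer(grids) -> NormalizationStats:
    """Per-channel mean/SD pooled over all training stays and hours."""
    grids = list(grids)
    if len(grids) < 2:
        raise ConfigError("fit_normalizer requires at least 2 training grids")
    channels = grids[0].channels
    for g in grids:
        if g.channels != channels:
            raise ContractError("grids disagree on channel ordering")
    stacked = np.vstack([g.values for g in grids])
    return NormalizationStats(
        channels=list(channels),
        means=stacked.mean(axis=0),
        sds=stacked.std(axis=0),
    )


def apply_normalizer(grid: RegularGrid, stats: NormalizationStats) -> RegularGrid:
    """z = (x - mean) / SD per channel; constant channels map to 0."""
    if grid.channels != stats.channels:
        raise ContractError(
            f"channel ordering mismatch: grid {grid.channels} vs stats {stats.channels}"
        )
    sds = np.where(stats.sds > 0, stats.sds, 1.0)
    z = (grid.values - stats.means) / sds
    z[:, stats.sds == 0] = 0.0
    return RegularGrid(stay_id=grid.stay_id, values=z, channels=list(grid.channels))


def invert_normalizer(grid: RegularGrid, stats: NormalizationStats) -> RegularGrid:
    """Undo :func:`apply_normalizer` (zero-SD channels return their mean)."""
    if grid.channels != stats.channels:
        raise ContractError("channel ordering mismatch")
    x = grid.values * np.where(stats.sds > 0, stats.sds, 0.0) + stats.means
    return RegularGrid(stay_id=grid.stay_id, values=x, channels=list(grid.channels))
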