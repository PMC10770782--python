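"""Synthetic ICU cohorts with irregular vital-sign sampling.

Real early-warning cohorts live in credentialed-access clinical databases,
so every downstream stage is exercised on simulated stays instead.  Each
stay is a stationary Gaussian AR(1) process per channel around a
population baseline, with a configurable shared factor that induces
cross-channel correlation.  Stays labelled as cardiac-arrest (CA)
additionally receive, from a configurable onset before the end of the
record, a linear drift (tachycardia/tachypnoea up, blood pressure and SpO2
down), variance inflation, and optionally a loss of cross-channel
correlation — the kinds of pre-arrest instability the pipeline is built to
detect.

Default channel baselines follow published ICU heart-failure cohort
statistics for the non-CA population (e.g. HR 87.11 bpm, SD 17.22).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from cawarn.channels import VITAL_CHANNELS
from cawarn.errors import ConfigError

# Non-CA population mean (SD) per channel: HR bpm, pressures mmHg, TEMP
# Celsius, RR breaths/min, SpO2 percent.
DEFAULT_CHANNEL_MEANS = {
    "HR": 87.11,
    "SBP": 117.81,
    "DBP": 59.23,
    "MBP": 75.59,
    "TEMP": 36.93,
    "RR": 21.05,
    "SPO2": 96.98,
}
DEFAULT_CHANNEL_SDS = {
    "HR": 17.22,
    "SBP": 21.72,
    "DBP": 14.28,
    "MBP": 14.88,
    "TEMP": 0.71,
    "RR": 5.79,
    "SPO2": 3.11,
}

# Direction of pre-arrest drift per channel (in baseline-SD units).
DRIFT_SIGNS = {"HR": +1.0, "RR": +1.0, "SBP": -1.0, "SPO2": -1.0}

# Lag-1 (hourly) autocorrelation of each channel's latent trajectory.
AR1_RHO = 0.8

# Fraction of innovation variance carried by the shared cross-channel
# factor; equals the stationary cross-channel correlation.
CROSS_CORR = 0.3


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_stays: int = 2000
    ca_fraction: float = 82 / 1981  # observed CA prevalence in the cohort design
    window_hours: int = 24
    obs_rate_per_hour: float = 1.0
    missing_prob: float = 0.1
    channel_means: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_MEANS))
    channel_sds: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_SDS))
    effect_size: float = 2.0
    onset_hours_before_end: float = 3.0
    decouple_channels: bool = False
    lead_reserve_hours: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stays < 1:
            raise ConfigError("n_stays must be >= 1")
        if not 0.0 <= self.ca_fraction <= 1.0:
            raise ConfigError("ca_fraction must lie in [0, 1]")
        if self.window_hours not in (12, 24):
            raise ConfigError("window_hours must be 12 or 24")
        if self.obs_rate_per_hour <= 0:
            raise ConfigError("obs_rate_per_hour must be > 0")
        if not 0.0 <= self.missing_prob < 1.0:
            raise ConfigError("missing_prob must lie in [0, 1)")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.onset_hours_before_end < 0 or self.onset_hours_before_end > self.window_hours:
            raise ConfigError("onset_hours_before_end must lie in [0, window_hours]")
        if self.lead_reserve_hours < 0:
            raise ConfigError("lead_reserve_hours must be >= 0")
        for ch in VITAL_CHANNELS:
            if ch not in self.channel_means:
                raise ConfigError(f"channel_means missing channel {ch}")
            if ch not in self.channel_sds:
                raise ConfigError(f"channel_sds missing channel {ch}")
            if self.channel_sds[ch] <= 0:
                raise ConfigError(f"channel_sds[{ch}] must be > 0")


@dataclass
class CohortSample:
    """Generated records, per-stay CA labels and the config that made them."""

    records: pd.DataFrame  # columns: stay_id, time_hours, channel, value
    labels: dict  # stay_id -> {0, 1}
    truth: SimConfig


def _latent_trajectories(cfg: SimConfig, ca: np.ndarray, span: int, rng: np.random.Generator) -> np.ndarray:
    """Hourly latent z-trajectories, shape (n_stays, span, C), unit variance."""
    n, c = cfg.n_stays, len(VITAL_CHANNELS)
    shared = rng.standard_normal((n, span))
    own = rng.standard_normal((n, span, c))
    w = CROSS_CORR
    mixed = np.sqrt(w) * shared[:, :, None] + np.sqrt(1.0 - w) * own
    if cfg.decouple_channels and cfg.onset_hours_before_end > 0:
        onset = span - cfg.onset_hours_before_end
        hours = np.arange(span)
        late = hours >= onset
        # CA stays lose the shared factor after onset: pure idiosyncratic noise.
        mask = ca[:, None, None] & late[None, :, None]
        mixed = np.where(mask, own, mixed)
    z = np.empty((n, span, c))
    z[:, 0] = mixed[:, 0]
    scale = np.sqrt(1.0 - AR1_RHO**2)
    for t in range(1, span):
        z[:, t] = AR1_RHO * z[:, t - 1] + scale * mixed[:, t]
    return z


def generate_cohort(config: SimConfig) -> CohortSample:
    """Draw one cohort of irregularly sampled stays.

    Deterministic given ``config.seed``.  Records span
    ``window_hours + lead_reserve_hours`` hours; the (implicit) event for CA
    stays sits one hour past the end of the span.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, c = cfg.n_stays, len(VITAL_CHANNELS)
    span = cfg.window_hours + cfg.lead_reserve_hours

    n_ca = int(round(cfg.ca_fraction * n))
    ca = np.zeros(n, dtype=bool)
    ca[rng.choice(n, size=n_ca, replace=False)] = True

    z = _latent_trajectories(cfg, ca, span, rng)

    # Variance inflation after destabilization onset for CA stays.
    if cfg.effect_size > 0 and cfg.onset_hours_before_end > 0:
        onset = span - cfg.onset_hours_before_end
        late = np.arange(span) >= onset
        infl = np.sqrt(1.0 + cfg.effect_size / 2.0)
        z = np.where((ca[:, None] & late[None, :])[:, :, None], z * infl, z)

    # Irregular sampling: Poisson counts per stay-hour-channel, whole
    # buckets dropped with missing_prob, at least one observation kept per
    # stay and channel so imputation is always defined.
    counts = rng.poisson(cfg.obs_rate_per_hour, size=(n, span, c))
    keep = rng.random((n, span, c)) >= cfg.missing_prob
    counts = counts * keep
    empty = counts.sum(axis=1) == 0  # (n, c)
    if empty.any():
        idx_stay, idx_ch = np.nonzero(empty)
        fill_hours = rng.integers(0, span, size=idx_stay.size)
        counts[idx_stay, fill_hours, idx_ch] = 1

    total = int(counts.sum())
    flat = counts.ravel()
    rep = np.repeat(np.arange(flat.size), flat)
    stay_idx = rep // (span * c)
    hour_idx = (rep // c) % span
    ch_idx = rep % c

    times = hour_idx + rng.random(total)
    means = np.array([cfg.channel_means[ch] for ch in VITAL_CHANNELS])
    sds = np.array([cfg.channel_sds[ch] for ch in VITAL_CHANNELS])
    values = means[ch_idx] + sds[ch_idx] * z[stay_idx, hour_idx, ch_idx]

    # Linear pre-arrest drift, evaluated at the continuous observation time.
    if cfg.effect_size > 0 and cfg.onset_hours_before_end > 0:
        onset = span - cfg.onset_hours_before_end
        frac = np.clip((times - onset) / (span - onset), 0.0, None) if span > onset else 0.0
        signs = np.array([DRIFT_SIGNS.get(ch, 0.0) for ch in VITAL_CHANNELS])
        drift = cfg.effect_size * sds[ch_idx] * signs[ch_idx] * frac * ca[stay_idx]
        values = values + drift

    width = len(str(max(n - 1, 1)))
    stay_ids = np.array([f"S{i:0{width}d}" for i in range(n)])
    channels = np.array(VITAL_CHANNELS)

    records = pd.DataFrame(
        {
            "stay_id": stay_ids[stay_idx],
            "time_hours": times,
            "channel": channels[ch_idx],
            "value": values,
        }
    )
    records = records.sort_values(["stay_id", "time_hours", "channel"], kind="mergesort").reset_index(drop=True)
    labels = {sid: int(flag) for sid, flag in zip(stay_ids, ca)}
    return CohortSample(records=records, labels=labels, truth=cfg)


def permute_labels(cohort: CohortSample, seed: int) -> CohortSample:
    """Randomly reassign the existing label multiset across stays.

    The record data are untouched; this is the null-model harness used to
    check that the pipeline finds no signal where none exists.
    """
    if not cohort.labels:
        raise ConfigError("cannot permute labels of an empty cohort")
    rng = np.random.default_rng(seed)
    stay_ids = list(cohort.labels.keys())
    values = np.array([cohort.labels[s] for s in stay_ids])
    permuted = values[rng.permutation(len(values))]
    labels = {s: int(v) for s, v in zip(stay_ids, permuted)}
    return CohortSample(records=cohort.records, labels=labels, truth=replace(cohort.truth))
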