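import math

import numpy as np
import pytest

from cawarn.channels import GRID_CHANNELS
from cawarn.features import (
    DEFAULT_RESOLUTIONS,
    cosine_similarity_matrix,
    feature_names,
    featurize_grid,
    featurize_many,
    segment_stats,
    similarity_aggregate,
    similarity_multires_stats,
    weighted_matrix_features,
    SimilarityMatrices,
)
from cawarn.preprocess import RegularGrid
from conftest import random_grid


# ---------------------------------------------------------------- oracles

def oracle_segment_stats(values, channels, resolutions):
    """Pure-python loop reference for the multiresolution segment block."""
    T = len(values)
    out = {}
    for r in sorted(set(resolutions)):
        if r > T:
            continue
        for i in range(T // r):
            rows = [values[t] for t in range(i * r, (i + 1) * r)]
            for c, ch in enumerate(channels):
                seg = [row[c] for row in rows]
                n = len(seg)
                mean = sum(seg) / n
                srt = sorted(seg)
                median = srt[n // 2] if n % 2 else (srt[n // 2 - 1] + srt[n // 2]) / 2
                sd = math.sqrt(sum((x - mean) ** 2 for x in seg) / n)
                span = f"{i * r}-{(i + 1) * r}h"
                out[f"{ch}_{span}_mean"] = mean
                out[f"{ch}_{span}_median"] = median
                out[f"{ch}_{span}_min"] = min(seg)
                out[f"{ch}_{span}_max"] = max(seg)
                out[f"{ch}_{span}_sd"] = sd
    return out


def oracle_cosine(u, v):
    nu = math.sqrt(sum(x * x for x in u))
    nv = math.sqrt(sum(x * x for x in v))
    if nu == 0 or nv == 0:
        return 0.0
    return sum(a * b for a, b in zip(u, v)) / (nu * nv)


def oracle_row_aggregate(matrix):
    means, sds = [], []
    n = len(matrix)
    for i in range(n):
        off = [matrix[i][j] for j in range(n) if j != i]
        m = sum(off) / len(off)
        means.append(m)
        sds.append(math.sqrt(sum((x - m) ** 2 for x in off) / len(off)))
    return means, sds


def oracle_weighted(values, channels, m_t, m_c):
    out = {}
    T, C = len(values), len(channels)
    for tag, weight in (("W_time", lambda t, c: m_t[t]), ("W_chan", lambda t, c: m_c[c])):
        for c, ch in enumerate(channels):
            col = [values[t][c] * weight(t, c) for t in range(T)]
            mean = sum(col) / T
            srt = sorted(col)
            median = srt[T // 2] if T % 2 else (srt[T // 2 - 1] + srt[T // 2]) / 2
            out[f"{tag}_{ch}_mean"] = mean
            out[f"{tag}_{ch}_median"] = median
            out[f"{tag}_{ch}_min"] = min(col)
            out[f"{tag}_{ch}_max"] = max(col)
            out[f"{tag}_{ch}_sd"] = math.sqrt(sum((x - mean) ** 2 for x in col) / T)
    return out


# ----------------------------------------------------------------- counts

def test_feature_count_24h_default():
    assert len(feature_names(24)) == 823


def test_feature_count_12h_default():
    # resolution 24 exceeds the window and is skipped
    assert len(feature_names(12)) == 438


def test_block_counts_24h():
    g = random_grid(np.random.default_rng(0))
    assert len(segment_stats(g)[0]) == 13 * 5 * 9 == 585
    S = cosine_similarity_matrix(g)
    m_t, s_t, m_c, s_c = similarity_aggregate(S)
    assert len(similarity_multires_stats(m_t, s_t)[0]) == 13 * 5 * 2 == 130
    assert len(weighted_matrix_features(g, S)[0]) == 2 * 9 * 5 == 90


def test_names_unique_and_value_independent():
    names = feature_names(24)
    assert len(set(names)) == len(names)
    rng = np.random.default_rng(1)
    _, n1 = featurize_grid(random_grid(rng))
    _, n2 = featurize_grid(random_grid(rng))
    assert n1 == n2 == names


# ---------------------------------------------------------------- cosine

def test_cosine_trivial_cases():
    values = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]])
    g = RegularGrid(stay_id="x", values=values, channels=["a", "b", "c"])
    S = cosine_similarity_matrix(g)
    assert S.time_level[0, 2] == pytest.approx(1.0)
    assert S.time_level[0, 1] == pytest.approx(0.0)
    assert S.time_level[0, 3] == pytest.approx(-1.0)


def test_cosine_zero_norm_guard():
    values = np.zeros((3, 2))
    values[0] = [1.0, 1.0]
    S = cosine_similarity_matrix(RegularGrid(stay_id="x", values=values, channels=["a", "b"]))
    assert S.time_level[0, 0] == 1.0
    assert S.time_level[1, 1] == 0.0  # zero row: no well-defined self-similarity
    assert S.time_level[0, 1] == 0.0


@pytest.mark.parametrize("seed", range(20))
def test_similarity_invariants_random(seed):
    rng = np.random.default_rng(seed)
    g = random_grid(rng)
    for mat in (cosine_similarity_matrix(g).time_level, cosine_similarity_matrix(g).channel_level):
        np.testing.assert_allclose(mat, mat.T, atol=1e-12)
        assert (np.abs(mat) <= 1.0 + 1e-12).all()
        np.testing.assert_allclose(np.diag(mat), 1.0)


def test_row_aggregate_examples():
    mat = np.array([[1.0, 0.5, 0.9], [0.5, 1.0, 0.1], [0.9, 0.1, 1.0]])
    m, s, _, _ = similarity_aggregate(SimilarityMatrices(time_level=mat, channel_level=mat))
    assert m[0] == pytest.approx(0.7)
    ones = np.ones((4, 4))
    m, s, _, _ = similarity_aggregate(SimilarityMatrices(time_level=ones, channel_level=ones))
    assert (m == 1.0).all() and (s == 0.0).all()


# ----------------------------------------------------- oracle equivalence

@pytest.mark.parametrize("seed", range(10))
def test_all_blocks_match_oracles(seed):
    rng = np.random.default_rng(seed)
    T = int(rng.choice([12, 24]))
    g = RegularGrid(
        stay_id="r", values=rng.standard_normal((T, 9)), channels=list(GRID_CHANNELS)
    )
    vals, names = featurize_grid(g)
    got = dict(zip(names, vals))

    expected = oracle_segment_stats(g.values.tolist(), g.channels, DEFAULT_RESOLUTIONS)
    time_sim = [
        [oracle_cosine(g.values[i], g.values[j]) for j in range(T)] for i in range(T)
    ]
    chan_sim = [
        [oracle_cosine(g.values[:, a], g.values[:, b]) for b in range(9)] for a in range(9)
    ]
    m_t, s_t = oracle_row_aggregate(time_sim)
    m_c, s_c = oracle_row_aggregate(chan_sim)
    pseudo = [[m_t[t], s_t[t]] for t in range(T)]
    expected.update(oracle_segment_stats(pseudo, ["Cos_time_mean", "Cos_time_sd"], DEFAULT_RESOLUTIONS))
    for c, ch in enumerate(g.channels):
        expected[f"Cos_chan_mean_{ch}"] = m_c[c]
        expected[f"Cos_chan_sd_{ch}"] = s_c[c]
    expected.update(oracle_weighted(g.values.tolist(), g.channels, m_t, m_c))

    assert set(got) == set(expected)
    for name in got:
        assert got[name] == pytest.approx(expected[name], abs=1e-10), name


@pytest.mark.parametrize("seed", range(5))
def test_batch_featurizer_matches_per_stay(seed):
    rng = np.random.default_rng(seed)
    grids = [
        RegularGrid(stay_id=f"s{i}", values=rng.standard_normal((24, 9)), channels=list(GRID_CHANNELS))
        for i in range(8)
    ]
    X = featurize_many(grids)
    for g in grids:
        vals, names = featurize_grid(g)
        assert list(X.columns) == names
        np.testing.assert_allclose(X.loc[g.stay_id].to_numpy(), vals, atol=1e-12)


# ------------------------------------------------------------- structure

def test_constant_channel_segment_stats():
    values = np.zeros((24, 9))
    values[:, 2] = 3.5
    g = RegularGrid(stay_id="c", values=values, channels=list(GRID_CHANNELS))
    vals, names = segment_stats(g)
    d = dict(zip(names, vals))
    ch = GRID_CHANNELS[2]
    for stat, expected in [("mean", 3.5), ("median", 3.5), ("min", 3.5), ("max", 3.5), ("sd", 0.0)]:
        assert d[f"{ch}_0-4h_{stat}"] == expected


def test_weighted_identity_and_annihilation():
    rng = np.random.default_rng(2)
    g = random_grid(rng)
    S = cosine_similarity_matrix(g)
    m_t, _, m_c, _ = similarity_aggregate(S)
    vals, names = weighted_matrix_features(g, S)
    d = dict(zip(names, vals))
    # direct check against the definition for one channel
    col = g.values[:, 0] * m_t
    assert d[f"W_time_{g.channels[0]}_mean"] == pytest.approx(col.mean())
    assert d[f"W_time_{g.channels[0]}_sd"] == pytest.approx(col.std())


def test_channel_permutation_permutes_features_consistently():
    rng = np.random.default_rng(3)
    g = random_grid(rng)
    perm = rng.permutation(len(g.channels))
    pg = RegularGrid(
        stay_id=g.stay_id,
        values=g.values[:, perm],
        channels=[g.channels[i] for i in perm],
    )
    a = dict(zip(*reversed(featurize_grid(g))))
    b = dict(zip(*reversed(featurize_grid(pg))))
    assert set(a) == set(b)
    for name in a:
        assert a[name] == pytest.approx(b[name], abs=1e-10), name
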