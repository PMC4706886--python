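"""Block first-order statistics, the feature matrix, and row aggregation."""

import math

import numpy as np
import pytest

from eegmem import (
    FEATURE_NAMES,
    BlockFeatureVector,
    FeatureMatrix,
    TopomapSequence,
    aggregate_feature_matrix,
    block_stats,
    build_feature_matrix,
    concat_feature_matrix,
    feature_set,
    sequence_feature_matrix,
    topomap_feature_vector,
)
from eegmem.errors import ConsistencyError, ParameterError

from conftest import make_topomap, random_sequence


def oracle_stats(values, value_range=None):
    """Direct-summation reference for all five first-order statistics."""
    n = len(values)
    mu = sum(values) / n
    m2 = sum((x - mu) ** 2 for x in values) / n
    m3 = sum((x - mu) ** 3 for x in values) / n
    m4 = sum((x - mu) ** 4 for x in values) / n
    sd = math.sqrt(m2)
    sk = m3 / sd**3 if sd > 0 else 0.0
    ku = m4 / sd**4 if sd > 0 else 0.0
    lo, hi = value_range if value_range else (min(values), max(values))
    if hi <= lo:
        ent = 0.0
    else:
        counts = [0] * 256
        for x in values:
            b = min(int((x - lo) / (hi - lo) * 256), 255)
            counts[b] += 1
        ent = -sum(c / n * math.log2(c / n) for c in counts if c)
    return [mu, sd, ent, sk, ku]


class TestFeatureSet:
    def test_count_prefixes(self):
        assert feature_set(1) == ("mean",)
        assert feature_set(2) == ("mean", "standard_deviation")
        assert feature_set(5) == FEATURE_NAMES

    def test_subset_reordered_canonically(self):
        assert feature_set(["kurtosis", "mean"]) == ("mean", "kurtosis")

    def test_invalid(self):
        with pytest.raises(ParameterError):
            feature_set(0)
        with pytest.raises(ParameterError):
            feature_set(["sparkle"])
        with pytest.raises(ParameterError):
            feature_set([])


class TestBlockStats:
    def test_constant_block_degenerate_values(self):
        out = block_stats(np.full(30, 4.2))
        np.testing.assert_allclose(out, [4.2, 0.0, 0.0, 0.0, 0.0], atol=1e-12)

    def test_symmetric_block_zero_skew(self):
        out = block_stats(np.array([-1.0, 1.0] * 20), features=["skewness"])
        assert out[0] == pytest.approx(0.0, abs=1e-12)

    def test_random_block_matches_oracle(self, rng):
        vals = rng.normal(size=20)
        out = block_stats(vals)
        np.testing.assert_allclose(out, oracle_stats(list(vals)), atol=1e-10)

    def test_entropy_uses_supplied_range(self, rng):
        vals = rng.normal(size=50)
        wide = (vals.min() - 10, vals.max() + 10)
        narrow = block_stats(vals, features=["entropy"])[0]
        widened = block_stats(vals, features=["entropy"], value_range=wide)[0]
        assert narrow != pytest.approx(widened)  # range matters
        assert widened == pytest.approx(oracle_stats(list(vals), wide)[2], abs=1e-10)

    def test_empty_block_all_zero(self):
        np.testing.assert_array_equal(block_stats(np.array([])), np.zeros(5))


class TestTopomapFeatureVector:
    @pytest.mark.parametrize(
        "grid,b,f,expected",
        [(64, 16, 5, 1280), (64, 8, 1, 64), (32, 8, 2, 128)],
    )
    def test_dimension(self, rng, grid, b, f, expected):
        tmap = make_topomap(rng.normal(size=(grid, grid)))
        assert len(topomap_feature_vector(tmap, b, f)) == expected

    def test_constant_unmasked_map_mean_feature(self):
        tmap = make_topomap(np.full((64, 64), 7.0))
        vec = topomap_feature_vector(tmap, 8, 1)
        np.testing.assert_allclose(vec.values, 7.0)

    def test_masked_corner_blocks_emit_zero(self):
        xx, yy = np.meshgrid(np.linspace(-1, 1, 64), np.linspace(-1, 1, 64))
        mask = xx**2 + yy**2 <= 1
        tmap = make_topomap(np.full((64, 64), 7.0), mask)
        vec = topomap_feature_vector(tmap, 8, 1).values.reshape(8, 8)
        assert vec[0, 0] == 0.0 and vec[-1, -1] == 0.0  # corners fully masked
        assert vec[3, 3] == pytest.approx(7.0)

    def test_matches_per_block_stats(self, rng):
        pix = rng.normal(size=(16, 16))
        tmap = make_topomap(pix)
        vec = topomap_feature_vector(tmap, 4, 5).values.reshape(16, 5)
        vrange = (pix.min(), pix.max())
        k = 0
        for r in range(4):
            for c in range(4):
                block = pix[r * 4 : (r + 1) * 4, c * 4 : (c + 1) * 4].ravel()
                np.testing.assert_allclose(
                    vec[k], block_stats(block, value_range=vrange), atol=1e-10
                )
                k += 1

    def test_incompatible_blocks(self, rng):
        tmap = make_topomap(rng.normal(size=(8, 8)))
        with pytest.raises(ParameterError):
            topomap_feature_vector(tmap, 16, 1)


class TestFeatureMatrix:
    def test_single_vector_column(self, rng):
        v = BlockFeatureVector(rng.normal(size=6), time_index=0)
        fm = build_feature_matrix([v])
        np.testing.assert_array_equal(fm.values[:, 0], v.values)
        assert fm.values.shape == (6, 1)

    def test_paper_scale_shape(self, rng):
        vecs = [
            BlockFeatureVector(rng.normal(size=1280), time_index=t) for t in range(150)
        ]
        assert build_feature_matrix(vecs).values.shape == (1280, 150)

    def test_ragged_rejected(self, rng):
        vecs = [BlockFeatureVector(rng.normal(size=4)), BlockFeatureVector(rng.normal(size=5))]
        with pytest.raises(ConsistencyError):
            build_feature_matrix(vecs)

    def test_sequence_matrix_equals_stacked_vectors(self, rng):
        seq = random_sequence(rng, 5, side=16)
        fm = sequence_feature_matrix(seq, 4, 5)
        stacked = build_feature_matrix(
            [topomap_feature_vector(m, 4, 5) for m in seq.maps]
        )
        np.testing.assert_allclose(fm.values, stacked.values, atol=1e-12)


class TestAggregation:
    def test_dimension_is_4s_independent_of_L(self, rng):
        for L in (2, 7, 150):
            fm = FeatureMatrix(rng.normal(size=(1280, L)))
            assert len(aggregate_feature_matrix(fm)) == 5120

    def test_identical_columns_degenerate(self, rng):
        col = rng.normal(size=6)
        fm = FeatureMatrix(np.tile(col[:, None], (1, 4)))
        out = aggregate_feature_matrix(fm).values.reshape(6, 4)
        np.testing.assert_allclose(out[:, 0], col, atol=1e-12)  # mu = row value
        np.testing.assert_allclose(out[:, 1:], 0.0, atol=1e-12)  # delta, sk, k

    def test_matches_oracle_per_row(self, rng):
        fm = FeatureMatrix(rng.normal(size=(3, 4)))
        out = aggregate_feature_matrix(fm).values.reshape(3, 4)
        for i in range(3):
            mu, sd, _, sk, ku = oracle_stats(list(fm.values[i]))
            np.testing.assert_allclose(out[i], [mu, sd, sk, ku], atol=1e-10)

    def test_column_permutation_invariance(self, rng):
        fm = FeatureMatrix(rng.normal(size=(10, 8)))
        perm = rng.permutation(8)
        a = aggregate_feature_matrix(fm).values
        b = aggregate_feature_matrix(FeatureMatrix(fm.values[:, perm])).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_scale_covariance(self, rng):
        """Scaling pixels by c>0 scales mean/SD features by c and leaves
        entropy, skewness and kurtosis features unchanged."""
        seq = random_sequence(rng, 4, side=16)
        c = 3.7
        scaled = TopomapSequence(
            "q",
            tuple(make_topomap(m.pixels * c, m.mask, m.time_index) for m in seq.maps),
        )
        a = sequence_feature_matrix(seq, 4, 5).values.reshape(16, 5, 4)
        b = sequence_feature_matrix(scaled, 4, 5).values.reshape(16, 5, 4)
        np.testing.assert_allclose(b[:, 0], c * a[:, 0], atol=1e-9)  # mean
        np.testing.assert_allclose(b[:, 1], c * a[:, 1], atol=1e-9)  # SD
        np.testing.assert_allclose(b[:, 2:], a[:, 2:], atol=1e-9)  # ent, sk, ku


class TestConcatenation:
    def test_column_major_enumeration(self):
        fm = FeatureMatrix(np.array([[1.0, 3.0], [2.0, 4.0]]))
        np.testing.assert_array_equal(concat_feature_matrix(fm), [1, 2, 3, 4])

    def test_single_column(self, rng):
        col = rng.normal(size=5)
        np.testing.assert_array_equal(
            concat_feature_matrix(FeatureMatrix(col[:, None])), col
        )

    def test_paper_scale_length(self):
        fm = FeatureMatrix(np.zeros((1280, 100)))
        assert concat_feature_matrix(fm).size == 128000
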