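import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecsim
from ecsim import (
    INDEX_NAMES,
    ColumnSumVector,
    CounterSet,
    NormalizedMatrix,
    classify_counters,
    column_sums,
    extended_similarity,
    normalize,
    pairwise_similarity,
    resolve_index,
    resolve_indices,
    similarity_of_set,
)

from oracles import classical_binary_index, contingency_counts


class TestNormalize:
    @pytest.mark.parametrize("raw, expected, lo, hi", [
        ([[0, 2], [4, 2]], [[0, 0.5], [1, 0.5]], 0, 4),
        ([[0, 1], [1, 0]], [[0, 1], [1, 0]], 0, 1),   # already in {0,1}
        ([[3, 3], [3, 3]], [[0, 0], [0, 0]], 3, 3),   # degenerate constant
    ])
    def test_min_max_scaling(self, raw, expected, lo, hi):
        norm = normalize(np.array(raw, dtype=float))
        np.testing.assert_allclose(norm.values, expected)
        assert (norm.global_min, norm.global_max) == (lo, hi)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            normalize(np.array([[0.0, np.nan]]))

    def test_original_recoverable(self, rng):
        raw = rng.normal(5, 3, size=(7, 12))
        norm = normalize(raw)
        span = norm.global_max - norm.global_min
        np.testing.assert_allclose(norm.values * span + norm.global_min, raw)


class TestColumnSums:
    def test_basic_and_single_frame(self):
        norm = NormalizedMatrix(values=np.array([[0, 0.5], [1, 0.5]]),
                                global_min=0, global_max=4, n_objects=2)
        cs = column_sums(norm)
        np.testing.assert_allclose(cs.sums, [1.0, 1.0])
        assert cs.n_objects == 2
        single = NormalizedMatrix(values=np.array([[0.2, 0.8]]),
                                  global_min=0, global_max=1, n_objects=1)
        np.testing.assert_allclose(column_sums(single).sums, [0.2, 0.8])

    def test_identical_rows_scale_linearly(self, rng):
        row = rng.random(9)
        norm = NormalizedMatrix(values=np.tile(row, (5, 1)), global_min=0,
                                global_max=1, n_objects=5)
        np.testing.assert_allclose(column_sums(norm).sums, 5 * row)


class TestClassifyCounters:
    def test_hand_worked_example(self):
        cs = ColumnSumVector(sums=np.array([2.0, 0.0, 1.0, 1.6]), n_objects=2)
        c = classify_counters(cs, gamma=0.0, weighted=False)
        assert (c.a, c.d, c.bc, c.p) == (2, 1, 1, 4)

    def test_balanced_column_is_dissimilar(self):
        # Delta = 0 is never > gamma = 0
        cs = ColumnSumVector(sums=np.array([1.0, 1.0]), n_objects=2)
        c = classify_counters(cs, gamma=0.0)
        assert (c.a, c.d, c.bc) == (0, 0, 2)

    def test_rejects_single_object(self):
        with pytest.raises(ValueError, match="fewer than two"):
            classify_counters(ColumnSumVector(sums=np.array([0.5]),
                                              n_objects=1))

    @given(st.integers(2, 30), st.integers(1, 40), st.integers(0, 10 ** 6))
    @settings(max_examples=60, deadline=None)
    def test_count_partition(self, n, m, seed):
        """Nonweighted counters always partition the m columns."""
        rng = np.random.default_rng(seed)
        sums = rng.random(m) * n
        c = classify_counters(ColumnSumVector(sums=sums, n_objects=n))
        assert c.a + c.d + c.bc == m == c.p

    def test_weighted_family_partitions_to_its_own_total(self, rng):
        sums = rng.random(25) * 6
        c = classify_counters(ColumnSumVector(sums=sums, n_objects=6),
                              weighted=True)
        assert c.a + c.d + c.bc == pytest.approx(c.p)
        assert (c.a, c.d, c.bc) == (c.w_a, c.w_d, c.w_bc)


class TestExtendedSimilarity:
    def test_binary_counter_values(self):
        # counters of e.g. rows [1,1,0,1] and [1,0,0,1]
        c = CounterSet(a=2, d=1, bc=1, p=4)
        assert extended_similarity(c, "JT") == pytest.approx(2 / 3)
        assert extended_similarity(c, "RT") == pytest.approx(0.6)
        assert extended_similarity(c, "SM") == pytest.approx(0.75)
        assert extended_similarity(c, "CT2") == pytest.approx(
            (math.log(5) - math.log(2)) / math.log(5))

    def test_perfect_similarity_limit(self):
        c = CounterSet(a=30, d=0, bc=0, p=30)
        for name in ("JT", "RT", "SM", "RR", "CT2"):
            assert extended_similarity(c, name) == 1.0

    def test_total_dissimilarity_limit(self):
        c = CounterSet(a=0, d=0, bc=30, p=30)
        for name in ("JT", "CT2", "SM"):
            assert extended_similarity(c, name) == 0.0

    def test_zero_over_zero_returns_zero(self):
        c = CounterSet(a=0, d=5, bc=0, p=5)
        assert extended_similarity(c, "JT") == 0.0
        assert extended_similarity(c, "Gle") == 0.0

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    @settings(max_examples=120, deadline=None)
    def test_range_on_integer_counters(self, a, d, bc):
        if a + d + bc == 0:
            return
        c = CounterSet(a=a, d=d, bc=bc, p=a + d + bc)
        for name in INDEX_NAMES:
            assert 0.0 <= extended_similarity(c, name) <= 1.0

    def test_monotone_in_a_at_fixed_d_bc(self):
        """More 1-coincidence strictly raises JT, RR, CT3, CT4."""
        for name in ("JT", "RR", "CT3", "CT4"):
            for d in (0, 3):
                for bc in (1, 4):
                    vals = [extended_similarity(
                        CounterSet(a=a, d=d, bc=bc, p=a + d + bc), name)
                        for a in range(0, 8)]
                    assert all(x < y for x, y in zip(vals, vals[1:])), name


class TestSetAndPairwise:
    def test_matches_classical_tanimoto_on_bits(self):
        value = similarity_of_set(np.array([[1, 1, 0, 1], [1, 0, 0, 1]],
                                           dtype=float), "JT")
        assert value == pytest.approx(2 / 3)

    def test_identical_extreme_rows(self):
        frames = np.tile([1.0, 0.0, 1.0, 1.0], (4, 1))
        assert similarity_of_set(frames, "SM") == 1.0

    def test_row_permutation_invariance(self, rng):
        frames = rng.random((8, 10))
        perm = rng.permutation(8)
        for name in ("RT", "CT2", "JT"):
            assert similarity_of_set(frames, name) == pytest.approx(
                similarity_of_set(frames[perm], name), abs=1e-14)

    def test_column_permutation_invariance(self, rng):
        frames = rng.random((6, 12))
        perm = rng.permutation(12)
        for name in INDEX_NAMES:
            assert similarity_of_set(frames, name) == pytest.approx(
                similarity_of_set(frames[:, perm], name), abs=1e-14)

    def test_pairwise_complementary_bits(self):
        assert pairwise_similarity([1.0, 0.0], [0.0, 1.0], "JT") == 0.0

    def test_pairwise_identical_extreme_rows(self):
        row = [1.0, 0.0, 1.0]
        for name in ("SM", "RT"):
            assert pairwise_similarity(row, row, name) == 1.0

    def test_pairwise_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            pairwise_similarity([0.0, 1.0], [0.0, 1.0, 0.5], "JT")

    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=80, deadline=None)
    def test_binary_limit_equals_contingency_oracle(self, seed):
        """For {0,1} rows every extended index equals its classical
        pairwise coefficient computed independently by bit counting."""
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, 30)
        y = rng.integers(0, 2, 30)
        a, d, bc, p = contingency_counts(x, y)
        for name in INDEX_NAMES:
            expected = classical_binary_index(name, a, d, bc, p)
            got = pairwise_similarity(x.astype(float), y.astype(float), name)
            assert got == pytest.approx(expected, abs=1e-12), name

    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=60, deadline=None)
    def test_l1_distance_ordering_preserved_by_normalization(self, seed):
        """Min-max scaling is affine with positive slope, so the relative
        ordering of inter-frame L1 distances is untouched (the consistency
        requirement that justifies this normalization)."""
        rng = np.random.default_rng(seed)
        frames = rng.normal(0, 5, size=(4, 15))
        norm = normalize(frames).values
        raw_1 = np.abs(frames[0] - frames[1]).sum()
        raw_2 = np.abs(frames[2] - frames[3]).sum()
        scaled_1 = np.abs(norm[0] - norm[1]).sum()
        scaled_2 = np.abs(norm[2] - norm[3]).sum()
        assert np.sign(raw_1 - raw_2) == np.sign(scaled_1 - scaled_2)


class TestIndexNames:
    def test_case_insensitive_resolution(self):
        assert resolve_index("jt") == "JT"
        assert resolve_index("bub") == "BUB"
        assert resolve_index(" Ct2 ") == "CT2"

    def test_all_expands_to_sixteen(self):
        assert resolve_indices("all") == list(INDEX_NAMES)
        assert resolve_indices("rt,ct2") == ["RT", "CT2"]

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown similarity index"):
            resolve_index("tanimoto9000")
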