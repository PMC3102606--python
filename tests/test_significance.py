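"""The compression-based significance test: coder, penalties, d-score."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rme.exceptions import (
    DegenerateBackgroundError,
    ModuleTooSmallError,
)
from rme.significance import (
    EncodingState,
    SignificanceConfig,
    background_frequency,
    d_score,
    encoding_gain,
    log_star,
    rme_cell_probability,
    sort_submatrix,
)

from conftest import make_matrix


def trace_oracle(rows, p_null, eps):
    """Independent step-trace of the RME coder.

    Recomputes every quantity (column/row remaining counts, row-has-one flag,
    the Bayes-posterior denominator) from scratch at each cell by scanning the
    already-visited prefix, so it shares no state-update code with the
    implementation under test.
    """
    k, m = len(rows), len(rows[0])
    col_tot = [sum(r[j] for r in rows) for j in range(m)]
    row_tot = [sum(r) for r in rows]
    d = 0.0
    observed = []  # (i, j, x) in visiting order
    for i in range(k):
        for j in range(m):
            obs_col = [
                sum(1 for (oi, oj, ox) in observed if oj == jj and ox == 1)
                for jj in range(m)
            ]
            obs_row_ones = sum(1 for (oi, oj, ox) in observed if oi == i and ox == 1)
            a_j = col_tot[j] - obs_col[j]
            b_i = row_tot[i] - obs_row_ones
            if obs_row_ones > 0 or a_j == 0 or b_i == 0:
                p = eps
            else:
                denom = sum(col_tot[jj] - obs_col[jj] for jj in range(j, m))
                p = min(max(a_j / denom, eps), 1 - eps)
            x = rows[i][j]
            if x == 1:
                d += math.log2(p) - math.log2(p_null)
            else:
                d += math.log2(1 - p) - math.log2(1 - p_null)
            observed.append((i, j, x))
    return d


class TestLogStar:
    def test_base_case_is_constant_only(self):
        assert log_star(1) == pytest.approx(math.log2(2.865064))

    def test_value_at_two(self):
        # log2(2.865064) + 1
        assert log_star(2) == pytest.approx(2.5186, abs=1e-4)

    def test_monotone_over_wide_range(self):
        values = [log_star(x) for x in range(1, 10_001)]
        assert all(b >= a for a, b in zip(values, values[1:]))

    def test_domain_error_below_one(self):
        with pytest.raises(ValueError):
            log_star(0)


class TestBackgroundFrequency:
    def test_two_ones_in_two_by_two(self):
        assert background_frequency(make_matrix([[1, 0], [0, 1]])) == 0.5

    def test_gbm_scale_arithmetic(self):
        # 145 samples averaging 13.38 aberrant genes over 1290 genes
        rows = np.zeros((145, 1290), dtype=np.int8)
        total = round(13.38 * 145)
        flat = np.unravel_index(np.arange(total) * 7919 % rows.size, rows.shape)
        rows[flat] = 1
        assert rows.sum() == total
        m = make_matrix(rows.tolist())
        assert background_frequency(m) == pytest.approx(13.38 / 1290, rel=1e-3)

    def test_permutation_invariance(self, tiny_matrix):
        p = background_frequency(tiny_matrix)
        shuffled = make_matrix(
            tiny_matrix.values[::-1, ::-1].tolist(),
            samples=tiny_matrix.samples[::-1],
            genes=tiny_matrix.genes[::-1],
        )
        assert background_frequency(shuffled) == p

    def test_degenerate_matrices_rejected(self):
        with pytest.raises(DegenerateBackgroundError):
            background_frequency(make_matrix([[0, 0]]))
        with pytest.raises(DegenerateBackgroundError):
            background_frequency(make_matrix([[1, 1]]))


class TestSortSubmatrix:
    def test_distinct_counts_cost_nothing_in_tie_groups_mode(self):
        sub = np.array([[1, 1], [1, 0], [0, 0]])
        cfg = SignificanceConfig(sort_penalty_mode="tie_groups")
        sorted_sub, bits = sort_submatrix(sub, cfg)
        assert bits == 0.0
        assert np.array_equal(sorted_sub, sub)

    def test_tied_rows_cost_log2_factorial(self):
        sub = np.array([[1, 1], [1, 1], [1, 0]])  # row sums 2,2,1; col sums 3,2
        cfg = SignificanceConfig(sort_penalty_mode="tie_groups")
        _, bits = sort_submatrix(sub, cfg)
        assert bits == pytest.approx(1.0)  # log2(2!)

    def test_full_permutation_mode(self):
        sub = np.zeros((3, 2), dtype=int)
        sub[0, 0] = 1
        cfg = SignificanceConfig(sort_penalty_mode="full_permutation")
        _, bits = sort_submatrix(sub, cfg)
        assert bits == pytest.approx(math.log2(6) + 1.0)

    def test_canonicalisation_under_input_permutation(self):
        rng = np.random.default_rng(5)
        sub = (rng.random((6, 3)) < 0.4).astype(int)
        labels_s = [f"s{i}" for i in range(6)]
        labels_g = ["gA", "gB", "gC"]
        ref, ref_bits = sort_submatrix(sub, sample_labels=labels_s, gene_labels=labels_g)
        perm_r = rng.permutation(6)
        perm_c = rng.permutation(3)
        shuffled = sub[perm_r][:, perm_c]
        out, bits = sort_submatrix(
            shuffled,
            sample_labels=[labels_s[i] for i in perm_r],
            gene_labels=[labels_g[j] for j in perm_c],
        )
        assert np.array_equal(out, ref)
        assert bits == ref_bits


class TestCellProbability:
    def test_row_with_observed_one_gets_epsilon(self):
        state = EncodingState.for_submatrix(np.array([[1, 1]]))
        state.observe((0, 0), 1)
        cfg = SignificanceConfig(epsilon=1e-6)
        assert rme_cell_probability(state, (0, 1), cfg) == 1e-6

    def test_even_split_default(self):
        state = EncodingState.for_submatrix(np.array([[1, 0]]))
        # totals per gene (1, 1) before observation: imagine both columns open
        state.per_gene_remaining = np.array([1, 1])
        state.per_sample_remaining = np.array([1])
        assert rme_cell_probability(state, (0, 0)) == pytest.approx(0.5)

    def test_exhausted_gene_gets_epsilon(self):
        state = EncodingState.for_submatrix(np.array([[0, 1]]))
        cfg = SignificanceConfig(epsilon=1e-5)
        assert rme_cell_probability(state, (0, 0), cfg) == 1e-5

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.lists(st.integers(0, 1), min_size=3, max_size=3),
                    min_size=2, max_size=5))
    def test_probability_always_in_open_interval(self, rows):
        state = EncodingState.for_submatrix(np.array(rows))
        for j in range(3):
            p = rme_cell_probability(state, (0, j))
            assert 0 < p < 1
            assert 0 < 1 - p < 1


class TestEncodingGain:
    def test_empty_submatrix(self):
        assert encoding_gain(np.zeros((0, 0)), 0.1) == 0.0

    def test_matches_independent_trace_on_3x2(self):
        rows = [[1, 0], [0, 1], [0, 0]]
        cfg = SignificanceConfig(epsilon=2**-10)
        got = encoding_gain(np.array(rows), 0.25, cfg)
        assert got == pytest.approx(trace_oracle(rows, 0.25, 2**-10), abs=1e-9)
        assert got == pytest.approx(4.653102145842018, abs=1e-9)

    def test_matches_independent_trace_on_4x3(self):
        rows = [[1, 1, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]
        cfg = SignificanceConfig(epsilon=1e-4)
        got = encoding_gain(np.array(rows), 0.1, cfg)
        assert got == pytest.approx(trace_oracle(rows, 0.1, 1e-4), abs=1e-9)
        assert got == pytest.approx(0.4779049396498327, abs=1e-9)

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(2, 4).flatmap(
               lambda w: st.lists(
                   st.lists(st.integers(0, 1), min_size=w, max_size=w),
                   min_size=2, max_size=6)),
           st.floats(0.01, 0.4))
    def test_matches_trace_on_random_patterns(self, rows, p_null):
        cfg = SignificanceConfig(epsilon=1e-5)
        got = encoding_gain(np.array(rows), p_null, cfg)
        assert got == pytest.approx(trace_oracle(rows, p_null, 1e-5), abs=1e-9)

    def test_state_conservation_after_encoding(self):
        rows = np.array([[1, 1, 0], [1, 0, 0], [0, 1, 1]])
        state = EncodingState.for_submatrix(rows)
        assert state.remaining_mutations == state.per_gene_remaining.sum()
        assert state.remaining_mutations == state.per_sample_remaining.sum()
        for cell, value in [((0, 0), 1), ((0, 1), 1), ((0, 2), 0)]:
            state.observe(cell, value)
            assert state.per_gene_remaining.sum() == state.per_sample_remaining.sum()
            assert state.remaining_mutations == state.per_gene_remaining.sum()

    def test_perfect_exclusive_module_compresses(self):
        # full-coverage three-gene pattern over 100 samples, GBM-like background
        rows = np.zeros((100, 3), dtype=int)
        for i in range(100):
            rows[i, i % 3] = 1
        assert encoding_gain(rows, 13.38 / 1290) > 0


class TestDScore:
    def test_significance_at_fifty_bits(self):
        assert 2.0**-50 == pytest.approx(8.88e-16, rel=1e-3)

    def test_all_zero_module_capped_at_one(self):
        rows = np.zeros((6, 4), dtype=int)
        rows[0, 3] = 1  # keep the background non-degenerate
        m = make_matrix(rows.tolist())
        b = d_score(m, ["g0", "g1"], n_total=100)
        assert b.d <= 0
        assert b.significance == 1.0

    def test_breakdown_identity(self, tiny_matrix):
        b = d_score(tiny_matrix, ["gA", "gB"], n_total=50)
        recomputed = (
            b.d_prime
            - b.gene_identity_bits
            - b.sample_count_bits
            - b.gene_count_bits
            - b.sort_bits
        )
        assert b.d == pytest.approx(recomputed)
        assert b.gene_identity_bits == pytest.approx(2 * math.log2(50))

    def test_module_too_small(self, tiny_matrix):
        with pytest.raises(ModuleTooSmallError):
            d_score(tiny_matrix, ["gA"], n_total=50)

    def test_invariant_to_input_ordering(self):
        rng = np.random.default_rng(11)
        rows = (rng.random((12, 5)) < 0.3).astype(int)
        rows[0, 0] = 1  # non-degenerate
        m = make_matrix(rows.tolist())
        ref = d_score(m, ["g1", "g3", "g4"], n_total=40).d
        perm_r = rng.permutation(12)
        perm_c = rng.permutation(5)
        shuffled = make_matrix(
            rows[perm_r][:, perm_c].tolist(),
            samples=[f"s{i}" for i in perm_r],
            genes=[f"g{j}" for j in perm_c],
        )
        assert d_score(shuffled, ["g1", "g3", "g4"], n_total=40).d == pytest.approx(ref)
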