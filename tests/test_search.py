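"""Template formation, row inclusion, and bicluster enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nibclust import (
    BinaryMatrix,
    Bicluster,
    BiclusterSet,
    SearchParams,
    ValidationError,
    build_submask_table,
    encode_matrix,
    enumerate_biclusters,
    make_template,
    remove_symmetric,
    row_matches_template,
)
from nibclust.oracle import reference_pairwise_and

from conftest import random_binary


class TestTemplate:
    def test_nibblewise_and_example(self):
        enc = encode_matrix(
            BinaryMatrix(
                np.array([[0, 1, 0, 1, 1, 1, 0, 0], [0, 1, 1, 1, 1, 0, 0, 0]])
            )
        )
        t = make_template(enc, 0, 1)
        assert t.nibbles == (5, 8)
        assert t.width == 3
        assert t.columns == (1, 3, 4)

    def test_zero_row_absorbs(self, rng):
        rows = np.vstack([(rng.random(12) < 0.7).astype(np.uint8), np.zeros(12, np.uint8)])
        t = make_template(encode_matrix(BinaryMatrix(rows)), 0, 1)
        assert t.width == 0 and t.columns == ()

    def test_bad_seed_pair_rejected(self, rng):
        enc = encode_matrix(random_binary(rng, 4, 8, 0.5))
        with pytest.raises(IndexError):
            make_template(enc, 2, 2)
        with pytest.raises(IndexError):
            make_template(enc, 1, 7)

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_template_equals_bitwise_and_of_rows(self, data):
        m = data.draw(st.integers(4, 16))
        bits = data.draw(
            st.lists(st.lists(st.integers(0, 1), min_size=m, max_size=m),
                     min_size=2, max_size=2)
        )
        mat = BinaryMatrix(np.array(bits))
        t = make_template(encode_matrix(mat), 0, 1)
        expected_cols = tuple(
            c for c in range(m) if bits[0][c] and bits[1][c]
        )
        assert t.columns == expected_cols
        assert t.width == len(expected_cols)


class TestRowMatch:
    def test_submask_pass(self):
        enc = encode_matrix(BinaryMatrix(np.array([[0, 1, 0, 1, 1, 1, 0, 0]] * 2)))
        t = make_template(enc, 0, 1)
        row = np.array([7, 12], dtype=np.uint8)
        ok, checks = row_matches_template(row, t)
        assert ok and checks == 2

    def test_early_exit_at_first_failure(self):
        enc = encode_matrix(BinaryMatrix(np.array([[0, 1, 0, 1, 1, 0, 0, 0]] * 2)))
        t = make_template(enc, 0, 1)  # nibbles (5, 8)
        ok, checks = row_matches_template(np.array([3, 15], dtype=np.uint8), t)
        assert not ok and checks == 1

    def test_length_mismatch_rejected(self):
        enc = encode_matrix(BinaryMatrix(np.ones((2, 8), dtype=np.uint8)))
        t = make_template(enc, 0, 1)
        with pytest.raises(ValidationError):
            row_matches_template(np.array([1], dtype=np.uint8), t)

    @given(st.data())
    @settings(max_examples=80, deadline=None)
    def test_agrees_with_bitwise_oracle(self, data):
        m = data.draw(st.integers(4, 20))
        t_bits = data.draw(st.lists(st.integers(0, 1), min_size=m, max_size=m))
        r_bits = data.draw(st.lists(st.integers(0, 1), min_size=m, max_size=m))
        mat = BinaryMatrix(np.array([t_bits, t_bits, r_bits]))
        enc = encode_matrix(mat)
        t = make_template(enc, 0, 1)
        ok, _ = row_matches_template(enc.rows[2], t)
        # oracle: template AND row == template, at bit level
        expected = all(not tb or rb for tb, rb in zip(t_bits, r_bits))
        assert ok == expected


class TestEnumerate:
    def test_identity_yields_nothing(self, identity4):
        bs, _ = enumerate_biclusters(identity4)
        assert len(bs) == 0

    def test_all_ones_yields_everything(self, all_ones):
        bs, _ = enumerate_biclusters(all_ones)
        assert len(bs) == 1
        assert bs[0] == Bicluster(rows=tuple(range(6)), cols=tuple(range(8)))

    def test_block_diagonal(self, block_diagonal):
        bs, _ = enumerate_biclusters(block_diagonal)
        assert bs.as_set() == {
            (tuple(range(3)), tuple(range(4))),
            (tuple(range(3, 6)), tuple(range(4, 8))),
        }

    def test_minima_exceeding_shape_give_empty_result(self, all_ones):
        bs, _ = enumerate_biclusters(all_ones, SearchParams(r_min=99, mode="flex"))
        assert len(bs) == 0

    def test_soundness_all_ones_submatrices(self, rng):
        for _ in range(20):
            mat = random_binary(rng, 15, 15, 0.4)
            bs, _ = enumerate_biclusters(mat)
            for b in bs:
                assert mat.values[np.ix_(b.rows, b.cols)].all()

    def test_equivalent_to_reference_oracle(self, rng):
        for density in (0.1, 0.25, 0.4, 0.55):
            for _ in range(10):
                mat = random_binary(rng, 20, 20, density)
                fast, _ = enumerate_biclusters(mat)
                ref = reference_pairwise_and(mat)
                assert fast.as_set() == ref.as_set()

    def test_instrumented_path_matches_fast_path(self, rng):
        for _ in range(5):
            mat = random_binary(rng, 14, 18, 0.35)
            fast, _ = enumerate_biclusters(mat)
            slow, stats = enumerate_biclusters(mat, collect_stats=True)
            assert fast.as_set() == slow.as_set()
            assert stats.n_templates >= len(slow)

    def test_sparse_seed_skip_is_output_equivalent(self, rng):
        for _ in range(10):
            mat = random_binary(rng, 15, 12, 0.2)
            a, _ = enumerate_biclusters(mat, _skip_sparse_seeds=True)
            b, _ = enumerate_biclusters(mat, _skip_sparse_seeds=False)
            assert a.as_set() == b.as_set()

    def test_determinism(self, rng):
        mat = random_binary(rng, 18, 18, 0.3)
        a, _ = enumerate_biclusters(mat)
        b, _ = enumerate_biclusters(mat)
        assert list(a) == list(b)

    def test_duplicate_rows_kept_distinct(self):
        vals = np.array([[1, 1, 0, 0]] * 3 + [[0, 0, 1, 1]])
        bs, _ = enumerate_biclusters(BinaryMatrix(vals))
        assert bs.as_set() == {((0, 1, 2), (0, 1))}

    def test_base_mode_coerces_minima(self, caplog):
        p = SearchParams(r_min=5, c_min=3, mode="base")
        assert (p.r_min, p.c_min) == (2, 2)

    def test_flex_mode_honours_minima(self, block_diagonal):
        bs, _ = enumerate_biclusters(
            block_diagonal, SearchParams(r_min=3, c_min=4, mode="flex")
        )
        assert len(bs) == 2
        bs2, _ = enumerate_biclusters(
            block_diagonal, SearchParams(r_min=4, c_min=4, mode="flex")
        )
        assert len(bs2) == 0

    def test_flex_top_k_truncates_by_area(self, block_diagonal):
        vals = block_diagonal.values.copy()
        vals[5, :4] = 1  # grow one block's row support
        mat = BinaryMatrix(vals)
        full, _ = enumerate_biclusters(mat, SearchParams(mode="flex"))
        top1, _ = enumerate_biclusters(mat, SearchParams(mode="flex", top_k=1))
        assert len(top1) == 1
        assert top1[0].area == max(b.area for b in full)


class TestRemoveSymmetric:
    def _sq(self, n):
        labels = [f"p{i}" for i in range(n)]
        return BinaryMatrix(np.ones((n, n), dtype=np.uint8),
                            row_labels=labels, col_labels=labels)

    def test_transpose_pair_collapses(self):
        bs = BiclusterSet([
            Bicluster(rows=(0, 1), cols=(2, 3)),
            Bicluster(rows=(2, 3), cols=(0, 1)),
        ])
        out = remove_symmetric(bs, self._sq(4))
        assert len(out) == 1
        assert out[0].key() == ((0, 1), (2, 3))

    def test_no_pairs_is_identity(self):
        bs = BiclusterSet([Bicluster(rows=(0, 1), cols=(0, 2))])
        out = remove_symmetric(bs, self._sq(4))
        assert out.as_set() == bs.as_set()

    def test_self_symmetric_survives(self):
        bs = BiclusterSet([Bicluster(rows=(0, 1), cols=(0, 1))])
        out = remove_symmetric(bs, self._sq(3))
        assert len(out) == 1

    def test_non_square_is_identity_pass(self, block_diagonal):
        bs, _ = enumerate_biclusters(block_diagonal)
        out = remove_symmetric(bs, block_diagonal)
        assert out.as_set() == bs.as_set()

    def test_symmetric_adjacency_counts(self, rng):
        # brute-force transpose matching on small random symmetric matrices
        for _ in range(10):
            a = (rng.random((8, 8)) < 0.45).astype(np.uint8)
            a = np.triu(a, 1)
            a = a + a.T
            labels = [f"p{i}" for i in range(8)]
            mat = BinaryMatrix(a, row_labels=labels, col_labels=labels)
            bs, _ = enumerate_biclusters(mat)
            keys = bs.as_set()
            paired = sum(
                1 for (r, c) in keys if (c, r) in keys and (c, r) != (r, c)
            )
            self_sym = sum(1 for (r, c) in keys if (c, r) == (r, c))
            out = remove_symmetric(bs, mat)
            assert len(out) == paired // 2 + self_sym + (
                len(keys) - paired - self_sym
            )


class TestComparisonStats:
    def test_all_ones_is_worst_case(self, all_ones):
        _, stats = enumerate_biclusters(all_ones, collect_stats=True)
        n, p = all_ones.n_rows, 2
        assert stats.per_template_checks == [(n - 2) * p]

    def test_best_case_first_column_eliminates(self):
        # template column 0 set; all non-seed rows but one lack column 0
        vals = np.zeros((8, 8), dtype=np.uint8)
        vals[0, :] = 1
        vals[1, :] = 1
        vals[2, :] = 1          # the single surviving row
        vals[3:, 4:] = 1        # first nibble 0 -> fail at position 1
        _, stats = enumerate_biclusters(BinaryMatrix(vals), collect_stats=True)
        first = stats.rows_excluded_per_column[0]
        assert first[0] == 5    # five rows excluded at the first nibble
        assert stats.per_template_checks[0] == 5 * 1 + 1 * 2

    def test_checks_never_exceed_worst_bound(self, rng):
        for _ in range(5):
            mat = random_binary(rng, 12, 16, 0.4)
            _, stats = enumerate_biclusters(mat, collect_stats=True)
            bound = (mat.n_rows - 2) * stats.n_nibbles
            assert all(0 < c <= bound for c in stats.per_template_checks)
            for k_seq in stats.rows_excluded_per_column:
                assert sum(k_seq) <= mat.n_rows - 2

    def test_uniform_nibble_retention_near_quarter(self, rng):
        """Average-case analysis: with template and row nibbles uniform over
        0..15, the strict-membership success rate is 66/256 ≈ 1/4."""
        table = build_submask_table()
        t_nib = rng.integers(0, 16, size=20000)
        r_nib = rng.integers(0, 16, size=20000)
        hits = np.fromiter(
            (t in table.members[r] for t, r in zip(t_nib, r_nib)),
            dtype=bool,
        )
        assert hits.mean() == pytest.approx(66 / 256, abs=0.02)
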