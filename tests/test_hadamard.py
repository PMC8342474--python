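"""Walsh bases, the 2-D fast transform and the square sampling path."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spholo import (
    ComplexImage,
    HadamardPlan,
    InvalidArgumentError,
    basis_pattern,
    fwht2,
    ifwht2,
    project_and_sum,
    square_path,
    walsh_sequency_matrix,
)
from tests.conftest import random_object


class TestWalshSequencyMatrix:
    def test_smallest_nontrivial_case(self):
        assert np.array_equal(walsh_sequency_matrix(1), [[1, 1], [1, -1]])

    def test_m2_rows_sorted_by_sign_changes(self):
        expected = np.array(
            [[1, 1, 1, 1], [1, 1, -1, -1], [1, -1, -1, 1], [1, -1, 1, -1]]
        )
        assert np.array_equal(walsh_sequency_matrix(2), expected)

    @pytest.mark.parametrize("m", [0, 1, 2, 3, 4, 5])
    def test_row_k_has_k_sign_changes_and_orthogonality(self, m):
        w = walsh_sequency_matrix(m)
        n = 2**m
        changes = np.count_nonzero(np.diff(w, axis=1), axis=1)
        assert np.array_equal(changes, np.arange(n))
        assert np.array_equal(w @ w.T, n * np.eye(n))

    def test_negative_m_rejected(self):
        with pytest.raises(InvalidArgumentError):
            walsh_sequency_matrix(-1)


class TestBasisPattern:
    def test_dc_pattern_is_all_ones(self, plan8):
        assert np.all(basis_pattern(plan8, 1, "bipolar").values == 1)
        assert np.all(basis_pattern(plan8, 1, "binary").values == 1)

    def test_outer_product_of_sequency_rows(self):
        plan = HadamardPlan(2)
        n = plan.order_of(0, 1)
        pat = basis_pattern(plan, n, "bipolar")
        assert np.array_equal(pat.values, [[1, -1], [1, -1]])

    def test_binary_is_shifted_bipolar(self, plan8):
        for n in (1, 5, 23, 64):
            bi = basis_pattern(plan8, n, "bipolar").values
            b = basis_pattern(plan8, n, "binary").values
            assert np.array_equal(b, (bi + 1) // 2)

    @settings(derandomize=True, max_examples=30)
    @given(n=st.integers(min_value=2, max_value=64))
    def test_non_dc_binary_patterns_are_balanced(self, n):
        plan = HadamardPlan(8)
        assert basis_pattern(plan, n, "binary").values.sum() == plan.n_total // 2

    def test_out_of_range_order_rejected(self, plan8):
        for n in (0, 65):
            with pytest.raises(InvalidArgumentError):
                basis_pattern(plan8, n)

    def test_bipolar_orthogonality_all_pairs(self):
        plan = HadamardPlan(4)
        pats = [basis_pattern(plan, n, "bipolar").values for n in plan.path]
        gram = np.array([[int(np.sum(a * b)) for b in pats] for a in pats])
        assert np.array_equal(gram, plan.n_total * np.eye(plan.n_total, dtype=int))


class TestTransform:
    def test_delta_image_2x2_all_coefficients_half(self):
        plan = HadamardPlan(2)
        img = ComplexImage(np.array([[1.0, 0], [0, 0]]), np.zeros((2, 2)))
        coeffs = fwht2(img, plan)
        assert np.allclose(coeffs.values, 0.5)

    @pytest.mark.parametrize("side", [2, 4, 16])
    def test_uniform_image_has_only_dc(self, side):
        plan = HadamardPlan(side)
        amp = 0.7
        coeffs = fwht2(ComplexImage(np.full((side, side), amp), np.zeros((side, side))), plan)
        assert coeffs.value(1) == pytest.approx(side * amp)
        assert np.max(np.abs(coeffs.values[1:])) < 1e-12

    @pytest.mark.parametrize("side", [2, 8, 32])
    def test_round_trip_identity(self, side, rng):
        plan = HadamardPlan(side)
        obj = random_object(side, rng)
        back = ifwht2(fwht2(obj, plan), plan)
        assert np.max(np.abs(back.field - obj.field)) < 1e-10

    def test_parseval(self, plan16, rng):
        obj = random_object(16, rng)
        coeffs = fwht2(obj, plan16)
        lhs = np.sum(np.abs(coeffs.values) ** 2)
        rhs = np.sum(np.abs(obj.field) ** 2)
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_fast_transform_matches_brute_force_projection(self, plan8, rng):
        obj = random_object(8, rng)
        coeffs = fwht2(obj, plan8)
        for n in plan8.path:
            direct = project_and_sum(obj, basis_pattern(plan8, int(n), "bipolar"))
            assert abs(coeffs.value(int(n)) - direct) < 1e-10

    def test_size_mismatch_rejected(self, plan8, rng):
        with pytest.raises(InvalidArgumentError):
            fwht2(random_object(16, rng), plan8)

    def test_natural_ordering_round_trip(self, rng):
        plan = HadamardPlan(8, ordering="natural")
        obj = random_object(8, rng)
        back = ifwht2(fwht2(obj, plan), plan)
        assert np.max(np.abs(back.field - obj.field)) < 1e-10


class TestSquarePath:
    def test_side2_shell_enumeration(self):
        plan = HadamardPlan(2)
        path = square_path(plan)
        assert len(path) == 4
        u, v = plan.index_map(path)
        assert list(zip(u, v)) == [(0, 0), (0, 1), (1, 1), (1, 0)]

    def test_path_is_permutation_starting_at_dc(self, plan16):
        path = square_path(plan16)
        assert path[0] == 1
        assert np.array_equal(np.sort(path), np.arange(1, plan16.n_total + 1))

    def test_shell_index_nondecreasing(self, plan16):
        u, v = plan16.index_map(square_path(plan16))
        shells = np.maximum(u, v)
        assert np.all(np.diff(shells) >= 0)

    @pytest.mark.parametrize("sr", [0.03125, 0.0625, 0.125, 0.25, 0.5])
    def test_truncation_bounds_spatial_frequency(self, sr):
        plan = HadamardPlan(32)
        n_keep = int(np.ceil(sr * plan.n_total))
        u, v = plan.index_map(square_path(plan)[:n_keep])
        assert np.max(np.maximum(u, v)) <= np.ceil(plan.side * np.sqrt(sr)) + 1

    def test_non_power_of_two_side_rejected(self):
        with pytest.raises(InvalidArgumentError):
            HadamardPlan(12)
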