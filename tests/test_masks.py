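"""Mask construction: directional, scaled, bidirectional, composite; both
the verbatim published variants and the symmetry-consistent canonical ones."""

from fractions import Fraction

import numpy as np
import pytest

from fracim.core import rho_coefficients
from fracim.masks import (
    BIDIRECTIONAL_AXES,
    Direction,
    bidirectional_mask,
    composite_mask_5x5,
    directional_mask,
    scaled_mask,
)

F = Fraction
Z = (F(0), F(0))
R0 = lambda num, den=1: (F(num, den), F(0))  # noqa: E731
R1 = lambda num, den=1: (F(0), F(num, den))  # noqa: E731

ALPHAS = [0.3, 0.5, 0.7, 0.9, 1.0]


def coeffs(alpha=0.5):
    return rho_coefficients(alpha)


# rotating the image grid 90 degrees clockwise maps each direction to this one
ROT_CW = {
    Direction.POS_Y: Direction.POS_X,
    Direction.POS_X: Direction.NEG_Y,
    Direction.NEG_Y: Direction.NEG_X,
    Direction.NEG_X: Direction.POS_Y,
    Direction.UP_RIGHT: Direction.DOWN_RIGHT,
    Direction.DOWN_RIGHT: Direction.DOWN_LEFT,
    Direction.DOWN_LEFT: Direction.UP_LEFT,
    Direction.UP_LEFT: Direction.UP_RIGHT,
}


class TestDirectional:
    def test_unit_order_pos_y_pattern(self):
        m = directional_mask(rho_coefficients(1.0), Direction.POS_Y)
        expected = np.array([[0, 0.5, 0], [0, 1.0, 0], [0, 0, 0]])
        np.testing.assert_array_equal(m.weights, expected)

    @pytest.mark.parametrize("direction", list(Direction))
    def test_opposite_directions_are_180_rotations(self, direction):
        c = coeffs()
        m = directional_mask(c, direction)
        n = directional_mask(c, direction.opposite)
        np.testing.assert_array_equal(m.weights, n.weights[::-1, ::-1])

    def test_half_order_pos_x_values(self):
        m = directional_mask(coeffs(0.5), Direction.POS_X)
        assert m.weights[1, 1] == pytest.approx(1.27862, abs=1e-5)
        assert m.weights[1, 2] == pytest.approx(0.31966, abs=1e-5)

    def test_golden_transcription_all_eight(self):
        # the published eight-direction table, cell for cell
        c = coeffs()
        golden = {
            Direction.POS_Y: [[Z, R1(1), Z], [Z, R0(1), Z], [Z, Z, Z]],
            Direction.UP_RIGHT: [[Z, Z, R1(1)], [Z, R0(1), Z], [Z, Z, Z]],
            Direction.POS_X: [[Z, Z, Z], [Z, R0(1), R1(1)], [Z, Z, Z]],
            Direction.DOWN_RIGHT: [[Z, Z, Z], [Z, R0(1), Z], [Z, Z, R1(1)]],
            Direction.NEG_Y: [[Z, Z, Z], [Z, R0(1), Z], [Z, R1(1), Z]],
            Direction.DOWN_LEFT: [[Z, Z, Z], [Z, R0(1), Z], [R1(1), Z, Z]],
            Direction.NEG_X: [[Z, Z, Z], [R1(1), R0(1), Z], [Z, Z, Z]],
            Direction.UP_LEFT: [[R1(1), Z, Z], [Z, R0(1), Z], [Z, Z, Z]],
        }
        for d, grid in golden.items():
            assert directional_mask(c, d).symbolic == tuple(map(tuple, grid))


class TestScaled:
    def test_canonical_pos_y_layout(self):
        m = scaled_mask(coeffs(), Direction.POS_Y, "canonical")
        a, b = m.weights[0, 0], m.weights[2, 2]
        c = coeffs()
        assert a == pytest.approx(c.rho1 / 3)
        assert b == pytest.approx(c.rho0 / 5)
        np.testing.assert_allclose(m.weights[0], [a, a, a])
        assert m.weights[1, 1] == 0.0

    @pytest.mark.parametrize("direction", list(Direction))
    @pytest.mark.parametrize("alpha", ALPHAS)
    def test_canonical_entry_sum_is_rho0_plus_rho1(self, direction, alpha):
        c = rho_coefficients(alpha)
        m = scaled_mask(c, direction, "canonical")
        assert m.weights.sum() == pytest.approx(c.rho0 + c.rho1, rel=1e-12)

    @pytest.mark.parametrize("direction", list(Direction))
    def test_rotation_closure(self, direction):
        c = coeffs()
        rotated = np.rot90(scaled_mask(c, direction, "canonical").weights, k=-1)
        target = scaled_mask(c, ROT_CW[direction], "canonical").weights
        np.testing.assert_array_equal(rotated, target)

    def test_golden_transcription_printed_six(self):
        # the six published scaled grids, cell for cell
        A, B = R1(1, 3), R0(1, 5)
        golden = {
            Direction.POS_Y: [[A, A, A], [B, B, B], [B, Z, B]],
            Direction.UP_RIGHT: [[B, A, A], [B, B, A], [Z, B, B]],
            Direction.POS_X: [[B, B, A], [Z, B, A], [B, B, A]],
            Direction.DOWN_RIGHT: [[Z, B, B], [B, B, A], [B, A, A]],
            Direction.NEG_Y: [[B, Z, B], [B, B, B], [A, A, A]],
            Direction.DOWN_LEFT: [[B, B, Z], [A, B, B], [A, A, B]],
        }
        c = coeffs()
        for d, grid in golden.items():
            assert scaled_mask(c, d, "as_printed").symbolic == tuple(map(tuple, grid))

    @pytest.mark.parametrize("direction", [Direction.NEG_X, Direction.UP_LEFT])
    def test_reconstructed_grids_follow_rotation_rule(self, direction):
        # the two grids missing from the published table are rebuilt by
        # rotating their 90-degree neighbor
        c = coeffs()
        source = next(d for d, r in ROT_CW.items() if r is direction)
        rotated = np.rot90(scaled_mask(c, source, "as_printed").weights, k=-1)
        np.testing.assert_array_equal(
            rotated, scaled_mask(c, direction, "as_printed").weights
        )


class TestBidirectional:
    @pytest.mark.parametrize("axis", BIDIRECTIONAL_AXES)
    @pytest.mark.parametrize("alpha", ALPHAS)
    def test_canonical_zero_sum_and_antisymmetry(self, axis, alpha):
        m = bidirectional_mask(rho_coefficients(alpha), axis, "canonical")
        assert abs(m.weights.sum()) < 1e-12
        np.testing.assert_array_equal(m.weights, -m.weights[::-1, ::-1])
        assert m.entry_sum_symbolic() == (0, 0)

    def test_canonical_is_difference_of_scaled(self):
        c = coeffs(0.7)
        m = bidirectional_mask(c, Direction.POS_Y, "canonical")
        diff = (
            scaled_mask(c, Direction.POS_Y, "canonical").weights
            - scaled_mask(c, Direction.NEG_Y, "canonical").weights
        )
        np.testing.assert_allclose(m.weights, diff, atol=1e-15)

    def test_canonical_zero_response_on_constant(self):
        from fracim.enhance import apply_mask

        m = bidirectional_mask(coeffs(), Direction.POS_X, "canonical")
        out = apply_mask(np.full((8, 8), 77.0), m)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_golden_transcription_printed_blocks(self):
        # all eight published bidirectional blocks, verbatim — including
        # the anomalous rho1/5 and rho0/3 cells of the positive-x and
        # lower-right blocks
        A, B = R1(1, 3), R0(1, 5)
        nA = R1(-1, 3)
        nB = R0(-1, 5)
        A5, nA5 = R1(1, 5), R1(-1, 5)
        B3 = R0(1, 3)
        golden = {
            Direction.POS_Y: [[nA, nA, A], [nB, Z, B], [nB, B, B]],
            Direction.UP_RIGHT: [[nB, nA, nA], [nB, Z, A], [B, B, B]],
            Direction.POS_X: [[nB, nA5, nA5], [B, Z, nA5], [B3, B3, B3]],
            Direction.DOWN_RIGHT: [[B, nA5, nA5], [B3, Z, nA5], [B3, B3, nB]],
            Direction.NEG_Y: [[B, B, nB], [B, Z, nB], [A, nA, nA]],
            Direction.DOWN_LEFT: [[B, B, B], [A, Z, nB], [nA, nA, nB]],
            Direction.NEG_X: [[A, B, B], [nA, Z, B], [nA, nB, nB]],
            Direction.UP_LEFT: [[nA, A, B], [nA, Z, B], [nB, nB, B]],
        }
        c = coeffs()
        for d, grid in golden.items():
            m = bidirectional_mask(c, d, "as_printed")
            assert m.symbolic == tuple(map(tuple, grid))


class TestComposite:
    @pytest.mark.parametrize("alpha", ALPHAS)
    def test_zero_sum_and_exact_antisymmetry(self, alpha):
        m = composite_mask_5x5(rho_coefficients(alpha))
        assert abs(m.weights.sum()) < 1e-12
        np.testing.assert_array_equal(m.weights, -m.weights[::-1, ::-1])

    def test_middle_column_carries_rho0(self):
        c = coeffs(0.6)
        m = composite_mask_5x5(c)
        assert m.weights[1, 2] == -c.rho0
        assert m.weights[3, 2] == c.rho0

    def test_unit_order_corners(self):
        m = composite_mask_5x5(rho_coefficients(1.0))
        assert m.weights[0, 0] == pytest.approx(-1 / 6)
        assert m.weights[4, 4] == pytest.approx(1 / 6)

    def test_variants_identical(self):
        c = coeffs(0.4)
        np.testing.assert_array_equal(
            composite_mask_5x5(c, "canonical").weights,
            composite_mask_5x5(c, "as_printed").weights,
        )

    def test_golden_transcription(self):
        # the published 5x5 grid, cell for cell
        A, B = F(1, 3), F(1, 5)
        r0 = lambda k: (F(k), F(0))  # noqa: E731
        r1 = lambda k: (F(0), k * A)  # noqa: E731
        mix = lambda s: (F(s) * 2 * B, F(s) * A)  # noqa: E731
        golden = [
            [r1(-1), r1(-2), mix(-1), r1(2), r1(1)],
            [r1(-2), (F(-3, 5), F(0)), r0(-1), (F(3, 5), F(0)), r1(2)],
            [mix(-1), r0(-1), (F(0), F(0)), r0(1), mix(1)],
            [r1(-2), (F(-3, 5), F(0)), r0(1), (F(3, 5), F(0)), r1(2)],
            [r1(-1), r1(-2), mix(1), r1(2), r1(1)],
        ]
        m = composite_mask_5x5(coeffs())
        assert m.symbolic == tuple(map(tuple, golden))


class TestContinuity:
    def test_mask_entries_continuous_in_alpha(self):
        grid = np.linspace(0.3, 0.9, 61)
        weights = np.array(
            [composite_mask_5x5(rho_coefficients(a)).weights for a in grid]
        )
        slopes = np.abs(np.diff(weights, axis=0)) / np.diff(grid)[:, None, None]
        assert slopes.max() < 10.0


def test_invalid_variant_rejected():
    with pytest.raises(ValueError):
        scaled_mask(coeffs(), Direction.POS_X, "bogus")


def test_mask_text_export_roundtrip():
    m = composite_mask_5x5(coeffs(0.5))
    parsed = np.array(
        [[float(x) for x in line.split("\t")] for line in m.to_text().splitlines()]
    )
    np.testing.assert_allclose(parsed, m.weights, atol=1e-9)
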