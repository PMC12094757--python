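"""Fractional-order convolution masks.

Four mask families are built from a :class:`~fracim.core.CoefficientSet`:

* **directional** 3x3 masks — ``rho0`` at the center and ``rho1`` at the
  neighbor one step along one of the eight compass directions;
* **scaled** 3x3 masks — the center weight spread over the neighborhood:
  the three cells on the leading side of the direction receive ``rho1/3``
  each and the remaining five cells ``rho0/5`` each ("the weight is
  distributed evenly" over the equidistant neighbors);
* **bidirectional** 3x3 masks — the difference of two opposite scaled
  masks; antisymmetric, zero-sum, derivative-like;
* the **composite** 5x5 mask combining the eight directions, 180-degree
  antisymmetric and zero-sum for every fractional order.

Every mask exists in two variants. ``canonical`` (the default) follows the
symmetric construction rules above, so the published invariants
(anti-rotation capability, zero response on constant regions) hold exactly.
``as_printed`` reproduces the published tables verbatim, including their
irregularities: the scaled tables place the zero cell opposite the
direction rather than at the center, one bidirectional block mixes
``rho1/5`` and ``rho0/3`` denominators, and two scaled grids that the
source tables omit (a header is duplicated) are reconstructed here by the
rotation rule — a transcription repair, not an editorial fix.

Entries are kept symbolically as exact rational multiples ``c0*rho0 +
c1*rho1`` and only then evaluated numerically, so antisymmetric weight
pairs cancel to exactly zero in floating point.

Masks are meant to be applied as *correlation* (no kernel flip): ``rho1``
sits at the neighbor in the named direction in image coordinates, with row
index growing downward, so "positive y-axis" places ``rho1`` in the
top-center cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from typing import Iterable

import numpy as np

from .core import CoefficientSet

__all__ = [
    "Direction",
    "Mask",
    "directional_mask",
    "scaled_mask",
    "bidirectional_mask",
    "composite_mask_5x5",
    "BIDIRECTIONAL_AXES",
]

# symbolic mask entry: (c0, c1) meaning c0*rho0 + c1*rho1
Entry = tuple[Fraction, Fraction]
_ZERO: Entry = (Fraction(0), Fraction(0))


class Direction(Enum):
    """The eight compass directions, as (row, column) unit offsets.

    Image coordinates: row grows downward, column grows rightward, so the
    positive y direction (up) has row offset -1.
    """

    POS_X = (0, 1)
    NEG_X = (0, -1)
    POS_Y = (-1, 0)
    NEG_Y = (1, 0)
    UP_RIGHT = (-1, 1)
    UP_LEFT = (-1, -1)
    DOWN_RIGHT = (1, 1)
    DOWN_LEFT = (1, -1)

    @property
    def offset(self) -> tuple[int, int]:
        return self.value

    @property
    def opposite(self) -> "Direction":
        di, dj = self.value
        return Direction((-di, -dj))


#: the four independent axes; the other four bidirectional masks are their negatives
BIDIRECTIONAL_AXES = (
    Direction.POS_Y,
    Direction.UP_RIGHT,
    Direction.POS_X,
    Direction.DOWN_RIGHT,
)


@dataclass(frozen=True)
class Mask:
    """A square correlation kernel with its symbolic construction record."""

    size: int
    direction: str  # direction label, "composite", or "bidirectional:<label>"
    variant: str  # "as_printed" or "canonical"
    weights: np.ndarray
    symbolic: tuple[tuple[Entry, ...], ...]

    def entry_sum_symbolic(self) -> Entry:
        """Exact (c0, c1) sum of all entries; (0, 0) for zero-DC masks."""
        c0 = sum((e[0] for row in self.symbolic for e in row), Fraction(0))
        c1 = sum((e[1] for row in self.symbolic for e in row), Fraction(0))
        return (c0, c1)

    def entry_sum(self, coeffs: CoefficientSet) -> float:
        c0, c1 = self.entry_sum_symbolic()
        return float(c0) * coeffs.rho0 + float(c1) * coeffs.rho1

    def to_text(self) -> str:
        """Tab-separated numeric grid, one row per line."""
        return "\n".join(
            "\t".join(format(v, ".10g") for v in row) for row in self.weights
        )


def _check_variant(variant: str) -> str:
    if variant not in ("as_printed", "canonical"):
        raise ValueError(f"variant must be 'as_printed' or 'canonical', got {variant!r}")
    return variant


def _evaluate(sym: Iterable[Iterable[Entry]], coeffs: CoefficientSet) -> np.ndarray:
    """Evaluate a symbolic grid to floats.

    Each entry is computed as ``c0*rho0 + c1*rho1`` with the same float
    expression regardless of sign, so exact symbolic cancellations survive
    in floating point.
    """
    sym = tuple(tuple(row) for row in sym)
    n = len(sym)
    out = np.zeros((n, n))
    for i, row in enumerate(sym):
        for j, (c0, c1) in enumerate(row):
            out[i, j] = float(c0) * coeffs.rho0 + float(c1) * coeffs.rho1
    return out


def _make(sym, coeffs, size, direction, variant) -> Mask:
    sym = tuple(tuple(row) for row in sym)
    return Mask(
        size=size,
        direction=direction,
        variant=variant,
        weights=_evaluate(sym, coeffs),
        symbolic=sym,
    )


# ---------------------------------------------------------------------------
# symbolic grid construction


def _leading_cells(direction: Direction) -> list[tuple[int, int]]:
    """The three neighbor offsets on the leading side of a direction."""
    di, dj = direction.offset
    return [
        (i, j)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        if (i, j) != (0, 0) and i * di + j * dj >= 1
    ]


def _directional_symbolic(direction: Direction) -> list[list[Entry]]:
    grid: list[list[Entry]] = [[_ZERO] * 3 for _ in range(3)]
    grid[1][1] = (Fraction(1), Fraction(0))
    di, dj = direction.offset
    grid[1 + di][1 + dj] = (Fraction(0), Fraction(1))
    return grid


def _scaled_symbolic(direction: Direction, variant: str) -> list[list[Entry]]:
    lead = set(_leading_cells(direction))
    grid: list[list[Entry]] = [[_ZERO] * 3 for _ in range(3)]
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            if (i, j) in lead:
                grid[1 + i][1 + j] = (Fraction(0), Fraction(1, 3))
            elif (i, j) != (0, 0):
                grid[1 + i][1 + j] = (Fraction(1, 5), Fraction(0))
    if variant == "canonical":
        # center carries no weight; the five trailing cells share rho0
        grid[1][1] = _ZERO
    else:
        # published layout: the zero sits in the cell opposite the
        # direction and the center takes that cell's rho0/5 share
        di, dj = direction.offset
        grid[1][1] = (Fraction(1, 5), Fraction(0))
        grid[1 - di][1 - dj] = _ZERO
    return grid


def _sub(a: list[list[Entry]], b: list[list[Entry]]) -> list[list[Entry]]:
    return [
        [(ea[0] - eb[0], ea[1] - eb[1]) for ea, eb in zip(ra, rb)]
        for ra, rb in zip(a, b)
    ]


def _parse_entry(token: str) -> Entry:
    """Parse a printed-table cell like ``-p1/3`` or ``2p0/5+p1/3``."""
    token = token.replace(" ", "")
    if token == "0":
        return _ZERO
    c0, c1 = Fraction(0), Fraction(0)
    for part in token.replace("-", "+-").split("+"):
        if not part:
            continue
        sign = Fraction(1)
        if part.startswith("-"):
            sign, part = Fraction(-1), part[1:]
        coef = Fraction(1)
        if part[0].isdigit():
            coef = Fraction(int(part[0]))
            part = part[1:]
        sym, _, den = part.partition("/")
        if den:
            coef /= Fraction(int(den))
        if sym == "p0":
            c0 += sign * coef
        elif sym == "p1":
            c1 += sign * coef
        else:  # pragma: no cover - table data is static
            raise ValueError(f"bad table token {token!r}")
    return (c0, c1)


def _parse_grid(rows: list[str]) -> list[list[Entry]]:
    return [[_parse_entry(tok) for tok in row.split()] for row in rows]


# Verbatim transcription of the published bidirectional 3x3 blocks.
# The duplicated "negative y-axis" header is mapped to NEG_X (the block's
# pattern is the negative-x one); the POS_X and DOWN_RIGHT blocks keep
# their anomalous p1/5 and p0/3 denominators exactly as printed.
_BIDIRECTIONAL_PRINTED: dict[Direction, list[str]] = {
    Direction.POS_Y: [
        "-p1/3 -p1/3  p1/3",
        "-p0/5  0     p0/5",
        "-p0/5  p0/5  p0/5",
    ],
    Direction.UP_RIGHT: [
        "-p0/5 -p1/3 -p1/3",
        "-p0/5  0     p1/3",
        " p0/5  p0/5  p0/5",
    ],
    Direction.POS_X: [
        "-p0/5 -p1/5 -p1/5",
        " p0/5  0    -p1/5",
        " p0/3  p0/3  p0/3",
    ],
    Direction.DOWN_RIGHT: [
        " p0/5 -p1/5 -p1/5",
        " p0/3  0    -p1/5",
        " p0/3  p0/3 -p0/5",
    ],
    Direction.NEG_Y: [
        " p0/5  p0/5 -p0/5",
        " p0/5  0    -p0/5",
        " p1/3 -p1/3 -p1/3",
    ],
    Direction.DOWN_LEFT: [
        " p0/5  p0/5  p0/5",
        " p1/3  0    -p0/5",
        "-p1/3 -p1/3 -p0/5",
    ],
    Direction.NEG_X: [
        " p1/3  p0/5  p0/5",
        "-p1/3  0     p0/5",
        "-p1/3 -p0/5 -p0/5",
    ],
    Direction.UP_LEFT: [
        "-p1/3  p1/3  p0/5",
        "-p1/3  0     p0/5",
        "-p0/5 -p0/5  p0/5",
    ],
}

# Verbatim transcription of the published composite 5x5 mask; identical in
# both variants (the printed grid already satisfies 180-degree antisymmetry).
_COMPOSITE_PRINTED = [
    "-p1/3      -2p1/3  -2p0/5-p1/3  2p1/3  p1/3",
    "-2p1/3     -3p0/5  -p0          3p0/5  2p1/3",
    "-2p0/5-p1/3 -p0     0           p0     2p0/5+p1/3",
    "-2p1/3     -3p0/5   p0          3p0/5  2p1/3",
    "-p1/3      -2p1/3   2p0/5+p1/3  2p1/3  p1/3",
]


# ---------------------------------------------------------------------------
# public constructors


def directional_mask(coeffs: CoefficientSet, direction: Direction) -> Mask:
    """3x3 mask with ``rho0`` at the center and ``rho1`` one step along ``direction``.

    The published eight-direction table follows this rule exactly, so there
    is no as_printed/canonical distinction for this family.
    """
    sym = _directional_symbolic(direction)
    return _make(sym, coeffs, 3, direction.name.lower(), "canonical")


def scaled_mask(
    coeffs: CoefficientSet, direction: Direction, variant: str = "canonical"
) -> Mask:
    """3x3 mask with the weight spread over the neighborhood.

    The three leading cells (the row, column or diagonal bend on the side
    of ``direction``) get ``rho1/3`` each; the remaining cells share
    ``rho0`` in fifths. ``canonical`` zeroes the center; ``as_printed``
    reproduces the published layout, which zeroes the trailing cell
    opposite the direction instead.
    """
    variant = _check_variant(variant)
    sym = _scaled_symbolic(direction, variant)
    return _make(sym, coeffs, 3, direction.name.lower(), variant)


def bidirectional_mask(
    coeffs: CoefficientSet, axis_direction: Direction, variant: str = "canonical"
) -> Mask:
    """Antisymmetric 3x3 mask along an axis.

    ``canonical`` is the difference ``scaled(d) - scaled(-d)`` of two
    canonical scaled masks: exactly zero-sum, zero response on constant
    regions. ``as_printed`` is the verbatim published block, which is *not*
    zero-sum for every direction.
    """
    variant = _check_variant(variant)
    if variant == "canonical":
        sym = _sub(
            _scaled_symbolic(axis_direction, "canonical"),
            _scaled_symbolic(axis_direction.opposite, "canonical"),
        )
    else:
        sym = _parse_grid(_BIDIRECTIONAL_PRINTED[axis_direction])
    return _make(
        sym, coeffs, 3, f"bidirectional:{axis_direction.name.lower()}", variant
    )


def composite_mask_5x5(coeffs: CoefficientSet, variant: str = "canonical") -> Mask:
    """The combined-direction 5x5 mask.

    The published grid is 180-degree antisymmetric (``w[i,j] = -w[4-i,4-j]``)
    and therefore zero-sum for every fractional order; both variants return
    the same grid.
    """
    variant = _check_variant(variant)
    sym = _parse_grid(_COMPOSITE_PRINTED)
    return _make(sym, coeffs, 5, "composite", variant)
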