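"""Coaggregation (CoAg) index.

The binding-specificity assay mixes red- and green-labeled cell
populations; whether they intermix quantifies trans-homophilic recognition
between the two expressed isoforms. The micrograph is parsed into squares
just slightly larger than a single cell, squares containing no cells
(black) are discarded, and the CoAg index is the fraction of remaining
squares that contain more than one color. Completely separated populations
give a very low index (< 0.1); intermixing populations give a high index
(≥ 0.2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from sdscam.synthcells import CellFieldImage

SEGREGATED_MAX = 0.1   # classification: index < 0.1 -> segregated
INTERMIXED_MIN = 0.2   # classification: index >= 0.2 -> intermixed

#: Margin over the cell diameter for the default square side ("slightly
#: larger than the size of a single cell").
SQUARE_MARGIN_FACTOR = 2.4

#: Default per-color presence rule: at least this fraction of the square's
#: pixels must carry the color (floor of 1 px), making the call robust to
#: single-pixel bleed.
PRESENCE_AREA_FRACTION = 0.05


@dataclass(frozen=True)
class GridSpec:
    """Square tiling of an image."""

    square_side_px: int
    origin: tuple[int, int] = (0, 0)
    include_partial_edges: bool = False

    def __post_init__(self) -> None:
        if self.square_side_px < 1:
            raise ValueError("square_side_px must be >= 1")
        if any(o < 0 for o in self.origin):
            raise ValueError("origin offsets must be >= 0")


@dataclass(frozen=True)
class CoAgResult:
    """Square tallies and the resulting CoAg index.

    ``coag_index`` is ``None`` (undefined, distinct from 0) when every
    square is black.
    """

    coag_index: float | None
    n_squares_total: int
    n_black: int
    n_single_color: int
    n_mixed: int
    presence_min_px: int
    classification: str  # segregated | intermixed | indeterminate | undefined


def default_grid(image: CellFieldImage, origin: tuple[int, int] = (0, 0)) -> GridSpec:
    """Square side = ceil(2.4 × cell radius), slightly over a cell diameter."""
    return GridSpec(
        square_side_px=math.ceil(SQUARE_MARGIN_FACTOR * image.cell_radius_px),
        origin=origin,
    )


def grid_partition(
    image: CellFieldImage, grid: GridSpec
) -> list[tuple[int, int, int, int]]:
    """Non-overlapping square tiling as (y0, x0, y1, x1) windows.

    Tiles from ``grid.origin``; trailing partial squares are discarded
    unless ``include_partial_edges``.
    """
    h, w = image.shape
    s = grid.square_side_px
    oy, ox = grid.origin
    if s > h or s > w:
        raise ValueError(f"square side {s} exceeds image dims {image.shape}")
    squares = []
    y = oy
    while y < h:
        x = ox
        y1 = min(y + s, h)
        if y1 - y < s and not grid.include_partial_edges:
            break
        while x < w:
            x1 = min(x + s, w)
            if x1 - x < s and not grid.include_partial_edges:
                break
            squares.append((y, x, y1, x1))
            x = x1
        y = y1
    return squares


def _presence_counts(
    channel: np.ndarray, squares: list[tuple[int, int, int, int]], threshold: float
) -> np.ndarray:
    lit = channel > threshold
    return np.array([lit[y0:y1, x0:x1].sum() for y0, x0, y1, x1 in squares])


def coag_index(
    image: CellFieldImage,
    grid: GridSpec | None = None,
    presence_min_px: int | None = None,
    channel_threshold: float = 0.5,
) -> CoAgResult:
    """CoAg index of a two-color field.

    Per square, a color is present when at least ``presence_min_px`` pixels
    of its channel exceed ``channel_threshold``; black squares (no color
    present) are removed; the index is mixed / (single + mixed). With zero
    non-black squares the index is undefined, not 0.
    """
    if grid is None:
        grid = default_grid(image)
    if presence_min_px is None:
        presence_min_px = max(
            1, round(PRESENCE_AREA_FRACTION * grid.square_side_px**2)
        )
    squares = grid_partition(image, grid)
    red = _presence_counts(image.red_channel, squares, channel_threshold)
    green = _presence_counts(image.green_channel, squares, channel_threshold)
    red_present = red >= presence_min_px
    green_present = green >= presence_min_px
    n_mixed = int((red_present & green_present).sum())
    n_black = int((~red_present & ~green_present).sum())
    n_single = len(squares) - n_mixed - n_black
    denom = n_single + n_mixed
    index = None if denom == 0 else n_mixed / denom
    result = CoAgResult(
        coag_index=index,
        n_squares_total=len(squares),
        n_black=n_black,
        n_single_color=n_single,
        n_mixed=n_mixed,
        presence_min_px=presence_min_px,
        classification="undefined",
    )
    return CoAgResult(**{**result.__dict__, "classification": classify_mixing(result)})


def classify_mixing(result: CoAgResult) -> str:
    """Map a CoAg index to segregated / intermixed / indeterminate.

    Index < 0.1 -> segregated; index >= 0.2 -> intermixed; values in
    [0.1, 0.2) -> indeterminate (0.1 itself is indeterminate, 0.2 itself is
    intermixed, matching the strict/inclusive thresholds). An undefined
    index propagates as "undefined".
    """
    if result.coag_index is None:
        return "undefined"
    if result.coag_index < SEGREGATED_MAX:
        return "segregated"
    if result.coag_index >= INTERMIXED_MIN:
        return "intermixed"
    return "indeterminate"
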