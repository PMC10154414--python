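"""Aggregation-percentage quantification of assay micrographs.

The pipeline mirrors the standard cell-aggregation readout: the micrograph
is binarized, foreground pixels are grouped into connected objects, objects
of 300 or fewer pixels (about three cells at the assay's magnification) are
classified as "no aggregation", and the aggregation percentage is the sum
of pixels in objects larger than 300 px divided by the sum of all object
pixels. The 300-px boundary is strict: an object of exactly 300 px does not
count as an aggregate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as _sk_label

from sdscam.synthcells import CellFieldImage

DEFAULT_MIN_PIXELS = 300
REFERENCE_FRAME = (2160, 2560)


@dataclass(frozen=True)
class BinaryMask:
    """Foreground mask of a micrograph with the threshold that produced it."""

    mask: np.ndarray
    threshold: float
    method: str

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class LabeledObjects:
    """Connected-component decomposition of a binary mask."""

    labels: np.ndarray          # 0 = background, objects 1..n
    object_sizes: np.ndarray    # pixel count per object, index = label - 1
    connectivity: int           # 4 or 8

    @property
    def n_objects(self) -> int:
        return len(self.object_sizes)

    @property
    def total_foreground(self) -> int:
        return int(self.object_sizes.sum())


@dataclass(frozen=True)
class AggregationResult:
    """Aggregated-pixel fraction under the minimum-object-size rule."""

    aggregation_fraction: float
    min_pixels: int
    n_aggregates: int
    n_small_objects: int
    total_foreground: int
    empty_field: bool = False


def binarize_image(
    image: CellFieldImage,
    method: str = "otsu",
    fixed_threshold: float | None = None,
) -> BinaryMask:
    """Binarize the per-pixel max of the two channels.

    The max-merge keeps a pixel lit by either fluorophore; the threshold is
    Otsu's on the merged image (falling back to 0.5 with a warning when the
    image is constant) or a user-fixed value in [0, 1].
    """
    merged = np.maximum(image.red_channel, image.green_channel)
    if method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed method requires fixed_threshold")
        thr = float(fixed_threshold)
    elif method == "otsu":
        if np.ptp(merged) == 0:
            warnings.warn("constant image; Otsu undefined, falling back to 0.5")
            thr = 0.5
        else:
            thr = float(threshold_otsu(merged))
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return BinaryMask(mask=merged > thr, threshold=thr, method=method)


def label_connected_components(
    mask: BinaryMask | np.ndarray, connectivity: int = 8
) -> LabeledObjects:
    """Label connected foreground objects (8-connectivity by default)."""
    arr = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask, bool)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels = _sk_label(arr, connectivity=1 if connectivity == 4 else 2)
    sizes = np.bincount(labels.ravel())[1:]  # drop background
    return LabeledObjects(labels=labels, object_sizes=sizes, connectivity=connectivity)


def aggregation_percentage(
    objects: LabeledObjects, min_pixels: int = DEFAULT_MIN_PIXELS
) -> AggregationResult:
    """Fraction of foreground pixels in objects larger than ``min_pixels``.

    Objects with ``min_pixels`` or fewer pixels are "no aggregation"; the
    fraction is Σ(sizes > min_pixels) / Σ(all sizes). An empty field is
    reported as fraction 0 with ``empty_field=True``.
    """
    sizes = objects.object_sizes
    total = int(sizes.sum())
    if total == 0:
        warnings.warn("no foreground pixels; aggregation fraction undefined, reporting 0")
        return AggregationResult(0.0, min_pixels, 0, 0, 0, empty_field=True)
    large = sizes > min_pixels
    return AggregationResult(
        aggregation_fraction=float(sizes[large].sum() / total),
        min_pixels=min_pixels,
        n_aggregates=int(large.sum()),
        n_small_objects=int((~large).sum()),
        total_foreground=total,
    )


def rescaled_min_pixels(
    min_pixels: int,
    image_dims: tuple[int, int],
    reference: tuple[int, int] = REFERENCE_FRAME,
) -> int:
    """Rescale the object-size threshold for a non-reference frame size.

    The 300-px rule is calibrated to a 2160 × 2560 frame; for other
    resolutions the caller may opt in to scaling the threshold by the pixel
    area ratio. Never applied silently.
    """
    scale = (image_dims[0] * image_dims[1]) / (reference[0] * reference[1])
    return max(1, round(min_pixels * scale))


def quantify(
    image: CellFieldImage,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    connectivity: int = 8,
    min_pixels: int = DEFAULT_MIN_PIXELS,
    rescale_min_pixels: bool = False,
) -> AggregationResult:
    """End-to-end aggregation percentage for one micrograph."""
    if rescale_min_pixels:
        min_pixels = rescaled_min_pixels(min_pixels, image.shape)
    mask = binarize_image(image, method, fixed_threshold)
    objects = label_connected_components(mask, connectivity)
    return aggregation_percentage(objects, min_pixels)
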