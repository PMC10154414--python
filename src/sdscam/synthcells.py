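"""Synthetic inputs for the aggregation-assay and structure pipelines.

Three generators, all seeded and deterministic:

- :func:`generate_cell_field` paints red/green fluorescent cell fields that
  emulate the Sf9 binding-specificity assay: cells expressing matching
  isoforms coaggregate into mixed red-green clumps, mismatched isoforms form
  monochrome segregated aggregates, and non-adhesive cells stay dispersed.
- :func:`generate_repertoire_pair` draws two isoform repertoires from a
  common pool with an exact prescribed number of shared identities.
- :func:`generate_toy_dimer` builds a two-chain structure whose second chain
  is a known rigid transform (plus optional noise) of the first, as ground
  truth for superposition tests.

Cells are rendered as anti-aliased disks of unit intensity on a zero
background, so every painted pixel is unambiguous ground truth for
binarization-independent checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

from sdscam.repertoire_stats import IsoformRepertoire
from sdscam.structmetrics.model import StructureModel

#: Reference micrograph frame (rows, cols) used throughout the assay.
DEFAULT_FRAME: tuple[int, int] = (2160, 2560)

#: Default cell radius in pixels, chosen so that three cell disks cover about
#: 300 pixels (the "~3 cells" calibration of the aggregation threshold):
#: 3 * pi * 5.6^2 ~= 296 px.
DEFAULT_CELL_RADIUS_PX: float = 5.6

_MAX_PLACEMENT_ATTEMPTS = 10_000


class MixingMode(str, Enum):
    """Spatial arrangement of the two cell populations."""

    coaggregate = "coaggregate"  # both colors intermixed in shared clusters
    segregate = "segregate"      # monochrome clusters far apart
    disperse = "disperse"        # isolated single cells, no clusters


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place a cell within the frame."""


@dataclass
class CellFieldImage:
    """Two-channel intensity grid standing in for an assay micrograph."""

    red_channel: np.ndarray
    green_channel: np.ndarray
    cell_radius_px: float
    provenance: dict

    def __post_init__(self) -> None:
        if self.red_channel.shape != self.green_channel.shape:
            raise ValueError("channel dimensions differ")
        h, w = self.red_channel.shape
        if self.cell_radius_px >= min(h, w) / 4:
            raise ValueError("cell_radius_px too large for the frame")
        for ch in (self.red_channel, self.green_channel):
            if ch.size and (ch.min() < 0 or ch.max() > 1):
                raise ValueError("intensities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.red_channel.shape

    @property
    def height_px(self) -> int:
        return self.red_channel.shape[0]

    @property
    def width_px(self) -> int:
        return self.red_channel.shape[1]


def _paint_disk(channel: np.ndarray, cy: float, cx: float, r: float) -> None:
    """Max-composite an anti-aliased unit disk into ``channel`` in place."""
    h, w = channel.shape
    y0, y1 = max(0, int(cy - r - 1)), min(h, int(cy + r + 2))
    x0, x1 = max(0, int(cx - r - 1)), min(w, int(cx + r + 2))
    yy, xx = np.ogrid[y0:y1, x0:x1]
    dist = np.hypot(yy + 0.5 - cy, xx + 0.5 - cx)
    disk = np.clip(r + 0.5 - dist, 0.0, 1.0)
    np.maximum(channel[y0:y1, x0:x1], disk, out=channel[y0:y1, x0:x1])


def _place_in_disk(
    rng: np.random.Generator,
    center: np.ndarray,
    cluster_radius: float,
    cell_radius: float,
    dims: tuple[int, int],
) -> np.ndarray:
    """Uniform point in a cluster disk, with the cell disk fully in frame."""
    h, w = dims
    for _ in range(_MAX_PLACEMENT_ATTEMPTS):
        u = rng.uniform(0, 1)
        ang = rng.uniform(0, 2 * math.pi)
        rad = cluster_radius * math.sqrt(u)
        p = center + rad * np.array([math.sin(ang), math.cos(ang)])
        if cell_radius <= p[0] <= h - cell_radius and cell_radius <= p[1] <= w - cell_radius:
            return p
    raise PlacementError(
        "could not place a cell inside the frame; cluster_radius_px or the "
        "cluster centers leave too little room within image_dims"
    )


def _cluster_centers(
    rng: np.random.Generator,
    n: int,
    min_separation: float,
    margin: float,
    dims: tuple[int, int],
) -> np.ndarray:
    h, w = dims
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise PlacementError(
            "image_dims too small for the requested cluster_radius_px margin"
        )
    centers: list[np.ndarray] = []
    for _ in range(n):
        for _ in range(_MAX_PLACEMENT_ATTEMPTS):
            c = np.array(
                [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
            )
            if all(np.linalg.norm(c - prev) >= min_separation for prev in centers):
                centers.append(c)
                break
        else:
            raise PlacementError(
                "could not separate cluster centers; min cluster separation "
                f"{min_separation:.0f}px does not fit in image_dims {dims}"
            )
    return np.array(centers).reshape(n, 2)


def generate_cell_field(
    n_red: int,
    n_green: int,
    mode: MixingMode | str,
    cluster_count: int = 2,
    cluster_radius_px: float = 80.0,
    image_dims: tuple[int, int] = DEFAULT_FRAME,
    cell_radius_px: float = DEFAULT_CELL_RADIUS_PX,
    seed: int = 0,
    noise_sigma: float = 0.0,
    cluster_separation_factor: float = 4.5,
) -> CellFieldImage:
    """Generate a two-color synthetic cell field.

    Parameters
    ----------
    n_red, n_green
        Number of mCherry-like (red) and EGFP-like (green) cell disks.
    mode
        ``coaggregate``: both colors assigned uniformly to each of
        ``cluster_count`` shared clusters. ``segregate``: clusters are
        monochrome, colors alternating over clusters, and cluster centers are
        kept at least ``cluster_separation_factor * cluster_radius_px``
        apart. ``disperse``: cells placed uniformly over the frame.
    cluster_radius_px
        Radius of the disk within which clustered cells are placed. The
        default together with 100 cells per cluster gives the dense, nearly
        confluent aggregates seen in shaken-culture adhesion assays
        (~50% area fill).
    noise_sigma
        Optional additive Gaussian noise (clipped back to [0, 1]).

    Cell centers, cluster centers, mode, and the seed are recorded in
    ``provenance`` so downstream checks can verify results by construction.
    """
    mode = MixingMode(mode)
    if n_red < 0 or n_green < 0:
        raise ValueError("cell counts must be >= 0")
    if cluster_radius_px < cell_radius_px:
        raise ValueError("cluster_radius_px must be >= cell_radius_px")
    h, w = image_dims
    if h <= 0 or w <= 0:
        raise ValueError("image_dims must be positive")
    rng = np.random.default_rng(seed)

    red = np.zeros((h, w), dtype=np.float32)
    green = np.zeros((h, w), dtype=np.float32)

    red_centers: list[np.ndarray] = []
    green_centers: list[np.ndarray] = []
    centers = np.empty((0, 2))

    if mode is MixingMode.disperse:
        for color_centers, count in ((red_centers, n_red), (green_centers, n_green)):
            for _ in range(count):
                if h - 2 * cell_radius_px <= 0 or w - 2 * cell_radius_px <= 0:
                    raise PlacementError("image_dims smaller than one cell")
                p = np.array(
                    [
                        rng.uniform(cell_radius_px, h - cell_radius_px),
                        rng.uniform(cell_radius_px, w - cell_radius_px),
                    ]
                )
                color_centers.append(p)
    else:
        if cluster_count < 1:
            raise ValueError("clustered modes need cluster_count >= 1")
        sep = cluster_separation_factor * cluster_radius_px
        centers = _cluster_centers(
            rng, cluster_count, sep, cluster_radius_px + cell_radius_px, (h, w)
        )
        if mode is MixingMode.coaggregate:
            red_assign = rng.integers(0, cluster_count, size=n_red)
            green_assign = rng.integers(0, cluster_count, size=n_green)
        else:  # segregate: alternate monochrome clusters
            red_clusters = np.arange(0, cluster_count, 2)
            green_clusters = np.arange(1, cluster_count, 2)
            if len(green_clusters) == 0 and n_green > 0:
                raise ValueError("segregate mode with green cells needs >= 2 clusters")
            red_assign = red_clusters[rng.integers(0, len(red_clusters), size=n_red)]
            green_assign = green_clusters[
                rng.integers(0, len(green_clusters), size=n_green)
            ]
        for idx in red_assign:
            red_centers.append(
                _place_in_disk(rng, centers[idx], cluster_radius_px, cell_radius_px, (h, w))
            )
        for idx in green_assign:
            green_centers.append(
                _place_in_disk(rng, centers[idx], cluster_radius_px, cell_radius_px, (h, w))
            )

    for p in red_centers:
        _paint_disk(red, p[0], p[1], cell_radius_px)
    for p in green_centers:
        _paint_disk(green, p[0], p[1], cell_radius_px)

    if noise_sigma > 0:
        red = np.clip(red + rng.normal(0, noise_sigma, red.shape), 0, 1).astype(np.float32)
        green = np.clip(green + rng.normal(0, noise_sigma, green.shape), 0, 1).astype(np.float32)

    provenance = {
        "mode": mode.value,
        "n_red": n_red,
        "n_green": n_green,
        "seed": seed,
        "cluster_count": cluster_count if mode is not MixingMode.disperse else 0,
        "cluster_radius_px": cluster_radius_px,
        "cluster_centers": centers,
        "red_centers": np.array(red_centers).reshape(-1, 2),
        "green_centers": np.array(green_centers).reshape(-1, 2),
        "noise_sigma": noise_sigma,
    }
    return CellFieldImage(red, green, cell_radius_px, provenance)


def generate_repertoire_pair(
    pool_size: int, k: int, shared_count: int, seed: int
) -> tuple[IsoformRepertoire, IsoformRepertoire]:
    """Two size-k repertoires from a pool of ``pool_size`` sharing exactly
    ``shared_count`` identities.

    Conditional on the shared count, the draw is uniform: the shared block
    and both private blocks are a single without-replacement sample from the
    pool, which by exchangeability makes every admissible pair of sets
    equally likely.
    """
    if not (0 <= shared_count <= k <= pool_size):
        raise ValueError("need 0 <= shared_count <= k <= pool_size")
    if 2 * k - shared_count > pool_size:
        raise ValueError(
            f"pool of {pool_size} cannot host two size-{k} repertoires "
            f"sharing only {shared_count}"
        )
    rng = np.random.default_rng(seed)
    draw = rng.choice(pool_size, size=2 * k - shared_count, replace=False)
    shared = draw[:shared_count]
    a_private = draw[shared_count:k]
    b_private = draw[k : 2 * k - shared_count]
    rep_a = IsoformRepertoire(
        "A", frozenset(int(i) for i in np.concatenate([shared, a_private])), pool_size
    )
    rep_b = IsoformRepertoire(
        "B", frozenset(int(i) for i in np.concatenate([shared, b_private])), pool_size
    )
    return rep_a, rep_b


# ---------------------------------------------------------------------------
# Toy structures


@dataclass(frozen=True)
class ToyStructureSpec:
    """Recipe for a synthetic two-chain dimer with a known rigid transform."""

    n_residues: int = 50
    geometry: str = "helix"  # "helix" | "strand" | "coil"
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be a 3x3 orthonormal matrix")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det +1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.geometry not in ("helix", "strand", "coil"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


def _trace_coords(spec: ToyStructureSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_residues
    i = np.arange(n)
    if spec.geometry == "helix":
        # ideal alpha-helix CA trace: 2.3 A radius, 1.5 A rise, 100 deg/res
        ang = np.deg2rad(100.0) * i
        return np.stack([2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * i], axis=1)
    if spec.geometry == "strand":
        # extended beta trace: 3.3 A rise with alternating 1 A zig-zag
        return np.stack(
            [np.where(i % 2 == 0, 1.0, -1.0), np.zeros(n), 3.3 * i], axis=1
        )
    # self-avoiding-ish random coil: cumulative 3.8 A steps
    steps = rng.normal(size=(n, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    return np.cumsum(3.8 * steps, axis=0)


def generate_toy_dimer(spec: ToyStructureSpec) -> StructureModel:
    """Two-chain CA-only structure; chain B = R @ chain A + t (+ noise).

    The ground-truth transform is stored in ``model.meta`` under
    ``"rotation"`` and ``"translation"``.
    """
    rng = np.random.default_rng(spec.seed)
    coords_a = _trace_coords(spec, rng)
    coords_b = coords_a @ np.asarray(spec.rotation, float).T + np.asarray(
        spec.translation, float
    )
    if spec.noise_sigma > 0:
        coords_b = coords_b + rng.normal(0, spec.noise_sigma, coords_b.shape)

    n = spec.n_residues
    model = StructureModel.from_arrays(
        chain_ids=["A"] * n + ["B"] * n,
        res_ids=list(range(1, n + 1)) * 2,
        res_names=["ALA"] * (2 * n),
        atom_names=["CA"] * (2 * n),
        elements=["C"] * (2 * n),
        coords=np.vstack([coords_a, coords_b]),
    )
    model.meta["rotation"] = np.asarray(spec.rotation, float)
    model.meta["translation"] = np.asarray(spec.translation, float)
    model.meta["noise_sigma"] = spec.noise_sigma
    return model


# ---------------------------------------------------------------------------
# Disk I/O for generated images


def write_image(image: CellFieldImage, path: str | Path) -> None:
    """Write the field as RGB (blue = 0) PNG or TIFF, with a sidecar
    ``<path>.provenance.txt`` recording mode, counts, seed, and centers."""
    path = Path(path)
    rgb = np.zeros((*image.shape, 3), dtype=np.uint8)
    rgb[..., 0] = np.round(image.red_channel * 255).astype(np.uint8)
    rgb[..., 1] = np.round(image.green_channel * 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, rgb)
    else:
        from PIL import Image

        Image.fromarray(rgb).save(path)
    prov = image.provenance
    lines = [
        f"mode\t{prov['mode']}",
        f"n_red\t{prov['n_red']}",
        f"n_green\t{prov['n_green']}",
        f"seed\t{prov['seed']}",
        f"cell_radius_px\t{image.cell_radius_px}",
    ]
    for key in ("cluster_centers", "red_centers", "green_centers"):
        for y, x in np.asarray(prov[key]).reshape(-1, 2):
            lines.append(f"{key}\t{y:.3f}\t{x:.3f}")
    Path(str(path) + ".provenance.txt").write_text("\n".join(lines) + "\n")


def read_image(path: str | Path, cell_radius_px: float = DEFAULT_CELL_RADIUS_PX) -> CellFieldImage:
    """Load an RGB image written by :func:`write_image` (or any micrograph
    with red/green channels) back into a :class:`CellFieldImage`."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("RGB"))
    arr = arr.astype(np.float32) / 255.0
    prov: dict = {"source": str(path), "mode": "unknown"}
    return CellFieldImage(arr[..., 0], arr[..., 1], cell_radius_px, prov)
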