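"""Shrake–Rupley solvent-accessible surface area.

Each atom is inflated by the probe radius (1.4 Å water by default) and
covered with a deterministic quasi-uniform point set (golden-section
spiral); the accessible area is the fraction of points not occluded by any
neighboring inflated sphere. The point set is fixed, so results are
bit-stable across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from sdscam.structmetrics.model import StructureModel

#: van der Waals radii (Å) shipped with the package for bit-stable results.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.10,
    "P": 1.80,
    "SE": 1.90,
}

#: Radius used when an element is missing from the table.
FALLBACK_RADIUS: float = 1.80

DEFAULT_PROBE: float = 1.4
DEFAULT_N_POINTS: int = 960


@dataclass(frozen=True)
class SasaResult:
    """Per-atom solvent-accessible areas for one structure."""

    per_atom: np.ndarray     # Å² per atom, order matching the input model
    probe_radius: float
    n_points: int
    radii: np.ndarray        # vdW radius assigned to each atom

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def atom_radii(elements: np.ndarray) -> np.ndarray:
    radii = np.empty(len(elements))
    missing = set()
    for i, el in enumerate(elements):
        key = str(el).upper()
        r = VDW_RADII.get(key)
        if r is None:
            missing.add(key)
            r = FALLBACK_RADIUS
        radii[i] = r
    if missing:
        warnings.warn(
            f"no vdW radius for element(s) {sorted(missing)}; "
            f"using fallback {FALLBACK_RADIUS} Å"
        )
    return radii


def shrake_rupley_sasa(
    model: StructureModel,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    include_hetero: bool = False,
    include_hydrogens: bool = False,
) -> SasaResult:
    """Accessible surface area of every atom of ``model``.

    Waters, glycans and other heteroatoms are excluded by default (they are
    not part of the protein surface being compared across structures), as
    are hydrogens, which crystal structures rarely resolve.
    """
    work = model if include_hetero else model.polymer()
    if not include_hydrogens:
        work = work.heavy()
    if len(work) == 0:
        return SasaResult(np.zeros(0), probe, n_points, np.zeros(0))
    radii = atom_radii(work.elements)
    coords = work.coords
    inflated = radii + probe
    pts = sphere_points(n_points)

    tree = cKDTree(coords)
    areas = np.zeros(len(work))
    for i in range(len(work)):
        ri = inflated[i]
        neighbors = tree.query_ball_point(coords[i], ri + inflated.max())
        neighbors = [j for j in neighbors if j != i]
        surface = coords[i] + ri * pts
        if neighbors:
            nb = np.asarray(neighbors)
            d2 = ((surface[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (inflated[nb] ** 2)[None, :]).any(axis=1)
            accessible = np.count_nonzero(~buried)
        else:
            accessible = n_points
        areas[i] = 4.0 * np.pi * ri * ri * accessible / n_points
    return SasaResult(areas, probe, n_points, radii)
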