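"""Intermembrane zipper geometry.

In the zipper assembly two membranes are spanned by Ig1-3 arms that emerge
from FNIII cis-dimer bases on each surface and meet in antiparallel
Ig1:Ig1 trans-dimers. With arm length ``L_arm``, antiparallel Ig1 overlap
``o``, base height ``h`` (all nm) and the arms tilted at angle ``theta`` to
the membrane plane, the intermembrane distance is

    d = 2 h + (2 L_arm − o) · sin(theta)

Fixing d to the ~24 nm adhesion-interface spacing measured for Drosophila
Dscam1 and inverting for theta gives the arm tilt the model predicts
(~53° with domain dimensions taken from the deposited sDscam fragments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace


@dataclass(frozen=True)
class GeometryModel:
    """Dimensions of the zipper unit cell, all in nm (theta in degrees)."""

    L_arm: float          # Ig1-3 arm length along its principal axis
    overlap: float        # antiparallel Ig1:Ig1 overlap length
    h: float              # FNIII cis-dimer height normal to the membrane
    d: float | None = None      # intermembrane distance
    theta: float | None = None  # arm tilt from the membrane plane

    def __post_init__(self) -> None:
        if self.L_arm <= 0 or self.h < 0 or self.overlap < 0:
            raise ValueError("lengths must be positive (h, overlap >= 0)")
        if 2 * self.L_arm <= self.overlap:
            raise ValueError("need 2*L_arm > overlap")
        if self.theta is not None and not (0.0 <= self.theta <= 90.0):
            raise ValueError("theta must lie in [0, 90] degrees")

    @property
    def span(self) -> float:
        """Projected arm span 2·L_arm − o available to tilt."""
        return 2.0 * self.L_arm - self.overlap


class GeometryInfeasibleError(ValueError):
    """The requested intermembrane distance is outside the attainable range."""


def intermembrane_distance(model: GeometryModel, theta: float | None = None) -> float:
    """d(theta) = 2h + span·sin(theta); theta in degrees."""
    t = model.theta if theta is None else theta
    if t is None:
        raise ValueError("theta not set")
    return 2.0 * model.h + model.span * math.sin(math.radians(t))


def solve_zipper_geometry(model: GeometryModel) -> GeometryModel:
    """Solve the arm tilt from the intermembrane distance.

    theta = arcsin((d − 2h) / (2·L_arm − o)), returned in degrees; the
    round trip ``intermembrane_distance(solve(model))`` reproduces ``d``
    exactly. Raises :class:`GeometryInfeasibleError` when ``d`` lies outside
    [2h, 2h + span], reporting the attainable range.
    """
    if model.d is None:
        raise ValueError("model.d must be set to solve for theta")
    lo, hi = 2.0 * model.h, 2.0 * model.h + model.span
    sin_t = (model.d - 2.0 * model.h) / model.span
    if sin_t < 0.0 or sin_t > 1.0:
        raise GeometryInfeasibleError(
            f"d = {model.d:.3g} nm is unreachable; this geometry attains "
            f"d in [{lo:.3g}, {hi:.3g}] nm"
        )
    return replace(model, theta=math.degrees(math.asin(sin_t)))
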