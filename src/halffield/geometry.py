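"""Half-field dish geometry, region classification, and penumbral dose model.

A single circular culture dish is half-covered by a lead block during
irradiation, splitting it into an irradiated (In-field) half and a shielded
(Out-of-field) half.  A band of configurable width straddling the shield edge
is excluded from analysis because the dose gradient (penumbra) there is steep
and the physical setup uncertain.  All geometry is expressed in millimetres
with the origin at the dish centre; the shield edge is the vertical line
``x = boundary_x`` and the irradiated half is ``x < boundary_x``.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.special import ndtr


class FieldLabel(str, Enum):
    """Region assignment of a position on a half-field dish."""

    IN_FIELD = "IN_FIELD"
    OUT_OF_FIELD = "OUT_OF_FIELD"
    EXCLUDED = "EXCLUDED"
    OUTSIDE_DISH = "OUTSIDE_DISH"


@dataclass(frozen=True)
class DishGeometry:
    """Geometry of a half-field irradiated culture dish.

    Parameters
    ----------
    diameter : float
        Dish diameter in mm (default 60, a standard 60 mm dish).
    boundary_x : float
        x position of the shield edge in mm (default 0, dish centre).
    exclusion_half_width : float
        Half-width in mm of the analysis-exclusion band centred on the
        shield edge.  The default 10 mm realises a 20 mm wide exclusion
        region; set 20 for the alternative reading in which 20 mm is the
        half-width.
    penumbra_sigma : float
        Width parameter (mm) of the sigmoidal dose falloff at the field
        edge.  The falloff is modelled as a normal CDF.
    nominal_dose : float
        Dose (Gy) delivered deep inside the irradiated half.
    """

    diameter: float = 60.0
    boundary_x: float = 0.0
    exclusion_half_width: float = 10.0
    penumbra_sigma: float = 1.0
    nominal_dose: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < 2.0 * self.exclusion_half_width < self.diameter:
            raise ValueError(
                "exclusion band must be non-empty and narrower than the dish: "
                f"0 < {2 * self.exclusion_half_width} < {self.diameter} fails"
            )
        if self.penumbra_sigma <= 0:
            raise ValueError("penumbra_sigma must be > 0")
        if self.nominal_dose < 0:
            raise ValueError("nominal_dose must be >= 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


def assign_field(position: tuple[float, float], geometry: DishGeometry) -> FieldLabel:
    """Classify a position (x mm, y mm) into a dish region.

    A position is OUTSIDE_DISH when it lies beyond the dish radius,
    EXCLUDED when its x coordinate lies within ``exclusion_half_width`` of
    the shield edge (inclusive), IN_FIELD on the irradiated side
    (``x < boundary_x``) and OUT_OF_FIELD on the shielded side.  Total
    function: every position receives exactly one label.
    """
    x, y = float(position[0]), float(position[1])
    if np.hypot(x, y) > geometry.radius:
        return FieldLabel.OUTSIDE_DISH
    if abs(x - geometry.boundary_x) <= geometry.exclusion_half_width:
        return FieldLabel.EXCLUDED
    return FieldLabel.IN_FIELD if x < geometry.boundary_x else FieldLabel.OUT_OF_FIELD


def dose_at(position: tuple[float, float], geometry: DishGeometry) -> float:
    """Dose (Gy) at a position inside the dish under the penumbra model.

    The lateral profile is ``nominal_dose * Phi((boundary_x - x) / sigma)``
    with Phi the standard normal CDF: saturated at ``nominal_dose`` deep in
    the irradiated half, half the nominal dose exactly at the shield edge,
    and monotonically non-increasing with x.  Dose scattered by secondary
    electrons is deliberately not modelled.
    """
    x, y = float(position[0]), float(position[1])
    if np.hypot(x, y) > geometry.radius:
        raise ValueError(f"position ({x}, {y}) mm lies outside the dish")
    return geometry.nominal_dose * float(
        ndtr((geometry.boundary_x - x) / geometry.penumbra_sigma)
    )


def analyzable_fraction(geometry: DishGeometry) -> float:
    """Fraction of the dish area outside the exclusion band, in closed form.

    The excluded area is the part of the disc between the two vertical
    chords at ``boundary_x -/+ exclusion_half_width``; for a band centred on
    the dish (``boundary_x = 0``) its area is
    ``2 * (w * sqrt(R^2 - w^2) + R^2 * arcsin(w / R))``.  Off-centre
    boundaries are handled by integrating each chordal cap separately.
    """
    r = geometry.radius
    lo = np.clip(geometry.boundary_x - geometry.exclusion_half_width, -r, r)
    hi = np.clip(geometry.boundary_x + geometry.exclusion_half_width, -r, r)

    def antiderivative(x: float) -> float:
        # integral of the chord length 2*sqrt(R^2 - x^2)
        return x * np.sqrt(max(r * r - x * x, 0.0)) + r * r * np.arcsin(x / r)

    band = antiderivative(hi) - antiderivative(lo)
    return float(1.0 - band / (np.pi * r * r))
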