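"""Closed-form geometric model of the A-T advancement flap.

An A-T flap converts a circular skin defect of radius ``r`` into an
isosceles-triangle excision (apex angle ``2*theta``) whose base lies on a
horizontal incision line; the base incision is extended laterally and the
two lateral sheets are advanced medially, leaving a T-shaped scar.

Three quantities drive the preoperative design, all functions of the
half-apex angle ``theta`` and the defect radius ``r``:

* length-width ratio      ``h/d = 1 / (2 tan(theta))``
* maximum suture distance ``d   = 2 r (1 + sin(theta)) / cos(theta)``
* suture (excision) area  ``S   = r^2 (1 + sin(theta))^2 / (sin(theta) cos(theta))``

The defect circle is inscribed against the triangle: tangent to both waists
and to the base line, which is what ties ``d`` and ``S`` to ``r``.

The design convention places the triangle base on the x axis centred at the
origin (the future T-joint), apex on +y, all lengths in mm.  Angles are
radians internally; the user-facing apex angle (``2*theta``) is in degrees
at CLI/config boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FlapDesign",
    "length_width_ratio",
    "max_suture_distance",
    "suture_area",
    "sweep",
    "optimal_apex",
    "design_flap",
]


def _check_theta(theta: float) -> None:
    if not (0.0 < theta < math.pi / 2):
        raise ValueError(f"half-apex angle must lie in (0, pi/2); got {theta!r}")


def _check_radius(r: float) -> None:
    if not r > 0.0:
        raise ValueError(f"defect radius must be positive; got {r!r}")


def length_width_ratio(theta: float) -> float:
    """Length-width ratio h/d of the flap at half-apex angle ``theta`` (rad).

    Strictly decreasing in ``theta``: slimmer triangles are proportionally
    longer.
    """
    _check_theta(theta)
    return 1.0 / (2.0 * math.tan(theta))


def max_suture_distance(r: float, theta: float) -> float:
    """Maximum suture distance d (mm): the triangle base width.

    This is the widest span that has to be pulled together during closure.
    Strictly increasing in ``theta`` and proportional to ``r``; tends to the
    defect diameter ``2 r`` as ``theta -> 0``.
    """
    _check_radius(r)
    _check_theta(theta)
    return 2.0 * r * (1.0 + math.sin(theta)) / math.cos(theta)


def suture_area(r: float, theta: float) -> float:
    """Suture area S (mm^2): area of the excised triangle.

    Equals ``d * h / 2`` of the other two relations; scales with ``r**2``.
    """
    _check_radius(r)
    _check_theta(theta)
    s, c = math.sin(theta), math.cos(theta)
    return r * r * (1.0 + s) ** 2 / (s * c)


def suture_area_derivative(theta: float) -> float:
    """d(log S)/d(theta) for r = 1: ``2 cos/(1+sin) - cot + tan``.

    Vanishes exactly at ``theta = pi/6`` (apex angle 60 deg), the minimum of
    the suture area.  Exposed for the analytic optimality check.
    """
    _check_theta(theta)
    s, c = math.sin(theta), math.cos(theta)
    return 2.0 * c / (1.0 + s) - c / s + s / c


def sweep(r: float, apex_angles_deg) -> pd.DataFrame:
    """Design table over apex angles (degrees), one row per angle.

    Columns: ``apex_deg``, ``ratio`` (h/d), ``d_mm``, ``S_mm2``,
    ``h_mm`` and ``S_over_r2`` (the dimensionless area, which is what the
    published comparison table prints under its area column).
    """
    _check_radius(r)
    rows = []
    for apex in apex_angles_deg:
        theta = math.radians(apex) / 2.0
        ratio = length_width_ratio(theta)
        d = max_suture_distance(r, theta)
        S = suture_area(r, theta)
        rows.append(
            {
                "apex_deg": float(apex),
                "ratio": ratio,
                "d_mm": d,
                "S_mm2": S,
                "h_mm": ratio * d,
                "S_over_r2": S / (r * r),
            }
        )
    return pd.DataFrame(
        rows, columns=["apex_deg", "ratio", "d_mm", "S_mm2", "h_mm", "S_over_r2"]
    )


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching the printed design tables."""
    q = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


def optimal_apex(
    ratio_max: float = 3.0,
    theta_range_deg: tuple[float, float] = (5.0, 85.0),
    resolution_deg: float = 0.001,
) -> float:
    """Apex angle (degrees) minimising the suture area S(theta).

    The minimisation is subject to the clinical length-width bound
    ``h/d <= ratio_max`` (classical advancement flaps use 1:1 to 2:1, with
    3:1 as the blood-supply limit).  Since ``h/d`` decreases with ``theta``,
    the bound is a lower bound on ``theta``; since ``S`` has a unique
    interior minimum at ``theta = pi/6``, the constrained optimum is either
    60 degrees or the constraint boundary.

    A grid search at ``resolution_deg`` over the admissible half-angle range
    is used rather than the closed form so that the routine remains valid
    for any monotone constraint set.
    """
    if not ratio_max > 0.0:
        raise ValueError("ratio_max must be positive")
    lo, hi = (math.radians(a) for a in theta_range_deg)
    # h/d <= ratio_max  <=>  tan(theta) >= 1/(2*ratio_max)
    theta_min = math.atan(1.0 / (2.0 * ratio_max))
    lo = max(lo, theta_min)
    if lo >= hi:
        raise ValueError(
            f"constraint h/d <= {ratio_max} infeasible on the angle range "
            f"{theta_range_deg} deg"
        )
    n = max(2, int(round(math.degrees(hi - lo) / resolution_deg)) + 1)
    thetas = np.linspace(lo, hi, n)
    s, c = np.sin(thetas), np.cos(thetas)
    S = (1.0 + s) ** 2 / (s * c)
    return float(math.degrees(2.0 * thetas[int(np.argmin(S))]))


@dataclass(frozen=True)
class FlapDesign:
    """A fully determined A-T flap design.

    Lengths in mm, angles in radians (``half_apex``); ``incision_layout``
    holds the 2-D points of the planned incisions: triangle apex, base
    corners B and C, and the lateral base-extension endpoints.
    """

    defect_radius: float
    half_apex: float
    flap_length: float
    flap_width: float
    ratio: float
    suture_area: float
    incision_layout: dict = field(default_factory=dict)

    @property
    def apex_angle_deg(self) -> float:
        return math.degrees(2.0 * self.half_apex)

    def validate(self, rtol: float = 1e-9) -> None:
        """Check the internal consistency of the closed-form relations."""
        r, th = self.defect_radius, self.half_apex
        _check_radius(r)
        _check_theta(th)
        for got, want, name in [
            (self.ratio, length_width_ratio(th), "ratio"),
            (self.flap_width, max_suture_distance(r, th), "flap_width"),
            (self.suture_area, suture_area(r, th), "suture_area"),
            (self.flap_length, self.ratio * self.flap_width, "flap_length"),
            (self.suture_area, self.flap_width * self.flap_length / 2.0, "area=d*h/2"),
        ]:
            if abs(got - want) > rtol * max(1.0, abs(want)):
                raise ValueError(f"inconsistent design field {name}: {got} vs {want}")


def design_flap(
    r: float, apex_angle_deg: float, base_extension_factor: float = 3.0
) -> FlapDesign:
    """Build a :class:`FlapDesign` from radius (mm) and apex angle (deg).

    ``base_extension_factor`` encodes the clinical rule that the total base
    incision runs about 3 defect diameters: the lateral extensions are sized
    so the full horizontal incision length is ``factor * 2 r`` (floored at
    the triangle base width ``d``).
    """
    if base_extension_factor < 1.0:
        raise ValueError("base_extension_factor must be >= 1")
    theta = math.radians(apex_angle_deg) / 2.0
    ratio = length_width_ratio(theta)
    d = max_suture_distance(r, theta)
    S = suture_area(r, theta)
    h = ratio * d
    half_span = max(d / 2.0, base_extension_factor * r)
    layout = {
        "apex": (0.0, h),
        "base_corner_left": (-d / 2.0, 0.0),
        "base_corner_right": (d / 2.0, 0.0),
        "extension_end_left": (-half_span, 0.0),
        "extension_end_right": (half_span, 0.0),
    }
    design = FlapDesign(
        defect_radius=r,
        half_apex=theta,
        flap_length=h,
        flap_width=d,
        ratio=ratio,
        suture_area=S,
        incision_layout=layout,
    )
    design.validate()
    return design
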