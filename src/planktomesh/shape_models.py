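"""Closed-form geometric proxies for plankton cell morphometry.

Classical biovolume work approximates a cell by a simple solid (sphere,
spheroid, ellipsoid, capsule, cylinder, or a drop-shaped solid of revolution)
and reads surface area and volume off the corresponding formula.  These
proxies contextualize mesh-based morphometry and provide exact ground truth
for the tessellated test fixtures.

Dimensions are micrometres.  Spheroids use ``a`` for the equatorial semi-axis
(the two equal ones) and ``c`` for the polar semi-axis: prolate means c > a
(cigar), oblate c < a (lens).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

from scipy.integrate import quad

__all__ = [
    "GeometricShape",
    "shape_surface_area",
    "shape_volume",
    "drop_profile",
    "sphere",
    "prolate_spheroid",
    "oblate_spheroid",
    "general_ellipsoid",
    "capsule",
    "cylinder",
]

_KINDS = {
    "sphere", "prolate_spheroid", "oblate_spheroid", "general_ellipsoid",
    "capsule", "cylinder", "drop_of_revolution",
}

#: Exponent of the Thomsen approximation for the general-ellipsoid surface
#: area, S ≈ 4π((a^p b^p + a^p c^p + b^p c^p)/3)^(1/p); worst-case relative
#: error about 1.1%.
THOMSEN_P = 1.6075


@dataclass(frozen=True)
class GeometricShape:
    """A named solid with positive dimensions in μm.

    ``profile`` is only set for ``drop_of_revolution``: the radius r(z) of the
    surface of revolution, defined on z in [0, length].
    """

    kind: str
    dimensions: dict[str, float]
    profile: Callable[[float], float] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}")
        for name, value in self.dimensions.items():
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"{self.kind} dimension {name}={value} must be positive")
        d = self.dimensions
        if self.kind == "prolate_spheroid" and not d["c"] > d["a"]:
            raise ValueError("prolate spheroid requires c > a")
        if self.kind == "oblate_spheroid" and not d["c"] < d["a"]:
            raise ValueError("oblate spheroid requires c < a")
        if self.kind == "drop_of_revolution" and self.profile is None:
            raise ValueError("drop_of_revolution requires a radius profile")


def sphere(r: float) -> GeometricShape:
    return GeometricShape("sphere", {"r": r})


def prolate_spheroid(a: float, c: float) -> GeometricShape:
    """Equatorial semi-axis ``a`` (= b), polar semi-axis ``c`` > a."""
    return GeometricShape("prolate_spheroid", {"a": a, "c": c})


def oblate_spheroid(a: float, c: float) -> GeometricShape:
    """Equatorial semi-axis ``a`` (= b), polar semi-axis ``c`` < a."""
    return GeometricShape("oblate_spheroid", {"a": a, "c": c})


def general_ellipsoid(a: float, b: float, c: float) -> GeometricShape:
    return GeometricShape("general_ellipsoid", {"a": a, "b": b, "c": c})


def capsule(r: float, h: float) -> GeometricShape:
    """Cylinder of radius ``r`` and height ``h`` with hemispherical caps."""
    return GeometricShape("capsule", {"r": r, "h": h})


def cylinder(r: float, h: float) -> GeometricShape:
    return GeometricShape("cylinder", {"r": r, "h": h})


def shape_surface_area(shape: GeometricShape) -> float:
    """Surface area in μm² from the classical closed forms.

    Sphere 4πr²; prolate spheroid 2πa²(1 + (c/(a e))·arcsin e) with
    e = sqrt(1 − a²/c²); oblate spheroid 2πa² + (πc²/e)·ln((1+e)/(1−e)) with
    e = sqrt(1 − c²/a²); general ellipsoid via the Thomsen approximation;
    capsule 2πrh + 4πr²; cylinder 2πr(r + h); drop of revolution by quadrature
    of 2π r(z) sqrt(1 + r'(z)²).
    """
    d = shape.dimensions
    if shape.kind == "sphere":
        return 4.0 * math.pi * d["r"] ** 2
    if shape.kind == "prolate_spheroid":
        a, c = d["a"], d["c"]
        e = math.sqrt(1.0 - a * a / (c * c))
        return 2.0 * math.pi * a * a * (1.0 + (c / (a * e)) * math.asin(e))
    if shape.kind == "oblate_spheroid":
        a, c = d["a"], d["c"]
        e = math.sqrt(1.0 - c * c / (a * a))
        return 2.0 * math.pi * a * a + (math.pi * c * c / e) * math.log((1.0 + e) / (1.0 - e))
    if shape.kind == "general_ellipsoid":
        a, b, c = d["a"], d["b"], d["c"]
        p = THOMSEN_P
        mean = ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
        return 4.0 * math.pi * mean ** (1.0 / p)
    if shape.kind == "capsule":
        return 2.0 * math.pi * d["r"] * d["h"] + 4.0 * math.pi * d["r"] ** 2
    if shape.kind == "cylinder":
        return 2.0 * math.pi * d["r"] * (d["r"] + d["h"])
    if shape.kind == "drop_of_revolution":
        length = d["length"]
        r = shape.profile

        def integrand(z: float) -> float:
            eps = 1e-7 * length
            drdz = (r(min(z + eps, length)) - r(max(z - eps, 0.0))) / (
                min(z + eps, length) - max(z - eps, 0.0)
            )
            return 2.0 * math.pi * r(z) * math.sqrt(1.0 + drdz * drdz)

        val, _ = quad(integrand, 0.0, length, limit=200)
        return val
    raise AssertionError(shape.kind)


def shape_volume(shape: GeometricShape) -> float:
    """Volume in μm³: sphere (4/3)πr³; spheroids and ellipsoids (4/3)πabc;
    capsule πr²h + (4/3)πr³; cylinder πr²h; drop of revolution by quadrature
    of π∫ r(z)² dz."""
    d = shape.dimensions
    if shape.kind == "sphere":
        return (4.0 / 3.0) * math.pi * d["r"] ** 3
    if shape.kind in ("prolate_spheroid", "oblate_spheroid"):
        return (4.0 / 3.0) * math.pi * d["a"] * d["a"] * d["c"]
    if shape.kind == "general_ellipsoid":
        return (4.0 / 3.0) * math.pi * d["a"] * d["b"] * d["c"]
    if shape.kind == "capsule":
        return math.pi * d["r"] ** 2 * d["h"] + (4.0 / 3.0) * math.pi * d["r"] ** 3
    if shape.kind == "cylinder":
        return math.pi * d["r"] ** 2 * d["h"]
    if shape.kind == "drop_of_revolution":
        r = shape.profile
        val, _ = quad(lambda z: math.pi * r(z) ** 2, 0.0, d["length"], limit=200)
        return val
    raise AssertionError(shape.kind)


def drop_profile(length: float, max_width: float, shoulder: float = 0.5) -> GeometricShape:
    """Pyriform (drop-shaped) solid of revolution, the gross morphology of a
    Prorocentrum-like cell: rounded at the anterior end, widest at
    ``z = shoulder * length``, tapering to a point at the posterior end.

    The radius profile is C¹-smooth and piecewise:

    * anterior, z in [0, z_s]: quarter ellipse
      r(z) = (W/2) sqrt(1 − ((z_s − z)/z_s)²)  — vertical tangent at z = 0
      (a rounded tip), horizontal tangent at the shoulder;
    * posterior, z in (z_s, L]: parabolic taper
      r(z) = (W/2)(1 − u²), u = (z − z_s)/(L − z_s) — horizontal tangent at
      the shoulder, finite slope (a point) at z = L.

    r(0) = r(L) = 0 and r > 0 in between.
    """
    if not 0.0 < shoulder < 1.0:
        raise ValueError("shoulder must lie strictly between 0 and 1")
    if not (length > 0 and max_width > 0):
        raise ValueError("length and max_width must be positive")
    z_s = shoulder * length
    half_w = max_width / 2.0

    def profile(z: float) -> float:
        if z <= 0.0 or z >= length:
            return 0.0
        if z <= z_s:
            t = (z_s - z) / z_s
            return half_w * math.sqrt(max(0.0, 1.0 - t * t))
        u = (z - z_s) / (length - z_s)
        return half_w * (1.0 - u * u)

    return GeometricShape(
        "drop_of_revolution",
        {"length": length, "max_width": max_width, "shoulder": shoulder},
        profile=profile,
    )
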