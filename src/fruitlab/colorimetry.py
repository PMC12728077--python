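"""CIELAB colour arithmetic for fruit-skin colorimetry.

The colorimeter delivers one (L*, a*, b*) triple per fruit.  This module
provides the derived parameters used throughout the pipeline — chroma C*,
hue angle H*, the Euclidean total colour difference ΔE*, stage-transition
deltas between harvest maturity and physiological ripeness — plus the
CIELAB → sRGB conversion used to render colour swatches.

Conventions
-----------
* Hue uses the quadrant-aware two-argument arctangent mapped to [0, 360).
* The Lab → sRGB conversion assumes the D65 white point, the 2° standard
  observer, sRGB primaries and the IEC 61966-2-1 transfer function;
  channels are clipped to [0, 1] and rounded half-up to 0–255.
* The signed hue difference is the smallest angular difference in
  (−180, 180], positive counter-clockwise in the (a*, b*) plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LabColor",
    "ColorDelta",
    "RGBColor",
    "chroma",
    "hue",
    "delta_e",
    "aggregate_replicates",
    "hue_difference",
    "stage_deltas",
    "lab_to_rgb",
    "rgb_to_lab",
    "rgb_hex",
]


@dataclass(frozen=True)
class LabColor:
    """One colorimeter reading: L* in [0, 100], a* and b* unbounded."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        for name, v in (("L", self.L), ("a", self.a), ("b", self.b)):
            if not math.isfinite(v):
                raise ValueError(f"{name}* must be finite, got {v!r}")
        if not 0.0 <= self.L <= 100.0:
            raise ValueError(f"L* must lie in [0, 100], got {self.L}")

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)


@dataclass(frozen=True)
class ColorDelta:
    """Stage-transition deltas (physiological ripeness minus harvest)."""

    dL: float
    da: float
    db: float
    dE: float
    dC: float
    dH: float


@dataclass(frozen=True)
class RGBColor:
    """8-bit sRGB triple; ``gamut_clipped`` marks out-of-gamut Lab input."""

    r: int
    g: int
    b: int
    gamut_clipped: bool = False

    def __post_init__(self) -> None:
        for c in (self.r, self.g, self.b):
            if not 0 <= c <= 255:
                raise ValueError(f"channel out of range: {c}")


def _lab(c: "LabColor | Sequence[float]") -> LabColor:
    if isinstance(c, LabColor):
        return c
    L, a, b = c
    return LabColor(float(L), float(a), float(b))


def chroma(lab: "LabColor | Sequence[float]") -> float:
    """C* = sqrt(a*² + b*²), the radial distance in the (a*, b*) plane."""
    lab = _lab(lab)
    return math.hypot(lab.a, lab.b)


def hue(lab: "LabColor | Sequence[float]") -> float:
    """Hue angle H* in degrees in [0, 360); undefined at a* = b* = 0."""
    lab = _lab(lab)
    if lab.a == 0.0 and lab.b == 0.0:
        raise ValueError("hue is undefined at the achromatic point a*=b*=0")
    return math.degrees(math.atan2(lab.b, lab.a)) % 360.0


def delta_e(x: "LabColor | Sequence[float]", y: "LabColor | Sequence[float]") -> float:
    """Euclidean total colour difference ΔE* between two Lab points."""
    x, y = _lab(x), _lab(y)
    return math.sqrt((x.L - y.L) ** 2 + (x.a - y.a) ** 2 + (x.b - y.b) ** 2)


def aggregate_replicates(readings: Iterable["LabColor | Sequence[float]"]) -> LabColor:
    """Component-wise mean of replicate fruit readings (accession value)."""
    arr = np.array([_lab(r).as_array() for r in readings], dtype=float)
    if arr.size == 0:
        raise ValueError("cannot aggregate an empty list of readings")
    m = arr.mean(axis=0)
    return LabColor(float(m[0]), float(m[1]), float(m[2]))


def hue_difference(h_from: float, h_to: float) -> float:
    """Signed smallest angular difference h_to − h_from, in (−180, 180]."""
    d = (h_to - h_from) % 360.0
    if d > 180.0:
        d -= 360.0
    return d


def stage_deltas(h: "LabColor | Sequence[float]", p: "LabColor | Sequence[float]") -> ColorDelta:
    """Per-accession colour change from harvest maturity to ripeness.

    dL/da/db are signed (ripeness minus harvest), dE is the Euclidean
    total difference, dC the chroma change and dH the signed smallest
    hue-angle change (0 when either stage is achromatic).
    """
    h, p = _lab(h), _lab(p)
    d_l, d_a, d_b = p.L - h.L, p.a - h.a, p.b - h.b
    d_c = chroma(p) - chroma(h)
    if (h.a == 0.0 and h.b == 0.0) or (p.a == 0.0 and p.b == 0.0):
        d_h = 0.0
    else:
        d_h = hue_difference(hue(h), hue(p))
    return ColorDelta(d_l, d_a, d_b, delta_e(h, p), d_c, d_h)


# --- CIELAB <-> sRGB (D65, 2° observer, IEC 61966-2-1) -------------------

_WHITE_D65 = np.array([0.95047, 1.0, 1.08883])
_XYZ_TO_RGB = np.array(
    [
        [3.2404542, -1.5371385, -0.4985314],
        [-0.9692660, 1.8760108, 0.0415560],
        [0.0556434, -0.2040259, 1.0572252],
    ]
)
_RGB_TO_XYZ = np.linalg.inv(_XYZ_TO_RGB)
_DELTA = 6.0 / 29.0


def _f_inv(t: np.ndarray) -> np.ndarray:
    return np.where(t > _DELTA, t**3, 3.0 * _DELTA**2 * (t - 4.0 / 29.0))


def _f(t: np.ndarray) -> np.ndarray:
    return np.where(t > _DELTA**3, np.cbrt(t), t / (3.0 * _DELTA**2) + 4.0 / 29.0)


def _gamma_encode(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * np.power(np.clip(c, 0.0, None), 1 / 2.4) - 0.055)


def _gamma_decode(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.04045, c / 12.92, np.power((c + 0.055) / 1.055, 2.4))


def lab_to_rgb(lab: "LabColor | Sequence[float]") -> RGBColor:
    """Convert a Lab colour to 8-bit sRGB, flagging out-of-gamut input.

    Channels outside [0, 1] before quantisation are clipped and the
    result carries ``gamut_clipped=True``.  Rounding is half-up.
    """
    lab = _lab(lab)
    fy = (lab.L + 16.0) / 116.0
    fx = fy + lab.a / 500.0
    fz = fy - lab.b / 200.0
    xyz = _f_inv(np.array([fx, fy, fz])) * _WHITE_D65
    lin = _XYZ_TO_RGB @ xyz
    srgb = _gamma_encode(lin)
    # tolerance absorbs the ~6e-8 inconsistency between the published
    # 7-digit sRGB matrix and the D65 white point
    clipped = bool(np.any(srgb < -1e-6) | np.any(srgb > 1.0 + 1e-6))
    srgb = np.clip(srgb, 0.0, 1.0)
    r, g, b = (int(v) for v in np.floor(srgb * 255.0 + 0.5))
    return RGBColor(r, g, b, gamut_clipped=clipped)


def rgb_to_lab(r: int, g: int, b: int) -> LabColor:
    """Inverse conversion (8-bit sRGB → Lab), for round-trip checks."""
    srgb = np.array([r, g, b], dtype=float) / 255.0
    if np.any(srgb < 0) or np.any(srgb > 1):
        raise ValueError("RGB channels must lie in [0, 255]")
    xyz = _RGB_TO_XYZ @ _gamma_decode(srgb)
    fx, fy, fz = _f(xyz / _WHITE_D65)
    L = 116.0 * fy - 16.0
    return LabColor(float(np.clip(L, 0.0, 100.0)), float(500.0 * (fx - fy)), float(200.0 * (fy - fz)))


def rgb_hex(rgb: RGBColor) -> str:
    """``#RRGGBB`` hex string for report output."""
    return f"#{rgb.r:02X}{rgb.g:02X}{rgb.b:02X}"
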