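"""Color-space conversions and the CIE76 color difference.

8-bit sRGB (IEC 61966-2-1 transfer curve, D65 native white) is converted to
CIE XYZ and CIELAB; CIELAB values carry an illuminant tag (D65 or D50) and
cross-illuminant values are re-expressed with the Bradford chromatic
adaptation transform. The color difference ``delta_e_ab`` is the plain
Euclidean distance in CIELAB (CIE76) — the metric used throughout skin
colorimetry, with ~3.0 commonly taken as the threshold of a just-noticeable
difference for a human observer.

Array functions operate on ``(..., 3)`` float arrays; the small dataclasses
:class:`SRGBColor` and :class:`LABColor` give a typed scalar interface with
range and illuminant checking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Illuminant",
    "ILLUMINANTS",
    "SRGBColor",
    "LABColor",
    "GamutError",
    "IlluminantMismatchError",
    "srgb_to_lab",
    "lab_to_srgb",
    "adapt_white",
    "delta_e_ab",
    "srgb_to_xyz",
    "xyz_to_srgb",
    "xyz_to_lab",
    "lab_to_xyz",
    "adapt_xyz",
]


class GamutError(ValueError):
    """A CIELAB color falls outside the sRGB gamut and clipping was refused."""


class IlluminantMismatchError(ValueError):
    """Two CIELAB values under different illuminants were combined."""


@dataclass(frozen=True)
class Illuminant:
    """A reference white: name plus XYZ tristimulus with Y normalized to 1."""

    name: str
    white_point: tuple[float, float, float]

    def __post_init__(self) -> None:
        wp = np.asarray(self.white_point, dtype=float)
        if wp.shape != (3,) or not np.all(wp > 0):
            raise ValueError("white_point must be a strictly positive XYZ triplet")
        if abs(wp[1] - 1.0) > 1e-9:
            raise ValueError("white_point Y must be normalized to 1")


# CIE 1931 2-degree observer tristimulus values (ASTM E308 scaling, Y = 1).
ILLUMINANTS: dict[str, Illuminant] = {
    "D65": Illuminant("D65", (0.95047, 1.0, 1.08883)),
    "D50": Illuminant("D50", (0.96422, 1.0, 0.82521)),
}


def _resolve_illuminant(illum: "Illuminant | str") -> Illuminant:
    if isinstance(illum, Illuminant):
        return illum
    try:
        return ILLUMINANTS[str(illum).upper()]
    except KeyError:
        raise ValueError(f"unknown illuminant {illum!r}; expected one of {sorted(ILLUMINANTS)}") from None


def _rgb_to_xyz_matrix() -> np.ndarray:
    # Derived from the sRGB primaries and D65 white so that RGB=(1,1,1) maps
    # exactly onto the white point (rows sum to it by construction).
    xy = np.array([[0.64, 0.33], [0.30, 0.60], [0.15, 0.06]])
    prim = np.stack(
        [xy[:, 0] / xy[:, 1], np.ones(3), (1.0 - xy[:, 0] - xy[:, 1]) / xy[:, 1]],
        axis=0,
    )  # columns are primaries' XYZ at unit Y
    scale = np.linalg.solve(prim, np.asarray(ILLUMINANTS["D65"].white_point))
    return prim * scale


_M_RGB2XYZ = _rgb_to_xyz_matrix()
_M_XYZ2RGB = np.linalg.inv(_M_RGB2XYZ)

# Bradford cone-response matrix.
_M_BRADFORD = np.array(
    [
        [0.8951, 0.2664, -0.1614],
        [-0.7502, 1.7135, 0.0367],
        [0.0389, -0.0685, 1.0296],
    ]
)
_M_BRADFORD_INV = np.linalg.inv(_M_BRADFORD)

_EPS = (6.0 / 29.0) ** 3  # CIE f(t) linear-segment breakpoint
_KAPPA = (29.0 / 6.0) ** 2 / 3.0


def srgb_decode(v: np.ndarray) -> np.ndarray:
    """IEC 61966-2-1 decoding of normalized sRGB values to linear light."""
    v = np.asarray(v, dtype=float)
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def srgb_encode(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`srgb_decode` (linear light to normalized sRGB)."""
    v = np.asarray(v, dtype=float)
    vc = np.clip(v, 0.0, None)
    return np.where(v <= 0.0031308, v * 12.92, 1.055 * vc ** (1.0 / 2.4) - 0.055)


def srgb_to_xyz(rgb: np.ndarray) -> np.ndarray:
    """8-bit sRGB ``(..., 3)`` in [0, 255] to XYZ (D65, Y of white = 1)."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape[-1] != 3:
        raise ValueError("expected trailing axis of size 3")
    if np.any(rgb < 0) or np.any(rgb > 255):
        raise ValueError("sRGB channels must lie in [0, 255]")
    return srgb_decode(rgb / 255.0) @ _M_RGB2XYZ.T


def xyz_to_srgb(xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """XYZ (D65) to 8-bit sRGB.

    Returns ``(rgb, in_gamut)`` where out-of-gamut results are clipped to
    [0, 255] and flagged ``False`` in the boolean mask (one flag per color).
    """
    lin = np.asarray(xyz, dtype=float) @ _M_XYZ2RGB.T
    in_gamut = np.all((lin >= -1e-9) & (lin <= 1.0 + 1e-9), axis=-1)
    rgb = srgb_encode(np.clip(lin, 0.0, 1.0)) * 255.0
    return np.clip(rgb, 0.0, 255.0), in_gamut


def _f_cie(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(t > _EPS, np.cbrt(t), _KAPPA * t + 4.0 / 29.0)


def _f_cie_inv(ft: np.ndarray) -> np.ndarray:
    ft = np.asarray(ft, dtype=float)
    return np.where(ft > 6.0 / 29.0, ft**3, (ft - 4.0 / 29.0) / _KAPPA)


def xyz_to_lab(xyz: np.ndarray, illuminant: "Illuminant | str" = "D65") -> np.ndarray:
    illum = _resolve_illuminant(illuminant)
    wp = np.asarray(illum.white_point)
    f = _f_cie(np.asarray(xyz, dtype=float) / wp)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def lab_to_xyz(lab: np.ndarray, illuminant: "Illuminant | str" = "D65") -> np.ndarray:
    illum = _resolve_illuminant(illuminant)
    lab = np.asarray(lab, dtype=float)
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    f = np.stack([fx, fy, fz], axis=-1)
    return _f_cie_inv(f) * np.asarray(illum.white_point)


def adapt_xyz(
    xyz: np.ndarray,
    source: "Illuminant | str",
    target: "Illuminant | str",
) -> np.ndarray:
    """Bradford chromatic adaptation of XYZ from one reference white to another."""
    src = _resolve_illuminant(source)
    dst = _resolve_illuminant(target)
    if src.name == dst.name:
        return np.asarray(xyz, dtype=float)
    cone_src = _M_BRADFORD @ np.asarray(src.white_point)
    cone_dst = _M_BRADFORD @ np.asarray(dst.white_point)
    m = _M_BRADFORD_INV @ np.diag(cone_dst / cone_src) @ _M_BRADFORD
    return np.asarray(xyz, dtype=float) @ m.T


@dataclass(frozen=True)
class SRGBColor:
    """An 8-bit-encoded sRGB color; channels kept at full float precision."""

    r: float
    g: float
    b: float

    def __post_init__(self) -> None:
        for name in ("r", "g", "b"):
            v = getattr(self, name)
            if not (0.0 <= v <= 255.0):
                raise ValueError(f"channel {name}={v} outside [0, 255]")

    def to_array(self) -> np.ndarray:
        return np.array([self.r, self.g, self.b], dtype=float)

    def to_lab(self, illuminant: "Illuminant | str" = "D65") -> "LABColor":
        lab = srgb_to_lab(self.to_array(), illuminant)
        return LABColor(*lab, illuminant=_resolve_illuminant(illuminant).name)


@dataclass(frozen=True)
class LABColor:
    """A CIELAB triplet under a declared illuminant."""

    L: float
    a: float
    b: float
    illuminant: str = "D65"

    def __post_init__(self) -> None:
        if not (0.0 <= self.L <= 100.0):
            raise ValueError(f"L={self.L} outside [0, 100]")
        _resolve_illuminant(self.illuminant)
        object.__setattr__(self, "illuminant", self.illuminant.upper())

    def to_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b], dtype=float)

    def to_srgb(self) -> "tuple[SRGBColor, bool]":
        rgb, in_gamut = lab_to_srgb(self.to_array(), self.illuminant)
        return SRGBColor(*rgb), bool(in_gamut)


def srgb_to_lab(rgb, illuminant: "Illuminant | str" = "D65"):
    """Convert sRGB (values in [0, 255]) to CIELAB under the given illuminant.

    D50 output goes through Bradford adaptation from sRGB's native D65 white.
    Accepts an :class:`SRGBColor` (returns :class:`LABColor`) or any
    ``(..., 3)`` array-like (returns an array).
    """
    if isinstance(rgb, SRGBColor):
        return rgb.to_lab(illuminant)
    illum = _resolve_illuminant(illuminant)
    xyz = srgb_to_xyz(rgb)
    if illum.name != "D65":
        xyz = adapt_xyz(xyz, "D65", illum)
    return xyz_to_lab(xyz, illum)


def lab_to_srgb(lab, illuminant: "Illuminant | str | None" = None):
    """Convert CIELAB to 8-bit sRGB; inverse of :func:`srgb_to_lab`.

    Returns ``(rgb, in_gamut)``: out-of-gamut colors are clipped to [0, 255]
    and flagged ``False``. For a :class:`LABColor` input the illuminant tag on
    the value is used and a single ``(SRGBColor, bool)`` pair is returned.
    """
    if isinstance(lab, LABColor):
        return lab.to_srgb()
    illum = _resolve_illuminant(illuminant if illuminant is not None else "D65")
    xyz = lab_to_xyz(lab, illum)
    if illum.name != "D65":
        xyz = adapt_xyz(xyz, illum, "D65")
    return xyz_to_srgb(xyz)


def adapt_white(c, target: "Illuminant | str", source: "Illuminant | str | None" = None):
    """Re-express a CIELAB value under a different reference white (Bradford).

    Identity when source and target coincide. Accepts a :class:`LABColor`
    (source read from its tag) or an array plus explicit ``source``.
    """
    dst = _resolve_illuminant(target)
    if isinstance(c, LABColor):
        src = _resolve_illuminant(c.illuminant)
        if src.name == dst.name:
            return c
        xyz = adapt_xyz(lab_to_xyz(c.to_array(), src), src, dst)
        return LABColor(*xyz_to_lab(xyz, dst), illuminant=dst.name)
    if source is None:
        raise ValueError("source illuminant required for array input")
    src = _resolve_illuminant(source)
    if src.name == dst.name:
        return np.asarray(c, dtype=float)
    return xyz_to_lab(adapt_xyz(lab_to_xyz(c, src), src, dst), dst)


def delta_e_ab(x, y) -> "float | np.ndarray":
    """CIE76 color difference: Euclidean distance between two CIELAB values.

    For :class:`LABColor` inputs the illuminant tags must match — comparing
    LAB coordinates under different whites is meaningless.
    """
    if isinstance(x, LABColor) or isinstance(y, LABColor):
        if not (isinstance(x, LABColor) and isinstance(y, LABColor)):
            raise TypeError("mixed LABColor/array comparison; convert explicitly")
        if x.illuminant != y.illuminant:
            raise IlluminantMismatchError(
                f"illuminant mismatch: {x.illuminant} vs {y.illuminant}"
            )
        return float(np.linalg.norm(x.to_array() - y.to_array()))
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.norm(x - y, axis=-1)
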