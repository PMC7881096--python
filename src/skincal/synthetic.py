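"""Seeded synthetic chart photographs with known ground truth.

Real validation data for chart-based skin-color calibration — printed charts,
phone photographs, spectrophotometer readings — cannot ship with a library,
so this module renders the whole acquisition chain synthetically: an ideal
chart image from a reference palette, a parametric camera (per-channel gamma,
affine channel mixing, additive Gaussian noise) and multiplicative vignetting
applied in linear light. Every output is a pure function of its spec,
model and seed, which makes end-to-end recovery properties testable: a
calibration fitted on the distorted chart should map the distorted segment
means back to the reference palette.

The default 16-color palette spans light-to-dark skin tones plus four neutral
anchors — the regime a prosthesis-matching chart is built for; interpolation
error grows for colors far outside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chart import ChartLayout, grid_layout
from .colorspace import lab_to_srgb, srgb_decode, srgb_encode

__all__ = [
    "CameraModel",
    "SceneSpec",
    "default_skin_palette",
    "render_chart",
    "apply_camera",
    "apply_vignette",
    "radial_field",
    "linear_field",
]


def default_skin_palette() -> np.ndarray:
    """16 CIELAB (D65) colors: 12 skin tones, light to dark, + 4 neutrals."""
    return np.array(
        [
            [80.0, 8.0, 16.0],
            [75.0, 10.0, 18.0],
            [70.0, 12.0, 20.0],
            [66.0, 13.0, 21.0],
            [62.0, 15.0, 22.0],
            [58.0, 16.0, 23.0],
            [54.0, 17.0, 24.0],
            [50.0, 18.0, 24.0],
            [45.0, 17.0, 23.0],
            [40.0, 16.0, 21.0],
            [34.0, 14.0, 18.0],
            [28.0, 12.0, 15.0],
            [95.0, 0.0, 0.0],
            [70.0, 0.0, 0.0],
            [45.0, 0.0, 0.0],
            [20.0, 0.0, 0.0],
        ]
    )


@dataclass
class SceneSpec:
    """Geometry and palette of a synthetic chart scene.

    ``palette_lab`` rows are reference colors under ``illuminant``; the grid
    is rows x cols square patches of ``patch_size`` pixels separated by
    ``gap`` with an outer ``margin``, on a light-gray background.
    ``skin_patches`` adds extra ground-truth LAB colors rendered as patches
    below the chart (stand-ins for photographed skin segments).
    """

    palette_lab: np.ndarray = field(default_factory=default_skin_palette)
    illuminant: str = "D65"
    rows: int = 4
    cols: int = 4
    patch_size: int = 48
    margin: int = 16
    gap: int = 8
    background: float = 225.0
    skin_patches_lab: "np.ndarray | None" = None

    def __post_init__(self) -> None:
        self.palette_lab = np.atleast_2d(np.asarray(self.palette_lab, dtype=float))
        if self.palette_lab.shape != (self.rows * self.cols, 3):
            raise ValueError(
                f"palette has {self.palette_lab.shape[0]} colors; grid needs {self.rows * self.cols}"
            )
        if self.skin_patches_lab is not None:
            self.skin_patches_lab = np.atleast_2d(np.asarray(self.skin_patches_lab, dtype=float))

    @classmethod
    def from_json(cls, path) -> "SceneSpec":
        import json
        from pathlib import Path

        d = json.loads(Path(path).read_text())
        if "palette_lab" in d:
            d["palette_lab"] = np.array(d["palette_lab"], dtype=float)
        if d.get("skin_patches_lab") is not None:
            d["skin_patches_lab"] = np.array(d["skin_patches_lab"], dtype=float)
        return cls(**d)


@dataclass
class CameraModel:
    """Parametric device distortion: gamma, affine mixing, sensor noise.

    Channels are normalized to [0, 1], raised to the per-channel ``gamma``,
    mixed by the 3x4 ``affine`` ``[offset | M]`` (offset in normalized
    units), Gaussian noise of ``noise_sd`` (8-bit units) added, and the
    result re-encoded to [0, 255] with clamping. Deterministic given ``seed``.
    """

    affine: np.ndarray = field(default_factory=lambda: np.hstack([np.zeros((3, 1)), np.eye(3)]))
    gamma: "float | np.ndarray" = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (3, 4):
            raise ValueError("affine must be 3x4 ([offset | mixing])")
        self.gamma = np.broadcast_to(np.asarray(self.gamma, dtype=float), (3,)).copy()
        if np.any(self.gamma <= 0):
            raise ValueError("gamma must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @classmethod
    def from_json(cls, path) -> "CameraModel":
        import json
        from pathlib import Path

        d = json.loads(Path(path).read_text())
        if "affine" in d:
            d["affine"] = np.array(d["affine"], dtype=float)
        return cls(**d)


def render_chart(spec: SceneSpec) -> tuple[np.ndarray, ChartLayout, pd.DataFrame]:
    """Render the ideal (noiseless, distortion-free) chart image.

    Returns the float RGB image (patch pixels equal the palette's sRGB values
    exactly), the segment layout, and the reference table
    (``segment_id, L, a, b, illuminant``). Out-of-gamut palette entries are an
    error listing the offenders.
    """
    rgb, in_gamut = lab_to_srgb(spec.palette_lab, spec.illuminant)
    if not np.all(in_gamut):
        bad = np.flatnonzero(~in_gamut) + 1
        raise ValueError(f"palette colors outside the sRGB gamut: segments {bad.tolist()}")
    layout = grid_layout(spec.rows, spec.cols, spec.patch_size, spec.margin, spec.gap)
    width = 2 * spec.margin + spec.cols * spec.patch_size + (spec.cols - 1) * spec.gap
    height = 2 * spec.margin + spec.rows * spec.patch_size + (spec.rows - 1) * spec.gap

    extra_rects = []
    if spec.skin_patches_lab is not None:
        skin_rgb, skin_ok = lab_to_srgb(spec.skin_patches_lab, spec.illuminant)
        if not np.all(skin_ok):
            bad = np.flatnonzero(~skin_ok) + 1
            raise ValueError(f"skin patches outside the sRGB gamut: {bad.tolist()}")
        y0 = height
        height += spec.margin + spec.patch_size
        for k in range(spec.skin_patches_lab.shape[0]):
            x0 = spec.margin + k * (spec.patch_size + spec.gap)
            extra_rects.append((x0, y0, skin_rgb[k]))
        width = max(width, extra_rects[-1][0] + spec.patch_size + spec.margin)

    image = np.full((height, width, 3), float(spec.background))
    for seg, color in zip(layout.segments, rgb):
        image[seg.y0 : seg.y1, seg.x0 : seg.x1] = color
    for x0, y0, color in extra_rects:
        image[y0 : y0 + spec.patch_size, x0 : x0 + spec.patch_size] = color

    reference = pd.DataFrame(
        {
            "segment_id": layout.ids,
            "L": spec.palette_lab[:, 0],
            "a": spec.palette_lab[:, 1],
            "b": spec.palette_lab[:, 2],
            "illuminant": spec.illuminant,
        }
    )
    return image, layout, reference


def skin_patch_layout(spec: SceneSpec) -> ChartLayout:
    """Layout of the extra skin patches rendered below the chart."""
    if spec.skin_patches_lab is None:
        raise ValueError("scene has no skin patches")
    chart_h = 2 * spec.margin + spec.rows * spec.patch_size + (spec.rows - 1) * spec.gap
    from .chart import SegmentRect

    rects = []
    for k in range(spec.skin_patches_lab.shape[0]):
        x0 = spec.margin + k * (spec.patch_size + spec.gap)
        rects.append(
            SegmentRect(k + 1, x0, chart_h, x0 + spec.patch_size, chart_h + spec.patch_size)
        )
    return ChartLayout(rects)


def apply_camera(image: np.ndarray, model: CameraModel) -> np.ndarray:
    """Distort an RGB image through the parametric camera model."""
    v = np.clip(np.asarray(image, dtype=float) / 255.0, 0.0, 1.0)
    v = v ** model.gamma
    v = v @ model.affine[:, 1:].T + model.affine[:, 0]
    if model.noise_sd > 0:
        rng = np.random.default_rng(model.seed)
        v = v + rng.normal(0.0, model.noise_sd / 255.0, size=v.shape)
    return np.clip(v, 0.0, 1.0) * 255.0


def radial_field(shape: tuple[int, int], center: float = 1.0, corner: float = 0.85) -> np.ndarray:
    """Radially symmetric multiplicative field: ``center`` in the middle,
    falling quadratically to ``corner`` at the frame corners."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (cy**2 + cx**2)
    return center + (corner - center) * r2


def linear_field(shape: tuple[int, int], left: float = 0.9, right: float = 1.1) -> np.ndarray:
    """Horizontal linear gradient from ``left`` to ``right``."""
    H, W = shape
    ramp = np.linspace(left, right, W)
    return np.tile(ramp, (H, 1))


def apply_vignette(image: np.ndarray, field: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Multiply the image by an illumination field in linear light.

    ``field`` values must lie in (0, 1.5]. The image is decoded sRGB->linear,
    scaled per pixel, re-encoded and clamped. Returns ``(image, field)`` so
    the ground-truth field is available for round-trip checks.
    """
    field = np.asarray(field, dtype=float)
    img = np.asarray(image, dtype=float)
    if field.shape != img.shape[:2]:
        raise ValueError("field shape must match the image frame")
    if np.any(field <= 0) or np.any(field > 1.5):
        raise ValueError("field values must lie in (0, 1.5]")
    lin = srgb_decode(img / 255.0) * field[..., None]
    out = srgb_encode(np.clip(lin, 0.0, 1.0)) * 255.0
    return np.clip(out, 0.0, 255.0), field
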