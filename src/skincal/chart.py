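"""Chart-segment geometry and mean-color extraction.

Segment geometry is supplied explicitly (CSV/JSON of labeled rectangles) or
built with :func:`grid_layout` for the standard 4x4 chart; automatic chart
detection and perspective rectification are out of scope. Coordinates are
0-based, half-open, ``(x, y) = (column, row)``.

Each segment's mean RGB is taken over an inner sub-rectangle: a ``shrink``
fraction (default 0.15 per side) excludes the printed edge of a patch, where
ink bleed and demosaicing mix neighboring colors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import ControlPointSet
from .colorspace import GamutError, lab_to_srgb

__all__ = [
    "SegmentRect",
    "ChartLayout",
    "SegmentReading",
    "DegenerateROIError",
    "SegmentMappingError",
    "grid_layout",
    "extract_segment_means",
    "build_control_points",
    "load_reference_csv",
    "save_reference_csv",
]

DEFAULT_SHRINK = 0.15


class DegenerateROIError(ValueError):
    """A segment rectangle is empty after the shrink margin is applied."""


class SegmentMappingError(ValueError):
    """Segment ids of readings and reference table do not line up."""


@dataclass(frozen=True)
class SegmentRect:
    """An axis-aligned segment rectangle, 0-based, half-open."""

    id: int
    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(f"segment {self.id}: empty rectangle")
        if min(self.x0, self.y0) < 0:
            raise ValueError(f"segment {self.id}: negative coordinates")


@dataclass
class ChartLayout:
    """Labeled segment rectangles of a chart, ids unique and 1-based."""

    segments: list[SegmentRect]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("layout has no segments")
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate segment ids in layout")
        self.segments = sorted(self.segments, key=lambda s: s.id)

    @property
    def n(self) -> int:
        return len(self.segments)

    @property
    def ids(self) -> list[int]:
        return [s.id for s in self.segments]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            [(s.id, s.x0, s.y0, s.x1, s.y1) for s in self.segments],
            columns=["segment_id", "x0", "y0", "x1", "y1"],
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ChartLayout":
        df = pd.read_csv(path)
        return cls(
            [
                SegmentRect(int(r.segment_id), int(r.x0), int(r.y0), int(r.x1), int(r.y1))
                for r in df.itertuples()
            ]
        )

    @classmethod
    def from_json(cls, path) -> "ChartLayout":
        rows = json.loads(Path(path).read_text())
        return cls(
            [
                SegmentRect(int(r["segment_id"]), int(r["x0"]), int(r["y0"]), int(r["x1"]), int(r["y1"]))
                for r in rows
            ]
        )


@dataclass(frozen=True)
class SegmentReading:
    """Mean RGB of one segment and the pixel count it averages."""

    segment_id: int
    mean_rgb: tuple[float, float, float]
    pixel_count: int

    def __post_init__(self) -> None:
        if self.pixel_count < 1:
            raise ValueError("pixel_count must be >= 1")


def grid_layout(
    rows: int = 4,
    cols: int = 4,
    patch_size: int = 64,
    margin: int = 16,
    gap: int = 8,
) -> ChartLayout:
    """Regular rows x cols grid of square patches, ids row-major from 1."""
    segments = []
    for r in range(rows):
        for c in range(cols):
            x0 = margin + c * (patch_size + gap)
            y0 = margin + r * (patch_size + gap)
            segments.append(
                SegmentRect(r * cols + c + 1, x0, y0, x0 + patch_size, y0 + patch_size)
            )
    return ChartLayout(segments)


def extract_segment_means(
    image: np.ndarray,
    layout: ChartLayout,
    shrink: float = DEFAULT_SHRINK,
) -> list[SegmentReading]:
    """Per-segment arithmetic mean RGB over the shrunken rectangles.

    ``shrink`` in [0, 0.5) removes that fraction of the width/height from
    each side before averaging. Readings follow layout id order.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    if not (0.0 <= shrink < 0.5):
        raise ValueError("shrink must lie in [0, 0.5)")
    H, W = img.shape[:2]
    readings = []
    for seg in layout.segments:
        if seg.x1 > W or seg.y1 > H:
            raise ValueError(f"segment {seg.id} exceeds image bounds {W}x{H}")
        dx = int(round((seg.x1 - seg.x0) * shrink))
        dy = int(round((seg.y1 - seg.y0) * shrink))
        patch = img[seg.y0 + dy : seg.y1 - dy, seg.x0 + dx : seg.x1 - dx]
        if patch.size == 0:
            raise DegenerateROIError(f"segment {seg.id} empty after shrink={shrink}")
        mean = patch.reshape(-1, 3).mean(axis=0)
        readings.append(
            SegmentReading(seg.id, tuple(float(v) for v in mean), patch.shape[0] * patch.shape[1])
        )
    return readings


def load_reference_csv(path) -> pd.DataFrame:
    """Read a reference chart table: ``segment_id, L, a, b, illuminant``."""
    df = pd.read_csv(path)
    required = {"segment_id", "L", "a", "b", "illuminant"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    return df


def save_reference_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def build_control_points(
    readings: "list[SegmentReading]",
    reference: pd.DataFrame,
    on_gamut: str = "raise",
) -> ControlPointSet:
    """Join measured segment means with the reference table into control points.

    Reference LAB rows are converted to sRGB under their tagged illuminant
    (D50 references are Bradford-adapted to sRGB's D65 white). Rows are
    aligned by segment id, ascending, so reading order does not matter.
    ``on_gamut='clip'`` downgrades out-of-gamut reference colors to a warning.
    """
    if on_gamut not in ("raise", "clip"):
        raise ValueError("on_gamut must be 'raise' or 'clip'")
    read_ids = [r.segment_id for r in readings]
    if len(set(read_ids)) != len(read_ids):
        dupes = sorted({i for i in read_ids if read_ids.count(i) > 1})
        raise SegmentMappingError(f"duplicate reading segment ids: {dupes}")
    ref_ids = reference["segment_id"].tolist()
    if len(set(ref_ids)) != len(ref_ids):
        dupes = sorted({i for i in ref_ids if ref_ids.count(i) > 1})
        raise SegmentMappingError(f"duplicate reference segment ids: {dupes}")
    missing = sorted(set(read_ids) - set(ref_ids))
    if missing:
        raise SegmentMappingError(f"readings without reference rows: {missing}")

    by_id = {r.segment_id: r for r in readings}
    ref = reference.set_index("segment_id")
    measured, ref_rgb, out_of_gamut = [], [], []
    for sid in sorted(read_ids):
        measured.append(by_id[sid].mean_rgb)
        row = ref.loc[sid]
        rgb, in_gamut = lab_to_srgb(
            np.array([row["L"], row["a"], row["b"]]), str(row["illuminant"])
        )
        if not in_gamut:
            out_of_gamut.append(sid)
        ref_rgb.append(rgb)
    if out_of_gamut:
        msg = f"reference colors outside the sRGB gamut for segments {out_of_gamut}"
        if on_gamut == "raise":
            raise GamutError(msg)
        warnings.warn(msg + "; clipped", stacklevel=2)
    return ControlPointSet(measured=np.array(measured), reference=np.array(ref_rgb))
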