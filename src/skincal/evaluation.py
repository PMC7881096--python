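"""Agreement analytics for calibrated color measurements.

Two descriptive tools are provided, matching how skin-colorimetry studies
report device and condition agreement:

* pairwise CIE76 color differences between aligned measurement sets
  (e.g. the same skin segments photographed with different cameras or
  lighting), summarized as mean ± SD;
* Bland–Altman statistics of paired measurements per channel — mean
  difference, sample SD of the differences, and limits of agreement at
  ±1.96 SD.

``compare_methods`` runs the full chart pipeline for the linear and TPS
corrections side by side and tabulates the per-segment residual ΔEab*.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import calibration as cal_mod
from .chart import ChartLayout, build_control_points, extract_segment_means
from .colorspace import IlluminantMismatchError, LABColor, delta_e_ab, srgb_to_lab
from .illumination import correct_lab_image

__all__ = [
    "AgreementReport",
    "BlandAltman",
    "pairwise_delta_e",
    "bland_altman",
    "bland_altman_lab",
    "compare_methods",
    "bland_altman_plot",
]


@dataclass
class AgreementReport:
    """Labeled per-pair ΔEab* values with their mean ± sample SD."""

    per_pair: list[tuple[str, float]]

    @property
    def n(self) -> int:
        return len(self.per_pair)

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.per_pair], dtype=float)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.n > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_pair, columns=["pair", "delta_e"])

    def summary(self) -> str:
        return f"delta_E_ab = {self.mean:.2f} +/- {self.sd:.2f}  (n={self.n} pairs)"


@dataclass
class BlandAltman:
    """Bland–Altman agreement of paired measurements on one channel."""

    label: str
    mean_diff: float
    sd_diff: float
    n: int
    loa_multiplier: float = 1.96

    @property
    def loa_low(self) -> float:
        return self.mean_diff - self.loa_multiplier * self.sd_diff

    @property
    def loa_high(self) -> float:
        return self.mean_diff + self.loa_multiplier * self.sd_diff

    def summary(self) -> str:
        return (
            f"{self.label}: mean diff {self.mean_diff:+.3f}, "
            f"LoA [{self.loa_low:.3f}, {self.loa_high:.3f}]  (n={self.n})"
        )


def _as_lab_matrix(s) -> np.ndarray:
    """Accept an (m, 3) array or a sequence of LABColor; enforce one illuminant."""
    if len(s) and isinstance(s[0], LABColor):
        tags = {c.illuminant for c in s}
        if len(tags) > 1:
            raise IlluminantMismatchError(f"mixed illuminants within one set: {sorted(tags)}")
        return np.stack([c.to_array() for c in s]), tags.pop()
    arr = np.atleast_2d(np.asarray(s, dtype=float))
    if arr.shape[1] != 3:
        raise ValueError("each measurement set must be (m, 3) LAB")
    return arr, None


def pairwise_delta_e(sets: "Mapping[str, Sequence] | Sequence[Sequence]") -> AgreementReport:
    """ΔEab* between every unordered pair of measurement sets, per segment.

    Sets are aligned by position (segment i of one set pairs with segment i of
    every other). Entries are labeled ``"<setA>|<setB>|seg<i>"``.
    """
    if isinstance(sets, Mapping):
        items = list(sets.items())
    else:
        items = [(f"set{i + 1}", s) for i, s in enumerate(sets)]
    if len(items) < 2:
        raise ValueError("need at least two measurement sets")
    matrices = []
    tags = set()
    for label, s in items:
        arr, tag = _as_lab_matrix(s)
        if tag is not None:
            tags.add(tag)
        matrices.append((label, arr))
    if len(tags) > 1:
        raise IlluminantMismatchError(f"sets under different illuminants: {sorted(tags)}")
    m = matrices[0][1].shape[0]
    if any(arr.shape[0] != m for _, arr in matrices):
        raise ValueError("all measurement sets must have the same length")
    per_pair = []
    for (la, a), (lb, b) in combinations(matrices, 2):
        des = delta_e_ab(a, b)
        per_pair.extend((f"{la}|{lb}|seg{i + 1}", float(d)) for i, d in enumerate(des))
    return AgreementReport(per_pair=per_pair)


def bland_altman(x, y, label: str = "", loa_multiplier: float = 1.96) -> BlandAltman:
    """Bland–Altman statistics of paired scalar measurements x and y.

    Differences are ``x - y``; SD uses the sample (n-1) denominator and the
    limits of agreement sit at mean ± ``loa_multiplier`` · SD.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if x.size < 2:
        raise ValueError("Bland–Altman needs at least 2 paired measurements")
    d = x - y
    return BlandAltman(
        label=label,
        mean_diff=float(np.mean(d)),
        sd_diff=float(np.std(d, ddof=1)),
        n=int(x.size),
        loa_multiplier=loa_multiplier,
    )


def bland_altman_lab(x_lab, y_lab, loa_multiplier: float = 1.96) -> list[BlandAltman]:
    """Per-channel (L*, a*, b*) Bland–Altman of paired LAB measurements."""
    x, _ = _as_lab_matrix(x_lab)
    y, _ = _as_lab_matrix(y_lab)
    if x.shape != y.shape:
        raise ValueError("paired LAB sets must have the same shape")
    return [
        bland_altman(x[:, i], y[:, i], label=ch, loa_multiplier=loa_multiplier)
        for i, ch in enumerate(("L", "a", "b"))
    ]


def compare_methods(
    image: np.ndarray,
    layout: ChartLayout,
    reference: pd.DataFrame,
    methods: Sequence[str] = ("linear", "tps"),
    with_illumination: bool = False,
    shrink: float = 0.15,
    sigma: "float | None" = None,
) -> pd.DataFrame:
    """Per-segment residual ΔEab* of each correction method on a chart image.

    For each method the chart's control points are fitted and the corrected
    segment means are compared to the reference colors (CIE76, D65). With
    ``with_illumination`` the image is first illumination-corrected in LAB
    (L* channel only) and the segment means re-extracted from the corrected
    image. Returns a tidy frame with one row per segment × method.
    """
    img = np.asarray(image, dtype=float)
    if with_illumination:
        from .colorspace import lab_to_srgb

        lab = srgb_to_lab(img)
        img, _ = lab_to_srgb(correct_lab_image(lab, sigma=sigma))
    readings = extract_segment_means(img, layout, shrink=shrink)
    cps = build_control_points(readings, reference)
    rows = []
    for method in methods:
        if method == "none":
            # no correction: raw measured means against the reference
            errs = delta_e_ab(srgb_to_lab(cps.measured), srgb_to_lab(cps.reference))
        elif method == "linear":
            cal = cal_mod.fit_linear(cps)
            errs = cal_mod.calibration_residuals(cal, cps, space="LAB").per_segment
        elif method == "tps":
            cal = cal_mod.fit_tps(cps)
            errs = cal_mod.calibration_residuals(cal, cps, space="LAB").per_segment
        else:
            raise ValueError(f"unknown method {method!r}; expected 'none', 'linear' or 'tps'")
        for sid, err in zip(sorted(r.segment_id for r in readings), errs):
            rows.append({"segment_id": sid, "method": method, "delta_e": float(err)})
    return pd.DataFrame(rows)


def bland_altman_plot(ba: BlandAltman, x, y, path) -> None:
    """Scatter of differences against means with the LoA lines, saved to file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((x + y) / 2.0, x - y, s=18, alpha=0.7)
    for val, style in ((ba.mean_diff, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(val, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference")
    ax.set_title(ba.label or "Bland-Altman")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
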