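"""Chart-based color correction: linear least-squares and 3-D thin-plate spline.

Both methods map measured RGB to reference RGB using the paired mean colors of
the calibration-chart segments as control points.

The linear baseline fits a single affine transform ``y = A_lin @ (1, R, G, B)``
by least squares — it captures channel mixing and offsets but cannot represent
non-linear device response (gamma, saturation roll-off).

The thin-plate spline (TPS-3D) treats the three reference channels as three
scalar fields over measured RGB space and interpolates them exactly at the
control points while minimizing bending energy. With control colors
``(R_i, G_i, B_i)`` and kernel ``U(r) = 2 r^2 log(r + 1e-20)`` the fit solves
the block system

    [ K   P ] [ W ]   [ V ]
    [ P^T 0 ] [ A ] = [ 0 ]

where ``K[i, j] = U(|c_i - c_j|)``, ``P`` is the ``n x 4`` design ``[1 | RGB]``,
and ``V`` the ``n x 3`` reference matrix. A corrected pixel is then
``[U(r_1) ... U(r_n), 1, R, G, B] @ [W; A]`` with ``r_i`` the Euclidean
distance from the pixel to control color ``i``. RGB values enter the spline in
native [0, 255] units; the kernel uses the natural logarithm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import LinAlgError, lstsq, solve
from scipy.spatial.distance import cdist

__all__ = [
    "ControlPointSet",
    "LinearCalibration",
    "TPSCalibration",
    "SegmentResiduals",
    "DuplicateControlPointError",
    "SingularFitError",
    "tps_kernel",
    "fit_linear",
    "fit_tps",
    "apply_linear",
    "apply_tps",
    "apply_calibration",
    "calibration_residuals",
    "save_calibration",
    "load_calibration",
]

_KERNEL_GUARD = 1e-20  # keeps U(0) = 0 without a special case


class DuplicateControlPointError(ValueError):
    """Two chart segments measured the same RGB color; the TPS system is singular."""


class SingularFitError(ValueError):
    """The calibration system has no unique solution."""


@dataclass
class ControlPointSet:
    """Paired measured / reference mean RGB values for the chart segments."""

    measured: np.ndarray  # (n, 3), native [0, 255]
    reference: np.ndarray  # (n, 3), native [0, 255]

    def __post_init__(self) -> None:
        self.measured = np.atleast_2d(np.asarray(self.measured, dtype=float))
        self.reference = np.atleast_2d(np.asarray(self.reference, dtype=float))
        if self.measured.shape != self.reference.shape or self.measured.shape[1] != 3:
            raise ValueError("measured and reference must both be (n, 3)")
        if self.measured.shape[0] < 5:
            raise ValueError("need at least 5 control points (4 affine dof + 1)")
        for name, arr in (("measured", self.measured), ("reference", self.reference)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            if np.any(arr < 0) or np.any(arr > 255):
                raise ValueError(f"{name} values must lie in [0, 255]")

    @property
    def n(self) -> int:
        return self.measured.shape[0]

    def design_matrix(self) -> np.ndarray:
        """The n x 4 matrix P = [1 | measured RGB]."""
        return np.hstack([np.ones((self.n, 1)), self.measured])


@dataclass
class LinearCalibration:
    """Affine color correction: 3x4 weights applied to (1, R, G, B)."""

    A_lin: np.ndarray

    def __post_init__(self) -> None:
        self.A_lin = np.asarray(self.A_lin, dtype=float)
        if self.A_lin.shape != (3, 4) or not np.all(np.isfinite(self.A_lin)):
            raise ValueError("A_lin must be a finite 3x4 matrix")


@dataclass
class TPSCalibration:
    """Fitted thin-plate-spline map: kernel weights W, affine part A, and the
    control colors needed to evaluate the kernel at new pixels."""

    W: np.ndarray  # (n, 3)
    A: np.ndarray  # (4, 3)
    control_measured: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.control_measured = np.asarray(self.control_measured, dtype=float)
        n = self.control_measured.shape[0]
        if self.W.shape != (n, 3) or self.A.shape != (4, 3):
            raise ValueError("inconsistent W/A/control_measured shapes")
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.A))):
            raise ValueError("non-finite TPS coefficients")

    @property
    def n(self) -> int:
        return self.control_measured.shape[0]


def tps_kernel(r):
    """Radial kernel U(r) = 2 r^2 log(r + 1e-20) of the thin-plate spline.

    The additive guard makes U(0) = 0 exactly (the zero diagonal of K).
    Natural logarithm; negative distances are a domain error.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("tps_kernel requires r >= 0")
    out = 2.0 * r**2 * np.log(r + _KERNEL_GUARD)
    return float(out) if out.ndim == 0 else out


def fit_linear(cps: ControlPointSet) -> LinearCalibration:
    """Least-squares affine fit of reference on (1, R, G, B) of measured."""
    X = cps.design_matrix()
    if np.linalg.matrix_rank(X) < 4:
        raise SingularFitError(
            "design matrix [1 | measured RGB] is rank-deficient: control colors "
            "are affinely dependent (e.g. collinear in RGB space)"
        )
    coeffs, *_ = lstsq(X, cps.reference)
    return LinearCalibration(A_lin=coeffs.T)


def fit_tps(cps: ControlPointSet, regularization: float = 0.0) -> TPSCalibration:
    """Solve the TPS block system for the kernel and affine weights.

    ``regularization`` adds a Tikhonov term to the diagonal of K, trading
    exact interpolation for stability when control colors nearly coincide
    (default 0: exact interpolation).
    """
    dists = cdist(cps.measured, cps.measured)
    off_diag = dists + np.diag(np.full(cps.n, np.inf))
    if np.any(off_diag == 0.0):
        i, j = np.argwhere(off_diag == 0.0)[0]
        raise DuplicateControlPointError(
            f"control points {i} and {j} share the measured color "
            f"{cps.measured[i]}; merge or drop one of them"
        )
    K = tps_kernel(dists)
    if regularization:
        K = K + regularization * np.eye(cps.n)
    P = cps.design_matrix()
    n = cps.n
    system = np.zeros((n + 4, n + 4))
    system[:n, :n] = K
    system[:n, n:] = P
    system[n:, :n] = P.T
    rhs = np.vstack([cps.reference, np.zeros((4, 3))])
    try:
        sol = solve(system, rhs)
    except LinAlgError as exc:
        raise SingularFitError(
            "TPS block system is singular; near-duplicate control colors? "
            "Try a small regularization (e.g. regularization=1e-6)"
        ) from exc
    if not np.all(np.isfinite(sol)):
        raise SingularFitError("TPS solve produced non-finite coefficients")
    return TPSCalibration(W=sol[:n], A=sol[n:], control_measured=cps.measured.copy())


def _as_pixels(image: np.ndarray) -> tuple[np.ndarray, tuple]:
    arr = np.asarray(image, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("expected an RGB array with trailing axis of size 3")
    return arr.reshape(-1, 3), arr.shape


def apply_linear(cal: LinearCalibration, image) -> np.ndarray:
    """Per-pixel affine correction, clamped to [0, 255]."""
    pixels, shape = _as_pixels(image)
    out = pixels @ cal.A_lin[:, 1:].T + cal.A_lin[:, 0]
    return np.clip(out, 0.0, 255.0).reshape(shape)


def apply_tps(cal: TPSCalibration, image, chunk_size: int = 1 << 16) -> np.ndarray:
    """Per-pixel TPS correction, clamped to [0, 255].

    Pixels are processed in chunks to bound the pixel-to-control distance
    matrix; results are bit-identical regardless of chunking.
    """
    pixels, shape = _as_pixels(image)
    out = np.empty_like(pixels)
    for start in range(0, pixels.shape[0], chunk_size):
        chunk = pixels[start : start + chunk_size]
        kernel = tps_kernel(cdist(chunk, cal.control_measured))
        affine = np.hstack([np.ones((chunk.shape[0], 1)), chunk])
        out[start : start + chunk_size] = kernel @ cal.W + affine @ cal.A
    return np.clip(out, 0.0, 255.0).reshape(shape)


def apply_calibration(cal, image) -> np.ndarray:
    """Dispatch on calibration type (linear or TPS)."""
    if isinstance(cal, LinearCalibration):
        return apply_linear(cal, image)
    if isinstance(cal, TPSCalibration):
        return apply_tps(cal, image)
    raise TypeError(f"unsupported calibration type {type(cal).__name__}")


@dataclass
class SegmentResiduals:
    """Per-segment calibration error plus its mean and sample SD."""

    per_segment: np.ndarray
    space: str

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_segment))

    @property
    def sd(self) -> float:
        n = len(self.per_segment)
        return float(np.std(self.per_segment, ddof=1)) if n > 1 else 0.0


def calibration_residuals(cal, cps: ControlPointSet, space: str = "LAB") -> SegmentResiduals:
    """Error between corrected control colors and their references.

    ``space='RGB'`` gives the per-segment Euclidean RGB distance;
    ``space='LAB'`` converts both sides sRGB->CIELAB (D65) and reports the
    CIE76 color difference — the scale on which calibration quality is judged.
    """
    from .colorspace import delta_e_ab, srgb_to_lab

    corrected = apply_calibration(cal, cps.measured)
    if space.upper() == "RGB":
        err = np.linalg.norm(corrected - cps.reference, axis=1)
    elif space.upper() == "LAB":
        err = delta_e_ab(srgb_to_lab(corrected), srgb_to_lab(cps.reference))
    else:
        raise ValueError("space must be 'RGB' or 'LAB'")
    return SegmentResiduals(per_segment=np.asarray(err, dtype=float), space=space.upper())


def save_calibration(cal, path) -> None:
    """Serialize a fitted calibration to JSON (matrices row-major)."""
    if isinstance(cal, TPSCalibration):
        payload = {
            "method": "tps",
            "n": cal.n,
            "control_measured": cal.control_measured.tolist(),
            "W": cal.W.tolist(),
            "A": cal.A.tolist(),
        }
    elif isinstance(cal, LinearCalibration):
        payload = {"method": "linear", "A_lin": cal.A_lin.tolist()}
    else:
        raise TypeError(f"unsupported calibration type {type(cal).__name__}")
    Path(path).write_text(json.dumps(payload, indent=1))


def load_calibration(path):
    """Load a calibration serialized by :func:`save_calibration`."""
    payload = json.loads(Path(path).read_text())
    method = payload.get("method")
    if method == "tps":
        return TPSCalibration(
            W=np.array(payload["W"]),
            A=np.array(payload["A"]),
            control_measured=np.array(payload["control_measured"]),
        )
    if method == "linear":
        return LinearCalibration(A_lin=np.array(payload["A_lin"]))
    raise ValueError(f"unknown calibration method {method!r}")
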