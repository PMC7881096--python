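# Methods

## Color spaces and conventions

8-bit sRGB is decoded with the IEC 61966-2-1 piecewise curve (linear
segment below 0.04045, exponent 2.4 above). The RGB→XYZ matrix is derived
from the sRGB primaries and the D65 white point rather than taken from
rounded published tables, so that RGB = (255, 255, 255) maps onto the white
point exactly and neutral colors land on a* = b* = 0 to machine precision.
White points use the 2° observer values (D65: 0.95047, 1, 1.08883; D50:
0.96422, 1, 0.82521), Y normalized to 1 internally. L* uses the standard
CIE f(t) with its linear segment below (6/29)³.

CIELAB values always carry an illuminant tag; combining D65 and D50 values
in a color difference is an error, not a warning. Cross-illuminant
re-expression goes through XYZ with the Bradford chromatic adaptation
transform — the common choice in ICC-style workflows; the alternative (von
Kries, CAT02) would change adapted a*/b* by well under the measurement
noise this pipeline deals with. The color difference is CIE76 (plain
Euclidean distance in CIELAB). ΔE2000 is deliberately not offered: the
agreement statistics here follow the skin-colorimetry convention of
reporting ΔE*ab, and mixing metrics would make summaries incomparable.

`lab_to_srgb` reports an in-gamut flag per color (linear RGB outside
[0, 1] before encoding) and clips; reference-table colors that fall outside
the gamut raise by default because a calibration anchored on unprintable
reference colors is a data error, with an explicit `on_gamut="clip"`
escape hatch.

## Thin-plate-spline color correction

The three reference channels are treated as scalar fields over measured
RGB space and interpolated with the kernel U(r) = 2 r² log(r + 1e-20).
Numerical choices:

* **Natural logarithm.** The kernel's log base is unspecified in common
  write-ups; a base change only rescales the solved weights, but natural
  log is fixed for reproducibility. The 1e-20 guard makes U(0) = 0 exactly
  without a branch.
* **Native [0, 255] units.** The kernel is not scale-invariant, so the
  convention that control colors and pixels enter in 8-bit units is part of
  the model definition, not a free choice.
* **Dense solve, no inversion.** The (n+4)×(n+4) block system is solved
  with LAPACK partial pivoting. For 16 control points conditioning is
  benign (interpolation residuals ~1e-12 of full scale in tests).
* **Duplicates are errors.** Two segments measuring the same RGB color make
  the system singular; they are reported, not merged — a chart photographed
  so badly that two tonalities coincide needs re-acquisition. For
  *near*-duplicates an optional Tikhonov term on the K diagonal
  (`regularization`, default 0) trades exactness for stability.
* **Clamping.** Corrected values are clamped to [0, 255] after mapping and
  rounded only at image write; all intermediate math is floating point.
* `n` is parameterized (default 16, minimum 5 = 4 affine dof + 1), so
  non-4×4 charts work unchanged.

The linear baseline is an ordinary least-squares fit of the reference on
(1, R, G, B); it is kept both as the comparison method and as the fast path
when the device response is known to be affine.

Properties enforced by tests: exact interpolation (K W + P A = V), the
orthogonality side condition Pᵀ W = 0, collapse to the pure affine map
(W → 0) on affinely consistent data, control-point-order invariance, and
equality of the linear fit with an independent normal-equations solve.

## Illumination correction

The illumination surface is the Gaussian blur of L* with reflective
boundaries and a normalized kernel, so a constant channel is its own
estimate and the blur preserves the mean exactly. The default
σ = max(H, W)/2 keeps the estimate well above the spatial scale of real
image content; smaller σ lets the scene itself (dark and light chart
patches) leak into the estimate, and dividing by such a field visibly
corrupts patch colors — the tests demonstrate this trade-off, which is why
σ is exposed as a parameter but the wide default is kept. The correction
divides L* by the estimate and renormalizes by C = mean(F)/mean(F/I)
(whole-frame means), which preserves mean lightness exactly before the
final clip to [0, 100]; a* and b* are returned bit-identical. A division
guard ε = 1e-6 covers degenerate dark fields.

Because the wide blur attenuates even the shading it is meant to capture, a
strong frame-scale gradient is reduced, not erased (roughly the blur's
transfer gain at the gradient's frequency). The step is therefore optional
in the pipeline and exposed as a flag/command: it helps when shading is
visible, and is an identity to within 1e-6 under uniform light.

## Chart geometry and extraction

Segment geometry is explicit (CSV/JSON rectangles, 0-based half-open
pixel coordinates, x = column); chart localization and perspective are out
of scope. Segment means are taken over an inner window: the default
`shrink = 0.15` per side excludes printed-edge bleed, and synthetic
bleed tests (Gaussian-blurred chart) show extraction error is monotone
non-increasing in the shrink fraction up to 0.25. Control points are
joined to the reference table strictly by segment id, so reading order
never matters.

## Synthetic scenes

The simulator emulates the acquisition chain the method is designed for:

* **Palette.** 16 CIELAB colors — 12 skin tones from light to dark plus 4
  neutral anchors — because the calibration is built to be accurate in the
  skin region of color space; colors far outside the control hull
  extrapolate with growing error.
* **Camera.** Per-channel gamma applied to normalized channels, a 3×4
  affine channel-mixing matrix, additive Gaussian noise in 8-bit units
  (default study settings: gamma ~ U(1.5, 2.5), affine entries jittered by
  up to 5%, noise SD 1), clamped on re-encoding. Deterministic given its
  seed.
* **Vignette.** A multiplicative field applied in linear light (radial,
  corner factor 0.85 by default — typical residual smartphone vignetting —
  or a linear side-light gradient), with the ground-truth field returned
  for round-trip checks.

All generator outputs are pure functions of (spec, camera model, seed).
What the synthetic scenes do *not* model: perspective and lens geometry,
printer ICC behavior, demosaicing, shot (Poisson) noise, specular
highlights, and the translucency of real skin. Passing tests therefore
establish the correctness of the algorithms under the stated distortion
model, not field performance on photographs.

## Study sizes

The packaged studies use 4×4 charts with 48-pixel patches (512×512 frames
for illumination scenes), 2 simulated printers × 2 cameras for the method
comparison, 20 seeds for the non-linear-advantage sweep, and 5 photographs
× 3 skin patches for the agreement analysis — small enough to run in
seconds while leaving every effect far above numerical noise.

## Known limitations

* The TPS map is defined on RGB triplets; calibrating in CIELAB or a
  spectrally motivated space is out of scope.
* Exact interpolation means control-point residuals are not a useful
  goodness measure for the spline itself; end-to-end checks re-extract
  colors from corrected images instead, and generalization is assessed on
  colors (skin patches) off the control set.
* The illumination model is multiplicative and smooth; cast shadows with
  sharp edges violate it and are not corrected.
* Bland–Altman statistics are per channel with the sample (n−1) SD and a
  1.96 multiplier (configurable); no hypothesis testing is performed.
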