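# Methods

## The quantification model

A reacted test-strip pad and the manufacturer's reference chart are both
photographed; colors are treated as points in device RGB space. For a
sampled pad color **c** and reference swatches with colors **r**ᵢ at
known concentrations Vᵢ:

1. **Nearest match.** The discrete reading is the level minimizing the
   Euclidean distance D(c, rᵢ) = √(ΔR² + ΔG² + ΔB²) — the mathematical
   analog of a person picking the closest-looking swatch.
2. **Bracketing.** The nearest level is paired with whichever of its two
   concentration-adjacent neighbors (immediately below or above in the
   sorted key) is closer in color, giving one lower- and one
   higher-concentration anchor. Using the *globally* second-nearest color
   instead could select two anchors on the same concentration side when
   the key's path through RGB space bends, which would make "interpolate
   between a lower and a higher level" meaningless.
3. **Inverse distance weighting.** With anchor distances D₁, D₂ and
   weights Wᵢ = 1/Dᵢ, the continuous estimate is
   V = (W₁V₁ + W₂V₂)/(W₁ + W₂). V always lies in [V₁, V₂]: the method
   never extrapolates beyond the chart, and endpoint matches are flagged
   so callers can report "≤ lowest level" / "≥ highest level".

Key exact properties (all tested):

* **Collinearity.** If c lies on the RGB segment between the anchors at
  fraction t, then D₁ = tL, D₂ = (1−t)L and V = V₁ + t(V₂ − V₁): IDW
  reduces to linear interpolation. This is also why the synthetic
  forward model (below) makes recovery a sharp test.
* **Uniform-lighting cancellation.** An affine map x ↦ ax + o (a > 0,
  identical across channels, no clipping) applied to *both* the test
  color and every reference color multiplies all distances by a, leaving
  the ranking, the bracket and the weights unchanged. This is the
  mathematical content of sampling test and reference colors from the
  same photograph: shared illumination cancels.
* **Continuity.** Dᵢ = 0 short-circuits to Vᵢ, the limit of the IDW
  formula, so the estimator is continuous through exact matches.

Exact distance ties are broken toward the lower concentration
(conservative for contaminants) and flagged.

### A known, intrinsic ambiguity

Just above an interior reference level, the blended color can sit closer
to the *lower* adjacent level than to the upper one, so the bracket
flips to the wrong side and the estimate lands slightly below the level
instead of slightly above. The generating side is unknowable from the
color alone — any color-proximity bracketing rule shares this behavior.
The flip zones are narrow (the affected parameter range shrinks with the
asymmetry of adjacent color-gap lengths) and the error is locally
bounded; in practice it sits well inside the 8-bit quantization
tolerance below.

## Color sampling

"Averaging over 1, 3 or 5 neighboring pixels" is implemented as centered
square windows of side 1, 3, 5 (1, 9, 25 pixels); centered odd squares
keep the estimate unbiased around the selected pixel. At raster edges
the window is clipped, never padded — padding would invent color. Means
are kept real-valued; re-rounding would discard the variance reduction
the averaging buys. No gamma linearization or white balancing is
applied: distances are computed in device RGB exactly as sampled, and
calibration cards are deliberately out of scope.

## Reference charts

Charts are JSON: per analyte an ordered list of (color, concentration)
levels. Levels are canonically re-sorted by concentration at load (file
order is not meaningful; the bracketing logic needs concentration
order). Chart colors are integers 0–255 (transcribed from photographs).
Duplicate colors within a key are a hard error — nearest-matching would
be ill-posed — while two swatches closer than 5.0 RGB units trigger a
"poorly separable" warning. pH is an ordinary analyte with empty units
on its own scale. The bundled 11-analyte chart is synthetic: plausible
level ladders with hand-chosen monotone color ramps whose within-key
pairwise distances are ≥ 30; it is not a transcription of any
manufacturer's sheet.

## Agreement statistics

* Pearson r; 95% CI by Fisher z: tanh(atanh r ± z₀.₉₇₅/√(n−3)). This
  interval reproduces, after 2-decimal rounding, all 22 CI brackets of
  the published n = 34 field comparison it is checked against.
* Two-sided p from t = r√(n−2)/√(1−r²) with n−2 df; stars at
  p ≤ 0.05 / 0.01 / 0.001. Twenty of the 22 published star codes follow
  from the printed r values; the remaining two (visual-method nitrate,
  r = 0.41, and cyanuric acid, r = 0.38, both printed **) give
  p = 0.016 and 0.027 under this — or any standard — test, an internal
  inconsistency of the printed table that the package reports rather
  than reproduces.
* Bland–Altman: differences d = a − b; bias = mean(d); limits of
  agreement bias ± 1.96·SD (sample SD, n−1; multiplier configurable).
  Proportional bias is the OLS slope of d on the pair means with its
  t-test — the conventional check behind a "no proportional bias" claim.
* No multiple-testing correction is applied across analytes, matching
  the protocol being emulated.
* Site series: per-analyte min–max standardization to [0, 1]; a constant
  series maps to zeros with a warning. "Cumulative concentration" along
  a transect is ambiguous between a running sum of standardized values
  and the standardized series itself, so both are emitted and neither is
  asserted as canonical.

## Synthetic scenes

`render_array` paints pads (forward-model colors at the true
concentrations) and reference swatches (chart colors) on a light
background, then applies gain/offset, a linear shadow ramp, i.i.d.
Gaussian pixel noise (after lighting, before clipping), and clips and
quantizes to 8 bits. One seed drives all randomness and is recorded in
the scene JSON; renders are byte-reproducible. Default geometry is a
12 px pad per analyte row with its swatches alongside — small enough
that a full 11-analyte scene renders in about a millisecond, which is
what makes the Monte-Carlo suites below cheap.

The generator emulates: known truths, same-image chart placement, mild
global lighting changes, sensor noise, quantization. It does not
emulate: chemistry kinetics, turbidity or background-color
interference, perspective, lens or JPEG artifacts, or non-linear camera
response — so passing tests demonstrate the correctness and the
lighting-robustness *mechanism* of the algorithm, not field accuracy on
real strips.

## Numerical choices and tolerances

* All distance/weight arithmetic is double precision; reported
  concentrations are rounded only at the CSV boundary, to a per-analyte
  decimal count stored in the chart (default 2).
* **Quantization tolerance.** Rounding to 8 bits moves each sampled
  channel by ≤ 0.5, hence each anchor distance by ≤ √3/2 and the
  interpolation parameter by ≤ √3/L for an anchor separation L, giving a
  per-bracket concentration bound of 2√3·ΔV/(gain·L), maximized over
  brackets. Recovery RMSE and lighting-cancellation shifts are asserted
  against this bound; "correlation of 1.0" for noiseless recovery is
  asserted as r ≥ 0.999, the quantization floor for narrow-range
  analytes (e.g. iron, 0–2 mg/L).
* Monte-Carlo problem sizes: 20 strips × 11 analytes for noiseless
  recovery; 40 strips per noise level (σ ∈ {0, 2, 5, 10}) with common
  truths across levels for the noise-degradation trend, asserted
  non-increasing within a 0.002 slack (≈ 2× the standard error of a
  mean-r estimate at that size); 120 paired replicates for the
  window-5 vs window-1 variance comparison, pooled across analytes after
  normalizing by each chart range (observed ratio ≈ 1/25, the
  theoretical 25-pixel averaging gain).

## Limitations

Device RGB only (no CIEDE2000/Lab alternatives — simplicity is the
point of the method); two-anchor IDW only; no automatic pad detection
(coordinates are human-supplied by design); no white-balance
calibration; synthetic validation as discussed above.
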