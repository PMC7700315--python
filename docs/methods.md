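# Measurement model and design notes

## The color model

The pipeline works in a geometric HSI space derived from normalised RGB
(components divided by 255):

- intensity `I = (R + G + B) / 3`,
- saturation `S = 1 − min(R, G, B) / I` (0 for achromatic pixels),
- hue `H` from the classical arccos construction on the chromaticity
  triangle, reflected into (180°, 360°) where `B > G`; achromatic pixels
  report `H = 0` with a validity flag.

The inverse uses the standard 120°-sector formulas and round-trips within
1e-6 for in-gamut inputs. The hexcone (HSV) alternative was considered and
rejected: the mean-based intensity matches the "intensity = color
brightness" semantics the code chart is built on, and the geometric variant
keeps saturation scale-invariant, which the chart's chromaticness axis
relies on.

## The code chart

Colors are reported as NCS-style codes `<blackness><chromaticness>-<hue>`.
The chart spans 16 hue tokens (G, G10Y … G90Y, Y, Y10R … Y50R), 8
chromaticness steps (10, 15, 20, 30, 40, 50, 60, 80) and 4 blackness steps
(5, 10, 20, 40) — 512 codes. Hue tokens sit on the HSI hue circle at
G = 120°, Y = 60°, R = 0°, linearly spaced (6° per 10 % step), giving a
strictly monotone 16-bin hue axis from 120° down to 30° (Y50R).

Quantization is nearest-bin per axis: hue angle → nearest token anchor;
`S × 100` → nearest chromaticness step; blackness → nearest blackness step.
Exact midpoints resolve to the lower step.

**Blackness is measured relative to the gamut ceiling.** The naive reading
`blackness = 100 × (1 − I)` cannot support a self-consistent chart: for
saturated hues the inverse-HSI point at intensity `(100 − blackness)/100`
lies far outside RGB gamut (at hue G, S = 0.8, the required channel value
reaches 2.47), and clipping would destroy the code. Instead blackness is
measured against the brightest representable color of the same hue and
saturation: `blackness = 100 × (1 − I / I_max(H, S))`, which reduces
algebraically to `100 × (1 − max(R, G, B))`. This mirrors the perceptual
definition of blackness (distance from the maximal chromatic color) and
makes every chart entry exactly representable: each representative color is
the inverse HSI at the anchor hue, `chromaticness/100` saturation and
`(1 − blackness/100) × I_max`. All 512 representative colors survive the
8-bit round trip and quantize back to their own codes (exhaustively
tested; the worst hue error after rounding is 1.5°, half a bin step being
3°).

Chart numbering is `hue_index × 32 + chromaticness_index × 4 +
blackness_index + 1` (hue outermost, 1-based). The numbering is this
package's own deterministic convention; the exported chart table carries the
full number ↔ code map so downstream users can re-map onto any other
numbering scheme.

Codes with `blackness + chromaticness > 100` (e.g. `4080-Y`) exist in the
full grid and parse, enumerate and quantize normally; only the `whiteness`
operation treats them as inadmissible (error by default, clamp-to-zero
behind a flag).

Lenient parsing accepts off-grid codes — any percent pair and any hue token
on the G…R arc — because the standard color-check chart itself contains one
(`S 1040 Y60R`, whose hue lies beyond the chart's Y50R limit). The color
check quantizes each patch on axes extended by the expected code's values,
so off-grid references are recognised as themselves.

## Calibration and color check

The camera response is modelled per channel as a monotone piecewise-linear
map through (measured, reference) node pairs on [0, 1] — the practice of
reading values off a plotted nonlinear response curve by linear
interpolation. Duplicate measured values are averaged; a non-monotone
reference sequence triggers a warning and an isotonic repair; extrapolation
clamps to the end segments. Calibration is applied in normalised RGB before
the HSI conversion, keeping the color-space math exact and the calibration
separable (the alternative — interpolating on the HSI side — is
observationally equivalent for monotone response curves but couples the
channels).

Flat-field correction divides the image by a white reference frame
normalised per channel to its median; a linear illumination ramp is divided
out exactly (within one digital level of re-quantization). The reference is
assumed clean (an averaged frame); `smooth_sigma` optionally Gaussian-smooths
a noisy one. Note that gradients that saturate a channel at capture
(value 255) are unrecoverable in principle.

The color check renders/measures five reference patches (S 1020 G,
S 1040 Y60R, S 0530 Y, S 0515 G20Y, S 2020 G80Y) and passes a patch when at
least `100 − tolerance` percent of its pixels quantize to the expected code
(tolerance 5 by default). The official 15-step brown intensity references
used for oven-browning calibration are not public; the shipped
`brown_reference_ramp` is a clearly labelled synthetic stand-in that spans
the intensity axis purely to exercise the fitting code.

## Segmentation

Foreground extraction is chroma-keying against a nominal background color
(default saturated blue, hue 240° — far from the chart's green-red arc)
with a Euclidean distance threshold in normalised RGB (default 0.25),
followed by largest-connected-component selection and hole filling; a
multi-object mode keeps all components. No fruit-shape model is used: shape
is irrelevant to the color statistics, and the chroma-key reduction is
deterministic and testable.

Fruit pixels are then partitioned into:

- **BLACK** — intensity below 0.10 (too dark to carry reliable hue);
- **RED** — chromatic pixels (saturation ≥ 0.05) with hue outside
  [27°, 123°], i.e. more than 3° beyond the chart arc on either end;
- **COLOR** — the remainder, the basis of all histograms.

The dark/red cutoffs are this package's choices; the categories themselves
are standard for excluding unevaluable pixels. No chart color comes close to
the black floor (the darkest representative has intensity 0.23).

## Histograms and the dominant code

The three marginal histograms are percentages of COLOR pixels and each sums
to 100. The joint code table is a percentage of the whole fruit surface, so
its entries are directly comparable with the BLACK/RED shares of the PIXEL
section; it sums to the COLOR share. The dominant code is reported by two
rules: composing the three marginal argmax bins (the classic rule, which can
name a code with low joint share on mixtures) and the joint-table argmax;
both appear in the export.

### Spatial majority vote

After per-pixel quantization the code field is regularised by a 3×3
majority vote restricted to COLOR pixels (ties keep the pixel's own code).
The operation is the identity on locally constant code fields and on
majority-stable boundaries — noiseless scenes are untouched — while
noise-flipped pixels near bin edges are voted back to their neighbourhood's
code. Without it, unbiased Gaussian channel noise of σ = 3 digital levels
leaks about 2 percentage points of a code's share into adjacent bins
(~1.5 points across the 3°-half-step hue boundary plus ~1.5 across the
blackness 5/10 boundary); with it the recovered shares are within ~0.02
points of ground truth at 10⁴-pixel fruit. The stage can be disabled via
`PipelineConfig.spatial_vote`.

## Ripeness trajectories

Replicate measurements at the same hour are averaged arithmetically per
code (the series shows batch means, not a single fruit). Series-dominant
codes are ranked by the *maximum* share attained anywhere in the series —
the mean would under-rank transient peaks such as a peel indicator that
overshoots late in ripening and then recedes. Trend classification uses a
flat band of 5 percentage points (aligned with the ±5 % measurement
tolerance): excursions within the band are "flat"; an interior maximum
exceeding both endpoints by more than the band is "peaked"; otherwise the
sign of end − start decides rising/falling.

The ripeness fraction `share(rising) / (share(rising) + share(falling))`
runs from 0 (unripe) to 1 (ripe), is invariant to all non-indicator codes,
and is undefined (error) when both indicator shares are zero.

Built-in indicator presets: NDM and MHC pulp (falling 0560-Y20R, rising
0560-Y40R), NDM peel (rising 1050-Y40R), MHC peel (rising 1060-Y40R, peaked
profile), Kent pulp (0550-Y20R, peaked profile), and Kent peel as an
explicit *not-applicable* marker — the peel stays rich green throughout
ripening, and requesting its evaluation returns a structured note, not an
exception. Peel samples can be tracked longitudinally; pulp cannot (the
fruit is cut for the measurement), so no cross-hour sample identity is
assumed.

## Synthetic fixtures

The generator emulates the measuring chamber's scenes: an elliptical fruit
on a uniform chroma-key background at the camera's 1280 × 1024 8-bit frame
(tests scale the canvas down), painted with a known mixture of chart
representative colors plus optional pure-black and out-of-arc red
fractions. Fractions are realised as contiguous angular sectors (exact to
one pixel by largest-remainder rounding), so connected-component logic is
exercised; a speckle mode scatters them instead. Optional Gaussian channel
noise (σ in digital levels) and a multiplicative linear illumination ramp
complete the scene; everything is seeded and bit-reproducible.

Ripening series follow a logistic between start and end shares (default
midpoint 36 h, the half-way point of a 0–70 h run sampled every 12 h;
default endpoints 9.2 → 29.1 % rising against 27 → 4.9 % falling, the
magnitude of a typical pulp-indicator excursion), with near-constant
bystander codes filling the remainder and the mixture renormalised to 1.
A Gaussian-bump profile models rise-and-fall peel indicators.

What the generator does **not** emulate: real fruit texture and specular
highlights, spatially correlated (non-Gaussian) sensor noise, shadows and
curved-surface shading, and camera demosaicing artefacts. Passing tests
therefore demonstrate the correctness of the accounting, calibration and
quantization machinery under controlled conditions — not field performance
on real mangos.

## Numerical choices and degenerate inputs

- Quantization ties resolve to the lower step; marginal-histogram argmax
  ties resolve to the lower-index bin and are flagged.
- Gray pixels carry hue 0 with a chromatic=False flag and are never RED.
- Zero COLOR pixels: histograms return empty with a warning; the dominant
  code raises; an all-background scene raises `EmptySceneError`.
- 8-bit re-quantization is round-half-up; all percentage identities hold to
  1e-9 in double precision.
- Test problem sizes: fruit scenes of ~10⁴ pixels for noise-recovery
  properties, one full 1280 × 1024 frame for the end-to-end command; these
  sizes already give sub-0.1-point quantization granularity.

## Known limitations

- The chart numbering is conventional; numbers from other implementations
  of the same 512-code grid need re-mapping via the exported table.
- The hue anchors (G = 120°, Y = 60°, R = 0°) assume camera RGB is already
  roughly perceptually aligned; no spectral/colorimetric NCS definitions
  are used and none are claimed.
- The ±5 % color-check criterion is interpreted as a matching-pixel
  fraction; a per-channel-deviation variant may suit some chart prints
  better and can be layered on the same report structure.
- Indicator presets encode cultivar-specific behaviour of NDM, MHC and
  Kent; other cultivars need user-supplied rules.
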