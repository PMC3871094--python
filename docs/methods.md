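# Methods

## Scope and model

`reefwatch` turns fixed-view time-lapse photographs of a uniform reference
panel into a fish-count time series and a rhythm analysis. The underlying
assumptions are: the camera, panel, chart and counting ROI are fixed for the
whole deployment (all pixel geometry comes from configuration, never from
detection); illumination and water conditions change between frames but are
approximately uniform within the small chart-patch windows; fish appear as
compact regions whose color contrasts with the panel; and the biological
signal of interest is the diel (≈24 h) modulation of the number of fish per
frame, not the identity or species of individuals.

## Colorimetric reference

Patch spectra are reflectance factors on a fixed 400–700 nm grid with a
10 nm step (31 samples). Tristimulus integration uses rectangular
quadrature on that grid — no interpolation to 1 nm, since the difference is
far below 8-bit quantization — with normalization `k = 100/Σ S ȳ Δλ` so a
perfect diffuser has Y = 100. The measurement illuminant defaults to D50
with the CIE 1931 2° observer (the geometry of the integrating-sphere
instrument assumed to have produced the spectra); sRGB's white is D65, so a
Bradford chromatic adaptation from the computed source white to the D65
white precedes the IEC 61966-2-1 primaries matrix and transfer curve.
Encoding rounds half-up and clips; out-of-gamut linear values are clipped
rather than gamut-mapped, which is the common practice for 8-bit chart
targets. The CIE color-matching functions and D50/D65 spectral power
tables are embedded as standard constants.

## Thin-plate-spline color calibration

The calibration warp is a 3-D thin-plate spline in RGB space: kernel
`φ(r) = r`, the biharmonic Green's function in three dimensions (the 2-D
`r² log r` kernel does not apply), plus a full affine part. Colors are
normalized to [0, 1] before solving the `(9+4)×(9+4)` symmetric system for
conditioning and de-normalized on application. The regularization λ
defaults to 0 (exact interpolation of the nine patch targets); a small λ
(≈1e−3 in normalized units) is exposed for noisy charts. The side
conditions Σw = 0 and Σw·c = 0 are implied by the polynomial block of the
system and are asserted to 1e−8 after every fit. Duplicate control points
make the kernel matrix singular; the fit reports which patch pairs collide.
One model is fitted per frame — each frame carries its own chart — and
applied to the whole frame, with output clipped to [0, 255]. Because the
degradations the chart can see (gain, color cast, uniform haze) are
affine in RGB, the spline reproduces their inverses exactly; its bending
capacity only engages for channel clipping and other non-affine effects.

## Quality screening

Frames are summarized by the mean calibrated RGB of a fixed panel-center
window; PCA is computed on the covariance (channels share 8-bit units) via
SVD of the column-centered matrix, with each loading's largest-magnitude
element made positive so runs are reproducible. The default selection rule
keeps a frame iff its squared Mahalanobis distance to the training cloud
(mean and covariance of the manually vetted frames' PC1–PC3 scores) is at
most the χ²₃ quantile at the configured coverage (default 0.99), with the
threshold raised to the training cloud's own maximum distance so training
frames are never discarded. The literal positive-PC1-and-PC3 sign rule is
kept as an alternative: it describes one dataset's geometry, while the
distance rule generalizes it. Screening quality depends on the training
set covering the range of acceptable conditions; small or temporally
clustered training sets make the rule conservative (clear frames near the
boundary get discarded, which only costs missing slots downstream).
The feature window should be placed where fish rarely linger: a fish
crossing the window moves the frame's feature and can trigger a discard.

## Counting

The distance map `d = ‖pixel − background‖₂` (background = mean of the
panel-center window) is passed through the Roberts cross operator, whose
magnitude is reported on the (h−1, w−1) grid of 2×2 neighborhoods. The
edge threshold defaults to Otsu's value computed inside the ROI, but never
below a robust noise floor `median + 5·1.4826·MAD` of the ROI edge
magnitudes: Otsu presumes a bimodal histogram, and on a fishless frame it
would bisect the sensor-noise mode, after which closing welds the speckle
into one giant blob. Body outlines are converted to solid regions by
morphological closing (disk radius 2 px) and hole filling — the edge
operator traces silhouettes, it does not fill them — then restricted to
the ROI, labeled with 8-connectivity, and filtered at `min_area` (default
30 px at 640×480). Objects belong to the ROI by centroid membership,
avoiding double counting at the boundary. Overlapping or touching fish
merge into one object: edge-based counting has no occlusion splitting, so
counts are a lower bound during crowding. Frames are counted independently;
at a 30-min cadence there is no meaningful identity linkage to track.

## Rhythm analysis

The chi-square periodogram folds the series at every integer slot count K
from `ceil(660/Δt)` to `floor(1500/Δt)` and computes
`Q_P = N·(Σ_h (M_h − M̄)²/K)/(Σ_i (x_i − M̄)²/N)` over the N non-missing
points, which is asymptotically `χ²_{K−1}` under the no-rhythm null; the
percent variance `100·Q_P/N` is the share of total variance carried by the
folded means. Missing slots are simply left out of the column means and of
N — the minimal consistent extension when a third of frames are discarded.
The raw p < 0.05 quantile line is reported per period, along with a
Bonferroni-corrected line across the ~29 tested periods; the peak is the
significant period maximizing Q. Candidate periods are integer slot
multiples only: the statistic is defined on whole-slot folds, and sub-slot
interpolation would manufacture resolution the sampling does not have.

The waveform folds the series on the standard 24-h day (48 bins at 30 min),
ignoring missing slots per bin. MESOR is the mean of bin means; onset is
the first bin above MESOR scanning from midnight and offset the last bin of
that contiguous above-MESOR phase (the first-below convention, which
reports the following bin, is available — the two differ by exactly one
bin). The daytime activity percentage is the sum of bin means inside the
daytime window over the sum of all bins; the night window is configuration
(default 20:00–08:00), never computed from an ephemeris, since the relevant
band is site- and season-specific. The turbidity diagnostic runs the same
waveform on the uncalibrated green-channel mean of the green chart patch
and overlays per-bin totals of discarded frames.

## Synthetic data

The generator renders the deployment's geometry: a red panel (default
(168, 52, 44)), the nine-patch chart, and elliptical "fish" of contrasting
color, degraded by `clip(cast · gain · ideal)` mixed toward a gray-green
haze color by the turbidity level and Gaussian sensor noise, quantized to
uint8, all bit-reproducible from a seed. Turbidity is spatially patchy — a
smooth random field scales the nominal level across the frame — because
uniform haze would be an affine map the chart inverts exactly, and real
suspended matter never is; patchiness is what leaves turbid frames
detectable after calibration. Extra noise grows with turbidity. Fish
counts are Poisson (negative binomial if a dispersion is set) with mean 8
per frame in the 08:00–20:00 day window and 1 at night, sampled every
30 min over 18 days — the cadence and day-high/night-low contrast of the
deployment the protocol targets; daytime turbidity episodes occur at a
configurable per-slot rate. Sequences place fish by rejection sampling
with a minimum separation so clean-scene counts have unambiguous truth.

What the generator does not emulate: fish shape and texture (ellipses
only), motion blur, partial occlusion by the panel edge, biofouling of the
chart, specular glints, or optically correct underwater attenuation. Tests
passing on synthetic runs therefore demonstrate the pipeline's mechanics —
calibration recovery, screening separability, count fidelity on separated
bodies, rhythm detection through missing data — not performance on any
particular field deployment.

For test geometry the chart is laid out as a single row whose patch
windows scale with the frame (60×60 px patches with 40×40 windows at
640×480; smaller in compact test frames): nine of the conventional
100×100 px windows cannot sit in one row of a 640-wide frame. Window sizes
travel with the chart layout, so a real configuration uses its measured
pixel rectangles unchanged.

## Problem sizes and tolerances

The test suite exercises: TPS interpolation/affine reproduction at 1e−6
and side conditions at 1e−8; calibration recovery over 200 randomized
scenes (gain 0.4–1.3, random casts, patch noise σ ≤ 3) at a mean patch
error ≤ 2 8-bit units; Roberts and connected-components equivalence against
brute-force oracles (explicit convolution; stack-based flood fill over
1,000 random masks); ≥ 95% exact count recovery over 100 clean layouts of
1–8 fish; periodogram null calibration over 1,000 rhythm-free Poisson
series (per-period rejection ≈ α, Bonferroni familywise rate ≤ α); and
closed-form waveform checks on noiseless square waves. End-to-end pipeline
tests run 3-day, 240×320 sequences (144 frames), sizes chosen to keep the
full suite within a few minutes on one CPU while leaving every stage's
statistics interpretable.

## Known limitations

- Counting merges touching fish and misses fish off the panel; automated
  totals under-count relative to exhaustive manual counts, while phase
  metrics (peak period, onset/offset) remain stable — the intended use.
- The screening rule presumes the training set spans the acceptable
  conditions; it does not learn and cannot flag novel failure modes that
  leave panel color unchanged.
- The chi-square significance line is asymptotic; for very short series or
  heavily missing columns the χ² approximation degrades.
- Calibration is only as good as the chart: clipped (saturated) patches
  anchor the warp at the gamut boundary, and conditions the chart does not
  witness (spatially varying casts) are not corrected.
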