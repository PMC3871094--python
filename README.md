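# reefwatch

Automated day–night fish counting for fixed-view underwater time-lapse
imagery, with colorimetric calibration and chronobiological analysis.

Shallow coastal camera platforms can photograph the same scene every few
minutes for weeks, but turning those frames into a usable activity time
series is the bottleneck: illumination swings over the day–night cycle,
turbidity episodes wash out contrast, and manual counting does not scale.
`reefwatch` implements a protocol built around a uniform reference panel
carrying a nine-patch color chart placed in the camera's field of view:

1. **Chart reference** (`reefwatch.colorimetry`) — the patches' measured
   reflectance spectra `R(λ)` (400–700 nm, 10 nm step) are integrated
   against the measurement illuminant `S(λ)` and the CIE 1931 2° observer,
   `X = k·Σ R(λ)S(λ)x̄(λ)Δλ` with `k = 100/Σ S(λ)ȳ(λ)Δλ`, Bradford-adapted
   to D65 and encoded as 8-bit sRGB. These nine triplets are the fixed
   calibration targets.
2. **3D thin-plate-spline color calibration** (`reefwatch.tps`) — per frame,
   the warp `f(x) = a₀ + A·x + Σᵢ wᵢ φ(‖x − cᵢ‖)` of RGB space (biharmonic
   kernel `φ(r) = r`) pinning the frame's observed chart-patch means `cᵢ`
   onto the reference triplets, solved from the polyharmonic system
   `[[K + λI, P], [Pᵀ, 0]][w; a] = [t; 0]`, is applied to every pixel.
3. **Quality screening** (`reefwatch.quality`) — each calibrated frame is
   summarized by the mean RGB of the panel-center window, ordinated by PCA,
   and kept iff its squared Mahalanobis distance to the score cloud of a
   manually vetted good-visibility training set is within the χ²₃ quantile
   (coverage 0.99 by default; the positive-PC1/PC3 sign rule is available).
4. **Counting** (`reefwatch.segmentation`) — inside a fixed ROI polygon,
   the per-pixel Euclidean RGB distance to the panel background is passed
   through the Roberts cross operator; thresholded edges are closed,
   hole-filled and counted as 8-connected components above a minimum area.
5. **Rhythms** (`reefwatch.rhythms`) — the count series (discarded frames =
   missing slots) is screened with the Sokolove–Bushell chi-square
   periodogram over 660–1,500 min, `Q_P = N·Var(M_h)/Var(x) ~ χ²_{K−1}`
   under the null; the folded 24-h waveform yields the MESOR (mean of bin
   means), activity onset/offset (first/last bin above MESOR) and the
   daytime activity percentage. A green-channel turbidity diagnostic
   relates image discards to water clarity.

A fully ground-truthed synthetic scene generator (`reefwatch.synthetic`)
emulates the deployment — red panel, chart, diel Poisson fish counts,
illumination drift, patchy turbidity — so the whole pipeline is testable
without field data.

## Worked example

```bash
python examples/05_rhythms.py
```

```
planted period      : 1440 min
detected peak       : 1440 min (72.8% of variance)
MESOR               : 4.36 fish/frame
activity onset      : 08:00:00
activity offset     : 19:30:00
daytime activity    : 88.0%
```

An 18-day synthetic count series (30-min cadence, Poisson mean 8 by day and
1 by night, 32% of slots discarded at random) is analyzed: the periodogram
peak at 1,440 min is the planted 24-h rhythm, the percent variance is the
share of total variance carried by the folded daily profile, and onset/
offset bracket the planted 08:00–20:00 activity window. The other examples
(`examples/01…06`) walk through chart building, calibration, screening,
counting and the full pipeline; `reefwatch simulate|calibrate|screen|count|
rhythms|run --help` exposes the same stages from the shell.

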