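# Methods

## Generative model

The package is organized around a two-channel generative model for
ratiometric biosensor images:

```
image1(x,y) = [a0 + a1(x,y)]·S2(x,y) + B1 + shade1(x,y) + N1(x,y)
image2(x,y) =                S2(x,y) + B2 + shade2(x,y) + N2(x,y)
```

`S2` is the pure (background- and noise-free) denominator signal,
proportional to the local cell thickness; `a0` the basal channel
proportionality (the "background FRET" of a single-chain sensor);
`a1(x,y)` the activity deviation from basal; `B1, B2` additive camera/
ambient background constants; `shade` optional graded background; `N1,
N2` zero-mean noise. Exact rearrangement of the ratio shows that
subtracting `NCF = B1 − a0·B2` from the numerator alone leaves a
denominator `S2 + B2 + N2` that is never noise-dominated, because the
background offset `B2` survives. All estimation and diagnostic code
treats this identity as the object of interest; the synthetic generator
emits scenes that satisfy it bit-exactly.

## NCF estimation

Five routes are computed side by side and reported together rather than
declaring one canonical — their mutual agreement is itself the main
internal consistency check:

| route | definition | needs |
|---|---|---|
| theoretical | `B1 − a0·B2` with box-measured backgrounds and fitted `a0` | channel proportionality |
| fit intercept | intercept of the pixelwise OLS of image1 on image2 | channel proportionality |
| Dev_in | argmin of mean `(Ratio_NCF − Ratio_MBS)²` over the eroded interior | trustworthy MBS away from the edge |
| Dev_out | argmin of mean `(Ratio_NCF − a0_ref)²` over the background ring | nothing (dual-chain route) |
| flatness | argmin of the relative range of the mean-ratio-vs-distance profile | a roughly uniform-activity cell |

All minimizations are exhaustive 1-D grid searches (default 1001 points
over `[0, 2·bg1]`): the objectives are cheap and possibly noisy, and a
recorded dev curve makes every result auditable. Ties break toward the
smallest candidate; an argmin on a grid boundary triggers a warning.
Candidates where an objective is undefined (a non-positive flatness
denominator) are recorded as `+inf`, not errors. `a0_ref` for Dev_out is
the mean MBS ratio over the *eroded* interior, not the full mask, so the
reference is not contaminated by the very edge artifact being corrected.
The proportionality fit is unconstrained OLS with intercept; when its
residual RMS is large relative to the in-cell intensity span (weak
proportionality, typical of dual-chain sensors) the calibrator logs an
advisory recommending Dev_out but never switches objectives silently.

## Geometry conventions

Coordinates are 0-based `(row, col)`; distances in pixels; foreground is
8-connected, background 4-connected (the standard digital-topology
pairing — the convention is ours, chosen once). Contours are traced per
connected component by clockwise Moore boundary following from the
topmost-then-leftmost boundary pixel, terminating when the first directed
move repeats; outer contours are the background pixels 8-adjacent to the
mask, ordered by the inner traversal they touch. Pixels on the image
border count as boundary only when 8-adjacent to true in-image
background, so border-clipped contours may be open; smoothing then uses
reflective instead of periodic padding. The default mask-threshold policy
when the user supplies none is background-box mean + 3·std — the same 3σ
rule used for pixel classification. An optional `pixel_size_um` tag is
carried through I/O but never used in computation.

## Background models

Contour smoothing uses a Gaussian kernel truncated at ±3σ with weights
renormalized to sum to 1 (so constants are preserved exactly); σ is in
contour-pixel units, default 10, and the inverse-distance interpolation
exponent `m` defaults to 2 — both exposed as parameters and recorded in
the result provenance, since no canonical values exist for them. The
interpolated field is evaluated over the full image by default (cost
`O(domain × contour)`, chunked; contour subsampling available). Pixels
whose subtracted denominator is ≤ 0 are flagged invalid (NaN) rather
than clipped, and are excluded from every downstream statistic with
their count reported.

## Diagnostics

Distance profiles bin valid in-mask pixels by `ceil(d)`, so bin 1 is the
innermost contour layer; bins under `min_bin_count` (default 50) are
dropped to keep the relative-range metric from being driven by
tiny-sample spikes. Edge bands use the same ceiling rule signed across
the edge: offset `+k` is the k-th pixel layer inside, `−k` the k-th
layer outside, and offset 0 — the geometric edge line between the two
innermost layers — holds no pixels. Adjacent bands are compared with
two-sided Welch t-tests (the unequal-variance form is the safer default
and is recorded in metadata); for the band pair spanning the edge, −1 is
tested against +1. P-values are reported raw, with Bonferroni-adjusted
values alongside.

## Synthetic study conditions

The default scene is a 256×256 image with one disc cell of radius 80 px,
signal ramping linearly in Euclidean distance from the edge over 20 px to
an `S2` plateau of 2000, `B1 = 120`, `B2 = 100`, `a0 = 0.7` (true
NCF = 50), and unclipped zero-mean Gaussian noise of σ = 8 per channel —
edge-layer SNR (plateau/ramp)/σ ≈ 12.5, high interior SNR, clearly
visible edge artifact. Noise is deliberately not clipped at zero and
images stay floating point so the algebraic identities hold exactly;
uint16 export rounds and clips with a warning. The two-cell scene uses
per-cell `a0` of 0.63 and 0.72 by default. The negative-control
experiment (nonuniform vs distant background) adds a linear graded
background of amplitude 150 counts along the image diagonal, split
between channels in proportion `a0 : 1` — a stand-in for cell-derived
stray light, which raises both channels proportionally; under it the
distant box under-subtracts (cushioning the MBS denominator) while the
edge-sampled nonuniform field removes the local level exactly, which is
precisely the regime where accurate background subtraction amplifies the
edge artifact. The edge-band detection experiment uses a 2-px band with
activity amplitude calibrated at run time to 10× the noise-induced ratio
SD of the band.

What the generator does **not** emulate: optical blur (no PSF), photon
shot noise (noise is additive Gaussian, not Poisson), out-of-focus light
(only its graded-background surrogate), bleedthrough, or photobleaching.
Passing tests therefore demonstrate the correctness of the algebra,
estimators and statistics under the stated model — not camera
calibration or segmentation robustness on real microscope data.

## Numerical choices and degenerate inputs

* Exhaustive grids rather than gradient descent everywhere; problem
  sizes (256² scenes, ≤ 20 seeds, 1001-point grids) keep the full test
  and reproduction runs in the tens of seconds on one core.
* The flatness grid search exploits the ratio's affinity in the
  candidate: bin means are `mean(I1/I2) − c·mean(1/I2)`, so one binning
  pass serves the whole grid; a unit test pins this fast path to the
  direct per-candidate evaluation.
* Empty masks, empty interiors (cell thinner than `2·depth_in`), empty
  rings, degenerate (constant-denominator) fits, all-invalid ratios and
  non-positive flatness denominators raise explicit errors naming the
  offending parameter; `depth_out = 0` yields an empty ring with a
  warning.
* A pixel exactly at the `bg_mean + 3σ` classification boundary falls in
  the near-edge background class; a pixel at the mask threshold is
  in-cell.

## Known limitations

* The NCF is a single scalar per cell (or per scene); spatially varying
  or time-drifting correction factors are out of scope.
* Nonuniform-background interpolation deep inside a large cell is no
  more trustworthy than a distant-box constant; the package exposes the
  field but makes no accuracy claim away from the edge.
* Channel registration and spectral bleedthrough correction are assumed
  done upstream; the pipeline consumes already-corrected channels.
* Segmentation is global thresholding only; sophisticated cell
  segmentation and time-lapse tracking belong to other tools.
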