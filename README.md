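# ncfratio

Ratiometric analysis of FRET biosensor images with **noise-correction-factor
(NCF)** calibration, for quantitative cell biologists who study signalling
at the cell edge — the thinnest, dimmest and most artifact-prone part of
the cell.

## The problem and the method

A ratiometric biosensor image is the per-pixel quotient of two channels,
conventionally FRET over donor. With background subtraction,

```
Ratio(x,y) = (image1(x,y) − BG1) / (image2(x,y) − BG2).
```

Near the cell edge the cell is thin, so the pure signal `S2 → 0` and the
subtracted denominator becomes noise-dominated: the ratio inherits heavy,
asymmetric outliers (downward noise can only push the quotient toward
infinity faster than upward noise pushes it toward zero), creating a
spurious rim of apparent activity. Making the background *more* accurate
makes this worse, not better, because an accurate local background leaves
even less signal in the denominator.

When the two channels share a proportional pure signal,
`image1 = a0·S2 + B1 + N1` and `image2 = S2 + B2 + N2`, the raw ratio can
be rewritten exactly as

```
image1/image2 = [a0·(S2 + B2) + (B1 − a0·B2) + N1] / [(S2 + B2) + N2].
```

Subtracting the single constant **NCF = B1 − a0·B2 from the numerator
only** therefore yields

```
Ratio_NCF(x,y) = (image1(x,y) − NCF) / image2(x,y),
```

whose denominator keeps its background offset `B2 ≫ N2` and is never
noise-dominated — the edge artifact vanishes, and the ratio is defined
over the whole image, background included (where it averages `a0`).

The package provides:

* the NCF ratio plus the baselines it improves on (distant-box "MBS",
  halfway, and nonuniform edge-interpolated background subtraction);
* five mutually checking NCF estimators — theoretical (`B1 − a0·B2`),
  the intercept of the pixelwise channel–channel linear fit, and grid
  minimizers of `Dev_in` (NCF-vs-MBS disagreement in the eroded cell
  interior), `Dev_out` (deviation from the basal ratio in the background
  ring just outside the edge, the route for dual-chain biosensors), and
  the distance-profile flatness metric;
* diagnostics: mean-ratio-vs-distance-from-edge profiles, the relative
  range flatness metric `(max⟨I⟩ − min⟨I⟩)/min⟨I⟩`, per-band edge
  statistics with Welch t-tests, 3σ pixel classification;
* masking/geometry utilities (global thresholding, Moore contour tracing,
  Euclidean distance maps, eroded interiors and dilated background rings);
* a ground-truthed synthetic scene generator (the "wedge" cell whose
  signal rises linearly from zero at the edge) with optional activity
  bands and graded-background (shade) artifacts;
* TIFF I/O, dark-current and flat-field corrections, and an `ncfratio`
  command-line interface (`simulate`, `ratio`, `calibrate`, `profile`,
  `bandstats`, `run`).

## Worked example

Calibrate the NCF on a synthetic scene whose ground truth is known
(`B1 = 120`, `B2 = 100`, `a0 = 0.7`, so the true NCF is 50):

```python
import warnings; warnings.simplefilter("ignore")
from ncfratio import (SceneSpec, make_wedge_scene, build_region_set,
                      box_background, ncf_ratio, mbs_ratio,
                      distance_from_edge, distance_profile, relative_range)
from ncfratio.ncf import calibrate

scene = make_wedge_scene(SceneSpec(seed=1))          # true NCF = 50
mask = scene.truth.mask_true
regions = build_region_set(mask, bg_box=(8, 8, 48, 48))
bg1, _ = box_background(scene.img1, (8, 8, 48, 48))
bg2, _ = box_background(scene.img2, (8, 8, 48, 48))

cal = calibrate(scene.img1, scene.img2, regions, bg1, bg2)
print("fitted a0:", round(cal["a0"], 4))
for name, value in cal["ncf"].items():
    print(f"NCF ({name}): {value:.2f}")

distmap = distance_from_edge(mask)
r_ncf = ncf_ratio(scene.img1, scene.img2, cal["ncf"]["dev_in"])
r_mbs = mbs_ratio(scene.img1, scene.img2, bg1, bg2)
for label, r in [("MBS", r_mbs), ("NCF", r_ncf)]:
    flat = relative_range(distance_profile(r, distmap))
    print(f"{label} edge flatness: {100 * flat:.2f}%")
```

prints

```
fitted a0: 0.6998
NCF (theoretical): 49.82
NCF (fit_intercept): 50.27
NCF (dev_in): 49.86
NCF (dev_out): 50.82
NCF (flatness): 50.82
MBS edge flatness: 1.97%
NCF edge flatness: 0.81%
```

All five estimators agree with the true NCF of 50 to within ~2%, and the
NCF ratio's mean-vs-distance profile is more than twice as flat as the
background-subtracted (MBS) one — the residual edge bias of MBS is the
division-by-small-numbers artifact the method removes.

The same workflow from the shell:

```sh
ncfratio simulate --outdir scene --seed 1
ncfratio calibrate --numerator scene/img1.tif --denominator scene/img2.tif \
    --bg-box 8,8,48,48 --outdir cal
```

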