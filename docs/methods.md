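# Methods

## The detection model

Hard exudates are bright, compact deposits on a smoothly shaded retinal
background. Both detection prongs share one template — white top-hat,
adaptive equalization, fixed threshold, field-of-view intersection — and
differ in operand and scale:

| | operand | disk radius | threshold |
|---|---|---|---|
| step 1 (bright) | grayscale (BT.601) | round(W/4) | 0.37 |
| step 2 (faint) | green plane | round(W/25) | 0.25 |

The white top-hat `I − opening(I, B_r)` removes every structure that can
contain the disk `B_r` — in particular background illumination — while
passing smaller bright blobs. A *linear* shading ramp is removed exactly
(a flat structuring element fits a ramp); what survives is curvature of
the illumination field and the floor-depression caused by dark vessels
inside the disk's support. Radii are fractions of the full image width,
rounded to the nearest integer with a floor of one. Thresholds apply
strictly (`>`) on the [0, 1] scale of the equalized image.

Disk erosion/dilation is computed exactly by decomposing the Euclidean
disk into horizontal chords and running 1-D sliding minima/maxima per
chord (O(N·r) instead of O(N·r²), which matters at r = W/4). Windows are
clipped at the raster boundary; out-of-bounds pixels never contribute.

### Equalization and the meaning of the thresholds

`adaptive_hist_eq` delegates to scikit-image's CLAHE (8×8 tile grid, clip
limit 0.01, both configurable), which **min–max normalizes its input**
before tiling. This is load-bearing: the top-hat residue occupies a small
absolute range, and a contrast-limited equalization over a *fixed* [0, 1]
range can raise a +0.06-contrast lesion at most ~0.05 of output range
above the local background top for any clip limit — the fixed thresholds
0.37/0.25 would then be unreachable for faint lesions. With the
normalization, the scene's brightest residue (optic disc, brightest
exudate) anchors the scale and the thresholds act relative to it, which
is the only reading under which the published operating point behaves as
described (detecting faint exudates at all). Consequence: on a completely
featureless frame the anchor is noise; the detector therefore
short-circuits to an empty mask when the top-hat residue is exactly
constant, and the FOV intersection suppresses the rim response of
equalization (the surround is camera matting, not retina).

### Baseline

The comparison method selects the green plane, histograms it (256 bins,
FOV pixels only — the near-black surround would otherwise dominate the
background class), and thresholds at the Kapur maximum-entropy level:
the `t` maximizing `H_b(t) + H_f(t)`, the Shannon entropies (natural log,
`0·log 0 := 0`) of the normalized histograms of bins `[0..t]` and
`[t+1..255]`. Candidates leaving a class empty are skipped; ties break to
the smallest `t`. Exudates are the bright class, so the mask is "strictly
above `t`". Being a single global cut, the threshold settles just above
the brightest background; faint exudates in dimmer parts of the field
fall below it — the failure mode the two-step detector removes.

## Quantification

* Exclusion boxes are half-open `[x0,x1)×[y0,y1)` rectangles, 0-based,
  origin top-left, clipped to the frame; fully outside boxes are ignored
  with a warning. This scripts the "semi-automated" manual outlier
  removal and makes it testable.
* Areas: `pixel_count × mm_per_pixel²`, totals and per 8-connected
  component (lesions are blob-like; 4-connectivity available).
* Calibration: user-supplied mm/pixel wins; otherwise a field-of-view
  route assumes a 50° acquisition and the emmetropic retinal scale of
  0.288 mm/degree, `mm_per_pixel = 50·0.288 / fov_diameter_px`. The
  fallback is logged and tagged — it is an explicit stand-in, not a
  reproduction of any camera's true pixel pitch.
* Method difference is `baseline − proposed` (negative = baseline
  underestimates). Grading bins are `[0,30), [30,60), [60,90), [90,100]`.
* Agreement: the uncentered CC is implemented verbatim as
  `Σxy/√(Σx²Σy²)`; because it is not mean-centred it is near 1 for any
  two positive similar-magnitude series, so the centred Pearson
  correlation is provided alongside under its own name. ICC is the
  two-way mixed, absolute-agreement, single-measure coefficient
  (McGraw–Wong A,1; computed via pingouin); designs too small for the
  mean-squares decomposition warn and report NaN. Bland–Altman uses the
  sample (N−1) standard deviation.

## The synthetic world

`generate_scene` emulates the intensity structure of a diabetic-macular-
edema fundus photograph; all geometry is invented and parameterized, only
the gray-level architecture is calibrated: HEs 85–200, cotton-wool spots
80–130, optic disc 90–200, vessel reflections 80–110 (8-bit grayscale).
Defaults and the reasoning behind the free choices:

* **Canvas**: 512×512, circular FOV of diameter 0.95·min(H, W) on a
  near-black (≤5) surround; reddish background, base RGB (160, 80, 30).
* **Illumination** (`illumination_gradient`, default 0.3 relative
  amplitude): a tilted plane brightening toward the nasal (disc) side
  plus a broad gentle bump. Real fundus photographs are brightest around
  the disc and darker at the macula; the tilt-dominated field also keeps
  the top-hat honest (ramps vanish in the opening). The dim macula is
  what makes a global threshold miss faint lesions — the regime the
  method was designed for. 0.3 of the base level (~25 gray levels of
  green-plane spread) exceeds the faint-lesion contrast (~15), as it
  does in shaded clinical photographs.
* **Optic disc**: bright ellipse at 0.62·FOV-radius on the nasal side,
  radial profile inside 90–200.
* **Vessels**: 2–4 random-walk paths from the disc, widths 2–4 px, at a
  constant *fractional* contrast (0.80–0.88 of the local background,
  deeper in green/blue). Relative contrast matters: absolute-gray
  vessels would be ~30 levels deep in the bright region and drag the
  top-hat background up across whole equalization tiles. Bright
  centerline reflections (gray 80–110) cover a random 30 % of each path.
* **Bright HEs** (`n_bright_he`, default 6): clusters of 1–8 elliptical
  blobs (semi-axes 1–6 px) in the macular half, gray in the upper half
  of 85–200.
* **Faint HEs** (`n_faint_he`, default 6): blobs (semi-axes 3–6 px)
  whose green channel sits `faint_green_excess`·255 (default +15 levels)
  above the local background and whose grayscale stays in the lower half
  of the HE range, a few levels above background — visible locally,
  invisible globally.
* **Cotton-wool spots** (`n_cws`, default 2): larger fuzzy blobs
  (Gaussian-blurred alpha, σ ≈ 2 px), gray 80–130.
* **Noise**: additive Gaussian, sd 0.01·255, inside the FOV only (so the
  surround stays near-black for FOV estimation); clipped and rounded.

Placement uses rejection sampling (≤1000 attempts per lesion, then an
error naming the class) with a 3-px separation from all previously
placed structures, so HE truth is disjoint from disc, vessel and CWS
masks and percent-detected is well defined per class. Truth masks are
recorded *before* blur and noise: the blur models acquisition, not
lesion extent. Scenes are bit-deterministic functions of the spec.

`confounder_boxes` emulates the manual outlier-removal step: one
bounding box (margin 10 px) per disc and CWS component, and a string of
small tiled boxes along the vessel/reflection course — a human grader
boxes vessel segments; a single bounding box of the whole tree would
blank most of the field. The margin absorbs the top-hat halo that dark
vessels cast on their surroundings.

### What a green test does and does not establish

The generator reproduces the *intensity* logic of the problem — class
gray ranges, shading, locally-faint lesions, bright confounders — so
passing tests establish that the implementation behaves as the method
intends: bright lesions are always found, faint lesions are found
locally but missed globally, confounder exclusion leaves ≈ no residue,
recall degrades monotonically with contrast. The scenes do **not**
reproduce real lesion morphometry, vessel anatomy, media opacity, or
camera optics, and no clinical quantity (areas in mm², agreement
percentages) is claimed to match any cohort; those depend on data the
package does not ship.

## Numerical choices and degenerate inputs

* Strict `>` at both thresholds; level-exact ties therefore fall to
  background.
* Histogram binning for the baseline is `round(v·255)`.
* 16-bit inputs are down-scaled by integer division (65535 → 255) with a
  logged warning; grayscale inputs are replicated to RGB with a warning.
* All-dark frames: FOV estimation raises; with an explicit FOV, detection
  returns an empty mask (constant top-hat short-circuit).
* Uniform images make the baseline raise (a one-bin histogram cannot be
  split into two classes).
* A top-hat ramp retains a `slope·r` residue within one radius of the
  raster edge (clipped windows); the FOV intersection makes this moot on
  photographs.

## Known limitations

* The equalization geometry of the original pipeline is unknown; the
  thresholds 0.37/0.25 are coupled to it. Both are configurable
  (`DetectParams`), and the defaults are the mainstream CLAHE defaults.
* The mm² scale of any real photograph requires a supplied calibration;
  the 50°/0.288 mm-degree fallback is a documented convention.
* The detector is intensity-based: it does not classify the optic disc,
  vessels or cotton-wool spots — exclusion is the user's (scripted)
  responsibility, as in the semi-automated workflow it implements.
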