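# hequant

Semi-automated quantification of **hard exudates** (HEs) in colour fundus
photographs.

Hard exudates — yellow lipid deposits in the retina — are a hallmark of
diabetic retinopathy and of macular edema. Clinicians typically grade them
qualitatively; monitoring treatment response calls for a number: the retinal
area the exudates cover, in mm². Manual delineation is impractical because
HEs are numerous, small, and topologically complex. `hequant` implements a
two-pronged morphological detector for bright *and* faint exudates, the
green-plane maximum-entropy baseline it improves upon, scripted outlier
removal, mm² area measurement, observer-agreement statistics, and a seeded
synthetic fundus generator so the whole pipeline is testable without
clinical data.

## Method

The detector runs twice and unions the results. With `I` the input
photograph, `∘` the morphological opening by a flat disk `B_r`, and
`CLAHE` contrast-limited adaptive histogram equalization:

* **step 1 (bright HEs)** on the grayscale image `I_gray`
  (BT.601, `0.2989 R + 0.5870 G + 0.1140 B`):

  `M₁ = [ CLAHE( I_gray − I_gray ∘ B_{W/4} ) > 0.37 ]`

* **step 2 (faint HEs)** on the green plane `I_G`, where faint exudates
  are best contrasted:

  `M₂ = [ CLAHE( I_G − I_G ∘ B_{W/25} ) > 0.25 ]`

* `M = (M₁ ∪ M₂) ∩ FOV`, followed by scripted rectangular exclusion
  boxes over the optic disc, vessel reflections and cotton-wool spots —
  the structures that share the exudates' brightness.

The white top-hat `I − I ∘ B_r` flattens uneven illumination and passes
bright structures smaller than the disk; the radii (one-fourth and
one-twenty-fifth of the image width) and thresholds (0.37, 0.25) are the
method's published operating point. The baseline (`baseline_detect`)
reproduces the earlier ImageJ protocol: Kapur maximum-entropy thresholding
of the green-plane histogram — a single global cut that misses exudates
whose contrast is smaller than the image's shading.

Areas are `pixel count × (mm/pixel)²`, per 8-connected component and in
total. Grading agreement is summarized with the uncentered correlation
`CC = Σxᵢyᵢ / √(Σxᵢ² Σyᵢ²)`, the Pearson correlation, the intraclass
correlation (two-way mixed, absolute agreement, single measure) and
Bland–Altman limits of agreement `bias ± 1.96·SD`.

## Worked example

```sh
python examples/baseline_comparison.py
```

```
proposed: 0.1136 mm^2 | baseline: 0.0691 mm^2
difference (baseline - proposed): -0.0445 mm^2
  proposed: recovers 100% of bright and 49% of faint HE area
  baseline: recovers 100% of bright and 16% of faint HE area
```

A synthetic scene (seed 4, 512×512, 10 µm pixels) is rendered with six
bright HE clusters and six faint HEs; both detectors run on it and
confounder regions are excluded. Both find every bright exudate, but the
global-threshold baseline recovers only 16 % of the faint-exudate area
against 49 % for the two-step detector — so the baseline *underestimates*
the exudate load (negative area difference), which is the clinical failure
mode the two-pronged design addresses. The other examples cover detection
and measurement (`detect_and_measure.py`), a paired multi-seed sweep with
grading-bin summaries (`faint_exudate_sweep.py`), and observer-agreement
reporting (`observer_agreement.py`).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Re-runs the full pipeline from scratch: renders seeded synthetic scenes,
runs the proposed detector and the maximum-entropy baseline on each,
applies scripted confounder exclusions, measures areas in mm², and prints
a paired summary of how much of the true exudate area each method
recovers, together with the grading-bin counts.

## Layout

| module | contents |
| --- | --- |
| `hequant.imgio` | reading/writing, gray/green planes, FOV estimation, calibration |
| `hequant.morphology` | exact Euclidean-disk erosion/dilation, white top-hat |
| `hequant.detect` | CLAHE, thresholding, the two-step detector |
| `hequant.baseline` | Kapur maximum-entropy thresholding of the green plane |
| `hequant.quantify` | exclusion boxes, mm² areas, binning, CC/ICC/Bland–Altman |
| `hequant.synth` | seeded synthetic fundus scenes with per-class ground truth |
| `hequant.pipeline` | batch workflows: detect, evaluate, agreement reports |

See `docs/methods.md` for the modelling assumptions, parameter rationale,
and what the synthetic scenes do and do not establish.
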