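# odseg — optic-disc segmentation with a hybrid level-set model

The optic disc (OD) is the bright oval region of the retina where the
optic nerve and vessels enter; its boundary underpins glaucoma metrics
such as the cup-to-disc ratio. Segmenting it in fundus photographs is
harder than it looks: dark vessels notch the boundary, parapapillary
atrophy (PPA) crescents and bright noise mimic disc tissue, and
wide-angle cameras deliver low-contrast red/green-only images.

`odseg` implements a complete classical pipeline for this problem:

1. **Localization** — the disc is found by combining high vessel density
   (top-hat map of the inverted green channel), high brightness (the
   candidate window holding the most of the brightest 2% of value-channel
   pixels) and oval shape (circular Hough refinement); a square ROI of
   three disc diameters is cut around it.
2. **Preprocessing** — channel selection by contrast-to-noise ratio
   (CNR = (μ_fg − μ_bg)/σ_bg over nine color channels; the HSV value
   channel wins on fundus data), then vessel and noise removal by
   Gaussian blur → grayscale closing/opening → hard FFT low-pass.
3. **Initialization** — an adaptive mean threshold, binary opening and
   largest-4-connected-component selection isolate the disc blob; a
   direct least-squares ellipse fit to its boundary gives the shape
   prior φ_init (as a signed-distance field).
4. **Evolution** — the contour is the zero set of φ (negative inside)
   minimizing the four-term energy

   ```
   E(φ) = μ ∫ p(|∇φ|)                       distance regularizer
        + α ∫ δ_ε(φ)|∇φ|  + β ∫ H_ε(φ)      length + balloon
        + λ_in ∫ (u0−c1)² (1−H_ε(φ))
        + λ_out ∫ (u0−c2)² H_ε(φ)           region (Chan-Vese) fit
        + λ_shape ∫ (H_ε(φ) − H_ε(φ_init))² shape prior
   ```

   with c1/c2 the mean intensities inside/outside the contour. The
   shape term is what keeps PPA crescents and bright blobs out of the
   final contour; the region term handles weak-gradient boundaries; the
   distance regularizer keeps |∇φ| ≈ 1 so φ is never reinitialized.
   Defaults: μ=0.1, α=3.0, β=0.2, λ_in=4.3, λ_out=2.0, λ_shape=1.1.

5. **Evaluation** — mask IoU, plus the four-side evaluation (FSE)
   geometry: superior/nasal/inferior/temporal 90° sectors about the
   disc center, per-sector agreement proxies and 0–5 score aggregation.

Everything is exercised on a seeded synthetic fundus generator
(`odseg.synthetic`) that renders the disc, vessels, PPA crescents,
bright blobs, low contrast and the wide-angle aperture with known
ground truth — no clinical data is required to test the package.

## Worked example

```python
from odseg import RunConfig, iou, segment_image
from odseg.synthetic import standard_suite

(image, gt, spec), *_ = standard_suite(1, seed=42)
mask, report = segment_image(image, RunConfig(style=spec.style))
print(round(iou(mask, gt), 3), report["iterations"], report["prior"]["semi_axes"])
```

prints (clean synthetic case)

```
0.928 10 [52.4, 48.6]
```

i.e. the segmented mask overlaps the true disc at IoU 0.93, the
evolution settled within 10 iterations of the fitted prior, and the
prior ellipse recovered the true semi-axes (50.5, 46.8 px here) within
a couple of pixels — the residual is the systematic inflation of the
local-mean threshold, discussed in `docs/methods.md`. The narrative
scripts in `examples/` walk through each capability (synthesis,
localization, preprocessing, segmentation, the shape-prior ablation and
sector scoring) and print the numbers they compute.

A thin CLI wraps the same functions:

```bash
odseg synth --n 12 --seed 7 --out suite/       # images + masks + specs
odseg segment --image suite/case_000.png --out mask.png --trace
odseg evaluate --masks results/ --gts suite/   # IoU summary table
odseg cnr --n 12 --seed 7                      # channel CNR ranking
```

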