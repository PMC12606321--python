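# bbtquant

Quantification and longitudinal comparison of benign bone tumours (BBTs) on
plain radiographs.

Follow-up of a benign bone lesion on X-ray hinges on two questions: has its
physical size or area changed, and has its contour become irregular?  In
routine practice both are answered by eye, comparing films side by side.
`bbtquant` implements the measurement chain that makes the comparison
quantitative:

1. **Detection** — localise the lesion with a bounding box (pluggable
   backend; a deterministic classical reference detector is included) and
   pad it by 25 px to preserve contour context.
2. **Wavelet channel fusion** — single-level orthonormal Haar transform of
   the crop; the LL/LH/HL subbands become the R/G/B channels of a fusion
   image (HH is discarded as noise), optionally stacked with the grayscale
   crop into a 4-channel segmentation input.
3. **Segmentation** — a compact U-Net (pure numpy, CPU-trainable) with an
   ablation harness comparing 1-, 3- and 4-channel inputs by mean accuracy,
   mean IoU and boundary F1.
4. **Contour extraction** — a mask pixel is an edge pixel iff any of its 8
   neighbours is background: `E = {(x,y) | L(x,y)=1 ∧ ∃(x',y')∈N(x,y),
   L(x',y')=0}`.
5. **Calibration** — the scale bar in the leftmost 10% of the image is the
   tallest thresholded component; its printed label (e.g. "13 cm"), read by
   OCR, gives the spatial resolution `S = bar_mm / bar_px` (mm/pixel).
6. **Measurement** — `width = W_px·S`, `height = H_px·S` from the minimum
   bounding box, and `area = N_px·S²` from the mask pixel count, which
   handles irregular shapes that a width×height product overestimates.
7. **Temporal comparison** — masks from successive visits are recentred on
   their centroids (integer translation, areas preserved exactly), contours
   overlaid in colour, and any |area change| > 10% is flagged, growth or
   shrinkage.

Clinical radiographs of this kind are IRB-restricted, so the package ships a
**phantom generator**: synthetic radiographs with a bone-like background, a
Fourier-perturbed elliptical lesion and a rendered, labelled scale bar —
with exact ground truth for every stage.  All quantitative claims the
package makes are computed on these phantoms or on bundled worked-example
tables.

## Worked example

```python
from bbtquant import PhantomConfig, generate_series, calibrate, compare_series

series = generate_series(PhantomConfig(seed=42), growth_factors=[1.0, 1.18])
calibs = [calibrate(s.image) for s in series]          # scale bar + fixture OCR
cmp = compare_series([s.mask for s in series], calibs, threshold=10.0)
for k, m in enumerate(cmp.measurements):
    print(f"visit {k}: {m.width_mm:.2f} x {m.height_mm:.2f} mm, "
          f"area {m.area_mm2:.1f} mm^2  (scale {m.calibration.mm_per_px:.4f} mm/px)")
for c in cmp.changes:
    print(f"{c.kind} {c.from_idx}->{c.to_idx}: {c.pct_change:+.1f}%  "
          f"{'FLAGGED' if c.flagged else 'ok'}")
```

prints

```
visit 0: 46.31 x 85.31 mm, area 3135.1 mm^2  (scale 0.8125 mm/px)
visit 1: 50.38 x 93.44 mm, area 3693.6 mm^2  (scale 0.8125 mm/px)
consecutive 0->1: +17.8%  FLAGGED
```

The two phantom visits share one lesion whose true area grows by 18%; the
calibration is recovered from the rendered scale bar (130 mm / 160 px =
0.8125 mm/px), the measured area change (+17.8%, discretisation included)
exceeds the 10% clinical-significance threshold, and the change is flagged.
`cmp.overlay` holds the colour contour overlay of the centroid-aligned
masks.

The same chain is available from the shell:

```sh
bbt phantom series --growth 1.0,1.18 --seed 42 --out visits/
bbt pipeline visits/image_0.png visits/image_1.png --out report/
bbt report --pred pred.csv --gt gt.csv --out deviations.csv
```

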