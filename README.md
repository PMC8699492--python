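# semmorph

Morphometric, fractal and textural quantification of cells in scanning
electron micrographs (SEM).

SEM delivers high-resolution grayscale images of cells on arbitrary —
including opaque — substrates, but turning those images into numbers
still tends to happen by hand-tracing in ImageJ. `semmorph` packages
the standard descriptor sets as a tested Python library and CLI:

* **Rod-shaped bacteria** (e.g. *E. coli*): per-cell length *L*, width
  *W*, aspect ratio *W/L* (~0.25 for *E. coli* rods, 1 for cocci),
  projected area, and the spherocylinder model quantities

  &nbsp;&nbsp;&nbsp;&nbsp;V = (πW²/4)(L − W/3),&nbsp;&nbsp;S = πWL,&nbsp;&nbsp;S/V

  used to study bacterial size control and surface-to-volume
  homeostasis.
* **Neuron-like cells** (e.g. B35 neuroblastoma on biomaterials): soma
  diameter (maximal inscribed disc), neurite count / average / maximum
  length, radial distance and straightness per neurite, alignment of
  each neurite chord to a reference axis (parallel < 15°,
  perpendicular > 75°, intermediate between), cell area *A*, perimeter
  *P*, circularity C = 4πA/P² (1 for a disc), and differentiated-cell
  counting (≥ 1 neurite at least as long as the soma diameter).
* **Fractal descriptors** of binary silhouettes: box-counting fractal
  dimension *D* (slope of log N(ε) vs log 1/ε) and gliding-box
  lacunarity Λ(r) = var(M)/mean(M)² + 1, quantifying branching
  complexity and gappiness of cells or networks.
* **GLCM texture**: gray-level co-occurrence matrices and the five
  Haralick descriptors — angular second moment, entropy, contrast,
  correlation, inverse difference moment — whole-image or as
  sliding-window feature maps.

A seeded synthetic-fixture module generates rod fields, neuron
silhouettes, known-dimension fractals and analytic textures with exact
ground truth, so the entire measurement chain is testable without any
external micrograph.

## Worked example

Generate a noise-free field of 12 *E. coli*-like rods (lengths uniform
on 2–4 µm, aspect ratio 0.25, 0.02 µm/px), segment it and measure every
cell:

```python
from semmorph import (binarize, clean_mask, label_instances,
                      gen_rod_population)
from semmorph.bacteria import measure_population

img, mask, truth = gen_rod_population(n=12, seed=7)
m = clean_mask(binarize(img, method="otsu"), min_object_px=25)
cells = label_instances(m, exclude_border=True)
table, summary = measure_population(cells, source_id="demo")
print(f"n measured: {summary['n']}")
for k in ("length", "width", "aspect_ratio", "volume", "sv_ratio"):
    s = summary[k]
    print(f"{k:>13}: mean = {s['mean']:.4f}, sd = {s['sd']:.4f}")
```

```
n measured: 12
       length: mean = 3.0409, sd = 0.6144
        width: mean = 0.7456, sd = 0.1534
 aspect_ratio: mean = 0.2450, sd = 0.0030
       volume: mean = 1.3571, sd = 0.7366
     sv_ratio: mean = 6.0971, sd = 1.3766
```

The recovered mean aspect ratio (0.245) matches the generator's 0.25 to
within the ~2 % discretisation bias of the medial-axis estimator;
lengths are in µm, volumes in µm³, S/V in µm⁻¹. Fractal descriptors
work the same way on any binary mask:

```python
from semmorph import gen_fractal, fractal_dimension, lacunarity

mask, _ = gen_fractal("sierpinski", iterations=9)
fr = fractal_dimension(mask)
lac = lacunarity(mask, box_sizes=fr.box_sizes_px)
print(f"D = {fr.dimension_D:.4f} (R^2 = {fr.fit_r2:.4f}), "
      f"mean lacunarity = {lac.mean_lambda:.4f}")
```

```
D = 1.5850 (R^2 = 1.0000), mean lacunarity = 4.1207
```

(the Sierpinski gasket's analytic dimension is log 3/log 2 ≈ 1.5850).

The same analyses are available from the shell:

```bash
semmorph synth rods --n 50 --seed 1 --out fixtures/
semmorph measure-bacteria --input fixtures/rods_image.png \
    --pixel-size 0.02 --out rods.csv
semmorph fractal --input silhouette.png --pixel-size 0.2 --mask --out fractal.csv
semmorph texture --input micrograph.tif --pixel-size 0.02 --window 64 --out tex.csv
```

Every output CSV gets a `.config.json` sidecar recording the full
configuration and seed that produced it.

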