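# rootgrain

Fine-grained, per-root phenotyping for in situ root scans.

Root systems imaged against the acrylic face of a soil-filled growth box
(RhizoPot-style) or in a minirhizotron are usually analysed with semantic
segmentation: one root/soil mask per image, yielding only whole-system
traits such as total root length. Instance segmentation instead delivers
one mask per root segment, which opens the door to *fine-grained* traits —
the length, diameter, surface area and curvature of every individual root.
`rootgrain` implements the computational machinery around such a workflow:

- **Annotation tiling** — flatbed scans at 1200 dpi reach 10 200 × 14 039 px,
  far beyond GPU memory. `rootgrain.annotation_tiler` splits an image and
  its polygon annotation document (Labelme JSON dialect) into s × s tiles
  (2048 px by default), either with historical vertex-deletion semantics
  (`faithful`) or clean polygon–rectangle intersection (`clip`).
- **Instance-mask post-processing** — a detector predicting a long root often
  drags fragments of neighbouring roots into its mask.
  `rootgrain.instance_postprocess` keeps only the largest connected domain
  of each predicted mask, restoring a one-to-one box↔root correspondence.
- **Skeletonization** — `rootgrain.skeletonize` thins each single-root mask
  to a one-pixel-wide medial curve (K3M phased border-marking thinning, with
  an independent fallback), prunes noise spurs, and orders the result into
  an endpoint-to-endpoint polyline.
- **Phenotypes** — `rootgrain.phenotypes` measures tip-to-tip length,
  EDT-based diameters, projected and cylindrical surface area, and curvature.
  The skeleton polyline is fitted with a quadratic

  $$y = a x^2 + b x + c$$

  (after rotating its principal axis horizontal), and the plane-curve
  curvature and radius of curvature follow as

  $$K = \frac{|y''|}{\left(1 + y'^2\right)^{3/2}}, \qquad \rho = \frac{1}{K},$$

  reported per root (with a −ln K transform for cross-day trend analysis).
- **Architecture accounting** — `rootgrain.netarch` reconstructs the layer
  graphs of the YoloV8seg family (n/s/m/l/x) and of an improved elongated-
  target variant of the n model — two extra stride-2 downsampling stages in
  the backbone and two large-target detect/segment heads at strides 64 and
  128 — and counts enumerated layers, parameters and FLOPs in closed form
  (no network is ever instantiated; training and inference are out of scope).
  It also implements the training-target filter whose aspect-ratio limit is
  removed so elongated root boxes stay in training.
- **Synthetic scenes** — `rootgrain.synthetic_roots` generates seeded root
  scenes (straight / arc / parabolic medial curves, constant or tapering
  diameter, speckle soil background) with analytic ground truth for length,
  diameter and curvature, so the whole pipeline is testable offline.

## Worked example

Simulate a 4-root scene at 300 dpi, measure every instance, and inspect the
improved network's accounting:

```bash
rootgrain simulate --n 4 --dpi 300 --seed 7 --out sim
rootgrain phenotype --masks sim/masks --dpi 300 --out traits.csv
rootgrain archcount --variant improved_n
```

`traits.csv` (selected columns) against the generator's ground truth:

```
 instance_id  length_mm  avg_diameter_mm  curvature_per_mm  radius_of_curvature_mm
           0  14.334913         0.553411          0.068386               14.622878
           1   6.602896         0.771477          0.000355             2814.151169
           2   6.210303         0.524401          0.009227              108.376722
           3  10.242011         0.810472          0.043554               22.960256

 truth:       length_mm  diameter_mm  curvature_per_mm  pattern
           0  14.528967     0.551328          0.069240   curved
           1   6.578069     0.762960          0.003266 straight
           2   6.147747     0.526186          0.000000 straight
           3  10.310526     0.868763          0.042900   curved
```

Root 0 is a strongly curved root (radius of curvature ≈ 14.6 mm, i.e.
K ≈ 0.068 mm⁻¹, within 2 % of the generated 0.069 mm⁻¹); roots 1–2 are
effectively straight, so their radius of curvature is large and their
−ln K sits at the measurement resolution floor. Lengths recover to ~1 %,
diameters to a few percent at this desk-scale resolution.

`archcount` prints the closed-form accounting of the improved variant:

```json
{
  "variant": "improved_n",
  "layers": 431,
  "parameters_m": 10.46,
  "flops_g": 13.7,
  "input_hw": [640, 640],
  "head_strides": [8, 16, 32, 64, 128]
}
```

For comparison, `--variant n` reports 261 layers, 3.26 M parameters and
12.1 GFLOPs — the improved model more than triples its parameter count yet
stays below the s variant (11.79 M) while adding only ~1.6 GFLOPs, because
the added stages operate on 10 × 10 and 5 × 5 feature maps.

The same operations are available as library calls
(`rootgrain.gen_scene`, `rootgrain.phenotype_batch`,
`rootgrain.build_spec`, `rootgrain.count_params`, ...).

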