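# chromasal

Color-aware visual saliency analysis in Python: what does *color alone*
contribute to where people look, and how can a salient-object detector use
that?

When the same scene is viewed in color and in grayscale, a uniquely colored
object pops out only in the color condition. `chromasal` implements the
full analysis and modeling stack around that observation:

- **Fixation maps and DAS.** Recorded eye fixations are smoothed with an
  isotropic Gaussian (σ = one degree of visual angle) and max-normalized to
  an *attention score* in [0, 1]. The *difference in attention score*
  (DAS = color − gray) between a color stimulus and its grayscale
  counterpart isolates the contribution of color: content is identical, so
  positive DAS marks locations that attract gaze *because of* their color.
- **Salient colors.** CIELab is uniformly quantized to 16 levels per
  channel (4096 codes, `code = 256·L' + 16·a' + b'`); codes whose mean DAS
  exceeds 0.1 are a stimulus's salient colors, each carrying its mean DAS
  as an attention weight.
- **MIC channel ranking.** The maximal information coefficient
  MIC(x, y) = max I(x, y) / log₂ min(n_x, n_y) over grids with
  n_x·n_y < n^0.6 measures how strongly each normalized color channel
  associates with DAS. On the color/gray eye-tracking corpus this yields
  L: 0.61, a: 0.52, b: 0.76 (total 1.89), dominating RGB (1.35) and
  HSI (1.16) — so the analysis and the detector live in CIELab.
- **RNCw detection.** A region-contrast detector whose color distances
  weight the Lab channels by those associations,
  w = (0.61, 0.52, 0.76)/1.89 = (0.32, 0.28, 0.40):
  d_w(i,j) = √(w_L ΔL² + w_a Δa² + w_b Δb²) drives both the graph-based
  segmentation and the region contrast
  S(r_x) = Σ_{y≠x} exp(−D_s(r_x,r_y)/σ_s²) · w(r_y) · D_wr(r_x,r_y) with
  σ_s² = 0.4 on [0,1]-normalized centroids. A salient-color prior can
  re-weight any saliency map pixel-wise (floor 0.1 for unobserved colors).
- **Metrics.** MAE, S-measure and PR curves for salient-object detection;
  AUC-Judd, AUC-Borji, shuffled AUC, NSS, SIM, CC, KL, exact-LP EMD and
  information gain for fixation prediction.
- **Synthetic stimuli.** A seeded generator of paired color/gray scenes
  with planted salient colors and subject-level fixations, so the whole
  stack is testable without any eye-tracking data download.

## Worked example

```python
import numpy as np
from chromasal import (generate_scene, build_fixation_map, compute_das,
                       extract_salient_colors, top_salient_colors,
                       detect_saliency, apply_color_prior, metrics, synthetic)

# a paired color/gray stimulus with 18 subjects' fixations per condition
bundle = generate_scene(seed=0)
geom = synthetic.scene_geometry(bundle.spec)
shape = bundle.color_image.shape[:2]

map_color = build_fixation_map(bundle.fixations_color, shape, geom)
map_gray = build_fixation_map(bundle.fixations_gray, shape, geom)
das = compute_das(map_color, map_gray)

table = extract_salient_colors(das, bundle.color_image, threshold=0.1)
print("salient colors:", top_salient_colors(table, 3))

sal = detect_saliency(bundle.color_image)          # RNCw saliency map
print(f"MAE = {metrics.mae(sal, bundle.mask):.3f}")
print(f"S-measure = {metrics.s_measure(sal, bundle.mask):.3f}")

sal_prior = apply_color_prior(sal, bundle.color_image, table)
pts = bundle.fixations_color[["x", "y"]].to_numpy()
print(f"NSS = {metrics.nss(sal_prior, pts):.2f}")
```

prints

```
salient colors: [(2491, 0.23793694126120063), (2235, 0.22692831489611578), (2507, 0.22320668105344615)]
MAE = 0.034
S-measure = 0.735
NSS = 0.42
```

The three codes are quantized L'a'b' colors of the planted high-chroma
object; their weights are the mean attention surplus (DAS ≈ 0.22–0.24) the
color condition produced on them. The detector recovers the object almost
exactly (MAE 0.034 against the ground-truth mask, S-measure 0.735), and the
prior-weighted map scores the recorded fixations 0.42 standard deviations
above the map mean.

## Command line

```bash
chromasal synth --out data/ --n-scenes 20 --seed 0       # synthetic corpus
chromasal detect data/scene000_color.png -o sal.png      # RNCw detection
chromasal analyze-das --color-image ... --fixations ...  # DAS + color table
chromasal mic --x L --y das samples.csv                  # MIC of two columns
chromasal eval --task sod --sal maps/ --gt masks/ --out-csv res.csv
```

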