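# Methods

## The attention model

A fixation map for one stimulus pools all subjects' fixations, places an
isotropic Gaussian at each (σ equal to one degree of visual angle,
truncated at 4σ where the tail is below 4·10⁻⁴ of the peak), and divides by
the maximum, so the *attention score* of a pixel lies in [0, 1] and the
best-attended location scores exactly 1. Subjects are pooled before
normalization; fixation durations are not weighted. The default viewing
geometry is a 1680-px-wide display spanning 42.48° of visual angle
(≈ 39.5 px/degree); for synthetic scenes the image width is mapped onto the
same 42.48° so the smoothing scale tracks the synthetic resolution.

DAS (difference in attention score) is computed **color − gray**. The sign
convention matters: salient colors are defined as those *gaining* attention
in the color condition, so they must carry positive DAS and the 0.1
extraction threshold must select them. Per quantized color, DAS is
aggregated by the mean over that color's pixels — robust to how many pixels
a color covers — and colors with mean DAS > 0.1 form the salient-color
table, weight = mean DAS.

The color-block-combination statistic treats every 4-adjacent pixel pair
with distinct quantized codes as one observation of that unordered code
pair, scores it by the two pixels' mean DAS, and reports pairs whose
overall mean exceeds the threshold. This is one concrete reading of a
qualitative observation; no canonical algorithm exists for it.

## Color spaces and quantization

Lab conversion is CIE 1976 L\*a\*b\* under sRGB companding and D65 white
(scikit-image), the universal default for natural photographs. Grayscale is
Rec.601 luma (0.299 R + 0.587 G + 0.114 B), replicated to three channels.
HSI uses the classical geometric hue formula with I = (R+G+B)/3. Channel
normalization for the MIC analysis maps each channel's *theoretical* range
([0,100] for L, [−127,127] for a/b, etc.) affinely onto [0,1]; empirical
ranges would make the statistic dataset-dependent.

Quantization composes the two published fragments of the coding scheme:
each channel is first mapped to the 0–255 working scale (L' = 2.55 L,
a' = a + 127, b' = b + 127) and then floor-divided into 16 uniform bins,
values at the top of a range clipping into bin 15 (half-open bins, last bin
closed). The code is 256·L' + 16·a' + b' with the binned values, a
bijection onto 0..4095. Where Lab values must be reconstructed from codes
(region contrast, palette remapping), bin centers are used: this makes the
region-contrast double sum O(colors²) instead of O(pixels²).

## MIC

MIC(x, y) = max over grid shapes (n_x, n_y), n_x·n_y < n^0.6, of the
plug-in mutual information (base 2) normalized by log₂ min(n_x, n_y). Cut
points never separate tied values. Because n^0.6 < 4 for n ≤ 10 would
admit no grid at all, the 2×2 shape is always admitted.

Per shape, one axis's cut placements are enumerated exhaustively when the
combination count is at most 48 and mass-equipartitioned otherwise; the
other axis is then optimized exactly by dynamic programming over clump
boundaries (capped at 64 near-equal-mass superclumps), and both axis roles
are tried. Pure equipartition of one axis is *not* exact even for 2×2
grids — a 4-point counterexample exists where the optimal split is off the
median — and every grid shape admissible at n ≤ 16 is fully enumerable, so
the hybrid search is exact exactly where the brute-force oracle
(`exhaustive_mic`, n ≤ 20) can check it. The suite verifies equality on
100 seeded samples.

`channel_mic_profile` restricts to pixels with DAS > 0.1 (the salient-color
condition) and subsamples them (default 1000, seeded) before the grid
search, since MIC's grid enumeration grows superlinearly in n.

## RNCw

Segmentation is Felzenszwalb–Huttenlocher greedy merging over the pixel
grid (4-connected by default, 8 available) with edge weights equal to the
channel-weighted Lab distance; channel scaling by √w turns that distance
into plain Euclidean, so one edge sort drives the standard union-find
merge. Defaults k = 300, min_size = 50, pre-smoothing σ = 0.8 are the usual
values for this segmenter on ~400×300 natural images; undersized components
are absorbed across their cheapest boundary edge.

Region contrast: D_wr(r_x, r_y) is the frequency-weighted mean pairwise
channel-weighted distance between the two regions' quantized-color
histograms (after non-uniform palette reduction keeping the most frequent
codes covering 95% of pixels and remapping dropped codes to their nearest
kept color). Spatial weighting multiplies each term by
exp(−D_s/σ_s²), σ_s² = 0.4, with D_s the Euclidean distance between region
centroids in per-axis-normalized coordinates.

Two outer weightings of the summed contrast exist: by the *scored* region's
own pixel count, or only by the *other* regions' counts. Own-size weighting
makes the largest region — in practice the background — the most salient:
on a two-region scene the two scores are provably identical, and on pop-out
fixtures it inverts the map entirely. The full pipeline therefore defaults
to other-region weighting (`legacy_rc_weighting=True`); both forms are
implemented and unit-tested, and the low-level `region_saliency_*`
functions default to the own-size form so either convention is one flag
away. The final map is painted per region and min-max normalized to [0,1].

The color prior multiplies each pixel by its code's salient-color weight
(floor 0.1 for colors never observed to attract attention) and rescales so
the maximum equals the input map's maximum; a uniform table is therefore an
exact identity, and an all-zero map passes through unchanged.

## Metrics

AUC variants use Mann–Whitney counting with half credit for ties, which
makes a constant map score exactly 0.5. AUC-Borji draws 100 uniform
negative sets (seeded); shuffled AUC draws negatives from other stimuli's
fixations. NSS standardizes with the population standard deviation. KL uses
ε = 2.2204·10⁻¹⁶ in the direction KL(fixations ‖ saliency). EMD
mass-downsamples both maps (default 24×32 grid, mirroring the coarse map
resolution used in fixation-prediction practice), drops empty cells, and
solves the transport problem exactly as a linear program (HiGHS); ground
distance is Euclidean between cell centers in cell units. Information gain
is log₂(P + ε) − log₂(baseline + ε) averaged over fixations, uniform
baseline by default with a center-Gaussian alternative. S-measure follows
the published structure-measure definition (object term on
foreground/background statistics, region term as block-wise SSIM about the
mask centroid, α = 0.5, with the all-zero/all-one mask special cases).

## Synthetic stimuli

Each scene is a noisy Lab background plus geometric objects; one object
carries a planted high-chroma color. Fixations per condition are a mixture
of a center-biased Gaussian (σ = ¼ image width; share 0.35), uniform
scatter, and — in the color condition only — directed looks at
salient-color objects at (boost − 1) times their uniform chance rate.
Grayscale removes the pop-out cue, so no object is special in gray; this is
what concentrates positive DAS on the planted colors after
max-normalization. Defaults mirror the emulated study: 18 subjects, 50
fixations each, boost 5. All randomness flows through one seeded generator;
equal seeds give byte-identical bundles. The planted-color table lists
quantized codes covering ≥ 3 pixels of the salient object and absent
elsewhere in the scene.

The generator reproduces the *structure* of the color-attention effect, not
natural-image statistics: object colors are few and flat, background chroma
is near-neutral, and fixations have no saccade dynamics or subject
idiosyncrasy. Consequently the color-space MIC comparison run on synthetic
scenes does not reproduce the ordering measured on real stimuli (synthetic
Lab totals can fall below RGB), and passing tests certify the pipeline's
correctness and the recovery of planted structure — not performance on
natural images. Detector scores on synthetic fixtures (MAE ≈ 0.03,
S-measure ≈ 0.74) likewise characterize the fixtures, not any benchmark.

## Problem sizes and determinism

Tests and the acceptance script use scenes of 120×160 (fixtures 96×128 or
48×64), 8–20 seeded scenes per study, MIC subsamples of ≤ 800 and a 12×16
EMD grid; these sizes make the whole suite run in seconds while every
comparison against a brute-force oracle stays exact. Larger images and
grids only change runtime, not code paths. Every stochastic routine takes
an explicit seed; derived seeds stay below 2³¹.

## Known limitations

- The adjacency-pair reading of color-block combinations is one
  interpretation among several defensible ones.
- Whether the first (onset) fixation should be discarded is not modeled;
  all fixations count equally.
- MIC beyond the exhaustively checkable regime uses the
  equipartition/DP approximation standard in the MIC literature; it is a
  lower bound on the definitional maximum.
- Region spatial distance uses centroids; pixel-averaged distances would
  differ for concave regions.
- The detector's segmentation defaults (k, min_size, σ) are generic, not
  tuned per dataset.
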