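# Methods

This note documents the models, estimators and numerical choices behind
`vacuoquant`, what the synthetic-histology generator does and does not
emulate, and the design decisions taken where more than one reasonable
definition exists.

## Segmentation model

White vacuolar lesions are detected by a four-stage chain applied to 8-bit
RGB micrographs:

1. **Exclusion masking.** A binary mask (manual in real studies, generated
   with the synthetic vein here) marks white structures that are not
   lesions — sinuses, central veins. Excluded pixels are removed *before*
   histogram computation, not merely zeroed afterwards: a large white vein
   left in the histogram would drag the Otsu level upward and distort the
   threshold for the actual lesions.
2. **Contrast stretch.** Each channel is linearly rescaled so that its
   `[p, 1−p]` quantiles (default `p = 0.01`) map onto `[0, 255]`, clipping
   outside; a constant channel is passed through unchanged. This is the
   simplest "standardisation" consistent with heterogeneous acquisition;
   the rescale multiplies by 255 before dividing so half-integer results
   round predictably to nearest.
3. **Per-channel Otsu at a configurable fraction.** The Otsu level is
   computed on 256 bins, representing the cut between bins k and k+1 as the
   level k+0.5 and averaging all tied argmax cuts (so a half-zeros /
   half-255s channel thresholds at exactly 127.5). The working threshold is
   `otsu_scale × level` with default 0.5 — a deliberately permissive
   setting that keeps faint vacuoles in the foreground; `otsu_scale = 1`
   recovers plain Otsu. Foreground is `intensity ≥ threshold`. A constant
   (degenerate) channel contributes *no* foreground: a flat plane carries
   no white/non-white contrast, and this convention makes an all-black
   plane AND-fuse to an empty mask rather than to everything.
4. **Fusion and small-region removal.** Default fusion is AND across the
   three planes — "white" means bright in every channel; OR is available.
   Components (8-connected by default) with area < 10 px are removed:
   segmentation noise always produces such fragments and single pixels
   break several shape descriptors.

The chain is anti-extensive (each stage only removes foreground), and the
final mask never intersects the exclusion mask.

## Shape descriptors

Five measures per region; per image, the mean and sample SD (n−1) of each,
in the fixed order area, perimeter, MAL, eccentricity, circularity — ten
predictors total.

* **Area** — pixel count.
* **Perimeter** — chain-code length of the outer boundary traced through
  pixel centres (Moore-neighbour tracing; axial step 1, diagonal √2). The
  trace's deterministic state is (pixel, backtrack neighbour); the walk is
  followed until that state repeats and the cycle length is the perimeter,
  which handles spurs and one-pixel-wide necks (they are traversed twice,
  as a boundary-following pathologist's pen would). The estimator choice
  matters — circularity depends on P² — so it is recorded in the
  segmentation sidecar metadata. Chain code overestimates smooth oblique
  boundaries by up to ~8% (exact on axis-aligned and 45° edges), which is
  why rasterized disks score circularity ≈ 0.9, not 1.
* **MAL / eccentricity** — from the ellipse with the same normalized second
  central moments as the pixel set, with +1/12 added to each coordinate
  variance (a pixel treated as a unit square). The correction keeps
  single-file rows/columns at finite eccentricity (< 1), preserving the
  `[0, 1)` invariant.
* **Circularity** — `4πA/P²`, no small-size correction.
* Degenerate regions (a traced boundary of zero length, i.e. single
  pixels) raise an error; the <10 px filter keeps them out of the pipeline.
* Images with zero regions keep an all-zero, flagged predictor vector (so a
  32-image design stays 32 rows for VD-presence classification); one-region
  images get SD components of 0 with a flag. Zero-region images are
  excluded from pooled region-level estimators by construction (they
  contribute no regions).

Scale behaviour, tested: under nearest-neighbour pixel doubling the moment
measures scale homogeneously (area ×4 exactly, MAL ×2, eccentricity
stable), but the chain-code perimeter of a pixel-doubled shape inflates
~11% beyond ×2 because doubling staircases the boundary; perimeter
homogeneity (×2 within 10%) holds under *redigitization* of the same
continuous geometry at doubled scale, and that is what the test asserts.
Circularity is stable to ~0.1 across scales (the chain-code bias decays
only slowly with resolution).

## Group statistics

Pooled ("merged") estimators aggregate all regions across a group's images
— not per-image means — giving a groups × 10 table of mean/SD per measure.
Anderson–Darling normality (estimated mean and variance, small-sample
modification `A*² = A²(1 + 0.75/n + 2.25/n²)`, standard p approximation;
delegated to statsmodels, which implements exactly this) is used to judge
whether parametric modelling of the pooled distributions is defensible —
for log-normal-like lesion areas it decisively is not, motivating the
nonparametric comparison. Two-sample Kolmogorov–Smirnov
(`D = sup|F̂x − F̂y|`, asymptotic p with effective n = n_x·n_y/(n_x+n_y);
scipy) compares control vs each treatment for each of the five measures,
since no single measure is singled out a priori. No multiple-testing
correction is applied; outputs carry raw p-values and are labelled as such.

Power caveat: with Table-style calibrations the control and CEG area
distributions differ with a true KS distance of only ≈ 0.12, so rejection
at α = 0.05 needs roughly 800 pooled regions per side. A 6-image control
arm with ~50% lesion prevalence yields ~100 regions — far too few. The
distribution-test suite therefore runs on a lesion-dense dataset (~1600
regions for the heavy-tailed groups) where power is ample; on small
paper-shaped designs the control–CEG comparison should be expected to be
inconclusive.

## Linear classifier and exhaustive subset search

With 10 predictors there are 1023 non-empty subsets; each is scored
exhaustively. The classifier is the smallest-parameter linear
discriminant: pooled within-class covariance Fisher LDA with empirical
class priors. The covariance is regularized by `λ·trace(Σ)/p·I` with
`λ = 10⁻⁶` — invisible numerically when Σ is well-conditioned, but
guaranteeing solvability when p approaches the number of images; a
zero-trace covariance (all selected features constant) falls back to the
identity, reducing the rule to priors (majority class). Score ties resolve
to the class listed first in the scheme definition.

**Evaluation protocol.** Resubstitution accuracy is the default: with ~32
cases and up to 10 features, held-out protocols are so variable as to be
uninterpretable, and resubstitution is the only protocol under which a
3-predictor 100% result on such data is reproducible. Leave-one-out is
available (`eval_method="loocv"`) and always labelled distinctly.

**Schemes.** One-vs-rest (each group vs the merged remainder); common
predictors (one shared subset, scored by the *average* of the four
one-vs-rest accuracies — necessarily ≤ the best individual one); paired
(control vs each treatment separately, no merging); VD presence (all
images merged, zero-lesion images included with their flagged zero
vectors); control vs merged treatments (restricted to VD-positive images
— on a paper-shaped design that is ~24 rows). A scheme whose class would
have fewer than two rows is skipped with a warning rather than fitted.

**Reporting.** Results sort by (accuracy desc, subset size asc, bitmask
asc); *all* subsets tied at the maximal accuracy and minimal size are
listed (ties are common and meaningful at this sample size), along with
the Pareto front under (maximize accuracy, minimize predictor count) —
accuracies strictly increase along the front. Searches can be restricted
to the five means or five SDs, with excluded columns marked `-`.

## Synthetic histology: what it emulates, and what it does not

The generator stands in for unavailable micrographs. Each group's
`GroupProfile` holds: lesion count range per image (default 5–60 — real
counts per field are not documented, this is a field-plausible choice),
log-normal area parameters, axis-ratio (minor/major) mean and SD, boundary
roughness, and the probability that an image shows VD at all (defaults
0.50 / 0.90 / 0.75 / 0.66 for control/TMG/CMG/CEG; an image without VD
gets zero lesions). Area/axis defaults are calibrated to the pooled
region statistics of the motivating study's four arms (e.g. control mean
area 88.49 px², SD 231.74 px²; mean eccentricity ≈ 0.78 maps to axis ratio
√(1−e²) ≈ 0.62, with the spread propagated by the delta method).

Key numerical choices:

* **Truncated moment matching.** Areas are log-normal, but the <10 px
  filter would censor the left tail downstream and (for control/CEG, whose
  SD is ~2.6× the mean) bias the *measured* pooled mean upward by >20%.
  The sampler therefore solves for log-normal parameters whose
  left-truncation at 12 px² has exactly the target mean/SD (closed-form
  truncated moments + root-finding, falling back to plain moment matching
  if the solve fails), and draws from that truncated law. Measured pooled
  means then recover the profile targets through the full pipeline with no
  detectable pipeline bias (<0.1% against planted rasterized truth).
* **Geometry.** Lesions are ellipses (optionally roughened by a few
  bounded radial harmonics), rasterized by a pixel-centre-inside test;
  placement is rejection sampling with a circumscribed-circle overlap test,
  3 px gaps, and a 1000-retry bound per lesion. Default canvas is
  964×1286 — half the nominal acquisition size, for speed; full size is a
  config away.
* **Palette.** Background ≈ (228, 75, 160), nuclei ≈ (70, 40, 90), lesions
  and vein at 250 on all channels, independent per-channel Gaussian noise
  (SD 8). The palette is cosmetic — descriptor truth lives in the planted
  geometry — but it is *chosen so the default segmentation is sound*: the
  green channel separates tissue from white with a ≥3σ margin below the
  half-Otsu threshold after the contrast stretch, while red/blue stay pink;
  background pixels that pass one channel's threshold by noise are removed
  by AND fusion (channel noise is independent) and the <10 px filter.
* **Speckles.** Sparse bright speckles (1–5 px) are stamped on a coarse
  grid with spacing that makes ≥10 px coalescence geometrically impossible
  and keeps them clear of lesions and vein. They play the role of the
  white noise objects that motivate the small-region filter, and they
  anchor the upper contrast quantile even in images with few lesions.
* **Vein / exclusion mask.** One large white elliptical "central vein" per
  image (when enabled), placed clear of lesions, with the exclusion mask
  its 3 px dilation — so mask coverage of the vein is guaranteed, and
  ignoring the mask yields exactly one extra large component.
* **Seeding.** A master seed fans out per image through
  `SeedSequence([master, group_index, image_index])`, so datasets are byte
  reproducible and adding images or groups never perturbs existing ones.

Not emulated: staining chemistry and its artifacts, lipid vs hydropic
vacuole subtypes, intensity texture within lesions, vignetting, spatially
correlated noise, or touching/overlapping vacuoles. Passing tests
demonstrate that the *pipeline* measures what was planted under controlled
appearance; they cannot certify segmentation accuracy on real slides,
where boundary contrast and exclusion-mask quality dominate.

## Problem sizes used by the test suite and benchmark script

The suite runs the full default 32-image design (6/10/9/7 images at
964×1286) once for structural checks; calibration-recovery and
distribution tests use dedicated lesion-dense datasets (~1600 regions per
heavy-tailed group at 720×720); the paired-separability benchmark uses 10
+ 10 images at 512×512 with control/treatment mean areas 88.5 vs 1200 px²
(mean MAL separations of tens of pooled SDs, comfortably past linear
separability). These sizes were picked so every statistical assertion has
comfortable power at its stated tolerance.

## Known limitations

* Resubstitution accuracy is optimistic by construction; it is reported
  because it is the protocol appropriate to the tiny-sample exhaustive
  search design, not as a generalization estimate.
* The chain-code perimeter is one of several legitimate estimators;
  circularity values are comparable only within a fixed estimator.
* Asymptotic KS p-values are used throughout (region counts are large);
  exact small-sample p-values are not implemented.
* The heavy-tailed control/CEG area profiles make small-sample pooled
  means noisy; comparisons on paper-sized designs should lean on the
  classifier search or on larger synthetic designs.
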