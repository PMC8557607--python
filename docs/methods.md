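# Methods

`stromascore` implements a fully automatic pipeline that turns a pair of
CD3- and CD8-stained immunohistochemistry (IHC) whole-slide images into a
prognostic *stroma-immune score*, and an evaluation battery that measures
that score's association with overall survival. Because no patient data
ship with the package, every stage is exercised end-to-end on synthetic
slides and cohorts with known ground truth; this note records the models,
the defaults, and what the synthetic conditions do and do not show.

## Tissue segmentation

A slide at 20× working magnification (0.5 µm/px; 40× sources are
downscaled ×2) is covered with 224×224 px tiles on an overlapped grid with
a 75 px overlap border, i.e. stride 149. Regular anchors sit at multiples
of the stride; if the last regular tile leaves uncovered pixels, one extra
anchor per axis is snapped to `dim − 224`, so every pixel is covered and
no synthetic padding is ever classified. Each tile is assigned the tissue
class of maximum probability among nine colorectal classes (tumor
epithelium, stroma, adipose, background, debris, lymphocytes, mucus,
smooth muscle, normal mucosa; indices 0–8 in that order). Per-pixel labels
are the majority vote among covering tiles; vote ties go to the covering
tile whose anchor is earliest in row-major order, which makes the label
image independent of processing order.

A known limitation of hard tile voting: when a region boundary crosses a
tile's interior, that tile's single label is applied to the whole tile
footprint, so one overlap band (up to 75 px) along the boundary can be
systematically misattributed. When boundaries fall on tile edges the vote
plus tie-break recovers region areas essentially exactly, and the test
suite pins that case.

The tumor–stroma ratio (TSR) is stroma area over stroma-plus-epithelium
area on the label image; ≥ 0.5 is called stroma-high. By default the TSR
is taken from the CD3 slide's map (one TSR per patient; the choice of
slide is a package convention, flag-controlled).

## Tile classifier

The two-stage training topology is the method: a network is trained from
random initialization on one tile corpus (*pretrain*), then training
continues on a second corpus with a small fixed learning rate
(*fine-tune*: SGD with momentum 0.9, learning rate 3·10⁻⁴, mini-batch 64,
10 epochs). The architecture is pluggable; the default desk-scale model is
a one-hidden-layer (64-unit) MLP over a 16×16 RGB downsample of the tile
concatenated with per-channel standard deviations and mean gradient
magnitudes — texture statistics that survive downsampling — with a
standardization layer frozen at pretrain time. Pretrain defaults are 80
epochs at learning rate 0.01 (the pretrain optimizer is otherwise
unspecified by the recipe and config-exposed). Seeded training is
bit-reproducible on CPU; all shuffling derives from `SeedSequence`
substreams.

Evaluation reports accuracy with an exact (Clopper–Pearson) binomial 95%
CI and a 9×9 confusion matrix (rows = truth). Argmax ties resolve to the
lowest class index.

## Positive-cell quantification

Brown (DAB) chromogen is isolated by Ruifrok–Johnston color
deconvolution. Optical density per 8-bit channel is
`OD = −log10((I+1)/256)` (the +1 keeps black pixels finite); the OD vector
is expressed in the H-DAB basis — hematoxylin (0.650, 0.704, 0.286), DAB
(0.268, 0.570, 0.776), residual = their unit cross product — and the DAB
coefficient, clipped at zero, is the detection channel.

Detection inside an ROI mask: threshold the DAB channel at OD ≥ 0.15,
fill holes, drop connected components below 30 px, watershed-split
components above 1500 px on the distance transform (seeds = local maxima
≥ 5 px apart), and count components. The size window brackets a
lymphocyte footprint (7–10 µm diameter ≈ 150–300 px at 0.5 µm/px) with
generous slack; all four knobs are config-exposed
(`CellDetectionParams`). Density is count over ROI area, in cells/mm²,
with area = ROI pixels × mpp² / 10⁶.

## Stroma-immune score

Per patient, the CD3 and CD8 stromal densities are each converted to a
percentile of the *development group's* density distribution using the
mid-rank empirical CDF: `100·(#below + 0.5·#equal)/n`, clamped to
[0, 100]. The stroma-immune score is the mean of the two percentiles.
Two thresholds split the development scores into three near-equal groups
(quantile grouping in the style of Hmisc's `cut2`: the k-th threshold is
the smallest score of the k-th upper group, sorted index ⌊k·n/3⌋; ties
advance the upper threshold to the next distinct value). Scores at a
threshold join the upper group. The two-level score collapses
intermediate+high into high. References and thresholds are derived once
on the development cohort and frozen; validation cohorts are always
mapped through the stored artifacts. The intraepithelial-immune score is
the identical computation with the tumor-epithelium ROI and its own
reference and thresholds.

## Survival evaluation

Cohort tables use months and a binary death indicator. The battery:

- **Kaplan–Meier** product-limit curves per score category, with
  Greenwood log–log confidence intervals (lifelines); the 5-year rate is
  the step function evaluated at 60 months.
- **Log-rank** tests across categories (df = groups − 1).
- **Cox proportional hazards** by partial-likelihood maximization
  (statsmodels PHReg), Efron tie correction by default and Breslow by
  flag, in unadjusted and multivariable forms with optional
  stratification; categorical covariates are dummy-coded against their
  first level. Categories are coded with "low" as reference, so a
  protective high score shows a hazard ratio below 1. Non-convergence and
  monotone likelihood (non-finite or exploding estimates) raise an
  explicit diagnostic rather than returning numbers.
- **Harrell's C-index**, authored in-package: a pair is usable when the
  order of failures is identifiable under censoring (earlier time is an
  event, or equal times with exactly one event); higher risk predicting
  the earlier failure is concordant, risk ties count ½. Equal-time
  equal-status pairs are excluded.
- **Bootstrap C comparison**: B resamples with replacement (default
  1000); each candidate Cox model is refitted per resample and its
  apparent C recorded; two-sided p-values come from the empirical
  distribution of C differences with a (1+k)/(B+1) correction, Bonferroni
  adjusted across pairs. Resamples with no events, or whose refit is
  degenerate, are redrawn (at most 10 retries) — this only matters for
  very small cohorts. B < 100 is rejected.
- **Baseline tables**: Kruskal–Wallis for numeric variables, uncorrected
  Pearson chi-square for categoricals (the classic formula; no Yates
  correction), with Bonferroni-adjusted p-values across variables.

## Synthetic data

The generators define the study conditions; they emulate the *inputs* of
the pipeline, not histology.

- **Tiles.** Each class is a base color plus a class-specific texture
  (nuclei disks, fibrous sinusoid streaks, septa rings, stripes, glands,
  speckle). Colors are hematoxylin-counterstain blue-gray/lavender tints
  chosen so bare tissue projects near zero onto the DAB vector — only
  chromogen should light the detection channel. Training tiles for the
  T-cell-bearing classes (stroma, lymphocytes, tumor epithelium) carry a
  zero-inflated random load of brown disks, as stained tissue would; the
  load range brackets the planted slide densities. The study-condition
  corpus is 80 tiles/class at 224 px.
- **Slides.** A region layout (rectangles or polygons, rasterized by the
  pixel-center rule, later regions overwriting earlier, uncovered canvas
  = background) is rendered chromogen-free with the same class recipes,
  then listed cells are drawn as brown disks whose OD profile lies along
  the DAB vector (center OD 0.75–1.05, falling toward the rim, ±4 RGB
  jitter). Planted disks must be pairwise disjoint and inside their
  declared region, so the planted list is exact ground truth for counts
  and the layout is exact ground truth for the label mask. Default cell
  radius 7 px ≈ 7 µm at 0.5 µm/px. Density scales are set so stromal CD3
  ≈ 1304 and CD8 ≈ 472 cells/mm², the magnitudes the score operates on.
- **Cohorts.** Patient score z ~ N(0,1); event times are exponential with
  hazard `λ₀·exp(β·z + covariate effects)` (λ₀ = ln2/60 per month, median
  survival 60 months). Censoring is independent uniform administrative
  censoring on [0, T_max], with T_max solved numerically so the expected
  censored fraction equals the requested rate (default 0.25);
  `censor_rate` 0 and 1 are handled as the exact corner cases.
- **Studies on disk.** `generate_study` writes per-patient CD3/CD8 slide
  pairs (560×560 px, mpp 0.5; the stroma band is kept wider than one
  224 px tile) plus a cohort CSV whose hazard depends on the same latent
  immune level that sets the correlated CD3/CD8 planted densities
  (log-normal around the scales above), default β = ln 0.4 per SD.

All randomness flows from one seed through named `SeedSequence` spawn
keys, so any individual tile, slide, or patient is independently
reproducible and whole runs are bit-identical under a fixed master seed.

What passing tests show: the pipeline recovers planted counts, areas,
densities, known hazard ratios, and calibrated type-I error rates under
these synthetic conditions. What they do not show: robustness to scanner
and stain variation, tissue morphology the texture recipes do not model,
touching or out-of-focus cells, or the tile-classification difficulty of
real histology. Cohort-specific clinical values (survival rates, hazard
ratios, C-indices, derived category thresholds) depend on the patient
population at hand; the synthetic conditions make no claim about any real
cohort.

## Problem sizes and numerics

The default test/evaluation scales were chosen as the smallest that
exercise every code path with stable statistics: 80 tiles/class corpora;
slides of 500–1400 px; 20-slide count-recovery batches; 200-replicate
null calibrations; hazard-ratio recovery at n = 800 with 100 replicates
and B = 200 bootstrap; one 30 + 12-patient end-to-end study. Tolerances:
probability vectors sum to 1 ± 1e-6; Cox estimates match a brute-force
partial-likelihood optimizer to 1e-6 on toys; planted-count recovery is
within 5% and planted-density recovery within 5% at fixture scale.
Degenerate inputs (empty ROIs, all-censored cohorts, constant covariates,
single-value references) raise explicit errors rather than propagating
NaNs; a patient whose map contains no stroma on either stain is flagged
unscorable rather than scored zero.
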