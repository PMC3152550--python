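# Methods

`ldscreen` re-creates, as a tested pipeline with synthetic ground truth, a
classic high-content screen for lipid-droplet (LD) biogenesis: adherent cells
are depleted of droplets in delipidated serum, loaded with oleic acid, stained
with a DNA dye (nuclei channel) and a neutral-lipid dye (droplet channel), and
imaged per well. The primary readout is the mean number of LDs per cell; the
number of nuclei per field serves as a cytotoxicity surrogate; the
background-corrected integrated cytoplasmic intensity per cell quantifies
fluorescent fatty-acid uptake.

## Simulator (`ldscreen.synth`)

Each field is rendered on a 16-bit grayscale canvas:

- **Nuclei** are Gaussian-shaded ellipses (mean radius 12 px, ±2 px jitter,
  random orientation), peak 3000 grayscale units. Centres are placed by
  rejection sampling with a minimum pairwise distance (default 2.2× the
  nucleus radius); exceeding the bounded retry budget raises a capacity error
  rather than forcing overlaps.
- **Cytoplasm territories** are nearest-centre (Voronoi) regions clipped at
  the cytoplasm radius; a nucleus always belongs to its own territory even
  where it pokes past the bisector of a close neighbour. Territories are
  disjoint by construction.
- **LD counts per cell are Poisson(λ)** with λ set by the treatment. The
  source assay reports means and left/right shifts of the per-cell count
  distribution but no distributional form; Poisson is the minimal counting
  model and is exposed per treatment in `ScenarioConfig`.
- **Droplets** are Gaussian spots whose FWHM is drawn uniformly from the
  configured diameter range (default 3–8 px) with ±20% peak jitter (default
  peak 600). Spots are placed on territory pixels that keep a margin
  (default 2 px) from the nucleus edge and from the territory bisector, with
  a minimum centre-to-centre separation (default 8 px) inside each cell. If a
  cell is too crowded to honour the separation it is halved and then dropped
  before a capacity error is raised; this keeps extreme treatments (e.g. a
  3× rate increaser) renderable at the cost of more spot blending, which is
  exactly how such wells would look under the microscope.
- **Optics and camera**: constant background (100), a single Gaussian PSF
  (σ = 1 px), additive Gaussian read noise (SD 20), rounding and clipping to
  `uint16`. Default spot peak / noise SD = 30, far above the SNR ≥ 5 regime
  the detector is validated at. Z-stacks are not simulated; the rendered
  droplet image stands for the already-collapsed stack (the projection
  operator itself lives in the segmentation module).

All randomness flows from one seed through `numpy.random.SeedSequence`
substreams (per well, per field), so equal seeds give bit-identical images
and truth. The truth records every nucleus, territory, droplet position and
per-cell count.

**Calibrated regimes.** The shipped scenarios anchor two rates: delipidated
cells at λ = 3.5 (the "<5 LDs per cell" baseline) and oleic-loaded cells at
λ = 35 (the ~10-fold increase). The triacsin-C ladder scales the loaded rate
by 1, 0.8, 0.5, 0.2, 0.05 over 0–3 µM; the heterofibrin-like inhibitor ladder
uses scales 0.97, 0.85, 0.65, 0.46, 0.30 over 1–50 µM, whose 20 µM point
corresponds to ~60% inhibition against the loaded/delipidated window.
Cytotoxicity is binomial thinning of the nominal cell number by a per-
treatment survival fraction. The fatty-acid uptake time course is
I(t) = I_max·(1 − e^(−t/τ)) with defaults I_max = 100, τ = 10/3 min, i.e. a
95% plateau at 10 min.

**Imaging scales.** Two field configurations are used. The compact scale
(512×512 px, 30 cells, cytoplasm radius 40 px) matches moderate rates
(λ ≲ 20) and is the default. At the loaded rate and above, ~4.5k px² of
cytoplasm per cell cannot hold 35+ resolvable spots, so experiments that
image loaded cells — the regime and fold-change checks, the dose ladders and
the screening plate — use a spread-cell scale (cytoplasm radius 60 px;
plates use 320×320 px fields with 6 nominal cells each). This mirrors the
real assay, where magnification and cell density are chosen so droplets
remain countable; it is an imaging choice, not a change of the treatment
rates. Plate fields of 320² with one field per well keep a 96-well,
20-plate experiment within minutes on one CPU.

## Segmentation (`ldscreen.segment`)

The chain mirrors a standard CellProfiler-style pipeline; the original
pipeline's module settings are not published in the main text, so every
threshold and gate here is a configurable, stated default:

1. **Stack collapse**: per-pixel maximum projection.
2. **Nuclei**: light Gaussian smoothing (σ = 2), global Otsu threshold (or a
   fixed value) with a contrast guard — the threshold must clear the image
   median by 3 robust SDs, otherwise the image is declared blank (Otsu would
   happily bisect pure noise). Holes filled, optional declumping by watershed
   on the distance transform with peaks at least 10 px apart (≈ the nucleus
   radius: far enough apart not to split a jittered ellipse, close enough to
   separate 30%-overlapping pairs), area gate 80–2000 px², border-touching
   nuclei excluded by default.
3. **Cytoplasm**: distance-limited nearest-nucleus expansion (Euclidean
   distance transform with index return), clipped at the cytoplasm radius
   (default 40 px). Ties fall on the equidistant boundary pixel-by-pixel.
4. **Droplets** (default detector): white top-hat with a disk of the maximum
   LD radius, robust threshold median + k·MAD (k = 5, MAD scaled ×1.4826),
   with a floor of 10% of the top-hat maximum so near-noiseless images do
   not threshold at zero. Touching spots are split by a marker watershed
   seeded at local maxima (minimum distance = the minimum LD diameter).
   Diameter gates are applied to the thresholded support with factors
   0.5/2.0 around the nominal 3–10 px range, because the support of a
   PSF-blurred Gaussian spot is wider than its FWHM. A multiscale
   Laplacian-of-Gaussian detector is available as an alternative
   (`ld_detector="log"`), thresholded at 0.5·k·σ_robust on the
   scale-normalized response.
5. **Assignment**: each spot goes to the territory containing its rounded
   centroid; spots on background are reported as unassigned. Every spot is
   counted exactly once.

On noiseless, well-separated scenes the chain recovers nuclei counts and
per-cell LD counts exactly; at the validated SNR and separation regime the
pooled mean LDs/cell stays within a few percent of truth (test suite and
acceptance script re-measure both).

## Quantification (`ldscreen.quantify`)

Per cell: LD count, cytoplasm area, and integrated cytoplasmic intensity
(sum of pixel − background over the territory, clipped at zero; background
is the per-image median — the territory sum, not each pixel, is clipped, so
symmetric noise does not bias the estimate). Per well: cells are pooled
across fields at the cell level (a well-level value weighs each cell
equally; the source assay reports one value per well), nuclei per field =
total cells / number of fields, and the LD-count histogram uses unit bins
with an open-ended top bin (default cap 80). An empty well yields an
explicit NaN mean, never a silent zero. The distribution-shift statistic is
mean(B) − mean(A) on a shared bin grid (positive = right shift); it is exact
under translation and degrades gracefully for mass above the cap.

## Screen analytics (`ldscreen.screen`)

- **Duplicate averaging**: arithmetic mean of each metric over replicate
  wells (NaN-skipping; all-NaN stays NaN).
- **Normal range**: mean ± k·SD over the duplicate-averaged extract values
  of the plate, k = 1 by default (the source rule states "±SD" without a
  multiplier), population SD by default (ddof configurable; immaterial at
  42 extracts but pinned for reproducibility). Controls are excluded from
  the range: they are intentionally extreme.
- **Hit calling**: LD increase above the upper bound, LD decrease below the
  lower; cytotoxicity only below the lower nuclei bound (loss of cells —
  elevated nuclei counts are not "toxic"). Flags are independent;
  cytotoxic/LD-shift overlap is reported as a co-occurrence table, not
  inferred away.
- **Hit rate**: whole-number percentage, rounded half away from zero.
- **Percent inhibition**: 100·(1 − (treated − baseline)/(loaded − baseline))
  with loaded (oleic) as positive control and delipidated as baseline; affine
  invariant in the three inputs.
- **Dose–response**: per-concentration means ± SD, Spearman rank correlation
  of mean response vs concentration as the monotone-trend statistic (flagged
  undefined for constant responses), optional 4-parameter logistic whose
  midpoint is only reported when the fit converges and the midpoint lies
  within the dosed range.
- **Uptake kinetics**: least-squares fit of I(t) = I_max·(1 − e^(−t/τ));
  plateau time reported as 3τ (95% of I_max). Degenerate input or
  non-convergence returns an explicit failure result with NaN parameters.
- **QC**: Z′ = 1 − 3(σ₊ + σ₋)/|μ₊ − μ₋| between the triacsin-C (inhibited)
  and inactive-extract (loaded) control wells, plus the window μ₋/μ₊; equal
  means give an undefined, flagged record.

## What the synthetic data does and does not show

The generator reproduces the features the analysis chain depends on: two
channels, Poisson per-cell counts with treatment-dependent rates, binomial
cell loss, PSF blur, read noise and plate structure with on-plate controls.
It does not model uneven illumination, photobleaching, cell-shape
heterogeneity beyond radius jitter, 3-D droplet stacking, focus drift or
debris. Passing tests therefore demonstrate that the measurement and
hit-calling chain is correct and well-calibrated under the stated imaging
model — not that any specific biological sample would be segmented this
accurately.

## Problem sizes and numerical choices

Validation experiments use: 20 fields (30 cells, λ = 20) for count recovery;
20 seeds × (delipidated + loaded) fields for the regime check; 20 seeds × 5
doses for the ladder; 20 full 96-well plates (42 extracts in duplicate, 6 + 6
control wells, planted 3× increaser, two 0.4× decreasers, two survival-0.3
cytotoxics) for the screen; 20 noisy series (2% of I_max) for kinetics.
These sizes are the package's desk-scale choice and are printed in the
acceptance output as `n`. Coordinates are 0-based (row, col) pixel centres;
areas in px²; concentrations in µM unless a layout states otherwise. Fits
use `scipy.optimize.curve_fit` with positivity bounds and data-driven
starting values; ties in spot assignment go to the territory labelled at the
centroid pixel.

## Known limitations

- At rates far above the resolvable packing of a territory the measured
  count saturates sublinearly; strong increasers are still flagged (the
  measured value remains far above the plate range) but their absolute
  LDs/cell is an underestimate. This matches the physics of any 2-D
  spot-counting assay.
- The plate rule is a per-plate range rule by design: no multi-plate
  batch correction (B-score/median polish) and no FDR machinery.
- The 4PL midpoint has no confidence interval; the trend statistic is the
  inferential summary.
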