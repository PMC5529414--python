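# Methods

`conedetect` implements patch-classification-based detection of cone
photoreceptors in adaptive-optics scanning light ophthalmoscope (AOSLO)
images. This note records the model, the numerical choices, and what the
synthetic fixtures do and do not establish.

## Detection model

Cone detection is cast as per-pixel binary classification. A small
convolutional network maps a 33×33 intensity patch to P(cone at the central
pixel). Applied to the patch around every pixel of an image (mirror-padded
by 16 px at the borders, duplicating the edge pixel — half-sample symmetric
reflection), this yields a probability map the size of the image. Cones are
then localized by:

1. Gaussian smoothing with standard deviation σ (reflective boundary,
   kernel truncated at 4σ; σ = 0 is the identity);
2. the extended-maxima transform with height H: regional maxima of the
   H-maxima transform, i.e. of the morphological reconstruction by dilation
   of (map − H) under the map, with 8-connectivity throughout (the MATLAB
   `imextendedmax` convention; H = 0 reduces to plain regional maxima, and a
   constant map is one maximal region covering everything);
3. labeling the 8-connected clusters of the binary mask, removing clusters
   whose maximum smoothed probability is below a threshold T, and reporting
   the unweighted pixel centroid of each surviving cluster (fractional
   coordinates). A probability-weighted centroid is available as an option
   but is not the default, which follows the simplest reading of cluster
   "centers".

Regional maxima are computed by flood-filling "dominated" status through
equal-valued plateaus (iterated masked maximum filter) rather than by
scikit-image's `local_maxima`, because the latter returns no maxima for a
globally constant image while the convention adopted here (and verified
against a brute-force plateau-BFS oracle in the tests) marks the whole image.

## Network and training

Layer stack (activation sizes as height × width × channels):
conv 5×5×1→32 (pad 2) → batch-norm → max-pool 3×3/2 → ReLU → 16×16×32 →
conv 5×5×32→32 (pad 2) → batch-norm → ReLU → avg-pool 3×3/2 → 8×8×32 →
conv 5×5×32→64 (pad 2) → batch-norm → ReLU → avg-pool 3×3/2 → 4×4×64 →
FC 1024→64 → batch-norm → ReLU → FC 64→2 → soft-max. Class index 0 is
non-cone, 1 is cone.

Pooling uses 3×3 windows with stride 2. 33→16 needs no padding; 16→8 and
8→4 use one zero pad row/column at the bottom/right, and average pooling
divides by the full window size (9) including padded zeros. Convolutions are
zero-padded by 2 so they preserve spatial size; these choices reproduce the
published activation-size chain, which is the authoritative contract (the
original description omits padding details).

Training is plain mini-batch SGD: batches of 100 drawn by per-epoch
shuffling, weight learning rate 1e-3 (1e-4 for the final fully-connected
layer), bias learning rate 0.1 (0.01 final layer), both dropped ×10 entering
epochs 31 and 41 of the 45-epoch full schedule, weight decay 1e-4 on
convolution/FC weights. Decisions where the source toolbox's defaults had to
be read in: momentum 0.9 (configurable, 0 gives the strict plain-SGD
reading); Gaussian weight initialization with std 0.01 and zero biases;
batch-norm ε = 1e-5 with running statistics by exponential moving average
(momentum 0.1) frozen at inference; no weight decay on batch-norm
parameters; class imbalance (~1 cone : 2.5 non-cone) left unreweighted;
patches enter the network on the 0–255 normalized scale without further
standardization. Reduced-epoch runs place the two learning-rate drops at the
same relative positions (31/45, 41/45) of the shortened schedule.

Everything is NumPy: convolutions are evaluated channels-last as one BLAS
matrix product per kernel tap accumulated in place, and at inference each
batch-norm layer is folded into the preceding linear layer (exact algebra,
verified against the unfused path to <1e-6). This keeps per-pixel inference
at ~15 s per 150×150 image on one CPU core and makes training bit-reproducible
single-threaded.

## Training-set construction

Images are min–max stretched to [0, 255] (a constant image maps to zeros).
Cone patches are extracted at every manual mark rounded to the nearest pixel;
patches crossing the image border are excluded. Non-cone patches come from
the Voronoi diagram of the manual marks: one point per Voronoi edge, uniform
along the clipped segment's arc length, rounded to the nearest pixel.
Unbounded ridges are clipped at the image rectangle and kept if the clipped
part has positive length; edges shorter than 1 px contribute their midpoint;
rounded duplicates are deduplicated (identical patches add no information).

## Parameter selection

(σ, H, T) are selected by exhaustive grid search maximizing the mean
per-image Dice coefficient on training images, using their precomputed
probability maps (CNN inference dominates the cost; smoothing/maxima/
thresholding are cheap, so the grid can be dense). Default grid:
σ ∈ {0, 0.1, …, 3.0}, H ∈ {0, 0.05, …, 0.5}, T ∈ {0.1, 0.2, …, 0.9} —
steps chosen so the published optima (1.3, 0, 0.3), (2, 0.1, 0.5) and
(0.4, 0.25, 0.9) are exact grid points. Ties break to the smallest σ, then
smallest H, then largest T (the most conservative filter among equivalent
optima); the original grid ranges are unpublished, so these defaults are a
design choice, not a reconstruction.

## Validation metrics

Matching radius d = 0.75 × the median nearest-neighbor distance among the
manual cones of the image ("median spacing" is not defined in the original
description; median NN distance is the standard mosaic spacing statistic).
Both point sets are pruned of cones within 7 px of the image edges, then
candidate pairs with distance ≤ d are accepted greedily in ascending
distance order, one-to-one (ties break on the lower manual index). This
operationalizes the per-cone "closest automatic cone wins" rule and agrees
with a maximum-cardinality assignment oracle on small random instances.
TPR = TP/manual, FDR = FP/automatic, Dice = 2·TP/(manual + automatic);
a rate with zero denominator is reported as undefined, never as 0.

Cone density is count / full ROI area (mm², from the microns-per-pixel
scale). By default the count is *not* border-pruned: pruning 7 px of a
150×150 image removes ~17% of cones while the area stays fixed, which would
bias density systematically; pruning remains available as an option.
Bland–Altman agreement uses the mean of per-image density differences and
mean ± 1.96 × sample SD (n−1) as 95% limits.

## Synthetic fixtures

`conedetect.synthetic` plants cones on a triangular lattice (lattice
constant 14 px, Gaussian jitter SD 0.9 px, 12% dropout) in a 150×150 image
— about 100 cones per mosaic, matching the ROI sizing convention of real
datasets. Confocal rendering: Gaussian blobs (σ ≈ 2.8 px, amplitude 1.0 ±
0.15) on background 0.15; split-detector rendering: horizontal
derivative-of-Gaussian dipoles (bright left / dark right lobe) on mid-gray
0.5. Both add a low-frequency background field (smoothed noise, amplitude
0.08) and white Gaussian noise (SD 0.06); the scale defaults to
0.45 µm/px. These values were fixed once as a realistic desk-scale model of
parafoveal mosaics and are not fitted to any test outcome.

The generator reproduces blob/dipole appearance, quasi-hexagonal geometry,
photometric variability and additive noise. It does **not** model AOSLO
optics (PSF, scanning distortion, speckle), rods, vasculature shadows,
pathology, or inter-grader ambiguity of manual marks. Passing the
synthetic end-to-end checks therefore demonstrates that the pipeline's
machinery (patch sampling, training, inference, post-processing, tuning,
metrics) is correct and self-consistent — not that the reported real-data
performance transfers; full-scale replication requires the original image
sets.

## Problem sizes

The standard fixture suite is 20 training + 10 held-out mosaics per
modality. Reduced-scale end-to-end runs (tests and the acceptance script)
train for 8 epochs (training accuracy saturates by epoch 4 on these
fixtures), tune on the probability maps of 3 training images, and evaluate
all 10 held-out mosaics per modality. These sizes are the package's chosen
desk-scale defaults; full-scale training (45 epochs, hundreds of images) is
exposed through the same configuration objects.

## Known limitations

* Per-pixel inference is exact but O(pixels × network); large batches of
  big images are slow on one core.
* Greedy matching can in principle differ from a maximum-cardinality
  matching on adversarial configurations (it is verified equal on random
  instances typical of detection output).
* The probability-weighted-centroid and Voronoi-neighbor-spacing options
  exist because the original descriptions are ambiguous on these points;
  defaults follow the simplest readings.
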