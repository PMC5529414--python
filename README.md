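# conedetect

Automatic detection of cone photoreceptors in adaptive-optics scanning
light ophthalmoscope (AOSLO) images with a small convolutional neural
network.

Quantifying the cone mosaic (spacing, density, regularity) requires the
position of every cone in an image, and manual grading is slow and
subjective. `conedetect` trains a patch classifier from manually marked
images of *any* AOSLO modality — confocal (cones are bright blobs) or
non-confocal split detector (cones are bright/dark dipoles) — and then
detects cones in unseen images with no modality-specific rules. The package
is aimed at researchers analyzing photoreceptor mosaics who want a
trainable, fully reproducible detection pipeline plus the standard
evaluation metrics.

## Method

**Training.** Images are min–max normalized to [0, 255]. 33×33 patches
centered on every manual cone mark form the cone class; the non-cone class
is sampled automatically from the Voronoi diagram of the marks (one random
point per Voronoi edge — the locus equidistant between neighboring cones).
A 17-layer CNN (three 5×5 convolution blocks with batch-norm and 3×3/2
pooling, then two fully-connected layers and a soft-max; ~144k parameters)
is trained by mini-batch SGD (batch 100, weight/bias learning rates
10⁻³/10⁻¹, ×0.1 drops late in the schedule, weight decay 10⁻⁴).

**Detection.** For a new image, the patch around every pixel is classified
(mirror padding at borders), giving a probability map p(x, y). The map is
smoothed with a Gaussian of width σ, the extended-maxima transform with
height H extracts significant peaks, clusters whose maximum probability is
below T are discarded, and each remaining cluster's centroid is a cone.
(σ, H, T) are selected automatically by maximizing the mean Dice
coefficient over the training images on a dense grid.

**Evaluation.** Automatic cones are matched one-to-one to manual cones
within d = 0.75 × median nearest-neighbor spacing (closest match wins, 7-px
border excluded); true-positive rate, false-discovery rate, Dice
coefficient, cone density (cones/mm²) and Bland–Altman limits of agreement
are reported per image. The CNN itself is implemented in NumPy (BLAS-backed
convolutions), so results are bit-reproducible on a single thread.

A synthetic mosaic generator (jittered hexagonal lattices rendered in
either modality, with noise and background drift) provides ground-truth
data so the whole pipeline can be exercised and tested without real
recordings. See `docs/methods.md` for modeling details and limitations.

## Worked example

Train on 20 synthetic confocal mosaics (~100 cones each), tune the
post-processing, and evaluate on 10 held-out mosaics:

```python
import numpy as np
import conedetect as cd

suite = cd.make_fixture_suite(seed=0, modality="confocal")  # 20 train + 10 val
patches = cd.build_training_set(suite.train_images, suite.train_marks, rng_seed=0)
net = cd.build_network(seed=0)
cd.train_network(net, patches.patches, patches.labels,
                 cd.TrainingConfig(seed=0).scaled(8))

probmaps = [cd.compute_probability_map(net, cd.normalize_intensity(im))
            for im in suite.train_images[:3]]
tuned = cd.optimize_params(probmaps, suite.train_marks[:3])
print("tuned (sigma, H, T):", tuned.params.astuple())

dices = []
for image, truth in zip(suite.val_images, suite.val_marks):
    cones = cd.detect_cones(image, net, tuned.params)
    match = cd.match_cones(cones, truth, cd.match_radius(truth),
                           (image.height, image.width))
    dices.append(cd.compute_metrics(match).dice)
print("mean Dice on held-out mosaics:", round(float(np.mean(dices)), 4))
```

Output (about 10 minutes on one CPU core):

```
tuned (sigma, H, T): (0.6, 0.0, 0.7)
mean Dice on held-out mosaics: 0.9963
```

A Dice coefficient of 1.0 means detected and manual cone sets coincide
within the matching radius; ~0.99+ on these fixtures says the trained
classifier recovers essentially every planted cone with almost no spurious
detections. On real AOSLO data the tuned parameters differ per modality
(e.g. larger σ for the smoother split-detector maps).

The same workflow is available from the shell:

```sh
conedetect simulate --modality confocal --n 20 --out data/train
conedetect simulate --modality confocal --n 10 --out data/val --seed 1
conedetect run-all --config config.json
conedetect detect --image img.tif --model out/model --out cones.csv
```

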