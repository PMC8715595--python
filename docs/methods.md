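# Methods

## Problem and approach

Intersubject brain-CT registration estimates, for a (moving, reference)
image pair, a dense displacement field `u` such that the warped moving image
`M(x + u(x))` matches the reference (backward warping). Supervised training
of a displacement-prediction network normally founders on the absence of
gold-standard fields; this package follows the hybrid-supervision recipe:

1. A **simulator** draws random affine + multiscale elastic fields. Warping
   a real (here: phantom) image by a drawn field `Fg0` fabricates a
   reference `I0` whose true correspondence to `M` is `Fg0` — exact, free
   supervision.
2. Each training step also draws a **self-supervised pair** `(M, I1)` of
   distinct subjects with no gold field.
3. Both pairs pass through the same network; the loss is

   `L = alpha * L_F + beta * L_M0 + gamma * L_M1`,  alpha = 1/13, beta = gamma = 0.4,

   where `L_F` is the mean Euclidean deviation (mm) between predicted and
   gold fields over all voxels, and `L_M0`, `L_M1` are negated means of the
   squared local windowed normalized cross-correlation between each
   reference and the correspondingly warped moving image.

## Containers and conventions

* Voxel indices are 0-based; physical mm coordinate = index x spacing +
  origin. Landmark files are physical mm.
* Displacement fields are stored in voxel units with the spacing carried
  alongside; every mm statement converts per-axis through the spacing.
  `L_F` and EPE are computed in mm so anisotropic spacing (e.g.
  0.36 x 0.36 x 2 mm CT) weights axes physically.
* One backward-warping kernel is shared by every consumer; out-of-bounds
  image samples replicate the border (avoids dark halos in similarity
  losses), field sampling at continuous points is multilinear.
* All randomness flows through explicitly threaded `numpy` generators
  seeded from user-visible integers; there is no global RNG state.

## Phantoms

Clinical CT is not shippable, so every pipeline stage runs on synthetic
skull-bearing head phantoms: an ellipsoidal head with a bone shell
(1000 HU), uniform brain (35 HU), paired elongated CSF ventricles (8 HU),
air background (-1000 HU), and additive Gaussian noise (sd 4 HU, truncated
at +-3 sd so tissue HU ranges stay disjoint). An angular sector of the
brain stands in for the MCA territory label. Landmarks are deterministic
feature points: four ventricle-horn tips plus a golden-angle interior ring,
all strictly inside the brain mask. Intersubject variation multiplies radii
and offsets by jitters proportional to `variation_scale` (geometry and
noise use separate seed streams, so zero variation reproduces the base
phantom bit-exactly).

What the phantoms do **not** emulate: sulcal/gyral texture, partial-volume
and beam-hardening artefacts, pathology, and the true variability of human
anatomy. Passing tests therefore demonstrate that the machinery — the
simulator supervision, the loss, the optimization, and the evaluation —
works as specified, not that clinical accuracy matches any reported
clinical figure.

## Preprocessing

Skull stripping is threshold-and-topology based: bone = HU >= 300,
closed with a 1-voxel structuring element; the brain mask is the largest
connected component enclosed by the bone shell; outside voxels are set to
-1000 HU. Z-scoring uses brain-mask voxels only (population sd) and zeroes
the outside; background would otherwise dominate the statistics. These are
documented conventions, not clinical-grade algorithms.

## Simulator

Affine parameters (rotation, per-axis scale, shear, translation about the
grid centre) are drawn uniformly from configurable intervals. The elastic
part draws i.i.d. Gaussian node displacements on coarse grids (spacings
8/16/32 voxels), interpolates cubically to full resolution, smooths with a
Gaussian (sigma 2 voxels), sums scales, and rescales the result so its peak
magnitude equals `max_displacement` exactly (a zero cap gives the zero
field). Elastic is composed outside affine via backward-map composition
`u(x) = inner(x) + outer(x + inner(x))`. A configurable fraction
(default 0.2) of draws comes from a "large deformation" regime.

Head-scale defaults: small regime rotation +-10 deg, scale [0.9, 1.1],
shear +-0.05, translation +-10 mm, elastic cap 5 mm; large regime +-20 deg,
[0.8, 1.25], +-20 mm, 15 mm. For desk-scale phantoms (brain radius
~25 mm vs ~85 mm at head scale) the mm-valued ranges shrink by the radius
ratio 0.3 (`desk_simulator()`); angles, scales and shears are dimensionless
and stay unchanged. This keeps the simulated intersubject variation
proportionally the same as at head scale and leaves the unregistered
territory overlap substantially degraded (Dice ~0.74) so that the
evaluation is not trivial.

## Network

A dimension-generic (2-D/3-D) U-Net on the package's own numpy
reverse-mode autodiff engine (no deep-learning framework is a dependency):
channel-concatenated input pair, 4 levels (16/32/64/128 channels), per
block one convolution per dilation rate (default rates 1 and 2), instance
normalization and LeakyReLU after every convolution, max pooling 2x,
nearest-neighbour upsampling with skip concatenation, and a near-zero
initialized head (weight sd 1e-4, zero bias) whose output is multiplied by
a fixed `output_scale` (default 10 voxels). The scale lets displacements
span many voxels while the head weights stay at natural magnitudes, which
matters for optimizer step sizes; the untrained model still predicts a
near-identity transform (max |u| < 0.1 voxel). Dropout (p = 0.2) sits only
in the two coarsest blocks: at batch size 1, masking fine-scale features
proved too noisy to train through. Instance normalization and the
head-initialization scale are the choices that made batch-1 training
converge at all: without normalization the optimizer stalls, and a head
initialized orders of magnitude smaller starves every upstream layer of
gradient.

## Training

Per step: draw an ordered pair of distinct subjects (M, I1); simulate
(I0, Fg0) from M; add Gaussian noise (sd 0.05, z-scored units) to all four
network inputs (loss targets stay clean); forward both pairs; apply one
Adam update (default moments, batch size 1) of the combined loss. The
field-deviation loss has non-vanishing gradient magnitude near its optimum
(its gradient is a unit direction field), so a constant step size makes
Adam random-walk around — and occasionally away from — the solution; the
loop therefore uses linear warmup (5%) into a cosine decay, base rate
2e-3 at desk scale. An exponential moving average of the weights
(decay 0.99) is validated and checkpointed instead of the raw iterates;
"until convergence" is operationalized as a fixed step budget plus
best-validation-EPE checkpoint selection.

## Evaluation

* **Landmark EPE (mm)**: multilinear sample of the predicted field at each
  landmark vs the gold sparse vector; out-of-extent points are flagged and
  excluded, never silently clamped.
* **NMI**: joint histogram, 32 bins per image over each image's own range,
  normalized as `2 I(A;B) / (H(A) + H(B))`, guaranteed in [0, 1]; constant
  images raise (zero entropy).
* **Dice**: `2|A n B| / (|A| + |B|)` of the transported territory label
  (nearest-neighbour mask warping).
* **Paired t-test**: two-sided on per-case differences, df = n - 1.
* Reports carry per-case rows; aggregates (mean, sample sd) always
  recompute from the rows.

Cohort evaluation draws simulated (reference, moving) pairs from held-out
test subjects, so gold sparse vectors come exactly from the generating
field sampled at the landmarks — replacing manual annotation with exact
synthetic truth.

## The desk-scale study

The bundled end-to-end experiment (`run_desk_experiment`, also what
`scripts/acceptance.py` runs) uses 2-D 64 x 64 phantoms at 1 x 1 mm,
split 8/2/4 (train/val/test, mirroring a 57/14/30 clinical split ratio),
variation 0.3, the desk-scaled simulator, the default network, and 2000
training steps — sized to run in a few minutes on one CPU core. It reports
landmark EPE, territory Dice and NMI for the trained model against the
identity-field baseline on the same held-out simulated pairs.

Alongside the trained model, the experiment evaluates two anchors on the
same test cases: the identity (zero-field) baseline, and an oracle that
replays each case's exact affine component but no elastic part. A trained
model must sit between them; how close it gets to the affine oracle
measures how much of the smooth deformation it actually recovers.

A genuine limitation surfaces here. The phantom brain is internally
uniform, so away from the ventricles and the (faint, noise-dominated)
brain boundary the deformation is simply not observable in the images;
per-landmark analysis shows the trained model recovers ventricle-horn
motion far better than skull-inner motion. Under the desk conditions the
trained model removes roughly a quarter of the landmark error and raises
territory Dice by several points over the unregistered baseline, well
short of the affine oracle — a bound set by the phantom's information
content as much as by the learner. Real CT, with cortical and
deep-structure detail, gives a registration network far more signal than
these deliberately minimal phantoms do.

## Numerical choices and degenerate inputs

* Similarity windows: half-width 4 (9 voxels per axis), epsilon 1e-5 in the
  denominator; constant windows (stripped background) contribute ~0 rather
  than being excluded from the average. Border neighbourhoods clamp.
* `sqrt` in the field loss carries a 1e-12 floor so the gradient exists at
  exact-zero deviation.
* Z-scoring raises on zero within-mask variance; NMI raises on constant
  images; Dice raises on two empty masks; paired t raises on zero-variance
  differences. Training aborts with the offending sub-loss named if any
  loss part goes non-finite.
* Network arithmetic is float32; the autodiff engine preserves the dtype it
  is given, and all gradient checks run in float64.

## Known limitations

* Phantom realism as above; no claim of clinical transfer.
* No diffeomorphism guarantee — fields may fold; the method defines no
  regularization penalty beyond the simulator's smoothness.
* Skull stripping targets clean, complete bone shells.
* The 3-D paper-scale preset (512 x 512 x 64 at 0.36 x 0.36 x 2 mm) is
  configurable but untested at that size; desk-scale grids are the tested
  regime.
* Inverse fields are not computed; evaluation relies on simulated forward
  fields.
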