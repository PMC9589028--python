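# Methods

This note documents the model, the numerical choices, and what the
desk-scale experiments do and do not establish.

## Forward model

The acquisition is modelled as rotational **parallel-beam maximum
intensity projection** about the volume's Z (cranio-caudal) axis. The
clinical cone beam is treated as already corrected to parallel
geometry. A view at angle θ is computed by rotating the volume in the
X–Y plane so the rays align with the +Y grid axis and taking the axis
maximum; θ = 180° is the anteroposterior view (rays along +Y) and
θ = 90° the lateral view. Multiples of 90° are pure index
permutations and therefore exact; oblique angles use bilinear in-plane
resampling. The projector is differentiable in the subgradient sense:
the gradient of each ray's maximum flows to the *first* maximal sample
(a deterministic tie-break), and back through the rotation's adjoint
(the transpose of the sparse interpolation operator).

Smear back-projection replicates a view `depth` times along its ray
direction and resamples onto the canonical grid; for oblique angles
this requires a square in-plane grid. Channels are cropped to the
inscribed cylinder — the 3D space swept by the full 180° rotation — so
all view channels live in one support regardless of the scheme.

View schemes are evenly spaced, `span·k/n` for `k = 1..n`. For a 180°
span and even n this contains both 90° and 180°, the two clinically
standard supervision views. The exact clinical angle tables are not
public; even spacing satisfies every stated constraint and is the
symmetric default.

## Network

Both stages are 3D U-Nets (double 3×3×3 conv + ReLU per level,
factor-2 max pooling, factor-2 nearest upsampling with skip
concatenation, 1×1×1 output head, channel widths doubling from
`base_features`). Clinical-scale defaults are depth 4 and 16 base
features; the desk-scale fixtures use depth 2 and 4 features so tiny
grids stay divisible and a CPU run stays in minutes.

Each back-projected view channel is lifted by a convolution whose
weights are **shared across views**, making the parameter count
independent of the view count. The per-view feature maps are fused by
an element-wise **minimum**. This is a deliberate design choice where
the method description is open: the true volume lies inside the
intersection of the back-projected smears, and the pointwise minimum
over views is the classical sparse-MIP reconstruction estimate. The
lift convolution starts at a *near-identity* initialisation (unit
centre tap plus He noise), so at epoch 0 the fused features already
equal that classical estimate and training only refines it. Mean
fusion is available (`fusion="mean"`) for comparison; in our
experiments min fusion roughly halves the held-out error.

Stage 2 receives the high-resolution channels plus the stage-1
prediction upsampled by trilinear interpolation. The y1 channel enters
through a **zero-initialised convolution** (a zero-conv residual
branch): the refiner starts exactly equal to a stage-2-only network
and learns to draw on the coarse context only where it helps.

Inference clamps predictions to [0, 1]; training leaves them
unconstrained so the loss keeps useful gradients. Inputs whose spatial
dims are not divisible by 2^depth are zero-padded and cropped back.
`patched_apply` runs a network over full-cross-section Z-slabs (the
memory-limited inference mode of the clinical setting); patched and
direct application agree on voxels further than the receptive-field
half-width `H(l) = 2·H(l−1) + 4r + 2`, `H(0) = 2r` from a slab cut,
which the tests assert.

## Training

The loss is the projection-consistency MSE, summed over views. The
written form is a plain sum of squared pixel errors; the default
reduction divides by (views × pixels) so the learning rate decouples
from resolution — the sum form is available and is what the oracle
tests pin. Optimisation is Adam with a per-epoch exponential
learning-rate decay, one case per step, fully seeded (initialisation,
data order); the checkpoint with the smallest validation loss is
restored at the end. Clinical-scale defaults follow the clinical
recipe (initial rates 0.001/0.03 for the two stages, decay 0.9,
1500/400 epochs). A non-finite loss aborts with the epoch named.

Stage 1 trains first and is frozen while stage 2 trains
(`freeze_stage1=False` enables joint fine-tuning, in which the
stage-1 forward pass joins the graph through the differentiable
upsampler). Validation uses the last ~10% of cases (at least one);
with a single case, validation falls back to the training case and
best-checkpoint selection degenerates gracefully.

### Desk-scale fixtures

All training-based checks use two fixed fixtures chosen once:

* **desk** — 8 training + 2 held-out phantoms at 64³ (low grid 32³),
  8 views over 180°, 60 + 12 epochs, learning rates 2·10⁻³, decay
  0.98. The epoch split mirrors the stage-1-heavy clinical ratio.
  ~6 minutes on one CPU core; held-out SSIM ≈ 0.89.
* **mini** — 3 training + 2 held-out phantoms at 32³ (low 16³),
  60 + 20 epochs, five seeds per condition; used for the view-count
  sweep, the limited-angle comparison and the stage ablation, where
  several trainings per condition are averaged. Its refiner uses
  depth 1 so the full-resolution receptive field stays small relative
  to the grid, as it is at clinical scale.

## Post-processing

The volume is partitioned into full-cross-section Z-slabs
(`patch_shape[2]` thick; the last partial slab is judged on its true
extent); any slab whose voxel mean exceeds the threshold is zeroed
entirely and reported. The rule is implemented verbatim with the
threshold exposed (default 0.01, loosened to 0.02 when dense-vessel
slabs would be deleted). Note the rule zeroes *high*-mean slabs: on
desk-scale phantoms, whose vessel density per slab is far higher than
in a 512×512×32 clinical patch, the clinical default threshold would
delete real vessels, so post-processing is a separate explicit step
(library call or `ssdr postprocess`) rather than part of the default
reconstruction path.

## Metrics

MSE and MAE are per-voxel means (the raw norms sit behind
`normalize=False`; the per-voxel form is what makes the magnitudes of
reported clinical values consistent on [0, 1] data). PSNR is
`20·log10(max(ref)/√MSE)`, capped at 200 dB for a zero-error
reconstruction, and undefined (an error) for an all-zero reference.
SSIM is computed from *global* volume statistics — one mean, SD and
covariance per volume, not windowed — with the metric's classic
constants c1 = (0.01 L)², c2 = (0.03 L)², c3 = c2/2 at dynamic range
L = 1. Per-dataset summaries report mean ± sample SD (n−1).
Held-out reconstructions are compared against the ground-truth phantom
cropped to the same cylindrical support the reconstruction lives in.

## What the phantoms do and do not show

The generator emulates the properties the method depends on: sparse
(<10 % foreground), bright, tubular, branching structures with smooth
walls (one-voxel anti-aliased ramp), optional aneurysm bulges, and
faint clipped-Gaussian background noise on [0, 1] grids. It does not
model real cerebral anatomy (no Circle of Willis topology), contrast
dynamics, detector physics, scatter, or inter-scanner variation.
Passing tests therefore demonstrate that the *mechanism* — recovering
a sparse 3D structure from 4–12 MIPs via projection consistency —
works and degrades in the expected directions (fewer views worse,
narrower angular coverage much worse); they do not certify clinical
image quality, and the absolute metric values are properties of the
phantom distribution, not of patient data.

## Known limitations

* The cascade's advantage over a stage-2-only network does not
  reproduce at desk scale: with 32³–64³ grids the refiner's receptive
  field covers most of the volume, so the coarse stage adds no
  information and the two are statistically tied (the ablation still
  shows stage-1-only clearly worst). The gradual stage-1 → stage-2 →
  cascade improvement belongs to 512³ clinical volumes, where the
  full-resolution network is strongly context-limited.
* Oblique projection and back-projection use bilinear resampling;
  round-trip error on smooth images is ≤ 0.05 but sharp single-voxel
  structures can shift by a voxel at oblique angles.
* Training at clinical 512×512×395 resolution is supported by the code
  paths (Z-slab patching, configurable shapes) but is far outside a
  single-CPU budget and is not exercised by the tests.
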