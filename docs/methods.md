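# Methods note

This note records the scientific model behind `dkparc`, the parameter
choices and their rationale, and the known limits of the desk-scale study
conditions the package ships with.

## 1. Problem

`dkparc` produces a hierarchical, Desikan-Killiany-style parcellation of
brain tissue directly from diffusion-MRI-derived scalar maps, without a T1
image. 101 final labels are organised into seven coarse groups — left/right
cerebral white matter (terminal, one label each), left/right deep and
periventricular structures (13 labels each), left/right cortical parcels
(34 each), and midline/central structures (5):

    1 + 1 + 13 + 13 + 34 + 34 + 5 = 101

Grouping the labels flattens the severe voxel-count imbalance of the final
namespace (on the shipped skewed phantom, a max-to-median ratio of ~40 at
the final level versus ~1.5 at the coarse level), which is the motivation
for the two-stage design: a seven-way coarse segmentation first, then one
dedicated model per non-terminal group that only has to separate labels of
comparable size inside its own territory.

## 2. Signal model and scalar maps

The diffusion signal follows the single-tensor model
`S_i = S0 * exp(-b_i * g_i^T D g_i)`. Taking logs makes the model linear in
`(ln S0, Dxx, Dxy, Dxz, Dyy, Dyz, Dzz)`, fitted per voxel by ordinary least
squares over all volumes; baseline volumes enter as rows with zero diffusion
weighting, so multiple baselines are averaged implicitly. Voxels with any
non-positive sample are flagged invalid rather than clamped.

From the eigenvalues `E1 >= E2 >= E3`:

* `FA = sqrt( [(E1-E2)^2 + (E2-E3)^2 + (E1-E3)^2] / [2 (E1^2+E2^2+E3^2)] )`
* `CL = (E1-E2)/T`, `CP = 2(E2-E3)/T`, `CS = 3*E3/T` with `T = E1+E2+E3`
* `MD = T/3`

`CL + CP + CS = 1` wherever the trace is positive; this identity is checked
to 1e-10 in the test suite. The default model input is the four-channel
selection `(T, F, CS, E1)`; all eight maps are available for channel
ablations.

## 3. Phantom

The phantom is a deterministic function of a `PhantomSpec` (grid size, noise
level and model, skew, seed). Geometry: a ball of radius `0.44*N` on a
1 mm LIA-conformed cube, split by a midsagittal column; per hemisphere an
outer cortical ribbon cut into 34 angular sectors, a deep nuclear ball cut
into 13 sectors, and a single white-matter core label; the central column
carries the 5 midline labels as axial slabs. Every final id is guaranteed at
least 8 voxels.

Tissue archetypes (eigenvalues in mm²/s, S0 = 100):

| group | archetype | eigenvalues |
|---|---|---|
| 1, 2 | cerebral white matter | (1.7, 0.3, 0.3)e-3, radial principal axis |
| 3, 4 | deep gray nuclei | (1.0, 0.55, 0.55)e-3 |
| 5, 6 | cortical gray | (0.9, 0.7, 0.7)e-3 |
| 7 | midline fluid | (3.0, 3.0, 3.0)e-3, isotropic |

A fourth archetype (deep gray) deliberately extends the minimal
three-tissue design: deep nuclei such as thalamus and putamen have higher
FA than cortex in vivo, and without this contrast the deep/cortical coarse
distinction would rest on geometry alone. The value was chosen on
physiological grounds before any end-to-end evaluation.

Acquisition: one baseline plus 64 directions at b = 1000 s/mm², directions
from a deterministic Fibonacci spiral. Noise is Gaussian (default
sigma = 1.0, i.e. SNR 100 against S0) or Rician (magnitude of a complex
signal with Gaussian components). The `skew` parameter inflates the
white-matter core at the expense of the cortical ribbon; it is the knob for
imbalance experiments, not a realism parameter.

What the phantom does **not** emulate: partial-volume averaging (labels are
assigned per voxel, the forward model is piecewise-constant), crossing
fibres, susceptibility or motion artefacts, spatially varying noise, and
anatomically realistic parcel shapes. Its purpose is an end-to-end
correctness and recovery harness, not a realism benchmark.

## 4. Two-stage segmentation engine

**Stage one** maps the four normalised channels to background + 7 groups.
**Stage two** trains one model per non-terminal group on five channels: the
four maps plus the coarse mask encoded as `coarse_id / 7` (a single scalar
channel in [0, 1], injective and order-preserving on group ids; the mask
channel bypasses z-scoring). Stages are trained sequentially, never
jointly. The fine models can train against the reference coarse mask
("teacher", default) or the trained coarse model's own prediction
("predicted").

Channels are z-scored per channel over foreground voxels (any channel
non-zero); trained models store the statistics and replay them at
inference. Models also record their channel-name order and refuse
mismatched input.

**Loss**: equally weighted (1:1) soft Dice over the foreground classes of
the sample plus cross-entropy; a control variant swaps in class-weighted
cross-entropy with inverse-label-frequency weights (proportional to
1/count, normalised to mean 1, absent classes receiving the maximum
weight). Gradients of the composite loss with respect to the logits are
computed in closed form and verified against finite differences.

**Patch sampling** draws at least a configurable fraction (default 0.5
coarse / 0.7 fine) of patches centred on a foreground voxel, the rest
uniform, with zero-padded edges.

**Inference** tiles the volume with 0.5-overlap sliding windows, blends
per-window class scores under a separable Gaussian (sigma = patch/8),
renormalises to a voxel-wise simplex and takes the argmax. For a model with
receptive field 1 the windowed argmax equals the full-volume argmax exactly
(an acceptance property).

The published training scale for this family of pipelines (patch 128³,
batch 2, GPU) is recorded as constants; the desk-scale defaults (patch 24,
batch 2, 300–400 iterations) are sized so the full pipeline trains on one
CPU core in about three minutes.

## 5. Reference backbone

The backbone is pluggable; anything with `n_in_channels`, `n_classes` and
`predict` works. The shipped reference network is a small numpy
implementation — conv3×3×3 → ReLU → conv1 → ReLU → conv1 → softmax with
hidden widths (32, 64), im2col+GEMM convolutions, exact hand-written
gradients, float32 parameters. Design decisions:

* **No framework dependency.** The training loop is plain gradient descent
  over explicit gradients; no autograd library is required.
* **Spherical positional encoding.** Seven internal channels are appended:
  centred voxel coordinates scaled to [-1, 1] over the volume, the radial
  distance, and the unit direction vector from the volume centre. Large
  GPU-scale networks see most of a head per 128³ window and infer position
  from anatomy; a desk-scale receptive field cannot tell the hemispheres of
  a symmetric phantom apart without position. The unit-direction channels
  make every angular-sector boundary through the centre a *linear* function
  of the inputs, which is what lets a tiny network separate 34 cortical
  sectors. Declared `n_in_channels` counts data channels only.
* **Conv → nonlinearity without an internal normalisation layer.** The
  engine's per-channel foreground z-scoring standardises the input; keeping
  the blocks norm-free keeps the exact gradients simple.
* **First-layer kernel per stage.** The coarse model uses a 3×3×3 first
  convolution (local averaging of noisy maps); the fine models use
  receptive-field-1 (1×1×1) layers throughout — final parcels within a
  group are position-defined, so a voxel-wise classifier over
  (maps, mask, position) suffices and trains ~3× faster.
* **Optimiser.** Both plain fixed-step SGD with Nesterov momentum (0.99)
  and Adam are implemented, under the same polynomial learning-rate decay
  (power 0.9). Adam is the desk-scale default: plain SGD needs several
  thousand iterations to separate the 34-class fine stages, beyond a
  sensible CPU budget, and adaptive-step methods are standard for this
  model family.

## 6. Post-processing

Fixed order: restrict each fine output to its coarse mask → constrained
majority fill → per-label largest 26-connected component → merge → optional
nearest-neighbour resampling to the native grid → optional lookup-table
remap (e.g. to FreeSurfer colour-table ids; injective, total on present
labels).

The "dilation" step is realised as a constrained majority fill:
unconditional morphological dilation is ill-defined for overlapping
multi-label parcels, whereas letting background voxels inside the coarse
mask adopt the majority label among their 26-neighbours (ties to the lowest
id, at most 3 sweeps) closes small gaps without ever moving a boundary
across another label or outside the coarse region. The largest-component
rule applies no minimum-size threshold; ties keep the component containing
the smallest x-fastest linear voxel index.

## 7. Metrics

* **DSC** `2|P∩R|/(|P|+|R|)`; both masks empty → 1 (vacuous agreement).
* **HD95**: boundary voxels (mask minus 6-connectivity erosion), directed
  Euclidean distances both ways (spacing-aware), pooled, 95th percentile
  with linear interpolation; either mask empty → NaN, never 0.
* **RSD** = population std / mean of a map inside a parcel; the label-free
  homogeneity criterion. Near-zero mean → NaN; negative mean → negative
  RSD with a warning.
* **Confidence maps** from the coarse softmax: confidence (max score),
  uncertainty (1 − confidence), margin (top minus second score).

Macro averages run over labels present in either volume; NaN HD95 values
are excluded from macros. Reports are TSV, with per-subject and pooled
macro rows.

## 8. Numerical choices

* Tensor fit uses one shared pseudo-inverse of the design matrix (the
  design is voxel-independent).
* Backbone parameters and activations are float32; losses and metrics are
  float64.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; phantom, training and inference are bit-reproducible for a given
  configuration.
* Dice uses epsilon 1e-5 in the denominator; probabilities are clipped at
  1e-12 inside the log only.

## 9. Limitations

* The phantom's parcels are geometric sectors, far more learnable than
  anatomical parcels; recovery scores here say nothing about in-vivo
  accuracy.
* The reference backbone is intentionally tiny. Its positional encoding
  effectively teaches it the phantom's coordinate frame; models trained on
  one geometry will not transfer to another.
* Training is single-volume; there is no train/validation split at desk
  scale, so reported recovery is resubstitution accuracy on a noisy volume.
* The Rician noise path is provided for realism experiments but the
  log-linear tensor fit has no Rician bias correction.
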