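# Methods

`chorangio` reconstructs choroidal angiograms from densely collected OCT
B-scan cubes by segmenting Sattler's vessels (SV) and Haller's vessels (HV)
slice by slice, and computes choroidal vascularity biomarkers from the
resulting label volume.  Because dense cubes are acquired with few repeats,
their B-scans are speckle-heavy and blurry compared with the high-definition
(HD) scans that experts can annotate.  The segmentor is therefore trained as a
cross-domain problem: supervised on labeled HD scans, adapted to the
unlabeled low-quality domain with a mean-teacher self-training branch and an
output-space adversarial branch.

## Model

The segmentation task is decomposed into two subtasks: a binary vessel map
and a 3-class sublayer map {background, Sattler band (SL), Haller band (HL)}.
The composed 3-class prediction {bg, SV, HV} is the per-pixel product
P(SV) = P(vessel)·P(SL), P(HV) = P(vessel)·P(HL).  Subtask heads can be two
independent networks or two 1×1-conv heads on a shared U-Net trunk
(`multi_task`); the bundled backbone is a compact U-Net (depth 3, base width
16) chosen so CPU training on phantom data completes in minutes.  Larger
backbones plug in behind the same forward contract.

Training combines three losses, `L = Ls + λ1·Lt + λ2·La` with λ1 = 1.5,
λ2 = 0.5:

* **Ls** — soft dice on labeled HD scans, background channel excluded,
  smoothing ε = 1 (foreground/background imbalance remedy).
* **Lt** — masked self-training dice on unlabeled low-quality scans.  An EMA
  teacher predicts the weak-augmented scan; its per-pixel argmax is the
  pseudo-label; the student is trained on a strong-augmented view of the same
  scan.  The mask is the confusion-sample selection (CSS) product of two
  strict gates: teacher max-probability > α, and β1 < S < β2 where S is the
  discriminator's upsampled domain score.  Presets: (α, β1, β2) =
  (0.85, 0.1, 0.9) for the sublayer subtask, (0.85, 0.15, 0.85) for vessels.
* **La** — adversarial adaptation.  The discriminator (EDD: five 4×4
  convolutions, channels 64/128/256/512/1, strides 2/2/1/1/1, paddings 1,
  leaky-ReLU 0.2, sigmoid score with 0 = source-like) is trained to separate
  the teacher's (temporally ensembled) target output space from the student's
  source output space; the student in turn minimizes −log S on its source
  predictions (single-term form: the teacher branch carries no gradient).

Optimization: Adam, lr 6e-4 divided by 10 at epoch 150 (250-epoch default),
batch 4 + 4; the EDD has its own Adam at 6e-5.  Teacher decay defaults to
0.999.  All randomness flows from one integer seed through
`numpy.random.SeedSequence`; runs are bit-reproducible on one platform.

### Numerical core

The network stack (reverse-mode autodiff, im2col convolution, pooling,
softmax, Adam/SGD) is implemented directly on numpy in `chorangio.nn`, in
float32.  Convolution gradients were verified against central finite
differences; the EDD's output size follows the conv arithmetic
⌊(n + 2p − k)/s⌋ + 1 per layer (448 → 109, 64 → 13).  Argmax ties break to
the lowest class index (background-favoring).  Logs inside the adversarial
losses are clamped at 1e-7.

### Design choices that were genuinely open

* **EDD input**: the softmax output map of the trained subtask (2 or 3
  channels); in multi-task mode the 5-channel concatenation of both heads.
* **EDD initialization**: N(0, 0.02) (the PatchGAN/DCGAN convention).  With
  He-scaled initial weights the early adversarial gradients through the
  512-channel stack are comparable to the supervised gradient and the game
  destabilizes before the segmentor has learned anything.
* **Warm-up** (`warmup_epochs`, default 0): the target and adaptation
  branches can be deferred for a number of source-supervised epochs.  The
  teacher's pseudo-labels and the discriminator's "target exemplars" are only
  meaningful once the teacher is source-trained; engaging them from step 0
  makes the discriminator separate "has anatomy" from "washed out" and the
  adversarial term then erases anatomy from the student's predictions.  At
  journal-scale step counts this start-up transient washes out; in short runs
  it dominates, so the bundled benchmark warms up for half its epochs.
* **EMA horizon**: 1/(1−decay) should be a small fraction of the run length;
  0.999 (horizon ≈ 1000 steps) assumes tens of thousands of steps.  The
  desk-scale benchmark uses 0.99.
* **Le/La reduction**: mean over spatial locations and batch, for
  size-invariance of the loss scale.
* **Strict inequalities** at all gate thresholds, as printed.
* **Iterations per epoch**: ⌈max(N_source, N_target)/batch⌉, the smaller set
  cycling with reshuffles.

## Synthetic phantom

The generator emulates the two acquisition regimes over a layered choroid:
retina band, choriocapillaris strip (no resolvable vessels), Sattler band
with small elliptical lumens, Haller band with large ones; lumens are
hyporeflective.  Vessels are planted by rejection sampling until each band's
area (volume) fraction is within ±10 % of its target; centers are sampled
past the field edges so coverage stays uniform out to the boundary.  Cubes
plant 3-D ellipsoidal tubes spanning ≥ 2 adjacent slices.

Speckle is fully developed: each realization multiplies the clean
reflectivity by unit-mean exponential noise, and an acquisition averages
`n` independent realizations — the expectation equals the reflectivity and
per-pixel variance scales exactly as 1/n (HD: n = 30; low-quality: n = 2).
The low-quality domain additionally receives a Gaussian focus blur and a
gamma contrast shift.  Default vessel densities (SL 0.40, HL 0.45) sit in
the range of published choroidal vascularity indices for healthy eyes.

What the phantom does **not** model: OCT attenuation and sensitivity
roll-off, retinal vessel shadowing, motion artifacts, pathology.  Passing
tests on the phantom demonstrate that the machinery (losses, gates,
adaptation loop, biomarker arithmetic) behaves as specified, not that the
bundled weights segment clinical scans.

## Desk-scale benchmark

`chorangio.benchmark` trains a source-only baseline and the full framework
on one data draw: 20 labeled HD scans, 100 unlabeled low-quality scans, and
a 20-scan labeled low-quality test set, and reports per-class dice plus the
SV&HV composite.  Problem sizes are chosen for a single CPU core: 48×64
B-scans (layer stack 10/2/12/18 px, SV radius 1.5–2.5 px, HV 3–5 px), focus
blur σ = 0.8 px — about half the smallest vessel radius, so small vessels
are degraded but not erased, as in real dense scans — gamma 1.4, compact
U-Net in multi-task mode, 16 epochs with 8 warm-up epochs, EMA decay 0.99,
3 seeds.  Strong-augmentation smoothing is scaled to the resolution
(σ ∈ [0.2, 0.5]); all other hyperparameters are the published defaults.
The deployed segmentor is the EMA teacher (temporal ensembling), for both
conditions symmetrically, and evaluation mirrors the training-time weak
transform (resize only, ground truth resized nearest-neighbor).

## Angiography and biomarkers

`segment_cube` runs the trained segmentors slice-wise (resize-free; inputs
are padded to the backbone's stride and cropped back) and composes hard
labels.  Per A-scan column the module computes vascular density (depth
fraction labeled vessel), CVI = (SV+HV)/(SL+HL), CVI-H = HV/HL,
CVI-S = SV/SL, and thicknesses CT-H/CT-S = layer pixel count × axial
spacing (µm).  Columns with an empty denominator are missing (NaN) and are
excluded from regional means; zero-filling would bias CVI downward.
Regional summaries are means over fovea-centered circles; the conventional
1/3/6/9/12 mm figures are interpreted as **diameters** (ETDRS convention —
they cannot all be radii on a 12 mm field); `unit="radius"` restores the
other reading.  Group comparison reports mean ± SD and a two-sided t test —
Welch's unpaired by default, since cohorts of different sizes cannot be
paired; a paired mode exists for paired designs.  Evaluation dice is the
hard overlap 2|A∩B|/(|A|+|B|) × 100 per class (SL, HL, CV from the subtask
maps; SV, HV from composed labels), with both-empty = 100 and one-empty = 0.

## Known limitations

* The choriocapillaris carries no ground-truth vessels; capillary-scale
  structure is out of reach of this pipeline by design.
* The numpy backend trains small models on small images; journal-scale
  geometry (448×448, SwinUNetR-class backbones) requires a GPU framework
  behind the same module contracts.
* The adversarial branch is sensitive to the discriminator/segmentor
  learning-rate race at short horizons; the warm-up and EMA-horizon
  scalings above are what make it behave in minutes-long runs.
* Fovea localization is not implemented; region statistics take the center
  from the manifest or the cube midpoint.
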