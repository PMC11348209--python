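# Methods

## Model

The segmenter is trained by unpaired image-to-image translation between an
imaging domain X (grayscale photoacoustic volumes, normalised to [-1, 1])
and a segmentation domain Y (binary vessel masks, mapped to {-1, +1} so
both domains share the network value range). Two generators G: X → Y and
F: Y → X are 3-D deep residual U-Nets; two discriminators D_X, D_Y are
five-layer 3-D PatchGANs returning a spatial grid of real/fake logits.

Assumptions inherited from the translation setup: the two unpaired
datasets describe the *same underlying anatomy class* (branching tubular
networks), so a cycle-consistent pair of mappings exists; vessels are the
only bright structures; and the synthetic mask distribution is rich enough
(branching order, angle, taper, tortuosity) that G never needs to invent
topology absent from Y.

### Losses

With x a real volume and y a synthetic mask:

* forward cycle x → G(x) → F(G(x)): mean absolute error and a structural
  similarity (SSIM) reconstruction term 1 − SSIM(x, F(G(x)));
* backward cycle y → F(y) → G(F(y)): voxelwise binary cross-entropy (after
  mapping [-1, 1] → [0, 1], predictions clipped to [1e-7, 1 − 1e-7]) plus
  the topology term (1−α)(1 − softDice) + α(1 − softclDice), where the
  soft skeleton is computed by iterated soft erosion (min-pooling over the
  three axis-aligned 3-voxel windows) and soft opening (cube max-pooling);
* least-squares adversarial terms for all four networks, with Gaussian
  noise of annealed variance 0.1·(1 − i/epochs) added to every
  discriminator input and before each internal convolution block.

Totals use α = 0.5, λ = 10 (cycle), η = 5 (reconstruction/topology).
Under the default `per_generator` split each generator receives gradients
only from the cycle terms of the reconstruction it produces (the inner
generator output is detached), so G's segmentations of real volumes are
constrained only adversarially; `loss_split="joint"` restores the fully
coupled classic formulation for baseline comparisons. No identity-mapping
loss is used (meaningless for grayscale/binary volume pairs).

SSIM uses a separable Gaussian window (size 11, σ 1.5 by default) over
valid window positions, C1 = (0.01·L)², C2 = (0.03·L)² with dynamic range
L = 2. Expectations are realised as arithmetic means over voxels and
batch. Soft-Dice/clDice use additive smoothing 1; the soft skeleton runs
10 iterations by default (covers vessel radii up to ~10 voxels; the
desk-scale study uses 5, matching its ≤3-voxel radii).

### Optimisation

Adam (β₁ = 0.5, β₂ = 0.9), learning rate 2·10⁻⁴ constant until the decay
start epoch (100 of 200 by default) then linearly to zero; every
parameter tensor's gradient is individually norm-clipped at 100. One step
updates D_X and D_Y first (on noise-injected real and detached fake
inputs), then G and F. Global batch 2 on one device (batch 1 in the
desk-scale study). Patches are augmented by a Z-axis rotation drawn from
{0, π/2, π, 3π/2, 2π} — the identity appears twice in the published set
and is implemented literally, so it is twice as likely. Segmentation
patches are drawn with the vessel bias rule: an empty patch is accepted
with probability 0.1 and redrawn otherwise (bounded at 100 redraws).
Datasets are split 10% test, then 80/20 train/validation; the checkpoint
with the lowest validation generator total is retained as `best.npz`
(an automatable proxy for the published qualitative model selection).

## Synthetic vasculature

A stochastic L-system generates instruction strings (default grammar:
axiom `F`, rule `F → F[+F][-F]`; branching order 5–8 at full scale, 4–5
at desk scale). The 3-D turtle samples a branch angle ~ N(40°, 10°) per
rotation symbol, applies a tortuosity bend ~ N(0°, 5°) about a random
perpendicular axis per step, and scales step length (×0.8) and radius
(×0.75) on branch entry; optional shrinkage (radius ratio halved) and
aneurysms (node radius doubled) occur with configurable probabilities.
Graphs are voxelized as capsules with linearly interpolated radii — a
voxel is foreground iff its centre, at (i + 0.5)·voxel size, lies inside
any capsule — and stored 8-bit (0/255). The default grid is 512×512×140
at 20 µm isotropic. The exact published grammar constants are not
reproduced; every parameter is exposed instead.

## Appearance emulator and preprocessing

`emulate_pai` renders a mask with the signature artefacts of mesoscopic
photoacoustics: exponential depth attenuation (default 0.8 mm⁻¹ below the
illuminated surface), the limited-illumination arc (the top-surface voxel
of each vertical vessel run keeps full strength; deeper voxels of the run
are dimmed by factor 1 − 0.6), Gaussian PSF blur (σ 1 voxel) and additive
Gaussian noise (σ 0.05). It is a fast synthetic stand-in for full
optical/acoustic simulation and is not claimed to be physically
quantitative; defaults were chosen once for qualitative resemblance.

`preprocess` applies, in order: per-XY-slice z-score (σ = 0 slices map to
zero), global two-sided percentile clipping at 0.05% (the clipping scope
is not specified per-slice vs per-volume in the source recipe; global was
chosen for stability), cubic-spline resampling of Z to 128 voxels, and an
affine rescale to exactly [-1, 1] (a globally constant volume maps to
zeros). Binarised outputs are cubic-resampled back to 140 Z voxels.

## Sliding-window assembly

Inference tiles the volume with 128³ windows at stride 25 in X/Y (Z is
128 after preprocessing). The volume is mirror-padded symmetrically for
*full-overlap* tiling: each side receives at least window − stride
voxels, rounded up so the stride tiles the padded extent exactly. Border
voxels are then visited as often as interior ones; per-voxel visit counts
are tracked and the probability map is the per-voxel mean (sum/count).
Exact count uniformity holds whenever the stride divides the window; at
the published stride 25 the counts necessarily alternate between 5 and 6
(⌊128/25⌋ and ⌈128/25⌉ windows cover a voxel depending on its position
modulo 25) and the count-normalised mean is what makes the assembly
exact. Thresholding uses Otsu's criterion on the map histogram by
default (the histogram-threshold variant is otherwise unspecified), with
a manual override; a constant map yields an empty mask with a warning.

## Metrics and topology

Voxelwise metrics follow the standard confusion-matrix formulas
(F1 = 2·precision·sensitivity/(precision+sensitivity),
IoU = TP/(TP+FP+FN)); conventions for degenerate cases: two empty masks
score F1 = IoU = 1, sensitivity is 1 when the truth has no positives.
Note F1 = 2·IoU/(1 + IoU) identically.

Skeletons come from our own homotopic 3-D curve thinning (`_thinning`):
voxels are removed when they are simple points (Bertrand–Malandain
characterisation in (26, 6) digital topology), visited in increasing
Euclidean-distance-transform order within eight coordinate-parity
subfields per round, with permanent protection of curve isthmuses.
The parity split keeps a removal front from cascading through a whole
structure in one sweep; isthmus (rather than endpoint) protection avoids
surface spurs. A solid cylinder reduces to a simple path and a solid
torus to a single cycle. This component was written in-package because a
correct 3-D thinning primitive with these guarantees was needed; thinned
tubes lose roughly one tube-radius of length at their open ends, which
does not affect the topological descriptors.

The skeleton graph connects 26-adjacent skeleton voxels; diagonal edges
with a strictly lower-rank two-step bypass through a common neighbour are
dropped (triangle chords carry no topology for thin curves). Betti-0 is
the number of graph components (union-find), Betti-1 = E − V + C. Node
radii are distance-transform values × voxel size; diameter statistics are
unweighted over skeleton nodes. Network volume is the foreground voxel
count × voxel volume; surface area counts exposed voxel faces (simple and
rotation-robust at 20 µm resolution; a marching-cubes alternative was
deliberately not used); connectivity is the largest 26-connected mask
component's volume as a percentage of total foreground.

## Desk-scale study

`vangan.studies.run_desk_scale_study` is the CPU-sized version of the
full experiment: 26 L-system masks at 32³ (radii ≈ 90 µm ≈ 4.5 voxels;
foreground 4–10%), rendered by the emulator in a high-SNR regime
(attenuation 0.2 mm⁻¹, no illumination artefact, PSF 0.5, noise 0.05)
and mapped directly to [-1, 1] via the emulator's known physical scale.
Eighteen volumes train the model (levels 2, base filters 8,
discriminator filters 8, batch 1, 15 epochs × 20 steps = 300 steps,
schedules annealed over the 15 epochs), two serve as validation for
best-checkpoint selection by the validation generator total, and six
held-out volumes score the Otsu-binarised segmenter against ground
truth. The direct [-1, 1] mapping matters: at
32³ the acquisition preprocessing chain amplifies background noise in
near-empty XY slices to vessel scale (a direct Otsu threshold on such
volumes only reaches F1 ≈ 0.13), which is precisely the regime the
full-scale adversarial training is designed to survive but which no
300-step model can, so the study isolates the learning question from the
normalisation question. The fixture vessels are deliberately thick: at
very sparse foreground (<3%) the all-background generator pair is a
near-optimum of every cycle loss and short unpaired runs can collapse
into it, while at 4–10% foreground the collapse is costly and training
escapes it reliably.

What passing at desk scale shows — and what it does not: the study
demonstrates that the unpaired adversarial loop, with all its published
loss terms and schedules, learns a usable segmenter from scratch on
unpaired data in minutes on one CPU. It does not emulate real
photoacoustic physics (no acoustic reconstruction artefacts, no spectral
effects, no speckle), tumour-like chaotic vasculature, or the
publication-scale setting (449 physics-simulated 600×600×140 volumes,
200 epochs, GPU training, reported F1 ≈ 0.84), whose reproduction is out
of desk-scale reach by design.

## Numerical choices

* All network tensors are float32; oracles and tests use float64 where
  precision matters. The autodiff engine accumulates gradients on leaf
  tensors only; wrapping an array in a fresh tensor detaches it.
* Convolution is direct shift-and-GEMM (one small matrix product per
  kernel offset, channels-last layout) — faster and leaner than im2col at
  these channel counts; its backward was verified against finite
  differences to ~1e-9 relative.
* Reflection padding everywhere in the networks (minimises boundary
  artefacts); pooling treats out-of-bounds as the identity element.
* Instance normalisation uses ε = 1e-5 and a fused hand-derived backward.
* He-normal weight init, seeded per network from a single study seed;
  every run is bit-reproducible from one integer.
* Ties in Otsu thresholding and in max-pooling argmax resolve to the
  first (lowest-index) candidate, fixed by numpy semantics.
* Preprocessing is only approximately idempotent: re-running the chain on
  an already-normalised volume re-scales each XY slice by its own
  statistics, leaving a small residual (mean absolute difference below
  0.1, correlation above 0.99) rather than reproducing it exactly.

## Known limitations

* The numpy stack is CPU-bound: publication-scale training (128³ patches,
  200 epochs) is out of reach; the package targets desk-scale studies and
  method development.
* GAN training at a few hundred steps is noisy; held-out F1 fluctuates
  by roughly ±0.1 between epochs at desk scale.
* The emulator is an appearance model, not physics; conclusions about
  real RSOM data require the full simulation pipeline it stands in for.
* Thinning-based descriptors depend on voxelization quality at radii
  below ~2 voxels; diameter statistics are biased low for such vessels.
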