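# Methods

## Problem and model

`lungood` frames COPD assessment on chest CT as out-of-distribution
anomaly detection. The lung is decomposed into cubic patches x_i; a
self-supervised contrastive encoder maps each patch to a latent
representation z_i = f(x_i); a generative model p(z) is fitted **only** to
representations of normal-appearing patches from control subjects; each
patch is scored by its negative log likelihood

    s(x_i) = -log p(f(x_i)),

so low likelihood under the normal-tissue density reads as high anomaly.
A patient-level score S(X) aggregates the patch scores and is evaluated
against control/diseased labels with the Mann–Whitney AUC. Patch scores can
also be reassembled into volumetric anomaly maps for visual reading.

The rationale is that diseased parenchyma is heterogeneous and hard to
enumerate with supervised labels, whereas normal-appearing lung is
comparatively homogeneous: modeling the normal class and measuring
deviations captures the disease spectrum implicitly.

## Pre-processing

Patches are laid on a regular grid over the lung-mask bounding box with a
configurable edge (default 50 voxels for clinical-resolution CT, the scale
of a secondary pulmonary lobule; tests and phantoms use 16 on 64-cube
volumes) and overlap fraction (0% or 20% are the standard settings).
Design choices the pipeline contract does not fix elsewhere:

- the grid is anchored at the bounding-box minimum corner, with a final
  clamped row per axis so patches reach the bounding-box maximum — this
  guarantees edge coverage;
- patches with lung fraction below `min_lung_fraction` (default 0.5) are
  discarded; the union coverage of retained patches over the lung mask is
  reported and a warning (not an error) is raised when it falls below the
  0.70 target;
- coordinates are 0-based voxel indices; a patch occupies the half-open
  box [origin, origin + edge).

When pooling "normal-appearing" patches for the density fit, patches with
**1% or more** in-lung inspiratory voxels below −950 HU are excluded (the
emphysema health filter; the boundary is strictly below 1%). The fraction
is computed over in-lung voxels of the patch, matching the lung-restricted
definition of the LAA metrics. The filter is applied only when building
the density-training pool, never at inference.

Per subject at most 100 patches are used, selected uniformly at random
with a fixed seed — beyond that patch count adds redundancy only.
Intensities are clipped to [−1024, 100] HU and mapped affinely to [0, 1].

## Quantitative CT metrics

LAA-950% is the percentage of in-lung inspiratory voxels strictly below
−950 HU (emphysema surrogate); LAA-856% the percentage of in-lung
expiratory voxels strictly below −856 HU (air trapping). Plain voxel
thresholding, no resampling or smoothing: these are the defined metrics
here, not reproductions of commercial pipelines.

## Contrastive encoder

The pretext task is instance discrimination: two stochastic augmentations
of one patch form a positive pair; other patches in the batch are
negatives. The NT-Xent loss on cosine similarities (temperature τ, default
0.1) is minimized; self-similarity is excluded from the softmax
denominator, and with a single pair the loss is identically 0.

Architecture: stride-2 valid 3D convolutions with ReLU (3 blocks for patch
edges < 32, 4 otherwise, widths 8·2^i), global average pooling, a linear
map to the latent space (`latent_dim`, default 64), and a 2-layer
projection head (`projection_dim`, default 32) used only by the loss.
Downstream representations are the backbone output, pre-projection (the
standard SimCLR convention). Before encoding, non-lung voxels of a patch
are zeroed (`mask_background`, on by default): soft-tissue background is
~900 HU brighter than parenchyma and otherwise dominates the variance of
lung-boundary patches, drowning the parenchymal signal the method cares
about. Augmentations: per-axis random flips, small
rotations (≤10°) in a random plane, random crop-rescale (0.8–1.0), and
additive intensity jitter (σ = 0.02 in normalized units ≈ 22 HU). All
weights, data order and augmentations are seeded; training is
deterministic for a fixed seed and thread policy.

The network, the NT-Xent loss and the normalizing flow below run on a
small in-package reverse-mode automatic-differentiation engine over numpy
arrays (`lungood.nn`), with an Adam optimizer; 3D convolution is expressed
as an im2col gather plus matrix product. Gradients are verified against
finite differences in the test suite. This keeps the whole method
dependency-light and CPU-friendly at the problem sizes the package
targets.

## Density models

Two families expose the same `log_prob` contract:

- **Gaussian mixture (default).** EM from a k-means initialization, best
  of `n_init` restarts by final log-likelihood, per-iteration total
  log-likelihood trace recorded (non-decreasing by the EM guarantee).
  Diagonal covariances with a variance floor of 1e-6 are the default —
  robust for moderate-dimensional representations at desk-scale N; full
  covariances are available. K is chosen by BIC over 1..10 unless fixed in
  the configuration. Log densities are evaluated with log-sum-exp.
- **Normalizing flow.** Affine coupling layers (default 6) with
  alternating even/odd masks; each coupling's scale and shift come from
  one-hidden-layer tanh MLPs, with the log-scale passed through a tanh cap
  (±3) for conditioning. Couplings are zero-initialized, so the untrained
  flow is the identity and its log_prob equals the standard-normal base
  density exactly. A fitted input standardization is folded into the
  change of variables. Training maximizes mean log-likelihood by
  full-batch Adam (lr 1e-3 — small on purpose: near an optimum, Adam's
  normalized steps at larger rates walk away from it).

The anomaly score is exactly `-log_prob`, in nats.

## Aggregation, selection and evaluation

Candidate aggregations: mean, max, top-k mean (k ∈ {5, 10}), and upper
percentiles (q ∈ {90, 95}, linear interpolation). All are permutation
invariant and bounded by the patch-score range. The strategy is selected
by the highest mean validation AUC over repeated runs, ties broken by
lower AUC standard deviation, then candidate order. AUC uses the
Mann–Whitney formulation (ties count half), diseased as the positive
class. Each run re-trains both the encoder and the density model on a
fresh seeded subject-level stratified split (default 0.5/0.2/0.3) — the
conservative reading of "run".

## Anomaly maps

Each voxel covered by at least one patch receives the arithmetic mean of
all covering patch scores; uncovered voxels are missing (NaN). For display
the map is min-max normalized by the 5th/95th percentiles of the full
evaluation set's patch scores (so maps are comparable across subjects) and
clipped to [0, 1]; the CT underlay is windowed to [−1300, 50] HU, and the
overlay uses a red-emphasizing colormap. Rendering composes the RGB array
directly and writes it losslessly, so identical inputs give byte-identical
PNGs.

## Synthetic phantoms

The phantom emulates what the pipeline needs from cohort CT and nothing
more: a two-lobe lung (two overlapping ellipsoids — non-convex, so the
patch-coverage logic is exercised), Gaussian parenchyma textures
(inspiration N(−850, 40) HU, expiration N(−750, 40)), soft-tissue
background N(30, 20), and spherical lesions of radius 2–4 voxels placed by
rejection sampling without same-type overlap. Emphysema-like lesions set
inspiratory HU to N(−980, 15); air-trapping-like lesions set expiratory HU
to N(−900, 15). Normal tissue sits clearly above, and lesions clearly
below, the −950/−856 HU thresholds, so LAA metrics recover the ground-truth
burden (the fraction of lung voxels occupied by lesions) within a few
percent relative.

Lesions are concentrated in a focal disease region — the fraction of lung
voxels nearest to a few random foci (default 3), sized at three times the
larger single-type burden (at least 15% of the lung). This emulates the
regional heterogeneity of COPD: a diseased lung retains genuinely
normal-appearing regions, which is precisely what patch-level anomaly maps
are supposed to resolve. Both lesion types share the foci, as emphysematous
regions also trap air; the two channels are otherwise modified
independently so the two LAA metrics stay orthogonal.

What the phantom does **not** model: airway and vascular anatomy, real
parenchymal texture, respiratory motion, registration error, scanner and
dose effects. Passing the phantom benchmarks therefore demonstrates that
the pipeline machinery (representation learning, density estimation,
scoring, aggregation) detects and localizes low-attenuation burden under
controlled conditions — not clinical performance on cohort CT.

## Problem sizes and numerical choices

Default phantom volumes are 64³ voxels with 16-voxel patches; the
end-to-end benchmark uses 40 control + 40 diseased phantoms with per-type
burdens 0.10–0.20, three runs, encoder batches of 32, a handful of epochs,
and BIC-selected mixture size — sizes chosen so the full suite runs on one
CPU in minutes while every stage operates above the small-sample regime.
Mixture capacity matters once background masking is on: benign patch
subpopulations (interior vs boundary patches) need their own components,
or they inflate the tails and drown lesion-driven scores.
Burden-response runs share one trained encoder per seed across burden
levels and re-fit only the density and scores: the encoder is a
burden-agnostic representation learner, and what varies across levels is
the scored content. Patch-level localization benchmarks use a
control-heavy cohort (mirroring the control-heavy density-training pool of
cohort studies) and a K=6 mixture, which lets mixture components absorb
benign patch subpopulations (e.g. lung-boundary patches) instead of
pushing them into the tails.

Other numerical details: EM convergence at relative tolerance 1e-7 with
assertion that responsibilities sum to one per point; degenerate inputs
(all-identical representations, empty masks, empty score lists, p5 = p95
normalization references, single-class AUC) raise explicit errors rather
than returning quiet numbers; percentiles interpolate linearly throughout;
seeds derive from `numpy.random.SeedSequence` so nested randomness is
reproducible.

## Known limitations

- Phantom realism is intentionally minimal (see above); absolute AUC
  values on phantoms say nothing about cohort AUCs.
- The desk-scale encoder is far smaller than cohort-scale backbones; its
  job here is to order patches by abnormality, not to transfer.
- Diagonal-covariance mixtures can misestimate densities on strongly
  correlated latent spaces; the flow family is provided as the
  alternative.
- Inspiration–expiration registration is assumed given; lung segmentation
  is an input, not a product.
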