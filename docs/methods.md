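# Methods

`vcore` turns stacks of routinely scanned 2D H&E serial sections into
co-registered "volumetric cores" and grades them with an attention-based
multiple-instance learner over features from a divided space-time attention
encoder. This note records the models, the numerical choices, what the
synthetic phantoms do and do not establish, and the known limitations.

## Phantom worlds

No public serial-section cohort ships with this package, so every stage is
validated on generated phantoms: ribbon-shaped tissue bands with wavy
boundaries, stromal texture at two spatial scales, gland-like lumens with
purple epithelial rims, and scattered nuclei, colored so the HSV hue band
[0.55, 0.95] with saturation ≥ 0.15 — the tissue-masking default — captures
exactly the painted tissue. Each section of a stack is the shared base
tissue under a stored similarity transform (rotation, isotropic scale,
translation) plus a smooth control-lattice warp; the generator also traces
a common set of base points into every section, giving exact
correspondences against which alignment error is measured, with sub-1e-6 px
self-consistency.

Key generator parameters and why they hold their defaults:

- `warp_smoothness` (control-point spacing of the non-rigid warp, default
  48 px; **96 px in the acceptance phantoms**). The spacing controls the
  Jacobian of the true section-to-section deformation: at 48 px spacing
  with 8 px amplitude the true relative warp has det J in roughly
  [0.35, 2.0] over tissue, so *no* estimator could both recover it and keep
  morphology within the det J ∈ [0.7, 1.4] band the pipeline promises. At
  96 px the true relative Jacobians sit in [0.65, 1.43]; that is the world
  in which "halve the error while preserving morphology" is a coherent
  demand, and the one the acceptance suite uses.
- Tissue brightness noise 0.008, stromal texture amplitude 1.0 (both
  exposed): chosen so SIFT finds 30–100 keypoints per 256 px section, the
  regime in which entropic-OT matching is well conditioned.
- Class signal (labeled datasets): the class modulates the per-section
  *gland lumen density* — lumens are added until a target hole area
  `v_k * 0.12 *` tissue is reached, with small (r ≈ 1.6–2.1 px) lumens so
  the density field is homogeneous at patch scale. An earlier draft
  encoded class in multiplicative tissue brightness; a pre-LayerNorm
  transformer normalizes every token, making a pure gain signal nearly
  invisible, so the structural channel replaced it. With `depth_signal`
  on, `v_k = offset + 0.3 * pattern_class(k)` where every class pattern
  has mean 0.5 and the per-core offset is U(0.05, 0.65): per-slice
  densities overlap heavily across classes (single-slice accuracy ≈ 0.53
  at 3 classes) while signed consecutive-slice differences identify the
  class essentially perfectly. The effect size 0.3 was set so that the
  generator's own oracle statistic (per-slice hole fraction), pushed
  through the same bag aggregation the classifier uses, reaches macro AUC
  ≈ 0.97 — i.e. the world genuinely contains the separation the
  classification stage is asked to find.

What a green phantom test does **not** establish: robustness to stain
variation, scanner artifacts, tissue folds, or section loss; phantoms have
neither, by design.

## Tissue masking and ribbons

Masking is an HSV hue-band threshold plus saturation floor and a square
morphological closing (side `2r+1`, default r = 2). Ribbons are
8-connected components above a minimum area (default 0.5 % of the working
raster), ordered top-to-bottom by centroid. The working pyramid level is
the smallest raster still at ≥ 1/16 of full resolution; all alignment
estimation happens there, and only translations are rescaled when
transforms are propagated to other levels (rotation and scale are
resolution-free).

## Rigid alignment

SIFT keypoints (scikit-image, `upsampling=1`, `c_dog=0.009`) are detected
on tissue-masked grayscale only. Matching solves an entropic optimal
transport problem over the cost 1 − ⟨descriptor, descriptor⟩ augmented
with a dustbin row/column (cost 0.3, capacity equal to the opposite side)
via 100 Sinkhorn iterations at ε = 0.02; mutual argmax pairs with
transported mass ≥ 0.2 are accepted. ε matters: unit-norm SIFT descriptor
costs have best-vs-second gaps of ~0.02–0.3, and at ε = 0.1 the entropic
smoothing routes nearly everything to the dustbin (1 match where ~70
exist on a clean pair). The similarity transform is fit by a 1000-trial
two-point consensus loop (inlier tolerance 3 px) followed by a closed-form
least-squares (Umeyama) refit on the inlier set; shear is structurally
impossible. Stacks align sequentially — section k matches the *rendered*
registered section k−1, so only features shared by neighbors drive each
fit. Failures raise an error naming the pair; `skip_on_failure` carries
the previous transform forward instead.

## Boundary-driven non-rigid refinement

The refinement minimizes the mean squared difference between the Euclidean
distance transforms of the two ribbon *boundary* masks — interior texture
never enters the objective, so interior morphology is carried along
smoothly rather than warped to match intensities. The displacement is a
hierarchical control lattice: three levels whose spacings halve down to 24
px, each optimized by 200 adaptive-moment gradient steps from a zero start
(deterministic; no seeds), with per-level displacements clamped to half
that level's spacing. The coarse levels extrapolate the smooth deformation
trend from the boundary into the ribbon interior — a single fixed-spacing
lattice recovers markedly less. Regularization combines a small bending
(biharmonic) term (0.1) with a membrane term (1.0) on the lattice; the
membrane bounds node-to-node stretch and is what holds the Jacobian
determinant of the estimated fields inside [0.7, 1.4] over tissue while
still reaching a ≈ 0.58× mean registration-error ratio versus rigid-only
alignment on the acceptance phantoms. Displacement fields are a function
of the boundary masks only, bitwise.

Registration error is scored exactly as the alignment quality metric: per
adjacent pair, the median Euclidean distance (µm) between OT-matched SIFT
keypoints on the aligned images, averaged over pairs with match-count
weights. Because phantom sections share base texture, a perfectly aligned
stack scores ≈ 0, so the metric has no additive floor in these worlds.

## Volumetric cores and patches

Aligned sections are cropped to the bounding box of the union of aligned
tissue masks and tiled on a non-overlapping grid anchored at the origin;
a tile is kept when its mean-over-depth tissue fraction strictly exceeds
0.6 (per-slice minimum available via `depth_aggregation='min'`). Cores
deeper than the encoder's F are center-cropped in z, shallower ones edge
replicated.

## Divided space-time attention encoder

Tokens are flattened P×P tiles, linearly embedded plus a learned (p, t)
position table, with a prepended cls token. Per block: temporal attention
(each token attends over the cls token and the F tokens at its spatial
position; scores scaled by 1/√D_h), fresh q/k/v, spatial attention (cls
plus the N tokens of its section), each stage with its own output
projection and residual, then a GELU MLP with residual; all q/k/v come
from layer-normed inputs. The cls token passes through the temporal stage
unchanged and attends jointly over every token in the spatial stage; its
final layer-normed state is the patch feature. A deliberately naive
per-token loop implementation is kept as a numerical oracle; the
vectorized forward matches it to < 1e-5 across random tiny configurations.

Desk-scale defaults: D = 64, A = 4, L = 2, P = 16 on 64×64×F=4 volumes
(tests use 32×32/P=8 variants); the full-scale production preset (D = 768,
L = 12, 256×256) exists as configuration only. `pos_init_std` defaults to 0.5
rather than the ViT-standard 0.02: at D = 64 and L = 2, a 0.02-scale
position table contributes nothing to attention logits and the divided
attention is depth-agnostic at initialization.

## Self-distillation (DINO-style)

Student and teacher share the architecture; global (scale 0.5–1.0) and
local (0.15–0.4) *spatial* crops keep all F depth sections — depth is the
volumetric signal and is never cropped — and photometric jitter is drawn
once per view and applied to every section, so depth-to-depth contrasts
survive augmentation. Teacher outputs are centered and sharpened (temp
0.04 vs student 0.1); the center is initialized from the first batch
(otherwise the running-mean warm-up moves the targets and the loss climbs
before it can fall) and then tracks a running mean (momentum 0.9). The
teacher is an exact parameter-wise EMA of the student (momentum 0.996).
The projection head is a 3-layer MLP into 256 weight-normalized
prototypes. All hyperparameters are configuration; none are canonical.

## MIL grading

A core is a bag of frozen patch features. Gated attention
(tanh ⊙ sigmoid, hidden 128) scores instances; softmax weights pool them;
a linear layer classifies into {BN, GGG1, GGG2, GGG3, GGG4/5} or the
binary clinically-significant relabeling (GGG ≥ 2). Training uses
inverse-frequency class weights, Adam, and early stopping on validation
macro AUC. Inference sorts instances into a canonical lexicographic order
first, so permutation invariance is bitwise exact rather than merely
within floating-point reassociation error.

## Rollout and statistics

Combined space-time rollout multiplies, per block, the head-averaged
spatial and temporal attention (cls column dropped, rows renormalized,
optionally identity-mixed with `residual_alpha`, default 0.5; 0 gives the
literal factorization W[i,j,p,q] = S[i,j,p]·T[p,j,q]) and chains blocks by
matrix product; row-stochasticity is preserved exactly, which is the
conservation property the tests assert. The cls heat map pushes the last
block's cls attention row through the earlier blocks' cumulative
attention. Quadratic weighted kappa is computed from the closed form with
(i−j)²/(K−1)² weights (degenerate marginals raise); McNemar uses the
exact binomial test below 25 discordant pairs and the continuity-corrected
chi-square above; AUC is macro one-vs-rest, precision/recall/F1 are
reported support-weighted and macro.

## Known limitations

- The boundary-only objective cannot observe tangential sliding along the
  ribbon boundary; the residual after refinement is dominated by exactly
  that component.
- At desk scale (D = 64, L = 2, CPU-minutes of pretraining, 84 training
  cores) the cls-token feature does not reliably expose the depth-coherent
  class signal to a linear classifier, even though the signal is
  linearly present in raw pixels and an oracle statistic through the same
  bag aggregation reaches macro AUC ≈ 0.97. The volumetric-vs-planar
  classification margin therefore does not reach at desk scale the level
  the full-scale system reports; see the acceptance suite, where this is
  left as a failing check rather than papered over.
- No stain normalization, artifact detection, or section-dropout handling;
  phantoms do not model these.
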