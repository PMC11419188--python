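# vcore

Volumetric cores from serial-section histology.

Prostate biopsy cores are three-dimensional, but routine pathology cuts
them into serial 2D sections and grades the slices. `vcore` reconstructs a
**volumetric core** — a co-registered z-stack — from the routinely scanned
2D whole-slide images, then grades it with a deep pipeline that sees the
tissue volumetrically:

1. **Tissue masking & ribbon extraction** — HSV hue-band thresholding with
   morphological closing; connected components above a minimum area are the
   individual serial sections ("ribbons").
2. **Morphology-preserving alignment** — SIFT keypoints matched by an
   entropic optimal-transport assignment with a dustbin for unmatchable
   points; a robust consensus fit constrained to *similarity* transforms
   (rotation θ, isotropic scale s, translation t — never shear), applied
   sequentially along the stack; then a **boundary-driven non-rigid
   refinement** that aligns ribbon outlines via their distance transforms
   over a hierarchical control lattice, so interior gland morphology is
   carried smoothly instead of being warped to match intensities.
   Alignment quality is the match-count-weighted mean over adjacent pairs
   of the median matched-keypoint distance (µm).
3. **Volumetric patching** — non-overlapping F×256×256 (desk scale:
   F×32×32) patches with strictly more than 60 % tissue.
4. **Divided space-time attention encoder** — per block, temporal
   attention across depth at fixed spatial position, then spatial
   attention within a section (softmax of qᵀk/√D_h per head), pretrained
   by DINO-style self-distillation with a momentum teacher; spatial-only
   crops keep every depth section.
5. **Attention-based MIL** — a core is a bag of frozen patch features;
   gated attention pools instances into a Gleason Grade Group (or binary
   clinically-significant, GGG ≥ 2) prediction. Space-time attention
   rollout W[i,j,p,q] = S[i,j,p]·T[p,j,q] and MIL attention maps provide
   interpretability; evaluation ships macro AUC, weighted P/R/F1,
   quadratic weighted kappa and McNemar's paired test.

No public cohort accompanies the method, so the package includes a
first-class phantom generator: serial sections with known similarity
transforms, smooth warps, exact point correspondences, and labeled
datasets whose class signal lives only in the *depth coherence* of gland
density — decodable from consecutive sections jointly, nearly invisible in
any single section.

## Worked example

```python
import numpy as np
from vcore.phantom import PhantomSpec, generate_phantom_stack
from vcore.rigid import align_stack_rigid
from vcore.nonrigid import align_stack_nonrigid, registration_error
from vcore import imageops

spec = PhantomSpec(image_size=(256, 256), n_sections=6,
                   max_rotation=8, max_translation=10, max_scale_dev=0.04,
                   warp_amplitude=8, warp_smoothness=96, seed=1)
stack, truth = generate_phantom_stack(spec)

rigid = align_stack_rigid(stack.sections, seed=1)
imgs = [imageops.to_uint8(im) for im in rigid.aligned_images]
print(f"rigid:     {registration_error(imgs, 2.0, masks=rigid.aligned_masks).core_error:.2f} um")

images, masks, fields = align_stack_nonrigid(rigid)
imgs = [imageops.to_uint8(im) for im in images]
print(f"non-rigid: {registration_error(imgs, 2.0, masks=masks).core_error:.2f} um")
```

prints (seed 1):

```
rigid:     3.99 um
non-rigid: 2.81 um
```

— the similarity stage brings the warped six-section stack to ≈ 4 µm
(2 px at the phantom's 2 µm/px), and the boundary-driven refinement
removes a further share of the residual deformation while keeping every
displacement field's Jacobian determinant within [0.7, 1.4] over tissue
(no gland-shape distortion). Across the ten acceptance phantoms the mean
non-rigid/rigid error ratio is ≈ 0.58.

A CLI covers the same pipeline from the shell: `vcore simulate`,
`vcore mask`, `vcore ribbons`, `vcore align rigid|nonrigid|score`,
`vcore patch`, `vcore pretrain`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the pipeline from scratch on seeded phantoms — rigid + non-rigid
alignment with registration-error scoring, patch extraction, a short
self-distillation run, MIL training on frozen features, and the evaluation
statistics — printing each stage's numbers and writing the JSON report.

See `docs/methods.md` for the models, parameter choices, what the phantoms
do and do not establish, and known desk-scale limitations.
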