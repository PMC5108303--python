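# hippomorph

Surface-based shape morphometry, simplified tensor-based morphometry (TBM)
and Cavalieri stereology for subcortical structures segmented on anisotropic
MRI — with a synthetic-cohort generator that gives every stage a recoverable
ground truth.

## Who this is for

Preclinical neuroimaging studies often segment a structure (here modelled on
the rodent hippocampus) on 2-D multi-slice acquisitions with fine in-plane
resolution but thick slices, then ask whether an intervention changed the
structure's **size** (volume) or its **shape** (localized surface
deformation).  `hippomorph` implements the three complementary analyses such
a study uses:

1. **Elastic surface-based shape analysis.** Binary masks are converted to
   smooth surfaces by interpolating per-slice 2-D signed distance transforms
   between slices (correcting the stair-step artifact of thick slices), a
   reference surface is brought into dense correspondence with every subject
   by iterated normal-ray correspondence search, least-squares rigid
   alignment (SVD/Kabsch) and a stiffness-modulated elastic step (60
   iterations, stiffness β decreasing), and per-vertex displacement vectors
   relative to the population-average surface are tested with a two-sample
   Hotelling's T² whose null distribution comes from subject-level
   permutation, FDR-controlled at q = 0.05 (Benjamini–Hochberg).  A vertex's
   correspondence is accepted only if the source and target normals agree
   within 60° (dot product > 0.5) and no earlier intersection blocks the
   ray.  Volume can be removed as a factor by rescaling every surface to
   unit volume before testing.
2. **TBM.** A mean template is built by iterative 6-d.f. rigid alignment;
   multi-resolution diffeomorphic demons registration maps it to each
   subject; the log-Jacobian determinant of each deformation field is tested
   voxel-wise (one-way ANOVA over three groups plus pairwise t tests,
   FDR-corrected per contrast) inside the structure mask, which can also be
   propagated to subject space via the inverse field.
3. **Cavalieri stereology.** Volume from systematic sections with point
   counting, `V = t_eff · (a/p) · ΣP`, with the Gundersen–Jensen (m = 1)
   coefficient of error, plus a virtual probe that applies the estimator to
   masks so its unbiasedness can be verified.

## Worked example

```python
import numpy as np
import hippomorph as hm
from hippomorph.synthetic import deformed_level_set

grid = hm.desk_grid()                      # 96 x 96 x 40 at (0.25, 0.25, 0.5) mm
mask = hm.make_template_mask(grid)         # curved-tube structure, ~212 mm^3
source = hm.extract_surface(deformed_level_set(mask, []), decimate_to=1300)

site = tuple(source.vertices[np.argmax(source.vertices[:, 1])])
effect = hm.EffectSpec(site, radius=2.5, amplitude=0.4, group="")
_, truth = hm.apply_local_deformation(mask, effect)
target = hm.extract_surface(deformed_level_set(mask, [effect]), decimate_to=2600)

registered, error, rigid = hm.register(source, target)
recovered = np.einsum("vi,vi->v", registered.vertices - source.vertices,
                      source.vertex_normals())
r = np.corrcoef(recovered, truth.normal_displacement(source.vertices))[0, 1]
print(f"mean geometric error {error.mean*1000:.2f} um, truth correlation r={r:.3f}")
```

prints

```
mean geometric error 0.83 um, truth correlation r=0.948
```

i.e. after registration the deformed surface matches the target to
sub-micrometre mean distance, and the recovered per-vertex displacement
field correlates at r = 0.95 with the planted 0.4 mm deformation.  The
scripts in `examples/` walk through each capability (cohort synthesis,
stair-step-corrected surfaces, registration, vertex statistics, TBM,
stereology) and print the numbers they compute.

A thin CLI wraps the pipeline for shell use:

```bash
morph shape --config run.yaml --seed 3     # synthesize -> surfaces -> stats
morph tbm   --config run.yaml
morph stereo --config run.yaml
```

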