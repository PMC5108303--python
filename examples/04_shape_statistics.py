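"""Vertex-wise permutation Hotelling's T2 on corresponded surfaces.

Builds a vertex-level cohort (two groups, one carrying a 0.4 mm outward
bump), tests every vertex, applies BH-FDR and reports how well the
significant set localizes the planted effect — with and without unit-volume
rescaling, which removes size as a factor.
"""

import numpy as np
import trimesh

import hippomorph as hm
from hippomorph.stats import StatsConfig

tm = trimesh.creation.icosphere(subdivisions=3, radius=4.0)
mesh = hm.SurfaceMesh(np.asarray(tm.vertices) + 8.0, np.asarray(tm.faces))
site = tuple(mesh.vertices[np.argmax(mesh.vertices[:, 2])])
effect = hm.EffectSpec(site, radius=2.5, amplitude=0.4, group="B")

meshes, labels, truth = hm.make_vertex_cohort(
    mesh, (effect,), n_per_group=8, subject_noise=0.05, seed=7,
)
average = mesh.with_vertices(np.mean([m.vertices for m in meshes], axis=0))
disp = hm.displacement_vectors(average, meshes, labels)
res = hm.permutation_test(disp, "A", "B", StatsConfig(n_permutations=5000, seed=7))

support = np.abs(truth["B"]) > 0
sig = res.significant
dice = 2 * np.sum(sig & support) / (sig.sum() + support.sum())
print(f"{sig.sum()} of {mesh.n_vertices} vertices FDR-significant at q=0.05 "
      f"({res.metadata['notice']})")
print(f"overlap with the planted support: Dice {dice:.2f}; "
      f"signed displacement at significant vertices is "
      f"{'outward' if np.median(res.signed_mm[sig]) > 0 else 'inward'} "
      f"(median {np.median(res.signed_mm[sig]):+.2f} mm)")

unit = [hm.normalize_volume(m, about=average.centroid) for m in meshes]
avg_unit = hm.normalize_volume(average, about=average.centroid)
res_unit = hm.permutation_test(
    hm.displacement_vectors(avg_unit, unit, labels), "A", "B",
    StatsConfig(n_permutations=5000, seed=7),
)
agree = 2 * np.sum(sig & res_unit.significant) / (
    sig.sum() + res_unit.significant.sum()
)
print(f"after volume normalization (every surface rescaled to volume 1): "
      f"{res_unit.significant.sum()} significant, map agreement Dice {agree:.2f}")
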