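"""Recover a known 0.4 mm surface deformation by elastic registration.

Registers the template surface to an exactly-deformed copy and correlates
the recovered per-vertex normal displacement with the planted field.
"""

import numpy as np

import hippomorph as hm
from hippomorph.synthetic import deformed_level_set

grid = hm.desk_grid()
mask = hm.make_template_mask(grid)
source = hm.extract_surface(deformed_level_set(mask, []), decimate_to=1300)

site = tuple(source.vertices[np.argmax(source.vertices[:, 1])])
effect = hm.EffectSpec(site, radius=2.5, amplitude=0.4, group="")
_, truth = hm.apply_local_deformation(mask, effect)
target = hm.extract_surface(deformed_level_set(mask, [effect]), decimate_to=2600)

registered, error, rigid = hm.register(source, target, hm.RegistrationConfig())

recovered = np.einsum("vi,vi->v", registered.vertices - source.vertices,
                      source.vertex_normals())
planted = truth.normal_displacement(source.vertices)
r = np.corrcoef(recovered, planted)[0, 1]
print(f"final mean geometric error: {error.mean * 1000:.2f} um "
      f"(max {error.max * 1000:.1f} um)")
print(f"truth correlation r = {r:.3f}  "
      f"(recovered peak {recovered.max():.2f} mm vs planted 0.40 mm)")
print("the error map measures surface mismatch; the correlation measures "
      "whether each vertex tracked its anatomical location")
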