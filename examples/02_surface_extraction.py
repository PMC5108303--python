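"""Stair-step-corrected surface extraction from an anisotropic mask.

Compares a surface meshed from the inter-slice-interpolated distance field
with one meshed from naive nearest-slice replication: the interpolated
surface lies much closer to the analytic sphere it discretizes.
"""

import numpy as np

import hippomorph as hm

grid = hm.GridSpec((56, 56, 56), (0.25, 0.25, 0.25))
sphere = hm.make_template_mask(grid, curvature=0.0, length=0.0, radius=5.0)
# simulate a 0.75 mm slice acquisition by subsampling z
anis = hm.ImageVolume(sphere.data[:, :, ::3], (0.25, 0.25, 0.75), sphere.origin)
center = anis.grid.center

corrected = hm.extract_surface(hm.interslice_distance_interpolation(anis, 0.25))
stair = hm.extract_surface(
    hm.signed_distance_3d(
        hm.ImageVolume(np.repeat(anis.data, 3, axis=2), (0.25, 0.25, 0.25),
                       anis.origin)
    )
)

for name, mesh in (("interpolated", corrected), ("stair-step", stair)):
    err = np.abs(np.linalg.norm(mesh.vertices - center, axis=1) - 5.0)
    print(f"{name:>13}: {mesh.n_vertices} vertices, "
          f"volume {hm.mesh_volume(mesh):.1f} mm^3 (analytic 523.6), "
          f"max radial error {err.max():.3f} mm")
print("the interpolated surface passes through the acquired slice contours "
      "while removing the stair artifact between slices")
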